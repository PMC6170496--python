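"""Dispersion shrinkage, Wald/logistic position tests, BH, DMP/DMR calling."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import epitar as ep
from epitar.dmp import call_dmrs

from conftest import make_united, simulate_betabin


class TestDispersion:
    def test_identical_replicates_give_small_shrunk_phi(self):
        M = np.full((200, 3), 50.0)
        C = np.full((200, 3), 100.0)
        ut = make_united(M, C, M, C)
        d = ep.estimate_dispersion(ut)
        assert np.nanmean(d.phi_raw) < 0.01
        assert (d.phi < 0.02).all()

    def test_identical_positions_collapse_to_raw(self):
        # zero across-position variance -> zero prior variance -> phi = prior = raw
        M = np.tile([3.0, 7.0, 5.0], (50, 1))
        C = np.full((50, 3), 10.0)
        ut = make_united(M, C, M, C)
        d = ep.estimate_dispersion(ut)
        assert d.prior_var == 0.0
        assert np.allclose(d.phi, d.phi[0])

    def test_recovers_generative_phi(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.05, 0.95, 5000)
        Ma, Ca, _ = simulate_betabin(5000, 3, 0.1, p=p, rng=rng)
        Mb, Cb, _ = simulate_betabin(5000, 3, 0.1, p=p, rng=rng)
        d = ep.estimate_dispersion(make_united(Ma, Ca, Mb, Cb))
        assert np.mean(d.phi) == pytest.approx(0.1, abs=0.02)

    def test_shrunk_lies_between_raw_and_prior(self):
        rng = np.random.default_rng(3)
        Ma, Ca, _ = simulate_betabin(500, 3, 0.05, rng=rng)
        Mb, Cb, _ = simulate_betabin(500, 3, 0.05, rng=rng)
        d = ep.estimate_dispersion(make_united(Ma, Ca, Mb, Cb))
        lo = np.minimum(d.phi_raw, d.prior_mean) - 1e-12
        hi = np.maximum(d.phi_raw, d.prior_mean) + 1e-12
        assert ((d.phi >= lo) & (d.phi <= hi)).all()


class TestWaldTest:
    def test_identical_groups_null(self):
        d, p = ep.test_position([[5.0, 6.0]], [[10.0, 10.0]],
                                [[5.0, 6.0]], [[10.0, 10.0]], 0.0)
        assert d[0] == 0.0 and p[0] == 1.0

    def test_phi_zero_equals_two_proportion_z(self):
        # closed-form oracle: delta = 0.7, z = 0.7/sqrt(.85*.15/20 + .15*.85/20)
        d, p = ep.test_position([[9.0, 8.0]], [[10.0, 10.0]],
                                [[1.0, 2.0]], [[10.0, 10.0]], 0.0)
        z = 0.7 / np.sqrt(0.85 * 0.15 / 20 + 0.15 * 0.85 / 20)
        assert d[0] == pytest.approx(0.7)
        assert p[0] == pytest.approx(2 * stats.norm.sf(z), rel=1e-12)

    def test_dispersion_inflates_variance(self):
        M = np.array([[9.0, 8.0]])
        C = np.array([[10.0, 10.0]])
        _, p0 = ep.test_position(M, C, [[1.0, 2.0]], C, 0.0)
        _, p1 = ep.test_position(M, C, [[1.0, 2.0]], C, 0.2)
        assert p1[0] > p0[0]

    def test_delta_antisymmetric_p_invariant_under_swap(self):
        rng = np.random.default_rng(4)
        Ma, Ca, _ = simulate_betabin(100, 3, 0.05, rng=rng)
        Mb, Cb, _ = simulate_betabin(100, 3, 0.05, rng=rng)
        d1, p1 = ep.test_position(Ma, Ca, Mb, Cb, 0.05)
        d2, p2 = ep.test_position(Mb, Cb, Ma, Ca, 0.05)
        np.testing.assert_allclose(d1, -d2)
        np.testing.assert_allclose(p1, p2)

    def test_boundary_proportions_use_pseudocounts(self):
        d, p = ep.test_position([[10.0, 10.0]], [[10.0, 10.0]],
                                [[0.0, 0.0]], [[10.0, 10.0]], 0.0)
        assert np.isfinite(p[0]) and p[0] < 1e-6
        assert d[0] == 1.0

    def test_zero_group_coverage_rejected(self):
        with pytest.raises(ValueError, match="coverage"):
            ep.test_position([[0.0]], [[0.0]], [[1.0]], [[2.0]], 0.0)


class TestLogisticBackend:
    def test_identical_groups_null(self):
        d, p = ep.test_position_logistic([[5.0, 6.0]], [[10.0, 10.0]],
                                         [[5.0, 6.0]], [[10.0, 10.0]])
        assert d[0] == 0.0 and p[0] == 1.0

    def test_agrees_with_wald_on_toy_table(self):
        Ma, Ca = [[9.0, 8.0]], [[10.0, 10.0]]
        Mb, Cb = [[1.0, 2.0]], [[10.0, 10.0]]
        dw, pw = ep.test_position([[9.0, 8.0]], Ca, [[1.0, 2.0]], Cb, 0.0)
        dl, pl = ep.test_position_logistic(Ma, Ca, Mb, Cb)
        assert dl[0] == pytest.approx(dw[0])
        assert np.log10(pl[0]) == pytest.approx(np.log10(pw[0]), rel=0.10)

    def test_matches_statsmodels_glm_components(self):
        # independent oracle for the closed form: statsmodels binomial GLM
        # gives the group coefficient, its (unscaled) SE and the Pearson chi2
        import statsmodels.api as sm
        Ma, Ca = np.array([[7.0, 5.0, 6.0]]), np.array([[10.0, 9.0, 12.0]])
        Mb, Cb = np.array([[2.0, 3.0, 1.0]]), np.array([[11.0, 10.0, 8.0]])
        dl, pl = ep.test_position_logistic(Ma, Ca, Mb, Cb)
        y = np.column_stack([np.r_[Ma[0], Mb[0]],
                             np.r_[Ca[0] - Ma[0], Cb[0] - Mb[0]]])
        X = sm.add_constant(np.r_[np.ones(3), np.zeros(3)])
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        beta, se = fit.params[1], fit.bse[1]
        scale = fit.pearson_chi2 / fit.df_resid
        z2 = beta**2 / (se**2 * scale)
        assert pl[0] == pytest.approx(stats.chi2.sf(z2, 1), rel=1e-3)
        assert dl[0] == pytest.approx(Ma.sum() / Ca.sum() - Mb.sum() / Cb.sum())

    def test_separation_handled_by_continuity_adjustment(self):
        d, p = ep.test_position_logistic([[10.0, 10.0]], [[10.0, 10.0]],
                                         [[0.0, 1.0]], [[10.0, 10.0]])
        assert np.isfinite(p[0]) and 0 < p[0] < 0.05

    def test_direction_and_calls_agree_with_wald_on_panel(self):
        # well-separated effects: the backends must agree on direction always
        # and on the call itself away from the decision boundary
        rng = np.random.default_rng(6)
        p0 = rng.uniform(0.15, 0.45, 500)
        shift = np.where(rng.random(500) < 0.3, 0.5, 0.0)
        p1 = p0 + shift
        Ma, Ca, _ = simulate_betabin(500, 3, 0.02, p=p1, cov_mean=50, rng=rng)
        Mb, Cb, _ = simulate_betabin(500, 3, 0.02, p=p0, cov_mean=50, rng=rng)
        ut = make_united(Ma, Ca, Mb, Cb)
        w = ep.call_dmps(ut, backend="wald")
        l = ep.call_dmps(ut, backend="logistic")
        nonzero = (w["delta"] != 0).to_numpy()
        assert (w["direction"][nonzero] == l["direction"][nonzero]).all()
        agree = (w["significant"] == l["significant"]).mean()
        assert agree >= 0.95


class TestBH:
    def test_single_p(self):
        assert ep.adjust_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_applied_step_up(self):
        np.testing.assert_allclose(ep.adjust_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert (ep.adjust_fdr([1.0, 1.0, 1.0]) == 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ep.adjust_fdr([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_matches_step_up_oracle_and_preserves_order(self, pvals):
        p = np.asarray(pvals)
        q = ep.adjust_fdr(p)
        # brute-force BH: q_(i) = min_{j>=i} m p_(j) / j, capped at 1
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        ranked = p[order] * m / np.arange(1, m + 1)
        oracle = np.minimum.accumulate(ranked[::-1])[::-1]
        oracle = np.minimum(oracle, 1.0)
        np.testing.assert_allclose(q[order], oracle, atol=1e-12)
        assert ((p[:, None] <= p[None, :]) <= (q[:, None] <= q[None, :] + 1e-12)).all()


class TestCallDMPs:
    def test_alpha_zero_empty(self):
        rng = np.random.default_rng(7)
        Ma, Ca, _ = simulate_betabin(100, 3, 0.0, rng=rng)
        Mb, Cb, _ = simulate_betabin(100, 3, 0.0, rng=rng)
        out = ep.call_dmps(make_united(Ma, Ca, Mb, Cb), alpha=0.0)
        assert out["significant"].sum() == 0

    def test_direction_matches_delta_sign(self):
        rng = np.random.default_rng(8)
        Ma, Ca, _ = simulate_betabin(200, 3, 0.02, rng=rng)
        Mb, Cb, _ = simulate_betabin(200, 3, 0.02, rng=rng)
        out = ep.call_dmps(make_united(Ma, Ca, Mb, Cb))
        assert ((out["delta"] > 0) == (out["direction"] == "hyper")).all()

    def test_explicit_group_order_flips_delta(self):
        rng = np.random.default_rng(9)
        Ma, Ca, _ = simulate_betabin(50, 3, 0.0, rng=rng)
        Mb, Cb, _ = simulate_betabin(50, 3, 0.0, rng=rng)
        ut = make_united(Ma, Ca, Mb, Cb)
        ab = ep.call_dmps(ut, order=("A", "B"))
        ba = ep.call_dmps(ut, order=("B", "A"))
        np.testing.assert_allclose(ab["delta"], -ba["delta"])

    def test_null_call_fraction_bounded(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(0.05, 0.95, 5000)
        Ma, Ca, _ = simulate_betabin(5000, 3, 0.05, p=p, rng=rng)
        Mb, Cb, _ = simulate_betabin(5000, 3, 0.05, p=p, rng=rng)
        out = ep.call_dmps(make_united(Ma, Ca, Mb, Cb))
        frac = out["significant"].mean()
        assert frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 5000)


class TestCallDMRs:
    def _region_table(self, deltas, positions, reps=3, cov=200.0):
        """High-coverage table with exact fraction differences at positions."""
        n = len(positions)
        base = np.full((n, reps), 0.4)
        Ca = Cb = np.full((n, reps), cov)
        Ma = (base + np.asarray(deltas)[:, None]) * cov
        Mb = base * cov
        ut = make_united(Ma, Ca, Mb, Cb)
        ut.sites["pos"] = positions
        return ut

    def test_no_qualifying_positions_empty(self):
        ut = self._region_table([0.0] * 5, [100, 120, 140, 160, 180])
        assert len(call_dmrs(ut)) == 0

    def test_toy_track_single_region(self):
        # five qualifying CGs within 80 bp, mean delta 0.25 -> one DMR
        ut = self._region_table([0.25] * 5, [100, 120, 140, 160, 180])
        out = call_dmrs(ut)
        assert len(out) == 1
        r = out.iloc[0]
        assert (r["start"], r["end"]) == (100, 180)
        assert r["n_significant"] == 5
        assert r["mean_delta"] == pytest.approx(0.25, abs=0.02)
        assert r["direction"] == "hyper"

    def test_weak_region_filtered_by_min_diff(self):
        # positions qualify at delta 0.1 cut but overall difference < 10%
        ut = self._region_table([0.1, 0.1, 0.1, 0.1, 0.1],
                                [100, 120, 140, 160, 180])
        out = call_dmrs(ut, min_diff=0.12)
        assert len(out) == 0

    def test_gap_splits_regions(self):
        ut = self._region_table([0.3] * 6, [100, 130, 160, 400, 430, 460])
        out = call_dmrs(ut)
        assert len(out) == 2
        assert list(out["start"]) == [100, 400]
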