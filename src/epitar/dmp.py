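"""Per-position differential-methylation testing with over-dispersion handling.

Replicate methylation counts at a cytosine are modelled as beta-binomial:
M_i ~ BetaBin(C_i, p, phi), with Var(M_i/C_i) = p(1-p)[1 + (C_i-1)phi]/C_i.
The default backend estimates a per-position dispersion phi by the method of
moments, shrinks it toward an empirical prior fitted across positions
(dispersion-shrinkage in the DSS tradition), and tests the group difference of
pooled methylation fractions with a Wald statistic.  A logistic-regression
backend with a Pearson-chi-square scale factor is provided as an alternative
with the same interface.

q-values are Benjamini-Hochberg, computed per context and per comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import UnitedTable

PHI_MAX = 0.99


@dataclass
class DispersionEstimate:
    """Per-position beta-binomial dispersions, raw and shrunk, plus the prior.

    ``prior_log_mean``/``prior_log_var`` describe the moment-matched log-normal
    with the prior's natural-scale mean and variance.
    """

    phi_raw: np.ndarray
    phi: np.ndarray
    prior_mean: float
    prior_var: float
    prior_log_mean: float
    prior_log_var: float
    weight: np.ndarray          # shrinkage weight on the raw estimate

    def __post_init__(self) -> None:
        if (self.phi < 0).any() or (self.phi >= 1).any():
            raise ValueError("shrunk phi must lie in [0, 1)")


def _group_indices(united: UnitedTable, design: dict[str, str] | None,
                   order: tuple[str, str] | None = None):
    design = design or united.design
    groups: dict[str, list[int]] = {}
    for j, s in enumerate(united.samples):
        if s not in design:
            raise ValueError(f"sample {s} missing from design")
        groups.setdefault(design[s], []).append(j)
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {sorted(groups)}")
    if order is not None:
        if set(order) != set(groups):
            raise ValueError(f"order {order} does not match groups {sorted(groups)}")
        ga, gb = order
    else:
        ga, gb = sorted(groups)
    return ga, np.asarray(groups[ga]), gb, np.asarray(groups[gb])


def _moment_phi(M: np.ndarray, C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unclipped per-position MoM dispersion within one group, and df used."""
    with np.errstate(invalid="ignore", divide="ignore"):
        phat = M / C
        n = np.sum(~np.isnan(phat), axis=1)
        pbar = np.nansum(M, axis=1) / np.nansum(C, axis=1)
        s2 = np.nanvar(phat, axis=1, ddof=1)
        mean_inv_c = np.nanmean(1.0 / C, axis=1)
        pq = pbar * (1.0 - pbar)
        denom = pq * (1.0 - mean_inv_c)
        phi = (s2 - pq * mean_inv_c) / denom
    phi[(n < 2) | ~np.isfinite(phi)] = np.nan
    return phi, np.maximum(n - 1, 0)


def estimate_dispersion(
    united: UnitedTable,
    design: dict[str, str] | None = None,
) -> DispersionEstimate:
    """Shrunken per-position dispersions from replicate counts.

    Raw per-group moment estimates are combined with (n_g - 1) weights; the
    empirical prior mean m and variance v come from the across-position moments
    of the raw estimates with the average sampling variance subtracted.  Each
    position is shrunk by precision weighting, w = v / (v + sampling var), on
    the natural scale; positions with no usable raw estimate sit at the prior
    mean.  Shrinkage acts on the unclipped raw value (so the prior mean is
    recovered on average) and the result is clipped to [0, PHI_MAX].
    """
    _, ia, _, ib = _group_indices(united, design)
    phis, dfs = [], []
    for idx in (ia, ib):
        phi_g, df_g = _moment_phi(united.M[:, idx], united.C[:, idx])
        phis.append(phi_g)
        dfs.append(df_g)
    df = dfs[0] + dfs[1]
    with np.errstate(invalid="ignore"):
        num = np.nansum([dfs[0] * phis[0], dfs[1] * phis[1]], axis=0)
        den = (dfs[0] * ~np.isnan(phis[0]) + dfs[1] * ~np.isnan(phis[1])).astype(float)
        phi_raw = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)

    ok = np.isfinite(phi_raw)
    if not ok.any():
        m, v = 0.0, 0.0
    else:
        m = float(np.mean(phi_raw[ok]))
        v_obs = float(np.var(phi_raw[ok]))
        # sampling variance of a variance-based moment estimate: ~ 2 E[phi_hat]^2
        # per df, on the scale of (1/(C-1) + phi)
        cbar = np.nanmean(np.where(np.isfinite(united.C), united.C, np.nan))
        scale = 1.0 / max(cbar - 1.0, 1.0) + max(m, 0.0)
        v_samp = 2.0 * scale**2 / np.maximum(df.astype(float), 1.0)
        v = max(v_obs - float(np.mean(v_samp[ok])), 0.0)
    m_c = float(np.clip(m, 1e-4, 0.5))
    if v > 0:
        cbar = np.nanmean(np.where(np.isfinite(united.C), united.C, np.nan))
        scale = 1.0 / max(cbar - 1.0, 1.0) + max(m, 0.0)
        v_samp = 2.0 * scale**2 / np.maximum(df.astype(float), 1.0)
        w = np.where(ok, v / (v + v_samp), 0.0)
    else:
        w = np.zeros(len(phi_raw))
    shrunk = np.where(ok, w * np.nan_to_num(phi_raw) + (1.0 - w) * m_c, m_c)
    shrunk = np.clip(shrunk, 0.0, PHI_MAX)
    log_mean = float(np.log(m_c**2 / np.sqrt(m_c**2 + v))) if m_c > 0 else float("-inf")
    log_var = float(np.log1p(v / m_c**2)) if m_c > 0 else 0.0
    return DispersionEstimate(
        phi_raw=np.clip(np.nan_to_num(phi_raw, nan=m_c), 0.0, PHI_MAX),
        phi=shrunk, prior_mean=m_c, prior_var=v,
        prior_log_mean=log_mean, prior_log_var=log_var, weight=w,
    )


def _group_stats(M: np.ndarray, C: np.ndarray, phi: np.ndarray):
    """Pooled fraction and beta-binomial variance of the pooled fraction.

    p_g = sum(M)/sum(C); Var(p_g) = pq * sum_i C_i (1 + (C_i - 1) phi) / (sum C)^2.
    At p in {0,1} the variance uses 0.5 pseudo-counts on M and U (variance only).
    """
    sumC = np.nansum(C, axis=1)
    sumM = np.nansum(M, axis=1)
    if (sumC <= 0).any():
        raise ValueError("zero total coverage in a group")
    p = sumM / sumC
    nrep = np.sum(~np.isnan(C), axis=1)
    p_var = (sumM + 0.5) / (sumC + 1.0)
    p_var = np.where((p > 0) & (p < 1), p, p_var)
    pq = p_var * (1.0 - p_var)
    with np.errstate(invalid="ignore"):
        wsum = np.nansum(C * (1.0 + (C - 1.0) * phi[:, None]), axis=1)
    var = pq * wsum / sumC**2
    return p, var, nrep


def test_position(
    M_a: np.ndarray, C_a: np.ndarray,
    M_b: np.ndarray, C_b: np.ndarray,
    phi: np.ndarray | float,
) -> tuple[np.ndarray, np.ndarray]:
    """Wald test of the pooled methylation-fraction difference (A - B).

    Returns (delta, two-sided normal p).  With phi = 0 the statistic reduces to
    the unpooled two-proportion z-test on the pooled counts.
    """
    M_a, C_a = np.atleast_2d(M_a).astype(float), np.atleast_2d(C_a).astype(float)
    M_b, C_b = np.atleast_2d(M_b).astype(float), np.atleast_2d(C_b).astype(float)
    phi_arr = np.broadcast_to(np.asarray(phi, dtype=float), (M_a.shape[0],)).copy()
    p_a, var_a, _ = _group_stats(M_a, C_a, phi_arr)
    p_b, var_b, _ = _group_stats(M_b, C_b, phi_arr)
    delta = p_a - p_b
    se = np.sqrt(var_a + var_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(se > 0, delta / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(delta == 0.0, 1.0, p)
    return delta, np.clip(p, 0.0, 1.0)


def test_position_logistic(
    M_a: np.ndarray, C_a: np.ndarray,
    M_b: np.ndarray, C_b: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Binomial regression of methylation on group with a dispersion scale.

    With one binary covariate the MLE fits are the group pooled proportions, so
    the coefficient is logit(p_a) - logit(p_b) with the standard binomial
    variance; the scale factor is the sum of squared Pearson residuals over the
    residual df, and the squared scaled coefficient is referred to chi-square(1).
    Separation (a group entirely at 0 or 1) gets 0.5/0.5 pseudo-counts on every
    sample of the affected position (documented continuity adjustment).
    """
    M_a, C_a = np.atleast_2d(M_a).astype(float), np.atleast_2d(C_a).astype(float)
    M_b, C_b = np.atleast_2d(M_b).astype(float), np.atleast_2d(C_b).astype(float)
    sums = lambda M, C: (np.nansum(M, axis=1), np.nansum(C, axis=1))
    sMa, sCa = sums(M_a, C_a)
    sMb, sCb = sums(M_b, C_b)
    if (sCa <= 0).any() or (sCb <= 0).any():
        raise ValueError("zero total coverage in a group")
    delta = sMa / sCa - sMb / sCb
    sep = (sMa == 0) | (sMa == sCa) | (sMb == 0) | (sMb == sCb)

    def adjust(M, C):
        M2, C2 = M.copy(), C.copy()
        M2[sep] = M2[sep] + 0.5
        C2[sep] = C2[sep] + 1.0
        return M2, C2

    M_a, C_a = adjust(M_a, C_a)
    M_b, C_b = adjust(M_b, C_b)
    sMa, sCa = sums(M_a, C_a)
    sMb, sCb = sums(M_b, C_b)
    p_a, p_b = sMa / sCa, sMb / sCb
    beta = np.log(p_a / (1 - p_a)) - np.log(p_b / (1 - p_b))
    se2 = 1.0 / (sCa * p_a * (1 - p_a)) + 1.0 / (sCb * p_b * (1 - p_b))

    def pearson(M, C, p):
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = (M - C * p[:, None]) ** 2 / (C * (p * (1 - p))[:, None])
        return np.nansum(r2, axis=1), np.sum(~np.isnan(C), axis=1)

    x2a, na = pearson(M_a, C_a, p_a)
    x2b, nb = pearson(M_b, C_b, p_b)
    df = na + nb - 2.0
    scale = np.where(df > 0, (x2a + x2b) / np.maximum(df, 1.0), 1.0)
    scale = np.where(scale > 0, scale, 1.0)
    chi2 = beta**2 / (se2 * scale)
    p = stats.chi2.sf(chi2, df=1)
    p = np.where(beta == 0.0, 1.0, p)
    return delta, np.clip(p, 0.0, 1.0)


def adjust_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_dmps(
    united: UnitedTable,
    design: dict[str, str] | None = None,
    alpha: float = 0.05,
    backend: str = "wald",
    min_per_group: int = 2,
    order: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Differentially methylated positions between two groups at q < alpha.

    Returns the full per-position table (chrom, pos, context, delta, p, q,
    direction, significant); q-values are BH-adjusted within each context.
    ``order = (treatment, control)`` fixes the sign of delta (treatment minus
    control); by default groups are taken alphabetically, so direction is
    hyper when the first group is higher.
    """
    if backend not in ("wald", "logistic"):
        raise ValueError(f"unknown backend {backend!r}")
    ga, ia, gb, ib = _group_indices(united, design, order)
    cov_a = np.sum(~np.isnan(united.C[:, ia]), axis=1)
    cov_b = np.sum(~np.isnan(united.C[:, ib]), axis=1)
    usable = (cov_a >= min_per_group) & (cov_b >= min_per_group)
    sub = UnitedTable(united.sites.loc[usable].reset_index(drop=True),
                      united.M[usable], united.C[usable],
                      list(united.samples), dict(united.design))
    if backend == "wald":
        disp = estimate_dispersion(sub, design)
        delta, p = test_position(sub.M[:, ia], sub.C[:, ia],
                                 sub.M[:, ib], sub.C[:, ib], disp.phi)
    else:
        delta, p = test_position_logistic(sub.M[:, ia], sub.C[:, ia],
                                          sub.M[:, ib], sub.C[:, ib])
    out = sub.sites.copy()
    out["delta"] = delta
    out["p"] = p
    out["q"] = np.nan
    for ctx in out["context"].unique():
        mask = (out["context"] == ctx).to_numpy()
        out.loc[mask, "q"] = adjust_fdr(p[mask])
    out["direction"] = np.where(out["delta"] > 0, "hyper", "hypo")
    out["significant"] = out["q"] < alpha
    out.attrs["comparison"] = f"{ga}-vs-{gb}"
    out.attrs["backend"] = backend
    return out


def call_dmrs(
    united: UnitedTable,
    design: dict[str, str] | None = None,
    p_cut: float = 0.01,
    delta_cut: float = 0.1,
    min_diff: float = 0.10,
    min_positions: int = 3,
    min_length: int = 50,
    max_gap: int = 100,
    min_qualifying_fraction: float = 0.5,
    backend: str = "wald",
) -> pd.DataFrame:
    """Differentially methylated regions from relaxed per-position calls.

    Positions with p < p_cut and |delta| >= delta_cut qualify; runs of
    qualifying positions separated by < max_gap bp merge into one region.
    Regions must span >= min_length bp, contain >= min_positions qualifying
    positions of which >= min_qualifying_fraction of all member positions
    qualify, and show |mean delta| >= min_diff over member positions.
    """
    table = call_dmps(united, design, alpha=1.0, backend=backend)
    records = []
    for (chrom, ctx), grp in table.groupby(["chrom", "context"], sort=True):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy()
        delta = grp["delta"].to_numpy()
        qual = (grp["p"].to_numpy() < p_cut) & (np.abs(delta) >= delta_cut)
        qpos = pos[qual]
        if len(qpos) == 0:
            continue
        breaks = np.where(np.diff(qpos) >= max_gap)[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(qpos) - 1]])
        for s, e in zip(starts, ends):
            lo, hi = int(qpos[s]), int(qpos[e])
            members = (pos >= lo) & (pos <= hi)
            n_pos = int(members.sum())
            n_sig = int(qual[members].sum())
            mean_delta = float(delta[members].mean())
            if n_sig < min_positions:
                continue
            if hi - lo + 1 < min_length:
                continue
            if n_sig / n_pos < min_qualifying_fraction:
                continue
            if abs(mean_delta) < min_diff:
                continue
            records.append((chrom, lo, hi, ctx, n_pos, n_sig, mean_delta,
                            "hyper" if mean_delta > 0 else "hypo"))
    return pd.DataFrame(records, columns=[
        "chrom", "start", "end", "context", "n_positions", "n_significant",
        "mean_delta", "direction"])


def dmps_to_bed(table: pd.DataFrame, path) -> None:
    """BED export (0-based half-open) with score = -log10 q."""
    sig = table[table["significant"]]
    with open(path, "w") as fh:
        for _, r in sig.iterrows():
            score = -np.log10(max(r["q"], 1e-300))
            fh.write(f"{r['chrom']}\t{r['pos'] - 1}\t{r['pos']}\t"
                     f"{r['direction']}\t{score:.4g}\n")
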