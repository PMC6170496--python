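import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import epitar as ep
from epitar.io import UnitedTable

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_sample(rows, sample_id="s", control_rows=None):
    """SampleTable from (chrom, pos, strand, M, U, context) tuples."""
    cols = ["chrom", "pos", "strand", "M", "U", "context"]
    data = pd.DataFrame(rows, columns=cols)
    control = pd.DataFrame(control_rows, columns=cols) if control_rows else None
    return ep.SampleTable(sample_id=sample_id, data=data, control=control)


def make_united(Ma, Ca, Mb, Cb, context="CG"):
    """Two-group united table from per-group (n_pos x reps) count arrays."""
    Ma, Ca, Mb, Cb = (np.atleast_2d(np.asarray(x, dtype=float))
                      for x in (Ma, Ca, Mb, Cb))
    n = Ma.shape[0]
    sites = pd.DataFrame({"chrom": "Chr1", "pos": 10 * np.arange(1, n + 1),
                          "strand": "+", "context": context})
    samples = [f"A{i+1}" for i in range(Ma.shape[1])] + \
              [f"B{i+1}" for i in range(Mb.shape[1])]
    design = {s: s[0] for s in samples}
    return UnitedTable(sites, np.hstack([Ma, Mb]), np.hstack([Ca, Cb]),
                       samples, design)


def simulate_betabin(n, reps, phi, p=None, cov_mean=20.0, cov_size=5.0, rng=None):
    """Beta-binomial replicate counts with NB coverage; returns (M, C, p)."""
    rng = rng or np.random.default_rng(0)
    if p is None:
        p = rng.uniform(0.05, 0.95, n)
    C = rng.negative_binomial(cov_size, cov_size / (cov_size + cov_mean),
                              size=(n, reps)).astype(float)
    C = np.maximum(C, 3)
    if phi > 0:
        a = p * (1 - phi) / phi
        b = (1 - p) * (1 - phi) / phi
        pi = rng.beta(np.repeat(a[:, None], reps, 1),
                      np.repeat(b[:, None], reps, 1))
    else:
        pi = np.repeat(p[:, None], reps, 1)
    M = rng.binomial(C.astype(int), pi).astype(float)
    return M, C, p


@pytest.fixture(scope="session")
def f3_study():
    """Two mock and two triple-stressed lines, three replicate pools each."""
    ped = ep.build_pedigree(["MMM", "MMM", "SSS", "SSS"], replicates=3)
    return ep.simulate_study(ped, ep.EpigenomeModel(seed=11))


@pytest.fixture(scope="session")
def f3_united_cg(f3_study):
    return ep.preprocess_samples(f3_study.samples, f3_study.design, context="CG")


@pytest.fixture(scope="session")
def removal_study():
    """Three lines per treatment: with six lineages a chance exclusive
    grouping of the stressed lines after signal removal is rare, so the
    removal experiment's negative verdict is informative."""
    ped = ep.build_pedigree(["MMM"] * 3 + ["SSS"] * 3, replicates=3)
    study = ep.simulate_study(ped, ep.EpigenomeModel(seed=11))
    united = ep.preprocess_samples(study.samples, study.design, context="CG")
    return study, united


@pytest.fixture(scope="session")
def dose_study():
    """One mock, one single-stress and one triple-stress line (3:1 dose)."""
    ped = ep.build_pedigree(["MMM", "SMM", "SSS"], replicates=3)
    return ep.simulate_study(ped, ep.EpigenomeModel(seed=21))
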