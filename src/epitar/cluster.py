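"""Sample-level structure: Ward clustering on correlation distances with
multiscale-bootstrap edge support, and centered PCA summaries.

The dissimilarity between two samples is 1 - Pearson correlation of their
percent-methylation profiles, computed pairwise-complete over positions both
samples cover.  Edge support follows the multiscale bootstrap construction:
positions are resampled with replacement at a grid of relative sizes r, the
per-edge presence frequency BP_r is recorded, and the approximately unbiased
(AU) value is obtained by weighted least-squares extrapolation of the
normal-quantile transform of BP_r along (sqrt(r), 1/sqrt(r)) to r = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.41, 0.1), 2))


@dataclass
class ClusterTree:
    """Rooted binary merge tree over samples with optional per-edge support."""

    linkage_matrix: np.ndarray
    labels: list[str]
    # clade (frozenset of labels) -> (AU, BP), both percentages in [0, 100]
    support: dict[frozenset, tuple[float, float]] = field(default_factory=dict)
    nboot: int = 0
    degraded: bool = False      # True when nboot was too small for stable AU

    def clades(self) -> list[frozenset]:
        """Leaf sets of the internal nodes, smallest first."""
        n = len(self.labels)
        members: dict[int, frozenset] = {i: frozenset([self.labels[i]])
                                         for i in range(n)}
        out = []
        for k, (a, b, _, _) in enumerate(self.linkage_matrix):
            members[n + k] = members[int(a)] | members[int(b)]
            out.append(members[n + k])
        return out

    def has_clade(self, samples) -> bool:
        return frozenset(samples) in set(self.clades())

    def clade_support(self, samples) -> tuple[float, float] | None:
        return self.support.get(frozenset(samples))

    def to_newick(self) -> str:
        n = len(self.labels)
        heights = {i: 0.0 for i in range(n)}
        clades = self.clades()

        def node(i: int) -> str:
            if i < n:
                return self.labels[i]
            a, b, h, _ = self.linkage_matrix[i - n]
            heights[i] = h
            left, right = node(int(a)), node(int(b))
            la = max(h - heights[int(a)], 0.0)
            lb = max(h - heights[int(b)], 0.0)
            sup = self.support.get(clades[i - n])
            lab = f"{sup[0]:.0f}|{sup[1]:.0f}" if sup else ""
            return f"({left}:{la:.6g},{right}:{lb:.6g}){lab}"

        return node(n + len(self.linkage_matrix) - 1) + ";"


def filter_low_variation(matrix: pd.DataFrame) -> pd.DataFrame:
    """Drop positions whose across-sample sd is strictly below the median sd.

    Ties with the median are kept (strict-inequality rule).
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two samples")
    sds = matrix.std(axis=1, ddof=1, skipna=True)
    cut = sds.median()
    return matrix.loc[sds >= cut]


def pairwise_complete_corr(X: np.ndarray) -> np.ndarray:
    """Pearson correlation between columns over rows where both are present."""
    X = np.asarray(X, dtype=float)
    W = (~np.isnan(X)).astype(float)
    X0 = np.where(np.isnan(X), 0.0, X)
    N = W.T @ W
    Sx = X0.T @ W
    Sxx = (X0 * X0).T @ W
    Sxy = X0.T @ X0
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = Sxy - Sx * Sx.T / N
        var_x = Sxx - Sx**2 / N
        corr = cov / np.sqrt(var_x * var_x.T)
    return np.clip(corr, -1.0, 1.0)


def correlation_distance(matrix: pd.DataFrame) -> np.ndarray:
    """Condensed 1 - Pearson distance between sample columns."""
    corr = pairwise_complete_corr(matrix.to_numpy())
    col_ok = np.nanvar(matrix.to_numpy(), axis=0) > 0
    if not col_ok.all():
        bad = [matrix.columns[j] for j in np.where(~col_ok)[0]]
        raise ValueError(f"zero-variance samples, correlation undefined: {bad}")
    if np.isnan(corr).any():
        raise ValueError("correlation undefined for some sample pair "
                         "(no shared positions)")
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return squareform(d, checks=False)


def ward_correlation_tree(matrix: pd.DataFrame) -> ClusterTree:
    """Ward linkage on 1 - Pearson distances.

    Samples are ordered lexicographically before clustering so that equal-
    distance merges break ties deterministically by sample id.
    """
    cols = sorted(matrix.columns)
    matrix = matrix[cols]
    Z = linkage(correlation_distance(matrix), method="ward")
    return ClusterTree(linkage_matrix=Z, labels=list(cols))


def _clade_sets(Z: np.ndarray, labels: list[str]) -> list[frozenset]:
    n = len(labels)
    members: dict[int, frozenset] = {i: frozenset([labels[i]]) for i in range(n)}
    out = []
    for k, (a, b, _, _) in enumerate(Z):
        members[n + k] = members[int(a)] | members[int(b)]
        out.append(members[n + k])
    return out


def _fit_au(scales: np.ndarray, bps: np.ndarray, nboot: int) -> float:
    """AU from the multiscale BP curve by WLS on z_r = d*sqrt(r) + c/sqrt(r)."""
    eps = 1.0 / (2.0 * nboot)
    if (bps >= 1.0).all():
        return 100.0
    if (bps <= 0.0).all():
        return 0.0
    bp = np.clip(bps, eps, 1.0 - eps)
    z = stats.norm.ppf(1.0 - bp)
    X = np.column_stack([np.sqrt(scales), 1.0 / np.sqrt(scales)])
    w = nboot * stats.norm.pdf(z) ** 2 / (bp * (1.0 - bp))
    WX = X * w[:, None]
    try:
        coef = np.linalg.solve(X.T @ WX, WX.T @ z)
    except np.linalg.LinAlgError:
        return float(100.0 * np.mean(bps))
    d, c = coef
    return float(100.0 * (1.0 - stats.norm.cdf(d - c)))


def multiscale_bootstrap(
    matrix: pd.DataFrame,
    nboot: int = 10000,
    scales=DEFAULT_SCALES,
    seed: int = 0,
) -> ClusterTree:
    """Ward correlation tree with AU/BP edge support.

    For each scale r, ``nboot`` resamples of round(r*n) positions are drawn
    with replacement, the tree recomputed, and each original edge's presence
    frequency recorded.  BP is the plain bootstrap proportion at r = 1; AU is
    the weighted least-squares extrapolation described in the module docstring.
    A run with nboot < 100 is flagged as degraded.
    """
    tree = ward_correlation_tree(matrix)
    cols = list(tree.labels)
    X = matrix[cols].to_numpy(dtype=float)
    n = X.shape[0]
    scales = np.asarray(sorted(scales), dtype=float)
    if 1.0 not in scales:
        scales = np.sort(np.append(scales, 1.0))
    base_clades = _clade_sets(tree.linkage_matrix, cols)
    counts = {cl: np.zeros(len(scales)) for cl in base_clades}
    rng = np.random.default_rng(seed)
    complete = not np.isnan(X).any()
    for si, r in enumerate(scales):
        m = max(int(round(r * n)), 2)
        for _ in range(nboot):
            idx = rng.integers(0, n, size=m)
            Xb = X[idx]
            if complete:
                sd = Xb.std(axis=0)
                if (sd == 0).any():
                    continue
                corr = np.corrcoef(Xb.T)
                d = squareform(1.0 - corr, checks=False)
            else:
                try:
                    corr = pairwise_complete_corr(Xb)
                    if np.isnan(corr).any():
                        continue
                    dd = 1.0 - corr
                    np.fill_diagonal(dd, 0.0)
                    d = squareform(dd, checks=False)
                except ValueError:
                    continue
            Zb = linkage(d, method="ward")
            for cl in _clade_sets(Zb, cols):
                if cl in counts:
                    counts[cl][si] += 1
    i1 = int(np.argmin(np.abs(scales - 1.0)))
    support = {}
    for cl, cnt in counts.items():
        bps = cnt / nboot
        au = _fit_au(scales, bps, nboot)
        support[cl] = (float(np.clip(au, 0.0, 100.0)),
                       float(100.0 * bps[i1]))
    tree.support = support
    tree.nboot = nboot
    tree.degraded = nboot < 100
    return tree


def pca_scores(matrix: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered PCA of samples over complete-case positions.

    Returns (scores per sample, explained-variance fractions summing to 1).
    """
    complete = matrix.dropna(axis=0)
    if len(complete) < 2:
        raise ValueError("fewer than 2 complete-case positions")
    X = complete.to_numpy(dtype=float).T          # samples x positions
    X = X - X.mean(axis=0, keepdims=True)
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    k = min(X.shape[0] - 1, X.shape[1])
    k = max(k, 1)
    scores = U[:, :k] * S[:k]
    total = (S[:k] ** 2).sum()
    frac = (S[:k] ** 2) / total if total > 0 else np.full(k, 1.0 / k)
    cols = [f"PC{i + 1}" for i in range(k)]
    return pd.DataFrame(scores, index=list(matrix.columns), columns=cols), frac
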