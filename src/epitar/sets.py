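"""Direction-aware DMP set algebra and the downstream inference built on it.

A DMP set maps positions to a direction (hyper/hypo) and an effect size in
percentage points, for one comparison against a common control.  Two
comparisons share a DMP only when the position is significant in both with the
same direction; positions significant in both but in *opposite* directions are
treated as non-overlapping and counted in both exclusive sections, so the
unique union of positions is the sum of the three sections minus the
opposite-direction count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cluster import ClusterTree, filter_low_variation, multiscale_bootstrap
from .io import UnitedTable


@dataclass
class DMPSet:
    """Members of one comparison: position -> (direction, delta in pp)."""

    label: str
    members: pd.DataFrame     # index (chrom, pos); columns direction, delta

    def __post_init__(self) -> None:
        if self.members.index.duplicated().any():
            raise ValueError("a position may appear once per comparison")
        bad = set(self.members["direction"]) - {"hyper", "hypo"}
        if bad:
            raise ValueError(f"unknown directions {bad}")

    @classmethod
    def from_items(cls, label: str, items: dict) -> "DMPSet":
        """items: {(chrom, pos): direction} or {(chrom, pos): (direction, delta)}."""
        keys, dirs, deltas = [], [], []
        for k, v in items.items():
            keys.append(k)
            if isinstance(v, str):
                dirs.append(v)
                deltas.append(np.nan)
            else:
                dirs.append(v[0])
                deltas.append(v[1])
        idx = pd.MultiIndex.from_tuples(keys, names=["chrom", "pos"]) if keys else \
            pd.MultiIndex.from_tuples([], names=["chrom", "pos"])
        return cls(label, pd.DataFrame({"direction": dirs, "delta": deltas}, index=idx))

    @classmethod
    def from_dmp_table(cls, table: pd.DataFrame, label: str | None = None,
                       context: str | None = None) -> "DMPSet":
        """Significant rows of a ``call_dmps`` table, deltas in percentage points."""
        t = table[table["significant"]]
        if context is not None:
            t = t[t["context"] == context]
        idx = pd.MultiIndex.from_frame(t[["chrom", "pos"]])
        df = pd.DataFrame({"direction": t["direction"].to_numpy(),
                           "delta": 100.0 * t["delta"].to_numpy()}, index=idx)
        return cls(label or table.attrs.get("comparison", "dmps"), df)

    def __len__(self) -> int:
        return len(self.members)

    def positions(self) -> set:
        return set(self.members.index)

    def with_direction(self, direction: str) -> "DMPSet":
        return DMPSet(self.label, self.members[self.members["direction"] == direction])


@dataclass
class SharedSummary:
    """Three-section accounting of two DMP sets over a common control."""

    shared: pd.DataFrame        # same direction in both; columns direction, delta_a, delta_b
    a_only: set
    b_only: set
    opposite: set               # significant in both, opposite directions
    label_a: str = "a"
    label_b: str = "b"

    @property
    def section_sum(self) -> int:
        """Sections summed with opposite-direction members counted twice."""
        return len(self.shared) + len(self.a_only) + len(self.b_only)

    @property
    def unique_union(self) -> int:
        return self.section_sum - len(self.opposite)

    def venn_counts(self) -> dict:
        return {
            "shared": len(self.shared),
            f"{self.label_a}_only": len(self.a_only),
            f"{self.label_b}_only": len(self.b_only),
            "opposite_direction": len(self.opposite),
            "section_sum": self.section_sum,
            "unique_union": self.unique_union,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.venn_counts(), fh, indent=2)


def intersect_dmps(a: DMPSet, b: DMPSet) -> SharedSummary:
    """Direction-aware intersection: shared requires equal direction; positions
    differing in direction go to *both* exclusive sections."""
    pa, pb = a.positions(), b.positions()
    common = pa & pb
    if common:
        da = a.members.loc[list(common), "direction"]
        db = b.members.loc[list(common), "direction"]
        same = da.index[(da == db).to_numpy()]
        opposite = set(da.index[(da != db).to_numpy()])
    else:
        same = pd.Index([])
        opposite = set()
    shared = pd.DataFrame({
        "direction": a.members.loc[same, "direction"],
        "delta_a": a.members.loc[same, "delta"],
        "delta_b": b.members.loc[same, "delta"],
    }) if len(same) else pd.DataFrame(columns=["direction", "delta_a", "delta_b"])
    a_only = (pa - pb) | opposite
    b_only = (pb - pa) | opposite
    return SharedSummary(shared=shared, a_only=a_only, b_only=b_only,
                         opposite=opposite, label_a=a.label, label_b=b.label)


def dose_intensity(
    shared: SharedSummary,
    threshold: float = 20.0,
) -> tuple[dict, pd.DataFrame]:
    """Which comparison shows the stronger effect at shared DMPs.

    For hyper-methylated shared DMPs, a position is "more pronounced" in B when
    delta_b - delta_a >= threshold (percentage points); for hypo-methylated
    DMPs the same rule is applied to the negated deltas.  Returns counts per
    direction per side plus the paired (delta_a, delta_b) table.
    """
    t = shared.shared.copy()
    missing = t["delta_a"].isna() | t["delta_b"].isna()
    excluded = int(missing.sum())
    t = t[~missing]
    sign = np.where(t["direction"] == "hyper", 1.0, -1.0)
    adv_b = sign * (t["delta_b"] - t["delta_a"])
    counts = {
        "pronounced_b_hyper": int(((t["direction"] == "hyper") & (adv_b >= threshold)).sum()),
        "pronounced_b_hypo": int(((t["direction"] == "hypo") & (adv_b >= threshold)).sum()),
        "pronounced_a_hyper": int(((t["direction"] == "hyper") & (-adv_b >= threshold)).sum()),
        "pronounced_a_hypo": int(((t["direction"] == "hypo") & (-adv_b >= threshold)).sum()),
        "excluded_missing_delta": excluded,
    }
    paired = t.rename(columns={"delta_a": f"delta_{shared.label_a}",
                               "delta_b": f"delta_{shared.label_b}"})
    return counts, paired


@dataclass
class ReclusterResult:
    before: ClusterTree
    after: ClusterTree
    ignored_removals: int
    verdict_before: dict
    verdict_after: dict


def _treatment_verdict(tree: ClusterTree, treatment_samples) -> dict:
    """Whether the treatment samples form an exclusive clade, and whether that
    clade is supported at the conventional AU >= 95 level."""
    target = frozenset(treatment_samples)
    present = tree.has_clade(target)
    au = bp = None
    if present and tree.support:
        sup = tree.clade_support(target)
        if sup is not None:
            au, bp = sup
    supported = bool(present and au is not None and au >= 95.0)
    return {"exclusive_clade": bool(present), "supported_clade": supported,
            "au": au, "bp": bp}


def removal_reclustering(
    united: UnitedTable,
    remove: set,
    treatment_samples,
    nboot: int = 1000,
    seed: int = 0,
    low_variation_filter: bool = True,
) -> ReclusterResult:
    """Cluster the full table and the table minus ``remove`` with the same seed
    stream, and report whether the treatment samples form an exclusive clade.

    ``remove`` holds (chrom, pos) keys; members absent from the table are
    ignored and counted.
    """
    keys = set(remove)
    present = set(map(tuple, united.sites[["chrom", "pos"]].itertuples(index=False)))
    ignored = len(keys - present)
    reduced = united.drop_positions(keys)
    if reduced.n_sites < 2:
        raise ValueError("removal would leave fewer than 2 positions")

    def run(tab: UnitedTable) -> ClusterTree:
        m = tab.percent_matrix()
        if low_variation_filter:
            m = filter_low_variation(m)
        return multiscale_bootstrap(m, nboot=nboot, seed=seed)

    before = run(united)
    after = run(reduced)
    return ReclusterResult(
        before=before, after=after, ignored_removals=ignored,
        verdict_before=_treatment_verdict(before, treatment_samples),
        verdict_after=_treatment_verdict(after, treatment_samples),
    )


@dataclass
class LabilityResult:
    table: pd.DataFrame          # rows: set labels; cols labile/stable/unclassified
    contingency: np.ndarray      # 2x2 labile/stable x dmps/comparator
    odds_ratio: float
    p: float


def lability_overlap(
    dmps: DMPSet,
    classes: pd.DataFrame,
    comparator: DMPSet,
) -> LabilityResult:
    """Cross-tabulate DMP sets against labile/stable position classes and test
    for a compositional shift with a two-sided Fisher's exact 2x2 test.

    ``classes``: columns chrom, pos, class in {labile, stable}; positions not
    listed count as unclassified and are excluded from the test.
    """
    if len(comparator) == 0:
        raise ValueError("empty comparator set")
    lookup = classes.set_index(["chrom", "pos"])["class"]

    def tally(s: DMPSet) -> dict:
        cls = lookup.reindex(list(s.positions())) if len(s) else pd.Series(dtype=object)
        return {
            "labile": int((cls == "labile").sum()),
            "stable": int((cls == "stable").sum()),
            "unclassified": int(cls.isna().sum()),
        }

    rows = {dmps.label: tally(dmps), comparator.label: tally(comparator)}
    table = pd.DataFrame(rows).T[["labile", "stable", "unclassified"]]
    cont = table[["labile", "stable"]].to_numpy()
    odds, p = stats.fisher_exact(cont, alternative="two-sided")
    return LabilityResult(table=table, contingency=cont,
                          odds_ratio=float(odds), p=float(p))


def _round_half_up(x: float, decimals: int = 1) -> float:
    f = 10.0**decimals
    return np.floor(x * f + 0.5) / f


def cross_experiment_overlap(a: DMPSet, b: DMPSet) -> dict:
    """Same-direction overlap of two experiments' DMP sets, with percentages of
    each set rounded half-up to one decimal."""
    common = a.positions() & b.positions()
    same = [k for k in common
            if a.members.loc[k, "direction"] == b.members.loc[k, "direction"]]
    n = len(same)
    return {
        "n_overlap": n,
        "n_a": len(a),
        "n_b": len(b),
        "pct_of_a": _round_half_up(100.0 * n / len(a)) if len(a) else 0.0,
        "pct_of_b": _round_half_up(100.0 * n / len(b)) if len(b) else 0.0,
    }
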