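"""Reading, filtering, normalising and uniting per-cytosine count tables.

The on-disk dialect is the Bismark cytosine report: tab-separated
``chrom, pos (1-based), strand (+/-), count methylated, count unmethylated,
context (CG/CHG/CHH)`` with an optional trinucleotide column.  All coordinates
in this package are 1-based with inclusive endpoints; the bedGraph exporter is
the single place where 0-based half-open coordinates appear.

Reads aligning to the chloroplast (contig ``ChrC`` by default) are split off
into a conversion-control table at read time: chloroplast DNA is unmethylated,
so its apparent methylation measures bisulfite non-conversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

VALID_CONTEXTS = frozenset({"CG", "CHG", "CHH"})
DEFAULT_CONTROL_CHROMS = frozenset({"ChrC"})

_REPORT_COLUMNS = ["chrom", "pos", "strand", "M", "U", "context"]


@dataclass
class SampleTable:
    """Per-sample cytosine counts, keyed by (chrom, pos, strand)."""

    sample_id: str
    data: pd.DataFrame                    # chrom,pos,strand,M,U,context
    control: pd.DataFrame | None = None   # conversion-control records (ChrC)
    line_id: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        d = self.data
        if len(d):
            if (d["M"] < 0).any() or (d["U"] < 0).any():
                raise ValueError("negative counts")
            keys = d[["chrom", "pos", "strand"]]
            if keys.duplicated().any():
                raise ValueError("duplicate (chrom, pos, strand) keys")

    @property
    def coverage(self) -> pd.Series:
        return self.data["M"] + self.data["U"]

    def qc_summary(self) -> dict:
        """Per-sample QC numbers (the pipeline reports, it never auto-discards)."""
        c = self.coverage
        n = len(self.data)
        return {
            "sample_id": self.sample_id,
            "n_positions": n,
            "median_coverage": float(c.median()) if n else float("nan"),
            "mean_coverage": float(c.mean()) if n else float("nan"),
            "mean_methylation": float((self.data["M"] / c).mean()) if n else float("nan"),
        }


@dataclass
class UnitedTable:
    """Positions x samples count matrix after group-wise completeness filtering.

    ``M`` and ``C`` are float arrays of shape (n_sites, n_samples) with NaN
    marking entries absent in a sample (absent, not zero).
    """

    sites: pd.DataFrame          # chrom, pos, strand, context
    M: np.ndarray
    C: np.ndarray
    samples: list[str]
    design: dict[str, str] = field(default_factory=dict)   # sample -> group

    def __post_init__(self) -> None:
        if self.M.shape != self.C.shape or self.M.shape != (len(self.sites), len(self.samples)):
            raise ValueError("matrix shapes inconsistent with sites/samples")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def groups(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for j, s in enumerate(self.samples):
            out.setdefault(self.design.get(s, "all"), []).append(j)
        return out

    def subset_context(self, context: str) -> "UnitedTable":
        mask = (self.sites["context"] == context).to_numpy()
        return UnitedTable(
            self.sites.loc[mask].reset_index(drop=True),
            self.M[mask], self.C[mask], list(self.samples), dict(self.design),
        )

    def drop_positions(self, keys: set[tuple[str, int]]) -> "UnitedTable":
        mask = ~pd.MultiIndex.from_frame(self.sites[["chrom", "pos"]]).isin(keys)
        mask = np.asarray(mask)
        return UnitedTable(
            self.sites.loc[mask].reset_index(drop=True),
            self.M[mask], self.C[mask], list(self.samples), dict(self.design),
        )

    def percent_matrix(self) -> pd.DataFrame:
        """Percent methylation (100*M/C) indexed by (chrom, pos); NaN = missing."""
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * self.M / self.C
        idx = pd.MultiIndex.from_frame(self.sites[["chrom", "pos"]])
        return pd.DataFrame(pct, index=idx, columns=self.samples)


def read_cytosine_report(
    path,
    sample_id: str | None = None,
    mincov: int = 3,
    control_chroms=DEFAULT_CONTROL_CHROMS,
) -> SampleTable:
    """Read a Bismark-style cytosine report.

    Records with coverage below ``mincov`` are dropped; records on
    ``control_chroms`` go to the conversion-control table (same mincov rule).
    Malformed lines raise with their 1-based line number.
    """
    if mincov < 0:
        raise ValueError("mincov must be >= 0")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}: malformed line {lineno}: expected >=6 fields")
            chrom, pos, strand, m, u, context = parts[:6]
            if context not in VALID_CONTEXTS:
                raise ValueError(f"{path}: line {lineno}: unknown context {context!r}")
            if strand not in ("+", "-"):
                raise ValueError(f"{path}: line {lineno}: bad strand {strand!r}")
            try:
                pos_i, m_i, u_i = int(pos), int(m), int(u)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer field") from exc
            rows.append((chrom, pos_i, strand, m_i, u_i, context))
    df = pd.DataFrame(rows, columns=_REPORT_COLUMNS)
    if len(df):
        df = df[(df["M"] + df["U"]) >= mincov].reset_index(drop=True)
    is_control = df["chrom"].isin(control_chroms) if len(df) else pd.Series(dtype=bool)
    control = df[is_control].reset_index(drop=True) if len(df) else None
    data = df[~is_control].reset_index(drop=True) if len(df) else df
    if sample_id is None:
        sample_id = str(path)
    return SampleTable(sample_id=sample_id, data=data, control=control)


def write_cytosine_report(table: SampleTable, path, include_control: bool = True) -> None:
    """Write a SampleTable back to the cytosine-report dialect (round-trip safe)."""
    frames = [table.data]
    if include_control and table.control is not None and len(table.control):
        frames.append(table.control)
    df = pd.concat(frames, ignore_index=True) if len(frames) > 1 else frames[0]
    df.to_csv(path, sep="\t", header=False, index=False,
              columns=_REPORT_COLUMNS)


def filter_by_coverage(table: SampleTable, hi_perc: float = 99.9) -> SampleTable:
    """Drop records with coverage strictly above the sample's hi_perc percentile.

    Percentiles use linear interpolation between order statistics.
    """
    if not (0 < hi_perc <= 100):
        raise ValueError("hi_perc must lie in (0, 100]")
    if not len(table.data):
        raise ValueError("cannot coverage-filter an empty table")
    cov = table.coverage.to_numpy()
    cut = np.percentile(cov, hi_perc)
    keep = cov <= cut
    return replace(table, data=table.data.loc[keep].reset_index(drop=True))


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def normalize_coverage(tables: list[SampleTable]) -> list[SampleTable]:
    """Scale each sample's counts so median coverages match across samples.

    Sample *s* with median coverage ``m_s`` gets factor
    ``median_over_samples(m_s) / m_s``; M and C are scaled and rounded half-up,
    then U = C - M with M clamped to C and C kept >= 1.
    """
    if not tables:
        raise ValueError("no samples")
    medians = []
    for t in tables:
        if not len(t.data):
            raise ValueError(f"sample {t.sample_id}: empty table")
        m = float(t.coverage.median())
        if m <= 0:
            raise ValueError(f"sample {t.sample_id}: zero median coverage")
        medians.append(m)
    ref = float(np.median(medians))
    out = []
    for t, m in zip(tables, medians):
        f = ref / m
        c_old = t.coverage.to_numpy()
        m_new = _round_half_up(t.data["M"].to_numpy() * f)
        c_new = np.maximum(_round_half_up(c_old * f), 1.0)
        m_new = np.minimum(m_new, c_new)
        df = t.data.copy()
        df["M"] = m_new.astype(int)
        df["U"] = (c_new - m_new).astype(int)
        out.append(replace(t, data=df))
    return out


def destrand_cg(table: SampleTable) -> SampleTable:
    """Merge symmetric CG pairs (+ at pos i, - at pos i+1) onto the + coordinate.

    Non-CG records pass through untouched.  Unpaired CG records keep their own
    coordinate; all CG output rows are reported on the + strand so that
    destranded tables are strand-uniform.
    """
    df = table.data
    cg = df[df["context"] == "CG"]
    rest = df[df["context"] != "CG"]
    if not len(cg):
        return table
    plus = cg[cg["strand"] == "+"]
    minus = cg[cg["strand"] == "-"].copy()
    # a minus record at pos i+1 pairs with a plus record at pos i
    minus["pair_pos"] = minus["pos"] - 1
    merged = plus.merge(
        minus[["chrom", "pair_pos", "M", "U"]],
        left_on=["chrom", "pos"], right_on=["chrom", "pair_pos"],
        how="left", suffixes=("", "_minus"),
    )
    merged["M"] = merged["M"] + merged["M_minus"].fillna(0).astype(int)
    merged["U"] = merged["U"] + merged["U_minus"].fillna(0).astype(int)
    paired_minus = minus.merge(
        plus[["chrom", "pos"]], left_on=["chrom", "pair_pos"],
        right_on=["chrom", "pos"], how="inner", suffixes=("", "_p"),
    )
    paired_keys = set(zip(paired_minus["chrom"], paired_minus["pos"]))
    lone_minus = minus[~minus.set_index(["chrom", "pos"]).index.isin(paired_keys)].copy()
    lone_minus["strand"] = "+"
    out = pd.concat(
        [merged[_REPORT_COLUMNS], lone_minus[_REPORT_COLUMNS], rest],
        ignore_index=True,
    )
    out = out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return replace(table, data=out)


def unite(
    tables: list[SampleTable],
    group_design: dict[str, str],
    min_per_group: int = 2,
) -> UnitedTable:
    """Join samples on (chrom, pos, strand, context), keeping positions covered
    in at least ``min_per_group`` samples of every group.  Missing entries are
    NaN, never zero.
    """
    if min_per_group < 1:
        raise ValueError("min_per_group must be >= 1")
    groups: dict[str, list[str]] = {}
    for t in tables:
        if t.sample_id not in group_design:
            raise ValueError(f"sample {t.sample_id} missing from group design")
        groups.setdefault(group_design[t.sample_id], []).append(t.sample_id)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g, members in groups.items():
        if len(members) < min_per_group:
            raise ValueError(f"group {g!r} has {len(members)} samples < min_per_group")

    samples = [t.sample_id for t in tables]
    frames = []
    for t in tables:
        d = t.data.set_index(["chrom", "pos", "strand", "context"])
        frames.append(pd.DataFrame({
            ("M", t.sample_id): d["M"],
            ("C", t.sample_id): d["M"] + d["U"],
        }))
    wide = pd.concat(frames, axis=1, join="outer")
    C = wide["C"].reindex(columns=samples).to_numpy(dtype=float)
    M = wide["M"].reindex(columns=samples).to_numpy(dtype=float)
    covered = ~np.isnan(C)
    keep = np.ones(len(wide), dtype=bool)
    for g, members in groups.items():
        idx = [samples.index(s) for s in members]
        keep &= covered[:, idx].sum(axis=1) >= min_per_group
    sites = wide.index.to_frame(index=False)[["chrom", "pos", "strand", "context"]]
    sites = sites.loc[keep].reset_index(drop=True)
    ut = UnitedTable(sites=sites, M=M[keep], C=C[keep], samples=samples,
                     design=dict(group_design))
    order = np.lexsort((ut.sites["pos"].to_numpy(), ut.sites["chrom"].to_numpy()))
    return UnitedTable(ut.sites.iloc[order].reset_index(drop=True),
                       ut.M[order], ut.C[order], ut.samples, ut.design)


def preprocess_samples(
    samples: list[SampleTable],
    design: dict[str, str],
    hi_perc: float = 99.9,
    min_per_group: int = 2,
    destrand: bool = True,
    context: str | None = None,
) -> UnitedTable:
    """Standard preprocessing chain: coverage outlier filter, median-coverage
    normalisation, CG destranding, group-wise unite."""
    tables = [filter_by_coverage(t, hi_perc=hi_perc) for t in samples]
    tables = normalize_coverage(tables)
    if destrand:
        tables = [destrand_cg(t) for t in tables]
    ut = unite(tables, design, min_per_group=min_per_group)
    if context is not None:
        ut = ut.subset_context(context)
    return ut


def estimate_conversion(control_table: pd.DataFrame) -> float:
    """Bisulfite conversion rate from chloroplast records: sum(U)/sum(M+U)."""
    if control_table is None or not len(control_table):
        raise ValueError("empty conversion-control table")
    total = int(control_table["M"].sum() + control_table["U"].sum())
    if total == 0:
        raise ValueError("conversion-control table has zero total coverage")
    return float(control_table["U"].sum()) / total


def tile_windows(united: UnitedTable, width: int = 100) -> UnitedTable:
    """Summarise counts over non-overlapping 1-based windows [1,w], [w+1,2w], ...

    Window counts are per-sample sums over member positions; a sample's window
    entry is missing only when the sample covers none of its member positions.
    """
    if width < 1:
        raise ValueError("window width must be >= 1")
    win = (united.sites["pos"].to_numpy() - 1) // width
    key = pd.DataFrame({
        "chrom": united.sites["chrom"].to_numpy(),
        "win": win,
        "context": united.sites["context"].to_numpy(),
    })
    grouped = key.groupby(["chrom", "win", "context"], sort=True).indices
    n = len(grouped)
    M = np.full((n, len(united.samples)), np.nan)
    C = np.full((n, len(united.samples)), np.nan)
    rows = []
    for i, ((chrom, w, context), idx) in enumerate(sorted(grouped.items())):
        idx = np.asarray(idx)
        with np.errstate(invalid="ignore"):
            any_cov = ~np.all(np.isnan(united.C[idx]), axis=0)
            M[i, any_cov] = np.nansum(united.M[idx][:, any_cov], axis=0)
            C[i, any_cov] = np.nansum(united.C[idx][:, any_cov], axis=0)
        rows.append((chrom, int(w) * width + 1, "+", context))
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context"])
    return UnitedTable(sites=sites, M=M, C=C, samples=list(united.samples),
                       design=dict(united.design))


def to_bedgraph(table: SampleTable, path) -> None:
    """Export percent methylation as bedGraph (0-based half-open intervals)."""
    d = table.data
    with open(path, "w") as fh:
        for chrom, pos, m, u in zip(d["chrom"], d["pos"], d["M"], d["U"]):
            pct = 100.0 * m / (m + u)
            fh.write(f"{chrom}\t{pos - 1}\t{pos}\t{pct:.6g}\n")


def bedgraph_interval(pos: int) -> tuple[int, int]:
    """1-based inclusive position -> 0-based half-open (start, end)."""
    if pos < 1:
        raise ValueError("positions are 1-based")
    return pos - 1, pos


def write_united(united: UnitedTable, path) -> None:
    """Tab-separated wide export: site columns then M_<sample>, C_<sample>."""
    df = united.sites.copy()
    for j, s in enumerate(united.samples):
        df[f"M_{s}"] = united.M[:, j]
        df[f"C_{s}"] = united.C[:, j]
    df.to_csv(path, sep="\t", index=False)


def read_united(path, design: dict[str, str]) -> UnitedTable:
    df = pd.read_csv(path, sep="\t")
    samples = [c[2:] for c in df.columns if c.startswith("M_")]
    M = df[[f"M_{s}" for s in samples]].to_numpy(dtype=float)
    C = df[[f"C_{s}" for s in samples]].to_numpy(dtype=float)
    sites = df[["chrom", "pos", "strand", "context"]].copy()
    return UnitedTable(sites=sites, M=M, C=C, samples=samples, design=dict(design))
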