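"""Mapping positions onto genomic features with transposon > gene > intergenic
priority.

The feature index flattens a GFF3 (or BED) annotation into per-chromosome
interval stores.  A coordinate inside both a transposon and a gene is classed
transposon; inside a gene it additionally resolves to a sub-feature (5'UTR,
3'UTR, exon, or intron when within the gene but outside annotated exons/UTRs);
everything else is intergenic.  GFF intervals are 1-based inclusive; BED is
0-based half-open and converted on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

TRANSPOSON_TYPES = {"transposable_element", "transposable_element_gene",
                    "transposon_fragment", "transposon"}
GENE_TYPES = {"gene"}
SUBFEATURE_TYPES = {"five_prime_UTR": "5'UTR", "three_prime_UTR": "3'UTR",
                    "exon": "exon"}
# within-gene resolution order: UTRs shadow exons, introns are the remainder
_SUB_PRIORITY = ("5'UTR", "3'UTR", "exon")


@dataclass
class FeatureIndex:
    """Per-chromosome interval trees per feature class (1-based inclusive)."""

    transposons: dict[str, IntervalTree] = field(default_factory=dict)
    genes: dict[str, IntervalTree] = field(default_factory=dict)
    subfeatures: dict[str, dict[str, IntervalTree]] = field(default_factory=dict)
    promoter_window: int = 1000

    def _add(self, store: dict, chrom: str, start: int, end: int) -> None:
        # intervaltree is half-open; store [start, end] as [start, end+1)
        store.setdefault(chrom, IntervalTree()).addi(start, end + 1)

    def classify(self, chrom: str, pos: int) -> tuple[str, str | None]:
        """Priority class and gene sub-feature for one 1-based position."""
        t = self.transposons.get(chrom)
        if t is not None and t.overlaps(pos):
            return "transposon", None
        g = self.genes.get(chrom)
        if g is not None and g.overlaps(pos):
            subs = self.subfeatures.get(chrom, {})
            for name in _SUB_PRIORITY:
                tree = subs.get(name)
                if tree is not None and tree.overlaps(pos):
                    return "gene", name
            return "gene", "intron"
        return "intergenic", None


def _parse_gff_line(line: str, lineno: int, path) -> tuple | None:
    if not line.strip() or line.startswith("#"):
        return None
    parts = line.rstrip("\n").split("\t")
    if len(parts) < 8:
        raise ValueError(f"{path}: malformed GFF3 record at line {lineno}")
    chrom, _, ftype, start, end = parts[0], parts[1], parts[2], parts[3], parts[4]
    try:
        s, e = int(start), int(end)
    except ValueError as exc:
        raise ValueError(f"{path}: non-integer coordinates at line {lineno}") from exc
    if e < s:
        raise ValueError(f"{path}: end < start at line {lineno}")
    return chrom, ftype, s, e


def build_feature_index(path, fmt: str = "gff3",
                        promoter_window: int = 1000) -> FeatureIndex:
    """Flatten a GFF3 or BED annotation into a priority FeatureIndex.

    BED input needs 4 columns (chrom, start, end, class) with class in
    {transposon, gene}; gaps in either format are intergenic.
    """
    idx = FeatureIndex(promoter_window=promoter_window)
    if fmt == "bed":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "cls"])
        for r in df.itertuples(index=False):
            start, end = int(r.start) + 1, int(r.end)       # to 1-based inclusive
            if r.cls == "transposon":
                idx._add(idx.transposons, r.chrom, start, end)
            elif r.cls == "gene":
                idx._add(idx.genes, r.chrom, start, end)
            else:
                raise ValueError(f"{path}: unknown BED feature class {r.cls!r}")
        return idx
    if fmt != "gff3":
        raise ValueError(f"unknown annotation format {fmt!r}")
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = _parse_gff_line(line, lineno, path)
            if rec is None:
                continue
            chrom, ftype, s, e = rec
            if ftype in TRANSPOSON_TYPES:
                idx._add(idx.transposons, chrom, s, e)
            elif ftype in GENE_TYPES:
                idx._add(idx.genes, chrom, s, e)
            elif ftype in SUBFEATURE_TYPES:
                sub = SUBFEATURE_TYPES[ftype]
                idx.subfeatures.setdefault(chrom, {})
                idx._add(idx.subfeatures[chrom], sub, s, e)
    return idx


def annotate_positions(positions: pd.DataFrame, index: FeatureIndex) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Class per position plus per-class, per-direction count summary.

    ``positions`` needs columns chrom, pos; direction and context are used for
    the summary when present.  Positions on chromosomes absent from the index
    are counted under "unmapped" with a warning.
    """
    known = set(index.transposons) | set(index.genes) | set(index.subfeatures)
    out = positions.copy()
    classes, subs = [], []
    n_unmapped = 0
    for chrom, pos in zip(out["chrom"], out["pos"]):
        if chrom not in known:
            classes.append("unmapped")
            subs.append(None)
            n_unmapped += 1
            continue
        cls, sub = index.classify(chrom, int(pos))
        classes.append(cls)
        subs.append(sub)
    if n_unmapped:
        warnings.warn(f"{n_unmapped} positions on chromosomes absent from the "
                      "annotation counted as unmapped")
    out["feature"] = classes
    out["subfeature"] = subs
    group_cols = ["feature"]
    for extra in ("direction", "context"):
        if extra in out.columns:
            group_cols.append(extra)
    summary = (out.groupby(group_cols, dropna=False).size()
               .rename("n").reset_index())
    return out, summary
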