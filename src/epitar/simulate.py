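"""Pedigree-structured synthetic methylomes.

The generator emulates the study design behind transgenerational
acquired-resistance (TAR) methylome experiments in Arabidopsis: single-seed
descent lines treated per generation with mock (M) or pathogen stress (S),
final-generation individuals each founding a pooled replicate sample of 10
plants, whole-genome-bisulfite-style counts with negative-binomial coverage
and imperfect bisulfite conversion, and a chloroplast contig of unmethylated
cytosines serving as conversion control.

Epigenetic state is diploid and three-valued: each position carries 0, 0.5 or
1 (neither/one/both epialleles methylated).  Spontaneous epimutation flips one
epiallele step per generation with probability ``eps_labile`` at labile CG
positions and ``eps_stable`` elsewhere.  Stress adds a heritable shift at a
designated set of stress-responsive CG positions: every S generation moves the
germline's expected population methylation by ``delta_stress`` toward the
position's designated direction, and each pooled plant expresses that shift
with probability ``penetrance``.  The expected population shift of a line with
``k`` stressed generations is therefore ``k * delta_stress * penetrance`` —
additive in the stress dose, which is what makes the SSS:SMM 3:1 contrast of
the analysis reproducible by construction.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SampleTable, write_cytosine_report

TREATMENT_ALPHABET = frozenset({"M", "S"})


@dataclass
class Pedigree:
    """Lines of single-seed descent with per-generation treatments."""

    lines: list[tuple[str, str]]        # (line_id, treatment string over {M,S})
    replicates_per_line: int = 3
    pool_size: int = 10

    def __post_init__(self) -> None:
        if not self.lines:
            raise ValueError("pedigree needs at least one line")
        lengths = {len(t) for _, t in self.lines}
        if len(lengths) != 1:
            raise ValueError("all treatment strings must have the same length")
        for lid, t in self.lines:
            if not t:
                raise ValueError(f"line {lid}: empty treatment string")
            bad = set(t) - TREATMENT_ALPHABET
            if bad:
                raise ValueError(f"line {lid}: illegal treatment characters {bad}")
        if self.replicates_per_line < 1:
            raise ValueError("replicates_per_line must be >= 1")
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")

    @property
    def generations(self) -> int:
        return len(self.lines[0][1])

    def stress_generations(self, line_id: str) -> int:
        for lid, t in self.lines:
            if lid == line_id:
                return t.count("S")
        raise KeyError(line_id)


def build_pedigree(design_strings, replicates: int = 3, pool_size: int = 10) -> Pedigree:
    """Pedigree from treatment strings; line ids are the strings, deduplicated
    with numeric suffixes (["MMM","MMM","SSS"] -> MMM_1, MMM_2, SSS_1)."""
    counts: dict[str, int] = {}
    lines = []
    for t in design_strings:
        counts[t] = counts.get(t, 0) + 1
    seen: dict[str, int] = {}
    for t in design_strings:
        if counts[t] > 1:
            seen[t] = seen.get(t, 0) + 1
            lid = f"{t}_{seen[t]}"
        else:
            lid = t
        lines.append((lid, t))
    return Pedigree(lines=lines, replicates_per_line=replicates, pool_size=pool_size)


@dataclass
class EpigenomeModel:
    """Generative parameters for the synthetic methylome.

    Epimutation rates are free simulation parameters — the source experiments
    report none — and are not estimates of mutation-accumulation-line rates.
    """

    n_cg: int = 2000
    n_chg: int = 400
    n_chh: int = 400
    labile_fraction: float = 0.1
    eps_labile: float = 0.005
    eps_stable: float = 1e-4
    n_stress_responsive: int = 100
    delta_stress: float = 0.25          # per-S-generation shift, expressed plants
    penetrance: float = 0.9             # fraction of pooled plants expressing it
    n_chloroplast: int = 2000
    conversion_rate: float = 0.995
    coverage_mean: float = 20.0
    coverage_dispersion: float = 5.0    # NB size parameter; var = m + m^2/k
    founder_meth_cg: float = 0.3        # P(founder CG state fully methylated)
    founder_half_cg: float = 0.1
    founder_meth_non_cg: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("labile_fraction", "eps_labile", "eps_stable", "delta_stress",
                     "penetrance", "conversion_rate", "founder_meth_cg",
                     "founder_half_cg", "founder_meth_non_cg"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.eps_labile < self.eps_stable:
            raise ValueError("eps_labile must be >= eps_stable")
        if self.n_stress_responsive > self.n_cg:
            raise ValueError("n_stress_responsive cannot exceed n_cg")
        if self.coverage_mean <= 0 or self.coverage_dispersion <= 0:
            raise ValueError("coverage parameters must be positive")


@dataclass
class GenomeLayout:
    """Deterministic coordinates plus per-position classes drawn from the seed.

    CG sites occupy two cytosines, (pos, +) and (pos+1, -), so that CG
    destranding in the analysis has real work to do.
    """

    contexts: np.ndarray        # per site: "CG"/"CHG"/"CHH"
    positions: np.ndarray       # plus-strand coordinate per site
    labile: np.ndarray          # bool per site
    responsive: np.ndarray      # bool per site (CG only)
    stress_direction: np.ndarray  # +1 hyper / -1 hypo / 0
    founder: np.ndarray         # founder state per site in {0, 0.5, 1}
    chrom: str = "Chr1"

    @property
    def n_sites(self) -> int:
        return len(self.positions)


def build_layout(model: EpigenomeModel) -> GenomeLayout:
    rng = np.random.default_rng([model.seed, 101])
    n = model.n_cg + model.n_chg + model.n_chh
    contexts = np.array(["CG"] * model.n_cg + ["CHG"] * model.n_chg
                        + ["CHH"] * model.n_chh)
    positions = 1 + 10 * np.arange(n)
    labile = np.zeros(n, dtype=bool)
    cg_idx = np.arange(model.n_cg)
    n_labile = int(round(model.labile_fraction * model.n_cg))
    labile[rng.choice(cg_idx, size=n_labile, replace=False)] = True
    responsive = np.zeros(n, dtype=bool)
    responsive[rng.choice(cg_idx, size=model.n_stress_responsive, replace=False)] = True

    founder = np.zeros(n)
    u = rng.random(n)
    is_cg = contexts == "CG"
    founder[is_cg & (u < model.founder_meth_cg)] = 1.0
    founder[is_cg & (u >= model.founder_meth_cg)
            & (u < model.founder_meth_cg + model.founder_half_cg)] = 0.5
    founder[~is_cg & (u < model.founder_meth_non_cg)] = 1.0

    # stress pushes away from the founder baseline so shifts are not clamped:
    # unmethylated baselines hyper-methylate under stress and vice versa
    direction = np.zeros(n, dtype=int)
    direction[responsive & (founder <= 0.5)] = 1
    direction[responsive & (founder > 0.5)] = -1
    return GenomeLayout(contexts=contexts, positions=positions, labile=labile,
                        responsive=responsive, stress_direction=direction,
                        founder=founder)


@dataclass
class PlantMethylome:
    """One individual: per-site epiallele state in {0, 0.5, 1} plus the
    heritable stress shift it carries at responsive positions."""

    states: np.ndarray
    stress_shift: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not np.isin(self.states, (0.0, 0.5, 1.0)).all():
            raise ValueError("epiallele states must lie in {0, 0.5, 1}")
        if self.stress_shift is None:
            self.stress_shift = np.zeros_like(self.states)


def propagate_generation(
    parent: PlantMethylome,
    treatment: str,
    model: EpigenomeModel,
    rng: np.random.Generator,
    layout: GenomeLayout,
) -> PlantMethylome:
    """Single-seed descent: one child, epimutation plus (under S) stress shift.

    Each position flips one epiallele step with probability eps_labile (labile)
    or eps_stable (others); a heterozygous 0.5 state steps up or down with equal
    probability.  Under S the child's heritable shift at responsive positions
    grows by delta_stress toward the designated direction.
    """
    if treatment not in TREATMENT_ALPHABET:
        raise ValueError(f"treatment must be M or S, got {treatment!r}")
    s = parent.states.copy()
    eps = np.where(layout.labile, model.eps_labile, model.eps_stable)
    flip = rng.random(len(s)) < eps
    up = rng.random(len(s)) < 0.5
    stepped = s.copy()
    stepped[flip & (s == 0.0)] = 0.5
    stepped[flip & (s == 1.0)] = 0.5
    mid = flip & (s == 0.5)
    stepped[mid & up] = 1.0
    stepped[mid & ~up] = 0.0
    shift = parent.stress_shift.copy()
    if treatment == "S":
        shift = shift + model.delta_stress * layout.stress_direction
    return PlantMethylome(states=stepped, stress_shift=shift)


def pool_population(
    plants: list[PlantMethylome],
    expressing: np.ndarray | None = None,
) -> np.ndarray:
    """Population methylation fractions: per-position mean over pooled plants.

    ``expressing`` (bool per plant) marks plants that express their heritable
    stress shift; an expressing plant contributes clamp(state + shift, 0, 1).
    With no shifts this is the plain mean of epiallele states.
    """
    if not plants:
        raise ValueError("empty pool")
    n = len(plants[0].states)
    if any(len(p.states) != n for p in plants):
        raise ValueError("plants must share one position set")
    if expressing is None:
        expressing = np.zeros(len(plants), dtype=bool)
    acc = np.zeros(n)
    for p, ex in zip(plants, expressing):
        v = p.states + p.stress_shift if ex else p.states
        acc += np.clip(v, 0.0, 1.0)
    return acc / len(plants)


def sample_counts(
    fracs: np.ndarray,
    model: EpigenomeModel,
    rng: np.random.Generator,
    layout: GenomeLayout,
    sample_id: str = "sample",
) -> SampleTable:
    """Observed counts from true population fractions.

    Coverage per cytosine record is negative-binomial; the apparent methylation
    probability is p' = p + (1-p)(1-c) — unconverted unmethylated cytosines
    read as methylated.  CG sites emit two records (+ at pos, - at pos+1); the
    chloroplast contig ChrC is generated with p = 0.
    """
    c = model.conversion_rate
    rows_chrom, rows_pos, rows_strand, rows_ctx, rows_p = [], [], [], [], []
    is_cg = layout.contexts == "CG"
    for strand, offset in (("+", 0), ("-", 1)):
        take = is_cg if strand == "-" else np.ones(layout.n_sites, dtype=bool)
        rows_chrom.append(np.full(take.sum(), layout.chrom))
        rows_pos.append(layout.positions[take] + offset)
        rows_strand.append(np.full(take.sum(), strand))
        rows_ctx.append(layout.contexts[take])
        rows_p.append(fracs[take])
    # conversion control: unmethylated chloroplast cytosines
    rows_chrom.append(np.full(model.n_chloroplast, "ChrC"))
    rows_pos.append(1 + 5 * np.arange(model.n_chloroplast))
    rows_strand.append(np.full(model.n_chloroplast, "+"))
    rows_ctx.append(np.full(model.n_chloroplast, "CHH"))
    rows_p.append(np.zeros(model.n_chloroplast))

    chrom = np.concatenate(rows_chrom)
    pos = np.concatenate(rows_pos)
    strand = np.concatenate(rows_strand)
    ctx = np.concatenate(rows_ctx)
    p = np.concatenate(rows_p)
    p_apparent = p + (1.0 - p) * (1.0 - c)
    k = model.coverage_dispersion
    cov = rng.negative_binomial(k, k / (k + model.coverage_mean), size=len(p))
    meth = rng.binomial(cov, p_apparent)
    df = pd.DataFrame({
        "chrom": chrom, "pos": pos.astype(int), "strand": strand,
        "M": meth, "U": cov - meth, "context": ctx,
    })
    order = np.lexsort((df["pos"].to_numpy(), df["chrom"].to_numpy()))
    df = df.iloc[order].reset_index(drop=True)
    is_ctrl = (df["chrom"] == "ChrC").to_numpy()
    return SampleTable(sample_id=sample_id,
                       data=df[~is_ctrl].reset_index(drop=True),
                       control=df[is_ctrl].reset_index(drop=True))


@dataclass
class StudyResult:
    samples: list[SampleTable]
    design: dict[str, str]              # sample -> line id
    truth_responsive: pd.DataFrame      # chrom,pos,direction,labile
    truth_line_effects: pd.DataFrame    # line_id,n_stress_gens,expected_shift
    truth_classes: pd.DataFrame         # chrom,pos,context,class
    layout: GenomeLayout

    def responsive_site_keys(self) -> set:
        """(chrom, pos) keys covering BOTH cytosines of each responsive CG
        site.  A symmetric CG site emits records at pos (+) and pos+1 (-); a
        destranded table normally reports the site at pos, but a sample whose
        plus-strand record failed coverage filters keeps the lone minus record
        at pos+1, so removals must target both coordinates."""
        keys = set()
        for chrom, pos in zip(self.truth_responsive["chrom"],
                              self.truth_responsive["pos"]):
            keys.add((chrom, int(pos)))
            keys.add((chrom, int(pos) + 1))
        return keys


def simulate_study(pedigree: Pedigree, model: EpigenomeModel,
                   outdir=None) -> StudyResult:
    """End-to-end driver: one cytosine report per replicate plus truth tables.

    Fully reproducible from ``model.seed``: the germline of line *i* uses
    substream (seed, 1, i); replicate *r* of line *i* uses (seed, 2, i, r).
    Truth line effects are the expected population shifts
    ``n_S * delta_stress * penetrance``.
    """
    layout = build_layout(model)
    samples: list[SampleTable] = []
    design: dict[str, str] = {}
    for i, (line_id, treatment) in enumerate(pedigree.lines):
        germ_rng = np.random.default_rng([model.seed, 1, i])
        germ = PlantMethylome(states=layout.founder.copy())
        for t in treatment:
            germ = propagate_generation(germ, t, model, germ_rng, layout)
        for r in range(pedigree.replicates_per_line):
            rep_rng = np.random.default_rng([model.seed, 2, i, r])
            plants = [propagate_generation(germ, "M", model, rep_rng, layout)
                      for _ in range(pedigree.pool_size)]
            expressing = rep_rng.random(pedigree.pool_size) < model.penetrance
            fracs = pool_population(plants, expressing=expressing)
            sid = f"{line_id}.{r + 1}"
            samples.append(sample_counts(fracs, model, rep_rng, layout, sample_id=sid))
            samples[-1].line_id = line_id
            design[sid] = line_id

    truth_responsive = pd.DataFrame({
        "chrom": layout.chrom,
        "pos": layout.positions[layout.responsive],
        "direction": np.where(layout.stress_direction[layout.responsive] > 0,
                              "hyper", "hypo"),
        "labile": layout.labile[layout.responsive],
    })
    truth_line_effects = pd.DataFrame({
        "line_id": [lid for lid, _ in pedigree.lines],
        "n_stress_gens": [t.count("S") for _, t in pedigree.lines],
        "expected_shift": [t.count("S") * model.delta_stress * model.penetrance
                           for _, t in pedigree.lines],
    })
    is_cg = layout.contexts == "CG"
    truth_classes = pd.DataFrame({
        "chrom": layout.chrom,
        "pos": layout.positions[is_cg],
        "context": "CG",
        "class": np.where(layout.labile[is_cg], "labile", "stable"),
    })
    result = StudyResult(samples=samples, design=design,
                         truth_responsive=truth_responsive,
                         truth_line_effects=truth_line_effects,
                         truth_classes=truth_classes, layout=layout)
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        for s in samples:
            write_cytosine_report(s, os.path.join(outdir, f"{s.sample_id}.cov.txt"))
        truth_responsive.to_csv(os.path.join(outdir, "truth_responsive.tsv"),
                                sep="\t", index=False)
        truth_line_effects.to_csv(os.path.join(outdir, "truth_line_effects.tsv"),
                                  sep="\t", index=False)
        truth_classes.to_csv(os.path.join(outdir, "truth_classes.tsv"),
                             sep="\t", index=False)
        pd.Series(design).rename("line").rename_axis("sample").to_csv(
            os.path.join(outdir, "design.tsv"), sep="\t")
    return result
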