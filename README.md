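# epitar

Analysis toolkit for the methylome signature of **transgenerational acquired
resistance (TAR)** — the enhanced disease resistance that progeny of
pathogen-stressed *Arabidopsis* plants inherit across generations. The package
takes whole-genome bisulfite sequencing data from the per-cytosine count stage
(Bismark-style cytosine reports) through:

- coverage filtering, median-coverage normalisation, CG destranding and
  group-wise uniting of replicate samples;
- per-position differential-methylation (DMP) calling with beta-binomial
  over-dispersion shrinkage and BH false-discovery control, plus region (DMR)
  calling;
- Ward/Pearson-correlation sample clustering with multiscale-bootstrap AU/BP
  edge support, and PCA summaries;
- direction-aware shared-DMP set algebra, dose-intensity quantification,
  DMP-removal clustering attribution, and labile/stable position overlap;
- mapping DMPs onto genomic features with transposon > gene > intergenic
  priority;
- exact Fisher tests (2×K) with letter groupings for pathogen
  colonisation-class assays.

Because the statistical structure of such studies is hard to probe on real
data alone, the package includes a first-class **pedigree simulator**:
single-seed-descent lines treated mock (M) or stressed (S) each generation,
spontaneous epimutation concentrated at methylation-labile CG positions, a
heritable stress shift at responsive positions that grows additively with the
number of stressed generations, pooled samples of 10 plants, negative-binomial
read coverage and imperfect bisulfite conversion with a chloroplast control
contig. Every downstream stage is tested against this generator's known truth.

## The statistics at the core

Replicate methylated counts at a cytosine are modelled beta-binomially,
`M_i ~ BetaBin(C_i, p, φ)` with `Var(M_i/C_i) = p(1−p)[1+(C_i−1)φ]/C_i`.
Per-position method-of-moments dispersions φ are shrunk toward an empirical
prior fitted across positions, and group differences of pooled methylation
fractions Δ = p̂_A − p̂_B are tested with a Wald statistic using the
beta-binomial variance (a logistic-regression backend with a Pearson-χ²
scale factor is available with the same interface). DMPs are positions with
BH-adjusted q < 0.05, split hyper/hypo by the sign of Δ and per context
(CG/CHG/CHH). Shared DMPs between two stress comparisons require the *same
direction*; positions significant in both but in opposite directions are
counted in both exclusive sections, so the unique union equals the section
sum minus the opposite-direction count. Edge support in sample dendrograms
follows the multiscale bootstrap: presence frequencies BP_r at resampling
scales r ∈ [0.5, 1.4] are extrapolated through a weighted least-squares fit of
`Φ⁻¹(1−BP_r) = d√r + c/√r` to the approximately unbiased value
`AU = 1 − Φ(d − c)`.

## Worked example

Simulate a dose study — one mock line (MMM), one line stressed in the first
generation only (SMM), one stressed three generations running (SSS), three
replicate pools of 10 plants each — and quantify the dose dependence of shared
differential methylation:

```python
import epitar as ep
from epitar.sets import DMPSet

pedigree = ep.build_pedigree(["MMM", "SMM", "SSS"], replicates=3, pool_size=10)
study = ep.simulate_study(pedigree, ep.EpigenomeModel(seed=21))
print("conversion rate:", round(ep.estimate_conversion(study.samples[0].control), 4))

united = ep.preprocess_samples(study.samples, study.design, context="CG")
print("united CG positions:", united.n_sites)

def against_mock(line):
    keep = [j for j, s in enumerate(united.samples) if s.startswith((line, "MMM"))]
    design = {united.samples[j]: ("T" if united.samples[j].startswith(line) else "C")
              for j in keep}
    sub = ep.UnitedTable(united.sites, united.M[:, keep], united.C[:, keep],
                         [united.samples[j] for j in keep], design)
    dmps = ep.call_dmps(sub, order=("T", "C"))
    print(f"{line} vs MMM: {int(dmps['significant'].sum())} DMPs at q < 0.05")
    return DMPSet.from_dmp_table(dmps, label=line)

shared = ep.intersect_dmps(against_mock("SMM"), against_mock("SSS"))
print("shared DMPs:", len(shared.shared), "| unique union:", shared.unique_union)
counts, _ = ep.dose_intensity(shared, threshold=20.0)
print("more pronounced in SSS:",
      counts["pronounced_b_hyper"] + counts["pronounced_b_hypo"],
      "| in SMM:", counts["pronounced_a_hyper"] + counts["pronounced_a_hypo"])
```

Output:

```
conversion rate: 0.9944
united CG positions: 2000
SMM vs MMM: 102 DMPs at q < 0.05
SSS vs MMM: 107 DMPs at q < 0.05
shared DMPs: 98 | unique union: 111
more pronounced in SSS: 89 | in SMM: 0
```

Reading: the bisulfite-conversion estimate recovers the simulated 99.5%
non-conversion control; both stressed lines yield ~100 CG DMPs against the
mock line; 98 positions are differentially methylated in the *same direction*
in both comparisons; and at 89 of those the effect is ≥ 20 percentage points
stronger in the triple-stressed line versus none stronger in the
single-stressed line — the dose-dependent signature the set algebra is built
to expose.

A command-line surface wraps the same functions:

```sh
epitar simulate config.yaml --outdir sim/
epitar unite sim/*.cov.txt --design design.tsv --out united.tsv
epitar dmp united.tsv --design design.tsv --context CG --out dmps.tsv
epitar cluster united.tsv --design design.tsv --nboot 10000 --out tree.nwk
```

## Layout

```
src/epitar/
  simulate.py     pedigree + epigenome model + study simulator
  io.py           cytosine-report IO, filtering, normalisation, unite
  dmp.py          dispersion shrinkage, Wald/logistic tests, DMP/DMR calling
  cluster.py      Ward correlation trees, multiscale bootstrap, PCA
  sets.py         shared-DMP algebra, dose, removal, lability analyses
  annotate.py     feature-priority annotation
  resistance.py   exact 2×K tests, letter groups, assay simulator
  cli.py          `epitar` command-line interface
docs/methods.md   model, parameter and design documentation
```
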