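# Methods

This note documents the models, parameters and numerical conventions behind
`epitar`, and the design choices made where the design was genuinely open.

## Coordinate and format conventions

All coordinates are 1-based with inclusive endpoints (the cytosine-report
convention). The only 0-based half-open surface is the bedGraph/BED exporter
and the BED annotation reader, both of which convert explicitly and are
tested. Cytosine reports are tab-separated
`chrom, pos, strand, M, U, context`; the chloroplast contig (`ChrC` by
default) is split off at read time as the bisulfite-conversion control, since
chloroplast DNA is unmethylated and its apparent methylation estimates the
non-conversion rate `1 − c`.

## Preprocessing

- **Coverage filter**: records above the sample's 99.9th coverage percentile
  are dropped (PCR-duplicate guard). Percentiles interpolate linearly between
  order statistics; the convention is fixed here because the operation's
  common implementations do not agree on one.
- **Normalisation**: sample counts are scaled by
  `median(sample medians)/own median`, rounded half-up on M and on C, then
  U = C − M with M clamped to C and C kept ≥ 1, so no record collapses to
  zero coverage.
- **CG destranding**: symmetric CG pairs (+ at pos, − at pos+1) are summed
  onto the plus coordinate. Unpaired records keep their own coordinate but
  are reported on the + strand so destranded tables are strand-uniform. The
  operation conserves ΣM and ΣC. Note one consequence for position
  bookkeeping: a site whose plus-strand record failed coverage filters in
  some sample surfaces there at pos+1; `StudyResult.responsive_site_keys()`
  returns both coordinates of each simulated responsive site for this reason.
- **Unite**: positions are kept only when covered in ≥ 2 samples of *every*
  group (configurable). Missing entries are NaN, never zero.
- Per-sample QC summaries (coverage and methylation moments) are exposed but
  nothing is auto-discarded; outlier-replicate decisions are left to the
  analyst because no principled automatic criterion exists at n = 3
  replicates.

## Differential methylation

Replicate counts at a position follow a beta-binomial model:
`Var(M_i/C_i) = p(1−p)[1 + (C_i−1)φ]/C_i` with dispersion φ ∈ [0, 1).

**Dispersion estimation.** The raw per-position φ is the method-of-moments
estimate from the replicate variance of p̂ within each group, combined across
the two groups with (n_g − 1) weights. With three replicates per group the raw
estimate is extremely noisy and frequently non-positive, so shrinkage on a log
scale (fitting the prior to floored log values) is dominated by the floor and
biases the posterior mean downward; instead the empirical prior is fitted on
the natural scale — prior mean m from the across-position average, prior
variance v from the across-position variance minus the average sampling
variance — and each position is shrunk by precision weighting,
`φ* = w·φ̂ + (1−w)·m`, `w = v/(v + sampling var)`, applied to the *unclipped*
raw value and clipped to [0, 0.99) afterwards so the empirical-Bayes mean is
unbiased. On data simulated at φ = 0.1 (5,000 positions, 3+3 replicates,
coverage 20) the mean shrunk φ recovers the generative value within ±0.02
(tested). The moment-matched log-normal parameters of the prior are reported
for reference. Degenerate cases: a position with no usable raw estimate sits
at the prior mean; if the across-position prior variance is zero (all
positions identical) the shrunk value equals the raw value.

**Wald backend (default).** Group summaries are pooled fractions
p̂_g = ΣM/ΣC with variance `p̂q̂ · Σ C_i(1+(C_i−1)φ)/ (ΣC)²`; the statistic is
`Δ/√(var_A+var_B)` referred to the standard normal, two-sided. At p̂ ∈ {0, 1}
the variance (only) uses 0.5 pseudo-counts on M and U. With φ = 0 this is
exactly the unpooled two-proportion z-test.

**Logistic backend.** With one binary covariate the binomial-GLM MLE is
available in closed form: coefficient `logit(p̂_A) − logit(p̂_B)`, standard
binomial variance, and a dispersion scale factor equal to the sum of squared
Pearson residuals over the residual degrees of freedom; the squared scaled
coefficient is referred to χ²(1). The scale is applied as estimated (it may
deflate as well as inflate); separation (a group entirely at 0 or 1) is
handled by adding 0.5/0.5 pseudo-counts to every sample of the affected
position. The closed form is validated against a statsmodels GLM fit in the
tests. Both backends are exposed because the field's two standard tools
implement one each; results are labelled with the backend used.

**Multiple testing.** Benjamini–Hochberg, computed per context and per
comparison. DMPs are positions with q < 0.05 (configurable).

**DMR calling.** Qualifying positions (p < 0.01 and |Δ| ≥ 0.1) are chained
when consecutive qualifying positions lie < 100 bp apart; a region must span
≥ 50 bp, contain ≥ 3 qualifying positions, have ≥ 50% of its member positions
qualifying, and show |mean Δ| ≥ 0.10 over member positions. The chaining
parameters are package defaults (segmentation conventions vary between tools)
and are all configurable.

**Why the over-dispersion correction matters.** On null beta-binomial
simulations (20,000 positions, φ ∈ {0, 0.05, 0.15}) the shrinkage-based test
keeps the fraction of q < 0.05 calls at or below the nominal level, while the
naive binomial test (φ forced to 0) calls thousands of false positives at
φ = 0.15 (tested).

## Clustering

The dissimilarity between samples is 1 − Pearson correlation of their percent
methylation profiles, computed pairwise-complete over the positions both
samples cover; PCA instead uses complete-case positions only (the two
conventions are documented because they genuinely differ on missing data).
Positions with across-sample standard deviation strictly below the median are
removed first (ties kept). Linkage is Ward (the ward.D2 update on the given
dissimilarities, via scipy); samples are sorted lexicographically before
clustering so equal-distance merges break ties deterministically, and the
implementation is validated against a brute-force Lance–Williams
agglomeration oracle.

Edge support uses the multiscale bootstrap: at each scale
r ∈ {0.5, 0.6, …, 1.4}, positions are resampled with replacement at size
round(r·n) for `nboot` iterations and each original clade's presence
frequency BP_r recorded. The AU value per edge comes from a weighted
least-squares fit of `Φ⁻¹(1−BP_r) = d√r + c/√r` (binomial-information
weights), extrapolated as `AU = 1 − Φ(d − c)`; BP is reported as the raw
proportion at r = 1. BP values of exactly 0 or 1 are clamped by half a count
before the normal-quantile transform; edges with BP ≡ 1 (or ≡ 0) across all
scales short-circuit to 100 (or 0). Runs with nboot < 100 are flagged
degraded. A clade is called *supported* at the conventional AU ≥ 95 level.

## Set analysis

A DMP is **shared** between two comparisons over a common control only when
significant in both with the same direction; opposite-direction positions are
counted in *both* exclusive sections, so `unique union = section sum −
opposite count` (property-tested on random sets). **Dose intensity**: a hyper
shared DMP is "more pronounced" in comparison B when Δ_B − Δ_A ≥ 20
percentage points (hypo: the same rule on −Δ); the threshold and rule are
configurable since the definition admits variants. Percentages in overlap
reports are rounded half-up to one decimal.

**Removal reclustering** clusters the full and the reduced table with the
same bootstrap seed stream and reports the treatment-clade verdict for both.
Two design notes: (i) removals are keyed by (chrom, pos) and members absent
from the table are counted, not errors; (ii) the experiment is only
informative with enough lines — with two lines per treatment the four
remaining lineages regroup the two treated lines by pure chance about one
time in three after true-signal removal, so the packaged experiment uses
three lines per treatment and the AU ≥ 95 supported-clade rule, under which
true-signal clades score AU ≈ 100 and chance groupings fall below the
threshold in the simulations shipped with the tests.

**Lability overlap** cross-tabulates a DMP set and a comparator set against a
user-supplied labile/stable position catalogue and tests the compositional
shift with a two-sided Fisher's exact 2×2 test (unclassified positions are
tallied but excluded from the test). The choice of a 2×2 exact test is the
package's, as the shift statistic admits alternatives.

## Annotation

The feature index flattens GFF3 (or 4-column BED) annotation into
per-chromosome interval trees with strict priority transposon > gene >
intergenic; within genes, UTRs shadow exons and the remainder is intron.
Priority resolution is independent of record order. The promoter window
(default 1 kb upstream) is exposed as a parameter only; no promoter calls are
made by default because promoter definitions vary.

## Resistance assay

The 2×K exact conditional test enumerates all tables with the observed
margins (vectorised over the free first-row entries) and sums the probability
of tables whose point probability does not exceed the observed one — the
standard two-sided convention — validated against full enumeration on all
tables with total ≤ 40 and against the 2×2 exact test. At assay scale
(150–250 leaves per line, four classes) the enumeration is a few million
tables and runs in well under a second. All-versus-all line comparisons are
BH-adjusted (pooled per figure/experiment) and summarised as a compact letter
display built by greedy insertion over the non-significance graph — the
display convention shows letters only, so the construction algorithm is a
package choice.

## Synthetic data generator

The generator emulates the pedigree structure of multi-generation stress
experiments: single-seed descent, per-generation mock/stress treatment,
final-generation individuals each founding one pooled replicate of
`pool_size` plants (default 10, matching the pooled-leaf sampling such
studies use).

**State model.** Each position carries a diploid epiallele state in
{0, ½, 1} — the simplest model that yields quantitative population fractions.
Spontaneous epimutation flips one epiallele step per generation with
probability `eps_labile` at labile CG positions (default 0.005) and
`eps_stable` elsewhere (default 1e-4); a ½ state steps up or down with equal
probability. These rates are **free simulation parameters**: the source
experiments report no spontaneous rates, and the defaults are chosen only to
put visible but non-dominant lineage noise into a three-generation study, not
as estimates of mutation-accumulation-line rates. `labile_fraction` defaults
to 0.1 of CG positions.

**Stress.** `n_stress_responsive` CG positions (default 100 of 2,000) carry a
designated stress direction — away from their founder state, so shifts are
not clamped. Each stressed generation adds `delta_stress` (default 0.25) to
the germline's heritable shift at those positions; each pooled plant
expresses the accumulated shift with probability `penetrance` (default 0.9),
so the expected population shift of a line with k stressed generations is
`k · delta_stress · penetrance` — additive in the dose, which makes the 3:1
SSS:SMM contrast hold exactly on the truth tables. The defaults put
per-generation population shifts (~22.5 pp) and triple-stress totals (~67 pp)
in the range where single-generation effects are detectable but far weaker
than triple-generation effects, the regime the dose analyses are about.

**Observation model.** Coverage per cytosine record is negative-binomial
(mean 20, size 5); apparent methylation is `p' = p + (1−p)(1−c)` with
bisulfite conversion `c = 0.995` (the 99.4–99.6% range typical of such
libraries); methylated counts are binomial. CG sites emit two records
(pos +, pos+1 −) so destranding has real work to do; `n_chloroplast`
unmethylated cytosines on `ChrC` provide the conversion control. Streams are
split deterministically per (seed, line) and (seed, line, replicate), so the
same seed reproduces byte-identical outputs.

**What the generator does not emulate** — and hence what passing tests do not
show about real data: no sequence-context realism (positions are abstract
coordinates on one nuclear chromosome), no linkage between neighbouring
positions beyond the CG pair, no read-level error or mapping artefacts, no TE
mobilisation or genetic mutation, no environment-by-line interactions, and
line-level noise that is exactly exchangeable across lines. Results on real
libraries can differ wherever those features matter (e.g. DMR structure,
coverage biases, batch effects).

## Problem sizes used in the shipped checks

The test suite and the acceptance script run on deliberately compact
instances chosen as the smallest that exercise each property cleanly: null
FDR at 20,000 positions; dispersion recovery at 5,000; sensitivity at 200
responsive among 2,200; pedigree studies with 2,000 CG positions, 2–3 lines
per treatment and 3 replicate pools; bootstrap support at nboot = 120–200
(the CLI default remains nboot = 10,000, the convention for publication-grade
support values).
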