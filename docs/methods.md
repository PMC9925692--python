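# Methods

`chronopattern` implements a temporal-pattern analysis for balanced
two-condition time-course expression experiments — the design where cultures
are sampled hourly under a vehicle and a drug treatment with a fixed number
of replicate cultures per condition and hour, and the question is *when* and
*in which direction* the drug reshapes each gene's trajectory.  The
motivating system is budding yeast treated with myriocin, a sphingolipid-
synthesis inhibitor that extends chronological lifespan, profiled over the
first six hours of treatment (2 conditions x 7 hourly samples x 3
replicates), but nothing in the package is specific to that experiment.

## Normalisation and gene filtering

Counts are converted to transcripts per million (TPM): per sample, each
gene's count is divided by its effective length in kilobases and the
resulting rates are rescaled to sum to 10^6.  Column sums are enforced to
10^6 within a relative 10^-6 whenever a matrix is tagged `tpm`.

Filtering keeps genes that (a) carry a unique gene-symbol annotation
(duplicated symbols drop every claimant; when no symbol map is supplied all
genes pass) and (b) show sufficient signal: non-zero in at least
`min_expressed_frac` of samples (default 0.5) and mean abundance at least
`min_mean` (default 1 TPM).  The exact signal rule used by the original
study is not recoverable, so both thresholds are configurable and the
removal counts per criterion are logged.

Downstream statistics run on `log2(x + pseudocount)` with pseudocount 1 by
default.  The pseudocount is configurable; 0 is exact on strictly positive
matrices and is what the synthetic recovery tests use, since the generator's
abundances are exactly `2**log2-signal`.

## Two-way ANOVA gate and Euler sectors

Each gene is fit with the classical balanced two-factor fixed-effects
decomposition over condition (2 levels) and hour (default: every sampled
hour except hour 0, which is the pre-treatment baseline — 6 levels in the
default design):

SS_total = SS_drug + SS_time + SS_interaction + SS_error,
df = 1, T-1, T-1 and 2T(r-1).

F ratios use the residual mean square; p-values come from the F
distribution.  The decomposition is computed in closed form, vectorised over
genes, and is checked in the tests against both a naive loop oracle (to
1e-10) and statsmodels OLS `anova_lm`.  Genes with zero residual variation
(all replicates identical) cannot support an F test and are returned
degenerate with all p = 1.

A gene is a DEG when any of the three p-values is <= alpha (default 0.01,
inclusive, uncorrected — multiple-testing control is deliberately reserved
for the gene-set stage; the gate is a screen, not an inference).  The subset
of significant terms places the gene in one of the Euler sectors T, D, I,
T&D, T&I, D&I, T&D&I, or ns.

## Temporal template library

For T analysis timepoints the library holds one flat shape (`00`) plus
non-flat families, each in an `a` orientation and its negated (vertically
mirrored) `b` reflection:

* `01` — change confined to the first hour: (1,0,0,0,0,0);
* `02`-`04` — plateaus switching on at hours 2-4 through a graded
  half-height onset, e.g. `02a` = (0,.5,1,1,1,1), `04a` = (0,0,0,.5,1,1);
* `05` — change confined to the last hour: (0,0,0,0,0,1);
* `06`-`09` — single-hour spikes at the interior hours 2-5;
* `10` — a linear ramp.

That is 21 shapes at T = 6; crossing with three drug-effect classes
(up / down / unchanged) gives 63 patterns.  The construction generalises to
any T >= 3 (4T-3 shapes).

The graded plateau onset is a deliberate design choice: with a hard step at
hour 2, the plateau `02` and the mirrored first-point change `01` are
*identical* after z-scoring — under Pearson matching the two categories
cannot be told apart, and recovery of library-generated data caps out around
91% with arbitrary tie-breaking.  The half-height onset keeps the verbal
taxonomy (a level change reached at hour 2 and held) while making all 21
shapes pairwise non-collinear; the largest remaining inter-template
correlation is 0.924 (late plateau vs. ramp), far enough below 1 that
realistic replicate noise rarely flips an assignment.

## Template assignment and pattern enrichment

A gene's profile is its per-hour mean over replicates — averaged over both
conditions for main-effect (T/D/T&D) genes, per condition for interaction
genes — z-standardized across hours.  The profile is Pearson-correlated with
every non-flat template; the best r wins (ties broken by lowest shape code)
provided r > `r_min` (default 0.85, exclusive), otherwise the gene is
unassigned.  Zero-variance profiles route directly to `00`.  Because
Pearson correlation is invariant to affine rescaling, the template vectors'
scale and offset are immaterial; only their shape matters.

The drug-effect class comes from the ANOVA record: `unchanged` when the drug
main effect misses the gate, otherwise the sign of (drug grand mean -
vehicle grand mean); an exact tie falls back to `unchanged` with a warning.

Pattern over-assignment is tested per pattern with a one-sided exact
binomial test: n = number of assigned genes, null probability 1/63 (uniform
over patterns — the simplest null; the original analysis does not state its
expected-count model), flagged at p <= 0.01.

## Interaction analysis

Genes with p_interaction <= 0.01 are profiled per condition, each profile is
template-matched independently, and the counts land on a 21 x 21
(vehicle shape) x (drug shape) grid.  Cells holding strictly more than
`flag_threshold` genes (default 100) are flagged; genes unassigned in either
condition are tallied separately.

Per-hour drug effects use Fisher's protected LSD: at hour t,
t = (drug cell mean - vehicle cell mean) / sqrt(MSE * 2/r) with the pooled
ANOVA residual MS and its df; two-sided p from the t distribution.
Protection means the comparison is only defined for genes that passed the
omnibus gate — calling it on a non-significant gene raises.  The reported
fold change is log2((drug mean + 1)/(vehicle mean + 1)) on the abundance
scale; the +1 guards zeros and is negligible at TPM-scale means.  A hit is
`up`/`down` when p <= 0.05 and the fold change is positive/negative.

## Overrepresentation analysis

Query lists (pattern members, sectors, grid cells) are tested against GMT
gene sets with the one-sided hypergeometric upper tail
P(X >= Sig | N, Tot, n).  The universe is the genes annotated to at least
one set intersected with the analysed genes; sets outside [10, 2000] members
after restriction are excluded.  Each row reports Tot, Sig,
Exp = n·Tot/N, Ratio = Sig/Exp, p, and the Benjamini-Hochberg step-up FDR
across the tested sets (implemented in-package; cross-checked against
statsmodels in the tests).  Only over-representation is tested.

## Lifespan AUC statistics

Viability curves (percent viable vs. day, per replicate) are summarised by
the trapezoid area under the curve over the measured days — no
extrapolation below the first or beyond the last sampled day.  Groups are
compared by a two-tailed pooled-variance Student's t-test on the replicate
AUCs (Welch available via a flag) with a confidence interval for the
difference of group means.  Zero pooled variance is degenerate: the CI
collapses onto the observed difference.

## Synthetic data generator

The generator emulates the study design, not its biology: a balanced
2 x 7 x 3 grid (~5000 genes), baseline log2 abundance drawn N(6, 2) so
TPM-like magnitudes arise, a configurable fraction of genes following a
uniformly drawn non-flat library template with log2 amplitude `amplitude`
(the template is z-scored, so the amplitude is in log2 SD units), a drug
shift of +/- `drug_shift` log2 units for drug-affected genes (applied to
all hours, or confined to `drug_effect_hours` to plant interaction rather
than a main effect), and i.i.d. N(0, noise_sd) log2 replicate noise.  Hour
0 carries baseline only, mirroring the analysis default of a 6-level time
factor over hours 1-6.  Truth labels reuse the template engine's shape
codes, so recovery checks are a direct join.

Defaults are fixtures chosen once for a plausible regime — noise_sd 0.15
log2 (≈11% CV), amplitude 1.5, drug_shift 1.0 (a 2-fold effect),
frac_patterned 0.2 — not estimates of the original study, which publishes no
noise or effect magnitudes.  What the generator does **not** model: count
sampling noise and the mean-variance relation of real RNA-seq, library-size
and spike-in artefacts, gene-gene correlation, profiles between template
shapes, and asymmetric replicate dispersion.  Passing recovery tests
therefore demonstrate correctness of the machinery under the stated noise
model, not expected assignment rates on real data.

Gene-set fixtures: one set equal to the genes of the most common planted
shape (a guaranteed true positive for ORA) plus uniform random sets (nulls).

## Numerical choices and degenerate inputs

* ANOVA degeneracy: SS_error <= 1e-12 x max(SS_total, 1) is treated as zero.
* Flat-profile routing in assignment uses the same relative tolerance on the
  profile SD.
* Assignment r threshold is exclusive (r > 0.85); gate and enrichment
  thresholds are inclusive (p <= alpha), as printed in the conventions this
  reimplements.
* BH is the standard step-up with a reverse cumulative minimum; output is
  order-invariant and capped at 1.
* All randomness flows through `numpy.random.default_rng(seed)`; identical
  seeds give byte-identical outputs, including pipeline TSVs (fixed float
  format `%.6g`).

## Problem sizes used in the checks

The shipped tests and drivers use 120-5000 genes: 5000 null genes for
type-I calibration, 2000 library-generated genes for the noisy recovery
check, 300-400 genes for interaction and pipeline end-to-end runs.  These
sizes make the whole suite run in well under a minute while keeping the
binomial calibration bands tight.

## Known limitations

* The original study's exact template vectors are unpublished; per-pattern
  gene counts (e.g. which 12 patterns dominate) are reported, not asserted.
* The gate runs on raw per-term p-values by design; its DEG counts are not
  FDR-controlled.
* The ANOVA input scale (raw TPM vs. log TPM) used by the original analysis
  is unstated; both are supported and can shift replicated counts
  substantially (see `analysis/07_deposited_check.py`).
* ORA treats gene sets as flat lists: no GO-DAG propagation or redundancy
  reduction.
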