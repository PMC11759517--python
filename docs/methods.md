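# Methods

This note documents the models and procedures `prmflux` implements, the
parameters that matter, the synthetic-data generator's assumptions, and the
design choices made where the problem was genuinely open. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Assay design

Candidate peptides are produced by in-silico tryptic digestion: cleavage
C-terminal to K/R, suppressed before proline (the Keil rule; configurable
off, since some protocols treat K/R-P bonds as partially cleavable).
Coordinates are 1-based inclusive, e.g. `ATG3[12-24]` for residues 12–24.
The default is fully tryptic peptides (0 missed cleavages); missed
cleavages can be requested and are labeled per peptide.

Selection rules: length within 7–25 residues (LC and MS practicality) and
no methionine (post-lysis oxidation makes Met peptides chemically
unstable). When a peptide fails several rules the verdict reports the first
failure in the fixed order length → methionine, so diagnostics are
deterministic. Every input peptide is returned with a verdict; nothing is
silently dropped. Screening against prior MS detectability evidence is out
of scope; an allow-list hook stands in for it (`fail_detectability`).

Two registries ship with the package: the 41 shortlisted proteins of
interest and the final panel of 37 proteins with quantifiable peptides.
They are transcriptions of the published target lists and carry
accession/gene/category only (no sequences).

## Calibration and LOD/LOQ

The response model is bilinear ("hockey stick"):

    I(c) = b                    for c <= c0
    I(c) = b + s * (c - c0)     for c >  c0

with baseline `b`, changepoint `c0` and slope `s >= 0`. This realizes a
noise plateau at low amounts and a linear response above it, in the spirit
of established LOB/LOD calibration modeling for targeted MS; the functional
form is this package's choice. The changepoint is found on a log-spaced
grid (129 points from c_min/50 to c_max) with golden-section refinement,
ties broken toward the smaller changepoint; baseline and slope are linear
least squares given the changepoint, with the slope clamped at 0.

Before fitting, the saturated top of the series is removed. Two policies:
`drop_top` (always remove the highest concentration — the 1 pmol point of
the reference design routinely loses linearity) and `lack_of_fit` (remove
the top only if its mean response falls more than 20% — configurable —
below the linear extrapolation through the two preceding concentration
means). Fewer than 3 remaining concentrations flags the precursor
not-quantifiable rather than raising.

Uncertainty is nonparametric bootstrap, n_boot = 500 by default,
ci_level = 0.95, all resampling seeded (index-based, so rescaling all
responses by k scales every derived intensity by exactly k):

* **noise bound** — blank responses resampled with replacement plus
  resampled baseline-region fit residuals; the ci_level percentile of these
  draws is `noise_upper`, the predictive upper bound for a blank injection.
* **response band** — replicate responses resampled within each
  concentration; (b, s) refit per resample with the changepoint held at the
  full-data estimate. Re-searching the changepoint per resample adds cost
  without materially changing the band on these designs. The lower
  confidence curve is the one-sided (1 − ci_level) percentile across
  resamples.

LOD is the smallest concentration where the mean fitted curve exceeds
`noise_upper`; LOQ the smallest where the lower confidence curve does.
Crossings are located on a 2048-point log grid over [c_min·10⁻³, c_max]
and refined by bisection; `loq` is clamped to `>= lod` against numerical
slack (the definitions already imply the ordering). No crossing within the
fitted range, or a flat fit, yields NaN LOD/LOQ with a not-quantifiable
flag — the analogue of peptides that cannot be reproducibly detected or
quantified. Calibration responses are first normalized per run to the
background-matrix keratin-18 peptide `QSVENDIHGLR` (run-level scalar);
absent that peptide, raw areas are used with a warning.

Whether the original analysis used a parametric or resampling-based blank
interval is not stated anywhere we could rely on; the bootstrap here is
this package's documented choice, not a claim about the original.

## Quantification

Fragment areas are the atomic inputs. Per precursor and run:

* automatic interference flagging compares each light fragment's share of
  the light total with its share in the heavy reference pattern; a light
  fragment exceeding 3× (configurable) its reference share is flagged. The
  rule is one-sided by design: interference *adds* signal, and a two-sided
  rule would spuriously flag the remaining fragments, whose renormalized
  shares shrink when one fragment is contaminated.
* retained fragments must be present in both labels and unflagged;
  validity requires ≥ 3 retained transitions and positive total heavy area
  (reason codes `lt3_transitions`, `no_heavy`).
* the peptide ratio is Σ light / Σ heavy over retained fragments — this
  cancels run-level intensity scale exactly, which is the point of the
  heavy spike-in.

**LOQ gating and roll-up.** LOD/LOQ are in fmol but ratios are unitless,
so gating uses the back-computed on-column amount: ratio × spiked heavy
amount (default 120 fmol; 12 is the assay's other standard spike). A
peptide above LOQ in at least one run is a *candidate* for its protein; if
the subset of candidates valid in every run is non-empty, only that subset
is used (the stricter published rule), otherwise all candidates are used
with per-run missingness. Both sets and the choice are recorded per protein
in the roll-up log, because the two published descriptions of the inclusion
rule differ and a reader should be able to see which applied. The protein
value per run is the arithmetic mean of the included peptide ratios; a
protein with no candidates is missing everywhere.

**Imputation.** Technical replicates are first averaged into biological
samples (imputation operates at the level where per-condition bars are
drawn). A protein with ≥ 2 measured biological samples and ≥ 1 missing one
has each missing cell drawn from Normal(0.8·μ_measured, σ_measured)
truncated at 0 — a deliberately conservative "present but reduced"
estimate. One draw per cell by default; a multi-draw mode reports the mean
draw. Each imputed cell records the seed and draw index. Fewer than 2
measured samples leaves the cell missing (`insufficient_support`).

## Statistics

* **CV** — 100·sd/mean (n−1 denominator), linear scale. Technical CVs are
  computed within each biological sample's technical replicates and
  averaged across samples. The technical CV *report* divides each CV by the
  c4 constant (≈ 0.886 for triplicates) by default: with n = 3 the raw sd
  underestimates σ by ~11%, so an average of raw triplicate CVs would
  systematically understate the assay's true technical variability. The
  plain `cv()` function applies no correction.
* **Flux** — mean(+BafA1)/mean(−BafA1) per protein and condition, linear
  scale, with a two-sided unpaired t-test between arms. A zero-variance tie
  reports p = 1.0 (no evidence of a difference); zero variance with
  differing means reports p = 0.
* **ANOVA filter** — one-way ANOVA per protein across (condition, BafA1)
  groups on log2 values (abundances are ratio-scale, so effects are
  multiplicative; the log2 choice is this package's). Retention requires
  p strictly below alpha (default 0.01). No multiple-testing correction by
  default, matching the raw-p filter convention; a Benjamini–Hochberg
  adjustment can be applied downstream if desired.
* **Peptide correlation QC** — Pearson correlation of log2 ratios between
  peptides of the same protein across ≥ 3 shared samples; the report lists
  the per-pair values, their median, and pairs below 0.5 (candidates for
  PTM interference or noise-dominated signals).
* **Clustering** — rows z-scored (mean 0, sd 1, n−1 denominator),
  agglomerative clustering with Euclidean distance and complete linkage
  (the defaults of the common heatmap tooling), deterministic leaf order,
  zero-variance rows excluded with a warning. Requires a complete
  (post-imputation) matrix.

## Synthetic-data generator

The generator emulates the study's designs: 7-point 6-fold serial dilutions
(1000 → 0.021 fmol) with 3 replicates and 3 blanks for calibration, and
condition × ±BafA1 × 3 biological × 3 technical replicate treatment
experiments. Ground truth (response curves, fragment patterns, noise CVs,
per-protein condition log2 fold-changes and flux) is serialized with every
dataset.

All noise is multiplicative lognormal with unit mean,
σ_log = sqrt(ln(1 + CV²)), because intensities are positive and
heteroscedastic. The noise chain and defaults:

| factor | drawn per | default CV | role |
|---|---|---|---|
| run scale | run | 10% | instrument drift; cancels in light/heavy ratios |
| technical | run × protein | 5% | net LC-MS noise surviving heavy normalization |
| biological | protein × dish | 5% | culture/preparation variability |
| fragment | fragment area | 1% | integration noise |

The technical factor is deliberately drawn at the (run × protein) level and
shared by that protein's peptides: run-level scale is removed by heavy
normalization, and what remains in real data is the protein-level
reproducibility the assay reports (average ~5% for PRM). Modeling it at
protein level makes the injected CV the quantity the CV report estimates,
which is exactly the recovery property the tests check. A consequence worth
knowing: peptides of one protein are near-perfectly correlated in synthetic
data, so the correlation QC exercised on simulations is a smoke test, not a
PTM-sensitivity test.

In experiments, a protein's on-column amount is
baseline × 2^log2fc(condition), divided by the true flux in the −BafA1 arm
(so the ratio of arm means equals the flux), times the biological and
technical factors. Light areas distribute the amount over the peptide's
fixed Dirichlet-drawn fragment pattern at its response slope; heavy areas
sit at the nominal spike (120 fmol default). Light signal below a peptide's
LOD is dropped entirely while the heavy standard stays, which downstream
becomes an invalid precursor and, if universal, a missing protein — the
imputation path. Blank calibration responses are baseline plus truncated
Gaussian noise (sd = 25% of baseline by default).

What the generator does **not** emulate: chromatographic peak shapes and
integration-boundary errors, retention-time drift, correlated
interferences, peptide-specific digestion efficiency, and
sub-stoichiometric PTM occupancy. Passing recovery tests therefore shows
the *computational* pipeline is unbiased and correctly calibrated under the
stated noise model, not that the wet-lab assay achieves these numbers on
arbitrary samples.

## Problem sizes and seeds

Monte-Carlo checks use sizes at which the relevant estimator's error is
comfortably inside the asserted tolerance: 10,000 draws for the imputation
moments (standard error ≈ 0.1% of the mean), 100 proteins × 2 conditions of
technical triplicates for CV recovery (standard error ≈ 0.2 CV points), and
10 effect-carrying proteins at 3 × 3 replication for effect recovery
(standard error ≈ 0.8 points on a 20% effect under technical-only noise).
Every stochastic step takes an explicit seed; fits and generated datasets
are bit-identical given identical inputs and seed, and CLI manifests record
seeds so `prmflux replay` reproduces outputs exactly.

## Known limitations

* LOD/LOQ depend on the bootstrap percentile at n_boot = 500; very small
  blank sets make the upper bound coarse.
* The bilinear model's changepoint is weakly identified when the series has
  no points on the plateau; the fitted changepoint then drifts upward while
  the crossings (the quantities of interest) remain internally consistent.
* The roll-up assumes proteotypic peptides; a peptide mapped to two
  proteins is a configuration error, not a resolvable case.
* Absolute amounts are indicative: spiked peptide purity is not corrected
  for, so LOD/LOQ and back-computed amounts share any purity bias.
* Modified (PTM-carrying) peptides are not quantified separately.
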