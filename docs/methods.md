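# Methods

This note documents the models behind `tendonkit`: what the synthetic
generators emulate, how the estimators work, the parameter choices that
matter, and what the tests do and do not demonstrate about real data.

## Study design being emulated

The packaged scenario reproduces the structure of a mouse Achilles-tendon
injury study: six groups crossing lesion type (none / unilateral /
bilateral) with running-wheel access (free / blocked), 64 animals monitored
continuously in home cages for 7 days before and 28 days after surgery, and
52 tendons harvested at day 28 for histomorphometry (8 control, 6
unilateral and 12 bilateral tendons per wheel condition). Day 0 is the
surgery day throughout; pre-surgery days carry negative indices.

## Activity traces

The locomotion index is simulated at one-minute resolution (the cadence is
a package choice — fine enough for 3-hour bins, cheap to simulate). The
expected value at minute *t* is

```
E[x(t)] = template[bin(t)] · f(day(t))
```

where `template` holds eight 3-hour levels (bin 0 at lights-on, 07:00;
dark bins 4–7 exceed light bins, peaking in bin 4 just after lights-off)
and `f` is the injury factor

```
f(d) = 1                                   d < 0
f(d) = g + (1 − δ − g)·exp(−d/τ)           d ≥ 0
```

with dip depth δ (so `f(0) = 1 − δ` is the global minimum — activity
bottoms out on the surgery day), recovery time constant τ (days) and
asymptotic gain g (final-to-baseline night ratio). Gaussian noise
(SD 0.05 index units) is added and the trace clipped to [0, 1]. Group
presets encode the qualitative orderings reported for this kind of study:
bilateral-free recovers highest (g = 1.25), unilateral-free fastest
(τ = 2.5 d), blocked-wheel groups end below baseline (g < 1); controls have
δ = 0. These are scenario parameters, not claimed quantitative fits — the
emulated study reports only trends for these curves.

Activity metrics follow the conventional definitions. Light period =
[lights-on, lights-off) half-open, so the light/dark split is an exact
partition; the dark period of day *d* is the 12 h after that day's
lights-off. Baseline normalization divides each post-surgery night mean by
the mean night activity of the last 3 pre-surgery days; control
normalization divides each animal's day 0–27 mean by the wheel-matched
control-group mean. Day 0–27 (not 1–27) is the default aggregation window,
switchable. Days {0, 14} (surgery and food supplementation) are masked from
light-period summaries only. SEM uses the n−1 sample SD.

## Histology fields

A field is 370 × 250 μm at 0.5 μm/pixel (740 × 500 px), chosen so the
5-area × 4-field tendon scheme totals exactly 1.85 mm². Nuclei counts are
Poisson (mean 70 for healthy control); centers are placed by rejection
sampling with a 15 μm minimum spacing (placements forced after 200 failed
attempts are recorded in the ground truth; at control density this
essentially never happens). Nuclei are rendered as anti-aliased filled
ellipses of 14 × 2.8 μm (spindle-shaped tenocyte nuclei) at intensity 2500
counts over a 400-count background, plus Gaussian camera noise (SD 80) on a
16-bit scale. Orientations are drawn from a Normal(μ, σ) folded to
(−90°, 90°]; a Gaussian latent (rather than von Mises) keeps the generator
on the same family the orientation estimator fits. The healthy preset uses
μ = 17.02°, σ = 8°; lesioned groups are hypercellular (110–135
nuclei/field) with drifted direction (26–48°) and larger dispersion
(14–28°), ordered bilateral-free (closest to healthy) → unilateral-blocked
(farthest). Because the minimum spacing exceeds the nucleus major axis,
nuclei never overlap at these densities, which is what makes exact count
recovery a meaningful detector test.

### Nuclei detection

Gaussian smoothing (σ = 1 μm) → global Otsu threshold → 8-connected
components → area filter 8–120 μm² → watershed declumping on the distance
transform for components above 80 μm². The declump trigger is 1.8× the
median *segmented* single-nucleus area of the packaged preset (~45 μm²;
smoothing and Otsu inflate the true 31 μm² ellipse area — using the
geometric area as the trigger would split single nuclei). A constant image
(undefined Otsu) returns an empty set with a warning rather than raising.
Per-object orientation comes from central second moments
(θ = ½·atan2(2μ₁₁, μ₂₀−μ₀₂), x rightward, y down).

### Directionality

Per-pixel orientation is estimated from the structure tensor. Two numerical
choices matter and were made once, on constructed fixtures:

* **Gaussian-derivative gradients (σ = 1 px)** instead of small difference
  kernels. Sobel's angular transfer-function anisotropy biases the
  recovered angle by over a degree for structures near 15–30°, which is
  exactly where the healthy tendon direction sits; Gaussian derivatives are
  rotation-isotropic to well under the 2°-bin resolution.
* **Tensor smoothing σ = 6 px (3 μm), coherence² weighting.** Smoothing the
  tensor at roughly the nucleus scale makes each elongated nucleus
  contribute a single coherent orientation. With a small smoothing scale
  the histogram instead collects the full boundary-tangent spread of every
  ellipse, inflating the fitted dispersion to ~12° even when all nuclei are
  perfectly parallel; at the nucleus scale the fitted SD tracks the latent
  orientation SD (8.4° recovered at a true 8°).

Orientations are accumulated into 90 bins of 2° over (−90°, 90°], weighted
by coherence² × gradient energy and normalized. A single Gaussian (with a
constant baseline absorbing the isotropic floor) is least-squares fitted
after circularly shifting the tallest bin to the center (orientation wraps
with period 180°); the fitted center is folded back. The goodness value is
the circular histogram mass within ±2 SD of the peak. Images where no bin
reaches 2× the uniform level are flagged unreliable; the reported
dispersion then carries little meaning.

The direction *ratio* vs. healthy folds both directions to [0°, 90°] and
divides (ratio 1 = healthy-like departure from the tendon axis); an
absolute angular difference mode is provided for the degenerate case of a
0° reference and for users who prefer deviations. Tendon-level direction
and dispersion are goodness-weighted means of the per-field values
(directions averaged as doubled angles to respect the 180° period), which
agrees with refitting the pooled histogram to about a degree on
homogeneous tendons.

## Scoring rubric

The six sub-scores each map to {0, 1, 2, 3}; THS is their exact integer
sum. The quantitative bands live in a versioned YAML rule table
(`tendonkit/data/scoring_rules.yaml`) so every boundary and its inclusivity
is auditable:

* cellularity fold change: >3 → 0; (2, 3] → 1; [1.3, 2] → 2; <1.3 → 3
  (exact 3 scores 1; exact 1.3 scores 2 — the strict "<1.3" reading);
* alignment: ratio >3 → 0; (2.1, 3] → 1; ratio <1 with dispersion <25% → 3;
  everything else → 2. The published band wording leaves (2, 2.1]
  unassigned and overlaps at 2; the rule table keeps 2.1 as the printed
  score-1 boundary and lets score 2 absorb everything ≤ 2.1 that is not
  score 3;
* COL1: no expression or 0 aligned areas → 0; 1–2 → 1; 3–4 → 2; all 5 → 3;
* vascularity: plexus → 0; scattered/≤1 area aligned → 1; 1–4 areas
  aligned → 2; few vessels aligned as in healthy tendon → 3;
* metaplasia (chondro and osteo share the map): foci in all 5 areas → 0;
  2–4 → 1; 1 → 2; none → 3 ("up to four areas" read as 2–4 since one area
  has its own band).

The dispersion enters the alignment score as a percentage; the package
converts degrees as 100·σ/90 (the source rubric states "25%" without a
unit; this choice puts the healthy ~8° at 9% and the worst groups at
18–31%, straddling the 25% boundary).

## Agreement

Percent agreement, Cohen's κ = (p_o − p_e)/(1 − p_e), and weighted
κ_w = 1 − Σw·observed/Σw·expected with linear (default; conventional for
ordinal clinical scores) or quadratic weights. Categories are fixed at
{0, 1, 2, 3} regardless of which occur. A table where both assessors use a
single identical category has p_e = 1 and is returned as κ = 1 by
convention; zero expected weighted disagreement alongside observed
disagreement raises. The simulated assessors perturb true scores by ±1
steps only — consistent with the high agreement regime this rubric
operates in, and keeping κ_w expectations tractable.

## Inference

Pearson r is product-moment on pairwise-complete rows (n reported per
pair); p from t = r√((n−2)/(1−r²)) on n−2 df, two-tailed; 95% CI from
Fisher's Z′, tanh(atanh r ± 1.96/√(n−3)). |r| = 1 is reported with a
degenerate-CI flag instead of infinities. No multiplicity correction is
applied to the matrix by default (matching the emulated analysis); a Holm
column is available by flag. ANOVA/Tukey, the t-test (pooled Student's by
default — the classical "independent t-test" — with Welch by flag) and the
D'Agostino–Pearson omnibus (n ≥ 8 required) are delegated to scipy behind
this module's interface.

The metric-cohort generator draws (normalized night activity, cell
alignment, angle dispersion, cellularity) from a joint Gaussian whose
correlation matrix sets r(activity, alignment) = 0.41,
r(activity, dispersion) = −0.76, r(cellularity, alignment) = 0.54 and all
other off-diagonals to 0 (this matrix is comfortably positive definite;
smallest eigenvalue 0.086). Factorization is by symmetric
eigendecomposition A = V√λVᵀ, which also handles exact ±1 correlations;
validation symmetrizes and clips eigenvalues in [−1e−10, 0) (round-off),
rejecting anything more negative with the offending eigenvalue named.
Cohort means/SDs (1.0 ± 0.25, 1.8 ± 0.45, 30° ± 8°, 1.8 ± 0.5) are
plausible tendon-level values; only the correlation structure is anchored.

## Pipeline

`run_all` executes simulate → activity → histology → scoring → agreement →
correlation, writing every intermediate table so each stage can be re-run
and audited; the log records the flags actually used. Per-unit seeds derive
from the master seed via `SeedSequence([master, stage_id, unit_index])`
(all below 2³¹), so runs are byte-identical under a fixed seed. The default
configuration keeps the full 64-animal activity design but measures 2
tendons per group at 2 fields per area — image analysis dominates runtime,
and the demo scale keeps a full run interactive; the complete 4-field
scheme is a config change. A design with no lesioned groups skips the
correlation stage with a logged reason (no healing variance to correlate).
The correlation stage draws the tendon-level cohort (default n = 52
tendons) from the metric generator: the per-animal↔tendon activity pairing
is latent in the design, and the joint metric model is the defined carrier
of the correlation structure.

## What the synthetic tests do and do not show

The generators reproduce the statistical *structure* of the study —
circadian light/dark contrast, an injury dip with group-dependent recovery,
oriented elliptical nuclei at group-dependent density and dispersion,
band-consistent semi-quantitative observations, and the reported
correlation signs — with every latent quantity recorded. Passing tests
therefore demonstrate that the estimators recover known inputs under
realistic noise, not that they are accurate on real micrographs: real DAPI
fields have intensity inhomogeneity, touching and out-of-focus nuclei,
staining artifacts and non-Gaussian orientation mixtures that the
generator deliberately omits. Group-level results (e.g. THS means) depend
on scenario presets, which are qualitative: ordered to match the emulated
study, not fitted to it. Known further limitations: no COL1/vessel-channel
image synthesis (those parameters enter as observations), no wheel-usage
signal, no mixed-model or rank-based longitudinal inference.

## Problem sizes

The test suite and acceptance script use 740 × 500 px fields, ≤ 100 fields
per recovery check, 500 cohorts of n = 52 for correlation recovery, 2 000
cohorts for CI coverage, and exhaustive enumeration (4⁶ tables) for the
kappa oracle — sizes chosen so the whole suite completes in about a minute
on one CPU while keeping Monte-Carlo standard errors well below the
quantities being checked.
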