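# Methods

## The inference problem

Multi-well worm-tracking assays yield, per well, a vector of behavioural
features for each of three recording periods (prestim / bluelight /
poststim). Replication is structured: wells are recorded on a small number
of independent tracking days, and wells from the same day share plate,
food, temperature and handling. Day-to-day variation is routinely as large
as or larger than genuine group differences, so treating wells as i.i.d.
replicates inflates type-I error. Every inferential statement in this
package is therefore conditioned on that block structure.

## Block permutation t-test

For a two-group comparison on one feature, the observed statistic is the
two-sample t (Welch form by default; the pooled-variance form is a config
switch — with equal well counts the two coincide, and Welch is the safer
default under imbalance). The null distribution is generated by re-assigning
group labels uniformly at random among the wells *within each day*,
preserving per-day label counts; labels never cross days. Under the null
hypothesis that group labels are exchangeable within a day — which additive
day-level batch shifts do not violate — this test is exact.

Implementation notes:

- When the total number of distinct within-day arrangements R is at most
  `exhaustive_threshold` (default 10,000), all arrangements are enumerated
  and p = #{|t*| ≥ |t|}/R is exact. The canonical screen design (3 days ×
  (3+3) wells) has 20³ = 8000 arrangements and is always enumerated. Note
  the two-sided exact p has a floor of 2/R on balanced designs, because
  every arrangement and its complement give equal |t|.
- Otherwise `n_permutations` random arrangements (default 10,000; 100,000
  available by config) are drawn and the +1-corrected estimator
  p = (1 + #{|t*| ≥ |t|})/(R + 1) keeps p-values valid (never zero).
- Ties in |t| are counted with a relative tolerance of 1e-9 so the
  identity arrangement always counts itself.
- All features of one comparison share a single permutation stream
  (one seeded generator per comparison), and the permutation matrix is
  applied to the whole wells × features matrix via two matrix products on
  per-group sums and sums of squares. This makes 10,000 permutations over
  ~10⁴ features a seconds-scale operation on one CPU and means feature-wise
  results are jointly reproducible.
- Features with zero pooled variance are flagged undefined (p = NaN) and
  excluded; features undefined in more than half the wells of either group
  are excluded up front and logged.

## False-discovery control

Per-feature p-values from one comparison are corrected with the
Benjamini–Yekutieli step-up procedure at q = 0.05, using the harmonic-sum
penalty c(m) = Σ_{i≤m} 1/i, which is valid under the arbitrary dependence
present in behavioural fingerprints. The implementation delegates to
statsmodels' `fdr_by`; tests verify it against the closed-form step-up
formula to 1e-12. Undefined features are excluded before correction so m
counts tested features only. Rejection requires adjusted p strictly below q.

Two consequences worth knowing. First, the exact-p floor of 2/R interacts
with the BY threshold: with m ≈ 10³ features, a feature can only be
rejected if a few dozen features reach small p together, so single isolated
effects are undetectable at 9 wells/group no matter how large — this is a
property of the design, not a bug. Second, power drops quickly with m,
which is the quantitative rationale for screening on a reduced core-feature
set rather than the full fingerprint.

## Feature extraction

Skeletons are ordered head-to-tail midlines (49 points in the synthetic
generator; any count ≥ 5 is accepted) with per-point widths, in µm.

- *Length*: summed inter-point segment lengths.
- *Width*: mean over the middle third of the width profile (ends taper).
- *Curvature*: derivative of the unwrapped tangent angle with respect to
  arc length, on a midline smoothed with a Gaussian of σ = 1 point. The
  per-skeleton summary is the mean absolute curvature over interior points;
  the two points at each end are excluded because one-sided differences
  there bias the estimate (the dominant error term on a circular arc).
- *Speed*: centroid displacement per unit time; the signed variant projects
  the centroid velocity on the centroid→head direction (head identity comes
  from track metadata; no head/tail detection is attempted).
- *Motion mode*: paused when |signed speed| < 10 µm/s (configurable; the
  threshold is not standardised across trackers), else forward/backward by
  sign. The three fractions sum to 1 by construction.
- *QC*: skeletons are retained iff length ∈ [700, 1300] µm **and** width ∈
  [20, 200] µm, bounds inclusive (the convention when a range is stated
  without strictness). Counts of rejected skeletons are logged.
- *Windows*: for each blue-light pulse starting at t₀, features are
  computed in 10 s windows centred at t₀−5, t₀+10 and t₀+20 s (frame
  ranges [t₀−10, t₀], [t₀+5, t₀+15], [t₀+15, t₀+25] × frame rate) and
  averaged over the three pulses. Windows are clipped to the recording.
- *Well aggregation*: unweighted mean over tracks (a duration-weighted
  alternative was considered and rejected for simplicity; with synthetic
  tracks of equal length they coincide). Wells flagged bad are excluded
  from all downstream analysis.

## Fingerprints, clustering, phenospace

Fingerprints concatenate per-period feature vectors in fixed order
(prestim, bluelight, poststim) with a period barcode; nothing is
transformed until `z_normalise`, which z-scores each column across entities
with the sample SD (n−1) and zeroes zero-variance columns. Clustering is
agglomerative with Euclidean metric and average linkage (a common default
for fingerprint heatmaps; both are configurable), on label-sorted entities
so results are input-order invariant. The phenospace PCA is fitted once on
the pooled strain × period mean rows (z-scored feature-wise across those
rows) so that all periods share axes; wells are projected onto the same
axes to attach a standard error of the mean to every (strain, period)
coordinate. Missing fingerprint entries must be imputed (per-feature entity
mean) before clustering; the count is logged.

## Screen inference

Hit rule: for each compound, the three core features (blue-light curvature,
speed, fraction paused) are tested against the disease-vehicle control with
the block permutation test, BY-corrected *within the compound* (m = 3).
A hit must have every core feature significant **and** directed toward the
wild-type control mean; an exactly zero wild-type–vehicle gap counts as
not-toward. Correcting across compounds instead is available as an option
but is not the default: each compound is an independent decision in a
screening funnel. Side effects are computed only at confirmation
replication (24 wells per day × 3 days): D = features separating wild-type
from untreated mutants after BY; a compound's side effects are features
outside D that separate wild-type from the drug-treated mutant. Compounds
with more than `side_effect_threshold` (default 1000) side effects are
flagged.

## Synthetic data: what it emulates and what it does not

A well value is (group shift) + (day shift) + noise: day shifts are drawn
per (day, feature, period) and shared by every well of that day across
groups — the additive batch structure that motivates day-blocking — and
noise is i.i.d. Gaussian (a heavy-tailed option exists but is off by
default). Planted effects are specified on a Cohen's-d scale in units of
the well noise SD and may be restricted to one period (`"feat@bluelight"`).
Defaults: day_sd = 0.3, noise_sd = 1.0 — the assays this emulates report
day-to-day variation clearly visible but smaller than well scatter; the
type-I calibration experiments additionally stress day_sd = 2×noise_sd.
No quantitative effect-size or variance figures are available for real
strains, so all generator magnitudes are calibration choices, not
measurements.

Screen layouts plant compound categories. Full rescuers close the whole
mutant–wild-type gap on the rescue features; toxic compounds additionally
shift a chosen set of off-target period-features; inert compounds change
nothing. The *partial* rescuer default closes 25% of the gap: the design
intent is a rescue that is real but does not reliably clear the
three-core-feature conjunction at screen replication, and an explicit power
simulation of the conjunction rule (joint BY-significance probability at
9 vs 9 wells: ≈0.13 at a 40% rescue, ≈0.003 at 25%) fixed the default at
0.25. With that mix the screen funnel separates categories cleanly; a
library in which "partial" meant 50% rescue would legitimately yield hits
on partial rescuers, because the hit definition requires improvement, not
full rescue.

Skeleton tracks are built from a sinusoidal tangent-angle profile
integrated at fixed segment length, so arc length equals the nominal body
length exactly at every frame; the head leads, translation is constant
while moving, and paused frames freeze both translation and undulation
phase. The "fainter" phenotype pauses the worm for 10 s after each pulse
ends with a configurable probability. The generator does not emulate
pixel-level imaging, segmentation error, track fragmentation, omega turns
or reversals beyond the signed-speed convention, multi-worm collisions, or
non-Gaussian well effects — so passing tests demonstrate correctness of the
analysis chain under the stated statistical model, not robustness to
tracker artefacts.

## Problem sizes and numerical choices

The validation experiments (tests and `scripts/acceptance.py`) use:
10,000 null features for type-I calibration; 50 instances for Monte-Carlo
vs exhaustive agreement (2000 draws each); 20 replicate experiments for
planted-effect recovery (1000 features, 100 planted at d = 3, 9 wells per
group); 10 replicate 50-compound screens for hit precision/recall; one
confirmation-scale study (400 features × 3 periods, 24 wells per day) for
side-effect calibration. These sizes give binomial/medians stable enough
for the stated bounds while keeping the whole validation a ~1-minute,
single-CPU run. Exhaustive enumeration is preferred wherever R ≤ 10⁴ so
the corresponding checks are exact rather than sampled.

## Known limitations

- Inference is at the well level; per-track variation within a well is
  averaged away, matching the track-averaged feature tables the pipeline
  consumes.
- The permutation test loses resolution below 2/R; designs with a single
  tracking day (no freedom) are warned about, not rejected.
- Strain-level fingerprints weight wells equally regardless of worm counts.
- Curvature sign conventions are consistent within the package but the
  summary reports magnitudes only.
- No dose–response modelling: dose is metadata passthrough (single-dose
  screening).
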