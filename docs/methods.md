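# Methods

## Kinematic model

Each glove sample is a set of eleven global orientation unit quaternions
(scalar-first, Hamilton convention — the format common to consumer IMU
fusion processors). The magnetometer-free fusion upstream of this package
means global headings drift arbitrarily; all angles are therefore built
from *relative* rotations between anatomically adjacent sensors, which are
invariant to any rigid rotation applied to the whole hand. The package
verifies this invariance as a property test.

Joint angles use swing–twist reduction: for relative rotation
`q = (w, v)` and unit axis `a`, the twist component is
`normalize((w, (v·a)a))` and the reported angle is `2·atan2(v·a, w)`,
wrapped to (−180°, 180°]. A pure swing (no component about the axis)
reports 0°. Quaternion double cover is resolved by canonicalizing `w ≥ 0`
plus continuity unwrapping along the time axis; physiological joints stay
far from ±180°, so unwrapping only guards against noise.

The device's per-angle rotation axes are not public. The hand model
declares them as constants in each sensor's local frame: x = mediolateral
(flexion axis for MCP/PIP), z = palmar-dorsal normal (finger-spread axis),
and a fixed oblique axis (0, 0.5, 0.866) normalized for thumb opposition.
These are model conventions, not reconstructions of the device firmware;
any consistent choice yields the same Δ-angles because simulation and
extraction share the model.

Calibration: the *Reset* posture's orientations become per-sensor
references; every frame is re-expressed as `q_ref^{-1} ⊗ q`, so all joint
angles on the reset frame are exactly 0° by construction, and calibration
is idempotent.

## ROM extraction

The course signal for a pattern is a scalar time series: the spread or
opposition angle directly, or — for fist opening — the mean over the four
long fingers of (MCP + PIP), keeping units in degrees of composite
flexion. Movements are detected by prominence-based peak finding
(`scipy.signal.find_peaks`) with prominence
`max(10°, 20% of the run's global amplitude)`; each peak is paired with
the signal minimum since the previous peak, yielding trough→peak segments
in the movement direction analyzed per pattern. This is amplitude-based on
purpose: it tolerates irregular sampling and plateaus without assuming
movement timing. A trailing rising edge that ends the recording at its
maximum is counted as a final peak if it clears the prominence.

Δ-angle = peak − trough per segment. Revision discards values above a
physiological ceiling (finger spread 90°, thumb opposition 180°, fist
opening 360° — configurable) or below 0.25 × the run median (incomplete
movements); every discard carries a reason code, and kept + discarded
always equals detected. The mean of the kept Δ-angles is the assessment
outcome. If a patient cannot perform a pattern (no detected movements, or
all discarded), the outcome is *missing*, never zero — zero would fake a
measured absence of motion.

## Synthetic data

`simulate_run` is the exact inverse of the extraction chain: raised-cosine
strokes 0 → ROM → 0, one oscillation per pair of alternating obstacles
(50-obstacle course → 25 target movements), at 25 Hz with one second per
obstacle. Joint targets are converted to sensor quaternions by chaining
proximal→distal rotations about the model axes; optional orientation noise
applies a small random-axis rotation (SD in degrees) to every sensor per
frame. It reproduces the *geometry and timing structure* of a run; it does
not emulate soft-tissue artifact, sensor misalignment from glove fit,
drift, or behavioral variation between strokes, so pipeline tests
demonstrate correctness of the computation, not robustness to every
real-world artifact.

`simulate_cohort` uses a single-factor latent design: one subject ability
factor `U_i ~ N(0,1)`. Per-visit ROM latents load on `U_i` with
`sqrt(ρ)` (ρ = test–retest correlation, default 0.9, consistent with the
good-to-excellent reliability the device class achieves) and get marginal
group means/SDs set to the published impaired / non-impaired summaries
(finger spread 32.7 (15.8)° vs 47.0 (6.7)°; thumb opposition 91.6 (36.1)°
vs 117.3 (15.6)°; fist opening 129.2 (36.2)° vs 154.5 (12.4)°) at the
study sizes 14 / 11. Clinical scores load with `target_r / sqrt(ρ)` so
their cross-sectional correlation with ROM approximates the target
(defaults follow the published magnitudes: grip 0.70, MRC 0.40,
INCAT −0.55, R-ODS 0.40); infeasible combinations (|loading| > 1) are
rejected at config time. Ordinal MRC/INCAT arm sub-scores arise by
thresholding latent function/disability, which produces the heavy ties
real ordinal scales show. Grip-strength marginals (45 (20) vs 85 (18) kPa)
are synthetic choices — subgroup grip summaries are not published. Group
labels are assigned by design, never by thresholding outcomes, mirroring
clinician-assigned impairment status. No time trend is simulated by
default (the study cohort was stable); `time_slope_deg` exists for power
experiments. NCV/CSA columns are only populated at T2/T4, following the
study schedule. A single shared factor is deliberately the simplest
mechanism that hits group separation, reliability and correlation targets
simultaneously; it cannot represent, e.g., dissociations between patterns
within a patient.

## Statistics

* **ICC(A,1)** — two-way, absolute-agreement, single-measure form, computed
  from the ANOVA mean squares
  `(MS_R − MS_E) / (MS_R + (k−1)MS_E + (k/n)(MS_C − MS_E))` with the
  F-based McGraw–Wong confidence interval and Koo & Li rating bands.
  Single-measure is appropriate because a single assessment per timepoint
  is analyzed. Rows with missing sessions are dropped and counted.
* **Weighted kappa** — linear weights `w_ij = 1 − |i−j|/(k−1)`, asymptotic
  (Fleiss–Cohen–Everitt) standard error, Landis & Koch bands.
* **Welch t-test** — from raw samples or printed summaries; the two paths
  agree exactly, which the suite asserts.
* **ROC** — trapezoidal AUC (equals the Mann–Whitney U/(n⁺n⁻) identity,
  asserted against an independent rank computation); impairment is the
  positive class and lower ROM flags impairment, so the decision rule is
  "ROM ≤ cutoff ⇒ impaired". The cutoff maximizes Youden's J with ties
  broken toward higher specificity. The composite ROC z-standardizes each
  feature over available subjects, sign-aligns so larger = better
  function, and averages available features per subject.
* **Correlations** — Pearson for metric pairs, Kendall tau-b (tie-corrected)
  for ordinal; Cohen bands; two-sided p; no multiplicity correction, by
  design of the validation battery.
* **Mixed models** — `statsmodels` MixedLM, REML, random intercept per
  subject. Categorical time gives the repeated-measures-ANOVA analogue via
  an omnibus Wald test over the time dummies, followed by Holm-adjusted
  pairwise contrasts. The slope comparison stacks two z-standardized
  instruments and tests the time × instrument interaction; its type-I rate
  measured over 200 null simulations at n = 25 is ~7.5% (Wald z is mildly
  liberal at this size), within the accepted 2–9% calibration band.

## Numerical and scale choices

Angles are degrees everywhere; radians never surface in interfaces.
Quaternions below norm 1e-9 are rejected as invalid samples naming sensor
and timestamp. Streams round-trip through CSV/JSON-lines at 1e-9
quaternion precision. Simulation sizes used in tests: full courses are
1251 frames (50 s at 25 Hz); replicate-cohort checks use 200 seeds at the
study's 25-subject design; segmentation noise checks run 100 seeds at the
signal level. Timepoint vocabulary is T0–T4 with T0 (the familiarization
visit) excluded from analyses by default; the cohort carries one analyzed
hand per subject (the dominant, affected side).

## Known limitations

The revision rule (ceiling + 0.25 × median floor) is a declared,
configurable stand-in: the device vendor's exact revision procedure is not
public. Segmentation is signal-driven; if the original analysis windowed
Δ-angles by the game engine's obstacle timing, per-movement correspondence
could differ on noisy runs even though clean-run counts agree. The LMM
pairwise contrasts use normal-approximation Wald tests, slightly liberal
for small cohorts. Published cohort-dependent results (ICC 0.83–0.94,
AUC 0.714–0.929, the correlation table) depend on unavailable patient
data; the package reproduces their *structure* on synthetic cohorts and
the printed-summary statistics (Welch p-values) exactly.
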