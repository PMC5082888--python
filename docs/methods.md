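# Methods

## Model and assumptions

The estimator treats the head as a homogeneous attenuating medium per
local region: detected intensity follows I_out = I_in·exp(−μl) with
μ = μ_a(t,λ) + μ_s(λ). Three assumptions carry the whole method:

1. **Constant, linear scattering.** μ_s(λ) = γ₁(1 − γ₂λ) with
   γ₁ = 1.45 mm⁻¹ and γ₂ = 4.5×10⁻⁴ nm⁻¹ (0.954 mm⁻¹ at 760 nm,
   0.908 mm⁻¹ at 830 nm). Scattering is assumed uniform across the probed
   region and constant in time.
2. **Neighboring-channel homogeneity.** The short and long pair of a
   gradient channel are assumed to sample the same attenuation
   coefficient; their acquisition-time offset is 1/(frame rate × optode
   count) ≈ 17 ms for 32 optodes at 1.81 Hz, which justifies treating μ
   as common. Under this assumption the spatial absorbance gradient
   (A_long − A_short)/δl equals μ_a + μ_s exactly, and any *additive*
   absorbance term shared by the two pairs (scalp signal, instrumental
   common mode) cancels identically.
3. **Two-species absorption.** μ_a is a linear combination of HbO and HbR
   extinction; the 2×2 wavelength system is solved per sample. The
   condition number of the default extinction matrix is ≈3.5; the
   inversion refuses matrices with condition number above 10⁶.

Negative concentrations are never clipped: they indicate model mismatch
and are logged as warnings so they surface in pipeline runs.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| wavelengths | 760, 830 | nm | standard CW pair straddling the isosbestic point |
| γ₁, γ₂ | 1.45, 4.5e-4 | mm⁻¹, nm⁻¹ | adult-head scattering model |
| extinction table | Prahl compilation | mm⁻¹·μM⁻¹ (ln base) | the method's source does not print its values; the shipped TSV carries the citation and is swappable (`ExtinctionTable.from_tsv`) — absolute concentration scale depends directly on this choice |
| DPF (MBLL baseline) | 6.0 both λ | — | common literature value; configurable |
| short separation | 5 | mm | scalp-sampling channel |
| long separations | 12.5–35.4 (patch) / 15–45 (nominal line bundle) | mm | see geometry note below |
| polynomial order | 4 | — | drift removal over the full 320 s recording |
| low-pass cut-off | 0.15 | Hz | removes respiratory (~0.3 Hz) and aliased cardiac (~0.71 Hz) lines; order-4 Butterworth, zero-phase |
| HRF | double gamma (6, 16, 1, 1, ratio 6) | s | canonical form; the source names the form but not parameters, so the standard defaults are used |
| activation rule | t > 0 and one-tailed p < 0.05 at df = 53 | — | df is M−1 for the M = 54-sample averaged trial; see "df convention" below |
| CNR windows | task 6–16 s, rest −6–0 s | — | fixed analysis windows |
| ROI mean window | 4–14 s | — | summary statistic of active channels |
| epoch window | −6 to 24 s | — | covers both the CNR rest window and the ROI mean window |

## Geometry

The default montage reconstructs a 40 × 15 mm motor-cortex patch: four
rows 5 mm apart, each with two inward-facing emitters (x = 0 and 40 mm)
and six shared detectors (x = 5, 12.5, 17.5, 22.5, 27.5, 35 mm). Each
emitter's 5 mm neighbor is its short-separation detector; the remaining
five row detectors plus one detector borrowed from the paired row form
its six long detectors — 8 emitters + 24 detectors = 32 optodes, 8
bundles, 48 gradient channels. The published arrangement fixes the
topology (counts, patch size, separation range) but not the within-patch
coordinates, so the spacings here are the package's documented choice; a
collinear `line_bundle_layout()` with the exact nominal separations
(5, 15, 25, 30, 35, 40, 45 mm) is provided for controlled work. The
nominal list contains five published long distances; the sixth (45 mm) is
a package default added so a full bundle yields six gradients, and all
separations are config-overridable. Channel ids are bundle-major,
distance-ascending. Coordinates are planar-scalp approximations — the
channel sits under the pair midpoint at depth half the separation — with
no head-surface registration.

## The df convention

The activation t-test uses df = M − 1 = 53 for the M = 54-sample averaged
trial, although a two-regressor fit conventionally leaves M − 2 = 52.
The M − 1 convention is retained deliberately (it shifts the critical t
from 1.675 to 1.674, i.e. by less than the reporting precision) and df is
configurable. `ActivationConfig` accepts an explicit `t_crt` but
validates it against the Student quantile at (df, α) to 10⁻³.

## Robust fit

Channel statistics use iteratively reweighted least squares with Tukey
bisquare weights at the conventional tuning constant 4.685 (statsmodels
`RLM`), matching the default of the robust-fit routine this analysis
style is usually run with; plain OLS is available via
`ActivationConfig(method="ols")`. Numerically perfect fits collapse the
robust scale estimate, so a zero-residual OLS pre-check reports a capped
t of ±10⁶ instead.

## Synthetic data: what it emulates, and what it does not

The simulator reproduces the acquisition geometry and paradigm: 32
optodes / 48 channels, 1.81 Hz, 760/830 nm, 20 s initial rest plus ten
trials of 10 s task + 20 s rest with a seeded, balanced (5+5) random
condition order — 320 s in total. Per physical pair it composes, in
absorbance space: the concentration-driven attenuation (baseline
~5 μM HbO / ~3.4 μM HbR, echoing typical absolute-scale estimates;
HRF-shaped responses of 0.35/0.25 μM for the two conditions in one
whole bundle each; HbR responding at −0.33× the HbO response), a
per-channel quartic drift (±0.5 μM scale), systemic oscillations
(cardiac 1.1 Hz, respiratory 0.3 Hz, Mayer 0.1 Hz; 70% injected into the
scalp compartment and 30% cerebral), a superficial common-mode term
shared by all pairs of a bundle (smoothed noise, sd 0.01 absorbance
units — several times the response's absorbance footprint, so scalp noise
*dominates*), and white measurement noise (sd 6×10⁻⁵ absorbance, chosen
so the propagated concentration noise is roughly 10% of the default
response amplitude on a typical gradient channel).

Two modeling choices deserve emphasis:

- **Phase-diffused oscillations.** The 30 s trial period is an exact
  multiple of the 0.1 Hz Mayer period; a strictly periodic sinusoid would
  be phase-locked to the paradigm and never average out across trials —
  a degeneracy real physiology does not have. Oscillations therefore
  carry a random-walk phase (0.15 rad/√s), giving them a realistic
  finite coherence time. The cardiac line aliases to 0.71 Hz under
  1.81 Hz sampling, still inside the low-pass stopband.
- **Bundle-granular responses.** Exact forward–inverse amplitude recovery
  requires the short and long pair to share the response attenuation
  (assumption 2 above), so a bundle's short pair carries the response
  only when *all six* of its gradient channels respond identically —
  hence the default responding sets are whole bundles. Partial-bundle
  responses are supported but recover with a geometric inflation factor
  of l_long/δl, which is exactly the crosstalk the homogeneity assumption
  trades away.

Not emulated: anatomically realistic photon migration (banana-path
partial volumes), motion artifacts, subject-to-subject variability,
wavelength-dependent pathlength. Passing tests therefore demonstrate the
*arithmetic and statistical* correctness of the pipeline and its
noise-cancellation structure, not field performance on real heads.

## Numerical choices

- Polynomial detrending fits on a [0, 1]-scaled abscissa for
  conditioning; residual and trend are both returned and the operation is
  idempotent to ~10⁻⁹.
- The low-pass filter is an order-4 Butterworth applied
  forward–backward (`sosfiltfilt`, odd-reflection padding of default
  length), so the effective attenuation is squared and phase is exactly
  zero; outputs are bit-reproducible given a configuration.
- Common-mode cancellation in the gradient is exact in the algebra; in
  floating point, (A+s) − (A_short+s) can differ from A − A_short in the
  last ulp, so "unchanged" means to ≤10⁻⁹ μM for arbitrary inputs (and
  bit-identical for exactly representable ones).
- Min–max normalization of the activation map spans all 48 channel
  summaries; inactive channels are pinned to exactly 0 afterwards, and an
  all-equal active map normalizes to 1 (division-by-zero rule). A map
  with no active channels skips normalization with a warning.
- Reported summary tables round half-up at 2 d.p. via decimal
  arithmetic on the printed inputs, so exact ties (e.g. a 9.665 mean)
  round the way published tables do rather than the way binary floats do.
- Seeds: every stochastic component (paradigm order, all noise terms)
  derives from a single integer seed; identical seeds give bit-identical
  recordings.

## Design decisions on open points

- Filtering is applied to the continuous series, then epoched (the
  alternative — epoch, then filter — is not offered).
- The activation t-test runs on the trial-averaged series (M = 54), not
  the full recording.
- The two-condition comparison summarizes each trial by its 4–14 s
  window mean — the same statistic as the activation map — before the
  two-sample t-test; the HR summary window is 0–20 s post-onset.
- MBLL reference intensity defaults to the mean of the initial 20 s rest
  (first-sample reference available).

## Known limitations

- The absolute concentration scale is only as good as the extinction
  table and the homogeneity assumption; no attempt is made to reproduce
  any particular subject-level absolute magnitudes.
- The activation criterion applies no multiple-comparison correction, and
  the 0.15 Hz low-pass leaves residual noise strongly autocorrelated, so
  the *full-pipeline* false-positive rate of the uncorrected threshold
  substantially exceeds the nominal α that holds for white noise (the
  null calibration in the tests is therefore stated for white-noise
  traces, where the criterion's one-tailed rate is ≈0.05). Prewhitening
  or cluster statistics are out of scope.
- With only five trials per condition, responses of one condition are
  imperfectly averaged out of the other condition's epochs, producing
  occasional cross-condition activations — visible in the worked example
  and inherent to short randomized designs.
- Planar geometry: depth is a separation proxy, not a tissue-layer model.
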