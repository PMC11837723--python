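# Methods

This note documents the models, parameters and design choices behind
`sfpf`: what is computed, why the defaults are what they are, and what
the synthetic data can and cannot show.

## Physiology core

Saturation–tension coupling uses the Severinghaus form of the
oxyhemoglobin dissociation curve,

    S(P) = 1 / (23400 · (P³ + 150·P)⁻¹ + 1),

whose P50 is ≈ 26.86 mmHg. The inverse is computed in closed form
(Cardano's solution of P³ + 150P − K = 0, K = 23400·S/(1−S)), so the
forward/inverse round trip is exact to numerical precision — no
iteration, no tolerance knobs. pH, PaCO₂ and temperature shifts of the
curve are not modeled; a scalar shift hook exists but defaults to 1 and
is outside the validated scope.

The alveolar gas equation PAO₂ = FiO₂·(Pb − PH₂O) − PaCO₂/RQ uses
sea-level standard constants (760 / 47 mmHg, RQ 0.8). These are held in
`PhysiologyConstants` and configurable because any fixed choice encodes
assumptions about altitude and metabolism. The Respiratory Index
RI = (PAO₂ − PaO₂)/PaO₂ may come out slightly negative on noisy inputs
(measured PaO₂ above computed PAO₂); such values are retained and
handled by the trending gate's RI floor rather than clipped, because
clipping would bias proportional-change statistics.

## Severity classification

Thresholds are the 2024 global-definition boundaries (PF 100/200/300;
SF 148/235/315), inclusive on the more-severe side, applied to
full-precision ratios (no rounding before thresholding). The
admission-level "most severe sustained" category requires at least two
consecutive classifications at or above a category; formally it is the
maximum over adjacent valid-datapoint pairs of the pairwise minimum
category. Two open points were resolved as follows: a single-datapoint
admission falls back to that datapoint's category (excluding such
admissions would silently drop them), and "consecutive" means adjacent
*valid* datapoints regardless of the time gap between them.

## Time matching

One candidate datapoint is built per ABG event.

* **Reference time.** For high-resolution admissions with an arterial
  pressure channel, the draw time is the end of the latest ≥ 30 s gap
  in the 1-Hz pressure samples within 15 min before the lab timestamp
  (the line is flushed during a draw; the latest gap is chosen because
  the draw immediately precedes the lab result). Otherwise the nominal
  lab timestamp is used.
* **Signal summary.** SpO₂ and FiO₂ are the median of samples between
  5 and 2 min before the reference time (window closed on both ends —
  deterministic and testable) for high/minute-resolution data, or the
  nearest sample within 30 min for hourly data (ties go to the earlier
  sample).
* **Settings channels.** FiO₂ is an event-sampled setting (recorded on
  change), so it is forward-filled onto the SpO₂ sample grid before the
  windowed statistics are applied — this reproduces how charted
  settings appear in clinical databases and prevents a sparse setting
  channel from producing spuriously "incomplete" datapoints.
* **Validity.** A datapoint is valid iff it is complete (PaO₂, SpO₂,
  FiO₂ all matched), SpO₂ ≤ 97% (above that the dissociation curve is
  too flat for SpO₂ to carry information), and support criteria hold
  (invasive ventilation / NIV / CPAP with PEEP ≥ 5 cmH₂O, or HFNO with
  flow ≥ 30 L/min). The first failing rule is recorded; the filter is
  idempotent and order-preserving, and the per-reason counts partition
  the excluded set.

The admission's resolution class is not part of the CSV schema; when
absent from a cohort manifest it is inferred from the SpO₂ channel's
median sampling interval (≤ 2 s high, ≤ 120 s minute, else hourly).

## Synthetic cohort generator

The generator's purpose is *structure*, not parameter fidelity to any
particular hospital: it produces data in which the known failure modes
of the SF ratio are present and measurable.

* **Gas exchange.** Each admission draws log RI ~ N(ln 4.5, 0.55) and
  follows a random walk (hourly log-sd 0.10) with rare worsening jumps
  (probability 0.015/h, factor 1.6). The initial distribution yields a
  moderate/severe-heavy cohort, the case mix in which the surrogate
  question is clinically pressing.
* **Titration.** FiO₂ is reviewed every 15 min against the observed
  SpO₂: below 92% it steps up by 0.10, above 96% down by 0.05 (hypoxemia
  corrected faster than hyperoxia), clamped to [0.21, 1.0]. This policy
  is what makes the SF ratio FiO₂-determined: the numerator is pinned
  to the target band while the denominator tracks illness severity.
* **Blood gases.** ABGs occur at U(1, 6) h intervals. PaCO₂ ~ N(42, 5)
  truncated to [25, 80] is redrawn at each ABG and held constant in
  between, so the RI computed from an ABG equals the latent RI at that
  moment while remaining independent across gates. Co-oximeter SaO₂
  noise sd is 0.004 (fraction).
* **Oximeter error.** SpO₂ = round(SaO₂ + slope·(SaO₂ − 94) + ε),
  ε ~ N(0, 2.0²), clamped to (0, 100]. See calibration below.
* **Resolutions.** The SpO₂ channel is emitted at 1 s / 60 s / 3600 s
  per the admission's class; FiO₂ is event-sampled. High-resolution
  admissions also carry a 1-Hz pressure channel with a 45–90 s gap
  before each draw (probability 0.9) and a lab delay of 2–10 min on the
  nominal timestamp; lower resolutions use the draw time as the lab
  time, since no waveform correction is possible there anyway.
* **Determinism.** Admission *i* uses a generator seeded from
  (master seed, i), so cohorts are byte-reproducible and admissions
  mutually independent — dropping one leaves the others unchanged.

### Oximeter calibration

The error model was calibrated jointly with a documented **reference
saturation mix** — SaO₂ = 100 − (2 + Exp(mean 2.75)), truncated at 40 —
a left-skewed, ICU-like distribution (mean ≈ 95.3%) whose bulk stays
below 98% so that the 100% ceiling censors few readings. Against this
mix the defaults (slope 0.45, crossing 94, sd 2.0) give mean bias
≈ +0.4%, precision ≈ 2.1%, and a recoverable bias-profile zero crossing
at ≈ 94.7%.

Two estimator notes. The ceiling clamp plus errors-in-variables (the
noise appears in both the bias and the SpO₂ regressor) systematically
pulls the bias-on-SpO₂ regression crossing upward; a shallower slope
(e.g. 0.25) cannot simultaneously produce a ≈ +0.5% cohort bias and a
crossing recoverable near 94, which is why the steeper — and, at low
saturations, more realistic — slope is the default. Second, the slope
and noise sd themselves are recovered from the OLS of SpO₂ on SaO₂
(fitted slope − 1; residual sd), which is unbiased because SaO₂ is the
reference; only the crossing uses the bias-on-SpO₂ line, matching how
bias profiles are plotted.

## Agreement and trending analyses

Confusion matrices put the PF category on rows (reference) and SF on
columns (test). Overall accuracy is trace/total; per-category recall is
reported as absent (not zero) for empty reference rows; over/under
rates count cells above/below the diagonal so that
accuracy + over + under = 1 holds exactly in counts. FiO₂ bins are
[c − 2.5, c + 2.5) percentage points at multiples of 5 (half-open to
avoid double counting); pooled accuracy equals the n-weighted bin mean
by construction. The SF–PF correlation is computed on raw ratios of
valid datapoints, pooled across the cohort.

Trending pairs adjacent valid datapoints within an admission. The
stability gate keeps pairs ≤ 6 h apart with proportional RI change
within ±20%; proportional (not absolute) change matches the ± phrasing
of the gate and is undefined at tiny RI, hence a floor of 0.05 on the
first RI with separate accounting, likewise for pairs missing PaCO₂
(which are still usable for change detection, which needs no RI).
Change detection is direction-only (down/same/up on each scale): the
detection rate is the fraction of PF-changed pairs whose SF transition
has the same direction. Change correlations default to pairs where FiO₂
actually changed; a correlation whose component has zero variance is
reported absent rather than as a number.

## Conversion equations

The bundled registry holds the two published linear imputations whose
coefficients could be transcribed with confidence — Rice 2007
(SF = 64 + 0.84·PF) and Bilan 2015 (SF = 57 + 0.61·PF) — plus a
package-derived log-linear reference, ln PF = −0.6371 + 1.0557·ln SF,
fitted to Severinghaus-curve-exact SF/PF pairs (PaO₂ 40–92 mmHg ×
FiO₂ 0.21–1.0, SpO₂ ≤ 97%) and labeled synthetic in its source field.
R² and MAE are always computed on the PF scale (log-linear predictions
exponentiated first) so the two forms are comparable. Equations stated
in the SF-from-PF direction are inverted for prediction; SF values at
or below a linear equation's intercept are outside its invertible
domain and are excluded per equation, with the evaluated n reported.
The published coefficients are sanity-checked against a refit oracle:
on curve-exact data the Rice prediction's MAE over PF ∈ [50, 300] stays
small relative to the ratio scale and is dominated by the refit.

## Numerical conventions

Timestamps are seconds since admission; SpO₂ is percent, SaO₂ a
fraction, FiO₂ a fraction in [0.21, 1.0] (values > 1 read as percent;
values < 0.15 rejected as implausible). Duplicate channel timestamps
collapse to their median. CSV round trips are exact: numeric fields are
parsed with correctly-rounded conversion because the fast pandas parser
can be one ulp off, which would break reproducibility checks.
Percentages in reports are carried as fractions and rounded only at the
JSON boundary (10 decimal digits).

## Problem sizes

The default study conditions — and the sizes used by the test suite —
are 200 admissions × 48 h at minute resolution (≈ 2 800 ABGs, ≈ 2 600
valid datapoints), which a single CPU simulates and analyzes in a few
seconds. Calibration and recovery checks use n = 10 000–20 000 pairs.

## Limitations

The generator reproduces the *mechanisms* (titration pinning,
dissociation-curve flattening, heteroscedastic oximeter error,
intermittent ABGs, waveform gaps), not any hospital's case mix. It does
not model motion artifacts, skin pigmentation or perfusion effects on
oximetry, dyshemoglobins, hemoglobin or shunt physiology, ECMO, support-
mode changes within an admission, or correlated PaCO₂ dynamics; the
induced severity distribution is more severe-heavy than typical
registry cohorts. Passing mechanism tests therefore shows that the
pipeline measures these effects correctly where they exist — it does
not predict their magnitude in any real population. The oximetry
calibration anchors hold for the documented reference mix, not for
every cohort the generator can produce.
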