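# Methods

This note documents the models, parameter choices and numerical decisions
behind `optoerg`, and what the synthetic testbed does and does not show about
real recordings.

## Photometric model

Ganzfeld flash stimulators report flash energy photometrically (cd·s/m²);
channelrhodopsin actuators are characterized by retinal photon flux.  For a
fixed stimulator geometry and a dilated mouse pupil the mapping is linear,
so a single constant converts between the scales:

    flux [photons·cm⁻²·s⁻¹] = k_flash × energy [cd·s/m²]

`k_flash` defaults to `8e14 / 68 ≈ 1.176e13`, anchored at the ReaChR
activation threshold (8×10¹⁴ photons·cm⁻²·s⁻¹ ↔ 68 cd·s/m²).  A flash is
classified *ReaChR-activating* when its weighted flux reaches the threshold;
the comparison is inclusive because the anchor equates the threshold flux
with a concrete flash energy.  Published flux figures for 68 and
100 cd·s/m² are mutually consistent with this constant; a third printed
value (3×10¹³ at 3 cd·s/m²) is not (the linear constant gives 3.5×10¹³) and
may reflect a scotopic conversion; we use the single linear constant
everywhere and note the discrepancy rather than model it.

Spectral sensitivity is reduced to one dimensionless weight per LED primary
(red 1.0, green 0.8, blue 0.2, white 1.0, amber 0.9 as a red+green mixture),
reflecting ReaChR's red-shifted action spectrum (λmax ≈ 590 nm) without a
full action-spectrum model.  Steady backgrounds are placed on the
flash-energy scale by integrating luminance over a 1 s window
(`background_integration_s`); a background whose weighted flux reaches
10¹⁶ photons·cm⁻²·s⁻¹ (`preactivation_flux`) counts as pre-activating —
bright enough for weak continuous ReaChR drive, as in the blue-flash-on-
amber paradigm (3,500 cd/m² amber ≈ 3.7×10¹⁶ after weighting).  Pupil
dynamics, eye geometry and scotopic/photopic luminous-efficiency conversion
are out of scope.

## Filtering

All filters are Butterworth designs applied forward-backward
(`sosfiltfilt`, reflect padding), i.e. zero-phase: implicit times are not
biased by group delay, verified by the ≤ 1 sample peak shift of a symmetric
Gaussian pulse.  Bands are 0.125–300 Hz (ERG), 3–100 Hz (VEP), 75–300 Hz
(oscillatory potentials), with a 50 Hz notch added for light-adapted VEP
only; ERG traces are never notched because the protocol's intertrial
intervals (987/1,987 ms, not multiples of the 20 ms mains period) make
trial averaging cancel 50 Hz interference (20 trials at 987 ms rotate the
mains phase through exactly 7 full turns, giving near-perfect cancellation).

Two parameters required a choice the band corners alone do not fix:

* **Order 4 per band edge.**  A 2nd-order zero-phase band-pass leaves ~16 %
  of a 50 Hz tone inside the 75–300 Hz OP band; order 4 brings the residual
  to ~1 % while passing 120 Hz within 1 %, matching the attenuation
  behaviour the analysis assumes.
* **Notch Q = 10.**  A Q = 30 notch rings for ~190 ms — ~40 % of a 500 ms
  record — and in practice attenuates a steady 50 Hz tone by only ~80 %
  mid-trace.  Q = 10 reaches ≥ 95 % attenuation at 50 Hz while leaving a
  30 Hz tone above 99 %.

Trial averaging is a plain point-wise mean with no artifact rejection;
rejection would be an undocumented behaviour change relative to the
acquisition description the pipeline mirrors.

## Marker placement

Markers are window-restricted extrema on the filtered, trial-averaged
trace: a_o (0.5, 12] ms, a (12, 30] ms, b (20, 120] ms for ERG; N1_o
(15, 40] ms, P1 (30, 50] ms, N1 (40, 90] ms and after P1 for VEP.  Windows
bracket the published medians and interquartile ranges with margin and are
configurable.  Plateau ties resolve to the earliest sample (implicit time
is time-to-first-attainment).

Presence is decided by a deterministic surrogate for the original blinded
human annotation: a marker exists when its amplitude reaches
`max(3 × baseline sd, 2 µV)`.  The 2 µV floor keeps the criterion
meaningful on noise-free synthetic traces, where the baseline sd is zero.
N1_o, which often sits just above noise, is additionally accepted between
2σ and 3σ with a *low* confidence flag.  Two structural rules prevent
systematic misreads:

* the **a_o trough must be interior** to its window — a monotone descent
  ending on the window's last sample is the leading flank of a native
  a-wave, not a distinct optogenetic deflection;
* the **a trough must be interior on both sides** — a minimum on the first
  sample is the decaying tail of an a_o, one on the last sample a slow
  negative drift.

Amplitude conventions follow clinical practice: a and a_o from the
pre-stimulus baseline mean; b from the a-wave trough level under dark
adaptation (falling back to baseline for dim scotopic flashes with no
measurable a-wave) and from baseline under light adaptation, where
optogenetic deflections superimpose the true a-wave; N1 from the P1 peak
level.  All amplitudes are reported as positive magnitudes with the
reference recorded.  When an a_o is present the a-wave is still measured
but flagged *low* confidence — the oscillations following the optogenetic
deflection contaminate it, and downstream summaries should treat it as
unquantifiable rather than silently drop it.

## Oscillatory potentials

OPs are extracted with the 75–300 Hz zero-phase band-pass and analyzed in
the fixed 20–230 ms post-stimulus window (no adaptive a-wave-dependent
start).  The spectrum is a plain rectangular-window DFT — spectral leakage
is accepted and irrelevant to the ratio-based group comparison — zero-padded
to a 1 s equivalent length so the reported peak frequency sits on a ~1 Hz
grid (the native 210 ms window alone resolves only ~4.8 Hz).  Power is
normalized as |X(f)|²/N with N the unpadded sample count; total power then
satisfies a Parseval identity used as a test invariant, and the peak power
is checked against an independently coded DFT correlation sum.

## Synthetic data

### Waveform components

No waveform equations exist to copy, so components use the simplest shapes
matching the published morphology.  Pulse-like waves (a, b, P1, N1, N1_o,
the degenerate retina's slow positive deflection) are two-sided Gaussians
with independent rise/decay widths.  Oscillatory components (OP burst at
110 Hz, τ 15 ms, onset 25 ms — an in-band default, as no mouse OP frequency
is printed; post-a_o oscillations at 140 Hz, τ 8 ms, onset 10 ms) are
exponentially damped sinusoids.  The a_o rises as a blend of an effectively
instantaneous jump (35 %, τ 0.2 ms) and a saturating exponential (τ 3 ms),
then decays as a Gaussian (σ 2.5 ms): the onset is faster than the 2 kHz
sampling resolves — the first 0.5 ms sample is already > 3σ off baseline —
while the 8 ms trough stays distinct through the ERG band-pass.  A single
saturating rise cannot do both: it plateaus, and the filtered argmin jumps
to the onset edge.

Pulse widths were chosen so that the full measurement chain (filters
included) returns each component's generating time within one sample and
its amplitude within 1 % on noise-free traces; component overlap and filter
droop otherwise bias the extrema.  One exception is fundamental: the
3–100 Hz VEP high-pass redistributes 10–30 % of a 10–20 ms cortical pulse's
amplitude regardless of shape, so VEP *amplitudes* are only asserted to
35 % of template while VEP *times* still hold to one sample.

### Genotype templates

Timing and amplitude anchors are the published group medians; amplitudes
scale with flash energy through a Hill saturation `E^n/(E^n+E50^n)`
normalized at the anchor's reference energy (the figures show saturation
but fit no curve; E50 and n are plausible defaults exposed in config).

* **WT** — dark: a (−150 µV at 3 cd·s/m², 16 ms), b (+300 µV, 35.75 ms);
  light: a (−15 µV at 100, 17.4 ms), b (61.92 µV at 10, 51.62 ms), OP
  burst; blue-on-amber: a (−8 µV), b (107.86 µV at 5); VEP: P1 (+10 µV,
  40 ms), N1 (−20 µV, 55.25 ms).  A P1 peak time is not printed anywhere;
  40 ms sits between the published N1_o and N1 medians.
* **WT_ReaChR** — WT plus a_o (−33.76 µV at 100 cd·s/m², 8.0 ms, E50 150,
  n 2) and post-a_o oscillations, both hard-gated by the ReaChR threshold;
  the b-wave is dampened ×0.556 in light-adapted classes (×0.538 under the
  pre-activating amber background) and delayed +16.13 ms (= 67.75 − 51.62)
  for activating flashes; VEP adds N1_o (−8 µV, 27.12 ms).  The
  non-significant dark-adapted b-delay trend is not modeled.
* **RD1_ReaChR** — no native components; a_o (−6.36 µV at 100) plus a slow
  positive deflection (1.8 µV, 60 ms, flat scaling) for activating flashes
  only.  The deflection is kept below the 2 µV detection floor so the
  b-wave detector never attributes a b-wave to a photoreceptor-free retina,
  while the component the real traces show is still present.

### Noise and cohorts

Each sweep adds white noise (default sd 3 µV) and a 2 µV 50 Hz mains
sinusoid whose phase advances with the trial onsets (`k × ITI`), so the
protocol's mains-cancellation property emerges rather than being assumed.
Trial counts and ITIs follow the protocol (dark: 3 trials at 5/10 s —
intervals that *are* multiples of 20 ms, which protocol validation flags
with a warning; light: 20 trials at 987 ms, 5 trials for 150 cd·s/m²,
1,987 ms above 150).

Between-animal variability is lognormal on component amplitudes
(median-unbiased, cv 0.2 — the low end of the spread implied by the
published amplitude IQRs) and additive normal on peak times (sd 1.0 ms).
A multiplicative cv on latencies would imply a ~13 ms sd on the 67.75 ms
b time, far wider than any printed time IQR (implied cv 0.05–0.16), so
times get their own absolute jitter scale.  Group sizes default to the
study's 6 / 11 / 6.  Cohorts are bitwise-reproducible from a single seed
via spawned per-animal generators.

### What the testbed does not show

The simulator validates the *measurement chain*, not the biology: real
recordings contain drift, blink/movement artifacts, electrode impedance
variation, inter-stimulus adaptation carry-over, genuine OP wavelet
structure, and waveform shapes that differ from the parametric forms used
here.  Passing recovery tests therefore demonstrates that the pipeline
measures what the generator encodes under realistic noise — not that the
templates are faithful biophysical models.  The phenotype truth table
(which markers exist for which genotype × stimulus) is likewise enforced by
construction and verified, not discovered.

## Statistics

Summaries are median with Tukey hinges (hinge depth `(⌊(n+1)/2⌋+1)/2`,
matching the box-plot convention of the source workflow).  Two-group
comparisons gate on Shapiro–Wilk at α = 0.05 per group — both groups must
pass for the unpaired two-tailed t path, which uses Welch's
unequal-variance form since group sizes differ (6 vs 11); otherwise a
two-tailed Wilcoxon rank-sum is used, with the exact null enumerated for
combined n ≤ 12 (ties fall back to the tie-free null, a conservative
choice at these sample sizes) and a continuity-corrected normal
approximation above.  Constant samples are routed to the rank-sum path
(normality p reported as 0) since Shapiro–Wilk is undefined for them.
Families of ≥ 3 groups use Tukey's HSD (studentized range, family-wise
error controlled); no multiplicity correction is applied across stimulus
levels, matching per-stimulus reporting.  The dampening ratio is
100 × treated median / control median, reported unrounded to one decimal;
from the printed blue-on-amber medians this gives 53.9 % (printed: 53.8 %).
The separately printed "67.0 %" for 10 cd·s/m² does not equal the ratio of
the printed 10 cd·s/m² medians (55.6 %); this module computes from medians
and documents the definition rather than reverse-engineering the rounding.

## Problem sizes

Recovery checks run at the study's own scale: 500 ms traces at 2 kHz
(1,000 samples), 20-trial light-adapted recordings, cohorts of 6/11/6
animals, and 20 cohort seeds for the stochastic recovery check — about
1,400 recordings end to end, a few seconds of compute.

## Known limitations

* The photometric constant ignores pupil area and eye geometry; absolute
  fluxes are only as good as the single anchor.
* Presence thresholds (3σ + 2 µV floor) are a deterministic surrogate for
  blinded human annotation; borderline components will classify differently
  than a human would.
* The a-wave under an a_o is reported low-confidence rather than suppressed;
  consumers must filter on the confidence flag.
* VEP amplitudes are systematically attenuated by the mandated 3–100 Hz
  band; only times are comparable across analyses at the 1-sample level.
* OP spectral power is window-normalized with an arbitrary absolute scale;
  only ratios between groups are meaningful.
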