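# Methods

`stuneeg` judges whether an electrical stun rendered an animal
unconscious from single-channel EEG recorded immediately before and
after the stun, and summarises stun effectiveness across a cohort of
animals assigned to four treatments (stunner frequency 50 or 400 Hz,
electrode position P1 on the cranial plate over the brain or P2 on the
neck behind the skull). This note describes the analysis chain, the
synthetic-data model used to test it, the defaults and their rationale,
and the limits of what the synthetic tests demonstrate.

## Analysis chain

**Cleaning.** Each recording is trimmed by 2 s at both ends (edge
artefacts from applying/removing the electrode wand), then band-pass
filtered 0–30 Hz with a 4th-order Butterworth applied forward–backward.
Zero-phase filtering preserves epoch timing; the filter type is a
package choice, as is the order. Artifacts are detected automatically by
an amplitude rule: samples whose deviation from the trace median exceeds
`threshold_mads` (default 6) times the robust trace scale
(1.4826 × median absolute deviation) seed artifact intervals, which are
merged across gaps shorter than 0.25 s and widened to at least 0.1 s.
The detector replaces the manual, video-referenced rejection a human
scorer would perform; manual annotations, when present, are honoured and
unioned with detections. An amplitude-only criterion deliberately risks
flagging genuine high-amplitude seizure activity if the post-stun trace
has little background signal; the defaults keep roughly a factor-of-two
margin between seizure peaks and the detection threshold under the
synthetic model's default amplitudes.

**Spectral quantification.** The cleaned signal is cut into 1-s epochs
at 25% overlap (0.75 s stride; a trailing partial epoch is discarded).
Each epoch is Hann-windowed and transformed with a 1024-point FFT
(epochs shorter than 1024 samples are zero-padded), giving a one-sided
power spectrum scaled so that the bin powers sum to the epoch's mean
square (window power compensation: the periodogram is divided by the
squared-window sum). Band powers sum the bins whose centre frequency
falls in the half-open band [lo, hi); the five bands — very-low
[0, 0.1), delta [0.1, 4), theta [4, 8), alpha [8, 12), beta [12, 30) Hz
— partition [0, 30), so band powers conserve the total exactly.

Two consequences of the 1-s window are worth stating plainly. First, a
1-s epoch cannot resolve 0.1 Hz: at the default rate the very-low band
is represented by the 0 Hz bin alone, a documented convention, not a
claim that sub-0.1 Hz structure is measured. Second, Hann leakage is
wide at this resolution: a pure DC level puts exactly 2/3 of its
measured power in bin 0 and 1/3 in bin 1 (the bottom of delta). Band
powers are therefore comparisons under a fixed measurement convention,
not physical band integrals.

**Periods.** Three analysis periods are summarised per animal: T0
(pre-stun baseline), T1 (from the first usable post-stun epoch to 25 s
post-stun) and T2 (26–50 s post-stun), with the stun application as the
post-stun time origin. For each period, the ten consecutive epochs
minimising (number of artifact-contaminated epochs, then total-power
variance, then start time — a lexicographic tie-break) are selected;
when a window holds fewer than ten epochs (common in T1, where usable
signal may begin as late as 20 s post-stun) all available epochs are
used and a warning is logged. The period summary reports, per band, the
RMS of the band-limited signal — the square root of the mean selected
band power, so RMS² equals mean power identically — and percentage
power, 100 × band power sum / total power sum over the selected epochs.
An alternative reading of band "RMS" (the RMS of the power values
themselves) was considered and rejected; band RMS as amplitude is the
standard meaning of the quadratic mean of a signal.

**Baseline normalisation and dB change.** The per-animal baseline is the
median power over clean pre-stun epochs, computed per band, for the
pooled delta+theta ("low frequency") power, and for total power. Each
post-stun epoch is expressed as a decibel change

    dBchange = 100 × log10(value / baseline)

in the printed 100× convention, under which a power doubling is +30.103
units and a tenfold change is 100. A config switch (`db_scale = 10`)
selects the conventional 10× power-decibel scale; thresholds are then
interpreted in the active unit. Epochs with zero power map to −∞, are
flagged, and are excluded from run-length logic without breaking runs.

**Classification.** A stun is classified as effective ("good stun",
sustained change) when the pooled delta+theta dB change is at or above
the threshold (default 30 units, i.e. a power doubling) for a contiguous
run of usable epochs that is present at 25 s post-stun and continues
past it. Requiring the run to straddle the 25-s mark, rather than merely
to end after it, prevents an isolated late excursion from counting as a
sustained change. The magnitude threshold and the delta+theta pooling
are declared package defaults (no quantitative criterion is published
for "visible dB change"); classification outputs always carry the
threshold used. The nadir is the epoch (reported at its centre time)
with the greatest absolute total-power dB change — "greatest change"
does not fix a sign, so both the time and the signed value are reported.
A suppression interval is the maximal run with total dB change at or
below minus the threshold.

**Group statistics.** Band RMS across treatments and periods is fitted
with a quasi GLM: log link, constant variance, dispersion estimated from
Pearson residuals, treatment and period as categorical fixed effects.
Repeated measures within animal are handled with animal-clustered robust
standard errors. (The published model formula omits the animal term its
accompanying text describes as a random factor; this package follows the
printed quasi-GLM and addresses the repeated-measures structure through
cluster-robust inference rather than a random-intercept likelihood,
which is out of scope.) Post hoc contrasts use the two-sample
Kolmogorov–Smirnov test on epoch-level dB values within period — the
observation level fed to each contrast is not published, so epoch level
is a declared convention — with no multiple-testing adjustment by
default (none is reported; Holm adjustment is available). Good-stun
counts per treatment are compared with Pearson's χ² without continuity
correction; expected counts below 5 raise a warning flag rather than an
automatic switch to an exact test. Treatments are ranked by good-stun
proportion.

## Synthetic EEG model

No recordings were published, so the generator produces cohorts with the
statistical structure the analysis assumes, carrying ground-truth labels
for every downstream test.

**Carriers.** Each band's signal is a small set of coherent sinusoids at
seed-randomised frequencies and phases, normalised to unit RMS and
scaled by the band's RMS amplitude target. Tone placement keeps every
carrier ≥ ~1.5 Hz inside its band edges (the 1-s Hann main lobe spans
roughly ±2 Hz), and multi-tone bands (beta carries five tones) space
tones more than ~3 Hz apart so that beat terms average out within an
epoch. The very-low band is modelled as slow electrode drift: a constant
offset carrying 98% of the band amplitude plus one tone below 0.1 Hz. A
1/f background spans 1.5–45 Hz; its low cut keeps sub-epoch-resolution
stochastic content out of the background, because no 1-s window can
average spectral structure narrower than ~1 Hz and such content would
otherwise dominate epoch-to-epoch power variance. The summed trace
passes through a 50 Hz low-pass emulating the acquisition chain.

This deliberately trades spectral realism (line spectra within bands)
for near-deterministic short-time band power, which is the property the
pipeline measures and the property the generator must control to carry
usable ground truth: with broadband within-band noise, per-epoch band
power estimates at 1-s resolution have relative SD of order 0.5
(χ²-distributed with ~2·bandwidth·duration degrees of freedom), i.e.
±15–20 units on the printed dB scale, which would swamp single-epoch
landmarks like the nadir. Real EEG has broadband fluctuations,
amplitude modulation, and nonstationary rhythms that this model does not
emulate; passing tests on synthetic cohorts therefore demonstrates
correctness of the measurement and classification chain under controlled
power trajectories, not field performance on real recordings.

**Defaults.** Band RMS amplitudes (µV): very-low 4, delta 3, theta 3,
alpha 8, beta 3, background 1, at 1024 Hz (so a 1-s epoch is exactly the
1024-point FFT without padding; the acquisition rate is not published
and is configurable). The baseline is alpha-dominant, matching the
resting character reported for crocodilians once sub-0.1 Hz content is
set aside as a recording artifact. The background level (1 µV) is set so
that a baseline trace re-analysed against an independent baseline stays
within ±10 dB units at every clean epoch — the residual wobble comes
from coherent cross-terms between carriers and background in shared
bins, which scale with the background amplitude.

**Post-stun response.** Stun-to-recording latency is drawn from
[1, 3] s, and usable signal begins 7–20 s post-stun; the interval in
between is filled with high-amplitude low-frequency movement-artifact
bursts (default 10× baseline RMS) and annotated as artifact. Each band's
amplitude follows a piecewise envelope: unity through the artifact
window, a linear rise to the band's gain at the nadir (drawn from
[10, 22] s, at least 2 s after usable signal begins), a fast relaxation
(τ = 4 s) onto a sustained plateau at `1 + (gain−1)·0.35`, a hold until
35 s post-stun, then decay (τ = 4 s) toward a suppression floor applied
to all bands. Good stuns have amplitude gains delta 6, theta 4
(power × 36 and × 16) and a suppression floor of 0.35 × baseline power
(−45.6 dB units); electro-immobilisation has beta gain 3 and no
low-frequency rise or suppression; failed stuns have all gains 1.
The suppression depth is chosen so that the late suppression (≈ −46
units) never rivals the activation peak (≈ +70 units) for "greatest
absolute change" — otherwise the injected nadir would not be the
ground-truth nadir — while staying well below the −30 unit suppression
detection threshold.

**Cohorts.** Default group sizes are 31/29/29/30 (P1–50, P1–400, P2–50,
P2–400) with good-stun probabilities 0.94/0.90/0.90/0.73; non-good
animals split evenly between immobilised and failed. Labels are drawn
independently (Bernoulli) per animal by default; `label_allocation =
"quota"` instead fixes each group's good count at `round(p·n)` to
reproduce a study's exact composition. Per-animal seeds derive from the
master seed through `numpy` seed sequences, so a cohort is bit-identical
for a fixed design and seed. Note that under Bernoulli labels the
sampling variability of the group proportions themselves caps the
probability of reproducing the full published ranking (first and last
place) near 0.6 at these group sizes; this is a property of binomial
sampling, not of the classifier.

## Numerical choices and degenerate inputs

- Band edges are half-open [lo, hi) so the partition is exact; touching
  printed edges (4–8, 8–12) are resolved by assigning the shared edge to
  the upper band.
- Spectral scaling divides by the squared-window sum, making band powers
  comparable across window lengths; a full-scale sinusoid's measured
  power equals its mean square within 5% (the residual is Hann leakage
  outside the summed range).
- A zero baseline median in any band is an error, not a value: the dB
  transform is undefined there, and the error message suggests wider
  bands or a longer baseline.
- Zero-power epochs (−∞ dB) are excluded from run logic without breaking
  runs; classification is monotone in the threshold by construction.
- Serial-epoch selection breaks ties lexicographically (unclean count,
  total-power variance, earliest start), so results are deterministic.
- Recordings too short for one epoch, trims longer than the record,
  band edges outside (0, Nyquist], non-positive sampling rates, and
  annotations outside the record span are all rejected with explicit
  errors rather than repaired.

## Problem sizes in tests and the acceptance script

Monte-Carlo studies (classification accuracy, cohort ranking) run at
reduced sampling rates (256 Hz; epochs zero-padded into the same
1024-point FFT), which leaves band powers and classification decisions
essentially unchanged while keeping the full suite fast. The
parameter-recovery study uses 100 animals at the default rate with no
very-low drift, so the delta-band baseline isolates the injected gain;
recovery is then compared against the analytic expectation
100·log10(gain²). The acceptance script regenerates a full 119-animal
cohort at the default rate, reruns the recovery and calibration studies,
and reports cohort ranking over 30 reduced-rate cohorts.

## Known limitations

- The generator's line-spectrum carriers do not emulate broadband EEG
  variability; classifier operating characteristics on real recordings
  cannot be inferred from the synthetic sensitivity/specificity.
- The amplitude-only artifact detector cannot separate genuine
  high-amplitude seizure activity from movement artifact when their
  amplitudes overlap; annotated (ground-truth or manual) artifact
  windows remain the primary mask.
- The very-low band at 1-s epochs is a 0 Hz-bin convention; treat
  very-low percentages as bookkeeping, not physiology.
- Cluster-robust standard errors address repeated measures to first
  order but are not a random-effects likelihood; with only four
  treatment groups the χ² test on counts is low-powered, mirroring the
  published non-significance.
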