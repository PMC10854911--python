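# Methods

`gasstun` implements the EEG- and behaviour-based procedure used to assess
broiler-chicken welfare during controlled-atmosphere stunning (CAS): when do
birds lose consciousness (LOC), when do they reach brain death, and how much
aversion do they express before losing posture.  Because no recordings from
such trials are publicly available, the package ships a synthetic-data
generator whose ground truth is known, so every stage of the analysis is
testable end to end.

## Detection procedure

EEG traces are single-channel recordings in µV sampled at 1 kHz, with a 90 s
conscious baseline followed by a gas-exposure window (240 s by default).
Exposure time zero is the start of the lift descent into the gas pit; onset
times are reported on that axis.

1. **Filtering.** A 1–30 Hz band-pass: 4th-order Butterworth applied
   forward–backward (`sosfiltfilt`).  Only the pass-band is part of the
   procedure's definition; the zero-phase realisation is our choice, so that
   filtering introduces no group delay and detection latencies stay
   unbiased.  The analogue acquisition filters (0.1–100 Hz) are assumed to
   have been applied by hardware and are not re-implemented.
2. **Epoching.** Non-overlapping 1 s epochs per phase; trailing partial
   epochs are discarded; epoch start times are phase-relative.
3. **Spectra.** Per epoch, a Welch power spectrum with 1024-point FFT
   segments, Hamming window, 50 % segment overlap, zero-frequency bin
   removed.  A 1 s epoch at 1 kHz holds fewer than 1024 samples and
   degenerates to a single segment zero-padded to 1024 points (the stated
   50 % overlap applies across FFT segments *within* an epoch, not across
   epochs).  Powers use density scaling integrated over the bin width, so
   summed power approximates the signal's mean square (µV²).
4. **Features.** Ptot (summed power), F50 and F95 (smallest grid frequency
   at which cumulative power reaches 50 % / 95 % of Ptot — left-continuous
   and deterministic), and band fractions over Delta (<4 Hz), Theta (4–8),
   Alpha (8–13), Beta (13–32) and Gamma (32–200, capped at Nyquist).  Band
   fractions are normalised over the power inside the defined bands, so
   defined fractions sum to one exactly; after the 1–30 Hz filter the
   difference from Ptot-normalised fractions is negligible.  A zero-power
   epoch yields *undefined* features (flagged, never compared against
   thresholds).
5. **Baseline.** Per-bird medians of Ptot, F50 and the Delta fraction over
   baseline epochs, after removing epochs with F50 < 4 Hz — those are
   low-frequency movement artifacts.  If nothing survives, the bird is
   flagged `no_baseline` and no baseline-relative detection is attempted.
6. **LOC.** An exposure epoch qualifies when F50 < 50 % of the baseline
   median (criterion A) and the Delta fraction exceeds the baseline median
   by more than 65 % (criterion B).  The onset is the start time of the
   first run of ≥ 4 consecutive qualifying epochs.  The A-and-B combination
   is the default; an A-or-B mode (`loc_rule_combiner="either"`) and an
   absolute Delta threshold (`delta_mode="absolute"`) are available.  We
   default to *and* because, at 1 s epochs, the Delta-band power estimate
   has only a couple of effective degrees of freedom (the Hamming mainlobe
   is ~4 Hz wide — the entire Delta band), so the 65 %-increase criterion
   alone trips on single-epoch noise and biases onsets early; requiring
   both criteria removes those false starts while the F50 criterion
   contributes essentially no additional delay.
7. **Brain death, spectral.** Same run logic on Ptot < 10 % of the baseline
   median.
8. **Brain death, isoelectric.** The visually flat trace is operationalised
   as an absolute rule: first run of ≥ 4 epochs with Ptot < 2.5 µV²,
   independent of baseline.  The source procedure states the level ("very
   low Ptot (<2.5 µV)") but neither its unit reconciliation nor a duration,
   so both are config-exposed (`isoelectric_ptot_level`,
   `isoelectric_persistence`).
9. **Quality.** The Gamma band carries instrument/muscle noise; a trace is
   flagged when any epoch's Gamma fraction reaches 2 %.

Epochs with undefined features break qualifying runs rather than extending
them (conservative detection).  Increasing persistence, or tightening any
threshold, can only delay an onset — both properties are tested.

## Synthetic data

**EEG.** A sum of independent band-limited Gaussian noise components (white
noise, 4th-order Butterworth band-pass per band, normalised to unit
variance, scaled to a target band power).  Synthesis bands are clipped to
the 1–30 Hz analysis pass-band so programmed powers survive filtering.
Defaults, chosen to represent a clean subdermal recording at a total power
of 100 µV²:

| state | Delta | Theta | Alpha | Beta | F50 | Delta fraction |
|---|---|---|---|---|---|---|
| conscious | 15 | 15 | 32 | 38 | ≈ 11 Hz | ≈ 0.15 |
| unconscious | 90 | 7 | 2 | 1 | ≈ 3 Hz | ≈ 0.90 |

Band powers cross-fade linearly over `transition_width` (default 3 s)
starting at the programmed LOC time; after the programmed death time the
amplitude decays exponentially (`death_decay_tau`, default 1 s) towards an
always-present isoelectric residual of band-limited noise at 1 µV RMS.
Movement artifacts are sparse ~1.5 Hz, 0.8 s, 300 µV transients injected
into the baseline window only (they are exactly what the baseline F50 < 4 Hz
rule removes).

Two generator defaults were calibrated against the detector's statistics at
design time, and the reasoning matters more than the numbers.  A 1 s epoch
gives the Delta-fraction estimate a relative spread of roughly 50 %, so
(i) the unconscious mix must dominate Delta strongly (0.90 rather than,
say, 0.75) or envelope fades intermittently break qualifying runs and
detections arrive late; and (ii) with a 2 s ramp, the epoch containing the
programmed onset is mixed enough that estimation noise can make it qualify,
producing detections slightly *before* the programmed time.  A 3 s ramp
keeps the boundary epoch mostly conscious while full Delta dominance is
still reached two epochs later.  With these defaults the detector recovers
LOC within [truth, truth+4 s] for ≥ 95 % of birds and spectral death within
[truth, truth+6 s] for ≥ 90 % (tested on 200-bird cohorts).

**Cohorts.** Per-bird event times are truncated-normal draws on
(0, exposure]; the published tables report mean ± sd over bounded ranges
and state no distributional form, so the truncated normal is our choice.
Death draws landing within 8 s of the bird's LOC draw are rejected and
redrawn: observed LOC-to-death gaps in such trials never approach that
closely, and a shorter gap leaves no room for any 4-epoch rule to operate.

**Behaviour.** Each simulated bird gets exactly one loss-of-posture (LOP)
and one motionlessness anchor.  Event counts per behaviour and phase are
Poisson with configured rates; point events (head shaking, deep inhalation,
gasping, jumping, high-pitch vocalisation) occur at uniform times with zero
duration; state events (sitting, standing, walking, ataxia, wing flapping,
leg paddling) start uniformly and last an exponential time clipped at the
phase end.  `gasstun.presets` converts the published per-treatment tables
(events/bird and total state durations before and after LOP) into rates per
minute using the mean phase duration.

**Gas.** Piecewise-constant phase targets plus Gaussian sensor noise, with
a linear ramp from atmospheric air over the 23 s lift descent.  Treatment
definitions: two-phase CO2 (40C90C: <40 % CO2 for 2 min, then >90 % CO2
and <2 % O2), CO2/N2 mixtures (40C60N, 20C80N: fixed CO2 with <2 % O2 for
4 min), and an atmospheric-air control.

What the generator does **not** model: real electrode artifacts (eyelid
movement, lead detachment, 50 Hz mains), non-stationary baselines,
signal degradation near zero power (which in real traces inflates spectral
death estimates — the 20C80N preset therefore uses the isoelectric onset,
66.3 ± 8.1 s, as its death-time distribution rather than the degraded
spectral figure), inter-bird interference, or any biophysics of hypoxia.
Passing tests therefore demonstrate that the *procedure* is implemented
correctly and recovers known truth under its stated assumptions, not that
it would perform identically on slaughterhouse recordings.

## Statistics

Proportions of birds expressing a behaviour are compared across treatments
with Pearson's chi-squared test on the shown/not-shown contingency table
(df = groups − 1); group means with a two-sample t test (pooled-variance
Student by default, Welch optional), usable from summary statistics.  Both
are authored closed-form and verified against reference implementations to
1e-10.  The source analysis additionally fitted mixed models with the
stunning cycle as a random effect; that is deliberately out of scope here —
tables are produced at bird level, and p-values in `behaviour_tests.csv`
ignore the cycle grouping (a caveat, not an oversight).  Significance is
reported at 0.05 but never used to drop rows.

## Problem sizes and numerical choices

Analysis drivers simulate 6 EEG birds per treatment and behaviour cohorts
at the study's group sizes (76/63/54); the recovery tests use 200-bird EEG
cohorts.  The EDF writer quantises to 16 bits over the trace's physical
range (relative error ~3e-5 of the range); text I/O round-trips at 1e-6 µV.
F50/F95 land on the FFT grid (0.977 Hz spacing at 1 kHz).  Ties in
first-occurrence ordering keep catalogue order.  All randomness flows from
explicit integer seeds through `numpy.random.Generator`; identical seeds
give bit-identical traces and byte-identical pipeline outputs.
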