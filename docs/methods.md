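# Methods

## Problem and model

During focal seizures, high-frequency oscillations (HFOs; here the ripple
band, 80–150 Hz) tend to occur at preferred phases of the slower ictal
rhythm (4–30 Hz spike-wave activity). Channels showing this
phase-amplitude coupling are candidate markers of epileptogenic tissue.
`plhfo` quantifies the coupling with four windowed measures and relates
per-seizure channel selections to resected tissue and surgical outcome.

For each channel the package derives, by zero-phase FIR band-pass
filtering and the Hilbert transform, three instantaneous quantities: the
low-frequency phase Φ_LF, the HFO envelope A_HFO, and the phase Φ_HFO of
the envelope's fluctuation. On a sliding window of *n* samples:

- **MVL** = |mean(A_HFO · e^{iΦ_LF})| — amplitude-weighted mean phase
  vector; scales linearly with HFO power.
- **PLHG** = |mean((A_HFO / Ā_base) · e^{i(Φ_LF − Φ_HFO)})| with Ā_base
  the channel's mean envelope over a 30-s preictal baseline.
- **PLV** = |mean(e^{i(Φ_LF − Φ_HFO)})| ∈ [0, 1]; amplitude-blind.
- **MI** = D_KL(P, U) / log N, where P is the phase-binned mean-envelope
  histogram (N = 18 bins of 20°) and U uniform; scale-invariant.
- **HFO power** = mean(A_HFO) — the amplitude-only reference.

The measure algebra is the crux of the method comparison: scaling A_HFO by
c > 0 scales MVL and HFO power by exactly c, leaves PLV and MI exactly
unchanged, and leaves PLHG unchanged when the baseline scales along. A
channel can therefore outrank genuinely coupled tissue on MVL/PLHG purely
by being loud.

## Preprocessing

Recordings are re-referenced to the per-sample median of artifact-free
channels, then (if sampled at an integer multiple of 512 Hz) decimated to
512 Hz with the classic order-8 Chebyshev type I low-pass (0.05 dB ripple,
cutoff 0.8× target Nyquist) applied zero-phase. Band-pass filters are
Hamming-window FIRs with order = round(3 · rate / low_cutoff) (three
cycles of the low cutoff: 384 taps + 1 for 4 Hz, 19 + 1 for 80 Hz at
512 Hz), applied forward-backward. Filtering always precedes windowing so
window edges carry no transients. Note that zero-phase application squares
the magnitude response; narrow-band amplitudes are reproduced at |H(f)|²,
about 1–3 % below unity depending on the band.

**Envelope phase.** A strictly positive envelope has no meaningful phase,
so a baseline is subtracted before the second Hilbert transform. We use a
1-s moving-average baseline (configurable; `envelope_detrend=None` gives
the global per-channel mean). The local baseline is a deliberate choice:
with a single global mean, any stretch whose power sits well below the
recording-wide average has an envelope pinned far below zero and an
essentially constant, power-dependent phase, which couples PLV and PLHG to
HFO power through an artifact of the reference rather than through the
signal. With the local baseline, the PLV-vs-power log-log slope on
amplitude-ramp channels is ≈ 0.03 instead of ≈ 0.27.

## Windowing, thresholding, evaluation

Measures are computed on 3-s windows advanced by 333 ms (1536 and 170
samples at 512 Hz; a 60-s span yields 172 windows), then smoothed per
channel by a centered 10-point moving average (truncated and renormalized
at the series edges; no phase lag). A channel is *suprathreshold* for a
measure if any ictal window exceeds mean + 2.5 SD pooled over all channels
and ictal windows of that seizure (equivalently, pooled ictal z > 2.5; SD
uses ddof = 1). Ictal windows are those fully contained in
[onset, offset).

The **resection ratio** is the percentage of suprathreshold channels lying
in resected tissue — over the whole seizure, or over the first k = 9
channels ordered by first threshold crossing (ties broken by larger z at
the crossing window, then channel index). Seizures with no suprathreshold
channel have an undefined ratio and are excluded from group statistics by
default (a 0% convention is available); treating "nothing detected" as 0%
would conflate it with "detected outside the resection". Good-outcome
(Engel I–II) and poor-outcome (Engel IV) ratios are compared with a
two-sided Mann-Whitney U test at the Bonferroni-corrected level α = 0.01
(five measures). With per-subject ids present, at most two seizures per
subject enter the statistics.

The **confound analysis** regresses log(measure) on log(HFO power) per
channel across all windows (preictal + ictal + postictal; windows with a
non-positive value are excluded from the log fit, channels with fewer than
3 usable windows are skipped) and computes the Pearson correlation of the
raw series, aggregated as mean ± SEM over channels.

## Synthetic data

The generator plants recoverable coupling in an idealized ictal channel
model: a sinusoidal low-frequency rhythm (analytically known Hilbert
phase; optional sawtooth skew for robustness checks), discrete
quarter-cycle Hann-tapered HFO bursts, and 1/f background noise. Per LF
cycle a burst occurs with probability `burst_probability`; its center
phase is the planted preferred phase with probability `modulation_depth`
and uniform otherwise, and its envelope is scaled by
(1 + depth · cos(Φ_LF − preferred_phase))/2. Depth 0 is therefore exactly
phase-uniform and depth 1 fully locked. Defaults approximate ictal iEEG
scales: 100 µV rhythm, 20 µV bursts, 10 µV background, 512 Hz.

Choices that matter, and why:

- **Channel diversity.** Scenario builders give each channel its own LF
  frequency (5.0–9.9 Hz) and phase. Identical rhythms on all channels
  would survive into the per-sample median and be cancelled by
  re-referencing.
- **Episodic coupling.** Planted channels couple during a mid-seizure
  episode (45–75 % of the ictal segment by default). Ictal coupling waxes
  and wanes in real recordings; it is also a mathematical requirement for
  pooled thresholding — a series that is uniformly high on f of all
  channel-windows can reach a pooled z of at most sqrt((1−f)/f), which is
  below 2.5 for 2 constantly-coupled channels of 6.
- **Ictal-only "hot" channel in the confound scenario.** The loud channel
  carries 10× HFO amplitude *during the seizure only* (its preictal
  baseline is ordinary — otherwise PLHG's baseline normalization would
  cancel the loudness) and its HFO-band background scales with its bursts
  (high HFO power means elevated band energy, not giant bursts over a
  silent floor; the latter would also inflate MI's small-sample bias).
- **Pre/postictal segments** are uncoupled with bursts attenuated to 25 %,
  so ictal-window restriction in the evaluation is meaningful.

What the generator does *not* emulate: asymmetric spike-wave morphology
(beyond the optional skew), inter-channel correlation, artifacts,
nonstationary rhythm frequency, and fast ripples (> 150 Hz). Passing
tests therefore validate the measures and the evaluation machinery, not
clinical performance on patient data.

## Numerical conventions

- Sample indices are 0-based; intervals half-open. Phases wrapped to
  [−π, π). Phase bins are the N equal arcs of [−π, π); a sample exactly at
  π is clipped into the last bin.
- MI: empty bins contribute 0 (0·log 0 := 0); an all-zero envelope gives
  MI = 0. The phase-nonuniformity correction replaces P by
  normalize(max(P − Q + 1/N, 0)) with Q the per-bin phase-count fraction;
  it is an exact no-op for uniform phase and is on by default
  (`mi_phase_correction=False` disables it).
- Window step: round(0.333 s · rate) = 170 samples at 512 Hz; the final
  partial window is dropped.
- Smoothing length 10 windows; a 20-sample variant can be configured
  (both lengths appear in prior practice).
- PLHG without a preictal baseline is a hard error, not a fallback.
- Filter-order rounding is half-up; an even-length (type II) band-pass FIR
  is accepted since its Nyquist zero is irrelevant for bands strictly
  below Nyquist.

## Problem sizes in tests and the acceptance script

Test batches use 6–8-channel cases with 30 s preictal, 20–60 s ictal and
5–10 s postictal segments; replicate counts are 100 for the recovery and
confound-direction checks in the test suite and 40–50 in the acceptance
script, with an 8-seizure batch for the group statistics. These sizes are
the package's chosen desk-scale study conditions; the clinical study this
mirrors (32 seizures, 16 patients, ~64 channels per seizure) is out of
scope because it requires the external patient dataset.

## Known limitations

- Per-window MI carries a positive small-sample bias for sparse discrete
  bursts (few events over 18 bins in 3 s); it cancels between channels
  with similar burst statistics but not between channels with very
  different event rates.
- At planted depth 0.6 with default SNR, exact-set recovery by MI
  thresholding is ~90 % rather than ≥ 95 % (the default scenario depth is
  0.8); the miss mode is a coupled channel's peak landing just below the
  pooled threshold.
- The EDF writer quantizes to 16 bits over each channel's observed range;
  round trips are exact only to that quantum.
- The Mann-Whitney test falls back to the normal approximation in the
  presence of ties (scipy `method="auto"`), as with heavily tied ratio
  values.
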