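"""Re-referencing, resampling, band-splitting and Hilbert decomposition.

Every coupling measure consumes three instantaneous quantities derived from
a multichannel recording:

* ``phi_lf``      -- instantaneous phase of the low-frequency band (radians),
* ``a_hfo``       -- instantaneous envelope of the HFO band (same units as
                     the input signal, conventionally microvolts),
* ``phi_hfo_env`` -- instantaneous phase of the (de-meaned) HFO envelope.

Band-pass filtering uses window-method linear-phase FIR filters with an
order of three cycles of the low cutoff frequency, applied forward and
backward so the net phase shift is zero.  Filtering always operates on the
whole recording, never on windows, so that window edges carry no filter
transients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .io import Recording

__all__ = [
    "BandConfig",
    "AnalyticBands",
    "median_reference",
    "downsample_to_512",
    "fir_order",
    "design_fir",
    "decompose",
    "wrap_phase",
]

#: Alternative low-frequency bands that are reasonable choices for ictal
#: recordings.  The wide default preserves the sharp shape of spike-waves;
#: the narrower bands isolate classical delta/theta rhythms.
LOW_BAND_PRESETS = {
    "wide": (4.0, 30.0),
    "delta": (0.5, 4.0),
    "low16": (1.0, 16.0),
    "low30": (1.0, 30.0),
}


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap angles into the half-open interval [-pi, pi)."""
    return np.mod(np.asarray(phi) + np.pi, 2.0 * np.pi) - np.pi


@dataclass(frozen=True)
class BandConfig:
    """Pass bands for the slow and fast components.

    Parameters
    ----------
    lf_band
        (low, high) edges in Hz of the low-frequency band whose phase
        modulates HFO amplitude.  Default (4, 30): wide enough to keep the
        shape of spike-waves, whose sharp transients would be destroyed by
        narrow-band filtering.
    hfo_band
        (low, high) edges in Hz of the high-frequency-oscillation band.
        Default (80, 150), the ripple band reachable at a 512 Hz rate.
    """

    lf_band: tuple[float, float] = (4.0, 30.0)
    hfo_band: tuple[float, float] = (80.0, 150.0)

    def validate(self, rate: float) -> None:
        nyq = rate / 2.0
        for name, (lo, hi) in (("lf_band", self.lf_band), ("hfo_band", self.hfo_band)):
            if not (0.0 < lo < hi < nyq):
                raise ValueError(
                    f"{name}=({lo}, {hi}) must satisfy 0 < low < high < rate/2 "
                    f"(= {nyq} Hz)"
                )
        lo1, hi1 = sorted([self.lf_band, self.hfo_band])
        if hi1[0] < lo1[1]:
            raise ValueError("lf_band and hfo_band must not overlap")


@dataclass
class AnalyticBands:
    """Instantaneous phase/envelope matrices, channels x time.

    All three matrices share the shape of the source recording.  Phases
    are wrapped to [-pi, pi); the envelope is non-negative.
    """

    phi_lf: np.ndarray
    a_hfo: np.ndarray
    phi_hfo_env: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        if not (self.phi_lf.shape == self.a_hfo.shape == self.phi_hfo_env.shape):
            raise ValueError("phase/envelope matrices must share one shape")

    @property
    def n_channels(self) -> int:
        return self.phi_lf.shape[0]

    @property
    def n_samples(self) -> int:
        return self.phi_lf.shape[1]


def median_reference(recording: Recording) -> Recording:
    """Subtract the per-sample median of usable channels from each usable channel.

    The median is computed across channels marked usable in
    ``recording.channel_mask`` only; masked-out channels are returned
    untouched and contribute nothing to the reference.
    """
    mask = recording.channel_mask
    n_usable = int(mask.sum())
    if n_usable < 2:
        raise ValueError(f"median reference needs >= 2 usable channels, got {n_usable}")
    out = recording.samples.copy()
    med = np.median(out[mask], axis=0)
    out[mask] -= med
    return Recording(out, recording.rate, list(recording.channel_labels), mask.copy())


def downsample_to_512(recording: Recording, target_rate: float = 512.0) -> Recording:
    """Anti-aliased decimation to 512 Hz.

    Uses an order-8 Chebyshev type I low-pass (0.05 dB ripple, cutoff at
    0.8x the target Nyquist) applied zero-phase -- the classic decimation
    defaults -- followed by sample dropping.  A recording already at the
    target rate passes through unchanged.
    """
    if recording.rate == target_rate:
        return recording
    factor = recording.rate / target_rate
    q = int(round(factor))
    if abs(factor - q) > 1e-9 or q < 1:
        raise ValueError(
            f"rate {recording.rate} Hz is not an integer multiple of {target_rate} Hz"
        )
    out = signal.decimate(recording.samples, q, ftype="iir", zero_phase=True, axis=-1)
    return Recording(
        np.ascontiguousarray(out),
        target_rate,
        list(recording.channel_labels),
        recording.channel_mask.copy(),
    )


def fir_order(low_cutoff: float, rate: float) -> int:
    """Filter order from the three-cycles rule: round(3 * rate / low_cutoff).

    Rounding is half-up.  E.g. at 512 Hz: low cutoff 4 Hz -> 384,
    80 Hz -> 19 (from 19.2), 0.5 Hz -> 3072.
    """
    return int(math.floor(3.0 * rate / low_cutoff + 0.5))


def design_fir(band: tuple[float, float], rate: float) -> np.ndarray:
    """Window-method (Hamming) linear-phase band-pass FIR coefficients.

    The order follows :func:`fir_order`; the returned array holds
    ``order + 1`` taps.  An odd order yields an even-length (type II)
    filter, which has a structural zero at Nyquist; that is harmless for
    any band strictly below Nyquist, and the order is bumped by one only
    in the degenerate case where the band touches Nyquist.
    """
    lo, hi = band
    if not (0.0 < lo < hi < rate / 2.0):
        raise ValueError(f"band ({lo}, {hi}) invalid for rate {rate}")
    order = fir_order(lo, rate)
    numtaps = order + 1
    if numtaps % 2 == 0 and hi >= rate / 2.0 - 1e-9:
        numtaps += 1
    return signal.firwin(numtaps, [lo, hi], pass_zero=False, fs=rate, window="hamming")


def _filtfilt(taps: np.ndarray, x: np.ndarray, band_name: str) -> np.ndarray:
    padlen = 3 * len(taps)
    if x.shape[-1] <= padlen:
        raise ValueError(
            f"signal of {x.shape[-1]} samples is too short for the {band_name} "
            f"filter ({len(taps)} taps; needs > {padlen} samples)"
        )
    return signal.filtfilt(taps, [1.0], x, axis=-1, padlen=padlen)


def decompose(
    recording: Recording,
    bands: BandConfig | None = None,
    envelope_detrend: float | None = 1.0,
) -> AnalyticBands:
    """Band-split a recording and extract the three analytic quantities.

    Each channel is filtered forward-backward in both bands (zero net phase
    shift).  ``phi_lf`` is the angle of the analytic low-frequency signal;
    ``a_hfo`` is the modulus of the analytic HFO signal; ``phi_hfo_env`` is
    the angle of the analytic signal of the envelope itself.

    A strictly positive envelope has no meaningful phase, so its baseline
    is removed before the second Hilbert transform.  ``envelope_detrend``
    sets the length in seconds of the moving-average baseline (default
    1 s); a local baseline keeps the envelope phase well-defined even when
    HFO power drifts across the recording, whereas subtracting one global
    mean would leave low-power stretches pinned far below zero with a
    degenerate, power-dependent phase.  Pass None to subtract the global
    per-channel mean instead.
    """
    bands = bands or BandConfig()
    bands.validate(recording.rate)
    x = np.asarray(recording.samples, dtype=np.float64)

    taps_lf = design_fir(bands.lf_band, recording.rate)
    taps_hfo = design_fir(bands.hfo_band, recording.rate)
    lf = _filtfilt(taps_lf, x, f"low-frequency ({bands.lf_band[0]}-{bands.lf_band[1]} Hz)")
    hf = _filtfilt(taps_hfo, x, f"HFO ({bands.hfo_band[0]}-{bands.hfo_band[1]} Hz)")

    phi_lf = wrap_phase(np.angle(signal.hilbert(lf, axis=-1)))
    a_hfo = np.abs(signal.hilbert(hf, axis=-1))
    if envelope_detrend is None:
        baseline = a_hfo.mean(axis=-1, keepdims=True)
    else:
        size = max(int(round(envelope_detrend * recording.rate)), 2)
        baseline = ndimage.uniform_filter1d(a_hfo, size=size, axis=-1, mode="nearest")
    env = a_hfo - baseline
    phi_hfo_env = wrap_phase(np.angle(signal.hilbert(env, axis=-1)))
    return AnalyticBands(phi_lf, a_hfo, phi_hfo_env, recording.rate)
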