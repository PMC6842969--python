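"""The five windowed measures: MVL, PLHG, PLV, MI, and HFO power.

All four coupling measures quantify, in different ways, whether high-
frequency-oscillation (HFO) activity concentrates at particular phases of
a slow rhythm within a short analysis window:

* **MVL** (mean vector length): modulus of the mean of the complex numbers
  ``A_HFO * exp(i * Phi_LF)``; amplitude-weighted, so it scales linearly
  with HFO power.
* **PLHG** (phase-locked high gamma): like MVL but on the phase difference
  ``Phi_LF - Phi_HFO`` with the envelope normalized by its mean over a
  30-s preictal baseline.
* **PLV** (phase-locking value): modulus of the mean unit vector of the
  phase difference; bounded in [0, 1] and blind to amplitude.
* **MI** (modulation index): Kullback-Leibler divergence of the
  phase-binned mean-amplitude histogram from uniform, normalized by
  log(N); scale-invariant because the histogram is normalized.
* **HFO power**: mean HFO envelope over the window, the amplitude-only
  reference the coupling measures are compared against.

The amplitude-scale algebra is the mechanism behind the power confound:
scaling the envelope by c > 0 scales MVL and HFO power by exactly c while
PLV and MI are exactly unchanged (and PLHG is unchanged when the baseline
scales along).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .preprocessing import AnalyticBands

__all__ = [
    "MEASURES",
    "WindowConfig",
    "PhaseAmplitudeHistogram",
    "MeasureMatrix",
    "compute_mvl",
    "compute_plhg",
    "compute_plv",
    "compute_mi",
    "compute_hfo_power",
    "phase_amplitude_histogram",
    "sliding_measures",
    "moving_average",
]

MEASURES = ("MVL", "PLHG", "PLV", "MI", "HFO_POWER")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window geometry and smoothing for the measure time series.

    Defaults: 3-s windows advanced by 333 ms, followed by a 10-point
    centered moving average on each channel's series.  At 512 Hz that is a
    1536-sample window and a 170-sample step.
    """

    window_length: float = 3.0
    step: float = 0.333
    smoothing_points: int = 10

    def __post_init__(self) -> None:
        if not (self.window_length > self.step > 0):
            raise ValueError("need window_length > step > 0")
        if self.smoothing_points < 1:
            raise ValueError("smoothing_points must be >= 1")

    def window_samples(self, rate: float) -> int:
        return _round_half_up(self.window_length * rate)

    def step_samples(self, rate: float) -> int:
        return _round_half_up(self.step * rate)


@dataclass
class PhaseAmplitudeHistogram:
    """Mean HFO amplitude per low-frequency phase bin.

    ``mean_amplitude`` is the raw per-bin average envelope (empty bins
    hold 0); ``normalized`` is the same vector normalized to a probability
    distribution over the N equal 2*pi/N phase arcs partitioning [-pi, pi).
    """

    n_bins: int
    mean_amplitude: np.ndarray
    normalized: np.ndarray

    def preferred_phase(self) -> float:
        """Circular mean of bin-center phases weighted by the histogram."""
        centers = -np.pi + (np.arange(self.n_bins) + 0.5) * 2 * np.pi / self.n_bins
        return float(np.angle(np.sum(self.normalized * np.exp(1j * centers))))


@dataclass
class MeasureMatrix:
    """One measure's channels x windows time series for one recording span."""

    measure_name: str
    values: np.ndarray
    window_starts: np.ndarray
    window_length_samples: int
    step_samples: int
    rate: float
    smoothed: bool = False
    channel_labels: list[str] | None = None

    @property
    def window_centers(self) -> np.ndarray:
        return self.window_starts + self.window_length_samples // 2

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_windows(self) -> int:
        return self.values.shape[1]

    def windows_within(self, start: int, stop: int) -> tuple[int, int]:
        """Index span of windows fully contained in sample interval [start, stop)."""
        ok = (self.window_starts >= start) & (
            self.window_starts + self.window_length_samples <= stop
        )
        idx = np.nonzero(ok)[0]
        if idx.size == 0:
            return (0, 0)
        return int(idx[0]), int(idx[-1] + 1)


def _check_windows(*arrays: np.ndarray) -> None:
    shapes = {np.asarray(a).shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"windows must share one shape, got {sorted(shapes)}")
    if np.asarray(arrays[0]).shape[-1] == 0:
        raise ValueError("empty window")


def compute_mvl(phi_lf: np.ndarray, a_hfo: np.ndarray) -> float | np.ndarray:
    """Mean vector length: |mean(a_hfo * exp(i * phi_lf))| over the window."""
    _check_windows(phi_lf, a_hfo)
    return np.abs(np.mean(np.asarray(a_hfo) * np.exp(1j * np.asarray(phi_lf)), axis=-1))


def compute_plhg(
    phi_lf: np.ndarray,
    a_hfo: np.ndarray,
    phi_hfo_env: np.ndarray,
    baseline_mean: float | np.ndarray,
) -> float | np.ndarray:
    """Phase-locked high gamma: baseline-normalized phase-difference vector modulus.

    ``baseline_mean`` is the mean HFO envelope over the case's 30-s
    preictal reference segment and must be strictly positive.
    """
    _check_windows(phi_lf, a_hfo, phi_hfo_env)
    baseline_mean = np.asarray(baseline_mean, dtype=np.float64)
    if np.any(baseline_mean <= 0):
        raise ValueError("PLHG baseline mean must be strictly positive")
    a_norm = np.asarray(a_hfo) / baseline_mean[..., None]
    return np.abs(
        np.mean(a_norm * np.exp(1j * (np.asarray(phi_lf) - np.asarray(phi_hfo_env))), axis=-1)
    )


def compute_plv(phi_lf: np.ndarray, phi_hfo_env: np.ndarray) -> float | np.ndarray:
    """Phase-locking value: |mean(exp(i * (phi_lf - phi_hfo_env)))|, in [0, 1]."""
    _check_windows(phi_lf, phi_hfo_env)
    return np.abs(np.mean(np.exp(1j * (np.asarray(phi_lf) - np.asarray(phi_hfo_env))), axis=-1))


def _bin_indices(phi: np.ndarray, n_bins: int) -> np.ndarray:
    # equal 2*pi/n arcs partitioning [-pi, pi); clip guards phi == pi
    idx = np.floor((phi + np.pi) / (2 * np.pi / n_bins)).astype(np.intp)
    return np.clip(idx, 0, n_bins - 1)


def phase_amplitude_histogram(
    phi_lf: np.ndarray, a_hfo: np.ndarray, n_bins: int = 18
) -> PhaseAmplitudeHistogram:
    """Bin the HFO envelope by low-frequency phase (N equal bins, default 18)."""
    if n_bins < 2:
        raise ValueError("need at least 2 phase bins")
    _check_windows(phi_lf, a_hfo)
    phi = np.asarray(phi_lf, dtype=np.float64).ravel()
    amp = np.asarray(a_hfo, dtype=np.float64).ravel()
    idx = _bin_indices(phi, n_bins)
    counts = np.bincount(idx, minlength=n_bins).astype(np.float64)
    sums = np.bincount(idx, weights=amp, minlength=n_bins)
    mean_amp = np.divide(sums, counts, out=np.zeros(n_bins), where=counts > 0)
    total = mean_amp.sum()
    normalized = mean_amp / total if total > 0 else np.zeros(n_bins)
    return PhaseAmplitudeHistogram(n_bins, mean_amp, normalized)


def _mi_from_distributions(p: np.ndarray, q: np.ndarray, phase_correction: bool) -> np.ndarray:
    """Normalized KL divergence of p from uniform, with optional correction.

    ``p`` is the normalized phase-amplitude histogram and ``q`` the phase
    count distribution (fraction of window samples per bin), both with the
    bin axis last.  The correction re-centers p on the uniform law by the
    observed phase distribution: normalize(max(p - q + 1/N, 0)).  For a
    uniform phase distribution q == 1/N it is an exact no-op.
    """
    n_bins = p.shape[-1]
    if phase_correction:
        p = np.clip(p - q + 1.0 / n_bins, 0.0, None)
        tot = p.sum(axis=-1, keepdims=True)
        p = np.divide(p, tot, out=np.zeros_like(p), where=tot > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p * n_bins), 0.0)
    return terms.sum(axis=-1) / np.log(n_bins)


def compute_mi(
    phi_lf: np.ndarray,
    a_hfo: np.ndarray,
    n_bins: int = 18,
    phase_correction: bool = True,
) -> float:
    """Modulation index: D_KL(P, U) / log(N) of the phase-amplitude histogram.

    P(i) is the mean envelope over the samples whose low-frequency phase
    falls in bin i, normalized to sum to 1; U is uniform.  Empty bins
    contribute nothing (0*log 0 := 0).  An all-zero envelope carries no
    information and yields MI = 0.  With ``phase_correction`` the histogram
    is first adjusted for a non-uniform phase distribution (see
    :func:`_mi_from_distributions`).
    """
    _check_windows(phi_lf, a_hfo)
    phi = np.asarray(phi_lf, dtype=np.float64).ravel()
    amp = np.asarray(a_hfo, dtype=np.float64).ravel()
    if phi.size < n_bins:
        warnings.warn(
            f"window of {phi.size} samples is smaller than {n_bins} phase bins; "
            "MI will be coarse",
            stacklevel=2,
        )
    if not np.any(amp > 0):
        return 0.0
    hist = phase_amplitude_histogram(phi, amp, n_bins)
    idx = _bin_indices(phi, n_bins)
    q = np.bincount(idx, minlength=n_bins) / phi.size
    return float(_mi_from_distributions(hist.normalized, q, phase_correction))


def compute_hfo_power(a_hfo: np.ndarray) -> float | np.ndarray:
    """Mean HFO envelope over the window."""
    _check_windows(a_hfo)
    return np.mean(np.asarray(a_hfo), axis=-1)


def moving_average(x: np.ndarray, n_points: int) -> np.ndarray:
    """Centered moving average along the last axis, truncated at the edges.

    Each output sample averages the input over ``[i - n//2, i + (n-1)//2]``
    clipped to the series, normalized by the actual number of samples, so
    the series keeps its length, constants stay constant, and there is no
    phase lag.  ``n_points == 1`` is the identity.
    """
    x = np.asarray(x, dtype=np.float64)
    if n_points <= 1:
        return x.copy()
    n = x.shape[-1]
    h_lo, h_hi = n_points // 2, (n_points - 1) // 2
    pos = np.arange(n)
    lo = np.maximum(pos - h_lo, 0)
    hi = np.minimum(pos + h_hi, n - 1) + 1
    cs = np.concatenate([np.zeros(x.shape[:-1] + (1,)), np.cumsum(x, axis=-1)], axis=-1)
    return (cs[..., hi] - cs[..., lo]) / (hi - lo)


def _window_view(x: np.ndarray, starts: np.ndarray, win: int) -> np.ndarray:
    # (channels, n_windows, win) view without copying
    views = sliding_window_view(x, win, axis=-1)
    return views[:, starts, :]


def sliding_measures(
    bands: AnalyticBands,
    config: WindowConfig | None = None,
    which: tuple[str, ...] = MEASURES,
    baseline_mean: np.ndarray | None = None,
    span: tuple[int, int] | None = None,
    mi_bins: int = 18,
    mi_phase_correction: bool = True,
    channel_labels: list[str] | None = None,
) -> list[MeasureMatrix]:
    """Compute the requested measures on a sliding window over ``span``.

    Windows start at the beginning of the analyzed span and advance by the
    step; a final partial window is dropped.  After the raw per-window
    values, each channel's series is smoothed by a centered moving average
    of ``config.smoothing_points``.  ``baseline_mean`` (per-channel mean
    preictal HFO envelope) is required whenever PLHG is requested.

    Returns one :class:`MeasureMatrix` per requested measure, in the order
    requested.
    """
    config = config or WindowConfig()
    unknown = set(which) - set(MEASURES)
    if unknown:
        raise ValueError(f"unknown measures: {sorted(unknown)}")
    if "PLHG" in which and baseline_mean is None:
        raise ValueError(
            "PLHG requires the per-channel mean HFO envelope over the 30-s "
            "preictal baseline; pass baseline_mean"
        )
    start, stop = span if span is not None else (0, bands.n_samples)
    if not (0 <= start < stop <= bands.n_samples):
        raise ValueError(f"span [{start}, {stop}) outside recording of {bands.n_samples}")
    win = config.window_samples(bands.rate)
    step = config.step_samples(bands.rate)
    if stop - start < win:
        raise ValueError(
            f"span of {stop - start} samples is shorter than one {win}-sample window"
        )
    starts = np.arange(start, stop - win + 1, step)

    w_phi_lf = _window_view(bands.phi_lf, starts, win)
    need_env_phase = {"PLHG", "PLV"} & set(which)
    w_phi_env = _window_view(bands.phi_hfo_env, starts, win) if need_env_phase else None
    w_amp = _window_view(bands.a_hfo, starts, win)

    out: list[MeasureMatrix] = []
    for name in which:
        if name == "MVL":
            vals = compute_mvl(w_phi_lf, w_amp)
        elif name == "PLV":
            vals = compute_plv(w_phi_lf, w_phi_env)
        elif name == "PLHG":
            vals = compute_plhg(w_phi_lf, w_amp, w_phi_env, np.asarray(baseline_mean)[:, None])
        elif name == "HFO_POWER":
            vals = compute_hfo_power(w_amp)
        elif name == "MI":
            vals = _sliding_mi(w_phi_lf, w_amp, mi_bins, mi_phase_correction)
        vals = moving_average(np.asarray(vals, dtype=np.float64), config.smoothing_points)
        out.append(
            MeasureMatrix(
                measure_name=name,
                values=vals,
                window_starts=starts.copy(),
                window_length_samples=win,
                step_samples=step,
                rate=bands.rate,
                smoothed=config.smoothing_points > 1,
                channel_labels=list(channel_labels) if channel_labels else None,
            )
        )
    return out


def _sliding_mi(
    w_phi: np.ndarray, w_amp: np.ndarray, n_bins: int, phase_correction: bool
) -> np.ndarray:
    """Vectorized MI over a (channels, n_windows, win) stack of windows."""
    n_ch, n_win, win = w_phi.shape
    idx = _bin_indices(np.ascontiguousarray(w_phi), n_bins)
    offsets = (np.arange(n_ch * n_win) * n_bins).reshape(n_ch, n_win, 1)
    flat = (idx + offsets).ravel()
    minlength = n_ch * n_win * n_bins
    counts = np.bincount(flat, minlength=minlength).reshape(n_ch, n_win, n_bins)
    sums = np.bincount(
        flat, weights=np.ascontiguousarray(w_amp).ravel(), minlength=minlength
    ).reshape(n_ch, n_win, n_bins)
    mean_amp = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
    tot = mean_amp.sum(axis=-1, keepdims=True)
    p = np.divide(mean_amp, tot, out=np.zeros_like(mean_amp), where=tot > 0)
    q = counts / win
    mi = _mi_from_distributions(p, q, phase_correction)
    return np.where(tot[..., 0] > 0, mi, 0.0)
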