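"""Synthetic multichannel seizure recordings with planted phase-amplitude coupling.

The generator builds a deliberately simple but recoverable signal model of
an ictal iEEG channel:

* a rhythmic low-frequency component, by default a pure sinusoid so its
  Hilbert phase is analytically known (an optional sawtooth skew mimics
  asymmetric spike-wave shapes for robustness checks);
* discrete HFO bursts: per low-frequency cycle, with probability
  ``burst_probability``, a short (default quarter-cycle) Hann-tapered
  burst of an ``hfo_freq`` carrier is inserted.  With probability
  ``modulation_depth`` the burst is centered where the low-frequency phase
  equals ``preferred_phase``; otherwise its center phase is uniform.
  During a burst the envelope is additionally scaled by
  ``(1 + modulation_depth * cos(phi_LF - preferred_phase)) / 2``.  At
  depth 0 burst timing and amplitude are phase-uniform (no coupling); at
  depth 1 every burst sits at the preferred phase;
* 1/f-shaped background noise (spectrally shaped white noise).

A whole seizure case concatenates preictal / ictal / postictal segments.
Outside the ictal segment the modulation depth is forced to 0 and the HFO
amplitude attenuated: in this model coupling is strictly an ictal
phenomenon, which is what makes ictal-window thresholding downstream
meaningful.

Channel amplitudes default to an ictal-iEEG-like scale: ~100 uV rhythmic
activity, ~20 uV HFO bursts, ~10 uV background.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _sig

from .io import BASELINE_SECONDS, Recording, SeizureCase

__all__ = [
    "ChannelSpec",
    "SyntheticSeizureConfig",
    "generate_channel",
    "generate_seizure_case",
    "coupled_spec",
    "uncoupled_spec",
    "planted_config",
    "confound_pair_config",
]


@dataclass(frozen=True)
class ChannelSpec:
    """Generative parameters of one synthetic channel.

    ``modulation_depth`` in [0, 1] controls how strongly HFO bursts lock to
    ``preferred_phase`` (0 = no coupling).  ``burst_probability`` in (0, 1]
    is the per-cycle chance that a burst occurs at all, modeling the
    discreteness of ictal HFOs.  ``burst_fraction`` is the burst length as
    a fraction of one low-frequency cycle.  ``hfo_amplitude_ramp``, if
    given, linearly scales the burst amplitude from ``ramp[0]`` to
    ``ramp[1]`` times ``hfo_amplitude`` across the generated segment --
    used to vary HFO power while coupling stays fixed.

    ``coupling_window``, as a (start, stop) pair of fractions of the
    generated segment, restricts phase locking to a sub-interval: outside
    it the effective modulation depth is 0 (bursts keep occurring, at
    phase-uniform times).  Ictal coupling is episodic -- rhythmic
    discharges with locked HFOs occupy part of a seizure, not all of it --
    and an episodic plant is also what gives a pooled mean + 2.5 SD
    threshold headroom to detect anything.  None means always active.

    ``interictal_attenuation`` overrides, for this channel, the factor by
    which the case generator scales HFO amplitude outside the ictal
    segment -- so a channel's ictal power gain relative to its own
    baseline can differ across channels.  None uses the case-level value.
    """

    lf_freq: float = 6.0
    lf_phase: float = 0.0
    lf_amplitude: float = 100.0
    hfo_freq: float = 110.0
    hfo_amplitude: float = 20.0
    modulation_depth: float = 0.8
    preferred_phase: float = 0.0
    burst_probability: float = 0.8
    noise_scale: float = 10.0
    burst_fraction: float = 0.25
    lf_skew: float = 0.0
    hfo_amplitude_ramp: tuple[float, float] | None = None
    coupling_window: tuple[float, float] | None = None
    interictal_attenuation: float | None = None

    def validate(self, lf_band=(4.0, 30.0), hfo_band=(80.0, 150.0)) -> None:
        if not 0.0 <= self.modulation_depth <= 1.0:
            raise ValueError(f"modulation_depth {self.modulation_depth} outside [0, 1]")
        if not 0.0 < self.burst_probability <= 1.0:
            raise ValueError(f"burst_probability {self.burst_probability} outside (0, 1]")
        if not lf_band[0] < self.lf_freq < lf_band[1]:
            raise ValueError(f"lf_freq {self.lf_freq} outside the open band {lf_band}")
        if not hfo_band[0] < self.hfo_freq < hfo_band[1]:
            raise ValueError(f"hfo_freq {self.hfo_freq} outside the open band {hfo_band}")
        if not 0.0 < self.burst_fraction <= 1.0:
            raise ValueError("burst_fraction must be in (0, 1]")


@dataclass(frozen=True)
class SyntheticSeizureConfig:
    """Study-condition parameters for one synthetic seizure case.

    Durations are in seconds; ``preictal_duration`` must cover the 30-s
    PLHG baseline.  ``resected_channels`` holds 0-based channel indices.
    ``interictal_hfo_attenuation`` scales the HFO amplitude outside the
    ictal segment.
    """

    channel_specs: tuple[ChannelSpec, ...]
    n_channels: int | None = None
    sampling_rate: float = 512.0
    preictal_duration: float = 30.0
    ictal_duration: float = 60.0
    postictal_duration: float = 10.0
    resected_channels: frozenset[int] = frozenset()
    outcome: str = "I"
    seed: int = 0
    interictal_hfo_attenuation: float = 0.25
    case_id: str | None = None
    subject_id: str | None = None

    def __post_init__(self) -> None:
        n = self.n_channels if self.n_channels is not None else len(self.channel_specs)
        object.__setattr__(self, "n_channels", n)

    def validate(self) -> None:
        if len(self.channel_specs) != self.n_channels:
            raise ValueError(
                f"{len(self.channel_specs)} channel specs for {self.n_channels} channels"
            )
        if self.ictal_duration <= 0:
            raise ValueError("ictal_duration must be positive")
        if self.preictal_duration < BASELINE_SECONDS:
            raise ValueError(
                f"preictal_duration {self.preictal_duration} s cannot hold the "
                f"{BASELINE_SECONDS} s PLHG baseline"
            )
        if self.resected_channels and not set(self.resected_channels) <= set(
            range(self.n_channels)
        ):
            raise ValueError("resected_channels must be 0-based indices < n_channels")
        for spec in self.channel_specs:
            spec.validate()


def _pink_noise(rng: np.random.Generator, n: int, scale: float) -> np.ndarray:
    """1/f-power-shaped noise with standard deviation ``scale``."""
    if scale == 0.0 or n == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    spec[1:] /= np.sqrt(freqs[1:])
    spec[0] = 0.0
    out = np.fft.irfft(spec, n=n)
    sd = out.std()
    return out * (scale / sd) if sd > 0 else out


def generate_channel(
    spec: ChannelSpec, duration: float, rate: float, seed
) -> np.ndarray:
    """Generate one channel of ``duration`` seconds at ``rate`` Hz.

    Deterministic for a given seed (an integer or a
    ``numpy.random.SeedSequence``).
    """
    if duration <= 0 or rate <= 0:
        raise ValueError("duration and rate must be positive")
    spec.validate()
    n = int(round(duration * rate))
    if duration * rate < 10 * rate / spec.lf_freq:
        raise ValueError("segment must span at least 10 low-frequency cycles")
    rng = np.random.default_rng(seed)
    t = np.arange(n) / rate

    # theta is the phase the Hilbert transform recovers from a sine carrier:
    # sin(w t + p) = cos(w t + p - pi/2)
    theta = 2 * np.pi * spec.lf_freq * t + spec.lf_phase - np.pi / 2
    if spec.lf_skew > 0:
        width = min(0.5 + 0.5 * spec.lf_skew, 1.0)
        lf = spec.lf_amplitude * _sig.sawtooth(
            2 * np.pi * spec.lf_freq * t + spec.lf_phase, width=width
        )
    else:
        lf = spec.lf_amplitude * np.sin(2 * np.pi * spec.lf_freq * t + spec.lf_phase)

    x = lf + _pink_noise(rng, n, spec.noise_scale)

    cycle_len = rate / spec.lf_freq
    burst_len = max(int(round(spec.burst_fraction * cycle_len)), 4)
    taper = np.hanning(burst_len)
    n_cycles = int(np.floor(n / cycle_len))
    if spec.hfo_amplitude_ramp is not None:
        r0, r1 = spec.hfo_amplitude_ramp
        ramp = r0 + (r1 - r0) * np.arange(n) / max(n - 1, 1)
    else:
        ramp = None

    for k in range(n_cycles):
        # draw per-cycle randomness unconditionally so burst placement in
        # later cycles does not depend on earlier accept/reject outcomes
        u_occur = rng.random()
        u_lock = rng.random()
        u_phase = rng.uniform(-np.pi, np.pi)
        carrier_phase = rng.uniform(0.0, 2 * np.pi)
        if u_occur >= spec.burst_probability:
            continue
        depth = spec.modulation_depth
        if spec.coupling_window is not None:
            frac = (k + 0.5) / n_cycles
            if not (spec.coupling_window[0] <= frac < spec.coupling_window[1]):
                depth = 0.0
        center_phase = spec.preferred_phase if u_lock < depth else u_phase
        # cycle k spans theta in [2*pi*k - pi/2, 2*pi*(k+1) - pi/2); place the
        # center at the wrapped target phase within it
        theta_c = 2 * np.pi * k + center_phase
        t_c = (theta_c + np.pi / 2 - spec.lf_phase) / (2 * np.pi * spec.lf_freq)
        c = int(round(t_c * rate))
        lo = c - burst_len // 2
        hi = lo + burst_len
        if lo < 0 or hi > n:
            continue
        seg = slice(lo, hi)
        envelope = (
            spec.hfo_amplitude
            * (1.0 + depth * np.cos(theta[seg] - spec.preferred_phase))
            / 2.0
        )
        if ramp is not None:
            envelope = envelope * ramp[seg]
        burst = taper * envelope * np.cos(
            2 * np.pi * spec.hfo_freq * (t[seg] - t_c) + carrier_phase
        )
        x[seg] += burst
    return x


def generate_seizure_case(config: SyntheticSeizureConfig) -> SeizureCase:
    """Generate a full multichannel seizure case from a config.

    Preictal / ictal / postictal segments are generated per channel and
    concatenated; annotations mark onset, offset and the 30-s baseline
    ending at onset; resection labels and the Engel outcome are attached.
    Outside the ictal segment the channel spec is replaced by an uncoupled,
    attenuated variant.  Deterministic given ``config.seed``.
    """
    config.validate()
    rate = config.sampling_rate
    n_pre = int(round(config.preictal_duration * rate))
    n_ict = int(round(config.ictal_duration * rate))
    n_post = int(round(config.postictal_duration * rate))
    root = np.random.SeedSequence(config.seed)
    chan_seeds = root.spawn(config.n_channels)

    rows = []
    for spec, chan_ss in zip(config.channel_specs, chan_seeds):
        att = (
            spec.interictal_attenuation
            if spec.interictal_attenuation is not None
            else config.interictal_hfo_attenuation
        )
        # a channel-specific attenuation beyond the case-wide factor marks an
        # ictal-only power gain; scale that part out of the background too
        quiet = replace(
            spec,
            modulation_depth=0.0,
            hfo_amplitude=spec.hfo_amplitude * att,
            noise_scale=spec.noise_scale * att / config.interictal_hfo_attenuation,
        )
        seg_seeds = chan_ss.spawn(3)
        parts = [
            generate_channel(quiet, config.preictal_duration, rate, seg_seeds[0]),
            generate_channel(spec, config.ictal_duration, rate, seg_seeds[1]),
        ]
        if n_post > 0:
            parts.append(
                generate_channel(quiet, config.postictal_duration, rate, seg_seeds[2])
            )
        rows.append(np.concatenate(parts))

    samples = np.vstack(rows)
    labels = [f"ch{i + 1:02d}" for i in range(config.n_channels)]
    recording = Recording(samples, rate, labels)
    resected = np.zeros(config.n_channels, dtype=bool)
    resected[list(config.resected_channels)] = True
    n_base = int(round(BASELINE_SECONDS * rate))
    return SeizureCase(
        recording=recording,
        seizure_onset=n_pre,
        seizure_offset=n_pre + n_ict,
        baseline_span=(n_pre - n_base, n_pre),
        resected=resected,
        outcome=config.outcome,
        case_id=config.case_id,
        subject_id=config.subject_id,
        provenance={"generator": "plhfo.synth", "config": _config_dict(config)},
    )


def _config_dict(config: SyntheticSeizureConfig) -> dict:
    d = {
        k: v
        for k, v in vars(config).items()
        if k not in ("channel_specs", "resected_channels")
    }
    d["resected_channels"] = sorted(config.resected_channels)
    d["channel_specs"] = [vars(s) | {} for s in config.channel_specs]
    for cs in d["channel_specs"]:
        if cs["hfo_amplitude_ramp"] is not None:
            cs["hfo_amplitude_ramp"] = list(cs["hfo_amplitude_ramp"])
    return d


# ---------------------------------------------------------------------------
# Canonical study scenarios
# ---------------------------------------------------------------------------

def coupled_spec(depth: float = 0.8, **overrides) -> ChannelSpec:
    """A phase-amplitude-coupled channel at the default ictal scale."""
    return replace(ChannelSpec(), modulation_depth=depth, **overrides)


def uncoupled_spec(**overrides) -> ChannelSpec:
    """A channel with HFO bursts at phase-uniform times (no coupling)."""
    return replace(ChannelSpec(), modulation_depth=0.0, **overrides)


def _diversify(specs: tuple[ChannelSpec, ...]) -> tuple[ChannelSpec, ...]:
    """Give each channel its own rhythm frequency and phase.

    Identical low-frequency waveforms on every channel would survive into
    the per-sample median and be cancelled by re-referencing; distinct
    frequencies and phases, as on real electrode grids, keep the common
    median small.
    """
    out = []
    for i, s in enumerate(specs):
        out.append(
            replace(
                s,
                lf_freq=5.0 + 0.7 * (i % 8),
                lf_phase=float((2 * np.pi * i * 0.381966) % (2 * np.pi)),
            )
        )
    return tuple(out)


def planted_config(
    seed: int,
    n_channels: int = 6,
    coupled_channels: tuple[int, ...] = (0, 1),
    depth: float = 0.8,
    ictal_duration: float = 60.0,
    resect_coupled: bool = True,
    outcome: str | None = None,
    coupling_window: tuple[float, float] | None = (0.45, 0.75),
    **case_overrides,
) -> SyntheticSeizureConfig:
    """A case with a known coupled-channel set -- the planted ground truth.

    Coupled channels phase-lock during ``coupling_window`` (fractions of
    the ictal segment; default the mid-seizure 45-75% episode -- ictal
    coupling is episodic, not sustained).  When ``resect_coupled`` the
    coupled channels are exactly the resected set (a good-outcome
    scenario, default Engel I); otherwise the resection misses them
    entirely (a poor-outcome scenario, default Engel IV).
    """
    specs = _diversify(
        tuple(
            coupled_spec(depth, coupling_window=coupling_window)
            if i in coupled_channels
            else uncoupled_spec()
            for i in range(n_channels)
        )
    )
    if resect_coupled:
        resected = frozenset(coupled_channels)
        outcome = outcome or "I"
    else:
        resected = frozenset(i for i in range(n_channels) if i not in coupled_channels)
        outcome = outcome or "IV"
    return SyntheticSeizureConfig(
        channel_specs=specs,
        resected_channels=resected,
        outcome=outcome,
        seed=seed,
        ictal_duration=ictal_duration,
        **case_overrides,
    )


def confound_pair_config(
    seed: int,
    power_factor: float = 10.0,
    depth: float = 0.8,
    n_channels: int = 6,
    ictal_duration: float = 60.0,
    coupling_window: tuple[float, float] | None = (0.45, 0.75),
    **case_overrides,
) -> SyntheticSeizureConfig:
    """The HFO-power confound: loud-but-uncoupled vs quiet-but-coupled.

    Channel 0 carries ``power_factor`` times the usual HFO amplitude
    during the seizure (its own preictal baseline stays at the usual
    level, so the gain is an ictal phenomenon) but zero coupling; channel
    1 has unit amplitude and ``depth`` coupling; the remaining channels
    are ordinary uncoupled background.  Amplitude-weighted measures (MVL,
    PLHG) rank channel 0 above channel 1; scale-invariant ones (MI)
    should not.
    """
    base = ChannelSpec()
    default_att = SyntheticSeizureConfig.__dataclass_fields__[
        "interictal_hfo_attenuation"
    ].default
    # a genuinely "hot" channel is loud across the HFO band, background
    # included, not only during bursts
    loud = uncoupled_spec(
        hfo_amplitude=base.hfo_amplitude * power_factor,
        noise_scale=base.noise_scale * power_factor,
        interictal_attenuation=default_att / power_factor,
    )
    specs = _diversify(
        (loud, coupled_spec(depth, coupling_window=coupling_window))
        + tuple(uncoupled_spec() for _ in range(n_channels - 2))
    )
    return SyntheticSeizureConfig(
        channel_specs=specs,
        resected_channels=frozenset({1}),
        outcome="I",
        seed=seed,
        ictal_duration=ictal_duration,
        **case_overrides,
    )
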