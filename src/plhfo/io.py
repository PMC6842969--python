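"""On-disk contract: EDF / delimited-matrix signals, JSON sidecars, result files.

A seizure case on disk is a pair of files:

* a **signal file** -- EDF (the canonical interchange format for EEG) or a
  delimited numeric matrix (``.csv`` / ``.tsv`` / ``.txt``, one row per
  sample, one column per channel);
* a **JSON sidecar** holding the sampling rate, channel labels and mask,
  seizure onset/offset, the 30-s preictal baseline span, per-channel
  resection flags and the Engel outcome class.

All sample indices are 0-based and intervals are half-open ``[start, stop)``.

EDF files are written by a small built-in encoder (16-bit, 1-s data
records, per-channel physical scaling) and read back through :mod:`mne`,
which provides an independent decode path.  Optionally, HDF5 containers
with a ``/data`` matrix are accepted behind the same :class:`Recording`
contract.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "Recording",
    "SeizureCase",
    "read_case",
    "write_case",
    "write_results",
    "read_results",
    "BASELINE_SECONDS",
]

#: Length of the preictal reference segment used to normalize PLHG.
BASELINE_SECONDS = 30.0

ENGEL_CLASSES = ("I", "II", "III", "IV")


class FormatError(ValueError):
    """Signal file and sidecar disagree, or a sidecar field is invalid."""


@dataclass
class Recording:
    """A multichannel signal: channels x time matrix in microvolts.

    ``channel_mask`` marks channels usable for analysis (True = free of
    permanent artifacts).  Masked-out channels are excluded from every
    downstream computation, including the median reference.
    """

    samples: np.ndarray
    rate: float
    channel_labels: list[str]
    channel_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.samples.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.channel_mask is None:
            self.channel_mask = np.ones(self.samples.shape[0], dtype=bool)
        else:
            self.channel_mask = np.asarray(self.channel_mask, dtype=bool)
            if self.channel_mask.shape != (self.samples.shape[0],):
                raise ValueError("channel_mask length must equal channel count")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate


@dataclass
class SeizureCase:
    """A recording with seizure annotations, resection labels, and outcome.

    ``baseline_span`` is the 30-s preictal interval whose mean HFO envelope
    normalizes PLHG; it must end at or before ``seizure_onset``.
    """

    recording: Recording
    seizure_onset: int
    seizure_offset: int
    baseline_span: tuple[int, int]
    resected: np.ndarray
    outcome: str
    case_id: str | None = None
    subject_id: str | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.resected = np.asarray(self.resected, dtype=bool)
        n = self.recording.n_samples
        b0, b1 = self.baseline_span
        if not (0 <= self.seizure_onset < self.seizure_offset <= n):
            raise FormatError(
                f"need 0 <= onset ({self.seizure_onset}) < offset "
                f"({self.seizure_offset}) <= length ({n})"
            )
        if not (0 <= b0 < b1 <= self.seizure_onset):
            raise FormatError(
                f"baseline span [{b0}, {b1}) must lie before onset {self.seizure_onset}"
            )
        expected = int(round(BASELINE_SECONDS * self.recording.rate))
        if b1 - b0 != expected:
            raise FormatError(
                f"baseline span holds {b1 - b0} samples; expected {expected} "
                f"(= {BASELINE_SECONDS} s at {self.recording.rate} Hz)"
            )
        if self.resected.shape != (self.recording.n_channels,):
            raise FormatError(
                f"{self.resected.size} resection flags for "
                f"{self.recording.n_channels} channels"
            )
        if self.outcome not in ENGEL_CLASSES:
            raise FormatError(f"outcome must be one of {ENGEL_CLASSES}, got {self.outcome!r}")


# ---------------------------------------------------------------------------
# EDF encoding (16-bit, 1-second data records)
# ---------------------------------------------------------------------------

def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"field {s!r} exceeds {width} ASCII characters")
    return s.ljust(width).encode("ascii")


def _num8(value: float) -> bytes:
    """Format a float into EDF's 8-character numeric field."""
    for fmt in ("%.8g", "%.7g", "%.6g", "%.5g", "%.4g", "%.3g", "%.2g"):
        s = fmt % value
        if len(s) <= 8:
            return s.ljust(8).encode("ascii")
    raise ValueError(f"cannot format {value} in 8 characters")


def _write_edf(path: Path, samples: np.ndarray, rate: float, labels: list[str]) -> None:
    n_ch, n_samp = samples.shape
    spr = int(round(rate))  # samples per 1-s record, per channel
    if abs(rate - spr) > 1e-9:
        raise ValueError(f"EDF writer requires an integer sampling rate, got {rate}")
    n_rec = math.ceil(n_samp / spr)
    padded = np.zeros((n_ch, n_rec * spr), dtype=np.float64)
    padded[:, :n_samp] = samples

    pmin = padded.min(axis=1)
    pmax = padded.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmax[flat] = pmin[flat] + 1.0
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.rint((padded - pmin[:, None]) * scale[:, None] + dmin).astype("<i2")

    now = _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            _ascii("0", 8),
            _ascii("X X X X", 80),
            _ascii("Startdate X X X X", 80),
            _ascii(now.strftime("%d.%m.%y"), 8),
            _ascii(now.strftime("%H.%M.%S"), 8),
            _ascii(256 * (1 + n_ch), 8),
            _ascii("", 44),
            _ascii(n_rec, 8),
            _ascii(1, 8),
            _ascii(n_ch, 4),
        ]
    )
    header += b"".join(_ascii(lab[:16], 16) for lab in labels)
    header += b"".join(_ascii("", 80) for _ in range(n_ch))
    header += b"".join(_ascii("uV", 8) for _ in range(n_ch))
    header += b"".join(_num8(v) for v in pmin)
    header += b"".join(_num8(v) for v in pmax)
    header += b"".join(_ascii(dmin, 8) for _ in range(n_ch))
    header += b"".join(_ascii(dmax, 8) for _ in range(n_ch))
    header += b"".join(_ascii("", 80) for _ in range(n_ch))
    header += b"".join(_ascii(spr, 8) for _ in range(n_ch))
    header += b"".join(_ascii("", 32) for _ in range(n_ch))

    with open(path, "wb") as fh:
        fh.write(header)
        # record-major layout: all of channel 1's samples for record r, then
        # channel 2's, ...
        for r in range(n_rec):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())


def _read_edf(path: Path) -> tuple[np.ndarray, float, list[str]]:
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data()  # SI units: volts for uV-dimensioned channels
    return data * 1e6, float(raw.info["sfreq"]), list(raw.ch_names)


def _read_matrix(path: Path) -> np.ndarray:
    delim = {".csv": ",", ".tsv": "\t"}.get(path.suffix.lower())
    mat = np.loadtxt(path, delimiter=delim, ndmin=2)
    return mat.T  # rows = samples on disk -> channels x time in memory


# ---------------------------------------------------------------------------
# Case round trip
# ---------------------------------------------------------------------------

def write_case(case: SeizureCase, signal_path, sidecar_path) -> None:
    """Write a seizure case as a signal file plus JSON sidecar.

    The signal format follows the extension of ``signal_path`` (``.edf``,
    ``.csv``, ``.tsv`` or ``.txt``).  The sidecar echoes rate, labels and
    true sample count so the reader can trim EDF record padding.
    """
    signal_path, sidecar_path = Path(signal_path), Path(sidecar_path)
    rec = case.recording
    if signal_path.suffix.lower() == ".edf":
        _write_edf(signal_path, rec.samples, rec.rate, rec.channel_labels)
    else:
        delim = {".csv": ",", ".tsv": "\t"}.get(signal_path.suffix.lower(), " ")
        np.savetxt(signal_path, rec.samples.T, delimiter=delim, fmt="%.9g")
    sidecar = {
        "rate": rec.rate,
        "channel_labels": rec.channel_labels,
        "channel_mask": rec.channel_mask.tolist(),
        "n_samples": rec.n_samples,
        "seizure_onset": case.seizure_onset,
        "seizure_offset": case.seizure_offset,
        "baseline_span": list(case.baseline_span),
        "resected": case.resected.tolist(),
        "outcome": case.outcome,
        "case_id": case.case_id,
        "subject_id": case.subject_id,
        "provenance": _jsonable(case.provenance),
    }
    sidecar_path.write_text(json.dumps(sidecar, indent=1))


def read_case(signal_path, sidecar_path) -> SeizureCase:
    """Read and validate a seizure case from a signal file plus sidecar."""
    signal_path, sidecar_path = Path(signal_path), Path(sidecar_path)
    meta = json.loads(sidecar_path.read_text())
    suffix = signal_path.suffix.lower()
    if suffix == ".edf":
        data, rate, labels = _read_edf(signal_path)
        if abs(rate - meta["rate"]) > 1e-6:
            raise FormatError(f"EDF rate {rate} != sidecar rate {meta['rate']}")
        if labels != list(meta["channel_labels"]):
            raise FormatError("EDF channel labels do not match the sidecar")
    elif suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(signal_path, "r") as fh:
            data = np.asarray(fh["data"], dtype=np.float64)
        rate = float(meta["rate"])
    else:
        data = _read_matrix(signal_path)
        rate = float(meta["rate"])
    n_samples = int(meta.get("n_samples", data.shape[1]))
    if data.shape[1] < n_samples:
        raise FormatError(
            f"signal holds {data.shape[1]} samples but sidecar declares {n_samples}"
        )
    data = data[:, :n_samples]
    if data.shape[0] != len(meta["channel_labels"]):
        raise FormatError(
            f"signal has {data.shape[0]} channels but sidecar lists "
            f"{len(meta['channel_labels'])} labels"
        )
    if len(meta["resected"]) != data.shape[0]:
        raise FormatError(
            f"sidecar lists {len(meta['resected'])} resection flags for "
            f"{data.shape[0]} channels"
        )
    rec = Recording(
        data,
        float(meta["rate"]),
        list(meta["channel_labels"]),
        np.asarray(meta.get("channel_mask", [True] * data.shape[0]), dtype=bool),
    )
    return SeizureCase(
        recording=rec,
        seizure_onset=int(meta["seizure_onset"]),
        seizure_offset=int(meta["seizure_offset"]),
        baseline_span=tuple(meta["baseline_span"]),
        resected=np.asarray(meta["resected"], dtype=bool),
        outcome=meta["outcome"],
        case_id=meta.get("case_id"),
        subject_id=meta.get("subject_id"),
        provenance=meta.get("provenance") or {},
    )


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, float) and not math.isfinite(obj):
        return None
    return obj


def write_results(result, out_dir) -> None:
    """Write an evaluation result as JSON plus flat CSV tables.

    ``results.json`` carries the full structure (rankings, suprathreshold
    sets, resection ratios, group statistics, confound statistics) at full
    numeric precision.  ``resection_ratios.csv`` holds one row per
    (measure, variant, seizure) -- the long form of the per-group ratio
    panels -- and ``confound_stats.csv`` one row per measure with log-log
    slope and Pearson correlation aggregates versus HFO power.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    doc = _jsonable(result.to_dict())
    (out_dir / "results.json").write_text(json.dumps(doc, indent=1))

    rows = []
    for sz in doc["seizures"]:
        for name, md in sz["measures"].items():
            for variant, rr in md["resection_ratios"].items():
                rows.append(
                    {
                        "measure": name,
                        "variant": variant,
                        "seizure_id": sz["case_id"],
                        "subject_id": sz["subject_id"],
                        "outcome": sz["outcome"],
                        "n_selected": rr["denominator"],
                        "n_selected_resected": rr["numerator"],
                        "resection_ratio_pct": rr["ratio"],
                    }
                )
    pd.DataFrame(
        rows,
        columns=[
            "measure",
            "variant",
            "seizure_id",
            "subject_id",
            "outcome",
            "n_selected",
            "n_selected_resected",
            "resection_ratio_pct",
        ],
    ).to_csv(out_dir / "resection_ratios.csv", index=False)

    crows = [
        {
            "measure": c["measure_name"],
            "slope_mean": c["slope_mean"],
            "slope_sem": c["slope_sem"],
            "pearson_mean": c["pearson_mean"],
            "pearson_sem": c["pearson_sem"],
            "n_channels": c["n_channels"],
        }
        for c in doc["confounds"]
    ]
    pd.DataFrame(
        crows,
        columns=["measure", "slope_mean", "slope_sem", "pearson_mean", "pearson_sem", "n_channels"],
    ).to_csv(out_dir / "confound_stats.csv", index=False)


def read_results(out_dir):
    """Read back a result written by :func:`write_results`."""
    from .evaluation import EvaluationResult

    doc = json.loads((Path(out_dir) / "results.json").read_text())
    return EvaluationResult.from_dict(doc)
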