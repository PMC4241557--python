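"""Domain types and file I/O for current-clamp recordings.

Canonical units throughout the package: mV (voltage), pA (current),
ms (time and sampling step), MOhm, pF, seconds for interspike intervals and
percent for their coefficient of variation.  Unit conversion happens only at
I/O boundaries.

Trace files come in two flavours:

* delimited text with header ``time_ms,voltage_mV[,current_pA]``;
* HDF5 with datasets ``/time_step_ms``, ``/voltage``, ``/current`` and root
  attributes for metadata.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "VoltageTrace",
    "RecordingSet",
    "STAGE_BINS",
    "STAGE_ORDER",
    "stage_for_age",
    "stage_mid_age",
    "read_trace",
    "write_trace",
    "read_recording_set",
    "write_recording_set",
    "TraceParseError",
]


class TraceParseError(ValueError):
    """Raised when a trace file is malformed (names the offending location)."""


#: Developmental stage bins (postnatal days, inclusive).  Ages outside the
#: bins (P4, P24-P27) were not sampled and are rejected.
STAGE_BINS: dict[str, tuple[int, int]] = {
    "P2-P3": (2, 3),
    "P5": (5, 5),
    "P6": (6, 6),
    "P7": (7, 7),
    "P8-P9": (8, 9),
    "P10-P11": (10, 11),
    "P12-P13": (12, 13),
    "P14": (14, 14),
    "P15-P16": (15, 16),
    "P17": (17, 17),
    "P18": (18, 18),
    "P19": (19, 19),
    "P20": (20, 20),
    "P21-P23": (21, 23),
    "P28-P29": (28, 29),
}

STAGE_ORDER: list[str] = list(STAGE_BINS)


def stage_for_age(age_days: int) -> str:
    """Return the stage bin containing ``age_days`` (raises for gap ages)."""
    for label, (lo, hi) in STAGE_BINS.items():
        if lo <= age_days <= hi:
            return label
    raise ValueError(
        f"age P{age_days} falls outside the sampled stage bins "
        f"(valid: 2-3, 5-23, 28-29)"
    )


def stage_mid_age(stage: str) -> float:
    """Midpoint age (days) of a stage bin, used for age axes."""
    lo, hi = STAGE_BINS[stage]
    return (lo + hi) / 2.0


@dataclass
class VoltageTrace:
    """A uniformly sampled membrane-potential trace with its current command.

    Parameters
    ----------
    time_step : float
        Sampling interval in ms (0.05 ms at the default 20 kHz).
    voltage : ndarray
        Membrane potential samples, mV.
    current : ndarray
        Injected current samples, pA; all-zero for spontaneous recordings.
    label : str
        Free-text description (protocol name, neuron id, ...).
    """

    time_step: float
    voltage: np.ndarray
    current: np.ndarray = None  # type: ignore[assignment]
    label: str = ""

    def __post_init__(self) -> None:
        self.voltage = np.asarray(self.voltage, dtype=float)
        if self.current is None:
            self.current = np.zeros_like(self.voltage)
        self.current = np.asarray(self.current, dtype=float)
        if not self.time_step > 0:
            raise ValueError(f"time_step must be > 0, got {self.time_step}")
        if self.voltage.ndim != 1 or self.voltage.size < 2:
            raise ValueError("voltage must be a 1-d array of length >= 2")
        if self.current.shape != self.voltage.shape:
            raise ValueError(
                f"current length {self.current.size} != voltage length "
                f"{self.voltage.size}"
            )
        if not np.all(np.isfinite(self.voltage)) or not np.all(
            np.isfinite(self.current)
        ):
            raise ValueError("voltage/current must contain only finite values")

    @property
    def n_samples(self) -> int:
        return self.voltage.size

    @property
    def duration_ms(self) -> float:
        return (self.n_samples - 1) * self.time_step

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.time_step

    def pulse_window(self) -> tuple[float, float]:
        """(onset, offset) in ms of the non-zero current epoch.

        Raises if the current command is identically zero.
        """
        nz = np.flatnonzero(self.current != 0)
        if nz.size == 0:
            raise ValueError("trace has no current pulse (command is all zero)")
        return nz[0] * self.time_step, (nz[-1] + 1) * self.time_step


@dataclass
class RecordingSet:
    """All protocols recorded from one neuron plus its metadata.

    ``passive_pulses``/``fi_pulses`` are lists of ``(trace, step_pA)`` pairs;
    ``sag_pulse`` is a single such pair or ``None``.  Every protocol list may
    be empty except the spontaneous recording.
    """

    neuron_id: str
    age_days: int
    stage: str
    spontaneous: VoltageTrace
    passive_pulses: list[tuple[VoltageTrace, float]] = field(default_factory=list)
    sag_pulse: tuple[VoltageTrace, float] | None = None
    fi_pulses: list[tuple[VoltageTrace, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 2 <= self.age_days <= 29:
            raise ValueError(f"age_days must be in [2, 29], got {self.age_days}")
        expected = stage_for_age(self.age_days)
        if self.stage != expected:
            raise ValueError(
                f"stage {self.stage!r} inconsistent with age P{self.age_days} "
                f"(expected {expected!r})"
            )


# ---------------------------------------------------------------------------
# Trace file I/O


def _is_hdf5(path: str, fmt: str | None) -> bool:
    if fmt is not None:
        if fmt not in ("text", "hdf5"):
            raise ValueError(f"unknown trace format {fmt!r}")
        return fmt == "hdf5"
    return os.path.splitext(path)[1].lower() in (".h5", ".hdf5")


def read_trace(path: str, fmt: str | None = None) -> VoltageTrace:
    """Read a voltage trace from delimited text or HDF5.

    Text files must carry the header ``time_ms,voltage_mV`` with an optional
    ``current_pA`` third column and a uniform time grid.
    """
    if _is_hdf5(path, fmt):
        with h5py.File(path, "r") as f:
            for ds in ("time_step_ms", "voltage"):
                if ds not in f:
                    raise TraceParseError(f"{path}: missing dataset /{ds}")
            dt = float(f["time_step_ms"][()])
            v = np.asarray(f["voltage"][:], dtype=float)
            c = np.asarray(f["current"][:], dtype=float) if "current" in f else None
            label = str(f.attrs.get("label", ""))
        return VoltageTrace(dt, v, c, label=label)

    with open(path) as fh:
        header = fh.readline().strip()
        cols = [c.strip() for c in header.split(",")]
        if cols[:2] != ["time_ms", "voltage_mV"] or (
            len(cols) == 3 and cols[2] != "current_pA"
        ) or len(cols) > 3:
            raise TraceParseError(
                f"{path}:1: expected header 'time_ms,voltage_mV[,current_pA]', "
                f"got {header!r}"
            )
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != len(cols):
                raise TraceParseError(
                    f"{path}:{lineno}: expected {len(cols)} fields, "
                    f"got {len(parts)}"
                )
            try:
                rows.append([float(x) for x in parts])
            except ValueError as e:
                raise TraceParseError(f"{path}:{lineno}: {e}") from None
    if len(rows) < 2:
        raise TraceParseError(f"{path}: traces need at least 2 samples")
    arr = np.asarray(rows)
    t = arr[:, 0]
    steps = np.diff(t)
    dt = steps[0]
    if dt <= 0 or not np.allclose(steps, dt, rtol=1e-6, atol=1e-9):
        raise TraceParseError(f"{path}: time column is not a uniform grid")
    current = arr[:, 2] if arr.shape[1] == 3 else None
    return VoltageTrace(dt, arr[:, 1], current)


def write_trace(trace: VoltageTrace, path: str, fmt: str | None = None) -> None:
    """Write a trace; text values use the shortest round-trip representation
    so read_trace(write_trace(x)) reproduces the samples bit-exactly."""
    if _is_hdf5(path, fmt):
        with h5py.File(path, "w") as f:
            f.create_dataset("time_step_ms", data=trace.time_step)
            f.create_dataset("voltage", data=trace.voltage)
            f.create_dataset("current", data=trace.current)
            f.attrs["label"] = trace.label
        return
    with_current = np.any(trace.current != 0)
    with open(path, "w") as fh:
        fh.write("time_ms,voltage_mV,current_pA\n" if with_current
                 else "time_ms,voltage_mV\n")
        t = trace.times_ms
        if with_current:
            for ti, vi, ci in zip(t, trace.voltage, trace.current):
                fh.write(f"{float(ti)!r},{float(vi)!r},{float(ci)!r}\n")
        else:
            for ti, vi in zip(t, trace.voltage):
                fh.write(f"{float(ti)!r},{float(vi)!r}\n")


# ---------------------------------------------------------------------------
# RecordingSet HDF5 I/O (one file per neuron)


def _write_pulse(grp: h5py.Group, name: str, trace: VoltageTrace, step: float) -> None:
    g = grp.create_group(name)
    g.create_dataset("time_step_ms", data=trace.time_step)
    g.create_dataset("voltage", data=trace.voltage)
    g.create_dataset("current", data=trace.current)
    g.attrs["label"] = trace.label
    g.attrs["step_pA"] = step


def _read_pulse(g: h5py.Group) -> tuple[VoltageTrace, float]:
    tr = VoltageTrace(
        float(g["time_step_ms"][()]),
        np.asarray(g["voltage"][:]),
        np.asarray(g["current"][:]),
        label=str(g.attrs.get("label", "")),
    )
    return tr, float(g.attrs["step_pA"])


def write_recording_set(rec: RecordingSet, path: str) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["neuron_id"] = rec.neuron_id
        f.attrs["age_days"] = rec.age_days
        f.attrs["stage"] = rec.stage
        _write_pulse(f, "spontaneous", rec.spontaneous, 0.0)
        pg = f.create_group("passive_pulses")
        for i, (tr, amp) in enumerate(rec.passive_pulses):
            _write_pulse(pg, f"pulse_{i:03d}", tr, amp)
        if rec.sag_pulse is not None:
            _write_pulse(f, "sag_pulse", rec.sag_pulse[0], rec.sag_pulse[1])
        fg = f.create_group("fi_pulses")
        for i, (tr, amp) in enumerate(rec.fi_pulses):
            _write_pulse(fg, f"pulse_{i:03d}", tr, amp)


def read_recording_set(path: str) -> RecordingSet:
    with h5py.File(path, "r") as f:
        spont, _ = _read_pulse(f["spontaneous"])
        passive = [_read_pulse(f["passive_pulses"][k])
                   for k in sorted(f["passive_pulses"])]
        sag = _read_pulse(f["sag_pulse"]) if "sag_pulse" in f else None
        fi = [_read_pulse(f["fi_pulses"][k]) for k in sorted(f["fi_pulses"])]
        return RecordingSet(
            neuron_id=str(f.attrs["neuron_id"]),
            age_days=int(f.attrs["age_days"]),
            stage=str(f.attrs["stage"]),
            spontaneous=spont,
            passive_pulses=passive,
            sag_pulse=sag,
            fi_pulses=fi,
        )
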