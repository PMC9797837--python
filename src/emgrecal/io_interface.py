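"""On-disk session layout, validation, config and logging.

A *session* is one continuous armband donning: an 8-channel surface-EMG
series at a nominal 1,000 Hz, a sparser stream of kinematic frame
timestamps (~72 Hz on average), and a table of annotated gesture
instances (label, instance index, start/end time).  Sessions are stored
one-per-directory as delimited text so they are portable and diff-able::

    <session_dir>/
        emg.csv      timestamp_ms, ch1..ch8
        kin.csv      timestamp_ms
        labels.csv   label, instance_index, start_ms, end_ms
        meta.yaml    session_id, day_index, units, nominal_rate_hz, meta

All timestamps are floating-point milliseconds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "N_CHANNELS",
    "EMGSeries",
    "GestureInstance",
    "Session",
    "SessionError",
    "IncompleteSessionError",
    "CorruptTimelineError",
    "ChannelMismatchError",
    "read_session",
    "write_session",
    "load_yaml_config",
    "setup_logging",
]

N_CHANNELS = 8

log = logging.getLogger("emgrecal")


class SessionError(ValueError):
    """Base class for invalid or unreadable sessions."""


class IncompleteSessionError(SessionError):
    """A required session file is missing ("incomplete session")."""


class CorruptTimelineError(SessionError):
    """Timestamps are non-monotone or annotations leave the EMG range."""


class ChannelMismatchError(SessionError):
    """EMG table does not carry exactly 8 channels."""


@dataclass
class EMGSeries:
    """8-channel EMG: ``samples`` is (8, N), ``timestamps`` ascending ms."""

    timestamps: np.ndarray
    samples: np.ndarray
    units: str = "counts"          # "counts" | "millivolts"
    nominal_rate: float = 1000.0   # Hz

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.samples = np.asarray(self.samples, dtype=float)

    def validate(self) -> None:
        if self.samples.ndim != 2 or self.samples.shape[0] != N_CHANNELS:
            raise ChannelMismatchError(
                f"channel mismatch: expected {N_CHANNELS} channels, "
                f"got shape {self.samples.shape}"
            )
        if self.timestamps.shape[0] != self.samples.shape[1]:
            raise CorruptTimelineError(
                "corrupt timeline: timestamp count != sample count"
            )
        if self.timestamps.size > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise CorruptTimelineError("corrupt timeline: EMG timestamps not strictly increasing")
        if self.units not in ("counts", "millivolts"):
            raise SessionError(f"unknown EMG units {self.units!r}")
        if not self.nominal_rate > 0:
            raise SessionError("nominal_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass(frozen=True, order=True)
class GestureInstance:
    """One cued performance-and-hold of a gesture; atomic unit of splitting."""

    label: str
    instance_index: int
    start_ms: float
    end_ms: float

    def validate(self) -> None:
        if not self.start_ms < self.end_ms:
            raise CorruptTimelineError(
                f"corrupt timeline: instance {self.label}#{self.instance_index} "
                "has start_ms >= end_ms"
            )
        if self.instance_index < 1:
            raise SessionError("instance_index must be >= 1")

    @property
    def key(self) -> tuple[str, int]:
        return (self.label, self.instance_index)


@dataclass
class Session:
    """One recording unit: EMG, kinematic timestamps, annotations, metadata."""

    session_id: str
    day_index: int
    emg: EMGSeries
    kinematic_times: np.ndarray
    annotations: list[GestureInstance] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.kinematic_times = np.asarray(self.kinematic_times, dtype=float)

    def validate(self) -> None:
        self.emg.validate()
        if self.kinematic_times.size > 1 and not np.all(np.diff(self.kinematic_times) > 0):
            raise CorruptTimelineError(
                "corrupt timeline: kinematic timestamps not strictly increasing"
            )
        if self.emg.n_samples == 0 and (self.annotations or self.kinematic_times.size):
            raise CorruptTimelineError("corrupt timeline: annotations without EMG samples")
        if self.emg.n_samples:
            t0, t1 = self.emg.timestamps[0], self.emg.timestamps[-1]
            for ann in self.annotations:
                ann.validate()
                if ann.start_ms < t0 or ann.end_ms > t1:
                    raise CorruptTimelineError(
                        f"corrupt timeline: annotation {ann.label}#{ann.instance_index} "
                        f"[{ann.start_ms}, {ann.end_ms}] outside EMG range [{t0}, {t1}]"
                    )
        seen: set[tuple[str, int]] = set()
        for ann in self.annotations:
            if ann.key in seen:
                raise SessionError(f"duplicate instance key {ann.key}")
            seen.add(ann.key)

    @property
    def labels(self) -> list[str]:
        return sorted({a.label for a in self.annotations})

    def with_annotations(self, annotations: list[GestureInstance]) -> "Session":
        return replace(self, annotations=list(annotations))


# ---------------------------------------------------------------------------
# on-disk layout
# ---------------------------------------------------------------------------

_EMG_FMT = "%.10g"      # ADC counts / mV and ms timestamps
_EXACT_FMT = "%.17g"    # round-trips float64 exactly


def write_session(session: Session, root_path: str | Path) -> Path:
    """Write ``session`` under ``root_path`` in the standard text layout.

    The layout is byte-stable: writing the same session twice produces
    identical files.
    """
    session.validate()
    root = Path(root_path)
    root.mkdir(parents=True, exist_ok=True)

    emg_tab = pd.DataFrame(
        np.column_stack([session.emg.timestamps, session.emg.samples.T]),
        columns=["timestamp_ms"] + [f"ch{i + 1}" for i in range(N_CHANNELS)],
    )
    emg_tab.to_csv(root / "emg.csv", index=False, float_format=_EMG_FMT)

    pd.DataFrame({"timestamp_ms": session.kinematic_times}).to_csv(
        root / "kin.csv", index=False, float_format=_EXACT_FMT
    )

    lab = pd.DataFrame(
        [(a.label, a.instance_index, a.start_ms, a.end_ms) for a in session.annotations],
        columns=["label", "instance_index", "start_ms", "end_ms"],
    )
    lab.to_csv(root / "labels.csv", index=False, float_format=_EXACT_FMT)

    meta = {
        "session_id": session.session_id,
        "day_index": int(session.day_index),
        "units": session.emg.units,
        "nominal_rate_hz": float(session.emg.nominal_rate),
        "meta": dict(session.meta),
    }
    (root / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
    return root


def read_session(root_path: str | Path) -> Session:
    """Read and validate one session directory; rejects malformed layouts."""
    root = Path(root_path)
    for name in ("emg.csv", "kin.csv", "labels.csv", "meta.yaml"):
        if not (root / name).is_file():
            raise IncompleteSessionError(f"incomplete session: missing {name} in {root}")

    meta = yaml.safe_load((root / "meta.yaml").read_text())
    emg_tab = pd.read_csv(root / "emg.csv")
    n_chan = emg_tab.shape[1] - 1
    if n_chan != N_CHANNELS:
        raise ChannelMismatchError(f"channel mismatch: {n_chan} channels in emg.csv")
    emg = EMGSeries(
        timestamps=emg_tab["timestamp_ms"].to_numpy(),
        samples=emg_tab.iloc[:, 1:].to_numpy().T,
        units=meta["units"],
        nominal_rate=float(meta["nominal_rate_hz"]),
    )

    kin = pd.read_csv(root / "kin.csv", float_precision="round_trip")["timestamp_ms"].to_numpy(dtype=float)

    lab = pd.read_csv(
        root / "labels.csv",
        dtype={"label": str, "instance_index": int, "start_ms": float, "end_ms": float},
        float_precision="round_trip",
    )
    annotations = [
        GestureInstance(r.label, int(r.instance_index), float(r.start_ms), float(r.end_ms))
        for r in lab.itertuples(index=False)
    ]

    session = Session(
        session_id=str(meta["session_id"]),
        day_index=int(meta["day_index"]),
        emg=emg,
        kinematic_times=kin,
        annotations=annotations,
        meta=dict(meta.get("meta") or {}),
    )
    session.validate()
    return session


def load_yaml_config(path: str | Path) -> dict:
    """Load a YAML config file into a plain dict (empty file -> {})."""
    out = yaml.safe_load(Path(path).read_text())
    return dict(out or {})


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s: %(message)s",
    )
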