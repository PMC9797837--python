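"""Multi-session synthetic surface-EMG generator with session domain shift.

Signal model, per channel c::

    x_c(t) = g_c * sum_m W'[c, m] * envelope_m(t) * carrier_m(t)
             + offset_c + line(t) + noise(t)

where ``envelope_m`` are smooth non-negative per-muscle activation
curves (one ~1 s bump per cued gesture hold, idle in between),
``carrier_m`` is band-limited (60-500 Hz) unit-variance noise standing
in for the interference pattern of many motor units, ``W`` is an 8 x
n_muscles electrode-mixing matrix, and ``W'`` is ``W`` with its rows
circularly shifted by a fractional amount — the signature of re-donning
an electrode armband in a slightly rotated position.  Per-channel gain,
baseline offset, sensor noise and 60 Hz line interference complete the
session perturbation; severity levels scale all of them monotonically.

Sessions share one gesture-template set, so a classifier can in
principle generalize across sessions; with severity "none" sessions are
statistically exchangeable, while moderate or severe perturbations
create the inter-session domain shift that rapid recalibration targets.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import signal as sig

from .dataset import INTERACTION_GESTURES, REMOVED_GESTURES
from .io_interface import EMGSeries, GestureInstance, N_CHANNELS, Session, write_session

__all__ = [
    "SimConfig",
    "GestureTemplate",
    "SessionPerturbation",
    "SEVERITY_LEVELS",
    "make_gesture_templates",
    "sample_perturbation",
    "rotate_mixing",
    "synthesize_session",
    "make_dataset",
]

log = logging.getLogger("emgrecal.synthetic")

_RETAINED = [g for g in INTERACTION_GESTURES if g not in REMOVED_GESTURES]


@dataclass(frozen=True)
class SimConfig:
    """Study-condition defaults: 6 gestures x 10 one-second holds per session."""

    n_gestures: int = 6
    n_instances_per_gesture: int = 10
    n_muscles: int = 6
    emg_rate: float = 1000.0          # Hz
    kin_rate: float = 72.0            # mean Hz of the kinematic stream
    kin_jitter: float = 0.15          # fractional frame-interval jitter
    hold_ms: float = 1000.0           # cued static hold
    idle_gap_ms: float = 500.0        # minimum idle between instances
    edge_ramp_ms: float = 150.0       # envelope on/off ramp inside the hold
    signal_mv: float = 0.5            # activation amplitude scale (mV RMS-ish)
    template_min_dist: float = 0.5    # pairwise distance floor, unit-norm space
    mixing_sigma: float = 1.0         # electrode spatial spread (channels)
    adc_gain_v_per_count: float = 1e-7  # 0.1 uV/count, 24-bit-style resolution

    def validate(self) -> None:
        window_ms = 24 * 1000.0 / self.kin_rate
        if not self.idle_gap_ms > window_ms:
            raise ValueError(
                f"idle_gap_ms {self.idle_gap_ms} must exceed the window duration "
                f"({window_ms:.0f} ms) to guarantee split independence"
            )
        if self.n_gestures < 2 or self.n_muscles < 2:
            raise ValueError("need n_gestures >= 2 and n_muscles >= 2")
        if self.n_instances_per_gesture < 1:
            raise ValueError("need at least one instance per gesture")

    @property
    def gesture_names(self) -> list[str]:
        if self.n_gestures <= len(_RETAINED):
            return list(_RETAINED[: self.n_gestures])
        return [f"g{i:02d}" for i in range(self.n_gestures)]

    def mixing_matrix(self) -> np.ndarray:
        """Deterministic 8 x n_muscles circular-Gaussian electrode coupling."""
        w = np.empty((N_CHANNELS, self.n_muscles))
        centers = N_CHANNELS * np.arange(self.n_muscles) / self.n_muscles
        for m, cm in enumerate(centers):
            d = np.abs(np.arange(N_CHANNELS) - cm)
            d = np.minimum(d, N_CHANNELS - d)
            w[:, m] = np.exp(-(d ** 2) / (2 * self.mixing_sigma ** 2))
        return w


@dataclass
class GestureTemplate:
    """Per-muscle activation envelopes for one gesture's ~1 s hold."""

    label: str
    envelopes: np.ndarray       # (n_muscles, hold_samples), non-negative
    force_scale: float = 1.0

    def validate(self) -> None:
        if np.any(self.envelopes < 0):
            raise ValueError("envelopes must be non-negative")
        if self.envelopes.size and (
            np.any(self.envelopes[:, 0] != 0) or np.any(self.envelopes[:, -1] != 0)
        ):
            raise ValueError("envelopes must be zero at both ends")


@dataclass
class SessionPerturbation:
    """Session-level distortion: gain, electrode rotation and placement
    jitter, baseline offset, sensor noise, line interference.

    ``mixing_jitter_sd`` models the residual electrode-placement change
    that a pure circular rotation cannot express (tilt, translation,
    contact-quality differences): an additive per-session random
    distortion of the electrode-mixing matrix with this standard
    deviation, drawn inside :func:`synthesize_session`.
    """

    channel_gains: np.ndarray = field(default_factory=lambda: np.ones(N_CHANNELS))
    electrode_rotation: float = 0.0          # fractional channels, in [0, 8)
    baseline_offset_mv: np.ndarray = field(default_factory=lambda: np.zeros(N_CHANNELS))
    noise_sd_mv: float = 0.01
    line_amp_mv: float = 0.0
    mixing_jitter_sd: float = 0.0

    def validate(self) -> None:
        if np.any(self.channel_gains <= 0):
            raise ValueError("gains must be positive")
        if not 0 <= self.electrode_rotation < N_CHANNELS:
            raise ValueError("rotation must lie in [0, 8)")
        if self.mixing_jitter_sd < 0:
            raise ValueError("mixing_jitter_sd must be >= 0")

    def to_dict(self) -> dict:
        return {
            "channel_gains": [float(g) for g in self.channel_gains],
            "electrode_rotation": float(self.electrode_rotation),
            "baseline_offset_mv": [float(o) for o in self.baseline_offset_mv],
            "noise_sd_mv": float(self.noise_sd_mv),
            "line_amp_mv": float(self.line_amp_mv),
            "mixing_jitter_sd": float(self.mixing_jitter_sd),
        }


#: (gain half-range, rotation range, offset range mV, noise range mV,
#:  line range mV, mixing jitter sd)
SEVERITY_LEVELS = {
    "none": None,
    "mild": (0.10, (0.10, 0.40), 0.02, (0.015, 0.030), (0.02, 0.08), 0.10),
    "moderate": (0.30, (0.50, 1.50), 0.05, (0.030, 0.070), (0.05, 0.15), 0.20),
    "severe": (0.50, (1.50, 3.00), 0.10, (0.060, 0.150), (0.10, 0.30), 0.40),
}


def make_gesture_templates(config: SimConfig, seed: int = 0) -> list[GestureTemplate]:
    """Pairwise-distinct gesture templates (seeded, reproducible).

    Distinctness is enforced in the space of unit-norm per-muscle
    amplitude vectors; sampling retries until every pair is at least
    ``config.template_min_dist`` apart.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    hold_n = int(round(config.hold_ms * config.emg_rate / 1000.0))
    ramp_n = max(2, int(round(config.edge_ramp_ms * config.emg_rate / 1000.0)))
    bump = np.ones(hold_n)
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
    bump[:ramp_n] = ramp
    bump[-ramp_n:] = ramp[::-1]
    bump[0] = bump[-1] = 0.0

    # sparse random recruitment: each gesture activates about half the
    # muscle groups with random strengths, the way distinct hand
    # gestures engage distinct (but overlapping) forearm muscle sets
    amps: list[np.ndarray] = []
    for _ in range(config.n_gestures):
        for _attempt in range(500):
            a = rng.uniform(0.0, 1.0, size=config.n_muscles)
            a[a < np.sort(a)[config.n_muscles // 2]] = 0.0
            norm = np.linalg.norm(a)
            if norm == 0:
                continue
            a = a / norm
            if all(np.linalg.norm(a - b) >= config.template_min_dist for b in amps):
                amps.append(a)
                break
        else:
            raise ValueError(
                "infeasible distinctness: could not draw "
                f"{config.n_gestures} templates at min distance {config.template_min_dist}"
            )

    return [
        GestureTemplate(
            label=name,
            envelopes=np.outer(amps[i], bump),
            force_scale=1.0,
        )
        for i, name in enumerate(config.gesture_names)
    ]


def sample_perturbation(severity: str, seed: int = 0) -> SessionPerturbation:
    """Draw one session perturbation at a named severity level."""
    if severity not in SEVERITY_LEVELS:
        raise ValueError(f"unknown severity {severity!r}; choose from {sorted(SEVERITY_LEVELS)}")
    if severity == "none":
        return SessionPerturbation()
    g_half, (rot_lo, rot_hi), off, (n_lo, n_hi), (l_lo, l_hi), jit = SEVERITY_LEVELS[severity]
    rng = np.random.default_rng(seed)
    rot = float(rng.choice([-1.0, 1.0]) * rng.uniform(rot_lo, rot_hi)) % N_CHANNELS
    p = SessionPerturbation(
        channel_gains=rng.uniform(1 - g_half, 1 + g_half, size=N_CHANNELS),
        electrode_rotation=rot,
        baseline_offset_mv=rng.uniform(-off, off, size=N_CHANNELS),
        noise_sd_mv=float(rng.uniform(n_lo, n_hi)),
        line_amp_mv=float(rng.uniform(l_lo, l_hi)),
        mixing_jitter_sd=jit,
    )
    p.validate()
    return p


def rotate_mixing(w: np.ndarray, rotation: float) -> np.ndarray:
    """Circular fractional shift of the mixing-matrix rows (electrodes)."""
    k = int(np.floor(rotation))
    frac = rotation - k
    idx = np.arange(N_CHANNELS)
    w_k = w[(idx + k) % N_CHANNELS]
    w_k1 = w[(idx + k + 1) % N_CHANNELS]
    return (1 - frac) * w_k + frac * w_k1


def _bandlimited_carriers(rng: np.random.Generator, n_muscles: int, n: int,
                          rate: float) -> np.ndarray:
    sos = sig.butter(4, [60.0, min(500.0, 0.45 * rate)], btype="bandpass",
                     fs=rate, output="sos")
    white = rng.standard_normal((n_muscles, n))
    x = sig.sosfilt(sos, white, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def synthesize_session(
    templates: list[GestureTemplate],
    perturbation: SessionPerturbation,
    config: SimConfig,
    seed: int = 0,
    session_id: str = "sim00",
    day_index: int = 0,
) -> Session:
    """Generate one full session: EMG, kinematic timestamps, annotations.

    Instances appear in seeded random order, separated by idle gaps that
    always exceed the 24-frame window duration.
    """
    config.validate()
    perturbation.validate()
    rng = np.random.default_rng(seed)
    rate = config.emg_rate
    hold_n = templates[0].envelopes.shape[1]

    # randomized instance schedule with jittered idle gaps
    order = [t for t in templates for _ in range(config.n_instances_per_gesture)]
    order = [order[i] for i in rng.permutation(len(order))]
    counters: dict[str, int] = {}
    annotations: list[GestureInstance] = []
    starts_samples: list[tuple[int, GestureTemplate]] = []
    t_ms = config.idle_gap_ms * rng.uniform(1.0, 1.3)
    for tmpl in order:
        start = t_ms
        end = start + config.hold_ms
        counters[tmpl.label] = counters.get(tmpl.label, 0) + 1
        annotations.append(GestureInstance(tmpl.label, counters[tmpl.label], start, end))
        starts_samples.append((int(round(start * rate / 1000.0)), tmpl))
        t_ms = end + config.idle_gap_ms * rng.uniform(1.0, 1.3)
    total_ms = t_ms
    n = int(np.ceil(total_ms * rate / 1000.0)) + 1

    envelopes = np.zeros((config.n_muscles, n))
    for s0, tmpl in starts_samples:
        envelopes[:, s0:s0 + hold_n] += tmpl.force_scale * tmpl.envelopes[:, : n - s0]

    carriers = _bandlimited_carriers(rng, config.n_muscles, n, rate)
    w_rot = rotate_mixing(config.mixing_matrix(), perturbation.electrode_rotation)
    if perturbation.mixing_jitter_sd > 0:
        w_rot = w_rot + rng.normal(0.0, perturbation.mixing_jitter_sd, size=w_rot.shape)
    activation = w_rot @ (envelopes * carriers) * config.signal_mv

    t_sec = np.arange(n) / rate
    line = perturbation.line_amp_mv * np.sin(
        2 * np.pi * 60.0 * t_sec + rng.uniform(0, 2 * np.pi)
    )
    mv = (
        perturbation.channel_gains[:, None] * activation
        + perturbation.baseline_offset_mv[:, None]
        + line[None, :]
    )
    if perturbation.noise_sd_mv > 0:
        mv = mv + rng.normal(0.0, perturbation.noise_sd_mv, size=(N_CHANNELS, n))

    counts = np.round(mv / (config.adc_gain_v_per_count * 1e3))
    emg = EMGSeries(
        timestamps=np.arange(n) * (1000.0 / rate),
        samples=counts,
        units="counts",
        nominal_rate=rate,
    )

    # jittered kinematic frame stream averaging kin_rate
    dt = (1000.0 / config.kin_rate) * (
        1.0 + rng.uniform(-config.kin_jitter, config.kin_jitter,
                          size=int(np.ceil(total_ms / (1000.0 / config.kin_rate))) + 8)
    )
    kin = np.cumsum(dt) + 1.0
    kin = kin[kin <= emg.timestamps[-1]]

    session = Session(
        session_id=session_id,
        day_index=day_index,
        emg=emg,
        kinematic_times=kin,
        annotations=annotations,
        meta={
            "synthetic": True,
            "adc_gain_v_per_count": config.adc_gain_v_per_count,
            "perturbation": perturbation.to_dict(),
        },
    )
    session.validate()
    return session


def _templates_hash(templates: list[GestureTemplate]) -> str:
    h = hashlib.sha256()
    for t in templates:
        h.update(t.label.encode())
        h.update(np.ascontiguousarray(t.envelopes).tobytes())
    return h.hexdigest()


def make_dataset(
    n_train_sessions: int = 12,
    n_test_sessions: int = 3,
    severity: str = "moderate",
    config: SimConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[list[Session], list[Session]]:
    """Generate a multi-session dataset sharing one gesture-template set.

    Each session receives its own perturbation draw at ``severity``.
    When ``out_dir`` is given, sessions are written in the standard
    layout together with ``sim_truth.yaml`` (template hash and the true
    per-session perturbations, for parameter-recovery checks).
    """
    if n_train_sessions < 1 or n_test_sessions < 0:
        raise ValueError("session counts must be >= 1 train / >= 0 test")
    config = config or SimConfig()
    base = int(seed) % (2 ** 31 - 10_000)
    templates = make_gesture_templates(config, seed=base)

    def _make(tag: str, i: int, k: int) -> Session:
        pert = (SessionPerturbation() if severity == "none"
                else sample_perturbation(severity, seed=base + 1000 + k))
        return synthesize_session(
            templates, pert, config, seed=base + 5000 + k,
            session_id=f"{tag}_{i:02d}", day_index=k,
        )

    train = [_make("train", i, i) for i in range(n_train_sessions)]
    test = [_make("test", i, n_train_sessions + i) for i in range(n_test_sessions)]

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        truth = {
            "templates_sha256": _templates_hash(templates),
            "severity": severity,
            "seed": int(seed),
            "sessions": {},
        }
        for s in train + test:
            write_session(s, out / s.session_id)
            truth["sessions"][s.session_id] = s.meta["perturbation"]
        (out / "sim_truth.yaml").write_text(yaml.safe_dump(truth, sort_keys=True))
    return train, test
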