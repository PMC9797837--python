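"""Windowed dataset construction and leakage-free instance-based splits.

Classifier samples are 8x24 windows of processed (kinematic-rate,
millivolt) EMG, each lying entirely inside one annotated gesture hold.
Because consecutive windows overlap heavily, splitting individual
windows at random would leak near-identical data across train and test.
Splits are therefore made at the level of whole gesture *instances*: an
80/20 split of 10 instances per gesture assigns the first eight
instances of each gesture to training and the last two to test.  Idle
gaps between instances exceed the window duration, so windows from
different instances never share a raw sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_interface import GestureInstance, N_CHANNELS
from .preprocessing import ProcessedSeries

__all__ = [
    "WIN_LEN",
    "REMOVED_GESTURES",
    "INTERACTION_GESTURES",
    "Window",
    "SplitSpec",
    "retain_classes",
    "make_windows",
    "split_by_instance",
    "cv_folds",
    "windows_in_split",
    "window_sample_indices",
    "save_windows",
    "load_windows",
]

log = logging.getLogger("emgrecal.dataset")

WIN_LEN = 24  # kinematic frames per window (~330 ms at ~72 Hz)

#: Gestures excluded from the static-hold classification task.
REMOVED_GESTURES = frozenset({"Nearer", "Further", "Zoom"})

#: Representative 14-gesture interaction set (smartphone/XR-style cues);
#: the three names in ``REMOVED_GESTURES`` are dropped for classification,
#: leaving 11 classes.
INTERACTION_GESTURES = (
    "Tap", "DoubleTap", "SwipeLeft", "SwipeRight", "SwipeUp", "SwipeDown",
    "Grab", "Release", "Rotate", "Point", "Rest",
    "Nearer", "Further", "Zoom",
)


@dataclass
class Window:
    """One 8x24 classifier sample with provenance."""

    values: np.ndarray                 # (8, WIN_LEN) mV
    label: str
    session_id: str
    instance_key: tuple[str, int]
    start_index: int                   # position in the processed series

    def validate(self, win_len: int = WIN_LEN) -> None:
        if self.values.shape != (N_CHANNELS, win_len):
            raise ValueError(f"bad window: shape {self.values.shape}")


@dataclass
class SplitSpec:
    """Disjoint per-class instance assignment to train/val/test."""

    train_instances: set = field(default_factory=set)
    val_instances: set = field(default_factory=set)
    test_instances: set = field(default_factory=set)
    fractions: tuple[float, float, float] = (0.8, 0.0, 0.2)

    def validate(self) -> None:
        parts = [self.train_instances, self.val_instances, self.test_instances]
        for i in range(3):
            for j in range(i + 1, 3):
                if parts[i] & parts[j]:
                    raise ValueError(f"invalid split: overlapping parts {sorted(parts[i] & parts[j])}")

    def part(self, name: str) -> set:
        return {"train": self.train_instances, "val": self.val_instances,
                "test": self.test_instances}[name]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (part, label, idx)
            for part in ("train", "val", "test")
            for (label, idx) in sorted(self.part(part))
        ]
        return pd.DataFrame(rows, columns=["part", "label", "instance_index"])


def retain_classes(
    annotations: list[GestureInstance],
    removed: frozenset[str] | set[str] = REMOVED_GESTURES,
) -> list[GestureInstance]:
    """Drop annotations whose label is in ``removed``; warn on absent labels."""
    present = {a.label for a in annotations}
    for lab in sorted(set(removed) - present):
        log.warning("removed label %r not present in annotations", lab)
    kept = [a for a in annotations if a.label not in removed]
    log.info("retained %d classes (%d removed)",
             len({a.label for a in kept}), len(present & set(removed)))
    return kept


def make_windows(
    series: ProcessedSeries,
    instances: list[GestureInstance],
    win_len: int = WIN_LEN,
    stride: int = 1,
) -> list[Window]:
    """Slide a ``win_len``-frame window (step ``stride``) inside each hold.

    An instance spanning ``n`` processed frames yields
    ``(n - win_len) // stride + 1`` windows (zero when ``n < win_len``).
    Windows never cross instance boundaries.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    t = series.timestamps
    out: list[Window] = []
    for inst in sorted(instances):
        lo = int(np.searchsorted(t, inst.start_ms, side="left"))
        hi = int(np.searchsorted(t, inst.end_ms, side="right"))
        n = hi - lo
        if n < win_len:
            log.debug("instance %s#%d too short (%d frames)", inst.label, inst.instance_index, n)
            continue
        for s in range(lo, hi - win_len + 1, stride):
            out.append(
                Window(
                    values=series.samples[:, s:s + win_len],
                    label=inst.label,
                    session_id=series.session_id,
                    instance_key=inst.key,
                    start_index=s,
                )
            )
    return out


def _part_sizes(n: int, fractions: tuple[float, float, float]) -> list[int]:
    # round-half-up per part, then repair so totals match and non-zero
    # fractions get at least one instance
    raw = [f * n for f in fractions]
    sizes = [int(np.floor(r + 0.5)) for r in raw]
    while sum(sizes) > n:
        sizes[int(np.argmax(sizes))] -= 1
    while sum(sizes) < n:
        sizes[int(np.argmax([r - s for r, s in zip(raw, sizes)]))] += 1
    for i, f in enumerate(fractions):
        if f > 0 and sizes[i] == 0:
            donor = int(np.argmax(sizes))
            sizes[donor] -= 1
            sizes[i] += 1
    return sizes


def split_by_instance(
    instances: list[GestureInstance],
    fractions: tuple[float, float, float] = (0.8, 0.0, 0.2),
) -> SplitSpec:
    """Assign whole instances per class, earliest first, to train/val/test.

    With 10 instances per class and fractions (0.8, 0, 0.2) the first
    eight instances of each class go to training and the last two to
    test.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"invalid split: fractions {fractions} do not sum to 1")
    by_class: dict[str, list[GestureInstance]] = {}
    for a in instances:
        by_class.setdefault(a.label, []).append(a)
    spec = SplitSpec(fractions=tuple(fractions))
    for label, anns in by_class.items():
        anns = sorted(anns, key=lambda a: a.instance_index)
        n_parts = sum(1 for f in fractions if f > 0)
        if len(anns) < n_parts:
            raise ValueError(f"invalid split: class {label!r} has {len(anns)} < {n_parts} instances")
        n_tr, n_va, _ = _part_sizes(len(anns), tuple(fractions))
        for a in anns[:n_tr]:
            spec.train_instances.add(a.key)
        for a in anns[n_tr:n_tr + n_va]:
            spec.val_instances.add(a.key)
        for a in anns[n_tr + n_va:]:
            spec.test_instances.add(a.key)
    spec.validate()
    return spec


def cv_folds(
    instances: list[GestureInstance],
    k: int = 5,
    repeats: int = 2,
    seed: int = 0,
) -> list[SplitSpec]:
    """Repeated instance-based k-fold assignment (k * repeats SplitSpecs).

    Per repeat, each class's instances are shuffled (seeded) and cut
    into ``k`` equal folds; each fold serves as the test part once with
    the remaining instances as training.
    """
    by_class: dict[str, list[GestureInstance]] = {}
    for a in instances:
        by_class.setdefault(a.label, []).append(a)
    for label, anns in by_class.items():
        if len(anns) < k:
            raise ValueError(f"insufficient instances: class {label!r} has {len(anns)} < {k}")
    specs: list[SplitSpec] = []
    for rep in range(repeats):
        rng = np.random.default_rng(seed + rep)
        fold_of: dict[tuple[str, int], int] = {}
        for label in sorted(by_class):
            anns = sorted(by_class[label], key=lambda a: a.instance_index)
            order = rng.permutation(len(anns))
            for pos, j in enumerate(order):
                fold_of[anns[j].key] = pos % k
        for f in range(k):
            spec = SplitSpec(fractions=(1 - 1 / k, 0.0, 1 / k))
            for key, fk in fold_of.items():
                (spec.test_instances if fk == f else spec.train_instances).add(key)
            spec.validate()
            specs.append(spec)
    return specs


def windows_in_split(windows: list[Window], spec: SplitSpec, part: str) -> list[Window]:
    keys = spec.part(part)
    return [w for w in windows if w.instance_key in keys]


def window_sample_indices(windows: list[Window], win_len: int = WIN_LEN) -> set[tuple[str, int]]:
    """All (session_id, processed-frame index) pairs covered by ``windows``."""
    out: set[tuple[str, int]] = set()
    for w in windows:
        for i in range(w.start_index, w.start_index + win_len):
            out.add((w.session_id, i))
    return out


def save_windows(windows: list[Window], path) -> None:
    """Export windows as one array plus a CSV provenance manifest."""
    from pathlib import Path

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arr = np.stack([w.values for w in windows]) if windows else np.zeros((0, N_CHANNELS, WIN_LEN))
    np.savez_compressed(path / "windows.npz", values=arr)
    pd.DataFrame(
        [(w.label, w.session_id, w.instance_key[1], w.start_index) for w in windows],
        columns=["label", "session_id", "instance_index", "start_index"],
    ).to_csv(path / "manifest.csv", index=False)


def load_windows(path) -> list[Window]:
    from pathlib import Path

    path = Path(path)
    arr = np.load(path / "windows.npz")["values"]
    man = pd.read_csv(path / "manifest.csv")
    return [
        Window(arr[i], str(r.label), str(r.session_id), (str(r.label), int(r.instance_index)),
               int(r.start_index))
        for i, r in enumerate(man.itertuples(index=False))
    ]
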