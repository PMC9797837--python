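"""The three training schemes and the recalibration evaluation protocol.

* **Single-session**: train on the first 70% of gesture instances of one
  session, validate on the next 10%, test on the last 20%.
* **Cumulative**: pool the first 80% of instances of every training
  session (last 20% of each as validation) into one backbone; evaluate
  on 100% of each held-out session with no per-session adaptation.
* **Recalibration**: train sessions sequentially; for each session a
  fresh shape-preserving calibrator is trained while the backbone is
  frozen, then the backbone is trained while the calibrator is frozen.
  An unseen session is handled the same two-stage way, using only its
  first 20% of instances (the next 20% drive early stopping); accuracy
  is measured on the final 60%, and the trained backbone itself is
  never mutated (the second stage adapts a per-session clone).

All splits are instance-based (see :mod:`emgrecal.dataset`), so
overlapping windows never straddle split boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from .dataset import (
    SplitSpec, Window, cv_folds, make_windows, retain_classes,
    split_by_instance, windows_in_split,
)
from .io_interface import Session
from .models import (
    AdamOptimizer, BackboneModel, CalibratorModel, ModelConfig,
    build_backbone, build_calibrator, softmax_cross_entropy,
)
from .preprocessing import FilterSpec, preprocess_session

__all__ = [
    "TrainConfig",
    "EvalReport",
    "session_windows",
    "train_single_session",
    "train_cumulative",
    "train_recalibration",
    "fit_test_calibrator",
    "evaluate_recalibration",
    "evaluate_windows",
    "cross_validate_single_session",
    "desk_scale_configs",
    "run_scheme_comparison",
]

log = logging.getLogger("emgrecal.training")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (Adam, lr 0.01, batch 128, early stopping)."""

    optimizer: str = "adam"
    learning_rate: float = 0.01
    batch_size: int = 128
    max_epochs_per_session: int = 40
    early_stopping_patience: int = 5
    seed: int = 0
    grad_clip: float = 5.0   # global grad-norm ceiling; 0 disables
    stride: int = 1
    calibrator_init: str = "identity"
    #: calibrator phases train a tiny shallow network and tolerate (and
    #: need) a hotter optimizer than the recurrent backbone
    calibrator_learning_rate: float = 0.01
    calibration_max_epochs: int = 40
    calibration_patience: int = 8
    #: test-time recalibration mirrors the two training stages: calibrator
    #: with frozen backbone, then backbone with frozen calibrator, both on
    #: the 20% calibration portion; set False for calibrator-only
    adapt_backbone_at_test: bool = True
    #: from-scratch backbone fits occasionally stick in class-merge local
    #: minima at small widths; >1 trains this many seeded initializations
    #: and keeps the one with the best validation loss
    n_restarts: int = 1

    def validate(self) -> None:
        if not (self.learning_rate > 0 and self.batch_size >= 1
                and self.max_epochs_per_session >= 1 and self.stride >= 1):
            raise ValueError(f"invalid training config: {self}")


@dataclass
class EvalReport:
    """Accuracy + confusion matrix for one scheme evaluation."""

    scheme: str
    accuracy: float
    confusion: np.ndarray            # (K, K) counts, rows = true class
    labels: list[str]
    per_session_accuracy: dict[str, float] = field(default_factory=dict)
    folds: list[float] = field(default_factory=list)

    def validate(self) -> None:
        total = self.confusion.sum()
        if total and abs(self.accuracy - np.trace(self.confusion) / total) > 1e-9:
            raise ValueError("accuracy inconsistent with confusion matrix")

    def confusion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.confusion, index=self.labels, columns=self.labels)


# ---------------------------------------------------------------------------
# window plumbing
# ---------------------------------------------------------------------------

def session_windows(
    session: Session,
    stride: int = 1,
    filter_spec: FilterSpec | None = None,
    removed: frozenset[str] | set[str] | None = None,
) -> tuple[list[Window], list]:
    """Preprocess one session and emit its labelled windows + annotations."""
    from .dataset import REMOVED_GESTURES

    removed = REMOVED_GESTURES if removed is None else removed
    key = (stride, filter_spec, frozenset(removed))
    cache = getattr(session, "_window_cache", None)
    if cache is not None and key in cache:
        return cache[key]
    processed = preprocess_session(session, spec=filter_spec)
    annotations = retain_classes(session.annotations, removed)
    windows = make_windows(processed, annotations, stride=stride)
    if cache is None:
        cache = {}
        session._window_cache = cache
    cache[key] = (windows, annotations)
    return windows, annotations


def _to_arrays(windows: list[Window], labels: list[str]):
    idx = {lab: i for i, lab in enumerate(labels)}
    x = np.stack([w.values for w in windows]).astype(np.float32)
    y = np.array([idx[w.label] for w in windows], dtype=np.int64)
    return x, y


def _labels_of(annotation_lists) -> list[str]:
    labs: set[str] = set()
    for anns in annotation_lists:
        labs |= {a.label for a in anns}
    return sorted(labs)


# ---------------------------------------------------------------------------
# core fit loop
# ---------------------------------------------------------------------------

def _clip_grad_norm(grads: list[dict | None], max_norm: float) -> None:
    total = 0.0
    for g in grads:
        if g is None:
            continue
        for v in g.values():
            total += float(np.dot(v.ravel(), v.ravel()))
    norm = np.sqrt(total)
    if norm > max_norm:
        scale = np.float32(max_norm / norm)
        for g in grads:
            if g is None:
                continue
            for v in g.values():
                v *= scale


def _eval_pass(backbone, calibrator, x, y, batch: int = 512):
    losses, correct, n = 0.0, 0, x.shape[0]
    preds = np.empty(n, dtype=np.int64)
    scale = np.float32(backbone.input_scale)
    for s in range(0, n, batch):
        xb = x[s:s + batch] * scale
        if calibrator is not None:
            xb, _ = calibrator.forward(xb)
        probs, _, cache = backbone.forward(xb, train=False, prescaled=True)
        loss, _ = softmax_cross_entropy(cache["logits"], y[s:s + batch])
        losses += loss * xb.shape[0]
        preds[s:s + batch] = probs.argmax(axis=1)
    correct = int((preds == y).sum())
    return losses / max(n, 1), correct / max(n, 1), preds


def _fit(
    backbone: BackboneModel,
    calibrator: CalibratorModel | None,
    x_tr, y_tr, x_va, y_va,
    cfg: TrainConfig,
    rng: np.random.Generator,
    phase: str = "train",
    session_id: str = "",
) -> list[dict]:
    """Minibatch Adam with early stopping on validation loss (restore best).

    Models whose ``frozen`` flag is set are never updated; their
    parameters are bitwise identical before and after.
    """
    cfg.validate()
    models = [backbone] + ([calibrator] if calibrator is not None else [])
    trainable = [m for m in models if not m.frozen]
    calibrator_only = backbone.frozen and calibrator is not None and not calibrator.frozen
    lr = cfg.calibrator_learning_rate if calibrator_only else cfg.learning_rate
    opt = AdamOptimizer(models, lr=lr)
    best_val = np.inf
    best_params = [m.copy_params() for m in trainable]
    patience_left = cfg.early_stopping_patience
    have_val = x_va is not None and x_va.shape[0] > 0
    curve: list[dict] = []
    n = x_tr.shape[0]
    scale = np.float32(backbone.input_scale)

    for epoch in range(cfg.max_epochs_per_session):
        order = rng.permutation(n)
        tr_loss, tr_correct = 0.0, 0
        for s in range(0, n, cfg.batch_size):
            idx = order[s:s + cfg.batch_size]
            xb, yb = x_tr[idx] * scale, y_tr[idx]
            if calibrator is not None:
                xb_c, cal_cache = calibrator.forward(xb)
            else:
                xb_c = xb
            probs, _, cache = backbone.forward(xb_c, train=True, rng=rng,
                                               prescaled=True)
            loss, d_log = softmax_cross_entropy(cache["logits"], yb)
            g_back = None if backbone.frozen else backbone.zero_grads()
            dx = backbone.backward(g_back, d_log, cache)
            grads = [g_back]
            if calibrator is not None:
                if calibrator.frozen:
                    grads.append(None)
                else:
                    g_cal = calibrator.zero_grads()
                    calibrator.backward(g_cal, dx, cal_cache)
                    grads.append(g_cal)
            if cfg.grad_clip > 0:
                _clip_grad_norm(grads, cfg.grad_clip)
            opt.step(grads)
            tr_loss += loss * xb.shape[0]
            tr_correct += int((probs.argmax(axis=1) == yb).sum())

        row = {
            "phase": phase, "session_id": session_id, "epoch": epoch,
            "train_loss": tr_loss / n, "train_acc": tr_correct / n,
            "val_loss": np.nan, "val_acc": np.nan,
        }
        monitor = row["train_loss"]
        if have_val:
            va_loss, va_acc, _ = _eval_pass(backbone, calibrator, x_va, y_va)
            row["val_loss"], row["val_acc"] = va_loss, va_acc
            monitor = va_loss
        curve.append(row)

        if monitor < best_val - 1e-9:
            best_val = monitor
            best_params = [m.copy_params() for m in trainable]
            patience_left = cfg.early_stopping_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break

    for m, p in zip(trainable, best_params):
        m.set_params(p)
    return curve


def _fit_best_restart(model_cfg, labels, x_tr, y_tr, x_va, y_va, cfg, phase):
    """Train ``cfg.n_restarts`` fresh backbones; keep the best by val loss."""
    best = None
    for r in range(max(1, cfg.n_restarts)):
        seed = cfg.seed + 101 * r
        backbone = build_backbone(model_cfg, seed=seed)
        backbone.fit_input_scale(x_tr)
        backbone.class_labels = labels
        rng = np.random.default_rng(seed)
        _fit(backbone, None, x_tr, y_tr, x_va, y_va, cfg, rng, phase=phase)
        loss, _, _ = (_eval_pass(backbone, None, x_va, y_va)
                      if x_va.shape[0] else _eval_pass(backbone, None, x_tr, y_tr))
        if best is None or loss < best[0]:
            best = (loss, backbone)
    return best[1]


def evaluate_windows(
    backbone: BackboneModel,
    calibrator: CalibratorModel | None,
    windows: list[Window],
    labels: list[str],
    scheme: str = "eval",
) -> EvalReport:
    """Accuracy + confusion matrix of a model on labelled windows."""
    x, y = _to_arrays(windows, labels)
    _, acc, preds = _eval_pass(backbone, calibrator, x, y)
    k = len(labels)
    confusion = np.zeros((k, k), dtype=np.int64)
    np.add.at(confusion, (y, preds), 1)
    report = EvalReport(scheme=scheme, accuracy=acc, confusion=confusion, labels=labels)
    report.validate()
    return report


# ---------------------------------------------------------------------------
# scheme 1: single session
# ---------------------------------------------------------------------------

def train_single_session(
    session: Session,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
    filter_spec: FilterSpec | None = None,
    split: SplitSpec | None = None,
) -> tuple[BackboneModel, EvalReport]:
    """Train and evaluate a backbone on one session (70/10/20 by default).

    ``fractions=(0.2, 0.2, 0.6)`` gives the calibration-budget baseline
    used to contextualize test-time recalibration.  An explicit
    ``split`` (e.g. a CV fold) overrides ``fractions``.
    """
    windows, annotations = session_windows(session, stride=train_cfg.stride,
                                           filter_spec=filter_spec)
    labels = _labels_of([annotations])
    if len(windows) == 0 or any(
        sum(1 for a in annotations if a.label == lab) < sum(f > 0 for f in fractions)
        for lab in labels
    ):
        raise ValueError("insufficient data: too few instances per class")
    model_cfg = dc_replace(model_cfg, n_classes=len(labels))
    spec = split if split is not None else split_by_instance(annotations, fractions)

    tr = windows_in_split(windows, spec, "train")
    va = windows_in_split(windows, spec, "val")
    te = windows_in_split(windows, spec, "test")
    x_tr, y_tr = _to_arrays(tr, labels)
    x_va, y_va = _to_arrays(va, labels) if va else (np.zeros((0,) + x_tr.shape[1:], np.float32),
                                                   np.zeros(0, np.int64))

    backbone = _fit_best_restart(model_cfg, labels, x_tr, y_tr, x_va, y_va,
                                 train_cfg, phase="single")

    report = evaluate_windows(backbone, None, te, labels, scheme="single")
    report.per_session_accuracy[session.session_id] = report.accuracy
    return backbone, report


def cross_validate_single_session(
    session: Session,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    k: int = 5,
    repeats: int = 2,
) -> EvalReport:
    """Repeated instance-based k-fold CV of the single-session scheme."""
    _, annotations = session_windows(session, stride=train_cfg.stride)
    folds = cv_folds(annotations, k=k, repeats=repeats, seed=train_cfg.seed)
    accs, last = [], None
    for spec in folds:
        _, rep = train_single_session(session, model_cfg, train_cfg, split=spec)
        accs.append(rep.accuracy)
        last = rep
    report = EvalReport(
        scheme="single_cv", accuracy=float(np.mean(accs)), confusion=last.confusion,
        labels=last.labels, folds=accs,
        per_session_accuracy={session.session_id: float(np.mean(accs))},
    )
    return report


# ---------------------------------------------------------------------------
# scheme 2: cumulative
# ---------------------------------------------------------------------------

def train_cumulative(
    train_sessions: list[Session],
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    test_sessions: list[Session] | None = None,
) -> tuple[BackboneModel, EvalReport]:
    """Pool the 80% portions of every training session into one backbone.

    Held-out sessions are evaluated on *all* of their windows with no
    per-session adaptation.
    """
    if not train_sessions:
        raise ValueError("insufficient data: empty training set")
    per_sess = [session_windows(s, stride=train_cfg.stride) for s in train_sessions]
    labels = _labels_of([anns for _, anns in per_sess])
    model_cfg = dc_replace(model_cfg, n_classes=len(labels))

    tr_windows: list[Window] = []
    va_windows: list[Window] = []
    for (windows, annotations) in per_sess:
        spec = split_by_instance(annotations, (0.8, 0.2, 0.0))
        tr_windows += windows_in_split(windows, spec, "train")
        va_windows += windows_in_split(windows, spec, "val")

    x_tr, y_tr = _to_arrays(tr_windows, labels)
    x_va, y_va = _to_arrays(va_windows, labels)
    backbone = _fit_best_restart(model_cfg, labels, x_tr, y_tr, x_va, y_va,
                                 train_cfg, phase="cumulative")

    per_session: dict[str, float] = {}
    confusion = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for sess in test_sessions or []:
        windows, _ = session_windows(sess, stride=train_cfg.stride)
        rep = evaluate_windows(backbone, None, windows, labels, scheme="cumulative")
        per_session[sess.session_id] = rep.accuracy
        confusion += rep.confusion
    total = confusion.sum()
    acc = float(np.trace(confusion) / total) if total else float("nan")
    report = EvalReport(scheme="cumulative", accuracy=acc, confusion=confusion,
                        labels=labels, per_session_accuracy=per_session)
    return backbone, report


# ---------------------------------------------------------------------------
# scheme 3: recalibration
# ---------------------------------------------------------------------------

def train_recalibration(
    train_sessions: list[Session],
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
) -> tuple[BackboneModel, dict[str, CalibratorModel], pd.DataFrame]:
    """Alternating-freeze training over sessions in chronological order.

    Per session: a fresh calibrator is trained with the backbone frozen,
    then the backbone is trained with the calibrator frozen, both on the
    session's 80/20 instance split.  Returns the backbone, per-session
    calibrators, and the epoch-level training curve with session/phase
    markers.
    """
    if len(train_sessions) < 1:
        raise ValueError("insufficient data: no training sessions")
    order = sorted(train_sessions, key=lambda s: (s.day_index, s.session_id))
    per_sess = {s.session_id: session_windows(s, stride=train_cfg.stride) for s in order}
    labels = _labels_of([anns for _, anns in per_sess.values()])
    model_cfg = dc_replace(model_cfg, n_classes=len(labels))

    all_tr = np.concatenate([
        _to_arrays(windows_in_split(w, split_by_instance(a, (0.8, 0.2, 0.0)), "train"),
                   labels)[0]
        for (w, a) in per_sess.values()
    ])
    backbone = build_backbone(model_cfg, seed=train_cfg.seed)
    backbone.fit_input_scale(all_tr)
    backbone.class_labels = labels
    rng = np.random.default_rng(train_cfg.seed)

    calibrators: dict[str, CalibratorModel] = {}
    curve_rows: list[dict] = []
    for si, sess in enumerate(order):
        windows, annotations = per_sess[sess.session_id]
        spec = split_by_instance(annotations, (0.8, 0.2, 0.0))
        x_tr, y_tr = _to_arrays(windows_in_split(windows, spec, "train"), labels)
        x_va, y_va = _to_arrays(windows_in_split(windows, spec, "val"), labels)

        calibrator = build_calibrator(model_cfg, seed=train_cfg.seed + si + 1,
                                      init=train_cfg.calibrator_init)
        backbone.frozen, calibrator.frozen = True, False
        rows = _fit(backbone, calibrator, x_tr, y_tr, x_va, y_va, train_cfg,
                    rng, phase="calibrator", session_id=sess.session_id)
        for j, r in enumerate(rows):
            r["session_switch"] = (j == 0)
        curve_rows += rows

        backbone.frozen, calibrator.frozen = False, True
        rows = _fit(backbone, calibrator, x_tr, y_tr, x_va, y_va, train_cfg,
                    rng, phase="backbone", session_id=sess.session_id)
        for r in rows:
            r["session_switch"] = False
        curve_rows += rows
        backbone.frozen = False
        calibrators[sess.session_id] = calibrator
        log.info("recalibration: finished session %s (%d/%d)",
                 sess.session_id, si + 1, len(order))

    return backbone, calibrators, pd.DataFrame(curve_rows)


def fit_test_calibrator(
    backbone: BackboneModel,
    test_session: Session,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
) -> tuple[CalibratorModel, SplitSpec, list[Window], BackboneModel]:
    """Rapid recalibration on the first 20% of an unseen session.

    Mirrors the two training stages: a fresh calibrator is trained with
    the backbone frozen, then (``adapt_backbone_at_test``) a *clone* of
    the backbone is fine-tuned with the calibrator frozen.  The next 20%
    of instances drive early stopping; the final 60% are left untouched
    for evaluation.  The caller's backbone is never mutated: its
    parameters are bitwise identical before and after.  Returns the
    calibrator, the split, the session windows and the (possibly
    adapted) backbone to evaluate with.
    """
    labels = backbone.class_labels
    windows, annotations = session_windows(test_session, stride=train_cfg.stride)
    if any(sum(1 for a in annotations if a.label == lab) < 3 for lab in labels):
        raise ValueError("insufficient instances for a 20/20/60 split")
    spec = split_by_instance(annotations, (0.2, 0.2, 0.6))

    x_tr, y_tr = _to_arrays(windows_in_split(windows, spec, "train"), labels)
    x_va, y_va = _to_arrays(windows_in_split(windows, spec, "val"), labels)
    calibrator = build_calibrator(
        dc_replace(model_cfg, n_classes=len(labels)),
        seed=train_cfg.seed, init=train_cfg.calibrator_init,
    )
    rng = np.random.default_rng(train_cfg.seed)
    cal_cfg = dc_replace(train_cfg,
                         max_epochs_per_session=train_cfg.calibration_max_epochs,
                         early_stopping_patience=train_cfg.calibration_patience)
    local = backbone.clone()
    local.frozen, calibrator.frozen = True, False
    _fit(local, calibrator, x_tr, y_tr, x_va, y_va, cal_cfg,
         rng, phase="recal_eval_cal", session_id=test_session.session_id)
    if train_cfg.adapt_backbone_at_test:
        local.frozen, calibrator.frozen = False, True
        _fit(local, calibrator, x_tr, y_tr, x_va, y_va, cal_cfg,
             rng, phase="recal_eval_backbone", session_id=test_session.session_id)
    local.frozen, calibrator.frozen = False, False
    return calibrator, spec, windows, local


def evaluate_recalibration(
    backbone: BackboneModel,
    test_session: Session,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
) -> EvalReport:
    """Rapid test-time recalibration on an unseen session.

    A fresh calibrator is trained on the first 20% of instances (next
    20% drive early stopping) with the backbone frozen; accuracy and the
    confusion matrix come from the final 60% of instances, which the
    model never sees during calibration.
    """
    calibrator, spec, windows, adapted = fit_test_calibrator(
        backbone, test_session, model_cfg, train_cfg
    )
    te = windows_in_split(windows, spec, "test")
    report = evaluate_windows(adapted, calibrator, te, backbone.class_labels,
                              scheme="recal")
    report.per_session_accuracy[test_session.session_id] = report.accuracy
    return report


# ---------------------------------------------------------------------------
# bundled desk-scale study
# ---------------------------------------------------------------------------

def desk_scale_configs(seed: int = 0) -> tuple[ModelConfig, TrainConfig]:
    """CPU-scale model/optimizer settings used by the bundled synthetic study.

    Relative to the full-size defaults, the recurrent width is halved
    (32 units per direction), dropout is removed (the small model
    underfits rather than overfits at this scale), the learning rate is
    lowered to 3e-3, windows are strided by 2 frames, and epochs per
    session are capped at 8 with early stopping.  See the methods note
    for the reasoning.
    """
    model_cfg = ModelConfig(bilstm_hidden=32, fc_hidden=16, dropout=0.0)
    train_cfg = TrainConfig(learning_rate=0.003, max_epochs_per_session=8,
                            early_stopping_patience=3, stride=2, seed=seed)
    return model_cfg, train_cfg


def run_scheme_comparison(
    n_train_sessions: int = 12,
    n_test_sessions: int = 3,
    severity: str = "moderate",
    seeds: tuple[int, ...] = (0,),
    sim_cfg=None,
    model_cfg: ModelConfig | None = None,
    train_cfg: TrainConfig | None = None,
    with_latent: bool = False,
    schemes: tuple[str, ...] = ("recal", "cumulative", "single_budget"),
) -> pd.DataFrame:
    """Run the three training schemes end to end on synthetic data.

    Per seed, a fresh multi-session dataset is generated; the schemes
    are then compared on the held-out test sessions:

    * ``cumulative``   - pooled backbone, no adaptation;
    * ``recal``        - alternating-freeze backbone + per-session test
      calibrator trained on the first 20% of instances;
    * ``single_budget``- a fresh backbone trained only on that same 20%
      calibration budget.

    All three schemes are scored on the same final 60% of instances of
    each test session.  Returns one row per (seed, scheme, session)
    with accuracy and (optionally) the bottleneck silhouette score.
    """
    from .synthetic_data import SimConfig, make_dataset

    sim_cfg = sim_cfg or SimConfig()
    rows: list[dict] = []
    for seed in seeds:
        mc, tc = desk_scale_configs(seed)
        if model_cfg is not None:
            mc = model_cfg
        if train_cfg is not None:
            tc = dc_replace(train_cfg, seed=seed)
        train_sessions, test_sessions = make_dataset(
            n_train_sessions, n_test_sessions, severity, sim_cfg, seed=seed
        )

        bb_cum, rep_cum = train_cumulative(train_sessions, mc, tc,
                                           test_sessions=test_sessions)
        bb_rec, _cals, _curve = train_recalibration(train_sessions, mc, tc)

        for sess in test_sessions:
            calibrator, spec, windows, bb_adapted = fit_test_calibrator(
                bb_rec, sess, mc, tc)
            te = windows_in_split(windows, spec, "test")
            labels = bb_rec.class_labels
            rep_r = evaluate_windows(bb_adapted, calibrator, te, labels, scheme="recal")
            rep_c = evaluate_windows(bb_cum, None, te, bb_cum.class_labels,
                                     scheme="cumulative")
            bb_single = rep_s = None
            if "single_budget" in schemes:
                bb_single, rep_s = train_single_session(
                    sess, mc, tc, fractions=(0.2, 0.2, 0.6)
                )

            sil_r = sil_s = np.nan
            if with_latent:
                from .latent_analysis import extract_bottleneck, separability_score

                emb_r = extract_bottleneck(bb_adapted, calibrator, te, scheme="recal")
                sil_r = separability_score(emb_r)
                if bb_single is not None:
                    emb_s = extract_bottleneck(bb_single, None, te, scheme="single")
                    sil_s = separability_score(emb_s)

            for scheme, rep, sil in (("recal", rep_r, sil_r),
                                     ("cumulative", rep_c, np.nan),
                                     ("single_budget", rep_s, sil_s)):
                if scheme not in schemes or rep is None:
                    continue
                rows.append({
                    "seed": seed, "scheme": scheme, "session_id": sess.session_id,
                    "accuracy": rep.accuracy, "silhouette": sil,
                    "n_test_windows": int(rep.confusion.sum()),
                })
            log.info("seed %d session %s: %s", seed, sess.session_id,
                     {r["scheme"]: round(r["accuracy"], 3)
                      for r in rows if r["session_id"] == sess.session_id
                      and r["seed"] == seed})
    return pd.DataFrame(rows)
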