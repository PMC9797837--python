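"""Training-scheme behavior on small synthetic datasets.

These tests exercise real end-to-end training and are sized to finish
in tens of seconds each: 3-4 gestures, a handful of sessions, the
CPU-scale model from :func:`emgrecal.training.desk_scale_configs`.
"""

from dataclasses import replace

import numpy as np
import pytest

from emgrecal import (
    SessionPerturbation, SimConfig, make_dataset, make_gesture_templates,
    synthesize_session,
)
from emgrecal.dataset import split_by_instance, windows_in_split
from emgrecal.training import (
    _fit, _to_arrays, cross_validate_single_session, desk_scale_configs,
    evaluate_recalibration, session_windows, train_cumulative,
    train_recalibration, train_single_session,
)

MC, TC = desk_scale_configs(0)


@pytest.fixture(scope="module")
def separable_session():
    """Zero-noise session with well-separated (near-orthogonal) templates."""
    cfg = SimConfig(template_min_dist=0.9)
    templates = make_gesture_templates(cfg, seed=0)
    return cfg, synthesize_session(
        templates, SessionPerturbation(noise_sd_mv=0.0), cfg, seed=1,
        session_id="sep00",
    )


class TestSingleSession:
    def test_separable_session_reaches_high_accuracy(self, separable_session):
        """On noise-free, well-separated data the scheme should approach the
        nearest-template oracle (which is ~perfect here)."""
        _, sess = separable_session
        tc = replace(TC, stride=1, max_epochs_per_session=60,
                     early_stopping_patience=10)
        # oracle: nearest class centroid on log per-channel window RMS
        windows, anns = session_windows(sess, stride=1)
        labels = sorted({a.label for a in anns})
        spec = split_by_instance(anns, (0.7, 0.1, 0.2))
        xtr, ytr = _to_arrays(windows_in_split(windows, spec, "train"), labels)
        xte, yte = _to_arrays(windows_in_split(windows, spec, "test"), labels)
        feats = lambda x: np.log(np.sqrt((x ** 2).mean(axis=2)) + 1e-12)
        cent = np.stack([feats(xtr)[ytr == k].mean(axis=0) for k in range(len(labels))])
        oracle = (np.argmin(((feats(xte)[:, None] - cent[None]) ** 2).sum(-1), axis=1)
                  == yte).mean()
        assert oracle >= 0.95

        _, report = train_single_session(sess, MC, tc)
        assert report.accuracy >= 0.9

    def test_permuted_labels_give_chance_accuracy(self, separable_session):
        _, sess = separable_session
        labels = sorted({a.label for a in sess.annotations})
        # relabel instances uniformly at random: breaks the label-signal
        # link, so nothing generalizes to held-out instances
        rng2 = np.random.default_rng(1)
        randomized = sess.with_annotations([
            replace(a, label=str(rng2.choice(labels)), instance_index=i + 1)
            for i, a in enumerate(sess.annotations)
        ])
        tc = replace(TC, max_epochs_per_session=4, early_stopping_patience=4)
        _, report = train_single_session(randomized, MC, tc)
        assert report.accuracy == pytest.approx(1 / 6, abs=0.12)

    def test_split_parts_share_no_instance(self, separable_session):
        _, sess = separable_session
        spec = split_by_instance(sess.annotations, (0.7, 0.1, 0.2))
        spec.validate()
        assert spec.train_instances and spec.val_instances and spec.test_instances

    def test_cross_validation_folds_average(self, small_sim_config, small_templates):
        sess = synthesize_session(small_templates, SessionPerturbation(),
                                  small_sim_config, seed=2)
        mc = replace(MC, bilstm_hidden=4, fc_hidden=4)
        tc = replace(TC, max_epochs_per_session=1, early_stopping_patience=1)
        report = cross_validate_single_session(sess, mc, tc, k=4, repeats=1)
        assert len(report.folds) == 4
        assert report.accuracy == pytest.approx(np.mean(report.folds))


class TestCumulative:
    def test_more_matched_data_beats_single_session(self):
        """With zero inter-session perturbation, a backbone pooled over
        several sessions should match or beat one trained on a single
        session, on the same held-out windows (3 seeds)."""
        cfg = SimConfig(n_gestures=4, n_instances_per_gesture=6, hold_ms=700.0,
                        idle_gap_ms=400.0)
        tc = replace(TC, max_epochs_per_session=5, early_stopping_patience=5)
        cum_accs, single_accs = [], []
        for seed in (0, 1, 2):
            train, test = make_dataset(2, 1, "none", cfg, seed=seed)
            _, rep_c = train_cumulative(train, MC, replace(tc, seed=seed),
                                        test_sessions=test)
            _, rep_s = train_single_session(test[0], MC, replace(tc, seed=seed))
            cum_accs.append(rep_c.accuracy)
            single_accs.append(rep_s.accuracy)
        assert np.mean(cum_accs) >= np.mean(single_accs) - 0.02

    def test_evaluation_consumes_all_heldout_windows(self, small_sim_config):
        train, test = make_dataset(2, 1, "none", small_sim_config, seed=3)
        mc = replace(MC, bilstm_hidden=4, fc_hidden=4)
        tc = replace(TC, max_epochs_per_session=1, early_stopping_patience=1)
        _, report = train_cumulative(train, mc, tc, test_sessions=test)
        expected = len(session_windows(test[0], stride=tc.stride)[0])
        assert int(report.confusion.sum()) == expected

    def test_single_training_session_degenerates_to_80_20(self, small_sim_config):
        train, _ = make_dataset(1, 0, "none", small_sim_config, seed=4)
        mc = replace(MC, bilstm_hidden=4, fc_hidden=4)
        tc = replace(TC, max_epochs_per_session=1, early_stopping_patience=1)
        backbone, report = train_cumulative(train, mc, tc)
        assert backbone.n_params() > 0
        assert np.isnan(report.accuracy)  # no held-out sessions to score

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="insufficient data"):
            train_cumulative([], MC, TC)


class TestRecalibration:
    @pytest.fixture(scope="class")
    def recal_run(self):
        cfg = SimConfig(n_gestures=4, n_instances_per_gesture=5, hold_ms=700.0,
                        idle_gap_ms=400.0)
        train, test = make_dataset(5, 1, "moderate", cfg, seed=5)
        mc = replace(MC, bilstm_hidden=16, fc_hidden=8)
        tc = replace(TC, max_epochs_per_session=6, early_stopping_patience=6,
                     calibration_max_epochs=8, calibration_patience=4)
        backbone, calibrators, curve = train_recalibration(train, mc, tc)
        return train, test, mc, tc, backbone, calibrators, curve

    def test_one_calibrator_per_session_with_phase_markers(self, recal_run):
        train, _, _, _, _, calibrators, curve = recal_run
        assert set(calibrators) == {s.session_id for s in train}
        assert set(curve["phase"]) == {"calibrator", "backbone"}
        assert curve["session_switch"].sum() == len(train)

    def test_accuracy_drops_at_session_switches(self, recal_run):
        """When an unseen perturbed session arrives, training accuracy on it
        starts below the previous session's plateau for most switches."""
        _, _, _, _, _, _, curve = recal_run
        bb = curve[curve["phase"] == "backbone"]
        plateaus = bb.groupby("session_id", sort=False)["train_acc"].last()
        cal_first = (curve[curve["phase"] == "calibrator"]
                     .groupby("session_id", sort=False)["train_acc"].first())
        sessions = list(plateaus.index)
        drops = [
            cal_first[sessions[k + 1]] < plateaus[sessions[k]]
            for k in range(len(sessions) - 1)
        ]
        assert sum(drops) >= len(drops) - 1

    def test_evaluation_leaves_trained_backbone_untouched(self, recal_run):
        _, test, mc, tc, backbone, _, _ = recal_run
        before = {k: v.tobytes() for k, v in backbone.params.items()}
        report = evaluate_recalibration(backbone, test[0], mc, tc)
        after = {k: v.tobytes() for k, v in backbone.params.items()}
        assert before == after
        assert 0.0 <= report.accuracy <= 1.0

    def test_calibration_validation_evaluation_disjoint(self, recal_run):
        _, test, _, _, _, _, _ = recal_run
        spec = split_by_instance(test[0].annotations, (0.2, 0.2, 0.6))
        spec.validate()
        per_class = {}
        for (lab, _idx) in spec.test_instances:
            per_class[lab] = per_class.get(lab, 0) + 1
        assert all(n >= 3 for n in per_class.values())  # ~60% of 6 instances


class TestEarlyStopping:
    def test_restored_checkpoint_has_minimal_validation_loss(self):
        from emgrecal.models import build_backbone
        from emgrecal.training import _eval_pass

        rng = np.random.default_rng(0)
        x = rng.normal(size=(300, 8, 24)).astype(np.float32)
        y = rng.integers(0, 3, 300)
        mc = replace(MC, n_classes=3, bilstm_hidden=4, fc_hidden=4)
        bb = build_backbone(mc, seed=0)
        bb.class_labels = ["a", "b", "c"]
        tc = replace(TC, max_epochs_per_session=8, early_stopping_patience=2)
        curve = _fit(bb, None, x[:200], y[:200], x[200:], y[200:], tc,
                     np.random.default_rng(0))
        restored_loss, _, _ = _eval_pass(bb, None, x[200:], y[200:])
        best_seen = min(r["val_loss"] for r in curve)
        assert restored_loss <= best_seen + 1e-6
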