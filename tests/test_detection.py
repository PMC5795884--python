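"""Training-set assembly, grid-search SVM, event declaration and scoring."""

import numpy as np
import pytest

from earseiz.detection import (
    DetectionEvents,
    PatientPerformance,
    PatientRecords,
    PerformanceReport,
    SvmConfig,
    build_training_set,
    channel_subset_comparison,
    classify_windows,
    compare_reports_wilcoxon,
    declare_events,
    grid_search_train,
    loo_evaluate,
    score_epoch,
)
from earseiz.montage import MultichannelSignal, PatientMetadata, SeizureAnnotation
from earseiz.preprocess import AnnotatedEpoch

FS = 250.0
SMALL_GRID = SvmConfig(c_grid=(1.0, 100.0), sigma_grid=(1.0, 10.0), seed=0)


def make_epoch(duration_s, annotations=(), seed=0, n_channels=1, ictal_amp=0.0):
    """Epoch of pink-ish noise, optionally with a 4 Hz rhythm inside annotations."""
    rng = np.random.default_rng(seed)
    n = int(duration_s * FS)
    data = rng.normal(0, 5.0, (n_channels, n))
    t = np.arange(n) / FS
    for ann in annotations:
        mask = (t >= ann.onset_s) & (t < ann.end_s)
        data[:, mask] += ictal_amp * np.sin(2 * np.pi * 4.0 * t[mask])
    sig = MultichannelSignal(FS, [f"ch{i}" for i in range(n_channels)], data)
    cls = "seizure" if annotations else "non_seizure"
    return AnnotatedEpoch(sig, list(annotations), cls)


def make_patient(pid=1, n_seizures=3, seed=0, ictal_amp=40.0, focus_side="right"):
    seiz = [
        make_epoch(
            60.0, [SeizureAnnotation(20.0, 40.0)], seed=seed + i, ictal_amp=ictal_amp,
            n_channels=2,
        )
        for i in range(n_seizures)
    ]
    nonseiz = [
        make_epoch(60.0, seed=seed + 100 + i, n_channels=2) for i in range(2)
    ]
    meta = PatientMetadata(pid, n_seizures, "F", 30.0, focus_side, "temporal", 1.0)
    return PatientRecords(pid, seiz, nonseiz, meta)


class TestTrainingSet:
    def test_positive_window_count(self):
        patient = make_patient(n_seizures=8)
        x, y, test_epoch = build_training_set(
            patient.seizure_epochs, patient.nonseizure_epochs, 2
        )
        assert np.sum(y == 1) == 7 * 3  # 6 s / 2 s = 3 windows per training seizure
        assert np.sum(y == -1) == 2 * 30  # all windows of two 60 s epochs
        assert test_epoch is patient.seizure_epochs[2]

    def test_single_seizure_patient_trains_on_its_own_onset(self):
        patient = make_patient(n_seizures=1)
        x, y, test_epoch = build_training_set(
            patient.seizure_epochs, patient.nonseizure_epochs, 0
        )
        assert np.sum(y == 1) == 3
        assert test_epoch is patient.seizure_epochs[0]

    def test_out_of_range_heldout_rejected(self):
        patient = make_patient(n_seizures=2)
        with pytest.raises(IndexError):
            build_training_set(
                patient.seizure_epochs, patient.nonseizure_epochs, 5
            )


class TestGridSearch:
    def _separable(self, rng, n=60, d=8, dist=10.0):
        x = np.vstack(
            [rng.normal(0, 1, (n, d)), rng.normal(dist, 1, (n, d))]
        )
        y = np.concatenate([-np.ones(n), np.ones(n)])
        return x, y

    def test_separable_classes_reach_zero_error(self, rng):
        x, y = self._separable(rng)
        model = grid_search_train(x, y, SvmConfig(seed=0))
        assert model.inner_error == 0.0
        assert np.array_equal(model.predict(x), y)

    def test_duplicate_grid_values_deduplicated(self, rng):
        x, y = self._separable(rng, n=20)
        cfg = SvmConfig(c_grid=(1.0, 1.0, 1.0), sigma_grid=(1.0, 1.0), seed=0)
        model = grid_search_train(x, y, cfg)
        assert (model.c, model.sigma) == (1.0, 1.0)

    def test_deterministic_under_seed(self, rng):
        x = rng.normal(size=(80, 6))
        y = np.sign(x[:, 0] + 0.3 * rng.normal(size=80))
        y[y == 0] = 1
        a = grid_search_train(x, y, SMALL_GRID)
        b = grid_search_train(x, y, SMALL_GRID)
        assert (a.c, a.sigma, a.inner_error) == (b.c, b.sigma, b.inner_error)
        assert np.array_equal(a.decision_function(x), b.decision_function(x))

    def test_single_class_rejected(self, rng):
        x = rng.normal(size=(20, 3))
        with pytest.raises(ValueError):
            grid_search_train(x, np.ones(20), SMALL_GRID)

    def test_classification_handles_degenerate_rows(self, rng):
        x, y = self._separable(rng, n=30)
        model = grid_search_train(x, y, SMALL_GRID)
        out = classify_windows(model, np.zeros((4, x.shape[1])))
        assert set(out) <= {-1, 1}

    def test_permuting_windows_permutes_labels(self, rng):
        x, y = self._separable(rng, n=30)
        model = grid_search_train(x, y, SMALL_GRID)
        perm = rng.permutation(len(x))
        assert np.array_equal(classify_windows(model, x)[perm],
                              classify_windows(model, x[perm]))


class TestEvents:
    def test_run_rules(self):
        times = np.arange(4) * 2.0
        ev = declare_events([-1, 1, 1, -1], times)
        assert ev.events == [(2.0, 6.0)]
        assert declare_events([1, -1, 1], np.arange(3) * 2.0).events == []

    def test_nearby_runs_merge(self):
        labels = [1, 1, -1, -1, -1, -1, -1, 1, 1]  # runs 10 s apart
        times = np.arange(9) * 2.0
        ev = declare_events(labels, times, merge_gap_s=30.0)
        assert ev.events == [(0.0, 18.0)]
        ev2 = declare_events(labels, times, merge_gap_s=5.0)
        assert len(ev2.events) == 2

    def test_min_consecutive_monotonicity(self, rng):
        labels = rng.choice([-1, 1], size=200)
        times = np.arange(200) * 2.0
        counts = [
            len(declare_events(labels, times, min_consecutive=k, merge_gap_s=0.0).events)
            for k in range(1, 6)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestScoring:
    ANN = [SeizureAnnotation(100.0, 160.0)]

    def test_overlapping_event_detects(self):
        ev = DetectionEvents([(110.0, 130.0)])
        assert score_epoch(ev, self.ANN) == {"detected": True, "n_false": 0}

    def test_extra_event_counts_false(self):
        ev = DetectionEvents([(110.0, 130.0), (300.0, 310.0)])
        assert score_epoch(ev, self.ANN) == {"detected": True, "n_false": 1}

    def test_no_events(self):
        assert score_epoch(DetectionEvents([]), self.ANN) == {
            "detected": False, "n_false": 0
        }

    def test_matches_bruteforce_recount(self, rng):
        for _ in range(50):
            anns = [
                SeizureAnnotation(float(o), float(o + rng.uniform(5, 50)))
                for o in rng.uniform(0, 500, rng.integers(1, 4))
            ]
            events = DetectionEvents(
                [
                    (float(s), float(s + rng.uniform(2, 40)))
                    for s in np.sort(rng.uniform(0, 600, rng.integers(0, 6)))
                ]
            )
            got = score_epoch(events, anns)
            detected = False
            n_false = 0
            for s, e in events.events:
                hit = False
                for a in anns:
                    if not (e < a.onset_s or s > a.end_s):
                        hit = True
                if hit:
                    detected = True
                else:
                    n_false += 1
            assert got == {"detected": detected, "n_false": n_false}


class TestLooEvaluate:
    def test_high_snr_patient_fully_detected(self):
        patient = make_patient(n_seizures=3, ictal_amp=40.0)
        perf = loo_evaluate(patient, svm_cfg=SMALL_GRID)
        assert perf.sensitivity_pct == 100.0
        assert perf.fdr_per_hour == 0.0
        assert len(perf.events_per_seizure) == 3

    def test_report_shapes_and_single_seizure_flag(self):
        patient = make_patient(n_seizures=1)
        perf = loo_evaluate(patient, svm_cfg=SMALL_GRID)
        assert perf.single_seizure_protocol
        assert perf.n_seizures == 1

    def test_all_negative_labels_score_zero(self):
        ev = declare_events(-np.ones(100), np.arange(100) * 2.0)
        score = score_epoch(ev, [SeizureAnnotation(10.0, 20.0)])
        assert score == {"detected": False, "n_false": 0}


class TestReportComparison:
    def _report(self, label, sens, fdr):
        per = [
            PatientPerformance(
                patient_id=i + 1, n_seizures=2, n_detected=int(round(2 * s / 100)),
                n_false=int(f), tested_hours=1.0,
            )
            for i, (s, f) in enumerate(zip(sens, fdr))
        ]
        return PerformanceReport(label, per)

    def test_identical_reports_p_one(self):
        a = self._report("a", [100, 50, 100, 0, 100], [0, 1, 2, 0, 1])
        b = self._report("b", [100, 50, 100, 0, 100], [0, 1, 2, 0, 1])
        res = compare_reports_wilcoxon(a, b)
        assert res == {"p_sensitivity": 1.0, "p_fdr": 1.0}

    def test_one_signed_differences_exact_p(self):
        sens_a = [100.0] * 12
        sens_b = [50.0] * 12
        a = self._report("a", sens_a, [0] * 12)
        b = self._report("b", sens_b, [0] * 12)
        res = compare_reports_wilcoxon(a, b)
        assert res["p_sensitivity"] == pytest.approx(2 * 0.5**12)

    def test_mismatched_patient_sets_rejected(self):
        a = self._report("a", [100, 100], [0, 0])
        b = self._report("b", [100, 100, 100], [0, 0, 0])
        with pytest.raises(ValueError):
            compare_reports_wilcoxon(a, b)

    def test_aggregate_statistics(self):
        rep = self._report("a", [0.0, 100.0, 100.0], [0, 0, 0])
        agg = rep.aggregate()
        assert agg["sensitivity"]["median"] == 100.0
        assert agg["sensitivity"]["mean"] == pytest.approx(200.0 / 3)


class TestChannelSubset:
    def test_focus_side_maps_roles(self):
        from earseiz.detection import _role_channel

        assert _role_channel("ipsilateral", "right") == "RT-RC"
        assert _role_channel("contralateral", "right") == "LT-LC"
        assert _role_channel("ipsilateral", "left") == "LT-LC"
        assert _role_channel("cross_head_1", "left") == "LC-RC"

    def test_missing_focus_side_rejected(self):
        patient = make_patient()
        patient.metadata = None
        with pytest.raises(ValueError):
            channel_subset_comparison([patient], SMALL_GRID)
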