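"""Patient-specific seizure detection with an RBF-SVM.

Training follows the leave-one-seizure-out protocol: for each withheld
seizure, the classifier trains on the 2 s windows from the first six
seconds of every *other* seizure (positives) plus every window of the
non-seizure epochs (negatives), picks the penalty ``c`` and Gaussian
kernel width ``sigma`` by inner cross-validation over a log grid spanning
[1e-3, 1e3], and is then applied to the withheld seizure epoch.  Runs of
consecutive positive windows are declared as events; sensitivity is the
fraction of seizures whose epoch produced an overlapping event, and the
false-detection rate counts non-overlapping events per tested epoch hour.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .features import FeatureConfig, FeatureMatrix, build_feature_matrix
from .montage import PatientMetadata, SeizureAnnotation
from .preprocess import AnnotatedEpoch
from .stats import signed_rank_test

__all__ = [
    "SvmConfig",
    "TrainedDetector",
    "DetectionEvents",
    "PatientRecords",
    "PatientPerformance",
    "PerformanceReport",
    "build_training_set",
    "grid_search_train",
    "classify_windows",
    "declare_events",
    "score_epoch",
    "loo_evaluate",
    "compare_reports_wilcoxon",
    "channel_subset_comparison",
]

_DEFAULT_GRID = tuple(float(v) for v in np.logspace(-3, 3, 7))


@dataclass(frozen=True)
class SvmConfig:
    c_grid: tuple[float, ...] = _DEFAULT_GRID
    sigma_grid: tuple[float, ...] = _DEFAULT_GRID
    inner_folds: int = 5
    class_weight: str | dict | None = "balanced"
    seed: int = 0
    positive_window_s: float = 6.0   # seconds after onset used as positives
    min_consecutive: int = 2         # windows per declared event
    merge_gap_s: float = 30.0

    def __post_init__(self) -> None:
        if min(self.c_grid) <= 0 or min(self.sigma_grid) <= 0:
            raise ValueError("grids must be positive")
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be >= 2")


@dataclass
class TrainedDetector:
    svc: SVC
    c: float
    sigma: float
    feature_mean: np.ndarray
    feature_std: np.ndarray
    inner_error: float

    def decision_function(self, x: np.ndarray) -> np.ndarray:
        z = (np.asarray(x, dtype=float) - self.feature_mean) / self.feature_std
        return self.svc.decision_function(z)

    def predict(self, x: np.ndarray) -> np.ndarray:
        z = (np.asarray(x, dtype=float) - self.feature_mean) / self.feature_std
        return self.svc.predict(z)


@dataclass
class DetectionEvents:
    events: list[tuple[float, float]]
    window_labels: np.ndarray = field(default_factory=lambda: np.empty(0))
    window_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class PatientRecords:
    """Everything the detector needs for one (pseudo-)patient."""

    patient_id: int
    seizure_epochs: list[AnnotatedEpoch]
    nonseizure_epochs: list[AnnotatedEpoch]
    metadata: PatientMetadata | None = None


@dataclass
class PatientPerformance:
    patient_id: int
    n_seizures: int
    n_detected: int
    n_false: int
    tested_hours: float
    events_per_seizure: list[list[tuple[float, float]]] = field(default_factory=list)
    single_seizure_protocol: bool = False

    @property
    def sensitivity_pct(self) -> float:
        return 100.0 * self.n_detected / self.n_seizures

    @property
    def fdr_per_hour(self) -> float:
        return self.n_false / self.tested_hours if self.tested_hours > 0 else 0.0


@dataclass
class PerformanceReport:
    montage_label: str
    per_patient: list[PatientPerformance]

    def sensitivities(self) -> np.ndarray:
        return np.array([p.sensitivity_pct for p in self.per_patient])

    def fdrs(self) -> np.ndarray:
        return np.array([p.fdr_per_hour for p in self.per_patient])

    def patient_ids(self) -> list[int]:
        return [p.patient_id for p in self.per_patient]

    def aggregate(self) -> dict:
        """Median (min, max) and mean +/- sample SD, per metric."""
        out = {}
        for name, vals in (("sensitivity", self.sensitivities()),
                           ("fdr", self.fdrs())):
            out[name] = {
                "median": float(np.median(vals)),
                "min": float(np.min(vals)),
                "max": float(np.max(vals)),
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
            }
        return out


# ---------------------------------------------------------------------------
# training-set assembly


def _positive_vectors(
    epoch: AnnotatedEpoch,
    montage_channels: list[str] | None,
    feat_cfg: FeatureConfig,
    positive_window_s: float,
) -> np.ndarray:
    """Feature vectors of the first ``positive_window_s`` after seizure onset."""
    onset = epoch.annotations[0].onset_s
    sub_sig = epoch.signal.slice_seconds(onset, onset + positive_window_s)
    sub = AnnotatedEpoch(
        sub_sig,
        [SeizureAnnotation(0.0, sub_sig.duration_s + 1e-9)],
        "seizure",
        epoch.patient_id,
    )
    fm = build_feature_matrix(sub, montage_channels, feat_cfg)
    return fm.vectors


def build_training_set(
    seizure_epochs: Sequence[AnnotatedEpoch],
    nonseizure_epochs: Sequence[AnnotatedEpoch],
    heldout_seizure_index: int,
    montage_channels: list[str] | None = None,
    feat_cfg: FeatureConfig | None = None,
    svm_cfg: SvmConfig | None = None,
):
    """Assemble (X, y, test_epoch) for one leave-one-seizure-out fold.

    Positives are the non-overlapping 2 s windows inside the first six
    seconds of every non-withheld seizure; negatives are all windows of
    every non-seizure epoch.  A patient with a single seizure has no other
    seizure to train on, so that seizure's onset windows enter the training
    set and the same epoch is tested (flagged upstream).
    """
    feat_cfg = feat_cfg or FeatureConfig()
    svm_cfg = svm_cfg or SvmConfig()
    n = len(seizure_epochs)
    if not (0 <= heldout_seizure_index < n):
        raise IndexError(
            f"held-out index {heldout_seizure_index} out of range for {n} seizures"
        )
    train_idx = [i for i in range(n) if i != heldout_seizure_index] or [
        heldout_seizure_index
    ]
    pos = np.vstack(
        [
            _positive_vectors(
                seizure_epochs[i], montage_channels, feat_cfg,
                svm_cfg.positive_window_s,
            )
            for i in train_idx
        ]
    )
    if not nonseizure_epochs:
        raise ValueError("need at least one non-seizure epoch for negatives")
    neg = np.vstack(
        [
            build_feature_matrix(e, montage_channels, feat_cfg).vectors
            for e in nonseizure_epochs
        ]
    )
    x = np.vstack([pos, neg])
    y = np.concatenate([np.ones(len(pos)), -np.ones(len(neg))])
    return x, y, seizure_epochs[heldout_seizure_index]


# ---------------------------------------------------------------------------
# grid-search training


def grid_search_train(
    x: np.ndarray, y: np.ndarray, cfg: SvmConfig | None = None
) -> TrainedDetector:
    """Select (c, sigma) by stratified inner CV and refit on all data.

    Features are z-scored on training statistics.  For each kernel width
    the full pairwise squared-distance matrix is reused, so the grid search
    costs one kernel evaluation per sigma rather than per (c, sigma, fold).
    The selection criterion is the balanced error rate (mean of the
    per-class error rates); ties resolve to the smaller c, then smaller
    sigma.
    """
    cfg = cfg or SvmConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training set contains a single class")

    mean = x.mean(axis=0)
    std = x.std(axis=0)
    std[std == 0] = 1.0
    z = (x - mean) / std

    # pairwise squared distances, shared across the sigma grid
    sq = np.sum(z**2, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * z @ z.T, 0.0)

    n_minority = int(min(np.sum(y == c) for c in classes))
    k = min(cfg.inner_folds, n_minority)
    if k < 2:
        raise ValueError(
            f"minority class has {n_minority} sample(s); cannot stratify inner CV"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=cfg.seed)
    folds = list(skf.split(z, y))

    c_grid = np.unique(np.asarray(cfg.c_grid, dtype=float))
    s_grid = np.unique(np.asarray(cfg.sigma_grid, dtype=float))

    best: tuple[float, float, float] | None = None  # (error, c, sigma)
    for sigma in s_grid:
        kernel = np.exp(-d2 / (2.0 * sigma**2))
        for c in c_grid:
            errors = []
            for tr, te in folds:
                svc = SVC(C=c, kernel="precomputed", class_weight=cfg.class_weight)
                svc.fit(kernel[np.ix_(tr, tr)], y[tr])
                pred = svc.predict(kernel[np.ix_(te, tr)])
                per_class = [
                    np.mean(pred[y[te] == cl] != cl) for cl in classes
                    if np.any(y[te] == cl)
                ]
                errors.append(np.mean(per_class))
            err = float(np.mean(errors))
            cand = (err, c, sigma)
            if best is None or cand < best:
                best = cand
    err, c, sigma = best
    svc = SVC(
        C=c, kernel="rbf", gamma=1.0 / (2.0 * sigma**2),
        class_weight=cfg.class_weight,
    )
    svc.fit(z, y)
    return TrainedDetector(svc, c, sigma, mean, std, err)


def classify_windows(model: TrainedDetector, epoch_features) -> np.ndarray:
    """+/-1 label per window via the stored decision function."""
    x = epoch_features.vectors if isinstance(epoch_features, FeatureMatrix) else epoch_features
    return model.predict(x).astype(int)


# ---------------------------------------------------------------------------
# events and scoring


def declare_events(
    window_labels,
    window_times_s,
    window_s: float = 2.0,
    min_consecutive: int = 2,
    merge_gap_s: float = 30.0,
) -> DetectionEvents:
    """Turn per-window labels into declared seizure events.

    Runs of at least ``min_consecutive`` consecutive positive windows become
    events spanning first-window start to last-window end; events separated
    by less than ``merge_gap_s`` merge into one.
    """
    labels = np.asarray(window_labels)
    times = np.asarray(window_times_s, dtype=float)
    if labels.shape != times.shape:
        raise ValueError("labels and times must align")
    pos = labels > 0
    raw: list[tuple[float, float]] = []
    i = 0
    n = len(pos)
    while i < n:
        if pos[i]:
            j = i
            while j + 1 < n and pos[j + 1]:
                j += 1
            if j - i + 1 >= min_consecutive:
                raw.append((times[i], times[j] + window_s))
            i = j + 1
        else:
            i += 1
    merged: list[tuple[float, float]] = []
    for ev in raw:
        if merged and ev[0] - merged[-1][1] < merge_gap_s:
            merged[-1] = (merged[-1][0], ev[1])
        else:
            merged.append(ev)
    return DetectionEvents(merged, labels, times)


def score_epoch(
    events: DetectionEvents, annotations: Sequence[SeizureAnnotation]
) -> dict:
    """Detected if any event overlaps a seizure; other events are false."""
    detected = False
    n_false = 0
    for s, e in events.events:
        overlaps = any(s <= a.end_s and e >= a.onset_s for a in annotations)
        if overlaps:
            detected = True
        else:
            n_false += 1
    return {"detected": detected, "n_false": n_false}


# ---------------------------------------------------------------------------
# leave-one-seizure-out evaluation


def loo_evaluate(
    patient: PatientRecords,
    montage_channels: list[str] | None = None,
    svm_cfg: SvmConfig | None = None,
    feat_cfg: FeatureConfig | None = None,
) -> PatientPerformance:
    """Train/test over every withheld seizure of one patient."""
    svm_cfg = svm_cfg or SvmConfig()
    feat_cfg = feat_cfg or FeatureConfig()
    n = len(patient.seizure_epochs)
    if n == 0:
        raise ValueError("patient has no seizure epochs")
    single = n == 1
    n_detected = 0
    n_false = 0
    tested_h = 0.0
    per_seizure_events = []
    for held in range(n):
        x, y, test_epoch = build_training_set(
            patient.seizure_epochs, patient.nonseizure_epochs, held,
            montage_channels, feat_cfg, svm_cfg,
        )
        model = grid_search_train(x, y, svm_cfg)
        fm = build_feature_matrix(test_epoch, montage_channels, feat_cfg)
        labels = classify_windows(model, fm)
        events = declare_events(
            labels, fm.window_times_s, feat_cfg.window_s,
            svm_cfg.min_consecutive, svm_cfg.merge_gap_s,
        )
        score = score_epoch(events, test_epoch.annotations)
        n_detected += int(score["detected"])
        n_false += score["n_false"]
        tested_h += test_epoch.duration_s / 3600.0
        per_seizure_events.append(events.events)
    return PatientPerformance(
        patient_id=patient.patient_id,
        n_seizures=n,
        n_detected=n_detected,
        n_false=n_false,
        tested_hours=tested_h,
        events_per_seizure=per_seizure_events,
        single_seizure_protocol=single,
    )


def compare_reports_wilcoxon(
    report_a: PerformanceReport, report_b: PerformanceReport
) -> dict:
    """Paired signed-rank tests across patients on sensitivity and FDR."""
    if report_a.patient_ids() != report_b.patient_ids():
        raise ValueError("reports cover different patient sets")
    return {
        "p_sensitivity": signed_rank_test(
            report_a.sensitivities(), report_b.sensitivities()
        )["p_value"],
        "p_fdr": signed_rank_test(report_a.fdrs(), report_b.fdrs())["p_value"],
    }


_EAR_ROLES = ("cross_head_1", "cross_head_2", "ipsilateral", "contralateral")


def _role_channel(role: str, focus_side: str) -> str:
    if role == "cross_head_1":
        return "LC-RC"
    if role == "cross_head_2":
        return "LT-RT"
    ipsi = "LT-LC" if focus_side == "left" else "RT-RC"
    contra = "RT-RC" if focus_side == "left" else "LT-LC"
    return ipsi if role == "ipsilateral" else contra


def channel_subset_comparison(
    patients: Sequence[PatientRecords],
    svm_cfg: SvmConfig | None = None,
    feat_cfg: FeatureConfig | None = None,
) -> dict:
    """Single-channel detection per behind-the-ear channel role.

    Runs leave-one-seizure-out detection on each ear channel alone and
    groups the unilateral channels by side relative to each patient's
    seizure focus.  Returns ``{"reports": {role: PerformanceReport},
    "pairwise_p": {(role_a, role_b): {...}}}``.
    """
    for p in patients:
        if p.metadata is None or p.metadata.focus_side not in ("left", "right"):
            raise ValueError(
                f"patient {p.patient_id}: focus_side required for ipsi/contra roles"
            )
    reports = {}
    for role in _EAR_ROLES:
        per_patient = []
        for p in patients:
            ch = _role_channel(role, p.metadata.focus_side)
            per_patient.append(loo_evaluate(p, [ch], svm_cfg, feat_cfg))
        reports[role] = PerformanceReport(role, per_patient)
    pairwise = {}
    for i, a in enumerate(_EAR_ROLES):
        for b in _EAR_ROLES[i + 1 :]:
            pairwise[(a, b)] = compare_reports_wilcoxon(reports[a], reports[b])
    return {"reports": reports, "pairwise_p": pairwise}
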