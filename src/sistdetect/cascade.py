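"""Two-stage sit-to-stand recognition.

Stage 1 classifies every epoch as sitting vs anything else.  A small state
machine turns those decisions into a SITTING context: the system enters the
context after ``enter_count`` consecutive sitting decisions and leaves it
after ``hangover`` consecutive non-sitting decisions without a detection.
Stage 2 — which decides whether a SiSt transition is being initiated — runs
only inside the SITTING context; the hangover keeps it live through the
transition onset, when stage 1 naturally stops seeing a seated posture.
The first stage-2 positive emits a detection and closes the context until
it is re-entered, so each sitting bout can fire at most once.  Because
stage 2 is structurally silent while the wearer stands or walks, false
positives during those activities are impossible — the property the cascade
exists for.

Each stage carries its own normalization bounds and mRMR+FFS-selected
feature subset, fitted on training data only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from .classify import ELMClassifier, MLPClassifier, make_classifier
from .features import extract_feature_matrix, lag_concat
from .preprocess import EPOCH_LENGTH, preprocess_trial
from .select import SelectedFeatureSet, discretize, forward_select, mrmr_rank

__all__ = ["TrialFeatures", "build_trial_features", "CascadeDetector",
           "DetectionOutcome", "save_model", "load_model"]


@dataclass
class TrialFeatures:
    """Per-trial base feature matrix plus epoch-level ground truth."""

    subject_id: int
    activity_id: int
    position_id: int | None
    sample_rate: int
    epoch_length: int
    features: np.ndarray            # n_epochs x 154, raw (unnormalized)
    sit_labels: np.ndarray
    transition_labels: np.ndarray
    regions: list[tuple[int, int]]  # annotated SiSt regions, sample units
    has_sist: bool

    @property
    def n_epochs(self) -> int:
        return self.features.shape[0]

    def truncated(self, n_epochs: int) -> "TrialFeatures":
        """First ``n_epochs`` epochs of the trial (causality checks)."""
        limit = n_epochs * self.epoch_length
        return TrialFeatures(
            subject_id=self.subject_id,
            activity_id=self.activity_id,
            position_id=self.position_id,
            sample_rate=self.sample_rate,
            epoch_length=self.epoch_length,
            features=self.features[:n_epochs],
            sit_labels=self.sit_labels[:n_epochs],
            transition_labels=self.transition_labels[:n_epochs],
            regions=[(a, min(b, limit)) for a, b in self.regions if a < limit],
            has_sist=self.has_sist,
        )


def build_trial_features(trial, epoch_length: int = EPOCH_LENGTH,
                         apply_denoise: bool = True) -> TrialFeatures:
    """Denoise, epoch, annotate and featurize one simulated trial."""
    ep = preprocess_trial(trial, epoch_length, apply_denoise)
    feats = extract_feature_matrix(ep.epochs, trial.sample_rate)
    return TrialFeatures(
        subject_id=trial.subject_id,
        activity_id=trial.activity_id,
        position_id=trial.position_id,
        sample_rate=trial.sample_rate,
        epoch_length=epoch_length,
        features=feats.astype(np.float32),
        sit_labels=ep.sit_labels,
        transition_labels=ep.transition_labels,
        regions=ep.transition_regions,
        has_sist=trial.has_sist,
    )


@dataclass
class DetectionOutcome:
    """Streaming detection result of one trial."""

    stage1_decisions: np.ndarray            # per-epoch {0,1}
    stage2_epochs: list[int]                # epochs where stage 2 ran
    stage2_decisions: dict[int, int]        # epoch -> {0,1}, gated only
    detections: list[int]                   # detection epoch indices
    detection_times_s: list[float]          # epoch start times, seconds
    detected: bool                          # >= 1 detection inside a region

    def epoch_predictions(self, n_epochs: int) -> np.ndarray:
        """Per-epoch transition predictions implied by the gated stream."""
        pred = np.zeros(n_epochs, dtype=np.int8)
        for e, d in self.stage2_decisions.items():
            pred[e] = d
        return pred


@dataclass
class _Stage:
    bounds_min: np.ndarray
    bounds_max: np.ndarray
    feature_set: SelectedFeatureSet
    classifier: object


class CascadeDetector(BaseEstimator):
    """Trainable two-stage SiSt detector over per-trial feature bundles.

    ``fit`` consumes a list of :class:`TrialFeatures`; ``detect`` streams
    one trial through the cascade.  Stage 1 learns sitting vs other on all
    epochs; stage 2 learns transition vs non-transition on epochs whose
    trial time lies in sitting or SiSt-transition context (the distribution
    the gate exposes it to at run time).
    """

    def __init__(self, lag: int = 8, classifier: str = "elm",
                 n_hidden: int = 300, mrmr_depth: int = 60,
                 mi_bins: int = 10, mi_row_cap: int = 12000,
                 ffs_row_cap: int = 30000, ffs_patience: int = 5,
                 ffs_max_features: int = 30, enter_count: int = 3,
                 hangover: int = 10, random_state: int | None = None):
        self.lag = lag
        self.classifier = classifier
        self.n_hidden = n_hidden
        self.mrmr_depth = mrmr_depth
        self.mi_bins = mi_bins
        self.mi_row_cap = mi_row_cap
        self.ffs_row_cap = ffs_row_cap
        self.ffs_patience = ffs_patience
        self.ffs_max_features = ffs_max_features
        self.enter_count = enter_count
        self.hangover = hangover
        self.random_state = random_state

    # -- training ----------------------------------------------------------

    def fit(self, trials: list[TrialFeatures], y=None):
        if self.enter_count < 1 or self.hangover < 1:
            raise ValueError("gating parameters must be >= 1")
        if not 1 <= self.lag <= 10:
            raise ValueError("lag must be in 1..10")
        sit_any = any(t.sit_labels.any() for t in trials)
        trans_any = any(t.transition_labels.any() for t in trials)
        if not sit_any or not trans_any:
            missing = "sitting" if not sit_any else "transition"
            raise ValueError(f"training data contains no {missing} epochs")

        rng = np.random.default_rng(self.random_state)
        subjects = sorted({t.subject_id for t in trials})
        # inner validation subject for the FFS wrapper
        if len(subjects) > 1:
            val_subject = subjects[int(rng.integers(len(subjects)))]
        else:
            val_subject = None
        self.train_subjects_ = subjects
        self.ffs_val_subject_ = val_subject

        self.stage1_ = self._fit_stage(
            trials, labels=[t.sit_labels for t in trials],
            context=[np.ones(t.n_epochs, dtype=bool) for t in trials],
            val_subject=val_subject, rng=rng)
        self.stage2_ = self._fit_stage(
            trials, labels=[t.transition_labels for t in trials],
            context=[(t.sit_labels | t.transition_labels).astype(bool)
                     for t in trials],
            val_subject=val_subject, rng=rng)
        return self

    def _fit_stage(self, trials, labels, context, val_subject, rng) -> _Stage:
        base = np.concatenate([t.features[c] for t, c in zip(trials, context)])
        bounds_min = base.min(axis=0).astype(np.float64)
        bounds_max = base.max(axis=0).astype(np.float64)

        rows, ys = [], []
        val_rows, val_ys = [], []
        for t, lab, ctx in zip(trials, labels, context):
            lagged = self._lagged(t, bounds_min, bounds_max)
            if val_subject is not None and t.subject_id == val_subject:
                val_rows.append(lagged[ctx])
                val_ys.append(lab[ctx])
            else:
                rows.append(lagged[ctx])
                ys.append(lab[ctx])
        X = np.concatenate(rows)
        y = np.concatenate(ys)
        Xval = np.concatenate(val_rows) if val_rows else None
        yval = np.concatenate(val_ys) if val_rows else None

        # mRMR ranking on a seeded row subsample
        idx = np.arange(X.shape[0])
        if idx.size > self.mi_row_cap:
            idx = rng.choice(idx, self.mi_row_cap, replace=False)
        depth = min(self.mrmr_depth, X.shape[1])
        codes = discretize(X[idx], self.mi_bins)
        order = mrmr_rank(codes, y[idx], depth, bins=self.mi_bins,
                          discretized=True)

        # wrapper FFS on an inner train/validation split
        probe_seed = int(rng.integers(2**31 - 1))
        if Xval is not None and yval.size and np.unique(y).size == 2:
            ffs_idx = np.arange(X.shape[0])
            if ffs_idx.size > self.ffs_row_cap:
                ffs_idx = rng.choice(ffs_idx, self.ffs_row_cap, replace=False)

            def probe():
                return ELMClassifier(n_hidden=100, random_state=probe_seed,
                                     class_weight="balanced")

            selected = forward_select(order, X[ffs_idx], y[ffs_idx],
                                      Xval, yval, classifier_factory=probe,
                                      patience=self.ffs_patience,
                                      max_features=self.ffs_max_features)
        else:
            selected = order[:min(self.ffs_max_features, len(order))]

        feature_set = SelectedFeatureSet(mrmr_order=order, selected=selected,
                                         mi_bins=self.mi_bins)

        # final stage classifier on all training subjects (incl. the FFS
        # validation subject), restricted to the selected columns
        if Xval is not None:
            X = np.concatenate([X, Xval])
            y = np.concatenate([y, yval])
        clf_seed = int(rng.integers(2**31 - 1))
        n_hidden = min(self.n_hidden, X.shape[0])
        clf = make_classifier(self.classifier, n_hidden, clf_seed)
        clf.fit(X[:, selected], y)
        return _Stage(bounds_min=bounds_min, bounds_max=bounds_max,
                      feature_set=feature_set, classifier=clf)

    def _lagged(self, trial: TrialFeatures, lo: np.ndarray,
                hi: np.ndarray, columns: list[int] | None = None) -> np.ndarray:
        span = hi - lo
        degenerate = span <= 0
        safe = np.where(degenerate, 1.0, span)
        norm = 2.0 * (trial.features - lo) / safe - 1.0
        norm[:, degenerate] = 0.0
        lagged = lag_concat(norm, self.lag)
        return lagged if columns is None else lagged[:, columns]

    # -- streaming detection ----------------------------------------------

    def detect_stream(self, trial: TrialFeatures) -> DetectionOutcome:
        """Run the gated two-stage state machine over one trial."""
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "stage1_")
        if trial.features.shape[1] != self.stage1_.bounds_min.size:
            raise ValueError("trial feature layout differs from training")

        s1 = self.stage1_
        s2 = self.stage2_
        X1 = self._lagged(trial, s1.bounds_min, s1.bounds_max,
                          s1.feature_set.selected)
        X2 = self._lagged(trial, s2.bounds_min, s2.bounds_max,
                          s2.feature_set.selected)
        sit_pred = (self.stage1_.classifier.predict(X1) == 1).astype(np.int8)

        stage2_epochs: list[int] = []
        stage2_decisions: dict[int, int] = {}
        detections: list[int] = []
        in_sitting = False
        sit_run = 0
        nonsit_run = 0
        for e in range(trial.n_epochs):
            s = sit_pred[e]
            if not in_sitting:
                sit_run = sit_run + 1 if s else 0
                if sit_run >= self.enter_count:
                    in_sitting = True
                    nonsit_run = 0
            else:
                stage2_epochs.append(e)
                d = int(s2.classifier.predict(X2[e:e + 1])[0] == 1)
                stage2_decisions[e] = d
                if d:
                    detections.append(e)
                    in_sitting = False
                    sit_run = 0
                    continue
                nonsit_run = 0 if s else nonsit_run + 1
                if nonsit_run >= self.hangover:
                    in_sitting = False
                    sit_run = 0

        ep_len = trial.epoch_length
        in_region = [any(e * ep_len < b and (e + 1) * ep_len > a
                         for a, b in trial.regions) for e in detections]
        times = [e * ep_len / trial.sample_rate for e in detections]
        return DetectionOutcome(
            stage1_decisions=sit_pred,
            stage2_epochs=stage2_epochs,
            stage2_decisions=stage2_decisions,
            detections=detections,
            detection_times_s=times,
            detected=any(in_region),
        )


# ---------------------------------------------------------------------------
# JSON model serialization

def _classifier_to_dict(clf) -> dict:
    if isinstance(clf, ELMClassifier):
        return {
            "kind": "elm", "params": clf.get_params(),
            "classes": clf.classes_.tolist(),
            "input_weights": clf.input_weights_.tolist(),
            "biases": clf.biases_.tolist(),
            "output_weights": clf.output_weights_.tolist(),
        }
    if isinstance(clf, MLPClassifier):
        return {
            "kind": "mlp", "params": clf.get_params(),
            "classes": clf.classes_.tolist(),
            "hidden_weights": clf.hidden_weights_.tolist(),
            "hidden_onsets": clf.hidden_onsets_.tolist(),
            "output_weights": clf.output_weights_.tolist(),
            "output_onset": clf.output_onset_,
        }
    raise TypeError(f"cannot serialize {type(clf)}")


def _classifier_from_dict(d: dict):
    if d["kind"] == "elm":
        clf = ELMClassifier(**d["params"])
        clf.classes_ = np.array(d["classes"])
        clf.input_weights_ = np.array(d["input_weights"])
        clf.biases_ = np.array(d["biases"])
        clf.output_weights_ = np.array(d["output_weights"])
        clf.n_features_in_ = clf.input_weights_.shape[1]
        return clf
    clf = MLPClassifier(**d["params"])
    clf.classes_ = np.array(d["classes"])
    clf.hidden_weights_ = np.array(d["hidden_weights"])
    clf.hidden_onsets_ = np.array(d["hidden_onsets"])
    clf.output_weights_ = np.array(d["output_weights"])
    clf.output_onset_ = d["output_onset"]
    clf.n_features_in_ = clf.hidden_weights_.shape[0]
    return clf


def _stage_to_dict(stage: _Stage) -> dict:
    return {
        "bounds_min": stage.bounds_min.tolist(),
        "bounds_max": stage.bounds_max.tolist(),
        "mrmr_order": stage.feature_set.mrmr_order,
        "selected": stage.feature_set.selected,
        "mi_bins": stage.feature_set.mi_bins,
        "classifier": _classifier_to_dict(stage.classifier),
    }


def _stage_from_dict(d: dict) -> _Stage:
    return _Stage(
        bounds_min=np.array(d["bounds_min"]),
        bounds_max=np.array(d["bounds_max"]),
        feature_set=SelectedFeatureSet(mrmr_order=d["mrmr_order"],
                                       selected=d["selected"],
                                       mi_bins=d["mi_bins"]),
        classifier=_classifier_from_dict(d["classifier"]),
    )


def save_model(model: CascadeDetector, path: str | Path) -> None:
    Path(path).write_text(json.dumps({
        "params": model.get_params(),
        "train_subjects": model.train_subjects_,
        "stage1": _stage_to_dict(model.stage1_),
        "stage2": _stage_to_dict(model.stage2_),
    }))


def load_model(path: str | Path) -> CascadeDetector:
    d = json.loads(Path(path).read_text())
    model = CascadeDetector(**d["params"])
    model.train_subjects_ = d["train_subjects"]
    model.ffs_val_subject_ = None
    model.stage1_ = _stage_from_dict(d["stage1"])
    model.stage2_ = _stage_from_dict(d["stage2"])
    return model
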