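"""Epoch- and transition-level scoring, detection time and the LOSO sweep.

Epoch-level counting follows the convention that a positive prediction in
any epoch overlapping a transition region is a true positive, while false
positives are counted only among epochs wholly outside every region:

    Accuracy = (TP + TN) / (TP + FP + TN + FN)
    TPR      = TP / (TP + FN)
    TNR      = TN / (TN + FP)
    F1       = 2 TP / (2 TP + FP + FN)

Transition-level counting is per trial: one correctly detected transition
epoch suffices to score a transition trial as detected (TP_t); a transition
trial with no in-region detection is a Failed-To-Detect (FTD); a
non-transition trial is TN_t when silent and FP_t when any detection fires.
Detection time (DT) is measured from the annotated region onset to the
start of the first in-region detection epoch, and also expressed as a
percentage of the transition duration; FTD trials contribute no DT.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .cascade import CascadeDetector, TrialFeatures

__all__ = [
    "EpochMetrics",
    "MetricsReport",
    "epoch_metrics",
    "transition_metrics",
    "detection_time",
    "loso_evaluate",
    "paired_t_test",
]


@dataclass
class EpochMetrics:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def accuracy(self) -> float:
        total = self.tp + self.tn + self.fp + self.fn
        return (self.tp + self.tn) / total if total else 1.0

    @property
    def tpr(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else 1.0

    @property
    def tnr(self) -> float:
        denom = self.tn + self.fp
        return self.tn / denom if denom else 1.0

    @property
    def f1(self) -> float:
        denom = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / denom if denom else 1.0


def epoch_metrics(pred_labels, true_labels, transition_regions,
                  epoch_length: int = 100) -> EpochMetrics:
    """Confusion counts of epoch-level transition predictions.

    ``transition_regions`` are half-open sample intervals; an epoch overlaps
    a region when any of its samples falls inside one.
    """
    pred = np.asarray(pred_labels).astype(bool)
    true = np.asarray(true_labels).astype(bool)
    if pred.size != true.size:
        raise ValueError("prediction and truth must have equal length")
    n = pred.size
    overlaps = np.zeros(n, dtype=bool)
    for a, b in transition_regions:
        first = a // epoch_length
        last = (b - 1) // epoch_length
        overlaps[max(0, first):min(n, last + 1)] = True

    tp = int(np.sum(pred & overlaps))
    fp = int(np.sum(pred & ~overlaps))
    fn = int(np.sum(~pred & true))
    tn = int(np.sum(~pred & ~true))
    return EpochMetrics(tp=tp, tn=tn, fp=fp, fn=fn)


def transition_metrics(trial_outcomes) -> dict[str, int]:
    """Trial-level counts from (has_sist, detections, in_region) records.

    Each element of ``trial_outcomes`` is a mapping with keys ``has_sist``
    (bool), ``n_detections`` (int) and ``detected`` (bool: any in-region
    detection).
    """
    tp = tn = fp = ftd = 0
    for rec in trial_outcomes:
        if "has_sist" not in rec:
            raise ValueError("trial record lacks truth metadata")
        if rec["has_sist"]:
            if rec["detected"]:
                tp += 1
            else:
                ftd += 1
        else:
            if rec["n_detections"] > 0:
                fp += 1
            else:
                tn += 1
    return {"TP_t": tp, "TN_t": tn, "FP_t": fp, "FTD": ftd}


def detection_time(detection_epochs, truth_region, epoch_length_s: float,
                   ) -> tuple[float, float]:
    """Detection time of one trial, in seconds and % of the transition.

    ``detection_epochs`` are epoch indices; the first whose epoch overlaps
    ``truth_region = (onset_s, offset_s)`` (in seconds) defines the
    detection point at its epoch start time, clipped below at the region
    onset.  Raises when no in-region detection exists (FTD trials carry no
    detection time).
    """
    onset_s, offset_s = truth_region
    duration = offset_s - onset_s
    for e in detection_epochs:
        start = e * epoch_length_s
        end = start + epoch_length_s
        if end > onset_s and start < offset_s:
            dt = max(0.0, start - onset_s)
            return dt, 100.0 * dt / duration
    raise ValueError("no in-region detection; trial is failed-to-detect")


def paired_t_test(f1_a, f1_b) -> tuple[float, float]:
    """Two-tailed paired t-test on per-subject score pairs.

    Degenerate branches: identical samples return ``(0.0, 1.0)``; constant
    non-zero differences return ``(+/-inf, 0.0)``.
    """
    a = np.asarray(f1_a, dtype=float)
    b = np.asarray(f1_b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    diff = a - b
    if np.std(diff, ddof=1) == 0:
        if np.all(diff == 0):
            return 0.0, 1.0
        return float(np.sign(diff.mean()) * np.inf), 0.0
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


@dataclass
class MetricsReport:
    """Aggregated LOSO metrics for one lag count and classifier."""

    lag: int
    classifier: str
    tpr_e: float
    tnr_e: float
    accuracy_e: float
    f1_e: float
    fp_e: int
    tp_t: int
    tn_t: int
    fp_t: int
    ftd: int
    dt_mean_s: float
    dt_sd_s: float
    dt_pct_of_transition: float
    f1_by_subject: list[float] = field(default_factory=list)

    @property
    def detection_rate_pct(self) -> float:
        denom = self.tp_t + self.ftd
        return 100.0 * self.tp_t / denom if denom else 100.0

    def to_row(self) -> dict:
        d = asdict(self)
        d.pop("f1_by_subject")
        d["detection_rate_pct"] = self.detection_rate_pct
        return d


def loso_evaluate(trials: list[TrialFeatures], lags=(8,),
                  classifier_kind: str = "elm", seed: int | None = 0,
                  cascade_kwargs: dict | None = None,
                  return_models: bool = False):
    """Leave-one-subject-out evaluation across lag counts.

    For every lag and every held-out subject, normalization bounds, feature
    selection and both cascade stages are fitted on the remaining subjects
    only; the held-out subject's trials are then streamed through the
    cascade.  Epoch metrics are averaged over folds; transition counts are
    summed over folds; detection-time statistics pool all detected trials.
    """
    subjects = sorted({t.subject_id for t in trials})
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    lags = [int(k) for k in lags]
    kwargs = dict(cascade_kwargs or {})
    rng = np.random.default_rng(seed)

    reports: list[MetricsReport] = []
    models: dict[tuple[int, int], CascadeDetector] = {}
    for lag in lags:
        fold_em: list[EpochMetrics] = []
        f1_by_subject: list[float] = []
        trial_records: list[dict] = []
        dts: list[float] = []
        dt_pcts: list[float] = []
        for held_out in subjects:
            fold_seed = int(rng.integers(2**31 - 1))
            train = [t for t in trials if t.subject_id != held_out]
            test = [t for t in trials if t.subject_id == held_out]
            model = CascadeDetector(lag=lag, classifier=classifier_kind,
                                    random_state=fold_seed, **kwargs)
            model.fit(train)
            if return_models:
                models[(lag, held_out)] = model

            fold_counts = EpochMetrics(0, 0, 0, 0)
            for t in test:
                outcome = model.detect_stream(t)
                pred = outcome.epoch_predictions(t.n_epochs)
                em = epoch_metrics(pred, t.transition_labels, t.regions,
                                   t.epoch_length)
                fold_counts.tp += em.tp
                fold_counts.tn += em.tn
                fold_counts.fp += em.fp
                fold_counts.fn += em.fn
                trial_records.append({
                    "has_sist": t.has_sist,
                    "n_detections": len(outcome.detections),
                    "detected": outcome.detected,
                })
                if t.has_sist and outcome.detected and t.regions:
                    ep_s = t.epoch_length / t.sample_rate
                    region_s = (t.regions[0][0] / t.sample_rate,
                                t.regions[0][1] / t.sample_rate)
                    dt, pct = detection_time(outcome.detections, region_s, ep_s)
                    dts.append(dt)
                    dt_pcts.append(pct)
            fold_em.append(fold_counts)
            f1_by_subject.append(fold_counts.f1)

        tcounts = transition_metrics(trial_records)
        reports.append(MetricsReport(
            lag=lag,
            classifier=classifier_kind,
            tpr_e=float(np.mean([m.tpr for m in fold_em])),
            tnr_e=float(np.mean([m.tnr for m in fold_em])),
            accuracy_e=float(np.mean([m.accuracy for m in fold_em])),
            f1_e=float(np.mean([m.f1 for m in fold_em])),
            fp_e=int(np.sum([m.fp for m in fold_em])),
            tp_t=tcounts["TP_t"],
            tn_t=tcounts["TN_t"],
            fp_t=tcounts["FP_t"],
            ftd=tcounts["FTD"],
            dt_mean_s=float(np.mean(dts)) if dts else float("nan"),
            dt_sd_s=float(np.std(dts)) if dts else float("nan"),
            dt_pct_of_transition=float(np.mean(dt_pcts)) if dt_pcts else float("nan"),
            f1_by_subject=f1_by_subject,
        ))
    if return_models:
        return reports, models
    return reports


def reports_to_frame(reports: list[MetricsReport]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in reports])
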