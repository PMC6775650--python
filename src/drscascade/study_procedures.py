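"""Study-specific procedures: depth labeling, depth sweep, zero-FN threshold.

Three procedures sit on top of the generic cascade:

* **Depth-based labeling** (:func:`depth_label`).  Histopathology gives, for
  each tumor measurement, the distance from the measurement surface to the
  first tumor tissue and the lateral extent of tumor on the section.  A
  location counts as tumor when tumor lies within ``max_depth_mm`` of the
  surface (default 1.5 mm, the probe's approximate sensing depth at
  1.29 mm fiber separation); locations whose within-depth tumor extends
  over less than ``min_extent_mm`` (default 0.5 mm) laterally are
  *inconclusive* and excluded from training and evaluation.

* **Depth sweep** (:func:`depth_sweep`).  The maximum depth for the tumor
  label is swept from 0 mm to beyond 4 mm; for each value the dataset is
  relabeled and the cascade is retrained and re-tested from scratch,
  tracing how tumor accuracy and MCC fall off once tumor sits deeper than
  the probe can sense.

* **Sensitivity-constrained operating point** (:func:`zero_fn_threshold`
  and :func:`evaluate_uncertain`).  To support resection decisions the
  tumor threshold is recalibrated so that *no* tumor location is called
  healthy on a calibration subset (the locations the surgeon was certain
  about), then the thresholded classifier is compared against the
  surgeon's own judgement on the uncertain locations, as paired 2x2
  confusion tables versus histopathology.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import cascade as _cascade
from . import evaluation as _evaluation
from . import preprocess as _preprocess
from .errors import CalibrationError, ConfigError, DataError, EvaluationError, FoldError
from .synthetic_data import Dataset

DEFAULT_DEPTH_GRID = (0.0, 1.0, 1.5, 2.0, 3.0, 4.0, np.inf)

#: Threshold placement margin when the minimum tumor score is the global
#: minimum (no healthy score to take a midpoint with).
THRESHOLD_EPSILON = 1e-6


@dataclass(frozen=True)
class DepthRule:
    """Tumor-labeling rule: maximum depth and minimum conclusive extent (mm)."""

    max_depth_mm: float = 1.5
    min_extent_mm: float = 0.5

    def __post_init__(self) -> None:
        # max_depth 0 is meaningful (surface tumor only, the sweep's first bin)
        if self.max_depth_mm < 0 or not self.min_extent_mm > 0:
            raise ConfigError("DepthRule thresholds must be non-negative / positive")


def depth_label(loc, rule: DepthRule = DepthRule()) -> str:
    """Histopathology label of one location: tumor, non_tumor or excluded."""
    if loc.true_class != "tumor":
        return "non_tumor"
    if loc.tumor_depth_mm is None:
        raise DataError(f"tumor location {loc.location_id} has no depth annotation")
    if loc.tumor_depth_mm <= rule.max_depth_mm:
        if loc.tumor_extent_mm is not None and loc.tumor_extent_mm < rule.min_extent_mm:
            return "excluded"
        return "tumor"
    return "non_tumor"


def effective_labels(meta: pd.DataFrame, rule: DepthRule = DepthRule()) -> pd.Series:
    """Per-spectrum 3-class analysis labels under a depth rule.

    Fat and wall locations keep their class.  Tumor locations become
    ``tumor`` when within the rule, ``wall`` when the tumor starts deeper
    (the probe then sees the overlying wall), or ``NaN`` when the
    histopathology correlation is inconclusive (to be dropped).
    """

    def label_row(row) -> Optional[str]:
        if row["true_class"] != "tumor":
            return row["true_class"]
        if row["tumor_depth_mm"] is None or pd.isna(row["tumor_depth_mm"]):
            raise DataError(f"tumor location {row['location_id']} has no depth annotation")
        if row["tumor_depth_mm"] <= rule.max_depth_mm:
            if row["tumor_extent_mm"] is not None and row["tumor_extent_mm"] < rule.min_extent_mm:
                return None
            return "tumor"
        return "wall"

    return meta.apply(label_row, axis=1)


@dataclass
class PipelineResult:
    """Preprocessed features, labels and out-of-fold predictions of one run."""

    predictions: pd.DataFrame
    report: _evaluation.MetricsReport
    n_excluded_locations: int
    labels: pd.Series
    meta: pd.DataFrame


def run_pipeline(
    dataset: Dataset,
    rule: DepthRule = DepthRule(),
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
    group_by_patient: bool = False,
    svm_cost: float = 1.0,
) -> PipelineResult:
    """Preprocess, depth-label, cross-validate and score a dataset."""
    X, _grid, meta = _preprocess.process_dataset(dataset)
    labels = effective_labels(meta, rule)
    keep = labels.notna().to_numpy()
    n_excluded = meta.loc[~keep, "location_id"].nunique()
    meta_kept = meta.loc[keep].reset_index(drop=True)
    labels_kept = labels.loc[keep].reset_index(drop=True)
    predictions = _cascade.cross_validate(
        X[keep],
        meta_kept,
        labels_kept.to_numpy(),
        k=k,
        repeats=repeats,
        seed=seed,
        group_by_patient=group_by_patient,
        svm_cost=svm_cost,
    )
    report = _evaluation.metrics_report(predictions)
    return PipelineResult(
        predictions=predictions,
        report=report,
        n_excluded_locations=int(n_excluded),
        labels=labels_kept,
        meta=meta_kept,
    )


def depth_sweep(
    dataset: Dataset,
    depths: Sequence[float] = DEFAULT_DEPTH_GRID,
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
    min_extent_mm: float = 0.5,
    group_by_patient: bool = False,
    svm_cost: float = 1.0,
) -> pd.DataFrame:
    """Retrain and re-test the cascade for each maximum tumor depth.

    Returns one row per depth with the across-repeat mean/SD of the tumor
    one-vs-all accuracy and MCC.  Depth bins with no tumor-labeled location
    (or too few to stratify k folds) are flagged, not silently dropped.
    """
    X, _grid, meta = _preprocess.process_dataset(dataset)
    rows = []
    for max_depth in depths:
        rule = DepthRule(max_depth_mm=max_depth if np.isfinite(max_depth) else 1e9,
                         min_extent_mm=min_extent_mm)
        labels = effective_labels(meta, rule)
        keep = labels.notna().to_numpy()
        meta_kept = meta.loc[keep].reset_index(drop=True)
        labels_kept = labels.loc[keep].to_numpy()
        loc_labels = pd.DataFrame(
            {"location_id": meta_kept["location_id"], "label": labels_kept}
        ).drop_duplicates("location_id")
        n_tumor = int((loc_labels["label"] == "tumor").sum())
        row = {
            "max_depth_mm": max_depth,
            "n_tumor_locations": n_tumor,
            "empty": n_tumor == 0,
            "insufficient": 0 < n_tumor < k,
        }
        if n_tumor >= k:
            try:
                predictions = _cascade.cross_validate(
                    X[keep], meta_kept, labels_kept,
                    k=k, repeats=repeats, seed=seed,
                    group_by_patient=group_by_patient, svm_cost=svm_cost,
                )
            except FoldError:
                row["insufficient"] = True
            else:
                per_repeat = []
                for _, frame in predictions.groupby("repeat", sort=True):
                    c = _evaluation.confusion(
                        frame["predicted_class"], frame["true_class"], "tumor"
                    )
                    per_repeat.append(
                        (_evaluation.basic_rates(c).accuracy, _evaluation.mcc(c))
                    )
                acc, mcc_vals = zip(*per_repeat)
                row.update(
                    accuracy_mean=float(np.mean(acc)),
                    accuracy_sd=float(np.std(acc, ddof=0)),
                    mcc_mean=float(np.mean(mcc_vals)),
                    mcc_sd=float(np.std(mcc_vals, ddof=0)),
                )
        for key in ("accuracy_mean", "accuracy_sd", "mcc_mean", "mcc_sd"):
            row.setdefault(key, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ThresholdCalibration:
    """Tumor threshold calibrated for zero false negatives.

    ``tumor_threshold`` applied as ``call tumor iff score > threshold``
    yields ``fn == 0`` on the calibration subset by construction, with the
    fewest possible false positives under that constraint.
    """

    tumor_threshold: float
    n_calibration: int
    fn: int
    fp: int


def zero_fn_threshold(
    location_scores: Sequence[float], truths: Sequence[bool]
) -> ThresholdCalibration:
    """Largest threshold that keeps every true tumor above it.

    ``location_scores`` are location-level cascade tumor scores;
    ``truths`` flag true tumor locations.  The threshold is placed at the
    midpoint between the minimum tumor score and the largest healthy score
    strictly below it (or a fixed epsilon below the minimum tumor score if
    nothing lies below).  A healthy location tied exactly with the minimum
    tumor score therefore stays above the threshold and counts as a false
    positive.
    """
    scores = np.asarray(location_scores, dtype=float)
    truths = np.asarray(truths, dtype=bool)
    if scores.shape != truths.shape:
        raise CalibrationError("scores and truths must align")
    if not truths.any():
        raise CalibrationError("calibration subset contains no tumor location")
    min_tumor = scores[truths].min()
    below = scores[scores < min_tumor]
    if below.size:
        threshold = float((below.max() + min_tumor) / 2.0)
    else:
        threshold = float(min_tumor - THRESHOLD_EPSILON * max(1.0, abs(min_tumor)))
    calls = scores > threshold
    fn = int(np.sum(truths & ~calls))
    fp = int(np.sum(~truths & calls))
    return ThresholdCalibration(
        tumor_threshold=threshold, n_calibration=int(scores.size), fn=fn, fp=fp
    )


@dataclass
class SurgeonComparison:
    """Paired 2x2 tables versus histopathology on the uncertain subset."""

    classifier: _evaluation.ConfusionCounts
    surgeon: _evaluation.ConfusionCounts
    classifier_fp_rate: float
    surgeon_fp_rate: float
    n_uncertain: int


def evaluate_uncertain(
    locations: pd.DataFrame, calibration: ThresholdCalibration
) -> SurgeonComparison:
    """Compare thresholded classifier and surgeon on uncertain locations.

    ``locations`` needs one row per uncertain location with columns
    ``tumor_score``, ``truth_tumor`` (bool, histopathology) and
    ``surgeon_class`` ({'healthy', 'tumor'}).  Classes are collapsed to
    healthy (fat + wall) versus tumor.  The reported FP rate of each rater
    is the fraction of healthy-truth locations called tumor.
    """
    if len(locations) == 0:
        raise EvaluationError("uncertain subset is empty")
    truth = locations["truth_tumor"].to_numpy(dtype=bool)
    clf_call = locations["tumor_score"].to_numpy(dtype=float) > calibration.tumor_threshold
    surgeon_call = locations["surgeon_class"].to_numpy() == "tumor"

    def table(calls: np.ndarray) -> _evaluation.ConfusionCounts:
        return _evaluation.ConfusionCounts(
            tp=int(np.sum(calls & truth)),
            tn=int(np.sum(~calls & ~truth)),
            fp=int(np.sum(calls & ~truth)),
            fn=int(np.sum(~calls & truth)),
        )

    clf_table = table(clf_call)
    surgeon_table = table(surgeon_call)
    n_healthy = int(np.sum(~truth))
    if n_healthy == 0:
        raise EvaluationError("uncertain subset has no healthy-truth locations")
    return SurgeonComparison(
        classifier=clf_table,
        surgeon=surgeon_table,
        classifier_fp_rate=clf_table.fp / n_healthy,
        surgeon_fp_rate=surgeon_table.fp / n_healthy,
        n_uncertain=len(locations),
    )


@dataclass
class SurgeonStudyResult:
    """End-to-end output of the surgeon-comparison procedure."""

    calibration: ThresholdCalibration
    comparison: SurgeonComparison
    certain_locations: pd.DataFrame
    uncertain_locations: pd.DataFrame


def compare_to_surgeon(
    dataset: Dataset,
    rule: DepthRule = DepthRule(),
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
    group_by_patient: bool = False,
    svm_cost: float = 1.0,
    pipeline: Optional[PipelineResult] = None,
) -> SurgeonStudyResult:
    """Full sensitivity-constrained comparison against surgeon judgement.

    Runs the cross-validated pipeline, averages each location's out-of-fold
    cascade tumor score over replicates and repeats, calibrates the
    zero-false-negative threshold on the surgeon-certain locations, and
    evaluates both raters on the surgeon-uncertain locations.
    """
    result = pipeline or run_pipeline(
        dataset, rule=rule, k=k, repeats=repeats, seed=seed,
        group_by_patient=group_by_patient, svm_cost=svm_cost,
    )
    loc_scores = (
        result.predictions.groupby("location_id")["tumor_score"].mean().rename("tumor_score")
    )
    loc_meta = (
        result.meta.drop_duplicates("location_id")
        .set_index("location_id")[["true_class", "tumor_depth_mm", "tumor_extent_mm",
                                   "surgeon_class", "surgeon_certain"]]
    )
    loc_labels = pd.DataFrame(
        {"location_id": result.meta["location_id"], "label": result.labels}
    ).drop_duplicates("location_id").set_index("location_id")["label"]
    table = loc_meta.join(loc_scores).join(loc_labels.rename("analysis_label"))
    table["truth_tumor"] = table["analysis_label"] == "tumor"
    certain = table[table["surgeon_certain"]].reset_index()
    uncertain = table[~table["surgeon_certain"]].reset_index()
    if len(certain) == 0 or not certain["truth_tumor"].any():
        raise CalibrationError("no surgeon-certain tumor locations to calibrate on")
    calibration = zero_fn_threshold(
        certain["tumor_score"].to_numpy(), certain["truth_tumor"].to_numpy()
    )
    comparison = evaluate_uncertain(uncertain, calibration)
    return SurgeonStudyResult(
        calibration=calibration,
        comparison=comparison,
        certain_locations=certain,
        uncertain_locations=uncertain,
    )
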