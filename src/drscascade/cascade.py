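"""Two-stage linear-SVM cascade with repeated stratified cross-validation.

Stage 1 separates fat from everything else (fat vs {wall, tumor}, trained
with wall and tumor merged into one class).  Spectra not called fat are
passed to stage 2, which separates healthy colorectal wall from tumor.  The
tumor call of stage 2 is made against an adjustable signed-score threshold
(default 0), which is what the sensitivity-constrained operating-point
procedure in :mod:`drscascade.study_procedures` later moves.

Both stages are linear SVMs; after fitting, only the weight vector and bias
are kept, so a trained model is a pair of linear discriminants plus the
threshold and is trivially serializable.

Cross-validation folds are formed over *measurement locations*, never over
individual replicate spectra, so the three replicates of one site always
share a fold.  Folds are stratified by class; optional grouping keeps all
locations of one patient in the same fold.  The whole k-fold procedure is
repeated ``repeats`` times with reshuffled folds and every spectrum gets
exactly one out-of-fold prediction per repeat.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.svm import SVC

from .errors import FoldError, GridMismatchError, TrainingError

CLASS_PRIORITY = ("tumor", "wall", "fat")  # majority-vote tie-break order


@dataclass(frozen=True)
class LinearDiscriminant:
    """Signed-distance linear scorer: score(x) = w . x + b."""

    weights: np.ndarray
    bias: float

    def score(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.weights.size:
            raise GridMismatchError(
                f"feature dimension {X.shape[1]} != model dimension {self.weights.size}"
            )
        return X @ self.weights + self.bias


@dataclass
class CascadeModel:
    """Trained cascade: fat-vs-rest and wall-vs-tumor discriminants.

    Positive ``svm_fat`` score means fat; positive ``svm_tumor`` score means
    tumor side.  A spectrum is called tumor only when its stage-2 score
    strictly exceeds ``tumor_threshold`` (ties go to wall).
    """

    svm_fat: LinearDiscriminant
    svm_tumor: LinearDiscriminant
    tumor_threshold: float = 0.0
    wavelengths: Optional[np.ndarray] = None

    def to_json(self) -> str:
        payload = {
            "svm_fat": {"weights": self.svm_fat.weights.tolist(), "bias": self.svm_fat.bias},
            "svm_tumor": {"weights": self.svm_tumor.weights.tolist(), "bias": self.svm_tumor.bias},
            "tumor_threshold": self.tumor_threshold,
            "wavelengths": None if self.wavelengths is None else self.wavelengths.tolist(),
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "CascadeModel":
        payload = json.loads(text)
        return cls(
            svm_fat=LinearDiscriminant(
                np.asarray(payload["svm_fat"]["weights"], float), payload["svm_fat"]["bias"]
            ),
            svm_tumor=LinearDiscriminant(
                np.asarray(payload["svm_tumor"]["weights"], float), payload["svm_tumor"]["bias"]
            ),
            tumor_threshold=payload["tumor_threshold"],
            wavelengths=None
            if payload["wavelengths"] is None
            else np.asarray(payload["wavelengths"], float),
        )


@dataclass(frozen=True)
class PredictionRecord:
    """Out-of-fold prediction for one replicate spectrum."""

    measurement_id: str
    fold: int
    repeat: int
    score_fat: float
    score_tumor: Optional[float]  # absent when routed to fat
    predicted_class: str


def _fit_binary(X: np.ndarray, y: np.ndarray, cost: float) -> LinearDiscriminant:
    svm = SVC(kernel="linear", C=cost)
    svm.fit(X, y)
    w = np.asarray(svm.coef_, dtype=float).ravel()
    b = float(svm.intercept_[0])
    # sklearn orders classes [0, 1]; decision_function > 0 means class 1,
    # which is how y is encoded by the callers (positive class = 1).
    return LinearDiscriminant(w, b)


def train_cascade(
    X: np.ndarray,
    labels: Sequence[str],
    svm_cost: float = 1.0,
    wavelengths: Optional[np.ndarray] = None,
) -> CascadeModel:
    """Fit both stages on normalized spectra.

    Stage 1 uses every spectrum with wall and tumor merged into a single
    non-fat class; stage 2 is fit on wall and tumor spectra only.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if X.shape[0] != labels.size:
        raise GridMismatchError("X rows and labels must align")
    present = set(np.unique(labels))
    for needed in ("fat", "wall", "tumor"):
        if needed not in present:
            raise TrainingError(f"class {needed!r} absent from training data")
    y_fat = (labels == "fat").astype(int)
    stage2_mask = labels != "fat"
    y_tumor = (labels[stage2_mask] == "tumor").astype(int)
    return CascadeModel(
        svm_fat=_fit_binary(X, y_fat, svm_cost),
        svm_tumor=_fit_binary(X[stage2_mask], y_tumor, svm_cost),
        wavelengths=wavelengths,
    )


def score_cascade(model: CascadeModel, X: np.ndarray) -> pd.DataFrame:
    """Raw stage scores and routed class for a batch of spectra.

    Returns a frame with ``score_fat``, ``score_tumor`` (NaN for spectra
    routed to fat), ``tumor_score`` and ``predicted_class``.  ``tumor_score``
    is defined for *every* spectrum as min(-score_fat, score_tumor): a
    spectrum is on the tumor side of the cascade only if it is on the
    non-fat side of stage 1 and the tumor side of stage 2.  This single
    monotone score is what threshold sweeps (ROC, zero-false-negative
    calibration) operate on.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    s_fat = model.svm_fat.score(X)
    s_tumor_all = model.svm_tumor.score(X)
    is_fat = s_fat > 0
    tumor_call = ~is_fat & (s_tumor_all > model.tumor_threshold)
    predicted = np.where(is_fat, "fat", np.where(tumor_call, "tumor", "wall"))
    return pd.DataFrame(
        {
            "score_fat": s_fat,
            "score_tumor": np.where(is_fat, np.nan, s_tumor_all),
            "stage2_score": s_tumor_all,
            "tumor_score": np.minimum(-s_fat, s_tumor_all),
            "predicted_class": predicted,
        }
    )


def predict(model: CascadeModel, spectrum: np.ndarray) -> PredictionRecord:
    """Classify a single normalized spectrum (no CV context: fold/repeat -1)."""
    row = score_cascade(model, np.atleast_2d(spectrum)).iloc[0]
    score_tumor = None if np.isnan(row["score_tumor"]) else float(row["score_tumor"])
    return PredictionRecord(
        measurement_id="",
        fold=-1,
        repeat=-1,
        score_fat=float(row["score_fat"]),
        score_tumor=score_tumor,
        predicted_class=str(row["predicted_class"]),
    )


def _location_table(meta: pd.DataFrame, labels: np.ndarray) -> pd.DataFrame:
    table = meta[["location_id", "patient_id"]].copy()
    table["label"] = labels
    table = table.drop_duplicates("location_id").reset_index(drop=True)
    per_loc = pd.DataFrame({"location_id": meta["location_id"], "label": labels})
    if (per_loc.groupby("location_id")["label"].nunique() > 1).any():
        raise TrainingError("labels must be constant within a measurement location")
    return table


def cross_validate(
    X: np.ndarray,
    meta: pd.DataFrame,
    labels: Sequence[str],
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
    group_by_patient: bool = False,
    svm_cost: float = 1.0,
) -> pd.DataFrame:
    """Repeated stratified k-fold over locations; out-of-fold cascade scores.

    Returns one row per (spectrum, repeat) with the columns of
    :func:`score_cascade` plus identifiers, fold and repeat indices and the
    training label, i.e. ``repeats`` out-of-fold predictions per spectrum.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    loc_table = _location_table(meta, labels)
    class_counts = loc_table["label"].value_counts()
    if (class_counts < k).any():
        small = class_counts[class_counts < k].to_dict()
        raise FoldError(f"every class needs >= k={k} locations; got {small}")

    rng = np.random.default_rng(seed)
    fold_seeds = rng.integers(0, 2**31 - 1, size=repeats)
    loc_index = {loc: idx for idx, loc in enumerate(loc_table["location_id"])}
    spectrum_loc = meta["location_id"].map(loc_index).to_numpy()

    frames = []
    for repeat, fold_seed in enumerate(fold_seeds):
        if group_by_patient:
            splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=int(fold_seed))
            splits = splitter.split(
                np.zeros(len(loc_table)), loc_table["label"], groups=loc_table["patient_id"]
            )
        else:
            splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(fold_seed))
            splits = splitter.split(np.zeros(len(loc_table)), loc_table["label"])
        for fold, (train_locs, test_locs) in enumerate(splits):
            train_mask = np.isin(spectrum_loc, train_locs)
            test_mask = np.isin(spectrum_loc, test_locs)
            model = train_cascade(X[train_mask], labels[train_mask], svm_cost=svm_cost)
            scored = score_cascade(model, X[test_mask])
            scored.insert(0, "measurement_id", meta.loc[test_mask, "measurement_id"].to_numpy())
            scored.insert(1, "location_id", meta.loc[test_mask, "location_id"].to_numpy())
            scored.insert(2, "patient_id", meta.loc[test_mask, "patient_id"].to_numpy())
            scored.insert(3, "repeat", repeat)
            scored.insert(4, "fold", fold)
            scored["true_class"] = labels[test_mask]
            frames.append(scored)
    return pd.concat(frames, ignore_index=True)


def location_predictions(predictions: pd.DataFrame) -> pd.DataFrame:
    """Aggregate replicate-level predictions to one row per (repeat, location).

    Class = majority vote of the replicates (ties broken tumor > wall > fat,
    the cautious direction); ``tumor_score`` = mean of the replicate cascade
    tumor scores.
    """

    def majority(values: pd.Series) -> str:
        counts = values.value_counts()
        top = counts[counts == counts.max()].index
        for cls in CLASS_PRIORITY:
            if cls in top:
                return cls
        return top[0]

    grouped = predictions.groupby(["repeat", "location_id"], sort=True)
    out = grouped.agg(
        patient_id=("patient_id", "first"),
        predicted_class=("predicted_class", majority),
        tumor_score=("tumor_score", "mean"),
        true_class=("true_class", "first"),
    ).reset_index()
    return out
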