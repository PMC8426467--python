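"""Tile → ROI → patient evaluation: majority voting and summary metrics.

A classifier emits, per tile, a probability of *immature* stroma in [0, 1]
(0 = confidently mature, 1 = confidently immature).  Tiles are classified
immature when the probability is greater than or equal to the cutoff
(default 0.5, boundary inclusive).  Tile labels are aggregated to region of
interest (ROI) level and ROI labels to patient level by majority vote; an
exact tie at patient level is called mature, and the same conservative tie
direction is used (configurably) at ROI level.

Immature is the positive class throughout, so the confusion matrix cells
read: TN = true mature, FP = false immature, TP = true immature,
FN = false mature.  Metrics where the denominator vanishes return ``None``
(a distinguished "undefined" marker) rather than 0.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MATURE = "mature"
IMMATURE = "immature"
_LABELS = (MATURE, IMMATURE)

PREDICTION_COLUMNS = ["patient_id", "roi_id", "tile_id", "true_label",
                      "prob_immature"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with immature fixed as the positive class."""

    tn: int  # true mature
    fp: int  # false immature
    tp: int  # true immature
    fn: int  # false mature

    def __post_init__(self):
        if min(self.tn, self.fp, self.tp, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.tp + self.fn


def load_predictions(path: str | os.PathLike) -> pd.DataFrame:
    """Read a per-tile prediction table (CSV with columns
    patient_id, roi_id, tile_id, true_label, prob_immature) and validate it."""
    df = pd.read_csv(path, dtype={"patient_id": str, "roi_id": str,
                                  "tile_id": str})
    return validate_predictions(df)


def validate_predictions(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PREDICTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"prediction table missing columns: {missing}")
    if df.empty:
        raise ValueError("prediction table is empty")
    bad = ~df["true_label"].isin(_LABELS)
    if bad.any():
        raise ValueError(f"unknown true_label values: "
                         f"{sorted(df.loc[bad, 'true_label'].unique())}")
    p = df["prob_immature"].to_numpy(dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("prob_immature must lie in [0, 1]")
    if df.duplicated(subset=["patient_id", "roi_id", "tile_id"]).any():
        raise ValueError("duplicate (patient_id, roi_id, tile_id) rows")
    return df


def classify_tile(prob: float, cutoff: float = 0.5) -> str:
    """Immature iff prob >= cutoff (the boundary counts as immature)."""
    if not 0 <= prob <= 1:
        raise ValueError(f"probability must be in [0, 1], got {prob}")
    if not 0 <= cutoff <= 1:
        raise ValueError(f"cutoff must be in [0, 1], got {cutoff}")
    return IMMATURE if prob >= cutoff else MATURE


def _vote(labels, tie: str) -> str:
    labels = list(labels)
    if not labels:
        raise ValueError("cannot vote on an empty list of labels")
    unknown = set(labels) - set(_LABELS)
    if unknown:
        raise ValueError(f"unknown labels: {sorted(unknown)}")
    n_imm = sum(1 for x in labels if x == IMMATURE)
    n_mat = len(labels) - n_imm
    if n_imm > n_mat:
        return IMMATURE
    if n_mat > n_imm:
        return MATURE
    return tie


def roi_vote(tile_labels, tie: str = MATURE) -> str:
    """Majority label of an ROI's tiles; an exact tie resolves to *tie*
    (mature by default, matching the patient-level rule)."""
    return _vote(tile_labels, tie)


def patient_vote(roi_labels, tie: str = MATURE) -> str:
    """Majority label of a patient's ROIs; when immature and mature ROI
    counts are equal the patient is considered mature."""
    return _vote(roi_labels, tie)


def confusion(true_labels, pred_labels) -> ConfusionMatrix:
    """Count the 2x2 table with immature as the positive class."""
    true_labels, pred_labels = list(true_labels), list(pred_labels)
    if len(true_labels) != len(pred_labels):
        raise ValueError(f"length mismatch: {len(true_labels)} true vs "
                         f"{len(pred_labels)} predicted")
    if not true_labels:
        raise ValueError("empty label lists")
    tn = fp = tp = fn = 0
    for t, p in zip(true_labels, pred_labels):
        if t not in _LABELS or p not in _LABELS:
            raise ValueError(f"unknown label in pair ({t!r}, {p!r})")
        if t == IMMATURE:
            tp += p == IMMATURE
            fn += p == MATURE
        else:
            tn += p == MATURE
            fp += p == IMMATURE
    return ConfusionMatrix(tn=tn, fp=fp, tp=tp, fn=fn)


def precision(cm: ConfusionMatrix) -> float | None:
    """tp / (tp + fp); None when no positive predictions exist."""
    d = cm.tp + cm.fp
    return cm.tp / d if d else None


def recall(cm: ConfusionMatrix) -> float | None:
    """tp / (tp + fn), i.e. sensitivity; None when no true positives exist."""
    d = cm.tp + cm.fn
    return cm.tp / d if d else None


def f1(cm: ConfusionMatrix) -> float | None:
    """Harmonic mean of precision and recall."""
    p, r = precision(cm), recall(cm)
    if p is None or r is None or p + r == 0:
        return None
    return 2 * p * r / (p + r)


def accuracy(cm: ConfusionMatrix) -> float:
    """(tp + tn) / total."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return (cm.tp + cm.tn) / cm.total


def specificity(cm: ConfusionMatrix) -> float | None:
    """tn / (tn + fp); None when no true negatives or false positives exist."""
    d = cm.tn + cm.fp
    return cm.tn / d if d else None


def sensitivity(cm: ConfusionMatrix) -> float | None:
    """Alias for recall (true-positive rate)."""
    return recall(cm)


def exact_binomial_ci(successes: int, trials: int,
                      level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson exact confidence interval for a binomial proportion."""
    if trials < 1 or not 0 <= successes <= trials:
        raise ValueError(f"invalid counts: {successes}/{trials}")
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    a = 1 - level
    low = 0.0 if successes == 0 else float(
        stats.beta.ppf(a / 2, successes, trials - successes + 1))
    high = 1.0 if successes == trials else float(
        stats.beta.ppf(1 - a / 2, successes + 1, trials - successes))
    return (low, high)


def roc_auc(true_labels, probs) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve, midranks for
    ties: the probability a random immature tile outranks a random mature
    one, counting ties as half."""
    true_labels = list(true_labels)
    probs = np.asarray(list(probs), dtype=float)
    if len(true_labels) != len(probs):
        raise ValueError("length mismatch between labels and probabilities")
    is_pos = np.array([t == IMMATURE for t in true_labels])
    n1 = int(is_pos.sum())
    n0 = len(is_pos) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("ROC AUC needs both classes present")
    ranks = stats.rankdata(probs)  # midranks for ties
    return float((ranks[is_pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def fleiss_kappa(ratings: np.ndarray) -> float | None:
    """Fleiss' kappa for an items x raters table of categorical labels.

    kappa = (P_bar - P_e_bar) / (1 - P_e_bar).  Returns None when expected
    agreement is 1 (every rating in a single category), where kappa is
    undefined.
    """
    ratings = np.asarray(ratings)
    if ratings.ndim != 2:
        raise ValueError("ratings must be a 2-D items x raters table")
    n_items, n_raters = ratings.shape
    if n_items < 2 or n_raters < 2:
        raise ValueError("need >= 2 items and >= 2 raters")
    cats = np.unique(ratings)
    counts = np.stack([(ratings == c).sum(axis=1) for c in cats], axis=1)
    n = n_raters
    p_i = ((counts * counts).sum(axis=1) - n) / (n * (n - 1))
    p_bar = p_i.mean()
    p_j = counts.sum(axis=0) / (n_items * n)
    p_e = float((p_j ** 2).sum())
    if math.isclose(p_e, 1.0):
        return None
    return float((p_bar - p_e) / (1 - p_e))


@dataclass
class AggregationResult:
    """Labelled tables and confusion matrices at the three prediction levels."""

    tiles: pd.DataFrame     # + pred_label column
    rois: pd.DataFrame      # patient_id, roi_id, true_label, pred_label
    patients: pd.DataFrame  # patient_id, true_label, pred_label
    tile_cm: ConfusionMatrix
    roi_cm: ConfusionMatrix
    patient_cm: ConfusionMatrix


def aggregate_predictions(table: pd.DataFrame, cutoff: float = 0.5,
                          tie: str = MATURE) -> AggregationResult:
    """Classify tiles at *cutoff*, then vote tiles → ROI and ROIs → patient.

    Ground truth above tile level is derived by the same voting applied to
    the tile truth labels (ROIs with heterogeneous tile truth are permitted;
    their truth is voted, not rejected).  Returns the labelled tables plus a
    confusion matrix per level.
    """
    df = validate_predictions(table).copy()
    df["pred_label"] = [classify_tile(p, cutoff)
                        for p in df["prob_immature"]]

    roi_rows = []
    for (pid, rid), grp in df.groupby(["patient_id", "roi_id"], sort=True):
        roi_rows.append({
            "patient_id": pid, "roi_id": rid,
            "true_label": roi_vote(grp["true_label"], tie),
            "pred_label": roi_vote(grp["pred_label"], tie),
        })
    rois = pd.DataFrame(roi_rows)

    patient_rows = []
    for pid, grp in rois.groupby("patient_id", sort=True):
        patient_rows.append({
            "patient_id": pid,
            "true_label": patient_vote(grp["true_label"], tie),
            "pred_label": patient_vote(grp["pred_label"], tie),
        })
    patients = pd.DataFrame(patient_rows)

    return AggregationResult(
        tiles=df, rois=rois, patients=patients,
        tile_cm=confusion(df["true_label"], df["pred_label"]),
        roi_cm=confusion(rois["true_label"], rois["pred_label"]),
        patient_cm=confusion(patients["true_label"], patients["pred_label"]),
    )


def summarise(cm: ConfusionMatrix, ndigits: int | None = 3) -> dict:
    """Precision/recall/F1/accuracy/specificity for one confusion matrix,
    optionally rounded for report tables (internal computation stays at full
    precision)."""
    vals = {"tn": cm.tn, "fp": cm.fp, "tp": cm.tp, "fn": cm.fn,
            "precision": precision(cm), "recall": recall(cm), "f1": f1(cm),
            "accuracy": accuracy(cm), "specificity": specificity(cm)}
    if ndigits is not None:
        vals = {k: (round(v, ndigits) if isinstance(v, float) else v)
                for k, v in vals.items()}
    return vals
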