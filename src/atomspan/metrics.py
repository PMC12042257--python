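"""Evaluation metrics for protein function, binding affinity, and
covalent-adduct prediction.

* ``f_max`` — protein-centric maximum F1 over a score-threshold sweep
  (the CAFA convention for multi-label protein-function prediction:
  precision is averaged only over proteins with at least one prediction
  above the threshold, recall over all proteins with annotations).
* ``auprc`` — micro-averaged area under the precision-recall curve with
  step-wise integration.
* ``concordance_index`` — probability-style ranking score over all pairs
  whose true affinities differ: full credit for concordant predictions,
  half for predicted ties.
* ``regression_suite`` — RMSE, Pearson r, r² (squared Pearson, the QSAR
  convention), the through-origin r0² of Roy et al., and the penalized
  r_m² = r²·(1 − sqrt(r² − r0²)).
* ``adduct_task_accuracy`` — exact-match accuracies for the generated
  adduct SMILES (after canonicalization) and binding position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score

from .chem import canonical_smiles
from .covalent import parse_adduct_prediction

__all__ = [
    "ThresholdSweep",
    "MetricReport",
    "RegressionReport",
    "f_max",
    "auprc",
    "concordance_index",
    "regression_suite",
    "adduct_task_accuracy",
]


@dataclass(frozen=True)
class ThresholdSweep:
    """Per-threshold protein-centric precision/recall."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray


@dataclass
class MetricReport:
    """Aggregate report across the evaluation suite (fields optional)."""

    f_max: float | None = None
    auprc: float | None = None
    ci: float | None = None
    rmse: float | None = None
    pearson_r: float | None = None
    r_squared: float | None = None
    r0_squared: float | None = None
    rm_squared: float | None = None
    adduct_accuracy: float | None = None
    position_accuracy: float | None = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def _as_2d(truth, scores):
    t = np.asarray(truth, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if t.shape != s.shape or t.ndim != 2:
        raise ValueError("truth and scores must be 2-D arrays of equal shape")
    if not t.any():
        raise ValueError("no positive labels")
    return t, s


def threshold_sweep(truth, scores) -> ThresholdSweep:
    """Protein-centric precision/recall at every distinct score value."""
    t, s = _as_2d(truth, scores)
    thresholds = np.unique(s)
    n_prot = t.shape[0]
    has_truth = t.any(axis=1)
    n_true = t.sum(axis=1)

    prec = np.empty(len(thresholds))
    rec = np.empty(len(thresholds))
    for i, thr in enumerate(thresholds):
        # a zero score is "no prediction" at any threshold (CAFA reading)
        pred = (s >= thr) & (s > 0)
        tp = (pred & t).sum(axis=1)
        n_pred = pred.sum(axis=1)
        covered = n_pred > 0
        prec[i] = (tp[covered] / n_pred[covered]).mean() if covered.any() else 0.0
        rec[i] = (tp[has_truth] / n_true[has_truth]).mean()
    denom = prec + rec
    f1 = np.where(denom > 0, 2 * prec * rec / np.where(denom > 0, denom, 1), 0.0)
    return ThresholdSweep(thresholds, prec, rec, f1)


def f_max(truth, scores) -> tuple[float, float]:
    """Maximum protein-centric F1 over the threshold sweep.

    ``truth`` is an (n_proteins, n_classes) boolean label matrix and
    ``scores`` the matching score matrix.  Returns (F_max, argmax
    threshold).
    """
    sweep = threshold_sweep(truth, scores)
    k = int(np.argmax(sweep.f1))
    return float(sweep.f1[k]), float(sweep.thresholds[k])


def auprc(truth, scores) -> float:
    """Micro-averaged area under the precision-recall curve."""
    t, s = _as_2d(np.atleast_2d(truth), np.atleast_2d(scores))
    return float(average_precision_score(t.ravel().astype(int), s.ravel()))


def concordance_index(y_true, y_pred) -> float:
    """Ranking concordance over all strictly ordered true pairs.

    For every pair with y_true_i > y_true_j: credit 1 if
    y_pred_i > y_pred_j, 0.5 if predictions tie, 0 otherwise; normalized
    by the number Z of such pairs.  0.5 is chance level, 1 is a perfect
    ordering; the score is invariant under strictly monotone transforms
    of the predictions.
    """
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if yt.shape != yp.shape or yt.ndim != 1 or len(yt) < 2:
        raise ValueError("need two 1-D vectors of equal length >= 2")
    dt = yt[:, None] - yt[None, :]
    dp = yp[:, None] - yp[None, :]
    ordered = dt > 0
    z = int(ordered.sum())
    if z == 0:
        raise ValueError("all true values are tied; concordance undefined")
    credit = np.where(dp > 0, 1.0, np.where(dp == 0, 0.5, 0.0))
    return float(credit[ordered].sum() / z)


@dataclass(frozen=True)
class RegressionReport:
    rmse: float
    pearson_r: float
    r_squared: float
    r0_squared: float
    rm_squared: float


def regression_suite(y_true, y_pred) -> RegressionReport:
    """RMSE, Pearson r, r², Roy's through-origin r0², and r_m².

    r² is the squared Pearson correlation; r0² is the coefficient of
    determination of the least-squares regression of y_true on y_pred
    through the origin (Roy et al.); r_m² = r²·(1 − sqrt(r² − r0²)) with
    the radicand clamped at zero.
    """
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if yt.shape != yp.shape or yt.ndim != 1 or len(yt) < 3:
        raise ValueError("need two 1-D vectors of equal length >= 3")
    if not (np.isfinite(yt).all() and np.isfinite(yp).all()):
        raise ValueError("non-finite values")
    if np.ptp(yt) == 0 or np.ptp(yp) == 0:
        raise ValueError("zero variance in y_true or y_pred")

    rmse = float(np.sqrt(np.mean((yt - yp) ** 2)))
    r = float(np.corrcoef(yt, yp)[0, 1])
    r2 = r * r
    k = float(np.dot(yt, yp) / np.dot(yp, yp))
    ss_res0 = float(np.sum((yt - k * yp) ** 2))
    ss_tot = float(np.sum((yt - yt.mean()) ** 2))
    r0_2 = 1.0 - ss_res0 / ss_tot
    rm2 = r2 * (1.0 - np.sqrt(max(r2 - r0_2, 0.0)))
    return RegressionReport(rmse, r, r2, r0_2, float(rm2))


def adduct_task_accuracy(predictions, references) -> tuple[float, float]:
    """Exact-match accuracies of generated adduct SMILES and positions.

    Both lists hold adduct-task target texts.  A predicted adduct counts
    as correct iff its canonical SMILES equals the reference's canonical
    SMILES; a position counts iff the parsed positions match.  Malformed
    or chemically invalid predictions are wrong on both counts.
    """
    if len(predictions) != len(references):
        raise ValueError("predictions and references differ in length")
    if not references:
        raise ValueError("empty evaluation set")
    adduct_ok = 0
    position_ok = 0
    for pred, ref in zip(predictions, references):
        ref_parsed = parse_adduct_prediction(ref)
        if ref_parsed is None:
            raise ValueError(f"malformed reference: {ref!r}")
        ref_pos, ref_smiles = ref_parsed
        pred_parsed = parse_adduct_prediction(pred)
        if pred_parsed is None:
            continue
        pred_pos, pred_smiles = pred_parsed
        if pred_pos == ref_pos:
            position_ok += 1
        try:
            if canonical_smiles(pred_smiles) == canonical_smiles(ref_smiles):
                adduct_ok += 1
        except ValueError:
            pass
    n = len(references)
    return adduct_ok / n, position_ok / n
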