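"""Connectome-based prediction of treatment outcome.

A multivariate linear model maps baseline state-dependent FC features to
the HAMD reduction rate under leave-one-out cross-validation (LOOCV):
each patient is predicted from a model fitted on all others, features are
standardised on the training fold only, and the fit uses minimum-norm
least squares so over-parameterised folds (p >= n-1) remain well defined.
Model performance is the Pearson correlation between observed and
predicted outcomes; its significance comes from a permutation test that
re-runs the entire LOOCV loop on outcome-shuffled data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np

__all__ = [
    "PredictionResult",
    "build_features",
    "loocv_predict",
    "permutation_test",
]

logger = logging.getLogger(__name__)


@dataclass
class PredictionResult:
    observed: np.ndarray
    predicted: np.ndarray
    pearson_r: float
    permutation_p: float | None = None
    permutation_null: np.ndarray | None = None
    significant: bool | None = None
    roi_weights: np.ndarray | None = None
    subject_ids: list[str] = field(default_factory=list)


def build_features(
    state_matrices: dict[str, np.ndarray],
    mode: str = "roi_mean",
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Feature matrix from per-subject state FC matrices.

    ``state_matrices`` maps subject id -> R x R dFC strength matrix of the
    state of interest (NaN matrix means the subject never visited the state
    and is excluded with a warning).

    mode='roi_mean' (default): feature i is the mean off-diagonal z-FC of
    ROI i, giving R features and per-ROI weight reporting.
    mode='masked_edges': upper-triangle edges inside the boolean ``mask``.
    """
    if mode not in ("roi_mean", "masked_edges"):
        raise ValueError("mode must be 'roi_mean' or 'masked_edges'")
    kept_ids, rows = [], []
    for sid, mat in state_matrices.items():
        mat = np.asarray(mat, dtype=float)
        if np.all(np.isnan(mat)):
            logger.warning("subject %s has no windows in this state; excluded", sid)
            continue
        r = mat.shape[0]
        if mode == "roi_mean":
            rows.append(mat.sum(axis=1) / (r - 1))  # zero diagonal
        else:
            if mask is None:
                raise ValueError("masked_edges mode requires a mask")
            iu = np.triu_indices(r, k=1)
            sel = np.asarray(mask, dtype=bool)[iu]
            if not np.any(sel):
                raise ValueError("empty feature set: mask selects no edges")
            rows.append(mat[iu][sel])
        kept_ids.append(sid)
    if not rows:
        raise ValueError("empty feature set: no subject has the state")
    return np.vstack(rows), kept_ids


def _fit_predict(
    x_train: np.ndarray, y_train: np.ndarray, x_test: np.ndarray
) -> tuple[float, np.ndarray]:
    """Standardise on the training fold, minimum-norm least squares, predict."""
    mu = x_train.mean(axis=0)
    sd = x_train.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    xt = (x_train - mu) / sd
    xs = (x_test - mu) / sd
    design = np.column_stack([np.ones(len(xt)), xt])
    coef, *_ = np.linalg.lstsq(design, y_train, rcond=None)
    pred = float(coef[0] + xs @ coef[1:])
    return pred, coef[1:]


def _loocv_operator(x: np.ndarray) -> np.ndarray:
    """n x n matrix W with pred = W @ y, W[i, i] = 0.

    LOOCV predictions are exactly linear in the outcome vector: fold
    standardisation and the minimum-norm least-squares solution depend on
    the features only, so each held-out prediction is a fixed linear
    functional of the training outcomes.  This lets the permutation test
    re-run the full LOOCV for every shuffle at matrix-vector cost while
    producing the same numbers as the explicit loop.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    w = np.zeros((n, n))
    for i in range(n):
        mask = np.arange(n) != i
        xt = x[mask]
        mu = xt.mean(axis=0)
        sd = xt.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
        design = np.column_stack([np.ones(n - 1), (xt - mu) / sd])
        row = np.concatenate([[1.0], (x[i] - mu) / sd])
        w[i, mask] = row @ np.linalg.pinv(design)
    return w


def loocv_predict(x: np.ndarray, y: np.ndarray) -> PredictionResult:
    """Leave-one-out prediction and observed-vs-predicted Pearson r.

    ``roi_weights`` holds the mean absolute regression weight of each
    feature across folds (interpretable as per-ROI weight in roi_mean mode).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 subjects for LOOCV")
    if np.std(y) == 0:
        raise ValueError("constant outcome: correlation undefined")
    preds = np.empty(n)
    weights = np.zeros(x.shape[1])
    for i in range(n):
        mask = np.arange(n) != i
        preds[i], coef = _fit_predict(x[mask], y[mask], x[i])
        weights += np.abs(coef)
    if np.std(preds) == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(y, preds)[0, 1])
    return PredictionResult(
        observed=y, predicted=preds, pearson_r=r, roi_weights=weights / n
    )


def permutation_test(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
) -> PredictionResult:
    """Permutation assessment of the LOOCV prediction.

    Each permutation shuffles the outcomes across participants and re-runs
    the full LOOCV loop.  p = (1 + #{r_perm >= r_obs}) / (n_perm + 1), and
    the model is declared significant when r_obs exceeds the null's 95th
    percentile (one-sided).  Deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    result = loocv_predict(x, y)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    y = np.asarray(y, dtype=float)
    w = _loocv_operator(x)  # exact linear form of the LOOCV loop
    for b in range(n_perm):
        y_perm = rng.permutation(y)
        preds = w @ y_perm
        if np.std(preds) == 0:
            null[b] = 0.0
        else:
            null[b] = float(np.corrcoef(y_perm, preds)[0, 1])
    r_obs = result.pearson_r
    result.permutation_null = null
    result.permutation_p = float((1 + np.sum(null >= r_obs)) / (n_perm + 1))
    result.significant = bool(r_obs > np.percentile(null, 95))
    return result
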