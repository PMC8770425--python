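"""Recurring-state discovery over windowed FC matrices.

All baseline windows of all participants are pooled and clustered with
k-means under the correlation distance d(x, c) = 1 - PearsonCorr(x, c);
the number of states is chosen by an elbow criterion on the ratio of
within- to between-cluster dispersion over a candidate range (default
2-9).  Post-treatment windows never influence the centroids: they are
assigned to the baseline state with which they correlate most.

State labels are 1-based (state 1, state 2, ...) and ordered by
descending total occurrence, so state 1 is always the most visited state
in the clustering pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StateModel",
    "vectorize_fc",
    "devectorize_fc",
    "kmeans_correlation",
    "elbow_select",
    "assign_to_states",
    "occurrence_proportion",
]


def vectorize_fc(z_fc: np.ndarray) -> np.ndarray:
    """Upper triangle (i < j, row-major) of a symmetric zero-diagonal matrix."""
    z_fc = np.asarray(z_fc, dtype=float)
    if z_fc.ndim != 2 or z_fc.shape[0] != z_fc.shape[1]:
        raise ValueError("expected a square matrix")
    if np.abs(z_fc - z_fc.T).max() > 1e-8:
        raise ValueError("matrix is not symmetric")
    iu = np.triu_indices(z_fc.shape[0], k=1)
    return z_fc[iu]


def devectorize_fc(vec: np.ndarray, n_roi: int) -> np.ndarray:
    """Inverse of :func:`vectorize_fc` (zero diagonal)."""
    vec = np.asarray(vec, dtype=float)
    expected = n_roi * (n_roi - 1) // 2
    if vec.shape != (expected,):
        raise ValueError(f"expected {expected} features for R={n_roi}")
    out = np.zeros((n_roi, n_roi))
    iu = np.triu_indices(n_roi, k=1)
    out[iu] = vec
    return out + out.T


def stack_windows(windowed_fcs) -> tuple[np.ndarray, list[tuple[str, int]]]:
    """Pool the windows of several sessions into one N x E feature matrix.

    Returns the matrix plus a (subject_id, n_windows) index preserving order,
    used to split pooled labels back per subject.
    """
    feats, index = [], []
    for wfc in windowed_fcs:
        iu = np.triu_indices(wfc.n_rois, k=1)
        feats.append(wfc.z_fc[:, iu[0], iu[1]])
        index.append((wfc.subject_id, wfc.n_windows))
    return np.vstack(feats), index


@dataclass
class StateModel:
    """k-means solution over the pooled baseline windows."""

    k: int
    centroids: np.ndarray  # k x E, element-wise means of member windows
    labels: np.ndarray  # pooled window labels, values 1..k
    inertia: float  # total within-cluster correlation distance
    k_candidates: tuple[int, ...] = ()
    distortion_curve: dict[int, float] = field(default_factory=dict)
    converged: bool = True

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.min() < 1 or self.labels.max() > self.k:
            raise ValueError("labels must lie in 1..k")


def _corr_rows(x: np.ndarray) -> np.ndarray:
    """Rows centred and scaled to unit norm (for Pearson via dot product)."""
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(xc, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("constant feature vector: correlation undefined")
    return xc / norms


def _lloyd_once(
    x: np.ndarray, xn: np.ndarray, k: int, rng: np.random.Generator, max_iter: int
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    n = x.shape[0]
    centers = x[rng.choice(n, size=k, replace=False)].copy()
    labels = np.full(n, -1)
    converged = False
    for _ in range(max_iter):
        corr = xn @ _corr_rows(centers).T  # N x k
        new_labels = np.argmax(corr, axis=1)
        # empty clusters: re-seed with the currently worst-fit window
        for s in range(k):
            if not np.any(new_labels == s):
                worst = np.argmin(corr[np.arange(n), new_labels])
                new_labels[worst] = s
                corr[worst, s] = 1.0
        if np.array_equal(new_labels, labels):
            converged = True
            break
        labels = new_labels
        for s in range(k):
            centers[s] = x[labels == s].mean(axis=0)
    # final assignment pass: labels are nearest-centroid consistent
    corr = xn @ _corr_rows(centers).T
    labels = np.argmax(corr, axis=1)
    inertia = float(np.sum(1.0 - corr[np.arange(n), labels]))
    return labels, centers, inertia, converged


def kmeans_correlation(
    x: np.ndarray,
    k: int,
    n_init: int = 100,
    seed: int = 0,
    max_iter: int = 500,
) -> StateModel:
    """Best-of-``n_init`` Lloyd k-means under the correlation distance.

    Each restart seeds the centroids with k distinct windows drawn
    uniformly; the restart with the smallest total within-cluster
    correlation distance wins.  States are then relabelled 1..k in order
    of descending occurrence.  Deterministic given ``seed``.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n <= k:
        raise ValueError(f"need more than k={k} windows, got {n}")
    xn = _corr_rows(x)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        labels, centers, inertia, conv = _lloyd_once(x, xn, k, rng, max_iter)
        if best is None or inertia < best[2]:
            best = (labels, centers, inertia, conv)
    labels, centers, inertia, conv = best
    # order states by descending occurrence; 1-based labels
    counts = np.bincount(labels, minlength=k)
    order = np.argsort(-counts, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return StateModel(
        k=k,
        centroids=centers[order],
        labels=remap[labels] + 1,
        inertia=inertia,
        converged=conv,
    )


def _dispersion_ratio(x: np.ndarray, xn: np.ndarray, model: StateModel) -> float:
    """Within-cluster over between-cluster correlation-distance dispersion."""
    centers = model.centroids
    corr_own = np.sum(
        xn * _corr_rows(centers)[model.labels - 1], axis=1
    )
    within = float(np.sum(1.0 - corr_own))
    grand = x.mean(axis=0, keepdims=True)
    counts = np.bincount(model.labels - 1, minlength=model.k)
    corr_cg = (_corr_rows(centers) * _corr_rows(grand)).sum(axis=1)
    between = float(np.sum(counts * (1.0 - corr_cg)))
    if between <= 0:
        return np.inf
    return within / between


def elbow_select(
    x: np.ndarray,
    kmin: int = 2,
    kmax: int = 9,
    n_init: int = 100,
    seed: int = 0,
    return_curve: bool = False,
):
    """Elbow choice of the state count over ``kmin..kmax``.

    For each candidate k the clustering validity index CVI(k) =
    within-dispersion / between-dispersion is computed from the best
    k-means solution; the selected k maximises the discrete curvature
    CVI(k-1) - 2 CVI(k) + CVI(k+1) over interior candidates.  Endpoints
    are returned only in degenerate cases: fewer than three candidates,
    or a curve that starts essentially at zero (CVI(kmin) < 0.05, i.e.
    the smallest candidate already yields near-perfectly tight clusters,
    as with well-separated point clouds), where the most parsimonious
    candidate wins.
    """
    if kmax < kmin:
        raise ValueError("kmax must be >= kmin")
    if kmin == kmax:
        return (kmin, {kmin: np.nan}) if return_curve else kmin
    ks = list(range(kmin, kmax + 1))
    xn = _corr_rows(np.asarray(x, dtype=float))
    curve: dict[int, float] = {}
    for i, k in enumerate(ks):
        model = kmeans_correlation(x, k, n_init=n_init, seed=seed + i)
        curve[k] = _dispersion_ratio(x, xn, model)
    if curve[kmin] < 0.05:
        return (kmin, curve) if return_curve else kmin
    if len(ks) == 2:
        k_sel = ks[int(np.argmin([curve[k] for k in ks]))]
        return (k_sel, curve) if return_curve else k_sel
    interior = ks[1:-1]
    curvature = [curve[k - 1] - 2 * curve[k] + curve[k + 1] for k in interior]
    k_sel = interior[int(np.argmax(curvature))]
    return (k_sel, curve) if return_curve else k_sel


def assign_to_states(windows, model: StateModel) -> np.ndarray:
    """Assign windows to the baseline state of maximum Pearson correlation.

    ``windows`` is a WindowedFC or an N x E feature matrix.  Ties break to
    the lowest state index.  Returns 1-based labels.
    """
    if hasattr(windows, "z_fc"):
        iu = np.triu_indices(windows.n_rois, k=1)
        feats = windows.z_fc[:, iu[0], iu[1]]
    else:
        feats = np.asarray(windows, dtype=float)
    if feats.shape[1] != model.centroids.shape[1]:
        raise ValueError("feature dimension does not match centroids")
    corr = _corr_rows(feats) @ _corr_rows(model.centroids).T
    # argmax returns the first (lowest-index) maximum, the tie-break we want
    return np.argmax(corr, axis=1) + 1


def occurrence_proportion(labels: np.ndarray, k: int) -> np.ndarray:
    """Per-state fraction of windows; sums to 1."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("no labels")
    if labels.min() < 1 or labels.max() > k:
        raise ValueError(f"labels outside 1..{k}")
    counts = np.bincount(labels - 1, minlength=k)
    return counts / labels.size
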