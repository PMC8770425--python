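"""Per-subject state-dependent indices.

For every subject-session and every state the package reports

* occurrence proportion — fraction of the session's windows in the state;
* dFC strength — the element-wise mean Fisher-z FC matrix over the
  windows assigned to the state (missing when the subject never visits it);
* average weighted local efficiency of the dFC strength matrix, computed
  on its non-negative part;
* static FC (sFC) — whole-scan Pearson correlation, Fisher z-transformed.

Local efficiency follows the weighted formulation of Rubinov & Sporns:
for node i with positive-weight neighbourhood N(i) of size k_i >= 2,

    E_loc(i) = sum_{j != h in N(i)} (w_ij w_ih / d_jh(N_i))^(1/3)
               / (k_i (k_i - 1)),

where d_jh(N_i) is the shortest path length between j and h inside the
subgraph induced by N(i) with connection lengths 1 / w^(1/3).  Weights are
first zeroed below 0 and rescaled to (0, 1] by the graph maximum (the
rescaling can be disabled).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path

from .states import occurrence_proportion
from .windows import R_CLIP, SubjectTimeSeries, WindowedFC

__all__ = [
    "StateMetrics",
    "dfc_strength",
    "static_fc",
    "local_efficiency",
    "compute_state_metrics",
]


@dataclass
class StateMetrics:
    subject_id: str
    session: str
    occurrence: np.ndarray  # k
    dfc_strength: np.ndarray  # k x R x R, NaN slices for unvisited states
    avg_local_efficiency: np.ndarray  # k, NaN for unvisited states
    sfc: np.ndarray  # R x R

    @property
    def k(self) -> int:
        return len(self.occurrence)

    def visited(self, state: int) -> bool:
        return bool(self.occurrence[state - 1] > 0)


def dfc_strength(windows: WindowedFC, labels: np.ndarray, state: int) -> np.ndarray | None:
    """Mean z-FC over the windows assigned to ``state`` (1-based); None if unvisited."""
    labels = np.asarray(labels)
    if len(labels) != windows.n_windows:
        raise ValueError("labels are not aligned to windows")
    member = labels == state
    if not np.any(member):
        return None
    return windows.z_fc[member].mean(axis=0)


def static_fc(ts: SubjectTimeSeries) -> np.ndarray:
    """Whole-scan Pearson correlation, Fisher z, zero diagonal."""
    data = ts.data
    if np.any(data.std(axis=0) == 0):
        bad = np.where(data.std(axis=0) == 0)[0]
        raise ValueError(f"constant ROI column(s): {bad.tolist()}")
    r = np.clip(np.corrcoef(data.T), -R_CLIP, R_CLIP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    return z


def local_efficiency(
    w: np.ndarray, rescale: bool = True
) -> tuple[np.ndarray, float]:
    """Weighted local efficiency per node and its average over all nodes.

    Negative weights are set to zero first; the diagonal is ignored.  With
    ``rescale=True`` (default) the non-negative weights are divided by their
    maximum so path lengths are computed on weights in (0, 1].
    """
    w = np.asarray(w, dtype=float)
    n = w.shape[0]
    if w.shape != (n, n):
        raise ValueError("expected a square matrix")
    if np.abs(w - w.T).max() > 1e-10:
        raise ValueError("weight matrix is not symmetric")
    w = np.where(w > 0, w, 0.0)
    np.fill_diagonal(w, 0.0)
    if rescale and w.max() > 0:
        w = w / w.max()
    eloc = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(w[i] > 0)
        k_i = len(nbrs)
        if k_i < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        with np.errstate(divide="ignore"):
            lengths = np.where(sub > 0, 1.0 / np.cbrt(sub), np.inf)
        np.fill_diagonal(lengths, 0.0)
        d = shortest_path(lengths, method="D", directed=False)
        wi = w[i, nbrs]
        with np.errstate(divide="ignore"):
            inv_d = np.where(d > 0, 1.0 / d, 0.0)
        np.fill_diagonal(inv_d, 0.0)
        terms = np.cbrt(np.outer(wi, wi) * inv_d)
        eloc[i] = terms.sum() / (k_i * (k_i - 1))
    return eloc, float(eloc.mean())


def compute_state_metrics(
    ts: SubjectTimeSeries,
    windows: WindowedFC,
    labels: np.ndarray,
    k: int,
) -> StateMetrics:
    """All state-dependent indices for one subject-session."""
    n_roi = windows.n_rois
    occurrence = occurrence_proportion(labels, k)
    strength = np.full((k, n_roi, n_roi), np.nan)
    eff = np.full(k, np.nan)
    for s in range(1, k + 1):
        m = dfc_strength(windows, labels, s)
        if m is None:
            continue
        strength[s - 1] = m
        eff[s - 1] = local_efficiency(m)[1]
    return StateMetrics(
        subject_id=ts.subject_id,
        session=ts.session,
        occurrence=occurrence,
        dfc_strength=strength,
        avg_local_efficiency=eff,
        sfc=static_fc(ts),
    )
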