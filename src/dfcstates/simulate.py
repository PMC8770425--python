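"""Synthetic state-switching BOLD cohort generator.

The generator emulates the statistical structure the analysis pipeline
assumes: each subject's 36-ROI series follows a hidden-Markov switching
multivariate Gaussian — at every TR a state-specific block-structured
covariance generates the innovation, an AR(1) filter adds temporal
smoothness, and white observation noise is added on top.  Group structure
enters in two places only:

* occupancy — the Markov transition matrices are dwell-biased (diagonal
  0.9) with patients tilted towards states 1 and 3 and controls towards
  state 2;
* one edge — in state 2 the left amygdala - left cuneus correlation is
  attenuated by ``delta`` in patients.

Treatment outcome (HAMD reduction rate) is a linear function of the
subject's realised state-2 connectivity (loaded on the medial frontal
gyrus seed) plus noise, targeted at roughly 60% responders; follow-up
sessions are simulated for treated patients, with responders' transition
matrix moved to the control values (occupancy normalisation) and
non-responders unchanged.

Everything is reproducible from (spec, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .atlas import ROIAtlas, atlas_masks, load_roi_table
from .windows import SubjectTimeSeries

__all__ = [
    "SyntheticCohortSpec",
    "SyntheticCohort",
    "make_state_covariances",
    "stationary_distribution",
    "transition_matrix",
    "simulate_subject",
    "simulate_cohort",
    "render_nifti",
]

logger = logging.getLogger(__name__)

#: 0-based indices of the planted deficit edge: left amygdala, left cuneus.
AMYGDALA_L = 19
CUNEUS_L = 31
#: 0-based index of the medial frontal gyrus seed carrying the outcome signal.
MFG = 25


@dataclass
class SyntheticCohortSpec:
    """Study conditions for one synthetic cohort."""

    n_mdd: int = 20
    n_hc: int = 20
    n_post: int = 20  # MDD subjects with a follow-up session and outcome
    t_points: int = 230
    tr_seconds: float = 2.0
    k_true: int = 4
    within_r: float = 0.3  # within-network block correlation, all states
    between_base: float = 0.05  # unspecified inter-network correlation
    between_strong: float = 0.4  # state-defining inter-network correlation
    delta: float = 0.3  # MDD attenuation of the state-2 amygdala-cuneus edge
    dwell: float = 0.9  # transition-matrix diagonal
    # off-diagonal transition preferences (normalised per row over j != i);
    # patients favour states 1 and 3, controls state 2
    pref_mdd: tuple[float, ...] = (0.34, 0.14, 0.32, 0.20)
    pref_hc: tuple[float, ...] = (0.18, 0.42, 0.12, 0.28)
    ar_phi: float = 0.3
    noise_sd: float = 0.2
    # individual differences: each subject's state-2 MFG connectivity row is
    # scaled by (1 + trait_sd * u), u ~ N(0, 1) truncated to +/- 2.5
    # (scale factor floored at 0.1 so correlations keep their sign)
    trait_sd: float = 0.5
    # outcome model: RR = rr_mean + rr_beta * u + N(0, rr_sd)
    rr_mean: float = 55.0
    rr_beta: float = 15.0
    rr_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_post > self.n_mdd:
            raise ValueError("n_post cannot exceed n_mdd")
        if not (0 < self.dwell < 1):
            raise ValueError("dwell must be in (0, 1)")


def _nearest_pd(mat: np.ndarray, loading: float = 0.05, min_eig: float = 1e-6) -> np.ndarray:
    """Eigenvalue clipping, diagonal loading and diagonal re-normalisation.

    The block construction can produce indefinite or near-singular
    matrices (between-block values above within-block ones); negative
    eigenvalues are clipped, a small ridge keeps the smallest eigenvalue
    away from zero so simulated series are not degenerate, and the result
    is rescaled back to unit diagonal.
    """
    sym = 0.5 * (mat + mat.T)
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() <= min_eig:
        logger.info("template repaired: min eigenvalue %.2e clipped", vals.min())
        vals = np.clip(vals, min_eig, None)
        sym = (vecs * vals) @ vecs.T
    fixed = (1 - loading) * sym + loading * np.eye(sym.shape[0])
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    return 0.5 * (fixed + fixed.T)


def make_state_covariances(
    spec: SyntheticCohortSpec, atlas: ROIAtlas | None = None, group: str = "HC"
) -> list[np.ndarray]:
    """The k_true block-structured state correlation templates for one group."""
    atlas = atlas or load_roi_table()
    n = len(atlas)
    nets = [atlas.network_members(i) for i in (1, 2, 3, 4)]

    def blank() -> np.ndarray:
        c = np.full((n, n), spec.between_base)
        for members in nets:
            c[np.ix_(members, members)] = spec.within_r
        np.fill_diagonal(c, 1.0)
        return c

    def couple(c: np.ndarray, a: int, b: int) -> None:
        c[np.ix_(nets[a], nets[b])] = spec.between_strong
        c[np.ix_(nets[b], nets[a])] = spec.between_strong

    s1 = blank()
    couple(s1, 0, 1)
    s2 = blank()
    couple(s2, 1, 2)
    couple(s2, 1, 3)
    couple(s2, 2, 3)
    if group == "MDD":
        weakened = spec.between_strong - spec.delta
        s2[AMYGDALA_L, CUNEUS_L] = weakened
        s2[CUNEUS_L, AMYGDALA_L] = weakened
    s3 = blank()
    s4 = blank()
    couple(s4, 0, 1)
    couple(s4, 3, 0)
    couple(s4, 3, 1)
    templates = [_nearest_pd(s) for s in (s1, s2, s3, s4)[: spec.k_true]]
    for t in templates:
        if np.linalg.eigvalsh(t).min() <= 1e-8:
            raise ValueError("state template not repairable to positive definite")
    return templates


def transition_matrix(spec: SyntheticCohortSpec, group: str) -> np.ndarray:
    """Row-stochastic dwell-biased transition matrix for one group."""
    pref = np.asarray(spec.pref_mdd if group == "MDD" else spec.pref_hc, dtype=float)
    k = spec.k_true
    if k == 1:
        return np.ones((1, 1))
    if len(pref) < k:
        raise ValueError("preference vector shorter than k_true")
    pref = pref[:k] / pref[:k].sum()  # reduced state counts reuse the prefix
    p = np.zeros((k, k))
    for i in range(k):
        off = pref.copy()
        off[i] = 0.0
        p[i] = (1 - spec.dwell) * off / off.sum()
        p[i, i] = spec.dwell
    return p


def stationary_distribution(p: np.ndarray) -> np.ndarray:
    """Left eigenvector of the transition matrix at eigenvalue 1."""
    vals, vecs = np.linalg.eig(p.T)
    idx = np.argmin(np.abs(vals - 1.0))
    pi = np.real(vecs[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def simulate_subject(
    spec: SyntheticCohortSpec,
    group: str,
    session: str,
    seed: int,
    subject_id: str = "sub",
    templates: list[np.ndarray] | None = None,
    transitions: np.ndarray | None = None,
) -> tuple[SubjectTimeSeries, np.ndarray]:
    """One session's series plus the true state path (1-based labels)."""
    rng = np.random.default_rng(seed)
    if templates is None:
        templates = make_state_covariances(spec, group=group)
    if transitions is None:
        transitions = transition_matrix(spec, group)
    chols = [np.linalg.cholesky(t) for t in templates]
    k = spec.k_true
    pi = stationary_distribution(transitions)
    u = rng.random(spec.t_points)
    cum = np.cumsum(transitions, axis=1)
    path = np.empty(spec.t_points, dtype=int)
    path[0] = int(np.searchsorted(np.cumsum(pi), u[0]))
    for t in range(1, spec.t_points):
        path[t] = int(np.searchsorted(cum[path[t - 1]], u[t]))
    path = np.minimum(path, k - 1)
    n_roi = templates[0].shape[0]
    innov = rng.standard_normal((spec.t_points, n_roi))
    for s in range(k):
        member = path == s
        if np.any(member):
            innov[member] = innov[member] @ chols[s].T
    phi = spec.ar_phi
    scale = np.sqrt(1.0 - phi**2)
    driven = scale * innov
    driven[0] = innov[0]  # stationary start: first sample at full variance
    x = lfilter([1.0], [1.0, -phi], driven, axis=0)
    if spec.noise_sd > 0:
        x = x + spec.noise_sd * rng.standard_normal(x.shape)
    ts = SubjectTimeSeries(
        subject_id=subject_id,
        group=group,
        session=session,
        data=x,
        tr_seconds=spec.tr_seconds,
    )
    return ts, path + 1


def _trait_templates(
    templates: list[np.ndarray], trait: float, trait_sd: float
) -> list[np.ndarray]:
    """Subject-specific templates: scale the state-2 MFG row by the trait."""
    out = [t.copy() for t in templates]
    s2 = out[1]
    factor = max(1.0 + trait_sd * trait, 0.1)
    s2[MFG, :] *= factor
    s2[:, MFG] *= factor
    s2[MFG, MFG] = 1.0
    out[1] = _nearest_pd(s2, loading=0.0)
    return out


@dataclass
class SyntheticCohort:
    spec: SyntheticCohortSpec
    timeseries: list[SubjectTimeSeries]
    clinical: pd.DataFrame
    true_paths: dict[tuple[str, str], np.ndarray]
    templates: dict[str, list[np.ndarray]]
    transitions: dict[str, np.ndarray]
    traits: dict[str, float] = field(default_factory=dict)

    def sessions(self, session: str) -> list[SubjectTimeSeries]:
        return [t for t in self.timeseries if t.session == session]


def simulate_cohort(spec: SyntheticCohortSpec) -> SyntheticCohort:
    """Full two-group cohort with baseline (all) and follow-up (n_post MDD).

    The clinical table carries subject id, group, age, sex, mean FD, HAMD at
    baseline and week 12 (completers only), the reduction rate RR and the
    responder flag.  Ages, sex ratios, motion and baseline severity follow
    the distributions documented in the methods note.
    """
    root = np.random.SeedSequence([spec.seed, 982451653])
    seeds = root.generate_state(4 * (spec.n_mdd + spec.n_hc) + 8) % (2**31)
    rng = np.random.default_rng(seeds[-1])
    templates = {
        "MDD": make_state_covariances(spec, group="MDD"),
        "HC": make_state_covariances(spec, group="HC"),
    }
    transitions = {
        "MDD": transition_matrix(spec, "MDD"),
        "HC": transition_matrix(spec, "HC"),
    }
    timeseries: list[SubjectTimeSeries] = []
    paths: dict[tuple[str, str], np.ndarray] = {}
    rows = []
    si = 0
    traits: dict[str, float] = {}
    subject_templates: dict[str, list[np.ndarray]] = {}
    for g, n in (("MDD", spec.n_mdd), ("HC", spec.n_hc)):
        for j in range(n):
            sid = f"{g.lower()}{j + 1:03d}"
            traits[sid] = float(np.clip(rng.standard_normal(), -2.5, 2.5))
            subject_templates[sid] = _trait_templates(
                templates[g], traits[sid], spec.trait_sd
            )
            ts, path = simulate_subject(
                spec,
                g,
                "baseline",
                int(seeds[si]),
                subject_id=sid,
                templates=subject_templates[sid],
                transitions=transitions[g],
            )
            si += 1
            timeseries.append(ts)
            paths[(sid, "baseline")] = path
            rows.append(
                {
                    "subject_id": sid,
                    "group": g,
                    "age": float(np.round(np.clip(rng.normal(27 if g == "MDD" else 29, 9), 18, 60), 1)),
                    "sex": "M" if rng.random() < 0.33 else "F",
                    "mean_fd": float(np.round(np.clip(rng.normal(0.11, 0.05), 0.02, 0.5), 4)),
                    "hamd_baseline": int(np.clip(np.round(rng.normal(28, 6)), 12, 50)),
                }
            )
    clinical = pd.DataFrame(rows)
    # outcome model on patients: RR tied to the planted state-2 MFG trait
    mdd_ids = clinical.loc[clinical.group == "MDD", "subject_id"].tolist()
    f = np.array([traits[s] for s in mdd_ids])
    rr_raw = spec.rr_mean + spec.rr_beta * f + spec.rr_sd * rng.standard_normal(
        len(mdd_ids)
    )
    completers = mdd_ids[: spec.n_post]
    clinical["hamd_week12"] = pd.array([pd.NA] * len(clinical), dtype="Int64")
    for sid, rr in zip(mdd_ids, rr_raw):
        if sid not in completers:
            continue
        base = int(clinical.loc[clinical.subject_id == sid, "hamd_baseline"].iloc[0])
        week12 = int(np.clip(np.round(base * (1 - rr / 100.0)), 0, base + 10))
        clinical.loc[clinical.subject_id == sid, "hamd_week12"] = week12
    clinical["rr"] = np.where(
        clinical["hamd_week12"].notna(),
        100.0
        * (clinical["hamd_baseline"] - clinical["hamd_week12"].astype(float))
        / clinical["hamd_baseline"],
        np.nan,
    )
    clinical["responder"] = pd.array(
        [pd.NA if np.isnan(r) else r > 50.0 for r in clinical["rr"]], dtype="boolean"
    )
    # follow-up sessions: responders shift to the control transition matrix
    for sid in completers:
        row = clinical.loc[clinical.subject_id == sid].iloc[0]
        trans = transitions["HC"] if bool(row.responder) else transitions["MDD"]
        ts, path = simulate_subject(
            spec,
            "MDD",
            "post",
            int(seeds[si]),
            subject_id=sid,
            templates=subject_templates[sid],
            transitions=trans,
        )
        si += 1
        timeseries.append(ts)
        paths[(sid, "post")] = path
    return SyntheticCohort(
        spec=spec,
        timeseries=timeseries,
        clinical=clinical,
        true_paths=paths,
        templates=templates,
        transitions=transitions,
        traits=traits,
    )


def render_nifti(
    ts: SubjectTimeSeries,
    atlas: ROIAtlas,
    background_sd: float = 0.1,
    seed: int = 0,
):
    """Render a series as a 4D NIfTI image on the atlas grid.

    Every voxel of ROI i carries the ROI's signal (overlapping ROI voxels
    sum their signals, with a warning); all voxels receive independent
    Gaussian background noise of ``background_sd``.
    """
    import nibabel as nib

    masks = atlas_masks(atlas)
    shape = tuple(atlas.grid.shape) + (ts.n_timepoints,)
    rng = np.random.default_rng(seed)
    vol = (
        rng.standard_normal(shape).astype(np.float32) * background_sd
        if background_sd > 0
        else np.zeros(shape, dtype=np.float32)
    )
    hit = np.zeros(atlas.grid.shape, dtype=bool)
    overlap = False
    for i, m in enumerate(masks):
        if np.any(hit[m[:, 0], m[:, 1], m[:, 2]]):
            overlap = True
        hit[m[:, 0], m[:, 1], m[:, 2]] = True
        vol[m[:, 0], m[:, 1], m[:, 2], :] += ts.data[:, i].astype(np.float32)
    if overlap:
        logger.warning("overlapping ROI masks: voxel signals summed")
    return nib.Nifti1Image(vol, atlas.grid.affine)
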