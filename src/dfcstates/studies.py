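"""Repeated-simulation studies: power and calibration of the pipeline.

These drivers run the generator-plus-analysis loop many times to measure
operating characteristics under known ground truth:

* detection power for the planted group effects (state-2 occupancy shift
  and the amygdala-cuneus state-2 edge deficit), end-to-end through
  window estimation, state assignment and covariate-adjusted group tests;
* type-I error of the GLM group test under a null (no planted difference);
* rejection-rate calibration of the permutation prediction test under a
  null outcome.

The power loop keeps the full 36-ROI estimation chain but runs on
shortened scans with windows sampled every other TR, and assigns windows
to the known state templates instead of re-discovering them each
repetition; state discovery itself is validated separately on a
full-scale cohort.  These problem sizes are the package's documented
defaults for repeated studies (see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .prediction import loocv_predict, permutation_test
from .simulate import (
    AMYGDALA_L,
    CUNEUS_L,
    SyntheticCohortSpec,
    make_state_covariances,
    simulate_subject,
    transition_matrix,
)
from .states import StateModel, assign_to_states, occurrence_proportion, vectorize_fc
from .stats import glm_group_test
from .windows import compute_windowed_fc, make_taper

__all__ = [
    "PowerStudyResult",
    "template_state_model",
    "planted_effect_power",
    "glm_type1_error",
    "prediction_null_calibration",
    "state_count_selection",
    "pure_window_ari",
]


def template_state_model(templates: list[np.ndarray]) -> StateModel:
    """A StateModel whose centroids are the (Fisher-z) planted templates.

    Used by the repeated power studies to hold state identity fixed;
    assignment works on Pearson correlation, so the monotone z-transform
    of the template correlations is the natural centroid scale.
    """
    cents = []
    for t in templates:
        c = t.copy()
        np.fill_diagonal(c, 0.0)
        cents.append(np.arctanh(np.clip(vectorize_fc(c), -0.999999, 0.999999)))
    k = len(cents)
    return StateModel(
        k=k, centroids=np.vstack(cents), labels=np.arange(1, k + 1), inertia=0.0
    )


def _covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "age": rng.normal(28, 10, n),
            "sex": (rng.random(n) < 0.33).astype(float),
            "mean_fd": np.clip(rng.normal(0.11, 0.05, n), 0.02, 0.5),
        }
    )


@dataclass
class PowerStudyResult:
    occupancy_power: float
    edge_power: float
    n_reps: int
    occupancy_t: np.ndarray
    edge_t: np.ndarray


def planted_effect_power(
    n_reps: int = 200,
    spec: SyntheticCohortSpec | None = None,
    t_points: int = 230,
    step: int = 7,
    lam: float = 0.1,
    alpha: float = 0.05,
    seed: int = 0,
    glasso_tol: float = 1e-3,
) -> PowerStudyResult:
    """Detection power for the planted occupancy shift and edge deficit.

    Each repetition simulates a fresh two-group cohort, estimates windowed
    FC, assigns windows to the planted state templates, and runs the
    covariate-adjusted GLM on (a) state-2 occurrence proportion and (b) the
    state-2 amygdala-cuneus dFC-strength edge.  A detection is a two-sided
    p < alpha with the planted sign (patients lower in both).
    """
    spec = spec or SyntheticCohortSpec()
    spec = replace(spec, t_points=t_points, n_post=0)
    taper = make_taper()
    templates = {
        "MDD": make_state_covariances(spec, group="MDD"),
        "HC": make_state_covariances(spec, group="HC"),
    }
    transitions = {g: transition_matrix(spec, g) for g in ("MDD", "HC")}
    model = template_state_model(templates["HC"])
    root = np.random.SeedSequence([seed, 77003])
    rep_seeds = root.generate_state(n_reps * 2 + 1) % (2**31)
    occ_t = np.empty(n_reps)
    edge_t = np.empty(n_reps)
    occ_hits = 0
    edge_hits = 0
    for rep in range(n_reps):
        rng = np.random.default_rng(int(rep_seeds[2 * rep]))
        sub_seeds = rng.integers(0, 2**31, size=spec.n_mdd + spec.n_hc)
        occ2, edge, group = [], [], []
        for i, g in enumerate(["MDD"] * spec.n_mdd + ["HC"] * spec.n_hc):
            ts, _ = simulate_subject(
                spec, g, "baseline", int(sub_seeds[i]),
                templates=templates[g], transitions=transitions[g],
            )
            wfc = compute_windowed_fc(ts, taper, step=step, lam=lam, tol=glasso_tol)
            labels = assign_to_states(wfc, model)
            occ2.append(occurrence_proportion(labels, spec.k_true)[1])
            member = labels == 2
            if np.any(member):
                edge.append(wfc.z_fc[member, AMYGDALA_L, CUNEUS_L].mean())
            else:
                edge.append(np.nan)
            group.append(1.0 if g == "MDD" else 0.0)
        group = np.asarray(group)
        cov = _covariates(rng, len(group))
        res_occ = glm_group_test(np.asarray(occ2), group, cov)
        occ_t[rep] = res_occ.t_statistic
        occ_hits += res_occ.p_value < alpha and res_occ.t_statistic < 0
        edge_arr = np.asarray(edge)
        keep = np.isfinite(edge_arr)
        res_edge = glm_group_test(
            edge_arr[keep], group[keep], cov.loc[keep].reset_index(drop=True)
        )
        edge_t[rep] = res_edge.t_statistic
        edge_hits += res_edge.p_value < alpha and res_edge.t_statistic < 0
    return PowerStudyResult(
        occupancy_power=occ_hits / n_reps,
        edge_power=edge_hits / n_reps,
        n_reps=n_reps,
        occupancy_t=occ_t,
        edge_t=edge_t,
    )


def state_count_selection(
    seed: int = 0,
    lam: float = 0.1,
    n_init: int = 10,
    k_min: int = 2,
    k_max: int = 9,
):
    """Elbow-based state-count selection on a full default synthetic cohort.

    Simulates the default two-group cohort (20 + 20 subjects, 230 TRs),
    estimates all baseline windowed FC at the fixed penalty, pools the
    windows and runs the elbow sweep.  Returns ``(selected_k, curve,
    pooled_features, cohort)`` so callers can reuse the expensive products.
    """
    from .simulate import simulate_cohort
    from .states import elbow_select, stack_windows

    spec = SyntheticCohortSpec(seed=seed)
    cohort = simulate_cohort(spec)
    taper = make_taper()
    wfcs = [
        compute_windowed_fc(ts, taper, lam=lam, tol=1e-3)
        for ts in cohort.sessions("baseline")
    ]
    x, index = stack_windows(wfcs)
    k_sel, curve = elbow_select(
        x, k_min, k_max, n_init=n_init, seed=seed, return_curve=True
    )
    return k_sel, curve, x, cohort


def pure_window_ari(
    seed: int = 0,
    n_per_state: int = 200,
    n_init: int = 100,
    lam: float = 0.1,
) -> float:
    """Adjusted Rand agreement of correlation k-means with planted states.

    Windows are generated entirely inside single states (the only windows
    whose planted label is well defined), passed through the same taper /
    graphical-LASSO / Fisher-z chain as the pipeline, and clustered at the
    true k.  Returns the adjusted Rand index against the planted labels.
    """
    from scipy.signal import lfilter
    from sklearn.metrics import adjusted_rand_score

    from .states import kmeans_correlation
    from .windows import cov_to_fisher_z, glasso_fit, weighted_window_cov

    spec = SyntheticCohortSpec()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 77011]).generate_state(1)[0])
    templates = make_state_covariances(spec, group="HC")
    chols = [np.linalg.cholesky(t) for t in templates]
    taper = make_taper()
    length = taper.length_trs
    phi, scale = spec.ar_phi, np.sqrt(1 - spec.ar_phi**2)
    feats, labels = [], []
    for s in range(spec.k_true):
        for _ in range(n_per_state):
            e = rng.standard_normal((length, templates[0].shape[0])) @ chols[s].T
            driven = scale * e
            driven[0] = e[0]
            x = lfilter([1.0], [1.0, -phi], driven, axis=0)
            x = x + spec.noise_sd * rng.standard_normal(x.shape)
            cov = weighted_window_cov(x, taper)
            d = np.diag(cov)
            cov = cov / np.sqrt(np.outer(d, d))
            est, _ = glasso_fit(cov, lam, tol=1e-3)
            feats.append(vectorize_fc(cov_to_fisher_z(est)))
            labels.append(s + 1)
    model = kmeans_correlation(np.array(feats), spec.k_true, n_init=n_init, seed=seed)
    return float(adjusted_rand_score(labels, model.labels))


def prediction_signal_power(
    n_reps: int = 50,
    spec: SyntheticCohortSpec | None = None,
    step: int = 7,
    lam: float = 0.1,
    n_perm: int = 500,
    seed: int = 0,
    return_details: bool = False,
):
    """Power of the permutation-tested LOOCV prediction on planted cohorts.

    Each repetition simulates a default cohort (with its planted outcome
    trait), estimates windowed FC, assigns windows to the planted state
    templates, builds per-ROI state-2 features for the patients with an
    outcome, and runs the LOOCV + permutation test; a success is a model
    declared significant by the 95th-percentile rule.  The static-FC
    control model's rejection rate is returned alongside.
    """
    from .metrics import static_fc
    from .prediction import build_features, permutation_test
    from .simulate import simulate_cohort
    from .states import assign_to_states

    spec = spec or SyntheticCohortSpec()
    taper = make_taper()
    root = np.random.SeedSequence([seed, 77013])
    rep_seeds = root.generate_state(n_reps * 2) % (2**31)
    hits = 0
    sfc_hits = 0
    r_values = []
    for rep in range(n_reps):
        cohort = simulate_cohort(
            SyntheticCohortSpec(
                **{**spec.__dict__, "seed": int(rep_seeds[2 * rep])}
            )
        )
        model = template_state_model(cohort.templates["HC"])
        cl = cohort.clinical.set_index("subject_id")
        mats, sfc_mats = {}, {}
        for ts in cohort.sessions("baseline"):
            if ts.group != "MDD" or not np.isfinite(cl.loc[ts.subject_id, "rr"]):
                continue
            wfc = compute_windowed_fc(ts, taper, step=step, lam=lam, tol=1e-3)
            member = assign_to_states(wfc, model) == 2
            if not np.any(member):
                continue
            mats[ts.subject_id] = wfc.z_fc[member].mean(axis=0)
            sfc_mats[ts.subject_id] = static_fc(ts)
        x, kept = build_features(mats)
        y = cl.loc[kept, "rr"].to_numpy(float)
        res = permutation_test(x, y, n_perm=n_perm, seed=int(rep_seeds[2 * rep + 1]))
        hits += res.significant
        r_values.append(res.pearson_r)
        xs, kept_s = build_features({s: sfc_mats[s] for s in kept})
        res_s = permutation_test(
            xs, y, n_perm=n_perm, seed=int(rep_seeds[2 * rep + 1]) + 1
        )
        sfc_hits += res_s.significant
    power = hits / n_reps
    sfc_rate = sfc_hits / n_reps
    if return_details:
        return power, sfc_rate, np.array(r_values)
    return power, sfc_rate


def glm_type1_error(
    n_measures: int = 1000,
    n_per_group: int = 20,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Type-I error of the covariate-adjusted GLM on null measures.

    Each measure draws both groups from the same distribution (no planted
    difference); reported is the fraction of two-sided p < alpha.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 77005]).generate_state(1)[0])
    group = np.concatenate([np.ones(n_per_group), np.zeros(n_per_group)])
    hits = 0
    for _ in range(n_measures):
        y = rng.standard_normal(2 * n_per_group)
        cov = _covariates(rng, 2 * n_per_group)
        hits += glm_group_test(y, group, cov).p_value < alpha
    return hits / n_measures


def prediction_null_calibration(
    n_reps: int = 200,
    n_subjects: int = 20,
    n_features: int = 36,
    n_perm: int = 500,
    seed: int = 0,
) -> float:
    """Rejection rate of the permutation prediction test under a null outcome.

    Features follow the empirical scale of state FC summaries; outcomes are
    independent of them, so the 95th-percentile rule should reject at
    roughly its nominal 5%.
    """
    root = np.random.SeedSequence([seed, 77007])
    rep_seeds = root.generate_state(n_reps * 2) % (2**31)
    rejections = 0
    for rep in range(n_reps):
        rng = np.random.default_rng(int(rep_seeds[2 * rep]))
        x = 0.2 + 0.1 * rng.standard_normal((n_subjects, n_features))
        y = 55 + 18 * rng.standard_normal(n_subjects)
        res = permutation_test(x, y, n_perm=n_perm, seed=int(rep_seeds[2 * rep + 1]))
        rejections += res.significant
    return rejections / n_reps
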