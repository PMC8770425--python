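"""Pipeline orchestration: baseline, longitudinal and prediction stages.

A :class:`PipelineConfig` gathers every tunable parameter with the study's
default values (window 22 TRs with sigma 3 taper, step 1 TR, 5-fold x 50
repetition penalty selection, k candidates 2-9 with 100 k-means restarts,
alpha 0.05, FDR q 0.05, 10,000 outcome permutations).  A master seed fans
out to per-stage seeds through named spawn keys, so any stage can be re-run
independently and every run is reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import StateMetrics, compute_state_metrics
from .prediction import PredictionResult, build_features, loocv_predict, permutation_test
from .states import (
    StateModel,
    assign_to_states,
    elbow_select,
    kmeans_correlation,
    stack_windows,
)
from .stats import GroupStatResult, conjunction_mask, fdr_bh, glm_group_test, paired_t
from .windows import SubjectTimeSeries, WindowedFC, compute_windowed_fc, make_taper

logger = logging.getLogger(__name__)

_STAGE_KEYS = {"simulate": 0, "dfc": 1, "cluster": 2, "metrics": 3, "stats": 4, "predict": 5}


@dataclass
class PipelineConfig:
    window_length: int = 22
    window_sigma: float = 3.0
    window_step: int = 1
    lambda_grid: tuple[float, ...] | None = None  # None -> packaged default grid
    lambda_fixed: float | None = None  # skip CV when set
    cv_folds: int = 5
    cv_reps: int = 50
    k_min: int = 2
    k_max: int = 9
    k_fixed: int | None = None  # skip elbow selection when set
    n_init: int = 100
    alpha: float = 0.05
    fdr_q: float = 0.05
    conjunction: str = "union"
    feature_mode: str = "roi_mean"
    n_perm: int = 10000
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        ss = np.random.SeedSequence([self.seed, _STAGE_KEYS[stage]])
        return int(ss.generate_state(1)[0] % (2**31))

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        if raw.get("lambda_grid") is not None:
            raw["lambda_grid"] = tuple(raw["lambda_grid"])
        return cls(**raw)


@dataclass
class BaselineResult:
    windowed: dict[str, WindowedFC]  # subject_id -> baseline windows
    model: StateModel
    labels: dict[str, np.ndarray]  # subject_id -> window state labels
    metrics: dict[str, StateMetrics]
    occupancy_tests: list[GroupStatResult]
    efficiency_tests: list[GroupStatResult]
    edge_tests: dict[int, pd.DataFrame]  # state -> edgewise results in mask
    selected_k: int
    distortion_curve: dict[int, float]


def _covariate_frame(clinical: pd.DataFrame, subject_ids: list[str]) -> pd.DataFrame:
    cl = clinical.set_index("subject_id").loc[subject_ids]
    return pd.DataFrame(
        {
            "age": cl["age"].to_numpy(float),
            "sex": (cl["sex"] == "M").astype(float).to_numpy(),
            "mean_fd": cl["mean_fd"].to_numpy(float),
        }
    )


def _group_indicator(clinical: pd.DataFrame, subject_ids: list[str]) -> np.ndarray:
    cl = clinical.set_index("subject_id").loc[subject_ids]
    return (cl["group"] == "MDD").astype(float).to_numpy()


def run_baseline(
    timeseries: list[SubjectTimeSeries],
    clinical: pd.DataFrame,
    config: PipelineConfig,
) -> BaselineResult:
    """Baseline workflow: windowed FC, state discovery, indices, group tests.

    When the cohort contains a single group the state analysis still runs
    but the group comparisons are skipped.
    """
    if clinical is None or len(clinical) == 0:
        raise ValueError("clinical table is required before computation starts")
    baseline = [t for t in timeseries if t.session == "baseline"]
    if not baseline:
        raise ValueError("no baseline sessions")
    taper = make_taper(config.window_length, config.window_sigma)
    grid = np.asarray(config.lambda_grid) if config.lambda_grid else None
    dfc_seed = config.stage_seed("dfc")
    windowed: dict[str, WindowedFC] = {}
    for i, ts in enumerate(baseline):
        try:
            windowed[ts.subject_id] = compute_windowed_fc(
                ts,
                taper,
                step=config.window_step,
                lam=config.lambda_fixed,
                grid=grid,
                folds=config.cv_folds,
                reps=config.cv_reps,
                seed=dfc_seed + i,
            )
        except Exception as err:
            raise RuntimeError(
                f"dfc stage failed for subject {ts.subject_id}: {err}"
            ) from err
        logger.info("dfc: %s done (lambda=%.4g)", ts.subject_id, windowed[ts.subject_id].lambda_selected)
    order = [ts.subject_id for ts in baseline]
    x, index = stack_windows([windowed[s] for s in order])
    cluster_seed = config.stage_seed("cluster")
    curve: dict[int, float] = {}
    if config.k_fixed is not None:
        k = config.k_fixed
    else:
        k, curve = elbow_select(
            x, config.k_min, config.k_max, n_init=config.n_init,
            seed=cluster_seed, return_curve=True,
        )
    model = kmeans_correlation(x, k, n_init=config.n_init, seed=cluster_seed)
    model.k_candidates = tuple(range(config.k_min, config.k_max + 1))
    model.distortion_curve = curve
    splits = np.split(model.labels, np.cumsum([n for _, n in index])[:-1])
    labels = {sid: lab for (sid, _), lab in zip(index, splits)}
    ts_by_id = {t.subject_id: t for t in baseline}
    metrics = {
        sid: compute_state_metrics(ts_by_id[sid], windowed[sid], labels[sid], k)
        for sid in order
    }
    groups = set(clinical.loc[clinical.subject_id.isin(order), "group"])
    occupancy_tests: list[GroupStatResult] = []
    efficiency_tests: list[GroupStatResult] = []
    edge_tests: dict[int, pd.DataFrame] = {}
    if {"MDD", "HC"} <= groups:
        cov = _covariate_frame(clinical, order)
        grp = _group_indicator(clinical, order)
        occupancy_tests = _family_tests(
            {s: np.array([metrics[sid].occurrence[s - 1] for sid in order]) for s in range(1, k + 1)},
            grp, cov, "occurrence", config.fdr_q,
        )
        efficiency_tests = _family_tests(
            {s: np.array([metrics[sid].avg_local_efficiency[s - 1] for sid in order]) for s in range(1, k + 1)},
            grp, cov, "local_efficiency", config.fdr_q, allow_missing=True,
        )
        edge_tests = _edge_tests(metrics, order, grp, cov, k, config)
    else:
        logger.info("single-group cohort: group comparisons skipped")
    return BaselineResult(
        windowed=windowed,
        model=model,
        labels=labels,
        metrics=metrics,
        occupancy_tests=occupancy_tests,
        efficiency_tests=efficiency_tests,
        edge_tests=edge_tests,
        selected_k=k,
        distortion_curve=curve,
    )


def _family_tests(
    values_by_state: dict[int, np.ndarray],
    group: np.ndarray,
    covariates: pd.DataFrame,
    family: str,
    fdr_q: float,
    allow_missing: bool = False,
) -> list[GroupStatResult]:
    """Per-state GLM group tests with one FDR family across states."""
    results = []
    for s, y in values_by_state.items():
        if allow_missing:
            keep = np.isfinite(y)
            if keep.sum() < 4 or len(set(group[keep])) < 2:
                continue
            res = glm_group_test(
                y[keep], group[keep], covariates.loc[keep].reset_index(drop=True),
                measure=f"{family}_state{s}",
            )
        else:
            res = glm_group_test(y, group, covariates, measure=f"{family}_state{s}")
        res.family = family
        results.append(res)
    # degenerate measures (e.g. a state nobody visits) yield NaN p-values
    testable = [r for r in results if np.isfinite(r.p_value)]
    if testable:
        q, _ = fdr_bh(np.array([r.p_value for r in testable]), fdr_q)
        for r, qv in zip(testable, q):
            r.q_value = float(qv)
    return results


def _edge_tests(
    metrics: dict[str, StateMetrics],
    order: list[str],
    group: np.ndarray,
    covariates: pd.DataFrame,
    k: int,
    config: PipelineConfig,
) -> dict[int, pd.DataFrame]:
    """Edgewise dFC-strength group tests within the conjunction mask, per state."""
    out: dict[int, pd.DataFrame] = {}
    for s in range(1, k + 1):
        stack = np.array([metrics[sid].dfc_strength[s - 1] for sid in order])
        g1 = stack[group == 1]
        g2 = stack[group == 0]
        mask = conjunction_mask(g1, g2, alpha=config.alpha, combine=config.conjunction)
        iu = np.triu_indices(stack.shape[1], k=1)
        rows = []
        for i, j in zip(*iu):
            if not mask[i, j]:
                continue
            y = stack[:, i, j]
            keep = np.isfinite(y)
            if keep.sum() < 4 or len(set(group[keep])) < 2:
                continue
            res = glm_group_test(
                y[keep], group[keep], covariates.loc[keep].reset_index(drop=True),
                measure=f"edge_{i + 1}_{j + 1}",
            )
            if np.isfinite(res.p_value):
                rows.append((s, i + 1, j + 1, res.t_statistic, res.p_value))
        df = pd.DataFrame(rows, columns=["state", "roi_i", "roi_j", "t", "p"])
        if len(df):
            q, rej = fdr_bh(df["p"].to_numpy(), config.fdr_q)
            df["q"] = q
            df["reject"] = rej
        out[s] = df
    return out


@dataclass
class LongitudinalResult:
    post_labels: dict[str, np.ndarray]
    post_metrics: dict[str, StateMetrics]
    paired_tests: pd.DataFrame  # responder-split paired tests per state/measure


def run_longitudinal(
    timeseries: list[SubjectTimeSeries],
    clinical: pd.DataFrame,
    baseline: BaselineResult,
    config: PipelineConfig,
) -> LongitudinalResult:
    """Assign post-treatment windows to baseline states; paired comparisons.

    Occurrence and efficiency changes are tested with paired t-tests within
    responders and non-responders separately; zero-variance differences are
    reported as no-change rows rather than errors.
    """
    post = [t for t in timeseries if t.session == "post"]
    if not post:
        raise ValueError("no post-treatment sessions")
    taper = make_taper(config.window_length, config.window_sigma)
    grid = np.asarray(config.lambda_grid) if config.lambda_grid else None
    dfc_seed = config.stage_seed("dfc") + 10_000
    k = baseline.model.k
    post_labels: dict[str, np.ndarray] = {}
    post_metrics: dict[str, StateMetrics] = {}
    for i, ts in enumerate(post):
        wfc = compute_windowed_fc(
            ts, taper, step=config.window_step, lam=config.lambda_fixed,
            grid=grid, folds=config.cv_folds, reps=config.cv_reps, seed=dfc_seed + i,
        )
        lab = assign_to_states(wfc, baseline.model)
        post_labels[ts.subject_id] = lab
        post_metrics[ts.subject_id] = compute_state_metrics(ts, wfc, lab, k)
    cl = clinical.set_index("subject_id")
    rows = []
    for resp_flag, resp_name in ((True, "responder"), (False, "non_responder")):
        sids = [
            s for s in post_labels
            if s in cl.index and cl.loc[s, "responder"] is not pd.NA
            and bool(cl.loc[s, "responder"]) == resp_flag and s in baseline.metrics
        ]
        if len(sids) < 2:
            continue
        for s in range(1, k + 1):
            for measure, getter in (
                ("occurrence", lambda m, st: m.occurrence[st - 1]),
                ("local_efficiency", lambda m, st: m.avg_local_efficiency[st - 1]),
            ):
                pre = np.array([getter(baseline.metrics[x], s) for x in sids])
                pst = np.array([getter(post_metrics[x], s) for x in sids])
                keep = np.isfinite(pre) & np.isfinite(pst)
                if keep.sum() < 2:
                    continue
                try:
                    t, p = paired_t(pre[keep], pst[keep])
                except ValueError:
                    t, p = 0.0, 1.0  # identical pre/post: no change
                rows.append((resp_name, s, measure, int(keep.sum()), t, p))
    paired = pd.DataFrame(
        rows, columns=["group", "state", "measure", "n", "t", "p"]
    )
    if len(paired):
        for (g, m), sub in paired.groupby(["group", "measure"]):
            ok = sub[np.isfinite(sub["p"])]
            if len(ok):
                q, _ = fdr_bh(ok["p"].to_numpy(), config.fdr_q)
                paired.loc[ok.index, "q"] = q
    return LongitudinalResult(
        post_labels=post_labels, post_metrics=post_metrics, paired_tests=paired
    )


def run_prediction(
    baseline: BaselineResult,
    clinical: pd.DataFrame,
    config: PipelineConfig,
    states: list[int] | None = None,
) -> dict[str, PredictionResult]:
    """LOOCV + permutation prediction of the HAMD reduction rate.

    One model per requested state (default: every state) from state-dependent
    dFC strength, plus an 'sfc' control model from static FC.
    """
    cl = clinical.set_index("subject_id")
    with_outcome = [
        s for s in baseline.metrics
        if s in cl.index and cl.loc[s, "group"] == "MDD" and np.isfinite(cl.loc[s, "rr"])
    ]
    if len(with_outcome) < 3:
        raise ValueError("fewer than 3 subjects with an outcome")
    k = baseline.model.k
    seed = config.stage_seed("predict")
    out: dict[str, PredictionResult] = {}
    for s in states or range(1, k + 1):
        mats = {sid: baseline.metrics[sid].dfc_strength[s - 1] for sid in with_outcome}
        try:
            x, kept = build_features(mats, mode=config.feature_mode)
        except ValueError:
            continue
        y = cl.loc[kept, "rr"].to_numpy(float)
        if len(kept) < 3 or np.std(y) == 0:
            continue
        res = permutation_test(x, y, n_perm=config.n_perm, seed=seed + s)
        res.subject_ids = kept
        out[f"state{s}"] = res
    sfc_mats = {sid: baseline.metrics[sid].sfc for sid in with_outcome}
    x, kept = build_features(sfc_mats, mode=config.feature_mode)
    y = cl.loc[kept, "rr"].to_numpy(float)
    res = permutation_test(x, y, n_perm=config.n_perm, seed=seed + k + 1)
    res.subject_ids = kept
    out["sfc"] = res
    return out


# ---------------------------------------------------------------------------
# provenance / persistence helpers
# ---------------------------------------------------------------------------


def write_provenance(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(config), indent=2, default=list))


def read_provenance(path: str | Path) -> PipelineConfig:
    raw = json.loads(Path(path).read_text())
    if raw.get("lambda_grid") is not None:
        raw["lambda_grid"] = tuple(raw["lambda_grid"])
    return PipelineConfig(**raw)
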