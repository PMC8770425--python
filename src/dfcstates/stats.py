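"""Group-level statistics and outcome bookkeeping.

Covariate-adjusted group comparisons use an ordinary-least-squares general
linear model with age, sex and mean framewise displacement as nuisance
covariates; longitudinal change uses paired t-tests; multiple comparisons
within a family of tests are controlled with Benjamini-Hochberg FDR.
Edgewise between-group tests of dFC strength are restricted to a
conjunction mask built from within-group one-sample t-tests.

Treatment outcome is the percentage reduction of the 24-item Hamilton
Depression Rating Scale (HAMD) from baseline to week 12; a responder is a
patient with a reduction rate strictly greater than 50%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ClinicalRecord",
    "GroupStatResult",
    "glm_group_test",
    "paired_t",
    "two_sample_t_from_summary",
    "chi_square_2x2",
    "fdr_bh",
    "conjunction_mask",
    "reduction_rate",
    "classify_responder",
]


@dataclass
class ClinicalRecord:
    subject_id: str
    group: str
    age: float
    sex: str  # M/F
    mean_fd: float
    hamd_baseline: int
    hamd_week12: int | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be M or F, got {self.sex!r}")
        if self.hamd_baseline < 0:
            raise ValueError("negative HAMD score")

    @property
    def rr(self) -> float | None:
        if self.hamd_week12 is None:
            return None
        return reduction_rate(self.hamd_baseline, self.hamd_week12)

    @property
    def responder(self) -> bool | None:
        return None if self.rr is None else classify_responder(self.rr)


@dataclass
class GroupStatResult:
    measure: str
    t_statistic: float
    p_value: float
    n_per_group: tuple[int, int]
    q_value: float | None = None
    family: str | None = None


def reduction_rate(hamd_baseline: int, hamd_week12: int) -> float:
    """Percent HAMD reduction: 100 (baseline - week12) / baseline."""
    if hamd_baseline <= 0:
        raise ValueError("baseline HAMD must be positive")
    return 100.0 * (hamd_baseline - hamd_week12) / hamd_baseline

def classify_responder(rr: float) -> bool:
    """Responder rule: reduction rate strictly greater than 50%."""
    return rr > 50.0


def glm_group_test(
    y: np.ndarray,
    group: np.ndarray,
    covariates: pd.DataFrame | None = None,
    measure: str = "",
) -> GroupStatResult:
    """OLS test of a group effect, adjusting for optional covariates.

    ``group`` is a binary indicator (1 = patient group); the reported t and
    two-sided p belong to the group coefficient.  With no covariates this
    is algebraically the pooled two-sample t-test.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    group = np.asarray(group, dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError("y contains missing values")
    design = pd.DataFrame({"group": group})
    if covariates is not None:
        cov = covariates.reset_index(drop=True).copy()
        for c in cov.columns:
            if cov[c].dtype == object:
                cov[c] = pd.factorize(cov[c])[0].astype(float)
        design = pd.concat([design, cov], axis=1)
    x = sm.add_constant(design, has_constant="add")
    rank = np.linalg.matrix_rank(x.to_numpy())
    if rank < x.shape[1]:
        raise ValueError(
            f"rank-deficient design (rank {rank} < {x.shape[1]} columns: "
            f"{list(x.columns)})"
        )
    fit = sm.OLS(y, x).fit()
    n1 = int(np.sum(group == 1))
    n0 = int(np.sum(group == 0))
    return GroupStatResult(
        measure=measure,
        t_statistic=float(fit.tvalues["group"]),
        p_value=float(fit.pvalues["group"]),
        n_per_group=(n1, n0),
    )


def paired_t(pre: np.ndarray, post: np.ndarray) -> tuple[float, float]:
    """Standard paired t-test (two-sided)."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.size < 2:
        raise ValueError("pre/post must be equal-length vectors of size >= 2")
    diff = post - pre
    if np.std(diff, ddof=1) == 0:
        raise ValueError("zero variance of paired differences")
    res = sps.ttest_rel(post, pre)
    return float(res.statistic), float(res.pvalue)


def two_sample_t_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> tuple[float, float]:
    """Pooled-variance two-sample t from group summaries, df = n1 + n2 - 2."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if s1 < 0 or s2 < 0:
        raise ValueError("negative standard deviation")
    if s1 == 0 and s2 == 0 and m1 == m2:
        raise ValueError("degenerate input: identical constants")
    res = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def chi_square_2x2(counts) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, df = 1, no continuity correction."""
    table = np.asarray(counts)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        raise ValueError("counts must be non-negative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero margin in the contingency table")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up within one test family.

    Returns (q_values, reject flags); q-values are monotone in p rank.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q_values, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return q_values, reject


def conjunction_mask(
    fc_group1: np.ndarray,
    fc_group2: np.ndarray,
    alpha: float = 0.05,
    combine: str = "union",
) -> np.ndarray:
    """Edge mask from within-group one-sample t-tests against zero.

    ``fc_group*`` are n_subjects x R x R stacks (NaN slices allowed for
    subjects missing the state; they are dropped edge-wise).  An edge enters
    the mask when its one-sample test is significant at ``alpha`` in group 1
    or group 2 (``combine='union'``) or in both (``'intersection'``).  Edges
    with fewer than 2 valid subjects in a group are treated as
    non-significant there, so they are excluded under intersection and can
    only enter a union mask through the other group.
    """
    if combine not in ("union", "intersection"):
        raise ValueError("combine must be 'union' or 'intersection'")

    def _sig(stack: np.ndarray) -> np.ndarray:
        stack = np.asarray(stack, dtype=float)
        n_valid = np.sum(~np.isnan(stack), axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            res = sps.ttest_1samp(stack, 0.0, axis=0, nan_policy="omit")
            p = np.asarray(res.pvalue)
        sig = (p < alpha) & (n_valid >= 2)
        np.fill_diagonal(sig, False)
        return sig

    s1, s2 = _sig(fc_group1), _sig(fc_group2)
    return (s1 | s2) if combine == "union" else (s1 & s2)
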