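"""Group-level edge inference on cohort connectivity.

Implements the group-comparison ladder used for resting-state
connectomes: rank-consensus selection of "valid" edges, per-edge Welch
t-tests, family-wise omnibus correction by max-statistic permutation,
split-half sign-consistency resampling as a robustness criterion, a
covariate (age / gender / intracranial volume) multiple-regression
variant of the resampling test, and the classical post-hoc power
computation for a two-sample t-test.

All procedures operate on a :class:`CohortData`: stacked subject-level
edge vectors plus group labels and covariates.  The edge-vector
convention (upper triangle, 0-based, i<j, lexicographic) is shared with
:mod:`envnet.connectivity`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "CohortData",
    "ValidEdgeMask",
    "EdgeGroupStats",
    "RegressionEdgeStats",
    "rank_threshold",
    "welch_edges",
    "omnibus_permutation",
    "split_half_robustness",
    "covariate_regression_robustness",
    "ttest_power",
]


# --------------------------------------------------------------------------
# Containers
# --------------------------------------------------------------------------

@dataclass
class CohortData:
    """Stacked subject edge vectors with group labels and covariates.

    ``values`` is (n_subjects, n_edges); ``is_case`` marks the case
    group.  Covariates are optional and only required by the regression
    test: ``age`` (years), ``gender`` (0/1), ``icv`` (voxel count).
    """

    subject_ids: list[str]
    values: np.ndarray
    is_case: np.ndarray
    age: np.ndarray | None = None
    gender: np.ndarray | None = None
    icv: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.is_case = np.asarray(self.is_case, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("values must be (n_subjects, n_edges)")
        if len(self.subject_ids) != self.values.shape[0]:
            raise ValueError("subject_ids length mismatch")
        if self.is_case.shape[0] != self.values.shape[0]:
            raise ValueError("is_case length mismatch")
        for name in ("age", "gender", "icv"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape[0] != self.values.shape[0]:
                    raise ValueError(f"covariate {name!r} length mismatch")
                setattr(self, name, v)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_edges(self) -> int:
        return self.values.shape[1]

    @property
    def n_case(self) -> int:
        return int(self.is_case.sum())

    @property
    def n_control(self) -> int:
        return int((~self.is_case).sum())

    def require_groups(self, min_per_group: int = 2) -> None:
        if self.n_case < min_per_group or self.n_control < min_per_group:
            raise ValueError(
                f"need >= {min_per_group} subjects per group "
                f"(have {self.n_case} cases, {self.n_control} controls)"
            )


@dataclass
class ValidEdgeMask:
    """Consensus edge selection with its rank-map provenance."""

    mask: np.ndarray  # boolean, one per edge
    fraction: float
    group_mean_ranks: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def edge_indices(self) -> np.ndarray:
        return np.nonzero(self.mask)[0]

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())


@dataclass
class EdgeGroupStats:
    """Welch-test results at valid edges, with omnibus and robustness."""

    edge_indices: np.ndarray
    t: np.ndarray
    df: np.ndarray
    p: np.ndarray
    omnibus_threshold: float | None = None
    omnibus_significant: np.ndarray | None = None
    consistency: np.ndarray | None = None
    robust: np.ndarray | None = None
    sign: np.ndarray | None = None  # +1 case>control, -1 case<control


@dataclass
class RegressionEdgeStats:
    """Group-slope robustness under covariate adjustment."""

    edge_indices: np.ndarray
    group_slope: np.ndarray
    covariate_slopes: dict[str, np.ndarray]
    consistency: np.ndarray
    robust: np.ndarray
    sign: np.ndarray


# --------------------------------------------------------------------------
# Valid-edge selection by rank consensus
# --------------------------------------------------------------------------

def rank_threshold(
    cohort: CohortData, fraction: float = 0.20
) -> ValidEdgeMask:
    """Select edges whose group-averaged within-subject rank is top-X%.

    Each subject's edges are ranked ascending (ties get average ranks)
    and normalized by the edge count to (0, 1]; the normalized rank maps
    are averaged within each group, and an edge is "valid" for a group
    when its mean rank exceeds ``1 - fraction``.  The returned mask is
    the union of the two groups' selections, so strong edges present in
    either cohort are retained.

    Because only ranks enter, the selection is invariant under any
    strictly increasing per-subject transformation of edge values.
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must lie in (0, 1)")
    cohort.require_groups(min_per_group=1)
    E = cohort.n_edges
    ranks = stats.rankdata(cohort.values, axis=1) / E
    out = np.zeros(E, dtype=bool)
    mean_ranks: dict[str, np.ndarray] = {}
    for name, sel in (("case", cohort.is_case), ("control", ~cohort.is_case)):
        mr = ranks[sel].mean(axis=0)
        mean_ranks[name] = mr
        out |= mr > 1.0 - fraction
    return ValidEdgeMask(mask=out, fraction=fraction,
                         group_mean_ranks=mean_ranks)


# --------------------------------------------------------------------------
# Welch t-tests
# --------------------------------------------------------------------------

def _welch(
    x_case: np.ndarray, x_ctrl: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Welch t and Welch–Satterthwaite df along axis 0.

    Sign convention: positive t means case > control.  Edges where both
    groups have zero variance yield NaN (flagged, not an error).
    """
    n1, n2 = x_case.shape[0], x_ctrl.shape[0]
    m1, m2 = x_case.mean(axis=0), x_ctrl.mean(axis=0)
    v1 = x_case.var(axis=0, ddof=1)
    v2 = x_ctrl.var(axis=0, ddof=1)
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
    return t, df


def welch_edges(cohort: CohortData, mask: ValidEdgeMask) -> EdgeGroupStats:
    """Welch's unequal-variance t-test at every valid edge.

    Returns t, Welch–Satterthwaite df and two-sided p per valid edge.
    """
    cohort.require_groups()
    idx = mask.edge_indices
    if idx.size == 0:
        raise ValueError("valid-edge mask is empty")
    X = cohort.values[:, idx]
    t, df = _welch(X[cohort.is_case], X[~cohort.is_case])
    with np.errstate(invalid="ignore"):
        p = 2.0 * stats.t.sf(np.abs(t), df)
    return EdgeGroupStats(edge_indices=idx, t=t, df=df, p=p)


# --------------------------------------------------------------------------
# Omnibus (max-statistic) permutation correction
# --------------------------------------------------------------------------

def omnibus_permutation(
    cohort: CohortData,
    mask: ValidEdgeMask,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> EdgeGroupStats:
    """Family-wise error control via the max-|t| permutation distribution.

    Group labels are randomly reassigned (preserving group sizes)
    ``n_perm`` times; the maximum |Welch t| over valid edges is recorded
    per permutation, and the omnibus threshold is the empirical
    (1 - alpha) quantile of that null distribution.  Observed edges with
    |t| >= threshold are flagged omnibus-significant.  Controlling the
    maximum statistic controls the family-wise error rate over all valid
    edges simultaneously.
    """
    cohort.require_groups()
    if mask.n_valid == 0:
        raise ValueError("valid-edge mask is empty")
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} is very low for omnibus thresholding",
            RuntimeWarning, stacklevel=2,
        )
    res = welch_edges(cohort, mask)
    X = cohort.values[:, res.edge_indices]
    n, n1 = cohort.n_subjects, cohort.n_case
    rng = np.random.default_rng(seed)
    max_t = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        t, _ = _welch(X[perm[:n1]], X[perm[n1:]])
        max_t[b] = np.nanmax(np.abs(t))
    thr = float(np.quantile(max_t, 1.0 - alpha))
    res.omnibus_threshold = thr
    with np.errstate(invalid="ignore"):
        res.omnibus_significant = np.abs(res.t) >= thr
    res.omnibus_significant &= ~np.isnan(res.t)
    return res


# --------------------------------------------------------------------------
# Split-half sign-consistency resampling
# --------------------------------------------------------------------------

def _half_indices(
    rng: np.random.Generator, group_idx: np.ndarray
) -> np.ndarray:
    half = group_idx.size // 2
    return rng.choice(group_idx, size=half, replace=False)


def split_half_robustness(
    cohort: CohortData,
    mask: ValidEdgeMask,
    n_iter: int = 10_000,
    consistency: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> EdgeGroupStats:
    """Robustness of effect direction under half-cohort resampling.

    Per iteration, half of each group (floor(n_g / 2), without
    replacement) is drawn and the case-minus-control mean difference is
    computed at every valid edge; the sign of the difference is
    tabulated.  An edge is "robust" when one sign occurs in at least
    ``consistency`` of iterations.  Exact zero differences count against
    both signs, so they can never inflate consistency.
    """
    cohort.require_groups(min_per_group=4)
    idx = mask.edge_indices
    if idx.size == 0:
        raise ValueError("valid-edge mask is empty")
    X = cohort.values[:, idx]
    case_idx = np.nonzero(cohort.is_case)[0]
    ctrl_idx = np.nonzero(~cohort.is_case)[0]
    rng = np.random.default_rng(seed)
    pos = np.zeros(idx.size)
    neg = np.zeros(idx.size)
    for _ in range(n_iter):
        d = (
            X[_half_indices(rng, case_idx)].mean(axis=0)
            - X[_half_indices(rng, ctrl_idx)].mean(axis=0)
        )
        pos += d > 0
        neg += d < 0
    pos /= n_iter
    neg /= n_iter
    frac = np.maximum(pos, neg)
    res = welch_edges(cohort, mask)
    res.consistency = frac
    res.robust = frac >= consistency
    res.sign = np.where(pos >= neg, 1, -1)
    return res


# --------------------------------------------------------------------------
# Covariate regression with split-half resampling
# --------------------------------------------------------------------------

_COVARIATES = ("age", "gender", "icv")


def covariate_regression_robustness(
    cohort: CohortData,
    mask: ValidEdgeMask,
    n_iter: int = 1_000,
    consistency: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> RegressionEdgeStats:
    """Group-effect robustness with age, gender and ICV adjusted for.

    Per iteration and per valid edge, edge values of a random half of
    each group are regressed (ordinary least squares) on [intercept,
    group indicator, age, gender, ICV]; the sign of the group slope is
    tabulated across iterations.  Edges whose group slope keeps one sign
    in at least ``consistency`` of iterations are robust to both
    subsampling and linear confound effects.
    """
    cohort.require_groups(min_per_group=4)
    for name in _COVARIATES:
        if getattr(cohort, name) is None:
            raise ValueError(f"cohort is missing covariate {name!r}")
    n_half = cohort.n_case // 2 + cohort.n_control // 2
    if n_half < 6:
        raise ValueError(
            f"half-cohorts of {n_half} subjects cannot identify a "
            "5-parameter regression; need at least 6 per half"
        )
    idx = mask.edge_indices
    if idx.size == 0:
        raise ValueError("valid-edge mask is empty")
    Y = cohort.values[:, idx]
    Z_full = np.column_stack(
        [
            np.ones(cohort.n_subjects),
            cohort.is_case.astype(float),
            cohort.age,
            cohort.gender,
            cohort.icv,
        ]
    )
    colnames = ("intercept", "group") + _COVARIATES
    rank = np.linalg.matrix_rank(Z_full)
    if rank < Z_full.shape[1]:
        # name the columns that do not add rank, scanning left to right
        bad = []
        r_prev = 0
        for c in range(Z_full.shape[1]):
            r_now = np.linalg.matrix_rank(Z_full[:, : c + 1])
            if r_now == r_prev:
                bad.append(colnames[c])
            r_prev = r_now
        raise ValueError(f"collinear design matrix; offending: {bad}")

    # full-cohort fit for the reported slopes
    beta_full, *_ = np.linalg.lstsq(Z_full, Y, rcond=None)

    case_idx = np.nonzero(cohort.is_case)[0]
    ctrl_idx = np.nonzero(~cohort.is_case)[0]
    rng = np.random.default_rng(seed)
    pos = np.zeros(idx.size)
    neg = np.zeros(idx.size)
    for _ in range(n_iter):
        rows = np.concatenate(
            [_half_indices(rng, case_idx), _half_indices(rng, ctrl_idx)]
        )
        Zh = Z_full[rows]
        if np.linalg.matrix_rank(Zh) < Zh.shape[1]:
            raise ValueError(
                "rank-deficient half-cohort design matrix encountered"
            )
        beta, *_ = np.linalg.lstsq(Zh, Y[rows], rcond=None)
        g = beta[1]
        pos += g > 0
        neg += g < 0
    pos /= n_iter
    neg /= n_iter
    frac = np.maximum(pos, neg)
    return RegressionEdgeStats(
        edge_indices=idx,
        group_slope=beta_full[1],
        covariate_slopes={
            name: beta_full[2 + k] for k, name in enumerate(_COVARIATES)
        },
        consistency=frac,
        robust=frac >= consistency,
        sign=np.where(pos >= neg, 1, -1),
    )


# --------------------------------------------------------------------------
# Post-hoc power of the two-sample t-test
# --------------------------------------------------------------------------

def ttest_power(
    d: float, n_per_group: int, alpha: float = 0.05
) -> float:
    """Power of a two-sided two-sample t-test at effect size Cohen's d.

    Classical equal-n power analysis: noncentrality ncp = d * sqrt(n/2),
    pooled df = 2n - 2; power is the probability that |T'| exceeds the
    central-t critical value under the noncentral t distribution.  At
    d = 0 this returns the type-I rate alpha.
    """
    if d < 0:
        raise ValueError("d must be >= 0")
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    df = 2 * n_per_group - 2
    ncp = d * np.sqrt(n_per_group / 2.0)
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(
        stats.nct.sf(t_crit, df, ncp) + stats.nct.cdf(-t_crit, df, ncp)
    )
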