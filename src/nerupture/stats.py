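"""Statistical battery for comparing kinetic traces and snapshot scores.

Two complementary routes are exposed and never silently selected between:

* a linear mixed model for the group-by-time interaction of longitudinal
  traces (random intercept per subject cell, group, time and group x time
  as fixed effects, REML);
* rank-based tests for endpoint and snapshot comparisons: Mann-Whitney U
  (exact by enumeration at small n, tie/continuity-corrected normal
  approximation otherwise), Kruskal-Wallis with the Steel-Dwass all-pairs
  post-hoc, and the two-sided Smirnov-Grubbs outlier test with a P < 0.001
  "far outlier" convention, applied iteratively.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

from .errors import ConfigurationError

__all__ = [
    "StatsConfig",
    "StatsResult",
    "mann_whitney",
    "kruskal_wallis",
    "steel_dwass",
    "grubbs_far_outliers",
    "grubbs_critical_value",
    "mixed_model_interaction",
    "validate_long_table",
]


@dataclass
class StatsConfig:
    """Significance levels and computational settings.

    ``grubbs_alpha`` is the far-outlier level; ``exact_max_n`` bounds the
    per-group n for exact Mann-Whitney enumeration; ``mc_reps`` is the
    permutation replicate count for the optional Steel-Dwass permutation
    mode.
    """

    alpha: float = 0.05
    grubbs_alpha: float = 0.001
    exact_max_n: int = 8
    mc_reps: int = 2000
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")
        if not 0 < self.grubbs_alpha < 1:
            raise ConfigurationError("grubbs_alpha must be in (0, 1)")
        if self.mc_reps < 1000:
            raise ConfigurationError("mc_reps must be >= 1000 when used")


@dataclass
class StatsResult:
    """Outcome of one statistical procedure."""

    method: str
    statistic: float | dict
    pvalue: Optional[float] = None
    pairwise: Optional[pd.DataFrame] = None
    decisions: dict = field(default_factory=dict)
    removed: list = field(default_factory=list)
    details: dict = field(default_factory=dict)


def validate_long_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format trace table: required columns, >= 2 groups,
    each cell in exactly one group."""
    required = {"cell_id", "group", "time_s", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ConfigurationError(f"long table missing columns {sorted(missing)}")
    if table["group"].nunique() < 2:
        raise ConfigurationError("need at least 2 groups")
    per_cell = table.groupby("cell_id")["group"].nunique()
    if (per_cell > 1).any():
        bad = per_cell[per_cell > 1].index.tolist()
        raise ConfigurationError(f"cells in more than one group: {bad}")
    return table


def mann_whitney(x: Sequence[float], y: Sequence[float],
                 config: Optional[StatsConfig] = None) -> StatsResult:
    """Two-sided Mann-Whitney U with midrank ties.

    Exact p by full enumeration of labelings when both samples have
    ``n <= exact_max_n`` and there are no ties; otherwise the normal
    approximation with tie and continuity corrections.
    """
    config = config or StatsConfig()
    config.validate()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ConfigurationError("both samples must be nonempty")
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < len(combined)
    exact = (max(len(x), len(y)) <= config.exact_max_n) and not has_ties
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return StatsResult(
        method="mann-whitney-exact" if exact else "mann-whitney-normal",
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        decisions={"significant": bool(res.pvalue < config.alpha)},
        details={"n_x": len(x), "n_y": len(y), "ties": bool(has_ties)},
    )


def kruskal_wallis(groups: Sequence[Sequence[float]],
                   config: Optional[StatsConfig] = None) -> StatsResult:
    """Kruskal-Wallis H with tie correction; chi-square p on k-1 df."""
    config = config or StatsConfig()
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ConfigurationError("need at least 2 groups")
    combined = np.concatenate(groups)
    if np.ptp(combined) == 0:
        return StatsResult(method="kruskal-wallis", statistic=0.0, pvalue=1.0,
                           decisions={"significant": False})
    h, p = sps.kruskal(*groups)
    return StatsResult(
        method="kruskal-wallis",
        statistic=float(h),
        pvalue=float(p),
        decisions={"significant": bool(p < config.alpha)},
        details={"df": len(groups) - 1},
    )


def _pair_z(xi: np.ndarray, xj: np.ndarray) -> float:
    """Standardized pairwise rank-sum with midranks and tie-corrected variance."""
    n_i, n_j = len(xi), len(xj)
    pooled = np.concatenate([xi, xj])
    n = n_i + n_j
    ranks = sps.rankdata(pooled)
    w = ranks[:n_i].sum()
    e = n_i * (n + 1) / 2.0
    v = n_i * n_j / (n * (n - 1.0)) * ((ranks**2).sum() - n * (n + 1.0) ** 2 / 4.0)
    if v <= 0:
        return 0.0
    return float((w - e) / np.sqrt(v))


def steel_dwass(groups: Sequence[Sequence[float]],
                config: Optional[StatsConfig] = None,
                method: str = "studentized") -> StatsResult:
    """Steel-Dwass all-pairs comparison after Kruskal-Wallis.

    Each pair is compared with a rank-sum statistic computed on that pair
    only; the standardized statistic is referred to the studentized range
    distribution with k groups and infinite df
    (``p = P(Q_{k,inf} >= sqrt(2) |z|)``). ``method="permutation"`` instead
    estimates single-step max-|z| adjusted p-values by permuting all group
    labels (seeded), which serves as an internal oracle for the analytic
    route.
    """
    config = config or StatsConfig()
    config.validate()
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ConfigurationError("need at least 2 groups")
    for i, g in enumerate(groups):
        if len(g) < 2:
            raise ConfigurationError(f"group {i} has fewer than 2 observations")
    pairs = list(itertools.combinations(range(k), 2))
    z_obs = {(i, j): _pair_z(groups[i], groups[j]) for i, j in pairs}

    if method == "studentized":
        pvals = {
            ij: float(sps.studentized_range.sf(np.sqrt(2.0) * abs(z), k, np.inf))
            for ij, z in z_obs.items()
        }
    elif method == "permutation":
        rng = np.random.default_rng(config.seed)
        sizes = [len(g) for g in groups]
        pooled = np.concatenate(groups)
        edges = np.cumsum([0] + sizes)
        exceed = {ij: 0 for ij in pairs}
        for _ in range(config.mc_reps):
            perm = rng.permutation(pooled)
            pg = [perm[edges[i]: edges[i + 1]] for i in range(k)]
            zmax = max(abs(_pair_z(pg[i], pg[j])) for i, j in pairs)
            for ij in pairs:
                if zmax >= abs(z_obs[ij]):
                    exceed[ij] += 1
        pvals = {ij: (exceed[ij] + 1) / (config.mc_reps + 1) for ij in pairs}
    else:
        raise ConfigurationError(f"unknown method {method!r}")

    mat = pd.DataFrame(np.ones((k, k)), dtype=float)
    for (i, j), p in pvals.items():
        mat.iat[i, j] = mat.iat[j, i] = p
    return StatsResult(
        method=f"steel-dwass-{method}",
        statistic={f"{i}-{j}": z for (i, j), z in z_obs.items()},
        pairwise=mat,
        decisions={f"{i}-{j}": bool(p < config.alpha) for (i, j), p in pvals.items()},
        details={"k": k},
    )


def grubbs_critical_value(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value
    ``G_crit = ((n-1)/sqrt(n)) sqrt(t^2 / (n - 2 + t^2))`` with ``t`` the
    upper ``alpha/(2n)`` quantile of Student's t with n-2 df."""
    if n < 3:
        raise ConfigurationError("Grubbs test needs n >= 3")
    t = sps.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return float((n - 1.0) / np.sqrt(n) * np.sqrt(t**2 / (n - 2.0 + t**2)))


def grubbs_far_outliers(x: Sequence[float],
                        config: Optional[StatsConfig] = None,
                        iterative: bool = True) -> StatsResult:
    """Two-sided Smirnov-Grubbs test at the far-outlier level (default 0.001).

    The most extreme point is removed whenever
    ``G = max |x_i - mean| / sd`` exceeds the critical value; with
    ``iterative=True`` (default) the test is re-applied to the reduced sample
    until nothing exceeds it. The result depends only on the multiset of
    values, not their order. Constant samples are returned unchanged.
    """
    config = config or StatsConfig()
    config.validate()
    values = list(np.asarray(x, dtype=float))
    removed: list[float] = []
    g_seq: list[float] = []
    while True:
        n = len(values)
        arr = np.asarray(values)
        if n < 3 or arr.std(ddof=1) == 0:
            break
        mean, sd = arr.mean(), arr.std(ddof=1)
        idx = int(np.argmax(np.abs(arr - mean)))
        g = abs(arr[idx] - mean) / sd
        g_crit = grubbs_critical_value(n, config.grubbs_alpha)
        if g < g_crit:
            break
        removed.append(float(arr[idx]))
        g_seq.append(float(g))
        values.pop(idx)
        if not iterative:
            break
    return StatsResult(
        method="grubbs-two-sided",
        statistic=float(g_seq[0]) if g_seq else float("nan"),
        removed=removed,
        decisions={"n_removed": len(removed)},
        details={"kept": values, "g_sequence": g_seq,
                 "alpha": config.grubbs_alpha, "iterative": iterative},
    )


def mixed_model_interaction(table: pd.DataFrame,
                            time_as: str = "continuous",
                            config: Optional[StatsConfig] = None) -> StatsResult:
    """Group-by-time interaction test from a linear mixed model.

    Fits ``value ~ group + time + group:time`` with a random intercept per
    subject cell by REML and tests the joint null that all interaction
    coefficients are zero with a Wald F-statistic
    (``df = (q, n_obs - n_fixed)``). Time enters as a continuous covariate by
    default; ``time_as="categorical"`` is available for saturated designs.

    If the mixed fit fails to converge or is singular, the same fixed-effect
    model is refit by OLS and the result is flagged
    (``details["fallback"]``) with the caveat that within-cell correlation is
    then ignored.
    """
    import warnings

    config = config or StatsConfig()
    validate_long_table(table)
    n_times = table["time_s"].nunique()
    n_cells = table.groupby("group")["cell_id"].nunique()
    if n_times < 3:
        raise ConfigurationError("need >= 3 time points")
    if (n_cells < 3).any():
        raise ConfigurationError("need >= 3 cells per group")
    data = table.copy()
    time_term = "time_s" if time_as == "continuous" else "C(time_s)"
    formula = f"value ~ C(group) + {time_term} + C(group):{time_term}"

    fallback = False
    res = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, data, groups=data["cell_id"])
            try:
                res = model.fit(reml=True)
            except np.linalg.LinAlgError:
                res = model.fit(reml=True, method="powell")
            # The optimizer's convergence flag can be raised spuriously when
            # a variance component sits at its boundary; the fit is unusable
            # only when the scale collapses or standard errors are not finite.
            usable = (
                np.isfinite(res.fe_params).all()
                and np.isfinite(res.bse_fe).all()
                and (res.bse_fe > 0).all()
                and res.scale > 0
            )
        if not usable:
            fallback = True
    except (np.linalg.LinAlgError, ValueError):
        fallback = True

    if fallback or res is None:
        ols = smf.ols(formula, data).fit()
        params = ols.params
        cov = ols.cov_params()
        nobs, k_fe = int(ols.nobs), len(params)
        group_var = 0.0
        method = "ols-interaction-F (cluster structure ignored; mixed fit failed)"
    else:
        params = res.fe_params
        cov = pd.DataFrame(res.cov_params().iloc[: len(params), : len(params)].values,
                           index=params.index, columns=params.index)
        nobs, k_fe = int(res.nobs), len(params)
        group_var = float(res.cov_re.iloc[0, 0])
        method = "lmm-reml-wald-F"

    inter = [name for name in params.index if ":" in name]
    if not inter:
        raise ConfigurationError("model has no interaction terms")
    b = params[inter].values
    v = cov.loc[inter, inter].values
    q = len(inter)
    fstat = float(b @ np.linalg.solve(v, b) / q)
    df_resid = nobs - k_fe
    pval = float(sps.f.sf(fstat, q, df_resid))
    return StatsResult(
        method=method,
        statistic=fstat,
        pvalue=pval,
        decisions={"significant": bool(pval < config.alpha)},
        details={
            "interaction_terms": inter,
            "fixed_effects": {k: float(v) for k, v in params.items()},
            "random_intercept_var": group_var,
            "df": (q, df_resid),
            "fallback": fallback,
            "time_as": time_as,
        },
    )
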