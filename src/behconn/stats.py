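"""Group comparisons of global graph metrics: ANCOVA and permutation AUC tests.

The group effect on each metric is tested in a linear model with group
dummies plus covariates (age, sex, motion, mean FC), Type II sums of squares.
Partial eta squared is SS_effect / (SS_effect + SS_error). Robustness across
cost thresholds is assessed on the per-subject trapezoid AUC of the metric
over costs, with significance from a group-label permutation null of the
ANCOVA F.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .graphmetrics import auc_over_costs
from .pls import PermutationResult

__all__ = ["AncovaResult", "ancova", "permutation_f_auc"]


@dataclass
class AncovaResult:
    f: float
    p: float
    eta_p2: float
    df_effect: int
    df_error: int
    covariate_coef: dict[str, float]
    group_means: pd.DataFrame = field(default=None)
    pairwise: pd.DataFrame = field(default=None)


def _design(groups: pd.Series, covariates: pd.DataFrame | None) -> pd.DataFrame:
    dummies = pd.get_dummies(groups, prefix="group", drop_first=True).astype(float)
    parts = [dummies]
    if covariates is not None:
        cov = covariates.astype(float)
        # constant columns are absorbed by the intercept (plain ANOVA limit)
        cov = cov.loc[:, cov.std(ddof=0) > 0]
        if cov.shape[1]:
            parts.append(cov)
    x = pd.concat(parts, axis=1)
    x.insert(0, "const", 1.0)
    return x


def _fit_f(metric: np.ndarray, groups: pd.Series,
           covariates: pd.DataFrame | None) -> tuple[float, float, float, int, int, dict]:
    x = _design(groups, covariates)
    rank = np.linalg.matrix_rank(x.to_numpy())
    if rank < x.shape[1]:
        corr = x.drop(columns="const").corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax()
        raise ValueError(f"rank-deficient design; near-collinear columns {worst}")
    full = sm.OLS(metric, x).fit()
    gcols = [c for c in x.columns if c.startswith("group_")]
    reduced = sm.OLS(metric, x.drop(columns=gcols)).fit()
    df_eff = len(gcols)
    df_err = int(full.df_resid)
    ss_eff = reduced.ssr - full.ssr  # Type II: group adjusted for covariates
    ss_err = full.ssr
    f = (ss_eff / df_eff) / (ss_err / df_err) if ss_err > 0 else 0.0
    f = max(f, 0.0)
    from scipy.stats import f as fdist
    p = float(fdist.sf(f, df_eff, df_err)) if ss_err > 0 else 1.0
    eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
    coefs = {c: float(full.params[c]) for c in x.columns if not c.startswith("group_")}
    return float(f), p, float(max(eta, 0.0)), df_eff, df_err, coefs


def ancova(metric: pd.Series | np.ndarray, groups: pd.Series,
           covariates: pd.DataFrame | None = None,
           pairwise: bool = True) -> AncovaResult:
    """ANCOVA of one metric on group, adjusting for covariates.

    Pairwise follow-ups run the same model on each group pair with Bonferroni
    correction over the pairs.
    """
    groups = pd.Series(groups).astype(str)
    metric = np.asarray(metric, dtype=float)
    if groups.nunique() < 2:
        raise ValueError("need >= 2 groups")
    f, p, eta, df_e, df_r, coefs = _fit_f(metric, groups, covariates)

    gm = pd.DataFrame({"mean": pd.Series(metric).groupby(groups.values).mean(),
                       "sd": pd.Series(metric).groupby(groups.values).std(ddof=1)})

    pw = None
    if pairwise:
        uniq = list(pd.unique(groups))
        rows = []
        pairs = [(a, b) for i, a in enumerate(uniq) for b in uniq[i + 1:]]
        for a, b in pairs:
            sel = groups.isin([a, b]).to_numpy()
            cov_ab = covariates.iloc[sel] if covariates is not None else None
            fa, pa, ea, *_ = _fit_f(metric[sel], groups[sel].reset_index(drop=True),
                                    None if cov_ab is None else cov_ab.reset_index(drop=True))
            rows.append({"group_a": a, "group_b": b, "F": fa, "p": pa,
                         "eta_p2": ea,
                         "p_bonferroni": min(1.0, pa * len(pairs))})
        pw = pd.DataFrame(rows)
    return AncovaResult(f=f, p=p, eta_p2=eta, df_effect=df_e, df_error=df_r,
                        covariate_coef=coefs, group_means=gm, pairwise=pw)


def permutation_f_auc(metric_by_cost: pd.DataFrame, groups: pd.Series,
                      covariates: pd.DataFrame | None = None,
                      n_perm: int = 1000, seed: int = 0) -> PermutationResult:
    """Permutation test of the group effect on the metric's AUC over costs.

    ``metric_by_cost``: subjects x costs (columns are ascending cost values).
    Only the group labels shuffle; each subject keeps its covariates and AUC.
    p = (1 + #{F_null >= F_obs}) / (1 + n_perm).
    """
    costs = np.array([float(c) for c in metric_by_cost.columns])
    auc = np.array([auc_over_costs(row, costs)
                    for row in metric_by_cost.to_numpy(dtype=float)])
    groups = pd.Series(groups).reset_index(drop=True).astype(str)
    cov = covariates.reset_index(drop=True) if covariates is not None else None
    if np.ptp(auc) == 0:
        return PermutationResult(observed=0.0, null=np.zeros(n_perm), p=1.0,
                                 seed=seed, extra={"note": "constant metric"})
    f_obs, *_ = _fit_f(auc, groups, cov)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        gp = pd.Series(groups.to_numpy()[rng.permutation(len(groups))])
        null[b], *_ = _fit_f(auc, gp, cov)
    p = (1 + int((null >= f_obs).sum())) / (1 + n_perm)
    return PermutationResult(observed=f_obs, null=null, p=p, seed=seed)
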