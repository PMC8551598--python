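"""PLS prediction of profile membership with permutation and bootstrap inference.

Group membership (one-hot) is regressed on standardised connectivity features
by multi-response PLS (NIPALS with deflation). Model complexity is chosen by
repeated stratified k-fold cross-validation with the one-standard-error rule
on the casewise RMSE; significance comes from label-permutation nulls of the
full CV pipeline; feature stability from bootstrap resampling with orthogonal
Procrustes alignment of loadings to the full-sample reference model.

Covariates (age, sex, motion, mean FC) are controlled by residualising the
features on them, with residualisation and standardisation parameters always
estimated on the training subjects only (no leakage).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes
from sklearn.model_selection import StratifiedKFold

__all__ = ["DesignMatrices", "PLSModel", "CVResult", "PermutationResult",
           "BootstrapLoadings", "build_design", "fit_pls", "cross_validate",
           "select_components", "permutation_test", "permutation_test_auc",
           "bootstrap_loadings", "score_group_test", "constant_predictor_rmse"]


# ---------------------------------------------------------------- design


@dataclass
class Preprocessor:
    """Training-set residualisation on covariates followed by standardisation."""

    coef: np.ndarray | None = None   # (n_cov+1) x p, intercept first
    mean: np.ndarray | None = None
    sd: np.ndarray | None = None

    def fit(self, x: np.ndarray, cov: np.ndarray | None) -> "Preprocessor":
        x = np.asarray(x, dtype=float)
        if cov is not None:
            z = np.column_stack([np.ones(len(x)), cov])
            self.coef, *_ = np.linalg.lstsq(z, x, rcond=None)
            x = x - z @ self.coef
        self.mean = x.mean(axis=0)
        sd = x.std(axis=0, ddof=0)
        self.sd = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, x: np.ndarray, cov: np.ndarray | None) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.coef is not None:
            z = np.column_stack([np.ones(len(x)), cov])
            x = x - z @ self.coef
        return (x - self.mean) / self.sd


@dataclass
class DesignMatrices:
    x: np.ndarray                  # subjects x features (raw)
    y: np.ndarray                  # subjects x groups, one-hot
    groups: np.ndarray             # integer group codes
    group_names: list[str]
    covariates: np.ndarray | None
    feature_names: list[str] = field(default_factory=list)
    subjects: list[str] = field(default_factory=list)


def build_design(features: pd.DataFrame, groups: pd.Series,
                 covariates: pd.DataFrame | None = None,
                 group_order: list[str] | None = None,
                 covariate_mode: str = "residualise") -> DesignMatrices:
    """Assemble X (features), one-hot Y and the covariate block.

    Only complete cases (subjects present in every table) are used. The raw X
    is stored; residualisation/standardisation happen at fit time on training
    subjects so cross-validation never leaks test-set statistics. With
    ``covariate_mode="append"`` the covariates enter X as extra predictor
    columns instead of being regressed out.
    """
    if covariate_mode not in ("residualise", "append"):
        raise ValueError("covariate_mode must be 'residualise' or 'append'")
    idx = features.index.intersection(groups.index)
    if covariates is not None:
        idx = idx.intersection(covariates.index)
    features = features.loc[idx]
    groups = groups.loc[idx]
    if group_order is None:
        group_order = sorted(pd.unique(groups))
    codes = np.array([group_order.index(g) for g in groups])
    y = np.eye(len(group_order))[codes]
    cov = covariates.loc[idx] if covariates is not None else None
    names = list(features.columns)
    x = features.to_numpy(dtype=float)
    if cov is not None and covariate_mode == "append":
        x = np.column_stack([x, cov.to_numpy(dtype=float)])
        names += list(cov.columns)
        cov = None
    return DesignMatrices(x=x, y=y, groups=codes,
                          group_names=list(group_order),
                          covariates=None if cov is None
                          else cov.to_numpy(dtype=float),
                          feature_names=names, subjects=list(idx))


# ---------------------------------------------------------------- NIPALS PLS2


@dataclass
class PLSModel:
    n_components: int
    x_weights: np.ndarray    # p x k  (W)
    x_loadings: np.ndarray   # p x k  (P)
    y_loadings: np.ndarray   # q x k  (C, w.r.t. scores)
    x_scores: np.ndarray     # n x k  (T)
    x_mean: np.ndarray
    y_mean: np.ndarray

    def coefficients(self, k: int | None = None) -> np.ndarray:
        """Regression coefficients B (p x q) using the first ``k`` components."""
        k = self.n_components if k is None else k
        w, p, c = self.x_weights[:, :k], self.x_loadings[:, :k], self.y_loadings[:, :k]
        return w @ np.linalg.solve(p.T @ w, c.T)

    def predict(self, x: np.ndarray, k: int | None = None) -> np.ndarray:
        return (np.asarray(x) - self.x_mean) @ self.coefficients(k) + self.y_mean

    def transform(self, x: np.ndarray, k: int | None = None) -> np.ndarray:
        """Component scores for new (already preprocessed) feature rows."""
        k = self.n_components if k is None else k
        w, p = self.x_weights[:, :k], self.x_loadings[:, :k]
        rot = w @ np.linalg.solve(p.T @ w, np.eye(k))
        return (np.asarray(x) - self.x_mean) @ rot


def fit_pls(x: np.ndarray, y: np.ndarray, k: int, max_iter: int = 500,
            tol: float = 1e-12) -> PLSModel:
    """Multi-response PLS (PLS2) by NIPALS with deflation of X and Y.

    ``x`` is expected preprocessed (residualised/standardised); both blocks
    are centred internally. Deterministic: the u-vector is initialised from
    the Y column with the largest variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n, p = x.shape
    if k > min(n - 1, p):
        raise ValueError(f"k={k} exceeds the rank bound min(n-1, p)={min(n - 1, p)}")
    x_mean, y_mean = x.mean(axis=0), y.mean(axis=0)
    xc, yc = x - x_mean, y - y_mean
    ws, ps, cs, ts = [], [], [], []
    for comp in range(k):
        if not np.any(np.abs(yc) > 1e-14):
            break  # Y fully explained; further components are degenerate
        u = yc[:, int(np.argmax(yc.var(axis=0)))]
        if not u.any():
            u = yc[:, 0]
        t_old = None
        for _ in range(max_iter):
            w = xc.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                raise ValueError(f"k={k} exceeds rank(X): X deflated to zero "
                                 f"at component {comp + 1}")
            w /= nw
            t = xc @ w
            c = yc.T @ t / (t @ t)
            u = yc @ c / (c @ c)
            if t_old is not None and np.linalg.norm(t - t_old) < tol * np.linalg.norm(t):
                break
            t_old = t
        pvec = xc.T @ t / (t @ t)
        xc = xc - np.outer(t, pvec)
        yc = yc - np.outer(t, c)
        ws.append(w); ps.append(pvec); cs.append(c); ts.append(t)
    return PLSModel(n_components=len(ws),
                    x_weights=np.stack(ws, axis=1),
                    x_loadings=np.stack(ps, axis=1),
                    y_loadings=np.stack(cs, axis=1),
                    x_scores=np.stack(ts, axis=1),
                    x_mean=x_mean, y_mean=y_mean)


# ---------------------------------------------------------------- CV


def casewise_rmse(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    """Per-subject RMSE across the one-hot response columns."""
    return np.sqrt(np.mean((y_true - y_pred) ** 2, axis=1))


def constant_predictor_rmse(n_groups: int = 4) -> float:
    """Casewise RMSE of the uninformative constant (1/g, ..., 1/g) predictor."""
    g = n_groups
    return float(np.sqrt(((1 - 1 / g) ** 2 + (g - 1) * (1 / g) ** 2) / g))


@dataclass
class CVResult:
    k: int
    fold_rmse: np.ndarray       # one value per fold x repeat
    fold_accuracy: np.ndarray

    @property
    def mean_rmse(self) -> float:
        return float(self.fold_rmse.mean())

    @property
    def sem_rmse(self) -> float:
        return float(self.fold_rmse.std(ddof=1) / np.sqrt(self.fold_rmse.size))

    @property
    def mean_accuracy(self) -> float:
        return float(self.fold_accuracy.mean())

    @property
    def sem_accuracy(self) -> float:
        return float(self.fold_accuracy.std(ddof=1) / np.sqrt(self.fold_accuracy.size))


def _cv_fold_stats(d: DesignMatrices, ks: list[int], folds: int, repeats: int,
                   seed: int) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Fold-wise RMSE / accuracy for each k (single pass, nested components)."""
    kmax = max(ks)
    out = {k: ([], []) for k in ks}
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=(seed + rep) % (2**31))
        for train, test in skf.split(d.x, d.groups):
            prep = Preprocessor().fit(
                d.x[train], None if d.covariates is None else d.covariates[train])
            xtr = prep.transform(d.x[train],
                                 None if d.covariates is None else d.covariates[train])
            xte = prep.transform(d.x[test],
                                 None if d.covariates is None else d.covariates[test])
            model = fit_pls(xtr, d.y[train], kmax)
            for k in ks:
                pred = model.predict(xte, k=k)
                rmse = casewise_rmse(d.y[test], pred).mean()
                acc = (np.argmax(pred, axis=1) == d.groups[test]).mean()
                out[k][0].append(rmse)
                out[k][1].append(acc)
    return {k: (np.array(v[0]), np.array(v[1])) for k, v in out.items()}


def cross_validate(d: DesignMatrices, k_max: int, folds: int = 5,
                   repeats: int = 10, seed: int = 0) -> dict[int, CVResult]:
    """Repeated stratified k-fold CV; returns a CVResult per component count.

    Components are nested under NIPALS deflation, so one fit at ``k_max``
    yields predictions for every smaller k.
    """
    ks = list(range(1, k_max + 1))
    stats = _cv_fold_stats(d, ks, folds, repeats, seed)
    return {k: CVResult(k=k, fold_rmse=r, fold_accuracy=a)
            for k, (r, a) in stats.items()}


def select_components(cv_by_k: dict[int, CVResult]) -> int:
    """One-standard-error rule: smallest k with RMSE <= min RMSE + its SEM."""
    if not cv_by_k:
        raise ValueError("empty CV results")
    ks = sorted(cv_by_k)
    means = np.array([cv_by_k[k].mean_rmse for k in ks])
    best = int(np.argmin(means))
    cut = means[best] + cv_by_k[ks[best]].sem_rmse
    for k, m in zip(ks, means):
        if m <= cut:
            return k
    return ks[best]


# ---------------------------------------------------------------- inference


@dataclass
class PermutationResult:
    observed: float
    null: np.ndarray
    p: float
    seed: int
    extra: dict = field(default_factory=dict)


def _perm_design(d: DesignMatrices, rng: np.random.Generator) -> DesignMatrices:
    perm = rng.permutation(len(d.groups))
    return DesignMatrices(x=d.x, y=d.y[perm], groups=d.groups[perm],
                          group_names=d.group_names, covariates=d.covariates,
                          feature_names=d.feature_names, subjects=d.subjects)


def permutation_test(d: DesignMatrices, k: int, n_perm: int = 1000,
                     folds: int = 5, repeats: int = 10, seed: int = 0
                     ) -> PermutationResult:
    """Label-permutation test of the cross-validated casewise RMSE.

    The whole CV pipeline, including fold-wise preprocessing, is re-run for
    every permutation; p = (1 + #{null <= observed}) / (1 + n_perm).
    """
    rng = np.random.default_rng(seed)
    obs_cv = cross_validate(d, k, folds=folds, repeats=repeats,
                            seed=int(rng.integers(2**31 - 1)))[k]
    null = np.empty(n_perm)
    for b in range(n_perm):
        dp = _perm_design(d, rng)
        null[b] = cross_validate(dp, k, folds=folds, repeats=repeats,
                                 seed=int(rng.integers(2**31 - 1)))[k].mean_rmse
    obs = obs_cv.mean_rmse
    p = (1 + int((null <= obs).sum())) / (1 + n_perm)
    return PermutationResult(observed=obs, null=null, p=p, seed=seed,
                             extra={"accuracy": obs_cv.mean_accuracy,
                                    "sem_rmse": obs_cv.sem_rmse,
                                    "null_mean": float(null.mean())})


def permutation_test_auc(designs_by_cost: dict[float, DesignMatrices], k: int,
                         n_perm: int = 1000, folds: int = 5, repeats: int = 10,
                         seed: int = 0) -> PermutationResult:
    """AUC variant: statistic = trapezoid AUC of CV RMSE over cost thresholds."""
    from .graphmetrics import auc_over_costs
    costs = np.array(sorted(designs_by_cost))
    rng = np.random.default_rng(seed)

    def stat(ds: dict[float, DesignMatrices]) -> float:
        rmses = [cross_validate(ds[c], k, folds=folds, repeats=repeats,
                                seed=int(rng.integers(2**31 - 1)))[k].mean_rmse
                 for c in costs]
        return auc_over_costs(np.array(rmses), costs)

    obs = stat(designs_by_cost)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(len(next(iter(designs_by_cost.values())).groups))
        permuted = {}
        for c, d in designs_by_cost.items():
            permuted[c] = DesignMatrices(
                x=d.x, y=d.y[perm], groups=d.groups[perm],
                group_names=d.group_names, covariates=d.covariates,
                feature_names=d.feature_names, subjects=d.subjects)
        null[b] = stat(permuted)
    p = (1 + int((null <= obs).sum())) / (1 + n_perm)
    return PermutationResult(observed=obs, null=null, p=p, seed=seed)


@dataclass
class BootstrapLoadings:
    mean: np.ndarray          # p x k mean aligned loading
    sem: np.ndarray           # p x k bootstrap SE
    ratio: np.ndarray         # mean / sem, NaN where sem == 0 and mean == 0
    reference: PLSModel
    scores: np.ndarray        # boot x n x k aligned full-sample scores
    rotations: list[np.ndarray]
    feature_names: list[str]

    def top_fraction(self, frac: float, component: int) -> np.ndarray:
        """Indices of the top ``frac`` features by |bootstrap ratio|."""
        r = np.abs(self.ratio[:, component])
        n_top = max(1, int(round(frac * len(r))))
        return np.argsort(-r, kind="stable")[:n_top]

    def table(self) -> pd.DataFrame:
        k = self.mean.shape[1]
        cols = {}
        for j in range(k):
            cols[f"mean_c{j + 1}"] = self.mean[:, j]
            cols[f"sem_c{j + 1}"] = self.sem[:, j]
            cols[f"ratio_c{j + 1}"] = self.ratio[:, j]
        return pd.DataFrame(cols, index=pd.Index(self.feature_names, name="feature"))


def _fit_preprocessed(d: DesignMatrices, idx: np.ndarray, k: int
                      ) -> tuple[PLSModel, Preprocessor]:
    cov = None if d.covariates is None else d.covariates[idx]
    prep = Preprocessor().fit(d.x[idx], cov)
    model = fit_pls(prep.transform(d.x[idx], cov), d.y[idx], k)
    return model, prep


def bootstrap_loadings(d: DesignMatrices, k: int, n_boot: int = 1000,
                       seed: int = 0) -> BootstrapLoadings:
    """Bootstrap stability of X-loadings with orthogonal Procrustes alignment.

    Each resample (full sample size, with replacement) is refit end-to-end;
    its loading matrix is rotated onto the full-sample reference (SVD-based
    orthogonal Procrustes, reflections allowed) and full-sample component
    scores are recomputed under the same rotation. The bootstrap ratio is the
    mean aligned loading over its bootstrap SE.
    """
    n = len(d.groups)
    all_idx = np.arange(n)
    ref, ref_prep = _fit_preprocessed(d, all_idx, k)
    cov = d.covariates
    x_full = ref_prep.transform(d.x, cov)

    rng = np.random.default_rng(seed)
    loads = np.empty((n_boot, *ref.x_loadings.shape))
    scores = np.empty((n_boot, n, k))
    rotations = []
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if len(np.unique(d.groups[idx])) < d.y.shape[1]:
            # resample must span the groups for the one-hot block to be useful
            idx = np.concatenate([idx, [np.flatnonzero(d.groups == g)[0]
                                        for g in range(d.y.shape[1])
                                        if g not in d.groups[idx]]])[:n]
        model, prep = _fit_preprocessed(d, idx, k)
        rot, _ = orthogonal_procrustes(model.x_loadings, ref.x_loadings)
        rotations.append(rot)
        loads[b] = model.x_loadings @ rot
        xb = prep.transform(d.x, cov)
        scores[b] = model.transform(xb) @ rot
    mean = loads.mean(axis=0)
    sem = loads.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(sem > 0, mean / sem, np.nan)  # undefined at SEM = 0
    return BootstrapLoadings(mean=mean, sem=sem, ratio=ratio, reference=ref,
                             scores=scores, rotations=rotations,
                             feature_names=d.feature_names)


def score_group_test(scores: np.ndarray, groups: np.ndarray,
                     n_perm: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Two-sided permutation tests of group mean differences in scores.

    ``scores`` is subjects x components (e.g. the reference-model scores or
    the bootstrap-mean aligned scores). For every component and group pair the
    statistic is the difference in group means; labels are permuted across the
    pooled subjects of the pair.
    """
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    rng = np.random.default_rng(seed)
    uniq = sorted(pd.unique(groups))  # canonical pair order: sign is meaningful
    rows = []
    for comp in range(scores.shape[1]):
        for i, a in enumerate(uniq):
            for b_ in uniq[i + 1:]:
                sel = (groups == a) | (groups == b_)
                s = scores[sel, comp]
                is_a = groups[sel] == a
                obs = s[is_a].mean() - s[~is_a].mean()
                null = np.empty(n_perm)
                for t in range(n_perm):
                    perm = rng.permutation(is_a)
                    null[t] = s[perm].mean() - s[~perm].mean()
                p = (1 + int((np.abs(null) >= abs(obs)).sum())) / (1 + n_perm)
                rows.append({"component": comp + 1, "group_a": a, "group_b": b_,
                             "mean_diff": float(obs), "p": float(p)})
    return pd.DataFrame(rows)
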