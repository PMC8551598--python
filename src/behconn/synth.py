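"""Synthetic cohorts: behavioural ratings, regional time series, covariates.

The generator plants the statistical structure the downstream analysis
assumes — three clinical behavioural profiles plus a comparison group, and
regional BOLD-like time series drawn from a zero-mean multivariate Gaussian
with intrinsic-connectivity-network (ICN) block covariance, optionally
perturbed per group. It makes no attempt at a haemodynamic forward model or
motion artefacts in the signal; framewise displacement is simulated as an
independent covariate so quality-control rules can be exercised.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

__all__ = ["CohortSpec", "SyntheticCohort", "default_spec",
           "gen_behaviour_cohort", "gen_timeseries_cohort", "gen_null_relabel"]


def _load_defaults() -> dict:
    with importlib.resources.files("behconn").joinpath("defaults.yaml").open() as fh:
        return yaml.safe_load(fh)


@dataclass
class CohortSpec:
    """All knobs of the synthetic cohort generator (see ``defaults.yaml``)."""

    groups: list[str]
    n_per_group: int
    scale_names: list[str]
    group_profile_means: dict[str, list[float]]  # group -> per-scale T-score mean
    behaviour_noise_sd: float
    tscore_range: tuple[float, float]
    n_regions: int
    n_timepoints: int
    icn_labels: list[str]
    base_block_covariance: dict[str, float]
    group_effect: list[tuple[str, str, float, list[str]]]
    covariate_model: dict[str, float]
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.behaviour_noise_sd < 0:
            raise ValueError("behaviour_noise_sd must be >= 0")
        for g in self.groups:
            if g not in self.group_profile_means:
                raise ValueError(f"no profile means for group {g!r}")
            if len(self.group_profile_means[g]) != len(self.scale_names):
                raise ValueError(
                    f"profile for group {g!r} has "
                    f"{len(self.group_profile_means[g])} values, expected "
                    f"{len(self.scale_names)} (one per scale)")

    def icn_map(self) -> pd.DataFrame:
        """Region -> ICN assignment: contiguous near-equal blocks, L/R split."""
        n, labels = self.n_regions, self.icn_labels
        edges = np.linspace(0, n, len(labels) + 1).round().astype(int)
        rows = []
        for k, lab in enumerate(labels):
            for i in range(edges[k], edges[k + 1]):
                hemi = "L" if (i - edges[k]) < (edges[k + 1] - edges[k]) / 2 else "R"
                rows.append((f"R{i:03d}", lab, hemi))
        return pd.DataFrame(rows, columns=["region_id", "icn_label", "hemisphere"])

    def model_covariance(self, group: str | None = None) -> np.ndarray:
        """ICN block covariance, plus the group's planted deltas if any."""
        p = self.base_block_covariance
        icn = self.icn_map()["icn_label"].to_numpy()
        same = icn[:, None] == icn[None, :]
        cov = np.where(same, p["within_icn"], p["between_icn"]).astype(float)
        np.fill_diagonal(cov, p["variance"])
        if group is not None:
            for a, b, delta, grps in self.group_effect:
                if group in grps:
                    blk = (icn[:, None] == a) & (icn[None, :] == b)
                    blk |= (icn[:, None] == b) & (icn[None, :] == a)
                    blk &= ~np.eye(self.n_regions, dtype=bool)
                    cov = cov + delta * blk
        mineig = np.linalg.eigvalsh(cov).min()
        if mineig <= 0:
            where = f" after deltas for group {group!r}" if group else ""
            raise ValueError(
                f"block covariance not positive definite{where} "
                f"(min eigenvalue {mineig:.3g}); offending deltas: "
                f"{[e for e in self.group_effect if group in (e[3] if group else [])]}")
        return cov


def default_spec(**overrides) -> CohortSpec:
    """CohortSpec populated from the shipped ``defaults.yaml``."""
    d = _load_defaults()
    d["tscore_range"] = tuple(d["tscore_range"])
    d["group_effect"] = [tuple(e) for e in d["group_effect"]]
    spec = CohortSpec(**d)
    return replace(spec, **overrides) if overrides else spec


@dataclass
class SyntheticCohort:
    behaviour: pd.DataFrame          # subject_id index, group + scale columns
    true_labels: pd.Series           # subject_id -> group
    timeseries: dict[str, np.ndarray]  # subject -> regions x timepoints
    covariates: pd.DataFrame         # age, sex, mean_fd per subject
    fd_traces: pd.DataFrame          # timepoints x subjects, mm per volume
    icn_map: pd.DataFrame = field(default=None)

    @property
    def subjects(self) -> list[str]:
        return list(self.behaviour.index)


def _subject_ids(spec: CohortSpec) -> tuple[list[str], np.ndarray]:
    ids, groups = [], []
    i = 1
    for g in spec.groups:
        for _ in range(spec.n_per_group):
            ids.append(f"S{i:04d}")
            groups.append(g)
            i += 1
    return ids, np.array(groups)


def gen_behaviour_cohort(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Behaviour table: group profile mean + iid Gaussian noise per scale.

    Scores are rounded to integers and clipped to ``tscore_range``, mimicking
    integer T-scores from a rating questionnaire. Deterministic in
    ``(spec, seed)``; ``seed=None`` uses ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    ids, groups = _subject_ids(spec)
    means = np.stack([spec.group_profile_means[g] for g in groups])
    noise = rng.normal(0.0, spec.behaviour_noise_sd, size=means.shape)
    lo, hi = spec.tscore_range
    scores = np.clip(np.round(means + noise), lo, hi).astype(int)
    df = pd.DataFrame(scores, index=pd.Index(ids, name="subject_id"),
                      columns=spec.scale_names)
    df.insert(0, "group", groups)
    return df


def _gen_covariates(spec: CohortSpec, ids: list[str],
                    rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    m = spec.covariate_model
    n = len(ids)
    age = rng.uniform(*m["age_range"], size=n)
    sex = (rng.random(n) < m["p_female"]).astype(int)  # 1 = female
    base = np.exp(rng.normal(np.log(m["fd_median"]), m["fd_sigma"], size=n))
    traces = base[None, :] * np.exp(
        rng.normal(0.0, m["fd_within_sigma"], size=(spec.n_timepoints, n)))
    spikes = rng.random((spec.n_timepoints, n)) < m["spike_prob"]
    traces = traces + spikes * rng.uniform(*m["spike_extra"],
                                           size=(spec.n_timepoints, n))
    fd = pd.DataFrame(traces, columns=ids)
    cov = pd.DataFrame({"age": age, "sex": sex, "mean_fd": traces.mean(axis=0)},
                       index=pd.Index(ids, name="subject_id"))
    return cov, fd


def gen_timeseries_cohort(spec: CohortSpec, seed: int | None = None) -> SyntheticCohort:
    """Full synthetic cohort: behaviour, time series, covariates, FD traces.

    Each subject's regional time series is drawn from N(0, Sigma_g) where
    Sigma_g is the ICN block covariance plus that subject's group deltas.
    """
    master = spec.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    s_beh, s_ts, s_cov = ss.spawn(3)
    behaviour = gen_behaviour_cohort(
        spec, seed=int(s_beh.generate_state(1)[0] % (2**31)))
    ids = list(behaviour.index)
    groups = behaviour["group"]

    chol = {g: np.linalg.cholesky(spec.model_covariance(g)) for g in spec.groups}
    rng = np.random.default_rng(s_ts)
    timeseries = {}
    for sid in ids:
        z = rng.standard_normal((spec.n_regions, spec.n_timepoints))
        timeseries[sid] = chol[groups[sid]] @ z

    covariates, fd = _gen_covariates(spec, ids, np.random.default_rng(s_cov))
    return SyntheticCohort(behaviour=behaviour,
                           true_labels=groups.rename("group"),
                           timeseries=timeseries, covariates=covariates,
                           fd_traces=fd, icn_map=spec.icn_map())


def gen_null_relabel(cohort: SyntheticCohort, seed: int) -> SyntheticCohort:
    """Copy of the cohort with group labels randomly permuted (null cohort)."""
    if not cohort.subjects:
        raise ValueError("empty cohort")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(cohort.subjects))
    labels = cohort.true_labels.iloc[perm].to_numpy()
    behaviour = cohort.behaviour.copy()
    behaviour["group"] = labels
    new_labels = pd.Series(labels, index=cohort.true_labels.index, name="group")
    return replace(cohort, behaviour=behaviour, true_labels=new_labels)
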