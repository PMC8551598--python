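"""Behavioural profiling: subject network, consensus profiles, group stats.

The subject network correlates every pair of children across the six rating
scales (inattention, hyperactivity/impulsivity, learning problems, executive
function, aggression, peer relations); consensus Louvain community detection
on that signed network yields data-driven behavioural profiles, which are then
characterised with nonparametric statistics against a comparison group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import adjusted_rand_score

from . import community
from .community import ConsensusResult, Partition, match_labels

__all__ = ["SubjectNetwork", "build_subject_network", "louvain_partition",
           "consensus_partition", "partition_agreement", "profile_group_stats"]

SCALE_COLUMNS_EXCLUDED = {"group", "negative_impressions"}


@dataclass
class SubjectNetwork:
    """Subject x subject Pearson correlation network over the rating scales."""

    matrix: np.ndarray
    subjects: list[str]
    excluded: list[tuple[str, str]] = field(default_factory=list)


def _scale_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in SCALE_COLUMNS_EXCLUDED]


def build_subject_network(table: pd.DataFrame,
                          negative_impressions_cut: float | None = None
                          ) -> SubjectNetwork:
    """Correlate every pair of subjects across their scale scores.

    Subjects with zero variance across scales cannot be correlated and are
    excluded (with reason); optionally subjects whose ``negative_impressions``
    score exceeds ``negative_impressions_cut`` are excluded first, emulating
    removal of ratings with an overly negative informant bias.
    """
    if not table.index.is_unique:
        raise ValueError("subject_ids must be unique")
    scales = _scale_columns(table)
    scores = table[scales]
    if scores.isna().any().any():
        raise ValueError("missing scale scores for included subjects")
    excluded: list[tuple[str, str]] = []
    keep = pd.Series(True, index=table.index)
    if negative_impressions_cut is not None and "negative_impressions" in table:
        hi = table["negative_impressions"] > negative_impressions_cut
        for sid in table.index[hi]:
            excluded.append((sid, "negative impressions above cutoff"))
        keep &= ~hi
    zerovar = scores.std(axis=1, ddof=0) == 0
    for sid in table.index[keep & zerovar]:
        excluded.append((sid, "zero variance"))
    keep &= ~zerovar
    kept = scores.loc[keep]
    if len(kept) < 3:
        raise ValueError(f"only {len(kept)} valid subjects; need >= 3")
    mat = np.corrcoef(kept.to_numpy(dtype=float))
    np.fill_diagonal(mat, 0.0)
    return SubjectNetwork(matrix=mat, subjects=list(kept.index), excluded=excluded)


def louvain_partition(net: SubjectNetwork, gamma: float = 1.0,
                      seed: int | None = None) -> Partition:
    """Single Louvain run on the signed subject network."""
    return community.louvain(net.matrix, gamma=gamma, seed=seed)


def consensus_partition(net: SubjectNetwork, n_iter: int = 100, tau: float = 0.5,
                        gamma: float = 1.0, seed: int | None = None
                        ) -> ConsensusResult:
    """Consensus partition across ``n_iter`` Louvain runs (default 100)."""
    return community.consensus(net.matrix, n_iter=n_iter, tau=tau, gamma=gamma,
                               seed=seed)


def partition_agreement(p1: np.ndarray, p2: np.ndarray) -> tuple[float, float]:
    """(fraction identically assigned after optimal label matching, ARI)."""
    p1 = np.asarray(p1)
    p2 = np.asarray(p2)
    if p1.shape != p2.shape:
        raise ValueError("partitions cover different subject sets")
    aligned = match_labels(p1, p2)
    frac = float((aligned == community._relabel(p2)).mean())
    return frac, float(adjusted_rand_score(p1, p2))


def _mannwhitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    method = "exact" if (len(x) <= 8 and len(y) <= 8) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def profile_group_stats(table: pd.DataFrame, labels: pd.Series,
                        categorical: pd.DataFrame | None = None,
                        continuous: pd.DataFrame | None = None) -> dict:
    """Nonparametric group comparisons of the behavioural profiles.

    Mann-Whitney U per scale for every pair of groups (Bonferroni over the
    whole scale x pair family), chi-square tests of frequency differences for
    categorical variables, and Welch t-tests (Bonferroni) for continuous
    characteristics.
    """
    labels = labels.loc[table.index]
    groups = [g for g in pd.unique(labels)]
    sizes = labels.value_counts()
    scales = _scale_columns(table)
    pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]

    rows, skipped = [], []
    for a, b in pairs:
        if sizes[a] < 2 or sizes[b] < 2:
            skipped.append((a, b, "group of size < 2"))
            continue
        for s in scales:
            u, p = _mannwhitney(table.loc[labels == a, s].to_numpy(dtype=float),
                                table.loc[labels == b, s].to_numpy(dtype=float))
            rows.append({"group_a": a, "group_b": b, "scale": s,
                         "U": u, "p": p})
    scale_tests = pd.DataFrame(rows)
    if len(scale_tests):
        m = len(scale_tests)  # family: all scale x pair tests in this call
        scale_tests["p_bonferroni"] = np.minimum(1.0, scale_tests["p"] * m)

    cat_rows = []
    if categorical is not None:
        for col in categorical.columns:
            tab = pd.crosstab(labels, categorical.loc[table.index, col])
            chi2, p, dof, _ = sps.chi2_contingency(tab, correction=False)
            cat_rows.append({"variable": col, "chi2": float(chi2),
                             "p": float(p), "dof": int(dof)})

    cont_rows = []
    if continuous is not None:
        for col in continuous.columns:
            for a, b in pairs:
                t, p = sps.ttest_ind(continuous.loc[labels == a, col],
                                     continuous.loc[labels == b, col],
                                     equal_var=False)
                cont_rows.append({"variable": col, "group_a": a, "group_b": b,
                                  "t": float(t), "p": float(p)})
        if cont_rows:
            m = len(cont_rows)
            for r in cont_rows:
                r["p_bonferroni"] = min(1.0, r["p"] * m)

    return {"scales": scale_tests, "categorical": pd.DataFrame(cat_rows),
            "continuous": pd.DataFrame(cont_rows), "skipped_pairs": skipped}
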