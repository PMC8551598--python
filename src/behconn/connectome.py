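"""Functional connectome construction, QC filtering, thresholding, ICN means.

Connectomes are region x region Pearson correlation matrices of already
parcellated time series. Proportional ("cost") thresholding keeps a fixed
fraction of the strongest positive edges — either one mask from the
group-mean matrix applied to everyone (comparable edge sets) or per subject.
Motion exclusion follows the standard framewise-displacement rules (mean FD,
then spike fraction), and mean-FC outliers beyond 3 SD are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["Connectome", "correlation_connectome", "motion_filter",
           "group_threshold", "individual_threshold", "normalise_to_max",
           "fc_outlier_filter", "icn_features", "icn_feature_names"]

SMALL_POSITIVE = 0.001  # replacement for negative edges surviving a group mask
SPIKE_FD_MM = 0.5       # a volume is a motion spike if FD exceeds this


@dataclass
class Connectome:
    matrix: np.ndarray
    region_ids: list[str]
    icn_map: pd.Series | None = None  # region_id -> ICN label
    subject_id: str | None = None
    provenance: dict = field(default_factory=dict)

    def mean_fc(self) -> float:
        """Mean off-diagonal weight (upper triangle)."""
        iu = np.triu_indices_from(self.matrix, k=1)
        return float(self.matrix[iu].mean())


def correlation_connectome(ts: np.ndarray, region_ids: list[str] | None = None,
                           subject_id: str | None = None,
                           icn_map: pd.Series | None = None) -> Connectome:
    """Pearson correlation of regional time series, diagonal zeroed."""
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2 or ts.shape[1] < 3:
        raise ValueError("need a regions x timepoints matrix with >= 3 timepoints")
    if region_ids is None:
        region_ids = [f"R{i:03d}" for i in range(ts.shape[0])]
    sd = ts.std(axis=1)
    if np.any(sd == 0):
        bad = [region_ids[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant time series for regions {bad}")
    mat = np.corrcoef(ts)
    mat = 0.5 * (mat + mat.T)
    np.fill_diagonal(mat, 0.0)
    return Connectome(matrix=mat, region_ids=list(region_ids), icn_map=icn_map,
                      subject_id=subject_id,
                      provenance={"threshold": None, "normalised": False})


def motion_filter(fd_traces: pd.DataFrame, fd_cut: float = 0.5,
                  spike_cut: float = 0.2) -> pd.DataFrame:
    """Per-subject motion QC: mean-FD rule first, then spike-fraction rule.

    ``fd_traces`` is timepoints x subjects in mm. Returns a QC table with
    mean_fd, spike_fraction, included flag and exclusion reason.
    """
    if fd_traces.empty:
        raise ValueError("empty FD traces")
    mean_fd = fd_traces.mean(axis=0)
    spike_frac = (fd_traces > SPIKE_FD_MM).mean(axis=0)
    rows = []
    for sid in fd_traces.columns:
        if mean_fd[sid] > fd_cut:
            included, reason = False, "mean FD"
        elif spike_frac[sid] > spike_cut:
            included, reason = False, "spikes"
        else:
            included, reason = True, ""
        rows.append({"subject_id": sid, "mean_fd": float(mean_fd[sid]),
                     "spike_fraction": float(spike_frac[sid]),
                     "included": included, "reason": reason})
    return pd.DataFrame(rows).set_index("subject_id")


def _upper(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def _edge_mask(values: np.ndarray, n_keep: int, n: int) -> np.ndarray:
    """Boolean symmetric mask keeping the n_keep largest positive entries.

    ``values`` are the upper-triangle weights in row-major order; ties broken
    by first occurrence (stable sort), so the mask is deterministic.
    """
    n_pos = int((values > 0).sum())
    if n_pos < n_keep:
        raise ValueError(f"only {n_pos} positive edges, cannot retain {n_keep}")
    order = np.argsort(-values, kind="stable")[:n_keep]
    mask = np.zeros((n, n), dtype=bool)
    iu, ju = _upper(n)
    mask[iu[order], ju[order]] = True
    return mask | mask.T


def _n_keep(values: np.ndarray, cost: float, cost_basis: str) -> int:
    """Edge budget: fraction of all possible edges (default) or of the
    positive subset."""
    if cost_basis == "all":
        return int(np.floor(cost * values.size))
    if cost_basis == "positive":
        return int(np.floor(cost * (values > 0).sum()))
    raise ValueError("cost_basis must be 'all' or 'positive'")


def group_threshold(stack: dict[str, Connectome], cost: float = 0.25,
                    cost_basis: str = "all"
                    ) -> tuple[dict[str, Connectome], np.ndarray]:
    """Group-level proportional threshold: one mask for every subject.

    The mask keeps the top ``floor(cost * E)`` edges of the group-mean matrix
    among positive mean edges (E = number of distinct region pairs, or the
    number of positive mean edges under ``cost_basis="positive"``). Negative
    individual weights that survive the mask are set to 0.001 so that all
    retained weights are positive while the edge set stays identical across
    subjects.
    """
    if not stack:
        raise ValueError("empty connectome stack")
    mats = [c.matrix for c in stack.values()]
    n = mats[0].shape[0]
    if any(m.shape != (n, n) for m in mats):
        raise ValueError("connectomes have mismatched dimensions")
    mean = np.mean(mats, axis=0)
    iu, ju = _upper(n)
    n_keep = _n_keep(mean[iu, ju], cost, cost_basis)
    mask = _edge_mask(mean[iu, ju], n_keep, n)
    out = {}
    for sid, c in stack.items():
        w = np.where(mask, c.matrix, 0.0)
        w[mask & (w <= 0)] = SMALL_POSITIVE
        out[sid] = replace(c, matrix=w, provenance={
            **c.provenance, "threshold": "group", "cost": cost,
            "n_edges": n_keep})
    return out, mask


def individual_threshold(conn: Connectome, cost: float = 0.25,
                         cost_basis: str = "all") -> Connectome:
    """Per-subject proportional threshold from the subject's own edges."""
    n = conn.matrix.shape[0]
    iu, ju = _upper(n)
    n_keep = _n_keep(conn.matrix[iu, ju], cost, cost_basis)
    mask = _edge_mask(conn.matrix[iu, ju], n_keep, n)
    w = np.where(mask, conn.matrix, 0.0)
    w[mask & (w <= 0)] = SMALL_POSITIVE
    return replace(conn, matrix=w, provenance={
        **conn.provenance, "threshold": "individual", "cost": cost,
        "n_edges": n_keep})


def normalise_to_max(conn: Connectome) -> Connectome:
    """Divide all weights by the maximum retained weight (max becomes 1)."""
    mx = conn.matrix.max()
    if mx <= 0:
        raise ValueError("no positive weights to normalise")
    return replace(conn, matrix=conn.matrix / mx,
                   provenance={**conn.provenance, "normalised": True})


def fc_outlier_filter(stack: dict[str, Connectome], n_sd: float = 3.0
                      ) -> pd.DataFrame:
    """Flag subjects whose mean FC is outside mean +/- ``n_sd`` SD (one pass)."""
    if len(stack) < 3:
        raise ValueError("need >= 3 subjects for outlier screening")
    fc = pd.Series({sid: c.mean_fc() for sid, c in stack.items()}).sort_index()
    mu, sd = fc.mean(), fc.std(ddof=1)
    if sd == 0:
        outlier = pd.Series(False, index=fc.index)
    else:
        outlier = (fc - mu).abs() > n_sd * sd
    return pd.DataFrame({"mean_fc": fc, "included": ~outlier})


def icn_feature_names(icn_labels: list[str]) -> list[str]:
    names = [f"within_{a}" for a in icn_labels]
    names += [f"between_{a}_{b}" for a, b in combinations(icn_labels, 2)]
    return names


def icn_features(conn: Connectome, icn_labels: list[str] | None = None
                 ) -> pd.Series:
    """Mean retained-edge weight within each ICN and between each ICN pair.

    For 8 ICNs this is the 36-feature connectivity profile (8 within blocks +
    28 between blocks). Blocks with no retained edge get 0 (logged).
    """
    if conn.icn_map is None:
        raise ValueError("connectome has no ICN map")
    icn = conn.icn_map.loc[conn.region_ids].to_numpy()
    if icn_labels is None:
        icn_labels = list(pd.unique(icn))
    w = conn.matrix
    retained = w > 0
    iu, ju = _upper(w.shape[0])
    vals = {}
    for name, (a, b) in zip(
            icn_feature_names(icn_labels),
            [(a, a) for a in icn_labels] + list(combinations(icn_labels, 2))):
        in_block = ((icn[iu] == a) & (icn[ju] == b)) | \
                   ((icn[iu] == b) & (icn[ju] == a))
        sel = in_block & retained[iu, ju]
        if sel.any():
            vals[name] = float(w[iu, ju][sel].mean())
        else:
            logger.warning("no retained edges in ICN block %s (subject %s)",
                           name, conn.subject_id)
            vals[name] = 0.0
    return pd.Series(vals, name=conn.subject_id)
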