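"""Connector / provincial hub classification from nodal graph metrics.

Connector hubs bridge modules: betweenness centrality AND participation
coefficient both above the 70th percentile of regions. Provincial hubs are
central within their own module: within-module degree z above the 70th
percentile with participation below it. Percentiles use numpy's linear
interpolation; "above" is strict, so values tied with the cut are excluded —
the rules are rank-based and invariant to monotone transforms of the metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["HubSet", "classify_hubs", "aggregate_nodal"]


@dataclass
class HubSet:
    connector_ids: list[str]
    provincial_ids: list[str]
    percentile_cut: float
    basis: dict = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        rows = [{"region_id": r, "type": "connector"} for r in self.connector_ids]
        rows += [{"region_id": r, "type": "provincial"} for r in self.provincial_ids]
        return pd.DataFrame(rows, columns=["region_id", "type"])


def aggregate_nodal(per_subject: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Mean of per-subject nodal metrics over all included subjects."""
    return pd.concat(per_subject.values()).groupby(level=0, sort=False).mean()


def classify_hubs(nodal: pd.DataFrame, pct: float = 70.0) -> HubSet:
    """Classify hubs from sample-aggregated nodal metrics.

    ``nodal`` must carry ``betweenness``, ``participation`` and
    ``within_module_z`` columns indexed by region.
    """
    needed = ["betweenness", "participation", "within_module_z"]
    for col in needed:
        if col not in nodal:
            raise ValueError(f"nodal metrics missing column {col!r}")
        if np.ptp(nodal[col].to_numpy()) == 0:
            raise ValueError(f"degenerate (constant) metric vector: {col}")
    cuts = {col: np.percentile(nodal[col].to_numpy(), pct) for col in needed}
    connector = nodal.index[(nodal["betweenness"] > cuts["betweenness"])
                            & (nodal["participation"] > cuts["participation"])]
    provincial = nodal.index[(nodal["within_module_z"] > cuts["within_module_z"])
                             & (nodal["participation"] < cuts["participation"])]
    return HubSet(connector_ids=list(connector), provincial_ids=list(provincial),
                  percentile_cut=pct,
                  basis={"aggregation": "mean over subjects",
                         "percentile_cuts": {k: float(v) for k, v in cuts.items()}})
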