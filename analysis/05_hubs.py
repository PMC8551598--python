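#!/usr/bin/env python
"""Classify connector and provincial hubs from sample-mean nodal metrics.

Connector hubs: betweenness and participation both above the 70th percentile
of regions. Provincial hubs: within-module degree z above the 70th percentile
with participation below it.
Requires 04_graph_metrics.py to have run.
"""

from pathlib import Path

from behconn import hubs
from behconn.io import read_table, write_json, write_table

METRICS = Path("results/analysis/metrics")
OUT = Path("results/analysis/hubs")


def main() -> None:
    nodal = read_table(METRICS / "nodal_metrics.tsv")
    agg = nodal.drop(columns="subject_id").groupby(level=0, sort=False).mean()
    hubset = hubs.classify_hubs(agg, pct=70.0)
    write_table(hubset.table(), OUT / "hubs.tsv", index=False)
    write_json({"n_connector": len(hubset.connector_ids),
                "n_provincial": len(hubset.provincial_ids),
                **hubset.basis}, OUT / "summary.json")
    print(f"{len(hubset.connector_ids)} connector and "
          f"{len(hubset.provincial_ids)} provincial hubs "
          f"out of {len(agg)} regions")


if __name__ == "__main__":
    main()
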