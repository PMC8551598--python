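#!/usr/bin/env python
"""Build, QC-filter and threshold the functional connectomes.

Applies the motion exclusion rules (mean FD > 0.5 mm, then > 20% spike
volumes), correlates each subject's regional time series, removes mean-FC
outliers beyond 3 SD, applies the 25% group-level proportional threshold, and
writes the 36 ICN connectivity features per subject.
Requires 01_simulate_cohort.py to have run.
"""

from pathlib import Path

import pandas as pd

from behconn import connectome as cn
from behconn.io import read_matrix, read_table, write_matrix, write_table

COHORT = Path("results/analysis/cohort")
OUT = Path("results/analysis/connectome")
COST = 0.25


def main() -> None:
    fd = read_table(COHORT / "fd_traces.tsv")
    qc = cn.motion_filter(fd)
    write_table(qc, OUT / "qc_motion.tsv")
    included = list(qc.index[qc["included"]])

    icn = read_table(COHORT / "icn_map.tsv", index_col=None)
    icn_series = icn.set_index("region_id")["icn_label"]
    stack = {}
    for sid in included:
        ts = read_matrix(COHORT / "timeseries" / f"{sid}.tsv")
        stack[sid] = cn.correlation_connectome(ts, list(icn_series.index),
                                               subject_id=sid,
                                               icn_map=icn_series)
    fc_qc = cn.fc_outlier_filter(stack)
    write_table(fc_qc, OUT / "qc_meanfc.tsv")
    stack = {s: c for s, c in stack.items() if fc_qc.loc[s, "included"]}

    thr, mask = cn.group_threshold(stack, cost=COST)
    write_matrix(mask.astype(int), OUT / "group_mask.tsv")
    for sid, c in thr.items():
        write_matrix(c.matrix, OUT / "thresholded" / f"{sid}.tsv")
    icn_labels = list(pd.unique(icn_series))
    feats = pd.DataFrame({sid: cn.icn_features(c, icn_labels)
                          for sid, c in thr.items()}).T
    feats.index.name = "subject_id"
    write_table(feats, OUT / "icn_features.tsv")
    print(f"{len(thr)} connectomes retained "
          f"({int((~qc['included']).sum())} motion exclusions, "
          f"{int((~fc_qc['included']).sum())} mean-FC outliers); "
          f"group mask holds {thr[next(iter(thr))].provenance['n_edges']} edges")


if __name__ == "__main__":
    main()
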