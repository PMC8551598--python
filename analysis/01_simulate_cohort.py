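#!/usr/bin/env python
"""Generate the synthetic study cohort and write its raw tables.

Creates 200 children (comparison group + three planted clinical behavioural
profiles), each with six integer T-scores, a 100-region resting-state time
series with ICN block covariance (plus the shipped group-specific
connectivity deltas), and covariates (age, sex, framewise displacement).
Outputs go to results/analysis/cohort/.
"""

from pathlib import Path

from behconn import synth
from behconn.io import write_matrix, write_table

OUT = Path("results/analysis/cohort")
SEED = 11


def main() -> None:
    spec = synth.default_spec(n_per_group=50, seed=SEED)
    cohort = synth.gen_timeseries_cohort(spec)
    write_table(cohort.behaviour, OUT / "behaviour.tsv")
    write_table(cohort.covariates, OUT / "covariates.tsv")
    write_table(cohort.fd_traces, OUT / "fd_traces.tsv")
    write_table(cohort.icn_map, OUT / "icn_map.tsv", index=False)
    ts_dir = OUT / "timeseries"
    for sid, ts in cohort.timeseries.items():
        write_matrix(ts, ts_dir / f"{sid}.tsv")
    print(f"wrote {len(cohort.subjects)} subjects "
          f"({spec.n_regions} regions x {spec.n_timepoints} timepoints) "
          f"to {OUT}")


if __name__ == "__main__":
    main()
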