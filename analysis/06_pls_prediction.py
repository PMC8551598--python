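#!/usr/bin/env python
"""Predict profile membership from ICN connectivity with PLS.

Regresses one-hot group membership on the 36 ICN features (residualised on
age, sex, motion and mean FC), selects the component count by the
one-standard-error rule over 5-fold x 10-repeat CV, tests significance with a
label-permutation null, and assesses loading stability with Procrustes-
aligned bootstrap ratios plus component-score group tests.
Requires 03_connectomes.py to have run.
"""

from pathlib import Path

import pandas as pd

from behconn import connectome as cn
from behconn import pls as P
from behconn.io import read_matrix, read_table, write_json, write_table

COHORT = Path("results/analysis/cohort")
CONN = Path("results/analysis/connectome")
OUT = Path("results/analysis/pls")
SEED = 61
GROUPS = ["comparison", "C1", "C2", "C3"]


def main() -> None:
    feats = read_table(CONN / "icn_features.tsv")
    groups = read_table(COHORT / "behaviour.tsv")["group"]
    covs = read_table(COHORT / "covariates.tsv")
    icn = read_table(COHORT / "icn_map.tsv", index_col=None)
    icn_series = icn.set_index("region_id")["icn_label"]
    covs["mean_fc"] = pd.Series({
        sid: cn.correlation_connectome(
            read_matrix(COHORT / "timeseries" / f"{sid}.tsv"),
            list(icn_series.index)).mean_fc()
        for sid in feats.index})

    d = P.build_design(feats, groups, covs, group_order=GROUPS)
    cv = P.cross_validate(d, k_max=6, seed=SEED)
    k = P.select_components(cv)
    perm = P.permutation_test(d, k, n_perm=499, seed=SEED + 1)
    boot = P.bootstrap_loadings(d, k, n_boot=500, seed=SEED + 2)
    write_table(boot.table(), OUT / "loadings.tsv")
    gtest = P.score_group_test(boot.scores.mean(axis=0), d.groups,
                               n_perm=499, seed=SEED + 3)
    gtest["group_a"] = [GROUPS[g] for g in gtest["group_a"]]
    gtest["group_b"] = [GROUPS[g] for g in gtest["group_b"]]
    write_table(gtest, OUT / "score_group_tests.tsv", index=False)
    write_json({"k_selected": k,
                "cv": {str(kk): {"rmse": cv[kk].mean_rmse,
                                 "sem": cv[kk].sem_rmse,
                                 "accuracy": cv[kk].mean_accuracy}
                       for kk in cv},
                "permutation": {"observed_rmse": perm.observed,
                                "null_rmse": float(perm.null.mean()),
                                "p": perm.p},
                "chance_rmse": P.constant_predictor_rmse(len(GROUPS))},
               OUT / "summary.json")
    print(f"selected {k} components: CV RMSE {cv[k].mean_rmse:.3f} "
          f"(SEM {cv[k].sem_rmse:.3f}), accuracy {cv[k].mean_accuracy:.3f}, "
          f"permutation p = {perm.p:.4f} "
          f"(null RMSE {perm.null.mean():.3f})")


if __name__ == "__main__":
    main()
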