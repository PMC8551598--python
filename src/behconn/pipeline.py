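"""End-to-end orchestration: synthetic cohort -> profiles -> connectomes ->
graph metrics & hubs -> PLS -> group statistics.

Every stage seed is derived deterministically from one master seed and the
stage name, so two runs with the same config produce identical output bundles
(no timestamps are written). Outputs are TSV/JSON under the configured
directory, plus a manifest with the config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behaviour, connectome as conn_mod, graphmetrics, hubs as hubs_mod
from . import pls as pls_mod, stats as stats_mod, synth
from .io import write_json, write_matrix, write_table

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]


@dataclass
class RunConfig:
    out_dir: str = "results/run"
    seed: int = 0
    # synth
    n_per_group: int = 50
    n_regions: int = 100
    n_timepoints: int = 266
    behaviour_noise_sd: float = 5.0
    # behaviour
    cluster_exclude_groups: tuple = ("comparison",)
    n_iter: int = 100
    tau: float = 0.5
    gamma: float = 1.0
    negative_impressions_cut: float | None = None
    # connectome
    cost: float = 0.25
    costs: tuple = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30)
    fd_cut: float = 0.5
    spike_cut: float = 0.2
    # graph metrics
    n_nulls: int = 100
    swaps_per_edge: int = 10
    # hubs
    hub_pct: float = 70.0
    # pls
    k_max: int = 8
    folds: int = 5
    repeats: int = 10
    n_perm: int = 1000
    n_boot: int = 1000
    # stage toggles
    stages: tuple = ("synth", "behaviour", "connectome", "metrics", "hubs",
                     "pls", "stats")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        return cfg

    def validate(self) -> None:
        order = ["synth", "behaviour", "connectome", "metrics", "hubs",
                 "pls", "stats"]
        enabled = set(self.stages)
        unknown = enabled - set(order)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        needs = {"metrics": "connectome", "hubs": "metrics",
                 "pls": "connectome", "stats": "metrics",
                 "behaviour": "synth", "connectome": "synth"}
        for stage, dep in needs.items():
            if stage in enabled and dep not in enabled:
                raise ValueError(f"stage {stage!r} requires stage {dep!r}")


def stage_seed(master: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _config_dict(cfg: RunConfig) -> dict:
    # the output location is not part of the scientific configuration
    return {k: v for k, v in asdict(cfg).items() if k != "out_dir"}


def _config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(_config_dict(cfg), sort_keys=True,
                   default=str).encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the enabled stages in order; returns a dict of key results."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {}

    # ---- synth ----------------------------------------------------------
    spec = synth.default_spec(n_per_group=cfg.n_per_group,
                              n_regions=cfg.n_regions,
                              n_timepoints=cfg.n_timepoints,
                              behaviour_noise_sd=cfg.behaviour_noise_sd,
                              seed=stage_seed(cfg.seed, "synth"))
    cohort = synth.gen_timeseries_cohort(spec)
    write_table(cohort.behaviour, out / "behaviour.tsv")
    write_table(cohort.covariates, out / "covariates.tsv")
    write_table(cohort.icn_map, out / "icn_map.tsv", index=False)
    logger.info("synth: %d subjects, %d regions", len(cohort.subjects),
                cfg.n_regions)

    # ---- behaviour profiling -------------------------------------------
    consensus_res = None
    labels_for_analysis = cohort.true_labels
    if "behaviour" in cfg.stages:
        clin = cohort.behaviour[
            ~cohort.behaviour["group"].isin(cfg.cluster_exclude_groups)]
        net = behaviour.build_subject_network(
            clin, negative_impressions_cut=cfg.negative_impressions_cut)
        consensus_res = behaviour.consensus_partition(
            net, n_iter=cfg.n_iter, tau=cfg.tau, gamma=cfg.gamma,
            seed=stage_seed(cfg.seed, "behaviour"))
        part = pd.DataFrame({"subject_id": net.subjects,
                             "community": consensus_res.partition.labels})
        write_table(part, out / "partition.tsv", index=False)
        write_matrix(consensus_res.agreement, out / "agreement.tsv")
        truth = cohort.true_labels.loc[net.subjects]
        _, ari = behaviour.partition_agreement(
            consensus_res.partition.labels,
            pd.Categorical(truth).codes)
        pstats = behaviour.profile_group_stats(
            cohort.behaviour.drop(columns="group"), cohort.true_labels)
        write_table(pstats["scales"], out / "profile_stats.tsv", index=False)
        report["behaviour"] = {
            "Q": consensus_res.partition.q,
            "n_communities": consensus_res.partition.n_communities,
            "stability": consensus_res.stability,
            "ari_vs_truth": ari,
        }

    # ---- QC + connectomes ----------------------------------------------
    if "connectome" not in cfg.stages:
        manifest = {"config": _config_dict(cfg),
                    "config_hash": _config_hash(cfg),
                    "stage_seeds": {s: stage_seed(cfg.seed, s)
                                    for s in cfg.stages}}
        write_json(manifest, out / "manifest.json")
        write_json(report, out / "report.json")
        return report
    qc = conn_mod.motion_filter(cohort.fd_traces, fd_cut=cfg.fd_cut,
                                spike_cut=cfg.spike_cut)
    write_table(qc, out / "qc_motion.tsv")
    included = list(qc.index[qc["included"]])
    icn_series = cohort.icn_map.set_index("region_id")["icn_label"]
    raw_stack = {sid: conn_mod.correlation_connectome(
        cohort.timeseries[sid], region_ids=list(icn_series.index),
        subject_id=sid, icn_map=icn_series) for sid in included}
    fc_qc = conn_mod.fc_outlier_filter(raw_stack)
    write_table(fc_qc, out / "qc_meanfc.tsv")
    raw_stack = {sid: c for sid, c in raw_stack.items()
                 if fc_qc.loc[sid, "included"]}
    thr_stack, mask = conn_mod.group_threshold(raw_stack, cost=cfg.cost)
    write_matrix(mask.astype(int), out / "group_mask.tsv")
    feats = pd.DataFrame({sid: conn_mod.icn_features(c, spec.icn_labels)
                          for sid, c in thr_stack.items()}).T
    feats.index.name = "subject_id"
    write_table(feats, out / "icn_features.tsv")
    report["connectome"] = {"n_included": len(thr_stack),
                            "n_excluded_motion": int((~qc["included"]).sum()),
                            "n_excluded_fc": int((~fc_qc["included"]).sum()),
                            "n_edges": int(mask[np.triu_indices_from(mask, 1)].sum())}

    mean_fc = pd.Series({sid: c.mean_fc() for sid, c in raw_stack.items()},
                        name="mean_fc")
    covs = cohort.covariates.loc[list(thr_stack)].join(mean_fc)
    covs = covs[["age", "sex", "mean_fd", "mean_fc"]]
    labels_inc = labels_for_analysis.loc[list(thr_stack)]

    # ---- graph metrics --------------------------------------------------
    if "metrics" in cfg.stages:
        mseed = stage_seed(cfg.seed, "metrics")
        icn_codes = icn_series.to_numpy()
        glob_rows, nodal_by_subj = {}, {}
        for i, (sid, c) in enumerate(thr_stack.items()):
            glob_rows[sid] = graphmetrics.global_metrics(c.matrix, seed=mseed + i)
            nodal_by_subj[sid] = graphmetrics.nodal_metrics(
                c.matrix, icn_codes, region_ids=c.region_ids)
        glob = pd.DataFrame(glob_rows).T
        glob.index.name = "subject_id"
        write_table(glob, out / "global_metrics_raw.tsv")
        # normalisation by nulls of the group-mean thresholded connectome
        mean_thr = np.mean([c.matrix for c in thr_stack.values()], axis=0)
        nulls = graphmetrics.null_ensemble(mean_thr, n_nulls=cfg.n_nulls,
                                           swaps_per_edge=cfg.swaps_per_edge,
                                           seed=mseed)
        norm = pd.DataFrame({
            sid: graphmetrics.normalise_metrics(row.to_dict(), nulls)
            for sid, row in glob.iterrows()}).T
        norm.index.name = "subject_id"
        write_table(norm, out / "global_metrics_normalised.tsv")
        write_json({"null_means": nulls.means.to_dict(),
                    "n_nulls": cfg.n_nulls}, out / "null_ensemble.json")
        report["metrics"] = {"mean_normalised_smallworldness":
                             float(norm["small_worldness"].mean())}

    # ---- hubs -----------------------------------------------------------
    if "hubs" in cfg.stages:
        agg = hubs_mod.aggregate_nodal(nodal_by_subj)
        write_table(agg, out / "nodal_metrics_mean.tsv")
        hubset = hubs_mod.classify_hubs(agg, pct=cfg.hub_pct)
        write_table(hubset.table(), out / "hubs.tsv", index=False)
        report["hubs"] = {"n_connector": len(hubset.connector_ids),
                          "n_provincial": len(hubset.provincial_ids)}

    # ---- PLS ------------------------------------------------------------
    if "pls" in cfg.stages:
        pseed = stage_seed(cfg.seed, "pls")
        design = pls_mod.build_design(feats, labels_inc, covs,
                                      group_order=list(spec.groups))
        cv = pls_mod.cross_validate(design, k_max=min(cfg.k_max, feats.shape[1] - 1),
                                    folds=cfg.folds, repeats=cfg.repeats,
                                    seed=pseed)
        k_star = pls_mod.select_components(cv)
        perm = pls_mod.permutation_test(design, k_star, n_perm=cfg.n_perm,
                                        folds=cfg.folds, repeats=cfg.repeats,
                                        seed=pseed + 1)
        boot = pls_mod.bootstrap_loadings(design, k_star, n_boot=cfg.n_boot,
                                          seed=pseed + 2)
        write_table(boot.table(), out / "pls_loadings.tsv")
        scores = boot.scores.mean(axis=0)
        gtest = pls_mod.score_group_test(scores, design.groups,
                                         n_perm=cfg.n_perm, seed=pseed + 3)
        gtest["group_a"] = [design.group_names[g] for g in gtest["group_a"]]
        gtest["group_b"] = [design.group_names[g] for g in gtest["group_b"]]
        write_table(gtest, out / "pls_score_tests.tsv", index=False)
        report["pls"] = {
            "k_selected": k_star,
            "cv_rmse": cv[k_star].mean_rmse,
            "cv_rmse_sem": cv[k_star].sem_rmse,
            "cv_accuracy": cv[k_star].mean_accuracy,
            "perm_p": perm.p,
            "perm_null_rmse": float(perm.null.mean()),
        }
        write_json({str(k): {"rmse": cv[k].mean_rmse, "sem": cv[k].sem_rmse,
                             "accuracy": cv[k].mean_accuracy}
                    for k in cv}, out / "pls_cv.json")

    # ---- ANCOVA stats ---------------------------------------------------
    if "stats" in cfg.stages:
        sseed = stage_seed(cfg.seed, "stats")
        rows = {}
        for metric in ["strength", "modularity", "path_length",
                       "global_efficiency", "clustering", "small_worldness"]:
            res = stats_mod.ancova(norm[metric], labels_inc, covs,
                                   pairwise=False)
            rows[metric] = {"F": res.f, "p": res.p, "eta_p2": res.eta_p2}
        anc = pd.DataFrame(rows).T
        anc.index.name = "metric"
        write_table(anc, out / "ancova_global.tsv")
        report["stats"] = {"max_F": float(anc["F"].max())}

    manifest = {"config": _config_dict(cfg), "config_hash": _config_hash(cfg),
                "stage_seeds": {s: stage_seed(cfg.seed, s) for s in cfg.stages}}
    write_json(manifest, out / "manifest.json")
    write_json(report, out / "report.json")
    return report
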