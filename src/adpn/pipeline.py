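"""End-to-end orchestration: simulate -> preprocess -> classify -> explain ->
longitudinal/clinical -> psychosis prediction -> network analysis.

Every stage's randomness derives deterministically from one global seed, and a
provenance manifest (config hash, derived seeds, output checksums) is written
next to the artifacts so a run can be audited and reproduced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, clinical, explain, graph, prediction
from .classify import TrainConfig, evaluate_classifier, baseline_roi_svm
from .synthetic import (GROUP_ADNP, GROUP_ADP, GROUP_HEC, SimConfig,
                        generate_cohort)
from .volumes import Volume, normalize_to_reference, roi_means_matrix

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "demo_sim_config", "run_pipeline", "load_run_config"]


def demo_sim_config(seed: int = 0, **overrides) -> SimConfig:
    """The desk-scale demonstration cohort: the full three-group longitudinal
    design at reduced group sizes, with a strongly separated disease effect
    so the case/control classification is near-ceiling by construction."""
    kwargs = dict(
        n_subjects={GROUP_HEC: 88, GROUP_ADP: 88, GROUP_ADNP: 88},
        effect_size_disease=1.5,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@dataclass
class RunConfig:
    """Single auditable home for every stage's thresholds and seeds."""

    out_dir: str = "run"
    seed: int = 0
    sim: dict = field(default_factory=dict)           # SimConfig overrides
    train: dict = field(default_factory=dict)         # TrainConfig overrides
    n_models: int = 3          # init-ensemble size for stable saliency scoring
    train_fraction: float = 0.8
    selection_alpha: float = 0.05
    clinical_train_fraction: float = 0.5
    predict_folds: int = 5
    graph_r_gate: float = 0.6
    graph_dr_gate: float = 0.2
    graph_n_perm: int = 1000
    graph_n_boot: int = 100
    graph_grid: tuple = graph.DEFAULT_THRESHOLD_GRID
    write_scans: bool = False
    log_level: str = "INFO"

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2 ** 31 - 1)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["graph_grid"] = [float(g) for g in d["graph_grid"]]
        Path(path).write_text(yaml.safe_dump(d))


def load_run_config(path: str | Path) -> RunConfig:
    d = yaml.safe_load(Path(path).read_text())
    if "graph_grid" in d:
        d["graph_grid"] = tuple(d["graph_grid"])
    return RunConfig(**d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def validate_config(config: RunConfig) -> list[str]:
    """Pre-flight validation of every stage config; returns problem list."""
    problems = []
    try:
        SimConfig(**{**config.sim, "seed": config.seed})
    except (ValueError, TypeError) as exc:
        problems.append(f"sim: {exc}")
    try:
        TrainConfig(**config.train)
    except TypeError as exc:
        problems.append(f"train: {exc}")
    if not (0 < config.train_fraction < 1):
        problems.append("train_fraction must be in (0,1)")
    if not (0 < config.selection_alpha <= 1):
        problems.append("selection_alpha must be in (0,1]")
    if list(config.graph_grid) != sorted(config.graph_grid) or not config.graph_grid:
        problems.append("graph_grid must be non-empty ascending")
    return problems


def run_pipeline(config: RunConfig, dry_run: bool = False) -> dict:
    """Execute the full analysis on a synthetic cohort.

    Returns a results dictionary (also serialized under ``out_dir``); raises
    with the failing stage's name on error, leaving earlier outputs intact.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid configuration: " + "; ".join(problems))
    if dry_run:
        return {"dry_run": True, "problems": []}

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"seed": config.seed}
    provenance: dict = {"config_sha": hashlib.sha256(
        json.dumps(dataclasses.asdict(config), sort_keys=True, default=str).encode()).hexdigest(),
        "stage_seeds": {}, "outputs": {}}
    stage = "simulate"
    try:
        # ------------------------------------------------------------- simulate
        sim_cfg = SimConfig(**{**config.sim, "seed": config.stage_seed("simulate")})
        provenance["stage_seeds"][stage] = sim_cfg.seed
        manifest, gt, atlas, volumes = generate_cohort(
            sim_cfg, out_dir=out / "sim" if config.write_scans else None)
        if config.write_scans:
            from .volumes import read_volume
            volumes = {r.scan_id: read_volume(out / "sim" / r.path)
                       for r in manifest.itertuples()}
        manifest.to_csv(out / "manifest.csv", index=False)
        gt.to_json(out / "ground_truth.json")

        # ----------------------------------------------------------- preprocess
        stage = "preprocess"
        volumes = {sid: normalize_to_reference(v, atlas) for sid, v in volumes.items()}
        roi = roi_means_matrix([volumes[s] for s in manifest["scan_id"]], atlas,
                               list(manifest["scan_id"]))
        roi.to_csv(out / "roi_means.csv")

        # ---------------------------------------------------------------- train
        stage = "train"
        split = classify.make_subject_split(manifest, (GROUP_ADP, GROUP_HEC),
                                            config.train_fraction,
                                            seed=config.stage_seed("split"))
        tr_cfg = TrainConfig(**{**config.train, "seed": config.stage_seed("train")})
        provenance["stage_seeds"]["train"] = tr_cfg.seed
        tr_vols = [volumes[s] for s in split.train_scans["scan_id"]]
        te_vols = [volumes[s] for s in split.test_scans["scan_id"]]
        ensemble = classify.train_classifier_ensemble(
            tr_vols, split.train_scans["label"].to_numpy(), config=tr_cfg,
            n_models=config.n_models)
        clf = ensemble[0]
        cnn_metrics = evaluate_classifier(clf, te_vols, split.test_scans["label"].to_numpy())
        tr_idx = roi.index.get_indexer(split.train_scans["scan_id"])
        te_idx = roi.index.get_indexer(split.test_scans["scan_id"])
        y_split = np.concatenate([split.train_scans["label"], split.test_scans["label"]])
        svm_metrics = baseline_roi_svm(
            pd.concat([roi.iloc[tr_idx], roi.iloc[te_idx]]), y_split,
            train_idx=np.arange(len(tr_idx)),
            test_idx=np.arange(len(tr_idx), len(tr_idx) + len(te_idx)))
        results["classifier"] = {"cnn": cnn_metrics.as_dict(), "roi_svm": svm_metrics.as_dict()}
        clf.fit_report.to_csv(out / "fit_report.csv", index=False)

        # -------------------------------------------------------------- explain
        stage = "explain"
        order = list(manifest["scan_id"])
        expression = explain.ensemble_expression(ensemble, volumes, order, atlas,
                                                 target_class=1)
        expression.to_csv(out / "expression.csv")
        meta = manifest.set_index("scan_id")
        train_scan_ids = list(split.train_scans["scan_id"])
        expr_train = expression.loc[train_scan_ids]
        groups_train = meta.loc[train_scan_ids, "group"]
        selection = explain.select_regions(expr_train, groups_train,
                                           (GROUP_ADP, GROUP_HEC),
                                           direction=GROUP_ADP,
                                           alpha=config.selection_alpha)
        hec_selection = explain.select_regions(expr_train, groups_train,
                                              (GROUP_HEC, GROUP_ADP),
                                              direction=GROUP_HEC,
                                              alpha=config.selection_alpha)
        results["network_regions"] = selection.selected_region_ids
        results["control_regions"] = hec_selection.selected_region_ids
        ref_ids = [s for s in train_scan_ids
                   if meta.at[s, "group"] == GROUP_HEC and meta.at[s, "months"] == 0]
        scores, ref_stats = explain.composite_score(expression,
                                                    selection.selected_region_ids, ref_ids)
        scores.join(meta[["subject_id", "group", "months", "cdrsb", "mmse"]]).to_csv(
            out / "composite_scores.csv")
        (out / "selection.json").write_text(json.dumps(
            {"network_regions": results["network_regions"],
             "control_regions": results["control_regions"],
             "reference": ref_stats}, indent=2))
        # group-average explainable maps (canonical classifier), for display
        from .volumes import write_volume
        for grp in (GROUP_HEC, GROUP_ADP, GROUP_ADNP):
            ids = [s for s in order
                   if meta.at[s, "group"] == grp and meta.at[s, "months"] == 0]
            if not ids:
                continue
            gmaps = [explain.gradcam(clf, volumes[s], target_class=1, scan_id=s,
                                     output_shape=atlas.shape) for s in ids]
            mean_map = explain.group_mean_map(gmaps, scan_id=f"mean_{grp}")
            write_volume(Volume(mean_map.data, atlas.voxel_size_mm, "explain-map"),
                         out / f"group_map_{grp.replace('+', 'p').replace('-', 'n')}.nii.gz")

        # ----------------------------------------------- longitudinal + clinical
        stage = "clinical"
        joined = scores.join(meta[["subject_id", "group", "months", "cdrsb", "mmse"]])
        longitudinal = {}
        for grp in (GROUP_ADP, GROUP_HEC):
            sub = joined[joined["group"] == grp].rename(columns={"z": "score"})
            longi_subjects = sub.groupby("subject_id")["months"].nunique()
            sub = sub[sub["subject_id"].isin(longi_subjects[longi_subjects > 1].index)]
            if sub["months"].nunique() >= 2:
                res = clinical.longitudinal_glm(sub[["subject_id", "months", "score"]], group=grp)
                longitudinal[grp] = {"f": res.f_stat, "p": res.p_omnibus,
                                     "contrasts": res.contrasts.to_dict("records")}
        results["longitudinal"] = longitudinal

        adp_base = joined[(joined["group"] == GROUP_ADP) & (joined["months"] == 0)]
        expr_adp = expression.loc[adp_base.index, results["network_regions"]]
        pred = clinical.fit_clinical_regression(expr_adp, adp_base["cdrsb"],
                                                train_fraction=config.clinical_train_fraction,
                                                seed=config.stage_seed("clinical"))
        test_rows = pred.predictions[pred.predictions["role"] == "test"]
        r_mmse, p_mmse = clinical.correlate(test_rows["predicted"].to_numpy(),
                                            adp_base.loc[test_rows.index, "mmse"].to_numpy())
        results["clinical"] = {"cdrsb_r_train": pred.r_train, "cdrsb_r_test": pred.r_test,
                               "cdrsb_p_test": pred.p_test, "mmse_r": r_mmse,
                               "mmse_p": p_mmse, "regularized": pred.regularized}

        # -------------------------------------------------------------- predict
        stage = "predict"
        base = meta[(meta["months"] == 0) & meta["group"].isin([GROUP_ADP, GROUP_ADNP])]
        expr_b = expression.loc[base.index]
        report = prediction.predict_psychosis(
            expr_b, base["group"], base["subject_id"], GROUP_ADP, GROUP_ADNP,
            k_folds=config.predict_folds, seed=config.stage_seed("predict"),
            selection_alpha=config.selection_alpha)
        report_roi = prediction.predict_psychosis(
            expr_b, base["group"], base["subject_id"], GROUP_ADP, GROUP_ADNP,
            k_folds=config.predict_folds, seed=config.stage_seed("predict"),
            feature_table=roi.loc[base.index], selection_alpha=config.selection_alpha)
        results["psychosis_prediction"] = {"expression": report.pooled.as_dict(),
                                           "roi_baseline": report_roi.pooled.as_dict()}

        # ---------------------------------------------------------------- graph
        stage = "graph"
        nodes = results["network_regions"]
        gseed = config.stage_seed("graph")
        activities = {}
        for grp in (GROUP_HEC, GROUP_ADP, GROUP_ADNP):
            ids = meta[(meta["group"] == grp) & (meta["months"] == 0)].index
            activities[grp] = graph.node_activity(roi.loc[ids], node_ids=nodes, group=grp)
        adj = {grp: graph.bootstrap_adjacency(act, n_boot=config.graph_n_boot, seed=gseed)
               for grp, act in activities.items()}
        for grp, a in adj.items():
            a.r_values.to_csv(out / f"adjacency_{grp.replace('+', 'p').replace('-', 'n')}.csv")
        changes_pn = graph.detect_edge_changes(
            activities[GROUP_ADP], activities[GROUP_ADNP],
            r_gate=config.graph_r_gate, dr_gate=config.graph_dr_gate,
            n_perm=config.graph_n_perm, n_boot=config.graph_n_boot, seed=gseed)
        changes_ph = graph.detect_edge_changes(
            activities[GROUP_ADP], activities[GROUP_HEC],
            r_gate=config.graph_r_gate, dr_gate=config.graph_dr_gate,
            n_perm=config.graph_n_perm, n_boot=config.graph_n_boot, seed=gseed)
        changes_pn.to_csv(out / "edge_changes_adp_vs_adnp.tsv", sep="\t", index=False)
        changes_ph.to_csv(out / "edge_changes_adp_vs_hec.tsv", sep="\t", index=False)
        results["edge_changes"] = {
            "adp_vs_adnp": changes_pn[changes_pn["change"] != "none"].to_dict("records"),
            "adp_vs_hec": changes_ph[changes_ph["change"] != "none"].to_dict("records")}
        metric_tables = {grp: graph.metrics_over_thresholds(
            act, grid=config.graph_grid, n_boot=min(config.graph_n_boot, 25),
            seed=gseed, n_random=5) for grp, act in activities.items()}
        pd.concat(metric_tables.values()).to_csv(out / "graph_metrics.csv", index=False)
        comparisons = {}
        for metric in ("mean_degree", "clustering", "path_length", "small_worldness"):
            comparisons[metric] = graph.compare_metrics_glm(
                metric_tables[GROUP_ADP], metric_tables[GROUP_ADNP], metric)
        results["graph_comparisons_adp_vs_adnp"] = {
            m: {"f": c["f_group"], "p": c["p_group"]} for m, c in comparisons.items()}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    # ------------------------------------------------------------- provenance
    (out / "results.json").write_text(json.dumps(results, indent=2, default=float))
    for p in sorted(out.glob("*")):
        if p.is_file() and p.name != "provenance.json":
            provenance["outputs"][p.name] = _sha256(p)
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return results
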