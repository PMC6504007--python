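"""End-to-end orchestration: counts → FPKM → DE → staging → markers → QC.

A run is driven by one :class:`PipelineConfig` (inputs or a simulation
request, thresholds, output directory, seed) and writes every module's
tables plus a manifest echoing the full configuration, so a results
directory is self-describing and a fixed config + seed reproduces it
byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as edio
from . import lineage_panels, qc, quantify, simdata, stagedyn
from .diffexpr import DEResult, DEThresholds, de_noreplicate, de_replicated
from .stagedyn import StageOrdering

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    counts: str | None = None
    annotation: str | None = None
    sample_sheet: str | None = None
    simulate: simdata.SimConfig | None = None
    design: str = "design27"
    stage_labels: tuple[str, ...] = simdata.DEFAULT_STAGES
    thresholds: DEThresholds = field(default_factory=DEThresholds)
    stage_specific_hi: float = 5.0
    stage_specific_lo: float = 1.0
    first_expressed_cut: float = 1.0
    marker_te_max: float = 1.0
    marker_it_min: float = 10.0
    expressed_threshold: float = 1.0
    outdir: str = "embryodyn_out"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.simulate is None:
            for label, path in (("counts", self.counts),
                                ("annotation", self.annotation),
                                ("sample_sheet", self.sample_sheet)):
                if path is None:
                    raise PipelineError(
                        f"config lacks {label!r} and no simulation is requested")
                if not Path(path).exists():
                    raise PipelineError(f"{label} file {path!r} does not exist")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path, encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        if "simulate" in raw and raw["simulate"] is not None:
            sim = dict(raw["simulate"])
            if "stage_labels" in sim:
                sim["stage_labels"] = tuple(sim["stage_labels"])
            if "group_perturbations" in sim:
                sim["group_perturbations"] = {
                    k: tuple(v) for k, v in sim["group_perturbations"].items()}
            raw["simulate"] = simdata.SimConfig(**sim)
        if "thresholds" in raw:
            raw["thresholds"] = DEThresholds(**raw["thresholds"])
        if "stage_labels" in raw:
            raw["stage_labels"] = tuple(raw["stage_labels"])
        return cls(**raw)

    def to_dict(self) -> dict:
        out = asdict(self)
        out["stage_labels"] = list(self.stage_labels)
        if self.simulate is not None:
            sim = asdict(self.simulate)
            sim["stage_labels"] = list(self.simulate.stage_labels)
            out["simulate"] = sim
        return out


def _group_ordering(sheet: pd.DataFrame, group: str,
                    stage_labels) -> StageOrdering | None:
    """The group's embryo stage series, in master order; None if < 2 stages."""
    present = set(sheet.loc[(sheet["group"] == group)
                            & (sheet["lineage"] == "none"), "stage"])
    stages = tuple(s for s in stage_labels if s in present)
    return StageOrdering(stages) if len(stages) >= 2 else None


def _is_replicated(sheet: pd.DataFrame, group: str) -> bool:
    sub = sheet[(sheet["group"] == group) & (sheet["lineage"] == "none")]
    return bool((sub.groupby("stage")["sample_id"].count() >= 2).any())


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write its tables; returns the manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "embryodyn",
        "version": __version__,
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "seed": config.seed,
        "config": config.to_dict(),
        "tables": {},
    }

    # ---- inputs -----------------------------------------------------------
    try:
        if config.simulate is not None:
            sim_cfg = simdata.replace(config.simulate, seed=config.seed)
            dataset = simdata.simulate_dataset(sim_cfg, config.design)
            simdata.write_dataset(dataset, outdir / "inputs")
            counts, annotation, sheet = (dataset.counts, dataset.annotation,
                                         dataset.sample_sheet)
            stage_labels = sim_cfg.stage_labels
        else:
            counts = edio.read_counts(config.counts)
            annotation = edio.read_annotation(config.annotation)
            sheet = edio.read_sample_sheet(config.sample_sheet)
            stage_labels = config.stage_labels
            simdata.validate_sample_sheet(sheet, stage_labels)
    except Exception as err:
        raise PipelineError(f"input stage failed: {err}") from err

    # ---- quantify ---------------------------------------------------------
    try:
        fpkm = quantify.compute_fpkm(counts, annotation)
        _, n_expressed = quantify.call_expressed(fpkm, config.expressed_threshold)
        try:
            mr = quantify.size_factors_median_ratio(counts)
        except ValueError:
            mr = None
            logger.warning("median-of-ratios unavailable; replicated contrasts "
                           "will fall back to TMM effective sizes")
        tmm = quantify.trimmed_mean_factors(counts)
        edio.write_matrix(fpkm, outdir / "fpkm.tsv")
        factors = pd.DataFrame({
            "sample_id": counts.columns,
            "library_size": counts.sum(axis=0).to_numpy(),
            "n_expressed": n_expressed.to_numpy(),
            "tmm_factor": tmm.factors.to_numpy(),
            "tmm_effective_size": tmm.effective_sizes.to_numpy(),
        })
        if mr is not None:
            factors["size_factor_median_ratio"] = mr.factors.to_numpy()
        edio.write_table(factors, outdir / "norm_factors.tsv")
        manifest["tables"]["fpkm"] = len(fpkm)
        manifest["tables"]["norm_factors"] = len(factors)
        manifest["fpkm_denominator"] = "total counted fragments in matrix"
        manifest["tmm_reference"] = tmm.reference
    except Exception as err:
        raise PipelineError(f"quantify stage failed: {err}") from err

    # ---- differential expression ------------------------------------------
    groups = [g for g in sheet["group"].unique()
              if _group_ordering(sheet, g, stage_labels) is not None]
    de_tables = []
    successive: dict[str, dict[tuple[str, str], DEResult]] = {}
    try:
        size_factors = (mr.factors if mr is not None
                        else tmm.effective_sizes / tmm.effective_sizes.mean())
        for group in groups:
            ordering = _group_ordering(sheet, group, stage_labels)
            sub = sheet[(sheet["group"] == group) & (sheet["lineage"] == "none")]
            replicated = _is_replicated(sheet, group)
            successive[group] = {}
            for earlier, later in ordering.transitions():
                ids_e = sub.loc[sub["stage"] == earlier, "sample_id"].tolist()
                ids_l = sub.loc[sub["stage"] == later, "sample_id"].tolist()
                if replicated:
                    res = de_replicated(counts, size_factors, ids_l, ids_e,
                                        config.thresholds)
                    res.condition_a = f"{group}_{later}"
                    res.condition_b = f"{group}_{earlier}"
                else:
                    res = de_noreplicate(counts, tmm.effective_sizes,
                                         ids_l[0], ids_e[0], config.thresholds)
                successive[group][(earlier, later)] = res
                de_tables.append(res)
        # same-stage contrasts of each cloned group against IV-D
        if "IV-D" in groups:
            for group in groups:
                if group == "IV-D":
                    continue
                ga = _group_ordering(sheet, group, stage_labels)
                gb = _group_ordering(sheet, "IV-D", stage_labels)
                for stage in [s for s in ga.stages if s in gb.stages]:
                    ids_a = sheet.loc[(sheet["group"] == group)
                                      & (sheet["stage"] == stage)
                                      & (sheet["lineage"] == "none"),
                                      "sample_id"].tolist()
                    ids_b = sheet.loc[(sheet["group"] == "IV-D")
                                      & (sheet["stage"] == stage)
                                      & (sheet["lineage"] == "none"),
                                      "sample_id"].tolist()
                    if len(ids_a) >= 2 and len(ids_b) >= 2:
                        res = de_replicated(counts, size_factors, ids_a, ids_b,
                                            config.thresholds)
                        res.condition_a = f"{group}_{stage}"
                        res.condition_b = f"IV-D_{stage}"
                    else:
                        res = de_noreplicate(counts, tmm.effective_sizes,
                                             ids_a[0], ids_b[0],
                                             config.thresholds)
                    de_tables.append(res)
        from .diffexpr import de_result_frame

        de_out = pd.concat([de_result_frame(r, annotation) for r in de_tables])
        edio.write_table(de_out, outdir / "de_results.tsv")
        manifest["tables"]["de_results"] = len(de_out)
        manifest["contrasts"] = [r.contrast for r in de_tables]
    except Exception as err:
        raise PipelineError(f"diffexpr stage failed: {err}") from err

    # ---- staging ----------------------------------------------------------
    try:
        transition_rows, ss_rows, fe_rows = [], [], []
        fe_sets: dict[str, dict[str, set]] = {}
        for group in groups:
            ordering = _group_ordering(sheet, group, stage_labels)
            means = stagedyn.stage_mean_fpkm(fpkm, sheet, group, ordering)
            trans = stagedyn.successive_stage_degs(successive[group], ordering)
            trans.insert(0, "group", group)
            transition_rows.append(trans)
            ss = stagedyn.classify_stage_specific(
                means, ordering, annotation,
                hi=config.stage_specific_hi, lo=config.stage_specific_lo)
            ss.insert(0, "group", group)
            ss_rows.append(ss)
            de_prev = {later: successive[group][(earlier, later)]
                       for earlier, later in ordering.transitions()}
            fe = stagedyn.detect_first_expressed(
                means, de_prev, ordering,
                expr=config.first_expressed_cut,
                q_cut=config.thresholds.q_cut_rep)
            fe.insert(0, "group", group)
            fe_rows.append(fe)
            for stage, sub in fe.groupby("stage"):
                fe_sets.setdefault(stage, {})[group] = set(sub["gene_id"])
        transitions = pd.concat(transition_rows, ignore_index=True)
        stage_specific = pd.concat(ss_rows, ignore_index=True)
        first_expressed = pd.concat(fe_rows, ignore_index=True)
        venn_rows = []
        for stage in [s for s in stage_labels if s in fe_sets]:
            per_group = fe_sets[stage]
            if len(per_group) >= 2:
                venn = stagedyn.overlap_sets(
                    {g: per_group[g] for g in sorted(per_group)[:3]})
                venn.insert(0, "stage", stage)
                venn_rows.append(venn)
        venn_table = (pd.concat(venn_rows, ignore_index=True) if venn_rows
                      else pd.DataFrame(columns=["stage", "region", "n"]))
        edio.write_table(transitions, outdir / "transitions.tsv")
        edio.write_table(stage_specific, outdir / "stage_specific.tsv")
        edio.write_table(first_expressed, outdir / "first_expressed.tsv")
        edio.write_table(venn_table, outdir / "venn_regions.tsv")
        manifest["tables"].update({
            "transitions": len(transitions),
            "stage_specific": len(stage_specific),
            "first_expressed": len(first_expressed),
            "venn_regions": len(venn_table),
        })
    except Exception as err:
        raise PipelineError(f"stagedyn stage failed: {err}") from err

    # ---- lineage markers and panels ---------------------------------------
    try:
        marker_frames = []
        for group in sheet["group"].unique():
            sub = sheet[sheet["group"] == group]
            if {"IT", "TE"} <= set(sub["lineage"]):
                markers = lineage_panels.icm_markers(
                    fpkm, sheet, te_max=config.marker_te_max,
                    it_min=config.marker_it_min, group=group)
                markers.insert(0, "group", group)
                marker_frames.append(markers)
        markers_out = (pd.concat(marker_frames, ignore_index=True)
                       if marker_frames else
                       pd.DataFrame(columns=["group", "gene_id", "fpkm_it",
                                             "fpkm_te", "marker"]))
        edio.write_table(markers_out, outdir / "icm_markers.tsv")
        panels = lineage_panels.builtin_panels()
        traj_frames, unmatched_all = [], {}
        for name, members in panels.items():
            shared = _shared_ordering(sheet, groups, stage_labels)
            table, unmatched = lineage_panels.panel_trajectories(
                fpkm, members, annotation, sheet, shared, panel_name=name)
            traj_frames.append(table)
            unmatched_all[name] = unmatched
        trajectories = pd.concat(traj_frames, ignore_index=True)
        edio.write_table(trajectories, outdir / "panel_trajectories.tsv")
        manifest["tables"]["icm_markers"] = len(markers_out)
        manifest["tables"]["panel_trajectories"] = len(trajectories)
        manifest["unmatched_panel_genes"] = unmatched_all
    except Exception as err:
        raise PipelineError(f"lineage_panels stage failed: {err}") from err

    # ---- QC ---------------------------------------------------------------
    try:
        deg_union: set = set()
        for res in de_tables:
            deg_union |= set(res.table.index[res.table["significant"]])
        subset = sorted(deg_union) if len(deg_union) >= 2 else None
        tree = qc.hclust_samples(fpkm, gene_subset=subset)
        edio.write_table(tree.to_frame(), outdir / "linkage.tsv")
        (outdir / "dendrogram.nwk").write_text(tree.to_newick() + "\n",
                                               encoding="utf-8")
        coords, varfrac = qc.pca_samples(fpkm)
        pca_out = coords.copy()
        pca_out.insert(0, "sample_id", coords.index)
        edio.write_table(pca_out, outdir / "pca.tsv")
        r2 = qc.pairwise_r2(fpkm)
        edio.write_matrix(r2, outdir / "r2_matrix.tsv", index_label="sample_id")
        manifest["tables"]["linkage"] = len(tree.to_frame())
        manifest["tables"]["pca"] = len(pca_out)
        manifest["tables"]["r2_matrix"] = len(r2)
        manifest["pca_variance_fractions"] = [round(float(v), 6)
                                              for v in varfrac[:5]]
        manifest["clustering_gene_subset"] = (
            f"DEG union ({len(deg_union)} genes)" if subset else "all genes")
    except Exception as err:
        raise PipelineError(f"qc stage failed: {err}") from err

    with open(outdir / "manifest.json", "w", encoding="utf-8") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return manifest


def _shared_ordering(sheet, groups, stage_labels) -> StageOrdering:
    """Stages every staged group covers, for panel trajectory extraction."""
    shared = None
    for group in groups:
        present = set(sheet.loc[(sheet["group"] == group)
                                & (sheet["lineage"] == "none"), "stage"])
        shared = present if shared is None else shared & present
    stages = tuple(s for s in stage_labels if s in (shared or set()))
    if not stages:
        raise ValueError("no stage is shared by all staged groups")
    return StageOrdering(stages)
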