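"""ICM marker identification and gene-panel trajectory extraction.

The blastocyst cannot be microdissected into pure inner cell mass (ICM) and
trophectoderm (TE); instead it is bisected into a pure-TE half and an "IT"
half carrying both lineages. A transcript is called an ICM marker when its
mean FPKM is < 1 in TE halves and > 10 in IT halves (strict bounds): TE
expression would leak into the IT half, so anything strong in IT but absent
in TE must come from the ICM.

Gene panels (pluripotency factors, H3K4/H3K9/H3K27 methyltransferases and
demethylases) ship as editable GMT files; trajectory extraction returns a
tidy gene × group × stage table of mean and per-replicate FPKM.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from . import io as edio
from .stagedyn import StageOrdering


def builtin_panels() -> dict[str, list[str]]:
    """All panels shipped with the package (pluripotency, kmt, kdm)."""
    panels: dict[str, list[str]] = {}
    root = resources.files("embryodyn").joinpath("data/panels")
    for entry in sorted(root.iterdir(), key=lambda e: e.name):
        if entry.name.endswith(".gmt"):
            with resources.as_file(entry) as path:
                panels.update(edio.read_gmt(path))
    return panels


def icm_markers(fpkm: pd.DataFrame, sample_sheet: pd.DataFrame,
                te_max: float = 1.0, it_min: float = 10.0,
                group: str | None = None, estimate_icm: bool = False,
                it_mixture: float = 0.5) -> pd.DataFrame:
    """Flag ICM-specific transcripts from bisected blastocyst halves.

    Replicate halves are collapsed by mean FPKM; output is sorted by IT
    expression, markers first. ``estimate_icm`` adds a model-based column
    back-estimating the pure ICM level as (IT − (1−ρ)·TE)/ρ for the mixture
    fraction ρ — derived under the bisection mixture model, not observed.
    """
    sheet = sample_sheet
    if group is not None:
        sheet = sheet[sheet["group"] == group]
    it_ids = sheet.loc[sheet["lineage"] == "IT", "sample_id"].tolist()
    te_ids = sheet.loc[sheet["lineage"] == "TE", "sample_id"].tolist()
    if not it_ids or not te_ids:
        raise ValueError("need at least one IT and one TE sample (lineage tags)")
    out = pd.DataFrame({
        "fpkm_it": fpkm[it_ids].mean(axis=1),
        "fpkm_te": fpkm[te_ids].mean(axis=1),
    })
    out["marker"] = (out["fpkm_te"] < te_max) & (out["fpkm_it"] > it_min)
    if estimate_icm:
        est = (out["fpkm_it"] - (1 - it_mixture) * out["fpkm_te"]) / it_mixture
        out["fpkm_icm_estimated"] = est.clip(lower=0.0)
    out = out.sort_values(["marker", "fpkm_it"], ascending=[False, False],
                          kind="mergesort")
    out.insert(0, "gene_id", out.index)
    return out.reset_index(drop=True)


def resolve_panel(panel: list[str], annotation: pd.DataFrame
                  ) -> tuple[dict[str, str], list[str]]:
    """Map panel symbols to gene ids by case-insensitive exact name match.

    Returns (symbol → gene_id, unmatched symbols). Unmatched members are
    reported, never silently dropped.
    """
    names = annotation["gene_name"].dropna()
    lookup: dict[str, str] = {}
    for gene_id, name in names.items():
        lookup.setdefault(str(name).upper(), gene_id)
    matched, unmatched = {}, []
    for symbol in panel:
        gene_id = lookup.get(symbol.upper())
        if gene_id is None:
            unmatched.append(symbol)
        else:
            matched[symbol] = gene_id
    return matched, unmatched


def panel_trajectories(fpkm: pd.DataFrame, panel: list[str],
                       annotation: pd.DataFrame, sample_sheet: pd.DataFrame,
                       ordering: StageOrdering, panel_name: str = "panel"
                       ) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene expression trajectories across stages and groups.

    Long-format rows: panel, gene symbol, group, stage, mean FPKM and the
    per-replicate values (`|`-joined, replicate order). Returns the table
    and the list of panel symbols not found in the annotation.
    """
    if len(set(panel)) != len(panel):
        raise ValueError("panel members must be unique")
    matched, unmatched = resolve_panel(panel, annotation)
    sheet = sample_sheet[sample_sheet["lineage"] == "none"]
    groups = [g for g in sheet["group"].unique()
              if set(ordering.stages) <= set(sheet.loc[sheet["group"] == g, "stage"])]
    rows = []
    for symbol, gene_id in matched.items():
        for group in groups:
            sub = sheet[sheet["group"] == group]
            for stage in ordering.stages:
                ids = sub.loc[sub["stage"] == stage].sort_values("replicate")
                vals = fpkm.loc[gene_id, ids["sample_id"]].to_numpy(float)
                rows.append({
                    "panel": panel_name, "gene": symbol, "gene_id": gene_id,
                    "group": group, "stage": stage,
                    "mean_fpkm": vals.mean(),
                    "replicate_fpkm": "|".join(f"{v:.6g}" for v in vals),
                })
    table = pd.DataFrame(rows, columns=["panel", "gene", "gene_id", "group",
                                        "stage", "mean_fpkm", "replicate_fpkm"])
    return table, unmatched
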