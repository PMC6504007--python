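"""Staging analyses: successive-stage DEG profiles, stage-specific and
first-expressed gene classification, set overlaps, and over-representation.

All classification thresholds here are strict inequalities, matching the
wording of the rules they implement:

* stage-specific — mean FPKM > 5 at exactly one stage of a group's series
  and < 1 at every other stage, restricted to genes with an assigned symbol;
* first-expressed — mean FPKM > 1 at a stage, < 1 at all earlier stages of
  the series, and adjusted p < 0.05 against the immediately preceding stage
  with the gene higher at the later stage. The first stage of a series has
  no predecessor and can never be called.

Stage series are evaluated within one group; replicates are collapsed by
the arithmetic mean FPKM per group × stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import DEResult, adjust_bh


@dataclass
class StageOrdering:
    """Ordered developmental stages; rank 0 is the earliest (oocyte)."""

    stages: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.stages)) != len(self.stages) or not self.stages:
            raise ValueError("stage ordering must be non-empty and unique")

    def rank(self, stage: str) -> int:
        return self.stages.index(stage)

    def transitions(self) -> list[tuple[str, str]]:
        """Consecutive (earlier, later) stage pairs."""
        return list(zip(self.stages[:-1], self.stages[1:]))


def stage_mean_fpkm(fpkm: pd.DataFrame, sample_sheet: pd.DataFrame,
                    group: str, ordering: StageOrdering) -> pd.DataFrame:
    """Collapse replicates: mean FPKM per gene × stage for one group.

    Whole-embryo samples only (lineage tag ``none``); errors if a stage of
    the ordering has no sample in the group.
    """
    sub = sample_sheet[(sample_sheet["group"] == group)
                       & (sample_sheet["lineage"] == "none")]
    cols = {}
    for stage in ordering.stages:
        ids = sub.loc[sub["stage"] == stage, "sample_id"].tolist()
        if not ids:
            raise ValueError(f"group {group!r} has no sample at stage {stage!r}")
        cols[stage] = fpkm[ids].mean(axis=1)
    return pd.DataFrame(cols, index=fpkm.index)


def successive_stage_degs(de_results: dict[tuple[str, str], DEResult],
                          ordering: StageOrdering) -> pd.DataFrame:
    """Count up/down/total DEGs per consecutive stage pair.

    Each DEResult must be oriented later-over-earlier: a positive fold
    change means induction at the later stage.
    """
    rows = []
    for earlier, later in ordering.transitions():
        key = (earlier, later)
        if key not in de_results:
            raise ValueError(f"missing DE result for transition {earlier} -> {later}")
        table = de_results[key].table
        n_up = int((table["direction"] == "up").sum())
        n_down = int((table["direction"] == "down").sum())
        rows.append({"from_stage": earlier, "to_stage": later,
                     "n_up": n_up, "n_down": n_down, "n_total": n_up + n_down})
    return pd.DataFrame(rows)


def classify_stage_specific(stage_fpkm: pd.DataFrame, ordering: StageOrdering,
                            annotation: pd.DataFrame | None = None,
                            hi: float = 5.0, lo: float = 1.0,
                            named_only: bool = True) -> pd.DataFrame:
    """Genes expressed at exactly one stage: FPKM > hi there, < lo elsewhere.

    Returns gene, stage, fpkm_at_stage, max_fpkm_elsewhere. Genes with any
    missing FPKM across the series are excluded; with ``named_only``, genes
    lacking a symbol are excluded too.
    """
    mat = stage_fpkm[list(ordering.stages)]
    complete = mat.notna().all(axis=1)
    mat = mat[complete].to_numpy(float)
    index = stage_fpkm.index[complete]
    above = mat > hi
    below = mat < lo
    rows = []
    for s, stage in enumerate(ordering.stages):
        others = np.delete(np.arange(len(ordering.stages)), s)
        hit = above[:, s] & below[:, others].all(axis=1)
        for i in np.flatnonzero(hit):
            rows.append({"gene_id": index[i], "stage": stage,
                         "fpkm_at_stage": mat[i, s],
                         "max_fpkm_elsewhere": mat[i, others].max()})
    out = pd.DataFrame(rows, columns=["gene_id", "stage", "fpkm_at_stage",
                                      "max_fpkm_elsewhere"])
    if named_only:
        if annotation is None:
            raise ValueError("named_only=True requires an annotation with gene_name")
        named = annotation["gene_name"].notna()
        out = out[out["gene_id"].map(named).fillna(False)].reset_index(drop=True)
    return out


def detect_first_expressed(stage_fpkm: pd.DataFrame,
                           de_vs_previous: dict[str, DEResult],
                           ordering: StageOrdering,
                           expr: float = 1.0, q_cut: float = 0.05) -> pd.DataFrame:
    """Earliest stage where a gene turns on with statistical support.

    ``de_vs_previous[stage]`` is the later-over-earlier contrast of that
    stage against its immediate predecessor. A gene is first-expressed at
    the earliest stage s with FPKM > expr, FPKM < expr at all earlier
    stages, adjusted p < q_cut for s vs s−1 and a positive fold change.
    """
    stages = ordering.stages
    for stage in stages[1:]:
        if stage not in de_vs_previous:
            raise ValueError(f"missing DE result for {stage} vs its predecessor")
    mat = stage_fpkm[list(stages)]
    complete = mat.notna().all(axis=1)
    index = stage_fpkm.index[complete]
    vals = mat[complete].to_numpy(float)
    qmat = np.column_stack([
        de_vs_previous[stage].table["padj"].reindex(index).to_numpy()
        for stage in stages[1:]])
    lfcmat = np.column_stack([
        de_vs_previous[stage].table["log2FC"].reindex(index).to_numpy()
        for stage in stages[1:]])
    rows = []
    on = vals > expr
    off_before = np.ones(len(index), dtype=bool)
    called = np.zeros(len(index), dtype=bool)
    for s in range(1, len(stages)):
        off_before &= vals[:, s - 1] < expr
        hit = (~called) & on[:, s] & off_before \
            & (qmat[:, s - 1] < q_cut) & (lfcmat[:, s - 1] > 0)
        for i in np.flatnonzero(hit):
            rows.append({"gene_id": index[i], "stage": stages[s],
                         "fpkm_at_stage": vals[i, s],
                         "max_fpkm_before": vals[i, :s].max(),
                         "padj_vs_previous": qmat[i, s - 1]})
        called |= hit
    return pd.DataFrame(rows, columns=["gene_id", "stage", "fpkm_at_stage",
                                       "max_fpkm_before", "padj_vs_previous"])


def overlap_sets(named_sets: dict[str, set]) -> pd.DataFrame:
    """Counts for every region of a 2- or 3-set Venn partition."""
    if not 2 <= len(named_sets) <= 3:
        raise ValueError("overlap_sets supports 2 or 3 sets")
    names = list(named_sets)
    sets = {k: set(v) for k, v in named_sets.items()}
    rows = []
    for r in range(1, len(names) + 1):
        for inside in combinations(names, r):
            region = set.intersection(*(sets[k] for k in inside))
            for k in names:
                if k not in inside:
                    region -= sets[k]
            rows.append({"region": "&".join(inside), "n": len(region)})
    return pd.DataFrame(rows)


def ora_fisher(gene_list, universe, gene_sets: dict[str, list[str]],
               q_cut: float = 0.05) -> pd.DataFrame:
    """One-sided Fisher exact over-representation test per gene set.

    2×2 table of membership in the query list × membership in the set,
    within the universe; p-values BH-adjusted across sets.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    query = set(gene_list)
    if not query <= universe:
        raise ValueError("gene_list must be a subset of the universe")
    rows = []
    for name, members in gene_sets.items():
        inset = set(members) & universe
        k = len(query & inset)
        table = [[k, len(query) - k],
                 [len(inset) - k, len(universe) - len(query) - len(inset) + k]]
        odds, p = stats.fisher_exact(table, alternative="greater")
        rows.append({"set": name, "n_set": len(inset), "n_overlap": k,
                     "odds_ratio": odds, "pval": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["padj"] = adjust_bh(out["pval"].to_numpy())
        out["significant"] = out["padj"] < q_cut
    return out
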