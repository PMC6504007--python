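"""Staging analyses: successive-stage DEGs, first-expressed genes, and the
activation delay of cloned embryos.

First-expressed = FPKM > 1 at a stage, < 1 at all earlier stages, with
q < 0.05 against the previous stage. Comparing the distribution of
first-expression stages between IV-D and NT-D exposes the cloned group's
embryonic-genome-activation delay.
"""

import embryodyn as ed
from embryodyn.diffexpr import de_replicated
from embryodyn.stagedyn import (StageOrdering, detect_first_expressed,
                                stage_mean_fpkm, successive_stage_degs)

ds = ed.simulate_dataset(ed.SimConfig(n_genes=2000, seed=4), "design27")
fpkm = ed.compute_fpkm(ds.counts, ds.annotation)
sf = ed.size_factors_median_ratio(ds.counts).factors
ordering = StageOrdering(("oocyte", "4-cell", "8-cell", "blastocyst"))

for group in ("IV-D", "NT-D"):
    sub = ds.sample_sheet.query("group == @group and lineage == 'none'")
    de_by_transition, de_prev = {}, {}
    for earlier, later in ordering.transitions():
        ids_e = sub.loc[sub["stage"] == earlier, "sample_id"].tolist()
        ids_l = sub.loc[sub["stage"] == later, "sample_id"].tolist()
        res = de_replicated(ds.counts, sf, ids_l, ids_e)
        de_by_transition[(earlier, later)] = res
        de_prev[later] = res
    table = successive_stage_degs(de_by_transition, ordering)
    print(f"\n{group} successive-stage DEGs:")
    print(table.to_string(index=False))
    means = stage_mean_fpkm(fpkm, ds.sample_sheet, group, ordering)
    fe = detect_first_expressed(means, de_prev, ordering)
    print(f"{group} first-expressed genes by stage:")
    print(fe["stage"].value_counts().reindex(ordering.stages[1:]).to_string())

# The NT-D histogram is shifted toward later stages relative to IV-D: the
# share of genes first expressed at 8-cell instead of 4-cell grows with the
# planted delay probability — the hallmark of impaired reprogramming.
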