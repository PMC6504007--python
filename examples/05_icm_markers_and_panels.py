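"""ICM marker calling from bisected blastocysts and panel trajectories.

The 25-sample layout bisects the IV-D blastocyst into a pure-TE half and an
IT half (ICM+TE). Transcripts with FPKM < 1 in TE and > 10 in IT must come
from the inner cell mass. Gene panels (pluripotency, KMT, KDM) are tracked
as mean-FPKM trajectories across stages and groups.
"""

import embryodyn as ed
from embryodyn.lineage_panels import (builtin_panels, icm_markers,
                                      panel_trajectories)
from embryodyn.stagedyn import StageOrdering

ds = ed.simulate_dataset(ed.SimConfig(n_genes=1500, seed=5), "design25")
fpkm = ed.compute_fpkm(ds.counts, ds.annotation)

markers = icm_markers(fpkm, ds.sample_sheet, group="IV-D")
called = markers[markers["marker"]]
print(f"ICM markers (FPKM < 1 in TE, > 10 in IT): {len(called)}")
print(called.head(8).to_string(index=False))

truth_class = ds.truth.genes["class"]
print("\ntrue classes of called markers:")
print(truth_class.loc[called["gene_id"]].value_counts().to_string())

panels = builtin_panels()
table, unmatched = panel_trajectories(
    fpkm, panels["pluripotency"], ds.annotation, ds.sample_sheet,
    StageOrdering(ds.truth.config.stage_labels), panel_name="pluripotency")
print("\nunmatched panel symbols:", unmatched or "none")
pou5f1 = table.query("gene == 'POU5F1' and group == 'IV-D'")
print("\nPOU5F1 trajectory in IV-D (mean FPKM per stage):")
print(pou5f1[["stage", "mean_fpkm"]].to_string(index=False))
# POU5F1 is planted as a zygotic gene: silent until activation, then on.
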