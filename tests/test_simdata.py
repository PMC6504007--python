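"""Simulator contracts: determinism, planted-truth invariants, noise model."""

import numpy as np
import pandas as pd
import pytest

import embryodyn as ed
from embryodyn.simdata import (ConfigurationError, DONOR_STAGE, SimConfig,
                               emulate_design, sample_counts, simulate_dataset,
                               simulate_truth, validate_sample_sheet)


@pytest.mark.parametrize("kwargs, message", [
    ({"class_fractions": {"maternal": 0.8, "zygotic": 0.5}}, "class_fractions"),
    ({"maternal_decay": 1.5}, "maternal_decay"),
    ({"stage_labels": ("oocyte", "oocyte")}, "stage_labels"),
    ({"dispersion": -0.1}, "dispersion"),
    ({"it_mixture": 1.0}, "it_mixture"),
    ({"group_perturbations": {"NT-D": (1.5, 0.7)}}, "delay_prob"),
    ({"activation_weights": {"4-cell": 0.5}}, "activation_weights"),
])
def test_invalid_config_names_offending_field(kwargs, message):
    with pytest.raises(ConfigurationError, match=message):
        SimConfig(**kwargs)


class TestDesigns:
    def test_design27_layout(self):
        sheet = emulate_design("design27")
        assert len(sheet) == 27
        assert set(sheet["group"]) == {"NT-D", "IV-D", "donor"}
        embryos = sheet[sheet["stage"] != DONOR_STAGE]
        assert set(embryos["stage"]) == {"oocyte", "4-cell", "8-cell", "blastocyst"}
        per_cell = embryos.groupby(["group", "stage"])["sample_id"].count()
        assert (per_cell == 3).all()
        assert (sheet.loc[sheet["group"] == "donor", "replicate"] == [1, 2, 3]).all()

    def test_design25_layout(self):
        sheet = emulate_design("design25")
        assert len(sheet) == 25
        embryos = sheet[(sheet["stage"] != DONOR_STAGE) & (sheet["lineage"] == "none")]
        for group in ("NT-LW", "NT-D", "IV-D"):
            assert len(embryos[embryos["group"] == group]) == 7
        # bisected IV-D blastocyst halves carry the lineage tags
        assert set(sheet.loc[sheet["lineage"] != "none", "lineage"]) == {"IT", "TE"}

    def test_unknown_design_lists_valid_names(self):
        with pytest.raises(ValueError, match="design25, design27"):
            emulate_design("design99")

    def test_duplicate_sample_id_rejected(self):
        sheet = emulate_design("design27")
        sheet.loc[1, "sample_id"] = sheet.loc[0, "sample_id"]
        with pytest.raises(ValueError, match="duplicate sample_id"):
            validate_sample_sheet(sheet)


class TestTruth:
    def test_planted_class_rules(self, design27_dataset):
        truth = design27_dataset.truth
        cfg = truth.config
        mu = truth.true_fpkm
        sheet = truth.sample_sheet
        rank = {s: i for i, s in enumerate(cfg.stage_labels)}
        classes = truth.genes["class"]
        for row in sheet.itertuples(index=False):
            if row.stage == DONOR_STAGE:
                continue
            col = mu[row.sample_id]
            r = rank[row.stage]
            # zygotic genes silent before their realized activation stage
            act = truth.group_activation[row.group]
            pre = classes.eq("zygotic") & act.notna() & (act.map(rank) > r)
            assert (col[pre] == 0).all()
            # maternal transcripts fully degraded from the degradation stage
            if r >= rank[cfg.degradation_stage]:
                assert (col[classes == "maternal"] == 0).all()
            assert (col[classes == "silent"] == 0).all()

    def test_housekeeping_constant_within_group(self, design27_dataset):
        truth = design27_dataset.truth
        hk = truth.genes.index[truth.genes["class"] == "housekeeping"]
        sub = truth.sample_sheet
        for group, ids in sub.groupby("group")["sample_id"]:
            vals = truth.true_fpkm.loc[hk, list(ids)]
            assert np.allclose(vals.sub(vals.iloc[:, 0], axis=0), 0.0)

    def test_it_mixture_identity(self):
        cfg = SimConfig(n_genes=300, seed=3)
        ds = simulate_dataset(cfg, "design25")
        truth = ds.truth
        icm = truth.genes.index[truth.genes["class"] == "lineage_icm"]
        sheet = truth.sample_sheet
        it_id = sheet.loc[sheet["lineage"] == "IT", "sample_id"].iloc[0]
        te_id = sheet.loc[sheet["lineage"] == "TE", "sample_id"].iloc[0]
        # IT half = ρ × pure ICM level, exactly; TE half sees nothing
        expected = cfg.it_mixture * truth.genes.loc[icm, "baseline_fpkm"]
        assert np.allclose(truth.true_fpkm.loc[icm, it_id], expected)
        assert (truth.true_fpkm.loc[icm, te_id] == 0).all()


class TestCounts:
    def test_bit_identical_under_same_seed(self):
        cfg = SimConfig(n_genes=200, seed=42)
        a = simulate_dataset(cfg, "design27")
        b = simulate_dataset(SimConfig(n_genes=200, seed=42), "design27")
        pd.testing.assert_frame_equal(a.counts, b.counts)
        pd.testing.assert_frame_equal(a.truth.true_fpkm, b.truth.true_fpkm)

    def test_removing_samples_leaves_other_draws_alone(self):
        cfg = SimConfig(n_genes=200, seed=5)
        full = simulate_dataset(cfg, "design27")
        sheet = full.sample_sheet.iloc[:-3]  # drop the donor trio
        partial = simulate_dataset(cfg, sheet)
        shared = sheet["sample_id"].tolist()
        pd.testing.assert_frame_equal(full.counts[shared], partial.counts)

    def test_zero_mean_gives_zero_counts(self, design27_dataset):
        truth = design27_dataset.truth
        zero = truth.true_fpkm == 0
        assert (design27_dataset.counts.values[zero.values] == 0).all()

    def test_poisson_limit_variance_equals_mean(self):
        # α = 0 must degenerate to Poisson: var/mean of many draws ≈ 1
        n_samples = 200
        sheet = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(n_samples)],
            "group": "IV-D", "stage": "oocyte", "replicate": 1,
            "lineage": "none"})
        ds = simulate_dataset(SimConfig(
            n_genes=500, dispersion=0.0, seed=9, depth_log_sd=0.0,
            class_fractions={"housekeeping": 1.0}), sheet)
        lengths = ds.annotation["length_bp"].to_numpy(float)
        means = (ds.truth.true_fpkm.to_numpy()
                 * lengths[:, None] * ds.truth.depths.to_numpy()[None, :] / 1e9)
        counts = ds.counts.to_numpy(float)
        m = means[:, 0]  # constant across samples at fixed depth
        big = m > 10
        ratios = counts[big].var(axis=1, ddof=1) / m[big]
        se = np.sqrt((2.0 / (n_samples - 1) + 1.0 / (n_samples * m[big])).mean()
                     / big.sum())
        assert abs(ratios.mean() - 1.0) < 3 * se

    def test_nb_variance_inflation(self):
        sheet = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(300)],
            "group": "IV-D", "stage": "oocyte", "replicate": 1,
            "lineage": "none"})
        alpha = 0.2
        ds = simulate_dataset(SimConfig(
            n_genes=300, dispersion=alpha, seed=4, depth_log_sd=0.0,
            class_fractions={"housekeeping": 1.0}), sheet)
        lengths = ds.annotation["length_bp"].to_numpy(float)
        means = (ds.truth.true_fpkm.to_numpy()
                 * lengths[:, None] * ds.truth.depths.to_numpy()[None, :] / 1e9)
        m = means[:, 0]
        big = m > 50
        observed = ds.counts.to_numpy(float)[big].var(axis=1, ddof=1)
        expected = m[big] * (1 + alpha * m[big])
        assert np.median(observed / expected) == pytest.approx(1.0, rel=0.25)


def test_zygotic_fpkm_crosses_threshold_at_activation(design27_dataset,
                                                      design27_fpkm):
    """Planted zygotic genes read as expressed (FPKM ≥ 1) exactly from their
    activation stage onwards in ≥95% of genes, and never before."""
    truth = design27_dataset.truth
    cfg = truth.config
    sheet = truth.sample_sheet
    rank = {s: i for i, s in enumerate(cfg.stage_labels)}
    ok = 0
    total = 0
    for group in ("IV-D",):
        act = truth.group_activation[group]
        zyg = truth.genes["class"].eq("zygotic") & act.notna()
        sub = sheet[(sheet["group"] == group) & (sheet["lineage"] == "none")]
        stages = [s for s in cfg.stage_labels if s in set(sub["stage"])]
        means = {s: design27_fpkm[
            sub.loc[sub["stage"] == s, "sample_id"]].mean(axis=1)
            for s in stages}
        for gene in truth.genes.index[zyg]:
            a = rank[act[gene]]
            before = [means[s][gene] for s in stages if rank[s] < a]
            after = [means[s][gene] for s in stages if rank[s] >= a]
            if not after:
                continue
            total += 1
            if all(v < 1 for v in before) and all(v >= 1 for v in after):
                ok += 1
    assert ok / total >= 0.95


def test_stronger_delay_means_more_late_detections():
    """Raising δ for the cloned group increases the number of genes whose
    detected first-expression stage trails the fertilized group's."""
    from embryodyn.diffexpr import de_replicated
    from embryodyn.stagedyn import (StageOrdering, detect_first_expressed,
                                    stage_mean_fpkm)

    late_counts = []
    for delta in (0.1, 0.5):
        cfg = SimConfig(n_genes=600, seed=21, group_perturbations={
            "IV-D": (0.0, 1.0), "NT-D": (delta, 1.0)})
        ds = simulate_dataset(cfg, "design27")
        fpkm = ed.compute_fpkm(ds.counts, ds.annotation)
        sf = ed.size_factors_median_ratio(ds.counts).factors
        ordering = StageOrdering(("oocyte", "4-cell", "8-cell", "blastocyst"))
        detected = {}
        for group in ("IV-D", "NT-D"):
            sub = ds.sample_sheet[(ds.sample_sheet["group"] == group)
                                  & (ds.sample_sheet["lineage"] == "none")]
            de_prev = {}
            for earlier, later in ordering.transitions():
                ids_e = sub.loc[sub["stage"] == earlier, "sample_id"].tolist()
                ids_l = sub.loc[sub["stage"] == later, "sample_id"].tolist()
                de_prev[later] = de_replicated(ds.counts, sf, ids_l, ids_e)
            means = stage_mean_fpkm(fpkm, ds.sample_sheet, group, ordering)
            fe = detect_first_expressed(means, de_prev, ordering)
            detected[group] = fe.set_index("gene_id")["stage"].map(
                list(ordering.stages).index)
        both = detected["IV-D"].index.intersection(detected["NT-D"].index)
        late_counts.append(
            int((detected["NT-D"][both] > detected["IV-D"][both]).sum()))
    assert late_counts[1] > late_counts[0]
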