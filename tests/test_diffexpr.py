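"""Exact tests, dispersion estimation, BH adjustment, and DEG calling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from embryodyn.diffexpr import (DEThresholds, adjust_bh, call_degs,
                                de_noreplicate, de_replicated,
                                estimate_dispersion, log2_fold_change,
                                nb_exact_test, two_library_exact_test)
from conftest import mock_de_result


class TestTwoLibraryExactTest:
    def test_no_information_gives_p_one(self):
        assert two_library_exact_test(0, 0, 1e6, 1e6) == 1.0

    def test_ten_to_zero_split_equal_sizes(self):
        # P(X<=10) = 1, P(X>=10) = (1/2)^10, doubled
        p = two_library_exact_test(10, 0, 5e5, 5e5)
        assert p == pytest.approx(2 / 1024)

    def test_matches_bruteforce_pmf_summation(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(1, 21))
            k1 = int(rng.integers(0, n + 1))
            n1, n2 = rng.uniform(1e5, 1e6, size=2)
            p0 = n1 / (n1 + n2)
            pmf = stats.binom.pmf(np.arange(n + 1), n, p0)
            lower = pmf[: k1 + 1].sum()
            upper = pmf[k1:].sum()
            expected = min(1.0, 2 * min(lower, upper))
            got = two_library_exact_test(k1, n - k1, n1, n2)
            assert got == pytest.approx(expected, rel=1e-9)

    def test_symmetry_under_condition_swap(self):
        for k1, k2 in [(3, 9), (0, 5), (20, 20)]:
            a = two_library_exact_test(k1, k2, 4e5, 6e5)
            b = two_library_exact_test(k2, k1, 6e5, 4e5)
            assert a == pytest.approx(b)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            two_library_exact_test(-1, 2, 1e5, 1e5)
        with pytest.raises(ValueError):
            two_library_exact_test(1, 2, 0, 1e5)


class TestLog2FoldChange:
    def test_equal_normalized_counts_give_zero(self):
        assert log2_fold_change(10, 20, 1.0, 2.0) == pytest.approx(0.0)

    def test_direct_arithmetic(self):
        assert log2_fold_change(7, 3, 1, 1, pseudocount=1) == pytest.approx(1.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        k1, k2 = rng.integers(0, 100, size=2)
        s1, s2 = rng.uniform(0.5, 2.0, size=2)
        assert log2_fold_change(k1, k2, s1, s2) == pytest.approx(
            -log2_fold_change(k2, k1, s2, s1))


class TestDispersion:
    def test_identical_replicates_give_zero(self):
        counts = pd.DataFrame({"a1": [5, 9], "a2": [5, 9],
                               "b1": [7, 2], "b2": [7, 2]})
        sf = pd.Series(1.0, index=counts.columns)
        labels = pd.Series(["A", "A", "B", "B"], index=counts.columns)
        alpha = estimate_dispersion(counts, sf, labels)
        assert (alpha == 0).all()

    def test_poisson_truth_yields_near_zero_median(self):
        rng = np.random.default_rng(2)
        mu = rng.lognormal(5.0, 0.5, size=3000)
        counts = pd.DataFrame(rng.poisson(mu[:, None], size=(3000, 6)),
                              columns=[f"s{i}" for i in range(6)])
        sf = pd.Series(1.0, index=counts.columns)
        labels = pd.Series(["A"] * 3 + ["B"] * 3, index=counts.columns)
        alpha = estimate_dispersion(counts, sf, labels)
        assert 0 <= alpha.median() <= 0.05

    def test_planted_dispersion_recovered_within_half(self):
        # 3 replicates is a noisy regime for method-of-moments; the median
        # over many genes must still land within ±50% of the planted value
        rng = np.random.default_rng(3)
        alpha_true = 0.2
        r = 1 / alpha_true
        mu = rng.lognormal(5.5, 0.8, size=2000)
        counts = pd.DataFrame(
            rng.negative_binomial(r, r / (r + mu[:, None]), size=(2000, 6)),
            columns=[f"s{i}" for i in range(6)])
        sf = pd.Series(1.0, index=counts.columns)
        labels = pd.Series(["A"] * 3 + ["B"] * 3, index=counts.columns)
        alpha = estimate_dispersion(counts, sf, labels)
        assert alpha.median() == pytest.approx(alpha_true, rel=0.5)

    def test_requires_a_replicated_condition(self):
        counts = pd.DataFrame({"a": [5], "b": [7]})
        sf = pd.Series(1.0, index=counts.columns)
        with pytest.raises(ValueError, match="noreplicate"):
            estimate_dispersion(counts, sf,
                                pd.Series(["A", "B"], index=counts.columns))


class TestNbExactTest:
    def test_symmetric_observation_is_mode(self):
        s = np.ones(3)
        assert nb_exact_test([10, 10, 10], [10, 10, 10], s, s, 0.1) == 1.0

    def test_poisson_limit_matches_conditional_binomial(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            ka = rng.integers(0, 40, size=3)
            kb = rng.integers(0, 40, size=3)
            sa = rng.uniform(0.5, 2.0, size=3)
            sb = rng.uniform(0.5, 2.0, size=3)
            if ka.sum() + kb.sum() == 0:
                continue
            p_nb = nb_exact_test(ka, kb, sa, sb, alpha=0.0)
            p_bin = two_library_exact_test(int(ka.sum()), int(kb.sum()),
                                           sa.sum(), sb.sum(),
                                           two_sided="minlike")
            assert p_nb == pytest.approx(p_bin, abs=1e-6)

    def test_matches_direct_enumeration(self):
        rng = np.random.default_rng(5)
        for alpha in (0.0, 0.1, 0.5):
            for _ in range(10):
                ka = rng.integers(0, 9, size=2)
                kb = rng.integers(0, 9, size=2)
                sa = rng.uniform(0.8, 1.2, size=2)
                sb = rng.uniform(0.8, 1.2, size=2)
                total = int(ka.sum() + kb.sum())
                if total == 0:
                    continue
                got = nb_exact_test(ka, kb, sa, sb, alpha)
                q0 = (np.sum(ka / sa) + np.sum(kb / sb)) / 4
                ma, mb = q0 * sa.sum(), q0 * sb.sum()
                va = ma + alpha * q0**2 * np.sum(sa**2)
                vb = mb + alpha * q0**2 * np.sum(sb**2)

                def pmf(x, m, v):
                    if v <= m:
                        return stats.poisson.pmf(x, m)
                    r = m**2 / (v - m)
                    return stats.nbinom.pmf(x, r, r / (r + m))

                probs = np.array([pmf(a, ma, va) * pmf(total - a, mb, vb)
                                  for a in range(total + 1)])
                obs = probs[int(ka.sum())]
                expected = probs[probs <= obs * (1 + 1e-8)].sum() / probs.sum()
                assert got == pytest.approx(expected, rel=1e-9)

    def test_symmetry_under_condition_swap(self):
        rng = np.random.default_rng(6)
        ka = rng.integers(0, 50, size=3)
        kb = rng.integers(0, 50, size=3)
        s = rng.uniform(0.5, 2.0, size=6)
        a = nb_exact_test(ka, kb, s[:3], s[3:], 0.2)
        b = nb_exact_test(kb, ka, s[3:], s[:3], 0.2)
        assert a == pytest.approx(b, rel=1e-9)


class TestBenjaminiHochberg:
    def test_hand_example(self):
        q = adjust_bh([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert adjust_bh([0.2]) == pytest.approx([0.2])

    def test_matches_min_over_suffix_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            m = int(rng.integers(1, 40))
            p = rng.random(m)
            p[rng.random(m) < 0.2] = rng.choice([0.0, 1.0, 0.5])  # ties/extremes
            q = adjust_bh(p)
            order = np.argsort(p, kind="mergesort")
            brute = np.empty(m)
            for rank, idx in enumerate(order, start=1):
                candidates = [p[order[j]] * m / (j + 1)
                              for j in range(rank - 1, m)]
                brute[idx] = min(1.0, min(candidates))
            assert np.allclose(q, brute)

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(8)
        p = rng.random(200)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(adjust_bh(p), q_sm)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(9)
        p = rng.random(50)
        perm = rng.permutation(50)
        assert np.allclose(adjust_bh(p)[perm], adjust_bh(p[perm]))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.2])
        with pytest.raises(ValueError):
            adjust_bh([np.nan])


class TestCallDegs:
    def test_noreplicate_thresholds_are_strict(self):
        genes = ["boundary_q", "small_lfc", "clear_hit"]
        res = mock_de_result(genes, padj=[0.005, 0.001, 0.001],
                             log2fc=[2.0, 0.9, 2.0], mode="noreplicate")
        sig = res.table["significant"]
        assert not sig["boundary_q"]  # q = 0.005 exactly fails "< 0.005"
        assert not sig["small_lfc"]  # |lfc| = 0.9 fails "> 1"
        assert sig["clear_hit"]

    def test_replicated_threshold_is_strict(self):
        res = mock_de_result(["a", "b"], padj=[0.05, 0.049],
                             log2fc=[3.0, 3.0], mode="replicated")
        assert res.table["significant"].tolist() == [False, True]

    def test_swapping_conditions_swaps_directions(self, design27_dataset):
        counts = design27_dataset.counts
        sheet = design27_dataset.sample_sheet
        import embryodyn as ed

        sf = ed.size_factors_median_ratio(counts).factors
        a = sheet.loc[(sheet["group"] == "IV-D") & (sheet["stage"] == "8-cell"),
                      "sample_id"].tolist()
        b = sheet.loc[(sheet["group"] == "IV-D") & (sheet["stage"] == "4-cell"),
                      "sample_id"].tolist()
        fwd = de_replicated(counts, sf, a, b)
        rev = de_replicated(counts, sf, b, a)
        assert (fwd.table["direction"] == "up").sum() \
            == (rev.table["direction"] == "down").sum()
        assert np.allclose(fwd.table["pval"], rev.table["pval"], rtol=1e-9)
        assert np.allclose(fwd.table["log2FC"], -rev.table["log2FC"])

    def test_thresholds_must_be_positive(self):
        with pytest.raises(ValueError):
            DEThresholds(q_cut_norep=0.0)


class TestContrastTables:
    def test_noreplicate_table_contract(self, design25_dataset):
        import embryodyn as ed

        counts = design25_dataset.counts
        tmm = ed.trimmed_mean_factors(counts)
        res = de_noreplicate(counts, tmm.effective_sizes,
                             "IV-D_8-cell", "IV-D_4-cell")
        t = res.table
        assert ((t["pval"] >= 0) & (t["pval"] <= 1)).all()
        assert (t["padj"] >= t["pval"] - 1e-12).all()
        assert res.mode == "noreplicate"

    def test_power_grows_with_effect_size(self):
        # planting a 4x shift yields more discoveries than a 2x shift
        rng = np.random.default_rng(10)
        mu = rng.lognormal(4.5, 0.6, size=800)
        sf = pd.Series(1.0, index=[f"s{i}" for i in range(6)])
        hits = []
        for fold in (2.0, 4.0):
            shifted = mu.copy()
            shifted[:200] *= fold
            r = 1 / 0.05
            counts = pd.DataFrame(np.column_stack([
                rng.negative_binomial(r, r / (r + shifted), size=(3, 800)).T,
                rng.negative_binomial(r, r / (r + mu), size=(3, 800)).T,
            ]), columns=sf.index)
            res = de_replicated(counts, sf, list(sf.index[:3]),
                                list(sf.index[3:]), dispersion=0.05)
            hits.append(res.n_significant)
        assert hits[1] > hits[0]
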