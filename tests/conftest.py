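import numpy as np
import pandas as pd
import pytest

import embryodyn as ed


@pytest.fixture(scope="session")
def design27_dataset() -> ed.SimulatedDataset:
    """Small replicated design shared by read-only tests."""
    return ed.simulate_dataset(ed.SimConfig(n_genes=400, seed=7), "design27")


@pytest.fixture(scope="session")
def design25_dataset() -> ed.SimulatedDataset:
    return ed.simulate_dataset(ed.SimConfig(n_genes=400, seed=7), "design25")


@pytest.fixture(scope="session")
def design27_fpkm(design27_dataset) -> pd.DataFrame:
    return ed.compute_fpkm(design27_dataset.counts, design27_dataset.annotation)


def mock_de_result(index, padj, log2fc, mode="replicated",
                   cond_a="later", cond_b="earlier") -> ed.DEResult:
    """Build a DEResult directly from adjusted p and fold-change vectors."""
    padj = np.asarray(padj, float)
    log2fc = np.asarray(log2fc, float)
    table = pd.DataFrame({
        "baseMeanA": np.zeros(len(index)),
        "baseMeanB": np.zeros(len(index)),
        "log2FC": log2fc,
        "pval": padj,
        "padj": padj,
    }, index=index)
    result = ed.DEResult(table=table, condition_a=cond_a, condition_b=cond_b,
                         mode=mode)
    from embryodyn.diffexpr import call_degs

    return call_degs(result)
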