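"""Scoring detected stage dynamics against the simulator's planted truth.

The simulator knows each zygotic gene's realized activation stage per group;
these helpers map that truth onto a study's observed stage series (a stage
activated between two sampled stages is first observable at the next sampled
stage) and score first-expressed calls against it.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .simdata import TruthTable
from .stagedyn import StageOrdering


def observable_activation(truth: TruthTable, group: str,
                          ordering: StageOrdering) -> pd.Series:
    """Planted activation mapped to the first sampled stage at/after it.

    Genes never active within the sampled series map to missing. The first
    stage of the series can never host a first-expressed call (no
    predecessor), so activations at or before it also map to the second
    sampled stage only if they fall strictly after the first; activations at
    or before the series start are unobservable and map to missing.
    """
    stage_rank = {s: i for i, s in enumerate(truth.config.stage_labels)}
    obs_ranks = [(s, stage_rank[s]) for s in ordering.stages]
    first_rank = obs_ranks[0][1]

    def map_one(label):
        if label is None or pd.isna(label):
            return None
        r = stage_rank[label]
        if r <= first_rank:
            return None
        for stage, rank in obs_ranks[1:]:
            if rank >= r:
                return stage
        return None

    return truth.group_activation[group].map(map_one)


@dataclass
class RecoveryScore:
    n_detectable: int
    n_correct: int
    n_wrong_stage: int

    @property
    def correct_fraction(self) -> float:
        return self.n_correct / self.n_detectable if self.n_detectable else 0.0

    @property
    def wrong_fraction(self) -> float:
        return self.n_wrong_stage / self.n_detectable if self.n_detectable else 0.0


def score_first_expressed(truth: TruthTable, group: str,
                          ordering: StageOrdering,
                          first_expressed: pd.DataFrame,
                          min_level: float = 5.0) -> RecoveryScore:
    """Compare first-expressed calls with the planted activation stages.

    ``min_level`` restricts scoring to genes whose planted post-activation
    FPKM (after group damping) is high enough to be detectable at the
    simulated sequencing depth; weaker genes are not counted either way.
    """
    _, gamma = truth.config.group_perturbations.get(group, (0.0, 1.0))
    expected = observable_activation(truth, group, ordering)
    zyg = truth.genes["class"] == "zygotic"
    detectable = zyg & expected.notna() \
        & (truth.genes["baseline_fpkm"] * gamma >= min_level)
    called = first_expressed.set_index("gene_id")["stage"]
    got = called.reindex(expected.index[detectable])
    exp = expected[detectable]
    n_correct = int((got == exp).sum())
    n_wrong = int((got.notna() & (got != exp)).sum())
    return RecoveryScore(n_detectable=int(detectable.sum()),
                         n_correct=n_correct, n_wrong_stage=n_wrong)


def delayed_stage_shift(truth: TruthTable, ordering: StageOrdering,
                        detected: dict[str, pd.Series],
                        cloned: str = "NT-D", reference: str = "IV-D"
                        ) -> pd.Series:
    """Observed stage-rank shift (cloned − reference) for delayed genes.

    ``detected`` maps group → Series gene_id → called stage. Only genes whose
    planted activation was delayed in the cloned group and that were called
    in both groups contribute.
    """
    idx = truth.genes.index
    delayed = truth.delayed[cloned] & (truth.genes["class"] == "zygotic")
    rank = {s: i for i, s in enumerate(ordering.stages)}
    a = detected[cloned].reindex(idx).map(rank)
    b = detected[reference].reindex(idx).map(rank)
    both = delayed & a.notna() & b.notna()
    return (a - b)[both]
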