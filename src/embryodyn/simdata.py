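"""Synthetic pre-implantation embryo RNA-seq with planted ground truth.

The simulator emulates the transcriptome dynamics of pig embryos developing
from the MII oocyte to the blastocyst, in three groups: in vivo fertilized
Duroc embryos (IV-D) and two cloned (somatic cell nuclear transfer) groups
(NT-D, NT-LW). Genes belong to one of seven classes:

``maternal``
    deposited in the oocyte, decaying geometrically each cleavage stage and
    fully degraded from a configurable stage onwards (maternal-zygotic
    transition).
``zygotic``
    silent until an activation stage drawn from a wave concentrated on the
    4-cell/8-cell stages (embryonic genome activation), then expressed at a
    gene-specific level. In cloned groups each zygotic gene is damped by a
    factor γ and its activation is independently delayed one stage with
    probability δ — the reprogramming defect the analysis must detect.
``housekeeping``
    constant across stages within a group.
``stage_specific``
    expressed at exactly one stage.
``lineage_icm`` / ``lineage_te``
    expressed only in the inner cell mass / trophectoderm of the blastocyst.
    A bisected "IT" half (ICM+TE) sees the ICM level mixed at a fraction ρ.
``silent``
    never expressed.

Counts are drawn per gene and sample from a negative binomial with mean
``μ·L·D/1e9`` (true FPKM μ, gene length L in bp, depth D in fragments) and
variance ``m(1+αm)``; ``α = 0`` degenerates to Poisson. True FPKM is scaled
once so that the mean per-sample ``Σ μ·L`` is 1e9, hence planted FPKM lives
on the same scale the quantifier recovers and D is the expected library
size. Every random draw comes from a stream derived from the master seed by
a stable label, so adding samples never reshuffles earlier draws.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import io as edio

GENE_CLASSES = (
    "maternal",
    "zygotic",
    "housekeeping",
    "stage_specific",
    "lineage_icm",
    "lineage_te",
    "silent",
)

DEFAULT_STAGES = (
    "oocyte",
    "1-cell",
    "2-cell",
    "4-cell",
    "8-cell",
    "morula",
    "blastocyst",
)

#: Stage label used for cultured donor fibroblast samples; donor cells sit
#: outside the developmental stage series and are excluded from staging rules.
DONOR_STAGE = "donor"

DEFAULT_CLASS_FRACTIONS = {
    "maternal": 0.25,
    "zygotic": 0.30,
    "housekeeping": 0.25,
    "stage_specific": 0.05,
    "lineage_icm": 0.02,
    "lineage_te": 0.03,
}

DEFAULT_ACTIVATION_WEIGHTS = {"2-cell": 0.10, "4-cell": 0.55, "8-cell": 0.35}

# (delay probability δ, damping factor γ) per group; groups not listed are
# unperturbed. δ(NT-D) ≥ δ(NT-LW) ≥ δ(IV-D) = 0 mirrors the observed ranking
# of reprogramming failure between donor cell lines.
DEFAULT_GROUP_PERTURBATIONS = {
    "IV-D": (0.0, 1.0),
    "NT-LW": (0.25, 0.85),
    "NT-D": (0.40, 0.70),
}

# Marker symbols planted onto genes of the matching class so panel lookups
# and marker calls have realistic names to resolve.
_PLANTED_NAMES = {
    "zygotic": [
        "KLF17", "MYC", "NANOG", "KLF4", "MBD3", "SOX2", "BMP4", "POU5F1",
        "KDM4A", "KDM4B", "KDM4C", "KDM4D", "KDM5A", "KDM5B", "KDM5C",
        "KDM5D", "KDM6A", "KDM6B",
    ],
    "maternal": [
        "KMT2A", "KMT2C", "KMT2E", "SUV39H1", "SUV39H2", "SETDB1", "SETDB2",
        "PRDM2", "EZH1", "EZH2",
    ],
    "lineage_icm": [
        "GSC", "RUNX1T1", "SNAI1", "BATF3", "BCL3", "DLX5", "OSR2", "ZFP36L2",
    ],
    "lineage_te": ["CDX2", "GATA3", "KRT8", "KRT18", "ELF5"],
}


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class SimConfig:
    """Parameters of one simulated embryo-transcriptome study."""

    n_genes: int = 2000
    class_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS))
    stage_labels: tuple[str, ...] = DEFAULT_STAGES
    activation_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ACTIVATION_WEIGHTS))
    maternal_decay: float = 0.5
    degradation_stage: str = "8-cell"
    group_perturbations: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_PERTURBATIONS))
    dispersion: float = 0.1
    depth_log_mean: float = math.log(5e5)
    depth_log_sd: float = 0.3
    it_mixture: float = 0.5
    blastocyst_icm_fraction: float = 0.3
    unnamed_fraction: float = 0.15
    donor_zygotic_overlap: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        unknown = set(self.class_fractions) - set(GENE_CLASSES)
        if unknown:
            raise ConfigurationError(f"class_fractions: unknown classes {sorted(unknown)}")
        if any(f < 0 for f in self.class_fractions.values()):
            raise ConfigurationError("class_fractions must be non-negative")
        if sum(self.class_fractions.values()) > 1 + 1e-12:
            raise ConfigurationError("class_fractions must sum to <= 1 (remainder is silent)")
        if not self.stage_labels:
            raise ConfigurationError("stage_labels must be non-empty")
        if len(set(self.stage_labels)) != len(self.stage_labels):
            raise ConfigurationError("stage_labels must be unique")
        bad = set(self.activation_weights) - set(self.stage_labels)
        if bad:
            raise ConfigurationError(f"activation_weights: stages {sorted(bad)} not in stage_labels")
        if not math.isclose(sum(self.activation_weights.values()), 1.0, abs_tol=1e-9):
            raise ConfigurationError("activation_weights must sum to 1")
        if not 0 < self.maternal_decay < 1:
            raise ConfigurationError("maternal_decay must be in (0, 1)")
        if self.degradation_stage not in self.stage_labels:
            raise ConfigurationError("degradation_stage must be one of stage_labels")
        for group, (delta, gamma) in self.group_perturbations.items():
            if not 0 <= delta <= 1:
                raise ConfigurationError(f"group_perturbations[{group}]: delay_prob must be in [0, 1]")
            if not 0 < gamma <= 1:
                raise ConfigurationError(f"group_perturbations[{group}]: damping must be in (0, 1]")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")
        if self.depth_log_sd < 0:
            raise ConfigurationError("depth_log_sd must be >= 0")
        if not 0 < self.it_mixture < 1:
            raise ConfigurationError("it_mixture must be in (0, 1)")
        if not 0 < self.blastocyst_icm_fraction < 1:
            raise ConfigurationError("blastocyst_icm_fraction must be in (0, 1)")
        if not 0 <= self.unnamed_fraction < 1:
            raise ConfigurationError("unnamed_fraction must be in [0, 1)")


@dataclass
class TruthTable:
    """Planted ground truth for one simulated dataset.

    ``genes`` holds per-gene class, baseline true FPKM and the unperturbed
    activation stage; ``group_activation`` / ``delayed`` record the realized
    (possibly delayed) activation per group; ``true_fpkm`` is the noiseless
    per-sample expression every count was drawn around.
    """

    genes: pd.DataFrame
    group_activation: pd.DataFrame
    delayed: pd.DataFrame
    true_fpkm: pd.DataFrame
    sample_sheet: pd.DataFrame
    depths: pd.Series
    config: SimConfig


@dataclass
class SimulatedDataset:
    counts: pd.DataFrame
    annotation: pd.DataFrame
    sample_sheet: pd.DataFrame
    truth: TruthTable


def _stream(seed: int, label: str) -> np.random.Generator:
    """Independent RNG stream derived from the master seed by a stable label."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(label.encode())])


# ---------------------------------------------------------------------------
# sample sheets


def validate_sample_sheet(sheet: pd.DataFrame, stage_labels=DEFAULT_STAGES) -> pd.DataFrame:
    sheet = sheet.reset_index(drop=True)
    if sheet["sample_id"].duplicated().any():
        dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id {dup!r} in sample sheet")
    allowed = set(stage_labels) | {DONOR_STAGE}
    bad = set(sheet["stage"]) - allowed
    if bad:
        raise ValueError(f"stage labels {sorted(bad)} not in the declared stage ordering")
    bad_lin = set(sheet["lineage"]) - {"none", "IT", "TE"}
    if bad_lin:
        raise ValueError(f"lineage tags {sorted(bad_lin)} not in {{none, IT, TE}}")
    return sheet


def _rows(group: str, stage: str, n_rep: int, lineage: str = "none") -> list[dict]:
    out = []
    for rep in range(1, n_rep + 1):
        suffix = f"_r{rep}" if n_rep > 1 else ""
        tag = "" if lineage == "none" else f"_{lineage}"
        out.append({
            "sample_id": f"{group}_{stage}{tag}{suffix}",
            "group": group, "stage": stage, "replicate": rep, "lineage": lineage,
        })
    return out


def emulate_design(name: str = "design27", stage_labels=DEFAULT_STAGES,
                   bisect_groups: tuple[str, ...] = ()) -> pd.DataFrame:
    """Build one of the two study layouts, or validate a custom sheet.

    ``design27``: NT-D and IV-D at oocyte, 4-cell, 8-cell and blastocyst with
    three biological replicates each, plus three Duroc donor-cell replicates
    (27 samples). ``design25``: NT-LW, NT-D and IV-D at seven consecutive
    stages without replicates, plus two donor-cell samples and the IV-D
    blastocyst bisected into an IT (ICM+TE) and a TE half (25 samples).
    ``bisect_groups`` adds IT/TE halves for further groups.
    """
    rows: list[dict] = []
    if name == "design27":
        for group in ("NT-D", "IV-D"):
            for stage in ("oocyte", "4-cell", "8-cell", "blastocyst"):
                rows += _rows(group, stage, 3)
        rows += _rows("donor", DONOR_STAGE, 3)
    elif name == "design25":
        for group in ("NT-LW", "NT-D", "IV-D"):
            for stage in stage_labels:
                rows += _rows(group, stage, 1)
        rows += _rows("donor-LW", DONOR_STAGE, 1)
        rows += _rows("donor-D", DONOR_STAGE, 1)
        for group in ("IV-D",) + tuple(g for g in bisect_groups if g != "IV-D"):
            rows += _rows(group, "blastocyst", 1, lineage="IT")
            rows += _rows(group, "blastocyst", 1, lineage="TE")
    else:
        raise ValueError(f"unknown design {name!r}; valid names: design25, design27")
    for group in bisect_groups:
        if name == "design27":
            rows += _rows(group, "blastocyst", 1, lineage="IT")
            rows += _rows(group, "blastocyst", 1, lineage="TE")
    return validate_sample_sheet(pd.DataFrame(rows), stage_labels)


# ---------------------------------------------------------------------------
# annotation and truth


def make_annotation(config: SimConfig) -> pd.DataFrame:
    """Gene ids, symbols (a fraction left unnamed, written ``.``) and lengths.

    Lengths are log-uniform on [500, 10000] bp, standing in for union-exon
    transcript lengths. Class-matched marker symbols are planted by
    :func:`simulate_truth`; here every named gene gets a generic symbol.
    """
    rng = _stream(config.seed, "annotation")
    n = config.n_genes
    gene_ids = [f"G{i:06d}" for i in range(1, n + 1)]
    lengths = np.exp(rng.uniform(math.log(500), math.log(10000), size=n))
    lengths = np.round(lengths).astype("int64")
    unnamed = rng.random(n) < config.unnamed_fraction
    names = pd.array([f"GENE{i:05d}" for i in range(1, n + 1)], dtype="object")
    names[unnamed] = None
    return pd.DataFrame({"gene_name": names, "length_bp": lengths},
                        index=pd.Index(gene_ids, name="gene_id"))


def _assign_classes(config: SimConfig) -> np.ndarray:
    n = config.n_genes
    counts = {c: int(round(config.class_fractions.get(c, 0.0) * n))
              for c in GENE_CLASSES if c != "silent"}
    while sum(counts.values()) > n:  # rounding overflow
        counts[max(counts, key=counts.get)] -= 1
    labels = []
    for cls in GENE_CLASSES:
        if cls != "silent":
            labels += [cls] * counts[cls]
    labels += ["silent"] * (n - len(labels))
    return np.array(labels, dtype=object)


def simulate_truth(config: SimConfig, sample_sheet: pd.DataFrame | None = None,
                   annotation: pd.DataFrame | None = None) -> TruthTable:
    """Plant gene classes, activation stages and noiseless per-sample FPKM."""
    config.validate()
    if sample_sheet is None:
        sample_sheet = emulate_design("design27", config.stage_labels)
    sheet = validate_sample_sheet(sample_sheet, config.stage_labels)
    if annotation is None:
        annotation = make_annotation(config)
    lengths = annotation["length_bp"].to_numpy(float)
    if (lengths <= 0).any():
        raise ConfigurationError("gene lengths must be > 0")

    n = config.n_genes
    stage_rank = {s: i for i, s in enumerate(config.stage_labels)}
    deg_rank = stage_rank[config.degradation_stage]
    blastocyst = config.stage_labels[-1]

    classes = _assign_classes(config)
    annotation = _plant_marker_names(annotation, classes)

    rng_base = _stream(config.seed, "baseline")
    base = np.exp(rng_base.normal(math.log(20.0), 1.0, size=n))
    ss_mask = classes == "stage_specific"
    lin_mask = np.isin(classes, ["lineage_icm", "lineage_te"])
    base[ss_mask] = np.exp(rng_base.normal(math.log(60.0), 0.7, size=ss_mask.sum()))
    base[lin_mask] = np.exp(rng_base.normal(math.log(40.0), 0.7, size=lin_mask.sum()))
    base[classes == "silent"] = 0.0

    rng_act = _stream(config.seed, "activation")
    act_stages = list(config.activation_weights)
    act_probs = np.array([config.activation_weights[s] for s in act_stages])
    zyg_mask = classes == "zygotic"
    activation = np.array([None] * n, dtype=object)
    activation[zyg_mask] = rng_act.choice(act_stages, size=zyg_mask.sum(), p=act_probs)
    ss_stage = np.array([None] * n, dtype=object)
    ss_stage[ss_mask] = rng_act.choice(config.stage_labels, size=ss_mask.sum())
    activation[ss_mask] = ss_stage[ss_mask]

    rng_donor = _stream(config.seed, "donor")
    donor_expr = zyg_mask & (rng_donor.random(n) < config.donor_zygotic_overlap)

    groups = sorted(set(sheet["group"]))
    act_rank = np.full(n, np.inf)
    for i in np.flatnonzero(zyg_mask):
        act_rank[i] = stage_rank[activation[i]]
    group_act_rank: dict[str, np.ndarray] = {}
    delayed = pd.DataFrame(False, index=annotation.index, columns=groups)
    for group in groups:
        delta, _ = config.group_perturbations.get(group, (0.0, 1.0))
        rng_g = _stream(config.seed, f"perturb:{group}")
        flip = rng_g.random(n) < delta
        is_delayed = zyg_mask & flip
        ranks = act_rank.copy()
        ranks[is_delayed] += 1  # shifted past the last stage = never activates
        group_act_rank[group] = ranks
        delayed[group] = is_delayed

    mu = np.zeros((n, len(sheet)))
    mat_mask = classes == "maternal"
    hk_mask = classes == "housekeeping"
    icm_mask = classes == "lineage_icm"
    te_mask = classes == "lineage_te"
    ss_rank = np.full(n, -1.0)
    ss_rank[ss_mask] = [stage_rank[s] for s in ss_stage[ss_mask]]
    rho = config.it_mixture
    whole = config.blastocyst_icm_fraction

    for j, row in enumerate(sheet.itertuples(index=False)):
        col = np.zeros(n)
        if row.stage == DONOR_STAGE:
            col[hk_mask] = base[hk_mask]
            col[donor_expr] = base[donor_expr]
        else:
            r = stage_rank[row.stage]
            if r < deg_rank:
                col[mat_mask] = base[mat_mask] * config.maternal_decay ** r
            _, gamma = config.group_perturbations.get(row.group, (0.0, 1.0))
            on = zyg_mask & (group_act_rank[row.group] <= r)
            col[on] = base[on] * gamma
            col[hk_mask] = base[hk_mask]
            at = ss_mask & (ss_rank == r)
            col[at] = base[at]
            if row.stage == blastocyst:
                if row.lineage == "IT":
                    col[icm_mask] = rho * base[icm_mask]
                    col[te_mask] = (1 - rho) * base[te_mask]
                elif row.lineage == "TE":
                    col[te_mask] = base[te_mask]
                else:
                    col[icm_mask] = whole * base[icm_mask]
                    col[te_mask] = (1 - whole) * base[te_mask]
        mu[:, j] = col

    # One global rescale so the mean per-stage Σ μ·L of an unperturbed
    # whole-embryo series is 1e9: planted FPKM is then on the scale FPKM
    # quantification recovers and depth D is the expected library size. The
    # factor depends only on the configuration (not on the sample sheet), so
    # adding or removing samples never shifts the planted values; a single
    # factor keeps housekeeping constancy and the IT mixture identity exact.
    ref_sums = np.empty(len(config.stage_labels))
    for r in range(len(config.stage_labels)):
        col = np.zeros(n)
        if r < deg_rank:
            col[mat_mask] = base[mat_mask] * config.maternal_decay ** r
        on = zyg_mask & (act_rank <= r)
        col[on] = base[on]
        col[hk_mask] = base[hk_mask]
        at = ss_mask & (ss_rank == r)
        col[at] = base[at]
        if r == len(config.stage_labels) - 1:
            col[icm_mask] = whole * base[icm_mask]
            col[te_mask] = (1 - whole) * base[te_mask]
        ref_sums[r] = float(col @ lengths)
    scale = 1e9 / ref_sums.mean()
    mu *= scale
    base *= scale

    rng_depth = _stream(config.seed, "depths")
    depths = np.exp(rng_depth.normal(config.depth_log_mean, config.depth_log_sd,
                                     size=len(sheet)))

    genes = pd.DataFrame({
        "class": classes,
        "baseline_fpkm": base,
        "activation_stage": [a if a is not None else None for a in activation],
    }, index=annotation.index)
    genes["gene_name"] = annotation["gene_name"]

    group_activation = pd.DataFrame(None, index=annotation.index, columns=groups,
                                    dtype=object)
    for group in groups:
        ranks = group_act_rank[group]
        lab = np.array([None] * n, dtype=object)
        ok = zyg_mask & (ranks < len(config.stage_labels))
        lab[ok] = [config.stage_labels[int(r)] for r in ranks[ok]]
        group_activation[group] = lab

    return TruthTable(
        genes=genes,
        group_activation=group_activation,
        delayed=delayed,
        true_fpkm=pd.DataFrame(mu, index=annotation.index,
                               columns=sheet["sample_id"].tolist()),
        sample_sheet=sheet,
        depths=pd.Series(depths, index=sheet["sample_id"].tolist(), name="depth"),
        config=config,
    )


def _plant_marker_names(annotation: pd.DataFrame, classes: np.ndarray) -> pd.DataFrame:
    annotation = annotation.copy()
    names = annotation["gene_name"].to_numpy(object)
    for cls, symbols in _PLANTED_NAMES.items():
        idx = np.flatnonzero(classes == cls)[: len(symbols)]
        for pos, symbol in zip(idx, symbols):
            names[pos] = symbol
    annotation["gene_name"] = names
    return annotation


# ---------------------------------------------------------------------------
# counts


def sample_counts(truth: TruthTable, annotation: pd.DataFrame,
                  config: SimConfig | None = None) -> pd.DataFrame:
    """Draw NB(mean μ·L·D/1e9, dispersion α) counts for every gene × sample.

    Each sample has its own RNG stream keyed by sample id, so extending a
    design leaves existing samples' counts untouched.
    """
    config = config or truth.config
    lengths = annotation.loc[truth.true_fpkm.index, "length_bp"].to_numpy(float)
    alpha = config.dispersion
    cols = {}
    for sample_id in truth.true_fpkm.columns:
        mean = (truth.true_fpkm[sample_id].to_numpy()
                * lengths * truth.depths[sample_id] / 1e9)
        if (mean < 0).any():
            raise RuntimeError("internal error: negative NB mean")
        rng = _stream(config.seed, f"counts:{sample_id}")
        if alpha == 0:
            draw = rng.poisson(mean)
        else:
            r = 1.0 / alpha
            draw = rng.negative_binomial(r, r / (r + mean))
        cols[sample_id] = draw.astype("int64")
    return pd.DataFrame(cols, index=truth.true_fpkm.index)


def simulate_dataset(config: SimConfig, design: str | pd.DataFrame = "design27",
                     **design_kwargs) -> SimulatedDataset:
    """Convenience wrapper: design → annotation → truth → counts."""
    if isinstance(design, str):
        sheet = emulate_design(design, config.stage_labels, **design_kwargs)
    else:
        sheet = validate_sample_sheet(design, config.stage_labels)
    annotation = make_annotation(config)
    truth = simulate_truth(config, sheet, annotation)
    annotation = annotation.copy()
    annotation["gene_name"] = truth.genes["gene_name"]
    counts = sample_counts(truth, annotation, config)
    return SimulatedDataset(counts=counts, annotation=annotation,
                            sample_sheet=sheet, truth=truth)


def write_dataset(dataset: SimulatedDataset, outdir) -> None:
    """Write counts, annotation, sample sheet and truth tables as TSV."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    edio.write_counts(dataset.counts, outdir / "counts.tsv")
    edio.write_annotation(dataset.annotation, outdir / "annotation.tsv")
    edio.write_sample_sheet(dataset.sample_sheet, outdir / "sample_sheet.tsv")
    truth = dataset.truth
    genes = truth.genes.copy()
    genes["activation_stage"] = genes["activation_stage"].fillna(".")
    genes["gene_name"] = genes["gene_name"].fillna(".")
    edio.write_table(genes.reset_index(), outdir / "truth_genes.tsv")
    edio.write_matrix(truth.true_fpkm, outdir / "truth_fpkm.tsv")
    edio.write_table(truth.group_activation.fillna(".").reset_index(),
                     outdir / "truth_activation.tsv")
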