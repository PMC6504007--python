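"""Count normalization: FPKM, expressed-gene calls, and scaling factors.

FPKM here is ``k · 1e9 / (N · L)`` with ``N`` the total counted fragments of
the sample *within the matrix* (the pipeline never sees unmapped or
intergenic reads) and ``L`` the union-exon gene length in bp. Two library
scaling schemes are provided: median-of-ratios size factors (the companion
normalization of the replicated NB test) and trimmed-mean-of-M-values (TMM)
scaling factors for the unreplicated design.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class AnnotationError(ValueError):
    pass


class DegenerateSampleError(ValueError):
    pass


@dataclass
class NormFactors:
    """Per-sample scaling with a tag naming the method that produced it."""

    factors: pd.Series
    method: str
    effective_sizes: pd.Series | None = None
    reference: str | None = None


def compute_fpkm(counts: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million counted fragments.

    Genes absent from the annotation are dropped (logged, never silent);
    non-positive lengths and zero-count samples are hard errors.
    """
    missing = counts.index.difference(annotation.index)
    if len(missing):
        logger.warning("dropping %d gene(s) missing from annotation", len(missing))
        counts = counts.drop(index=missing)
    lengths = annotation.loc[counts.index, "length_bp"].astype(float)
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0][0]
        raise AnnotationError(f"gene {bad!r} has non-positive length")
    totals = counts.sum(axis=0).astype(float)
    if (totals == 0).any():
        bad = totals.index[totals == 0][0]
        raise DegenerateSampleError(f"sample {bad!r} has zero total counts")
    fpkm = counts.astype(float).div(totals, axis=1).div(lengths, axis=0) * 1e9
    return fpkm


def call_expressed(fpkm: pd.DataFrame, threshold: float = 1.0) -> tuple[pd.DataFrame, pd.Series]:
    """Expressed = FPKM ≥ threshold (inclusive). Returns (mask, per-sample counts)."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    mask = fpkm >= threshold
    return mask, mask.sum(axis=0)


def size_factors_median_ratio(counts: pd.DataFrame, rescale: bool = False) -> NormFactors:
    """Median-of-ratios size factors.

    s_j = median over genes (positive in every sample) of k_ij divided by the
    gene's geometric mean across samples. ``rescale`` divides by the
    geometric mean of the factors so they average (geometrically) to 1.
    """
    mat = counts.to_numpy(float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; "
            "use trimmed_mean_factors instead")
    sub = mat[positive]
    log_geo = np.mean(np.log(sub), axis=1)
    ratios = np.log(sub) - log_geo[:, None]
    s = np.exp(np.median(ratios, axis=0))
    if rescale:
        s = s / np.exp(np.mean(np.log(s)))
    factors = pd.Series(s, index=counts.columns, name="size_factor")
    return NormFactors(factors=factors, method="median_ratio")


def _choose_reference(counts: pd.DataFrame) -> str:
    """Sample whose upper-quartile count fraction is closest to the mean."""
    frac = counts.astype(float).div(counts.sum(axis=0), axis=1)
    uq = frac.apply(lambda col: np.percentile(col[col > 0], 75), axis=0)
    return (uq - uq.mean()).abs().idxmin()


def trimmed_mean_factors(counts: pd.DataFrame, ref_sample: str | None = None,
                         trim_m: float = 0.30, trim_a: float = 0.05) -> NormFactors:
    """TMM scaling factors against a reference sample.

    Per gene shared between library j and the reference r:
    M = log2((k_j/N_j)/(k_r/N_r)), A = ½·log2((k_j/N_j)(k_r/N_r)); the most
    extreme ``trim_m`` of M and ``trim_a`` of A on each side are discarded
    and the rest averaged with inverse delta-method variance weights;
    f_j = 2^mean. Effective library size is N_j · f_j.
    """
    if ref_sample is None:
        ref_sample = _choose_reference(counts)
    if ref_sample not in counts.columns:
        raise ValueError(f"reference sample {ref_sample!r} not in matrix")
    totals = counts.sum(axis=0).astype(float)
    kr = counts[ref_sample].to_numpy(float)
    nr = totals[ref_sample]
    out = {}
    for sample in counts.columns:
        kj = counts[sample].to_numpy(float)
        nj = totals[sample]
        keep = (kj > 0) & (kr > 0)
        j, r = kj[keep], kr[keep]
        m = np.log2((j / nj) / (r / nr))
        a = 0.5 * np.log2((j / nj) * (r / nr))
        w = (nj - j) / (nj * j) + (nr - r) / (nr * r)
        n = len(m)
        lo_m, hi_m = int(np.floor(n * trim_m)), n - int(np.floor(n * trim_m))
        lo_a, hi_a = int(np.floor(n * trim_a)), n - int(np.floor(n * trim_a))
        rank_m = m.argsort().argsort()
        rank_a = a.argsort().argsort()
        sel = (rank_m >= lo_m) & (rank_m < hi_m) & (rank_a >= lo_a) & (rank_a < hi_a)
        if sel.sum() < 10:
            warnings.warn(
                f"fewer than 10 genes survive TMM trimming for {sample!r}; "
                "falling back to the untrimmed weighted mean", stacklevel=2)
            sel = np.ones(n, dtype=bool)
        with np.errstate(divide="ignore"):
            inv_w = 1.0 / w[sel]
        f = 2 ** (np.sum(m[sel] * inv_w) / np.sum(inv_w)) if sel.any() else 1.0
        out[sample] = f
    factors = pd.Series(out, name="scaling_factor")
    return NormFactors(factors=factors, method="tmm",
                       effective_sizes=totals * factors, reference=ref_sample)


def union_exon_lengths(gtf_path) -> pd.Series:
    """Union-exon gene lengths (bp) from a GTF (1-based inclusive coordinates).

    Overlapping exon intervals of a gene are merged before summing, so
    alternative isoforms are not double-counted.
    """
    import pyranges as pr

    gr = pr.read_gtf(str(gtf_path))
    exons = gr[gr.Feature == "exon"]
    merged = exons.merge(by="gene_id")
    df = merged.df
    # GTF is 1-based inclusive; pyranges stores 0-based half-open, so
    # End - Start is already the inclusive span in bp.
    df["length"] = df["End"] - df["Start"]
    return df.groupby("gene_id")["length"].sum().rename("length_bp")
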