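"""Pairwise differential expression for unreplicated and replicated designs.

Two exact tests are provided, both conditioned on the total count of a gene
across the two conditions so no free nuisance parameter remains:

* :func:`two_library_exact_test` — one library per condition. Under the null
  of equal concentration, k1 given k1+k2=n is Binomial(n, Ñ1/(Ñ1+Ñ2)) with
  Ñ the effective library sizes; the two-sided p doubles the smaller tail
  (``minlike`` summation available by flag).
* :func:`nb_exact_test` — replicated conditions. The condition count sums
  K_A, K_B are modeled as negative binomials with moments propagated from
  the per-sample NB(mean q0·s_j, dispersion α); conditioned on K_A+K_B, the
  p-value sums the probability of all splits no more likely than the
  observed one. With α = 0 this collapses to the conditional binomial test.

P-values are adjusted by the Benjamini–Hochberg step-up, implemented
directly so it can be checked against an O(m²) oracle. DEG calling uses
strict thresholds: adjusted p < 0.005 and |log2FC| > 1 without replicates,
adjusted p < 0.05 with replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

# relative tolerance when comparing pmf values for "as or less likely":
# splits within this factor of the observed probability count as ties.
_TIE_REL = 1e-8


@dataclass
class DEThresholds:
    q_cut_norep: float = 0.005
    lfc_cut: float = 1.0
    q_cut_rep: float = 0.05

    def __post_init__(self) -> None:
        if min(self.q_cut_norep, self.lfc_cut, self.q_cut_rep) <= 0:
            raise ValueError("all thresholds must be positive")


@dataclass
class DEResult:
    """One pairwise contrast: per-gene statistics plus orientation metadata."""

    table: pd.DataFrame
    condition_a: str
    condition_b: str
    mode: str  # "noreplicate" | "replicated"
    thresholds: DEThresholds = field(default_factory=DEThresholds)

    @property
    def contrast(self) -> str:
        return f"{self.condition_a}_vs_{self.condition_b}"

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())


# ---------------------------------------------------------------------------
# elementary statistics


def log2_fold_change(k1, k2, s1, s2, pseudocount: float = 1.0):
    """log2((k1/s1 + c)/(k2/s2 + c)); antisymmetric in the two conditions."""
    if np.any(np.asarray(s1) <= 0) or np.any(np.asarray(s2) <= 0):
        raise ValueError("size factors must be > 0")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return np.log2((np.asarray(k1, float) / s1 + pseudocount)
                   / (np.asarray(k2, float) / s2 + pseudocount))


def two_library_exact_test(k1: int, k2: int, n1: float, n2: float,
                           two_sided: str = "doubling") -> float:
    """Conditional binomial exact test for one library per condition.

    ``doubling``: p = min(1, 2·min(P(X ≤ k1), P(X ≥ k1))).
    ``minlike``: sum of binomial pmf over outcomes no more likely than k1.
    """
    if k1 < 0 or k2 < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("effective library sizes must be > 0")
    n = k1 + k2
    if n == 0:
        return 1.0
    p0 = n1 / (n1 + n2)
    if two_sided == "doubling":
        lower = stats.binom.cdf(k1, n, p0)
        upper = stats.binom.sf(k1 - 1, n, p0)
        return float(min(1.0, 2.0 * min(lower, upper)))
    if two_sided == "minlike":
        x = np.arange(n + 1)
        logpmf = stats.binom.logpmf(x, n, p0)
        keep = logpmf <= logpmf[k1] + np.log1p(_TIE_REL)
        return float(min(1.0, np.exp(logsumexp(logpmf[keep]))))
    raise ValueError(f"unknown two_sided rule {two_sided!r}")


def estimate_dispersion(counts: pd.DataFrame, size_factors: pd.Series,
                        condition_labels: pd.Series) -> pd.Series:
    """Pooled method-of-moments NB dispersion per gene.

    α = max(0, (v − m) / m²) with m the grand mean of normalized counts and
    v the variance pooled within conditions. With three replicates this is a
    noisy estimator; its bias and spread are documented, not hidden.
    """
    condition_labels = pd.Series(condition_labels, index=counts.columns)
    sizes = condition_labels.value_counts()
    if (sizes < 2).all():
        raise ValueError("no condition has >= 2 replicates; use noreplicate mode")
    z = counts.div(size_factors, axis=1)
    m = z.mean(axis=1)
    ss = pd.Series(0.0, index=counts.index)
    df = 0
    for cond, cols in condition_labels.groupby(condition_labels).groups.items():
        if len(cols) < 2:
            continue
        sub = z[list(cols)]
        ss = ss + ((sub.sub(sub.mean(axis=1), axis=0)) ** 2).sum(axis=1)
        df += len(cols) - 1
    v = ss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (v - m) / m**2
    alpha = alpha.where(m > 0, 0.0).clip(lower=0.0).fillna(0.0)
    alpha.name = "dispersion"
    return alpha


def _sum_nb_logpmf(x: np.ndarray, mean: float, var: float) -> np.ndarray:
    """log pmf of a condition count sum, NB by moments (Poisson if var<=mean)."""
    if mean == 0:
        out = np.full(len(x), -np.inf)
        out[x == 0] = 0.0
        return out
    if var <= mean:
        return stats.poisson.logpmf(x, mean)
    r = mean**2 / (var - mean)
    return stats.nbinom.logpmf(x, r, r / (r + mean))


def nb_exact_test(counts_a, counts_b, size_factors_a, size_factors_b,
                  alpha: float) -> float:
    """Conditioned exact test on negative-binomial condition sums.

    The pooled concentration q0 is the mean of k/s over all samples; the sum
    over condition c has mean q0·Σs_j and variance Σ(q0·s_j + α·q0²·s_j²).
    Given K_A + K_B, the two-sided p sums P(a)·P(b) over all splits with
    probability not exceeding the observed split's.
    """
    ka = np.asarray(counts_a, float)
    kb = np.asarray(counts_b, float)
    sa = np.asarray(size_factors_a, float)
    sb = np.asarray(size_factors_b, float)
    if (ka < 0).any() or (kb < 0).any():
        raise ValueError("counts must be non-negative")
    if alpha < 0:
        raise ValueError("dispersion must be >= 0")
    q0 = (np.sum(ka / sa) + np.sum(kb / sb)) / (len(ka) + len(kb))
    total = int(ka.sum() + kb.sum())
    if q0 == 0 or total == 0:
        return 1.0
    mean_a = q0 * sa.sum()
    mean_b = q0 * sb.sum()
    var_a = q0 * sa.sum() + alpha * q0**2 * np.sum(sa**2)
    var_b = q0 * sb.sum() + alpha * q0**2 * np.sum(sb**2)
    grid = np.arange(total + 1)
    log_pa = _sum_nb_logpmf(grid, mean_a, var_a)
    log_pb = _sum_nb_logpmf(grid, mean_b, var_b)
    log_joint = log_pa + log_pb[::-1]  # a + b = total
    log_obs = log_pa[int(ka.sum())] + log_pb[int(kb.sum())]
    denom = logsumexp(log_joint)
    if not np.isfinite(denom):
        raise RuntimeError("internal error: conditional distribution not normalizable")
    keep = log_joint <= log_obs + np.log1p(_TIE_REL)
    return float(min(1.0, np.exp(logsumexp(log_joint[keep]) - denom)))


def adjust_bh(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up: q_(i) = min_{j≥i} p_(j)·m/j, capped at 1."""
    p = np.asarray(pvals, float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# contrast tables


def _base_table(index, base_a, base_b, lfc, pvals, cond_a, cond_b) -> pd.DataFrame:
    q = adjust_bh(pvals)
    return pd.DataFrame({
        "baseMeanA": base_a,
        "baseMeanB": base_b,
        "log2FC": lfc,
        "pval": pvals,
        "padj": q,
    }, index=index)


def de_noreplicate(counts: pd.DataFrame, effective_sizes: pd.Series,
                   sample_a: str, sample_b: str,
                   thresholds: DEThresholds | None = None,
                   two_sided: str = "doubling",
                   pseudocount: float = 1.0) -> DEResult:
    """One-sample-per-condition contrast (conditional binomial exact test)."""
    thresholds = thresholds or DEThresholds()
    k1 = counts[sample_a].to_numpy()
    k2 = counts[sample_b].to_numpy()
    n1 = float(effective_sizes[sample_a])
    n2 = float(effective_sizes[sample_b])
    if two_sided == "doubling":
        n = k1 + k2
        p0 = n1 / (n1 + n2)
        lower = stats.binom.cdf(k1, n, p0)
        upper = stats.binom.sf(k1 - 1, n, p0)
        pvals = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
        pvals[n == 0] = 1.0
    else:
        pvals = np.array([two_library_exact_test(a, b, n1, n2, two_sided)
                          for a, b in zip(k1, k2)])
    # fold change on depth-normalized counts, scaled to the mean effective
    # size so the pseudocount acts on a count-like magnitude
    scale = (n1 + n2) / 2
    lfc = log2_fold_change(k1, k2, n1 / scale, n2 / scale, pseudocount)
    table = _base_table(counts.index, k1 / n1 * scale, k2 / n2 * scale,
                        lfc, pvals, sample_a, sample_b)
    result = DEResult(table=table, condition_a=sample_a, condition_b=sample_b,
                      mode="noreplicate", thresholds=thresholds)
    return call_degs(result, thresholds)


def de_replicated(counts: pd.DataFrame, size_factors: pd.Series,
                  samples_a: list[str], samples_b: list[str],
                  thresholds: DEThresholds | None = None,
                  dispersion: pd.Series | float | None = None,
                  pseudocount: float = 1.0) -> DEResult:
    """Replicated contrast via the conditioned NB exact test on count sums."""
    thresholds = thresholds or DEThresholds()
    if not samples_a or not samples_b:
        raise ValueError("both conditions need at least one sample")
    sa = size_factors[samples_a].to_numpy(float)
    sb = size_factors[samples_b].to_numpy(float)
    ka = counts[samples_a].to_numpy(float)
    kb = counts[samples_b].to_numpy(float)
    if dispersion is None:
        labels = pd.Series(["A"] * len(samples_a) + ["B"] * len(samples_b),
                           index=samples_a + samples_b)
        dispersion = estimate_dispersion(counts[samples_a + samples_b],
                                         size_factors[samples_a + samples_b],
                                         labels)
    if np.isscalar(dispersion):
        alpha = np.full(len(counts), float(dispersion))
    else:
        alpha = pd.Series(dispersion).reindex(counts.index).fillna(0.0).to_numpy()
    pvals = np.empty(len(counts))
    for i in range(len(counts)):
        pvals[i] = nb_exact_test(ka[i], kb[i], sa, sb, alpha[i])
    base_a = (ka / sa).mean(axis=1)
    base_b = (kb / sb).mean(axis=1)
    lfc = np.log2((base_a + pseudocount) / (base_b + pseudocount))
    table = _base_table(counts.index, base_a, base_b, lfc, pvals, "A", "B")
    table["dispersion"] = alpha
    result = DEResult(table=table, condition_a="A", condition_b="B",
                      mode="replicated", thresholds=thresholds)
    return call_degs(result, thresholds)


def call_degs(result: DEResult, thresholds: DEThresholds | None = None) -> DEResult:
    """Flag significant genes (strict thresholds) and label direction."""
    thresholds = thresholds or result.thresholds
    table = result.table
    if result.mode == "noreplicate":
        sig = (table["padj"] < thresholds.q_cut_norep) \
            & (table["log2FC"].abs() > thresholds.lfc_cut)
    elif result.mode == "replicated":
        sig = table["padj"] < thresholds.q_cut_rep
    else:
        raise ValueError(f"unknown mode {result.mode!r}")
    table = table.copy()
    table["significant"] = sig
    direction = np.where(table["log2FC"] > 0, "up", "down")
    direction = np.where(table["log2FC"] == 0, "none", direction)
    table["direction"] = np.where(sig, direction, "none")
    return DEResult(table=table, condition_a=result.condition_a,
                    condition_b=result.condition_b, mode=result.mode,
                    thresholds=thresholds)


def de_result_frame(result: DEResult, annotation: pd.DataFrame | None = None) -> pd.DataFrame:
    """Flat export table for one contrast (gene_name column if annotated)."""
    out = result.table.copy()
    out.insert(0, "gene_id", out.index)
    if annotation is not None and "gene_name" in annotation:
        out.insert(1, "gene_name",
                   annotation["gene_name"].reindex(out.index).fillna("."))
    out["contrast"] = result.contrast
    out["mode"] = result.mode
    return out.reset_index(drop=True)
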