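"""Count normalisation, expressed-gene filtering and differential expression.

Counts are normalised to rpkm (reads per kilobase per million mapped
reads), log2-transformed with a pseudocount, and genes are kept when
log2(rpkm) exceeds 1 in at least one sample.  Differential expression is a
negative-binomial Wald test: median-of-ratios size factors, per-gene
method-of-moments dispersion shrunk halfway (in log space) toward a fitted
mean-dispersion trend, and a Wald z on the log2 fold change of shrunken
group means.  DE calls use organism-specific thresholds: |log2FC| >= 1 and
FDR < 0.05 for human, |log2FC| >= 0.5 and FDR < 0.05 for mouse (the mouse
stromal signal is weaker, so a looser fold-change cutoff is used).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .stats_core import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "DEThresholds",
    "HUMAN_THRESHOLDS",
    "MOUSE_THRESHOLDS",
    "compute_rpkm",
    "filter_expressed",
    "de_test",
    "apply_de_thresholds",
]

LOG2_PSEUDOCOUNT = 1.0
MIN_DISPERSION = 1e-8


@dataclass(frozen=True)
class DEThresholds:
    """Fold-change and FDR cutoffs used to call a gene differentially
    expressed: |log2fc| >= fc_cutoff (inclusive) and adj_p < fdr_cutoff
    (strict)."""

    fc_cutoff: float
    fdr_cutoff: float
    organism: str

    @classmethod
    def for_organism(cls, organism: str) -> "DEThresholds":
        if organism == "human":
            return HUMAN_THRESHOLDS
        if organism == "mouse":
            return MOUSE_THRESHOLDS
        raise ValueError(f"unknown organism: {organism!r}")


HUMAN_THRESHOLDS = DEThresholds(fc_cutoff=1.0, fdr_cutoff=0.05, organism="human")
MOUSE_THRESHOLDS = DEThresholds(fc_cutoff=0.5, fdr_cutoff=0.05, organism="mouse")


def compute_rpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    pseudocount: float = LOG2_PSEUDOCOUNT,
) -> pd.DataFrame:
    """log2(rpkm + pseudocount) from a gene x sample count matrix.

    rpkm = count * 1e9 / (gene_length_bp * library_size), library size being
    the column sum of counts.  Genes without a length are dropped with a log
    message.
    """
    missing = counts.index.difference(gene_lengths.index)
    if len(missing):
        logger.warning("%d genes without a length: dropped from rpkm", len(missing))
        counts = counts.drop(index=missing)
    lengths = gene_lengths.reindex(counts.index).astype(float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValueError("every sample must have a positive library size")
    rpkm = counts.astype(float).mul(1e9).div(lengths, axis=0).div(lib, axis=1)
    return np.log2(rpkm + pseudocount)


def filter_expressed(expr: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Keep genes whose log2(rpkm) exceeds ``threshold`` (strictly) in at
    least one sample."""
    keep = (expr > threshold).any(axis=1)
    out = expr.loc[keep]
    if out.empty:
        logger.warning("expressed-gene filter removed every gene")
    return out


def _size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (geometric-mean reference)."""
    with np.errstate(divide="ignore"):
        log_counts = np.log(counts)
    usable = np.all(np.isfinite(log_counts), axis=1)
    if not usable.any():
        logger.warning("no gene with all-positive counts: size factors set to 1")
        return np.ones(counts.shape[1])
    log_ref = log_counts[usable].mean(axis=1)
    sf = np.exp(np.median(log_counts[usable] - log_ref[:, None], axis=0))
    return sf / np.exp(np.mean(np.log(sf)))


def _fit_dispersion_trend(means: np.ndarray, disps: np.ndarray) -> np.ndarray:
    """Fit the parametric trend alpha(mu) = a1/mu + a0 by least squares on
    genes with a positive moment estimate; evaluated at every gene mean."""
    ok = (disps > MIN_DISPERSION * 2) & (means > 0)
    if ok.sum() < 10:
        # too few informative genes for a trend: flat fallback
        a0, a1 = max(float(np.median(disps[disps > 0])) if (disps > 0).any() else 0.01, MIN_DISPERSION), 0.0
    else:
        X = np.column_stack([np.ones(ok.sum()), 1.0 / means[ok]])
        coef, *_ = np.linalg.lstsq(X, disps[ok], rcond=None)
        a0, a1 = float(coef[0]), float(coef[1])
        a0 = max(a0, MIN_DISPERSION)
        a1 = max(a1, 0.0)
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / np.maximum(means, 1e-8)
    return np.maximum(trend, MIN_DISPERSION)


def de_test(
    counts: pd.DataFrame,
    groups: pd.Series | list,
    reference: str | None = None,
) -> pd.DataFrame:
    """Negative-binomial Wald differential expression test.

    Parameters
    ----------
    counts : gene x sample raw count matrix.
    groups : two-level factor over samples.
    reference : the baseline level; log2fc is the other level minus this
        one.  Defaults to the first level in sorted label order.

    Returns a DataFrame indexed by gene with columns ``log2fc, p, adj_p``
    plus ``base_mean``.  Genes with all-zero counts are excluded from
    testing and reported in the log.
    """
    g = pd.Series(groups, index=counts.columns) if not isinstance(groups, pd.Series) else groups
    levels = sorted(pd.unique(g))
    if len(levels) != 2:
        raise ValueError("groups must have exactly two levels")
    if reference is not None:
        if reference not in levels:
            raise ValueError(f"reference {reference!r} not a group level")
        levels = [reference, next(l for l in levels if l != reference)]
    maskA = (g == levels[0]).to_numpy()
    maskB = (g == levels[1]).to_numpy()
    if maskA.sum() < 2 or maskB.sum() < 2:
        raise ValueError("need >= 2 samples per group")

    K = counts.to_numpy(dtype=float)
    nonzero = K.sum(axis=1) > 0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        logger.info("%d all-zero genes excluded from DE testing", n_dropped)
    K = K[nonzero]
    genes = counts.index[nonzero]

    sf = _size_factors(K)
    Q = K / sf  # normalised counts

    qA, qB = Q[:, maskA], Q[:, maskB]
    nA, nB = qA.shape[1], qB.shape[1]
    muA, muB = qA.mean(axis=1), qB.mean(axis=1)
    base_mean = Q.mean(axis=1)

    # method-of-moments dispersion pooled within groups:
    # Var(K/s) ~ mu * E[1/s] + alpha * mu^2  =>  alpha = (v - mu*c)/mu^2
    cA = float(np.mean(1.0 / sf[maskA]))
    cB = float(np.mean(1.0 / sf[maskB]))
    varA = qA.var(axis=1, ddof=1)
    varB = qB.var(axis=1, ddof=1)
    pooled_var = (varA * (nA - 1) + varB * (nB - 1)) / (nA + nB - 2)
    pooled_mu = (muA * nA + muB * nB) / (nA + nB)
    pooled_c = (cA * nA + cB * nB) / (nA + nB)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mom = (pooled_var - pooled_mu * pooled_c) / pooled_mu**2
    alpha_mom = np.nan_to_num(alpha_mom, nan=MIN_DISPERSION)
    alpha_mom = np.maximum(alpha_mom, MIN_DISPERSION)

    trend = _fit_dispersion_trend(pooled_mu, alpha_mom)
    # shrink halfway toward the trend in log space
    alpha = np.exp(0.5 * (np.log(alpha_mom) + np.log(trend)))

    # fold change on shrunken group means (pseudocount stabilises zeros)
    eps = 0.5
    log2fc = np.log2((muB + eps) / (muA + eps))

    # delta-method variance of log(mean) per group:
    # Var(q_hat_group) = (1/n^2) * sum_j (mu/s_j + alpha mu^2)
    def _var_logmean(mu: np.ndarray, mask: np.ndarray) -> np.ndarray:
        n = int(mask.sum())
        s = sf[mask]
        var_mean = (mu[:, None] / s[None, :] + alpha[:, None] * mu[:, None] ** 2).sum(axis=1) / n**2
        return var_mean / np.maximum(mu + eps, 1e-8) ** 2

    se_log2fc = np.sqrt(_var_logmean(muA, maskA) + _var_logmean(muB, maskB)) / np.log(2)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = log2fc / se_log2fc
    wald = np.nan_to_num(wald, nan=0.0)
    p = 2.0 * stats.norm.sf(np.abs(wald))
    p = np.clip(p, 0.0, 1.0)
    adj = np.asarray(bh_adjust(p).adjusted)

    return pd.DataFrame(
        {"base_mean": base_mean, "log2fc": log2fc, "p": p, "adj_p": adj},
        index=genes,
    )


def apply_de_thresholds(
    results: pd.DataFrame, thresholds: DEThresholds
) -> tuple[list[str], list[str]]:
    """Split DE results into up/down gene lists under the organism cutoffs.

    Fold-change comparison is inclusive (>= cutoff), FDR strict (< cutoff).
    """
    sig = results["adj_p"] < thresholds.fdr_cutoff
    up = results.index[sig & (results["log2fc"] >= thresholds.fc_cutoff)].tolist()
    down = results.index[sig & (results["log2fc"] <= -thresholds.fc_cutoff)].tolist()
    return up, down


def annotate_de(results: pd.DataFrame, thresholds: DEThresholds) -> pd.DataFrame:
    """Return results with ``is_de`` and ``direction`` columns added."""
    up, down = apply_de_thresholds(results, thresholds)
    out = results.copy()
    out["is_de"] = out.index.isin(up) | out.index.isin(down)
    direction = pd.Series("", index=out.index, dtype=object)
    direction[out.index.isin(up)] = "up"
    direction[out.index.isin(down)] = "down"
    out["direction"] = direction
    return out
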