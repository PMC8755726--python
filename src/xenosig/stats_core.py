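"""Statistical primitives shared by every pipeline stage.

Exact small-sample tests (Mann-Whitney, Fisher), Benjamini-Hochberg FDR
control, hypergeometric gene-set over-representation, Student's t-test,
z-score standardisation and the caliper/ultrasound tumour-volume formulas.

The exact tests delegate to scipy but own the switching rules (when the
exact null distribution is enumerated vs when a tie-corrected normal
approximation is used), which is what downstream figure-legend statistics
depend on.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "PValueSet",
    "EnrichmentResult",
    "Contingency2x2",
    "mann_whitney_exact",
    "fisher_exact_2x2",
    "bh_adjust",
    "hypergeometric_enrichment",
    "unpaired_t_test",
    "tumor_volume",
    "zscore",
]

#: largest combined sample size for which the exact Mann-Whitney null
#: distribution is enumerated; beyond this (or with ties) the tie-corrected
#: normal approximation is used.
EXACT_MW_MAX_N = 20


@dataclass(frozen=True)
class PValueSet:
    """Raw p-values with their Benjamini-Hochberg adjusted counterparts.

    Order of ``adjusted`` matches ``raw``.
    """

    raw: tuple[float, ...]
    adjusted: tuple[float, ...]
    method: str = "benjamini-hochberg"

    def __post_init__(self) -> None:
        if len(self.raw) != len(self.adjusted):
            raise ValueError("raw and adjusted must have equal length")


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric over-representation of one gene set.

    k of n selected genes fall in a set of size K inside a universe of N.
    """

    term_id: str
    k: int
    K: int
    n: int
    N: int
    p: float
    adj_p: float = math.nan
    significant: bool = False


@dataclass(frozen=True)
class Contingency2x2:
    """2x2 contingency table; rows are groups, columns outcome yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} must be a non-empty sample")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def mann_whitney_exact(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test, exact for small tie-free samples.

    The exact null distribution of U is used when ``n1 + n2 <= 20`` and the
    pooled sample has no ties; otherwise a tie-corrected normal
    approximation (without continuity correction in the tied case) is used
    and a warning is logged.

    Returns
    -------
    (U, p) : U is ``min(U_x, U_y)``; p is twice the one-sided tail
        probability, capped at 1.
    """
    xa = _as_1d(x, "x")
    ya = _as_1d(y, "y")
    pooled = np.concatenate([xa, ya])
    has_ties = np.unique(pooled).size < pooled.size
    exact_ok = (xa.size + ya.size) <= EXACT_MW_MAX_N and not has_ties
    if not exact_ok:
        if has_ties and (xa.size + ya.size) <= EXACT_MW_MAX_N:
            logger.warning(
                "ties present (n1=%d, n2=%d): falling back to tie-corrected "
                "normal approximation for Mann-Whitney",
                xa.size,
                ya.size,
            )
        method = "asymptotic"
    else:
        method = "exact"
    res = stats.mannwhitneyu(xa, ya, alternative="two-sided", method=method)
    u_x = float(res.statistic)
    u_y = xa.size * ya.size - u_x
    return min(u_x, u_y), min(float(res.pvalue), 1.0)


def fisher_exact_2x2(t: Contingency2x2) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Uses the probability-mass rule: the p-value sums the hypergeometric
    probabilities of every margin-preserving table whose probability does
    not exceed that of the observed table.  A degenerate table (an all-zero
    row or column margin) carries no information and returns p = 1.
    """
    arr = t.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        logger.warning("degenerate 2x2 table %s: p set to 1", arr.tolist())
        return 1.0
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def bh_adjust(raw: Sequence[float]) -> PValueSet:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    arr = np.asarray(list(raw), dtype=float)
    if arr.size == 0:
        return PValueSet(raw=(), adjusted=())
    if np.any(arr < 0) or np.any(arr > 1) or not np.all(np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    adj = multipletests(arr, method="fdr_bh")[1]
    return PValueSet(raw=tuple(arr.tolist()), adjusted=tuple(adj.tolist()))


def hypergeometric_enrichment(
    selected: Sequence[str],
    sets: Mapping[str, Sequence[str]],
    universe: Sequence[str],
    p_cutoff: float = 0.001,
    adj_cutoff: float = 0.01,
) -> list[EnrichmentResult]:
    """One-sided hypergeometric over-representation of each gene set.

    Gene sets are intersected with ``universe`` before testing; selected
    genes absent from the universe are dropped with a logged count.  Only
    sets overlapping the selection (k >= 1) are reported.  A result is
    flagged significant when ``p < p_cutoff`` and ``adj_p < adj_cutoff``
    (defaults are the human-data cutoffs; mouse analyses conventionally use
    0.01 / 0.1).
    """
    uni = set(universe)
    sel = set(selected)
    dropped = sel - uni
    if dropped:
        logger.warning("%d selected genes absent from universe, dropped", len(dropped))
        sel &= uni
    N, n = len(uni), len(sel)
    results: list[EnrichmentResult] = []
    for term, members in sets.items():
        members_in = set(members) & uni
        K = len(members_in)
        k = len(members_in & sel)
        if k < 1:
            continue
        # upper tail: P(X >= k) with X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        results.append(EnrichmentResult(term_id=term, k=k, K=K, n=n, N=N, p=p))
    if not results:
        return []
    adj = bh_adjust([r.p for r in results]).adjusted
    return [
        EnrichmentResult(
            term_id=r.term_id,
            k=r.k,
            K=r.K,
            n=r.n,
            N=r.N,
            p=r.p,
            adj_p=a,
            significant=(r.p < p_cutoff and a < adj_cutoff),
        )
        for r, a in zip(results, adj)
    ]


def unpaired_t_test(x, y) -> tuple[float, float]:
    """Two-sided Student (pooled-variance) t-test.

    Degenerate zero-variance input: equal means give p = 1; unequal means
    give p = 0 with a warning (an infinite t statistic in the limit).
    """
    xa = _as_1d(x, "x")
    ya = _as_1d(y, "y")
    if xa.size < 2 or ya.size < 2:
        raise ValueError("each group needs at least 2 observations")
    sp2 = (np.var(xa, ddof=1) * (xa.size - 1) + np.var(ya, ddof=1) * (ya.size - 1)) / (
        xa.size + ya.size - 2
    )
    if sp2 == 0:
        if np.isclose(xa.mean(), ya.mean()):
            return 0.0, 1.0
        logger.warning("zero pooled variance with unequal means: p set to 0")
        return math.copysign(math.inf, xa.mean() - ya.mean()), 0.0
    res = stats.ttest_ind(xa, ya, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def tumor_volume(kind: str, dims: Sequence[float]) -> float:
    """Tumour volume (mm^3) from caliper or ultrasound measurements (mm).

    ``orthotopic`` uses three diameters: 4/3 * pi * (depth*sagittal*transversal)/6.
    ``subcutaneous`` uses two: (length * width^2)/2.
    """
    d = [float(v) for v in dims]
    if any(v <= 0 for v in d):
        raise ValueError("dimensions must be positive")
    if kind == "orthotopic":
        if len(d) != 3:
            raise ValueError("orthotopic volume needs 3 dimensions")
        return 4.0 / 3.0 * math.pi * (d[0] * d[1] * d[2]) / 6.0
    if kind == "subcutaneous":
        if len(d) != 2:
            raise ValueError("subcutaneous volume needs 2 dimensions")
        return d[0] * d[1] ** 2 / 2.0
    raise ValueError(f"unknown tumour kind: {kind!r}")


def zscore(values, ddof: int = 0) -> np.ndarray:
    """Standardise to mean 0, sd 1 using the population sd by default.

    Heatmap-style display standardisation: a constant vector maps to all
    zeros (with a warning) rather than raising.
    """
    arr = _as_1d(values, "values")
    if arr.size < 2:
        raise ValueError("zscore needs at least 2 values")
    sd = np.std(arr, ddof=ddof)
    if sd == 0:
        logger.warning("constant vector passed to zscore: returning zeros")
        return np.zeros_like(arr)
    return (arr - arr.mean()) / sd
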