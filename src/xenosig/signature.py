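"""Prognostic signature derivation by correlation / fold-change sign concordance.

The procedure seeds on an anchor gene (TWIST1 in the original study):
every cohort gene is correlated with the anchor (Pearson, log-scale
expression); genes passing |R| > 0.225 are crossed with the xenograft DE
genes; members whose correlation sign agrees with their fold-change sign
form the signature (R>0 & FC>0 -> up list, R<0 & FC<0 -> down list), while
discordant genes are reported separately and excluded.  Samples are scored
with a size-weighted combination of per-gene cohort z-scores.

Also here: the annotation-driven tumour-stroma gene list (DE genes tagged
as growth factors, cytokines/chemokines/inflammatory mediators, integrins
and their ligands or receptors) and set-overlap (Venn) partitioning used by
the cross-omics comparisons.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats_core import zscore

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationResult",
    "GeneSignature",
    "R_THRESHOLD_DEFAULT",
    "ANNOTATION_CATEGORIES",
    "correlate_with_anchor",
    "derive_signature",
    "score_signature",
    "build_annotation_signature",
    "cross_sets",
]

R_THRESHOLD_DEFAULT = 0.225

ANNOTATION_CATEGORIES = (
    "growth_factor",
    "cytokine",
    "chemokine",
    "inflammatory_mediator",
    "receptor",
    "integrin",
    "integrin_ligand",
)

# Fig-style display grouping of the fine-grained categories
CATEGORY_GROUPS = {
    "growth_factor": "growth factors",
    "cytokine": "cytokines",
    "chemokine": "cytokines",
    "inflammatory_mediator": "cytokines",
    "receptor": "growth factors",
    "integrin": "integrins & ligands",
    "integrin_ligand": "integrins & ligands",
}


@dataclass(frozen=True)
class CorrelationResult:
    gene: str
    R: float
    passes: bool


@dataclass(frozen=True)
class GeneSignature:
    """Disjoint up/down gene lists anchored on one gene.

    ``discordant`` holds crossed genes whose R and FC signs disagree (they
    are excluded from scoring but kept for reporting).
    """

    name: str
    anchor: str
    up: tuple[str, ...]
    down: tuple[str, ...]
    discordant: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if set(self.up) & set(self.down):
            raise ValueError("up and down lists must be disjoint")

    @property
    def genes(self) -> tuple[str, ...]:
        return self.up + self.down

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t".join([f"{self.name}_UP", f"anchor={self.anchor}", *self.up]) + "\n")
            fh.write("\t".join([f"{self.name}_DOWN", f"anchor={self.anchor}", *self.down]) + "\n")


def correlate_with_anchor(
    expr: pd.DataFrame,
    anchor: str,
    threshold: float = R_THRESHOLD_DEFAULT,
) -> pd.DataFrame:
    """Pearson correlation of every cohort gene with the anchor gene.

    ``expr`` is gene x sample log-scale expression.  Zero-variance genes
    have undefined R and are excluded with a log message.  ``passes`` is
    strict: |R| > threshold.
    """
    if anchor not in expr.index:
        raise ValueError(f"anchor gene {anchor!r} absent from cohort")
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples to correlate")
    X = expr.to_numpy(dtype=float)
    a = expr.loc[anchor].to_numpy(dtype=float)
    a_c = a - a.mean()
    sa = np.sqrt((a_c**2).sum())
    if sa == 0:
        raise ValueError("anchor gene has zero variance")
    Xc = X - X.mean(axis=1, keepdims=True)
    sx = np.sqrt((Xc**2).sum(axis=1))
    valid = sx > 0
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.warning("%d zero-variance genes excluded from correlation", n_dropped)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = (Xc @ a_c) / (sx * sa)
    out = pd.DataFrame({"R": R}, index=expr.index).loc[valid]
    out["passes"] = out["R"].abs() > threshold
    return out


def derive_signature(
    correlations: pd.DataFrame,
    de_results: pd.DataFrame,
    name: str,
    anchor: str = "",
) -> GeneSignature:
    """Cross correlation-passing genes with DE genes under sign concordance.

    ``correlations`` needs columns R/passes; ``de_results`` needs log2fc and
    an ``is_de`` column (see :func:`xenosig.expression.annotate_de`).
    Matching is on exact gene-label equality.
    """
    if "is_de" not in de_results.columns:
        raise ValueError("de_results must carry an is_de column")
    passing = correlations.index[correlations["passes"]]
    de_genes = de_results.index[de_results["is_de"]]
    common = passing.intersection(de_genes)
    if len(common) == 0:
        logger.warning("no overlap between correlated and DE genes: empty signature")
        return GeneSignature(name=name, anchor=anchor, up=(), down=())
    R = correlations.loc[common, "R"]
    fc = de_results.loc[common, "log2fc"]
    up = common[(R > 0) & (fc > 0)]
    down = common[(R < 0) & (fc < 0)]
    discordant = common.difference(up.union(down))
    logger.info(
        "signature %s: %d crossed genes -> %d up, %d down, %d discordant",
        name,
        len(common),
        len(up),
        len(down),
        len(discordant),
    )
    return GeneSignature(
        name=name,
        anchor=anchor,
        up=tuple(sorted(up)),
        down=tuple(sorted(down)),
        discordant=tuple(sorted(discordant)),
    )


def score_signature(
    expr: pd.DataFrame,
    sig: GeneSignature,
    weighted: bool = True,
) -> pd.Series:
    """Per-sample signature score from cohort z-scores.

    Each signature gene is z-scored across cohort samples.  The default
    ("weighted") score averages up-gene z minus down-gene z over all
    signature genes, weighting each sub-list by its size:
    ``(sum_up z - sum_down z) / (n_up + n_down)``.  With ``weighted=False``
    the two sub-list means get equal weight: ``(mean_up z - mean_down z)/2``.
    Signature genes missing from the cohort are logged and skipped.
    """
    up = [g for g in sig.up if g in expr.index]
    down = [g for g in sig.down if g in expr.index]
    n_missing = len(sig.up) + len(sig.down) - len(up) - len(down)
    if n_missing:
        logger.warning("%d signature genes absent from cohort", n_missing)
    if not up and not down:
        raise ValueError("no signature gene present in cohort")
    Z = pd.DataFrame(
        {g: zscore(expr.loc[g].to_numpy()) for g in up + down},
        index=expr.columns,
    ).T
    up_sum = Z.loc[up].sum(axis=0) if up else pd.Series(0.0, index=expr.columns)
    down_sum = Z.loc[down].sum(axis=0) if down else pd.Series(0.0, index=expr.columns)
    if weighted:
        score = (up_sum - down_sum) / (len(up) + len(down))
    else:
        terms = []
        if up:
            terms.append(up_sum / len(up))
        if down:
            terms.append(-down_sum / len(down))
        score = sum(terms) / len(terms)
    score.name = f"{sig.name}_score"
    return score


def build_annotation_signature(
    de_results: pd.DataFrame,
    annotations: pd.DataFrame,
    name: str = "tumor_stroma",
) -> pd.DataFrame:
    """Extract DE genes carrying at least one crosstalk annotation.

    ``annotations`` is indexed by gene with a ``categories`` column holding
    an iterable (or ';'-joined string) of category labels drawn from
    :data:`ANNOTATION_CATEGORIES`.  Output rows carry the gene's log2fc,
    direction (sign of log2fc) and display category group.
    """
    if "is_de" not in de_results.columns:
        raise ValueError("de_results must carry an is_de column")
    de = de_results[de_results["is_de"]]
    rows = []
    for gene in de.index:
        if gene not in annotations.index:
            continue
        cats = annotations.loc[gene, "categories"]
        if isinstance(cats, str):
            cats = [c for c in cats.split(";") if c]
        cats = [c for c in cats if c in ANNOTATION_CATEGORIES]
        if not cats:
            continue
        fc = float(de.loc[gene, "log2fc"])
        rows.append(
            {
                "gene": gene,
                "log2fc": fc,
                "direction": "up" if fc > 0 else "down",
                "categories": ";".join(cats),
                "group": CATEGORY_GROUPS[cats[0]],
                "signature": name,
            }
        )
    if not rows:
        logger.warning("no annotated DE gene: empty annotation signature")
        return pd.DataFrame(
            columns=["gene", "log2fc", "direction", "categories", "group", "signature"]
        ).set_index("gene")
    return pd.DataFrame(rows).set_index("gene")


def cross_sets(sets: dict[str, set]) -> dict[str, set]:
    """Full Venn partition of 2 or 3 named sets.

    Returns a mapping from region key (member set names joined by '&',
    e.g. ``"A"``, ``"A&B"``, ``"A&B&C"``) to the elements exclusive to that
    region.  Region sizes sum to the size of the union.
    """
    names = list(sets)
    if len(names) not in (2, 3):
        raise ValueError("cross_sets takes 2 or 3 sets")
    universe = set().union(*sets.values())
    regions: dict[str, set] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set().union(*(sets[n] for n in names if n not in combo)) if r < len(names) else set()
            regions["&".join(combo)] = inside - outside
    assert sum(len(v) for v in regions.values()) == len(universe)
    return regions
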