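"""Label-free secretome differential analysis.

Conditioned-medium proteomics quantified by label-free LFQ intensities, in
a small replicated design (3 control vs 3 knockout by default).  The chain
is: peptide-support and completeness filtering; left-censored missing-value
imputation from a per-sample normal down-shifted by 1.8 observed SDs and
narrowed to 0.3 SD (modelling detection-limit censoring); per-protein
unpaired Student t-tests on log2 intensities with Benjamini-Hochberg FDR
control at q < 0.01.  The effect size is the delta-LFQ, mean control minus
mean knockout log2 intensity, so a positive value means higher secretion in
the control (anchor-gene expressing) condition.
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
    "LFQMatrix",
    "DOWNSHIFT_SD",
    "DOWNSHIFT_WIDTH",
    "Q_THRESHOLD_DEFAULT",
    "filter_proteins",
    "impute_downshift",
    "differential_secretome",
    "split_terms",
]

DOWNSHIFT_SD = 1.8
DOWNSHIFT_WIDTH = 0.3
Q_THRESHOLD_DEFAULT = 0.01  # the alternative preset used for display is 0.02


@dataclass
class LFQMatrix:
    """Protein x sample log2 LFQ intensities with explicit missingness.

    ``intensities`` holds NaN for missing cells (never zero-coded after
    ingest).  ``condition`` maps each sample column to control/knockout.
    ``imputed`` marks cells filled by imputation.
    """

    intensities: pd.DataFrame
    peptide_counts: pd.Series
    condition: pd.Series
    imputed: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.intensities.columns.equals(self.condition.index):
            self.condition = self.condition.reindex(self.intensities.columns)
        if self.condition.isna().any():
            raise ValueError("every sample needs a condition label")
        bad = set(self.condition.unique()) - {"control", "knockout"}
        if bad:
            raise ValueError(f"unknown condition labels: {bad}")
        if not self.intensities.index.equals(self.peptide_counts.index):
            self.peptide_counts = self.peptide_counts.reindex(self.intensities.index)

    def samples_of(self, cond: str) -> list[str]:
        return self.condition.index[self.condition == cond].tolist()

    @classmethod
    def from_tsv(cls, path, condition: pd.Series) -> "LFQMatrix":
        """Read an LFQ TSV (protein, peptide_count, per-sample columns);
        zeros and empty cells become explicit missing values."""
        df = pd.read_csv(path, sep="\t", index_col="protein")
        pep = df.pop("peptide_count").astype(int)
        vals = df.astype(float).replace(0.0, np.nan)
        return cls(intensities=vals, peptide_counts=pep, condition=condition)


def filter_proteins(m: LFQMatrix, min_peptides: int = 2) -> LFQMatrix:
    """Keep proteins supported by >= ``min_peptides`` peptides AND fully
    quantified (no missing value) in at least one condition."""
    pep_ok = m.peptide_counts >= min_peptides
    complete_any = pd.Series(False, index=m.intensities.index)
    for cond in ("control", "knockout"):
        cols = m.samples_of(cond)
        complete_any |= m.intensities[cols].notna().all(axis=1)
    keep = pep_ok & complete_any
    logger.info(
        "protein filter: %d/%d retained (peptides>=%d and one complete condition)",
        int(keep.sum()),
        len(keep),
        min_peptides,
    )
    return LFQMatrix(
        intensities=m.intensities.loc[keep].copy(),
        peptide_counts=m.peptide_counts.loc[keep].copy(),
        condition=m.condition.copy(),
        imputed=None if m.imputed is None else m.imputed.loc[keep].copy(),
    )


def impute_downshift(
    m: LFQMatrix,
    width: float = DOWNSHIFT_WIDTH,
    shift: float = DOWNSHIFT_SD,
    seed: int = 0,
    per_sample: bool = True,
) -> LFQMatrix:
    """Impute missing log2 intensities from a down-shifted narrow normal.

    For each sample (default) or the whole matrix, the observed values give
    mean mu and SD sigma; each missing cell is drawn from
    ``Normal(mu - shift*sigma, (width*sigma)^2)``.  This models values
    missing because they fell below the detection limit.  Deterministic
    under ``seed``; the imputed mask is retained on the result.
    """
    vals = m.intensities.copy()
    mask = vals.isna()
    rng = np.random.default_rng(seed)
    if not mask.to_numpy().any():
        return LFQMatrix(vals, m.peptide_counts.copy(), m.condition.copy(), imputed=mask)
    if per_sample:
        for col in vals.columns:
            obs = vals[col].dropna()
            n_miss = int(mask[col].sum())
            if n_miss == 0:
                continue
            if obs.size < 2:
                raise ValueError(f"sample {col!r} has <2 observed values")
            mu, sigma = float(obs.mean()), float(obs.std(ddof=1))
            draws = rng.normal(mu - shift * sigma, width * sigma, size=n_miss)
            vals.loc[mask[col], col] = draws
    else:
        obs = vals.to_numpy()[~mask.to_numpy()]
        if obs.size < 2:
            raise ValueError("matrix has <2 observed values")
        mu, sigma = float(obs.mean()), float(obs.std(ddof=1))
        flat = vals.to_numpy()
        miss = mask.to_numpy()
        flat[miss] = rng.normal(mu - shift * sigma, width * sigma, size=int(miss.sum()))
        vals = pd.DataFrame(flat, index=vals.index, columns=vals.columns)
    return LFQMatrix(vals, m.peptide_counts.copy(), m.condition.copy(), imputed=mask)


def differential_secretome(
    m: LFQMatrix, q_threshold: float = Q_THRESHOLD_DEFAULT
) -> pd.DataFrame:
    """Per-protein unpaired t-test with BH correction.

    Requires the imputed matrix (no missing values).  Tests run on the
    imputed log2 intensities; the reported per-group means are recomputed
    on observed (non-imputed) values only, mirroring the convention of
    stripping imputed values from output tables.  Returns a DataFrame with
    delta_lfq (mean control minus mean knockout), t, p, q, significant and
    imputed_fraction.
    """
    vals = m.intensities
    if vals.isna().to_numpy().any():
        raise ValueError("differential_secretome requires an imputed (complete) matrix")
    ctrl_cols = m.samples_of("control")
    ko_cols = m.samples_of("knockout")
    if len(ctrl_cols) < 2 or len(ko_cols) < 2:
        raise ValueError("need >= 2 replicates per condition")
    X = vals[ctrl_cols].to_numpy()
    Y = vals[ko_cols].to_numpy()
    t_stat, p = stats.ttest_ind(X, Y, axis=1, equal_var=True)
    # degenerate zero-variance proteins: equal means -> p 1, unequal -> p 0
    flat = np.isnan(p)
    if flat.any():
        logger.warning("%d proteins with zero variance in both groups", int(flat.sum()))
        eq = np.isclose(X.mean(axis=1), Y.mean(axis=1))
        p = np.where(flat & eq, 1.0, np.where(flat, 0.0, p))
        t_stat = np.where(flat, 0.0, t_stat)
    q = np.asarray(bh_adjust(p).adjusted)
    delta = X.mean(axis=1) - Y.mean(axis=1)

    imputed = m.imputed if m.imputed is not None else pd.DataFrame(False, index=vals.index, columns=vals.columns)
    imp_frac = imputed.mean(axis=1).to_numpy()
    observed = vals.where(~imputed)
    mean_ctrl_obs = observed[ctrl_cols].mean(axis=1)
    mean_ko_obs = observed[ko_cols].mean(axis=1)

    return pd.DataFrame(
        {
            "delta_lfq": delta,
            "t": t_stat,
            "p": p,
            "q": q,
            "significant": q < q_threshold,
            "imputed_fraction": imp_frac,
            "mean_control_observed": mean_ctrl_obs,
            "mean_knockout_observed": mean_ko_obs,
        },
        index=vals.index,
    )


def split_terms(terms: list[str], separator: str = ";") -> tuple[list[str], int]:
    """Flatten multi-gene term entries into a deduplicated gene list.

    Returns the flat list (first-occurrence order) and the number of
    duplicate mentions removed.  Empty entries are skipped with a log line.
    """
    seen: dict[str, None] = {}
    n_dup = 0
    n_empty = 0
    for entry in terms:
        parts = [p.strip() for p in entry.split(separator)]
        for part in parts:
            if not part:
                n_empty += 1
                continue
            if part in seen:
                n_dup += 1
            else:
                seen[part] = None
    if n_empty:
        logger.info("%d empty term entries skipped", n_empty)
    return list(seen), n_dup
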