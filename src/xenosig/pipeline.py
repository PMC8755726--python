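"""End-to-end orchestration: split -> counts -> DE -> signature -> scoring ->
survival, with the secretome branch in parallel and set-crossing last.

Every stage reads and writes files (TSV/GMT/JSON), so individual stages can
be re-run; no stage mutates its inputs.  A manifest with a configuration
hash makes reruns verifiable.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import pandas as pd

from . import expression, io, secretome, signature, survival, xenosplit
from .expression import DEThresholds
from .secretome import LFQMatrix

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclasses.dataclass
class PipelineConfig:
    """All thresholds and policy flags for a full run.

    Defaults are the study's printed constants: correlation threshold
    0.225; DE cutoffs |log2FC| >= 1 / FDR < 0.05 (human) and 0.5 / 0.05
    (mouse); secretome q < 0.01 with downshift 1.8 SD, width 0.3;
    enrichment cutoffs p < 0.001 / adj < 0.01 (human).
    """

    out_dir: str = "xenosig_run"
    seed: int = 0
    r_threshold: float = signature.R_THRESHOLD_DEFAULT
    human_fc_cutoff: float = 1.0
    mouse_fc_cutoff: float = 0.5
    fdr_cutoff: float = 0.05
    secretome_q: float = secretome.Q_THRESHOLD_DEFAULT
    downshift_sd: float = secretome.DOWNSHIFT_SD
    downshift_width: float = secretome.DOWNSHIFT_WIDTH
    enrichment_p: float = 0.001
    enrichment_adj: float = 0.01
    split_policy: str = "paper_asymmetric"
    weighted_score: bool = True
    impute_per_sample: bool = True
    anchor: str = "ANCHOR"

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(
    cfg: PipelineConfig,
    cohort_expression: pd.DataFrame,
    clinical: pd.DataFrame,
    xeno_counts: pd.DataFrame,
    xeno_groups: pd.Series,
    lfq_intensities: pd.DataFrame | None = None,
    lfq_peptides: pd.Series | None = None,
    lfq_condition: pd.Series | None = None,
    alignment_records: list | None = None,
) -> dict:
    """Run the dependency-ordered pipeline on in-memory inputs.

    Returns a dict of stage outputs; everything is also written under
    ``cfg.out_dir``.  The transcriptome arm derives and scores the
    anchor-gene signature and tests its survival association; the secretome
    arm (optional) runs filter -> impute -> test; the final crossing stage
    compares the DE gene set with the secretome hit set when both exist.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline run: defaults %s", cfg.as_dict())
    outputs: list[str] = []
    results: dict = {}

    if alignment_records is not None:
        classes = xenosplit.classify_reads(alignment_records)
        human, mouse, report = xenosplit.split_by_policy(classes, cfg.split_policy)
        report.to_frame().to_csv(out / "split_report.tsv", sep="\t", index=False)
        outputs.append("split_report.tsv")
        results["split_report"] = report

    thresholds = DEThresholds(cfg.human_fc_cutoff, cfg.fdr_cutoff, "human")
    de = expression.de_test(xeno_counts, xeno_groups, reference="knockout")
    de = expression.annotate_de(de, thresholds)
    de.to_csv(out / "de_results.tsv", sep="\t")
    outputs.append("de_results.tsv")
    results["de"] = de

    corr = signature.correlate_with_anchor(
        cohort_expression, cfg.anchor, threshold=cfg.r_threshold
    )
    corr.to_csv(out / "anchor_correlations.tsv", sep="\t")
    outputs.append("anchor_correlations.tsv")
    results["correlations"] = corr

    sig = signature.derive_signature(corr, de, name="anchor_signature", anchor=cfg.anchor)
    sig.to_gmt(out / "signature.gmt")
    outputs.append("signature.gmt")
    results["signature"] = sig

    if sig.genes:
        scores = signature.score_signature(
            cohort_expression, sig, weighted=cfg.weighted_score
        )
        scores.rename("score").to_frame().to_csv(out / "signature_scores.tsv", sep="\t")
        outputs.append("signature_scores.tsv")
        results["scores"] = scores

        assoc = survival.survival_association(
            clinical, scores, scan_seed=cfg.seed
        )
        results["survival"] = assoc
        rows = []
        for ep, r in assoc["endpoints"].items():
            rows.append(
                {
                    "endpoint": ep,
                    "cutoff": assoc["rule"].cutoff,
                    "logrank_p": r["logrank"]["p"],
                    "gbw_p": r["gbw"]["p"],
                    "n_high": r["n_high"],
                    "n_low": r["n_low"],
                }
            )
        pd.DataFrame(rows).to_csv(out / "survival_tests.tsv", sep="\t", index=False)
        outputs.append("survival_tests.tsv")

    if lfq_intensities is not None:
        m = LFQMatrix(lfq_intensities, lfq_peptides, lfq_condition)
        m = secretome.filter_proteins(m)
        m = secretome.impute_downshift(
            m,
            width=cfg.downshift_width,
            shift=cfg.downshift_sd,
            seed=cfg.seed,
            per_sample=cfg.impute_per_sample,
        )
        sec = secretome.differential_secretome(m, q_threshold=cfg.secretome_q)
        sec.to_csv(out / "secretome_results.tsv", sep="\t")
        outputs.append("secretome_results.tsv")
        results["secretome"] = sec

        de_set = set(de.index[de["is_de"]])
        sec_set = set(sec.index[sec["significant"]])
        if de_set or sec_set:
            regions = signature.cross_sets(
                {"transcriptome": de_set, "secretome": sec_set}
            )
            pd.DataFrame(
                [{"region": k, "count": len(v)} for k, v in regions.items()]
            ).to_csv(out / "cross_sets.tsv", sep="\t", index=False)
            outputs.append("cross_sets.tsv")
            results["cross"] = regions

    io.write_manifest(out, cfg.as_dict(), outputs)
    return results
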