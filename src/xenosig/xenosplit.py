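"""Host/graft read disambiguation for xenograft RNA-seq.

Xenograft tumours contain human (graft) and mouse (host stroma) cells, so
reads are aligned to both genomes simultaneously.  Each read is classified
from its per-organism hits as human-only, mouse-only, ambiguous (hits on
both genomes) or unmapped, and an ambiguity policy decides which reads feed
each organism's gene counts.

The default ``paper_asymmetric`` policy discards ambiguous reads from the
mouse side only (they are overwhelmingly human reads cross-mapping to
conserved mouse loci, and the mouse signal is the scarce one to protect);
``strict_both`` discards them from both sides for sensitivity analysis.

Input is a minimal SAM-like TSV dialect (columns: read_id, organism,
gene_id with '-' for intergenic hits, n_hits) so the splitting logic is
testable without aligner binaries.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentRecord",
    "ReadClassification",
    "SplitReport",
    "MULTIMAP_CAP",
    "classify_reads",
    "split_by_policy",
    "count_genes",
    "read_alignment_tsv",
    "write_alignment_tsv",
]

#: multi-mapping cap mirrored from typical aligner settings (at most 50
#: reported hits per read)
MULTIMAP_CAP = 50

ORGANISMS = ("human", "mouse")
CALLS = ("human_only", "mouse_only", "ambiguous", "unmapped")

Policy = Literal["paper_asymmetric", "strict_both"]


@dataclass(frozen=True)
class AlignmentRecord:
    """One read's hit on one organism's genome.

    ``gene_id`` is None for an intergenic hit.  ``n_hits`` is the number of
    loci the aligner reported for this read on this genome.
    """

    read_id: str
    organism: str
    gene_id: str | None
    n_hits: int = 1

    def __post_init__(self) -> None:
        if self.organism not in ORGANISMS:
            raise ValueError(f"organism must be one of {ORGANISMS}")
        if not 1 <= self.n_hits <= MULTIMAP_CAP:
            raise ValueError(f"n_hits must be in [1, {MULTIMAP_CAP}]")


@dataclass(frozen=True)
class ReadClassification:
    read_id: str
    call: str

    def __post_init__(self) -> None:
        if self.call not in CALLS:
            raise ValueError(f"call must be one of {CALLS}")


@dataclass(frozen=True)
class SplitReport:
    """Class tallies and retained totals for one split run."""

    human_only: int
    mouse_only: int
    ambiguous: int
    unmapped: int
    policy: str
    human_retained: int
    mouse_retained: int

    @property
    def total(self) -> int:
        return self.human_only + self.mouse_only + self.ambiguous + self.unmapped

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": [*CALLS, "human_retained", "mouse_retained"],
                "count": [
                    self.human_only,
                    self.mouse_only,
                    self.ambiguous,
                    self.unmapped,
                    self.human_retained,
                    self.mouse_retained,
                ],
            }
        )


def classify_reads(
    records: Iterable[AlignmentRecord],
    all_read_ids: Iterable[str] | None = None,
) -> list[ReadClassification]:
    """Assign each read exactly one of the four class calls.

    A read with hits on only one genome is `<organism>_only`; hits on both
    genomes make it `ambiguous`.  Reads listed in ``all_read_ids`` but
    absent from the records are `unmapped` (without that list, unmapped
    reads are not representable since records only exist for mapped reads).
    Duplicate (read_id, organism, gene_id) records are deduplicated with a
    logged count.
    """
    seen: set[tuple[str, str, str | None]] = set()
    orgs_per_read: dict[str, set[str]] = defaultdict(set)
    order: list[str] = []
    n_dup = 0
    for rec in records:
        key = (rec.read_id, rec.organism, rec.gene_id)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        if rec.read_id not in orgs_per_read:
            order.append(rec.read_id)
        orgs_per_read[rec.read_id].add(rec.organism)
    if n_dup:
        logger.warning("deduplicated %d duplicate alignment records", n_dup)

    out: list[ReadClassification] = []
    for rid in order:
        orgs = orgs_per_read[rid]
        if orgs == {"human"}:
            call = "human_only"
        elif orgs == {"mouse"}:
            call = "mouse_only"
        else:
            call = "ambiguous"
        out.append(ReadClassification(rid, call))
    if all_read_ids is not None:
        for rid in all_read_ids:
            if rid not in orgs_per_read:
                out.append(ReadClassification(rid, "unmapped"))
    return out


def split_by_policy(
    classes: list[ReadClassification], policy: Policy = "paper_asymmetric"
) -> tuple[set[str], set[str], SplitReport]:
    """Partition classified reads into per-organism retained sets.

    ``paper_asymmetric``: ambiguous reads stay in the human set but are
    discarded from the mouse set.  ``strict_both``: ambiguous reads are
    discarded from both.
    """
    if policy not in ("paper_asymmetric", "strict_both"):
        raise ValueError(f"unknown split policy: {policy!r}")
    by_call: dict[str, set[str]] = {c: set() for c in CALLS}
    for cl in classes:
        by_call[cl.call].add(cl.read_id)
    human = set(by_call["human_only"])
    if policy == "paper_asymmetric":
        human |= by_call["ambiguous"]
    mouse = set(by_call["mouse_only"])
    report = SplitReport(
        human_only=len(by_call["human_only"]),
        mouse_only=len(by_call["mouse_only"]),
        ambiguous=len(by_call["ambiguous"]),
        unmapped=len(by_call["unmapped"]),
        policy=policy,
        human_retained=len(human),
        mouse_retained=len(mouse),
    )
    logger.info(
        "split (%s): human_only=%d mouse_only=%d ambiguous=%d unmapped=%d "
        "-> human=%d mouse=%d",
        policy,
        report.human_only,
        report.mouse_only,
        report.ambiguous,
        report.unmapped,
        report.human_retained,
        report.mouse_retained,
    )
    return human, mouse, report


def count_genes(
    reads: set[str],
    records: Iterable[AlignmentRecord],
    organism: str,
    sample: str,
    seed: int = 0,
) -> pd.Series:
    """Per-gene read counts for one organism and one sample.

    Each retained read contributes 1 to exactly one gene: its unique gene
    if all its hits on this organism agree, otherwise a seeded uniform
    random choice among its hit genes (a deterministic simplification of
    expectation-maximisation assignment that preserves totals).
    Intergenic-only reads are dropped; retained reads with no record for
    this organism are counted as dropped and logged.
    """
    if organism not in ORGANISMS:
        raise ValueError(f"organism must be one of {ORGANISMS}")
    genes_per_read: dict[str, list[str]] = defaultdict(list)
    for rec in records:
        if rec.organism != organism or rec.read_id not in reads:
            continue
        if rec.gene_id is not None and rec.gene_id not in genes_per_read[rec.read_id]:
            genes_per_read[rec.read_id].append(rec.gene_id)
        else:
            genes_per_read[rec.read_id]  # register intergenic-only reads too

    rng = np.random.default_rng(seed)
    counts: dict[str, int] = defaultdict(int)
    n_intergenic = 0
    # reads assigned in sorted order so the seeded choice is order-independent
    for rid in sorted(genes_per_read):
        genes = genes_per_read[rid]
        if not genes:
            n_intergenic += 1
            continue
        gene = genes[0] if len(genes) == 1 else str(rng.choice(sorted(genes)))
        counts[gene] += 1
    n_missing = len(reads) - len(genes_per_read)
    if n_missing:
        logger.warning(
            "%d retained reads had no %s record: dropped", n_missing, organism
        )
    if n_intergenic:
        logger.info("%d intergenic-only reads dropped for %s", n_intergenic, organism)
    return pd.Series(counts, name=sample, dtype=int).sort_index()


def read_alignment_tsv(path) -> list[AlignmentRecord]:
    """Read the alignment TSV dialect: read_id, organism, gene_id ('-' =
    intergenic), n_hits."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["read_id", "organism", "gene_id", "n_hits"]
    if list(df.columns) != expected:
        raise ValueError(
            f"alignment TSV {path}: expected columns {expected}, got {list(df.columns)}"
        )
    return [
        AlignmentRecord(
            read_id=row.read_id,
            organism=row.organism,
            gene_id=None if row.gene_id == "-" else row.gene_id,
            n_hits=int(row.n_hits),
        )
        for row in df.itertuples(index=False)
    ]


def write_alignment_tsv(records: Iterable[AlignmentRecord], path) -> None:
    df = pd.DataFrame(
        [
            (r.read_id, r.organism, r.gene_id if r.gene_id is not None else "-", r.n_hits)
            for r in records
        ],
        columns=["read_id", "organism", "gene_id", "n_hits"],
    )
    df.to_csv(path, sep="\t", index=False)
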