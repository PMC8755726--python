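"""Synthetic inputs with planted ground truth for every pipeline stage.

Four generators emulate the data shapes the pipeline consumes:

* a tumour cohort (log2-scale expression, survival, clinical labels) whose
  expression contains an anchor gene, genes correlated and anti-correlated
  with it, and survival times tied to a planted latent signature score;
* a two-condition xenograft experiment (negative-binomial counts with
  planted human and mouse DE genes) plus dual-genome alignment records
  with known class labels;
* a 3-vs-3 label-free secretome with intensity-dependent (left-censoring)
  missingness and planted delta-LFQ effects;
* gene sets (GMT) and crosstalk annotations, one set deliberately enriched
  in planted DE genes.

Every generator is deterministic under the config seed and returns its
ground truth alongside the data; cross-module recovery tests consume only
that sidecar.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
import pandas as pd
from scipy.special import expit

from .xenosplit import AlignmentRecord

__all__ = [
    "SimConfig",
    "GroundTruth",
    "generate_cohort",
    "generate_xenograft",
    "generate_secretome",
    "generate_gene_sets_and_annotations",
]


@dataclass
class SimConfig:
    """Study-condition knobs for all generators.

    Defaults mirror the emulated designs: a ~500-patient cohort, a 4-vs-4
    xenograft comparison, a 3-vs-3 secretome; planted effect sizes are the
    scales the recovery analyses probe (cohort correlation 0.6, xenograft
    log2 fold change 2 with NB dispersion 0.05, secretome delta-LFQ 2 with
    replicate SD 0.5).
    """

    seed: int = 0
    # cohort
    n_samples: int = 498
    n_genes: int = 2000
    n_anchor_pos: int = 100
    n_anchor_neg: int = 100
    rho: float = 0.6
    hazard_ratio_per_sd: float = 2.0
    censor_rate: float = 0.3
    mna_fraction: float = 0.2
    median_survival_months: float = 60.0
    anchor_name: str = "ANCHOR"
    # xenograft
    n_per_group: int = 4
    n_de: int = 200
    log2fc_planted: float = 2.0
    nb_dispersion: float = 0.05
    mean_count: float = 200.0
    n_reads: int = 4000
    ambiguous_fraction: float = 0.1
    mouse_read_fraction: float = 0.25
    # secretome
    n_proteins: int = 1000
    n_replicates: int = 3
    secretome_effect_fraction: float = 0.1
    delta_lfq_planted: float = 2.0
    lfq_replicate_sd: float = 0.5
    lfq_mean: float = 25.0
    lfq_spread: float = 2.0
    missing_rate: float = 0.9  # ceiling of the logistic missingness curve
    missing_midpoint_sd: float = 1.5  # curve midpoint, SDs below the LFQ mean
    missing_steepness: float = 1.0
    single_peptide_fraction: float = 0.1
    # gene sets
    n_sets: int = 20
    set_size: int = 50

    def __post_init__(self) -> None:
        if not -1 < self.rho < 1:
            raise ValueError("rho must lie in (-1, 1)")
        if not 0 <= self.censor_rate <= 1:
            raise ValueError("censor_rate must lie in [0, 1]")
        if self.n_anchor_pos + self.n_anchor_neg >= self.n_genes:
            raise ValueError("planted correlated genes must fit inside n_genes")


@dataclass
class GroundTruth:
    """Planted truth serialized alongside every generated dataset."""

    planted_signature_up: list[str] = field(default_factory=list)
    planted_signature_down: list[str] = field(default_factory=list)
    latent_score: dict[str, float] = field(default_factory=dict)
    read_class_labels: dict[str, str] = field(default_factory=dict)
    planted_de: dict[str, float] = field(default_factory=dict)
    planted_secretome: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _gene_names(n: int, prefix: str = "G") -> list[str]:
    return [f"{prefix}{i:05d}" for i in range(n)]


def generate_cohort(cfg: SimConfig) -> tuple[dict, GroundTruth]:
    """Cohort expression + survival + clinical labels with a planted score.

    Expression is simulated directly on the log2 scale.  The anchor gene is
    a standard-normal latent; planted genes are ``rho * anchor + noise``
    (negated for the anti-correlated block); all other genes are
    independent noise.  The latent score is the mean planted-gene z
    (anti-correlated genes entering with flipped sign).  Survival times are
    exponential with hazard proportional to
    ``hazard_ratio_per_sd ** standardized_score``; censoring replaces the
    event time by a uniform draw below it with probability
    ``censor_rate``.  MYCN amplification (MNA), risk and stage labels are
    drawn with score-dependent log-odds.

    Returns ``(cohort, truth)`` where cohort is a dict with ``expression``
    (gene x sample DataFrame) and ``clinical`` (per-sample DataFrame with
    OS/EFS times and events plus mycn/risk/stage).
    """
    rng = np.random.default_rng(cfg.seed)
    n, g = cfg.n_samples, cfg.n_genes
    samples = [f"S{i:04d}" for i in range(n)]
    genes = _gene_names(g)

    anchor_latent = rng.standard_normal(n)
    expr = rng.standard_normal((g, n))  # baseline: independent noise

    n_pos, n_neg = cfg.n_anchor_pos, cfg.n_anchor_neg
    pos_idx = np.arange(1, 1 + n_pos)  # gene 0 is the anchor itself
    neg_idx = np.arange(1 + n_pos, 1 + n_pos + n_neg)
    w = np.sqrt(1 - cfg.rho**2)
    expr[pos_idx] = cfg.rho * anchor_latent + w * rng.standard_normal((n_pos, n))
    expr[neg_idx] = -cfg.rho * anchor_latent + w * rng.standard_normal((n_neg, n))
    expr[0] = anchor_latent

    # per-gene affine placement onto a log2-expression-like scale
    base = rng.uniform(4, 12, size=g)
    scale = rng.uniform(0.5, 2.0, size=g)
    values = expr * scale[:, None] + base[:, None]
    expression = pd.DataFrame(values, index=genes, columns=samples)
    expression.index.name = "gene"
    anchor = cfg.anchor_name
    expression = expression.rename(index={genes[0]: anchor})
    genes = list(expression.index)

    z = (expr - expr.mean(axis=1, keepdims=True)) / expr.std(axis=1, keepdims=True)
    latent = (z[pos_idx].sum(axis=0) - z[neg_idx].sum(axis=0)) / (n_pos + n_neg)
    latent_std = (latent - latent.mean()) / latent.std()

    def _draw_survival(seed_offset: int) -> tuple[np.ndarray, np.ndarray]:
        r = np.random.default_rng(cfg.seed + seed_offset)
        base_rate = np.log(2) / cfg.median_survival_months
        rate = base_rate * cfg.hazard_ratio_per_sd**latent_std
        t_event = r.exponential(1.0 / rate)
        censored = r.random(n) < cfg.censor_rate
        t_obs = np.where(censored, r.random(n) * t_event, t_event)
        return t_obs, (~censored).astype(int)

    os_t, os_e = _draw_survival(101)
    efs_t, efs_e = _draw_survival(202)

    r = np.random.default_rng(cfg.seed + 303)
    logit_base = np.log(cfg.mna_fraction / (1 - cfg.mna_fraction))
    p_mna = expit(logit_base + 0.8 * latent_std)
    mna = r.random(n) < p_mna
    p_hr = expit(np.log(0.35 / 0.65) + 1.0 * latent_std)
    high_risk = r.random(n) < p_hr
    stage_score = latent_std + r.standard_normal(n)
    stage = np.select(
        [stage_score < -0.5, stage_score < 0.5], ["1-2", "3"], default="4"
    )

    clinical = pd.DataFrame(
        {
            "OS_time": os_t,
            "OS_event": os_e,
            "EFS_time": efs_t,
            "EFS_event": efs_e,
            "mycn": np.where(mna, "MNA", "no-MNA"),
            "risk": np.where(high_risk, "HR", "LR"),
            "stage": stage,
        },
        index=pd.Index(samples, name="sample"),
    )

    truth = GroundTruth(
        planted_signature_up=[genes[i] for i in pos_idx],
        planted_signature_down=[genes[i] for i in neg_idx],
        latent_score=dict(zip(samples, latent_std.round(8).tolist())),
    )
    return {"expression": expression, "clinical": clinical, "anchor": anchor}, truth


def _nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB draws parameterised by mean and dispersion alpha (var = mu + alpha mu^2);
    the alpha -> 0 limit is Poisson."""
    if dispersion <= 1e-12:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def generate_xenograft(
    cfg: SimConfig,
    planted_up: list[str] | None = None,
    planted_down: list[str] | None = None,
    gene_names: list[str] | None = None,
    organism: str = "human",
) -> tuple[pd.DataFrame, pd.Series, list[AlignmentRecord], GroundTruth]:
    """Two-condition NB counts with planted DE genes, plus alignment records.

    ``planted_up``/``planted_down`` name genes forced DE (positive /
    negative log2fc, control minus knockout orientation: "up" genes are
    higher in the control condition); by default the first ``n_de`` genes
    are planted, half up, half down.  Alignment records for ``n_reads``
    reads are drawn with known human/mouse/ambiguous fractions, gene
    assignment following the first control sample's count proportions, so
    classification truth is exact by construction.

    Returns ``(counts, groups, records, truth)``; counts columns are
    control/knockout replicates, ``groups`` maps sample -> condition.
    """
    rng = np.random.default_rng(cfg.seed + 17)
    genes = list(gene_names) if gene_names is not None else _gene_names(cfg.n_genes)
    g = len(genes)
    n_rep = cfg.n_per_group
    samples = [f"ctrl_{i}" for i in range(n_rep)] + [f"ko_{i}" for i in range(n_rep)]
    groups = pd.Series(
        ["control"] * n_rep + ["knockout"] * n_rep, index=samples, name="condition"
    )

    if planted_up is None or planted_down is None:
        half = cfg.n_de // 2
        planted_up = genes[:half]
        planted_down = genes[half : cfg.n_de]
    fc = pd.Series(0.0, index=genes)
    fc.loc[planted_up] = cfg.log2fc_planted
    fc.loc[planted_down] = -cfg.log2fc_planted

    base = rng.lognormal(mean=np.log(cfg.mean_count), sigma=0.8, size=g)
    # split the planted fold change symmetrically around the base mean
    mu_ctrl = base * 2.0 ** (fc.to_numpy() / 2)
    mu_ko = base * 2.0 ** (-fc.to_numpy() / 2)
    counts = np.empty((g, 2 * n_rep), dtype=int)
    for j in range(n_rep):
        counts[:, j] = _nb_counts(rng, mu_ctrl, cfg.nb_dispersion)
        counts[:, n_rep + j] = _nb_counts(rng, mu_ko, cfg.nb_dispersion)
    count_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=samples)

    records, labels = _alignment_records(cfg, count_df, organism, rng)
    truth = GroundTruth(
        planted_de={gene: float(f) for gene, f in fc.items() if f != 0.0},
        read_class_labels=labels,
    )
    return count_df, groups, records, truth


def _alignment_records(
    cfg: SimConfig,
    counts: pd.DataFrame,
    organism: str,
    rng: np.random.Generator,
) -> tuple[list[AlignmentRecord], dict[str, str]]:
    other = "mouse" if organism == "human" else "human"
    frac_other = cfg.mouse_read_fraction if organism == "human" else 1 - cfg.mouse_read_fraction
    frac_amb = cfg.ambiguous_fraction
    frac_main = 1.0 - frac_other - frac_amb
    if frac_main <= 0:
        raise ValueError("read fractions leave no unambiguous graft reads")
    probs = counts.iloc[:, 0].to_numpy(dtype=float)
    probs = probs / probs.sum()
    genes = counts.index.to_numpy()
    records: list[AlignmentRecord] = []
    labels: dict[str, str] = {}
    u = rng.random(cfg.n_reads)
    gene_draws = rng.choice(genes, size=cfg.n_reads, p=probs)
    other_gene_draws = rng.choice(genes, size=cfg.n_reads, p=probs)
    for i in range(cfg.n_reads):
        rid = f"r{i:06d}"
        if u[i] < frac_main:
            records.append(AlignmentRecord(rid, organism, str(gene_draws[i])))
            labels[rid] = f"{organism}_only"
        elif u[i] < frac_main + frac_other:
            records.append(AlignmentRecord(rid, other, str(gene_draws[i])))
            labels[rid] = f"{other}_only"
        else:
            records.append(AlignmentRecord(rid, organism, str(gene_draws[i])))
            records.append(AlignmentRecord(rid, other, str(other_gene_draws[i])))
            labels[rid] = "ambiguous"
    return records, labels


def generate_secretome(cfg: SimConfig) -> tuple[pd.DataFrame, pd.Series, pd.Series, GroundTruth]:
    """3-vs-3 log2 LFQ intensities with left-censoring missingness.

    Per-protein true abundance is normal (``lfq_mean`` +/- ``lfq_spread``);
    replicates add noise of SD ``lfq_replicate_sd``; a planted fraction of
    proteins carries ``delta_lfq_planted`` (control minus knockout, half in
    each direction).  Each cell goes missing with probability
    ``missing_rate * sigmoid((midpoint - value) * steepness)`` — a logistic
    in the true cell intensity, concentrating missingness at low abundance
    exactly as downshift imputation assumes.  Peptide counts are >= 1 with
    ``single_peptide_fraction`` of proteins at exactly 1 to exercise the
    peptide filter.

    Returns ``(intensities, peptide_counts, condition, truth)``.
    """
    rng = np.random.default_rng(cfg.seed + 29)
    p, n_rep = cfg.n_proteins, cfg.n_replicates
    proteins = [f"P{i:05d}" for i in range(p)]
    samples = [f"ctrl_{i}" for i in range(n_rep)] + [f"ko_{i}" for i in range(n_rep)]
    condition = pd.Series(
        ["control"] * n_rep + ["knockout"] * n_rep, index=samples, name="condition"
    )

    n_eff = int(round(cfg.secretome_effect_fraction * p))
    half = n_eff // 2
    delta = np.zeros(p)
    delta[:half] = cfg.delta_lfq_planted
    delta[half:n_eff] = -cfg.delta_lfq_planted

    abundance = rng.normal(cfg.lfq_mean, cfg.lfq_spread, size=p)
    mu_ctrl = abundance + delta / 2
    mu_ko = abundance - delta / 2
    vals = np.empty((p, 2 * n_rep))
    for j in range(n_rep):
        vals[:, j] = rng.normal(mu_ctrl, cfg.lfq_replicate_sd)
        vals[:, n_rep + j] = rng.normal(mu_ko, cfg.lfq_replicate_sd)

    midpoint = cfg.lfq_mean - cfg.missing_midpoint_sd * cfg.lfq_spread
    p_miss = cfg.missing_rate * expit((midpoint - vals) * cfg.missing_steepness)
    missing = rng.random(vals.shape) < p_miss
    vals_obs = np.where(missing, np.nan, vals)

    peptides = 1 + rng.poisson(4, size=p)
    single = rng.random(p) < cfg.single_peptide_fraction
    peptides[single] = 1

    intensities = pd.DataFrame(
        vals_obs, index=pd.Index(proteins, name="protein"), columns=samples
    )
    truth = GroundTruth(
        planted_secretome={
            proteins[i]: float(delta[i]) for i in range(p) if delta[i] != 0.0
        }
    )
    return intensities, pd.Series(peptides, index=intensities.index, name="peptide_count"), condition, truth


def generate_gene_sets_and_annotations(
    cfg: SimConfig,
    planted_de: list[str] | None = None,
    gene_universe: list[str] | None = None,
) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Random GMT-style gene sets plus one set enriched in planted DE genes,
    and a crosstalk annotation table tagging a known gene subset."""
    rng = np.random.default_rng(cfg.seed + 41)
    universe = list(gene_universe) if gene_universe is not None else _gene_names(cfg.n_genes)
    sets: dict[str, list[str]] = {}
    for i in range(cfg.n_sets):
        members = rng.choice(universe, size=min(cfg.set_size, len(universe)), replace=False)
        sets[f"RANDOM_SET_{i:02d}"] = sorted(members.tolist())
    if planted_de:
        k_planted = min(len(planted_de), cfg.set_size // 2)
        chosen = rng.choice(planted_de, size=k_planted, replace=False).tolist()
        filler_pool = [g for g in universe if g not in set(chosen)]
        filler = rng.choice(
            filler_pool, size=max(cfg.set_size - k_planted, 0), replace=False
        ).tolist()
        sets["ENRICHED_SET"] = sorted(chosen + filler)

    categories = (
        "growth_factor",
        "cytokine",
        "chemokine",
        "inflammatory_mediator",
        "receptor",
        "integrin",
        "integrin_ligand",
    )
    n_ann = min(len(universe), max(cfg.n_sets * 5, 50))
    annotated = rng.choice(universe, size=n_ann, replace=False)
    rows = [
        {"gene": gene, "categories": str(rng.choice(categories))} for gene in annotated
    ]
    ann = pd.DataFrame(rows).set_index("gene").sort_index()
    return sets, ann
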