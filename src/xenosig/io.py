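"""Plain-text readers/writers: GMT gene sets and the pipeline's TSV dialects."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

__all__ = [
    "read_gmt",
    "write_gmt",
    "read_expression_tsv",
    "read_clinical_tsv",
    "write_manifest",
]


def read_gmt(path) -> dict[str, list[str]]:
    """GMT: one set per line — name, description, then member genes,
    tab-separated."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: malformed GMT line")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def read_expression_tsv(path) -> pd.DataFrame:
    """Gene x sample matrix with a leading ``gene`` column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty expression matrix")
    return df.astype(float)


def read_clinical_tsv(path) -> pd.DataFrame:
    """Per-sample clinical table: sample, {OS,EFS}_time/_event, mycn, risk, stage."""
    df = pd.read_csv(path, sep="\t", index_col="sample")
    for col in ("OS_time", "OS_event"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col}")
    return df


def write_manifest(out_dir, config: dict, outputs: list[str]) -> Path:
    """Write a run manifest with a deterministic hash of the configuration."""
    payload = json.dumps(config, sort_keys=True, default=str)
    digest = hashlib.sha256(payload.encode()).hexdigest()[:16]
    manifest = {"config": config, "config_hash": digest, "outputs": sorted(outputs)}
    path = Path(out_dir) / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return path
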