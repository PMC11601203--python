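"""File formats, run configuration and provenance manifests.

Formats are deliberately plain: FASTA for sequences (Biopython-backed), CSV
for assay tables / scorecards / coordinates / background frequencies, JSON
for landscapes, reports and manifests, YAML for run configuration.  Assay
tables follow the deep-mutational-scanning convention of a ``mutant`` column
("Q786L", multisite joined by ';' or ':') and a numeric ``score`` column.

Every CLI run writes a manifest next to its outputs: config hash, seeds,
package and library versions, and SHA-256 checksums of the inputs, so any
output file is re-derivable from its manifest.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pydantic import BaseModel, ConfigDict

from .design import AssayRecord
from .scoring import Variant, parse_variant


# ----------------------------------------------------------------- sequences
def read_fasta(path) -> list[tuple[str, str]]:
    """(id, sequence) pairs in file order; ids cut at first whitespace."""
    records = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty record {rec.id!r} in {path}")
        seen[rec.id] = seen.get(rec.id, 0) + 1
        records.append((rec.id, seq))
    dupes = sorted(k for k, n in seen.items() if n > 1)
    if dupes:
        raise ValueError(f"duplicate FASTA ids in {path}: {dupes}")
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(path, records: list[tuple[str, str]]) -> None:
    SeqIO.write([SeqRecord(Seq(seq), id=rid, description="")
                 for rid, seq in records], str(path), "fasta")


# -------------------------------------------------------------- assay tables
def read_assay_csv(path, wild_type: str, mutant_col: str = "mutant",
                   score_col: str = "score",
                   round_tag: int = 0) -> list[AssayRecord]:
    """Parse a labeled-mutant table, validating variants against a wild type.

    Both ';'- and ':'-joined multisite notations are accepted.  Errors name
    the offending row (1-based, excluding the header).
    """
    df = pd.read_csv(path)
    for col in (mutant_col, score_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r} "
                             f"(have {list(df.columns)})")
    records, seen = [], set()
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        text = str(getattr(row, mutant_col))
        try:
            variant = parse_variant(text, wild_type)
        except ValueError as e:
            raise ValueError(f"{path} row {row_no}: {e}") from e
        score = getattr(row, score_col)
        try:
            score = float(score)
        except (TypeError, ValueError):
            raise ValueError(
                f"{path} row {row_no}: non-numeric score {score!r}") from None
        key = str(variant)
        if key in seen:
            raise ValueError(f"{path} row {row_no}: duplicate variant {key}")
        seen.add(key)
        records.append(AssayRecord(variant, score, round_tag=round_tag))
    return records


def write_scorecard_csv(path, scorecard: pd.DataFrame) -> None:
    scorecard.to_csv(path, index=False, float_format="%.17g")


def read_ogt_corpus_csv(path) -> list[tuple[str, str, float]]:
    """(id, sequence, OGT °C) records from a 3-column CSV."""
    df = pd.read_csv(path)
    for col in ("id", "sequence", "ogt"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return [(str(r.id), str(r.sequence), float(r.ogt))
            for r in df.itertuples(index=False)]


# -------------------------------------------------------------- coordinates
def read_coords_csv(path) -> dict[int, np.ndarray]:
    """position -> (n_points, 3) Å coordinates from position,x,y,z rows."""
    df = pd.read_csv(path)
    for col in ("position", "x", "y", "z"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if not np.isfinite(df[["x", "y", "z"]].to_numpy()).all():
        raise ValueError(f"{path}: non-finite coordinates")
    return {int(pos): g[["x", "y", "z"]].to_numpy(dtype=float)
            for pos, g in df.groupby("position")}


# -------------------------------------------------------------------- config
class RunConfig(BaseModel):
    """Schema-validated run configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    preset: str = "desk"            # desk | paper (paper is documentation)
    n_layers: int = 2
    n_heads: int = 4
    embed_dim: int = 64
    max_len: int = 512
    noise_rate: float = 0.20
    mask_share: float = 0.70
    substitute_share: float = 0.20
    keep_share: float = 0.10
    mlm_weight: float = 1.0
    ogt_weight: float = 0.01
    corr_weight: float = 1.0
    learning_rate: float = 1e-4
    total_steps: int = 300
    tokens_per_microbatch: int = 1024
    scoring_mode: str = "wt-marginal"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


# ------------------------------------------------------------------ manifest
def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_path, config: dict, seed: int,
                   inputs: list = ()) -> Path:
    """Write a JSON provenance manifest beside an output file."""
    from . import __version__
    payload = dict(
        schema="run-manifest/1",
        package_version=__version__,
        numpy_version=np.__version__,
        seed=seed,
        config=config,
        config_hash=hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        inputs={str(p): _sha256(p) for p in inputs if Path(p).exists()},
    )
    out = Path(str(out_path) + ".manifest.json")
    out.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return out


__all__ = ["read_fasta", "write_fasta", "read_assay_csv",
           "write_scorecard_csv", "read_ogt_corpus_csv", "read_coords_csv",
           "RunConfig", "write_manifest", "Variant"]
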