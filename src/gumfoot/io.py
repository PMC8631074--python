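"""Readers, writers and run configuration for the gumfoot pipeline.

Canonical tabular dialect is TSV (UTF-8, '.' decimal); CSV is accepted on
read. Result files start with comment lines embedding the configuration
hash and seed so that reruns are traceable and byte-identical apart from
log timestamps. Column schemas are documented in ``data/schemas.md``
shipped with the package.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .enrichment import LFQMatrix, SchemaError
from .mechanics import ExtensionSeries, SupportLine, droplet_geometry

__all__ = [
    "PipelineConfig",
    "read_fasta",
    "write_fasta",
    "read_table",
    "read_lfq_table",
    "write_lfq_table",
    "read_measurements",
    "write_measurements",
    "read_ptm_table",
    "read_tpm_table",
    "write_results",
    "SchemaError",
]

_INTERVALS = (0, 20, 40, 60, 80, 100)

MEASUREMENT_COLUMNS = (
    ["droplet_id", "DL", "DW", "flattened_droplet_area", "flattened_core_area",
     "fiber_count", "fiber_diameter", "fiber_modulus", "span"]
    + [f"L_{i}" for i in _INTERVALS]
    + [f"theta_{i}" for i in _INTERVALS]
)

LFQ_COLUMNS = ["protein_id", "sample_id", "sample_type", "run", "lfq", "score"]
PTM_COLUMNS = ["peptide_id", "sample_id", "sample_type",
               "glycosylated", "phosphorylated"]


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and presets for a reproducible pipeline run."""

    seed: int = 0
    species: str = "L_hesperus"
    modulus_window: tuple[float, float] = (0.6, 0.8)
    length_convention: str = "radius"
    score_min: float = 50.0
    fdr_alpha: float = 0.05
    min_ptm_samples: int = 5
    outlier_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.fdr_alpha < 1.0):
            raise ValueError("fdr_alpha must lie in (0, 1)")
        if not (0.0 <= self.outlier_threshold <= 1.0):
            raise ValueError("outlier_threshold must lie in [0, 1]")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "modulus_window" in data:
            data["modulus_window"] = tuple(data["modulus_window"])
        return cls(**data)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs; wrapped lines joined.

    A non-empty file whose first record line is not a ``>`` header raises a
    parse error naming the line.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise SchemaError(
                    f"{path.name}:{lineno}: expected FASTA header, "
                    f"got {line.strip()[:30]!r}"
                )
            break
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=pid, description="") for pid, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# tabular files
# ---------------------------------------------------------------------------


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_table(path: str | Path, required: list[str],
               numeric: list[str] | None = None) -> pd.DataFrame:
    """Read a TSV/CSV, check required columns, validate numeric columns.

    Missing columns raise :class:`SchemaError` naming the column; stray
    text in a numeric column raises with a per-row report (1-based data row
    numbers, as a user would count them in the file).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s): {missing}")
    for col in numeric or []:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & df[col].notna()]
        if len(bad):
            rows = ", ".join(str(i + 1) for i in bad[:10])
            raise SchemaError(
                f"{path.name}: column {col!r} is not numeric in row(s) {rows}"
            )
        df[col] = converted
    return df


def read_lfq_table(path: str | Path) -> LFQMatrix:
    """Load a long-format LFQ TSV into an :class:`LFQMatrix`.

    Required columns: protein_id, sample_id, sample_type, run, lfq, score.
    Optional: ptm_modified (0/1), ptm_score.
    """
    df = read_table(path, required=LFQ_COLUMNS, numeric=["lfq", "score", "run"])
    values = df.pivot_table(index="protein_id", columns="sample_id",
                            values="lfq", aggfunc="first").fillna(0.0)
    samples = (
        df[["sample_id", "sample_type", "run"]]
        .drop_duplicates("sample_id")
        .set_index("sample_id")
    )
    samples["run"] = samples["run"].astype(int)
    scores = df.pivot_table(index="protein_id", columns="run",
                            values="score", aggfunc="max")
    ptm_modified = None
    ptm_scores = None
    if "ptm_modified" in df.columns:
        ptm_modified = (
            df.pivot_table(index="protein_id", columns="sample_id",
                           values="ptm_modified", aggfunc="first")
            .fillna(0)
            .astype(bool)
        )
    if "ptm_score" in df.columns:
        ptm_scores = df.groupby("protein_id")["ptm_score"].max()
    return LFQMatrix(values=values, samples=samples, scores=scores,
                     ptm_modified=ptm_modified, ptm_scores=ptm_scores)


def write_lfq_table(matrix: LFQMatrix, path: str | Path) -> None:
    """Write an :class:`LFQMatrix` in the long-format LFQ dialect."""
    rows = []
    for pid in matrix.proteins:
        for sid in matrix.values.columns:
            run = int(matrix.samples.loc[sid, "run"])
            rows.append({
                "protein_id": pid,
                "sample_id": sid,
                "sample_type": matrix.samples.loc[sid, "sample_type"],
                "run": run,
                "lfq": matrix.values.loc[pid, sid],
                "score": matrix.scores.loc[pid, run],
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_measurements(path: str | Path) -> list[dict]:
    """Load droplet measurement rows into mechanics-ready objects.

    Returns one dict per droplet: ``droplet_id``, ``geometry``, ``line``,
    ``series``.
    """
    numeric = [c for c in MEASUREMENT_COLUMNS if c != "droplet_id"]
    df = read_table(path, required=MEASUREMENT_COLUMNS, numeric=numeric)
    out = []
    for _, row in df.iterrows():
        geom = droplet_geometry(
            row["DL"], row["DW"],
            row["flattened_droplet_area"], row["flattened_core_area"],
        )
        line = SupportLine(
            fiber_count=int(row["fiber_count"]),
            fiber_diameter=row["fiber_diameter"],
            fiber_modulus=row["fiber_modulus"],
            span=row["span"],
        )
        series = ExtensionSeries(
            fractions=tuple(i / 100.0 for i in _INTERVALS),
            lengths=tuple(float(row[f"L_{i}"]) for i in _INTERVALS),
            angles=tuple(float(row[f"theta_{i}"]) for i in _INTERVALS),
        )
        out.append({"droplet_id": row["droplet_id"], "geometry": geom,
                    "line": line, "series": series})
    return out


def write_measurements(rows: list[dict], path: str | Path) -> None:
    """Write droplet measurement rows (inverse of :func:`read_measurements`)."""
    records = []
    for r in rows:
        geom, line, series = r["geometry"], r["line"], r["series"]
        rec = {
            "droplet_id": r["droplet_id"],
            "DL": geom.DL, "DW": geom.DW,
            "flattened_droplet_area": geom.flattened_droplet_area,
            "flattened_core_area": geom.flattened_core_area,
            "fiber_count": line.fiber_count,
            "fiber_diameter": line.fiber_diameter,
            "fiber_modulus": line.fiber_modulus,
            "span": line.span,
        }
        if len(series.fractions) != len(_INTERVALS):
            raise ValueError("measurement files use the six standard intervals")
        for i, j in zip(_INTERVALS, range(len(series.fractions))):
            rec[f"L_{i}"] = series.lengths[j]
            rec[f"theta_{i}"] = series.angles[j]
        records.append(rec)
    pd.DataFrame(records, columns=MEASUREMENT_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_ptm_table(path: str | Path) -> pd.DataFrame:
    df = read_table(path, required=PTM_COLUMNS)
    df["glycosylated"] = df["glycosylated"].astype(bool)
    df["phosphorylated"] = df["phosphorylated"].astype(bool)
    return df


def read_tpm_table(path: str | Path) -> pd.DataFrame:
    """Gland TPM table: transcript_id index, one numeric column per gland."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), comment="#")
    if "transcript_id" not in df.columns:
        raise SchemaError(f"{path.name}: missing required column(s): "
                          f"['transcript_id']")
    return df.set_index("transcript_id")


def write_results(df: pd.DataFrame, path: str | Path, config: PipelineConfig,
                  index: bool = True) -> None:
    """Write a result table with a provenance header (config hash + seed)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config.config_hash()}\n")
        fh.write(f"# seed={config.seed}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.8g")
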