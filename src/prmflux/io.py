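"""Readers and writers for the pipeline's plain-text formats.

The transition report is a Skyline-style CSV at fragment-ion level; its
dialect is defined by :data:`REQUIRED_COLUMNS` (header matched after
case-folding). Designs, LOD/LOQ tables and protein matrices are TSV; run
manifests are JSON. All files are UTF-8 with "." as decimal separator.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .assay_design import ProteinTarget
from .quantify import ProteinQuantMatrix

logger = logging.getLogger("prmflux")

__all__ = [
    "REQUIRED_COLUMNS",
    "ReportData",
    "read_transition_report",
    "write_transition_report",
    "read_design",
    "write_design",
    "read_fasta",
    "read_concentration_map",
    "read_protein_matrix",
    "write_protein_matrix",
    "write_manifest",
    "read_manifest",
]

REQUIRED_COLUMNS = [
    "sample", "condition", "bafa1", "bio_rep", "tech_rep",
    "protein", "peptide", "charge", "fragment", "label", "area",
]
OPTIONAL_COLUMNS = ["concentration_fmol", "interference_flag"]

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f"}


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"not a boolean: {value!r}")


@dataclass
class ReportData:
    """Parsed transition report: typed records plus the embedded design."""

    records: pd.DataFrame
    design: pd.DataFrame
    rejected: list[dict] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def read_transition_report(path: str | Path) -> ReportData:
    """Read and validate a transition-report CSV.

    Headers are matched after case-folding; a missing required column raises
    ``ValueError("missing column: <name>")``. Rows with an unparseable or
    negative area, a bad label or a bad boolean are rejected individually
    and reported (with their file line number) in ``rejected``; counts are
    logged. The per-sample design table (condition, bafa1, bio_rep,
    tech_rep) is extracted from the record columns.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    raw.columns = [c.strip().lower() for c in raw.columns]
    for col in REQUIRED_COLUMNS:
        if col not in raw.columns:
            raise ValueError(f"missing column: {col}")

    rejected: list[dict] = []
    rows = []
    for i, row in enumerate(raw.itertuples(index=False)):
        lineno = i + 2  # header is line 1
        rec = dict(zip(raw.columns, row))
        try:
            area = float(rec["area"])
            if not np.isfinite(area) or area < 0:
                raise ValueError("negative or non-finite area")
            label = rec["label"].strip().lower()
            if label not in ("light", "heavy"):
                raise ValueError(f"bad label {rec['label']!r}")
            parsed = {
                "sample": rec["sample"].strip(),
                "condition": rec["condition"].strip(),
                "bafa1": _parse_bool(rec["bafa1"]),
                "bio_rep": int(rec["bio_rep"]),
                "tech_rep": int(rec["tech_rep"]),
                "protein": rec["protein"].strip(),
                "peptide": rec["peptide"].strip(),
                "charge": int(rec["charge"]),
                "fragment": rec["fragment"].strip(),
                "label": label,
                "area": area,
            }
            if "concentration_fmol" in raw.columns and rec.get("concentration_fmol", "") != "":
                parsed["concentration_fmol"] = float(rec["concentration_fmol"])
            if "interference_flag" in raw.columns and rec.get("interference_flag", "") != "":
                parsed["interference_flag"] = _parse_bool(rec["interference_flag"])
            rows.append(parsed)
        except (ValueError, TypeError) as exc:
            rejected.append({"line": lineno, "reason": str(exc)})
    records = pd.DataFrame(rows)
    if "interference_flag" not in records.columns:
        records["interference_flag"] = False
    dup = records.duplicated(
        subset=["sample", "peptide", "charge", "fragment", "label"]
    )
    if dup.any():
        raise ValueError(
            f"{int(dup.sum())} duplicate (sample, peptide, charge, fragment, label) rows"
        )
    design = (
        records.groupby("sample")[["condition", "bafa1", "bio_rep", "tech_rep"]]
        .first()
        .sort_index()
    )
    logger.info(
        "read %d records from %s (%d rejected rows)", len(records), path, len(rejected)
    )
    if rejected:
        logger.warning("rejected rows: %s", rejected[:10])
    return ReportData(records=records, design=design, rejected=rejected)


def write_transition_report(records: pd.DataFrame, path: str | Path) -> None:
    """Write a transition report in the dialect :func:`read_transition_report` accepts."""
    df = records.copy()
    cols = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in df.columns]
    df = df[cols]
    for col in ("bafa1", "interference_flag"):
        if col in df.columns:
            df[col] = df[col].map(lambda b: "true" if _parse_bool(b) else "false")
    df.to_csv(path, index=False)


def read_design(path: str | Path) -> pd.DataFrame:
    """Read a sample-design TSV (sample, condition, bafa1, bio_rep[, tech_rep])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("sample", "condition", "bafa1", "bio_rep"):
        if col not in df.columns:
            raise ValueError(f"missing column: {col}")
    df["bafa1"] = df["bafa1"].map(_parse_bool)
    df["bio_rep"] = df["bio_rep"].astype(int)
    if "tech_rep" in df.columns:
        df["tech_rep"] = df["tech_rep"].astype(int)
    return df.set_index("sample")


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    out = design.copy()
    out["bafa1"] = out["bafa1"].map(lambda b: "true" if b else "false")
    out.to_csv(path, sep="\t", index_label="sample")


def read_fasta(path: str | Path) -> list[ProteinTarget]:
    """Read protein targets from FASTA.

    UniProt-style headers (``sp|ACC|GENE_ORGANISM``) yield accession and
    gene; otherwise the first header token is the accession. Empty records
    and duplicate accessions raise ``ValueError``.
    """
    from Bio import SeqIO

    targets: list[ProteinTarget] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for record {record.id!r}")
        parts = record.id.split("|")
        if len(parts) >= 3 and parts[0] in ("sp", "tr"):
            accession = parts[1]
            gene = parts[2].split("_")[0]
        else:
            accession = parts[0]
            gene = ""
        if accession in seen:
            raise ValueError(f"duplicate accession {accession}")
        seen.add(accession)
        targets.append(ProteinTarget(accession=accession, gene=gene, sequence=seq))
    if not targets:
        raise ValueError(f"no FASTA records in {path}")
    return targets


def read_concentration_map(path: str | Path) -> dict[str, float]:
    """Read a calibration design TSV mapping sample -> spiked fmol (0 = blank)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    if "sample" not in df.columns or "concentration_fmol" not in df.columns:
        raise ValueError("concentration map needs columns: sample, concentration_fmol")
    out = {}
    for _, row in df.iterrows():
        c = float(row["concentration_fmol"])
        if c < 0:
            raise ValueError(f"negative concentration for sample {row['sample']!r}")
        out[row["sample"].strip()] = c
    return out


def write_protein_matrix(matrix: ProteinQuantMatrix, path: str | Path) -> None:
    """Write a protein matrix as tidy TSV (protein, sample, value, status)."""
    matrix.to_tidy().to_csv(path, sep="\t", index=False, na_rep="NA")


def read_protein_matrix(path: str | Path, design: pd.DataFrame) -> ProteinQuantMatrix:
    """Read a tidy protein TSV back into a :class:`ProteinQuantMatrix`."""
    tidy = pd.read_csv(path, sep="\t", na_values=["NA"])
    for col in ("protein", "sample", "value", "status"):
        if col not in tidy.columns:
            raise ValueError(f"missing column: {col}")
    values = tidy.pivot(index="protein", columns="sample", values="value")
    status = tidy.pivot(index="protein", columns="sample", values="status")
    order = [s for s in design.index if s in values.columns]
    values, status = values[order], status[order]
    return ProteinQuantMatrix(values=values, status=status, design=design.copy())


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    *,
    command: str,
    argv: list[str],
    params: dict,
    seed: int | None,
    inputs: list[str | Path],
    outputs: list[str | Path],
) -> None:
    """Write a JSON run manifest (inputs with checksums, parameters, seed).

    Re-running the recorded ``argv`` (see the ``replay`` CLI command)
    reproduces the outputs bit-identically: every stochastic stage is seeded
    and the seed is part of the manifest.
    """
    from . import __version__

    manifest = {
        "command": command,
        "argv": list(argv),
        "params": params,
        "seed": seed,
        "version": __version__,
        "inputs": [
            {"path": str(p), "sha256": _sha256(Path(p))}
            for p in inputs
            if Path(p).is_file()
        ],
        "outputs": [str(p) for p in outputs],
    }
    Path(path).write_text(json.dumps(manifest, indent=1), encoding="utf-8")


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
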