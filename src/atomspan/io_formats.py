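"""Readers and writers for the plain-text formats the pipeline touches:
FASTA proteins, one-per-line SMILES and reaction SMILES, affinity TSVs,
and JSONL adduct / covalent-record files."""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO

from .chem import AdductSpec
from .covalent import CovalentRecord

__all__ = [
    "ReactionRecord",
    "read_fasta",
    "read_smiles_lines",
    "read_reactions",
    "write_reactions",
    "read_affinity_table",
    "read_jsonl",
    "write_jsonl",
    "read_adducts",
    "read_covalent_records",
    "write_covalent_records",
]


def _open_read(path):
    if path == "-":
        return sys.stdin
    return open(path)


def _open_write(path):
    if path == "-":
        return sys.stdout
    return open(path, "w")


def read_fasta(path) -> list[tuple[str, str]]:
    """FASTA records as (id, uppercased sequence), order preserved."""
    with _open_read(path) as fh:
        # Biopython tolerates leading junk; enforce the header-first rule.
        text = fh.read()
    for line in text.splitlines():
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise ValueError("sequence data before the first FASTA header")
        break
    from io import StringIO

    return [
        (rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(StringIO(text), "fasta")
    ]


def read_smiles_lines(path) -> list[str]:
    """One SMILES per line; blank lines skipped."""
    with _open_read(path) as fh:
        return [line.strip() for line in fh if line.strip()]


@dataclass(frozen=True)
class ReactionRecord:
    """A single-step reaction, serialized 'reactants>reagents>products'."""

    reactants: str
    reagents: str
    product: str

    def to_string(self) -> str:
        return f"{self.reactants}>{self.reagents}>{self.product}"


def read_reactions(path) -> list[ReactionRecord]:
    records = []
    with _open_read(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(">")
            if len(parts) != 3:
                raise ValueError(
                    f"line {lineno}: expected 'reactants>reagents>products', "
                    f"got {line!r}"
                )
            records.append(ReactionRecord(*parts))
    return records


def write_reactions(records, path) -> None:
    with _open_write(path) as fh:
        for r in records:
            fh.write(r.to_string() + "\n")


REQUIRED_AFFINITY_COLUMNS = ("smiles", "sequence", "affinity")


def read_affinity_table(path) -> tuple[list[tuple[str, str, float]], int]:
    """Drug-target affinity TSV with columns (smiles, sequence, affinity).

    Rows whose affinity does not parse as a decimal are dropped; returns
    (records, n_dropped).
    """
    df = pd.read_csv(path if path != "-" else sys.stdin, sep="\t")
    missing = [c for c in REQUIRED_AFFINITY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    values = pd.to_numeric(df["affinity"], errors="coerce")
    keep = values.notna()
    n_dropped = int((~keep).sum())
    records = [
        (str(s), str(q), float(a))
        for s, q, a in zip(df["smiles"][keep], df["sequence"][keep], values[keep])
    ]
    return records, n_dropped


def read_jsonl(path) -> list[dict]:
    with _open_read(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]


def write_jsonl(rows, path) -> None:
    with _open_write(path) as fh:
        for row in rows:
            fh.write(json.dumps(row) + "\n")


def read_adducts(path) -> list[AdductSpec]:
    """Adduct specs from JSONL rows {name, smiles}; each is validated."""
    specs = []
    for row in read_jsonl(path):
        spec = AdductSpec(smiles_with_dummy=row["smiles"], name=row.get("name", ""))
        spec.validate()
        specs.append(spec)
    return specs


def read_covalent_records(path) -> list[CovalentRecord]:
    """Covalent records from JSONL rows
    {protein, ligand_smiles, position, adduct_smiles}."""
    records = []
    for row in read_jsonl(path):
        rec = CovalentRecord(
            protein=row["protein"],
            ligand_smiles=row["ligand_smiles"],
            position=int(row["position"]),
            adduct=AdductSpec(smiles_with_dummy=row["adduct_smiles"],
                              name=row.get("adduct_name", "")),
        )
        rec.validate()
        records.append(rec)
    return records


def write_covalent_records(records, path) -> None:
    rows = [
        {
            "protein": r.protein,
            "ligand_smiles": r.ligand_smiles,
            "position": r.position,
            "adduct_smiles": r.adduct.smiles_with_dummy,
            "adduct_name": r.adduct.name,
        }
        for r in records
    ]
    write_jsonl(rows, path)
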