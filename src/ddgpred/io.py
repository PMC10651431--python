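"""Readers and writers for the formats the framework touches.

Mutation tables are CSV/TSV with a header; each source declares a *dialect*
mapping its column names onto the canonical fields and stating the unit and
sign convention of its ddG column, so that heterogeneous sources are
normalised at the boundary (kcal/mol, positive = destabilizing) instead of
being mixed silently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.PDB import PDBParser
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

from .datamodel import (
    AA_SET,
    HeteroResidue,
    MutationCodeError,
    MutationRecord,
    Residue,
    StructureModel,
    kj_to_kcal,
)

THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}


class TableFormatError(ValueError):
    """A mutation table is missing a mandatory column."""


@dataclass
class DialectConfig:
    """Column mapping + conventions for one tabular source.

    ``ddg_unit`` is ``"kcal/mol"`` or ``"kJ/mol"``; ``ddg_sign`` is
    ``"destabilizing_positive"`` or ``"stabilizing_positive"``.
    """

    columns: dict = field(default_factory=lambda: {
        "pdb_id": "pdb_id", "chain": "chain", "mut_code": "mut_code",
        "ddg": "ddg", "ph": "ph", "temp": "temp",
    })
    ddg_unit: str = "kcal/mol"
    ddg_sign: str = "destabilizing_positive"
    source_name: str = ""
    delimiter: Optional[str] = None  # None = infer from extension

    def __post_init__(self) -> None:
        if self.ddg_unit not in ("kcal/mol", "kJ/mol"):
            raise ValueError(f"unknown ddg unit {self.ddg_unit!r}")
        if self.ddg_sign not in ("destabilizing_positive", "stabilizing_positive"):
            raise ValueError(f"unknown sign convention {self.ddg_sign!r}")

    @classmethod
    def from_file(cls, path) -> "DialectConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def normalize_ddg(self, value: float) -> float:
        if self.ddg_unit == "kJ/mol":
            value = kj_to_kcal(value)
        if self.ddg_sign == "stabilizing_positive":
            value = -value
        return value


@dataclass
class RejectedRow:
    """A table row that failed validation, kept for the curation report."""

    row_index: int
    reason: str
    raw: dict


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    if s == "" or s.lower() in ("na", "nan", "none", "-"):
        return None
    return float(s)


def read_mutation_table(path, dialect: DialectConfig
                        ) -> tuple[list[MutationRecord], list[RejectedRow]]:
    """Read one tabular source into validated records.

    Rows failing validation are returned as :class:`RejectedRow` with a
    reason, never silently dropped.  ddG is normalised to kcal/mol with
    positive = destabilizing according to the dialect.
    """
    path = Path(path)
    sep = dialect.delimiter
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str)

    mandatory = ("pdb_id", "chain", "mut_code", "ddg")
    for key in mandatory:
        col = dialect.columns.get(key, key)
        if col not in df.columns:
            raise TableFormatError(f"missing mandatory column {col!r} in {path}")

    col = {k: dialect.columns.get(k, k) for k in
           ("pdb_id", "chain", "mut_code", "ddg", "ph", "temp")}
    records: list[MutationRecord] = []
    rejected: list[RejectedRow] = []
    for idx, row in df.iterrows():
        raw = row.to_dict()
        try:
            ddg = _opt_float(row[col["ddg"]])
            if ddg is None:
                rejected.append(RejectedRow(idx, "missing target", raw))
                continue
            ph = _opt_float(row[col["ph"]]) if col["ph"] in df.columns else None
            temp = _opt_float(row[col["temp"]]) if col["temp"] in df.columns else None
            rec = MutationRecord(
                pdb_id=str(row[col["pdb_id"]]),
                chain=str(row[col["chain"]]),
                mut_code=str(row[col["mut_code"]]),
                ddg=dialect.normalize_ddg(ddg),
                ph=ph,
                temp=temp,
                source=dialect.source_name or path.name,
            )
        except MutationCodeError as exc:
            reason = ("wild-type equals mutant"
                      if "wild-type equals mutant" in str(exc) else str(exc))
            rejected.append(RejectedRow(idx, reason, raw))
            continue
        except (ValueError, KeyError) as exc:
            rejected.append(RejectedRow(idx, str(exc), raw))
            continue
        records.append(rec)
    return records, rejected


def write_mutation_table(records: Iterable[MutationRecord], path) -> None:
    """Write records as TSV in the canonical dialect (round-trip stable)."""
    rows = [
        {"pdb_id": r.pdb_id, "chain": r.chain, "mut_code": r.mut_code,
         "ddg": r.ddg, "ph": r.ph, "temp": r.temp, "source": r.source}
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


CANONICAL_DIALECT = DialectConfig(delimiter="\t")


# ---------------------------------------------------------------------------
# Variant-pair datasets (model inputs)


def write_variant_pairs(pairs, path) -> None:
    """TSV with wt_seq, mt_seq, 0-based position and the ddG target."""
    from .datamodel import VariantPair  # local import avoids cycle at module load

    rows = [{"wt_seq": p.wt_seq, "mt_seq": p.mt_seq, "position": p.position,
             "ddg": p.ddg} for p in pairs]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_variant_pairs(path) -> list:
    from .datamodel import VariantPair

    df = pd.read_csv(path, sep="\t")
    pairs = []
    for _, row in df.iterrows():
        ddg = None if ("ddg" not in df.columns or pd.isna(row["ddg"])) else float(row["ddg"])
        pairs.append(VariantPair(wt_seq=row["wt_seq"], mt_seq=row["mt_seq"],
                                 position=int(row["position"]), ddg=ddg))
    return pairs


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    """Read sequences keyed by accession (``pdbid_chain`` convention)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# PDB structures


class EmptyStructureError(ValueError):
    """The PDB file contains no ATOM records."""


def read_structure(pdb_path, name: str = "") -> StructureModel:
    """Parse a PDB file into a :class:`StructureModel`.

    First model only; highest-occupancy altloc per atom; polymer residues
    restricted to the 20 canonical amino acids, everything else (HETATM or
    nonstandard residues) kept as hetero-residues.  Hydrogens are excluded —
    all downstream distance rules are heavy-atom rules.
    """
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure(name or Path(pdb_path).stem, str(pdb_path))
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise EmptyStructureError(f"no models in {pdb_path}")

    chains: dict[str, list[Residue]] = {}
    hetero: list[HeteroResidue] = []
    n_atoms = 0
    for chain in model:
        for res in chain:
            hetfield, resnum, icode = res.id
            coords = []
            for atom in res:
                # DisorderedAtom resolves to the highest-occupancy altloc
                if atom.element == "H":
                    continue
                coords.append(tuple(float(c) for c in atom.coord))
            if not coords:
                continue
            n_atoms += len(coords)
            resname = res.get_resname().strip()
            one = THREE_TO_ONE.get(resname)
            if hetfield.strip() == "" and one is not None:
                chains.setdefault(chain.id, []).append(
                    Residue(number=resnum, aa=one, coords=coords,
                            insertion_code=icode.strip()))
            elif resname != "HOH":
                hetero.append(HeteroResidue(ligand_code=resname, chain=chain.id,
                                            number=resnum, coords=coords))
    if n_atoms == 0:
        raise EmptyStructureError(f"no ATOM records in {pdb_path}")
    chains = {c: residues for c, residues in chains.items() if residues}
    return StructureModel(chains=chains, hetero=hetero,
                          name=name or Path(pdb_path).stem)
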