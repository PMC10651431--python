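"""Domain types for single-point stability measurements.

The unit of experimental information is one measurement of the free-energy
change of unfolding caused by a single amino-acid substitution, keyed by
(PDB ID, chain, mutation code).  The unit of model input is a pair of
full-length sequences differing at exactly one position.

Conventions fixed here and used everywhere else in the package:

* ddG is stored in kcal/mol, with positive values destabilizing.
* Mutation-code positions are in the *source* (PDB) numbering; the mapping
  to a 0-based sequence index happens exactly once, when a
  :class:`VariantPair` is built, through an explicit offset.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Optional

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AA_ALPHABET)

#: 1 kcal = 4.184 kJ (thermochemical calorie)
KJ_PER_KCAL = 4.184

_MUT_CODE_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


class MutationCodeError(ValueError):
    """Raised for a mutation code that cannot be parsed or validated."""


class ResidueMismatchError(ValueError):
    """Raised when the wild-type residue named by a mutation does not match
    the sequence at the resolved position (guards PDB-numbering drift)."""


def kj_to_kcal(x: float) -> float:
    return x / KJ_PER_KCAL


def kcal_to_kj(x: float) -> float:
    return x * KJ_PER_KCAL


def parse_mutation_code(code: str) -> tuple[str, int, str]:
    """Parse a compact mutation code like ``"A123G"``.

    Returns ``(wt_aa, position, mt_aa)`` with the position as an integer in
    the source's own numbering.  Raises :class:`MutationCodeError` for
    malformed codes, non-canonical residues, positions < 1, or silent
    (wt == mt) substitutions.
    """
    m = _MUT_CODE_RE.match(code.strip())
    if m is None:
        raise MutationCodeError(f"malformed mutation code: {code!r}")
    wt, pos_s, mt = m.group(1).upper(), m.group(2), m.group(3).upper()
    if wt not in AA_SET:
        raise MutationCodeError(f"unknown wild-type residue {wt!r} in {code!r}")
    if mt not in AA_SET:
        raise MutationCodeError(f"unknown mutant residue {mt!r} in {code!r}")
    pos = int(pos_s)
    if pos < 1:
        raise MutationCodeError(f"position must be >= 1 in {code!r}")
    if wt == mt:
        raise MutationCodeError(f"wild-type equals mutant in {code!r}")
    return wt, pos, mt


@dataclass(frozen=True, order=True)
class RecordID:
    """Aggregation key: PDB ID + chain + mutation code."""

    pdb_id: str
    chain: str
    mut_code: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.pdb_id}_{self.chain}_{self.mut_code}"


@dataclass
class MutationRecord:
    """One experimental ddG measurement.

    ``ddg`` is in kcal/mol, positive = destabilizing (normalised on read).
    ``ph``/``temp`` may be None when the source did not report conditions.
    """

    pdb_id: str
    chain: str
    mut_code: str
    ddg: float
    ph: Optional[float] = None
    temp: Optional[float] = None
    source: str = ""

    def __post_init__(self) -> None:
        self.pdb_id = self.pdb_id.strip().upper()
        self.chain = self.chain.strip()
        self.mut_code = self.mut_code.strip().upper()
        if len(self.pdb_id) != 4:
            raise ValueError(f"PDB ID must be 4 characters: {self.pdb_id!r}")
        if len(self.chain) != 1:
            raise ValueError(f"chain must be a single character: {self.chain!r}")
        parse_mutation_code(self.mut_code)  # validates residues/position
        if not math.isfinite(self.ddg):
            raise ValueError("ddg must be finite")

    @property
    def record_id(self) -> RecordID:
        return RecordID(self.pdb_id, self.chain, self.mut_code)

    @property
    def wt_aa(self) -> str:
        return parse_mutation_code(self.mut_code)[0]

    @property
    def position(self) -> int:
        return parse_mutation_code(self.mut_code)[1]

    @property
    def mt_aa(self) -> str:
        return parse_mutation_code(self.mut_code)[2]

    def has_conditions(self) -> bool:
        """True when pH *and* temperature are both reported."""
        return self.ph is not None and self.temp is not None


@dataclass
class VariantPair:
    """Wild-type / mutant sequence pair, the unit of model input.

    ``position`` is the 0-based index of the single differing residue.
    """

    wt_seq: str
    mt_seq: str
    position: int
    ddg: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.wt_seq) != len(self.mt_seq):
            raise ValueError("wild-type and mutant sequences differ in length")
        diffs = [i for i, (a, b) in enumerate(zip(self.wt_seq, self.mt_seq)) if a != b]
        if diffs != [self.position]:
            raise ValueError(
                f"sequences must differ exactly at position {self.position}, "
                f"found differences at {diffs}"
            )

    def reversed(self) -> "VariantPair":
        """The reverse mutation: swap sequences, negate the target."""
        return VariantPair(
            wt_seq=self.mt_seq,
            mt_seq=self.wt_seq,
            position=self.position,
            ddg=None if self.ddg is None else -self.ddg,
        )


def apply_mutation(wt_seq: str, wt_aa: str, seq_position: int, mt_aa: str,
                   ddg: Optional[float] = None) -> VariantPair:
    """Substitute ``mt_aa`` at a 0-based sequence index, checking the
    wild-type residue actually found there.

    A mismatch raises :class:`ResidueMismatchError` naming expected vs found
    residue; it is never auto-corrected, because a silent off-by-one between
    PDB numbering and sequence index would corrupt every downstream example.
    """
    if not 0 <= seq_position < len(wt_seq):
        raise IndexError(f"position {seq_position} outside sequence of length {len(wt_seq)}")
    found = wt_seq[seq_position]
    if found != wt_aa:
        raise ResidueMismatchError(
            f"expected {wt_aa} at index {seq_position}, found {found}"
        )
    if mt_aa not in AA_SET:
        raise MutationCodeError(f"unknown mutant residue {mt_aa!r}")
    if mt_aa == wt_aa:
        raise MutationCodeError("wild-type equals mutant")
    mt_seq = wt_seq[:seq_position] + mt_aa + wt_seq[seq_position + 1:]
    return VariantPair(wt_seq=wt_seq, mt_seq=mt_seq, position=seq_position, ddg=ddg)


# ---------------------------------------------------------------------------
# Structures


@dataclass
class Residue:
    """One polymer residue: number (verbatim from the file), 1-letter type,
    heavy-atom coordinates in Angstrom as an (n_atoms, 3) list."""

    number: int
    aa: str
    coords: list = field(default_factory=list)  # list of (x, y, z)
    insertion_code: str = ""


@dataclass
class HeteroResidue:
    """Non-polymer residue (ligand, cofactor, modified residue)."""

    ligand_code: str
    chain: str
    number: int
    coords: list = field(default_factory=list)


@dataclass
class StructureModel:
    """Per-chain ordered polymer residues plus hetero-residues.

    Only the first model of a multi-model file is represented; altloc
    duplicates are resolved to the highest-occupancy conformer at parse time.
    """

    chains: dict  # chain id -> list[Residue]
    hetero: list  # list[HeteroResidue]
    name: str = ""

    def chain_sequence(self, chain: str) -> str:
        return "".join(r.aa for r in self.chains[chain])
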