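"""Deterministic generators of synthetic inputs.

Real stability compilations mix duplicate measurements at divergent pH/T,
conflicting signs, and high-variance groups.  These generators emulate that
heterogeneity *with a known answer*: every emitted record comes with a
manifest stating which curation step should keep or drop it and what the
averaged ddG must be, so curation tests are exact rather than statistical.
Everything is a pure function of its spec and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import AA_ALPHABET, MutationRecord, VariantPair, kj_to_kcal
from .embedding import MockBackbone

SCENARIOS = ("single_core", "multi_avg", "window_reject", "sign_conflict",
             "high_variance", "group2_unique", "group2_dup")


@dataclass
class FixtureSpec:
    n_proteins: int = 8
    seq_len_range: tuple = (30, 50)
    ids_per_protein: int = 6
    frac_missing_conditions: float = 0.15
    frac_sign_conflict: float = 0.10
    frac_high_variance: float = 0.10
    n_tables: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.frac_missing_conditions, self.frac_sign_conflict,
                 self.frac_high_variance)
        if any(not 0 <= f <= 1 for f in fracs) or sum(fracs) > 1:
            raise ValueError("scenario fractions must lie in [0,1] and sum to <= 1")
        if self.n_proteins < 1 or self.ids_per_protein < 1:
            raise ValueError("need at least one protein and one ID")
        if not 2 <= self.n_tables <= 3:
            raise ValueError("emit 2 or 3 overlapping source tables")

    @property
    def n_ids(self) -> int:
        return self.n_proteins * self.ids_per_protein


@dataclass
class MutationFixture:
    """Generated tables plus the by-construction expected curation outcome."""

    tables: list  # list of DataFrame, canonical dialect columns
    sequences: dict  # accession -> sequence
    manifest: dict  # str(RecordID) -> expectation dict
    spec: FixtureSpec

    def all_records(self) -> list[MutationRecord]:
        recs = []
        for i, df in enumerate(self.tables):
            for _, row in df.iterrows():
                recs.append(MutationRecord(
                    pdb_id=row.pdb_id, chain=row.chain, mut_code=row.mut_code,
                    ddg=float(row.ddg),
                    ph=None if pd.isna(row.ph) else float(row.ph),
                    temp=None if pd.isna(row.temp) else float(row.temp),
                    source=f"table{i}"))
        return recs

    def write(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for i, df in enumerate(self.tables):
            df.to_csv(out_dir / f"source{i}.csv", index=False)
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=1)
        from .io import write_fasta
        write_fasta(self.sequences, out_dir / "sequences.fasta")


def _random_sequence(rng, length: int) -> str:
    return "".join(rng.choice(list(AA_ALPHABET), size=length))

def _pdb_id(i: int) -> str:
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    return f"1{letters[i // 26 % 26]}{letters[i % 26]}{i % 10}"


def make_mutation_tables(spec: FixtureSpec) -> MutationFixture:
    """Emit overlapping source tables whose curation outcome is known.

    Scenario counts are exact (rounded from the FixtureSpec fractions): e.g. a
    50-ID spec with 10% sign conflicts marks exactly 5 IDs for the
    opposite-sign drop.  Values are in kcal/mol, destabilizing positive.
    """
    rng = np.random.default_rng(spec.seed)
    sequences: dict[str, str] = {}
    proteins = []
    for p in range(spec.n_proteins):
        pdb = _pdb_id(p)
        length = int(rng.integers(spec.seq_len_range[0], spec.seq_len_range[1] + 1))
        seq = _random_sequence(rng, length)
        sequences[f"{pdb}_A"] = seq
        proteins.append((pdb, seq))

    n = spec.n_ids
    n_conflict = round(spec.frac_sign_conflict * n)
    n_highvar = round(spec.frac_high_variance * n)
    n_missing = round(spec.frac_missing_conditions * n)
    scenario_pool = (["sign_conflict"] * n_conflict + ["high_variance"] * n_highvar)
    # half of the missing-condition IDs are unique to Group II, half duplicated
    scenario_pool += ["group2_unique"] * (n_missing - n_missing // 2)
    scenario_pool += ["group2_dup"] * (n_missing // 2)
    rest = n - len(scenario_pool)
    for i in range(rest):
        scenario_pool.append(["single_core", "multi_avg", "window_reject"][i % 3])
    rng.shuffle(scenario_pool)

    rows: list[dict] = []
    manifest: dict[str, dict] = {}
    used_positions: dict[str, set] = {}
    for i, scenario in enumerate(scenario_pool):
        pdb, seq = proteins[i % spec.n_proteins]
        taken = used_positions.setdefault(pdb, set())
        pos = int(rng.integers(1, len(seq) + 1))
        while pos in taken:
            pos = int(rng.integers(1, len(seq) + 1))
        taken.add(pos)
        wt = seq[pos - 1]
        mt = rng.choice([a for a in AA_ALPHABET if a != wt])
        code = f"{wt}{pos}{mt}"
        rid = f"{pdb}_A_{code}"
        base = float(np.round(rng.normal(1.0, 1.2), 3))
        if base == 0.0:
            base = 0.5
        entry = {"scenario": scenario, "expected": "kept", "reason": None,
                 "expected_mean": None, "n_members_selected": None}

        def add(ddg, ph, temp):
            rows.append(dict(pdb_id=pdb, chain="A", mut_code=code,
                             ddg=float(np.round(ddg, 4)), ph=ph, temp=temp))

        if scenario == "single_core":
            add(base, 7.0, 25.0)
            entry.update(expected_mean=round(base, 4), n_members_selected=1)
        elif scenario == "multi_avg":
            sign = 1.0 if base >= 0 else -1.0
            members = [sign * (abs(base) + 0.05 * j) for j in range(3)]
            add(members[0], 7.0, 25.0)
            add(members[1], 7.3, 30.0)
            add(members[2], 6.6, 20.0)
            entry.update(expected_mean=round(float(np.mean(np.round(members, 4))), 6),
                         n_members_selected=3)
        elif scenario == "window_reject":
            add(base, 7.0, 25.0)
            add(base + 0.3, 7.8, 25.0)  # outside the +/-0.5 pH window
            entry.update(expected_mean=round(base, 4), n_members_selected=1)
        elif scenario == "sign_conflict":
            v = abs(base) + 0.2
            add(v, 7.0, 25.0)
            add(-v / 2, 7.2, 28.0)
            entry.update(expected="dropped", reason="opposite signs")
        elif scenario == "high_variance":
            # two same-sign members 4 kJ/mol apart: sample variance 8 > 5
            lo = abs(base) + kj_to_kcal(1.0)
            add(lo, 7.0, 25.0)
            add(lo + kj_to_kcal(4.0), 6.8, 22.0)
            entry.update(expected="dropped", reason="variance")
        elif scenario == "group2_unique":
            # one of pH/T present still counts as conditions unavailable
            if i % 2 == 0:
                add(base, None, None)
            else:
                add(base, 7.0, None)
            entry.update(expected_mean=round(base, 4), n_members_selected=1)
        elif scenario == "group2_dup":
            add(base, 7.0, 25.0)
            add(base + 5.0, None, None)  # dropped: ID already in Group I
            entry.update(expected_mean=round(base, 4), n_members_selected=1)
        manifest[rid] = entry

    # deal rows round-robin into overlapping source tables
    tables = [[] for _ in range(spec.n_tables)]
    for j, row in enumerate(rows):
        tables[j % spec.n_tables].append(row)
    dfs = [pd.DataFrame(t, columns=["pdb_id", "chain", "mut_code", "ddg", "ph", "temp"])
           for t in tables]
    return MutationFixture(tables=dfs, sequences=sequences, manifest=manifest,
                           spec=spec)


# ---------------------------------------------------------------------------
# Toy structures


@dataclass
class ToyStructure:
    name: str
    pdb_text: str
    expected_interface: set = field(default_factory=set)  # (chain, resnum)
    expected_ligand_contacts: set = field(default_factory=set)
    expected_fraction: dict = field(default_factory=dict)  # chain -> fraction

    def write(self, out_dir) -> Path:
        path = Path(out_dir) / f"{self.name}.pdb"
        path.write_text(self.pdb_text)
        return path


def _atom_line(serial: int, name: str, resname: str, chain: str, resnum: int,
               xyz, hetero: bool = False, element: str = "C") -> str:
    record = "HETATM" if hetero else "ATOM  "
    return (f"{record}{serial:5d} {name:^4s}{resname:>4s} {chain}{resnum:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
            f"          {element:>2s}")


def make_toy_structures(n_residues: int = 10, n_contacts: int = 4,
                        contact_distance: float = 4.4,
                        far_distance: float = 20.0,
                        plant_ligand: bool = True) -> dict[str, ToyStructure]:
    """Small idealized structures with contacts planted at controlled
    separations (Calpha-only residues on a 6 A grid, so only the planted
    cross-chain distances fall near the cutoff).

    Returns a ``dimer`` (the first ``n_contacts`` chain-A residues at
    ``contact_distance`` from their chain-B partner, the rest far), a
    ``monomer``, a ``boundary`` dimer with closest approaches at exactly 4.4
    and 4.6 A, and optionally a ``liganded`` monomer with a HEM iron 3 A
    from residue 1.
    """
    if not 0 <= n_contacts <= n_residues:
        raise ValueError("n_contacts must be within the chain")
    out: dict[str, ToyStructure] = {}

    # dimer ---------------------------------------------------------------
    lines, serial = [], 1
    interface = set()
    for i in range(n_residues):
        lines.append(_atom_line(serial, "CA", "ALA", "A", i + 1, (6.0 * i, 0.0, 0.0)))
        serial += 1
    for i in range(n_residues):
        d = contact_distance if i < n_contacts else far_distance
        lines.append(_atom_line(serial, "CA", "ALA", "B", i + 1, (6.0 * i, d, 0.0)))
        serial += 1
        if d <= 4.5:
            interface.add(("A", i + 1))
            interface.add(("B", i + 1))
    frac = {"A": n_contacts / n_residues, "B": n_contacts / n_residues}
    out["dimer"] = ToyStructure("dimer", "\n".join(lines + ["END", ""]),
                                expected_interface=interface,
                                expected_fraction=frac)

    # monomer -------------------------------------------------------------
    lines = [_atom_line(i + 1, "CA", "GLY", "A", i + 1, (6.0 * i, 0.0, 0.0))
             for i in range(n_residues)]
    out["monomer"] = ToyStructure("monomer", "\n".join(lines + ["END", ""]),
                                  expected_fraction={"A": 0.0})

    # boundary dimer: 4.4 A (inside) and 4.6 A (outside) ------------------
    lines = [
        _atom_line(1, "CA", "ALA", "A", 1, (0.0, 0.0, 0.0)),
        _atom_line(2, "CA", "ALA", "A", 2, (6.0, 0.0, 0.0)),
        _atom_line(3, "CA", "ALA", "B", 1, (0.0, 4.4, 0.0)),
        _atom_line(4, "CA", "ALA", "B", 2, (6.0, 4.6, 0.0)),
    ]
    out["boundary"] = ToyStructure(
        "boundary", "\n".join(lines + ["END", ""]),
        expected_interface={("A", 1), ("B", 1)},
        expected_fraction={"A": 0.5, "B": 0.5})

    # liganded monomer ----------------------------------------------------
    if plant_ligand:
        lines = [_atom_line(i + 1, "CA", "ALA", "A", i + 1, (6.0 * i, 0.0, 0.0))
                 for i in range(n_residues)]
        lines.append(_atom_line(n_residues + 1, "FE", "HEM", "A", 900,
                                (0.0, 3.0, 0.0), hetero=True, element="FE"))
        out["liganded"] = ToyStructure(
            "liganded", "\n".join(lines + ["END", ""]),
            expected_ligand_contacts={("A", 1)},
            expected_fraction={"A": 0.0})
    return out


# ---------------------------------------------------------------------------
# Recoverable training dataset


def make_recoverable_dataset(backbone: MockBackbone, n: int, seed: int,
                             noise_sd: float = 0.0, seq_length: int = 30
                             ) -> tuple[list[VariantPair], np.ndarray]:
    """Variant pairs whose targets are an exact linear antisymmetric
    function of the mutation-row embedding difference.

    target = beta . (row_WT - row_MT) + noise, with the rows taken from the
    backbone's *raw* (pre-projection) embedding, so the generating
    coefficients are recoverable by least squares on those features.
    Returns (pairs, beta).
    """
    rng = np.random.default_rng(seed)
    beta = rng.standard_normal(backbone.width)
    pairs = []
    for _ in range(n):
        seq = _random_sequence(rng, seq_length)
        pos = int(rng.integers(0, seq_length))
        wt = seq[pos]
        mt = rng.choice([a for a in AA_ALPHABET if a != wt])
        mt_seq = seq[:pos] + mt + seq[pos + 1:]
        diff = (backbone.raw_embed(seq)[pos + 1]
                - backbone.raw_embed(mt_seq)[pos + 1])
        target = float(beta @ diff)
        if noise_sd > 0:
            target += float(rng.normal(0.0, noise_sd))
        pairs.append(VariantPair(wt_seq=seq, mt_seq=mt_seq, position=pos,
                                 ddg=target))
    return pairs, beta


# ---------------------------------------------------------------------------
# Synthetic DSSP-format output


def make_dssp_text(assignments: dict[tuple[str, int], tuple[str, float, str]]) -> str:
    """Synthetic text in classic DSSP layout (header + fixed columns) for
    testing the DSSP reader without running the external tool.

    ``assignments`` maps (chain, resnum) -> (one-letter aa, ASA, 8-state SS).
    """
    lines = [
        "==== Secondary Structure Definition by the program DSSP (synthetic fixture) ====",
        "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N    N-H-->O    O-->H-N    TCO  KAPPA ALPHA  PHI   PSI    X-CA   Y-CA   Z-CA",
    ]
    for i, ((chain, resnum), (aa, acc, ss8)) in enumerate(sorted(assignments.items())):
        line = list(" " * 120)
        line[0:5] = f"{i + 1:5d}"
        line[5:10] = f"{resnum:5d}"
        line[11] = chain
        line[13] = aa
        line[16] = ss8 if ss8.strip() else " "
        line[34:38] = f"{int(round(acc)):4d}"
        lines.append("".join(line))
    return "\n".join(lines) + "\n"
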