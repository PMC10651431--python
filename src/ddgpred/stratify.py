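"""Structure-derived stratification of predictions.

Where a mutation sits in the fold changes how hard its stability effect is
to predict: buried residues are constrained by packing, interface residues
feel neighbouring subunits the sequence alone cannot see, and cofactor-site
residues feel the ligand.  This module derives those labels from a parsed
structure (interface and ligand contacts by heavy-atom distance) and from
DSSP output (relative accessible surface area and secondary structure), and
slices the evaluation metrics by stratum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .datamodel import StructureModel
from .evaluation import metrics

#: Theoretical maximum accessible surface area per residue type (A^2),
#: Tien et al. 2013 values; relative ASA = ASA / max, clipped to [0, 1].
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

#: 8-state DSSP -> 3-class collapse.
SS8_TO_SS3 = {
    "H": "helix", "G": "helix", "I": "helix",
    "E": "strand", "B": "strand",
}


@dataclass
class ContactConfig:
    cutoff: float = 4.5  # A, heavy-atom minimum distance
    interface_fraction_threshold: float = 0.30  # strict >
    burial_threshold: float = 0.25  # relative ASA below this = buried
    ligand_codes: tuple = ("HEM", "HEC", "BLA")

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if not 0 < self.interface_fraction_threshold < 1:
            raise ValueError("interface fraction threshold must be in (0, 1)")


@dataclass
class ResidueAnnotation:
    chain: str
    number: int
    rel_asa: float = float("nan")
    ss3: str = "unknown"
    interface: bool = False
    ligand_contact: bool = False
    known: bool = True  # False when DSSP had no entry for this residue

    def __post_init__(self) -> None:
        if self.known and not (np.isnan(self.rel_asa) or 0.0 <= self.rel_asa <= 1.0):
            raise ValueError("relative ASA must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Distance rules


def _chain_atoms(structure: StructureModel, chain: str) -> tuple[np.ndarray, np.ndarray]:
    """All heavy atoms of a chain as (coords, residue-index-within-chain)."""
    coords, owner = [], []
    for i, res in enumerate(structure.chains[chain]):
        for xyz in res.coords:
            coords.append(xyz)
            owner.append(i)
    return np.asarray(coords, dtype=float), np.asarray(owner, dtype=int)


def interchain_contacts(structure: StructureModel, cutoff: float = 4.5
                        ) -> set[tuple[str, int]]:
    """Residues with any heavy atom within ``cutoff`` of any heavy atom of a
    *different* chain, as (chain, residue number) pairs."""
    chains = list(structure.chains)
    flagged: set[tuple[str, int]] = set()
    atoms = {c: _chain_atoms(structure, c) for c in chains}
    trees = {c: cKDTree(xyz) for c, (xyz, _) in atoms.items() if len(xyz)}
    for i, ca in enumerate(chains):
        xyz_a, owner_a = atoms[ca]
        if len(xyz_a) == 0:
            continue
        for cb in chains[i + 1:]:
            xyz_b, owner_b = atoms[cb]
            if len(xyz_b) == 0:
                continue
            pairs = trees[ca].query_ball_tree(trees[cb], r=cutoff)
            for ia, near_b in enumerate(pairs):
                if near_b:
                    flagged.add((ca, structure.chains[ca][owner_a[ia]].number))
                    for ib in near_b:
                        flagged.add((cb, structure.chains[cb][owner_b[ib]].number))
    return flagged


def interface_fraction(structure: StructureModel, chain: str,
                       cutoff: float = 4.5) -> float:
    """Fraction of the chain's residues flagged as inter-chain contacts."""
    if chain not in structure.chains or not structure.chains[chain]:
        raise ValueError(f"chain {chain!r} is empty or absent")
    flagged = interchain_contacts(structure, cutoff)
    residues = structure.chains[chain]
    n_flagged = sum(1 for r in residues if (chain, r.number) in flagged)
    return n_flagged / len(residues)


def ligand_contacts(structure: StructureModel, ligand_codes=("HEM", "HEC", "BLA"),
                    cutoff: float = 4.5) -> set[tuple[str, int]]:
    """Residues with any heavy atom within ``cutoff`` of any atom of a
    hetero-residue whose code is in ``ligand_codes``."""
    if cutoff <= 0:
        return set()
    lig_coords = [xyz for het in structure.hetero
                  if het.ligand_code in set(ligand_codes) for xyz in het.coords]
    if not lig_coords:
        return set()
    tree = cKDTree(np.asarray(lig_coords, dtype=float))
    flagged: set[tuple[str, int]] = set()
    for chain, residues in structure.chains.items():
        for res in residues:
            if not res.coords:
                continue
            d, _ = tree.query(np.asarray(res.coords, dtype=float), k=1)
            if np.min(d) <= cutoff:
                flagged.add((chain, res.number))
    return flagged


# ---------------------------------------------------------------------------
# DSSP-derived burial and secondary structure


def parse_dssp(text: str) -> dict[tuple[str, int], tuple[float, str]]:
    """Parse classic DSSP output into (chain, resnum) -> (ASA, 8-state SS).

    Only the fixed columns used here are read: residue number, chain,
    one-letter structure code, and the ACC (solvent accessibility) field.
    """
    out: dict[tuple[str, int], tuple[float, str]] = {}
    in_body = False
    for line in text.splitlines():
        if not in_body:
            if line.lstrip().startswith("#  RESIDUE"):
                in_body = True
            continue
        if len(line) < 38 or line[13] == "!":
            continue
        try:
            resnum = int(line[5:10])
        except ValueError:
            continue
        chain = line[11]
        ss = line[16]
        acc = float(line[34:38])
        out[(chain, resnum)] = (acc, ss)
    return out


def annotate_burial_ss(structure: StructureModel, dssp_text: str,
                       config: ContactConfig | None = None
                       ) -> tuple[list[ResidueAnnotation], int]:
    """Relative ASA and 3-class secondary structure for every polymer
    residue; residues missing from the DSSP output are annotated unknown.
    Returns (annotations, number unknown)."""
    config = config or ContactConfig()
    dssp = parse_dssp(dssp_text)
    interface = interchain_contacts(structure, config.cutoff)
    lig = ligand_contacts(structure, config.ligand_codes, config.cutoff)
    annotations = []
    n_unknown = 0
    for chain, residues in structure.chains.items():
        for res in residues:
            key = (chain, res.number)
            ann = ResidueAnnotation(chain=chain, number=res.number,
                                    interface=key in interface,
                                    ligand_contact=key in lig)
            entry = dssp.get(key)
            if entry is None:
                ann.known = False
                n_unknown += 1
            else:
                acc, ss8 = entry
                max_asa = MAX_ASA.get(res.aa)
                ann.rel_asa = min(acc / max_asa, 1.0) if max_asa else float("nan")
                ann.ss3 = SS8_TO_SS3.get(ss8, "coil")
            annotations.append(ann)
    return annotations, n_unknown


# ---------------------------------------------------------------------------
# Stratified metrics


@dataclass
class StratumResult:
    n: int
    r: float = float("nan")
    rmse: float = float("nan")
    mae: float = float("nan")
    insufficient: bool = False

    def to_dict(self) -> dict:
        return dict(n=self.n, r=self.r, rmse=self.rmse, mae=self.mae,
                    insufficient=self.insufficient)


def _stratum_labels(ann: ResidueAnnotation, config: ContactConfig) -> list[str]:
    if not ann.known:
        return ["unknown"]
    labels = ["buried" if ann.rel_asa < config.burial_threshold else "exposed",
              ann.ss3,
              "interface" if ann.interface else "non-interface",
              "ligand-contact" if ann.ligand_contact else "non-ligand-contact"]
    return labels


def stratified_metrics(predictions, targets,
                       annotations: list[ResidueAnnotation | None],
                       config: ContactConfig | None = None
                       ) -> dict[str, StratumResult]:
    """Evaluation metrics within each structural stratum.

    ``annotations[i]`` labels mutation i (None = unannotated, pooled with
    ``unknown``).  Strata with fewer than two points are reported as
    insufficient rather than crashing or silently vanishing.
    """
    config = config or ContactConfig()
    predictions = np.asarray(predictions, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if len(predictions) != len(annotations) or len(targets) != len(annotations):
        raise ValueError("predictions, targets and annotations must align")
    buckets: dict[str, list[int]] = {}
    for i, ann in enumerate(annotations):
        labels = ["unknown"] if ann is None else _stratum_labels(ann, config)
        for lab in labels:
            buckets.setdefault(lab, []).append(i)
    out: dict[str, StratumResult] = {}
    for label, idx in sorted(buckets.items()):
        if len(idx) < 2:
            out[label] = StratumResult(n=len(idx), insufficient=True)
            continue
        r, rmse, mae = metrics(predictions[idx], targets[idx])
        out[label] = StratumResult(n=len(idx), r=r, rmse=rmse, mae=mae)
    return out
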