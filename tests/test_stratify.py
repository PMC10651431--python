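"""Contact detection against a brute-force all-pairs oracle, burial and
secondary-structure annotation, and per-stratum metrics."""

import math

import numpy as np
import pytest

from ddgpred.fixtures import make_dssp_text, make_toy_structures
from ddgpred.io import read_structure
from ddgpred.stratify import (
    MAX_ASA,
    ContactConfig,
    ResidueAnnotation,
    annotate_burial_ss,
    interchain_contacts,
    interface_fraction,
    ligand_contacts,
    parse_dssp,
    stratified_metrics,
)


def brute_force_interchain(structure, cutoff):
    """O(n^2) atom-pair scan, no spatial indexing."""
    flagged = set()
    chains = list(structure.chains)
    for ca in chains:
        for ra in structure.chains[ca]:
            hit = False
            for cb in chains:
                if cb == ca:
                    continue
                for rb in structure.chains[cb]:
                    for xa in ra.coords:
                        for xb in rb.coords:
                            d = math.dist(xa, xb)
                            if d <= cutoff:
                                hit = True
            if hit:
                flagged.add((ca, ra.number))
    return flagged


def brute_force_ligand(structure, codes, cutoff):
    flagged = set()
    for chain, residues in structure.chains.items():
        for res in residues:
            for het in structure.hetero:
                if het.ligand_code not in codes:
                    continue
                for xa in res.coords:
                    for xb in het.coords:
                        if math.dist(xa, xb) <= cutoff:
                            flagged.add((chain, res.number))
    return flagged


class TestContacts:
    @pytest.mark.parametrize("name", ["dimer", "monomer", "boundary", "liganded"])
    def test_matches_brute_force_and_expectation(self, name, toy_structure_files):
        path, toy = toy_structure_files[name]
        s = read_structure(path)
        got = interchain_contacts(s, 4.5)
        assert got == brute_force_interchain(s, 4.5)
        assert got == toy.expected_interface

    def test_boundary_distances(self, toy_structure_files):
        """Closest approaches at 4.4 A flag both partners; 4.6 A flags none."""
        path, _ = toy_structure_files["boundary"]
        s = read_structure(path)
        got = interchain_contacts(s, 4.5)
        assert ("A", 1) in got and ("B", 1) in got
        assert ("A", 2) not in got and ("B", 2) not in got

    def test_symmetry_of_flags(self, toy_structure_files):
        path, _ = toy_structure_files["dimer"]
        s = read_structure(path)
        got = interchain_contacts(s, 4.5)
        chains_flagged = {c for c, _ in got}
        assert chains_flagged in (set(), {"A", "B"})

    def test_fraction_monotone_in_cutoff(self, toy_structure_files):
        path, _ = toy_structure_files["dimer"]
        s = read_structure(path)
        fracs = [interface_fraction(s, "A", c) for c in (3.0, 4.5, 7.0, 25.0)]
        assert fracs == sorted(fracs)

    def test_fraction_values_and_strict_rule(self, toy_structure_files):
        path, toy = toy_structure_files["dimer"]
        s = read_structure(path)
        assert interface_fraction(s, "A", 4.5) == pytest.approx(0.40)
        three_of_ten = make_toy_structures(n_residues=10, n_contacts=3)["dimer"]
        s2 = read_structure(three_of_ten.write(path.parent))
        frac = interface_fraction(s2, "A", 4.5)
        assert frac == pytest.approx(0.30)
        assert not frac > 0.30  # boundary: "over 30%" excludes exactly 30%

    def test_single_chain_empty(self, toy_structure_files):
        path, _ = toy_structure_files["monomer"]
        s = read_structure(path)
        assert interchain_contacts(s, 4.5) == set()
        with pytest.raises(ValueError):
            interface_fraction(s, "Z", 4.5)

    def test_ligand_contacts(self, toy_structure_files):
        path, toy = toy_structure_files["liganded"]
        s = read_structure(path)
        got = ligand_contacts(s, ("HEM", "HEC", "BLA"), 4.5)
        assert got == toy.expected_ligand_contacts
        assert got == brute_force_ligand(s, {"HEM", "HEC", "BLA"}, 4.5)
        assert ligand_contacts(s, ("HEM",), 0.0) == set()

    def test_no_matching_ligand(self, toy_structure_files):
        path, _ = toy_structure_files["dimer"]
        s = read_structure(path)
        assert ligand_contacts(s) == set()

    def test_random_structures_match_oracle(self, tmp_path):
        """Randomly placed 2-chain structures up to 50 residues."""
        rng = np.random.default_rng(13)
        from ddgpred.datamodel import Residue, StructureModel
        for trial in range(5):
            chains = {}
            for cid, n in (("A", 25), ("B", 25)):
                chains[cid] = [
                    Residue(number=i + 1, aa="A",
                            coords=[tuple(rng.uniform(0, 25, 3))
                                    for _ in range(rng.integers(1, 4))])
                    for i in range(n)]
            s = StructureModel(chains=chains, hetero=[])
            assert interchain_contacts(s, 4.5) == brute_force_interchain(s, 4.5)


class TestDssp:
    def test_parse_and_collapse(self, toy_structure_files):
        path, _ = toy_structure_files["dimer"]
        s = read_structure(path)
        assign = {}
        codes = ["H", "G", "I", "E", "B", "T", "S", " ", "H", "E"]
        for i in range(10):
            assign[("A", i + 1)] = ("A", 20.0, codes[i])
            if i < 9:  # B10 intentionally missing from the DSSP output
                assign[("B", i + 1)] = ("A", 140.0, " ")
        anns, n_unknown = annotate_burial_ss(s, make_dssp_text(assign))
        assert n_unknown == 1
        by_key = {(a.chain, a.number): a for a in anns}
        expected3 = ["helix", "helix", "helix", "strand", "strand",
                     "coil", "coil", "coil", "helix", "strand"]
        assert [by_key[("A", i + 1)].ss3 for i in range(10)] == expected3
        assert not by_key[("B", 10)].known

    def test_relative_asa_and_clipping(self, toy_structure_files):
        path, _ = toy_structure_files["monomer"]  # glycine chain
        s = read_structure(path)
        assign = {("A", i + 1): ("G", 52.0 if i else 999.0, "H") for i in range(10)}
        anns, _ = annotate_burial_ss(s, make_dssp_text(assign))
        by_num = {a.number: a for a in anns}
        assert by_num[1].rel_asa == 1.0  # 999 exceeds the glycine maximum
        assert by_num[2].rel_asa == pytest.approx(52.0 / MAX_ASA["G"])

    def test_parse_dssp_columns(self):
        text = make_dssp_text({("A", 7): ("K", 123.0, "E")})
        assert parse_dssp(text) == {("A", 7): (123.0, "E")}


class TestStratifiedMetrics:
    def ann(self, **kw):
        base = dict(chain="A", number=1, rel_asa=0.5, ss3="helix",
                    interface=False, ligand_contact=False)
        base.update(kw)
        return ResidueAnnotation(**base)

    def test_partition_conservation(self):
        anns = [self.ann(rel_asa=0.1), self.ann(rel_asa=0.9),
                self.ann(ss3="strand"), None]
        preds = [1.0, 2.0, 3.0, 4.0]
        out = stratified_metrics(preds, preds, anns)
        # every annotated mutation appears in exactly one burial stratum
        n_burial = sum(out[k].n for k in ("buried", "exposed") if k in out)
        assert n_burial + out["unknown"].n == 4

    def test_perfect_predictions_everywhere(self):
        anns = [self.ann(rel_asa=0.1), self.ann(rel_asa=0.05),
                self.ann(rel_asa=0.8), self.ann(rel_asa=0.9)]
        preds = [1.0, 2.0, 3.0, 4.5]
        out = stratified_metrics(preds, preds, anns)
        for key in ("buried", "exposed"):
            assert out[key].r == pytest.approx(1.0)
            assert out[key].rmse == 0.0

    def test_small_strata_marked_insufficient(self):
        anns = [self.ann(interface=True), self.ann(), self.ann()]
        out = stratified_metrics([1, 2, 3], [1, 2, 3], anns)
        assert out["interface"].insufficient and out["interface"].n == 1
        assert not out["non-interface"].insufficient

    def test_all_in_one_stratum_no_crash(self):
        anns = [self.ann(), self.ann()]
        out = stratified_metrics([1.0, 2.0], [2.0, 1.0], anns)
        assert "buried" not in out
        assert out["exposed"].n == 2
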