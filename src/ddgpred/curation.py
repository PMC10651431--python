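"""Dataset construction: condition-aware aggregation of heterogeneous ddG
sources into one measurement per mutation.

Thermodynamic stability measurements for the same mutation are scattered
across sources at different pH and temperature, sometimes with conflicting
values.  Because sequence-based predictors do not consume experimental
conditions as features, the pipeline collapses this heterogeneity in five
steps, each keyed by the (PDB ID, chain, mutation code) identity:

1. *Split* records by whether both pH and T are reported (Group I) or not
   (Group II).
2. *Select core samples*: per ID, the Group-I record closest to standard
   conditions (pH 7, 25 degC).
3. *Select additional samples*: remaining Group-I records within the
   pH +/- 0.5 / T +/- 10 degC windows around their core's conditions, plus
   Group-II records whose ID never occurs in Group I.
4. *Average* ddG per ID over the selected members.
5. *Discard inconsistencies*: IDs whose members disagree in sign or whose
   variance exceeds 5 (kJ/mol)^2.

Afterwards come mega-source subsampling (at most 70 records per wild-type
sequence), homology-aware train/test separation (BLAST-style identity > 30%
and E-value < 0.05 removes a training protein), and reverse-mutation
augmentation of the *training* split only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .datamodel import (
    MutationRecord,
    RecordID,
    VariantPair,
    kcal_to_kj,
)
from .identity import IdentityHit

HEME_LIGANDS = ("HEM", "HEC", "BLA")


@dataclass
class CurationConfig:
    """Tunable parameters of the pipeline; defaults are the published
    protocol's values.  ``variance_threshold`` is in (kJ/mol)^2 — member
    ddG values (stored in kcal/mol) are converted to kJ/mol for this one
    comparison.
    """

    ph_standard: float = 7.0
    temp_standard: float = 25.0
    ph_window: float = 0.5
    temp_window: float = 10.0
    variance_threshold: float = 5.0
    per_wt_cap: int = 70
    identity_threshold: float = 30.0
    evalue_threshold: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ph_window", "temp_window", "variance_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.per_wt_cap < 1:
            raise ValueError("per_wt_cap must be >= 1")


@dataclass
class AveragedRecord:
    """One ID after step 4: the mean ddG plus the member values that went
    into it (needed by the step-5 consistency filter)."""

    record: MutationRecord
    members: list  # member ddG values, kcal/mol

    @property
    def record_id(self) -> RecordID:
        return self.record.record_id


@dataclass
class CurationReport:
    """Per-step accounting; every input record lands in exactly one
    step-1..3 bucket and every ID in exactly one step-5 bucket."""

    n_input: int = 0
    n_group1: int = 0
    n_group2: int = 0
    n_core: int = 0
    n_additional_group1: int = 0
    n_window_rejected: int = 0
    n_group2_unique: int = 0
    n_group2_duplicate_rejected: int = 0
    n_ids_averaged: int = 0
    n_ids_kept: int = 0
    n_ids_discarded: int = 0
    discard_reasons: dict = field(default_factory=dict)  # str(ID) -> reason
    seed: Optional[int] = None

    def check_conservation(self) -> None:
        if self.n_group1 + self.n_group2 != self.n_input:
            raise AssertionError("group split does not conserve records")
        g1 = self.n_core + self.n_additional_group1 + self.n_window_rejected
        if g1 != self.n_group1:
            raise AssertionError("Group-I records not conserved across steps 2-3")
        g2 = self.n_group2_unique + self.n_group2_duplicate_rejected
        if g2 != self.n_group2:
            raise AssertionError("Group-II records not conserved across step 3")
        if self.n_ids_kept + self.n_ids_discarded != self.n_ids_averaged:
            raise AssertionError("IDs not conserved across step 5")

    def to_dict(self) -> dict:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# Step 1


def split_by_conditions(records: list[MutationRecord]
                        ) -> tuple[list[MutationRecord], list[MutationRecord]]:
    """Group I = both pH and T reported; Group II = the rest (including
    records with only one of the two)."""
    group1 = [r for r in records if r.has_conditions()]
    group2 = [r for r in records if not r.has_conditions()]
    return group1, group2


# ---------------------------------------------------------------------------
# Step 2


def condition_distance(record: MutationRecord, config: CurationConfig) -> float:
    """Distance to standard conditions, scaled by the step-3 window widths
    so one pH-window equals one T-window."""
    dph = (record.ph - config.ph_standard) / config.ph_window
    dt = (record.temp - config.temp_standard) / config.temp_window
    return math.hypot(dph, dt)


def select_core_samples(group1: list[MutationRecord], config: CurationConfig
                        ) -> dict[RecordID, MutationRecord]:
    """Per ID, the record closest to standard conditions; ties broken by
    lower pH deviation, then input order."""
    best: dict[RecordID, tuple[tuple, MutationRecord]] = {}
    for idx, rec in enumerate(group1):
        key = (condition_distance(rec, config),
               abs(rec.ph - config.ph_standard), idx)
        rid = rec.record_id
        if rid not in best or key < best[rid][0]:
            best[rid] = (key, rec)
    return {rid: rec for rid, (_, rec) in best.items()}


# ---------------------------------------------------------------------------
# Step 3


def in_window(record: MutationRecord, core: MutationRecord,
              config: CurationConfig) -> bool:
    """Closed-interval window around the *core's* conditions."""
    return (abs(record.ph - core.ph) <= config.ph_window
            and abs(record.temp - core.temp) <= config.temp_window)


def select_additional_samples(group1_rest: list[MutationRecord],
                              group2: list[MutationRecord],
                              cores: dict[RecordID, MutationRecord],
                              config: CurationConfig,
                              group1_ids: Optional[set] = None,
                              ) -> list[MutationRecord]:
    """Remaining Group-I records inside their core's window, plus Group-II
    records whose ID never occurs in Group I.

    ``group1_ids`` defaults to the cores' IDs; pass the full set of Group-I
    IDs when ``group1_rest`` does not cover all of Group I.
    """
    if group1_ids is None:
        group1_ids = set(cores) | {r.record_id for r in group1_rest}
    kept: list[MutationRecord] = []
    for rec in group1_rest:
        core = cores.get(rec.record_id)
        if core is not None and in_window(rec, core, config):
            kept.append(rec)
    for rec in group2:
        if rec.record_id not in group1_ids:
            kept.append(rec)
    return kept


# ---------------------------------------------------------------------------
# Step 4


def average_by_id(selected: list[MutationRecord]) -> list[AveragedRecord]:
    """One record per ID with the arithmetic-mean ddG; member values are
    retained for the consistency filter.  Conditions on the averaged record
    are the first member's (the core comes first by construction)."""
    by_id: dict[RecordID, list[MutationRecord]] = {}
    order: list[RecordID] = []
    for rec in selected:
        if rec.record_id not in by_id:
            order.append(rec.record_id)
        by_id.setdefault(rec.record_id, []).append(rec)
    out = []
    for rid in order:
        members = by_id[rid]
        values = [m.ddg for m in members]
        first = members[0]
        mean_rec = MutationRecord(
            pdb_id=rid.pdb_id, chain=rid.chain, mut_code=rid.mut_code,
            ddg=float(np.mean(values)), ph=first.ph, temp=first.temp,
            source="+".join(sorted({m.source for m in members if m.source})))
        out.append(AveragedRecord(record=mean_rec, members=values))
    return out


# ---------------------------------------------------------------------------
# Step 5


def _sample_variance_kj(members_kcal: list[float]) -> float:
    """Unbiased (n-1) sample variance of the members expressed in kJ/mol;
    zero for a single member."""
    if len(members_kcal) < 2:
        return 0.0
    kj = [kcal_to_kj(v) for v in members_kcal]
    return float(np.var(kj, ddof=1))


def discard_inconsistent(averaged: list[AveragedRecord], config: CurationConfig
                         ) -> tuple[list[AveragedRecord], list[tuple[AveragedRecord, str]]]:
    """Drop IDs whose members conflict: strictly-positive and
    strictly-negative values together (zeros are neutral), or sample
    variance above the threshold.  Single-member IDs are always kept."""
    kept, discarded = [], []
    for item in averaged:
        has_pos = any(v > 0 for v in item.members)
        has_neg = any(v < 0 for v in item.members)
        if has_pos and has_neg:
            discarded.append((item, "opposite signs"))
        elif _sample_variance_kj(item.members) > config.variance_threshold:
            discarded.append((item, "variance"))
        else:
            kept.append(item)
    return kept, discarded


# ---------------------------------------------------------------------------
# Full five-step pipeline


def run_pipeline(records: list[MutationRecord], config: CurationConfig
                 ) -> tuple[list[AveragedRecord], CurationReport]:
    """Steps 1-5 with full accounting."""
    report = CurationReport(n_input=len(records), seed=config.seed)
    group1, group2 = split_by_conditions(records)
    report.n_group1, report.n_group2 = len(group1), len(group2)

    cores = select_core_samples(group1, config)
    report.n_core = len(cores)
    core_objs = {id(rec) for rec in cores.values()}
    group1_rest = [r for r in group1 if id(r) not in core_objs]
    group1_ids = {r.record_id for r in group1}

    additional = select_additional_samples(group1_rest, group2, cores, config,
                                           group1_ids=group1_ids)
    add_g1 = [r for r in additional if r.has_conditions()]
    add_g2 = [r for r in additional if not r.has_conditions()]
    report.n_additional_group1 = len(add_g1)
    report.n_window_rejected = len(group1_rest) - len(add_g1)
    report.n_group2_unique = len(add_g2)
    report.n_group2_duplicate_rejected = len(group2) - len(add_g2)

    # cores first so the averaged record inherits the core's conditions
    selected = list(cores.values()) + additional
    averaged = average_by_id(selected)
    report.n_ids_averaged = len(averaged)

    kept, discarded = discard_inconsistent(averaged, config)
    report.n_ids_kept = len(kept)
    report.n_ids_discarded = len(discarded)
    report.discard_reasons = {str(item.record_id): reason
                              for item, reason in discarded}
    report.check_conservation()
    return kept, report


# ---------------------------------------------------------------------------
# Mega-source subsampling


def subsample_per_wt(records: list[MutationRecord], sequences: dict[str, str],
                     config: CurationConfig) -> list[MutationRecord]:
    """At most ``per_wt_cap`` records per wild-type *sequence* (uniform
    random, deterministic under the config seed); keeps diversity when one
    high-throughput source floods the set with short proteins.

    ``sequences`` maps ``PDBID_chain`` accessions to sequences; records on
    the same sequence string count against one cap.
    """
    groups: dict[str, list[int]] = {}
    for i, rec in enumerate(records):
        seq = sequences[f"{rec.pdb_id}_{rec.chain}"]
        groups.setdefault(seq, []).append(i)
    rng = np.random.default_rng(config.seed)
    keep = np.zeros(len(records), dtype=bool)
    for seq in sorted(groups):  # fixed iteration order for determinism
        idx = groups[seq]
        if len(idx) <= config.per_wt_cap:
            chosen = idx
        else:
            chosen = [idx[j] for j in
                      rng.choice(len(idx), size=config.per_wt_cap, replace=False)]
        keep[chosen] = True
    return [rec for i, rec in enumerate(records) if keep[i]]


# ---------------------------------------------------------------------------
# Reverse augmentation (training split only)


def augment_with_reverses(pairs: list[VariantPair]) -> list[VariantPair]:
    """Each (wt, mt, ddg) gains its mirror (mt, wt, -ddg); output is exactly
    twice the input, originals first."""
    return list(pairs) + [p.reversed() for p in pairs]


# ---------------------------------------------------------------------------
# Homology filter


@dataclass
class RemovedRecord:
    record: MutationRecord
    hit: IdentityHit


def homology_filter(train_records: list[MutationRecord],
                    train_sequences: dict[str, str],
                    test_sequences: dict[str, str],
                    config: CurationConfig,
                    identity_backend,
                    ) -> tuple[list[MutationRecord], list[RemovedRecord]]:
    """Remove training records whose wild-type sequence hits any test
    sequence with identity > threshold AND E-value < threshold (both
    conditions must hold).  Each removal records its triggering hit."""
    if identity_backend is None:
        raise ValueError(
            "no identity backend given; pass NaiveIdentityBackend() (bundled) "
            "or BlastIdentityBackend()")
    used = sorted({f"{r.pdb_id}_{r.chain}" for r in train_records})
    queries = {name: train_sequences[name] for name in used}
    hits = identity_backend.search(queries, test_sequences)
    trigger: dict[str, IdentityHit] = {}
    for h in hits:
        if h.identity > config.identity_threshold and h.evalue < config.evalue_threshold:
            trigger.setdefault(h.query, h)
    kept, removed = [], []
    for rec in train_records:
        hit = trigger.get(f"{rec.pdb_id}_{rec.chain}")
        if hit is None:
            kept.append(rec)
        else:
            removed.append(RemovedRecord(record=rec, hit=hit))
    return kept, removed


# ---------------------------------------------------------------------------
# Structure-derived stability test sets


@dataclass
class StratifiedSubset:
    name: str
    records: list


def build_stability_test_sets(records: list[MutationRecord],
                              structures: dict[str, "object"],
                              config: Optional[CurationConfig] = None,
                              cutoff: float = 4.5,
                              interface_threshold: float = 0.30,
                              ) -> tuple[dict[str, StratifiedSubset], int]:
    """Two structure-defined test subsets plus a skipped-record count.

    * ``hemoglobin``: records whose structure carries a HEM, HEC or BLA
      hetero-residue (heme/biliverdin-binding proteins).
    * ``oligomerization``: records whose chain has strictly more than 30% of
      its residues within 4.5 A of another chain.
    """
    from .stratify import interface_fraction

    hemo, oligo = [], []
    skipped = 0
    for rec in records:
        structure = structures.get(rec.pdb_id)
        if structure is None:
            warnings.warn(f"no structure for {rec.pdb_id}; record skipped")
            skipped += 1
            continue
        codes = {h.ligand_code for h in structure.hetero}
        if codes & set(HEME_LIGANDS):
            hemo.append(rec)
        if rec.chain in structure.chains:
            frac = interface_fraction(structure, rec.chain, cutoff)
            if frac > interface_threshold:  # strictly over
                oligo.append(rec)
    subsets = {"hemoglobin": StratifiedSubset("hemoglobin", hemo),
               "oligomerization": StratifiedSubset("oligomerization", oligo)}
    return subsets, skipped
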