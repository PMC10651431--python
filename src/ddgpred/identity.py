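"""Sequence-identity backends for homology filtering and clustering.

A backend searches a set of query sequences against a set of targets and
reports hits as (identity %, E-value).  The bundled naive backend computes
global-alignment identity with Biopython's PairwiseAligner and a surrogate
E-value of 0.0 — adequate for fixtures and tests.  Production-scale
filtering should use the BLAST-based backend (requires ``makeblastdb`` and
``blastp`` on PATH).
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

from Bio import Align


@dataclass(frozen=True)
class IdentityHit:
    query: str
    target: str
    identity: float  # percent, 0..100
    evalue: float


class BackendUnavailableError(RuntimeError):
    pass


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity in percent: matches / alignment columns."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(a, b)[0]
    matches = 0
    columns = 0
    for (qs, qe), (ts, te) in zip(*aln.aligned):
        seg_q = a[qs:qe]
        seg_t = b[ts:te]
        matches += sum(x == y for x, y in zip(seg_q, seg_t))
        columns += qe - qs
    # count gap columns too: alignment length = columns + unaligned residues
    gap_cols = (len(a) - columns) + (len(b) - columns)
    total = columns + gap_cols
    return 100.0 * matches / total if total else 0.0


class NaiveIdentityBackend:
    """All-vs-all global-alignment identity; surrogate E-value 0.0.

    Every (query, target) pair is reported as a hit, so downstream filters
    decide purely on the identity/E-value conjunction.
    """

    def search(self, queries: dict[str, str], targets: dict[str, str]
               ) -> list[IdentityHit]:
        hits = []
        for qname, qseq in queries.items():
            for tname, tseq in targets.items():
                ident = pairwise_identity(qseq, tseq)
                hits.append(IdentityHit(qname, tname, ident, 0.0))
        return hits


class BlastIdentityBackend:
    """blastp all-vs-all search; identity and E-value straight from BLAST."""

    def __init__(self) -> None:
        if shutil.which("blastp") is None or shutil.which("makeblastdb") is None:
            raise BackendUnavailableError(
                "blastp/makeblastdb not found on PATH; use the bundled "
                "NaiveIdentityBackend instead")

    def search(self, queries: dict[str, str], targets: dict[str, str]
               ) -> list[IdentityHit]:
        with tempfile.TemporaryDirectory() as tmp:
            tmp = Path(tmp)
            qfa, tfa = tmp / "q.fasta", tmp / "t.fasta"
            for path, seqs in ((qfa, queries), (tfa, targets)):
                with open(path, "w") as fh:
                    for name, seq in seqs.items():
                        fh.write(f">{name}\n{seq}\n")
            subprocess.run(["makeblastdb", "-in", str(tfa), "-dbtype", "prot"],
                           check=True, capture_output=True)
            out = subprocess.run(
                ["blastp", "-query", str(qfa), "-db", str(tfa),
                 "-outfmt", "6 qseqid sseqid pident evalue", "-evalue", "10"],
                check=True, capture_output=True, text=True).stdout
        hits = []
        for line in out.splitlines():
            q, t, pident, evalue = line.split("\t")
            hits.append(IdentityHit(q, t, float(pident), float(evalue)))
        return hits
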