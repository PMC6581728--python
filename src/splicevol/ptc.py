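"""Premature-termination-codon annotation via the 50-nt rule.

A transcript is PTC-containing when the stop codon of its longest ORF lies
at least 50 nt upstream of the final exon-exon boundary in mature
(spliced) coordinates.  An AS event is assignable to the AS+PTC / AS-PTC
classes only when it maps to exactly two transcripts whose sole structural
difference is the AS region and at least one of them lacks a PTC.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import revcomp
from .io import GeneModel, TranscriptRecord

STOP_CODONS = {"TAA", "TAG", "TGA"}
NMD_RULE_NT = 50


@dataclass
class TranscriptModel:
    transcript_id: str
    exons: list[tuple[int, int]]  # genomic, 0-based half-open, genomic order
    strand: str
    mature_sequence: str
    junction_positions: list[int]  # mature coordinates, 5'->3'

    @classmethod
    def from_exons(
        cls,
        transcript_id: str,
        exons: Sequence[tuple[int, int]],
        strand: str,
        chrom_seq: str,
    ) -> "TranscriptModel":
        ex = sorted(exons)
        parts = [chrom_seq[s:e] for s, e in ex]
        if strand == "-":
            parts = [revcomp(p) for p in reversed(parts)]
        lengths = [len(p) for p in parts]
        junctions = list(np.cumsum(lengths)[:-1])
        return cls(
            transcript_id=transcript_id,
            exons=ex,
            strand=strand,
            mature_sequence="".join(parts),
            junction_positions=[int(x) for x in junctions],
        )

    @classmethod
    def from_record(
        cls, record: TranscriptRecord, gene: GeneModel, chrom_seq: str
    ) -> "TranscriptModel":
        return cls.from_exons(record.transcript_id, record.exons, gene.strand, chrom_seq)


@dataclass
class ORF:
    start: int  # mature coordinate of the A of ATG
    stop: int  # exclusive end (last base of the stop codon, or sequence end)
    protein: str

    @property
    def length(self) -> int:
        return self.stop - self.start


@dataclass
class PTCStatus:
    transcript_id: str
    has_ptc: bool
    distance_to_final_junction: Optional[int]  # signed, nt; None when no ORF/junction


class PTCClass(str, Enum):
    AS_PLUS_PTC = "AS_plus_PTC"
    AS_MINUS_PTC = "AS_minus_PTC"
    UNASSIGNED = "unassigned"


_CODON_TABLE = {}


def _translate(seq: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(seq).translate())


def longest_orf(mature_sequence: str) -> Optional[ORF]:
    """Longest ATG-initiated forward-strand ORF; ties go to the 5'-most start.

    Candidate ORFs containing an N before their stop are discarded.  An ORF
    with no in-frame stop runs to the last complete codon.
    """
    seq = mature_sequence.upper()
    n = len(seq)
    best: Optional[ORF] = None
    for frame in range(3):
        # positions of stops and Ns in this frame, in order
        boundaries = []  # (codon_start, kind)
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if "N" in codon:
                boundaries.append((i, "N"))
            elif codon in STOP_CODONS:
                boundaries.append((i, "stop"))
        starts = [i for i in range(frame, n - 2, 3) if seq[i : i + 3] == "ATG"]
        boundary_starts = [b[0] for b in boundaries]
        bidx = 0
        for s in starts:
            while bidx < len(boundary_starts) and boundary_starts[bidx] < s:
                bidx += 1
            if bidx == len(boundaries):
                end = s + ((n - s) // 3) * 3
            elif boundaries[bidx][1] == "N":
                continue  # aborted by N
            else:
                end = boundaries[bidx][0] + 3
            if end - s < 3:
                continue
            if best is None or (end - s) > best.length or (
                (end - s) == best.length and s < best.start
            ):
                best = ORF(start=s, stop=end, protein="")
    if best is None:
        return None
    coding = seq[best.start : best.stop]
    protein = _translate(coding)
    if protein.endswith("*"):
        protein = protein[:-1]
    return ORF(start=best.start, stop=best.stop, protein=protein)


def annotate_ptc(
    transcript: TranscriptModel, rule: str = "final"
) -> PTCStatus:
    """Apply the 50-nt rule to a transcript.

    ``rule='final'`` measures against the final exon-exon boundary (the
    standard NMD convention); ``rule='any'`` flags a PTC if the stop is
    >= 50 nt upstream of any boundary (equivalent for ordered junctions).
    """
    if rule not in ("final", "any"):
        raise ValueError(f"unknown rule {rule!r}")
    if not transcript.junction_positions:
        return PTCStatus(transcript.transcript_id, False, None)
    orf = longest_orf(transcript.mature_sequence)
    if orf is None:
        return PTCStatus(transcript.transcript_id, False, None)
    reference_junction = max(transcript.junction_positions)
    distance = reference_junction - orf.stop
    return PTCStatus(
        transcript_id=transcript.transcript_id,
        has_ptc=distance >= NMD_RULE_NT,
        distance_to_final_junction=distance,
    )


def _structural_difference(
    tx_a: TranscriptModel, tx_b: TranscriptModel
) -> list[tuple[int, int]]:
    """Genomic intervals covered by exactly one of the two exon sets."""
    points = sorted({p for s, e in tx_a.exons + tx_b.exons for p in (s, e)})
    diffs = []
    for lo, hi in zip(points[:-1], points[1:]):
        in_a = any(s <= lo and hi <= e for s, e in tx_a.exons)
        in_b = any(s <= lo and hi <= e for s, e in tx_b.exons)
        if in_a != in_b:
            diffs.append((lo, hi))
    # merge adjacent
    merged: list[tuple[int, int]] = []
    for lo, hi in diffs:
        if merged and merged[-1][1] == lo:
            merged[-1] = (merged[-1][0], hi)
        else:
            merged.append((lo, hi))
    return merged


def classify_event_ptc(
    event_region: tuple[int, int],
    transcripts: Sequence[tuple[TranscriptModel, PTCStatus]],
) -> PTCClass:
    """Assign AS+PTC / AS-PTC when the event maps to exactly two transcripts.

    ``event_region`` is the genomic interval altered by the AS event.  The
    class is assigned only when the two transcripts differ structurally in
    (a subset of) that region alone and at least one transcript lacks a
    PTC; two PTC+ transcripts are treated as annotation artifacts.
    """
    if len(transcripts) != 2:
        return PTCClass.UNASSIGNED
    (tx1, st1), (tx2, st2) = transcripts
    diffs = _structural_difference(tx1, tx2)
    lo, hi = event_region
    if not diffs or any(d_lo < lo or d_hi > hi for d_lo, d_hi in diffs):
        return PTCClass.UNASSIGNED
    if st1.has_ptc and st2.has_ptc:
        return PTCClass.UNASSIGNED
    if st1.has_ptc or st2.has_ptc:
        return PTCClass.AS_PLUS_PTC
    return PTCClass.AS_MINUS_PTC


def compare_ptc_conservation(records: pd.DataFrame) -> tuple[np.ndarray, float, float]:
    """2x2 table of PTC class vs conservation with a two-sided exact test.

    ``records`` needs boolean columns ``has_ptc`` and ``conserved``.
    Returns (table, sample odds ratio, p-value); the table rows are
    [AS+PTC, AS-PTC] and columns [conserved, not conserved].
    """
    a = int(((records["has_ptc"]) & (records["conserved"])).sum())
    b = int(((records["has_ptc"]) & (~records["conserved"])).sum())
    c = int(((~records["has_ptc"]) & (records["conserved"])).sum())
    d = int(((~records["has_ptc"]) & (~records["conserved"])).sum())
    table = np.array([[a, b], [c, d]])
    if table.sum() == 0:
        raise ValueError("all-zero contingency table")
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return table, float(odds), float(p)
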