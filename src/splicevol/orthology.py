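"""Cross-species junction orthology and AS conservation.

One-to-one orthologous genes are found by reciprocal-best protein
alignment; exon-exon junctions (EEJs, represented by up to 100 bp of
exonic sequence on each side) are then matched between species by
reciprocal-best six-frame translated local alignment restricted to
ortholog gene pairs.  Accepted matches must pass all of: one-to-one
ortholog pair, reciprocal best, >= 3 aligned amino acids on both flanks,
aligned coverage >= 60 bp, and a significance threshold.

An AS event is conserved only when the same AS type is present at both
matched EEJs; otherwise the pair is labeled lost/gained (directional,
relative to the first species) or a type switch.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from ._util import revcomp
from .io import GeneModel
from .junctions import ASEvent, Junction

logger = logging.getLogger(__name__)

FLANK_BP = 100
MIN_FLANK_AA = 3
MIN_COVERAGE_BP = 60
DEFAULT_MATCH_EVALUE = 1e-3
DEFAULT_ORTHOLOG_EVALUE = 1e-6

# gapped BLOSUM62 Karlin-Altschul parameters for the significance proxy
_KA_LAMBDA = 0.267
_KA_K = 0.041

TRANSITION_STATES = ("none", "AltA", "AltD", "ES", "IR")


def _protein_aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def _evalue(score: float, m: int, n: int) -> float:
    """Karlin-Altschul style significance proxy for a local alignment."""
    bits = (_KA_LAMBDA * score - math.log(_KA_K)) / math.log(2)
    return m * n * 2.0 ** (-bits)


class EEJContextError(ValueError):
    """Raised when a junction has no annotated flanking exons."""


def find_orthologs(
    proteins_a: dict[str, str],
    proteins_b: dict[str, str],
    evalue_max: float = DEFAULT_ORTHOLOG_EVALUE,
) -> list[tuple[str, str]]:
    """One-to-one ortholog pairs by reciprocal best protein alignment.

    Genes whose best hit is tied between several targets are excluded
    (one-to-one means unique).
    """
    if not proteins_a or not proteins_b:
        logger.warning("empty protein set; no orthologs")
        return []
    aligner = _protein_aligner("local")
    ids_a, ids_b = sorted(proteins_a), sorted(proteins_b)
    scores: dict[tuple[str, str], float] = {}
    for ga in ids_a:
        pa = proteins_a[ga]
        for gb in ids_b:
            pb = proteins_b[gb]
            s = aligner.score(pa, pb)
            if _evalue(s, len(pa), len(pb)) < evalue_max:
                scores[(ga, gb)] = s

    def best_unique(ids, other_ids, lookup):
        out = {}
        for g in ids:
            hits = [(lookup(g, o), o) for o in other_ids if lookup(g, o) is not None]
            if not hits:
                continue
            top = max(s for s, _ in hits)
            winners = [o for s, o in hits if s == top]
            if len(winners) == 1:
                out[g] = winners[0]
        return out

    best_a = best_unique(ids_a, ids_b, lambda a, b: scores.get((a, b)))
    best_b = best_unique(ids_b, ids_a, lambda b, a: scores.get((a, b)))
    return sorted(
        (ga, gb) for ga, gb in best_a.items() if best_b.get(gb) == ga
    )


@dataclass
class EEJSequence:
    junction: Junction
    gene_id: str
    upstream: str  # sense-strand exonic sequence 5' of the junction, <=100 bp
    downstream: str

    @property
    def combined(self) -> str:
        return self.upstream + self.downstream


def extract_eej_sequence(
    genome: dict[str, str],
    gene_model: GeneModel,
    junction: Junction,
    flank: int = FLANK_BP,
) -> EEJSequence:
    """Up to ``flank`` bp of exonic sequence from each side of the junction,
    truncated at exon boundaries, in sense orientation."""
    exons: set[tuple[int, int]] = set(gene_model.exons)
    for tx in gene_model.transcripts.values():
        exons.update(tx.exons)
    left = [e for e in exons if e[1] == junction.start]
    right = [e for e in exons if e[0] == junction.end]
    if not left or not right:
        raise EEJContextError(
            f"junction {junction.key} has no annotated flanking exons in "
            f"{gene_model.gene_id}"
        )
    chrom_seq = genome[junction.chrom]
    lstart = max(max(s for s, _ in left), junction.start - flank)
    left_seq = chrom_seq[lstart : junction.start]
    rend = min(max(e for _, e in right), junction.end + flank)
    right_seq = chrom_seq[junction.end : rend]
    if junction.strand == "+":
        up, down = left_seq, right_seq
    else:
        up, down = revcomp(right_seq), revcomp(left_seq)
    return EEJSequence(
        junction=junction, gene_id=gene_model.gene_id, upstream=up, downstream=down
    )


@dataclass
class EEJMatch:
    eej_a: EEJSequence
    eej_b: EEJSequence
    aligned_aa_up: int  # aligned residues inside species-A's upstream flank
    aligned_aa_down: int
    coverage_bp: int
    score: float
    evalue_like: float


def _six_frames(nt: str) -> list[tuple[str, int, str]]:
    """(strand, offset, protein) for all six reading frames."""
    frames = []
    rc = revcomp(nt)
    for strand, seq in (("+", nt), ("-", rc)):
        for off in range(3):
            sub = seq[off : off + 3 * ((len(seq) - off) // 3)]
            if len(sub) >= 3:
                frames.append((strand, off, str(Seq(sub).translate())))
    return frames


def _residue_nt_span(strand: str, off: int, i: int, length: int) -> tuple[int, int]:
    """Nucleotide interval (original coordinates) covered by residue ``i``."""
    if strand == "+":
        return off + 3 * i, off + 3 * i + 3
    end = length - (off + 3 * i)
    return end - 3, end


def _translated_match(
    seq_a: str, seq_b: str, len_up_a: int, len_up_b: int, aligner: Align.PairwiseAligner
) -> Optional[dict]:
    """Best six-frame translated local alignment with flank footprints."""
    frames_a = _six_frames(seq_a)
    frames_b = _six_frames(seq_b)
    best = None
    for fa in frames_a:
        for fb in frames_b:
            if not fa[2] or not fb[2]:
                continue
            s = aligner.score(fa[2], fb[2])
            if best is None or s > best[0]:
                best = (s, fa, fb)
    if best is None or best[0] <= 0:
        return None
    score, fa, fb = best
    aln = aligner.align(fa[2], fb[2])[0]
    blocks_a, blocks_b = aln.aligned
    aligned_residues = int(sum(e - s for s, e in blocks_a))

    def flank_counts(blocks, strand, off, length, len_up):
        n_up = n_down = 0
        for bs, be in blocks:
            for i in range(bs, be):
                lo, hi = _residue_nt_span(strand, off, i, length)
                if hi <= len_up:
                    n_up += 1
                elif lo >= len_up:
                    n_down += 1
        return n_up, n_down

    up_a, down_a = flank_counts(blocks_a, fa[0], fa[1], len(seq_a), len_up_a)
    up_b, down_b = flank_counts(blocks_b, fb[0], fb[1], len(seq_b), len_up_b)
    return {
        "score": score,
        "aligned_residues": aligned_residues,
        "coverage_bp": 3 * aligned_residues,
        "aa_up": min(up_a, up_b),
        "aa_down": min(down_a, down_b),
        "evalue": _evalue(score, len(fa[2]), len(fb[2])),
    }


def passes_match_filters(
    aligned_aa_up: int,
    aligned_aa_down: int,
    coverage_bp: int,
    evalue_like: float,
    evalue_max: float = DEFAULT_MATCH_EVALUE,
) -> bool:
    """The per-alignment acceptance filters (flank aa, coverage, significance)."""
    return (
        aligned_aa_up >= MIN_FLANK_AA
        and aligned_aa_down >= MIN_FLANK_AA
        and coverage_bp >= MIN_COVERAGE_BP
        and evalue_like < evalue_max
    )


def match_eejs(
    eejs_a: Sequence[EEJSequence],
    eejs_b: Sequence[EEJSequence],
    ortholog_pairs: Iterable[tuple[str, str]],
    evalue_max: float = DEFAULT_MATCH_EVALUE,
) -> list[EEJMatch]:
    """Reciprocal-best translated EEJ matches within ortholog gene pairs."""
    aligner = _protein_aligner("local")
    pairs = set(ortholog_pairs)
    by_gene_a: dict[str, list[EEJSequence]] = {}
    by_gene_b: dict[str, list[EEJSequence]] = {}
    for e in eejs_a:
        by_gene_a.setdefault(e.gene_id, []).append(e)
    for e in eejs_b:
        by_gene_b.setdefault(e.gene_id, []).append(e)

    candidates: list[EEJMatch] = []
    for ga, gb in sorted(pairs):
        for ea in by_gene_a.get(ga, []):
            for eb in by_gene_b.get(gb, []):
                res = _translated_match(
                    ea.combined, eb.combined, len(ea.upstream), len(eb.upstream), aligner
                )
                if res is None:
                    continue
                if not passes_match_filters(
                    res["aa_up"], res["aa_down"], res["coverage_bp"], res["evalue"],
                    evalue_max,
                ):
                    continue
                candidates.append(
                    EEJMatch(
                        eej_a=ea,
                        eej_b=eb,
                        aligned_aa_up=res["aa_up"],
                        aligned_aa_down=res["aa_down"],
                        coverage_bp=res["coverage_bp"],
                        score=res["score"],
                        evalue_like=res["evalue"],
                    )
                )

    def best_map(key_fn):
        best: dict[tuple, list[EEJMatch]] = {}
        for m in candidates:
            k = key_fn(m)
            cur = best.get(k)
            if cur is None or m.score > cur[0].score:
                best[k] = [m]
            elif m.score == cur[0].score:
                cur.append(m)
        return {
            k: v[0] for k, v in best.items() if len(v) == 1
        }  # score ties excluded, symmetric in both directions

    best_a = best_map(lambda m: m.eej_a.junction.key)
    best_b = best_map(lambda m: m.eej_b.junction.key)
    out = []
    for key_a, m in sorted(best_a.items()):
        partner = best_b.get(m.eej_b.junction.key)
        if partner is not None and partner.eej_a.junction.key == key_a:
            out.append(m)
    return out


@dataclass
class ConservationLabel:
    match: EEJMatch
    state: str  # conserved / gained / lost / type_switch / none
    as_type_a: str  # 'none' when no AS
    as_type_b: str


def _types_by_junction(events: Iterable[ASEvent]) -> dict[tuple, set[str]]:
    out: dict[tuple, set[str]] = {}
    for e in events:
        out.setdefault(e.authentic.key, set()).add(e.type)
    return out


def call_conservation(
    matches: Sequence[EEJMatch],
    events_a: Sequence[ASEvent],
    events_b: Sequence[ASEvent],
) -> list[ConservationLabel]:
    """Label matched EEJ pairs; pairs with >1 AS type on either side are
    excluded (multi-type EEJs are removed from the analysis)."""
    types_a = _types_by_junction(events_a)
    types_b = _types_by_junction(events_b)
    labels = []
    for m in matches:
        ta = types_a.get(m.eej_a.junction.key, set())
        tb = types_b.get(m.eej_b.junction.key, set())
        if len(ta) > 1 or len(tb) > 1:
            continue
        a = next(iter(ta)) if ta else "none"
        b = next(iter(tb)) if tb else "none"
        if a == "none" and b == "none":
            state = "none"
        elif a == b:
            state = "conserved"
        elif b == "none":
            state = "lost"  # AS present in A only: lost in the other species
        elif a == "none":
            state = "gained"
        else:
            state = "type_switch"
        labels.append(ConservationLabel(match=m, state=state, as_type_a=a, as_type_b=b))
    return labels


def transition_spectrum(labels: Sequence[ConservationLabel]) -> pd.DataFrame:
    """5x5 count matrix of AS states at matched EEJs (A rows, B columns)."""
    mat = pd.DataFrame(
        0, index=list(TRANSITION_STATES), columns=list(TRANSITION_STATES), dtype=int
    )
    for lab in labels:
        mat.loc[lab.as_type_a, lab.as_type_b] += 1
    return mat
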