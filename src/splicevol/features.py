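"""Splice-site determinant extraction.

Covers the sequence features used to discriminate alternative from
constitutive junctions: 12-mer splice-site weight-matrix models and
candidate-site scanning, distances from the authentic splice site to the
nearest alternative site / internal GT-AG, polypyrimidine and UA tract
detection near the 3' splice site, branch-site heptamer search, log2
odds-ratio effect sizes, hexamer enhancer/silencer enrichment, and the
per-junction feature matrix feeding the classifiers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._util import derived_rng, revcomp
from .io import GeneModel
from .junctions import ASEvent, Junction

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

SS_WINDOW = 12  # 5 bp upstream + dinucleotide + 5 bp downstream
SS_ANCHOR = 5  # offset of the GT/AG dinucleotide inside the window
MATCH_SCORE_THRESHOLD = 2.0

TRACT_WINDOW = 50  # last N intronic bases searched for tracts
TRACT_MIN_LEN = 5
TRACT_MIN_COMPOSITION = 0.85  # strict: composition must exceed this
PPT_END_WITHIN = 10  # polypyrimidine tract must end in the last N bases

BRANCH_WINDOW = 100
BRANCH_CONSENSUS = "TACTAAC"
BRANCH_PATTERNS = ("NNYTRAY", "NNCTYAC", "NNRTAAC", "NNCTAAA")

ABSENT_DISTANCE = 200  # sentinel used when no candidate/internal site exists

_IUPAC = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "Y": "CT",
    "R": "AG",
    "N": "ACGT",
}


# ---------------------------------------------------------------------------
# splice-site models


@dataclass
class SpliceSiteModel:
    """Position weight matrix over the 12-base splice-site window."""

    side: str  # '5prime' or '3prime'
    pwm: np.ndarray  # (12, 4) probabilities, rows sum to 1
    background: np.ndarray  # (4,) base frequencies

    def score(self, window: str) -> float:
        """Summed per-position log2 odds vs background; N contributes 0."""
        total = 0.0
        for i, base in enumerate(window.upper()):
            idx = BASE_INDEX.get(base)
            if idx is None:
                continue
            total += math.log2(self.pwm[i, idx] / self.background[idx])
        return total


@dataclass
class CandidateSS:
    position: int  # index of the anchor dinucleotide in the scanned sequence
    side: str
    match_score: float
    is_authentic: bool = False


def build_ss_model(
    positives: Sequence[str],
    background: Sequence[str],
    side: str = "5prime",
    pseudocount: float = 1.0,
) -> SpliceSiteModel:
    """Estimate a 12-column PWM from positive windows and a background base
    distribution from background windows (both sets of 12-mers)."""
    if side not in ("5prime", "3prime"):
        raise ValueError(f"unknown side {side!r}")
    for group, name in ((positives, "positive"), (background, "background")):
        for w in group:
            if len(w) != SS_WINDOW:
                raise ValueError(f"{name} window {w!r} is not {SS_WINDOW} bp")
    counts = np.full((SS_WINDOW, 4), pseudocount)
    for w in positives:
        for i, base in enumerate(w.upper()):
            if base in BASE_INDEX:
                counts[i, BASE_INDEX[base]] += 1
    pwm = counts / counts.sum(axis=1, keepdims=True)
    bg_counts = np.full(4, pseudocount)
    for w in background:
        for base in w.upper():
            if base in BASE_INDEX:
                bg_counts[BASE_INDEX[base]] += 1
    bg = bg_counts / bg_counts.sum()
    return SpliceSiteModel(side=side, pwm=pwm, background=bg)


def scan_candidate_ss(
    sequence: str,
    model: SpliceSiteModel,
    threshold: float = MATCH_SCORE_THRESHOLD,
) -> list[CandidateSS]:
    """All GT (5') or AG (3') anchored positions scoring above threshold.

    Returned positions index the anchor dinucleotide within ``sequence``;
    only positions where the full 12-mer window fits are scanned.
    """
    anchor = "GT" if model.side == "5prime" else "AG"
    seq = sequence.upper()
    hits = []
    for pos in range(SS_ANCHOR, len(seq) - (SS_WINDOW - SS_ANCHOR) + 1):
        if seq[pos : pos + 2] != anchor:
            continue
        window = seq[pos - SS_ANCHOR : pos - SS_ANCHOR + SS_WINDOW]
        score = model.score(window)
        if score > threshold:
            hits.append(CandidateSS(position=pos, side=model.side, match_score=score))
    return hits


# ---------------------------------------------------------------------------
# distances


@dataclass
class DistanceFeatures:
    junction_size: int
    alt_ss_distance: Optional[int]  # authentic -> nearest alternative candidate SS
    alt_ss_frameshift: bool
    inter_distance: Optional[int]  # authentic -> nearest internal GT/AG
    inter_frameshift: bool

    @property
    def alt_ss_present(self) -> bool:
        return self.alt_ss_distance is not None

    @property
    def inter_present(self) -> bool:
        return self.inter_distance is not None


def _internal_dinucleotide_distances(intron_seq: str, side: str) -> list[int]:
    """Distances (>=1) from the authentic SS to each internal GT/AG."""
    seq = intron_seq.upper()
    n = len(seq)
    out = []
    if side == "5prime":
        for p in range(1, n - 1):
            if seq[p : p + 2] == "GT":
                out.append(p)
    else:
        # authentic AG occupies [n-2, n); internal AG at p gives an
        # alternative intron ending at p+2, i.e. distance n - (p + 2)
        for p in range(0, n - 2):
            if seq[p : p + 2] == "AG":
                d = n - (p + 2)
                if d >= 1:
                    out.append(d)
    return sorted(out)


def junction_distances(
    intron_seq: str,
    side: str,
    candidate_distances: Optional[Iterable[int]] = None,
) -> DistanceFeatures:
    """Distance features for one junction on one side.

    ``candidate_distances`` are distances from the authentic SS to
    PWM-passing candidate sites (from :func:`scan_candidate_ss`, mapped to
    distances by the caller); ``None`` means no scan was performed, in
    which case the alternative-SS features are reported absent.
    """
    if side not in ("5prime", "3prime"):
        raise ValueError(f"unknown side {side!r}")
    inter = _internal_dinucleotide_distances(intron_seq, side)
    inter_d = inter[0] if inter else None
    cand = sorted(d for d in (candidate_distances or []) if d >= 1)
    alt_d = cand[0] if cand else None
    return DistanceFeatures(
        junction_size=len(intron_seq),
        alt_ss_distance=alt_d,
        alt_ss_frameshift=bool(alt_d is not None and alt_d % 3 != 0),
        inter_distance=inter_d,
        inter_frameshift=bool(inter_d is not None and inter_d % 3 != 0),
    )


# ---------------------------------------------------------------------------
# tracts and branch sites


@dataclass
class TractHit:
    kind: str  # 'polypyrimidine' or 'UA'
    start: int  # indices within the searched window
    end: int  # exclusive
    composition: float

    @property
    def length(self) -> int:
        return self.end - self.start


def find_tract(window: str, kind: str) -> Optional[TractHit]:
    """Longest substring (>=5 nt) with C+T (polypyrimidine) or A+T (UA)
    composition strictly above 85%; polypyrimidine hits must additionally
    end within the last 10 bases of the window.  Length ties break 3'-most.
    """
    if kind == "polypyrimidine":
        alphabet = {"C", "T"}
    elif kind == "UA":
        alphabet = {"A", "T"}
    else:
        raise ValueError(f"unknown tract kind {kind!r}")
    seq = window.upper()
    n = len(seq)
    good = np.fromiter((c in alphabet for c in seq), dtype=int, count=n)
    prefix = np.concatenate([[0], np.cumsum(good)])
    best: Optional[TractHit] = None
    for s in range(n):
        for e in range(s + TRACT_MIN_LEN, n + 1):
            if kind == "polypyrimidine" and e - 1 < n - PPT_END_WITHIN:
                continue
            count = prefix[e] - prefix[s]
            comp = count / (e - s)
            if comp <= TRACT_MIN_COMPOSITION:
                continue
            if (
                best is None
                or (e - s) > best.length
                or ((e - s) == best.length and e > best.end)
            ):
                best = TractHit(kind=kind, start=s, end=e, composition=comp)
    return best


@dataclass
class BranchSiteHit:
    heptamer: str
    position: int  # start index of the heptamer within the searched window
    mismatches: int


def _matches_pattern(heptamer: str, pattern: str) -> bool:
    return all(b in _IUPAC[p] for b, p in zip(heptamer, pattern))


def find_branch_site(intron_seq: str) -> Optional[BranchSiteHit]:
    """Branch-site search in the last 100 intronic nt (terminal AG excluded).

    Heptamers matching any of the degenerate consensi are scored by
    mismatches to TACTAAC; a hit is reported only when the most downstream
    hit also carries the (tied-or-)best score.
    """
    window = intron_seq.upper()[:-2][-BRANCH_WINDOW:]
    hits = []
    for p in range(len(window) - 6):
        hept = window[p : p + 7]
        if any(ch not in "ACGT" for ch in hept):
            continue
        if any(_matches_pattern(hept, pat) for pat in BRANCH_PATTERNS):
            mm = sum(a != b for a, b in zip(hept, BRANCH_CONSENSUS))
            hits.append(BranchSiteHit(heptamer=hept, position=p, mismatches=mm))
    if not hits:
        return None
    downstream = max(hits, key=lambda h: h.position)
    best_score = min(h.mismatches for h in hits)
    if downstream.mismatches != best_score:
        return None
    return downstream


# ---------------------------------------------------------------------------
# effect sizes and hexamer enrichment


@dataclass
class EffectSizeInput:
    k_with: int
    n_with: int
    k_without: int
    n_without: int

    def __post_init__(self):
        if not (0 <= self.k_with <= self.n_with and 0 <= self.k_without <= self.n_without):
            raise ValueError("counts must satisfy 0 <= k <= n")
        if self.n_with == 0 and self.n_without == 0:
            raise ValueError("both group sizes are zero")


def effect_size(inp: EffectSizeInput) -> float:
    """log2 odds ratio of AS frequency with vs without the motif/tract.

    When any cell of the implied 2x2 table is zero, 0.5 is added to all
    four cells so the ratio stays finite.
    """
    a = inp.k_with
    b = inp.n_with - inp.k_with
    c = inp.k_without
    d = inp.n_without - inp.k_without
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return math.log2((a / b) / (c / d))


def hexamer_enrichment(
    positive_windows: Sequence[str],
    background_windows: Sequence[str],
    max_background: int = 10000,
    k: int = 6,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Presence-based k-mer enrichment between positive and background windows.

    Background windows beyond ``max_background`` are subsampled with the
    given seed.  For each k-mer observed in any window a hypergeometric
    enrichment p-value is computed in both directions; enhancer = enriched
    in positives, silencer = enriched in background.  P-values are BH
    adjusted across all tested k-mers; ``significant`` marks adjusted
    p < alpha.
    """
    if len(positive_windows) < 10 or len(background_windows) < 10:
        raise ValueError("need at least 10 windows per side")
    bg = list(background_windows)
    if len(bg) > max_background:
        rng = derived_rng(seed, "background")
        idx = rng.choice(len(bg), size=max_background, replace=False)
        bg = [bg[i] for i in sorted(idx)]

    def kmer_sets(windows):
        return [
            {w[i : i + k].upper() for i in range(len(w) - k + 1)} for w in windows
        ]

    pos_sets = kmer_sets(positive_windows)
    bg_sets = kmer_sets(bg)
    universe = set().union(*pos_sets, *bg_sets)
    universe = {m for m in universe if all(c in BASES for c in m)}
    n_pos, n_bg = len(pos_sets), len(bg_sets)
    total = n_pos + n_bg
    rows = []
    for motif in sorted(universe):
        a = sum(motif in s for s in pos_sets)
        b = sum(motif in s for s in bg_sets)
        drawn = a + b
        p_enh = stats.hypergeom.sf(a - 1, total, drawn, n_pos)
        p_sil = stats.hypergeom.sf(b - 1, total, drawn, n_bg)
        if p_enh <= p_sil:
            direction, p = "enhancer", p_enh
        else:
            direction, p = "silencer", p_sil
        rows.append(
            {
                "motif": motif,
                "n_positive": a,
                "n_background": b,
                "direction": direction,
                "p_value": p,
                "log2_odds": effect_size(EffectSizeInput(a, n_pos, b, n_bg)),
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        reject, adj, _, _ = multipletests(table["p_value"], alpha=alpha, method="fdr_bh")
        table["p_adjusted"] = adj
        table["significant"] = reject
        table = table.sort_values("p_adjusted", kind="stable").reset_index(drop=True)
    return table


# ---------------------------------------------------------------------------
# the feature matrix


@dataclass
class FeatureContext:
    """Sequence access for feature extraction."""

    genome: dict[str, str]
    gene_models: dict[str, GeneModel]

    def intron_sense(self, j: Junction) -> str:
        seq = self.genome[j.chrom][j.start : j.end]
        return seq if j.strand == "+" else revcomp(seq)

    def flank(self, j: Junction, where: str, length: int) -> str:
        """Exonic sequence adjacent to the intron, sense orientation.

        ``where`` is 'up' (5' exon, ends at the donor) or 'down' (3' exon,
        starts at the acceptor).
        """
        chrom_seq = self.genome[j.chrom]
        if (j.strand == "+") == (where == "up"):
            lo = max(0, j.start - length)
            seq = chrom_seq[lo : j.start]
        else:
            seq = chrom_seq[j.end : j.end + length]
        return seq if j.strand == "+" else revcomp(seq)

    def ss_window(self, j: Junction, side: str) -> Optional[str]:
        """The 12-mer around the authentic donor (5prime) or acceptor (3prime)."""
        intron = self.intron_sense(j)
        if len(intron) < SS_WINDOW:
            return None
        if side == "5prime":
            w = self.flank(j, "up", SS_ANCHOR) + intron[: SS_WINDOW - SS_ANCHOR]
        else:
            w = intron[-(SS_WINDOW - SS_ANCHOR) :] + self.flank(j, "down", SS_ANCHOR)
        return w if len(w) == SS_WINDOW else None


def default_ss_models(
    junctions: Sequence[Junction], ctx: FeatureContext
) -> dict[str, SpliceSiteModel]:
    """Train both splice-site models from the authentic sites of the given
    junctions, with internal GT/AG windows as background."""
    models = {}
    for side in ("5prime", "3prime"):
        positives = []
        background = []
        for j in junctions:
            w = ctx.ss_window(j, side)
            if w is not None:
                positives.append(w)
            intron = ctx.intron_sense(j)
            for d in _internal_dinucleotide_distances(intron, side):
                if side == "5prime":
                    p = d
                else:
                    p = len(intron) - 2 - d
                if SS_ANCHOR <= p <= len(intron) - (SS_WINDOW - SS_ANCHOR):
                    background.append(intron[p - SS_ANCHOR : p - SS_ANCHOR + SS_WINDOW])
        if not background:
            background = positives
        models[side] = build_ss_model(positives, background, side=side)
    return models


def _candidate_distances(
    intron: str, up_flank: str, down_flank: str, model: SpliceSiteModel
) -> list[int]:
    """Scan the intron (with exonic padding) and convert candidate anchor
    positions to distances from the authentic SS."""
    if model.side == "5prime":
        scan = up_flank[-SS_ANCHOR:] + intron
        offset = len(up_flank[-SS_ANCHOR:])
        hits = scan_candidate_ss(scan, model)
        return [h.position - offset for h in hits if h.position - offset >= 1]
    scan = intron + down_flank[: SS_WINDOW - SS_ANCHOR]
    hits = scan_candidate_ss(scan, model)
    out = []
    for h in hits:
        d = len(intron) - (h.position + 2)
        if d >= 1:
            out.append(d)
    return out


FEATURE_COLUMNS = [
    "junction_size",
    "alt5_distance",
    "alt5_present",
    "alt5_frameshift",
    "inter_gt_distance",
    "inter_gt_present",
    "inter_gt_frameshift",
    "alt3_distance",
    "alt3_present",
    "alt3_frameshift",
    "inter_ag_distance",
    "inter_ag_present",
    "inter_ag_frameshift",
    "ppt_present",
    "ua_tract_present",
    "branch_present",
    "mean_reads",
]


def build_feature_matrix(
    events: Sequence[ASEvent],
    junctions: Sequence[Junction],
    ctx: FeatureContext,
    side: str,
    ss_models: Optional[dict[str, SpliceSiteModel]] = None,
    motifs: Sequence[str] = (),
    min_mean_reads: float = 5.0,
    all_genes: bool = False,
) -> pd.DataFrame:
    """One row per eligible junction of genes carrying the requested AS type
    (or of every gene when ``all_genes`` is set, as needed when the rows
    feed the cross-species conservation dataset).

    Junctions with mean support below ``min_mean_reads`` or with multiple
    AS types are excluded, as are the alternative-isoform junctions of
    events.  Labels are 'alternative' (authentic junction of exactly one
    event of type ``side``) or 'constitutive' (no event involvement).
    """
    if side not in ("AltD", "AltA", "IR"):
        raise ValueError(f"unsupported side {side!r}")
    types_by_junction: dict[tuple, set[str]] = {}
    alt_keys: set[tuple] = set()
    genes_with_side: set[str] = set()
    for e in events:
        types_by_junction.setdefault(e.authentic.key, set()).add(e.type)
        if e.alternative is not None:
            alt_keys.add(e.alternative.key)
        if e.type == side:
            genes_with_side.add(e.gene_id)

    from .junctions import _assign_to_genes  # gene assignment, same rules

    by_gene = _assign_to_genes(junctions, ctx.gene_models)
    if ss_models is None:
        pool = [j for js in by_gene.values() for j in js]
        ss_models = default_ss_models(pool, ctx)

    eligible = set(by_gene) if all_genes else (genes_with_side & set(by_gene))
    rows = []
    for gene_id in sorted(eligible):
        for j in by_gene[gene_id]:
            types = types_by_junction.get(j.key, set())
            if len(types) > 1:
                continue  # multi-type EEJs are removed
            if j.key in alt_keys and not types:
                continue  # alternative-isoform junction, not a unit of its own
            if types and types != {side}:
                continue
            if j.reads < min_mean_reads:
                continue
            label = "alternative" if types == {side} else "constitutive"
            intron = ctx.intron_sense(j)
            up = ctx.flank(j, "up", 50)
            down = ctx.flank(j, "down", 50)
            d5 = junction_distances(
                intron,
                "5prime",
                _candidate_distances(intron, up, down, ss_models["5prime"]),
            )
            d3 = junction_distances(
                intron,
                "3prime",
                _candidate_distances(intron, up, down, ss_models["3prime"]),
            )
            tract_window = intron[:-2][-TRACT_WINDOW:]
            ppt = find_tract(tract_window, "polypyrimidine")
            ua = find_tract(tract_window, "UA")
            branch = find_branch_site(intron)
            row = {
                "junction_id": f"{j.chrom}:{j.start}-{j.end}:{j.strand}",
                "gene_id": gene_id,
                "label": label,
                "junction_size": d5.junction_size,
                "alt5_distance": d5.alt_ss_distance or ABSENT_DISTANCE,
                "alt5_present": int(d5.alt_ss_present),
                "alt5_frameshift": int(d5.alt_ss_frameshift),
                "inter_gt_distance": d5.inter_distance or ABSENT_DISTANCE,
                "inter_gt_present": int(d5.inter_present),
                "inter_gt_frameshift": int(d5.inter_frameshift),
                "alt3_distance": d3.alt_ss_distance or ABSENT_DISTANCE,
                "alt3_present": int(d3.alt_ss_present),
                "alt3_frameshift": int(d3.alt_ss_frameshift),
                "inter_ag_distance": d3.inter_distance or ABSENT_DISTANCE,
                "inter_ag_present": int(d3.inter_present),
                "inter_ag_frameshift": int(d3.inter_frameshift),
                "ppt_present": int(ppt is not None),
                "ua_tract_present": int(ua is not None),
                "branch_present": int(branch is not None),
                "mean_reads": float(j.reads),
            }
            for m in motifs:
                windows = (up, intron[:50], intron[-50:], down)
                row[f"motif_{m}"] = int(any(m.upper() in w.upper() for w in windows))
            rows.append(row)
    cols = ["junction_id", "gene_id", "label"] + FEATURE_COLUMNS + [
        f"motif_{m}" for m in motifs
    ]
    return pd.DataFrame(rows, columns=cols)
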