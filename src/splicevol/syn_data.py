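"""Synthetic multi-species cohort generator.

Builds genomes, gene models, junction tables and ground-truth labels with
the statistical structure the downstream analysis assumes: multi-exon
genes with GT..AG introns, planted AS events of the four types with known
PSI, binomially sampled junction support, ortholog gene pairs with
controlled sequence divergence and known conserved/gained/lost AS labels,
planted splice-site determinant signal (alternative-SS distance, tract
presence), and planted PTC-generating minor isoforms.

Construction notes (all deliberate, so ground truth is exactly
recoverable):

* Junction support counts are sampled directly (no read sequences); for a
  planted event the total is Poisson(depth) and the inclusion count is
  Binomial(total, true PSI).
* Each intron gets a planted alternative/decoy splice-site dinucleotide at
  a known distance from the authentic site; the surrounding window is
  scrubbed of competing GT/AG dinucleotides so "nearest internal site"
  features recover the planted distance exactly.
* Genes carrying a designed coding sequence (used for PTC planting) are
  copied verbatim between species; all other gene bodies receive i.i.d.
  substitutions at the configured divergence, after which the splice-site
  invariants are re-imposed.
* Between-species conservation signal: conserved events share the planted
  distance, lost/gained events shift it by a fixed offset in one species.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from ._util import derived_rng, revcomp
from .io import (
    GeneModel,
    TranscriptRecord,
    read_fasta,
    read_gff3,
    read_junction_table,
    read_tsv,
    write_fasta,
    write_gff3,
    write_junction_table,
    write_tsv,
)

AS_TYPES = ("IR", "AltD", "AltA", "ES")
CONS_STATES = ("conserved", "gained", "lost")

SYN_OVERHANG = 25  # emitted overhang, comfortably above the 13-bp filter
DONOR_CONTEXT = "AATA"  # planted intron bases just after GT (no GT/AG substring)
ACCEPTOR_CONTEXT = "TGTT"  # planted intron bases just before AG
CONTEXT_BIAS = 0.8
SCRUB_WINDOW = 64
DISTANCE_SHIFT = 15  # lost/gained events move the planted site by this much
STOP_ALL_FRAMES = "TAAATAAATAA"  # stop codon in each of the three frames
PTC_DISTANCES = (15, 18, 21, 24)  # frame-preserving, long enough for the stops


class ConfigurationError(ValueError):
    pass


class GenerationError(RuntimeError):
    pass


@dataclass
class CohortConfig:
    n_genes: int = 60
    exons_per_gene: tuple[int, int] = (3, 5)
    exon_len: tuple[int, int] = (90, 180)
    intron_len: tuple[int, int] = (110, 220)
    as_fraction: float = 0.3
    as_type_mix: dict = field(
        default_factory=lambda: {"IR": 0.25, "AltD": 0.25, "AltA": 0.25, "ES": 0.25}
    )
    psi_range: tuple[float, float] = (0.2, 0.8)
    depth: float = 100.0
    n_species: int = 2
    divergence: float = 0.01
    conservation_mix: dict = field(
        default_factory=lambda: {"conserved": 1 / 3, "gained": 1 / 3, "lost": 1 / 3}
    )
    ptc_fraction: float = 0.0
    determinant_signal: float = 0.0
    emit_decoys: bool = False
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.intron_len
        if not (41 <= lo <= hi <= 50000):
            raise ConfigurationError(
                f"intron_len {self.intron_len} must lie within [41, 50000]"
            )
        for name, vec, keys in (
            ("as_type_mix", self.as_type_mix, AS_TYPES),
            ("conservation_mix", self.conservation_mix, CONS_STATES),
        ):
            if set(vec) != set(keys):
                raise ConfigurationError(f"{name} must have keys {keys}")
            if abs(sum(vec.values()) - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} must sum to 1")
        if not (0.0 < self.psi_range[0] <= self.psi_range[1] < 1.0):
            raise ConfigurationError("psi_range must lie inside (0, 1)")
        needs_sites = self.as_fraction > 0 or self.determinant_signal != 0
        max_d = max(self.distance_ladder(), default=0) + DISTANCE_SHIFT
        if needs_sites and lo < 41 + max_d:
            raise ConfigurationError(
                f"intron_len lower bound {lo} cannot host an alternative splice "
                f"site at distance {max_d} while keeping the alternative intron "
                f">= 41 bp (need >= {41 + max_d})"
            )
        if self.ptc_fraction > 0 and self.exon_len[0] < 60:
            raise ConfigurationError(
                "PTC planting needs exon_len lower bound >= 60 to guarantee the "
                "50-nt margin to the final junction"
            )

    def distance_ladder(self) -> list[int]:
        return list(range(6, 37, 3))


# ---------------------------------------------------------------------------
# per-junction / per-event plans


@dataclass
class _EventPlan:
    gene_index: int
    intron_index: int
    as_type: str
    psi: float
    labels: dict[str, str]  # non-ref species -> conserved/gained/lost
    ptc: Optional[bool] = None  # None: not a designed (coding) event

    def present_in(self, species_index: int, species: str) -> bool:
        if species_index == 0:
            # gained = AS only in the other species
            return not all(lab == "gained" for lab in self.labels.values()) or not self.labels
        return self.labels.get(species, "conserved") in ("conserved", "gained")


@dataclass
class _GenePlan:
    index: int
    strand: str
    exon_lens: list[int]
    intron_lens: list[int]
    d_ref: list[int]  # planted distance per intron, reference species
    d_shifted: list[bool]  # whether non-ref species shift the site
    shift_in_ref: list[bool]  # gained events shift the reference decoy instead
    tract: list[bool]
    branch: list[bool]
    events: list[_EventPlan]
    designed: bool = False
    designed_event: Optional[_EventPlan] = None

    def sense_length(self) -> int:
        return sum(self.exon_lens) + sum(self.intron_lens)


def _plan_gene(gi: int, cfg: CohortConfig, rng: np.random.Generator) -> _GenePlan:
    n_exons = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
    exon_lens = [int(rng.integers(cfg.exon_len[0], cfg.exon_len[1] + 1)) for _ in range(n_exons)]
    intron_lens = [
        int(rng.integers(cfg.intron_len[0], cfg.intron_len[1] + 1))
        for _ in range(n_exons - 1)
    ]
    strand = "+" if rng.random() < 0.5 else "-"
    ladder = cfg.distance_ladder()
    n_introns = n_exons - 1
    d_ref = [int(rng.choice(ladder)) for _ in range(n_introns)]

    def p_as(d: int) -> float:
        base = cfg.as_fraction
        if cfg.determinant_signal == 0 or base in (0.0, 1.0):
            return base
        mid = float(np.median(ladder))
        logit = np.log(base / (1 - base)) - cfg.determinant_signal * (d - mid) / 10.0
        return float(1.0 / (1.0 + np.exp(-logit)))

    species_others = [f"sp{i}" for i in range(1, cfg.n_species)]
    events: list[_EventPlan] = []
    used: set[int] = set()
    tract = []
    branch = []
    d_shifted = [False] * n_introns
    shift_in_ref = [False] * n_introns
    for k in range(n_introns):
        is_as = k not in used and rng.random() < p_as(d_ref[k])
        as_type = ""
        if is_as:
            as_type = str(rng.choice(AS_TYPES, p=[cfg.as_type_mix[t] for t in AS_TYPES]))
            if as_type == "ES" and (k + 1 >= n_introns or (k + 1) in used):
                as_type = str(rng.choice(["IR", "AltD", "AltA"]))
        if is_as:
            labels = {
                sp: str(rng.choice(CONS_STATES, p=[cfg.conservation_mix[s] for s in CONS_STATES]))
                for sp in species_others
            }
            psi = float(rng.uniform(*cfg.psi_range))
            ev = _EventPlan(gene_index=gi, intron_index=k, as_type=as_type, psi=psi, labels=labels)
            events.append(ev)
            used.add(k)
            if as_type == "ES":
                used.add(k + 1)
            if any(lab == "lost" for lab in labels.values()):
                d_shifted[k] = True
            if all(lab == "gained" for lab in labels.values()) and labels:
                shift_in_ref[k] = True
        # tract/branch planting; AS junctions get fewer tracts when the
        # determinant signal couples AS to tract absence
        p_tract = 0.5 - (0.3 if (is_as and cfg.determinant_signal > 0) else 0.0)
        tract.append(bool(rng.random() < p_tract))
        branch.append(bool(rng.random() < 0.5))

    plan = _GenePlan(
        index=gi,
        strand=strand,
        exon_lens=exon_lens,
        intron_lens=intron_lens,
        d_ref=d_ref,
        d_shifted=d_shifted,
        shift_in_ref=shift_in_ref,
        tract=tract,
        branch=branch,
        events=events,
    )
    if cfg.ptc_fraction > 0:
        for ev in events:
            if ev.as_type == "AltA" and ev.intron_index <= n_introns - 2:
                ev.ptc = bool(rng.random() < cfg.ptc_fraction)
                plan.d_ref[ev.intron_index] = int(rng.choice(PTC_DISTANCES))
                plan.designed = True
                plan.designed_event = ev
                plan.tract[ev.intron_index] = False
                break
    return plan


# ---------------------------------------------------------------------------
# sequence assembly (all in sense-strand space; strand applied at the end)


def _random_seq(rng: np.random.Generator, n: int) -> list[str]:
    return list(rng.choice(list("ACGT"), size=n))


def _scrub(seq: list[str], lo: int, hi: int, dinuc: str) -> None:
    """Remove occurrences of GT (mutate T->C) or AG (mutate A->C) in [lo, hi)."""
    for p in range(max(lo, 0), min(hi, len(seq) - 1)):
        if seq[p] == dinuc[0] and seq[p + 1] == dinuc[1]:
            if dinuc == "GT":
                seq[p + 1] = "C"
            else:
                seq[p] = "C"


def _plant_context(seq: list[str], pos: int, context: str, rng: np.random.Generator) -> None:
    for i, base in enumerate(context):
        p = pos + i
        if 0 <= p < len(seq):
            seq[p] = base if rng.random() < CONTEXT_BIAS else str(rng.choice(list("ACGT")))


def _finalize_intron(
    intron: list[str],
    d_alt: Optional[int],
    side: str,
    tract: bool,
    branch: bool,
    rng: np.random.Generator,
    ptc_segment: Optional[list[str]] = None,
) -> tuple[bool, bool]:
    """Impose the splice-site invariants and planted signals on an intron
    (in place).  ``d_alt`` plants an alternative GT (side='5prime') or AG
    (side='3prime') at that distance from the authentic site.

    Returns the effective (tract, branch) planting flags: tract/branch
    strings are skipped when they would collide with the alternative-site
    region or a designed PTC segment.
    """
    n = len(intron)
    w = min(SCRUB_WINDOW, n - 2)
    _scrub(intron, 1, w, "GT")
    _scrub(intron, n - w, n - 2, "AG")
    intron[0], intron[1] = "G", "T"
    intron[-2], intron[-1] = "A", "G"
    _plant_context(intron, 2, DONOR_CONTEXT, rng)
    _plant_context(intron, n - 2 - len(ACCEPTOR_CONTEXT), ACCEPTOR_CONTEXT, rng)
    protected: list[tuple[int, int]] = []
    if d_alt is not None:
        if side == "5prime":
            intron[d_alt], intron[d_alt + 1] = "G", "T"
            _plant_context(intron, d_alt + 2, DONOR_CONTEXT, rng)
            protected.append((d_alt, d_alt + 2 + len(DONOR_CONTEXT)))
        else:
            p = n - d_alt - 2
            intron[p], intron[p + 1] = "A", "G"
            _plant_context(intron, p - len(ACCEPTOR_CONTEXT), ACCEPTOR_CONTEXT, rng)
            protected.append((p - len(ACCEPTOR_CONTEXT), p + 2))
    if ptc_segment is not None:
        # gained exonic segment of a designed AltA event: last d bases,
        # terminal AG preserved
        d = len(ptc_segment)
        intron[n - d : n - 2] = ptc_segment[:-2]
        intron[-2], intron[-1] = "A", "G"
        protected.append((n - d, n))

    def clear(lo: int, hi: int) -> bool:
        return lo >= 0 and hi <= n - 2 and all(
            hi <= plo or lo >= phi for plo, phi in protected
        )

    branch_eff = False
    if branch and clear(n - 32, n - 25):
        intron[n - 32 : n - 25] = list("TACTAAC")
        branch_eff = True
    tract_eff = False
    if tract and clear(n - 12, n - 3):
        intron[n - 12 : n - 3] = list("TTTTCTTTT")
        tract_eff = True
    return tract_eff, branch_eff


def _alt_site_distance(plan: _GenePlan, k: int, species_index: int) -> int:
    """Planted site distance for intron k in a given species."""
    d = plan.d_ref[k]
    if species_index > 0 and plan.d_shifted[k]:
        return d + DISTANCE_SHIFT
    if species_index == 0 and plan.shift_in_ref[k]:
        return d + DISTANCE_SHIFT
    return d


def _alt_side(plan: _GenePlan, k: int) -> str:
    ev = next((e for e in plan.events if e.intron_index == k), None)
    if ev is not None and ev.as_type == "AltD":
        return "5prime"
    return "3prime"


def _designed_segment(
    d: int, ptc: bool, frame: int, rng: np.random.Generator
) -> list[str]:
    """The d intronic bases gained by the designed AltA minor isoform.

    For a PTC+ event the segment carries a stop codon in every frame; for a
    PTC- event it continues the reading frame without stops (``frame`` is
    the codon phase at the segment start). The last two bases stay AG.
    """
    if ptc:
        seg = list(STOP_ALL_FRAMES) + _random_seq(rng, d - len(STOP_ALL_FRAMES))
        for i in range(len(STOP_ALL_FRAMES), d - 2):
            if seg[i] == "G" and seg[i - 1] == "A":
                seg[i] = "C"
    else:
        safe = [
            c
            for c in (a + b + cx for a in "ACGT" for b in "ACGT" for cx in "ACGT")
            if c not in ("TAA", "TAG", "TGA", "ATG")
        ]
        seg = []
        phase = frame
        while len(seg) < d:
            codon = str(rng.choice(safe))
            take = codon[phase:] if phase else codon
            seg.extend(take)
            phase = 0
        seg = seg[:d]
    seg[-2], seg[-1] = "A", "G"
    return seg


def _longest_orf_end(seq: str) -> Optional[tuple[int, int]]:
    """(start, stop-exclusive) of the longest ATG ORF; local re-derivation
    used only to verify planted PTC construction."""
    best = None
    n = len(seq)
    for frame in range(3):
        stops = [
            i
            for i in range(frame, n - 2, 3)
            if seq[i : i + 3] in ("TAA", "TAG", "TGA")
        ]
        starts = [i for i in range(frame, n - 2, 3) if seq[i : i + 3] == "ATG"]
        si = 0
        for s in starts:
            while si < len(stops) and stops[si] < s:
                si += 1
            end = stops[si] + 3 if si < len(stops) else s + ((n - s) // 3) * 3
            if best is None or end - s > best[1] - best[0] or (
                end - s == best[1] - best[0] and s < best[0]
            ):
                best = (s, end)
    return best


# ---------------------------------------------------------------------------
# cohort container


@dataclass
class SyntheticCohort:
    config: CohortConfig
    species: list[str]
    genomes: dict[str, dict[str, str]]
    gene_models: dict[str, dict[str, GeneModel]]
    proteins: dict[str, dict[str, str]]
    junction_tables: dict[str, pd.DataFrame]
    orthologs: pd.DataFrame  # columns gene_a, gene_b (per non-ref species)
    truth: pd.DataFrame  # per planted-event, per species
    junction_truth: pd.DataFrame  # per junction, per species
    conservation: pd.DataFrame  # per AS junction, ref vs other species

    def equals(self, other: "SyntheticCohort") -> bool:
        if self.species != other.species or self.genomes != other.genomes:
            return False
        for sp in self.species:
            if not self.junction_tables[sp].equals(other.junction_tables[sp]):
                return False
            mine, theirs = self.gene_models[sp], other.gene_models[sp]
            if set(mine) != set(theirs):
                return False
            for gid in mine:
                a, b = mine[gid], theirs[gid]
                if (a.chrom, a.strand, sorted(a.exons)) != (b.chrom, b.strand, sorted(b.exons)):
                    return False
                if {t: sorted(tx.exons) for t, tx in a.transcripts.items()} != {
                    t: sorted(tx.exons) for t, tx in b.transcripts.items()
                }:
                    return False
        return _frames_close(self.truth, other.truth) and self.orthologs.equals(
            other.orthologs
        )


def _frames_close(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    """Column-wise equality with float tolerance (TSV round-trips may lose
    the last bit of a float's decimal representation)."""
    if list(a.columns) != list(b.columns) or len(a) != len(b):
        return False
    for col in a.columns:
        if pd.api.types.is_float_dtype(a[col]):
            if not np.allclose(a[col], b[col], rtol=1e-12, equal_nan=True):
                return False
        elif not a[col].reset_index(drop=True).equals(b[col].reset_index(drop=True)):
            return False
    return True


def emit_junction_counts(
    true_psi: float, depth: float, rng: np.random.Generator
) -> tuple[int, int]:
    """Sample (inclusion, exclusion) reads: total ~ Poisson(depth),
    inclusion ~ Binomial(total, true_psi)."""
    if not 0.0 <= true_psi <= 1.0:
        raise ValueError("true_psi must be in [0, 1]")
    if depth <= 0:
        raise ValueError("depth must be positive")
    total = int(rng.poisson(depth))
    inclusion = int(rng.binomial(total, true_psi)) if total else 0
    return inclusion, total - inclusion


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    config.validate()
    cfg = config
    rng_plan = derived_rng(cfg.seed, "events")
    plans = [_plan_gene(gi, cfg, rng_plan) for gi in range(cfg.n_genes)]
    species = [f"sp{i}" for i in range(cfg.n_species)]

    genomes: dict[str, dict[str, str]] = {}
    gene_models: dict[str, dict[str, GeneModel]] = {}
    proteins: dict[str, dict[str, str]] = {}
    junction_rows: dict[str, list[dict]] = {sp: [] for sp in species}
    truth_rows: list[dict] = []
    junction_truth_rows: list[dict] = []
    conservation_rows: list[dict] = []
    ortholog_rows: list[dict] = []

    # reference sense-strand sequences per gene (exons, introns as lists)
    rng_genome = derived_rng(cfg.seed, "genome")
    ref_exons: list[list[list[str]]] = []
    ref_introns: list[list[list[str]]] = []
    for plan in plans:
        ref_exons.append([_random_seq(rng_genome, L) for L in plan.exon_lens])
        ref_introns.append([_random_seq(rng_genome, L) for L in plan.intron_lens])

    spacer = "".join(_random_seq(rng_genome, 100))

    for si, sp in enumerate(species):
        rng_div = derived_rng(cfg.seed, "divergence", si)
        rng_counts = derived_rng(cfg.seed, "counts", si)
        chrom = "chr1"
        parts: list[str] = []
        offset = 0
        models: dict[str, GeneModel] = {}
        prots: dict[str, str] = {}
        for plan, exons0, introns0 in zip(plans, ref_exons, ref_introns):
            gid = f"{sp}_g{plan.index:04d}"
            exons = [list(e) for e in exons0]
            introns = [list(i) for i in introns0]
            if si > 0 and not plan.designed and cfg.divergence > 0:
                for block in exons + introns:
                    muts = rng_div.random(len(block)) < cfg.divergence
                    for p in np.flatnonzero(muts):
                        block[p] = str(rng_div.choice([b for b in "ACGT" if b != block[p]]))
            designed_ev = plan.designed_event
            seg_by_intron: dict[int, list[str]] = {}
            if plan.designed:
                exons, seg = _design_coding(plan, exons, introns, cfg, si)
                if designed_ev is not None and designed_ev.present_in(si, sp):
                    seg_by_intron[designed_ev.intron_index] = seg
            effective: dict[int, tuple[bool, bool]] = {}
            for k, intron in enumerate(introns):
                d_alt = _alt_site_distance(plan, k, si)
                effective[k] = _finalize_intron(
                    intron,
                    d_alt,
                    _alt_side(plan, k),
                    plan.tract[k],
                    plan.branch[k],
                    derived_rng(cfg.seed, "genome", plan.index * 97 + k * 7 + si),
                    ptc_segment=seg_by_intron.get(k),
                )
            if plan.designed:
                _verify_designed(plan, exons, introns, si, sp)

            sense = "".join(
                "".join(exons[i]) + ("".join(introns[i]) if i < len(introns) else "")
                for i in range(len(exons))
            )
            glen = len(sense)
            gstart = offset + len(spacer)

            def to_genomic(s: int, e: int) -> tuple[int, int]:
                if plan.strand == "+":
                    return gstart + s, gstart + e
                return gstart + glen - e, gstart + glen - s

            # sense-space exon/intron coordinates
            sense_exons = []
            pos = 0
            sense_introns = []
            for i, L in enumerate(plan.exon_lens):
                sense_exons.append((pos, pos + L))
                pos += L
                if i < len(plan.intron_lens):
                    sense_introns.append((pos, pos + plan.intron_lens[i]))
                    pos += plan.intron_lens[i]

            gm = GeneModel(gene_id=gid, chrom=chrom, strand=plan.strand)
            t1 = TranscriptRecord(f"{gid}.t1", sorted(to_genomic(s, e) for s, e in sense_exons))
            gm.transcripts[t1.transcript_id] = t1
            gm.exons = list(t1.exons)

            present_events = [
                ev for ev in plan.events if ev.present_in(si, sp)
            ]
            for ti, ev in enumerate(present_events, start=2):
                minor = _minor_isoform_sense(sense_exons, sense_introns, ev, plan)
                rec = TranscriptRecord(
                    f"{gid}.t{ti}", sorted(to_genomic(s, e) for s, e in minor)
                )
                gm.transcripts[rec.transcript_id] = rec
            models[gid] = gm

            prots[gid] = _protein(sense, plan)

            # junction rows: constitutive support for every intron, event
            # counts overriding where planted
            intron_counts: dict[int, dict] = {}
            for ev in present_events:
                inc, exc = emit_junction_counts(ev.psi, cfg.depth, rng_counts)
                intron_counts[ev.intron_index] = {"event": ev, "inc": inc, "exc": exc}
                truth_rows.append(
                    _truth_row(sp, gid, chrom, plan, ev, to_genomic, sense_introns, inc, exc)
                )
            for k, (s, e) in enumerate(sense_introns):
                a, b = to_genomic(s, e)
                info = intron_counts.get(k)
                reads = int(rng_counts.poisson(cfg.depth))
                coverage = 0
                if info is not None:
                    ev = info["event"]
                    if ev.as_type == "IR":
                        reads, coverage = info["exc"], info["inc"]
                    elif ev.as_type in ("AltA", "AltD"):
                        reads = info["inc"]
                    elif ev.as_type == "ES":
                        reads = info["inc"] - info["inc"] // 2
                elif k > 0 and (k - 1) in intron_counts and intron_counts[k - 1][
                    "event"
                ].as_type == "ES":
                    reads = intron_counts[k - 1]["inc"] // 2
                junction_rows[sp].append(
                    {
                        "chrom": chrom,
                        "intron_start": a,
                        "intron_end": b,
                        "strand": plan.strand,
                        "reads": reads,
                        "min_overhang": SYN_OVERHANG,
                        "intron_coverage": coverage,
                    }
                )
                ev_here = (
                    intron_counts[k]["event"]
                    if k in intron_counts
                    else (
                        intron_counts[k - 1]["event"]
                        if k > 0
                        and (k - 1) in intron_counts
                        and intron_counts[k - 1]["event"].as_type == "ES"
                        else None
                    )
                )
                junction_truth_rows.append(
                    {
                        "species": sp,
                        "gene_id": gid,
                        "chrom": chrom,
                        "start": a,
                        "end": b,
                        "strand": plan.strand,
                        "intron_index": k,
                        "d_planted": _alt_site_distance(plan, k, si),
                        "has_as": ev_here is not None,
                        "as_type": ev_here.as_type if ev_here is not None else "none",
                        "tract_planted": effective[k][0],
                        "branch_planted": effective[k][1],
                    }
                )
            # minor-isoform junction rows for two-junction events
            for k, info in intron_counts.items():
                ev = info["event"]
                s, e = sense_introns[k]
                if ev.as_type == "AltA":
                    alt = (s, e - _alt_site_distance(plan, k, si))
                elif ev.as_type == "AltD":
                    alt = (s + _alt_site_distance(plan, k, si), e)
                elif ev.as_type == "ES":
                    alt = (s, sense_introns[k + 1][1])
                else:
                    continue
                a, b = to_genomic(*alt)
                junction_rows[sp].append(
                    {
                        "chrom": chrom,
                        "intron_start": a,
                        "intron_end": b,
                        "strand": plan.strand,
                        "reads": info["exc"],
                        "min_overhang": SYN_OVERHANG,
                        "intron_coverage": 0,
                    }
                )
            offset = gstart + glen
            parts.append(spacer)
            parts.append(sense if plan.strand == "+" else revcomp(sense))
        genomes[sp] = {chrom: "".join(parts) + spacer}
        gene_models[sp] = models
        proteins[sp] = prots
        if cfg.emit_decoys:
            first = plans[0]
            s, e = 100 + first.exon_lens[0], 100 + first.exon_lens[0] + first.intron_lens[0]
            junction_rows[sp].append(
                {
                    "chrom": "chr1",
                    "intron_start": s,
                    "intron_end": e,
                    "strand": first.strand,
                    "reads": 20,
                    "min_overhang": 10,  # sub-threshold overhang decoy
                    "intron_coverage": 0,
                }
            )
            junction_rows[sp].append(
                {
                    "chrom": "chr1",
                    "intron_start": s,
                    "intron_end": s + 40,  # sub-minimum intron length decoy
                    "strand": first.strand,
                    "reads": 20,
                    "min_overhang": SYN_OVERHANG,
                    "intron_coverage": 0,
                }
            )

    # orthologs and conservation labels (reference species vs each other)
    for si in range(1, cfg.n_species):
        sp = species[si]
        for plan in plans:
            ga, gb = f"sp0_g{plan.index:04d}", f"{sp}_g{plan.index:04d}"
            ortholog_rows.append({"species_b": sp, "gene_a": ga, "gene_b": gb})
            gm_a, gm_b = gene_models["sp0"][ga], gene_models[sp][gb]
            introns_a, introns_b = gm_a.introns, gm_b.introns
            for ev in plan.events:
                # gene.introns is in genomic order; the plan indexes introns
                # in sense (5'->3') order
                k = ev.intron_index
                if plan.strand == "-":
                    k = len(introns_a) - 1 - k
                conservation_rows.append(
                    {
                        "species_a": "sp0",
                        "species_b": sp,
                        "gene_a": ga,
                        "gene_b": gb,
                        "a_start": introns_a[k][0],
                        "a_end": introns_a[k][1],
                        "b_start": introns_b[k][0],
                        "b_end": introns_b[k][1],
                        "strand": plan.strand,
                        "as_type": ev.as_type,
                        "label": ev.labels.get(sp, "conserved"),
                    }
                )

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "event_id",
            "species",
            "gene_id",
            "chrom",
            "strand",
            "as_type",
            "authentic_start",
            "authentic_end",
            "alt_start",
            "alt_end",
            "true_psi",
            "inclusion",
            "exclusion",
            "distance",
            "ptc",
            "designed",
        ],
    )
    return SyntheticCohort(
        config=cfg,
        species=species,
        genomes=genomes,
        gene_models=gene_models,
        proteins=proteins,
        junction_tables={
            sp: pd.DataFrame(
                junction_rows[sp],
                columns=[
                    "chrom",
                    "intron_start",
                    "intron_end",
                    "strand",
                    "reads",
                    "min_overhang",
                    "intron_coverage",
                ],
            )
            for sp in species
        },
        orthologs=pd.DataFrame(ortholog_rows, columns=["species_b", "gene_a", "gene_b"]),
        truth=truth,
        junction_truth=pd.DataFrame(junction_truth_rows),
        conservation=pd.DataFrame(
            conservation_rows,
            columns=[
                "species_a",
                "species_b",
                "gene_a",
                "gene_b",
                "a_start",
                "a_end",
                "b_start",
                "b_end",
                "strand",
                "as_type",
                "label",
            ],
        ),
    )


def _minor_isoform_sense(sense_exons, sense_introns, ev: _EventPlan, plan: _GenePlan):
    k = ev.intron_index
    d = plan.d_ref[k] if ev.ptc is not None else None
    exons = list(sense_exons)
    s, e = sense_introns[k]
    if ev.as_type == "AltA":
        dd = plan.d_ref[k]
        exons[k + 1] = (e - dd, exons[k + 1][1])
    elif ev.as_type == "AltD":
        dd = plan.d_ref[k]
        exons[k] = (exons[k][0], s + dd)
    elif ev.as_type == "ES":
        exons = exons[: k + 1] + exons[k + 2 :]
    elif ev.as_type == "IR":
        exons = exons[:k] + [(exons[k][0], exons[k + 1][1])] + exons[k + 2 :]
    return exons


def _truth_row(sp, gid, chrom, plan, ev, to_genomic, sense_introns, inc, exc):
    k = ev.intron_index
    s, e = sense_introns[k]
    if ev.as_type == "AltA":
        alt = (s, e - plan.d_ref[k])
    elif ev.as_type == "AltD":
        alt = (s + plan.d_ref[k], e)
    elif ev.as_type == "ES":
        alt = (s, sense_introns[k + 1][1])
    else:
        alt = None
    a, b = to_genomic(s, e)
    if alt is not None:
        aa, ab = to_genomic(*alt)
    else:
        aa, ab = -1, -1
    return {
        "event_id": f"g{plan.index:04d}_i{k}",
        "species": sp,
        "gene_id": gid,
        "chrom": chrom,
        "strand": plan.strand,
        "as_type": ev.as_type,
        "authentic_start": a,
        "authentic_end": b,
        "alt_start": aa,
        "alt_end": ab,
        "true_psi": ev.psi,
        "inclusion": inc,
        "exclusion": exc,
        "distance": plan.d_ref[k],
        "ptc": ev.ptc if ev.ptc is not None else None,
        "designed": ev.ptc is not None,
    }


def _design_coding(plan: _GenePlan, exons, introns, cfg: CohortConfig, si: int):
    """Overwrite exon sequence with a designed coding frame and return the
    gained segment for the designed AltA event.

    The major isoform carries ATG..stop with the stop inside the final exon
    (no PTC); the minor isoform of the designed event gains ``d`` intronic
    bases that either contain stops in every frame (PTC+) or continue the
    frame cleanly (PTC-).  Construction is verified and re-randomized until
    both guarantees hold.
    """
    ev = plan.designed_event
    assert ev is not None
    k = ev.intron_index
    d = plan.d_ref[k]
    rng = derived_rng(cfg.seed, "genome", 10_000 + plan.index)
    safe_codons = [
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in ("TAA", "TAG", "TGA", "ATG")
    ]
    for _attempt in range(60):
        mature_len = sum(len(e) for e in exons)
        orf_start = 3
        final_exon_start = mature_len - len(exons[-1])
        stop_pos = final_exon_start + 9
        stop_pos -= (stop_pos - orf_start) % 3  # in frame
        coding = ["A", "T", "G"]
        while orf_start + len(coding) < stop_pos:
            coding.extend(rng.choice(safe_codons))
        coding = coding[: stop_pos - orf_start] + ["T", "A", "A"]
        mature = (
            _random_seq(rng, orf_start)
            + coding
            + _random_seq(rng, mature_len - orf_start - len(coding))
        )
        pos = 0
        for i in range(len(exons)):
            L = len(exons[i])
            exons[i][:] = mature[pos : pos + L]
            pos += L
        seg_mature_pos = sum(len(e) for e in exons[: k + 1])
        phase = (seg_mature_pos - orf_start) % 3
        seg = _designed_segment(d, bool(ev.ptc), (3 - phase) % 3, rng)
        if _check_designed(plan, exons, seg):
            return exons, seg
    raise GenerationError(
        f"could not satisfy the PTC construction for gene {plan.index}"
    )


def _check_designed(plan: _GenePlan, exons, seg) -> bool:
    ev = plan.designed_event
    assert ev is not None
    k = ev.intron_index
    major = "".join("".join(e) for e in exons)
    junctions_major = np.cumsum([len(e) for e in exons])[:-1]
    orf = _longest_orf_end(major)
    if orf is None or junctions_major[-1] - orf[1] >= 50:
        return False  # major isoform must not be NMD-flagged
    minor_parts = ["".join(e) for e in exons]
    minor_parts.insert(k + 1, "".join(seg))
    minor = "".join(minor_parts)
    jm = np.cumsum([len(p) for p in minor_parts])[:-1]
    orf_m = _longest_orf_end(minor)
    if orf_m is None:
        return False
    is_ptc = jm[-1] - orf_m[1] >= 50
    return is_ptc == bool(ev.ptc)


def _verify_designed(plan: _GenePlan, exons, introns, si: int, sp: str) -> None:
    ev = plan.designed_event
    if ev is None or not ev.present_in(si, sp):
        return
    k = ev.intron_index
    d = plan.d_ref[k]
    seg = introns[k][-d:]
    if not _check_designed(plan, exons, seg):
        raise GenerationError(
            f"designed PTC event failed verification in {sp} gene {plan.index}"
        )


def _protein(sense: str, plan: _GenePlan) -> str:
    mature = sense
    # proteins are used only for ortholog detection; translate the mature
    # major isoform (frame 0) with stops masked
    exon_seq = []
    pos = 0
    for i, L in enumerate(plan.exon_lens):
        exon_seq.append(mature[pos : pos + L])
        pos += L
        if i < len(plan.intron_lens):
            pos += plan.intron_lens[i]
    cds = "".join(exon_seq)
    cds = cds[: (len(cds) // 3) * 3]
    return str(Seq(cds).translate()).replace("*", "X")


def simulate_psi_profiles(
    n_events: int = 300,
    n_species: int = 2,
    n_tissues: int = 2,
    species_sd: float = 1.5,
    tissue_sd: float = 0.1,
    depth: float = 200.0,
    seed: int = 0,
) -> pd.DataFrame:
    """PSI matrix (events x samples) with controlled species/tissue structure.

    Each event has a baseline PSI; species and tissue effects are additive
    on the logit scale with the given standard deviations, and observed PSI
    is re-estimated from binomially sampled junction counts.  Entries with
    fewer than 10 supporting reads are missing.  With
    ``species_sd > tissue_sd`` samples cluster by species; inverting the
    two flips the structure.
    """
    rng = derived_rng(seed, "counts", 999_983)
    cols = [f"sp{s}_t{t}" for s in range(n_species) for t in range(n_tissues)]
    base = rng.uniform(0.15, 0.85, size=n_events)
    sp_eff = rng.normal(0.0, species_sd, size=(n_events, n_species))
    ti_eff = rng.normal(0.0, tissue_sd, size=(n_events, n_tissues))
    logit = np.log(base / (1 - base))
    out = np.full((n_events, len(cols)), np.nan)
    for ci, col in enumerate(cols):
        s, t = int(col[2]), int(col[-1])
        psi = 1.0 / (1.0 + np.exp(-(logit + sp_eff[:, s] + ti_eff[:, t])))
        for ei in range(n_events):
            inc, exc = emit_junction_counts(float(psi[ei]), depth, rng)
            if inc + exc >= 10:
                out[ei, ci] = inc / (inc + exc)
    return pd.DataFrame(out, columns=cols, index=[f"ev{i}" for i in range(n_events)])


# ---------------------------------------------------------------------------
# bundle I/O


def write_bundle(cohort: SyntheticCohort, out_dir: str | Path) -> list[Path]:
    out = Path(out_dir)
    written: list[Path] = []
    try:
        out.mkdir(parents=True, exist_ok=True)
        for sp in cohort.species:
            spd = out / sp
            spd.mkdir(exist_ok=True)
            write_fasta(cohort.genomes[sp], spd / "genome.fa")
            write_fasta(cohort.proteins[sp], spd / "proteins.fa")
            write_gff3(cohort.gene_models[sp], spd / "genes.gff3")
            write_junction_table(cohort.junction_tables[sp], spd / "junctions.tsv")
            written += [
                spd / "genome.fa",
                spd / "proteins.fa",
                spd / "genes.gff3",
                spd / "junctions.tsv",
            ]
        write_tsv(cohort.orthologs, out / "orthologs.tsv")
        write_tsv(cohort.truth, out / "truth.tsv")
        write_tsv(cohort.junction_truth, out / "junction_truth.tsv")
        write_tsv(cohort.conservation, out / "conservation.tsv")
        (out / "config.json").write_text(json.dumps(dataclasses.asdict(cohort.config), indent=1))
        (out / "species.json").write_text(json.dumps(cohort.species))
        written += [
            out / "orthologs.tsv",
            out / "truth.tsv",
            out / "junction_truth.tsv",
            out / "conservation.tsv",
            out / "config.json",
        ]
    except OSError as exc:
        raise OSError(f"failed writing bundle under {out_dir}: {exc}") from exc
    return written


def read_bundle(out_dir: str | Path) -> SyntheticCohort:
    out = Path(out_dir)
    raw = json.loads((out / "config.json").read_text())
    for key in ("exons_per_gene", "exon_len", "intron_len", "psi_range"):
        raw[key] = tuple(raw[key])
    cfg = CohortConfig(**raw)
    species = json.loads((out / "species.json").read_text())
    genomes, models, prots, jts = {}, {}, {}, {}
    for sp in species:
        spd = out / sp
        genomes[sp] = read_fasta(spd / "genome.fa")
        prots[sp] = read_fasta(spd / "proteins.fa")
        models[sp] = read_gff3(spd / "genes.gff3")
        jts[sp] = read_junction_table(spd / "junctions.tsv")
    truth = read_tsv(out / "truth.tsv")
    if "ptc" in truth.columns:
        truth["ptc"] = truth["ptc"].map(
            lambda v: None if pd.isna(v) else bool(v), na_action=None
        )
    return SyntheticCohort(
        config=cfg,
        species=species,
        genomes=genomes,
        gene_models=models,
        proteins=prots,
        junction_tables=jts,
        orthologs=read_tsv(out / "orthologs.tsv"),
        truth=truth,
        junction_truth=read_tsv(out / "junction_truth.tsv"),
        conservation=read_tsv(out / "conservation.tsv"),
    )
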