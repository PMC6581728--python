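"""Junction evidence handling: loading/filtering, AS event classification, PSI.

Event definitions (strand-aware; "donor" is the 5' end of the intron on the
sense strand):

* AltD -- two junctions sharing the acceptor, differing at the donor
* AltA -- two junctions sharing the donor, differing at the acceptor
* ES   -- a junction whose intron spans a full annotated exon that is
          included by a pair of flanking junctions
* IR   -- a junction with both spliced reads and intron-coverage evidence

PSI = inclusion / (inclusion + exclusion), defined only when at least 10
reads support the event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .io import GeneModel, MalformedInputError, read_junction_table

logger = logging.getLogger(__name__)

AS_TYPES = ("IR", "AltD", "AltA", "ES")

MIN_EVENT_READS = 10  # events below this total support have undefined PSI
DEFAULT_MIN_OVERHANG = 13
DEFAULT_INTRON_BOUNDS = (41, 50000)


@dataclass(frozen=True)
class Junction:
    """One intron-spanning piece of evidence.

    ``start``/``end`` delimit the intron as a 0-based half-open interval.
    """

    chrom: str
    start: int
    end: int
    strand: str
    reads: int
    min_overhang: int
    intron_coverage: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def donor(self) -> int:
        """Genomic coordinate of the 5' intron end on the sense strand."""
        return self.start if self.strand == "+" else self.end

    @property
    def acceptor(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.strand)


@dataclass
class ASEvent:
    event_id: str
    gene_id: str
    type: str
    authentic: Junction
    alternative: Optional[Junction]
    inclusion_reads: int
    exclusion_reads: int
    sample_id: str = "sample"

    @property
    def support(self) -> int:
        """Total supporting reads (the >=10-read filter operates on this)."""
        return self.inclusion_reads + self.exclusion_reads

    @property
    def psi(self) -> Optional[float]:
        return compute_psi(self)


def compute_psi(event: ASEvent) -> Optional[float]:
    """PSI = inclusion/(inclusion+exclusion); None below 10 total reads."""
    total = event.inclusion_reads + event.exclusion_reads
    if total < MIN_EVENT_READS:
        return None
    return event.inclusion_reads / total


def load_junctions(
    path: str | Path,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
    intron_bounds: tuple[int, int] = DEFAULT_INTRON_BOUNDS,
) -> list[Junction]:
    """Load a junction TSV, merge duplicates, and apply the quality filters.

    Duplicate rows (same chrom/start/end/strand) are merged by summing
    ``reads`` and ``intron_coverage`` and keeping the largest observed
    overhang.  Junctions with overhang below ``min_overhang`` or intron
    length outside ``intron_bounds`` are removed.
    """
    df = read_junction_table(path)
    return filter_junctions(_merge_duplicates(df), min_overhang, intron_bounds)


def _merge_duplicates(df: pd.DataFrame) -> list[Junction]:
    merged: dict[tuple, Junction] = {}
    for row in df.itertuples(index=False):
        j = Junction(
            chrom=str(row.chrom),
            start=int(row.intron_start),
            end=int(row.intron_end),
            strand=str(row.strand),
            reads=int(row.reads),
            min_overhang=int(row.min_overhang),
            intron_coverage=int(row.intron_coverage),
        )
        if j.end <= j.start:
            raise MalformedInputError(f"intron end <= start at {j.chrom}:{j.start}")
        if j.key in merged:
            prev = merged[j.key]
            merged[j.key] = replace(
                prev,
                reads=prev.reads + j.reads,
                intron_coverage=prev.intron_coverage + j.intron_coverage,
                min_overhang=max(prev.min_overhang, j.min_overhang),
            )
        else:
            merged[j.key] = j
    return list(merged.values())


def filter_junctions(
    junctions: Iterable[Junction],
    min_overhang: int = DEFAULT_MIN_OVERHANG,
    intron_bounds: tuple[int, int] = DEFAULT_INTRON_BOUNDS,
) -> list[Junction]:
    lo, hi = intron_bounds
    return [
        j
        for j in junctions
        if j.min_overhang >= min_overhang and lo <= j.length <= hi
    ]


def _assign_to_genes(
    junctions: Iterable[Junction], gene_models: dict[str, GeneModel]
) -> dict[str, list[Junction]]:
    """Coordinate/strand overlap assignment; ambiguous junctions are skipped."""
    by_gene: dict[str, list[Junction]] = {}
    for j in junctions:
        hits = [
            g.gene_id
            for g in gene_models.values()
            if g.chrom == j.chrom
            and g.strand == j.strand
            and j.start >= g.start
            and j.end <= g.end
        ]
        if len(hits) == 1:
            by_gene.setdefault(hits[0], []).append(j)
        elif not hits:
            logger.info("junction %s overlaps no gene; skipped", j.key)
        else:
            logger.info("junction %s overlaps %d genes; skipped", j.key, len(hits))
    return by_gene


def classify_as_events(
    junctions: Iterable[Junction],
    gene_models: dict[str, GeneModel],
    sample_id: str = "sample",
) -> list[ASEvent]:
    """Classify AS events gene by gene.

    ES is detected first and its exclusion junction is consumed so the same
    junction pair is not double-reported as AltD/AltA.  For two-junction
    events the junction matching an annotated intron is "authentic"
    (inclusion isoform); if neither or both are annotated, the junction with
    more reads is taken as authentic.
    """
    events: list[ASEvent] = []
    by_gene = _assign_to_genes(junctions, gene_models)
    counter = 0
    for gene_id in sorted(by_gene):
        gene = gene_models[gene_id]
        js = sorted(by_gene[gene_id], key=lambda j: (j.start, j.end))
        # authenticity is judged against the reference (major) isoform only;
        # minor-isoform introns are the alternative junctions by definition
        annotated = set(gene.introns)
        consumed_es: set[tuple] = set()

        by_start: dict[int, list[Junction]] = {}
        by_end: dict[int, list[Junction]] = {}
        for j in js:
            by_start.setdefault(j.start, []).append(j)
            by_end.setdefault(j.end, []).append(j)

        # --- exon skipping: junction spanning a full annotated exon with
        # both inclusion junctions present
        gene_exons = sorted(set(gene.exons))
        for j in js:
            for estart, eend in gene_exons:
                if not (j.start < estart and eend < j.end):
                    continue
                # exon-spanning junctions are ES exclusion candidates and
                # never enter AltD/AltA pairing, even with partial evidence
                consumed_es.add(j.key)
                left = [x for x in by_end.get(estart, []) if x.start == j.start]
                right = [x for x in by_start.get(eend, []) if x.end == j.end]
                if left and right:
                    counter += 1
                    inc = left[0].reads + right[0].reads
                    # the event is anchored at the inclusion junction that
                    # shares its donor with the skip junction
                    anchor = left[0] if gene.strand == "+" else right[0]
                    events.append(
                        ASEvent(
                            event_id=f"{sample_id}:ev{counter}",
                            gene_id=gene_id,
                            type="ES",
                            authentic=anchor,
                            alternative=j,
                            inclusion_reads=inc,
                            exclusion_reads=j.reads,
                            sample_id=sample_id,
                        )
                    )
                    consumed_es.add(j.key)

        # --- Alt donor / Alt acceptor: pairs sharing one intron boundary
        def _emit_pairs(groups: dict[int, list[Junction]], shared_is_donor: bool):
            nonlocal counter
            for _, group in sorted(groups.items()):
                group = [g for g in group if g.key not in consumed_es]
                if len(group) < 2:
                    continue
                auth = _pick_authentic(group, annotated)
                for alt in group:
                    if alt.key == auth.key:
                        continue
                    # shared donor -> acceptors differ -> AltA; shared acceptor -> AltD
                    etype = "AltA" if shared_is_donor else "AltD"
                    counter += 1
                    events.append(
                        ASEvent(
                            event_id=f"{sample_id}:ev{counter}",
                            gene_id=gene_id,
                            type=etype,
                            authentic=auth,
                            alternative=alt,
                            inclusion_reads=auth.reads,
                            exclusion_reads=alt.reads,
                            sample_id=sample_id,
                        )
                    )

        if gene.strand == "+":
            _emit_pairs(by_start, shared_is_donor=True)
            _emit_pairs(by_end, shared_is_donor=False)
        else:
            _emit_pairs(by_start, shared_is_donor=False)
            _emit_pairs(by_end, shared_is_donor=True)

        # --- intron retention: spliced + intronic coverage evidence.
        # Inclusion isoform is the retained intron; total support is
        # junction reads + intron coverage.
        for j in js:
            if j.intron_coverage >= 1 and j.key not in consumed_es:
                counter += 1
                events.append(
                    ASEvent(
                        event_id=f"{sample_id}:ev{counter}",
                        gene_id=gene_id,
                        type="IR",
                        authentic=j,
                        alternative=None,
                        inclusion_reads=j.intron_coverage,
                        exclusion_reads=j.reads,
                        sample_id=sample_id,
                    )
                )
    return events


def _pick_authentic(group: list[Junction], annotated: set[tuple[int, int]]) -> Junction:
    ann = [j for j in group if (j.start, j.end) in annotated]
    pool = ann if len(ann) == 1 else group
    return max(pool, key=lambda j: (j.reads, -j.start, j.end))


def events_to_frame(events: Iterable[ASEvent]) -> pd.DataFrame:
    rows = []
    for e in events:
        rows.append(
            {
                "event_id": e.event_id,
                "gene_id": e.gene_id,
                "type": e.type,
                "chrom": e.authentic.chrom,
                "authentic_start": e.authentic.start,
                "authentic_end": e.authentic.end,
                "alt_start": e.alternative.start if e.alternative else -1,
                "alt_end": e.alternative.end if e.alternative else -1,
                "strand": e.authentic.strand,
                "inclusion": e.inclusion_reads,
                "exclusion": e.exclusion_reads,
                "psi": e.psi if e.psi is not None else float("nan"),
                "sample_id": e.sample_id,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "event_id",
            "gene_id",
            "type",
            "chrom",
            "authentic_start",
            "authentic_end",
            "alt_start",
            "alt_end",
            "strand",
            "inclusion",
            "exclusion",
            "psi",
            "sample_id",
        ],
    )
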