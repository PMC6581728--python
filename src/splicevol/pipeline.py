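"""Convenience wiring of the pipeline stages over synthetic cohorts.

These helpers run the real analysis modules (never the ground truth) on a
:class:`~splicevol.syn_data.SyntheticCohort`, and are shared by the test
suite and the acceptance report.
"""

from __future__ import annotations

import pandas as pd

from . import features as feat
from . import models as mdl
from . import orthology as orth
from .junctions import ASEvent, Junction, classify_as_events, filter_junctions
from .syn_data import SyntheticCohort


def junctions_from_frame(df: pd.DataFrame, apply_filters: bool = True) -> list[Junction]:
    js = [
        Junction(
            chrom=str(r.chrom),
            start=int(r.intron_start),
            end=int(r.intron_end),
            strand=str(r.strand),
            reads=int(r.reads),
            min_overhang=int(r.min_overhang),
            intron_coverage=int(r.intron_coverage),
        )
        for r in df.itertuples(index=False)
    ]
    return filter_junctions(js) if apply_filters else js


def junction_id(j: Junction) -> str:
    return f"{j.chrom}:{j.start}-{j.end}:{j.strand}"


def species_junctions(cohort: SyntheticCohort, species: str) -> list[Junction]:
    return junctions_from_frame(cohort.junction_tables[species])


def species_events(cohort: SyntheticCohort, species: str) -> list[ASEvent]:
    return classify_as_events(
        species_junctions(cohort, species), cohort.gene_models[species], sample_id=species
    )


def species_eejs(cohort: SyntheticCohort, species: str) -> list[orth.EEJSequence]:
    genes = cohort.gene_models[species]
    genome = cohort.genomes[species]
    out = []
    for j in species_junctions(cohort, species):
        hits = [
            g
            for g in genes.values()
            if g.chrom == j.chrom and g.strand == j.strand and g.start <= j.start and j.end <= g.end
        ]
        if len(hits) != 1:
            continue
        try:
            out.append(orth.extract_eej_sequence(genome, hits[0], j))
        except orth.EEJContextError:
            continue
    return out


def find_minor_transcript(gene, alt_start: int, alt_end: int):
    """The isoform whose intron set contains the given alternative junction
    (AltD/AltA/ES), or whose exons bridge it (IR)."""
    for tid, rec in gene.transcripts.items():
        ex = sorted(rec.exons)
        introns = {(ex[i][1], ex[i + 1][0]) for i in range(len(ex) - 1)}
        if (alt_start, alt_end) in introns:
            return rec
    return None


def conservation_labels(
    cohort: SyntheticCohort, species_a: str = "sp0", species_b: str = "sp1"
) -> list[orth.ConservationLabel]:
    """Full cross-species path: orthologs -> EEJ matching -> labels."""
    pairs = orth.find_orthologs(cohort.proteins[species_a], cohort.proteins[species_b])
    matches = orth.match_eejs(
        species_eejs(cohort, species_a), species_eejs(cohort, species_b), pairs
    )
    return orth.call_conservation(
        matches, species_events(cohort, species_a), species_events(cohort, species_b)
    )


def feature_matrix(
    cohort: SyntheticCohort, species: str, side: str, all_genes: bool = False
) -> pd.DataFrame:
    js = species_junctions(cohort, species)
    ctx = feat.FeatureContext(
        genome=cohort.genomes[species], gene_models=cohort.gene_models[species]
    )
    return feat.build_feature_matrix(
        species_events(cohort, species), js, ctx, side=side, all_genes=all_genes
    )


def conservation_dataset(
    cohort: SyntheticCohort, side: str = "AltA", species_a: str = "sp0", species_b: str = "sp1"
) -> pd.DataFrame:
    """Per-ortholog-pair feature differences labeled with the planted
    conservation states (features are measured, labels are ground truth)."""
    rows = {}
    flanks = {}
    for sp in (species_a, species_b):
        rows[sp] = feature_matrix(cohort, sp, side, all_genes=True)
        ctx = feat.FeatureContext(
            genome=cohort.genomes[sp], gene_models=cohort.gene_models[sp]
        )
        flanks[sp] = {
            junction_id(j): ctx.flank(j, "up", 50) + ctx.flank(j, "down", 50)
            for j in species_junctions(cohort, sp)
        }
    cons = cohort.conservation
    cons = cons[(cons["species_a"] == species_a) & (cons["species_b"] == species_b)]
    pairs = [
        (
            f"chr1:{r.a_start}-{r.a_end}:{r.strand}",
            f"chr1:{r.b_start}-{r.b_end}:{r.strand}",
            r.label,
        )
        for r in cons.itertuples()
    ]
    return mdl.build_conservation_dataset(
        rows[species_a], rows[species_b], pairs, flanks[species_a], flanks[species_b]
    )
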