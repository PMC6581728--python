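"""Readers and writers for the plain-text interchange formats.

FASTA goes through Biopython; GFF3 and the junction/ground-truth TSV
dialects are simple enough that they are parsed directly (strict about the
columns this package emits).

Coordinate conventions: internally everything is 0-based half-open; GFF3
output converts to 1-based inclusive at the boundary.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

JUNCTION_COLUMNS = [
    "chrom",
    "intron_start",
    "intron_end",
    "strand",
    "reads",
    "min_overhang",
    "intron_coverage",
]


class MalformedInputError(ValueError):
    """Raised for rows that violate the declared TSV dialect."""


@dataclass
class TranscriptRecord:
    """One isoform: ordered exon blocks in genomic coordinates (0-based half-open)."""

    transcript_id: str
    exons: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    transcripts: dict[str, TranscriptRecord] = field(default_factory=dict)

    @property
    def start(self) -> int:
        return min(s for s, _ in self.exons)

    @property
    def end(self) -> int:
        return max(e for _, e in self.exons)

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons, genomic order."""
        ex = sorted(self.exons)
        return [(ex[i][1], ex[i + 1][0]) for i in range(len(ex) - 1)]


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def _gff3_attributes(raw: str) -> dict[str, str]:
    out = {}
    for item in raw.strip().split(";"):
        if item and "=" in item:
            key, value = item.split("=", 1)
            out[key] = value
    return out


def read_gff3(path: str | Path) -> dict[str, GeneModel]:
    """Parse gene/mRNA/exon features into :class:`GeneModel` objects."""
    genes: dict[str, GeneModel] = {}
    tx_to_gene: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise MalformedInputError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _, ftype, start, end, _, strand, _, attrs = fields
            start0, end0 = int(start) - 1, int(end)  # to 0-based half-open
            attributes = _gff3_attributes(attrs)
            if ftype == "gene":
                gid = attributes["ID"]
                genes[gid] = GeneModel(gene_id=gid, chrom=chrom, strand=strand)
            elif ftype == "mRNA":
                tid = attributes["ID"]
                gid = attributes["Parent"]
                tx_to_gene[tid] = gid
                genes[gid].transcripts[tid] = TranscriptRecord(transcript_id=tid)
            elif ftype == "exon":
                tid = attributes["Parent"]
                gid = tx_to_gene[tid]
                genes[gid].transcripts[tid].exons.append((start0, end0))
    for gene in genes.values():
        for tx in gene.transcripts.values():
            tx.exons.sort()
        # gene-level exons follow the first listed (reference) isoform
        if gene.transcripts:
            first = next(iter(gene.transcripts.values()))
            gene.exons = sorted(first.exons)
    return genes


def write_gff3(genes: dict[str, GeneModel], path: str | Path) -> None:
    buf = _stdio.StringIO()
    buf.write("##gff-version 3\n")
    for gene in genes.values():
        buf.write(
            f"{gene.chrom}\tsplicevol\tgene\t{gene.start + 1}\t{gene.end}\t.\t"
            f"{gene.strand}\t.\tID={gene.gene_id}\n"
        )
        for tx in gene.transcripts.values():
            tstart = min(s for s, _ in tx.exons)
            tend = max(e for _, e in tx.exons)
            buf.write(
                f"{gene.chrom}\tsplicevol\tmRNA\t{tstart + 1}\t{tend}\t.\t"
                f"{gene.strand}\t.\tID={tx.transcript_id};Parent={gene.gene_id}\n"
            )
            for start, end in sorted(tx.exons):
                buf.write(
                    f"{gene.chrom}\tsplicevol\texon\t{start + 1}\t{end}\t.\t"
                    f"{gene.strand}\t.\tParent={tx.transcript_id}\n"
                )
    Path(path).write_text(buf.getvalue())


def read_junction_table(path: str | Path) -> pd.DataFrame:
    """Read the junction TSV dialect; validates columns and count signs."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    missing = [c for c in JUNCTION_COLUMNS if c not in df.columns]
    if missing:
        raise MalformedInputError(f"{path}: missing columns {missing}")
    for col in ("reads", "min_overhang", "intron_coverage"):
        bad = df.index[df[col] < 0]
        if len(bad):
            raise MalformedInputError(f"{path}: negative {col} at line {bad[0] + 2}")
    if not df["strand"].isin(["+", "-"]).all():
        raise MalformedInputError(f"{path}: strand must be + or -")
    return df


def write_junction_table(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, JUNCTION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
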