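"""Sequence/annotation I/O and gene-model handling.

All coordinates inside the package are 0-based half-open on the forward
genomic strand; conversion from GFF3's 1-based inclusive convention happens
once, at the parser boundary.  Promoters are measured from the annotated
translation start (ATG) on the coding strand.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "SeqRecord",
    "Promoter",
    "GeneModel",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "extract_promoter",
    "exon_count_table",
    "translate_cds",
]

DEFAULT_PROMOTER_LENGTH = 1500  # bp upstream of the ATG


@dataclass
class SeqRecord:
    """A named nucleotide or amino-acid sequence."""

    id: str
    seq: str
    alphabet: str = "dna"  # {"dna", "protein"}

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Promoter(SeqRecord):
    """Upstream regulatory sequence; ``truncated`` marks scaffold-edge clipping."""

    truncated: bool = False


@dataclass
class GeneModel:
    """A protein-coding gene: genomic location, exon/CDS layout and products.

    ``complete`` is False when the assembled CDS is not a clean ORF
    (length not a multiple of 3, or internal stop); such models are kept so
    family counts match the annotation, but divergence analyses refuse them.
    """

    gene_id: str
    seq_id: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds_regions: list[tuple[int, int]] = field(default_factory=list)
    cds: str = ""
    protein: str = ""
    complete: bool = True

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.end <= self.start:
            raise ValueError(f"{self.gene_id}: end must exceed start")
        for s, e in list(self.exons) + list(self.cds_regions):
            if e <= s:
                raise ValueError(f"{self.gene_id}: empty interval ({s},{e})")

    @property
    def exon_count(self) -> int:
        return len(self.exons)


def translate_cds(cds: str) -> str:
    """Translate a CDS with the standard code, dropping one trailing stop."""
    prot = str(Seq(cds[: len(cds) - len(cds) % 3]).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    return prot


def read_fasta(path: str | os.PathLike, alphabet: str = "dna") -> list[SeqRecord]:
    """Read a multi-FASTA file into upper-cased records, order preserved.

    Raises ``ValueError`` on duplicate IDs (naming the offender) and on an
    empty file, which almost always indicates a broken upstream step.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id!r}")
        seen.add(rec.id)
        records.append(SeqRecord(rec.id, str(rec.seq), alphabet))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: list[SeqRecord], path: str | os.PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def _genome_index(genome: list[SeqRecord]) -> dict[str, SeqRecord]:
    return {rec.id: rec for rec in genome}


def read_gff3(path: str | os.PathLike, genome: list[SeqRecord]) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS features into :class:`GeneModel` objects.

    One model is built per gene, from its first mRNA.  The CDS is assembled
    in transcription order and reverse-complemented for minus-strand genes.
    Models whose CDS length is not a multiple of 3 (or that contain an
    internal stop) are flagged ``complete=False`` rather than dropped.
    """
    import gffutils

    scaffolds = _genome_index(genome)
    # gffutils requires a file-backed or :memory: sqlite db
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        if not mrnas:
            continue
        mrna = mrnas[0]  # first isoform only, by design
        if gene.seqid not in scaffolds:
            raise ValueError(
                f"{gene.id}: scaffold {gene.seqid!r} absent from the supplied genome"
            )
        scaffold = scaffolds[gene.seqid].seq
        exons = sorted(
            (f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")
        )
        cds_regions = sorted(
            (f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS")
        )
        parts = [scaffold[s:e] for s, e in cds_regions]
        cds = "".join(parts)
        if gene.strand == "-":
            cds = str(Seq(cds).reverse_complement())
        complete = len(cds) % 3 == 0
        protein = ""
        if complete and cds:
            protein = translate_cds(cds)
            body = protein
            complete = "*" not in body
        models.append(
            GeneModel(
                gene_id=gene.id,
                seq_id=gene.seqid,
                start=gene.start - 1,
                end=gene.end,
                strand=gene.strand,
                exons=exons if exons else cds_regions,
                cds_regions=cds_regions,
                cds=cds,
                protein=protein,
                complete=complete,
            )
        )
    return models


def extract_promoter(
    model: GeneModel,
    genome: list[SeqRecord],
    length: int = DEFAULT_PROMOTER_LENGTH,
) -> Promoter:
    """Return up to ``length`` bp immediately 5' of the translation start.

    The promoter is reported on the coding strand (reverse-complemented for
    minus-strand genes).  A gene too close to the scaffold edge yields a
    shorter sequence with ``truncated=True``; a gene starting at position 0
    yields an empty, truncated promoter rather than an error.
    """
    scaffolds = _genome_index(genome)
    if model.seq_id not in scaffolds:
        raise ValueError(f"{model.gene_id}: scaffold {model.seq_id!r} not in genome")
    scaffold = scaffolds[model.seq_id].seq
    regions = model.cds_regions or model.exons or [(model.start, model.end)]
    if model.strand == "+":
        atg = min(s for s, _ in regions)
        lo = max(0, atg - length)
        seq = scaffold[lo:atg]
        truncated = atg - length < 0
    else:
        atg = max(e for _, e in regions)
        hi = min(len(scaffold), atg + length)
        seq = str(Seq(scaffold[atg:hi]).reverse_complement())
        truncated = atg + length > len(scaffold)
    return Promoter(id=model.gene_id, seq=seq, alphabet="dna", truncated=truncated)


def exon_count_table(
    models: list[GeneModel],
) -> tuple[dict[str, int], dict[int, int]]:
    """Per-gene exon counts plus the family-level histogram of counts."""
    counts = {m.gene_id: m.exon_count for m in models}
    histogram = dict(sorted(Counter(counts.values()).items()))
    return counts, histogram
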