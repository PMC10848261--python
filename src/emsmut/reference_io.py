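"""Reference genome, gene-model and codon-usage I/O.

Coordinates follow the field's file formats at the boundary (GFF3 and VCF
are 1-based inclusive); all public interval attributes here are 1-based
closed intervals, matching what the reports print.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Malformed input file."""


@dataclass
class Genome:
    """Named nucleotide sequences with length and composition access."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            bad = set(seq) - VALID_BASES
            if bad:
                raise FormatError(
                    f"contig {name!r} contains non-IUPAC characters: {sorted(bad)}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def fetch(self, contig: str, start: int, end: int) -> str:
        """1-based closed-interval slice of a contig."""
        return self.contigs[contig][start - 1 : end]

    def base_at(self, contig: str, pos: int) -> str:
        return self.contigs[contig][pos - 1]

    def gc_fraction(self, exclude_n: bool = True) -> float:
        gc = at = 0
        for seq in self.contigs.values():
            gc += seq.count("G") + seq.count("C")
            at += seq.count("A") + seq.count("T")
        denom = gc + at if exclude_n else self.total_length
        return gc / denom if denom else float("nan")


@dataclass
class GeneModel:
    """Strand-aware gene with ordered CDS segments and a promoter window.

    ``cds_segments`` are 1-based closed genomic intervals sorted in
    transcription order (descending genomic coordinates on the minus
    strand), each with its phase.
    """

    gene_id: str
    contig: str
    strand: str
    gene_span: tuple[int, int]
    cds_segments: list[tuple[int, int]]
    phases: list[int] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)
    promoter: tuple[int, int] | None = None

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)

    def contains(self, pos: int) -> bool:
        return self.gene_span[0] <= pos <= self.gene_span[1]

    def in_cds(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.cds_segments)

    def in_utr5(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.utr5)

    def in_utr3(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.utr3)

    def in_promoter(self, pos: int) -> bool:
        return self.promoter is not None and self.promoter[0] <= pos <= self.promoter[1]


@dataclass
class CodonUsageTable:
    """Relative synonymous codon usage, normalized within amino-acid groups."""

    usage: dict[str, float]
    by_aa: dict[str, list[str]]
    preferred: dict[str, str]

    def group_fraction(self, codon: str) -> float:
        return self.usage[codon]


def read_fasta(path: str | Path) -> Genome:
    """Load a FASTA file into memory, uppercasing all sequence.

    Duplicate headers are rejected; non-IUPAC characters raise FormatError.
    """
    contigs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in contigs:
            raise FormatError(f"duplicate FASTA header: {record.id!r}")
        contigs[record.id] = str(record.seq).upper()
    if not contigs:
        raise FormatError(f"no FASTA records found in {path}")
    return Genome(contigs)


def write_fasta(genome: Genome, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.contigs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def promoter_window(
    gene: GeneModel, size: int = 3000, contig_length: int | None = None
) -> tuple[int, int] | None:
    """Up to ``size`` bases immediately upstream (5') of the gene span.

    The window is truncated at the contig edge; a gene flush against the
    edge gets no promoter (None).
    """
    start, end = gene.gene_span
    if gene.strand == "+":
        lo, hi = max(1, start - size), start - 1
    else:
        lo, hi = end + 1, end + size
        if contig_length is not None:
            hi = min(hi, contig_length)
    if hi < lo:
        log.debug("gene %s promoter empty after edge truncation", gene.gene_id)
        return None
    return (lo, hi)


def read_gff3(
    path: str | Path, genome: Genome | None = None, promoter_size: int = 3000
) -> list[GeneModel]:
    """Parse gene/mRNA/CDS (+ optional UTR) features into GeneModels.

    One model per gene, taken from the first mRNA in file order when a gene
    has several transcripts. CDS segments are returned in transcription
    order; on the minus strand that is descending genomic coordinates.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        contig = gene.seqid
        if genome is not None and contig not in genome.contigs:
            raise FormatError(f"gene {gene.id} on unknown contig {contig!r}")
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        parent = mrnas[0] if mrnas else gene
        if len(mrnas) > 1:
            log.info("gene %s: %d mRNAs, using first (%s)", gene.id, len(mrnas), parent.id)
        cds = list(db.children(parent, featuretype="CDS", order_by="start"))
        segments = [(f.start, f.end) for f in cds]
        phases = []
        for f in cds:
            try:
                phases.append(int(f.frame))
            except (TypeError, ValueError):
                log.warning("gene %s: CDS missing phase, assuming 0", gene.id)
                phases.append(0)
        if genome is not None:
            clen = genome.lengths[contig]
            for s, e in segments:
                if s < 1 or e > clen:
                    raise FormatError(
                        f"gene {gene.id}: CDS {s}..{e} outside contig {contig} (len {clen})"
                    )
        utr5 = [
            (f.start, f.end)
            for f in db.children(parent, featuretype="five_prime_UTR", order_by="start")
        ]
        utr3 = [
            (f.start, f.end)
            for f in db.children(parent, featuretype="three_prime_UTR", order_by="start")
        ]
        if gene.strand == "-":
            segments = segments[::-1]
            phases = phases[::-1]
        model = GeneModel(
            gene_id=gene.id,
            contig=contig,
            strand=gene.strand,
            gene_span=(gene.start, gene.end),
            cds_segments=segments,
            phases=phases,
            utr5=utr5,
            utr3=utr3,
        )
        clen = genome.lengths[contig] if genome is not None else None
        model.promoter = promoter_window(model, promoter_size, contig_length=clen)
        models.append(model)
    return models


def extract_cds_sequence(genome: Genome, gene: GeneModel) -> str:
    """Spliced, strand-corrected coding sequence of a gene.

    Segments are concatenated in transcription order; minus-strand genes
    are reverse-complemented. A length not divisible by 3 is an error.
    """
    if gene.contig not in genome.contigs:
        raise KeyError(f"contig {gene.contig!r} not in genome")
    if gene.strand == "+":
        seq = "".join(genome.fetch(gene.contig, s, e) for s, e in gene.cds_segments)
    else:
        seq = "".join(
            reverse_complement(genome.fetch(gene.contig, s, e))
            for s, e in gene.cds_segments
        )
    if len(seq) % 3 != 0:
        raise FormatError(
            f"gene {gene.gene_id}: CDS length {len(seq)} not divisible by 3"
        )
    return seq


# amino-acid grouping of codons under the standard genetic code comes from
# codon_model to keep a single source of truth for the code
def read_codon_usage(path: str | Path) -> CodonUsageTable:
    """Read a ``codon<TAB>frequency`` table and normalize within AA groups.

    Accepts raw counts or per-thousand frequencies (any non-negative
    scale); only within-amino-acid proportions matter downstream. Ties for
    the preferred codon break to the lexicographically smallest codon.
    """
    from .codon_model import CODON_TO_AA, SENSE_CODONS, STOP_CODONS

    raw: dict[str, float] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if i == 0 and parts[0].lower() in {"codon"}:
                continue
            if len(parts) < 2:
                raise FormatError(f"codon-usage line {i + 1}: expected 2 columns")
            codon = parts[0].upper().replace("U", "T")
            freq = float(parts[1])
            if freq < 0:
                raise FormatError(f"negative usage frequency for {codon}")
            raw[codon] = freq
    missing = (SENSE_CODONS | STOP_CODONS) - set(raw)
    if missing:
        raise FormatError(f"codon-usage table missing codons: {sorted(missing)}")
    return build_usage_table(raw)


def build_usage_table(raw: dict[str, float]) -> CodonUsageTable:
    """Normalize raw codon weights within each amino-acid group."""
    from .codon_model import CODON_TO_AA

    by_aa: dict[str, list[str]] = {}
    for codon, aa in sorted(CODON_TO_AA.items()):
        if aa == "*":
            continue
        by_aa.setdefault(aa, []).append(codon)
    usage: dict[str, float] = {}
    preferred: dict[str, str] = {}
    for aa, codons in by_aa.items():
        total = sum(raw.get(c, 0.0) for c in codons)
        if total == 0:
            # degenerate group: fall back to uniform
            for c in codons:
                usage[c] = 1.0 / len(codons)
        else:
            for c in codons:
                usage[c] = raw.get(c, 0.0) / total
        preferred[aa] = max(sorted(codons), key=lambda c: usage[c])
    return CodonUsageTable(usage=usage, by_aa=by_aa, preferred=preferred)


def write_codon_usage(table: CodonUsageTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("codon\tfrequency\n")
        for codon in sorted(table.usage):
            fh.write(f"{codon}\t{table.usage[codon]:.6f}\n")
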