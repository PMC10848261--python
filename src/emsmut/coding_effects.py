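"""Region annotation, coding-effect classification, and gene-level summaries.

A variant gets exactly one region label under the precedence rule
CDS > UTR > intron > promoter > intergenic, applied across all overlapping
genes, so region percentages are mutually exclusive and sum to 100.
Coding effects are computed on the transcript strand: the codon carrying
the variant is located through the transcription-order CDS coordinates and
both the reference and mutated codon are translated with the standard code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from intervaltree import IntervalTree

from .codon_model import translate_codon
from .reference_io import COMPLEMENT, Genome, GeneModel, extract_cds_sequence
from .variant_io import Variant, VariantSet

log = logging.getLogger(__name__)

REGIONS = ("CDS", "five_prime_UTR", "three_prime_UTR", "intron", "promoter", "intergenic")
_PRECEDENCE = {r: i for i, r in enumerate(REGIONS)}

EFFECT_CLASSES = ("synonymous", "missense", "stop_gain", "stop_loss", "start_loss")


@dataclass
class RegionAnnotation:
    region: str
    gene_id: str | None = None
    overlapping_genes: list[str] = field(default_factory=list)


class GeneIndex:
    """Interval index over gene spans and promoter windows, per contig."""

    def __init__(self, genes: list[GeneModel]):
        self.genes = {g.gene_id: g for g in genes}
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            tree = self._trees.setdefault(g.contig, IntervalTree())
            lo, hi = g.gene_span
            if g.promoter is not None:
                lo, hi = min(lo, g.promoter[0]), max(hi, g.promoter[1])
            tree[lo : hi + 1] = g.gene_id  # half-open over 1-based coords

    def overlapping(self, contig: str, pos: int) -> list[GeneModel]:
        tree = self._trees.get(contig)
        if tree is None:
            return []
        return [self.genes[iv.data] for iv in sorted(tree[pos], key=lambda iv: iv.data)]


def _region_within_gene(pos: int, gene: GeneModel) -> str | None:
    if gene.in_cds(pos):
        return "CDS"
    if gene.in_utr5(pos):
        return "five_prime_UTR"
    if gene.in_utr3(pos):
        return "three_prime_UTR"
    if gene.contains(pos):
        return "intron"
    if gene.in_promoter(pos):
        return "promoter"
    return None


def annotate_region(variant: Variant, index: GeneIndex) -> RegionAnnotation:
    """Single region label for a variant under the precedence rule."""
    candidates = index.overlapping(variant.contig, variant.pos)
    best: tuple[int, str, str] | None = None
    for gene in candidates:
        region = _region_within_gene(variant.pos, gene)
        if region is None:
            continue
        rank = _PRECEDENCE[region]
        if best is None or rank < best[0]:
            best = (rank, region, gene.gene_id)
    if best is None:
        return RegionAnnotation("intergenic", None, [g.gene_id for g in candidates])
    return RegionAnnotation(best[1], best[2], [g.gene_id for g in candidates])


@dataclass
class CodingEffect:
    gene_id: str
    codon_index: int  # 1-based
    from_codon: str
    to_codon: str
    from_aa: str
    to_aa: str
    effect_class: str


def _cds_offset(pos: int, gene: GeneModel) -> int:
    """0-based offset of a genomic position within the spliced CDS."""
    offset = 0
    for s, e in gene.cds_segments:
        if s <= pos <= e:
            return offset + (pos - s if gene.strand == "+" else e - pos)
        offset += e - s + 1
    raise ValueError(f"position {pos} not in CDS of {gene.gene_id}")


def coding_effect(variant: Variant, gene: GeneModel, genome: Genome) -> CodingEffect:
    """Classify a CDS SNP as synonymous/missense/stop_gain/stop_loss/start_loss.

    The alternate allele is complemented on minus-strand genes before being
    substituted into the transcript-strand codon. Any non-synonymous change
    in codon 1 is a start_loss; a change in a stop codon producing a sense
    codon is a stop_loss.
    """
    if not variant.is_snp:
        raise ValueError("coding_effect is defined for SNPs")
    if not gene.in_cds(variant.pos):
        raise ValueError(f"variant {variant.contig}:{variant.pos} not in CDS of {gene.gene_id}")
    cds = extract_cds_sequence(genome, gene)
    offset = _cds_offset(variant.pos, gene)
    ref_tx = variant.ref if gene.strand == "+" else variant.ref.translate(COMPLEMENT)
    alt_tx = variant.alt if gene.strand == "+" else variant.alt.translate(COMPLEMENT)
    if cds[offset] != ref_tx:
        raise ValueError(
            f"reference mismatch for {gene.gene_id} at CDS offset {offset}: "
            f"CDS has {cds[offset]}, variant ref (transcript strand) is {ref_tx}"
        )
    ci = offset // 3
    within = offset % 3
    from_codon = cds[ci * 3 : ci * 3 + 3]
    to_codon = from_codon[:within] + alt_tx + from_codon[within + 1 :]
    from_aa = translate_codon(from_codon)
    to_aa = translate_codon(to_codon)
    if from_aa == to_aa:
        effect = "synonymous"
    elif ci == 0:
        effect = "start_loss"
    elif to_aa == "*":
        effect = "stop_gain"
    elif from_aa == "*":
        effect = "stop_loss"
    else:
        effect = "missense"
    return CodingEffect(
        gene_id=gene.gene_id,
        codon_index=ci + 1,
        from_codon=from_codon,
        to_codon=to_codon,
        from_aa=from_aa,
        to_aa=to_aa,
        effect_class=effect,
    )


def classify_indel(variant: Variant) -> tuple[str, str]:
    """('frameshift'|'non_frameshift', 'insertion'|'deletion')."""
    if variant.is_snp:
        raise ValueError("classify_indel requires an InDel")
    shift = abs(len(variant.ref) - len(variant.alt)) % 3
    return ("frameshift" if shift else "non_frameshift", variant.kind)


@dataclass
class EffectSummary:
    per_line_regions: dict[str, dict[str, int]]
    per_line_effects: dict[str, dict[str, int]]
    pooled_regions: dict[str, int]
    pooled_effects: dict[str, int]
    per_line_indels: dict[str, dict[str, int]]
    gene_fractions: dict[str, float]  # any / cds / missense / promoter, in percent
    effects: list[CodingEffect]

    @property
    def pooled_region_percent(self) -> dict[str, float]:
        total = sum(self.pooled_regions.values())
        return {r: 100.0 * n / total for r, n in self.pooled_regions.items()} if total else {}

    @property
    def pooled_effect_percent(self) -> dict[str, float]:
        total = sum(self.pooled_effects.values())
        return {e: 100.0 * n / total for e, n in self.pooled_effects.items()} if total else {}


def effect_summary(
    population: list[VariantSet], genes: list[GeneModel], genome: Genome
) -> EffectSummary:
    """Per-line and pooled region/effect tallies plus gene-level fractions.

    Gene fractions (percent of all annotated genes): with at least one
    variant anywhere in the gene, with a CDS variant, with a missense
    variant, and with a promoter variant.
    """
    index = GeneIndex(genes)
    per_regions: dict[str, dict[str, int]] = {}
    per_effects: dict[str, dict[str, int]] = {}
    per_indels: dict[str, dict[str, int]] = {}
    pooled_regions = {r: 0 for r in REGIONS}
    pooled_effects = {e: 0 for e in EFFECT_CLASSES}
    genes_any: set[str] = set()
    genes_cds: set[str] = set()
    genes_missense: set[str] = set()
    genes_promoter: set[str] = set()
    all_effects: list[CodingEffect] = []

    for vs in population:
        regions = {r: 0 for r in REGIONS}
        effects = {e: 0 for e in EFFECT_CLASSES}
        indels = {"frameshift_insertion": 0, "frameshift_deletion": 0,
                  "non_frameshift_insertion": 0, "non_frameshift_deletion": 0}
        for v in vs:
            ann = annotate_region(v, index)
            regions[ann.region] += 1
            if ann.region in {"CDS", "five_prime_UTR", "three_prime_UTR", "intron"}:
                genes_any.add(ann.gene_id)
            if ann.region == "promoter":
                genes_promoter.add(ann.gene_id)
            if not v.is_snp:
                frame, kind = classify_indel(v)
                indels[f"{frame}_{kind}"] += 1
                continue
            if ann.region == "CDS":
                genes_cds.add(ann.gene_id)
                eff = coding_effect(v, index.genes[ann.gene_id], genome)
                effects[eff.effect_class] += 1
                all_effects.append(eff)
                if eff.effect_class == "missense":
                    genes_missense.add(eff.gene_id)
        per_regions[vs.line_id] = regions
        per_effects[vs.line_id] = effects
        per_indels[vs.line_id] = indels
        for r, n in regions.items():
            pooled_regions[r] += n
        for e, n in effects.items():
            pooled_effects[e] += n

    n_genes = len(genes)
    frac = lambda s: 100.0 * len(s) / n_genes if n_genes else float("nan")
    return EffectSummary(
        per_line_regions=per_regions,
        per_line_effects=per_effects,
        pooled_regions=pooled_regions,
        pooled_effects=pooled_effects,
        per_line_indels=per_indels,
        gene_fractions={
            "any_variant": frac(genes_any),
            "cds_variant": frac(genes_cds),
            "missense_variant": frac(genes_missense),
            "promoter_variant": frac(genes_promoter),
        },
        effects=all_effects,
    )


def deleterious_genes(
    population: list[VariantSet], genes: list[GeneModel], threshold: float = 0.05
) -> dict[str, list[Variant]]:
    """Genes carrying at least one CDS variant with SIFT score <= threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"SIFT threshold {threshold} outside [0,1]")
    index = GeneIndex(genes)
    out: dict[str, list[Variant]] = {}
    for vs in population:
        for v in vs:
            if v.sift_score is None or v.sift_score > threshold:
                continue
            ann = annotate_region(v, index)
            if ann.region == "CDS":
                out.setdefault(ann.gene_id, []).append(v)
    return out


def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """BED3/BED4 intervals (0-based half-open) as (contig, start, end, name)."""
    intervals = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line {i + 1}: {line!r}")
            start, end = int(parts[1]), int(parts[2])
            if start < 0 or end < start:
                raise ValueError(f"malformed BED interval at line {i + 1}: {start}-{end}")
            name = parts[3] if len(parts) > 3 else f"interval_{i}"
            intervals.append((parts[0], start, end, name))
    return intervals


@dataclass
class IntervalCounts:
    per_interval: dict[str, int]
    total: int
    n_hom: int
    n_het: int


def count_variants_in_intervals(
    population: list[VariantSet], intervals: list[tuple[str, int, int, str]]
) -> IntervalCounts:
    """Count variants inside BED intervals, once per overlapping interval.

    BED coordinates are 0-based half-open, so a 1-based variant position p
    is inside [start, end) iff start < p <= end. The total is over unique
    variant keys hitting at least one interval; the zygosity split counts
    each (variant, line) occurrence.
    """
    trees: dict[str, IntervalTree] = {}
    for contig, start, end, name in intervals:
        if end > start:
            trees.setdefault(contig, IntervalTree())[start:end] = name
    per_interval: dict[str, int] = {name: 0 for _, _, _, name in intervals}
    hit_keys: set[tuple] = set()
    n_hom = n_het = 0
    for vs in population:
        for v in vs:
            tree = trees.get(v.contig)
            if tree is None:
                continue
            hits = tree[v.pos - 1]  # 0-based point query
            if not hits:
                continue
            for iv in hits:
                per_interval[iv.data] += 1
            if v.key not in hit_keys:
                hit_keys.add(v.key)
            if v.zygosity == "hom":
                n_hom += 1
            elif v.zygosity == "het":
                n_het += 1
    return IntervalCounts(per_interval=per_interval, total=len(hit_keys), n_hom=n_hom, n_het=n_het)


def read_pathway_table(path: str | Path) -> dict[str, list[str]]:
    """TSV ``gene<TAB>pathway`` -> gene -> [pathways]."""
    mapping: dict[str, list[str]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if i == 0 and parts[0].lower() == "gene":
                continue
            if len(parts) < 2:
                raise ValueError(f"malformed pathway line {i + 1}")
            mapping.setdefault(parts[0], []).append(parts[1])
    return mapping


@dataclass
class PathwayCounts:
    per_pathway: dict[str, list[str]]  # pathway -> sorted gene list
    unassigned: list[str]

    def count(self, pathway: str) -> int:
        return len(self.per_pathway.get(pathway, []))


def pathway_counts(gene_set, gene_to_pathway: dict[str, list[str]]) -> PathwayCounts:
    """Per-pathway counts of (deleterious) genes; unmapped genes listed apart."""
    per: dict[str, set[str]] = {}
    unassigned = []
    for gene in sorted(gene_set):
        pathways = gene_to_pathway.get(gene)
        if not pathways:
            unassigned.append(gene)
            continue
        for p in pathways:
            per.setdefault(p, set()).add(gene)
    return PathwayCounts(
        per_pathway={p: sorted(gs) for p, gs in sorted(per.items())}, unassigned=unassigned
    )
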