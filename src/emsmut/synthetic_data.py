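"""Synthetic EMS-mutagenized population generator with truth tables.

Emulates the statistical structure of a chemically mutagenized diploid
population: a toy genome at a configurable GC content carrying compact
protein-coding genes, per-line SNP sets drawn at a target density with a
strand-collapsed substitution-class distribution dominated by the two
transition classes, a configurable homozygous fraction, optional sharing
of mutations between paired lines, optional InDels, and background
"cultivar" variant panels. Every draw is recorded in a truth table so each
downstream statistic (spectrum, density, zygosity, context, region,
coding effect, uniqueness) can be checked against its generating value.

Truth-table region and coding-effect labels are computed here by direct
interval scans and full-CDS translation diffs, independently of the
annotation modules they are used to validate.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

from .reference_io import Genome, GeneModel, promoter_window, reverse_complement, write_fasta
from .spectrum_stats import COLLAPSED_CLASSES, classify_substitution
from .variant_io import Variant, VariantSet, write_vcf

log = logging.getLogger(__name__)

_B = {"A": 65, "C": 67, "G": 71, "T": 84}

#: alt allele implied by (collapsed class, ref base)
ALT_FOR = {
    ("GC>AT", "G"): "A", ("GC>AT", "C"): "T",
    ("AT>GC", "A"): "G", ("AT>GC", "T"): "C",
    ("GC>TA", "G"): "T", ("GC>TA", "C"): "A",
    ("GC>CG", "G"): "C", ("GC>CG", "C"): "G",
    ("AT>CG", "A"): "C", ("AT>CG", "T"): "G",
    ("AT>TA", "A"): "T", ("AT>TA", "T"): "A",
}
GC_CLASSES = ("GC>AT", "GC>TA", "GC>CG")
AT_CLASSES = ("AT>GC", "AT>CG", "AT>TA")


def default_class_probs() -> dict[str, float]:
    """Transition classes at their population-average frequencies; the
    remaining mass split equally over the four transversion classes."""
    rest = (1.0 - 0.2786 - 0.2762) / 4.0
    return {
        "GC>AT": 0.2786, "AT>GC": 0.2762,
        "GC>TA": rest, "GC>CG": rest, "AT>CG": rest, "AT>TA": rest,
    }


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic population.

    ``density`` is bp per mutation. ``site_gc_prob`` controls how the
    mutated-site base pool is drawn: a number draws the pool first
    (Bernoulli) and the class conditionally within the pool, so the
    site-GC fraction is exact; None draws the class first, so the class
    marginals are exact and the site-GC fraction is the summed mass of
    the G/C classes. The two marginals cannot both be pinned because the
    collapsed class determines the site pool.
    """

    seed: int = 0
    genome_length: int = 1_000_000
    n_contigs: int = 2
    gc_content: float = 0.37
    n_genes: int = 20
    mean_cds_length: int = 300
    two_exon_fraction: float = 0.5
    utr_length: int = 30
    intron_length: int = 80
    gene_spacing: int = 400
    promoter_size: int = 3000
    n_lines: int = 2
    density: float = 3057.0
    class_probs: dict[str, float] = field(default_factory=default_class_probs)
    site_gc_prob: float | None = 0.47
    hom_fraction: float = 0.167
    shared_fraction: float = 0.0
    indels_per_line: float = 0.0
    indel_frameshift_fraction: float = 0.75
    indel_max_len: int = 5
    panel_size: int = 0
    panel_density: float = 2000.0

    def __post_init__(self) -> None:
        total = sum(self.class_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_probs sum to {total}, expected 1")
        if set(self.class_probs) != set(COLLAPSED_CLASSES):
            raise ValueError("class_probs must cover the 6 collapsed classes")
        if self.density <= 0:
            raise ValueError("density must be positive")
        for name in ("gc_content", "hom_fraction", "shared_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.site_gc_prob is not None and not 0.0 <= self.site_gc_prob <= 1.0:
            raise ValueError("site_gc_prob outside [0,1]")
        if self.mean_cds_length % 3 != 0:
            raise ValueError("mean_cds_length must be a multiple of 3")


@dataclass
class TruthTable:
    """Generating values for every emitted record."""

    per_line: dict[str, dict] = field(default_factory=dict)
    gene_cds: dict[str, str] = field(default_factory=dict)
    genome_length: int = 0
    cds_length: int = 0
    contig_lengths: dict[str, int] = field(default_factory=dict)
    panel_overlap: dict[str, int] = field(default_factory=dict)
    provenance: dict[str, dict[str, str]] = field(default_factory=dict)  # line -> key-str -> tag

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


_SENSE_NO_STOP = None


def _sense_codons_rng(rng: np.random.Generator, n: int) -> str:
    """n random non-stop, non-ATG-start-agnostic sense codons."""
    global _SENSE_NO_STOP
    if _SENSE_NO_STOP is None:
        from .codon_model import SENSE_CODONS

        _SENSE_NO_STOP = sorted(SENSE_CODONS)
    idx = rng.integers(0, len(_SENSE_NO_STOP), size=n)
    return "".join(_SENSE_NO_STOP[i] for i in idx)


def simulate_genome(config: SimulationConfig) -> tuple[Genome, list[GeneModel], TruthTable]:
    """Random genome at the configured GC content with packed gene cassettes.

    Each gene is UTR5 + CDS (one or two exons) + UTR3; the CDS begins with
    ATG and ends with a stop, with no internal stop codons. Genes never
    overlap each other (promoter windows may reach into neighbors; the
    annotation precedence rule resolves those sites).
    """
    rng = np.random.default_rng([config.seed, 7])
    gc = config.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    per_contig = config.genome_length // config.n_contigs
    contigs: dict[str, np.ndarray] = {}
    for i in range(config.n_contigs):
        length = per_contig if i < config.n_contigs - 1 else (
            config.genome_length - per_contig * (config.n_contigs - 1)
        )
        draws = rng.choice(np.array([_B["A"], _B["C"], _B["G"], _B["T"]], dtype=np.uint8),
                           size=length, p=p)
        contigs[f"chr{i + 1}"] = draws

    genes: list[GeneModel] = []
    truth = TruthTable(genome_length=config.genome_length)
    names = list(contigs)
    cursor = {name: config.gene_spacing for name in names}
    ci = 0
    for gi in range(config.n_genes):
        n_codons = max(10, int(round(rng.normal(config.mean_cds_length / 3, config.mean_cds_length / 12))))
        body = _sense_codons_rng(rng, n_codons - 2)
        stop = ["TAA", "TAG", "TGA"][rng.integers(0, 3)]
        cds = "ATG" + body + stop
        two_exon = rng.random() < config.two_exon_fraction
        if two_exon:
            cut = int(rng.integers(3, len(cds) - 3))
            pieces = [
                ("utr5", config.utr_length), ("exon", cut), ("intron", config.intron_length),
                ("exon", len(cds) - cut), ("utr3", config.utr_length),
            ]
            exon_seqs = [cds[:cut], cds[cut:]]
        else:
            pieces = [("utr5", config.utr_length), ("exon", len(cds)), ("utr3", config.utr_length)]
            exon_seqs = [cds]
        cassette_len = sum(n for _, n in pieces)

        # find a contig with room, round-robin
        placed = False
        for _ in range(len(names)):
            name = names[ci % len(names)]
            if cursor[name] + cassette_len + config.gene_spacing <= len(contigs[name]):
                placed = True
                break
            ci += 1
        if not placed:
            raise ValueError(
                f"cannot pack {config.n_genes} genes into {config.genome_length} bp"
            )
        gstart = cursor[name] + 1  # 1-based
        cursor[name] += cassette_len + config.gene_spacing
        ci += 1

        strand = "+" if rng.random() < 0.5 else "-"
        # assemble cassette in transcript order
        cassette = ""
        exon_i = 0
        offsets: list[tuple[str, int, int]] = []  # (kind, offset, length) transcript order
        off = 0
        for kind, length in pieces:
            if kind == "exon":
                seq = exon_seqs[exon_i]
                exon_i += 1
            elif kind == "intron":
                seq = "GT" + _random_bases(rng, length - 4, gc) + "AG"
            else:
                seq = _random_bases(rng, length, gc)
            cassette += seq
            offsets.append((kind, off, length))
            off += length
        L = len(cassette)
        gend = gstart + L - 1
        arr = contigs[name]
        if strand == "+":
            arr[gstart - 1 : gend] = np.frombuffer(cassette.encode(), dtype=np.uint8)
            coord = lambda o, ln: (gstart + o, gstart + o + ln - 1)
        else:
            arr[gstart - 1 : gend] = np.frombuffer(
                reverse_complement(cassette).encode(), dtype=np.uint8
            )
            coord = lambda o, ln: (gend - o - ln + 1, gend - o)
        cds_segments, phases, utr5, utr3 = [], [], [], []
        cds_off = 0
        for kind, o, ln in offsets:
            iv = coord(o, ln)
            if kind == "exon":
                cds_segments.append(iv)
                phases.append((3 - cds_off % 3) % 3)
                cds_off += ln
            elif kind == "utr5":
                utr5.append(iv)
            elif kind == "utr3":
                utr3.append(iv)
        gene = GeneModel(
            gene_id=f"g{gi + 1:04d}",
            contig=name,
            strand=strand,
            gene_span=(gstart, gend),
            cds_segments=cds_segments,
            phases=phases,
            utr5=utr5,
            utr3=utr3,
        )
        genes.append(gene)
        truth.gene_cds[gene.gene_id] = cds

    genome = Genome({name: arr.tobytes().decode() for name, arr in contigs.items()})
    for gene in genes:
        gene.promoter = promoter_window(
            gene, config.promoter_size, contig_length=genome.lengths[gene.contig]
        )
    truth.contig_lengths = genome.lengths
    truth.cds_length = sum(g.cds_length for g in genes)
    return genome, genes, truth


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    if n <= 0:
        return ""
    draws = rng.choice(
        np.array([_B["A"], _B["C"], _B["G"], _B["T"]], dtype=np.uint8),
        size=n,
        p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2],
    )
    return draws.tobytes().decode()


class _SiteIndex:
    """Global 0-based site index over all contigs, split by base pool."""

    def __init__(self, genome: Genome):
        self.names = list(genome.contigs)
        arrays = [np.frombuffer(genome.contigs[n].encode(), dtype=np.uint8) for n in self.names]
        self.bounds = np.cumsum([0] + [len(a) for a in arrays])
        cat = np.concatenate(arrays)
        self.bases = cat
        gc_mask = (cat == _B["G"]) | (cat == _B["C"])
        at_mask = (cat == _B["A"]) | (cat == _B["T"])
        self.gc_sites = np.nonzero(gc_mask)[0]
        self.at_sites = np.nonzero(at_mask)[0]

    def locate(self, gidx: int) -> tuple[str, int]:
        """(contig, 1-based pos) for a global 0-based index."""
        c = int(np.searchsorted(self.bounds, gidx, side="right")) - 1
        return self.names[c], int(gidx - self.bounds[c]) + 1

    def base(self, gidx: int) -> str:
        return chr(self.bases[gidx])


def _draw_without_collision(
    rng: np.random.Generator, pool: np.ndarray, n: int, taken: set[int]
) -> list[int]:
    if n == 0:
        return []
    if n > len(pool) - len(taken):
        raise ValueError("mutation density exhausts available sites")
    out: list[int] = []
    need = n
    while need > 0:
        cand = rng.choice(pool, size=min(len(pool), need * 2 + 8), replace=False)
        for g in cand:
            g = int(g)
            if g in taken:
                continue
            taken.add(g)
            out.append(g)
            need -= 1
            if need == 0:
                break
    return out


def _line_rng(seed: int, line_idx: int) -> np.random.Generator:
    return np.random.default_rng([seed, 1000 + line_idx])


def _truth_region(pos: int, contig: str, genes: list[GeneModel]) -> str:
    """Independent linear-scan region call with the precedence rule."""
    best = 99
    order = {"CDS": 0, "five_prime_UTR": 1, "three_prime_UTR": 1, "intron": 2, "promoter": 3}
    label = "intergenic"
    for g in genes:
        if g.contig != contig:
            continue
        if g.in_cds(pos):
            r = "CDS"
        elif g.in_utr5(pos):
            r = "five_prime_UTR"
        elif g.in_utr3(pos):
            r = "three_prime_UTR"
        elif g.contains(pos):
            r = "intron"
        elif g.in_promoter(pos):
            r = "promoter"
        else:
            continue
        if order[r] < best:
            best, label = order[r], r
    return label


def _splice(genome_seq: dict[str, str], gene: GeneModel, patch: dict[int, str]) -> str:
    """Spliced CDS with optional single-base patches {1-based pos: base}."""
    parts = []
    seq = genome_seq[gene.contig]
    for s, e in gene.cds_segments:
        frag = list(seq[s - 1 : e])
        for pos, base in patch.items():
            if s <= pos <= e:
                frag[pos - s] = base
        frag = "".join(frag)
        if gene.strand == "-":
            frag = reverse_complement(frag)
        parts.append(frag)
    return "".join(parts)


def _truth_effect(variant_pos: int, alt: str, gene: GeneModel, genome: Genome) -> str:
    """Coding-effect class by full-CDS mutation, translation and diff."""
    ref_cds = _splice(genome.contigs, gene, {})
    mut_cds = _splice(genome.contigs, gene, {variant_pos: alt})
    ref_prot = str(Seq(ref_cds).translate())
    mut_prot = str(Seq(mut_cds).translate())
    if ref_prot == mut_prot:
        return "synonymous"
    diff = [i for i, (a, b) in enumerate(zip(ref_prot, mut_prot)) if a != b]
    i = diff[0]
    if i == 0:
        return "start_loss"
    if mut_prot[i] == "*":
        return "stop_gain"
    if ref_prot[i] == "*":
        return "stop_loss"
    return "missense"


def _cds_gene_at(pos: int, contig: str, genes: list[GeneModel]) -> GeneModel | None:
    for g in genes:
        if g.contig == contig and g.in_cds(pos):
            return g
    return None


def simulate_population(
    config: SimulationConfig, genome: Genome, genes: list[GeneModel], truth: TruthTable | None = None
) -> tuple[list[VariantSet], TruthTable]:
    """Per-line SNP (and optional InDel) sets with full truth accounting.

    Per line, Poisson(genome_length/density) sites are drawn without
    replacement. Lines are paired (0,1), (2,3), ...; the second line of a
    pair receives ``shared_fraction`` of its mutations copied from the
    first. Each line has its own random stream derived from
    (seed, line index), so adding lines does not perturb existing ones.
    """
    if truth is None:
        truth = TruthTable(genome_length=genome.total_length, contig_lengths=genome.lengths)
    index = _SiteIndex(genome)
    class_names = list(COLLAPSED_CLASSES)
    probs = np.array([config.class_probs[c] for c in class_names])

    population: list[VariantSet] = []
    pair_variants: dict[int, list[Variant]] = {}
    for li in range(config.n_lines):
        rng = _line_rng(config.seed, li)
        line_id = f"line{li + 1:03d}"
        lam = genome.total_length / config.density
        n = int(rng.poisson(lam))

        # pairing rule: the second line of a pair copies shared_fraction of
        # its partner's SNPs and draws (1 - shared_fraction) of its own
        # Poisson count fresh, so shared_fraction 1 gives identical key sets
        shared: list[Variant] = []
        partner_idx = li - 1 if li % 2 == 1 else None
        if partner_idx is not None and config.shared_fraction > 0:
            partner = pair_variants.get(partner_idx, [])
            n_shared = int(round(config.shared_fraction * len(partner)))
            if n_shared:
                from dataclasses import replace as _replace

                pick = rng.choice(len(partner), size=n_shared, replace=False)
                shared = [_replace(partner[i], line_id=line_id) for i in sorted(pick)]
            n_fresh = int(round((1.0 - config.shared_fraction) * n))
        else:
            n_fresh = n

        taken: set[int] = set()
        for v in shared:
            gidx = index.bounds[index.names.index(v.contig)] + v.pos - 1
            taken.add(int(gidx))

        if config.site_gc_prob is None:
            counts = rng.multinomial(n_fresh, probs)
            class_list: list[str] = []
            for cname, k in zip(class_names, counts):
                class_list.extend([cname] * int(k))
            n_gc = sum(k for cname, k in zip(class_names, counts) if cname in GC_CLASSES)
        else:
            n_gc = int(rng.binomial(n_fresh, config.site_gc_prob))
            gc_p = np.array([config.class_probs[c] for c in GC_CLASSES])
            at_p = np.array([config.class_probs[c] for c in AT_CLASSES])
            gc_p, at_p = gc_p / gc_p.sum(), at_p / at_p.sum()
            gc_counts = rng.multinomial(n_gc, gc_p)
            at_counts = rng.multinomial(n_fresh - n_gc, at_p)
            class_list = []
            for cname, k in zip(GC_CLASSES, gc_counts):
                class_list.extend([cname] * int(k))
            for cname, k in zip(AT_CLASSES, at_counts):
                class_list.extend([cname] * int(k))

        gc_classes = [c for c in class_list if c in GC_CLASSES]
        at_classes = [c for c in class_list if c in AT_CLASSES]
        gc_pos = _draw_without_collision(rng, index.gc_sites, len(gc_classes), taken)
        at_pos = _draw_without_collision(rng, index.at_sites, len(at_classes), taken)

        variants: list[Variant] = list(shared)
        prov = {f"{v.contig}:{v.pos}:{v.ref}:{v.alt}": "copied" for v in shared}
        counts_class = {c: 0 for c in COLLAPSED_CLASSES}
        counts_raw: dict[str, int] = {}
        n_hom = sum(1 for v in shared if v.zygosity == "hom")
        region_counts: dict[str, int] = {}
        effect_counts: dict[str, int] = {}
        for v in shared:
            raw, coll, _ = classify_substitution(v.ref, v.alt)
            counts_class[coll] += 1
            counts_raw[raw] = counts_raw.get(raw, 0) + 1

        zyg_draws = rng.random(len(gc_pos) + len(at_pos))
        zi = 0
        for gidx, cname in list(zip(gc_pos, gc_classes)) + list(zip(at_pos, at_classes)):
            contig, pos = index.locate(gidx)
            ref = index.base(gidx)
            alt = ALT_FOR[(cname, ref)]
            zyg = "hom" if zyg_draws[zi] < config.hom_fraction else "het"
            zi += 1
            if zyg == "hom":
                n_hom += 1
            v = Variant(line_id=line_id, contig=contig, pos=pos, ref=ref, alt=alt, zygosity=zyg)
            variants.append(v)
            counts_class[cname] += 1
            raw = f"{ref}>{alt}"
            counts_raw[raw] = counts_raw.get(raw, 0) + 1
            prov[f"{contig}:{pos}:{ref}:{alt}"] = "fresh"

        # independent truth annotation for SNPs
        for v in variants:
            region = _truth_region(v.pos, v.contig, genes)
            region_counts[region] = region_counts.get(region, 0) + 1
            if region == "CDS":
                g = _cds_gene_at(v.pos, v.contig, genes)
                eff = _truth_effect(v.pos, v.alt, g, genome)
                effect_counts[eff] = effect_counts.get(eff, 0) + 1

        indel_counts = {"frameshift": 0, "non_frameshift": 0}
        if config.indels_per_line > 0:
            n_indels = int(rng.poisson(config.indels_per_line))
            all_sites = np.arange(len(index.bases))
            pos_idx = _draw_without_collision(rng, all_sites, n_indels, taken)
            for gidx in pos_idx:
                contig, pos = index.locate(gidx)
                if pos >= genome.lengths[contig] - config.indel_max_len - 1:
                    continue
                frameshift = rng.random() < config.indel_frameshift_fraction
                length = int(rng.choice([1, 2, 4, 5])) if frameshift else 3
                anchor = genome.base_at(contig, pos)
                if rng.random() < 0.5:  # insertion
                    ins = _random_bases(rng, length, 0.5)
                    ref, alt = anchor, anchor + ins
                else:
                    ref = genome.fetch(contig, pos, pos + length)
                    alt = anchor
                zyg = "hom" if rng.random() < config.hom_fraction else "het"
                try:
                    v = Variant(line_id=line_id, contig=contig, pos=pos, ref=ref, alt=alt, zygosity=zyg)
                except ValueError:
                    continue
                variants.append(v)
                indel_counts["frameshift" if frameshift else "non_frameshift"] += 1
                prov[f"{contig}:{pos}:{ref}:{alt}"] = "indel"

        vs = VariantSet(line_id, variants)
        population.append(vs)
        pair_variants[li] = [v for v in variants if v.is_snp]
        truth.per_line[line_id] = {
            "n_variants": len(vs),
            "n_snps": len(pair_variants[li]),
            "n_shared_copied": len(shared),
            "class_counts": counts_class,
            "raw_counts": counts_raw,
            "n_hom": n_hom,
            "n_het": len(pair_variants[li]) - n_hom,
            "region_counts": region_counts,
            "effect_counts": effect_counts,
            "indel_counts": indel_counts,
            "true_density_kb": genome.total_length / len(vs) / 1000.0 if len(vs) else None,
        }
        truth.provenance[line_id] = prov
    return population, truth


def simulate_background_panel(
    config: SimulationConfig, genome: Genome
) -> list[VariantSet]:
    """Background cultivar-style panels with an unbiased class distribution."""
    index = _SiteIndex(genome)
    alts = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}
    panel = []
    for pi in range(config.panel_size):
        rng = np.random.default_rng([config.seed, 50_000 + pi])
        n = int(rng.poisson(genome.total_length / config.panel_density))
        taken: set[int] = set()
        sites = _draw_without_collision(rng, np.arange(len(index.bases)), n, taken)
        variants = []
        for gidx in sites:
            contig, pos = index.locate(gidx)
            ref = index.base(gidx)
            if ref == "N":
                continue
            alt = alts[ref][rng.integers(0, 3)]
            variants.append(
                Variant(
                    line_id=f"panel{pi + 1:03d}", contig=contig, pos=pos, ref=ref, alt=alt,
                    zygosity="hom" if rng.random() < 0.5 else "het",
                )
            )
        panel.append(VariantSet(f"panel{pi + 1:03d}", variants))
    return panel


def record_panel_overlap(
    truth: TruthTable, population: list[VariantSet], panel: list[VariantSet]
) -> None:
    """Record per-line overlap with the union of the panel key sets."""
    panel_keys: set[tuple] = set()
    for vs in panel:
        panel_keys |= vs.keys
    for vs in population:
        truth.panel_overlap[vs.line_id] = len(vs.keys & panel_keys)


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    """Emit gene/mRNA/UTR/CDS rows (1-based inclusive, phase on CDS)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = g.gene_span
            base = f"{g.contig}\temsmut\t"
            tail = f"\t.\t{g.strand}\t"
            fh.write(f"{base}gene\t{s}\t{e}{tail}.\tID={g.gene_id}\n")
            mrna = f"{g.gene_id}.1"
            fh.write(f"{base}mRNA\t{s}\t{e}{tail}.\tID={mrna};Parent={g.gene_id}\n")
            for us, ue in g.utr5:
                fh.write(f"{base}five_prime_UTR\t{us}\t{ue}{tail}.\tParent={mrna}\n")
            for (cs, ce), ph in zip(g.cds_segments, g.phases):
                fh.write(f"{base}CDS\t{cs}\t{ce}{tail}{ph}\tParent={mrna}\n")
            for us, ue in g.utr3:
                fh.write(f"{base}three_prime_UTR\t{us}\t{ue}{tail}.\tParent={mrna}\n")


def write_simulation(
    outdir: str | Path,
    genome: Genome,
    genes: list[GeneModel],
    population: list[VariantSet],
    truth: TruthTable,
    panel: list[VariantSet] | None = None,
) -> dict[str, Path]:
    """Write FASTA + GFF3 + per-line VCFs + truth JSON into a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["fasta"] = outdir / "genome.fa"
    write_fasta(genome, paths["fasta"])
    paths["gff3"] = outdir / "genes.gff3"
    write_gff3(genes, paths["gff3"])
    for vs in population + (panel or []):
        p = outdir / f"{vs.line_id}.vcf"
        write_vcf(vs, p, genome.lengths)
        paths[vs.line_id] = p
    paths["truth"] = outdir / "truth.json"
    truth.to_json(paths["truth"])
    return paths
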