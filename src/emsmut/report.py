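"""Pipeline orchestration and consolidated reporting.

Runs filter -> subtract -> spectrum -> context -> effects -> codon model
over a set of per-line VCFs against a reference genome and annotation,
writing every table plus a manifest (inputs, parameters, digests) into a
run directory. All stages are deterministic given fixed inputs.
"""

from __future__ import annotations

import glob as globmod
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .codon_model import (
    mutagenicity_ratios,
    normalize_rows_missense,
    observed_aa_matrix,
    observed_vs_theoretical,
    theoretical_aa_matrix,
)
from .coding_effects import (
    count_variants_in_intervals,
    deleterious_genes,
    effect_summary,
    pathway_counts,
    read_bed,
    read_pathway_table,
)
from .context_analysis import composition_matrix, extract_context, site_vs_flank_gc, write_composition_tsv
from .reference_io import read_codon_usage, read_fasta, read_gff3
from .spectrum_stats import (
    mutation_density,
    per_contig_counts,
    spectrum_table,
    unique_snps,
    zygosity_fractions,
)
from .variant_io import (
    apply_hard_filters,
    attach_sift,
    read_sift_table,
    read_vcf,
    subtract_parental,
    write_variant_table,
)

log = logging.getLogger(__name__)


class ValidationError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    fasta: str
    gff3: str
    vcf_glob: str
    outdir: str
    parental_vcf: str | None = None
    usage_table: str | None = None
    sift_table: str | None = None
    pathway_table: str | None = None
    bed: str | None = None
    context_k: int = 20
    promoter_size: int = 3000
    sift_threshold: float = 0.05
    genome_denominator_bp: int | None = None
    max_context_snps: int = 100_000

    def validate(self) -> list[str]:
        paths = [self.fasta, self.gff3]
        for opt in (self.parental_vcf, self.usage_table, self.sift_table,
                    self.pathway_table, self.bed):
            if opt is not None:
                paths.append(opt)
        missing = [p for p in paths if not Path(p).exists()]
        vcfs = sorted(globmod.glob(self.vcf_glob))
        if not vcfs:
            missing.append(self.vcf_glob)
        if missing:
            raise ValidationError(f"missing inputs: {missing}")
        if not 0.0 <= self.sift_threshold <= 1.0:
            raise ValidationError("sift_threshold outside [0,1]")
        if self.context_k < 1:
            raise ValidationError("context_k must be >= 1")
        return vcfs


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle; returns the summary."""
    vcf_paths = config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "load_reference"
    try:
        genome = read_fasta(config.fasta)
        genes = read_gff3(config.gff3, genome, promoter_size=config.promoter_size)
        stage = "load_variants"
        population = [read_vcf(p) for p in vcf_paths]
        stage = "filter"
        population = [apply_hard_filters(vs) for vs in population]
        if config.parental_vcf:
            stage = "subtract_parental"
            parental = read_vcf(config.parental_vcf, "parental")
            population = [subtract_parental(vs, parental) for vs in population]
        if config.sift_table:
            stage = "attach_sift"
            table = read_sift_table(config.sift_table)
            population = [attach_sift(vs, table) for vs in population]

        stage = "spectrum"
        denominator = config.genome_denominator_bp or genome.total_length
        cds_bp = sum(g.cds_length for g in genes)
        per_line = {}
        for vs in population:
            spec = spectrum_table(vs)
            dens = mutation_density(spec.n_total, denominator)
            gcat = mutation_density(
                spec.collapsed_counts["GC>AT"], denominator, scope="GC>AT"
            )
            zyg = zygosity_fractions(vs.snps())
            per_line[vs.line_id] = {
                "n_variants": len(vs),
                "n_snps": spec.n_total,
                "spectrum_percent": spec.frequencies,
                "kb_per_mutation": dens.kb_per_mutation,
                "kb_per_gc_to_at": gcat.kb_per_mutation,
                "zygosity_percent": zyg,
                "per_contig": per_contig_counts(vs),
            }
            write_variant_table(vs, outdir / f"{vs.line_id}.variants.tsv")
        pooled_spec = spectrum_table(v for vs in population for v in vs)
        uniq = unique_snps(population) if len(population) >= 2 else None

        stage = "context"
        windows = []
        for vs in population:
            for v in vs.snps()[: config.max_context_snps]:
                windows.append(extract_context(genome, v, k=config.context_k))
        context = None
        if windows:
            matrix = composition_matrix(windows)
            write_composition_tsv(matrix, outdir / "context_composition.tsv")
            context = site_vs_flank_gc(matrix)

        stage = "effects"
        effects = effect_summary(population, genes, genome)
        deleterious = None
        pathways = None
        if config.sift_table:
            dele = deleterious_genes(population, genes, threshold=config.sift_threshold)
            deleterious = {
                "n_genes": len(dele),
                "percent_of_genes": 100.0 * len(dele) / len(genes) if genes else None,
            }
            if config.pathway_table:
                pc = pathway_counts(set(dele), read_pathway_table(config.pathway_table))
                pathways = {p: len(gs) for p, gs in pc.per_pathway.items()}
        intervals = None
        if config.bed:
            ic = count_variants_in_intervals(population, read_bed(config.bed))
            known = ic.n_hom + ic.n_het
            intervals = {
                "total_unique_variants": ic.total,
                "n_intervals_hit": sum(1 for n in ic.per_interval.values() if n),
                "het_percent": 100.0 * ic.n_het / known if known else None,
            }

        stage = "codon"
        codon = None
        if effects.effects:
            observed = observed_aa_matrix(effects.effects)
            theoretical = theoretical_aa_matrix()
            ratios = observed_vs_theoretical(normalize_rows_missense(observed), theoretical)
            codon = {
                "mean_transition_ratio": ratios.mean_transition,
                "mean_transversion_ratio": ratios.mean_transversion,
            }
            if config.usage_table:
                usage = read_codon_usage(config.usage_table)
                counts: dict[str, int] = {}
                for eff in effects.effects:
                    counts[eff.from_codon] = counts.get(eff.from_codon, 0) + 1
                mut = mutagenicity_ratios(counts, usage)
                with open(outdir / "mutagenicity.tsv", "w") as fh:
                    fh.write("codon\taa\tusage\tobserved\tratio\tpreferred\n")
                    for row in mut.rows:
                        obs = "" if row["observed"] is None else f"{row['observed']:.6f}"
                        rat = "" if row["ratio"] is None else f"{row['ratio']:.6f}"
                        fh.write(
                            f"{row['codon']}\t{row['aa']}\t{row['usage']:.6f}\t{obs}\t{rat}\t"
                            f"{int(row['preferred'])}\n"
                        )

        stage = "summary"
        bundle = {
            "per_line": per_line,
            "pooled_spectrum_percent": pooled_spec.frequencies,
            "unique": None
            if uniq is None
            else {
                "population_unique_total": uniq.population_unique_total,
                "per_line_percent": uniq.per_line_percent,
            },
            "context": context,
            "regions_percent": effects.pooled_region_percent,
            "effects_percent": effects.pooled_effect_percent,
            "gene_fractions_percent": effects.gene_fractions,
            "deleterious": deleterious,
            "pathways": pathways,
            "intervals": intervals,
            "codon": codon,
            "denominators": {"genome_bp": denominator, "cds_bp": cds_bp},
        }
        summary = summarize(bundle)
        bundle["population_summary"] = summary
        with open(outdir / "report.json", "w") as fh:
            json.dump(bundle, fh, indent=1, default=float)
    except ValidationError:
        raise
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "inputs": {"fasta": config.fasta, "gff3": config.gff3, "vcfs": vcf_paths},
        "parameters": {
            "context_k": config.context_k,
            "promoter_size": config.promoter_size,
            "sift_threshold": config.sift_threshold,
        },
        "outputs": {
            p.name: _digest(p) for p in sorted(outdir.iterdir()) if p.name != "manifest.json"
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return bundle


def summarize(bundle: dict) -> dict:
    """Population means and ranges of the per-line headline statistics."""
    per_line = bundle.get("per_line")
    if not per_line:
        raise ValueError("empty report bundle")

    def stats(values):
        vals = [v for v in values if v is not None]
        if not vals:
            return None
        return {"mean": sum(vals) / len(vals), "min": min(vals), "max": max(vals)}

    return {
        "n_lines": len(per_line),
        "snps_per_line": stats(d["n_snps"] for d in per_line.values()),
        "kb_per_mutation": stats(d["kb_per_mutation"] for d in per_line.values()),
        "hom_percent": stats(
            d["zygosity_percent"]["hom"] if d["zygosity_percent"] else None
            for d in per_line.values()
        ),
        "gc_to_at_percent": stats(
            d["spectrum_percent"]["GC>AT"] if d["spectrum_percent"] else None
            for d in per_line.values()
        ),
    }
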