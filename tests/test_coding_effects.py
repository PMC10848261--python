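import random

import pytest

from emsmut.coding_effects import (
    GeneIndex,
    annotate_region,
    classify_indel,
    coding_effect,
    count_variants_in_intervals,
    deleterious_genes,
    effect_summary,
    pathway_counts,
    read_bed,
)
from emsmut.reference_io import Genome, GeneModel, extract_cds_sequence, reverse_complement
from emsmut.variant_io import Variant, VariantSet


@pytest.fixture()
def toy():
    """50 bp prefix + UTR5(6) + exon1 ATGGTT + intron(10) + exon2 TGGTAA + UTR3(6)."""
    seq = (
        "A" * 50
        + "TTTTTT"          # utr5 51-56
        + "ATGGTT"          # exon1 57-62
        + "GT" + "C" * 6 + "AG"  # intron 63-72
        + "TGGTAA"          # exon2 73-78
        + "TTTTTT"          # utr3 79-84
        + "A" * 16
    )
    genome = Genome({"c": seq})
    gene = GeneModel(
        "g1", "c", "+",
        gene_span=(51, 84),
        cds_segments=[(57, 62), (73, 78)],
        phases=[0, 0],
        utr5=[(51, 56)],
        utr3=[(79, 84)],
        promoter=(21, 50),
    )
    assert extract_cds_sequence(genome, gene) == "ATGGTTTGGTAA"
    return genome, gene


def _v(pos, ref, alt, line="L1", zyg="het", sift=None):
    return Variant(line, "c", pos, ref, alt, zyg, sift_score=sift)


class TestAnnotateRegion:
    @pytest.mark.parametrize(
        "pos,region",
        [
            (60, "CDS"),
            (75, "CDS"),
            (65, "intron"),
            (53, "five_prime_UTR"),
            (80, "three_prime_UTR"),
            (30, "promoter"),
            (50, "promoter"),
            (10, "intergenic"),
            (95, "intergenic"),
        ],
    )
    def test_precedence_regions(self, toy, pos, region):
        genome, gene = toy
        index = GeneIndex([gene])
        ref = genome.base_at("c", pos)
        alt = "A" if ref != "A" else "G"
        assert annotate_region(_v(pos, ref, alt), index).region == region

    def test_overlapping_genes_take_highest_precedence(self, toy):
        genome, gene = toy
        # a second gene whose promoter covers the first gene's CDS
        other = GeneModel("g2", "c", "-", (90, 95), [(90, 95)], [0], promoter=(50, 80))
        index = GeneIndex([gene, other])
        ann = annotate_region(_v(60, "G", "A"), index)
        assert ann.region == "CDS"
        assert ann.gene_id == "g1"


class TestCodingEffect:
    def test_missense_val_to_ala(self, toy):
        genome, gene = toy
        eff = coding_effect(_v(61, "T", "C"), gene, genome)
        assert (eff.from_codon, eff.to_codon) == ("GTT", "GCT")
        assert (eff.from_aa, eff.to_aa, eff.effect_class) == ("V", "A", "missense")
        assert eff.codon_index == 2

    def test_stop_gain_in_second_exon(self, toy):
        genome, gene = toy
        eff = coding_effect(_v(75, "G", "A"), gene, genome)
        assert (eff.from_codon, eff.to_codon) == ("TGG", "TGA")
        assert eff.effect_class == "stop_gain"

    def test_start_loss(self, toy):
        genome, gene = toy
        eff = coding_effect(_v(58, "T", "C"), gene, genome)
        assert (eff.from_codon, eff.to_codon) == ("ATG", "ACG")
        assert eff.effect_class == "start_loss"

    def test_synonymous_third_position(self, toy):
        genome, gene = toy
        eff = coding_effect(_v(62, "T", "C"), gene, genome)  # GTT -> GTC
        assert eff.effect_class == "synonymous"

    def test_non_cds_rejected(self, toy):
        genome, gene = toy
        with pytest.raises(ValueError):
            coding_effect(_v(65, "C", "T"), gene, genome)

    def test_reference_mismatch_rejected(self, toy):
        genome, gene = toy
        with pytest.raises(ValueError, match="mismatch"):
            coding_effect(_v(61, "A", "C"), gene, genome)


def _independent_effect(v, gene, genome):
    """Oracle: mutate the contig, splice, translate both proteins, diff."""
    from Bio.Seq import Seq

    seq = genome.contigs[gene.contig]
    mutated = Genome({gene.contig: seq[: v.pos - 1] + v.alt + seq[v.pos :]})
    ref_prot = str(Seq(extract_cds_sequence(genome, gene)).translate())
    mut_prot = str(Seq(extract_cds_sequence(mutated, gene)).translate())
    if ref_prot == mut_prot:
        return "synonymous"
    i = next(k for k, (a, b) in enumerate(zip(ref_prot, mut_prot)) if a != b)
    if i == 0:
        return "start_loss"
    if mut_prot[i] == "*":
        return "stop_gain"
    if ref_prot[i] == "*":
        return "stop_loss"
    return "missense"


class TestOracleEquivalence:
    def test_every_simulated_cds_snp(self, small_sim):
        _, genome, genes, population, _ = small_sim
        index = GeneIndex(genes)
        n_checked = 0
        for vs in population:
            for v in vs.snps():
                ann = annotate_region(v, index)
                if ann.region != "CDS":
                    continue
                gene = index.genes[ann.gene_id]
                eff = coding_effect(v, gene, genome)
                assert eff.effect_class == _independent_effect(v, gene, genome)
                n_checked += 1
        assert n_checked > 10

    def test_matches_truth_table_counts(self, small_sim):
        _, genome, genes, population, truth = small_sim
        snp_pop = [VariantSet(vs.line_id, vs.snps()) for vs in population]
        summary = effect_summary(snp_pop, genes, genome)
        for vs in snp_pop:
            t = truth.per_line[vs.line_id]
            observed = {k: n for k, n in summary.per_line_effects[vs.line_id].items() if n}
            assert observed == t["effect_counts"]
            regions = {k: n for k, n in summary.per_line_regions[vs.line_id].items() if n}
            assert regions == t["region_counts"]

    def test_strand_invariance_under_genome_reversal(self, small_sim):
        _, genome, genes, population, _ = small_sim
        index = GeneIndex(genes)
        lengths = genome.lengths
        flipped = Genome({c: reverse_complement(s) for c, s in genome.contigs.items()})
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}

        def mirror_gene(g):
            L = lengths[g.contig]
            mirror = lambda iv: (L - iv[1] + 1, L - iv[0] + 1)
            return GeneModel(
                g.gene_id, g.contig, "-" if g.strand == "+" else "+",
                mirror(g.gene_span),
                [mirror(iv) for iv in g.cds_segments],
                list(g.phases),
                [mirror(iv) for iv in g.utr5],
                [mirror(iv) for iv in g.utr3],
            )

        checked = 0
        for v in population[0].snps():
            ann = annotate_region(v, index)
            if ann.region != "CDS":
                continue
            gene = index.genes[ann.gene_id]
            eff = coding_effect(v, gene, genome)
            L = lengths[v.contig]
            v2 = Variant(v.line_id, v.contig, L - v.pos + 1, comp[v.ref], comp[v.alt])
            eff2 = coding_effect(v2, mirror_gene(gene), flipped)
            assert eff2.effect_class == eff.effect_class
            assert eff2.codon_index == eff.codon_index
            checked += 1
        assert checked > 0


class TestClassifyIndel:
    @pytest.mark.parametrize(
        "ref,alt,expect",
        [
            ("GAT", "G", ("frameshift", "deletion")),       # 2 bp deletion
            ("G", "GATC", ("non_frameshift", "insertion")),  # 3 bp insertion
            ("GATCA", "G", ("frameshift", "deletion")),      # 4 bp deletion
            ("G", "GA", ("frameshift", "insertion")),
        ],
    )
    def test_frame_rule(self, ref, alt, expect):
        assert classify_indel(_v(10, ref, alt)) == expect

    def test_snp_rejected(self):
        with pytest.raises(ValueError):
            classify_indel(_v(10, "G", "A"))


class TestEffectSummary:
    def test_region_percentages_sum_to_100(self, small_sim):
        _, genome, genes, population, _ = small_sim
        summary = effect_summary(population, genes, genome)
        assert sum(summary.pooled_region_percent.values()) == pytest.approx(100.0, abs=0.01)
        assert sum(summary.pooled_effect_percent.values()) == pytest.approx(100.0, abs=0.01)

    def test_single_missense_gene_fractions(self, toy):
        genome, gene = toy
        pop = [VariantSet("L1", [_v(61, "T", "C")])]
        summary = effect_summary(pop, [gene], genome)
        assert summary.gene_fractions == {
            "any_variant": 100.0,
            "cds_variant": 100.0,
            "missense_variant": 100.0,
            "promoter_variant": 0.0,
        }

    def test_empty_population(self, toy):
        genome, gene = toy
        summary = effect_summary([], [gene], genome)
        assert sum(summary.pooled_regions.values()) == 0
        assert summary.gene_fractions["any_variant"] == 0.0


class TestDeleteriousGenes:
    def test_inclusive_threshold(self, toy):
        genome, gene = toy
        pop = [VariantSet("L1", [_v(61, "T", "C", sift=0.05)])]
        assert set(deleterious_genes(pop, [gene])) == {"g1"}

    def test_above_threshold_excluded(self, toy):
        genome, gene = toy
        pop = [VariantSet("L1", [_v(61, "T", "C", sift=0.06)])]
        assert deleterious_genes(pop, [gene]) == {}

    def test_unscored_excluded_and_bad_threshold(self, toy):
        genome, gene = toy
        pop = [VariantSet("L1", [_v(61, "T", "C")])]
        assert deleterious_genes(pop, [gene]) == {}
        with pytest.raises(ValueError):
            deleterious_genes(pop, [gene], threshold=1.5)


class TestIntervalCounting:
    def test_bed_half_open_convention(self):
        intervals = [("c", 100, 101, "m1")]
        inside = [VariantSet("L1", [_v(101, "G", "A")])]
        outside = [VariantSet("L1", [_v(100, "G", "A")])]
        assert count_variants_in_intervals(inside, intervals).total == 1
        assert count_variants_in_intervals(outside, intervals).total == 0

    def test_zygosity_split(self):
        intervals = [("c", 0, 50, "m1")]
        pop = [VariantSet("L1", [_v(1, "G", "A", zyg="hom"), _v(2, "G", "A"), _v(3, "G", "A")])]
        counts = count_variants_in_intervals(pop, intervals)
        assert counts.n_hom == 1 and counts.n_het == 2

    def test_matches_brute_force(self):
        rng = random.Random(13)
        intervals = [
            ("c", s, s + rng.randint(1, 30), f"iv{i}")
            for i, s in enumerate(rng.sample(range(0, 500), 20))
        ]
        pop = [
            VariantSet(f"L{j}", [_v(p, "G", "A", line=f"L{j}") for p in rng.sample(range(1, 520), 60)])
            for j in range(3)
        ]
        counts = count_variants_in_intervals(pop, intervals)
        for contig, start, end, name in intervals:
            brute = sum(
                1 for vs in pop for v in vs if v.contig == contig and start < v.pos <= end
            )
            assert counts.per_interval[name] == brute

    def test_malformed_bed_rejected(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("c\t10\t5\n")
        with pytest.raises(ValueError, match="malformed"):
            read_bed(p)


class TestPathwayCounts:
    def test_simple_join(self):
        mapping = {"g1": ["P1"], "g2": ["P1"], "g3": ["P2"]}
        counts = pathway_counts({"g1", "g2", "g3"}, mapping)
        assert counts.count("P1") == 2
        assert counts.count("P2") == 1
        assert counts.unassigned == []

    def test_empty_mapping_all_unassigned(self):
        counts = pathway_counts({"g1", "g2"}, {})
        assert counts.per_pathway == {}
        assert counts.unassigned == ["g1", "g2"]

    def test_matches_brute_force_join(self):
        rng = random.Random(3)
        genes = [f"g{i}" for i in range(40)]
        mapping = {
            g: [f"P{rng.randint(1, 5)}" for _ in range(rng.randint(0, 2))]
            for g in genes
            if rng.random() < 0.8
        }
        mapping = {g: sorted(set(ps)) for g, ps in mapping.items() if ps}
        selected = set(rng.sample(genes, 25))
        counts = pathway_counts(selected, mapping)
        for pw in {p for ps in mapping.values() for p in ps}:
            brute = sorted(g for g in selected if pw in mapping.get(g, []))
            assert counts.per_pathway.get(pw, []) == brute
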