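import pytest

from oracles import oracle_tandem_chains
from wgdscan import synthetic_data as sd
from wgdscan.genome_model import GeneModel, assign_ranks
from wgdscan.homology import HitIndex, SimilarityHit
from wgdscan.synteny import (
    GeneCatalog,
    assemble_ortholog_groups,
    classify_tandem,
    detect_duplicated_block,
    detect_interspecies_block,
    flank_window,
    scan_intraspecies,
    synteny_quality,
    DuplicatedBlock,
    SyntenicBlock,
)


def chromosome(n, chrom="chr1", species="sp", spacing=3000, prefix="g"):
    genes = [
        GeneModel(f"{prefix}{i:03d}", species, chrom, 1 + i * spacing, 900 + i * spacing)
        for i in range(n)
    ]
    return assign_ranks(genes)


def hit_index(*pairs):
    idx = HitIndex()
    for q, s, e in pairs:
        idx.add(SimilarityHit(q, s, e, 100.0, 90.0))
        idx.add(SimilarityHit(s, q, e, 100.0, 90.0))
    return idx.finalize()


class TestFlankWindow:
    def test_truncated_at_chromosome_start(self):
        genes = chromosome(30)
        w = flank_window(genes, "g002", k=15)
        assert len(w.upstream) == 2 and len(w.downstream) == 15
        assert w.upstream == ["g001", "g000"]  # nearest first

    def test_full_window_mid_chromosome(self):
        genes = chromosome(41)
        w = flank_window(genes, "g020", k=15)
        assert len(w.upstream) == len(w.downstream) == 15

    def test_zero_k_gives_empty_window(self):
        genes = chromosome(10)
        assert flank_window(genes, "g005", k=0).genes == []

    def test_unplaced_anchor_is_an_error(self):
        genes = chromosome(5) + [GeneModel("u1", "sp", "scaffold_9", 1, 9, placed=False)]
        with pytest.raises(ValueError, match="not on chromosome"):
            flank_window(genes, "u1")


class TestDetectDuplicatedBlock:
    def two_regions(self):
        # two chromosomes; anchors a=g010 (chr1) and b=h010 (chr2)
        genes = chromosome(21) + chromosome(21, chrom="chr2", prefix="h")
        return assign_ranks(genes)

    def test_five_conserved_flanks_make_a_duplicated_block(self):
        genes = self.two_regions()
        cat = GeneCatalog(genes)
        pairs = [(f"g{i:03d}", f"h{i:03d}", 1e-30) for i in (5, 7, 9, 12, 14)]
        idx = hit_index(*pairs, ("g010", "h010", 1e-40))
        block = detect_duplicated_block(
            "g010", "h010", flank_window(cat, "g010"), flank_window(cat, "h010"), idx
        )
        assert block.support == 5 and block.status == "duplicated"

    def test_three_flanks_fall_in_flexible_set(self):
        genes = self.two_regions()
        cat = GeneCatalog(genes)
        idx = hit_index(*[(f"g{i:03d}", f"h{i:03d}", 1e-30) for i in (5, 9, 14)])
        block = detect_duplicated_block(
            "g010", "h010", flank_window(cat, "g010"), flank_window(cat, "h010"), idx
        )
        assert block.support == 3 and block.status == "flexible"

    def test_no_conserved_flanks_is_unsupported(self):
        genes = self.two_regions()
        cat = GeneCatalog(genes)
        block = detect_duplicated_block(
            "g010", "h010", flank_window(cat, "g010"), flank_window(cat, "h010"), HitIndex()
        )
        assert block.support == 0 and block.status == "unsupported"

    def test_anchor_pair_does_not_count_as_support(self):
        genes = self.two_regions()
        cat = GeneCatalog(genes)
        idx = hit_index(("g010", "h010", 1e-60), ("g005", "h005", 1e-30))
        block = detect_duplicated_block(
            "g010", "h010", flank_window(cat, "g010"), flank_window(cat, "h010"), idx
        )
        assert block.support == 1
        assert ("g010", "h010") not in block.matched_pairs

    def test_one_to_one_pairing_prevents_reuse(self):
        genes = self.two_regions()
        cat = GeneCatalog(genes)
        # two flank genes whose best match is the same partner gene
        idx = hit_index(("g005", "h005", 1e-40), ("g006", "h005", 1e-35))
        block = detect_duplicated_block(
            "g010", "h010", flank_window(cat, "g010"), flank_window(cat, "h010"), idx
        )
        assert block.support == 1
        assert block.matched_pairs == [("g005", "h005")]

    def test_threshold_excludes_weak_matches(self):
        genes = self.two_regions()
        cat = GeneCatalog(genes)
        idx = hit_index(("g005", "h005", 1e-8))
        block = detect_duplicated_block(
            "g010", "h010", flank_window(cat, "g010"), flank_window(cat, "h010"), idx
        )
        assert block.support == 0


class TestScanIntraspecies:
    def test_simulated_wgd_fully_recovered(self, one_wgd_genome, one_wgd_index):
        blocks = scan_intraspecies(
            one_wgd_genome.family, one_wgd_genome.genes, one_wgd_index
        )
        truth = {
            frozenset((p.gene_a, p.gene_b))
            for p in one_wgd_genome.truth.anchor_pairs()
        }
        found = {
            frozenset((b.anchor_a, b.anchor_b))
            for b in blocks
            if b.status == "duplicated"
        }
        assert found == truth
        assert all(b.status == "duplicated" for b in blocks)

    def test_shuffled_positions_yield_no_blocks(self):
        """Genome-scale negative control: once gene order is randomized,
        a homolog lands in a given 30-gene window with probability
        window/genome, so at realistic gene counts no anchor pair keeps
        even two supporting flanks."""
        cfg = sd.SimulationConfig(
            n_chromosomes=4, genes_per_chromosome=5000, n_family_loci=4,
            wgd_events=[sd.WgdEvent(0.0, 0.0, 0.0)], tandem_prob=0.0,
            mean_gene_length_codons=60, seed=11,
        )
        genome = sd.simulate_genome(cfg, compute_realized_ks=False)
        index = sd.truth_hit_index(genome.truth)
        shuffled = sd.shuffle_gene_positions(genome.genes, seed=3)
        assert scan_intraspecies(genome.family, shuffled, index) == []

    def test_single_member_family_gives_nothing(self, one_wgd_genome, one_wgd_index):
        assert (
            scan_intraspecies(
                one_wgd_genome.family[:1], one_wgd_genome.genes, one_wgd_index
            )
            == []
        )

    def test_support_symmetry_on_symmetric_matches(self, one_wgd_genome, one_wgd_index):
        blocks = scan_intraspecies(
            one_wgd_genome.family, one_wgd_genome.genes, one_wgd_index
        )
        assert blocks and not any(b.non_reciprocal for b in blocks)


class TestClassifyTandem:
    def genes_at(self, starts, family_flags, spacing_prefix="g"):
        genes = [
            GeneModel(f"g{i:02d}", "sp", "chr1", s, s + 500)
            for i, s in enumerate(starts)
        ]
        assign_ranks(genes)
        family = [g.gene_id for g, fam in zip(genes, family_flags) if fam]
        return genes, family

    def test_adjacent_pair_within_40kb(self):
        genes, family = self.genes_at([1, 40_001], [True, True])
        (cluster,) = classify_tandem(family, genes)
        assert cluster.genes == ["g00", "g01"] and cluster.spacer_tier == 0

    def test_pair_beyond_100kb_not_tandem(self):
        genes, family = self.genes_at([1, 150_001], [True, True])
        assert classify_tandem(family, genes) == []

    def test_spacer_tier_reflects_intervening_genes(self):
        starts = [1, 10_001, 20_001, 30_001, 40_001, 50_001, 60_001]
        flags = [True, False, False, False, False, True, True]
        genes, family = self.genes_at(starts, flags)
        (cluster,) = classify_tandem(family, genes)
        assert cluster.genes == ["g00", "g05", "g06"]
        assert cluster.spacer_tier == 5  # four spacers between g00 and g05
        assert cluster.max_span_ok

    def test_agrees_with_exhaustive_oracle_on_random_layouts(self):
        import numpy as np

        rng = np.random.default_rng(17)
        for trial in range(25):
            n = int(rng.integers(5, 50))
            starts = np.cumsum(rng.integers(2_000, 60_000, size=n)).tolist()
            flags = rng.random(n) < 0.4
            genes, family = self.genes_at(starts, flags.tolist())
            got = [tuple(c.genes) for c in classify_tandem(family, genes)]
            positions = {
                g.gene_id: (g.chromosome, g.start, g.rank) for g in genes
            }
            want = oracle_tandem_chains(positions, family)
            assert got == want, f"trial {trial}"


class TestSyntenyQuality:
    @pytest.mark.parametrize(
        "a,b,m,q", [(10, 10, 10, 1.0), (10, 10, 0, 0.0), (12, 8, 5, 0.5)]
    )
    def test_formula(self, a, b, m, q):
        assert synteny_quality([f"a{i}" for i in range(a)], [f"b{i}" for i in range(b)], m) == q

    def test_symmetry_and_bounds(self):
        a, b = [f"a{i}" for i in range(7)], [f"b{i}" for i in range(13)]
        assert synteny_quality(a, b, 5) == synteny_quality(b, a, 5)
        assert 0.0 <= synteny_quality(a, b, 5) <= 1.0

    def test_empty_segments_error(self):
        with pytest.raises(ValueError):
            synteny_quality([], [], 0)


class TestInterspecies:
    def two_species(self):
        genes = chromosome(30, species="spA", prefix="a") + chromosome(
            30, chrom="chr1", species="spB", prefix="b"
        )
        return assign_ranks(genes)

    def test_conserved_segments_form_a_block(self):
        genes = self.two_species()
        pairs = [(f"a{i:03d}", f"b{i:03d}", 1e-40) for i in range(8, 23)]
        idx = hit_index(*pairs)
        blocks = detect_interspecies_block("a015", ["b015"], genes, idx)
        assert len(blocks) == 1
        assert len(blocks[0].homolog_pairs) >= 3
        assert 0 < blocks[0].quality <= 1

    def test_two_shared_genes_are_not_enough(self):
        genes = self.two_species()
        idx = hit_index(("a014", "b014", 1e-40), ("a016", "b016", 1e-40))
        assert detect_interspecies_block("a015", ["b015"], genes, idx) == []

    def test_anchor_without_hits_gives_nothing(self):
        genes = self.two_species()
        assert detect_interspecies_block("a015", ["b015"], genes, HitIndex()) == []

    def test_evalue_threshold_is_stricter_than_intraspecies(self):
        genes = self.two_species()
        pairs = [(f"a{i:03d}", f"b{i:03d}", 1e-15) for i in range(10, 20)]
        idx = hit_index(*pairs)
        assert detect_interspecies_block("a015", ["b015"], genes, idx) == []


class TestOrthologGroups:
    def seg_block(self, sa, aa, sb, ab):
        return SyntenicBlock(sa, sb, aa, ab, [(aa, ab), ("x", "y"), ("z", "w")], 0.5)

    def test_chain_of_links_becomes_one_group(self):
        blocks = [
            self.seg_block("A", "a1", "B", "b1"),
            self.seg_block("B", "b1", "C", "c1"),
            self.seg_block("C", "c1", "D", "d1"),
        ]
        (group,) = assemble_ortholog_groups(blocks)
        assert len(group.segments) == 4 and len(group.species) == 4

    def test_disjoint_pairs_stay_separate(self):
        blocks = [
            self.seg_block("A", "a1", "B", "b1"),
            self.seg_block("A", "a2", "B", "b2"),
        ]
        groups = assemble_ortholog_groups(blocks)
        assert len(groups) == 2
        assert groups[0].group_id == "OG01" and groups[1].group_id == "OG02"

    def test_single_species_components_are_dropped(self):
        intra = [
            DuplicatedBlock("A", "a1", "a2", [("x", "y"), ("z", "w")], 2, "flexible")
        ]
        assert assemble_ortholog_groups([], intra) == []

    def test_intra_edges_join_homoeologs_into_the_group(self):
        blocks = [self.seg_block("A", "a1", "B", "b1")]
        intra = [
            DuplicatedBlock("A", "a1", "a2", [("x", "y")] * 4, 4, "duplicated")
        ]
        (group,) = assemble_ortholog_groups(blocks, intra)
        assert ("A", "a2") in group.segments
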