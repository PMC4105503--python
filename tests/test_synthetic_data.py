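import math

import numpy as np
import pytest

from conftest import random_cds
from oracles import oracle_ng86
from wgdscan import synthetic_data as sd
from wgdscan.genome_model import read_annotation, read_sequences


def small_config(**overrides):
    base = dict(
        n_chromosomes=2,
        genes_per_chromosome=30,
        n_family_loci=2,
        wgd_events=[sd.WgdEvent(0.2, 0.0, 0.0)],
        tandem_prob=0.0,
        mean_gene_length_codons=100,
        seed=3,
    )
    base.update(overrides)
    return sd.SimulationConfig(**base)


class TestEvolvePair:
    def test_zero_target_returns_input(self):
        cds = random_cds(np.random.default_rng(1), 50)
        assert sd.evolve_pair(cds, 0.0, 0.3, 1) == cds

    def test_measured_ks_reaches_target(self):
        rng = np.random.default_rng(2)
        cds = random_cds(rng, 300)
        evolved = sd.evolve_pair(cds, 0.3, 0.3, 7)
        got = oracle_ng86(cds, evolved)
        assert got["Ks"] >= 0.3
        assert got["Ks"] < 0.3 * 1.15  # stops at first crossing

    def test_omega_zero_preserves_protein(self):
        from wgdscan.genome_model import translate_cds

        cds = random_cds(np.random.default_rng(3), 120)
        evolved = sd.evolve_pair(cds, 0.25, 0.0, 9)
        assert translate_cds(evolved) == translate_cds(cds)
        assert evolved != cds

    def test_unreachable_target_errors(self):
        # Met-Trp has no synonymous site and omega 0 blocks every
        # nonsynonymous change, so no target is reachable
        with pytest.raises(ValueError, match="unreachable"):
            sd.evolve_pair("ATGTGG", 0.5, 0.0, 1)


class TestSimulateGenome:
    def test_same_seed_is_byte_identical(self, tmp_path):
        a = sd.simulate_genome(small_config())
        b = sd.simulate_genome(small_config())
        pa = sd.emit(a, tmp_path / "a")
        pb = sd.emit(b, tmp_path / "b")
        for key in pa:
            assert pa[key].read_bytes() == pb[key].read_bytes(), key

    def test_zero_loss_doubles_gene_count(self):
        genome = sd.simulate_genome(small_config())
        assert len(genome.genes) == 2 * 2 * 30

    def test_total_loss_leaves_no_surviving_pair(self):
        genome = sd.simulate_genome(
            small_config(wgd_events=[sd.WgdEvent(0.2, 1.0, 1.0)])
        )
        assert genome.truth.homolog_pairs == []

    def test_invalid_config_rejected_before_work(self):
        with pytest.raises(ValueError):
            sd.simulate_genome(small_config(tandem_prob=1.5))
        with pytest.raises(ValueError):
            sd.simulate_genome(
                small_config(wgd_events=[sd.WgdEvent(0.2, 0.1), sd.WgdEvent(0.7, 0.1)])
            )

    def test_family_gets_both_domains(self):
        genome = sd.simulate_genome(small_config())
        labels = {}
        for h in genome.domains:
            labels.setdefault(h.gene_id, set()).add(h.domain_label)
        for gid in genome.family:
            assert labels[gid] == {"DBD", "HR-A/B"}

    def test_tandem_copies_recorded_in_truth(self):
        genome = sd.simulate_genome(small_config(tandem_prob=1.0, seed=5))
        assert len(genome.truth.tandem_clusters) == len(genome.family) // 2
        for _sp, ids in genome.truth.tandem_clusters:
            assert len(ids) == 2

    def test_truth_pair_count_matches_survivors(self):
        genome = sd.simulate_genome(
            small_config(wgd_events=[sd.WgdEvent(0.2, 0.3, 0.3)], seed=9)
        )
        by_locus = {}
        for g in genome.genes:
            locus = g.gene_id.split("_")[1].split("w")[0]
            by_locus.setdefault(locus, []).append(g.gene_id)
        expected = sum(
            len(m) * (len(m) - 1) // 2 for m in by_locus.values()
        )
        assert len(genome.truth.homolog_pairs) == expected


class TestEmitRoundtrip:
    def test_reread_preserves_ranks_and_sequences(self, tmp_path):
        genome = sd.simulate_genome(small_config())
        paths = sd.emit(genome, tmp_path)
        reread = read_annotation(paths["gff3"], "sim")
        orig = {g.gene_id: g.rank for g in genome.genes}
        assert {g.gene_id: g.rank for g in reread} == orig
        records = read_sequences(paths["cds"], paths["protein"])
        assert set(records) == set(genome.records)


class TestMultiLineage:
    def test_lineage_event_depth_layering(self):
        """Pairs coalescing at each event measure that event's Ks: the
        shared ancient WGD, the lineage-specific recent WGD, and
        orthologs at the speciation depth."""
        cfg = small_config(
            n_chromosomes=1,
            genes_per_chromosome=20,
            n_family_loci=1,
            wgd_events=[sd.WgdEvent(0.7, 0.0, 0.0)],
            mean_gene_length_codons=300,
            seed=13,
        )
        genome = sd.simulate_lineages(
            cfg,
            [sd.LineageSpec("A", (sd.WgdEvent(0.155, 0.0, 0.0),)), sd.LineageSpec("B")],
            speciation_ks=0.45,
        )
        recent = [p.realized_ks for p in genome.truth.homolog_pairs if p.event_label == "recent"]
        ancient = [p.realized_ks for p in genome.truth.homolog_pairs if p.event_label == "ancient"]
        assert recent and ancient
        assert abs(np.median(recent) - 0.155) / 0.155 < 0.25
        assert abs(np.median(ancient) - 0.70) / 0.70 < 0.15
        # cross-lineage orthologs measure the speciation depth
        a_genes = {g.gene_id for g in genome.genes if g.species == "A"}
        ortho = []
        for ga in sorted(a_genes):
            label = ga.split("_")[1]
            gb = f"B_{label}"
            if "w2" not in label and gb in genome.records:
                cols = list(zip(sd._codons(genome.records[ga].cds),
                                sd._codons(genome.records[gb].cds)))
                from wgdscan.evolrates import ng86

                ortho.append(ng86(cols, ga, gb).Ks)
        assert ortho and abs(np.median(ortho) - 0.45) / 0.45 < 0.2

    def test_zero_events_negative_control(self):
        cfg = small_config(wgd_events=[])
        genome = sd.simulate_lineages(
            cfg, [sd.LineageSpec("A"), sd.LineageSpec("B")], speciation_ks=0.3
        )
        assert genome.truth.anchor_pairs() == []
        for sp in ("A", "B"):
            census = genome.truth.true_ortholog_census(sp)
            assert census.pair_groups == 0
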