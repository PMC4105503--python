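import numpy as np
import pytest

from wgdscan import synthetic_data as sd
from wgdscan.genome_model import SequenceRecord, translate_cds


def make_record(gene_id: str, cds: str) -> SequenceRecord:
    return SequenceRecord(gene_id=gene_id, cds=cds, protein=translate_cds(cds))


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(sd.SENSE_CODONS), size=n_codons - 1)
    return "ATG" + "".join(sd.SENSE_CODONS[i] for i in idx)


@pytest.fixture(scope="session")
def one_wgd_genome():
    """One WGD at Ks 0.15, zero loss, well-separated family loci: every
    flank is perfectly conserved, so detection failures are algorithmic."""
    cfg = sd.SimulationConfig(
        n_chromosomes=2,
        genes_per_chromosome=80,
        n_family_loci=4,
        wgd_events=[sd.WgdEvent(0.15, 0.0, 0.0)],
        tandem_prob=0.0,
        mean_gene_length_codons=150,
        seed=11,
    )
    return sd.simulate_genome(cfg)


@pytest.fixture(scope="session")
def one_wgd_index(one_wgd_genome):
    from wgdscan.homology import build_index

    return build_index(one_wgd_genome.records)


@pytest.fixture(scope="session")
def two_lineage_run():
    """The study-conditions analog: 17 family loci, shared ancient WGD
    (Ks 0.70, family loss 25%) plus a one-lineage recent WGD (Ks 0.155,
    family loss 16%), analyzed end to end. One locus per chromosome keeps
    anchor windows disjoint, as in real genomes where family members sit
    on separate chromosomes."""
    from wgdscan.pipeline import analyze

    cfg = sd.papilionoid_config(seed=0)
    shared = [e for e in cfg.wgd_events if e.target_ks >= 0.25]
    recent = tuple(e for e in cfg.wgd_events if e.target_ks < 0.25)
    cfg.wgd_events = shared
    genome = sd.simulate_lineages(
        cfg,
        [sd.LineageSpec("gmx", recent), sd.LineageSpec("vul")],
        speciation_ks=0.45,
    )
    result = analyze(genome.genes, genome.records, genome.domains)
    return genome, result
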