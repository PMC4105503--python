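"""Simulation of genomes with a known polyploidy/loss/tandem history.

The generator emulates a papilionoid-legume-like history: an ancestral
gene order; a shared ancient whole-genome duplication whose copy pairs
measure Ks ~= 0.70 today; an optional lineage-specific recent WGD at
Ks ~= 0.155; independent per-copy gene loss (fractionation) after each
round, heavier for background genes than for the retained anchor family;
occasional tandem duplication; and codon-level divergence evolved under
purifying selection (omega < 1).

Divergence is applied time-layered and symmetrically: between
consecutive events every surviving gene evolves by half the remaining
event depth, so *every* pair coalescing at a given WGD measures that
event's target Ks, exactly as a rate-constant clock implies. Sequence
evolution is substitution-by-substitution with synonymous changes
accepted at rate 1, nonsynonymous at rate omega and stop-creating
changes rejected, stopping when the NG86-measured Ks along the branch
first reaches its target, so realized distances track targets to within
one substitution.

Every run is reproducible from its seed, and truth tables record the
full genealogy so each pipeline stage can be scored against the history
that generated its input.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .evolrates import (
    BASES,
    CODON_TABLE,
    STOP_CODONS,
    assign_wgd_event,
    codon_pair_differences,
    codon_sites,
    jukes_cantor,
    ng86,
)
from .genome_model import DomainHit, GeneModel, SequenceRecord, assign_ranks
from .homology import HitIndex, SimilarityHit
from .loss_inference import DuplicationGroupModel, OrthoCensus
from .synteny import TandemCluster

SENSE_CODONS = tuple(
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in STOP_CODONS
)


@dataclass(frozen=True)
class WgdEvent:
    """One whole-genome duplication: pairs created by it measure
    ``target_ks`` today; each copy is deleted independently with the
    family/background per-copy loss probability."""

    target_ks: float
    loss_prob: float
    background_loss_prob: float | None = None

    def bg_loss(self) -> float:
        return (
            self.loss_prob
            if self.background_loss_prob is None
            else self.background_loss_prob
        )


@dataclass
class SimulationConfig:
    n_chromosomes: int = 2
    genes_per_chromosome: int = 60
    n_family_loci: int = 8
    wgd_events: list[WgdEvent] = field(default_factory=list)
    tandem_prob: float = 0.05
    omega: float = 0.3
    mean_gene_length_codons: int = 300
    intergenic_bp: int = 2000
    seed: int = 0
    species: str = "sim"
    tandem_ks: float = 0.01
    decoy_domain_prob: float = 0.02

    def validate(self) -> None:
        for name in ("tandem_prob", "decoy_domain_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for e in self.wgd_events:
            if not 0.0 <= e.loss_prob <= 1.0 or not 0.0 <= e.bg_loss() <= 1.0:
                raise ValueError("loss probabilities must be in [0,1]")
            if e.target_ks < 0:
                raise ValueError("target_ks must be >= 0")
        depths = [e.target_ks for e in self.wgd_events]
        if any(d2 >= d1 for d1, d2 in zip(depths, depths[1:])):
            raise ValueError("wgd_events must be ordered oldest (deepest Ks) first")
        if self.n_family_loci > self.n_chromosomes * self.genes_per_chromosome:
            raise ValueError("more family loci than genes")


def papilionoid_config(**overrides) -> SimulationConfig:
    """The default study conditions: one ancient WGD at Ks 0.70 with 25%
    per-copy family loss, one recent WGD at Ks 0.155 with 16% family
    loss; background fractionation 40%/45%; 17 family loci on separate
    chromosomes so anchor windows stay disjoint after fractionation."""
    cfg = SimulationConfig(
        wgd_events=[
            WgdEvent(0.70, 0.25, 0.40),
            WgdEvent(0.155, 0.16, 0.45),
        ],
        n_chromosomes=17,
        genes_per_chromosome=110,
        n_family_loci=17,
        intergenic_bp=6000,
    )
    return replace(cfg, **overrides)


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------


def _codon_contrib(orig: str, cur: str) -> tuple[float, float, float, float]:
    """This codon pair's (S, N, Sd, Nd) contribution; zeros when no
    stop-free pathway exists (the column is skipped)."""
    sd, nd, usable = codon_pair_differences(orig, cur)
    if not usable:
        return 0.0, 0.0, 0.0, 0.0
    so, no = codon_sites(orig)
    sc, nc = codon_sites(cur)
    return (so + sc) / 2.0, (no + nc) / 2.0, sd, nd


def evolve_pair(
    cds: str,
    target_ks: float,
    omega: float = 0.3,
    seed: int | np.random.Generator = 0,
) -> str:
    """Evolve a copy of ``cds`` until NG86 Ks(original, evolved) first
    reaches ``target_ks``; returns the evolved CDS.

    Proposals are uniform single-base changes; synonymous proposals are
    always accepted, nonsynonymous ones with probability ``omega``, and
    changes creating a stop codon are rejected. Raises if the target is
    unreachable within a bounded number of proposals (sequence too short
    or target beyond saturation).
    """
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    if target_ks <= 0:
        return cds
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    orig = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    cur = list(orig)
    n_codons = len(cur)
    contrib = [_codon_contrib(o, c) for o, c in zip(orig, cur)]
    S = sum(c[0] for c in contrib)
    N = sum(c[1] for c in contrib)
    Sd = sum(c[2] for c in contrib)
    Nd = sum(c[3] for c in contrib)
    max_attempts = max(200_000, 3000 * n_codons)
    for _ in range(max_attempts):
        pos = int(rng.integers(0, 3 * n_codons))
        ci, off = divmod(pos, 3)
        codon = cur[ci]
        alts = [b for b in BASES if b != codon[off]]
        base = alts[int(rng.integers(0, 3))]
        new_codon = codon[:off] + base + codon[off + 1 :]
        if new_codon in STOP_CODONS:
            continue
        syn = CODON_TABLE[codon] == CODON_TABLE[new_codon]
        if not syn and rng.random() > omega:
            continue
        cur[ci] = new_codon
        old = contrib[ci]
        new = _codon_contrib(orig[ci], new_codon)
        contrib[ci] = new
        S += new[0] - old[0]
        N += new[1] - old[1]
        Sd += new[2] - old[2]
        Nd += new[3] - old[3]
        ks = jukes_cantor(Sd / S) if S > 0 else 0.0
        if not math.isnan(ks) and ks >= target_ks:
            return "".join(cur)
    raise ValueError(
        f"target Ks {target_ks} unreachable for a {n_codons}-codon sequence"
    )


# ---------------------------------------------------------------------------
# Genome representation and history
# ---------------------------------------------------------------------------


@dataclass
class SimGene:
    label: str  # ancestral locus label + copy-path suffixes
    locus: str  # ancestral locus label
    path: tuple[int, ...]  # which copy at each WGD event passed through
    is_family: bool
    cds: str
    tandem_of: str | None = None

    def gene_id(self, species: str) -> str:
        return f"{species}_{self.label}"


@dataclass(frozen=True)
class TruePair:
    gene_a: str
    gene_b: str
    species: str
    event_index: int  # index into the lineage's event depth list
    target_ks: float
    event_label: str
    is_family: bool
    locus: str
    realized_ks: float = math.nan


@dataclass
class TruthTables:
    """Genealogy of a simulated run: every surviving homolog pair with
    its generating event, tandem clusters, per-locus survivors, and the
    event depth list per lineage."""

    homolog_pairs: list[TruePair]
    tandem_clusters: list[tuple[str, tuple[str, ...]]]
    locus_members: dict[tuple[str, str], list[str]]  # (species, locus) -> family ids
    event_depths: dict[str, list[float]]
    speciation_ks: float | None = None

    def anchor_pairs(self, species: str | None = None) -> list[TruePair]:
        """Family homolog pairs within one lineage — the anchor pairs an
        intraspecies scan should recover as blocks."""
        return [
            p
            for p in self.homolog_pairs
            if p.is_family and (species is None or p.species == species)
        ]

    def true_duplication_groups(self, species: str) -> list[DuplicationGroupModel]:
        """Groups built directly from the history: loci with >=2 surviving
        family members, with recent/ancient pair labels from the true
        generating events (tandem copies excluded)."""
        groups: list[DuplicationGroupModel] = []
        pairs = self.anchor_pairs(species)
        loci = sorted(
            {
                locus
                for (sp, locus), members in self.locus_members.items()
                if sp == species and len(members) >= 2
            }
        )
        for i, locus in enumerate(loci):
            members = self.locus_members[(species, locus)]
            recent = sorted(
                tuple(sorted((p.gene_a, p.gene_b)))
                for p in pairs
                if p.locus == locus and p.event_label == "recent"
            )
            ancient = sorted(
                tuple(sorted((p.gene_a, p.gene_b)))
                for p in pairs
                if p.locus == locus and p.event_label == "ancient"
            )
            groups.append(
                DuplicationGroupModel(
                    group_id=f"{species}-TRUE{i + 1:02d}",
                    species=species,
                    members=sorted(members),
                    recent_pairs=recent,
                    ancient_edges=ancient,
                    segmental_members=[],
                )
            )
        return groups

    def shared_loci(self, min_species: int = 2) -> list[str]:
        """Ancestral family loci surviving in >= min_species lineages —
        the true orthologous segment groups."""
        by_locus: dict[str, set[str]] = {}
        for (sp, locus), members in self.locus_members.items():
            if members:
                by_locus.setdefault(locus, set()).add(sp)
        return sorted(l for l, sps in by_locus.items() if len(sps) >= min_species)

    def true_ortholog_census(self, species: str, min_species: int = 2) -> OrthoCensus:
        loci = self.shared_loci(min_species)
        single = pair = absent = 0
        for locus in loci:
            n = len(self.locus_members.get((species, locus), []))
            if n == 0:
                absent += 1
            elif n == 1:
                single += 1
            else:
                pair += 1
        return OrthoCensus(
            lineage=species,
            n_groups=len(loci),
            single_groups=single,
            pair_groups=pair,
            absent_groups=absent,
        )


@dataclass
class SimulatedGenome:
    genes: list[GeneModel]
    records: dict[str, SequenceRecord]
    domains: list[DomainHit]
    truth: TruthTables
    family: list[str]
    config: SimulationConfig


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons - 1)
    return "ATG" + "".join(SENSE_CODONS[i] for i in idx)


def _build_ancestor(
    config: SimulationConfig, rng: np.random.Generator
) -> list[list[SimGene]]:
    """Ancestral chromosomes with family loci spread evenly (with jitter)
    so neighbouring anchor windows stay distinct."""
    per_chrom = [
        config.n_family_loci // config.n_chromosomes
        + (1 if c < config.n_family_loci % config.n_chromosomes else 0)
        for c in range(config.n_chromosomes)
    ]
    chromosomes: list[list[SimGene]] = []
    for ci in range(config.n_chromosomes):
        n = config.genes_per_chromosome
        k = per_chrom[ci]
        family_pos: set[int] = set()
        if k:
            spacing = n / k
            for j in range(k):
                base = int((j + 0.5) * spacing)
                jitter = int(rng.integers(-min(2, n // 10) - 0, min(2, n // 10) + 1))
                family_pos.add(min(n - 1, max(0, base + jitter)))
            while len(family_pos) < k:  # jitter collisions
                family_pos.add(int(rng.integers(0, n)))
        chrom = []
        for gi in range(n):
            label = f"c{ci + 1}g{gi + 1:04d}"
            chrom.append(
                SimGene(
                    label=label,
                    locus=label,
                    path=(),
                    is_family=gi in family_pos,
                    cds=_random_cds(rng, config.mean_gene_length_codons),
                )
            )
        chromosomes.append(chrom)
    return chromosomes


def _duplicate(
    chromosomes: list[list[SimGene]], event_idx: int
) -> list[list[SimGene]]:
    out: list[list[SimGene]] = []
    copies: list[list[SimGene]] = []
    for chrom in chromosomes:
        kept, dup = [], []
        for g in chrom:
            kept.append(replace(g, path=g.path + (0,)))
            dup.append(
                replace(g, label=f"{g.label}w{event_idx}", path=g.path + (1,))
            )
        out.append(kept)
        copies.append(dup)
    return out + copies


def _apply_loss(
    chromosomes: list[list[SimGene]], event: WgdEvent, rng: np.random.Generator
) -> list[list[SimGene]]:
    out = []
    for chrom in chromosomes:
        kept = []
        for g in chrom:
            p = event.loss_prob if g.is_family else event.bg_loss()
            if rng.random() >= p:
                kept.append(g)
        out.append(kept)
    return out


def _evolve_all(
    chromosomes: list[list[SimGene]],
    branch_ks: float,
    omega: float,
    rng: np.random.Generator,
) -> None:
    if branch_ks <= 0:
        return
    for chrom in chromosomes:
        for g in chrom:
            g.cds = evolve_pair(g.cds, branch_ks, omega, rng)


def _add_tandems(
    chromosomes: list[list[SimGene]], config: SimulationConfig, rng: np.random.Generator
) -> None:
    for chrom in chromosomes:
        i = 0
        while i < len(chrom):
            g = chrom[i]
            if g.is_family and g.tandem_of is None and rng.random() < config.tandem_prob:
                copy = replace(
                    g,
                    label=f"{g.label}t",
                    tandem_of=g.label,
                    cds=evolve_pair(g.cds, config.tandem_ks, config.omega, rng),
                )
                chrom.insert(i + 1, copy)
                i += 1
            i += 1


def _finalize_lineage(
    species: str,
    chromosomes: list[list[SimGene]],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[list[GeneModel], dict[str, SequenceRecord], list[DomainHit], list[str]]:
    from .genome_model import translate_cds

    genes: list[GeneModel] = []
    records: dict[str, SequenceRecord] = {}
    domains: list[DomainHit] = []
    family: list[str] = []
    gene_nt = 3 * config.mean_gene_length_codons
    for ci, chrom in enumerate(chromosomes):
        for gi, g in enumerate(chrom):
            gid = g.gene_id(species)
            start = 1 + gi * (gene_nt + config.intergenic_bp)
            genes.append(
                GeneModel(
                    gene_id=gid,
                    species=species,
                    chromosome=f"chr{ci + 1}",
                    start=start,
                    end=start + len(g.cds) - 1,
                    strand="+" if rng.random() < 0.5 else "-",
                    family_member=g.is_family,
                )
            )
            protein = translate_cds(g.cds)
            records[gid] = SequenceRecord(gene_id=gid, cds=g.cds, protein=protein)
            if g.is_family:
                family.append(gid)
                plen = len(protein)
                domains.append(DomainHit(gid, "DBD", 5, min(104, plen), 250.0))
                domains.append(
                    DomainHit(gid, "HR-A/B", min(120, plen - 30), min(155, plen), 80.0)
                )
            elif rng.random() < config.decoy_domain_prob:
                domains.append(DomainHit(gid, "DBD", 5, min(104, len(protein)), 60.0))
    assign_ranks(genes)
    return genes, records, domains, sorted(family)


def _collect_truth(
    lineages: dict[str, list[list[SimGene]]],
    event_depths: dict[str, list[float]],
    compute_realized: bool,
    records: dict[str, SequenceRecord],
    speciation_ks: float | None,
) -> TruthTables:
    pairs: list[TruePair] = []
    tandems: list[tuple[str, tuple[str, ...]]] = []
    locus_members: dict[tuple[str, str], list[str]] = {}
    for species, chromosomes in lineages.items():
        depths = event_depths[species]
        by_locus: dict[str, list[SimGene]] = {}
        for chrom in chromosomes:
            for g in chrom:
                by_locus.setdefault(g.locus, []).append(g)
        for locus in sorted(by_locus):
            members = by_locus[locus]
            wgd_members = [g for g in members if g.tandem_of is None]
            locus_members[(species, locus)] = sorted(
                g.gene_id(species) for g in wgd_members if g.is_family
            )
            for t in members:
                if t.tandem_of is not None:
                    sib = next(
                        (m for m in members if m.label == t.tandem_of), None
                    )
                    if sib is not None:
                        tandems.append(
                            (species, (sib.gene_id(species), t.gene_id(species)))
                        )
            for i, a in enumerate(wgd_members):
                for b in wgd_members[i + 1 :]:
                    diff = next(
                        (k for k, (x, y) in enumerate(zip(a.path, b.path)) if x != y),
                        None,
                    )
                    if diff is None:
                        continue
                    target = depths[diff]
                    ga, gb = sorted((a.gene_id(species), b.gene_id(species)))
                    realized = math.nan
                    if compute_realized:
                        cols = list(
                            zip(
                                _codons(records[ga].cds),
                                _codons(records[gb].cds),
                            )
                        )
                        realized = ng86(cols, ga, gb).Ks
                    pairs.append(
                        TruePair(
                            gene_a=ga,
                            gene_b=gb,
                            species=species,
                            event_index=diff,
                            target_ks=target,
                            event_label=assign_wgd_event(target),
                            is_family=a.is_family,
                            locus=locus,
                            realized_ks=realized,
                        )
                    )
    pairs.sort(key=lambda p: (p.species, p.gene_a, p.gene_b))
    return TruthTables(
        homolog_pairs=pairs,
        tandem_clusters=sorted(tandems),
        locus_members=locus_members,
        event_depths=event_depths,
        speciation_ks=speciation_ks,
    )


def _codons(cds: str) -> list[str]:
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]


def simulate_genome(
    config: SimulationConfig, compute_realized_ks: bool = True
) -> SimulatedGenome:
    """Simulate a single-lineage genome under ``config``.

    Events are applied oldest first: duplicate every chromosome, delete
    each copy independently with its per-copy loss probability, then let
    every surviving gene evolve by half the Ks depth separating this
    event from the next (or from the present).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    chromosomes = _build_ancestor(config, rng)
    depths = [e.target_ks for e in config.wgd_events]
    for k, event in enumerate(config.wgd_events):
        chromosomes = _duplicate(chromosomes, k + 1)
        chromosomes = _apply_loss(chromosomes, event, rng)
        next_depth = depths[k + 1] if k + 1 < len(depths) else 0.0
        _evolve_all(chromosomes, (event.target_ks - next_depth) / 2.0, config.omega, rng)
    _add_tandems(chromosomes, config, rng)
    genes, records, domains, family = _finalize_lineage(
        config.species, chromosomes, config, rng
    )
    truth = _collect_truth(
        {config.species: chromosomes},
        {config.species: depths},
        compute_realized_ks,
        records,
        None,
    )
    return SimulatedGenome(
        genes=genes,
        records=records,
        domains=domains,
        truth=truth,
        family=family,
        config=config,
    )


@dataclass(frozen=True)
class LineageSpec:
    """A descendant lineage: its name and any WGD events that happened
    after the speciation (ordered oldest first, depths < speciation_ks)."""

    name: str
    wgd_events: tuple[WgdEvent, ...] = ()


def simulate_lineages(
    config: SimulationConfig,
    lineages: Sequence[LineageSpec],
    speciation_ks: float = 0.45,
    compute_realized_ks: bool = True,
) -> SimulatedGenome:
    """Simulate several lineages sharing the configured WGD events.

    Shared duplications happen in the common ancestor, but fractionation
    after them is lineage-specific: loss draws for shared events are
    deferred until after the split, so each lineage loses its own copies
    independently, as post-polyploid genomes do. Orthologs between
    lineages diverge to ``speciation_ks``.
    """
    config.validate()
    shared_depths = [e.target_ks for e in config.wgd_events]
    if shared_depths and speciation_ks >= min(shared_depths):
        pass  # speciation after the shared events (depth below them) is the norm
    rng = np.random.default_rng(config.seed)
    chromosomes = _build_ancestor(config, rng)
    for k, event in enumerate(config.wgd_events):
        chromosomes = _duplicate(chromosomes, k + 1)
        next_depth = (
            shared_depths[k + 1] if k + 1 < len(shared_depths) else speciation_ks
        )
        _evolve_all(chromosomes, (event.target_ks - next_depth) / 2.0, config.omega, rng)

    all_genes: list[GeneModel] = []
    all_records: dict[str, SequenceRecord] = {}
    all_domains: list[DomainHit] = []
    all_family: list[str] = []
    sim_lineages: dict[str, list[list[SimGene]]] = {}
    event_depths: dict[str, list[float]] = {}
    for spec in lineages:
        lin_rng = np.random.default_rng(rng.integers(0, 2**31))
        lin_chrom = [[replace(g) for g in chrom] for chrom in chromosomes]
        # deferred, lineage-specific fractionation for the shared events
        for event in config.wgd_events:
            lin_chrom = _apply_loss(lin_chrom, event, lin_rng)
        own_depths = [e.target_ks for e in spec.wgd_events]
        first_own = own_depths[0] if own_depths else 0.0
        _evolve_all(
            lin_chrom, (speciation_ks - first_own) / 2.0, config.omega, lin_rng
        )
        for k, event in enumerate(spec.wgd_events):
            lin_chrom = _duplicate(lin_chrom, len(config.wgd_events) + k + 1)
            lin_chrom = _apply_loss(lin_chrom, event, lin_rng)
            next_depth = own_depths[k + 1] if k + 1 < len(own_depths) else 0.0
            _evolve_all(
                lin_chrom, (event.target_ks - next_depth) / 2.0, config.omega, lin_rng
            )
        _add_tandems(lin_chrom, config, lin_rng)
        genes, records, domains, family = _finalize_lineage(
            spec.name, lin_chrom, config, lin_rng
        )
        all_genes.extend(genes)
        all_records.update(records)
        all_domains.extend(domains)
        all_family.extend(family)
        sim_lineages[spec.name] = lin_chrom
        event_depths[spec.name] = shared_depths + own_depths
    truth = _collect_truth(
        sim_lineages, event_depths, compute_realized_ks, all_records, speciation_ks
    )
    return SimulatedGenome(
        genes=all_genes,
        records=all_records,
        domains=all_domains,
        truth=truth,
        family=sorted(all_family),
        config=config,
    )


# ---------------------------------------------------------------------------
# Controls and helpers
# ---------------------------------------------------------------------------


def shuffle_gene_positions(
    genes: Sequence[GeneModel], seed: int = 0, keep_family: bool = True
) -> list[GeneModel]:
    """Negative control: permute the genomic slots of (non-family) genes
    across chromosomes, destroying local gene-order conservation while
    leaving every sequence and homology relation intact."""
    rng = np.random.default_rng(seed)
    movable = [g for g in genes if not (keep_family and g.family_member)]
    slots = [(g.species, g.chromosome, g.start, g.end, g.strand) for g in movable]
    order = rng.permutation(len(slots))
    out = [replace(g) for g in genes]
    movable_out = [g for g in out if not (keep_family and g.family_member)]
    for g, si in zip(movable_out, order):
        sp, chrom, start, end, strand = slots[int(si)]
        g.species, g.chromosome, g.start, g.end, g.strand = (
            sp,
            chrom,
            start,
            end,
            strand,
        )
    assign_ranks(out)
    return out


def truth_hit_index(truth: TruthTables) -> HitIndex:
    """A hit index derived from the genealogy: every true homolog pair is
    mutually each other's hit, with e-value a monotone proxy of its true
    divergence. Lets position-level logic be exercised at genome scale
    without sequence alignment."""
    index = HitIndex()
    for p in truth.homolog_pairs:
        exponent = max(10.0, 170.0 - 110.0 * p.target_ks)
        hit = SimilarityHit(
            query=p.gene_a,
            subject=p.gene_b,
            evalue=10.0 ** (-exponent),
            bitscore=exponent,
            identity_pct=100.0 * math.exp(-p.target_ks / 2.0),
        )
        index.add(hit)
        index.add(replace_hit(hit))
    return index.finalize()


def replace_hit(hit: SimilarityHit) -> SimilarityHit:
    return SimilarityHit(
        query=hit.subject,
        subject=hit.query,
        evalue=hit.evalue,
        bitscore=hit.bitscore,
        identity_pct=hit.identity_pct,
    )


def emit(genome: SimulatedGenome, out_dir: str | Path) -> dict[str, Path]:
    """Write the simulated genome as standard flat files: GFF3, CDS and
    protein FASTA, a domain TSV, and truth tables. Re-reading the GFF3
    reproduces identical gene ranks."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    gff = out / "genes.gff3"
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genome.genes, key=lambda g: (g.species, g.chromosome, g.start, g.gene_id)):
            fh.write(
                f"{g.chromosome}\twgdscan_sim\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id};species={g.species}\n"
            )
    paths["gff3"] = gff

    cds = out / "cds.fasta"
    prot = out / "protein.fasta"
    with open(cds, "w") as fc, open(prot, "w") as fp:
        for gid in sorted(genome.records):
            rec = genome.records[gid]
            fc.write(f">{gid}\n{rec.cds}\n")
            fp.write(f">{gid}\n{rec.protein}\n")
    paths["cds"] = cds
    paths["protein"] = prot

    dom = out / "domains.tsv"
    with open(dom, "w") as fh:
        fh.write("gene_id\tdomain_label\tstart_aa\tend_aa\tscore\n")
        for h in genome.domains:
            fh.write(
                f"{h.gene_id}\t{h.domain_label}\t{h.start_aa}\t{h.end_aa}\t{h.score}\n"
            )
    paths["domains"] = dom

    tp = out / "truth_pairs.tsv"
    with open(tp, "w") as fh:
        fh.write(
            "gene_a\tgene_b\tspecies\tevent_index\ttarget_ks\tevent_label\t"
            "is_family\tlocus\trealized_ks\n"
        )
        for p in genome.truth.homolog_pairs:
            fh.write(
                f"{p.gene_a}\t{p.gene_b}\t{p.species}\t{p.event_index}\t"
                f"{p.target_ks}\t{p.event_label}\t{int(p.is_family)}\t{p.locus}\t"
                f"{p.realized_ks}\n"
            )
    paths["truth_pairs"] = tp

    tt = out / "truth_tandem.tsv"
    with open(tt, "w") as fh:
        fh.write("species\tgenes\n")
        for sp, ids in genome.truth.tandem_clusters:
            fh.write(f"{sp}\t{','.join(ids)}\n")
    paths["truth_tandem"] = tt

    cfgp = out / "config.json"
    cfg = genome.config
    with open(cfgp, "w") as fh:
        json.dump(
            {
                "n_chromosomes": cfg.n_chromosomes,
                "genes_per_chromosome": cfg.genes_per_chromosome,
                "n_family_loci": cfg.n_family_loci,
                "wgd_events": [
                    [e.target_ks, e.loss_prob, e.bg_loss()] for e in cfg.wgd_events
                ],
                "tandem_prob": cfg.tandem_prob,
                "omega": cfg.omega,
                "mean_gene_length_codons": cfg.mean_gene_length_codons,
                "intergenic_bp": cfg.intergenic_bp,
                "seed": cfg.seed,
                "species": cfg.species,
            },
            fh,
            indent=1,
        )
    paths["config"] = cfgp
    return paths
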