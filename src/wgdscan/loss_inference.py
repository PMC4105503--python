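"""Duplicate-retention bookkeeping after one or two rounds of whole-genome
duplication.

The idealized model: every duplication group (a connected component of
within-species duplicated/flexible blocks) descends from one gene in the
pre-WGD ancestor, so after the shared ancient polyploidy each group
expects 2 lineages, and a lineage that also underwent the recent
tetraploidy expects each surviving post-ancient lineage (plus any
segmental duplicate that predated it) to double again. Comparing those
expectations with the observed members yields per-round loss percentages.

The packaged fixtures encode the soybean duplication-group data (dated
pairs, the flexible set, the segmental duplicate) and the ortholog-group
censuses of the single-WGD lineages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import networkx as nx

from .evolrates import assign_wgd_event, ks_to_mya
from .synteny import DuplicatedBlock, OrthologGroup


@dataclass(frozen=True)
class PairRecord:
    """One anchor pair feeding group assembly; event is None for flexible
    (undated) pairs."""

    species: str
    gene_a: str
    gene_b: str
    event: str | None = None
    ks_mean: float | None = None
    ks_sd: float | None = None
    n_flank: int | None = None
    date_mya: float | None = None


@dataclass
class DuplicationGroupModel:
    group_id: str
    species: str
    members: list[str]
    recent_pairs: list[tuple[str, str]]
    ancient_edges: list[tuple[str, str]]
    segmental_members: list[str]
    n_post_ancient_lineages_expected: int = 2

    @property
    def singles(self) -> list[str]:
        paired = {g for pair in self.recent_pairs for g in pair}
        return [m for m in self.members if m not in paired]


@dataclass
class LossReport:
    lineage: str
    n_groups: int
    expected_post_ancient: int
    retained_post_ancient: int
    lost_ancient: int
    ancient_loss_pct: float
    expected_post_recent: int | None = None
    lost_recent: int | None = None
    recent_loss_pct: float | None = None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass(frozen=True)
class OrthoCensus:
    """Per-lineage census over orthologous segment groups: how many groups
    hold one region, a duplicated pair, or no region of the lineage."""

    lineage: str
    n_groups: int
    single_groups: int
    pair_groups: int
    absent_groups: int


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def pair_records_from_blocks(blocks: Iterable[DuplicatedBlock]) -> list[PairRecord]:
    """Adapt dated/assigned intraspecies blocks to group-assembly input."""
    return [
        PairRecord(
            species=b.species,
            gene_a=b.anchor_a,
            gene_b=b.anchor_b,
            event=b.event if b.status == "duplicated" else None,
            ks_mean=b.mean_ks,
            ks_sd=b.sd_ks,
            n_flank=b.support,
            date_mya=b.date_mya,
        )
        for b in blocks
    ]


def build_groups(
    pairs: Sequence[PairRecord],
    segmental_flags: set[str] | None = None,
    include_flexible: bool = True,
) -> list[DuplicationGroupModel]:
    """Duplication groups as connected components over duplicated (and,
    by default, flexible) pairs within one species.

    Intermediate-event pairs mark a segmental duplication predating the
    recent WGD; unless explicit ``segmental_flags`` are given, the member
    of such a pair with no ancient-event edge is flagged as the segmental
    copy (ties: fewer ancient edges, then the lexicographically later id).
    """
    graphs: dict[str, nx.Graph] = {}
    for p in pairs:
        if p.event is None and not include_flexible:
            continue
        graphs.setdefault(p.species, nx.Graph()).add_edge(
            p.gene_a, p.gene_b, event=p.event
        )
    ancient_degree: dict[str, int] = {}
    for p in pairs:
        if p.event == "ancient":
            for g in (p.gene_a, p.gene_b):
                ancient_degree[g] = ancient_degree.get(g, 0) + 1
    segmental: set[str] = set(segmental_flags or ())
    if segmental_flags is None:
        for p in pairs:
            if p.event == "intermediate":
                a, b = p.gene_a, p.gene_b
                da, db = ancient_degree.get(a, 0), ancient_degree.get(b, 0)
                if da == db:
                    segmental.add(max(a, b))
                else:
                    segmental.add(a if da < db else b)
    groups: list[DuplicationGroupModel] = []
    for species in sorted(graphs):
        graph = graphs[species]
        components = sorted(
            (sorted(c) for c in nx.connected_components(graph)), key=lambda c: c[0]
        )
        for i, comp in enumerate(components):
            sub = graph.subgraph(comp)
            recent = sorted(
                tuple(sorted((u, v)))
                for u, v, ev in sub.edges(data="event")
                if ev == "recent"
            )
            ancient = sorted(
                tuple(sorted((u, v)))
                for u, v, ev in sub.edges(data="event")
                if ev == "ancient"
            )
            groups.append(
                DuplicationGroupModel(
                    group_id=f"{species}-DG{i + 1:02d}",
                    species=species,
                    members=comp,
                    recent_pairs=recent,
                    ancient_edges=ancient,
                    segmental_members=sorted(set(comp) & segmental),
                )
            )
    return groups


def count_two_round_losses(
    groups: Sequence[DuplicationGroupModel], lineage: str | None = None
) -> LossReport:
    """Loss accounting for a lineage that underwent both WGD rounds.

    Each group expects 2 post-ancient lineages. A post-ancient lineage
    survived if it is visible today as a recent pair or as a single gene
    (except segmental singles, which arose by segmental duplication after
    the ancient event and are not ancient survivors). Every survivor plus
    every segmental duplicate then doubled in the recent WGD, so the
    recent expectation is twice their sum, compared against the members
    actually observed.
    """
    if lineage is None:
        species = sorted({g.species for g in groups})
        lineage = species[0] if len(species) == 1 else "+".join(species)
    n_groups = len(groups)
    n_recent_pairs = sum(len(g.recent_pairs) for g in groups)
    singles = [m for g in groups for m in g.singles]
    segmental_singles = [
        m for g in groups for m in g.singles if m in set(g.segmental_members)
    ]
    n_members = sum(len(g.members) for g in groups)

    expected_post_ancient = 2 * n_groups
    retained_post_ancient = n_recent_pairs + len(singles) - len(segmental_singles)
    lost_ancient = expected_post_ancient - retained_post_ancient
    expected_post_recent = 2 * (retained_post_ancient + len(segmental_singles))
    lost_recent = expected_post_recent - n_members
    if lost_ancient < 0 or lost_recent < 0:
        raise ValueError(
            "inconsistent duplication groups: negative loss "
            f"(ancient {lost_ancient}, recent {lost_recent})"
        )
    return LossReport(
        lineage=lineage,
        n_groups=n_groups,
        expected_post_ancient=expected_post_ancient,
        retained_post_ancient=retained_post_ancient,
        lost_ancient=lost_ancient,
        ancient_loss_pct=_round_half_up(
            100.0 * lost_ancient / expected_post_ancient
        ) if expected_post_ancient else 0,
        expected_post_recent=expected_post_recent,
        lost_recent=lost_recent,
        recent_loss_pct=_round_half_up(100.0 * lost_recent / expected_post_recent)
        if expected_post_recent
        else 0,
    )


def count_one_round_losses(census: OrthoCensus) -> LossReport:
    """Loss accounting for a lineage with only the shared ancient WGD,
    from its orthologous-segment-group census."""
    if (
        census.single_groups + census.pair_groups + census.absent_groups
        != census.n_groups
    ):
        raise ValueError("census does not sum to n_groups")
    expected = 2 * census.n_groups
    retained = census.single_groups + 2 * census.pair_groups
    lost = expected - retained
    if lost < 0:
        raise ValueError("inconsistent census: negative loss")
    return LossReport(
        lineage=census.lineage,
        n_groups=census.n_groups,
        expected_post_ancient=expected,
        retained_post_ancient=retained,
        lost_ancient=lost,
        ancient_loss_pct=_round_half_up(100.0 * lost / expected) if expected else 0,
    )


def census_from_groups(
    ortho_groups: Sequence[OrthologGroup], lineage: str
) -> OrthoCensus:
    """Derive a lineage's census from assembled orthologous groups."""
    single = pair = absent = 0
    for g in ortho_groups:
        n = sum(1 for s, _a in g.segments if s == lineage)
        if n == 0:
            absent += 1
        elif n == 1:
            single += 1
        else:
            pair += 1
    return OrthoCensus(
        lineage=lineage,
        n_groups=len(ortho_groups),
        single_groups=single,
        pair_groups=pair,
        absent_groups=absent,
    )


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------


def _data_text(name: str) -> str:
    return resources.files("wgdscan.data").joinpath(name).read_text()


def load_dated_pairs(species: str | None = None) -> list[PairRecord]:
    """The packaged dated anchor pairs (per-block flank count, mean Ks,
    s.d. and printed date), event-labeled from mean Ks by the standard
    thresholds."""
    out: list[PairRecord] = []
    for line in _data_text("table2_pairs.tsv").splitlines()[1:]:
        sp, a, b, n_flank, ks, sd, date = line.split("\t")
        if species is not None and sp != species:
            continue
        out.append(
            PairRecord(
                species=sp,
                gene_a=a,
                gene_b=b,
                event=assign_wgd_event(float(ks)),
                ks_mean=float(ks),
                ks_sd=float(sd),
                n_flank=int(n_flank),
                date_mya=float(date),
            )
        )
    return out


def load_flexible_pairs(species: str | None = None) -> list[PairRecord]:
    """The packaged flexible-set anchor pairs (2-3 conserved flank genes;
    undated, event None)."""
    out: list[PairRecord] = []
    for line in _data_text("flexible_pairs.tsv").splitlines()[1:]:
        sp, a, b = line.split("\t")
        if species is not None and sp != species:
            continue
        out.append(PairRecord(species=sp, gene_a=a, gene_b=b))
    return out


def load_ortholog_censuses() -> list[OrthoCensus]:
    """Packaged per-lineage censuses over the 17 orthologous segment groups."""
    out: list[OrthoCensus] = []
    for line in _data_text("ortholog_census.tsv").splitlines()[1:]:
        lineage, n, single, pairs, absent = line.split("\t")
        out.append(
            OrthoCensus(
                lineage=lineage,
                n_groups=int(n),
                single_groups=int(single),
                pair_groups=int(pairs),
                absent_groups=int(absent),
            )
        )
    return out


def soybean_duplication_groups() -> list[DuplicationGroupModel]:
    """The soybean duplication-group fixture: dated pairs plus the four
    flexible pairs, with the segmental copy inferred from the
    intermediate-Ks pair."""
    pairs = load_dated_pairs("Gmax") + load_flexible_pairs("Gmax")
    return build_groups(pairs)
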