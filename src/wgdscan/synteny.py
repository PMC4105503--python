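"""Microsynteny detection anchored on gene-family members.

Implements the anchor-and-flank strategy: every family gene is an anchor;
the 15 protein-coding genes on each side form its flank window. Two
anchors of one species sit in a *duplicated block* when >=4 flank genes of
one have their best non-self match (e-value < 1e-10) inside the other's
window (2-3 such genes: the weaker *flexible set*). Across species, a
*syntenic block* needs >=3 homolog pairs (e-value < 1e-20) within 100 kb
of each anchor. Connected components of all blocks form orthologous
groups of segments.

All rules are strand-agnostic; distances in the 100 kb rules are measured
between gene start coordinates; every output is deterministically sorted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .genome_model import GeneModel
from .homology import HitIndex, best_nonself_match

TANDEM_SPACER_TIERS = (0, 1, 5, 10)


class GeneCatalog:
    """Rank/position lookups over one or more species' gene models."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.by_id: dict[str, GeneModel] = {}
        self._chrom: dict[tuple[str, str], list[GeneModel]] = {}
        for g in genes:
            if g.gene_id in self.by_id:
                raise ValueError(f"duplicate gene_id {g.gene_id!r} in catalog")
            self.by_id[g.gene_id] = g
            if g.placed:
                self._chrom.setdefault((g.species, g.chromosome), []).append(g)
        for lst in self._chrom.values():
            lst.sort(key=lambda g: g.rank)

    def chromosome_genes(self, species: str, chromosome: str) -> list[GeneModel]:
        return self._chrom.get((species, chromosome), [])

    def neighbors_by_rank(self, gene: GeneModel, k: int) -> tuple[list[str], list[str]]:
        """Up to k gene ids on each side by rank, nearest first; truncated
        (never wrapped) at chromosome ends."""
        row = self.chromosome_genes(gene.species, gene.chromosome)
        r = gene.rank
        upstream = [row[i].gene_id for i in range(r - 1, max(r - k - 1, -1), -1)]
        downstream = [row[i].gene_id for i in range(r + 1, min(r + k + 1, len(row)))]
        return upstream, downstream

    def genes_within_bp(self, gene: GeneModel, window_bp: int) -> list[str]:
        """Ids of placed genes (anchor included) whose start lies within
        window_bp of the anchor's start on the same chromosome."""
        row = self.chromosome_genes(gene.species, gene.chromosome)
        return [
            g.gene_id for g in row if abs(g.start - gene.start) <= window_bp
        ]

    def species_of(self, gene_id: str) -> str:
        return self.by_id[gene_id].species


@dataclass
class FlankWindow:
    anchor: str
    upstream: list[str]
    downstream: list[str]

    @property
    def genes(self) -> list[str]:
        return self.upstream + self.downstream


@dataclass
class TandemCluster:
    """>=2 family genes chained on one chromosome, each consecutive pair
    within 100 kb and separated by <=10 non-family spacer genes."""

    genes: list[str]
    spacer_tier: int
    max_span_ok: bool


@dataclass
class DuplicatedBlock:
    species: str
    anchor_a: str
    anchor_b: str
    matched_pairs: list[tuple[str, str]]
    support: int
    status: str  # duplicated | flexible | unsupported
    non_reciprocal: bool = False
    mean_ks: float | None = None
    sd_ks: float | None = None
    date_mya: float | None = None
    event: str | None = None  # recent | ancient | intermediate


@dataclass
class SyntenicBlock:
    species_a: str
    species_b: str
    anchor_a: str
    anchor_b: str
    homolog_pairs: list[tuple[str, str]]
    quality: float


@dataclass
class OrthologGroup:
    group_id: str
    segments: list[tuple[str, str]]  # (species, anchor gene_id)
    member_genes: list[str]

    @property
    def species(self) -> set[str]:
        return {s for s, _ in self.segments}


def flank_window(
    genes: Iterable[GeneModel] | GeneCatalog, anchor: str, k: int = 15
) -> FlankWindow:
    """The anchor's k-gene flank window on each side (rank order)."""
    catalog = genes if isinstance(genes, GeneCatalog) else GeneCatalog(genes)
    gene = catalog.by_id[anchor]
    if not gene.placed:
        raise ValueError(f"anchor not on chromosome: {anchor}")
    up, down = catalog.neighbors_by_rank(gene, k)
    return FlankWindow(anchor=anchor, upstream=up, downstream=down)


def _status_for(support: int, min_duplicated: int, flexible_range: tuple[int, int]) -> str:
    if support >= min_duplicated:
        return "duplicated"
    if flexible_range[0] <= support <= flexible_range[1]:
        return "flexible"
    return "unsupported"


def detect_duplicated_block(
    anchor_a: str,
    anchor_b: str,
    window_a: FlankWindow,
    window_b: FlankWindow,
    index: HitIndex,
    species: str = "",
    max_evalue: float = 1e-10,
    min_duplicated: int = 4,
    flexible_range: tuple[int, int] = (2, 3),
) -> DuplicatedBlock:
    """Count flank genes of ``a`` whose best non-self match sits in ``b``'s
    window; one-to-one pairing is enforced greedily in ascending-evalue
    order, and the anchor pair itself never contributes support."""
    if anchor_a == anchor_b:
        raise ValueError("anchor pair must be two distinct genes")
    window_b_set = set(window_b.genes)
    candidates: list[tuple[float, str, str]] = []
    for flank in window_a.genes:
        if flank in (anchor_a, anchor_b):
            continue
        match = best_nonself_match(flank, index, max_evalue=max_evalue)
        if match is None or match not in window_b_set or match in (anchor_a, anchor_b):
            continue
        evalue = next(
            h.evalue for h in index.query_hits(flank) if h.subject == match
        )
        candidates.append((evalue, flank, match))
    candidates.sort()
    used_a: set[str] = set()
    used_b: set[str] = set()
    pairs: list[tuple[str, str]] = []
    for _ev, flank, match in candidates:
        if flank in used_a or match in used_b:
            continue
        used_a.add(flank)
        used_b.add(match)
        pairs.append((flank, match))
    pairs.sort()
    support = len(pairs)
    return DuplicatedBlock(
        species=species,
        anchor_a=anchor_a,
        anchor_b=anchor_b,
        matched_pairs=pairs,
        support=support,
        status=_status_for(support, min_duplicated, flexible_range),
    )


def classify_tandem(
    family: Sequence[str],
    genes: Iterable[GeneModel] | GeneCatalog,
    index: HitIndex | None = None,
    max_distance_bp: int = 100_000,
    max_spacers: int = 10,
) -> list[TandemCluster]:
    """Maximal same-chromosome chains of family genes where each
    consecutive pair lies within 100 kb (start-to-start) and is separated
    by at most ``max_spacers`` non-family spacer genes.

    ``spacer_tier`` is the smallest of the tiers (0, <=1, <=5, <=10)
    covering the chain's largest spacer count. ``index`` is accepted for
    interface parity but unused: spacer genes are "nonhomologous" in the
    sense of not belonging to the screened family.
    """
    catalog = genes if isinstance(genes, GeneCatalog) else GeneCatalog(genes)
    family_set = set(family)
    clusters: list[TandemCluster] = []
    by_chrom: dict[tuple[str, str], list[GeneModel]] = {}
    for gid in sorted(family_set):
        g = catalog.by_id.get(gid)
        if g is None or not g.placed:
            continue
        by_chrom.setdefault((g.species, g.chromosome), []).append(g)
    for key in sorted(by_chrom):
        members = sorted(by_chrom[key], key=lambda g: g.rank)
        chain: list[GeneModel] = []
        max_spacer_seen = 0

        def flush() -> None:
            nonlocal chain, max_spacer_seen
            if len(chain) >= 2:
                tier = next(t for t in TANDEM_SPACER_TIERS if max_spacer_seen <= t)
                span_ok = all(
                    abs(x.start - y.start) <= max_distance_bp
                    for i, x in enumerate(chain)
                    for y in chain[i + 1 :]
                )
                clusters.append(
                    TandemCluster(
                        genes=[g.gene_id for g in chain],
                        spacer_tier=tier,
                        max_span_ok=span_ok,
                    )
                )
            chain = []
            max_spacer_seen = 0

        for g in members:
            if not chain:
                chain = [g]
                continue
            prev = chain[-1]
            spacers = g.rank - prev.rank - 1
            if abs(g.start - prev.start) <= max_distance_bp and spacers <= max_spacers:
                chain.append(g)
                max_spacer_seen = max(max_spacer_seen, spacers)
            else:
                flush()
                chain = [g]
        flush()
    return clusters


def tandem_comember_pairs(clusters: Iterable[TandemCluster]) -> set[frozenset[str]]:
    pairs: set[frozenset[str]] = set()
    for c in clusters:
        for i, a in enumerate(c.genes):
            for b in c.genes[i + 1 :]:
                pairs.add(frozenset((a, b)))
    return pairs


def scan_intraspecies(
    family: Sequence[str],
    genes: Iterable[GeneModel] | GeneCatalog,
    index: HitIndex,
    flank_k: int = 15,
    max_evalue: float = 1e-10,
    min_duplicated: int = 4,
    flexible_range: tuple[int, int] = (2, 3),
    tandem_clusters: Sequence[TandemCluster] | None = None,
) -> list[DuplicatedBlock]:
    """Evaluate every unordered pair of placed family anchors (excluding
    tandem co-members) and return blocks with support >= 2, ordered by
    (anchor_a, anchor_b). Support asymmetric under direction reversal is
    flagged ``non_reciprocal`` (the forward, sorted-anchor direction is
    reported)."""
    catalog = genes if isinstance(genes, GeneCatalog) else GeneCatalog(genes)
    anchors = [
        gid
        for gid in sorted(set(family))
        if gid in catalog.by_id and catalog.by_id[gid].placed
    ]
    if tandem_clusters is None:
        tandem_clusters = classify_tandem(family, catalog)
    tandem_pairs = tandem_comember_pairs(tandem_clusters)
    windows = {gid: flank_window(catalog, gid, k=flank_k) for gid in anchors}
    blocks: list[DuplicatedBlock] = []
    for i, a in enumerate(anchors):
        for b in anchors[i + 1 :]:
            if catalog.species_of(a) != catalog.species_of(b):
                continue
            if frozenset((a, b)) in tandem_pairs:
                continue
            fwd = detect_duplicated_block(
                a, b, windows[a], windows[b], index,
                species=catalog.species_of(a), max_evalue=max_evalue,
                min_duplicated=min_duplicated, flexible_range=flexible_range,
            )
            if fwd.status == "unsupported":
                continue
            rev = detect_duplicated_block(
                b, a, windows[b], windows[a], index,
                species=catalog.species_of(a), max_evalue=max_evalue,
                min_duplicated=min_duplicated, flexible_range=flexible_range,
            )
            fwd.non_reciprocal = rev.support != fwd.support
            blocks.append(fwd)
    return blocks


def synteny_quality(
    segment_a: Sequence[str], segment_b: Sequence[str], matches: int
) -> float:
    """Twice the number of matches divided by the total genes in both
    segments; discounts amplification, rewards conserved content."""
    total = len(segment_a) + len(segment_b)
    if total == 0:
        raise ValueError("both segments empty")
    if matches > min(len(segment_a), len(segment_b)):
        raise ValueError("matches exceed the smaller segment")
    return 2.0 * matches / total


def detect_interspecies_block(
    anchor_a: str,
    species_b_family: Sequence[str],
    genes: Iterable[GeneModel] | GeneCatalog,
    index: HitIndex,
    max_evalue: float = 1e-20,
    window_bp: int = 100_000,
    min_pairs: int = 3,
    flank_k: int = 15,
) -> list[SyntenicBlock]:
    """Syntenic blocks between ``anchor_a``'s region and each candidate
    partner anchor of the other species: one-to-one homolog pairs
    (e-value < 1e-20), each gene within 100 kb of its anchor, >=3 pairs.

    Quality uses segments restricted to the anchor's 15-gene rank window
    intersected with the 100 kb region.
    """
    catalog = genes if isinstance(genes, GeneCatalog) else GeneCatalog(genes)
    gene_a = catalog.by_id[anchor_a]
    if not gene_a.placed:
        raise ValueError(f"anchor not on chromosome: {anchor_a}")
    region_a = catalog.genes_within_bp(gene_a, window_bp)
    region_a_set = set(region_a)
    blocks: list[SyntenicBlock] = []
    for anchor_b in sorted(set(species_b_family)):
        gene_b = catalog.by_id.get(anchor_b)
        if gene_b is None or not gene_b.placed:
            continue
        if gene_b.species == gene_a.species:
            continue
        region_b_set = set(catalog.genes_within_bp(gene_b, window_bp))
        candidates: list[tuple[float, str, str]] = []
        for g in sorted(region_a_set):
            for hit in index.query_hits(g):
                if hit.evalue >= max_evalue:
                    break  # sorted ascending; nothing further qualifies
                if hit.subject in region_b_set:
                    candidates.append((hit.evalue, g, hit.subject))
        candidates.sort()
        used_a: set[str] = set()
        used_b: set[str] = set()
        pairs: list[tuple[str, str]] = []
        for _ev, g, h in candidates:
            if g in used_a or h in used_b:
                continue
            used_a.add(g)
            used_b.add(h)
            pairs.append((g, h))
        if len(pairs) < min_pairs:
            continue
        pairs.sort()
        win_a = set(flank_window(catalog, anchor_a, k=flank_k).genes) | {anchor_a}
        win_b = set(flank_window(catalog, anchor_b, k=flank_k).genes) | {anchor_b}
        seg_a = sorted(region_a_set & win_a)
        seg_b = sorted(region_b_set & win_b)
        matched = sum(1 for g, h in pairs if g in set(seg_a) and h in set(seg_b))
        quality = synteny_quality(seg_a, seg_b, matched)
        blocks.append(
            SyntenicBlock(
                species_a=gene_a.species,
                species_b=gene_b.species,
                anchor_a=anchor_a,
                anchor_b=anchor_b,
                homolog_pairs=pairs,
                quality=quality,
            )
        )
    blocks.sort(key=lambda b: (b.species_b, b.anchor_b))
    return blocks


def assemble_ortholog_groups(
    blocks: Sequence[SyntenicBlock],
    intra: Sequence[DuplicatedBlock] = (),
    include_flexible: bool = True,
    min_species: int = 2,
) -> list[OrthologGroup]:
    """Connected components over (species, anchor) segments, edges being
    interspecies syntenic blocks plus intraspecies duplicated (and, by
    default, flexible) blocks; components spanning >= min_species species
    are reported with stable ids ordered by smallest member."""
    graph = nx.Graph()
    for b in blocks:
        graph.add_edge((b.species_a, b.anchor_a), (b.species_b, b.anchor_b))
    for d in intra:
        if d.status == "duplicated" or (include_flexible and d.status == "flexible"):
            graph.add_edge((d.species, d.anchor_a), (d.species, d.anchor_b))
    components = [sorted(c) for c in nx.connected_components(graph)]
    components = [c for c in components if len({s for s, _ in c}) >= min_species]
    components.sort(key=lambda c: c[0])
    return [
        OrthologGroup(
            group_id=f"OG{i + 1:02d}",
            segments=comp,
            member_genes=sorted(a for _s, a in comp),
        )
        for i, comp in enumerate(components)
    ]
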