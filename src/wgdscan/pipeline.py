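"""End-to-end orchestration: screen -> homology -> tandem -> intraspecies
blocks -> rates/dating -> interspecies blocks -> orthologous groups ->
loss report, with deterministic TSV/JSON artifacts.

Defaults equal the method's published constants (15-gene flanks, 1e-10 /
1e-20 e-value cutoffs, >=4 / 2-3 support classes, 100 kb windows,
150 bp / 9 bp sliding windows, lambda = 6.1e-9); every threshold is
overridable through :class:`PipelineConfig`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import evolrates, homology, loss_inference, synteny
from .genome_model import (
    DomainHit,
    GeneModel,
    SequenceRecord,
    read_annotation,
    read_domain_table,
    read_sequences,
    screen_family,
)

logger = logging.getLogger(__name__)


@dataclass
class SpeciesInput:
    species: str
    annotation: str
    cds: str
    protein: str | None = None
    domains: str | None = None


@dataclass
class PipelineConfig:
    inputs: list[SpeciesInput] = field(default_factory=list)
    hits: str | None = None  # external outfmt-6 file; overrides the built-in aligner
    out_dir: str = "wgdscan_out"
    seed: int = 0
    flank_k: int = 15
    intra_evalue: float = 1e-10
    intra_min_pairs: int = 4
    flexible_range: tuple[int, int] = (2, 3)
    inter_evalue: float = 1e-20
    inter_window_bp: int = 100_000
    inter_min_pairs: int = 3
    tandem_window_bp: int = 100_000
    window_nt: int = 150
    step_nt: int = 9
    lambda_rate: float = 6.1e-9
    recent_ks_max: float = 0.25
    ancient_ks_range: tuple[float, float] = (0.45, 1.0)
    include_flexible_edges: bool = True

    @classmethod
    def from_dict(cls, data: Mapping) -> "PipelineConfig":
        data = dict(data)
        inputs = [SpeciesInput(**i) for i in data.pop("inputs", [])]
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("flexible_range", "ancient_ks_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(inputs=inputs, **data)


@dataclass
class PipelineResult:
    family: dict[str, list[str]]  # species -> screened family gene ids
    tandem: list[synteny.TandemCluster]
    blocks: list[synteny.DuplicatedBlock]
    flank_rates: list[evolrates.RateEstimate]
    anchor_rates: list[evolrates.RateEstimate]
    syntenic_blocks: list[synteny.SyntenicBlock]
    ortholog_groups: list[synteny.OrthologGroup]
    loss_reports: list[loss_inference.LossReport]
    stage_counts: dict[str, int]

    def ks_values(self) -> list[float]:
        return [
            r.Ks for r in self.flank_rates if not r.saturated and not math.isnan(r.Ks)
        ]


def _rate_for_pair(
    a: SequenceRecord, b: SequenceRecord
) -> evolrates.RateEstimate | None:
    try:
        return evolrates.ng86(evolrates.codon_align(a, b))
    except ValueError:
        logger.warning("rate estimation failed for %s / %s", a.gene_id, b.gene_id)
        return None


def date_and_assign(
    blocks: Sequence[synteny.DuplicatedBlock],
    records: Mapping[str, SequenceRecord],
    cfg: PipelineConfig,
) -> tuple[list[evolrates.RateEstimate], list[evolrates.RateEstimate]]:
    """Fill mean_ks/date/event on duplicated blocks from the NG86 Ks of
    their conserved flanking pairs (flexible blocks are left undated, and
    the anchor pair never enters the dating)."""
    flank_rates: list[evolrates.RateEstimate] = []
    anchor_rates: list[evolrates.RateEstimate] = []
    cache: dict[tuple[str, str], evolrates.RateEstimate | None] = {}

    def rate(x: str, y: str) -> evolrates.RateEstimate | None:
        key = (x, y) if x <= y else (y, x)
        if key not in cache:
            if x in records and y in records:
                cache[key] = _rate_for_pair(records[key[0]], records[key[1]])
            else:
                cache[key] = None
        return cache[key]

    for block in blocks:
        r = rate(block.anchor_a, block.anchor_b)
        if r is not None:
            anchor_rates.append(r)
        if block.status != "duplicated":
            continue
        estimates = [
            r for f, m in block.matched_pairs if (r := rate(f, m)) is not None
        ]
        flank_rates.extend(estimates)
        try:
            date = evolrates.date_block(estimates, lambda_rate=cfg.lambda_rate)
        except ValueError:
            logger.warning(
                "undatable block %s/%s", block.anchor_a, block.anchor_b
            )
            continue
        block.mean_ks = date.mean_ks
        block.sd_ks = date.sd_ks
        block.date_mya = date.T_mya
        block.event = evolrates.assign_wgd_event(
            date.mean_ks, cfg.recent_ks_max, cfg.ancient_ks_range
        )
    return flank_rates, anchor_rates


def tandem_representatives(
    family: Sequence[str], clusters: Sequence[synteny.TandemCluster]
) -> list[str]:
    """Collapse each tandem cluster to its first member: tandem copies
    share their sibling's flanks, so scanning them as separate anchors
    would duplicate every block of the cluster."""
    drop = {g for c in clusters for g in c.genes[1:]}
    return [g for g in family if g not in drop]


def analyze(
    genes: Sequence[GeneModel],
    records: Mapping[str, SequenceRecord],
    domains: Sequence[DomainHit],
    cfg: PipelineConfig | None = None,
    index: homology.HitIndex | None = None,
) -> PipelineResult:
    """Run the full analysis on in-memory inputs (single or multi-species)."""
    cfg = cfg or PipelineConfig()
    catalog = synteny.GeneCatalog(genes)
    family_ids = screen_family(genes, domains)
    by_species: dict[str, list[str]] = {}
    for gid in family_ids:
        by_species.setdefault(catalog.species_of(gid), []).append(gid)
    if index is None:
        index = homology.build_index(records)

    species_of = {g.gene_id: g.species for g in genes}
    tandem: list[synteny.TandemCluster] = []
    blocks: list[synteny.DuplicatedBlock] = []
    multi_species = len(by_species) > 1
    for species in sorted(by_species):
        fam = by_species[species]
        clusters = synteny.classify_tandem(
            fam, catalog, max_distance_bp=cfg.tandem_window_bp
        )
        tandem.extend(clusters)
        anchors = tandem_representatives(fam, clusters)
        # intraspecies microsynteny is a within-genome comparison
        sp_index = (
            homology.restrict_to_species(index, species_of, species)
            if multi_species
            else index
        )
        blocks.extend(
            synteny.scan_intraspecies(
                anchors,
                catalog,
                sp_index,
                flank_k=cfg.flank_k,
                max_evalue=cfg.intra_evalue,
                min_duplicated=cfg.intra_min_pairs,
                flexible_range=cfg.flexible_range,
                tandem_clusters=clusters,
            )
        )
    flank_rates, anchor_rates = date_and_assign(blocks, records, cfg)

    syntenic: list[synteny.SyntenicBlock] = []
    species_list = sorted(by_species)
    for i, sa in enumerate(species_list):
        for sb in species_list[i + 1 :]:
            for anchor in tandem_representatives(
                by_species[sa], [t for t in tandem if t.genes[0] in set(by_species[sa])]
            ):
                syntenic.extend(
                    synteny.detect_interspecies_block(
                        anchor,
                        tandem_representatives(
                            by_species[sb],
                            [t for t in tandem if t.genes[0] in set(by_species[sb])],
                        ),
                        catalog,
                        index,
                        max_evalue=cfg.inter_evalue,
                        window_bp=cfg.inter_window_bp,
                        min_pairs=cfg.inter_min_pairs,
                        flank_k=cfg.flank_k,
                    )
                )
    groups = synteny.assemble_ortholog_groups(
        syntenic, blocks, include_flexible=cfg.include_flexible_edges
    )

    loss_reports: list[loss_inference.LossReport] = []
    for species in species_list:
        sp_blocks = [b for b in blocks if b.species == species]
        has_recent = any(b.event == "recent" for b in sp_blocks)
        try:
            if has_recent:
                sp_groups = loss_inference.build_groups(
                    loss_inference.pair_records_from_blocks(sp_blocks),
                    include_flexible=cfg.include_flexible_edges,
                )
                loss_reports.append(
                    loss_inference.count_two_round_losses(sp_groups, lineage=species)
                )
            elif groups:
                census = loss_inference.census_from_groups(groups, species)
                loss_reports.append(loss_inference.count_one_round_losses(census))
        except ValueError as exc:
            logger.warning("loss accounting skipped for %s: %s", species, exc)

    counts = {
        "genes": len(genes),
        "sequences": len(records),
        "family": len(family_ids),
        "tandem_clusters": len(tandem),
        "duplicated_blocks": sum(1 for b in blocks if b.status == "duplicated"),
        "flexible_blocks": sum(1 for b in blocks if b.status == "flexible"),
        "dated_blocks": sum(1 for b in blocks if b.event is not None),
        "syntenic_blocks": len(syntenic),
        "ortholog_groups": len(groups),
    }
    return PipelineResult(
        family=by_species,
        tandem=tandem,
        blocks=blocks,
        flank_rates=flank_rates,
        anchor_rates=anchor_rates,
        syntenic_blocks=syntenic,
        ortholog_groups=groups,
        loss_reports=loss_reports,
        stage_counts=counts,
    )


# ---------------------------------------------------------------------------
# Artifact writing and the file-level entry point
# ---------------------------------------------------------------------------


def _fmt(x: float | None, nd: int = 4) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    return f"{x:.{nd}f}"


def write_artifacts(result: PipelineResult, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    p = out / "blocks.tsv"
    with open(p, "w") as fh:
        fh.write(
            "species\tanchor_a\tanchor_b\tsupport\tstatus\tnon_reciprocal\t"
            "mean_ks\tsd_ks\tdate_mya\tevent\n"
        )
        for b in result.blocks:
            fh.write(
                f"{b.species}\t{b.anchor_a}\t{b.anchor_b}\t{b.support}\t{b.status}\t"
                f"{int(b.non_reciprocal)}\t{_fmt(b.mean_ks)}\t{_fmt(b.sd_ks)}\t"
                f"{_fmt(b.date_mya, 2)}\t{b.event or 'NA'}\n"
            )
    paths["blocks"] = p

    p = out / "tandem.tsv"
    with open(p, "w") as fh:
        fh.write("genes\tspacer_tier\tmax_span_ok\n")
        for t in result.tandem:
            fh.write(f"{','.join(t.genes)}\t{t.spacer_tier}\t{int(t.max_span_ok)}\n")
    paths["tandem"] = p

    p = out / "rates.tsv"
    with open(p, "w") as fh:
        fh.write("gene_a\tgene_b\tKa\tKs\tomega\tsaturated\n")
        for r in sorted(
            result.anchor_rates + result.flank_rates, key=lambda r: (r.gene_a, r.gene_b)
        ):
            fh.write(
                f"{r.gene_a}\t{r.gene_b}\t{_fmt(r.Ka)}\t{_fmt(r.Ks)}\t"
                f"{_fmt(r.omega)}\t{int(r.saturated)}\n"
            )
    paths["rates"] = p

    p = out / "groups.tsv"
    with open(p, "w") as fh:
        fh.write("group_id\tspecies\tanchor\n")
        for g in result.ortholog_groups:
            for sp, anchor in g.segments:
                fh.write(f"{g.group_id}\t{sp}\t{anchor}\n")
    paths["groups"] = p

    p = out / "ks_histogram.tsv"
    with open(p, "w") as fh:
        fh.write("ks_bin\tn_pairs\n")
        for edge, n in evolrates.ks_histogram(result.ks_values()):
            fh.write(f"{edge}\t{n}\n")
    paths["ks_histogram"] = p

    p = out / "loss_report.tsv"
    with open(p, "w") as fh:
        fields = list(loss_inference.LossReport.__dataclass_fields__)
        fh.write("\t".join(fields) + "\n")
        for r in result.loss_reports:
            fh.write(
                "\t".join(
                    "NA" if getattr(r, f) is None else str(getattr(r, f))
                    for f in fields
                )
                + "\n"
            )
    paths["loss_tsv"] = p

    p = out / "loss_report.json"
    with open(p, "w") as fh:
        json.dump([r.to_dict() for r in result.loss_reports], fh, indent=1)
    paths["loss_json"] = p

    p = out / "summary.json"
    with open(p, "w") as fh:
        json.dump(result.stage_counts, fh, indent=1)
    paths["summary"] = p
    return paths


def run(cfg: PipelineConfig) -> PipelineResult:
    """File-level pipeline: read inputs, analyze, write artifacts + run log."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("wgdscan")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    stage = "config"
    try:
        genes: list[GeneModel] = []
        records: dict[str, SequenceRecord] = {}
        domains: list[DomainHit] = []
        for inp in cfg.inputs:
            stage = "annotation"
            genes.extend(read_annotation(inp.annotation, inp.species))
            stage = "sequences"
            records.update(read_sequences(inp.cds, inp.protein))
            stage = "domains"
            if inp.domains:
                domains.extend(read_domain_table(inp.domains))
        stage = "hits"
        index = homology.read_hits(cfg.hits) if cfg.hits else None
        stage = "analysis"
        result = analyze(genes, records, domains, cfg, index=index)
        stage = "artifacts"
        write_artifacts(result, out)
        logger.info("pipeline complete: %s", result.stage_counts)
        return result
    except Exception as exc:
        logger.exception("pipeline failed at stage %r", stage)
        raise PipelineError(stage) from exc
    finally:
        root.removeHandler(handler)
        handler.close()


class PipelineError(RuntimeError):
    def __init__(self, stage: str):
        super().__init__(f"pipeline failed at stage {stage!r}")
        self.stage = stage
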