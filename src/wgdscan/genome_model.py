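"""Domain types and I/O for annotated genomes, coding sequences and domain tables.

Coordinates are GFF3-style throughout: 1-based, inclusive on both ends.
Gene order on a chromosome is expressed as a 0-based ``rank`` assigned by
ascending start coordinate (ties broken by gene id), which is what all
microsynteny logic operates on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

#: chromosome-name prefixes treated as unanchored scaffolds (case-insensitive)
UNPLACED_PREFIXES = ("scaffold", "contig", "chrun", "un", ".")

#: domain labels recognised in domain tables
DOMAIN_LABELS = frozenset({"DBD", "HR-A/B", "NLS", "NES", "AHA"})


class AnnotationError(ValueError):
    """Raised for malformed annotation input; message names the offending line."""


@dataclass
class GeneModel:
    """One protein-coding gene placed (or not) on a chromosome.

    ``rank`` is the ordinal position among genes of the same species and
    chromosome, 0-based and consistent with sorting by (start, gene_id).
    Genes on unanchored scaffolds carry ``placed=False`` and are excluded
    from all synteny operations but still count toward family size.
    """

    gene_id: str
    species: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"
    rank: int = -1
    family_member: bool = False
    placed: bool = True

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise AnnotationError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )


@dataclass
class SequenceRecord:
    """A gene's CDS and its conceptual translation (terminal stop stripped)."""

    gene_id: str
    cds: str
    protein: str


@dataclass
class DomainHit:
    """A precomputed protein-domain annotation (amino-acid coordinates)."""

    gene_id: str
    domain_label: str
    start_aa: int
    end_aa: int
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.start_aa > self.end_aa:
            raise ValueError(
                f"domain hit {self.gene_id}/{self.domain_label}: "
                f"start {self.start_aa} > end {self.end_aa}"
            )


def _is_placed(chromosome: str) -> bool:
    low = chromosome.lower()
    return not any(low.startswith(p) for p in UNPLACED_PREFIXES)


def assign_ranks(genes: Iterable[GeneModel]) -> list[GeneModel]:
    """Assign per-chromosome ranks in place; returns the genes in rank order.

    Ranks are a contiguous 0..n-1 permutation per (species, chromosome),
    ordered by (start, gene_id).
    """
    ordered = sorted(genes, key=lambda g: (g.species, g.chromosome, g.start, g.gene_id))
    prev_key = None
    rank = 0
    for g in ordered:
        key = (g.species, g.chromosome)
        if key != prev_key:
            rank = 0
            prev_key = key
        g.rank = rank
        rank += 1
    return ordered


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            key, _, val = part.partition("=")
            out[key.strip()] = val.strip()
    return out


def read_annotation(path: str | Path, species: str) -> list[GeneModel]:
    """Read gene models from GFF3 (``gene`` features) or a 6-column BED-like table.

    The format is sniffed from the extension (``.bed`` / ``.tsv`` means
    BED-like, 0-based starts; anything else is treated as GFF3). Ranks are
    assigned per chromosome by ascending start with a deterministic
    (start, gene_id) tie-break.
    """
    path = Path(path)
    bedlike = path.suffix.lower() in {".bed", ".tsv"}
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if bedlike:
                    if len(fields) < 6:
                        raise AnnotationError(
                            f"{path}:{lineno}: expected 6 BED-like columns, "
                            f"got {len(fields)}"
                        )
                    chrom, start_s, end_s, gene_id, _score, strand = fields[:6]
                    start = int(start_s) + 1  # BED is 0-based half-open
                    end = int(end_s)
                else:
                    if len(fields) != 9:
                        raise AnnotationError(
                            f"{path}:{lineno}: expected 9 GFF3 columns, "
                            f"got {len(fields)}"
                        )
                    chrom, _src, ftype, start_s, end_s, _score, strand, _frame, attrs = fields
                    if ftype != "gene":
                        continue
                    start = int(start_s)
                    end = int(end_s)
                    gene_id = _parse_gff3_attributes(attrs).get("ID", "")
                    if not gene_id:
                        raise AnnotationError(
                            f"{path}:{lineno}: gene feature without ID attribute"
                        )
            except ValueError as exc:
                if isinstance(exc, AnnotationError):
                    raise
                raise AnnotationError(f"{path}:{lineno}: malformed coordinates") from exc
            if gene_id in seen:
                raise AnnotationError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    species=species,
                    chromosome=chrom,
                    start=start,
                    end=end,
                    strand=strand if strand in {"+", "-"} else "+",
                    placed=_is_placed(chrom),
                )
            )
    return assign_ranks(genes)


def translate_cds(cds: str) -> str:
    """Translate a CDS with the standard code, stripping one terminal stop."""
    protein = str(Seq(cds).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    return protein


def _validate_cds(gene_id: str, cds: str) -> str | None:
    """Return the translation if the CDS is usable, else None (logged)."""
    cds = cds.upper()
    if len(cds) % 3 != 0:
        logger.warning("rejecting %s: CDS length %d not divisible by 3", gene_id, len(cds))
        return None
    if any(base not in "ACGTN" for base in cds):
        logger.warning("rejecting %s: CDS contains non-nucleotide characters", gene_id)
        return None
    protein = translate_cds(cds)
    if "*" in protein:
        logger.warning("rejecting %s: internal stop codon", gene_id)
        return None
    return protein


def read_sequences(
    cds_path: str | Path, protein_path: str | Path | None = None
) -> dict[str, SequenceRecord]:
    """Read CDS FASTA (plus optional protein FASTA) into validated records.

    Records failing the CDS invariants (length divisible by 3, no internal
    stop) are dropped with a logged warning; a supplied protein that
    disagrees with the translation likewise drops the record. When one
    gene id occurs several times the longest CDS is kept, one
    representative per gene.
    """
    proteins: dict[str, str] = {}
    if protein_path is not None:
        proteins = {
            rec.id: str(rec.seq).upper().rstrip("*")
            for rec in SeqIO.parse(str(protein_path), "fasta")
        }
    records: dict[str, SequenceRecord] = {}
    for rec in SeqIO.parse(str(cds_path), "fasta"):
        cds = str(rec.seq).upper()
        existing = records.get(rec.id)
        if existing is not None and len(existing.cds) >= len(cds):
            continue
        protein = _validate_cds(rec.id, cds)
        if protein is None:
            continue
        if rec.id in proteins and proteins[rec.id] != protein:
            logger.warning(
                "rejecting %s: supplied protein disagrees with CDS translation", rec.id
            )
            continue
        records[rec.id] = SequenceRecord(gene_id=rec.id, cds=cds, protein=protein)
    return records


def read_domain_table(path: str | Path) -> list[DomainHit]:
    """Read a TSV domain table (gene_id, domain_label, start_aa, end_aa, score)."""
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene_id\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise AnnotationError(f"{path}:{lineno}: expected >=4 columns")
            score = float(fields[4]) if len(fields) > 4 else 0.0
            hits.append(
                DomainHit(
                    gene_id=fields[0],
                    domain_label=fields[1],
                    start_aa=int(fields[2]),
                    end_aa=int(fields[3]),
                    score=score,
                )
            )
    return hits


def screen_family(
    genes: Sequence[GeneModel], domains: Iterable[DomainHit]
) -> list[str]:
    """Select family members: genes with >=1 DBD hit AND >=1 HR-A/B hit.

    The family here is an Hsf-style transcription-factor family defined by
    the joint presence of a DNA-binding domain and an oligomerization
    (HR-A/B) region; candidates lacking either are excluded. NLS/NES/AHA
    hits are metadata only. Sets ``family_member`` on the retained genes
    and returns their ids sorted.
    """
    by_id = {g.gene_id: g for g in genes}
    labels: dict[str, set[str]] = {}
    for hit in domains:
        if hit.gene_id not in by_id:
            logger.warning("domain hit for unknown gene %s skipped", hit.gene_id)
            continue
        labels.setdefault(hit.gene_id, set()).add(hit.domain_label)
    family = sorted(
        gid for gid, labs in labels.items() if "DBD" in labs and "HR-A/B" in labs
    )
    for gid in family:
        by_id[gid].family_member = True
    return family
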