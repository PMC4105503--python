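"""All-vs-all protein similarity: external BLAST-style hit tables or a
built-in Smith-Waterman aligner for fixture-scale data, plus
best-non-self-match queries.

The built-in aligner is a fixture-scale stand-in for a database search
tool: exact local alignment (BLOSUM62, affine gaps 11/1) with a
Karlin-Altschul-style bitscore/e-value transformation using fixed
constants. External outfmt-6 hit files take precedence in the pipeline
when both sources are available.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .genome_model import SequenceRecord

logger = logging.getLogger(__name__)

# Karlin-Altschul-style constants for the built-in aligner (ungapped-style).
LAMBDA = 0.267
K_CONST = 0.041


@dataclass(frozen=True)
class SimilarityHit:
    """A scored directed protein-vs-protein match."""

    query: str
    subject: str
    evalue: float
    bitscore: float
    identity_pct: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


def _sort_key(hit: SimilarityHit) -> tuple:
    return (hit.evalue, -hit.bitscore, hit.subject)


@dataclass
class HitIndex:
    """Directed mapping query -> hits, each list sorted by
    (ascending evalue, descending bitscore, ascending subject id)."""

    hits: dict[str, list[SimilarityHit]] = field(default_factory=dict)

    def add(self, hit: SimilarityHit) -> None:
        if hit.query == hit.subject:
            return
        self.hits.setdefault(hit.query, []).append(hit)

    def finalize(self) -> "HitIndex":
        """Collapse duplicate (query, subject) pairs keeping the best hit,
        then sort every hit list; call once after adding all hits."""
        for query, lst in self.hits.items():
            best: dict[str, SimilarityHit] = {}
            for h in lst:
                prev = best.get(h.subject)
                if prev is None or _sort_key(h) < _sort_key(prev):
                    best[h.subject] = h
            self.hits[query] = sorted(best.values(), key=_sort_key)
        return self

    def query_hits(self, gene_id: str) -> list[SimilarityHit]:
        return self.hits.get(gene_id, [])


def read_hits(path: str | Path) -> HitIndex:
    """Read a 12-column tabular alignment file (BLAST outfmt 6 order:
    query, subject, identity, length, mismatches, gapopens, qstart, qend,
    sstart, send, evalue, bitscore). Self-hits are dropped; duplicate
    pairs keep the best e-value."""
    index = HitIndex()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 columns, got {len(fields)}"
                )
            index.add(
                SimilarityHit(
                    query=fields[0],
                    subject=fields[1],
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                    identity_pct=float(fields[2]),
                )
            )
    return index.finalize()


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER: Align.PairwiseAligner | None = None


def align_pair(a: SequenceRecord, b: SequenceRecord) -> SimilarityHit:
    """Score one protein pair by exact local alignment.

    Bitscore = (lambda*S - ln K)/ln 2 with fixed constants; e-value =
    m*n*2**(-bitscore). Deterministic: identity is read off the first
    optimal alignment in Biopython's canonical order.
    """
    global _ALIGNER
    if not a.protein or not b.protein:
        raise ValueError("cannot align empty protein sequence")
    if _ALIGNER is None:
        _ALIGNER = _make_aligner()
    alignments = _ALIGNER.align(a.protein, b.protein)
    score = alignments.score
    aln = alignments[0]
    matches = 0
    length = 0
    seq_a, seq_b = str(aln[0]), str(aln[1])
    for ca, cb in zip(seq_a, seq_b):
        length += 1
        if ca == cb and ca != "-":
            matches += 1
    identity = 100.0 * matches / length if length else 0.0
    bitscore = (LAMBDA * score - math.log(K_CONST)) / math.log(2)
    evalue = len(a.protein) * len(b.protein) * 2.0 ** (-bitscore)
    return SimilarityHit(
        query=a.gene_id,
        subject=b.gene_id,
        evalue=evalue,
        bitscore=bitscore,
        identity_pct=identity,
    )


def _kmer_set(protein: str, k: int) -> set[str]:
    return {protein[i : i + k] for i in range(len(protein) - k + 1)}


def _identity_pct(a: str, b: str) -> float:
    """Approximate percent identity from a unit-cost global edit distance
    (used for bulk indexing; align_pair reports exact alignment identity)."""
    import edlib

    dist = edlib.align(a, b, task="distance")["editDistance"]
    return 100.0 * (1.0 - dist / max(len(a), len(b)))


def _score_pair(a: SequenceRecord, b: SequenceRecord) -> SimilarityHit:
    """Like align_pair but computes only the optimal score (no traceback),
    with edit-distance identity; several-fold faster for bulk indexing."""
    global _ALIGNER
    if _ALIGNER is None:
        _ALIGNER = _make_aligner()
    score = _ALIGNER.score(a.protein, b.protein)
    bitscore = (LAMBDA * score - math.log(K_CONST)) / math.log(2)
    evalue = len(a.protein) * len(b.protein) * 2.0 ** (-bitscore)
    return SimilarityHit(
        query=a.gene_id,
        subject=b.gene_id,
        evalue=evalue,
        bitscore=bitscore,
        identity_pct=_identity_pct(a.protein, b.protein),
    )


def build_index(
    records: Mapping[str, SequenceRecord] | Sequence[SequenceRecord],
    max_evalue: float = 10.0,
    seed_k: int = 5,
    min_shared_kmers: int = 2,
) -> HitIndex:
    """All-vs-all similarity over a set of records.

    Pairs sharing fewer than ``min_shared_kmers`` exact ``seed_k``-mers are
    skipped without alignment — a pure speed filter: unrelated random
    proteins essentially never share two 5-mers, while homologs above
    ~50% identity share many. Proteins shorter than 5*seed_k are always
    aligned. Each aligned pair is stored in both directions.
    """
    if isinstance(records, Mapping):
        recs = sorted(records.values(), key=lambda r: r.gene_id)
    else:
        recs = sorted(records, key=lambda r: r.gene_id)
    index = HitIndex()
    kmer_to_genes: dict[str, list[int]] = {}
    for i, rec in enumerate(recs):
        for kmer in _kmer_set(rec.protein, seed_k):
            kmer_to_genes.setdefault(kmer, []).append(i)
    shared: dict[tuple[int, int], int] = {}
    for members in kmer_to_genes.values():
        if len(members) < 2:
            continue
        for ai in range(len(members)):
            for bi in range(ai + 1, len(members)):
                pair = (members[ai], members[bi])
                shared[pair] = shared.get(pair, 0) + 1
    short_cut = 5 * seed_k
    candidates = {p for p, n in shared.items() if n >= min_shared_kmers}
    shorts = [i for i, r in enumerate(recs) if len(r.protein) < short_cut]
    for i in shorts:
        for j in range(len(recs)):
            if i != j:
                candidates.add((min(i, j), max(i, j)))
    for i, j in sorted(candidates):
        hit = _score_pair(recs[i], recs[j])
        if hit.evalue > max_evalue:
            continue
        index.add(hit)
        index.add(
            SimilarityHit(
                query=hit.subject,
                subject=hit.query,
                evalue=hit.evalue,
                bitscore=hit.bitscore,
                identity_pct=hit.identity_pct,
            )
        )
    return index.finalize()


def restrict_to_species(
    index: HitIndex, species_of: Mapping[str, str] | None = None, species: str | None = None
) -> HitIndex:
    """A filtered view keeping only hits whose query AND subject belong to
    ``species`` — the within-genome search an intraspecies scan needs
    (otherwise closer cross-species orthologs shadow ancient paralogs as
    best non-self matches)."""
    out = HitIndex()
    for query, hits in index.hits.items():
        if species_of is not None and species_of.get(query) != species:
            continue
        kept = [
            h
            for h in hits
            if species_of is None or species_of.get(h.subject) == species
        ]
        if kept:
            out.hits[query] = kept  # already sorted; order preserved by filter
    return out


def best_nonself_match(
    gene_id: str, index: HitIndex, max_evalue: float = 1e-10
) -> str | None:
    """The top-ranked non-self subject with evalue < max_evalue, else None."""
    hits = index.query_hits(gene_id)
    if not hits:
        logger.debug("no hits recorded for %s", gene_id)
        return None
    for hit in hits:
        if hit.subject != gene_id:
            return hit.subject if hit.evalue < max_evalue else None
    return None
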