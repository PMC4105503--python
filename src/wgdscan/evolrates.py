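"""Protein-guided codon alignment, Nei-Gojobori (1986) Ka/Ks estimation,
sliding-window omega profiles, and Ks-based duplication dating.

The NG86 estimator: per codon, the synonymous site count at each position
is the fraction of viable (non-stop) single-base changes that preserve
the amino acid, so every codon contributes exactly three sites split
between synonymous and nonsynonymous; site counts are averaged over the
two sequences. Observed differences between a codon pair are averaged
with equal weight over all minimal substitution pathways that avoid stop
codons. Proportions are Jukes-Cantor corrected,
d = -(3/4)ln(1 - (4/3)p), undefined (saturated) at p >= 3/4.

Divergence times use T = Ks / (2*lambda) with the default substitution
rate lambda = 6.1e-9 synonymous substitutions per site per year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

from .genome_model import SequenceRecord

BASES = "ACGT"
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
CODON_TABLE = dict(standard_dna_table.forward_table)
DEFAULT_RATE = 6.1e-9  # substitutions / synonymous site / year
GAP_CODON = "---"


def _translate_codon(codon: str) -> str | None:
    if codon in STOP_CODONS:
        return None
    return CODON_TABLE.get(codon)


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one sense codon.

    At each position the three alternative bases are examined; changes to
    stop codons are excluded from the denominator, so the two counts
    always sum to 3.
    """
    aa = _translate_codon(codon)
    if aa is None:
        raise ValueError(f"stop codon has no site counts: {codon}")
    syn = 0.0
    for pos in range(3):
        viable = 0
        syn_here = 0
        for base in BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            alt_aa = _translate_codon(alt)
            if alt_aa is None:
                continue
            viable += 1
            if alt_aa == aa:
                syn_here += 1
        if viable:
            syn += syn_here / viable
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def codon_pair_differences(codon_a: str, codon_b: str) -> tuple[float, float, bool]:
    """(synonymous, nonsynonymous) difference counts between two sense
    codons, averaged with equal weight over all minimal substitution
    pathways that avoid stop codons.

    Returns (sd, nd, usable); usable is False when every pathway passes
    through a stop codon, in which case the codon pair is skipped.
    """
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0, True
    syn_total = 0.0
    nonsyn_total = 0.0
    n_paths = 0
    for order in permutations(diff_positions):
        current = codon_a
        syn = nonsyn = 0
        valid = True
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            aa_cur = _translate_codon(current)
            aa_nxt = _translate_codon(nxt)
            if aa_nxt is None:
                valid = False
                break
            if aa_cur == aa_nxt:
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        if valid:
            syn_total += syn
            nonsyn_total += nonsyn
            n_paths += 1
    if n_paths == 0:
        return 0.0, 0.0, False
    return syn_total / n_paths, nonsyn_total / n_paths, True


@dataclass
class CodonAlignment:
    """Aligned codon columns for one gene pair; '---' marks gaps."""

    gene_a: str
    gene_b: str
    codon_columns: list[tuple[str, str]]

    @property
    def length_nt(self) -> int:
        return 3 * len(self.codon_columns)

    @property
    def ungapped_length_nt(self) -> int:
        return 3 * sum(
            1 for a, b in self.codon_columns if GAP_CODON not in (a, b)
        )

    def back_translate(self, row: int) -> str:
        return "".join(col[row] for col in self.codon_columns).replace("-", "")


@dataclass
class RateEstimate:
    """NG86 Ka, Ks and omega for one aligned pair (nan when undefined)."""

    gene_a: str
    gene_b: str
    Ka: float
    Ks: float
    omega: float
    N_sites: float
    S_sites: float
    Nd: float
    Sd: float
    n_codons: int
    saturated: bool


@dataclass
class WindowProfile:
    gene_a: str
    gene_b: str
    window_size_nt: int
    step_nt: int
    windows: list[tuple[int, float]]  # (offset_nt, omega; nan = undefined)
    short: bool = False


@dataclass
class DuplicationDate:
    mean_ks: float
    sd_ks: float
    n_flanks: int
    lambda_rate: float
    T_mya: float


_PROT_ALIGNER: Align.PairwiseAligner | None = None


def _align_proteins(a: str, b: str) -> tuple[str, str]:
    global _PROT_ALIGNER
    if _PROT_ALIGNER is None:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11
        aligner.extend_gap_score = -1
        _PROT_ALIGNER = aligner
    aln = _PROT_ALIGNER.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def _strip_terminal_stop(cds: str) -> str:
    if len(cds) >= 3 and cds[-3:] in STOP_CODONS:
        return cds[:-3]
    return cds


def codon_align(
    a: SequenceRecord,
    b: SequenceRecord,
    protein_alignment: tuple[str, str] | None = None,
) -> CodonAlignment:
    """Thread each CDS through its protein alignment, expanding every
    aligned amino-acid column to the source codon ('---' under gaps).
    With no alignment supplied, a global BLOSUM62 alignment is computed.
    """
    if protein_alignment is None:
        protein_alignment = _align_proteins(a.protein, b.protein)
    row_a, row_b = protein_alignment
    if len(row_a) != len(row_b):
        raise ValueError("protein alignment rows differ in length")
    cds_a = _strip_terminal_stop(a.cds)
    cds_b = _strip_terminal_stop(b.cds)
    if len(cds_a) != 3 * len(row_a.replace("-", "")):
        raise ValueError(f"protein/CDS length mismatch for {a.gene_id}")
    if len(cds_b) != 3 * len(row_b.replace("-", "")):
        raise ValueError(f"protein/CDS length mismatch for {b.gene_id}")
    columns: list[tuple[str, str]] = []
    ia = ib = 0
    for ca, cb in zip(row_a, row_b):
        if ca == "-":
            codon_a = GAP_CODON
        else:
            codon_a = cds_a[3 * ia : 3 * ia + 3]
            ia += 1
        if cb == "-":
            codon_b = GAP_CODON
        else:
            codon_b = cds_b[3 * ib : 3 * ib + 3]
            ib += 1
        columns.append((codon_a, codon_b))
    return CodonAlignment(gene_a=a.gene_id, gene_b=b.gene_id, codon_columns=columns)


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction; nan at or beyond the p = 3/4 ceiling."""
    if p >= 0.75:
        return math.nan
    if p <= 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def _usable_column(codon_a: str, codon_b: str) -> bool:
    if GAP_CODON in (codon_a, codon_b):
        return False
    if any(c not in BASES for c in codon_a + codon_b):
        return False
    if codon_a in STOP_CODONS or codon_b in STOP_CODONS:
        return False
    return True


def ng86(
    aln: CodonAlignment | Sequence[tuple[str, str]],
    gene_a: str = "",
    gene_b: str = "",
) -> RateEstimate:
    """NG86 rate estimate over the alignment's usable codon columns."""
    if isinstance(aln, CodonAlignment):
        columns = aln.codon_columns
        gene_a, gene_b = aln.gene_a, aln.gene_b
    else:
        columns = list(aln)
    S = N = Sd = Nd = 0.0
    n_codons = 0
    for codon_a, codon_b in columns:
        if not _usable_column(codon_a, codon_b):
            continue
        sd, nd, usable = codon_pair_differences(codon_a, codon_b)
        if not usable:
            continue
        sa, na = codon_sites(codon_a)
        sb, nb = codon_sites(codon_b)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        Sd += sd
        Nd += nd
        n_codons += 1
    if n_codons == 0:
        raise ValueError("no usable codon columns for rate estimation")
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    Ks = jukes_cantor(pS)
    Ka = jukes_cantor(pN)
    saturated = math.isnan(Ks) or math.isnan(Ka)
    if not saturated and Ks > 0:
        omega = Ka / Ks
    else:
        omega = math.nan
    return RateEstimate(
        gene_a=gene_a,
        gene_b=gene_b,
        Ka=Ka,
        Ks=Ks,
        omega=omega,
        N_sites=N,
        S_sites=S,
        Nd=Nd,
        Sd=Sd,
        n_codons=n_codons,
        saturated=saturated,
    )


def sliding_window_omega(
    aln: CodonAlignment, window_nt: int = 150, step_nt: int = 9
) -> WindowProfile:
    """Per-window omega along the codon alignment.

    Windows are measured in alignment coordinates (gap columns included in
    the span, gapped codons skipped inside each window), so the window
    count floor((L - window)/step) + 1 depends only on alignment length.
    Windows with Ks = 0, saturation or no usable codons are nan.
    """
    L = aln.length_nt
    short = L < window_nt
    offsets = [0] if short else list(range(0, L - window_nt + 1, step_nt))
    windows: list[tuple[int, float]] = []
    for off in offsets:
        end = L if short else off + window_nt
        cols = aln.codon_columns[off // 3 : end // 3]
        try:
            est = ng86(cols, aln.gene_a, aln.gene_b)
            omega = est.omega
        except ValueError:
            omega = math.nan
        windows.append((off, omega))
    return WindowProfile(
        gene_a=aln.gene_a,
        gene_b=aln.gene_b,
        window_size_nt=window_nt,
        step_nt=step_nt,
        windows=windows,
        short=short,
    )


def ks_to_mya(ks: float, lambda_rate: float = DEFAULT_RATE) -> float:
    """Divergence time in Mya: T = Ks / (2*lambda), scaled to millions of years."""
    return ks / (2.0 * lambda_rate) * 1e-6


def date_block(
    flank_estimates: Iterable[RateEstimate],
    lambda_rate: float = DEFAULT_RATE,
    round_ks: bool = False,
) -> DuplicationDate:
    """Date a duplicated block from the Ks of its conserved flanking pairs
    (the anchor pair itself is excluded upstream). ``round_ks`` rounds the
    mean to 2 decimals before conversion, matching how printed per-block
    Ks values convert to dates."""
    ks_values = [
        e.Ks for e in flank_estimates if not e.saturated and not math.isnan(e.Ks)
    ]
    if not ks_values:
        raise ValueError("undatable block: all flanking estimates saturated")
    n = len(ks_values)
    mean = sum(ks_values) / n
    sd = math.sqrt(sum((k - mean) ** 2 for k in ks_values) / (n - 1)) if n > 1 else 0.0
    used = round(mean, 2) if round_ks else mean
    return DuplicationDate(
        mean_ks=mean,
        sd_ks=sd,
        n_flanks=n,
        lambda_rate=lambda_rate,
        T_mya=ks_to_mya(used, lambda_rate),
    )


def assign_wgd_event(
    mean_ks: float,
    recent_ks_max: float = 0.25,
    ancient_ks_range: tuple[float, float] = (0.45, 1.0),
) -> str:
    """Label a dated block by the Ks peak it falls in: the recent
    lineage-specific tetraploidy (~0.155), the ancient shared papilionoid
    polyploidy (~0.70), or 'intermediate' for anything between/beyond
    (e.g. a single segmental duplication at Ks ~0.38)."""
    if mean_ks < recent_ks_max:
        return "recent"
    if ancient_ks_range[0] <= mean_ks <= ancient_ks_range[1]:
        return "ancient"
    return "intermediate"


def ks_histogram(
    ks_values: Iterable[float], bin_width: float = 0.05, max_ks: float = 2.0
) -> list[tuple[float, int]]:
    """Counts of pairs per Ks bin (left edges), the age-distribution view
    in which WGD events appear as peaks."""
    n_bins = int(round(max_ks / bin_width))
    counts = [0] * n_bins
    for k in ks_values:
        if math.isnan(k) or k < 0 or k >= max_ks:
            continue
        counts[int(k / bin_width)] += 1
    return [(round(i * bin_width, 10), c) for i, c in enumerate(counts)]
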