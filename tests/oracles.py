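"""Independent brute-force oracles used only by the tests.

These deliberately share no code with the package: the genetic code is
written out literally, alignment is a plain dynamic program, and codon
counting enumerates every pathway explicitly.
"""

from __future__ import annotations

import math
from itertools import permutations

GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def oracle_sites(codon: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous site counts; stop-bound changes are
    excluded from the per-position denominator so the counts sum to 3."""
    aa = GENETIC_CODE[codon]
    syn = 0.0
    for pos in range(3):
        outcomes = []
        for base in "ACGT":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            alt_aa = GENETIC_CODE[alt]
            if alt_aa == "*":
                continue
            outcomes.append(alt_aa == aa)
        if outcomes:
            syn += sum(outcomes) / len(outcomes)
    return syn, 3.0 - syn


def oracle_pathways(c1: str, c2: str) -> tuple[float, float, bool]:
    """Pathway-averaged (syn, nonsyn) differences between two codons;
    usable=False when every pathway crosses a stop codon."""
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0, True
    totals = []
    for order in permutations(positions):
        cur = c1
        syn = nonsyn = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if GENETIC_CODE[nxt] == "*":
                ok = False
                break
            if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if ok:
            totals.append((syn, nonsyn))
    if not totals:
        return 0.0, 0.0, False
    return (
        sum(t[0] for t in totals) / len(totals),
        sum(t[1] for t in totals) / len(totals),
        True,
    )


def oracle_ng86(cds1: str, cds2: str) -> dict:
    """Full NG86 estimate computed codon by codon from the tables above."""
    assert len(cds1) == len(cds2) and len(cds1) % 3 == 0
    S = N = Sd = Nd = 0.0
    n_codons = 0
    for i in range(0, len(cds1), 3):
        a, b = cds1[i : i + 3], cds2[i : i + 3]
        if GENETIC_CODE[a] == "*" or GENETIC_CODE[b] == "*":
            continue
        sd, nd, usable = oracle_pathways(a, b)
        if not usable:
            continue
        s1, n1 = oracle_sites(a)
        s2, n2 = oracle_sites(b)
        S += (s1 + s2) / 2
        N += (n1 + n2) / 2
        Sd += sd
        Nd += nd
        n_codons += 1
    if n_codons == 0:
        return {"usable": False}
    pS = Sd / S if S else 0.0
    pN = Nd / N if N else 0.0

    def jc(p: float) -> float:
        if p >= 0.75:
            return math.nan
        if p <= 0:
            return 0.0
        return -0.75 * math.log(1 - 4 * p / 3)

    return {
        "usable": True,
        "S": S,
        "N": N,
        "Sd": Sd,
        "Nd": Nd,
        "Ks": jc(pS),
        "Ka": jc(pN),
        "n_codons": n_codons,
    }


def oracle_smith_waterman(
    a: str, b: str, matrix, open_cost: float = 11.0, extend_cost: float = 1.0
) -> float:
    """Plain three-matrix affine-gap local alignment score. A gap of
    length k costs open + (k-1)*extend, matching the package aligner's
    convention."""
    n, m = len(a), len(b)
    NEG = -1e9
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - open_cost, E[i][j - 1] - extend_cost)
            F[i][j] = max(H[i - 1][j] - open_cost, F[i - 1][j] - extend_cost)
            sub = H[i - 1][j - 1] + matrix[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def oracle_tandem_chains(
    positions: dict[str, tuple[str, int, int]],
    family: list[str],
    max_distance: int = 100_000,
    max_spacers: int = 10,
) -> list[tuple[str, ...]]:
    """Exhaustive tandem chains: family genes keyed to (chromosome, start,
    rank); consecutive family genes chain when within max_distance and
    separated by <= max_spacers non-family genes."""
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for gid in family:
        chrom, start, rank = positions[gid]
        by_chrom.setdefault(chrom, []).append((rank, start, gid))
    chains = []
    for chrom in sorted(by_chrom):
        members = sorted(by_chrom[chrom])
        current = [members[0]]
        for prev, cur in zip(members, members[1:]):
            linked = (
                abs(cur[1] - prev[1]) <= max_distance
                and cur[0] - prev[0] - 1 <= max_spacers
            )
            if linked:
                current.append(cur)
            else:
                if len(current) >= 2:
                    chains.append(tuple(g for _r, _s, g in current))
                current = [cur]
        if len(current) >= 2:
            chains.append(tuple(g for _r, _s, g in current))
    return chains
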