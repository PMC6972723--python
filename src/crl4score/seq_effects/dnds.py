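"""Pairwise dN/dS by the Nei-Gojobori (1986) counting method.

Synonymous and nonsynonymous *sites* are counted per codon as the fraction
of the three possible changes at each position that preserve the amino
acid (changes to a stop codon count as nonsynonymous); *differences*
between two codons are averaged over all minimal mutational paths, with
paths passing through stop codons excluded when any stop-free path exists.
Proportions are corrected for multiple hits with the Jukes-Cantor formula
d = -3/4 ln(1 - 4p/3), and omega = dN/dS (undefined when dS = 0).

This is a deliberate simplification relative to maximum-likelihood codon
models: substitution paths are weighted equally and no transition /
transversion bias is modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOPS = frozenset(_TABLE.stop_codons)
_AA = dict(_TABLE.forward_table)
BASES = "ACGT"


@dataclass
class DnDsResult:
    N: float  # nonsynonymous sites (average of both sequences)
    S: float  # synonymous sites
    Nd: float  # nonsynonymous differences
    Sd: float  # synonymous differences
    pN: float
    pS: float
    dN: float | None  # None when the Jukes-Cantor correction is undefined
    dS: float | None
    omega: float | None  # None when dS is 0 or undefined
    n_codons: int  # codon pairs actually compared (stop-containing pairs excluded)
    notes: tuple[str, ...] = ()


def _syn_site_fraction(codon: str) -> float:
    """Synonymous sites of one codon: per position, the fraction of the 3
    single-base changes that are synonymous (stop destinations are not)."""
    aa = _AA[codon]
    total = 0.0
    for i in range(3):
        syn = 0
        for b in BASES:
            if b == codon[i]:
                continue
            mut = codon[:i] + b + codon[i + 1 :]
            if mut not in STOPS and _AA[mut] == aa:
                syn += 1
        total += syn / 3.0
    return total


def _path_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences averaged over minimal paths."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff_pos):
        cur = c1
        sd = nd = 0
        through_stop = False
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1 :]
            if nxt in STOPS:
                through_stop = True
                nd += 1  # counted nonsynonymous if no stop-free path exists
            elif cur in STOPS or _AA[cur] != _AA[nxt]:
                nd += 1
            else:
                sd += 1
            cur = nxt
        paths.append((sd, nd, through_stop))
    clean = [(s, n) for s, n, stop in paths if not stop]
    use = clean if clean else [(s, n) for s, n, _ in paths]
    sd = sum(s for s, _ in use) / len(use)
    nd = sum(n for _, n in use) / len(use)
    return sd, nd


def _jukes_cantor(p: float) -> float | None:
    if p >= 0.75:
        return None
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_dnds(cds_a: str, cds_b: str) -> DnDsResult:
    """Pairwise dN/dS for two aligned, gap-free, equal-length CDS strings."""
    a, b = cds_a.upper(), cds_b.upper()
    if len(a) != len(b):
        raise ValueError(f"sequences differ in length ({len(a)} vs {len(b)})")
    if len(a) % 3:
        raise ValueError(f"alignment length {len(a)} not divisible by 3")
    if set(a + b) - set(BASES):
        raise ValueError("sequences must be gap-free and over ACGT")
    notes: list[str] = []
    S_a = S_b = Sd = Nd = 0.0
    n_codons = 0
    for i in range(0, len(a), 3):
        c1, c2 = a[i : i + 3], b[i : i + 3]
        if c1 in STOPS or c2 in STOPS:
            notes.append(f"codon {i // 3} contains a stop; pair excluded")
            continue
        n_codons += 1
        S_a += _syn_site_fraction(c1)
        S_b += _syn_site_fraction(c2)
        sd, nd = _path_differences(c1, c2)
        Sd += sd
        Nd += nd
    if n_codons == 0:
        raise ValueError("no comparable codons")
    S = (S_a + S_b) / 2.0
    N = 3.0 * n_codons - S
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = _jukes_cantor(pS)
    dN = _jukes_cantor(pN)
    if dS is None:
        notes.append("pS >= 3/4: synonymous Jukes-Cantor correction undefined")
    if dN is None:
        notes.append("pN >= 3/4: nonsynonymous Jukes-Cantor correction undefined")
    omega: float | None
    if dS is None or dN is None or dS == 0.0:
        omega = None
        if dS == 0.0:
            notes.append("dS = 0: omega undefined")
    else:
        omega = dN / dS
    return DnDsResult(
        N=N, S=S, Nd=Nd, Sd=Sd, pN=pN, pS=pS, dN=dN, dS=dS,
        omega=omega, n_codons=n_codons, notes=tuple(notes),
    )
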