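"""Codon-usage tables and synonymous-shift verdicts.

A synonymous variant swaps one codon for another within the same
synonymous family.  Whether the new codon is more or less frequently used
is judged at two scopes: the gene's own translation (table built from its
CDS) and the whole genome (a user-supplied reference table; a human-like
fixture ships with the package).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD.stop_codons)

#: codon -> amino acid (stops excluded)
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)

#: amino acid -> synonymous family (sorted codons)
FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    FAMILIES.setdefault(_aa, ())
    FAMILIES[_aa] = FAMILIES[_aa] + (_codon,)


@dataclass
class CodonUsageTable:
    """Codon counts plus within-family relative frequencies for one scope."""

    counts: dict[str, int]
    scope: str = "gene"
    frequencies: dict[str, float] = field(init=False)

    def __post_init__(self):
        unknown = set(self.counts) - set(CODON_TO_AA)
        if unknown - STOP_CODONS:
            raise ValueError(f"unknown codons in table: {sorted(unknown - STOP_CODONS)}")
        self.counts = {c: int(n) for c, n in self.counts.items() if c not in STOP_CODONS}
        self.frequencies = {}
        for aa, family in FAMILIES.items():
            total = sum(self.counts.get(c, 0) for c in family)
            for c in family:
                self.frequencies[c] = self.counts.get(c, 0) / total if total else 1.0 / len(family)

    def family(self, codon: str) -> tuple[str, ...]:
        return FAMILIES[CODON_TO_AA[codon]]

    def rank(self, codon: str) -> int:
        """Dense rank of the codon within its family (1 = most frequent)."""
        freqs = sorted({self.frequencies[c] for c in self.family(codon)}, reverse=True)
        return freqs.index(self.frequencies[codon]) + 1

    @classmethod
    def from_tsv(cls, path: str | Path, scope: str = "genome") -> "CodonUsageTable":
        df = pd.read_csv(path, sep="\t", dtype={"codon": str})
        return cls(counts=dict(zip(df["codon"], df["count"])), scope=scope)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            sorted(self.counts.items()), columns=["codon", "count"]
        ).to_csv(path, sep="\t", index=False)


def _codons(cds: str) -> Iterable[str]:
    for i in range(0, len(cds) - len(cds) % 3, 3):
        yield cds[i : i + 3].upper()


def codon_usage_table(cds_seqs: Iterable[str], scope: str = "gene") -> CodonUsageTable:
    """Count codons over one or more CDS sequences.

    Each CDS is expected to start with ATG, end with a stop and have length
    divisible by 3 (warnings otherwise).  Internal stop codons are excluded
    from the counts with a warning; the terminal stop is not counted.
    """
    cds_seqs = list(cds_seqs)
    if not cds_seqs:
        raise ValueError("no CDS sequences supplied")
    counts: Counter[str] = Counter()
    for idx, cds in enumerate(cds_seqs):
        cds = cds.upper()
        if len(cds) % 3:
            warnings.warn(f"CDS {idx} length {len(cds)} not divisible by 3; tail ignored")
        codons = list(_codons(cds))
        if not codons:
            continue
        if codons[0] != "ATG":
            warnings.warn(f"CDS {idx} does not start with ATG")
        if codons[-1] in STOP_CODONS:
            codons = codons[:-1]
        else:
            warnings.warn(f"CDS {idx} does not end with a stop codon")
        for c in codons:
            if c in STOP_CODONS:
                warnings.warn(f"internal stop codon {c} in CDS {idx}; excluded")
            elif c in CODON_TO_AA:
                counts[c] += 1
            else:
                warnings.warn(f"ambiguous codon {c!r} in CDS {idx}; excluded")
    return CodonUsageTable(counts=dict(counts), scope=scope)


SHIFT_VERDICTS = ("to_most_frequent", "to_less_frequent", "unchanged_rank")


def _shift_verdict(ref_codon: str, alt_codon: str, table: CodonUsageTable) -> str:
    r_ref, r_alt = table.rank(ref_codon), table.rank(alt_codon)
    if r_alt < r_ref:
        return "to_most_frequent"
    if r_alt > r_ref:
        return "to_less_frequent"
    return "unchanged_rank"


def synonymous_codon_shift(
    ref_codon: str,
    alt_codon: str,
    tables: Mapping[str, CodonUsageTable],
) -> dict[str, str]:
    """Per-scope verdict on whether the swap moves toward or away from the
    family's preferred codon (by within-family frequency rank)."""
    ref_codon, alt_codon = ref_codon.upper(), alt_codon.upper()
    for c in (ref_codon, alt_codon):
        if c not in CODON_TO_AA:
            raise ValueError(f"{c!r} is a stop or invalid codon")
    if CODON_TO_AA[ref_codon] != CODON_TO_AA[alt_codon]:
        raise ValueError(
            f"{ref_codon}->{alt_codon} is not synonymous "
            f"({CODON_TO_AA[ref_codon]} vs {CODON_TO_AA[alt_codon]})"
        )
    return {scope: _shift_verdict(ref_codon, alt_codon, t) for scope, t in tables.items()}


def synonymous_shift_for_variant(variant, gm, cds_seq: str, genome_table: CodonUsageTable):
    """Scope-resolved shift verdict for a coding-synonymous SNV.

    Builds the gene-scope table from the gene's own CDS and compares against
    the supplied genome-scope table.
    """
    from ..data_io import CodingEffect, coding_effect, revcomp

    if coding_effect(variant, gm, cds_seq) is not CodingEffect.SYNONYMOUS:
        raise ValueError(f"{variant.vid} is not coding-synonymous in {gm.gene}")
    cpos = gm.cds_position(variant.pos - 1)
    ci, within = divmod(cpos, 3)
    ref_codon = cds_seq[3 * ci : 3 * ci + 3].upper()
    alt_base = variant.alt.upper() if gm.strand == "+" else revcomp(variant.alt).upper()
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    gene_table = codon_usage_table([cds_seq], scope="gene")
    return synonymous_codon_shift(
        ref_codon, alt_codon, {"gene": gene_table, "genome": genome_table}
    )


def default_genome_table() -> CodonUsageTable:
    """The packaged human-like genome-scope codon-usage fixture."""
    path = Path(__file__).resolve().parent.parent / "data" / "human_codon_usage.tsv"
    return CodonUsageTable.from_tsv(path, scope="genome")
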