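"""Bisulfite-conversion simulation and methylation calling.

Sodium bisulfite deaminates unmethylated cytosine to uracil (read as
thymine after PCR) while 5-methylcytosine at CpG sites is protected.
Comparing a converted read with the original genomic sequence therefore
recovers the methylation state of every CpG cytosine.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Collection

import numpy as np


def cpg_sites(seq: str) -> list[int]:
    """0-based positions of the C of every CpG dinucleotide."""
    s = seq.upper()
    return [i for i in range(len(s) - 1) if s[i] == "C" and s[i + 1] == "G"]


def bisulfite_convert(
    seq: str,
    methylated: Collection[int],
    conversion_failure_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> str:
    """Convert every unmethylated C to T; methylated CpG cytosines are kept.

    ``methylated`` lists the (0-based) CpG cytosine positions carrying a
    methyl mark; positions that are not CpG cytosines are rejected.  A
    nonzero ``conversion_failure_rate`` leaves that fraction of
    unmethylated cytosines unconverted (incomplete-conversion noise); the
    default models complete conversion.
    """
    sites = set(cpg_sites(seq))
    methylated = set(methylated)
    bad = methylated - sites
    if bad:
        raise ValueError(f"methylation states at non-CpG-cytosine positions: {sorted(bad)[:5]}")
    if not 0.0 <= conversion_failure_rate <= 1.0:
        raise ValueError("conversion_failure_rate must be in [0, 1]")
    if conversion_failure_rate > 0 and rng is None:
        rng = np.random.default_rng()
    out = []
    for i, base in enumerate(seq):
        if base.upper() == "C" and i not in methylated:
            if conversion_failure_rate > 0 and rng.random() < conversion_failure_rate:
                out.append(base)
            else:
                out.append("T" if base.isupper() else "t")
        else:
            out.append(base)
    return "".join(out)


@dataclass
class MethylationCall:
    """Per-CpG-site methylation status: methylated / unmethylated / uninformative."""

    positions: list[int]
    status: dict[int, str]

    @property
    def methylated(self) -> list[int]:
        return [p for p in self.positions if self.status[p] == "methylated"]

    @property
    def n_methylated(self) -> int:
        return len(self.methylated)


def call_methylation(original: str, converted: str) -> MethylationCall:
    """Invert the bisulfite mapping at every CpG cytosine of ``original``.

    A retained C is called methylated, a C->T read unmethylated, anything
    else uninformative (e.g. a sequencing mismatch).
    """
    if len(original) != len(converted):
        raise ValueError(
            f"length mismatch: original {len(original)} vs converted {len(converted)}"
        )
    positions = cpg_sites(original)
    status: dict[int, str] = {}
    for p in positions:
        base = converted[p].upper()
        if base == "C":
            status[p] = "methylated"
        elif base == "T":
            status[p] = "unmethylated"
        else:
            status[p] = "uninformative"
    return MethylationCall(positions=positions, status=status)
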