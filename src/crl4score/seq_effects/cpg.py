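"""CpG-island detection and per-variant island impact.

Islands follow the Gardiner-Garden & Frommer criteria: every 200-bp window
with GC fraction >= 0.5 and observed/expected CpG >= 0.6 qualifies, and
overlapping qualifying windows are merged into maximal islands.  The
observed/expected ratio is #CpG / (#C x #G / L).  ``N`` bases disqualify
any window containing them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class CpGIsland:
    start: int  # 0-based half-open
    end: int
    gc_fraction: float
    obs_exp: float

    @property
    def length(self) -> int:
        return self.end - self.start


def _window_stats(seq: str, start: int, end: int) -> tuple[float, float]:
    sub = seq[start:end].upper()
    c = sub.count("C")
    g = sub.count("G")
    cpg = sub.count("CG")
    gc = (c + g) / len(sub) if sub else 0.0
    oe = cpg / (c * g / len(sub)) if c > 0 and g > 0 else 0.0
    return gc, oe


def find_cpg_islands(
    seq: str,
    min_length: int = 200,
    gc_min: float = 0.5,
    oe_min: float = 0.6,
) -> list[CpGIsland]:
    """Maximal merged islands whose every sliding window meets the criteria.

    The window length equals ``min_length`` and slides with step 1; CpG
    dinucleotides are counted when they lie entirely inside the window.
    """
    n = len(seq)
    w = min_length
    if n < w:
        return []
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype="S1")
    is_c = arr == b"C"
    is_g = arr == b"G"
    is_bad = ~(is_c | is_g | (arr == b"A") | (arr == b"T"))
    is_cpg = np.zeros(n, dtype=bool)
    is_cpg[:-1] = is_c[:-1] & is_g[1:]

    def win_sums(x: np.ndarray, width: int) -> np.ndarray:
        cs = np.concatenate(([0], np.cumsum(x)))
        return cs[width:] - cs[:-width]

    c = win_sums(is_c, w).astype(float)
    g = win_sums(is_g, w).astype(float)
    bad = win_sums(is_bad, w)
    # CpG fully inside window [s, s+w): start index in [s, s+w-1)
    cpg = win_sums(is_cpg[: n - 1] if n > 1 else is_cpg, w - 1).astype(float)
    cpg = cpg[: n - w + 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        gc_ok = (c + g) / w >= gc_min
        oe = np.where((c > 0) & (g > 0), cpg / (c * g / w), 0.0)
    qualify = (bad == 0) & gc_ok & (oe >= oe_min)

    islands: list[CpGIsland] = []
    starts = np.flatnonzero(qualify)
    if starts.size == 0:
        return islands
    run_start = starts[0]
    prev = starts[0]
    for s in starts[1:]:
        if s > prev + w:  # windows no longer overlap: close the island
            islands.append(_make_island(seq, run_start, prev + w))
            run_start = s
        prev = s
    islands.append(_make_island(seq, run_start, prev + w))
    return islands


def _make_island(seq: str, start: int, end: int) -> CpGIsland:
    gc, oe = _window_stats(seq, start, end)
    return CpGIsland(start=start, end=end, gc_fraction=gc, obs_exp=oe)


def _overlapping(islands: list[CpGIsland], lo: int, hi: int) -> list[CpGIsland]:
    return [i for i in islands if i.end > lo and i.start < hi]


def cpg_island_delta(
    seq: str,
    pos: int,
    ref: str,
    alt: str,
    min_length: int = 200,
    gc_min: float = 0.5,
    oe_min: float = 0.6,
) -> tuple[str, int]:
    """Island impact of substituting ``alt`` for ``ref`` at 1-based ``pos``.

    Compares islands overlapping the variant neighbourhood (+/- 2 window
    lengths) before and after the edit and reports one of
    {created, disrupted, enlarged, shrunk, none} plus the net island-length
    change in bp.
    """
    p = pos - 1
    if not 0 <= p < len(seq):
        raise ValueError(f"position {pos} outside sequence of length {len(seq)}")
    if seq[p : p + len(ref)].upper() != ref.upper():
        raise ValueError(
            f"REF mismatch at {pos}: sequence has {seq[p : p + len(ref)]!r}, expected {ref!r}"
        )
    alt_seq = seq[:p] + alt + seq[p + len(ref) :]
    lo = max(0, p - 2 * min_length)
    hi_ref = p + len(ref) + 2 * min_length
    hi_alt = p + len(alt) + 2 * min_length
    params = dict(min_length=min_length, gc_min=gc_min, oe_min=oe_min)
    before = _overlapping(find_cpg_islands(seq, **params), lo, hi_ref)
    after = _overlapping(find_cpg_islands(alt_seq, **params), lo, hi_alt)
    bp_before = sum(i.length for i in before)
    bp_after = sum(i.length for i in after)
    delta = bp_after - bp_before
    if not before and not after:
        return "none", 0
    if not before and after:
        return "created", delta
    if before and not after:
        return "disrupted", delta
    if delta > 0:
        return "enlarged", delta
    if delta < 0:
        return "shrunk", delta
    return "none", 0
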