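"""Position-weight-matrix scoring of transcription-factor binding-site
disruption by a variant (log-odds scanning of both strands around the site)."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class PWM:
    """Probability matrix (L x 4, columns A,C,G,T) with background model.

    ``probs`` must already include any pseudocount smoothing: every row sums
    to 1 and no entry is zero, so log-odds are finite.
    """

    name: str
    probs: np.ndarray
    background: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("PWM probabilities must be an L x 4 matrix")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM rows must each sum to 1 after pseudocount normalization")
        if (self.probs <= 0).any():
            raise ValueError("PWM probabilities must be strictly positive (use a pseudocount)")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background frequencies must sum to 1")

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """log2(p / background), L x 4 (bits)."""
        return np.log2(self.probs / self.background)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=1).sum())

    @classmethod
    def from_counts(cls, name: str, counts: np.ndarray, pseudocount: float = 0.25) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        probs = (counts + pseudocount) / (counts.sum(axis=1, keepdims=True) + 4 * pseudocount)
        return cls(name=name, probs=probs)

    def score_window(self, window: str) -> float:
        """Log-odds score of one window of exactly L bases; -inf on non-ACGT."""
        if len(window) != self.length:
            raise ValueError(f"window length {len(window)} != motif length {self.length}")
        lo = self.log_odds
        score = 0.0
        for i, base in enumerate(window.upper()):
            j = _BASE_INDEX.get(base)
            if j is None:
                return float("-inf")
            score += lo[i, j]
        return float(score)


def read_jaspar(path: str | Path, pseudocount: float = 0.25) -> PWM:
    """Read the first motif of a JASPAR-format file via Biopython."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        m = bio_motifs.read(fh, "jaspar")
    counts = np.array([[m.counts[b][i] for b in BASES] for i in range(m.length)])
    return PWM.from_counts(name=m.name or m.matrix_id or "motif", counts=counts, pseudocount=pseudocount)


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgt", "TGCAtgca"))[::-1]


def best_score_near(seq: str, pwm: PWM, lo: int, hi: int) -> float:
    """Best log-odds over both strands among windows overlapping [lo, hi)."""
    L = pwm.length
    best = float("-inf")
    for start in range(max(0, lo - L + 1), min(len(seq) - L, hi - 1) + 1):
        window = seq[start : start + L]
        best = max(best, pwm.score_window(window), pwm.score_window(_revcomp(window)))
    return best


@dataclass(frozen=True)
class MotifBreakResult:
    ref_score: float
    alt_score: float
    delta: float
    verdict: str  # broken | weakened | unchanged | strengthened


def pwm_motif_break(
    seq: str,
    pos: int,
    ref: str,
    alt: str,
    pwm: PWM,
    score_threshold: float | None = None,
    weak_delta: float = 1.0,
) -> MotifBreakResult:
    """Score the best motif window overlapping a variant before and after the edit.

    ``score_threshold`` is the log-odds level above which a site is
    considered bound (default: 80% of the motif's maximum score, a
    conservative choice).  Verdicts:

    - ``broken``: reference site above threshold, alternate below;
    - ``strengthened``: alternate crosses above threshold, or gains >=
      ``weak_delta`` bits;
    - ``weakened``: loses >= ``weak_delta`` bits without dropping below
      threshold;
    - ``unchanged`` otherwise.
    """
    p = pos - 1
    if seq[p : p + len(ref)].upper() != ref.upper():
        raise ValueError(f"REF mismatch at {pos}: {seq[p : p + len(ref)]!r} != {ref!r}")
    if score_threshold is None:
        score_threshold = 0.8 * pwm.max_score
    alt_seq = seq[:p] + alt + seq[p + len(ref) :]
    ref_score = best_score_near(seq, pwm, p, p + len(ref))
    alt_score = best_score_near(alt_seq, pwm, p, p + len(alt))
    finite = [s for s in (ref_score, alt_score) if np.isfinite(s)]
    delta = alt_score - ref_score if len(finite) == 2 else 0.0
    if ref_score >= score_threshold and alt_score < score_threshold:
        verdict = "broken"
    elif alt_score >= score_threshold and ref_score < score_threshold:
        verdict = "strengthened"
    elif delta <= -weak_delta:
        verdict = "weakened"
    elif delta >= weak_delta:
        verdict = "strengthened"
    else:
        verdict = "unchanged"
    return MotifBreakResult(ref_score=ref_score, alt_score=alt_score, delta=delta, verdict=verdict)


def default_ikzf1_pwm() -> PWM:
    """Packaged synthetic Ikaros-family-like PWM (GGGAA-core consensus)."""
    path = Path(__file__).resolve().parent.parent / "data" / "ikzf1_like_synthetic.jaspar"
    return read_jaspar(path)
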