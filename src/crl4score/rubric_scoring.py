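"""Severity rubric: turn normalized predictor verdicts into per-variant scores.

External functional predictors (deleteriousness ensembles, splicing and
polyadenylation tools, TFBS/miRNA-binding scanners, CpG and mRNA-structure
analyses, enhancer overlap, codon-usage screens) are ingested as normalized
annotations: one verdict in {none, possible, strong} per category.  The
rubric maps each (category, verdict) to points; the per-variant total over
the ten categories ranges from 0 to 20 under the default weighting, and
variants totalling at least 10 points make the reporting heatmap.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .data_io import GeneModel, Variant

log = logging.getLogger(__name__)

#: annotation categories, one column each in the score heatmap
CATEGORIES: tuple[str, ...] = (
    "ensemble_deleteriousness",
    "protein_effect",
    "splicing",
    "polyadenylation",
    "tfbs",
    "mirna_binding",
    "cpg_island",
    "mrna_structure",
    "enhancer",
    "codon_usage",
)


class Verdict(enum.IntEnum):
    NONE = 0
    POSSIBLE = 1
    STRONG = 2

    @classmethod
    def parse(cls, value) -> "Verdict":
        if isinstance(value, Verdict):
            return value
        if isinstance(value, (int, float)) and int(value) == value:
            return cls(int(value))
        try:
            return cls[str(value).strip().upper()]
        except KeyError:
            raise ValueError(f"unknown verdict {value!r}") from None


@dataclass(frozen=True)
class Annotation:
    """One raw predictor verdict for one variant."""

    vid: str
    category: str
    verdict: Verdict
    source: str = ""

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown annotation category {self.category!r}")
        object.__setattr__(self, "verdict", Verdict.parse(self.verdict))


@dataclass
class Rubric:
    """Category x verdict -> points map plus positional modifiers.

    The default reconstruction gives 0/1/2 points for none/possible/strong
    in each of the ten categories, so the maximum attainable total is 20.
    """

    points: dict[str, dict[Verdict, int]]
    promote_splicing_before_critical_exon: bool = True

    def __post_init__(self):
        for cat in CATEGORIES:
            if cat not in self.points:
                raise ValueError(f"rubric missing category {cat!r}")
            p = {Verdict.parse(k): int(v) for k, v in self.points[cat].items()}
            for v in Verdict:
                p.setdefault(v, 0)
            if p[Verdict.NONE] != 0:
                raise ValueError(f"rubric must give 0 points to verdict none ({cat})")
            if not p[Verdict.NONE] <= p[Verdict.POSSIBLE] <= p[Verdict.STRONG]:
                raise ValueError(f"rubric points not monotone in severity ({cat})")
            if min(p.values()) < 0:
                raise ValueError(f"negative rubric points ({cat})")
            self.points[cat] = p

    @classmethod
    def default(cls) -> "Rubric":
        return cls(
            points={c: {Verdict.NONE: 0, Verdict.POSSIBLE: 1, Verdict.STRONG: 2} for c in CATEGORIES}
        )

    @property
    def max_total(self) -> int:
        return sum(max(p.values()) for p in self.points.values())

    def score(self, category: str, verdict: Verdict) -> int:
        return self.points[category][Verdict.parse(verdict)]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Rubric":
        raw = yaml.safe_load(Path(path).read_text())
        points = {
            cat: {Verdict.parse(k): int(v) for k, v in table.items()}
            for cat, table in raw["points"].items()
        }
        return cls(
            points=points,
            promote_splicing_before_critical_exon=bool(
                raw.get("promote_splicing_before_critical_exon", True)
            ),
        )

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "points": {
                cat: {v.name.lower(): pts for v, pts in sorted(table.items())}
                for cat, table in self.points.items()
            },
            "promote_splicing_before_critical_exon": self.promote_splicing_before_critical_exon,
        }
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


VerdictProfile = dict[str, Verdict]  # category -> consolidated verdict


def consolidate_annotations(records: Iterable[Annotation]) -> dict[str, VerdictProfile]:
    """Keep the most severe verdict per (variant, category).

    Categories with no record default to ``none`` at scoring time; duplicate
    records at equal severity are collapsed silently into one (logged).
    """
    out: dict[str, VerdictProfile] = {}
    seen: dict[tuple[str, str], int] = {}
    for rec in records:
        if not isinstance(rec, Annotation):
            rec = Annotation(*rec)
        profile = out.setdefault(rec.vid, {})
        prev = profile.get(rec.category, Verdict.NONE)
        key = (rec.vid, rec.category)
        if key in seen and rec.verdict == prev:
            log.debug("duplicate verdict %s for %s/%s", rec.verdict.name, *key)
        profile[rec.category] = max(prev, rec.verdict)
        seen[key] = seen.get(key, 0) + 1
    return out


def apply_modifiers(
    v: Variant, gm: GeneModel, profile: VerdictProfile, rubric: Rubric
) -> VerdictProfile:
    """Positional severity promotion.

    Any splicing-relevant verdict on a variant lying in, or within the
    intronic flank of, an exon upstream of the first critical exon is
    promoted to ``strong``: losing such an exon removes everything the
    critical exons encode (for Cereblon, the C-terminal thalidomide-binding
    region behind exon 10).
    """
    out = dict(profile)
    if not rubric.promote_splicing_before_critical_exon or not gm.critical_exons:
        return out
    verdict = out.get("splicing", Verdict.NONE)
    if verdict == Verdict.NONE or verdict == Verdict.STRONG:
        return out
    exon_no = gm.nearest_exon_number(v.pos - 1)
    if exon_no is not None and exon_no < min(gm.critical_exons):
        out["splicing"] = Verdict.STRONG
    return out


@dataclass
class VariantScore:
    vid: str
    points: dict[str, int]
    total: int = field(init=False)

    def __post_init__(self):
        self.total = sum(self.points.values())


def score_variant(vid: str, profile: VerdictProfile, rubric: Rubric) -> VariantScore:
    points = {c: rubric.score(c, profile.get(c, Verdict.NONE)) for c in CATEGORIES}
    return VariantScore(vid=vid, points=points)


def score_variants(
    variants: Iterable[Variant],
    models: Mapping[str, GeneModel] | None,
    consolidated: Mapping[str, VerdictProfile],
    rubric: Rubric | None = None,
) -> pd.DataFrame:
    """Score every variant; returns a vid-indexed frame of per-category points + total.

    When gene models are supplied the positional splicing modifier is applied
    before scoring; otherwise verdicts are scored as-is.
    """
    rubric = rubric or Rubric.default()
    rows = {}
    genes = {}
    for v in variants:
        profile = dict(consolidated.get(v.vid, {}))
        if models is not None and v.gene in models:
            profile = apply_modifiers(v, models[v.gene], profile, rubric)
        sc = score_variant(v.vid, profile, rubric)
        rows[v.vid] = {**sc.points, "total": sc.total}
        genes[v.vid] = v.gene
    df = pd.DataFrame.from_dict(rows, orient="index", dtype=int)
    if df.empty:
        df = pd.DataFrame(columns=[*CATEGORIES, "total"], dtype=int)
    df = df[[*CATEGORIES, "total"]]
    df.insert(0, "gene", pd.Series(genes, dtype=str))
    df.index.name = "vid"
    return df


def build_heatmap(scores: pd.DataFrame, threshold: int = 10) -> pd.DataFrame:
    """Restrict to variants totalling >= threshold, best first (ties by vid)."""
    kept = scores[scores["total"] >= threshold]
    if kept.empty:
        warnings.warn(f"no variant reaches the score threshold {threshold}")
    order = sorted(kept.index, key=lambda vid: (-kept.at[vid, "total"], vid))
    return kept.loc[order]


def plot_heatmap(heatmap: pd.DataFrame, path: str | Path, title: str = "") -> None:
    """Optional PNG rendering of the score heatmap (never load-bearing)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = heatmap[list(CATEGORIES)]
    fig, ax = plt.subplots(figsize=(8, max(2, 0.3 * len(data) + 1.5)))
    im = ax.imshow(data.values, aspect="auto", cmap="YlOrRd", vmin=0)
    ax.set_xticks(range(len(CATEGORIES)), CATEGORIES, rotation=60, ha="right", fontsize=7)
    ax.set_yticks(range(len(data)), [f"{v} ({heatmap.at[v, 'total']})" for v in data.index], fontsize=7)
    fig.colorbar(im, ax=ax, label="points")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def read_annotations(path: str | Path) -> list[Annotation]:
    """Annotations TSV with columns vid, category, verdict, source."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"vid", "category", "verdict"}
    if not required <= set(df.columns):
        raise ValueError(f"annotation TSV missing columns: {sorted(required - set(df.columns))}")
    return [
        Annotation(r.vid, r.category, Verdict.parse(r.verdict), getattr(r, "source", "") or "")
        for r in df.itertuples(index=False)
    ]


def write_annotations(annotations: Iterable[Annotation], path: str | Path) -> None:
    pd.DataFrame(
        [(a.vid, a.category, a.verdict.name.lower(), a.source) for a in annotations],
        columns=["vid", "category", "verdict", "source"],
    ).to_csv(path, sep="\t", index=False)
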