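"""Per-individual burden and cohort-level statistics.

Burden is computed two ways, following how the cohort analysis frames it:
(1) the absolute number of variants an individual carries and (2) the sum
of the severity scores of those variants.  Group comparisons use a pooled
two-sample t-test (Welch optional), one-way ANOVA across three groups,
and Pearson chi-square (no continuity correction) with a Fisher exact
companion on 2x2 genotype-endophenotype tables.  Nominal p-values are
reported by default; Benjamini-Hochberg adjustment is opt-in.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import GenotypeMatrix, LocationDistribution, PANEL_CATEGORIES, Variant

log = logging.getLogger(__name__)

OVERALL = "__all__"  # pseudo-gene key for panel-wide burden


@dataclass
class GroupComparison:
    """One statistical comparison between sample groups."""

    test: str  # t_test | welch_t | anova | chisq | fisher
    target: str  # what was compared (e.g. "score:CRBN", "count:__all__")
    groups: dict[str, int]  # group -> n
    means: dict[str, float] = field(default_factory=dict)
    statistic: float = float("nan")
    df: float = float("nan")
    p_value: float = float("nan")
    effect: float = float("nan")  # mean difference or odds ratio
    note: str = ""

    def __post_init__(self):
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0,1]: {self.p_value}")


def individual_burden(
    gmatrix: GenotypeMatrix,
    scores: Mapping[str, int | float],
    variant_genes: Mapping[str, str],
    weighting: str = "carrier",
) -> pd.DataFrame:
    """Per-individual, per-gene variant counts and score sums.

    ``carrier`` weighting counts each carried variant (dosage >= 1) once;
    ``dosage`` weighting multiplies by the alt-allele dosage.  Missing
    genotypes contribute nothing (logged).  Variants without a score
    contribute to counts with score 0 (logged).  Returns a tidy frame
    (individual, gene, variant_count, score_sum) including an ``__all__``
    panel-wide row per individual.
    """
    if weighting not in ("carrier", "dosage"):
        raise ValueError(f"unknown weighting {weighting!r}")
    dosage = gmatrix.dosage
    n_missing = int(dosage.isna().sum().sum())
    if n_missing:
        log.info("%d missing genotypes excluded from burden sums", n_missing)
    unscored = [v for v in dosage.columns if v not in scores]
    if unscored:
        log.info("%d variants lack scores; counted with score 0", len(unscored))
    score_vec = np.array([float(scores.get(v, 0)) for v in dosage.columns])
    gene_of = np.array([variant_genes.get(v, "") for v in dosage.columns])
    weights = dosage.fillna(0.0).to_numpy()
    if weighting == "carrier":
        weights = (weights >= 1).astype(float)
    rows = []
    genes = sorted(set(gene_of))
    for gi, ind in enumerate(dosage.index):
        w = weights[gi]
        for gene in genes:
            mask = gene_of == gene
            rows.append(
                (ind, gene, float(w[mask].sum()), float((w[mask] * score_vec[mask]).sum()))
            )
        rows.append((ind, OVERALL, float(w.sum()), float((w * score_vec).sum())))
    return pd.DataFrame(rows, columns=["individual", "gene", "variant_count", "score_sum"])


def _burden_values(
    profiles: pd.DataFrame, individuals: Sequence[str], by: str, gene: str
) -> np.ndarray:
    col = {"count": "variant_count", "score": "score_sum"}[by]
    sub = profiles[(profiles["gene"] == gene) & profiles["individual"].isin(set(individuals))]
    sub = sub.set_index("individual").loc[list(individuals)]
    return sub[col].to_numpy(dtype=float)


def compare_burden(
    profiles: pd.DataFrame,
    cohorts: Mapping[str, Sequence[str]],
    by: str = "score",
    gene: str = OVERALL,
    welch: bool = False,
) -> GroupComparison:
    """Two-sided two-sample t-test of burden between two groups.

    ``cohorts`` maps exactly two group names to individual-id lists.  The
    default is the pooled-variance Student's t-test; ``welch`` switches to
    the unequal-variance form.  Degenerate zero-variance inputs with equal
    means return t = 0, p = 1.
    """
    if len(cohorts) != 2:
        raise ValueError("compare_burden needs exactly two groups")
    (name_a, ids_a), (name_b, ids_b) = cohorts.items()
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError("each group needs n >= 2")
    a = _burden_values(profiles, ids_a, by, gene)
    b = _burden_values(profiles, ids_b, by, gene)
    test = "welch_t" if welch else "t_test"
    note = ""
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        if np.mean(a) == np.mean(b):
            t, p, dof = 0.0, 1.0, len(a) + len(b) - 2
            note = "zero variance in both groups, equal means"
        else:
            t, p, dof = np.inf, 0.0, len(a) + len(b) - 2
            note = "zero variance in both groups, unequal means"
    else:
        res = stats.ttest_ind(a, b, equal_var=not welch)
        t, p = float(res.statistic), float(res.pvalue)
        dof = float(res.df)
    return GroupComparison(
        test=test,
        target=f"{by}:{gene}",
        groups={name_a: len(ids_a), name_b: len(ids_b)},
        means={name_a: float(np.mean(a)), name_b: float(np.mean(b))},
        statistic=t,
        df=dof,
        p_value=p,
        effect=float(np.mean(a) - np.mean(b)),
        note=note,
    )


def anova_burden(
    profiles: pd.DataFrame,
    cohorts: Mapping[str, Sequence[str]],
    by: str = "score",
    gene: str = OVERALL,
) -> GroupComparison:
    """One-way ANOVA of burden across three or more groups."""
    if len(cohorts) < 3:
        raise ValueError("anova_burden needs at least three groups")
    values = {}
    for name, ids in cohorts.items():
        if len(ids) < 2:
            raise ValueError(f"group {name!r} needs n >= 2")
        values[name] = _burden_values(profiles, ids, by, gene)
    groups = list(values.values())
    if all(np.var(g) == 0.0 for g in groups) and len({float(np.mean(g)) for g in groups}) == 1:
        f, p = 0.0, 1.0
    else:
        res = stats.f_oneway(*groups)
        f, p = float(res.statistic), float(res.pvalue)
    k = len(groups)
    n = sum(len(g) for g in groups)
    return GroupComparison(
        test="anova",
        target=f"{by}:{gene}",
        groups={name: len(ids) for name, ids in cohorts.items()},
        means={name: float(np.mean(v)) for name, v in values.items()},
        statistic=f,
        df=float(k - 1),  # between-group df; residual df = n - k
        p_value=p,
        effect=float(max(np.mean(v) for v in values.values()) - min(np.mean(v) for v in values.values())),
        note=f"residual df={n - k}",
    )


def compare_location_distribution(
    sample: LocationDistribution,
    reference: LocationDistribution,
    n_monte_carlo: int = 20000,
    rng: np.random.Generator | None = None,
) -> GroupComparison:
    """Pearson chi-square homogeneity test on the 2 x k location-count table.

    When any expected cell drops below 1 a Monte-Carlo exact p-value
    (conditional on the margins) is reported instead, with a note.
    """
    cats = [c for c in PANEL_CATEGORIES]
    obs = np.array(
        [[sample.counts.get(c, 0) for c in cats], [reference.counts.get(c, 0) for c in cats]],
        dtype=float,
    )
    keep = obs.sum(axis=0) > 0
    obs = obs[:, keep]
    if obs.shape[1] < 2 or (obs.sum(axis=1) == 0).any():
        raise ValueError("need at least two populated categories in both samples")
    chi2, p, dof, expected = stats.chi2_contingency(obs, correction=False)
    note = ""
    if (expected < 1).any():
        rng = rng or np.random.default_rng()
        p = _monte_carlo_chi2_p(obs, chi2, n_monte_carlo, rng)
        note = f"expected cell < 1: Monte-Carlo exact p ({n_monte_carlo} tables)"
        warnings.warn("expected count below 1; reporting Monte-Carlo exact p-value")
    return GroupComparison(
        test="chisq",
        target="location_distribution",
        groups={sample.sample: int(obs[0].sum()), reference.sample: int(obs[1].sum())},
        statistic=float(chi2),
        df=float(dof),
        p_value=float(p),
        note=note,
    )


def _monte_carlo_chi2_p(obs: np.ndarray, chi2_obs: float, n: int, rng: np.random.Generator) -> float:
    row = obs.sum(axis=1).astype(int)
    col = obs.sum(axis=0).astype(int)
    total = int(obs.sum())
    hits = 0
    pool = np.repeat(np.arange(len(col)), col)
    for _ in range(n):
        rng.shuffle(pool)
        first = pool[: row[0]]
        t0 = np.bincount(first, minlength=len(col))
        table = np.vstack([t0, col - t0])
        with np.errstate(divide="ignore", invalid="ignore"):
            exp = np.outer(table.sum(axis=1), col) / total
            stat = np.nansum((table - exp) ** 2 / exp)
        if stat >= chi2_obs - 1e-12:
            hits += 1
    return (hits + 1) / (n + 1)


def genotype_phenotype_test(
    vid: str,
    gmatrix: GenotypeMatrix,
    groups: Mapping[str, Sequence[str]],
    mode: str = "carrier",
) -> list[GroupComparison]:
    """Association between one variant and two endophenotype groups.

    ``carrier`` mode tests the 2x2 carrier-vs-noncarrier table with Pearson
    chi-square (no continuity correction) and Fisher's exact test;
    ``genotype`` mode tests the genotype-level 2x3 table with chi-square
    only.  Monomorphic variants (a degenerate table column) are skipped
    with a notice and return an empty list.
    """
    if mode not in ("carrier", "genotype"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(groups) != 2:
        raise ValueError("genotype_phenotype_test needs exactly two groups")
    dosages = {
        name: gmatrix.dosage.loc[list(ids), vid].dropna() for name, ids in groups.items()
    }
    (name_a, d_a), (name_b, d_b) = dosages.items()
    if mode == "carrier":
        table = np.array(
            [
                [int((d_a >= 1).sum()), int((d_a == 0).sum())],
                [int((d_b >= 1).sum()), int((d_b == 0).sum())],
            ]
        )
    else:
        table = np.array(
            [[int((d == g).sum()) for g in (0, 1, 2)] for d in (d_a, d_b)]
        )
        table = table[:, table.sum(axis=0) > 0]
    if (table.sum(axis=0) == 0).any() or table.shape[1] < 2:
        log.info("variant %s monomorphic in tested groups; association skipped", vid)
        return []
    out = []
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    out.append(
        GroupComparison(
            test="chisq",
            target=f"{vid}:{mode}",
            groups={name_a: int(table[0].sum()), name_b: int(table[1].sum())},
            statistic=float(chi2),
            df=float(dof),
            p_value=float(p),
        )
    )
    if table.shape == (2, 2):
        odds, p_fisher = stats.fisher_exact(table)
        out.append(
            GroupComparison(
                test="fisher",
                target=f"{vid}:{mode}",
                groups={name_a: int(table[0].sum()), name_b: int(table[1].sum())},
                statistic=float("nan"),
                df=float("nan"),
                p_value=float(p_fisher),
                effect=float(odds),
            )
        )
    return out


def rarity_flags(frequencies: Mapping[str, float], maf_threshold: float = 0.01) -> pd.DataFrame:
    """Flag rare variants (MAF strictly below the threshold).

    Frequencies above 0.5 are folded to the minor allele.  Missing (NaN)
    frequencies yield an unknown flag.  The returned frame carries the rare
    fraction among known-frequency variants in ``df.attrs['rare_fraction']``.
    """
    rows = []
    for vid, f in frequencies.items():
        if f is None or (isinstance(f, float) and np.isnan(f)):
            rows.append((vid, np.nan, None))
            continue
        maf = min(float(f), 1.0 - float(f))
        rows.append((vid, maf, bool(maf < maf_threshold)))
    df = pd.DataFrame(rows, columns=["vid", "maf", "rare"])
    known = df["rare"].notna()
    df.attrs["rare_fraction"] = float(df.loc[known, "rare"].mean()) if known.any() else float("nan")
    return df


GENOTYPE_LABELS = {0: "Ref/Ref", 1: "Ref/Alt", 2: "Alt/Alt"}


def genotype_heatmap(
    gmatrix: GenotypeMatrix, variants: Iterable[Variant], gene: str
) -> tuple[pd.DataFrame, pd.Series]:
    """Categorical variants x individuals genotype matrix for one gene,
    plus the per-individual carried-variant count."""
    vids = [v.vid for v in variants if v.gene == gene]
    if not vids:
        raise ValueError(f"no variants for gene {gene!r}")
    sub = gmatrix.dosage[vids]
    labels = sub.T.map(lambda d: GENOTYPE_LABELS.get(int(d), "missing") if pd.notna(d) else "missing")
    counts = (sub >= 1).sum(axis=1).astype(int)
    counts.name = "carried_variants"
    return labels, counts


def benjamini_hochberg(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    """Optional multiple-testing adjustment over a set of comparisons."""
    from statsmodels.stats.multitest import multipletests

    ps = [c.p_value for c in comparisons]
    rejected, adjusted, *_ = multipletests(ps, method="fdr_bh")
    return pd.DataFrame(
        {
            "test": [c.test for c in comparisons],
            "target": [c.target for c in comparisons],
            "p_value": ps,
            "p_adjusted": adjusted,
            "rejected_at_0.05": rejected,
        }
    )


def comparisons_frame(comparisons: Iterable[GroupComparison]) -> pd.DataFrame:
    """Flatten comparisons for TSV export."""
    rows = []
    for c in comparisons:
        rows.append(
            {
                "test": c.test,
                "target": c.target,
                "groups": ";".join(f"{k}={v}" for k, v in c.groups.items()),
                "means": ";".join(f"{k}={v:.4f}" for k, v in c.means.items()),
                "statistic": c.statistic,
                "df": c.df,
                "p_value": c.p_value,
                "effect": c.effect,
                "note": c.note,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["test", "target", "groups", "means", "statistic", "df", "p_value", "effect", "note"],
    )
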