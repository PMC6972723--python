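"""Burden profiles, group tests and genotype-endophenotype association."""

import math
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crl4score.cohort_stats import (
    OVERALL,
    anova_burden,
    benjamini_hochberg,
    compare_burden,
    compare_location_distribution,
    genotype_heatmap,
    genotype_phenotype_test,
    individual_burden,
    rarity_flags,
)
from crl4score.data_io import GenotypeMatrix, LocationDistribution, Variant


def _gm(data, individuals, vids):
    return GenotypeMatrix(pd.DataFrame(data, index=individuals, columns=vids, dtype=float))


# --- closed-form oracles ---------------------------------------------------

def pearson_chi2(table):
    table = np.asarray(table, dtype=float)
    exp = np.outer(table.sum(1), table.sum(0)) / table.sum()
    return float(((table - exp) ** 2 / exp).sum())


def fisher_exact_p(table):
    """Two-sided Fisher p by exhaustive enumeration over fixed margins
    (summing all tables with point probability <= the observed one)."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    return sum(prob(x) for x in range(max(0, c1 - r2), min(r1, c1) + 1)
               if prob(x) <= p_obs * (1 + 1e-12))


class TestIndividualBurden:
    GENES = {"v1": "CRBN", "v2": "CRBN", "v3": "DDB1"}
    SCORES = {"v1": 5, "v2": 10, "v3": 20}

    def test_all_reference_genotypes(self):
        gm = _gm([[0, 0, 0]], ["i1"], ["v1", "v2", "v3"])
        b = individual_burden(gm, self.SCORES, self.GENES)
        row = b[(b.individual == "i1") & (b.gene == OVERALL)].iloc[0]
        assert row.variant_count == 0 and row.score_sum == 0

    def test_carrier_weighting_hand_sum(self):
        gm = _gm([[1, 2, 0]], ["i1"], ["v1", "v2", "v3"])
        b = individual_burden(gm, self.SCORES, self.GENES, weighting="carrier")
        row = b[(b.individual == "i1") & (b.gene == OVERALL)].iloc[0]
        assert row.variant_count == 2 and row.score_sum == 15

    def test_dosage_weighting_hand_sum(self):
        gm = _gm([[1, 2, 0]], ["i1"], ["v1", "v2", "v3"])
        b = individual_burden(gm, self.SCORES, self.GENES, weighting="dosage")
        row = b[(b.individual == "i1") & (b.gene == OVERALL)].iloc[0]
        assert row.variant_count == 3 and row.score_sum == 25

    def test_missing_genotype_excluded(self):
        gm = _gm([[1, np.nan, 1]], ["i1"], ["v1", "v2", "v3"])
        b = individual_burden(gm, self.SCORES, self.GENES)
        row = b[(b.individual == "i1") & (b.gene == OVERALL)].iloc[0]
        assert row.variant_count == 2 and row.score_sum == 25

    def test_overall_equals_sum_of_genes(self, dataset):
        scores = dataset.scores["total"].to_dict()
        genes = {v.vid: v.gene for v in dataset.variants}
        b = individual_burden(dataset.gmatrix, scores, genes)
        per_gene = b[b.gene != OVERALL].groupby("individual")[["variant_count", "score_sum"]].sum()
        overall = b[b.gene == OVERALL].set_index("individual")[["variant_count", "score_sum"]]
        pd.testing.assert_frame_equal(per_gene.sort_index(), overall.sort_index())


def _profiles(values_by_group):
    rows = []
    ids = {}
    for gname, values in values_by_group.items():
        ids[gname] = []
        for i, v in enumerate(values):
            ind = f"{gname}{i}"
            ids[gname].append(ind)
            rows.append((ind, OVERALL, v, v))
    return pd.DataFrame(rows, columns=["individual", "gene", "variant_count", "score_sum"]), ids


class TestCompareBurden:
    def test_identical_groups_t_zero_p_one(self):
        profiles, ids = _profiles({"a": [1, 2, 3], "b": [1, 2, 3]})
        r = compare_burden(profiles, ids, by="score")
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_pooled_t_matches_closed_form(self):
        profiles, ids = _profiles({"a": [1, 2, 3], "b": [4, 5, 6]})
        r = compare_burden(profiles, ids, by="score")
        # pooled variance = 1, se = sqrt(1*(1/3+1/3)), t = -3/se
        t_expected = -3.0 / math.sqrt(2.0 / 3.0)
        p_expected = 2 * stats.t.sf(abs(t_expected), df=4)
        assert r.statistic == pytest.approx(t_expected, rel=1e-12)
        assert r.p_value == pytest.approx(p_expected, rel=1e-12)
        assert r.df == 4
        assert r.effect == pytest.approx(-3.0)

    def test_zero_variance_equal_means_degenerate(self):
        profiles, ids = _profiles({"a": [2, 2, 2], "b": [2, 2]})
        r = compare_burden(profiles, ids)
        assert (r.statistic, r.p_value) == (0.0, 1.0)

    def test_requires_two_groups_of_two(self):
        profiles, ids = _profiles({"a": [1], "b": [2, 3]})
        with pytest.raises(ValueError, match="n >= 2"):
            compare_burden(profiles, ids)


class TestAnova:
    def test_three_identical_groups(self):
        profiles, ids = _profiles({"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]})
        r = anova_burden(profiles, ids)
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_textbook_three_by_three(self):
        groups = {"a": [1, 2, 3], "b": [2, 3, 4], "c": [5, 6, 7]}
        profiles, ids = _profiles(groups)
        r = anova_burden(profiles, ids)
        # hand computation: grand mean 33/9; SSB = 3*[(2-m)^2+(3-m)^2+(6-m)^2], SSW = 6
        m = 33 / 9
        ssb = 3 * ((2 - m) ** 2 + (3 - m) ** 2 + (6 - m) ** 2)
        f_expected = (ssb / 2) / (6 / 6)
        assert r.statistic == pytest.approx(f_expected, rel=1e-12)
        assert r.df == 2

    def test_highest_group_mean_identified(self, default_config, rng):
        from crl4score.synthetic_cohort import simulate_burden_replicate

        totals, dosage, pheno = simulate_burden_replicate(default_config, rng)
        ssum = (dosage > 0) @ totals
        labels = pheno["endophenotype"].to_numpy()
        means = {
            g: ssum[labels == g].mean()
            for g in ("pre_axial_longitudinal", "intercalary_transverse")
        }
        means["reference"] = ssum[pheno["cohort"].to_numpy() == "reference"].mean()
        assert max(means, key=means.get) == default_config.effect_subgroup


class TestLocationComparison:
    def test_identical_distributions(self):
        a = LocationDistribution("a", {"coding": 10, "utr5": 5, "utr3": 30, "intronic_flank": 20})
        b = LocationDistribution("b", {"coding": 10, "utr5": 5, "utr3": 30, "intronic_flank": 20})
        r = compare_location_distribution(a, b)
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_two_by_two_closed_form(self):
        a = LocationDistribution("a", {"coding": 10, "utr3": 90})
        b = LocationDistribution("b", {"coding": 50, "utr3": 50})
        r = compare_location_distribution(a, b)
        assert r.statistic == pytest.approx(pearson_chi2([[10, 90], [50, 50]]), rel=1e-12)

    def test_k4_matches_pearson_formula(self):
        a = LocationDistribution("a", {"coding": 11, "utr5": 17, "utr3": 74, "intronic_flank": 43})
        b = LocationDistribution("b", {"coding": 40, "utr5": 25, "utr3": 60, "intronic_flank": 30})
        r = compare_location_distribution(a, b)
        table = [[11, 17, 74, 43], [40, 25, 60, 30]]
        assert r.statistic == pytest.approx(pearson_chi2(table), rel=1e-12)
        assert r.df == 3


class TestGenotypePhenotype:
    def _matrix(self, dosages_by_group):
        ids, rows = [], []
        for gname, dosages in dosages_by_group.items():
            for i, d in enumerate(dosages):
                ids.append(f"{gname}{i}")
                rows.append([d])
        return _gm(rows, ids, ["v1"]), {
            g: [f"{g}{i}" for i in range(len(ds))] for g, ds in dosages_by_group.items()
        }

    def test_printed_carrier_table_matches_oracles(self):
        """Carriers 6/10 in one endophenotype group vs 1/14 in the other."""
        gm, groups = self._matrix(
            {"pre": [1, 1, 2, 2, 2, 2, 0, 0, 0, 0], "inter": [1] + [0] * 13}
        )
        results = genotype_phenotype_test("v1", gm, groups, mode="carrier")
        chisq = next(r for r in results if r.test == "chisq")
        fisher = next(r for r in results if r.test == "fisher")
        table = [[6, 4], [1, 13]]
        assert chisq.statistic == pytest.approx(pearson_chi2(table), abs=1e-10)
        assert chisq.statistic == pytest.approx(7.888, abs=5e-3)
        assert fisher.p_value == pytest.approx(fisher_exact_p(table), abs=1e-10)

    def test_balanced_table_is_null(self):
        gm, groups = self._matrix({"a": [1] * 5 + [0] * 5, "b": [1] * 5 + [0] * 5})
        results = genotype_phenotype_test("v1", gm, groups, mode="carrier")
        chisq = next(r for r in results if r.test == "chisq")
        assert chisq.statistic == pytest.approx(0.0)
        assert chisq.p_value == pytest.approx(1.0)

    def test_monomorphic_variant_skipped(self):
        gm, groups = self._matrix({"a": [1, 1, 1], "b": [2, 1, 1]})
        assert genotype_phenotype_test("v1", gm, groups, mode="carrier") == []

    def test_genotype_mode_builds_2x3(self):
        gm, groups = self._matrix({"a": [0, 1, 2, 1], "b": [0, 0, 1, 2]})
        results = genotype_phenotype_test("v1", gm, groups, mode="genotype")
        assert len(results) == 1  # chi-square only for the 2x3 table
        assert results[0].df == 2

    @pytest.mark.parametrize("seed", range(6))
    def test_fisher_matches_enumeration_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.integers(1, 10, size=2)
        ca = rng.integers(0, a + 1)
        cb = rng.integers(0, b + 1)
        dosages = {"x": [1] * ca + [0] * (a - ca), "y": [1] * cb + [0] * (b - cb)}
        gm, groups = self._matrix(dosages)
        results = genotype_phenotype_test("v1", gm, groups, mode="carrier")
        if not results:
            return
        fisher = next(r for r in results if r.test == "fisher")
        table = [[ca, a - ca], [cb, b - cb]]
        assert fisher.p_value == pytest.approx(fisher_exact_p(table), abs=1e-10)


class TestRarity:
    def test_threshold_is_strict(self):
        df = rarity_flags({"a": 0.009, "b": 0.01, "c": 0.5})
        flags = df.set_index("vid")["rare"]
        assert flags["a"] is True or flags["a"] == True  # noqa: E712
        assert not flags["b"]  # boundary: MAF = 0.01 is not rare
        assert not flags["c"]

    def test_frequency_folding_and_missing(self):
        df = rarity_flags({"a": 0.995, "b": float("nan")})
        assert df.set_index("vid").loc["a", "rare"]  # folded MAF 0.005
        assert df.set_index("vid").loc["b", "rare"] is None

    def test_synthetic_rare_fraction(self, dataset):
        df = rarity_flags(dataset.mafs)
        assert int(df["rare"].sum()) == dataset.config.n_rare
        from crl4score.data_io import truncate1

        assert truncate1(100 * df.attrs["rare_fraction"]) == 29.6  # 43/145


class TestGenotypeHeatmap:
    def test_dosage_to_label_mapping(self):
        variants = [Variant("c", 1, "A", "G", vid="v1", gene="G")]
        gm = _gm([[0], [1], [2]], ["i1", "i2", "i3"], ["v1"])
        labels, counts = genotype_heatmap(gm, variants, "G")
        assert labels["i1"]["v1"] == "Ref/Ref"
        assert labels["i2"]["v1"] == "Ref/Alt"
        assert labels["i3"]["v1"] == "Alt/Alt"
        assert counts.tolist() == [0, 1, 1]

    def test_counts_equal_carrier_row_sums(self, dataset):
        gene = dataset.variants[0].gene
        labels, counts = genotype_heatmap(dataset.gmatrix, dataset.variants, gene)
        vids = [v.vid for v in dataset.variants if v.gene == gene]
        expected = (dataset.gmatrix.dosage[vids] >= 1).sum(axis=1)
        assert (counts == expected).all()

    def test_tsv_output_byte_stable(self, tmp_path, dataset):
        gene = dataset.variants[0].gene
        out = []
        for i in range(2):
            labels, _ = genotype_heatmap(dataset.gmatrix, dataset.variants, gene)
            p = tmp_path / f"hm{i}.tsv"
            labels.to_csv(p, sep="\t")
            out.append(p.read_bytes())
        assert out[0] == out[1]


def test_benjamini_hochberg_adjustment():
    profiles, ids = _profiles({"a": [1, 2, 3], "b": [4, 5, 6]})
    comps = [compare_burden(profiles, ids, by=by) for by in ("count", "score")]
    adj = benjamini_hochberg(comps)
    assert (adj["p_adjusted"] >= adj["p_value"] - 1e-15).all()
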