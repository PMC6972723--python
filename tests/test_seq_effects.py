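"""CpG islands, codon usage, motif disruption and bisulfite round-trips."""

import math

import numpy as np
import pytest

from crl4score.seq_effects import (
    CodonUsageTable,
    bisulfite_convert,
    call_methylation,
    codon_usage_table,
    cpg_island_delta,
    cpg_sites,
    find_cpg_islands,
    pwm_motif_break,
    read_jaspar,
    synonymous_codon_shift,
)
from crl4score.seq_effects.codon_usage import default_genome_table
from crl4score.seq_effects.motifs import PWM


# --- independent brute-force island oracle -------------------------------

def brute_force_islands(seq, min_length=200, gc_min=0.5, oe_min=0.6):
    """O(n*w) literal re-statement of the criteria: mark every qualifying
    window, take the union, return (start, end) runs."""
    n, w = len(seq), min_length
    covered = [False] * n
    s = seq.upper()
    for i in range(n - w + 1):
        win = s[i : i + w]
        if set(win) - set("ACGT"):
            continue
        c, g = win.count("C"), win.count("G")
        if (c + g) / w < gc_min or c == 0 or g == 0:
            continue
        if win.count("CG") / (c * g / w) < oe_min:
            continue
        for j in range(i, i + w):
            covered[j] = True
    runs, start = [], None
    for j, flag in enumerate(covered):
        if flag and start is None:
            start = j
        elif not flag and start is not None:
            runs.append((start, j))
            start = None
    if start is not None:
        runs.append((start, n))
    return runs


class TestCpGIslands:
    def test_at_desert_has_no_islands(self):
        assert find_cpg_islands("AT" * 500) == []

    def test_cg_repeat_is_one_saturated_island(self):
        seq = "CG" * 150
        islands = find_cpg_islands(seq)
        assert len(islands) == 1
        isl = islands[0]
        assert (isl.start, isl.end) == (0, 300)
        assert isl.gc_fraction == 1.0
        assert math.isclose(isl.obs_exp, 2.0)  # 150 CpG vs 150*150/300 expected

    def test_too_short_sequence(self):
        assert find_cpg_islands("CG" * 50) == []

    def test_n_breaks_islands(self):
        seq = "CG" * 100 + "N" + "CG" * 100
        islands = find_cpg_islands(seq)
        assert all(i.end <= 200 or i.start >= 201 for i in islands)

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_brute_force_on_gc_rich_sequences(self, trial):
        rng = np.random.default_rng(1000 + trial)
        seq = "".join(rng.choice(list("ACGT"), size=2000, p=[0.22, 0.28, 0.28, 0.22]))
        found = [(i.start, i.end) for i in find_cpg_islands(seq)]
        assert found == brute_force_islands(seq)


def _borderline_segment():
    """200-bp window with exactly c=g=50, 8 CpGs: obs/exp = 0.64, GC = 0.50."""
    seg = "CG" * 8 + "C" * 42 + "T" + "G" * 42 + "AT" * 49 + "A"
    assert len(seg) == 200
    return seg


class TestCpGIslandDelta:
    def test_substitution_in_desert_is_none(self):
        seq = "AT" * 500
        verdict, delta = cpg_island_delta(seq, pos=501, ref="A", alt="G")
        assert (verdict, delta) == ("none", 0)

    def test_borderline_island_disrupted_by_single_substitution(self):
        seg = _borderline_segment()
        seq = "TA" * 200 + seg + "TA" * 200
        assert find_cpg_islands(seq)  # qualifies before the edit
        pos = 400 + 1  # first C of the segment (1-based)
        verdict, delta = cpg_island_delta(seq, pos=pos, ref="C", alt="A")
        assert verdict == "disrupted"
        assert delta < 0

    def test_island_created_by_single_substitution(self):
        seg = _borderline_segment()
        broken = "A" + seg[1:]
        seq = "TA" * 200 + broken + "TA" * 200
        assert find_cpg_islands(seq) == []
        verdict, delta = cpg_island_delta(seq, pos=401, ref="A", alt="C")
        assert verdict == "created"
        assert delta > 0

    def test_consistent_with_detector_when_island_sets_equal(self):
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGT"), size=1200, p=[0.35, 0.15, 0.15, 0.35]))
        for pos in (100, 600, 1100):
            ref = seq[pos - 1]
            alt = "A" if ref != "A" else "T"
            before = find_cpg_islands(seq)
            edited = seq[: pos - 1] + alt + seq[pos:]
            if find_cpg_islands(edited) == before:
                verdict, _ = cpg_island_delta(seq, pos=pos, ref=ref, alt=alt)
                assert verdict == "none"

    def test_ref_mismatch_raises(self):
        with pytest.raises(ValueError, match="REF mismatch"):
            cpg_island_delta("ACGT" * 100, pos=1, ref="G", alt="T")


class TestCodonUsage:
    def test_hand_counted_glycine_family(self):
        table = codon_usage_table(["ATGGGAGGAGGGTAA"])
        assert table.counts == {"ATG": 1, "GGA": 2, "GGG": 1}
        assert math.isclose(table.frequencies["GGA"], 2 / 3)
        assert math.isclose(table.frequencies["GGG"], 1 / 3)
        assert table.frequencies["GGT"] == 0.0

    def test_single_codon_family_has_frequency_one(self):
        table = codon_usage_table(["ATGGGATAA"])
        assert table.frequencies["ATG"] == 1.0  # Met family is just ATG

    def test_empty_cds_set_is_an_error(self):
        with pytest.raises(ValueError, match="no CDS"):
            codon_usage_table([])

    def test_internal_stop_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="internal stop"):
            table = codon_usage_table(["ATGTGAGGATAA"])
        assert "TGA" not in table.counts

    def test_concatenation_equals_count_sum(self, rng):
        from crl4score.synthetic_cohort import _random_cds

        a = _random_cds(60, rng)
        b = _random_cds(90, rng)
        combined = codon_usage_table([a, b]).counts
        ca = codon_usage_table([a]).counts
        cb = codon_usage_table([b]).counts
        assert combined == {c: ca.get(c, 0) + cb.get(c, 0) for c in set(ca) | set(cb)}

    def test_family_frequencies_sum_to_one(self):
        table = default_genome_table()
        from crl4score.seq_effects.codon_usage import FAMILIES

        for family in FAMILIES.values():
            assert math.isclose(sum(table.frequencies[c] for c in family), 1.0)


class TestSynonymousShift:
    def test_alt_is_top_codon_in_both_scopes(self):
        gene = CodonUsageTable({"GGA": 1, "GGC": 9}, scope="gene")
        genome = CodonUsageTable({"GGA": 10, "GGC": 90}, scope="genome")
        verdicts = synonymous_codon_shift("GGA", "GGC", {"gene": gene, "genome": genome})
        assert verdicts == {"gene": "to_most_frequent", "genome": "to_most_frequent"}

    def test_scope_dependent_verdict(self):
        # alt preferred within the gene but rarer genome-wide
        gene = CodonUsageTable({"GCA": 2, "GCC": 8}, scope="gene")
        genome = CodonUsageTable({"GCA": 80, "GCC": 20}, scope="genome")
        verdicts = synonymous_codon_shift("GCA", "GCC", {"gene": gene, "genome": genome})
        assert verdicts == {"gene": "to_most_frequent", "genome": "to_less_frequent"}

    def test_manual_rank_comparison(self):
        table = CodonUsageTable({"CTA": 5, "CTC": 10, "CTG": 50, "CTT": 10}, scope="gene")
        assert synonymous_codon_shift("CTG", "CTA", {"g": table}) == {"g": "to_less_frequent"}
        assert synonymous_codon_shift("CTC", "CTT", {"g": table}) == {"g": "unchanged_rank"}

    def test_non_synonymous_rejected(self):
        with pytest.raises(ValueError, match="not synonymous"):
            synonymous_codon_shift("GGA", "GAA", {"g": default_genome_table()})


class TestMotifBreak:
    def test_hand_computed_log_odds(self, tmp_path):
        path = tmp_path / "toy.jaspar"
        path.write_text(
            ">T0001 toy\n"
            "A [ 6 0 0 0 ]\n"
            "C [ 0 6 0 0 ]\n"
            "G [ 2 2 8 0 ]\n"
            "T [ 0 0 0 8 ]\n"
        )
        pwm = read_jaspar(path, pseudocount=1.0)
        # column sums 8; with pseudocount 1: p = (count+1)/12
        # window "ACGT": log2(7/12/.25)+log2(7/12/.25)+log2(9/12/.25)+log2(9/12/.25)
        expected = 2 * math.log2((7 / 12) / 0.25) + 2 * math.log2((9 / 12) / 0.25)
        assert math.isclose(pwm.score_window("ACGT"), expected, rel_tol=1e-12)

    def test_palindromic_motif_strand_symmetric(self):
        counts = np.array([[10, 0, 0, 0], [0, 0, 0, 10], [10, 0, 0, 0], [0, 0, 0, 10]])
        pwm = PWM.from_counts("pal", counts)  # consensus ATAT, revcomp ATAT
        seq = "GGGGATATGGGG"
        res = pwm_motif_break(seq, pos=5, ref="A", alt="C", pwm=pwm)
        # same window range the scanner uses for a variant at 0-based 4
        fwd = max(pwm.score_window(seq[i : i + 4]) for i in range(1, 5))
        assert math.isclose(res.ref_score, fwd)

    def test_variant_far_from_scoring_window_unchanged(self):
        counts = np.full((4, 4), 5)
        pwm = PWM.from_counts("flat", counts)  # uninformative motif: all scores equal
        seq = "ACGTACGTACGT"
        res = pwm_motif_break(seq, pos=6, ref="C", alt="A", pwm=pwm, score_threshold=100.0)
        assert res.verdict == "unchanged"
        assert res.delta == 0.0

    def test_core_substitution_breaks_site(self):
        counts = np.zeros((6, 4))
        for i, base in enumerate("GGGAAT"):
            counts[i, "ACGT".index(base)] = 20
        pwm = PWM.from_counts("ik", counts)
        seq = "TTTTTGGGAATTTTTT"
        res = pwm_motif_break(seq, pos=8, ref="G", alt="C", pwm=pwm)
        assert res.verdict == "broken"
        assert res.delta < 0

    def test_invalid_pwm_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            PWM(name="bad", probs=np.array([[0.5, 0.5, 0.1, 0.1]]))


class TestBisulfite:
    def test_fully_unmethylated_reads_all_t(self):
        seq = "ACGTCCGA"
        converted = bisulfite_convert(seq, methylated=[])
        assert "C" not in converted
        call = call_methylation(seq, converted)
        assert all(s == "unmethylated" for s in call.status.values())

    def test_fully_methylated_cpgs_retained(self):
        seq = "ACGTCGCA"
        sites = cpg_sites(seq)
        converted = bisulfite_convert(seq, methylated=sites)
        call = call_methylation(seq, converted)
        assert call.methylated == sites
        # the non-CpG C still converts
        assert converted[6] == "T"

    def test_roundtrip_recovers_states_on_random_fixtures(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGT"), size=300))
            sites = cpg_sites(seq)
            methylated = [p for p in sites if rng.random() < 0.5]
            call = call_methylation(seq, bisulfite_convert(seq, methylated))
            assert call.methylated == methylated
            assert set(call.status.values()) <= {"methylated", "unmethylated"}

    def test_state_on_non_cpg_position_rejected(self):
        with pytest.raises(ValueError, match="non-CpG"):
            bisulfite_convert("ACGTCA", methylated=[4])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length mismatch"):
            call_methylation("ACGT", "ACG")

    def test_mutated_base_is_uninformative(self):
        seq = "ACGA"
        call = call_methylation(seq, "AGGA")  # C read as G
        assert call.status[1] == "uninformative"
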