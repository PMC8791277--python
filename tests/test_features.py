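"""Pol II matching, read-through, inverted SINEs, editing filter, IR test."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from proxiscape.features import (
    apply_ir_cutoffs,
    cpmk,
    filter_edit_events,
    find_inverted_sine_pairs,
    has_inverted_pair,
    ir_incidence_test,
    match_unlabeled_by_median,
    readthrough_ratio,
    summarize_repeat_editing,
)
from proxiscape.types import CoverageTrack, EditEvent, GeneRecord, RepeatInterval


class TestCpmk:
    def test_worked_example(self):
        assert cpmk(100, 2000, 1_000_000) == pytest.approx(50.0)

    def test_zero_counts(self):
        assert cpmk(0, 500, 10_000) == 0.0

    def test_linearity_in_library_size(self):
        assert cpmk(100, 2000, 2_000_000) == pytest.approx(cpmk(100, 2000, 1_000_000) / 2)

    @pytest.mark.parametrize("length, total", [(0, 100), (100, 0)])
    def test_degenerate_inputs_error(self, length, total):
        with pytest.raises(ValueError):
            cpmk(10, length, total)


class TestMedianMatching:
    def test_brute_force_example(self):
        """labeled median 5; prefix medians of sorted {10,9,7,5,3,2,1} are
        10, 9.5, 9, 8, 7, 6, 5 — only k=7 hits tol 0, returning all seven."""
        subset = match_unlabeled_by_median([4, 5, 6], [10, 9, 7, 5, 3, 2, 1], tol=0)
        assert sorted(subset.tolist()) == [1, 2, 3, 5, 7, 9, 10]

    def test_full_set_returned_when_already_matched(self):
        subset = match_unlabeled_by_median([5], [4, 5, 6], tol=0)
        assert sorted(subset.tolist()) == [4, 5, 6]

    def test_empty_labeled_errors(self):
        with pytest.raises(ValueError):
            match_unlabeled_by_median([], [1, 2], tol=1)

    def test_unreachable_tolerance_reports_best(self):
        with pytest.raises(ValueError, match="best achievable"):
            match_unlabeled_by_median([100], [1, 2, 3], tol=0.5)

    @given(st.data())
    @settings(max_examples=200, derandomize=True)
    def test_returned_subset_always_within_tol(self, data):
        lab = data.draw(st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=15))
        unlab = data.draw(st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=30))
        tol = data.draw(st.floats(0, 50, allow_nan=False))
        try:
            subset = match_unlabeled_by_median(lab, unlab, tol)
        except ValueError:
            return
        assert abs(np.median(subset) - np.median(lab)) <= tol
        # the subset is a top-k prefix of the sorted controls
        assert sorted(subset.tolist()) == sorted(unlab, reverse=True)[: subset.size][::-1]


def make_track(body, down, gene, pad=10_000):
    lo = max(gene.start - pad, 0)
    hi = gene.end + pad
    values = np.zeros(hi - lo)
    values[gene.start - lo : gene.end - lo] = body
    if gene.strand == "+":
        values[gene.end - lo :] = down
    else:
        values[: gene.start - lo] = down
    return CoverageTrack(chrom=gene.chrom, strand=gene.strand, start=lo, values=values)


class TestReadthrough:
    def test_plus_strand_ratio(self):
        gene = GeneRecord("g", "chrA", 50_000, 52_000, "+")
        assert readthrough_ratio(make_track(10, 5, gene), gene) == pytest.approx(0.5)

    def test_minus_strand_window_is_upstream_in_genomic_coordinates(self):
        gene = GeneRecord("g", "chrA", 50_000, 52_000, "-")
        track = make_track(10, 5, gene)  # coverage placed before gene start
        assert readthrough_ratio(track, gene) == pytest.approx(0.5)
        # the same coverage pattern on a + gene reads the empty downstream side
        plus = GeneRecord("g", "chrA", 50_000, 52_000, "+")
        assert readthrough_ratio(track, plus) == 0.0

    def test_zero_downstream_coverage(self):
        gene = GeneRecord("g", "chrA", 50_000, 52_000, "+")
        assert readthrough_ratio(make_track(10, 0, gene), gene) == 0.0

    def test_zero_body_coverage_flagged_nan(self):
        gene = GeneRecord("g", "chrA", 50_000, 52_000, "+")
        assert np.isnan(readthrough_ratio(make_track(0, 5, gene), gene))

    def test_rpm_scale_invariance(self):
        gene = GeneRecord("g", "chrA", 50_000, 52_000, "+")
        r1 = readthrough_ratio(make_track(10, 4, gene), gene)
        r2 = readthrough_ratio(make_track(10 * 7.3, 4 * 7.3, gene), gene)
        assert r1 == pytest.approx(r2)


class TestInvertedSines:
    REGION = ("chrA", 0, 1000)

    def test_opposite_strand_same_family_pairs(self):
        reps = [
            RepeatInterval("chrA", 100, 400, "+", "Alu"),
            RepeatInterval("chrA", 600, 900, "-", "Alu"),
        ]
        assert len(find_inverted_sine_pairs(reps, self.REGION)) == 1

    def test_same_strand_no_pair(self):
        reps = [
            RepeatInterval("chrA", 100, 400, "+", "Alu"),
            RepeatInterval("chrA", 600, 900, "+", "Alu"),
        ]
        assert find_inverted_sine_pairs(reps, self.REGION) == []

    def test_family_gate(self):
        reps = [
            RepeatInterval("chrA", 100, 400, "+", "Alu"),
            RepeatInterval("chrA", 600, 900, "-", "MIR"),
        ]
        assert find_inverted_sine_pairs(reps, self.REGION) == []
        assert len(find_inverted_sine_pairs(reps, self.REGION, same_family=False)) == 1

    def test_max_gap_bound(self):
        reps = [
            RepeatInterval("chrA", 100, 400, "+", "Alu"),
            RepeatInterval("chrA", 600, 900, "-", "Alu"),
        ]
        assert find_inverted_sine_pairs(reps, self.REGION, max_gap=100) == []
        assert len(find_inverted_sine_pairs(reps, self.REGION, max_gap=200)) == 1

    def test_repeat_outside_region_excluded(self):
        reps = [
            RepeatInterval("chrA", 100, 400, "+", "Alu"),
            RepeatInterval("chrA", 950, 1250, "-", "Alu"),  # extends past the region
        ]
        assert find_inverted_sine_pairs(reps, self.REGION) == []

    def test_count_invariant_to_input_order_and_monotone_in_region(self):
        rng = np.random.default_rng(12)
        reps = [
            RepeatInterval("chrA", int(s), int(s) + 300, strand, family)
            for s, strand, family in zip(
                rng.integers(0, 5000, 12),
                rng.choice(["+", "-"], 12),
                rng.choice(["Alu", "MIR"], 12),
            )
        ]
        region_small, region_big = ("chrA", 0, 3000), ("chrA", 0, 6000)
        n = len(find_inverted_sine_pairs(reps, region_small))
        n_rev = len(find_inverted_sine_pairs(reps[::-1], region_small))
        assert n == n_rev
        assert len(find_inverted_sine_pairs(reps, region_big)) >= n
        if has_inverted_pair(reps, region_small):
            assert has_inverted_pair(reps, region_big)


class TestEditFilter:
    @pytest.mark.parametrize(
        "ref, alt, strand, at_snp, kept",
        [
            ("A", "G", "+", False, True),
            ("T", "C", "-", False, True),
            ("A", "G", "+", True, False),  # SNP position filtered regardless of allele
            ("A", "G", "-", False, False),  # wrong strand signature
            ("T", "C", "+", False, False),
            ("C", "T", "+", False, False),
        ],
    )
    def test_strand_and_snp_rules(self, ref, alt, strand, at_snp, kept):
        ev = EditEvent("chrA", 100, ref, alt, 3, 10, strand)
        snps = {("chrA", 100)} if at_snp else set()
        assert (filter_edit_events([ev], snps) == [ev]) is kept


class TestRepeatEditingSummary:
    REP = RepeatInterval("chrA", 0, 1000, "+", "Alu")

    def test_fraction_of_total_coverage(self):
        evs = [
            EditEvent("chrA", 10, "A", "G", 3, 10, "+"),
            EditEvent("chrA", 20, "A", "G", 1, 10, "+"),
        ]
        df = summarize_repeat_editing(evs, [self.REP])
        assert df.edited_fraction.iloc[0] == pytest.approx(0.2)

    def test_no_events_zero(self):
        df = summarize_repeat_editing([], [self.REP])
        assert df.edited_fraction.iloc[0] == 0.0

    def test_saturated_event(self):
        evs = [EditEvent("chrA", 10, "A", "G", 10, 10, "+")]
        df = summarize_repeat_editing(evs, [self.REP])
        assert df.edited_fraction.iloc[0] == 1.0

    def test_all_positions_denominator(self):
        evs = [EditEvent("chrA", 10, "A", "G", 5, 10, "+")]
        cov = {("chrA", 10): 10, ("chrA", 20): 10}
        df = summarize_repeat_editing(evs, [self.REP], all_positions=True, position_coverage=cov)
        assert df.edited_fraction.iloc[0] == pytest.approx(0.25)

    def test_empty_repeats_error(self):
        with pytest.raises(ValueError):
            summarize_repeat_editing([], [])


class TestIrIncidence:
    def test_chi2_worked_example(self):
        table, chi2, p = ir_incidence_test([True] * 30 + [False] * 70, [True] * 10 + [False] * 90)
        assert chi2 == pytest.approx(12.5)
        assert p < 0.001

    def test_equal_incidence_zero_statistic(self):
        table, chi2, p = ir_incidence_test([True] * 20 + [False] * 80, [True] * 20 + [False] * 80)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_small_expected_cells_fall_back_to_exact_test(self):
        table, chi2, p = ir_incidence_test([True, True, False], [False, False, False])
        assert np.isnan(chi2)
        assert 0 < p <= 1

    def test_delta_psi_cutoff_is_strict(self):
        ir = pd.DataFrame(
            {
                "intron_id": ["i1", "i2"],
                "gene_id": ["gA", "gB"],
                "delta_psi": [0.10, 0.101],
                "fdr": [0.01, 0.01],
            }
        )
        flags = apply_ir_cutoffs(ir)
        assert not flags["gA"]  # exactly 10% does not count
        assert flags["gB"]
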