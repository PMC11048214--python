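import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from mitocohort.enrichment_stats import (
    ContingencyTable,
    GroupSummary,
    build_tables,
    chi_square,
    classify_substitution,
    fisher_exact_2x2,
    run_panel,
    t_test_from_summary,
)
from mitocohort.variant_filter import MtVariantCall

from frozen_stats import WES_BLOCKS, WGS_BLOCKS, T_TEST_BLOCKS


def fisher_oracle(table) -> float:
    """Exhaustive enumeration over all margin-fixed 2x2 tables, exact arithmetic."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    def point(k):
        return Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), denom)
    p_obs = point(a)
    total = sum(
        (p for k in range(max(0, c1 - r2), min(r1, c1) + 1) if (p := point(k)) <= p_obs),
        Fraction(0),
    )
    return float(total)


def chi_square_oracle(table):
    """Hand formula: sum (obs-exp)^2/exp with margin-derived expectations."""
    t = np.asarray(table, dtype=float)
    n = t.sum()
    stat = 0.0
    for i in range(t.shape[0]):
        for j in range(t.shape[1]):
            exp = t[i].sum() * t[:, j].sum() / n
            stat += (t[i, j] - exp) ** 2 / exp
    return stat


class TestFisher:
    def test_strong_heteroplasmy_excess(self):
        assert fisher_exact_2x2([[17, 34], [2, 68]]).p < 0.0001

    def test_cr_enrichment_to_4dp(self):
        assert round(fisher_exact_2x2([[74, 247], [54, 270]]).p, 4) == 0.0482

    def test_identical_columns(self):
        assert fisher_exact_2x2([[0, 10], [0, 10]]).p == 1.0

    def test_non_2x2_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, 2, 3], [4, 5, 6]])

    def test_matches_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            t = rng.integers(0, 30, size=(2, 2))
            if t.sum() == 0:
                continue
            assert fisher_exact_2x2(t).p == pytest.approx(
                sps.fisher_exact(t)[1], abs=1e-10
            )

    @given(st.lists(st.integers(0, 15), min_size=4, max_size=4))
    @settings(max_examples=150, deadline=None)
    def test_matches_enumeration_oracle(self, cells):
        table = [cells[:2], cells[2:]]
        if sum(cells) == 0 or sum(cells) > 60:
            return
        assert abs(fisher_exact_2x2(table).p - fisher_oracle(table)) < 1e-9

    def test_symmetry_under_transposition(self):
        t = [[7, 3], [2, 11]]
        assert fisher_exact_2x2(t).p == pytest.approx(
            fisher_exact_2x2(np.array(t).T).p, abs=1e-12
        )


class TestChiSquare:
    def test_wes_substitution_spectrum(self):
        res = chi_square([[21, 34], [6, 13], [4, 10], [20, 12]])
        assert round(res.p, 4) == 0.0527
        assert res.df == 3

    def test_wgs_substitution_spectrum(self):
        assert round(chi_square([[92, 54], [46, 64], [129, 144], [36, 46]]).p, 3) == 0.002

    def test_uniform_table(self):
        res = chi_square([[5, 5], [5, 5]])
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square([[0, 0], [5, 5]])

    def test_small_expected_counts_warn_in_note(self):
        res = chi_square([[1, 2], [3, 1]])
        assert "expected counts" in res.note

    @given(
        st.integers(2, 5), st.integers(2, 4),
        st.integers(0, 1_000_000),
    )
    @settings(max_examples=100, deadline=None)
    def test_statistic_matches_hand_formula(self, r, c, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(1, 40, size=(r, c))
        res = chi_square(t)
        assert res.statistic == pytest.approx(chi_square_oracle(t), rel=1e-12)
        assert res.df == (r - 1) * (c - 1)
        assert res.p == pytest.approx(float(sps.chi2.sf(res.statistic, res.df)), abs=1e-12)


class TestTTest:
    def test_cn_wgs_comparison(self):
        res = t_test_from_summary(GroupSummary(8, 450.3, 71.85), GroupSummary(4, 362.0, 7.20))
        assert round(res.p, 4) == 0.0377
        assert res.df == 10

    def test_burden_wgs_comparison(self):
        res = t_test_from_summary(GroupSummary(8, 40.13, 28.75), GroupSummary(4, 81.0, 70.16))
        assert round(res.p, 2) == 0.17

    def test_identical_summaries(self):
        a = GroupSummary(5, 10.0, 2.0)
        res = t_test_from_summary(a, a)
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_zero_variance_equal_means(self):
        res = t_test_from_summary(GroupSummary(3, 1.0, 0.0), GroupSummary(3, 1.0, 0.0))
        assert res.p == 1.0

    def test_n_below_two_rejected(self):
        with pytest.raises(ValueError):
            GroupSummary(1, 5.0, 1.0)


class TestClassifySubstitution:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [("T", "C", "T>C"), ("G", "A", "G>A"), ("A", "G", "A>G"),
         ("C", "T", "C>T"), ("A", "C", "transversion"), ("g", "t", "transversion")],
    )
    def test_classes(self, ref, alt, expected):
        assert classify_substitution(ref, alt) == expected

    def test_indel_rejected(self):
        with pytest.raises(ValueError):
            classify_substitution("AT", "A")

    def test_identical_rejected(self):
        with pytest.raises(ValueError):
            classify_substitution("A", "A")


def _cohort_for_counts(atlas):
    """Two-sample cohort engineered to reproduce the WES het/hom and
    CR/coding stratifications exactly."""
    cr_positions = [
        p for p in range(16024, 16570) if not atlas.is_homopolymer(p)
    ] + [p for p in range(1, 577) if not atlas.is_homopolymer(p)]
    coding_positions = [p for p in range(3307, 4263)]  # inside MT-ND1

    def build(sample, n_cr, n_coding, n_het):
        calls = []
        positions = cr_positions[:n_cr] + coding_positions[:n_coding]
        for i, pos in enumerate(positions):
            hf = 0.4 if i < n_het else 1.0
            calls.append(
                MtVariantCall(
                    sample_id=sample, position=pos, ref="T", alt="C", hf=hf,
                    depth=100, alt_fwd=int(50 * hf), alt_rev=int(50 * hf),
                )
            )
        return calls

    calls = build("ALS_1", 18, 33, 17) + build("CNTR_1", 17, 53, 2)
    return calls, {"ALS_1": "case", "CNTR_1": "control"}


class TestBuildTables:
    def test_reproduces_wes_marginals(self, atlas):
        calls, design = _cohort_for_counts(atlas)
        tables = build_tables(calls, design, atlas)
        assert tables["type_of_variant"].counts.tolist() == [[17, 2], [34, 68]]
        assert tables["distribution_of_variants"].counts.tolist() == [[18, 17], [33, 53]]
        results = run_panel(tables)
        assert results["type_of_variant"].method == "fisher_exact_2x2"
        assert results["type_of_variant"].p < 0.0001
        assert round(results["distribution_of_variants"].p, 4) == 0.2250

    def test_column_totals_conserved(self, atlas):
        calls, design = _cohort_for_counts(atlas)
        tables = build_tables(calls, design, atlas)
        # every observation lands in exactly one row of these exhaustive tables
        for name in ("type_of_variant", "distribution_of_variants"):
            assert tables[name].column_totals.tolist() == [51, 70]

    def test_single_sample_single_variant(self, atlas):
        calls = [
            MtVariantCall(
                sample_id="S", position=7410, ref="C", alt="T", hf=1.0,
                depth=20, alt_fwd=10, alt_rev=10,
            )
        ]
        tables = build_tables(calls, {"S": "case", "X": "control"}, atlas)
        for table in tables.values():
            assert all(t in (0, 1) for t in table.column_totals.tolist())

    def test_unknown_sample_raises(self, atlas):
        calls, _ = _cohort_for_counts(atlas)
        with pytest.raises(ValueError, match="missing from design"):
            build_tables(calls, {"ALS_1": "case"}, atlas)


class TestRunPanel:
    def test_method_dispatch_by_row_count(self):
        tables = {
            "two": ContingencyTable("two", ["a", "b"], ["x", "y"], [[5, 1], [2, 6]]),
            "four": ContingencyTable(
                "four", list("abcd"), ["x", "y"],
                [[5, 1], [2, 6], [3, 3], [4, 2]],
            ),
        }
        results = run_panel(tables)
        assert results["two"].method == "fisher_exact_2x2"
        assert results["four"].method == "chi_square"

    def test_zero_rows_pruned_before_dispatch(self):
        t = ContingencyTable(
            "domains", list("abcd"), ["x", "y"],
            [[3, 6], [0, 0], [4, 0], [0, 0]],
        )
        results = run_panel({"domains": t})
        assert results["domains"].method == "fisher_exact_2x2"

    def test_untestable_table_skipped(self):
        t = ContingencyTable("empty", ["a", "b"], ["x", "y"], [[0, 0], [0, 0]])
        assert run_panel({"empty": t}) == {}

    def test_het_and_hom_spectra_tested_separately(self):
        tables = {
            name: ContingencyTable(name, list("abcd"), ["x", "y"], counts)
            for name, counts in [
                ("substitution_het", [[8, 8], [21, 33], [105, 121], [5, 4]]),
                ("substitution_hom", [[84, 46], [25, 31], [24, 23], [31, 42]]),
            ]
        }
        results = run_panel(tables)
        assert len(results) == 2
        assert round(results["substitution_het"].p, 3) == 0.675


class TestFrozenBlocks:
    """The full set of frozen summary blocks tests the right method each."""

    @pytest.mark.parametrize(
        "name,block", list(WES_BLOCKS.items()) + list(WGS_BLOCKS.items())
    )
    def test_method_assignment(self, name, block):
        counts, _, method = block
        assert method == ("fisher_exact_2x2" if len(counts) == 2 else "chi_square")
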