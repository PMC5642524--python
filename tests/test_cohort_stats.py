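"""Gene-by-subtype tables, the exact Fisher-Freeman-Halton test, pathway
summaries and exact binomial confidence intervals."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.stats import multivariate_hypergeom

from gastrosubtype import (
    CaseAssay,
    PathwayGeneSets,
    clopper_pearson,
    ffh_exact_test,
    gene_subtype_table,
    mutation_rate_per_subtype,
    pathway_alteration_summary,
    round_half_up,
)
from gastrosubtype.cnv_caller import GeneCNA
from gastrosubtype.cohort_stats import GeneSubtypeTable, chi_square_test
from gastrosubtype.msi_caller import call_msi_status
from gastrosubtype.tables import (
    GENE_SUBTYPE_COUNTS,
    MSI_MARKERS,
    SUBTYPE_SIZES,
    SUBTYPES,
    gene_subtype_count_frame,
)
from gastrosubtype.variant_filtering import VariantCall


def test_round_half_up():
    assert round_half_up(2.25, 1) == 2.3
    assert round_half_up(2.649999, 1) == 2.6
    assert round_half_up(-2.25, 1) == -2.3
    assert round_half_up(17.757, 1) == 17.8


def published_table() -> GeneSubtypeTable:
    frame = gene_subtype_count_frame()
    return GeneSubtypeTable(
        genes=tuple(frame.index),
        subtypes=tuple(SUBTYPES),
        mutated_counts=frame.to_numpy(),
        subtype_sizes=tuple(SUBTYPE_SIZES[s] for s in SUBTYPES),
    )


class TestGeneSubtypeTable:
    def _case(self, cid, genes, n_calls_per_gene=1):
        calls = [
            VariantCall(case_id=cid, chrom="1", pos=100 + i * 10 + k,
                        ref_allele="A", alt_allele="T", gene_symbol=g,
                        total_depth=100, vaf_tumor=0.3)
            for i, g in enumerate(genes)
            for k in range(n_calls_per_gene)
        ]
        return CaseAssay(case_id=cid, somatic_calls=calls)

    def test_case_counts_once_per_gene(self):
        cases = [self._case("A", ["ARID1A"], n_calls_per_gene=3),
                 self._case("B", ["ARID1A", "TP53"])]
        labels = {"A": "MSI", "B": "CIN"}
        table = gene_subtype_table(cases, labels, ["ARID1A", "TP53"])
        assert table.row("ARID1A").tolist() == [0, 1, 1, 0]
        assert table.row("TP53").tolist() == [0, 0, 1, 0]

    def test_unlabeled_case_raises(self):
        with pytest.raises(ValueError, match="unlabeled"):
            gene_subtype_table([self._case("A", ["TP53"])], {}, ["TP53"])

    def test_empty_gene_list(self):
        table = gene_subtype_table(
            [self._case("A", ["TP53"])], {"A": "CIN"}, []
        )
        assert table.mutated_counts.shape == (0, 4)

    def test_mutation_rates_from_published_counts(self):
        rates = mutation_rate_per_subtype(published_table())
        assert rates == {"EBV": 2.6, "MSI": 6.6, "CIN": 1.8, "GS": 1.5}

    def test_zero_size_subtype_rate_is_na(self):
        table = GeneSubtypeTable(
            genes=("TP53",), subtypes=("A", "B"),
            mutated_counts=np.array([[0, 3]]), subtype_sizes=(0, 5),
        )
        rates = mutation_rate_per_subtype(table)
        assert rates["A"] is None and rates["B"] == 0.6


class TestFfhExactTest:
    def test_identical_proportions_give_p_one(self):
        res = ffh_exact_test([[2, 4, 6], [2, 4, 6]])
        assert res.p_value == pytest.approx(1.0)

    def test_two_by_two_hand_enumeration(self):
        # margins (4,4)x(4,4): hypergeometric outcomes 1,16,36,16,1 over 70;
        # observed x=3 -> p = (16+16+1+1)/70
        res = ffh_exact_test([[3, 1], [1, 3]])
        assert res.p_value == pytest.approx(34 / 70, abs=1e-12)
        assert res.method == "ffh_enumeration"

    def test_matches_scipy_hypergeometric_oracle_on_small_tables(self):
        """Agreement with an independent enumeration built on scipy's
        multivariate hypergeometric pmf, over all 2x3 tables with n <= 12."""
        rng = np.random.default_rng(0)
        checked = 0
        for n in range(2, 13):
            for _ in range(3):
                cols = rng.multinomial(n, [1 / 3] * 3)
                if (cols == 0).any():
                    continue
                m1 = int(rng.integers(1, n))
                top = rng.multivariate_hypergeometric(cols, m1)
                table = np.vstack([top, cols - top])
                expected = _ffh_oracle(table)
                got = ffh_exact_test(table).p_value
                assert got == pytest.approx(expected, rel=1e-9), table
                checked += 1
        assert checked >= 20

    def test_column_permutation_invariance(self):
        base = np.array([[0, 5, 26, 10], [7, 14, 20, 25]])
        p0 = ffh_exact_test(base).p_value
        for perm in itertools.permutations(range(4)):
            assert ffh_exact_test(base[:, perm]).p_value == pytest.approx(p0, rel=1e-9)

    def test_negative_cell_raises(self):
        with pytest.raises(ValueError):
            ffh_exact_test([[1, -1], [2, 3]])

    def test_monte_carlo_fallback_close_to_exact(self):
        table = np.array([[4, 9, 20, 8], [3, 10, 26, 27]])
        exact = ffh_exact_test(table).p_value
        mc = ffh_exact_test(table, budget=10)
        assert mc.method == "ffh_montecarlo"
        assert mc.p_value == pytest.approx(exact, abs=0.02)

    def test_chi_square_agrees_in_rank(self):
        """Both tests call the strongly-associated table far more
        significant than the flat one."""
        flat = [[5, 5, 5, 5], [10, 10, 10, 10]]
        skew = [[15, 1, 1, 1], [0, 14, 14, 14]]
        assert ffh_exact_test(skew).p_value < 1e-6 < ffh_exact_test(flat).p_value
        assert chi_square_test(skew).p_value < chi_square_test(flat).p_value

    def test_type_one_error_under_null(self):
        """Empirical size <= 0.06 at alpha = 0.05 over 2,000 simulated 2x4
        tables with a common mutation proportion."""
        rng = np.random.default_rng(314159)
        sizes = np.array([7, 19, 46, 35])
        rejections = 0
        n_reps = 2000
        for _ in range(n_reps):
            top = rng.binomial(sizes, 0.2)
            table = np.vstack([top, sizes - top])
            if ffh_exact_test(table).p_value < 0.05:
                rejections += 1
        assert rejections / n_reps <= 0.06


def _ffh_oracle(table: np.ndarray) -> float:
    """Independent FFH enumeration via scipy's multivariate hypergeometric
    pmf, iterating candidate top rows in lexicographic order."""
    cols = table.sum(axis=0)
    m1 = int(table[0].sum())
    p_obs = multivariate_hypergeom.pmf(table[0], cols, m1)
    total = 0.0
    for top in itertools.product(*(range(c + 1) for c in cols)):
        if sum(top) != m1:
            continue
        p = multivariate_hypergeom.pmf(list(top), cols, m1)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return float(total)


class TestPathwaySummary:
    def _case(self, cid, mutated=(), amplified=()):
        calls = [
            VariantCall(case_id=cid, chrom="1", pos=50 + i, ref_allele="A",
                        alt_allele="T", gene_symbol=g, total_depth=100,
                        vaf_tumor=0.2)
            for i, g in enumerate(mutated)
        ]
        cnas = [GeneCNA(g, "duplication", 4, 0.6) for g in amplified]
        return CaseAssay(case_id=cid, somatic_calls=calls, gene_cnas=cnas)

    def test_combined_fraction_counts_each_case_once(self):
        cases = []
        for i in range(20):
            cases.append(self._case(f"A{i}", mutated=["ERBB2"]))  # RTK only
        for i in range(10):
            cases.append(self._case(f"B{i}", mutated=["KRAS", "EGFR"]))  # both sets
        for i in range(7):
            cases.append(self._case(f"C{i}", amplified=["PIK3CA"]))
        for i in range(70):
            cases.append(self._case(f"D{i}"))
        summary = pathway_alteration_summary(cases)
        assert summary.combined_altered == 37
        assert summary.combined_fraction_pct == 34.6
        assert summary.rtk_altered == 30
        assert summary.ras_pi3k_altered == 17

    def test_erbb2_substitutions_and_amplifications(self):
        cases = [self._case(f"S{i}", mutated=["ERBB2"]) for i in range(8)]
        cases += [self._case(f"A{i}", amplified=["ERBB2"]) for i in range(5)]
        cases += [self._case(f"N{i}") for i in range(94)]
        summary = pathway_alteration_summary(cases)
        assert summary.per_gene_altered["ERBB2"] == 13
        assert summary.exclusivity_violations == {}

    def test_violation_reported_when_both_event_types_present(self):
        case = self._case("X", mutated=["ERBB2"], amplified=["ERBB2"])
        summary = pathway_alteration_summary([case])
        assert summary.exclusivity_violations == {"ERBB2": ["X"]}

    def test_empty_gene_sets(self):
        gs = PathwayGeneSets(rtk=frozenset(), ras_pi3k=frozenset())
        summary = pathway_alteration_summary(
            [self._case("X", mutated=["ERBB2"])], gs
        )
        assert summary.combined_altered == 0


class TestClopperPearson:
    def test_three_of_four(self):
        lo, hi = clopper_pearson(3, 4)
        assert lo == pytest.approx(0.194, abs=5e-4)
        assert hi == pytest.approx(0.994, abs=5e-4)

    def test_boundaries(self):
        assert clopper_pearson(0, 10)[0] == 0.0
        assert clopper_pearson(10, 10)[1] == 1.0

    def test_all_successes_lower_bound(self):
        # exact closed form: lower = (alpha/2)^(1/n) for x = n
        lo, hi = clopper_pearson(39, 39)
        assert lo == pytest.approx(0.025 ** (1 / 39), rel=1e-9)
        assert lo == pytest.approx(0.910, abs=5e-4)

    def test_invalid_counts_raise(self):
        with pytest.raises(ValueError):
            clopper_pearson(5, 4)
        with pytest.raises(ValueError):
            clopper_pearson(0, 0)

    def test_intervals_nest_across_levels(self):
        for n in range(1, 31):
            for x in range(n + 1):
                lo95, hi95 = clopper_pearson(x, n, 0.95)
                lo99, hi99 = clopper_pearson(x, n, 0.99)
                assert lo99 <= lo95 + 1e-12
                assert hi99 >= hi95 - 1e-12
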