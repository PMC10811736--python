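import itertools
import math

import numpy as np
import pandas as pd
import pytest

from aoapan.io_formats import LineageMap
from aoapan.pangenome import (
    PangenomeCurve,
    count_combinations,
    detect_enriched_ogs,
    expected_pan_core_exact,
    filter_genomes_by_completeness,
    fit_heaps,
    openness_new_genes_per_mbp,
    pangenome_curve,
    sample_combinations,
)
from aoapan.synthetic import PangenomeSpec, simulate_presence_matrix

from _oracles import pascal_binomial


def _curve_from_values(ns, pans):
    table = pd.DataFrame(
        {
            "m": ns,
            "pan_mean": pans,
            "pan_sd": 0.0,
            "core_mean": 0.0,
            "core_sd": 0.0,
            "n_combos": 1,
            "exhaustive": True,
        }
    )
    return PangenomeCurve(table=table, n_genomes=len(ns), n_ogs=0, cap=0, seed=0)


class TestCountCombinations:
    @pytest.mark.parametrize(
        "n,m,expected", [(5, 2, 10), (7, 0, 1), (7, 7, 1), (23, 12, 1352078)]
    )
    def test_known_values(self, n, m, expected):
        assert count_combinations(n, m) == expected
        assert count_combinations(n, m) == pascal_binomial(n, m)

    def test_m_exceeding_n_is_error(self):
        with pytest.raises(ValueError):
            count_combinations(3, 4)

    def test_large_n_no_overflow(self):
        assert count_combinations(200, 100) == pascal_binomial(200, 100)


class TestSampleCombinations:
    def test_exhaustive_below_cap(self):
        combos, exhaustive = sample_combinations(4, 2, cap=5000, seed=0)
        assert exhaustive and len(combos) == 6
        assert set(combos) == set(itertools.combinations(range(4), 2))

    def test_cap_binds_with_distinct_sets(self):
        combos, exhaustive = sample_combinations(30, 15, cap=100, seed=1)
        assert not exhaustive
        assert len(combos) == len(set(combos)) == 100
        assert all(len(set(c)) == 15 for c in combos)

    def test_deterministic_under_seed(self):
        a, _ = sample_combinations(30, 15, cap=50, seed=3)
        b, _ = sample_combinations(30, 15, cap=50, seed=3)
        assert a == b

    def test_bad_cap_is_error(self):
        with pytest.raises(ValueError):
            sample_combinations(5, 2, cap=0)


class TestPangenomeCurve:
    def test_worked_matrix_m2(self, worked_matrix):
        c = pangenome_curve(worked_matrix, seed=0).table
        row = c[c["m"] == 2].iloc[0]
        assert row["pan_mean"] == pytest.approx(13 / 3, abs=1e-12)
        assert row["core_mean"] == pytest.approx(7 / 3, abs=1e-12)

    def test_worked_matrix_m1_means_are_row_sums(self, worked_matrix):
        c = pangenome_curve(worked_matrix, seed=0).table
        row = c[c["m"] == 1].iloc[0]
        assert row["pan_mean"] == pytest.approx(10 / 3, abs=1e-12)
        assert row["core_mean"] == pytest.approx(10 / 3, abs=1e-12)

    def test_worked_matrix_full_set(self, worked_matrix):
        c = pangenome_curve(worked_matrix, seed=0).table
        row = c[c["m"] == 3].iloc[0]
        assert (row["pan_mean"], row["core_mean"]) == (5, 2)

    def test_monotone_in_m(self):
        spec = PangenomeSpec(
            n_genomes=10, core_size=5,
            accessory_pool=[(f"a{j}", 0.3) for j in range(20)], unique_rate=2.0, seed=2,
        )
        m = simulate_presence_matrix(spec)
        t = pangenome_curve(m, cap=200, seed=1).table
        assert (np.diff(t["pan_mean"]) >= -1e-12).all()
        assert (np.diff(t["core_mean"]) <= 1e-12).all()

    def test_conservation_at_full_set(self, worked_matrix):
        t = pangenome_curve(worked_matrix, seed=0).table
        final = t.iloc[-1]
        assert final["pan_mean"] == worked_matrix.shape[0]
        assert final["core_mean"] == (worked_matrix.sum(axis=1) == 3).sum()

    def test_sampled_mean_close_to_exact_expectation(self):
        spec = PangenomeSpec(
            n_genomes=14, core_size=10,
            accessory_pool=[(f"a{j}", 0.4) for j in range(30)], seed=8,
        )
        mat = simulate_presence_matrix(spec)
        t = pangenome_curve(mat, cap=500, seed=5).table
        for m in (5, 7, 9):
            row = t[t["m"] == m].iloc[0]
            if row["exhaustive"]:
                continue
            e_pan, _ = expected_pan_core_exact(mat, m)
            sd = row["pan_sd"] / math.sqrt(row["n_combos"])
            assert abs(row["pan_mean"] - float(e_pan)) <= 4 * max(sd, 1e-9)


class TestExactExpectation:
    def test_worked_matrix_m2(self, worked_matrix):
        from fractions import Fraction

        assert expected_pan_core_exact(worked_matrix, 2) == (
            Fraction(13, 3),
            Fraction(7, 3),
        )

    def test_limit_cases(self, worked_matrix):
        e_pan, e_core = expected_pan_core_exact(worked_matrix, 3)
        assert (e_pan, e_core) == (5, 2)
        from fractions import Fraction

        e_pan1, e_core1 = expected_pan_core_exact(worked_matrix, 1)
        assert e_pan1 == e_core1 == Fraction(int(worked_matrix.sum().sum()), 3)

    def test_m_out_of_range(self, worked_matrix):
        with pytest.raises(ValueError):
            expected_pan_core_exact(worked_matrix, 4)


class TestFitHeaps:
    def test_noiseless_pan_power_law(self):
        ns = np.arange(1, 11)
        fit = fit_heaps(_curve_from_values(ns, 10 * ns**0.5))
        assert fit.gamma == pytest.approx(0.5, abs=1e-9)
        assert fit.kappa_pan == pytest.approx(10, abs=1e-9)

    def test_noiseless_new_gene_decay(self):
        ns = np.arange(1, 12)
        pans = np.concatenate([[50.0], 50 + np.cumsum(50 * ns[1:] ** -0.8)])
        fit = fit_heaps(_curve_from_values(ns, pans))
        assert fit.alpha == pytest.approx(0.8, abs=1e-9)
        assert fit.kappa_new == pytest.approx(50, abs=1e-9)
        assert fit.open_flag

    def test_nonpositive_new_gene_points_excluded_with_warning(self):
        pans = [10.0, 12.0, 12.0, 14.0, 15.0, 16.0]
        with pytest.warns(UserWarning, match="non-positive"):
            fit = fit_heaps(_curve_from_values(np.arange(1, 7), pans))
        assert np.isfinite(fit.alpha)

    def test_too_few_points_is_error(self):
        with pytest.raises(ValueError):
            fit_heaps(_curve_from_values(np.array([1, 2]), np.array([5.0, 6.0])))


class TestOpenness:
    def test_two_genome_worked_example(self):
        matrix = pd.DataFrame(
            {"g1": [1, 1, 0, 0], "g2": [0, 1, 1, 1]}, index=list("ABCD")
        )
        sizes = {"g1": 2_000_000, "g2": 1_000_000}
        res = openness_new_genes_per_mbp(matrix, sizes, n_orders=10, seed=0)
        # order (g1, g2): g2 adds {C, D} over 1 Mb -> 2.0
        # order (g2, g1): g1 adds {A} over 2 Mb -> 0.5
        assert res.new_genes_per_mbp == pytest.approx(1.25)

    def test_identical_genomes_add_nothing(self):
        matrix = pd.DataFrame({"g1": [1, 1], "g2": [1, 1]}, index=["A", "B"])
        res = openness_new_genes_per_mbp(matrix, {"g1": 1e6, "g2": 1e6}, seed=0)
        assert res.new_genes_per_mbp == 0.0

    def test_matches_exhaustive_permutation_oracle(self):
        spec = PangenomeSpec(
            n_genomes=5, core_size=3,
            accessory_pool=[(f"a{j}", 0.5) for j in range(6)], unique_rate=1.0, seed=3,
        )
        matrix = simulate_presence_matrix(spec)
        sizes = {g: 1e6 * (1 + i) for i, g in enumerate(matrix.columns)}
        res = openness_new_genes_per_mbp(matrix, sizes, n_orders=10**6, seed=0)

        genomes = list(matrix.columns)
        og_sets = {g: set(matrix.index[matrix[g] == 1]) for g in genomes}
        contribs = []
        for order in itertools.permutations(genomes):
            seen = set(og_sets[order[0]])
            for g in order[1:]:
                contribs.append(len(og_sets[g] - seen) / (sizes[g] / 1e6))
                seen |= og_sets[g]
        assert res.new_genes_per_mbp == pytest.approx(np.mean(contribs), abs=1e-12)

    def test_missing_size_is_error(self, worked_matrix):
        with pytest.raises(ValueError, match="missing"):
            openness_new_genes_per_mbp(worked_matrix, {"g1": 1e6}, seed=0)


class TestEnrichment:
    def _lineage_map(self):
        lm = LineageMap()
        for g in ("g1", "g2"):
            lm.add(g, "Focal", 1_000_000)
        for g in ("g3", "g4"):
            lm.add(g, "Other", 1_000_000)
        return lm

    def test_focal_specific_og_detected(self):
        m = pd.DataFrame(
            {"g1": [1, 1], "g2": [1, 1], "g3": [0, 1], "g4": [0, 1]},
            index=["OG1", "OG2"],
        )
        assert detect_enriched_ogs(m, self._lineage_map(), "Focal") == ["OG1"]

    def test_universal_og_not_enriched(self):
        m = pd.DataFrame(
            {g: [1] for g in ("g1", "g2", "g3", "g4")}, index=["OG1"]
        )
        assert detect_enriched_ogs(m, self._lineage_map(), "Focal") == []

    def test_unknown_lineage_is_error(self):
        m = pd.DataFrame({g: [1] for g in ("g1", "g2", "g3", "g4")}, index=["OG1"])
        with pytest.raises(ValueError, match="lineage"):
            detect_enriched_ogs(m, self._lineage_map(), "Nope")

    def test_thresholds_inclusive(self):
        lm = LineageMap()
        for i in range(5):
            lm.add(f"f{i}", "Focal", 1_000_000)
        for i in range(10):
            lm.add(f"o{i}", "Other", 1_000_000)
        # prevalence exactly 0.8 focal and exactly 0.1 elsewhere
        data = {f"f{i}": [1 if i < 4 else 0] for i in range(5)}
        data.update({f"o{i}": [1 if i == 0 else 0] for i in range(10)})
        m = pd.DataFrame(data, index=["OG1"])
        assert detect_enriched_ogs(m, lm, "Focal") == ["OG1"]


class TestCompletenessFilter:
    def test_boundary_is_strict(self):
        kept = filter_genomes_by_completeness(
            ["a", "b"], {"a": 50.0, "b": 50.1}, min_completeness=50
        )
        assert kept == ["b"]

    def test_missing_value_is_error(self):
        with pytest.raises(ValueError):
            filter_genomes_by_completeness(["a"], {})

    def test_empty_survivor_set_warns(self):
        with pytest.warns(UserWarning):
            assert filter_genomes_by_completeness(["a"], {"a": 10.0}) == []
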