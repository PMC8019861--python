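"""Differential-expression statistics and DEG calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from netprio import expression as E
from netprio.synthetic import SyntheticStudyConfig, gene_symbols, generate_expression

from _oracles import oracle_fisher_two_sided


def make_matrix(values, n_case, n_control, genes=None):
    values = np.asarray(values, dtype=float)
    samples = [f"S{i}" for i in range(values.shape[1])]
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    groups = pd.Series(["case"] * n_case + ["control"] * n_control, index=samples)
    return E.GeneExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        sample_groups=groups,
    )


class TestAnova:
    def test_identical_groups(self):
        F, p = E.anova_pvalue([1, 2, 3], [1, 2, 3])
        assert F == 0.0 and p == 1.0

    def test_hand_computed_f(self):
        F, p = E.anova_pvalue([1, 2, 3], [4, 5, 6])
        assert F == pytest.approx(13.5)
        assert p == pytest.approx(stats.f.sf(13.5, 1, 4))

    def test_degenerate_constant_groups(self):
        with pytest.warns(RuntimeWarning, match="zero within-group variance"):
            F, p = E.anova_pvalue([2.0, 2.0], [5.0, 5.0])
        assert p == 0.0 and np.isinf(F)

    def test_too_few_values(self):
        with pytest.raises(ValueError, match="at least 2"):
            E.anova_pvalue([1.0], [2.0, 3.0])

    @given(
        case=st.lists(st.floats(-50, 50, allow_subnormal=False), min_size=2, max_size=10),
        control=st.lists(st.floats(-50, 50, allow_subnormal=False), min_size=2, max_size=10),
        shift=st.floats(-100, 100),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_equals_squared_t_and_shift_invariant(self, case, control, shift):
        if np.ptp(case) < 1e-6 and np.ptp(control) < 1e-6:
            return  # numerically degenerate: within-group variance ~ 0
        F, p = E.anova_pvalue(case, control)
        t = stats.ttest_ind(case, control).statistic
        assert F == pytest.approx(t**2, rel=1e-9, abs=1e-9)
        F2, _ = E.anova_pvalue(np.add(case, shift), np.add(control, shift))
        assert F2 == pytest.approx(F, rel=1e-6, abs=1e-6)
        F3, _ = E.anova_pvalue(control, case)  # label exchange
        assert F3 == pytest.approx(F, rel=1e-9, abs=1e-12)


class TestFisher:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ((3, 1, 1, 3), 34 / 70),
            ((0, 5, 5, 0), 2 / 252),
            ((2, 2, 2, 2), 1.0),
        ],
    )
    def test_enumerated_examples(self, table, expected):
        assert E.fisher_exact_two_sided(*table) == pytest.approx(expected, rel=1e-12)

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            E.fisher_exact_two_sided(0, 0, 0, 0)
        with pytest.raises(ValueError, match="non-negative"):
            E.fisher_exact_two_sided(-1, 2, 3, 4)

    @given(
        a=st.integers(0, 8), b=st.integers(0, 8),
        c=st.integers(0, 8), d=st.integers(0, 8),
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_matches_enumeration_and_symmetries(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        p = E.fisher_exact_two_sided(a, b, c, d)
        assert p == pytest.approx(oracle_fisher_two_sided(a, b, c, d), rel=1e-9)
        # transposing the table and swapping rows both preserve p
        assert E.fisher_exact_two_sided(a, c, b, d) == pytest.approx(p, rel=1e-9)
        assert E.fisher_exact_two_sided(c, d, a, b) == pytest.approx(p, rel=1e-9)


class TestBHAdjust:
    def test_equal_ps_are_fixed_points(self):
        assert np.allclose(E.bh_adjust([0.02, 0.02, 0.02]), 0.02)

    def test_hand_step_up(self):
        out = E.bh_adjust([0.005, 0.01, 0.03, 0.04])
        assert np.allclose(out, [0.02, 0.02, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert E.bh_adjust([0.3]) == pytest.approx([0.3])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError, match=r"\(0, 1\]"):
            E.bh_adjust([0.1, 0.0])
        with pytest.raises(ValueError):
            E.bh_adjust([1.2])

    @given(st.lists(st.floats(1e-6, 1.0, exclude_min=False), min_size=1, max_size=40),
           st.randoms(use_true_random=False))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_permutation_invariance_and_bounds(self, p_values, rnd):
        adjusted = E.bh_adjust(p_values)
        assert np.all(adjusted >= np.asarray(p_values) - 1e-15)
        assert np.all(adjusted <= 1.0)
        perm = list(range(len(p_values)))
        rnd.shuffle(perm)
        permuted = E.bh_adjust([p_values[i] for i in perm])
        assert np.allclose(permuted, adjusted[perm])


class TestMinPMerge:
    def test_min_and_single_platform_fallback(self):
        merged = E.min_p_across_platforms([{"X": 0.03, "Y": 0.5}, {"X": 0.2, "Z": 0.01}])
        assert merged == {"X": 0.03, "Y": 0.5, "Z": 0.01}

    def test_identical_tables_identity(self):
        table = {"A": 0.1, "B": 0.9}
        assert E.min_p_across_platforms([table, dict(table)]) == table

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            E.min_p_across_platforms([])


class TestCallDegs:
    def test_planted_matrix_recall_and_directions(self):
        config = SyntheticStudyConfig(seed=5)
        matrix, truth = generate_expression(config, gene_symbols(config.n_genes))
        result = E.call_degs(matrix, alpha=0.05, route="anova")
        called = set(result.table["gene"])
        recall = len(called & truth.true_deg_genes) / len(truth.true_deg_genes)
        assert recall >= 0.95
        directions = dict(zip(result.table["gene"], result.table["direction"]))
        for gene in called & truth.true_deg_genes:
            assert directions[gene] == truth.true_directions[gene]

    def test_alpha_zero_empty(self):
        matrix = make_matrix(np.random.default_rng(0).normal(size=(20, 8)), 4, 4)
        assert len(E.call_degs(matrix, alpha=0.0).table) == 0

    def test_constant_gene_not_called(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(5, 10))
        values[0] = 3.0  # constant across all samples
        matrix = make_matrix(values, 5, 5)
        result = E.call_degs(matrix, alpha=0.99)
        assert result.n_degenerate == 1
        assert "G0" not in set(result.table["gene"])

    def test_fisher_route_thresholds_adjusted_p(self):
        config = SyntheticStudyConfig(seed=11, n_genes=300, effect_size=3.0)
        matrix, truth = generate_expression(config, gene_symbols(config.n_genes))
        result = E.call_degs(matrix, alpha=0.05, route="fisher_bh")
        table = result.table
        assert (table["p_adjusted"] < 0.05).all()
        assert (table["p_adjusted"] >= table["p_value"] - 1e-15).all()
        assert set(table["source"]) == {"fisher"}
        called = set(table["gene"])
        recall = len(called & truth.true_deg_genes) / len(truth.true_deg_genes)
        assert recall >= 0.8  # median-split test is less powerful than ANOVA

    def test_matrix_validation(self):
        values = np.ones((3, 4))
        values[1, 2] = np.nan
        with pytest.raises(ValueError, match="missing values"):
            make_matrix(values, 2, 2)
        with pytest.raises(ValueError, match="no samples"):
            make_matrix(np.ones((3, 4)), 4, 0)

    def test_tsv_round_trip(self, tmp_path):
        config = SyntheticStudyConfig(seed=2, n_genes=50)
        matrix, _ = generate_expression(config, gene_symbols(50))
        matrix.to_tsv(tmp_path / "expr.tsv", tmp_path / "groups.tsv")
        back = E.GeneExpressionMatrix.from_tsv(tmp_path / "expr.tsv", tmp_path / "groups.tsv")
        assert np.allclose(back.values, matrix.values)
        assert (back.sample_groups == matrix.sample_groups).all()
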