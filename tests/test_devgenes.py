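"""Developmental gene selection: filters, ANOVA, fold, cutoff optimization."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from mamprog.data_model import GeneSet, TimeCourseMatrix
from mamprog.devgenes import (
    anova_across_timepoints,
    build_dev_table,
    max_min_fold,
    optimize_fold_cutoff,
    present_filter,
    select_dev_genes,
)
from mamprog.synthetic import SimulationConfig, simulate_development, simulate_reference_list


def _matrix(rows: dict[str, list[float]], groups: list[str]) -> TimeCourseMatrix:
    values = pd.DataFrame(rows).T
    values.columns = [f"a{i}" for i in range(values.shape[1])]
    design = pd.Series(groups, index=values.columns)
    return TimeCourseMatrix(values=values, design=design,
                            timepoint_order=list(dict.fromkeys(groups)))


class TestPresentFilter:
    def test_boundary_and_extremes(self):
        values = pd.DataFrame(np.ones((3, 10)),
                              index=["all", "half", "none"],
                              columns=[f"a{i}" for i in range(10)])
        calls = pd.DataFrame([["P"] * 10,
                              ["P"] * 5 + ["A"] * 5,
                              ["A"] * 10],
                             index=values.index, columns=values.columns)
        design = pd.Series(["T1"] * 5 + ["T2"] * 5, index=values.columns)
        m = TimeCourseMatrix(values=values, design=design,
                             timepoint_order=["T1", "T2"], calls=calls)
        kept = present_filter(m, 0.5).gene_ids
        assert kept == ["all", "half"]  # boundary inclusive, all-Absent dropped

    def test_no_calls_passes_through_with_warning(self, tiny_matrix, caplog):
        with caplog.at_level("WARNING", logger="mamprog"):
            out = present_filter(tiny_matrix, 0.5)
        assert out.gene_ids == tiny_matrix.gene_ids
        assert any("no detection calls" in r.message for r in caplog.records)


class TestAnova:
    def test_hand_computed_f(self):
        # groups {0,1},{2,3},{4,5}: SSB=16 (df 2), SSW=1.5 (df 3) -> F=16
        m = _matrix({"g": [0, 1, 2, 3, 4, 5]}, ["T1", "T1", "T2", "T2", "T3", "T3"])
        p = anova_across_timepoints(m)
        expected = scipy.stats.f.sf(16.0, 2, 3)
        assert p["g"] == pytest.approx(expected, rel=1e-12)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(30, 12))
        groups = ["T1"] * 4 + ["T2"] * 4 + ["T3"] * 4
        m = _matrix({f"g{i}": vals[i] for i in range(30)}, groups)
        ours = anova_across_timepoints(m)
        for i in range(30):
            ref = scipy.stats.f_oneway(vals[i, :4], vals[i, 4:8], vals[i, 8:]).pvalue
            assert ours[f"g{i}"] == pytest.approx(ref, rel=1e-9)

    def test_zero_variance_conventions(self):
        m = _matrix({"const": [5, 5, 5, 5],
                     "step": [1, 1, 2, 2]}, ["T1", "T1", "T2", "T2"])
        p = anova_across_timepoints(m)
        assert p["const"] == 1.0  # zero total variance
        assert p["step"] == 0.0   # zero within, nonzero between


class TestMaxMinFold:
    def test_plain_ratio(self):
        m = _matrix({"g": [2, 2, 6, 6, 4, 4]}, ["T1", "T1", "T2", "T2", "T3", "T3"])
        assert max_min_fold(m, floor=0.01)["g"] == pytest.approx(3.0)

    def test_constant_gene_is_one(self):
        m = _matrix({"g": [5, 5, 5, 5]}, ["T1", "T1", "T2", "T2"])
        assert max_min_fold(m, floor=0.01)["g"] == pytest.approx(1.0)

    def test_floor_caps_denominator(self):
        m = _matrix({"g": [0.0001, 0.0001, 8, 8]}, ["T1", "T1", "T2", "T2"])
        assert max_min_fold(m, floor=0.01)["g"] == pytest.approx(800.0)


class TestSelection:
    @pytest.mark.parametrize("p,fold,expected", [
        (0.005, 3.5, True),   # both pass
        (0.02, 10.0, False),  # p fails (strict)
        (0.001, 3.0, True),   # fold boundary inclusive
        (0.01, 5.0, False),   # p boundary is strict
    ])
    def test_cut_boundaries(self, p, fold, expected):
        anova_p = pd.Series({"g": p})
        folds = pd.Series({"g": fold})
        selected = select_dev_genes(anova_p, folds, p_cut=0.01, fold_cut=3.0)
        assert ("g" in selected.ids) is expected

    def test_permissive_cuts_select_everything(self):
        anova_p = pd.Series({"g1": 0.5, "g2": 1.0})
        folds = pd.Series({"g1": 1.0, "g2": 2.0})
        assert len(select_dev_genes(anova_p, folds, 1.01, 1.0)) == 2

    def test_monotone_nesting_over_cutoffs(self):
        rng = np.random.default_rng(1)
        anova_p = pd.Series(rng.uniform(size=50), index=[f"g{i}" for i in range(50)])
        folds = pd.Series(rng.uniform(1, 6, size=50), index=anova_p.index)
        prev = None
        for cut in (1.5, 2.5, 3.5, 4.5):
            sel = select_dev_genes(anova_p, folds, 0.5, cut).ids
            if prev is not None:
                assert sel <= prev
            prev = sel


class TestOptimizeFoldCutoff:
    def test_noiseless_recovers_planted_amplitude(self):
        cfg = SimulationConfig(seed=3, n_genes=800, noise_sd=0.0)
        matrix, truth = simulate_development(cfg)
        ref = simulate_reference_list(truth, 1.0, 0.0, seed=3)
        curve = optimize_fold_cutoff(matrix, ref)
        assert curve.best_cutoff == 3.0

    def test_curve_odds_ratios_match_brute_force(self):
        cfg = SimulationConfig(seed=8, n_genes=120)
        matrix, truth = simulate_development(cfg)
        ref = simulate_reference_list(truth, 0.8, 0.2, seed=8)
        grid = [2.0, 3.0, 4.0]
        curve = optimize_fold_cutoff(matrix, ref, grid=grid)
        # independent recomputation from raw sets
        present = present_filter(matrix, 0.5)
        p = anova_across_timepoints(present)
        fold = max_min_fold(present)
        uni = set(p.index[p < 0.01])
        for c, or_got, flagged in zip(grid, curve.odds_ratios, curve.corrected):
            sel = {g for g in uni if fold[g] >= c}
            a = len(sel & ref.ids)
            b = len((uni - sel) & ref.ids)
            cc = len(sel - ref.ids)
            d = len(uni - sel - ref.ids)
            if np.isnan(or_got):
                assert len(sel) in (0, len(uni))
            elif flagged:
                assert or_got == pytest.approx(
                    (a + .5) * (d + .5) / ((b + .5) * (cc + .5)))
            else:
                assert or_got == pytest.approx(a * d / (b * cc))

    def test_grid_of_length_one(self):
        cfg = SimulationConfig(seed=8, n_genes=200)
        matrix, truth = simulate_development(cfg)
        ref = simulate_reference_list(truth, 0.9, 0.1, seed=8)
        curve = optimize_fold_cutoff(matrix, ref, grid=[2.5])
        assert curve.grid == [2.5]
        assert curve.best_cutoff == 2.5

    def test_non_increasing_grid_rejected(self, small_development):
        matrix, truth = small_development
        ref = simulate_reference_list(truth, 0.9, 0.1, seed=1)
        with pytest.raises(ValueError, match="strictly increasing"):
            optimize_fold_cutoff(matrix, ref, grid=[3.0, 2.0])


def test_dev_table_invariant(small_development):
    matrix, _ = small_development
    present = present_filter(matrix, 0.5)
    p = anova_across_timepoints(present)
    fold = max_min_fold(present)
    table = build_dev_table(p, fold).table
    assert (table["fold_ratio"] >= 1).all()
    assert (table["is_developmental"] ==
            (table["passes_p"] & table["passes_fold"])).all()
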