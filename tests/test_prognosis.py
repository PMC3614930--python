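"""Tumor clustering, risk labeling, and survival statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from mamprog.data_model import ClinicalTable, GeneSet, TumorCohort
from mamprog.prognosis import (
    cluster_two_groups,
    clinical_factor_hr,
    hazard_ratio,
    km_estimate,
    label_risk,
    logrank,
    risk_factor_distribution,
    survival_comparison,
)


def _cohort(log_ratios, clinical_extra=None, name="c"):
    clin = pd.DataFrame({"metastasis": 0, "time_to_event": 10.0, "event": 0},
                        index=log_ratios.columns)
    if clinical_extra is not None:
        for k, v in clinical_extra.items():
            clin[k] = v
    return TumorCohort(name=name, log_ratios=log_ratios,
                       clinical=ClinicalTable(clin))


def _two_block_matrix(n_per=6, n_genes=20, shift=3.0, noise=0.05, seed=0):
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=n_genes)
    cols, data = [], []
    for i in range(n_per):
        cols.append(f"A{i:02d}")
        data.append(signs * shift + rng.normal(0, noise, n_genes))
    for i in range(n_per):
        cols.append(f"B{i:02d}")
        data.append(-signs * shift + rng.normal(0, noise, n_genes))
    return pd.DataFrame(np.array(data).T,
                        index=[f"g{i:02d}" for i in range(n_genes)],
                        columns=cols)


class TestClustering:
    def test_two_planted_blocks_recovered_exactly(self):
        lr = _two_block_matrix()
        labels = cluster_two_groups(_cohort(lr), GeneSet("g", frozenset(lr.index)))
        a = {labels[t] for t in lr.columns if t.startswith("A")}
        b = {labels[t] for t in lr.columns if t.startswith("B")}
        assert len(a) == 1 and len(b) == 1 and a != b

    def test_duplicated_profiles_cocluster(self):
        lr = _two_block_matrix(n_per=4)
        dup = lr.copy()
        dup.columns = [f"{c}_dup" for c in lr.columns]
        both = pd.concat([lr, dup], axis=1)
        labels = cluster_two_groups(_cohort(both), GeneSet("g", frozenset(lr.index)))
        for c in lr.columns:
            assert labels[c] == labels[f"{c}_dup"]

    def test_input_order_invariance(self):
        lr = _two_block_matrix()
        perm = lr.sample(frac=1, axis=1, random_state=3)
        l1 = cluster_two_groups(_cohort(lr), GeneSet("g", frozenset(lr.index)))
        l2 = cluster_two_groups(_cohort(perm), GeneSet("g", frozenset(lr.index)))
        agree = (l1 == l2.loc[l1.index]).mean()
        assert agree in (0.0, 1.0)  # identical up to cluster naming

    def test_zero_variance_tumor_assigned_by_centroid(self, caplog):
        lr = _two_block_matrix()
        lr["FLAT"] = 0.0
        with caplog.at_level("WARNING", logger="mamprog"):
            labels = cluster_two_groups(_cohort(lr),
                                        GeneSet("g", frozenset(lr.index)))
        assert "FLAT" in labels.index
        assert any("zero-variance" in r.message for r in caplog.records)

    def test_too_few_genes_rejected(self):
        lr = _two_block_matrix()
        with pytest.raises(ValueError, match="classifier genes"):
            cluster_two_groups(_cohort(lr), GeneSet("g", frozenset(["g00"])))


class TestLabelRisk:
    def _partition(self, n_high, n_low, events_high, events_low):
        ids = [f"H{i:03d}" for i in range(n_high)] + [f"L{i:03d}" for i in range(n_low)]
        labels = pd.Series([0] * n_high + [1] * n_low, index=ids)
        meta = ([1] * events_high + [0] * (n_high - events_high)
                + [1] * events_low + [0] * (n_low - events_low))
        clin = ClinicalTable(pd.DataFrame({
            "metastasis": meta,
            "time_to_event": 10.0,
            "event": meta,
        }, index=ids))
        return labels, clin

    def test_reported_accuracy_arithmetic(self):
        """48-vs-30 split with 27/7 metastatic: accuracy (23+27)/78 = 64.1%."""
        labels, clin = self._partition(48, 30, 27, 7)
        part = label_risk(labels, clin)
        assert (part.risk[labels == 0] == "high").all()
        assert part.accuracy * 100 == pytest.approx(64.1, abs=0.05)
        assert part.confusion.a == 27 and part.confusion.d == 23

    def test_all_negative_outcomes_tie_flag(self):
        labels, clin = self._partition(10, 6, 0, 0)
        part = label_risk(labels, clin)
        assert part.tie_flag
        assert part.accuracy == pytest.approx(6 / 16)  # low-risk fraction

    def test_cluster_name_swap_leaves_risk_unchanged(self):
        labels, clin = self._partition(12, 8, 9, 1)
        part1 = label_risk(labels, clin)
        part2 = label_risk(1 - labels, clin)
        assert (part1.risk == part2.risk).all()


class TestKm:
    def test_no_censoring_is_empirical_survivor(self):
        times = pd.Series([1.0, 2.0, 3.0, 4.0])
        events = pd.Series([1, 1, 1, 1])
        groups = pd.Series(["g"] * 4)
        curve = km_estimate(times, events, groups)["g"]
        surv = dict(zip(curve["time"], curve["survival"]))
        got = [surv[t] for t in (1.0, 2.0, 3.0, 4.0)]
        assert got == pytest.approx([0.75, 0.5, 0.25, 0.0], abs=1e-12)

    def test_all_censored_stays_at_one(self):
        curve = km_estimate(pd.Series([2.0, 5.0]), pd.Series([0, 0]),
                            pd.Series(["g", "g"]))["g"]
        assert (curve["survival"] == 1.0).all()

    def test_hand_product_limit_with_censoring(self):
        # censored at t=1 leaves risk set of 1 at t=2 -> S(2) = 0
        curve = km_estimate(pd.Series([1.0, 2.0]), pd.Series([0, 1]),
                            pd.Series(["g", "g"]))["g"]
        assert curve.loc[curve["time"] == 2.0, "survival"].iloc[0] == 0.0

    def test_curves_start_at_one_and_decrease(self):
        rng = np.random.default_rng(0)
        times = pd.Series(rng.exponential(10, 50))
        events = pd.Series(rng.integers(0, 2, 50))
        curve = km_estimate(times, events, pd.Series(["g"] * 50))["g"]
        assert curve["survival"].iloc[0] <= 1.0
        assert (np.diff(curve["survival"]) <= 1e-12).all()


class TestLogrankAndHr:
    def _duplicated_groups(self):
        times = pd.Series([1.0, 3.0, 5.0, 7.0] * 2)
        events = pd.Series([1, 0, 1, 1] * 2)
        groups = pd.Series(["a"] * 4 + ["b"] * 4)
        return times, events, groups

    def test_identical_groups_null(self):
        times, events, groups = self._duplicated_groups()
        chi2, p = logrank(times, events, groups)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-9)
        hr, _, flag = hazard_ratio(times, events, groups, positive="a")
        assert flag == ""
        assert hr == pytest.approx(1.0, abs=1e-6)

    def test_zero_events_flagged(self):
        chi2, p = logrank(pd.Series([1.0, 2.0]), pd.Series([0, 0]),
                          pd.Series(["a", "b"]))
        assert math.isnan(chi2) and math.isnan(p)

    def test_relabeling_inverts_hr(self):
        rng = np.random.default_rng(2)
        times = pd.Series(np.r_[rng.exponential(5, 40), rng.exponential(15, 40)])
        events = pd.Series([1] * 80)
        groups = pd.Series(["fast"] * 40 + ["slow"] * 40)
        hr_f, _, _ = hazard_ratio(times, events, groups, positive="fast")
        hr_s, _, _ = hazard_ratio(times, events, groups, positive="slow")
        assert hr_f == pytest.approx(1 / hr_s, rel=1e-6)
        assert hr_f > 1

    def test_complete_separation_flagged(self):
        times = pd.Series([1.0, 2.0, 3.0, 4.0])
        events = pd.Series([1, 1, 0, 0])
        groups = pd.Series(["high", "high", "low", "low"])
        hr, ci, flag = hazard_ratio(times, events, groups)
        assert flag == "separation"
        assert math.isinf(hr)

    def test_logrank_and_hr_agree_in_direction(self):
        rng = np.random.default_rng(5)
        times = pd.Series(np.r_[rng.exponential(4, 60), rng.exponential(12, 60)])
        events = pd.Series([1] * 120)
        groups = pd.Series(["high"] * 60 + ["low"] * 60)
        comp = survival_comparison(times, events, groups)
        assert comp.hazard_ratio > 1
        assert comp.logrank_p < 0.01


class TestClinicalFactors:
    def _clinical(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        grade = rng.choice(["1", "2", "3"], n)
        times = rng.exponential(20, n)
        clin = pd.DataFrame({
            "metastasis": rng.integers(0, 2, n),
            "time_to_event": times,
            "event": rng.integers(0, 2, n),
            "grade": grade,
        }, index=[f"t{i:02d}" for i in range(n)])
        return ClinicalTable(clin)

    def test_independent_factor_hr_near_one(self):
        hrs = []
        for seed in range(20):
            clin = self._clinical(seed=seed)
            hr, _, flag = clinical_factor_hr(clin, "grade", {"3"})
            if flag == "":
                hrs.append(math.log(hr))
        assert abs(np.mean(hrs)) < 0.25

    def test_missing_heavy_factor_rejected(self):
        clin = self._clinical()
        clin.table.loc[clin.table.index[:20], "grade"] = pd.NA
        with pytest.raises(ValueError, match="missing"):
            clinical_factor_hr(clin, "grade", {"3"})

    def test_factor_identical_to_partition_matches_hr(self):
        rng = np.random.default_rng(1)
        n = 80
        risk = pd.Series(["high"] * 40 + ["low"] * 40,
                         index=[f"t{i:02d}" for i in range(n)])
        times = pd.Series(np.r_[rng.exponential(5, 40), rng.exponential(15, 40)],
                          index=risk.index)
        events = pd.Series([1] * n, index=risk.index)
        clin = ClinicalTable(pd.DataFrame({
            "metastasis": 1, "time_to_event": times, "event": 1,
            "grade": np.where(risk == "high", "3", "1"),
        }, index=risk.index))
        hr_direct, _, _ = hazard_ratio(times, events, risk)
        hr_factor, _, _ = clinical_factor_hr(clin, "grade", {"3"})
        assert hr_factor == pytest.approx(hr_direct, rel=1e-9)


class TestRiskFactorDistribution:
    def test_percentages_and_counts_conserved(self):
        rng = np.random.default_rng(0)
        n = 40
        ids = [f"t{i:02d}" for i in range(n)]
        meta = rng.integers(0, 2, n)
        clin = ClinicalTable(pd.DataFrame({
            "metastasis": meta, "time_to_event": 10.0, "event": meta,
            "grade": rng.choice(["1", "2", "3"], n),
        }, index=ids))
        labels = pd.Series(rng.integers(0, 2, n), index=ids)
        part = label_risk(labels, clin)
        dist = risk_factor_distribution(part, clin)
        grade_rows = dist.loc["grade"]
        n_cols = [c for c in grade_rows.columns if c.endswith("_n")]
        assert grade_rows[n_cols].to_numpy().sum() == n
        for cell in {c[:-2] for c in n_cols}:
            total = grade_rows[f"{cell}_n"].sum()
            if total:
                assert grade_rows[f"{cell}_pct"].sum() == pytest.approx(100.0)
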