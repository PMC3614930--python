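"""Clinical outcome prediction from classifier-gene expression.

Tumors are clustered into two groups by average-linkage hierarchical
clustering on 1 - Pearson correlation between their classifier-gene
profiles (the dendrogram cut at its top split); the cluster holding the
larger fraction of event-positive tumors is labeled high risk; the two
risk groups are compared by accuracy against the observed outcome, Fisher
exact test, Kaplan-Meier curves, the log-rank test, and a univariate
proportional-hazards hazard ratio. Clinical risk factors (size, grade, ER
status, ...) are dichotomized and run through the same hazard-ratio
machinery for comparison.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

from .data_model import ClinicalTable, GeneSet, TumorCohort
from .enrichment import Contingency2x2, fisher_exact

logger = logging.getLogger("mamprog")

HIGH, LOW = "high", "low"


@dataclass
class RiskPartition:
    """Per-tumor cluster and risk labels with prediction summaries."""

    labels: pd.Series       # tumor_id -> cluster {0, 1}
    risk: pd.Series         # tumor_id -> {"high", "low"}
    accuracy: float
    confusion: Contingency2x2  # a=event&high, b=event&low, c=no-event&high, d=no-event&low
    fisher_p: float
    tie_flag: bool = False


@dataclass
class SurvivalComparison:
    km_curves: dict[str, pd.DataFrame]  # group -> (time, survival)
    logrank_chi2: float
    logrank_p: float
    hazard_ratio: float
    hr_ci95: tuple[float, float]
    hr_flag: str = ""  # "" | "separation"


def cluster_two_groups(cohort: TumorCohort, genes: GeneSet,
                       metric: str = "correlation",
                       linkage: str = "average") -> pd.Series:
    """Two-way unsupervised clustering of tumors on a gene subset.

    Distance is 1 - Pearson correlation between tumor profiles (Euclidean
    available as an option), agglomerated with average linkage and cut at the
    top split into exactly two clusters. Tumors are processed in sorted-id
    order, making the result independent of input order. A zero-variance
    tumor has no defined correlation; it is held out, the rest clustered,
    and it joins the nearest (Euclidean) cluster centroid.
    """
    shared = [g for g in cohort.log_ratios.index if g in genes.ids]
    if len(shared) < 2:
        raise ValueError("need at least 2 classifier genes present in the cohort")
    tumors = sorted(cohort.tumor_ids)
    if len(tumors) < 4:
        raise ValueError("need at least 4 tumors to cluster")
    X = cohort.log_ratios.loc[shared, tumors].to_numpy(dtype=float).T  # tumors x genes

    degenerate = np.zeros(len(tumors), dtype=bool)
    if metric == "correlation":
        degenerate = X.std(axis=1) == 0
        if degenerate.any():
            logger.warning("cluster_two_groups: %d zero-variance tumor(s) assigned "
                           "by nearest centroid", int(degenerate.sum()))
    core = X[~degenerate]
    dist = ssd.pdist(core, metric=metric if metric != "correlation" else "correlation")
    Z = sch.linkage(dist, method=linkage)
    core_labels = sch.fcluster(Z, t=2, criterion="maxclust") - 1

    labels = np.empty(len(tumors), dtype=int)
    labels[~degenerate] = core_labels
    if degenerate.any():
        centroids = np.stack([core[core_labels == k].mean(axis=0) for k in (0, 1)])
        for i in np.where(degenerate)[0]:
            labels[i] = int(np.argmin(((centroids - X[i]) ** 2).sum(axis=1)))
    return pd.Series(labels, index=tumors, name="cluster")


def label_risk(labels: pd.Series, clinical: ClinicalTable,
               endpoint: str = "metastasis") -> RiskPartition:
    """Label the cluster richer in outcome-positive tumors as high risk.

    Accuracy is the fraction of tumors whose risk label matches their
    observed outcome (event-positive in high plus event-negative in low).
    A tie in outcome fractions falls back to the larger cluster as high
    risk, flagged.
    """
    outcome = clinical.table.loc[labels.index, endpoint].astype(int)
    frac = {k: outcome[labels == k].mean() for k in (0, 1)}
    tie = math.isclose(frac[0], frac[1])
    if tie:
        high_cluster = max((0, 1), key=lambda k: (labels == k).sum())
        logger.warning("label_risk: outcome fractions tied; larger cluster set high risk")
    else:
        high_cluster = max((0, 1), key=lambda k: frac[k])
    risk = labels.map(lambda k: HIGH if k == high_cluster else LOW)
    a = int(((risk == HIGH) & (outcome == 1)).sum())
    b = int(((risk == LOW) & (outcome == 1)).sum())
    c = int(((risk == HIGH) & (outcome == 0)).sum())
    d = int(((risk == LOW) & (outcome == 0)).sum())
    confusion = Contingency2x2(a, b, c, d)
    accuracy = (a + d) / confusion.n
    return RiskPartition(labels=labels, risk=risk, accuracy=accuracy,
                         confusion=confusion, fisher_p=fisher_exact(confusion),
                         tie_flag=tie)


def km_estimate(times: pd.Series, events: pd.Series,
                groups: pd.Series) -> dict[str, pd.DataFrame]:
    """Product-limit survival curve per group."""
    curves: dict[str, pd.DataFrame] = {}
    for g in pd.unique(groups):
        mask = groups == g
        if not mask.any():
            logger.warning("km_estimate: group %r empty", g)
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        sf = kmf.survival_function_
        curves[str(g)] = pd.DataFrame({
            "time": sf.index.to_numpy(dtype=float),
            "survival": sf.iloc[:, 0].to_numpy(dtype=float),
        })
    return curves


def logrank(times: pd.Series, events: pd.Series,
            groups: pd.Series) -> tuple[float, float]:
    """Two-group log-rank test: (chi2, p)."""
    names = sorted(pd.unique(groups.astype(str)))
    if len(names) != 2:
        raise ValueError("logrank needs exactly two groups")
    if events.sum() == 0:
        logger.warning("logrank: zero events; test undefined")
        return math.nan, math.nan
    g = groups.astype(str)
    res = logrank_test(times[g == names[0]], times[g == names[1]],
                       events[g == names[0]], events[g == names[1]])
    return float(res.test_statistic), float(res.p_value)


def hazard_ratio(times: pd.Series, events: pd.Series, groups: pd.Series,
                 positive: str = HIGH) -> tuple[float, tuple[float, float], str]:
    """Univariate proportional-hazards HR of ``positive`` vs the other group.

    Fit by partial-likelihood maximization on the group indicator; returns
    (hr, (ci_low, ci_high), flag). Complete separation (all events in one
    group) yields an infinite or zero HR with a one-sided CI, flagged
    "separation".
    """
    g = groups.astype(str)
    names = sorted(g.unique())
    if len(names) != 2:
        raise ValueError("hazard_ratio needs exactly two groups")
    indicator = (g == positive).astype(float)
    ev_pos = events[indicator == 1].sum()
    ev_neg = events[indicator == 0].sum()
    if ev_pos == 0 or ev_neg == 0:
        hr = math.inf if ev_neg == 0 else 0.0
        logger.warning("hazard_ratio: complete separation (events %d vs %d)",
                       int(ev_pos), int(ev_neg))
        return hr, (0.0, math.inf), "separation"
    df = pd.DataFrame({"time": times.to_numpy(dtype=float),
                       "event": events.to_numpy(dtype=int),
                       "x": indicator.to_numpy()})
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event")
    hr = float(np.exp(cph.params_["x"]))
    lo, hi = np.exp(cph.confidence_intervals_.loc["x"]).to_numpy(dtype=float)
    return hr, (float(lo), float(hi)), ""


def survival_comparison(times: pd.Series, events: pd.Series,
                        groups: pd.Series) -> SurvivalComparison:
    """KM curves, log-rank test and high-vs-low hazard ratio in one bundle."""
    chi2, p = logrank(times, events, groups)
    hr, ci, flag = hazard_ratio(times, events, groups)
    return SurvivalComparison(
        km_curves=km_estimate(times, events, groups),
        logrank_chi2=chi2, logrank_p=p,
        hazard_ratio=hr, hr_ci95=ci, hr_flag=flag,
    )


def clinical_factor_hr(clinical: ClinicalTable, factor: str,
                       positive_levels: set[str],
                       max_missing_frac: float = 0.2) -> tuple[float, tuple[float, float], str]:
    """Hazard ratio of a dichotomized clinical factor.

    Tumors whose factor level lies in ``positive_levels`` form the positive
    group; missing values are dropped (rejected if more than
    ``max_missing_frac`` of tumors are missing the factor).
    """
    col = clinical.table[factor]
    missing = col.isna()
    if missing.mean() > max_missing_frac:
        raise ValueError(
            f"factor {factor!r} missing for {missing.mean():.0%} of tumors "
            f"(limit {max_missing_frac:.0%})"
        )
    keep = ~missing
    groups = col[keep].astype(str).isin({str(v) for v in positive_levels})
    groups = groups.map({True: "positive", False: "negative"})
    if groups.nunique() < 2:
        logger.warning("clinical_factor_hr: one side of factor %r empty", factor)
        return math.nan, (math.nan, math.nan), "one_sided"
    return hazard_ratio(
        clinical.table.loc[keep.index[keep], "time_to_event"],
        clinical.table.loc[keep.index[keep], "event"].astype(int),
        groups, positive="positive",
    )


def risk_factor_distribution(partition: RiskPartition,
                             clinical: ClinicalTable,
                             endpoint: str = "metastasis") -> pd.DataFrame:
    """Factor-level counts and percentages per (outcome x risk) cell.

    Rows are (factor, level); columns are the four cells of observed outcome
    crossed with predicted risk, each holding a count and the within-cell
    percentage among tumors with the factor recorded.
    """
    outcome = clinical.table.loc[partition.risk.index, endpoint].astype(int)
    cells = {
        f"outcome{o}_{r}": partition.risk.index[(outcome == o) & (partition.risk == r)]
        for o in (0, 1) for r in (LOW, HIGH)
    }
    rows = []
    from .data_model import FACTOR_COLUMNS
    for factor in FACTOR_COLUMNS:
        if factor not in clinical.table.columns:
            continue
        col = clinical.table[factor]
        for level in sorted(col.dropna().astype(str).unique()):
            row: dict[str, object] = {"factor": factor, "level": level}
            for cell, ids in cells.items():
                sub = col.loc[ids].dropna().astype(str)
                n = int((sub == level).sum())
                row[f"{cell}_n"] = n
                row[f"{cell}_pct"] = 100.0 * n / len(sub) if len(sub) else math.nan
            rows.append(row)
    return pd.DataFrame(rows).set_index(["factor", "level"])
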