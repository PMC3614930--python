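"""Prognosis-classifier derivation from tumor-cohort alteration counts.

Each developmental gene is tested for altered expression in each of K tumor
cohorts (|mean log2-ratio| above a fold cutoff with a one-sample t-test
against zero), genes are partitioned into Sub0..SubK by how many cohorts
call them altered, and the classifier is the subset altered in at least two
cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .data_model import GeneSet, TumorCohort

logger = logging.getLogger("mamprog")


@dataclass
class AlterationMatrix:
    """Gene x cohort altered flags with per-gene alteration counts."""

    flags: pd.DataFrame  # bool, genes x cohorts

    @property
    def counts(self) -> pd.Series:
        return self.flags.sum(axis=1).astype(int)

    @property
    def n_cohorts(self) -> int:
        return self.flags.shape[1]


@dataclass
class ClassifierSet:
    """Genes altered in at least ``min_count`` cohorts."""

    ids: GeneSet
    min_count: int
    counts: pd.Series  # alteration count for every input gene


def call_altered(cohort: TumorCohort, abs_log2fc_cut: float = 1.0,
                 p_cut: float = 0.01) -> GeneSet:
    """Genes with significant mean log2-ratio shift across the cohort.

    A gene is altered iff |mean log2-ratio| >= ``abs_log2fc_cut`` and a
    two-sided one-sample t-test of its log-ratios against zero gives
    p < ``p_cut``. A zero-variance gene with nonzero mean is altered by
    convention (t diverges, p -> 0).
    """
    n = len(cohort.tumor_ids)
    if n < 3:
        raise ValueError(f"cohort {cohort.name!r} has {n} tumors; need >=3 for the t-test")
    X = cohort.log_ratios.to_numpy(dtype=float)
    mean = X.mean(axis=1)
    sd = X.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
        p = 2.0 * scipy.stats.t.sf(np.abs(t), df=n - 1)
    zero_var = sd == 0
    p = np.where(zero_var & (mean != 0), 0.0, p)
    p = np.where(zero_var & (mean == 0), 1.0, p)
    altered = (np.abs(mean) >= abs_log2fc_cut) & (p < p_cut)
    ids = frozenset(cohort.log_ratios.index[altered])
    logger.info("call_altered[%s]: %d of %d genes altered", cohort.name,
                len(ids), len(cohort.gene_ids))
    return GeneSet(f"altered_{cohort.name}", ids,
                   f"|log2fc|>={abs_log2fc_cut}, p<{p_cut}")


def count_alterations(dev_genes: GeneSet,
                      altered_per_cohort: list[GeneSet]) -> AlterationMatrix:
    """Per-developmental-gene altered flags across cohorts.

    A gene absent from a cohort's universe simply is not in its altered
    list and counts as not-altered there, keeping counts on a uniform 0..K
    range.
    """
    if not altered_per_cohort:
        raise ValueError("need at least one cohort's altered list")
    genes = sorted(dev_genes.ids)
    data = {
        gs.name or f"cohort{k}": [g in gs.ids for g in genes]
        for k, gs in enumerate(altered_per_cohort)
    }
    flags = pd.DataFrame(data, index=genes, dtype=bool)
    return AlterationMatrix(flags=flags)


def derive_classifier(am: AlterationMatrix, min_count: int = 2) -> ClassifierSet:
    """Classifier = developmental genes altered in >= min_count cohorts."""
    if not (0 <= min_count <= am.n_cohorts + 1):
        raise ValueError("min_count out of range")
    counts = am.counts
    ids = frozenset(counts.index[counts >= min_count])
    if not ids:
        logger.warning("derive_classifier: empty classifier at min_count=%d", min_count)
    return ClassifierSet(
        ids=GeneSet("prognosis_classifier", ids, f"altered in >={min_count} cohorts"),
        min_count=min_count,
        counts=counts,
    )


def subset_annotation_table(am: AlterationMatrix, annotated: GeneSet) -> pd.DataFrame:
    """Sub0..SubK partition sizes and annotated fractions.

    Mirrors the subset table of the derivation figure: genes grouped by the
    number of cohorts calling them altered, with the fraction belonging to a
    reference (cancer-modulated) list per group.
    """
    counts = am.counts
    rows = []
    for k in range(am.n_cohorts + 1):
        members = set(counts.index[counts == k])
        n = len(members)
        n_ann = len(members & annotated.ids)
        rows.append({
            "subset": f"Sub{k}",
            "n_genes": n,
            "n_annotated": n_ann,
            "fraction_annotated": n_ann / n if n else float("nan"),
        })
    return pd.DataFrame(rows).set_index("subset")
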