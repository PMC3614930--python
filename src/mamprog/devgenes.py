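"""Definition of the developmentally associated gene subset.

Three filters applied to the time-course matrix: (1) a detection filter
keeping genes called Present on at least half the arrays; (2) a per-gene
one-way ANOVA across time points at p < 0.01; (3) a max/min fold cutoff on
time-point mean expression, chosen to maximize the odds ratio of a reference
gene list between the selected and rejected subsets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .data_model import GeneSet, TimeCourseMatrix
from .enrichment import build_contingency, odds_ratio

logger = logging.getLogger("mamprog")

DEFAULT_GRID = [1.5 + 0.5 * i for i in range(10)]  # 1.5 .. 6.0


@dataclass
class DevGeneTable:
    """Per-gene ANOVA p, max/min fold, and the two pass flags."""

    table: pd.DataFrame  # columns: anova_p, fold_ratio, passes_p, passes_fold, is_developmental
    p_cut: float
    fold_cut: float

    @property
    def selected(self) -> GeneSet:
        ids = self.table.index[self.table["is_developmental"]]
        return GeneSet("developmental", frozenset(ids),
                       f"anova_p<{self.p_cut}, fold>={self.fold_cut}")


@dataclass
class CutoffCurve:
    """Odds-ratio profile over candidate fold cutoffs."""

    grid: list[float]
    odds_ratios: list[float]  # NaN where undefined (empty subset)
    corrected: list[bool]  # zero-cell (Haldane) corrected grid points
    best_cutoff: float
    best_or: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fold_cutoff": self.grid,
                             "odds_ratio": self.odds_ratios,
                             "corrected": self.corrected})


def present_filter(matrix: TimeCourseMatrix, min_present_frac: float = 0.5) -> TimeCourseMatrix:
    """Drop genes called Present on fewer than ``min_present_frac`` of arrays.

    Boundary inclusive: a gene Present on exactly the threshold fraction is
    retained. Without detection calls the matrix passes through unchanged.
    """
    if matrix.calls is None:
        logger.warning("present_filter: no detection calls; passing all genes through")
        return matrix
    frac = matrix.present_fraction()
    keep = frac.index[frac >= min_present_frac]
    logger.info("present_filter: retained %d of %d genes", len(keep), len(frac))
    return matrix.subset_genes(keep)


def anova_across_timepoints(matrix: TimeCourseMatrix) -> pd.Series:
    """One-way fixed-effects ANOVA p-value per gene, groups = time points.

    Vectorized F-test over all genes: F = (SSB/(T-1)) / (SSW/(N-T)) with T
    time points and N arrays. Degenerate genes follow two conventions, both
    logged: zero total variance -> p = 1; zero within-group variance with
    nonzero between-group variance -> p = 0.
    """
    tps = matrix.timepoint_order
    if len(tps) < 2:
        raise ValueError("ANOVA needs at least two time points")
    X = matrix.values.to_numpy(dtype=float)
    groups = [matrix.arrays_for(tp) for tp in tps]
    sizes = np.array([len(g) for g in groups])
    if not (sizes >= 1).all() or (sizes >= 2).sum() < 1:
        raise ValueError("each time point needs >=1 array and at least one needs replicates")
    n_total = sizes.sum()
    col_idx = {a: j for j, a in enumerate(matrix.values.columns)}

    grand = X.mean(axis=1)
    ssb = np.zeros(X.shape[0])
    ssw = np.zeros(X.shape[0])
    for g, size in zip(groups, sizes):
        cols = [col_idx[a] for a in g]
        sub = X[:, cols]
        gm = sub.mean(axis=1)
        ssb += size * (gm - grand) ** 2
        ssw += ((sub - gm[:, None]) ** 2).sum(axis=1)

    df_between = len(tps) - 1
    df_within = n_total - len(tps)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = (ssb / df_between) / (ssw / df_within)
        p = scipy.stats.f.sf(f_stat, df_between, df_within)

    tol = 1e-12 * np.maximum(1.0, (X ** 2).sum(axis=1))
    zero_within = ssw <= tol
    zero_between = ssb <= tol
    p = np.where(zero_within & zero_between, 1.0, p)
    p = np.where(zero_within & ~zero_between, 0.0, p)
    n_deg = int((zero_within).sum())
    if n_deg:
        logger.info("anova: %d gene(s) with zero within-group variance (convention applied)", n_deg)
    return pd.Series(p, index=matrix.values.index, name="anova_p")


def default_fold_floor(matrix: TimeCourseMatrix) -> float:
    """Denominator floor: 1st percentile of all positive matrix values."""
    vals = matrix.values.to_numpy(dtype=float)
    pos = vals[vals > 0]
    if pos.size == 0:
        raise ValueError("matrix has no positive values")
    floor = float(np.percentile(pos, 1))
    logger.info("fold floor = %.6g (1st percentile of positive values)", floor)
    return floor


def max_min_fold(matrix: TimeCourseMatrix, floor: float | None = None) -> pd.Series:
    """Max/min ratio of time-point mean expression per gene (>= 1 always).

    The denominator is floored at ``floor`` (default: 1st percentile of
    positive values) so near-zero minima cannot blow the statistic up.
    """
    if floor is None:
        floor = default_fold_floor(matrix)
    if floor <= 0:
        raise ValueError("floor must be positive")
    means = matrix.timepoint_means().to_numpy(dtype=float)
    hi = means.max(axis=1)
    lo = np.maximum(means.min(axis=1), floor)
    fold = np.maximum(hi / lo, 1.0)
    return pd.Series(fold, index=matrix.values.index, name="fold_ratio")


def build_dev_table(anova_p: pd.Series, fold: pd.Series, p_cut: float = 0.01,
                    fold_cut: float = 3.0) -> DevGeneTable:
    """Combine the two statistics into the per-gene selection table.

    p is compared strictly (p < p_cut); fold inclusively (fold >= fold_cut).
    """
    if not anova_p.index.equals(fold.index):
        raise ValueError("p-values and folds must cover the same gene universe")
    passes_p = anova_p < p_cut
    passes_fold = fold >= fold_cut
    table = pd.DataFrame({
        "anova_p": anova_p,
        "fold_ratio": fold,
        "passes_p": passes_p,
        "passes_fold": passes_fold,
        "is_developmental": passes_p & passes_fold,
    })
    return DevGeneTable(table=table, p_cut=p_cut, fold_cut=fold_cut)


def select_dev_genes(anova_p: pd.Series, fold: pd.Series, p_cut: float = 0.01,
                     fold_cut: float = 3.0) -> GeneSet:
    """Genes with anova_p < p_cut and fold >= fold_cut."""
    selected = build_dev_table(anova_p, fold, p_cut, fold_cut).selected
    if len(selected) == 0:
        logger.warning("select_dev_genes: empty selection at p<%g, fold>=%g", p_cut, fold_cut)
    return selected


def optimize_fold_cutoff(
    matrix: TimeCourseMatrix,
    reference: GeneSet,
    p_cut: float = 0.01,
    grid: list[float] | None = None,
    floor: float | None = None,
    min_present_frac: float = 0.5,
) -> CutoffCurve:
    """Choose the fold cutoff maximizing reference-list odds ratio.

    The universe is the Present, ANOVA-passing genes. At each candidate
    cutoff the universe splits into selected (fold >= c) and rejected
    subsets; the odds ratio of reference membership between them is recorded.
    Cutoffs with an empty side are recorded as NaN and excluded from the
    argmax. Cutoffs whose odds ratio needed a zero-cell correction stay in
    the curve but only enter the argmax when no uncorrected point exists (an
    optimum resting on an empty contingency cell is an artifact of the
    grid's tails, not a real enrichment peak). Ties break toward the smaller
    cutoff.
    """
    if grid is None:
        grid = list(DEFAULT_GRID)
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("grid must be strictly increasing")
    present = present_filter(matrix, min_present_frac)
    anova_p = anova_across_timepoints(present)
    fold = max_min_fold(present, floor=floor)
    universe_ids = anova_p.index[anova_p < p_cut]
    universe = GeneSet("universe", frozenset(universe_ids), "Present & p-passing")
    if not (reference.ids & universe.ids):
        raise ValueError("reference list does not intersect the gene universe")
    fold_u = fold.loc[universe_ids]

    ors: list[float] = []
    flags: list[bool] = []
    for c in grid:
        sel_ids = frozenset(fold_u.index[fold_u >= c])
        if len(sel_ids) == 0 or len(sel_ids) == len(universe.ids):
            ors.append(math.nan)
            flags.append(True)
            continue
        res = odds_ratio(build_contingency(GeneSet("selected", sel_ids),
                                           reference, universe))
        ors.append(res.value)
        flags.append(res.corrected)

    candidates = [(o, c) for c, o, f in zip(grid, ors, flags)
                  if not math.isnan(o) and not f]
    if not candidates:  # fall back to corrected points (degenerate data)
        logger.warning("optimize_fold_cutoff: every grid point zero-cell corrected")
        candidates = [(o, c) for c, o in zip(grid, ors) if not math.isnan(o)]
    if not candidates:
        raise ValueError("odds ratio undefined at every grid point")
    best_or = max(o for o, _ in candidates)
    best_cutoff = min(c for o, c in candidates if o == best_or)
    return CutoffCurve(grid=list(grid), odds_ratios=ors, corrected=flags,
                       best_cutoff=best_cutoff, best_or=best_or)
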