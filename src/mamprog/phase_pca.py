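"""Phase assignment of developmental genes by PCA quadrants.

Each developmental gene's profile is standardized to mean zero / variance
one across arrays, PCA is run with genes as observations and arrays as
variables, the first two components are sign-oriented against the peak-time
structure, and each gene is assigned growth (PC1 > 0), involution
(PC1 <= 0 & PC2 > 0) or lactation (PC1 <= 0 & PC2 <= 0).

PCA sign is arbitrary, so orientation is fixed deterministically: PC1 is
flipped if needed so genes peaking in the growth block average positive on
it, then PC2 so genes peaking in the involution block average positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .data_model import GeneSet, TimeCourseMatrix

logger = logging.getLogger("mamprog")

_NONZERO_TOL = 1e-9


@dataclass
class PcaSummary:
    variance_fractions: np.ndarray  # per nonzero component
    n_nonzero: int


@dataclass
class PhaseAssignment:
    """Per-gene oriented PC scores, phase label and peak time point."""

    table: pd.DataFrame  # columns: pc1, pc2, phase, peak_timepoint

    @property
    def phases(self) -> pd.Series:
        return self.table["phase"]

    def phase_set(self, phase: str) -> GeneSet:
        ids = self.table.index[self.table["phase"] == phase]
        return GeneSet(phase, frozenset(ids), "PCA quadrant assignment")


def standardize_profiles(matrix: TimeCourseMatrix, dev_genes: GeneSet) -> pd.DataFrame:
    """Per-gene zero-mean unit-variance profiles, restricted to dev_genes.

    Variance uses the population convention (ddof=0). Constant genes cannot
    be standardized and are excluded with a warning.
    """
    missing = dev_genes.ids - set(matrix.values.index)
    if missing:
        raise ValueError(f"gene(s) not in matrix: {sorted(missing)[:3]}")
    sub = matrix.values.loc[[g for g in matrix.values.index if g in dev_genes.ids]]
    X = sub.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    constant = sd[:, 0] <= _NONZERO_TOL * np.abs(mu[:, 0]).clip(min=1.0)
    if constant.any():
        logger.warning("standardize_profiles: excluded %d zero-variance gene(s)",
                       int(constant.sum()))
    Z = (X[~constant] - mu[~constant]) / sd[~constant]
    return pd.DataFrame(Z, index=sub.index[~constant], columns=sub.columns)


def pca_timecourse(standardized: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, PcaSummary]:
    """PCA with genes as observations, arrays as variables.

    Returns (scores, loadings, summary): scores are gene projections on all
    components; loadings are the component vectors over arrays; the summary
    holds per-nonzero-component variance fractions.
    """
    n_genes, n_arrays = standardized.shape
    if n_genes < 2 or n_arrays < 3:
        raise ValueError("PCA needs at least 2 genes and 3 arrays")
    X = standardized.to_numpy(dtype=float)
    if not np.any(np.abs(X - X.mean(axis=0)) > 0):
        raise ValueError("rank-0 input: no variance across genes")
    pca = PCA(n_components=min(n_genes, n_arrays), svd_solver="full")
    scores = pca.fit_transform(X)
    ev = pca.explained_variance_
    nonzero = ev > _NONZERO_TOL * max(ev[0], 1.0)
    n_nonzero = int(nonzero.sum())
    fractions = ev[nonzero] / ev[nonzero].sum()
    score_df = pd.DataFrame(
        scores[:, :n_nonzero], index=standardized.index,
        columns=[f"PC{i + 1}" for i in range(n_nonzero)],
    )
    loading_df = pd.DataFrame(
        pca.components_[:n_nonzero], columns=standardized.columns,
        index=[f"PC{i + 1}" for i in range(n_nonzero)],
    )
    return score_df, loading_df, PcaSummary(variance_fractions=fractions,
                                            n_nonzero=n_nonzero)


def peak_timepoints(matrix: TimeCourseMatrix, dev_genes: GeneSet) -> pd.Series:
    """Time point of maximal replicate-mean expression per gene.

    Ties resolve to the earliest tied time point in design order (logged).
    Computed on unstandardized means; per-gene standardization preserves the
    argmax.
    """
    sub = matrix.subset_genes(dev_genes.ids)
    means = sub.timepoint_means()
    arr = means.to_numpy(dtype=float)
    idx = arr.argmax(axis=1)  # argmax returns the first maximum -> earliest
    n_ties = int((arr == arr.max(axis=1, keepdims=True)).sum(axis=1).max() > 1)
    if n_ties:
        logger.info("peak_timepoints: ties resolved to earliest time point")
    tps = np.array(matrix.timepoint_order, dtype=object)
    return pd.Series(tps[idx], index=means.index, name="peak_timepoint")


def peak_histogram(matrix: TimeCourseMatrix, dev_genes: GeneSet) -> tuple[pd.Series, pd.Series]:
    """Gene count per peak time point, plus the per-gene peak labels."""
    peaks = peak_timepoints(matrix, dev_genes)
    hist = peaks.value_counts().reindex(matrix.timepoint_order, fill_value=0)
    hist.name = "n_genes"
    return hist, peaks


def orient_components(
    scores: pd.DataFrame,
    peaks: pd.Series,
    phase_blocks: dict[str, list[str]],
    loadings: pd.DataFrame | None = None,
    design: pd.Series | None = None,
    timepoint_order: list[str] | None = None,
) -> pd.DataFrame:
    """Fix the arbitrary PCA signs using the peak-time structure.

    PC1 is flipped so the mean PC1 of genes peaking in the growth block is
    positive; PC2 so the mean PC2 of genes peaking in the involution block
    is positive. If a block contains no peaking genes the axis falls back to
    correlating its loadings with the array time order (requires ``loadings``
    and ``design``).
    """
    oriented = scores.copy()
    for pc, phase in (("PC1", "growth"), ("PC2", "involution")):
        if pc not in oriented.columns:
            continue
        block = set(phase_blocks[phase])
        in_block = peaks.index[peaks.isin(block)]
        in_block = [g for g in in_block if g in oriented.index]
        if in_block:
            mean_score = oriented.loc[in_block, pc].mean()
        else:
            if loadings is None or design is None or timepoint_order is None:
                raise ValueError(
                    f"no genes peak in the {phase} block and no loadings/design "
                    "supplied for the fallback orientation"
                )
            logger.warning("orient_components: %s block empty; orienting %s by "
                           "time-order correlation", phase, pc)
            t_rank = design.map({tp: i for i, tp in enumerate(timepoint_order)})
            t_rank = t_rank.reindex(loadings.columns).to_numpy(dtype=float)
            mean_score = float(np.corrcoef(loadings.loc[pc].to_numpy(), t_rank)[0, 1])
            if phase == "growth":
                mean_score = -mean_score  # growth genes peak early
        if mean_score < 0:
            oriented[pc] = -oriented[pc]
            logger.info("orient_components: flipped %s", pc)
    return oriented


def assign_phase(oriented: pd.DataFrame, peaks: pd.Series | None = None) -> PhaseAssignment:
    """Quadrant rule on oriented scores.

    growth: PC1 > 0 (and the PC1 = 0 boundary); involution: PC1 <= 0 and
    PC2 > 0; lactation: PC1 <= 0 and PC2 <= 0. Exact zeros are measure-zero
    and logged when hit.
    """
    pc1 = oriented["PC1"].to_numpy(dtype=float)
    pc2 = oriented["PC2"].to_numpy(dtype=float)
    n_zero = int((pc1 == 0).sum() + ((pc1 <= 0) & (pc2 == 0)).sum())
    if n_zero:
        logger.info("assign_phase: %d boundary score(s) resolved by closure rule", n_zero)
    phase = np.where(pc1 >= 0, "growth",
                     np.where(pc2 > 0, "involution", "lactation"))
    # pc1 == 0 -> growth per the closure rule (>= catches it)
    table = pd.DataFrame({"pc1": pc1, "pc2": pc2, "phase": phase},
                         index=oriented.index)
    if peaks is not None:
        table["peak_timepoint"] = peaks.reindex(oriented.index)
    return PhaseAssignment(table=table)


def phase_pipeline(
    matrix: TimeCourseMatrix,
    dev_genes: GeneSet,
    phase_blocks: dict[str, list[str]],
) -> tuple[PhaseAssignment, PcaSummary]:
    """standardize -> PCA -> orient -> assign, in one call."""
    Z = standardize_profiles(matrix, dev_genes)
    scores, loadings, summary = pca_timecourse(Z)
    peaks = peak_timepoints(matrix, GeneSet("std", frozenset(Z.index)))
    oriented = orient_components(scores, peaks, phase_blocks, loadings=loadings,
                                 design=matrix.design,
                                 timepoint_order=matrix.timepoint_order)
    return assign_phase(oriented, peaks), summary
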