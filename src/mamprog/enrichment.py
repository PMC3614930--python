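"""2x2 set-overlap statistics: odds ratio, Fisher exact test, phase tables.

The odds ratio used throughout the pipeline is the odds of reference-list
membership inside a selected gene subset against the odds outside it:
OR = (p1/(1-p1)) / (p2/(1-p2)) where p1 and p2 are the annotated fractions
of the selected and rejected subsets — algebraically the cross-product ratio
a*d/(b*c) of the 2x2 table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd
import scipy.stats

from .data_model import GeneSet

logger = logging.getLogger("mamprog")


@dataclass(frozen=True)
class Contingency2x2:
    """Counts of a gene universe split by annotation and selection.

    a = annotated & selected, b = annotated & rejected,
    c = unannotated & selected, d = unannotated & rejected.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def p1(self) -> float:
        """Annotated fraction within the selected subset."""
        sel = self.a + self.c
        return self.a / sel if sel else math.nan

    @property
    def p2(self) -> float:
        """Annotated fraction within the rejected subset."""
        rej = self.b + self.d
        return self.b / rej if rej else math.nan


@dataclass(frozen=True)
class OddsRatioResult:
    value: float
    corrected: bool  # Haldane-Anscombe +0.5 applied

    def __float__(self) -> float:
        return self.value


def build_contingency(selected: GeneSet, annotated: GeneSet,
                      universe: GeneSet) -> Contingency2x2:
    """Cross-classify the universe by selection and annotation membership."""
    if len(universe) == 0:
        raise ValueError("empty universe")
    if not selected.ids <= universe.ids:
        raise ValueError("selected set must be a subset of the universe")
    ann = annotated.ids & universe.ids
    n_outside = len(annotated.ids - universe.ids)
    if n_outside:
        logger.info("build_contingency: dropped %d annotated ID(s) outside universe", n_outside)
    if not ann:
        logger.warning("build_contingency: annotated set disjoint from universe")
    a = len(ann & selected.ids)
    b = len(ann - selected.ids)
    c = len(selected.ids - ann)
    d = len(universe.ids - selected.ids - ann)
    return Contingency2x2(a, b, c, d)


def odds_ratio(t: Contingency2x2) -> OddsRatioResult:
    """Cross-product odds ratio a*d/(b*c) with zero-cell correction.

    If b or c is zero the Haldane-Anscombe 0.5 correction is added to all
    four cells and the result flagged. With no annotated genes at all
    (a = b = 0) the ratio is undefined and NaN is returned, flagged.
    """
    if t.a + t.b == 0:
        logger.warning("odds_ratio: no annotated genes; undefined")
        return OddsRatioResult(math.nan, True)
    if t.b == 0 or t.c == 0:
        a, b, c, d = (t.a + 0.5, t.b + 0.5, t.c + 0.5, t.d + 0.5)
        return OddsRatioResult((a * d) / (b * c), True)
    return OddsRatioResult((t.a * t.d) / (t.b * t.c), False)


def fisher_exact(t: Contingency2x2, alternative: str = "two_sided") -> float:
    """Fisher exact p-value of the 2x2 table with fixed margins.

    Two-sided p sums the probabilities of all tables with the same margins
    whose point probability does not exceed the observed one (the standard
    point-probability convention).
    """
    alt = {"two_sided": "two-sided", "greater": "greater"}.get(alternative)
    if alt is None:
        raise ValueError(f"unknown alternative {alternative!r}")
    _, p = scipy.stats.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative=alt)
    return float(p)


def phase_composition(phases: pd.Series, annotated: GeneSet) -> pd.DataFrame:
    """Annotated fraction per phase with pairwise Fisher comparisons.

    Parameters
    ----------
    phases : Series
        Gene id -> phase label.
    annotated : GeneSet
        Reference list (intersected with the phase universe).

    Returns a table indexed by phase with columns ``n_genes``,
    ``n_annotated``, ``fraction`` and ``fisher_p_vs_<other>`` per other phase.
    """
    universe = set(phases.index)
    ann = annotated.ids & universe
    labels = list(dict.fromkeys(phases))
    rows = {}
    for ph in labels:
        members = set(phases.index[phases == ph])
        n = len(members)
        k = len(members & ann)
        rows[ph] = {"n_genes": n, "n_annotated": k,
                    "fraction": k / n if n else math.nan}
        if n == 0:
            logger.warning("phase_composition: phase %r is empty", ph)
    df = pd.DataFrame.from_dict(rows, orient="index")
    for ph in labels:
        for other in labels:
            if other == ph:
                continue
            m1 = set(phases.index[phases == ph])
            m2 = set(phases.index[phases == other])
            t = Contingency2x2(
                a=len(m1 & ann), b=len(m2 & ann),
                c=len(m1 - ann), d=len(m2 - ann),
            )
            df.loc[ph, f"fisher_p_vs_{other}"] = (
                fisher_exact(t) if (len(m1) and len(m2)) else math.nan
            )
    return df
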