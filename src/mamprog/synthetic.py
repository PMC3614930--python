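"""Synthetic data with known ground truth.

Emulates the statistical structure the analysis assumes: a mouse mammary
gland pregnancy-cycle time course in which a subset of genes has a unimodal
expression bump peaking in the growth, lactation or involution phase with a
planted max/min amplitude; literature-style reference gene lists with
controlled recall and contamination; and human tumor cohorts with two latent
risk classes, planted log2-fold alterations on classifier genes, and
exponential survival with a planted hazard ratio under independent censoring.

Every artifact draws from its own pseudo-random stream derived from
``(seed, artifact_tag)``, so generating one artifact never perturbs another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data_model import (
    ABSENT,
    PRESENT,
    ClinicalTable,
    GeneSet,
    TimeCourseMatrix,
    TumorCohort,
)

#: Developmental time points of the mammary pregnancy cycle: virgin,
#: pregnancy days 1-17, lactation days 1-9, involution day 2.
DEFAULT_TIMEPOINTS = ["Vir", "P1", "P3", "P7", "P12", "P17", "L1", "L2", "L9", "Invol2"]

#: Phase blocks over the default time points. The boundary between late
#: pregnancy and lactation is a modeling choice; configurable.
DEFAULT_PHASE_BLOCKS = {
    "growth": ["Vir", "P1", "P3", "P7", "P12", "P17"],
    "lactation": ["L1", "L2", "L9"],
    "involution": ["Invol2"],
}

PHASES = ["growth", "lactation", "involution"]


def _rng(seed: int, tag: str) -> np.random.Generator:
    """Independent stream per (seed, artifact tag)."""
    return np.random.default_rng([seed, zlib.crc32(tag.encode())])


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with defaults mirroring the real one.

    Defaults: ~12k-probe chip scaled to 2000 genes with 35% low-expressed
    (Absent) probes; planted developmental amplitude of 3-fold; two replicate
    arrays per time point; a reference list recovering 75% of true
    developmental genes; tumor cohorts with 44% high-risk tumors and a
    planted hazard ratio of 3.5 (the range of reported breast-cancer
    classifier HRs).
    """

    seed: int = 0
    n_genes: int = 2000
    frac_growth: float = 0.15
    frac_lactation: float = 0.10
    frac_involution: float = 0.05
    planted_fold: float = 3.0
    background_fold_min: float = 1.6
    background_fold_max: float = 2.8
    noise_sd: float = 0.1
    replicates_per_timepoint: int = 2
    timepoints: list[str] = field(default_factory=lambda: list(DEFAULT_TIMEPOINTS))
    phase_blocks: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_PHASE_BLOCKS.items()}
    )
    absent_frac: float = 0.35
    lit_recall: float = 0.75
    lit_contamination: float = 0.3
    n_tumors: int = 100
    frac_high_risk: float = 0.44
    n_classifier_genes: int = 100
    classifier_log2fc: float = 1.5
    tumor_noise_sd: float = 1.0
    baseline_hazard: float = 0.01
    planted_hr: float = 3.5
    censor_rate: float = 0.01
    followup_max: float = 120.0

    def __post_init__(self) -> None:
        fracs = (self.frac_growth, self.frac_lactation, self.frac_involution,
                 self.absent_frac, self.lit_recall, self.lit_contamination,
                 self.frac_high_risk)
        if any(not (0.0 <= f <= 1.0) for f in fracs):
            raise ValueError("all fractions must lie in [0, 1]")
        if self.frac_growth + self.frac_lactation + self.frac_involution > 1.0:
            raise ValueError("phase fractions must sum to at most 1")
        if self.planted_fold < 1.0:
            raise ValueError("planted_fold must be >= 1")
        if not 1.0 <= self.background_fold_min <= self.background_fold_max:
            raise ValueError("need 1 <= background_fold_min <= background_fold_max")
        if self.planted_hr <= 0:
            raise ValueError("planted_hr must be positive")
        if self.replicates_per_timepoint < 2:
            raise ValueError("need at least 2 replicates per time point")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class DevTruth:
    """Ground truth of the developmental simulation.

    ``table`` is indexed by gene id with columns ``is_developmental`` (bool),
    ``true_phase`` ({growth, lactation, involution, none}) and ``is_absent``
    (bool).
    """

    table: pd.DataFrame

    @property
    def developmental(self) -> GeneSet:
        ids = self.table.index[self.table["is_developmental"]]
        return GeneSet("true_developmental", frozenset(ids), "simulation truth")

    def phase_genes(self, phase: str) -> GeneSet:
        ids = self.table.index[self.table["true_phase"] == phase]
        return GeneSet(f"true_{phase}", frozenset(ids), "simulation truth")


@dataclass
class CohortTruth:
    """Latent tumor classes and truly-altered gene flags for one cohort."""

    latent_class: pd.Series  # tumor_id -> "high" | "low"
    truly_altered: pd.Series  # gene_id -> bool


def _gene_ids(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"g{i:0{width}d}" for i in range(n)]


def simulate_development(config: SimulationConfig) -> tuple[TimeCourseMatrix, DevTruth]:
    """Simulate the developmental time course with planted phase structure.

    Developmental genes get a raised-cosine bump over their phase's
    time-point block such that (max time-point mean)/(min time-point mean)
    equals ``planted_fold`` exactly before noise. Non-developmental Present
    genes carry low-amplitude temporal variation — a bump at a uniformly
    random time point with max/min amplitude log-uniform on
    ``[background_fold_min, background_fold_max]`` — mirroring real chips where nearly all
    expressed probes vary significantly across the pregnancy cycle and the
    fold cutoff, not the ANOVA, is the discriminating filter. Replicate
    noise is log-normal with log-scale sd ``noise_sd``; ``absent_frac`` of
    the non-developmental genes are flat, low-intensity, and flagged Absent
    on every array.
    """
    rng = _rng(config.seed, "development")
    tps = config.timepoints
    n_tp = len(tps)
    reps = config.replicates_per_timepoint
    genes = _gene_ids(config.n_genes)

    n_growth = int(round(config.frac_growth * config.n_genes))
    n_lact = int(round(config.frac_lactation * config.n_genes))
    n_invol = int(round(config.frac_involution * config.n_genes))
    n_dev = n_growth + n_lact + n_invol
    n_absent = int(round(config.absent_frac * (config.n_genes - n_dev)))

    perm = rng.permutation(config.n_genes)
    phase_of = np.array(["none"] * config.n_genes, dtype=object)
    phase_of[perm[:n_growth]] = "growth"
    phase_of[perm[n_growth:n_growth + n_lact]] = "lactation"
    phase_of[perm[n_growth + n_lact:n_dev]] = "involution"
    is_absent = np.zeros(config.n_genes, dtype=bool)
    is_absent[perm[n_dev:n_dev + n_absent]] = True

    tp_index = {tp: i for i, tp in enumerate(tps)}
    log_fold = np.log(config.planted_fold)
    baseline = 100.0
    absent_level = 2.0
    bump_width = 2.5  # time-point index units; support always < full course

    profiles = np.empty((config.n_genes, n_tp))
    for i in range(config.n_genes):
        if is_absent[i]:
            profiles[i] = absent_level
            continue
        if phase_of[i] == "none":
            # background temporal variation, amplitude below the planted fold
            peak = int(rng.integers(n_tp))
            amp = rng.uniform(np.log(config.background_fold_min),
                              np.log(config.background_fold_max))
        else:
            block = config.phase_blocks[phase_of[i]]
            peak = tp_index[block[rng.integers(len(block))]]
            amp = log_fold
        dist = np.abs(np.arange(n_tp) - peak)
        bump = np.where(dist < bump_width,
                        0.5 * (1.0 + np.cos(np.pi * dist / bump_width)), 0.0)
        # exact fold: min of bump over time points is 0, max is 1
        profiles[i] = baseline * np.exp(amp * bump)

    arrays, design_tp = [], []
    for tp in tps:
        for r in range(reps):
            arrays.append(f"{tp}_r{r + 1}")
            design_tp.append(tp)
    means = np.repeat(profiles, reps, axis=1)
    if config.noise_sd > 0:
        noise = rng.normal(0.0, config.noise_sd, size=means.shape)
        values = means * np.exp(noise)
    else:
        values = means.copy()

    values_df = pd.DataFrame(values, index=genes, columns=arrays)
    calls = np.where(is_absent[:, None], ABSENT, PRESENT)
    calls_df = pd.DataFrame(np.broadcast_to(calls, values.shape).copy(),
                            index=genes, columns=arrays)
    design = pd.Series(design_tp, index=arrays)
    matrix = TimeCourseMatrix(values=values_df, design=design,
                              timepoint_order=list(tps), calls=calls_df)
    truth = DevTruth(pd.DataFrame({
        "is_developmental": phase_of != "none",
        "true_phase": phase_of,
        "is_absent": is_absent,
    }, index=genes))
    return matrix, truth


def simulate_reference_list(truth: DevTruth, recall: float, contamination: float,
                            seed: int) -> GeneSet:
    """Imperfect literature-style reference list of developmental genes.

    Samples ``recall * |true developmental|`` true genes plus enough
    non-developmental genes that they make up ``contamination`` of the final
    list, both without replacement.
    """
    if not (0.0 <= recall <= 1.0 and 0.0 <= contamination <= 1.0):
        raise ValueError("recall and contamination must lie in [0, 1]")
    rng = _rng(seed, "reference_list")
    true_ids = sorted(truth.developmental.ids)
    other_ids = sorted(set(truth.table.index) - set(true_ids))
    n_true = int(round(recall * len(true_ids)))
    if contamination >= 1.0:
        n_contam = len(other_ids)
    else:
        n_contam = int(round(n_true * contamination / (1.0 - contamination)))
    if n_contam > len(other_ids):
        raise ValueError("requested contamination exceeds available non-developmental genes")
    picked = list(rng.choice(true_ids, size=n_true, replace=False)) if n_true else []
    picked += list(rng.choice(other_ids, size=n_contam, replace=False)) if n_contam else []
    return GeneSet("reference_list", frozenset(picked),
                   f"simulated recall={recall} contamination={contamination}")


def simulate_tumor_cohort(config: SimulationConfig, classifier_genes: GeneSet,
                          seed: int, name: str = "cohort") -> tuple[TumorCohort, CohortTruth]:
    """Simulate one tumor cohort with two latent risk classes.

    On the classifier genes the two latent classes get opposite mean
    log2-ratio shifts, ``+classifier_log2fc`` for high-risk and
    ``-classifier_log2fc`` for low-risk tumors (sign fixed per gene), so
    each class is an internally coherent expression block as in real
    prognosis cohorts; survival is exponential
    with hazard ``baseline_hazard`` (low risk) or ``baseline_hazard *
    planted_hr`` (high risk), censored by an independent exponential clock at
    ``censor_rate`` truncated at ``followup_max`` months.
    """
    genes = _gene_ids(config.n_genes)
    missing = classifier_genes.ids - set(genes)
    if missing:
        raise ValueError(f"classifier gene(s) outside simulated universe: {sorted(missing)[:3]}")
    rng = _rng(seed, f"tumor_cohort:{name}")
    n = config.n_tumors
    tumor_ids = [f"{name}_t{i:03d}" for i in range(n)]
    n_high = int(round(config.frac_high_risk * n))
    latent = np.array(["low"] * n, dtype=object)
    latent[rng.permutation(n)[:n_high]] = "high"

    log_ratios = rng.normal(0.0, config.tumor_noise_sd, size=(config.n_genes, n))
    cls_idx = np.array([i for i, g in enumerate(genes) if g in classifier_genes.ids])
    signs = rng.choice([-1.0, 1.0], size=len(cls_idx))
    high_mask = latent == "high"
    if len(cls_idx):
        direction = np.where(high_mask, 1.0, -1.0)
        shift = np.outer(signs * config.classifier_log2fc, direction)
        log_ratios[cls_idx, :] += shift

    hazards = np.where(high_mask, config.baseline_hazard * config.planted_hr,
                       config.baseline_hazard)
    event_times = rng.exponential(1.0 / hazards)
    if config.censor_rate > 0:
        censor_times = rng.exponential(1.0 / config.censor_rate, size=n)
    else:
        censor_times = np.full(n, np.inf)
    censor_times = np.minimum(censor_times, config.followup_max)
    observed = np.minimum(event_times, censor_times)
    event = (event_times <= censor_times).astype(int)

    factors = _simulate_factors(rng, high_mask)
    clin = pd.DataFrame({
        "metastasis": event,
        "time_to_event": observed,
        "event": event,
        **factors,
    }, index=tumor_ids)
    cohort = TumorCohort(
        name=name,
        log_ratios=pd.DataFrame(log_ratios, index=genes, columns=tumor_ids),
        clinical=ClinicalTable(clin),
    )
    truly_altered = pd.Series(False, index=genes)
    if len(cls_idx):
        truly_altered.iloc[cls_idx] = True
    truth = CohortTruth(
        latent_class=pd.Series(latent, index=tumor_ids),
        truly_altered=truly_altered,
    )
    return cohort, truth


def _simulate_factors(rng: np.random.Generator, high_mask: np.ndarray) -> dict[str, list]:
    """Clinical risk factors weakly associated with the latent class."""
    n = len(high_mask)

    def pick(levels, p_high, p_low):
        out = []
        for h in high_mask:
            out.append(str(rng.choice(levels, p=p_high if h else p_low)))
        return out

    return {
        "size_class": pick(["<2cm", "2-5cm", ">5cm"],
                           [0.25, 0.60, 0.15], [0.55, 0.40, 0.05]),
        "grade": pick(["1", "2", "3"], [0.10, 0.30, 0.60], [0.40, 0.40, 0.20]),
        "er_status": pick(["positive", "negative"], [0.60, 0.40], [0.85, 0.15]),
        "angioinvasion": pick(["0", "1"], [0.55, 0.45], [0.85, 0.15]),
        "lymphocytic_infiltrate": pick(["0", "1"], [0.70, 0.30], [0.90, 0.10]),
        "node_status": pick(["negative", "positive"], [0.45, 0.55], [0.65, 0.35]),
    }


def write_truth(truth: DevTruth, path) -> None:
    truth.table.to_csv(path, sep="\t", index_label="gene_id")
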