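"""End-to-end pipeline: simulate -> devgenes -> phases -> enrich ->
classifier -> prognosis, from a single JSON-able config.

Every stage reads and writes files in the data_model formats inside one
working directory and contributes a stanza (input digests, parameters, key
numbers) to a machine-readable run report. Outputs are pure functions of
(inputs, parameters, seed); the report isolates its timestamp in a single
field so determinism is directly testable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import classifier as clf
from . import devgenes, enrichment, phase_pca, prognosis
from .data_model import (
    GeneSet,
    read_cohort,
    read_expression,
    read_gene_set,
    write_cohort,
    write_expression,
    write_gene_set,
)
from .synthetic import (
    SimulationConfig,
    simulate_development,
    simulate_reference_list,
    simulate_tumor_cohort,
    write_truth,
)

logger = logging.getLogger("mamprog")

ALL_STAGES = ["simulate", "devgenes", "phases", "enrich", "classifier", "prognosis"]

DEFAULT_PARAMS = {
    "p_cut": 0.01,
    "fold_grid": list(devgenes.DEFAULT_GRID),
    "min_present_frac": 0.5,
    "min_count": 2,
    "abs_log2fc_cut": 1.0,
    "altered_p_cut": 0.01,
    "n_cohorts": 5,
    "cluster_metric": "correlation",
    "cluster_linkage": "average",
    "endpoint": "metastasis",
    "cancer_list_recall": 0.6,
    "cancer_list_contamination": 0.4,
}


class PipelineError(RuntimeError):
    pass


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _require(workdir: Path, names: list[str], stage: str) -> dict[str, str]:
    digests = {}
    for name in names:
        p = workdir / name
        if not p.exists():
            raise PipelineError(f"stage {stage!r}: missing input file {name}")
        digests[name] = _digest(p)
    return digests


def run_pipeline(config: dict, workdir: str | Path) -> dict:
    """Run the requested stages in dependency order and write report.json.

    ``config`` holds a ``seed``, optional ``stages`` list, a ``simulation``
    sub-dict overriding SimulationConfig fields, and any of the
    DEFAULT_PARAMS analysis knobs.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    params = {**DEFAULT_PARAMS, **{k: v for k, v in config.items()
                                   if k in DEFAULT_PARAMS}}
    seed = int(config.get("seed", 0))
    sim_cfg = SimulationConfig(seed=seed, **config.get("simulation", {}))
    stages = config.get("stages", ALL_STAGES)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise PipelineError(f"unknown stage(s): {sorted(unknown)}")

    report: dict = {"config": {**params, "seed": seed,
                               "simulation": sim_cfg.to_dict()},
                    "stages": {}, "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S")}
    runners = {
        "simulate": _stage_simulate, "devgenes": _stage_devgenes,
        "phases": _stage_phases, "enrich": _stage_enrich,
        "classifier": _stage_classifier, "prognosis": _stage_prognosis,
    }
    for stage in ALL_STAGES:
        if stage not in stages:
            continue
        logger.info("[%s] starting", stage)
        try:
            report["stages"][stage] = runners[stage](workdir, params, sim_cfg)
        except Exception as exc:
            (workdir / "FAILED").write_text(f"{stage}: {exc}\n")
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    (workdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


# --- stages -----------------------------------------------------------------


def _stage_simulate(workdir: Path, params: dict, sim_cfg: SimulationConfig) -> dict:
    matrix, truth = simulate_development(sim_cfg)
    write_expression(matrix, workdir / "timecourse.tsv", workdir / "design.tsv",
                     workdir / "calls.tsv")
    write_truth(truth, workdir / "truth.tsv")
    ref = simulate_reference_list(truth, sim_cfg.lit_recall,
                                  sim_cfg.lit_contamination, sim_cfg.seed)
    write_gene_set(ref, workdir / "reference_mammary.txt")

    # planted classifier genes: a sample of the true developmental genes
    rng = np.random.default_rng([sim_cfg.seed, zlib.crc32(b"classifier_genes")])
    dev_ids = sorted(truth.developmental.ids)
    n_cls = min(sim_cfg.n_classifier_genes, len(dev_ids))
    planted = GeneSet("planted_classifier",
                      frozenset(rng.choice(dev_ids, size=n_cls, replace=False)),
                      "simulation truth")
    write_gene_set(planted, workdir / "planted_classifier.txt")

    # literature-style cancer-modulated list: recalls the planted classifier
    # genes with contamination from the remaining genes
    all_ids = sorted(truth.table.index)
    others = sorted(set(all_ids) - planted.ids)
    n_true = int(round(params["cancer_list_recall"] * len(planted.ids)))
    cont = params["cancer_list_contamination"]
    n_cont = int(round(n_true * cont / (1.0 - cont))) if cont < 1 else len(others)
    cancer_ids = list(rng.choice(sorted(planted.ids), size=n_true, replace=False))
    cancer_ids += list(rng.choice(others, size=min(n_cont, len(others)), replace=False))
    write_gene_set(GeneSet("cancer_modulated", frozenset(cancer_ids), "simulated"),
                   workdir / "reference_cancer.txt")

    latent = {}
    # derivation cohorts emulate "altered vs reference pool" databases: the
    # planted alteration is a property of the tumors as a class. Each cohort
    # additionally alters a database-specific random subset of developmental
    # genes, so alteration counts grade over the full Sub0..SubK range.
    derivation_cfg = dataclasses.replace(sim_cfg, frac_high_risk=1.0)
    non_classifier_dev = sorted(set(dev_ids) - planted.ids)
    n_extra = min(n_cls // 2, len(non_classifier_dev) // 5)
    for k in range(params["n_cohorts"]):
        extra = rng.choice(non_classifier_dev, size=n_extra, replace=False)
        cohort_genes = GeneSet(f"altered_truth_cohort{k + 1}",
                               planted.ids | frozenset(extra))
        cohort, ctruth = simulate_tumor_cohort(derivation_cfg, cohort_genes,
                                               sim_cfg.seed, name=f"cohort{k + 1}")
        write_cohort(cohort, workdir / f"cohort{k + 1}.tsv",
                     workdir / f"cohort{k + 1}_clinical.tsv")
        latent[cohort.name] = ctruth.latent_class
    val_cohort, val_truth = simulate_tumor_cohort(sim_cfg, planted, sim_cfg.seed,
                                                  name="validation")
    write_cohort(val_cohort, workdir / "validation.tsv",
                 workdir / "validation_clinical.tsv")
    latent["validation"] = val_truth.latent_class
    pd.DataFrame(latent).to_csv(workdir / "latent_classes.tsv", sep="\t",
                                index_label="tumor_id")
    (workdir / "sim_config.json").write_text(
        json.dumps(sim_cfg.to_dict(), indent=2, sort_keys=True) + "\n")
    return {
        "inputs": {},
        "parameters": {"seed": sim_cfg.seed},
        "key_numbers": {
            "n_genes": sim_cfg.n_genes,
            "n_true_developmental": int(truth.table["is_developmental"].sum()),
            "n_planted_classifier": len(planted),
        },
    }


def _read_timecourse(workdir: Path):
    return read_expression(workdir / "timecourse.tsv", workdir / "design.tsv",
                           workdir / "calls.tsv")


def _stage_devgenes(workdir: Path, params: dict, sim_cfg: SimulationConfig) -> dict:
    digests = _require(workdir, ["timecourse.tsv", "design.tsv", "calls.tsv",
                                 "reference_mammary.txt"], "devgenes")
    matrix = _read_timecourse(workdir)
    reference = read_gene_set(workdir / "reference_mammary.txt", "reference_mammary")
    curve = devgenes.optimize_fold_cutoff(
        matrix, reference, p_cut=params["p_cut"], grid=params["fold_grid"],
        min_present_frac=params["min_present_frac"])
    present = devgenes.present_filter(matrix, params["min_present_frac"])
    anova_p = devgenes.anova_across_timepoints(present)
    fold = devgenes.max_min_fold(present)
    table = devgenes.build_dev_table(anova_p, fold, params["p_cut"], curve.best_cutoff)
    table.table.to_csv(workdir / "devgene_table.tsv", sep="\t", index_label="gene_id")
    curve.to_frame().to_csv(workdir / "cutoff_curve.tsv", sep="\t", index=False)
    write_gene_set(table.selected, workdir / "dev_genes.txt")
    return {
        "inputs": digests,
        "parameters": {k: params[k] for k in
                       ("p_cut", "fold_grid", "min_present_frac")},
        "key_numbers": {
            "n_present": len(present.gene_ids),
            "n_p_passing": int((anova_p < params["p_cut"]).sum()),
            "best_cutoff": curve.best_cutoff,
            "best_odds_ratio": curve.best_or,
            "n_developmental": len(table.selected),
            "dev_fraction_of_present": len(table.selected) / len(present.gene_ids),
        },
    }


def _stage_phases(workdir: Path, params: dict, sim_cfg: SimulationConfig) -> dict:
    digests = _require(workdir, ["timecourse.tsv", "design.tsv", "dev_genes.txt"],
                       "phases")
    matrix = _read_timecourse(workdir)
    dev = read_gene_set(workdir / "dev_genes.txt", "developmental")
    assignment, summary = phase_pca.phase_pipeline(matrix, dev, sim_cfg.phase_blocks)
    assignment.table.to_csv(workdir / "phases.tsv", sep="\t", index_label="gene_id")
    hist, _ = phase_pca.peak_histogram(matrix, dev)
    hist.to_csv(workdir / "peak_histogram.tsv", sep="\t", index_label="time_point")
    pd.DataFrame({"variance_fraction": summary.variance_fractions}).to_csv(
        workdir / "pca_summary.tsv", sep="\t", index_label="component")
    counts = assignment.phases.value_counts().to_dict()
    return {
        "inputs": digests,
        "parameters": {"phase_blocks": sim_cfg.phase_blocks},
        "key_numbers": {
            "n_nonzero_components": summary.n_nonzero,
            "pc1_variance_fraction": float(summary.variance_fractions[0]),
            **{f"n_{ph}": int(counts.get(ph, 0)) for ph in
               ("growth", "lactation", "involution")},
        },
    }


def _stage_enrich(workdir: Path, params: dict, sim_cfg: SimulationConfig) -> dict:
    digests = _require(workdir, ["dev_genes.txt", "reference_cancer.txt",
                                 "devgene_table.tsv", "phases.tsv"], "enrich")
    dev = read_gene_set(workdir / "dev_genes.txt", "developmental")
    cancer = read_gene_set(workdir / "reference_cancer.txt", "cancer_modulated")
    table = pd.read_csv(workdir / "devgene_table.tsv", sep="\t", index_col=0)
    universe = GeneSet("present_universe", frozenset(table.index.astype(str)))
    t = enrichment.build_contingency(dev.intersect(universe.ids), cancer, universe)
    or_res = enrichment.odds_ratio(t)
    p = enrichment.fisher_exact(t)
    phases = pd.read_csv(workdir / "phases.tsv", sep="\t", index_col=0)["phase"]
    comp = enrichment.phase_composition(phases, cancer)
    comp.to_csv(workdir / "phase_composition.tsv", sep="\t")
    row = pd.DataFrame([{"a": t.a, "b": t.b, "c": t.c, "d": t.d,
                         "p1": t.p1, "p2": t.p2, "odds_ratio": or_res.value,
                         "fisher_p": p, "corrected": or_res.corrected}])
    row.to_csv(workdir / "enrichment.tsv", sep="\t", index=False)
    coverage = t.a / (t.a + t.b) if (t.a + t.b) else float("nan")
    return {
        "inputs": digests,
        "parameters": {},
        "key_numbers": {"odds_ratio": or_res.value, "fisher_p": p,
                        "cancer_gene_coverage": coverage},
    }


def _stage_classifier(workdir: Path, params: dict, sim_cfg: SimulationConfig) -> dict:
    names = ["dev_genes.txt", "reference_cancer.txt"]
    names += [f"cohort{k + 1}.tsv" for k in range(params["n_cohorts"])]
    names += [f"cohort{k + 1}_clinical.tsv" for k in range(params["n_cohorts"])]
    digests = _require(workdir, names, "classifier")
    dev = read_gene_set(workdir / "dev_genes.txt", "developmental")
    cancer = read_gene_set(workdir / "reference_cancer.txt", "cancer_modulated")
    altered = []
    for k in range(params["n_cohorts"]):
        cohort = read_cohort(workdir / f"cohort{k + 1}.tsv",
                             workdir / f"cohort{k + 1}_clinical.tsv",
                             name=f"cohort{k + 1}")
        altered.append(clf.call_altered(cohort, params["abs_log2fc_cut"],
                                        params["altered_p_cut"]))
    am = clf.count_alterations(dev, altered)
    am.flags.to_csv(workdir / "alteration_matrix.tsv", sep="\t",
                    index_label="gene_id")
    cls = clf.derive_classifier(am, params["min_count"])
    write_gene_set(cls.ids, workdir / "classifier_genes.txt")
    sub = clf.subset_annotation_table(am, cancer)
    sub.to_csv(workdir / "subset_table.tsv", sep="\t")
    return {
        "inputs": digests,
        "parameters": {k: params[k] for k in
                       ("abs_log2fc_cut", "altered_p_cut", "min_count", "n_cohorts")},
        "key_numbers": {
            "classifier_size": len(cls.ids),
            **{f"sub{k}_n": int(sub.loc[f"Sub{k}", "n_genes"])
               for k in range(params["n_cohorts"] + 1)},
        },
    }


def _stage_prognosis(workdir: Path, params: dict, sim_cfg: SimulationConfig) -> dict:
    digests = _require(workdir, ["validation.tsv", "validation_clinical.tsv",
                                 "classifier_genes.txt"], "prognosis")
    cohort = read_cohort(workdir / "validation.tsv",
                         workdir / "validation_clinical.tsv", name="validation")
    genes = read_gene_set(workdir / "classifier_genes.txt", "prognosis_classifier")
    labels = prognosis.cluster_two_groups(cohort, genes,
                                          metric=params["cluster_metric"],
                                          linkage=params["cluster_linkage"])
    part = prognosis.label_risk(labels, cohort.clinical, endpoint=params["endpoint"])
    clin = cohort.clinical.table.loc[part.risk.index]
    comp = prognosis.survival_comparison(clin["time_to_event"],
                                         clin["event"].astype(int), part.risk)
    pd.DataFrame({"cluster": part.labels, "risk": part.risk}).to_csv(
        workdir / "risk_partition.tsv", sep="\t", index_label="tumor_id")
    for gname, curve in comp.km_curves.items():
        curve.to_csv(workdir / f"km_{gname}.tsv", sep="\t", index=False)

    factor_rows = [{"factor": "classifier", "hr": comp.hazard_ratio,
                    "ci_low": comp.hr_ci95[0], "ci_high": comp.hr_ci95[1]}]
    factor_positive = {
        "size_class": {"2-5cm", ">5cm"}, "grade": {"3"},
        "er_status": {"negative"}, "angioinvasion": {"1"},
        "lymphocytic_infiltrate": {"1"}, "node_status": {"positive"},
    }
    for factor, pos in factor_positive.items():
        try:
            hr, ci, flag = prognosis.clinical_factor_hr(cohort.clinical, factor, pos)
        except ValueError:
            continue
        factor_rows.append({"factor": factor, "hr": hr, "ci_low": ci[0],
                            "ci_high": ci[1]})
    pd.DataFrame(factor_rows).to_csv(workdir / "hr_comparison.tsv", sep="\t",
                                     index=False)
    dist = prognosis.risk_factor_distribution(part, cohort.clinical,
                                              endpoint=params["endpoint"])
    dist.to_csv(workdir / "risk_factor_distribution.tsv", sep="\t")
    prediction = {
        "accuracy": part.accuracy,
        "fisher_p": part.fisher_p,
        "confusion": dataclasses.asdict(part.confusion),
    }
    (workdir / "prediction.json").write_text(
        json.dumps(prediction, indent=2, sort_keys=True) + "\n")
    return {
        "inputs": digests,
        "parameters": {k: params[k] for k in
                       ("cluster_metric", "cluster_linkage", "endpoint")},
        "key_numbers": {
            "accuracy": part.accuracy,
            "fisher_p": part.fisher_p,
            "hazard_ratio": comp.hazard_ratio,
            "hr_ci_low": comp.hr_ci95[0],
            "hr_ci_high": comp.hr_ci95[1],
            "logrank_p": comp.logrank_p,
            "n_high_risk": int((part.risk == "high").sum()),
        },
    }
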