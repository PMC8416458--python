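"""End-to-end pipeline: simulate -> QC -> classify -> comet -> BMC -> report.

Drives the whole analysis on a simulated study with known ground truth and
writes plain-text artifacts (TSV/CSV/JSON) to an output directory.  The run
is fully determined by the configuration (including the seed): rerunning
with the same configuration reproduces the same tables.
"""

from __future__ import annotations

import json
import hashlib
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import bmc as bmcmod
from . import classify as cls
from . import comet as cometmod
from . import qc as qcmod
from . import synthetic as syn
from .integrate import combine_calls, potency_report

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "analyze_experiment"]


@dataclass
class PipelineConfig:
    """Configuration for a full simulated-study run."""

    seed: int = 0
    n_chemicals_ddi: int = 3
    n_chemicals_non_ddi: int = 1
    bmc_range: tuple[float, float] = (5.0, 500.0)
    simulation: syn.SimulationConfig = None
    bmc: bmcmod.BmcConfig = None
    nsc_delta: float | None = None        # None -> choose by cross-validation
    posterior_threshold: float = 0.90
    pca_epsilon: float = 0.10
    alpha: float = 0.05
    viability_threshold: float = 40.0
    run_bootstrap: bool = True

    def __post_init__(self) -> None:
        if self.simulation is None:
            self.simulation = syn.SimulationConfig(seed=self.seed)
        if self.bmc is None:
            self.bmc = bmcmod.BmcConfig()


@dataclass
class PipelineResult:
    truths: dict[str, syn.GroundTruth]
    calls: pd.DataFrame                 # per chemical x concentration
    integrated: pd.DataFrame
    accuracy: dict[str, float]
    potency: pd.DataFrame
    comet_results: dict[str, object]
    tgx_bmc: dict[str, bmcmod.GeneSetBMC]
    comet_bmc: dict[str, bmcmod.BMCEstimate]
    exclusions: pd.DataFrame
    provenance: dict = field(default_factory=dict)


def default_truths(cfg: PipelineConfig) -> dict[str, syn.GroundTruth]:
    """Ground truths with BMCs log-spaced over the configured range."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 917]))
    truths = {}
    n = cfg.n_chemicals_ddi
    bmcs = np.geomspace(*cfg.bmc_range, num=max(n, 1))
    for i in range(n):
        b = float(bmcs[i])
        truths[f"DDICHEM{i+1:02d}"] = syn.GroundTruth(
            chemical_id=f"DDICHEM{i+1:02d}", is_ddi=True,
            true_bmc_tgx=b, true_bmc_comet=b * float(rng.uniform(0.8, 1.25)),
            viability_ec50=b * 16.0)
    for i in range(cfg.n_chemicals_non_ddi):
        truths[f"NEGCHEM{i+1:02d}"] = syn.GroundTruth(
            chemical_id=f"NEGCHEM{i+1:02d}", is_ddi=False)
    return truths


def analyze_experiment(exp: syn.SimulatedExperiment, training: cls.TrainingSet,
                       cfg: PipelineConfig, delta: float):
    """QC + classification + comet + BMC for a single chemical's experiment."""
    scfg = exp.config
    metrics = qcmod.qc_metrics(exp.counts)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        flags = qcmod.flag_metric_outliers(metrics)
        norm = qcmod.normalize_counts(exp.counts)
        singles = qcmod.detect_singletons(norm.log2_shifted)
        exclusions = qcmod.filter_samples(
            metrics, exp.metadata, exp.viability, flags, singles,
            viability_threshold=cfg.viability_threshold)
    cytotoxic = set(qcmod.cytotoxic_concentrations(
        exp.viability, cfg.viability_threshold)["concentration_uM"])

    drop = set(exclusions.loc[exclusions["reason"] != "cytotoxic", "sample_id"])
    usable = [s for s in exp.counts.columns if s not in drop]
    log2 = norm.log2_shifted[usable]
    gene_level = cls.collapse_probes(log2, exp.probe_gene_map,
                                    required_genes=pd.Index(training.genes))
    # vehicle groups (concentration 0) are never cytotoxic by construction
    meta = exp.metadata[exp.metadata["sample_id"].isin(usable)
                        & ~exp.metadata["concentration_uM"].isin(cytotoxic)]
    profiles, _ = cls.condition_log2fc(gene_level, meta)
    calls = cls.classify_conditions(training, profiles, delta,
                                    cfg.posterior_threshold, cfg.pca_epsilon)

    comet_res = cometmod.analyze_comet_table(
        exp.comet, {exp.truth.chemical_id: cytotoxic}, cfg.alpha
    )[exp.truth.chemical_id]
    return dict(calls=calls, comet=comet_res, cytotoxic=cytotoxic,
                gene_level=gene_level, log2=log2, exclusions=exclusions,
                metadata=meta)


def run_pipeline(cfg: PipelineConfig, outdir: str | Path | None = None,
                 truths: dict[str, syn.GroundTruth] | None = None,
                 ) -> PipelineResult:
    """Execute the full pipeline; optionally write artifacts to ``outdir``."""
    scfg = cfg.simulation
    training_mat, training_labels = syn.generate_training_set(scfg)
    training = cls.TrainingSet(training_mat, training_labels)
    delta = cfg.nsc_delta if cfg.nsc_delta is not None else \
        cls.choose_delta(training, seed=cfg.seed)

    if truths is None:
        truths = default_truths(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 40121]))

    call_rows, comet_results = [], {}
    tgx_chem_calls, comet_chem_calls = {}, {}
    tgx_bmc: dict[str, bmcmod.GeneSetBMC] = {}
    comet_bmc: dict[str, bmcmod.BMCEstimate] = {}
    exclusion_frames = []
    for chem, truth in truths.items():
        exp = syn.generate_test_experiment(truth, scfg)
        res = analyze_experiment(exp, training, cfg, delta)
        exclusion_frames.append(res["exclusions"].assign(chemical=chem))
        comet_results[chem] = res["comet"]
        per_conc = {c.concentration: c.overall for c in res["calls"]}
        tgx_overall = cls.chemical_call(per_conc, res["cytotoxic"])
        tgx_chem_calls[chem] = "+" if tgx_overall == cls.DDI else (
            "U" if tgx_overall == cls.UNCLASSIFIED else "-")
        comet_chem_calls[chem] = "+" if res["comet"].positive_call else "-"
        for c in res["calls"]:
            call_rows.append(dict(
                chemical=chem, concentration_uM=c.concentration,
                pa=c.pa_call, pca=c.pca_call, hc=c.hc_call,
                posterior_ddi=c.posterior_ddi, overall=c.overall,
                cytotoxic=c.concentration in res["cytotoxic"]))

        # BMC modeling only for positive calls, cytotoxic concentrations removed
        if tgx_chem_calls[chem] == "+":
            gene_series = bmcmod.gene_series_from_profiles(
                res["gene_level"], exp.metadata, chem,
                genes=list(training.genes),
                exclude_concentrations=res["cytotoxic"])
            if cfg.run_bootstrap:
                tgx_bmc[chem] = bmcmod.bootstrap_bmc_ci(gene_series, cfg.bmc, rng)
            else:
                retained = bmcmod.williams_prefilter(gene_series, cfg.bmc, rng)
                per_gene = {g: bmcmod.estimate_bmc(s, cfg.bmc, rng=rng)
                            for g, s in gene_series.items()
                            if retained[g]["retained"]}
                med, nmod = bmcmod.gene_set_median_bmc(per_gene)
                tgx_bmc[chem] = bmcmod.GeneSetBMC(
                    per_gene=per_gene, n_genes_modeled=nmod, median_bmc=med)
        if comet_chem_calls[chem] == "+":
            series = bmcmod.comet_series_from_table(
                exp.comet, chem, exclude_concentrations=res["cytotoxic"])
            comet_bmc[chem] = bmcmod.estimate_bmc(series, cfg.bmc, rng=rng)

    expected = {c: ("positive" if t.is_ddi else "negative")
                for c, t in truths.items()}
    integrated, accuracy = combine_calls(comet_chem_calls, tgx_chem_calls, expected)

    cc = {c: e.bmc for c, e in comet_bmc.items()
          if e.passed_filters and np.isfinite(e.bmc)}
    tgx_boot = {c: g.bootstrap_median for c, g in tgx_bmc.items()
                if g.bootstrap_median is not None}
    tgx_med = {c: g.median_bmc for c, g in tgx_bmc.items()
               if g.median_bmc is not None}
    potency = potency_report(cc, tgx_boot or tgx_med, tgx_med)

    calls = pd.DataFrame(call_rows)
    exclusions = (pd.concat(exclusion_frames, ignore_index=True)
                  if exclusion_frames else pd.DataFrame(columns=["sample_id", "reason"]))
    provenance = dict(seed=cfg.seed, nsc_delta=delta,
                      config_hash=_config_hash(cfg))
    result = PipelineResult(truths=truths, calls=calls, integrated=integrated,
                            accuracy=accuracy, potency=potency,
                            comet_results=comet_results, tgx_bmc=tgx_bmc,
                            comet_bmc=comet_bmc, exclusions=exclusions,
                            provenance=provenance)
    if outdir is not None:
        _write_artifacts(result, Path(outdir))
    return result


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_artifacts(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.calls.to_csv(outdir / "classification_calls.tsv", sep="\t", index=False)
    result.integrated.to_csv(outdir / "integrated_calls.tsv", sep="\t", index=False)
    pot = result.potency.copy()
    pot.to_csv(outdir / "potency.tsv", sep="\t", na_rep="n.m.")
    result.exclusions.to_csv(outdir / "exclusions.tsv", sep="\t", index=False)
    summary = dict(
        accuracy=result.accuracy,
        provenance=result.provenance,
        tgx_bmc={c: dict(median=g.median_bmc, bootstrap_median=g.bootstrap_median,
                         ci95=g.ci95, n_genes_modeled=g.n_genes_modeled)
                 for c, g in result.tgx_bmc.items()},
        comet_bmc={c: dict(bmc=e.bmc, bmcl=e.bmcl, bmcu=e.bmcu,
                           model=e.fit.model_name if e.fit else None,
                           passed=e.passed_filters)
                   for c, e in result.comet_bmc.items()},
    )
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
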