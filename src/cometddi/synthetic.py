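"""Synthetic TempO-Seq-like experiments with known genotoxicity ground truth.

Emulates the design of an integrated HepaRG genotoxicity study: a targeted
probe panel sequenced to ~1M reads per sample, a 64-gene DNA-damage biomarker
whose log2 fold changes follow a saturating (Hill) concentration-response for
DNA-damage-inducing (DDI) chemicals, CometChip median % tail DNA with a
monotone concentration-response, and declining logistic viability curves.

Every generator is driven by a single top-level seed; per-chemical child
seeds are spawned deterministically so partial reruns reproduce exactly.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedExperiment",
    "generate_training_set",
    "generate_test_experiment",
    "generate_corrupt_samples",
    "expected_log2fc",
    "expected_tail_dna",
    "expected_viability",
    "default_concentrations",
    "write_experiment",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the simulated study design.

    Defaults mirror the emulated study: a 64-gene biomarker inside a targeted
    panel, 14 reference compounds per class (28 total), five concentrations
    with n = 4 replicates, and a 1M-read target depth.  ``noise_sd`` is the
    log2-scale residual SD used both for training-set noise and for
    calibrating where the Hill curve departs control by one SD.
    """

    n_biomarker_genes: int = 64
    n_background_probes: int = 436
    n_reference_compounds_per_class: int = 14
    n_concentrations: int = 5
    n_replicates: int = 4
    effect_size_log2: float = 2.0
    noise_sd: float = 0.3
    dispersion: float = 0.05
    depth_target: int = 1_000_000
    hill_coef: float = 2.0
    size_factor_jitter: float = 0.15
    comet_baseline: float = 3.0
    comet_max_increase: float = 25.0
    comet_noise_sd: float = 1.2
    viability_slope: float = 3.0
    viability_noise_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_biomarker_genes", "n_background_probes",
                     "n_reference_compounds_per_class", "n_concentrations",
                     "n_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def n_probes(self) -> int:
        return self.n_biomarker_genes + self.n_background_probes

    def biomarker_genes(self) -> list[str]:
        return [f"BMK{i:03d}" for i in range(1, self.n_biomarker_genes + 1)]

    def gene_signs(self) -> np.ndarray:
        """Designated response direction per biomarker gene.

        The first half of the panel is up-regulated by DDI exposure and the
        second half down-regulated, mimicking a biomarker containing both
        induced and repressed DNA-damage-response genes.
        """
        signs = np.ones(self.n_biomarker_genes)
        signs[self.n_biomarker_genes // 2:] = -1.0
        return signs


@dataclass(frozen=True)
class GroundTruth:
    """True potency parameters for one simulated chemical.

    ``true_bmc_tgx`` is the concentration at which responsive biomarker
    genes' expected |log2 fold change| equals the residual noise SD (the
    1SD benchmark response); finite only for DDI chemicals.
    """

    chemical_id: str
    is_ddi: bool
    true_bmc_tgx: float | None = None
    true_bmc_comet: float | None = None
    viability_ec50: float | None = None

    def __post_init__(self) -> None:
        for name in ("true_bmc_tgx", "true_bmc_comet", "viability_ec50"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not self.is_ddi and self.true_bmc_tgx is not None:
            raise ValueError(
                "non-DDI chemical cannot have a finite transcriptomic BMC")


@dataclass
class SimulatedExperiment:
    """All artifacts of one simulated chemical exposure series."""

    truth: GroundTruth
    config: SimulationConfig
    concentrations: np.ndarray
    counts: pd.DataFrame            # probes x samples, raw integer counts
    probe_gene_map: pd.Series       # probe id -> gene symbol
    metadata: pd.DataFrame          # sample_id, chemical, concentration_uM, replicate, is_vehicle
    comet: pd.DataFrame             # chemical, concentration_uM, well, median_pct_tail_dna
    viability: pd.DataFrame         # chemical, concentration_uM, pct_viability
    true_size_factors: pd.Series = field(default=None)


def _child_rng(seed: int, *stream) -> np.random.Generator:
    """Deterministic child generator for a named sub-stream.

    String stream labels are folded in through CRC32 (stable across runs and
    platforms, unlike the salted built-in ``hash``).
    """
    entropy = [int(seed)] + [zlib.crc32(s.encode()) if isinstance(s, str) else int(s)
                             for s in stream]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def hill_response(conc, emax: float, k: float, h: float):
    """Saturating Hill curve ``emax * c^h / (c^h + k^h)`` (0 at c = 0)."""
    c = np.asarray(conc, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = emax * c**h / (c**h + k**h)
    return np.where(c > 0, r, 0.0)


def hill_k_for_bmc(bmc: float, emax: float, sd: float, h: float) -> float:
    """Half-max constant K such that the Hill curve crosses ``sd`` at ``bmc``.

    Closed-form inversion of ``emax * bmc^h / (bmc^h + K^h) = sd``; requires
    ``emax > sd`` so the curve actually reaches a 1SD departure.
    """
    if not emax > sd > 0:
        raise ValueError("need effect amplitude > noise SD > 0 to calibrate")
    return bmc * ((emax - sd) / sd) ** (1.0 / h)


def expected_log2fc(truth: GroundTruth, cfg: SimulationConfig, conc) -> np.ndarray:
    """Noise-free |log2 FC| of a responsive biomarker gene at ``conc``.

    Returns zeros for non-DDI chemicals at every concentration.
    """
    if not truth.is_ddi or truth.true_bmc_tgx is None:
        return np.zeros_like(np.asarray(conc, dtype=float))
    k = hill_k_for_bmc(truth.true_bmc_tgx, cfg.effect_size_log2,
                       cfg.noise_sd, cfg.hill_coef)
    return hill_response(conc, cfg.effect_size_log2, k, cfg.hill_coef)


def expected_tail_dna(truth: GroundTruth, cfg: SimulationConfig, conc) -> np.ndarray:
    """Noise-free median % tail DNA at ``conc`` (baseline for inert chemicals)."""
    base = np.full_like(np.asarray(conc, dtype=float), cfg.comet_baseline)
    if truth.true_bmc_comet is None:
        return base
    k = hill_k_for_bmc(truth.true_bmc_comet, cfg.comet_max_increase,
                       cfg.comet_noise_sd, cfg.hill_coef)
    return base + hill_response(conc, cfg.comet_max_increase, k, cfg.hill_coef)


def expected_viability(truth: GroundTruth, cfg: SimulationConfig, conc) -> np.ndarray:
    """Noise-free % viability: declining logistic with midpoint at the EC50."""
    c = np.asarray(conc, dtype=float)
    if truth.viability_ec50 is None:
        return np.full_like(c, 100.0)
    with np.errstate(over="ignore"):
        v = 100.0 / (1.0 + (c / truth.viability_ec50) ** cfg.viability_slope)
    return v


def default_concentrations(truth: GroundTruth, cfg: SimulationConfig) -> np.ndarray:
    """Five-point geometric concentration series bracketing the true BMC.

    For DDI chemicals the series spans 1/4x to 4x the transcriptomic BMC
    (mirroring range-finding around an expected active concentration); for
    inert chemicals a generic high-concentration series is used.
    """
    n = cfg.n_concentrations
    anchor = truth.true_bmc_tgx or truth.true_bmc_comet
    if anchor is None:
        return 10_000.0 * 2.0 ** np.arange(-(n - 1), 1)
    mid = (n - 1) / 2.0
    return anchor * 2.0 ** (np.arange(n) - mid)


def generate_training_set(
    cfg: SimulationConfig,
    responsive_fraction: float = 1.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Reference-compound training set: gene x compound log2 ratios + labels.

    DDI-class compounds shift the designated responsive biomarker genes by
    +/- ``effect_size_log2`` plus N(0, noise_sd) noise; non-DDI compounds are
    pure noise.  ``responsive_fraction`` trims the responsive subset from the
    top of each sign block (1.0 = all genes respond).
    """
    if cfg.effect_size_log2 < 0:
        raise ValueError("effect_size_log2 must be >= 0")
    if not 0.0 < responsive_fraction <= 1.0:
        raise ValueError("responsive_fraction must be in (0, 1]")
    rng = _child_rng(cfg.seed, "training")
    genes = cfg.biomarker_genes()
    signs = cfg.gene_signs()
    n_resp = max(1, int(round(responsive_fraction * cfg.n_biomarker_genes)))
    responsive = np.zeros(cfg.n_biomarker_genes, dtype=bool)
    responsive[:n_resp] = True

    n_per = cfg.n_reference_compounds_per_class
    compounds = [f"DDI{i:02d}" for i in range(1, n_per + 1)] + \
                [f"NDI{i:02d}" for i in range(1, n_per + 1)]
    labels = pd.Series(["DDI"] * n_per + ["non-DDI"] * n_per,
                       index=compounds, name="label")
    mean = np.zeros((cfg.n_biomarker_genes, 2 * n_per))
    mean[:, :n_per] = (signs * responsive * cfg.effect_size_log2)[:, None]
    values = mean + rng.normal(0.0, cfg.noise_sd, size=mean.shape)
    return pd.DataFrame(values, index=genes, columns=compounds), labels


def _probe_table(cfg: SimulationConfig, rng: np.random.Generator):
    """Probe ids, gene map and relative baseline abundances for the panel.

    Biomarker genes mostly have one probe; every fourth has two (to exercise
    probe-to-gene averaging).  Baseline abundances are log-normal, the
    standard shape for targeted sequencing panels.
    """
    probe_ids, gene_syms = [], []
    for i, g in enumerate(cfg.biomarker_genes()):
        probe_ids.append(f"{g}_P1")
        gene_syms.append(g)
        if i % 4 == 0:
            probe_ids.append(f"{g}_P2")
            gene_syms.append(g)
    for j in range(1, cfg.n_background_probes + 1):
        probe_ids.append(f"BG{j:04d}_P1")
        gene_syms.append(f"BG{j:04d}")
    weights = rng.lognormal(mean=0.0, sigma=1.0, size=len(probe_ids))
    return probe_ids, pd.Series(gene_syms, index=probe_ids, name="gene_symbol"), weights


def generate_test_experiment(
    truth: GroundTruth,
    cfg: SimulationConfig,
    concentrations: np.ndarray | None = None,
) -> SimulatedExperiment:
    """Simulate one chemical's full exposure series with matched vehicle.

    Counts are negative-binomial around the target depth with log-normal
    per-sample size-factor jitter; responsive biomarker genes follow the
    calibrated Hill log2-FC curve; comet % tail DNA and viability follow
    their own calibrated curves with Gaussian replicate noise.
    """
    if concentrations is None:
        concentrations = default_concentrations(truth, cfg)
    concentrations = np.asarray(concentrations, dtype=float)
    if not np.all(np.diff(concentrations) > 0):
        raise ValueError("concentrations must be strictly increasing")
    if not truth.is_ddi and truth.true_bmc_tgx is not None:
        raise ValueError("non-DDI truth cannot carry a transcriptomic BMC")

    rng = _child_rng(cfg.seed, "experiment", truth.chemical_id)
    probe_ids, gene_map, weights = _probe_table(cfg, rng)
    signs = cfg.gene_signs()
    sign_by_gene = dict(zip(cfg.biomarker_genes(), signs))

    all_conc = np.concatenate([[0.0], concentrations])
    lfc_mag = expected_log2fc(truth, cfg, all_conc)

    sample_ids, meta_rows = [], []
    count_cols = {}
    size_factors = {}
    for ci, conc in enumerate(all_conc):
        for rep in range(1, cfg.n_replicates + 1):
            sid = f"{truth.chemical_id}_C{ci}_R{rep}"
            sample_ids.append(sid)
            meta_rows.append(dict(sample_id=sid, chemical=truth.chemical_id,
                                  concentration_uM=conc, replicate=rep,
                                  is_vehicle=ci == 0))
            sf = rng.lognormal(0.0, cfg.size_factor_jitter)
            size_factors[sid] = sf
            fold = np.ones(len(probe_ids))
            if lfc_mag[ci] > 0:
                for k, pid in enumerate(probe_ids):
                    g = gene_map.iloc[k]
                    s = sign_by_gene.get(g)
                    if s is not None:
                        fold[k] = 2.0 ** (s * lfc_mag[ci])
            w = weights * fold
            mu = cfg.depth_target * sf * w / w.sum()
            r = 1.0 / cfg.dispersion
            p = r / (r + mu)
            count_cols[sid] = rng.negative_binomial(r, p)

    counts = pd.DataFrame(count_cols, index=pd.Index(probe_ids, name="probe_id"))
    metadata = pd.DataFrame(meta_rows)

    comet_rows = []
    tail_mean = expected_tail_dna(truth, cfg, all_conc)
    for ci, conc in enumerate(all_conc):
        vals = np.clip(
            tail_mean[ci] + rng.normal(0.0, cfg.comet_noise_sd, cfg.n_replicates),
            0.0, 100.0)
        for rep, v in enumerate(vals, start=1):
            comet_rows.append(dict(chemical=truth.chemical_id,
                                   concentration_uM=conc, well=rep,
                                   median_pct_tail_dna=float(v)))
    comet = pd.DataFrame(comet_rows)

    viab_mean = expected_viability(truth, cfg, all_conc)
    viability = pd.DataFrame(dict(
        chemical=truth.chemical_id,
        concentration_uM=all_conc,
        pct_viability=np.clip(
            viab_mean + rng.normal(0.0, cfg.viability_noise_sd, len(all_conc)),
            0.0, 110.0),
    ))

    return SimulatedExperiment(
        truth=truth, config=cfg, concentrations=concentrations,
        counts=counts, probe_gene_map=gene_map, metadata=metadata,
        comet=comet, viability=viability,
        true_size_factors=pd.Series(size_factors, name="size_factor"),
    )


_CORRUPT_KINDS = ("low_depth", "singleton", "skewed")


def generate_corrupt_samples(
    kind: str,
    cfg: SimulationConfig,
    template: pd.DataFrame | None = None,
) -> pd.Series:
    """One count column violating a single QC rule.

    ``low_depth``: < 100,000 total reads; ``singleton``: probe ranks
    decorrelated from any normal sample; ``skewed``: reads concentrated on a
    handful of probes (extreme Gini).
    """
    if kind not in _CORRUPT_KINDS:
        raise ValueError(f"unknown corruption kind {kind!r}; "
                         f"expected one of {_CORRUPT_KINDS}")
    rng = _child_rng(cfg.seed, "corrupt", kind)
    if template is None:
        probe_ids, _, weights = _probe_table(cfg, _child_rng(cfg.seed, "corrupt-template"))
        index = pd.Index(probe_ids, name="probe_id")
    else:
        index = template.index
        weights = template.mean(axis=1).to_numpy() + 0.5

    n = len(index)
    if kind == "low_depth":
        mu = 50_000 * weights / weights.sum()
    elif kind == "singleton":
        mu = cfg.depth_target * rng.permutation(weights) / weights.sum()
    else:  # skewed
        w = np.full(n, 1e-4)
        w[rng.choice(n, size=5, replace=False)] = 1.0
        mu = cfg.depth_target * w / w.sum()
    r = 1.0 / cfg.dispersion
    vals = rng.negative_binomial(r, r / (r + mu))
    return pd.Series(vals, index=index, name=f"CORRUPT_{kind}")


def write_experiment(exp: SimulatedExperiment, outdir: str | Path) -> dict[str, Path]:
    """Write the experiment in the pipeline's plain-text on-disk schema."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "probe_map": outdir / "probe_map.tsv",
        "metadata": outdir / "metadata.tsv",
        "comet": outdir / "comet.csv",
        "viability": outdir / "viability.csv",
        "truth": outdir / "truth.json",
    }
    exp.counts.to_csv(paths["counts"], sep="\t")
    exp.probe_gene_map.rename_axis("probe_id").to_frame().to_csv(
        paths["probe_map"], sep="\t")
    exp.metadata.to_csv(paths["metadata"], sep="\t", index=False)
    exp.comet.to_csv(paths["comet"], index=False)
    exp.viability.to_csv(paths["viability"], index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(asdict(exp.truth), fh, indent=2)
    return paths
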