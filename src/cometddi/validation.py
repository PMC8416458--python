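"""Recovery and calibration studies for the pipeline on synthetic truth.

Each function runs a self-contained simulation study against the package's
own machinery and returns the headline number(s): oracle agreement for the
classifier, bootstrap-CI coverage of a known BMC, type-I calibration of the
Williams prefilter and the Dunnett pipeline, end-to-end call accuracy, and
cross-assay potency-rank agreement.  These back the worked examples and the
reproducibility script; problem sizes are chosen so a full run stays within
minutes on one core.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import bmc as B
from . import classify as cls
from . import comet as cm
from . import synthetic as syn
from .integrate import combine_calls, potency_report
from .pipeline import PipelineConfig, analyze_experiment

__all__ = [
    "nsc_oracle_agreement", "bmc_closed_form_max_error", "bmc_ci_coverage",
    "williams_null_retention", "dunnett_fwer", "dunnett_vs_monte_carlo",
    "integrated_call_accuracy", "potency_rank_agreement",
]

_CONC = np.repeat([0.0, 2.5, 5.0, 10.0, 20.0, 40.0], 4)


def _toy_training(rng, n_genes=8, n_per_class=5, effect=1.0, sd=1.0):
    genes = [f"g{i}" for i in range(n_genes)]
    cols = [f"d{i}" for i in range(n_per_class)] + \
           [f"n{i}" for i in range(n_per_class)]
    labels = pd.Series([cls.DDI] * n_per_class + [cls.NON_DDI] * n_per_class,
                       index=cols)
    signs = np.where(np.arange(n_genes) % 2 == 0, 1.0, -1.0)
    mean = np.zeros((n_genes, 2 * n_per_class))
    mean[:, :n_per_class] = (signs * effect)[:, None]
    mat = pd.DataFrame(mean + rng.normal(0, sd, mean.shape),
                       index=genes, columns=cols)
    return cls.TrainingSet(mat, labels)


def nsc_oracle_agreement(n_sets: int = 50, seed: int = 0) -> dict:
    """Unshrunk NSC vs a diagonal-covariance nearest-centroid oracle.

    With Delta = 0 and equal class sizes the NSC discriminant reduces to the
    standardized squared distance to the unshrunk class centroids, so the
    two classifiers must agree on every profile.
    """
    rng = np.random.default_rng(seed)
    agree = total = 0
    for _ in range(n_sets):
        tr = _toy_training(rng)
        model = cls.train_nsc(tr, 0.0)
        var = (model.within_class_sd + model.s0) ** 2
        for _ in range(5):
            prof = pd.Series(rng.normal(0, 1.5, len(tr.genes)), index=tr.genes)
            post, _ = cls.classify_nsc(model, prof, posterior_threshold=0.5)
            nsc = cls.DDI if post > 0.5 else cls.NON_DDI
            d = (((prof.to_numpy()[:, None] - model.class_centroids) ** 2)
                 / var[:, None]).sum(axis=0)
            oracle = model.classes[int(np.argmin(d))]
            agree += nsc == oracle
            total += 1
    return dict(agree=agree, total=total, agreement=agree / total)


def bmc_closed_form_max_error(n_cases: int = 100, seed: int = 0) -> float:
    """Max |closed-form - root-finder| over random Linear/Exp2 parameters."""
    rng = np.random.default_rng(seed)
    s = B.DoseResponseSeries(_CONC, 10 + 0.1 * _CONC)
    worst = 0.0
    for _ in range(n_cases):
        sd = rng.uniform(0.05, 1.0)
        fits = [
            B.ModelFit("Linear", np.array([rng.normal(10, 2),
                                           rng.uniform(0.05, 2)]),
                       0, 1.0, sd, "up", 0, 2),
            B.ModelFit("Exp2", np.array([rng.uniform(0.5, 20),
                                         rng.choice([-1, 1])
                                         * rng.uniform(0.005, 0.08)]),
                       0, 1.0, sd, "up", 0, 2),
        ]
        for fit in fits:
            closed = B.bmc_from_fit(fit, s)
            root = B.bmc_root_generic(fit, s)
            if np.isfinite(closed) and closed <= 10 * s.cmax:
                worst = max(worst, abs(closed - root))
    return worst


def bmc_ci_coverage(n_reps: int = 50, n_genes: int = 6, true_bmc: float = 10.0,
                    seed: int = 0, cfg: B.BmcConfig | None = None) -> dict:
    """Coverage of the two-level bootstrap 95% CI for a known gene-set BMC.

    Every gene follows a Hill curve calibrated so its 1SD departure from
    control sits exactly at ``true_bmc``; per-gene noise SDs are drawn from
    0.1-0.3 (log2 scale) and the design is the standard 5 doses + control
    with n = 4.
    """
    cfg = cfg or B.BmcConfig()
    covered = usable = 0
    for rep in range(n_reps):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 51, rep]))
        series = {}
        for g in range(n_genes):
            sd = rng.uniform(0.1, 0.3)
            k = syn.hill_k_for_bmc(true_bmc, 2.0, sd, 2.0)
            sign = 1.0 if g % 2 == 0 else -1.0
            mu = 8.0 + sign * syn.hill_response(_CONC, 2.0, k, 2.0)
            series[f"g{g}"] = B.DoseResponseSeries(
                _CONC, mu + rng.normal(0, sd, _CONC.size))
        res = B.bootstrap_bmc_ci(series, cfg, rng)
        if res.ci95 is None:
            continue
        usable += 1
        covered += res.ci95[0] <= true_bmc <= res.ci95[1]
    return dict(covered=covered, usable=usable, n_reps=n_reps,
                coverage=covered / max(usable, 1))


def williams_null_retention(n_genes: int = 10_000, seed: int = 0,
                            alpha: float = 0.05) -> dict:
    """Retention rate of pure-noise genes by the Williams permutation test.

    The fold-change gate is disabled so the rate isolates the trend test's
    type-I error at the nominal level.
    """
    rng = np.random.default_rng(seed)
    perms = B._perm_indices(_CONC.size, 250, rng)
    kept = 0
    for _ in range(n_genes):
        y = rng.normal(8.0, 0.3, _CONC.size)
        s = B.DoseResponseSeries(_CONC, y)
        _, p = B.williams_test(s, 250, perms=perms)
        kept += p < alpha
    return dict(retained=kept, n_genes=n_genes, rate=kept / n_genes)


def dunnett_fwer(n_chemicals: int = 2000, seed: int = 0,
                 alpha: float = 0.05) -> dict:
    """Familywise error of the full comet pipeline under the global null."""
    rng = np.random.default_rng(seed)
    positives = 0
    for _ in range(n_chemicals):
        groups = {c: np.clip(rng.normal(20.0, 3.0, 4), 0, 100)
                  for c in [0.0, 1.0, 2.0, 4.0, 8.0, 16.0]}
        res = cm.analyze_chemical(cm.CometSeries("null", groups), alpha=alpha)
        positives += res.positive_call
    return dict(positives=positives, n=n_chemicals, fwer=positives / n_chemicals)


def dunnett_vs_monte_carlo(n_draws: int = 1_000_000, n_datasets: int = 20,
                           seed: int = 0) -> dict:
    """Compare Dunnett adjusted p-values with a max-|t| Monte-Carlo oracle.

    Fixed design: control + two treatments, n = 4 each.  The oracle samples
    the null distribution of the maximum |t| (pooled variance, df = 9)
    directly from group-level normal draws.
    """
    rng = np.random.default_rng(seed)
    k, n = 3, 4
    df = k * n - k
    # oracle null distribution of max |t|
    chunks = []
    per = 200_000
    done = 0
    while done < n_draws:
        m = min(per, n_draws - done)
        x = rng.normal(size=(m, k, n))
        means = x.mean(axis=2)
        sse = ((x - means[:, :, None]) ** 2).sum(axis=(1, 2))
        s2 = sse / df
        t = (means[:, 1:] - means[:, [0]]) / np.sqrt(s2[:, None] * (2 / n))
        chunks.append(np.abs(t).max(axis=1))
        done += m
    null_max_t = np.sort(np.concatenate(chunks))

    worst = 0.0
    for _ in range(n_datasets):
        groups = {c: rng.normal(10 + c * 0.3, 2.0, n) for c in [0.0, 1.0, 2.0]}
        table = cm.dunnett_pairwise(cm.CometSeries("x", {
            c: np.clip(v, 0, 100) for c, v in groups.items()}))
        for _, row in table.iterrows():
            p_mc = 1.0 - np.searchsorted(null_max_t, abs(row["t"])) / len(null_max_t)
            worst = max(worst, abs(row["adj_p"] - p_mc))
    return dict(max_abs_diff=worst, n_draws=n_draws)


def _standard_pipeline(seed: int, scfg: syn.SimulationConfig | None = None):
    scfg = scfg or syn.SimulationConfig(seed=seed)
    cfg = PipelineConfig(seed=seed, simulation=scfg)
    mat, labels = syn.generate_training_set(scfg)
    training = cls.TrainingSet(mat, labels)
    delta = cls.choose_delta(training, seed=seed)
    return cfg, training, delta


def _chemical_calls(truth, cfg, training, delta):
    exp = syn.generate_test_experiment(truth, cfg.simulation)
    res = analyze_experiment(exp, training, cfg, delta)
    per_conc = {c.concentration: c.overall for c in res["calls"]}
    tgx = cls.chemical_call(per_conc, res["cytotoxic"])
    tgx_code = "+" if tgx == cls.DDI else ("U" if tgx == cls.UNCLASSIFIED else "-")
    comet_code = "+" if res["comet"].positive_call else "-"
    return exp, res, comet_code, tgx_code


def integrated_call_accuracy(n_chemicals: int = 40, seed: int = 0) -> dict:
    """Ground-truth agreement of OR-rule integrated calls on simulated chemicals.

    Half the chemicals are DDI with transcriptomic BMCs log-spaced over
    3-300 uM (matched comet BMCs); half are inert.  Study conditions follow
    the generator defaults (effect 2.0 log2, noise SD 0.3, 5 doses, n = 4).
    """
    cfg, training, delta = _standard_pipeline(seed)
    n_ddi = n_chemicals // 2
    bmcs = np.geomspace(3.0, 300.0, n_ddi)
    comet_calls, tgx_calls, expected = {}, {}, {}
    for i in range(n_chemicals):
        if i < n_ddi:
            truth = syn.GroundTruth(f"D{seed}_{i}", True,
                                    true_bmc_tgx=float(bmcs[i]),
                                    true_bmc_comet=float(bmcs[i]))
        else:
            truth = syn.GroundTruth(f"N{seed}_{i}", False)
        _, _, ccode, tcode = _chemical_calls(truth, cfg, training, delta)
        comet_calls[truth.chemical_id] = ccode
        tgx_calls[truth.chemical_id] = tcode
        expected[truth.chemical_id] = "positive" if truth.is_ddi else "negative"
    _, acc = combine_calls(comet_calls, tgx_calls, expected)
    acc["accuracy"] = acc["combined_correct"] / acc["n"]
    return acc


def potency_rank_agreement(n_seeds: int = 30, seed: int = 0) -> dict:
    """Cross-assay potency-rank agreement on chemicals spanning 100x in potency.

    Per seed, four DDI chemicals with true BMCs 2/9/43/200 uM are analyzed
    end to end; TGx gene-set BMCs use the trend-prefiltered median over the
    64 biomarker genes and comet BMCs the profile-likelihood path.  A seed
    counts as agreeing when the Spearman correlation between the two potency
    rankings over the jointly modeled chemicals (>= 3 required) equals 1.
    """
    perfect = 0
    details = []
    for s in range(n_seeds):
        run_seed = seed * 1000 + s
        cfg, training, delta = _standard_pipeline(run_seed)
        rng = np.random.default_rng(np.random.SeedSequence([run_seed, 7]))
        true_bmcs = np.geomspace(2.0, 200.0, 4)
        cc, tgx = {}, {}
        for i, b in enumerate(true_bmcs):
            truth = syn.GroundTruth(f"R{s}_{i}", True, true_bmc_tgx=float(b),
                                    true_bmc_comet=float(b))
            exp, res, ccode, tcode = _chemical_calls(truth, cfg, training, delta)
            if tcode == "+":
                gene_series = B.gene_series_from_profiles(
                    res["gene_level"], exp.metadata, truth.chemical_id,
                    genes=list(training.genes),
                    exclude_concentrations=res["cytotoxic"])
                retained = B.williams_prefilter(gene_series, cfg.bmc, rng)
                per_gene = {g: B.estimate_bmc(sr, cfg.bmc, rng=rng)
                            for g, sr in gene_series.items()
                            if retained[g]["retained"]}
                med, _ = B.gene_set_median_bmc(per_gene)
                if med is not None:
                    tgx[truth.chemical_id] = med
            if ccode == "+":
                series = B.comet_series_from_table(
                    exp.comet, truth.chemical_id,
                    exclude_concentrations=res["cytotoxic"])
                est = B.estimate_bmc(series, cfg.bmc, rng=rng)
                if est.passed_filters and np.isfinite(est.bmc):
                    cc[truth.chemical_id] = est.bmc
        rep = potency_report(cc, tgx)
        both = rep.dropna(subset=["rank_cc", "rank_tgx"])
        if len(both) >= 3:
            rho = stats.spearmanr(both["rank_cc"], both["rank_tgx"]).statistic
            ok = bool(rho == 1.0)
        else:
            ok = False
        perfect += ok
        details.append(ok)
    return dict(perfect=perfect, n_seeds=n_seeds, rate=perfect / n_seeds,
                details=details)
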