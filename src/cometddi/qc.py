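"""Sample QC and count normalization for targeted RNA-seq count matrices.

Implements median-of-ratios size factors, per-sample library-complexity
metrics (reads, probes capturing the top 80% of signal, Gini coefficient,
active probes), Tukey outer-fence outlier flagging, singleton detection by
complete-linkage clustering on 1 - Spearman correlation, and the combined
sample/concentration exclusion rules (minimum depth, metric outliers,
singletons, < 40% viability).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

__all__ = [
    "NormalizedMatrix",
    "compute_size_factors",
    "normalize_counts",
    "qc_metrics",
    "flag_metric_outliers",
    "detect_singletons",
    "filter_samples",
    "gini_coefficient",
]

MIN_READS = 100_000          # 10% of the 1M-read target depth
FENCE_MULTIPLIER = 3.0       # Tukey's outer fence
SINGLETON_CUT = 0.1          # dissimilarity at which singletons are cut
VIABILITY_THRESHOLD = 40.0   # % viability below which a concentration is cytotoxic
ACTIVE_MIN_READS = 5


@dataclass
class NormalizedMatrix:
    """Median-of-ratios normalized counts with their log2(x + 0.5) transform."""

    size_factors: pd.Series
    normalized: pd.DataFrame
    log2_shifted: pd.DataFrame


def compute_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (the DESeq estimator).

    The reference is the per-probe geometric mean across samples, computed
    over probes with no zero count in any sample; each sample's size factor
    is the median of its ratios to that reference.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples to estimate size factors")
    x = counts.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("count matrix contains negative entries")
    all_pos = (x > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "median-of-ratios undefined: no probe has nonzero counts in "
            "every sample")
    logx = np.log(x[all_pos])
    ref = logx.mean(axis=1)
    sf = np.exp(np.median(logx - ref[:, None], axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame,
                     size_factors: pd.Series | None = None) -> NormalizedMatrix:
    """Divide by size factors and take log2(normalized + 0.5)."""
    if size_factors is None:
        size_factors = compute_size_factors(counts)
    norm = counts / size_factors
    return NormalizedMatrix(size_factors=size_factors, normalized=norm,
                            log2_shifted=np.log2(norm + 0.5))


def gini_coefficient(x: np.ndarray) -> float:
    """Gini inequality index, mean |xi - xj| / (2 * mean); NaN if sum is 0.

    Computed with the sorted-rank identity, which equals the pairwise
    definition exactly.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    total = x.sum()
    if total <= 0:
        return float("nan")
    i = np.arange(1, n + 1)
    return float((2.0 * np.sum(i * x) / (n * total)) - (n + 1.0) / n)


def qc_metrics(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample library metrics: total reads, n_top80, Gini, active probes.

    ``n_top80`` is the smallest number of probes whose (largest) counts sum
    to at least 80% of the sample total; ``n_active`` counts probes with at
    least 5 reads.  An all-zero sample gets NaN Gini and automatically fails.
    """
    if counts.size == 0:
        raise ValueError("empty count matrix")
    rows = []
    for sid in counts.columns:
        x = counts[sid].to_numpy(dtype=float)
        total = x.sum()
        if total > 0:
            desc = np.sort(x)[::-1]
            n_top80 = int(np.searchsorted(np.cumsum(desc), 0.8 * total) + 1)
        else:
            n_top80 = 0
        rows.append(dict(
            sample_id=sid,
            total_reads=int(total),
            n_top80=n_top80,
            gini=gini_coefficient(x),
            n_active=int((x >= ACTIVE_MIN_READS).sum()),
        ))
    return pd.DataFrame(rows).set_index("sample_id")


OUTLIER_METRICS = ("n_top80", "gini", "n_active")


def flag_metric_outliers(metrics: pd.DataFrame,
                         fence_multiplier: float = FENCE_MULTIPLIER) -> pd.DataFrame:
    """Flag samples strictly outside Tukey's outer fence on each QC metric.

    Fences are [Q1 - m*IQR, Q3 + m*IQR] with linearly interpolated quartiles;
    values exactly on a fence are not flagged.  With fewer than 4 samples the
    fences are not meaningful, so nothing is flagged (a warning is emitted).
    """
    flags = pd.DataFrame(False, index=metrics.index,
                         columns=[f"outlier_{m}" for m in OUTLIER_METRICS])
    if len(metrics) < 4:
        warnings.warn("fewer than 4 samples: outer-fence outlier flags skipped")
        return flags
    for m in OUTLIER_METRICS:
        v = metrics[m].to_numpy(dtype=float)
        q1, q3 = np.nanpercentile(v, [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - fence_multiplier * iqr, q3 + fence_multiplier * iqr
        flags[f"outlier_{m}"] = (v < lo) | (v > hi)
    return flags


def detect_singletons(values: pd.DataFrame,
                      dissimilarity_cut: float = SINGLETON_CUT,
                      min_active_fraction: float = 0.5) -> pd.Series:
    """Flag samples that cluster alone at 1 - Spearman dissimilarity 0.1.

    ``values`` are log2(normalized + 0.5) expression values (columns =
    samples); probes active (>= 5 raw-scale units ~ log2 value above
    log2(5.5)) in fewer than half the samples are dropped first, since rank
    correlation on near-zero counts is noise-dominated.  Complete-linkage
    agglomerative clustering is cut at the given height; any sample alone in
    its cluster is a singleton.  A zero-variance sample has undefined
    Spearman correlation and is flagged directly.
    """
    if values.shape[1] < 3:
        raise ValueError("need at least 3 samples for singleton detection")
    active = (values > np.log2(ACTIVE_MIN_READS + 0.5)).mean(axis=1) >= min_active_fraction
    sub = values.loc[active] if active.any() else values
    x = sub.to_numpy(dtype=float)
    flagged = pd.Series(False, index=values.columns, name="is_singleton")

    degenerate = x.std(axis=0) == 0
    flagged[degenerate] = True
    ok = ~degenerate
    if ok.sum() >= 3:
        rho = spearmanr(x[:, ok]).statistic
        rho = np.atleast_2d(rho)
        d = np.clip(1.0 - rho, 0.0, None)
        np.fill_diagonal(d, 0.0)
        z = linkage(squareform(d, checks=False), method="complete")
        labels = fcluster(z, t=dissimilarity_cut, criterion="distance")
        sizes = pd.Series(labels).value_counts()
        singleton = np.array([sizes[lab] == 1 for lab in labels])
        flagged[values.columns[ok]] = singleton
    return flagged


def filter_samples(
    metrics: pd.DataFrame,
    metadata: pd.DataFrame,
    viability: pd.DataFrame | None = None,
    outlier_flags: pd.DataFrame | None = None,
    singleton_flags: pd.Series | None = None,
    min_reads: int = MIN_READS,
    viability_threshold: float = VIABILITY_THRESHOLD,
    manual_exclusions: list[str] | None = None,
) -> pd.DataFrame:
    """Apply the sample/concentration exclusion rules.

    Returns a table (sample_id, reason) with machine-readable reason codes:
    ``min_reads``, ``outlier_<metric>``, ``singleton``, ``gini_undefined``,
    ``manual`` (caller-supplied list, e.g. a leverage outlier identified by
    inspection) and ``cytotoxic`` (the last excludes whole concentration
    groups whose viability is below the threshold).  Cytotoxicity governs classification
    and BMC modeling; comet summary statistics may still be computed at
    cytotoxic concentrations, so that flag is carried separately by callers.
    """
    reasons: list[dict] = []
    for sid in manual_exclusions or ():
        reasons.append(dict(sample_id=sid, reason="manual"))
    for sid, row in metrics.iterrows():
        if row["total_reads"] < min_reads:
            reasons.append(dict(sample_id=sid, reason="min_reads"))
        if np.isnan(row["gini"]):
            reasons.append(dict(sample_id=sid, reason="gini_undefined"))
    if outlier_flags is not None:
        for col in outlier_flags.columns:
            for sid in outlier_flags.index[outlier_flags[col]]:
                reasons.append(dict(sample_id=sid, reason=col))
    if singleton_flags is not None:
        for sid in singleton_flags.index[singleton_flags]:
            reasons.append(dict(sample_id=sid, reason="singleton"))
    if viability is not None:
        toxic = viability.loc[
            viability["pct_viability"] < viability_threshold,
            ["chemical", "concentration_uM"]]
        for _, t in toxic.iterrows():
            hit = metadata[(metadata["chemical"] == t["chemical"]) &
                           (metadata["concentration_uM"] == t["concentration_uM"])]
            for sid in hit["sample_id"]:
                reasons.append(dict(sample_id=sid, reason="cytotoxic"))
    out = pd.DataFrame(reasons, columns=["sample_id", "reason"]).drop_duplicates()

    kept = set(metadata["sample_id"]) - set(out["sample_id"])
    for (chem, conc), grp in metadata.groupby(["chemical", "concentration_uM"]):
        if not any(s in kept for s in grp["sample_id"]):
            warnings.warn(
                f"all samples excluded for {chem} at {conc} uM; "
                "condition dropped from downstream analysis")
    return out.reset_index(drop=True)


def cytotoxic_concentrations(viability: pd.DataFrame,
                             viability_threshold: float = VIABILITY_THRESHOLD,
                             ) -> pd.DataFrame:
    """Concentration groups below the viability threshold (chemical, conc)."""
    return viability.loc[
        viability["pct_viability"] < viability_threshold,
        ["chemical", "concentration_uM"]].reset_index(drop=True)
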