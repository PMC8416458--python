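"""Statistical analysis of CometChip median % tail DNA.

Per chemical: one-way ANOVA across concentration groups with assumption
checks (Anderson-Darling normality on pooled residuals, Fligner-Killeen
homogeneity of variances; either failing at 0.05 triggers a rank-transform
rerun), pairwise pooled-variance t-tests of each concentration against the
matched vehicle control with Dunnett many-to-one FWER adjustment, and a
per-chemical hazard call (positive iff a non-cytotoxic concentration shows a
statistically significant *increase* over vehicle).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CometSeries", "CometTestResult",
    "anova_with_assumptions", "dunnett_pairwise", "comet_hazard_call",
    "analyze_chemical", "analyze_comet_table",
]

ALPHA = 0.05
ASSUMPTION_ALPHA = 0.05
_DUNNETT_RNG = 171360  # fixed stream for the multivariate-t integration


@dataclass
class CometSeries:
    """Replicate median % tail DNA per concentration group (0 = vehicle)."""

    chemical: str
    groups: dict[float, np.ndarray]

    def __post_init__(self) -> None:
        self.groups = {float(c): np.asarray(v, dtype=float)
                       for c, v in sorted(self.groups.items())}
        if 0.0 not in self.groups:
            raise ValueError(f"{self.chemical}: vehicle group (0 uM) missing")
        allv = np.concatenate(list(self.groups.values()))
        if ((allv < 0) | (allv > 100)).any():
            raise ValueError("% tail DNA values must lie in [0, 100]")

    @property
    def treatments(self) -> list[float]:
        return [c for c in self.groups if c > 0]


@dataclass
class CometTestResult:
    """ANOVA + Dunnett results and the per-chemical hazard call."""

    chemical: str
    anova_p: float
    used_rank_transform: bool
    table: pd.DataFrame   # concentration, mean, se, diff, raw_p, adj_p, direction, significant
    positive_call: bool | None = None
    warnings: list[str] = field(default_factory=list)


def anova_with_assumptions(series: CometSeries,
                           assumption_alpha: float = ASSUMPTION_ALPHA,
                           ) -> tuple[float, bool, list[str]]:
    """One-way ANOVA p-value with a rank-transform fallback.

    Anderson-Darling is applied to the pooled within-group residuals (group
    sizes of ~4 are too small to test normality per group); Fligner-Killeen
    to the raw groups.  If either rejects, all observations are ranked
    jointly and the ANOVA is repeated on the ranks.
    """
    groups = list(series.groups.values())
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 replicates each")
    notes: list[str] = []
    if all(np.ptp(g) == 0 for g in groups):
        notes.append("zero within-group variance in every group; ANOVA degenerate")
        warnings.warn(notes[-1])
        return 1.0, False, notes

    resid = np.concatenate([g - g.mean() for g in groups])
    use_rank = False
    try:
        ad_p = stats.anderson(resid, dist="norm", method="interpolate").pvalue
    except Exception:
        ad_p = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fk_p = stats.fligner(*groups).pvalue
        except Exception:
            fk_p = np.nan
    if (np.isfinite(ad_p) and ad_p < assumption_alpha) or \
       (np.isfinite(fk_p) and fk_p < assumption_alpha):
        use_rank = True
        groups = _rank_groups(series)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.f_oneway(*groups)
    p = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
    return p, use_rank, notes


def _rank_groups(series: CometSeries) -> list[np.ndarray]:
    """Replace all observations by their joint ranks, keeping the grouping."""
    sizes = [len(v) for v in series.groups.values()]
    ranks = stats.rankdata(np.concatenate(list(series.groups.values())))
    out, i = [], 0
    for n in sizes:
        out.append(ranks[i:i + n])
        i += n
    return out


def dunnett_pairwise(series: CometSeries,
                     used_rank_transform: bool = False) -> pd.DataFrame:
    """Each concentration vs vehicle: pooled-variance t and Dunnett-adjusted p.

    Raw p-values come from a two-sided t statistic with the residual variance
    pooled across all groups (df = N - k); the adjustment integrates the
    Dunnett many-to-one multivariate-t distribution with the design's
    correlation structure (fixed quasi-random stream for reproducibility).
    The adjusted p is floored at the raw p so adjustment is always monotone.
    """
    groups = (_rank_groups(series) if used_rank_transform
              else list(series.groups.values()))
    concs = list(series.groups)
    ctrl = groups[concs.index(0.0)]
    treat = [g for c, g in zip(concs, groups) if c > 0]
    tconc = [c for c in concs if c > 0]
    if not treat:
        raise ValueError("no treatment groups")

    k = len(groups)
    n_total = sum(len(g) for g in groups)
    df = n_total - k
    sse = sum(((g - g.mean()) ** 2).sum() for g in groups)
    s2 = sse / df if df > 0 else np.nan

    rows = []
    if s2 > 0:
        dres = stats.dunnett(*treat, control=ctrl, alternative="two-sided",
                             rng=_DUNNETT_RNG)
        adj = np.atleast_1d(dres.pvalue)
    else:
        adj = np.ones(len(treat))
    raw_means = {c: series.groups[c].mean() for c in concs}
    for j, (c, g) in enumerate(zip(tconc, treat)):
        diff = g.mean() - ctrl.mean()
        if s2 > 0:
            t = diff / np.sqrt(s2 * (1 / len(g) + 1 / len(ctrl)))
            raw_p = 2.0 * stats.t.sf(abs(t), df)
        else:
            t, raw_p = 0.0, 1.0
        adj_p = max(float(adj[j]), float(raw_p)) if len(treat) > 1 else float(raw_p)
        raw_diff = raw_means[c] - raw_means[0.0]
        rows.append(dict(
            concentration_uM=c,
            mean=raw_means[c],
            se=series.groups[c].std(ddof=1) / np.sqrt(len(series.groups[c])),
            diff_vs_control=raw_diff,
            direction="increase" if raw_diff > 0 else "decrease",
            t=float(t), raw_p=float(raw_p), adj_p=adj_p,
        ))
    return pd.DataFrame(rows)


def comet_hazard_call(table: pd.DataFrame,
                      cytotoxic: set[float] = frozenset(),
                      alpha: float = ALPHA) -> bool:
    """Positive iff a non-cytotoxic concentration shows a significant increase."""
    ok = ~table["concentration_uM"].isin(list(cytotoxic))
    sig = ok & (table["adj_p"] < alpha) & (table["direction"] == "increase")
    return bool(sig.any())


def analyze_chemical(series: CometSeries,
                     cytotoxic: set[float] = frozenset(),
                     alpha: float = ALPHA,
                     assumption_alpha: float = ASSUMPTION_ALPHA,
                     ) -> CometTestResult:
    """Full per-chemical analysis: assumption-checked ANOVA, Dunnett, call."""
    anova_p, use_rank, notes = anova_with_assumptions(series, assumption_alpha)
    table = dunnett_pairwise(series, used_rank_transform=use_rank)
    table["significant"] = (table["adj_p"] < alpha) & (table["direction"] == "increase")
    res = CometTestResult(chemical=series.chemical, anova_p=anova_p,
                          used_rank_transform=use_rank, table=table,
                          warnings=notes)
    res.positive_call = comet_hazard_call(table, cytotoxic, alpha)
    return res


def analyze_comet_table(comet: pd.DataFrame,
                        cytotoxic_by_chemical: dict[str, set[float]] | None = None,
                        alpha: float = ALPHA) -> dict[str, CometTestResult]:
    """Analyze every chemical in a long-format comet table.

    Expects columns ``chemical, concentration_uM, median_pct_tail_dna``
    (the synthetic-data on-disk schema).
    """
    cytotoxic_by_chemical = cytotoxic_by_chemical or {}
    out = {}
    for chem, sub in comet.groupby("chemical"):
        groups = {c: g["median_pct_tail_dna"].to_numpy()
                  for c, g in sub.groupby("concentration_uM")}
        series = CometSeries(chemical=chem, groups=groups)
        out[chem] = analyze_chemical(
            series, cytotoxic=set(cytotoxic_by_chemical.get(chem, ())),
            alpha=alpha)
    return out
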