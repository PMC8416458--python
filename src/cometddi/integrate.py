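"""Endpoint integration: OR-rule hazard calls and cross-assay potency ranking.

A chemical's combined genotoxicity call is positive if either the CometChip
DNA-damage call or the TGx-DDI transcriptomic call is positive (an
unclassified transcriptomic call counts as not-positive but is surfaced).
Potency is compared through the ratio of the transcriptomic bootstrap-median
BMC to the comet BMC, and through the within-endpoint potency ranks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["IntegratedCall", "combine_calls", "potency_report"]

POSITIVE = "+"
NEGATIVE = "-"
UNCLASSIFIED = "U"


@dataclass
class IntegratedCall:
    chemical: str
    comet_call: str       # "+" or "-"
    tgx_call: str         # "+", "-", or "U"
    combined: str
    expected: str | None = None   # "positive"/"negative"
    correct: bool | None = None


def _combined(comet_call: str, tgx_call: str) -> str:
    return POSITIVE if POSITIVE in (comet_call, tgx_call) else NEGATIVE


def combine_calls(comet_calls: dict[str, str], tgx_calls: dict[str, str],
                  expected: dict[str, str] | None = None,
                  ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Apply the OR rule per chemical; report per-assay and combined accuracy.

    ``comet_calls`` maps chemical -> "+"/"-"; ``tgx_calls`` maps chemical ->
    "+"/"-"/"U" (unclassified is treated as not-positive).  When expected
    labels ("positive"/"negative") are supplied, accuracies and the
    sensitivity on the expected-positive chemicals are returned.
    """
    if set(comet_calls) != set(tgx_calls):
        only_c = sorted(set(comet_calls) - set(tgx_calls))
        only_t = sorted(set(tgx_calls) - set(comet_calls))
        raise ValueError(f"chemical sets differ: comet-only {only_c}, "
                         f"tgx-only {only_t}")
    rows = []
    for chem in sorted(comet_calls):
        cc, tc = comet_calls[chem], tgx_calls[chem]
        comb = _combined(cc, tc)
        exp = expected.get(chem) if expected else None
        correct = None
        if exp is not None:
            correct = comb == (POSITIVE if exp == "positive" else NEGATIVE)
        rows.append(dict(chemical=chem, comet_call=cc, tgx_call=tc,
                         combined=comb, expected=exp, correct=correct))
    table = pd.DataFrame(rows)
    acc: dict[str, float] = {}
    if expected:
        want_pos = table["expected"] == "positive"
        exp_call = np.where(want_pos, POSITIVE, NEGATIVE)
        acc["n"] = len(table)
        acc["comet_correct"] = int((table["comet_call"] == exp_call).sum())
        acc["tgx_correct"] = int(
            ((table["tgx_call"] == POSITIVE) == want_pos).sum())
        acc["combined_correct"] = int(table["correct"].sum())
        n_pos = int(want_pos.sum())
        if n_pos:
            acc["combined_sensitivity"] = float(
                (table.loc[want_pos, "combined"] == POSITIVE).mean())
    return table, acc


def potency_report(bmc_cc: dict[str, float],
                   bmc_tgx: dict[str, float],
                   bmc_tgx_median: dict[str, float] | None = None,
                   ) -> pd.DataFrame:
    """Cross-assay potency table: ratios, ranks and max fold deviation.

    ``bmc_cc`` and ``bmc_tgx`` map chemical -> BMC (NaN/None for not
    modeled, rendered "n.m." downstream).  The ratio BMC_TGx / BMC_CC and
    the fold deviation max(ratio, 1/ratio) are defined only where both are
    finite; ranks are by ascending BMC within each endpoint over its modeled
    chemicals, ties broken by chemical label.
    """
    chems = sorted(set(bmc_cc) | set(bmc_tgx))
    cc = pd.Series({c: bmc_cc.get(c, np.nan) for c in chems}, dtype=float)
    tgx = pd.Series({c: bmc_tgx.get(c, np.nan) for c in chems}, dtype=float)
    ratio = tgx / cc
    fold_dev = np.maximum(ratio, 1.0 / ratio)

    def ranks(s: pd.Series) -> pd.Series:
        modeled = s.dropna().sort_values(kind="stable")
        # stable sort on value then label gives deterministic tie-breaking
        order = sorted(modeled.index, key=lambda c: (modeled[c], c))
        return pd.Series({c: i + 1 for i, c in enumerate(order)})

    report = pd.DataFrame({
        "bmc_cc": cc,
        "bmc_tgx_bootstrap": tgx,
        "ratio_tgx_cc": ratio,
        "fold_deviation": fold_dev,
        "rank_cc": ranks(cc),
        "rank_tgx": ranks(tgx),
    })
    if bmc_tgx_median is not None:
        report.insert(1, "bmc_tgx_median",
                      pd.Series({c: bmc_tgx_median.get(c, np.nan)
                                 for c in chems}, dtype=float))
    report.index.name = "chemical"
    return report
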