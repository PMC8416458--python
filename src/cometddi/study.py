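"""Published summary tables of the HepaRG CometChip + TGx-DDI validation study.

The validation study (12 test chemicals, transcriptomic data at NCBI GEO
accession GSE171360) reported per-concentration hazard calls for both
endpoints and benchmark concentrations for the chemicals that could be
modeled.  The printed summary cells are encoded here as inputs for
worked examples: applying the package's call-combination and potency-ratio
logic to them reproduces the study's headline accuracy and concordance
numbers.

Call codes per concentration: "+" positive, "-" negative, "U" unclassified,
"X" overtly cytotoxic (excluded from classification and modeling).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .integrate import combine_calls, potency_report

__all__ = [
    "CHEMICALS", "EXPECTED_LABEL", "COMET_CALLS", "TGX_CALLS",
    "BMC_CC", "BMC_TGX_MEDIAN", "BMC_TGX_BOOTSTRAP",
    "chemical_level_calls", "summary_accuracy", "published_potency_report",
]

# Expected genotoxicity label: the nine DNA-damage-inducing chemicals
# (including propyl gallate, reassigned to the genotoxic group) are expected
# positive; 2-deoxy-D-glucose, eugenol and urea are expected negative.
EXPECTED_LABEL = {
    "AFB1": "positive",   # aflatoxin B1
    "BaP": "positive",    # benzo[a]pyrene
    "CISP": "positive",   # cisplatin
    "CP": "positive",     # cyclophosphamide
    "AraC": "positive",   # cytosine arabinoside
    "MMS": "positive",    # methyl methanesulfonate
    "ENU": "positive",    # N-ethyl-N-nitrosourea
    "ZDV": "positive",    # zidovudine
    "PG": "positive",     # propyl gallate
    "2DG": "negative",    # 2-deoxy-D-glucose
    "EUG": "negative",    # eugenol
    "Urea": "negative",
}
CHEMICALS = list(EXPECTED_LABEL)

# Per-concentration CometChip calls (C1..C5).
COMET_CALLS = {
    "AFB1": ["-", "-", "-", "-", "-"],
    "BaP":  ["-", "-", "-", "+", "+"],
    "CISP": ["-", "-", "-", "+", "+"],
    "CP":   ["-", "-", "-", "-", "+"],
    "AraC": ["-", "+", "+", "+", "+"],
    "MMS":  ["-", "+", "+", "+", "+"],
    "ENU":  ["-", "-", "+", "+", "X"],
    "ZDV":  ["-", "+", "+", "+", "+"],
    "PG":   ["-", "-", "-", "-", "X"],
    "2DG":  ["-", "-", "-", "-", "-"],
    "EUG":  ["-", "-", "-", "-", "X"],
    "Urea": ["-", "-", "-", "-", "-"],
}

# Per-concentration TGx-DDI composite calls (C1..C5).
TGX_CALLS = {
    "AFB1": ["+", "+", "+", "+", "+"],
    "BaP":  ["+", "+", "+", "+", "+"],
    "CISP": ["-", "+", "+", "+", "+"],
    "CP":   ["-", "-", "-", "+", "+"],
    "AraC": ["+", "+", "+", "+", "+"],
    "MMS":  ["-", "-", "+", "+", "+"],
    "ENU":  ["+", "+", "+", "+", "X"],
    "ZDV":  ["-", "-", "-", "-", "-"],
    "PG":   ["-", "-", "+", "+", "X"],
    "2DG":  ["-", "-", "-", "-", "-"],
    "EUG":  ["-", "-", "U", "+", "X"],
    "Urea": ["-", "-", "-", "-", "-"],
}

# Benchmark concentrations (uM): comet endpoint and the transcriptomic
# biomarker gene set (median over modeled genes, and the two-level
# bootstrap median).  None = not modeled ("n.m.": negative call or no
# passing model).
BMC_CC = {
    "AFB1": None, "BaP": 1.7, "CISP": 8.5, "CP": 8079.0, "AraC": 12.1,
    "MMS": 21.3, "ENU": 536.0, "ZDV": 82.5, "PG": None, "2DG": None,
    "EUG": None, "Urea": None,
}
BMC_TGX_MEDIAN = {
    "AFB1": 2.9, "BaP": 0.56, "CISP": 4.5, "CP": 4808.0, "AraC": 16.6,
    "MMS": 67.1, "ENU": 285.0, "ZDV": None, "PG": 273.0, "2DG": None,
    "EUG": 535.0, "Urea": None,
}
BMC_TGX_BOOTSTRAP = {
    "AFB1": 2.7, "BaP": 0.68, "CISP": 5.4, "CP": 4949.0, "AraC": 12.9,
    "MMS": 76.5, "ENU": 271.0, "ZDV": None, "PG": 336.0, "2DG": None,
    "EUG": 529.0, "Urea": None,
}


def chemical_level_calls(per_conc: dict[str, list[str]]) -> dict[str, str]:
    """Chemical-level call over non-cytotoxic concentrations.

    Positive if any non-cytotoxic concentration is "+"; negative otherwise
    (an unclassified concentration alone does not make a positive).
    """
    out = {}
    for chem, calls in per_conc.items():
        usable = [c for c in calls if c != "X"]
        out[chem] = "+" if "+" in usable else "-"
    return out


def summary_accuracy() -> dict[str, float]:
    """Recompute the study's headline accuracies from the printed calls.

    Returns counts of correctly classified chemicals (of 12) for each assay
    alone and for the OR-rule combination, plus the combined sensitivity on
    the nine expected-positive chemicals.
    """
    comet = chemical_level_calls(COMET_CALLS)
    tgx = chemical_level_calls(TGX_CALLS)
    _, acc = combine_calls(comet, tgx, EXPECTED_LABEL)
    return acc


def published_potency_report() -> pd.DataFrame:
    """Potency ratios and ranks recomputed from the printed BMC cells."""
    cc = {c: v for c, v in BMC_CC.items() if v is not None}
    tgx = {c: v for c, v in BMC_TGX_BOOTSTRAP.items() if v is not None}
    med = {c: v for c, v in BMC_TGX_MEDIAN.items() if v is not None}
    return potency_report(cc, tgx, med)
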