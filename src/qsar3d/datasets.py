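"""Bundled reference tables for the thienopyridine IKKβ inhibitor series.

The activity table holds the published IC50 values (μM) of the 46-compound
series together with the standard 35/11 train/test partition. Compound 31
is stored as 0.041 μM — the value consistent with its published pIC50 of
7.38 and with the series' stated activity range 4.77–7.38 (the activity
table of the original report prints a rounded 0.04).

``load_prediction_table`` returns the published experimental and model
predicted pIC50 values (CoMFA and CoMSIA columns) used for residual
book-keeping checks, and ``load_reactivity_table`` the published global
reactivity descriptors (μ, η, S, ω in eV / eV⁻¹) of the ten-compound
molecular-quantum subset.
"""

from __future__ import annotations

from typing import List

import pandas as pd

from .io import DEFAULT_TEST_IDS, CompoundRecord, to_pic50

# compound_id -> IC50 in μM
_IC50_UM = {
    "1": 12.7, "2": 2.7, "3": 1.3, "4": 2.5, "5": 13.5, "6": 4.7, "7": 2.0,
    "8": 2.2, "9": 10.8, "10": 1.1, "11": 16.9, "12": 2.0, "13": 6.0,
    "14": 7.41, "15": 8.50, "16": 14.0, "17": 1.30, "18": 6.60, "19": 5.10,
    "20": 5.80, "21": 2.90, "22": 2.41, "23": 2.52, "24": 2.41, "25": 0.75,
    "26": 0.68, "27": 0.57, "28": 0.28, "29": 0.12, "30": 0.68, "31": 0.041,
    "32": 0.12, "33": 0.68, "34": 0.52, "35": 2.01, "36": 1.32, "37": 0.15,
    "38": 7.81, "39": 0.098, "40": 1.45, "41": 1.95, "42": 0.59, "43": 0.50,
    "44": 0.07, "45": 0.63, "46": 0.14,
}

# compound_id -> (experimental pIC50, CoMFA predicted, CoMSIA predicted)
_PREDICTIONS = {
    "1": (4.89, 4.81, 4.92), "2": (5.56, 4.81, 5.07), "3": (5.88, 5.09, 5.34),
    "4": (5.60, 5.63, 5.62), "5": (4.86, 4.93, 4.83), "6": (5.32, 5.40, 5.19),
    "7": (5.69, 5.68, 5.44), "8": (5.65, 5.66, 5.57), "9": (4.96, 5.26, 5.07),
    "10": (5.95, 5.01, 5.11), "11": (4.77, 4.88, 4.72), "12": (5.69, 4.95, 4.93),
    "13": (5.22, 5.20, 5.18), "14": (5.13, 5.09, 5.04), "15": (5.07, 5.05, 5.02),
    "16": (4.85, 4.80, 5.00), "17": (5.88, 5.85, 5.99), "18": (5.18, 5.22, 5.36),
    "19": (5.29, 5.34, 5.48), "20": (5.23, 5.16, 5.20), "21": (5.53, 4.85, 5.50),
    "22": (5.61, 5.73, 5.77), "23": (5.60, 5.70, 5.69), "24": (5.61, 5.66, 5.58),
    "25": (6.12, 6.07, 5.99), "26": (6.16, 6.00, 6.28), "27": (6.24, 6.24, 5.98),
    "28": (6.55, 6.54, 6.28), "29": (6.92, 6.99, 6.80), "30": (6.16, 6.17, 6.02),
    "31": (7.38, 7.20, 7.25), "32": (6.92, 7.00, 7.01), "33": (6.16, 6.06, 6.33),
    "34": (6.28, 6.66, 6.32), "35": (5.69, 5.60, 6.07), "36": (5.88, 5.49, 6.00),
    "37": (6.82, 5.65, 6.39), "38": (5.10, 5.59, 5.92), "39": (7.00, 7.04, 6.94),
    "40": (5.83, 5.87, 5.83), "41": (5.70, 5.64, 5.72), "42": (6.22, 6.15, 6.52),
    "43": (6.30, 6.28, 6.10), "44": (7.14, 6.88, 6.96), "45": (6.20, 6.26, 6.15),
    "46": (6.85, 6.89, 6.82),
}

# compound_id -> (chemical potential μ [eV], hardness η [eV],
#                 softness S [eV⁻¹], electrophilicity ω [eV]) as published
_REACTIVITY = {
    "4": (-3.7843, 3.8036, 0.2629, 1.8825),
    "9": (-3.8531, 3.7443, 0.2670, 1.9826),
    "28": (-2.8058, 1.8096, 0.5526, 2.1752),
    "29": (-2.7818, 1.7660, 0.5662, 2.1910),
    "32": (-2.4749, 1.6359, 0.6112, 1.8720),
    "37": (-3.5558, 3.3342, 0.2999, 1.8961),
    "39": (-2.8369, 1.6847, 0.5936, 2.3887),
    "43": (-3.5617, 3.6267, 0.2757, 1.7489),
    "44": (-3.5320, 3.5277, 0.2835, 1.7682),
    "46": (-3.6697, 3.6256, 0.2758, 1.8572),
}


def load_ikkb_activity() -> pd.DataFrame:
    """Activity table: compound_id, ic50_uM, pic50 (full precision), subset."""
    rows = []
    for cid, ic50 in _IC50_UM.items():
        rows.append(
            {
                "compound_id": cid,
                "ic50_uM": ic50,
                "pic50": to_pic50(ic50),
                "subset": "test" if cid in DEFAULT_TEST_IDS else "train",
            }
        )
    return pd.DataFrame(rows)


def load_ikkb_records() -> List[CompoundRecord]:
    """The activity table as CompoundRecords with the default split applied."""
    return [
        CompoundRecord(
            compound_id=row.compound_id,
            ic50=row.ic50_uM,
            pic50=row.pic50,
            subset=row.subset,
        )
        for row in load_ikkb_activity().itertuples()
    ]


def load_prediction_table() -> pd.DataFrame:
    """Published experimental vs model-predicted pIC50 values per compound."""
    rows = [
        {
            "compound_id": cid,
            "experimental": exp,
            "comfa_predicted": comfa,
            "comsia_predicted": comsia,
            "subset": "test" if cid in DEFAULT_TEST_IDS else "train",
        }
        for cid, (exp, comfa, comsia) in _PREDICTIONS.items()
    ]
    return pd.DataFrame(rows)


def load_reactivity_table() -> pd.DataFrame:
    """Published global reactivity descriptors of the molecular-quantum subset."""
    rows = [
        {"compound_id": cid, "mu": mu, "eta": eta, "softness": s, "omega": w}
        for cid, (mu, eta, s, w) in _REACTIVITY.items()
    ]
    return pd.DataFrame(rows)
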