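"""Published reference panel of 18 PFAS for the IVIVE worked example.

Literature-reported values for 18 per- and polyfluoroalkyl substances:
identity (DTXSID), molecular weight, longest fluorinated-carbon chain (CF2),
OECD structural category, measured fraction unbound in plasma, measured in
vitro intrinsic clearance (µL/min/10⁶ cells), the predicted steady-state
blood concentration C_ss (µM) at a continuous 1 mg/kg/day exposure, the
5th-percentile AC50 point of departure from high-throughput bioactivity
screening (µM), and the administered equivalent dose (mg/kg/day).

The AED column is algebraically determined by the POD and C_ss columns
(AED = POD / C_ss × 1 mg/kg/day), which :func:`aed_identity_check` verifies
at each row's printed precision.  ``NA`` marks chemicals with no positive
bioactivity curve after filtering.  AED strings are kept verbatim so the
printed number of decimals is preserved.
"""

from __future__ import annotations

import math

import pandas as pd

__all__ = ["load_reference_panel", "aed_identity_check"]

# dtxsid, name, mol_wt, cf2, category, fup, clint, css_uM, pod_uM, aed (string)
_PANEL = [
    ("DTXSID6062599", "PFPeA", 263.98, 4, "PFCAs", 0.0440, 0.0, 20.78, None, "NA"),
    ("DTXSID5030030", "PFBS", 299.95, 4, "PFSAs", 0.0128, 4.75, 7.51, 6.22, "0.83"),
    ("DTXSID30891564", "4:2 FTS", 327.98, 4, "n:2 FTSAs", 0.0050, 4.28, 19.12, None, "NA"),
    ("DTXSID3031862", "PFHxA", 313.98, 5, "PFCAs", 0.0068, 0.0, 113.04, 9.06, "0.08"),
    ("DTXSID20874028", "5:3 FTCA", 342.01, 5, "n:3 acids", 0.0059, 11.84, 6.18, 6.10, "0.99"),
    ("DTXSID6067331", "6:2 FTS", 427.98, 6, "n:2 FTSAs", 0.0143, 1.4, 12.36, 11.02, "0.89"),
    ("DTXSID1037303", "PFHpA", 363.98, 6, "PFCAs", 0.0004, 0.0, 1657.68, 16.57, "0.01"),
    ("DTXSID70379917", "6:3 FTCA", 392.01, 6, "n:3 acids", 0.0023, 5.05, 30.01, 5.49, "0.18"),
    ("DTXSID70565479", "8H-PFOA", 395.98, 6, "1-H PFCAs", 0.0021, 0.0, 290.23, 10.59, "0.04"),
    ("DTXSID7040150", "PFHxS", 399.94, 6, "PFSAs", 0.0009, 0.0, 670.49, 22.38, "0.033"),
    ("DTXSID50226894", "9H-PFNA", 445.98, 7, "1-H PFCAs", 0.0009, 0.0, 601.28, 2.47, "0.004"),
    ("DTXSID8059920", "PFHpS", 449.94, 7, "PFSAs", 0.0006, 0.0, 893.98, 18.05, "0.02"),
    ("DTXSID90382620", "7:3 FTCA", 442.01, 7, "n:3 acids", 0.0051, 15.7, 4.99, 0.96, "0.19"),
    ("DTXSID8031865", "PFOA", 413.97, 7, "PFCAs", 0.0010, 0.0, 582.99, 8.07, "0.01"),
    ("DTXSID8031863", "PFNA", 463.97, 8, "PFCAs", 0.0016, 0.0, 325.11, 14.73, "0.05"),
    ("DTXSID3031864", "PFOS", 499.94, 8, "PFSAs", 0.0049, 0.0, 98.52, 8.02, "0.08"),
    ("DTXSID5061954", "11H-PFUnDA", 545.98, 9, "1-H PFCAs", 0.0015, 0.0, 294.69, 7.41, "0.03"),
    ("DTXSID3031860", "PFDA", 513.97, 9, "PFCAs", 0.0027, 0.0, 173.91, 10.89, "0.06"),
]

_COLUMNS = [
    "chemical_id", "name", "mol_wt", "cf2", "oecd_category", "fup",
    "clint", "css_uM", "pod_uM", "aed_str",
]


def load_reference_panel() -> pd.DataFrame:
    """The 18-chemical reference panel as a tidy DataFrame.

    ``pod_uM`` is NaN where no POD was determined; ``aed_str`` holds the
    reported AED verbatim (``"NA"`` when absent) and ``aed_mg_per_kg_day``
    its numeric value.
    """
    df = pd.DataFrame(_PANEL, columns=_COLUMNS)
    df["aed_mg_per_kg_day"] = [
        float(s) if s != "NA" else math.nan for s in df["aed_str"]
    ]
    return df


def _decimals(number_str: str) -> int:
    return len(number_str.split(".")[1]) if "." in number_str else 0


def aed_identity_check(panel: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recompute AED = POD / C_ss for every POD-bearing row.

    Returns a frame with the recomputed dose, the value rounded to each
    row's reported precision, and a boolean ``matches`` column.  Under the
    steady-state model this identity must hold exactly, so any mismatch
    signals an inconsistent panel.
    """
    panel = load_reference_panel() if panel is None else panel
    rows = []
    for _, r in panel.iterrows():
        if r["aed_str"] == "NA" or pd.isna(r["pod_uM"]):
            continue
        aed = r["pod_uM"] / r["css_uM"]  # × 1 mg/kg/day
        nd = _decimals(r["aed_str"])
        rows.append(
            {
                "chemical_id": r["chemical_id"],
                "name": r["name"],
                "aed_computed": aed,
                "aed_rounded": round(aed, nd),
                "aed_reported": float(r["aed_str"]),
                "matches": round(aed, nd) == float(r["aed_str"]),
            }
        )
    return pd.DataFrame(rows)
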