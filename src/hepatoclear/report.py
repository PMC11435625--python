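"""Category-level summaries and publication-shaped tables.

Three outputs: a distribution summary of point estimates across a panel
(``summary.csv``), a wide pivot of Cl_int by fluorinated-chain length and
structural category (``category_pivot.csv``), and the combined
identity/TK/IVIVE table with one row per chemical (``full_table.csv``).
Absent PODs and AEDs render as the literal string ``NA``; other missing
numerics render as empty fields.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ChemicalRecord
from .ivive import IVIVEResult
from .point import ClintEstimate, ClintSummary

__all__ = [
    "CategorySummary",
    "category_summaries",
    "category_pivot",
    "full_table",
    "write_full_table",
    "write_summary",
    "plot_clint_distribution",
]

NA = "NA"


@dataclass
class CategorySummary:
    oecd_category: str
    n: int
    n_zero: int
    mean_clint: float
    min_clint: float
    max_clint: float


def _match(estimates: Sequence[ClintEstimate], chemicals: Sequence[ChemicalRecord]):
    recs = {c.chemical_id: c for c in chemicals}
    unknown = sorted(e.chemical_id for e in estimates if e.chemical_id not in recs)
    if unknown:
        raise ValueError(f"unknown chemical ids: {unknown}")
    return recs


def category_summaries(
    estimates: Sequence[ClintEstimate], chemicals: Sequence[ChemicalRecord]
) -> list[CategorySummary]:
    """Per-category n, zero count, mean and range of Cl_int point estimates."""
    recs = _match(estimates, chemicals)
    by_cat: dict[str, list[ClintEstimate]] = {}
    for e in estimates:
        cat = recs[e.chemical_id].oecd_category or "uncategorized"
        by_cat.setdefault(cat, []).append(e)
    out = []
    for cat in sorted(by_cat):
        vals = np.array([e.clint for e in by_cat[cat]])
        out.append(
            CategorySummary(
                oecd_category=cat,
                n=len(vals),
                n_zero=int(np.sum(~np.array([e.significant for e in by_cat[cat]]))),
                mean_clint=float(vals.mean()),
                min_clint=float(vals.min()),
                max_clint=float(vals.max()),
            )
        )
    return out


def category_pivot(
    estimates: Sequence[ClintEstimate],
    chemicals: Sequence[ChemicalRecord],
    *,
    on_duplicate: str = "error",
) -> pd.DataFrame:
    """Wide Cl_int table: one row per CF2 chain length, one column per category.

    Cell values are the point estimates themselves — never aggregated.  When
    two chemicals share a (CF2, category) cell the default is to raise;
    ``on_duplicate`` may instead name a reduction ("min", "max", "mean").
    Chemicals without a category land in an ``uncategorized`` column; empty
    cells are NaN.
    """
    recs = _match(estimates, chemicals)
    if not estimates:
        return pd.DataFrame()
    rows = [
        {
            "cf2": recs[e.chemical_id].cf2,
            "category": recs[e.chemical_id].oecd_category or "uncategorized",
            "clint": e.clint,
        }
        for e in estimates
    ]
    df = pd.DataFrame(rows)
    dup = df.duplicated(subset=["cf2", "category"], keep=False)
    if dup.any() and on_duplicate == "error":
        cells = df[dup][["cf2", "category"]].drop_duplicates().to_dict("records")
        raise ValueError(
            f"multiple chemicals share pivot cell(s) {cells}; pass "
            "on_duplicate='min'|'max'|'mean' to aggregate"
        )
    agg = "first" if not dup.any() else on_duplicate
    return df.pivot_table(
        index="cf2", columns="category", values="clint", aggfunc=agg
    ).sort_index()


def full_table(
    chemicals: Sequence[ChemicalRecord],
    estimates: Sequence[ClintEstimate],
    ivive_results: Sequence[IVIVEResult],
) -> pd.DataFrame:
    """Combined per-chemical report: identity, binding, Cl_int, C_ss, POD, AED.

    Every input chemical appears exactly once; estimates and IVIVE rows are
    matched by id and an error lists any orphans.
    """
    est = {e.chemical_id: e for e in estimates}
    ivr = {r.chemical_id: r for r in ivive_results}
    ids = {c.chemical_id for c in chemicals}
    orphans = sorted((set(est) | set(ivr)) - ids)
    if orphans:
        raise ValueError(f"results for unknown chemical ids: {orphans}")
    rows = []
    for c in chemicals:
        e = est.get(c.chemical_id)
        r = ivr.get(c.chemical_id)
        rows.append(
            {
                "chemical_id": c.chemical_id,
                "name": c.name,
                "mol_wt": c.mol_wt,
                "cf2": c.cf2,
                "oecd_category": c.oecd_category,
                "fup": c.fup,
                "clint": e.clint if e else np.nan,
                "css_uM": r.css_uM if r else np.nan,
                "pod_uM": (r.pod_uM if r and r.pod_uM is not None else np.nan),
                "aed_mg_per_kg_day": (
                    r.aed_mg_per_kg_day
                    if r and r.aed_mg_per_kg_day is not None
                    else np.nan
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chemical_id", "name", "mol_wt", "cf2", "oecd_category", "fup",
            "clint", "css_uM", "pod_uM", "aed_mg_per_kg_day",
        ],
    )


def write_full_table(table: pd.DataFrame, path) -> None:
    """Write the combined table; absent POD/AED cells become literal ``NA``."""
    out = table.copy()
    for col in ("pod_uM", "aed_mg_per_kg_day"):
        out[col] = out[col].map(lambda v: NA if pd.isna(v) else v)
    out.to_csv(path, index=False)


def write_summary(summary: ClintSummary, path) -> None:
    row = {
        "n": summary.n,
        "n_zero": summary.n_zero,
        "median_significant": summary.median_significant,
    }
    for p, v in summary.percentiles.items():
        row[f"p{int(round(p * 100))}"] = v
    pd.DataFrame([row]).to_csv(path, index=False)


def plot_clint_distribution(estimates: Sequence[ClintEstimate], ax=None):
    """Optional plotting hook: histogram of point estimates with the zero
    spike separated.  Requires matplotlib."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    vals = np.array([e.clint for e in estimates])
    ax.hist(vals[vals > 0], bins=20, color="#4878b0", label="cleared")
    ax.bar([0], [np.sum(vals == 0)], width=0.5, color="#b0b0b0", label="no clearance")
    ax.set_xlabel("Cl$_{int}$ (µL/min/10$^6$ cells)")
    ax.set_ylabel("chemicals")
    ax.legend(frameon=False)
    return ax
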