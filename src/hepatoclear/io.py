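"""Data model and delimited-text I/O for substrate-depletion experiments.

The assay design: a test chemical is incubated at ``C_test`` (default 1 µM)
with a pooled primary human hepatocyte suspension at ~0.5 × 10⁶ viable
cells/mL, and triplicate samples are drawn over 0–240 min.  Each drawn sample
yields a mass-spectrometric *response* — a peak area, or a peak-area ratio to
an isotope-labelled internal standard — for the parent compound.  Matched
negative controls (medium only, or heat-inactivated hepatocytes) isolate
abiotic loss, and calibration standards at known nominal concentrations tie
response to concentration.

Everything downstream consumes the two dataclasses defined here:

* :class:`Measurement` — one response at one time point in one condition.
* :class:`DepletionDataset` — all measurements for one chemical plus the
  assay constants (C_test, cell density, LOQ).

On-disk format is a single tidy CSV, one row per measurement (see
:data:`DEPLETION_COLUMNS`).  Concentrations are µM and times are minutes
throughout; molecular weight enters only at the IVIVE boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "CONDITIONS",
    "CONTROL_CONDITIONS",
    "DEPLETION_COLUMNS",
    "CHEMICAL_COLUMNS",
    "SchemaError",
    "ValidationError",
    "Measurement",
    "DepletionDataset",
    "ChemicalRecord",
    "read_depletion_table",
    "write_depletion_table",
    "read_chemical_table",
    "write_chemical_table",
    "validate_chemical_table",
]

#: Valid incubation conditions. ``cells`` is the live metabolic incubation;
#: ``no_cells`` and ``heat_inactivated`` are the abiotic negative controls;
#: ``calibration`` rows are external standards at known nominal concentration.
CONDITIONS = ("cells", "no_cells", "heat_inactivated", "calibration")
CONTROL_CONDITIONS = ("no_cells", "heat_inactivated")

#: Core tidy-CSV schema, one row per measurement.
DEPLETION_COLUMNS = [
    "chemical_id",
    "time_min",
    "condition",
    "replicate",
    "response",
    "has_internal_standard",
    "nominal_conc_uM",
]

#: Per-dataset assay constants appended after the core columns so that a
#: written table round-trips to an identical dataset.  Readers tolerate their
#: absence (defaults apply).
DATASET_META_COLUMNS = ["c_test_uM", "cell_density_millions_per_mL", "loq_uM"]

CHEMICAL_COLUMNS = [
    "chemical_id",
    "name",
    "mol_wt",
    "cf2",
    "oecd_category",
    "fup",
    "blood_plasma_ratio",
]


class SchemaError(ValueError):
    """A delimited file does not match the documented column schema."""


class ValidationError(ValueError):
    """A dataset or record violates a type invariant; message names the rule."""


@dataclass
class Measurement:
    """One analyte response at one time point.

    ``response`` is the raw instrument readout: a peak area, or the peak-area
    ratio to the internal standard when ``has_internal_standard`` is true.
    ``nominal_conc_uM`` is required for (and only meaningful on) calibration
    rows.
    """

    chemical_id: str
    time_min: float
    condition: str
    replicate: int = 1
    response: float = 0.0
    has_internal_standard: bool = True
    nominal_conc_uM: float | None = None

    def validate(self) -> list[str]:
        """Return invariant violations for this row (empty when valid)."""
        problems: list[str] = []
        who = f"{self.chemical_id}"
        if self.condition not in CONDITIONS:
            problems.append(
                f"{who}: condition {self.condition!r} not one of {CONDITIONS}"
            )
        if not math.isfinite(self.time_min) or self.time_min < 0:
            problems.append(f"{who}: time_min must be finite and >= 0")
        if not math.isfinite(self.response) or self.response < 0:
            problems.append(f"{who}: response must be finite and >= 0")
        if self.replicate < 1:
            problems.append(f"{who}: replicate must be >= 1")
        if self.condition == "calibration":
            if self.nominal_conc_uM is None or not self.nominal_conc_uM > 0:
                problems.append(
                    f"{who}: calibration rows require nominal_conc_uM > 0"
                )
        elif self.nominal_conc_uM is not None:
            problems.append(
                f"{who}: nominal_conc_uM only allowed on calibration rows"
            )
        return problems


@dataclass
class DepletionDataset:
    """All measurements for one chemical in one depletion experiment."""

    chemical_id: str
    measurements: list[Measurement] = field(default_factory=list)
    c_test_uM: float = 1.0
    cell_density_millions_per_mL: float = 0.5
    loq_uM: float = 0.01

    # -- validation ---------------------------------------------------------
    def problems(self) -> list[str]:
        """All invariant violations, each naming the chemical and the rule."""
        out: list[str] = []
        cid = self.chemical_id
        if not self.c_test_uM > 0:
            out.append(f"{cid}: c_test_uM must be > 0")
        if not self.cell_density_millions_per_mL > 0:
            out.append(f"{cid}: cell_density_millions_per_mL must be > 0")
        if not self.loq_uM > 0:
            out.append(f"{cid}: loq_uM must be > 0")
        elif self.loq_uM >= self.c_test_uM:
            out.append(f"{cid}: loq_uM must be < c_test_uM")
        for m in self.measurements:
            if m.chemical_id != cid:
                out.append(f"{cid}: row with foreign chemical_id {m.chemical_id!r}")
            out.extend(m.validate())
        cell_times = {m.time_min for m in self.measurements if m.condition == "cells"}
        if len(cell_times) < 2:
            out.append(f"{cid}: needs >= 2 distinct time points in the cells condition")
        return out

    def validate(self) -> None:
        probs = self.problems()
        if probs:
            raise ValidationError("; ".join(probs))

    # -- access helpers -----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Tidy frame of the measurements (core schema columns only)."""
        return pd.DataFrame(
            {
                "chemical_id": [m.chemical_id for m in self.measurements],
                "time_min": [m.time_min for m in self.measurements],
                "condition": [m.condition for m in self.measurements],
                "replicate": [m.replicate for m in self.measurements],
                "response": [m.response for m in self.measurements],
                "has_internal_standard": [
                    m.has_internal_standard for m in self.measurements
                ],
                "nominal_conc_uM": [m.nominal_conc_uM for m in self.measurements],
            }
        )

    def rows(self, *conditions: str) -> list[Measurement]:
        return [m for m in self.measurements if m.condition in conditions]

    @property
    def has_controls(self) -> bool:
        return any(m.condition in CONTROL_CONDITIONS for m in self.measurements)

    @property
    def has_calibration(self) -> bool:
        return any(m.condition == "calibration" for m in self.measurements)

    @property
    def t_max(self) -> float:
        times = [m.time_min for m in self.measurements if m.condition != "calibration"]
        return max(times) if times else 0.0

    def sorted(self) -> "DepletionDataset":
        """Copy with measurements in canonical order (condition, time, rep)."""
        order = {c: i for i, c in enumerate(CONDITIONS)}
        ms = sorted(
            self.measurements,
            key=lambda m: (
                order.get(m.condition, 99),
                m.time_min,
                m.replicate,
                m.nominal_conc_uM or 0.0,
            ),
        )
        return replace(self, measurements=ms)


@dataclass
class ChemicalRecord:
    """Identity and binding metadata for one chemical.

    ``cf2`` is the longest contiguous chain of fluorinated carbons; ``fup``
    is the experimentally measured fraction unbound in plasma, and
    ``blood_plasma_ratio`` the blood-to-plasma partitioning value used to
    convert it to fraction unbound in blood.
    """

    chemical_id: str
    name: str
    mol_wt: float
    cf2: int = 0
    oecd_category: str = ""
    fup: float = 1.0
    blood_plasma_ratio: float = 1.0

    def problems(self) -> list[str]:
        out = []
        cid = self.chemical_id
        if not self.mol_wt > 0:
            out.append(f"{cid}: mol_wt must be > 0")
        if not 0 < self.fup <= 1:
            out.append(f"{cid}: fup out of (0,1]")
        if not self.blood_plasma_ratio > 0:
            out.append(f"{cid}: blood_plasma_ratio must be > 0")
        if self.cf2 < 0:
            out.append(f"{cid}: cf2 must be >= 0")
        return out


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


_TRUE = {"true", "1", "t", "yes"}


def _as_bool(x) -> bool:
    if isinstance(x, bool):
        return x
    return str(x).strip().lower() in _TRUE


def read_depletion_table(
    path,
    *,
    c_test_uM: float = 1.0,
    cell_density_millions_per_mL: float = 0.5,
    loq_uM: float = 0.01,
    validate: bool = True,
) -> list[DepletionDataset]:
    """Read a tidy depletion CSV into one :class:`DepletionDataset` per chemical.

    The keyword defaults supply the assay constants when the optional
    metadata columns (``c_test_uM``, ``cell_density_millions_per_mL``,
    ``loq_uM``) are not present in the file.

    Raises :class:`SchemaError` for a malformed file and
    :class:`ValidationError` (naming the chemical and rule) when ``validate``
    is true and a dataset breaks an invariant.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, DEPLETION_COLUMNS, path)

    datasets: list[DepletionDataset] = []
    for cid, grp in df.groupby("chemical_id", sort=True):
        meta = {}
        for col, default in zip(
            DATASET_META_COLUMNS, (c_test_uM, cell_density_millions_per_mL, loq_uM)
        ):
            if col in grp.columns and grp[col].notna().any():
                meta[col] = float(grp[col].dropna().iloc[0])
            else:
                meta[col] = default
        ms = []
        for _, row in grp.iterrows():
            nominal = row["nominal_conc_uM"]
            ms.append(
                Measurement(
                    chemical_id=str(cid),
                    time_min=float(row["time_min"]),
                    condition=str(row["condition"]),
                    replicate=int(row["replicate"]),
                    response=float(row["response"]),
                    has_internal_standard=_as_bool(row["has_internal_standard"]),
                    nominal_conc_uM=None if pd.isna(nominal) else float(nominal),
                )
            )
        ds = DepletionDataset(chemical_id=str(cid), measurements=ms, **meta).sorted()
        if validate:
            ds.validate()
        datasets.append(ds)
    return datasets


def write_depletion_table(datasets: Iterable[DepletionDataset], path) -> Path:
    """Write datasets to a tidy CSV readable by :func:`read_depletion_table`.

    Output row order and column order are canonical, so writing the result of
    a read produces a byte-identical file.
    """
    path = Path(path)
    frames = []
    for ds in datasets:
        ds = ds.sorted()
        f = ds.to_frame()
        f["c_test_uM"] = ds.c_test_uM
        f["cell_density_millions_per_mL"] = ds.cell_density_millions_per_mL
        f["loq_uM"] = ds.loq_uM
        frames.append(f)
    cols = DEPLETION_COLUMNS + DATASET_META_COLUMNS
    if frames:
        out = pd.concat(frames, ignore_index=True).sort_values(
            "chemical_id", kind="stable"
        )
    else:
        out = pd.DataFrame(columns=cols)
    out.to_csv(path, index=False, columns=cols)
    return path


def read_chemical_table(path) -> list[ChemicalRecord]:
    """Read ``chemicals.csv`` (see :data:`CHEMICAL_COLUMNS`)."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, CHEMICAL_COLUMNS, path)
    records = []
    for _, row in df.iterrows():
        records.append(
            ChemicalRecord(
                chemical_id=str(row["chemical_id"]),
                name=str(row["name"]),
                mol_wt=float(row["mol_wt"]),
                cf2=int(row["cf2"]),
                oecd_category="" if pd.isna(row["oecd_category"]) else str(row["oecd_category"]),
                fup=float(row["fup"]),
                blood_plasma_ratio=(
                    1.0 if pd.isna(row["blood_plasma_ratio"]) else float(row["blood_plasma_ratio"])
                ),
            )
        )
    return records


def write_chemical_table(records: Iterable[ChemicalRecord], path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [
            {
                "chemical_id": r.chemical_id,
                "name": r.name,
                "mol_wt": r.mol_wt,
                "cf2": r.cf2,
                "oecd_category": r.oecd_category,
                "fup": r.fup,
                "blood_plasma_ratio": r.blood_plasma_ratio,
            }
            for r in records
        ],
        columns=CHEMICAL_COLUMNS,
    )
    df.to_csv(path, index=False)
    return path


def validate_chemical_table(records: Sequence[ChemicalRecord]) -> list[str]:
    """Report-based validation: list every invariant violation (never raises).

    An empty list means all records are valid.  Duplicate ``chemical_id``
    values are flagged in addition to per-record rule violations.
    """
    report: list[str] = []
    seen: dict[str, int] = {}
    for r in records:
        report.extend(r.problems())
        seen[r.chemical_id] = seen.get(r.chemical_id, 0) + 1
    for cid, n in seen.items():
        if n > 1:
            report.append(f"{cid}: duplicate chemical_id ({n} rows)")
    return report
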