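"""In vitro–in vivo extrapolation and reverse dosimetry.

Forward dosimetry chain for one chemical under continuous oral exposure at
``dose_rate`` (default 1 mg/kg/day):

* f_ub = f_up / R_b — fraction unbound in blood from the plasma value and
  the blood-to-plasma partitioning ratio.
* Cl_int,whole = Cl_int × hepatocellularity × liver mass × 60 × 10⁻⁶ (L/h)
  — scale the per-million-cells in vitro rate to the whole liver.
* Cl_h = Q_h·f_ub·Cl_int,whole / (Q_h + f_ub·Cl_int,whole) — well-stirred
  liver model with restrictive (unbound-only) clearance, capped at hepatic
  blood flow Q_h.
* Cl_renal = GFR·f_ub — passive glomerular filtration of unbound chemical.
* C_ss = (dose_rate·BW/24) / (Cl_renal + Cl_h) in mg/L, converted to µM via
  the molecular weight.

Reverse dosimetry inverts the linear C_ss–dose relationship: the
administered equivalent dose is AED = POD / C_ss(at unit dose) × dose_rate,
where the POD is the 5th-percentile AC50 across filtered positive
bioactivity curves (hitcall ≥ 0.9, fewer than four caution flags).
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import ChemicalRecord

__all__ = [
    "PhysioParams",
    "IVIVEResult",
    "BioactivityCurve",
    "fub_from_fup",
    "scale_clint",
    "hepatic_clearance",
    "renal_clearance",
    "css_steady_state",
    "derive_pod",
    "aed_reverse_dosimetry",
    "ivive_pipeline",
    "propagate_uncertainty",
    "read_curve_table",
    "write_ivive_results",
]

CURVE_COLUMNS = ["chemical_id", "ac50_uM", "hitcall", "n_flags"]


@dataclass
class PhysioParams:
    """Human physiological scalars for the steady-state model.

    Defaults are standard adult IVIVE values: 70 kg body weight, 6.7 L/h
    glomerular filtration rate, 90 L/h hepatic blood flow, 1800 g liver,
    110 × 10⁶ hepatocytes per gram of liver, and a 1 mg/kg/day dose rate.
    """

    body_weight_kg: float = 70.0
    gfr_L_per_h: float = 6.7
    hepatic_blood_flow_L_per_h: float = 90.0
    liver_mass_g: float = 1800.0
    hepatocellularity_millions_per_g: float = 110.0
    dose_rate_mg_per_kg_day: float = 1.0

    def validate(self) -> None:
        for name, value in vars(self).items():
            if not value > 0:
                raise ValueError(f"PhysioParams.{name} must be > 0 (got {value})")

    @classmethod
    def from_yaml(cls, path) -> "PhysioParams":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        params = cls(**data)
        params.validate()
        return params


@dataclass
class IVIVEResult:
    chemical_id: str
    fub: float
    cl_int_whole_L_per_h: float
    cl_hepatic_L_per_h: float
    cl_renal_L_per_h: float
    css_mg_per_L: float
    css_uM: float
    pod_uM: float | None = None
    aed_mg_per_kg_day: float | None = None


@dataclass
class BioactivityCurve:
    """One concentration-response curve from a bioactivity screen."""

    chemical_id: str
    ac50_uM: float
    hitcall: float  # probability the curve is a true positive, in [0,1]
    n_flags: int = 0  # caution flags raised during curve review


def fub_from_fup(fup: float, blood_plasma_ratio: float = 1.0) -> float:
    """Fraction unbound in blood from the plasma value: f_ub = f_up / R_b.

    Clipped to 1 (with a warning) when a small blood-to-plasma ratio would
    push it above unity.
    """
    if not 0 < fup <= 1:
        raise ValueError(f"fup must be in (0,1], got {fup}")
    if not blood_plasma_ratio > 0:
        raise ValueError(f"blood_plasma_ratio must be > 0, got {blood_plasma_ratio}")
    fub = fup / blood_plasma_ratio
    if fub > 1.0:
        _warnings.warn(
            f"f_ub = f_up/R_b = {fub:.3g} > 1; clipping to 1", stacklevel=2
        )
        fub = 1.0
    return fub


def scale_clint(clint: float, physio: PhysioParams) -> float:
    """Whole-liver intrinsic clearance (L/h) from µL/min/10⁶ cells.

    Cl_int,whole = Cl_int × hepatocellularity × liver mass × 60 min/h ×
    10⁻⁶ L/µL.
    """
    if clint < 0:
        raise ValueError("clint must be >= 0")
    return (
        clint
        * physio.hepatocellularity_millions_per_g
        * physio.liver_mass_g
        * 60.0
        * 1e-6
    )


def hepatic_clearance(cl_int_whole: float, fub: float, physio: PhysioParams) -> float:
    """Well-stirred liver model: Cl_h = Q·f_ub·Cl_int / (Q + f_ub·Cl_int)."""
    if cl_int_whole < 0 or fub < 0:
        raise ValueError("inputs must be >= 0")
    q = physio.hepatic_blood_flow_L_per_h
    x = fub * cl_int_whole
    if x == 0:
        return 0.0
    return q * x / (q + x)


def renal_clearance(fub: float, physio: PhysioParams) -> float:
    """Passive renal clearance of unbound chemical: GFR × f_ub (L/h)."""
    return physio.gfr_L_per_h * fub


def css_steady_state(
    record: ChemicalRecord,
    clint: float,
    physio: PhysioParams | None = None,
) -> IVIVEResult:
    """Steady-state blood concentration under continuous unit-dose exposure.

    C_ss (mg/L) = dose_rate·BW / 24 h divided by total clearance
    (GFR·f_ub + Cl_h); µM via the molecular weight.
    """
    physio = physio or PhysioParams()
    physio.validate()
    probs = record.problems()
    if probs:
        raise ValueError("; ".join(probs))
    fub = fub_from_fup(record.fup, record.blood_plasma_ratio)
    cl_int_whole = scale_clint(clint, physio)
    cl_h = hepatic_clearance(cl_int_whole, fub, physio)
    cl_r = renal_clearance(fub, physio)
    total = cl_h + cl_r
    if total <= 0:
        raise ValueError(
            f"{record.chemical_id}: no elimination pathway (total clearance 0)"
        )
    dose_mg_per_h = physio.dose_rate_mg_per_kg_day * physio.body_weight_kg / 24.0
    css_mg_per_L = dose_mg_per_h / total
    css_uM = css_mg_per_L / record.mol_wt * 1000.0
    return IVIVEResult(
        chemical_id=record.chemical_id,
        fub=fub,
        cl_int_whole_L_per_h=cl_int_whole,
        cl_hepatic_L_per_h=cl_h,
        cl_renal_L_per_h=cl_r,
        css_mg_per_L=css_mg_per_L,
        css_uM=css_uM,
    )


def derive_pod(
    curves: Sequence[BioactivityCurve],
    *,
    hitcall_min: float = 0.9,
    max_flags: int = 3,
    quantile: float = 0.05,
    quantile_method: str = "linear",
) -> float | None:
    """5th-percentile AC50 across filtered positive curves, or None.

    Curves with four or more caution flags are censored and only curves with
    hitcall ≥ 0.9 count as positive.  None (no surviving curve) means no in
    vitro POD could be determined.
    """
    surviving = [
        c.ac50_uM
        for c in curves
        if c.n_flags <= max_flags and c.hitcall >= hitcall_min
    ]
    if not surviving:
        return None
    return float(np.quantile(np.array(surviving, dtype=float), quantile,
                             method=quantile_method))


def aed_reverse_dosimetry(
    pod_uM: float, css_uM_at_unit_dose: float, dose_rate: float = 1.0
) -> float:
    """Administered equivalent dose: AED = POD / C_ss × dose_rate.

    Valid because C_ss is linear in dose under the steady-state model, so
    the external dose producing a blood concentration equal to the POD is
    the unit dose scaled by POD/C_ss.
    """
    if not pod_uM > 0 or not css_uM_at_unit_dose > 0:
        raise ValueError("pod_uM and css_uM must be > 0")
    return pod_uM / css_uM_at_unit_dose * dose_rate


def ivive_pipeline(
    record: ChemicalRecord,
    clint: float,
    curves: Sequence[BioactivityCurve] = (),
    physio: PhysioParams | None = None,
) -> IVIVEResult:
    """Forward C_ss plus POD filtering and reverse dosimetry for one chemical."""
    physio = physio or PhysioParams()
    result = css_steady_state(record, clint, physio)
    pod = derive_pod([c for c in curves if c.chemical_id == record.chemical_id])
    result.pod_uM = pod
    if pod is not None:
        result.aed_mg_per_kg_day = aed_reverse_dosimetry(
            pod, result.css_uM, physio.dose_rate_mg_per_kg_day
        )
    return result


def propagate_uncertainty(
    clint_samples: Sequence[float],
    fup_samples: Sequence[float],
    record: ChemicalRecord,
    physio: PhysioParams | None = None,
    pod_uM: float | None = None,
    n_draws: int = 5000,
    seed: int = 0,
) -> dict[str, float]:
    """Monte-Carlo propagation of TK uncertainty into C_ss and AED.

    Each draw pairs an intrinsic-clearance posterior sample with a fraction
    unbound sample, recomputes C_ss (and AED when a POD is supplied), and
    the medians and central 95% intervals are reported.  Deterministic given
    ``seed``.
    """
    clint_samples = np.asarray(clint_samples, dtype=float)
    fup_samples = np.asarray(fup_samples, dtype=float)
    if clint_samples.size == 0 or fup_samples.size == 0:
        raise ValueError("empty sample sets")
    physio = physio or PhysioParams()
    rng = np.random.default_rng(seed)
    ci = rng.integers(0, clint_samples.size, n_draws)
    fi = rng.integers(0, fup_samples.size, n_draws)
    css = np.empty(n_draws)
    for j in range(n_draws):
        rec = ChemicalRecord(
            chemical_id=record.chemical_id,
            name=record.name,
            mol_wt=record.mol_wt,
            cf2=record.cf2,
            oecd_category=record.oecd_category,
            fup=float(np.clip(fup_samples[fi[j]], 1e-12, 1.0)),
            blood_plasma_ratio=record.blood_plasma_ratio,
        )
        css[j] = css_steady_state(rec, max(0.0, clint_samples[ci[j]]), physio).css_uM
    out = {
        "css_uM_median": float(np.percentile(css, 50)),
        "css_uM_lo": float(np.percentile(css, 2.5)),
        "css_uM_hi": float(np.percentile(css, 97.5)),
    }
    if pod_uM is not None:
        aed = pod_uM / css * physio.dose_rate_mg_per_kg_day
        out.update(
            aed_median=float(np.percentile(aed, 50)),
            aed_lo=float(np.percentile(aed, 2.5)),
            aed_hi=float(np.percentile(aed, 97.5)),
        )
    return out


def read_curve_table(path) -> list[BioactivityCurve]:
    """Read ``curves.csv`` (columns ``chemical_id,ac50_uM,hitcall,n_flags``)."""
    df = pd.read_csv(Path(path))
    missing = [c for c in CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return [
        BioactivityCurve(
            chemical_id=str(r["chemical_id"]),
            ac50_uM=float(r["ac50_uM"]),
            hitcall=float(r["hitcall"]),
            n_flags=int(r["n_flags"]),
        )
        for _, r in df.iterrows()
    ]


IVIVE_RESULT_COLUMNS = [
    "chemical_id", "fub", "cl_hepatic_L_per_h", "cl_renal_L_per_h",
    "css_mg_per_L", "css_uM", "pod_uM", "aed_mg_per_kg_day",
]


def write_ivive_results(results: Iterable[IVIVEResult], path) -> None:
    df = pd.DataFrame(
        [
            {
                "chemical_id": r.chemical_id,
                "fub": r.fub,
                "cl_hepatic_L_per_h": r.cl_hepatic_L_per_h,
                "cl_renal_L_per_h": r.cl_renal_L_per_h,
                "css_mg_per_L": r.css_mg_per_L,
                "css_uM": r.css_uM,
                "pod_uM": r.pod_uM,
                "aed_mg_per_kg_day": r.aed_mg_per_kg_day,
            }
            for r in results
        ],
        columns=IVIVE_RESULT_COLUMNS,
    )
    df.to_csv(path, index=False)
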