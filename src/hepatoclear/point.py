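"""Frequentist intrinsic-clearance pipeline for substrate-depletion data.

Workflow for one chemical:

1. :func:`fit_calibration` — zero-intercept least squares of calibration
   responses on nominal concentration gives the response factor RF
   (response units per µM).
2. :func:`quantify` — convert every incubation response to a concentration
   ``conc = response / RF`` and flag values below the LOQ as censored.
3. :func:`fit_log_linear` — ordinary least squares of ln(conc) on time for
   one condition.  First-order depletion makes this line straight with slope
   equal to minus the elimination rate constant k (1/min).
4. :func:`clint_from_fit` — significance-gate the slope and convert to
   intrinsic clearance, ``Cl_int = k × 1000 / density`` in µL/min/10⁶ cells
   (the volume of incubation medium per million cells is 1000/density µL).
5. :func:`assess_abiotic` — the same regression applied to the pooled
   negative-control rows estimates non-metabolic loss.

The significance gate is directional by default: a chemical is *cleared*
when the slope is negative and the one-sided p-value for depletion is below
``alpha`` (0.05), giving a 5% false-positive rate on stable chemicals.  The
two-sided slope p-value is always reported in :class:`RegressionFit`.

Censored (<LOQ) observations are excluded here; only the Bayesian module
handles them in the likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import CONTROL_CONDITIONS, DepletionDataset, ValidationError

__all__ = [
    "CalibrationError",
    "RegressionError",
    "CalibrationFit",
    "RegressionFit",
    "ClintEstimate",
    "ClintSummary",
    "fit_calibration",
    "quantify",
    "fit_log_linear",
    "clint_from_fit",
    "assess_abiotic",
    "estimate_clint",
    "summarize_distribution",
    "write_clint_results",
    "read_clint_results",
]

LN2 = math.log(2.0)


class CalibrationError(ValueError):
    pass


class RegressionError(ValueError):
    pass


@dataclass
class CalibrationFit:
    """Zero-intercept calibration line response = RF × concentration."""

    chemical_id: str
    response_factor: float
    fit_residual_sd: float  # sd of ln(response) - ln(RF*conc)
    n_points: int


@dataclass
class RegressionFit:
    """OLS of ln(concentration) on time for one condition."""

    slope: float  # 1/min (ln-concentration per minute)
    slope_se: float
    p_value: float  # two-sided t-test for slope = 0
    intercept: float  # ln(µM)
    r_squared: float
    n_obs: int
    condition: str = "cells"

    def one_sided_p(self) -> float:
        """p-value against the directional alternative slope < 0 (depletion)."""
        if self.slope < 0:
            return self.p_value / 2.0
        return 1.0 - self.p_value / 2.0


@dataclass
class ClintEstimate:
    """Point estimate of intrinsic clearance for one chemical.

    ``clint`` is the significance-gated headline value (0 unless the
    depletion slope passes the gate); ``clint_raw`` is the ungated
    rate-based estimate max(0, −slope)×1000/density, useful for recovery
    studies and rank comparisons; ``clint_corrected`` additionally subtracts
    any fitted abiotic rate, max(0, k_cells − k_abiotic)×1000/density.
    """

    chemical_id: str
    clint: float  # µL/min/10^6 cells, 0 when not significant
    significant: bool
    half_life_min: float | None = None
    clint_raw: float = 0.0
    clint_corrected: float = 0.0
    abiotic_significant: bool = False
    abiotic_rate: float = 0.0  # 1/min, >= 0
    slope: float = 0.0
    slope_se: float = float("nan")
    p_value: float = float("nan")
    warnings: list[str] = field(default_factory=list)


@dataclass
class ClintSummary:
    """Panel-level distribution summary of point estimates."""

    n: int
    n_zero: int
    median_significant: float | None
    percentiles: dict[float, float]


# ---------------------------------------------------------------------------
# calibration and quantification
# ---------------------------------------------------------------------------

def fit_calibration(dataset: DepletionDataset) -> CalibrationFit:
    """Fit the response factor from calibration-standard rows.

    Zero-intercept least squares, RF = Σxy / Σx², which is the maximum
    likelihood slope for responses proportional to concentration with
    homoscedastic additive error through the origin.  The residual sd is
    reported on the log scale (matching the multiplicative error model used
    downstream).
    """
    cal = dataset.rows("calibration")
    levels = {m.nominal_conc_uM for m in cal}
    if len(cal) < 2 or len(levels) < 2:
        raise CalibrationError(
            f"{dataset.chemical_id}: calibration needs >= 2 rows at >= 2 "
            f"distinct nominal concentrations (got {len(cal)} rows, "
            f"{len(levels)} levels)"
        )
    x = np.array([m.nominal_conc_uM for m in cal], dtype=float)
    y = np.array([m.response for m in cal], dtype=float)
    rf = float(np.dot(x, y) / np.dot(x, x))
    if not rf > 0:
        raise CalibrationError(
            f"{dataset.chemical_id}: nonpositive response factor {rf}"
        )
    pos = y > 0
    resid = np.log(y[pos]) - np.log(rf * x[pos])
    ddof = 1 if resid.size > 2 else 0
    sd = float(np.std(resid, ddof=ddof)) if resid.size > 1 else 0.0
    return CalibrationFit(
        chemical_id=dataset.chemical_id,
        response_factor=rf,
        fit_residual_sd=sd,
        n_points=len(cal),
    )


def quantify(dataset: DepletionDataset, cal: CalibrationFit) -> pd.DataFrame:
    """Convert incubation responses to concentrations (µM).

    Returns a tidy frame with columns ``chemical_id, time_min, condition,
    replicate, conc_uM, censored``.  Values below ``loq_uM`` are flagged
    censored but retained.  Calibration rows are not quantified.
    """
    if cal.chemical_id != dataset.chemical_id:
        raise ValidationError(
            f"calibration for {cal.chemical_id!r} applied to "
            f"{dataset.chemical_id!r}"
        )
    if not cal.response_factor > 0:
        raise CalibrationError("invalid calibration: response_factor <= 0")
    rows = [m for m in dataset.measurements if m.condition != "calibration"]
    conc = np.array([m.response for m in rows], dtype=float) / cal.response_factor
    return pd.DataFrame(
        {
            "chemical_id": dataset.chemical_id,
            "time_min": [m.time_min for m in rows],
            "condition": [m.condition for m in rows],
            "replicate": [m.replicate for m in rows],
            "conc_uM": conc,
            "censored": conc < dataset.loq_uM,
        }
    )


# ---------------------------------------------------------------------------
# log-linear regression and clearance
# ---------------------------------------------------------------------------

def fit_log_linear(concs: pd.DataFrame, condition: str = "cells") -> RegressionFit:
    """OLS of ln(concentration) on time for one condition.

    Censored and nonpositive concentrations are excluded.  Requires >= 3
    usable observations at >= 2 distinct times; the p-value is the two-sided
    t-test of slope = 0.
    """
    sub = concs[concs["condition"] == condition] if "condition" in concs else concs
    usable = sub[(~sub["censored"]) & (sub["conc_uM"] > 0)]
    t = usable["time_min"].to_numpy(dtype=float)
    y = np.log(usable["conc_uM"].to_numpy(dtype=float))
    if t.size < 3 or np.unique(t).size < 2:
        raise RegressionError(
            f"insufficient quantifiable data for condition {condition!r} "
            f"({t.size} usable observations, {np.unique(t).size} distinct times)"
        )
    if np.ptp(y) == 0.0:
        # perfectly flat series: zero slope, no evidence against it
        return RegressionFit(
            slope=0.0, slope_se=0.0, p_value=1.0, intercept=float(y[0]),
            r_squared=0.0, n_obs=int(t.size), condition=condition,
        )
    res = stats.linregress(t, y)
    return RegressionFit(
        slope=float(res.slope),
        slope_se=float(res.stderr),
        p_value=float(res.pvalue),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_obs=int(t.size),
        condition=condition,
    )


def clint_from_fit(
    fit: RegressionFit,
    dataset: DepletionDataset,
    *,
    alpha: float = 0.05,
    tail: Literal["one-sided", "two-sided"] = "one-sided",
) -> ClintEstimate:
    """Significance-gate a cells-condition fit and convert to Cl_int.

    A chemical is significant when the slope is negative and its p-value
    (directional by default; see module docstring) is below ``alpha``.
    Non-significant chemicals get Cl_int = 0.  Otherwise
    ``t½ = ln2 / (−slope)`` and ``Cl_int = (−slope) × 1000 / density``
    (equals −slope × 2000 at 0.5 × 10⁶ cells/mL).
    """
    p_gate = fit.one_sided_p() if tail == "one-sided" else fit.p_value
    density = dataset.cell_density_millions_per_mL
    per_million = 1000.0 / density  # µL of incubation per 10^6 cells
    significant = bool(fit.slope < 0 and p_gate < alpha)
    clint_raw = max(0.0, -fit.slope) * per_million
    if significant:
        clint = -fit.slope * per_million
        half_life = LN2 / (-fit.slope)
    else:
        clint = 0.0
        half_life = None
    return ClintEstimate(
        chemical_id=dataset.chemical_id,
        clint=clint,
        significant=significant,
        half_life_min=half_life,
        clint_raw=clint_raw,
        clint_corrected=clint,
        slope=fit.slope,
        slope_se=fit.slope_se,
        p_value=fit.p_value,
    )


def assess_abiotic(
    dataset: DepletionDataset,
    cal: CalibrationFit,
    *,
    alpha: float = 0.05,
    tail: Literal["one-sided", "two-sided"] = "one-sided",
) -> tuple[RegressionFit | None, bool, float, list[str]]:
    """Regress the pooled negative-control rows to estimate abiotic loss.

    Returns ``(fit, abiotic_significant, abiotic_rate, warnings)``.  When the
    dataset has no control rows the fit is absent and a warning is emitted;
    abiotic loss is then assumed zero.
    """
    warnings: list[str] = []
    if not dataset.has_controls:
        warnings.append(
            f"{dataset.chemical_id}: no negative-control rows; abiotic loss "
            "not assessed"
        )
        return None, False, 0.0, warnings
    concs = quantify(dataset, cal)
    sub = concs[concs["condition"].isin(CONTROL_CONDITIONS)].copy()
    sub["condition"] = "control"
    try:
        fit = fit_log_linear(sub, condition="control")
    except RegressionError as err:
        warnings.append(f"{dataset.chemical_id}: abiotic regression failed: {err}")
        return None, False, 0.0, warnings
    p_gate = fit.one_sided_p() if tail == "one-sided" else fit.p_value
    significant = bool(fit.slope < 0 and p_gate < alpha)
    rate = max(0.0, -fit.slope)
    return fit, significant, rate, warnings


def estimate_clint(
    dataset: DepletionDataset,
    *,
    alpha: float = 0.05,
    tail: Literal["one-sided", "two-sided"] = "one-sided",
) -> ClintEstimate:
    """Full point pipeline: calibrate, quantify, regress, gate, and assess
    abiotic loss for one chemical."""
    dataset.validate()
    cal = fit_calibration(dataset)
    concs = quantify(dataset, cal)
    fit = fit_log_linear(concs, condition="cells")
    est = clint_from_fit(fit, dataset, alpha=alpha, tail=tail)
    _, ab_sig, ab_rate, warns = assess_abiotic(dataset, cal, alpha=alpha, tail=tail)
    est.abiotic_significant = ab_sig
    est.abiotic_rate = ab_rate
    est.warnings.extend(warns)
    if est.significant:
        per_million = 1000.0 / dataset.cell_density_millions_per_mL
        k_net = max(0.0, -est.slope - ab_rate)
        est.clint_corrected = k_net * per_million
    return est


# ---------------------------------------------------------------------------
# panel summaries and result tables
# ---------------------------------------------------------------------------

def summarize_distribution(
    estimates: Sequence[ClintEstimate],
    *,
    probs: Sequence[float] = (0.05, 0.25, 0.5, 0.75, 0.95),
    quantile_method: str = "linear",
) -> ClintSummary:
    """Distribution summary across a panel of chemicals.

    ``n_zero`` counts chemicals gated to Cl_int = 0; the median is computed
    across the chemicals with significant clearance only, while the
    percentiles span all chemicals (zeros included).  The quantile rule
    defaults to linear interpolation between order statistics.
    """
    if not estimates:
        raise ValueError("summarize_distribution: empty estimate list")
    values = np.array([e.clint for e in estimates], dtype=float)
    sig = np.array([e.clint for e in estimates if e.significant], dtype=float)
    return ClintSummary(
        n=len(estimates),
        n_zero=int(np.sum(~np.array([e.significant for e in estimates]))),
        median_significant=(
            float(np.median(sig)) if sig.size else None
        ),
        percentiles={
            p: float(np.quantile(values, p, method=quantile_method)) for p in probs
        },
    )


CLINT_RESULT_COLUMNS = [
    "chemical_id",
    "slope",
    "slope_se",
    "p_value",
    "half_life_min",
    "clint",
    "significant",
    "abiotic_rate",
    "abiotic_significant",
]


def write_clint_results(estimates: Iterable[ClintEstimate], path) -> None:
    df = pd.DataFrame(
        [
            {
                "chemical_id": e.chemical_id,
                "slope": e.slope,
                "slope_se": e.slope_se,
                "p_value": e.p_value,
                "half_life_min": e.half_life_min,
                "clint": e.clint,
                "significant": e.significant,
                "abiotic_rate": e.abiotic_rate,
                "abiotic_significant": e.abiotic_significant,
            }
            for e in estimates
        ],
        columns=CLINT_RESULT_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_clint_results(path) -> pd.DataFrame:
    return pd.read_csv(path)
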