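"""Synthetic depletion experiments with known ground truth.

Emulates the assay design: triplicate samples on a {0, 15, 30, 60, 120,
240} min grid at C_test = 1 µM and 0.5 × 10⁶ cells/mL, with matched
negative controls and a small external calibration series.  Live-cell rows
decay at k_bio + k_abio, control rows at k_abio alone, and every response
is the true response factor times the concentration perturbed by
multiplicative lognormal noise.  Responses falling below RF·LOQ are exactly
what the quantification step will flag as censored.

Panels mirror the landscape seen in real PFAS screens: a majority of
chemicals metabolically stable (k_bio = 0) and the rest drawing Cl_int from
a lognormal spread over roughly 0–50 µL/min/10⁶ cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import DepletionDataset, Measurement
from .ivive import BioactivityCurve

__all__ = [
    "DEFAULT_TIME_GRID",
    "DEFAULT_CAL_LEVELS",
    "SimulationTruth",
    "simulate_depletion",
    "simulate_panel",
    "simulate_curves",
    "clint_to_k",
    "k_to_clint",
]

DEFAULT_TIME_GRID = (0.0, 15.0, 30.0, 60.0, 120.0, 240.0)
DEFAULT_CAL_LEVELS = (0.05, 0.1, 0.25, 0.5, 1.0)


def clint_to_k(clint: float, density: float = 0.5) -> float:
    """First-order rate (1/min) producing a given Cl_int at a cell density."""
    return clint * density / 1000.0


def k_to_clint(k: float, density: float = 0.5) -> float:
    return k * 1000.0 / density


@dataclass
class SimulationTruth:
    """Generating parameters for one synthetic chemical."""

    chemical_id: str
    k_bio_true: float = 0.0
    k_abio_true: float = 0.0
    rf_true: float = 1.0e5
    noise_sd_true: float = 0.1
    loq_uM: float = 0.01
    time_grid_min: tuple[float, ...] = DEFAULT_TIME_GRID
    n_replicates: int = 3
    seed: int = 0

    @property
    def clint_true(self) -> float:
        return k_to_clint(self.k_bio_true)


def simulate_depletion(
    truth: SimulationTruth,
    include_controls: bool = True,
    *,
    include_calibration: bool = True,
    control_condition: str = "no_cells",
    c_test_uM: float = 1.0,
    cell_density_millions_per_mL: float = 0.5,
    has_internal_standard: bool = True,
    cal_levels: tuple[float, ...] = DEFAULT_CAL_LEVELS,
    cal_replicates: int = 2,
) -> tuple[DepletionDataset, SimulationTruth]:
    """Generate one chemical's depletion dataset; deterministic given seed."""
    if truth.n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(truth.seed)
    ms: list[Measurement] = []

    def noisy(mean: float) -> float:
        if truth.noise_sd_true == 0:
            return mean
        return mean * float(np.exp(truth.noise_sd_true * rng.standard_normal()))

    k_cells = truth.k_bio_true + truth.k_abio_true
    for t in truth.time_grid_min:
        conc = c_test_uM * np.exp(-k_cells * t)
        for rep in range(1, truth.n_replicates + 1):
            ms.append(
                Measurement(
                    chemical_id=truth.chemical_id,
                    time_min=float(t),
                    condition="cells",
                    replicate=rep,
                    response=noisy(truth.rf_true * conc),
                    has_internal_standard=has_internal_standard,
                )
            )
    if include_controls:
        for t in truth.time_grid_min:
            conc = c_test_uM * np.exp(-truth.k_abio_true * t)
            for rep in range(1, truth.n_replicates + 1):
                ms.append(
                    Measurement(
                        chemical_id=truth.chemical_id,
                        time_min=float(t),
                        condition=control_condition,
                        replicate=rep,
                        response=noisy(truth.rf_true * conc),
                        has_internal_standard=has_internal_standard,
                    )
                )
    if include_calibration:
        for level in cal_levels:
            for rep in range(1, cal_replicates + 1):
                ms.append(
                    Measurement(
                        chemical_id=truth.chemical_id,
                        time_min=0.0,
                        condition="calibration",
                        replicate=rep,
                        response=noisy(truth.rf_true * level),
                        has_internal_standard=has_internal_standard,
                        nominal_conc_uM=float(level),
                    )
                )
    dataset = DepletionDataset(
        chemical_id=truth.chemical_id,
        measurements=ms,
        c_test_uM=c_test_uM,
        cell_density_millions_per_mL=cell_density_millions_per_mL,
        loq_uM=truth.loq_uM,
    ).sorted()
    return dataset, truth


def simulate_panel(
    n_chemicals: int,
    fraction_stable: float = 35.0 / 54.0,
    clint_distribution: dict | None = None,
    seed: int = 0,
    *,
    abiotic_fraction: float = 0.05,
    abiotic_rate: float = 0.002,
    **truth_kwargs,
) -> tuple[list[DepletionDataset], list[SimulationTruth]]:
    """Generate a labelled multi-chemical panel.

    Exactly ``round(fraction_stable × n)`` chemicals get k_bio = 0; the rest
    draw Cl_int from a lognormal (default median 4.5, log-sd 1.0, truncated
    at 50 µL/min/10⁶ cells — spanning the spread seen across real PFAS
    panels) back-converted to a rate via the cell density.  A small fraction
    additionally suffers abiotic loss.  Deterministic given ``seed``.
    """
    if n_chemicals < 1:
        raise ValueError("n_chemicals must be >= 1")
    dist = {"median": 4.5, "sigma_log": 1.0, "max": 50.0}
    if clint_distribution:
        dist.update(clint_distribution)
    rng = np.random.default_rng(seed)
    n_stable = int(round(fraction_stable * n_chemicals))
    stable = np.zeros(n_chemicals, dtype=bool)
    stable[rng.permutation(n_chemicals)[:n_stable]] = True
    child_seeds = rng.integers(0, 2**31 - 1, n_chemicals)

    datasets, truths = [], []
    for i in range(n_chemicals):
        if stable[i]:
            clint = 0.0
        else:
            clint = float(
                np.minimum(
                    np.exp(np.log(dist["median"]) + dist["sigma_log"] * rng.standard_normal()),
                    dist["max"],
                )
            )
        k_abio = abiotic_rate if rng.uniform() < abiotic_fraction else 0.0
        truth = SimulationTruth(
            chemical_id=f"SIM{i:04d}",
            k_bio_true=clint_to_k(clint),
            k_abio_true=k_abio,
            seed=int(child_seeds[i]),
            **truth_kwargs,
        )
        ds, truth = simulate_depletion(truth)
        datasets.append(ds)
        truths.append(truth)
    return datasets, truths


def simulate_curves(
    chemical_id: str,
    n_curves: int,
    active_fraction: float = 0.6,
    ac50_range: tuple[float, float] = (0.1, 100.0),
    flag_rate: float = 0.1,
    seed: int = 0,
) -> list[BioactivityCurve]:
    """Generate bioactivity curves for POD derivation.

    ``active_fraction`` of curves get hitcall in [0.9, 1] (positive), the
    rest in [0, 0.9); AC50s are log-uniform over ``ac50_range``; caution
    flags are Binomial(6, flag_rate), so flag_rate = 1 censors everything.
    """
    if n_curves < 0:
        raise ValueError("n_curves must be >= 0")
    rng = np.random.default_rng(seed)
    curves = []
    lo, hi = np.log(ac50_range[0]), np.log(ac50_range[1])
    for _ in range(n_curves):
        active = rng.uniform() < active_fraction
        hitcall = rng.uniform(0.9, 1.0) if active else rng.uniform(0.0, 0.9)
        curves.append(
            BioactivityCurve(
                chemical_id=chemical_id,
                ac50_uM=float(np.exp(rng.uniform(lo, hi))),
                hitcall=float(hitcall),
                n_flags=int(rng.binomial(6, flag_rate)),
            )
        )
    return curves
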