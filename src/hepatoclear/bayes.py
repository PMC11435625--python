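"""Bayesian measurement model separating biotic from abiotic depletion.

The observed instrument response for a sample drawn at time *t* is modelled
as lognormal around the response factor times the true concentration:

    y ~ LogNormal( ln(RF · C(t)), σ )

with condition-specific mean concentrations sharing parameters:

    cells:     C(t) = C_test · exp( −(z_bio·k_bio + z_abio·k_abio) · t )
    controls:  C(t) = C_test · exp( −z_abio·k_abio · t )
    standards: C    = nominal concentration (ties down RF and σ)

``z_bio`` and ``z_abio`` are Bernoulli indicators for whether any metabolic
(respectively abiotic) first-order loss is happening at all, with prior
probabilities 0.5 and 0.05; the loss rates ``k_bio`` and ``k_abio`` carry
uniform priors on [0, k_max] where k_max = −ln(LOQ/C_test)/t_max — the
fastest decline distinguishable from a drop straight to the limit of
quantitation over the assay window.  Observations below the LOQ enter the
likelihood as left-censored (lognormal CDF at RF·LOQ).

Inference is by Metropolis-within-Gibbs: the indicators are flipped from
their exact full conditionals, the continuous parameters move by Gaussian
random walks whose step sizes adapt during burn-in only (frozen afterwards
so the post-burn chain satisfies detailed balance).  When an indicator is 0
its rate is refreshed from a pseudo-prior (a truncated normal pinned at
build time near the crude OLS rate, with the Carlin–Chib density-ratio
correction in the flip), so chains mix freely across the four on/off
sub-models without changing the posterior.  Five chains with overdispersed
starting points are run by default and convergence is declared only when the
Gelman–Rubin potential scale reduction factor of every continuous parameter
is below 1.1.  The posterior of Cl_int = z_bio·k_bio × 1000/density is
summarised by its median and central 95% credible interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, log_ndtr, ndtr, ndtri
from scipy.stats import rankdata

from .io import CONTROL_CONDITIONS, DepletionDataset
from .point import ClintEstimate, fit_calibration

__all__ = [
    "PriorSpec",
    "PosteriorSample",
    "ClintPosterior",
    "DepletionModel",
    "MCMCSamples",
    "ModelError",
    "build_model",
    "run_mcmc",
    "psrf",
    "summarize_posterior",
    "bayes_clint",
    "concordance_report",
    "write_bayes_results",
]

CONTINUOUS_PARAMS = ("k_bio", "k_abio", "log_rf", "log_sigma")


class ModelError(ValueError):
    pass


@dataclass
class PriorSpec:
    """Prior configuration for the measurement model.

    ``slope_upper=None`` derives k_max from the dataset's LOQ and assay span;
    ``rf_meanlog=None`` centres the (weak, sd=1 on the log scale) response
    factor prior on a calibration-based point estimate.  The half-normal
    scale of the noise sd widens from 0.3 to 1.0 when responses lack an
    internal standard, reflecting unnormalised recovery variation.
    """

    p_clearance: float = 0.5
    p_abiotic: float = 0.05
    slope_lower: float = 0.0
    slope_upper: float | None = None
    rf_meanlog: float | None = None
    rf_sdlog: float = 1.0
    noise_sd_scale: float = 0.3
    noise_sd_scale_no_is: float = 1.0

    def validate(self) -> None:
        if not (0.0 <= self.p_clearance <= 1.0 and 0.0 <= self.p_abiotic <= 1.0):
            raise ModelError("Bernoulli prior probabilities must lie in [0,1]")
        if self.slope_lower != 0.0:
            raise ModelError("slope_lower is fixed at 0 for this model family")
        if self.slope_upper is not None and not self.slope_upper > 0:
            raise ModelError("slope_upper must be > 0")


@dataclass
class PosteriorSample:
    """One post-burn-in draw from one chain."""

    z_bio: int
    z_abio: int
    k_bio: float
    k_abio: float
    response_factor: float
    noise_sd: float
    chain: int
    iteration: int


@dataclass
class ClintPosterior:
    """Posterior summary of intrinsic clearance for one chemical."""

    chemical_id: str
    p_cleared: float
    clint_median: float
    clint_ci95: tuple[float, float]
    p_abiotic_post: float
    psrf_max: float
    converged: bool


@dataclass
class DepletionModel:
    """Compiled likelihood for one chemical's depletion experiment."""

    chemical_id: str
    log_ctest: float
    log_loq: float
    k_max: float
    density: float
    rf_meanlog: float
    rf_sdlog: float
    sigma_scale: float
    p_clearance: float
    p_abiotic: float
    extra_noise: bool  # true when no internal standard was available
    t_cells: np.ndarray
    logy_cells: np.ndarray
    cens_cells: np.ndarray
    t_ctrl: np.ndarray
    logy_ctrl: np.ndarray
    cens_ctrl: np.ndarray
    lognom_cal: np.ndarray
    logy_cal: np.ndarray
    #: pseudo-prior (mean, sd) for each rate when its indicator is off —
    #: a truncated normal around the crude OLS rate, fixed at build time.
    #: None falls back to the uniform prior (e.g. the prior-only model).
    kb_pseudo: tuple[float, float] | None = None
    ka_pseudo: tuple[float, float] | None = None

    @property
    def n_obs(self) -> int:
        return self.t_cells.size + self.t_ctrl.size + self.lognom_cal.size

    def loglik(
        self,
        kb_eff: np.ndarray,
        ka_eff: np.ndarray,
        log_rf: np.ndarray,
        sigma: np.ndarray,
    ) -> np.ndarray:
        """Vectorised log likelihood; every argument has shape (n_chains,)."""
        ll = np.zeros_like(sigma)
        inv_s2 = 0.5 / sigma**2
        for t, logy, cens, k in (
            (self.t_cells, self.logy_cells, self.cens_cells, kb_eff + ka_eff),
            (self.t_ctrl, self.logy_ctrl, self.cens_ctrl, ka_eff),
        ):
            if t.size == 0:
                continue
            logC = self.log_ctest - k[:, None] * t[None, :]
            unc = ~cens
            if unc.any():
                r = logy[None, unc] - log_rf[:, None] - logC[:, unc]
                ll += -unc.sum() * np.log(sigma) - inv_s2 * (r**2).sum(axis=1)
            if cens.any():
                # threshold ln(RF·LOQ) minus mean ln(RF·C) — RF cancels
                z = (self.log_loq - logC[:, cens]) / sigma[:, None]
                ll += log_ndtr(z).sum(axis=1)
        if self.lognom_cal.size:
            r = self.logy_cal[None, :] - log_rf[:, None] - self.lognom_cal[None, :]
            ll += -self.lognom_cal.size * np.log(sigma) - inv_s2 * (r**2).sum(axis=1)
        return ll


def build_model(
    dataset: DepletionDataset,
    priors: PriorSpec | None = None,
    *,
    require_data: bool = True,
) -> DepletionModel:
    """Compile a dataset into the likelihood used by :func:`run_mcmc`.

    Censoring flags are fixed at build time by comparing each response to
    RF̂·LOQ with a calibration point estimate of the response factor (a
    threshold moving with the sampled RF would make the likelihood
    discontinuous).  Zero responses are always treated as censored.  With
    ``require_data=False`` an empty model (prior-only target) is allowed.
    """
    priors = priors or PriorSpec()
    priors.validate()
    cells = dataset.rows("cells")
    if require_data and not cells:
        raise ModelError(f"{dataset.chemical_id}: no cells-condition rows")

    t_max = dataset.t_max or 240.0
    k_max = priors.slope_upper
    if k_max is None:
        k_max = -math.log(dataset.loq_uM / dataset.c_test_uM) / t_max

    # point estimate of RF used for the censoring flags and prior centre
    rf_hat = None
    if dataset.has_calibration:
        try:
            rf_hat = fit_calibration(dataset).response_factor
        except ValueError:
            rf_hat = None
    non_cal = [m for m in dataset.measurements if m.condition != "calibration"]
    if rf_hat is None and non_cal:
        t0 = min(m.time_min for m in non_cal)
        r0 = [m.response for m in non_cal if m.time_min == t0 and m.response > 0]
        rf_hat = (float(np.mean(r0)) / dataset.c_test_uM) if r0 else 1.0
    if rf_hat is None or not rf_hat > 0:
        rf_hat = 1.0
    rf_meanlog = (
        priors.rf_meanlog if priors.rf_meanlog is not None else math.log(rf_hat)
    )

    extra_noise = any(not m.has_internal_standard for m in non_cal)
    sigma_scale = priors.noise_sd_scale_no_is if extra_noise else priors.noise_sd_scale

    def arrays(rows):
        t = np.array([m.time_min for m in rows], dtype=float)
        resp = np.array([m.response for m in rows], dtype=float)
        cens = (resp <= 0) | (resp < rf_hat * dataset.loq_uM)
        logy = np.where(resp > 0, np.log(np.maximum(resp, 1e-300)), 0.0)
        return t, logy, cens

    t_cells, logy_cells, cens_cells = arrays(cells)
    t_ctrl, logy_ctrl, cens_ctrl = arrays(dataset.rows(*CONTROL_CONDITIONS))

    def pseudo(t, logy, cens):
        # crude OLS depletion rate on the uncensored log responses; pins the
        # pseudo-prior of the off-state rate near the data-supported region
        t, logy = t[~cens], logy[~cens]
        if t.size < 3 or np.unique(t).size < 2:
            return None
        tc = t - t.mean()
        sxx = float(np.dot(tc, tc))
        slope = float(np.dot(tc, logy - logy.mean()) / sxx)
        resid = logy - logy.mean() - slope * tc
        dof = max(t.size - 2, 1)
        se = math.sqrt(float(np.dot(resid, resid)) / dof / sxx)
        mean = min(max(-slope, 0.0), k_max)
        sd = max(3.0 * se, k_max / 100.0)
        return (mean, sd)

    kb_pseudo = pseudo(t_cells, logy_cells, cens_cells)
    ka_pseudo = pseudo(t_ctrl, logy_ctrl, cens_ctrl)
    cal = [m for m in dataset.rows("calibration") if m.response > 0]
    lognom_cal = np.array([math.log(m.nominal_conc_uM) for m in cal], dtype=float)
    logy_cal = np.array([math.log(m.response) for m in cal], dtype=float)

    return DepletionModel(
        chemical_id=dataset.chemical_id,
        log_ctest=math.log(dataset.c_test_uM),
        log_loq=math.log(dataset.loq_uM),
        k_max=float(k_max),
        density=dataset.cell_density_millions_per_mL,
        rf_meanlog=rf_meanlog,
        rf_sdlog=priors.rf_sdlog,
        sigma_scale=sigma_scale,
        p_clearance=priors.p_clearance,
        p_abiotic=priors.p_abiotic,
        extra_noise=extra_noise,
        t_cells=t_cells,
        logy_cells=logy_cells,
        cens_cells=cens_cells,
        t_ctrl=t_ctrl,
        logy_ctrl=logy_ctrl,
        cens_ctrl=cens_ctrl,
        lognom_cal=lognom_cal,
        logy_cal=logy_cal,
        kb_pseudo=kb_pseudo,
        ka_pseudo=ka_pseudo,
    )


@dataclass
class MCMCSamples:
    """Post-burn-in draws from all chains, arrays of shape (n_chains, n_keep)."""

    chemical_id: str
    density: float
    n_chains: int
    n_iter: int
    n_burn: int
    z_bio: np.ndarray
    z_abio: np.ndarray
    k_bio: np.ndarray
    k_abio: np.ndarray
    log_rf: np.ndarray
    log_sigma: np.ndarray

    def chains(self, param: str) -> np.ndarray:
        return getattr(self, param)

    def pooled(self, param: str) -> np.ndarray:
        return getattr(self, param).ravel()

    def clint_draws(self) -> np.ndarray:
        """Pooled posterior draws of Cl_int in µL/min/10⁶ cells."""
        return (self.z_bio * self.k_bio).ravel() * 1000.0 / self.density

    def samples(self) -> list[PosteriorSample]:
        out = []
        n_keep = self.z_bio.shape[1]
        for c in range(self.n_chains):
            for i in range(n_keep):
                out.append(
                    PosteriorSample(
                        z_bio=int(self.z_bio[c, i]),
                        z_abio=int(self.z_abio[c, i]),
                        k_bio=float(self.k_bio[c, i]),
                        k_abio=float(self.k_abio[c, i]),
                        response_factor=float(np.exp(self.log_rf[c, i])),
                        noise_sd=float(np.exp(self.log_sigma[c, i])),
                        chain=c + 1,
                        iteration=self.n_burn + i + 1,
                    )
                )
        return out


_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def _pseudo_draw(rng, pseudo, kmax: float, m: int) -> np.ndarray:
    """Draw m off-state rates from the pseudo-prior (inverse-CDF sampling)."""
    if pseudo is None:
        return rng.uniform(0.0, kmax, m)
    mean, sd = pseudo
    a = ndtr((0.0 - mean) / sd)
    b = ndtr((kmax - mean) / sd)
    q = np.clip(a + rng.uniform(size=m) * (b - a), 1e-15, 1.0 - 1e-15)
    return mean + sd * ndtri(q)


def _log_prior_over_pseudo(k: np.ndarray, pseudo, kmax: float) -> np.ndarray:
    """log prior(k) − log g(k); zero when the pseudo-prior is the prior."""
    if pseudo is None:
        return np.zeros_like(k)
    mean, sd = pseudo
    norm = ndtr((kmax - mean) / sd) - ndtr((0.0 - mean) / sd)
    log_g = (
        -math.log(sd) - 0.5 * ((k - mean) / sd) ** 2
        - math.log(norm) - _LOG_SQRT_2PI
    )
    return -math.log(kmax) - log_g


def run_mcmc(
    model: DepletionModel,
    n_chains: int = 5,
    n_iter: int = 10000,
    n_burn: int = 2000,
    seed: int = 0,
) -> MCMCSamples:
    """Metropolis-within-Gibbs sampler for :class:`DepletionModel`.

    Deterministic given ``seed``.  Chains start overdispersed (rates spread
    across the prior range, RF and noise sd offset around their prior
    centres) and are advanced in lockstep from a single generator stream.
    Step sizes adapt toward ~40% acceptance during burn-in only.
    """
    if n_chains < 2:
        raise ModelError("need >= 2 chains for convergence diagnostics")
    if n_iter <= n_burn:
        raise ModelError("n_iter must exceed n_burn")
    rng = np.random.default_rng(seed)
    m = n_chains
    kmax = model.k_max

    # overdispersed initial values
    strat = (np.arange(m) + 0.5) / m
    k_bio = strat * kmax
    k_abio = strat[::-1].copy() * kmax
    z_bio = (np.arange(m) % 2).astype(float)
    z_abio = (np.arange(m) % 3 == 0).astype(float)
    log_rf = model.rf_meanlog + np.linspace(-1.0, 1.0, m)
    log_sigma = np.log(np.geomspace(0.05, 0.8, m))

    ll = model.loglik(
        z_bio * k_bio, z_abio * k_abio, log_rf, np.exp(log_sigma)
    )
    if not np.all(np.isfinite(ll)):
        raise ModelError(
            f"{model.chemical_id}: non-finite likelihood at initialization "
            f"(ll={ll})"
        )

    def lp_rf(x):
        return -0.5 * ((x - model.rf_meanlog) / model.rf_sdlog) ** 2

    def lp_logsig(x):
        # half-normal prior on sigma plus the log-scale Jacobian
        s = np.exp(x)
        return -0.5 * (s / model.sigma_scale) ** 2 + x

    steps = {"k_bio": np.full(m, 0.1 * kmax), "k_abio": np.full(m, 0.1 * kmax),
             "log_rf": np.full(m, 0.2), "log_sigma": np.full(m, 0.3)}
    acc = {k: np.zeros(m) for k in steps}
    n_keep = n_iter - n_burn
    keep = {
        "z_bio": np.empty((m, n_keep)), "z_abio": np.empty((m, n_keep)),
        "k_bio": np.empty((m, n_keep)), "k_abio": np.empty((m, n_keep)),
        "log_rf": np.empty((m, n_keep)), "log_sigma": np.empty((m, n_keep)),
    }
    ADAPT_WINDOW = 50

    for it in range(n_iter):
        sigma = np.exp(log_sigma)

        # --- k_bio: RW Metropolis where z=1, pseudo-prior refresh where z=0
        prop = k_bio + steps["k_bio"] * rng.standard_normal(m)
        fresh = _pseudo_draw(rng, model.kb_pseudo, kmax, m)
        inb = (prop > 0) & (prop < kmax)
        ll_new = model.loglik(z_bio * prop, z_abio * k_abio, log_rf, sigma)
        logr = np.where(inb, ll_new - ll, -np.inf)
        accept = np.log(rng.uniform(size=m)) < logr
        on = z_bio == 1
        take = accept & on
        k_bio = np.where(take, prop, k_bio)
        ll = np.where(take, ll_new, ll)
        k_bio = np.where(~on, fresh, k_bio)  # likelihood unaffected when z=0
        acc["k_bio"] += take | ~on

        # --- k_abio
        prop = k_abio + steps["k_abio"] * rng.standard_normal(m)
        fresh = _pseudo_draw(rng, model.ka_pseudo, kmax, m)
        inb = (prop > 0) & (prop < kmax)
        ll_new = model.loglik(z_bio * k_bio, z_abio * prop, log_rf, sigma)
        logr = np.where(inb, ll_new - ll, -np.inf)
        accept = np.log(rng.uniform(size=m)) < logr
        on = z_abio == 1
        take = accept & on
        k_abio = np.where(take, prop, k_abio)
        ll = np.where(take, ll_new, ll)
        k_abio = np.where(~on, fresh, k_abio)
        acc["k_abio"] += take | ~on

        # --- z_bio: exact full-conditional flip (ll for the current z is cached)
        flip = model.loglik(
            np.where(z_bio == 1, 0.0, k_bio), z_abio * k_abio, log_rf, sigma
        )
        ll1 = np.where(z_bio == 1, ll, flip)
        ll0 = np.where(z_bio == 0, ll, flip)
        if model.p_clearance <= 0.0:
            z_bio = np.zeros(m)
        elif model.p_clearance >= 1.0:
            z_bio = np.ones(m)
        else:
            # Carlin–Chib flip: the on-state carries the uniform rate prior,
            # the off-state the pseudo-prior, hence the density-ratio term
            logit = (
                math.log(model.p_clearance) - math.log1p(-model.p_clearance)
                + ll1 - ll0
                + _log_prior_over_pseudo(k_bio, model.kb_pseudo, kmax)
            )
            z_bio = (rng.uniform(size=m) < expit(logit)).astype(float)
        ll = np.where(z_bio == 1, ll1, ll0)

        # --- z_abio
        flip = model.loglik(
            z_bio * k_bio, np.where(z_abio == 1, 0.0, k_abio), log_rf, sigma
        )
        ll1 = np.where(z_abio == 1, ll, flip)
        ll0 = np.where(z_abio == 0, ll, flip)
        if model.p_abiotic <= 0.0:
            z_abio = np.zeros(m)
        elif model.p_abiotic >= 1.0:
            z_abio = np.ones(m)
        else:
            logit = (
                math.log(model.p_abiotic) - math.log1p(-model.p_abiotic)
                + ll1 - ll0
                + _log_prior_over_pseudo(k_abio, model.ka_pseudo, kmax)
            )
            z_abio = (rng.uniform(size=m) < expit(logit)).astype(float)
        ll = np.where(z_abio == 1, ll1, ll0)

        # --- response factor (log scale, Gaussian prior)
        prop = log_rf + steps["log_rf"] * rng.standard_normal(m)
        ll_new = model.loglik(z_bio * k_bio, z_abio * k_abio, prop, sigma)
        logr = ll_new + lp_rf(prop) - ll - lp_rf(log_rf)
        accept = np.log(rng.uniform(size=m)) < logr
        log_rf = np.where(accept, prop, log_rf)
        ll = np.where(accept, ll_new, ll)
        acc["log_rf"] += accept

        # --- noise sd (log scale, half-normal prior with Jacobian)
        prop = log_sigma + steps["log_sigma"] * rng.standard_normal(m)
        ll_new = model.loglik(
            z_bio * k_bio, z_abio * k_abio, log_rf, np.exp(prop)
        )
        logr = ll_new + lp_logsig(prop) - ll - lp_logsig(log_sigma)
        accept = np.log(rng.uniform(size=m)) < logr
        log_sigma = np.where(accept, prop, log_sigma)
        ll = np.where(accept, ll_new, ll)
        acc["log_sigma"] += accept

        # --- step-size adaptation, burn-in only
        if it < n_burn and (it + 1) % ADAPT_WINDOW == 0:
            for name in steps:
                rate = acc[name] / ADAPT_WINDOW
                steps[name] *= np.exp(np.clip(rate - 0.4, -0.5, 0.5))
                acc[name][:] = 0.0
        elif it == n_burn - 1:
            for name in acc:
                acc[name][:] = 0.0

        if it >= n_burn:
            j = it - n_burn
            keep["z_bio"][:, j] = z_bio
            keep["z_abio"][:, j] = z_abio
            keep["k_bio"][:, j] = k_bio
            keep["k_abio"][:, j] = k_abio
            keep["log_rf"][:, j] = log_rf
            keep["log_sigma"][:, j] = log_sigma

    return MCMCSamples(
        chemical_id=model.chemical_id,
        density=model.density,
        n_chains=m,
        n_iter=n_iter,
        n_burn=n_burn,
        **keep,
    )


def psrf(chains: np.ndarray) -> float:
    """Gelman–Rubin potential scale reduction factor.

    ``chains`` has shape (n_chains, n_samples).  Computed as
    sqrt(((n−1)/n·W + B/n) / W) with W the mean within-chain variance and
    B = n·Var(chain means).  Degenerate conventions: all chains constant and
    equal → 1.0; chains constant but different → +inf.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("psrf needs a 2-D array with >= 2 chains")
    n = chains.shape[1]
    if n < 10:
        raise ValueError("psrf needs >= 10 samples per chain")
    W = float(np.mean(np.var(chains, axis=1, ddof=1)))
    B = n * float(np.var(np.mean(chains, axis=1), ddof=1))
    # constant chains produce variances at float rounding level, not exact 0
    tiny = 1e-24 * (1.0 + float(np.mean(chains)) ** 2)
    if W <= tiny:
        return 1.0 if B <= tiny else float("inf")
    var_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(var_hat / W))


def summarize_posterior(
    samples: MCMCSamples,
    dataset: DepletionDataset | None = None,
    *,
    psrf_threshold: float = 1.1,
) -> ClintPosterior:
    """Reduce MCMC output to a :class:`ClintPosterior`.

    Convergence requires PSRF < 1.1 for every continuous parameter
    (k_bio, k_abio, log RF, log σ); the Cl_int credible interval is the
    central 95% of the pooled z_bio·k_bio draws scaled by 1000/density.
    """
    if samples.z_bio.size == 0:
        raise ValueError("empty post-burn sample")
    draws = samples.clint_draws()
    lo, med, hi = np.percentile(draws, [2.5, 50.0, 97.5])
    psrfs = [psrf(samples.chains(p)) for p in CONTINUOUS_PARAMS]
    psrf_max = float(max(psrfs))
    return ClintPosterior(
        chemical_id=samples.chemical_id,
        p_cleared=float(np.mean(samples.z_bio)),
        clint_median=float(med),
        clint_ci95=(float(lo), float(hi)),
        p_abiotic_post=float(np.mean(samples.z_abio)),
        psrf_max=psrf_max,
        converged=bool(psrf_max < psrf_threshold),
    )


def bayes_clint(
    dataset: DepletionDataset,
    priors: PriorSpec | None = None,
    *,
    n_chains: int = 5,
    n_iter: int = 10000,
    n_burn: int = 2000,
    seed: int = 0,
) -> ClintPosterior:
    """Convenience pipeline: build, sample, summarise for one chemical."""
    model = build_model(dataset, priors)
    samples = run_mcmc(model, n_chains=n_chains, n_iter=n_iter, n_burn=n_burn,
                       seed=seed)
    return summarize_posterior(samples, dataset)


# ---------------------------------------------------------------------------
# point-vs-Bayes concordance
# ---------------------------------------------------------------------------

@dataclass
class ConcordanceReport:
    table: pd.DataFrame
    counts: dict[str, int]
    rank_correlation: float


def concordance_report(
    point: Sequence[ClintEstimate],
    bayes: Sequence[ClintPosterior],
    *,
    p_threshold: float = 0.95,
) -> ConcordanceReport:
    """Per-chemical agreement between the frequentist gate and the posterior.

    A chemical counts as Bayes-cleared when p_cleared > ``p_threshold``
    (0.95, mirroring the method's conservatism) and as indeterminate when
    its chains did not converge.  The rank correlation is Spearman's rho of
    posterior median Cl_int against the point estimate.
    """
    pmap = {e.chemical_id: e for e in point}
    bmap = {b.chemical_id: b for b in bayes}
    orphans = sorted(set(pmap) ^ set(bmap))
    if orphans:
        raise ValueError(f"mismatched chemical ids: {orphans}")
    rows = []
    for cid in sorted(pmap):
        e, b = pmap[cid], bmap[cid]
        if not b.converged:
            klass = "indeterminate"
        elif e.significant and b.p_cleared > p_threshold:
            klass = "both cleared"
        elif e.significant:
            klass = "point-only"
        elif b.p_cleared > p_threshold:
            klass = "bayes-only"
        else:
            klass = "neither"
        rows.append(
            {
                "chemical_id": cid,
                "point_clint": e.clint,
                "point_significant": e.significant,
                "bayes_clint_median": b.clint_median,
                "p_cleared": b.p_cleared,
                "converged": b.converged,
                "agreement": klass,
            }
        )
    table = pd.DataFrame(rows)
    counts = {
        k: int((table["agreement"] == k).sum())
        for k in ("both cleared", "point-only", "bayes-only", "neither",
                  "indeterminate")
    }
    x = table["point_clint"].to_numpy()
    y = table["bayes_clint_median"].to_numpy()
    if len(table) > 1 and np.std(x) > 0 and np.std(y) > 0:
        rx, ry = rankdata(x), rankdata(y)
        rho = float(np.corrcoef(rx, ry)[0, 1])
    else:
        rho = float("nan")
    return ConcordanceReport(table=table, counts=counts, rank_correlation=rho)


BAYES_RESULT_COLUMNS = [
    "chemical_id", "p_cleared", "clint_median", "clint_ci_lo", "clint_ci_hi",
    "p_abiotic_post", "psrf_max", "converged",
]


def write_bayes_results(posteriors: Iterable[ClintPosterior], path) -> None:
    df = pd.DataFrame(
        [
            {
                "chemical_id": p.chemical_id,
                "p_cleared": p.p_cleared,
                "clint_median": p.clint_median,
                "clint_ci_lo": p.clint_ci95[0],
                "clint_ci_hi": p.clint_ci95[1],
                "p_abiotic_post": p.p_abiotic_post,
                "psrf_max": p.psrf_max,
                "converged": p.converged,
            }
            for p in posteriors
        ],
        columns=BAYES_RESULT_COLUMNS,
    )
    df.to_csv(path, index=False)
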