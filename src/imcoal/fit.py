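"""Maximum-likelihood fitting of the isolation-with-migration (IM) and
clean-split isolation (I) models, AIC model comparison and unit scaling.

Both models are fitted by Nelder-Mead over log-transformed free
parameters; the ordering constraint tau1 <= tau2 of the IM model is kept
by optimizing log(tau1) and log(tau2 - tau1), so the search stays
unconstrained.  The IM model has five free parameters (tau1, tau2,
coalescence, recombination and migration rate), the I model three, giving
AIC = 2k - 2 log L for the comparison: delta = AIC_I - AIC_IM, positive
values preferring the model with gene flow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .emissions import (
    end_conditioned_means,
    isolation_means,
    jc_emissions,
)
from .hmm import forward_loglik
from .model import (
    IsolationParameters,
    ModelParameters,
    discretize,
    hmm_transition,
    interval_chain,
    isolation_interval_chain,
    joint_matrix,
)
from .symbols import DIFFERENT, MISSING

__all__ = [
    "FitResult",
    "ModelComparison",
    "ScaledEstimates",
    "build_im_hmm",
    "build_iso_hmm",
    "im_loglik",
    "iso_loglik",
    "moment_init",
    "fit",
    "compare",
    "segment_analysis",
    "scale_estimates",
]

log = logging.getLogger(__name__)

_PENALTY = 1e12
_LOG_CLIP = 40.0


@dataclass
class FitResult:
    """ML estimates for one model on one alignment segment."""

    model: str  # "im" or "iso"
    params: ModelParameters | IsolationParameters
    loglik: float
    n_params: int
    n_evals: int
    converged: bool
    seed: int | None = None
    n_restarts: int = 0

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik


@dataclass
class ModelComparison:
    """AIC comparison of the I and IM models on the same data.

    ``delta = aic_iso - aic_im``: positive values prefer the
    isolation-with-migration model, negative the clean split.
    """

    fit_iso: FitResult
    fit_im: FitResult

    @property
    def aic_iso(self) -> float:
        return self.fit_iso.aic

    @property
    def aic_im(self) -> float:
        return self.fit_im.aic

    @property
    def delta(self) -> float:
        return self.aic_iso - self.aic_im


@dataclass(frozen=True)
class ScaledEstimates:
    """Estimates converted to years and individuals.

    ``years = tau / mu_per_year``; the effective population size uses the
    convention N_e = 1 / (2 C mu_per_generation) with
    mu_per_generation = mu_per_year * generation_time (haploid sequences,
    coalescence rate 1/(2 N_e) per generation).  Pure reparameterization:
    nothing is refitted.
    """

    mu_per_year: float
    generation_time: float
    split_times_years: dict
    n_e: float


def build_im_hmm(
    params: ModelParameters, n_mig: int = 10, n_anc: int = 10, anc_span: float | None = None
):
    """(pi, T, E, means) of the IM CoalHMM at the given parameters."""
    disc = discretize(params, n_mig=n_mig, n_anc=n_anc, anc_span=anc_span)
    chain = interval_chain(params, disc=disc)
    J = joint_matrix(chain)
    T, pi = hmm_transition(J)
    means = end_conditioned_means(params, disc)
    E = jc_emissions(means)
    return pi, T, E, means


def build_iso_hmm(params: IsolationParameters, n_intervals: int = 20, span: float | None = None):
    """(pi, T, E, means) of the clean-split CoalHMM."""
    chain = isolation_interval_chain(params, n_intervals=n_intervals, span=span)
    J = joint_matrix(chain)
    T, pi = hmm_transition(J)
    means = isolation_means(params, chain.disc)
    E = jc_emissions(means)
    return pi, T, E, means


def _auto_anc_span(params: ModelParameters, n_mig: int, n_anc: int) -> float | None:
    """Ancestral-interval width: the equal-width rule (Delta_anc =
    Delta_mig) whenever it covers >= ~4/C of the ancestral epoch, else
    widen so the finite intervals always span 4/C (~98% of the post-split
    coalescence mass).  Guards against degenerate geometry when the
    migration epoch is much shorter than the coalescent time scale."""
    delta = (params.tau2 - params.tau1) / n_mig
    floor = 4.0 / (params.coal_rate * n_anc)
    if delta >= floor:
        return None  # equal widths
    return floor * n_anc


def im_loglik(params: ModelParameters, columns: np.ndarray, n_mig: int = 10, n_anc: int = 10) -> float:
    span = _auto_anc_span(params, n_mig, n_anc)
    pi, T, E, _ = build_im_hmm(params, n_mig=n_mig, n_anc=n_anc, anc_span=span)
    return forward_loglik(pi, T, E, columns).loglik


def iso_loglik(params: IsolationParameters, columns: np.ndarray, n_intervals: int = 20) -> float:
    pi, T, E, _ = build_iso_hmm(params, n_intervals=n_intervals)
    return forward_loglik(pi, T, E, columns).loglik


def moment_init(columns: np.ndarray) -> ModelParameters:
    """Method-of-moments starting point from the mean pairwise difference.

    The Jukes-Cantor distance t_div (per lineage) estimates
    E[TMRCA] ~ tau_split + 1/C; the start splits it evenly between split
    time and coalescent depth, puts tau1 at tau2/2, and uses a moderate
    migration rate and a recombination rate proportional to C.
    """
    informative = columns != MISSING
    n_inf = int(informative.sum())
    if n_inf == 0:
        raise ValueError("no informative columns")
    p_diff = float((columns[informative] == DIFFERENT).mean())
    p_diff = min(max(p_diff, 1e-6), 0.74)
    t_div = -0.375 * np.log(1.0 - (4.0 / 3.0) * p_diff)  # half the JC distance
    tau2 = t_div / 2.0
    C = 2.0 / t_div
    return ModelParameters(
        tau1=tau2 / 2.0, tau2=tau2, coal_rate=C, rec_rate=4e-4 * C, mig_rate=100.0
    )


def _im_to_x(p: ModelParameters) -> np.ndarray:
    return np.log([p.tau1, p.tau2 - p.tau1, p.coal_rate, p.rec_rate, p.mig_rate])


def _x_to_im(x: np.ndarray) -> ModelParameters:
    v = np.exp(np.clip(x, -_LOG_CLIP, _LOG_CLIP))
    return ModelParameters(
        tau1=v[0], tau2=v[0] + v[1], coal_rate=v[2], rec_rate=v[3], mig_rate=v[4]
    )


def _iso_to_x(p: IsolationParameters) -> np.ndarray:
    return np.log([p.tau, p.coal_rate, p.rec_rate])


def _x_to_iso(x: np.ndarray) -> IsolationParameters:
    v = np.exp(np.clip(x, -_LOG_CLIP, _LOG_CLIP))
    return IsolationParameters(tau=v[0], coal_rate=v[1], rec_rate=v[2])


def fit(
    columns: np.ndarray,
    model: str = "im",
    init: ModelParameters | IsolationParameters | None = None,
    n_mig: int = 10,
    n_anc: int = 10,
    n_intervals: int = 20,
    restarts: int = 2,
    seed: int = 0,
    maxfev: int = 500,
    xatol: float = 2e-3,
    fatol: float = 5e-2,
) -> FitResult:
    """Maximize the HMM likelihood with Nelder-Mead (best of
    ``1 + restarts`` starts: the method-of-moments point plus seeded
    log-normal perturbations of it).
    """
    columns = np.asarray(columns)
    if model == "im":
        if init is None:
            init = moment_init(columns)
        to_x, from_x = _im_to_x, _x_to_im
        k = 5

        def nll(x):
            try:
                return -im_loglik(from_x(x), columns, n_mig=n_mig, n_anc=n_anc)
            except (ValueError, FloatingPointError, np.linalg.LinAlgError):
                return _PENALTY
    elif model == "iso":
        if init is None:
            m = moment_init(columns)
            init = IsolationParameters(
                tau=0.75 * m.tau2, coal_rate=m.coal_rate, rec_rate=m.rec_rate
            )
        to_x, from_x = _iso_to_x, _x_to_iso
        k = 3

        def nll(x):
            try:
                return -iso_loglik(from_x(x), columns, n_intervals=n_intervals)
            except (ValueError, FloatingPointError, np.linalg.LinAlgError):
                return _PENALTY
    else:
        raise ValueError("model must be 'im' or 'iso'")

    rng = np.random.default_rng(seed)
    x0 = to_x(init)
    starts = [x0] + [x0 + rng.normal(0.0, 0.4, size=len(x0)) for _ in range(restarts)]
    best = None
    n_evals = 0
    for x_start in starts:
        res = minimize(
            nll,
            x_start,
            method="Nelder-Mead",
            options={"maxfev": maxfev, "xatol": xatol, "fatol": fatol, "adaptive": True},
        )
        n_evals += res.nfev
        if best is None or res.fun < best.fun:
            best = res
    if best.fun >= _PENALTY:
        raise RuntimeError("all optimizer starts failed to reach a finite likelihood")
    est = from_x(best.x)
    # the optimizer contract: never return something worse than the start
    f0 = nll(x0)
    if best.fun > f0:
        est, best_fun = init, f0
    else:
        best_fun = best.fun
    return FitResult(
        model=model,
        params=est,
        loglik=-float(best_fun),
        n_params=k,
        n_evals=n_evals,
        converged=bool(best.success),
        seed=seed,
        n_restarts=restarts,
    )


def compare(
    columns: np.ndarray,
    n_mig: int = 10,
    n_anc: int = 10,
    n_intervals: int = 20,
    restarts: int = 2,
    seed: int = 0,
    maxfev: int = 500,
) -> ModelComparison:
    """Fit both models and compare by AIC."""
    fit_im = fit(
        columns, model="im", n_mig=n_mig, n_anc=n_anc,
        restarts=restarts, seed=seed, maxfev=maxfev,
    )
    fit_iso = fit(
        columns, model="iso", n_intervals=n_intervals,
        restarts=restarts, seed=seed, maxfev=maxfev,
    )
    return ModelComparison(fit_iso=fit_iso, fit_im=fit_im)


def segment_analysis(
    columns: np.ndarray,
    segment_length: int = 10_000_000,
    keep_tail: bool = False,
    min_informative: int = 10_000,
    restarts: int = 1,
    seed: int = 0,
    maxfev: int = 500,
) -> pd.DataFrame:
    """Fit and compare both models in consecutive windows.

    Returns one row per analysed segment with the estimates, log
    likelihoods, AICs and the AIC difference (aic_iso - aic_im, positive
    preferring gene flow).  Segments with fewer informative (non-missing)
    columns than ``min_informative`` are skipped with a logged reason.
    """
    columns = np.asarray(columns)
    edges = list(range(0, len(columns), segment_length))
    rows = []
    for si, start in enumerate(edges):
        end = min(start + segment_length, len(columns))
        if end - start < segment_length and not keep_tail:
            log.info("skipping %d bp tail segment at %d (keep_tail=False)", end - start, start)
            continue
        seg = columns[start:end]
        n_inf = int((seg != MISSING).sum())
        if n_inf < min_informative:
            log.info(
                "skipping segment %d-%d: %d informative columns < %d",
                start, end, n_inf, min_informative,
            )
            continue
        cmp_res = compare(seg, restarts=restarts, seed=seed + si, maxfev=maxfev)
        pim = cmp_res.fit_im.params
        piso = cmp_res.fit_iso.params
        rows.append(
            dict(
                start=start,
                end=end,
                n_informative=n_inf,
                tau1=pim.tau1,
                tau2=pim.tau2,
                coal_rate_im=pim.coal_rate,
                rec_rate_im=pim.rec_rate,
                mig_rate=pim.mig_rate,
                loglik_im=cmp_res.fit_im.loglik,
                aic_im=cmp_res.aic_im,
                tau_iso=piso.tau,
                coal_rate_iso=piso.coal_rate,
                rec_rate_iso=piso.rec_rate,
                loglik_iso=cmp_res.fit_iso.loglik,
                aic_iso=cmp_res.aic_iso,
                delta_aic=cmp_res.delta,
            )
        )
    return pd.DataFrame(rows)


def scale_estimates(
    result: FitResult, mu_per_year: float, generation_time: float
) -> ScaledEstimates:
    """Convert substitution-scaled estimates to years and individuals."""
    if mu_per_year <= 0 or generation_time <= 0:
        raise ValueError("mutation rate and generation time must be positive")
    mu_gen = mu_per_year * generation_time
    p = result.params
    if result.model == "im":
        times = {"tau1_years": p.tau1 / mu_per_year, "tau2_years": p.tau2 / mu_per_year}
    else:
        times = {"tau_years": p.tau / mu_per_year}
    n_e = 1.0 / (2.0 * p.coal_rate * mu_gen)
    return ScaledEstimates(
        mu_per_year=mu_per_year,
        generation_time=generation_time,
        split_times_years=times,
        n_e=n_e,
    )
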