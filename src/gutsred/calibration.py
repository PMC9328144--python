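"""Maximum-likelihood calibration of GUTS-RED parameters.

The observation model is the interval-censored multinomial death process:
for a treatment observed at times ``t_0 = 0 < t_1 < ... < t_K`` with
survivor counts ``n_0 >= n_1 >= ... >= n_K``, the ``d_i = n_{i-1} - n_i``
deaths in interval ``(t_{i-1}, t_i]`` contribute

    LL = sum_i d_i * ln(S(t_{i-1}) - S(t_i)) + n_K * ln S(t_K)

(the multinomial coefficient is parameter-free and dropped). All
parameters — including background mortality — are fitted jointly, in
log10 space within data-scaled bounds, by a Latin-hypercube screen
followed by Nelder-Mead refinement of the best screen points.
Confidence intervals are likelihood-ratio profiles: the 95% interval for
one parameter is the range over which the log-likelihood, re-maximised
over the remaining parameters, stays within chi2(1, 0.95)/2 = 1.921 of
the maximum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import qmc

from .dataset_prep import SurvivalDataset
from .guts_core import (
    ITParams,
    SDParams,
    damage,
    it_survival_constant,
    sd_survival_constant,
    survival_it,
    survival_sd,
)

__all__ = [
    "FitOptions",
    "FitResult",
    "GofMetrics",
    "default_bounds",
    "log_likelihood",
    "fit",
    "profile_ci",
    "goodness_of_fit",
]

#: chi2(1, 0.95) / 2 — log-likelihood drop defining 95% profile intervals.
CHI2_95_HALF = 1.9207294

#: Floor applied to interval probabilities before taking logs.
PROB_FLOOR = 1e-30

_SD_NAMES = ("kD", "zw", "bw", "hb")
_IT_NAMES = ("kD", "mw", "beta", "hb")


@dataclass
class FitOptions:
    """Search settings for :func:`fit`.

    n_screen : Latin-hypercube screening points in log10 parameter space.
    n_refine : number of best screen points refined by Nelder-Mead.
    compute_ci : whether to run profile-likelihood intervals for every
        parameter after the fit.
    bounds : optional override of the data-scaled default bounds, a dict
        of name -> (lo, hi) on the natural scale.
    """

    n_screen: int = 200
    n_refine: int = 10
    nm_maxiter: int = 600
    compute_ci: bool = True
    bounds: dict | None = None


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood calibration."""

    variant: str
    params: SDParams | ITParams
    loglik: float
    ci: dict[str, tuple[float, float]]
    converged: bool
    n_starts: int
    boundary_flags: dict[str, bool]
    bounds: dict[str, tuple[float, float]]
    floored_intervals: int = 0
    seed: int | None = None

    @property
    def param_names(self) -> tuple[str, ...]:
        return _SD_NAMES if self.variant == "SD" else _IT_NAMES

    def param_values(self) -> np.ndarray:
        p = self.params
        return np.array([getattr(p, n) for n in self.param_names])

    def summary(self) -> dict:
        """JSON-ready report with stable field names."""
        return {
            "variant": self.variant,
            "params": {n: float(getattr(self.params, n)) for n in self.param_names},
            "loglik": float(self.loglik),
            "ci": {k: [float(a), float(b)] for k, (a, b) in self.ci.items()},
            "converged": bool(self.converged),
            "n_starts": int(self.n_starts),
            "boundary_flags": {k: bool(v) for k, v in self.boundary_flags.items()},
            "floored_intervals": int(self.floored_intervals),
        }


@dataclass
class GofMetrics:
    """EFSA-style quantitative goodness-of-fit metrics.

    nrmse : normalised root-mean-square error of survivor numbers over all
        treatment x time cells (dimensionless; screening band < 0.5).
    sppe : survival probability prediction error per treatment at the final
        observation, in percentage points (band |sppe| < 50).
    """

    nrmse: float
    sppe: dict[str, float]


# ---------------------------------------------------------------------
# likelihood core
# ---------------------------------------------------------------------


def _data_arrays(data: SurvivalDataset):
    """Extract numpy views and detect the all-constant-exposure fast path."""
    times = data.observation_times
    counts = np.stack([tr.survivors for tr in data.treatments])
    if np.any(np.diff(counts, axis=1) > 0):
        raise ValueError("survivor counts increase in time; prepare the dataset first")
    concs = np.array([tr.concentration for tr in data.treatments])
    constant = all(
        tr.exposure.is_constant() and tr.exposure.t_end >= times[-1] - 1e-12
        for tr in data.treatments
    )
    return times, concs, counts, constant


def _survival_matrix(params, variant, data, times, concs, constant) -> np.ndarray:
    if constant:
        if variant == "SD":
            return sd_survival_constant(concs, times, params)
        return it_survival_constant(concs, times, params)
    rows = []
    for tr in data.treatments:
        traj = damage(tr.exposure, params.kD, eval_times=times)
        curve = survival_sd(traj, params) if variant == "SD" else survival_it(traj, params)
        rows.append(curve.at(times))
    return np.stack(rows)


def _loglik_from_survival(S: np.ndarray, counts: np.ndarray) -> tuple[float, int]:
    """Interval-censored multinomial log-likelihood from a survival matrix
    (treatments x observation times, S[:, 0] == 1)."""
    deaths = -np.diff(counts, axis=1)
    p_int = S[:, :-1] - S[:, 1:]
    p_end = S[:, -1]
    floored = int(np.sum((p_int < PROB_FLOOR) & (deaths > 0)))
    floored += int(np.sum((p_end < PROB_FLOOR) & (counts[:, -1] > 0)))
    ll = float(
        np.sum(deaths * np.log(np.maximum(p_int, PROB_FLOOR)))
        + np.sum(counts[:, -1] * np.log(np.maximum(p_end, PROB_FLOOR)))
    )
    return ll, floored


def log_likelihood(params, data: SurvivalDataset, variant: str | None = None):
    """Log-likelihood of a parameter vector given a prepared dataset.

    ``variant`` may be omitted; it is inferred from the parameter type.
    """
    if variant is None:
        variant = "SD" if isinstance(params, SDParams) else "IT"
    variant = variant.upper()
    times, concs, counts, constant = _data_arrays(data)
    S = _survival_matrix(params, variant, data, times, concs, constant)
    if not np.all(np.isfinite(S)):
        raise ValueError("non-finite model survival")
    ll, _ = _loglik_from_survival(S, counts)
    return ll


def _make_nll(data: SurvivalDataset, variant: str):
    """Closure computing -LL from a log10 parameter vector, with data
    arrays hoisted out of the optimisation loop."""
    times, concs, counts, constant = _data_arrays(data)
    cls = SDParams if variant == "SD" else ITParams

    def nll(theta_log10: np.ndarray) -> float:
        vals = 10.0 ** np.asarray(theta_log10, dtype=float)
        try:
            p = cls(*vals)
            S = _survival_matrix(p, variant, data, times, concs, constant)
        except (ValueError, OverflowError):
            return 1e12
        if not np.all(np.isfinite(S)):
            return 1e12
        ll, _ = _loglik_from_survival(S, counts)
        return -ll

    return nll


# ---------------------------------------------------------------------
# bounds and multi-start search
# ---------------------------------------------------------------------


def default_bounds(data: SurvivalDataset, variant: str) -> dict[str, tuple[float, float]]:
    """Data-scaled search bounds on the natural scale.

    kD lower bound: a compound needing ~3 half-lives to reach 95% of
    steady state over the test would have kD ~= ln(20)/t_end; one
    hundredth of that is treated as effectively-no-kinetics. Threshold
    bounds span well below the lowest positive tested concentration and
    up to twice the highest, so an estimate pinned at a bound is a
    diagnosable sign of uninformative data rather than a silent clip.
    """
    variant = variant.upper()
    t_end = float(data.observation_times[-1])
    concs = data.concentrations
    pos = concs[concs > 0]
    if pos.size == 0:
        raise ValueError("need at least one positive-concentration treatment")
    thr_lo, thr_hi = float(pos.min() / 1000.0), float(2.0 * concs.max())
    kd_lo = math.log(20.0) / t_end / 100.0
    b = {"kD": (kd_lo, 1000.0), "hb": (1e-6, 0.1)}
    if variant == "SD":
        b["zw"] = (thr_lo, thr_hi)
        b["bw"] = (1e-4, 1e4)
    else:
        b["mw"] = (thr_lo, thr_hi)
        b["beta"] = (0.1, 100.0)
    return b


def fit(data: SurvivalDataset, variant: str, options: FitOptions | None = None,
        seed: int = 0) -> FitResult:
    """Calibrate one GUTS-RED variant to a prepared dataset.

    Multi-start maximum likelihood in log10 parameter space: a seeded
    Latin-hypercube screen of ``n_screen`` points, Nelder-Mead refinement
    from the best ``n_refine``, and (optionally) profile-likelihood 95%
    intervals for every parameter. Deterministic for a given seed.
    """
    variant = variant.upper()
    if variant not in ("SD", "IT"):
        raise ValueError(f"variant must be 'SD' or 'IT', got {variant!r}")
    if len(data.treatments) < 2:
        raise ValueError("need at least 2 treatments (including a control)")
    options = options or FitOptions()
    names = _SD_NAMES if variant == "SD" else _IT_NAMES
    bounds_nat = dict(default_bounds(data, variant))
    if options.bounds:
        bounds_nat.update(options.bounds)
    lo = np.log10([bounds_nat[n][0] for n in names])
    hi = np.log10([bounds_nat[n][1] for n in names])

    nll = _make_nll(data, variant)
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    screen = lo + sampler.random(options.n_screen) * (hi - lo)
    screen_nll = np.array([nll(x) for x in screen])
    order = np.argsort(screen_nll)

    best_x, best_f = None, np.inf
    n_ok = 0
    for idx in order[: options.n_refine]:
        res = minimize(
            nll, screen[idx], method="Nelder-Mead",
            bounds=list(zip(lo, hi)),
            options={"maxiter": options.nm_maxiter, "xatol": 1e-6, "fatol": 1e-9},
        )
        if np.isfinite(res.fun):
            n_ok += 1
            if res.fun < best_f:
                best_f, best_x = res.fun, res.x
    converged = n_ok > 0 and best_f < 1e11
    if best_x is None:
        best_x = screen[order[0]]
        best_f = screen_nll[order[0]]

    # tie-break for flat likelihoods: if sliding the threshold to its upper
    # bound (no predicted toxicity) or hb to its lower bound costs nothing,
    # snap there so uninformative data yield a recognisable boundary estimate
    thr_idx = 1  # zw or mw
    for pidx, bidx in ((thr_idx, 1), (3, 0)):
        cand = best_x.copy()
        cand[pidx] = hi[pidx] if bidx else lo[pidx]
        if nll(cand) <= best_f + 1e-9:
            best_x, best_f = cand, min(best_f, nll(cand))

    cls = SDParams if variant == "SD" else ITParams
    params = cls(*(10.0 ** best_x))
    span = hi - lo
    boundary = {
        n: bool(best_x[i] - lo[i] < 0.01 * span[i] or hi[i] - best_x[i] < 0.01 * span[i])
        for i, n in enumerate(names)
    }
    times, concs, counts, constant = _data_arrays(data)
    _, floored = _loglik_from_survival(
        _survival_matrix(params, variant, data, times, concs, constant), counts
    )
    result = FitResult(
        variant=variant, params=params, loglik=-best_f, ci={},
        converged=converged, n_starts=options.n_screen,
        boundary_flags=boundary,
        bounds=bounds_nat, floored_intervals=floored, seed=seed,
    )
    if options.compute_ci and converged:
        for name in names:
            interval, clipped = _profile_interval(result, nll, name, lo, hi)
            result.ci[name] = interval
            if clipped:
                result.boundary_flags[name] = True
    return result


# ---------------------------------------------------------------------
# profile likelihood
# ---------------------------------------------------------------------


def _profile_value(nll, fixed_idx, fixed_val, warm_starts, lo, hi, maxiter=200):
    """-LL minimised over the free parameters with one parameter pinned.

    Started from every point in ``warm_starts`` (typically the previous
    profile point's optimum plus the global MLE); a single chained warm
    start can strand Nelder-Mead in a shallow basin and corrupt the whole
    profile trace.
    """
    free = [i for i in range(lo.size) if i != fixed_idx]

    def reduced(theta_free):
        full = np.empty(lo.size)
        full[fixed_idx] = fixed_val
        full[free] = theta_free
        return nll(full)

    best_f, best_x = np.inf, None
    for warm in warm_starts:
        res = minimize(
            reduced, np.clip(warm[free], lo[free], hi[free]), method="Nelder-Mead",
            bounds=[(lo[i], hi[i]) for i in free],
            options={"maxiter": maxiter, "xatol": 1e-6, "fatol": 1e-8},
        )
        if res.fun < best_f:
            best_f, best_x = res.fun, res.x
    full = np.empty(lo.size)
    full[fixed_idx] = fixed_val
    full[free] = best_x
    return best_f, full


def _profile_interval(fit_result: FitResult, nll, name, lo, hi):
    """Likelihood-ratio 95% interval for one parameter by outward stepping
    plus bisection refinement; clipped (and flagged) at search bounds."""
    names = fit_result.param_names
    idx = names.index(name)
    x0 = np.log10(fit_result.param_values())
    f0 = -fit_result.loglik
    target = f0 + CHI2_95_HALF
    clipped = False
    limits = []
    for direction in (-1.0, +1.0):
        bound = lo[idx] if direction < 0 else hi[idx]
        x, fx, warm = x0[idx], f0, x0.copy()
        step = 0.05 * (hi[idx] - lo[idx])
        hit_bound = False
        while True:
            x_new = x + direction * step
            if (direction < 0 and x_new <= bound) or (direction > 0 and x_new >= bound):
                x_new = bound
                hit_bound = True
            f_new, warm = _profile_value(nll, idx, x_new, (warm, x0), lo, hi)
            if f_new > target:
                break
            x, fx = x_new, f_new
            if hit_bound:
                break
            step *= 1.7
        if hit_bound and fx <= target:
            limits.append(bound)
            clipped = True
            continue
        # bisect between (x, inside) and (x_new, outside)
        a, b = x, x_new
        fa, fb = fx, f_new
        for _ in range(5):
            mid = 0.5 * (a + b)
            fm, warm = _profile_value(nll, idx, mid, (warm, x0), lo, hi)
            if fm > target:
                b, fb = mid, fm
            else:
                a, fa = mid, fm
        # linear interpolation on the last bracket
        if fb > fa:
            frac = (target - fa) / (fb - fa)
            limits.append(a + frac * (b - a))
        else:
            limits.append(0.5 * (a + b))
    lo_nat, hi_nat = sorted(10.0 ** np.asarray(limits))
    # the interval must contain the point estimate
    val = fit_result.param_values()[idx]
    return (min(lo_nat, val), max(hi_nat, val)), clipped


def profile_ci(fit_result: FitResult, data: SurvivalDataset, param_name: str):
    """Stand-alone profile-likelihood 95% interval for one parameter."""
    if not fit_result.converged:
        raise ValueError("profile_ci requires a converged fit")
    names = fit_result.param_names
    if param_name not in names:
        raise ValueError(f"unknown parameter {param_name!r} for {fit_result.variant}")
    nll = _make_nll(data, fit_result.variant)
    bounds_nat = fit_result.bounds
    lo = np.log10([bounds_nat[n][0] for n in names])
    hi = np.log10([bounds_nat[n][1] for n in names])
    interval, _ = _profile_interval(fit_result, nll, param_name, lo, hi)
    return interval


# ---------------------------------------------------------------------
# goodness of fit
# ---------------------------------------------------------------------


def goodness_of_fit(fit_result: FitResult, data: SurvivalDataset) -> GofMetrics:
    """NRMSE over all treatment x time cells and per-treatment SPPE.

    Predicted survivor numbers are ``n0 * S_model(t)``. NRMSE is the RMS
    of (observed - predicted) divided by the mean observed count; SPPE is
    ``100 * (observed - predicted) / n0`` at the final observation.
    """
    if not fit_result.converged:
        raise ValueError("goodness_of_fit requires a converged fit")
    times, concs, counts, constant = _data_arrays(data)
    S = _survival_matrix(fit_result.params, fit_result.variant, data, times, concs, constant)
    n0 = counts[:, 0][:, None]
    pred = n0 * S
    nrmse = float(np.sqrt(np.mean((counts - pred) ** 2)) / np.mean(counts))
    sppe = {}
    for j, tr in enumerate(data.treatments):
        label = tr.exposure.label or f"{tr.concentration:g} ug/L"
        sppe[label] = float(100.0 * (counts[j, -1] - pred[j, -1]) / counts[j, 0])
    return GofMetrics(nrmse=nrmse, sppe=sppe)
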