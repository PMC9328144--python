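"""LPx endpoints: profile multiplication factors for x% mortality.

The LPx of an exposure profile is the factor by which the whole profile
must be multiplied for the model to predict x% toxicant-attributable
mortality at the end of the profile window. Background mortality is set
to zero during prediction, so the endpoint measures toxicity only and is
independent of test-specific control survival.

Damage is linear in the exposure concentration, so scaling the profile by
``f`` scales the whole damage trajectory by ``f``. For SD the end
survival is then monotone decreasing in ``f`` and the factor is found by
root bracketing; for IT the first-exceedance structure gives a closed
form,

    LPx = (mw / Dmax1) * (x / (100 - x))^(1/beta),

with ``Dmax1`` the running-maximum damage of the unscaled profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .calibration import CHI2_95_HALF, FitResult, _make_nll
from .dataset_prep import SurvivalDataset
from .exposure_profiles import ExposureProfile
from .guts_core import ITParams, SDParams, damage, survival_sd

__all__ = ["LPxResult", "lpx", "lpx_uncertainty"]


@dataclass
class LPxResult:
    """A lethal-profile endpoint with its uncertainty interval."""

    x: float
    factor: float
    ci: tuple[float, float] | None
    profile_label: str
    variant: str
    n_accepted: int | None = None
    flagged: bool = False


def _sd_end_survival_fn(params: SDParams, profile: ExposureProfile, subdiv: int = 16):
    """Return f -> end-of-window survival under ``profile`` scaled by f.

    The base damage trajectory is computed once (exact, with interior
    extrema on the grid) and densified; scaling by f multiplies the
    damage values, so each evaluation is a vector operation. Threshold
    crossings of ``f*D = zw`` are resolved by linear interpolation on the
    dense grid before the trapezoid hazard integral.
    """
    p = params.without_background()
    traj = damage(profile, p.kD)
    base = traj.times
    # subdivide each interval; resolve the exponential transient (time
    # scale 1/kD) even on coarse two-node profiles
    pieces = [np.array([base[0]])]
    for t0, t1 in zip(base[:-1], base[1:]):
        n = int(min(max(subdiv, np.ceil((t1 - t0) * p.kD * 16)), 4000))
        pieces.append(np.linspace(t0, t1, n + 1)[1:])
    grid = np.concatenate(pieces)
    D = np.maximum(traj.value_at(grid), 0.0)
    dt = np.diff(grid)

    def s_end(f: float) -> float:
        g = f * D - p.zw
        # trapezoid of max(0, g) with exact treatment of linear sign changes:
        # on a linearly-interpolated subinterval the positive-part integral is
        # (g+)^2 / (g+ - g-) / 2 when the sign changes
        g0, g1 = g[:-1], g[1:]
        both_pos = (g0 >= 0) & (g1 >= 0)
        cross = (g0 > 0) != (g1 > 0)
        seg = np.where(both_pos, 0.5 * (g0 + g1), 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            pos = np.maximum(g0, g1)
            seg = np.where(cross, 0.5 * pos**2 / np.abs(g1 - g0), seg)
        integral = float(np.sum(seg * dt))
        return float(np.exp(-p.bw * integral))

    return s_end


def lpx(params: SDParams | ITParams, profile: ExposureProfile, x: float = 50.0,
        rtol: float = 1e-4) -> float:
    """Multiplication factor giving x% mortality at the profile's end.

    Background hazard is zeroed internally. SD uses monotone root
    bracketing on the factor (bracket [1e-6, 1e6], grown from the damage
    linearity of the model); IT uses the closed form.
    """
    if not (0.0 < x < 100.0):
        raise ValueError(f"x must be in (0, 100), got {x}")
    target = 1.0 - x / 100.0
    if isinstance(params, ITParams):
        traj = damage(profile, params.kD)
        dmax1 = float(traj.running_max[-1])
        if dmax1 <= 0.0:
            raise ValueError("profile has zero exposure; LPx undefined")
        return (params.mw / dmax1) * (x / (100.0 - x)) ** (1.0 / params.beta)

    s_end = _sd_end_survival_fn(params, profile)

    def g(log10_f: float) -> float:
        return s_end(10.0**log10_f) - target

    lo, hi = -6.0, 6.0
    if g(lo) < 0.0:
        raise ValueError("profile causes > x% mortality even at factor 1e-6")
    if g(hi) > 0.0:
        raise ValueError("factor bracket [1e-6, 1e6] exhausted; exposure too weak")
    root = brentq(g, lo, hi, xtol=rtol / 4.0)
    return float(10.0**root)


def sd_end_survival(params: SDParams, profile: ExposureProfile, factor: float = 1.0) -> float:
    """End-of-window survival (toxicity only, hb = 0) of a scaled profile,
    via the full damage + hazard-integration path. Used as the
    independent check of the LPx defining property."""
    scaled = profile.scale(factor)
    p = params.without_background()
    traj = damage(scaled, p.kD)
    return survival_sd(traj, p).end


def lpx_uncertainty(fit_result: FitResult, data: SurvivalDataset,
                    profile: ExposureProfile, x: float = 50.0,
                    n_draws: int = 200, seed: int = 0) -> LPxResult:
    """Propagate calibration uncertainty into an LPx interval.

    Parameter sets are drawn uniformly (in log10 space) from the box
    spanned by the per-parameter profile intervals and accepted when
    their log-likelihood lies within chi2(1,0.95)/2 of the maximum — the
    95% likelihood region. The interval is the min/max LPx over the
    accepted draws plus the best fit. Fewer than 20 accepted draws flags
    the interval as unreliable.
    """
    if not fit_result.converged:
        raise ValueError("lpx_uncertainty requires a converged fit")
    if not fit_result.ci:
        raise ValueError("fit has no confidence intervals; run with compute_ci=True")
    rng = np.random.default_rng(seed)
    names = fit_result.param_names
    cls = SDParams if fit_result.variant == "SD" else ITParams
    lo = np.array([max(fit_result.ci[n][0], fit_result.bounds[n][0]) for n in names])
    hi = np.array([min(fit_result.ci[n][1], fit_result.bounds[n][1]) for n in names])
    log_lo, log_hi = np.log10(lo), np.log10(hi)
    nll = _make_nll(data, fit_result.variant)
    target = -fit_result.loglik + CHI2_95_HALF

    best = lpx(fit_result.params, profile, x)
    values = [best]
    accepted = 0
    max_attempts = 25 * n_draws
    attempts = 0
    while accepted < n_draws and attempts < max_attempts:
        attempts += 1
        theta = log_lo + rng.random(len(names)) * (log_hi - log_lo)
        if nll(theta) > target:
            continue
        try:
            values.append(lpx(cls(*(10.0**theta)), profile, x))
        except ValueError:
            continue
        accepted += 1
    flagged = accepted < 20
    return LPxResult(
        x=x, factor=best, ci=(float(min(values)), float(max(values))),
        profile_label=profile.label, variant=fit_result.variant,
        n_accepted=accepted, flagged=flagged,
    )
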