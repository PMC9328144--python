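"""Synthetic toxicity tests and FOCUS-like exposure scenarios.

Every stage of the analysis chain is testable without external data:
toxicity tests are simulated under known GUTS-RED parameters with the
same conditional-binomial death process the likelihood assumes, and
exposure scenarios are parametric idealisations of the three surface-water
patterns typical of FOCUS step-3 output — a single peak followed by a
slow decline, a single sharp peak, and a train of sharp peaks. Profiles
are built on hourly nodes, like TOXSWA output.

The built-in species panel spans dominant rate constants from ~0.25/day
("slow" — damage averages exposure over weeks, so long decline tails are
decisive) to ~100/day ("fast" — damage tracks the exposure, so short
peaks are decisive). Slow kinetics are paired with a low threshold and
fast kinetics with a higher one, so the panel's sensitivity ranking
reverses between pulse-like and long-tail exposure — the mechanism by
which species sensitivity depends on the exposure profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset_prep import SurvivalDataset, Treatment
from .exposure_profiles import ExposureProfile, constant_profile
from .guts_core import (
    ITParams,
    SDParams,
    SurvivalCurve,
    it_survival_constant,
    sd_survival_constant,
    simulate_survivors,
)

__all__ = [
    "TestDesign",
    "ScenarioSpec",
    "SpeciesSpec",
    "generate_test",
    "generate_scenario",
    "generate_species_panel",
]

_HOUR = 1.0 / 24.0


@dataclass(frozen=True)
class TestDesign:
    """Design of a constant-exposure toxicity test.

    Defaults follow a standard acute fish test: five concentrations on a
    roughly geometric ladder plus a (pooled) control, 40 fish per
    treatment, daily observation over 4 days.
    """

    concentrations: tuple = (0.0, 1.8, 3.2, 5.6, 10.0, 18.0)
    n0: int = 40
    observation_times: tuple = (0.0, 1.0, 2.0, 3.0, 4.0)

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")
        if not np.any(c == 0):
            raise ValueError("design needs a control (concentration 0)")
        if not np.any(c > 0):
            raise ValueError("design needs at least one positive concentration")
        if self.n0 < 1:
            raise ValueError("n0 must be >= 1")
        t = np.asarray(self.observation_times, dtype=float)
        if t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValueError("observation times must start at 0 and increase")

    @property
    def duration(self) -> float:
        return float(self.observation_times[-1])


@dataclass(frozen=True)
class ScenarioSpec:
    """Parametric exposure-scenario shape.

    shape : ``single-peak-slow-decline`` | ``single-sharp-peak`` | ``multi-peak``
    peak_conc : maximum concentration, ug/L
    duration : profile window, days
    n_peaks : number of pulses (multi-peak only, >= 2)
    decline_halflife : half-life of the post-peak decline, days
        (slow-decline only)
    """

    shape: str
    peak_conc: float = 1.0
    duration: float | None = None
    n_peaks: int = 4
    decline_halflife: float = 10.0
    label: str = ""

    _SHAPES = ("single-peak-slow-decline", "single-sharp-peak", "multi-peak")
    _DEFAULT_DURATION = {
        "single-peak-slow-decline": 60.0,
        "single-sharp-peak": 2.0,
        "multi-peak": 30.0,
    }

    def __post_init__(self) -> None:
        if self.shape not in self._SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}; expected one of {self._SHAPES}")
        if not (self.peak_conc > 0):
            raise ValueError("peak_conc must be > 0")
        if self.duration is None:
            object.__setattr__(self, "duration", self._DEFAULT_DURATION[self.shape])
        if not (self.duration > 0):
            raise ValueError("duration must be > 0")
        if self.shape == "multi-peak" and self.n_peaks < 2:
            raise ValueError("multi-peak needs n_peaks >= 2")
        if self.shape == "single-peak-slow-decline" and not (self.decline_halflife > 0):
            raise ValueError("decline_halflife must be > 0")
        if not self.label:
            object.__setattr__(self, "label", self.shape)


def generate_test(params: SDParams | ITParams, variant: str, design: TestDesign,
                  seed: int = 0) -> SurvivalDataset:
    """Simulate a constant-exposure toxicity test under known parameters.

    Each treatment is a two-node constant profile; survivors follow the
    conditional-binomial death process along the exact model survival
    curve. Reproducible under ``seed`` (independent substreams per
    treatment).
    """
    variant = variant.upper()
    if variant not in ("SD", "IT"):
        raise ValueError(f"variant must be 'SD' or 'IT', got {variant!r}")
    if variant == "SD" and not isinstance(params, SDParams):
        raise TypeError("variant 'SD' needs SDParams")
    if variant == "IT" and not isinstance(params, ITParams):
        raise TypeError("variant 'IT' needs ITParams")
    times = np.asarray(design.observation_times, dtype=float)
    rng_streams = np.random.SeedSequence(seed).spawn(len(design.concentrations))
    treatments = []
    for conc, ss in zip(design.concentrations, rng_streams):
        if variant == "SD":
            S = sd_survival_constant([conc], times, params)[0]
        else:
            S = it_survival_constant([conc], times, params)[0]
        curve = SurvivalCurve(times, S)
        counts = simulate_survivors(curve, design.n0, times,
                                    np.random.default_rng(ss))
        label = "control" if conc == 0 else f"{conc:g} ug/L"
        treatments.append(
            Treatment(constant_profile(conc, design.duration, label=label), counts)
        )
    return SurvivalDataset(times, tuple(treatments), species="synthetic",
                           study_type="acute")


def _hourly(t_end: float) -> np.ndarray:
    n = int(round(t_end / _HOUR))
    return np.linspace(0.0, n * _HOUR, n + 1)


def _triangle(t: np.ndarray, center: float, rise: float, fall: float, peak: float) -> np.ndarray:
    up = peak * (t - (center - rise)) / rise
    down = peak * ((center + fall) - t) / fall
    return np.clip(np.minimum(up, down), 0.0, peak)


def generate_scenario(spec: ScenarioSpec) -> ExposureProfile:
    """Build an hourly-resolved exposure profile from a scenario spec.

    All shapes start and end at zero concentration and reach exactly
    ``peak_conc`` at their maximum.
    """
    t = _hourly(spec.duration)
    if spec.shape == "single-sharp-peak":
        # ~1 day rising limb, ~1 day fall, centred in the window
        rise = min(1.0, spec.duration / 2)
        fall = min(1.0, spec.duration / 2)
        c = _triangle(t, rise, rise, fall, spec.peak_conc)
    elif spec.shape == "single-peak-slow-decline":
        # fast rise (2 h), then first-order decline with the given half-life
        t_peak = 2 * _HOUR
        lam = np.log(2.0) / spec.decline_halflife
        c = np.where(
            t <= t_peak,
            spec.peak_conc * t / t_peak,
            spec.peak_conc * np.exp(-lam * (t - t_peak)),
        )
        c[-1] = 0.0
    else:  # multi-peak
        half = 0.5  # days: sharp pulses, 12 h rise and fall
        centers = np.linspace(half, spec.duration - half, spec.n_peaks)
        c = np.zeros_like(t)
        for ctr in centers:
            c = np.maximum(c, _triangle(t, ctr, half, half, spec.peak_conc))
    c[0] = 0.0
    c[-1] = 0.0
    # ensure the nominal peak is attained exactly at the nearest node
    c[np.argmax(c)] = spec.peak_conc
    return ExposureProfile(t, c, label=spec.label)


@dataclass(frozen=True)
class SpeciesSpec:
    """A synthetic species: a label plus matched SD and IT parameter sets."""

    label: str
    sd: SDParams
    it: ITParams


def generate_species_panel(seed: int = 0) -> list[SpeciesSpec]:
    """Deterministic five-species panel spanning slow to fast kinetics.

    kD spans ~3 orders of magnitude (0.25 to 100 per day). The slow end
    pairs low kD with a low threshold (long-tail exposure accumulates
    damage and is decisive); the fast end pairs high kD with a higher
    threshold and killing rate (short pulses are decisive). The panel is
    fixed — the seed is accepted for interface symmetry with the other
    generators and future randomised panels.
    """
    del seed  # panel is deterministic
    hb = 0.01
    return [
        SpeciesSpec(
            "slow-accumulator",
            SDParams(kD=0.25, zw=0.30, bw=0.8, hb=hb),
            ITParams(kD=0.25, mw=0.60, beta=4.0, hb=hb),
        ),
        SpeciesSpec(
            "slow-intermediate",
            SDParams(kD=1.0, zw=0.45, bw=0.6, hb=hb),
            ITParams(kD=1.0, mw=0.90, beta=3.5, hb=hb),
        ),
        SpeciesSpec(
            "mid-kinetics",
            SDParams(kD=4.0, zw=0.70, bw=1.0, hb=hb),
            ITParams(kD=4.0, mw=1.20, beta=3.0, hb=hb),
        ),
        SpeciesSpec(
            "fast-intermediate",
            SDParams(kD=20.0, zw=0.90, bw=1.5, hb=hb),
            ITParams(kD=20.0, mw=1.50, beta=3.5, hb=hb),
        ),
        SpeciesSpec(
            "fast-tracker",
            SDParams(kD=100.0, zw=1.20, bw=2.0, hb=hb),
            ITParams(kD=100.0, mw=2.00, beta=4.0, hb=hb),
        ),
    ]
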