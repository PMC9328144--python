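"""Time-variable exposure concentration profiles.

An :class:`ExposureProfile` is a piecewise-linear concentration time series
``Cw(t)`` in micrograms per litre, with time in days. It is the external
driver of the reduced GUTS damage state: toxicity-test treatments are
represented as two-node constant profiles, while predicted surface-water
time series (e.g. hourly TOXSWA output) carry one node per sample point.

Linear interpolation between nodes is used throughout; no extrapolation is
performed outside the recorded window, so model predictions are defined
only on the profile's support.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ExposureProfile",
    "constant_profile",
    "read_profile",
    "write_profile",
]

#: Unit factor: 1 g/m^3 == 1000 ug/L.
_GM3_TO_UGL = 1000.0
_HOURS_PER_DAY = 24.0


@dataclass(frozen=True)
class ExposureProfile:
    """Piecewise-linear exposure concentration time series.

    Parameters
    ----------
    times
        Observation/sample times in days, strictly increasing, starting at 0.
    concentrations
        Concentrations in ug/L, same length as ``times``, non-negative.
    label
        Free-text identifier (scenario name, treatment level, ...).
    """

    times: np.ndarray
    concentrations: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.ndim != 1 or c.ndim != 1 or t.size != c.size:
            raise ValueError("times and concentrations must be 1-D and equal length")
        if t.size < 2:
            raise ValueError("profile needs at least 2 nodes")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(c)):
            raise ValueError("times and concentrations must be finite")
        if t[0] != 0.0:
            raise ValueError(f"first time must be 0, got {t[0]}")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)

    # -- basic queries -------------------------------------------------

    @property
    def t_end(self) -> float:
        """Last recorded time in days."""
        return float(self.times[-1])

    @property
    def peak(self) -> float:
        """Maximum nodal concentration in ug/L (the true maximum, since the
        profile is piecewise linear)."""
        return float(self.concentrations.max())

    def at(self, t) -> np.ndarray | float:
        """Concentration at time(s) ``t`` by linear interpolation.

        Raises ``ValueError`` for any ``t`` outside ``[0, t_end]``; the
        profile is not extrapolated.
        """
        ta = np.asarray(t, dtype=float)
        if np.any(ta < self.times[0]) or np.any(ta > self.times[-1]):
            raise ValueError(
                f"time outside profile support [0, {self.t_end}] for profile "
                f"{self.label!r}"
            )
        out = np.interp(ta, self.times, self.concentrations)
        return float(out) if np.isscalar(t) or ta.ndim == 0 else out

    def scale(self, factor: float) -> "ExposureProfile":
        """Return a copy with all concentrations multiplied by ``factor``.

        This is the operation underlying LPx endpoints: the multiplication
        factor applied uniformly to the whole profile.
        """
        factor = float(factor)
        if not np.isfinite(factor) or factor < 0:
            raise ValueError(f"scale factor must be finite and >= 0, got {factor}")
        return ExposureProfile(
            self.times.copy(), self.concentrations * factor, self.label
        )

    def is_constant(self, rtol: float = 0.0) -> bool:
        c = self.concentrations
        if c[0] == 0.0:
            return bool(np.all(c == 0.0))
        return bool(np.all(np.abs(c - c[0]) <= rtol * abs(c[0])))


def concentration_at(profile: ExposureProfile, t):
    """Functional alias for :meth:`ExposureProfile.at`."""
    return profile.at(t)


def scale(profile: ExposureProfile, factor: float) -> ExposureProfile:
    """Functional alias for :meth:`ExposureProfile.scale`."""
    return profile.scale(factor)


def constant_profile(conc: float, duration: float, label: str = "") -> ExposureProfile:
    """Two-node constant profile ``[(0, conc), (duration, conc)]``.

    Toxicity-test treatments (nominally constant exposure) are represented
    this way so a single code path serves both laboratory tests and field
    profiles.
    """
    conc = float(conc)
    duration = float(duration)
    if conc < 0:
        raise ValueError("concentration must be non-negative")
    if duration <= 0:
        raise ValueError("duration must be positive")
    return ExposureProfile(np.array([0.0, duration]), np.array([conc, conc]), label)


# -- file I/O ----------------------------------------------------------

_DIALECTS = ("two-column-ugL", "toxswa-gm3")


def read_profile(path, dialect: str = "two-column-ugL", label: str | None = None) -> ExposureProfile:
    """Read a two-column exposure table.

    Dialects
    --------
    ``two-column-ugL``
        time in days, concentration in ug/L — the package's native format.
    ``toxswa-gm3``
        time in hours, concentration in g/m^3 (the TOXSWA outfile variable
        ConLiqWatLay); converted to days and ug/L on read
        (1 g/m^3 = 1000 ug/L, hours / 24 = days).

    Columns may be comma-, tab- or whitespace-separated; a single header
    row of non-numeric text is skipped. Unparseable rows are rejected with
    their line number.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    path = Path(path)
    times: list[float] = []
    concs: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p for p in line.replace(",", " ").replace("\t", " ").split() if p]
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            try:
                t, c = float(parts[0]), float(parts[1])
            except ValueError:
                if lineno == 1 and not times:
                    continue  # header row
                raise ValueError(f"{path}:{lineno}: unparseable row {line!r}") from None
            times.append(t)
            concs.append(c)
    if len(times) < 2:
        raise ValueError(f"{path}: fewer than 2 data rows")
    t = np.asarray(times)
    c = np.asarray(concs)
    if dialect == "toxswa-gm3":
        t = t / _HOURS_PER_DAY
        c = c * _GM3_TO_UGL
    if np.any(np.diff(t) <= 0):
        bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 2
        raise ValueError(f"{path}: times not strictly increasing at data row {bad}")
    if np.any(c < 0):
        bad = int(np.flatnonzero(c < 0)[0]) + 1
        raise ValueError(f"{path}: negative concentration at data row {bad}")
    return ExposureProfile(t, c, label if label is not None else path.stem)


def write_profile(profile: ExposureProfile, path) -> None:
    """Write a profile as a native two-column table (days, ug/L).

    Uses ``repr`` floats so a read of the written file reproduces the
    profile bit for bit.
    """
    path = Path(path)
    buf = io.StringIO()
    buf.write("time_d,conc_ugL\n")
    for t, c in zip(profile.times, profile.concentrations):
        buf.write(f"{float(t)!r},{float(c)!r}\n")
    path.write_text(buf.getvalue())
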