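"""Survival-count datasets from toxicity tests, and their preparation.

Raw counts from fish toxicity tests need three kinds of preparation before
they can drive an interval-censored survival likelihood:

* **Monotonicity censoring** — reported survivor numbers occasionally rise
  between observations (individuals erroneously scored dead). Each
  sequence is capped at its previous value so counts never increase, which
  preserves the total number of individuals reported at the final day.
* **Replicate pooling** — replicates of a treatment are summed per time
  point.
* **Control pooling** — control and solvent control are summed when their
  survival is similar (similarity testing is up to the data author; this
  module only performs the pooling).

Early-life-stage (ELS) tests additionally have a pre-hatch egg phase that
the reduced GUTS model cannot represent (the organism changes life stage),
so observations before hatch are dropped and time is re-zeroed at hatch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .exposure_profiles import ExposureProfile, constant_profile

__all__ = [
    "Treatment",
    "SurvivalDataset",
    "enforce_monotone",
    "pool_groups",
    "prepare_els",
    "read_survival_table",
    "write_survival_table",
]


@dataclass(frozen=True)
class Treatment:
    """One exposure level of a toxicity test.

    ``survivors[i]`` is the number of live organisms at
    ``observation_times[i]`` of the parent dataset; ``survivors[0]`` is the
    number introduced at test start.
    """

    exposure: ExposureProfile
    survivors: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.survivors)
        if np.any(s < 0):
            raise ValueError("survivor counts must be non-negative")
        if not np.all(s == np.floor(s)):
            raise ValueError("survivor counts must be integers")
        object.__setattr__(self, "survivors", s.astype(int))

    @property
    def n0(self) -> int:
        return int(self.survivors[0])

    @property
    def concentration(self) -> float:
        """Nominal (constant) concentration of the treatment, ug/L."""
        return float(self.exposure.concentrations[0])


@dataclass(frozen=True)
class SurvivalDataset:
    """Survivor counts for all treatments of one toxicity test.

    study_type is ``"acute"`` (typically 4-day, constant exposure) or
    ``"ELS"`` (early life stage, post-hatch phase only after preparation).
    """

    observation_times: np.ndarray
    treatments: tuple[Treatment, ...]
    species: str = ""
    study_type: str = "acute"

    def __post_init__(self) -> None:
        t = np.asarray(self.observation_times, dtype=float)
        if t[0] != 0.0:
            raise ValueError("first observation time must be 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("observation times must be strictly increasing")
        if self.study_type not in ("acute", "ELS"):
            raise ValueError(f"unknown study_type {self.study_type!r}")
        object.__setattr__(self, "observation_times", t)
        object.__setattr__(self, "treatments", tuple(self.treatments))
        for tr in self.treatments:
            if len(tr.survivors) != t.size:
                raise ValueError(
                    "treatment survivor sequence length does not match "
                    "observation times"
                )

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([tr.concentration for tr in self.treatments])

    def is_monotone(self) -> bool:
        return all(
            np.all(np.diff(tr.survivors) <= 0) for tr in self.treatments
        )


def enforce_monotone(survivors) -> np.ndarray:
    """Cap each count at the previous (capped) value.

    ``out[0] = in[0]``; ``out[i] = min(in[i], out[i-1])``. Leaves already
    non-increasing sequences untouched and never changes the final count
    when the final count is consistent with the earlier record, so the
    total number of individuals reported at the last observation is
    preserved.
    """
    s = np.asarray(survivors)
    if np.any(s < 0):
        raise ValueError("survivor counts must be non-negative")
    out = s.astype(int).copy()
    for i in range(1, out.size):
        if out[i] > out[i - 1]:
            out[i] = out[i - 1]
    return out


def pool_groups(groups) -> np.ndarray:
    """Element-wise sum of survivor sequences observed at identical times."""
    groups = list(groups)
    if not groups:
        raise ValueError("no groups to pool")
    arrs = [np.asarray(g, dtype=int) for g in groups]
    n = arrs[0].size
    if any(a.size != n for a in arrs):
        raise ValueError("groups must have equal length (identical observation times)")
    return np.sum(arrs, axis=0)


def prepare_els(raw: SurvivalDataset, hatch_day: float) -> SurvivalDataset:
    """Prepare a raw ELS dataset for calibration.

    Steps, in order:

    1. drop observations before ``hatch_day`` and re-zero time at hatch
       (the egg phase is outside the model's scope);
    2. enforce monotone survivor counts per replicate;
    3. pool replicates per treatment level (equal concentration);
    4. pool controls (concentration 0) with solvent controls.

    Replicates are represented as multiple ``Treatment`` entries sharing a
    concentration. Steps 3 and 4 both reduce to summation over equal
    concentrations; monotonicity is applied strictly before pooling, which
    matters because capping does not commute with summation.
    """
    t = raw.observation_times
    if hatch_day >= t[-1]:
        raise ValueError(f"hatch_day {hatch_day} at or beyond last observation {t[-1]}")
    keep = t >= hatch_day
    # re-zero: the observation at (or first after) hatch becomes t=0
    new_t = t[keep] - t[keep][0]

    # steps 1+2 per replicate
    prepared: list[tuple[float, np.ndarray]] = []
    for tr in raw.treatments:
        s = enforce_monotone(tr.survivors[keep])
        prepared.append((tr.concentration, s))

    # steps 3+4: pool by concentration, keeping first-seen order
    order: list[float] = []
    by_conc: dict[float, list[np.ndarray]] = {}
    for conc, s in prepared:
        if conc not in by_conc:
            by_conc[conc] = []
            order.append(conc)
        by_conc[conc].append(s)

    duration = float(new_t[-1])
    treatments = [
        Treatment(constant_profile(conc, duration, label=f"{conc:g} ug/L"),
                  pool_groups(by_conc[conc]))
        for conc in order
    ]
    return SurvivalDataset(new_t, tuple(treatments), raw.species, "ELS")


# -- file I/O ----------------------------------------------------------


def read_survival_table(path, species: str = "", study_type: str = "acute") -> SurvivalDataset:
    """Read a survival table.

    Format: comma- or tab-separated; first column = observation time in
    days; remaining columns = treatments with the concentration in ug/L as
    header (the literal header ``control`` means 0 ug/L); cells = survivor
    counts.
    """
    path = Path(path)
    lines = [l for l in path.read_text().splitlines() if l.strip() and not l.startswith("#")]
    if len(lines) < 3:
        raise ValueError(f"{path}: need a header and at least 2 observation rows")
    sep = "\t" if "\t" in lines[0] else ","
    header = [h.strip() for h in lines[0].split(sep)]
    concs = []
    for h in header[1:]:
        if h.lower() in ("control", "solvent-control", "solvent_control"):
            concs.append(0.0)
        else:
            try:
                concs.append(float(h))
            except ValueError:
                raise ValueError(f"{path}: bad treatment header {h!r}") from None
    times = []
    counts = []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = [p.strip() for p in line.split(sep)]
        if len(parts) != len(header):
            raise ValueError(f"{path}:{lineno}: expected {len(header)} columns")
        try:
            times.append(float(parts[0]))
            counts.append([int(p) for p in parts[1:]])
        except ValueError:
            raise ValueError(f"{path}:{lineno}: unparseable row {line!r}") from None
    t = np.asarray(times)
    counts_arr = np.asarray(counts, dtype=int)
    duration = float(t[-1])
    treatments = [
        Treatment(constant_profile(c, duration, label=h), counts_arr[:, j])
        for j, (c, h) in enumerate(zip(concs, header[1:]))
    ]
    return SurvivalDataset(t, tuple(treatments), species, study_type)


def write_survival_table(data: SurvivalDataset, path) -> None:
    """Write a dataset in the table format of :func:`read_survival_table`.

    Round-trips exactly with the reader (counts are integers and headers
    carry full-precision concentrations).
    """
    path = Path(path)
    headers = ["time_d"]
    for tr in data.treatments:
        headers.append("control" if tr.concentration == 0.0 else repr(tr.concentration))
    rows = [",".join(headers)]
    for i, t in enumerate(data.observation_times):
        cells = [repr(float(t))] + [str(int(tr.survivors[i])) for tr in data.treatments]
        rows.append(",".join(cells))
    path.write_text("\n".join(rows) + "\n")
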