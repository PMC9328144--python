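"""Species sensitivity distributions over LP50 values, HP5, and rankings.

An SSD here is a log-normal (base-10) distribution fitted by maximum
likelihood to one LP50 per species for a given exposure profile and model
variant. Its 5th percentile is the HP5 — the multiplication factor at
which 5% of species are predicted to reach 50% mortality. Rankings order
species by ascending LP50 (most sensitive first); the change report
lists species pairs whose relative order differs between profiles, the
study-level observable that sensitivity rank depends on exposure
dynamics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = ["SSDFit", "RankingTable", "fit_ssd", "hp5", "rank_species"]

_Z05 = float(norm.ppf(0.05))  # -1.6448536...


@dataclass(frozen=True)
class SSDFit:
    """Log-normal SSD: ``log10(LP50) ~ Normal(mu, sigma)``.

    sigma is the maximum-likelihood estimate (n denominator). hp5 is the
    5th percentile back on the natural scale.
    """

    mu: float
    sigma: float
    hp5: float
    n_species: int

    def cdf(self, values) -> np.ndarray:
        """Fraction of species affected at the given multiplication
        factor(s) — the SSD curve."""
        return norm.cdf((np.log10(values) - self.mu) / self.sigma)


@dataclass
class RankingTable:
    """Per-(profile, variant) species orderings and the cross-profile
    change report."""

    orderings: dict[tuple[str, str], list[tuple[str, float]]]
    changes: list[dict]
    ties: list[dict] = field(default_factory=list)

    @property
    def changed(self) -> bool:
        return len(self.changes) > 0

    def most_sensitive(self, profile: str, variant: str) -> str:
        return self.orderings[(profile, variant)][0][0]


def fit_ssd(lp50s) -> SSDFit:
    """Maximum-likelihood log-normal SSD fit to per-species LP50 values.

    Requires at least 3 distinct positive values; fewer than 5 species
    triggers a warning (the fit is then weakly informed, as is typical
    for fish risk assessments). hp5 = 10^(mu + sigma * z_0.05).
    """
    v = np.asarray(list(lp50s), dtype=float)
    if v.size < 3:
        raise ValueError(f"need >= 3 LP50 values, got {v.size}")
    if np.any(v <= 0) or not np.all(np.isfinite(v)):
        raise ValueError("LP50 values must be positive and finite")
    if np.unique(v).size == 1:
        raise ValueError("all LP50 values identical; SSD sigma degenerate")
    if v.size < 5:
        warnings.warn(
            f"SSD fitted to only {v.size} species; percentile estimates are "
            "weakly informed", stacklevel=2,
        )
    logs = np.log10(np.sort(v))  # canonical order: strict permutation invariance
    mu = float(np.mean(logs))
    sigma = float(np.std(logs))  # ML estimate: n denominator
    return SSDFit(mu=mu, sigma=sigma, hp5=float(10.0 ** (mu + sigma * _Z05)),
                  n_species=int(v.size))


def hp5(ssd: SSDFit) -> float:
    """The 5% hazard profile: multiplication factor at which 5% of species
    reach 50% mortality (5th percentile of the SSD)."""
    return ssd.hp5


def rank_species(lp50_table: pd.DataFrame) -> RankingTable:
    """Rank species by LP50 per (profile, variant) and report changes.

    ``lp50_table`` is tidy with columns ``species``, ``profile``,
    ``variant``, ``lp50``; every species must have a value for every
    (profile, variant) combination. The change report lists each species
    pair whose relative order differs between any two profiles under the
    same variant.
    """
    required = {"species", "profile", "variant", "lp50"}
    missing_cols = required - set(lp50_table.columns)
    if missing_cols:
        raise ValueError(f"lp50_table missing columns: {sorted(missing_cols)}")
    lp50_table = lp50_table.drop_duplicates()
    species = sorted(lp50_table["species"].unique())
    cells = lp50_table.set_index(["species", "profile", "variant"])["lp50"]
    if cells.index.has_duplicates:
        dupes = cells.index[cells.index.duplicated()].tolist()
        raise ValueError(f"conflicting LP50 values for cells: {dupes}")
    combos = sorted(
        set(zip(lp50_table["profile"], lp50_table["variant"]))
    )
    missing = [
        (s, pr, va) for s in species for (pr, va) in combos
        if (s, pr, va) not in cells.index
    ]
    if missing:
        raise ValueError(f"missing LP50 cells: {missing}")

    orderings: dict[tuple[str, str], list[tuple[str, float]]] = {}
    ties: list[dict] = []
    for pr, va in combos:
        vals = [(s, float(cells[(s, pr, va)])) for s in species]
        vals.sort(key=lambda x: (x[1], x[0]))
        orderings[(pr, va)] = vals
        for (s1, v1), (s2, v2) in zip(vals[:-1], vals[1:]):
            if v1 == v2:
                ties.append({"profile": pr, "variant": va, "pair": (s1, s2), "lp50": v1})

    changes: list[dict] = []
    variants = sorted({va for _, va in combos})
    for va in variants:
        profs = [pr for pr, v in combos if v == va]
        rank_of = {
            pr: {s: i for i, (s, _) in enumerate(orderings[(pr, va)])} for pr in profs
        }
        for i, s1 in enumerate(species):
            for s2 in species[i + 1:]:
                for a_idx, pa in enumerate(profs):
                    for pb in profs[a_idx + 1:]:
                        da = rank_of[pa][s1] - rank_of[pa][s2]
                        db = rank_of[pb][s1] - rank_of[pb][s2]
                        if da * db < 0:
                            changes.append({
                                "variant": va, "pair": (s1, s2),
                                "profiles": (pa, pb),
                            })
    return RankingTable(orderings=orderings, changes=changes, ties=ties)
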