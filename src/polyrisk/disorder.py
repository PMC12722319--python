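"""Isolated-site configurational disorder model.

Each disordered fragment ("site") is treated as an independent unit whose
discrete configurations are Boltzmann-populated at temperature T.  The model
yields per-configuration occupancies

    pᵢ = dᵢ·exp(−gᵢ/RT) / Σⱼ dⱼ·exp(−gⱼ/RT)

and a configurational free-energy stabilization

    ΔF_site = min(g) − (−RT·ln Σᵢ dᵢ·exp(−gᵢ/RT)) ≥ 0,

the amount by which the configurational ensemble lies below the best single
ordered configuration.  Sites are assumed non-interacting, so the joint
partition function factorizes and the total stabilization is the sum over
sites.  Closely interacting disordered groups violate this assumption and
are deliberately unsupported.

Stabilizations are reported as positive magnitudes ("stabilizes by x
kJ/mol"); apply them by *subtracting* from a free energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .constants import R_KJ_MOL_K
from .errors import InfiniteGapError

__all__ = [
    "DisorderSiteModel",
    "DisorderCorrection",
    "site_occupancies",
    "site_stabilization",
    "energy_gap_from_occupancies",
    "apply_disorder_correction",
]


@dataclass(frozen=True)
class DisorderSiteModel:
    """One disordered fragment: per-configuration free energies and degeneracies.

    Energies are in kJ/mol; degeneracies default to 1 per configuration.
    """

    site_id: str
    config_free_energies: tuple
    degeneracies: tuple = ()

    def __post_init__(self):
        g = tuple(float(x) for x in self.config_free_energies)
        if len(g) < 1:
            raise ValueError("need at least one configuration")
        if not all(math.isfinite(x) for x in g):
            raise ValueError("configuration energies must be finite")
        d = self.degeneracies or (1,) * len(g)
        d = tuple(int(x) for x in d)
        if len(d) != len(g):
            raise ValueError("degeneracies must match configuration count")
        if any(x < 1 for x in d):
            raise ValueError("degeneracies must be positive integers")
        object.__setattr__(self, "config_free_energies", g)
        object.__setattr__(self, "degeneracies", d)


@dataclass(frozen=True)
class DisorderCorrection:
    """Aggregated disorder correction over independent sites."""

    total_stabilization: float
    per_site: dict
    occupancies: dict


def _check_temperature(T: float) -> None:
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")


def site_occupancies(site: DisorderSiteModel, T: float = 300.0) -> np.ndarray:
    """Boltzmann configuration probabilities at temperature T (K)."""
    _check_temperature(T)
    g = np.asarray(site.config_free_energies)
    d = np.asarray(site.degeneracies, dtype=float)
    # max-shift for numerical stability
    x = -(g - g.min()) / (R_KJ_MOL_K * T)
    w = d * np.exp(x)
    return w / w.sum()


def site_stabilization(site: DisorderSiteModel, T: float = 300.0) -> float:
    """Configurational stabilization of one site in kJ/mol (positive magnitude)."""
    _check_temperature(T)
    g = np.asarray(site.config_free_energies)
    d = np.asarray(site.degeneracies, dtype=float)
    RT = R_KJ_MOL_K * T
    g0 = g.min()
    # F_ensemble = -RT ln Σ d e^{-g/RT};  stabilization = min(g) - F_ensemble
    f_ens = g0 - RT * logsumexp(-(g - g0) / RT, b=d)
    return float(g0 - f_ens)


def energy_gap_from_occupancies(p: Sequence[float], T: float = 300.0) -> float:
    """Invert the two-configuration Boltzmann relation: Δg = −RT·ln(p₂/p₁).

    ``p`` is the (p₁, p₂) occupancy pair of a two-configuration site with
    unit degeneracies; returns the free-energy gap g₂ − g₁ in kJ/mol.
    """
    _check_temperature(T)
    p1, p2 = float(p[0]), float(p[1])
    if not (0.0 < p1 < 1.0 and 0.0 < p2 < 1.0):
        raise InfiniteGapError("occupancies of 0 or 1 imply an infinite energy gap")
    return -R_KJ_MOL_K * T * math.log(p2 / p1)


def disorder_correction(sites: Sequence[DisorderSiteModel], T: float = 300.0) -> DisorderCorrection:
    """Total stabilization and occupancies for a set of independent sites."""
    per_site = {s.site_id: site_stabilization(s, T) for s in sites}
    occ = {s.site_id: site_occupancies(s, T) for s in sites}
    return DisorderCorrection(
        total_stabilization=float(sum(per_site.values())),
        per_site=per_site,
        occupancies=occ,
    )


def apply_disorder_correction(entry, sites: Sequence[DisorderSiteModel], T: float = 300.0):
    """Lower a landscape entry's free energy by the total site stabilization.

    Returns a copy of the entry with ``free_energy_rel`` reduced by the sum
    of per-site stabilizations and ``disordered`` set.  An empty site list
    returns the entry unchanged.
    """
    if not sites:
        return entry
    corr = disorder_correction(sites, T)
    return replace(
        entry,
        free_energy_rel=entry.free_energy_rel - corr.total_stabilization,
        disordered=True,
    )
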