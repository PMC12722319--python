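"""Crystal-energy-landscape assembly.

A crystal structure prediction study delivers, per candidate structure, a
lattice energy E_latt and — for an affordable subset — an explicitly
computed vibrational free-energy term F_vib(T).  This module combines them
into room-temperature free energies relative to the global minimum:

* explicit entries:  F = E_latt + F_vib, error bar = σ_base
* remaining entries: F = E_latt + mean(F_vib over the explicit subset),
  error bar = √(σ_base² + sd(F_vib)²)

i.e. candidates whose vibrational term is only estimated by the uniform
shift carry the spread of the explicit F_vib values in quadrature on top of
the energy model's one standard error.  Entries are ranked by relative free
energy; the best-matching candidate for each named experimental pattern can
be labeled via the powder-pattern similarity ranking.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .similarity import SimilarityParams, rank_candidates

__all__ = [
    "LandscapeEntry",
    "ShiftEstimate",
    "estimate_fvib_shift",
    "assemble_landscape",
    "attach_match_labels",
    "landscape_table",
    "read_energy_table",
    "write_landscape_csv",
    "read_landscape_csv",
    "plot_landscape",
]

DEFAULT_TEMPERATURE = 300.0  # K, standard reporting temperature
DEFAULT_SIGMA_BASE = 1.9  # kJ/mol, one standard error of the free-energy model


@dataclass(frozen=True)
class LandscapeEntry:
    """One candidate polymorph on the energy landscape.

    Energies are kJ/mol per molecule.  ``fvib`` is the explicit vibrational
    free-energy term when available; ``free_energy_rel``, ``sigma`` and
    ``rank`` are filled in by :func:`assemble_landscape`.
    """

    id: str
    elatt: float
    spacegroup: str = "?"
    fvib: Optional[float] = None
    density: float = float("nan")
    free_energy_rel: float = float("nan")
    sigma: float = float("nan")
    fvib_explicit: bool = False
    rank: int = 0
    match_label: Optional[str] = None
    disordered: bool = False


@dataclass(frozen=True)
class ShiftEstimate:
    """Uniform vibrational shift: mean and spread of the explicit F_vib values."""

    mean_fvib: float
    sd_fvib: float
    n_explicit: int


def estimate_fvib_shift(entries: Sequence[LandscapeEntry]) -> ShiftEstimate:
    """Mean and sample standard deviation (n−1) of the explicit F_vib values."""
    fvibs = [e.fvib for e in entries if e.fvib is not None]
    if len(fvibs) < 2:
        raise ValueError(
            f"need at least 2 entries with explicit fvib, got {len(fvibs)}"
        )
    arr = np.asarray(fvibs)
    return ShiftEstimate(
        mean_fvib=float(arr.mean()),
        sd_fvib=float(arr.std(ddof=1)),
        n_explicit=len(fvibs),
    )


def assemble_landscape(
    entries: Sequence[LandscapeEntry],
    T: float = DEFAULT_TEMPERATURE,
    sigma_base: float = DEFAULT_SIGMA_BASE,
) -> list:
    """Combine energies, apply the uniform shift, attach error bars, rank.

    Returns new entries sorted by relative free energy (the global minimum
    at 0), with ties broken by higher density then id.  ``T`` is carried for
    reporting; the energies themselves are inputs already evaluated at T.
    """
    if not entries:
        raise ValueError("no landscape entries")
    if sigma_base < 0:
        raise ValueError("sigma_base must be non-negative")
    has_missing = any(e.fvib is None for e in entries)
    shift = estimate_fvib_shift(entries) if has_missing else None

    absolute = []
    for e in entries:
        if e.fvib is not None:
            F = e.elatt + e.fvib
            sigma = sigma_base
            explicit = True
        else:
            F = e.elatt + shift.mean_fvib
            sigma = math.hypot(sigma_base, shift.sd_fvib)
            explicit = False
        absolute.append((e, F, sigma, explicit))

    fmin = min(F for _, F, _, _ in absolute)
    keyed = sorted(
        absolute,
        key=lambda t: (t[1] - fmin, -(t[0].density if math.isfinite(t[0].density) else 0.0), t[0].id),
    )
    out = []
    for i, (e, F, sigma, explicit) in enumerate(keyed):
        out.append(
            replace(
                e,
                free_energy_rel=F - fmin,
                sigma=sigma,
                fvib_explicit=explicit,
                rank=i + 1,
            )
        )
    return out


def attach_match_labels(
    entries: Sequence[LandscapeEntry],
    experimental_patterns: Mapping[str, "object"],
    structures: Mapping[str, "object"],
    sim_params: SimilarityParams = SimilarityParams(),
    **pattern_kwargs,
) -> list:
    """Label the best-scoring candidate for each named experimental pattern.

    ``experimental_patterns`` maps a form name to a :class:`PowderPattern`;
    ``structures`` maps entry ids to :class:`CrystalStructure`.  Each
    pattern's best-scoring candidate receives the form name as its
    ``match_label``; a candidate matched by several patterns keeps all
    labels (comma-joined) with a warning.
    """
    if not experimental_patterns:
        return list(entries)
    labels: dict = {}
    for form_name in sorted(experimental_patterns):
        pattern = experimental_patterns[form_name]
        results = rank_candidates(pattern, structures, sim_params, **pattern_kwargs)
        best = results[0].candidate_id
        if best in labels:
            warnings.warn(
                f"candidate {best!r} is the best match for multiple patterns "
                f"({labels[best]} and {form_name})",
                stacklevel=2,
            )
            labels[best] = f"{labels[best]},{form_name}"
        else:
            labels[best] = form_name
    return [
        replace(e, match_label=labels[e.id]) if e.id in labels else e for e in entries
    ]


# ----------------------------------------------------------------------------
# tabular I/O


_COLUMNS = [
    "id",
    "spacegroup",
    "density",
    "free_energy_rel",
    "sigma",
    "fvib_explicit",
    "rank",
    "match_label",
]


def landscape_table(entries: Sequence[LandscapeEntry]) -> pd.DataFrame:
    """Assembled landscape as a DataFrame sorted by rank."""
    rows = [
        {
            "id": e.id,
            "spacegroup": e.spacegroup,
            "density": e.density,
            "free_energy_rel": e.free_energy_rel,
            "sigma": e.sigma,
            "fvib_explicit": e.fvib_explicit,
            "rank": e.rank,
            "match_label": e.match_label if e.match_label else "",
        }
        for e in sorted(entries, key=lambda e: e.rank)
    ]
    return pd.DataFrame(rows, columns=_COLUMNS)


def write_landscape_csv(entries: Sequence[LandscapeEntry], path) -> None:
    landscape_table(entries).to_csv(path, index=False)


def read_landscape_csv(path) -> list:
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    out = []
    for _, row in df.iterrows():
        out.append(
            LandscapeEntry(
                id=str(row["id"]),
                elatt=float("nan"),
                spacegroup=str(row["spacegroup"]),
                density=float(row["density"]),
                free_energy_rel=float(row["free_energy_rel"]),
                sigma=float(row["sigma"]),
                fvib_explicit=str(row["fvib_explicit"]).strip().lower() in ("true", "1"),
                rank=int(row["rank"]),
                match_label=(str(row["match_label"]) or None)
                if not pd.isna(row["match_label"])
                else None,
            )
        )
    return out


def read_energy_table(path_or_buf) -> list:
    """Read an input energy table (CSV) into unassembled entries.

    Expected columns: ``id``, ``elatt_kjmol`` (required), ``spacegroup``,
    ``fvib_kjmol`` (blank = not explicitly computed), ``density``.
    """
    df = pd.read_csv(path_or_buf)
    if "id" not in df.columns or "elatt_kjmol" not in df.columns:
        raise ValueError("energy table needs 'id' and 'elatt_kjmol' columns")
    out = []
    for _, row in df.iterrows():
        fvib = row.get("fvib_kjmol")
        fvib = None if fvib is None or pd.isna(fvib) else float(fvib)
        density = row.get("density", float("nan"))
        density = float(density) if not pd.isna(density) else float("nan")
        out.append(
            LandscapeEntry(
                id=str(row["id"]),
                elatt=float(row["elatt_kjmol"]),
                spacegroup=str(row.get("spacegroup", "?")),
                fvib=fvib,
                density=density,
            )
        )
    return out


def plot_landscape(entries: Sequence[LandscapeEntry], path=None):
    """Free energy (relative to the global minimum) vs density scatter plot."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    dens = [e.density for e in entries]
    frel = [e.free_energy_rel for e in entries]
    sig = [e.sigma for e in entries]
    ax.errorbar(dens, frel, yerr=sig, fmt="o", ms=4, capsize=2, lw=0.8, alpha=0.8)
    for e in entries:
        if e.match_label:
            ax.annotate(e.match_label, (e.density, e.free_energy_rel), fontsize=8,
                        xytext=(3, 3), textcoords="offset points")
    ax.set_xlabel("density / g cm$^{-3}$")
    ax.set_ylabel("relative free energy / kJ mol$^{-1}$")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
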