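"""Synthetic study-condition generators.

Everything downstream of a crystal structure prediction run — the candidate
energy tables, the experimental powder pattern to be matched, the
per-fragment disorder energetics — is expensive to produce for real
(quantum-mechanical energies, digitized experimental data).  These
generators emulate those inputs at desk scale:

* toy molecular crystals in common chiral space groups (P1, P2₁, C2,
  P2₁2₁2₁) with random cells and a handful of light-atom sites;
* candidate landscapes of ~10–50 structures with a global minimum,
  exponential energy spacing above it, a subset carrying explicit
  vibrational terms, and Gaussian energy noise of stated σ;
* noisy powder patterns with a polynomial background, a zero-point 2θ
  shift, and multiplicative (Poisson-like) intensity noise;
* disorder ensembles of 2–3 configurations per site.

All generators are pure functions of (seed, parameters); a single root seed
fans out to fixed substreams so that adding one fixture never perturbs
another.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np

from .crystal_io import AtomSite, CrystalStructure, SymmetryOp, UnitCell
from .disorder import DisorderSiteModel
from .landscape import LandscapeEntry
from .xrpd import PowderPattern, simulate_pattern

__all__ = [
    "SyntheticTruth",
    "make_toy_structure",
    "make_candidate_landscape",
    "make_noisy_pattern",
    "make_disorder_ensemble",
]

_ELEMENTS = ("C", "N", "O", "S")

_SPACEGROUP_OPS = {
    "P1": ["x,y,z"],
    "P21": ["x,y,z", "-x,y+1/2,-z"],
    "C2": ["x,y,z", "-x,y,-z", "x+1/2,y+1/2,z", "-x+1/2,y+1/2,-z"],
    "P212121": [
        "x,y,z",
        "-x+1/2,-y,z+1/2",
        "-x,y+1/2,-z+1/2",
        "x+1/2,-y+1/2,-z",
    ],
}


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth behind a generated study, serializable next to outputs."""

    seed: int
    true_free_energies: tuple = ()
    noise_sigma: float = 0.0
    true_target_id: str = ""
    pattern_noise: float = 0.0
    background_coeffs: tuple = ()
    zero_shift: float = 0.0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _rng(seed: int, stream: int) -> np.random.Generator:
    # counter-based substreams: the pair (seed, stream) seeds independently
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, int(stream)])


def make_toy_structure(
    seed: int,
    spacegroup: str = "P21",
    n_atoms: int = 5,
) -> CrystalStructure:
    """A random toy molecular crystal in a common chiral space group.

    Cell edges are drawn in 4–30 Å and free angles in 80–120° (constrained
    to the crystal system); atoms are light elements at random general
    positions.  Deterministic for a fixed (seed, spacegroup, n_atoms).
    """
    if spacegroup not in _SPACEGROUP_OPS:
        raise ValueError(f"unsupported space group {spacegroup!r}; "
                         f"choose from {sorted(_SPACEGROUP_OPS)}")
    if not 1 <= n_atoms <= 20:
        raise ValueError("n_atoms must be in 1..20")
    rng = _rng(seed, 1)
    a, b, c = rng.uniform(4.0, 30.0, size=3)
    if spacegroup == "P1":
        alpha, beta, gamma = rng.uniform(80.0, 120.0, size=3)
    elif spacegroup in ("P21", "C2"):
        alpha, gamma = 90.0, 90.0
        beta = rng.uniform(80.0, 120.0)
    else:  # orthorhombic
        alpha = beta = gamma = 90.0
    cell = UnitCell(a, b, c, alpha, beta, gamma)
    ops = [SymmetryOp.from_xyz(t) for t in _SPACEGROUP_OPS[spacegroup]]

    sites = []
    for i in range(n_atoms):
        el = _ELEMENTS[rng.integers(0, len(_ELEMENTS))]
        # keep away from cell edges so random sites never sit on special positions
        xyz = tuple(rng.uniform(0.05, 0.45, size=3))
        sites.append(AtomSite(label=f"{el}{i + 1}", element=el, frac_xyz=xyz))
    return CrystalStructure(
        cell=cell,
        spacegroup=spacegroup,
        ops=ops,
        sites=sites,
        name=f"toy_{spacegroup}_{seed}",
    )


def make_candidate_landscape(
    seed: int,
    n_candidates: int = 20,
    spacing_scale: float = 2.0,
    n_explicit_fvib: int = 5,
    noise_sigma: float = 0.0,
    fvib_mean: float = -3.0,
):
    """Candidate energy table with ground truth.

    True relative free energies follow an exponential-spacing model above a
    global minimum at 0 (scale ``spacing_scale`` kJ/mol), qualitatively
    matching the dense-above-minimum shape of predicted landscapes.  The
    observed lattice energies carry Gaussian noise of ``noise_sigma``;
    per-candidate vibrational terms scatter around ``fvib_mean`` with the
    same σ and are reported only for the ``n_explicit_fvib`` lowest-energy
    candidates.  With ``noise_sigma = 0`` the assembled landscape reproduces
    the true ranking exactly.

    Returns ``(entries, truth)``: unassembled :class:`LandscapeEntry` rows
    and the :class:`SyntheticTruth` that generated them.
    """
    if n_candidates < 2:
        raise ValueError("need at least 2 candidates")
    if n_explicit_fvib < 2 or n_explicit_fvib > n_candidates:
        raise ValueError("need 2 <= n_explicit_fvib <= n_candidates")
    rng = _rng(seed, 2)
    gaps = rng.exponential(scale=spacing_scale, size=n_candidates - 1)
    true_f = np.concatenate([[0.0], np.cumsum(gaps)])

    fvib_true = fvib_mean + (rng.normal(0.0, noise_sigma, n_candidates)
                             if noise_sigma > 0 else np.zeros(n_candidates))
    elatt_true = true_f - fvib_true
    elatt_obs = elatt_true + (rng.normal(0.0, noise_sigma, n_candidates)
                              if noise_sigma > 0 else 0.0)
    density = rng.uniform(1.10, 1.40, n_candidates)
    sgs = rng.choice(list(_SPACEGROUP_OPS), n_candidates)

    entries = []
    for i in range(n_candidates):
        entries.append(
            LandscapeEntry(
                id=f"cand_{i + 1:03d}",
                elatt=float(elatt_obs[i]),
                spacegroup=str(sgs[i]),
                fvib=float(fvib_true[i]) if i < n_explicit_fvib else None,
                density=float(density[i]),
            )
        )
    truth = SyntheticTruth(
        seed=seed,
        true_free_energies=tuple(float(f) for f in true_f),
        noise_sigma=noise_sigma,
    )
    return entries, truth


def make_noisy_pattern(
    structure: CrystalStructure,
    seed: int,
    noise_level: float = 0.05,
    background_coeffs: Sequence[float] = (),
    zero_shift: float = 0.0,
    **pattern_kwargs,
) -> PowderPattern:
    """An 'experimental' pattern: simulation + shift + background + noise.

    The clean simulated pattern is displaced by ``zero_shift`` degrees 2θ,
    a polynomial background (coefficients in ascending powers of 2θ, on the
    max-100 intensity scale) is added, and multiplicative Gaussian noise of
    fractional level ``noise_level`` is applied; negatives are clipped.
    Deterministic for fixed (structure, seed, parameters).
    """
    clean = simulate_pattern(structure, **pattern_kwargs)
    rng = _rng(seed, 3)
    grid = clean.two_theta
    # zero-point displacement: the whole pattern slides by zero_shift
    y = np.interp(grid - zero_shift, grid, clean.intensity, left=0.0, right=0.0)
    if len(background_coeffs):
        y = y + np.polynomial.polynomial.polyval(grid, np.asarray(background_coeffs))
    if noise_level > 0:
        y = y * (1.0 + rng.normal(0.0, noise_level, size=len(y)))
    return PowderPattern(grid, np.clip(y, 0.0, None), clean.wavelength)


def make_disorder_ensemble(
    seed: int,
    n_sites: int = 1,
    gap_scale: float = 2.0,
) -> list:
    """Independent disorder sites with 2–3 configurations each.

    Each site's lowest configuration sits at 0 kJ/mol and the others at gaps
    drawn uniformly in [0, gap_scale]; all degeneracies are 1.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = _rng(seed, 4)
    sites = []
    for i in range(n_sites):
        n_cfg = int(rng.integers(2, 4))
        energies = (0.0,) + tuple(float(g) for g in rng.uniform(0.0, gap_scale, n_cfg - 1))
        sites.append(DisorderSiteModel(site_id=f"site_{i + 1}", config_free_energies=energies))
    return sites
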