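"""Kinematic powder X-ray diffraction simulation.

Given a crystal structure, enumerate the Bragg reflections inside the
d-spacing sphere of the requested 2θ window, compute |F|² from tabulated
Cromer–Mann form factors, apply the Lorentz–polarization correction, and
convolve the resulting stick pattern with a pseudo-Voigt profile.

The simulation is intentionally minimal — no Kα₂ doublet, no preferred
orientation, no instrument geometry beyond LP — because its consumer is a
cross-correlation similarity score dominated by peak *positions*, not a
Rietveld fit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .crystal_io import CrystalStructure, UnitCell, expand_symmetry
from .errors import PolyriskError

__all__ = [
    "Reflection",
    "PowderPattern",
    "d_spacing",
    "bragg_two_theta",
    "structure_factor_sq",
    "simulate_pattern",
    "CU_KALPHA1",
]

#: Cu Kα₁ wavelength in Å (typical laboratory source)
CU_KALPHA1 = 1.5406

#: 2θ coincidence tolerance (degrees) for merging equivalent reflections
TWO_THETA_MERGE_TOL = 1e-4


@dataclass(frozen=True)
class Reflection:
    hkl: tuple
    d: float
    two_theta: float
    multiplicity: int
    f2: float
    intensity: float


@dataclass
class PowderPattern:
    """A powder diffractogram: intensity sampled on a strictly increasing 2θ grid."""

    two_theta: np.ndarray
    intensity: np.ndarray
    wavelength: float = CU_KALPHA1
    reflections: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        self.two_theta = np.asarray(self.two_theta, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.two_theta.shape != self.intensity.shape or self.two_theta.ndim != 1:
            raise ValueError("two_theta and intensity must be 1-D arrays of equal length")
        if len(self.two_theta) >= 2 and not np.all(np.diff(self.two_theta) > 0):
            raise ValueError("two_theta grid must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)) or np.any(self.intensity < 0):
            raise ValueError("intensities must be finite and non-negative")

    def write_xy(self, path) -> None:
        header = f"# wavelength={self.wavelength}\n# two_theta intensity\n"
        body = "\n".join(
            f"{t:.6f} {i:.8g}" for t, i in zip(self.two_theta, self.intensity)
        )
        with open(path, "w") as fh:
            fh.write(header + body + "\n")

    @classmethod
    def read_xy(cls, path) -> "PowderPattern":
        wavelength = CU_KALPHA1
        tt, inten = [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    if "wavelength=" in line:
                        wavelength = float(line.split("wavelength=")[1].split()[0])
                    continue
                a, b = line.split()[:2]
                tt.append(float(a))
                inten.append(float(b))
        return cls(np.array(tt), np.clip(np.array(inten), 0, None), wavelength)


# ----------------------------------------------------------------------------
# geometry


def d_spacing(cell: UnitCell, hkl) -> float:
    """Interplanar spacing d(hkl) in Å via the reciprocal metric tensor."""
    h = np.asarray(hkl, dtype=float)
    if not np.any(h):
        raise ValueError("hkl must not be (0, 0, 0)")
    inv_d2 = float(h @ cell.reciprocal_metric() @ h)
    return 1.0 / math.sqrt(inv_d2)


def bragg_two_theta(d: float, wavelength: float = CU_KALPHA1):
    """Diffraction angle 2θ in degrees, or ``None`` if the reflection is
    outside the Ewald sphere (λ/2d > 1)."""
    if d <= 0 or wavelength <= 0:
        raise ValueError("d and wavelength must be positive")
    x = wavelength / (2.0 * d)
    if x > 1.0:
        return None
    return 2.0 * math.degrees(math.asin(x))


# ----------------------------------------------------------------------------
# structure factors


def _form_factors(elements, stol2: np.ndarray, model: str = "it92") -> np.ndarray:
    """f(sinθ/λ) per element (rows) on an array of (sinθ/λ)² values (cols)."""
    out = np.empty((len(elements), len(stol2)))
    for i, el in enumerate(elements):
        g = gemmi.Element(el)
        if g.atomic_number == 0:
            raise ValueError(f"no scattering data for element {el!r}")
        if model == "it92":
            coef = g.it92
            if coef is None:
                # fall back to a constant equal to the atomic number
                out[i] = float(g.atomic_number)
            else:
                a = np.asarray(coef.a)
                b = np.asarray(coef.b)
                out[i] = np.exp(-np.outer(stol2, b)) @ a + coef.c
        elif model == "z":
            out[i] = float(g.atomic_number)
        else:
            raise ValueError(f"unknown form-factor model {model!r}")
    return out


def structure_factor_sq(expanded_sites, hkl, stol2: float = 0.0, model: str = "it92") -> float:
    """|F(hkl)|² for a fully expanded unit cell.

    F = Σⱼ oⱼ·fⱼ(sinθ/λ)·exp(2πi·hkl·xⱼ).  ``stol2`` is (sinθ/λ)² = 1/(4d²).
    ``model`` selects 4-term Cromer–Mann coefficients (``"it92"``) or a
    constant equal to the atomic number (``"z"``).
    """
    f2 = _structure_factors_bulk(expanded_sites, np.asarray([hkl]), np.asarray([stol2]), model)
    return float(f2[0])


def _structure_factors_bulk(expanded_sites, hkls: np.ndarray, stol2: np.ndarray, model: str) -> np.ndarray:
    """|F|² for many reflections at once (hkls: (n,3), stol2: (n,))."""
    if len(expanded_sites) == 0:
        return np.zeros(len(hkls))
    xyz = np.array([s.frac_xyz for s in expanded_sites])  # (m, 3)
    occ = np.array([s.occupancy for s in expanded_sites])  # (m,)
    elements = sorted({s.element for s in expanded_sites})
    f_table = _form_factors(elements, stol2, model)  # (e, n)
    el_index = np.array([elements.index(s.element) for s in expanded_sites])
    phase = np.exp(2j * np.pi * (hkls @ xyz.T))  # (n, m)
    F = np.zeros(len(hkls), dtype=complex)
    for e in range(len(elements)):
        mask = el_index == e
        F += f_table[e] * (phase[:, mask] @ occ[mask])
    return np.abs(F) ** 2


# ----------------------------------------------------------------------------
# full pattern


def _lp_factor(two_theta_deg: np.ndarray) -> np.ndarray:
    """Lorentz–polarization factor (1+cos²2θ)/(sin²θ·cosθ)."""
    tt = np.radians(two_theta_deg)
    th = tt / 2.0
    return (1.0 + np.cos(tt) ** 2) / (np.sin(th) ** 2 * np.cos(th))


def _pseudo_voigt(x: np.ndarray, fwhm: float, eta: float) -> np.ndarray:
    """Area-normalized pseudo-Voigt profile η·L + (1−η)·G."""
    gl = x / fwhm
    gauss = 2.0 * math.sqrt(math.log(2.0) / math.pi) / fwhm * np.exp(-4.0 * math.log(2.0) * gl**2)
    lorentz = (2.0 / (math.pi * fwhm)) / (1.0 + 4.0 * gl**2)
    return eta * lorentz + (1.0 - eta) * gauss


def enumerate_reflections(
    structure: CrystalStructure,
    wavelength: float = CU_KALPHA1,
    two_theta_range=(3.0, 40.0),
    model: str = "it92",
) -> list:
    """All merged reflections of ``structure`` inside the 2θ window.

    Friedel mates and symmetry equivalents are merged by 2θ coincidence
    (tolerance 1e-4°), accumulating multiplicity; the merged intensity is
    multiplicity × LP × mean |F|².
    """
    tt_lo, tt_hi = two_theta_range
    if not 0.0 < tt_lo < tt_hi <= 90.0:
        raise ValueError("two_theta_range must satisfy 0 < lo < hi <= 90")
    d_min = wavelength / (2.0 * math.sin(math.radians(tt_hi / 2.0)))
    d_max = wavelength / (2.0 * math.sin(math.radians(tt_lo / 2.0)))

    cell = structure.cell
    hmax = int(cell.a / d_min)
    kmax = int(cell.b / d_min)
    lmax = int(cell.c / d_min)
    h, k, l = np.meshgrid(
        np.arange(-hmax, hmax + 1),
        np.arange(-kmax, kmax + 1),
        np.arange(-lmax, lmax + 1),
        indexing="ij",
    )
    hkls = np.column_stack([h.ravel(), k.ravel(), l.ravel()])
    hkls = hkls[np.any(hkls != 0, axis=1)]

    Gstar = cell.reciprocal_metric()
    inv_d2 = np.einsum("ni,ij,nj->n", hkls, Gstar, hkls)
    d = 1.0 / np.sqrt(inv_d2)
    sel = (d >= d_min) & (d <= d_max * 1.0000001)
    hkls, d = hkls[sel], d[sel]
    sin_th = wavelength / (2.0 * d)
    sel = sin_th <= 1.0
    hkls, d, sin_th = hkls[sel], d[sel], sin_th[sel]
    two_theta = 2.0 * np.degrees(np.arcsin(sin_th))
    sel = (two_theta >= tt_lo) & (two_theta <= tt_hi)
    hkls, d, two_theta = hkls[sel], d[sel], two_theta[sel]
    if len(hkls) == 0:
        return []

    sites = expand_symmetry(structure)
    stol2 = 1.0 / (4.0 * d**2)
    f2 = _structure_factors_bulk(sites, hkls.astype(float), stol2, model)
    lp = _lp_factor(two_theta)

    order = np.argsort(two_theta, kind="stable")
    reflections = []
    i = 0
    tt, dd, ff, lplp, hh = two_theta[order], d[order], f2[order], lp[order], hkls[order]
    while i < len(tt):
        j = i + 1
        while j < len(tt) and tt[j] - tt[j - 1] <= TWO_THETA_MERGE_TOL:
            j += 1
        mult = j - i
        mean_f2 = float(np.mean(ff[i:j]))
        intensity = float(np.sum(lplp[i:j] * ff[i:j]))
        reflections.append(
            Reflection(
                hkl=tuple(int(v) for v in hh[i]),
                d=float(np.mean(dd[i:j])),
                two_theta=float(np.mean(tt[i:j])),
                multiplicity=mult,
                f2=mean_f2,
                intensity=intensity,
            )
        )
        i = j
    return reflections


def simulate_pattern(
    structure: CrystalStructure,
    wavelength: float = CU_KALPHA1,
    two_theta_range=(3.0, 40.0),
    step: float = 0.02,
    fwhm: float = 0.1,
    eta: float = 0.5,
    model: str = "it92",
) -> PowderPattern:
    """Simulate a powder pattern, normalized to a maximum intensity of 100.

    Parameters follow typical laboratory conditions: Cu Kα₁, 3–40° 2θ at
    0.02° steps, 0.1° FWHM pseudo-Voigt peaks with mixing ``eta`` (0 = pure
    Gaussian, 1 = pure Lorentzian).
    """
    if step <= 0 or fwhm <= 0 or not 0.0 <= eta <= 1.0:
        raise ValueError("require step > 0, fwhm > 0, 0 <= eta <= 1")
    tt_lo, tt_hi = two_theta_range
    grid = np.arange(tt_lo, tt_hi + step / 2.0, step)
    reflections = enumerate_reflections(structure, wavelength, two_theta_range, model)

    y = np.zeros_like(grid)
    for refl in reflections:
        if refl.intensity > 0:
            y += refl.intensity * _pseudo_voigt(grid - refl.two_theta, fwhm, eta)
    peak = y.max() if len(y) else 0.0
    if peak <= 0:
        warnings.warn(
            f"structure {structure.name!r} has no observable reflection in "
            f"{two_theta_range}; returning a flat zero pattern",
            stacklevel=2,
        )
    else:
        y = y * (100.0 / peak)
    return PowderPattern(grid, y, wavelength, reflections=reflections)
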