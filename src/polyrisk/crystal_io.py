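"""Crystal structures: CIF input/output, symmetry expansion, volume and density.

The in-memory model is deliberately small: a unit cell, a list of symmetry
operations, and the asymmetric-unit atom sites with occupancies.  CIF syntax
handling is delegated to :mod:`gemmi`; this module owns the domain model and
the crystallographic arithmetic (triclinic volume, density, symmetry
expansion with periodic merging of special positions).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Optional, Sequence

import gemmi
import numpy as np

from .constants import AVOGADRO, atomic_weight
from .errors import CIFParseError, InvalidCellError

__all__ = [
    "UnitCell",
    "SymmetryOp",
    "AtomSite",
    "CrystalStructure",
    "parse_cif",
    "write_cif",
    "cell_volume",
    "crystal_density",
    "expand_symmetry",
    "parse_formula",
    "formula_weight",
]

#: fractional-coordinate distance below which symmetry images are merged
MERGE_TOL = 0.01


@dataclass(frozen=True)
class UnitCell:
    """Unit-cell parameters: lengths in Å, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise InvalidCellError(f"cell edges must be positive: {self}")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise InvalidCellError(f"cell angles must lie in (0, 180): {self}")
        if self._discriminant() <= 0:
            raise InvalidCellError(f"cell angles are geometrically inconsistent: {self}")

    def _discriminant(self) -> float:
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        return 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg

    def lattice_matrix(self) -> np.ndarray:
        """3×3 matrix with rows = lattice vectors a, b, c in Cartesian Å.

        Convention: **a** along x, **b** in the xy plane.
        """
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = math.sin(math.radians(self.gamma))
        v = self.a * self.b * self.c * math.sqrt(self._discriminant())
        return np.array(
            [
                [self.a, 0.0, 0.0],
                [self.b * cg, self.b * sg, 0.0],
                [self.c * cb, self.c * (ca - cb * cg) / sg, v / (self.a * self.b * sg)],
            ]
        )

    def reciprocal_metric(self) -> np.ndarray:
        """Reciprocal metric tensor G* (Å⁻²), so that 1/d² = h·G*·h."""
        A = self.lattice_matrix()
        return np.linalg.inv(A @ A.T)


@dataclass(frozen=True)
class SymmetryOp:
    """Space-group operation x' = R·x + t with integer R and rational t."""

    rotation: tuple  # 3×3 nested tuple of ints
    translation: tuple  # 3-tuple of Fraction, reduced mod 1

    def __post_init__(self):
        det = round(float(np.linalg.det(np.array(self.rotation, dtype=float))))
        if det not in (1, -1):
            raise ValueError(f"rotation determinant must be ±1, got {det}")
        object.__setattr__(
            self, "translation", tuple(Fraction(t) % 1 for t in self.translation)
        )

    @classmethod
    def from_xyz(cls, triplet: str) -> "SymmetryOp":
        """Parse an operator triplet such as ``-x, y+1/2, -z``."""
        try:
            op = gemmi.Op(triplet.strip().lower())
        except Exception as exc:
            raise CIFParseError(f"malformed symmetry operator: {triplet!r}") from exc
        den = gemmi.Op.DEN
        rot = tuple(tuple(v // den for v in row) for row in op.rot)
        if any(v % den for row in op.rot for v in row):
            raise CIFParseError(f"non-integer rotation in operator: {triplet!r}")
        tran = tuple(Fraction(t, den) for t in op.tran)
        return cls(rot, tran)

    def to_xyz(self) -> str:
        den = gemmi.Op.DEN
        op = gemmi.Op()
        op.rot = [[int(v) * den for v in row] for row in self.rotation]
        op.tran = [int(t * den) for t in self.translation]
        return op.triplet()

    def apply(self, frac_xyz: Sequence[float]) -> np.ndarray:
        R = np.asarray(self.rotation, dtype=float)
        t = np.array([float(x) for x in self.translation])
        return R @ np.asarray(frac_xyz, dtype=float) + t


IDENTITY_OP = SymmetryOp(((1, 0, 0), (0, 1, 0), (0, 0, 1)), (Fraction(0),) * 3)


@dataclass(frozen=True)
class AtomSite:
    """One asymmetric-unit atom site in fractional coordinates."""

    label: str
    element: str
    frac_xyz: tuple
    occupancy: float = 1.0
    disorder_group: Optional[str] = None

    def __post_init__(self):
        if not 0.0 < self.occupancy <= 1.0:
            raise ValueError(f"occupancy must be in (0, 1]: {self.label} {self.occupancy}")
        xyz = tuple(float(v) for v in self.frac_xyz)
        if not all(math.isfinite(v) for v in xyz):
            raise ValueError(f"non-finite coordinates for site {self.label}")
        object.__setattr__(self, "frac_xyz", xyz)


@dataclass
class CrystalStructure:
    """A crystal: cell, space-group symmetry, asymmetric-unit sites."""

    cell: UnitCell
    spacegroup: str = "P 1"
    ops: list = field(default_factory=lambda: [IDENTITY_OP])
    sites: list = field(default_factory=list)
    z_formula: Optional[int] = None
    formula: Optional[str] = None
    name: str = "crystal"

    def __post_init__(self):
        if not self.ops:
            raise ValueError("structure needs at least one symmetry operation")
        if self.z_formula is None:
            # Z' = 1 convention: one formula unit per asymmetric unit
            self.z_formula = len(self.ops)
        self._check_disorder_occupancies()

    def _check_disorder_occupancies(self):
        # sites sharing a disorder_group are alternative positions of the
        # same fragment, so their occupancies must close to 1
        sums: dict = {}
        for s in self.sites:
            if s.disorder_group is not None:
                sums[s.disorder_group] = sums.get(s.disorder_group, 0.0) + s.occupancy
        for grp, total in sums.items():
            if abs(total - 1.0) > 0.01:
                raise ValueError(
                    f"occupancies of disorder group {grp!r} sum to {total:.3f}, not 1"
                )

    @property
    def n_ops(self) -> int:
        return len(self.ops)


# ----------------------------------------------------------------------------
# chemical formulas


_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


def parse_formula(formula: str) -> dict:
    """Parse ``'C37 H48 N6 O5 S2'`` (spaces optional) into {element: count}."""
    counts: dict = {}
    for sym, num in _FORMULA_RE.findall(formula.replace(" ", "")):
        counts[sym] = counts.get(sym, 0.0) + (float(num) if num else 1.0)
    if not counts:
        raise ValueError(f"cannot parse chemical formula: {formula!r}")
    return counts


def formula_weight(formula: str) -> float:
    """Molar mass in g/mol of a chemical formula string."""
    return sum(atomic_weight(el) * n for el, n in parse_formula(formula).items())


# ----------------------------------------------------------------------------
# cell arithmetic


def cell_volume(cell: UnitCell) -> float:
    """Unit-cell volume in ų.

    Uses the general triclinic expression
    V = abc·√(1 − cos²α − cos²β − cos²γ + 2·cosα·cosβ·cosγ),
    which reduces to abc·sinβ for monoclinic cells.
    """
    disc = cell._discriminant()
    if disc <= 0:
        raise InvalidCellError(f"non-positive volume discriminant for {cell}")
    return cell.a * cell.b * cell.c * math.sqrt(disc)


def crystal_density(structure: CrystalStructure, molar_mass: Optional[float] = None) -> float:
    """Crystallographic density ρ = Z·M / (N_A·V) in g/cm³.

    The molar mass is taken (in order of preference) from the ``molar_mass``
    argument, the structure's declared chemical formula, or the occupancy-
    weighted mass of the asymmetric-unit site list.  Using the declared
    formula is more robust when hydrogen sites are missing from the model.
    """
    V = cell_volume(structure.cell)
    if V <= 0:
        raise InvalidCellError("zero cell volume")
    if molar_mass is None:
        if structure.formula:
            molar_mass = formula_weight(structure.formula)
        elif structure.sites:
            molar_mass = sum(s.occupancy * atomic_weight(s.element) for s in structure.sites)
        else:
            raise ValueError("no molar mass, formula, or sites to compute density from")
    if molar_mass <= 0:
        raise ValueError("molar mass must be positive")
    Z = structure.z_formula
    # V in ų = 1e-24 cm³
    return Z * molar_mass / (AVOGADRO * V * 1e-24)


# ----------------------------------------------------------------------------
# symmetry expansion


def _wrap01(x: np.ndarray) -> np.ndarray:
    return x - np.floor(x)


def expand_symmetry(structure: CrystalStructure, merge_tol: float = MERGE_TOL) -> list:
    """Map every asymmetric-unit site by every operation into one unit cell.

    Coordinates are wrapped into [0, 1).  Images of the *same* source site
    that land within ``merge_tol`` fractional distance (minimum-image) are
    merged, keeping one copy — this collapses special positions.
    """
    expanded: list = []
    for site in structure.sites:
        images: list = []
        for op in structure.ops:
            xyz = _wrap01(op.apply(site.frac_xyz))
            dup = False
            for prev in images:
                d = np.abs(xyz - prev)
                d = np.minimum(d, 1.0 - d)
                if float(np.max(d)) < merge_tol:
                    dup = True
                    break
            if not dup:
                images.append(xyz)
        for k, xyz in enumerate(images):
            expanded.append(replace(site, label=f"{site.label}_{k}", frac_xyz=tuple(xyz)))
    return expanded


# ----------------------------------------------------------------------------
# CIF reading / writing

_CELL_TAGS = {
    "a": "_cell_length_a",
    "b": "_cell_length_b",
    "c": "_cell_length_c",
    "alpha": "_cell_angle_alpha",
    "beta": "_cell_angle_beta",
    "gamma": "_cell_angle_gamma",
}

_SYMOP_LOOPS = ("_space_group_symop_operation_xyz", "_symmetry_equiv_pos_as_xyz")
_SG_TAGS = (
    "_space_group_name_H-M_alt",
    "_symmetry_space_group_name_H-M",
    "_space_group_name_Hall",
)

#: built-in symbol table covering the common chiral pharmaceutical groups;
#: any other Hermann–Mauguin symbol is resolved through gemmi's full table.
_COMMON_GROUPS = {"P1", "P21", "C2", "P212121", "P21212", "P-1", "P2", "C2221"}


def _sg_ops_from_symbol(symbol: str) -> list:
    sg = gemmi.find_spacegroup_by_name(symbol)
    if sg is None:
        raise CIFParseError(f"unknown space-group symbol: {symbol!r}")
    return [SymmetryOp.from_xyz(op.triplet()) for op in sg.operations()]


def parse_cif(text: str) -> CrystalStructure:
    """Parse a CIF 1.1 document (core subset) into a :class:`CrystalStructure`.

    Accepts both ``_symmetry_equiv_pos_as_xyz`` and
    ``_space_group_symop_operation_xyz`` operator loops; falls back to the
    Hermann–Mauguin symbol when no operator loop is present.  Occupancy
    defaults to 1 when the tag is absent.
    """
    try:
        doc = gemmi.cif.read_string(text)
        block = doc.sole_block()
    except Exception as exc:
        raise CIFParseError(f"not a parseable CIF document: {exc}") from exc

    cell_kwargs = {}
    for attr, tag in _CELL_TAGS.items():
        raw = block.find_value(tag)
        if raw is None:
            if attr in ("a", "b", "c"):
                raise CIFParseError(f"missing required cell tag {tag}")
            continue  # angles default to 90
        cell_kwargs[attr] = gemmi.cif.as_number(raw)
    cell = UnitCell(**cell_kwargs)

    ops: list = []
    for tag in _SYMOP_LOOPS:
        col = block.find_loop(tag)
        triplets = [gemmi.cif.as_string(v) for v in col]
        if triplets:
            ops = [SymmetryOp.from_xyz(t) for t in triplets]
            break
    symbol = None
    for tag in _SG_TAGS:
        raw = block.find_value(tag)
        if raw is not None:
            symbol = gemmi.cif.as_string(raw).strip()
            break
    if not ops:
        if symbol is None:
            raise CIFParseError(
                "missing symmetry: no operator loop "
                f"({' or '.join(_SYMOP_LOOPS)}) and no space-group symbol tag"
            )
        ops = _sg_ops_from_symbol(symbol)
    if symbol is None:
        symbol = "P 1" if len(ops) == 1 else "?"

    labels = list(block.find_loop("_atom_site_label"))
    if not labels:
        raise CIFParseError("missing required loop _atom_site_label")

    def _col(tag, cast, default=None):
        vals = list(block.find_loop(tag))
        if not vals:
            if default is None:
                raise CIFParseError(f"missing required loop tag {tag}")
            return [default] * len(labels)
        return [cast(v) if v not in (".", "?") else default for v in vals]

    fx = _col("_atom_site_fract_x", gemmi.cif.as_number)
    fy = _col("_atom_site_fract_y", gemmi.cif.as_number)
    fz = _col("_atom_site_fract_z", gemmi.cif.as_number)
    occ = _col("_atom_site_occupancy", gemmi.cif.as_number, default=1.0)
    typ = _col("_atom_site_type_symbol", gemmi.cif.as_string, default="")
    dgrp = _col("_atom_site_disorder_group", gemmi.cif.as_string, default="")

    sites = []
    for i, lab in enumerate(labels):
        lab = gemmi.cif.as_string(lab)
        element = typ[i] or re.match(r"([A-Za-z]{1,2})", lab).group(1).capitalize()
        element = element[0].upper() + element[1:].lower() if len(element) > 1 else element.upper()
        sites.append(
            AtomSite(
                label=lab,
                element=element,
                frac_xyz=(fx[i], fy[i], fz[i]),
                occupancy=occ[i] if occ[i] is not None else 1.0,
                disorder_group=dgrp[i] or None,
            )
        )

    z_raw = block.find_value("_cell_formula_units_Z")
    z = int(gemmi.cif.as_number(z_raw)) if z_raw is not None else None
    f_raw = block.find_value("_chemical_formula_sum")
    formula = gemmi.cif.as_string(f_raw).strip() if f_raw is not None else None

    return CrystalStructure(
        cell=cell,
        spacegroup=symbol,
        ops=ops,
        sites=sites,
        z_formula=z,
        formula=formula,
        name=block.name or "crystal",
    )


def write_cif(structure: CrystalStructure) -> str:
    """Serialize a structure to CIF text (round-trips through :func:`parse_cif`)."""
    c = structure.cell
    lines = [
        f"data_{structure.name}",
        f"_cell_length_a {c.a:.6f}",
        f"_cell_length_b {c.b:.6f}",
        f"_cell_length_c {c.c:.6f}",
        f"_cell_angle_alpha {c.alpha:.6f}",
        f"_cell_angle_beta {c.beta:.6f}",
        f"_cell_angle_gamma {c.gamma:.6f}",
        f"_symmetry_space_group_name_H-M '{structure.spacegroup}'",
    ]
    if structure.z_formula is not None:
        lines.append(f"_cell_formula_units_Z {structure.z_formula}")
    if structure.formula:
        lines.append(f"_chemical_formula_sum '{structure.formula}'")
    lines += ["loop_", "_space_group_symop_operation_xyz"]
    lines += [f"  '{op.to_xyz()}'" for op in structure.ops]
    lines += [
        "loop_",
        "_atom_site_label",
        "_atom_site_type_symbol",
        "_atom_site_fract_x",
        "_atom_site_fract_y",
        "_atom_site_fract_z",
        "_atom_site_occupancy",
        "_atom_site_disorder_group",
    ]
    for s in structure.sites:
        x, y, z = s.frac_xyz
        grp = s.disorder_group if s.disorder_group else "."
        lines.append(
            f"  {s.label} {s.element} {x:.8f} {y:.8f} {z:.8f} {s.occupancy:.6f} {grp}"
        )
    return "\n".join(lines) + "\n"
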