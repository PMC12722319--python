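import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from polyrisk.crystal_io import (
    AtomSite,
    CrystalStructure,
    SymmetryOp,
    UnitCell,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

P21_OPS = [SymmetryOp.from_xyz("x,y,z"), SymmetryOp.from_xyz("-x,y+1/2,-z")]
P212121_OPS = [
    SymmetryOp.from_xyz("x,y,z"),
    SymmetryOp.from_xyz("-x+1/2,-y,z+1/2"),
    SymmetryOp.from_xyz("-x,y+1/2,-z+1/2"),
    SymmetryOp.from_xyz("x+1/2,-y+1/2,-z"),
]


@pytest.fixture
def form4_cell():
    """Published monoclinic cell of ritonavir form 4 (298 K)."""
    return UnitCell(14.13, 5.16, 26.47, 90.0, 96.67, 90.0)


@pytest.fixture
def p21_structure():
    """Small P2_1 structure with atoms at general positions."""
    return CrystalStructure(
        cell=UnitCell(8.0, 6.0, 10.0, 90.0, 95.0, 90.0),
        spacegroup="P21",
        ops=list(P21_OPS),
        sites=[
            AtomSite("C1", "C", (0.12, 0.23, 0.34)),
            AtomSite("N1", "N", (0.41, 0.05, 0.27)),
            AtomSite("O1", "O", (0.33, 0.38, 0.11)),
        ],
    )


@pytest.fixture
def p1_cubic_atom():
    """Single carbon atom in a P1 cell with cubic metric, a = 5 Å."""
    return CrystalStructure(
        cell=UnitCell(5.0, 5.0, 5.0),
        spacegroup="P1",
        sites=[AtomSite("C1", "C", (0.0, 0.0, 0.0))],
    )


def random_cell(rng) -> UnitCell:
    """A random valid triclinic cell (used by several property tests)."""
    while True:
        a, b, c = rng.uniform(4.0, 25.0, 3)
        al, be, ga = rng.uniform(70.0, 110.0, 3)
        try:
            return UnitCell(a, b, c, al, be, ga)
        except Exception:
            continue


def gaussian_peak_pattern(centers, grid, fwhm=0.02, heights=None):
    """Sum of Gaussian peaks on a grid — a synthetic diffractogram."""
    y = np.zeros_like(grid)
    heights = heights or [1.0] * len(centers)
    for c, h in zip(centers, heights):
        y += h * np.exp(-4.0 * np.log(2.0) * ((grid - c) / fwhm) ** 2)
    return y
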