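import math

import numpy as np
import pytest

from polyrisk.crystal_io import AtomSite, CrystalStructure, UnitCell, expand_symmetry
from polyrisk.synthetic import make_toy_structure
from polyrisk.xrpd import (
    PowderPattern,
    bragg_two_theta,
    d_spacing,
    enumerate_reflections,
    simulate_pattern,
    structure_factor_sq,
)

from conftest import P21_OPS, P212121_OPS


class TestDSpacing:
    def test_cubic_100(self):
        assert d_spacing(UnitCell(10, 10, 10), (1, 0, 0)) == pytest.approx(10.0)

    def test_monoclinic_001_closed_form(self, form4_cell):
        # for b-unique monoclinic, d(00l) = c·sinβ / l
        expected = 26.47 * math.sin(math.radians(96.67))
        assert d_spacing(form4_cell, (0, 0, 1)) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(26.29, abs=5e-3)

    def test_friedel_symmetry(self, form4_cell):
        rng = np.random.default_rng(3)
        for _ in range(20):
            hkl = rng.integers(-5, 6, 3)
            if not hkl.any():
                continue
            assert d_spacing(form4_cell, hkl) == pytest.approx(
                d_spacing(form4_cell, -hkl), rel=1e-12
            )

    def test_zero_hkl_rejected(self, form4_cell):
        with pytest.raises(ValueError):
            d_spacing(form4_cell, (0, 0, 0))


class TestBraggAngle:
    def test_d_equals_wavelength_gives_60_degrees(self):
        assert bragg_two_theta(1.5406, 1.5406) == pytest.approx(60.0, abs=1e-9)

    def test_form4_001(self, form4_cell):
        d = d_spacing(form4_cell, (0, 0, 1))
        tt = bragg_two_theta(d, 1.5406)
        assert tt == pytest.approx(2 * math.degrees(math.asin(1.5406 / (2 * d))), rel=1e-12)
        assert tt == pytest.approx(3.358, abs=2e-3)

    def test_unobservable_reflection_dropped(self):
        assert bragg_two_theta(0.7, 1.5406) is None


class TestStructureFactor:
    def test_single_atom_constant_model(self):
        site = AtomSite("C1", "C", (0.0, 0.0, 0.0))
        for hkl in [(1, 0, 0), (2, 3, 1), (0, 0, 5)]:
            assert structure_factor_sq([site], hkl, 0.0, model="z") == pytest.approx(36.0)

    def test_body_centering_absence(self):
        sites = [
            AtomSite("C1", "C", (0.0, 0.0, 0.0)),
            AtomSite("C2", "C", (0.5, 0.5, 0.5)),
        ]
        assert structure_factor_sq(sites, (1, 0, 0), 0.1) == pytest.approx(0.0, abs=1e-20)
        assert structure_factor_sq(sites, (1, 1, 1), 0.1) == pytest.approx(0.0, abs=1e-20)
        # even h+k+l: constructive
        assert structure_factor_sq(sites, (2, 0, 0), 0.1) > 1.0

    def test_brute_force_complex_sum_oracle(self):
        rng = np.random.default_rng(7)
        sites = [
            AtomSite(f"X{i}", el, tuple(rng.uniform(0, 1, 3)), occupancy=float(o))
            for i, (el, o) in enumerate(
                zip(["C", "N", "O", "S", "C", "H"], rng.uniform(0.3, 1.0, 6))
            )
        ]
        import gemmi

        def cromer_mann(el, stol2):
            c = gemmi.Element(el).it92
            return sum(a * math.exp(-b * stol2) for a, b in zip(c.a, c.b)) + c.c

        for hkl in [(1, 2, 3), (2, 0, 1), (4, 4, 4)]:
            stol2 = 0.04
            # independent oracle: direct complex sum, atom by atom
            F = 0j
            for s in sites:
                f = cromer_mann(s.element, stol2)
                F += s.occupancy * f * np.exp(2j * np.pi * np.dot(hkl, s.frac_xyz))
            expected = abs(F) ** 2
            assert structure_factor_sq(sites, hkl, stol2) == pytest.approx(
                expected, rel=1e-10
            )

    def test_unknown_element_raises(self):
        site = AtomSite("Q1", "Xx", (0, 0, 0))
        with pytest.raises(ValueError, match="Xx"):
            structure_factor_sq([site], (1, 0, 0))


class TestSimulatePattern:
    def test_p21_screw_axis_absences(self, p21_structure):
        refl = enumerate_reflections(p21_structure, two_theta_range=(3.0, 60.0))
        mx = max(r.intensity for r in refl)
        absent = [r for r in refl if r.hkl[0] == 0 and r.hkl[2] == 0 and r.hkl[1] % 2 == 1]
        assert absent, "expected odd 0k0 reflections in range"
        for r in absent:
            assert r.intensity < 1e-9 * mx

    def test_p212121_screw_axis_absences(self):
        s = make_toy_structure(2, "P212121", 4)
        refl = enumerate_reflections(s, two_theta_range=(3.0, 50.0))
        mx = max(r.intensity for r in refl)
        for r in refl:
            axes_zero = [i for i in range(3) if r.hkl[i] != 0]
            if len(axes_zero) == 1:  # axial reflection h00 / 0k0 / 00l
                if r.hkl[axes_zero[0]] % 2 == 1:
                    assert r.intensity < 1e-9 * mx

    def test_lowest_angle_peak_single_atom_cubic(self, p1_cubic_atom):
        pat = simulate_pattern(p1_cubic_atom, two_theta_range=(3.0, 40.0))
        expected_tt = 2 * math.degrees(math.asin(1.5406 / (2 * 5.0)))
        first = min(r.two_theta for r in pat.reflections)
        assert first == pytest.approx(expected_tt, abs=1e-6)
        assert expected_tt == pytest.approx(17.72, abs=5e-3)

    def test_occupancy_scaling_quadratic(self, p21_structure):
        from dataclasses import replace

        half = CrystalStructure(
            cell=p21_structure.cell,
            spacegroup=p21_structure.spacegroup,
            ops=p21_structure.ops,
            sites=[replace(s, occupancy=0.5) for s in p21_structure.sites],
        )
        r_full = enumerate_reflections(p21_structure)
        r_half = enumerate_reflections(half)
        for a, b in zip(r_full, r_half):
            assert a.hkl == b.hkl
            assert a.intensity == pytest.approx(4.0 * b.intensity, rel=1e-9)

    def test_site_order_invariance(self, p21_structure):
        reordered = CrystalStructure(
            cell=p21_structure.cell,
            spacegroup=p21_structure.spacegroup,
            ops=p21_structure.ops,
            sites=list(reversed(p21_structure.sites)),
        )
        p1 = simulate_pattern(p21_structure)
        p2 = simulate_pattern(reordered)
        assert np.allclose(p1.intensity, p2.intensity, atol=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_structures_nonnegative_finite(self, seed):
        sgs = ["P1", "P21", "C2", "P212121"]
        s = make_toy_structure(seed, sgs[seed % 4], n_atoms=3 + seed % 4)
        pat = simulate_pattern(s)
        assert np.all(np.isfinite(pat.intensity))
        assert np.all(pat.intensity >= 0)
        assert pat.intensity.max() == pytest.approx(100.0)

    def test_empty_window_warns_and_returns_flat(self):
        tiny = CrystalStructure(
            cell=UnitCell(4.0, 4.0, 4.0),
            sites=[AtomSite("C1", "C", (0, 0, 0))],
        )
        with pytest.warns(UserWarning, match="no observable reflection"):
            pat = simulate_pattern(tiny, two_theta_range=(3.0, 10.0))
        assert np.all(pat.intensity == 0)


class TestPatternIO:
    def test_xy_round_trip(self, tmp_path, p21_structure):
        pat = simulate_pattern(p21_structure)
        path = tmp_path / "pattern.xy"
        pat.write_xy(path)
        back = PowderPattern.read_xy(path)
        assert back.wavelength == pytest.approx(pat.wavelength)
        assert np.allclose(back.two_theta, pat.two_theta, atol=1e-6)
        assert np.allclose(back.intensity, pat.intensity, atol=1e-6)

    def test_grid_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            PowderPattern(np.array([1.0, 0.5, 2.0]), np.zeros(3))

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            PowderPattern(np.array([1.0, 2.0]), np.array([1.0, -0.1]))
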