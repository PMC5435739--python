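"""Composition counting, VABC group contributions, voxel volumes, FFV."""

import numpy as np
import pytest

from hygroelast import (
    Atom,
    Box,
    CompositionCount,
    ElementRadii,
    MolecularConfiguration,
    count_composition,
    fractional_free_volume,
    make_toy_polymer,
    make_water_box,
    vabc_volume,
    volume_report,
    voxel_volume,
)
from hygroelast.freevolume import (
    InconsistencyError,
    ResolutionError,
    eq10_implied_coefficients,
)
from hygroelast.structures import Ring
from hygroelast.synthetic import hydrate, xylan_like_unit


def _single_water():
    atoms = [
        Atom(0, "O", (5, 5, 5), 0),
        Atom(1, "H", (5.96, 5, 5), 0),
        Atom(2, "H", (4.76, 5.93, 5), 0),
    ]
    return MolecularConfiguration(atoms, {(0, 1), (0, 2)}, [], Box((10, 10, 10)))


def _benzene_like():
    """Planar C6H6 hexagon with an aromatic ring annotation."""
    ang = np.arange(6) * np.pi / 3
    catoms = [Atom(i, "C", (5 + 1.39 * np.cos(a), 5 + 1.39 * np.sin(a), 5.0), 0) for i, a in enumerate(ang)]
    hatoms = [Atom(6 + i, "H", (5 + 2.48 * np.cos(a), 5 + 2.48 * np.sin(a), 5.0), 0) for i, a in enumerate(ang)]
    bonds = {(i, (i + 1) % 6) for i in range(6)} | {(i, 6 + i) for i in range(6)}
    return MolecularConfiguration(catoms + hatoms, bonds, [Ring(tuple(range(6)), True)], Box((10, 10, 10)))


class TestCountComposition:
    def test_single_water(self):
        c = count_composition(_single_water())
        assert (c.N_O, c.N_C, c.N_H, c.N_Bonds) == (1, 0, 2, 2)
        assert c.N_ARings == c.N_NARings == 0
        assert c.N == 3 and c.n_molecules == 1

    def test_benzene_like_ring(self):
        c = count_composition(_benzene_like())
        assert (c.N_C, c.N_H, c.N_Bonds, c.N_ARings) == (6, 6, 12, 1)
        assert c.N - 1 + c.N_ARings + c.N_NARings == c.N_Bonds  # cyclomatic identity

    def test_polymer_counts_scale_with_template(self):
        unit = xylan_like_unit()
        cfg = make_toy_polymer("xylan_like", 3, seed=0, box=Box((25, 12, 12)))
        c = count_composition(cfg)
        assert c.N_C == 3 * unit.elements.count("C")
        assert c.N_O == 3 * unit.elements.count("O")
        assert c.N_NARings == 3
        assert c.N_Bonds == 3 * len(unit.bonds) + 2

    def test_ring_perception_fallback(self):
        """Without explicit ring annotations the cycle basis supplies them."""
        bz = _benzene_like()
        bare = MolecularConfiguration(list(bz.atoms), set(bz.bonds), [], bz.box)
        c = count_composition(bare)
        assert c.N_ARings == 1 and c.N_NARings == 0

    def test_identity_violation_names_the_molecule(self):
        # three atoms in one labelled molecule but only one bond
        atoms = [Atom(i, "O", (float(i * 3), 0, 0), 0) for i in range(3)]
        cfg = MolecularConfiguration(atoms, {(0, 1)}, [], Box((10, 10, 10)))
        with pytest.raises(InconsistencyError, match="molecule 0"):
            count_composition(cfg)


class TestVABC:
    def test_water_both_variants_agree_at_printed_value(self):
        c = count_composition(_single_water())
        # 14.71 + 2(7.24) - 2(5.92) = 17.35 = 8.79 + 2(1.32) + 5.92
        assert vabc_volume(c, "eq8") == pytest.approx(17.35)
        assert vabc_volume(c, "eq10") == pytest.approx(17.35)

    def test_benzene_like_hand_value(self):
        c = count_composition(_benzene_like())
        # 6(20.58) + 6(7.24) - 12(5.92) - 14.7 = 81.18
        assert vabc_volume(c, "eq8") == pytest.approx(81.18)

    @pytest.mark.parametrize("n_o,n_h", [(1, 2), (2, 2), (3, 4), (5, 0)])
    def test_variants_agree_for_carbon_free_acyclic_molecules(self, n_o, n_h):
        """Collapsing the bond count only changes the carbon coefficient, so
        carbon-free single molecules score identically in both variants."""
        c = CompositionCount(N_O=n_o, N_C=0, N_H=n_h, N_Bonds=n_o + n_h - 1,
                             N_ARings=0, N_NARings=0, n_molecules=1)
        assert vabc_volume(c, "eq8") == pytest.approx(vabc_volume(c, "eq10"), abs=1e-9)

    def test_variants_differ_through_the_carbon_coefficient(self):
        c = count_composition(_benzene_like())
        diff = vabc_volume(c, "eq10") - vabc_volume(c, "eq8")
        assert diff == pytest.approx((14.93 - 14.66) * 6, abs=1e-9)

    def test_implied_collapsed_coefficients_are_exact(self):
        implied = {k: float(v) for k, v in eq10_implied_coefficients().items()}
        assert implied["N_O"] == 8.79
        assert implied["N_H"] == 1.32
        assert implied["N_ARings"] == -20.62
        assert implied["N_NARings"] == -9.72
        assert implied["constant"] == 5.92
        assert implied["N_C"] == 14.66  # not the printed 14.93

    def test_multi_molecule_constant_term(self):
        wb = make_water_box(5, Box((15, 15, 15)), seed=1)
        c = count_composition(wb)
        assert c.n_molecules == 5
        assert vabc_volume(c, "eq10") == pytest.approx(5 * 17.35)
        assert vabc_volume(c, "eq8") == pytest.approx(5 * 17.35)


class TestVoxelVolume:
    def _one_atom(self, element, box=10.0):
        return MolecularConfiguration(
            [Atom(0, element, (box / 2,) * 3)], set(), [], Box((box,) * 3)
        )

    @pytest.mark.parametrize("element,radius", [("C", 1.7), ("H", 1.2)])
    def test_single_sphere_matches_closed_form(self, element, radius):
        v = voxel_volume(self._one_atom(element), spacing=0.1)
        assert v == pytest.approx(4.0 / 3.0 * np.pi * radius**3, rel=0.01)

    def test_single_sphere_converges_with_spacing(self):
        """Grid refinement drives the oxygen sphere, whose boundary sits
        exactly on voxel centres at 0.1 Å, to the closed form."""
        exact = 4.0 / 3.0 * np.pi * 1.55**3
        err_coarse = abs(voxel_volume(self._one_atom("O"), spacing=0.1) - exact)
        err_fine = abs(voxel_volume(self._one_atom("O"), spacing=0.05) - exact)
        assert err_fine < err_coarse
        assert err_fine <= 0.005 * exact

    def test_cocentred_spheres_union_is_one_sphere(self):
        cfg = MolecularConfiguration(
            [Atom(0, "C", (5, 5, 5)), Atom(1, "C", (5, 5, 5))], set(), [], Box((10, 10, 10))
        )
        assert voxel_volume(cfg, spacing=0.15) == voxel_volume(self._one_atom("C"), spacing=0.15)

    def test_disjoint_spheres_add(self):
        cfg = MolecularConfiguration(
            [Atom(0, "C", (4, 4, 4)), Atom(1, "O", (11, 11, 11))], set(), [], Box((16, 16, 16))
        )
        expected = 4.0 / 3.0 * np.pi * (1.7**3 + 1.55**3)
        assert voxel_volume(cfg, spacing=0.1) == pytest.approx(expected, rel=0.01)

    def test_overlap_is_strictly_subadditive(self):
        cfg = MolecularConfiguration(
            [Atom(0, "C", (5, 5, 5)), Atom(1, "C", (6.5, 5, 5))], set(), [], Box((12, 12, 12))
        )
        v = voxel_volume(cfg, spacing=0.1)
        assert v < 2 * 4.0 / 3.0 * np.pi * 1.7**3 * 0.999

    def test_periodic_wrap_keeps_volume(self):
        """A sphere centred on a box corner wraps into all octants."""
        cfg = MolecularConfiguration([Atom(0, "C", (0, 0, 0))], set(), [], Box((8, 8, 8)))
        assert voxel_volume(cfg, spacing=0.1) == pytest.approx(4.0 / 3.0 * np.pi * 1.7**3, rel=0.01)

    def test_monte_carlo_union_oracle(self, water_box20):
        """Voxel union volume agrees with hit-or-miss Monte Carlo."""
        v_vox = voxel_volume(water_box20, spacing=0.15)
        rng = np.random.default_rng(12345)
        n_pts = 200_000
        L = np.array(water_box20.box.lengths)
        pts = rng.uniform(0, 1, (n_pts, 3)) * L
        pos = water_box20.positions
        radii = np.array([ElementRadii().of(e) for e in water_box20.elements])
        d = pts[:, None, :] - pos[None, :, :]
        d -= L * np.round(d / L)
        hit = (np.linalg.norm(d, axis=-1) <= radii[None, :]).any(axis=1)
        p = hit.mean()
        v_mc = p * water_box20.box.volume
        sigma = np.sqrt(p * (1 - p) / n_pts) * water_box20.box.volume
        assert abs(v_vox - v_mc) <= 3 * sigma + 0.01 * v_mc  # sampling + grid error

    def test_probe_leaves_single_convex_sphere_unchanged(self):
        """The solvent-excluded volume of one sphere is the sphere itself."""
        v0 = voxel_volume(self._one_atom("C", box=12.0), spacing=0.15, probe=0.0)
        v1 = voxel_volume(self._one_atom("C", box=12.0), spacing=0.15, probe=1.4)
        assert v1 == pytest.approx(v0, rel=0.05)

    def test_probe_fills_narrow_crevices(self):
        """Two nearly-touching spheres trap probe-inaccessible volume."""
        cfg = MolecularConfiguration(
            [Atom(0, "C", (5, 6, 6)), Atom(1, "C", (8.6, 6, 6))], set(), [], Box((14, 12, 12))
        )
        assert voxel_volume(cfg, spacing=0.15, probe=1.4) > voxel_volume(cfg, spacing=0.15, probe=0.0)

    def test_spacing_coarser_than_radius_rejected(self):
        with pytest.raises(ResolutionError):
            voxel_volume(self._one_atom("H"), spacing=1.3)


class TestFFV:
    def test_limiting_values(self):
        assert fractional_free_volume(100.0, 100.0) == 0.0
        assert fractional_free_volume(90.0, 100.0) == pytest.approx(0.1)

    def test_overpacked_warns_and_goes_negative(self):
        with pytest.warns(UserWarning, match="over-packed"):
            assert fractional_free_volume(120.0, 100.0) < 0

    def test_vabc_route_cross_checked_arithmetic(self):
        """FFV of a toy polymer in a 20^3 box equals 1 - 1.3 v_W / 8000."""
        cfg = make_toy_polymer("lignin_like", 2, seed=1, box=Box((20.0, 20.0, 20.0)))
        rep = volume_report(cfg, "vabc_eq8")
        v_w = vabc_volume(count_composition(cfg), "eq8")
        assert rep.v_T == 8000.0
        assert rep.ffv == pytest.approx(1.0 - 1.3 * v_w / 8000.0, abs=1e-12)
        assert rep.v_OC == pytest.approx(1.3 * rep.v_W)

    def test_void_filling_lowers_ffv(self):
        """Water inserted into pre-existing voids (fixed box) raises the
        occupied volume at constant total volume, so FFV must fall."""
        roomy = make_toy_polymer("lignin_like", 3, seed=0, box=Box((30.0, 15.0, 15.0)))
        wet = hydrate(roomy, 6.0, seed=2)
        assert wet.n_atoms > roomy.n_atoms
        assert volume_report(wet).ffv < volume_report(roomy).ffv

    def test_forced_expansion_raises_ffv(self):
        """A densely packed chain that swells by more than the water's
        occupied volume per molecule gains free volume on hydration."""
        dense = make_toy_polymer("xylan_like", 4, seed=0, box=Box((17.5, 6.1, 7.0)))
        r0 = volume_report(dense)
        assert r0.ffv < 0.35  # genuinely dense fixture
        wet = hydrate(dense, 6.0, seed=2, min_dist=1.8, expansion_volume=40.0)
        assert wet.n_atoms > dense.n_atoms
        assert volume_report(wet).ffv > r0.ffv
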