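import numpy as np
import pytest

from mdmx import (
    Structure,
    TrajectoryWindow,
    UnitCell,
    component_sf,
    density_to_sf,
    electron_count,
    form_factor,
    frame_density,
    make_trajectory,
    mean_density,
    scale_absolute,
    sf_direct,
    sf_to_density,
    spacegroup_from_symbol,
)
from mdmx.density import DensityGrid, GridSpec, StructureFactorSet
from mdmx.formfactors import get_entry
from mdmx.structure import AtomRecord

# Independent Cromer–Mann tabulation (published 4-Gaussian coefficients)
# for the dual-source check of the runtime coefficient table.
CM_REFERENCE = {
    "C": ([2.31000, 1.02000, 1.58860, 0.86500],
          [20.8439, 10.2075, 0.56870, 51.6512], 0.21560),
    "O": ([3.04850, 2.28680, 1.54630, 0.86700],
          [13.2771, 5.70110, 0.32390, 32.9089], 0.25080),
    "H": ([0.493002, 0.322912, 0.140191, 0.040810],
          [10.5109, 26.1257, 3.14236, 57.7997], 0.003038),
}


def cm_eval(element, s):
    a, b, c = CM_REFERENCE[element]
    return sum(ai * np.exp(-bi * s * s) for ai, bi in zip(a, b)) + c


def single_atom(element="C", pos=(6.0, 6.0, 6.0), cell=None, occupancy=1.0):
    cell = cell or UnitCell(12, 12, 12)
    atom = AtomRecord(1, element.upper(), "GLY", "A", 1, np.array(pos), element,
                      occupancy=occupancy)
    return Structure([atom], cell, spacegroup_from_symbol("P 1"))


class TestFormFactor:
    @pytest.mark.parametrize("element,z", [("C", 6), ("O", 8), ("N", 7), ("H", 1),
                                           ("Mg", 12), ("Cl", 17), ("P", 15), ("S", 16)])
    def test_f_at_zero_is_electron_count(self, element, z):
        assert form_factor(element, 0.0) == pytest.approx(z, abs=0.02)
        assert electron_count(element) == z

    @pytest.mark.parametrize("element", ["C", "O", "H"])
    def test_matches_independent_tabulation(self, element):
        """Runtime coefficients agree with a second, hand-embedded tabulation."""
        for s in (0.0, 0.1, 0.3, 0.5):
            assert form_factor(element, s) == pytest.approx(cm_eval(element, s), abs=2e-3)

    def test_monotone_non_increasing_for_light_atoms(self):
        s = np.linspace(0, 1.2, 200)
        for element in ("C", "N", "O", "H"):
            f = form_factor(element, s)
            assert np.all(np.diff(f) <= 1e-9)

    def test_untabulated_element_rejected(self):
        with pytest.raises(KeyError):
            form_factor("Xq", 0.1)

    def test_gaussian_term_weights_sum_to_z(self):
        for element in ("C", "N", "O", "S", "Mg"):
            entry = get_entry(element)
            for b_extra in (0.0, 15.0):
                assert sum(a for a, _ in entry.gaussian_terms(b_extra)) == pytest.approx(
                    entry.z, abs=0.1
                )


class TestFrameDensity:
    def test_empty_selection_warns_and_returns_zero_grid(self, toy_p1):
        asu, _ = toy_p1
        with pytest.warns(UserWarning, match="no atoms"):
            g = frame_density(asu, "resname XXX", GridSpec((8, 8, 8)))
        assert not g.values.any()

    def test_single_carbon_integral_is_six(self):
        s = single_atom("C")
        g = frame_density(s, None, GridSpec.from_spacing(s.cell, 0.15))
        assert g.integral() == pytest.approx(6.0, rel=0.005)

    def test_occupancy_scales_contribution(self):
        s = single_atom("C", occupancy=0.5)
        g = frame_density(s, None, GridSpec.from_spacing(s.cell, 0.15))
        assert g.integral() == pytest.approx(3.0, rel=0.005)

    def test_corner_atom_splits_periodically_integral_unchanged(self):
        s = single_atom("O", pos=(0.0, 0.0, 0.0))
        g = frame_density(s, None, GridSpec.from_spacing(s.cell, 0.15))
        assert g.integral() == pytest.approx(8.0, rel=0.005)
        # peak sits at the origin voxel, density symmetric across the 8 corners
        v = g.values
        assert v[0, 0, 0] == v.max()
        n = v.shape[0]
        assert v[1, 0, 0] == pytest.approx(v[n - 1, 0, 0], rel=1e-6)

    def test_conservation_on_mixed_composition(self, toy_p1):
        """Density integral equals selected electron count within 0.5%."""
        asu, manifest = toy_p1
        g = frame_density(asu, "all", GridSpec.from_spacing(asu.cell, 0.15))
        assert g.integral() == pytest.approx(manifest["electrons"]["all"], rel=0.005)
        gw = frame_density(asu, "water", GridSpec.from_spacing(asu.cell, 0.15))
        assert gw.integral() == pytest.approx(manifest["electrons"]["water"], rel=0.005)

    def test_smearing_preserves_integral_and_broadens(self):
        s = single_atom("C")
        spec = GridSpec.from_spacing(s.cell, 0.15)
        g0 = frame_density(s, None, spec)
        g1 = frame_density(s, None, spec, smear_b=20.0)
        assert g1.integral() == pytest.approx(g0.integral(), rel=0.005)
        assert g1.values.max() < g0.values.max()


class TestMeanDensity:
    def test_identical_frames_idempotent(self, toy_p1):
        asu, _ = toy_p1
        spec = GridSpec((16, 16, 16))
        traj = TrajectoryWindow([asu] * 3, 10.0 * np.arange(3))
        gm = mean_density(traj, "all", spec, smear_b=10.0)
        g1 = frame_density(asu, "all", spec, smear_b=10.0)
        assert np.abs(gm.values - g1.values).max() < 1e-12

    def test_two_positions_give_half_height_pair(self):
        cell = UnitCell(12, 12, 12)
        a = single_atom("C", (4.0, 6.0, 6.0), cell)
        b = single_atom("C", (8.0, 6.0, 6.0), cell)
        spec = GridSpec.from_spacing(cell, 0.2)
        traj = TrajectoryWindow([a, b], np.array([0.0, 10.0]))
        gm = mean_density(traj, None, spec)
        ga = frame_density(a, None, spec)
        assert gm.integral() == pytest.approx(6.0, rel=0.005)
        assert gm.values.max() == pytest.approx(0.5 * ga.values.max(), rel=1e-6)

    def test_layout_mismatch_rejected(self, toy_p1):
        asu, _ = toy_p1
        short = asu.subset(np.arange(len(asu)) < 4)
        with pytest.raises(ValueError):
            TrajectoryWindow([asu, short], np.array([0.0, 10.0]))

    def test_jitter_variance_recovered_from_second_moment(self):
        """Planted σ appears in the mean peak as profile variance + σ²."""
        cell = UnitCell(12, 12, 12)
        s = single_atom("C")
        sigma = 0.25
        traj = make_trajectory(s, sigma, 300, seed=3)
        spec = GridSpec.from_spacing(cell, 0.15)
        gm = mean_density(traj, None, spec)
        g0 = frame_density(s, None, spec)
        mom = _radial_second_moment(gm, s.coords[0])
        mom0 = _radial_second_moment(g0, s.coords[0])
        recovered = np.sqrt((mom - mom0) / 3.0)
        assert recovered == pytest.approx(sigma, rel=0.05)


def _radial_second_moment(grid, center):
    divs = np.array(grid.divisions)
    idx = np.stack(np.meshgrid(*[np.arange(n) for n in divs], indexing="ij"), axis=-1)
    d = idx / divs - grid.cell.fractionalize(center)
    d -= np.round(d)
    cart = d @ grid.cell.orthogonalization.T
    r2 = np.einsum("...i,...i->...", cart, cart)
    return float((grid.values * r2).sum() / grid.values.sum())


class TestStructureFactors:
    def test_constant_density_has_only_f000(self, p1_cell):
        grid = DensityGrid(np.full((12, 12, 12), 0.5), p1_cell, {"f000": 0.5 * p1_cell.volume})
        sf = density_to_sf(grid, 4.0)
        f000 = sf.f000()
        assert f000 == pytest.approx(0.5 * p1_cell.volume)
        others = sf.values[~np.all(sf.hkl == 0, axis=1)]
        assert np.abs(others).max() < 1e-9 * abs(f000)

    def test_fft_matches_direct_summation_oracle(self, rng):
        """FFT-path structure factors vs quadratic direct sum on 5 atoms."""
        cell = UnitCell(14, 15, 16)
        atoms = [
            AtomRecord(i + 1, el, "GLY", "A", i + 1,
                       cell.orthogonalize(rng.random(3)), el)
            for i, el in enumerate(["C", "N", "O", "S", "C"])
        ]
        s = Structure(atoms, cell, spacegroup_from_symbol("P 1"))
        grid = frame_density(s, None, GridSpec.from_spacing(cell, 0.3), smear_b=15.0)
        sf_fft = density_to_sf(grid, 2.0)
        sf_ref = sf_direct(s, None, sf_fft.hkl, smear_b=15.0)
        rel = np.abs(sf_fft.values - sf_ref.values) / np.abs(sf_ref.values).max()
        assert rel.max() < 1e-3

    def test_fft_matches_direct_unsmeared_on_fine_grid(self):
        s = single_atom("C")
        grid = frame_density(s, None, GridSpec.from_spacing(s.cell, 0.1))
        sf_fft = density_to_sf(grid, 2.0)
        sf_ref = sf_direct(s, None, sf_fft.hkl)
        rel = np.abs(sf_fft.values - sf_ref.values) / np.abs(sf_ref.values)
        assert rel.max() < 1e-3

    def test_direct_sum_one_atom_at_origin_real_positive(self):
        s = single_atom("C", pos=(0.0, 0.0, 0.0))
        hkl = [[1, 0, 0], [0, 2, 0], [1, 1, 1]]
        sf = sf_direct(s, None, hkl, match_density_model=False)
        d = s.cell.d_spacing(np.array(hkl))
        expected = form_factor("C", 1.0 / (2.0 * d))
        assert np.allclose(sf.values.imag, 0.0, atol=1e-12)
        assert np.allclose(sf.values.real, expected)

    def test_centrosymmetric_pair_has_centric_phases(self):
        cell = UnitCell(12, 12, 12)
        atoms = [
            AtomRecord(1, "C", "GLY", "A", 1, cell.orthogonalize([0.3, 0.35, 0.4]), "C"),
            AtomRecord(2, "C", "GLY", "A", 2, cell.orthogonalize([0.7, 0.65, 0.6]), "C"),
        ]
        s = Structure(atoms, cell, spacegroup_from_symbol("P 1"))
        sf = sf_direct(s, None, [[1, 0, 0], [2, 1, 0], [3, 1, 2]])
        ph = np.degrees(np.angle(sf.values * np.exp(2j * np.pi * (sf.hkl @ [0.5, 0.5, 0.5]))))
        # phases referred to the inversion center are 0 or 180
        assert np.all(np.minimum(np.abs(np.mod(ph, 180.0)), 180.0 - np.abs(np.mod(ph, 180.0))) < 1e-6)

    def test_lattice_translation_leaves_amplitudes_unchanged(self, toy_p1):
        asu, _ = toy_p1
        spec = GridSpec((16, 18, 18))
        sf_a = density_to_sf(frame_density(asu, "all", spec, smear_b=12.0), 3.0)
        moved = asu.with_coords(asu.coords + asu.cell.orthogonalize([1.0, 1.0, -2.0]))
        sf_b = density_to_sf(frame_density(moved, "all", spec, smear_b=12.0), 3.0)
        assert np.abs(sf_a.amplitudes - sf_b.amplitudes).max() < 1e-8 * sf_a.amplitudes.max()

    def test_friedel_symmetry(self, toy_p1):
        asu, _ = toy_p1
        sf = density_to_sf(frame_density(asu, "all", GridSpec((16, 18, 18)), smear_b=12.0), 3.0)
        lut = sf.lookup()
        for (h, k, l), v in lut.items():
            mate = lut.get((-h, -k, -l))
            if mate is not None:
                assert abs(v - np.conj(mate)) < 1e-10 * max(abs(v), 1.0)

    def test_f000_equals_electron_count(self, toy_p1):
        asu, manifest = toy_p1
        sf = density_to_sf(frame_density(asu, "all", GridSpec.from_spacing(asu.cell, 0.15)), 3.0)
        assert np.real(sf.f000()) == pytest.approx(manifest["electrons"]["all"], rel=0.005)
        assert abs(np.imag(sf.f000())) < 1e-10

    def test_grid_too_coarse_rejected(self, toy_p1):
        asu, _ = toy_p1
        g = frame_density(asu, "all", GridSpec((6, 6, 6)), smear_b=12.0)
        with pytest.raises(ValueError, match="too coarse"):
            density_to_sf(g, 2.0)


class TestInverseTransform:
    def test_roundtrip_on_band_limited_grid(self, toy_p1):
        asu, _ = toy_p1
        spec = GridSpec((18, 18, 20))
        sf = density_to_sf(frame_density(asu, "all", spec, smear_b=15.0), 3.0)
        rho = sf_to_density(sf, spec)
        sf2 = density_to_sf(rho, 3.0)
        assert np.abs(sf2.values - sf.values).max() < 1e-8 * np.abs(sf.values).max()

    def test_f000_only_gives_constant_grid(self, p1_cell):
        sf = StructureFactorSet([[0, 0, 0]], [100.0 + 0j], p1_cell)
        rho = sf_to_density(sf, GridSpec((10, 10, 10)))
        assert np.allclose(rho.values, 100.0 / p1_cell.volume)

    def test_missing_friedel_mates_synthesized(self, p1_cell):
        """A hemisphere-only input still yields a real map."""
        sf = StructureFactorSet([[1, 0, 0], [0, 1, 0]], [3 + 4j, 1 - 2j], p1_cell)
        rho = sf_to_density(sf, GridSpec((8, 8, 8)))
        assert np.isrealobj(rho.values)
        back = density_to_sf(rho, 4.0).lookup()
        assert abs(back[(1, 0, 0)] - (3 + 4j)) < 1e-10
        assert abs(back[(-1, 0, 0)] - (3 - 4j)) < 1e-10


class TestAbsoluteScale:
    def test_normalized_grid_unchanged(self, toy_p1):
        asu, _ = toy_p1
        g = frame_density(asu, "all", GridSpec((16, 16, 16)), smear_b=10.0)
        g.provenance["f000"] = g.integral()  # declare current integral as truth
        out = scale_absolute(g)
        assert np.abs(out.values - g.values).max() == 0.0

    def test_doubled_grid_recovered(self, toy_p1):
        asu, _ = toy_p1
        g = frame_density(asu, "all", GridSpec((16, 16, 16)), smear_b=10.0)
        doubled = g.copy()
        doubled.values *= 2.0
        out = scale_absolute(doubled)
        assert np.abs(out.values - g.values * (g.provenance["f000"] / g.integral())).max() < 1e-9

    def test_f000_double_count_oracle(self, toy_p1):
        """Σ occ·Z by atom loop equals Σ occ·f(0) by form-factor loop."""
        asu, _ = toy_p1
        by_z = sum(a.occupancy * electron_count(a.element) for a in asu.atoms)
        by_f0 = sum(a.occupancy * float(form_factor(a.element, 0.0)) for a in asu.atoms)
        assert by_z == pytest.approx(by_f0, abs=0.05 * len(asu))
        g = frame_density(asu, "all", GridSpec((16, 16, 16)), smear_b=10.0)
        assert g.provenance["f000"] == pytest.approx(by_z)

    def test_nonpositive_f000_rejected(self, p1_cell):
        g = DensityGrid(np.ones((4, 4, 4)), p1_cell, {"f000": 0.0})
        with pytest.raises(ValueError):
            scale_absolute(g)


class TestComponents:
    def test_partition_all_equals_full(self, toy_p1):
        asu, _ = toy_p1
        traj = TrajectoryWindow([asu], np.array([0.0]))
        spec = GridSpec((16, 16, 16))
        only = component_sf(traj, ["all"], 3.0, spec, smear_b=10.0)[0]
        full = density_to_sf(mean_density(traj, "all", spec, smear_b=10.0), 3.0)
        assert np.abs(only.values - full.values).max() == 0.0

    def test_component_additivity(self, toy_p212121):
        """Protein + water + ion structure factors sum to the full system."""
        asu, _ = toy_p212121
        traj = TrajectoryWindow([asu], np.array([0.0]))
        spec = GridSpec((20, 24, 24))
        parts = ["protein", "water", "resname MG or resname CL"]
        comps = component_sf(traj, parts, 3.0, spec, smear_b=10.0)
        full = density_to_sf(mean_density(traj, "all", spec, smear_b=10.0), 3.0)
        total = sum(c.values for c in comps)
        assert np.abs(total - full.values).max() < 1e-8 * np.abs(full.values).max()

    def test_overlapping_partition_rejected(self, toy_p1):
        asu, _ = toy_p1
        traj = TrajectoryWindow([asu], np.array([0.0]))
        with pytest.raises(ValueError, match="overlap"):
            component_sf(traj, ["protein", "element C"], 3.0, GridSpec((8, 8, 8)))

    def test_water_component_peaks_at_planted_sites(self, toy_p212121):
        from mdmx import find_peaks, min_image_distance

        asu, manifest = toy_p212121
        traj = make_trajectory(asu, 0.1, 10, seed=6)
        g = mean_density(traj, "water", GridSpec.from_spacing(asu.cell, 0.4))
        peaks = find_peaks(g, 1.0)
        assert len(peaks) == len(manifest["water_sites"])
        for site in manifest["water_sites"]:
            nearest = min(
                min_image_distance(site, p.position, asu.cell) for p in peaks
            )
            assert nearest < 0.3
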