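import numpy as np
import pytest

from tjumpxtal.core_model import Atom, CrystalModel, ReflectionSet, UnitCell
from tjumpxtal.formfactors import COEFFS
from tjumpxtal.realspace import (
    DensityGrid,
    DifferenceSet,
    IADDATConfig,
    IADDATProfile,
    bscaled_difference,
    delta_iaddat,
    difference_structure_factors,
    iaddat,
    map_grid_shape,
    rscc,
    rscc_matrix,
    synthesize_from_complex,
    synthesize_map,
    weights,
)
from tjumpxtal.synthetic_data import generate_hkl, structure_factors_complex


def _refl(small_cell, hkl, f, sigf, phase=None, label="dark1"):
    return ReflectionSet(hkl=hkl, f=f, sigf=sigf, phase=phase,
                         cell=small_cell, d_min=2.0, label=label)


class TestDifferenceStructureFactors:
    def test_inner_join_and_quadrature(self, small_cell):
        f_t = _refl(small_cell, [[1, 0, 0], [2, 0, 0], [3, 0, 0]],
                    [10.0, 20.0, 30.0], [1.0, 2.0, 3.0], label="t20us")
        f_d = _refl(small_cell, [[2, 0, 0], [3, 0, 0], [4, 0, 0]],
                    [18.0, 33.0, 40.0], [1.5, 2.5, 4.0],
                    phase=[45.0, 90.0, 135.0])
        ds = difference_structure_factors(f_t, f_d)
        assert len(ds) == 2
        np.testing.assert_array_equal(ds.hkl, [[2, 0, 0], [3, 0, 0]])
        np.testing.assert_allclose(ds.delta_f, [2.0, -3.0])
        np.testing.assert_allclose(
            ds.sig_delta_f, [np.hypot(2.0, 1.5), np.hypot(3.0, 2.5)])
        # phases default to the dark set's
        np.testing.assert_allclose(ds.phase, [45.0, 90.0])

    def test_explicit_phase_array(self, small_cell):
        f_t = _refl(small_cell, [[1, 0, 0]], [10.0], [1.0])
        f_d = _refl(small_cell, [[1, 0, 0]], [8.0], [1.0])
        ds = difference_structure_factors(f_t, f_d, phases=np.array([30.0]))
        assert ds.phase[0] == pytest.approx(30.0)

    def test_unphased_source_rejected(self, small_cell):
        f_t = _refl(small_cell, [[1, 0, 0]], [10.0], [1.0])
        f_d = _refl(small_cell, [[1, 0, 0]], [8.0], [1.0])
        with pytest.raises(ValueError, match="phases"):
            difference_structure_factors(f_t, f_d)
        with pytest.raises(ValueError, match="phases"):
            difference_structure_factors(f_t, f_d, phases=f_d)

    def test_disjoint_sets_rejected(self, small_cell):
        f_t = _refl(small_cell, [[1, 0, 0]], [10.0], [1.0])
        f_d = _refl(small_cell, [[2, 0, 0]], [8.0], [1.0], phase=[0.0])
        with pytest.raises(ValueError, match="common"):
            difference_structure_factors(f_t, f_d)

    def test_cell_mismatch_rejected(self, small_cell):
        other = UnitCell(11.0, 10.0, 10.0)
        f_t = _refl(small_cell, [[1, 0, 0]], [10.0], [1.0])
        f_d = ReflectionSet(hkl=[[1, 0, 0]], f=[8.0], sigf=[1.0], phase=[0.0],
                            cell=other, d_min=2.0)
        with pytest.raises(ValueError, match="cell"):
            difference_structure_factors(f_t, f_d)


class TestWeights:
    def _uniform_ds(self, small_cell, n=10, df=2.0, sig=1.0):
        hkl = [[h, 0, 0] for h in range(1, n + 1)]
        return DifferenceSet(hkl=hkl, delta_f=np.full(n, df),
                             sig_delta_f=np.full(n, sig),
                             phase=np.zeros(n), cell=small_cell, d_min=1.0)

    def test_uniform_inputs_hand_value(self, small_cell):
        # sigma term = 1, amplitude term = alpha = 0.05 -> w = 1/2.05
        ds = weights(self._uniform_ds(small_cell))
        np.testing.assert_allclose(ds.weight, 1.0 / 2.05, rtol=1e-12)

    def test_zero_sigma_drops_sigma_term(self, small_cell):
        ds = weights(self._uniform_ds(small_cell, sig=0.0))
        np.testing.assert_allclose(ds.weight, 1.0 / 1.05, rtol=1e-12)

    def test_outlier_amplitude_downweighted(self, small_cell):
        base = self._uniform_ds(small_cell)
        base.delta_f[0] = 50.0
        ds = weights(base)
        assert ds.weight[0] < ds.weight[1:].min()
        assert np.all((ds.weight > 0) & (ds.weight <= 1.0))

    def test_by_shell_variant_valid(self, small_cell):
        rng = np.random.default_rng(0)
        hkl = generate_hkl(small_cell, 1.2)
        ds = DifferenceSet(hkl=hkl, delta_f=rng.normal(size=len(hkl)),
                           sig_delta_f=rng.uniform(0.5, 1.5, len(hkl)),
                           phase=np.zeros(len(hkl)), cell=small_cell, d_min=1.2)
        w = weights(ds, by_shell=True).weight
        assert w.shape == (len(hkl),)
        assert np.all((w > 0) & (w <= 1.0))

    def test_empty_set_rejected(self, small_cell):
        ds = DifferenceSet(hkl=np.empty((0, 3)), delta_f=[], sig_delta_f=[],
                           phase=[], cell=small_cell, d_min=1.0)
        with pytest.raises(ValueError, match="empty"):
            weights(ds)


class TestMapSynthesis:
    def test_grid_spacing(self, small_cell):
        shape = map_grid_shape(small_cell, 1.6)
        for n, length in zip(shape, (10.0, 10.0, 10.0)):
            assert length / n <= 0.25 * 1.6

    def test_single_atom_peaks_at_atom(self, small_cell):
        """Synthesis from calculated coefficients must place the density
        maximum at the atom position (catches index/orientation errors)."""
        frac = np.array([0.3, 0.4, 0.6])
        model = CrystalModel([Atom("C", frac, b=20.0)], small_cell)
        hkl = generate_hkl(small_cell, 1.6)
        coeffs = structure_factors_complex(model, hkl)
        grid = synthesize_from_complex(hkl, coeffs, small_cell, 1.6)
        peak = np.unravel_index(np.argmax(grid.values), grid.shape)
        peak_frac = np.array(peak) / np.array(grid.shape)
        delta = peak_frac - frac
        delta -= np.round(delta)
        dist = np.linalg.norm(delta * 10.0)
        assert dist <= 10.0 / min(grid.shape) + 1e-9

    def test_map_mean_is_zero_without_f000(self, small_cell):
        model = CrystalModel([Atom("O", np.array([0.2, 0.7, 0.1]), b=15.0)],
                             small_cell)
        hkl = generate_hkl(small_cell, 1.6)
        grid = synthesize_from_complex(
            hkl, structure_factors_complex(model, hkl), small_cell, 1.6)
        assert abs(grid.values.mean()) < 1e-12

    def test_bscale_difference_against_analytic_gaussians(self):
        """Independent oracle: for one atom, the B-inflation difference
        density is a closed-form sum of Gaussian differences. B = 50
        makes the signal effectively band-limited inside d_min = 1.5, so
        the Fourier synthesis must agree pointwise."""
        cell = UnitCell(12.0, 12.0, 12.0)
        frac = np.array([0.5, 0.5, 0.5])
        model = CrystalModel([Atom("C", frac, b=50.0)], cell)
        grid = bscaled_difference(model, scale=1.2, d_min=1.5)

        vox = grid.voxel_frac_coords()
        d = vox - frac
        d -= np.round(d)
        r2 = np.sum((d * 12.0) ** 2, axis=1)
        a, b, c = COEFFS["C"]
        analytic = np.zeros(len(vox))
        for b_iso in (60.0, 50.0):  # scaled then original
            sign = 1.0 if b_iso == 60.0 else -1.0
            for ai, bi in zip(list(a) + [c], list(b) + [0.0]):
                w = bi + b_iso
                analytic += sign * ai * (4 * np.pi / w) ** 1.5 * np.exp(
                    -4 * np.pi ** 2 * r2 / w)
        analytic -= analytic.mean()  # synthesis omits F(000)
        resid = grid.values.ravel() - analytic
        rel = np.sqrt(np.mean(resid ** 2)) / np.max(np.abs(analytic))
        assert rel < 0.005
        # signature of increased motion: negative at the atomic centre
        centre = tuple(np.round(frac * np.array(grid.shape)).astype(int))
        assert grid.values[centre] < 0

    def test_bscale_positive_halo(self, small_cell):
        model = CrystalModel([Atom("C", np.full(3, 0.5), b=20.0)], small_cell)
        grid = bscaled_difference(model, scale=1.2, d_min=1.6)
        assert grid.values.min() < 0 < grid.values.max()

    def test_invalid_bscale_rejected(self, small_cell):
        model = CrystalModel([Atom("C", np.full(3, 0.5), b=20.0)], small_cell)
        with pytest.raises(ValueError):
            bscaled_difference(model, scale=0.0)

    def test_synthesize_map_requires_weights(self, small_cell):
        ds = DifferenceSet(hkl=[[1, 0, 0]], delta_f=[1.0], sig_delta_f=[0.1],
                           phase=[0.0], cell=small_cell, d_min=1.6)
        with pytest.raises(ValueError, match="weights"):
            synthesize_map(ds)
        grid = synthesize_map(ds, use_weights=False)
        assert grid.shape == map_grid_shape(small_cell, 1.6)

    def test_synthesize_map_rejects_nonfinite_phase(self, small_cell):
        ds = DifferenceSet(hkl=[[1, 0, 0]], delta_f=[1.0], sig_delta_f=[0.1],
                           phase=[np.nan], cell=small_cell, d_min=1.6)
        with pytest.raises(ValueError, match="phases"):
            synthesize_map(ds, use_weights=False)

    def test_ccp4_roundtrip(self, tmp_path, small_cell):
        rng = np.random.default_rng(3)
        grid = DensityGrid(values=rng.normal(size=(8, 10, 12)), cell=small_cell)
        path = str(tmp_path / "map.ccp4")
        grid.write_ccp4(path)
        back = DensityGrid.read_ccp4(path)
        assert back.shape == grid.shape
        assert back.cell.isclose(grid.cell)
        np.testing.assert_allclose(back.values, grid.values, atol=1e-6)


class TestIADDAT:
    def _grid_one_voxel(self, small_cell, value=0.05, sign=1.0):
        values = np.zeros((10, 10, 10))
        values[2, 5, 7] = sign * value  # voxel centre at frac (0.2, 0.5, 0.7)
        return DensityGrid(values=values, cell=small_cell)

    def _two_residue_model(self, small_cell):
        atoms = [
            Atom("C", np.array([0.25, 0.5, 0.7]), b=10.0, resnum=1, chain="A"),
            Atom("N", np.array([0.25, 0.55, 0.7]), b=10.0, resnum=1, chain="A"),
            Atom("C", np.array([0.8, 0.1, 0.2]), b=10.0, resnum=2, chain="A"),
        ]
        return CrystalModel(atoms, small_cell)

    def test_hand_computed_single_voxel(self, small_cell):
        # voxel is 0.5 A from residue 1's first atom, ~7 A from residue 2
        grid = self._grid_one_voxel(small_cell)
        model = self._two_residue_model(small_cell)
        prof = iaddat(grid, model)
        assert prof.residue_ids == [("A", 1), ("A", 2)]
        assert prof.values[0] == pytest.approx(0.05 / 2.0)  # 2 atoms in res 1
        assert prof.values[1] == 0.0

    def test_negative_density_counts_absolutely(self, small_cell):
        grid = self._grid_one_voxel(small_cell, sign=-1.0)
        prof = iaddat(grid, self._two_residue_model(small_cell))
        assert prof.values[0] == pytest.approx(0.05 / 2.0)

    def test_subthreshold_ignored(self, small_cell):
        grid = self._grid_one_voxel(small_cell, value=0.039)
        prof = iaddat(grid, self._two_residue_model(small_cell))
        np.testing.assert_array_equal(prof.values, 0.0)

    def test_flat_map_gives_zeros(self, small_cell):
        grid = DensityGrid(values=np.zeros((10, 10, 10)), cell=small_cell)
        prof = iaddat(grid, self._two_residue_model(small_cell))
        np.testing.assert_array_equal(prof.values, 0.0)

    def test_waters_excluded(self, small_cell):
        grid = self._grid_one_voxel(small_cell)
        atoms = [Atom("O", np.array([0.2, 0.5, 0.7]), b=30.0, resnum=9,
                      chain="A", is_water=True, resname="HOH"),
                 Atom("C", np.array([0.8, 0.1, 0.2]), b=10.0, resnum=2,
                      chain="A")]
        prof = iaddat(grid, CrystalModel(atoms, small_cell))
        assert prof.residue_ids == [("A", 2)]
        with pytest.raises(ValueError):
            iaddat(grid, CrystalModel(atoms[:1], small_cell))

    def test_minimum_image_distance(self, small_cell):
        # atom at frac 0.98 is 0.4 A from a voxel at frac 0.0 across the
        # cell boundary
        values = np.zeros((10, 10, 10))
        values[0, 0, 0] = 0.1
        grid = DensityGrid(values=values, cell=small_cell)
        model = CrystalModel(
            [Atom("C", np.array([0.98, 0.0, 0.0]), b=10.0, resnum=1, chain="A")],
            small_cell)
        prof = iaddat(grid, model)
        assert prof.values[0] == pytest.approx(0.1)

    def test_normalized_and_frame(self, small_cell):
        prof = IADDATProfile(residue_ids=[("A", 1), ("A", 2)],
                             values=np.array([0.02, 0.04]))
        np.testing.assert_allclose(prof.normalized, [0.5, 1.0])
        frame = prof.to_frame()
        assert list(frame.columns) == ["chain", "resnum", "iaddat",
                                       "iaddat_normalized"]

    def test_delta_iaddat(self):
        p1 = IADDATProfile([("A", 1), ("A", 2)], np.array([0.05, 0.01]))
        p2 = IADDATProfile([("A", 1), ("A", 2)], np.array([0.02, 0.03]))
        d = delta_iaddat(p1, p2)
        np.testing.assert_allclose(d.values, [0.03, 0.02])
        p3 = IADDATProfile([("B", 1)], np.array([0.0]))
        with pytest.raises(ValueError):
            delta_iaddat(p1, p3)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            IADDATConfig(threshold=0.0)
        with pytest.raises(ValueError):
            IADDATConfig(radius=-1.0)


class TestRSCC:
    def _noise_grid(self, small_cell, seed=0, scale=0.1):
        rng = np.random.default_rng(seed)
        return DensityGrid(values=scale * rng.normal(size=(8, 8, 8)),
                           cell=small_cell)

    def test_self_correlation_is_one(self, small_cell):
        g = self._noise_grid(small_cell)
        assert rscc(g, g) == pytest.approx(1.0)

    def test_negated_map_gives_minus_one(self, small_cell):
        g = self._noise_grid(small_cell)
        neg = DensityGrid(values=-g.values, cell=small_cell)
        assert rscc(g, neg) == pytest.approx(-1.0)

    def test_zero_variance_returns_none(self, small_cell):
        g = self._noise_grid(small_cell)
        flat = DensityGrid(values=np.zeros((8, 8, 8)), cell=small_cell)
        assert rscc(g, flat) is None

    def test_threshold_removes_weak_voxels(self, small_cell):
        g1 = self._noise_grid(small_cell, seed=1)
        g2 = self._noise_grid(small_cell, seed=2)
        # with an enormous threshold every voxel zeroes out -> undefined
        assert rscc(g1, g2, threshold=1e9) is None

    def test_shape_mismatch_rejected(self, small_cell):
        g1 = self._noise_grid(small_cell)
        g2 = DensityGrid(values=np.zeros((4, 4, 4)), cell=small_cell)
        with pytest.raises(ValueError, match="dimensions"):
            rscc(g1, g2)

    def test_matrix_symmetric_unit_diagonal(self, small_cell):
        grids = {"a": self._noise_grid(small_cell, 1),
                 "b": self._noise_grid(small_cell, 2)}
        mat = rscc_matrix(grids)
        assert mat.loc["a", "a"] == pytest.approx(1.0)
        assert mat.loc["a", "b"] == pytest.approx(mat.loc["b", "a"])


class TestEndToEndDifferenceMap:
    def test_moved_atom_produces_local_signal(self, noise_free_data):
        """Noise-free pipeline: the weighted difference map's strongest
        features must sit near the displaced loop atoms (within two grid
        spacings of one), far from the unmoved decoys."""
        d = noise_free_data
        ds = weights(difference_structure_factors(d.f_t, d.f_dark1))
        grid = synthesize_map(ds)
        cell = d.ground.cell
        which = np.abs(
            d.excited.frac_coords - d.ground.frac_coords).sum(axis=1) > 0
        # the difference dipole's lobes straddle the ground and excited
        # positions, so measure against the union of the two
        moved = np.vstack([d.ground.frac_coords[which],
                           d.excited.frac_coords[which]])
        assert len(moved) > 0
        flat = np.abs(grid.values).ravel()
        top = np.argsort(flat)[-5:]
        vox = grid.voxel_frac_coords()[top]
        spacing = max(cell.a / grid.shape[0], cell.b / grid.shape[1],
                      cell.c / grid.shape[2])
        orth = cell.orthogonalization_matrix()
        for v in vox:
            delta = moved - v
            delta -= np.round(delta)
            dist = np.linalg.norm(delta @ orth.T, axis=1).min()
            assert dist <= 2.0 * spacing + 1e-9
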