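import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dosekin import (
    AtomSite,
    DensityMap,
    IntegrationSpec,
    MapFeature,
    MapSimConfig,
    StructureFactorSet,
    difference_map,
    gaussian_structure_factors,
    integrate_site,
    map_sigma,
    resample_to_grid,
    scale_amplitudes,
    series_site_kinetics,
    simulate_map_series,
)
from dosekin.density import gaussian_model_structure_factors, synthesize_map

CUBIC = (20.0, 20.0, 20.0, 90.0, 90.0, 90.0)


def brute_force_integrate(values, cell_edge, site_pos, radius, sigma_mult):
    """Reference triple-loop voxel integration (cubic cell, minimum image)."""
    nx, ny, nz = values.shape
    sigma = values.std()
    threshold = sigma_mult * sigma
    pos_sum = neg_sum = 0.0
    n_pos = n_neg = 0
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                d2 = 0.0
                for idx, n, s in ((i, nx, site_pos[0]), (j, ny, site_pos[1]), (k, nz, site_pos[2])):
                    d = idx / n * cell_edge - s
                    d -= cell_edge * round(d / cell_edge)
                    d2 += d * d
                if d2 > radius * radius:
                    continue
                v = values[i, j, k]
                if v > threshold:
                    pos_sum += v
                    n_pos += 1
                elif v < -threshold:
                    neg_sum += v
                    n_neg += 1
    return pos_sum, neg_sum, n_pos, n_neg


def hemisphere_hkl(n):
    out = []
    for h in range(-n, n + 1):
        for k in range(-n, n + 1):
            for l in range(0, n + 1):
                if l == 0 and (k < 0 or (k == 0 and h < 0)):
                    continue
                if h == k == l == 0:
                    continue
                out.append((h, k, l))
    return np.array(out)


class TestMapSigma:
    def test_constant_map_has_zero_sigma(self):
        assert map_sigma(DensityMap(np.full((4, 4, 4), 2.0), CUBIC)) == 0.0

    def test_plus_minus_one_map(self):
        values = np.ones((4, 4, 4))
        values[:2] = -1.0
        assert map_sigma(DensityMap(values, CUBIC)) == pytest.approx(1.0)

    def test_gaussian_noise_map(self):
        rng = np.random.default_rng(5)
        m = DensityMap(rng.normal(0, 0.03, (64, 64, 64)), CUBIC)
        assert map_sigma(m) == pytest.approx(0.03, abs=0.001)


class TestResample:
    def test_identity_on_own_grid(self):
        rng = np.random.default_rng(0)
        m = DensityMap(rng.normal(size=(8, 8, 8)), CUBIC)
        out = resample_to_grid(m, m)
        assert np.array_equal(out.values, m.values)

    def test_constant_map_stays_constant(self):
        m = DensityMap(np.full((8, 8, 8), 1.5), CUBIC)
        ref = DensityMap(np.zeros((12, 12, 12)), CUBIC)
        assert np.allclose(resample_to_grid(m, ref).values, 1.5)

    def test_trilinear_reproduces_linear_ramp(self):
        # ramp along x; trilinear interpolation is exact for linear fields
        # away from the periodic seam (the last fine-grid plane wraps)
        n = 8
        ramp = np.broadcast_to(
            np.arange(n)[:, None, None] / n, (n, n, n)
        ).astype(float)
        m = DensityMap(ramp.copy(), CUBIC)
        ref = DensityMap(np.zeros((2 * n, 2 * n, 2 * n)), CUBIC)
        out = resample_to_grid(m, ref)
        expected = np.arange(2 * n)[: 2 * n - 1] / (2 * n)
        assert np.allclose(out.values[: 2 * n - 1, 0, 0], expected, atol=1e-12)

    def test_incompatible_cells_rejected(self):
        m = DensityMap(np.zeros((4, 4, 4)), CUBIC)
        other = DensityMap(np.zeros((4, 4, 4)), (25, 20, 20, 90, 90, 90))
        with pytest.raises(ValueError):
            resample_to_grid(m, other)


class TestIntegrateSite:
    def test_all_zero_map(self):
        m = DensityMap(np.zeros((8, 8, 8)), CUBIC)
        res = integrate_site(m, AtomSite("X", np.array([10.0, 10.0, 10.0])))
        assert res.positive_sum == 0.0 and res.negative_sum == 0.0

    def test_single_spike_at_site(self):
        values = np.zeros((8, 8, 8))
        values[4, 4, 4] = 5.0
        m = DensityMap(values, CUBIC)
        site = AtomSite("X", np.array([10.0, 10.0, 10.0]))  # voxel (4,4,4)
        res = integrate_site(m, site, IntegrationSpec(radius_a=1.0, sigma_mult=3.0))
        oracle = brute_force_integrate(values, 20.0, (10.0, 10.0, 10.0), 1.0, 3.0)
        assert res.positive_sum == pytest.approx(5.0)
        assert (res.positive_sum, res.negative_sum, res.n_pos, res.n_neg) == pytest.approx(oracle)

    def test_gaussian_feature_matches_oracle_voxel_for_voxel(self):
        cfg = MapSimConfig(
            grid=(16, 16, 16),
            cell_a=20.0,
            features=(MapFeature((10, 10, 10), -0.15, 0.5, 79.5),),
            noise_sd=0.02,
            doses_kgy=np.array([200.0]),
            seed=9,
        )
        maps, _ = simulate_map_series(cfg)
        site = AtomSite("FE", np.array([10.0, 10.0, 10.0]))
        res = integrate_site(maps[0], site, IntegrationSpec(1.0, 3.0))
        oracle = brute_force_integrate(maps[0].values, 20.0, (10.0, 10.0, 10.0), 1.0, 3.0)
        assert (res.positive_sum, res.negative_sum, res.n_pos, res.n_neg) == pytest.approx(oracle)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_random_maps_match_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        edge = float(rng.uniform(5, 30))
        values = rng.normal(0, 1, (n, n, n))
        site_pos = rng.uniform(0, edge, 3)
        radius = float(rng.uniform(0.3, edge / 2.5))
        sigma_mult = float(rng.uniform(0, 3))
        cell = (edge, edge, edge, 90.0, 90.0, 90.0)
        res = integrate_site(
            DensityMap(values, cell),
            AtomSite("X", site_pos),
            IntegrationSpec(radius, sigma_mult),
        )
        oracle = brute_force_integrate(values, edge, site_pos, radius, sigma_mult)
        assert (res.positive_sum, res.negative_sum, res.n_pos, res.n_neg) == pytest.approx(oracle)

    def test_positive_scaling_covariance(self):
        rng = np.random.default_rng(2)
        values = rng.normal(0, 1, (12, 12, 12))
        site = AtomSite("X", np.array([5.0, 5.0, 5.0]))
        spec = IntegrationSpec(3.0, 2.0)
        base = integrate_site(DensityMap(values, CUBIC), site, spec)
        scaled = integrate_site(DensityMap(4.0 * values, CUBIC), site, spec)
        assert scaled.map_sigma == pytest.approx(4.0 * base.map_sigma)
        assert scaled.n_pos == base.n_pos and scaled.n_neg == base.n_neg
        assert scaled.positive_sum == pytest.approx(4.0 * base.positive_sum)
        assert scaled.negative_sum == pytest.approx(4.0 * base.negative_sum)

    def test_negation_antisymmetry(self):
        rng = np.random.default_rng(3)
        values = rng.normal(0, 1, (10, 10, 10))
        site = AtomSite("X", np.array([3.0, 17.0, 9.0]))
        spec = IntegrationSpec(2.5, 1.5)
        a = integrate_site(DensityMap(values, CUBIC), site, spec)
        b = integrate_site(DensityMap(-values, CUBIC), site, spec)
        assert b.negative_sum == pytest.approx(-a.positive_sum)
        assert b.positive_sum == pytest.approx(-a.negative_sum)

    def test_lattice_translation_invariance(self):
        rng = np.random.default_rng(4)
        values = rng.normal(0, 1, (8, 8, 8))
        shift_vox = 3  # shift by 3 voxels = 7.5 A along x
        shifted = np.roll(values, shift_vox, axis=0)
        site = AtomSite("X", np.array([6.0, 11.0, 2.0]))
        site_shifted = AtomSite("X", site.position + np.array([7.5, 0.0, 0.0]))
        spec = IntegrationSpec(2.0, 1.0)
        a = integrate_site(DensityMap(values, CUBIC), site, spec)
        b = integrate_site(DensityMap(shifted, CUBIC), site_shifted, spec)
        assert (a.positive_sum, a.negative_sum, a.n_pos, a.n_neg) == pytest.approx(
            (b.positive_sum, b.negative_sum, b.n_pos, b.n_neg)
        )

    def test_empty_sphere_warns_and_returns_zero_counts(self):
        m = DensityMap(np.ones((4, 4, 4)), CUBIC)  # 5 A voxels
        site = AtomSite("X", np.array([2.5, 2.5, 2.5]))  # between voxel centres
        with pytest.warns(UserWarning):
            res = integrate_site(m, site, IntegrationSpec(radius_a=0.5))
        assert res.n_pos == 0 and res.n_neg == 0


class TestScaleAmplitudes:
    def _sets(self, amp_n, amp_ref):
        hkl = hemisphere_hkl(2)
        m = min(len(hkl), len(amp_n))
        return (
            StructureFactorSet(hkl[:m], amp_n[:m], None, CUBIC),
            StructureFactorSet(hkl[:m], amp_ref[:m], None, CUBIC),
        )

    def test_identical_sets_scale_to_one(self):
        rng = np.random.default_rng(0)
        amp = rng.uniform(1, 10, 30)
        f_n, f_ref = self._sets(amp, amp)
        assert scale_amplitudes(f_n, f_ref) == pytest.approx(1.0)

    def test_doubled_amplitudes_scale_to_half(self):
        rng = np.random.default_rng(1)
        amp = rng.uniform(1, 10, 30)
        f_n, f_ref = self._sets(2 * amp, amp)
        assert scale_amplitudes(f_n, f_ref) == pytest.approx(0.5)

    def test_randomized_amplitudes_match_closed_form(self):
        rng = np.random.default_rng(2)
        amp_n = rng.uniform(1, 10, 30)
        amp_ref = rng.uniform(1, 10, 30)
        f_n, f_ref = self._sets(amp_n, amp_ref)
        expected = np.sum(amp_ref * amp_n) / np.sum(amp_n**2)
        assert scale_amplitudes(f_n, f_ref) == pytest.approx(expected)

    def test_too_few_common_reflections(self):
        hkl = hemisphere_hkl(1)[:5]
        a = StructureFactorSet(hkl, np.ones(5), None, CUBIC)
        with pytest.raises(ValueError):
            scale_amplitudes(a, a)


class TestDifferenceMap:
    def test_identical_sets_give_zero_map(self):
        hkl = hemisphere_hkl(6)
        sf = gaussian_structure_factors(hkl, CUBIC, (10, 5, 7), 0.5, 0.8)
        dm = difference_map(sf, sf)
        assert np.abs(dm.values).max() < 1e-10

    def test_synthesis_reproduces_gaussian_blob(self):
        hkl = hemisphere_hkl(12)
        sf = gaussian_structure_factors(hkl, CUBIC, (10, 5, 7), 0.5, 0.8)
        coeffs = sf.amplitude * np.exp(1j * np.radians(sf.phase_deg))
        m = synthesize_map(hkl, coeffs, CUBIC, (48, 48, 48))
        ijk = np.unravel_index(np.argmax(m.values), m.shape)
        peak_pos = np.array(ijk) / 48 * 20
        assert np.allclose(peak_pos, (10, 5, 7), atol=20 / 48)
        # peak value approaches the blob amplitude (band-limited truncation)
        assert m.values.max() == pytest.approx(0.5, rel=0.05)

    def test_displaced_atom_gives_flanking_peak_pair(self):
        hkl = hemisphere_hkl(12)
        anchor = ((4.0, 4.0, 4.0), 1.0, 0.9)
        f1 = gaussian_model_structure_factors(
            hkl, CUBIC, [anchor, ((10, 10, 10.0), 0.8, 0.8)]
        )
        fn = gaussian_model_structure_factors(
            hkl, CUBIC, [anchor, ((10, 10, 10.5), 0.8, 0.8)]
        )
        dm = difference_map(fn, f1, phases_from=f1)
        g = np.array(dm.shape)
        pos = np.array(np.unravel_index(np.argmax(dm.values), dm.shape)) / g * 20
        neg = np.array(np.unravel_index(np.argmin(dm.values), dm.shape)) / g * 20
        # paired peaks on the displacement axis: negative behind the old
        # position, positive ahead of the new one
        assert neg[2] < 10.0 < 10.5 < pos[2]
        assert np.allclose(pos[:2], (10, 10), atol=0.5)
        assert np.allclose(neg[:2], (10, 10), atol=0.5)

    def test_scaling_invariance_through_amplitude_scaling(self):
        hkl = hemisphere_hkl(8)
        anchor = ((4.0, 4.0, 4.0), 1.0, 0.9)
        f1 = gaussian_model_structure_factors(
            hkl, CUBIC, [anchor, ((10, 10, 10.0), 0.8, 0.8)]
        )
        fn = gaussian_model_structure_factors(
            hkl, CUBIC, [anchor, ((10, 10, 10.5), 0.8, 0.8)]
        )
        scaled = StructureFactorSet(fn.hkl, 2.7 * fn.amplitude, fn.phase_deg, CUBIC)
        base = difference_map(fn, f1, phases_from=f1, shape=(32, 32, 32))
        corrected = difference_map(scaled, f1, phases_from=f1, shape=(32, 32, 32))
        # least-squares scaling undoes the overall factor exactly
        assert np.allclose(corrected.values, base.values, atol=1e-8)

    def test_linearity_of_synthesis(self):
        hkl = hemisphere_hkl(4)
        rng = np.random.default_rng(6)
        n = len(hkl)
        f1 = StructureFactorSet(
            hkl, rng.uniform(0.0, 0.5, n), rng.uniform(-180, 180, n), CUBIC
        )
        fa = StructureFactorSet(hkl, rng.uniform(1, 2, n), None, CUBIC)
        fb = StructureFactorSet(hkl, rng.uniform(1, 2, n), None, CUBIC)
        fc = StructureFactorSet(hkl, fa.amplitude + fb.amplitude - f1.amplitude, None, CUBIC)
        shape = (16, 16, 16)
        ma = difference_map(fa, f1, shape=shape, scale=1.0)
        mb = difference_map(fb, f1, shape=shape, scale=1.0)
        mc = difference_map(fc, f1, shape=shape, scale=1.0)
        assert np.allclose(ma.values + mb.values, mc.values, atol=1e-10)

    def test_missing_phases_rejected(self):
        hkl = hemisphere_hkl(2)
        sf = StructureFactorSet(hkl, np.ones(len(hkl)), None, CUBIC)
        with pytest.raises(ValueError):
            difference_map(sf, sf)


class TestCcp4RoundTrip:
    def test_write_read_preserves_grid_and_cell(self, tmp_path):
        rng = np.random.default_rng(8)
        m = DensityMap(rng.normal(0, 0.1, (16, 16, 16)), CUBIC)
        path = tmp_path / "map.ccp4"
        m.to_ccp4(path)
        back = DensityMap.from_ccp4(path)
        assert back.shape == m.shape
        assert np.allclose(back.cell, m.cell, atol=1e-4)
        assert np.allclose(back.values, m.values, atol=1e-6)  # float32 storage


class TestSeriesKinetics:
    def test_constant_zero_maps_flagged(self):
        maps = [DensityMap(np.zeros((8, 8, 8)), CUBIC) for _ in range(6)]
        doses = np.arange(6) * 10.0
        table, fit = series_site_kinetics(
            maps, doses, AtomSite("X", np.array([10.0, 10.0, 10.0]))
        )
        assert np.allclose(table["negative_sum"], 0)
        assert fit is not None and not fit.converged

    def test_single_map_skips_fit_with_warning(self):
        maps = [DensityMap(np.zeros((8, 8, 8)), CUBIC)]
        with pytest.warns(UserWarning):
            table, fit = series_site_kinetics(
                maps, [10.0], AtomSite("X", np.array([1.0, 1.0, 1.0]))
            )
        assert len(table) == 1 and fit is None

    def test_growing_negative_feature_recovers_dose_constant(self):
        cfg = MapSimConfig(
            grid=(48, 48, 48),
            features=(MapFeature((10, 10, 10), -0.15, 0.5, 79.5),),
            noise_sd=0.0075,
            doses_kgy=np.linspace(14.4, 450, 20),
            seed=0,
        )
        maps, doses = simulate_map_series(cfg)
        table, fit = series_site_kinetics(
            maps, doses, AtomSite("FE", np.array([10.0, 10.0, 10.0]))
        )
        assert fit.converged and fit.direction == "rise"
        assert fit.tau_kgy == pytest.approx(79.5, rel=0.10)

    def test_joint_permutation_of_maps_and_doses_is_invariant(self):
        cfg = MapSimConfig(
            grid=(16, 16, 16),
            features=(MapFeature((10, 10, 10), -0.2, 0.8, 50.0),),
            noise_sd=0.01,
            doses_kgy=np.linspace(0, 200, 8),
            seed=1,
        )
        maps, doses = simulate_map_series(cfg)
        site = AtomSite("X", np.array([10.0, 10.0, 10.0]))
        _, fit = series_site_kinetics(maps, doses, site)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(maps))
        _, fit_perm = series_site_kinetics(
            [maps[i] for i in perm], doses[perm], site
        )
        assert fit_perm.tau_kgy == pytest.approx(fit.tau_kgy, rel=1e-9)

    def test_map_dose_count_mismatch_rejected(self):
        maps = [DensityMap(np.zeros((4, 4, 4)), CUBIC)] * 3
        with pytest.raises(ValueError):
            series_site_kinetics(maps, [0.0, 1.0], AtomSite("X", np.zeros(3)))
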