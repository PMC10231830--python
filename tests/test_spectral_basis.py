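"""Dye spectra, three-channel bases, projection, and sRGB rendering."""

import numpy as np
import pytest

from spectralstain.hsi_core import HyperspectralCube, make_wavelength_grid
from spectralstain.spectral_basis import (
    BasisSet,
    ColorimetricSystem,
    DyeSpectrum,
    basis_channel_select,
    basis_ldf_dyes,
    basis_ldf_pca,
    cie_1931_cmf,
    cube_to_srgb,
    default_colorimetric_system,
    default_eosin,
    default_hematoxylin,
    derive_ldf_lda,
    project_cube,
    spectral_pca,
    transmittance_from_absorbance,
)
from spectralstain.synthetic_data import PhantomConfig, labeled_spectra


class TestBeerLambert:
    @pytest.mark.parametrize("a,t", [(0.0, 1.0), (1.0, 0.1), (2.0, 0.01)])
    def test_absorbance_inversion(self, grid61, a, t):
        spec = DyeSpectrum(np.full(61, a), grid61)
        assert np.allclose(transmittance_from_absorbance(spec), t)

    def test_negative_absorbance_rejected(self, grid61):
        with pytest.raises(ValueError, match="nonnegative"):
            DyeSpectrum(np.full(61, -0.1), grid61)


class TestChannelSelectBasis:
    def test_default_channels_select_465_470_475(self, grid61):
        basis = basis_channel_select(grid61)
        wavelengths = [grid61.values[np.argmax(row)] for row in basis.matrix]
        assert wavelengths == [465, 470, 475]
        assert np.all(basis.matrix.sum(axis=1) == 1)

    def test_projection_equals_band_slicing(self, random_cube):
        basis = basis_channel_select(random_cube.grid, channels=(10, 11, 12))
        out = project_cube(random_cube, basis)
        assert np.allclose(out, random_cube.data[:, :, [9, 10, 11]])

    def test_out_of_range_channel_rejected(self, grid61):
        with pytest.raises(ValueError, match="out of range"):
            basis_channel_select(grid61, channels=(10, 11, 62))


class TestPcaBasis:
    def test_rank_two_data_fully_explained(self, grid61, rng):
        # pixels confined to a 2-D spectral subspace
        u = rng.uniform(size=61)
        v = rng.uniform(size=61)
        coeffs = rng.uniform(0, 1, size=(100, 2))
        pixels = coeffs @ np.vstack([u, v])
        cube = HyperspectralCube(pixels.reshape(10, 10, 61), grid61)
        _, evr = spectral_pca([cube], 2)
        assert evr.sum() == pytest.approx(1.0, abs=1e-10)

    def test_matches_dense_eigendecomposition_oracle(self, grid61, rng):
        pixels = rng.uniform(0, 1, size=(50, 61))
        cube = HyperspectralCube(pixels.reshape(5, 10, 61), grid61)
        comps, evr = spectral_pca([cube], 2)
        # independent oracle: explicit covariance + eigh
        x = pixels - pixels.mean(axis=0)
        evals, evecs = np.linalg.eigh(np.cov(x, rowvar=False))
        order = np.argsort(evals)[::-1]
        for k in range(2):
            v = evecs[:, order[k]]
            v = v if v[np.argmax(np.abs(v))] > 0 else -v
            assert np.allclose(comps[k], v, atol=1e-8)
            assert evr[k] == pytest.approx(evals[order[k]] / evals.sum())

    def test_components_orthonormal_and_variance_ordered(self, phantom):
        comps, evr = spectral_pca([phantom.he_cube], 3)
        assert np.allclose(comps @ comps.T, np.eye(3), atol=1e-8)
        assert np.all(np.diff(evr) <= 1e-12) and evr.sum() <= 1.0 + 1e-12

    def test_sklearn_pca_cross_check(self, phantom):
        from sklearn.decomposition import PCA

        comps, evr = spectral_pca([phantom.he_cube], 2)
        flat = phantom.he_cube.data.reshape(-1, 61)
        ref = PCA(n_components=2).fit(flat)
        for k in range(2):
            dot = abs(float(comps[k] @ ref.components_[k]))
            assert dot == pytest.approx(1.0, abs=1e-6)
        assert np.allclose(evr, ref.explained_variance_ratio_, atol=1e-8)

    def test_rank_deficient_rejected(self, grid61):
        flat = np.ones((20, 61))  # zero variance
        cube = HyperspectralCube(flat.reshape(4, 5, 61), grid61)
        with pytest.raises(ValueError, match="components"):
            spectral_pca([cube], 2)

    def test_ldf_pca_basis_rows(self, grid61, phantom):
        ldf = np.linspace(-1, 1, 61)
        basis = basis_ldf_pca(ldf, [phantom.he_cube])
        assert basis.row_names == ["PC1", "PC2", "LDF"]
        assert np.array_equal(basis.matrix[2], ldf)


class TestLdfDyeBasis:
    def test_zero_absorbance_eosin_row_is_ones(self, grid61):
        ldf = np.ones(61)
        eosin = DyeSpectrum(np.zeros(61), grid61, "eosin")
        hema = default_hematoxylin(grid61)
        basis = basis_ldf_dyes(ldf, hema, eosin)
        assert np.allclose(basis.matrix[1], 1.0)

    def test_shape_and_row_names(self, grid61):
        basis = basis_ldf_dyes(
            np.ones(61), default_hematoxylin(grid61), default_eosin(grid61)
        )
        assert basis.matrix.shape == (3, 61)
        assert basis.row_names == ["LDF", "eosin_T", "hematoxylin_T"]

    def test_grid_mismatch_rejected(self, grid61):
        other = make_wavelength_grid(400, 700, 5)
        with pytest.raises(ValueError, match="grids"):
            basis_ldf_dyes(
                np.ones(61), default_hematoxylin(grid61), default_eosin(other)
            )


class TestProjection:
    def test_matches_per_pixel_dot_product_oracle(self, grid61, rng):
        cube = HyperspectralCube(rng.uniform(0, 1, size=(2, 2, 61)), grid61)
        basis = BasisSet(rng.normal(size=(3, 61)), ["a", "b", "c"], grid61)
        out = project_cube(cube, basis)
        for h in range(2):
            for w in range(2):
                for k in range(3):
                    expect = sum(
                        basis.matrix[k, b] * cube.data[h, w, b] for b in range(61)
                    )
                    assert out[h, w, k] == pytest.approx(expect, rel=1e-12)

    def test_linearity(self, grid61, rng):
        x = rng.uniform(size=(3, 3, 61))
        y = rng.uniform(size=(3, 3, 61))
        basis = BasisSet(rng.normal(size=(3, 61)), ["a", "b", "c"], grid61)
        left = project_cube(HyperspectralCube(2 * x + 3 * y, grid61), basis)
        right = 2 * project_cube(HyperspectralCube(x, grid61), basis) + 3 * project_cube(
            HyperspectralCube(y, grid61), basis
        )
        assert np.allclose(left, right)

    def test_grid_mismatch_rejected(self, random_cube):
        other = make_wavelength_grid(400, 700, 5)
        basis = BasisSet(np.ones((3, other.count)), ["a", "b", "c"], other)
        with pytest.raises(ValueError, match="grids"):
            project_cube(random_cube, basis)

    def test_all_zero_row_rejected(self, grid61):
        m = np.ones((3, 61))
        m[1] = 0.0
        with pytest.raises(ValueError, match="zero row"):
            BasisSet(m, ["a", "b", "c"], grid61)


class TestSrgbRendering:
    def test_perfect_transmitter_is_white(self, grid61):
        cube = HyperspectralCube(np.ones((2, 2, 61)), grid61)
        assert np.all(cube_to_srgb(cube) == 255)

    def test_opaque_specimen_is_black(self, grid61):
        cube = HyperspectralCube(np.zeros((2, 2, 61)), grid61)
        assert np.all(cube_to_srgb(cube) == 0)

    def test_single_pixel_matches_quadrature_oracle(self, grid61, rng):
        t = rng.uniform(0.2, 1.0, size=(1, 1, 61))
        cube = HyperspectralCube(t, grid61)
        cs = default_colorimetric_system(grid61)
        got = cube_to_srgb(cube, cs)[0, 0].astype(float)
        # independent summation using the same CMF table
        xyz = np.zeros(3)
        for b in range(61):
            xyz += cs.illuminant[b] * t[0, 0, b] * cs.cmf[:, b] * 5.0
        white = np.array(
            [sum(cs.illuminant[b] * cs.cmf[i, b] * 5.0 for b in range(61)) for i in range(3)]
        )
        m = np.array(
            [[3.2406, -1.5372, -0.4986], [-0.9689, 1.8758, 0.0415], [0.0557, -0.2040, 1.0570]]
        )
        disp_white = np.linalg.solve(m, np.ones(3))
        lin = m @ (xyz / white * disp_white)
        lin = np.clip(lin, 0, 1)
        srgb = np.where(lin <= 0.0031308, 12.92 * lin, 1.055 * lin ** (1 / 2.4) - 0.055)
        assert np.all(np.abs(got - np.round(srgb * 255)) <= 1)

    def test_monotone_in_overall_brightness(self, grid61, rng):
        t = rng.uniform(0.1, 0.6, size=(2, 2, 61))
        low = cube_to_srgb(HyperspectralCube(t, grid61)).astype(int)
        high = cube_to_srgb(HyperspectralCube(1.3 * t, grid61)).astype(int)
        assert np.all(high >= low)

    def test_cmf_peaks_in_expected_bands(self, grid61):
        cmf = cie_1931_cmf(grid61)
        wl = grid61.values
        assert 590 <= wl[np.argmax(cmf[0])] <= 610  # xbar main lobe
        assert 545 <= wl[np.argmax(cmf[1])] <= 565  # ybar
        assert 440 <= wl[np.argmax(cmf[2])] <= 455  # zbar

    def test_grid_mismatch_rejected(self, random_cube):
        other = make_wavelength_grid(400, 700, 5)
        cs = default_colorimetric_system(other)
        with pytest.raises(ValueError, match="grids"):
            cube_to_srgb(random_cube, cs)


class TestBasisSerialization:
    def test_csv_roundtrip(self, grid61, rng):
        basis = BasisSet(rng.normal(size=(3, 61)), ["LDF", "eosin_T", "hematoxylin_T"], grid61)
        back = BasisSet.from_csv(basis.to_csv())
        assert back.row_names == basis.row_names
        assert np.allclose(back.matrix, basis.matrix, atol=1e-9)
        assert back.grid == basis.grid


class TestFallbackLdf:
    def test_separates_beer_lambert_dye_concentrations(self, grid61):
        elastic, collagen = labeled_spectra(PhantomConfig(seed=5), n_per_class=80)
        w = derive_ldf_lda(elastic, collagen)
        assert w.shape == (61,)
        assert np.mean(elastic @ w) > np.mean(collagen @ w)

    def test_single_dye_concentration_ordering_is_monotone(self, grid61):
        # projecting pure-eosin Beer-Lambert spectra onto the eosin
        # transmittance row orders concentrations monotonically
        eosin = default_eosin(grid61)
        concentrations = np.linspace(0.1, 1.5, 8)
        spectra = np.power(10.0, -np.outer(concentrations, eosin.absorbance))
        basis = basis_ldf_dyes(
            np.ones(61), default_hematoxylin(grid61), eosin
        )
        scores = spectra @ basis.matrix[1]
        assert np.all(np.diff(scores) < 0)
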