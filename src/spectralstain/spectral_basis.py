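"""Three-channel spectral bases and colorimetric rendering.

The identity mapping of the stain-conversion network needs the 61-band
H&E cube collapsed to 3 channels. Three candidate bases are provided:

* plain band selection (channels 10/11/12 = 465/470/475 nm by default),
* the first two principal components of pooled pixel spectra plus a
  linear discriminant function (LDF) separating elastic from collagen
  spectra,
* the LDF together with the eosin and hematoxylin transmittance spectra
  obtained from their absorbance via Beer-Lambert (T = 10**-A).

Rendering to sRGB integrates transmittance against CIE 1931 colour
matching functions under a configurable illuminant, normalised so that a
perfect transmitter maps to pure white.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from .hsi_core import HyperspectralCube, WavelengthGrid

__all__ = [
    "BasisSet",
    "DyeSpectrum",
    "ColorimetricSystem",
    "transmittance_from_absorbance",
    "basis_channel_select",
    "basis_ldf_pca",
    "basis_ldf_dyes",
    "project_cube",
    "cube_to_srgb",
    "cie_1931_cmf",
    "default_colorimetric_system",
    "default_hematoxylin",
    "default_eosin",
    "derive_ldf_lda",
]


@dataclass
class DyeSpectrum:
    """Nonnegative absorbance spectrum A(lambda) on a wavelength grid."""

    absorbance: np.ndarray
    grid: WavelengthGrid
    name: str = ""

    def __post_init__(self):
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.ndim != 1 or len(self.absorbance) != self.grid.count:
            raise ValueError("absorbance length must match the grid")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance must be finite")
        if np.any(self.absorbance < 0):
            raise ValueError("absorbance must be nonnegative")


@dataclass
class BasisSet:
    """A 3 x B projection matrix with named rows."""

    matrix: np.ndarray
    row_names: list
    grid: WavelengthGrid

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, self.grid.count):
            raise ValueError(
                f"basis must be 3 x {self.grid.count}, got {self.matrix.shape}"
            )
        if len(self.row_names) != 3:
            raise ValueError("exactly 3 row names required")
        if np.any(np.all(self.matrix == 0, axis=1)):
            raise ValueError("basis contains an all-zero row")

    def normalized(self) -> "BasisSet":
        """Per-row max-|coefficient| normalisation (conditioning option)."""
        scale = np.abs(self.matrix).max(axis=1, keepdims=True)
        return BasisSet(self.matrix / scale, list(self.row_names), self.grid)

    def to_csv(self) -> str:
        buf = io.StringIO()
        buf.write("wavelength_nm," + ",".join(self.row_names) + "\n")
        for i, wl in enumerate(self.grid.values):
            row = ",".join(f"{v:.10g}" for v in self.matrix[:, i])
            buf.write(f"{wl:g},{row}\n")
        return buf.getvalue()

    @classmethod
    def from_csv(cls, text: str) -> "BasisSet":
        lines = [l for l in text.strip().splitlines() if l.strip()]
        names = lines[0].split(",")[1:]
        wl, cols = [], []
        for line in lines[1:]:
            parts = line.split(",")
            wl.append(float(parts[0]))
            cols.append([float(p) for p in parts[1:]])
        wl = np.asarray(wl)
        step = wl[1] - wl[0] if len(wl) > 1 else 5.0
        grid = WavelengthGrid(wl[0], wl[-1], step)
        return cls(np.asarray(cols).T, names, grid)


@dataclass
class ColorimetricSystem:
    """CIE colour-matching functions and illuminant sampled on a grid."""

    cmf: np.ndarray  # 3 x B rows (xbar, ybar, zbar)
    illuminant: np.ndarray  # length B relative spectral power
    grid: WavelengthGrid

    def __post_init__(self):
        self.cmf = np.asarray(self.cmf, dtype=float)
        self.illuminant = np.asarray(self.illuminant, dtype=float)
        if self.cmf.shape != (3, self.grid.count):
            raise ValueError("cmf must be 3 x B")
        if self.illuminant.shape != (self.grid.count,):
            raise ValueError("illuminant length must match the grid")
        if np.any(self.cmf[1] < 0) or np.any(self.illuminant < 0):
            raise ValueError("ybar and illuminant must be nonnegative")


def transmittance_from_absorbance(spec: DyeSpectrum) -> np.ndarray:
    """Beer-Lambert inversion T = 10**(-A); output in (0, 1]."""
    return np.power(10.0, -spec.absorbance)


def basis_channel_select(grid: WavelengthGrid, channels=(10, 11, 12)) -> BasisSet:
    """One-hot basis selecting three bands by 1-based channel number.

    On the 420-720 nm / 5 nm grid the default picks 465, 470 and 475 nm.
    """
    channels = list(channels)
    if len(channels) != 3:
        raise ValueError("exactly 3 channels required")
    m = np.zeros((3, grid.count))
    names = []
    for k, ch in enumerate(channels):
        wl = grid.band_wavelength(ch)  # validates range
        m[k, ch - 1] = 1.0
        names.append(f"band_{wl:g}nm")
    return BasisSet(m, names, grid)


def _pooled_pixel_matrix(training_cubes) -> tuple[np.ndarray, WavelengthGrid]:
    cubes = list(training_cubes)
    if not cubes:
        raise ValueError("at least one training cube required")
    grid = cubes[0].grid
    rows = []
    for c in cubes:
        if c.grid != grid:
            raise ValueError("training cubes are on different grids")
        rows.append(c.data.reshape(-1, c.n_bands))
    return np.concatenate(rows, axis=0), grid


def spectral_pca(training_cubes, n_components: int = 2):
    """Covariance PCA of pooled, mean-centred pixel spectra.

    Returns (components (k, B), explained_variance_ratio (k,)). Components
    have their sign fixed so the largest-magnitude coefficient is positive.
    """
    x, _ = _pooled_pixel_matrix(training_cubes)
    x = x - x.mean(axis=0)
    cov = (x.T @ x) / (x.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    total = evals.sum()
    if total <= 0 or np.count_nonzero(evals > 1e-12 * max(total, 1.0)) < n_components:
        raise ValueError(
            f"pixel matrix supports fewer than {n_components} components"
        )
    comps = []
    for k in range(n_components):
        v = evecs[:, k]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        comps.append(v)
    return np.array(comps), evals[:n_components] / total


def basis_ldf_pca(ldf: np.ndarray, training_cubes) -> BasisSet:
    """Basis of [PC1, PC2, LDF] from pooled training-pixel spectra."""
    ldf = np.asarray(ldf, dtype=float)
    comps, _ = spectral_pca(training_cubes, n_components=2)
    grid = list(training_cubes)[0].grid
    if ldf.shape != (grid.count,):
        raise ValueError("ldf length must match the cube grid")
    return BasisSet(
        np.vstack([comps, ldf]), ["PC1", "PC2", "LDF"], grid
    )


def basis_ldf_dyes(
    ldf: np.ndarray, hematoxylin: DyeSpectrum, eosin: DyeSpectrum
) -> BasisSet:
    """Basis of [LDF, eosin transmittance, hematoxylin transmittance]."""
    if hematoxylin.grid != eosin.grid:
        raise ValueError("dye spectra are on different grids")
    grid = hematoxylin.grid
    ldf = np.asarray(ldf, dtype=float)
    if ldf.shape != (grid.count,):
        raise ValueError("ldf length must match the dye grid")
    m = np.vstack(
        [
            ldf,
            transmittance_from_absorbance(eosin),
            transmittance_from_absorbance(hematoxylin),
        ]
    )
    return BasisSet(m, ["LDF", "eosin_T", "hematoxylin_T"], grid)


def project_cube(cube: HyperspectralCube, basis: BasisSet) -> np.ndarray:
    """Collapse a cube to 3 channels: out[...,k] = sum_b basis[k,b]*cube[...,b]."""
    if cube.grid != basis.grid:
        raise ValueError("cube and basis are on different wavelength grids")
    return np.tensordot(cube.data, basis.matrix, axes=([2], [1]))


# ---------------------------------------------------------------------------
# Colorimetry


def _gauss_lobe(wl, mu, s1, s2):
    s = np.where(wl < mu, s1, s2)
    return np.exp(-0.5 * ((wl - mu) / s) ** 2)


def cie_1931_cmf(grid: WavelengthGrid) -> np.ndarray:
    """CIE 1931 2-degree observer sampled on the grid (analytic fit).

    Uses the Wyman-Sloan-Shirley multi-lobe Gaussian approximation, which
    matches the tabulated observer to a few parts in a thousand over the
    visible range.
    """
    wl = grid.values
    x = (
        1.056 * _gauss_lobe(wl, 599.8, 37.9, 31.0)
        + 0.362 * _gauss_lobe(wl, 442.0, 16.0, 26.7)
        - 0.065 * _gauss_lobe(wl, 501.1, 20.4, 26.2)
    )
    y = 0.821 * _gauss_lobe(wl, 568.8, 46.9, 40.5) + 0.286 * _gauss_lobe(
        wl, 530.9, 16.3, 31.1
    )
    z = 1.217 * _gauss_lobe(wl, 437.0, 11.8, 36.0) + 0.681 * _gauss_lobe(
        wl, 459.0, 26.0, 13.8
    )
    return np.vstack([x, y, z])


def default_colorimetric_system(grid: WavelengthGrid) -> ColorimetricSystem:
    """CIE 1931 observer with an equal-energy illuminant.

    The microscope's LED spectrum is acquisition-specific; supply a
    measured illuminant for device-accurate colour.
    """
    return ColorimetricSystem(cie_1931_cmf(grid), np.ones(grid.count), grid)


# XYZ -> linear sRGB (IEC 61966-2-1, D65 white)
_XYZ_TO_SRGB = np.array(
    [
        [3.2406, -1.5372, -0.4986],
        [-0.9689, 1.8758, 0.0415],
        [0.0557, -0.2040, 1.0570],
    ]
)


def _srgb_gamma(linear: np.ndarray) -> np.ndarray:
    a = 0.055
    return np.where(
        linear <= 0.0031308,
        12.92 * linear,
        (1 + a) * np.power(np.clip(linear, 0, None), 1 / 2.4) - a,
    )


def cube_to_srgb(cube: HyperspectralCube, cs: ColorimetricSystem | None = None) -> np.ndarray:
    """Render a transmittance cube to an 8-bit sRGB image.

    The spectral integral XYZ = sum_b S(b) T(b) cmf(:,b) dlambda is
    normalised per channel so a perfect transmitter (T = 1 everywhere)
    lands exactly on the display white point, then mapped through the
    standard XYZ->linear-sRGB matrix and gamma encoding.
    """
    if cs is None:
        cs = default_colorimetric_system(cube.grid)
    if cube.grid != cs.grid:
        raise ValueError("cube and colorimetric system grids differ")
    dl = cube.grid.step_nm
    weights = cs.illuminant[None, :] * cs.cmf * dl  # 3 x B
    xyz = np.tensordot(cube.data, weights, axes=([2], [1]))  # H x W x 3
    white_xyz = weights.sum(axis=1)  # XYZ of the perfect transmitter
    if np.any(white_xyz <= 0):
        raise ValueError("illuminant carries no energy in some channel")
    # white point of the sRGB display: M^-1 @ (1,1,1)
    display_white = np.linalg.solve(_XYZ_TO_SRGB, np.ones(3))
    xyz = xyz / white_xyz * display_white
    rgb_lin = xyz @ _XYZ_TO_SRGB.T
    rgb = _srgb_gamma(np.clip(rgb_lin, 0.0, 1.0))
    return np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Stand-in dye spectra and fallback LDF
#
# The published H&E absorbance curves and the elastic/collagen linear
# discriminant coefficients are not shipped with this package; the
# functions below provide smooth synthetic stand-ins so the pipeline runs
# end-to-end without external data. Replace them with measured spectra
# for real acquisitions.


def default_hematoxylin(grid: WavelengthGrid, amplitude: float = 1.0) -> DyeSpectrum:
    """Synthetic hematoxylin absorbance: broad peak near 605 nm.

    Absorbing orange/red light renders hematoxylin-rich structures
    (nuclei) bluish, as in real H&E.
    """
    wl = grid.values
    a = amplitude * np.exp(-0.5 * ((wl - 605.0) / 45.0) ** 2)
    return DyeSpectrum(a, grid, "hematoxylin(synthetic)")


def default_eosin(grid: WavelengthGrid, amplitude: float = 1.0) -> DyeSpectrum:
    """Synthetic eosin absorbance: peak near 525 nm (renders pink)."""
    wl = grid.values
    a = amplitude * np.exp(-0.5 * ((wl - 525.0) / 22.0) ** 2)
    return DyeSpectrum(a, grid, "eosin(synthetic)")


def derive_ldf_lda(elastic_spectra: np.ndarray, collagen_spectra: np.ndarray) -> np.ndarray:
    """Fallback LDF: two-class linear discriminant on labelled spectra.

    Returns a unit-norm length-B weight vector oriented so elastic
    spectra score higher than collagen spectra on average.
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    x = np.vstack([elastic_spectra, collagen_spectra])
    y = np.r_[
        np.ones(len(elastic_spectra), dtype=int),
        np.zeros(len(collagen_spectra), dtype=int),
    ]
    lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    lda.fit(x, y)
    w = lda.coef_.ravel()
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("degenerate discriminant: classes indistinguishable")
    w = w / norm
    if np.mean(elastic_spectra @ w) < np.mean(collagen_spectra @ w):  # orient
        w = -w
    return w
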