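"""Hyperspectral cube data model, calibration, and file I/O.

A transmittance cube is an ``H x W x B`` array with an attached uniformly
spaced wavelength grid (nm). Calibration converts raw camera counts to
transmittance using dark- and white-reference frames normalised by their
exposure times. Band indices exposed to users are 1-based, so that on the
420-720 nm / 5 nm grid "channels 10, 11, 12" name the 465/470/475 nm bands.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "WavelengthGrid",
    "HyperspectralCube",
    "CalibrationSet",
    "make_wavelength_grid",
    "calibrate_cube",
    "crop_band_range",
    "pad_with_zero_channels",
    "read_cube",
    "write_cube",
    "read_rgb",
    "write_rgb",
]


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength sampling in nanometres, inclusive of both ends."""

    start_nm: float
    stop_nm: float
    step_nm: float
    values: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        if self.step_nm <= 0:
            raise ValueError("step_nm must be positive")
        if self.stop_nm < self.start_nm:
            raise ValueError("stop_nm must be >= start_nm")
        span = self.stop_nm - self.start_nm
        n_steps = span / self.step_nm
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError(
                f"wavelength range {self.start_nm}-{self.stop_nm} nm is not "
                f"divisible by step {self.step_nm} nm"
            )
        vals = self.start_nm + self.step_nm * np.arange(int(round(n_steps)) + 1)
        object.__setattr__(self, "values", vals.astype(float))

    def __len__(self) -> int:
        return len(self.values)

    @property
    def count(self) -> int:
        return len(self.values)

    def index_of(self, wavelength_nm: float) -> int:
        """0-based index of an on-grid wavelength; raises if off-grid."""
        pos = (wavelength_nm - self.start_nm) / self.step_nm
        idx = int(round(pos))
        if abs(pos - idx) > 1e-9 or not (0 <= idx < self.count):
            raise ValueError(f"{wavelength_nm} nm is not on the grid")
        return idx

    def band_wavelength(self, channel: int) -> float:
        """Wavelength of a 1-based channel number."""
        if not (1 <= channel <= self.count):
            raise ValueError(
                f"channel {channel} out of range 1..{self.count}"
            )
        return float(self.values[channel - 1])

    def __eq__(self, other) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return (
            self.start_nm == other.start_nm
            and self.stop_nm == other.stop_nm
            and self.step_nm == other.step_nm
        )

    def __hash__(self):
        return hash((self.start_nm, self.stop_nm, self.step_nm))


def make_wavelength_grid(start_nm: float, stop_nm: float, step_nm: float) -> WavelengthGrid:
    """Build an inclusive uniform grid, e.g. (420, 720, 5) -> 61 bands."""
    return WavelengthGrid(start_nm, stop_nm, step_nm)


@dataclass
class HyperspectralCube:
    """Transmittance cube (H, W, B) with B matching the wavelength grid."""

    data: np.ndarray
    grid: WavelengthGrid

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be H x W x B")
        if self.data.shape[2] != self.grid.count:
            raise ValueError(
                f"cube has {self.data.shape[2]} bands but grid declares "
                f"{self.grid.count}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("cube contains non-finite values")

    @property
    def shape(self):
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]


@dataclass
class CalibrationSet:
    """Raw/dark/white count frames with their exposure values.

    The transmittance at each pixel and band is
    ``(raw/E_raw - dark/E_d) / (white/E_w - dark/E_d)``.
    """

    raw: np.ndarray
    dark: np.ndarray
    white: np.ndarray
    exposure_raw: float
    exposure_dark: float
    exposure_white: float
    grid: WavelengthGrid

    def __post_init__(self):
        self.raw = np.asarray(self.raw, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)
        self.white = np.asarray(self.white, dtype=float)
        if not (self.raw.shape == self.dark.shape == self.white.shape):
            raise ValueError(
                f"frame shapes differ: raw {self.raw.shape}, dark "
                f"{self.dark.shape}, white {self.white.shape}"
            )
        if self.raw.ndim != 3 or self.raw.shape[2] != self.grid.count:
            raise ValueError("frames must be H x W x B matching the grid")
        for name in ("exposure_raw", "exposure_dark", "exposure_white"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def calibrate_cube(cal: CalibrationSet) -> HyperspectralCube:
    """Exposure-normalised dark/white calibration to transmittance.

    Negative values (raw below dark) are clipped to 0; values above 1 are
    retained so bright-reference noise structure survives. A zero
    denominator anywhere is an error naming the first offending location.
    """
    num = cal.raw / cal.exposure_raw - cal.dark / cal.exposure_dark
    den = cal.white / cal.exposure_white - cal.dark / cal.exposure_dark
    bad = den == 0
    if np.any(bad):
        h, w, b = (int(i[0]) for i in np.nonzero(bad))
        raise ValueError(
            f"white and dark references coincide at pixel ({h}, {w}), "
            f"band {b + 1} ({cal.grid.values[b]:g} nm): zero denominator"
        )
    t = num / den
    np.clip(t, 0.0, None, out=t)
    return HyperspectralCube(t, cal.grid)


def crop_band_range(cube: HyperspectralCube, lo_nm: float, hi_nm: float) -> HyperspectralCube:
    """Restrict a cube to [lo_nm, hi_nm]; endpoints must lie on the grid."""
    if hi_nm < lo_nm:
        raise ValueError("hi_nm must be >= lo_nm")
    i0 = cube.grid.index_of(lo_nm)
    i1 = cube.grid.index_of(hi_nm)
    sub = make_wavelength_grid(lo_nm, hi_nm, cube.grid.step_nm)
    return HyperspectralCube(cube.data[:, :, i0 : i1 + 1].copy(), sub)


def pad_with_zero_channels(img: np.ndarray, target_channels: int) -> np.ndarray:
    """Append all-zero channels after the existing ones (e.g. 3 -> 61).

    Used to feed an RGB image to a network expecting the hyperspectral
    channel count: the 3 colour channels come first, the padding is zero.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 3:
        raise ValueError("image must be H x W x C")
    c = img.shape[2]
    if target_channels < c:
        raise ValueError(
            f"target_channels {target_channels} < current channels {c}"
        )
    if target_channels == c:
        return img.copy()
    pad = np.zeros(img.shape[:2] + (target_channels - c,), dtype=img.dtype)
    return np.concatenate([img, pad], axis=2)


# ---------------------------------------------------------------------------
# I/O: multi-page TIFF (one page per band) + JSON wavelength sidecar


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_cube(cube: HyperspectralCube, path) -> None:
    """Write a cube as a multi-page float TIFF plus a JSON grid sidecar."""
    path = Path(path)
    pages = np.moveaxis(cube.data, 2, 0)  # one page per band
    tifffile.imwrite(path, pages.astype(np.float64))
    meta = {
        "start_nm": cube.grid.start_nm,
        "stop_nm": cube.grid.stop_nm,
        "step_nm": cube.grid.step_nm,
    }
    _sidecar_path(path).write_text(json.dumps(meta))


def read_cube(path) -> HyperspectralCube:
    """Read a cube written by :func:`write_cube`, validating band count."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"wavelength sidecar {sidecar} missing for {path}"
        )
    meta = json.loads(sidecar.read_text())
    try:
        grid = make_wavelength_grid(
            meta["start_nm"], meta["stop_nm"], meta["step_nm"]
        )
    except KeyError as e:  # pragma: no cover - malformed sidecar
        raise ValueError(f"sidecar {sidecar} missing key {e}") from e
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.shape[0] != grid.count:
        raise ValueError(
            f"{path} holds {pages.shape[0]} pages but the sidecar grid "
            f"declares {grid.count} bands"
        )
    return HyperspectralCube(np.moveaxis(pages, 0, 2), grid)


def read_rgb(path) -> np.ndarray:
    """Read an 8-bit RGB image (PNG/TIFF), returning uint8 H x W x 3."""
    img = iio.imread(path)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=2)
    if img.shape[2] == 4:  # drop alpha
        img = img[:, :, :3]
    if img.dtype != np.uint8:
        raise ValueError(f"{path}: expected 8-bit image, got {img.dtype}")
    return img


def write_rgb(img: np.ndarray, path) -> None:
    img = np.asarray(img)
    if img.dtype != np.uint8:
        if img.min() < 0 or img.max() > 255:
            raise ValueError("RGB values must lie in [0, 255]")
        img = img.astype(np.uint8)
    iio.imwrite(path, img)
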