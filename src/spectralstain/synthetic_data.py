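"""Paired H&E-hyperspectral / EVG-RGB phantom generator.

Real training data for the stain-conversion pipeline (hyperspectral H&E
cubes with registered elastic-stain tiles) is not publicly available, so
this module fabricates tiles with the statistical structure the pipeline
assumes:

* curvilinear elastic and collagen fiber strokes plus elliptical nuclei;
* an H&E transmittance cube built by two-dye Beer-Lambert mixing,
  ``T(lambda) = 10**-(c_h A_h + c_e A_e)``, with *identical*
  eosin-dominant concentration distributions on both fiber classes —
  under H&E the classes are deliberately near-indistinguishable — except
  for a small, smooth class-specific transmittance bump near 560 nm on
  elastic fibers that only a many-band observer can exploit;
* an EVG rendering of the same geometry with deep-blue elastic fibers,
  orchid collagen and near-black nuclei, chosen to sit inside the
  fibrous HSV mask ranges used by the evaluation metrics.

Everything is driven by one seed and is bit-reproducible.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.draw import disk, ellipse

from . import spectral_basis as sb
from .hsi_core import (
    HyperspectralCube,
    make_wavelength_grid,
    write_cube,
    write_rgb,
)
from .registration import AffineTransform, warp_affine

__all__ = [
    "PhantomConfig",
    "PhantomSample",
    "generate_phantom",
    "generate_dataset",
    "labeled_spectra",
    "EVG_ELASTIC_RGB",
    "EVG_COLLAGEN_RGB",
]

# synthetic EVG palette (chosen inside the fibrous HSV mask ranges)
EVG_ELASTIC_RGB = (40, 40, 120)  # deep blue
EVG_COLLAGEN_RGB = (218, 112, 214)  # orchid
EVG_NUCLEI_RGB = (35, 30, 40)  # near black
EVG_BACKGROUND_RGB = (243, 238, 232)  # pale


@dataclass(frozen=True)
class PhantomConfig:
    """Knobs of the phantom generator.

    ``dye_concentration_ranges`` gives per-structure (low, high) draws for
    the Beer-Lambert concentrations; ``elastic_bump`` is the relative
    amplitude of the elastic-specific spectral perturbation (<= 0.05
    keeps the classes visually indistinguishable in H&E colour);
    ``noise_sd`` is the relative multiplicative transmittance noise.
    """

    size: tuple = (64, 64)
    n_elastic_fibers: int = 3
    n_collagen_fibers: int = 4
    n_nuclei: int = 6
    fiber_width_px: float = 2.0
    dye_concentration_ranges: dict = field(
        default_factory=lambda: {
            "eosin_fiber": (0.5, 1.0),
            "hematoxylin_fiber": (0.02, 0.08),
            "hematoxylin_nuclei": (0.8, 1.2),
            "eosin_nuclei": (0.1, 0.3),
        }
    )
    elastic_bump: float = 0.04
    elastic_bump_center_nm: float = 560.0
    elastic_bump_width_nm: float = 25.0
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if min(self.size) < 8:
            raise ValueError("phantom size must be at least 8 x 8")


@dataclass
class PhantomSample:
    """One paired record: H&E cube, EVG RGB, and structure masks."""

    he_cube: HyperspectralCube
    evg_rgb: np.ndarray
    elastic_mask: np.ndarray
    collagen_mask: np.ndarray
    nuclei_mask: np.ndarray

    def __post_init__(self):
        if self.elastic_mask.shape != self.collagen_mask.shape:
            raise ValueError("mask shapes differ")
        if np.any(self.elastic_mask & self.collagen_mask):
            raise ValueError("elastic and collagen masks overlap")


def _fiber_stroke(rng, shape, width_px):
    """Rasterise one random curvilinear stroke as a boolean mask."""
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    y = rng.uniform(0, h)
    x = rng.uniform(0, w)
    theta = rng.uniform(0, 2 * np.pi)
    length = int(rng.uniform(0.6, 1.4) * max(h, w))
    r = max(width_px / 2.0, 0.5)
    for _ in range(length):
        rr, cc = disk((y, x), r, shape=shape)
        mask[rr, cc] = True
        theta += rng.normal(0.0, 0.25)  # wiggle
        y += np.sin(theta)
        x += np.cos(theta)
        if not (-r <= y < h + r and -r <= x < w + r):
            break
    return mask


def _place_fibers(rng, shape, n_fibers, width_px, forbidden, max_retries=25):
    """Place strokes avoiding a forbidden mask; error when impossible."""
    placed = np.zeros(shape, dtype=bool)
    for k in range(n_fibers):
        for attempt in range(max_retries):
            stroke = _fiber_stroke(rng, shape, width_px)
            if stroke.any() and not (stroke & forbidden).any():
                placed |= stroke
                break
        else:
            raise RuntimeError(
                f"could not place fiber {k + 1}/{n_fibers} without overlap "
                f"after {max_retries} retries"
            )
    return placed


def generate_phantom(config: PhantomConfig) -> PhantomSample:
    """Draw one paired phantom tile (deterministic in ``config.seed``)."""
    rng = np.random.default_rng(config.seed)
    h, w = config.size
    grid = make_wavelength_grid(420, 720, 5)
    wl = grid.values

    collagen = _place_fibers(
        rng, (h, w), config.n_collagen_fibers, config.fiber_width_px,
        forbidden=np.zeros((h, w), dtype=bool),
    )
    elastic = _place_fibers(
        rng, (h, w), config.n_elastic_fibers, config.fiber_width_px,
        forbidden=collagen,
    )
    nuclei = np.zeros((h, w), dtype=bool)
    for _ in range(config.n_nuclei):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        ry, rx = rng.uniform(1.5, 3.5), rng.uniform(1.5, 3.5)
        rr, cc = ellipse(cy, cx, ry, rx, shape=(h, w),
                         rotation=rng.uniform(0, np.pi))
        nuclei[rr, cc] = True
    # nuclei occlude fibers where they overlap (they are drawn on top in
    # the EVG rendering), so fiber masks mark only visible fiber pixels
    collagen &= ~nuclei
    elastic &= ~nuclei

    # Beer-Lambert concentrations: identical distributions on both fiber
    # classes (H&E cannot tell them apart), hematoxylin on nuclei.
    ranges = config.dye_concentration_ranges
    c_eosin = np.zeros((h, w))
    c_hema = np.zeros((h, w))
    for mask in (collagen, elastic):
        n = int(mask.sum())
        c_eosin[mask] = rng.uniform(*ranges["eosin_fiber"], size=n)
        c_hema[mask] = rng.uniform(*ranges["hematoxylin_fiber"], size=n)
    n = int(nuclei.sum())
    c_hema[nuclei] = rng.uniform(*ranges["hematoxylin_nuclei"], size=n)
    c_eosin[nuclei] = rng.uniform(*ranges["eosin_nuclei"], size=n)

    a_e = sb.default_eosin(grid).absorbance
    a_h = sb.default_hematoxylin(grid).absorbance
    absorbance = c_eosin[..., None] * a_e + c_hema[..., None] * a_h
    t = np.power(10.0, -absorbance)

    # elastic-only smooth spectral signature (the hook the LDF exploits)
    bump = config.elastic_bump * np.exp(
        -0.5 * ((wl - config.elastic_bump_center_nm) / config.elastic_bump_width_nm) ** 2
    )
    t[elastic] *= 1.0 + bump

    if config.noise_sd > 0:
        t *= 1.0 + config.noise_sd * rng.standard_normal(t.shape)
    np.clip(t, 0.0, None, out=t)

    evg = np.empty((h, w, 3), dtype=float)
    evg[:] = EVG_BACKGROUND_RGB
    evg[collagen] = EVG_COLLAGEN_RGB
    evg[elastic] = EVG_ELASTIC_RGB
    evg[nuclei] = EVG_NUCLEI_RGB
    evg += rng.normal(0.0, 2.0, size=evg.shape)  # slight scanner noise
    evg = np.clip(np.round(evg), 0, 255).astype(np.uint8)

    return PhantomSample(
        he_cube=HyperspectralCube(t, grid),
        evg_rgb=evg,
        elastic_mask=elastic,
        collagen_mask=collagen,
        nuclei_mask=nuclei,
    )


def _random_misalignment(rng) -> AffineTransform:
    """Small random affine (rotation, isotropic scale, translation)."""
    theta = np.deg2rad(rng.uniform(-6.0, 6.0))
    s = rng.uniform(0.95, 1.05)
    tx, ty = rng.uniform(-4.0, 4.0, size=2)
    c, si = np.cos(theta), np.sin(theta)
    m = np.array([[s * c, -s * si, tx], [s * si, s * c, ty]])
    return AffineTransform(m)


def misalign_evg(evg: np.ndarray, rng) -> tuple[np.ndarray, AffineTransform]:
    """Warp an aligned EVG tile by a random affine.

    Returns the misaligned tile and the ground-truth transform ``t`` such
    that ``warp_affine(misaligned, t)`` realigns it with the H&E frame.
    """
    t_true = _random_misalignment(rng)
    inv = np.linalg.inv(t_true.homogeneous)
    misaligned = warp_affine(evg, AffineTransform(inv[:2]), out_shape=evg.shape[:2])
    return misaligned, t_true


def generate_dataset(
    config: PhantomConfig,
    out_dir,
    n_unpaired: int = 8,
    n_paired: int = 4,
    misalign: bool = False,
) -> Path:
    """Write unpaired H&E/EVG pools and a paired pool to disk.

    The unpaired EVG tiles come from different seeds than the unpaired
    H&E tiles, so the two pools are genuinely unpaired. With ``misalign``
    each paired EVG tile is perturbed by a random known affine whose
    ground truth is saved alongside, for registration testing. A
    ``manifest.csv`` lists every file with its seed and role.
    """
    if n_unpaired < 1 or n_paired < 1:
        raise ValueError("n_unpaired and n_paired must be >= 1")
    out = Path(out_dir)
    dirs = {
        "uhe": out / "unpaired" / "he",
        "uevg": out / "unpaired" / "evg",
        "phe": out / "paired" / "he",
        "pevg": out / "paired" / "evg",
        "pmask": out / "paired" / "masks",
        "ptf": out / "paired" / "transforms",
    }
    for d in dirs.values():
        d.mkdir(parents=True, exist_ok=True)
    rows = []

    def cfg_with_seed(seed):
        return PhantomConfig(**{**config.__dict__, "seed": seed})

    base = config.seed
    for i in range(n_unpaired):
        seed_he = base + i
        seed_evg = base + 10_000 + i  # disjoint seed set: truly unpaired
        s_he = generate_phantom(cfg_with_seed(seed_he))
        s_evg = generate_phantom(cfg_with_seed(seed_evg))
        p_he = dirs["uhe"] / f"he_{i:04d}.tiff"
        p_evg = dirs["uevg"] / f"evg_{i:04d}.png"
        write_cube(s_he.he_cube, p_he)
        write_rgb(s_evg.evg_rgb, p_evg)
        rows.append((p_he.relative_to(out), "unpaired_he", seed_he))
        rows.append((p_evg.relative_to(out), "unpaired_evg", seed_evg))

    mis_rng = np.random.default_rng(base + 20_000)
    for i in range(n_paired):
        seed = base + 30_000 + i
        s = generate_phantom(cfg_with_seed(seed))
        p_he = dirs["phe"] / f"he_{i:04d}.tiff"
        p_evg = dirs["pevg"] / f"evg_{i:04d}.png"
        write_cube(s.he_cube, p_he)
        evg = s.evg_rgb
        if misalign:
            evg, t_true = misalign_evg(evg, mis_rng)
            (dirs["ptf"] / f"evg_{i:04d}.json").write_text(
                json.dumps({"matrix": t_true.matrix.tolist()})
            )
        write_rgb(evg, p_evg)
        np.savez(
            dirs["pmask"] / f"masks_{i:04d}.npz",
            elastic=s.elastic_mask,
            collagen=s.collagen_mask,
            nuclei=s.nuclei_mask,
        )
        rows.append((p_he.relative_to(out), "paired_he", seed))
        rows.append((p_evg.relative_to(out), "paired_evg", seed))

    with open(out / "manifest.csv", "w", newline="") as f:
        writer = csv.writer(f)
        writer.writerow(["path", "role", "seed"])
        writer.writerows(rows)
    return out


def labeled_spectra(
    config: PhantomConfig, n_per_class: int = 200
) -> tuple[np.ndarray, np.ndarray]:
    """Sample labelled elastic/collagen pixel spectra from phantoms.

    Used to derive the fallback linear discriminant function. Draws
    phantoms with consecutive seeds until each class has ``n_per_class``
    pixel spectra.
    """
    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2")
    elastic_rows, collagen_rows = [], []
    seed = config.seed
    for _ in range(50):
        s = generate_phantom(PhantomConfig(**{**config.__dict__, "seed": seed}))
        seed += 1
        flat = s.he_cube.data.reshape(-1, s.he_cube.n_bands)
        elastic_rows.append(flat[s.elastic_mask.ravel()])
        collagen_rows.append(flat[s.collagen_mask.ravel()])
        if (
            sum(len(r) for r in elastic_rows) >= n_per_class
            and sum(len(r) for r in collagen_rows) >= n_per_class
        ):
            break
    elastic = np.concatenate(elastic_rows)[:n_per_class]
    collagen = np.concatenate(collagen_rows)[:n_per_class]
    if len(elastic) < n_per_class or len(collagen) < n_per_class:
        raise RuntimeError("phantoms produced too few fiber pixels")
    return elastic, collagen
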