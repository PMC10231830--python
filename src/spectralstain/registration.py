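"""Feature-based affine registration of EVG tiles onto H&E tiles.

H&E and elastic-stain images of the same tissue come from different
scanners at different times, so before they can serve as ground-truth
pairs the EVG tile must be aligned onto the H&E tile. The pipeline is:
scale/rotation-invariant keypoints (ORB by default; SIFT optional),
ratio-filtered descriptor matching, robust affine estimation by MSAC
(M-estimator SAmple Consensus, a RANSAC variant scoring hypotheses by
truncated squared residuals), and bilinear warping.

All point coordinates are (x, y) = (column, row), origin top-left.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import transform as sktf
from skimage.color import rgb2gray
from skimage.feature import ORB, SIFT, match_descriptors

__all__ = [
    "FeatureMatchSet",
    "AffineTransform",
    "detect_and_match",
    "estimate_affine_msac",
    "warp_affine",
    "overlay_check",
    "register_pair",
]


@dataclass
class FeatureMatchSet:
    """Matched keypoint pairs between a fixed and a moving image."""

    fixed_points: np.ndarray  # (n, 2) as (x, y)
    moving_points: np.ndarray
    scores: np.ndarray  # descriptor distances, lower is better

    def __post_init__(self):
        self.fixed_points = np.asarray(self.fixed_points, dtype=float)
        self.moving_points = np.asarray(self.moving_points, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        n = len(self.fixed_points)
        if len(self.moving_points) != n or len(self.scores) != n:
            raise ValueError("point lists and scores must have equal length")

    def __len__(self):
        return len(self.fixed_points)


@dataclass
class AffineTransform:
    """2x3 matrix mapping moving-image (x, y) onto fixed-image (x, y)."""

    matrix: np.ndarray
    inlier_count: int = 0

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (2, 3):
            raise ValueError("affine matrix must be 2 x 3")
        if abs(np.linalg.det(self.matrix[:, :2])) < 1e-12:
            raise ValueError("singular linear part")

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return pts @ self.matrix[:, :2].T + self.matrix[:, 2]

    @property
    def homogeneous(self) -> np.ndarray:
        return np.vstack([self.matrix, [0.0, 0.0, 1.0]])


def _to_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim == 3:
        return rgb2gray(img)
    return img.astype(float) / 255.0 if img.dtype == np.uint8 else img


_DETECTORS = ("orb", "sift")


def detect_and_match(
    fixed: np.ndarray,
    moving: np.ndarray,
    detector: str = "orb",
    max_ratio: float = 0.75,
    n_keypoints: int = 500,
) -> FeatureMatchSet:
    """Detect keypoints in both images and match descriptors.

    Matching is nearest-neighbour with Lowe's ratio filter (``max_ratio``)
    and cross-checking. Fewer than 3 surviving matches is an error since
    an affine fit would be underdetermined.
    """
    if detector not in _DETECTORS:
        raise ValueError(f"detector must be one of {_DETECTORS}")
    g_fixed, g_moving = _to_gray(fixed), _to_gray(moving)

    def _extract(img):
        if detector == "orb":
            d = ORB(n_keypoints=n_keypoints, fast_threshold=0.05)
        else:
            d = SIFT()
        d.detect_and_extract(img)
        return d.keypoints, d.descriptors

    try:
        kp_f, desc_f = _extract(g_fixed)
        kp_m, desc_m = _extract(g_moving)
    except RuntimeError as e:  # skimage raises when no keypoints found
        raise ValueError(f"feature detection failed: {e}") from e
    metric = "hamming" if detector == "orb" else None
    pairs = match_descriptors(
        desc_f, desc_m, metric=metric, cross_check=True, max_ratio=max_ratio
    )
    if len(pairs) < 3:
        raise ValueError(
            f"only {len(pairs)} matches found; at least 3 are needed for an "
            "affine fit"
        )
    # skimage keypoints are (row, col); convert to (x, y)
    fixed_pts = kp_f[pairs[:, 0]][:, ::-1]
    moving_pts = kp_m[pairs[:, 1]][:, ::-1]
    if metric == "hamming":
        dists = np.array(
            [
                np.count_nonzero(desc_f[i] != desc_m[j])
                for i, j in pairs
            ],
            dtype=float,
        )
    else:
        dists = np.linalg.norm(
            desc_f[pairs[:, 0]].astype(float) - desc_m[pairs[:, 1]].astype(float),
            axis=1,
        )
    return FeatureMatchSet(fixed_pts, moving_pts, dists)


def _fit_affine_lsq(moving: np.ndarray, fixed: np.ndarray) -> np.ndarray | None:
    """Least-squares 2x3 affine sending moving points onto fixed points."""
    n = len(moving)
    a = np.hstack([moving, np.ones((n, 1))])
    sol, _, rank, _ = np.linalg.lstsq(a, fixed, rcond=None)
    if rank < 3:
        return None
    return sol.T  # 2 x 3


def estimate_affine_msac(
    matches: FeatureMatchSet,
    inlier_tol_px: float = 3.0,
    n_iterations: int = 2000,
    seed: int = 0,
) -> AffineTransform:
    """Robust affine estimation by MSAC.

    Each iteration samples 3 matches, fits an exact affine and scores it
    by the sum of squared residuals truncated at ``inlier_tol_px**2``.
    The best hypothesis is refit by least squares on its inliers.
    Deterministic for a fixed seed.
    """
    if len(matches) < 3:
        raise ValueError("at least 3 matches required")
    rng = np.random.default_rng(seed)
    mv, fx = matches.moving_points, matches.fixed_points
    n = len(matches)
    tol2 = float(inlier_tol_px) ** 2
    best_score = np.inf
    best_inliers = None
    for _ in range(n_iterations):
        idx = rng.choice(n, size=3, replace=False)
        model = _fit_affine_lsq(mv[idx], fx[idx])
        if model is None:
            continue
        res2 = np.sum((mv @ model[:, :2].T + model[:, 2] - fx) ** 2, axis=1)
        score = np.minimum(res2, tol2).sum()
        if score < best_score:
            best_score = score
            best_inliers = res2 < tol2
    if best_inliers is None or best_inliers.sum() < 3:
        raise ValueError(
            "MSAC found no affine model with at least 3 inliers"
        )
    model = _fit_affine_lsq(mv[best_inliers], fx[best_inliers])
    if model is None:
        raise ValueError("degenerate inlier configuration")
    return AffineTransform(model, inlier_count=int(best_inliers.sum()))


def warp_affine(
    moving: np.ndarray, t: AffineTransform, out_shape: tuple[int, int] | None = None
) -> np.ndarray:
    """Warp the moving image into the fixed frame (bilinear, zero fill)."""
    moving = np.asarray(moving)
    was_uint8 = moving.dtype == np.uint8
    if out_shape is None:
        out_shape = moving.shape[:2]
    # skimage's AffineTransform works in (x, y); warp() wants the map from
    # output coordinates back to input, i.e. the inverse of t.
    fwd = sktf.AffineTransform(matrix=t.homogeneous)
    out = sktf.warp(
        moving.astype(float),
        inverse_map=fwd.inverse,
        output_shape=out_shape,
        order=1,
        mode="constant",
        cval=0.0,
        preserve_range=True,
    )
    if was_uint8:
        out = np.clip(np.round(out), 0, 255).astype(np.uint8)
    return out


def overlay_check(fixed: np.ndarray, registered: np.ndarray) -> np.ndarray:
    """Green/magenta registration overlay.

    The registered EVG luminance fills the green channel and the H&E
    luminance fills red+blue (magenta); aligned structure looks gray,
    misalignment shows coloured fringes.
    """
    fixed = np.asarray(fixed)
    registered = np.asarray(registered)
    if fixed.shape[:2] != registered.shape[:2]:
        raise ValueError("fixed and registered images must share H x W")
    lum_f = _to_gray(fixed) * 255.0
    lum_r = _to_gray(registered) * 255.0
    out = np.zeros(fixed.shape[:2] + (3,), dtype=np.uint8)
    out[:, :, 0] = np.clip(np.round(lum_f), 0, 255)
    out[:, :, 2] = out[:, :, 0]
    out[:, :, 1] = np.clip(np.round(lum_r), 0, 255)
    return out


def register_pair(
    fixed_rgb: np.ndarray,
    moving_rgb: np.ndarray,
    detector: str = "orb",
    inlier_tol_px: float = 3.0,
    seed: int = 0,
) -> tuple[np.ndarray, AffineTransform]:
    """Full registration: features, MSAC affine, warp onto the fixed frame."""
    matches = detect_and_match(fixed_rgb, moving_rgb, detector=detector)
    t = estimate_affine_msac(matches, inlier_tol_px=inlier_tol_px, seed=seed)
    registered = warp_affine(moving_rgb, t, out_shape=fixed_rgb.shape[:2])
    return registered, t
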