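"""Scikit-learn style estimators wrapping the stain-conversion pipeline.

``StainTranslator`` is the headline model: ``fit`` runs the unsupervised
CycleGAN phase on unpaired pools, ``refine`` runs the supervised phase
on registered pairs, and ``transform`` converts H&E cubes to EVG RGB
images. ``AffineRegistrar`` aligns an EVG tile onto an H&E tile. Both
follow the sklearn contract (``get_params``/``set_params``, fitted
attributes with trailing underscores) and compose with sklearn tooling.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import spectral_basis as sb
from . import stain_gan as sg
from . import training as tr
from .hsi_core import HyperspectralCube
from .registration import detect_and_match, estimate_affine_msac, warp_affine
from .synthetic_data import PhantomConfig, labeled_spectra

__all__ = ["StainTranslator", "AffineRegistrar"]


class StainTranslator(TransformerMixin, BaseEstimator):
    """Hyperspectral-H&E to RGB-EVG translator (heterogeneous CycleGAN).

    Parameters mirror the training configuration: network size (depth /
    base_filters and the discriminator analogues), loss weights
    (``lambda_cycle``, ``gamma_identity``), the spectral basis used for
    the identity mapping (``basis_mode`` in {"channels", "ldf_pca",
    "ldf_dyes"}, optionally a user-supplied ``ldf`` vector), epochs and
    learning rates of both phases, and a seed.

    Attributes after ``fit``: ``bundle_`` (the four networks),
    ``basis_``, ``history_``; after ``refine`` additionally
    ``refine_history_``.
    """

    def __init__(
        self,
        basis_mode: str = "ldf_dyes",
        ldf=None,
        depth: int = 2,
        base_filters: int = 8,
        d_levels: int = 2,
        d_base_filters: int = 8,
        epochs: int = 20,
        refine_epochs: int = 10,
        learning_rate: float = 2e-4,
        refine_learning_rate: float = 3e-5,
        batch_size: int = 1,
        lambda_cycle: float = 5.0,
        gamma_identity: float = 0.5,
        seed: int = 0,
    ):
        self.basis_mode = basis_mode
        self.ldf = ldf
        self.depth = depth
        self.base_filters = base_filters
        self.d_levels = d_levels
        self.d_base_filters = d_base_filters
        self.epochs = epochs
        self.refine_epochs = refine_epochs
        self.learning_rate = learning_rate
        self.refine_learning_rate = refine_learning_rate
        self.batch_size = batch_size
        self.lambda_cycle = lambda_cycle
        self.gamma_identity = gamma_identity
        self.seed = seed

    # -- internals ---------------------------------------------------------

    def _resolve_ldf(self, grid) -> np.ndarray:
        if self.ldf is not None:
            ldf = np.asarray(self.ldf, dtype=float)
            if ldf.shape != (grid.count,):
                raise ValueError("supplied ldf length does not match the grid")
            return ldf
        # fallback: discriminant derived from labelled synthetic spectra
        elastic, collagen = labeled_spectra(
            PhantomConfig(seed=self.seed), n_per_class=200
        )
        return sb.derive_ldf_lda(elastic, collagen)

    def _build_basis(self, cubes) -> sb.BasisSet:
        grid = cubes[0].grid
        if self.basis_mode == "channels":
            return sb.basis_channel_select(grid)
        ldf = self._resolve_ldf(grid)
        if self.basis_mode == "ldf_pca":
            return sb.basis_ldf_pca(ldf, cubes)
        if self.basis_mode == "ldf_dyes":
            return sb.basis_ldf_dyes(
                ldf, sb.default_hematoxylin(grid), sb.default_eosin(grid)
            )
        raise ValueError(f"unknown basis_mode {self.basis_mode!r}")

    def _phase_config(self, phase: int) -> tr.TrainingConfig:
        return tr.TrainingConfig(
            phase=phase,
            learning_rate=self.learning_rate if phase == 1 else self.refine_learning_rate,
            batch_size=self.batch_size,
            epochs=self.epochs if phase == 1 else self.refine_epochs,
            seed=self.seed,
            basis_mode=self.basis_mode,
            depth=self.depth,
            base_filters=self.base_filters,
            d_levels=self.d_levels,
            d_base_filters=self.d_base_filters,
            weights=tr.LossWeights(self.lambda_cycle, self.gamma_identity),
        )

    # -- sklearn surface ---------------------------------------------------

    def fit(self, X, y=None, val_pairs=None):
        """Phase-1 unsupervised training.

        ``X`` is the unpaired pool of H&E cubes, ``y`` the unpaired pool
        of EVG RGB tiles (both required; they need not correspond).
        """
        cubes = list(X)
        if y is None:
            raise ValueError("an unpaired pool of EVG RGB tiles is required")
        if not all(isinstance(c, HyperspectralCube) for c in cubes):
            raise TypeError("X must be a sequence of HyperspectralCube")
        self.basis_ = self._build_basis(cubes)
        self.bundle_, self.history_ = tr.train_phase1(
            (cubes, list(y)), self._phase_config(1), self.basis_,
            val_pairs=val_pairs,
        )
        return self

    def refine(self, pairs, from_random_init: bool = False):
        """Phase-2 supervised refinement on registered (cube, EVG) pairs.

        ``from_random_init`` is the ablation that discards the phase-1
        weights (normally a fresh estimator would be used for that; the
        flag exists so the comparison is one call away).
        """
        config = self._phase_config(2)
        if from_random_init:
            gen, hist = tr.train_phase2_refine(
                pairs, config, allow_random_init=True
            )
            self.bundle_ = None  # only the generator survives this path
            self.generator_ = gen
        else:
            check_is_fitted(self, "bundle_")
            gen, hist = tr.train_phase2_refine(
                pairs, config, bundle=self.bundle_
            )
            self.generator_ = gen
        self.refine_history_ = hist
        return self

    def transform(self, X):
        """Convert H&E cubes to EVG RGB images (list of uint8 arrays)."""
        check_is_fitted(self)
        gen = getattr(self, "generator_", None)
        if gen is None:
            gen = self.bundle_.g_he_to_evg
        return [tr.convert_cube(gen, c) for c in X]

    def save(self, path):
        check_is_fitted(self, "bundle_")
        sg.save_weights(self.bundle_, path)

    def __sklearn_is_fitted__(self):
        return (
            getattr(self, "bundle_", None) is not None
            or getattr(self, "generator_", None) is not None
        )


class AffineRegistrar(TransformerMixin, BaseEstimator):
    """Feature-based affine registration of a moving image onto a fixed one.

    ``fit(fixed, moving)`` estimates the affine; ``transform(img)`` warps
    an image (by default the moving one) into the fixed frame. Fitted
    attributes: ``transform_`` (2x3 AffineTransform), ``n_matches_``,
    ``inlier_count_``.
    """

    def __init__(
        self,
        detector: str = "orb",
        max_ratio: float = 0.75,
        inlier_tol_px: float = 3.0,
        n_iterations: int = 2000,
        seed: int = 0,
    ):
        self.detector = detector
        self.max_ratio = max_ratio
        self.inlier_tol_px = inlier_tol_px
        self.n_iterations = n_iterations
        self.seed = seed

    def fit(self, X, y=None):
        """``X`` is the fixed image, ``y`` the moving image."""
        if y is None:
            raise ValueError("a moving image is required")
        matches = detect_and_match(
            X, y, detector=self.detector, max_ratio=self.max_ratio
        )
        self.transform_ = estimate_affine_msac(
            matches,
            inlier_tol_px=self.inlier_tol_px,
            n_iterations=self.n_iterations,
            seed=self.seed,
        )
        self.n_matches_ = len(matches)
        self.inlier_count_ = self.transform_.inlier_count
        self._fixed_shape = np.asarray(X).shape[:2]
        return self

    def transform(self, X):
        check_is_fitted(self, "transform_")
        return warp_affine(X, self.transform_, out_shape=self._fixed_shape)

    def __sklearn_is_fitted__(self):
        return hasattr(self, "transform_")
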