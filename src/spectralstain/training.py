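"""Two-phase training of the stain-conversion CycleGAN.

Phase 1 trains the full CycleGAN on *unpaired* H&E cubes and EVG RGB
tiles with three losses combined as

    L_total = L_adversarial + lambda * L_cycle + gamma * L_identity

(defaults lambda = 5.0, gamma = 0.5). Adversarial terms are
least-squares (MSE) GAN losses on the PatchGAN score maps; cycle and
identity terms are mean absolute errors. The identity loss needs
cross-modality channel adaptation: the 61-band cube is collapsed to 3
channels by a spectral basis before entering the 3->61 generator, and
the RGB tile is zero-padded to 61 channels before entering the 61->3
generator.

Phase 2 re-trains the HE->EVG generator alone, supervised with MSE on a
small set of registered pairs, initialised from the phase-1 checkpoint
(optionally from scratch, as an ablation) at a reduced learning rate.

All losses are computed in the networks' [-1, 1] working range; data
order and weight initialisation are driven by the config seed, so runs
are bit-reproducible on CPU.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from . import stain_gan as sg
from .evaluation import ssim_rgb
from .hsi_core import HyperspectralCube, pad_with_zero_channels
from .nn import Adam
from .spectral_basis import BasisSet, project_cube

__all__ = [
    "LossWeights",
    "TrainingConfig",
    "IdentityInputs",
    "adversarial_loss",
    "generator_adversarial_loss",
    "cycle_loss",
    "identity_loss",
    "total_loss",
    "make_identity_inputs",
    "train_phase1",
    "train_phase2_refine",
    "convert_cube",
]


@dataclass(frozen=True)
class LossWeights:
    """Scalars weighting the cycle (lambda) and identity (gamma) terms."""

    lambda_cycle: float = 5.0
    gamma_identity: float = 0.5

    def __post_init__(self):
        if self.lambda_cycle < 0 or self.gamma_identity < 0:
            raise ValueError("loss weights must be >= 0")


@dataclass
class TrainingConfig:
    phase: int = 1
    learning_rate: float | None = None  # default 2e-4 (phase 1) / 3e-5 (phase 2)
    batch_size: int = 1
    epochs: int = 10
    seed: int = 0
    basis_mode: str = "ldf_dyes"  # channels | ldf_pca | ldf_dyes
    tile_size: int = 128
    depth: int = 4
    base_filters: int = 64
    d_levels: int = 3
    d_base_filters: int = 64
    weights: LossWeights = field(default_factory=LossWeights)

    def __post_init__(self):
        if self.phase not in (1, 2):
            raise ValueError("phase must be 1 or 2")
        if self.learning_rate is None:
            self.learning_rate = 2e-4 if self.phase == 1 else 3e-5
        if not (1 <= self.batch_size <= 6):
            raise ValueError("batch_size must be in 1..6")
        if self.basis_mode not in ("channels", "ldf_pca", "ldf_dyes"):
            raise ValueError(f"unknown basis_mode {self.basis_mode!r}")


@dataclass
class IdentityInputs:
    """Model-space tensors for the identity terms (each (C, H, W)).

    ``he_red`` is the basis projection of ``he_org``; channels 4..61 of
    ``evg_inc`` are the zero padding.
    """

    he_org: np.ndarray  # 61 channels
    he_red: np.ndarray  # 3 channels
    evg_org: np.ndarray  # 3 channels
    evg_inc: np.ndarray  # 61 channels; 58 are zero-padding (−1 after the
    # [0,255] -> [-1,1] rescaling, since padding happens in image space)

    def __post_init__(self):
        if self.he_red.shape[0] != 3 or self.evg_org.shape[0] != 3:
            raise ValueError("he_red and evg_org must have 3 channels")
        if self.he_org.shape[0] != self.evg_inc.shape[0]:
            raise ValueError("he_org and evg_inc channel counts differ")
        pad_value = sg.normalize_rgb(0.0)
        if np.any(self.evg_inc[3:] != pad_value):
            raise ValueError(
                "evg_inc padding channels must be zero in image space"
            )


def _chw(img: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(np.moveaxis(np.asarray(img, dtype=float), 2, 0))


def make_identity_inputs(
    cube: HyperspectralCube, evg_rgb: np.ndarray, basis: BasisSet
) -> IdentityInputs:
    """Build the four identity-mapping tensors from one tile of each domain."""
    he_org = _chw(sg.normalize_cube(cube.data))
    proj = project_cube(cube, basis)  # raises on grid mismatch
    scale = sg.projection_scale(basis.matrix)
    he_red = _chw(proj / scale[None, None, :])
    evg_org = _chw(sg.normalize_rgb(evg_rgb))
    # zero channels are appended to the 8-bit image *before* the [-1, 1]
    # rescaling, so the padding sits at the dark end of the working range
    evg_inc = _chw(
        sg.normalize_rgb(
            pad_with_zero_channels(
                np.asarray(evg_rgb, dtype=float), cube.n_bands
            )
        )
    )
    return IdentityInputs(he_org, he_red, evg_org, evg_inc)


# ---------------------------------------------------------------------------
# Loss primitives


def adversarial_loss(scores_real: np.ndarray, scores_fake: np.ndarray) -> float:
    """Least-squares discriminator loss: E[(D(real)-1)^2] + E[D(fake)^2]."""
    scores_real = np.asarray(scores_real, dtype=float)
    scores_fake = np.asarray(scores_fake, dtype=float)
    if scores_real.size == 0 or scores_fake.size == 0:
        raise ValueError("empty score map")
    return float(np.mean((scores_real - 1.0) ** 2) + np.mean(scores_fake**2))


def generator_adversarial_loss(scores_fake: np.ndarray) -> float:
    """Least-squares generator term: E[(D(fake)-1)^2]."""
    scores_fake = np.asarray(scores_fake, dtype=float)
    if scores_fake.size == 0:
        raise ValueError("empty score map")
    return float(np.mean((scores_fake - 1.0) ** 2))


def cycle_loss(x: np.ndarray, reconstructed_x: np.ndarray) -> float:
    """Mean absolute error between an image and its cycle reconstruction."""
    x = np.asarray(x, dtype=float)
    reconstructed_x = np.asarray(reconstructed_x, dtype=float)
    if x.shape != reconstructed_x.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {reconstructed_x.shape}")
    return float(np.mean(np.abs(x - reconstructed_x)))


def identity_loss(bundle: sg.ModelBundle, inputs: IdentityInputs) -> float:
    """MAE(G_EVG->HE(HE_red), HE_org) + MAE(G_HE->EVG(EVG_inc), EVG_org)."""
    id_he = bundle.g_evg_to_he.predict(inputs.he_red[None])[0]
    id_evg = bundle.g_he_to_evg.predict(inputs.evg_inc[None])[0]
    return cycle_loss(inputs.he_org, id_he) + cycle_loss(inputs.evg_org, id_evg)


def total_loss(adv: float, cyc: float, idt: float, w: LossWeights | None = None) -> float:
    """L_total = L_adv + lambda * L_cycle + gamma * L_identity."""
    w = w or LossWeights()
    return float(adv + w.lambda_cycle * cyc + w.gamma_identity * idt)


# ---------------------------------------------------------------------------
# Phase 1: unsupervised CycleGAN


def _prepare_domains(data_unpaired, basis: BasisSet):
    he_cubes, evg_tiles = data_unpaired
    he_cubes, evg_tiles = list(he_cubes), list(evg_tiles)
    if not he_cubes or not evg_tiles:
        raise ValueError("both unpaired pools must be non-empty")
    n_bands = he_cubes[0].n_bands
    scale = sg.projection_scale(basis.matrix)
    he, he_red = [], []
    for c in he_cubes:
        if c.grid != basis.grid:
            raise ValueError("cube and basis wavelength grids differ")
        he.append(_chw(sg.normalize_cube(c.data)))
        he_red.append(_chw(project_cube(c, basis) / scale[None, None, :]))
    evg, evg_inc = [], []
    for img in evg_tiles:
        evg.append(_chw(sg.normalize_rgb(img)))
        evg_inc.append(
            _chw(sg.normalize_rgb(
                pad_with_zero_channels(np.asarray(img, dtype=float), n_bands)
            ))
        )
    return he, he_red, evg, evg_inc, n_bands


def _batches(n_items: int, batch_size: int, rng) -> list[np.ndarray]:
    order = rng.permutation(n_items)
    return [order[i : i + batch_size] for i in range(0, n_items, batch_size)]


def train_phase1(
    data_unpaired,
    config: TrainingConfig,
    basis: BasisSet,
    bundle: sg.ModelBundle | None = None,
    val_pairs=None,
):
    """Unsupervised CycleGAN training on unpaired H&E cubes and EVG tiles.

    ``data_unpaired`` is ``(he_cubes, evg_rgb_tiles)``. Returns
    ``(bundle, history)`` where ``history`` has one record of epoch-mean
    losses per epoch. When ``val_pairs`` (registered (cube, evg) tuples)
    is given, the returned bundle carries the weights of the epoch with
    the best validation SSIM; otherwise the final-epoch weights.

    Setting ``gamma_identity`` to 0 reproduces the no-identity-loss
    ablation.
    """
    if config.phase != 1:
        raise ValueError("config.phase must be 1")
    he, he_red, evg, evg_inc, n_bands = _prepare_domains(data_unpaired, basis)
    tile_hw = he[0].shape[1:]
    div = 2**config.depth
    if tile_hw[0] % div or tile_hw[1] % div:
        raise ValueError(
            f"tile size {tile_hw} not divisible by 2**depth = {div}"
        )
    if bundle is None:
        bundle = sg.build_bundle(
            n_bands,
            depth=config.depth,
            base_filters=config.base_filters,
            d_levels=config.d_levels,
            d_base_filters=config.d_base_filters,
            seed=config.seed,
        )
    w = config.weights
    g_params = bundle.g_he_to_evg.params() + bundle.g_evg_to_he.params()
    d_params = bundle.d_he.params() + bundle.d_evg.params()
    opt_g = Adam(g_params, lr=config.learning_rate)
    opt_d = Adam(d_params, lr=config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = min(len(he), len(evg))
    history = []
    best = (-np.inf, None)
    g_he, g_eh, d_he, d_evg = (
        bundle.g_he_to_evg,
        bundle.g_evg_to_he,
        bundle.d_he,
        bundle.d_evg,
    )

    for epoch in range(config.epochs):
        idx_he = rng.permutation(len(he))[:n]
        idx_evg = rng.permutation(len(evg))[:n]
        sums = {"d": 0.0, "adv": 0.0, "cycle": 0.0, "identity": 0.0, "total": 0.0}
        n_batches = 0
        for start in range(0, n, config.batch_size):
            bh = idx_he[start : start + config.batch_size]
            be = idx_evg[start : start + config.batch_size]
            x_he = np.stack([he[i] for i in bh])
            x_he_red = np.stack([he_red[i] for i in bh])
            x_evg = np.stack([evg[i] for i in be])
            x_evg_inc = np.stack([evg_inc[i] for i in be])

            # --- discriminator update (generators frozen)
            fake_evg = g_he.predict(x_he)
            fake_he = g_eh.predict(x_evg)
            opt_d.zero_grad()
            s_real, c1 = d_evg.forward(x_evg)
            s_fake, c2 = d_evg.forward(fake_evg)
            loss_d = adversarial_loss(s_real, s_fake)
            d_evg.backward(c1, 2.0 * (s_real - 1.0) / s_real.size)
            d_evg.backward(c2, 2.0 * s_fake / s_fake.size)
            s_real, c1 = d_he.forward(x_he)
            s_fake, c2 = d_he.forward(fake_he)
            loss_d += adversarial_loss(s_real, s_fake)
            d_he.backward(c1, 2.0 * (s_real - 1.0) / s_real.size)
            d_he.backward(c2, 2.0 * s_fake / s_fake.size)
            opt_d.step()

            # --- generator update (discriminators frozen; their gradient
            #     buffers get polluted but are zeroed before their next step)
            opt_g.zero_grad()
            # HE -> EVG -> HE cycle + adversarial on fake EVG
            fake_evg, cg1 = g_he.forward(x_he)
            s_fake, cd = d_evg.forward(fake_evg)
            adv = generator_adversarial_loss(s_fake)
            d_fake_adv = d_evg.backward(cd, 2.0 * (s_fake - 1.0) / s_fake.size)
            rec_he, cg2 = g_eh.forward(fake_evg)
            cyc = cycle_loss(x_he, rec_he)
            d_rec = w.lambda_cycle * np.sign(rec_he - x_he) / rec_he.size
            d_fake_cyc = g_eh.backward(cg2, d_rec)
            g_he.backward(cg1, d_fake_adv + d_fake_cyc)
            # EVG -> HE -> EVG cycle + adversarial on fake HE
            fake_he, cg3 = g_eh.forward(x_evg)
            s_fake, cd = d_he.forward(fake_he)
            adv += generator_adversarial_loss(s_fake)
            d_fake_adv = d_he.backward(cd, 2.0 * (s_fake - 1.0) / s_fake.size)
            rec_evg, cg4 = g_he.forward(fake_he)
            cyc += cycle_loss(x_evg, rec_evg)
            d_rec = w.lambda_cycle * np.sign(rec_evg - x_evg) / rec_evg.size
            d_fake_cyc = g_he.backward(cg4, d_rec)
            g_eh.backward(cg3, d_fake_adv + d_fake_cyc)
            # identity terms
            idt = 0.0
            if w.gamma_identity > 0:
                id_he, cg5 = g_eh.forward(x_he_red)
                idt += cycle_loss(x_he, id_he)
                g_eh.backward(
                    cg5, w.gamma_identity * np.sign(id_he - x_he) / id_he.size
                )
                id_evg, cg6 = g_he.forward(x_evg_inc)
                idt += cycle_loss(x_evg, id_evg)
                g_he.backward(
                    cg6, w.gamma_identity * np.sign(id_evg - x_evg) / id_evg.size
                )
            opt_g.step()

            sums["d"] += loss_d
            sums["adv"] += adv
            sums["cycle"] += cyc
            sums["identity"] += idt
            sums["total"] += total_loss(adv, cyc, idt, w)
            n_batches += 1

        record = {"epoch": epoch + 1} | {
            k: v / n_batches for k, v in sums.items()
        }
        if val_pairs is not None:
            val = float(
                np.mean(
                    [
                        ssim_rgb(
                            np.asarray(gt, dtype=float),
                            convert_cube(g_he, cube).astype(float),
                        )
                        for cube, gt in val_pairs
                    ]
                )
            )
            record["val_ssim"] = val
            if val > best[0]:
                best = (val, {
                    k: p.value.copy() for k, p in bundle.named_params().items()
                })
        history.append(record)

    if val_pairs is not None and best[1] is not None:
        for k, p in bundle.named_params().items():
            p.value[...] = best[1][k]
    return bundle, history


# ---------------------------------------------------------------------------
# Phase 2: supervised refinement


def train_phase2_refine(
    paired_data,
    config: TrainingConfig,
    init_checkpoint=None,
    bundle: sg.ModelBundle | None = None,
    allow_random_init: bool = False,
):
    """Supervised MSE refinement of the HE->EVG generator on paired data.

    ``paired_data`` is a list of registered ``(cube, evg_rgb)`` tuples.
    The generator starts from ``init_checkpoint`` (or from an in-memory
    ``bundle``); starting from random weights requires the explicit
    ``allow_random_init`` ablation flag. Returns
    ``(generator, history)``; each history record carries the epoch-mean
    MSE and an ``init`` provenance tag.
    """
    if config.phase != 2:
        raise ValueError("config.phase must be 2")
    paired = list(paired_data)
    if not paired:
        raise ValueError("paired dataset is empty")
    n_bands = paired[0][0].n_bands
    init_tag = "random" if (bundle is None and init_checkpoint is None) else "phase1"
    if bundle is None:
        bundle = sg.build_bundle(
            n_bands,
            depth=config.depth,
            base_filters=config.base_filters,
            d_levels=config.d_levels,
            d_base_filters=config.d_base_filters,
            seed=config.seed,
        )
        if init_checkpoint is not None:
            sg.load_weights(init_checkpoint, bundle)
        elif not allow_random_init:
            raise ValueError(
                "phase 2 needs a phase-1 checkpoint (or the explicit "
                "allow_random_init ablation flag)"
            )
    gen = bundle.g_he_to_evg
    xs = [_chw(sg.normalize_cube(c.data))[None] for c, _ in paired]
    ys = [_chw(sg.normalize_rgb(img))[None] for _, img in paired]
    opt = Adam(gen.params(), lr=config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    history = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(xs))
        mse_sum = 0.0
        for i in order:
            opt.zero_grad()
            out, cache = gen.forward(xs[i])
            diff = out - ys[i]
            mse_sum += float(np.mean(diff**2))
            gen.backward(cache, 2.0 * diff / diff.size)
            opt.step()
        history.append(
            {"epoch": epoch + 1, "mse": mse_sum / len(xs), "init": init_tag}
        )
    return gen, history


def convert_cube(generator, cube: HyperspectralCube) -> np.ndarray:
    """Apply a trained HE->EVG generator to a cube; returns 8-bit RGB."""
    x = _chw(sg.normalize_cube(cube.data))[None]
    out = generator.predict(x)[0]
    return sg.denormalize_rgb(np.moveaxis(out, 0, 2))
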