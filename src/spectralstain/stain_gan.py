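"""Heterogeneous CycleGAN building blocks for stain conversion.

The two domains have different channel counts — 61-band H&E
transmittance cubes versus 3-channel EVG RGB — so unlike a standard
CycleGAN the two U-Net generators map 61->3 and 3->61, and the two
PatchGAN discriminators consume 61 and 3 channels respectively. Spatial
dimensions are preserved by the generators and reduced to a patch-score
map by the discriminators.

Images enter the networks scaled to [-1, 1]: transmittance with fixed
bounds [0, 1.2], RGB from [0, 255]. Generator outputs pass through tanh.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn

__all__ = [
    "GeneratorSpec",
    "DiscriminatorSpec",
    "ModelBundle",
    "build_generator",
    "build_discriminator",
    "build_bundle",
    "save_weights",
    "load_weights",
    "load_bundle",
    "normalize_cube",
    "denormalize_cube",
    "normalize_rgb",
    "denormalize_rgb",
    "projection_scale",
]

TRANSMITTANCE_MAX = 1.2  # fixed normalisation bound for calibrated cubes


@dataclass(frozen=True)
class GeneratorSpec:
    in_channels: int
    out_channels: int
    depth: int = 4
    base_filters: int = 64
    output_activation: str = "tanh"

    def __post_init__(self):
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be >= 1")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")


@dataclass(frozen=True)
class DiscriminatorSpec:
    in_channels: int
    levels: int = 3
    base_filters: int = 64

    def __post_init__(self):
        if self.in_channels < 1:
            raise ValueError("in_channels must be >= 1")
        if self.levels < 1:
            raise ValueError("levels must be >= 1")


class UNetGenerator:
    """Encoder-decoder with skip connections; spatial size is preserved.

    Each encoder level halves the spatial size with a stride-2 conv; the
    decoder mirrors it with nearest-neighbour upsampling, conv, and
    concatenation of the matching encoder feature map. Input height and
    width must be divisible by ``2**depth``.
    """

    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator):
        self.spec = spec
        f, d = spec.base_filters, spec.depth
        self.inc = nn.Sequential(
            nn.Conv2d(spec.in_channels, f, 3, 1, rng, "inc"), nn.LeakyReLU()
        )
        self.downs = []
        for i in range(d):
            self.downs.append(
                nn.Sequential(
                    nn.Conv2d(f * 2**i, f * 2 ** (i + 1), 3, 2, rng, f"down{i}"),
                    nn.InstanceNorm2d(f * 2 ** (i + 1), name=f"down{i}.in"),
                    nn.LeakyReLU(),
                )
            )
        self.bottleneck = nn.Sequential(
            nn.Conv2d(f * 2**d, f * 2**d, 3, 1, rng, "bott"),
            nn.InstanceNorm2d(f * 2**d, name="bott.in"),
            nn.ReLU(),
        )
        self.ups, self.fuses = [], []
        for i in reversed(range(d)):
            self.ups.append(
                nn.Sequential(
                    nn.Upsample2x(),
                    nn.Conv2d(f * 2 ** (i + 1), f * 2**i, 3, 1, rng, f"up{i}"),
                    nn.InstanceNorm2d(f * 2**i, name=f"up{i}.in"),
                    nn.ReLU(),
                )
            )
            self.fuses.append(
                nn.Sequential(
                    nn.Conv2d(2 * f * 2**i, f * 2**i, 3, 1, rng, f"fuse{i}"),
                    nn.InstanceNorm2d(f * 2**i, name=f"fuse{i}.in"),
                    nn.ReLU(),
                )
            )
        out_layers = [nn.Conv2d(f, spec.out_channels, 1, 1, rng, "out")]
        if spec.output_activation == "tanh":
            out_layers.append(nn.Tanh())
        elif spec.output_activation != "linear":
            raise ValueError(f"unknown activation {spec.output_activation!r}")
        self.out = nn.Sequential(*out_layers)

    def params(self):
        mods = [self.inc, *self.downs, self.bottleneck, *self.ups, *self.fuses, self.out]
        return [p for m in mods for p in m.params()]

    def _check_size(self, x):
        h, w = x.shape[2], x.shape[3]
        div = 2**self.spec.depth
        if h % div or w % div:
            raise ValueError(
                f"spatial size {h}x{w} must be divisible by 2**depth = {div}"
            )

    def forward(self, x):
        if x.shape[1] != self.spec.in_channels:
            raise ValueError(
                f"expected {self.spec.in_channels} input channels, got {x.shape[1]}"
            )
        self._check_size(x)
        caches = {}
        h, caches["inc"] = self.inc.forward(x)
        skips = []
        for i, down in enumerate(self.downs):
            skips.append(h)
            h, caches[f"down{i}"] = down.forward(h)
        h, caches["bott"] = self.bottleneck.forward(h)
        for j, (up, fuse) in enumerate(zip(self.ups, self.fuses)):
            h, caches[f"up{j}"] = up.forward(h)
            skip = skips[-(j + 1)]
            h = np.concatenate([h, skip], axis=1)
            h, caches[f"fuse{j}"] = fuse.forward(h)
        y, caches["out"] = self.out.forward(h)
        return y, caches

    def backward(self, caches, dy):
        dh = self.out.backward(caches["out"], dy)
        dskips = []
        for j in reversed(range(len(self.ups))):
            dcat = self.fuses[j].backward(caches[f"fuse{j}"], dh)
            c = dcat.shape[1] // 2
            dh, dskip = dcat[:, :c], dcat[:, c:]
            dskips.append(dskip)  # appended at j=d-1-m, pairs with skips[m]
            dh = self.ups[j].backward(caches[f"up{j}"], dh)
        dh = self.bottleneck.backward(caches["bott"], dh)
        for i in reversed(range(len(self.downs))):
            dh = self.downs[i].backward(caches[f"down{i}"], dh)
            # skips[i] fed both down i and its matching decoder fuse
            dh = dh + dskips[i]
        return self.inc.backward(caches["inc"], dh)

    def predict(self, x):
        y, _ = self.forward(x)
        return y


class PatchDiscriminator:
    """PatchGAN: stride-2 conv stack ending in a 1-channel score map."""

    def __init__(self, spec: DiscriminatorSpec, rng: np.random.Generator):
        self.spec = spec
        f = spec.base_filters
        layers = [nn.Conv2d(spec.in_channels, f, 4, 2, rng, "d0"), nn.LeakyReLU()]
        for i in range(1, spec.levels):
            layers += [
                nn.Conv2d(f * 2 ** (i - 1), f * 2**i, 4, 2, rng, f"d{i}"),
                nn.InstanceNorm2d(f * 2**i, name=f"d{i}.in"),
                nn.LeakyReLU(),
            ]
        layers.append(nn.Conv2d(f * 2 ** (spec.levels - 1), 1, 4, 1, rng, "dout"))
        self.net = nn.Sequential(*layers)

    def params(self):
        return self.net.params()

    def forward(self, x):
        if x.shape[1] != self.spec.in_channels:
            raise ValueError(
                f"expected {self.spec.in_channels} input channels, got {x.shape[1]}"
            )
        min_size = 2**self.spec.levels
        if x.shape[2] < min_size or x.shape[3] < min_size:
            raise ValueError(
                f"input {x.shape[2]}x{x.shape[3]} smaller than the receptive "
                f"stack ({min_size} px minimum)"
            )
        return self.net.forward(x)

    def backward(self, caches, dy):
        return self.net.backward(caches, dy)

    def predict(self, x):
        y, _ = self.forward(x)
        return y


@dataclass
class ModelBundle:
    """The four networks of the stain-conversion CycleGAN."""

    g_he_to_evg: UNetGenerator  # 61 -> 3
    g_evg_to_he: UNetGenerator  # 3 -> 61
    d_he: PatchDiscriminator  # scores 61-channel cubes
    d_evg: PatchDiscriminator  # scores 3-channel RGB

    def specs(self) -> dict:
        return {
            "g_he_to_evg": asdict(self.g_he_to_evg.spec),
            "g_evg_to_he": asdict(self.g_evg_to_he.spec),
            "d_he": asdict(self.d_he.spec),
            "d_evg": asdict(self.d_evg.spec),
        }

    def named_params(self) -> dict:
        out = {}
        for net_name in ("g_he_to_evg", "g_evg_to_he", "d_he", "d_evg"):
            for i, p in enumerate(getattr(self, net_name).params()):
                out[f"{net_name}/{i}:{p.name}"] = p
        return out


def build_generator(spec: GeneratorSpec, seed: int = 0) -> UNetGenerator:
    return UNetGenerator(spec, np.random.default_rng(seed))


def build_discriminator(spec: DiscriminatorSpec, seed: int = 0) -> PatchDiscriminator:
    return PatchDiscriminator(spec, np.random.default_rng(seed))


def build_bundle(
    n_bands: int = 61,
    depth: int = 4,
    base_filters: int = 64,
    d_levels: int = 3,
    d_base_filters: int = 64,
    seed: int = 0,
) -> ModelBundle:
    """Construct the four networks with a deterministic seed fan-out."""
    ss = np.random.SeedSequence(seed).spawn(4)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss]
    return ModelBundle(
        g_he_to_evg=UNetGenerator(
            GeneratorSpec(n_bands, 3, depth, base_filters), np.random.default_rng(seeds[0])
        ),
        g_evg_to_he=UNetGenerator(
            GeneratorSpec(3, n_bands, depth, base_filters), np.random.default_rng(seeds[1])
        ),
        d_he=PatchDiscriminator(
            DiscriminatorSpec(n_bands, d_levels, d_base_filters), np.random.default_rng(seeds[2])
        ),
        d_evg=PatchDiscriminator(
            DiscriminatorSpec(3, d_levels, d_base_filters), np.random.default_rng(seeds[3])
        ),
    )


def toy_bundle(n_bands: int = 61, seed: int = 0) -> ModelBundle:
    """Small preset (depth 2, 8 filters) for CPU experiments and tests."""
    return build_bundle(n_bands, depth=2, base_filters=8, d_levels=2,
                        d_base_filters=8, seed=seed)


def save_weights(bundle: ModelBundle, path) -> None:
    """Save all parameters (npz) with a JSON architecture sidecar."""
    path = Path(path)
    arrays = {k: p.value for k, p in bundle.named_params().items()}
    with open(path, "wb") as f:  # keep the exact filename (no .npz appended)
        np.savez(f, **arrays)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(bundle.specs(), indent=1)
    )


def load_bundle(path, seed: int = 0) -> ModelBundle:
    """Reconstruct a bundle from a checkpoint's architecture sidecar."""
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"architecture sidecar {sidecar} missing")
    specs = json.loads(sidecar.read_text())
    rng = np.random.default_rng(seed)
    bundle = ModelBundle(
        g_he_to_evg=UNetGenerator(GeneratorSpec(**specs["g_he_to_evg"]), rng),
        g_evg_to_he=UNetGenerator(GeneratorSpec(**specs["g_evg_to_he"]), rng),
        d_he=PatchDiscriminator(DiscriminatorSpec(**specs["d_he"]), rng),
        d_evg=PatchDiscriminator(DiscriminatorSpec(**specs["d_evg"]), rng),
    )
    return load_weights(path, bundle)


def load_weights(path, bundle: ModelBundle) -> ModelBundle:
    """Load a checkpoint into a bundle, validating the architecture."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"checkpoint {path} does not exist")
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        saved = json.loads(sidecar.read_text())
        mine = bundle.specs()
        diffs = [k for k in mine if saved.get(k) != mine[k]]
        if diffs:
            raise ValueError(
                "checkpoint architecture differs from the bundle in: "
                + ", ".join(
                    f"{k} (saved {saved.get(k)} vs expected {mine[k]})"
                    for k in diffs
                )
            )
    with np.load(path) as data:
        params = bundle.named_params()
        missing = set(params) - set(data.files)
        if missing:
            raise ValueError(f"checkpoint missing parameters: {sorted(missing)[:5]}")
        for k, p in params.items():
            arr = data[k]
            if arr.shape != p.value.shape:
                raise ValueError(
                    f"parameter {k}: saved shape {arr.shape} vs expected "
                    f"{p.value.shape}"
                )
            p.value[...] = arr
    return bundle


# ---------------------------------------------------------------------------
# Normalisation between physical units and the networks' [-1, 1] range


def normalize_cube(t: np.ndarray) -> np.ndarray:
    """Transmittance [0, TRANSMITTANCE_MAX] -> [-1, 1]."""
    return 2.0 * np.asarray(t, dtype=float) / TRANSMITTANCE_MAX - 1.0


def denormalize_cube(x: np.ndarray) -> np.ndarray:
    return np.clip((np.asarray(x) + 1.0) * (TRANSMITTANCE_MAX / 2.0), 0.0, None)


def normalize_rgb(img: np.ndarray) -> np.ndarray:
    """8-bit RGB [0, 255] -> [-1, 1]."""
    return np.asarray(img, dtype=float) / 127.5 - 1.0


def denormalize_rgb(x: np.ndarray) -> np.ndarray:
    return np.clip(np.round((np.asarray(x) + 1.0) * 127.5), 0, 255).astype(np.uint8)


def projection_scale(basis_matrix: np.ndarray) -> np.ndarray:
    """Per-row bound on |projection| of a cube with T <= TRANSMITTANCE_MAX.

    Dividing a projection by this scale puts each channel inside [-1, 1],
    matching the generators' working range.
    """
    return np.abs(np.asarray(basis_matrix)).sum(axis=1) * TRANSMITTANCE_MAX
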