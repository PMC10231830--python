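"""Loss operators and the two training phases."""

import numpy as np
import pytest

from spectralstain import stain_gan as sg
from spectralstain.synthetic_data import PhantomConfig, generate_phantom
from spectralstain.spectral_basis import basis_channel_select
from spectralstain.training import (
    IdentityInputs,
    LossWeights,
    TrainingConfig,
    adversarial_loss,
    convert_cube,
    cycle_loss,
    generator_adversarial_loss,
    identity_loss,
    make_identity_inputs,
    total_loss,
    train_phase1,
    train_phase2_refine,
)


class TestAdversarialLoss:
    def test_perfect_discrimination_gives_zero(self):
        assert adversarial_loss(np.ones((2, 2)), np.zeros((2, 2))) == 0.0

    def test_fooled_discriminator_zeroes_generator_term(self):
        assert generator_adversarial_loss(np.ones((3, 3))) == 0.0

    def test_scalar_half_scores(self):
        # (0.5-1)^2 + 0.5^2 = 0.25 + 0.25
        assert adversarial_loss(np.array([0.5]), np.array([0.5])) == pytest.approx(0.5)

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            adversarial_loss(np.empty(0), np.ones(2))


class TestCycleLoss:
    def test_perfect_reconstruction_is_zero(self, rng):
        x = rng.normal(size=(4, 4, 3))
        assert cycle_loss(x, x.copy()) == 0.0

    def test_constant_offset(self, rng):
        x = rng.normal(size=(4, 4, 3))
        assert cycle_loss(x, x + 0.2) == pytest.approx(0.2)

    def test_matches_elementwise_loop_oracle(self, rng):
        x = rng.normal(size=(4, 4, 3))
        y = rng.normal(size=(4, 4, 3))
        total = 0.0
        for i in range(4):
            for j in range(4):
                for k in range(3):
                    total += abs(x[i, j, k] - y[i, j, k])
        assert cycle_loss(x, y) == pytest.approx(total / 48)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            cycle_loss(rng.normal(size=(2, 2)), rng.normal(size=(3, 2)))


class TestIdentityLoss:
    @pytest.fixture
    def inputs(self, phantom):
        basis = basis_channel_select(phantom.he_cube.grid)
        return make_identity_inputs(phantom.he_cube, phantom.evg_rgb, basis)

    def test_padding_channels_are_image_space_zeros(self, inputs):
        # 58 channels of zero padding, i.e. -1 after [0,255] -> [-1,1]
        assert inputs.evg_inc.shape[0] == 61
        assert np.all(inputs.evg_inc[3:] == sg.normalize_rgb(0.0))
        assert inputs.evg_inc.shape[0] - inputs.evg_org.shape[0] == 58

    def test_matches_from_scratch_recomputation(self, inputs):
        bundle = sg.toy_bundle(n_bands=61, seed=8)
        got = identity_loss(bundle, inputs)
        id_he = bundle.g_evg_to_he.predict(inputs.he_red[None])[0]
        id_evg = bundle.g_he_to_evg.predict(inputs.evg_inc[None])[0]
        expect = float(np.mean(np.abs(id_he - inputs.he_org))) + float(
            np.mean(np.abs(id_evg - inputs.evg_org))
        )
        assert got == pytest.approx(expect, rel=1e-6)
        assert got > 0

    def test_zero_for_perfect_identity_generators(self, inputs):
        class Oracle:
            def __init__(self, target):
                self.target = target

            def predict(self, x):
                return self.target[None]

        bundle = type("B", (), {})()
        bundle.g_evg_to_he = Oracle(inputs.he_org)
        bundle.g_he_to_evg = Oracle(inputs.evg_org)
        assert identity_loss(bundle, inputs) == 0.0


class TestTotalLoss:
    def test_paper_weighted_combination(self):
        # 1 + 5*2 + 0.5*4
        assert total_loss(1.0, 2.0, 4.0) == pytest.approx(13.0)

    def test_zero_identity_weight_is_ablation(self):
        w = LossWeights(lambda_cycle=5.0, gamma_identity=0.0)
        assert total_loss(1.0, 2.0, 100.0, w) == pytest.approx(11.0)

    def test_all_zero_components(self):
        assert total_loss(0.0, 0.0, 0.0) == 0.0

    def test_linear_in_each_component(self, rng):
        a, c, i = rng.uniform(size=3)
        w = LossWeights()
        base = total_loss(a, c, i, w)
        assert total_loss(a + 1, c, i, w) == pytest.approx(base + 1)
        assert total_loss(a, c + 1, i, w) == pytest.approx(base + w.lambda_cycle)
        assert total_loss(a, c, i + 1, w) == pytest.approx(base + w.gamma_identity)


@pytest.fixture(scope="module")
def toy_basis():
    from spectralstain.hsi_core import make_wavelength_grid

    return basis_channel_select(make_wavelength_grid(420, 720, 5))


def _toy_config(**kw):
    defaults = dict(
        phase=1, epochs=2, seed=0, depth=2, base_filters=4,
        d_levels=2, d_base_filters=4, learning_rate=5e-4,
    )
    defaults.update(kw)
    return TrainingConfig(**defaults)


class TestPhase1:
    def test_zero_epochs_leaves_weights_at_initialization(self, phantom_pool, toy_basis):
        he, evg = phantom_pool
        bundle, history = train_phase1((he, evg), _toy_config(epochs=0), toy_basis)
        fresh = sg.build_bundle(61, depth=2, base_filters=4, d_levels=2,
                                d_base_filters=4, seed=0)
        for (ka, pa), (kb, pb) in zip(
            bundle.named_params().items(), fresh.named_params().items()
        ):
            assert ka == kb and np.array_equal(pa.value, pb.value)
        assert history == []

    def test_training_descends(self, phantom_pool, toy_basis):
        he, evg = phantom_pool
        _, history = train_phase1((he, evg), _toy_config(epochs=8), toy_basis)
        assert history[-1]["total"] < history[0]["total"]

    def test_same_seed_reproduces_loss_history_exactly(self, phantom_pool, toy_basis):
        he, evg = phantom_pool
        _, h1 = train_phase1((he[:2], evg[:2]), _toy_config(epochs=2), toy_basis)
        _, h2 = train_phase1((he[:2], evg[:2]), _toy_config(epochs=2), toy_basis)
        assert h1 == h2

    def test_empty_pool_rejected(self, phantom_pool, toy_basis):
        he, _ = phantom_pool
        with pytest.raises(ValueError, match="non-empty"):
            train_phase1((he, []), _toy_config(), toy_basis)

    def test_indivisible_tile_size_rejected(self, toy_basis):
        bad = generate_phantom(PhantomConfig(size=(30, 30), seed=0))
        with pytest.raises(ValueError, match="divisible"):
            train_phase1(
                ([bad.he_cube], [bad.evg_rgb]), _toy_config(depth=2), toy_basis
            )


@pytest.fixture(scope="module")
def pairs():
    samples = [generate_phantom(PhantomConfig(size=(32, 32), seed=70 + s)) for s in range(3)]
    return [(s.he_cube, s.evg_rgb) for s in samples]


class TestPhase2:
    def test_missing_checkpoint_without_ablation_flag_rejected(self, pairs):
        with pytest.raises(ValueError, match="checkpoint"):
            train_phase2_refine(pairs, _toy_config(phase=2))

    def test_refinement_descends(self, pairs):
        gen, history = train_phase2_refine(
            pairs, _toy_config(phase=2, epochs=6, learning_rate=1.5e-4),
            allow_random_init=True,
        )
        assert history[-1]["mse"] < history[0]["mse"]

    def test_already_optimal_pairs_give_near_zero_loss(self, pairs):
        bundle = sg.build_bundle(61, depth=2, base_filters=4, d_levels=2,
                                 d_base_filters=4, seed=4)
        # targets = what the generator already outputs
        fixed_point = [
            (cube, convert_cube(bundle.g_he_to_evg, cube)) for cube, _ in pairs
        ]
        before = {k: p.value.copy() for k, p in bundle.named_params().items()}
        # default phase-2 learning rate (3e-5) so Adam's normalised steps on
        # quantisation-noise gradients stay negligible within the epoch
        gen, history = train_phase2_refine(
            fixed_point,
            _toy_config(phase=2, epochs=1, learning_rate=None),
            bundle=bundle,
        )
        # residual loss comes only from the target's 8-bit quantisation
        assert history[0]["mse"] < 5e-4
        for k, p in bundle.named_params().items():
            if k.startswith("g_he_to_evg"):
                assert np.allclose(p.value, before[k], atol=1e-3)

    def test_provenance_tags_distinguish_init_modes(self, pairs):
        _, h_rand = train_phase2_refine(
            pairs, _toy_config(phase=2, epochs=1), allow_random_init=True
        )
        bundle = sg.build_bundle(61, depth=2, base_filters=4, d_levels=2,
                                 d_base_filters=4, seed=0)
        _, h_pre = train_phase2_refine(
            pairs, _toy_config(phase=2, epochs=1), bundle=bundle
        )
        assert h_rand[0]["init"] == "random"
        assert h_pre[0]["init"] == "phase1"


class TestConfigValidation:
    def test_phase_specific_learning_rate_defaults(self):
        assert TrainingConfig(phase=1).learning_rate == pytest.approx(2e-4)
        assert TrainingConfig(phase=2).learning_rate == pytest.approx(3e-5)

    def test_default_loss_weights_match_published_values(self):
        w = LossWeights()
        assert w.lambda_cycle == 5.0 and w.gamma_identity == 0.5

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            TrainingConfig(phase=3)
        with pytest.raises(ValueError):
            TrainingConfig(batch_size=7)
        with pytest.raises(ValueError):
            TrainingConfig(basis_mode="pca_only")
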