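"""Architecture contracts: dense blocks, generator, critic."""

import numpy as np
import pytest

from cgdenoise.networks import (
    Discriminator,
    DiscriminatorConfig,
    Generator,
    GeneratorConfig,
    RDBConfig,
    ResidualDenseBlock,
    discriminator_forward,
    generator_forward,
    rdb_forward,
)

SMALL_RDB = RDBConfig(n_conv_layers=3, growth_channels=4, block_channels=8)


def small_gen_config(**kwargs):
    defaults = dict(n_rdbs=2, base_channels=8, in_channels=2, rdb=SMALL_RDB)
    defaults.update(kwargs)
    return GeneratorConfig(**defaults)


class TestResidualDenseBlock:
    def test_zeroed_fusion_is_identity(self, rng):
        block = ResidualDenseBlock(SMALL_RDB, rng)
        block.fusion.params["weight"][...] = 0.0
        block.fusion.params["bias"][...] = 0.0
        x = rng.random((1, 8, 12, 12))
        np.testing.assert_array_equal(rdb_forward(block, x), x)

    def test_spatial_size_preserved(self, rng):
        block = ResidualDenseBlock(SMALL_RDB, rng)
        assert block.forward(rng.random((1, 8, 70, 70))).shape == (1, 8, 70, 70)

    def test_dense_concatenation_widths(self, rng):
        """Layer i sees block_channels + i*growth inputs; fusion sees the full stack."""
        cfg = RDBConfig(n_conv_layers=4, growth_channels=5, block_channels=16)
        block = ResidualDenseBlock(cfg, rng)
        for i, conv in enumerate(block.convs):
            assert conv.in_channels == 16 + i * 5
        assert block.fusion.in_channels == 16 + 4 * 5
        assert block.fusion.kernel_size == 1

    def test_channel_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            ResidualDenseBlock(SMALL_RDB, rng).forward(rng.random((1, 7, 8, 8)))


class TestGenerator:
    def test_shape_and_range_contract(self, rng):
        gen = Generator(small_gen_config(), 0)
        out = gen.forward(rng.random((1, 2, 64, 64)))
        assert out.shape == (1, 1, 64, 64)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_forward_deterministic(self, rng):
        gen = Generator(small_gen_config(), 0)
        x = rng.random((1, 2, 32, 32))
        np.testing.assert_array_equal(gen.forward(x), gen.forward(x))

    def test_fully_convolutional_across_sizes(self, rng):
        gen = Generator(small_gen_config(), 0)
        for size in (24, 40):
            assert gen.forward(rng.random((1, 2, size, size))).shape[2:] == (size, size)

    def test_parameter_count_analytic(self):
        """Closed-form layer-table sum for a small config."""
        cfg = small_gen_config()
        gen = Generator(cfg, 0)
        ch, g, nc = 8, 4, 3
        conv = lambda cin, cout, k: cout * cin * k * k + cout
        inorm = 2 * ch
        rdb = sum(conv(ch + i * g, g, 3) for i in range(nc)) + conv(ch + nc * g, ch, 1)
        expect = (
            conv(2, ch, 3) + inorm          # head
            + cfg.n_rdbs * rdb              # dense blocks
            + 2 * (conv(ch, ch, 3) + inorm) # tail fusion convs
            + conv(ch, 1, 3)                # output projection
        )
        assert gen.n_parameters() == expect

    def test_zeroed_blocks_reduce_to_outer_chain(self, rng):
        """With every fusion zeroed the RDB cascade is an identity between head and tails."""
        cfg = small_gen_config(n_rdbs=4)
        full = Generator(cfg, 3)
        short = Generator(small_gen_config(n_rdbs=1), 3)
        # align outer layers, zero all fusions
        sd = full.state_dict()
        for gen in (full, short):
            for b in gen.blocks:
                b.fusion.params["weight"][...] = 0.0
                b.fusion.params["bias"][...] = 0.0
        for name in ("head", "proj"):
            getattr(short, name).params.update(
                {k: v.copy() for k, v in getattr(full, name).params.items()}
            )
        for (c1, n1, _), (c2, n2, _) in zip(short.tails, full.tails):
            c1.params.update({k: v.copy() for k, v in c2.params.items()})
            n1.params.update({k: v.copy() for k, v in n2.params.items()})
        short.head_norm.params.update({k: v.copy() for k, v in full.head_norm.params.items()})
        x = rng.random((1, 2, 16, 16))
        np.testing.assert_allclose(full.forward(x), short.forward(x), rtol=1e-12)

    def test_gradient_reaches_first_convolution(self, rng):
        gen = Generator(small_gen_config(), 1)
        x = rng.random((1, 2, 16, 16))
        y = gen.forward(x)
        gen.zero_grad()
        gen.backward(np.ones_like(y))
        assert np.any(gen.head.grads["weight"] != 0.0)

    def test_wrong_channel_count_rejected(self, rng):
        with pytest.raises(ValueError):
            Generator(small_gen_config(), 0).forward(rng.random((1, 3, 16, 16)))

    def test_generator_forward_wrapper(self, phantom):
        gen = Generator(small_gen_config(), 0)
        out = generator_forward(gen, [phantom, phantom])
        assert out.shape == phantom.shape


class TestDiscriminator:
    CFG = DiscriminatorConfig(n_conv_stages=2, base_channels=4, input_size=(16, 16))

    def test_scalar_finite_score(self, phantom):
        disc = Discriminator(self.CFG, 0)
        score = discriminator_forward(disc, phantom[:16, :16], phantom[16:32, :16])
        assert np.isfinite(score)

    def test_final_layer_scaling_scales_score(self, rng):
        """No saturation: scaling fc weights by k scales the score deviation by k."""
        disc = Discriminator(self.CFG, 0)
        x = rng.random((1, 2, 16, 16))
        s1 = disc.forward(x)[0]
        disc.fc.params["weight"] *= 5.0
        disc.fc.params["bias"] *= 5.0
        assert disc.forward(x)[0] == pytest.approx(5.0 * s1, rel=1e-9)

    def test_swapping_pair_changes_score(self, rng):
        disc = Discriminator(self.CFG, 7)
        a, b = rng.random((16, 16)), rng.random((16, 16))
        assert discriminator_forward(disc, a, b) != discriminator_forward(disc, b, a)

    def test_dimension_mismatch_rejected(self, rng):
        disc = Discriminator(self.CFG, 0)
        with pytest.raises(ValueError):
            disc.score(rng.random((1, 1, 16, 16)), rng.random((1, 1, 8, 8)))

    def test_wrong_input_size_rejected(self, rng):
        disc = Discriminator(self.CFG, 0)
        with pytest.raises(ValueError):
            disc.forward(rng.random((1, 2, 32, 32)))


class TestConfigValidation:
    @pytest.mark.parametrize(
        "ctor",
        [
            lambda: RDBConfig(n_conv_layers=1),
            lambda: RDBConfig(growth_channels=0),
            lambda: GeneratorConfig(n_rdbs=0),
            lambda: GeneratorConfig(n_conv_layers_outer=1),
            lambda: GeneratorConfig(base_channels=32),  # mismatched rdb width
            lambda: DiscriminatorConfig(n_conv_stages=0),
        ],
    )
    def test_invalid_configs_rejected(self, ctor):
        with pytest.raises(ValueError):
            ctor()
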