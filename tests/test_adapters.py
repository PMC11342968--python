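"""Stain adapters: SAN, normalization, augmentation, mix-up, batch driver."""

import numpy as np
import pytest

import stainsan as ss
from stainsan.adapters import AdaptationConfig
from stainsan.errors import ConfigurationError, ParameterError, ShapeError
from stainsan.extraction import StainIntensityMatrix


def _norm_cfg(**kw):
    kw.setdefault("method", "normalize")
    kw.setdefault("percentile_rescale", None)
    return AdaptationConfig(**kw)


class TestPerturbIntensity:
    def test_epsilon_zero_is_identity(self, rng):
        h = StainIntensityMatrix(matrix=rng.uniform(0, 2, (2, 50)))
        assert ss.perturb_intensity(h, 0.0, rng) is h

    def test_single_alpha_within_bounds(self, rng):
        h = StainIntensityMatrix(matrix=rng.uniform(0.1, 2, (2, 50)))
        out = ss.perturb_intensity(h, 0.2, rng)
        ratio = out.matrix / h.matrix
        assert ratio.std() < 1e-12  # one global alpha
        assert 0.8 <= ratio.mean() <= 1.2

    def test_seeded_determinism(self, rng):
        h = StainIntensityMatrix(matrix=rng.uniform(0.1, 2, (2, 50)))
        a = ss.perturb_intensity(h, 0.2, np.random.default_rng(5))
        b = ss.perturb_intensity(h, 0.2, np.random.default_rng(5))
        assert np.array_equal(a.matrix, b.matrix)

    def test_epsilon_one_rejected(self, rng):
        h = StainIntensityMatrix(matrix=np.ones((2, 4)))
        with pytest.raises(ParameterError):
            ss.perturb_intensity(h, 1.0, rng)


class TestStainSan:
    def test_test_role_is_deterministic_normalization_to_w0(self, phantom_decomp, fitted_dist):
        cfg = AdaptationConfig(method="san", role="test")
        out1 = ss.adapt_stain_san(phantom_decomp, fitted_dist, cfg, rng=1)
        out2 = ss.adapt_stain_san(phantom_decomp, fitted_dist, cfg, rng=999)
        assert np.array_equal(out1.pixels, out2.pixels)  # zero-variance resampling
        norm = ss.adapt_normalize(phantom_decomp, fitted_dist.W0, _norm_cfg())
        assert np.array_equal(out1.pixels, norm.pixels)

    def test_degenerate_train_equals_normalization(self, phantom_decomp, fitted_dist):
        # sigma = 0 and epsilon = 0: all randomness degenerate (Dirac at W0)
        dist0 = ss.StainDistribution(W0=fitted_dist.W0, sigma=0.0)
        cfg = AdaptationConfig(method="san", role="train", epsilon=0.0)
        out = ss.adapt_stain_san(phantom_decomp, dist0, cfg, rng=3)
        norm = ss.adapt_normalize(phantom_decomp, fitted_dist.W0, _norm_cfg())
        assert np.array_equal(out.pixels, norm.pixels)

    def test_background_restored_verbatim(self, phantom, phantom_decomp, fitted_dist):
        image, _, _ = phantom
        cfg = AdaptationConfig(method="san", role="train")
        out = ss.adapt_stain_san(phantom_decomp, fitted_dist, cfg, rng=2)
        flat_out = out.pixels.reshape(-1, 3)
        flat_src = image.pixels.reshape(-1, 3)
        assert np.array_equal(flat_out[phantom_decomp.mask], flat_src[phantom_decomp.mask])

    def test_m_mismatch_rejected(self, phantom_decomp):
        bad = ss.StainDistribution(W0=np.full((3, 4), 0.5), sigma=0.01)
        with pytest.raises(ShapeError, match="mismatch"):
            ss.adapt_stain_san(
                phantom_decomp, bad, AdaptationConfig(method="san"), rng=0
            )

    def test_label_safety_dimensions_preserved(self, phantom, phantom_decomp, fitted_dist):
        image, _, _ = phantom
        out = ss.adapt_stain_san(
            phantom_decomp, fitted_dist, AdaptationConfig(method="san"), rng=0
        )
        assert out.pixels.shape == image.pixels.shape


class TestNormalize:
    def test_identity_adaptation(self, phantom_decomp):
        # reference = the image's own W, rescale off: pure round trip of W H
        out = ss.adapt_normalize(phantom_decomp, phantom_decomp.colors, _norm_cfg())
        recon = ss.od_to_rgb(
            ss.OdImage(
                od=np.maximum(
                    phantom_decomp.colors.matrix @ phantom_decomp.intensities.matrix, 0
                ),
                shape=phantom_decomp.source_shape,
            )
        )
        fg = ~phantom_decomp.mask
        assert np.array_equal(
            out.pixels.reshape(-1, 3)[fg], recon.pixels.reshape(-1, 3)[fg]
        )

    def test_two_images_converge_to_reference(self, small_study):
        _, train, test, _ = small_study
        ref = ss.cbcs_reference()
        cfg = _norm_cfg()
        recovered = []
        for img in (train.images[0], test.images[0]):
            out = ss.adapt_normalize(ss.decompose(img), ref.W0, cfg)
            recovered.append(ss.decompose(out).colors)
        target = ref.W0 / np.linalg.norm(ref.W0, axis=0)
        for w in recovered:
            assert ss.column_angles_degrees(w, target).max() < 2.0

    def test_percentile_rescale_matches_reference(self, phantom_decomp):
        from stainsan.adapters import stain_percentiles

        cfg = AdaptationConfig(method="normalize", percentile_rescale=99.0)
        ref_p = stain_percentiles(phantom_decomp, 99.0) * 1.5
        out = ss.adapt_normalize(
            phantom_decomp, phantom_decomp.colors, cfg, reference_percentiles=ref_p
        )
        d2 = ss.decompose(out)
        new_p = stain_percentiles(d2, 99.0)
        assert np.allclose(new_p, ref_p, rtol=0.05)

    def test_zero_reference_percentile_warns_and_skips(self, phantom_decomp):
        cfg = AdaptationConfig(method="normalize", percentile_rescale=99.0)
        with pytest.warns(UserWarning, match="skip"):
            out = ss.adapt_normalize(
                phantom_decomp,
                phantom_decomp.colors,
                cfg,
                reference_percentiles=np.zeros(2),
            )
        base = ss.adapt_normalize(phantom_decomp, phantom_decomp.colors, _norm_cfg())
        assert np.array_equal(out.pixels, base.pixels)


class TestAugment:
    def test_zero_epsilons_identity(self, phantom_decomp):
        cfg = AdaptationConfig(method="augment", role="train", epsilon1=0.0, epsilon2=0.0)
        out = ss.adapt_augment(phantom_decomp, cfg, rng=0)
        ident = ss.adapt_normalize(phantom_decomp, phantom_decomp.colors, _norm_cfg())
        assert np.array_equal(out.pixels, ident.pixels)

    def test_columns_within_support_box(self, phantom_decomp):
        w = phantom_decomp.colors.matrix
        gen = np.random.default_rng(5)
        for _ in range(50):
            alphas = gen.uniform(0.8, 1.2, size=2)
            betas = gen.uniform(-0.2, 0.2, size=2)
            w_prime = np.maximum(w * alphas[None, :] + betas[None, :], 0.0)
            assert np.all(w_prime >= np.maximum(0.8 * w - 0.2, 0.0) - 1e-12)
            assert np.all(w_prime <= 1.2 * w + 0.2 + 1e-12)

    def test_beta_as_printed_shifts_by_one(self, phantom_decomp):
        cfg = AdaptationConfig(
            method="augment",
            role="train",
            epsilon1=0.0,
            epsilon2=0.0,
            augment_beta_as_printed=True,
        )
        # epsilon2 = 0 forces beta_i = 1 exactly under the printed convention
        gen = np.random.default_rng(0)
        alphas = gen.uniform(1, 1, size=2)
        betas = gen.uniform(1, 1, size=2)
        assert np.all(betas == 1.0)
        out = ss.adapt_augment(phantom_decomp, cfg, rng=0)
        w_expected = phantom_decomp.colors.matrix + 1.0
        manual = ss.adapt_normalize(phantom_decomp, w_expected, _norm_cfg())
        assert np.array_equal(out.pixels, manual.pixels)

    def test_test_role_noop_with_warning(self, phantom_decomp):
        cfg = AdaptationConfig(method="augment", role="test")
        with pytest.warns(UserWarning, match="test"):
            out = ss.adapt_augment(phantom_decomp, cfg, rng=0)
        ident = ss.adapt_normalize(phantom_decomp, phantom_decomp.colors, _norm_cfg())
        assert np.array_equal(out.pixels, ident.pixels)


class TestMixup:
    def test_endpoints(self, phantom_decomp, small_study):
        _, _, test, _ = small_study
        other = ss.decompose(test.images[0]).colors
        cfg = AdaptationConfig(method="mixup", epsilon=0.0)
        at0 = ss.adapt_mixup(phantom_decomp, other, cfg, u=0.0)
        own = ss.adapt_normalize(phantom_decomp, phantom_decomp.colors, _norm_cfg())
        assert np.array_equal(at0.pixels, own.pixels)
        at1 = ss.adapt_mixup(phantom_decomp, other, cfg, u=1.0)
        theirs = ss.adapt_normalize(phantom_decomp, other, _norm_cfg())
        assert np.array_equal(at1.pixels, theirs.pixels)

    def test_interpolation_is_convex(self, phantom_decomp, small_study):
        _, _, test, _ = small_study
        wj = phantom_decomp.colors.matrix
        wk = ss.decompose(test.images[0]).colors.matrix
        for u in (0.25, 0.5, 0.9):
            w_mix = (1 - u) * wj + u * wk
            assert np.all(w_mix >= np.minimum(wj, wk) - 1e-12)
            assert np.all(w_mix <= np.maximum(wj, wk) + 1e-12)


class TestAdaptBatch:
    def test_seeded_batch_determinism(self, small_study, fitted_dist):
        _, train, _, _ = small_study
        cfg = AdaptationConfig(method="san", role="train", rng_seed=9)
        out1 = ss.adapt_batch(train.images[:5], cfg, dist=fitted_dist)
        out2 = ss.adapt_batch(train.images[:5], cfg, dist=fitted_dist)
        assert all(np.array_equal(a.pixels, b.pixels) for a, b in zip(out1, out2))

    def test_mixup_requires_other_batch(self, small_study):
        _, train, _, _ = small_study
        cfg = AdaptationConfig(method="mixup")
        with pytest.raises(ConfigurationError, match="other_batch"):
            ss.adapt_batch(train.images[:3], cfg)

    def test_san_test_role_requires_distribution(self, small_study):
        _, train, _, _ = small_study
        cfg = AdaptationConfig(method="san", role="test")
        with pytest.raises(ConfigurationError, match="dist"):
            ss.adapt_batch(train.images[:3], cfg)

    def test_san_test_batch_shares_color_basis(self, small_study, fitted_dist):
        _, _, test, _ = small_study
        cfg = AdaptationConfig(method="san", role="test")
        outs = ss.adapt_batch(test.images, cfg, dist=fitted_dist)
        target = fitted_dist.W0 / np.linalg.norm(fitted_dist.W0, axis=0)
        for out in outs:
            w = ss.decompose(out).colors
            assert ss.column_angles_degrees(w, target).max() < 2.0

    def test_san_train_fits_on_batch_when_no_dist(self, small_study):
        _, train, _, _ = small_study
        cfg = AdaptationConfig(method="san", role="train", rng_seed=4)
        outs, records = ss.adapt_batch(train.images, cfg, return_records=True)
        assert len(outs) == len(train.images)
        assert all("W_prime" in r and "alpha" in r for r in records)

    def test_energy_preserved_across_adapted_batch(self, small_study, fitted_dist):
        # sampled W' over a large batch carries the target energy 3 m sigma^2
        gen = np.random.default_rng(0)
        draws = np.stack(
            [
                ss.sample_color_matrix(fitted_dist, gen).flatten(order="F")
                for _ in range(5000)
            ]
        )
        trace = float(np.trace(np.cov(draws, rowvar=False, ddof=1)))
        assert trace == pytest.approx(fitted_dist.total_energy, rel=0.10)
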