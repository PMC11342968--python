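"""Stain domain adapters: SAN, normalization, augmentation, and mix-up.

All four methods share one skeleton — decompose ``V = W H``, choose an adapted
color matrix ``W'`` from a method-specific target domain, optionally perturb
the intensities ``H``, and reconstruct ``I' = I0 * exp(-W' H')`` — differing
only in the target domain for ``W'``:

================  ==========================  ==========================
method            training target              test target
================  ==========================  ==========================
normalize         point mass at ``W0``         point mass at ``W0``
augment           per-column uniform jitter    unchanged (point mass at W)
mixup             random interpolation to a    same (needs the other batch)
                  partner batch matrix
san               ``N(vec(W0), sigma^2 I)``    point mass at ``W0``
================  ==========================  ==========================

Stain SAN resamples ``W'`` from the energy-preserving spherical Gaussian
fitted on the training batch, so training images are augmented and test
images are normalized by the *same* target distribution; setting its variance
and the intensity jitter to zero recovers plain normalization exactly.

Background pixels (identified in OD space at decomposition time) are restored
verbatim from the source image in every adapted output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .distribution import (
    StainDistribution,
    estimate_distribution,
    sample_color_matrix,
)
from .errors import ConfigurationError, ParameterError, ShapeError
from .extraction import (
    StainColorMatrix,
    StainDecomposition,
    StainIntensityMatrix,
    decompose,
)
from .od_color import OdImage, RgbImage, od_to_rgb

__all__ = [
    "AdaptationConfig",
    "perturb_intensity",
    "adapt_stain_san",
    "adapt_normalize",
    "adapt_augment",
    "adapt_mixup",
    "adapt_batch",
    "stain_percentiles",
]

METHODS = ("san", "normalize", "augment", "mixup")
ROLES = ("train", "test")


@dataclass
class AdaptationConfig:
    """Knobs shared by decomposition and all adapters.

    ``epsilon`` bounds the global intensity jitter ``alpha ~ U(1-eps, 1+eps)``
    used by SAN and mix-up; ``epsilon1``/``epsilon2`` bound augmentation's
    per-column scale and shift.  All three default to 0.2, the setting under
    which the methods were benchmarked.  ``percentile_rescale`` is the
    percentile (default 99) matched across images when normalizing intensity
    rows; set to None to disable.  ``augment_beta_as_printed`` switches the
    augmentation shift from the physically sensible ``U(-eps2, +eps2)`` to the
    literal ``U(1-eps2, 1+eps2)`` convention.
    """

    method: str = "san"
    role: str = "train"
    epsilon: float = 0.2
    epsilon1: float = 0.2
    epsilon2: float = 0.2
    mask_threshold: float = 0.3
    incident_intensity: float = 255.0
    angle_percentile: float = 1.0
    percentile_rescale: float | None = 99.0
    rng_seed: int = 0
    augment_beta_as_printed: bool = False
    min_foreground: int = 100
    intensity_solver: str = "clip"

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ParameterError(f"method must be one of {METHODS}; got {self.method!r}")
        if self.role not in ROLES:
            raise ParameterError(f"role must be one of {ROLES}; got {self.role!r}")
        for name in ("epsilon", "epsilon1", "epsilon2"):
            val = getattr(self, name)
            if not 0 <= val < 1:
                raise ParameterError(
                    f"{name} must be in [0, 1) so intensities stay positive; got {val}"
                )
        if self.percentile_rescale is not None and not 0 < self.percentile_rescale <= 100:
            raise ParameterError(
                f"percentile_rescale must be in (0, 100]; got {self.percentile_rescale}"
            )


def _rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def perturb_intensity(
    intensities: StainIntensityMatrix,
    epsilon: float,
    rng: np.random.Generator | int | None = None,
) -> StainIntensityMatrix:
    """Scale the whole intensity matrix by one ``alpha ~ U(1-eps, 1+eps)``.

    A single alpha multiplies every entry (all stains, all pixels): this is a
    global staining-strength jitter, not a per-channel recoloring.
    """
    if not 0 <= epsilon < 1:
        raise ParameterError(
            f"epsilon must be in [0, 1) so alpha stays positive; got {epsilon}"
        )
    if epsilon == 0:
        return intensities
    alpha = _rng(rng).uniform(1 - epsilon, 1 + epsilon)
    return StainIntensityMatrix(matrix=alpha * intensities.matrix)


def _reconstruct(
    decomp: StainDecomposition,
    w_prime: np.ndarray,
    h_prime: np.ndarray,
    config: AdaptationConfig,
) -> RgbImage:
    """Rebuild RGB from adapted factors; background pixels restored verbatim."""
    od = np.maximum(np.asarray(w_prime) @ np.asarray(h_prime), 0.0)
    image = od_to_rgb(
        OdImage(od=od, shape=decomp.source_shape), I0=config.incident_intensity
    )
    if decomp.source_image is not None and decomp.mask.any():
        h, w = decomp.source_shape
        out = image.pixels.reshape(h * w, 3)
        src = decomp.source_image.pixels.reshape(h * w, 3)
        out[decomp.mask] = src[decomp.mask]
        image = RgbImage(
            pixels=out.reshape(h, w, 3), incident_intensity=config.incident_intensity
        )
    return image


def adapt_stain_san(
    decomp: StainDecomposition,
    dist: StainDistribution,
    config: AdaptationConfig,
    rng: np.random.Generator | int | None = None,
    sampled_W: np.ndarray | None = None,
    alpha: float | None = None,
) -> RgbImage:
    """Apply Stain SAN to one decomposed image.

    role='train': ``W'`` is resampled from the target Gaussian and ``H`` is
    scaled by ``alpha ~ U(1-eps, 1+eps)``.  role='test': ``W'`` is set to the
    target mean ``W0`` deterministically and ``H`` is left untouched
    (zero-variance resampling), which normalizes the test batch onto the
    training target domain.

    ``sampled_W``/``alpha`` force the random draws (used by the batch driver
    for audit logging and by equivalence tests).
    """
    if decomp.colors.m != dist.m:
        raise ShapeError(
            f"stain count mismatch: image has m={decomp.colors.m}, "
            f"distribution has m={dist.m}"
        )
    gen = _rng(rng)
    h = decomp.intensities.matrix
    if config.role == "test":
        w_prime = dist.W0
        h_prime = h
    else:
        if sampled_W is None:
            sampled_W = sample_color_matrix(dist, gen)
        w_prime = np.maximum(np.asarray(sampled_W, dtype=float), 0.0)
        if config.epsilon == 0:
            h_prime = h
        else:
            if alpha is None:
                alpha = gen.uniform(1 - config.epsilon, 1 + config.epsilon)
            h_prime = alpha * h
    return _reconstruct(decomp, w_prime, h_prime, config)


def stain_percentiles(
    decomp: StainDecomposition, q: float
) -> np.ndarray:
    """Per-row ``q``-th percentile of ``H`` over foreground pixels (length m)."""
    fg = ~decomp.mask
    if not fg.any():
        return np.zeros(decomp.intensities.m)
    return np.percentile(decomp.intensities.matrix[:, fg], q, axis=1)


def adapt_normalize(
    decomp: StainDecomposition,
    reference: StainColorMatrix | np.ndarray,
    config: AdaptationConfig,
    reference_percentiles: np.ndarray | None = None,
) -> RgbImage:
    """Classical stain normalization: replace ``W`` by a fixed reference.

    ``reference`` may be a :class:`StainColorMatrix` or a raw 3 x m array
    (e.g. a distribution mean ``W0``, whose columns need not be exactly unit
    norm).  If ``config.percentile_rescale`` is set and reference percentiles
    are provided, each intensity row is scaled so its foreground percentile
    matches the reference value, aligning staining strength across images.
    A zero percentile (reference or image) skips that row with a warning.
    """
    ref_matrix = np.asarray(getattr(reference, "matrix", reference), dtype=float)
    if ref_matrix.shape != decomp.colors.matrix.shape:
        raise ShapeError(
            f"reference matrix shape {ref_matrix.shape} does not match "
            f"image stain matrix shape {decomp.colors.matrix.shape}"
        )
    h_prime = decomp.intensities.matrix
    if config.percentile_rescale is not None and reference_percentiles is not None:
        ref = np.asarray(reference_percentiles, dtype=float)
        own = stain_percentiles(decomp, config.percentile_rescale)
        scale = np.ones_like(ref)
        for i in range(ref.size):
            if ref[i] <= 0 or own[i] <= 0:
                warnings.warn(
                    f"row {i}: zero percentile, intensity rescale skipped",
                    stacklevel=2,
                )
            else:
                scale[i] = ref[i] / own[i]
        h_prime = scale[:, None] * h_prime
    return _reconstruct(decomp, ref_matrix, h_prime, config)


def adapt_augment(
    decomp: StainDecomposition,
    config: AdaptationConfig,
    rng: np.random.Generator | int | None = None,
    alphas: np.ndarray | None = None,
    betas: np.ndarray | None = None,
) -> RgbImage:
    """Classical stain augmentation: jitter each color column independently.

    Column ``i`` of ``W`` becomes ``alpha_i * W(i) + beta_i`` with
    ``alpha_i ~ U(1-eps1, 1+eps1)`` and, by default, ``beta_i ~ U(-eps2,
    +eps2)`` added entrywise; negative entries are clipped.  ``H`` is left
    unchanged.  A training-time device only: at role='test' the image is
    returned round-tripped unchanged, with a warning.
    """
    if config.role == "test":
        warnings.warn(
            "stain augmentation does not alter test images; returning the "
            "reconstruction of the original factors",
            stacklevel=2,
        )
        return _reconstruct(
            decomp, decomp.colors.matrix, decomp.intensities.matrix, config
        )
    gen = _rng(rng)
    m = decomp.colors.m
    if alphas is None:
        alphas = gen.uniform(1 - config.epsilon1, 1 + config.epsilon1, size=m)
    if betas is None:
        if config.augment_beta_as_printed:
            betas = gen.uniform(1 - config.epsilon2, 1 + config.epsilon2, size=m)
        else:
            betas = gen.uniform(-config.epsilon2, config.epsilon2, size=m)
    w_prime = np.maximum(
        decomp.colors.matrix * np.asarray(alphas)[None, :] + np.asarray(betas)[None, :],
        0.0,
    )
    return _reconstruct(decomp, w_prime, decomp.intensities.matrix, config)


def adapt_mixup(
    decomp: StainDecomposition,
    other_colors: StainColorMatrix,
    config: AdaptationConfig,
    rng: np.random.Generator | int | None = None,
    u: float | None = None,
    alpha: float | None = None,
) -> RgbImage:
    """Stain mix-up: interpolate toward a partner image's color matrix.

    ``W' = (1 - u) * W_own + u * W_partner`` with one ``u ~ U(0, 1)`` per
    image, and ``H`` scaled by ``alpha ~ U(1-eps, 1+eps)``.  The partner is
    drawn from the opposite batch by the caller.
    """
    if other_colors.matrix.shape != decomp.colors.matrix.shape:
        raise ShapeError("partner stain color matrix shape mismatch")
    gen = _rng(rng)
    if u is None:
        u = gen.uniform(0.0, 1.0)
    if not 0 <= u <= 1:
        raise ParameterError(f"interpolation weight u must be in [0, 1]; got {u}")
    w_prime = (1 - u) * decomp.colors.matrix + u * other_colors.matrix
    h = decomp.intensities.matrix
    if config.epsilon > 0:
        if alpha is None:
            alpha = gen.uniform(1 - config.epsilon, 1 + config.epsilon)
        h = alpha * h
    return _reconstruct(decomp, w_prime, h, config)


def adapt_batch(
    images: list[RgbImage],
    config: AdaptationConfig,
    dist: StainDistribution | None = None,
    other_batch: list[RgbImage] | None = None,
    rng_seed: int | None = None,
    return_records: bool = False,
):
    """Adapt a batch of images with per-image independent randomness.

    Randomness for image ``i`` comes from a child stream of ``rng_seed``
    (default ``config.rng_seed``) spawned at index ``i``, so runs are
    reproducible and per-image draws are independent.

    Method requirements: ``san`` needs ``dist`` (or role='train', in which
    case the target distribution is fitted on the batch itself);
    ``normalize`` needs ``dist`` as the reference; ``mixup`` needs
    ``other_batch``.  Returns the adapted images, plus per-image audit
    records when ``return_records`` is set.
    """
    seed = config.rng_seed if rng_seed is None else rng_seed
    children = np.random.SeedSequence(seed).spawn(len(images))
    decomps = [decompose(img, config) for img in images]

    if config.method == "mixup":
        if other_batch is None:
            raise ConfigurationError(
                "method 'mixup' requires other_batch: the opposite-domain "
                "images providing partner stain color matrices"
            )
        partner_colors = [decompose(img, config).colors for img in other_batch]
    elif config.method == "san":
        if dist is None:
            if config.role != "train":
                raise ConfigurationError(
                    "method 'san' at role='test' requires dist: the target "
                    "distribution fitted on the training batch"
                )
            dist = estimate_distribution([d.colors for d in decomps])
    elif config.method == "normalize":
        if dist is None:
            raise ConfigurationError(
                "method 'normalize' requires dist: the reference stain "
                "distribution supplying the target color matrix"
            )

    # Normalization matches every image's intensity percentiles to a common
    # batch-level target so each H row has the same percentile across images.
    ref_percentiles = None
    if config.method == "normalize" and config.percentile_rescale is not None:
        per_image = np.stack(
            [stain_percentiles(d, config.percentile_rescale) for d in decomps]
        )
        ref_percentiles = np.median(per_image, axis=0)

    outputs: list[RgbImage] = []
    records: list[dict] = []
    for i, d in enumerate(decomps):
        gen = np.random.default_rng(children[i])
        rec: dict = {"index": i, "method": config.method, "role": config.role}
        if config.method == "san":
            if config.role == "train":
                w_samp = sample_color_matrix(dist, gen)
                alpha = (
                    gen.uniform(1 - config.epsilon, 1 + config.epsilon)
                    if config.epsilon > 0
                    else 1.0
                )
                out = adapt_stain_san(d, dist, config, sampled_W=w_samp, alpha=alpha)
                rec.update(alpha=alpha, W_prime=np.asarray(w_samp).tolist())
            else:
                out = adapt_stain_san(d, dist, config)
                rec.update(W_prime=dist.W0.tolist())
        elif config.method == "normalize":
            out = adapt_normalize(
                d, dist.W0, config, reference_percentiles=ref_percentiles
            )
            rec.update(W_prime=dist.W0.tolist())
        elif config.method == "augment":
            m = d.colors.m
            alphas = gen.uniform(1 - config.epsilon1, 1 + config.epsilon1, size=m)
            if config.augment_beta_as_printed:
                betas = gen.uniform(1 - config.epsilon2, 1 + config.epsilon2, size=m)
            else:
                betas = gen.uniform(-config.epsilon2, config.epsilon2, size=m)
            out = adapt_augment(d, config, alphas=alphas, betas=betas)
            rec.update(alphas=alphas.tolist(), betas=betas.tolist())
        else:  # mixup
            j = int(gen.integers(len(partner_colors)))
            u = gen.uniform(0.0, 1.0)
            alpha = (
                gen.uniform(1 - config.epsilon, 1 + config.epsilon)
                if config.epsilon > 0
                else 1.0
            )
            out = adapt_mixup(d, partner_colors[j], config, u=u, alpha=alpha)
            rec.update(partner_index=j, u=u, alpha=alpha)
        outputs.append(out)
        records.append(rec)

    if return_records:
        return outputs, records
    return outputs
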