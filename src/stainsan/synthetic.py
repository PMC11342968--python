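"""Two-domain H&E phantom generator with known ground truth.

Phantoms instantiate the image-formation model ``I = I0 * exp(-W H)`` forward:
each image gets a known stain color matrix ``W`` (its domain's center matrix
plus optional per-entry Gaussian jitter, columns re-normalized) and a known
non-negative intensity field ``H`` built from

* "nuclei": random disks with Gaussian radial profile, rich in channel 1
  (hematoxylin) and occluding the stroma underneath, so the darkest nucleus
  cores are nearly pure hematoxylin;
* "stroma": smooth low-frequency texture in channel 2 (eosin) with only a
  trace of channel 1, so typical tissue pixels are nearly pure eosin;
* a white background band with ``H = 0`` exactly (OD norm 0, below the 0.3
  masking threshold).

Disk edges sweep every hematoxylin/eosin mixing ratio, giving the dense
angular coverage that percentile-based stain extraction needs; the near-pure
extremes pin the percentile angles close to the true dye rays.

Two domains with centers a configurable angle apart emulate the systematic
purple-vs-pink staining difference between two labs; domain 0 plays the
training batch and domain 1 the test batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .distribution import cbcs_reference
from .errors import ParameterError
from .extraction import column_angles_degrees
from .od_color import RgbImage

__all__ = [
    "PhantomSpec",
    "default_domain_centers",
    "generate_phantom",
    "generate_two_domain_study",
]


def _rotate_columns(w: np.ndarray, degrees: float) -> np.ndarray:
    """Rotate each unit column by ``degrees`` within the positive octant.

    Each column is rotated in the plane it spans with the (normalized
    component of the) all-ones direction, which for H&E-like columns keeps
    every entry positive for rotations up to ~20 degrees.
    """
    theta = np.radians(degrees)
    out = np.empty_like(w)
    for j in range(w.shape[1]):
        c = w[:, j]
        aux = np.ones(3) - (np.ones(3) @ c) * c
        aux /= np.linalg.norm(aux)
        out[:, j] = np.cos(theta) * c + np.sin(theta) * aux
    if out.min() < 0:
        raise ParameterError(
            f"rotation by {degrees} degrees leaves the positive octant"
        )
    return out


def default_domain_centers(gap_degrees: float = 12.0) -> tuple[np.ndarray, np.ndarray]:
    """Domain centers: the packaged CBCS reference mean (unit-normalized
    columns) and the same matrix with each column rotated ``gap_degrees``
    within the positive octant — a purple-leaning vs pink-leaning pair."""
    w0 = cbcs_reference().W0
    w0 = w0 / np.linalg.norm(w0, axis=0)
    return w0, _rotate_columns(w0, gap_degrees)


@dataclass
class PhantomSpec:
    """Parameters of a two-domain phantom study.

    ``domain_spread`` is the per-entry standard deviation of Gaussian jitter
    applied to each image's true ``W`` around its domain center (columns
    re-normalized afterwards), emulating slide-to-slide staining variation.
    ``background_fraction`` of each image is a white band with zero optical
    density.  ``intensity_scale`` multiplies the whole ``H`` field.
    """

    n_images: int = 20
    image_size: tuple[int, int] = (96, 96)
    domain_centers: tuple[np.ndarray, np.ndarray] = field(default=None)  # type: ignore[assignment]
    domain_gap_degrees: float = 12.0
    domain_spread: float = 0.02
    nuclei_density: float = 0.15
    background_fraction: float = 0.25
    intensity_scale: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.domain_centers is None:
            self.domain_centers = default_domain_centers(self.domain_gap_degrees)
        centers = []
        for k, c in enumerate(self.domain_centers):
            c = np.asarray(c, dtype=float)
            if c.shape != (3, 2):
                raise ParameterError(f"domain center {k} must be 3 x 2; got {c.shape}")
            if c.min() < 0:
                raise ParameterError(f"domain center {k} has negative entries")
            if np.any(np.abs(np.linalg.norm(c, axis=0) - 1) > 1e-6):
                raise ParameterError(f"domain center {k} columns must be unit norm")
            centers.append(c)
        self.domain_centers = (centers[0], centers[1])
        if self.n_images < 1:
            raise ParameterError("n_images must be >= 1")
        if self.domain_spread < 0:
            raise ParameterError("domain_spread must be >= 0")
        if not 0 < self.nuclei_density < 1:
            raise ParameterError("nuclei_density must be in (0, 1)")
        if not 0 <= self.background_fraction <= 1:
            raise ParameterError("background_fraction must be in [0, 1]")
        if self.intensity_scale <= 0:
            raise ParameterError("intensity_scale must be positive")

    def gap_degrees(self) -> np.ndarray:
        """Per-column angular distance between the two domain centers."""
        return column_angles_degrees(*self.domain_centers)


def _true_color_matrix(spec: PhantomSpec, domain: int, rng: np.random.Generator) -> np.ndarray:
    center = spec.domain_centers[domain]
    if spec.domain_spread == 0:
        return center.copy()
    w = center + spec.domain_spread * rng.standard_normal(center.shape)
    w = np.maximum(w, 0.0)
    norms = np.linalg.norm(w, axis=0)
    norms[norms == 0] = 1.0
    return w / norms


def _intensity_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Build the 2 x d ground-truth intensity field (row-major pixel order)."""
    h_px, w_px = spec.image_size
    scale = spec.intensity_scale

    # Smooth eosin stroma in [0.35, 0.90] * scale: every tissue pixel keeps an
    # OD norm comfortably above the 0.3 background threshold.
    noise = rng.standard_normal((h_px, w_px))
    smooth = ndimage.gaussian_filter(noise, sigma=6.0, mode="reflect")
    lo, hi = smooth.min(), smooth.max()
    smooth = (smooth - lo) / (hi - lo) if hi > lo else np.full_like(smooth, 0.5)
    eosin = scale * (0.35 + 0.55 * smooth)
    hema = np.full((h_px, w_px), 0.01 * scale)

    bg_rows = int(round(spec.background_fraction * h_px))
    fg_h = h_px - bg_rows

    if fg_h > 0:
        mean_r = 4.5
        n_disks = max(
            1, int(round(spec.nuclei_density * fg_h * w_px / (np.pi * mean_r**2)))
        )
        for _ in range(n_disks):
            r = rng.uniform(3.0, 6.0)
            cy = rng.uniform(bg_rows, h_px - 1)  # tails into the bg band get zeroed
            cx = rng.uniform(0, w_px - 1)
            amp = scale * rng.uniform(0.9, 1.4)
            y0, y1 = int(max(cy - 3 * r, 0)), int(min(cy + 3 * r, h_px - 1)) + 1
            x0, x1 = int(max(cx - 3 * r, 0)), int(min(cx + 3 * r, w_px - 1)) + 1
            yy, xx = np.mgrid[y0:y1, x0:x1]
            prof = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * (r / 2) ** 2))
            hema[y0:y1, x0:x1] += amp * prof
            # Nuclei occlude stroma: eosin vanishes at the disk core so the
            # darkest nucleus pixels are nearly pure hematoxylin.
            eosin[y0:y1, x0:x1] *= np.clip(1.0 - 1.6 * prof, 0.0, 1.0)

    h_field = np.stack([hema.ravel(), eosin.ravel()])  # 2 x d, row-major
    if bg_rows > 0:
        bg_mask = np.zeros((h_px, w_px), dtype=bool)
        bg_mask[:bg_rows] = True
        h_field[:, bg_mask.ravel()] = 0.0
    return h_field


def generate_phantom(
    spec: PhantomSpec, domain: int, index: int
) -> tuple[RgbImage, np.ndarray, np.ndarray]:
    """Generate phantom ``index`` of ``domain`` (0 or 1) with its ground truth.

    Returns ``(image, true_W, true_H)``.  Deterministic in
    ``(spec.rng_seed, domain, index)``: the per-image stream is a spawned
    child keyed by domain and index, so images are independent and
    reproducible regardless of generation order.
    """
    if domain not in (0, 1):
        raise ParameterError(f"domain must be 0 or 1; got {domain}")
    ss = np.random.SeedSequence(spec.rng_seed, spawn_key=(domain, index))
    rng = np.random.default_rng(ss)
    true_w = _true_color_matrix(spec, domain, rng)
    true_h = _intensity_field(spec, rng)
    od = true_w @ true_h
    h_px, w_px = spec.image_size
    pixels = np.clip(np.round(255.0 * np.exp(-od)), 0, 255).astype(np.uint8)
    image = RgbImage(pixels=pixels.T.reshape(h_px, w_px, 3))
    return image, true_w, true_h


@dataclass
class PhantomBatch:
    """One domain's worth of phantoms with their ground truth."""

    images: list[RgbImage]
    true_colors: list[np.ndarray]
    true_intensities: list[np.ndarray]


def generate_two_domain_study(
    spec: PhantomSpec,
) -> tuple[PhantomBatch, PhantomBatch, dict]:
    """Generate the full study: domain 0 = training batch, domain 1 = test.

    Returns ``(train, test, manifest)`` where the manifest records the spec,
    the per-column center gap (an input, echoed), and per-image true color
    matrices for oracle tests.
    """
    batches = []
    for domain in (0, 1):
        images, ws, hs = [], [], []
        for i in range(spec.n_images):
            img, w, h = generate_phantom(spec, domain, i)
            images.append(img)
            ws.append(w)
            hs.append(h)
        batches.append(PhantomBatch(images=images, true_colors=ws, true_intensities=hs))
    manifest = {
        "n_images_per_domain": spec.n_images,
        "image_size": list(spec.image_size),
        "domain_centers": [c.tolist() for c in spec.domain_centers],
        "center_gap_degrees": spec.gap_degrees().tolist(),
        "domain_spread": spec.domain_spread,
        "nuclei_density": spec.nuclei_density,
        "background_fraction": spec.background_fraction,
        "intensity_scale": spec.intensity_scale,
        "rng_seed": spec.rng_seed,
        "true_colors": {
            "train": [w.tolist() for w in batches[0].true_colors],
            "test": [w.tolist() for w in batches[1].true_colors],
        },
    }
    return batches[0], batches[1], manifest
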