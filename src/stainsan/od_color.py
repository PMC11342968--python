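"""Beer-Lambert conversion between 8-bit RGB rasters and optical-density space.

Transmitted light through stained tissue follows the Beer-Lambert law: a pixel
with RGB value ``I`` under incident intensity ``I0`` has optical density (OD)
``-log(I / I0)`` per channel.  Stain contributions are additive in OD, which is
why all stain estimation happens there.  This module owns the two domain types
(:class:`RgbImage`, :class:`OdImage`), the forward/inverse transforms, the
background mask (near-white pixels carry no stain information), and 8-bit
image file IO.

Layout convention, fixed for reproducibility of pixel indices: OD rasters are
stored channel-first as a ``3 x d`` matrix whose columns are pixels in
row-major (C) order of the original ``height x width`` image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import DomainError, ParameterError, ShapeError

__all__ = [
    "RgbImage",
    "OdImage",
    "rgb_to_od",
    "od_to_rgb",
    "mask_background",
    "read_image",
    "write_image",
]

#: Default incident luminous intensity for 8-bit images.
DEFAULT_I0 = 255.0

#: Default OD-norm threshold below which a pixel counts as background.
DEFAULT_MASK_THRESHOLD = 0.3


@dataclass
class RgbImage:
    """8-bit, 3-channel RGB raster plus the incident intensity ``I0``.

    Parameters
    ----------
    pixels
        ``(height, width, 3)`` array of integers in ``[0, 255]``.
    incident_intensity
        Incident luminous intensity ``I0``; 255 for 8-bit images by common
        practice.
    """

    pixels: np.ndarray
    incident_intensity: float = DEFAULT_I0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ShapeError(
                f"RGB image must be (height, width, 3); got shape {px.shape}"
            )
        if not np.issubdtype(px.dtype, np.integer):
            if not np.all(px == np.round(px)):
                raise DomainError("RGB pixel values must be integers")
            px = px.astype(np.uint8)
        if px.min() < 0 or px.max() > 255:
            raise DomainError("RGB pixel values must lie in [0, 255]")
        self.pixels = px.astype(np.uint8)
        if self.incident_intensity <= 0:
            raise ParameterError(
                f"incident intensity must be positive; got {self.incident_intensity}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of the raster."""
        return self.pixels.shape[:2]

    @property
    def n_pixels(self) -> int:
        return self.pixels.shape[0] * self.pixels.shape[1]


@dataclass
class OdImage:
    """Optical-density image: ``3 x d`` matrix plus background bookkeeping.

    ``od[:, j]`` is the OD 3-vector of pixel ``j`` in row-major order of the
    source raster.  ``background_mask[j]`` is True where the pixel is
    near-white background, hidden from stain estimation but restored verbatim
    in reconstructed outputs.
    """

    od: np.ndarray
    shape: tuple[int, int]
    background_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        od = np.asarray(self.od, dtype=float)
        if od.ndim != 2 or od.shape[0] != 3:
            raise ShapeError(f"OD matrix must be 3 x d; got shape {od.shape}")
        if not np.all(np.isfinite(od)):
            raise DomainError("OD values must be finite")
        if od.min() < -1e-12:
            raise DomainError("OD values must be non-negative")
        self.od = np.maximum(od, 0.0)
        d = self.shape[0] * self.shape[1]
        if od.shape[1] != d:
            raise ShapeError(
                f"OD pixel count {od.shape[1]} does not match shape {self.shape}"
            )
        if self.background_mask is None:
            self.background_mask = np.zeros(d, dtype=bool)
        else:
            mask = np.asarray(self.background_mask, dtype=bool)
            if mask.shape != (d,):
                raise ShapeError("background_mask length must equal pixel count")
            self.background_mask = mask

    @property
    def n_pixels(self) -> int:
        return self.od.shape[1]

    @property
    def foreground(self) -> np.ndarray:
        """OD columns of foreground (unmasked) pixels."""
        return self.od[:, ~self.background_mask]


def rgb_to_od(image: RgbImage, clip_floor: float = 1.0) -> OdImage:
    """Convert an 8-bit RGB image to optical density via the Beer-Lambert law.

    ``od = -log(max(I, clip_floor) / I0)`` per channel.  Zero-valued pixels are
    clipped to ``clip_floor`` (default 1) before the log so the OD stays
    finite.  The returned mask is all-False; call :func:`mask_background` to
    identify background.
    """
    if not 0 < clip_floor <= 1:
        raise ParameterError(f"clip_floor must be in (0, 1]; got {clip_floor}")
    h, w = image.shape
    flat = image.pixels.reshape(h * w, 3).T.astype(float)  # 3 x d, row-major pixels
    od = -np.log(np.maximum(flat, clip_floor) / image.incident_intensity)
    return OdImage(od=np.maximum(od, 0.0), shape=(h, w))


def od_to_rgb(od_image: OdImage, I0: float = DEFAULT_I0) -> RgbImage:
    """Invert the Beer-Lambert transform: ``I = round(I0 * exp(-od))``.

    Values are clamped to [0, 255] and reshaped to the source
    ``height x width x 3`` raster.
    """
    od = np.asarray(od_image.od, dtype=float)
    if od.min() < 0:
        raise DomainError("cannot invert negative optical densities")
    vals = np.clip(np.round(I0 * np.exp(-od)), 0, 255)
    h, w = od_image.shape
    pixels = vals.T.reshape(h, w, 3).astype(np.uint8)
    return RgbImage(pixels=pixels, incident_intensity=I0)


def reconstruct_rgb(
    od: np.ndarray,
    shape: tuple[int, int],
    I0: float = DEFAULT_I0,
) -> RgbImage:
    """Convenience: wrap a raw 3 x d OD matrix (clipped at 0) and invert it."""
    return od_to_rgb(OdImage(od=np.maximum(od, 0.0), shape=shape), I0=I0)


def mask_background(
    od_image: OdImage, threshold: float = DEFAULT_MASK_THRESHOLD
) -> OdImage:
    """Mark pixels whose Euclidean OD norm is <= ``threshold`` as background.

    Near-white pixels have OD close to the origin and carry no stain signal;
    they are hidden from stain estimation and later restored verbatim when the
    adapted image is reconstructed.  The boundary (norm exactly equal to the
    threshold) is assigned to background.  Idempotent for a fixed threshold.
    """
    if threshold <= 0:
        raise ParameterError(f"mask threshold must be positive; got {threshold}")
    norms = np.linalg.norm(od_image.od, axis=0)
    return OdImage(
        od=od_image.od,
        shape=od_image.shape,
        background_mask=norms <= threshold,
    )


def read_image(path: str | Path) -> RgbImage:
    """Read an 8-bit RGB PNG/TIFF/JPEG from disk.

    Alpha channels and non-8-bit depths are rejected with a clear error.
    """
    arr = iio.imread(Path(path))
    if arr.ndim == 3 and arr.shape[2] == 4:
        raise ShapeError(f"{path}: alpha channels are not supported (got RGBA)")
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ShapeError(f"{path}: expected a 3-channel RGB image; got shape {arr.shape}")
    if arr.dtype != np.uint8:
        raise DomainError(f"{path}: only 8-bit images are supported; got {arr.dtype}")
    return RgbImage(pixels=arr)


def write_image(image: RgbImage, path: str | Path) -> None:
    """Write an RgbImage to disk; format inferred from the extension."""
    iio.imwrite(Path(path), image.pixels)
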