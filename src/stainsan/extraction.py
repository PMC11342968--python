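"""SVD plane-and-angle stain extraction (the Macenko method) for H&E images.

An OD image is modeled as ``V = W H`` with ``W`` a ``3 x 2`` stain color
matrix (unit columns: hematoxylin, eosin) and ``H`` a ``2 x d`` non-negative
stain intensity matrix.  Because every tissue pixel is a non-negative mixture
of the two dye directions, the foreground OD point cloud lies (up to noise) in
a 2-plane wedge bounded by the two dye rays.  The extraction therefore:

1. finds the best-fit plane through the foreground OD cloud (top-2 singular
   directions of the 3 x n pixel matrix);
2. expresses each pixel by its polar angle inside that plane;
3. takes robust extreme angles (the ``p``-th and ``(100 - p)``-th percentiles)
   as the two dye directions;
4. maps them back to 3-space, fixes signs into the non-negative octant,
   normalizes and orders hematoxylin (larger blue-channel OD) first.

Intensities are then recovered per pixel by exact non-negative least squares
(closed form for m = 2) or by pseudo-inverse with negative clipping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ConditioningError,
    DegenerateInputError,
    ParameterError,
    ShapeError,
    StainSanError,
)
from .od_color import OdImage, RgbImage, mask_background, rgb_to_od

__all__ = [
    "StainColorMatrix",
    "StainIntensityMatrix",
    "StainDecomposition",
    "extract_stain_colors",
    "extract_stain_intensities",
    "decompose",
    "column_angles_degrees",
]


def column_angles_degrees(w_a: np.ndarray, w_b: np.ndarray) -> np.ndarray:
    """Per-column angle in degrees between two 3 x m matrices' columns."""
    a = np.asarray(getattr(w_a, "matrix", w_a), dtype=float)
    b = np.asarray(getattr(w_b, "matrix", w_b), dtype=float)
    cos = np.sum(a * b, axis=0) / (
        np.linalg.norm(a, axis=0) * np.linalg.norm(b, axis=0)
    )
    return np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))

DEFAULT_ANGLE_PERCENTILE = 1.0
DEFAULT_MIN_FOREGROUND = 100

# Relative singular-value floor below which the OD cloud is treated as rank-1
# (single stain) and extraction refuses to invent a second dye direction.
_RANK_TOL = 1e-6


@dataclass
class StainColorMatrix:
    """``3 x m`` stain color matrix with unit-norm, non-negative columns.

    Column order is fixed: hematoxylin (the dye with the larger blue-channel
    OD component) first, eosin second.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.matrix, dtype=float)
        if w.ndim != 2 or w.shape[0] != 3:
            raise ShapeError(f"stain color matrix must be 3 x m; got {w.shape}")
        if w.shape[1] != 2:
            raise NotImplementedError(
                "only m = 2 stains (hematoxylin and eosin) are supported; "
                f"got m = {w.shape[1]}"
            )
        if w.min() < 0:
            raise StainSanError("stain color matrix entries must be non-negative")
        norms = np.linalg.norm(w, axis=0)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise StainSanError(
                f"stain color matrix columns must have unit norm; got norms {norms}"
            )
        self.matrix = w

    @property
    def m(self) -> int:
        return self.matrix.shape[1]

    @property
    def hematoxylin(self) -> np.ndarray:
        return self.matrix[:, 0]

    @property
    def eosin(self) -> np.ndarray:
        return self.matrix[:, 1]


@dataclass
class StainIntensityMatrix:
    """``m x d`` non-negative per-pixel dye concentrations."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        h = np.asarray(self.matrix, dtype=float)
        if h.ndim != 2:
            raise ShapeError(f"stain intensity matrix must be m x d; got {h.shape}")
        if h.min() < -1e-12:
            raise StainSanError("stain intensities must be non-negative")
        self.matrix = np.maximum(h, 0.0)

    @property
    def m(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.matrix.shape[1]


@dataclass
class StainDecomposition:
    """Result of decomposing one image: ``V ~= W H`` plus bookkeeping.

    Carries the background mask and source raster so adapters can restore
    hidden pixels verbatim, and the foreground relative reconstruction
    residual ``||V - WH|| / ||V||`` measured at fit time.
    """

    colors: StainColorMatrix
    intensities: StainIntensityMatrix
    mask: np.ndarray
    source_shape: tuple[int, int]
    source_image: RgbImage | None = None
    residual: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        d = self.source_shape[0] * self.source_shape[1]
        if self.intensities.n_pixels != d:
            raise ShapeError("intensity pixel count does not match source shape")
        if self.mask.shape != (d,):
            raise ShapeError("mask length does not match source shape")


def _order_hematoxylin_first(w: np.ndarray) -> np.ndarray:
    """Hematoxylin = column with the larger red-channel (first) OD component.

    Hematoxylin transmits blue (appearing blue-purple) and so absorbs
    comparatively strongly in red; eosin transmits red (appearing pink) and
    has a small red OD.  Columns are unit-norm, so the raw first entries are
    comparable; on a tie the existing order is kept.
    """
    if w[0, 0] < w[0, 1]:
        return w[:, ::-1].copy()
    return w


def extract_stain_colors(
    od_image: OdImage,
    angle_percentile: float = DEFAULT_ANGLE_PERCENTILE,
    min_foreground: int = DEFAULT_MIN_FOREGROUND,
) -> StainColorMatrix:
    """Estimate the 3 x 2 stain color matrix from foreground OD pixels.

    Parameters
    ----------
    od_image
        OD image whose background mask has already been set.
    angle_percentile
        Robust-extreme percentile ``p``: the dye directions are the ``p``-th
        and ``(100 - p)``-th percentile plane angles of the foreground cloud.
    min_foreground
        Minimum number of foreground pixels needed for a stable plane fit.

    Raises
    ------
    DegenerateInputError
        Fewer than ``min_foreground`` foreground pixels, or the foreground OD
        cloud is rank deficient (all pixels on one ray: a single stain).
    """
    if not 0 < angle_percentile < 50:
        raise ParameterError(
            f"angle_percentile must be in (0, 50); got {angle_percentile}"
        )
    fg = od_image.foreground  # 3 x n
    n = fg.shape[1]
    if n < min_foreground:
        raise DegenerateInputError(
            f"only {n} foreground pixels (< {min_foreground}); "
            "image is background-dominated or empty"
        )

    # Plane through the (uncentered) cloud: stains mix additively from the
    # origin, so the relevant plane contains the origin.
    u, s, _ = np.linalg.svd(fg, full_matrices=False)
    if s[0] <= 0 or s[1] / s[0] < _RANK_TOL:
        raise DegenerateInputError(
            "foreground OD cloud is rank deficient (single stain ray); "
            "two stain directions cannot be identified"
        )
    basis = u[:, :2]  # 3 x 2 orthonormal plane basis

    # Orient the basis so projections fall on the positive side; keeps the
    # angle distribution away from the atan2 branch cut.
    proj = basis.T @ fg  # 2 x n
    if proj[0].sum() < 0:
        basis[:, 0] *= -1
        proj[0] *= -1
    if proj[1].sum() < 0:
        basis[:, 1] *= -1
        proj[1] *= -1

    phi = np.arctan2(proj[1], proj[0])
    lo, hi = np.percentile(phi, [angle_percentile, 100.0 - angle_percentile])
    v_lo = basis @ np.array([np.cos(lo), np.sin(lo)])
    v_hi = basis @ np.array([np.cos(hi), np.sin(hi)])

    w = np.stack([v_lo, v_hi], axis=1)
    # Fix signs into the non-negative octant, then clear small numerical
    # negatives left by the plane fit.
    for j in range(2):
        if w[:, j].sum() < 0:
            w[:, j] *= -1
    w = np.maximum(w, 0.0)
    norms = np.linalg.norm(w, axis=0)
    if np.any(norms == 0):
        raise DegenerateInputError("extracted stain direction collapsed to zero")
    w /= norms
    return StainColorMatrix(matrix=_order_hematoxylin_first(w))


def extract_stain_intensities(
    od_image: OdImage,
    colors: StainColorMatrix,
    nonneg: str = "clip",
) -> StainIntensityMatrix:
    """Solve ``V = W H`` for ``H >= 0`` at every pixel (background included).

    ``nonneg='clip'`` (default) solves the unconstrained least-squares problem
    through the pseudo-inverse and clips negatives to zero — fast and
    deterministic.  ``nonneg='exact'`` computes the exact non-negative
    least-squares solution, which for m = 2 has a closed form: if the
    unconstrained solution is feasible it is optimal; otherwise the optimum
    sits on one axis and is the better of the two single-stain projections.
    """
    w = colors.matrix
    v = od_image.od
    gram = w.T @ w
    det = float(np.linalg.det(gram))
    if det < 1e-12:
        raise ConditioningError(
            "stain color columns are collinear; intensities are unidentifiable"
        )
    h_ls = np.linalg.solve(gram, w.T @ v)  # m x d unconstrained solution

    if nonneg == "clip":
        h = np.maximum(h_ls, 0.0)
    elif nonneg == "exact":
        h = np.maximum(h_ls, 0.0)
        bad = np.any(h_ls < 0, axis=0)
        if np.any(bad):
            vb = v[:, bad]
            # Candidate axis solutions: project onto each (unit) stain ray.
            h1 = np.maximum(w[:, 0] @ vb, 0.0)
            h2 = np.maximum(w[:, 1] @ vb, 0.0)
            # Residual^2 = ||v||^2 - h_i^2 for a unit-norm ray projection.
            pick_first = h1 >= h2
            hb = np.zeros((2, vb.shape[1]))
            hb[0, pick_first] = h1[pick_first]
            hb[1, ~pick_first] = h2[~pick_first]
            h[:, bad] = hb
    else:
        raise ParameterError(f"nonneg must be 'clip' or 'exact'; got {nonneg!r}")
    return StainIntensityMatrix(matrix=h)


def decompose(image: RgbImage, config: "AdaptationConfig | None" = None) -> StainDecomposition:
    """Full per-image stain decomposition: OD transform, background masking,
    color extraction on foreground, intensity solve on all pixels.

    Deterministic: two calls on the same image are bit-identical.
    """
    from .adapters import AdaptationConfig  # deferred: adapters imports this module

    cfg = config or AdaptationConfig()
    od = rgb_to_od(image)
    od = mask_background(od, threshold=cfg.mask_threshold)
    colors = extract_stain_colors(
        od,
        angle_percentile=cfg.angle_percentile,
        min_foreground=cfg.min_foreground,
    )
    intensities = extract_stain_intensities(od, colors, nonneg=cfg.intensity_solver)

    fg = ~od.background_mask
    v_fg = od.od[:, fg]
    recon = colors.matrix @ intensities.matrix[:, fg]
    denom = np.linalg.norm(v_fg)
    residual = float(np.linalg.norm(v_fg - recon) / denom) if denom > 0 else 0.0

    return StainDecomposition(
        colors=colors,
        intensities=intensities,
        mask=od.background_mask,
        source_shape=od.shape,
        source_image=image,
        residual=residual,
    )
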