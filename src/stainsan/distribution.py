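"""Energy-preserving Gaussian target distribution over stain color matrices.

A batch of images yields one 3 x 2 stain color matrix per image.  The target
distribution for resampling is a spherical (isotropic) Gaussian on the
vectorized matrices ``w = vec(W)`` in R^6:

* mean ``W0``: the element-wise median over the batch (robust to outlier
  stainings);
* variance ``sigma^2``: chosen so the total energy — the trace of the
  covariance of the vectorized matrices — is preserved exactly,
  ``3 * m * sigma^2 = trace(Cov(vec(W)))``.

Vectorization is column-stacked (hematoxylin column's three entries first);
the trace is invariant to this choice, so it only affects serialization.

A reference distribution estimated from the Carolina Breast Cancer Study
(CBCS) H&E images ships with the package as ``data/cbcs_reference.json`` and
is the default normalization target when no training batch is available.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .errors import EstimationError, FormatError
from .extraction import StainColorMatrix

__all__ = [
    "StainDistribution",
    "estimate_distribution",
    "sample_color_matrix",
    "load_distribution",
    "save_distribution",
    "cbcs_reference",
]


def _vec(w: np.ndarray) -> np.ndarray:
    """Column-stacked vectorization of a 3 x m matrix."""
    return np.asarray(w, dtype=float).flatten(order="F")


def _unvec(v: np.ndarray, m: int) -> np.ndarray:
    return np.asarray(v, dtype=float).reshape(3, m, order="F")


@dataclass
class StainDistribution:
    """Spherical Gaussian over vectorized stain color matrices.

    Attributes
    ----------
    W0
        3 x m mean matrix (element-wise median of the source batch).
    sigma
        Per-coordinate standard deviation of the isotropic Gaussian.
    n_source
        Number of stain matrices used in estimation (0 if unknown/external).
    notes
        Free-text provenance.
    """

    W0: np.ndarray
    sigma: float
    n_source: int = 0
    notes: str = ""

    def __post_init__(self) -> None:
        w0 = np.asarray(self.W0, dtype=float)
        if w0.ndim != 2 or w0.shape[0] != 3:
            raise FormatError(f"W0 must be 3 x m; got shape {w0.shape}")
        if not np.all(np.isfinite(w0)):
            raise FormatError("W0 must be finite")
        if self.sigma < 0:
            raise FormatError(f"sigma must be >= 0; got {self.sigma}")
        self.W0 = w0
        self.sigma = float(self.sigma)

    @property
    def m(self) -> int:
        return self.W0.shape[1]

    @property
    def total_energy(self) -> float:
        """Trace of the target covariance: ``3 * m * sigma^2``."""
        return 3 * self.m * self.sigma**2

    def mean_colors(self) -> StainColorMatrix:
        """W0 wrapped as a color matrix (columns re-normalized to unit norm).

        The raw median W0 is the resampling mean and is used as-is there; this
        accessor is for contexts that require strict unit columns.
        """
        w = np.maximum(self.W0, 0.0)
        return StainColorMatrix(matrix=w / np.linalg.norm(w, axis=0))


def estimate_distribution(
    colors_batch: list[StainColorMatrix],
) -> StainDistribution:
    """Fit the energy-preserving spherical Gaussian to a batch of >= 2 matrices.

    ``W0`` is the element-wise median; ``sigma`` satisfies
    ``3 * m * sigma^2 = trace(S)`` exactly, where ``S`` is the unbiased
    (n - 1 denominator) sample covariance of the vectorized matrices.
    """
    if len(colors_batch) < 2:
        raise EstimationError(
            f"need at least 2 stain color matrices to estimate a distribution; "
            f"got {len(colors_batch)} (use sigma=0 explicitly for a single image)"
        )
    ms = {c.m for c in colors_batch}
    if len(ms) != 1:
        raise FormatError(f"inconsistent stain counts in batch: {sorted(ms)}")
    m = ms.pop()
    stack = np.stack([c.matrix for c in colors_batch])  # n x 3 x m
    w0 = np.median(stack, axis=0)
    vecs = np.stack([_vec(c.matrix) for c in colors_batch])  # n x 3m
    cov = np.cov(vecs, rowvar=False, ddof=1)
    sigma = float(np.sqrt(np.trace(np.atleast_2d(cov)) / (3 * m)))
    return StainDistribution(
        W0=w0, sigma=sigma, n_source=len(colors_batch), notes="estimated from batch"
    )


def sample_color_matrix(
    dist: StainDistribution,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Draw one 3 x m stain color matrix from ``N(vec(W0), sigma^2 I)``.

    The draw is used as-is — columns are *not* re-normalized to unit norm,
    since re-normalization would destroy the energy-preservation property.
    Negative entries (possible in the Gaussian's tails) are clipped to zero
    with a warning, as OD stain vectors are physically non-negative.

    Returns a raw ndarray: sampled matrices intentionally do not satisfy the
    unit-column invariant of :class:`StainColorMatrix`.
    """
    gen = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    draw = _vec(dist.W0) + dist.sigma * gen.standard_normal(3 * dist.m)
    w = _unvec(draw, dist.m)
    if w.min() < 0:
        warnings.warn(
            "sampled stain color matrix had negative entries; clipped to 0",
            stacklevel=2,
        )
        w = np.maximum(w, 0.0)
    return w


def save_distribution(dist: StainDistribution, path: str | Path) -> None:
    """Write the distribution as JSON, lossless to full float precision."""
    payload = {
        "m": dist.m,
        "W0": [[float(x) for x in row] for row in dist.W0],
        "sigma": dist.sigma,
        "n_source": dist.n_source,
        "notes": dist.notes,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_distribution(path: str | Path) -> StainDistribution:
    """Read a distribution JSON written by :func:`save_distribution`."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: malformed distribution JSON: {exc}") from exc
    return _from_payload(payload, origin=str(path))


def _from_payload(payload: dict, origin: str) -> StainDistribution:
    try:
        m = int(payload["m"])
        w0 = np.asarray(payload["W0"], dtype=float)
        sigma = float(payload["sigma"])
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"{origin}: missing or invalid distribution fields: {exc}") from exc
    if w0.shape != (3, m):
        raise FormatError(
            f"{origin}: W0 shape {w0.shape} does not match declared m={m} (need 3x{m})"
        )
    return StainDistribution(
        W0=w0,
        sigma=sigma,
        n_source=int(payload.get("n_source", 0)),
        notes=str(payload.get("notes", "")),
    )


def cbcs_reference() -> StainDistribution:
    """The packaged CBCS reference distribution (the shipped default target)."""
    text = resources.files("stainsan").joinpath("data/cbcs_reference.json").read_text()
    return _from_payload(json.loads(text), origin="packaged cbcs_reference.json")
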