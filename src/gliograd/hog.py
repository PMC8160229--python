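"""Slice-wise rectangular-cell histograms of oriented gradients (R-HOG).

A 3D volume is sliced into 2D images along a configurable axis; each slice is
partitioned into a dense, non-overlapping, origin-anchored grid of square
cells; each cell contributes one signed-orientation gradient histogram of N
channels, with magnitude-weighted votes. The concatenation of all cell
histograms in canonical order (slice-major, then row-major within a slice) is
a subject's local-feature descriptor set.

Conventions, fixed for reproducibility:

* gradients by the 1-D kernel (-1, 0, 1) per axis, one-sided differences at
  borders (no 1/2 factor on centered differences);
* orientation channel k is *centered* at k * 360/N degrees;
* hard voting assigns each pixel's full magnitude to the nearest channel
  center (angular ties go to the lower channel index); bilinear voting splits
  the magnitude between the two flanking centers, wrapping 360 -> 0;
* trailing partial cells are discarded, so descriptor positions are
  comparable across subjects of an aligned cohort;
* all-zero-gradient cells yield the all-zero histogram (background slices are
  kept so vector length is constant across subjects).
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np

from ._utils import config_hash
from .preprocess import NormalizedVolume


@dataclasses.dataclass(frozen=True)
class HogConfig:
    """Geometry and binning parameters of the descriptor.

    ``cell_size`` is the side c (pixels) of the square cell; ``n_bins`` the
    orientation channel count N over the signed 0-360 degree circle.
    """

    cell_size: int = 10
    n_bins: int = 8
    signed: bool = True
    normalize: Literal["none", "l2", "l2hys"] = "none"
    vote_interp: Literal["hard", "bilinear"] = "bilinear"
    slice_axis: int = 2

    def __post_init__(self) -> None:
        if self.cell_size < 2:
            raise ValueError("cell_size must be >= 2")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if not self.signed:
            raise ValueError("only signed (0-360 degree) orientations are supported")
        if self.normalize not in ("none", "l2", "l2hys"):
            raise ValueError(f"unknown normalize mode {self.normalize!r}")
        if self.vote_interp not in ("hard", "bilinear"):
            raise ValueError(f"unknown vote_interp mode {self.vote_interp!r}")

    @property
    def hash(self) -> str:
        return config_hash(self)


@dataclasses.dataclass(frozen=True)
class CellDescriptor:
    """One cell's orientation histogram and its grid position.

    ``position`` is (slice index, cell row, cell column).
    """

    histogram: np.ndarray
    position: tuple[int, int, int]


@dataclasses.dataclass(frozen=True)
class SubjectDescriptorSet:
    """All cell histograms of one subject, in canonical order.

    ``histograms`` has shape (P, N) with P = m * R * Q; row p corresponds to
    position (slice, row, col) = unravel(p, grid). ``volume_shape`` is kept so
    classifier weights can be painted back into voxel space.
    """

    histograms: np.ndarray
    grid: tuple[int, int, int]  # (m slices, R rows, Q cols)
    config: HogConfig
    subject_id: str
    volume_shape: tuple[int, int, int]

    @property
    def config_hash(self) -> str:
        return self.config.hash

    @property
    def n_positions(self) -> int:
        return int(np.prod(self.grid))

    def position_of(self, p: int) -> tuple[int, int, int]:
        return tuple(int(i) for i in np.unravel_index(p, self.grid))


def pixel_gradients(slice2d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel gradient magnitude and direction (degrees in [0, 360)).

    Centered differences with kernel (-1, 0, 1) in the interior, one-sided
    differences at borders. ``gx`` runs along axis 1 (columns), ``gy`` along
    axis 0 (rows); direction = atan2(gy, gx), and zero-gradient pixels get
    direction 0 by convention.
    """
    a = np.asarray(slice2d, dtype=np.float64)
    if a.ndim != 2 or a.shape[0] < 2 or a.shape[1] < 2:
        raise ValueError(f"slice must be 2D with >= 2 rows and columns, got {a.shape}")
    gx = np.empty_like(a)
    gx[:, 1:-1] = a[:, 2:] - a[:, :-2]
    gx[:, 0] = a[:, 1] - a[:, 0]
    gx[:, -1] = a[:, -1] - a[:, -2]
    gy = np.empty_like(a)
    gy[1:-1, :] = a[2:, :] - a[:-2, :]
    gy[0, :] = a[1, :] - a[0, :]
    gy[-1, :] = a[-1, :] - a[-2, :]
    magnitude = np.hypot(gx, gy)
    direction = np.degrees(np.arctan2(gy, gx)) % 360.0
    direction[direction >= 360.0] = 0.0  # guard float wrap of tiny negatives
    direction[magnitude == 0.0] = 0.0
    return magnitude, direction


def _normalize(hist: np.ndarray, mode: str) -> np.ndarray:
    if mode == "none":
        return hist
    norm = float(np.linalg.norm(hist))
    if norm == 0.0:
        return hist  # all-zero-gradient cell stays all-zero
    hist = hist / norm
    if mode == "l2hys":
        hist = np.minimum(hist, 0.2)
        norm = float(np.linalg.norm(hist))
        if norm > 0:
            hist = hist / norm
    return hist


def _vote(
    magnitude: np.ndarray, direction: np.ndarray, config: HogConfig
) -> np.ndarray:
    """Accumulate magnitude-weighted orientation votes into N channels."""
    n = config.n_bins
    width = 360.0 / n
    mag = magnitude.ravel()
    ang = direction.ravel()
    hist = np.zeros(n, dtype=np.float64)
    if config.vote_interp == "hard":
        centers = np.arange(n) * width
        # wrapped angular distance to every center; argmin takes the lowest
        # channel index on exact ties
        dist = np.abs(((ang[:, None] - centers[None, :] + 180.0) % 360.0) - 180.0)
        idx = np.argmin(dist, axis=1)
        np.add.at(hist, idx, mag)
    else:
        t = ang / width
        k1 = np.floor(t).astype(np.intp) % n
        frac = t - np.floor(t)
        k2 = (k1 + 1) % n
        np.add.at(hist, k1, mag * (1.0 - frac))
        np.add.at(hist, k2, mag * frac)
    return hist


def cell_histogram(
    magnitude: np.ndarray,
    direction_deg: np.ndarray,
    cell_bounds: tuple[int, int, int, int],
    config: HogConfig,
    position: tuple[int, int, int] = (0, 0, 0),
) -> CellDescriptor:
    """Histogram of one cell given precomputed slice gradients.

    ``cell_bounds`` is (row_start, row_stop, col_start, col_stop), half-open,
    and must lie within the slice.
    """
    r0, r1, c0, c1 = cell_bounds
    h, w = magnitude.shape
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError(f"cell bounds {cell_bounds} outside slice of shape {(h, w)}")
    hist = _vote(magnitude[r0:r1, c0:c1], direction_deg[r0:r1, c0:c1], config)
    return CellDescriptor(
        histogram=_normalize(hist, config.normalize), position=position
    )


def extract_subject(
    vol: NormalizedVolume, config: HogConfig
) -> SubjectDescriptorSet:
    """Dense R-HOG extraction over every slice of a normalized volume."""
    data = vol.data
    if data.ndim != 3:
        raise ValueError("expected a 3D volume")
    axis = config.slice_axis
    m = data.shape[axis]
    plane_shape = tuple(s for i, s in enumerate(data.shape) if i != axis)
    c = config.cell_size
    if plane_shape[0] < c or plane_shape[1] < c:
        raise ValueError(
            f"cell_size {c} exceeds slice dimensions {plane_shape} "
            f"for subject {vol.subject_id}"
        )
    rows, cols = plane_shape[0] // c, plane_shape[1] // c
    out = np.empty((m * rows * cols, config.n_bins), dtype=np.float64)
    p = 0
    for s in range(m):
        slice2d = np.take(data, s, axis=axis)
        magnitude, direction = pixel_gradients(slice2d)
        for r in range(rows):
            for q in range(cols):
                bounds = (r * c, (r + 1) * c, q * c, (q + 1) * c)
                out[p] = cell_histogram(
                    magnitude, direction, bounds, config, position=(s, r, q)
                ).histogram
                p += 1
    return SubjectDescriptorSet(
        histograms=out,
        grid=(m, rows, cols),
        config=config,
        subject_id=vol.subject_id,
        volume_shape=tuple(int(s) for s in data.shape),
    )
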