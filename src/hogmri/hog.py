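"""N-dimensional histogram-of-oriented-gradients (HOG) descriptor.

The descriptor summarises local image texture by the distribution of
intensity-gradient orientations:

1. central-difference gradients per voxel (boundary voxels invalid);
2. each voxel's gradient is assigned to the neighbour-offset direction
   ``b`` maximising the cosine overlap ``alpha(g, b) = g.b / (|g| |b|)``
   — 26 directions in 3D, 8 in 2D — and contributes its magnitude
   ``|g|`` to that bin of its cell's histogram;
3. cells (8^3 voxels by default) tile the volume, trailing partial
   cells discarded;
4. overlapping blocks of 2x2x2 cells (16^3 voxels) are formed at a
   stride of one cell, each block's concatenated histograms
   ``v`` (8 x 26 = 208 values in 3D) normalised by
   ``v -> v / sqrt(|v|_2^2 + eps^2)``;
5. the normalised block vectors are concatenated into one flat feature
   vector (116,480 features on the canonical 79 x 95 x 68 grid).

Feature layout: blocks in x-fastest grid order, cells within a block in
the same x-fastest order, orientation bins innermost.  Binning is hard
assignment (no trilinear interpolation), with argmax ties broken by the
lowest index in the fixed lexicographic direction order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, ValidationError
from .volume_io import GridGeometry, Volume3D

#: Sentinel returned by :func:`bin_direction` for a zero gradient.
NO_BIN = -1


# ---------------------------------------------------------------------------
# Direction set
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DirectionSet:
    """The 3^D - 1 integer neighbour-offset vectors used as orientation bins.

    Order is lexicographic by components over (-1, 0, 1), the zero
    vector excluded; this order is the tie-break order everywhere.
    """

    vectors: np.ndarray  # (count, D) int

    @property
    def count(self) -> int:
        return self.vectors.shape[0]

    @property
    def ndim(self) -> int:
        return self.vectors.shape[1]


def make_direction_set(D: int) -> DirectionSet:
    """All nonzero offset vectors with components in {-1, 0, 1}: 8 in 2D, 26 in 3D."""
    if D not in (2, 3):
        raise ValueError(f"direction set defined for D in (2, 3), got {D}")
    vecs = np.array([v for v in itertools.product((-1, 0, 1), repeat=D) if any(v)], dtype=int)
    return DirectionSet(vecs)


# ---------------------------------------------------------------------------
# Gradients
# ---------------------------------------------------------------------------

@dataclass
class GradientField:
    """Central-difference gradient of a volume.

    ``components[..., a]`` holds the derivative along axis ``a``;
    ``magnitude`` the Euclidean norm; ``valid_mask`` marks interior
    voxels where the central difference exists on every axis.
    """

    components: np.ndarray  # shape dims + (D,)
    magnitude: np.ndarray   # shape dims
    valid_mask: np.ndarray  # shape dims, bool


def gradient(vol: Volume3D | np.ndarray) -> GradientField:
    """Per-voxel central differences ``(f(.+1) - f(.-1)) / 2`` on each axis.

    Differences are taken in voxel-index units (no physical-unit
    scaling).  Boundary voxels, where a neighbour is missing, are
    flagged invalid and excluded from histogram accumulation.
    """
    f = vol.intensities if isinstance(vol, Volume3D) else np.asarray(vol, dtype=float)
    D = f.ndim
    if any(s < 3 for s in f.shape):
        raise DegenerateInputError(f"every axis must have extent >= 3, got {f.shape}")
    comps = np.zeros(f.shape + (D,))
    for a in range(D):
        fwd = [slice(None)] * D
        bwd = [slice(None)] * D
        mid = [slice(None)] * D
        fwd[a] = slice(2, None)
        bwd[a] = slice(None, -2)
        mid[a] = slice(1, -1)
        comps[tuple(mid) + (a,)] = (f[tuple(fwd)] - f[tuple(bwd)]) / 2.0
    valid = np.zeros(f.shape, dtype=bool)
    valid[(slice(1, -1),) * D] = True
    mag = np.sqrt((comps ** 2).sum(axis=-1))
    mag[~valid] = 0.0
    return GradientField(comps, mag, valid)


def bin_direction(g, dirs: DirectionSet) -> int:
    """Index of the direction with maximum cosine overlap with ``g``.

    Returns :data:`NO_BIN` for a zero gradient (the voxel is skipped).
    Ties go to the lowest index in the fixed direction order.
    """
    g = np.asarray(g, dtype=float)
    if np.linalg.norm(g) == 0:
        return NO_BIN
    scores = dirs.vectors @ g / np.linalg.norm(dirs.vectors, axis=1)
    return int(np.argmax(scores))


# ---------------------------------------------------------------------------
# Cells, blocks, descriptor
# ---------------------------------------------------------------------------

def _per_axis(value, D: int) -> tuple[int, ...]:
    if np.isscalar(value):
        return (int(value),) * D
    t = tuple(int(v) for v in value)
    if len(t) != D:
        raise ValueError(f"expected {D} per-axis values, got {t}")
    return t


@dataclass(frozen=True)
class HOGParams:
    """Geometry and normalisation parameters of the descriptor.

    ``cell_size_voxels`` voxels per cell edge (default 8),
    ``block_cells`` cells per block edge (default 2, so a block spans
    16 voxels per axis at defaults), ``block_stride_cells`` the block
    stride in cells (default 1: overlapping blocks), ``epsilon`` the
    small constant guarding the block normalisation.
    """

    cell_size_voxels: int | tuple = 8
    block_cells: int | tuple = 2
    block_stride_cells: int | tuple = 1
    epsilon: float = 1e-5

    def resolved(self, D: int) -> tuple[tuple[int, ...], tuple[int, ...], tuple[int, ...]]:
        cell = _per_axis(self.cell_size_voxels, D)
        block = _per_axis(self.block_cells, D)
        stride = _per_axis(self.block_stride_cells, D)
        if min(cell) < 1 or min(block) < 1 or min(stride) < 1:
            raise ValueError("cell, block and stride sizes must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        return cell, block, stride


def cell_histograms(grad: GradientField, params: HOGParams,
                    dirs: DirectionSet | None = None) -> np.ndarray:
    """Accumulate gradient magnitudes into per-cell orientation histograms.

    The volume is tiled by non-overlapping cells of
    ``cell_size_voxels``; trailing partial cells are discarded.  Every
    valid voxel with a nonzero gradient adds ``|grad|`` to the bin of
    its maximum-overlap direction in its cell.  Returns an array of
    shape ``(n_cells_x, ..., n_bins)``.
    """
    D = grad.magnitude.ndim
    if dirs is None:
        dirs = make_direction_set(D)
    cell, _, _ = params.resolved(D)
    n_cells = tuple(s // c for s, c in zip(grad.magnitude.shape, cell))
    if min(n_cells) < 1:
        raise DegenerateInputError(
            f"volume {grad.magnitude.shape} smaller than one cell {cell}")
    crop = tuple(slice(0, n * c) for n, c in zip(n_cells, cell))
    mag = grad.magnitude[crop]
    comps = grad.components[crop]
    contrib = grad.valid_mask[crop] & (mag > 0)

    # max-overlap bin: argmax_b (g . b / |b|); |g| > 0 cancels in alpha
    unit = dirs.vectors / np.linalg.norm(dirs.vectors, axis=1, keepdims=True)
    scores = comps.reshape(-1, D) @ unit.T
    bins = np.argmax(scores, axis=1).reshape(mag.shape)

    grids = np.meshgrid(*(np.arange(n * c) // c for n, c in zip(n_cells, cell)),
                        indexing="ij")
    cell_flat = np.ravel_multi_index(tuple(grids), n_cells)
    flat = cell_flat * dirs.count + bins
    hist = np.bincount(flat[contrib], weights=mag[contrib],
                       minlength=int(np.prod(n_cells)) * dirs.count)
    return hist.reshape(n_cells + (dirs.count,))


def assemble_blocks(cells: np.ndarray, params: HOGParams) -> np.ndarray:
    """Concatenate cell histograms into (unnormalised) block vectors.

    Blocks of ``block_cells`` cells per axis are taken at
    ``block_stride_cells``; per axis the block count is
    ``floor((n_cells - block_cells) / stride) + 1``.  Returns an array
    of shape ``(n_blocks_total, block_cells^D * n_bins)`` with blocks
    in x-fastest order, cells within each block x-fastest, bins
    innermost.
    """
    D = cells.ndim - 1
    _, block, stride = params.resolved(D)
    n_cells = cells.shape[:D]
    if any(n < b for n, b in zip(n_cells, block)):
        raise DegenerateInputError(
            f"cell grid {n_cells} smaller than one block {block}")
    win = np.lib.stride_tricks.sliding_window_view(cells, block, axis=tuple(range(D)))
    # win shape: n_win per axis + (n_bins,) + block; subsample by stride
    win = win[tuple(slice(None, None, s) for s in stride)]
    nb = win.shape[:D]
    # reorder: blocks x-fastest (reverse block axes), cells within block
    # x-fastest (reverse window axes), bins innermost
    block_axes = tuple(range(D))[::-1]
    win_axes = tuple(range(D + 1, 2 * D + 1))[::-1]
    win = win.transpose(block_axes + win_axes + (D,))
    return win.reshape(int(np.prod(nb)), int(np.prod(block)) * cells.shape[-1])


def normalize_block(v: np.ndarray, epsilon: float) -> np.ndarray:
    """``v -> v / sqrt(|v|_2^2 + eps^2)``; a zero block stays zero.

    The epsilon keeps the map defined when every gradient magnitude in
    the block is zero, and bounds every output strictly below 1.
    """
    v = np.asarray(v, dtype=float)
    sq = (v ** 2).sum(axis=-1, keepdims=True)
    return v / np.sqrt(sq + epsilon ** 2)


@dataclass
class HOGDescriptor:
    """Flat HOG feature vector plus the geometry needed to invert indices."""

    features: np.ndarray
    params: HOGParams
    n_cells: tuple[int, ...]
    n_blocks: tuple[int, ...]
    n_bins: int

    @property
    def block_length(self) -> int:
        _, block, _ = self.params.resolved(len(self.n_cells))
        return int(np.prod(block)) * self.n_bins

    def index_map(self, idx: int) -> tuple[tuple[int, ...], tuple[int, ...], int]:
        """Feature index -> (block grid index, cell-within-block index, bin index)."""
        if not 0 <= idx < self.features.size:
            raise IndexError(f"feature index {idx} out of range [0, {self.features.size})")
        D = len(self.n_cells)
        _, block, _ = self.params.resolved(D)
        L = self.block_length
        block_flat, within = divmod(int(idx), L)
        cell_flat, bin_idx = divmod(within, self.n_bins)
        block_idx = []
        for n in self.n_blocks:  # x-fastest: x varies quickest
            block_flat, r = divmod(block_flat, n)
            block_idx.append(r)
        cell_idx = []
        for b in block:
            cell_flat, r = divmod(cell_flat, b)
            cell_idx.append(r)
        return tuple(block_idx), tuple(cell_idx), bin_idx

    def block_center_voxel(self, block_idx) -> tuple[float, ...]:
        """Geometric center (voxel coords, possibly fractional) of a block."""
        D = len(self.n_cells)
        cell, block, stride = self.params.resolved(D)
        return tuple(
            bi * st * c + (bc * c - 1) / 2.0
            for bi, st, c, bc in zip(block_idx, stride, cell, block)
        )


def extract_hog(vol: Volume3D | np.ndarray, params: HOGParams = HOGParams()) -> HOGDescriptor:
    """End-to-end HOG descriptor of a volume (or 2D image).

    Deterministic for fixed input; on the canonical 79 x 95 x 68 grid
    with default parameters the feature vector has 116,480 entries
    (560 blocks x 208 values).
    """
    arr = vol.intensities if isinstance(vol, Volume3D) else np.asarray(vol, dtype=float)
    D = arr.ndim
    dirs = make_direction_set(D)
    cell, block, stride = params.resolved(D)
    grad = gradient(arr)
    cells = cell_histograms(grad, params, dirs)
    blocks = assemble_blocks(cells, params)
    normed = normalize_block(blocks, params.epsilon)
    n_cells = cells.shape[:D]
    n_blocks = tuple((n - b) // s + 1 for n, b, s in zip(n_cells, block, stride))
    return HOGDescriptor(normed.ravel(), params, n_cells, n_blocks, dirs.count)


def map_feature_to_space(idx: int, desc: HOGDescriptor,
                         grid: GridGeometry) -> tuple[tuple[float, ...], np.ndarray, int]:
    """Map a feature index back to anatomical space.

    Returns the geometric center of the block containing the feature,
    in voxel coordinates and in mm (via the grid affine), plus the
    orientation-bin index.  Used to localise selected features in the
    brain.
    """
    block_idx, _cell, bin_idx = desc.index_map(idx)
    center_vox = desc.block_center_voxel(block_idx)
    center_mm = grid.voxel_to_mm(center_vox)
    return center_vox, center_mm, bin_idx
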