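"""Nonlocal self-similar patch grouping.

The volume is covered by overlapping ``b x b x B`` patches on a stride
lattice (edge-snapped so the last row/column/band is always covered).  Every
lattice patch is a key patch; each key is stacked with its ``d - 1`` nearest
neighbours (smallest Euclidean distance, searched in a spatial window around
the key) into a 4th-order tensor of shape ``(b, b, B, d)``.  Because similar
patches recur across organs and tissue textures, these matched stacks have
low multilinear rank — the prior the Tucker term exploits.

Coordinates are 0-based, inclusive start / exclusive end throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

logger = logging.getLogger(__name__)

__all__ = [
    "PatchGrid",
    "PatchGroup",
    "extract_patches",
    "extract_at",
    "match_patches",
    "build_groups",
    "aggregate_groups",
]


@dataclass(frozen=True)
class PatchGrid:
    """Patch lattice parameters.

    ``band_extent=None`` resolves to ``min(depth, 8)`` at extraction time;
    ``band_mode='full'`` forces full-depth slabs instead.
    """

    patch_size: int = 8
    stride: int = 4
    band_extent: int | None = None
    band_mode: str = "windowed"

    def __post_init__(self):
        if not 1 <= self.stride <= self.patch_size:
            raise ValueError("require 1 <= stride <= patch_size")
        if self.band_mode not in ("windowed", "full"):
            raise ValueError("band_mode must be 'windowed' or 'full'")

    def resolve_band(self, depth: int) -> int:
        if self.band_mode == "full":
            return depth
        b = self.band_extent if self.band_extent is not None else min(depth, 8)
        if b > depth:
            raise ValueError(f"band_extent {b} exceeds volume depth {depth}")
        return b


@dataclass
class PatchGroup:
    """One matched stack: ``data[..., j]`` is the patch at ``member_coords[j]``.

    ``member_coords[0]`` is the key patch.
    """

    data: np.ndarray
    member_coords: np.ndarray
    group_id: int = 0

    def __post_init__(self):
        if self.data.ndim != 4:
            raise ValueError("group data must be 4th-order (b, b, B, d)")
        if self.data.shape[3] != len(self.member_coords):
            raise ValueError("one coordinate per member patch required")


def _axis_positions(extent: int, size: int, stride: int) -> np.ndarray:
    """Stride-lattice start positions, edge-snapped to cover the last voxels."""
    if size > extent:
        raise ValueError(f"patch extent {size} exceeds volume extent {extent}")
    pos = list(range(0, extent - size + 1, stride))
    if pos[-1] != extent - size:
        pos.append(extent - size)
    return np.asarray(pos, dtype=np.intp)


def patch_coords(shape: tuple, grid: PatchGrid) -> np.ndarray:
    """All lattice patch coordinates, ordered axis-0 outer / axis-2 inner."""
    b, s = grid.patch_size, grid.stride
    band = grid.resolve_band(shape[2])
    p0 = _axis_positions(shape[0], b, s)
    p1 = _axis_positions(shape[1], b, s)
    p2 = _axis_positions(shape[2], band, s)
    grid0, grid1, grid2 = np.meshgrid(p0, p1, p2, indexing="ij")
    return np.stack([grid0.ravel(), grid1.ravel(), grid2.ravel()], axis=1)


def extract_at(volume: np.ndarray, coords: np.ndarray, b: int, band: int) -> np.ndarray:
    """Gather the ``(b, b, band)`` sub-blocks at each coordinate -> (n, b, b, band)."""
    volume = np.asarray(volume, dtype=float)
    windows = sliding_window_view(volume, (b, b, band))
    coords = np.asarray(coords, dtype=np.intp)
    return windows[coords[:, 0], coords[:, 1], coords[:, 2]]


def extract_patches(volume: np.ndarray, grid: PatchGrid):
    """All lattice patches of ``volume``.

    Returns
    -------
    patches : (K, b, b, B) array
    coords : (K, 3) array of top-left-front corners
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 3:
        raise ValueError("expected a 3rd-order volume")
    band = grid.resolve_band(volume.shape[2])
    coords = patch_coords(volume.shape, grid)
    return extract_at(volume, coords, grid.patch_size, band), coords


def match_patches(
    patches: np.ndarray,
    coords: np.ndarray,
    key_index: int,
    d: int,
    search_radius: int = 15,
) -> PatchGroup:
    """Group the key patch with its ``d - 1`` nearest patches.

    Distance is the Frobenius norm of the patch difference; candidates are
    restricted to a ``(2 * search_radius)``-wide spatial window around the
    key (all depths), with a whole-volume fallback (logged) when the window
    holds fewer than ``d`` patches.  Ties are broken by ascending patch
    index, so the selection is independent of candidate ordering.
    """
    patches = np.asarray(patches, dtype=float)
    coords = np.asarray(coords, dtype=np.intp)
    n = len(patches)
    if not 1 <= d <= n:
        raise ValueError(f"group size {d} invalid for {n} patches")
    key = coords[key_index]
    in_window = (np.abs(coords[:, 0] - key[0]) <= search_radius) & (
        np.abs(coords[:, 1] - key[1]) <= search_radius
    )
    in_window[key_index] = False
    cand = np.flatnonzero(in_window)
    if len(cand) < d - 1:
        logger.info(
            "search window around patch %d holds %d candidates < d-1 = %d; "
            "falling back to whole-volume search",
            key_index,
            len(cand),
            d - 1,
        )
        cand = np.flatnonzero(np.arange(n) != key_index)
    if d == 1:
        members = np.array([key_index], dtype=np.intp)
    else:
        diffs = patches[cand].reshape(len(cand), -1) - patches[key_index].ravel()
        dists = np.einsum("ij,ij->i", diffs, diffs)
        order = np.lexsort((cand, dists))
        members = np.concatenate([[key_index], cand[order[: d - 1]]]).astype(np.intp)
    data = np.stack([patches[m] for m in members], axis=-1)
    return PatchGroup(data=data, member_coords=coords[members], group_id=key_index)


def build_groups(
    volume: np.ndarray, grid: PatchGrid, d: int, search_radius: int = 15
) -> list[PatchGroup]:
    """Match every lattice patch of ``volume`` into its nonlocal group."""
    patches, coords = extract_patches(volume, grid)
    return [match_patches(patches, coords, k, d, search_radius) for k in range(len(coords))]


def aggregate_groups(
    groups: list[PatchGroup],
    hr_shape: tuple,
    fallback: np.ndarray | None = None,
) -> np.ndarray:
    """Scatter group slabs back into a volume, averaging overlaps.

    Each voxel takes the mean of every patch slab covering it; voxels not
    covered by any patch keep the ``fallback`` value (0 if absent).
    """
    if not groups:
        raise ValueError("empty group list")
    hr_shape = tuple(int(s) for s in hr_shape)
    acc = np.zeros(hr_shape, dtype=float)
    cnt = np.zeros(hr_shape, dtype=float)
    for g in groups:
        b1, b2, band = g.data.shape[:3]
        for j, (i0, i1, i2) in enumerate(np.asarray(g.member_coords)):
            if i0 + b1 > hr_shape[0] or i1 + b2 > hr_shape[1] or i2 + band > hr_shape[2]:
                raise ValueError("member coordinates exceed target shape")
            acc[i0 : i0 + b1, i1 : i1 + b2, i2 : i2 + band] += g.data[..., j]
            cnt[i0 : i0 + b1, i1 : i1 + b2, i2 : i2 + band] += 1.0
    covered = cnt > 0
    out = np.zeros(hr_shape, dtype=float) if fallback is None else np.array(fallback, dtype=float)
    out[covered] = acc[covered] / cnt[covered]
    return out
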