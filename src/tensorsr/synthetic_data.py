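"""Phantom generation for end-to-end solver validation.

The generator builds ground-truth volumes that exhibit, by construction, the
three structural priors the reconstruction model exploits:

* nonlocal self-similarity — a handful of texture motifs, each stamped at
  several locations as exact copies;
* piecewise smoothness — a piecewise-constant background of convex
  polyhedral regions, so the TV term has a meaningful null structure;
* low multilinear rank — each motif is a sum of a few separable (rank-1)
  components, keeping matched patch stacks low-rank along every mode.

Degradation follows the observation model Y = D S X + eps: Gaussian blur,
integer decimation, additive white Gaussian noise.  Everything is
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .operators import DegradationSpec, blur_downsample

__all__ = ["PhantomSpec", "generate_phantom", "degrade"]


@dataclass(frozen=True)
class PhantomSpec:
    """Ground-truth phantom parameters (intensities in [0, 1])."""

    shape: tuple = (64, 64, 16)
    n_motifs: int = 3
    motif_size: tuple = (8, 8, 8)
    repeats_per_motif: int = 6
    background_regions: int = 4
    motif_rank: int = 2
    intensity_jitter: float = 0.0
    noise_sigma: float = 0.01
    # motif corners are drawn on this lattice, which is also the motif
    # texture period: patches overlapping a motif then have exact
    # counterparts (same within-patch phase) at every other repeat
    placement_lattice: int = 8
    # motifs are only stamped where the surrounding halo is one background
    # level, so any patch overlapping a motif sees motif-plus-constant; this
    # keeps matched patch stacks low-rank along the similarity mode
    context_halo: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if any(m > s for m, s in zip(self.motif_size, self.shape)):
            raise ValueError("motif does not fit inside the volume")
        if self.background_regions < 1:
            raise ValueError("need at least one background region")


def _poly_background(shape: tuple, n_regions: int, rng: np.random.Generator) -> np.ndarray:
    """Piecewise-constant background of convex polyhedral cells.

    Cells are produced by recursive plane splits; split normals are drawn
    from the axis directions and the in-plane diagonals (1, 1, 0) and
    (1, -1, 0).  Every face is translation-invariant along directions on the
    patch stride lattice, so boundary patches have many nonlocal duplicates
    along their own face — while the diagonal faces still defeat plain
    nearest-neighbour upsampling (staircasing).
    """
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    fields = [ii, jj, kk, ii + jj, ii - jj]
    labels = np.zeros(shape, dtype=int)
    next_label = 1
    while next_label < n_regions:
        sizes = np.bincount(labels.ravel())
        cell = int(np.argmax(sizes))
        mask = labels == cell
        field = fields[int(rng.integers(len(fields)))]
        vals = field[mask]
        lo, hi = int(vals.min()), int(vals.max())
        if hi - lo < 4:
            continue
        cut = int(rng.integers(lo + 2, hi - 1))
        labels[mask & (field >= cut)] = next_label
        next_label += 1
    levels = rng.uniform(0.15, 0.85, size=next_label)
    return levels[labels]


def _low_rank_motif(
    size: tuple, rank: int, rng: np.random.Generator, period: int = 4
) -> np.ndarray:
    """Low-rank periodic texture, rescaled into [0.1, 0.9].

    A ``period``-sized cell (sum of ``rank`` separable components) is tiled
    to the motif extent.  Periodicity with the placement-lattice period means
    lattice-shifted windows into a motif are themselves near-duplicates, so
    the motif contributes nonlocal self-similarity at every patch offset,
    not only at whole-motif repeats.
    """
    cell_shape = tuple(min(period, s) for s in size)
    cell = np.zeros(cell_shape)
    for _ in range(rank):
        vecs = [np.cumsum(rng.normal(size=s)) for s in cell_shape]
        cell += np.einsum("i,j,k->ijk", *vecs)
    reps = tuple(-(-s // c) for s, c in zip(size, cell_shape))
    motif = np.tile(cell, reps)[: size[0], : size[1], : size[2]]
    lo, hi = motif.min(), motif.max()
    if hi - lo < 1e-12:
        return np.full(size, 0.5)
    return 0.1 + 0.8 * (motif - lo) / (hi - lo)


def generate_phantom(spec: PhantomSpec) -> np.ndarray:
    """Deterministic ground-truth volume in [0, 1] for ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    vol = _poly_background(spec.shape, spec.background_regions, rng)
    background = vol.copy()
    occupied: list[tuple] = []
    m0, m1, m2 = spec.motif_size
    lat = max(1, int(spec.placement_lattice))
    n_stamps = spec.n_motifs * spec.repeats_per_motif
    # placements come from a shuffled grid of slots spaced motif + halo
    # apart (spatially) and motif-depth apart (axially): non-overlapping by
    # construction, deterministic given the seed, and slot corners stay on
    # the placement lattice so motif-overlapping patches repeat exactly.
    halo = max(0, int(spec.context_halo))
    while True:
        step0 = -(-(m0 + halo) // lat) * lat
        step1 = -(-(m1 + halo) // lat) * lat
        step2 = -(-m2 // lat) * lat
        slots = [
            (i, j, k)
            for i in range(0, spec.shape[0] - m0 + 1, step0)
            for j in range(0, spec.shape[1] - m1 + 1, step1)
            for k in range(0, spec.shape[2] - m2 + 1, step2)
        ]
        if len(slots) >= n_stamps or halo == 0:
            break
        halo = max(0, halo - lat)  # relax the halo rather than fail
    if len(slots) < n_stamps:
        raise RuntimeError(
            "could not place motifs without overlap; reduce repeats or motif size"
        )

    # prefer giving all repeats of one motif the same constant background
    # context, so motif-overlapping patches repeat exactly (surround included)
    def context_level(c):
        lo = [max(0, c[i] - (halo if i < 2 else 0)) for i in range(3)]
        hi = [
            min(spec.shape[i], c[i] + spec.motif_size[i] + (halo if i < 2 else 0))
            for i in range(3)
        ]
        ctx = background[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        return float(ctx.min()) if ctx.max() - ctx.min() < 1e-12 else None

    order = rng.permutation(len(slots))
    pool = [slots[i] for i in order]
    by_level: dict = {}
    mixed = []
    for c in pool:
        lvl = context_level(c)
        (by_level.setdefault(lvl, []) if lvl is not None else mixed).append(c)

    placements: list[tuple] = []
    for _ in range(spec.n_motifs):
        take: list[tuple] = []
        best = max(by_level, key=lambda k: len(by_level[k]), default=None)
        if best is not None:
            lvl = by_level.pop(best)
            take = lvl[: spec.repeats_per_motif]
            if lvl[spec.repeats_per_motif :]:
                by_level[best] = lvl[spec.repeats_per_motif :]
        while len(take) < spec.repeats_per_motif:  # relaxed fill
            if mixed:
                take.append(mixed.pop(0))
                continue
            for key in list(by_level):
                if by_level[key]:
                    take.append(by_level[key].pop(0))
                    if not by_level[key]:
                        del by_level[key]
                    break
            else:
                raise RuntimeError(
                    "could not place motifs without overlap; "
                    "reduce repeats or motif size"
                )
        placements.extend(take)

    idx = 0
    for _ in range(spec.n_motifs):
        motif = _low_rank_motif(spec.motif_size, spec.motif_rank, rng, period=lat)
        for _ in range(spec.repeats_per_motif):
            c = placements[idx]
            occupied.append(c)
            idx += 1
            stamp = motif
            if spec.intensity_jitter > 0:
                stamp = motif + rng.normal(0.0, spec.intensity_jitter)
            vol[c[0] : c[0] + m0, c[1] : c[1] + m1, c[2] : c[2] + m2] = stamp
    return np.clip(vol, 0.0, 1.0)


def degrade(
    gt: np.ndarray,
    spec: DegradationSpec,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Low-resolution observation: blur + decimate + additive Gaussian noise."""
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    y = blur_downsample(gt, spec)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sigma, size=y.shape)
    return y
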