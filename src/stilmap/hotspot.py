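"""Local Getis-Ord Gi* hot-spot analysis on masked patch lattices.

Each tissue patch of a slide is treated as a geographic unit; TIL-positive
patches carry value 1 and all other tissue patches value 0. For spatial
weights w_ij (binary queen contiguity including self by default — the "star"
convention) the local statistic at patch i is reported as the z-score

    z_i = (sum_j w_ij x_j - xbar W_i) / (S * sqrt((n U_i - W_i^2) / (n - 1)))

with xbar the field mean, S the population standard deviation,
W_i = sum_j w_ij and U_i = sum_j w_ij^2, all sums running over the n tissue
patches only (background never dilutes the mean). Positive z marks local
enrichment of TIL-positive patches (a hot spot), negative z depletion.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from matplotlib import colormaps
from scipy import sparse

from .lattice import PatchGrid, PatchLabel

__all__ = [
    "SpatialWeights",
    "HotspotMap",
    "binarize_til_map",
    "build_lattice_weights",
    "local_gi_star",
    "compute_hotspot_map",
    "render_hotspot_map",
    "hotspot_table",
]

#: two-sided 5% cutoff on the normal approximation; defines the hot fraction
DEFAULT_HOT_THRESHOLD = 1.96

_NEIGHBOR_OFFSETS = {
    "queen": [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)],
    "rook": [(-1, 0), (0, -1), (0, 1), (1, 0)],
}


@dataclass
class SpatialWeights:
    """Binary contiguity weights among the tissue patches of one grid.

    ``matrix`` is an n x n sparse CSR matrix over tissue-patch indices, in the
    canonical (row, col)-sorted patch order stored in ``rows``/``cols``.
    """

    matrix: sparse.csr_matrix
    rows: np.ndarray
    cols: np.ndarray
    scheme: str
    include_self: bool

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def neighbors(self, i: int) -> np.ndarray:
        return self.matrix.indices[self.matrix.indptr[i]:self.matrix.indptr[i + 1]]


@dataclass
class HotspotMap:
    """Per-tissue-patch Gi* z-scores aligned to a source grid."""

    slide_id: str
    n_rows: int
    n_cols: int
    rows: np.ndarray
    cols: np.ndarray
    z: np.ndarray
    hot_threshold: float = DEFAULT_HOT_THRESHOLD
    degenerate: bool = False

    @property
    def hot_fraction(self) -> float:
        """Fraction of tissue patches with z at or above the hot threshold."""
        return float(np.mean(self.z >= self.hot_threshold))


def _tissue_order(grid: PatchGrid) -> np.ndarray:
    """Canonical patch ordering: lexicographic by (row, col)."""
    return np.lexsort((grid.cols, grid.rows))


def binarize_til_map(grid: PatchGrid) -> np.ndarray:
    """Binary field over tissue patches: 1 for TIL_POS, 0 for all others.

    Order follows the canonical (row, col) sort used by
    :func:`build_lattice_weights`.
    """
    order = _tissue_order(grid)
    return np.array(
        [1.0 if grid.labels[i] is PatchLabel.TIL_POS else 0.0 for i in order]
    )


def build_lattice_weights(
    grid: PatchGrid,
    scheme: Literal["queen", "rook"] = "queen",
    include_self: bool = True,
) -> SpatialWeights:
    """Binary contiguity weights restricted to the patches present in the grid.

    Queen contiguity counts all 8 surrounding lattice cells as neighbors, rook
    the 4 edge-sharing ones; only cells that exist as tissue patches get a
    weight. ``include_self`` adds w_ii = 1 (the Gi* convention). A patch with
    no tissue neighbors keeps just its self-weight.
    """
    if scheme not in _NEIGHBOR_OFFSETS:
        raise ValueError(f"unknown contiguity scheme {scheme!r}")
    order = _tissue_order(grid)
    rows = grid.rows[order]
    cols = grid.cols[order]
    index = {(int(r), int(c)): i for i, (r, c) in enumerate(zip(rows, cols))}

    ii: list[int] = []
    jj: list[int] = []
    offsets = _NEIGHBOR_OFFSETS[scheme]
    for i, (r, c) in enumerate(zip(rows, cols)):
        if include_self:
            ii.append(i)
            jj.append(i)
        for dr, dc in offsets:
            j = index.get((int(r) + dr, int(c) + dc))
            if j is not None:
                ii.append(i)
                jj.append(j)
    n = len(rows)
    matrix = sparse.csr_matrix(
        (np.ones(len(ii)), (np.array(ii), np.array(jj))), shape=(n, n)
    )
    return SpatialWeights(matrix=matrix, rows=rows, cols=cols,
                          scheme=scheme, include_self=include_self)


def local_gi_star(
    x: np.ndarray,
    w: SpatialWeights,
    slide_id: str = "",
    n_rows: int | None = None,
    n_cols: int | None = None,
    hot_threshold: float = DEFAULT_HOT_THRESHOLD,
) -> HotspotMap:
    """Gi* z-scores for a binary (or real) field over the weight lattice.

    A constant field has zero variance; every z is set to 0 and the map is
    flagged degenerate rather than raising, so cohort pipelines survive rare
    all-negative slides. Patches whose own denominator vanishes (e.g. a patch
    adjacent to every other patch, W_i^2 = n U_i) also get z = 0.
    """
    x = np.asarray(x, dtype=float)
    n = w.n
    if x.shape != (n,):
        raise ValueError(f"field length {x.shape} does not match weights n={n}")
    if n < 2:
        raise ValueError("Gi* requires at least 2 tissue patches")

    xbar = x.mean()
    s = np.sqrt(np.mean(x**2) - xbar**2)

    if s == 0.0:
        z = np.zeros(n)
        degenerate = True
    else:
        wx = w.matrix @ x
        ones = np.ones(n)
        w_i = w.matrix @ ones
        u_i = w.matrix.multiply(w.matrix) @ ones
        with np.errstate(invalid="ignore", divide="ignore"):
            denom = s * np.sqrt((n * u_i - w_i**2) / (n - 1))
            z = np.where(denom > 0, (wx - xbar * w_i) / np.where(denom > 0, denom, 1.0), 0.0)
        degenerate = False

    return HotspotMap(
        slide_id=slide_id,
        n_rows=n_rows if n_rows is not None else int(w.rows.max()) + 1,
        n_cols=n_cols if n_cols is not None else int(w.cols.max()) + 1,
        rows=w.rows,
        cols=w.cols,
        z=z,
        hot_threshold=hot_threshold,
        degenerate=degenerate,
    )


def compute_hotspot_map(
    grid: PatchGrid,
    scheme: Literal["queen", "rook"] = "queen",
    include_self: bool = True,
    hot_threshold: float = DEFAULT_HOT_THRESHOLD,
) -> HotspotMap:
    """Convenience: binarize a grid, build weights, and run Gi*."""
    w = build_lattice_weights(grid, scheme=scheme, include_self=include_self)
    x = binarize_til_map(grid)
    return local_gi_star(
        x, w, slide_id=grid.slide_id, n_rows=grid.n_rows, n_cols=grid.n_cols,
        hot_threshold=hot_threshold,
    )


def render_hotspot_map(
    hmap: HotspotMap, block_px: int = 8, z_clip: float = 4.0
) -> Image.Image:
    """Render a hot spot map as an RGB image (blue = cold, red = hot).

    Each tissue patch becomes a ``block_px`` square colored by a diverging
    blue-white-red map of z clipped to ``[-z_clip, +z_clip]`` and centered at
    z = 0; background is white. Deterministic for fixed input.
    """
    if block_px < 1:
        raise ValueError("block_px must be >= 1")
    cmap = colormaps["bwr"]
    t = (np.clip(hmap.z, -z_clip, z_clip) + z_clip) / (2 * z_clip)
    rgb = (np.asarray(cmap(t))[:, :3] * 255).round().astype(np.uint8)

    canvas = np.full((hmap.n_rows, hmap.n_cols, 3), 255, dtype=np.uint8)
    canvas[hmap.rows, hmap.cols] = rgb
    canvas = np.repeat(np.repeat(canvas, block_px, axis=0), block_px, axis=1)
    return Image.fromarray(canvas, mode="RGB")


def hotspot_table(hmap: HotspotMap) -> pd.DataFrame:
    """Gi* table: ``slide_id,row,col,z,hot`` with hot = 1[z >= threshold]."""
    return pd.DataFrame(
        {
            "slide_id": hmap.slide_id,
            "row": hmap.rows,
            "col": hmap.cols,
            "z": hmap.z,
            "hot": (hmap.z >= hmap.hot_threshold).astype(int),
        }
    )
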