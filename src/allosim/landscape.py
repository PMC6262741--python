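"""Toroidal cell lattice with regularly spaced suitable resource patches.

A landscape is a square grid of cells with wrapped (torus) boundaries.  A
fixed number of cells — 2,500 by default, arranged as a 50 x 50 sub-lattice —
are suitable patches on which the resource grows; all other cells are
unsuitable matrix.  Isolation is controlled by the nearest-neighbour distance
``nnd``: the number of unsuitable cells between adjacent suitable patches, so
the grid side is ``sqrt(n_suitable) * (1 + nnd)`` cells (50*(1+NND) at the
default patch count) and patch spacing is ``(nnd + 1)`` cells on both axes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LandscapeConfig",
    "Landscape",
    "generate_landscape",
    "torus_distance",
    "cells_within_radius",
]


@dataclass(frozen=True)
class LandscapeConfig:
    """Landscape geometry and resource parameters.

    ``nnd`` — unsuitable cells between adjacent suitable patches (>= 0);
    ``side_length_cell`` — cell edge in metres; ``n_suitable_target`` —
    number of suitable patches (must be a perfect square; 2,500 default,
    smaller values give desk-scale landscapes); ``resource_K`` — per-cell
    carrying capacity (J); ``resource_r`` — intrinsic daily growth rate;
    ``e_nc`` — non-consumable resource floor (J).
    """

    nnd: int = 0
    side_length_cell: float = 0.25
    n_suitable_target: int = 2_500
    resource_K: float = 2_000.0
    resource_r: float = 0.5
    e_nc: float = 1.0

    def __post_init__(self) -> None:
        if self.nnd < 0:
            raise ValueError("nnd must be non-negative")
        if self.side_length_cell <= 0:
            raise ValueError("cell side length must be positive")
        root = math.isqrt(self.n_suitable_target)
        if root * root != self.n_suitable_target:
            raise ValueError("n_suitable_target must be a perfect square")
        if not 0 <= self.e_nc <= self.resource_K:
            raise ValueError("need 0 <= e_nc <= resource_K")
        if self.resource_r < 0:
            raise ValueError("resource growth rate must be non-negative")


@dataclass
class Landscape:
    """A torus of cells with suitable patches and their resource state.

    ``coords`` holds the (row, col) grid coordinates of the suitable cells;
    ``resource`` the current energy (J) in each.  ``distance_matrix()``
    lazily builds the pairwise torus distances (metres) between suitable
    cells, used by the movement phase.
    """

    config: LandscapeConfig
    dim: int
    coords: np.ndarray  # (n_suitable, 2) int
    resource: np.ndarray  # (n_suitable,) float, J
    _distmat: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_suitable(self) -> int:
        return len(self.coords)

    @property
    def side_length_cell(self) -> float:
        return self.config.side_length_cell

    @property
    def extent_m(self) -> float:
        """Physical side of the torus in metres."""
        return self.dim * self.config.side_length_cell

    def suitable_mask(self) -> np.ndarray:
        """Dense boolean grid of suitability (dim x dim)."""
        mask = np.zeros((self.dim, self.dim), dtype=bool)
        mask[self.coords[:, 0], self.coords[:, 1]] = True
        return mask

    def distance_matrix(self) -> np.ndarray:
        if self._distmat is None:
            self._distmat = torus_distance(
                self.coords[:, None, :],
                self.coords[None, :, :],
                self.dim,
                self.config.side_length_cell,
            )
        return self._distmat

    def to_frame(self) -> pd.DataFrame:
        """Per-suitable-cell snapshot (x, y, resource_J)."""
        return pd.DataFrame(
            {
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "suitable": True,
                "resource_J": self.resource,
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def generate_landscape(cfg: LandscapeConfig) -> Landscape:
    """Build the regular torus lattice of suitable patches at spacing nnd+1.

    Every suitable cell starts at carrying capacity ``K``.  The suitable
    count equals ``cfg.n_suitable_target`` for every ``nnd``, so increasing
    isolation enlarges the grid (side ``sqrt(n) * (1 + nnd)`` cells) without
    removing habitat.
    """
    root = math.isqrt(cfg.n_suitable_target)
    spacing = cfg.nnd + 1
    dim = root * spacing
    ij = np.arange(root) * spacing
    rows, cols = np.meshgrid(ij, ij, indexing="ij")
    coords = np.column_stack([rows.ravel(), cols.ravel()]).astype(np.int64)
    resource = np.full(len(coords), float(cfg.resource_K))
    return Landscape(config=cfg, dim=dim, coords=coords, resource=resource)


def landscape_from_mask(mask, cfg: LandscapeConfig | None = None) -> Landscape:
    """Build a landscape from a custom boolean suitability grid.

    The grid must be square; every suitable cell starts at carrying
    capacity.  Resource parameters come from ``cfg`` (geometry fields are
    ignored in favour of the mask).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2 or mask.shape[0] != mask.shape[1]:
        raise ValueError("suitability mask must be a square grid")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("mask has no suitable cells")
    root = math.isqrt(n)
    base = cfg or LandscapeConfig()
    cfg = LandscapeConfig(
        nnd=base.nnd,
        side_length_cell=base.side_length_cell,
        n_suitable_target=root * root if root * root == n else base.n_suitable_target,
        resource_K=base.resource_K,
        resource_r=base.resource_r,
        e_nc=base.e_nc,
    )
    coords = np.argwhere(mask).astype(np.int64)
    resource = np.full(n, float(cfg.resource_K))
    return Landscape(config=cfg, dim=mask.shape[0], coords=coords, resource=resource)


def torus_distance(a, b, dim: int, side_length: float = 0.25):
    """Euclidean distance (m) between cell centres under wraparound.

    ``a`` and ``b`` are (row, col) coordinates (broadcastable arrays of
    trailing dimension 2); the per-axis offset is the shorter way around the
    torus, then scaled by the cell side length.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    delta = np.abs(a - b)
    delta = np.minimum(delta, dim - delta)
    d = np.hypot(delta[..., 0], delta[..., 1]) * side_length
    return d if np.ndim(d) else float(d)


def cells_within_radius(landscape: Landscape, origin, rad: float) -> np.ndarray:
    """Indices of suitable cells whose centres lie within ``rad`` m of origin.

    ``origin`` is a (row, col) grid coordinate; the origin cell itself is
    included when suitable.  Distances are centre-to-centre on the torus.
    """
    if rad < 0:
        raise ValueError("radius must be non-negative")
    d = torus_distance(
        np.asarray(origin, dtype=float),
        landscape.coords,
        landscape.dim,
        landscape.config.side_length_cell,
    )
    return np.flatnonzero(d <= rad)
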