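"""Region-boundary extraction and distance-to-boundary fields.

Two boundary operators are provided.  ``adjacency_boundary`` implements the
definition: a cell is a boundary cell when any of its queen (8-way)
neighbors carries a different region label.  ``buffer_sum_boundary``
implements the rasterize-buffer-sum procedure: each region layer is
dilated by a metric disk and the layers are summed; cells covered by more
than one dilated region form the boundary band.  The adjacency boundary is
always a subset of the buffer-sum boundary at the default 200-km buffer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, distance_transform_edt

from .community import Grid
from .exceptions import InvalidArgumentError

__all__ = [
    "BoundaryMap",
    "adjacency_boundary",
    "buffer_sum_boundary",
    "distance_to_boundary",
]

UNLABELED = -1


@dataclass
class BoundaryMap:
    """Binary boundary raster plus (optionally) distance-to-boundary in km."""

    grid: Grid
    boundary: np.ndarray  # (n_cells,) bool
    distance: Optional[np.ndarray] = None  # (n_cells,) km, 0 on boundary
    level: str = "region"
    provenance: dict = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.boundary = np.asarray(self.boundary, dtype=bool)
        if self.boundary.shape != (self.grid.n_cells,):
            raise InvalidArgumentError("boundary must cover every grid cell")
        if self.provenance is None:
            self.provenance = {}
        if self.distance is not None:
            self.distance = np.asarray(self.distance, dtype=float)
            if self.distance.shape != (self.grid.n_cells,):
                raise InvalidArgumentError("distance must cover every grid cell")

    @property
    def n_boundary_cells(self) -> int:
        return int(self.boundary.sum())

    def write_csv(self, path) -> None:
        df = pd.DataFrame({
            "cell_id": np.arange(self.grid.n_cells),
            "boundary": self.boundary.astype(int),
        })
        if self.distance is not None:
            df["distance_km"] = self.distance
        df.to_csv(path, index=False)


def _labels_2d(labels: np.ndarray, grid: Grid) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.shape != (grid.n_cells,):
        raise InvalidArgumentError("labels must cover every grid cell "
                                   f"({labels.shape} != ({grid.n_cells},))")
    return labels.reshape(grid.ny, grid.nx)


def adjacency_boundary(labels: np.ndarray, grid: Grid, queen: bool = True,
                       level: str = "region") -> BoundaryMap:
    """Cells whose 8-neighborhood (4 if ``queen=False``) mixes region labels.

    Cells labeled ``-1`` are treated as unlabeled and never become boundary,
    nor do they make their neighbors boundary.
    """
    img = _labels_2d(labels, grid)
    labeled = img != UNLABELED
    boundary = np.zeros_like(labeled)
    offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
               if (dr, dc) != (0, 0) and (queen or dr == 0 or dc == 0)]
    pad_img = np.pad(img, 1, constant_values=UNLABELED)
    for dr, dc in offsets:
        shifted = pad_img[1 + dr:grid.ny + 1 + dr, 1 + dc:grid.nx + 1 + dc]
        differs = labeled & (shifted != UNLABELED) & (shifted != img)
        boundary |= differs
    return BoundaryMap(grid=grid, boundary=boundary.reshape(-1), level=level,
                       provenance={"operator": "adjacency", "queen": queen})


def _disk(radius_cells: int) -> np.ndarray:
    r = int(radius_cells)
    y, x = np.ogrid[-r:r + 1, -r:r + 1]
    return (x * x + y * y) <= r * r


def buffer_sum_boundary(labels: np.ndarray, grid: Grid, buffer_km: float = 200.0,
                        level: str = "region") -> BoundaryMap:
    """Dilate each region layer by a metric disk and flag overlap (sum > 1)."""
    if buffer_km < 0:
        raise InvalidArgumentError("buffer_km must be >= 0")
    img = _labels_2d(labels, grid)
    radius = int(np.ceil(buffer_km / grid.cell_size_km))
    disk = _disk(radius)
    total = np.zeros((grid.ny, grid.nx), dtype=np.int32)
    for lab in np.unique(img):
        if lab == UNLABELED:
            continue
        layer = img == lab
        total += binary_dilation(layer, structure=disk)
    boundary = total > 1
    return BoundaryMap(grid=grid, boundary=boundary.reshape(-1), level=level,
                       provenance={"operator": "buffer_sum", "buffer_km": buffer_km})


def distance_to_boundary(b: BoundaryMap) -> BoundaryMap:
    """Exact Euclidean distance transform to the nearest boundary cell, in km."""
    if b.n_boundary_cells == 0:
        raise InvalidArgumentError("empty boundary: distances are all infinite")
    img = b.boundary.reshape(b.grid.ny, b.grid.nx)
    dist = distance_transform_edt(~img, sampling=b.grid.cell_size_km)
    return BoundaryMap(grid=b.grid, boundary=b.boundary.copy(),
                       distance=dist.reshape(-1), level=b.level,
                       provenance=dict(b.provenance))
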