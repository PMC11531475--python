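"""Equal-area grids and sparse presence/absence community matrices.

The grid is a flat ``nx`` x ``ny`` lattice of square cells indexed in
row-major order (cell 0 at row 0, column 0).  All geometry downstream is
computed in kilometres from cell centroids; the synthetic landscape is
already equal-area so no projection is involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .exceptions import (
    EmptyCommunityError,
    InvalidArgumentError,
    OutOfRangeError,
    UnknownSpeciesError,
)

__all__ = ["Grid", "CommunityMatrix", "build_community", "drop_empty"]


@dataclass(frozen=True)
class Grid:
    """Equal-area raster of square cells.

    Cell ids run ``0 .. nx*ny - 1`` in row-major order:
    ``cell_id = row * nx + col``.
    """

    nx: int
    ny: int
    cell_size_km: float = 100.0

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise InvalidArgumentError("grid dimensions must be positive")
        if self.cell_size_km <= 0:
            raise InvalidArgumentError("cell_size_km must be positive")

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    def rowcol(self, cell_id: np.ndarray | int):
        cell_id = np.asarray(cell_id)
        return cell_id // self.nx, cell_id % self.nx

    def cell_id(self, row, col):
        return np.asarray(row) * self.nx + np.asarray(col)

    def centroids(self, cell_ids: Sequence[int] | None = None) -> np.ndarray:
        """(n, 2) centroid coordinates (x_km, y_km)."""
        ids = np.arange(self.n_cells) if cell_ids is None else np.asarray(cell_ids)
        row, col = self.rowcol(ids)
        x = (col + 0.5) * self.cell_size_km
        y = (row + 0.5) * self.cell_size_km
        return np.column_stack([x, y]).astype(float)

    def to_2d(self, values: np.ndarray, fill=np.nan, cell_ids=None) -> np.ndarray:
        """Scatter a per-cell vector onto the (ny, nx) raster."""
        out = np.full((self.ny, self.nx), fill, dtype=np.result_type(values, type(fill)))
        ids = np.arange(self.n_cells) if cell_ids is None else np.asarray(cell_ids)
        row, col = self.rowcol(ids)
        out[row, col] = values
        return out

    def from_2d(self, raster: np.ndarray) -> np.ndarray:
        if raster.shape != (self.ny, self.nx):
            raise InvalidArgumentError(f"raster shape {raster.shape} != {(self.ny, self.nx)}")
        return raster.reshape(-1)


@dataclass
class CommunityMatrix:
    """Sparse binary cells x species incidence bound to a :class:`Grid`.

    ``cell_ids`` maps matrix rows to grid cell ids, so a matrix may cover a
    subset of the grid (e.g. after :func:`drop_empty`).
    """

    grid: Grid
    species: list[str]
    incidence: sparse.csr_matrix
    cell_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.cell_ids is None:
            self.cell_ids = np.arange(self.grid.n_cells)
        self.cell_ids = np.asarray(self.cell_ids, dtype=np.int64)
        self.incidence = sparse.csr_matrix(self.incidence, dtype=np.int8)
        if len(set(self.species)) != len(self.species):
            raise InvalidArgumentError("duplicate species labels")
        if self.incidence.shape != (len(self.cell_ids), len(self.species)):
            raise InvalidArgumentError(
                f"incidence shape {self.incidence.shape} != "
                f"({len(self.cell_ids)}, {len(self.species)})"
            )
        if self.incidence.nnz and not np.all(self.incidence.data == 1):
            raise InvalidArgumentError("incidence entries must be binary")

    @property
    def n_cells(self) -> int:
        return self.incidence.shape[0]

    @property
    def n_species(self) -> int:
        return self.incidence.shape[1]

    def richness(self) -> np.ndarray:
        return np.asarray(self.incidence.sum(axis=1)).ravel()

    def range_sizes(self) -> np.ndarray:
        return np.asarray(self.incidence.sum(axis=0)).ravel()

    def occupied_cells(self) -> np.ndarray:
        """Grid cell ids of rows with at least one presence."""
        return self.cell_ids[self.richness() > 0]

    def to_dense(self) -> np.ndarray:
        return self.incidence.toarray()

    # --- sparse-triplet CSV round trip -------------------------------------
    def write_triplets(self, path) -> None:
        coo = self.incidence.tocoo()
        df = pd.DataFrame(
            {
                "cell_id": self.cell_ids[coo.row],
                "species_id": [self.species[j] for j in coo.col],
                "presence": np.ones(coo.nnz, dtype=int),
            }
        ).sort_values(["cell_id", "species_id"])
        df.to_csv(path, index=False)

    @classmethod
    def read_triplets(cls, path, grid: Grid, species_universe: Sequence[str]) -> "CommunityMatrix":
        df = pd.read_csv(path, dtype={"species_id": str})
        return build_community(
            zip(df["cell_id"].to_numpy(), df["species_id"]), grid, species_universe
        )


def build_community(
    presences: Iterable[tuple[int, str]],
    grid: Grid,
    species_universe: Sequence[str],
) -> CommunityMatrix:
    """Assemble a binary community matrix from (cell_id, species) records.

    Duplicate records collapse to a single presence.  Species declared in
    ``species_universe`` but absent from the input are kept as all-zero
    columns so matrices from different scenarios stay column-aligned.
    """
    species = list(species_universe)
    if len(set(species)) != len(species):
        raise InvalidArgumentError("species_universe contains duplicates")
    col_of = {s: j for j, s in enumerate(species)}
    rows, cols = [], []
    for cell_id, label in presences:
        cell_id = int(cell_id)
        if not 0 <= cell_id < grid.n_cells:
            raise OutOfRangeError(f"cell_id {cell_id} outside grid of {grid.n_cells} cells")
        if label not in col_of:
            raise UnknownSpeciesError(label)
        rows.append(cell_id)
        cols.append(col_of[label])
    data = np.ones(len(rows), dtype=np.int8)
    inc = sparse.coo_matrix(
        (data, (rows, cols)), shape=(grid.n_cells, len(species))
    ).tocsr()
    inc.data[:] = 1  # collapse duplicates
    inc.sum_duplicates()
    inc.data[:] = 1
    return CommunityMatrix(grid=grid, species=species, incidence=inc)


def drop_empty(cm: CommunityMatrix) -> tuple[CommunityMatrix, np.ndarray, list[str]]:
    """Remove all-zero rows and columns.

    Returns the reduced matrix (whose ``cell_ids`` still refer to the
    original grid), the dropped grid cell ids and the dropped species labels.
    """
    row_keep = cm.richness() > 0
    if not row_keep.any():
        raise EmptyCommunityError("all cells are empty")
    col_keep = cm.range_sizes() > 0
    dropped_cells = cm.cell_ids[~row_keep]
    dropped_species = [s for s, k in zip(cm.species, col_keep) if not k]
    out = CommunityMatrix(
        grid=cm.grid,
        species=[s for s, k in zip(cm.species, col_keep) if k],
        incidence=cm.incidence[row_keep][:, col_keep],
        cell_ids=cm.cell_ids[row_keep],
    )
    return out, dropped_cells, dropped_species
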