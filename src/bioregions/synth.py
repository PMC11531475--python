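"""Synthetic phylogenies, landscapes, and scenario-structured species ranges.

Everything downstream (beta diversity, regionalization, boundaries,
determinant models) is exercised on data from this module, so it plants
known structure: a pure-birth ultrametric tree, smooth environmental
fields with one axis-aligned elevation ridge, and clade-faithful species
ranges confined to contiguous rectangular blocks of the grid ("regions").
Future scenarios contract, expand or translate every range to induce
differentiation, homogenization or boundary redefinition.

All randomness flows from one integer seed through named per-operation
substreams (:func:`_rng`), so identical calls are bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.ndimage import gaussian_filter

from .community import CommunityMatrix, Grid
from .exceptions import DegenerateScenarioError, InvalidArgumentError
from .phylobeta import Phylogeny

__all__ = [
    "Landscape",
    "ScenarioSet",
    "generate_phylogeny",
    "generate_landscape",
    "generate_ranges",
    "apply_scenario",
]


def _stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Named substream so each operation draws independently from one seed."""
    key = int.from_bytes(stream.encode(), "big") % (2**31)
    return np.random.default_rng(np.random.SeedSequence((int(seed), key)))


@dataclass
class Landscape:
    """Gridded environment: elevation, climate fields, and drift tracks."""

    grid: Grid
    elevation: np.ndarray
    temp_mean: np.ndarray
    temp_seasonality: np.ndarray
    precip_mean: np.ndarray
    precip_seasonality: np.ndarray
    past_velocity: np.ndarray
    drift_trajectories: np.ndarray  # (n_cells, T, 2) positions in km
    ridge_col: int = -1  # column index of the planted elevation ridge

    def __post_init__(self) -> None:
        n = self.grid.n_cells
        for name in ("elevation", "temp_mean", "temp_seasonality", "precip_mean",
                     "precip_seasonality", "past_velocity"):
            v = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, v)
            if v.shape != (n,):
                raise InvalidArgumentError(f"{name} must cover all {n} cells")
        for name in ("temp_seasonality", "precip_seasonality", "past_velocity"):
            if np.any(getattr(self, name) < 0):
                raise InvalidArgumentError(f"{name} must be non-negative")
        self.drift_trajectories = np.asarray(self.drift_trajectories, dtype=float)
        if self.drift_trajectories.ndim != 3 or self.drift_trajectories.shape[0] != n \
                or self.drift_trajectories.shape[2] != 2:
            raise InvalidArgumentError("drift_trajectories must be (n_cells, T, 2)")
        if self.drift_trajectories.shape[1] < 2:
            raise InvalidArgumentError("trajectories need T >= 2 timesteps")

    @property
    def field_names(self) -> list[str]:
        return ["elevation", "temp_mean", "temp_seasonality",
                "precip_mean", "precip_seasonality", "past_velocity"]

    def write_csv(self, path) -> None:
        import pandas as pd

        xy = self.grid.centroids()
        df = pd.DataFrame({"cell_id": np.arange(self.grid.n_cells),
                           "x_km": xy[:, 0], "y_km": xy[:, 1]})
        for name in self.field_names:
            df[name] = getattr(self, name)
        df.to_csv(path, index=False)


@dataclass
class ScenarioSet:
    """Present + future communities sharing one grid, species list and tree."""

    present: CommunityMatrix
    phylogeny: Phylogeny
    truth_labels: np.ndarray
    futures: dict[tuple[str, str], CommunityMatrix] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.truth_labels = np.asarray(self.truth_labels, dtype=np.int64)
        if self.truth_labels.shape != (self.present.grid.n_cells,):
            raise InvalidArgumentError("truth_labels must cover every grid cell")
        for cm in self.futures.values():
            if cm.species != self.present.species:
                raise InvalidArgumentError("future communities must share the species list")

    def write_manifest(self, path) -> None:
        manifest = {
            "n_species": self.present.n_species,
            "grid": {"nx": self.present.grid.nx, "ny": self.present.grid.ny,
                     "cell_size_km": self.present.grid.cell_size_km},
            "n_regions_truth": int(len(np.unique(self.truth_labels))),
            "futures": [list(k) for k in self.futures],
        }
        with open(path, "w") as fh:
            json.dump(manifest, fh, indent=2)


def generate_phylogeny(n_tips: int, seed: int) -> Phylogeny:
    """Pure-birth (Yule) ultrametric tree with tips ``sp0001``, ``sp0002``, ...

    Lineages split at unit rate; each split picks a uniform random extant
    lineage. Branch lengths are the waiting times, so the tree is exactly
    ultrametric.
    """
    if n_tips < 2:
        raise InvalidArgumentError("n_tips must be >= 2")
    rng = _stream_rng(seed, "phylogeny")
    # active lineages as (node_id, birth_time); build parent pointers
    parent = [-1]
    birth = [0.0]
    active = [0]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        node = active[i]
        left, right = len(parent), len(parent) + 1
        parent.extend([node, node])
        birth.extend([t, t])
        active[i] = left
        active.append(right)
    t_end = t + rng.exponential(1.0 / n_tips)
    parent_arr = np.asarray(parent)
    birth_arr = np.asarray(birth)
    n_nodes = len(parent)
    lengths = np.zeros(n_nodes)
    is_tip = np.ones(n_nodes, dtype=bool)
    is_tip[parent_arr[parent_arr >= 0]] = False
    for v in range(n_nodes):
        p = parent_arr[v]
        end = t_end if is_tip[v] else birth_arr[np.flatnonzero(parent_arr == v)[0]]
        if p >= 0:
            lengths[v] = end - birth_arr[v]
    # renumber into postorder for the Phylogeny contract
    children: dict[int, list[int]] = {}
    for v, p in enumerate(parent_arr):
        if p >= 0:
            children.setdefault(int(p), []).append(v)
    post: list[int] = []
    stack = [0]
    visited: set[int] = set()
    while stack:
        v = stack[-1]
        kids = children.get(v, [])
        if v not in visited and kids:
            visited.add(v)
            stack.extend(reversed(kids))
        else:
            post.append(stack.pop())
    rank = {v: i for i, v in enumerate(post)}
    new_parent = np.full(n_nodes, -1, dtype=np.int64)
    new_lengths = np.zeros(n_nodes)
    for v in range(n_nodes):
        new_lengths[rank[v]] = lengths[v]
        if parent_arr[v] >= 0:
            new_parent[rank[v]] = rank[parent_arr[v]]
    tip_old = sorted(np.flatnonzero(is_tip), key=lambda v: rank[v])
    tips = [f"sp{i + 1:04d}" for i in range(n_tips)]
    tip_nodes = np.asarray([rank[v] for v in tip_old])
    return Phylogeny(new_parent, new_lengths, tips, tip_nodes)


def _smooth_field(rng: np.random.Generator, ny: int, nx: int, smoothness: float) -> np.ndarray:
    if np.isinf(smoothness):
        return np.zeros((ny, nx))
    noise = rng.standard_normal((ny, nx))
    if smoothness <= 0:
        return noise
    out = gaussian_filter(noise, sigma=smoothness, mode="reflect")
    sd = out.std()
    return out / sd if sd > 0 else out


def generate_landscape(nx: int, ny: int, cell_size_km: float, smoothness: float,
                       seed: int, n_timesteps: int = 16) -> Landscape:
    """Smooth (Gaussian-filtered-noise) environmental fields on an equal-area grid.

    Elevation carries one additive axis-aligned ridge so determinant-recovery
    tests have a known orographic signal; drift trajectories are smooth random
    walks starting at the cell centroids.
    """
    if nx < 3 or ny < 3:
        raise InvalidArgumentError("grid must be at least 3 x 3")
    if cell_size_km <= 0:
        raise InvalidArgumentError("cell_size_km must be positive")
    grid = Grid(nx, ny, cell_size_km)
    rng = _stream_rng(seed, "landscape")

    def f() -> np.ndarray:
        return _smooth_field(rng, ny, nx, smoothness).reshape(-1)

    ridge_col = nx // 2
    cols = np.tile(np.arange(nx), ny).astype(float)
    ridge = 1500.0 * np.exp(-0.5 * ((cols - ridge_col) / max(1.0, nx / 20)) ** 2)
    elevation = 500.0 + 200.0 * f() + ridge
    temp_mean = 15.0 + 8.0 * f()
    temp_seasonality = np.abs(4.0 + 1.5 * f())
    precip_mean = 1000.0 + 300.0 * f()
    precip_seasonality = np.abs(30.0 + 10.0 * f())
    past_velocity = np.abs(0.5 + 0.3 * f())

    start = grid.centroids()
    steps = rng.standard_normal((n_timesteps - 1, ny, nx, 2))
    if np.isinf(smoothness):
        steps[:] = 0.0
    elif smoothness > 0:
        steps = gaussian_filter(steps, sigma=(0, smoothness, smoothness, 0), mode="reflect")
    steps = steps.reshape(n_timesteps - 1, ny * nx, 2) * (0.1 * cell_size_km)
    traj = np.empty((grid.n_cells, n_timesteps, 2))
    traj[:, 0] = start
    traj[:, 1:] = start[:, None, :] + np.cumsum(steps, axis=0).transpose(1, 0, 2)
    return Landscape(grid, elevation, temp_mean, temp_seasonality, precip_mean,
                     precip_seasonality, past_velocity, traj, ridge_col=ridge_col)


def _region_blocks(grid: Grid, n_regions: int) -> np.ndarray:
    """Partition the grid into contiguous near-equal vertical strips."""
    if n_regions > grid.nx:
        raise InvalidArgumentError("n_regions exceeds grid columns")
    edges = np.linspace(0, grid.nx, n_regions + 1)
    col = np.tile(np.arange(grid.nx), grid.ny)
    return np.clip(np.searchsorted(edges, col, side="right") - 1, 0, n_regions - 1)


def _grow_patch(grid: Grid, allowed: np.ndarray, start: int, size: int,
                rng: np.random.Generator) -> list[int]:
    """Random BFS patch of ``size`` cells inside the allowed mask."""
    in_patch = {start}
    frontier = [start]
    while len(in_patch) < size and frontier:
        i = frontier.pop(int(rng.integers(len(frontier))))
        r, c = int(i // grid.nx), int(i % grid.nx)
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < grid.ny and 0 <= cc < grid.nx:
                    j = rr * grid.nx + cc
                    if allowed[j] and j not in in_patch:
                        in_patch.add(j)
                        frontier.append(j)
                        if len(in_patch) >= size:
                            return sorted(in_patch)
    return sorted(in_patch)


def generate_ranges(phylo: Phylogeny, land: Landscape, n_regions: int,
                    n_species: int, occupancy: float, clade_fidelity: float,
                    seed: int, spillover: float = 0.0) -> ScenarioSet:
    """Plant clade-structured species ranges in contiguous grid blocks.

    Tips contiguous in the tree traversal share a home region; with
    probability ``1 - clade_fidelity`` a species is reassigned to a uniform
    random region, diluting the phylogenetic signal.  Each species occupies a
    contiguous random patch covering ``occupancy`` of its home region, plus
    (with probability ``spillover``) a few cells just across the region edge.
    """
    if n_regions < 2:
        raise InvalidArgumentError("n_regions must be >= 2")
    if n_species > phylo.n_tips:
        raise InvalidArgumentError("n_species exceeds tip count")
    if not 0 < occupancy <= 1:
        raise InvalidArgumentError("occupancy must be in (0, 1]")
    if not 0 <= clade_fidelity <= 1:
        raise InvalidArgumentError("clade_fidelity must be in [0, 1]")
    grid = land.grid
    if n_regions > grid.n_cells:
        raise InvalidArgumentError("n_regions exceeds number of cells")
    rng = _stream_rng(seed, "ranges")
    truth = _region_blocks(grid, n_regions)

    # tips in traversal order -> contiguous clade blocks across regions
    species = phylo.tips[:n_species]
    home = np.repeat(np.arange(n_regions), int(np.ceil(n_species / n_regions)))[:n_species]
    reassign = rng.random(n_species) >= clade_fidelity
    home[reassign] = rng.integers(n_regions, size=int(reassign.sum()))

    rows, cols = [], []
    for j, sp in enumerate(species):
        region_cells = np.flatnonzero(truth == home[j])
        allowed = np.zeros(grid.n_cells, dtype=bool)
        allowed[region_cells] = True
        size = max(1, int(round(occupancy * len(region_cells))))
        start = int(region_cells[rng.integers(len(region_cells))])
        patch = _grow_patch(grid, allowed, start, size, rng)
        if spillover > 0 and rng.random() < spillover:
            patch = _add_spillover(grid, truth, home[j], patch, rng)
        rows.extend(patch)
        cols.extend([j] * len(patch))
    inc = sparse.coo_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)),
        shape=(grid.n_cells, n_species),
    ).tocsr()
    inc.sum_duplicates()
    inc.data[:] = 1
    present = CommunityMatrix(grid=grid, species=list(species), incidence=inc)
    for r in range(n_regions):
        if not np.any(home == r):
            raise InvalidArgumentError(f"planted region {r} received no species")
    return ScenarioSet(present=present, phylogeny=phylo, truth_labels=truth)


def _add_spillover(grid: Grid, truth: np.ndarray, region: int, patch: list[int],
                   rng: np.random.Generator) -> list[int]:
    """Add up to 3 out-of-region cells adjacent to the patch (transition zone)."""
    out = set(patch)
    candidates = set()
    for i in patch:
        r, c = int(i // grid.nx), int(i % grid.nx)
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = r + dr, c + dc
                if 0 <= rr < grid.ny and 0 <= cc < grid.nx:
                    j = rr * grid.nx + cc
                    if truth[j] != region:
                        candidates.add(j)
    extra = sorted(candidates)
    rng.shuffle(extra)
    out.update(extra[:3])
    return sorted(out)


def _range_cells(cm: CommunityMatrix) -> list[np.ndarray]:
    csc = cm.incidence.tocsc()
    return [csc.indices[csc.indptr[j]:csc.indptr[j + 1]].copy()
            for j in range(cm.n_species)]


def apply_scenario(s: ScenarioSet, mode: str, magnitude: float, seed: int,
                   horizon: str | None = None, scenario: str | None = None) -> ScenarioSet:
    """Append a future community derived from the present ranges.

    ``contract`` removes the given fraction of each range starting from its
    patch edge; ``expand`` adds that fraction of adjacent cells (region
    borders may be crossed); ``shift`` translates every range ``magnitude``
    cells along +x, dropping cells pushed off the grid.
    """
    if mode not in ("contract", "expand", "shift"):
        raise InvalidArgumentError(f"unknown mode {mode!r}")
    if magnitude < 0:
        raise InvalidArgumentError("magnitude must be >= 0")
    grid = s.present.grid
    rng = _stream_rng(seed, f"scenario-{mode}")
    ranges = _range_cells(s.present)
    new_ranges: list[np.ndarray] = []
    for cells in ranges:
        if len(cells) == 0:
            new_ranges.append(cells)
            continue
        if mode == "shift":
            shift = int(round(magnitude))
            r, c = grid.rowcol(cells)
            c = c + shift
            keep = c < grid.nx
            new_ranges.append(np.asarray(grid.cell_id(r[keep], c[keep])))
        elif mode == "contract":
            n_remove = int(round(magnitude * len(cells)))
            new_ranges.append(_erode(grid, cells, n_remove, rng))
        else:
            n_add = int(round(magnitude * len(cells)))
            new_ranges.append(_dilate(grid, cells, n_add, rng))
    if all(len(c) == 0 for c in new_ranges):
        raise DegenerateScenarioError("scenario emptied every species range")
    rows = np.concatenate([c for c in new_ranges if len(c)]) if any(len(c) for c in new_ranges) else np.empty(0, int)
    cols = np.concatenate([np.full(len(c), j) for j, c in enumerate(new_ranges) if len(c)]) if len(rows) else np.empty(0, int)
    inc = sparse.coo_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)),
        shape=(grid.n_cells, s.present.n_species),
    ).tocsr()
    inc.sum_duplicates()
    inc.data[:] = 1
    future = CommunityMatrix(grid=grid, species=list(s.present.species), incidence=inc)
    key = (horizon or f"T{len(s.futures) + 1}", scenario or mode)
    futures = dict(s.futures)
    futures[key] = future
    return ScenarioSet(present=s.present, phylogeny=s.phylogeny,
                       truth_labels=s.truth_labels, futures=futures)


def _neighbor_count(grid: Grid, cells: np.ndarray) -> np.ndarray:
    member = np.zeros(grid.n_cells, dtype=bool)
    member[cells] = True
    img = member.reshape(grid.ny, grid.nx).astype(int)
    pad = np.pad(img, 1)
    count = sum(pad[1 + dr:grid.ny + 1 + dr, 1 + dc:grid.nx + 1 + dc]
                for dr in (-1, 0, 1) for dc in (-1, 0, 1) if not dr == dc == 0)
    return count.reshape(-1)[cells]


def _erode(grid: Grid, cells: np.ndarray, n_remove: int, rng: np.random.Generator) -> np.ndarray:
    cells = np.asarray(cells).copy()
    for _ in range(n_remove):
        if len(cells) == 0:
            break
        nc = _neighbor_count(grid, cells)
        edge = np.flatnonzero(nc == nc.min())
        drop = edge[rng.integers(len(edge))]
        cells = np.delete(cells, drop)
    return cells


def _dilate(grid: Grid, cells: np.ndarray, n_add: int, rng: np.random.Generator) -> np.ndarray:
    member = np.zeros(grid.n_cells, dtype=bool)
    member[cells] = True
    for _ in range(n_add):
        img = member.reshape(grid.ny, grid.nx)
        pad = np.pad(img, 1)
        neigh = np.zeros_like(img, dtype=bool)
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                neigh |= pad[1 + dr:grid.ny + 1 + dr, 1 + dc:grid.nx + 1 + dc]
        frontier = np.flatnonzero(neigh.reshape(-1) & ~member)
        if len(frontier) == 0:
            break
        member[frontier[rng.integers(len(frontier))]] = True
    return np.flatnonzero(member)
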