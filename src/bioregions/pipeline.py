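"""End-to-end orchestration: synthesize -> beta -> regionalize -> boundaries.

A run is driven by one :class:`RunConfig` (YAML on disk), writes every
intermediate artifact as plain text under an output directory, and records
a JSON manifest with seeds, per-stage summaries and file checksums so a
rerun with the same config is verifiably bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import boundaries as bnd
from . import changestats as cs
from . import phylobeta as pb
from . import regionalize as rg
from . import synth
from .community import drop_empty
from .exceptions import (
    AlignmentError,
    InvalidArgumentError,
    UndefinedCorrelationError,
)

__all__ = ["RunConfig", "ScenarioSpec", "run_pipeline", "compare_runs"]

log = logging.getLogger("bioregions")


@dataclass
class ScenarioSpec:
    mode: str
    magnitude: float
    horizon: str = "T1"
    scenario_id: str = "SSP126"

    def __post_init__(self) -> None:
        if self.mode not in ("contract", "expand", "shift"):
            raise InvalidArgumentError(f"unknown scenario mode {self.mode!r}")
        if self.magnitude < 0:
            raise InvalidArgumentError("magnitude must be >= 0")


@dataclass
class RunConfig:
    """Validated run settings; defaults mirror the standard analysis constants."""

    seed: int = 0
    nx: int = 20
    ny: int = 20
    cell_size_km: float = 100.0
    smoothness: float = 2.0
    n_tips: int = 80
    n_species: int = 60
    n_regions: int = 3
    occupancy: float = 0.5
    clade_fidelity: float = 1.0
    spillover: float = 0.0
    metric: str = "simpson"
    realm_threshold: float = 0.85
    region_threshold: float = 0.90
    buffer_km: float = 200.0
    radius_km: float = 283.0
    n_boot_effect: int = 1000
    n_boot_model: int = 200
    scenarios: list[ScenarioSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.metric not in ("simpson", "sorensen"):
            raise InvalidArgumentError(f"unknown metric {self.metric!r}")
        if not 0 < self.realm_threshold < self.region_threshold < 1:
            raise InvalidArgumentError("need 0 < realm_threshold < region_threshold < 1")
        self.scenarios = [
            s if isinstance(s, ScenarioSpec) else ScenarioSpec(**s) for s in self.scenarios
        ]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _regionalize_community(cm, tree, cfg: RunConfig):
    reduced, dropped_cells, _ = drop_empty(cm)
    d = pb.pairwise_beta(reduced, tree, metric=cfg.metric)
    reg = rg.regionalize(d, cfg.realm_threshold, cfg.region_threshold)
    return reduced, d, reg, dropped_cells


def _full_labels(grid, cell_ids, labels) -> np.ndarray:
    out = np.full(grid.n_cells, bnd.UNLABELED, dtype=np.int64)
    out[cell_ids] = labels
    return out


def run_pipeline(cfg: RunConfig, outdir) -> dict:
    """Execute all stages for the present plus every configured scenario."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(cfg), "stages": {}, "files": {}}

    log.info("synth: grid %dx%d, %d tips, %d species", cfg.nx, cfg.ny, cfg.n_tips, cfg.n_species)
    tree = synth.generate_phylogeny(cfg.n_tips, cfg.seed)
    land = synth.generate_landscape(cfg.nx, cfg.ny, cfg.cell_size_km, cfg.smoothness, cfg.seed)
    sset = synth.generate_ranges(tree, land, cfg.n_regions, cfg.n_species,
                                 cfg.occupancy, cfg.clade_fidelity, cfg.seed,
                                 spillover=cfg.spillover)
    for i, sc in enumerate(cfg.scenarios):
        sset = synth.apply_scenario(sset, sc.mode, sc.magnitude, cfg.seed + i + 1,
                                    horizon=sc.horizon, scenario=sc.scenario_id)
    tree.write_newick(outdir / "phylogeny.nwk")
    land.write_csv(outdir / "landscape.csv")
    sset.present.write_triplets(outdir / "community_present.csv")
    manifest["stages"]["synth"] = {
        "n_tips": tree.n_tips,
        "n_species": sset.present.n_species,
        "n_occupied_cells": int(len(sset.present.occupied_cells())),
        "scenarios": [f"{k[0]}-{k[1]}" for k in sset.futures],
    }

    runs = {"present": sset.present}
    for key, cm in sset.futures.items():
        runs[f"{key[0]}-{key[1]}"] = cm

    results: dict = {}
    for name, cm in runs.items():
        reduced, d, reg, dropped = _regionalize_community(cm, tree, cfg)
        cm.write_triplets(outdir / f"community_{name}.csv")
        d.write_csv(outdir / f"beta_{name}.csv")
        reg.write_labels(outdir / f"labels_{name}.csv")
        reg.write_merge(outdir / f"merge_{name}.csv")
        labels_region = _full_labels(cm.grid, reduced.cell_ids, reg.labels_region)
        labels_realm = _full_labels(cm.grid, reduced.cell_ids, reg.labels_realm)
        bmap = bnd.buffer_sum_boundary(labels_region, cm.grid, cfg.buffer_km)
        bmap = bnd.distance_to_boundary(bmap) if bmap.n_boundary_cells else bmap
        bmap.write_csv(outdir / f"boundary_region_{name}.csv")
        rmap = bnd.buffer_sum_boundary(labels_realm, cm.grid, cfg.buffer_km, level="realm")
        rmap = bnd.distance_to_boundary(rmap) if rmap.n_boundary_cells else rmap
        rmap.write_csv(outdir / f"boundary_realm_{name}.csv")
        results[name] = {"reduced": reduced, "beta": d, "reg": reg,
                         "labels_region_full": labels_region,
                         "labels_realm_full": labels_realm}
        manifest["stages"][name] = {
            "linkage": reg.linkage_method,
            "k_realm": reg.k_realm,
            "k_region": reg.k_region,
            "explained_realm": reg.explained_realm,
            "explained_region": reg.explained_region,
            "n_cells": int(d.n),
            "n_boundary_cells_region": int(bmap.n_boundary_cells),
            "dropped_cells": int(len(dropped)),
        }
        log.info("%s: linkage=%s k_realm=%d k_region=%d", name,
                 reg.linkage_method, reg.k_realm, reg.k_region)

    for f in sorted(outdir.glob("*.csv")) + sorted(outdir.glob("*.nwk")):
        manifest["files"][f.name] = _sha256(f)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    manifest["_results"] = results  # in-memory only; not serialized
    manifest["_tree"] = tree
    manifest["_truth"] = sset.truth_labels
    return manifest


def compare_runs(manifest: dict, name_a: str, name_b: str,
                 n_boot: int = 1000, seed: int = 0) -> dict:
    """Congruence + change report between two regionalizations of one run.

    Returns v-measures per level, boundary-distance correlations
    (Dutilleul-corrected) per level, and the within-region effect-size table
    computed on the present-day region labels.
    """
    res = manifest.get("_results")
    if res is None or name_a not in res or name_b not in res:
        raise InvalidArgumentError("manifest lacks in-memory results for those names")
    a, b = res[name_a], res[name_b]
    grid_cfg = manifest["config"]
    if a["beta"].n != b["beta"].n or not np.array_equal(a["beta"].cell_ids, b["beta"].cell_ids):
        common = np.intersect1d(a["beta"].cell_ids, b["beta"].cell_ids)
        if len(common) < 3:
            raise AlignmentError("runs share fewer than 3 cells")
        ia = np.searchsorted(a["beta"].cell_ids, common)
        ib = np.searchsorted(b["beta"].cell_ids, common)
        da, db = a["beta"].submatrix(ia), b["beta"].submatrix(ib)
        lab_a = {"region": a["reg"].labels_region[ia], "realm": a["reg"].labels_realm[ia]}
        lab_b = {"region": b["reg"].labels_region[ib], "realm": b["reg"].labels_realm[ib]}
    else:
        da, db = a["beta"], b["beta"]
        lab_a = {"region": a["reg"].labels_region, "realm": a["reg"].labels_realm}
        lab_b = {"region": b["reg"].labels_region, "realm": b["reg"].labels_realm}

    report: dict = {"a": name_a, "b": name_b, "v_measure": {}, "boundary_correlation": {}}
    from .community import Grid

    grid = Grid(grid_cfg["nx"], grid_cfg["ny"], grid_cfg["cell_size_km"])
    for level in ("region", "realm"):
        score = cs.v_measure(lab_a[level], lab_b[level])
        report["v_measure"][level] = {"v": score.v, "homogeneity": score.homogeneity,
                                      "completeness": score.completeness, "B": score.B}
        key = f"labels_{level}_full"
        ba = bnd.buffer_sum_boundary(a[key], grid, grid_cfg["buffer_km"], level=level)
        bb = bnd.buffer_sum_boundary(b[key], grid, grid_cfg["buffer_km"], level=level)
        if ba.n_boundary_cells and bb.n_boundary_cells:
            dist_a = bnd.distance_to_boundary(ba).distance
            dist_b = bnd.distance_to_boundary(bb).distance
            try:
                r, ess, p = cs.modified_ttest(dist_a, dist_b, grid.centroids())
                report["boundary_correlation"][level] = {"r": r, "ess": ess, "p": p}
            except UndefinedCorrelationError:
                # e.g. the boundary band covers the whole grid: distances constant
                report["boundary_correlation"][level] = None
        else:
            report["boundary_correlation"][level] = None

    effects, mean_d = cs.within_region_beta_change(
        lab_a["region"], da, db, n_boot=n_boot, seed=seed
    )
    report["effects"] = {
        str(k): {"d": e.d, "ci": [e.ci_low, e.ci_high], "t": e.t_stat,
                 "p": e.p_value, "n_pairs": e.n1}
        for k, e in effects.items()
    }
    report["global_mean_d"] = mean_d
    return report
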