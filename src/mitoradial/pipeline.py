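"""End-to-end orchestration: stacks -> segmentation -> radial statistics.

A run takes named conditions (synthetic phantom recipes, or TIFF stacks
plus an annotation table), segments every cell, pools normalized radial
distances per condition, and compares all condition pairs with a KS test
on the peripheral subset (or the full distributions). A sensitivity sweep
repeats the comparison over a grid of smoothing/threshold choices.

All randomness derives from one master seed; per-stage seeds are stable
hashes of (master seed, stage, condition), so a rerun with the same config
is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .phantom import ConditionDataset, PhantomSpec, make_condition_dataset
from .radial import (
    NormalizedDistanceSet,
    RadialHistogram,
    compute_pixel_distances,
    ks_two_sample,
    normalize_distances,
    peripheral_subset,
    pool_condition,
    radial_histogram,
)
from .segmentation import SegmentationConfig, component_stats, segment_stack
from .stack import read_stack

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticCondition",
    "TiffCondition",
    "RunConfig",
    "ConditionReport",
    "PipelineReport",
    "run_pipeline",
    "sensitivity_sweep",
    "load_config",
]


def derive_seed(master_seed: int, *context: object) -> int:
    """Stable 63-bit seed from a master seed and arbitrary context labels."""
    tag = ":".join([str(master_seed), *map(str, context)])
    return int.from_bytes(hashlib.blake2b(tag.encode(), digest_size=8).digest()) >> 1


@dataclass(frozen=True)
class SyntheticCondition:
    """A condition rendered from a phantom recipe."""

    name: str
    phantom: PhantomSpec
    n_cells: int = 10
    per_cell_jitter: float = 0.0


@dataclass(frozen=True)
class TiffCondition:
    """A condition read from disk: TIFF stacks plus an annotation CSV with
    columns ``cell_id,stack_path,nucleus_z,nucleus_y,nucleus_x``."""

    name: str
    annotations_csv: str
    voxel_size: tuple[float, float, float] = (0.2, 0.0542, 0.0542)


@dataclass(frozen=True)
class RunConfig:
    """Everything one end-to-end run needs."""

    conditions: tuple[SyntheticCondition | TiffCondition, ...]
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    distance_units: str = "physical"
    fraction: float = 0.30
    n_bins: int = 50
    ks_scope: str = "peripheral"  # or "full"
    out_dir: str | None = None
    master_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conditions) == 0:
            raise ValueError("at least one condition is required")
        names = [c.name for c in self.conditions]
        if len(set(names)) != len(names):
            raise ValueError("condition names must be unique")
        if self.ks_scope not in ("peripheral", "full"):
            raise ValueError("ks_scope must be 'peripheral' or 'full'")

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class ConditionReport:
    """Per-condition segmentation and radial statistics."""

    name: str
    cell_stats: pd.DataFrame
    pooled: np.ndarray
    histogram: RadialHistogram
    peripheral: np.ndarray
    excluded_cells: list[str]

    @property
    def n_cells(self) -> int:
        return int((self.cell_stats["n_components"] > 0).sum())

    @property
    def n_pixels(self) -> int:
        return int(self.pooled.size)


@dataclass
class PipelineReport:
    """All condition reports plus pairwise comparisons."""

    conditions: dict[str, ConditionReport]
    comparisons: list[dict]
    config: RunConfig

    def to_json(self) -> str:
        payload = {
            "master_seed": self.config.master_seed,
            "fraction": self.config.fraction,
            "ks_scope": self.config.ks_scope,
            "conditions": {
                name: {
                    "n_cells": rep.n_cells,
                    "n_pixels": rep.n_pixels,
                    "excluded_cells": rep.excluded_cells,
                    "mean_normalized_distance": float(rep.pooled.mean()) if rep.n_pixels else None,
                }
                for name, rep in self.conditions.items()
            },
            "comparisons": self.comparisons,
        }
        return json.dumps(payload, sort_keys=True, indent=2)


def _materialize(cond, master_seed: int) -> tuple[list[tuple[str, object, tuple[float, float, float], tuple[float, float, float]]], str]:
    """Expand a condition into (cell_id, stack, nucleus_center, voxel_size)."""
    cells = []
    if isinstance(cond, SyntheticCondition):
        ds: ConditionDataset = make_condition_dataset(
            cond.phantom,
            cond.n_cells,
            per_cell_jitter=cond.per_cell_jitter,
            seed=derive_seed(master_seed, "phantom", cond.name),
        )
        for (cell_id, stack, _truth), row in zip(ds.cells, ds.annotations.itertuples()):
            center = (row.nucleus_z, row.nucleus_y, row.nucleus_x)
            cells.append((cell_id, stack, center, stack.voxel_size))
    elif isinstance(cond, TiffCondition):
        table = pd.read_csv(cond.annotations_csv)
        base = Path(cond.annotations_csv).parent
        for row in table.itertuples():
            path = Path(row.stack_path)
            if not path.is_absolute():
                path = base / path
            stack = read_stack(path, voxel_size=cond.voxel_size)
            cells.append(
                (str(row.cell_id), stack, (row.nucleus_z, row.nucleus_y, row.nucleus_x), cond.voxel_size)
            )
    else:  # pragma: no cover - guarded by RunConfig typing
        raise TypeError(f"unknown condition type {type(cond)!r}")
    return cells, cond.name


def _analyze_condition(name, cells, cfg: RunConfig) -> ConditionReport:
    rows = []
    distance_sets: list[NormalizedDistanceSet] = []
    excluded: list[str] = []
    for cell_id, stack, center, voxel_size in cells:
        cs = segment_stack(stack, cfg.segmentation)
        stats = component_stats(cs)
        rows.append(
            {
                "cell_id": cell_id,
                "n_components": stats.n_components,
                "mean_size_voxels": stats.mean_component_size,
                "n_pixels": int(cs.sizes.sum()) if len(cs) else 0,
            }
        )
        if stats.n_components == 0:
            logger.warning("condition %s: cell %s has no surviving components; excluded", name, cell_id)
            excluded.append(cell_id)
            continue
        dists = compute_pixel_distances(cs, center, voxel_size, distance_units=cfg.distance_units)
        distance_sets.append(normalize_distances(dists, cell_id=cell_id))
    if not distance_sets:
        pooled = np.empty(0)
        hist = RadialHistogram(np.linspace(0, 1, cfg.n_bins + 1), np.zeros(cfg.n_bins))
        peripheral = np.empty(0)
    else:
        pooled = pool_condition(distance_sets)
        hist = radial_histogram(pooled, cfg.n_bins)
        peripheral = peripheral_subset(pooled, cfg.fraction)
    return ConditionReport(
        name=name,
        cell_stats=pd.DataFrame(rows),
        pooled=pooled,
        histogram=hist,
        peripheral=peripheral,
        excluded_cells=excluded,
    )


def _compare(rep_a: ConditionReport, rep_b: ConditionReport, cfg: RunConfig) -> dict:
    a = rep_a.peripheral if cfg.ks_scope == "peripheral" else rep_a.pooled
    b = rep_b.peripheral if cfg.ks_scope == "peripheral" else rep_b.pooled
    ks = ks_two_sample(a, b)
    return {
        "condition_a": rep_a.name,
        "condition_b": rep_b.name,
        "n_cells_a": rep_a.n_cells,
        "n_cells_b": rep_b.n_cells,
        "n_pixels": int(a.size + b.size),
        "D": ks.statistic,
        "p_value": ks.p_value,
        "fraction": cfg.fraction if cfg.ks_scope == "peripheral" else 1.0,
    }


def run_pipeline(cfg: RunConfig) -> PipelineReport:
    """Segment and analyze every condition, then compare all pairs."""
    reports: dict[str, ConditionReport] = {}
    for cond in cfg.conditions:
        cells, name = _materialize(cond, cfg.master_seed)
        reports[name] = _analyze_condition(name, cells, cfg)

    comparisons = []
    for name_a, name_b in combinations(reports, 2):
        rep_a, rep_b = reports[name_a], reports[name_b]
        if rep_a.n_pixels == 0 or rep_b.n_pixels == 0:
            logger.warning("skipping comparison %s vs %s: empty condition", name_a, name_b)
            continue
        comparisons.append(_compare(rep_a, rep_b, cfg))

    report = PipelineReport(conditions=reports, comparisons=comparisons, config=cfg)
    if cfg.out_dir is not None:
        _write_artifacts(report, Path(cfg.out_dir))
    return report


def _write_artifacts(report: PipelineReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, rep in report.conditions.items():
        rep.cell_stats.to_csv(out_dir / f"{name}_cell_stats.csv", index=False)
        hist = rep.histogram
        pd.DataFrame(
            {
                "bin_left": hist.bin_edges[:-1],
                "bin_right": hist.bin_edges[1:],
                "density": hist.densities,
            }
        ).to_csv(out_dir / f"{name}_histogram.csv", index=False)
        pd.DataFrame({"normalized_distance": rep.pooled}).to_csv(
            out_dir / f"{name}_distances.csv", index=False
        )
    (out_dir / "report.json").write_text(report.to_json())


def sensitivity_sweep(
    cfg: RunConfig,
    sigma_values: Sequence[float],
    threshold_values: Sequence[float],
) -> pd.DataFrame:
    """Repeat the first-pair comparison over a (sigma, threshold) grid.

    Input stacks are materialized once and re-segmented per grid point.
    Returns a long-format table with one row per (sigma, threshold):
    KS D and p for the first condition pair, pooled mean distance per
    condition, and a flag for grid points where some cell segmented empty.
    """
    if len(sigma_values) == 0 or len(threshold_values) == 0:
        raise ValueError("parameter grids must be nonempty")
    materialized = [_materialize(cond, cfg.master_seed) for cond in cfg.conditions]
    rows = []
    for sigma in sigma_values:
        for thr in threshold_values:
            sub = cfg.replace(
                segmentation=cfg.segmentation.replace(gaussian_sigma=sigma, threshold=thr),
                out_dir=None,
            )
            reports = {name: _analyze_condition(name, cells, sub) for cells, name in materialized}
            names = list(reports)
            row: dict = {"sigma": sigma, "threshold": thr}
            for name in names:
                row[f"mean_distance_{name}"] = (
                    float(reports[name].pooled.mean()) if reports[name].n_pixels else np.nan
                )
            row["n_excluded_cells"] = sum(len(r.excluded_cells) for r in reports.values())
            first_pair = next(
                (
                    (reports[a], reports[b])
                    for a, b in combinations(names, 2)
                    if reports[a].n_pixels and reports[b].n_pixels
                ),
                None,
            )
            if first_pair is None:
                row.update({"D": np.nan, "p_value": np.nan, "all_empty": True})
            else:
                cmp = _compare(first_pair[0], first_pair[1], sub)
                row.update({"D": cmp["D"], "p_value": cmp["p_value"], "all_empty": False})
            rows.append(row)
    return pd.DataFrame(rows)


def load_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML document."""
    import yaml

    doc = yaml.safe_load(Path(path).read_text())
    conditions: list[SyntheticCondition | TiffCondition] = []
    for name, spec in doc.get("conditions", {}).items():
        if "phantom" in spec:
            phantom_kwargs = dict(spec["phantom"])
            for key in ("stack_shape", "voxel_size", "mito_length_range", "nucleus_center"):
                if key in phantom_kwargs and phantom_kwargs[key] is not None:
                    phantom_kwargs[key] = tuple(phantom_kwargs[key])
            conditions.append(
                SyntheticCondition(
                    name=name,
                    phantom=PhantomSpec(**phantom_kwargs),
                    n_cells=spec.get("n_cells", 10),
                    per_cell_jitter=spec.get("per_cell_jitter", 0.0),
                )
            )
        else:
            conditions.append(
                TiffCondition(
                    name=name,
                    annotations_csv=spec["annotations_csv"],
                    voxel_size=tuple(spec.get("voxel_size", (0.2, 0.0542, 0.0542))),
                )
            )
    seg = SegmentationConfig(**doc.get("segmentation", {}))
    analysis = doc.get("analysis", {})
    return RunConfig(
        conditions=tuple(conditions),
        segmentation=seg,
        distance_units=analysis.get("distance_units", "physical"),
        fraction=analysis.get("fraction", 0.30),
        n_bins=analysis.get("n_bins", 50),
        ks_scope=analysis.get("ks_scope", "peripheral"),
        out_dir=doc.get("out_dir"),
        master_seed=doc.get("master_seed", 0),
    )
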