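"""End-to-end orchestration: cellness -> ROI -> orientation -> distributions.

``analyze_stack`` runs the slice-wise chain on one stack and returns its
orientation samples, density profile, and filter-chain counts.
``run`` drives a whole multi-stack analysis from a RunConfig (YAML/JSON),
pools the samples into an overall KDE, and writes all artifacts (samples
CSV, KDE grid, octiles, dispersion table, density profiles, run report).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cellness import (
    CellnessParams,
    binarize,
    cellness_filter,
    extract_clusters,
    filter_by_area,
    otsu_threshold,
)
from .distribution import (
    KdeParams,
    cell_density_profile,
    dispersion_table,
    kde2d_circular,
    octile_curves,
)
from .io import read_stack
from .orientation import anisotropy_ok, collect_samples, principal_angle
from .roi import AcquisitionGeometry, apply_roi, effective_roi
from .synthetic import ImageStack

logger = logging.getLogger("tubeorient")

__all__ = ["RunConfig", "StackResult", "RunReport", "analyze_stack", "run", "estimate_lm_thickness"]


@dataclass
class StackResult:
    stack_id: str
    samples: pd.DataFrame
    density: pd.DataFrame
    counts: Dict[str, int]
    rois: list
    lm_thickness_um: float


@dataclass
class RunConfig:
    """Configuration of a full run.

    ``stacks`` is a list of dicts with a ``path`` plus the per-stack
    acquisition geometry fields (outer_radius_um, wall_thickness_um,
    pixel_size_um, slice_spacing_um, and lm_thickness_um or
    ``"estimate"``).
    """

    stacks: List[dict]
    cellness: CellnessParams = field(default_factory=CellnessParams)
    delta_max_um: float = 2.0
    apex_offset_px: float = 0.0
    min_ratio: float = 1.5
    kde: KdeParams = field(default_factory=KdeParams)
    dispersion_depths: Sequence[float] = (0.2, 0.4, 0.6, 0.8)
    dispersion_window: float = 0.1
    output_dir: str = "tubeorient-out"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kw = dict(raw)
        if "cellness" in kw and isinstance(kw["cellness"], dict):
            kw["cellness"] = CellnessParams(**kw["cellness"])
        if "kde" in kw and isinstance(kw["kde"], dict):
            kw["kde"] = KdeParams(**kw["kde"])
        roi_block = kw.pop("roi", None)
        if roi_block:
            kw["delta_max_um"] = roi_block.get("delta_max_um", 2.0)
            kw["apex_offset_px"] = roi_block.get("apex_offset_px", 0.0)
        orient_block = kw.pop("orientation", None)
        if orient_block:
            kw["min_ratio"] = orient_block.get("min_ratio", 1.5)
        disp = kw.pop("dispersion", None)
        if disp:
            kw["dispersion_depths"] = tuple(disp.get("depths", (0.2, 0.4, 0.6, 0.8)))
            kw["dispersion_window"] = disp.get("window_halfwidth", 0.1)
        return cls(**kw)


@dataclass
class RunReport:
    stacks: List[dict]
    outputs: List[str]
    version: str
    config: dict


def estimate_lm_thickness(density: pd.DataFrame, fraction: float = 0.25) -> float:
    """Muscle-layer thickness as the contiguous depth range of high density.

    The layer is taken to extend over the longest contiguous run of slices
    whose cell density exceeds ``fraction`` of the profile maximum. This is
    an optional fallback when no measured thickness is supplied.
    """
    if len(density) == 0 or density["density_per_1e4um2"].max() <= 0:
        raise ValueError("cannot estimate thickness from an empty density profile")
    above = (
        density["density_per_1e4um2"] >= fraction * density["density_per_1e4um2"].max()
    ).to_numpy()
    depths = density["depth_um"].to_numpy()
    best, cur_start, best_span = None, None, 0.0
    for i, flag in enumerate(above):
        if flag and cur_start is None:
            cur_start = i
        if (not flag or i == len(above) - 1) and cur_start is not None:
            end = i if flag else i - 1
            span = depths[end] - depths[cur_start]
            if span > best_span:
                best_span, best = span, (cur_start, end)
            cur_start = None
    if best is None:
        raise ValueError("no contiguous high-density range found")
    return float(best_span)


def analyze_stack(
    stack: ImageStack,
    cellness_params: Optional[CellnessParams] = None,
    delta_max_um: float = 2.0,
    min_ratio: float = 1.5,
    lm_thickness_um: Optional[float] = None,
    apex_offset_px: float = 0.0,
) -> StackResult:
    """Run the full per-stack chain and collect samples and densities.

    Per slice: cellness filter, binarize, cluster, area filter, ROI
    application, then the anisotropy filter and angle computation. Density
    uses the in-ROI area-filtered clusters (detected nuclei); orientation
    uses the stricter anisotropy-passed subset.
    """
    params = cellness_params or CellnessParams()
    geom = stack.geometry
    if apex_offset_px:
        geom = dataclasses.replace(geom, apex_offset_px=apex_offset_px)
    px = geom.pixel_size_um

    counts = {"raw": 0, "area_filtered": 0, "in_roi": 0, "anisotropy_passed": 0}
    counts_per_slice: Dict[int, int] = {}
    oriented = []
    rois = []
    for k in range(stack.n_slices):
        cmap = cellness_filter(stack.data[k], params, px)
        thr = otsu_threshold(cmap) if params.use_otsu else params.threshold
        mask = binarize(cmap, thr)
        clusters = extract_clusters(mask, px, params.connectivity, slice_index=k)
        counts["raw"] += len(clusters)
        kept = filter_by_area(clusters, params.area_min_um2, params.area_max_um2)
        counts["area_filtered"] += len(kept)
        roi = effective_roi(geom, k, delta_max_um)
        rois.append(roi)
        in_roi = apply_roi(kept, roi, geom) if roi.valid else []
        counts["in_roi"] += len(in_roi)
        counts_per_slice[k] = len(in_roi)
        for cl in in_roi:
            if cl.n_pixels >= 2 and anisotropy_ok(cl, min_ratio):
                principal_angle(cl)
                oriented.append(cl)
    counts["anisotropy_passed"] = len(oriented)

    density = cell_density_profile(counts_per_slice, rois, geom, lm_thickness_um)
    lm = lm_thickness_um or geom.lm_thickness_um
    if lm is None:
        lm = estimate_lm_thickness(density)
        logger.info("%s: estimated LM thickness %.1f µm", stack.stack_id, lm)
        density = cell_density_profile(counts_per_slice, rois, geom, lm)
    samples = collect_samples(
        oriented, stack.stack_id, geom.slice_spacing_um, lm, geometry=geom
    )
    logger.info(
        "%s: %d raw -> %d area -> %d ROI -> %d oriented",
        stack.stack_id,
        counts["raw"],
        counts["area_filtered"],
        counts["in_roi"],
        counts["anisotropy_passed"],
    )
    return StackResult(stack.stack_id, samples, density, counts, rois, lm)


def _load_configured_stack(entry: dict) -> ImageStack:
    entry = dict(entry)
    path = entry.pop("path")
    stack_id = entry.pop("stack_id", None)
    lm = entry.pop("lm_thickness_um", None)
    if lm == "estimate":
        lm = None
    import tifffile

    with tifffile.TiffFile(path) as tif:
        n_slices = len(tif.pages)
        shape = tif.pages[0].shape
    geom = AcquisitionGeometry(
        outer_radius_um=entry["outer_radius_um"],
        wall_thickness_um=entry["wall_thickness_um"],
        pixel_size_um=entry.get("pixel_size_um", 0.5),
        slice_spacing_um=entry.get("slice_spacing_um", 0.5),
        field_size_px=shape,
        n_slices=n_slices,
        lm_thickness_um=lm,
    )
    return read_stack(path, geom, stack_id)


def run(config: RunConfig) -> RunReport:
    """Execute all stacks, pool the results, and write artifacts.

    Per-stack failures are logged and skipped; the run fails only if every
    stack fails. Deterministic for a fixed config.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    results: List[StackResult] = []
    stack_reports = []
    for entry in config.stacks:
        try:
            stack = _load_configured_stack(entry)
            res = analyze_stack(
                stack,
                config.cellness,
                config.delta_max_um,
                config.min_ratio,
                stack.geometry.lm_thickness_um,
                config.apex_offset_px,
            )
            results.append(res)
            stack_reports.append(
                {
                    "stack_id": res.stack_id,
                    "counts": res.counts,
                    "lm_thickness_um": res.lm_thickness_um,
                }
            )
        except Exception as exc:  # per-stack isolation
            logger.error("stack %s failed: %s", entry.get("path"), exc)
            stack_reports.append({"stack_id": str(entry.get("path")), "error": str(exc)})
    if not results:
        raise RuntimeError("all stacks failed")

    samples = pd.concat([r.samples for r in results], ignore_index=True)
    outputs = []

    def _write(df: pd.DataFrame, name: str):
        p = out / name
        df.to_csv(p, index=False, float_format="%.6g")
        outputs.append(str(p))

    _write(samples, "samples.csv")

    dist = kde2d_circular(
        samples["z_n"].to_numpy(),
        samples["alpha_deg"].to_numpy(),
        config.kde,
        stack_ids=samples["stack_id"].to_numpy(),
    )
    kde_long = pd.DataFrame(
        {
            "z_n": np.repeat(dist.depth_grid, len(dist.angle_grid)),
            "alpha_deg": np.tile(dist.angle_grid, len(dist.depth_grid)),
            "density": dist.density.ravel(),
        }
    )
    _write(kde_long, "kde.csv")

    octs = octile_curves(dist)
    oct_df = pd.DataFrame(
        octs.T, columns=[f"q{k}_8" for k in range(1, 8)]
    ).assign(z_n=dist.depth_grid)
    _write(oct_df, "octiles.csv")

    if len(results) >= 2:
        table = dispersion_table(
            samples, config.dispersion_depths, config.dispersion_window
        )
        _write(table, "dispersion_table.csv")

    density_all = pd.concat(
        [r.density.assign(stack_id=r.stack_id) for r in results], ignore_index=True
    )
    _write(density_all, "density_profiles.csv")

    report = RunReport(
        stacks=stack_reports,
        outputs=outputs,
        version=__version__,
        config=_config_echo(config),
    )
    (out / "run_report.json").write_text(json.dumps(dataclasses.asdict(report), indent=2))
    return report


def _config_echo(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["dispersion_depths"] = list(config.dispersion_depths)
    return d
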