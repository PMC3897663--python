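"""Reading and writing image stacks and run artifacts.

Stacks are multi-page TIFF files, one grayscale page per slice, ordered
from the adventitial (outer) to the proprial (inner) side. Synthetic
stacks are written as 16-bit pages with a fixed intensity scale plus a
JSON sidecar carrying the generating spec and the ground truth (angles in
degrees, positions in µm).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import tifffile

from .roi import AcquisitionGeometry
from .synthetic import (
    GroundTruth,
    ImageStack,
    NoiseModel,
    OrientationField,
    SyntheticSpec,
)

__all__ = ["read_stack", "write_stack", "read_sidecar", "write_synthetic_stack"]

_UINT16_SCALE = 50.0


def read_stack(path, geometry: AcquisitionGeometry, stack_id: Optional[str] = None) -> ImageStack:
    """Read a multi-page grayscale TIFF as an ImageStack.

    Pages must all be 2D and of one size; a color page or a size mismatch
    raises with the offending page index.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        shapes = []
        for i, page in enumerate(tif.pages):
            shp = page.shape
            if len(shp) != 2:
                raise ValueError(
                    f"{path.name}: page {i} is not grayscale (shape {shp})"
                )
            shapes.append(shp)
        if len(set(shapes)) > 1:
            bad = next(i for i, s in enumerate(shapes) if s != shapes[0])
            raise ValueError(
                f"{path.name}: page {bad} size {shapes[bad]} differs from "
                f"page 0 size {shapes[0]}"
            )
        data = tif.asarray()
    if data.ndim == 2:
        data = data[None, ...]
    return ImageStack(
        data=data, geometry=geometry, stack_id=stack_id or path.stem
    )


def _spec_to_dict(spec: SyntheticSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["orientation_field"] = [list(k) for k in spec.orientation_field.knots]
    return d


def _spec_from_dict(d: dict) -> SyntheticSpec:
    d = dict(d)
    d["orientation_field"] = OrientationField(
        tuple(tuple(k) for k in d["orientation_field"])
    )
    d["noise"] = NoiseModel(**d["noise"])
    d["field_size_px"] = tuple(d["field_size_px"])
    return SyntheticSpec(**d)


def write_synthetic_stack(
    path, stack: ImageStack, spec: SyntheticSpec, truth: GroundTruth
) -> Tuple[Path, Path]:
    """Write a synthetic stack as 16-bit TIFF plus a JSON sidecar."""
    path = Path(path)
    data16 = np.clip(
        np.round(stack.data.astype(np.float64) * _UINT16_SCALE), 0, 65535
    ).astype(np.uint16)
    tifffile.imwrite(path, data16, photometric="minisblack")
    sidecar = path.with_suffix(".json")
    payload = {
        "intensity_scale": _UINT16_SCALE,
        "spec": _spec_to_dict(spec),
        "ground_truth": {
            "nuclei": truth.nuclei.replace({np.nan: None}).to_dict("records"),
            "target_density": truth.target_density,
            "volume_density_per_um3": truth.volume_density_per_um3,
            "wall_thickness_um": truth.wall_thickness_um,
            "n_clutter": truth.n_clutter,
        },
    }
    sidecar.write_text(json.dumps(payload))
    return path, sidecar


def read_sidecar(path) -> Tuple[SyntheticSpec, GroundTruth]:
    """Read the spec and ground truth back from a synthetic sidecar JSON."""
    import pandas as pd

    payload = json.loads(Path(path).read_text())
    spec = _spec_from_dict(payload["spec"])
    gt = payload["ground_truth"]
    nuclei = pd.DataFrame(
        gt["nuclei"],
        columns=["x_um", "y_um", "z_um", "angle_deg", "is_round", "wall_depth_um"],
    )
    truth = GroundTruth(
        nuclei=nuclei,
        orientation_field=spec.orientation_field,
        target_density=gt["target_density"],
        volume_density_per_um3=gt["volume_density_per_um3"],
        wall_thickness_um=gt["wall_thickness_um"],
        n_clutter=gt["n_clutter"],
    )
    return spec, truth


def write_stack(path, stack: ImageStack) -> Path:
    """Write a stack's raw data as a multi-page TIFF (dtype preserved)."""
    path = Path(path)
    tifffile.imwrite(path, stack.data, photometric="minisblack")
    return path
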