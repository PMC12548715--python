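"""File formats and run configuration.

Stacks travel as multi-page TIFF (one page per z-slice, 8- or 16-bit,
single channel), ground truth as JSON (points in um, world coordinates,
z-y-x order), tables as CSV. The physical voxel size is carried in the TIFF
ImageJ metadata and/or supplied through :class:`RunConfig`; reading a stack
with no voxel size anywhere is an error, as is anisotropic metadata (this
pipeline is defined for isotropic voxels only).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .simulate import GroundTruth
from .stack import VolumeStack

__all__ = [
    "RunConfig",
    "read_stack",
    "write_stack",
    "read_ground_truth",
    "write_ground_truth",
]


@dataclass
class RunConfig:
    """Pipeline configuration; defaults are the standard analysis constants
    (0.09 um isotropic voxels, tubeness scale 0.32 um, ROI grid of
    89.51 um windows at 100 um spacing)."""

    voxel_size_um: float = 0.09
    sigma_um: float = 0.32
    threshold_mode: str = "otsu"  # "otsu" | "fixed"
    threshold_low: float | None = None
    threshold_high: float | None = None
    grid_spacing_um: float = 100.0
    grid_window_um: float = 89.51
    classifier_path: str | None = None
    seed: int = 0
    input_paths: list[str] = field(default_factory=list)
    output_dir: str = "."

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def hash(self) -> str:
        """Stable short hash of the full configuration, stamped on outputs."""
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def write_stack(stack: VolumeStack, path) -> None:
    """Write a stack as multi-page TIFF with the voxel size in the metadata."""
    voxels = stack.voxels
    if voxels.dtype not in (np.uint8, np.uint16):
        raise ValueError("stacks are stored as 8- or 16-bit TIFF; cast first")
    vs = stack.voxel_size_um
    tifffile.imwrite(
        path,
        voxels,
        imagej=True,
        resolution=(1.0 / vs, 1.0 / vs),
        metadata={"spacing": vs, "unit": "um", "axes": "ZYX"},
    )


def read_stack(path, voxel_size_um: float | None = None, channel_name: str = "") -> VolumeStack:
    """Read a multi-page TIFF as a :class:`VolumeStack`.

    The voxel size comes from the ImageJ metadata (z spacing and x/y
    resolution, which must agree — isotropy is an invariant of this
    pipeline) or from ``voxel_size_um``; having neither is an error.
    """
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        meta = tif.imagej_metadata or {}
        spacing = meta.get("spacing")
        xres = None
        page = tif.pages[0]
        if meta and "XResolution" in page.tags:
            num, den = page.tags["XResolution"].value
            if num and den:
                xres = den / num
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a single-channel z-stack, got shape {arr.shape}")
    vs = voxel_size_um
    if vs is None:
        if spacing is None:
            raise ValueError(f"{path}: no voxel size in metadata and none supplied")
        if xres is not None and abs(spacing - xres) > 1e-6 * max(spacing, xres):
            raise ValueError(
                f"{path}: anisotropic metadata (z {spacing} vs xy {xres} um); "
                "isotropic voxels are required"
            )
        vs = float(spacing)
    return VolumeStack(arr, vs, channel_name=channel_name)


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "coordinate_order": "zyx",
        "units": "um",
        "voxel_size_um": truth.voxel_size_um,
        "total_length_um": truth.total_length_um,
        "centerlines": [np.asarray(c).tolist() for c in truth.centerlines],
        "boutons": [
            {"center_um": np.asarray(c).tolist(), "radius_um": r} for c, r in truth.boutons
        ],
    }
    Path(path).write_text(json.dumps(payload))


def read_ground_truth(path) -> GroundTruth:
    data = json.loads(Path(path).read_text())
    truth = GroundTruth(
        centerlines=[np.asarray(c, dtype=float) for c in data["centerlines"]],
        total_length_um=float(data["total_length_um"]),
        boutons=[
            (np.asarray(b["center_um"], dtype=float), float(b["radius_um"]))
            for b in data["boutons"]
        ],
        voxel_size_um=float(data["voxel_size_um"]),
    )
    truth.validate()
    return truth
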