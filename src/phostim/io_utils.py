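"""File interchange: legacy-VTK, NIfTI and YAML configuration round-trips."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .phantom import (
    DEFAULT_EYE_CENTER_MM,
    DEFAULT_EYE_RADIUS_MM,
    VoxelPhantom,
    attach_torso,
    build_layered_head,
    carve_orbit,
    embed_eyes,
    seal_orbit_posterior,
)

__all__ = [
    "write_vtk_structured_points",
    "write_phantom_nifti",
    "save_phantom_config",
    "load_phantom_config",
    "phantom_from_config",
]


def write_vtk_structured_points(
    path: str | Path,
    phantom: VoxelPhantom,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
    title: str = "phostim field export",
) -> None:
    """ASCII legacy-VTK structured-points file with node and cell arrays.

    ``point_data`` arrays are per-node (flat, x fastest after transposition
    to VTK order); ``cell_data`` arrays are per-voxel scalars of the grid
    shape or (n_vox, 3) vectors.
    """
    nx, ny, nz = phantom.node_shape
    h = phantom.spacing_mm
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} {nz}",
        f"ORIGIN {phantom.origin_mm[0]} {phantom.origin_mm[1]} {phantom.origin_mm[2]}",
        f"SPACING {h} {h} {h}",
    ]

    def emit(arr):
        flat = np.asarray(arr)
        for chunk in np.array_split(flat.ravel(), max(1, flat.size // 9)):
            lines.append(" ".join(f"{v:.9g}" for v in np.atleast_1d(chunk)))

    if point_data:
        lines.append(f"POINT_DATA {nx * ny * nz}")
        for name, arr in point_data.items():
            grid = np.asarray(arr).reshape(phantom.node_shape)
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            emit(grid.transpose(2, 1, 0))  # VTK: x fastest
    if cell_data:
        ncell = int(np.prod(phantom.shape))
        lines.append(f"CELL_DATA {ncell}")
        for name, arr in cell_data.items():
            arr = np.asarray(arr)
            if arr.ndim == 2 and arr.shape[1] == 3:
                grid = arr.reshape(*phantom.shape, 3)
                lines.append(f"VECTORS {name} double")
                emit(grid.transpose(2, 1, 0, 3))
            else:
                grid = arr.reshape(phantom.shape)
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                emit(grid.transpose(2, 1, 0))
    Path(path).write_text("\n".join(lines) + "\n")


def write_phantom_nifti(phantom: VoxelPhantom, path: str | Path) -> None:
    """Label volume as NIfTI; the affine maps voxel indices to RAS mm."""
    import nibabel as nib

    h = phantom.spacing_mm
    affine = np.diag([h, h, h, 1.0])
    affine[:3, 3] = phantom.origin_mm + h / 2.0  # voxel (0,0,0) center
    img = nib.Nifti1Image(phantom.labels.astype(np.int16), affine)
    nib.save(img, str(path))


def save_phantom_config(config: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))


def load_phantom_config(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


DEFAULT_CONFIG = {
    "units": {"length": "mm", "conductivity": "S/m", "current": "A"},
    "head": {
        "radii_mm": [92.0, 86.0, 80.0, 78.0],
        "tissues": ["scalp", "skull", "csf", "brain"],
        "spacing_mm": 2.0,
    },
    "eyes": {
        "center_mm": list(DEFAULT_EYE_CENTER_MM),
        "radius_mm": DEFAULT_EYE_RADIUS_MM,
        "orbit_margin_mm": 4.0,
    },
    "torso": {"length_mm": 120.0, "radius_mm": 100.0},
}


def phantom_from_config(config: dict) -> VoxelPhantom:
    """Build a phantom from a (validated) YAML-style configuration dict."""
    head = config["head"]
    ph = build_layered_head(head["radii_mm"], head["tissues"], head["spacing_mm"])
    eyes = config.get("eyes")
    if eyes:
        c = np.asarray(eyes["center_mm"], float)
        margin = float(eyes.get("orbit_margin_mm", 4.0))
        for sx in (1.0, -1.0):
            carve_orbit(ph, c * np.array([sx, 1, 1]), eyes["radius_mm"] + margin)
        embed_eyes(ph, eye_center_mm=c, eye_radius_mm=eyes["radius_mm"])
        if len(head["radii_mm"]) > 1:
            seal_orbit_posterior(ph, c, head["radii_mm"][1])
    torso = config.get("torso")
    if torso and torso.get("length_mm", 0) > 0:
        ph = attach_torso(ph, torso["length_mm"], torso["radius_mm"])
    return ph
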