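"""Regions of interest, current-density summaries, and retinal maps.

ROIs mirror the quantities the threshold analysis needs: the outer element
layer of each eyeball (the coarse-eye model's "eye surface"), the posterior
retinal semi-shell (the compartmental model's retina), an occipital-cortex
stand-in (posterior spherical cap of brain tissue) and an LGN stand-in
(small deep ball each side).  Retinal topography is summarized on a
4-quadrant × 2-eccentricity-ring sector grid, in both retinal and
visual-field conventions — the visual-field map is the retinal map flipped
in both dimensions, because the eye's optics invert the image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fem_solver import CurrentDensityField
from .phantom import _FACE_DIRS, AIR, MontageSpec, VoxelPhantom

__all__ = [
    "ROISet",
    "RetinalMap",
    "build_rois",
    "mean_current_density",
    "retinal_topographic_map",
    "electrode_eye_distances",
]

OC_HALF_ANGLE_DEG = 30.0  # posterior cap half-angle for the OC stand-in
OC_MIN_RADIUS_FRACTION = 0.55  # keep the cap an outer shell, clear of the LGN
LGN_CENTER_MM = (12.0, -18.0, 0.0)  # right LGN stand-in (left mirrors x)
LGN_RADIUS_MM = 5.0
CENTRAL_BOUNDARY_DEG = 30.0  # central/peripheral split, polar angle from pole


@dataclass
class ROISet:
    """Named sets of voxel (element) ravel indices with their geometric rule."""

    rois: dict[str, np.ndarray]
    provenance: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.rois[name]

    def names(self) -> list[str]:
        return list(self.rois)


@dataclass
class RetinalMap:
    """Sector means of |J| (mA/m²): shape (2 rings, 2 vertical, 2 horizontal).

    Ring 0 is central, ring 1 peripheral.  In retinal convention, vertical
    index 0 = upper retina / 1 = lower, horizontal 0 = left (−x) / 1 = right
    (+x) in head coordinates.  The visual-field version flips both quadrant
    axes (not the rings).
    """

    sector_means: np.ndarray
    sector_counts: np.ndarray
    convention: str = "retinal"

    def to_visual_field(self) -> "RetinalMap":
        if self.convention == "visual_field":
            return self
        return RetinalMap(
            sector_means=self.sector_means[:, ::-1, ::-1].copy(),
            sector_counts=self.sector_counts[:, ::-1, ::-1].copy(),
            convention="visual_field",
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        rings = ("central", "peripheral")
        vert = ("upper", "lower")
        horiz = ("left", "right")
        for i, ring in enumerate(rings):
            for j, v in enumerate(vert):
                for k, hz in enumerate(horiz):
                    rows.append(
                        {
                            "ring": ring,
                            "vertical": v,
                            "horizontal": hz,
                            "mean_mA_per_m2": self.sector_means[i, j, k],
                            "n_elements": int(self.sector_counts[i, j, k]),
                        }
                    )
        return pd.DataFrame(rows)


def _ravel_of_mask(phantom: VoxelPhantom, mask: np.ndarray) -> np.ndarray:
    return np.flatnonzero(mask.ravel())


def build_rois(phantom: VoxelPhantom) -> ROISet:
    """Geometric ROIs on a phantom with embedded eyes and a brain.

    Produces, per side: ``{right,left}_eye_surface`` (outer element layer of
    the eyeball, optic nerve excluded), ``{right,left}_retina`` (retina-
    labeled elements), ``{right,left}_oc`` and ``{right,left}_lgn``.
    """
    names = phantom.name_to_id()
    eye_tissues = {
        "sclera", "cornea", "retina", "lens", "aqueous_humor", "vitreous_humor",
    }
    missing = [t for t in ("retina", "sclera") if t not in names]
    brain_ids = [i for i, n in phantom.tissue_names.items()
                 if n in ("brain", "gray_matter", "white_matter")]
    if missing or not brain_ids:
        lack = missing + ([] if brain_ids else ["brain"])
        raise ValueError(f"phantom lacks required tissues: {lack}")

    lab = phantom.labels
    eye_ids = [names[t] for t in eye_tissues if t in names]
    nerve_id = names.get("optic_nerve", -1)
    in_eye = np.isin(lab, eye_ids)
    retina_id = names["retina"]

    # outer layer: eye voxels with a face neighbor outside eye-or-nerve
    pad = np.pad(np.isin(lab, eye_ids + [nerve_id]), 1, constant_values=False)
    interior = np.ones(phantom.shape, dtype=bool)
    for d in _FACE_DIRS:
        nb = pad[
            1 + d[0] : phantom.shape[0] + 1 + d[0],
            1 + d[1] : phantom.shape[1] + 1 + d[1],
            1 + d[2] : phantom.shape[2] + 1 + d[2],
        ]
        interior &= nb
    outer_layer = in_eye & ~interior

    centers = phantom.voxel_centers()
    xs = centers[:, 0].reshape(phantom.shape)

    rois: dict[str, np.ndarray] = {}
    prov: dict[str, str] = {}
    for side, sign in (("right", 1.0), ("left", -1.0)):
        side_mask = (xs * sign) > 0
        rois[f"{side}_eye_surface"] = _ravel_of_mask(
            phantom, outer_layer & side_mask
        )
        prov[f"{side}_eye_surface"] = (
            "outer element layer of the eyeball (optic nerve excluded)"
        )
        rois[f"{side}_retina"] = _ravel_of_mask(
            phantom, (lab == retina_id) & side_mask
        )
        prov[f"{side}_retina"] = "retina-labeled posterior semi-shell elements"

    brain_mask = np.isin(lab, brain_ids)
    r = np.linalg.norm(centers, axis=1).reshape(phantom.shape)
    r_brain_max = r[brain_mask].max()
    with np.errstate(invalid="ignore"):
        cos_post = np.divide(-centers[:, 1], np.linalg.norm(centers, axis=1),
                             out=np.zeros(len(centers)),
                             where=np.linalg.norm(centers, axis=1) > 0)
    cos_post = cos_post.reshape(phantom.shape)
    cap = (
        brain_mask
        & (cos_post >= math.cos(math.radians(OC_HALF_ANGLE_DEG)))
        & (r >= OC_MIN_RADIUS_FRACTION * r_brain_max)
    )
    lgn_c = np.asarray(LGN_CENTER_MM)
    for side, sign in (("right", 1.0), ("left", -1.0)):
        side_mask = (xs * sign) > 0
        rois[f"{side}_oc"] = _ravel_of_mask(phantom, cap & side_mask)
        prov[f"{side}_oc"] = (
            f"brain voxels in the posterior cap (half-angle "
            f"{OC_HALF_ANGLE_DEG}°, outer {1 - OC_MIN_RADIUS_FRACTION:.0%} shell)"
        )
        c = lgn_c * np.array([sign, 1.0, 1.0])
        ball = (np.linalg.norm(centers - c, axis=1) <= LGN_RADIUS_MM).reshape(
            phantom.shape
        )
        rois[f"{side}_lgn"] = _ravel_of_mask(phantom, ball & brain_mask)
        prov[f"{side}_lgn"] = (
            f"{LGN_RADIUS_MM} mm ball at {tuple(c)} mm within brain tissue"
        )

    for name, idx in rois.items():
        if idx.size == 0:
            raise ValueError(f"ROI {name!r} is empty on this phantom")
    return ROISet(rois=rois, provenance=prov)


def mean_current_density(
    field: CurrentDensityField, roi: np.ndarray, unit: str = "mA/m2"
) -> float:
    """Volume-weighted mean |J| over the ROI (arithmetic for uniform voxels)."""
    roi = np.asarray(roi)
    if roi.size == 0:
        raise ValueError("ROI is empty")
    return float(field.magnitudes_at(roi, unit=unit).mean())


def retinal_topographic_map(
    field: CurrentDensityField,
    retina_roi: np.ndarray,
    eye_center_mm,
    optic_axis,
    central_boundary_deg: float = CENTRAL_BOUNDARY_DEG,
) -> RetinalMap:
    """Bin retinal elements into quadrant × eccentricity sectors of mean |J|.

    Elements are positioned about the optic axis: the polar angle from the
    posterior pole splits central (≤ ``central_boundary_deg``) from
    peripheral; the signs of the vertical (z) and horizontal (x) components
    in the plane orthogonal to the axis pick the quadrant.
    """
    axis = np.asarray(optic_axis, float)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise ValueError("degenerate optic axis")
    axis = axis / norm

    phantom = field.phantom
    pos = phantom.centers_of_ravel(np.asarray(retina_roi)) - np.asarray(
        eye_center_mm, float
    )
    mags = field.magnitudes_at(retina_roi, unit="mA/m2")

    # polar angle from the posterior pole (direction −axis)
    r = np.linalg.norm(pos, axis=1)
    cos_pole = (pos @ (-axis)) / np.maximum(r, 1e-12)
    polar = np.degrees(np.arccos(np.clip(cos_pole, -1.0, 1.0)))
    ring = (polar > central_boundary_deg).astype(int)  # 0 central, 1 peripheral

    # in-plane components: vertical from +z, horizontal from +x (projected)
    e_v = np.array([0.0, 0.0, 1.0]) - axis * axis[2]
    if np.linalg.norm(e_v) < 1e-9:
        raise ValueError("optic axis parallel to the vertical reference")
    e_v = e_v / np.linalg.norm(e_v)
    e_h = np.cross(e_v, -axis)  # completes a right-handed in-plane frame
    v = pos @ e_v
    hcomp = pos @ e_h
    vert = (v < 0).astype(int)  # 0 upper retina, 1 lower
    horiz = (hcomp > 0).astype(int)  # 0 left (−), 1 right (+)

    means = np.zeros((2, 2, 2))
    counts = np.zeros((2, 2, 2), dtype=int)
    for i in range(2):
        for j in range(2):
            for k in range(2):
                sel = (ring == i) & (vert == j) & (horiz == k)
                counts[i, j, k] = int(sel.sum())
                if sel.any():
                    means[i, j, k] = mags[sel].mean()
    return RetinalMap(sector_means=means, sector_counts=counts)


def electrode_eye_distances(
    phantom: VoxelPhantom,
    montage: MontageSpec,
    target: str = "right_eye_center",
    oc_roi: np.ndarray | None = None,
) -> dict[str, float]:
    """Average patch-centroid distances (cm) to the eye and to the OC centroid.

    Returns ``{"eye_cm": ..., "oc_cm": ...}``; the OC entry is only present
    when ``oc_roi`` is given.
    """
    if target not in phantom.landmarks:
        raise KeyError(f"phantom has no landmark {target!r}")
    eye = phantom.landmarks[target]
    dists = [np.linalg.norm(p.centroid_mm - eye) for p in montage.patches]
    out = {"eye_cm": float(np.mean(dists) / 10.0)}
    if oc_roi is not None:
        oc_centroid = phantom.centers_of_ravel(np.asarray(oc_roi)).mean(axis=0)
        d_oc = [np.linalg.norm(p.centroid_mm - oc_centroid) for p in montage.patches]
        out["oc_cm"] = float(np.mean(d_oc) / 10.0)
    return out
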