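"""Synthetic voxel phantoms of the head, eyes and torso, with electrode montages.

The phantoms are parameterized stand-ins for subject anatomy: concentric
spherical shells (scalp / skull / CSF / brain), mirror-symmetric compartmental
eyes (sclera, cornea, retina, lens, aqueous and vitreous humor, optic nerve)
embedded in carved orbital cavities, and an optional cylindrical torso so a
shoulder electrode can be placed.  Axes follow the RAS convention (+x right,
+y anterior, +z superior), voxel ownership is decided by the voxel center,
and all grids are built symmetric about the midsagittal plane x = 0 so that
mirror-symmetric configurations produce voxelwise mirror-symmetric phantoms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "VoxelPhantom",
    "ConductivityTable",
    "ElectrodePatch",
    "MontageSpec",
    "MODEL1",
    "MODEL2",
    "TEN_TWENTY_ANGLES",
    "build_layered_head",
    "carve_orbit",
    "embed_eyes",
    "seal_orbit_posterior",
    "attach_torso",
    "place_montage",
    "default_head",
    "DEFAULT_EYE_CENTER_MM",
    "DEFAULT_EYE_RADIUS_MM",
]

AIR = 0

# Default adult-average geometry (mm).
DEFAULT_HEAD_RADII_MM = (92.0, 86.0, 80.0, 78.0)
DEFAULT_HEAD_TISSUES = ("scalp", "skull", "csf", "brain")
DEFAULT_EYE_RADIUS_MM = 12.0
# Right eye center, anterior-lateral, with the corneal-side pole ~2.5 mm
# beneath the scalp surface (the eye sits directly under the thin lids);
# the left eye mirrors it through x = 0.
DEFAULT_EYE_CENTER_MM = (31.0, 70.0, -12.0)
ORBIT_MARGIN_MM = 4.0

PATCH_AREA_MM2 = 900.0  # 3 x 3 cm electrode
PATCH_GEODESIC_RADIUS_MM = math.sqrt(PATCH_AREA_MM2 / math.pi)

_FACE_DIRS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=np.int64,
)


@dataclass
class VoxelPhantom:
    """Labeled 3-D voxel grid with isotropic physical spacing.

    ``labels[i, j, k]`` is the tissue id of the voxel whose center is
    ``origin_mm + (index + 0.5) * spacing_mm``; id 0 is non-conducting air.
    """

    labels: np.ndarray
    spacing_mm: float
    origin_mm: np.ndarray
    tissue_names: dict[int, str]
    landmarks: dict[str, np.ndarray] = field(default_factory=dict)

    # -- bookkeeping ---------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def node_shape(self) -> tuple[int, int, int]:
        nx, ny, nz = self.labels.shape
        return (nx + 1, ny + 1, nz + 1)

    @property
    def n_nodes(self) -> int:
        nx, ny, nz = self.node_shape
        return nx * ny * nz

    def name_to_id(self) -> dict[str, int]:
        return {v: k for k, v in self.tissue_names.items()}

    def tissue_id(self, name: str, create: bool = False) -> int:
        ids = self.name_to_id()
        if name in ids:
            return ids[name]
        if not create:
            raise KeyError(f"phantom has no tissue named {name!r}")
        new_id = max(self.tissue_names, default=0) + 1
        self.tissue_names[new_id] = name
        return new_id

    def copy(self) -> "VoxelPhantom":
        return VoxelPhantom(
            labels=self.labels.copy(),
            spacing_mm=self.spacing_mm,
            origin_mm=self.origin_mm.copy(),
            tissue_names=dict(self.tissue_names),
            landmarks={k: v.copy() for k, v in self.landmarks.items()},
        )

    # -- geometry ------------------------------------------------------
    def voxel_centers(self, idx: np.ndarray | None = None) -> np.ndarray:
        """Centers (mm) of all voxels, or of the given (n, 3) multi-indices."""
        if idx is None:
            grids = np.meshgrid(
                *[np.arange(n) for n in self.shape], indexing="ij"
            )
            idx = np.stack([g.ravel() for g in grids], axis=1)
        return self.origin_mm + (np.asarray(idx, dtype=float) + 0.5) * self.spacing_mm

    def centers_of_ravel(self, ravel_idx: np.ndarray) -> np.ndarray:
        idx = np.stack(np.unravel_index(ravel_idx, self.shape), axis=1)
        return self.voxel_centers(idx)

    def node_coords(self, node_ids: np.ndarray) -> np.ndarray:
        idx = np.stack(np.unravel_index(node_ids, self.node_shape), axis=1)
        return self.origin_mm + idx * self.spacing_mm

    def voxel_node_ids(self, vox_multi: np.ndarray) -> np.ndarray:
        """(n, 8) global node ids of each voxel's corners.

        Corner order: x fastest sign, then y, then z —
        (0,0,0),(1,0,0),(0,1,0),(1,1,0),(0,0,1),(1,0,1),(0,1,1),(1,1,1).
        """
        offsets = np.array(
            [
                [0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0],
                [0, 0, 1], [1, 0, 1], [0, 1, 1], [1, 1, 1],
            ],
            dtype=np.int64,
        )
        corners = vox_multi[:, None, :] + offsets[None, :, :]
        return np.ravel_multi_index(
            (corners[..., 0], corners[..., 1], corners[..., 2]), self.node_shape
        )

    def outer_surface_mask(self) -> np.ndarray:
        """Conducting voxels with at least one face exposed to air (or grid edge)."""
        lab = self.labels
        cond = lab != AIR
        exposed = np.zeros_like(cond)
        padded = np.pad(lab, 1, constant_values=AIR)
        for d in _FACE_DIRS:
            nb = padded[
                1 + d[0] : lab.shape[0] + 1 + d[0],
                1 + d[1] : lab.shape[1] + 1 + d[1],
                1 + d[2] : lab.shape[2] + 1 + d[2],
            ]
            exposed |= cond & (nb == AIR)
        return exposed


# ---------------------------------------------------------------------------
# Conductivities
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConductivityTable:
    """Tissue name -> conductivity (S/m), with aliases for merged tissues.

    ``MODEL1`` is the coarse-eye preset (single homogeneous eye including the
    optic nerve); ``MODEL2`` the compartmental-eye preset.  Aliases let one
    phantom be solved under either preset: e.g. under MODEL1 every eye
    compartment resolves to the merged 0.4 S/m eye conductivity.
    """

    name: str
    sigma: dict[str, float]
    aliases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for tissue, s in self.sigma.items():
            if not s > 0:
                raise ValueError(f"conductivity for {tissue!r} must be > 0, got {s}")

    def sigma_for(self, tissue: str) -> float:
        t = self.aliases.get(tissue, tissue)
        if t not in self.sigma:
            raise KeyError(
                f"conductivity table {self.name!r} has no entry (or alias) for "
                f"tissue {tissue!r}"
            )
        return self.sigma[t]

    def for_phantom(self, phantom: VoxelPhantom) -> np.ndarray:
        """Per-label-id conductivity array (index = label id, air = 0)."""
        out = np.zeros(max(phantom.tissue_names, default=0) + 1)
        present = np.unique(phantom.labels)
        for lid in present:
            if lid == AIR:
                continue
            out[lid] = self.sigma_for(phantom.tissue_names[int(lid)])
        return out

    def with_sigma(self, **overrides: float) -> "ConductivityTable":
        sig = dict(self.sigma)
        sig.update(overrides)
        return replace(self, sigma=sig)


_EYE_COMPARTMENTS = (
    "vitreous_humor", "lens", "aqueous_humor", "retina", "sclera", "cornea",
)

MODEL1 = ConductivityTable(
    name="MODEL1",
    sigma={
        "scalp": 0.43,
        "csf": 1.79,
        "brain": 0.33,
        "skull": 0.01,
        "electrode": 1.5,
        "eye": 0.4,  # whole eye including optic nerve
        "orbit": 0.43,  # orbital cavity stand-in, scalp-like
    },
    aliases={
        **{t: "eye" for t in _EYE_COMPARTMENTS},
        "optic_nerve": "eye",
        "white_matter": "brain",
        "gray_matter": "brain",
        "muscle": "scalp",
        "fat": "scalp",
    },
)

MODEL2 = ConductivityTable(
    name="MODEL2",
    sigma={
        "white_matter": 0.14,
        "gray_matter": 0.33,
        "csf": 1.79,
        "skull": 0.014,
        "scalp": 0.33,
        "vitreous_humor": 1.55,
        "lens": 0.32,
        "aqueous_humor": 1.8,
        "retina": 0.7,
        "sclera": 0.56,
        "cornea": 0.5,
        "optic_nerve": 0.03,
        "muscle": 0.35,
        "fat": 0.04,
        "electrode": 1.4,
        "orbit": 0.35,  # orbital cavity stand-in, muscle-like
    },
    aliases={"brain": "gray_matter"},
)


# ---------------------------------------------------------------------------
# Phantom builders
# ---------------------------------------------------------------------------


def _symmetric_grid(extent_mm: np.ndarray, spacing_mm: float):
    """Grid sizes/origin for a box [-ex, ex] x [-ey, ey] x [zmin, zmax].

    x and y are symmetric about 0 (so the midsagittal plane is a node plane);
    z is given as (zmin, zmax).  All extents are rounded up to whole voxels.
    """
    ex, ey, zmin, zmax = extent_mm
    h = spacing_mm
    nxh = int(math.ceil(ex / h))
    nyh = int(math.ceil(ey / h))
    nzlo = int(math.ceil(-zmin / h))
    nzhi = int(math.ceil(zmax / h))
    shape = (2 * nxh, 2 * nyh, nzlo + nzhi)
    origin = np.array([-nxh * h, -nyh * h, -nzlo * h])
    return shape, origin


def build_layered_head(
    radii_mm,
    tissues,
    spacing_mm: float = 2.0,
) -> VoxelPhantom:
    """Concentric spherical shells, outermost first, centered at the origin.

    ``tissues[i]`` fills the shell between ``radii_mm[i]`` and
    ``radii_mm[i+1]``; the last tissue fills the innermost ball.
    """
    radii = [float(r) for r in radii_mm]
    tissues = list(tissues)
    if len(radii) != len(tissues):
        raise ValueError("need one tissue per radius")
    if any(r2 >= r1 for r1, r2 in zip(radii, radii[1:])):
        raise ValueError("radii must be strictly decreasing (outer to inner)")
    for i, (r1, r2) in enumerate(zip(radii, radii[1:])):
        if r1 - r2 < spacing_mm:
            raise ValueError(
                f"shell {tissues[i]!r} ({r2}-{r1} mm) is thinner than one "
                f"voxel at spacing {spacing_mm} mm"
            )

    R = radii[0]
    shape, origin = _symmetric_grid(np.array([R, R, -R, R]), spacing_mm)
    labels = np.zeros(shape, dtype=np.int16)
    tissue_names = {i + 1: t for i, t in enumerate(tissues)}

    ph = VoxelPhantom(labels, spacing_mm, origin, tissue_names)
    centers = ph.voxel_centers()
    r = np.linalg.norm(centers, axis=1).reshape(shape)
    # innermost ball first, then overwrite nothing: assign from outside in
    lab = np.zeros(shape, dtype=np.int16)
    for i, tissue in enumerate(tissues):
        outer = radii[i]
        inner = radii[i + 1] if i + 1 < len(radii) else 0.0
        lab[(r <= outer) & (r > inner)] = i + 1
    if len(radii) == 1:
        lab[r <= radii[0]] = 1
    ph.labels = lab
    return ph


def carve_orbit(phantom: VoxelPhantom, center_mm, radius_mm: float) -> None:
    """Relabel all non-air voxels within ``radius_mm`` of ``center_mm`` as orbit.

    This opens an orbital cavity through scalp/skull/CSF/brain so an eye can
    be embedded without intersecting the skull.  Mutates the phantom.
    """
    oid = phantom.tissue_id("orbit", create=True)
    centers = phantom.voxel_centers()
    d = np.linalg.norm(centers - np.asarray(center_mm, float), axis=1)
    mask = (d <= radius_mm).reshape(phantom.shape) & (phantom.labels != AIR)
    phantom.labels[mask] = oid


def embed_eyes(
    phantom: VoxelPhantom,
    eye_center_mm=DEFAULT_EYE_CENTER_MM,
    eye_radius_mm: float = DEFAULT_EYE_RADIUS_MM,
    optic_axis=None,
    lens_radius_mm: float = 4.0,
    cornea_half_angle_deg: float = 45.0,
    nerve_radius_mm: float = 2.5,
    nerve_length_mm: float = 18.0,
) -> VoxelPhantom:
    """Embed a mirror-symmetric pair of compartmental eyes (mutates phantom).

    ``eye_center_mm`` is the right-eye center (x > 0); the left eye is its
    reflection through the midsagittal plane.  Each eye is a sphere whose
    outer element layer is sclera, except the anterior cap (cornea) and the
    posterior semi-shell (retina); the interior holds lens, aqueous humor and
    vitreous humor, and an optic-nerve cylinder runs from the posterior pole
    toward the brain, carving the optic canal (and the optic disc out of the
    retina) on its way.

    ``optic_axis=None`` (default) points each eye radially outward through
    its own center — on a spherical head that is where the overlying scalp
    opening sits, so the cornea faces the surface and the optic nerve leaves
    toward the head center.  Pass an explicit unit vector (e.g. straight
    anterior gaze) to override.
    """
    c_right = np.asarray(eye_center_mm, dtype=float)
    if c_right[0] <= 0:
        raise ValueError("right-eye center must have x > 0")
    if optic_axis is None:
        axis = c_right / np.linalg.norm(c_right)
    else:
        axis = np.asarray(optic_axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
    h = phantom.spacing_mm

    centers = phantom.voxel_centers()
    lab = phantom.labels
    shape = phantom.shape

    skull_ids = [i for i, n in phantom.tissue_names.items() if n == "skull"]

    tid = {
        name: phantom.tissue_id(name, create=True)
        for name in (*_EYE_COMPARTMENTS, "optic_nerve")
    }

    for side_sign in (1.0, -1.0):
        c = c_right * np.array([side_sign, 1.0, 1.0])
        a = axis * np.array([side_sign, 1.0, 1.0]) if axis[0] != 0 else axis
        d = centers - c
        dist = np.linalg.norm(d, axis=1)
        in_eye = (dist <= eye_radius_mm).reshape(shape)
        if not in_eye.any():
            raise ValueError("eye sphere contains no voxels at this spacing")
        region = lab[in_eye]
        if np.isin(region, skull_ids).any():
            raise ValueError("eye sphere intersects the skull; carve an orbit first")
        if (region == AIR).any():
            raise ValueError("eye sphere pokes through the outer surface into air")

        # outer element layer of the eye sphere
        pad = np.pad(in_eye, 1, constant_values=False)
        interior = np.ones(shape, dtype=bool)
        for dd in _FACE_DIRS:
            nb = pad[
                1 + dd[0] : shape[0] + 1 + dd[0],
                1 + dd[1] : shape[1] + 1 + dd[1],
                1 + dd[2] : shape[2] + 1 + dd[2],
            ]
            interior &= nb
        outer = in_eye & ~interior
        inner = in_eye & interior

        along = (d @ a).reshape(shape)  # signed position along the optic axis
        cosang = np.divide(
            (d @ a), dist, out=np.zeros_like(dist), where=dist > 0
        ).reshape(shape)
        cornea = outer & (cosang >= math.cos(math.radians(cornea_half_angle_deg)))
        retina = outer & (along <= 0) & ~cornea
        sclera = outer & ~cornea & ~retina

        lens_c = c + lens_radius_mm * 1.25 * a
        in_lens = (
            np.linalg.norm(centers - lens_c, axis=1) <= lens_radius_mm
        ).reshape(shape) & inner
        aqueous = inner & ~in_lens & (along > lens_radius_mm * 1.25)
        vitreous = inner & ~in_lens & ~aqueous

        lab[sclera] = tid["sclera"]
        lab[cornea] = tid["cornea"]
        lab[retina] = tid["retina"]
        lab[in_lens] = tid["lens"]
        lab[aqueous] = tid["aqueous_humor"]
        lab[vitreous] = tid["vitreous_humor"]

        # optic nerve: cylinder from the posterior pole toward the head center
        pole = c - eye_radius_mm * a
        ndir = -pole / np.linalg.norm(pole)
        t = np.clip((centers - pole) @ ndir, 0.0, nerve_length_mm)
        closest = pole + t[:, None] * ndir
        near_nerve = (
            np.linalg.norm(centers - closest, axis=1) <= nerve_radius_mm
        ).reshape(shape)
        keep_interior = (dist <= eye_radius_mm - h).reshape(shape)
        nerve = near_nerve & ~keep_interior & (lab != AIR)
        lab[nerve] = tid["optic_nerve"]

        side = "right" if side_sign > 0 else "left"
        phantom.landmarks[f"{side}_eye_center"] = c.copy()
        phantom.landmarks[f"{side}_eye_axis"] = a.copy()
    phantom.landmarks["eye_radius_mm"] = np.array([eye_radius_mm])
    return phantom


def seal_orbit_posterior(
    phantom: VoxelPhantom,
    eye_center_mm,
    skull_outer_radius_mm: float,
    floor_margin_mm: float = 12.0,
    sleeve_mm: float = 4.0,
) -> None:
    """Rebuild the bony/sinus floor beneath each eye (mutates the phantom).

    Carving the orbital cavity opens a wide soft-tissue channel through the
    skull shell, and because the eyeball itself is large and highly
    conductive it would otherwise act as a low-resistance window straight
    through the skull: every montage then funnels its trans-skull current
    through the retina and distant montages acquire unphysically large
    retinal current densities.  In a real head the orbit rests on bone and
    air-filled sinuses, so deep current cannot take that shortcut.

    The seal relabels as skull every non-eye, non-nerve voxel within
    ``eye radius + floor_margin_mm`` of an eye center whose own radius is
    at or below ``skull_outer_radius_mm``, except for a thin soft sleeve
    (``sleeve_mm``) hugging the superficial hemisphere of the eyeball — the
    conjunctiva/lid tissue that connects the eye to the scalp.  Each eye
    ends up bone-encased below that sleeve, pierced only by the optic-nerve
    canal (labeled before this call, hence preserved), so the only way in
    or out of the orbit is through the scalp-side opening.
    """
    names = phantom.name_to_id()
    if "skull" not in names:
        return
    skull_id = names["skull"]
    protected = {
        names[t]
        for t in (*_EYE_COMPARTMENTS, "optic_nerve")
        if t in names
    }
    protected.add(AIR)
    centers = phantom.voxel_centers()
    r = np.linalg.norm(centers, axis=1).reshape(phantom.shape)
    eye_r = float(phantom.landmarks.get("eye_radius_mm", [DEFAULT_EYE_RADIUS_MM])[0])
    seal_r = eye_r + floor_margin_mm
    c_right = np.asarray(eye_center_mm, float)
    for sx in (1.0, -1.0):
        c = c_right * np.array([sx, 1.0, 1.0])
        u = c / np.linalg.norm(c)  # superficial (radial) direction
        d = np.linalg.norm(centers - c, axis=1).reshape(phantom.shape)
        near = d <= seal_r
        sleeve = (
            (d <= eye_r + sleeve_mm)
            & (((centers - c) @ u) > 0).reshape(phantom.shape)
        )
        mask = (
            near
            & (r <= skull_outer_radius_mm)
            & ~sleeve
            & ~np.isin(phantom.labels, list(protected))
        )
        phantom.labels[mask] = skull_id


def attach_torso(
    phantom: VoxelPhantom,
    length_mm: float = 120.0,
    radius_mm: float = 100.0,
    neck_radius_mm: float = 35.0,
) -> VoxelPhantom:
    """Attach a homogeneous scalp-conductivity torso cylinder below the head.

    Returns a new, larger phantom; ``length_mm = 0`` returns an unchanged
    copy.  A neck cylinder overlaps the head sphere so the conducting domain
    stays a single connected component; the right-shoulder electrode point
    ``rS`` is recorded as a landmark on the lateral torso surface.
    """
    if length_mm == 0:
        return phantom.copy()
    if length_mm < 0:
        raise ValueError("torso length must be >= 0")
    h = phantom.spacing_mm
    old = phantom
    head_r = float(np.abs(old.origin_mm).max())

    # head sphere reaches z = -sqrt(R^2 - neck_r^2) at the neck radius
    zmax_old = old.origin_mm[2] + old.shape[2] * h
    neck_top = -math.sqrt(max(head_r**2 - neck_radius_mm**2, 0.0)) + 2 * h
    torso_top = old.origin_mm[2] - 2 * h
    torso_bottom = torso_top - length_mm

    ex = max(-old.origin_mm[0], radius_mm) + h
    ey = max(-old.origin_mm[1], radius_mm) + h
    shape, origin = _symmetric_grid(
        np.array([ex, ey, torso_bottom, zmax_old]), h
    )
    labels = np.zeros(shape, dtype=np.int16)
    new = VoxelPhantom(labels, h, origin, dict(old.tissue_names), dict(old.landmarks))

    # copy old labels into the new grid (offsets are whole voxels by construction)
    off = np.rint((old.origin_mm - origin) / h).astype(int)
    if not np.allclose(old.origin_mm, origin + off * h, atol=1e-9):
        raise RuntimeError("grid extension is not voxel-aligned")
    sl = tuple(slice(o, o + n) for o, n in zip(off, old.shape))
    labels[sl] = old.labels

    scalp_id = new.tissue_id("scalp")
    centers = new.voxel_centers()
    rho = np.linalg.norm(centers[:, :2], axis=1)
    z = centers[:, 2]
    neck = (rho <= neck_radius_mm) & (z <= neck_top) & (z >= torso_top - 2 * h)
    torso = (rho <= radius_mm) & (z <= torso_top) & (z >= torso_bottom)
    add = (neck | torso).reshape(shape) & (labels == AIR)
    labels[add] = scalp_id

    new.landmarks["rS"] = np.array([radius_mm, 0.0, torso_top - 0.15 * length_mm])

    if not _single_conducting_component(labels):
        raise ValueError("torso is not connected to the head")
    return new


def _single_conducting_component(labels: np.ndarray) -> bool:
    from scipy import ndimage

    _, n = ndimage.label(labels != AIR)
    return n == 1


def default_head(
    spacing_mm: float = 2.0,
    with_torso: bool = True,
    torso_length_mm: float = 120.0,
    torso_radius_mm: float = 100.0,
) -> VoxelPhantom:
    """Default full phantom: 4-shell head, orbital cavities, eyes, torso."""
    ph = build_layered_head(DEFAULT_HEAD_RADII_MM, DEFAULT_HEAD_TISSUES, spacing_mm)
    for sx in (1.0, -1.0):
        c = np.asarray(DEFAULT_EYE_CENTER_MM) * np.array([sx, 1.0, 1.0])
        carve_orbit(ph, c, DEFAULT_EYE_RADIUS_MM + ORBIT_MARGIN_MM)
    embed_eyes(ph)
    seal_orbit_posterior(ph, DEFAULT_EYE_CENTER_MM, DEFAULT_HEAD_RADII_MM[1])
    if with_torso:
        ph = attach_torso(ph, length_mm=torso_length_mm, radius_mm=torso_radius_mm)
    return ph


# ---------------------------------------------------------------------------
# Montage placement
# ---------------------------------------------------------------------------

# 10/20-style tokens as (inclination from +z, azimuth from +y toward +x), deg.
# The circumferential ring (Fp, F7/8, T, O) sits on the z = 0 equator of the
# head sphere; So is the Fp2 meridian point rotated 25 deg below the equator.
TEN_TWENTY_ANGLES: dict[str, tuple[float, float]] = {
    "Cz": (0.0, 0.0),
    "Fpz": (90.0, 0.0),
    "Fp1": (90.0, -18.0),
    "Fp2": (90.0, 18.0),
    "F7": (90.0, -54.0),
    "F8": (90.0, 54.0),
    "T3": (90.0, -90.0),
    "T4": (90.0, 90.0),
    "O1": (90.0, -162.0),
    "O2": (90.0, 162.0),
    "Oz": (90.0, 180.0),
    # suborbital (infraorbital): directly below the right orbit — the
    # default eye center's azimuth, 25 deg below the Fp-ring inclination
    "So": (115.0, 24.0),
}

NEUMANN = "NEUMANN"
COMPLETE_ELECTRODE = "COMPLETE_ELECTRODE"

STANDARD_MONTAGES = (
    "Fp2-So", "Fp2-rS", "Fp2-Cz", "Fp2-O2", "So-rS", "Cz-F8", "F7-F8",
)


@dataclass
class ElectrodePatch:
    position_label: str
    footprint_voxels: np.ndarray  # ravel indices of scalp-surface voxels
    electrolyte_voxels: np.ndarray  # ravel indices of added electrolyte voxels
    outer_nodes: np.ndarray  # node ids on the exposed electrolyte surface
    contact_faces: np.ndarray  # (m, 4) node ids of exposed electrolyte faces
    centroid_mm: np.ndarray
    area_mm2: float
    thickness_mm: float
    conductivity: float
    contact_impedance_ohm: float | None = None


@dataclass
class MontageSpec:
    """Two electrode patches and the injected current (patch A source)."""

    name: str
    patches: tuple[ElectrodePatch, ElectrodePatch]
    injected_current_A: float
    mode: str = NEUMANN

    def __post_init__(self):
        if len(self.patches) != 2:
            raise ValueError("a montage has exactly two patches")
        a, b = self.patches
        if np.intersect1d(a.footprint_voxels, b.footprint_voxels).size:
            raise ValueError("electrode patches overlap")


def _direction_for(token: str) -> np.ndarray:
    if token not in TEN_TWENTY_ANGLES:
        raise KeyError(f"unknown 10/20 position token {token!r}")
    incl, az = (math.radians(a) for a in TEN_TWENTY_ANGLES[token])
    return np.array(
        [math.sin(incl) * math.sin(az), math.sin(incl) * math.cos(az), math.cos(incl)]
    )


def _build_patch(
    phantom: VoxelPhantom,
    token: str,
    thickness_mm: float,
    conductivity: float,
    contact_impedance_ohm: float | None,
    electrode_id: int,
) -> ElectrodePatch:
    h = phantom.spacing_mm
    surf = phantom.outer_surface_mask()
    surf_idx = np.argwhere(surf)
    surf_centers = phantom.voxel_centers(surf_idx)

    if token == "rS":
        if "rS" not in phantom.landmarks:
            raise KeyError("phantom has no shoulder landmark; attach a torso first")
        target = phantom.landmarks["rS"]
        d = np.linalg.norm(surf_centers - target, axis=1)
        cand = d <= d.min() + 1e-9
    else:
        # surface voxels at the smallest angle from the head center along u;
        # ties (e.g. the four voxels around the vertex for Cz) are averaged so
        # midline electrodes stay exactly on the midsagittal plane
        u = _direction_for(token)
        norms = np.linalg.norm(surf_centers, axis=1)
        cosang = (surf_centers @ u) / np.maximum(norms, 1e-12)
        cand = cosang >= cosang.max() - 1e-12
    seed_center = surf_centers[cand].mean(axis=0)

    # patch = surface voxels within chord distance of the seed point; for a
    # patch much smaller than the local curvature radius the chord metric is
    # within ~1% of the geodesic one, and it behaves identically on the
    # spherical scalp and the cylindrical shoulder
    near = np.linalg.norm(surf_centers - seed_center, axis=1) <= PATCH_GEODESIC_RADIUS_MM
    patch_multi = surf_idx[near]
    patch_ravel = np.ravel_multi_index(tuple(patch_multi.T), phantom.shape)
    patch_set = set(map(tuple, patch_multi))

    # exposed faces of the footprint, their vector-area sum, and the centroid
    lab = phantom.labels
    area_vec = np.zeros(3)
    for d in _FACE_DIRS:
        nb = patch_multi + d
        inside = np.all((nb >= 0) & (nb < np.array(phantom.shape)), axis=1)
        exposed = ~inside
        if inside.any():
            vals = lab[tuple(nb[inside].T)]
            e2 = np.zeros(len(patch_multi), dtype=bool)
            e2[inside] = vals == AIR
            exposed = exposed | e2
        area_vec += d * (h * h) * int(exposed.sum())
    area = float(np.linalg.norm(area_vec))
    centroid = phantom.voxel_centers(patch_multi).mean(axis=0)

    # extrude electrolyte outward through exposed faces
    n_layers = max(1, int(round(thickness_mm / h)))
    elec = set()
    frontier = patch_set
    for _ in range(n_layers):
        new_frontier = set()
        for v in frontier:
            for d in _FACE_DIRS:
                w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                if any(c < 0 for c in w) or any(
                    c >= n for c, n in zip(w, phantom.shape)
                ):
                    continue
                if lab[w] == AIR and w not in elec:
                    new_frontier.add(w)
        elec |= new_frontier
        frontier = new_frontier
    if not elec:
        raise ValueError(f"electrode patch {token!r} has no room for electrolyte")
    elec_multi = np.array(sorted(elec), dtype=np.int64)
    lab[tuple(elec_multi.T)] = electrode_id
    elec_ravel = np.ravel_multi_index(elec_multi.T, phantom.shape)

    # exposed (outer) faces of the electrolyte -> contact faces & outer nodes
    faces = []
    for d in _FACE_DIRS:
        nb = elec_multi + d
        inside = np.all((nb >= 0) & (nb < np.array(phantom.shape)), axis=1)
        exposed = ~inside.copy()
        if inside.any():
            vals = lab[tuple(nb[inside].T)]
            e2 = np.zeros(len(elec_multi), dtype=bool)
            e2[inside] = vals == AIR
            exposed = exposed | e2
        for v in elec_multi[exposed]:
            faces.append(_face_nodes(phantom, v, d))
    contact_faces = np.array(faces, dtype=np.int64)
    outer_nodes = np.unique(contact_faces)

    return ElectrodePatch(
        position_label=token,
        footprint_voxels=np.sort(patch_ravel),
        electrolyte_voxels=np.sort(elec_ravel),
        outer_nodes=outer_nodes,
        contact_faces=contact_faces,
        centroid_mm=centroid,
        area_mm2=area,
        thickness_mm=thickness_mm,
        conductivity=conductivity,
        contact_impedance_ohm=contact_impedance_ohm,
    )


def _face_nodes(phantom: VoxelPhantom, vox: np.ndarray, direction: np.ndarray):
    """Node ids of the voxel face whose outward normal is ``direction``."""
    i, j, k = (int(c) for c in vox)
    axis = int(np.argmax(np.abs(direction)))
    hi = direction[axis] > 0
    ranges = []
    for ax, base in enumerate((i, j, k)):
        if ax == axis:
            ranges.append([base + 1] if hi else [base])
        else:
            ranges.append([base, base + 1])
    nodes = [
        np.ravel_multi_index((a, b, c), phantom.node_shape)
        for a in ranges[0]
        for b in ranges[1]
        for c in ranges[2]
    ]
    return nodes


def place_montage(
    phantom: VoxelPhantom,
    montage: str,
    mode: str = NEUMANN,
    current_A: float = 1e-3,
    thickness_mm: float | None = None,
    conductivity: float | None = None,
    contact_impedance_ohm: float = 10_000.0,
) -> MontageSpec:
    """Place a named two-electrode montage (e.g. ``"F7-F8"``) on the phantom.

    Mutates the phantom by labeling electrolyte voxels atop the surface.
    Mode defaults follow the two presets: Neumann injection uses a 4 mm,
    1.4 S/m electrolyte; the complete-electrode mode a 5 mm, 1.5 S/m one with
    a 10 kOhm lumped contact impedance.
    """
    if mode not in (NEUMANN, COMPLETE_ELECTRODE):
        raise ValueError(f"unknown montage mode {mode!r}")
    if thickness_mm is None:
        thickness_mm = 4.0 if mode == NEUMANN else 5.0
    if conductivity is None:
        conductivity = 1.4 if mode == NEUMANN else 1.5
    tokens = montage.split("-")
    if len(tokens) != 2:
        raise ValueError(f"montage name {montage!r} is not of the form 'A-B'")
    eid = phantom.tissue_id("electrode", create=True)
    z = contact_impedance_ohm if mode == COMPLETE_ELECTRODE else None
    if z is not None and z <= 0:
        raise ValueError("contact impedance must be positive")
    patches = tuple(
        _build_patch(phantom, tok, thickness_mm, conductivity, z, eid)
        for tok in tokens
    )
    return MontageSpec(
        name=montage, patches=patches, injected_current_A=current_A, mode=mode
    )
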