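"""Closed-form potentials for point-current injection on concentric spheres.

These Legendre-series solutions are the FEM solver's ground truth: a pair of
point electrodes (source/sink, total current I) on the outer surface of a
homogeneous or N-layer concentric sphere, insulating (pure Neumann) boundary
elsewhere.  For the homogeneous ball of radius R and conductivity σ,

    φ(r, γ) = I / (4πσR) · Σ_{l≥1} (2l+1)/l · (r/R)^l
              · [P_l(cos γ_A) − P_l(cos γ_B)],

with γ_A/γ_B the angles to the two electrodes.  The layered solution expands
each layer as A_l r^l + B_l r^{−l−1} per degree, with coefficients obtained
by a transfer-matrix recursion enforcing continuity of φ and of σ∂φ/∂r at
each interface, regularity at the center, and the surface Neumann source.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import eval_legendre

__all__ = [
    "LayeredSphereSpec",
    "homogeneous_sphere_potential",
    "nlayer_sphere_potential",
]


@dataclass
class LayeredSphereSpec:
    """Concentric-sphere geometry with two surface point electrodes.

    Radii are ordered outer→inner (mm); electrode positions are unit vectors
    (source first); ``current_A`` is the total injected current and ``order``
    the Legendre truncation degree.
    """

    radii_mm: tuple[float, ...]
    conductivities: tuple[float, ...]
    electrode_a: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    electrode_b: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, -1.0]))
    current_A: float = 1e-3
    order: int = 120
    tail_tol: float = 1e-8

    def __post_init__(self):
        r = list(self.radii_mm)
        if any(r2 >= r1 for r1, r2 in zip(r, r[1:])):
            raise ValueError("radii must be strictly decreasing")
        if len(r) != len(self.conductivities):
            raise ValueError("need one conductivity per layer")
        if any(s <= 0 for s in self.conductivities):
            raise ValueError("conductivities must be positive")
        if self.order < 1:
            raise ValueError("series order must be >= 1")
        self.electrode_a = np.asarray(self.electrode_a, float)
        self.electrode_b = np.asarray(self.electrode_b, float)
        self.electrode_a /= np.linalg.norm(self.electrode_a)
        self.electrode_b /= np.linalg.norm(self.electrode_b)


def _angles(spec: LayeredSphereSpec, pts: np.ndarray):
    r = np.linalg.norm(pts, axis=1)
    R = spec.radii_mm[0]
    if (r > R * (1 + 1e-9)).any():
        raise ValueError("evaluation points must lie inside the sphere")
    with np.errstate(invalid="ignore"):
        u = pts / np.where(r[:, None] > 0, r[:, None], 1.0)
    cos_a = np.clip(u @ spec.electrode_a, -1.0, 1.0)
    cos_b = np.clip(u @ spec.electrode_b, -1.0, 1.0)
    at_electrode = (np.isclose(r, R, rtol=1e-9) & (
        np.isclose(cos_a, 1.0, atol=1e-12) | np.isclose(cos_b, 1.0, atol=1e-12)
    ))
    if at_electrode.any():
        raise ValueError("evaluation point coincides with an electrode")
    return r, cos_a, cos_b


def homogeneous_sphere_potential(
    spec: LayeredSphereSpec, eval_points_mm: np.ndarray
) -> np.ndarray:
    """Series potential (V) of the homogeneous ball at the given points (mm)."""
    if len(spec.radii_mm) != 1:
        raise ValueError("spec must have exactly one layer")
    pts = np.atleast_2d(np.asarray(eval_points_mm, float))
    r, cos_a, cos_b = _angles(spec, pts)
    R = spec.radii_mm[0]
    sigma = spec.conductivities[0]
    x = r / R

    phi = np.zeros(len(pts))
    prefac = spec.current_A / (4.0 * np.pi * sigma * R * 1e-3)
    prev_norm = np.inf
    for l in range(1, spec.order + 1):
        term = ((2 * l + 1) / l) * x**l * (
            eval_legendre(l, cos_a) - eval_legendre(l, cos_b)
        )
        phi += term
        tnorm = np.abs(term).max()
        if tnorm < spec.tail_tol and prev_norm < spec.tail_tol:
            break
        prev_norm = tnorm
    return prefac * phi


def _layer_coefficients(spec: LayeredSphereSpec, l: int) -> np.ndarray:
    """(n_layers, 2) coefficients (A, B) for degree l, radii normalized by R.

    Built inner→outer by transfer matrices; the returned coefficients solve
    the interface continuity conditions with A_inner scaled so the outer
    Neumann condition carries unit source amplitude f_l = 1 (the caller
    multiplies by the true f_l).
    """
    radii = np.asarray(spec.radii_mm, float) / spec.radii_mm[0]
    sig = np.asarray(spec.conductivities, float)
    n = len(radii)
    coeffs = np.zeros((n, 2))
    coeffs[n - 1] = (1.0, 0.0)  # regular at the center
    for k in range(n - 1, 0, -1):
        # interface at radii[k]: inner layer k, outer layer k-1
        ri = radii[k]
        A_in, B_in = coeffs[k]
        phi_val = A_in * ri**l + B_in * ri ** (-l - 1)
        dphi_val = sig[k] * (l * A_in * ri ** (l - 1)
                             - (l + 1) * B_in * ri ** (-l - 2))
        M = np.array(
            [
                [ri**l, ri ** (-l - 1)],
                [sig[k - 1] * l * ri ** (l - 1),
                 -sig[k - 1] * (l + 1) * ri ** (-l - 2)],
            ]
        )
        try:
            coeffs[k - 1] = np.linalg.solve(M, np.array([phi_val, dphi_val]))
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"degenerate interface radius {ri}") from exc
    # outer Neumann: σ_0 dφ/dr at r=1 should equal f_l (set to 1 here)
    A0, B0 = coeffs[0]
    slope = sig[0] * (l * A0 - (l + 1) * B0)
    if slope == 0:
        raise ValueError(f"singular transfer recursion at degree {l}")
    return coeffs / slope


def nlayer_sphere_potential(
    spec: LayeredSphereSpec, eval_points_mm: np.ndarray
) -> np.ndarray:
    """Series potential (V) of the N-layer sphere at the given points (mm).

    Reduces exactly to :func:`homogeneous_sphere_potential` for one layer.
    """
    pts = np.atleast_2d(np.asarray(eval_points_mm, float))
    r, cos_a, cos_b = _angles(spec, pts)
    R_mm = spec.radii_mm[0]
    x = r / R_mm
    radii_norm = np.asarray(spec.radii_mm, float) / R_mm

    # layer index per point: first layer whose inner radius is below x
    layer = np.zeros(len(pts), dtype=int)
    for k in range(1, len(radii_norm)):
        layer[x <= radii_norm[k]] = k

    R_m = R_mm * 1e-3
    phi = np.zeros(len(pts))
    prev_norm = np.inf
    for l in range(1, spec.order + 1):
        # surface source amplitude: j(γ) = I(δ_A − δ_B)/R² expanded in P_l
        f_l = spec.current_A * (2 * l + 1) / (4.0 * np.pi * R_m**2)
        coeffs = _layer_coefficients(spec, l) * (f_l * R_m)
        A = coeffs[layer, 0]
        B = coeffs[layer, 1]
        radial = A * x**l
        bmask = (B != 0) & (x > 0)  # B = 0 in the regular innermost layer
        if bmask.any():
            radial[bmask] += B[bmask] * x[bmask] ** (-l - 1.0)
        term = radial * (eval_legendre(l, cos_a) - eval_legendre(l, cos_b))
        phi += term
        tnorm = np.abs(term).max()
        if tnorm < spec.tail_tol * max(np.abs(phi).max(), 1e-300) and \
                prev_norm < spec.tail_tol * max(np.abs(phi).max(), 1e-300):
            break
        prev_norm = tnorm
    return phi
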