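"""Quasi-static current-injection FEM on hexahedral voxel phantoms.

Each conducting voxel is a trilinear 8-node hexahedral element with isotropic
conductivity; the weak form of ∇·(σ∇φ) = 0 with Neumann current injection
yields a symmetric positive semi-definite system Kφ = b whose nullspace is
the constant potential (the gauge).  Two injection modes are supported:

* pure Neumann point loads, the injected current split equally across the
  exposed outer nodes of each electrode's electrolyte layer;
* the complete electrode model, one auxiliary potential unknown per
  electrode coupled to the exposed electrolyte faces through a contact
  impedance, with the total current per electrode constrained.

The per-element current density is J = −σ∇φ evaluated at the element center
from the trilinear shape-function gradients.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph, linalg as spla

from .phantom import (
    AIR,
    COMPLETE_ELECTRODE,
    NEUMANN,
    ConductivityTable,
    MontageSpec,
    VoxelPhantom,
)

__all__ = [
    "FEMSystem",
    "PotentialField",
    "CurrentDensityField",
    "SolveReport",
    "unit_hex_stiffness",
    "assemble_stiffness",
    "build_rhs_neumann",
    "apply_complete_electrode",
    "solve_potential",
    "current_density",
    "flux_through_cut",
    "nodes_of_elements",
    "solve_montage",
]

MM = 1e-3  # mm -> m


@lru_cache(maxsize=None)
def unit_hex_stiffness() -> np.ndarray:
    """8x8 stiffness of a unit-cube trilinear element with σ = 1.

    Computed with 2x2x2 Gauss quadrature, which integrates the (at most
    biquadratic per coordinate) integrand exactly.  Corner order matches
    ``VoxelPhantom.voxel_node_ids``.
    """
    g = 1.0 / np.sqrt(3.0)
    pts = [(-g, -g, -g), (g, -g, -g), (-g, g, -g), (g, g, -g),
           (-g, -g, g), (g, -g, g), (-g, g, g), (g, g, g)]
    # corner signs in reference coords [-1, 1]^3, x fastest
    signs = np.array(
        [[sx, sy, sz] for sz in (-1, 1) for sy in (-1, 1) for sx in (-1, 1)],
        dtype=float,
    )
    K = np.zeros((8, 8))
    for xi, eta, zeta in pts:
        q = np.array([xi, eta, zeta])
        # dN_a/dq_i in reference coords; N_a = prod_i (1 + s_ai q_i) / 2
        dN = np.empty((8, 3))
        for a in range(8):
            s = signs[a]
            for i in range(3):
                others = [j for j in range(3) if j != i]
                dN[a, i] = (
                    s[i] / 2.0
                    * np.prod([(1.0 + s[j] * q[j]) / 2.0 for j in others])
                )
        # reference cube is [-1,1]^3 -> unit cube: grad scales by 2, dV by 1/8
        K += (dN * 4.0) @ dN.T / 8.0
    return K


@dataclass
class FEMSystem:
    """Assembled stiffness restricted to nodes of conducting elements."""

    K: sparse.csr_matrix  # (n_active, n_active), SPD up to the constant gauge
    node_ids: np.ndarray  # global node id per active node
    active_of_node: np.ndarray  # global node id -> active index (-1 = inactive)
    conn: np.ndarray  # (n_elements, 8) active-node indices per element
    elem_voxels: np.ndarray  # ravel voxel index per element
    sigma_elem: np.ndarray  # S/m per element
    phantom: VoxelPhantom

    @property
    def n_active(self) -> int:
        return self.node_ids.size

    def active_index(self, global_nodes: np.ndarray) -> np.ndarray:
        act = self.active_of_node[np.asarray(global_nodes)]
        if (act < 0).any():
            raise ValueError("node set includes nodes outside the conducting mesh")
        return act


@dataclass
class SolveReport:
    iterations: int
    relative_residual: float
    injected_current_A: float
    extracted_current_A: float
    imbalance_A: float
    converged: bool

    def to_dict(self) -> dict:
        return {
            "iterations": self.iterations,
            "relative_residual": self.relative_residual,
            "injected_current_A": self.injected_current_A,
            "extracted_current_A": self.extracted_current_A,
            "imbalance_A": self.imbalance_A,
            "converged": self.converged,
        }


@dataclass
class PotentialField:
    """Node potentials (V) on the active mesh, plus any electrode unknowns."""

    node_potentials: np.ndarray  # (n_active,)
    gauge: str
    electrode_potentials: np.ndarray | None = None  # CEM auxiliary unknowns
    report: SolveReport | None = None


@dataclass
class CurrentDensityField:
    """Per-element current-density vectors and magnitudes in A/m²."""

    element_vectors: np.ndarray  # (n_elements, 3)
    element_magnitudes: np.ndarray  # (n_elements,)
    elem_voxels: np.ndarray  # ravel voxel index per element
    phantom: VoxelPhantom

    def magnitude_grid(self, unit: str = "A/m2") -> np.ndarray:
        """Dense |J| grid over all voxels (zero in air), A/m² or mA/m²."""
        out = np.zeros(self.phantom.shape).ravel()
        out[self.elem_voxels] = self.element_magnitudes
        if unit == "mA/m2":
            out = out * 1e3
        elif unit != "A/m2":
            raise ValueError(f"unknown unit {unit!r}")
        return out.reshape(self.phantom.shape)

    def magnitudes_at(self, voxel_ravel: np.ndarray, unit: str = "mA/m2") -> np.ndarray:
        lookup = np.full(int(np.prod(self.phantom.shape)), np.nan)
        lookup[self.elem_voxels] = self.element_magnitudes
        vals = lookup[np.asarray(voxel_ravel)]
        if np.isnan(vals).any():
            raise ValueError("requested voxels include non-conducting elements")
        return vals * (1e3 if unit == "mA/m2" else 1.0)


def assemble_stiffness(
    phantom: VoxelPhantom, conductivities: ConductivityTable | np.ndarray
) -> FEMSystem:
    """Assemble the global stiffness over all conducting voxels.

    ``conductivities`` may be a :class:`ConductivityTable` or a per-label-id
    array.  Raises if a present label has no conductivity.
    """
    if isinstance(conductivities, ConductivityTable):
        sigma_of_label = conductivities.for_phantom(phantom)
    else:
        sigma_of_label = np.asarray(conductivities, dtype=float)
        present = np.unique(phantom.labels)
        for lid in present:
            if lid != AIR and (
                lid >= sigma_of_label.size or not sigma_of_label[lid] > 0
            ):
                name = phantom.tissue_names.get(int(lid), str(lid))
                raise KeyError(f"no conductivity for tissue {name!r}")

    lab = phantom.labels
    elem_multi = np.argwhere(lab != AIR)
    if elem_multi.size == 0:
        raise ValueError("phantom has no conducting voxels")
    elem_voxels = np.ravel_multi_index(tuple(elem_multi.T), phantom.shape)
    sigma_elem = sigma_of_label[lab[tuple(elem_multi.T)]]

    conn_global = phantom.voxel_node_ids(elem_multi)
    node_ids = np.unique(conn_global)
    active_of_node = np.full(phantom.n_nodes, -1, dtype=np.int64)
    active_of_node[node_ids] = np.arange(node_ids.size)
    conn = active_of_node[conn_global]

    K0 = unit_hex_stiffness()
    h_m = phantom.spacing_mm * MM
    scale = sigma_elem * h_m  # σ h for an h-cube element

    conn32 = conn.astype(np.int32)
    ii, jj = np.meshgrid(np.arange(8), np.arange(8), indexing="ij")
    ii, jj = ii.ravel(), jj.ravel()
    rows = conn32[:, ii].ravel()
    cols = conn32[:, jj].ravel()
    data = (scale[:, None] * K0.ravel()[None, :]).ravel()
    n = node_ids.size
    K = sparse.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    return FEMSystem(
        K=K,
        node_ids=node_ids,
        active_of_node=active_of_node,
        conn=conn,
        elem_voxels=elem_voxels,
        sigma_elem=sigma_elem,
        phantom=phantom,
    )


def build_rhs_neumann(system: FEMSystem, montage: MontageSpec) -> np.ndarray:
    """Point-load vector: ±I split equally over each patch's outer nodes."""
    if montage.mode != NEUMANN:
        raise ValueError("montage mode is not NEUMANN")
    b = np.zeros(system.n_active)
    current = montage.injected_current_A
    for patch, sign in zip(montage.patches, (+1.0, -1.0)):
        nodes = patch.outer_nodes
        if nodes.size == 0:
            raise ValueError(f"patch {patch.position_label!r} has no outer nodes")
        act = system.active_index(nodes)
        b[act] += sign * current / nodes.size
    return b


def apply_complete_electrode(system: FEMSystem, montage: MontageSpec):
    """Augment the system with one potential unknown per electrode (CEM).

    The lumped 10 kΩ electrode impedance R is converted to a surface
    impedance z = R·A over the patch contact area A, so each exposed
    electrolyte face f couples its nodes to the electrode potential U with
    conductance a_f/z (lumped equally onto its four nodes).  The augmented
    matrix stays symmetric positive semi-definite with the all-ones
    nullspace; the right-hand side puts ±I on the two electrode unknowns.

    Returns ``(K_aug, rhs, n_nodes)``.
    """
    if montage.mode != COMPLETE_ELECTRODE:
        raise ValueError("montage mode is not COMPLETE_ELECTRODE")
    n = system.n_active
    h = system.phantom.spacing_mm
    face_area = (h * MM) ** 2

    rows, cols, data = [], [], []
    diag_e = np.zeros(2)
    for e, patch in enumerate(montage.patches):
        if patch.contact_impedance_ohm is None or patch.contact_impedance_ohm <= 0:
            raise ValueError("complete electrode model needs a positive impedance")
        area = patch.contact_faces.shape[0] * face_area
        z_surface = patch.contact_impedance_ohm * area  # Ω·m²
        g_face = face_area / z_surface  # conductance per face, S
        act_faces = system.active_index(patch.contact_faces.ravel()).reshape(-1, 4)
        g_node = g_face / 4.0
        for quad in act_faces:
            for a in quad:
                rows.append(a); cols.append(a); data.append(g_node)
                rows.append(a); cols.append(n + e); data.append(-g_node)
                rows.append(n + e); cols.append(a); data.append(-g_node)
        diag_e[e] = patch.contact_faces.shape[0] * g_face

    m = n + 2
    B = sparse.coo_matrix((data, (rows, cols)), shape=(m, m))
    D = sparse.coo_matrix((diag_e, ([n, n + 1], [n, n + 1])), shape=(m, m))
    K_aug = (
        sparse.block_diag([system.K, sparse.csr_matrix((2, 2))]) + B + D
    ).tocsr()
    rhs = np.zeros(m)
    rhs[n] = montage.injected_current_A
    rhs[n + 1] = -montage.injected_current_A
    return K_aug, rhs, n


def solve_potential(
    system: FEMSystem | sparse.spmatrix,
    rhs: np.ndarray,
    tol: float = 1e-8,
    maxiter: int = 10_000,
    gauge: str = "zero-mean",
    n_nodes: int | None = None,
) -> PotentialField:
    """Jacobi-preconditioned CG solve of the (singular, consistent) system.

    ``gauge`` is ``"zero-mean"`` (default) or ``"pin-first"``; either fixes
    the additive constant after the solve, which cannot change J.  For CEM
    systems pass the augmented matrix together with ``n_nodes`` so electrode
    unknowns are reported separately.
    """
    if isinstance(system, FEMSystem):
        K = system.K
        if n_nodes is None:
            n_nodes = system.n_active
    else:
        K = system.tocsr()
        if n_nodes is None:
            n_nodes = K.shape[0]

    bnorm = np.linalg.norm(rhs)
    if bnorm == 0:
        phi = np.zeros(K.shape[0])
        report = SolveReport(0, 0.0, 0.0, 0.0, 0.0, True)
        elec = phi[n_nodes:] if n_nodes < phi.size else None
        return PotentialField(phi[:n_nodes], gauge, elec, report)

    injected = float(rhs[rhs > 0].sum())
    extracted = float(-rhs[rhs < 0].sum())
    if abs(rhs.sum()) > 1e-10 * bnorm:
        raise ValueError("incompatible load: net injected current is nonzero")

    # a load split across disconnected components cannot be solved
    ncomp, comp = csgraph.connected_components(K, directed=False)
    if ncomp > 1:
        for c in range(ncomp):
            s = rhs[comp == c].sum()
            if abs(s) > 1e-10 * bnorm:
                raise ValueError(
                    "electrodes sit on disconnected conducting components"
                )

    diag = K.diagonal()
    diag[diag <= 0] = 1.0
    M = spla.LinearOperator(K.shape, matvec=lambda x: x / diag)
    iters = 0

    def cb(_):
        nonlocal iters
        iters += 1

    phi, info = spla.cg(K, rhs, rtol=tol, atol=0.0, maxiter=maxiter, M=M, callback=cb)
    rel = float(np.linalg.norm(K @ phi - rhs) / bnorm)
    if info != 0 or rel > 10 * tol:
        raise RuntimeError(
            f"CG did not converge: info={info}, iterations={iters}, "
            f"relative residual={rel:.3e}"
        )

    node_phi = phi[:n_nodes]
    if gauge == "zero-mean":
        shift = node_phi.mean()
    elif gauge == "pin-first":
        shift = node_phi[0]
    else:
        raise ValueError(f"unknown gauge {gauge!r}")
    phi = phi - shift

    imbalance = abs(injected - extracted)
    report = SolveReport(iters, rel, injected, extracted, imbalance, True)
    elec = phi[n_nodes:] if n_nodes < phi.size else None
    return PotentialField(phi[:n_nodes], gauge, elec, report)


def current_density(system: FEMSystem, potential: PotentialField) -> CurrentDensityField:
    """J = −σ∇φ per element, gradients from trilinear shapes at the center."""
    phi = potential.node_potentials[system.conn]  # (n_e, 8)
    h_m = system.phantom.spacing_mm * MM
    # corner order: x fastest, then y, then z
    plus_x = [1, 3, 5, 7]; minus_x = [0, 2, 4, 6]
    plus_y = [2, 3, 6, 7]; minus_y = [0, 1, 4, 5]
    plus_z = [4, 5, 6, 7]; minus_z = [0, 1, 2, 3]
    grad = np.stack(
        [
            (phi[:, px].sum(1) - phi[:, mx].sum(1)) / (4.0 * h_m)
            for px, mx in ((plus_x, minus_x), (plus_y, minus_y), (plus_z, minus_z))
        ],
        axis=1,
    )
    J = -system.sigma_elem[:, None] * grad
    return CurrentDensityField(
        element_vectors=J,
        element_magnitudes=np.linalg.norm(J, axis=1),
        elem_voxels=system.elem_voxels,
        phantom=system.phantom,
    )


def nodes_of_elements(system: FEMSystem, elem_mask: np.ndarray) -> np.ndarray:
    """Active-node indices touched by the selected elements (a node cut set)."""
    return np.unique(system.conn[np.asarray(elem_mask)])


def flux_through_cut(
    K: sparse.spmatrix | FEMSystem, phi_full: np.ndarray, node_set: np.ndarray
) -> float:
    """Net discrete current (A) flowing out of a node set.

    Exactly ``Σ_{i∈S} (Kφ)_i``: by symmetry of K and its zero row sums this
    equals the sum of branch currents crossing the cut, and at convergence
    the injected current for any set containing one electrode's load nodes.
    """
    if isinstance(K, FEMSystem):
        K = K.K
    r = K @ phi_full
    return float(r[np.asarray(node_set)].sum())


def solve_montage(
    phantom: VoxelPhantom,
    conductivities: ConductivityTable,
    montage: MontageSpec,
    tol: float = 1e-8,
    gauge: str = "zero-mean",
):
    """Assemble, load, solve and differentiate in one call.

    Returns ``(system, potential, current_density_field)``.
    """
    system = assemble_stiffness(phantom, conductivities)
    if montage.mode == NEUMANN:
        rhs = build_rhs_neumann(system, montage)
        potential = solve_potential(system, rhs, tol=tol, gauge=gauge)
    else:
        K_aug, rhs, n_nodes = apply_complete_electrode(system, montage)
        potential = solve_potential(
            K_aug, rhs, tol=tol, gauge=gauge, n_nodes=n_nodes
        )
    field = current_density(system, potential)
    return system, potential, field
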