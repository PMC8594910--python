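"""Shared fixtures; the expensive FEM solves are session-scoped."""

from __future__ import annotations

import numpy as np
import pytest

from phostim import fem_solver as fs
from phostim.analytic_oracle import LayeredSphereSpec, nlayer_sphere_potential
from phostim.phantom import MODEL2, build_layered_head, default_head, place_montage
from phostim.report import solve_all_montages
from phostim.cohort_synthesis import STANDARD_MONTAGE_ORDER

# validation sphere: conductivity triple scalp/skull/brain, shells thick
# enough to be resolved by >= 4 elements at 2 mm spacing
SPHERE_RADII = (92.0, 84.0, 76.0)
SPHERE_SIGMAS = (0.43, 0.01, 0.33)
ELECTRODE_EXCLUSION_MM = 10.0


@pytest.fixture(scope="session")
def pipeline_phantom():
    """Default full head + eyes + torso phantom at the 2 mm study resolution."""
    return default_head(spacing_mm=2.0, with_torso=True)


@pytest.fixture(scope="session")
def small_head():
    """Head-only phantom with eyes (no torso), for geometry-level tests."""
    return default_head(spacing_mm=2.0, with_torso=False)


@pytest.fixture(scope="session")
def montage_solutions(pipeline_phantom):
    """ROI summaries for all seven montages (Neumann, compartmental eye)."""
    return solve_all_montages(
        pipeline_phantom, STANDARD_MONTAGE_ORDER, MODEL2, current_A=1e-3
    )


@pytest.fixture(scope="session")
def f78_solution(pipeline_phantom):
    """Full F7-F8 solve keeping the system and fields for flux/symmetry checks."""
    ph = pipeline_phantom.copy()
    spec = place_montage(ph, "F7-F8", mode="NEUMANN", current_A=1e-3)
    system, potential, field = fs.solve_montage(ph, MODEL2, spec)
    return {
        "phantom": ph,
        "spec": spec,
        "system": system,
        "potential": potential,
        "field": field,
    }


def _sphere_fem_error(spacing_mm: float) -> float:
    """Relative L2 error of the FEM potential vs the layered-sphere series."""
    tissues = [f"layer{i}" for i in range(len(SPHERE_RADII))]
    ph = build_layered_head(SPHERE_RADII, tissues, spacing_mm)
    sigma = np.array([0.0, *SPHERE_SIGMAS])
    system = fs.assemble_stiffness(ph, sigma)
    coords = ph.node_coords(system.node_ids)

    rhs = np.zeros(system.n_active)
    electrodes = []
    for pole, sign in ((np.array([0.0, 0.0, SPHERE_RADII[0]]), +1),
                       (np.array([0.0, 0.0, -SPHERE_RADII[0]]), -1)):
        i = int(np.argmin(np.linalg.norm(coords - pole, axis=1)))
        electrodes.append(coords[i])
        rhs[i] += sign * 1e-3
    potential = fs.solve_potential(system, rhs, tol=1e-8)

    spec = LayeredSphereSpec(
        SPHERE_RADII, SPHERE_SIGMAS,
        electrode_a=electrodes[0] / np.linalg.norm(electrodes[0]),
        electrode_b=electrodes[1] / np.linalg.norm(electrodes[1]),
        current_A=1e-3, order=200,
    )
    r = np.linalg.norm(coords, axis=1)
    mask = r <= SPHERE_RADII[0]
    for e in electrodes:
        mask &= np.linalg.norm(coords - e, axis=1) > ELECTRODE_EXCLUSION_MM
    idx = np.flatnonzero(mask)[::4]  # subsample: the norm is over ~100k points
    ref = nlayer_sphere_potential(spec, coords[idx])
    fem = potential.node_potentials[idx]
    fem = fem - fem.mean() + ref.mean()  # align gauges
    return float(np.linalg.norm(fem - ref) / np.linalg.norm(ref))


@pytest.fixture(scope="session")
def sphere_comparison():
    """FEM-vs-series errors at the study resolution and one refinement."""
    return {2.0: _sphere_fem_error(2.0), 1.5: _sphere_fem_error(1.5)}
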