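"""FEM assembly, boundary conditions, solves and current density."""

import numpy as np
import pytest
from scipy import sparse

from phostim import fem_solver as fs
from phostim.phantom import VoxelPhantom, build_layered_head, place_montage


def bar_phantom(nz=10, spacing=1.0, labels=None):
    lab = np.ones((1, 1, nz), dtype=np.int16) if labels is None else labels
    names = {int(i): f"t{int(i)}" for i in np.unique(lab) if i != 0}
    return VoxelPhantom(lab, spacing, np.zeros(3), names)


def end_face_rhs(system, phantom, current=1.0):
    coords = phantom.node_coords(system.node_ids)
    zmax = coords[:, 2].max()
    b = np.zeros(system.n_active)
    for zval, sign in ((0.0, 1.0), (zmax, -1.0)):
        m = np.isclose(coords[:, 2], zval)
        b[m] += sign * current / m.sum()
    return b, coords


class TestStiffness:
    def test_unit_cube_matches_symbolic_integration(self):
        import sympy as sp

        x, y, z = sp.symbols("x y z")
        shapes = []
        for sz in (0, 1):
            for sy in (0, 1):
                for sx in (0, 1):
                    nx = x if sx else 1 - x
                    ny = y if sy else 1 - y
                    nz_ = z if sz else 1 - z
                    shapes.append(nx * ny * nz_)
        K_sym = np.zeros((8, 8))
        grads = [
            [sp.diff(N, v) for v in (x, y, z)] for N in shapes
        ]
        for a in range(8):
            for b in range(a, 8):
                integrand = sum(grads[a][i] * grads[b][i] for i in range(3))
                val = sp.integrate(
                    integrand, (x, 0, 1), (y, 0, 1), (z, 0, 1)
                )
                K_sym[a, b] = K_sym[b, a] = float(val)
        assert np.allclose(fs.unit_hex_stiffness(), K_sym, atol=1e-12)

    def test_row_sums_vanish(self):
        ph = build_layered_head([10.0], ["scalp"], 2.0)
        system = fs.assemble_stiffness(ph, np.array([0.0, 0.43]))
        assert abs(system.K.sum(axis=1)).max() < 1e-12

    def test_linear_in_conductivity(self):
        ph = bar_phantom()
        k1 = fs.assemble_stiffness(ph, np.array([0.0, 1.0])).K
        k2 = fs.assemble_stiffness(ph, np.array([0.0, 2.0])).K
        assert abs(k2 - 2 * k1).max() < 1e-14

    def test_missing_conductivity_named(self):
        ph = bar_phantom()
        with pytest.raises(KeyError, match="t1"):
            fs.assemble_stiffness(ph, np.array([0.0, 0.0]))


class TestNeumannLoad:
    def test_load_split_equally(self, small_head):
        ph = small_head.copy()
        spec = place_montage(ph, "F7-F8", current_A=1e-3)
        from phostim.phantom import MODEL2

        system = fs.assemble_stiffness(ph, MODEL2)
        b = fs.build_rhs_neumann(system, spec)
        n_a = spec.patches[0].outer_nodes.size
        assert np.isclose(b.max(), 1e-3 / n_a)
        assert abs(b.sum()) < 1e-15 * abs(b).max() * b.size
        spec.injected_current_A = 0.0
        assert not fs.build_rhs_neumann(system, spec).any()


class TestSolve:
    def test_homogeneous_bar_linear_potential(self):
        ph = bar_phantom(nz=10, spacing=1.0)
        system = fs.assemble_stiffness(ph, np.array([0.0, 1.0]))
        b, coords = end_face_rhs(system, ph, current=1.0)
        pot = fs.solve_potential(system, b, tol=1e-12)
        # series-resistor hand calculation: drop = I * L / (sigma * A)
        drop = (
            pot.node_potentials[np.isclose(coords[:, 2], 0)].mean()
            - pot.node_potentials[np.isclose(coords[:, 2], 10)].mean()
        )
        expected = 1.0 * (10e-3) / (1.0 * (1e-3) ** 2)
        assert abs(drop - expected) / expected < 1e-9
        # potential is affine in z
        fit = np.polyfit(coords[:, 2], pot.node_potentials, 1)
        resid = pot.node_potentials - np.polyval(fit, coords[:, 2])
        assert np.abs(resid).max() < 1e-9 * expected

    def test_two_layer_bar_drop_ratio(self):
        lab = np.ones((1, 1, 10), dtype=np.int16)
        lab[:, :, 5:] = 2
        ph = bar_phantom(labels=lab)
        system = fs.assemble_stiffness(ph, np.array([0.0, 1.0, 2.0]))
        b, coords = end_face_rhs(system, ph)
        pot = fs.solve_potential(system, b, tol=1e-12)

        def mean_at(z):
            return pot.node_potentials[np.isclose(coords[:, 2], z)].mean()

        drop1 = mean_at(0) - mean_at(5)
        drop2 = mean_at(5) - mean_at(10)
        assert abs(drop1 / drop2 - 2.0) < 1e-8

    def test_gauge_choice_does_not_change_current_density(self):
        ph = bar_phantom()
        system = fs.assemble_stiffness(ph, np.array([0.0, 1.0]))
        b, _ = end_face_rhs(system, ph)
        j1 = fs.current_density(
            system, fs.solve_potential(system, b, gauge="zero-mean")
        ).element_vectors
        j2 = fs.current_density(
            system, fs.solve_potential(system, b, gauge="pin-first")
        ).element_vectors
        # identical up to rounding of the constant-offset subtraction
        assert np.allclose(j1, j2, rtol=0, atol=1e-12 * np.abs(j1).max())

    def test_reciprocity_negates_solution_exactly(self):
        ph = build_layered_head([10.0], ["scalp"], 2.0)
        system = fs.assemble_stiffness(ph, np.array([0.0, 0.43]))
        coords = ph.node_coords(system.node_ids)
        b = np.zeros(system.n_active)
        top = int(np.argmax(coords[:, 2]))
        bot = int(np.argmin(coords[:, 2]))
        b[top], b[bot] = 1e-3, -1e-3
        p1 = fs.solve_potential(system, b)
        p2 = fs.solve_potential(system, -b)
        assert np.array_equal(p1.node_potentials, -p2.node_potentials)

    def test_current_density_linear_in_current(self):
        ph = build_layered_head([10.0], ["scalp"], 2.0)
        system = fs.assemble_stiffness(ph, np.array([0.0, 0.43]))
        coords = ph.node_coords(system.node_ids)
        b = np.zeros(system.n_active)
        b[int(np.argmax(coords[:, 2]))] = 1e-3
        b[int(np.argmin(coords[:, 2]))] = -1e-3
        j1 = fs.current_density(system, fs.solve_potential(system, b))
        j2 = fs.current_density(system, fs.solve_potential(system, 2 * b))
        assert np.array_equal(2 * j1.element_vectors, j2.element_vectors)

    def test_incompatible_load_rejected(self):
        ph = bar_phantom()
        system = fs.assemble_stiffness(ph, np.array([0.0, 1.0]))
        b = np.zeros(system.n_active)
        b[0] = 1.0
        with pytest.raises(ValueError, match="net injected"):
            fs.solve_potential(system, b)

    def test_disconnected_components_rejected(self):
        lab = np.zeros((2, 2, 9), dtype=np.int16)
        lab[:, :, :4] = 1
        lab[:, :, 5:] = 1  # two blocks separated by air
        ph = bar_phantom(labels=lab)
        system = fs.assemble_stiffness(ph, np.array([0.0, 1.0]))
        coords = ph.node_coords(system.node_ids)
        b = np.zeros(system.n_active)
        b[int(np.argmin(coords[:, 2]))] = 1.0
        b[int(np.argmax(coords[:, 2]))] = -1.0
        with pytest.raises(ValueError, match="disconnected"):
            fs.solve_potential(system, b)


class TestCurrentDensity:
    def test_uniform_bar_magnitude(self):
        ph = bar_phantom(nz=10, spacing=1.0)
        system = fs.assemble_stiffness(ph, np.array([0.0, 1.0]))
        b, _ = end_face_rhs(system, ph, current=1.0)
        field = fs.current_density(system, fs.solve_potential(system, b, tol=1e-12))
        expected = 1.0 / (1e-3) ** 2  # I / A
        assert np.allclose(field.element_magnitudes, expected, rtol=1e-9)

    def test_air_has_zero_density(self):
        lab = np.zeros((3, 3, 3), dtype=np.int16)
        lab[1, 1, :] = 1
        ph = bar_phantom(labels=lab)
        system = fs.assemble_stiffness(ph, np.array([0.0, 1.0]))
        b, _ = end_face_rhs(system, ph)
        field = fs.current_density(system, fs.solve_potential(system, b))
        grid = field.magnitude_grid()
        assert (grid[lab == 0] == 0).all()


class TestConservation:
    def test_bar_midplane_flux_by_element_summation(self):
        ph = bar_phantom(nz=10, spacing=1.0)
        system = fs.assemble_stiffness(ph, np.array([0.0, 1.0]))
        b, _ = end_face_rhs(system, ph, current=1.0)
        field = fs.current_density(
            system, fs.solve_potential(system, b, tol=1e-12)
        )
        # independent oracle: sum J·n over the voxel faces at the mid-plane
        # (single-column bar: one face of area h², normal +z)
        area = (1e-3) ** 2
        flux = float(field.element_vectors[5, 2]) * area
        assert abs(flux - 1.0) < 1e-8

    def test_cut_flux_equals_injected_current(self):
        ph = bar_phantom(nz=10, spacing=1.0)
        system = fs.assemble_stiffness(ph, np.array([0.0, 1.0]))
        b, coords = end_face_rhs(system, ph, current=1.0)
        pot = fs.solve_potential(system, b, tol=1e-12)
        S = np.flatnonzero(coords[:, 2] <= 4.5)
        assert abs(fs.flux_through_cut(system, pot.node_potentials, S) - 1.0) < 1e-8

    def test_source_free_region_has_zero_net_flux(self):
        ph = bar_phantom(nz=10, spacing=1.0)
        system = fs.assemble_stiffness(ph, np.array([0.0, 1.0]))
        b, coords = end_face_rhs(system, ph, current=1.0)
        pot = fs.solve_potential(system, b, tol=1e-12)
        S = np.flatnonzero((coords[:, 2] > 2.5) & (coords[:, 2] < 7.5))
        assert abs(fs.flux_through_cut(system, pot.node_potentials, S)) < 1e-6


def _shunt_reference(system, montage, current):
    """Independent equal-potential-patch solve: collapse each patch's outer
    nodes onto a single degree of freedom and inject the total current there."""
    n = system.n_active
    group = np.full(n, -1)
    for e, patch in enumerate(montage.patches):
        group[system.active_index(patch.outer_nodes)] = e
    keep = np.flatnonzero(group == -1)
    col = np.empty(n, dtype=int)
    col[keep] = np.arange(keep.size)
    col[group == 0] = keep.size
    col[group == 1] = keep.size + 1
    P = sparse.coo_matrix(
        (np.ones(n), (np.arange(n), col)), shape=(n, keep.size + 2)
    ).tocsr()
    K_red = (P.T @ system.K @ P).tocsr()
    b = np.zeros(keep.size + 2)
    b[keep.size] = current
    b[keep.size + 1] = -current
    pot = fs.solve_potential(K_red, b, tol=1e-10)
    return P @ pot.node_potentials


@pytest.fixture(scope="module")
def cem_setup():
    ph = build_layered_head([18.0], ["scalp"], 2.0)
    spec = place_montage(ph, "Fpz-Oz", mode="COMPLETE_ELECTRODE", current_A=1e-3)
    from phostim.phantom import MODEL1

    system = fs.assemble_stiffness(ph, MODEL1)
    return ph, spec, system


class TestCompleteElectrode:
    def _cem_solve(self, system, spec, impedance):
        for p in spec.patches:
            p.contact_impedance_ohm = impedance
        K_aug, rhs, n_nodes = fs.apply_complete_electrode(system, spec)
        pot = fs.solve_potential(K_aug, rhs, tol=1e-10, n_nodes=n_nodes)
        return pot, K_aug

    def test_small_impedance_approaches_equal_potential_patches(self, cem_setup):
        ph, spec, system = cem_setup
        pot, _ = self._cem_solve(system, spec, 1e-4)
        ref = _shunt_reference(system, spec, 1e-3)
        a = pot.node_potentials - pot.node_potentials.mean()
        b = ref - ref.mean()
        assert np.linalg.norm(a - b) / np.linalg.norm(b) < 0.01

    def test_large_impedance_leaves_interior_field_unchanged(self, cem_setup):
        ph, spec, system = cem_setup
        pot1, _ = self._cem_solve(system, spec, 1e4)
        pot2, _ = self._cem_solve(system, spec, 1e6)
        j1 = fs.current_density(system, pot1)
        j2 = fs.current_density(system, pot2)
        # interior: away from both electrolyte layers
        interior = np.ones(j1.element_magnitudes.size, dtype=bool)
        centers = ph.centers_of_ravel(j1.elem_voxels)
        for p in spec.patches:
            c = p.centroid_mm
            interior &= np.linalg.norm(centers - c, axis=1) > 8.0
        num = np.linalg.norm(
            j1.element_vectors[interior] - j2.element_vectors[interior]
        )
        den = np.linalg.norm(j1.element_vectors[interior])
        assert num / den < 1e-4
        # contact drop (electrode potential minus mean surface potential)
        # grows linearly with the impedance
        def drop(pot, patch_i):
            act = system.active_index(spec.patches[patch_i].outer_nodes)
            return pot.electrode_potentials[patch_i] - pot.node_potentials[act].mean()

        ratio = drop(pot2, 0) / drop(pot1, 0)
        assert abs(ratio - 100.0) / 100.0 < 1e-3

    def test_electrode_current_constrained(self, cem_setup):
        ph, spec, system = cem_setup
        pot, K_aug = self._cem_solve(system, spec, 1e4)
        phi_full = np.concatenate(
            [pot.node_potentials, pot.electrode_potentials]
        )
        n = system.n_active
        flux_a = fs.flux_through_cut(K_aug, phi_full, np.array([n]))
        flux_b = fs.flux_through_cut(K_aug, phi_full, np.array([n + 1]))
        assert abs(flux_a - 1e-3) < 1e-8 * 1e-3
        assert abs(flux_b + 1e-3) < 1e-8 * 1e-3

    def test_nonpositive_impedance_rejected(self, cem_setup):
        ph, spec, system = cem_setup
        for p in spec.patches:
            p.contact_impedance_ohm = -1.0
        with pytest.raises(ValueError, match="positive impedance"):
            fs.apply_complete_electrode(system, spec)
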