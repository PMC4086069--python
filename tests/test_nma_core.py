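import numpy as np
import pytest

from icnma import elastic_network as enm
from icnma import internal_coords as ic
from icnma import nma_core as nc

from oracles import cholesky_pencil_eigs, random_spd_pencil


class TestDenseSolver:
    def test_diagonal_pencil(self):
        modes = nc.solve_dense(np.diag([8.0, 2.0]), np.eye(2))
        assert np.allclose(modes.eigenvalues, [2.0, 8.0])
        assert np.allclose(np.abs(modes.ic_vectors), np.eye(2)[:, ::-1])

    def test_identity_pencil(self, rng):
        _, T = random_spd_pencil(6, rng)
        modes = nc.solve_dense(T, T)
        assert np.allclose(modes.eigenvalues, 1.0)

    def test_matches_cholesky_reduction_oracle(self, rng):
        H, T = random_spd_pencil(20, rng)
        modes = nc.solve_dense(H, T)
        w_ref, _ = cholesky_pencil_eigs(H, T)
        assert np.allclose(modes.eigenvalues, w_ref, atol=1e-10 * abs(w_ref).max())

    def test_t_orthonormality(self, rng):
        H, T = random_spd_pencil(15, rng)
        modes = nc.solve_dense(H, T, m=8)
        G = modes.ic_vectors.T @ T @ modes.ic_vectors
        assert np.max(np.abs(G - np.eye(8))) < 1e-8

    def test_residuals(self, rng):
        H, T = random_spd_pencil(15, rng)
        modes = nc.solve_dense(H, T, m=8)
        for k in range(8):
            x = modes.ic_vectors[:, k]
            r = H @ x - modes.eigenvalues[k] * (T @ x)
            assert np.linalg.norm(r) <= 1e-8 * np.linalg.norm(H)


class TestKrylovSolver:
    def test_agrees_with_dense_n200(self, rng):
        H, T = random_spd_pencil(200, rng)
        m = 10
        dense = nc.solve_dense(H, T, m)
        krylov = nc.solve_lowest_krylov(H, T, m)
        assert np.allclose(krylov.eigenvalues, dense.eigenvalues,
                           rtol=1e-6, atol=1e-12)
        G = krylov.ic_vectors.T @ T @ krylov.ic_vectors
        assert np.max(np.abs(G - np.eye(m))) < 1e-6

    def test_full_subspace_limit(self, rng):
        H, T = random_spd_pencil(12, rng)
        dense = nc.solve_dense(H, T)
        full = nc.solve_lowest_krylov(H, T, 12)
        assert np.allclose(full.eigenvalues, dense.eigenvalues, rtol=1e-8)

    def test_degenerate_subspace_agreement(self, rng):
        # block-degenerate pencil: lambda = 1 (x3), 4 (x3), 9 (x4)
        lam = np.repeat([1.0, 4.0, 9.0], [3, 3, 4])
        Q, _ = np.linalg.qr(rng.normal(size=(10, 10)))
        H = Q @ np.diag(lam) @ Q.T
        T = np.eye(10)
        dense = nc.solve_dense(H, T, 6)
        krylov = nc.solve_lowest_krylov(H, T, 6)
        # principal angles between the two 6-dimensional eigenspaces
        Ua, _ = np.linalg.qr(dense.ic_vectors)
        Ub, _ = np.linalg.qr(krylov.ic_vectors)
        sv = np.linalg.svd(Ua.T @ Ub, compute_uv=False)
        angles = np.arccos(np.clip(sv, -1, 1))
        assert np.max(angles) < 1e-6


class TestModesOfStructure:
    def test_no_zero_modes_with_eckart(self, helix10_nma):
        *_, modes = helix10_nma
        assert modes.eigenvalues[0] > 1e-10

    def test_cartesian_vectors_momentum_free(self, helix10_nma):
        s, _, _, system, modes = helix10_nma
        U = modes.cartesian_vectors.reshape(s.n_atoms, 3, -1)
        m = s.masses
        assert np.max(np.abs(np.einsum("i,iak->ak", m, U))) < 1e-8 * m.sum()

    def test_eigenvalue_interlacing_with_cartesian_pencil(self, helix10_nma):
        # constrained Rayleigh quotient: the lowest torsional eigenvalue is
        # >= the lowest non-rigid eigenvalue of the Cartesian (K, M) pencil
        s, net, _, system, modes = helix10_nma
        K = enm.cartesian_hessian(net, s)
        M = np.diag(np.repeat(s.masses, 3))
        w = nc.solve_dense(K, M).eigenvalues
        lowest_nonrigid = w[np.nonzero(w > 1e-8 * w.max())[0][0]]
        assert modes.eigenvalues[0] >= lowest_nonrigid - 1e-10

    def test_rotated_input_gives_same_eigenvalues(self, helix10):
        from icnma._geom import rotation_about_axis

        R = rotation_about_axis(np.array([1.0, 2.0, 0.5]), 1.1)
        rot = helix10.with_coords(helix10.coords @ R.T + np.array([3.0, -1.0, 2.0]))
        lam = []
        for s in (helix10, rot):
            net = enm.build_network(s)
            system = ic.assemble(s, net, ic.define_dofs(s))
            lam.append(nc.solve_modes(system, m=8).eigenvalues)
        assert np.allclose(lam[0], lam[1], rtol=1e-6)


class TestAnimation:
    def test_peak_rmsd_matches_requested_amplitude(self, helix10_nma):
        s, _, dofs, _, modes = helix10_nma
        settings = nc.AnimationSettings(amplitude=1.5, n_frames=8)
        frames = nc.animate_mode(s, dofs, modes, 0, settings)
        assert len(frames) == 8
        ca = s.calpha_indices()
        rmsds = [np.sqrt(((f.coords[ca] - s.coords[ca]) ** 2).sum(1).mean())
                 for f in frames]
        assert max(rmsds) == pytest.approx(1.5, rel=0.01)

    def test_small_amplitude_limit(self, helix10_nma):
        s, _, dofs, _, modes = helix10_nma
        settings = nc.AnimationSettings(amplitude=1e-6, n_frames=4)
        frames = nc.animate_mode(s, dofs, modes, 0, settings)
        for f in frames:
            assert np.max(np.abs(f.coords - s.coords)) < 1e-4

    def test_bond_lengths_preserved_in_all_frames(self, helix10_nma):
        s, _, dofs, _, modes = helix10_nma
        frames = nc.animate_mode(s, dofs, modes, 1,
                                 nc.AnimationSettings(amplitude=3.0, n_frames=6))
        i, j = np.array(enm.bonds(s)).T
        ref = np.linalg.norm(s.coords[i] - s.coords[j], axis=1)
        for f in frames:
            d = np.linalg.norm(f.coords[i] - f.coords[j], axis=1)
            assert np.max(np.abs(d - ref)) < 1e-9


def test_nmd_export(helix10_nma, tmp_path):
    s, *_, modes = helix10_nma
    path = tmp_path / "modes.nmd"
    nc.write_nmd(s, modes, path)
    lines = path.read_text().splitlines()
    assert lines[0].startswith("title")
    coords = [ln for ln in lines if ln.startswith("coordinates")]
    assert len(coords) == 1 and len(coords[0].split()) == 1 + 3 * s.n_atoms
    assert sum(ln.startswith("mode ") for ln in lines) == modes.n_modes
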