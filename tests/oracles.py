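"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own linear-algebra paths: the
Hessian oracle differentiates the spring energy numerically, the
eigenproblem oracle reduces the pencil by an explicit Cholesky factor, and
the superposition oracle uses the quaternion eigenvector method.
"""

import numpy as np

from icnma.elastic_network import network_energy


def fd_hessian(net, coords, h=1e-5):
    """Central-difference Hessian of the spring energy."""
    x0 = np.asarray(coords, float).ravel().copy()
    n = len(x0)
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            xpp = x0.copy(); xpp[i] += h; xpp[j] += h
            xpm = x0.copy(); xpm[i] += h; xpm[j] -= h
            xmp = x0.copy(); xmp[i] -= h; xmp[j] += h
            xmm = x0.copy(); xmm[i] -= h; xmm[j] -= h
            H[i, j] = H[j, i] = (
                network_energy(net, xpp) - network_energy(net, xpm)
                - network_energy(net, xmp) + network_energy(net, xmm)
            ) / (4 * h * h)
    return H


def fd_jacobian_eckart(s, dofs, h=1e-6):
    """Central-difference d r / d q with the same frame convention as the
    analytic Jacobian (mass-weighted superposition onto the reference)."""
    from icnma.internal_coords import free_dofs, rebuild_cartesian

    free = free_dofs(dofs)
    J = np.zeros((3 * s.n_atoms, len(free)))
    for k in range(len(free)):
        dq = np.zeros(len(free))
        dq[k] = h
        rp = rebuild_cartesian(s, dofs, dq).coords
        dq[k] = -h
        rm = rebuild_cartesian(s, dofs, dq).coords
        J[:, k] = ((rp - rm) / (2 * h)).ravel()
    return J


def cholesky_pencil_eigs(H, T):
    """Reduce H x = lambda T x to a standard problem via T = L L^T."""
    L = np.linalg.cholesky(T)
    Linv = np.linalg.inv(L)
    A = Linv @ H @ Linv.T
    w, Y = np.linalg.eigh(0.5 * (A + A.T))
    X = Linv.T @ Y
    return w, X


def quaternion_superpose(mobile, ref):
    """Optimal rigid superposition via the Horn quaternion method."""
    mobile = np.asarray(mobile, float)
    ref = np.asarray(ref, float)
    mc = mobile.mean(axis=0)
    rc = ref.mean(axis=0)
    P = mobile - mc
    Q = ref - rc
    S = P.T @ Q
    K = np.array([
        [S[0, 0] + S[1, 1] + S[2, 2], S[1, 2] - S[2, 1], S[2, 0] - S[0, 2], S[0, 1] - S[1, 0]],
        [S[1, 2] - S[2, 1], S[0, 0] - S[1, 1] - S[2, 2], S[0, 1] + S[1, 0], S[0, 2] + S[2, 0]],
        [S[2, 0] - S[0, 2], S[0, 1] + S[1, 0], -S[0, 0] + S[1, 1] - S[2, 2], S[1, 2] + S[2, 1]],
        [S[0, 1] - S[1, 0], S[0, 2] + S[2, 0], S[1, 2] + S[2, 1], -S[0, 0] - S[1, 1] + S[2, 2]],
    ])
    w, V = np.linalg.eigh(K)
    q = V[:, -1]
    q0, q1, q2, q3 = q
    R = np.array([
        [q0**2 + q1**2 - q2**2 - q3**2, 2 * (q1 * q2 - q0 * q3), 2 * (q1 * q3 + q0 * q2)],
        [2 * (q1 * q2 + q0 * q3), q0**2 - q1**2 + q2**2 - q3**2, 2 * (q2 * q3 - q0 * q1)],
        [2 * (q1 * q3 - q0 * q2), 2 * (q2 * q3 + q0 * q1), q0**2 - q1**2 - q2**2 + q3**2],
    ])
    t = rc - R @ mc
    resid = mobile @ R.T + t - ref
    rmsd = float(np.sqrt((resid**2).sum(axis=1).mean()))
    return R, t, rmsd


def affine_normal_equations(coords, disp):
    """Direct normal-equations least squares for u ~ A r + t."""
    D = np.hstack([coords, np.ones((len(coords), 1))])
    sol = np.linalg.solve(D.T @ D, D.T @ disp)
    return sol[:3].T, sol[3]


def random_spd_pencil(n, rng):
    """Random symmetric PSD H with symmetric PD T."""
    A = rng.normal(size=(n, n))
    H = A @ A.T / n
    B = rng.normal(size=(n, n))
    T = B @ B.T / n + np.eye(n)
    return H, T
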