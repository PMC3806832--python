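"""Independent numerical oracles used by the test suite.

These deliberately avoid the implementation's code paths: the radial
finite-difference solver integrates the per-degree conduction ODE directly,
and the brute-force beamformer uses generic dense solvers voxel by voxel.
"""

import numpy as np
from scipy.linalg import solve_banded


def fdm_radial_gain(n, radii, conductivities, b, n_points=20000):
    """Per-degree radial gain of the multishell conductor by finite
    differences.

    Solves d/du (sigma(u) u^2 v') = sigma(u) n(n+1) v on [u_a, 1] (radii
    normalized to the outermost), with a Robin condition at u_a encoding the
    unit degree-n source at normalized depth ``b`` and zero radial current
    at the surface.  Returns v(1), comparable to the analytic shell gain
    times b^(n-1).
    """
    radii = np.asarray(radii, float) / radii[-1]
    u_a = 0.5 * (b + radii[0])
    u = np.linspace(u_a, 1.0, n_points)
    h = u[1] - u[0]

    def sigma_of(uv):
        return conductivities[np.searchsorted(radii, uv, side="left").clip(
            0, len(conductivities) - 1)]

    # conservative discretization: fluxes at midpoints
    u_half = 0.5 * (u[1:] + u[:-1])
    k_half = sigma_of(u_half) * u_half ** 2
    sig_u = sigma_of(u)

    # ODE: (k v')' - sigma n(n+1) v = 0 with k = sigma u^2
    N = n_points
    lower = np.zeros(N)
    diag = np.zeros(N)
    upper = np.zeros(N)
    rhs = np.zeros(N)
    for i in range(1, N - 1):
        lower[i - 1] = k_half[i - 1] / h ** 2
        upper[i + 1] = k_half[i] / h ** 2
        diag[i] = -(k_half[i - 1] + k_half[i]) / h ** 2 - sig_u[i] * n * (n + 1)
    # inner Robin: v' - (n/u_a) v = -(2n+1) * u_a^(-(n+2)) * b^(n-1)
    c_src = (2 * n + 1) * u_a ** (-(n + 2)) * b ** (n - 1)
    diag[0] = -1.0 / h - n / u_a
    upper[1] = 1.0 / h
    rhs[0] = -c_src
    # outer Neumann: v'(1) = 0
    diag[N - 1] = 1.0 / h
    lower[N - 2] = -1.0 / h
    rhs[N - 1] = 0.0

    ab = np.zeros((3, N))
    ab[0, 1:] = upper[1:]
    ab[1, :] = diag
    ab[2, :-1] = lower[:-1]
    v = solve_banded((1, 1), ab, rhs)
    return v[-1]


def analytic_radial_value(n, model, b):
    """Analytic counterpart of :func:`fdm_radial_gain` via the shell gains."""
    from ictalnet.forward import _shell_gains

    g = _shell_gains(model, n)[n - 1]
    return g * b ** (n - 1)


def brute_force_power_map(leadfield, csd_matrix, alpha):
    """Per-voxel LCMV power with generic dense solves, no vectorization."""
    C = np.asarray(csd_matrix, complex)
    E = C.shape[0]
    Cr = C.real + alpha * np.mean(np.diag(C.real)) * np.eye(E)
    out = np.empty(len(leadfield.grid))
    for v in range(len(leadfield.grid)):
        L = leadfield.matrices[v]
        Ci_L = np.linalg.solve(Cr, L)
        G = L.T @ Ci_L
        A = np.linalg.solve(G, Ci_L.T)
        H = A @ C @ A.conj().T
        out[v] = np.linalg.eigvalsh(0.5 * (H + H.conj().T))[-1].real
    return out
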