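"""Independent numerical oracles used by the test suite.

The diffusion oracle never calls the package's series evaluation: it evolves
the post-bleach concentration field under the 2-D diffusion equation with a
Crank-Nicolson finite-difference scheme on a radial grid (the problem is
radially symmetric) and integrates the field against the monitoring Gaussian.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import diags, identity
from scipy.sparse.linalg import splu


def pde_recovery_curve(
    K: float,
    D: float,
    w: float,
    t_eval: np.ndarray,
    r_max_factor: float = 30.0,
    dr_factor: float = 1.0 / 40.0,
    dt_factor: float = 1.0 / 800.0,
) -> np.ndarray:
    """Fractional recovery f(t) from a finite-difference solution of dc/dt = D lap c.

    Initial condition c(r, 0) = exp(-K exp(-2 r^2 / w^2)), far field c = 1.
    The observed signal is the concentration integrated against the
    monitoring profile exp(-2 r^2 / w^2), normalized to the pre-bleach level.
    """
    tau_d = w * w / (4.0 * D)
    dr = w * dr_factor
    M = int(round(r_max_factor * w / dr))
    r = (np.arange(M) + 0.5) * dr  # cell centers; Neumann at r=0 by construction
    dt = tau_d * dt_factor

    # flux-form radial Laplacian, tridiagonal
    r_ph = r + 0.5 * dr
    r_mh = r - 0.5 * dr
    lower = r_mh[1:] / (r[1:] * dr * dr)
    upper = r_ph[:-1] / (r[:-1] * dr * dr)
    main = -(r_ph + np.where(np.arange(M) == 0, 0.0, r_mh)) / (r * dr * dr)
    A = diags([lower, main, upper], offsets=[-1, 0, 1], format="csc")
    # Dirichlet c = 1 beyond the outer cell enters as a constant source
    b_dirichlet = np.zeros(M)
    b_dirichlet[-1] = r_ph[-1] / (r[-1] * dr * dr)

    lam = D * dt
    I = identity(M, format="csc")
    lhs = splu((I - 0.5 * lam * A).tocsc())
    rhs_mat = (I + 0.5 * lam * A).tocsc()

    G = np.exp(-2.0 * r * r / (w * w))
    norm = float(np.sum(G * r))  # pre-bleach signal (uniform c = 1)

    c = np.exp(-K * G)
    t_eval = np.asarray(t_eval, dtype=float)
    out = np.empty(t_eval.size)
    order = np.argsort(t_eval)
    t_now = 0.0
    for idx in order:
        target = t_eval[idx]
        n_steps = int(round((target - t_now) / dt))
        for _ in range(n_steps):
            c = lhs.solve(rhs_mat @ c + lam * b_dirichlet)
        t_now += n_steps * dt
        out[idx] = float(np.sum(c * G * r)) / norm
    return out
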