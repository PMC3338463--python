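"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's optimizers: sphere fitting is checked
against a grid search over centers, dipole fitting against an exhaustive
position grid with local polish, and source waveforms against explicitly
assembled normal equations.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

from vepmap.forward_model import HeadModel, leadfield


def grid_sphere(points: np.ndarray, center_guess: np.ndarray, half: float = 3.0,
                step: float = 0.5) -> tuple[np.ndarray, float]:
    """Grid search over sphere centers; radius closed-form per center."""
    best = (np.inf, None, None)
    grid = np.arange(-half, half + step / 2, step)
    for dx in grid:
        for dy in grid:
            for dz in grid:
                c = center_guess + np.array([dx, dy, dz])
                d = np.linalg.norm(points - c, axis=1)
                r = d.mean()  # least-squares radius for fixed center
                sse = np.sum((d - r) ** 2)
                if sse < best[0]:
                    best = (sse, c, r)
    return best[1], best[2]


def _avg_ref(x):
    return x - x.mean(axis=0, keepdims=True)


def _cost_at(pos, D, Gp, head, montage, rv_weight=0.8):
    """Compound cost via plain normal equations (no shared optimizer code)."""
    L = _avg_ref(leadfield(head, montage, pos, check_convergence=False).gains)
    # best orientation by scanning the 3D moment subspace directly:
    # solve for full 3-vector moment series, then take dominant direction
    X = np.column_stack([Gp, L])
    W, *_ = np.linalg.lstsq(X, D, rcond=None)
    M = W[Gp.shape[1]:]  # (3, T) free-moment series
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    u = U[:, 0]
    G = np.column_stack([Gp, L @ u])
    Wc, *_ = np.linalg.lstsq(G, D, rcond=None)
    resid = D - G @ Wc
    dp = np.sum(D**2)
    rv = 100 * np.sum(resid**2) / dp
    g2 = np.sum(G**2, axis=0)
    individual = np.sum(g2 * np.sum(Wc**2, axis=1))
    radiated = np.sum((G @ Wc) ** 2)
    en = 100 * max(0.0, individual - radiated) / dp
    return rv_weight * rv + (1 - rv_weight) * en


def grid_fit_dipole(
    D: np.ndarray,
    head: HeadModel,
    montage,
    priors_gains: np.ndarray | None = None,
    coarse_step: float = 6.0,
    fine_step: float = 2.0,
) -> np.ndarray:
    """Exhaustive posterior-volume grid + local refinement.

    Returns the compound-cost-minimizing position.  ``D`` must already be
    average-referenced.
    """
    Gp = priors_gains if priors_gains is not None else np.zeros((D.shape[0], 0))
    rmax = 0.88 * head.brain_radius
    best = (np.inf, None)
    for x in np.arange(-64, 64.1, coarse_step):
        for y in np.arange(-68, -7.9, coarse_step):
            for z in np.arange(-32, 56.1, coarse_step):
                p = np.array([x, y, z])
                if np.linalg.norm(p) > rmax:
                    continue
                c = _cost_at(p, D, Gp, head, montage)
                if c < best[0]:
                    best = (c, p)
    center = best[1]
    for dx in np.arange(-coarse_step, coarse_step + 0.1, fine_step):
        for dy in np.arange(-coarse_step, coarse_step + 0.1, fine_step):
            for dz in np.arange(-coarse_step, coarse_step + 0.1, fine_step):
                p = center + np.array([dx, dy, dz])
                if np.linalg.norm(p) > rmax:
                    continue
                c = _cost_at(p, D, Gp, head, montage)
                if c < best[0]:
                    best = (c, p)
    res = optimize.minimize(
        lambda p: _cost_at(p, D, Gp, head, montage),
        best[1],
        method="Nelder-Mead",
        options={"maxiter": 600, "fatol": 1e-10, "xatol": 1e-5},
    )
    return res.x if res.fun <= best[0] else best[1]


def normal_equations_waveforms(D: np.ndarray, gains: np.ndarray) -> np.ndarray:
    """Moments from explicitly assembled normal equations G'G m = G'd."""
    GtG = gains.T @ gains
    return np.linalg.solve(GtG, gains.T @ _avg_ref(D))
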