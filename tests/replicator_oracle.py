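"""Independent oracle: numerically integrated two-type replicator dynamics.

For a 2x2 game [[a, b], [c, d]], the frequency x of type 1 follows

    dx/dt = x (1 - x) [ (a - c) x + (b - d) (1 - x) ].

Integrating from an interior start determines the asymptotic outcome:
fixation of type 1 (x -> 1), fixation of type 2 (x -> 0), or convergence to
the interior equilibrium x* = (b - d) / ((b - d) + (c - a)). This is
independent of the sign-based classifier it is used to check.
"""

from __future__ import annotations

import numpy as np

FIX_SECOND = 0  # absorbed at x = 0
FIX_FIRST = 1  # absorbed at x = 1
INTERIOR = 2  # converged to the interior equilibrium


def interior_equilibrium(games: np.ndarray) -> np.ndarray:
    """x* = (b - d) / ((b - d) + (c - a)); NaN when undefined."""
    a, b = games[:, 0, 0], games[:, 0, 1]
    c, d = games[:, 1, 0], games[:, 1, 1]
    denom = (b - d) + (c - a)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom != 0, (b - d) / denom, np.nan)


def integrate_replicator(
    games: np.ndarray,
    x0: float,
    dt: float = 0.02,
    t_max: float = 1e5,
    tol: float = 1e-12,
) -> np.ndarray:
    """Integrate all games from frequency ``x0`` with fixed-step RK4.

    Runs until every trajectory reaches a fixed point (|dx/dt| < tol) or
    t_max is exhausted. Returns the final frequencies.
    """
    a, b = games[:, 0, 0], games[:, 0, 1]
    c, d = games[:, 1, 0], games[:, 1, 1]
    alpha, gamma = a - c, b - d

    def rhs(x: np.ndarray, sel: np.ndarray) -> np.ndarray:
        return x * (1.0 - x) * (alpha[sel] * x + gamma[sel] * (1.0 - x))

    x = np.full(len(games), float(x0))
    active = np.arange(len(games))
    steps_per_chunk = 500
    n_chunks = int(t_max / (dt * steps_per_chunk)) + 1
    for _ in range(n_chunks):
        if len(active) == 0:
            break
        xa = x[active]
        for _ in range(steps_per_chunk):
            k1 = rhs(xa, active)
            k2 = rhs(xa + 0.5 * dt * k1, active)
            k3 = rhs(xa + 0.5 * dt * k2, active)
            k4 = rhs(xa + dt * k3, active)
            xa = np.clip(xa + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4), 0.0, 1.0)
        x[active] = xa
        still = np.abs(rhs(xa, active)) >= tol
        active = active[still]
    return x


def outcome_of(x_final: np.ndarray, boundary_tol: float = 1e-4) -> np.ndarray:
    """Map final frequencies to FIX_SECOND / FIX_FIRST / INTERIOR."""
    out = np.full(len(x_final), INTERIOR, dtype=int)
    out[x_final < boundary_tol] = FIX_SECOND
    out[x_final > 1.0 - boundary_tol] = FIX_FIRST
    return out
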