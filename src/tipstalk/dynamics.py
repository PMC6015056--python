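"""Time integration of the lattice dynamics and relaxation to steady state.

Used both as a simulation front end and as the independent check on the
linear-stability verdicts: a stable root must recapture slightly
perturbed states, an unstable root must shed them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .core_model import (
    LatticeState,
    ModelParams,
    pack_classical,
    pack_full,
    unpack_classical,
    unpack_full,
)
from .errors import InvalidStateError, NumericalFailureError
from .steady_state import _full_rhs_vec_fn

__all__ = ["Trajectory", "integrate", "relax_to_steady", "perturb"]


@dataclass
class Trajectory:
    """Time series of lattice states from the integrator.

    ``times`` are dimensionless (unit = 1 / Delta decay rate) and start
    at 0; ``states`` are snapshots at those times; ``converged`` flags
    whether the final state is at steady state to ``final_residual``.
    """

    times: np.ndarray
    states: list[LatticeState]
    converged: bool
    final_residual: float

    @property
    def final_state(self) -> LatticeState:
        return self.states[-1]


def _to_vec(state: LatticeState, params: ModelParams) -> np.ndarray:
    if params.single_pool:
        return pack_classical(state.D, state.N_total)
    return pack_full(state)


def _from_vec(y: np.ndarray, params: ModelParams) -> LatticeState:
    n = params.n_cells
    if params.single_pool:
        D, N = unpack_classical(y, n)
        return LatticeState.single_pool(D, N)
    return unpack_full(y, n)


def integrate(
    params: ModelParams,
    init: LatticeState,
    t_end: float,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    n_snapshots: int = 200,
) -> Trajectory:
    """Integrate the model from ``init`` to ``t_end`` (stiff-capable).

    Uses an implicit BDF scheme.  Single-pool variants integrate the
    pooled equations (for the tension variant, the quasi-steady limit of
    the two-sided model); the heterogeneous variant integrates all three
    fields.  Snapshots are taken at ``n_snapshots`` evenly spaced times.
    """
    if t_end <= 0:
        raise InvalidStateError("t_end must be positive")
    init.validate(atol=0.0)
    if init.n_cells != params.n_cells:
        raise InvalidStateError("initial state size does not match params")
    fun, _ = _full_rhs_vec_fn(params)
    y0 = _to_vec(init, params)
    t_eval = np.linspace(0.0, t_end, max(n_snapshots, 2))
    sol = solve_ivp(
        lambda t, y: fun(y), (0.0, t_end), y0, method="BDF",
        rtol=rtol, atol=atol, t_eval=t_eval,
    )
    if not sol.success:
        raise NumericalFailureError(f"integrator failed: {sol.message}")
    states = [_from_vec(sol.y[:, k], params) for k in range(sol.y.shape[1])]
    final = states[-1]
    res = _full_residual_norm_dynamic(final, params)
    return Trajectory(times=sol.t, states=states, converged=res <= 1e-9,
                      final_residual=res)


def _full_residual_norm_dynamic(state: LatticeState, params: ModelParams) -> float:
    """Residual of the dynamical rhs actually integrated, so convergence
    is judged on the same vector field the trajectory follows."""
    fun, _ = _full_rhs_vec_fn(params)
    return float(np.max(np.abs(fun(_to_vec(state, params)))))


def relax_to_steady(
    params: ModelParams,
    init: LatticeState,
    tol: float = 1e-9,
    max_time: float = 1e5,
    t_chunk: float = 50.0,
) -> tuple[LatticeState, bool]:
    """Integrate in doubling time chunks until the rhs max-norm drops
    below ``tol`` or ``max_time`` is exceeded.

    Returns ``(state, converged)``; non-convergence is a data value.
    Convergence is declared on the rhs norm rather than on state
    displacement, which avoids false positives on slow transients.
    """
    state = init
    elapsed = 0.0
    chunk = t_chunk
    if _full_residual_norm_dynamic(state, params) <= tol:
        return state, True
    while elapsed < max_time:
        chunk = min(chunk, max_time - elapsed)
        traj = integrate(params, state, chunk, n_snapshots=2)
        state = traj.final_state
        # integration can leave tiny negative round-off; clip to manifold
        state = LatticeState(
            np.maximum(state.D, 0.0),
            np.clip(state.N_left, 0.0, 1.0),
            np.clip(state.N_right, 0.0, 1.0),
        )
        elapsed += chunk
        if _full_residual_norm_dynamic(state, params) <= tol:
            return state, True
        chunk *= 2.0
    return state, False


def perturb(state: LatticeState, magnitude: float, seed: int) -> LatticeState:
    """Multiply every variable by ``1 + magnitude * u``, ``u ~ U(-1, 1)``.

    Deterministic given ``seed``; Notch fractions are clipped back into
    [0, 1] and Delta to non-negative values so the result is admissible.
    """
    if magnitude < 0:
        raise InvalidStateError("perturbation magnitude must be >= 0")
    rng = np.random.default_rng(seed)
    n = state.n_cells

    def jiggle(arr: np.ndarray) -> np.ndarray:
        return arr * (1.0 + magnitude * rng.uniform(-1.0, 1.0, size=n))

    return LatticeState(
        np.maximum(jiggle(state.D), 0.0),
        np.clip(jiggle(state.N_left), 0.0, 1.0),
        np.clip(jiggle(state.N_right), 0.0, 1.0),
    )
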