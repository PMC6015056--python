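"""Model definition: parameters, lattice state, and right-hand sides.

The system is a linear one-dimensional array of ``n_cells`` endothelial
cells with periodic boundary conditions.  Each cell carries a
dimensionless Delta level ``D_j`` and, in the heterogeneous variants,
two activated-Notch fractions ``N_l,j`` and ``N_r,j`` (left and right
side of the cell) coupled by an intracellular diffusion rate ``W``.
Delta production is repressed by the cell's mean activated Notch through
a Hill function; Notch on each side is activated by the Delta of the
neighbour facing that side.

Three variants are distinguished by ``W`` and the tension-sensitivity
``h``:

* classical       — ``W`` infinite, ``h = 0``: one Notch pool per cell.
* heterogeneous   — ``W`` finite (``h = 0`` or ``h > 0``): two pools.
* tension-only    — ``W`` infinite, ``h > 0``: one pool per cell, with
  the binding rate of each cell-cell interface set by the intercellular
  distance through the Dembo law; its dynamics are the quasi-steady
  (pooled) limit of the two-sided model (:func:`rhs_pooled_vec`).  The
  idealised requirement that each side balance vanish separately is
  exposed as a diagnostic (:func:`side_resolved_residual`).

The Dembo-law rate of an interface between cells ``j`` and ``j+1`` is
``kf_j = kf0 * exp(-h * (x_m - lam)**2)`` where the intercellular
distance ``x_m`` decreases monotonically with the number of adherent
Delta-Notch pairs across the interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import (
    DegenerateInterfaceError,
    InvalidParameterError,
    InvalidStateError,
    UnsupportedVariantError,
)

__all__ = [
    "INFINITE",
    "DimensionalParams",
    "ModelParams",
    "LatticeState",
    "InterfaceRates",
    "nondimensionalize",
    "interface_distance",
    "binding_rate",
    "interface_rates",
    "rhs_full",
    "rhs_classical",
    "rhs_full_vec",
    "rhs_classical_vec",
    "rhs_pooled_vec",
    "side_resolved_residual",
    "pack_full",
    "unpack_full",
    "pack_classical",
    "unpack_classical",
]

#: Distinguished value for the intracellular Notch diffusion rate W
#: meaning "instantaneous equilibration": one Notch pool per cell.
INFINITE = math.inf

#: Interface-distance denominators at or below this are degenerate.
DISTANCE_FLOOR = 1e-9


@dataclass(frozen=True)
class DimensionalParams:
    """Dimensional rate constants of the lateral inhibition circuit.

    Attributes
    ----------
    B0 : float
        Maximum Delta expression rate (concentration / time).
    k_D, k_N : float
        First-order decay rates of Delta and of activated Notch (1/time).
    k : float
        Delta inhibitory coefficient: activated-Notch concentration at
        half-maximal Delta repression.
    K_F : float
        Delta-Notch binding rate constant (1/(concentration * time)).
    N0_total : float
        Total (activated + inactivated) Notch per membrane side.
    F_Notch : float
        Intracellular diffusion coefficient of Notch (length^2 / time).
    L : float
        Cell length.
    """

    B0: float
    k_D: float
    k_N: float
    k: float
    K_F: float
    N0_total: float
    F_Notch: float
    L: float

    def __post_init__(self) -> None:
        for name in ("B0", "k_D", "k_N", "k", "K_F", "N0_total", "L"):
            v = getattr(self, name)
            if not (v > 0) or not math.isfinite(v):
                raise InvalidParameterError(
                    f"DimensionalParams.{name} must be strictly positive, got {v!r}"
                )
        if self.F_Notch < 0 or not math.isfinite(self.F_Notch):
            raise InvalidParameterError(
                f"DimensionalParams.F_Notch must be finite and >= 0, got {self.F_Notch!r}"
            )


@dataclass(frozen=True)
class ModelParams:
    """Dimensionless parameter vector for one model variant on one lattice.

    Attributes
    ----------
    b0 : float
        Maximum dimensionless Delta production rate.
    K : float
        Dimensionless Delta inhibitory coefficient (Notch fraction at
        half-maximal repression).
    kd : float
        Dimensionless Notch decay rate (Notch decay over Delta decay).
    kf0 : float
        Baseline dimensionless Delta-Notch binding rate constant.
    h : float
        Tension-sensitivity coefficient of the Dembo law; ``h = 0``
        switches tension dependence off.
    lam : float
        Optimum dimensionless intercellular distance (the Dembo-law
        distance at which the binding rate is maximal).
    W : float
        Dimensionless intracellular Notch diffusion rate; ``math.inf``
        (:data:`INFINITE`) selects the single-pool reduction.
    n_cells : int
        Lattice size (periodic).
    hill : float
        Hill coefficient of Notch-mediated Delta repression (default 2).
    """

    b0: float
    K: float
    kd: float
    kf0: float
    h: float = 0.0
    lam: float = 10.0
    W: float = INFINITE
    n_cells: int = 12
    hill: float = 2.0

    def __post_init__(self) -> None:
        for name in ("b0", "K", "kd", "kf0"):
            v = getattr(self, name)
            if not (v > 0) or not math.isfinite(v):
                raise InvalidParameterError(
                    f"ModelParams.{name} must be strictly positive, got {v!r}"
                )
        if self.h < 0 or not math.isfinite(self.h):
            raise InvalidParameterError(f"ModelParams.h must be >= 0, got {self.h!r}")
        if not math.isfinite(self.lam) or self.lam <= 0:
            raise InvalidParameterError(
                f"ModelParams.lam must be strictly positive, got {self.lam!r}"
            )
        if self.W < 0 or math.isnan(self.W):
            raise InvalidParameterError(
                f"ModelParams.W must be >= 0 or INFINITE, got {self.W!r}"
            )
        if not isinstance(self.n_cells, (int, np.integer)) or self.n_cells < 2:
            raise InvalidParameterError(
                f"ModelParams.n_cells must be an integer >= 2, got {self.n_cells!r}"
            )
        if self.hill < 1 or not math.isfinite(self.hill):
            raise InvalidParameterError(
                f"ModelParams.hill must be >= 1, got {self.hill!r}"
            )

    # -- variant helpers ------------------------------------------------
    @property
    def single_pool(self) -> bool:
        """True when W is INFINITE: the two Notch sides are merged."""
        return math.isinf(self.W)

    @property
    def variant(self) -> str:
        """One of ``"classical"``, ``"tension"``, ``"heterogeneous"``."""
        if self.single_pool:
            return "tension" if self.h > 0 else "classical"
        return "heterogeneous"

    def with_lattice(self, n_cells: int) -> "ModelParams":
        """Copy of these parameters on a different lattice size."""
        return replace(self, n_cells=int(n_cells))


@dataclass
class LatticeState:
    """Per-cell Delta plus left/right activated-Notch fractions.

    The lattice is periodic: index arithmetic is modulo ``n_cells``.
    Single-pool (classical / tension-only) states are represented with
    ``N_left`` and ``N_right`` holding the same values.
    """

    D: np.ndarray
    N_left: np.ndarray
    N_right: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        self.N_left = np.asarray(self.N_left, dtype=float)
        self.N_right = np.asarray(self.N_right, dtype=float)

    @property
    def n_cells(self) -> int:
        return self.D.shape[0]

    @property
    def N_total(self) -> np.ndarray:
        """Per-cell mean activated Notch, (N_left + N_right)/2."""
        return 0.5 * (self.N_left + self.N_right)

    def validate(self, atol: float = 0.0) -> None:
        """Raise :class:`InvalidStateError` unless the state is admissible."""
        n = self.n_cells
        if not (self.N_left.shape == (n,) and self.N_right.shape == (n,)):
            raise InvalidStateError("state arrays have mismatched lengths")
        for arr, name in ((self.D, "D"), (self.N_left, "N_left"), (self.N_right, "N_right")):
            if not np.all(np.isfinite(arr)):
                raise InvalidStateError(f"{name} contains non-finite values")
        if np.any(self.D < -atol):
            raise InvalidStateError("Delta levels must be non-negative")
        for arr, name in ((self.N_left, "N_left"), (self.N_right, "N_right")):
            if np.any(arr < -atol) or np.any(arr > 1 + atol):
                raise InvalidStateError(f"{name} outside [0, 1]")

    def copy(self) -> "LatticeState":
        return LatticeState(self.D.copy(), self.N_left.copy(), self.N_right.copy())

    @classmethod
    def single_pool(cls, D: np.ndarray, N: np.ndarray) -> "LatticeState":
        """Build a single-pool state with both sides sharing N."""
        N = np.asarray(N, dtype=float)
        return cls(np.asarray(D, dtype=float), N.copy(), N.copy())

    def is_symmetric(self, atol: float = 1e-12) -> bool:
        """True if left and right Notch pools agree within ``atol``."""
        return bool(np.max(np.abs(self.N_left - self.N_right)) <= atol)


@dataclass
class InterfaceRates:
    """Per-interface distance and Dembo-law binding rate.

    ``x_m[j]`` and ``kf[j]`` refer to the interface between cell ``j``
    and cell ``j+1`` (mod n_cells).  The same ``kf[j]`` governs both
    directions across that interface: activation of ``N_r,j`` by
    ``D_{j+1}`` and of ``N_l,j+1`` by ``D_j``.
    """

    x_m: np.ndarray
    kf: np.ndarray


# ---------------------------------------------------------------------------
# Nondimensionalization
# ---------------------------------------------------------------------------

def nondimensionalize(
    dim: DimensionalParams,
    *,
    h: float = 0.0,
    lam: float = 10.0,
    n_cells: int = 12,
    hill: float = 2.0,
) -> ModelParams:
    """Map dimensional rate constants onto the dimensionless parameters.

    Time is rescaled by the Delta decay rate (``t = tau / k_D``), Delta
    by ``D_0 = k_d / B_0`` and Notch by the total per-side pool, giving

    * ``b0 = B0 / (k_D * D_0)``
    * ``K = k / N0_total``
    * ``kf0 = K_F * D_0 / (2 * k_D)``
    * ``kd = k_N / k_D``
    * ``W = F_Notch / (L**2 * k_D * N0_total)``

    ``h``, ``lam``, ``n_cells`` and ``hill`` are dimensionless already
    and are passed through from the caller.
    """
    kd = dim.k_N / dim.k_D
    D0 = kd / dim.B0
    return ModelParams(
        b0=dim.B0 / (dim.k_D * D0),
        K=dim.k / dim.N0_total,
        kd=kd,
        kf0=dim.K_F * D0 / (2.0 * dim.k_D),
        h=h,
        lam=lam,
        W=dim.F_Notch / (dim.L**2 * dim.k_D * dim.N0_total),
        n_cells=n_cells,
        hill=hill,
    )


# ---------------------------------------------------------------------------
# Interface geometry and Dembo-law rates
# ---------------------------------------------------------------------------

def interface_distance(
    N_r_j: float, D_next: float, N_l_next: float, D_j: float
) -> float:
    """Intercellular distance across one interface.

    The membranes are held together by adhesive Delta-Notch contacts;
    the number of contacts each signalling direction can sustain is set
    by its limiting species — the free Notch fraction on the receiving
    side or the Delta presented by the facing cell — and the distance is
    the reciprocal of the total contact capacity:

    ``x_m = 1 / ( min(1 - N_r_j, D_next) + min(1 - N_l_next, D_j) )``.

    Many contacts pull the membranes close (small ``x_m``); an interface
    with no possible contact is infinitely separated.  A denominator at
    or below the floor makes the distance undefined at this level and
    raises :class:`DegenerateInterfaceError`; the lattice-level rate
    computation instead takes the continuous limit (zero binding rate).
    """
    denom = min(1.0 - N_r_j, D_next) + min(1.0 - N_l_next, D_j)
    if denom <= DISTANCE_FLOOR:
        raise DegenerateInterfaceError(
            f"interface denominator {denom!r} at or below floor {DISTANCE_FLOOR}"
        )
    return 1.0 / denom


def binding_rate(x_m, params: ModelParams):
    """Dembo-law binding rate ``kf0 * exp(-h * (x_m - lam)**2)``.

    Equals ``kf0`` exactly when ``h = 0`` or at the optimum distance
    ``x_m = lam``; always in ``(0, kf0]``.  Accepts scalars or arrays.
    """
    x_m = np.asarray(x_m, dtype=float)
    if np.any(x_m <= 0):
        raise InvalidParameterError("intercellular distance must be positive")
    if params.h == 0.0:
        out = np.full_like(x_m, params.kf0)
    else:
        out = params.kf0 * np.exp(-params.h * (x_m - params.lam) ** 2)
    return out if out.ndim else float(out)



def _prev(a: np.ndarray) -> np.ndarray:
    """roll(a, +1) for 1-D arrays without np.roll overhead."""
    return np.concatenate((a[-1:], a[:-1]))


def _next(a: np.ndarray) -> np.ndarray:
    """roll(a, -1) for 1-D arrays without np.roll overhead."""
    return np.concatenate((a[1:], a[:1]))

def _interface_arrays(D, N_l, N_r, params: ModelParams):
    """Vectorized per-interface distance and rate on the periodic lattice.

    Interface j couples cell j (its right side) to cell j+1 (its left
    side).  Returns (x_m, kf), each of length n_cells.  Interfaces with
    no possible adhesive contact (denominator at the floor) are treated
    in the continuous limit: infinite distance, zero binding rate.
    """
    D_next = _next(D)
    N_l_next = _next(N_l)
    denom = np.minimum(1.0 - N_r, D_next) + np.minimum(1.0 - N_l_next, D)
    far = denom <= DISTANCE_FLOOR
    x_m = 1.0 / np.maximum(denom, DISTANCE_FLOOR)
    if params.h == 0.0:
        kf = np.full_like(x_m, params.kf0)
    else:
        kf = params.kf0 * np.exp(-params.h * (x_m - params.lam) ** 2)
        kf[far] = 0.0
    np.place(x_m, far, np.inf)
    return x_m, kf


def interface_rates(state: LatticeState, params: ModelParams) -> InterfaceRates:
    """Distances and binding rates for every interface of ``state``."""
    x_m, kf = _interface_arrays(state.D, state.N_left, state.N_right, params)
    return InterfaceRates(x_m=x_m, kf=kf)


# ---------------------------------------------------------------------------
# Right-hand sides
# ---------------------------------------------------------------------------

def _hill_production(N_eff, params: ModelParams):
    """Delta production repressed by effective Notch through a Hill term."""
    return params.b0 / (1.0 + (N_eff / params.K) ** params.hill)


def rhs_full_vec(D, N_l, N_r, params: ModelParams):
    """Heterogeneous-variant time derivatives (vectorized, no validation).

    dD_j   = -D_j + b0 / (1 + ((N_l,j + N_r,j) / (2 K))**hill)
    dN_l,j = -kd N_l,j + kf_{j-1} D_{j-1} (1 - N_l,j) + W (N_r,j - N_l,j)
    dN_r,j = -kd N_r,j + kf_j     D_{j+1} (1 - N_r,j) + W (N_l,j - N_r,j)

    Interface rates are recomputed from the current state, so the state
    dependence of the Dembo law is fully dynamic.
    """
    if params.h == 0.0:
        # Dembo law inactive: no distance computation (and no spurious
        # degenerate-interface error at N = 1, D = 0 corners).
        kf = np.full(len(np.asarray(D)), params.kf0)
    else:
        _, kf = _interface_arrays(D, N_l, N_r, params)
    D_prev = _prev(D)
    D_next = _next(D)
    kf_prev = _prev(kf)  # interface j-1, governing the left side of cell j
    dD = -D + _hill_production(0.5 * (N_l + N_r), params)
    dN_l = -params.kd * N_l + kf_prev * D_prev * (1.0 - N_l) + params.W * (N_r - N_l)
    dN_r = -params.kd * N_r + kf * D_next * (1.0 - N_r) + params.W * (N_l - N_r)
    return dD, dN_l, dN_r


def rhs_full(state: LatticeState, params: ModelParams) -> LatticeState:
    """Time derivative of a heterogeneous-variant state (validated).

    Requires finite ``W``.  Returns the derivative as a
    :class:`LatticeState`-shaped triple (the fields are derivatives, not
    an admissible state).
    """
    if params.single_pool:
        raise UnsupportedVariantError(
            "rhs_full requires finite W; use rhs_classical (h = 0) or the "
            "side-resolved steady-state treatment (h > 0) for W = INFINITE"
        )
    state.validate(atol=1e-9)
    if state.n_cells != params.n_cells:
        raise InvalidStateError(
            f"state has {state.n_cells} cells, params expect {params.n_cells}"
        )
    dD, dN_l, dN_r = rhs_full_vec(state.D, state.N_left, state.N_right, params)
    return LatticeState(dD, dN_l, dN_r)


def rhs_classical_vec(D, N, params: ModelParams):
    """Classical-variant derivatives: one Notch pool per cell.

    dD_j = -D_j + b0 / (1 + (N_j / K)**hill)
    dN_j = -kd N_j + kf0 (D_{j-1} + D_{j+1}) (1 - N_j)
    """
    dD = -D + _hill_production(N, params)
    dN = -params.kd * N + params.kf0 * (_prev(D) + _next(D)) * (1.0 - N)
    return dD, dN


def rhs_classical(D, N, params: ModelParams):
    """Validated classical right-hand side (W = INFINITE, h = 0).

    Tension with a single Notch pool has no printed dynamic law; it is
    handled at steady state only (:mod:`tipstalk.steady_state`), so
    calling this with ``h > 0`` raises :class:`UnsupportedVariantError`.
    """
    if params.h > 0:
        raise UnsupportedVariantError(
            "rhs_classical requires h = 0; the tension-only variant is "
            "treated at steady state via side_resolved_residual"
        )
    D = np.asarray(D, dtype=float)
    N = np.asarray(N, dtype=float)
    if D.shape != N.shape or D.shape != (params.n_cells,):
        raise InvalidStateError("D and N must both have length n_cells")
    if not (np.all(np.isfinite(D)) and np.all(np.isfinite(N))):
        raise InvalidStateError("state contains non-finite values")
    if np.any(D < -1e-9) or np.any(N < -1e-9) or np.any(N > 1 + 1e-9):
        raise InvalidStateError("state outside admissible ranges")
    return rhs_classical_vec(D, N, params)


def rhs_pooled_vec(D, N, params: ModelParams):
    """Single-pool tension dynamics: the W -> INFINITE quasi-steady limit.

    With instantaneous intracellular diffusion the two Notch sides of a
    cell equilibrate; averaging the two side equations (the diffusive
    exchange cancels) leaves one pool driven by the mean of the two
    tension-weighted inputs:

    dD_j = -D_j + b0 / (1 + (N_j/K)**hill)
    dN_j = -kd N_j + (kf_{j-1} D_{j-1} + kf_j D_{j+1}) / 2 * (1 - N_j)

    This is the exact limit of the two-sided model and carries the full
    state dependence of the Dembo-law interface rates.
    """
    D = np.asarray(D, dtype=float)
    N = np.asarray(N, dtype=float)
    if params.h == 0.0:
        kf = np.full(len(D), params.kf0)
    else:
        _, kf = _interface_arrays(D, N, N, params)
    kf_prev = _prev(kf)
    dD = -D + _hill_production(N, params)
    dN = -params.kd * N + 0.5 * (
        kf_prev * _prev(D) + kf * _next(D)
    ) * (1.0 - N)
    return dD, dN


def side_resolved_residual(D, N, params: ModelParams):
    """Per-side steady-state residuals of a single-pool state (diagnostic).

    At an idealised tension steady state each side's activation balance
    would vanish separately,

    0 = -D_j + b0 / (1 + (N_j/K)**hill)
    0 = -kd N_j + kf_{j-1} D_{j-1} (1 - N_j)      (left side)
    0 = -kd N_j + kf_j     D_{j+1} (1 - N_j)      (right side)

    which over-determines the 2n unknowns: exact roots require the
    per-cell interface balance ``kf_{j-1} D_{j-1} = kf_j D_{j+1}`` and
    exist only on a tuned parameter manifold.  Actual roots of the
    pooled limit (:func:`rhs_pooled_vec`) satisfy these side residuals
    only approximately; this function measures how closely.  Returns a
    vector of length ``3 n``.
    """
    D = np.asarray(D, dtype=float)
    N = np.asarray(N, dtype=float)
    if params.h == 0.0:
        kf = np.full(len(D), params.kf0)
    else:
        _, kf = _interface_arrays(D, N, N, params)
    kf_prev = _prev(kf)
    rD = -D + _hill_production(N, params)
    r_left = -params.kd * N + kf_prev * _prev(D) * (1.0 - N)
    r_right = -params.kd * N + kf * _next(D) * (1.0 - N)
    return np.concatenate([rD, r_left, r_right])


# ---------------------------------------------------------------------------
# Packing helpers (flat vectors for solvers and integrators)
# ---------------------------------------------------------------------------

def pack_full(state: LatticeState) -> np.ndarray:
    return np.concatenate([state.D, state.N_left, state.N_right])


def unpack_full(y: np.ndarray, n: int) -> LatticeState:
    return LatticeState(y[:n], y[n : 2 * n], y[2 * n : 3 * n])


def pack_classical(D, N) -> np.ndarray:
    return np.concatenate([np.asarray(D, float), np.asarray(N, float)])


def unpack_classical(y: np.ndarray, n: int):
    return y[:n], y[n : 2 * n]
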