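"""Deterministic fixture generation: reference parameter sets and
synthetic lattice states for classifier and oracle tests."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import INFINITE, LatticeState, ModelParams

__all__ = ["REFERENCE_SETS", "ReferenceCase", "generate_fixtures", "synthetic_spacing_state"]


@dataclass(frozen=True)
class ReferenceCase:
    """One published parameter set with its reported stable spacing."""

    params: ModelParams
    spacing: int


#: The published profile parameter sets, named by mechanism regime:
#: ``hetero_*`` — two Notch pools, no tension; ``tension_*`` — one pool
#: with Dembo-law rates; ``full_*`` — both mechanisms.
REFERENCE_SETS: dict[str, ReferenceCase] = {
    "hetero_zerocell": ReferenceCase(
        ModelParams(b0=0.5, K=1.0, kd=1.0, kf0=0.1, h=0.0, W=0.0), 0),
    "hetero_onecell": ReferenceCase(
        ModelParams(b0=0.8, K=0.01, kd=1.0, kf0=0.1, h=0.0, W=0.0), 1),
    "hetero_twocell": ReferenceCase(
        ModelParams(b0=0.8, K=0.01, kd=1.0, kf0=0.3, h=0.0, W=0.0), 2),
    "hetero_w0_twocell": ReferenceCase(
        ModelParams(b0=0.9, K=0.025, kd=0.2, kf0=0.3, h=0.0, W=0.0), 2),
    "hetero_w3_twocell": ReferenceCase(
        ModelParams(b0=0.9, K=0.025, kd=0.2, kf0=0.3, h=0.0, W=3.0), 2),
    "hetero_w50_twocell": ReferenceCase(
        ModelParams(b0=0.9, K=0.025, kd=0.2, kf0=0.3, h=0.0, W=50.0), 2),
    "tension_twocell": ReferenceCase(
        ModelParams(b0=0.9, K=0.1, kd=0.0225, kf0=3.719, h=0.0052, lam=30.0,
                    W=INFINITE), 2),
    "tension_threecell": ReferenceCase(
        ModelParams(b0=0.9, K=0.05, kd=0.4021, kf0=38.6324, h=0.0761, lam=10.0,
                    W=INFINITE), 3),
    "full_zerocell": ReferenceCase(
        ModelParams(b0=0.9, K=0.1, kd=0.4, kf0=40.0, h=0.076, lam=10.0, W=0.0), 0),
    "full_onecell": ReferenceCase(
        ModelParams(b0=0.9, K=0.07, kd=0.4, kf0=40.0, h=0.076, lam=10.0, W=0.0), 1),
    "full_twocell": ReferenceCase(
        ModelParams(b0=0.9, K=0.01, kd=0.4, kf0=40.0, h=0.076, lam=10.0, W=0.0), 2),
    "full_threecell": ReferenceCase(
        ModelParams(b0=0.9, K=0.01, kd=0.4, kf0=35.0, h=0.076, lam=10.0, W=0.0), 3),
}


def synthetic_spacing_state(
    spacing: int, n_cells: int = 12, tip_level: float = 0.8,
    stalk_level: float = 0.01, asymmetry: float = 0.0,
) -> LatticeState:
    """Hand-built periodic state with a known spacing (for classifier
    tests; not a model steady state).

    ``asymmetry`` offsets N_left vs N_right on stalk cells.
    """
    p = spacing + 1
    if n_cells % p:
        raise ValueError(f"period {p} must divide n_cells={n_cells}")
    D = np.full(n_cells, stalk_level)
    D[::p] = tip_level
    N = np.where(D == tip_level, 0.05, 0.8)
    N_l = np.clip(N - asymmetry * (D != tip_level), 0.0, 1.0)
    N_r = np.clip(N + asymmetry * (D != tip_level), 0.0, 1.0)
    return LatticeState(D, N_l, N_r)


def generate_fixtures(seed: int) -> dict:
    """Deterministic fixture set for tests.

    Returns a dict with:

    * ``states``: synthetic states of known spacing 0-3 (12 cells);
    * ``random_states``: admissible random states for rhs/Jacobian
      oracle tests (heterogeneous shape, 12 cells);
    * ``reference``: the published parameter sets
      (:data:`REFERENCE_SETS`).
    """
    rng = np.random.default_rng(seed)
    states = {s: synthetic_spacing_state(s) for s in (0, 1, 2, 3)}
    random_states = []
    for _ in range(6):
        random_states.append(
            LatticeState(
                rng.uniform(0.01, 0.9, 12),
                rng.uniform(0.0, 1.0, 12),
                rng.uniform(0.0, 1.0, 12),
            )
        )
    return {"states": states, "random_states": random_states,
            "reference": REFERENCE_SETS}
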