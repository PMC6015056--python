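"""Classification of lattice states into n-cell spacings and cell types.

An *n-cell spacing* is a periodic pattern with exactly ``n`` stalk cells
between consecutive tip cells (salt-and-pepper = one-cell spacing).
Tip cells are the cells with the highest Delta; stalk cells have low
Delta; a *hybrid* cell has moderate Delta, typically with high Notch on
one side and low Notch on the other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import LatticeState
from .errors import InvalidParameterError

__all__ = ["IRREGULAR", "PatternLabel", "classify_spacing", "label_cells", "notch_asymmetry"]

#: Sentinel spacing for states whose tip cells are not evenly spaced.
IRREGULAR = -1

#: Delta floor guarding the uniformity test against the all-zero state.
_UNIFORM_FLOOR = 1e-12


@dataclass(frozen=True)
class PatternLabel:
    """Per-cell categories plus the detected spacing and repeat length.

    ``spacing`` is the number of stalk cells between consecutive tips
    (0 for a uniform state) or :data:`IRREGULAR`; ``period`` is the
    tip-to-tip distance, or ``None`` when irregular.
    """

    labels: tuple[str, ...]
    spacing: int
    period: int | None


def _tip_mask(D: np.ndarray, rel_tol: float) -> np.ndarray:
    return D >= (1.0 - rel_tol) * D.max()


def classify_spacing(state: LatticeState, rel_tol: float = 1e-3) -> PatternLabel:
    """Detect the n-cell spacing of a (steady) state.

    A state whose Delta spread ``max(D) - min(D)`` is below
    ``rel_tol * max(max(D), floor)`` is uniform (spacing 0, including
    the degenerate case where every cell ties as a tip).  Otherwise the
    tips are the cells within ``rel_tol`` of the Delta maximum; if the
    circular gaps between consecutive tips are all equal to ``g`` the
    spacing is ``g - 1``, else :data:`IRREGULAR`.

    The classification is invariant under lattice rotation and
    reflection (it depends only on the multiset of circular gaps).
    """
    D = state.D
    n = state.n_cells
    scale = max(float(D.max()), _UNIFORM_FLOOR)
    if float(D.max() - D.min()) <= rel_tol * scale:
        return PatternLabel(labels=("tip",) * n if D.max() > _UNIFORM_FLOOR else ("stalk",) * n,
                            spacing=0, period=1)
    tips = np.flatnonzero(_tip_mask(D, rel_tol))
    if len(tips) == n:  # all cells tie as tips under the tolerance
        return PatternLabel(labels=("tip",) * n, spacing=0, period=1)
    gaps = np.diff(np.append(tips, tips[0] + n))
    labels = tuple("tip" if m else "stalk" for m in _tip_mask(D, rel_tol))
    if np.all(gaps == gaps[0]):
        g = int(gaps[0])
        return PatternLabel(labels=labels, spacing=g - 1, period=g)
    return PatternLabel(labels=labels, spacing=IRREGULAR, period=None)


def label_cells(
    state: LatticeState, tip_frac: float = 0.9, stalk_frac: float = 0.1
) -> PatternLabel:
    """Label each cell tip / stalk / hybrid by Delta relative to the max.

    Cells with ``D >= tip_frac * max(D)`` are tips, cells with
    ``D <= stalk_frac * max(D)`` are stalks, and everything in between —
    moderate Delta, characteristically with asymmetric left/right Notch —
    is hybrid.  Thresholds are for exploratory states; spacing detection
    on converged roots should use :func:`classify_spacing`.
    """
    if not (0.0 < stalk_frac < tip_frac < 1.0):
        raise InvalidParameterError(
            "label_cells requires 0 < stalk_frac < tip_frac < 1"
        )
    spacing_label = classify_spacing(state)
    Dmax = max(float(state.D.max()), _UNIFORM_FLOOR)
    labels = []
    for d in state.D:
        if d >= tip_frac * Dmax:
            labels.append("tip")
        elif d <= stalk_frac * Dmax:
            labels.append("stalk")
        else:
            labels.append("hybrid")
    return PatternLabel(labels=tuple(labels), spacing=spacing_label.spacing,
                        period=spacing_label.period)


def notch_asymmetry(state: LatticeState) -> np.ndarray:
    """Per-cell ``|N_left - N_right|`` — the intracellular polarity of
    activated Notch.  Identically zero for single-pool states and for
    zero- and one-cell-spacing roots; strictly positive on the stalk and
    hybrid cells of two-cell-spacing roots at finite diffusion."""
    return np.abs(state.N_left - state.N_right)
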