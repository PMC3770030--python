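"""Feature maps driving front propagation and level-set evolution.

Two scalar fields are derived from the gradient-magnitude map:

* a **speed map** — a sigmoid remapping of gradient magnitude that is high
  in homogeneous tissue and collapses at edges, used as the propagation
  speed of the fast-marching front;
* an **edge indicator** ``g = 1/(1 + gm^2)`` — the stopping function of
  edge-based level sets, equal to 1 in flat regions and small at edges.

Note the sigmoid's ``alpha``/``beta`` here are unrelated to the
energy-tune ``alpha``/``beta`` of :mod:`pancseg.energy`; they are kept in
separate configuration groups.
"""

from __future__ import annotations

import numpy as np

__all__ = ["sigmoid_speed", "edge_indicator"]


def sigmoid_speed(
    gm: np.ndarray,
    alpha: float = -0.5,
    beta: float = 3.0,
    out_min: float = 0.0,
    out_max: float = 1.0,
) -> np.ndarray:
    """Sigmoid intensity transform of a gradient-magnitude map.

    ``speed = (out_max - out_min) / (1 + exp(-(gm - beta)/alpha)) + out_min``

    With ``alpha < 0`` the map is monotone *decreasing* in gradient
    magnitude: fast in flat tissue, near ``out_min`` at strong edges.
    ``beta`` centres the transition; ``|alpha|`` sets its width.
    """
    if alpha == 0:
        raise ValueError("alpha must be nonzero")
    if not out_min < out_max:
        raise ValueError("out_min must be < out_max")
    gm = np.asarray(gm, dtype=np.float64)
    # clip the exponent: the asymptotes are exact at float saturation anyway
    z = np.clip(-(gm - beta) / alpha, -709.0, 709.0)
    return (out_max - out_min) / (1.0 + np.exp(z)) + out_min


def edge_indicator(gm: np.ndarray) -> np.ndarray:
    """Edge indicator ``g = 1/(1 + gm^2)``, in ``(0, 1]``.

    Equals 1 exactly where the gradient vanishes and decays toward 0 at
    strong edges; strictly decreasing in ``gm``.
    """
    gm = np.asarray(gm, dtype=np.float64)
    if np.any(gm < 0):
        raise ValueError("gradient magnitude must be non-negative")
    return 1.0 / (1.0 + gm * gm)
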