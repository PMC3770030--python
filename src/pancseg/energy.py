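"""Energy-decrement and energy-tune algorithms.

The pancreas is typically welded to neighbouring organs of nearly the same
intensity across a weak, sometimes fractured boundary.  A front or contour
driven only by image gradients leaks through such gaps ("bonding force").
Two complementary mechanisms suppress the leak:

**Energy-decrement** (fast-marching stage).  Given a physician-drawn
*standard line* separating the organs, every pixel within a distance
``t_d`` of the line has its propagation speed dropped to the speed map's
minimum, stalling the front in the coupling band:

    E_s(i,j) = I_min            if D_l(i,j) < t_d
               speed(i,j)       otherwise

**Energy-tune** (level-set stage).  The fast-marching initial region R0 is
treated as an *energy source*: each pixel receives energy from every
source pixel with exponential distance decay,

    E(i,j) = sum_{(i0,j0) in R0} exp(-D((i,j),(i0,j0))/sigma) * g(i0,j0).

The edge map g is then re-weighted: enhanced (toward 1) inside R0, decayed
(toward 0) in the coupling area — near the standard line but away from the
source, or, in the automatic variant without a line, beyond a distance
``d_t`` from the source.  The decayed band acts as a synthetic edge that
stops the level set where the true boundary is missing.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist
from skimage.draw import line as _draw_line

__all__ = [
    "StandardLine",
    "distance_to_line",
    "distance_to_mask",
    "energy_decrement",
    "source_energy",
    "energy_tune_line",
    "energy_tune_auto",
]


class StandardLine:
    """Polyline separating the target organ from an adjacent one.

    Vertices are ``(row, col)`` pairs, 0-based and pixel-centred, ordered
    along the line.  At least two vertices are required.
    """

    __slots__ = ("vertices",)

    def __init__(self, vertices) -> None:
        verts = tuple((int(r), int(c)) for r, c in vertices)
        if len(verts) < 2:
            raise ValueError("a standard line needs at least 2 vertices")
        self.vertices = verts

    def __repr__(self) -> str:  # pragma: no cover
        return f"StandardLine({list(self.vertices)!r})"

    def __eq__(self, other) -> bool:
        return isinstance(other, StandardLine) and self.vertices == other.vertices

    def __hash__(self) -> int:
        return hash(self.vertices)

    def rasterize(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of the grid pixels the polyline passes through."""
        nr, nc = shape
        for r, c in self.vertices:
            if not (0 <= r < nr and 0 <= c < nc):
                raise ValueError(f"vertex ({r}, {c}) outside image of shape {shape}")
        mask = np.zeros(shape, dtype=bool)
        for (r0, c0), (r1, c1) in zip(self.vertices[:-1], self.vertices[1:]):
            rr, cc = _draw_line(r0, c0, r1, c1)
            mask[rr, cc] = True
        return mask


def distance_to_line(line: StandardLine, shape: tuple[int, int]) -> np.ndarray:
    """Exact Euclidean distance transform to the rasterized polyline."""
    mask = line.rasterize(shape)
    return ndimage.distance_transform_edt(~mask)


def distance_to_mask(mask: np.ndarray) -> np.ndarray:
    """Exact Euclidean distance transform to a nonempty binary region."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    return ndimage.distance_transform_edt(~mask)


def energy_decrement(speed: np.ndarray, d_line: np.ndarray, t_d: float = 3.0) -> np.ndarray:
    """Stall the fast-marching front in a band around the standard line.

    Pixels with ``d_line < t_d`` are set to the minimum of the speed map;
    all others keep their speed.  ``t_d = 0`` leaves the map untouched.
    """
    speed = np.asarray(speed, dtype=np.float64)
    d_line = np.asarray(d_line, dtype=np.float64)
    if speed.shape != d_line.shape:
        raise ValueError(f"shape mismatch: speed {speed.shape} vs distance {d_line.shape}")
    if t_d < 0:
        raise ValueError("t_d must be non-negative")
    i_min = float(speed.min())
    return np.where(d_line < t_d, i_min, speed)


def source_energy(
    r0: np.ndarray,
    g: np.ndarray,
    sigma: float = 10.0,
    boundary_only: bool = False,
    chunk_pixels: int = 4096,
) -> np.ndarray:
    """Per-pixel energy received from the source region R0.

    Exact double sum ``E(p) = sum_{q in R0} exp(-|p-q|/sigma) g(q)`` with
    Euclidean pixel distances; strictly positive everywhere.  Cost is
    O(N * |R0|); ``boundary_only=True`` restricts the source to R0's
    4-connected boundary pixels as an opt-in approximation for large
    images.
    """
    r0 = np.asarray(r0, dtype=bool)
    g = np.asarray(g, dtype=np.float64)
    if r0.shape != g.shape:
        raise ValueError(f"shape mismatch: r0 {r0.shape} vs g {g.shape}")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not r0.any():
        raise ValueError("source region R0 is empty")
    src = r0
    if boundary_only:
        eroded = ndimage.binary_erosion(r0, structure=ndimage.generate_binary_structure(2, 1))
        src = r0 & ~eroded
    src_pts = np.argwhere(src).astype(np.float64)
    src_g = g[src]
    coords = np.indices(r0.shape).reshape(2, -1).T.astype(np.float64)
    out = np.empty(coords.shape[0], dtype=np.float64)
    for start in range(0, coords.shape[0], chunk_pixels):
        block = coords[start : start + chunk_pixels]
        d = cdist(block, src_pts)
        np.exp(-d / sigma, out=d)
        out[start : start + chunk_pixels] = d @ src_g
    return out.reshape(r0.shape)


def _check_tune_inputs(g, e_src, r0):
    g = np.asarray(g, dtype=np.float64)
    e_src = np.asarray(e_src, dtype=np.float64)
    r0 = np.asarray(r0, dtype=bool)
    if not (g.shape == e_src.shape == r0.shape):
        raise ValueError("g, e_src and r0 must share a shape")
    n = int(r0.sum())
    if n == 0:
        raise ValueError("source region R0 is empty")
    return g, e_src, r0, n


def energy_tune_line(
    g: np.ndarray,
    e_src: np.ndarray,
    r0: np.ndarray,
    d_line: np.ndarray,
    d_src: np.ndarray,
    tune_alpha: float = 1.0,
    tune_beta: float = 1.0,
) -> np.ndarray:
    """Standard-line energy-tune of the edge map.

    Branches, in order of precedence per pixel:

    1. in R0                -> ``min(1, (alpha/n) E + g)`` (enhance),
    2. ``d_line <= d_src``  -> ``max(0, g - beta E / d_line)`` (decay;
       the ``d_line = 0`` limit is 0 for ``E > 0``, ``g`` for ``E = 0``),
    3. otherwise            -> ``g`` unchanged.

    Output clamped to [0, 1].
    """
    g, e_src, r0, n = _check_tune_inputs(g, e_src, r0)
    d_line = np.asarray(d_line, dtype=np.float64)
    d_src = np.asarray(d_src, dtype=np.float64)
    if d_line.shape != g.shape or d_src.shape != g.shape:
        raise ValueError("distance fields must match the edge map's shape")

    out = g.copy()

    decay = ~r0 & (d_line <= d_src)
    with np.errstate(divide="ignore", invalid="ignore"):
        dec_val = np.maximum(0.0, g - tune_beta * e_src / d_line)
    on_line = d_line == 0
    # continuity of the limit at the line itself
    dec_val = np.where(on_line & (e_src > 0), 0.0, dec_val)
    dec_val = np.where(on_line & (e_src == 0), g, dec_val)
    out[decay] = dec_val[decay]

    out[r0] = np.minimum(1.0, (tune_alpha / n) * e_src[r0] + g[r0])
    return np.clip(out, 0.0, 1.0)


def energy_tune_auto(
    g: np.ndarray,
    e_src: np.ndarray,
    r0: np.ndarray,
    d_src: np.ndarray,
    d_t: float = 15.0,
    tune_alpha: float = 1.0,
    tune_beta: float = 1.0,
) -> np.ndarray:
    """Automatic energy-tune (no standard line).

    Branches, in order of precedence per pixel:

    1. in R0                 -> ``min(1, g + (alpha/n) E)``,
    2. ``d_src > d_t``       -> ``max(0, g - beta E / (d_src - d_t))``,
    3. ``0 < d_src <= d_t``  -> ``g / (1 + d_src/d_t)`` (attenuation band;
       the boundary ``d_src = d_t`` belongs here, giving ``g/2``),
    4. otherwise             -> ``g`` unchanged.

    Output clamped to [0, 1].
    """
    g, e_src, r0, n = _check_tune_inputs(g, e_src, r0)
    d_src = np.asarray(d_src, dtype=np.float64)
    if d_src.shape != g.shape:
        raise ValueError("distance field must match the edge map's shape")
    if d_t <= 0:
        raise ValueError("d_t must be positive")

    out = g.copy()

    atten = ~r0 & (d_src > 0) & (d_src <= d_t)
    out[atten] = g[atten] / (1.0 + d_src[atten] / d_t)

    far = ~r0 & (d_src > d_t)
    with np.errstate(divide="ignore", invalid="ignore"):
        far_val = np.maximum(0.0, g - tune_beta * e_src / (d_src - d_t))
    out[far] = far_val[far]

    out[r0] = np.minimum(1.0, g[r0] + (tune_alpha / n) * e_src[r0])
    return np.clip(out, 0.0, 1.0)
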