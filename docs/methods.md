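# Methods

## Problem and model

Soft-tissue organs such as the pancreas share weak, partially absent
boundaries with adjacent organs of nearly the same CT intensity. Any
contour driven purely by image gradients — a fast-marching front or an
edge-based level set — crosses such a gap and floods the neighbour
("leakage" / oversegmentation). The hybrid method implemented here
couples two stages so that each covers the other's weakness:

* fast marching is cheap and topology-free but leaks through gaps; it is
  constrained by the **energy-decrement** rule, which sets the front
  speed to the speed map's minimum within a distance `T_d` of a
  user-drawn *standard line* separating the organs (`E_s = I_min` where
  `D_l < T_d`, else the sigmoid speed);
* the level set refines the boundary accurately but needs a good
  initialization and an edge map that actually stops it; it receives the
  fast-marching region `R₀` as its initial contour and an **energy-tuned**
  edge map `E_t` in which the coupling area is decayed to ~0.

The tuning treats `R₀` as an energy source: every pixel receives
`E(p) = Σ_{q∈R₀} exp(−|p−q|/σ)·g(q)` with `g = 1/(1+g_m²)` the edge
indicator of the denoised image. With a standard line, pixels closer to
the line than to the source are decayed by `max(0, g − βE/D_l)` (with
the `D_l = 0` limit taken as 0 when `E > 0`); without a line, pixels
beyond a distance `D_t` from `R₀` are decayed by `max(0, g − βE/(D_r−D_t))`
and the band `0 < D_r ≤ D_t` is attenuated by `1/(1+D_r/D_t)` (the
boundary `D_r = D_t` is assigned to the attenuation branch — it halves
`g` there — because the decay branch is singular at that distance).
Inside `R₀`, `g` is enhanced by `(α/n)E`, clamped to 1.

The level-set evolution is the distance-regularized form: the double-well
potential `p(s)` (wells at `s = 0` and `s = 1`) penalizes `|∇φ|` so the
function keeps a signed-distance-like profile near the contour without
any reinitialization; the explicit update is

    φ ← φ + τ·[ μ div(d_p(|∇φ|)∇φ) + λ δ_ε(φ) div(E_t ∇φ/|∇φ|) + α E_t δ_ε(φ) ]

with `d_p(s) = p′(s)/s` (limit 1 at 0), `δ_ε`/`H_ε` the cosine-smoothed
delta/step of half-width `ε`, central differences and replicate borders.
Phase 1 runs with `α = −1` (the inside-negative region expands); phase 2
drops the area term so the edge term settles the contour in the valley
of `E_t`.

## Parameters

| name | default | units | rationale |
| --- | --- | --- | --- |
| MCDE conductance `K` | 10 | intensity | above the noise-gradient scale (σ=5 noise → gradients ≈ 4–6) and well below organ-edge gradients (≈ 30–80), so the conductance `exp(−(|∇I|/K)²)` diffuses noise and freezes edges |
| MCDE time step / iterations | 0.125 / 10 | – | 0.125 is the 2-D explicit stability bound commonly used for this filter; 10 iterations give a diffusion length of ≈ 2 px |
| gradient σ | 1.0 | px | resolves 2-px interfaces without merging the two organ rims |
| sigmoid `α`, `β` | −0.5, 3 | intensity/px | reported working point: speed ≈ 1 below gradient 2, ≈ 0 above 4 |
| `T_d` | 3 | px | decrement band just wide enough to cover the inter-organ gap plus one pixel of each rim |
| source σ | 10 | px | decay length comparable to the organ-gap scale in axial CT |
| `D_t` | 15 | px | trusted corridor around `R₀`; beyond it the level set has no business going when `R₀` is a good initial estimate |
| tune `α`, `β` | 1, 1 | – | unit weights; the decay branch is already dominated by the source energy `E` (hundreds near `R₀`) |
| `t*` | 100 (study: 60) | time | the interactive knob; in the phantom study 60 ≈ 1.5× the organ's minor semi-axis floods the interior and stalls at boundaries, so the snapshot is insensitive to the exact value |
| `μ, λ, α, ε, c` | 0.2, 5, −1/0, 1.5, 2 | – | reported working point of the two-phase scheme |
| τ (level set) | 1.0 | – | largest round value satisfying the stability requirement `μτ < 0.25` |
| iterations (inner/outer) | 40 / 15 | – | mid-points of the reported working ranges 20–60 and 10–20 |
| updates per iteration | 10 | – | see below |
| cleanup radius / min component | 2 px / 20 px | – | smooths 1–2 px boundary noise without moving the boundary; drops speckle but keeps any genuine leak visible to the metrics |

**Iteration semantics.** One bare explicit update with `τ = 1` moves the
contour by only a few hundredths of a pixel (the forcing acts inside the
`|φ| < ε` band and is rate-limited by the regularizer un-pinning pixels
ahead of the front). Reference implementations of distance-regularized
level sets therefore wrap a block of explicit updates in each "iteration",
and quoted iteration counts of a few tens correspond to hundreds of
updates. This package follows that convention with 10 updates per
iteration: defaults 40/15 iterations = 400/150 updates, under which
phase 1 traverses the ~10 px from the initial region to the boundary and
the leakage phenomenology (below) is actually expressible.

## The phantom

Two ellipses (semi-axes 118×40 and 122×40 px on a 256² grid) sit side by
side with a 1–2 px gap along a ≈ 55-row shared interface; intensities
120 / 110 over background 40, additive Gaussian noise σ = 5. A
contiguous central block of `round(gap_fraction × 55)` interface rows is
*fractured*: the intensity is linearly blended across the gap over
±16 px, so the local transition gradient (≈ 0.3 intensity/px) falls far
below the intact interface's (≈ 40). Ground truth is organ A's exact
ellipse mask; ≥ 3 seeds lie well inside it; the standard line traces the
mid-gap with vertices every 5 rows.

The facing boundaries are deliberately long: the fractured section must
be wide relative to the curvature-bridging scale of the level set
(`λ = 5` bridges gaps narrower than ≈ 10–15 px), otherwise the fracture
is not a functioning leak path and the phantom would not pose the
problem the method exists to solve. With gap fraction 0.3 the fracture
spans 16 rows and an untuned evolution demonstrably leaks through it.

What the phantom does **not** model: textured organ interiors, streak
and beam-hardening artefacts, Poisson noise statistics, anatomical shape
variability, and multi-organ surroundings. Passing the phantom study
shows the mechanics of the method (front stalling, energy decay,
leak blocking, boundary refinement) — not clinical accuracy.

## Numerical choices

* Eikonal solver: heap-ordered fast marching, first-order Godunov upwind
  on the 4-connected grid; the 8-neighbourhood of every seed is
  initialized with exact local distances (removes the O(1) diagonal
  error of the first ring). Zero-speed pixels are hard barriers (`+∞`).
* `|∇φ|` is regularized by `+1e−10` under the square root only in the
  curvature term's denominator; `d_p` uses the raw modulus with its
  analytic limits, so an exact unit-slope plane is bit-stationary.
* The sigmoid's exponent is clipped at ±709 so the asymptotes saturate
  without overflow.
* Source energy is an exact O(N·|R₀|) sum, evaluated in pixel chunks;
  restricting the source to `R₀`'s boundary is available but off by
  default (it is an approximation).
* Thresholding uses `φ < 0`; the `φ = 0` set has measure zero in
  practice.
* Degenerate inputs are rejected with messages: empty seed sets or
  source regions, non-finite images, unstable time steps, out-of-grid
  annotations, empty gold standards.

## Behaviour of the gradient-modulus profile

After phase 1 the level set keeps `|∇φ| ≈ 1` near the zero crossing
(mean deviation ≈ 0.20 within 2 px of the contour on the phantom) — the
property that makes reinitialization unnecessary. Away from the contour
the double-well's `s = 0` well keeps the function flat at the plateau
values `±c = ±2`, so any statistic taken over the *level band*
`|φ| ≤ 2ε = 3` — which with `c = 2` is the entire grid — is dominated by
the plateaus and reports a large deviation (≈ 0.97). Both numbers are
emitted by `scripts/acceptance.py` (`sdf_dev_near_contour_phase1`,
`sdf_dev_level_band_phase1`).

## Known limitations

* Strictly 2-D; volumes are processed slice by slice with a slice index.
* `t*` is user-chosen; no automatic stopping rule for the front.
* The automatic (line-free) variant inherits any leak already present in
  the fast-marching region: the tune protects and grows the initial
  region, it cannot retract it. With a standard line the decrement
  prevents that leak at the source.
* The exact source-energy sum is O(N·|R₀|) (seconds at 256²; minutes at
  512² — use `boundary_only` there).
* Single standard line; multi-line coupling areas are out of scope.
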