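# Model and methods

## The model

`sproutfield` simulates the growth of a single capillary sprout in two
dimensions with a phase-field (diffuse-interface) description.  A
conserved order parameter φ(r) distinguishes capillary (φ = +1) from
extracellular matrix (ECM, φ = −1); the capillary wall is the φ = 0 level
set, resolved over an interface width ε.  Values above 1 encode locally
proliferated endothelial matter.  Three coupled fields evolve:

**Order parameter.**

    ∂φ/∂t = M { ρ_φ ∇²(−φ + φ³ − ε²∇²φ)
                − μ₁ ∇²( Σ_ij (∂_ij w)² − (∇²w)²/d )
                − (α/L₀) [ ∇²χᵗ + 2μ₁ Σ_ij ∂_ij( φ ∂_ij w − δ_ij φ ∇²w / d ) ] }
            + α_p(V, φ, w)

The first bracketed term is conserved Cahn–Hilliard dynamics: it penalizes
interface area (a surface tension σ ∝ ρ_φ·ε) and keeps the two bulk phases
at φ = ±1.  The second is the rigidity-mismatch drive: the bracket is the
squared deviatoric strain of the tissue, and because the capillary is
softer than the ECM (contrast μ₁ > 0), endothelial matter lowers elastic
energy by occupying strained regions.  The third couples the cell-cell
adhesion α and the tip-cell traction potential χᵗ to the interface; its
sign is fixed so that the traction potential attracts vessel matter (see
"Sign conventions" below).  All three are total divergences, so ∫φ dA
changes only through the proliferation source α_p.

**Tissue mechanics** are quasi-static: the zeroth-order displacement field
is a potential flow u⁰ = ∇w with

    L₀ ∇²w = −α(φ − φ_ECM) + χᵗ ,   φ_ECM = −1,

solved at every time step.  The uniform source contributed by the pure-ECM
state (and the residual mean source) is gauged away: a spatially uniform
source has an isotropic parabolic potential with zero deviatoric strain
that cancels identically in both elastic terms, and removing it makes the
all-Neumann (mirror-boundary) problem solvable and the far field
strain-free.  Pinning w on any boundary instead forces the vessel's net
adhesion source to exit through that side as a flux whose discrete kink
registers as large spurious deviatoric strain and nucleates vessel matter
at the domain edge.

**Tip cell.** The tip is represented purely by its traction potential: a
radially symmetric C¹ bump χᵗ = A·cos²(πρ/2) (ρ = distance/radius) of
radius 5 μm — the radius of an endothelial cell — and peak amplitude A (the
maximum traction, study range 0–6 kPa).  Every t_cell ≈ 5 min the sprout
front is re-detected on the interpolated φ = 0 level set (the crossing
within a 15 μm search radius that is most advanced along the local VEGF
gradient) and the potential is re-centred there.  An optional forward
anisotropy A(θ) = (1 + cosθ)/2 is available but off by default: it halves
the effective drive and suppresses elongation at the study amplitudes.

**VEGF.** The angiogenic factor diffuses and is consumed by the vessel,
∂V/∂t = D_V∇²V − α_V·V·φ·Θ(φ), with V = 1 held at the hypoxic right
boundary and no-flux elsewhere.  Diffusion is fast compared with cell
movement, so the simulator uses the quasi-steady profile, obtained by a
direct sparse solve of the (linear) steady equation and refreshed at
tip-relocation events.  The iterative relaxation route prescribed by the
quasi-steady argument is also implemented and agrees with the direct solve
to the iteration tolerance.  Defaults D_V = 3.6·10⁴ μm²/hr (≈10⁻⁷ cm²/s)
and α_V = 180 hr⁻¹ give an absorption length √(D_V/α_V) ≈ 14 μm, chosen so
the quasi-steady level at the parental vessel is low but nonzero (~0.1
relative to the hypoxic boundary — the scale of the V_m = 0.05 trigger)
and the concentration grades several-fold across one sprout length; a
weaker consumption leaves V nearly saturated everywhere and collapses the
four proliferation-regulation scenarios onto the same behavior.

**Proliferation.** The local stretch proxy is s = α(1 − φ) + χᵗ (kPa): it
vanishes in a force-free confluent capillary and grows where cell density
drops below confluence or the tip pulls.  Four regulation scenarios map
(V, s) to a local rate: linear in s up to M_P at the limit strain L_S
(optionally gated by V > V_m = 0.05), or linear in V up to M_P at the limit
concentration L_V (optionally gated by s > S_m = 0.05 kPa).  Rates are
generated only by endothelial matter (φ > 0) and averaged over a
cell-sized disc (radius 5 μm), giving the source α_p ∈ [0, M_P].

## Numerics

Space: node-centered uniform grid, 5-point Laplacian, 4-point cross stencil
for the mixed derivative, all second order.  No-flux boundaries use
half-point reflection (ghost = boundary value), which makes every no-flux
operator symmetric and exactly sum-conserving.  The Poisson solves (w, and
the implicit part of the time step) use fast diagonalization: the separable
operators are eigendecomposed once per grid and each solve is four small
dense matrix products, verified against dense direct solves to 1e−10.

Time: the default integrator is semi-implicit (IMEX) — the stiff
fourth-order surface operator M·ρ_φ·ε²·∇⁴φ is treated implicitly in the
mirror-Laplacian eigenbasis, everything else explicitly.  The implicit
factor is 1 on the constant mode, so conservation is untouched.  Explicit
Euler (the reference scheme) is available via `scheme="explicit"`; the two
agree to the splitting error at matched dt.  Step bounds, fixed by an
empirical stability sweep at the reference resolution:

    explicit:      dt = 0.1 · h⁴ / (8 M ρ_φ ε²), capped by the
                   second-order estimate h²/(2M(3ρ_φ + μ₁ + α))
    semi-implicit: dt = 0.25 · h² / (M (3ρ_φ + μ₁ + α))

Within one step: solve w → advance φ → (every t_cell) relocate the tip,
rebuild χᵗ and refresh V.  Divergence (|φ| > 5 or non-finite values)
aborts with a partial trajectory.

## Parameters, units and calibration

Lengths μm, time hours, stresses kPa.  The stated physical inputs are the
ECM Young's modulus E = 3.0 kPa and Poisson ratio ν = 0.13, the tip radius
and peak traction, t_cell, and the proliferation cut-offs.  The remaining
constants are not stated numerically in the available text and are
reconstructed as follows (all config-exposed):

- **L₀ = 1.83 kPa** — order of the p-wave modulus (compressibility plus
  rigidity) averaged over vessel and ECM, from (E, ν) with the vessel
  carrying 20% of the ECM rigidity.
- **μ₁ = 3.2 kPa** — the rigidity-mismatch drive coefficient.  The naive
  shear-modulus contrast from (E, ν) is ≈1.1 kPa; at that value the
  traction field can only extend a sprout ~12 μm before stalling, far
  short of the reference behavior.  μ₁ is therefore treated as the main
  drive calibration constant (still of tissue order, kPa), set jointly
  with ρ_φ — see below.
- **ρ_φ = 0.58 kPa** — free-energy density scale.  Sets the surface tension
  σ ∝ ρ_φ·ε that the calibration trades off against μ₁: it determines the
  maximum length of a non-proliferating sprout.
- **M = 45 μm²/(kPa·hr)** — mobility, the single timescale.  Isolated-cell
  migration speed saturates in M (the wall equilibrates within each t_cell
  interval), so M is set in the saturated regime; the resulting detached
  cells migrate at ~4–6 μm/hr, covering the observed ~230 μm over the
  multi-day course of an explant assay.
- **ε = 2 μm**, h = 1 μm at reference resolution (interface spans ≥ 2
  cells); the initial vessel is a 10 μm-wide slab with a tanh wall profile
  against the left boundary; domain 150 × 100 μm for single runs.

The joint (μ₁, ρ_φ) calibration targets the two reference behaviors at
maximum traction 3.0 kPa: at adhesion α = 0.31 kPa the sprout must stay
intact through 14.5 hr, reaching its effective maximum length (~27 μm
here; the reference value is ~40 μm) with front velocity decaying below
2 μm/hr before 8 hr, while at α = 0.47 kPa the tip must break away.  The
breakage boundary is a genuine phase boundary and is extremely sensitive
to the reconstructed constants; the calibration picks the point that
reproduces the ordering and timing of breakage, accepting that absolute
intact lengths come out ~30% short (every probed parameter set that
reaches further crosses the breakage boundary at α = 0.31 instead of
lengthening).

## Sign conventions

The adhesion/traction coupling term is implemented with an overall minus
sign relative to a naive external-work bookkeeping, i.e. the traction
potential *attracts* endothelial matter.  This is empirically decisive:
with the opposite sign the tip digs a cavity at its own centre, no
elongation is ever possible, and the strain field contradicts the
localization of proliferation behind the tip.  With the implemented sign,
the bump pulls the wall forward, the stalk behind the tip carries positive
strain s (the quantity the proliferation triggers threshold on), and the
velocity-decay / maximum-length / pinch-off phenomenology all emerge.

## Breakage detection

Breakage is recorded in three observable forms, whichever comes first:

1. **split_detected** — more than one endothelial body (connected region
   of φ > 0, after discarding specks below half a cell area, π(2.5 μm)²)
   for 3 consecutive t_cell checks.  The persistence gate exists because
   the φ = 0 level set can pinch for a single 5-min interval at the neck
   and immediately re-heal while the material density there stays ≈ 0.5.
2. **sprout_lost** — no interface within the search radius of the tip:
   the detached cell the tip was following dissolved or escaped.
3. **front_collapse** — the measured length falls below half of its
   running peak after exceeding 10 μm: the signature of a shed tip cell
   that dissolves before the persistence gate can fire at this interface
   resolution.

`Trajectory.broke` is the union and is what the morphology classifier
uses for the "split" class.

## Morphology classes

Five labels reproduce the phase-diagram colour code: split (breakage as
above), slow (final length < 60 μm — the one stated threshold), then
thick_parental (parental slab width grew by > 1.5×), deformed (base/tip
width ratio > 2, or an interior bulge exceeding both ends by > 50%), else
well_formed.  The width profile excludes the first half-cell beyond the
parental wall and the rounded 5 μm tip cap.  All thresholds beyond the
60 μm cut-off are package choices, config-exposed; the original assignment
was by inspection.

## Desk-scale (coarse) presets

The sweep drivers default to h = 2 μm, ε = 4 μm on a 160 × 100 μm domain,
roughly 25× cheaper per run than reference resolution.  The doubled
interface width changes the effective constants, so the preset is
re-compensated to preserve the reference behavior at the study point
(ρ_φ = 0.3, μ₁ = 4.5: intact sprout at adhesion 0.31 kPa, breakage at
0.47 kPa).  Classification thresholds are compensated likewise
(`COARSE_THRESHOLDS`): sprout lengths roughly halve (slow cut-off 60 →
30 μm), every scenario shows baseline parental-wall growth from the
fattened proliferating band and all sprouts share the same smooth taper,
so the triangular back-widening of strain-regulated runs is read from
intermediate parental growth (ratio 2.5–5.5 → deformed) while only the
area-wise interior proliferation of the VEGF-graded mode exceeds 5.5×
(→ thick_parental); the shape-based taper/bulge tests are disabled at
this resolution.  Phase diagrams use 6×6 grids over M_P × L_S or
M_P × L_V (reference sampling is denser), the traction × adhesion sweep
defaults to 64 random points (reference: 640), and VEGF is refreshed
every third relocation.  These sizes are chosen so the full acceptance
reproduction completes on a laptop core in tens of minutes.

## What the synthetic data does and does not emulate

Test fixtures (slabs, kinks, blobs, fingers, triangles, band-limited random
fields) are generated programmatically and exercise the operators and the
classifier on known geometry.  The simulator itself is deterministic;
randomness exists only in sweep sampling.  None of this emulates real
microscopy: no imaging noise, no 3-D lumen structure, no multi-sprout
interactions (Notch-mediated tip selection is out of scope), and the ECM
is a homogeneous isotropic continuum.  Passing tests validate the
mathematical model and its implementation, not agreement with any
particular wet-lab preparation.

## Known limitations

- The breakage boundary's absolute position in the (traction, adhesion)
  plane depends on the reconstructed elastic constants; only its existence,
  orientation (breakage at high traction × adhesion) and the ordering of
  breakage times are robust here.
- Detached cells at ε = 2 μm are marginally resolved: they migrate but
  slowly shrink, so long free-cell migration distances are represented by
  the front-collapse signature rather than a persistent travelling cell.
- Intact maximum sprout lengths at the reference adhesion come out ~30%
  below the reference value (~27 vs ~40 μm); pushing the drive higher
  moves the run across the breakage boundary instead of lengthening it.
- The quasi-steady VEGF approximation and the relocation-cadence refresh
  are good to the extent the vessel moves ≪ the VEGF decay length per
  t_cell, which holds at all study parameters.
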