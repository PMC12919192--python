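# Methods

## Model

The cell is a half ellipsoid attached to a rigidly-coupled elastic membrane
along its basal plane z = 0, with an ellipsoidal nucleus embedded in the
cytoplasm. Default dimensions are explicit placeholders at the scale of a
spread mesenchymal stem cell — cell semi-axes 25 × 15 × 6 µm, nucleus
8 × 6 × 3 µm centered at (0, 0, 3) µm — and are config-overridable; with
these defaults the nucleus touches the basal plane tangentially (allowed,
with a warning; a nucleus crossing below z = 0 or the cell surface is
rejected). x is the long axis, y the short in-plane axis, z vertical.

Each bulk compartment is a Kelvin-Voigt solid described by a scalar
elasticity E and viscosity η. The 3D realization is stiffness-proportional:
σ = C(E, ν) : ε + τ C(E, ν) : ε̇ with a single relaxation time τ = η/E per
compartment. This is the simplest isotropic extension consistent with the
scalar pair (a deviatoric-only viscosity would be the main alternative; the
proportional form keeps the 1-D creep/oscillation closed forms exact per
compartment and is what the verification oracles assume). Defaults, from
experimental literature on adherent cells:

| compartment | E (Pa) | η (Pa·s) | τ = η/E (s) | ν |
|---|---|---|---|---|
| membrane (shell, 10 nm) | 2980 | 4010 | 1.35 | 0.45 |
| cytoplasm | 4000 | 5430 | 1.36 | 0.45 |
| nucleus | 2010 | 970 | 0.48 | 0.45 |

Poisson ratios are not part of the published compartment data; ν = 0.45
everywhere reflects near-incompressibility while staying well-posed in a
displacement formulation (ν = 0.5 exactly is not representable). The
membrane is not meshed volumetrically — a 10 nm shell at 25 µm cell scale
is unmeshable — but enters as plane-stress constant-strain triangles on the
outer curved facets, scaled by thickness, with the same proportional
damping. At these parameters the shell contribution is mechanically minor
(kPa × 10 nm ≪ kPa × µm of bulk).

Inertia is neglected: at ≤ 1 Hz loading, cellular mass effects are many
orders below the viscoelastic forces, so time stepping integrates the
first-order system K u + D u̇ = f.

Kinematics are small-strain. At the top of the sweep (17.5 %) this is a
stretch of the assumption; it is retained deliberately because the model
family is linear — the amplitude sweep then collapses onto one solution per
(waveform, frequency) up to scaling, and the reported amplitude-independence
of the X/Y strain ratio is exact rather than approximate.

## Loading

Waveforms are non-negative (stretch rigs cannot push the membrane into
compression) and start at zero strain, so the initial state is undeformed:

* sine: ε(t) = ε_max (1 − cos 2πft)/2;
* brachial: ε(t) = ε_max s(frac(ft)) with s a tabulated normalized pulse,
  interpolated monotone-cubically (PCHIP; no overshoot above ε_max).

The packaged brachial shape is a **synthetic stand-in** for a brachial-artery
distension waveform: two wrapped Gaussian lobes (systolic peak near 0.33 T
after rolling the diastolic minimum to t = 0, dicrotic bump near 0.58 T,
long diastolic decay), normalized to unit peak and periodically closed. Any
two-column `t_frac,amplitude` CSV can replace it (`waveform.shape_file`).
Results labeled "brachial" inherit this approximation.

Substrate coupling is perfect: every basal node follows
u = (ε(t) x, ε_y(t) y, 0), with ε_y = ε (equibiaxial, the default) or
ε_y = r ε (anisotropic mode, r ∈ [−0.5, 1]). All other surfaces carry only
the membrane-shell terms.

## Numerics

**Meshing.** The half-ellipsoid domain is convex, so the mesh is the
Delaunay triangulation (scipy/Qhull) of a deterministic graded point cloud:
quasi-uniform Fibonacci-lattice point sets on the outer surface, basal rim,
basal disk and nucleus surface, thinned to the local target size with an
additional chord cap of 0.55 × the local minimum curvature radius (keeps
the faceted boundary within the 2 % volume contract at coarse sizings), plus
Halton interior points thinned Poisson-disk-style. Element size grows
linearly from `h_refined` at the nucleus/membrane surfaces at rate
`growth_rate − 1` up to `h_max`. Tets are labeled nucleus/cytoplasm by
centroid; since points are sampled on the nucleus surface the labeled
interface tracks the ellipsoid to within one local element. Degenerate
(coplanar) slivers are dropped; all retained tets are positively oriented.
No randomness anywhere: meshes are bytewise reproducible.

Reference sizing is h_max = 0.99 µm, growth 1.4, h_refined = 0.159 µm
(`--profile fidelity`). The desk-scale profile used by the test suite, the
default CLI sweep and the acceptance script is h_max = 2.5 µm,
h_refined = 1.0 µm (~2 600 nodes, ~11 000 tets, 7 770 degrees of freedom);
halving h_max from a 5 µm baseline moves the peak volume-averaged nuclear
strain by ~1.3 %, so the desk-scale profile is inside the 5 % convergence
band the package promises.

**Time stepping.** Backward Euler by default; a generalized-α scheme for
first-order systems (spectral-radius parametrization, ρ∞ = 0.85) is
available. The step is dt = T / steps_per_cycle with steps_per_cycle ≥ 50
enforced (dt ≤ T/50). Dirichlet constraints are eliminated (not penalized),
the constrained operator A = α_f K + c_v D is factorized once per
(dt, constraint pattern) with SuperLU and reused across all steps and sweep
entries; direct solves leave relative residuals at ~1e−12, far inside the
1e−3 contract.

**Stress evaluation.** Strain histories are reconstructed from stored
displacements; the viscous stress needs ε̇, which is evaluated by central
differences of the strain history (second order, one-sided at the ends)
rather than the integrator's backward difference. This removes the half-step
phase bias and is what lets a single-element oscillation test reproduce the
analytic amplitude √(E² + (ωη)²)·ε₀ and phase lead arctan(ωη/E) to ~0.01 %
at 200 steps/cycle.

**Reductions.** Volume averages are Σ V_e v_e / Σ V_e over labeled tets.
Per-cycle peaks are signed extrema of largest magnitude within each cycle
window (so compressive z peaks are negative); the headline X/Y ratio uses
final-cycle peaks; a zero y-peak flags the ratio undefined instead of
returning infinity. Steady state is declared at the first cycle whose peaks
stay within 1 % (relative) of the final cycle for all components.

**Chromatin ODE.** ε̇_c = −(E/η) ε_c + σ(t)/η is integrated with the exact
exponential update for piecewise-linear σ (machine-accurate for that input
interpolation; a backward-Euler fallback exists for cross-checking, and the
two agree to < 0.1 % at solver resolution). The published viscous constants
are printed as dashpot constants (N·s/m), which is dimensionally
inconsistent with a strain-rate equation driven by stress in Pa; they are
used numerically as Pa·s, preserving the source model's dynamics — only
η/E and σ/E enter. Fold extension is 1 + ε_c, so "double native length"
is ε_c = 1. The driving stress is the volume-averaged nuclear σ_xx by
default (chromatin deformation is reported along x); von Mises and the
other normal components are selectable.

## Calibration of the anisotropic mode

Under equibiaxial loading the default geometry yields an X/Y nuclear strain
ratio of ~1.2 — a modestly eccentric cell cannot produce a strongly
uniaxial nuclear strain state from symmetric in-plane stretch. Because
published descriptions of this configuration report strongly uniaxial
ratios (≈11 for 0.1 Hz sine loading), the anisotropic mode exposes the
loading-mode ambiguity, and its default ratio r is calibrated once, at the
desk-scale profile, so that the sine 0.1 Hz ratio is ≈11: **r = 0.183**
(achieved ratio 10.97). The calibration exploits linearity: histories at
r = 0 and r = 1 span all r, and the crossing is solved directly. With r
fixed, the brachial ratio is a prediction, 9.0, and the frequency trend is
too (1 Hz gives 9.1 / 7.9 — more biaxial than 0.1 Hz, as expected when
viscous phase shifts weaken the near-cancellation in y). The predicted
brachial ratio remains well above the reported ≈3.5; a ratio drop of that
size between waveforms of identical amplitude cannot be produced by this
linear model's frequency response alone and most likely reflects geometry
details (and the true brachial shape) that are not published.

## What the defaults emulate — and what they do not

The default sweep grid (sine + brachial, 0.1/1 Hz, ε_max 2.5–17.5 % in
2.5 % steps, 10 cycles, 50 steps/cycle) is the standard conditioning
protocol family this model targets. The synthetic elements are the cell and
nucleus dimensions (placeholders at MSC scale) and the brachial pulse shape
(stand-in). Passing tests therefore demonstrate correct viscoelastic
mechanics, correct reductions and a faithful chromatin map for *a* generic
adherent cell — not a quantitative reproduction of any particular cell
line's nuclear strains, which are sensitive to the real geometry, adhesion
footprint and anisotropy of the loading.

Two model-level consequences deserve emphasis:

* With perfect basal coupling and the nucleus adjacent to the substrate,
  nearly all applied strain reaches the nucleus (mean nuclear ε_xx ≈ applied
  ε). Mean nuclear σ_xx at 7.5 % strain is then ~10² Pa, and the upper-bound
  chromatin estimate (all of it on one E = 3.82 Pa chromosome) saturates
  far above the 2–3× unfolding window (fold ≈ 37 at 7.5 %). The *relative*
  structure — linear amplitude scaling, interphase accumulation over cycles
  at 1 Hz versus rapid settling at 0.1 Hz, mitotic folds ~25× lower and
  sub-threshold throughout — is robust; the absolute fold values should be
  read as upper bounds with the transmission caveat attached.
* Transients at 0.1 Hz are tiny (compartment relaxation times of ~0.5–1.4 s
  against a 10 s period), so per-cycle peaks settle within ~0.1 % after
  cycle 1; at 1 Hz the first cycle visibly overshoots (x-peak ≈ 4 % above
  steady state) and the approach to the oscillatory steady state is
  exponential-type and monotone after cycle 2. The vertical (z) strain at
  0.1 Hz shares the tiny first-cycle overshoot of x and y rather than
  growing from below; models with longer effective relaxation times would
  show the opposite sign of that (sub-0.1 %) transient.

## Degenerate inputs and tie-breaks

A rotationally symmetric cell (a_x = a_y) is allowed but flagged: X/Y ratio
analyses are degenerate. A nucleus tangent to the basal plane is allowed
(warning); crossing it is not. All-zero waveform shape tables, open
(non-periodic) tables and non-monotone time fractions are rejected.
Per-cycle extrema resolve ties by the first occurrence (argmax of |·|).
Sweep runs execute in sorted (waveform, frequency, amplitude) order
regardless of config order, making outputs permutation-invariant and
byte-identical across repeated executions; a failed entry is recorded in
the manifest without aborting the sweep.

## Known limitations

Small-strain linear kinematics at up to 17.5 % stretch; no active
contractility, adhesion remodeling or focal-adhesion-resolved attachment;
the substrate is not modeled as its own elastic body (perfect coupling);
membrane bending stiffness is not included (in-plane shell only); chromatin
estimates are upper bounds driven by one stress component; the brachial
shape is a documented stand-in; constant material properties over the
loading (no mechano-adaptation).
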