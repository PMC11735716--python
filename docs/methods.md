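# Methods

## Orientation conventions

A domain's placement in the filament system is a rotation decomposed in
the z-y-z Euler convention, R = Rz(α) Ry(β) Rz(γ), acting on a molecular
basis M = [ref_perp, axis×ref_perp, axis]. The azimuth α about the
filament axis is unobservable in a cylindrically symmetric sample and is
never reported. β ∈ [0°, 180°] is the angle between the domain reference
axis (oriented N→C) and the filament +z axis (+z toward the pointed end
of actin); γ ∈ (−180°, 180°] is the rotation about the domain axis,
counterclockwise when viewed from the C-terminal end. Dipole probes
cannot distinguish (β, γ) from (180°−β, γ±180°); the canonical
representative has β ≤ 90°, and every peak list and comparison folds to
it.

The zero of γ is a convention. For frames fitted from coordinates, the
filament frame's γ=0 direction is the radial vector from the filament
axis toward the domain origin, and the molecular γ=0 witness is the
perpendicular component of the vector from the domain-axis origin to a
designated reference helix origin (for helix-only frames, to the first
Cα). Comparisons of γ across methods therefore require one global offset
per domain type, calibrated once against a single designated reference
entry and then frozen; all other entries are predictions. β requires no
calibration.

## Axis fitting

* **Helix axis**: weighted running average of the Cα trace with kernel
  [1, c, c, 1], c = −cos(3t/2)/cos(t/2) at the α-helical twist t = 100°/
  residue. This kernel nulls the helical phasor exactly, so the smoothed
  curve lies on the axis for an ideal helix; the axis is the principal
  (SVD) direction of the smoothed curve, oriented N→C. Minimum five
  residues. Under 0.3 Å isotropic coordinate noise on a 12-residue helix
  the axis error is ≈1° on average (measured by the acceptance script).
* **Coiled-coil axis**: normalized mean of the two co-oriented helix
  axes; axes more than 60° apart are rejected as not a coiled coil.
* **Filament axis**: principal direction of subunit (chain) centroids,
  signed toward the pointed end, which is named by configuration (the
  deposited thin-filament models are oriented pointed-end up; defaults
  follow that). Principal-axis fitting of centroids on a helical path is
  biased by incomplete turns — a fraction of a degree for ≥14 subunits —
  which is far inside the ±5° comparison band used for β.

Residue ranges for axis fits are configuration data (INI files), taken
from secondary-structure annotations of the reference structures, never
inferred from coordinates at run time.

## Photophysics

Order parameters of a probe under an orientation density f(β, γ) are
midpoint-rule quadratures with the sin β measure on a regular grid
(default 2°×2°; quadrature error < 10⁻⁴ there). Fast wobble (probe
motion faster than the fluorescence lifetime) multiplies each even rank:
observed = fast × slow. The two fast factors are tied by a one-parameter
wobble-in-cone model — the cap averages ⟨P₂⟩ = u(1+u)/2 and
⟨P₄⟩ = u(1+u)(7u²−3)/8 share the cone cosine u — and can be overridden
independently.

The polarised-intensity model is the package's own self-consistent
construction (the published analyses cite an external correction algebra
whose inputs are not reproduced here): absorption photoselects with
cos² of the angle between the excitation polarisation and the mean
dipole; emission through an analyser contributes
(1 + 2·p2_fast·P₂(cos η))/3 after azimuthal averaging of the fast wobble,
η the angle between analyser and mean dipole. Eight intensities
(excitation ∥/⊥ × emission ∥/⊥, on two illumination axes orthogonal to
the fibre) determine (⟨P₂⟩, ⟨P₄⟩, p2_fast) up to a common scale. The
inversion is a bounded 1-D search over p2_fast with an exact linear solve
inside; it is anchored by exact round trips through the forward model and
by the isotropic and parallel-delta limits. Rank-deficient data (only a
fully randomising fast wobble produces equal intensities everywhere) are
resolved to the maximum-entropy choice ⟨P₂⟩ = ⟨P₄⟩ = 0 via a tiny ridge.
Data outside the model's range space raise an error carrying the
relative residual.

Feasibility of a (⟨P₂⟩, ⟨P₄⟩) pair is decided by a linear program over a
0.5° polar-angle grid with a 10⁻⁴ slack absorbing the curvature of the
moment map between nodes.

## Maximum-entropy inversion

The ME distribution has the exponential-family form
f ∝ exp(Σⱼ λⱼ₂ P₂(cos θⱼ) + λⱼ₄ P₄(cos θⱼ)), with θⱼ(β, γ) the polar
angle of probe j's dipole. The multipliers minimise the convex dual
log Z(λ) − λᵀt (damped Newton with Cholesky solves and Armijo
backtracking, multipliers initialised at zero = uniform start).

Discretisation is handled explicitly. Order parameters generated by a
*single orientation between grid nodes* are extreme points of the moment
set and are not exactly representable on a finite grid. Target sets are
therefore classified by a linear program before solving:

1. exactly feasible (within 10⁻⁷) → hard constraints, Newton on the
   exact dual, convergence at 10⁻⁶ per order parameter;
2. feasible within a grid-curvature slack, 5·10⁻³·(Δ/2°)² for spacing Δ
   → χ²-relaxed dual (quadratic penalty, σ floor = slack/2), also used
   whenever measurement σ are supplied; convergence then means residuals
   within max(tol, 3σ_eff);
3. otherwise → `NoCompatibleOrientationError`, carrying the minimal L1
   violation from a second LP. This error is a finding, not a failure:
   no orientation distribution of the assumed fold reproduces the data,
   so the in-cell fold must differ from the input structure.

Peaks are strict local maxima above 50% of the global maximum (with a
10⁻⁹-relative tie slack so maxima centred between nodes are not
suppressed; exactly flat maps return no peaks), folded to the canonical
dipole branch and greedily merged within a 10° radius. The map width
reported by the resolution study is the effective diameter 2√(A/π) of
the half-maximum region, halved to count one dipole branch.

## Gaussian orientation model

A single-site wrapped Gaussian (β₀, γ₀, shared angular dispersion σ for
both angles — published refined models quote one dispersion number) is
fitted by nonlinear least squares on the order-parameter residuals,
multi-started from a deterministic coarse scan plus seeded random
starts. All local minima with misfit within 2× of the best are returned,
sorted by misfit then β₀ — probe sets with internal symmetry genuinely
have two solutions and these are never collapsed. Recovery bias is
< 2° at measurement noise s.d. 0.005 (50 seeds, measured by the
acceptance script).

## Hill titrations

Y = 1/(1 + 10^(nH(pCa−pCa50))), fitted by least squares in
(pCa50, log nH) from a deterministic start grid (pCa50 across the data
range × nH ∈ {1, 2, 4}). The variant without the "1 +" in the
denominator, which appears in some printed sources but has no
half-maximum at pCa50, is available behind `literal_form=True` and is
never fitted. Curves need ≥4 distinct pCa points.

## Synthetic fixtures

The generators emulate the study conditions the estimators assume:
ideal poly-alanine helices (rise 1.5 Å, twist 100°/residue, Cβ placed
radially at 1.53 Å — sufficient because only Cβ–Cβ *directions* enter
the dipole geometry); a five-helix toy domain whose probe dipoles are
spread over the sphere (pairwise axis separation > 25°); point-subunit
filament arrays at the actin geometry (rise 27.5 Å, twist −166.7°/
subunit) with chain order encoding polarity; order-parameter datasets
with i.i.d. Gaussian measurement noise (defaults 0.005–0.01, the scale
of replicate scatter in polarised-fluorescence work); titrations over
pCa 7.5–4.5 at pCa50 = 6.0, nH = 2.5. Identical parameters and seed give
byte-identical fixtures.

Not emulated: thermal ensembles and probe-linker dynamics, real
side-chain geometry, inter-domain flexibility, or background/bleaching
in intensities. Passing tests therefore demonstrate correctness of the
estimators under their stated statistical model, not robustness to
systematic errors of real measurements (dipole-attachment offsets,
fold differences between in-cell and reference structures) — the latter
surface as the documented infeasibility error instead.

## Problem sizes and numerical defaults

Default ME grid 2°×2° (90×180 nodes); resolution studies use 3° and a
few replicates; Monte-Carlo cross-checks use 10⁶ samples; noise studies
use 50 seeds. These sizes make the full test suite and the acceptance
script each run in well under a minute while leaving all measured
quantities comfortably inside their acceptance bands.

## Known limitations

* γ comparisons across methods are only defined up to the per-domain
  calibration offset; the designated calibration entry is part of the
  configuration, not the code.
* The intensity model is internally consistent but not a reproduction of
  any published instrument-specific correction; only order-parameter-level
  quantities should be compared across packages.
* ME maps inherit the grid: features narrower than the spacing are
  represented by the relaxed (σ-floored) solution, and multiplier
  magnitudes near extreme targets grow accordingly.
* The angle-table pipeline for deposited thin-filament entries depends on
  configured chain identities and helix ranges; these defaults could not
  be validated against every cited accession and should be checked per
  entry.
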