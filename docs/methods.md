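# Methods

This note records the models implemented in `densfunc`, the defaults and
why they were chosen, what the synthetic surrogate does and does not
emulate, and the numerical decisions that were genuinely open.

## Units and conventions

All internal quantities use one unit system: lengths in Å, energies in
kcal·mol⁻¹, masses in amu, time in fs. Conversions (bohr in cube headers,
atomic units of time for thermostat friction) happen only at file and
interface boundaries, with the constants defined once in
`densfunc.units` (1 bohr = 0.529177 Å; 1 a.u. time = 0.02418884 fs;
k_B = 1.9872041×10⁻³ kcal·mol⁻¹·K⁻¹). A friction of 0.01 a.u. is therefore
0.413 fs⁻¹.

Nuclear charges default to valence electron counts (H = 1, C = 4, N = 5,
O = 6), consistent with a frozen-core treatment in which the density being
modeled is the valence density; full atomic numbers are available via
`charge_mode="full"`.

Energy labels in a dataset are stored relative to the lowest low-level
energy in that dataset (the shift is retained for round-trips). This keeps
kernel-regression targets O(1–10) and makes errors directly comparable to
the chemical-accuracy yardstick of 1 kcal·mol⁻¹; high-minus-low
differences are unaffected.

## The potential descriptor

The input to the density map is the nuclear potential smeared by Gaussians
of width γ, sampled on a cubic grid. Distances between descriptors are
plain Euclidean norms over grid values; voxel-volume weighting is a
constant factor absorbed into the kernel width σ, which is tuned anyway.
Grids are fixed per dataset (molecule-centered on the aligned reference
frame), never per conformer — descriptor values are only comparable across
conformers when they share a frame and a grid. γ defaults to 0.6 Å for the
bundled systems; like σ it is a cross-validatable hyperparameter, not a
constant of the method. Grids should leave ≥ 3γ of margin between any atom
and the box wall; a warning is logged otherwise.

## The density basis

Densities are represented by coefficients in an orthonormal *real*
trigonometric basis on the box: f₀ = 1/√L, then paired
cosines/sines √(2/L)·cos(2πkx/L), √(2/L)·sin(2πkx/L) per dimension, with
3D functions as tensor products ordered by total frequency and then
lexicographically. A real basis spans the same band-limited space as
complex exponentials while keeping every per-coefficient regression real.
Two index sets exist: the full tensor product (`per_dim`³ functions) and a
total-frequency "ball" cutoff for trimming coefficient budgets. The widely
used configuration of 25 functions per dimension is quoted in the
literature alongside a total of 12,500 functions, which a full tensor
product (15,625) cannot produce; both modes are therefore provided and
neither guesses the unstated cutoff scheme.

Projection uses the plain voxel Riemann sum. On a uniform periodic-box
grid this is the trapezoid rule and is exact (to rounding) for integrands
below the Nyquist frequency; projection refuses grids whose sampling
cannot resolve the requested maximum frequency. Only the constant basis
function has a nonzero box integral, so the electron count is
u₀·L^{3/2} — a one-coefficient diagnostic used throughout the tests.

## Kernel ridge regression

All learned maps are Gaussian-kernel KRR in dual form, solved by Cholesky
factorization of K + λI. Defaults and their reasons:

- **λ = 10⁻¹⁰·tr(K)/M** (= 10⁻¹⁰ for a normalized kernel): scale-free
  jitter preserving near-interpolation. λ = 0 is allowed for exact
  interpolation on distinct inputs.
- **Prior mean**: zero for Δ-correction maps — predictions decay to *no
  correction* away from data, so the corrected total falls back on the
  cheap level rather than on nonsense; training-mean for direct energy
  maps — far-field predictions revert to the dataset mean.
- **Hyperparameter selection**: exhaustive (σ, λ) grid search under
  fivefold cross-validation, folds formed by a seeded shuffle followed by
  contiguous blocks (bit-reproducible). The σ grid is multiplicative
  around the median pairwise distance heuristic.
- **k-means training-set selection** picks, for each of k seeded k-means
  centers (k-means++ initialization, 300-iteration cap), the nearest
  unclaimed dataset member, ties broken toward the lowest index. The
  default feature space is the flattened potential descriptor.
- The HK map factorizes K + λI once and solves all L coefficient columns
  against it; per-coefficient independence is preserved exactly (verified
  against independent single-output fits). Its per-coefficient prior is
  the training-mean coefficient.

The repeated-shuffle protocol for small datasets shuffles the data
(seeded), holds out everything beyond the training pool, selects smaller
subsets by k-means, and reports mean/σ of the test MAE across shuffles —
e.g. a 102-record dataset with a 50-sample pool always tests on 52.

## The Δ-vs-direct comparison

The headline sample-efficiency comparison is run through the full
pipeline: the HK map is trained on the pool, and *both* energy maps are
trained and evaluated on HK-predicted coefficient vectors, with CV-chosen
kernel widths. This matters. With exact projected densities both maps
interpolate the smooth surrogate surfaces almost perfectly and the
comparison probes nothing; with predicted densities, density-prediction
error propagates into the direct map at the full energy scale but into the
Δ map only at the correction scale. That asymmetry — not any defect of
direct regression — is what makes the Δ route beat a 5× larger training
budget, and it is the mechanism the pipeline is designed around.

## Symmetry handling

Point-group detection enumerates candidate axes (principal axes, atom
directions, pair sums/differences, pair cross products), screens proper
and improper rotations up to order 6 plus reflections and the inversion
against the species-labeled point set (default tolerance 10⁻³ Å, optimal
assignment per species), polishes each survivor by orthogonal Procrustes,
and closes the set under composition. For planar molecules the point set
does not constrain the action along the plane normal, so the polish
completes the null-space sign from the candidate matrix — otherwise every
σh-type operation would collapse onto its proper partner and a hexagonal
ring would report 12 operations instead of 24. Detection is intended for
rigid point groups of small molecules (≤ 64 atoms); explicit operation
lists can be supplied instead.

Augmentation replaces each conformer by its orbit, copying energies
unchanged (they are group invariants) and recomputing descriptors and
densities from the transformed coordinates rather than rotating
coefficient vectors analytically — correctness over speed; the analytic
route is an optimization, not a semantic requirement. Geometric duplicates
(species-matched point sets within 10⁻⁴ Å after centroid removal) are
removed via a sorted-invariant sweep with cheap signature rejection before
exact assignment; duplicate geometries carrying labels that disagree
beyond 10⁻⁹ raise an error rather than silently averaging.

Alignment is Kabsch superposition on an atom subset (e.g. the carbon
skeleton), with the fitted rigid transform applied to all atoms.

## Dynamics

Forces default to central finite differences with ε = 0.001 Å — exact for
quadratics, second-order otherwise, and model-agnostic; analytic force
callables can be passed where they exist and are validated against FD in
the tests. Integrators: velocity Verlet (NVE); Langevin via BAOAB
splitting (best configurational accuracy at the 0.5 fs default timestep;
friction 0.413 fs⁻¹, temperature 350 K defaults), reducing exactly to
velocity Verlet at zero friction; and impulse r-RESPA — inner
velocity-Verlet steps on the cheap surface with the accurate-minus-cheap
force difference applied as symmetric half-kicks scaled to the outer step,
every `n_inner` = 3 steps by default. The impulse scheme is the canonical
reversible reference-system formulation consistent with periodic force
corrections; with identical surfaces it reproduces plain NVE exactly, and
with `n_inner` = 1 it collapses to NVE on the accurate surface.
Geometry optimization is L-BFGS on FD gradients until the largest force
component drops below 10⁻³ kcal·mol⁻¹·Å⁻¹ (default).

Two numerical lessons from optimization on learned surfaces are encoded in
the conformer-search protocol. First, optimization-grade Δ maps use a
stronger ridge (λ = 10⁻⁴) than interpolation-grade fits: a quasi-Newton
optimizer reliably finds and exploits the ringing of a near-interpolating
kernel fit between training points. Second, every geometry is rigidly
aligned to the dataset's reference frame before its density is computed.
The physical energy is invariant under rigid motions but the density
descriptor is not; without alignment an optimizer can translate or rotate
the molecule out of the training frame at zero physical cost and ride the
model into its extrapolation region, where a zero-prior correction
undershoots. The known-stationary-point geometries (the four torsional
minima) are included in the Δ map's training set, as a practitioner would
include them.

## The synthetic surrogate

The surrogate replaces external electronic-structure codes, not physics it
claims to predict. Low-level surfaces are harmonic bonds and angles plus
cosine torsion series with the minimum at the template geometry; the
high-level surface adds a smooth bounded correction: odd
a·tanh(d/w)·exp(−(d/2w)²) terms in bond displacement (short bonds
corrected down, stretched bonds up) and cosine terms in a torsion. The
correction magnitudes are calibrated so a thermally sampled ensemble shows
mean |high − low| in the 1–3 kcal·mol⁻¹ band with maxima around
5–7 — the error regime of a semilocal functional against coupled
cluster — and so the correction landscape has strictly smaller variation
than the total surface (the regime in which delta learning pays off). The
toy-water corrections use a 0.3 Å length scale, making them near-linear
over the thermal spread; the toy-ethanol correction acts on the soft
driving torsion only (amplitude 1.2, phase 0.3 rad), because a correction
mixing a short-length-scale bond term with a long-length-scale torsion
term is not learnable as a single-Gaussian-kernel functional of the
density at these training budgets. The O–H bond-correction variant of the
ethanol system (and a spatially coincident C–O–H fragment) exists for the
dataset-combination experiment, where a small molecule supplies extra
coverage of a coordinate it shares with a larger one.

Densities are superpositions of atomic Gaussians (SAD; widths H 0.35,
C 0.50, O 0.45 Å) integrating to the valence electron count, optionally
plus bond-midpoint Gaussians whose amplitude decays smoothly with bond
stretch, renormalized to the valence count — a stand-in for the bonding
rearrangement a self-consistent density would show. Energy labels carry no
stochastic noise: like real electronic-structure output they are
deterministic functions of geometry; the only randomness is seeded
conformer sampling. Z-matrix systems sample internal coordinates with
Gaussian widths √(E₀/k) at E₀ = 2 kcal·mol⁻¹ (ring systems use Cartesian
jitter), which makes 1000-sample ensembles span ≳ 10 kcal·mol⁻¹ with the
positive energy skew of soft modes.

What passing tests on the surrogate do *not* show: transferability to real
densities (plane-wave or Gaussian-basis valence densities are far more
structured than Gaussian superpositions), the cost profile of real
electronic structure, anharmonic couplings beyond the built-in terms, or
conformer distributions from actual force-field MD. The surrogate
validates the pipeline's statistical machinery — sample-efficiency
orderings, symmetry bookkeeping, integrator fidelity, fallback behavior —
not chemical accuracy for any real molecule.

## Problem sizes

Default experiment sizes were chosen so each pipeline stage completes in
seconds to a few minutes on one CPU: 32³ descriptor grids (48³ for
quadrature checks), 7 Fourier functions per dimension (343 coefficients),
ensembles of 60–120 conformers, 20-seed repetitions for orderings asserted
in the mean. All are parameters, not constants; the structure of every
result is unchanged under refinement, only runtimes grow.

## Known limitations

- Point-group detection does not handle continuous axes (C∞v) or orders
  above 6 by default (`max_order` raises it), and assumes near-rigid
  geometries.
- The energy-map kernel distance over u is plain Euclidean; with an
  orthonormal basis this is the L² distance between band-limited
  densities, but no basis-weighted alternative is implemented.
- Analytic coefficient rotation under symmetry operations is not
  implemented; augmented records recompute fields from transformed
  coordinates.
- The HK map predicts each coefficient independently; no covariance
  between coefficients is modeled.
- Self-consistent density refinement and explicit exchange-correlation
  functional forms are out of scope.
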