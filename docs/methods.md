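# Methods

`cytocrowd` rebuilds a pipeline from 2D micrograph statistics to 3D in
silico cytoplasm volumes and simulates obstructed diffusion in them, both in
continuous space and on a lattice. This note documents the models, the
defaults and why they were chosen, the numerical decisions, and the known
limitations.

## Image binarization and neighbor statistics

Electron-dense material (the "non-reactive obstacles", NRO) appears dark in
transmission electron micrographs. Images are binarized with the iterative
isodata threshold: a threshold `T` splits pixels into a dark class (≤ T) and
a bright class (> T); `T` is incremented until it first exceeds the mean of
the two class means. The iteration starts at the *minimum* intensity rather
than the image mean: for class-imbalanced images the mean already exceeds
the composite average, so a mean-started iteration would terminate
immediately at the mean and bias the threshold (for two modes at 50/200 with
37.6% dark pixels it returns ≈144 instead of the isodata fixed point ≈126,
inflating the dark fraction by ~0.008). Starting at the minimum makes the
result identical to an exhaustive scan for the first crossing. The increment
is 1 intensity unit for integer data with range ≥ 2, else 1/256 of the
range (histogram-bin stepping on 8-bit-like data).

From the binarized images three statistics drive volume generation:

* `cond3` — P(pixel black | states of the 3 preceding pixels on a scan
  line), an 8-entry table pooled over rows and columns in both scan orders.
  Diagonal directions are not collected: the generator only draws
  axis-aligned lines.
* `pairgap[j]` — P(pixel black | flanking pixels at ±j), j = 1…8, the
  conditional used for hierarchical interpolation.
* `blackness` — the pooled mean black fraction.

Border pixels lacking three predecessors are skipped, not padded.
Conditioning patterns never observed fall back to the marginal blackness and
are flagged. Note an exact-identity subtlety: marginalizing `cond3` against
the empirical pattern frequencies reproduces the black fraction *of
window-final pixels*, which differs from the pooled blackness by a border
term of order (window length / image size); the raw counts are stored so
both quantities are available.

## Synthetic micrographs

Real micrographs are not bundled; the fixture generator produces
statistically similar stand-ins: a Gaussian random field (white noise
smoothed with an isotropic kernel of scale `corr_length_px`, default 6 px)
is thresholded at the quantile giving the target black fraction (default
0.3755, the mean blackness of cytoplasmic TEM data this pipeline is
modeled on), then mapped to intensity modes 50 (dark/object) and 200
(background) with additive Gaussian noise (default SD 25, a realistic
signal-to-noise for stained sections; the modes are separated by 6 SD so
isodata thresholding recovers the field, while a few per-mille of pixels
flip and produce the isolated specks real thresholded micrographs show).
A paired "noisy vs denoised" set applies a 3×3 median filter to the same
images. Fixtures emulate second-order texture statistics only — no
organelle morphology, no illumination gradients — so tests on them validate
the statistical pipeline, not biological realism.

## Volume generation

A size-`N` volume (N divisible by the scaffold spacing, default 16) is
built in four stages:

1. **Scaffold.** Order-3 Markov chains sampled from `cond3` are drawn as
   lines along all three axes wherever both transverse coordinates are
   multiples of 16 (half-open convention: planes at 0, 16, …; the plane at
   N−1 is not duplicated). The first three entries of each line are i.i.d.
   Bernoulli(blackness).
2. **Interpolation.** Remaining voxels are filled at gaps 8, 4, 2, 1: at
   gap j, new voxels on the spacing-j grid are sampled from `pairgap[j]`
   given their two flanks at ±j. Voxels are processed by the number of
   "odd" coordinates (1, then 2, then 3) so both flanks are always already
   determined; the sampling axis is drawn uniformly among each voxel's odd
   axes for isotropy; flanks wrap periodically, which keeps every gap an
   exact power of two on divisible volumes.
3. **Statistics matching.** The raw volume is filtered until its measured
   directional `cond3` approaches the learned target. Each iteration
   evaluates five erosion/dilation-derived candidates (erosion, dilation,
   opening, closing, and the 27-neighborhood median — the rank filter midway
   between erosion and dilation), blends the raw volume back with weight
   `feedback_decay^k` (threshold 0.5, ties to the filtered volume), restores
   the occupied fraction exactly to the learned blackness by a
   *partial-depth* rank-ordered erosion/dilation of the boundary shell
   (fill the most-enclosed white voxels or remove the most-exposed black
   voxels first), and greedily keeps the candidate with the smallest
   per-entry `cond3` deviation. Full-depth single passes were found to
   overshoot the fraction by ±0.15 and cycle; constraining every iterate to
   the learned marginal makes the greedy search stable (4–8 iterations).
   Stopping: deviation ≤ `tol_stats` (default 0.02), an idempotent fixed
   point, five stalled iterations, or `max_iter` (50). The best volume seen
   is returned with a `converged` flag.

   On targets learned from noisy images the 0.02 per-entry tolerance is
   generally *not* reachable: the rare alternating patterns (010/101) carry
   speck-driven probabilities that fixed-scale morphology cannot sculpt —
   even an ideal isotropic 3D Gaussian field with the matching correlation
   deviates by ~0.10 on those entries. A non-converged flag with residual
   deviation ~0.05 is therefore the normal outcome; the occupied fraction
   contract (within 0.02 of blackness, in practice exact) holds regardless.
4. **Low-pass and crop.** An optional 3³ median filter smooths the surface
   (changing the occupied fraction by well under 0.05), and a margin crop
   plus inscribed-sphere mask produces the simulation volume: with the
   reference margin of 10 px on a 300 px volume at 17.6 nm/px, the 280
   usable px give a 4.928 µm sphere.

## Brownian dynamics (continuous space, static obstacles)

Each occupied voxel becomes a static sphere at the voxel center with radius
`r_s = (3a³/4π)^{1/3}` (10.92 nm at a = 17.6 nm) so sphere and voxel volumes
match. Inert tracers (radius `r_i` = 2.6 nm, free diffusion coefficient
`D0` = 1 µm²/s) take Gaussian steps with per-axis variance `2 D0 dt`; a step
ending within `r_i + r_s` of any obstacle center is rejected and the tracer
stays put. Rejection is the simplest scheme consistent with hard-core
hindrance; recorded trajectories provably never violate the contact
distance. Collision checks use the obstacle occupancy grid (only voxels
within the contact radius are inspected), which is exact and is
cross-checked in the tests against a KD-tree scan.

The default time step follows the step rule "four standard deviations of
the 1D step ≤ 0.08·(r_i+r_s)", giving dt ≈ 3.65×10⁻⁸ s. The reference
implementation this emulates quotes Δt = 1.27×10⁻⁷ s for the same rule;
that value is not derivable under common conventions (4σ, 3σ, or rms-step
readings all disagree), so the rule is exposed as `max_step_frac` and `dt`
accepts an explicit override. Several geometry-sensitive tests use a larger
dt (4.5×10⁻⁶ s, σ = 3 nm) so tracers explore beyond their seeding pocket at
desk scale; σ remains far below obstacle size, so no tunneling.

Tracers are seeded at the volume center (jittered outward until
collision-free). On small (64³) dense volumes the tracer-accessible space —
the free space eroded by the contact radius — can be disconnected, trapping
the whole ensemble in one pocket; this is a realization effect of small
boxes, which is why desk-scale defaults use 64³ only for ordering and
isotropy checks, not for absolute D_eff claims. First-exit stopping (end
the run when the first tracer reaches the bounding sphere) is available and
off by default in tests.

## Lattice Monte Carlo (mobile / aggregated obstacles)

A periodic 50³ lattice (1 px = 77.8 nm in the reference calibration) holds
point reactants and NRO. Reactants attempt one move per sweep to a uniform
6-neighbor: empty → move; NRO → the attempt fails and the walker stays
("blind ant"). The alternative literal reading of the source description —
allocate a random new position on a blocked attempt — was rejected: long
teleports can only speed diffusion and destroy the subdiffusion that
crowding is supposed to produce. With the reaction enabled, stepping onto
another reactant annihilates the target (A+A→A) and the mover takes its
site. NRO move as rigid blocks (edge 2·r_nro sites; r_nro = 1 is the 8-site
base object; single-site obstacles serve the mobility sweep) with per-sweep
probability `P_f`, translating one site when every newly covered site is
empty. Update order: all reactants in a fresh random permutation, then all
blocks in fixed order. MSD is accumulated from unwrapped coordinates, so
periodic wraps never truncate displacements; lattice units (site², sweep)
are used internally and physical units only at reporting.

A caution for interpreting the crowded-lattice anomaly: with 20% point
obstacles the free space (80%) is far above the site-percolation threshold
(~0.31), so site-exclusion random walks show only a ~2% MSD crossover
(MSD(1) ≈ 0.8·a², asymptotic slope ≈ 0.7·a²); fitted anomaly exponents stay
≥ 0.98 in every window, whether obstacles are static, slow (P_f = 1/10), or
reacting. Strong subdiffusion (α < 0.7) appears only when the free fraction
approaches the threshold (≈70% obstacles). The acceptance suite reports
measured values under the stated conditions rather than forcing agreement
with external anomaly estimates.

## Anomalous-diffusion analysis

`MSD = Γ t^α` is fitted by ordinary least squares on (log t, log MSD) —
standard for power laws and stable at desk scale; Γ and its standard error
come from the intercept via the delta method. The default window excludes
the first decade (step/lattice transients). Linearly sampled series are
thinned to log-uniform spacing before fitting so late decades are not
over-weighted. `D_eff(t) = MSD/(2 d (t−t0))` with d = 3 or per-axis d = 1;
t0 defaults to one grid spacing before the first recorded point (the
displacement origin). Degenerate inputs (non-positive MSD in the window,
< 10 points, zero-variance abscissa) raise.

The empiric relations α(D_nro) (linear) and α(ln r_nro) are ordinary
least-squares fits; eliminating α gives D_nro = (a₂/a₁) ln r + (b₂−b₁)/a₁.
With the reference coefficient pairs (0.0093, 0.4606) and (0.1302, 0.0976)
the composed relation is D = 14.0 ln r − 39.03; evaluating with the
3-significant-figure rounded pair (14.0, −39.0) at r = 77.8 nm and 389 nm
gives 21.96 and 44.49 µm²/s (the unrounded composition gives 21.93 and
44.46 — the difference is purely the rounding of the intercept).

## Percolation threshold

Site percolation on the simple cubic lattice, 6-connectivity, spanning =
one cluster touching two opposite faces along any axis. The spanning
probability R_L(p) is estimated on two lattice sizes (16³ and 32³, 200
replicates per occupancy over p ∈ [0.25, 0.40] in steps of 0.01), each
curve is fitted with a Gaussian CDF Φ((p−µ)/σ), and the threshold is the
crossing of the two fitted curves (bisection on their difference), which
cancels the leading finite-size shift. At these sizes the estimate lands
within ±0.01 of the literature value 0.3116.

## Problem sizes and defaults

Desk-scale defaults were chosen so every stage runs on a single CPU in
minutes: 5 × 300² fixture images; 128³ generated volumes (300³ with the
10-px margin crop is supported but slower); Brownian dynamics with
500–1000 tracers and 10⁴–2×10⁴ steps; lattice runs with 1000 reactants and
10⁵ sweeps; percolation with 200 replicates. The same code paths scale to
the full-size problems by changing configuration only.

## Known limitations

* Fixtures reproduce two-point texture statistics, not organelle shapes;
  a matched volume is "cytoplasm-like" only in that sense.
* Per-entry matching of `cond3` to noisy-image targets saturates around
  0.05 (see above); the converged flag reports this honestly.
* The Brownian simulator has static obstacles only; obstacle mobility is
  the lattice model's job.
* The lattice anomaly at moderate crowding is intrinsically weak for
  site-exclusion walks (see the caution above); mixtures of obstacle sizes
  and bimolecular kinetics are out of scope.
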