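# Methods

`nsphase` models and measures internal phase separation in binary DNA-nanostar
condensates: mixtures of two four-armed nanostars (A, B) cross-linked by three
divalent linkers (aa, bb, ab) that phase separate from solution and, depending
on linker stoichiometry, form either uniform (monophasic) or internally
de-mixed (biphasic/Janus) droplets.

## Stoichiometry and the mixing order parameter

Sticky-end neutrality — every nanostar sticky end matched by a complementary
linker end — imposes `4[A] = 2[aa] + [ab]` and `4[B] = 2[bb] + [ab]`, which
forces `[linker] : [NS] = 2 : 1` and reduces the composition space to two
coordinates: `F_A = [A]/[NS]` and `F_ab = [ab]/[linker]`.  Defaults are
`[NS] = 0.5 uM`, `[linker] = 1 uM`.  Feasibility requires
`F_ab <= 2 F_A` and `F_ab <= 2 (1 - F_A)`; compositions violating neutrality
are rejected, never repaired (experimental pipetting error is below the 5%
composition steps, so a projection rule would be unconstrained by data).

The mixing order parameter is the summed fraction of each sticky-end family
carried by ab linkers,

    order = F_ab/(2 F_A) + F_ab/(2 (1 - F_A)),

which predicts the monophasic/biphasic boundary at a composition-independent
value of about 0.5 (so `F_ab = 0.25` for the symmetric mixture).  The boundary
value is configurable (it is empirical); the value exactly at the threshold is
classified monophasic so the classification is deterministic.

## Phase-field model

The ternary Flory–Huggins free-energy density over volume fractions
`phi_A`, `phi_B` (solvent `phi_S = 1 - phi_A - phi_B`) is

    f = phi_A ln phi_A + phi_B ln phi_B + phi_S ln phi_S
        + chi_AB phi_A phi_B + chi_AA phi_A phi_S + chi_BB phi_B phi_S
        + (lambda^2 chi_AA / 2)|grad phi_A|^2 + (lambda^2 chi_BB / 2)|grad phi_B|^2.

The square-gradient stiffness is positive — a negative coefficient would make
the initial-value problem ill-posed at high wavenumber — and there is no
cross-gradient (A–B interface) term.  Fields evolve by conserved
Cahn–Hilliard dynamics `d phi_i/dt = M lap(mu_i)` with
`mu_i = df/dphi_i - lambda^2 chi_ii lap(phi_i)` and equal constant mobility
`M = 1` for both species (the simplest conservative choice).

Numerics: first-order semi-implicit Fourier-spectral integration on a
periodic `grid_n x grid_n` lattice (`dx = 1`).  The biharmonic term and a
constant convex-splitting stabilisation `a*lap(phi)` are implicit, the
remaining nonlinearity explicit; `a = max(2 max(chi), 33)`, the floor being
roughly `sup f''` at the dense-phase solvent fraction (~0.03) reached at
`chi ~ 4`.  The `k = 0` mode is untouched, so spatial means are conserved to
rounding error (`<= 1e-8` over 1e4+ steps in tests).  Logarithms are
evaluated on fields clipped to `[1e-6, 1 - 1e-6]` (and jointly rescaled onto
the simplex); the evolved state itself is never clipped.  The gradient energy
is evaluated spectrally with the same `k^2` symbol as the Laplacian in the
chemical potential, so `mu` equals the discrete functional derivative of the
total free energy to rounding error (verified against central differences to
1e-4 relative).

Parameter choices that matter:

- `lambda = 2` grid units (default).  The interface width must be resolved on
  the lattice: with `lambda = 1` and `dx = 1` the `chi = 4` interface is under
  one cell wide, producing spectral ringing (`phi < 0`) and non-monotone
  energy.  `lambda = 2, dx = 1` is the same continuum model as
  `lambda = 1` on a lattice of spacing 1/2.
- `dt = 0.1`.  Energy descent and field bounds were verified over 60k steps
  at `chi_AB` in {1.5, 3, 4}; `dt = 0.2` is unstable at `chi_AB = 4`.
- `phi_A0 = phi_B0 = 0.23`, `chi_AA = chi_BB = 4`: the study conditions for
  the condensate-forming regime.
- Initial condition: uniform means plus seeded, mean-subtracted i.i.d.
  Gaussian noise (amplitude 0.01).
- Default run: 60 000 steps (t = 6000), five geometrically spaced snapshot
  checkpoints, the last being the analysis snapshot.  The duration is set by
  two slow processes: near the internal de-mixing threshold
  (`chi_AB ~ 2.5`) composition contrast develops slowly (near-critical
  dynamics), and at strong de-mixing the contact geometry at inter-domain
  necks needs time to relax.  Shorter runs bias the measured
  cos(theta/2)-vs-chi_AB line.

A physical observation relevant to interpretation: 1-D interface-profile
relaxations of this free energy show that the solvent completely wets the
A–B interface over the whole `chi_AB` range of interest (a solvent film
between the two dense phases is the 1-D equilibrium: a dry A–B contact costs
more than two dense/solvent interfaces).  Janus droplets in 2-D snapshots —
in this package and in confocal experiments alike — are therefore long-lived
coarsening structures whose contact geometry correlates with `chi_AB`, not
equilibrium triple junctions; the calibration below measures exactly those
structures, which is what the cos(theta/2)-vs-chi_AB line is defined on.

## Morphometry

The measurement pipeline is identical for simulation snapshots and synthetic
micrographs (snapshots are additionally analysed on a 2x2 periodic tiling so
structures straddling the periodic boundary are measured whole, each counted
once).

1. **Segmentation** — Otsu threshold on the Gaussian-smoothed (sigma = 2 px)
   channel sum; 8-connected components above 64 px.  No watershed splitting:
   touching/branched condensates are genuine morphologies in this system.
2. **Domain split** — channels are smoothed (sigma = 1 px), normalised by
   their within-condensate 95th percentile, and compared per pixel.  The
   split is demoted to monophasic when either domain is below 2% of the
   condensate area or when the mean normalised-intensity separation between
   the domains is below 0.15: the apparent domains of nearly-mixed droplets
   are noise speckle, and domains with partition coefficients above ~0.85 are
   genuinely unresolvable by intensity comparison (the same behaviour the
   experimental segmentation shows near the mixing transition).
3. **Partition coefficients** — `rho_A` is the mean channel-A intensity over
   the B-rich mask divided by that over the A-rich mask (and symmetrically),
   each mask eroded by 2 px to suppress interface blur bleed-through; the
   mean (not median) is used for linearity in fluorophore density.  Raw
   ratios above 1 are capped at 1 for reporting (raw values retained).
   Monophasic condensates report (1, 1).
4. **Contact angles** — measured per A-rich/B-rich domain pair.  Sub-pixel
   contours (marching squares) refine the pixel arcs: the solvent-facing
   contour at the segmentation threshold, assigned to domains by proximity,
   and the A–B interface as the zero contour of the normalised channel
   difference.  Per triple junction, Taubin algebraic circles are fitted to
   each domain's solvent contour within a window of twice the component's
   equivalent radius and to the interface arc (demoted to a straight line
   when the fitted radius exceeds 25x the droplet radius); the triple point
   is the intersection of the two solvent circles nearest the junction, and
   `theta_A`/`theta_B` are the tangent-wedge angles interior to each phase,
   averaged over the interface's two junctions.  Recovery on synthetic
   ground truth: within 2 degrees and 0.02 in rho on clean droplets
   (radius >= 20 px), within 5 degrees and 0.05 with 1 px blur + 5% noise.
5. **Tensions** — Neumann force balance at the junction gives
   `gamma_A/gamma_AB = -sin(theta_B)/sin(theta_A + theta_B)` (and
   symmetrically), and under `gamma_A = gamma_B = gamma_0` the reduced A–B
   tension is `cos(theta/2) = gamma_AB/(2 gamma_0)` with
   `theta = 2 pi - theta_A - theta_B`.
6. **Melting traces** — per frame and channel, the coefficient of variation
   sigma/mean of the pixel values.  The transition temperature is the
   breakpoint of a continuous two-segment piecewise-linear fit, scanned over
   the observed temperatures and refined continuously; a trace is flagged
   `no_transition` when the two-segment fit barely improves on a single line
   (relative SSE gain < 0.25) or the slopes do not change markedly.

## Bond-count model

For `N_A = N_B = N` nanostars and a stoichiometrically matched linker pool
`N_L = 4N`, the possible nanostar–nanostar bond count is

    D_tot = 8 N^2 (F_ab^2/2 + (1 - F_ab)^2),

maximal at `F_ab = 0` (8 N^2) and minimal at `F_ab = 2/3` — the same
non-monotonic shape the measured condensate melting temperature follows.
The decomposition `D_AA = D_BB = 4 N^2 (1 - F_ab)^2`, `D_AB = 4 N^2 F_ab^2`
is the unique symmetric quadratic split consistent with the total; it is a
documented assumption, not a derivation.  Min–max normalisation of `D_tot`
gives the qualitative T_m trend proxy; converting counts to absolute melting
temperatures is out of scope.

## Calibration

cos(theta/2) falls linearly both with `chi_AB` (simulation axis) and with the
order parameter (experimental axis).  Equating the two straight lines —
matching slope and intercept under the affine substitution
`order = (chi_AB - c0)/c1` — gives `c1 = a_exp/a_sim`,
`c0 = (b_exp - b_sim)/a_sim`, which maps zero crossings onto each other.
The shipped defaults are `c0 = 4.1`, `c1 = -3.4`, so predictions work out of
the box; `calibrate_mapping` re-derives constants from any pair of fits.
Fits are unweighted least squares over per-composition medians; the
experimental-axis fit may be constrained exactly through
`(order, cos) = (0, 1)`.

The calibration sweep (`chi_AB` in {1.5, 2, 2.5, 3, 3.5, 4} at
`chi_AA = chi_BB = 4`, `phi = 0.23`, 128^2 grid) runs two replicate seeds per
`chi_AB` and pools contact angles at the interface level: after coarsening to
t = 6000 a snapshot holds only a handful of structures, so single-seed
medians are noisy.  The line is fitted by a Theil–Sen estimator over the
pooled per-interface values, restricted to `chi_AB` strictly below
`min(chi_AA, chi_BB)`: at and beyond that point A–B contact is no cheaper
than solvent contact, condensates de-mix into tangent or fully separate
droplets (the zero-cross-linker regime) and measured cos(theta/2) saturates
rather than following the line; near the mixing threshold, single interfaces
on weakly segregated domains occasionally report wild angles, which the
median-of-pairwise-slopes estimator absorbs.  The measured zero crossing
lands near `chi_AB ~ 2.2-2.35` (order parameter 0.52-0.55 through the
shipped constants), consistent with the dense-phase de-mixing threshold
estimated from the curvature of f (at dense-phase composition
`phi_A = phi_B ~ 0.45`, instability sets in near `chi_AB ~ 1/0.45 ~ 2.2`),
and is stable to about +-0.02 in the order parameter across disjoint seed
sets.

## Synthetic data

The generator renders what the measurement pipeline must survive, with exact
ground truth: monophasic discs and biphasic doublets built from two equal
solvent-facing circular caps joined through the two triple points by a
circular-arc interface.  For target angles the construction uses
tangent-chord angles: `tau = (theta_A + theta_B)/2` for both caps
(half-chord `h = R sin tau`) and `psi = (theta_A - theta_B)/2` for the
interface (radius `h/|sin psi|`, straight when symmetric); the interface's
centre of curvature lies inside the higher-angle phase — that phase has the
larger surface tension and Laplace pressure, so the interface bulges into
the lower-angle phase.  Re-measuring the analytic geometry returns the
targets exactly.  Channel intensities encode the target partition
coefficients; rendering applies Gaussian blur, then additive Gaussian noise
(optionally Poisson shot noise).  Every image is bit-reproducible from
specs + seed.

Composition grids default to five `F_A` levels {0.25, 0.375, 0.5, 0.625,
0.75} (a plausible symmetric emulation; the study's exact levels are not
published) with 5% `F_ab` steps; infeasible points are dropped.

Melting stacks conserve total fluorophore: each frame interpolates between
the condensed image and a uniform image of equal mean.  Condensed contrast
follows a softplus ramp in temperature (width 0.4 C) centred at
`T_m +- hysteresis/2` by ramp direction, so the CV trace is a flat baseline
with a single kink at the transition — the shape the breakpoint detector is
built for.  Default ramps span 30–60 C in 0.5 C steps.

What the generator does *not* emulate: PSF anisotropy, bleaching,
z-sectioning, branched "candy-cane" network morphologies, and temperature-
dependent sticky-end affinities.  Passing recovery tests therefore
demonstrates correctness of the geometry and intensity measurements under
blur and noise, not robustness to every confocal artefact.

## Problem sizes

Default analyses use a 128^2 grid, 60 000 steps, six `chi_AB` values and two
replicate seeds (the calibration sweep), 300^2-canvas synthetic fields of
3–5 droplets, and 61-frame melting stacks — sizes chosen so a full
calibration runs on a laptop-class single core in minutes while leaving the
measured boundaries stable against seed choice.

## Known limitations

- The mapping constants shipped as defaults reproduce the printed
  calibration; re-deriving them from this package's own sweep against a
  synthetic experimental axis reproduces them only to the extent the
  simulated line matches (scheme, duration and measurement choices shift the
  zero crossing by a few tenths in `chi_AB`).
- Contact angles on heavily branched structures are measured junction-by-
  junction; topologies whose circle fits fail are flagged, not guessed.
- The simulator is 2-D and athermal (`chi` constants carry no explicit
  temperature dependence); annealing-protocol phenomenology is reproduced
  only qualitatively via run duration.
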