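# Methods

## Model

One-dimensional periodic lattice of `n_cells` cells. Cell `j` carries a
dimensionless Delta level `D_j ≥ 0` and activated-Notch *fractions*
`N_l,j, N_r,j ∈ [0, 1]` on its left and right membranes. Delta
production is repressed by the cell's mean activated Notch through a
Hill function (coefficient `hill`, default 2 — the standard choice for
Notch-mediated repression); Delta and Notch decay linearly; each
membrane side is activated by the facing neighbour's Delta; the two
sides exchange Notch at diffusion rate `W`. Time is measured in units
of the Delta decay time, so the Delta decay coefficient is 1 and `kd`
is the Notch/Delta decay ratio. The mapping from dimensional rate
constants (`nondimensionalize`) uses `b0 = B0/(k_D·D0)` with
`D0 = kd/B0`, `K = k/N0`, `kf0 = K_F·D0/(2k_D)`, `kd = k_N/k_D`, and
`W = F_Notch/(L²·k_D·N0)`.

Three variants, dispatched on (`W`, `h`):

* **classical** (`W = ∞`, `h = 0`): one Notch pool per cell,
  `dN_j = −kd·N_j + kf0·(D_{j−1} + D_{j+1})·(1 − N_j)`. Note the
  convention: the baseline rate `kf0` absorbs the factor ½ of the
  two-sided average, so the classical equations match their standard
  printed form. Consequently a classical run at a given `kf0` has twice
  the effective binding of the heterogeneous model's `W → ∞` limit at
  the same `kf0`; the two variants are distinct parameterizations, not
  interchangeable limits at equal `kf0`.
* **heterogeneous** (`W < ∞`, any `h`): the full three-field system.
* **tension-only** (`W = ∞`, `h > 0`): the quasi-steady limit of the
  heterogeneous system — one pool driven by the *mean* of the two
  tension-weighted inputs,
  `dN_j = −kd·N_j + ½·(kf_{j−1}·D_{j−1} + kf_j·D_{j+1})·(1 − N_j)`.

### The interface distance law

Interface `j` (between cells `j` and `j+1`) has binding rate
`kf_j = kf0·exp(−h·(x_m,j − λ)²)`: maximal at the optimum intercellular
distance `λ`, reduced when the membranes are closer (steric hindrance)
or farther (unreachable partners). The distance is the reciprocal of
the interface's adhesive contact capacity,

```
x_m,j = 1 / ( min(1 − N_r,j, D_{j+1}) + min(1 − N_l,j+1, D_j) )
```

each signalling direction contributing the *limiting* species — free
Notch on the receiving membrane or Delta presented by the facing cell.
More possible contacts pull the membranes together. An interface with
no possible contact is infinitely separated; the lattice-level rate
computation takes the continuous limit `kf → 0` there, while the
scalar `interface_distance` treats a capacity at/below `1e−9` as a
degenerate input and raises. We note that a rational variant of this
denominator with `max` in place of `min` admits no patterned steady
state at all under tension at the parameter regimes of interest
(any interface facing a bright cell would then be pinned at `x_m ≲ 1`,
suppressing its rate by `e^{−hλ²}`), so the limiting-reagent form is
the one with scientific content and is the one implemented.

### Why the tension variant is solved in its pooled form

Requiring *each side's* balance to vanish separately at a `W = ∞`
steady state over-determines the system: every adjacent pair of cells
shares an interface, forcing all cells onto one level set of the
balance function `M` and leaving more Dembo-consistency conditions
than unknowns. Those per-side balances hold exactly only on a tuned
manifold in parameter space — and the interface-rate ratios they
require are invariant under rescaling of `kd` and `kf0`, so off that
manifold no choice of kinetic prefactors can restore them. The pooled
(mean-input) reduction above is the mathematically exact `W → ∞` limit
of the two-sided dynamics, is square, and reproduces the published
two- and three-cell tension patterns at their stated parameters. The
per-side balance is therefore exposed as a *diagnostic*
(`check_interface_balance`, `side_resolved_residual`,
`equality_residual`); at the published two-cell tension parameters it
holds to ~1e−3 — the parameters sit close to, but (at their printed
precision) not on, the balance manifold.

## Steady-state solving

A spacing-`s` ansatz imposes period `p = s + 1` (which must divide
`n_cells`; the default lattice `n_cells = 12` accommodates spacings
0–3, and sweeps probing spacing 4 use 60). The reduced equations on the
`p`-cell ring are exact for periodic tilings. Roots come from a damped
Newton iteration (step halving up to 20×, Broyden rank-one updates with
a fresh finite-difference Jacobian every 4 steps, stall cutoff), run
from a seed family:

* the plain structured guess — tip at `D = b0`, stalks at `0.05·b0`,
  Notch at the baseline quasi-steady level of its facing neighbour;
* for `h > 0`, Delta profiles covering flat stalk levels at several
  depths plus bright-hybrid and dim-valley shapes, each completed by
  *branch-resolved* quasi-steady Notch levels: the per-side balance
  with the Dembo feedback is bistable wherever an interface can sit
  near the optimum distance, so both the low- and high-activation
  branches are used as seeds (located by sign-change bracketing, not
  fixed-point iteration, which cannot hold the high branch);
* 8 seeded random restarts, Delta drawn log-uniformly on
  `[1e−5, b0]` — patterned roots span Delta decades, which uniform
  draws almost never propose — and Notch uniformly (default seed
  20180622).

A root is accepted only if admissible (`D ≥ 0`, `N ∈ [0, 1]`) and its
full-lattice residual max-norm is ≤ 1e−10. Among accepted roots the
solver prefers a stable root displaying the requested spacing (early
exit), then marginal, then unstable, then a collapsed root (one that
converged but displays a different spacing — e.g. a three-cell ansatz
landing on the alternating pattern); "nothing converged" is returned
as `None`, a data value. Stability comes from the eigenvalues of the
full-lattice Jacobian (central differences, step 1e−6, relative above
magnitude 1), so period-`p` roots are also tested against
longer-wavelength perturbations; verdicts use a marginal band of
±1e−8 on the largest real part. The uniform state has its own
bracketed scalar solver (`brentq` on the Delta nullcline, with an
inner solve for the self-consistent uniform Notch fraction when
`h > 0`).

## Dynamics

`integrate` uses implicit BDF (`scipy.solve_ivp`, rtol 1e−8,
atol 1e−10); single-pool variants integrate their pooled equations, so
the tension variant's trajectories follow the same vector field whose
roots the solver reports. `relax_to_steady` integrates in doubling
time chunks and declares convergence on the rhs max-norm (≤ 1e−9 by
default), not on state displacement, to avoid false positives on slow
transients. `perturb` multiplies every variable by `1 + m·u`,
`u ~ U(−1, 1)`, then clips to the admissible box — clipping (rather
than rejection) keeps the state admissible with negligible bias at the
1% magnitudes used.

## Classification

Tips are cells within a relative tolerance (default 1e−3) of the
Delta maximum; on converged roots the levels are exact plateaus so the
grouping is unambiguous. Equal circular gaps `g` between consecutive
tips give spacing `g − 1`; unequal gaps are IRREGULAR; a state whose
Delta spread is below tolerance (with a 1e−12 floor guarding the
all-zero state) is uniform, spacing 0, as is an all-tie state.
`label_cells` uses looser exploratory thresholds (tip ≥ 0.9·max,
stalk ≤ 0.1·max, hybrid between) for non-converged states.

## Sweeps

`sweep_existence` records, per (K, kf0) grid point and candidate
spacing, `stable` / `unstable-only` / `not-found`; collapsed roots
count as not-found for the requested spacing. Multiple spacings may be
stable at one point — the maps keep them all (multistability; initial
conditions select the realized pattern). Default grids are 40×40,
log-spaced, `K ∈ [1e−3, 1]`, `kf0 ∈ [1e−2, 1e2]`; point failures are
data, never aborts; re-running with the same restart seed reproduces
the map bit-identically. `regime_summary` reports the set of spacings
ever found stable for each mechanism quadrant (classical /
heterogeneity / tension / both) on a small reference grid around each
regime's published parameters.

## Findings the tests pin down

* Every published profile parameter set (all three mechanism regimes)
  yields a linearly stable steady state of its stated spacing.
* Without tension (`h = 0`, any finite `W`) the three-cell ansatz
  always collapses to the alternating pattern, with the two outer
  stalk cells identical to ≤ 1e−8 — the mirror-symmetry argument.
* With tension, the stable three-cell root is genuinely period-4 (its
  middle stalk stays far dimmer than the tip) — but it is *mirror
  symmetric*: the two stalk cells flanking the tip are identical.
  Tension's symmetry-breaking role is preventing the collapse to
  one-cell spacing, not making the outer stalks unequal; asymmetric
  three-cell roots exist at the same parameters but are all linearly
  unstable. Likewise the stable two-cell tension root has *equal*
  stalk Notch fractions, so the two-stalk balance equality
  `M(N1) = M(N2)` is satisfied on its diagonal rather than by a
  non-trivial pair.
* The `K < 1/(3√3)` cap: no non-collapsed two-cell tension pattern was
  found above the threshold, and the published two-cell parameters lie
  below it.
* Two qualitative statements often made about these models hold only
  with caveats in the implemented equations. First, the classical
  single-pool model is *not* strictly limited to zero- and one-cell
  spacing: at very steep inhibition (`K ≲ 0.03`) it supports robustly
  stable two-cell patterns (confirmed both spectrally and by
  relaxation); the restriction to `{0, 1}` holds at moderate `K`.
  Second, under tension alone, three-cell spacing is *not* strictly
  the maximum: small parameter pockets support linearly stable
  period-5 patterns, though these are graded (tip, hybrid-bright,
  dim-stalk cells) rather than canonical one-tip-four-dim-stalks
  profiles, and they occupy ~3% of the scanned grid versus broad
  regions for spacings ≤ 3. Three-cell spacing never appears without
  tension in any scan — that statement is robust.

## Limitations

* 1-D lattices only; no 2-D/hexagonal geometry, VEGF field, cell
  movement or stochastic (Langevin/Gillespie) dynamics.
* Existence maps are point-wise Newton solves, not continuation; a
  verdict of `not-found` means "no seed converged", which at the fixed
  restart budget can under-report patterns with very small basins.
* The dimensional mapping is provided as a convenience; all analysis
  is dimensionless, and the Dembo spring constant, Boltzmann factor
  and temperature are never represented individually (only their
  combination `h`).
* Pattern periods must divide the lattice size; incommensurate or
  defected (irregular) patterns are classified but not solved for.
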