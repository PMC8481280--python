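# Methods

## Model and assumptions

The analysis treats the gastrula-stage embryo as a rigid sphere. A single
static geometry (centre, radius) is obtained by least-squares sphere fits to
each frame's positions, averaged over frames; a per-frame option exists but
is off by default because embryo drift over the ~4 h recording is small
compared with the 110-um domain scale. The anatomical axes — the anterior
(animal-pole) direction and the dorsal meridian direction — are *inputs*
(config for real data, simulator outputs for synthetic data): registering
them from image content is out of scope. The elevation `theta` is measured
from the anterior pole and the azimuth `phi` from the dorsal meridian,
increasing anticlockwise seen from the anterior pole.

All tensor computation is done in physical units (um, min). The unit sphere
(`r0 = 1`) is used only for mesh construction and angular bookkeeping; this
avoids any unit ambiguity in the velocity-gradient tensor.

## Surface discretization

The 2000 "equally spaced" surface nodes are generated by the offset spherical
Fibonacci lattice and triangulated by the convex hull of the node set. The
lattice is deterministic (identical `n_nodes` gives bit-identical
coordinates), needs no iterative relaxation, and its nearest-neighbour
spacing has a coefficient of variation of ~0.013 at n = 2000. Local
anatomical frames `(e_AP, e_ML, e_r)` are singular at the poles; frames and
component maps are flagged missing within a polar cap of 0.05 rad
(`pole_exclusion`) around both poles.

## Tracking and velocities

Per-frame detections are linked by greedy *mutual* nearest neighbours: a pair
links only if each detection is the other's nearest neighbour in the adjacent
frame and the distance is below `max_disp` (default: 3x the median
frame-to-frame displacement estimated from an unthresholded first pass; the
tracker in this analysis class publishes no cutoff). Unmatched detections
start new tracks; a dropped-out cell that reappears gets a new id; division
daughters get new ids and no lineage tree is kept — the downstream analysis
needs velocities, not lineages.

Velocities are central differences over the 2-min frame interval, one-sided
at track ends, and absent across gaps longer than one frame. Two
finite-difference artefacts matter for validation against exact tensors
(frame interval h, affine generator A):

* central differences of the exact one-step flow give an *exactly affine*
  effective field with error `|A|^3 h^2 / 6` on the gradient;
* one-sided endpoint differences carry a symmetric bias `A^2 h / 2`, whose
  trace `-|omega|^2 h` is the only divergence artefact of a rigid rotation.

These closed forms set the amplitudes of the affine reference presets: the
`rigid` preset uses `|omega| = 5.6e-4 rad/min` so both artefacts stay below
the verification tolerances (1e-8/min on `L`, 1e-6 on the integrated
divergence), with the tighter bound coming from the endpoint-bias term.

## Gradient estimation

At each node the velocity gradient is a weighted affine least-squares fit
`v(x) ~ v0 + L (x - x_node)` over samples within the 110-um domain, with
Gaussian distance weights of bandwidth `domain_radius / 2` and the intercept
removed exactly by weighted centring. Two sample choices are provided:

* `cell_regression` (default): member-cell velocities against their 3D
  positions. A velocity field known only on a spherical surface cannot
  constrain radial derivatives, but the blastoderm shell has finite radial
  thickness (~30 um), and the individual cells sample it — this is what
  identifies `d/dr` and hence the radial strain.
* `node_field`: neighbouring domains' mean velocities, attached to the
  member-cell centroids (the mean of an affine field is the field at the
  centroid, so affine flows remain exactly recoverable). Radial information
  is then limited to the sphere's curvature and the centroid shell; with
  noisy data the radial column is effectively ridge-dominated.

Regularization is a *rescue*, not a default: the 3x3 scatter matrix is
eigen-decomposed, and a ridge `ridge_epsilon * tr(M)/3` (default 1e-6
relative) is added only when the smallest eigenvalue falls below `rank_tol`
(1e-10) times the largest. An always-on ridge of that size would bias the
weakest-direction derivatives by up to ~1e-5 relative and break the exact
recovery of affine fields, which the test suite requires to machine
precision. Per-node condition numbers are reported; nodes with fewer than
`max(4, min_cells_per_domain)` samples, or rank < 2 even after the rescue,
are invalid.

## Decomposition and sign conventions

`E = (L + L^T)/2`, `Omega = (L - L^T)/2`; the component scalars are
`e_AP = e_AP^T E e_AP` etc., `trace = tr(E)` (equal to the eigenvalue sum and
to `e_AP + e_ML + e_r` wherever the frame exists), and
`curl_r = 2 omega . e_r` with `omega = (Omega_32, Omega_13, Omega_21)`.
Positive `curl_r` means anticlockwise rotation viewed from outside the
embryo; a `clockwise_positive_curl` flag flips the convention, since both
conventions appear in practice. The eigen-decomposition of `E` is exposed
(sorted descending) but the maps and kymographs use the coordinate
projections, which is what the figures of such analyses show.

## Windowed integration

Component rates are integrated per node by the trapezoid rule over sliding
windows (default 30 min; 40 min for perturbation comparisons, applied to
control and treated alike), centred wherever the full window fits. Missing
samples inside a window are tolerated up to 20%: the mean rate over the
covered sub-intervals is scaled to the full window, which keeps a constant
rate integrating exactly to `rate x window` and keeps values comparable
across coverage levels; below 80% coverage the window is missing. Components
are integrated in the instantaneous local frame (component-then-integrate)
rather than integrating tensors in a fixed frame; the difference is
second-order at these strain magnitudes, and this matches how the kymographs
are built.

## Kymographs

The equatorial band takes nodes within `half_span` (default 0.19 rad, full
span 0.38) of the equatorial plane, parameterized by the signed azimuth
(-180 deg ventral, 0 dorsal, +180 ventral, anticlockwise); the axial bands
take constant-phi lunes of the same half-width around the dorsal or ventral
meridian, parameterized by elevation (0-180 deg). Values are averaged
*unweighted* over valid band nodes in 5-deg bins (bin width and weighting are
free choices; counts per bin are reported so a weighted variant can be
reconstructed). The dorsal 0-deg bin is centred and the +/-180-deg bins wrap
circularly. Constant-phi lunes pinch towards the poles; the polar caps are
excluded by the frame flag anyway, and near-pole bins simply come out empty.

## Synthetic embryo

The simulator is the package's study condition, not a tuning knob. Defaults:
5000 cells on a 350-um sphere with a 30-um shell, 2-min frames, 120 min
duration, 1-um Gaussian noise added to *reported* positions only (true
trajectories stay on the analytic flow, separating estimator error from
dynamical noise), divisions at 0.1 per cell per hour spawning daughters 2 um
away in a random tangential direction, and 2% detection dropout. Integration
is 4th-order Runge-Kutta per frame.

Flow forms are the lowest-order smooth fields exhibiting each named
morphogenetic movement, each with a hand-derived Cartesian Jacobian (verified
against central finite differences in the tests):

* epiboly `v_theta = A_ep sin(theta)` with `A_ep = 1 um/min`;
* convergence `v_phi = -A_conv sin(phi) sin(theta)` with `A_conv = 0.6`;
* extension `v_theta += A_ext u exp(-u^2/(2 theta_ext^2)) f(phi)`,
  `u = theta - pi/2`, with the periodic envelope
  `f(phi) = exp((cos(phi) - 1)/sigma_ext^2)` (smooth across the ventral
  wrap; its ventral leakage is ~0.4% of the dorsal amplitude). A Gaussian
  taper in `theta` replaces a hard support cutoff so the field is C-infinity
  away from the poles and the Jacobian oracle holds everywhere sampled.

The extension amplitude is set by a structural requirement: the gastrula
velocity field has a stagnation point (saddle) on the dorsal meridian with
meridional outflow, which with these forms needs
`A_ext theta_ext e^{-1/2} > A_ep`. With `theta_ext = 0.7`, `sigma_ext = 0.8`
and `A_ext = 2.5 um/min` (peak extension speed ~1 um/min, comparable to
epiboly) the saddle sits at `u ~ -0.44 rad` on the dorsal meridian. The `c59`
preset sets `A_ext = 0` and changes nothing else, emulating the
extension-specific loss under Wnt inhibition.

What the simulator does *not* emulate: cell-autonomous mechanics, signalling
gradients, yolk geometry, stage-dependent amplitude changes, segmentation
errors other than i.i.d. dropout, and the real embryo's absolute strain
magnitudes. Passing tests therefore demonstrate that the estimator recovers
known kinematics under realistic sampling, noise and tracking conditions —
not that any particular biological magnitude is correct.

## Validation scenario sizes

The test suite and `scripts/acceptance.py` use: the full 2000-node mesh with
5000-cell simulations (61 frames for `gastrula`/`c59`, 21 for the affine
references), a 1000-cell/20-frame tracker scenario whose rotation speed is
set to 45% of half the measured minimum inter-cell spacing (the premise of
the linking guarantee), and an 800-cell determinism run. Quadrant/meridian
curl statistics are computed on the time-averaged integrated map; the
meridian level is the strip *mean* of |curl| over nodes within 2.5 deg of the
dorsal/ventral meridians, because a pointwise maximum over ~56 noisy node
estimates measures the noise floor rather than the map pattern.

## Known limitations

* Domain smoothing (110 um ~ 0.31 rad) attenuates features narrower than the
  domain; for the gastrula extension peak this biases dorsal `e_AP` low by
  ~5-8%, well inside the 15% recovery tolerance but visible.
* The sphere approximation ignores embryo ellipticity and the vegetal yolk
  boundary; near the blastoderm margin, domains truncated by missing cells
  are simply flagged missing.
* Radial derivatives rest on the shell-thickness signal; with very thin
  shells or `node_field` mode they degrade gracefully (ridge rescue, high
  condition numbers) rather than failing loudly — inspect
  `condition_number` before trusting `e_r` on unusual data.
* The linker is greedy mutual-nearest-neighbour; it is deterministic and
  matches the stated algorithm class, but it does not attempt global
  assignment and will break tracks under displacements comparable to cell
  spacing.
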