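# Methods

`hlecell` simulates the coupled morphological evolution and motility of a
single adherent cell (parameterised for myofibroblasts) on rigid substrates
that are either uniformly adhesive or micropatterned with an adhesive stripe.
This note records the model, the numerical choices, and the limits of what
the scaled-down test problems demonstrate.

## Model

### Morphological microstates

A microstate is a smooth planar displacement field applied to the reference
disc of radius `R0` (the elastic resting shape, nucleus of radius
`R_N = 0.256 sqrt(pi) R0` concentric). The field is a bicubic tensor-product
spline — a 4x4 net of control points with open knot vectors of multiplicity
four and unit weights, i.e. a single Bezier patch over the bounding square
`[-R0, R0]^2` — so a microstate is a point in a 32-dimensional shape space.
The patch reproduces affine maps exactly and acts as a low-pass filter:
features below its characteristic wavelength (sub-filopodium scale) cannot
be represented. The disc is discretised with constant-strain triangles
(target edge `e`, default `R0/10`); each element carries a constant
deformation gradient `F`, principal stretches `(lambda_I, lambda_II)`, and a
region label. Out-of-plane incompressibility gives the current thickness
`b = b0/(lambda_I lambda_II)`.

### Free energy

The Gibbs free energy of a microstate on a rigid, densely coated substrate
is

```
G = rho0 V_C chi_u + int_C Psi_C dV + int_N Psi_N dV
```

* **Stress-fibre chemistry.** Actomyosin bundles at reference angle `phi`
  (from the stripe axis x2) carry `n_ss = lambda(phi)/(1+eps_ss)` functional
  units, with `lambda(phi) = sqrt(m.Cm)` the fibre stretch. Equality of the
  bound and unbound chemical potentials gives the angular concentration
  `eta(x, phi)` in closed form in the single global unknown `N_u` (unbound
  fraction), fixed by protein conservation; the whole cytoskeletal free
  energy then collapses to `rho0 V_C chi_u` with
  `chi_u = mu_u + kBT ln(N_u/(pi N_L))`. The assembly driving force is
  `(mu_u - mu_b)/kBT = -1 + sigma_max Omega (1+eps_ss)/kBT ~ 5.03` for the
  default parameters (`Omega` is read as a volume of `10^-7.1 um^3`; the
  bridge between chemical and mechanical units is
  `rho0 kBT ~ 12.84 kPa`).
* **Passive elasticity.** Cytoplasm and nucleus are 2D Ogden solids in the
  principal stretches (shear moduli 1.67 / 3.3 kPa, exponents 5 / 20, bulk
  moduli 35 kPa) plus a stiff quadratic area penalty (`kappa_bar = 1e5 kPa`)
  activating below `J = lambda_I lambda_II < Jc = 0.6`.
* The substrate is rigid (stores no energy) and the adhesion energy is
  configuration-independent on dense coatings, so both drop out of energy
  differences. All volume integrals use reference-configuration quadrature
  (equal to current volumes by incompressibility). The angular integrals use
  uniform bins on `[-pi/2, pi/2)` (default 36 bins = 5 degrees); for the
  pi-periodic integrands this mid-point rule is the periodic trapezoid rule
  and converges spectrally.

The unbound potential is unbounded below as `N_u -> 0`, and the exponentials
`exp(n_ss * 5.03)` grow quickly with stretch; both are evaluated in the log
domain with explicit guards.

### Suspension reference state

A cell in suspension cannot exchange traction with anything, so its stress
must vanish pointwise, *not* its energy gradient (the equilibrated Gibbs
energy is not conjugate to the total stress: its minimum is the spread
state). The package solves the one-degree-of-freedom traction-free balance
for a spatially uniform equibiaxial cytoplasm stretch with an undeformed,
stress-free nucleus:

```
(pi/2) H0 sigma_max eta(lambda) lambda  +  kappa_C J (J - 1)  (+ penalty) = 0
```

For the default parameters the root is `lambda_susp = 0.9140`, i.e. the
suspended cell is a circle of radius `0.914 R0`, with `N_u = 0.074` (93% of
stress-fibre protein bound) and `G_S = -4.106 kPa R0^3`. `G_S` normalises
all energies (`G_hat = G/|G_S|`) and times. A compatible axisymmetric
equilibrium solve (elastic nucleus, traction-free rim) gives an outer radius
of 0.934; the uniform solve is the package's reference definition because it
is the cleanest one-parameter statement of the same balance.

### Homeostatic ensemble and temperature

On a substrate the cell fluctuates over microstates with stationary law
`P ∝ exp(-zeta G)`. The distribution parameter is set by the homeostatic
constraint `<G> = G_S`, imposed here on the normalised energy:
`<G_hat> = sign(G_S) = -1`. `calibrate_zeta` estimates `<G_hat>(zeta_hat)`
by averaging several random-walk Metropolis chains (single-coordinate
Gaussian proposals, step adapted to ~30% acceptance during burn-in, hard
rejection of folded, over-stretched or off-stripe proposals) and solves the
monotone root problem by a doubling bracket plus bisection/secant, with
common random numbers across iterates. At the test resolution
(`e = R0/5`) the calibrated value is `zeta_hat ~ 4` on the unpatterned
substrate, and the homeostatic temperature `1/zeta_hat` increases as the
stripe narrows.

### Admissibility and the maximum-stretch cap

Microstates are rejected when any element folds over (`det F <= 0.01`) or
when the boundary self-intersects (shape observables flag this), and — a
deliberate regularisation of this package — when any local major principal
stretch exceeds `lambda_max = 4`. The affine recruitment law
`n_ss ∝ lambda` inside `exp(n_ss (mu_u-mu_b)/kBT)` makes a *single*
many-fold-stretched region lower the global chemical term roughly linearly
in `lambda`, while the Ogden deviatoric term (prefactor `2 mu/m^2`) grows
too slowly to contain it; unregularised chains therefore drift into spike
states (`lambda_I ~ 10-20`, `G_hat ~ -10`) far outside both the physical
intent of the chemistry (fibre recruitment at moderate stretch) and the
regime in which the elastic constants were calibrated. The cap bounds the
landscape depth; with it, the calibrated `zeta_hat` lands in the same range
as the full-scale framework and ensemble shapes stay in the observed
morphological range (aspect ratios up to ~5).

### Langevin dynamics

The control coordinates obey the overdamped normalised Langevin equation

```
dr_hat/dt_hat = -dG_hat/dr_hat + sqrt(2/(zeta_hat dt_hat)) N(0,1)
```

whose Fokker-Planck stationary law is exactly the homeostatic ensemble.
Time is measured in units of `gamma R0^2 / |G_S|` (about 10 minutes for
fibroblasts); the mobility `gamma` only relabels time. Integration is
forward Euler-Maruyama (default `dt_hat = 0.001`; the scaled-down studies
use 0.01, checked against halved steps for the reported qualitative
metrics). The gradient is numerical: plain central differences
(`h = 1e-6`) in the compiled fast path, adaptive Richardson-extrapolated
differences available through `energy_gradient`. On stripes a smooth
quartic barrier (stiffness `1e4` per node in normalised-energy units,
equilibrium protrusion depth well under half an element edge) supplies the
differentiable confinement force that the Monte-Carlo sampler implements as
hard rejection.

Explicit integration of this stiff, constraint-laden energy needs guards,
all inactive in benign states: the per-coordinate drift displacement is
capped at `0.05 R0` per step; a step raising the total normalised energy by
more than 20 (entering states with relative Boltzmann weight `< e^-20` at
`zeta_hat ~ 1`) is redrawn; steps producing inadmissible kinematics are
redrawn from a dedicated noise pool, then retried with halved sub-steps,
and in the rare irrecoverable case the state is frozen for one step. Seeds
fully determine trajectories (one RNG per trajectory, `seed + index`).

## Observables

Shape metrics come from the deformed boundary polygon: area, perimeter,
form factor `FF = p^2/(4 pi A)`, and the best-fit ellipse defined by equal
area and second area moments (aspect ratio `AS`, orientation `phi` from the
stripe axis in `(-pi/2, pi/2]`). Spreading is summarised by
`A_hat = (A_mean - A_R)/(A_inf - A_R)` with `A_R = pi (0.914 R0)^2` and
`A_inf` the late-time ensemble mean. Motility: squared centroid
displacement per trajectory, ensemble `MSD_hat`, stripe-direction
`MSD_hat_y`, and the dimensionality parameter
`Lambda_hat = 2 (MSD - MSD_y)/MSD` (1 isotropic, 0 for motion confined to
the stripe axis). Orientational order uses the doubled-angle construction
for axial data: `Theta = sqrt(<cos 2phi>^2 + <sin 2phi>^2)` over
trajectories, and the cytoskeletal analogue `Theta_cyto` applied to the
spatial (volume-weighted) distribution of dominant-bundle directions after
subtracting their volume average (computed per configuration, then averaged
over trajectories). Relaxation timescales are single-exponential fits
`x(t) = x_inf - (x_inf - x_R) exp(-t/tau)` with both endpoints taken from
the data and `tau` the only fitted parameter; MSD slopes are linear fits
over the late window `[0.1 T, T]`.

The reported MSD slope follows the single-particle convention in which the
slope is compared directly with `D_hat = 1/zeta_hat`; under the
per-coordinate Langevin algebra a free particle would have slope
`4/zeta_hat` (two coordinates, each `2 dt/zeta`), so both conventions are
stated where it matters. The observed full-model slope lies well below
either free-particle value: centroid motion requires coordinated
fluctuations of all 32 shape coordinates.

## Reduced ellipse model

Restricting the cell to a spatially uniform ellipse with axes along x1/x2
leaves two degrees of freedom `(lambda_1, lambda_2)`; the same free energy
is evaluated with a single global conservation solve (the nucleus deforms
affinely with the cytoplasm, which shifts the seeded energy ~0.3% above the
idealised suspension value). The noise-free gradient flow
`dlambda_i/dt = -dG_hat/dlambda_i` from the suspension circle shows the two
morphological timescales directly: a fast spreading regime (area ratio
rises to ~1.8 while `AS < 1.005`), then elongation at essentially constant
area toward the asymmetric minimum (`AS ~ 1.9`). The symmetric spread state
is a saddle; the seed therefore carries a relative `lambda_1` excess of
1e-3 — any smaller value gives the same path with a delayed elongation
onset, but must outgrow the flow's stopping tolerance (`||grad|| < 1e-4`).

## Scaled-down study sizes

The full-resolution problem (mesh edge `R0/10`, `dt_hat = 0.001`,
trajectories to `T_hat = 4000`, ensembles of 100) is a cluster-scale
computation. The shipped tests and examples use deliberately scaled-down
conditions chosen as the package's standard desk-scale study: mesh edge
`R0/5`, 18 angular bins, `dt_hat = 0.01`, ensembles of 10 trajectories to
`T_hat = 60`, with the homeostatic temperature recalibrated at that
resolution (`zeta_hat ~ 3.6` unpatterned, `~1.5` on the unit-width
stripe). These sizes resolve the contact-guidance phenomenology (loss of
the second motility dimension and rise of orientational order on narrow
stripes; higher homeostatic temperature under confinement;
sub-free-particle centroid diffusivity; Langevin/Metropolis stationary
agreement) but not the stochastic two-timescale separation: at this scale
the stationary mean aspect ratio (~1.4) barely exceeds the instantaneous
fluctuation level of a noisy shape's best-fit ellipse, so the slow
elongation drift visible at full resolution is masked, and the
area-before-elongation ordering is demonstrated by the deterministic
reduced model instead.

## Known limitations

* The stretch cap `lambda_max` is a regularisation, not part of the
  free-energy model itself; results within the admissible region are
  unaffected, but extreme filopodial protrusions are excluded by fiat.
* The 1-DOF suspension solve and the compatible axisymmetric solve bracket
  the deformed suspension radius (0.914 vs 0.934); the package reports the
  former.
* Euler-Maruyama at `dt_hat = 0.01` with the energy-jump guard slightly
  distorts the stationary law relative to the exact homeostatic ensemble;
  stationarity is verified exactly on low-dimensional toy systems and only
  qualitatively for the full model.
* Ballistic (persistent) motility below the noise correlation time is
  outside the model by construction; so are deformable substrates,
  explicit focal-adhesion kinetics, and 3D geometry.
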