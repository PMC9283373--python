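# hlecell

Langevin dynamics of single adherent cells: coupled morphological evolution
and motility on unpatterned and stripe-micropatterned rigid substrates.

## The problem

When a suspended cell (a fibroblast, say) is seeded on an adhesive
substrate, its area equilibrates in tens of minutes while its elongation
keeps evolving for many hours — an order-of-magnitude separation of
timescales produced by a single underlying dynamics. On substrates
micropatterned with adhesive stripes the same dynamics produces *contact
guidance*: cells align with the stripe and their random motility collapses
from two-dimensional to one-dimensional. `hlecell` is a self-contained
implementation of a statistical-mechanics framework that reproduces these
phenomena from one free-energy function and one stochastic equation, for
researchers in cell mechanobiology who want a hackable, tested reference
implementation.

## The model

A cell morphology is a smooth displacement field of a reference disc
(radius `R0`), parameterised by a 4×4 net of Bezier control points — 32
coordinates `r`. Each morphology carries a Gibbs free energy

    G = rho0 V_C chi_u + ∫ Psi_C dV + ∫ Psi_N dV,

where `chi_u` is the chemical potential of unbound stress-fibre protein
(set by chemical equilibrium between bound actomyosin functional units at
every orientation and the free pool, with conservation of total protein)
and `Psi_C`, `Psi_N` are 2D Ogden strain-energy densities of cytoplasm and
nucleus plus an area-compression penalty. Spreading lowers the cytoskeletal
term and raises the elastic one; that competition shapes the landscape.

A cell in suspension must be self-equilibrated, which pins a unique
traction-free state (stretch `lambda_susp = 0.914`, energy `G_S < 0`). On a
substrate the cell instead fluctuates over morphologies with stationary law
`P ∝ exp(-zeta G)`; the homeostatic constraint `<G> = G_S` calibrates the
"temperature" `1/zeta` of these non-thermal fluctuations. The dynamics is
the overdamped Langevin equation (normalised by `|G_S|` and the timescale
`gamma R0^2/|G_S|` ≈ 10 min)

    dr/dt = -dG/dr + sqrt(2/(zeta dt)) N(0,1),

whose Fokker–Planck stationary law is exactly that ensemble. Morphology and
motility are then two faces of one process: the centroid moves only through
coordinated shape fluctuations.

See `docs/methods.md` for the complete model description, parameter table
semantics, numerical guards and known limitations.

## Worked example

Suspension reference state (the traction-free balance of stress-fibre
tension against cytoplasm elasticity):

```text
$ hlecell suspension
{
  "lambda_susp": 0.9139855488868526,
  "radius_ratio": 0.9139855488868526,
  "GS_kPa_R03": -4.1062453085954,
  "Nu_hat": 0.07422192645459577,
  "stress_residual_kPa": 3.55e-15
}
```

The suspended cell is a circle of radius `0.914 R0`: contractility pulls it
8.6% below its elastic resting radius, with 93% of stress-fibre protein
bound (`Nu_hat = 0.074`). `GS_kPa_R03` is the reference energy that
normalises everything else.

The reduced two-variable ellipse model shows where the two morphological
timescales come from. `hlecell reduce --out out/` writes the landscape and
the noise-free descent path; selected columns of the path table read

```text
t_hat  A_over_AR  AS
0.0    1.000      1.001
0.4    1.629      1.001
0.8    1.774      1.002
2.0    1.800      1.011
4.4    1.774      1.452
6.0    1.886      1.896
7.6    1.892      1.899
```

— the area completes its rise by `t_hat ≈ 0.8` while the cell is still
circular (regime I), then the aspect ratio climbs to ~1.9 along an area
plateau (regime II): the free-energy landscape has a fast spreading valley
feeding a slow elongation canyon, so one rate constant yields two apparent
timescales.

Stochastic trajectories on a stripe (width `W = 2 R0`, i.e. `W_hat = 1`),
with the homeostatic temperature calibrated first:

```bash
hlecell simulate --pattern stripe --w-hat 1 --zeta-hat auto \
    --t-sim 60 --dt 0.01 --n-traj 10 --thin 25 --edge 0.2 --n-phi 18 \
    --seed 1 --out runs/stripe
hlecell analyze runs/stripe/*.h5 --out stripe_metrics.csv
```

`analyze` prints the fitted timescales and MSD slope and writes a tidy
table of ensemble means (area, aspect ratio, form factor, MSD, the
dimensionality parameter `Lambda_hat` and the order parameter `Theta`
against normalised time). On the stripe, `Lambda_hat` decays from ~1
toward 0 (motility turning one-dimensional) and `Theta` rises toward 1
(alignment with the stripe) — contact guidance emerging from confined
fluctuations. On an unpatterned substrate (`--pattern unpatterned`) the
same pipeline keeps `Lambda_hat` near 1, and the MSD slope lies far below
the free-particle value `1/zeta_hat` because centroid motion requires
coordinated fluctuations of all 32 shape coordinates.

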