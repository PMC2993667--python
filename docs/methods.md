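# Methods

## Model structure

A network model is a list of species and a list of weighted logic rules.
Species are either *inputs* — clamped algebraic signals whose value at time
t is the stimulus-schedule level times the species' Y_MAX — or *states*,
which obey

    dY/dt = (1/τ_Y) · (drive_Y · Y_MAX,Y − Y).

Treating inputs algebraically (rather than as fast ODE states) makes an
input's Y_MAX a well-defined perturbation target in sensitivity analysis
and removes an arbitrary input time constant from the dynamics.

`drive_Y` is assembled from the rules targeting Y in three groups:

* **activating / mixed rules** (at least one plain term): each contributes
  `W · Π f_act(plain terms) · Π f_inhib(negated terms)`; contributions are
  OR-combined by the probabilistic sum `1 − Π(1 − vᵢ)`, the unique
  associative extension of the two-input form `f(x)+f(y)−f(x)f(y)`.
* **constant sources** (empty left side): contribute `W` as an OR term.
  Their weight is the species' basal (constitutive) drive.
* **purely inhibitory rules** (every term negated): multiply the combined
  drive by `1 − W · Π f_act(negated terms)`. OR-combining an inhibitor
  could only ever raise activity, so inhibition must gate multiplicatively;
  with W = 1 and a single term this reduces to a plain `f_inhib` factor.

AND within a rule is the product of the terms' kernel values.

## Activation kernels

The default kernel is the normalized Hill function
`f_act(X) = B·Xⁿ/(Kⁿ+Xⁿ)` with `B = (EC50ⁿ−1)/(2·EC50ⁿ−1)` and
`K = (B−1)^{1/n}`, the unique closed form satisfying f(0)=0,
f(EC50)=0.5, f(1)=1. Validity requires `EC50 < 0.5^{1/n}` (otherwise K is
not real) and `2·EC50ⁿ ≠ 1`; construction fails loudly outside this region.
Outputs are clamped to exactly 1 for X ≥ 1 (so activities cannot exceed
Y_MAX) and to exactly 0 for X ≤ 0. The lower clamp is our own addition: the
solver can transiently undershoot zero within its tolerance, and without
the clamp a negative state raised to a non-integer power is undefined.
`f_inhib` is defined as `1 − f_act` everywhere, including the clamped
regions (so `f_inhib(X<0) = 1`).

Three comparison kernels share the interface so a model can be re-run with
only the scalar curve changed: traditional (unnormalized) Hill
`Xⁿ/(Kⁿ+Xⁿ)` with presets (n=3, K=0.3) and (n=2, EC50=0.5), a piecewise
step at 0.5, and the identity (linear). The traditional Hill kernel is not
clamped (it is already below 1); the step kernel can park species at values
where sensitivities are undefined, which the sensitivity module reports as
NaN rather than zero.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| W | 1 | reaction weight in [0,1]; fraction of maximal drive a rule can contribute |
| n | 1.4 | Hill coefficient (steepness); the robustness scan shows results are insensitive over ≈1.0–1.7 |
| EC50 | 0.5 | input activation for half-maximal output; 0.5 is the unique choice that neither amplifies nor attenuates a linear chain |
| τ | 1 | relaxation time constant (model time is dimensionless) |
| Y_MAX | 1 | maximal fractional activation; <1 models knock-down, >1 overexpression |

## Numerical integration and steady states

The system is non-stiff; we integrate with an adaptive explicit
Runge–Kutta 3(2) pair (`scipy.integrate.solve_ivp`, method RK23), rtol
1e-6, atol 1e-8. Stimulus-schedule breakpoints force solver restarts so
input steps are not smeared by the controller. Trajectories are sampled on
a uniform reporting grid (401 points by default).

Steady states are detected on the *derivative*: integration stops when
`max_i |dY_i/dt| < θ_ss` (default 1e-6 per unit time), so clamped inputs
cannot mask residual drift. Because a damped oscillation passes through
points where all derivatives are momentarily small, a candidate steady
state must persist through a 5-time-unit confirmation window before it is
accepted. If the derivative norm never settles within the search horizon
(T_max = 1e4 τ units), the run is flagged non-converged and the
time-average over the last 10% of the horizon is returned — oscillatory
regimes (which loop knockouts can produce) are reported, never silently
truncated.

## Sensitivity analysis

One column of the sensitivity matrix = one numerical experiment: copy the
model, scale one species' Y_MAX by (1 + dP) with dP = −0.25 by default,
rerun to steady state, and record `S_ij = (ΔY_i/ΔP_j)(P_o,j/Y_o,i)`.
Perturbed runs continue from the cached baseline steady state; this is
faster and, in multistable regimes, selects the branch continuously
connected to the baseline. Entries with `|Y_o,i| < 1e-9` are undefined and
NaN-masked (never replaced by 0); comparison statistics exclude them.
Qualitative classification maps S to {−1, 0, +1} with a ±0.003 dead zone.
Matrix-vs-matrix comparison reports the Pearson correlation over jointly
finite entries plus qualitative match/opposite-sign counts. Robustness
scans rebuild the model along one axis (perturbation magnitude dP, or the
default n or EC50 applied to all reactions) and correlate each matrix
against the default reference; grid points with an invalid (n, EC50) pair
are reported as NaN with a warning.

## Parameter fitting

`fit` frees a named set of parameters (τ, W, EC50, n, Y_MAX, or a basal
constant-source weight added to one species) with box bounds per kind and
minimizes the summed squared residual between simulated and target time
courses with `scipy.optimize.least_squares` (trust-region reflective).
Targets are linearly interpolated onto the simulation reporting grid.
Instead of manual tuning, the fit runs a seeded multi-restart (default 10;
first start at the user guess or box midpoint, the rest uniform in the
box) and keeps the best final residual, making results bit-reproducible
for a given seed. A simulation failure inside the objective contributes a
large constant penalty rather than aborting. An 11-parameter receptor-
proximal recipe (4 τ's, 3 weights, 3 EC50's, 1 basal receptor-activity
term) is validated in the test suite as a canonical use; `n` is fittable
but excluded from that recipe.

## The shipped fixtures

**toy** — inputs A, B; receptors C, D; output E with rules A⇒C, E⇒C
(OR-merged on C), B⇒D, C & !D ⇒ E. The C↔E positive feedback makes E a
latch: a transient A pulse switches E on permanently, and a B pulse (via
the !D gate) erases the memory. All parameters are defaults.

**betaAR** — the cardiac β₁-adrenergic network, 25 species / 36 reactions.
Two reconstruction choices were required because the published reaction
table does not fully specify the constitutive species:

1. *G-protein availability.* A recycling rule (GsaGDP & Gbg ⇒ GsaBg) would
   give G_βγ an outgoing edge — it is a terminal node in this model — and,
   because the normalized Hill kernel is superlinear near 0 (n > 1), such
   a loop is locally contractive at the origin: the G-protein pool would
   collapse to the dead state at any interior receptor activity. The
   inactive heterotrimeric pool GsaBg is instead constitutively available
   (source weight 1). GsaGDP is then a terminal bookkeeping node; it,
   PKAR and GRK are the three species outside the 22-species sensitivity
   set.
2. *Basal activity of negative regulators.* GRK, PDE, PKI, PP1 and PP2A
   are constitutive. A basal weight of 1 would pin them at Y_MAX, where
   f_inhib vanishes identically and the entire cAMP/PKA axis shuts off.
   Their source weights are set to 0.2, chosen once so that the model
   reproduces the network's documented qualitative behavior: interior
   steady states at baseline inputs (NE=0.5, FSK=0.2, IBMX=0.2), a
   monotone NE dose response, damped-oscillatory PLB adaptation under
   sustained NE, amplification of PLB by the inhibitor-1 feed-forward
   loop, steady-state adaptation controlled by the PKA receptor-feedback
   loop, and damping increased by the GRK feedback loop.

With this reconstruction the GRK-feedback knockout *reduces* damping
(larger late-transient PLB swings) but the oscillations still decay rather
than becoming strictly sustained; tests assert the directional effect
only.

**betaAR_integrin** — betaAR plus a mechanical Stress input, integrin
activation (Stress ⇒ Itg), integrin-dependent G-protein coupling
(Itg & GsaBg ⇒ GsaGTP) and PKA-mediated integrin β-subunit phosphorylation
(PKAC & Itg ⇒ Itgbp): mechanical load can drive the cAMP/PKA axis without
any adrenergic agonist.

## File formats

Species table (`name,role,tau,Ymax,y0`) and reaction table
(`id,rule,weight,n,EC50`), CSV or TSV, UTF-8, `#` comments ignored, blank
cells = defaults. The writer emits these exact columns, and
load(write(model)) is the identity on species and reactions. The
sensitivity set is not part of the file format; it defaults to all species
on load, and the built-in fixtures set it programmatically.

## What the fixtures do and do not show

The fixtures are reconstructions from a published network topology, not
measured data. Tests that pass on them demonstrate the *framework's*
properties — exact kernel normalization, gate algebra, forward invariance
of trajectories, robustness of the sensitivity matrix to the perturbation
magnitude (min Pearson r ≈ 0.99 over −10%…−75%) and to the default Hill
coefficient (min r ≈ 0.93 over 1.01…1.7), parameter recovery by the
fitter — and the network's qualitative logic. They do not validate kinetic
parameters against cardiac measurements: absolute activation levels and
oscillation periods depend on the basal-weight choices above. Comparisons
against detailed biochemical models of the same pathway require those
models' code and are out of scope; the comparison *statistics* (Pearson r
over jointly finite entries, qualitative match counts) are implemented and
oracle-tested on hand-built matrices.

## Problem sizes

The acceptance script computes one 22×22 reference matrix (23 steady-state
solves), a four-point perturbation-magnitude scan and an eight-point
Hill-coefficient scan — roughly 300 steady-state solves in total, well
under a minute on one CPU. The test suite's dynamic checks use horizons of
40–120 time units at 401–2401 reporting points.
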