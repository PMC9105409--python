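# Methods

## Scope and units

The package models a three-species system — a ligand (atRA), a binding
protein (CRABP1/2), and a CYP enzyme — through four layers: exact 1:1
binding equilibria, two-state association kinetics, steady-state enzyme
kinetics, and a combined protein–protein interaction rate law.

All concentrations are nM internally; first-order rates are min⁻¹ and
association rates M⁻¹ min⁻¹ (the stopped-flow convention), converted to
nM⁻¹ s⁻¹ only inside the ODE integrator. Public constructors accept
explicit unit tags (`uM`, `M`, …) because the source assays mix µM protein
stocks with nM dissociation constants and silent unit errors are the
dominant failure mode in this kind of analysis. Velocities are per-enzyme
rates (pmol·min⁻¹·pmol-CYP⁻¹ ≡ min⁻¹).

## Binding equilibrium

Unbound ligand comes from the positive root of the mass-balance
quadratic; the complex and unbound binder follow by mass balance. Two
degenerate paths are handled analytically: `kd = 0` returns the
stoichiometric limit `max(A_t − C_t, 0)` (the quadratic is 0/0 there),
and a negative discriminant after floating-point rounding is clamped to
zero. The closed form is verified against a bracketed-root oracle on 10⁴
random systems to 1e-6 relative.

Enzyme-bound species are deliberately neglected when computing unbound
ligand and binder: enzyme totals in the modelled assays (0.5–5 nM) are
2–3 orders of magnitude below ligand/binder totals, so the binary and
ternary enzyme complexes do not materially deplete either pool. This is a
documented assumption, not a runtime check; the package is not intended
for designs where enzyme and ligand totals are comparable.

## Stopped-flow kinetics

Association is modelled as single-step and bimolecular; conformational
intermediates are outside scope. The ODE is integrated with LSODA at
rtol 1e-8 / atol 1e-6 nM. These tight tolerances matter: at the default
design (0.5 µM binder, 2 µM ligand) the trace equilibrates in ~0.1 s and
k_off is identified from a plateau deficit of only ~0.3% of the binder
total, which sloppier tolerances bias. The initial condition holo = 0 is
applied at mixing time t = 0 regardless of where the fitted grid starts,
so dead-time exclusion never time-shifts the model.

Fitting runs in log₁₀(k_on, k_off) space with seeded multistart (8 starts
over k_on ∈ [10⁶, 10¹⁰] M⁻¹ min⁻¹, k_off ∈ [10⁻², 10²] min⁻¹) because the
two rates are strongly correlated at a single mixing condition. Replicate
injections are fitted jointly (one parameter pair, pooled residuals) by
default; per-experiment fits summarized as mean ± SD across days are the
intended replicate structure. The first 1 ms of each trace is excluded
(instrument dead time, configurable). No baseline/offset term is fitted
by default; an additive offset is available behind a flag.

Fluorescence is converted to holo-binder concentration by a per-nM yield
measured on saturating traces (windowed mean ÷ binder total; windows
0.4–0.8 s or 0.6–1.0 s depending on the binder, applied per injection).
One caveat discovered during development and worth stating: at a 4-fold
ligand excess binding is only ~99.7% complete, so the yield estimated
this way is biased low by the same ~0.3% that constitutes the k_off
-identifying plateau deficit. Recovery studies on synthetic data
therefore convert traces with the generator's known yield; with a
re-estimated yield the recovered K_d can be essentially arbitrary at this
design. This is an intrinsic identifiability limit of single-condition
stopped-flow, which is why K_d recovery is only asserted within ±50%.

## Enzyme kinetics

CYP26A1's Michaelis constant (~5 nM) is only tenfold above the assay
enzyme concentration (0.5 nM), so saturation curves use the Morrison
tight-binding quadratic with the enzyme total fixed at its known value —
fitting E₀ at this design is non-identifiable. The dilute-enzyme limit
reduces to Michaelis–Menten and is verified numerically.

Saturation fits are unweighted least squares (1/y² weighting available
behind a flag); technical duplicates are averaged per concentration
before fitting. For holo-binder substrate series (1:1 atRA:binder
complexes), the "unbound K_m" is obtained by transforming the substrate
axis to unbound atRA through the binding quadratic and refitting; the
Morrison form is used on the unbound axis as well by default, with plain
Michaelis–Menten available.

Free-drug predictions compare the Michaelis–Menten velocity at the
unbound ligand concentration with the velocity were the full ligand total
free, reporting 100·(1 − v_bound/v_free) at full precision; rounding is a
display concern only.

## Interaction rate law

The mixed inhibition/channeling law is evaluated in the unbound species.
Two exact reductions anchor it: with no apo-binder it is Michaelis–Menten,
and with βk_cat = k_cat and αK = K_i the interaction terms cancel
algebraically for any binder concentration ("no net interaction"). Both
hold to machine precision in the tests.

The composite parameters αK (nM) and βk_cat (min⁻¹) are fitted directly
rather than dimensionless α and β: the data constrain only the products,
and fitting the composites avoids committing to which constant α
multiplies (for CRABP1 the relevant K_d and K_m are numerically equal, so
the data cannot disambiguate). Dimensionless α is reported under both
conventions, and β as βk_cat/k_cat.

The global fit estimates (K_i, αK, βk_cat) in log space with seeded
multistart (16 starts; K_i, αK ∈ [10⁻³, 10³] nM, βk_cat ∈
[10⁻³·k_cat, 10·k_cat]) against the pooled residuals of all supplied
datasets, with K_m, k_cat and K_d fixed at their independently determined
values. Saturation and titration data are pooled by default. K_i is
mostly constrained by apo-excess points; if no point has binder total
above the atRA total the fit warns and flags K_i as weakly constrained,
and binder-free-only data raise a non-identifiability error. Parameter
uncertainty, when requested, comes from a seeded residual bootstrap
(200 resamples by default) since no analytic intervals are trustworthy
this close to identifiability boundaries.

## Synthetic data

The generators emulate the three assay designs end to end: stopped-flow
(0.5 µM binder + 2 µM atRA, 2 s, 1000 points, 5 injections per
experiment, 3 experiments), saturation series (2-fold steps 5–320 nM, 0.5
nM enzyme, triplicate), and apo-binder titrations (50 nM atRA, 0–400 nM
binder, triplicate). Defaults for noise are proportional Gaussian with 5%
CV for velocities (matching typical day-to-day scatter of such assays)
and additive Gaussian at ~2% of the plateau signal for fluorescence. Each
generator call takes one explicit seed and owns its RNG stream; identical
seeds give bit-identical data.

What the generators do *not* emulate: LC-MS/MS peak integration and
extraction recovery, substrate depletion over the incubation,
photobleaching, instrument drift, or day-level systematic (as opposed to
random) effects. Passing recovery tests therefore demonstrate that the
estimators are consistent and well-conditioned under the stated noise
model at the experimental designs — not that real data are free of the
systematic errors above.

## Problem sizes in tests and the acceptance script

Recovery studies use 20 seeded repetitions for the Morrison and
interaction-model medians (the interaction-model bias invariant uses
200), and 3 simulated experiments of 5 injections for the stopped-flow
K_d. These sizes give stable medians for the quantities asserted; the
studies are pure functions of the seed and scale up by changing one
argument.

## Known limitations

- Single-site 1:1 binding only; no cooperative or multi-site models, and
  no competition among more than two binding species.
- The two-state stopped-flow model cannot resolve k_on and k_off
  independently with confidence from one mixing condition; only
  multi-concentration designs would.
- The interaction rate law cannot distinguish slow ligand release from
  the ternary complex from a genuinely slower ternary turnover; βk_cat is
  a composite observable.
- The pipeline's simulation mode uses the known fluorescence yield; with
  measured data the yield calibration bias described above propagates
  into k_off.
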