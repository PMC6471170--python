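# Methods

`renalpk` studies how renal impairment (RI) changes the pharmacokinetics of
drugs that are eliminated almost entirely by hepatic metabolism. RI brings
three mechanistic handles into play: reduced glomerular filtration (GFR),
altered plasma protein binding (fraction unbound, fu), and altered
drug-metabolizing-enzyme (DME) expression/activity — the last partly through
circulating uremic toxins that competitively inhibit CYPs and UGTs. The
package provides a minimal mechanistic simulator for these effects, a
perturbation-grid layer for systematic exploration, and a ranking procedure
for selecting mechanistic modifications against observed clinical PK.

## The PK model

One oral dose D enters a gut depot; the absorbable fraction `f_abs · f_gut`
transfers to a one-compartment central volume with first-order rate `ka`
after hepatic first pass. Hepatic clearance is well-stirred:

    CL_h = Q_h · fu_b · CL_int,u / (Q_h + fu_b · CL_int,u),    fu_b = fu / B:P

with the unbound intrinsic clearance summed over enzyme pathways. Each
pathway follows Michaelis–Menten kinetics with competitive inhibition:

    v = Vmax · S / (KM · (1 + R) + S),      R = [I] / Ki

so the inhibition index R multiplies the apparent KM. In the linear range
(S ≪ KM, the default mode) each pathway contributes
`Vmax · abundance / (KM · (1 + R))`; Vmax is in pmol product/min/pmol enzyme,
total hepatic abundance in pmol (microsomal abundance × microsomal protein
per g liver × liver weight), KM in µM on an unbound-substrate basis.
Renal clearance is filtration only, `CL_r = fu · GFR · f_filtered`, because
the study compounds have negligible renal elimination of parent drug; the
zidovudine fixture carries a modest filtered fraction (0.18).
Bioavailability is mechanistic: `F = f_abs · f_gut · (1 − CL_h/Q_h)`.
The distribution volume scales proportionally with fu relative to the
compound's reference fu (`Vss = vss_per_kg · weight · fu/fu_ref`), the
leading-order behaviour of tissue partitioning when binding falls.

In linear mode the system is solved with the exact closed-form
one-compartment oral solution. A saturable mode integrates the ODEs
(`scipy.integrate.solve_ivp`, LSODA, rtol 1e-8) with CL_int saturated by the
unbound *systemic* concentration — a static well-stirred approximation that
avoids the implicit liver-outflow balance; it is cross-checked against the
closed form in the linear limit (they agree to ≪ 1 % in AUC) and conserves
mass to the solver tolerance.

### Exact consequences worth knowing

For oral dosing with hepatic-only elimination the well-stirred model gives
the identity `AUC_oral = f_abs · f_gut · D / (fu · CL_int,u)` — the (1 − E)
first-pass factor cancels the flow dependence of CL_h exactly. Three laws
follow, and the test suite asserts them on a single-pathway, low-extraction
probe compound:

* inhibition at index R raises oral AUC exactly (1 + R)-fold;
* raising fu from 0.04 to 1.0 lowers oral AUC exactly 25-fold;
* a k-fold expression change lowers oral AUC exactly k-fold.

Two further consequences are less obvious:

* **The fu fold is expression-invariant.** Because the identity contains
  `fu · CL_int` only, the 25-fold fu effect cannot grow or shrink with
  expression in this model class; and since Vss ∝ fu, the unbound
  concentration trajectory is fu-invariant, so Michaelis–Menten saturation
  cancels too. Reports of a slightly smaller fu effect at reduced expression
  must involve mechanisms outside this model (full-PBPK distribution with a
  plasma-volume floor, gut-wall physiology). The suite asserts the exact
  invariance rather than a direction the model provably does not contain.
* **Uniform expression scaling cancels in inhibition ratios.** If every
  pathway's Vmax is scaled by the same factor, the AUC ratio between R
  levels is unchanged. Attenuation of an inhibition effect in RI therefore
  requires *enzyme-selective* expression reduction (e.g. CYP3A4 only, while
  a CYP3A5 or UGT route persists) or concentration-dependent saturation.
  The directional tests enable a CYP3A4-selective multiplier for exactly
  this reason.

## Virtual populations

Three classes — healthy, moderate RI, severe RI — at 100 %, 50 % and 10 % of
a normal GFR (120 mL/min reference). Inter-individual variability is
lognormal around stated means with stated CVs: weight (81/66 kg M/F, CV
0.18), hepatic blood flow (90 L/h, CV 0.20), microsomal protein per g liver
(40 mg/g, CV 0.30), liver weight (1650 g, CV 0.23), GFR (CV 0.15), enzyme
abundances (CYP3A4 137, CYP3A5 20, CYP2C9 73, UGT2B7 70 pmol/mg; CVs
0.41–0.80). Trials are sampled as 10 trials × 10 subjects by default. The
"modified expression" flag additionally multiplies hepatic CYP abundance in
the impaired classes (defaults 0.85 moderate, 0.75 severe; configurable per
enzyme). The quantitative size of this reduction is not established, so it
is deliberately free configuration; UGTs are left unchanged by default.
Identical seeds reproduce identical subject tables, and because every class
consumes the random stream in the same order, classes sampled with the same
seed are *paired* draws differing only in the scaled quantities — used
throughout the tests to remove Monte-Carlo noise from class comparisons.

Only GFR and (optionally) CYP expression change in the impaired classes.
Hypoalbuminemia-driven fu changes are applied explicitly via perturbation,
never implicitly by the population; hematocrit, transporters and active
secretion are out of scope.

## Compound fixtures

Shipped parameterizations for nifedipine (fu 0.039; CYP3A4 + CYP3A5),
sildenafil (fu 0.036; CYP3A4 + CYP2C9) and zidovudine (fu 0.80; UGT2B7 +
renal filtration) use those binding values plus literature-plausible
absorption, disposition and pathway parameters. They are approximations
intended for mechanistic and directional work, not for bioequivalence-grade
prediction; absolute exposures from proprietary full-PBPK parameterizations
are not reproducible here and are treated only as directional anchors.

## NCA

Cmax/tmax are grid maxima (earliest on ties); AUC uses linear-up/log-down
trapezoids; AUC∞ adds `C_last/λz` with λz from a log-linear regression on
the last 5 positive samples. A non-negative terminal slope marks AUC∞ and
CL/F unavailable rather than guessing. Samples below Cmax × 1e-9 are ignored
when selecting terminal points (the ODE integrator's absolute-tolerance
floor can otherwise produce a flat artificial tail far below any real
quantification limit). Summaries report geometric mean (the lognormal PK
convention), arithmetic mean, median and CV; tmax is summarized by both
median and mean since conventions differ. F is model-reported
(`f_abs·f_gut·(1−E)`), not estimated from an IV reference.

Grid-resolution guidance: with ka ≈ 2 h⁻¹ the absorption peak needs a step
≤ 0.25 h for AUC to be converged to < 0.5 %; slow scenarios (large R, low
fu) need the grid extended to cover ≥ 5 half-lives, and the simulator warns
when it is not.

## Scenario grids and ranking

`ScenarioGrid` crosses dose × fu × per-enzyme expression fold × per-enzyme R
× population; per-scenario seeds are `sha256(grid seed | scenario id)`
truncated to 31 bits, so extending a grid never perturbs existing scenarios.
Fold changes are reported in fold-increase/fold-decrease convention
(reference/scenario when the ratio is < 1).

Candidate simulations are ranked against observed clinical PK by

    δ = |log10(predicted / observed)|,   Σδ_all = Σ_params δ

ascending (0 is perfect), ties broken lexicographically by label. Base 10 is
used; the base only rescales Σδ and cannot change the order. δ is symmetric
in over-/under-prediction and invariant to shared units. A comparison report
flags a parameter "improved" when a candidate's |log10 ratio| is strictly
below the base simulation's.

## Synthetic data

* **Toxin panels** give `R = Σ_toxins [I]/Ki` per enzyme (competitive
  inhibitors at one site are additive). The shipped severe-RI panel (benzyl
  alcohol, indoxyl sulfate, p-cresol, hippuric acid) is *synthetic*: its Ki
  values are back-constructed so the aggregate bounds are exactly 26.6
  (CYP3A4), 2.4 (CYP2C9) and 2.5 (UGT2B7); the per-toxin splits are not
  measurements. IC50 → Ki conversion assumes competitive inhibition assayed
  at substrate ≪ KM (Ki ≈ IC50).
* **Observed-PK generation** runs a truth scenario through the full
  pipeline and multiplies each summary parameter by lognormal noise
  `exp(N(0, σ))`, `σ² = ln(1 + CV²)`. CV defaults to 5 %, modelling the
  sampling error of a reported geometric-mean parameter from a ~100-subject
  study (inter-individual CV ≈ 50 % ⇒ SE ≈ 5 %).
* **Candidate enumerations** mirror the three clinical studies' sizes
  (30 nifedipine-like: 5 fu levels × 3 R × 2 expression sets; 126
  sildenafil-like: 7 fu levels × 3 R CYP3A4 × 3 R CYP2C9 × 2;
  15 zidovudine-like: 5 fu levels × 3 R, one expression set). The exact fu
  level lists are constructed, since only the counts and the ranges (+5 % to
  +50 %, R ∈ {1, 10}, zidovudine capped at fu = 1.0) are established.
* **Random compound fixtures** draw plausible parameters with a controlled
  hepatic extraction regime (low ≈ 0.05–0.25, high ≈ 0.7–0.9 at mean
  physiology) for property tests.

## Parameter recovery

The recovery study asks whether Σδ ranking can re-identify a known
generating scenario from noisy synthetic observations: truth = nifedipine
in the severe class at 20 mg with fu +50 %, CYP3A4 R = 10 and reduced RI
CYP expression; 50 replicates at noise CV 5 %; all 30 nifedipine-like
candidates are scored with common-random-number populations (shared
subjects), and top-1/top-3 recovery rates are reported.

Substrate and truth were chosen for identifiability, and the failures of the
alternatives are themselves informative limitations:

* zidovudine's "fu +25 %" and "fu = 1.0" candidates are numerically
  identical after clamping (fu 0.80 × 1.25 = 1.0) — a guaranteed tie;
* sildenafil's mechanism space is near-degenerate: "CYP2C9 R = 1 with
  healthy expression" almost exactly cancels "reduced CYP expression" in
  CL_int (noiseless Σδ gap ≈ 0.04), so these hypotheses are practically
  indistinguishable from PK parameters alone. This mirrors the clinical
  comparison itself, where the two best sildenafil candidates' Σδ differ by
  only 0.002 — distinct mechanistic stories, equal fits.

Passing recovery on synthetic data shows the ranking machinery and the
noise model behave as designed; it does not show that real clinical data
identify a unique mechanism — the degeneracies above are the reason.

## Numerical choices and limitations

* Linear mode is the default; saturation matters only when *unbound*
  concentrations approach KM, which for the shipped fixtures requires
  supratherapeutic doses.
* Inhibition R is applied hepatically only; gut-wall CYP3A4 inhibition is a
  config switch away conceptually but not enabled, since its magnitude is
  unparameterizable from available information.
* No multi-compartment distribution, enterohepatic recycling, metabolite
  kinetics, auto-induction, transporters, IV dosing, or dose
  superposition. Female subjects are supported structurally (body-size
  scaling only) but not validated against any data.
* Synthetic populations and fixtures emulate the *structure* of the study
  conditions (trial layout, variability magnitudes, perturbation ranges),
  not any proprietary parameterization; passing tests demonstrate internal
  mechanistic consistency, not clinical predictive accuracy.
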