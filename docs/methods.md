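# Methods

This note records the modelling assumptions, numerical choices and known
limitations behind `carbotherm`, in the order the computation flows.

## Group-contribution estimates

The boiling-point, critical-temperature and critical-volume sums are the
classical Joback–Reid forms.  Two transcription issues in the source tables
required decisions:

* The critical-temperature denominator squares the *critical-temperature*
  group sum S = Σ N_k tc_k (the standard Joback form).  Squaring the
  boiling-point sum instead — as a plain reading of the printed formula
  suggests — produces nonsensical values for polyols, while the tc form
  reproduces the published polyol critical temperatures (sorbitol 1092.90 K,
  xylitol 947.5 K) to better than 0.1%.
* The acyclic -CH2- boiling increment defaults to the standard Joback value
  22.88 K because only that value reproduces the published table; the
  transcribed 22.288 K is selectable with `load_group_table(verbatim=True)`.

Group assignments for acyclic polyols (xylitol, sorbitol, mannitol) are
structurally unambiguous and packaged as verified.  Ring-sugar assignments
are packaged *unverified*: no assignment constructible from the packaged
group table reproduces the published ring-sugar critical volumes (e.g.
glucopyranose gives 421.5 rather than 460 cm³/mol), so downstream consumers
use the published descriptor table directly rather than recomputed values.

## The equation of state

**Reference and perturbation.**  The universal functions F_a and F_b and the
closed forms of the hard-sphere-chain reference and van der Waals
perturbation are not restated in the source describing the sugar
parameterization; they are completed here from the original PHSC formulation
(Song–Lambert–Prausnitz), encapsulated in `phsc/universal.py` so the
coefficients are swappable.  The effective hard-sphere diameter follows
d³ = σ³ F_b.  Supporting evidence that this completion matches the
parameterization: the packaged water parameters then give a liquid density of
1.003 g/cm³ at 298.15 K and 1 bar — within 0.5% of real water — although no
density data enters this package.

**Contact radial distribution function.**  The third BMCS term is
implemented with ζ² (not ζ as printed): only the squared form reduces to the
Carnahan–Starling contact value (1−η/2)/(1−η)³ in the pure limit, which is
enforced in the tests to 1e-12.  The pair packing measure is
ζ_ij = 2 (d_i d_j/(d_i+d_j)) ξ₂ with ξ₂ = (π/6)ρ Σ x_k r_k d_k², chosen so
ζ_ii = η for a pure fluid.

**Combining rules.**  σ_ij = (σ_i+σ_j)/2 and ε_ij = √(ε_i ε_j) with no binary
interaction parameter, consistent with the parameterization's claim of
prediction without additional adjustable parameters.  Cross association uses
CR-1: ε^AiBj = (ε^Ai+ε^Bj)/2, κ^AiBj = √(κ^Ai κ^Bj); self-association-only
operation is available via `PhscEos(..., cross_association=False)`.

**Association bookkeeping.**  Each component carries n_sites/2 donor and
n_sites/2 acceptor sites; all donors (acceptors) of a component form one
site class with a common unbonded fraction, which reduces the mass-action
system to at most two unknowns per component.  Donor–donor and
acceptor–acceptor interactions are zero.  The solver runs a few successive
substitutions into the Newton basin, then Newton (quadratic convergence,
machine-precision residuals), with damped successive substitution
(damping 0.5, 10⁴ iterations) as a fallback; residuals above 1e-12 raise.

**Helmholtz energy and consistency.**  The residual Helmholtz energy is the
*exact* integral of (Z−1)/ρ: closed forms for the reference and perturbation
parts, and the Michelsen–Hendriks variational functional for association
(Q = Σ x s (ln X − X + 1) − (ρ/2) ΣΣ ysXΔXsy), whose stationarity lets all
derivatives be taken at fixed site fractions.  Two independent routes to the
association compressibility — implicit differentiation of the mass-action
equations versus the ρ-derivative of the variational functional at fixed X —
agree to ~1e-12 and are both kept as a standing cross-check.

**Derivatives are complex-step.**  Fugacity coefficients come from
ln φ_i = ∂(n·A_res/NkT)/∂n_i|_{T,V} − ln Z with the mole-number derivative
evaluated by complex-step differentiation (h = 1e-150): the entire Helmholtz
path, association solve included, is dtype-generic, so the derivative carries
no subtractive cancellation.  The same trick supplies exact dP/dη inside the
density Newton.  This matters quantitatively: finite-difference stencils left
a ~1e-9 relative noise floor on the osmotic coefficient (amplified by the
1000/(M_w m) factor at low molality), which stalled the parameter fits;
complex step reduces it to ~5e-12.  For the same reason ln Z in the fugacity
expression uses Z = P/(ρk_BT) at the converged root rather than re-evaluating
the EoS sum — identical at the root, but smooth in model parameters.

**Density roots.**  P(η) = P is solved by safeguarded Newton with exact
derivatives (warm-started from the previous state in sweeps, or from η = 0.55
for a cold liquid), falling back to a bracket scan over η ∈ (0, 0.74) with
Brent refinement; the liquid branch is the highest-density root with
(∂P/∂ρ)_T > 0, the vapor branch the lowest.  Roots converge to ~1 ulp of η.

**Units.**  Internal units are K, ångström and molecules/Å⁻³, with energies
divided by k_B; pressures convert to pascal only at the API boundary.
Molality converts as x_s = m/(m + 1000/M_w).

**Conventions.**  a_w = x_w φ_w/φ_0w (the mole-fraction factor is required
for a_w → 1 at infinite dilution) and φ = −1000 ln a_w/(M_w Σνm) (the minus
sign is required for φ → 1).  Both factors are missing from the printed
property definitions in the source; the limits decide.

## Parameter regression

Five parameters (r, σ, ε/k_B, ε^AB/k_B, κ^AB) are fitted per sugar to binary
osmotic-coefficient data; the site count is held fixed by the two-per-OH rule
and the water row is the packaged reference, never refit here.  The reported
objective is the sum of relative absolute deviations Σ|φ_exp−φ_calc|/φ_exp;
the optimizer minimizes its smooth least-squares surrogate (squared relative
residuals) with bounded trust-region least squares.  The objective surface is
*multimodal with long curved valleys*: plain multi-starts routinely converge
to local minima with curve errors of ~1e-4.  The fitter therefore screens a
seeded Latin-hypercube pool (≥64 points) on the raw objective, runs the local
searches from the best candidates, and polishes the winner.  With the
default 8 starts this recovers the generating osmotic curve of noiseless
synthetic glucose data to ≲2e-7 — while the individual parameters still trade
off strongly (ε^AB and κ^AB compensate along a near-degenerate direction, and
κ may rail at a bound).  Identifiability of individual parameters from a
single-temperature binary osmotic curve should *not* be assumed; the curve,
not the parameter vector, is the reproducible object.  Bounds default to
r ∈ [1,15], σ ∈ [2,5] Å, ε/k ∈ [150,600] K, ε^AB/k ∈ [800,3200] K,
κ ∈ [0.005,0.15], spanning the packaged table with headroom.

## The neural network

Architecture 6–32–3, tanh hidden activation, linear output — the
conventional choice for Levenberg–Marquardt regression; the source does not
state its activations, and this choice is configurable.  Inputs and outputs
are min–max scaled to [−1,1] on the training split and serialized with the
weights.  Training is full-batch LM with an analytic Jacobian, adaptive
damping (λ₀ = 0.01, ×10 up / ×0.1 down), a seeded 70/15/15 split, an epoch
cap of 3000 and early stopping after 50 non-improving validation epochs.

The packaged printed weight table is transcribed verbatim (32 hidden
neurons; the output-bias column holds three entries, read as the three
output biases).  Its input/output scaling was never published, so forward
passes through it are supported *only* for sensitivity analysis; prediction
requires user-supplied scaling, and the CLI refuses otherwise.

Garson importance is implemented with absolute values on both weight layers
and a denominator summing over hidden neurons for all inputs — the standard
algorithm; the printed formula is ambiguous on both counts.  Per-output and
output-averaged modes are both exposed.  On the printed weights the
output-averaged melting-enthalpy importance evaluates to 14.9% (per-output
14.3/15.6/14.9) against a quoted "≈14%", inside the one-point ambiguity band
the formula's unstated conventions leave; the temperature input averages
13.9%, consistent with the claim that melting enthalpy and temperature are
the two least influential inputs.

## Solubility

ΔC_p is treated as temperature-independent, as the equilibrium relation's
form implies.  The ideal route is closed-form x = exp(−RHS); with a
γ(x) provider the equation ln x + ln γ(x) = −RHS is solved by damped fixed
point (damping 0.5, tolerance 1e-10) and cross-checked by bisection on
f(x) = ln x + ln γ + RHS over x ∈ (1e-8, 0.999) — both pathways must agree to
1e-8.  At T ≥ T_m the boundary x = 1 is reported with a flag.  An ANN-backed
provider should interpolate network predictions on a molality grid before
root-finding, since the network predicts at discrete molalities.

## Synthetic data

The generator evaluates the PHSC model on a molality grid and applies
multiplicative Gaussian noise to φ (relative noise matches the relative-error
objective the fits minimize; additive mode exists).  Defaults mirror the
binary-data conditions behind the packaged parameter table: 298.15 K,
20 points, m ∈ [0.1, 4] mol/kg, 1% relative noise, all seeded.  The network
training table pairs glucose and sucrose curves at 298–308 K, 600 rows.

What a green test on synthetic data establishes: that the fitting and
training machinery recovers a known generating process at realistic size and
noise.  What it does not establish: agreement with laboratory measurements —
the published error tables rest on experimental compilations that are cited,
not printed, so they cannot be reproduced from this repository.  The CSV
import path (`carbotherm.io.read_osmotic_csv`) exists precisely so that
users holding those datasets can run the identical pipeline on them.

## Known limitations

* Binary sugar–water systems only; no ternary mixtures, electrolytes or
  mixed solvents.
* No second-derivative properties (heat capacity, speed of sound).
* Ring-sugar group assignments are best-effort and flagged unverified.
* The printed-weight network cannot make quantitative predictions without
  the unpublished scaling; it is shipped for sensitivity analysis.
* Parameter fits are reproducible but not uniquely identified (see above).
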