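# carbotherm

Thermodynamic properties of aqueous carbohydrate solutions: osmotic
coefficient, water activity, activity coefficients and solubility, predicted
by three complementary routes:

* a **perturbed hard-sphere-chain (PHSC) equation of state** with a
  Wertheim/SAFT hydrogen-bond association term, parameterized for thirteen
  sugars and water;
* a **Joback–Reid group-contribution** estimator for the critical properties
  of carbohydrates, which feed
* a **6–32–3 feed-forward neural network** (Levenberg–Marquardt trained, with
  Garson connection-weight sensitivity analysis) predicting the same solution
  properties from molecular descriptors.

The intended audience is food-science and pharmaceutical process modellers
who need water activity and sugar solubility across composition and
temperature, and anyone who wants a self-contained, testable implementation
of a SAFT-type association equation of state for sugar–water systems.

## The models

**PHSC EoS.**  The compressibility factor decomposes as

    Z = Z_ref + Z_pert + Z_assoc

with the hard-sphere-chain reference

    Z_ref = 1 + ρ Σ_ij x_i x_j r_i r_j b_ij(T) g_ij(d⁺) − Σ_i x_i (r_i−1)(g_ii(d⁺)−1)

using the Boublík–Mansoori–Carnahan–Starling contact value g_ij, a van der
Waals perturbation

    Z_pert = −(ρ/k_BT) Σ_ij x_i x_j r_i r_j a_ij(T)

with temperature-dependent parameters a(T) = (2π/3)σ³ε F_a(k_BT/ε) and
b(T) = (2π/3)σ³ F_b(k_BT/ε), and a Wertheim association term built from the
unbonded site fractions X^A (two sites per hydroxyl group: one donor, one
acceptor).  Water activity follows as a_w = x_w φ_w/φ_0w, the osmotic
coefficient as φ = −1000 ln a_w/(M_w Σ ν_i m_i), and the symmetric activity
coefficient as γ_i = φ_i/φ_0i.  Sugar solubility closes the loop through the
solid–liquid-equilibrium relation

    −ln(x γ) = (ΔH_m/R)(1/T − 1/T_m) + (ΔC_p/R) ln(T_m/T) − (ΔC_p/R)(T_m/T − 1)

**ANN + GC.**  The network maps (T_c, V_c, T_m, ΔH_m, molality, T) to
(φ, γ, a_w); T_c and V_c come from the Joback sums
T_b = 198 + Σ N_k tb_k, T_c = T_b/(0.584 + 0.965·S − S²) with S = Σ N_k tc_k,
and V_c = 17.5 + Σ N_k vc_k.  Garson's weight partitioning ranks the six
inputs' influence.

All published parameter tables ship as checksummed package resources: the
group-contribution increments, the sugar descriptor table, the fitted PHSC
pure-component parameters, the melting properties and the printed network
weights.

## Worked example

```python
import numpy as np
from carbotherm.phsc import load_components, predict_solution_properties

glucose, water = load_components("D-Glucose", "Water")
table = predict_solution_properties(glucose, water, 298.15, [0.5, 1.0, 2.0, 4.0])
print(table.round(5))
```

prints

```
      T_K  molality      a_w      phi  gamma_sugar
0  298.15       0.5  0.99101  1.00303      0.30381
1  298.15       1.0  0.98197  1.00994      0.30990
2  298.15       2.0  0.96357  1.03006      0.32592
3  298.15       4.0  0.92537  1.07637      0.36585
```

i.e. at 298.15 K water activity falls from 0.991 to 0.925 as glucose molality
rises from 0.5 to 4 mol/kg, the osmotic coefficient climbs above 1 (positive
deviation from the ideal-dilute solution), and the symmetric sugar activity
coefficient increases with concentration — the trends seen in measured
sugar–water data.  Solubility from the same parameters:

```python
from carbotherm import sle
provider = sle.phsc_activity_provider("Xylitol", 298.15)
res = sle.solve_solubility(298.15, sle.melting_properties("Xylitol"), provider)
print(round(res.molality, 2), round(res.gamma_at_solution, 3))
# 10.82 0.588
```

a saturation molality of ≈10.8 mol/kg for xylitol at 25 °C.

A command-line interface wraps the same functionality:

```bash
carbotherm gc-estimate --groups xylitol.json
carbotherm phsc-predict --sugar D-Glucose --temperature 298.15 --molality-grid 0:6:0.25 --out glucose.csv
carbotherm phsc-fit --data exp.csv --sugar Xylose --n-oh 4 --starts 8 --seed 1234 --out fit.json
carbotherm ann-train --data train.csv --seed 7 --out net.json
carbotherm ann-importance
carbotherm solubility --sugar D-fructose --temperature-grid 270:313:5 --model phsc --out sol.csv
carbotherm make-synthetic --sugar D-Glucose --noise-sd 0.01 --seed 0 --out pseudo.csv
```

## Acceptance script

`scripts/acceptance.py` recomputes the package's headline reported quantity
from scratch — it loads the packaged printed network weights, runs the Garson
connection-weight analysis and writes the melting-enthalpy input importance
to a JSON file:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

```
src/carbotherm/
  joback.py        group-contribution estimates + packaged descriptor tables
  phsc/            the equation of state (components, universal functions,
                   EoS core, derived solution properties)
  regression.py    fitting pure-sugar PHSC parameters to osmotic data
  ann.py           the 6-32-3 network, LM training, metrics, Garson analysis
  sle.py           solid-liquid-equilibrium solubility
  synthetic.py     seeded pseudo-experiment generator (model-backed)
  io.py            CSV/JSON schemas and round trips
  cli.py           the `carbotherm` command-line interface
  data/            checksummed parameter tables and printed weights
docs/methods.md    modelling assumptions, numerics and limitations
```
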