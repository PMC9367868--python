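# shelfkin

Predictive-microbiology shelf-life kinetics and intelligent-packaging
(time–temperature-integrator) matching for chilled foods.

`shelfkin` is written for food scientists and cold-chain engineers who
model the spoilage of perishable products — the motivating system is
gilthead seabream fillets under modified atmosphere packaging (MAP), with
and without a CO₂-emitter pad — and who need to pick a smart label whose
color kinetics track the product's remaining shelf life.

## What it computes

**Primary model.** Bacterial counts y(t) (log10 CFU/g) follow the
Baranyi–Roberts model with parameters (y0, ymax, μ, λ):

    ỹ(t) = ỹ0 + μ̃A(t) − ln(1 + (e^{μ̃A(t)} − 1)/e^{ỹmax−ỹ0}),
    A(t) = t + (1/μ̃)ln(e^{−μ̃t} + e^{−h0} − e^{−μ̃t−h0}),  h0 = μ̃λ,

(tilde = natural-log units). `BaranyiModel(times, counts).fit()` returns
estimates, standard errors, R² and residuals; a non-significant lag is
dropped by an F-test.

**Secondary model.** Rates follow Arrhenius, ln k = ln k_ref −
(Ea/R)(1/T − 1/T_ref), T_ref = 4 °C; lags scale with the opposite
(time-like) sign. `ArrheniusModel(points).fit()` gives k_ref, Ea and R².

**Shelf life.** t_SL(T) = (logN1 − logN0)/k(T) + λ_ref·e^{+(Ea/R)(1/T −
1/T_ref)} with the 7 log10 CFU/g acceptability limit for total viable
counts.

**TTI kinetics.** Enzymatic-label color, normalized from the CIELab sum
(a + b), follows a logistic in time with inflection k1 and spread k2;
across enzyme concentration C and temperature both constants follow
k_i = k_iref(C=1U)·C^(−α_i)·e^{+(Ea/R)(1/T − 1/T_ref)}. The label's
visual end point is norm = 0.8, reached at t = k1 + k2·ln 4.

**Matching and validation.** A label suits a product when its Ea is
within ±20 kJ/mol of the product's deterioration Ea and its end-point
curve tracks the shelf-life curve over 0–10 °C (candidates ranked by
maximum absolute relative deviation). Dynamic cold-chain profiles are
summarized by an effective temperature T_eff, growth under them is
predicted by ODE integration of the Baranyi system, and predictions are
validated with RE% = |(k_exp − k_pred)/k_exp|·100 against a 20% limit.

## Worked example

```python
import numpy as np
import shelfkin as sk

# fit a (here: simulated) count curve at 2.5 degC
params = sk.BaranyiParams(y0=4.54, ymax=8.48, mu=0.294, lag=2.88)
curve = sk.gen_growth_curve(params, np.linspace(0, 30, 12), noise_sd=0.15,
                            seed=42, organism="TVC", packaging="MAP_PAD",
                            temperature_c=2.5)
print(sk.BaranyiModel.from_curve(curve).fit(with_lag="auto").summary())

# shelf life from the bundled reference kinetics (pad-augmented MAP)
spec = sk.datasets.reference_shelf_spec("MAP_PAD")
grid = 273.15 + np.array([0.0, 2.5, 5.0, 10.0])
for t_c, days in zip(grid - 273.15, sk.shelf_life_curve(spec, grid)[:, 1]):
    print(f"shelf life at {t_c:>4} degC: {days:5.1f} d")

# rank M-type labels against that product
m = sk.datasets.tti_global_models()["M"]
cands = [(m, c) for c in (5., 10., 15., 20., 25., 50., 75., 100.)]
for i, rep in enumerate(sk.select_tti(spec, cands)[:2], 1):
    print(f"{i}. {rep.summary()}")
```

prints

```
Baranyi-Roberts growth model
  TVC / MAP_PAD @ 2.5 degC
  nobs = 12,  R^2 = 0.9934
     y0 =     4.5124  (se 0.1394)
   ymax =     8.5198  (se 0.0730)
     mu =     0.2703  (se 0.0205)
    lag =     2.4466  (se 0.9447)
shelf life at  0.0 degC:  16.9 d
shelf life at  2.5 degC:  10.8 d
shelf life at  5.0 degC:   6.9 d
shelf life at 10.0 degC:   2.9 d
1. M-50U: Ea 97.1 vs product 113.1 kJ/mol (compatible); max |rel dev| = 0.380; conservative at abuse: True
2. M-25U: Ea 97.1 vs product 113.1 kJ/mol (compatible); max |rel dev| = 0.445; conservative at abuse: False
```

The fitted parameters recover the generating values within their
standard errors; the shelf-life curve falls from ~17 days at 0 °C to ~3
days at 10 °C; and the 25- and 50-unit M-type labels are the closest
kinetic matches to the pad-augmented product.

A command-line interface mirrors the library
(`shelfkin simulate | fit-growth | fit-arrhenius | shelf-life | fit-tti |
match | validate | run`); see `shelfkin --help`.

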