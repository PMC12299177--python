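# tailrisk

Probabilistic groundwater-risk assessment for iron tailings reused as
road-subgrade material.

When mine tailings are blended into a road subgrade, rainfall slowly washes
soluble heavy metals (As, Mn, Ba, Ni, Co, Pb, …) out of the layer, through
the vadose zone, and into the aquifer, where they travel downgradient toward
wells. `tailrisk` models that whole chain with a source-depletion leaching
model coupled to the standard soil-screening dilution factors and the 1-D
advection–dispersion breakthrough solution, propagates hydrogeological and
source uncertainty by Monte Carlo, and turns the result into management
numbers: exceedance probabilities against groundwater standards, regional
(dry–wet climate) risk contrasts, and the maximum admissible tailings blend
fraction. It is written for environmental engineers and regulators doing
beneficial-reuse screening assessments.

## Model

For each pollutant with availability-leachate concentration $C_j$ (mg/L,
from a two-stage availability leaching test at cumulative liquid-to-solid
ratio 100 L/kg, so the releasable content is $C_{sw} = 100\,C_j$ mg/kg),
the well concentration at elapsed time $t$ is

$$c_{gw}(t) = c_w(t)\cdot LF \cdot DAF(x,t)$$

with:

* **Source depletion** — $c_w(t) = f\,C_j\,e^{-\lambda t}$, where $f$ is the
  tailings volume fraction and
  $\lambda = q\,C_j/(d\,f\,\rho\,C_{sw})$ (1/a) is exactly the first-order
  rate at which net infiltration $q=\alpha P$ exhausts the available
  inventory $d\,f\,\rho\,C_{sw}$ of a layer of thickness $d$ and density
  $\rho$.
* **Vadose leaching factor** —
  $LF = \dfrac{1}{K_{sw}}\cdot\dfrac{1}{1 + U_{gw}\delta_{gw}/(I\,W)}$
  (kg/L): soil–water partition
  $K_{sw} = (\theta_{ws} + K_d\rho_b + H\theta_{as})/\rho_b$ and dilution of
  the recharge $I\,W$ into the lateral groundwater flux
  $U_{gw}\delta_{gw}$ under a road of width $W$.
* **Dilution–attenuation factor** — the continuous-source breakthrough
  fraction at the well distance $x$,
  $DAF = \tfrac12\,\mathrm{erfc}\frac{x-ut}{2\sqrt{D_Lt}} +
  \tfrac12\,e^{ux/D_L}\,\mathrm{erfc}\frac{x+ut}{2\sqrt{D_Lt}}$,
  with seepage velocity $u = Ki/n$.

Uncertain parameters (infiltration coefficient, layer thickness, blend
fraction, road width, conductivity, gradient, porosity, dispersion,
leachate concentration, …) carry normal or uniform distributions; 10,000
Monte Carlo iterations give the distribution of the *peak* well
concentration over a 50-year horizon. Risk is summarized as the exceedance
probability against the Class III groundwater limit and the 95th-percentile
peak (the "exposure concentration") relative to that limit. Regional
scenarios draw annual precipitation from the dry–wet class bounds
(arid < 200 < semi-arid < 400 < semi-humid < 800 mm < humid) with
infiltration coupled to precipitation on both the source and vadose side;
the blend sweep fixes $f$ on a grid and finds the largest fraction keeping
the exposure concentration at or under the standard.

## Worked example

```python
import tailrisk as tr

scenario = tr.default_scenario()          # humid site, 900 mm/a, six metals
res = tr.run_monte_carlo(scenario, "Ni", tr.MCConfig(n_iter=10_000, seed=42))
print(tr.summarize_mc(res, scenario.pollutant("Ni")))
```

prints (abridged):

```
percentiles_mg_L: p50 0.0091, p95 0.0233, p99 0.0285
exceedance_probability: 0.1043
exceedance_multiple: 1.166
mean_peak_time_a: 4.57
```

Read: over 10,000 parameter draws, the median peak nickel concentration at
the 100 m well is 0.0091 mg/L; 10.4% of draws exceed the 0.02 mg/L Class III
limit; the 95th-percentile exposure concentration is 1.17× the limit,
typically peaking about 4–5 years after construction. The Potential Hazard
Index screen (mean leachate ÷ limit: Mn 18.6, Pb 5.0, As 4.0, Ni 4.0,
Ba 3.7, Co 1.6) ranks which metals merit this full pipeline at all.

The same analyses are available from the shell:

```sh
tailrisk synth --out fixture --seed 1            # synthetic leaching data
tailrisk phi --leaching fixture/leaching.csv --out results
tailrisk mc --pollutant Ni --seed 42 --out results
tailrisk region --regime semi_humid --pollutant Ni --seed 1 --out results
tailrisk blend-sweep --regime semi_humid --pollutant Mn --seed 1 --out results
```

Every output file embeds the scenario hash and seed, so any result can be
reproduced from its own provenance stamp.

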