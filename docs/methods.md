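# Methods

## Scope and structure

`tailrisk` estimates the probability that heavy metals leached from iron
tailings used in road subgrade exceed Class III groundwater limits at a
downgradient observation well, and derives management limits on the
tailings blend fraction. The chain is: availability-leaching statistics →
exponential source depletion → vadose leaching/dilution factor (LF) →
saturated-zone dilution–attenuation factor (DAF) → Monte Carlo risk
summary → regional scenarios and blend sweeps. Each stage is a separate
module with validated parameter objects, so any stage can be used (and
tested) alone.

## Source term

The availability leach (two batch stages at liquid-to-solid 50 L/kg,
equal-volume mixed ⇒ cumulative L/S = 100 L/kg) measures the mixed
leachate concentration `Cj` (mg/L); the releasable content is
`Csw = Cj · L/S` (mg/kg). In the subgrade, net infiltration `q = α·P`
(infiltration coefficient × annual precipitation) flushes the available
inventory per unit footprint area, `d·f·ρ·Csw`, giving a first-order
depletion rate

    λ = q·Cj / (d·f·ρ·Csw)   [1/a].

This grouping is the unique reading of the depletion-rate expression with
units of 1/a, and it is exactly mass-conserving: the cumulative flushed
mass `∫ q·Cj·e^(−λt) dt = q·Cj/λ` equals the inventory identically (a
tested invariant, closed form to 1e-9 relative plus an independent
quadrature check). With the default initial pore-water concentration
`C0 = f·Cj` the cumulative release is the fraction `f` of the inventory —
consistent with only the tailings fraction of the layer contacting
infiltrate. `C0 = Cj` is selectable (`c0_mode: cj`).

### Source-content convention

The exposure product `cgw(t) = cw(t)·LF·DAF` supports two conventions for
`cw`:

* `leachate` (default): `cw(t) = C0·e^(−λt)` — the pore-water leachate
  concentration, with the availability content entering only λ. This is
  the physically consistent choice: the leach test already measures the
  concentration water equilibrated with the material attains, and the
  vadose factor then only dilutes it.
* `availability`: `cw(t) = f·Csw·e^(−λt)` — treats the full availability
  content as instantaneously dissolved in the in-situ pore water. Because
  `Csw` embeds the laboratory liquid-to-solid ratio (100 L/kg) while the
  partition term of LF re-divides by the in-situ water volume
  (`Ksw ≈ θws/ρb ≈ 0.2 L/kg`), this convention re-applies the L/S ratio
  and inflates well concentrations by roughly two orders of magnitude. It
  is retained as an intentionally extreme upper-bound screen, not as the
  default.

## Vadose leaching factor

Standard soil-screening form: `LF = LFspw−gw / Ksw` with
`Ksw = (θws + Kd·ρb + H·θas)/ρb` (L/kg) and
`LFspw−gw = 1/(1 + Ugw·δgw/(I·W))`, the fraction of the mixed groundwater
flux beneath the road that is recharge. The groupings are fixed by
dimensional analysis (LF in kg/L, LFspw−gw dimensionless). For the six
non-volatile metals the defaults are `Kd = 0, H = 0` — sorption and
reaction neglected, the conservative screening position — both overridable
per scenario. Zero recharge is handled as the continuous limit
`LFspw−gw → 0` (no infiltration, no leaching), while a literal `I·W = 0`
in the bare function is a contract error.

## Saturated transport

`DAF(x,t)` is the classical continuous-injection solution of the 1-D
advection–dispersion equation with constant unit inlet concentration;
seepage velocity `u = K·i/n`. Retardation and first-order decay are fixed
at `R = 1, γ = 0` by default (no attenuation beyond dispersion —
conservative; the numerical solver accepts both for sensitivity use). The
exponentially weighted term is evaluated with the scaled complementary
error function: with `a± = (x ± ut)/(2√(DL·t))`,
`exp(ux/DL)·erfc(a₊) = exp(−a₋²)·erfcx(a₊)`, so the expression never
overflows however advection-dominated the system (tested to
`u·x/DL = 2·10⁴`). Output is clipped to [0, 1] against float round-off;
`t ≤ 0` returns 0 by convention.

Transport runs in days internally (conductivity and dispersion are
specified in m/d and m²/d); the exposure layer converts years to days at
exactly 365 d/a.

An independent Crank–Nicolson finite-difference solver (central
differences, Dirichlet inlet, inert zero-gradient outflow on a domain
extending past the advective front plus six dispersive standard
deviations) serves as the numerical oracle. Grids must satisfy cell
Péclet ≤ 2 and Courant ≤ 1 or a grid error is raised. At dx = 0.5 m,
dt = 1 d the oracle agrees with the closed form to better than 5·10⁻³
absolute across the tested (u, DL, t) lattice, and errors shrink under
2× refinement.

## Monte Carlo engine

Symbols are drawn in a frozen canonical order, one independent
`SeedSequence` child stream per symbol. Consequences, all tested:
bit-reproducibility from `(seed, config)`; changing one symbol's
distribution leaves the other streams untouched; growing `n_iter` extends
rather than reshuffles the draw matrix. Truncated normals (all physical
quantities truncate at zero) are sampled by inverse CDF on a per-index
uniform stream rather than by rejection — same distribution, but the
stream-stability guarantee above holds exactly. All default normals have
sd ≪ mean, so truncation bias is negligible (verified by moment recovery).

Per draw, the risk metric is the temporal maximum of `cgw(t)` on a uniform
grid (default horizon 50 a, step 0.05 a — the early-year breakthrough peak
is resolved to well under 1% height error; both configurable). Summaries
use empirical quantiles with linear interpolation; the exceedance
probability is the fraction of peak draws above the limit, and the
exceedance multiple is p95/limit, following the convention that the 95th
percentile of the peak distribution is "the" exposure concentration. A
10,000-iteration exceedance estimate is verified to sit inside the
binomial 95% CI of a 100,000-iteration run.

### Default parameter inventory (base case)

| symbol | meaning | unit | default |
|---|---|---|---|
| α | infiltration coefficient | – | N(0.2, 0.05) |
| P | annual precipitation | mm/a | 900 (site) |
| d | subgrade layer thickness | m | U(0.3, 1.2) |
| f | tailings volume fraction | – | U(0.1, 0.5) |
| ρ | subgrade material density | kg/L | N(2, 0.2) |
| ρ_b | soil bulk density | kg/L | 1.5 |
| θ_ws | water-filled porosity, vadose | – | 0.3 |
| U_gw | groundwater Darcy velocity | m/a | 25 |
| δ_gw | mixing-zone thickness | m | N(2, 0.082) |
| I | net recharge (base case) | m/a | 0.3 |
| W | road width | m | U(3.5, 30) |
| x | source-to-well distance | m | 100 |
| K | hydraulic conductivity | m/d | U(10, 50) |
| i | hydraulic gradient | ‰ | U(3, 6) |
| n | effective porosity | % | U(30, 50) |
| D_L | longitudinal dispersion | m²/d | U(5, 10) |

Leachate distributions (mg/L): As N(0.040, 0.005), Mn N(1.860, 0.600),
Ba N(2.600, 0.300), Ni N(0.080, 0.010), Co N(0.080, 0.006),
Pb N(0.050, 0.010); Class III limits 0.01 / 0.1 / 0.7 / 0.02 / 0.05 /
0.01 mg/L respectively.

In the base case the vadose recharge uses the generic fixed `I = 0.3 m/a`
while λ uses the site `q = α·P`; in regional mode both use `q = α·P`
(`couple_infiltration`), so precipitation drives release and dilution
coherently.

## Regional scenarios and blend sweep

Dry–wet regimes are uniform precipitation distributions on the class
bounds; the open-ended classes are closed at U(25, 200) mm (arid) and
U(800, 1600) mm (humid) — a hyper-arid floor and twice the humid
threshold — both overridable by setting `precip_mm_a` directly. Each
regional run reports a central-parameter time series (precipitation at the
regime mean) and the Monte Carlo summary with precipitation drawn per
iteration.

The blend sweep fixes `f` at each grid value (default 0.05…1.00 step
0.05), reruns the Monte Carlo with common random numbers (the same seed
for every `f`), and reports p95-peak/limit. Per draw the peak is monotone
increasing in `f` (the concentration scales with `f` and λ falls with
`f`), so with common random numbers the ratio curve is exactly
non-decreasing — asserted as a result invariant. `f_max` is the largest
grid fraction with ratio ≤ 1 (1.0 if never exceeded, 0.0 if even the
smallest grid value exceeds).

## Hazard screen

The Potential Hazard Index is defined as mean leachate concentration ÷
Class III limit; PHI < 1 proves a pollutant harmless at the well (every
downstream factor is ≤ 1 in the leachate convention). With the default
Table of leachate means the screen gives Mn 18.6, Pb 5.0, As 4.0, Ni 4.0,
Ba 3.71, Co 1.6. Published screening values for the same site (As 8.7,
Mn 22.7, Ba 4.2, Ni 12.6, Pb 5.8, Co 0.74) are *not* reproducible as mean
÷ limit from the published summary statistics; the concentrations behind
them are not stated, so this package implements the stated definition and
flags the discrepancy rather than chasing the printed numbers.

## Synthetic data

The generator emulates what the analysis assumes: per pollutant,
i.i.d. normal leachate concentrations across samples (default n = 100),
truncated at zero by rejection (bias negligible at the default mean/sd
ratios ≥ 3), with values under a detection limit flagged censored and
stored at the limit. Detection limits default to one tenth of each Class
III limit purely to exercise the censoring path; statistics substitute
half the detection limit for censored entries, the standard convention for
lightly censored environmental data. Deliberately *not* emulated: spatial
correlation among samples, inter-element correlation, heavy-tailed or
skewed leaching behaviour, and pH-dependence. Passing tests therefore
demonstrate correctness of the statistical machinery under the model's own
assumptions, not robustness to real-data pathologies. Normality of loaded
data is checked (Shapiro–Wilk) but only warned about, never enforced.

## Numerical and edge-case choices

* Peak extraction is an arg-max over the time grid (no interpolation);
  ties resolve to the earliest time.
* `DAF(t ≤ 0) = 0`; zero tailings fraction, zero leachate concentration or
  zero precipitation-with-coupling all yield an exactly zero series.
* Degenerate soil (`θws = Kd = H = 0`) makes `Ksw = 0` and is rejected
  with a pointed message rather than returning infinity.
* Percentile method: empirical, linear interpolation (`numpy.percentile`
  default).
* All randomness flows from one user seed; derived seeds are spawned via
  `SeedSequence` and kept below 2³¹.

## Known limitations and documented discrepancies

* One-dimensional, homogeneous, steady saturated flow; no transverse
  dispersion, no multi-layer vadose travel time, no sorption/decay by
  default — all conservative for screening, all overstating risk for
  strongly sorbing metals (Mn especially).
* Annual-average forcing only: no storm-scale or climate-change dynamics;
  regime bounds are annual means, so rare intense rainfall in arid regions
  is outside the model.
* The published reference figures this package is benchmarked against are
  internally inconsistent in two places, documented here deliberately:
  (i) the Mn risk figures (19% exceedance, 2.1× multiple) and the Ni
  figures (7%, 1.1×) cannot both follow from the published leachate
  statistics under any shared multiplicative pipeline — Mn's mean leachate
  is 23× Ni's while its limit is only 5× higher, so matching Ni (which
  this implementation does) necessarily overshoots the Mn figures several-
  fold; (ii) the published humid-region nickel peak (0.253 mg/L) is a ~9×
  outlier against the same source's own regional scaling (semi-humid
  0.014, semi-arid 0.007, arid 0.004 mg/L, which this implementation
  reproduces within ~20%). The acceptance script reports this package's
  computed values unmodified.
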