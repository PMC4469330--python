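# Methods

## Model

### Carrier cycle and quasi-steady-state reduction

The transporter is modeled as a single-site carrier that alternates between
the external and internal membrane face. Two time scales are separated:

1. **Binding** is rapid equilibrium. At a face with free substrate
   concentrations `c_j` and dissociation constants `K_j`, the occupancy
   fractions are `p_s = (c_s/K_s) / (1 + Σ_j c_j/K_j)` and
   `p_0 = 1 / (1 + Σ_j c_j/K_j)`; they sum to one. A substrate with
   `K = ∞` (e.g. an osmotic control such as mannitol) never binds.
2. **Translocation** is slow. The loaded carrier crosses at relative rate 1,
   the empty carrier at relative rate `h ≥ 0`. On the translocation time
   scale the carrier distribution between faces, `θ_ext + θ_int = 1`,
   relaxes to the quasi-steady state defined by the flux balance
   `θ_ext (L_ext + h p0_ext) = θ_int (L_int + h p0_int)`, where
   `L = Σ_s p_s` is the loaded fraction. When both rates vanish (`h = 0`
   and both faces empty) the distribution is conventionally (½, ½); no flux
   flows in that state, so the convention is inert.

The net inward transport of substrate `s`, expressed as the rate of change
of its intravesicular concentration, is

```
dc_int,s/dt = V · (θ_ext · p_s,ext − θ_int · p_s,int)
dc_ext,s/dt = −(v_in / v_out) · dc_int,s/dt
```

`V` (µM/min) is the effective uptake rate: carrier translocation capacity
normalized by intravesicular volume (`V ≡ D·T/v_in` for `T` carriers of
unidirectional rate constant `D`). `h = 0` gives an obligate 1:1 exchanger:
flux requires substrate on both faces and total intravesicular substrate is
conserved exactly. `h > 0` adds facilitated transport by the empty carrier
and allows net uptake into empty vesicles.

Radiotracer and unlabeled substrate are chemically identical, so they share
`K`; the model treats them as separate species that compete for the site,
which is exactly how isotope labeling works.

### Parameter values

The a-priori ("prediction") parameter set is `h = 0.04`, `K = 1129 µM`,
`V = 92 µM/min`; the package also carries a fitted mobility `h = 0.16` and
an obligate-fit endogenous intravesicular pool of 10 µM as presets. These
values are mutually consistent with apparent Michaelis kinetics of
zero-trans tracer uptake under this flux law: the apparent constants are
`Km,app = 2hK/(1+h) ≈ 87 µM` and `Vmax,app = Vh/(1+h) ≈ 3.5 µM/min`, which
back-derive `K = 1129 µM` and `V = 92 µM/min` at `h = 0.04`.

A consequence worth flagging: with these slow parameters the
counter-transport overshoot in the preloaded conditions peaks on the scale
of **hours** (≈ 180 min in condition 4b), far outside the 0.25–10 min assay
sampling grid. On the default grid the preloaded conditions are still on
their rising limb; overshoot detection in this package is therefore always
demonstrated and tested on extended horizons (up to 5000 min).

### Full mass-action oracle

An independent check integrates the unreduced cycle: free carrier and
carrier–substrate complexes at both faces as explicit species, with binding
(`k_on = fast_binding_factor · d / K_min`), dissociation (`k_off = k_on K`),
and translocation (`d` for loaded, `h·d` for empty) as mass-action steps.
The carrier amount is `T = V·v_in/d`. Initialization matches the QSSA state
exactly: complexes start at their binding-equilibrium values and the bound
amounts are debited from the free pools, so total species amounts agree to
machine precision. With `d = 10⁴ min⁻¹` and a 10³ binding speed-up the
intravesicular tracer traces of the two models agree to < 1% (verified over
randomized parameters and on the experimental matrix).

## Experimental design

The condition matrix crosses external and preloaded internal unlabeled
substrate with a constant external tracer (7.5 µM nominal):

| id | ext (µM) | int (µM) | buffer volume (µl) |
|----|---------|----------|--------------------|
| 1  | 0    | 0    | 20  |
| 2  | 250  | 0    | 20  |
| 3  | 250  | 250  | 20  |
| 4  | 250  | 1000 | 50  |
| 4b | 50   | 1000 | 380 |
| 5  | 1000 | 0    | 20  |
| 6  | 1000 | 250  | 20  |
| 7  | 1000 | 1000 | 20  |

20 µl of vesicle suspension (0.2 mg protein; intravesicular volume
1.3 µl/mg, hence `v_in = 0.26 µl`) is mixed with buffer; the preloaded
conditions dilute their 1000 µM preload medium to the stated external value
(4b: 1000 · 20/400 = 50 µM exactly). In the default *nominal* mode the
stated concentrations are taken at face value at t = 0; a mechanistic mode
instead applies the mixing dilution to every species including the tracer.
An optional endogenous amino acid pool can be layered onto the whole matrix
(internal += endo; external += endo · suspension fraction), or, for the
obligate fitting variant, a fitted `endo_int` is added to the vesicle
interior of every condition.

Units: concentrations in µM, volumes in µl, time in minutes; measured
uptake in pmol/mg converts via the 1.3 µl/mg volume (13 pmol/mg = 10 µM).

## Synthetic data generator

For each condition the tracer uptake curve is sampled at the assay grid
(0.25, 0.5, 1, 2, 5, 10 min by default). Replicate noise is Gaussian with
standard deviation `max(floor, cv · value)` (defaults: cv = 10%,
floor = 0.3 pmol/mg), clipped at zero; the per-condition replicate count is
drawn uniformly from 5–9 unless fixed. Reported values are the replicate
mean ± SEM. All randomness flows from a single seed through
`numpy.random.default_rng`, so datasets are bit-reproducible. A separate
generator produces trans-stimulation preload panels (one condition per
preloaded substrate, including a never-binding osmotic control and a
non-loaded control).

The generator's scope is the vesicle assay it mirrors: single transporter,
two competing labeled/unlabeled species (plus optional preload species), no
metabolism, no membrane leak, no binding to the filter or vesicle exterior.

## Fitting

Both variants are fitted to **all conditions simultaneously with one
parameter set** by bounded nonlinear least squares on the intravesicular
tracer concentration (µM):

- **mixed**: free `h`, `V`, `K` (tracer and substrate share `K`);
- **obligate**: `h` pinned to 0; free `V`, `K`, `endo_int` (initial
  endogenous intravesicular substrate, added to every condition).

`V` and `K` are optimized in log₁₀ space, `h` and `endo_int` linearly.
A fixed 8-point multistart grid (lead parameter × V₀ ∈ {10, 300} ×
K₀ ∈ {100, 5000}) feeds `scipy.optimize.least_squares` (TRF, xtol 1e-12,
ftol 1e-13); the best start by SSR wins and all start SSRs are reported.
Weighting is unweighted by default with inverse-SEM weighting as an option.
Goodness of fit is `R² = 1 − SSR/SST` about the grand mean of all points;
standard errors come from the Gauss–Newton approximation
`(JᵀJ)⁻¹ · SSR/(n−p)` with the log-space Jacobian mapped back by the chain
rule. Discrimination compares the two variants on the same data and prefers
the higher R² (equivalently lower SSR, since SST is shared).

Note that the two variants are *not* nested: each has one parameter the
other lacks (`h` vs `endo_int`). On data truly generated by an obligate
exchanger with no endogenous pool both collapse to the same optimum
(mixed drives `h → 0`), but on noisy data either can edge out the other by
a fraction of a percent of SSR.

## Numerics

The QSSA ODE is integrated with an adaptive Dormand–Prince 5(4) method
(FSAL, rtol 1e-8, atol 1e-10) compiled with numba; steps land exactly on
requested output times, so no dense-output interpolation error enters
reported values. A scipy (LSODA) engine is available as a cross-check and
agrees to < 1e-5 relative. The mass-action oracle is stiff (binding rates
~10⁷ min⁻¹) and is integrated with LSODA at rtol 1e-8 / atol 1e-12.
Warm-cache simulation of the full matrix takes ~0.4 ms; a full 8-start
mixed fit ~0.1 s; the 20-replicate discrimination study ~13 s on one CPU.

## Limitations

- The rapid-equilibrium binding assumption breaks down if binding and
  translocation rates are comparable; the oracle agreement is demonstrated
  only in the fast-binding regime.
- The noise model is Gaussian and independent across time points; real
  assay replicates share vesicle-prep and filtration error structure.
- The nominal mixing mode takes stated concentrations at face value;
  tracer dilution differences between mixing schemes are only represented
  in the mechanistic mode.
- Empirical goodness-of-fit numbers for real vesicle data are out of scope:
  the package validates by parameter recovery on its own generator and by
  oracle agreement, not against digitized experimental figures.
- `R²` about the grand mean is undefined for constant data; the fitter
  raises rather than reporting a value.
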