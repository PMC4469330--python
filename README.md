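# carrierflux

Carrier-cycle modeling of amino acid exchange and facilitated transport in
membrane vesicles, with synthetic assay data generation and model
discrimination by simultaneous least-squares fitting.

## Scientific background

Radiotracer uptake assays in plasma-membrane vesicles (for example,
[¹⁴C]serine uptake into placental microvillous membrane vesicles) are the
standard way to probe amino acid transporters such as system L / LAT2. The
classic qualitative signatures are:

- **cis-inhibition** — unlabeled substrate outside competes the tracer off
  the carrier and slows its influx;
- **trans-stimulation** — unlabeled substrate *inside* the vesicle returns
  the carrier to the outside face loaded, accelerating tracer influx;
- the **counter-transport overshoot** — with a steep outward substrate
  gradient, intravesicular tracer transiently rises far above its final
  equilibrium before relaxing back.

A central mechanistic question is whether such a transporter is an
**obligate 1:1 exchanger** (the empty carrier cannot cross the membrane, so
every inward translocation is paid for by an outward one) or whether it also
supports some **facilitated transport** by the empty carrier. `carrierflux`
implements a single carrier-cycle model in which one parameter — `h`, the
mobility of the unbound carrier relative to the loaded carrier — spans this
entire spectrum: `h = 0` is the obligate exchanger, `h > 0` a mixed
exchanger/facilitated transporter.

## The model

The carrier is a membrane protein with one binding site that alternates
between the external and internal face. Binding is rapid equilibrium: at
each face the probability that the carrier is occupied by substrate *s* is

```
p_s = (c_s / K_s) / (1 + Σ_j c_j / K_j),      p_0 = 1 / (1 + Σ_j c_j / K_j)
```

where `K_s` is the dissociation constant. Translocation is slow and sets the
quasi-steady-state distribution of the carrier between faces,
`θ_ext + θ_int = 1`, via the balance

```
θ_ext · (L_ext + h · p0_ext) = θ_int · (L_int + h · p0_int)
```

with `L` the total loaded fraction at each face. The net inward flux of
substrate *s* (as rate of change of its intravesicular concentration) is

```
dc_int,s/dt = V · (θ_ext · p_s,ext − θ_int · p_s,int)
```

and external pools are depleted in proportion to the volume ratio. `V` is
the effective uptake rate (carrier translocation capacity per intravesicular
volume, µM/min). A full mass-action ODE of the same cycle (explicit binding
and translocation steps) is included as an independent numerical oracle; in
the fast-binding regime the two agree to better than 1%.

The built-in experimental design mirrors a typical vesicle assay: 8
conditions crossing external (0/50/250/1000 µM) and preloaded internal
(0/250/1000 µM) unlabeled substrate with a constant 7.5 µM external tracer,
an intravesicular volume of 1.3 µl/mg protein, and mixing arithmetic for
converting preload media into initial face concentrations.

## Worked example

Generate noisy synthetic data from a mixed-carrier truth (`h = 0.16`,
`K = 1129 µM`, `V = 92 µM/min`) and refit all three parameters
simultaneously across the 8 conditions:

```python
import carrierflux as cf

matrix = cf.build_matrix()
truth = cf.prediction_params(h=0.16)
noise = cf.NoiseModel(cv=0.10, floor=0.3, n_replicates=5, seed=0)
ds = cf.generate_dataset(truth, matrix, noise=noise)
res = cf.fit(ds, matrix, cf.FitSpec(variant="mixed"))
print(res.params, res.r2)
```

Output (`examples/03_fit_recovery.py` prints the full table):

```
h: true  0.160   fit  0.148 ± 0.024
V: true 92.000   fit 94.888 ± 11.530
K: true 1129.0   fit 1144.6 ± 166.8
R² = 0.985805
```

Fitting both variants to the same dataset discriminates the mechanism
(`examples/04_discriminate.py`):

```
mixed    : h = 0.148, R² = 0.9858
obligate : endo_int = 219.0 µM, R² = 0.9262
verdict  : mixed-preferred (ΔR² = +0.0596)
...
mixed preferred in 10/10 replicates
```

With the a-priori parameter set (`h = 0.04`), the predicted structure
(`examples/01_simulate_predictions.py`) shows cis-inhibition
(initial rates 0.281 > 0.077 > 0.024 µM/min for external 0/250/1000 µM),
trans-stimulation (0.077 < 0.246 < 0.344 µM/min for internal 0/250/1000 µM),
and an overshoot only under the outward gradients: condition 4b
(50 µM out / 1000 µM in) peaks at 41.8 µM intravesicular tracer around
t ≈ 180 min — 5.6× its 7.5 µM equilibrium.

## Command line

```bash
carrierflux simulate --out out/sim              # per-condition time courses + overshoot table
carrierflux synth --h 0.16 --seed 3 --out d.csv # synthetic uptake dataset
carrierflux fit --data d.csv --variant both --out fit.json
carrierflux report --data d.csv --out report.json
carrierflux demo --seed 0 --out demo.json       # synth -> fit -> verdict in one step
```

All outputs embed a configuration digest and the data checksum, and every
random path is seeded, so runs are bit-reproducible.

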