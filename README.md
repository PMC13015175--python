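# stmap

Bayesian spatiotemporal disease mapping for city-level registry panels.

`stmap` is for epidemiologists and biostatisticians who have areal
incidence counts over a short run of years — a cancer-registry panel of
cities, say — and want the standard descriptive-to-model pipeline:
age-adjusted risk ratios, spatial and spatiotemporal autocorrelation,
and a Bayesian hierarchical decomposition of risk into stable
geography, common time trend, and city-by-year interaction.

## What it computes

**Standardized incidence ratios.** With observed counts `O_it`, male
population `N_it`, province age compositions `p_k` (bands 0–14 /
15–64 / 65+) and national reference rates `R_k` per 100,000:

    E_it = Σ_k N_it p_k(province(i), t) R_k / 1e5,    SIR_it = O_it / E_it.

**Autocorrelation.** Global Moran's I, local Moran (LISA) with
HH/LL/HL/LH typing, Getis-Ord Gi\* hotspot z-scores, and a
spatiotemporal Moran's I over joint space–time cells, all on
queen-contiguity weights with permutation inference.

**The model family.** Poisson counts with offset `E_it` and

    log θ_it = α + b_i + γ_t + φ_t + δ_it,

where `b_i` is a BYM2 spatial field
`b = (√(1−ω) v + √ω u*)/√τ_b` (iid `v`, scaled-ICAR `u*`, mixing ω =
structured share), `γ_t` is RW1/RW2/AR(1)/AR(2), `φ_t` iid year noise,
and `δ_it` a Knorr-Held Type I–IV interaction (Type IV =
`Q_space ⊗ Q_time`). Penalized-complexity priors throughout:
`pc_prec(U=1, α=0.01)` on precisions (P(sd > 1) = 1%),
`pc(U=0.5, α=0.5)` on ω (P(ω > 0.5) = 50%), N(0, 0.15) or `pc_cor0` on
the AR(1) coefficient, N(0, 10⁶) on α. Inference is
Metropolis-within-Gibbs MCMC with exact conjugate and
reparameterization moves; models are compared by DIC and WAIC and
checked with randomized PIT histograms. A one-axis-at-a-time prior
sensitivity grid (42 settings) probes robustness.

A synthetic registry generator produces complete, seeded datasets
(polygons, panel, compositions, rates) with known latent truth, so
every stage is testable without any external data.

## Worked example

Fit the bundled 132-city, 4-year scenario end to end:

```python
from stmap.synthetic_data import paper_scenario, generate_dataset
from stmap.standardize import compute_sir_panel
from stmap.geo_weights import binary_weights, row_standardize, build_st_weights
from stmap.spatial_stats import global_morans_i, st_morans_i
from stmap.bayes_stmodel import ModelSpec, fit_mcmc, dic, waic

ds = generate_dataset(paper_scenario(seed=1))
sir = compute_sir_panel(ds.panel, ds.composition, ds.rates)
cities = list(ds.graph.region_ids)
years = sorted(sir.year.unique())

w = row_standardize(binary_weights(ds.graph))
for y in years:
    v = sir[sir.year == y].set_index("city_id").loc[cities, "SIR"].to_numpy()
    r = global_morans_i(v, w, n_perm=999, seed=7)
    print(f"Moran's I {y}: {r.I:.3f}  (p = {r.p:.3f})")

mat = sir.pivot(index="city_id", columns="year", values="SIR") \
         .loc[cities, years].to_numpy()
st = st_morans_i(mat, build_st_weights(ds.graph, years), n_perm=999, seed=7)
print(f"spatiotemporal Moran's I: {st.I:.3f}  (z = {st.z:.1f}, p = {st.p:.3f})")

o = sir.pivot(index="city_id", columns="year", values="cases").loc[cities, years].to_numpy()
e = sir.pivot(index="city_id", columns="year", values="E").loc[cities, years].to_numpy()
fit = fit_mcmc(o, e, ModelSpec(), ds.graph, chains=2, iterations=4000,
               burn_in=2000, thin=2, seed=7)
print(fit.summary()[["parameter", "mean", "q2.5", "q97.5"]].round(3).to_string(index=False))
d, _ = dic(fit); wv, _ = waic(fit)
print(f"DIC = {d:.2f}   WAIC = {wv:.2f}")
```

Output:

```
Moran's I 2013: 0.135  (p = 0.005)
Moran's I 2014: 0.149  (p = 0.005)
Moran's I 2015: 0.142  (p = 0.004)
Moran's I 2016: 0.175  (p = 0.001)
spatiotemporal Moran's I: 0.279  (z = 13.5, p = 0.001)
parameter    mean   q2.5    q97.5
    alpha   0.015 -0.343    0.401
    tau_b   2.123  1.594    2.678
    omega   0.384  0.151    0.643
      rho   0.299  0.013    0.527
tau_gamma 320.186  3.890 1976.884
  tau_phi 270.007  7.210 1852.003
tau_delta  70.224 47.946   97.758
DIC = 4195.14   WAIC = 4159.46
```

Reading this: spatial clustering of risk is positive every year and
strengthens through the panel (Moran's I 0.135 → 0.175); persistence
across adjacent years raises the joint space–time statistic to 0.279.
In the fitted decomposition, most of the mixing posterior sits below
0.5 (here P(ω < 0.5) = 0.80): the spatial field is dominated by
unstructured city-to-city variation rather than broad regional
structure. The interaction precision `tau_delta` measures how much
city-year risk deviates from the additive space + time expectation.

The same pipeline runs from the shell:

```sh
stmap simulate --scenario paper --seed 1 --out data/
stmap run --config run.yaml          # SIR -> autocorrelation -> model ladder
stmap sensitivity --config run.yaml  # 42-cell prior grid
```

`stmap run` writes a reproducible bundle (config-hash-named directory):
per-year Moran table, LISA and Gi\* GeoJSONs, the space–time Moran
result, a model-comparison table (posterior summaries, DIC, WAIC),
the selected model's interaction surface binned for mapping, and the
PIT histogram.

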