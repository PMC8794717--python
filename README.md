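# isoniche

Individual dietary specialization from serial whisker stable-isotope
series.

Bulk stable isotopes archived along a growing vibrissa record an
animal's assimilated diet through time: δ15N tracks trophic level, δ13C
the habitat a consumer feeds in. For a population sampled one whisker
per animal, the isotopic niche decomposes into the spread of each
individual's own series and the spread between individuals, and the
ratio of the two measures how specialized each animal is. `isoniche`
implements this analysis chain end to end for studies like the Tasmanian
devil scavenging work it is modelled on — from raw instrument runs to
the table of specialization drivers — together with a seeded synthetic
population generator so every stage can be validated without field data.

## The model

For individual *i* with δ values *x*<sub>i1</sub>…*x*<sub>im</sub>
along its whisker:

* **INW<sub>i</sub>** (individual niche width) = Var(*x*<sub>ij</sub>),
  the variance of the individual's series (‰²);
* **BINW** (between-individual niche width) = Var over individuals of
  the per-individual means, computed once for the whole sampled
  population;
* **TNW** = mean(INW) + BINW, the total niche width;
* **SI<sub>i</sub>** = INW<sub>i</sub> / (INW<sub>i</sub> + BINW) ∈
  [0, 1].

SI < 0.2 classifies an individual as a specialist, SI > 0.5 as a
generalist, otherwise intermediate; the index is computed separately
for δ15N (NSI) and δ13C (CSI). Supporting stages:

* **Chronology** — whisker growth follows a von Bertalanffy curve
  L(t) = L∞(1 − e<sup>−k(t−t0)</sup>) (continuous or daily-discrete);
  inverting it dates any position and plans mass-constrained isotope
  segments separated by fixed-duration buffer cuts.
* **Normalization** — per-run two-point affine correction of raw
  readings against USGS40/USGS41a assigned values, per element.
* **Isoscape** — food-item group means ± SE shifted into consumer space
  by trophic discrimination factors (+3.5‰ N, +2.2‰ C by default).
* **Drivers** — all-subsets Gaussian linear models of NSI / log(CSI) on
  sex, age class, mass, site and competition level, ranked by
  AICc = −2logLik + 2k + 2k(k+1)/(n−k−1) with Akaike weights, ΔAICc < 2
  support, F tests against the null, and a simulation-calibrated
  quantile-plot envelope as the residual-normality screen.

## Worked example

```python
import isoniche as iso

pop = iso.simulate_population(iso.GeneratorConfig(seed=42))
res = iso.SpecializationModel.from_dataframe(pop.segments).fit()
print(res.summary())
```

```
Specialization index decomposition
  dialect: between-means  variance ddof: 1  thresholds: <0.2 specialist, >0.5 generalist
  NSI (d15N): n=71  BINW=1.816  TNW=3.173  median SI=0.164
      specialist: n= 39   54.9%
    intermediate: n= 20   28.2%
      generalist: n= 12   16.9%
  CSI (d13C): n=71  BINW=11.305  TNW=22.862  median SI=0.033
      specialist: n= 59   83.1%
    intermediate: n=  7    9.9%
      generalist: n=  5    7.0%
```

Most synthetic devils are nitrogen and carbon specialists, mirroring the
configured study conditions. Selecting drivers of the nitrogen index:

```python
est = iso.estimate_si(pop)                      # one row per individual
sel = iso.DriverSelection.from_dataframe(est, response="NSI")
print(sel.fit(seed=7).summary())
```

```
AICc model selection for NSI (n=70, 28 candidate models, 1 row(s) dropped for missing data)
Supported models (delta AICc < 2):
  1. mass                                               df=3 logLik=   4.240 dAICc= 0.00 w=0.528 p_vs_null=0.02056
  2. competition + mass                                 df=4 logLik=   4.648 dAICc= 1.44 w=0.257 p_vs_null=0.04725
  3. mass + sex                                         df=4 logLik=   4.468 dAICc= 1.80 w=0.215 p_vs_null=0.05614
Top model coefficients (R2=0.076):
  Intercept                     0.5658
  mass                         -0.0380
```

Heavier individuals have lower NSI (the negative mass coefficient): in
this population, as in the generator's truth model, large animals are
the trophic specialists. One animal lacks a mass record and is dropped
listwise, leaving n = 70; candidate models containing both site and
competition are aliased (competition level is a function of site) and
leave the candidate set with a warning.

The same analyses run from the shell:

```sh
isoniche simulate --out data/ --seed 42
isoniche si data/segments.csv --out si.csv
isoniche drivers si.csv data/covariates.csv --response NSI --out models.csv
isoniche run config.yaml            # full pipeline from one YAML config
```

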