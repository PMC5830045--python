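# ammlib

A portable model/data/metadata library for analysis provenance.

Agencies and research groups that manage natural resources under an
adaptive-management framework accumulate knowledge as fitted models:
each monitoring cycle produces new data, the data update the models,
and the updated models guide the next management decision. That only
works if every generation of model remains retrievable **together with**
the dataset that produced it and enough metadata to understand both
years later. Most statistical tooling is built for running analyses,
not for keeping them; `ammlib` is built for keeping them.

The central object is the **library** (`AmLibrary`), a single container
with four parts: a free-text description, key-value info about the
library itself, an ordered collection of *data* records (analysis
inputs) and an ordered collection of *model* records (analysis
outputs). Each record stores an opaque payload plus its own key-value
metadata, with a creation timestamp added automatically. Two metadata
keys are reserved for linkage: `data` on a model names the dataset it
was fit to, and `prior` names the model used as its prior. Links are
informal — by name, never by index, and never validated — but search
and subsetting honour them, so a query that finds a dataset brings
along the models fit to it and vice versa. Libraries are saved as
single-file ZIP archives with a JSON manifest carrying per-record
SHA-256 checksums, codecs, and version stamps.

Alongside the container, the package ships a seeded covariate
simulator (per-column distribution specs with independent seeds) and
two worked analyses used throughout the tests and the demo library:

* a one-factor ordinary least-squares fit, `ols_fit`, computed in
  closed form from the normal equations
  `β̂ = (XᵀX)⁻¹ Xᵀy` with the full summary surface — standard errors,
  t and F tests, residual quantiles, σ̂, R² and adjusted R²;
* conjugate beta-binomial updating, `beta_binomial_update`: a
  Beta(α, β) prior on a binomial success probability combined with
  y successes in n trials yields Beta(α + y, β + n − y).

## Worked example

```python
import ammlib as am

lib = am.build_demo_library()          # replay the demo sequence
print(am.list_names(lib, "data"))
# ['plant.data', 'apple.data', 'frog.data']

plant = am.get_record(lib, "data", "plant.data")
fit = am.ols_fit(plant["weight"], plant["group"])
print(fit.summary())
```

```
Residuals:
     Min       1Q   Median       3Q      Max
 -1.0710  -0.4938   0.0685   0.2462   1.3690

Coefficients:
                Estimate  Std. Error  t value  Pr(>|t|)
(Intercept)       5.0320      0.2202   22.850  9.55e-15
groupTrt         -0.3710      0.3114   -1.191     0.249

Residual standard error: 0.6964 on 18 degrees of freedom
Multiple R-squared: 0.073078,  Adjusted R-squared: 0.021582
F-statistic: 1.419 on 1 and 18 DF,  p-value: 0.249
```

The intercept 5.0320 is the mean weight of the ten control plants; the
effect −0.3710 is the treatment-minus-control difference, so treated
plants average 4.661. The F test on (1, 18) degrees of freedom shows
the treatment effect is weak (p ≈ 0.25), and the adjusted R² of 0.0216
says the grouping explains little of the weight variation.

Updating the apple-infestation prior with a new orchard sample:

```python
post = am.beta_binomial_update(am.BetaParams(2, 3),
                               am.BinomialObservation(y=25, n=100))
print(post)          # BetaParams(alpha=27, beta=78)
print(post.mean())   # 0.2571... — updated infestation probability
```

Link-aware search splits a library without losing pairings:

```python
parts = am.split_library(lib, "frog")
parts["extracted"].names("model")   # ['frog.model1', 'frog.model2']
parts["extracted"].names("data")    # ['frog.data']
```

The same operations are available from the shell via the `ammlib`
command (`ammlib demo --out demo.amml`, `ammlib search --pattern frog
demo.amml`, `ammlib summary demo.amml`, ...); see `ammlib --help`.

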