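# beescape

Landscape-scale floral-resource energetics and body-size-dependent bee
abundance modelling.

## The problem

Bees depend entirely on flowers for food, and land-use change around
remnant natural habitat reshapes how much nectar and pollen energy is
available to them — differently for large- and small-bodied species, which
differ in energetic requirements and foraging range.  `beescape` implements
the full analysis chain needed to ask whether a bee species' abundance
inside habitat remnants tracks the floral *energy* (calories, not just
flower counts) available from its partner plants, both within the remnant
patch and in the surrounding 1-km landscape matrix:

1. **Traits** — bee dry body mass (mg) predicted from body length via a
   log-log allometry with taxonomic-family and sex terms,
   `ln m = a + b ln L + family + sex`.
2. **Floral energetics** — nectar energy per flower as
   `Σ_s mass_s × (ΔH°c,s / MW_s)` over fructose/glucose/sucrose, pollen
   energy as pollen mass × mean calorific content (default 4.11 cal/mg);
   unmeasured species imputed from congeners, then confamilials, then
   literature values.
3. **Metaweb** — quantitative site-level bee × plant visitation matrices
   pooled into a regional metaweb; each bee's partner-plant set is the set
   of plants it was ever observed visiting.
4. **Landscape scaling** — flower densities per land-use class (plants
   missed by transects get a nominal density of half the class minimum),
   energy per m² summed over partner plants, multiplied by remnant area
   (patch energy) and by matrix land-use areas in the 1-km buffer
   (landscape energy), reported in Mcal.
5. **Abundance model** — counts per species × site modelled with a
   negative-binomial (NB2) GLMM: log link, ln(survey hours) offset,
   species random intercept, 2-SD-standardized predictors
   (ln mass, patch energy, landscape energy, patch area, and the
   mass × energy interactions), error-family comparison, VIF screening,
   all-subsets AICc selection with marginality, Nakagawa marginal /
   conditional R², and translation of fitted effects into percent of the
   observed capture-rate range.

A synthetic-data module generates every input with known ground truth
(including counts drawn from exactly the GLMM the pipeline fits), so each
stage has a parameter-recovery test without any external data.

## Worked example

Generate a synthetic study (23 sites, 53 bee species, 56 plant species) and
run the full pipeline:

```bash
beescape all --seed 1 --outdir out
```

or from Python:

```python
import numpy as np
from beescape import SimParams, full_dataset, NegativeBinomialGLMM
from beescape.inference import build_design

data = full_dataset(SimParams(seed=1))
f = data["frame"]                       # 53 x 23 species-site cells
X = build_design(f, tuple(data["global_terms"]))
m = NegativeBinomialGLMM(seed=1).fit(
    X, f["count"], groups=f["bee_species"],
    offset=np.log(f["effort_h"]))
print(m.wald_table().round(3))
```

which prints (abridged):

```
                 term  estimate    se       z     p
            Intercept    -2.598 0.085 -30.436 0.000
            z_ln_mass     0.336 0.166   2.028 0.043
              z_patch     0.005 0.106   0.044 0.965
          z_landscape     1.461 0.180   8.099 0.000
         z_patch_area    -0.063 0.105  -0.600 0.549
    z_ln_mass:z_patch     0.017 0.178   0.095 0.924
z_ln_mass:z_landscape     1.274 0.370   3.444 0.001
```

Read this as: bee capture rates rise steeply with partner-plant energy in
the surrounding landscape (`z_landscape`, here truth 1.313), and the rise
is much stronger for larger-bodied bees (positive `z_ln_mass:z_landscape`,
truth 1.235), while patch-level energy and patch area do nothing (truth 0)
— the generating parameters the estimator is recovering.  Coefficients are
on the 2-SD-standardized scale, so each is the change in log capture rate
across two standard deviations of its predictor.

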