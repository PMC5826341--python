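# lingadapt

Robustness analyses for cross-linguistic adaptation hypotheses — built around
the claim that ambient humidity shapes phonology (drier air makes precise
pitch control harder, so dry climates should select against complex lexical
tone and heavy vowel use).

Cross-linguistic data points are not independent: languages inherit traits
from common ancestors (families) and exchange them through contact (areas) —
Galton's problem.  A naive correlation between a climate variable and a
phonological trait is therefore easy to produce and hard to trust.  This
package implements, and calibrates on synthetic worlds, the battery of
procedures such a claim has to survive:

* **`world_sim`** — seeded generator of synthetic cross-linguistic worlds:
  languages nested in families and spatial grid areas, spatially
  autocorrelated specific humidity, Poisson tone counts with configurable
  humidity effects and an areal tone-diffusion confound, a second noisy tone
  measurement, vowel inventories with a humidity × inventory-size
  interaction, monthly tone-token corpora and formant tables.
* **`sampling_test`** — the independence-constrained percentile resampling
  test: repeatedly draw groups with no two languages sharing a family or an
  area (all languages **R**, complex-tone languages **C** — three or more
  tones — and non-complex **N**), and report the proportion of iterations in
  which the humidity-quantile difference (C − N) exceeds (C − R).
* **`agreement`** — measurement robustness: Cohen's (weighted) kappa,
  correlation and exact agreement between two tone measurements, plus a
  mixed-model test of whether between-source differences are biased by
  family, area or humidity.
* **`mixed_models`** — a Poisson/gaussian/binomial mixed-model engine
  (Laplace-approximated maximum likelihood) with random intercepts and
  humidity slopes for family and area; likelihood-ratio tests; the five-way
  random-effect ablation sweep; and an optimizer/start-point
  estimation-robustness sweep.
* **`vowel_geometry`** — vowel-space area as the convex hull of a language's
  (F1, F2) formant points.
* **`corpus_stats`** — tone contingencies for conversational-repair studies
  (Pearson χ²), seasonal contour-tone mixed models, and phoneme-level
  vowel/consonant ratio series with a periodic-smooth association test.
* **`phylo_asr`** — Brownian-motion ancestral-state reconstruction
  (weighted squared-change parsimony) and phylomorphospace coordinates.
* **`causal_dag`** — causal graphs with d-separation queries (witness paths
  included) and backdoor screening: which confounds still need control given
  the controls you already have.
* **`pipeline` / CLI** — one seeded entry point running
  simulate → tests → models → report.

## Worked example

Generate a confounded world — *no* causal humidity→tone effect, but strong
areal tone diffusion along the same geography that shapes humidity — and ask
whether the analyses are fooled:

```python
import lingadapt as la
from lingadapt.mixed_models import ablation_sweep

world = la.generate_world(la.WorldConfig(seed=42, beta_humidity_tone=0.0,
                                         borrowing_strength=0.8, area_slope_sd=0.1,
                                         n_families=50, languages_per_family=20))

res = la.percentile_test(world, la.PercentileTestConfig(n_iterations=2000, seed=1))
print({f"{int(k*100)}th": round(v, 3) for k, v in res.proportions.items()})

print(ablation_sweep(world)[["model", "estimate", "se", "z", "p"]].round(3)
      .to_string(index=False))
```

Output:

```
{'15th': 0.448, '25th': 0.474, '50th': 0.608, '75th': 0.724}
              model  estimate    se     z     p
         Full model     0.130 0.156 0.836 0.403
No family intercept     0.115 0.155 0.742 0.458
    No family slope     0.136 0.158 0.862 0.388
  No area intercept     0.489 0.078 6.245 0.000
      No area slope     0.349 0.065 5.386 0.000
```

Reading the numbers: the percentile test stays far from its 0.95 positive
threshold at every percentile (no evidence that complex-tone languages avoid
dry climates once family/area independence is enforced).  The ablation sweep
shows the diagnostic signature of an areal confound: the humidity coefficient
looks strongly significant as soon as either area random-effect term is
removed (z ≈ 5–6), but the full model with both area terms finds nothing
(β = 0.13 ± 0.16) — the "effect" lives entirely in geographic structure, as
it should in a world where humidity causes nothing.

The same pipeline runs from the shell:

```bash
lingadapt run --out results_run --seed 42
lingadapt dag --backdoor humidity tone_inventory --controlled contact
```

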