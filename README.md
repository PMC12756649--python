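# hircus

Pedigree-based genetic evaluation of early growth traits in goats, with the
additive genetic variance split into **autosomal** and **X-chromosomal**
components alongside **maternal genetic** and **maternal permanent
environmental** effects.

The package is aimed at quantitative geneticists and animal breeders who
want a transparent, fully testable implementation of the multivariate
animal model

    y_i = X_i b_i + Z_a,i a_i + Z_s,i s_i + Z_m,i m_i + Z_pe,i pe_i + e_i

with a ~ MVN(0, Σa⊗A), s ~ MVN(0, Σs⊗S), m ~ MVN(0, Σm⊗A),
pe ~ MVN(0, Σpe⊗I), e ~ MVN(0, Σe⊗I), where **A** is the numerator
relationship matrix and **S** its X-chromosomal analogue (gametic model:
males are hemizygous, a sire passes his whole X to every daughter and
nothing to sons; base females have S_ii = 1, base males ½).

What it does:

* pedigree reading, repair (duplicates, own-parent links, cycles, sex
  conflicts), topological ordering, inbreeding (Meuwissen–Luo) and
  structure statistics;
* dense A and S plus their sparse inverses by Henderson-style rules, all
  validated against a Monte-Carlo gene-dropping oracle;
* trait derivation (pre-weaning growth rate, Kleiber ratio, growth
  efficiency), mean ± 3 SD outlier QC, descriptive summaries, and
  marginal-F fixed-effect screening;
* multivariate **AI-REML** with exact scores from a Takahashi selected
  inverse, EM fallback, boundary handling, and AIC-based selection across
  the model ladder (full / no-X / no-maternal / free direct–maternal
  covariance), with heritabilities, variance ratios and genetic
  correlations plus delta-method standard errors;
* **BLUP** breeding values for every pedigree animal and genetic-trend
  regressions on birth date as a continuous covariate;
* a **synthetic-herd generator** reproducing the study design (15 does per
  buck, 8 birth years, 1–3-kid litters, weaning at 80 ± 5 days, optional
  truncation selection) whose generating (co)variances are the package's
  recovery-test ground truth.

## Worked example

```python
from hircus import (default_scenario, simulate_dataset, model_preset,
                    fit_reml, genetic_parameters, solve_mme, trend_table)

sc = default_scenario()                      # ~5,300 kids, BWT + WWT
ped, phen, truth = simulate_dataset(sc, seed=11)

spec = model_preset("model1", sc.traits,
                    {t: ["sex", "birth_year", "birth_type"] for t in sc.traits})
fit = fit_reml(spec, phen, ped)
print(f"logL={fit.logL:.2f}  AIC={fit.AIC:.2f}  P={fit.n_free_parameters}")
print(genetic_parameters(fit).table.round(3))

ebv = solve_mme(fit, phen, ped)
print(trend_table(ebv, sc.traits).round(4))
```

which prints (seed 11):

```
logL=-6294.85  AIC=12615.70  P=13
       sigma_P   h2_a  h2_a_se   h2_s  h2_s_se   h2_m  h2_m_se    pe2  pe2_se
trait
BWT      0.140  0.045    0.019  0.019    0.017  0.142    0.024  0.001   0.022
WWT      1.672  0.118    0.039  0.000    0.029  0.026    0.026    NaN     NaN

  trait  component  slope_per_year      SE  intercept     n
0   BWT  autosomal         -0.0013  0.0001     2.6460  6204
1   WWT  autosomal          0.0007  0.0007    -1.3602  6204
2   BWT    xlinked         -0.0003  0.0001     0.5637  6204
3   WWT    xlinked          0.0000  0.0000    -0.0000  6204
```

Read: the fitted phenotypic variance of birth weight is 0.140 kg², of which
4.5 % is direct autosomal, 1.9 % X-linked and 14.2 % maternal genetic —
each within two standard errors of the generating values (5.1 %, 2.9 %,
13.0 %). The trend table gives the per-year regression slopes of the
predicted autosomal and X-linked breeding values on birth date, in trait
units per year (near zero here: the default herd is unselected).

A command-line layer mirrors the library (`hircus ped stats`, `hircus
traits summary`, `hircus fit`, `hircus compare`, `hircus ebv`, `hircus
trend`, `hircus simulate`, `hircus pipeline run --config cfg.yaml`).

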