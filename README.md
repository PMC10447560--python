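# cogtraj

Age-related cognitive trajectories in autosomal dominant Alzheimer's
disease (ADAD), and how APOE genotype and education modify them.

Carriers of the PSEN1 E280A ("Paisa") mutation are genetically determined
to develop dementia, with median MCI onset around age 44 — yet onset
varies by years between individuals. `cogtraj` implements the statistical
pipeline for asking, from cross-sectional MMSE data (0–30, higher =
better), whether that variability tracks the APOE e4 allele (risk), the
e2 allele (protection) and years of education (cognitive reserve):

1. **Trajectory model.** Per group g, MMSE ~ Normal(x(age)ᵀβ_g, σ) where
   x(age) is a restricted cubic spline basis (k = 5 knots at Harrell
   quantiles, linear beyond the boundary knots); Cauchy priors on the
   coefficients, half-Cauchy on σ. Fitted by an in-package Hamiltonian
   Monte Carlo sampler (leapfrog, dual-averaging step size, dense-metric
   warmup; default 8 chains × 10,000 iterations, thin 10).
2. **Divergence age.** On a 0.1-year age grid, the posterior difference
   curve between two groups is summarized by a 99% equal-tailed credible
   band; the divergence age is the earliest age from which the band
   excludes zero, sustained for 5 years within the data's age support.
3. **Gene × environment regression.** Within each PSEN1 stratum, OLS of
   MMSE on genotype (e4+ or e2−), years of education, and their
   interaction.
4. **Demographics.** Mann–Whitney U and chi-square comparison tables,
   and the APOE genotype distribution table.
5. **Synthetic kindred generator.** The real registry data are
   access-restricted, so a generator with known ground truth (sigmoid
   decline whose onset is shifted by alleles and education) stands in;
   every stage is tested against it.

See `docs/methods.md` for model details, defaults and limitations.

## Worked example

```python
from cogtraj import (
    GeneratorParams, MCMC_PRESETS, compute_divergence, education_model,
    fit_group_trajectories, generate_cohort,
)

cohort, truth = generate_cohort(GeneratorParams(seed=1))  # 675 carriers, 594 non-carriers

fit = fit_group_trajectories(cohort, group="e4", stratum="carriers",
                             config=MCMC_PRESETS["desk"])
res = compute_divergence(fit, direction="lower")
print(f"e4+ carriers diverge from e4- carriers at {res.divergence_age:.1f} y")

reg = education_model(cohort, stratum="carriers", allele="e4")
for name in ("genotype", "education_years", "genotype_x_education"):
    print(f"{name:>22s}: beta = {reg.coef(name):+.2f}, p = {reg.p(name):.3g}")
```

Output:

```
e4+ carriers diverge from e4- carriers at 36.3 y
              genotype: beta = -3.26, p = 0.0188
       education_years: beta = +0.08, p = 0.282
  genotype_x_education: beta = +0.14, p = 0.399
```

Under this simulation, e4+ carriers leave the e4− trajectory in the
mid-to-late 30s (the generator shifts their latent onset 5 years
earlier) and carrying one e4 allele costs about three MMSE points among
carriers. The education and interaction coefficients carry the expected
signs (education protects; it attenuates the e4 penalty), but the
generator's cross-sectional interaction is a small effect that a single
cohort of this size detects in sign more reliably than in significance —
see the problem-size discussion in docs/methods.md.

The same analyses are available from the shell:

```bash
cogtraj simulate --seed 1 --out cohort.csv --truth truth.csv
cogtraj fit --cohort cohort.csv --group e4 --stratum carriers \
            --chains 4 --iters 2000 --thin 2 --seed 1 --out fit.npz
cogtraj diverge --fit fit.npz --direction lower --out divergence.csv
cogtraj regress --cohort cohort.csv --stratum carriers --allele e4 --out reg.csv
cogtraj run --seed 1 --out results/          # the full battery
```

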