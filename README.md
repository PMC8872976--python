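# phenocomb

Case-control phenotypes for a complex disorder are rarely defined one way.
Starting from a minimal "cardinal symptom" requirement (for major
depression: depressed mood or anhedonia), stricter definitions are built by
layering binary diagnostic components — episode recurrence, five or more
symptoms, long duration, functional impairment, persistence — and every
choice changes who counts as a case, who counts as a control, and
potentially the genetic architecture the phenotype captures.

`phenocomb` implements the full analysis grid for this question:

* **Combinatorial phenotype construction.** All 2⁵ = 32 subsets of five
  components on top of the cardinal baseline. A participant is a **case**
  when the cardinal item and every listed component are endorsed, a
  **control** as soon as one required element is explicitly not endorsed,
  and **missing** otherwise; exclusions (screening for other disorders)
  override status but are applied only after the sample prevalence is
  recorded.
* **Liability-scale SNP heritability** per phenotype by
  phenotype-correlation–genotype-correlation (PCGC) regression in its
  random-ascertainment form: Haseman–Elston regression of pairwise
  phenotype products y·y on genomic relatedness g over all i<j pairs,
  converted to the liability scale with
  h²₍liab₎ = h²₍obs₎ · K²(1−K)² / (z² P(1−P)), where K is the population
  prevalence (taken equal to the pre-exclusion sample prevalence), P the
  case proportion and z = φ(Φ⁻¹(1−K)).
* **Genetic correlations** with external cohorts by LD score regression:
  E[χ²ⱼ] = N h² ℓⱼ/M + Na + 1 per trait and
  E[z₁ⱼz₂ⱼ] = √(N₁N₂) ρ_g ℓⱼ/M + a for the cross term, with panel-computed
  bias-adjusted LD scores ℓⱼ and r_g = ρ_g/√(h²₁h²₂).
* **Difference tests that respect sample overlap.** Every pair of
  phenotypes shares nearly all of its sample, so differences in h² or r_g
  use a delete-one-block jackknife (200 blocks on a shared seeded
  partition; individuals for h², SNPs for r_g), pooled by enrichment level
  and by added component with inverse-variance weighting, with Bonferroni
  thresholds for the 32 phenotypes and the 25 component × enrichment cells.
* **A synthetic cohort generator.** Individual-level mental-health and
  genotype data of the kind this analysis needs are access-restricted, so
  the package ships a multivariate liability-threshold simulator: per-SNP
  effect vectors with a chosen cross-trait genetic correlation, correlated
  environmental deviates, realized-quantile thresholding (sample prevalence
  exact by construction), optional block LD, and an independent external
  cohort sharing the same effect vectors so the true r_g is known.

## Worked example

```python
import numpy as np
import phenocomb as pc

panel = pc.simulate_genotypes(n=4000, m=1500, n_chrom=10, seed=11,
                              bp_spacing=300_000, ld_block_size=4)
arch = pc.default_architecture()
table = pc.simulate_components(panel, arch, seed=11)

defs = pc.enumerate_phenotypes()
panel_h2, n_removed = pc.exclude_region(panel)   # MHC analog on chr 6
grm = pc.compute_grm(panel_h2)
for defn in (defs[0], defs[2], defs[-1]):
    asg = pc.assign_case_control(table, defn)
    est = pc.pcgc_h2(asg, grm)
    print(f"{defn.name}: K={est.K:.3f} "
          f"h2_liab={est.h2_liability:.3f} (SE {est.se_liability:.3f})")
```

prints

```
Cardinal: K=0.560 h2_liab=0.185 (SE 0.026)
Cardinal + Impairment: K=0.341 h2_liab=0.153 (SE 0.027)
Cardinal + Recurrence + Symptoms5 + Duration + Impairment + Persistence: K=0.094 h2_liab=0.163 (SE 0.052)
```

Each line is one phenotype definition with its sample prevalence K (used
as the population prevalence for the liability conversion) and its
liability-scale SNP heritability with a 200-block jackknife standard
error. Under the default architecture the generating liability
heritabilities lie between 0.10 and 0.16, and the estimates recover them
within their standard errors. Adding components shrinks the case set
(K drops from 0.560 to 0.094) while the control set grows.

The same workflow runs from the shell, stage by stage or end to end:

```bash
phenocomb all -c examples/config_small.yaml
```

producing `manifest.tsv`, `h2_estimates.tsv`, `rg_<trait>.tsv`,
`trend_*.tsv`, `attribution_*.tsv` and a bundled `report.json` in the
configured output directory. Every output carries the configuration hash
and seed in its header; two runs with the same configuration are
byte-identical.

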