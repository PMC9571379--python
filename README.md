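# ufcpred

Genomic prediction of cross means, progeny variances and the usefulness
criterion (UFC) for doubled-haploid (DH) breeding programmes — with a
synthetic multi-cycle barley-like programme to exercise the whole pipeline
end to end.

## The problem

Before a breeder makes a cross, its value lies in the distribution of the
progeny that cross would produce.  The usefulness criterion summarises that
distribution as

    UFC = mu + i * h * sigma_g

where `mu` is the expected family mean, `sigma_g` the genetic standard
deviation among progeny, `i` the selection intensity and `h` the square root
of heritability.  With genome-wide marker effects `alpha` from RRBLUP, both
ingredients can be predicted *before* the cross exists:

* **Mean** — the midparent genomic value, `sum_k w_k GEBV_k`, with weights
  `w` equal to each parent's expected genome contribution (1/2,1/2 for
  two-way; 1/4,1/4,1/2 for three-way; 1/4 each for four-way crosses).
* **Variance** — for a two-way cross of inbred parents, the DH progeny
  variance follows from the segregating loci and their linkage:

      sigma_G^2 = sum_c sum_{j,k in c} (q_jk/2 - 1/4)
                  (m_j m_k + v_j v_k - m_j v_k - v_j m_k)

  where `m_j`, `v_j` are the maternal/paternal diplotype effects
  (`2 alpha_j` times the allele indicator) and `q_jk = 1 - r_jk` is the
  probability that a locus pair stays in parental configuration, with
  `r_jk` the Haldane recombination fraction from the genetic map.  Unlinked
  pairs (`q = 1/2`) contribute nothing; the diagonal (`q = 1`) gives the
  per-locus terms.

The package implements this prediction machinery together with everything
around it: a breeding-programme simulator (meiosis under the Haldane model,
2-/3-/4-way crosses, DH induction, unbalanced alpha-lattice-like trials), a
two-stage REML mixed-model analysis of the phenotypes (per-environment BLUEs
and repeatability, across-environment BLUEs and heritability, family-specific
genetic variances), GBLUP/RRBLUP genomic prediction with marker QC and
cross-validation, and the validation scenarios a breeder would care about
(training set = prediction set; leave-final-cycle-out; training-size ladder;
a sweep of the selection constant `c = i*h`).

## Worked example

```python
import numpy as np
from ufcpred import simdata, validate, gpred, crosspred

ds = simdata.simulate_program(simdata.ProgramConfig(scale=0.25), seed=2024)
pheno = validate.analyze_phenotypes(ds)
print({t: round(p.h2, 2) for t, p in pheno.items()})
# {'ear_emergence': 0.85, 'grain_yield': 0.46, 'plant_height': 0.77}

res = validate.run_scenario_full(ds, validate.ScenarioConfig(seed=1), pheno)
print(res[res.trait == "ear_emergence"][["statistic", "r"]].to_string(index=False))
#                 statistic     r
#                      mean 0.964
#                  variance 0.693
#                     ufc_u 0.937
#                    ufc_mu 0.941
# mean_phenotypic_midparent 0.750
```

Read: on this simulated programme, predicted family means correlate with the
observed means at r = 0.96 while predicted family variances only reach
r = 0.69; the genomic midparent beats the phenotypic midparent baseline
(0.75).  The same ordering — means easy, variances hard — holds for all
three traits and is the package's central reproduced finding.

The numbered drivers under `analysis/` run the full study narrative
(simulation, phenotypic analysis, genotype-level cross-validation,
family-level validation, training-size ladder, c-sweep) and write tidy
tables under `results/`:

```bash
cd analysis
python 01_simulate_program.py
python 02_phenotypic_analysis.py
...
```

A CLI wraps the same steps for file-based use: `ufcpred simulate`,
`ufcpred pheno`, `ufcpred predict`, `ufcpred validate`, `ufcpred oracle`.

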