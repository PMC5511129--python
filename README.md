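# bmselect

Bayesian partition selection of protein biomarkers from clinical
concentration data.

## The problem

Given the measured concentrations of P proteins for N individuals of
known biological status (healthy `H` or pathological `P`), which subset
of proteins discriminates the two populations?  Instead of testing
proteins one at a time, `bmselect` treats the **partition** of the
protein list into a discriminant subset (+) and a non-discriminant
subset (−) as the decision variable and compares all candidate
partitions δ ∈ {+,−}^P at once.  Correlations between proteins are
handled intrinsically, because each subset is modeled jointly.

The model: statuses are Bernoulli(p) with p ~ Beta(a, b); discriminant
concentrations are multivariate Gaussian with status-dependent mean and
precision, x⁺ | b ~ N(m_b, Γ_b⁻¹); non-discriminant concentrations share
a common Gaussian, x⁻ ~ N(m_C, Γ_C⁻¹).  With Normal–Wishart priors
(ν, η, μ, Λ) on each (m, Γ) pair, the marginal likelihood (evidence) of
a partition is **exact**:

    f(x, b | δ) ∝ [KNW⁺ᵖˢᵗ_P / KNW⁺ᵖʳⁱ_P] · [KNW⁺ᵖˢᵗ_H / KNW⁺ᵖʳⁱ_H]
                  · [KNW⁻ᵖˢᵗ_C / KNW⁻ᵖʳⁱ_C] · B(a+N_P, b+N_H)/B(a, b)

a product of Normal–Wishart normalizing-constant ratios computed from
the conjugate posterior updates — no MCMC, no quadrature.  Normalizing
over all candidates by Bayes' rule gives the posterior probability of
every partition; selecting the most probable one minimizes the global
0/1 selection risk.

When concentrations are measured with additive Gaussian noise of
Wishart-distributed precision (y = x + ε, Γ_ε ~ W(ν_ε, Λ_ε)), the latent
x must also be integrated out.  `bmselect` implements the closed-form
Gaussian approximation of the resulting matrix-t factors (valid for
large prior degrees of freedom), giving a noisy-data selector of the
same enumerative form.

Hyperparameters are elicited by moment matching: expert orders of
magnitude E(m), V(m), E(Γ), V(Γ) (e.g. in µg/ml) are inverted through
E(Γ) = νΛ, V(m) = Λ⁻¹/[η(ν−P*−1)], Var(Γ_ii) = 2νΛ_ii².

The package also ships the Monte-Carlo benchmark of the selection error
rate τ (% of realizations where the selected partition differs from the
generating one) and four baseline selectors: per-protein Student t test,
linear LASSO, per-protein Bhattacharyya distance, and forward-HSIC
selection.

## Worked example

```python
import numpy as np
from bmselect import BayesPartitionSelector

rng = np.random.default_rng(0)
n = 400
y = rng.integers(0, 2, n)                      # 1 = pathological
X = rng.normal(1000.0, 0.03, (n, 3))           # three proteins, ug/ml
X[:, 1] += np.where(y == 1, 5.0, 0.0)          # protein 2 discriminates

sel = BayesPartitionSelector().fit(X, y)
print(sel.get_support())                       # [False  True False]
print(round(sel.map_posterior_, 4))            # 1.0
print(sel.posterior_table_.to_dataframe().head(3))
```

Output of the last line:

```
   bitmask discriminant_proteins  log_evidence  posterior_prob
0        2             protein_2   2190.014783        0.999950
1        3   protein_1;protein_2   2179.561413        0.000029
2        6   protein_2;protein_3   2179.246317        0.000021
```

The selector enumerated all 2³ = 8 partitions; the partition marking
exactly protein 2 discriminant carries posterior probability 0.99995,
and the runners-up are its one-protein supersets — their evidence is
*penalized* by ~10.5 logs relative to the MAP even though they nest it:
integrating out the extra parameters automatically discourages
overfitting.

The selectors are scikit-learn estimators (`fit`, `get_support`,
`transform`, `get_params`) and compose with pipelines and model
selection.  The same functionality is available from the shell:

```bash
bmselect simulate --p 3 --n 400 --partition 2 --seed 3 --out cohort.csv
bmselect select --input cohort.csv --top-k 4 --out ranked.tsv
bmselect benchmark --config bench.yaml --methods bms_as_d,ttest --out tau.tsv
bmselect oracle --input tiny.csv --partition 1 --samples 100000 --seed 1
```

`select` ranks partitions of a cohort CSV (one row per individual,
protein columns plus a `status` column); `benchmark` estimates τ for the
configured protocol; `oracle` cross-checks the closed-form evidence
against brute-force Monte-Carlo marginalization on a small cohort.

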