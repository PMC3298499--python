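# ipca — independent principal component analysis for omics matrices

Unsupervised projection methods are the workhorse for a first look at a
high-throughput experiment: project the `n × p` expression matrix
(samples × genes/transcripts/metabolites, with `n ≪ p`) onto a few
components and see whether samples cluster by biology or by artefact.
PCA finds the directions of maximal variance, but its loading vectors are
estimated in the presence of thousands of noise variables; classical ICA
finds statistically independent components but degrades badly in high
dimension.

**Independent principal component analysis (IPCA)** combines the two: it
uses FastICA not on the data but as a *denoiser of the PCA loading
vectors*.  The premise is that a biologically meaningful loading vector
is super-Gaussian — only a few variables carry large weights, the rest
hover near zero — while accumulated noise pushes its distribution toward
a Gaussian.  Concretely, for a centered matrix `X = U D Vᵀ`:

1. take the first `m` loading vectors (columns of `V`), standardized;
2. run FastICA on them to obtain independent loading vectors `S = W Ṽᵀ`
   (rows of `S`, unit variance);
3. project: the independent principal components are `Ũ = X Sᵀ`;
4. order components by the excess kurtosis `E{s⁴} − 3` of their loading
   vectors — a sudden drop in kurtosis marks the irrelevant dimensions.

The sparse variant **sIPCA** soft-thresholds each independent loading,
`ŝ_jk = sign(s_jk)(|s_jk| − γ)₊`, with `γ` chosen per component so that
exactly `keepX[j]` variables keep non-zero weight — a built-in variable
selection that also removes the noisy variables from the components
themselves.

The package additionally ships the two standard baselines (classical ICA
with PCA whitening, and sparse PCA via regularized SVD with
soft-thresholding), the evaluation metrics (loading angles,
Davies-Bouldin cluster validity, support identification rates), and a
planted-eigenvector simulation framework: `Σ = V C Vᵀ` with two known
leading eigenvectors (eigenvalues 400 and 300 against a flat bulk of 1)
drawn from Gaussian, Laplace/uniform, or sparse distributions, embedded
by Gram-Schmidt, and sampled as `N(0, Σ)` datasets of 50 × 500.

## Worked example

```python
import numpy as np
from ipca import (FastICAOptions, center, ipca_fit, kurtosis_drop_report,
                  make_design, sample_dataset, loading_angle)

sim = sample_dataset(make_design("super_gaussian"), seed=7)   # 50 x 500
data = center(sim.data)
fit = ipca_fit(data, ncomp=4, fastica_options=FastICAOptions(seed=0))
for comp, kurt, drop in kurtosis_drop_report(fit):
    print(f"component {comp}: kurtosis {kurt:7.2f}   drop {drop:7.2f}")
print("angle to planted v1:",
      round(min(loading_angle(sim.true_v1, s) for s in fit.independent_loadings), 1))
```

```
component 1: kurtosis   44.77   drop    0.00
component 2: kurtosis   34.17   drop   10.60
component 3: kurtosis    0.10   drop   34.07
component 4: kurtosis   -0.29   drop    0.39
angle to planted v1: 8.7
```

The two planted super-Gaussian eigenvectors show up as two
high-kurtosis independent loadings; the collapse at component 3 is the
"sudden drop" that tells you two components suffice.  The first
independent loading sits 8.7° from the planted direction, versus 14.5°
for the corresponding raw PCA loading on this draw.

The same workflow is available from the shell:

```sh
ipca fit --input expression.csv --method sipca --ncomp 2 --keepX 50 --seed 0 --outdir out/
ipca simulate --case sparse_gaussian --methods spca,sipca --keepX 50 --n-reps 500 --seed 0
ipca evaluate --input expression.csv --labels-column dose --method ipca --ncomp 2
```

`fit` writes `scores.csv`, `loadings.csv`, `kurtosis.json` and a
`run_log.json` that reproduces the run bit-for-bit.

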