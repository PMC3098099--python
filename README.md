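# duonorm

Normalisation toolkit for **dual-colour antibody microarrays** — spotted
arrays of capture antibodies incubated with two differently labelled
protein samples (e.g. Cy5 tumour vs Cy3 control) competing for binding.
The package is for statisticians and bioinformaticians pre-processing
such "boutique" protein arrays, where most printed features are
*expected* to be regulated and the standard assumptions of global loess
normalisation (most probes unchanged, symmetric regulation) fail.

## What it implements

Working in MA coordinates (M = log2 Cy5/Cy3, A = ½·(log2 Cy5 + log2 Cy3)),
normalised M-values are residuals of a weighted robust loess regression
of M on A. The package provides the full family of within-array methods:

- **GL** — global loess, every probe weight 1;
- **InvTseng** — iterative *rank-invariant* selection: start from probes
  with channel rank difference Δ_g = |r(Cy5_g) − r(Cy3_g)| < d whose
  average rank avoids the l most extreme ranks per side, iterate with
  threshold p·|S| until the set size stabilises; binary loess weights,
  linear tail extrapolation;
- **InvMod** — the modified selection: no boundary exclusion, slow
  high-retention iterations keeping the 99% of the current set with the
  smallest Δ, stopping once ≤ 25% of probes remain, and graded weights
  w_g = (maxΔ − Δ_g)/maxΔ; robust even when most regulation is one-sided;
- **RDWGL** — one global loess with the graded rank-difference weights;
- **NN** — no within-array normalisation (baseline).

Around them, the complete chain: normexp background correction
(S = Normal background + Exponential signal, corrected value
E[T|S] + offset 50), A-quantile between-array normalisation,
duplicate-spot averaging, and a limma-style moderated-t two-group test.
A synthetic self-self simulation study with a spike-in scheme
(truncated-normal M shifts, A unchanged) and ROC/AUC + nearest-shrunken-
centroid/.632-bootstrap evaluation quantifies how each normalisation
affects the ability to detect true differential expression.

Key estimators follow scikit-learn conventions (`WeightedLoess`,
`MANormalizer`, `ModeratedTTest`, `NearestShrunkenCentroid` with
`fit`/`transform`/`predict` and `get_params`), so they compose with
sklearn model selection; module functions operate on the domain
containers (`TwoColourArray`, `ArraySet`).

## Worked example

```python
import numpy as np
from duonorm import (BaselineModel, Scenario, generate_baseline, spike_in,
                     run_pipeline, roc_from_pvalues)

# 20 synthetic self-self arrays, 810 antibodies in duplicate, with a
# nonlinear dye bias and array-to-array variation
base = generate_baseline(BaselineModel(seed=0))

# 40% of antibodies upregulated (fully asymmetric), shifts ~ |N(0.1, 0.1)|
ds = spike_in(base, Scenario(prop_de=0.4, asym=1.0), run_seed=7)

for method in ("gl", "invmod", "nn"):
    res, antibodies = run_pipeline(ds.arrays, method=method)
    _, _, auc = roc_from_pvalues(res.p_raw, ds.truth_de)
    print(f"{method:7s} AUC = {auc:.3f}")
```

Output from this exact script:

```
gl      AUC = 0.610
invmod  AUC = 0.784
nn      AUC = 0.467
```

With 40% one-sided regulation, global loess (`gl`) drags the fitted
curve towards the upregulated cloud and shrinks true effects (AUC 0.61),
while the modified rank-invariant normalisation (`invmod`) fits its
curve through probes whose channel ranks agree and preserves the signal
(AUC 0.78). Unnormalised data (`nn`) is at the mercy of array-to-array
bias — this run lands below chance, other runs do well; across runs its
AUC spread is wide enough that the 95% interval always covers 0.5.

A thin CLI mirrors the chain:

```bash
duonorm simulate --prop-de 0.4 --asym 1.0 --runs 1 --seed 0 --out sim/
duonorm normalize --method invmod --in sim/run_000 --out norm/
duonorm diffexp --in norm/m_matrix.tsv --groups groups.tsv --out de.tsv
duonorm evaluate --methods gl,invmod,nn --prop-de 0.4 --asym 1.0 --runs 25 --seed 0 --out bench/
```

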