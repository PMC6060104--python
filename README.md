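# wsdm — weighted symbolic dependence metric for fMRI connectivity

Resting-state functional connectivity (FC) is usually measured with
Pearson's correlation, which is blind to non-linear coupling between brain
regions. Histogram-based mutual information is the classic non-linear
alternative, but it is unreliable on the short, sluggish BOLD time series
that fMRI provides (a few hundred samples at TR 2–3 s). This package
implements a weighted Symbolic Dependence Metric — **wSDM** — built for
exactly that regime, together with the seed-mapping, group-statistics and
classification machinery needed to use it in a case–control study, and a
synthetic BOLD generator to validate every stage against known ground
truth.

## The measure

For two time series x, y of length n:

1. **Copula dependence.** Replace each margin by its scaled ranks
   (pseudo-observations u = rank/n) and form the empirical copula C_n.
   Dependence is the normalized L² distance between C_n and the
   independence copula Π(u,v) = uv:

       Iφ²(x, y) = 90 ∬ (C_n(u,v) − uv)² du dv      (Hoeffding's Phi-Square)

   evaluated in closed form (the integral of the piecewise-constant C_n is
   exact, no numerical integration). Iφ² is 0 iff the series are
   independent, 1 for perfect monotone dependence, invariant under
   strictly increasing marginal transforms, and captures linear and
   non-linear association alike. The L¹ and L∞ analogues
   (Schweizer–Wolff σ = 12∬|C_n − Π| and κ = 4·sup|C_n − Π|) are provided
   as alternatives.

2. **Symbolic weight.** Encode each series as a binary string of local
   increases/decreases (symbol i is UP iff x[i+1] > x[i], giving n − 1
   symbols), and let

       sw(X̂, Ŷ) = 1 − d_H(X̂, Ŷ) / (n − 1)

   where d_H is the Hamming distance. sw ranges from 0 (every local
   movement disagrees) to 1 (the signals rise and fall in lockstep).

3. **wSDM.**

       wSDM(x, y) = sw(X̂, Ŷ) · Iφ²(x, y)

   The copula factor supplies robust rank-based dependence; the symbolic
   factor weights it by temporal coherence, so associations that are
   strong in rank but incoherent in time are pulled toward zero.

The unweighted measure (`dm`, the Phi-Square alone) and the linear
baseline (`pearson_positive`, Pearson's R with negative values set to
zero) are included for ablation and comparison.

## Worked example

`examples/01_coupled_series_metrics.py` generates band-limited
(0.01–0.08 Hz at TR 2.5 s, n = 200) signal pairs with linear, quadratic,
or no coupling and prints each measure with a circular-shift surrogate
test p-value:

```
      linear:  wsdm=0.592 (sw=0.86)  dm=0.685  pearson=0.893  p[wsdm]=0.001  p[pearson]=0.001
   quadratic:  wsdm=0.065 (sw=0.53)  dm=0.124  pearson=0.000  p[wsdm]=0.001  p[pearson]=1.000
 independent:  wsdm=0.008 (sw=0.49)  dm=0.016  pearson=0.000  p[wsdm]=0.446  p[pearson]=1.000
```

Linear coupling is seen by everything; purely quadratic coupling is
invisible to Pearson (r ≈ 0, p = 1) while wSDM rejects independence at
p = 0.001; with no coupling, nothing rejects. The other examples walk the
rest of the pipeline: `02` computes a thresholded seed map on a synthetic
brain with a planted coupled region, `03` runs two-sample t-maps,
conjunction and cross-site reproducibility, and `04` runs nested-CV
SVM classification for all three measures (wsdm 97.5 % outer accuracy vs
55 % for the Pearson baseline on the planted quadratic-coupling scenario).

A thin CLI mirrors the stages:

```bash
wsdm simulate --out sim/ --seed 3 --subjects 5
wsdm seedmap sim/sub-000.nii.gz --seeds seeds.yaml --measure wsdm --percentile 30 \
     --mask sim/mask_brain.nii.gz --out maps/
wsdm depend series.tsv --measure wsdm
```

## Library layout

| module | contents |
| --- | --- |
| `wsdm.symbolic` | up/down symbolisation, Hamming similarity weight |
| `wsdm.copula` | pseudo-observations, Hoeffding Phi-Square (closed form), Schweizer–Wolff σ/κ |
| `wsdm.metrics` | `wsdm`, `dm`, `pearson_positive`, association matrices, surrogate independence test |
| `wsdm.seedmap` | seed series extraction, voxelwise maps, proportional thresholding |
| `wsdm.groupstats` | one/two-sample t-maps with extent filtering, conjunction, cross-site reproducibility, slope comparison |
| `wsdm.classify` | leakage-free nested CV over the threshold percentile (SVM/kNN), ROC/AUC, paired measure comparison |
| `wsdm.simulate` | band-limited coupled series and toy two-group 4D datasets |
| `wsdm.io` / `wsdm.cli` | NIfTI + delimited-text I/O, YAML seed config, pipeline runner, CLI |

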