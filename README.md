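# modgrn — module-aware gene regulatory network inference

`modgrn` reconstructs a directed, ranked gene regulatory network (GRN)
from a gene expression matrix by exploiting the community structure of
transcriptional regulation. It is aimed at computational biologists
benchmarking network inference on microarray or single-cell RNA-seq
expression compendia with TF lists and gold-standard edge sets in the
usual benchmark text formats.

## Method in brief

1. **Module detection.** The expression matrix is decomposed as
   X = A·S by fixed-point ICA (negentropy maximisation, log-cosh
   contrast, symmetric decorrelation). Genes whose component loadings
   are significant under a false-discovery-rate test —
   q₍ᵢ₎ = p₍ᵢ₎·n/i with step-up monotonisation, against a robust
   Gaussian-bulk null — form one (possibly overlapping) module per
   component. Sign-split FDR, z-score, PCA-loading and k-means variants
   are included.
2. **Intra-module edges.** Within each module, every gene is regressed
   on its co-members (or the module's TFs) with stochastic gradient
   boosted trees (90% subsampling, out-of-bag early stopping); edge
   i → j is scored by i's accumulated variance reduction
   I(φ) = |S|·Var(S) − |S_l|·Var(S_l) − |S_r|·Var(S_r) over all its
   splits.
3. **Inter-module edges.** Pairs sharing no module are scored by
   closed-form ridge regression per target,
   min_α ‖E_t − E_r α‖² + ½‖α‖², edge score |α|.
4. **Assembly.** Each block of scores is min–max normalised separately,
   merged, deduplicated (max wins) and ranked descending — covering all
   n·(n−1) ordered pairs when no TF restriction applies.

Evaluation utilities cover overlap-aware module metrics
(Recovery/Relevance/F_rr from best-match Jaccard averages), AUROC/AUPR
of ranked edges against a gold standard, power-law degree fits
(log p_k = −α·log k + c), and the minimal/strict/interconnected
co-regulation module standards derived from an edge list. A synthetic
modular-GRN simulator (hub regulators, bursty super-Gaussian programs,
Gaussian noise, Bernoulli dropout) makes the whole stack testable
without external downloads. See `docs/methods.md` for the full model
description and design rationale.

## Worked example

Simulate an easy-regime dataset (200 genes, 4 modules of 25 with 2 TF
hubs each, 300 samples, no dropout), then run the full pipeline against
the simulated gold standards:

```bash
modgrn simulate --seed 7 --outdir sim
modgrn run sim/expression.tsv --n-comps 4 --repeats 3 --seed 7 \
    --tf-list sim/tf_list.txt --gold-edges sim/gold_edges.tsv \
    --gold-modules sim/gold_modules.txt --outdir run
```

The run prints (and writes to `run/report.json`):

```json
{
  "n_modules": 4,
  "n_ranked_edges": 1592,
  "n_regressors_fitted": 126,
  "auroc": 0.8197436112274821,
  "aupr": 0.6267234036877136,
  "f_rr": 0.8067849070713181,
  "recovery": 0.8067849070713181,
  "relevance": 0.8067849070713181,
  "f_rr_repeat_mean": 0.8054737120437253,
  "f_rr_repeat_sd": 0.0009271548954689802
}
```

Reading: the ICA-FDR step found 4 modules matching the planted ones at
F_rr ≈ 0.81 (1.0 would be exact recovery, stable across the 3 repeats);
the fused ranking of the 8 × 199 = 1592 TF→gene candidate edges
achieves AUROC ≈ 0.82 against the simulated gold network (0.5 would be
random), fitting only 126 boosted regressors — one per module
membership — instead of one per gene. `run/ranked_edges.tsv` holds the
ranked predictions (`regulator  target  score`), `run/modules.txt` the
detected modules, and `run/config.json` everything needed to replay the
run.

The same stages are available as library calls
(`modgrn.fastica`, `modgrn.fdr_assign`, `modgrn.infer_intra_module`,
`modgrn.infer_inter_module`, `modgrn.merge_and_rank`,
`modgrn.auroc_aupr`, ...) on in-memory `ExpressionMatrix` /
`ModuleSet` / `GoldStandardNetwork` objects.

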