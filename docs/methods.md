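# Methods

## The model

`modgrn` infers a directed gene regulatory network (GRN) from an expression
matrix **X** (n_samples × n_genes) under a modular view of transcription:
genes organise into (possibly overlapping) modules driven by shared
regulatory programs, with intra-module regulation dense and inter-module
regulation sparse and weak. Inference proceeds in four stages.

### 1. Module detection (ICA-FDR)

X is modelled as a linear mixture **X = A·S**: the columns of the mixing
matrix A (n_samples × n_comps) are statistically independent, non-Gaussian
module activity signals over samples, and row k of the source matrix S
(n_comps × n_genes) holds the loading of component k on every gene.

The estimator is the fixed-point FastICA scheme. Genes are first whitened:
the gene–gene covariance is eigendecomposed and the data projected onto the
top `n_comps` eigenvectors rescaled to unit variance (requesting more
components than the covariance's effective rank is an error). The unmixing
matrix then iterates

  w ← E{z·g(wᵀz)} − E{g′(wᵀz)}·w

for all components in parallel, followed by symmetric decorrelation
W ← (WWᵀ)^(−1/2)W each sweep, with the log-cosh contrast
(g(u) = tanh(a₁u), a₁ = 1) by default and the Gaussian-kernel contrast
(g(u) = u·e^(−u²/2)) available for very heavy-tailed data. Convergence is
declared when every unmixing direction changes by less than `tol = 1e−4`
(|1 − |⟨w_new, w_old⟩||); otherwise the loop runs to `max_iter = 20 000`
and returns with `converged=False` and a warning rather than raising —
repeat-averaging protocols tolerate occasional failed runs. Runs are
deterministic given the seed. S rows are rescaled to unit variance (A
absorbs the inverse scale), so A·S always reproduces the projection of the
centered data onto the retained subspace.

**Gene assignment.** Per component, loadings are converted to two-sided
standard-normal tail p-values and admitted to the module when their FDR
Q-value — q_(i) = p_(i)·n/i over the n ascending-sorted p-values, with the
step-up monotone completion (running minimum from the largest rank) —
falls strictly below `q_cutoff` (default 1e−3). The raw ratio without the
monotone completion can be non-monotone in rank, which would make the
threshold rule rank-inconsistent; the step-up completion is the standard
fix and is exposed separately (`qvalues(..., monotone=False)`).

**The null scale.** The Gaussian-bulk null is estimated robustly: each S
row is centered at its median and scaled by its normal-consistent MAD
rather than by the full-row standard deviation. The reason is arithmetic:
with unit-variance rows, a loading block containing a fraction *f* of the
genes can never exceed z = √((1−f)/f) under full-sd scaling (≈ 2.65 when a
quarter-sized module sits among 4× as many genes), which would blind the
test to any module above a few percent of the genes regardless of how
strong its loadings are. The median/MAD estimate is consistent for the
N(0, σ²) bulk and insensitive to the heavy module tail, so planted
loadings keep their nominal z-scale and the null calibration (pure-noise
components essentially never assign genes at q_cutoff = 1e−3, Simes bound)
is unchanged.

Variants:

* **ICA-FDR2** — the positive- and negative-loading tails are tested
  separately (one-sided p-values within each tail), yielding up to two
  modules per component; useful when a program activates some genes and
  represses others.
* **ICA-zscore** — thresholds |s_kj| > `z_cutoff` (default 1.5) directly
  on the unit-variance rows, with no re-standardisation; the different
  scale convention is why its cutoff grid differs from the FDR one.
* **PCA** — principal-axis loadings over genes, gene admitted when
  |loading| ≥ `loading_cutoff` · max|loading| of its component.
* **k-means** — Lloyd clustering of gene profiles (k-means++ seeding), a
  disjoint-partition baseline.

Empty modules are dropped everywhere; genes assigned nowhere stay
unassigned and are treated as singleton modules downstream.

### 2. Intra-module edges (stochastic gradient boosting)

Within each module, every member j in turn is the regression target
x_j = f_j(x^(−j)) + ε with the other members (or the module's TFs when a
TF list is supplied) as predictors. f_j is a boosted ensemble of
depth-limited least-squares regression trees; each tree is grown on a
fresh random 90% row subsample, and the held-out 10% monitors out-of-bag
loss improvement — boosting stops when the moving average of the
improvement over a 25-tree window drops to zero, or at 500 trees.
Defaults (learning rate 0.01, depth 3) follow the efficiency-oriented
stochastic-boosting regime standard in tree-based GRN inference; the
ensemble machinery is scikit-learn's `GradientBoostingRegressor` driven
through its monitor callback.

The confidence of edge i → j is predictor i's accumulated variance
reduction, summed over all its split nodes φ across the ensemble:

  I(φ) = |S|·Var(S) − |S_l|·Var(S_l) − |S_r|·Var(S_r)

with population variance (the standard weighted impurity decrease; it is
recomputed from the tree internals, not taken from scikit-learn's
normalised importances, so scores are comparable across targets).
Importances are non-negative and a predictor never split on scores exactly
zero. Degenerate problems — fewer than 2 predictors, fewer than 10
samples, or a constant target — return all-zero importances with a warning
instead of failing, so sparse modules degrade gracefully.

Restricting candidates to co-members is the efficiency mechanism: the
stage fits exactly Σ_k |m_k| regressors (one per module membership,
counting overlap multiplicity), never one per gene against all genes.

### 3. Inter-module edges (closed-form ridge)

Every ordered pair whose endpoints share no module is scored by per-target
ridge regression. For target t, the centered expression of all candidate
regulators outside t's modules forms E_r and the centered target E_t; the
coefficient vector minimises

  ‖E_t − E_r α‖² + λ‖α‖²,  λ = 1/2,

whose unique stationary point (E_rᵀE_r + λI)α = E_rᵀE_t is solved exactly
(λ > 0 guarantees invertibility; λ = 0 on a rank-deficient design falls
back to the least-norm solution with a warning). Centering absorbs the
additive intercept/noise term without altering α. The edge score is |α|:
the fused ranking needs a non-negative confidence comparable with tree
importances, so the sign is dropped. λ is exposed in the config.

Because unassigned genes act as singleton modules, the intra and inter
candidate sets partition the n·(n−1) ordered non-self pairs exactly — an
integer identity that holds for arbitrary overlapping module structures
and is enforced by tests.

### 4. Assembly

Each module's intra score list and the inter list are min–max normalised
**separately** (x′ = (x − min)/(max − min)); tree importances and ridge
coefficients live on incomparable scales and each module's importance
scale depends on its target variances, so per-block normalisation is the
only fusion that does not let one block's units dominate. A block of
constant scores maps to all zeros — no discriminating evidence should not
be promoted. Duplicate pairs from overlapping modules keep their maximum
normalised score; a pair scored by both stages is a hard error (stage
separation violated). The concatenation is sorted by score descending with
a lexicographic (regulator, target) tie-break, giving a byte-reproducible
ranking.

## Evaluation

* **Module similarity.** Recovery = mean over known modules of the best
  Jaccard index against any observed module; Relevance is the mirror;
  F_rr is their harmonic mean (defined as 0 when both vanish). These
  remain meaningful for overlapping modules, where partition metrics
  (Rand, NMI) break down. Swapping the argument order swaps Recovery and
  Relevance and leaves F_rr unchanged.
* **Ranking metrics.** Against a gold standard, the cut-off K sweeps the
  distinct score values of the ranked list (tied scores form one step);
  FPR/TPR and recall/precision at each step give ROC and PR curves whose
  trapezoidal areas are AUROC and AUPR. With ties handled this way the
  AUROC equals the pairwise statistic P(s⁺ > s⁻) + ½P(tie) exactly. The
  negative universe defaults to all scorable non-gold pairs (benchmark
  convention); an explicit label-0 negative set can be selected instead.
* **Degree distributions.** A binarised network's total-degree histogram
  is summarised by ordinary least squares on log₁₀ p_k vs log₁₀ k over
  degrees with p_k > 0, reported as (α, c) with slope = −α. For comparing
  an inferred network against a gold standard the list is cut at
  K = |gold edges| — the neutral choice that makes the distributions
  comparable. Note this estimator is biased low on heavy-tailed graphs
  (singleton tail bins flatten the slope): preferential-attachment graphs
  with theoretical exponent 3 fit near 1.3–2.0, and published
  gold-standard networks near 1.2–1.5; comparisons are therefore only
  meaningful between fits produced by the same estimator.
* **Co-regulation module standards** from an edge list: *minimal* — one
  module per regulator (its target set, duplicates collapsed); *strict* —
  equivalence classes of genes with identical regulator sets;
  *interconnected* — connected components of the graph joining co-regulated
  genes that are also directly linked by an edge. Singletons are dropped;
  the interconnected standard typically yields the fewest modules.

## The synthetic test-bed

`generate_modular_grn` plants a hub-structured gold standard: modules
occupy consecutive gene blocks, each with `n_tfs_per_module` TF hubs that
regulate every other member; each TF additionally regulates genes outside
its module independently with probability `cross_module_edge_rate`.
Remaining genes are unregulated background.

`simulate_expression` realises the linear mixing model generatively. Each
TF hub carries its own independent bursty activity signal — Laplace(0, 1)
amplitudes masked to a random ~30% of samples, rescaled to unit
variance — mimicking a program active in a cell subset. Regulated genes
express weighted sums of their regulators' profiles (weights U(0.5, 1.5)
within a module, U(0.2, 0.5) across modules — inter-module coupling is
weak by the modularity premise), so module coherence emerges from members
mixing their hubs' signals. All genes then receive additive N(0,
noise_sd²) noise (background genes are noise only), and an independent
Bernoulli dropout mask zeroes entries, the difficulty knob that emulates
increasingly sparse single-cell regimes.

Two generator choices matter and were fixed by design analysis:

* **Independent per-hub signals.** If both hubs shared one signal at unit
  coefficient while targets amplify it ~2×, high-amplitude *targets* would
  be strictly better greedy predictors of other targets than the
  regulators themselves — edge direction would be unidentifiable from
  ranking and the design degenerate, telling us nothing about the method.
* **Burstiness.** With plain Laplace activity the finite-sample ICA
  rotation error leaves secondary-module loadings several bulk-σ high,
  blurring module boundaries; the spike-and-slab signal is much further
  from Gaussian and cuts that error sharply.

**Defaults are the study conditions** used throughout the tests: 200
genes, 4 modules × 25 genes with 2 TF hubs each (100 background genes),
300 samples, noise_sd 0.5 against module signals of sd ≈ 2–3, cross-edge
rate 0.01, dropout 0 ("easy regime"); dropout 0.5/0.7 are the degraded
regimes. Under the easy regime, ICA-FDR at n_comps = 4, q_cutoff = 1e−3
recovers the planted modules at mean F_rr ≈ 0.9 over 10 seeds, and the
full two-stage pipeline reaches mean AUROC ≈ 0.78–0.80 against the
simulated gold standard (random baseline ≈ 0.5) — both recomputed, never
stored, by `scripts/acceptance.py` and the test suite.

**What the simulator does not model:** count statistics (no negative
binomial), expression-dependent dropout, kinetic/ODE dynamics, feedback
loops, or indirect regulation chains. Passing tests therefore demonstrate
correctness of the machinery and identifiability under the linear modular
model, not performance on real single-cell data.

**TF lists.** End-to-end edge evaluation supplies the simulator's TF list
to both inference stages, mirroring benchmark practice where gold edges
are TF→gene. This is not cosmetic: genes that share *all* their
regulators are statistically exchangeable with them in any observational
ranking, so without a TF list the fully co-regulated module interior
carries no directional signal. The pair-coverage identity and the
work-bound counter are verified without TF restriction.

## Pipeline orchestration

`run_pipeline` repeats the decomposition `repeats` times (default 10)
with consecutive seeds to damp ICA randomness. Because no gold modules
exist at inference time, the repeat feeding the inference stages is
chosen by a gold-free rule: the run whose **median module size** is
closest to n_genes / n_comps, i.e. the size a balanced decomposition
would produce (ties break to the earliest run; runs with no modules rank
last). When gold modules are supplied, the mean ± sd of F_rr across all
repeats is reported alongside the selected run's metrics. Every output
directory receives the ranked edge list, the module file, the metric
report and the fully serialised effective config, so a run can be
replayed exactly.

## Numerical conventions

* Population (ddof = 0) variance throughout — whitening, variance
  reduction, normalisations.
* Whitening tolerance: covariance of the whitened output equals the
  identity to 1e−8; eigenvalues below 1e−12 of the leading one count as
  rank deficiency.
* Scores are serialised with 12 fixed decimals; write→read round trips
  preserve ranks byte-for-byte.
* Ties in every ranking break lexicographically by (regulator, target).
* Ridge with λ > 0 uses a positive-definite solve; λ = 0 falls back to
  SVD least squares.
* Seeds: every stochastic component (ICA init, tree subsampling, k-means,
  simulation) takes an explicit integer seed; identical seeds give
  bitwise-identical results.

## Known limitations

* The FDR assignment assumes a unimodal Gaussian loading bulk; strongly
  bimodal loading distributions would mislead the MAD scale. Estimation
  noise in the MAD also makes the null mildly anti-conservative on short
  rows (pure-noise components of 100 genes assign at least one gene in
  roughly 1–1.5% of runs at q_cutoff = 1e−3, versus the ~0.1% a plain
  Simes bound would give).
* Under-complete ICA (n_comps below the number of latent programs) blends
  programs with overlapping gene support; module counts must come from
  prior knowledge or an external grid search, not from the method itself.
* The boosted-tree stage ranks direct and strong indirect regulators
  similarly when their profiles are nearly collinear; this is inherent to
  observational network inference, not to the implementation.
* AUPR anchors the PR curve at recall 0 with the first threshold's
  precision; alternative anchors change AUPR (not AUROC) by O(1/|gold|).
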