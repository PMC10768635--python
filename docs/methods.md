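# Methods

## Data model

Drug-induced single-cell expression data are held as a dense third-order
tensor X over (drugs, genes, cells) with a binary weight tensor W of the
same shape: w = 1 where an entry was measured, w = 0 where it was not.
Missingness has two sources. First, the design is one-drug-per-cell, so a
cell's fiber exists for exactly one drug; with D drugs this alone leaves a
fraction 1 − 1/D of the tensor unobserved. Second, zeros inside an observed
profile are treated as missing by default (`zeros_are_missing=True` in
`build_tensor`). This choice is deliberate: structural missingness with 4–9
drugs caps at 75–89%, whereas per-group missing ratios in real screens of
this design exceed 95%, which is only possible if dropout zeros are also
counted as unobserved. Missing entries carry a placeholder value of 0, and
every computation multiplies by W before differencing, so the placeholder is
provably irrelevant.

Counts are normalized as ln(count / cell_total × 10,000 + 1) (natural log;
the scale factor is the standard library-size convention). Base-2 logs are
reserved for response signatures.

## Completion

Both decompositions minimise f(θ) = ½‖W∗X − W∗X̂(θ)‖²  by gradient descent.

* **CP**: one Iₙ × R factor matrix per mode; an entry is the sum over R of
  the products of factor entries. Gradient: ∂f/∂A⁽ⁿ⁾ = (Z₍ₙ₎ − Y₍ₙ₎)A⁽⁻ⁿ⁾,
  where A⁽⁻ⁿ⁾ = A⁽ᴺ⁾ ⊙ ⋯ ⊙ A⁽ⁿ⁺¹⁾ ⊙ A⁽ⁿ⁻¹⁾ ⊙ ⋯ ⊙ A⁽¹⁾ (Khatri–Rao).
* **TT**: one rₙ₋₁ × Iₙ × rₙ core per mode, boundary ranks 1; an entry is the
  chained product of the selected lateral slices. Gradient:
  ∂f/∂G⁽ⁿ⁾₍₂₎ = (Z₍ₙ₎ − Y₍ₙ₎)(G^{>n}₍₁₎ ⊗ G^{<n}₍ₙ₎)ᵀ, with G^{>N} = G^{<1} = 1.

Matricization uses the column ordering in which the lowest remaining mode
varies fastest; this is the ordering under which both closed-form identities
hold, and it is pinned by tests that compare the identities against direct
reconstruction. Gradient implementations are verified against central finite
differences (relative error < 1e-5, in practice ~1e-9) on random instances,
fully and half observed.

Default ranks are CP R = 5 and TT {1, 5, 5, 1}, the grid-searched values for
data of this shape; `grid_search_rank` re-selects them on any dataset by
internal validation RSE with ties to the smaller rank.

### Optimizer

Steepest descent with Armijo backtracking (sufficient-decrease slope 1e-4,
shrink factor 0.5, maximum step 1.0), a 100-iteration default budget, and a
1e-6 relative-objective-change stopping tolerance. The trial step
warm-starts at twice the previously accepted step rather than restarting at
1.0: on ill-scaled instances a fixed restart either wastes a dozen
backtracks per iteration or stalls, and the warm start is what lets
noise-free planted tensors reach held-out RSE ~1e-3 within 100 iterations
and machine precision within 1,000. The objective trace is non-increasing
across accepted steps by construction; a non-finite objective raises
immediately with the iteration number.

### Initialization

Random but scaled to the data. Let rms be the root-mean-square of the
observed entries. For nonnegative data (expression), parameters are drawn as
s·|N(1, 0.3)| with s = (rms/R)^{1/3} for CP and s = (rms/√Πrᵢ)^{1/3} for TT,
so the initial reconstruction already sits at the data's magnitude; starting
near zero spends most of a fixed iteration budget growing scale rather than
fitting structure, and empirically leaves cell-type structure unrecovered.
For mixed-sign data the mean anchor is meaningless and a small sign-symmetric
N(0, 0.1) start descends fastest. Both draws are seeded; identical seeds give
bit-identical trajectories.

## Evaluation

Artificial missingness hides a fraction of the *observed* entries (sampled
uniformly without replacement, count rounded half away from zero), refits on
the remainder, and scores recovery by

    RSE = ‖x̂ − x‖₂ / ‖x‖₂   over the held-out entries,

which is 0 at perfect recovery, 1 for an all-zero imputation, and
scale-invariant. Multi-group experiments report the per-group RSE summarized
by the mean across groups.

## Signatures and enrichment

A profile is the (drug, :, cell) fiber of the imputed tensor. A response
signature contrasts a cell's treated profile with the same cell's
vehicle-control (DMSO) profile — well defined only after completion, since
each cell is physically measured under one drug. The default form is
x′ₘ = log₂((treatₘ + 1)/(ctrlₘ + 1)) with pseudocount 1.0 applied
symmetrically; a plain-difference mode is available
(`mode="difference"`), since both contrasts are in use for this kind of
analysis, the ratio for expression-scale comparisons and the difference for
trajectory-stage signatures. Model predictions can slightly undershoot zero;
they are clipped at 0 before the ratio, as expression is nonnegative.
`group_signature` contrasts mean profiles over a set of cells (for example
one cell type), which suppresses per-cell imputation noise and is the
recommended form for group-level enrichment.

The top and bottom floor(0.05·p) genes of a signature (stable-sorted by
value then gene index, so tie-breaks are deterministic and the two sets are
disjoint) form the up- and down-regulated query sets. Each is tested against
every pathway with the upper-tail hypergeometric probability at universe
size l (fixed at collection construction, not recomputed per signature);
evaluation goes through the log-space survival function, so it is accurate
at l in the thousands. P values are BH-FDR adjusted separately per direction
within one signature's pathway family, and per-cell features are
fₖ = −log₁₀(qₖ) — the FDR-corrected rather than raw value, so features are
comparable across cells with different signature sharpness. The significance
convention is q < 0.05.

## Trajectory stage

A trajectory is an undirected graph over vertexes embedded in the same 2-D
space as the cells. Trajectory inference itself is external (principal-graph
learners over a UMAP embedding); graphs are ingested via `read_trajectory`
(vertex, edge, and embedding TSVs; duplicate edges collapsed with a warning;
disconnected graphs accepted). `build_simple_trajectory` — k-means centroids
joined by their Euclidean MST — exists only so the full pipeline is testable
without external tools and is labelled as plumbing, not a contribution.

Each cell maps to its Euclidean-nearest vertex (ties to the earliest vertex
in the graph's order). Row j of F_act / F_inh is the arithmetic mean of the
assigned cells' feature vectors; vertexes with no cells keep an all-zero row
and an explicit empty flag so matrix rows and graph vertexes stay aligned.

## Synthetic data

The generator plants an exactly low-rank nonnegative CP ground truth with
one latent component per cell type plus one drug-effect component coupling
(effect drug) × (effect genes) × (affected type). Marker genes load strongly
(2.5–3.5) on their own type's component and near zero (< 0.05) on the
others; baseline gene loadings are U(0.3, 1.0) and cell loadings U(0.8, 1.2)
on the own-type component. Observation noise is Gaussian (sd 0.05 by
default) on the log-scale values, clipped at 0; dropout zeroes and unmasks
observed entries at rate 0.3 (islet preset). These defaults give a missing
ratio of ~0.82 at 4 drugs — scaled down from the >95% of real screens in
proportion to the scaled-down gene count, keeping the structural
(one-drug-per-cell plus dropout) character. The presets are sized for
desk-scale runs (islet: 4 drugs × 80 genes × 160 cells in 4 types; lineage:
4 × 60 × 180 in 3 lines that share one factor model); real screens are two
orders of magnitude larger in genes and cells, and nothing in the
implementation is specific to the preset sizes.

What the generator does *not* emulate: count-level distributions (no
negative-binomial library-size model), batch effects, doublets, or ambient
RNA. Tests passing on this data show that the algorithms recover planted
low-rank structure, markers, and pathway signal under realistic missingness —
not that they overcome distributional artifacts of real protocols.

## Numerical and design notes

* All randomness flows through explicit integer seeds; the CLI expands one
  root seed per stage deterministically.
* The heldout-count rounding is half-away-from-zero; a rate that rounds to
  zero held-out entries is an error rather than a silent no-op.
* `hypergeom_p` rejects impossible configurations (z > min(k, r), k or
  r > l); `bh_fdr` rejects p outside (0, 1]. BH re-adjustment is not
  idempotent (the m/rank factor re-applies); only flat vectors are fixed
  points, and the tests pin the definition by hand-computed examples
  instead.
* Empty up/down selections (fraction·p < 1 gene) raise rather than return
  empty enrichments.
* Known limitations: gradient descent on a nonconvex objective can stall in
  local minima for adversarial rank choices (the grid search mitigates but
  does not eliminate this); CP completion can overshoot the observed value
  range at missing entries, where TT stays in range — visible in the marker
  checks; the per-line vs pooled comparison assumes lines genuinely share
  latent structure.
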