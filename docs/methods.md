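# Methods

## The model

`phenowalk` treats gene–trait association prediction as link prediction on a
heterogeneous network. Nodes are human genes and traits; traits comprise a
*target* set (human diseases, or drugs in drug mode) plus the phenotype sets
of any number of model species, each mapped onto human genes upstream via
orthology. The adjacency matrix is the symmetric block matrix

    A = [[ G ,  P ],
         [ Pᵀ,  Φ ]]

with `G` a weighted gene–gene functional network (weights ≥ 0, zero
diagonal), `P = [P_t | P_s1 | P_s2 | …]` the column-concatenation of
per-species gene×trait association matrices (target first), and `Φ`
block-diagonal, nonzero only in the target block: trait–trait similarity is
available for human diseases (text-mined clinical similarity) but not for
model-species phenotypes or drugs. Raw similarities in [0, 1] pass through
the increasing logistic squashing `L(x) = 1/(1 + exp(c·x + d))` with
defaults `c = −15`, `d = ln 9999` (so `L(0) = 10⁻⁴`, `L(1) ≈ 0.9997`),
which suppresses weak text-mining similarity while keeping near-duplicates
strong. The diagonal of `Φ` is zeroed before any walk computation; leaving
self-similarity in place adds a constant self-walk boost to every score and
carries no ranking information.

### Truncated Katz

The truncated Katz score is `S = Σ_{ℓ=1..k} βℓ Aℓ`: a count of walks of
length ≤ k between each node pair, damped by `β` per step. `[Aℓ]_ij` is the
number of i–j walks of length ℓ (weight-products for weighted graphs).
Only the gene×target-trait block of `S` is needed for ranking, and
`katz_block` accumulates it by repeated sparse multiplication onto the
target columns — `βℓ Aℓ E` with `E` the target-column selector — without
ever forming a full matrix power. `katz_full` exists as the reference
implementation; their agreement to 10⁻¹⁰ on randomized instances is the
core correctness surface and is asserted in the acceptance suite.

Defaults `β = 0.01`, `k = 4`. Small truncations are standard for
walk-count link prediction; with `β = 0.01` each extra step costs a factor
100, so direct neighbourhood structure dominates but longer detours —
through species phenotypes or trait similarity — still break ties.
Both parameters are exposed in `KatzParams` and on the CLI.

### Catapult

Catapult replaces the fixed damping `βℓ` with learned weights, one per walk
*kind*. A kind is a block pattern `X · P_t · Φ_t^j` where `X` composes
gene→gene atoms from `{G}` and `{P_s P_sᵀ : species s, target included}`.
For lengths ≤ 4 and 9 species this catalogue has 45 kinds; species detours
are resolved per species, so e.g. mouse-phenotype walks can earn a
different weight from yeast ones. The length-1 kind (`P_t` itself) is
excluded by default: it restates the training label on positives and is
identically zero on any pair one would score.

The gene×target block expansion of `A⁴` also contains the kind
`P_t Φ_t P_tᵀ P_t`, which the catalogue's grammar (gene-side atoms, then
`P_t`, then `Φ_t` powers) deliberately omits; the learned-vs-fixed
equivalence below is therefore stated at `k = 3` (where the catalogue is
the complete expansion) and at `k = 4` with `Φ_t = 0` (drug mode), both
exact.

**Feature hygiene.** A pair that can be scored never has its own
association in the network, but a visible training positive does, and
kinds touching the target bipartite more than once would count walks
through the pair's own edge — `P_t P_tᵀ P_t` gains a term equal to the
trait's gene count from the self-walk alone. Training positives' feature
rows are therefore computed leave-one-out, with the pair's own entry of
`P_t` removed: closed form for kinds linear in `P_t`
(`value − w · X[g,g] · Φʲ[t,t]`), exact in-place re-evaluation for the
three kinds containing a target detour atom. Without this correction the
classifier learns to recognize the leak rather than the biology, and its
rankings degrade visibly.

**Learning.** Because negative associations are essentially never
reported, training is positive–unlabeled: all known associations are
positives, everything else is unlabeled with the prior that most pairs are
negative. Each of `K` bagging rounds draws `|positives|` unlabeled pairs
uniformly without replacement as pseudo-negatives and trains a biased
soft-margin linear SVM

    min ½‖w‖² + C⁺ Σ_{i∈pos} ξ_i + C⁻ Σ_{i∈neg} ξ_i
    s.t. y_i (w·x_i + b) ≥ 1 − ξ_i,  ξ_i ≥ 0

with `C⁺ ≥ C⁻`: mistakes on certified positives cost more than mistakes on
arbitrary pseudo-negatives. The optimizer is a linear-kernel SVM with
per-sample penalty weights, which minimizes exactly this objective; tests
verify the objective against an independent trust-region solve of the
Wolfe dual to 10⁻⁴ relative. Each unlabeled pair accumulates its decision
value over the rounds in which it was out of bag; the final score is the
out-of-bag mean where available and the mean-hyperplane decision value
otherwise (a flag switches to mean-hyperplane scoring everywhere). Feature
columns are scaled by their maximum over all pairs — raw walk counts span
orders of magnitude across lengths, and max-scaling preserves sparsity and
nonnegativity; unit-variance scaling and no scaling were both clearly
worse for ranking in pilot runs on held-out synthetic seeds.

Defaults: `K = 30` (bagging variance is visibly flat between 10 and 100 on
the synthetic scale), `C⁻ = 1`, ratio grid `{1, 2, 5, 10, 20, 50}`. The
penalty ratio is chosen by the method's own tuning protocol: sample 70% of
positives as a validation pool, split into 5 folds, train on 4 folds plus
an equal number of sampled pseudo-negatives, and score recall of the held
fold within the top-100 predictions; ties resolve to the smaller ratio.
`catapult_train(params=None)` runs this protocol; the evaluation scorers
use it.

**Relation to Katz.** With every kind of length ℓ pinned to weight `βℓ`
(on raw counts) plus the direct term `β P_t` added back, the dot-product
score *is* the truncated Katz block — asserted exactly in the tests. The
learner strictly generalizes the fixed damping.

### Comparators

*RWRH* builds a row-stochastic transition matrix on the same node set:
gene rows split mass `(1−λ)` on the row-normalized `G` and `λ` on the
row-normalized `P`, trait rows symmetrically; a row whose other block is
empty keeps full mass on the nonempty one, and fully isolated nodes get a
unit self-loop. The walker restarts with probability `γ` to a seed
distribution over the query trait's known genes (mass `η`) and the trait
node itself (mass `1−η`). Scores are the gene block of the stationary
vector `p = (1−γ)Mᵀp + γp₀`. Defaults `λ = 0.5`, `γ = 0.7`, `η = 0.5`
follow the conventions of the original formulations; the per-trait seed
split `η` is a parameter because the source descriptions leave it
implicit. By default only the target bipartite enters the transition
matrix (the configuration comparators are usually run in); a flag swaps in
the composite multi-species `P`.

*PRINCE* propagates over the symmetrically degree-normalized gene network
only: `F ← α W' F + (1−α) y` with `W' = D^{-1/2} G D^{-1/2}` and restart
vector `y_g` equal to the transformed similarity between the query and the
most similar trait for which `g` is a known gene (the query itself
counting at raw similarity 1, hence `L(1)`). It never walks through
gene–trait or trait–trait edges, so species data cannot help it.
Default `α = 0.9`. Both solvers are iterated to a 10⁻¹⁰ fixed-point
tolerance and are checked against direct linear solves to 10⁻⁸.

*Degree list* ranks genes by their number of known target associations,
identically for every query trait — the multifunctionality-only baseline.

## Evaluation protocols

Three cross-validation schemes share one rank machinery. For a hidden pair
(g, t), candidates are all network genes minus t's *training* positives;
the rank is `1 + #strictly better + #ties excluding itself` — worst rank
within a tie group, so a constant scorer scores rank = n everywhere (this
is asserted). Summaries are the rank CDF `P(rank ≤ k)` and macro-averaged
precision/recall at k ≤ 100.

* **threefold**: associations are split uniformly into three near-equal
  groups; each group is hidden in turn and the method re-runs on the rest.
* **singleton**: genes with exactly one target association have it hidden,
  leaving them with zero target degree — a probe for genuinely novel
  predictions on unstudied genes. Only target associations are masked;
  model-species edges stay visible. Retraining is batched (default 3
  batches of singletons masked together) to keep cost proportional to the
  number of fits rather than the number of singletons.
* **linkage**: candidates are restricted to genes whose interval overlaps
  a ±10 Mbp window around the hidden gene (1-based inclusive coordinates),
  emulating ranking within a mapped locus.

Masking hygiene is enforced, not assumed: every scheme asserts that each
hidden pair is absent from the target bipartite and the assembled matrix
the scorer receives.

A uniform-random scorer reproduces the analytic null `P(rank ≤ k) = k/n`
within binomial confidence over 50 worlds, which calibrates the machinery
end to end.

## The synthetic worlds

The generator produces the study conditions for every test; it emulates
the statistical structure guilt-by-association assumes, not any real
dataset's marginals.

* **Gene network**: a weighted stochastic block model, `n_genes = 300` in
  10 modules, edge probability `p_in = 0.25` within and `p_out = 0.02`
  between, weights Uniform(0, 1].
* **Associations**: every trait (40 target traits; 4 species × 20
  phenotype sets) is anchored to a module and draws its genes from it with
  probability `assoc_signal = 0.8`, else globally. Draws are weighted by a
  per-gene *study bias* `rank^(−degree_skew/2)` over a random gene order
  (default `degree_skew = 1`), shared across species — the same
  well-studied genes accumulate annotations everywhere.
* **Trait similarity**: Jaccard overlap of the *module composition* of two
  traits' gene sets, then logistic-squashed. Module-level similarity is
  gene-blind by construction: masking an association can never leak back
  through the similarity block, mirroring the fact that text-mined
  clinical similarity carries no information about individual held-out
  genes.
* **Coordinates**: uniform on 5 chromosomes of 50 Mbp; gene length 10 kbp.
* **Hold-out**: 20% of true target associations, drawn uniformly over
  associations, masked from the assembled network.

`degree_biased_variant(world, skew)` is the multifunctionality stressor:
per-trait totals and module anchors are conserved, but each re-drawn
association comes from a global hub pool (weights `study_rank^(−skew)`)
with probability `skew/(skew+1)`, else uniformly from the anchor module.
`skew = 0` is the identity; the top-decile association share grows
monotonically in `skew`. The qualitative-contrast tests run at
`skew = 1.0`, where the degree distribution has the regime observed in
real disease-gene data — a majority of singleton genes alongside hubs
carrying a quarter of all associations — and it is in exactly this regime
that the documented contrasts appear: the learner matches or beats fixed
damping under standard three-fold validation (it can exploit hubness),
the ordering reverses under singleton validation (hub features vanish for
a gene with zero target degree, while module proximity in `G` survives),
and the learner's per-trait top-10 lists overlap more across traits.

The no-signal control sets `assoc_signal = 1/n_modules` (chance-level
anchoring) and `degree_skew = 0`; there no method — including the
degree list — beats the uniform null at the 1% level.

What passing these tests does *not* show: the worlds have clean modular
structure, equal informativeness across species, binary associations, and
no ascertainment noise in `G`; real networks violate all four, and
absolute CDF values here do not transfer to real data — only the
identities, the calibration, and the direction of the contrasts are
claims.

## Numerical choices

* Katz intermediates stay sparse and are accumulated right-to-left from
  the target columns; `katz_full` warns above `k = 6` (dense fill-in).
* The SVM solver runs at `tol = 10⁻⁶` with a 10⁵ iteration cap — generous
  in normal regimes, bounded in degenerate ones (near-uninformative
  features make the dual grind); the objective cross-check tolerance is
  10⁻⁴ relative.
* All bagging randomness derives from one seed via spawned child streams,
  one per bootstrap round; identical seeds give bit-identical accumulators.
* RWRH rows with no outgoing mass get a unit self-loop; PRINCE gives
  isolated genes a zero normalization contribution rather than NaN.
* Duplicate undirected edges collapse by maximum weight; self-loops are
  dropped with a warning count; association rows naming genes outside the
  network's gene universe are dropped and counted, never silently added.
* Problem sizes in the test and acceptance runs (300-gene worlds, 10–20
  seeds per condition, 12–15-node instances for exact identities) were
  chosen so the full pipeline runs comfortably on a single CPU while
  leaving the binomial tests adequately powered.

## Known limitations

* The catalogue omits the `P_t Φ_t P_tᵀ P_t` kind at length 4 (see above);
  re-enabling the direct length-1 term and extending the grammar are flags
  away but not defaults.
* ProDiGe-style multiple-kernel learning is out of scope; external methods
  can be evaluated through the score-file interface instead.
* `tune_penalties` optimizes recall@k of held-out positives, which tracks
  but does not equal within-trait ranking quality.
* The generator does not reproduce real degree distributions, network
  sizes, or per-species informativeness differences; species in synthetic
  worlds are exchangeable, so learned species weights are only testable
  for structure (per-species resolution), not for their real-data values.
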