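# phenowalk

Walk-based prediction of gene–trait associations on a heterogeneous
gene/phenotype network, for computational biologists who want to
prioritize candidate genes for a disease (or targets for a drug) from a
functional gene network plus gene–phenotype annotations across species.

## The problem and the methods

Guilt-by-association: a gene is a good candidate for a trait when the
network places it near the trait's known genes. `phenowalk` assembles a
single heterogeneous network over gene and trait nodes,

```
A = [[ G ,  P ],      G  — weighted gene–gene functional network
     [ Pᵀ,  Φ ]]      P  — gene×trait associations, one block per species
                      Φ  — trait–trait similarity (target species only)
```

and scores gene–trait pairs four ways:

* **Truncated Katz** — `S = Σ_{ℓ≤k} βℓ Aℓ`, a damped count of walks of
  length ≤ k between gene and trait nodes, computed block-wise without
  forming matrix powers (`katz_block`).
* **Catapult** — a positive–unlabeled learner that replaces the fixed
  damping `βℓ` with one learned weight per walk *kind* (gene-network
  steps, per-species phenotype detours `P_s P_sᵀ`, trait-similarity
  steps), trained as a bagged ensemble of biased soft-margin SVMs
  (`min ½‖w‖² + C⁺Σ_pos ξ + C⁻Σ_neg ξ`, pseudo-negatives drawn from the
  unlabeled pairs, out-of-bag score aggregation). With weights pinned to
  `βℓ` it reproduces Katz exactly.
* **RWRH** and **PRINCE** — random walk with restart on the heterogeneous
  network, and label propagation on the degree-normalized gene network
  from a similarity-smoothed restart vector: the standard comparators.
* **Degree list** — genes ranked by association count alone, the
  multifunctionality baseline.

Three cross-validation protocols (standard 3-fold over associations,
singleton validation for poorly-studied genes, ±10 Mbp linkage-interval
ranking) report rank CDFs and precision/recall, with strict masking
hygiene and a conservative worst-rank tie rule. A synthetic-world
generator (stochastic block model gene network, module-anchored
associations per species, gene-blind trait similarity, study-bias skew,
genomic coordinates) makes the whole pipeline testable without any
downloads. See `docs/methods.md` for the full model description.

## Worked example

Simulate a 300-gene world (40 target traits, 4 model species), score it
with truncated Katz, and evaluate under 3-fold cross-validation:

```yaml
# run.yaml
simulate:
  n_genes: 300
  n_traits_target: 40
  n_species: 4
  seed: 7
method:
  name: katz
  params: {beta: 0.01, max_len: 4}
evaluation:
  scheme: threefold
  seed: 7
output_dir: out
```

```
$ phenowalk evaluate --config run.yaml
{
 "scheme": "threefold",
 "n_ranks": 256,
 "cdf@10": 0.2421875,
 "cdf@100": 0.87109375
}
```

256 associations were hidden (a third at a time); Katz retrieved the
hidden gene in its trait's top 10 for 24% of them and in the top 100 for
87% — against a uniform-random expectation of about 3% at k = 10. The
full report (`out/report.json`) carries the complete rank CDF, the
precision/recall curve, per-pair ranks, and a provenance block;
`out/scores.tsv` holds the per-trait gene rankings.

Training Catapult on the same world and exporting its learned weights:

```python
from phenowalk import SyntheticConfig, generate, catapult_train
from phenowalk.cli import export_weight_report

world = generate(SyntheticConfig(seed=7))
model = catapult_train(world.net, k=30, seed=7, params=None)  # tuned C+/C-
print(export_weight_report(model).sort_values("mean_weight",
                                              ascending=False).head(6))
```

```
                  feature species  walk_length  mean_weight
      P[sp0]*P[sp0]^T*P_t     sp0            3     2.082388
                  G*G*P_t       -            3     1.633854
      P[sp3]*P[sp3]^T*P_t     sp3            3     1.628736
P[target]*P[target]^T*P_t  target            3     1.596689
P[sp1]*P[sp1]^T*P_t*Phi_t     sp1            4     1.068628
P[sp0]*P[sp0]^T*P_t*Phi_t     sp0            4     1.042750
```

Species-resolved detours through phenotype sets and two-step gene-network
walks carry the most weight; longer walk kinds earn less — the structure
the learner is meant to discover.

Other subcommands: `phenowalk simulate` (write a world as TSV fixtures),
`katz`, `catapult fit|score|tune`, `rwrh`, `prince`, `degree-baseline`,
`evaluate`, `report` (rank-CDF plots). Score files are plain
`gene<TAB>trait<TAB>score` TSVs, and `--method external` evaluates any
such file, so third-party methods can be compared without
re-implementation.

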