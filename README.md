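# deregsub

Find **maximally deregulated, root-connected subgraphs** in directed
biomolecular networks from (multi-)omics node scores.

Classical gene-set enrichment tests predefined pathways; de-novo subnetwork
methods instead extract the deregulated "pathway" from the network itself.
`deregsub` takes a directed interaction network (e.g. a KEGG-derived
gene-gene graph), a per-gene deregulation score s : V → ℝ (cohort log2 fold
changes, trinary calls, personalized fold changes, promoter-methylation
scores, methylation–transcription consistency indicators — constructors
included), and finds the node set V* that optimizes the **average score**

    max  s(V*) / |V*|     s.t.  k_min ≤ |V*| ≤ k_max,

where V* must be reachable from a single root node by directed paths inside
V*, the root must belong to an optional receptor set R, and every selected
sink must belong to an optional terminal set T.  Averaging (a fractional
objective) frees the method from fixing the subgraph size a priori, which is
what allows it to connect receptor-type sources to terminal-type targets.
The fractional program is solved exactly by a Dinkelbach iteration over
parametric integer linear programs, max sᵀx − λ eᵀx, with the exponential
family of rooted-connectivity constraints separated lazily from strongly
connected components of each incumbent (HiGHS via `scipy.optimize.milp`).

Under a Bernoulli model — nodes deregulated with probability p′ inside an
unknown subgraph and p < p′ outside — the average-score maximizer is the
maximum-likelihood subgraph for rates matched to the optimal average, and
the classical fixed-size variant (also implemented, as the benchmark
comparator) is maximum-likelihood only at a known subgraph size.  See
`docs/methods.md` for the model, the solution scheme, and all numerical
choices.

The package is aimed at computational biologists doing network-guided
interpretation of expression/methylation cohorts: cohort-level ("global")
subgraphs, per-patient ("personalized") subgraphs, and downstream survival
stratification by subgraph membership (network-defined cancer genes).

## Worked example

A small growth-signaling network, scored with cohort log2 fold changes
(MAPK cascade strongly up, PI3K branch flat/down):

```sh
deregsub solve --graph net.sif --scores scores.tsv \
    --receptors receptors.txt --terminals terminals.txt \
    --kmin 4 --kmax 8 --suboptimal 2 --out out
```

prints

```
{"solutions": 3, "optimal_objective": 2.4285714285714284, "out": "out"}
```

and `out/subgraph_rank0.json` contains

```json
{
  "nodes": ["CCND1", "EGFR", "ERK", "MEK", "MYC", "RAF", "RAS"],
  "root": "EGFR",
  "objective": 2.4285714285714284,
  "total_score": 17.0,
  "rank": 0,
  "converged": true
}
```

The optimal subgraph is the receptor-rooted MAPK cascade
EGFR → RAS → RAF → MEK → ERK → MYC → CCND1: seven nodes with total score
17.0, i.e. an average deregulation of 17/7 ≈ 2.43 per gene.  The flat PI3K
branch and the weaker JUN node are excluded — adding JUN (score 1.9) would
drag the average from 2.429 to 2.363.  Each rank gets a GraphML of the
induced subgraph plus this JSON sidecar; a union summary across the optimal
and suboptimal solutions annotates each node with its occurrence frequency.

The same model is available programmatically:

```python
from deregsub import SubgraphInstance, load_network, load_scores, solve

net = load_network("net.sif")
inst = SubgraphInstance(network=net, score=load_scores("scores.tsv"),
                        receptors=frozenset({"EGFR"}),
                        terminals=frozenset({"CCND1", "GSK3B"}),
                        k_min=4, k_max=8)
sol = solve(inst)          # sol.node_set, sol.root, sol.objective
```

Other entry points: `deregsub benchmark` (planted-subgraph recovery against
the fixed-size comparator), `deregsub scores ...` (trinary-global,
personalized, methylation, consistency, absolute score constructors), and
`deregsub ndg` (survival stratification of per-patient subgraphs).

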