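# speakeasy2

Community detection for signed, weighted biological networks with the
SpeakEasy 2 (Champagne) algorithm, plus the cluster-quality metrics and
an LFR-style benchmark generator needed to validate it end to end.

Biological networks — coexpression modules, protein interaction maps,
cell–cell similarity graphs — are weighted, often signed (correlation
networks), and full of nodes that genuinely belong to more than one
module.  SpeakEasy 2 is a *popularity-corrected label propagation*
algorithm built for exactly this setting: each node repeatedly adopts
the label that is most **specific** to its neighborhood,

    spec(i, ℓ) = obs(i, ℓ) − p_ℓ · s_i,

the observed neighbor support for label ℓ minus the support expected
from ℓ's global popularity p_ℓ (s_i is node strength).  The correction
stops large clusters from swallowing the network simply by being large,
and it handles negative edges naturally — negative neighbor weight
pushes a node away from a label.

Single-node updates alone get stuck, so the dynamics alternate four
stages: **standard** updates (a random 90% of nodes adopt their argmax
label), a **bubble** stage that bursts oversized clusters by dispersing
their least-secure members onto fresh labels, a **nurture** stage that
updates only the worst-fitting nodes so promising proto-clusters
survive, and a **merge** stage that fuses whole label classes whose
cross-linking exceeds the configuration-model expectation
S_a·S_b/(2W).  Ten independent runs each contribute one partition to a
pool; the answer is the pool **medoid** under pairwise NMI — the most
typical partition, not a score optimum.  Nodes whose best and
second-best community scores stay close across the pool are optionally
nominated as multi-community and placed into their top-scoring
communities of the final partition.

The package also implements the evaluation toolkit used around such
algorithms — NMI, ARI, signed modularity Q, modularity density Qds,
omega index, set-based overlapping NMI, overlapping Q/Qds with
belonging coefficients, multi-community sensitivity/specificity/F1 —
and a self-contained LFR-style generator (power-law degrees, community
sizes and weights; mixing parameters μ and μ_w; three cross-linking
regimes; planted overlapping membership), so everything is testable
without downloading data.

## Worked example

```python
from speakeasy2 import (
    BenchmarkSpec, SE2Params, generate_benchmark, preprocess_graph,
    run_se2, nmi, ari, modularity_signed, modularity_density,
)

spec = BenchmarkSpec(n_nodes=2000, avg_degree=30, mu=0.3, seed=11)
inst = generate_benchmark(spec)          # graph + planted truth
g = preprocess_graph(inst.graph)
final, pool = run_se2(g, SE2Params(seed=5))
truth = inst.truth.to_partition()
print(f"communities found: {final.n_communities} (planted: {truth.n_communities})")
print(f"NMI vs planted truth: {nmi(final, truth):.3f}")
print(f"ARI vs planted truth: {ari(final, truth):.3f}")
print(f"modularity Q: {modularity_signed(g, final):.3f}")
print(f"modularity density Qds: {modularity_density(g, final):.3f}")
```

prints

```
communities found: 12 (planted: 13)
NMI vs planted truth: 0.987
ARI vs planted truth: 0.982
modularity Q: 0.730
modularity density Qds: 0.032
```

At 30% cross-linking the recovered partition matches the planted one
almost node for node (NMI/ARI ≈ 0.98; one small planted community is
absorbed, 12 found vs 13 planted).  Q ≈ 0.73 says most edge weight is
intra-community relative to chance; Qds is on its usual much smaller
scale because every community term is discounted by its internal
density.

The same pipeline is available from the shell:

```sh
se2 generate -o bench/ --seed 11 --config bench.yaml   # network + truth
se2 cluster -i bench/network.tsv -o out/ --seed 5 --overlap
se2 evaluate -g bench/network.tsv out/partition.tsv bench/truth.tsv
se2 benchmark -o sweep/ --seed 1 --config grid.yaml    # full grid sweep
```

Every run directory contains a `run_config.json` with the seed and the
complete effective configuration.

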