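# ishc — synchronization-based hierarchical clustering of PPI networks

`ishc` detects protein complexes (densely interacting modules) in
protein–protein interaction (PPI) networks. Biologists working with
interaction maps need to partition thousands of proteins into functional
modules; classical graph clusterers struggle with the small-world,
scale-free structure of these networks. `ishc` instead treats each protein
as a phase oscillator and lets nearby proteins synchronize, so clusters of
arbitrary number, shape and size emerge from the dynamics, with natural
outlier handling (isolated proteins never synchronize with anyone).

## The method

1. **Spectral embedding.** The interaction graph is condensed into an n×3
   coordinate matrix *X*. An edge-similarity matrix mixes the aggregation
   coefficient of each edge with its weighted counterpart,

   A<sub>ij</sub> = η (|N<sub>i</sub> ∩ N<sub>j</sub>| + 1) / min(|N<sub>i</sub>|, |N<sub>j</sub>|)
   + (1 − η) (Σ<sub>k∈I<sub>ij</sub></sub> w(i,k) · Σ<sub>k∈I<sub>ij</sub></sub> w(j,k)) /
   (Σ<sub>s∈N<sub>i</sub></sub> w(i,s) · Σ<sub>t∈N<sub>j</sub></sub> w(j,t)),

   is symmetrically degree-normalized, L = D<sup>−1/2</sup> A D<sup>−1/2</sup>,
   and the eigenvectors of L's three largest eigenvalues become the columns
   of *X* (rows scaled to unit norm).

2. **Synchronization clustering (SHC).** Objects within radius ε couple via
   the Kuramoto-style update
   x(t+1) = x(t) + (1/|N<sub>ε</sub>(x)|) Σ<sub>y∈N<sub>ε</sub>(x)</sub> sin(y(t) − x(t)).
   An *ε-neighborhood closure* — a set whose members' closed ε-neighborhoods
   all equal the set itself — is guaranteed to synchronize fully, so it is
   declared a cluster immediately, skipping the expensive run to coordinate
   coincidence. The loop alternates closure detection with one coupling step
   until every object is assigned.

3. **Firefly optimization of ε.** The clustering quality at radius ε is the
   weighted modularity
   fval = Σ<sub>H</sub> [2m<sub>H</sub>/(2m<sub>H</sub>+n<sub>H</sub>)]<sup>ρ</sup> · [w<sub>in</sub>(H)/w<sub>tot</sub>(H)]<sup>1−ρ</sup>,
   summed over clusters H (m internal edges, n boundary edges, w the
   weighted analogues). A swarm of candidate radii ("fireflies") moves
   toward brighter (higher-fval) candidates with attractiveness
   β₀ e<sup>−γr²</sup> plus an α-scaled random perturbation, replacing the
   slow hierarchical scan over radii.

Defaults: η = 0.5, ρ = 0.8, β₀ = 1, γ = 1, α = 0.9, 6 fireflies, 30
iterations. Evaluation against a reference complex catalogue uses
maximum-matching precision/recall and their harmonic mean (f-measure).

## Worked example

Generate a planted-module network (3 modules of 8 proteins, within-module
edge probability 0.9, between-module 0.02), cluster it, and score the
result against the planted ground truth:

```sh
ishc simulate --modules 3x8 --p-in 0.9 --p-out 0.02 --seed 1 -o data
ishc cluster --edges data/edges.tsv --seed 1 -o out
ishc evaluate --pred out/clusters.tsv --ref data/complexes.tsv --edges data/edges.tsv
```

prints

```
wrote data/edges.tsv (24 nodes, 77 edges)
INFO ishc: best eps=0.729724 objective=2.88262 clusters=3
precision	1.000000
recall	1.000000
f_measure	1.000000
fval	2.882619
```

The firefly search settled on synchronization radius ε ≈ 0.73, which yields
exactly 3 clusters with modularity fval ≈ 2.88 (each of the three modules
contributes close to its maximum of 1). Precision and recall of 1.0 mean
every cluster coincides exactly with a planted module. `out/manifest.json`
records all parameters, the seed and the chosen radius, and is sufficient
to reproduce the run; reruns with the same seed are byte-identical.

A YAML config can replace the flags (`ishc cluster --config run.yaml`);
flags win on conflict. `ishc embed` dumps the n×3 embedding,
`--optimizer grid` switches to the hierarchical radius scan baseline.

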