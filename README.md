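# umistates

Partition the cells of a UMI-based scRNA-seq dataset into subsets whose gene
expression states are **statistically indistinguishable** — the finest
clustering of the raw counts that is still supported by the data, with the
number of clusters determined by the data itself.

## Who this is for

Anyone analysing raw UMI count matrices who wants clusters with a concrete
probabilistic meaning instead of the usual normalise / reduce / cluster
pipeline: each inferred *cellstate* is a group of cells whose counts are
consistent with one shared vector of transcription quotients, up to
multinomial sampling noise. Typical uses: finding substructure inside
annotated cell types, and collapsing a dataset into deeply-sampled
pseudo-cells without discarding any real structure.

## The model

Conditioned on its total UMI count `N_c`, the counts of cell `c` are a
multinomial sample of its gene expression state (GES), a probability vector
`α⃗` over genes:

    n⃗_c | α⃗, N_c  ~  Multinomial(α⃗, N_c)

For a partition `ρ` of cells into clusters `s` with shared states, the
cluster-aggregated counts `n_gs` are again multinomial. Marginalising each
cluster's unknown `α⃗_s` against a Dirichlet prior with concentrations
`θ_g = θ·π_g` gives the closed-form marginal

    log P(n⃗_s | Θ) = lnΓ(θ) − lnΓ(θ + N_s) + Σ_g [lnΓ(θ_g + n_gs) − lnΓ(θ_g)]

(up to partition-independent multinomial coefficients, which are dropped).
The posterior over partitions is proportional to the product of these terms
over clusters; `umistates` maximises it jointly over the partition and the
scalar prior strength `θ` with a random-uphill MCMC over single-cell moves,
deterministic refinement, and best-of-`n` restarts.

The toolbox around the optimum: hierarchical merging of cellstates by
likelihood-ratio similarity into a binary tree (with Newick export),
per-gene differential-expression scores across any tree branch, overlap-based
marker-gene scores, homogeneity/completeness evaluation, diversity
statistics, a multinomial simulator with known ground truth, breakpoints,
and incremental partitioning of new cells.

## Worked example

```python
from umistates import PartitionModel, simulate

truth = simulate.sample_ground_truth(rng=0)       # 30 states, 800 cells
counts, generating = simulate.sample_counts(truth, rng=0)
res = PartitionModel(counts).fit(seed=11, n_runs=1)
print(res.summary())
rep = res.compare(generating)
print(f"homogeneity={rep.homogeneity:.4f} completeness={rep.completeness:.4f}")
```

prints (abridged):

```
Partition of UMI counts into gene expression states
=======================================================
cells                          800
genes                          924
cellstates                      29
singlets                         3
singlet fraction            0.0038
abundance entropy           2.8494
prior strength theta          1003
log-likelihood*       -11290566.785
...
homogeneity=1.0000 completeness=1.0000
```

29 of the 30 ground-truth states were realised in this draw, and the search
recovers the generating partition exactly: every cluster is pure
(homogeneity 1) and every true state lands in one cluster (completeness 1).
The fitted prior strength θ≈1000 matches the concentration the states were
drawn with. Downstream:

```python
tree = res.merge_tree()                  # binary tree over the 29 cellstates
coarse = res.cut(8)                      # 8 higher-order clusters
top = res.branch_de_scores(tree.root)    # genes driving the deepest split
markers = res.branch_marker_scores(tree.root)
```

A command-line interface mirrors the library
(`umistates simulate | run | hierarchy | de | markers | evaluate |
incremental`); every run writes a manifest with its seed, configuration and
input checksum so results are bit-reproducible.

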