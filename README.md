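# moses-seeds

Disease gene prediction from **warm and cold seeds** on the human
protein–protein interactome.

Most network-based gene prioritization methods rank candidates by proximity
to the known disease genes. This package implements the opposite-and-
complementary idea: for a disease with known genes (*warm seeds*, set S₀,
P = |S₀|), it first constructs a contrast class of *cold seeds* — genes that
are simultaneously far from the warm seeds on the interactome and involved
in none of their enriched biological functions — and then lets a clustering
of binary functional profiles separate "disease-like" from "cold-like"
genes. The genes that land with the warm seeds in every annotation database
are the predicted (putative) disease genes, PG.

It is written for computational biologists studying disease modules on
interactomes: the inputs are a plain-text edge list, GMT gene-set files
(GO-BP, KEGG, miRTarBase, …) and a disease gene list; the outputs are TSV
tables and gene lists.

## The algorithm

Three sequential phases per disease, per annotation database *i*:

1. **Warm-seed characterization.** Over-representation of S₀ in every term
   of database *i* by the exact hypergeometric upper tail
   P(X ≥ k), X ~ Hypergeom(N_bg, K, n), with Benjamini–Hochberg FDR across
   the database's terms. The Mᵢ terms with q < α (default α = 0.05) are the
   warm terms; only databases with Mᵢ ≥ 2 are retained.
2. **Cold-seed identification.** Starting from S = S₀ and NS = I ∖ S₀, whole
   first-neighbour layers are absorbed into S until P/|NS| ≥ 10⁻¹; the
   remaining NS are the *peripheral genes*. Peripheral genes annotated to any
   warm term of any retained database are discarded; the survivors are the
   cold seeds, which are then characterized by their top-Mᵢ enrichment terms
   (overlap ≥ 1, smallest p) per database.
3. **Adaptive clustering and integration.** The 2Mᵢ warm+cold terms (set J)
   define a binary G_J × 2Mᵢ membership matrix over all interactome genes
   annotated to ≥ 1 term of J. k-means under the Hamming distance (binary
   majority-vote centroids, k-means++-style seeding, 50 replicates) is run
   for k = 2, 3, …: with f(k) the largest fraction of in-matrix disease
   genes in one cluster, the loop continues while f(k) ≥ 90% and stops at
   the first k with 60% < f(k) < 90%, selecting that cluster C*ᵢ (at k = 2 a
   fraction ≥ 60% is accepted directly). The putative genes are
   PG = (∩ᵢ C*ᵢ) ∖ S₀.

Validation machinery ships with the tool: 10-fold cross-validation of
held-out warm-seed recovery against a random walk with restart baseline
(r = 0.7, scores p ← (1−r)Wp + r·p₀, cut at top |PG|) with a paired t-test,
and disease-module significance — the largest connected component (LCC) of
S₀ ∪ PG against the 95th percentile of LCCs of 1000 random same-size
modules.

A synthetic benchmark generator plants a dense module with matching
annotation databases in a random interactome, so every stage is testable
offline (see `docs/methods.md` for what it does and does not emulate).

## Worked example

```python
from moses import (BenchmarkSpec, RunConfig, generate_benchmark,
                   module_stats, recovery_report, run_moses)

net, dbs, disease, truth = generate_benchmark(BenchmarkSpec(rng_seed=7))
print(f"interactome: {net.n_genes} genes, {net.n_edges} edges")

result = run_moses(disease, net, dbs, RunConfig(rng_seed=7))
for name, sel in sorted(result.selections.items()):
    print(f"{name}: M={result.m_by_db[name]}, k_max={sel.k_max}, "
          f"q={sel.q:.3f}, |C*|={len(sel.members)}")
print(f"intersection: {len(result.intersection)} genes "
      f"({len(result.known)} known, {len(result.putative)} putative)")

rep = recovery_report(result, truth)
print(f"hidden-gene recall: {rep.recall:.3f}, precision: {rep.precision:.3f}")

stats = module_stats(net, set(disease.genes), set(result.putative),
                     reps=1000, rng_seed=7)
print(f"|LCC_WS| = {stats.lcc_ws}, |LCC_WS+PG| = {stats.lcc_ws_pg}, "
      f"null 95th percentile = {stats.threshold}, significant = {stats.significant}")
```

prints

```
interactome: 2000 genes, 12458 edges
DB1: M=16, k_max=3, q=0.833, |C*|=51
DB2: M=16, k_max=3, q=0.867, |C*|=52
intersection: 51 genes (25 known, 26 putative)
hidden-gene recall: 0.867, precision: 1.000
|LCC_WS| = 30, |LCC_WS+PG| = 56, null 95th percentile = 39, significant = True
```

Reading: both synthetic databases kept M = 16 significant warm terms; the
adaptive loop stopped at k_max = 3 with 83–87% of the in-matrix disease
genes in one cluster; intersecting the two optimal clusters left 51 genes,
of which 26 are new predictions. Those predictions recover 26/30 of the
module genes that were hidden from the algorithm, and extending the
known-gene module with them grows its largest connected component from 30
to 56 genes — well beyond the 39-gene 95th-percentile threshold of random
same-size modules, so the predicted module is significantly more connected
than chance.

The same pipeline runs from the shell on real data:

```bash
moses simulate --seed 7 --out demo/                 # or bring your own files
moses run --network demo/edges.tsv --node-list demo/nodes.txt \
          --disease demo/disease.txt --gmt demo/DB1.gmt --gmt demo/DB2.gmt \
          --seed 7 --out demo/run/
moses validate ... ; moses module-stats ...         # CV and LCC analyses
```

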