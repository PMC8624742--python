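# Methods

This note documents the model behind the pipeline, the defaults and the
numerical conventions, the design decisions that were genuinely open, and
what the synthetic benchmark does and does not establish.

## Model and assumptions

The pipeline rests on the disease-module view of the interactome: genes of
one disease tend to interact and to cluster in a connected, functionally
coherent neighbourhood. Rather than ranking candidates by proximity to the
known disease genes alone, it builds an explicit contrast class — the cold
seeds — and asks a clustering of binary functional profiles to separate the
two. The assumptions that matter:

* **Warm seeds are functionally coherent.** At least two terms per
  annotation database must be over-represented in S₀ (the M ≥ 2 gate), and
  at least `min_databases` databases (default 2) must pass it, otherwise
  the disease is reported as not analysable with the given annotations.
* **Topological and functional distance are both informative.** Cold seeds
  must survive the neighbour-absorption expansion *and* carry none of the
  warm terms. Either filter alone is insufficient: the expansion remainder
  still contains genes in disease-related functions, which the functional
  filter removes.
* **The optimal cluster is meaningful only inside the band.** A cluster
  holding ≥ 90% of the disease genes is suspected of being still too coarse
  (at small k almost everything annotated to warm terms sits together); one
  holding ≤ 60% means the disease genes do not cohere in profile space.
  The adaptive loop therefore accepts the first k whose top fraction f(k)
  falls strictly inside (60%, 90%) — with the one concession that at k = 2
  a fraction ≥ 60% is accepted as is. After a first drop below the band
  the loop does not search further: a split that scatters the disease
  genes is evidence against profile coherence, not a reason to try more
  clusters.

Genes are identified by their symbol string after case normalization
(uppercase by default); no identifier mapping is attempted. Warm seeds
absent from the interactome are dropped for the topology phase (P in the
stopping ratio counts only seeds in the network) but still count in the
enrichment query wherever the database annotates them within the
background.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `alpha` | 0.05 | FDR threshold on BH-adjusted q-values; `use_adjusted=False` switches to raw p |
| `stop_ratio` | 0.1 | expansion stops once P/\|NS\| ≥ stop_ratio; dimensionless |
| `band_low`, `band_high` | 0.6, 0.9 | acceptance band for f(k) |
| `replicates` | 50 | k-means restarts per k |
| `kmeans_max_iter` | 100 | iteration cap per replicate; convergence is assignment stability |
| `k_cap` | 20 | largest k tried; selected k_max is typically 3–5, so 20 is generous |
| `min_databases` | 2 | databases required for the integration step |
| `rwr_restart` | 0.7 | restart probability of the random-walk baseline |
| `rwr_tol`, `rwr_max_iter` | 1e-6, 1000 | L1 convergence of the power iteration |
| `rng_seed` | 0 | drives k-means seeding, CV folds and the permutation null |

The enrichment background for a database is the set of interactome genes
annotated in that database — the standard over-representation universe,
which keeps N_bg database-specific.

## Numerical conventions

* **Hypergeometric tail** is exact (`scipy.stats.hypergeom.sf`), never a
  normal approximation. Ties in p are broken by q, then term id, so top-M
  selection is total and deterministic.
* **Hamming k-means**: distance is the per-column mismatch fraction;
  centroids are binary, updated by per-column majority vote with exact ties
  resolved to 1 (any fixed rule works; this one makes reruns bit-exact).
  Seeding is k-means++ adapted to the metric (squared Hamming distance
  weights). Empty clusters are re-seeded with the row farthest from its
  centroid. The replicate with the lowest total within-cluster distance
  wins; equal objectives keep the lowest replicate index. The objective is
  non-increasing across iterations except immediately after a re-seed.
* **f(k) ties** across clusters: more disease genes, then smaller cluster,
  then lowest label.
* **RWR**: W is the column-normalized adjacency; mass on degree-zero nodes
  is redistributed to the restart vector, keeping scores summing to one.
  Top-n cuts exclude the training seeds and break score ties by gene id.
* **Paired t-test**: textbook mean-over-standard-error with n − 1 degrees
  of freedom, two-sided. Zero-variance differences are degenerate and
  flagged (t = 0, p = 1 if the mean is zero, else signed infinity, p = 0)
  rather than silently propagated.
* **LCC**: genes absent from the network count as singletons; equal-size
  components tie-break to the one containing the lowest gene id.
* **Permutation null**: the 95th percentile uses the nearest-rank
  convention on the sorted draws, and "significant" means *strictly*
  exceeding it. On small discrete LCC distributions heavy ties make this
  conservative: the empirical false-positive rate of the flag is 1–5%
  rather than exactly 5%.
* **Degenerate inputs**: an empty enrichment query, a warm-seed set
  disjoint from the network, or fewer annotated terms than M all raise
  immediately with the phase name; a clustering failure is returned as a
  diagnosed no-cluster outcome so a disease is reported, never silently
  dropped.

## The synthetic benchmark

`BenchmarkSpec` plants a module of m = 60 genes (internal edge probability
0.30) in a 2000-gene Erdős–Rényi interactome of mean degree ~12 (real
interactomes are denser still, and scale-free; the algorithm nowhere
depends on the degree distribution, so the simpler background is used, with
a preferential-attachment mode available). Half of the module is revealed
as warm seeds; the hidden half is the recovery ground truth.

Annotations model two features of real databases:

* **Annotation depth is a gene property.** Each gene has an intrinsic
  propensity shared by all databases — a fixed minority of the module
  (8/60 genes, propensity U(0.18, 0.30)) is poorly annotated everywhere,
  the rest follows a mild gradient (U(0.85, 1.0)). This mirrors literature
  bias: an understudied gene is under-annotated in every database at once.
  Without it, module profiles are exchangeable Bernoulli draws and the
  disease genes form a single indivisible blob that no k splits into the
  acceptance band — a regime real data does not exhibit.
* **Cold structure exists where the method looks for it.** "Far" genes
  hosting the cold terms are the peripheral set produced by the same
  neighbour-absorption rule the pipeline uses.

Each database carries 16 disease terms (module genes annotated with
probability 0.9 × propensity, others 0.02 × propensity), 16 cold terms
(same probabilities over far vs non-far genes) and 12 neutral terms
(probability 0.03 × propensity, everywhere). The warm/hidden reveal is
stratified over the two depth classes so that benchmark difficulty is
stable across seeds. Setting `module_edge_p = background_edge_p` yields an
exact null instance: module-internal pairs are rewired to carry exactly
that probability, so the "module" is topologically nothing special.

**What passing tests show — and do not.** On this benchmark the pipeline
recovers 80–87% of hidden module genes with precision ≈ 1, and the
predicted module's LCC beats the random null in essentially every
instance; under the null the significance flag stays at its nominal rate.
This validates the machinery — every phase, their interaction, and the
statistics — under conditions where the method's assumptions hold by
construction. It does not certify performance on real interactomes, where
annotation noise is structured rather than Bernoulli, databases are
mutually redundant, modules overlap, and the interactome itself is biased
toward well-studied genes.

## Open design choices

* FDR procedure: Benjamini–Hochberg step-up (the field default);
  significance is tested on adjusted values, with a raw-p mode exposed.
* Functional exclusion of cold seeds pools the warm terms of *all*
  retained databases (a single cold-seed set per disease).
* Disconnected components containing no warm seed are peripheral by
  definition (infinite distance); if expansion exhausts the warm
  component before the stopping ratio is reached, the remainder is
  returned with a `disconnected_remainder` flag.
* In cross-validation the RWR ranking excludes the training seeds before
  the top-|PG| cut (standard practice; switchable).
* Folds where the pipeline fails are recorded with a missing recovery and
  excluded from the pairing, with the count reported — never imputed.

## Known limitations

* The adaptive-k loop stops at the first fraction below the band; it never
  revisits larger k, and a disease whose genes split 50/50 in profile
  space at k = 2 is reported as failed (by design — but it means some
  diseases get no prediction).
* Putative-gene counts are sensitive to the number of databases: each
  additional database intersects the cluster sets and can only shrink PG.
* No ontology-graph handling: GO-style annotations are used exactly as
  given (no upward propagation), and record filtering covers only the
  IPI-evidence and NOT-qualifier rules.
* The expansion's peripheral set can be small on dense networks (the last
  shell before the stopping ratio may be thin); the cold-seed enrichment
  then has little material and the run is reported as failed for that
  disease.
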