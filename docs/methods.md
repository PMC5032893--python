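# Methods

## Model and assumptions

The package treats two independently collected descriptions of the same
population as partitions of a common unit set and asks where they agree:

* a **register side** — every area (parish or parish group) has a surname
  composition; pairwise isonymy `eta_ij = Σ_s n_si n_sj / (2 n_i n_j)`
  summarises compositional similarity. The statistic is bounded by 0.5
  (Cauchy–Schwarz on the count vectors), with equality exactly when both
  areas carry a single, identical surname, and 0 when no name is shared.
  Isonymy proxies relatedness only where surnames are hereditary, regionally
  variant, and migration is limited; the package takes this as given.
* a **sample side** — individuals carry a genetic-cluster label at each
  granularity level l. Cluster assignment is an *input*: the package never
  estimates co-ancestry from DNA. Assignments at different levels are not
  assumed nested (real probabilistic assignment procedures need not nest),
  even though the synthetic generator happens to produce nested ones.

The areas' isonymy taxonomy is assumed to be a meaningful hierarchy: the
regionalisation only ever merges groups that descend from a common parent, so
errors in the deep structure of the dendrogram cannot be undone downstream.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `min_pop` | 750 | minimum grouped-area population; groups below it merge with their nearest neighbour |
| `ward_dialect` | `"D"` | Lance–Williams recurrence on distances as given (`"D"`) or on squares (`"D2"`, the scipy/ward.D2 convention) |
| `zero_policy` | `"floor"` | zero isonymy becomes half the smallest positive off-diagonal entry before the log, keeping distances finite and order-preserving |
| `ari_threshold` | 0.15 | minimum peak agreement accepted as a regionalisation start; intrinsically a judgement call, exposed rather than hidden |
| `inflation_factor` | 1.1 | KDE bandwidth = factor × 95th percentile of within-group nearest-neighbour distances ("slightly wider" than typical spacing) |
| `require_four` | False | drop individuals with fewer than four located grandparents instead of applying the modal rule to the available ones |
| `dom_expectation` | `"uniform"` | chance expectation of Dominance is 1/L (clusters counted in the full table); `"margins"` (Σ (n_l/n)²) exists as an alternative but the uniform form is the method's definition |

Weighted Ward: cluster masses in the recurrence are summed area populations
(leaf mass = population), so populous areas anchor their clusters. Merge ties
break on the smallest node-index pair; the tree is deterministic.

## The synthetic world

`generate_world` emulates the study conditions the pipeline targets:

* **geography** — R = 5 contiguous regions of 12 parishes on a planar lattice
  with 70 km spacing (each region ≈ 280 × 210 km, a Great-Britain-like scale);
  populations log-normal (median ≈ 1 100).
* **surnames** — each region has a private pool of 60 names and shares a
  common pool of 40; bearer counts are multinomial with probability φ = 0.8 on
  the private pool and Zipf(1.07)-ranked frequencies within pools, mirroring
  the heavy tail of real surname distributions. φ and the Zipf exponent are
  artifact choices — no quantitative concentration model exists to copy — and
  are exposed as parameters.
* **sample** — 2 000 volunteers; ancestral locations drawn with mildly uneven
  per-region weights (2:1 across the map, echoing consent/recruitment-site
  skew); four grandparents drawn uniformly from areas within an 80 km radius
  of the ancestral location (uniform, not distance-decayed: the simplest
  model satisfying the recruitment rule). Genetic labels follow the *modal
  grandparent region* — genetics descends from the grandparents, not from the
  ancestral point — flipped to a uniformly random other cluster with
  probability ε = 0.02; coarser levels are deterministic coarsenings along
  the planted region hierarchy (a left-to-right chain).

What this does **not** emulate: temporal surname evolution and migration,
distance-decayed ancestry, non-nested cluster assignments, irregular area
geometries, and any resemblance to actual British geography. Passing tests
therefore show the *procedure* is correct and recoverable under controlled
noise — not that any particular real-world regionalisation is right.

With these defaults ~7–10% of individuals get a tied modal group at k = 5 and
the (l, k) agreement grid tops out near 0.8 at the planted combination —
comfortably away from both the trivial (agreement ≈ 1, nothing to test) and
the hopeless (agreement ≈ 0) regimes.

## Numerical and design choices

* **Adjusted Rand** is computed in the contingency-table form with exact
  integer pair counts; the degenerate case (both partitions trivial, zero
  denominator) returns 1. Brute-force pair enumeration and
  `sklearn.metrics.adjusted_rand_score` serve as independent oracles in tests.
* **Peaks** of the agreement grid are strict local maxima of the per-k best-l
  profile; plateau runs count once, at their smallest k; boundary ks compare
  against their single neighbour; a `min_prominence` margin can suppress
  shallow bumps (default 0: the flat tail of a declining profile genuinely
  carries small peaks, and the regionalisation is designed to start from
  disaggregate points and merge down).
* **Degenerate adjustments**: when an index's chance expectation equals its
  maximum (a single region, or a single cluster), the adjusted value is
  defined as 0 with a warning. A sample carrying one cluster at the chosen
  level makes every merger accept — homogeneity is vacuous everywhere, and
  the coarsest description is the only one not overfitted.
* **Negative adjusted components clamp to 0** before the RI product, so two
  below-chance indices cannot multiply into spurious positive integrity.
* **Merge schedule**: the loop visits every taxonomy cut below the start in
  decreasing-k order. The agreement peaks are thereby reached in decreasing
  order, while the intermediate dendrogram levels keep each proposal to one
  parent's worth of sub-regions; skipping directly between distant peak
  levels proved to collapse several hierarchy levels into single proposals
  and over-merge. The loop terminates when a level changes nothing, when one
  region remains, or when the coarsest level has been visited — at most
  k_start − 1 iterations.
* **Keep-best-merge-rest** applies unconditionally when a merger is refused
  and ≥ 2 non-best sub-regions remain; with exactly two sub-regions it
  degenerates to a logged no-op. The merged "rest" need not be a dendrogram
  node but always stays within one parent; if a later, finer schedule level
  would split such a composite across parents, the composite simply sits that
  level out.
* **Empty regions** (no linked individuals — possible under extreme sampling
  skew) are absorbed into their taxonomy-nearest sibling before the main
  loop, loudly flagged in the log.
* **Determinism**: one seed fans out to named substreams (simulation,
  tie-breaking); identical config + seed reproduces every artifact
  byte-for-byte. The regionalisation itself consumes no randomness.

## Scale of the shipped checks

The test suite and the acceptance script run at desk scale, sizes chosen so
the full suite completes in a couple of minutes on one core: property suites
at 10⁴ random count tables (isonymy bound), 200 random partition pairs of
n ≤ 60 (pair-counting oracle), 2 000 permutations (index nulls), 2 000
partition pairs (Rand null); parameter recovery over 20 seeded worlds at the
default study conditions. The per-seed recovery run (60 areas, 2 000
individuals, a 4 × 9 agreement grid) takes well under a second.

## Known limitations

* The 2-km/125 000-inhabitant "rural" rule is consumed as a pre-encoded flag;
  no gazetteer or geometry is re-derived.
* Grandparent points map to areas by nearest centroid, not polygon
  containment.
* No bootstrap/confidence machinery for RI; the indices are point estimates.
* Ward on a −log-isonymy matrix is a dialect choice, not a uniquely correct
  one; both common dialects are implemented and cross-checked against
  independent references, but results can differ between them on real data.
* With small per-region samples, Distinctiveness systematically penalises
  sparsely sampled regions; the merge algorithm exploits this deliberately
  (sparse regions merge), which is a feature under the method's logic but
  means RI values are not comparable across samples of different size.
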