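# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `barcodekit`, stage by stage.

## Stranding-record summaries (`records`)

A stranding table is long-format: one row per (taxon, year) with a count, a
taxonomic rank (`species`, `genus_or_higher`, `unknown`) and a broad group
(cetacean / pinniped / unknown). Conventions:

* *Undetermined* sums every row whose rank is not `species` — including the
  fully `unknown` rows. This is what makes the bundled Brittany table's
  arithmetic close (258 undetermined of 1530 total).
* *Species richness* counts a species in a year iff its count that year is
  positive (presence, not abundance).
* The undetermined percentage is **truncated** (not rounded) to one
  decimal, matching the convention of the source monitoring tables
  (258/1530 = 16.86% → printed 16.8%).

## Distances (`distances`)

Kimura's two-parameter model distinguishes transition (A↔G, C↔T) and
transversion substitutions. With proportions *P* and *Q* over the compared
sites of a pair,

    d = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q))   [substitutions/site]

* **Pairwise deletion**: a site enters a pair's comparison only when both
  sequences carry a plain A/C/G/T there. Gaps, N and all other IUPAC
  ambiguity codes are missing data. This matches the default behaviour of
  the standard barcode-analysis tools and keeps heavily truncated query
  sequences usable.
* **Saturation**: when `1 − 2P − Q ≤ 0` or `1 − 2Q ≤ 0` the distance is
  UNDEFINED and carried as NaN plus an explicit pair list
  (`DistanceMatrix.undefined_pairs`). A silent cap would corrupt
  nearest-neighbour searches, so there is none.
* Distances are stored in substitutions/site and converted to percent only
  in reports.

**NN identification** (`identify_query`) operationalizes a
barcode-identification engine as: nearest reference species by minimal K2P
distance; `ASSIGNED` iff that distance is ≤ `threshold` (default 2.0%) and
the runner-up species is farther by more than `tie_epsilon` (default
0.05%); `AMBIGUOUS` on a tie or when the best species belongs to a declared
low-divergence complex (default: the Delphininae, whose members cannot be
separated at COI); `NO_MATCH` beyond the threshold or when fewer than
`min_overlap` (default 100) sites are comparable with every reference. The
threshold, margin and complex list are explicit parameters because no
published engine documents its internal rule; the defaults reflect the
classical ~2% barcode threshold.

## Neighbour-Joining (`njtree`)

Standard Saitou–Nei agglomeration with the Studier–Keppler Q criterion.
Determinism and robustness choices:

* The Q matrix is symmetrized with `min(Q, Qᵀ)` before the argmin — float
  non-associativity otherwise makes `Q[i,j]` and `Q[j,i]` differ by 1 ulp
  and can hide the tie-break.
* Ties are broken by the lexicographically smallest (sorted) pair of
  cluster keys, a cluster's key being the smallest leaf label it contains.
  Output is therefore invariant to input order.
* Negative branch lengths (an NJ artefact on non-additive input) are
  clamped to zero with the deficit transferred to the sibling branch and a
  flag (`clamped_branches`) on the tree.
* No bootstrap: the tree is a visualization/exclusivity device here, not a
  phylogenetic inference.

`species_cluster_check` calls a species *exclusive* iff some edge
bipartition of the unrooted tree separates exactly that species' leaves.

## nMDS + LDA (`ordination`)

Kruskal non-metric MDS minimizing stress-1,

    stress-1 = sqrt( Σ (d̂_ij − d_ij)² / Σ d_ij² ),

where d are embedded Euclidean distances and d̂ the disparities from
isotonic (PAVA) regression of d on the input-distance order. Optimization
alternates the isotonic fit with a Guttman (SMACOF) majorization step;
disparities are rescaled to a fixed norm before each Guttman step to
prevent configuration shrinkage (stress-1 is invariant to that rescaling,
so the reported trace is unaffected).

* **Ties**: Kruskal's *primary* (weak) approach — within a block of equal
  input distances the disparities are unconstrained (implemented by sorting
  tie blocks by current embedded distance before PAVA). A consequence worth
  knowing: an all-tied input (e.g. four equidistant points) is fitted
  perfectly by *any* configuration, so its stress is 0. The secondary
  approach would report positive stress there; the primary approach is the
  common default and is what this package uses.
* **Restarts**: `n_restarts` (default 20) runs; the first is initialized
  from classical scaling (Torgerson PCoA) — which alone recovers planted
  metric configurations essentially exactly — the rest from seeded Gaussian
  starts. Best final stress wins. Convergence: stress-1 improvement below
  `tol` (default 1e-9); `converged=False` is reported, never raised.
* **k = 2** by default (the assignment plots are 2-D); configurable.

LDA: Gaussian classifier with pooled within-class covariance (dof = N − C)
and **equal priors** — reference panel sizes are sampling artefacts, not
prevalences. A singular/ill-conditioned pooled covariance receives a ridge
jitter of 1e-8 (flagged). References and queries are embedded **jointly**
in one nMDS; the LDA is then fitted on reference coordinates only, and
posteriors are reported for references (self-classification) and queries
alike. `assign_delphininae` wires distance matrix → nMDS → LDA and reports
stress, self-assignment rate and per-query posteriors.

## Intraspecific analysis (`popgen`)

* **Haplotype collapsing**: complete sequences group by identity; a
  sequence with missing data merges into a complete haplotype only when
  compatible with exactly one, otherwise it stays separate and is flagged.
* **Diversity**: h = n/(n−1)(1 − Σ pᵢ²); π is the mean pairwise per-site
  difference over all sequence pairs with pairwise deletion and **no
  multiple-hit correction** — the convention of the standard polymorphism
  software, and the scale (~1e-3) on which intraspecific mtDNA diversity is
  conventionally reported. π is computed from the underlying sequences, so
  it equals the mean pairwise p-distance of the `distances` module exactly.
* **Median-joining network**: Bandelt-style. (1) the ε-relaxed minimum
  spanning network — at ε = 0 exactly the union of all minimum spanning
  trees (a link is kept iff its endpoints are not connected by strictly
  shorter links); (2) for every node triple with ≥ 2 links in the MSN,
  the majority-consensus median vector is a candidate; all candidates
  within ε of the cheapest connection cost are added; (3) iterate to a
  fixpoint; (4) prune: keep only nodes and edges lying on some
  shortest connection between observed haplotypes. All tie-breaks
  (including median sites where all three states differ) are lexicographic
  on node labels, so the network is deterministic. Indels and ambiguity
  codes are missing data, not a fifth state. Zero-distance nodes (possible
  after ambiguous-merge flagging) are merged for network purposes and
  recorded in `merged_into`.
* **Haplogroups**: cut every edge with ≥ `min_cut_mutations` (default 2)
  mutations; components containing observed haplotypes become groups. The
  cut rule is an explicit operationalization of the visual grouping used in
  haplotype-network figures and is exposed as a flag.

**Known limitation.** The MST-containment property of the ε=0 network (its
subdivided edges realize every MST edge of the observed haplotypes as an
equal-length path) holds in the low-homoplasy regime where haplotype
networks are meaningful — few mutations spread over hundreds of sites, as
in real mtDNA data (e.g. 8 segregating sites in a 610-bp porpoise
alignment). Under heavy homoplasy (short, fast-evolving simulated
sequences) median chains can legitimately replace a direct link with a
longer path; this is inherent to median-joining, not an implementation
artefact. Tests therefore draw network instances from random
perfect-phylogeny genealogies.

## Synthetic data (`simulate`)

The generator deliberately matches the model the estimator assumes: a
per-site independent K2P substitution process (closed-form site transition
probabilities; transition/transversion rate ratio `kappa`, default 4 for a
COI-like, 8 for a control-region-like bias; no rate heterogeneity, no codon
structure), so realized K2P estimates are consistent for the planted
divergences.

* **Species**: star phylogeny; species *i* sits at branch `d_i/2` from a
  random root with `d_i` drawn from the configured interspecific range, so
  each pairwise expected divergence `(d_i+d_j)/2` stays inside the range.
* **Individuals**: star genealogy at `theta/2` from the species ancestor →
  expected pairwise intraspecific divergence `theta`. A coalescent tree is
  deliberately not simulated; the star is the simplest structure meeting
  the pairwise targets.
* **Default regimes** mirror the marine-mammal barcode setting:
  reference libraries at 5–17% interspecific / 0.3–0.5% intraspecific
  divergence over ~600 bp; `delphininae_mimic_config()` gives a 3-species
  complex at 1.5–3% (control-region regime, where nMDS+LDA succeeds) or
  0.8–1.5% (COI regime, where NN identification is inherently ambiguous);
  `simulate_two_haplogroups` plants two centroids ≥ 3 mutations apart with
  satellites ≤ 1 private mutation away, the structure under which the
  haplogroup cut rule provably recovers the planted bipartition.
* Divergence targets ≥ 0.7 substitutions/site are rejected up front as
  saturated for the K2P process.
* Everything is reproducible bit-for-bit from the seed.
* **What the generator does not emulate**: rate heterogeneity across sites,
  codon structure and selection, intraspecific coalescent genealogies,
  alignment error, heteroplasmy and nuclear mitochondrial copies. Passing
  tests demonstrate correctness of the estimators and engines under their
  own model assumptions and planted truth; they do not certify performance
  on real data where those assumptions are violated.

## Problem sizes used in tests and the acceptance script

Chosen once as realistic desk-scale workloads: 100 random 10-sequence sets
(250 bp) for the K2P oracle comparison; 200 random additive matrices of
4–12 taxa for NJ; 5 seeded 6-species libraries × 100 queries (500 total)
for NN identification; one 30-reference / 200-query complex for nMDS+LDA
(3 restarts there; the library default is 20); exhaustive haplotype spectra
for n ≤ 8; 100 seeded two-haplogroup samples (n = 20, 400 bp) for
haplogroup recovery; 5 planted 2-D configurations (8–14 points, 4 restarts)
for nMDS recovery.
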