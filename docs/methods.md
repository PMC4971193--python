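# Methods

This note records the models, conventions and numerical choices behind
`barcodetree`, in enough detail to judge what its tests do and do not
demonstrate.

## Record filtering

A barcode record passes the quality filter iff it has at least
`min_length` unambiguous A/C/G/T bases (default 501 — "more than
500 bp" read as a strict bound; gaps and IUPAC ambiguity codes do not
count), carries none of the rejected curator flags (matched
case-insensitively; defaults: `error`, `contaminant`, `stop_codon`),
and has at least one forward reading frame free of stop codons under
the invertebrate mitochondrial code (NCBI table 5, stops TAA/TAG).
Rejection reasons are reported in the fixed order length → flag →
stop codon, so a record failing several criteria is counted once,
deterministically. Three design points deserve note:

* Barcode submissions do not record the amplicon's reading frame, so a
  sequence is accepted if *any* forward frame is clean; reverse frames
  are not tested because barcodes are stored 5′→3′ on the coding
  strand.
* Codons containing ambiguity codes never count as stops (an `N` might
  be anything; rejecting on it would punish sequencing quality twice).
* The genetic code is configurable; the invertebrate mitochondrial
  default fits COI in insects.

## Haplotype collapsing and the label codec

"Identical haplotype" means exact string identity (case-insensitive).
Sequences differing only by ambiguity codes are *not* merged: wildcard
matching is order-dependent (an `N`-bearing read may be compatible with
two different haplotypes), so any such merge would make the OTU set
depend on input order. Sequences of unequal length never merge.

OTU labels pack the biology a tree reader needs into a Newick-safe
string: sanitized species name (spaces → `_`, other illegal characters
→ `-`), then one block per collection locality — a 3-letter country
code, a 2-letter state/province code when the country is one of the
seven largest by area, and the number of individuals sharing the
haplotype there. Localities are sorted for determinism. When one
haplotype carries conflicting species names the majority name (ties
alphabetical) is used with a `-cf` marker. The decoder inverts the
grammar by scanning for the first token that is a recognized country
code; everything before it is the species name. Two distinct haplotypes
of one species with identical locality profiles produce identical base
labels, so the batch writers append `.2`, `.3`, … in first-seen order;
the decoder ignores that suffix. Country/region code tables are
user-supplied TSV config; a small built-in table covers the big seven
and common barcode-contributing countries.

## Backbone constraints

Support thresholds follow the curation rule the pipeline is built
around: bootstrap **strictly above** 85 (a node at exactly 85 is
collapsed), posterior probability ≥ 1.0 with a 10⁻⁹ tolerance to absorb
serialization rounding, and an explicit per-node flag for corroboration
by two or more independent loci, which overrides support when accepted.
Locus corroboration is an *input annotation*, not something this
package computes — how to score it per node is an editorial judgement
made by whoever curated the source analysis. Support semantics
(bootstrap vs posterior) are declared per input tree, never guessed
from the magnitude of the numbers.

Collapsing promotes the children of a failing node to its parent,
yielding a multifurcating constraint; branch lengths are discarded
(a constraint carries topology only). Nesting a family- or genus-level
constraint into the order backbone is refinement-only: shared leaves
anchor the sub-tree, new leaves are attached at the MRCA of their
smallest anchored clade, and each clade of the sub-tree is then imposed
as a grouping constraint, which refines polytomies but raises a hard
error (naming the two offending splits) if it would break an existing
resolved split. There is no majority-rule fallback — curated
constraints that disagree need a human, not a vote.

## Grafting

The backbone is fixed; queries only attach to it. Queries are processed
in sorted-label order and each is inserted on the edge minimizing the
placement criterion, with exact ties resolved by the lowest post-order
edge index — two properties that make runs bit-reproducible. Restricting
the output to the backbone's leaves always reproduces the backbone
topology exactly; this is the module's central contract and is asserted
by property tests and the acceptance script.

* **parsimony** — total Fitch length of the tree after insertion,
  computed over all alignment columns with IUPAC codes as state sets
  and gaps as full sets. The score is recomputed exactly per candidate
  edge (no set-union shortcut), which is affordable at desk scale.
* **min_evolution** — weighted least squares: observed distances from
  the query to every current leaf are fitted to `a_i + s_i·t + y`,
  where `t` is the attachment position along the candidate edge and
  `y ≥ 0` the pendant length; weights are `1/d²` (Fitch–Margoliash), so
  the near neighbours that actually carry placement information are not
  swamped by the many distant, noisy pairs. The candidate edge with the
  smallest weighted residual wins. Distances default to K2P for this
  criterion because the multiple-hit correction keeps them
  approximately additive at depths where raw p-distances flatten;
  saturated (infinite) pairs are dropped from the fit, and a query with
  no finite corrected distance at all falls back to p-distances. When
  the backbone arrives without branch lengths (the normal case for a
  constraint tree), lengths are first fitted by ordinary least squares
  to the pairwise distance matrix.

On exact tree metrics the sequential least-squares placement provably
recovers the generating topology (residual zero on the true edge);
the test suite checks this by brute force on instances of ≤ 10 leaves.

Site-rate classes for partitioned ML export use the minimum number of
state changes per column on a guide tree (Fitch) as the rate proxy —
an intentionally simple stand-in for model-based per-site rates.
Columns are binned by midpoint-rank quantiles (fraction of strictly
slower sites plus half the tied fraction), which keeps ties in one
class and spreads skewed distributions; invariant columns are always
class 1. Requesting more classes than there are distinct proxy values
is an error.

## Quality control

Two detectors mirror the two analysis tracks:

* **Long branches** (per-family trees): a leaf is flagged when its
  terminal branch exceeds `factor` × the median terminal branch length
  (default factor 5 — no canonical value exists, so it is configurable;
  the rule is scale-invariant by construction). Trees with fewer than
  four leaves produce no flags: the median of three terminal branches
  is too unstable to threshold.
* **Label-vs-placement** (all-taxon tree): for each leaf, enclosing
  clades are examined from the smallest outward until one holds at
  least `min_clade` (default 3) other labeled leaves. The leaf is
  flagged only if the neighbours' most common label contradicts its own
  at every level including that final neighbourhood. The early exit is
  what makes the detector specific: a member of a small family is
  vindicated by its nearest neighbours before the search widens into
  other families, whereas a true intruder is foreign at every scale.
  Ties that include the leaf's own label never flag. Majority
  neighbourhoods rather than strict monophyly are used deliberately, so
  a single contaminant inside an otherwise coherent family is caught
  even when the family is non-monophyletic for unrelated reasons.

Flags are reports, not deletions — resolving one requires re-examining
the voucher specimen, and long branches are deliberately retained in
the trees.

A separate monophyly check returns, for any leaf set, either
`monophyletic` or the list of intruding leaves under its MRCA.

## MOTU clustering and concordance

Single-linkage clusters are the connected components of the graph with
an edge wherever `d < threshold` — strictly below, so a pair at exactly
the threshold is not linked. Missing distances (no comparable sites)
and saturation markers contribute no edge. Cluster ids are dense
integers numbered by each cluster's smallest member label. The default
threshold is 2% p-distance with pairwise deletion, the conventional
species-scale cut for COI; K2P is available by flag. Only single
linkage is implemented: it matches the chaining behaviour implicit in
talking about haplotype clusters, and other linkages would not be
comparable to registry-style cluster counts.

The concordance audit classifies each species against the partition:
`match` (one cluster, pure), `split` (≥ 2 clusters, all pure),
`merged` (one cluster shared with other species), `mixture` (the rest).
The categories are exhaustive and mutually exclusive by construction.

## The synthetic-data generator

The generator is the package's study system; every quantitative claim
the tests make is a claim about data of this form.

* **Species tree** — Yule (pure birth), with one shared terminal
  stretch added to all tips, drawn as `0.25 + Exp(0.25)` in units of
  1/birth-rate. The stretch emulates the barcode gap (sampled species
  separated by substantial pendant divergence) and bounds the ratio of
  deepest to shallowest leaf pair; it is bounded away from zero because
  the subsequent rescaling divides by the minimum pair and a near-zero
  draw would blow the tree depth past saturation. The tree is rescaled
  so the minimum leaf-pair divergence corresponds to an expected
  p-distance of `between_div` (default 4%). Internal edges are then
  floored at half that distance: at the defaults every internode
  carries ≈ 13 expected substitutions over 658 nt, which is the
  operational meaning of "strong signal" — pairwise-distance noise at
  these depths has a standard deviation near 0.02, and unfloored Yule
  internodes (often < 1 expected change) would be unrecoverable by any
  placement method. With `n_families > 1` a family-level Yule tree
  (three times deeper) is built first and each family tip replaced by a
  within-family subtree, so families are monophyletic by construction.
* **Sequences** — evolved site-independently under JC or K2P (closed-
  form transition matrices, no indels — alignment is out of scope
  project-wide). Frame-1 stop codons arising from substitution draws
  are repaired deterministically (TAA→TCA, TAG→TCG) because a real COI
  amplicon is translatable; without this the stop-codon filter would
  reject the generator's own output. The divergence regime is a
  guarantee about the emitted data, not just an expectation: a draw
  whose realized minimum between-species p-distance falls below
  `between_div` is redrawn (up to 50 seeded attempts, keeping the best),
  since binomial fluctuation over 658 sites spans a few percent and the
  downstream threshold logic is specified in terms of the data's actual
  divergences.
* **Haplotype clouds** — each species' haplotypes diverge independently
  from the species sequence by Uniform(0, `within_div`) substitutions
  per site: the expected pairwise within-species divergence equals
  `within_div` (default 0.5%) and is *bounded* by twice it, keeping the
  cloud strictly inside the clustering threshold. (An exponential draw
  with the same mean violates the stated ≤ 1% regime on a few percent
  of datasets via its tail.) Individuals per haplotype are drawn
  uniformly from a small range and assigned localities from a fixed
  pool that includes two big-seven countries with regions, so label
  encoding is exercised.
* **Label errors** — `round(rate · n)` records receive the species and
  family labels of a different species (optionally forced cross-family,
  emulating gross submission or contamination errors); a manifest lists
  every swap so detectors can be scored for recall.

All randomness flows through numpy generators seeded from the config;
identical configs give byte-identical outputs.

What the generator does **not** emulate: incomplete lineage sorting,
introgression, rate variation among lineages or sites, indels,
sequencing error in the reads themselves, and the hollow-curve
abundance distribution of real barcode libraries. Tests passing on
this generator therefore demonstrate the pipeline's correctness and
its behaviour under clean species-structured variation — not its
robustness to gene-tree/species-tree discordance, which the strategy
explicitly leaves to downstream curation.

## Problem sizes and expected figures

The shipped tests and the acceptance script run at desk scale: 1,000
synthetic records for the filter; 100 small datasets for haplotype
properties; support-annotated trees up to 50 leaves (compatibility
brute-forced at ≤ 12); 100 random backbone/query simulations; ten
30-leaf placement replicates with 20% of leaves deleted (60
placements); 200 random matrices for the clustering oracle; five
datasets for species-partition recovery; eight datasets at 5%
mislabeling for misplacement recall. Under these conditions the
measured figures are: restricted Robinson–Foulds distance 0 in every
grafting run, placement recovery around 0.95–1.0, Adjusted Rand Index
1.0 for 2% clusters against the generating species partition,
misplacement recall ≥ 0.9 with zero flags on uncorrupted data, and
bit-identical reruns.

## Known limitations

* Sequential insertion is greedy: an early ambiguous placement can in
  principle attract a later query; no simultaneous or re-visiting
  placement is attempted.
* The least-squares fit treats distances as independent observations;
  shared-path covariances are ignored (as in classical OLS/WLS
  branch-length fitting).
* The label decoder assumes species names do not contain a token equal
  to a 3-letter country code, and the `.k` disambiguation suffix is
  indistinguishable from a species name genuinely ending in `.digits`
  (none exist in practice).
* The site-rate proxy (parsimony steps) is a crude surrogate for
  model-based site-specific rates; it is exported for partitioned ML,
  not used for inference here.
* `nest_constraints` requires mutually compatible inputs; it is a
  refinement merger, not a supertree method.
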