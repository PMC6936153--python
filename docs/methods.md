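# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of the toolkit. Every number quoted here is computed
by the test suite or by `scripts/acceptance.py`; nothing is asserted that
the code does not measure.

## Recruitment model

A genomic sequence is treated as a bona fide prokaryotic virus when its
proteome carries a strong signal against a marker database of viral
orthologous groups. Each marker has a viral quotient VQ ∈ [0, 1]; the
sequence-level score is the added viral quotient, AVQ = Σ over proteins of
the VQ of that protein's best (highest-bitscore) marker hit. Tie-breaking
for "best hit" is bitscore, then lowest e-value, then lexicographic marker
ID — the last step only to make output platform-independent.

Thresholds (all inclusive, all exposed in config):

| parameter | default | meaning |
|---|---|---|
| round-1 matched proteins | ≥ 20 % | fraction of the proteome with ≥ 1 marker hit |
| round-1 AVQ | ≥ 5 | summed best-hit quotients |
| round-2 matched proteins | ≥ 20 % | distinct proteins best-mapping to one anchor |
| round-2 matches | ≥ 3 | absolute floor on distinct protein matches |
| completeness coverage | ≥ 70 % | of a complete genome A's proteins mapped into B |
| completeness length | ≥ 10 kbp | minimum length for "nearly complete" |

Round-2 percentages count distinct candidate proteins with at least one
hit to the anchor, not hit rows; the qualifying anchor with the most
matched proteins wins, ties broken by summed bitscore then genome ID.
Completeness containment is directional: it is coverage of the complete
genome A (how much of A is found in B), since B may carry extra genes.
Terminal-overlap detection for circularity is exact string matching
(longest proper border via the KMP failure function, flagged circular at
≥ 20 bp); approximate repeat detection is out of scope. Manual curation
and third-party viral predictors are not reimplemented; the report schema
reserves label values so externally flagged sequences can be merged.

## Dice distance

D_AB = 1 − 2·AB/(AA+BB) with AB the bitscore sum of all valid matches of
A's proteins against B's. Hit validity uses the standard filter profile
(identity ≥ 30 %, bitscore ≥ 30, alignment ≥ 30 aa, e ≤ 0.01; the marker
search uses bitscore ≥ 50 instead). Conventions:

* **Symmetrization.** The raw AB sum is directional; the matrix entry uses
  (AB + BA)/(AA + BB). Neighbor joining requires symmetry, and for a
  symmetric search this equals the directional formula exactly.
* **Multiple HSPs** between the same protein pair are summed (the distance
  is defined over *all* valid matches); `best_hsp_only=True` keeps only
  the top row per pair for sensitivity analysis.
* **Clamping.** Asymmetric scoring can push AB + BA marginally above
  AA + BB; negative distances are clamped to 0. Pairs with no hits are
  exactly 1 — no pseudo-count.
* A genome with AA = 0 is a hard error: it means the search lacked
  self-hits, and every distance involving it would be meaningless.

## Tree construction

Saitou–Nei neighbor joining (via scikit-bio) with negative branch lengths
clamped to zero, then midpoint rooting, then depth annotation
(depth = branch-length sum from the root). Determinism does not rely on
the NJ implementation's tie-breaking: the distance matrix is always passed
with lexicographically sorted genome IDs, which fixes the join order for
tied Q-criteria and the choice among tied diameter paths. A two-leaf tree
is rooted at the midpoint of its single edge directly (the general
midpoint routine assumes ≥ 3 tips). NJ is O(n³); at the intended scale of
a few thousand genomes this is minutes of work, and the pipeline keeps the
matrix in memory as float64.

## Lineage extraction

A node defines a lineage iff its depth and leaf count meet the level's
rule *and no ancestor also qualifies* (maximal qualifying clades). The
maximality condition is what makes lineages of one level pairwise
disjoint: without it every descendant of a qualifying node would also
qualify. Published defaults are level 1 (0.0014, ≥ 20), level 2
(0.0056, ≥ 3), level 3 (0.0189, ≥ 3); the minimum-size floors grow with
the level so that coarse lineages are backed by many genomes. Nestedness
across levels is automatic (deeper cutoffs select descendant nodes).
Leaves in no qualifying clade stay unassigned.

Calibration scans cutoffs over an inclusive grid (default 0.0001–0.2,
step 0.0001) and scores each partition against reference labels with the
**plain** Rand index — (agreeing pairs)/(all pairs), computed exactly via
contingency counts; an adjusted variant is available behind a flag.
Genomes unlabeled in the reference or unassigned at a cutoff are excluded
from that cutoff's score (cutoffs assigning fewer than two labeled genomes
score NaN); ties in the argmax resolve to the smallest cutoff.

Node identity in the robustness analysis is the exact leaf-label set on
the rooted tree, not an unrooted bipartition, because lineages are rooted
clades. Each iteration draws a fraction of protein IDs without
replacement (default 5 %, 100 iterations; note removing a fraction f of
proteins removes about 2f of the matches), drops every hit touching them,
and rebuilds the tree. Substreams are derived per iteration from a
counter, so runs are reproducible across platforms and iteration counts.
An iteration that strips a genome of all self-hits is redrawn from a fresh
substream.

## Closest-relative identification

The closest relative of a query is the classified genome with the highest
percentage of matched PEGs, ties broken by highest AAI, then lexicographic
ID. AAI is the unweighted mean of best-hit percent identities
(length-weighting behind a flag). Both cutoffs (matched PEGs ≥ 70 %,
AAI ≥ 50 %) must hold, and percentages are computed **over the query's
proteins**: queries are typically fragments, so demanding coverage of the
full-length relative would reject nearly everything. Expanded assignments
are flagged `method=CRI` and should be treated as tentative; expansion
never alters tree-derived assignments.

## Ecological profiling

Relative abundance of a sequence in a sample is 100 × reads / total mapped
reads (no length normalization by default; an RPKM-style option exists).
Lineage abundance sums members; the unassigned bucket closes each row to
100 %. Prevalence denominators exclude members lacking the annotation,
because host predictions are incomplete in real data. Rarefaction samples
genomes without replacement (25 draws per grid point, seeded); unassigned
genomes are drawn but contribute no lineage, so the expected count at
n = 1 is below 1 when unassigned genomes exist. An OG enters a lineage's
pan-genome at ≥ 3 detected member genomes and is promiscuous at ≥ 3
level-1 pan-genomes.

## Synthetic community generator

The pipeline consumes tabular homology hits, so fixtures synthesise the
hits directly rather than simulating sequences and running an aligner:
fast, deterministic, and the planted statistical structure is exactly what
the method consumes. Homologous slots get identities from strictly ordered
bands — within level-3 groups 86–92 % (full proteome shared, arranged as a
ladder so within-group topology is a stable caterpillar rather than a
noise-driven star), across level-3 groups 63–67 % at 80 % sharing, across
level-2 sublineages 43–47 % at 50 % sharing, and no sharing across level-1
lineages (Dice distance exactly 1). Bitscore = round(2 × length ×
identity/100); only monotonicity in identity × length matters to the Dice
ordering, so the constant is arbitrary. The defaults (3 level-1 × 2
level-2 × 2 level-3 lineages, 2–3 genomes per group ≈ 30 genomes, 12
proteins of 150–400 aa each) keep every stage's runtime in seconds while
leaving wide margins between the depth bands of the resulting tree
(level-1 nodes ≈ 0.10–0.13, level-2 ≈ 0.25–0.29, level-3 ≈ 0.43–0.46,
tips ≈ 0.5); `bundle.suggested_rules` places each cutoff between two
bands (0.05 / 0.18 / 0.35). Marker signal: 60 % of proteins hit a VQ-1.0
marker (AVQ ≈ 7 ≥ 5); about one genome per level-3 group has its marker
signal suppressed to exercise round-2 rescue. Eukaryotic-virus decoys hit
a designated marker subset (exercising pruning); cellular decoys carry one
weak low-VQ hit (exercising precision). Fragments re-emit 70–90 % of a
source genome's proteins with 95–99 % identity hits back to their group.

What the generator does **not** emulate: real sequence evolution (no
substitution model, no indels, no rearrangements), alignment artifacts
(partial-length HSPs, paralog cross-hits, chimeric contigs), skewed
lineage sizes, and marker databases with graded quotients. Passing tests
therefore demonstrate the *algorithmic* correctness and determinism of the
stages under separable planted structure — not that the published
thresholds are optimal for any particular real dataset, where identity
bands overlap and recruitment recall is genuinely below 100 %.

## Numerical and degenerate-input conventions

* All threshold comparisons are inclusive (≥ / ≤), so boundary hits pass.
* Rand index uses exact integer pair counts (`math.comb`); equality with a
  brute-force pair enumeration is exact, not approximate.
* All-zero distance matrices produce a tree with all-zero branch lengths;
  midpoint rooting of such a tree picks an edge deterministically.
* Homopolymer terminal-overlap detection returns length − 1 by
  definition of the longest proper border; callers should treat such
  sequences as suspect rather than circular.
* Every stochastic routine takes one integer seed; substreams are derived
  with counters (`default_rng([seed, i, ...])`), never by reusing a
  generator across unrelated concerns.

## Scope limits

Gene calling, the homology search itself, nucleotide dereplication, read
mapping, OG clustering, third-party viral predictors and ordination plots
are consumed as inputs or out of scope. Species-level clustering below
level 3 is not implemented (it would need deeper cutoffs than the level-3
default). Tree visualisation is out of scope.
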