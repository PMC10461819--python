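# Methods

## The criterion

An SSN at cutoff 10⁻ᵏ keeps an edge between two sequences when their best
pairwise e-value is at most 10⁻ᵏ. Sweeping k from permissive to stringent
peels edges away; subfamilies are the connected components at the chosen
cutoff. The quality signal used here is averaged per-component closeness
centrality: per node u in a component of size n ≥ 2,
C(u) = (n − 1) / Σ_v sp(u, v), with sp the unweighted shortest-path edge
count inside the component; the network score is the plain arithmetic mean
of C(u) over all nodes of degree ≥ 1. Intuition: C(u) = 1 iff u neighbours
every other node of its component, so the score is 1 exactly when every
non-singleton component is a clique. A handful of weak bridges between two
dense groups inflates average path lengths and drags the score far down;
the moment the bridges fall below the cutoff the groups separate and the
score rebounds. Those rebound points are the candidate subfamily schemes.

Two deliberate conventions:

- **Wasserman–Faust correction off.** The WF factor (n − 1)/(N − 1)
  rescales closeness by component size over graph size, penalising
  multi-component graphs. Since well-separated components are the target
  state, the factor would punish precisely the networks being sought; it
  is implemented (`wf_improved=True`) only for comparison.
- **Singletons excluded by default.** The mean runs over nodes with at
  least one neighbour, so isolated sequences never move the score
  (`singleton_mode="exclude"`). The alternative convention — count
  singletons as 0 (`singleton_mode="zero"`) — penalises heavily
  fragmented networks and is exposed for workflows that compare many
  schemes at once. A graph with no connected pair at all gets a defined
  score of 0 with a warning, so sweeps never crash on fully disintegrated
  networks.

Edges are never weighted: similarity only decides whether an edge exists
at a cutoff. The score is a mean over nodes, not over components, so a
large clean component and a small clean component weigh by membership.

The closeness computation is a per-component BFS written in this package;
networkx's `closeness_centrality` and a dense scipy all-pairs matrix serve
as independent cross-checks in the test suite only.

## The artificial benchmark

Criterion selection is grounded in network collections: two fixed
subnetworks (complete graphs of 50/200 nodes, G(n, m) random graphs of
200 nodes with 300–4000 edges, or 50/200 singletons), starting
disconnected and gaining one uniformly random cross edge per member until
all n_a·n_b pairs are joined. A good criterion must score both clean end
states high and the sparsely bridged middle low. Closeness does; mean
betweenness (and its relatives) scores a bag of singletons identically to
a perfect clique, which would reward total disintegration — the registry
ships both so the comparison is reproducible. For singleton-versus-network
pairings two further edge orders probe topology space: round-robin (every
singleton gets its first edge before any gets a second) and exhaust-node
(one singleton is fully wired before the next starts).

Collections are stored as the two subnetworks plus the seeded cross-edge
order and materialised lazily; a complete(200)×complete(200) collection
holds 40,001 graphs and is never held in memory at once. All randomness is
seeded; identical (specs, strategy, seed) reproduce identical collections.
The registry implements the nine criteria needed to reproduce the
selection argument (closeness with/without WF, mean degree/betweenness/
harmonic/clustering centralities, component count, edge count, average
degree); further criteria are an extension point.

## Hit parsing and the sweep

Input is the standard 12-column tabular alignment format. Directed hits
are aggregated per unordered pair, keeping the most significant e-value
and the highest bitscore in either direction (the digraph is flattened by
union: an undirected edge exists if either direction passes). Self-hits
are dropped; sequences named in the FASTA but absent from the hits become
singleton nodes at every cutoff.

Significance lives in −log10 space. A reported e-value of 0.0 is the
IEEE-754 double underflow (below ~1e-308) that affects long domains; it
maps to +inf and passes every e-value cutoff, so thresholding never
touches denormal floats. For families where most of the dynamic range
underflows, the sweep also runs in bitscore mode over a user-supplied or
quantile-derived grid; on data where bitscore is strictly monotone in
e-value the two modes produce the identical sequence of distinct
partitions (tested). Identity and coverage columns are parsed and kept
but not filtered on — the SSN construction applies no coverage filter.

The default grid is exponents 5..160 step 1. The sweep stops early after
the first cutoff where the component count exceeds `max_components`
(default 1000) or the edge set empties: everything past that point is
noise about an already disintegrated network.

## Optimum detection and assignment

A candidate optimum is a cutoff where the score strictly increases from
the previous cutoff *and* the component count rises at the same step — a
split event. The global maximum is always reported (ties to the least
stringent cutoff). Equal consecutive scores never create candidates, but
a split with an unchanged score is still surfaced, flagged
`score_neutral_split`; a profile with no split at all yields a single
candidate flagged `no_split_events` (the "no subfamilies" verdict). Each
candidate carries the trough preceding the jump (the running descent
minimum), the resulting drop depth, the number of reportable subfamilies
and the count of unclassified sequences. Candidates are ranked by score,
then drop depth, then leniency — but the tool never auto-picks: several
optima can be biologically meaningful (taxonomic vs functional splits)
and the curator decides with the table in hand.

Subfamily assignment at a cutoff labels components of at least `min_size`
members 1..k by descending size (ties by smallest member id); smaller
components and singletons pool as label 0. `min_size` defaults to 10 in
the CLI surface but is always an explicit, logged choice — reporting
conventions in the literature range from >10 to >100 members. Annotation
summaries tabulate multi-valued labels (e.g. dual EC numbers, split on
`;`) per subfamily with coverage fractions; annotation ids missing from
the network are reported, never fatal.

## Domain-sequence reconstruction

Profile HMM searches align locally, so a single divergent domain often
surfaces as several fragments. After dropping hits with independent
e-value ≥ 1e-4 (strict), fragments of one (sequence, HMM) pair are
chained greedily left-to-right; two consecutive fragments merge only if
(i) both their start and end coordinates are separated by more than 20
residues — closer pairs are near-duplicate local alignments of the same
region, not adjacent pieces; (ii) the sequence gap between them is at
most 200 residues; (iii) their profile coordinates overlap by at most 30
positions. Fragments whose sequence intervals overlap never merge, and a
fragment failing any rule starts a new assembly. Rule (i) is applied
pairwise between consecutive fragments; coordinates are 1-based inclusive
alignment coordinates, and overlap lengths use the +1 inclusive formula.
Greedy chaining (rather than an optimal chaining DP) matches the simple
consecutive-fragment semantics and is idempotent on its own output.

Assembled domains shorter than half the HMM length are discarded; over
the retained population, lengths outside mean ± 3 sample standard
deviations are flagged for manual inspection (kept, reported) — these are
usually gene-model artefacts. When two or more HMMs hit the same protein
(the iterative-SSN situation for families too diverse for one profile),
the longest assembled domain wins; exact ties go to the HMM listed first
in the configured order, and the decision is logged.

## Visualization subsampling

Large components are reduced per connected component, preserving the
component count exactly. Components below `min_keep` (default 10) nodes
pass through unchanged; larger ones are sampled by drawing edges
uniformly without replacement and keeping both endpoints until
max(min_keep, round(fraction·n)) nodes are collected, then induced (every
original edge among kept nodes is added). If induction leaves the sample
disconnected, the largest piece anchors a multi-source BFS over the
original component and the nearest stranded piece is reattached along
that shortest path, repeating until connected. Reconnection adds only
original nodes and edges, so the output is always a subgraph; it may
exceed the node target slightly, which is reported rather than prevented.
Per-component RNG streams derive from the seed and the component's
smallest node id, so results are independent of iteration order.

## What the synthetic data does and does not show

The synthetic family generator plants complete blocks with
uniformly-drawn within-block significances and exact-significance
bridges, plus optional orphan sequences. This reproduces the topology
the method exploits — dense groups, sparse bridges, hitless singletons —
with a known ground truth: blocks i and j disconnect exactly one
exponent past their bridge significance, so optimum detection can be
checked for exact recovery. Real families differ in ways the generator
does not emulate: within-subfamily similarity is not uniform (it decays
with phylogenetic distance, so blocks erode gradually rather than
vanishing at one cutoff), inter-subfamily similarity spans many
exponents, alignment coverage varies, and e-value underflow correlates
with domain length. Passing tests therefore demonstrate the machinery —
thresholding, scoring, split detection, refinement — not that any
particular biological family splits at any particular cutoff; on real
data the candidate table is evidence for a curator, not a verdict.

Default study conditions mirror the benchmark: subnetwork sizes 50 and
200, random subnetworks of 200 nodes with 300–4000 edges, sweep exponents
5..160 step 1, disintegration stop at 1000 components, minimum subfamily
size 10, subsampling fractions 0.25/0.50 with min_keep 10. Test fixtures
use blocks of 9–30 sequences so the full suite runs in seconds on one
CPU; the acceptance checks that depend on exact closed-form values
(complete graphs, single bridges) are size-independent.

## Numerical notes and limitations

- Closeness sums are exact integer distance sums divided once; agreement
  with independent oracles is asserted to 1e-12.
- Exponent arithmetic is done on the −log10 scale; cutoff comparison is
  `exponent ≥ k`, never a float division by a denormal.
- The sample standard deviation (ddof = 1) is used for the length-outlier
  flag; populations of fewer than two retained domains skip the flag.
- The criterion is independent of the number and size of components: two
  clean components of size 50 score the same as fifty of size 2. The
  `singleton_mode="zero"` convention is the built-in mitigation; the
  component-size columns in the profile are the other.
- Optimum detection reacts to single-step jumps; a split that unfolds
  across several cutoffs with non-monotone noise in between may surface
  as multiple shallow candidates. The drop-depth ranking is a heuristic,
  not a test statistic.
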