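# Methods

This note documents the models and conventions behind `morphoclad`, the
choices made where the methods literature leaves room, and what the
synthetic-data tests do and do not demonstrate.

## Parsimony model and scoring

All characters are binary, unordered and equally weighted; tree length
is the Fitch criterion (minimum summed state changes). Two scorers are
used, and the test suite checks them against each other and against an
exponential brute-force oracle that enumerates every internal-state
assignment:

- **Search scorer.** States are packed two bits per character into a
  single machine integer per node, so one Fitch down-pass step over all
  characters is a handful of bitwise operations (intersection; where a
  character's intersection is empty, union plus one step via a popcount
  on the conflict mask). This scorer assumes binary (fully resolved)
  trees, which is all the searches generate. Scoring aborts early once
  the running count exceeds the current search bound, which is what
  makes plain enumeration of all 2,027,025 ten-taxon topologies cheap
  (seconds, not minutes, on one core).
- **General scorer.** Arbitrary, possibly multifurcating trees are
  scored by Hartigan-style state counting (per node, keep the states
  attained by the maximum number of children; add children-minus-max to
  the length). This is exact on hard polytomies — a polytomy is scored
  as given, never implicitly resolved — which matters because collapsed
  consensus trees must be scorable. Parsimony length is independent of
  rooting, so the storage root is immaterial (property-tested).

## Searches

- **Enumeration / exhaustive.** Stepwise addition of each successive
  leaf onto every edge generates each unrooted binary topology exactly
  once; counts match `(2n−5)!!` (tested for n = 4..7, and the 10-leaf
  run reports 2,027,025 topologies examined).
- **Branch and bound.** Tree length is monotone under leaf addition, so
  any partial tree longer than the incumbent can be pruned exactly. A
  greedy stepwise-addition tree seeds the initial bound. Equivalence
  with plain enumeration (same length, same optimal set) is asserted on
  randomized instances.
- **Ratchet.** The heuristic alternates NNI hill-climbs on a perturbed
  matrix (a small random character sample upweighted ×2) and the
  original matrix, holding up to `trees_held` distinct trees between
  iterations. Defaults (5000 iterations, 5 trees held, 1 character
  resampled) follow the published run configuration; the reweighting
  multiplier is not stated there, so ×2 is the package default and a
  config knob. The "1 character sampled" reading (one character, not
  one percent) is likewise configurable. Seeded and reproducible.
- **Tree identity.** Topologies are deduplicated by canonical split-set
  (each bipartition oriented away from the lexicographically smallest
  leaf), so co-optimal duplicates from any search route collapse
  deterministically and no first-found tree is privileged.

## Fit indices

CI = M/S and RI = (G−S)/(G−M) are reported on the percent scale
**truncated** (floored) to integers, with exact rationals exposed
alongside. Truncation is the only convention consistent with the
bundled study's printed values (12/14 = 85.71 → 85); conventional
rounding would print 86. All characters enter the sums, informative or
not — excluding uninformative characters would give CI 83 on the
bundled matrix, not the printed 85. RI is reported as undefined when
G = M (no informative characters), CI when S = 0 (invariant matrix).

## Bremer support and collapsing

Bremer support is computed exactly: a branch-and-bound search over all
binary topologies *not* displaying the clade's split (membership is
checked on each complete tree; the incumbent bound is the best
clade-lacking tree found so far). No heuristic constrained search is
involved at these taxon counts. Clades are treated as unrooted splits
during search.

Unsupported-node collapse contracts every internal branch whose minimum
optimised length is zero — equivalently, every branch whose contraction
leaves the tree length unchanged (checked with the polytomy-exact
scorer). The procedure iterates to a fixed point and is idempotent. On
the bundled matrix this turns all 15 binary optima into one
multifurcating hypothesis, the same tree obtained by strict consensus;
the agreement of the two routes is asserted in the tests. Notably the
exact computation shows the three-taxon *Sipha (Rungsia)* +
*Chaetosiphella* group itself has zero minimum branch length: the
collapsed hypothesis holds those three taxa in a four-way polytomy with
the *Laingia* + *Atheroides* clade.

## Apomorphy mapping

Characters are optimised onto the outgroup-rooted tree by unit-cost
dynamic programming (exact on polytomies), then resolved top-down: on a
tie between keeping the parental state and changing, ACCTRAN changes
(placing changes rootward) and DELTRAN keeps (placing them tipward).
ACCTRAN is the default because the study figure prints specific
placements without stating a rule. The root state is inferred, not
assumed to be 0, with the outgroup's observed state breaking ties —
"forward" and "reversal" are only meaningful relative to that inferred
ancestral state. A change is *unique forward* when its character
changes exactly once on the tree, away from the ancestral state;
*reversal* when it returns to the ancestral state below an earlier
forward change; *homoplasious forward* otherwise. Changes whose branch
placement differs between ACCTRAN and DELTRAN are flagged ambiguous.
Per character, the number of mapped changes always equals the Fitch
step count (asserted at run time).

## Character coding

The twelve built-in definitions translate specimen observations into
matrix states. Ratio characters keep the printed thresholds, and the
open interval between the two state conditions (e.g. body elongation in
(3.0, 3.5); hindfemur/midfemur in (1.5, 1.6)) is an explicit *gap*: a
specimen falling inside it is unscorable, not rounded into a state,
because the state definitions are deliberately non-exhaustive and
ambiguous observations were excluded from the original matrix rather
than forced. "Subequal" is operationalised as a ratio ≤ 1.05
(configurable; the descriptions never quantify it). Antennae with fewer
than five segments (known in *A. brevicornis*) are coded with the
five-segmented (derived) state plus a warning, since the matrix only
distinguishes six from five.

The mining screen reproduces the character-discovery procedure: every
pairwise ratio of a measurement set across taxa, screened for a clear
gap. Visual histogram inspection is formalised as a largest-gap rule —
bimodal when the largest gap between consecutive sorted values is at
least 35% of the range (`gap_fraction`, configurable). The exact
measurement list used in the original mining is not recoverable, so the
screen accepts any list.

## Identification keys

The two keys are declarative couplet tables whose quantitative leads
reuse the character-coding predicates (the dorsal-seta-shape lead is
literally the character-5 scorer), so key and matrix cannot drift
apart. Boundary specimens that satisfy neither lead (exactly 30
pseudosensoria; marginal setae exactly as long as the hindfemur width)
return *indeterminate* with the conflicting couplet identified. The
printed back-reference "3 (2')" of the apterous key is treated as a
typographical slip for "3 (1')": lead targets, not provenance tags,
define the couplet graph. Validation checks acyclicity, reachability
and single occurrence of each terminal.

## Synthetic data

`simulate_characters` evolves each character independently on a known
topology: state 0 at the root, flipping along each branch with
probability p (a per-branch flip model rather than rate × length, since
the trees here are topology-only). `keep` selects which columns enter
the matrix: `"all"` (raw model), `"variable"`, or `"informative"`
(minority state in ≥ 2 taxa). The topology-recovery studies use
`keep="informative"`, because that is what an assembled morphological
matrix looks like — characters are only ever coded when they vary
informatively among the sampled taxa (the bundled study's mining step
explicitly discarded everything else), and constant or autapomorphic
columns carry no parsimony signal. Under the raw model at p = 0.05 only
about a quarter of columns are informative, and exact-topology recovery
at n = 8, k = 100 sits near 55–80%; with k = 100 informative columns it
exceeds 90%, which is the regime the recovery thresholds in the tests
describe. Problem sizes for the simulation studies (8–10 taxa, 60–100
characters, 50 replicates) keep each study within seconds while holding
binomial error on the recovery rate to a few percent.

`generate_specimens` draws measurements uniformly within per-species
ranges (published morphometric ranges where available; widths and seta
lengths otherwise placed inside the species' diagnostic ratio regions)
and copies categorical trait levels; pseudosensoria counts are uniform
integers in 18–27 for the new species' oviparae. Uniform sampling is
the default because no distributional information is printed; nothing
in the consumers depends on the distribution shape, only on the
ranges.

### What the synthetic tests show — and do not

Passing recovery tests show that the pipeline (simulation → exact
search → consensus → collapse) is internally consistent and that the
searches are exact at these sizes. They do not show that real
morphological characters evolve independently, symmetrically, or at a
common rate — real matrices correlate characters through shared
function and coding choices, and the specimen generator draws traits
independently within ranges, without the covariation real specimens
exhibit.

## Numerical and degenerate-input conventions

- Matrix cells are {0, 1, missing}; missing is supported in readers
  (`?`) even though the bundled matrix has none.
- Taxon labels are canonicalised (whitespace → underscores) for newick
  emission and cross-format matching; originals are kept for display.
- Fewer than 3 taxa cannot be searched; plain enumeration refuses more
  than 12 taxa (configurable guard) and points at branch-and-bound or
  the ratchet.
- Ties everywhere are resolved deterministically (sorted split sets,
  seeded RNG), so equal inputs give byte-equal outputs.
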