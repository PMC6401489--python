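# Methods

## Data model

The unit of input is a multi-condition antagonism screen: for each growth
condition, a square binary matrix over the same ordered strain collection,
with entry *(p, r) = 1* meaning producer *p* visibly inhibited receiver *r*
on that medium. Entries are presence/absence only — inhibition-zone sizes
are out of scope. Self-inhibition is not a measurable interaction in the
assay, so diagonal cells are accepted in files but must be 0; a nonzero
diagonal fails loudly rather than being dropped. The canonical strain order
is the order of the first condition file and is enforced everywhere.

Two serializations are supported: wide (one square table per condition,
strain ids as first row/column) and long (sparse rows
`producer receiver condition value`; unlisted cells mean "no inhibition
observed" and are counted in a single warning). One long file may carry all
conditions; rows are filtered by the condition column.

All statistics operate on the **union network**: an ordered pair is one
edge as soon as it is detected under ≥ 1 condition, annotated with its
exact support set. The number of conditions is not fixed at three —
every statistic generalizes to *k* ≥ 1.

## Statistics

**Connectance** is `E / S²`. The denominator deliberately includes the
diagonal (all ordered combinations of *S* species), the convention under
which a 21-strain screen with 105 edges gives 105/441 = 0.238 → 0.24; the
off-diagonal alternative (105/420 = 0.25) is not used.

**Sender–receiver asymmetry Q** contrasts structure on the producer and
receiver sides. With per-strain distinct-target out-degrees and
distinct-source in-degrees, `Q = (V_in − V_out) / (V_in + V_out)` using
population variances (divide by *n*; the ratio is convention-stable but one
choice must be fixed). `Q ∈ [−1, 1]`; `Q < 0` means out-degrees are more
dispersed — a few strong producers dominate ("producer determined");
transposing the network flips the sign exactly. A network with both degree
sequences constant is assigned Q = 0; an edgeless network has no defined Q
and raises. The statistic admits other formulations built on full
interaction profiles rather than degree sequences; the
`profile-correlation` switch is reserved for one but not implemented, and
the degree-variance form is the package's documented definition.

**Hierarchy scores.** Each strain receives +1 per distinct strain it
inhibits, −1 per distinct strain inhibiting it, and −1 more per reciprocal
partner; multi-condition support never multiplies points. Because each
edge contributes one reward and one in-penalty, Σ scores = −2 × (number of
reciprocal pairs); this conservation law is asserted on every computed
network. The reciprocal penalty being *additional* makes mutually
inhibiting pairs score below neutral, which is what pushes them to the
middle and bottom of the hierarchy. Levels (high/medium/low) are score
tertiles by default: group sizes as equal as possible with remainders to
the upper groups, a strain's group decided by its best rank (the count of
strictly better scores), so boundary ties all promote; explicit strictly
decreasing thresholds may be supplied instead. Levels are presentational
and never feed back into scores. The top-*k* producer share ranks strains
by (score desc, reward desc, id asc) — a deterministic artifact convention,
since score ties are real — and reports the fraction of all union edges
emitted by the top *k*.

**Conservation.** Every union edge belongs to exactly one Venn cell (its
exact support subset; 2^k − 1 cells for arbitrary *k*); the partition
identity (disjoint, exhaustive, totals matching) is asserted on every run.
Conserved-at-least-*s* percentages are relative to the union edge count.
"Nonhierarchical" edges are operationalized as directed edges whose reverse
also exists (mutual inhibition); broader cyclic notions are out of scope.
A reciprocal pair is `single-medium` only when both of its directed edges
have support size 1.

**Rounding.** Reports round half-even: connectance to 2 decimals, mean
partner count to 1, percentages to integers (e.g. 71/105 = 67.6 → 68%,
58/105 = 55.2 → 55%). JSON reports retain full precision alongside.

## Null models

Three families, all preserving strain count and edge count, never creating
self-loops, bit-for-bit reproducible given a seed:

- `erdos`: edges placed uniformly over off-diagonal ordered pairs without
  replacement;
- `out-preserving`: each producer keeps its out-degree, targets resampled
  uniformly without duplicates;
- `both-margins`: checkerboard swaps (a→b, c→d ⇒ a→d, c→b when valid)
  starting from the observed network, with a burn-in of 10 × |edges|
  accepted swaps (configurable). An attempt cap of 200 × the target guards
  against degenerate inputs; a matrix admitting no swap is the unique
  realization of its margins and is returned unchanged.

Condition-support sets travel with edge slots, so the support histogram is
an invariant of all three families. P-values use the add-one estimator
`p = (1 + #{null ≥ obs}) / (1 + n_perm)` (mirrored for `less`), standard
Monte-Carlo practice that avoids exact zeros; calibration under the
matched null is checked in the acceptance suite (KS test on replicate
p-values). Nulls operate on the union network; per-condition nulls are
deferred.

Choosing the family matters. The hierarchy score is
`out − in − reciprocal`, so under margin-preserving rewiring every strain's
out- and in-degree — and hence, essentially, the top-*k* membership and the
edges those producers emit — are invariants: the top-*k* share has no power
against `both-margins` (or `out-preserving`) and is tested against `erdos`.
Conversely the reciprocal-pair count is informative against `both-margins`
(does the hierarchy suppress mutual inhibition below what the degree
sequence alone implies?), which is how the analysis drivers pair statistics
with families.

## Synthetic screens

The generator is a noisy tournament with detection noise — the simplest
process producing layered inhibition networks with controlled deviation:

1. a latent producer ranking is drawn uniformly;
2. each unordered pair connects with probability `p_pair`; a connected
   pair is reciprocal (both directions) with probability
   `reciprocity_rate`, otherwise a single edge oriented down the ranking
   with probability `(1 + h)/2` (`h = 1`: perfectly rank-consistent,
   `h = 0`: coin flip);
3. every true edge is detected independently per condition with
   probability `detection_probs[c]`; an edge detected nowhere is absent.

`p_pair` is solved in closed form so the expected union edge count equals
`target_connectance × n²`: a true edge survives detection somewhere with
probability `q = 1 − Π(1 − d_c)`, a connected pair contributes
`q(1 + reciprocity_rate)` union edges in expectation, hence
`p_pair = target_connectance · n² / (n_pairs · q · (1 + r))`; targets with
`p_pair > 1` are rejected with the maximum achievable connectance named.
Defaults (21 species, 3 conditions, connectance 0.24, `h = 0.9`,
reciprocity 0.03, detection 0.8 per condition) emulate a screen of 21
rhizosphere isolates on three media with ~105 union edges, a strong
producer hierarchy, few reciprocal pairs, and a majority of interactions
detected on ≥ 2 media.

Detection noise is independent across conditions; condition-specific
biology (an interaction that exists only on a low-nutrient medium) is
representable only through unequal detection probabilities, not through
correlated condition effects — a known limitation. The generator also does
not model phylogenetic signal, transitivity beyond the latent order, or
zone-size intensities; passing tests on generator output therefore
demonstrate correctness of the statistics and calibration of the
machinery, not fidelity to any particular real community.

**Study-scale fixture.** For exact end-to-end checks, a deterministic
constructor pins a 21 × 21 × 3 tensor to the canonical headline totals:
105 union edges; support sizes 34/44/27 (so 71 edges conserved on ≥ 2
conditions, 27 on all 3); exactly 3 reciprocal pairs (6 strains); four
dominant producers with out-degrees 17/15/14/12 emitting exactly 58 edges
(55%). The layout is structural (a rank-consistent core plus three mutual
pairs in the mid/low field); the seed only permutes which strain label
plays which role and how supports are dealt to edges, so the totals are
invariants — they are nevertheless re-verified on every call, failing
loudly rather than returning a drifted fixture. Pinning totals exactly
(not in expectation) is deliberate: exact downstream checks need exact
inputs.

## Problem sizes and numerical conventions

The test and acceptance workloads are sized for a laptop-class single
core: exhaustive hierarchy-score verification over *all* directed edge
sets on up to 5 strains (≈ 1.05 M networks, against an independent
per-pair rule table); 1000-tensor sweeps for the conservation and
antisymmetry laws; 100-seed averages for latent-rank recovery
(mean Spearman ≥ 0.9 at `h = 1`, no reciprocity, full detection);
200-replicate × 199-permutation calibration of null p-values; 999
permutations in the analysis drivers. The whole suite runs in well under
a minute except the exhaustive sweep (~15 s) and calibration (~7 s).

Ties and degeneracies are resolved deterministically throughout: producer
ranking by (score, reward, id); tertile boundary ties promoted; Q of a
doubly-regular network defined as 0; empty networks raise
`UndefinedStatisticError` for statistics that would otherwise be 0/0.
Randomness always flows from a single integer seed through
`numpy.random.default_rng`.
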