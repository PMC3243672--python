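# Methods

This note records the model, the numerical choices, the defaults and their
rationale, and what the synthetic benchmark does and does not demonstrate.

## Correlation model

The unit of analysis is the *residue node*: a (column, residue) pair with
occurrence count n and marginal frequency n/N.  Perturbing the alignment
to the n_A sequences carrying node A and observing the count n_{B|A} of
node B gives, under the independence null, n_{B|A} ~ Binomial(n_A, n_B/N).
The signed score is −log10 of the upper tail when the joint count exceeds
its expectation n_A·n_B/N, and +log10 of the lower tail (a negative score)
when it falls below.  The exact-expectation boundary is assigned the upper
tail, whose value there is near zero and below any filter, keeping the
score continuous across the boundary.  Scores are computed for both
directions of each pair; the network edge weight is their mean.

Assumptions worth keeping in mind:

- The binomial null treats sequences as independent draws.  Phylogenetic
  relatedness violates this; the only correction applied is identity
  culling (below), which removes near-duplicates but not deeper tree
  structure.  Under the column-shuffle control the margins are fixed
  exactly, which makes the binomial tail conservative — the observed
  shuffled background (max |score| ≈ 3–4.5 at N = 675) sits comfortably
  below commonly used thresholds.
- Gap handling: a gap is a non-observation.  A sequence gapped at either
  column of a pair is excluded from both the trials and the joint count of
  that pair's tests; marginal frequencies keep the full N in the
  denominator.  Ambiguity codes (X, B, Z, U, O) are retained in the
  alignment but never form nodes and never match anything.

## Numerical evaluation of the tails

Scores of 100+ correspond to p-values far below 1e-308, so tails are
evaluated in log space throughout.  The fast path uses the vectorised
scipy binomial log-sf/log-cdf; when the p-value is above 1/2 the
complement is used through log1p to avoid total cancellation (this is
what keeps tiny scores relatively accurate); when the scipy path
underflows to −inf the tail is recomputed by an explicit
gammaln + logsumexp summation, which is exact in the log domain at any
magnitude.  The combined path agrees with arbitrary-precision rational
summation to better than 1e-13 relative error for n ≤ 60 (the test suite
asserts 1e-9 over 1000 random triples).

## Eligibility and thresholds

- `min_fraction` — minimum node frequency.  Default "auto": the smallest
  f on a 0.05 grid whose perturbed sub-alignment satisfies a central-limit
  variance floor (f·N)·f·(1−f) ≥ `clt_constant` (default 10).  The most
  extreme marginal frequency a node can have is the eligibility bound
  itself, hence the self-consistent form.  Practitioner presets in the
  30%/20% range for families of a few hundred to a thousand sequences are
  accepted directly as overrides.
- `max_fraction` — default 1 − min_fraction.  Quasi-invariant columns are
  excluded because near-universal residues co-occur with everything;
  such pairs reflect conservation, not correlation.
- `minlogp` (default 10) and `delta_f` (default 0.2) — an edge needs both
  directional scores *and* their mean beyond minlogp with a common sign
  (mixed-sign pairs are statistically pathological and dropped), and both
  conditional frequencies beyond the Δf band: above 1−Δf for positive
  edges, below Δf for negative ones.  Strict inequalities are used; edge
  counts are monotone in both thresholds.
- `identity_cutoff` — optional culling: a single greedy pass in input
  order compares each sequence to all retained predecessors; of any pair
  above the cutoff the sequence with fewer non-gap residues is removed
  (ties: the later one), keeping the most informative representative.
  The pass is deterministic and idempotent.

## Signed modularity and its optimisation

Q is the Gómez signed generalisation: weighted Newman modularities of the
positive and negative subgraphs combined with weights w⁺/(w⁺+w⁻) and
w⁻/(w⁺+w⁻); a missing sign class contributes zero.  The standard null
model (self-pair terms included) is used, so the whole-graph-in-one-
community partition always scores 0 and a lone positive edge split in two
scores −0.5.  All optimisers operate on the fixed matrix B with
Q = Σ_{same community} B_ij.

`detect_communities` evaluates: the two trivial baselines; a greedy
agglomerative pass tracking the best partition along the merge path; and
`n_restarts` (default 10) tabu searches from random partitions —
single-vertex moves to any community or a new singleton, tenure
⌈n/4⌉, aspiration on new incumbents, stopping after 100 non-improving
iterations.  Every candidate is refined by a fine-tuning pass of best
single-vertex moves *and* best community merges until neither improves.
Community-merge moves matter: pure single-vertex refinement can stall
when two halves of one natural community must cross a negative saddle.
The best candidate wins; equal-Q ties resolve to the lexicographically
smallest canonical assignment (communities numbered by descending size,
then smallest member label), making results reproducible.  On random
signed graphs of ≤ 10 vertices the heuristic attains the enumerated
global optimum (asserted over hundreds of graphs).

`exact_partition` enumerates set partitions by sequential placement with
an admissible optimistic bound for pruning; it is a test oracle, capped
at 13 vertices.

## Community statistics

- *Self-correlation matrix*: overall member frequencies and the full
  conditional matrix (row r's residue frequency among carriers of column
  c's member), percentages, full precision internally and one decimal in
  reports.
- *Δ_AB*: mean signed **raw** score over member pairs — sub-threshold
  pairs contribute their actual score, not zero, so weak but consistent
  relationships register.  The default is direction-resolved (source
  community perturbs), which is what makes Δ_AB and Δ_BA differ slightly;
  a symmetric mean-score mode is available.  Δ_AA averages unordered
  within-community pairs and is defined as 0 for singletons.  Member
  pairs sharing a column (possible across exclusive communities) have no
  defined score and are excluded from the average.
- *Member ranking*: repeatedly remove the member with the lowest mean raw
  score against the members still present (mean and sum are
  order-equivalent within a round; the mean is reported), down to the
  final pair.  Raw scores are used rather than surviving network edges so
  that an anti-correlated "outlier" member — compulsorily placed by the
  partition — ranks first out with a visibly negative mean.  A flag to
  score against the original member set instead of the shrinking one is
  deliberately not provided: recomputation against the remaining members
  is the behaviour consistent with the elimination semantics.
- *Adherence*: Adh(S, A) = Σ w_ij δ_S(i,j) / Σ w_ij over unordered member
  pairs, with w the positive intra-community edge weights (pairs without
  a stored edge contribute zero to both sums) and δ_S = 1 iff S carries
  both residues.  Bounded in [0, 1]; exactly 1 when S carries every
  member residue and 0 when it carries none.  Undefined (error) for
  communities with no positive internal weight.

## Synthetic benchmark

`generate_alignment` plants sub-family structure over an i.i.d.
background: per-column categorical draws with symmetric Dirichlet(1)
compositions over a 6-letter alphabet (narrow enough that background
marginals routinely enter the eligibility band, so the null is actually
exercised).  Class members carry their class residue with probability
`fidelity`; exclusive classes partition the sequences and share columns
with disjoint residues; independent classes are assigned independently on
disjoint columns.  At class columns the non-class residues are drawn from
the full remaining amino-acid alphabet: positions diagnostic for a
sub-family are typically heterogeneous outside it, and a narrow residual
alphabet there would manufacture spurious high-frequency "satellite"
nodes that are no part of the planted truth.

The standard fixture (two exclusive 6-residue classes, fractions
0.50/0.45, one independent 6-residue class, fraction 0.5, fidelity 0.95,
N = 800, 50 columns) is the study condition for the recovery, Δ and
adherence tests; the background/shuffle condition uses 675 × 200 with the
same planted layout.  What the generator does **not** emulate: indels,
phylogenetic correlation between sequences, column-specific substitution
preferences, or fragments.  Passing tests therefore demonstrate
correctness of the machinery and behaviour under the method's own
assumptions — not robustness to tree-structured redundancy beyond what
identity culling removes.

## Problem sizes and determinism

Test and benchmark sizes (N = 675–800, L = 50–200, 50 shuffle replicates,
20 recovery replicates, 100 oracle graphs) were chosen so the whole suite
runs in well under a minute of scoring time while keeping every binomial
count in the regime the thresholds were designed for.  All randomness
flows through explicit integer seeds (numpy Generator); reruns are
byte-identical, and the pipeline manifest records the seed and settings
of every run.

## Known limitations

- Identity culling is the only phylogenetic correction; deeply unbalanced
  taxon sampling can still inflate scores.
- Signed modularity compulsorily assigns every vertex, so anti-correlated
  outliers land *somewhere*; the ranking and self-correlation reports are
  the intended tools for spotting them.
- The tabu/agglomerative optimiser is exact in practice only for small
  networks; for hundreds of vertices it is a heuristic like any
  modularity maximiser, and the usual resolution-limit caveats apply.
- Δ_AB and adherence are descriptive statistics; no calibration into
  probabilities or significance levels is attempted.
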