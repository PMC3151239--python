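# Methods

## Model and procedure

The scanner asks, for each branch of a combined reference tree and each
single-copy gene family, whether the family's alignment supports the
branch where it stands or confidently prefers a different position.

**Placement set.** The clade the branch defines is pruned; its two
flanking branches merge into one (lengths summed), and the exact original
attachment point on the merged branch is remembered. One candidate
insertion point is placed at the midpoint of every residual branch —
2m−3 points for m residual leaves — except that on the branch carrying
the original attachment the exact attachment point itself is used, so the
original placement is always a member of the candidate set and is
recovered exactly when regrafting there. Midpoint insertion is a
convention (nothing in the displacement model says where on the target
branch a subtree attaches); it is symmetric, makes the path-length
distance well defined, and is configurable to the proximal endpoint.

**Likelihood.** Sitewise log-likelihoods come from Felsenstein pruning
under the JTT amino-acid model, with per-node rescaling against
underflow. The rate matrix uses the published JTT exchangeabilities and
frequencies, normalised to one expected substitution per site per unit
branch length. Per-family scans default to empirical ("+F") frequencies
counted from the alignment (zero counts floored at 1e-6 to keep the
chain irreducible) and to a single rate category; a discrete-gamma model
(Yang's equal-probability mean-per-category scheme, default 4 categories,
user-supplied shape α) is available by flag. Single-rate default reflects
how per-family placement runs are usually done with default program
settings; rate heterogeneity matters more for tree *construction*, which
is out of scope here (the combined tree is an input).

**Placement engine.** Evaluating ~2m−3 candidates per branch naively
costs a full pruning pass each. Instead, for the residual tree we compute
the conditional likelihood vector of every *directed* edge ("outside"
partials) once, plus the pruned subtree's own partial; a candidate
attachment then needs only three 20×20 transforms per site, and the three
branch lengths a regraft creates (the two halves of the split branch and
the subtree's stem) can be re-fit by bounded 1-D coordinate descent
(Brent, lengths clamped to [1e-8, 20], ≤5 sweeps, tolerance 1e-4
log-units) against fixed partials. Candidates more than 30 log-units
below the current best are not re-fit: a three-branch re-fit cannot
bridge such a gap, and the RELL weights of such candidates are
numerically zero either way. Full branch-length re-optimisation of whole
candidate trees is available through
`likelihood.optimize_branch_lengths(scope="full")` but is not the scan
default.

**ELW.** Expected likelihood weights are computed by RELL bootstrap:
sites are resampled with replacement (multinomial counts), each
candidate's replicate log-likelihood is the weighted sum of its sitewise
values, replicate weights are a softmax over candidates (computed in
log-sum-exp form), and the ELW is the mean weight over B = 1000
replicates (B configurable). Weights are nonnegative and sum to exactly
1 over the candidate set, so at most one candidate can exceed 0.5 —
which is why the calling cutoff is constrained to (0.5, 1] and every
(family, branch) pair yields at most one call. Every (family, branch)
evaluation derives its own resampling seed from the configured base seed
by a stable hash, so results are independent of execution order and of
which other families are scanned.

**Calling.** A displacement is called when the best non-original
placement has ELW ≥ 0.65 and lies at path-length distance ≥ 0.40
substitutions/site from the original attachment, measured on the
residual tree from the exact original attachment point to the candidate
point. Both cutoffs are inclusive by default; a strictness flag switches
the distance comparison to strictly greater, since either reading of a
"minimum distance" rule is defensible. The distance guard exists because a confident but
*nearby* alternative placement is better explained by phylogenetic
uncertainty than by transfer. The donor is reported as the combined-tree
branch on which the winning insertion point lies; for a point on the
merged branch, the pre-merge segment containing it decides.

**Filters.** Two post-calling rules: (1) if one family calls both X→Y
and Y→X, both are discarded — the direction of transfer cannot be
identified; (2) calls whose donor branch is root-ward of (ancestral to)
their recipient are discarded. The parameter grid (ELW 0.55–1.00 in
steps of 0.05 × distance 0.1–1.0 in steps of 0.1) re-applies calling and
filtering at each cell — the canonical 100-cell cutoff exploration.

## Synthetic data: what it emulates and what it does not

`synthdata` generates the study conditions end to end: a pure-birth
(Yule) species tree (default 12 taxa, branch lengths scaled so the tree
totals 8 substitutions/site — deep-phylogeny scale, pendant branches a
few tenths of a substitution per site); transfers as SPR moves of a
recipient clade onto the midpoint of a donor branch at residual-tree
distance ≥ 0.6 (displacement semantics: the recipient's gene copy now
descends from the donor; branch lengths are inherited unchanged);
alignments evolved forward under the same JTT model the scan uses
(default 500 sites, root states from π, per-site rate category uniform);
and Brownian trait tables (GC% reflected into [25, 75], log-normal
genome sizes around 3 Mb, multinomial habitat counts over six categories
with Brownian logit weights). The birth process is stopped at the n-th
speciation and every tip is extended by one exponential waiting time, so
the tree stays ultrametric and no pendant branch has length zero.

What it does **not** emulate: alignment error, indels, among-family and
among-lineage rate variation, model misspecification (sequences evolve
under exactly the scan's model), unsampled donors, and ancient signal
decay. Passing recovery tests on this generator therefore demonstrates
the machinery is correct and the statistics behave as designed — not
that real-data sensitivity reaches the same level.

**The reciprocal-filter trade-off.** On this idealised generator the
transferred clade and its donor form a cherry whose shared stem supports
the sister relationship *in both prune directions*: pruning the donor
branch almost always yields a confident mirror image of the true call,
and the reciprocal filter then removes both. This is the filter working
as specified — on perfectly symmetric, noise-free signal the direction
of transfer genuinely cannot be oriented from topology alone. The
recovery surface therefore scores *sensitivity* on the detection-stage
calls (before filtering), where the injected transfer is recovered with
the exact recipient and donor in ≥ 80% of replicates, while *false
positives* are scored on the conservative post-filter output, where
clean families are silent in ≥ 18/20 seeds. On real data, asymmetric
noise, denser taxon sampling and unsampled donors break the mirror
symmetry, so reciprocal doubles are expected to be the exception rather
than the rule in practice.

A transfer-bearing scan also produces *echo* calls on branches adjacent
to the true recipient or donor (see the worked example in the README):
the residual trees those branches are tested against still contain the
displaced copy, so they too prefer placements near the donor. Echoes are
a property of per-branch testing, not false positives of the
implementation; on clean families no such calls arise.

## Factor analyses, dating, rate

Ancestral states are deliberately simple clade summaries: unweighted
means (GC%, genome size in Mb) and summed habitat observation counts
converted to proportions — no model-based ancestral reconstruction.
Habitat distance is the Euclidean norm between two 6-category profiles
(range [0, √2]). Donor–acceptor evolutionary distance is the path length
between branch midpoints on the full combined tree; its null
distribution enumerates all unordered branch pairs excluding nested
(ancestral) pairs, mirroring the ancestral-donor filter so observed and
null share the same support.

Dating treats the transfer as a time anchor: donor and acceptor
coexisted, so on a clock-like tree the distances from their last common
ancestor to each branch's midpoint, widened by half the branch length on
each side (the event may have happened anywhere along either branch),
must overlap. On exactly ultrametric trees every temporally possible,
non-nested pair overlaps by construction; the fraction of overlapping
intervals on real branch lengths measures how clock-like they are.

The rate analysis pairs each clade's total internal branch length
(evolutionary opportunity; a leaf branch contributes its own length, an
internal branch the sum of lengths strictly inside its clade, its own
subtending branch excluded) with the number of calls whose recipient
falls inside the clade, either for every branch or for a user-named set
of independent clades. Linearity of count~length is interrogated three
ways: the OLS slope t-test, a quadratic-term t/F-test (lack-of-fit
proxy), and a Wald–Wolfowitz runs test on residual signs ordered along
the fitted axis (exact run-count tail probabilities up to n = 20,
continuity-corrected normal approximation beyond; exactly collinear
data reports runs p = 1 with a degeneracy flag). Linearity and runs
tests of this kind are usually delegated to R packages whose internals
differ in detail; the implementations here are transparent, documented
equivalents rather than emulations of any particular package. KS, Wilcoxon
rank-sum (continuity-corrected, exact when n·m ≤ 400 without ties, W
defined as R's statistic) and Pearson tests are delegated to scipy
behind this module's interface; the KS p-value uses the classical
Kolmogorov limiting distribution. All p-values are reported raw, with no
multiple-testing correction, and the CLI says so.

## Numerical choices

- Transition matrices by spectral decomposition of the reversible
  generator (symmetrised in the π^½ similarity frame), clipped to [0, 1];
  exact to ~1e-15 against `scipy.linalg.expm`.
- Pruning partials rescaled per node by the per-site maximum; log scale
  accumulators carry the magnitudes.
- ELW normalisation enforced exactly by a final renormalisation (the
  softmax already sums to 1 up to round-off).
- Branch lengths clamped to [1e-8, 20] substitutions/site during
  optimisation; zero-length input branches are legal everywhere.
- Newick round trips preserve lengths to 12 significant digits; trees are
  validated as strictly bifurcating at parse time (polytomies rejected —
  the 2n−3 placement algebra assumes bifurcation; resolve upstream).
- Branch enumeration is a deterministic post-order anchored at the
  lexicographically smallest leaf (or at the root point when set), so
  reports are byte-reproducible.
- A `BranchRef` may name either side of a bipartition; the named side is
  treated as the clade (pruned side, trait clade), which also covers the
  branch that carries the root point.

## Known limitations

- Single-copy families only: no paralogs, duplications or losses.
- The donor of an ancient transfer is reported as a branch of the extant
  tree even when the true donor lineage is unsampled or extinct.
- Local (3-branch) re-fitting slightly underestimates candidate
  likelihoods relative to full re-optimisation; both modes are exposed
  and calls can differ marginally between them.
- The recovery guarantees quantified by the test suite are for the
  synthetic generator's regime (10–12 taxa, 500 sites, transfer distance
  ≥ 0.6 substitutions/site); smaller distances approach the
  phylogenetic-uncertainty guard by design and are not called.
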