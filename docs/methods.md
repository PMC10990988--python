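# Methods

This note documents the models, defaults and numerical choices behind
`multiarrange`, and what the synthetic studies do and do not show.

## Stimulus design

Sentences are transitive event descriptions with an adverb-first surface
template ("&lt;adverb&gt; the &lt;agent&gt; &lt;verb&gt; the &lt;patient&gt;").  The
default vocabulary holds 24 nouns in four professional domains (medicine,
manual labor, sports, music), 12 verbs in two action domains
(communication, physical) and six temporal adverbs in two day-groups
(same-day, previous-day).  Generation satisfies five numbered constraints
— (1) each agent noun pairs once with a same-category and once with a
different-category patient, (2) every noun serves in both roles, (3) noun
categories appear equally often, (5) each noun category co-occurs equally
often with both verb categories, (6) each adverb precedes exactly two noun
categories and both verb categories equally often.  The numbering skips
(4) deliberately: the design history never had a fourth constraint and
keeping the gap leaves the other numbers citable.

The generator uses constraint-guided shuffling with rejection (cap 10,000
retries per stage) rather than exact combinatorial construction: the
same-category block uses per-category derangements, the different-category
block deals agents and patients through a balanced category-count table,
verb categories are drawn per agent-category half/half and resampled until
the patient margin balances, and adverbs are dealt through a bipartite
cover.  All stages are driven by one `numpy` Generator, so output is
bit-identical for a fixed seed.  Infeasible vocabularies (unequal
category sizes, odd splits, indivisible adverb covers) raise an error
naming the violated constraint.

Reference similarity is scored 0–3: bag-of-words = multiset overlap of
the two sentences' noun categories + shared verb category; relational =
agent-category match + patient-category match + shared verb category.
Reference *dissimilarity* is 3 − score; every downstream comparison is a
rank correlation, so any monotone choice is equivalent.

## Arrangement engine

The engine assumes a circular arena of radius 1.  Placement error is
modelled as an isotropic Gaussian of scale σ (default `placement_sigma` =
0.3 arena units) that is constant across trials, so the signal-to-noise
ratio of a pair placed at distance *d* is *d*/σ and its evidence
increment is (*d*/σ)².  With the default, a mid-arena pair contributes
evidence ≈ 1–4 per placement, so a handful of displays saturates a pair.
The utility of further evidence is *u(w) = 1 − e^{−wd}* with steepness
*d* = 10; sessions terminate when every pair reaches evidence 0.5 (where
utility is ≈ 0.993) or when the trial budget is spent.  Budgets replace
the wall-clock limits of live sessions: 40 trials for sets up to 24 items
and 120 above, bracketing the mean trial counts observed in live cohorts
(≈ 37 and ≈ 112).  Standard session layouts: the noun task shows all 24
items first with subsets of 3–24 after; the sentence task shows 10 of 48
first with subsets of 3–10.

Subset selection has two phases.  While any pair is unseen, the display
is grown greedily by the item that adds the most unseen pairs *with the
items already on display* — this covers all n(n−1)/2 pairs within ≈ 30
displays of 10 for 48 items, after which adaptive refinement begins.
(A simpler global unseen-degree ranking was tried first and left hundreds
of pairs uncovered within budget because the chosen items' mutual pairs
were already seen.)  Once covered, the display seeds with the globally
minimum-evidence pair (ties to the lowest pair index) and grows by the
single item that maximizes expected summed utility gain divided by trial
cost (cost = 1 + 1·|subset|, a stand-in for drag-and-drop time), stopping
when every addition would reduce efficiency; size is clamped to
[min_subset, max_subset].  Expected gains use predicted distances: the
current estimate rescaled so the subset's largest dissimilarity spans the
arena diameter, with unseen pairs at the subset median.

Partial arrangements are merged by iterative scale-and-average: each
trial's distance vector is aligned to the evolving global estimate by a
least-squares scale factor, then every pair is averaged over trials with
weights equal to the squared SNR of the *aligned* distances.  Weighting
by aligned rather than raw on-screen distances makes the result exactly
invariant to rescaling any one trial's coordinates (the alignment absorbs
the scale), which raw-distance weights would violate.  Iteration stops at
relative change < 1e−6 or 100 rounds, and the result is canonicalized to
unit RMS — combined RDMs are defined only up to scale because every trial
contributes relative distances.  Pairs never displayed stay NaN; asking
for a final RDM with unseen pairs raises an error listing them.

## Synthetic raters

A rater's ground truth is Σ_k w_k·M_k over binary dimension RDMs with
nonnegative attentional weights w.  Subset arrangements embed the
sub-RDM in 2D by metric MDS — classical (Torgerson) solution as the
initial configuration, refined by SMACOF (n_init = 1, eps = 1e−10) — then
center, rescale so the farthest item touches the rim, add N(0, σ²)
jitter per coordinate, and pull escapees back to the rim.  The classical
start makes the embedding exact for 2D-embeddable inputs and the whole
placement deterministic per (profile seed, trial index).

Three cohort generators serve different purposes:

- `simulate_cohort(..., mode="session")` runs the full adaptive engine per
  subject — the highest-fidelity but slowest emulation.
- `simulate_cohort(..., mode="single_arrangement")` takes one full-set
  arrangement per subject; it keeps the 2D compression of a lone display.
- `mixture_cohort_rdms` emulates *final estimated* RDMs directly as
  noisy linear mixtures.  Because multi-arrangement estimates are built
  from many small displays (each nearly faithful in 2D), final RDMs are
  close to linear in the attended dimensions; this generator captures
  that regime at a fraction of the cost.

The `mixture_cohort_rdms` defaults were calibrated once against the
observed group regime of the sentence task: Dirichlet concentrations
(1.2, 0.2, 0.2, 0.1, 0.1) over (verb category, verb identity, adverb,
agent, patient) plus 0.5 on one *idiosyncratic* private binary dimension
per subject, and estimation noise of SD 0.75 × the subject's signal SD.
Under these conditions a simulated cohort's group average correlates with
the verb-category model at ρ ≈ 0.86 while the average raw role contrast
is statistically indistinguishable from zero — the hallmark of strongly
verb-dominant, sparse attention in which only a minority of subjects
express role structure.  The idiosyncratic dimension models individual
sorting strategies that never generalize across subjects (the
rank-selection rule is explicitly designed to ignore them).  A smoother,
denser weight prior (concentrations (8, 2, 2, 3, 3), kept as the default
for the arrangement-level `CohortConfig`) gives every subject ≈ 17% mean
patient weight; a cohort t-test detects that at p < 0.01 under any
plausible noise, which no verb-dominant live cohort shows — hence the
sparse calibration for the estimated-RDM generator.

What the simulator does *not* model: reaction times, learning or fatigue
across trials, asymmetric similarity, pile-making shortcuts, and the
visual/typographic confounds of on-screen sentences.  Passing recovery
tests therefore show that the algorithms are correct under the stated
generative assumptions, not that human data meet those assumptions.

## Factorization

`build_ensemble` stacks row-major upper-triangle vectors, one subject per
row, each divided by its SD (exposed as a flag) so every subject
contributes at the same scale.  NMF minimizes ‖D − WH‖²_F by coordinate
descent from a seeded uniform-random start (max 2000 iterations,
tolerance 1e−6; non-convergence is flagged on the returned fit, and the
reported fit is recomputed from W and H directly).  The rank rule: for
each restart, a component is *general* if it is the argmax mixing weight
of at least 2 subjects; the restart votes for the largest k ∈ [2, 19]
with all components general (1 if none), and k\* is the rounded mean of
votes.  The k-scan runs its fits at a coarser solver setting
(max_iter = 500, tol = 1e−4): it only reads which component dominates
each subject, which stabilizes long before the objective converges, and
the coarse scan returns identical k\* at roughly an eighth of the cost.

Stability clustering pools unit-normalized components of all restarts,
computes the distance 1 − |Pearson r|, clusters with average linkage and
cuts at 0.85.  Clusters spanning ≥ 72% of restarts are retained and
averaged into unit-norm centroids (reliability order); mixing weights are
then refit per subject by nonnegative least squares, with subjects whose
residual exceeds 95% of their data norm flagged as unexplained.

**Known identifiability limit.**  Under a 1 − |r| cut at 0.85, two
dimensions whose model vectors correlate at |r| > 0.15 can never keep
separate clusters, whatever the linkage — their tight restart clusters
merge below the cut.  The sentence design itself creates such pairs:
sharing a verb implies sharing its category (verb identity ~ verb
category, r ≈ 0.27) and each adverb precedes only two agent categories
(adverb ~ agent, r ≈ 0.19).  Planted-recovery studies therefore use
*independent* random balanced binary dimensions, where the pipeline's
recovery is essentially exact (centroids |r| ≈ 0.999, weight recovery
r ≈ 0.98, variance explained ≈ 0.997); on the design's own correlated
dimensions the pipeline still recovers every dimension per restart but
reports merged centroids.  Empirical components from noisy heterogeneous
cohorts decorrelate enough that the threshold separates them in practice.

## Role-controlled contrast

For ordered noun categories (X, Y), X ≠ Y: reference subset = sentences
(agent X, patient Y); *semantics+role* subset = (agent Y, patient Y),
sharing Y in the same patient role; *semantics-only* subset = (agent Z ∉
{X, Y}, patient X), sharing X in the opposite role.  A pairing is kept
only when both comparison subsets exist with identical verb-category
proportions, so verb structure cancels from the difference (semantics-only
minus semantics+role); the generated design admits 16 such pairings (8
are skipped for composition mismatch).  By construction the agent
dimension also cancels (both comparisons mismatch the reference agent),
so the expected difference equals the patient-dimension weight — exactly
1 per pairing for the relational reference, exactly 0 for any
dissimilarity that depends only on the unordered noun-category multiset
plus verb category (the bag-of-words family).  Dimensions outside that
family (e.g. adverb identity) cancel only in expectation, not exactly.
The aggregate is tested by a one-sample, one-sided t-test of mean
difference > 0; degenerate inputs (fewer than two values, zero variance —
which the exact reference matrices produce by design) return NaN with a
warning rather than a fabricated p-value.  Per-subject application
computes the contrast on each subject's RDM and tests the per-subject
means.

Subject exclusion counts a pair as "rated" once it has any accumulated
evidence; subjects under 50 rated pairs are dropped, and exactly 50 is
retained.

## Problem sizes in the test suite

The shipped studies run at sizes chosen to exercise every code path at
full statistical fidelity: arrangement recovery at 8 items × 20 seeds ×
two noise levels; factorization recovery at 40 subjects × 1128 pairs with
20 k-scan restarts and 50 clustering restarts; the dissociation study at
30 subjects × 20 seeds with 20 restarts per seed.  The CLI default of 200
clustering restarts (1000 reproduces the original protocol) trades a
small reliability-resolution loss for an order-of-magnitude speedup.
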