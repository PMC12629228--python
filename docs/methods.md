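# Methods

## Problem setting

A transcriptomic signature is a vector of gene-level z-scores summarizing
how a perturbation shifts expression relative to control.  Connectivity
analysis scores the concordance between a query signature and each member
of a reference repository: strong positive connectivity suggests a shared
mechanism of action, strong negative connectivity suggests the reference
perturbagen reverses the query state and is a drug-repurposing candidate.
`sigconnect` implements the scoring engine for such screens; it assumes
query and references already share a gene identifier namespace (no
symbol/probe mapping is attempted) and that z-scores are comparable across
signatures, as is the case for moderated level-5 consensus signatures.

## Scores

All ranks are 1-based; ties in any z sort are broken by lexicographic gene
identifier so every ordering is reproducible across platforms and storage
orders.

**Pearson / Spearman / cosine** operate on the matched z vectors over the
genes shared by query and repository universe.  Spearman uses mid-ranks
for ties.  Zero-variance or zero-norm inputs raise rather than returning
a silent NaN.

**Extreme-gene selection.**  The query's up set is its K largest-z genes
in descending order, the down set its K smallest in ascending order
(K = 50 by default; 100/150/200 are common alternatives, any K with
2K ≤ universe size is accepted).  Selection happens after alignment to
the repository universe, so every extreme gene has a reference-side
value.  When z ties span the middle of the list, the down set is filled
from genes not already taken by the up set, preserving disjointness.

**WTCS.**  For each set, a weighted Kolmogorov–Smirnov running sum walks
the reference ranking (z descending): a hit at gene g adds
|z_ref(g)|^w normalized by the set total, a miss adds −1/(N − K); the
enrichment score is the signed maximal deviation, taking the earlier
deviation at an exact magnitude tie.  The weight exponent w is fixed at 1
(hits weighted by |z_ref|).  If every set gene carries exactly zero
reference weight the hit increments fall back to uniform 1/K — a
degenerate case reachable only with constant-zero reference regions.
WTCS is (ES_up − ES_down)/2 when the components have strictly opposite
signs and exactly 0 otherwise; components agreeing in sign are evidence of
neither mimicry nor reversal, and the zero rule also makes WTCS
antisymmetric under query negation.

**CSS.**  Reference genes receive signed ranks rank(|z|, ascending over
the N universe genes) × sign(z); the 2K query extremes receive the
analogous signed ranks computed among themselves.  The raw strength is
the inner product over the extremes; the normalizer pairs the 2K largest
reference rank magnitudes with the sorted query rank magnitudes, largest
with largest, so ±1 is attained exactly when the query extremes are the
reference's strongest genes with matching signs and importance order.
|z| ties get average ranks, consistent with the Spearman convention.

**XSum.**  Reference z-scores are zeroed outside the reference's own
top/bottom `ref_extreme_n` genes (default: equal to K); the score is the
sum over query up genes minus the sum over query down genes.  XSum is
unbounded; its scale grows with K and with the reference's tail z values.

## Permutation null and p-values

CSS and XSum significance uses a query-independent permutation null per
reference: each of `n_perm` (default 10 000) iterations draws 2K distinct
genes uniformly without replacement, randomly splits them into ordered up
and down lists of K, and records the statistic against the fixed
reference.  For CSS the query-side importance magnitudes are a fresh
uniform permutation of 1..2K each iteration, randomizing membership and
importance order.  This "random query set" null coincides in distribution
with permuting reference gene labels for fixed set sizes, and — unlike
label permutation — allows the expensive nulls to be precomputed once per
reference and reused for every query.

Empirical p-values are one-sided in the screen direction (upper tail for
positive screens, lower for negative) with the add-one rule
p = (1 + #{null ≥ obs}) / (n_perm + 1), so p is never 0 and is bounded
below by 1/(n_perm + 1).

Substream seeds are derived by hashing (master seed, sig_id, method, K),
making backgrounds bit-reproducible regardless of build order or
parallelism.  The on-disk store keeps one `.npz` per reference plus a JSON
manifest; lookups check that the stored `n_perm` matches the requested one
and refuse stale backgrounds.

## Screen orchestration

1. Align the query to the repository universe (genes absent from the
   universe are dropped, never imputed; below `min_overlap_frac` = 0.8
   retained the screen aborts, which in practice signals mismatched
   identifier namespaces).
2. Compute Pearson, Spearman, cosine, CSS and XSum for every reference
   (the first three vectorized over the whole matrix).
3. Each method casts votes: a reference votes 1 when its directional
   effective score — the raw score in a positive screen, its negation in
   a negative screen — ranks within the top ceil(vote_quantile × S) of
   the S screened references (vote_quantile = 0.05).  When a background
   store supplies CSS/XSum p-values, those two methods rank by p
   ascending instead.  Ties break by sig_id.
4. WTCS is computed only for references significant by ≥ 1 of the five
   (significance = that method's vote under the default rule; a
   p ≤ 0.05-based gate is config-selectable).  WTCS votes use the full
   screen size S as the cutoff denominator, with ungated references
   ineligible, keeping the 5% semantics comparable across methods.
5. The meta-score is the sum of the six votes (0–6).
6. Final ordering: meta-score descending, then a consensus score —
   the mean of the six directional percentile ranks (ungated WTCS counted
   as 0) — descending, then sig_id.  The percentiles are the same
   quantities the radar plot draws, so the ordering key is exactly "how
   high this reference sits across all six methods".  The ordering key
   was an open design choice; a single-method score would make the
   within-meta-score order depend on an arbitrary method pick, while the
   consensus percentile uses all available evidence and preserves the
   reversal duality (negating the query and flipping the screen direction
   yields the identical ranking).

Work is partitioned by reference signature across threads and merged
before the deterministic sort, so reports are byte-identical across
worker counts.

## Synthetic repositories

The generator emulates the structure of a level-5 reference repository at
desk scale: a shared gene universe, null signatures with i.i.d. standard
normal z, and planted signatures α·standardize(q) + ε (mimic) or
−α·standardize(q) + ε (reversal) with ε ~ N(0, noise_sd²).  Defaults:
1000 genes, 500 signatures, α = 1, noise_sd = 0.3 — a planted reversal
then has Pearson ≈ −0.96 with the query, a strong but not noise-free
signal.  The query is standardized before planting so α means the same
thing for any query scale.

What the generator does **not** emulate: gene–gene correlation, dose–
response and exposure-time structure, cell-line batch effects, and the
heavy-tailed z distributions of real signatures.  Passing tests therefore
demonstrate correctness of the scoring and screening machinery and
recovery of planted signals under an idealized null — not performance on
real repositories, where correlated genes inflate null connectivity and
method disagreement is larger.

## Problem sizes and numerical choices

The test suite and acceptance checks run at deliberately modest sizes
chosen as the package's own desk-scale study conditions: oracle
equivalence on universes of ≤ 12 genes (where brute force is exact),
the exact-null comparison at N = 6, K = 1 with 10 000 draws, p-value
uniformity with 1000 permutations and 200 null queries, and planted-
reversal recovery on 500 nulls × 1000 genes over 20 replicates.  Score
comparisons use absolute tolerance 1e-12 (pure floating-point
reassociation); the Monte-Carlo CDF check uses sup-norm 0.02, consistent
with the Dvoretzky–Kiefer–Wolfowitz bound at 10 000 draws.

Degenerate inputs fail loudly: duplicate or missing genes, non-finite z,
zero-variance signatures, 2K exceeding the universe, empty backgrounds
and mismatched `n_perm` all raise with messages naming the offender.

## Known limitations

* No normalized connectivity score (NCS) or tau percentile scaling; the
  meta-score is the cross-method consensus measure.
* No compound-level aggregation across replicate signatures of the same
  perturbagen, and no mechanism-of-action enrichment statistics.
* CSS/XSum p-values require precomputed backgrounds keyed to the exact
  (sig_id, method, K, n_perm); there is no on-the-fly fallback inside
  `run_screen` (build them with `sigconnect build-background`).
* The remote repository backend is specified as an in-process read
  contract (list / fetch / universe); no HTTP client or server ships with
  the package.
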