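# Methods

`indexweaver` implements the quantitative core of evaluation-index-system
construction by expert consensus: Delphi panel statistics, two-round
critical-value indicator screening, AHP weighting with consistency
testing, and hierarchical combination-weight aggregation. This note
documents the models, the defaults and why they were chosen, the numerical
conventions, and what the synthetic panel generator does and does not
emulate.

## Hierarchy and weight aggregation

An index system is a three-level tree: first-level dimensions, second-level
sub-dimensions, third-level (leaf) indicators. Each node has a *local*
weight — its AHP priority among siblings, so every sibling group sums
to 1 — and a *combination* weight, the product of local weights along the
path from its first-level ancestor. Leaf combination weights therefore sum
to 1 over the whole system.

Published weight tables round to 4 decimals. Tolerances are calibrated to
that: sibling groups must sum to 1 within 5×10⁻⁴ (each printed weight can
carry 5×10⁻⁵ rounding error; a group of ~10 accumulates up to ~5×10⁻⁴),
and leaf combination weights must sum to 1 within 2×10⁻³ (rounding
accumulates again through the products). Internally computed weights are
held to 1×10⁻¹² — the point of the two scales is to distinguish printing
artifacts from genuine errors. Display rounding is half-away-from-zero,
the convention under which the packaged reference table's cells reproduce.

The packaged fixture is a published doctor-evaluation index system for
online medical platforms (3 dimensions / 8 sub-dimensions / 60 leaf
indicators with local weights, plus its panel's response metadata). Two of
its 68 printed combination-weight cells (C42, C51) sit one unit in the 4th
decimal away from the product of the printed local weights: the table's
authors evidently multiplied unrounded intermediates. The package treats
products of printed local weights as ground truth and documents the
one-ulp residue rather than patching either cell.

## Delphi panel statistics

* **Response rate**: 100 × returned/distributed, reported to 2 dp.
* **Authority**: Cr = (Ca + Cs)/2; a panel with Cr ≥ 0.7 is conventionally
  called authoritative. The scoring tables mapping judgment-basis grades
  to Ca and familiarity levels to Cs are rarely published; the defaults
  here follow common practice (practical experience 0.5/0.4/0.3,
  theoretical analysis 0.3/0.2/0.1, literature and intuition 0.1 each;
  familiarity 1.0 … 0.0 over six levels) and are fully overridable.
* **Per-indicator statistics**: arithmetic mean; *sample* SD (n−1) — the
  usual convention in Delphi reporting; single-rater SD is defined as 0 to
  avoid NaN propagation; full-mark rate = share of raters giving the
  maximum score (read literally: only 5 counts on a 1–5 scale);
  CV = sd/mean.
* **Kendall's W** uses midranks for ties (Likert data are heavily tied)
  and the tie-corrected denominator m²(n³−n) − mΣ(t³−t); significance via
  the χ² = m(n−1)W approximation. A panel in which every expert scores
  flat has an undefined W and is reported as a degenerate-panel error, not
  silently as 0. Experts who skipped an indicator are dropped from that
  indicator's statistics and from the concordance matrix (complete-case
  per computation) — the simplest defensible rule, and it is logged.

## Two-round screening

Critical values are computed across the indicators of a scoring population
(per hierarchy level when a level map is supplied; the whole questionnaire
otherwise): mean-of-means − SD-of-means, mean rate − SD of rates, and
mean CV + SD of CVs. Boundary equality passes. Round 1: fail all three →
excluded; fail exactly two → inquiry item; otherwise retained (the
residual one-failure case must be retention for the bookkeeping to
balance). Inquiry items are put to a keep/exclude vote; the agreed
exclusion rate is rounded half-away-from-zero to 1 dp and the item is
dropped when the rate strictly exceeds 50%.

Round 2 applies fixed thresholds — retain iff mean > 3.5 **and**
CV < 0.25, strict inequalities — combined by default with the critical
values recomputed on the round-2 population (an item failing all three
also falls; policy `threshold_only` disables the critical-value part).
Recomputing rather than reusing round-1 thresholds is the default because
the round-2 population differs.

The ledger records every threshold, every indicator's pass/fail vector,
every vote, and per-item provenance; counts are conserved by construction
and property-tested. Editorial post-screening consolidation (merging or
deleting indicators on expert comments) is *not* automated: the engine
accepts an explicit manual-edits record and logs it.

## AHP weighting

Judgment matrices are positive reciprocal matrices on the Saaty 1–9
scale. Priorities default to the principal eigenvector (power iteration,
tolerance 10⁻¹², max 10⁴ iterations; λmax as the Rayleigh ratio), with
the row-geometric-mean method kept as a cross-check — the two coincide
exactly on consistent matrices and agree within ~0.02 absolute on
matrices with CR < 0.1 (checked empirically on seeded random instances).
Consistency: CI = (λmax − n)/(n − 1), CR = CI/RI(n) with Saaty's RI table
for orders 1–15; orders 1–2 are consistent by construction; CR ≥ 0.1 is
reported, never repaired.

When experts rate importance on the Likert scale instead of comparing
pairs, a group matrix is built from per-indicator mean scores: for means
m_i, m_j the grade is g = min(9, 1 + round(|m_i − m_j|/step)), entered as
g or 1/g by sign (ties → 1). The step — the score difference worth one
Saaty grade — defaults to 0.5 Likert units. Published studies seldom
disclose their mapping; two-element groups in the packaged reference
table (priority splits 2:1 and 3:1 for mean gaps of about 0.5 and 1.0)
are consistent with this default but do not uniquely identify it, so the
step is configurable. Group aggregation of per-expert matrices uses the
element-wise geometric mean, the only aggregator that preserves
reciprocity; it is computed on logs so the result is reciprocal to
machine precision.

## Synthetic panels

The generator emulates the study design the pipeline assumes, with
defaults matching the documented panel: 23 invited experts, 69 candidate
indicators, 19 respondents in round 1 and 21 in round 2. A rating is
clamp(round(latent_i + bias_e + ε), 1, 5): latent importances default to
uniform [2.5, 5.0] (pre-screened candidate indicators are rarely rated
unimportant on average); per-expert leniency bias ~ N(0, 0.3); per-rating
noise ~ N(0, 0.6) in round 1, shrunk by a consensus factor of 0.7 per
later round; between rounds each latent importance moves halfway (drift
0.5) toward its observed round-1 panel mean. Discretization is
round-then-clamp rather than truncated-normal sampling — simple and
faithful to an integer scale. Pairwise matrices scatter log-normally
around latent weight ratios and are clipped into [1/9, 9] (clips are
logged); inquiry votes are independent Bernoulli draws. All generators
run off one seeded `numpy.random.Generator` and are bit-reproducible.

What the generator does **not** emulate: expert attrition mid-round,
strategic or correlated voting, question-order effects, and systematic
subgroup disagreement. Passing tests therefore show the pipeline's
statistics and bookkeeping are correct under the stated generative model,
not that any particular real panel satisfies that model.

## Verification strategy and problem sizes

The published consultation released summary tables but not raw scores, so
verification is two-track. Quantities the publication *does* determine —
the weight table (reproduced cell by cell from local weights), the
screening bookkeeping (69 → 63 → 66 → 60 with agreed exclusion rates
52.4% and 71.4%), response rates 82.61%/91.30% — are asserted exactly.
Quantities it does not (raw-score concordance values, per-expert authority
coefficients) are replaced by property checks against independent oracles:
Kendall's W versus a from-definition evaluation over all 3-expert ×
4-indicator rank matrices; eigenvector priorities versus
characteristic-polynomial roots on random 3×3 reciprocal matrices;
noise-free and σ = 0.1 parameter recovery (200 replicates, n = 4, mean
absolute error < 0.02); and screening count conservation on 100
randomized panels of 40 indicators. These sizes keep the full suite
around ten seconds while leaving the Monte-Carlo estimates stable across
seeds.

## Known limitations

* The critical-value scoping population (per level vs whole
  questionnaire) materially changes thresholds; both are supported, and
  the choice must come from the study design.
* The mean-to-Saaty step is identifiable only up to the published
  two-element priority splits; different steps yield different matrices
  for multi-element groups.
* The χ² test for W is an approximation that is weak for small panels; a
  seeded permutation test is available as an option
  (`kendalls_w(..., n_permutations=...)`) but is not the default.
* Editorial merging/deletion of indicators after screening is recorded,
  never inferred.
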