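# Methods

## Model and assumptions

`ccipath` implements first-shell weighted label voting on a
chemical-chemical interaction network. The only model assumption is
assortativity of function: an interaction (reaction co-membership,
structural/activity similarity, or literature co-mention, as aggregated by
STITCH-style confidence scores) makes two compounds more likely to share a
metabolic pathway class. The class score is linear in the evidence — the
sum of edge weights to annotated neighbors per class — so a few
high-confidence neighbors and many low-confidence ones can contribute
equally. No propagation beyond direct neighbors is performed, no
per-evidence-channel weighting is applied (a single combined score column
is used), and no chemical structure information enters the model.

Consequences worth knowing:

- a multi-label neighbor contributes its full edge weight to *each* of its
  classes; large classes therefore attract score mass in proportion to
  their membership, which is intended (class prior times evidence);
- a query with no annotated neighbor is unpredictable; it receives an
  all-tie ranking, is flagged `no_evidence`, and is *kept* in evaluation so
  the accounting identities below stay exact;
- scores scale linearly with the edge weights, so the ranking is invariant
  to a global rescaling of confidences.

## Evaluation framework

Predictions are full permutations of the 11 class codes. Per-order
accuracy ACC_j, the average label count lambda, and coverage L(k) are
defined in the README. Because each true (compound, class) membership
appears at exactly one order of a permutation, `sum_j ACC_j == lambda`
holds exactly; the cross-validation report asserts it to 1e-12, and pair
coverage is computed as the cumulative captured-membership fraction, which
makes `L(k) = sum_{j<=k} ACC_j / lambda` an identity rather than an
estimate. Coverage also supports a stricter *subset* semantics (whole true
set inside the top k); pair semantics is the default because it is the one
consistent with reconstructing published overall coverage from an accuracy
table (e.g. first two orders 77.97% + 14.19% with lambda = 3606/3137 gives
L(2) = 80.2%).

The per-class accuracy matrix reports, for each class m, the distribution
over orders at which m is predicted among compounds truly in m; its
denominator is the number of pooled test compounds annotated to m, so each
populated row sums to 1.

### Folds

Cross-validation folds are stratified for the multi-label setting: classes
are processed from smallest to largest membership, each class's
not-yet-assigned compounds are shuffled with the seeded generator and dealt
round-robin across folds through a rolling cursor. Multi-label compounds
are therefore placed when their rarest class is processed, which keeps
classes with few members represented in every fold; overall fold sizes
differ by at most the number of classes. Whether the historical protocol
shuffled within classes is not documented anywhere we know of, so the
shuffle is seed-controlled and bit-reproducible.

### Tie-breaking

Exact score ties (including the all-zero case) are ordered randomly, per
the reference behaviour. The random order is drawn from a generator seeded
by `(policy seed, CRC32 of the query id)`: runs are bit-reproducible for a
fixed seed, while different all-tie queries still receive decorrelated
permutations — necessary for the null calibration below, since giving every
tied compound the *same* permutation would concentrate ACC_1 on one
arbitrary class. A deterministic lowest-code-first policy is available and
is what the worked-example tests use.

## Tunable parameters

| Parameter | Default | Units / range | Why |
|---|---|---|---|
| `score_scale` | `unit` | `unit` = floats in [0,1]; `stitch999` = integers 0–999, divided by 1000 | curated tables print unit-scale scores; raw STITCH dumps ship integers |
| folds `F` | 5 | ≥ 2 | the standard protocol for this benchmark family |
| coverage `k` | ceil(lambda) | 1–11 | smallest integer covering the average label count (2 for the reference profile) |
| tie policy | seeded random | — | reference behaviour; `code` for deterministic tests |
| `p_in`, `p_out` | 0.05, 0.002 | Bernoulli probabilities | sparse network, mean degree ≈ 9, clear but imperfect assortativity |
| `weight_in`, `weight_out` | U(0.4, 1.0), U(0.15, 0.5) | confidence units | shared-class edges carry systematically higher confidence, overlapping ranges |

Synthetic defaults for class sizes and the label-count histogram follow the
reference benchmark profile (11 class counts summing to 3,606 over 3,137
compounds; 2,820 single-class, …, 2 seven-class, giving lambda = 1.1495 and
baseline 10.45%).

## What the generator does and does not emulate

`simulate` plants assortativity at the label level: any shared class makes
a pair "intra" and raises both its edge probability and its weight range.
It reproduces realistic class-size imbalance, multi-label frequency, and
sparsity. It does **not** emulate STITCH's evidence-channel structure, the
empirical (heavily skewed) confidence distribution, degree heterogeneity
(hubs such as cofactors), or correlations between specific class pairs. A
green signal-recovery test therefore establishes that the predictor and
evaluator correctly exploit planted first-shell assortativity — not that
any particular accuracy level will be attained on real KEGG/STITCH data,
whose headline numbers depend on a historical database snapshot.

## Numerical choices and degenerate inputs

- Class-score accumulation runs in ascending training-id order, so sums are
  bit-reproducible; prediction TSVs print scores to 3 decimals, the
  precision at which confidence scores are distributed.
- Duplicate or bidirectional edge listings merge to the maximum weight
  (conservative for a likelihood semantics) with a warning; self-pairs are
  dropped with a warning; zero-score rows are dropped silently.
- Empty annotation files parse to empty tables; empty query lists produce
  header-only outputs; an edgeless network is a valid input and yields
  pure-tie rankings.
- Seeds are masked to 31 bits before reaching the generators.

## Known limitations

- Compound ids are opaque case-sensitive strings; no mapping between
  STITCH chemical ids and KEGG ligand ids is attempted — inputs must
  already share a namespace.
- Only first-shell evidence is used; compounds two hops from any annotated
  compound are unpredictable by construction.
- The per-class accuracy matrix evaluates a multi-label compound in every
  class row it belongs to; published analogues do not always state their
  convention, so cross-study comparisons of per-class rows should be made
  with care.
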