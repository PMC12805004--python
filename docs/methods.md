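# Methods

## Structures, symmetry, and the parity theorems

A structure is a finite space 𝒮 with a set 𝒯 of generating bijections.
A category system is a partition of 𝒮; on a connected space every block
must be connected (a category covering both ends of a line but not its
middle is not a possible category).  The system is symmetric when its
same-category relation satisfies R_C(x, y) = R_C(t(x), t(y)) for every
transformation t — equivalently, when every group element maps each block
exactly onto a block.  Both formulations are implemented independently
(`is_symmetric` checks the relation over all point pairs;
`induced_block_permutation` computes the block-level action) and the test
suite asserts their equivalence over every connected partition of every
canonical structure at small resolution.

Parity verdicts are proved by exhaustion, not asymptotics: at each
requested resolution the engine enumerates all connected partitions
(contiguous-block enumeration for intervals and cycles; set-partition
enumeration for feature spaces, where connectivity is vacuous), filters
for symmetry, and inspects the sizes.  Exhaustion at bounded resolution
is the contract; verdicts must agree across at least two resolutions, and
disagreement raises an error rather than a warning because it can only
signal a discretization artifact.

### Discretization conventions

These were the genuinely open design choices:

* **Circular spaces are sampled at cell midpoints** — point i sits at
  angle (2i+1)/2n turns — so no sample point lies on the privileged axis
  or its perpendicular.  The two privileged anchors of the bisected
  circle (e.g. the solstices) are represented as *edge markers* at angles
  0 and 1/2, not as sample points.  If the axis itself were sampled, the
  relational symmetry test would spuriously forbid the two-category
  summer/winter split that the underlying continuum clearly admits.  The
  even-parity theorem is unaffected: the half-turn rotation remains
  fixed-point-free on arcs, so it pairs the blocks of any nontrivial
  symmetric system into 2-cycles (asserted directly in the tests).
* **Linear spaces use even n** (no accidental centre point); **bisected
  linear spaces use odd n** so the privileged centre is a real sample
  point that some category must contain.  Violations raise errors naming
  the reason, since an off-parity discretization silently creates or
  destroys privileged points.
* The calendrical anchoring of the circular axis (solstices vs
  equinoxes, which may vary across cultures) is deliberately left
  abstract: the engine proves parity facts about the axis as such.
* Permutations are index arrays composed right-to-left; partitions are
  canonicalized by first-occurrence labelling so each relation R_C is
  counted once.  Group closure is capped at 10,000 elements
  (configurable) to guard malformed custom structures.
* Systems with unassigned points ("holes") are supported behind an
  option: the hole set must be mapped to itself by every group element
  and does not count toward size.  Overlapping (e.g. hierarchical)
  systems are not symmetry-checked; they enter only through extension
  counting in the kinship module.

## Kin-type grammar and inventories

Kin types are parsed from the compact genealogical codes used in kinship
databases (optional speaker-sex prefix m/f, optional relative-age marker
e/y, then an uppercase relative chain; FF = father's father, fZD = female
speaker's sister's daughter).  The sibling inventory is fixed at the 12
speaker-sex-specific types (meB … fyZ); the underspecified covers mG and
fG are excluded because inventories must contain only proper subsets of
the subdomain.  **The inventories for the five non-sibling subdomains
(parents' siblings, grandparents, grandchildren, nieces/nephews, cousins)
are reconstructions**: standard core kin-type lists with paternal/maternal
and, for nieces/nephews, speaker-sex distinctions.  They ship as editable
defaults (`DEFAULT_INVENTORIES`) and any analysis that depends on their
exact membership should state the inventory used.

A language's system size for a subdomain is the number of distinct term
extensions after restriction to the inventory.  This collapses synonyms
and orthographic variants (identical extensions count once) while
counting overlapping categories separately — both properties are
asserted, including a property test that the count is invariant to term
renaming, row order and row duplication.

## Curation rules

* **Glottocode dedupe**: one record per glottocode; when duplicates
  disagree in parity the record *contradicting* the predicted parity is
  kept, so duplicated sources cannot manufacture support for the
  hypothesis.  With no predicted parity the first record is kept with a
  warning.
* **Largest per language**: for domains where sources record nested
  systems (sections within subsections), only the largest per language.
* **Color consensus**: a term counts toward a language's color-system
  size when ≥ 60% of the survey's participants (boundary inclusive;
  threshold configurable) used it for at least one chip.  The denominator
  is the number of distinct participants in the table.
* Records lacking a glottocode are retained in size summaries but
  flagged and excluded from regression, and every filter logs records
  in/out so a pipeline run reproduces a full curation audit trail.
* The power-of-two flag treats 1 = 2⁰ as a power of two; the substantive
  typological claim concerns sizes 2, 4, 8.
* Elicitation bias (Western four-term templates inflating size-4 counts
  for lunar and cardinal systems) is a known property of the sources; no
  correction is defined, so none is applied — summaries only report.

## The parity-preference model

Intercept-only hierarchical logistic regression;
the estimand reported is logit⁻¹(α), the probability that a system is
even for a typical family (all random intercepts at zero).  Priors are
Student-t(3, 0, 2.5) on α and half-Student-t(3, 0, 2.5) on the group
SDs.  "Phylogenetic" structure is represented by family random
intercepts with optional nested language intercepts (required, and
enabled automatically, whenever a language contributes several records):
the available language phylogenies are taxonomies without branch
lengths, and for an intercept-only estimand the family grouping captures
the non-independence a tree covariance would encode.  A tree-covariance
extension would slot in at the family level; exact numeric replication
of published interval endpoints is therefore not claimed, only the
decision-rule outcomes.

### Sampler

Self-contained adaptive Metropolis-within-Gibbs on
(α, log σ_f, z_f, [log σ_l, z_l]) with the non-centered
parameterization u = σz, z ~ N(0,1).  Per iteration:

1. scalar random-walk updates of α and log σ (half-t prior plus log
   Jacobian);
2. a **centered interweaving move** for each scale: propose log σ
   holding the actual deviations u = σz fixed, so the likelihood cancels
   and only the N(0, σ²) density of u and the prior enter, then rescale
   z = u/σ′.  Alternating the two parameterizations decorrelates σ from
   z and is what makes the scales mix when the data are strongly skewed;
3. one vectorized componentwise update of all z coordinates (their
   conditional posteriors are independent given α and σ), with
   per-group likelihoods computed from sufficient statistics (k, n per
   group), so one update costs O(groups) regardless of record count.

Step sizes adapt every 25 warmup iterations toward a target acceptance
rate of 0.44 — the classic optimum for componentwise random-walk
proposals; HMC-style acceptance targets near 0.95 do not transfer to
random-walk samplers and would force near-degenerate steps.  Defaults
are 4 chains × 3000 iterations with 1500 warmup; convergence is gated on
split R̂ (arviz) ≤ 1.01 for α and the σs.  A non-converged fit is
returned flagged with a warning to raise iterations — strongly skewed
domains (nearly all outcomes even) identify σ_f weakly and genuinely
need 6000–10000 iterations, the same escalation applied in practice to
real survey domains.  One master seed deterministically spawns per-chain
seeds; identical configuration and seed reproduce draws bit-for-bit, and
family-label renaming leaves draws unchanged (grouping uses
first-occurrence factorization).

Degenerate inputs: fewer than two observations is an error; complete
separation in the frequentist analog (all outcomes one parity) is
reported explicitly with a one-sided exact Clopper–Pearson 95% bound
instead of a Wald interval.

## Synthetic surveys

The generator emulates the generative structure the model assumes:
families of languages, per-language probability-even
logit⁻¹(logit(θ_even) + family deviation + language deviation), sizes
drawn from parity-matched sawtooth weight maps, optional duplicate
records per language (distinct sources).  Defaults — 30 families × 5
languages, σ_family = 0.5 — give the medium-sized clustered survey the
estimator targets.  Named presets (day-names, seasons,
kinship-siblings) are qualitative shapes, not estimates of archived
data: day-name odd weights are modal at size 5, season even weights at
size 4, sibling even weights at 2 and 4.  A fixed language count per
family is the default; real surveys are more skewed (one family can
dominate a region's sample), which the generator does not emulate, nor
does it model elicitation bias.  Passing tests therefore show that the
pipeline recovers preferences from data with the assumed clustering
structure, not that any particular field survey satisfies those
assumptions.

All generators are pure functions of their seed.

## Problem sizes used in the checks

Parity theorems are proved at resolutions 3–12 (and k ≤ 3 features);
oracle equivalence is asserted exhaustively at n ≤ 8.  Parameter
recovery uses 50 replicates of 150-language surveys per condition at 4
chains × 1200 iterations — chain lengths chosen so the whole recovery
harness runs in a few minutes; the convergence-gated analyses in the
examples and pipeline tests use 2400–6000 iterations as flagged by R̂.

## Known limitations

* Family intercepts approximate, not implement, tree-structured
  covariance; domains dominated by one family carry most information in
  a handful of group-level observations.
* Non-sibling kin inventories are reconstructions (above).
* Disconnected categories arising from dual symmetry (same term for n
  days before and after today) are outside the symmetry test's scope;
  such systems should be sized on the full span before entry.
* The enumeration engine is exhaustive and therefore bounded: feature
  spaces beyond 2³ points fall back to capped set-partition enumeration
  and grow as the Bell numbers.
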