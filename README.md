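# catsym — symmetry and the parity of category systems

Across languages, some semantic domains favor category systems with an
*odd* number of categories (deictic day names like
yesterday/today/tomorrow, grammatical tense), others favor *even* systems
(seasons, cardinal directions, kinship terminologies, Australian social
classification), and others show no preference (folk-biological life
forms).  `catsym` implements the symmetry account of this pattern for
researchers in semantic typology and cognitive science, end to end:

1. **A group-action engine** that represents a domain as a *structure* —
   a finite space 𝒮 plus a set 𝒯 of transformations (bijections
   t : 𝒮 → 𝒮).  A category system 𝒞 is a partition of 𝒮 with
   same-category relation R_C; it is *symmetric* when
   R_C(x, y) = R_C(t(x), t(y)) for every t ∈ 𝒯.  By exhaustive
   enumeration of connected partitions the engine proves, at any small
   resolution, which parities symmetric systems can take:

   | structure | example domains | group | symmetric sizes |
   |---|---|---|---|
   | linear | life forms | D₂ (order 2) | both parities |
   | bisected linear (privileged centre) | day names, tense | D₂ | odd only |
   | bisected circular (privileged axis) | seasons, moon phases, cardinals | D₄ (order 4) | even only* |
   | binary features | kinship, social classes | order 2ᵏ | even only* |

   \* excluding the trivial one-category system.

2. **Counting and curation rules** that turn survey tables into system
   sizes: kin-term extension counting over fixed kin-type inventories,
   per-glottocode deduplication with conservative tie-breaking,
   largest-system-per-language filtering, and the 60%-consensus rule for
   color-naming matrices.

3. **A hierarchical Bayesian parity model**: an intercept-only logistic
   regression yᵢ ~ Bernoulli(logit⁻¹(α + u_family(i) + v_language(i))),
   u_f ~ N(0, σ_f²), v_l ~ N(0, σ_l²), with Student-t(3, 0, 2.5) priors,
   fit by an adaptive Metropolis-within-Gibbs sampler with split-R̂
   convergence gating.  A domain counts as *even-preferring* when the 95%
   credible interval for logit⁻¹(α) lies entirely above 0.5,
   *odd-preferring* when entirely below, *inconclusive* otherwise.  A
   frequentist intercept-only logistic fit is provided as a cross-check.

4. **A synthetic-survey generator** reproducing the statistical shape of
   cross-linguistic surveys (languages nested in families, logit-scale
   family heterogeneity, sawtooth size distributions), so the whole
   pipeline runs and is testable without any data download.

## Worked example

```python
import catsym as cs

# 1. parity theorem for the bisected circle, by exhaustion
verdict = cs.classify_parity("bisected_circular", (4, 8, 12))
print(verdict.verdict)            # -> even

# 2. simulate an even-preferring survey and recover the preference
records = cs.simulate_survey(cs.SurveySimConfig(
    theta_even=0.85, n_families=40, languages_per_family=4,
    sigma_family=0.5, seed=11))
fit = cs.fit_parity_model(
    cs.ParityDataset.from_records(records),
    config=cs.SamplerConfig(chains=4, iterations=6000, warmup=3000, seed=3))
mean, ci = cs.prob_even(fit)
print(round(mean, 3), [round(x, 3) for x in ci])
# -> 0.849 [0.783, 0.914]
print(cs.classify_preference(ci))  # -> even_preferring
```

The posterior mean 0.849 estimates the probability that a system in this
domain is even for a typical family; the interval [0.783, 0.914] excludes
0.5, so the domain is classified as even-preferring — matching the
generating value θ_even = 0.85.

The `examples/` directory holds one short narrative script per
capability (`parity_theorems.py`, `kin_counting.py`,
`survey_curation.py`, `fit_parity_preference.py`); each prints the
numbers it computes and a line on what they mean.  The same operations
are exposed as a thin CLI:

```sh
catsym classify-structure --kind bisected_linear --resolutions 5,7,9
catsym simulate --preset seasons --seed 7 -o synth.csv
catsym analyze --predicted-parity even synth.csv
catsym report config.yaml
```

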