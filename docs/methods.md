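# Methods

## Problem and pipeline

The package classifies two-class user-post corpora from social platforms:
`positive` personas (self-reported depressed / PPD authors) against matched
`control` personas. The pipeline runs in the order: corpus reading →
(optionally) curation → preprocessing → psycholinguistic profiling →
vectorization and feature union → linear classification → evaluation.

## Text preprocessing

Text is lowercased and split into maximal alphabetic runs; every
non-alphabetic character separates tokens, so contractions split ("can't" →
`can`, `t`) rather than fusing into words that were never typed. Two token
views are kept per unit:

- `raw_tokens`: all alphabetic tokens, used for every psycholinguistic count;
- `model_tokens`: `raw_tokens` after removing tokens shorter than
  `min_token_len` (default 3) and a vendored 127-word English stopword list,
  used for vectorization.

Counting lexicons over *raw* tokens is deliberate and consequential: the
stopword list contains `i`, `me`, `my`, `myself` and `all` — most of the
self-related lexicon and one absolutist word — so counting after filtering
would destroy those features. Titles are concatenated before bodies by
default (`concat_title=True`), since per-subject XML writings often carry
substantive titles. Both choices are configurable.

`min_token_len=3` means tokens are words of more than two letters; setting it
to 2 instead (keep words of ≥2 characters) is a supported configuration, as
descriptions of this kind of pipeline are ambiguous between the two readings.

## Psycholinguistic features

Three cues with per-unit values:

| feature | definition | default source |
| --- | --- | --- |
| `abs_rate` | absolutist words per 1,000 raw tokens | vendored 19-word validated absolutist dictionary |
| `self_rate` | self-related words per 1,000 raw tokens | `{i, me, my, mine, myself}` |
| `log_volume` | log10(1 + raw token count) | — |

Matching is exact string equality (no stemming): the dictionary lists surface
forms, and `every` must not fire on `everywhere`. The self-related list is
completed to the full first-person-singular pronoun/possessive set from the
usual exemplars (I, myself, mine); it is configurable. Volume enters as a
log because realistic per-user volumes span orders of magnitude and the raw
count would dominate a linear model.

The rule-based estimator is the standardised continuous 3-vector
`(x − μ)/σ` fitted on training units (population SD; degenerate features get
scale 1). Continuous features were chosen over hard thresholds because they
compose cleanly in a feature union, and because a weakly separated corpus
(equal absolutist rates across classes) should show up as a *weak feature*,
not as an arbitrary rule flip.

## Classification

tf-idf follows the standard smoothed formulation
`idf(t) = ln((1+N)/(1+df(t))) + 1` with L2-normalised document vectors,
vocabulary restricted to `min_df ≥ 2` (configurable) and sorted
lexicographically so fitting is deterministic. The feature union
concatenates the tf-idf block and the rule block with per-block weights,
1.0 each by default.

Families and defaults: multinomial naive Bayes (alpha = 1);
passive-aggressive (squared-hinge loss — the PA-II variant); SVM via SGD
(hinge loss, elastic-net, l1 ratio 0.95); perceptron. All stochastic
families take an explicit seed (default 0). Decisions threshold at margin 0
with ties toward `control`: for a screening task the conservative error is
the false negative we can re-examine, not an irreversible flag.

Two family-specific notes:

- Multinomial naive Bayes cannot consume negative standardised features, so
  when it is paired with the rule block that block is min-max rescaled to
  [0, 1] instead of z-scored. In practice the union degrades this family —
  the rule features act like heavily weighted pseudo-counts that overwhelm
  the tf-idf evidence — and the union is intended for the margin families
  (it was designed around the passive-aggressive classifier); the test suite
  pairs naive Bayes with tf-idf alone.
- Units with zero model tokens are classified at the rule-features-only
  point; with no rule block they receive the majority training class.

Models serialize to a single versioned file; loading a mismatched version
fails loudly, and serialize→load→predict is an exact identity.

## Synthetic corpora

The generator emits token-level mixtures: each token is independently an
absolutist word (probability `p_abs`, uniform over the dictionary), a
self-related word (`p_self`), a class topic word (`topic_weight`, uniform
over a 40-word class lexicon), or a Zipf-distributed background word
(default exponent 1.1 over 5,000 words). Token marginals are the only
structure the downstream features can see, so nothing richer is modelled.
Posts per user are shifted-Poisson (≥ 1), tokens per post Poisson, giving
the closed-form oracle `E[tokens] = posts_mean × tokens_mean` used by the
recovery tests. Per-unit random streams derive from `(seed, class, index)`,
so a corpus is reproducible byte-for-byte and individual units are invariant
to how many others are generated.

Preset parameters keep the published per-token rates and between-class
ratios of the reference collections while scaling per-user volume down ~35×
(600 expected tokens per control user instead of ~21,000), so that corpora
of 200 personas per class generate in under a second:

- `rsdd_like`: control E[tokens] = 600, `p_abs` 0.0091, `p_self` 0.0278;
  positive E[tokens] = 1980 (3.3×), `p_abs` 0.0101 (1.1×), `p_self` 0.0347
  (1.25×); `topic_weight` 0.05 for both classes.
- `losada_like`: equal `p_abs` = 0.0083 in both classes (the absolutist cue
  is uninformative), positive personas write *less* than controls
  (E[tokens] 462 vs 600), self rates 0.0445 vs 0.0202.
- `ppd_like`: post-unit corpus, 300 control / 150 positive posts of ~80
  tokens, class signal carried mainly by topic vocabulary
  (`topic_weight` 0.08) — the configuration for the term-removal ablation.

Domain shift: a `DomainSpec` with `shift = δ` replaces the first
`⌊δ·n⌋` entries of each topic lexicon with deterministic synonym spellings
(`<word>alt`), so topic-vocabulary overlap between a base and a shifted
domain decreases monotonically in δ, hitting zero at δ = 1. Per-post
statistics are free parameters (reference tables are per-user only); the
defaults above are the package's choice of realistic desk-scale values.

What the generator does **not** emulate: grammar, discourse, topic drift
over time, comment trees, label noise, and class-imbalance at the realistic
1:10 ratio of the original collections. Passing tests therefore show that
the pipeline recovers the *statistical* structure it is designed to exploit,
and that its qualitative findings (separability, transfer degradation,
ablation) follow from that structure — not that the same F1 values would be
reached on real corpora.

## Curation

The three cleaning stages are pure per-post predicates applied sequentially
with exact retention accounting: (1) drop posts whose lowercased title
contains a blacklist phrase (seeded with the advertising examples
"share your story here", "volunteers needed for a study"); (2) drop posts
whose body, after deleting URL spans, has fewer than 5 raw tokens
(configurable — the original protocol said only "short phrases") or whose
whole body is a courtesy phrase; (3) drop posts mentioning any excluded term
("postpartum depression", "ppd", "depression"), with single-word terms
matched as whole tokens (so "ppd" does not fire inside other words) and
multi-word terms as flexible-whitespace substrings. Because the predicates
are pure, the final survivor set is order-independent even though per-stage
counts are not.

`strip_terms` is the separate ablation operation: it deletes term
occurrences from titles and bodies without dropping posts, leaves untouched
texts byte-identical, and is idempotent.

## Evaluation

Positive-class precision/recall/F1 plus overall accuracy; zero denominators
yield 0 with a logged warning. Within-corpus evaluation uses a stratified
80/20 split with a fixed seed (the original splits are not available;
fraction and seed configurable). Cross-corpus evaluation trains one model on
all of the source corpus (splits merged) and tests on all of the target,
reporting the in-domain result alongside for the degradation comparison.
Seed-sensitive properties in the tests are asserted over 5–10 seeds rather
than a single run.

## Numerical and degeneracy choices

- Population (not sample) SD in the rule scaler; constant features get
  scale 1 rather than raising.
- Posts are ordered by ascending timestamp when *all* posts of a unit carry
  one, otherwise file order is kept — mixing the two would make
  concatenation order ambiguous.
- Canonical JSONL is written with sorted keys and no extra whitespace so
  identical corpora are byte-identical on disk.
- Problem sizes in the test suite and acceptance script (200 units/class,
  5–10 seeds) are the package's default study conditions; they generate and
  train in seconds while leaving the binomial standard errors small enough
  for 3σ rate-recovery checks.

## Known limitations

- The pipeline is bag-of-words end to end; no n-grams, negation handling or
  embeddings.
- The generator's independence assumptions make synthetic corpora easier to
  separate than real ones; absolute metric values on synthetic data are not
  forecasts for real collections.
- The eRisk-style XML reader requires the adjacent golden-truth file; there
  is no unlabelled-corpus path.
- Early-risk (chunked) evaluation metrics and significance testing between
  classifiers are out of scope.
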