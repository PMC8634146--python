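# Methods

This note documents the model implemented in `discrimlex`, its assumptions,
the parameters that matter, what the synthetic data does and does not
emulate, and the numerical choices made where the design was genuinely open.

## Form representation

Forms are strings with one character per phone (DISC-style); any single
character is accepted as a phone and no phone table is bundled. Cues are the
sliding n-grams of `#form#` (so a form of length L yields L+3−n cues when
L+2 ≥ n, and collapses to the single padded cue `#form#` otherwise — the
padding rule makes extraction total). Syllable n-grams window over
`[#, syl₁, …, syl_m, #]` joined by `-`; letter n-grams treat the orthographic
string exactly like a phone string. Cue inventories are ordered by first
occurrence over the training lexicon, which makes rebuilding byte-identical
without any sorting assumption. Presence coding is binary even for repeated
cues within a form. Homophones (identical strings) always receive identical
rows of **C**, which is the structural fact driving most of the evaluation
taxonomy below.

## Semantic representation

The meaning of an inflected word is compositional:
`lexeme + number + (case | semantic-role) [+ definiteness] + noise`.

* Simulated spaces draw lexeme vectors i.i.d. N(0, sd_lexeme²) and feature
  vectors N(0, (sd_feature·feature_scale)²) per dimension. Defaults:
  sd_lexeme = sd_feature = 4, sd_noise = 1, feature_scale = 1, and the
  dimension defaults to the cue dimension. With these defaults distinct
  lexemes are near-orthogonal, so all semantic similarity comes from shared
  inflectional structure.
* Number is equipollent by default (both SINGULAR and PLURAL are marked); a
  privative mode leaves the singular unmarked. Gender carries no semantic
  vector. When semantic roles are in play the role vector *replaces* the
  case vector: cases are distribution classes over roles, not meanings.
* Noise is drawn once per entry at composition time, not stored in the
  space, so homophones in different paradigm cells get distinct gold
  vectors while the feature vectors themselves stay fixed across entries.
* `feature_scale` shrinks the inflectional vectors relative to the lexemes
  (the wug pipeline defaults to 1/110). The L1-mass of inflectional vectors
  controls how strongly synthesis is pulled toward suffixation: at scale 1
  the plural shift dominates and suffixed candidates win; at 1/110 the stem
  dominates and bare or reduplicated candidates surface — that contrast is
  deliberate, not an artifact.

Empirical embeddings can be loaded from word2vec text format (optionally
gzipped), keyed by surface form, so homophones necessarily share a vector
and carry no inflectional structure of their own. Lexeme and feature vectors
can then be reconstructed analytically: a lexeme vector is the mean over the
lemma's entry vectors; a feature vector is the mean over the feature's
carriers *minus the grand mean over all entries*. The subtraction is a
design choice: with additively composed embeddings, plain carrier means
double-count the paradigm-average of the other feature family (the
reconstruction would be `target + 2·mean(number) + 2·mean(case)`), capping
the reconstruction correlation near 0.7; the contrast coding recovers the
additive structure exactly on balanced noise-free data, and the per-entry
Pearson r between reconstructed and original vectors is returned so the
residual idiosyncrasy of real usage stays measurable.

## Mappings

End-state estimation solves Y = XW by minimum-norm least squares (SVD
pseudoinverse). No intercept is fitted: the network formulation has none.
The minimum-norm solution is the natural choice under rank deficiency —
ubiquitous once homophones duplicate rows of **C** — because it is the limit
of error-driven learning started from zero weights.

Incremental learning applies the Widrow–Hoff update per token with zero
initialization (the discriminative-learning convention). The default
learning rate is η = 0.001; a single update is contractive iff
η·‖c‖² < 2, and `max_stable_eta` exposes that bound (2 over the largest
squared cue-row norm). Divergence is detected by a weight-norm guard that
reports the offending η. Single-pass training over a frequency-weighted
token stream is the realistic regime; multi-epoch replay exists to
demonstrate convergence to the end-state, which holds exactly on full-rank
problems. On numerically rank-deficient problems fixed-step cyclic learning
retains an O(η) error floor, which is why convergence fixtures check the
Gram spectrum first.

Token streams come in two schemes: `shuffled_census` (each entry exactly
frequency-many times, shuffled — one pass through the corpus) and
`frequency_proportional` (i.i.d. draws proportional to frequency).

Pruning zeroes all weights with |w| < ϑ and reports the pruned fraction;
many connection weights sit near zero (low discriminative value), so
substantial fractions prune without accuracy cost.

## Evaluation taxonomy

Comprehension is scored by highest Pearson correlation against *all* gold
vectors (train + validation), ties broken toward the lowest row index and
logged; constant vectors get r = 0 by convention. The report distinguishes:
`train` (model as memory; homophones counted leniently — an isolated
homophone gives no way to pick the cell — with `train_strict` alongside),
`val_all` (lenient over every validation entry, novel-lemma entries
included), `val_lenient`/`val_strict` (the homophone subset), and
`val_newform` (unseen forms whose lemma is known; entries of entirely novel
lemmas are excluded there but still count in `val_all`). Production uses the
same categories with exact string match of the top candidate; an empty
candidate list counts as incorrect.

## Production details

Graph mode admits cues with predicted support ≥ θ and up to t sub-threshold
cues per path, enumerating boundary-to-boundary paths by depth-first search
with a hard path budget. Candidate ranking is synthesis by analysis; ties
break to the shorter path, then the lexicographically smaller surface, for
determinism. Default maximum path length is the longest training path plus
two cues.

θ calibration: for each training form take the minimum predicted support
over its own cues; θ is half the median of those minima. The factor matters
in the interpolation regime (more cues than training rows), where every
own-cue support is ≈ 1 and a threshold placed exactly at the median would
cut trained and held-out forms on numerical noise; irrelevant cues cluster
near zero support, so the backed-off threshold still excludes them. As with
any support threshold, some per-dataset fine-tuning is expected.

Positional mode is this package's definition of position-restricted search
(the published description names the mechanism but not the algorithm): one
end-state regression per word position maps meanings to an indicator of
"cue x occurs at position p", and each search step is restricted to the
top-k cues for its position. Graph mode plus the brute-force enumerator is
the verifiable core; the enumerator is kept as an oracle and accepts its
exponential worst case at test scale.

## Wug pipeline

Five steps: train comprehension on all real words; map nonce cue vectors to
estimated singular meanings (nonces with no trained cue are rejected — the
reason wug items are restricted to forms with existing rhymes); re-estimate
the production mapping on real words plus the nonce singulars (end-state,
matching the rest of the pipeline); shift meanings by +PLURAL − SINGULAR;
synthesize ranked candidates. Letter bigrams are the default unit and
articles are omitted (participants produce bare plurals). The packaged
demonstration items are the twelve rhyming nonce nouns used in the published
wug materials.

## Synthetic data

The generator emulates the structural properties the machinery is sensitive
to: five declension classes at type frequencies 56.5 / 23.9 / 2.3 / 13.3 /
2.6% (renormalized), optional stem-vowel fronting, the homophony template
(nom/dat/acc singular identical; nom/gen/acc plural identical; dative plural
adds -n unless the base already ends in n or the class is -s; feminine
genitive singular is bare, making feminine singulars four-way homophones),
three genders, Zipf(2) token frequencies per distinct surface form, and
CV-maximal-onset syllabification over its own alphabet so the syllable cue
mode is exercisable. Wug nonces swap the initial consonant of an existing
form, giving maximal rhymes whose junction cues are familiar shapes.

It does *not* emulate: German phonotactics or real word lists, suprasegmental
structure (stress, tone), morphological family structure beyond a single
paradigm per lemma, or the usage idiosyncrasies that make real embeddings
only partly compositional. Passing tests on this data therefore demonstrate
the machinery's correctness and its qualitative behavioral signatures
(memory vs. productivity asymmetry, homophone caps, frequency effects,
tolerance rescue), not quantitative accuracy on any natural-language corpus
— headline accuracies on real lexicons depend on data that is not bundled.

## Semantic-role frequencies

Role expansion replaces each entry by one entry per role its case can
realize (agent/theme/patient for nominative, possessive/partitive for
genitive, beneficiary/location for dative, patient/motion/experiencer for
accusative, at probabilities .5/.4/.1, .9/.1, .5/.5, .4/.3/.3). Frequency
simulation shares a form's token count equally (freq_p) among the
case/number cells realizing it — computed from the lexicon's homophone
structure, e.g. 4 for a feminine singular — then drops each role of a cell
independently with probability 1/K (K roles per case; on average one role
omitted per cell), and allocates freq_p over survivors proportionally to
renormalized probabilities, rounded up. Ceiling rounding and renormalization
are adopted because together they uniquely reproduce every nonzero cell of
the published worked example (35 = ⌈34.25⌉, 20 = ⌈34.25·5/9⌉,
16 = ⌈34.25·4/9⌉, 18 = ⌈17.125⌉); cells that lose all roles keep frequency 0
and are logged.

## Problem sizes and statistical checks

The test suite and the acceptance script run on generated lexicons of 6–60
lemmas (48–480 entries), 200-entry lexicons for frequency-effect contrasts,
500-epoch replay for convergence checks, and 100 random ≤12-cue inventories
for the path oracle — sizes at which every check runs in seconds while the
relevant asymptotics (interpolation, rank structure, Zipf tails) are already
visible. Statistical acceptance checks use 3-standard-error bands for moment
checks, a discrete Kolmogorov–Smirnov bound for the Zipf marginal, and a
form-level permutation test for the absence of a frequency effect at the
end-state: prediction-quality values cluster within homophone groups, so a
naive Fisher interval on the rank correlation is anticonservative, while
permuting frequencies across distinct forms — exchangeable under the
frequency-blind end-state — yields a calibrated null.

## Known limitations

* Ranking by synthesis-by-analysis can prefer over-long cue concatenations
  when the path-length cap is generous; the default cap (longest training
  path + 2) keeps this in check but does not eliminate it.
* Incremental learning of *production* supports is not implemented in
  positional mode (positional predictors are end-state regressions), so
  frequency effects are demonstrated for comprehension.
* The evaluation assumes the gold semantic matrix covers train and
  validation entries jointly; nearest-neighbour search over other candidate
  sets is not exposed.
* With fixed learning rate, incremental training on rank-deficient input
  converges to a neighborhood of the end-state, not to it.
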