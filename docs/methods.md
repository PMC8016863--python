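# Methods

## Problem formulation

Documents are sequences of words x with latent per-word classes
y ∈ {0, …, k}, where class 0 means "outside any entity" for NER-style tasks
and k is the number of entity (or attribute) classes. Word positions are
addressed by a single flat, document-scoped 0-based index so that rows of
the label matrix map one-to-one onto words; character offsets are 0-based
half-open and must slice the original text back to the token surface
exactly. Span-attribute tasks (negation, document-relative time) use the
same machinery with one label-matrix row per pre-identified entity span
instead of per word; the two row modes never mix in one matrix.

## Label sources

A labeling function (LF) emits one vote per word (or per span) in
{−1, 0, …, k}, where −1 abstains. Terminologies become LFs through
templates:

- **Semantic-type LF.** Terms carry probability vectors over classes derived
  from their semantic-type assignments (normalized counts over the STY→class
  map; terms whose types all map to abstain are dropped; non-typed
  ontologies assign a single class). Matching is a greedy left-to-right
  longest-match scan in token length: at each position the longest
  in-dictionary candidate wins and the scan jumps past it, which resolves
  nested terms ("lung" as anatomy inside "lung cancer" as disease)
  deterministically. Matched words are voted the term's most probable class,
  abstaining on exact vector ties; everything else abstains. An optional
  slot pattern `{*} ({*})` fuses compositional mentions such as
  "Tylenol (Acetaminophen)" into one match.
- **Synset LF.** Votes only when more than one distinct synonym of the same
  concept occurs in a document, then labels every occurrence of those
  synonyms — the within-document redundancy disambiguates abbreviations.
  Optionally, Schwartz–Hearst definition pairs ("LONG (SHORT)", right-to-left
  character alignment with the short-form's first character anchored to a
  word start; short forms of 2–10 characters, at most two tokens; long-form
  window of min(|short|+5, 2·|short|) preceding words) license
  out-of-dictionary short forms whose long form is in the dictionary.
- **Pattern templates.** Regex LFs vote on words covered by a match;
  dictionary LFs (longest match, case-insensitive) support negative-class
  lists — punctuation, numbers, stopwords voting class 0 — which matter for
  identifiability (below). Bigram-graph LFs vote on maximal word runs
  (default minimum 2) whose every adjacent pair appears in some multi-word
  ontology term, a fuzzy matcher for compositional mentions.
- **Cue templates (span scope).** Context-window LFs search directional
  token windows (never crossing a sentence boundary) for cue phrases; the
  nearest cue wins and conflicting votes at equal distance abstain. A seed
  NegEx-style lexicon ships as an editable TSV. The datetime-distance LF
  resolves explicit date grammar (ISO, m/d/y, month-name, and "N unit ago"
  relative phrases with 30-day months and 365-day years) and votes by the
  nearest mention in token distance: strictly before the document timestamp
  → BEFORE, strictly after → AFTER, same calendar day → OVERLAP, equidistant
  mentions or unresolvable anchors abstain. The same-day→OVERLAP boundary is
  a declared choice; the underlying four-class convention does not pin it
  down. Section-header LFs vote a configured class for spans inside
  matching sections (e.g. "past medical history" → BEFORE).

Terminology preprocessing removes stopwords (a pinned built-in English
list, overridable by file), pure-number terms and single-character terms,
and normalizes case while preserving abbreviations: a term is lowercased
unless some token is all-uppercase of length ≤ 5 or mixed-case with
internal capitals, in which case it is kept verbatim and matched
case-sensitively. The abbreviation rule is a declared heuristic (the
length-5 bound trades DMD/mmHg-style forms against all-caps shouting);
preprocessing is idempotent. Suppressible-term flags in metathesaurus
dialects are deliberately ignored: sources are treated as plug-and-play.

Terminologies are ranked by corpus coverage — each term's document
frequency under longest-match occurrence, summed over the terminology
(type-level counting: one count per document per term) — and partitioned
into the top-s individual sources plus one merged remainder whose per-term
class vectors are averaged across contributors, so every term stays in play
at any s.

## Aggregation

**Majority vote** takes the per-row mode of non-abstain votes; ties and
all-abstain rows default to the corpus-wide majority-vote class (the tie
default is configurable; class 0 is a votable class like any other).

**Label model.** Sources are conditionally independent given y: source j
votes with coverage cⱼ independent of y, and a vote equals y with accuracy
aⱼ, otherwise uniform over the k wrong classes. Coverage independence means
abstains carry no evidence, matching an accuracy-factor parameterization;
full per-source confusion matrices are left unidentified deliberately —
they are not recoverable at realistic source counts without gold labels.

Fitting is EM on the marginal likelihood of Λ, collapsing to closed-form
M-steps: aⱼ is the posterior-expected fraction of correct votes among rows
where j votes (an optional L2 term acts as a pseudo-count pull toward the
accuracy prior), and π is the mean posterior over rows with at least one
vote. Initialization uses a uniform accuracy prior (default 0.7); for
binary tasks the closed-form triplet estimates override it when computable:
with votes recoded to ±1, E[λᵢλⱼ | both vote] = âᵢâⱼ, so
|âᵢ| = √|M̂ᵢⱼM̂ᵢₗ/M̂ⱼₗ| per triplet, aggregated by the median, sign resolved
positive (sources assumed better than random). π is initialized from
majority-vote frequencies. Convergence is a log-likelihood improvement
below 1e−6 or 500 iterations; the fit is fully deterministic. An EM fit of
this model family replaces the matrix-completion solver used by the
ecosystem's standard trainer: same accuracy-factor family, deterministic,
desk-scale, and independently checkable against the triplet closed form.

Numerical choices: accuracies are clamped to [1/(k+1)+0.01, 0.99] (this
also blocks the label-swapped EM mode), the prior is floored and
renormalized to avoid log 0, posterior rows are computed in log space and
normalized with logsumexp, and hard labels are the argmax with exact ties
(tolerance 1e−12) going to the majority-vote default class. All-abstain
rows return the prior and are flagged so downstream training can mask them.
With fewer than 3 sources accuracies are unidentifiable and `fit` refuses;
the partition sweep then substitutes MV-equivalent parameters (equal
accuracies, uniform prior), under which the posterior argmax provably
reproduces majority vote including its tie rule — this gives the exact
s = 1 degeneracy.

## Noise-aware end model

Posteriors are regrouped into sentence sequences; words where every source
abstained are masked. The training objective is the expected cross-entropy
under the probabilistic labels, −Σ_y Ŷ(y)·log p(y), averaged over unmasked
words; one-hot targets reduce it exactly to standard cross-entropy, masked
words contribute exactly zero, and predicted probabilities are clipped at
1e−12. Soft expectation (rather than sampling hard labels per batch) is the
fixed choice: it is the exact expectation and keeps training deterministic.
The loss is generalized from the binary form to categorical cross-entropy
so multiclass span tasks share the code path; the binary case reduces
exactly.

The bundled discriminative model is a linear softmax token classifier over
sparse lexical features (word identity, shape/casing, affixes up to length
3, neighbor identities within a window of 2), trained by full-batch
gradient descent from zero weights — deterministic at any seed. It is a
deliberately lightweight model whose job is to exercise the loss, masking,
and dataset contract, and to demonstrate generalization beyond the sources
(a synonym never voted by any LF is still tagged through shared features);
contextual encoders are expected to train externally on the exported
probabilistic CoNLL file (`token  mask  P(0)…P(k)`, 6 decimals).

## Evaluation

NER scoring is exact span matching on (document, start, end, class);
word-level IO predictions are decoded through the O→I-transition rule
within sentence bounds before scoring, which counts head-word errors but
cannot split adjacent same-class entities — an inherent IO limitation that
is asserted, not hidden. Span-attribute tasks use micro-averaged P/R/F1,
pooling per-class TP/FP/FN over the listed classes.

## Synthetic benchmarks

The generators make every stage testable without licensed ontologies or
gated corpora, and their defaults are the package's reference study
conditions:

- **Corpus.** Background and entity vocabularies are disjoint, so planted
  spans induce exact gold word labels. Defaults: 50 documents × 5 sentences,
  Poisson sentence lengths (mean 9, min 4), Poisson 0.8 planted entities
  per sentence drawn from a 40-term lexicon with 1–3-word terms
  (probabilities 0.45/0.40/0.15) — entity densities and term lengths in the
  range of biomedical NER corpora. Entities are never spliced inside one
  another; adjacency is allowed.
- **Terminologies.** Source j includes each gold term with probability
  `coverage` and labels it correctly with probability `accuracy`, and
  likewise includes background words as negative (class 0) terms with the
  same rates, mislabels being class-1 false positives. Both-class voting is
  essential: positive-only dictionary sources agree on every co-voting row,
  leaving accuracies unidentifiable from agreements. The induced LF's
  word-level accuracy and coverage track the spec values; the recovery
  benchmarks compare estimates against *measured* LF accuracies, not the
  nominal spec.
- **Label matrices.** Votes sampled directly from the label model's own
  generative assumptions, optionally with correlated source pairs (an
  entry copied from the partner with probability ρ) that deliberately
  violate conditional independence.

What the synthetic data does *not* emulate: real lexical ambiguity
(entity/background vocabularies are disjoint), discourse and section
structure, misspellings, and correlated ontology noise beyond the explicit
ρ-coupling. Passing benchmarks therefore demonstrate correctness of the
estimators and pipeline under the model's assumptions and controlled
violations of them — not clinical-grade F1 on real notes.

## Reference benchmark settings

Fixed in `ontoweave.experiments` and reused by the test suite and
`scripts/acceptance.py`:

- Triplet recovery: 5 binary sources with accuracies (0.6, 0.7, 0.8, 0.9,
  0.95), n = 10,000, 10 replicates, at coverage 1.0 and 0.8; EM/triplet
  cross-validation on one n = 20,000 matrix at coverage 0.8.
- Label-model gain: sources (0.95, 0.55, 0.55) at full coverage, uniform
  prior, n = 50,000 — the heterogeneous regime where equal-weight voting
  provably loses to accuracy weighting (the gap has a closed form over the
  8 vote patterns).
- End-to-end recovery: 200 documents, 6 terminologies with
  (accuracy, coverage) from (0.95, 0.9) down to (0.6, 0.5).
- Partition sweep: 8 terminologies, one strong (0.95) and seven weak
  (0.55–0.7), s ∈ {1, 2, 4, 8} with merged remainder.
- Correlation stress: baseline (0.9, 0.7, 0.6) plus 3 perfectly correlated
  copies of the 0.6 source, n = 10,000, median over 10 replicates — the
  duplicated block looks unanimously reliable to an independence-assuming
  model, which then follows the weak source; this quantifies the known
  independence-assumption failure mode (structure learning of source
  correlations is out of scope).

Problem sizes are chosen so the whole benchmark suite runs in well under a
minute per experiment on one CPU while keeping binomial sampling error
small against the stated tolerances.

## Known limitations

- The built-in tokenizer is a deterministic rule system (whitespace split,
  edge-punctuation peeling, terminal-punctuation + capital or blank-line
  sentence breaks); real clinical pipelines should swap in a biomedical
  tokenizer via the pluggable interface. Terms containing punctuation that
  the tokenizer separates (e.g. parenthesized terms) will not match as
  single dictionary entries.
- IO decoding merges adjacent same-class entities (asserted limitation).
- The label model assumes class-independent coverage and symmetric errors;
  correlated sources must currently be handled by partitioning/merging, not
  by dependency modeling.
- The metathesaurus RRF reader is an optional convenience (language filter,
  minimum 500 terms per source vocabulary); nothing in the package or tests
  requires licensed data.
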