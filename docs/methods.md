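# Methods

## Problem setting

Automatic rule-based labellers assign each free-text report one of three
ordered risk levels — *positive*, *uncertain*, *negative*. Two labellers of
different conservativeness agree on most documents and disagree on a small
fraction of systematically ambiguous ones. We train classifiers on the
primary labeller's labels and ask whether their predictive distributions are
*well-behaved under that disagreement*: higher NLPP / lower confidence where
the labellers disagree, and lower confidence on false negatives than on true
positives.

## Synthetic corpus generator

Each document carries a latent severity `s ~ Uniform(0,1)`. Two thresholds
`t_low < t_high`, placed so the class masses match the target proportions
(defaults 0.398 / 0.186 / 0.417 for negative / uncertain / positive, i.e.
the consistent-partition mix of the dual-labelled Oedema report corpus the
package emulates), map severity to the true class. Document length is
`max(3, Poisson(43.5))` tokens. Tokens come from four role groups:
affirmative findings ("edema", "effusion", ...), negation cues ("no",
"without", "not"), hedging cues ("possible", "likely", ...), and filler.

Both labellers share one rule structure, evaluated on tokens alone:

1. if the hedging-token count reaches the rule's `hedging_threshold` →
   *uncertain*;
2. else if an affirmative token appears that is **not** within
   `negation_scope` positions after a negation token → *positive*;
3. else → *negative*.

The primary labeller is the more conservative one: `hedging_threshold` 2
(vs. 3) and `negation_scope` 3 (vs. 1). Documents whose severity is farther
than `boundary_width` (default 0.05) from both thresholds are rendered with
unambiguous token patterns, so both rules agree by construction. Documents
within `boundary_width` of a threshold are rendered ambiguously — hedging
count exactly between the two thresholds, or a finding negated at a distance
inside only the wider negation scope — with a probability calibrated so the
overall disagreement rate hits its target (default 4%). Consequences, all
tested as invariants:

- disagreement is *localized*: every disagreeing document lies within
  `boundary_width` of a class threshold;
- the primary labeller emits at least as many *uncertain* verdicts among
  disagreements as the secondary (conservativeness asymmetry);
- `boundary_width = 0` yields an idealized fully consistent corpus; a target
  disagreement rate exceeding the borderline severity mass raises a
  configuration error naming both parameters.

One deliberate simplification: because the hedging check runs first and the
primary threshold is lower, the secondary labeller never answers *uncertain*
on a disagreement (in real dual-labelled corpora it occasionally does). The
asymmetry the analysis depends on — the primary labeller's uncertain-heavy
disagreement profile — is preserved.

The latent severity is persisted per report for diagnostics but is invisible
to every model stage: features are computed from tokens only.

### What the generator does not emulate

Real report text (syntax, section structure, negation/hedging interactions
beyond a fixed window), real labeller rule bases (mention extraction,
ontology matching), multiple pathologies, label errors *away* from class
boundaries, and the long-tailed vocabulary of clinical prose. Passing tests
on this corpus establish that the pipeline's uncertainty behaviour responds
correctly to boundary-localized label ambiguity — not that any model attains
particular numbers on a real corpus.

## Features

Tokens are lower-cased and split at punctuation/whitespace; each document is
the arithmetic mean of its in-vocabulary word vectors. Out-of-vocabulary
tokens are skipped (the divisor is the in-vocabulary count); a document with
no in-vocabulary tokens maps to the zero vector and is logged. Embedding
tables use the word2vec text format; the synthetic fixture table gives every
token an isotropic Gaussian base vector (scale 0.5) plus, for the three
class-indicative roles, a shared offset of 4.0 along mutually orthogonal
random directions — enough pooled signal for the classes to be learnable at
the default dimension of 50 without making them trivially separable.

## Splits and test variants

Stratified (by primary label) validation and test splits of 10% each, with
per-class counts by largest-remainder rounding; experiments run over
repeated splits (default 2) and report means, with all per-repeat raw values
retained. The test set decomposes into the consistent part (truth = the
agreed label) and the inconsistent part, evaluated twice — once per
labeller's truth. Headline consistent-set metrics use a uniform random
subsample of the consistent test set matched in size to the inconsistent
set, so the comparison is at equal cardinality.

## Sparse variational GP classifier

One zero-mean GP prior per class with a shared ARD-RBF kernel
`k(x,x') = σ² exp(-½ Σ_d (x_d-x'_d)²/ℓ_d²)`, summarized at M inducing inputs
(default 300; the desk-scale preset uses 100). The variational posterior per
latent function is a full-covariance Gaussian in whitened coordinates
(`u = L_m v`, `K_mm = L_m L_mᵀ`), which makes the KL to the prior
closed-form and kernel-independent, keeps the covariance positive definite
through its Cholesky factor, and improves optimizer conditioning. The ELBO's
expected log-likelihood uses a softmax inverse link, estimated by the
reparameterisation trick with 20 Monte-Carlo samples in training and 100 at
prediction; the data term is rescaled by `n/|batch|`. Training is RMSProp
(learning rate 0.003, batch 500); for corpora smaller than the full-scale
study the epoch count defaults to `max(2, ⌈200 / steps-per-epoch⌉)` so every
run gets on the order of 200 updates. Inducing inputs initialize at k-means
centroids of the training features and are optimized jointly with the kernel
hyperparameters (shared across the three latent functions) and variational
parameters. All gradients come from the package's reverse-mode autodiff
engine, whose Cholesky/triangular-solve adjoints are verified against finite
differences in the test suite.

Correctness anchors (both in the tests): the whitened KL coincides with the
general closed-form Gaussian KL and with Gauss–Hermite quadrature of
`E_q[log q - log p]`; and with a Gaussian likelihood and M = n inducing
points on the data, the optimized bound collapses onto the exact GP log
marginal likelihood (gap < 1e-4 at n = 5).

## Baselines

**Calibrated random forest** — 300 trees, max depth 40 (scikit-learn). Vote
frequencies are post-processed one-vs-rest by isotonic regression fitted on
the *validation* split (never on training scores, which would leak the
forest's overconfidence), then renormalized to the simplex. A class missing
from the calibration split degrades to an identity map with a warning.

**Deep ensemble** — five MLPs (three hidden layers × 200 units, batch norm,
He initialization), trained independently from distinct derived seeds with
Adam (3e-3) for 10 epochs, batch 100. Each batch's loss is the mean of the
clean cross-entropy and the cross-entropy on FGSM-perturbed inputs
`x + ε·sign(∇_x loss)`, with ε defaulting to 0.01 × the mean per-feature
interquartile range of the training inputs. The ensemble predictive
distribution is the arithmetic mean of member softmax outputs, so its NLPP
is bounded above by the mean member NLPP (Jensen), a property asserted
exactly in the tests.

## Evaluation

NLPP uses the natural logarithm (the convention of the GP literature this
builds on) with probabilities floored at 1e-12 before any log; floor events
are logged. Accuracy breaks argmax ties toward the lower class index and
logs tie counts. MMPCL of an empty group is an explicit undefined marker
carrying the count 0 — never a silent zero — and single-member groups are
flagged, since a one-point confidence average is anecdotal. Group-wise
analysis covers the positive and uncertain classes only; negative-class
errors are deliberately ignored (a missed positive is the asymmetric risk of
interest). The reliability analysis bins the maximum probability into
equal-width bins (default 10) and reports per-bin confidence vs. accuracy
and the expected calibration error; it stands in for a full calibration
study as the standard diagnostic.

## Numerical choices

- Kernel Gram matrices get a jitter of 1e-6 on the diagonal; on Cholesky
  failure the jitter escalates ×10 (logged) up to 1e-2 before a numerical
  error with diagnostics.
- Latent marginal variances are clipped at ≥ 0 before sampling; a 1e-12
  pad keeps `sqrt` differentiable at the origin.
- Length scales initialize at `std_d · √d` (per-dimension standard
  deviation, floored at 1e-3), keeping initial scaled distances O(1);
  signal variance initializes at 1.
- Every stochastic stage derives its seed as
  `sha256(global_seed : stage_tag) mod 2³¹-1`, so one integer plus the run
  manifest reproduces a run bit-identically (asserted in the tests).

## Desk-scale preset

`study_analog()` runs 10,000 synthetic reports, two repeated splits, and all
three models with the training hyperparameters above, using the
50-dimensional synthetic embedding table and 100 inducing points — sized so
a complete three-model run finishes in minutes on one CPU while preserving
the corpus conditions (class mix, ~4% boundary-localized disagreement, mean
length ~43.5 tokens). With a ~1,000-document test split the inconsistent
variants hold only ~35 documents, so per-variant metrics carry visible
sampling noise; the qualitative findings (inconsistent NLPP above the
size-matched consistent NLPP; FN confidence below TP confidence for the
positive class) are therefore asserted as majority-of-seeds properties, not
as fixed numbers.

## Known limitations

- The multiclass inverse link is softmax; robust-max is a reasonable
  alternative the package does not implement.
- Kernel hyperparameters are shared across the three latent functions
  (configurable in principle, but the shared setting is what is tested).
- The ensemble's FGSM ε and the clean/adversarial loss weighting follow
  common deep-ensemble practice; they are exposed in the config rather than
  fixed by any external reference.
- No decision-boundary / referral-threshold selection, no cross-validation,
  no transformer or alternative-kernel comparisons.
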