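# Methods

This note records the model, the numerical and design choices, what the
synthetic generator does and does not emulate, and the package's known
limitations.

## Task and tagging scheme

Given a tokenized sentence `S = {s_1..s_n}` and an ordered schema of `k`
event types, the model predicts one BIO tag per token over the tag
vocabulary of size `k̃ = 2k + 1` (`O` first, then `B-t`/`I-t` per type in
schema order). Typed trigger spans and BIO sequences convert losslessly in
both directions for valid inputs; decoded sequences may be ill-formed
(e.g. a stray `I-t` after `O`), and are repaired by the **begin-on-stray**
policy — a stray `I-t` opens a new `t` span — which is standard
sequence-labeling practice and guarantees that every decoded sequence maps
to a valid, non-overlapping span set (verified exhaustively for n ≤ 4,
k ≤ 2). Token indices are 0-based half-open.

## Architecture

* **Joint encoding.** Input `⟨[CLS], L, [SEP], S, [SEP]⟩`; segment id 0 for
  the prompt block, 1 for the sentence. The label prompt uses one *added
  special token per event type* (multi-word label names such as "Positive
  Regulation" stay a single token with its own trainable embedding), in a
  random order drawn once per experiment from a recorded seed — not
  resampled per batch. Word-level sentence vectors use the
  **first-sub-token** rule. Over-length inputs are truncated from the
  sentence tail at whole-word granularity; the prompt is never truncated.
* **Encoder contract.** Any map from the packed input to per-position
  vectors of dimension `d` implemented by multi-head self-attention over
  the full concatenation. The shipped `TinyTransformer` (pre-norm, learned
  positional and segment embeddings; default 2 layers, d=64, 4 heads,
  FFN 128) satisfies it and trains from scratch on a CPU; an
  `IdentityEncoder` (raw embedding lookup) exposes the split/gather logic
  to exact tests. A large pretrained biomedical transformer can stand
  behind the same contract for full-scale use.
* **LCAR** is single-head scaled dot-product attention (scale `1/√d`) with
  learned query (sentence), key and value (label) projections. The `1/N`
  averaging factor over the `N = m` labels is implemented literally and on
  by default, although it interacts with the softmax normalization of the
  attention weights (it uniformly shrinks `C`); `include_1_over_n=False`
  drops it. Head count is one because the formulation uses a single
  attention function.
* **LTAR** is `σ(h_Sᵀ W h_L + b)` with `W ∈ R^{d×d}` learned and `b`
  scalar; the raw per-label sigmoid activations (length `m`, prompt order)
  are the features entering the third projection head.
* **Projection heads** are three *independent* single-layer affine maps
  onto `R^{k̃}` with no hidden nonlinearity — their outputs serve directly
  as CRF emission scores, so inserting a squashing nonlinearity would only
  restrict the emission range. No concatenation: keeping the three
  representations in separate heads avoids inflating the feature space.
* **Combination** `x = X′ + α·X̂ + (1−α)·X̃` with α ∈ (0,1) open —
  the sentence term is an unweighted residual base. Default α = 0.5.
* **CRF.** Transition matrix over `k̃ + 2` states with explicit virtual
  START/STOP rows absorbing the boundary terms. All dynamic programming is
  in log space; there is no probability-space computation anywhere.
  Viterbi breaks ties toward the lowest tag index. Hard BIO masking is
  **off by default** — the CRF is left to learn that `I` must not follow
  `O` — and available as a config flag; "forbidden" is realized as a
  −10⁴ additive penalty rather than −∞ so training gradients stay finite.

## Training

Adam on the mean CRF negative log-likelihood. The gradient of the NLL with
respect to emissions and transitions is computed analytically (expected
minus observed feature counts via forward–backward marginals) and plugged
into the package's reverse-mode autodiff engine as a custom op; everything
upstream (encoder, LCAR/LTAR, heads) differentiates through the engine's
primitives. Both routes are verified against central finite differences.

Two profiles:

| parameter | full-scale default | tiny desk profile |
|---|---|---|
| learning rate | 5e-5 | 1e-3 |
| max epochs | 100 | 20 |
| max sequence length | 256 | 64 |
| encoder | pretrained (by contract) | 2-layer d=64 from scratch |
| dropout (drop prob.) | 0.1 | 0.1 |
| batch size | 16 | 32 |

The historical specification of "dropout of 0.9" for this architecture is
ambiguous between drop- and keep-probability; the default here is a drop
probability of 0.1, overridable in config. The tiny profile's larger
learning rate reflects training from random initialization rather than
fine-tuning. A seeded 10% slice of the training sentences is held out for
epoch selection (best dev micro-F1, kept parameters restored at the end);
training stops early once dev F1 clears 99.5%. Batches are length-sorted
and shuffled at chunk level, all from the experiment seed, so runs are
reproducible under single-threaded execution.

## Evaluation

A prediction is correct only on **exact token span + type** match — the
strictest standard rule, stated explicitly because shared-task tools differ.
Micro averaging pools TP/FP/FN globally; macro averaging is the unweighted
mean of per-type F1 over event types (not BIO tags) *present in gold*,
which avoids 0/0 artifacts for types a small evaluation split never shows.

## Synthetic generator

The generator emulates the statistical structure the method exploits, not
biomedical language. Each of the default 5 event types owns 4 unambiguous
trigger surfaces (one two tokens long, exercising `B-`/`I-`); 5 ambiguous
words are shared between type pairs — mirroring genuinely polysemous
triggers such as "proliferation" (growth vs cell-proliferation) — and each
(word, type) pair has a dedicated cue word whose presence decides the gold
type with probability 1 (a `cue_noise` knob exists, default 0, so recovery
thresholds stay sharp). Sentences (lengths uniform on [6, 12], background
vocabulary 200) are built slot-wise: one trigger slot per sentence, filled
with probability `trigger_density` = 0.6, ambiguous with probability
`ambiguity_rate` = 0.3; slot-wise construction guarantees non-overlapping
gold spans without rejection sampling. Documents are 10 sentences joined by
newlines, emitted as genuine standoff triples with T/E annotations and a
ground-truth generation log.

Because cues are deterministic, the Bayes-optimal classifier attains
F1 = 1.0, while any context-blind lexicon lookup is capped below 1 at
positive ambiguity rates (the `lexicon_baseline_score` function measures
that ceiling, ≈ 0.85 at the defaults). Passing the recovery experiment
therefore shows that the pipeline *mechanically* learns both the
lexicon and the cue→type association; it says nothing about robustness to
the diffuse, noisy context of real biomedical text, subword morphology,
nested annotations or annotation inconsistency.

A caveat the recovery experiment itself exposes: with probability-1
single-token cues, the joint self-attention encoder alone (the no-LSRL
ablation) also learns the cue association at convergence, so full-vs-ablated
gaps on the ambiguous subset saturate to ties on many seeds. The
label-aware terms show their value in under-trained or data-scarce regimes
rather than at convergence on this easy process.

## Corpus I/O choices

* A `T` annotation counts as an event trigger iff its type is in the schema
  **and**, when `E` lines exist, some `E` line references it; corpora
  without event structures fall back to type membership. This separates
  triggers from `.a1` entities without needing the argument structure.
* The default tokenizer splits on whitespace only (a sentence-final period
  stays attached, matching the canonical 8-token example); a
  punctuation-splitting mode and pluggable replacement exist. Sentence
  splitting is offset-preserving; a newline always splits.
* Discontinuous (semicolon-offset) annotations are skipped with a logged
  warning — BIO cannot express them. Triggers whose character extent
  crosses token boundaries are force-aligned to the smallest covering token
  run and logged.
* Corpus statistics report both trigger mentions and event instances, since
  the two differ when events share a trigger.

## Known limitations

* No nested or overlapping trigger representation (BIO only).
* The NumPy stack is single-threaded per op and float64; desk-scale corpora
  train in minutes, but fine-tuning a large pretrained encoder requires
  swapping a GPU-backed encoder behind the encoder contract.
* Argument extraction is out of scope; `E` lines are parsed only to locate
  trigger references.
* The label prompt must fit within the maximum sequence length; schemas
  with hundreds of types would need a longer window or prompt chunking.
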