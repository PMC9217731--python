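# Methods

## Scope and model

`cafedsim` simulates a parameter-server federation in virtual time: one
server, `n` worker devices, no real networking.  The object of study is
an asynchronous update rule in which the server applies each arriving
contribution immediately, damped per parameter entry by the inverse of
that entry's staleness, after optional Bernoulli thinning of uploads and
optional Gaussian randomization of the applied pseudo-gradient.  A
synchronous FedAvg baseline and a centralized SGD baseline share the same
model surface, logging schema and communication accounting, so the three
regimes are directly comparable.

All models expose their parameters as one flat float64 vector with a
documented `(layer, shape)` key order.  This is not a convenience: the
algorithm's central quantity — per-entry staleness — is only well defined
relative to a stable global index `k`, so the flattening *is* part of the
model contract.  Checkpoints store the key order in a JSON header ahead
of a little-endian float64 payload and round-trip bit-exactly.

### Classifiers

* **Text-CNN** — embedding → 1-D convolutions (ReLU) at filter lengths
  {3, 4, 5} → max-over-time pooling → concatenation → dropout → a single
  sigmoid output unit.  The "fully connected layer" and the output layer
  coincide (width 1): with one binary logit, an extra hidden layer adds
  parameters the data sizes here cannot justify.  Loss is mean binary
  cross-entropy plus `l2_coeff · Σ‖W‖²` over trainable weight matrices
  (convolution kernels, output weights, and the embedding only when it is
  trainable; biases are excluded, the usual convention).  Implementation
  is pure NumPy with analytic gradients; every gradient path is verified
  against central finite differences in the test-suite.
* **Embedding modes** — `rand` (seeded random init, trainable), `static`
  (pre-trained table, frozen), `nostatic` (pre-trained, fine-tuned).  In
  `static` mode the embedding is a frozen buffer *outside* the parameter
  vector, so federated arithmetic can never perturb it; tokens missing
  from the table receive seeded random rows (frozen in `static`).  Row 0
  is an all-zero padding vector and never trains.
* **Logistic model** — an l2-regularized logistic regression with the
  same `init/loss/grad/predict` surface; convex, hence analytically
  checkable.  It is both a test stand-in and a legitimate fast classifier
  over min-max-normalized bag-of-words features.
* **Quadratic model** — `F(w) = mean_i ½‖w − x_i‖²`, strongly convex with
  optimum at the data mean; used for convergence experiments where the
  optimum must be known exactly.

### Text pipeline

Corpora are pre-tokenized JSONL (one user per line: id, list of token
lists, binary label); no segmenter is bundled, because the synthetic
generator emits tokens directly.  Posts are concatenated in stored order
(assumed chronological), truncated or right-padded to a fixed length `L`;
`L` defaults to 400 — corpus-scale values in the tens of thousands are a
property of a specific crawl, not of the method.  Min-max normalization
is fitted on the training split only and applied with clipping to the
test split, avoiding leakage.  Embedding tables use the word2vec text
format (`|V| d` header, then one token per line).

## The asynchronous update rule

For a worker that pulled at global epoch τ and whose accepted push
arrives at epoch t:

    g      = w_back − w_new                      (pseudo-gradient)
    s_k    = #{ u ∈ [τ, t−1] : |g_u^k| > ϑ }     clamped at M
    ∂_k    = 1/s_k  (s_k ≠ 0),  1  (s_k = 0)
    w_new  : w_{t+1}^k = w_t^k − ∂_k (g^k + β σ N_k),  N_k iid N(0,1)

Decisions embedded here, each genuinely open in the underlying
formulation:

* **Noise is excluded from the staleness history.**  The history counts
  use the clean `g_u^k`.  Counting the noisy value would mark every entry
  at every update (Gaussian noise is almost surely nonzero), collapsing
  the per-entry weighting into a uniform 1/s — defeating its purpose.
* **Noise is drawn independently per entry** (the natural reading of a
  white-noise mechanism; a single shared scalar would leave all relative
  parameter information intact and protect nothing).
* **The push gate is evaluated once per completed local round**, not per
  parameter: accept iff `r < sigmoid(v)`, `r ~ U[0,1]`.
* **After a dropped push the worker discards its delta and re-pulls** the
  current global model.  Retraining from the stale local model would let
  staleness grow without bound across consecutive drops; re-pulling keeps
  it bounded, consistent with the bounded-staleness assumption under
  which the rule is analyzed.  Because a dropped delta is never observed
  by anyone, the simulator draws the gate before spending compute on the
  round; the event stream is identical to train-then-drop.
* **Staleness cap** `M` (default `10·n`): effective staleness is clamped,
  a mechanism for the boundedness the theory assumes but the algorithm
  text does not enforce.
* **Constant learning rate γ.**  A diminishing schedule appears only in
  convergence proofs of this family of methods (and reuses the symbol β
  for an unrelated constant); the simulator keeps γ constant.
* The noise scale σ is fixed at 1 by default ("unit-variance white
  noise"); β ∈ {0, 1e-4, 1e-3, 1e-2, 5e-2} is the tunable magnitude grid.

## Timing model

The event queue orders push arrivals by `(virtual time, device id)` — at
most one applied update per instant, ties broken deterministically.
Worker i's round duration is `speed_i × LogNormal(μ=0, σ=0.5)` with
`speed_i ~ LogNormal(0, 0.5)` drawn once per run: heterogeneous devices
with heavy-tailed round times, the regime that makes asynchrony
interesting.  Tests can script the duration streams exactly.  All
generators (per-worker delay, minibatch/dropout, gate; server noise)
spawn from one master seed through fixed keys, so the entire run log is a
pure function of (config, seed) — byte-identical on replay.

## Synthetic data: what it emulates and what it does not

* **Corpus generator** — users get Bernoulli(prevalence) labels; tokens
  are drawn from class-conditional multinomials over a Zipf-weighted
  vocabulary, identical except that the positive class's logits are
  shifted by `signal_strength` on the `signal_tokens` most frequent
  tokens.  Defaults (900 users, prevalence 327/900, vocabulary 2,000,
  50 signal tokens, shift 2.0, 3–10 posts of 5–25 tokens) mirror the
  shape of the private study population this stands in for.  What it does
  **not** emulate: word order and syntax carry no signal (the signal is
  purely lexical), there is no topic drift, no code-switching, no
  label noise, and prevalence is far above clinical base rates.  Passing
  tests therefore demonstrate correctness and relative behavior of the
  *trainers*, not clinical-grade detection performance.
* **Vector generator** — Gaussian class blobs (balanced 10-class, 60,000
  records by default) standing in for MNIST in partition arithmetic and
  non-IID experiments; `class_sep` controls linear separability.
* **Partitioner** — `iid` (seeded shuffle, near-equal cuts), `shards`
  (stable label sort → contiguous shards of fixed size → seeded shuffle →
  round-robin deal; with 200 shards of 300 over 10 balanced classes every
  device sees ≤ 2 labels), `imbalanced` (power-law sizes with a floor of
  one minibatch).

## Numerical choices

Float64 throughout; sigmoid and softplus are computed in the
numerically stable branch-split forms; BCE is evaluated from logits.
Prediction threshold is 0.5 with ties to the positive class.  Max-over-time
pooling routes gradients through the argmax (first maximum on exact
ties); ReLU passes no gradient at exactly 0.  Dropout is inverted
(scaling by 1/(1−p) at train time) and off at evaluation.  Displayed
metrics round half-up to two decimals in percent; logs keep full
precision, and undefined ratios (zero denominators) surface as explicit
nulls, never silent zeros.

## Problem sizes used by the test- and acceptance-suites

Chosen so a full run stays interactive on one CPU: SGD-equivalence over
200 updates of a 6-feature logistic model; staleness cross-checks on 100
randomized 3-worker runs of 15 updates; gate calibration at 10⁵ draws and
noise calibration at 10⁴ applications; quadratic convergence with 4
workers × 200 points × 500 updates; corpus experiments with 2,000 users /
10 devices (convergence comparison) and 900 users (privacy grid, 3 seeds
× 4 noise magnitudes), both using the logistic bag-of-words model, whose
convexity also removes initialization luck from cross-algorithm
comparisons.  Partition arithmetic runs at full 60,000-record scale.

## Known limitations

* Single-process virtual time: no real network latency, packet loss, or
  device dropout beyond the push gate.
* The Gaussian mechanism is implemented but not *accounted*: no (ε, δ)
  bookkeeping, clipping, or sensitivity analysis — β is a knob, not a
  certified privacy level.
* The NumPy text-CNN is exact but not fast; it is sized for hundreds to a
  few thousand users, not industrial corpora.
* FedAvg participants are sampled uniformly; no importance sampling or
  straggler handling mid-round.
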