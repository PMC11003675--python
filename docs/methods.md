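# Methods

This package simulates populations of *self-replicating artificial neural
networks*: individuals whose heritable material is a fixed-length bit-string
genotype, whose phenotype is a small text program describing a neural
architecture, and whose reproduction is mediated by the networks themselves
— each individual is trained both to classify images (which determines its
fertility) and to copy its own genotype (whose errors are the sole source of
mutation). Selection, drift and survival act through a Wright–Fisher model
with constant population size and non-overlapping generations.

## The phenotype dialect

A phenotype is a one-line text in a constrained layer-description language
rather than executable source in a host language: executing generated code
is a sandboxing hazard and non-portable, and the only part of the original
programs that varies between individuals is the layer block anyway. A spec
consists of a fixed scaffold — `input ;` … `merge ;` `loss_weight <x.xxxx> ;`
`output ;` — around a variable chain of hidden layers (`conv f , k act`,
`pool s`, `dense u act`, `dropout p`). Numbers are spelled digit-by-digit
(one token per lexeme, no significant whitespace), with `,` separating
adjacent numeric fields; the loss weight carries exactly four decimals,
finer than the smallest heritable shift of interest (~2×10⁻³). "Execution
error" in the original system maps here to parse/scaffold/shape failure.
The shipped vocabulary has 26 tokens; both the vocabulary and the dialect's
legal hyperparameter ranges are configuration.

Building a spec is pure and closed-form: shapes are propagated through the
chain ('same'-padded stride-1 convolutions, floor-division pooling, implicit
flatten before the first dense layer), the trainable-parameter count is
summed per layer plus the fixed scaffold branches, and any spec over the
parameter cap (default 2,000,000) is reported as invalid with kind
`parameter-cap-exceeded`. In the population such individuals remain alive
but sterile (fertility forced to 0), so they can be drawn yet leave no
offspring.

## The generator

Architectures are sampled from a first-order Markov chain over layer kinds
with an absorbing terminal state. Only one row of the transition matrix is
fixed by the system being emulated — out of a convolutional layer: pooling
0.7, convolution 0.2, fully-connected 0.1 — and one prior, the
fully-connected width ~ N(64, 15) clipped to [8, 128] and rounded. All other
rows and priors are shipped defaults, clearly marked configuration.
Hyperparameters are drawn from clipped normals rounded to an integer grid
(half away from zero); the dropout rate is encoded as an integer percent so
every prior yields integers. Draws that exceed the token budget (default
350) or fail to build are resampled up to 100 attempts.

The desk-scale (`tiny`) preset coarsens the prior grids (units in steps of
2, loss weight in steps of 10⁻²). This bounds the information content of a
spec so that a short genotype can carry it — see the codec section — and
matches the preset's tiny networks.

## The genotype codec

The codec is an autoencoder over token sequences: the encoder (embedding,
three strided 1-D convolutions, dense sigmoid head) maps a padded
d-token sequence to k Bernoulli parameters φ ∈ [0,1]^k; the decoder (one 1-D
convolution and a dense head) maps a genotype to d×r token scores, read
through a per-position softmax. Decoding takes the argmax token per
position and truncates at the first padding token. The training loss is the
sequence negative log-likelihood — deliberately with no KL/prior term on the
latent. Padding positions are included by default (a content mask is
available). At inference, bits are hardened at 0.5 (φ > 0.5 → 1, the
boundary mapping to 0), so encoding is deterministic.

During training the decoder input is a stochastic relaxation of φ, which is
what forces the learned code to tolerate bit noise. Two relaxations are
implemented:

- `printed` — soft gᵢ = logistic(log φᵢ + log uᵢ − log(1−uᵢ)), u ~ U(0,1).
  This form has a pathology: at φᵢ = 1 the sample is exactly uniform on
  (0,1), so even a saturated encoder transmits through a very noisy,
  asymmetric channel, and the gradient 1/φ ratchets units toward
  saturation. In our experiments at desk scale this form reliably collapses
  the latent (all inputs encode to a handful of genotypes) and
  whole-sequence reconstruction plateaus below 10%.
- `concrete` (default) — soft gᵢ = logistic(logit φᵢ + logit uᵢ), the
  standard temperature-1 binary Concrete relaxation. Here saturated φ
  yields samples concentrated near 0/1 ("mostly very close to 0 and 1"),
  the channel is symmetric, and training converges.

The `printed` form is retained as `concrete_relax` (it is the form the
formula in the source publication spells out) and as a config option; the
shipped default is `concrete`, on the grounds that the published
description of the relaxed samples' distribution, and the reference it
cites for the method, both match the logit form — and that the log form is
demonstrably untrainable. The relaxation has no temperature parameter
(fixed at 1) and no annealing.

The decoder's input stage exposes two fixed channels per bit: the raw value
and a clipped, scaled log-amplitude. Relaxed samples of a 0-bit sit orders
of magnitude below those of a 1-bit, so the two classes are linearly
separable on the log scale; hardened bits map to the extremes of the same
features. This is an architecture choice, not a change to the relaxation.

Capacity note: a k-bit genotype through the noisy training channel carries
somewhat less than k bits. Corpora whose per-spec description length
approaches k cannot be represented faithfully no matter how long the codec
trains; the tiny preset's coarsened priors keep the corpus entropy safely
below the 24-bit desk-scale genotype.

## Individuals and training

An individual's network is built from its spec: the image branch is the
heritable hidden chain; a fixed dense genotype branch, a merge
(concatenation), a shared dense head, and two outputs — class probabilities
(softmax) and a replicated genotype (k sigmoid units) — form the scaffold.
Weights are Glorot-initialised and never inherited. Training minimises
α·(categorical cross-entropy) + (1−α)·(mean squared error over genotype
bits) jointly per batch, with Adam; α is the spec's heritable loss weight.
Training pairs each image with a genotype drawn from the corpus genotype
pool (corpus specs encoded through the trained codec). Offspring genotypes
are the hardened (0.5-threshold) replication outputs on the shared
evaluation set, one potential offspring per evaluation image; because the
branches share the head, replication output depends on the paired image —
unexpected inputs act as mutagens, which is what the mutagen comparison
estimator measures.

Per-individual RNG substreams are derived from (run seed, generation,
individual index), so runs are bit-reproducible and resumable.

## The Wright–Fisher engine

Per generation: train all N individuals; fertility Fᵢ = accuracy on the
shared evaluation set; relative fertility fᵢ = Fᵢ/ΣF; offspring counts
Nᵢ ~ Multinomial(N, f); each offspring genotype is drawn (with replacement)
from its parent's pool and decoded; only buildable specs survive. The
publication asserts both constant N and removal of invalid offspring without
stating the reconciliation; here an invalid offspring is replaced by
*conditional resampling* — redraw a parent ∝ f and one pool member — until N
valid offspring exist or a budget of 50·N draws is exhausted (extinction,
reported with a full log flush). This preserves E[surviving offspring of i]
∝ Vᵢ·fᵢ at constant census size. Survivors among the initial Nᵢ draws are
recorded separately (they are the Ñᵢ of the fitness identities) from the
resampling top-up.

Fitness: absolute W = V·F (V = offspring survival rate, F = fertility);
relative w = V·F/F̄. In generation records V is the whole-pool decoded
validity when logged, otherwise the realized draw survival.

## Analysis estimators

- Mutation rate: μ_g = mean Hamming distance between a genotype and its
  offspring, with the per-site spectrum (fraction of offspring mutated at
  each site); μ_g equals the sum of per-site rates by construction.
- Survival: fraction of offspring decoding to buildable specs
  (cap-exceeded counts as surviving, consistent with the engine).
- DFE: fitness effects W_mutant/W_parent from parent–child links whose
  genotypes differ; pairs with zero parent fitness are excluded and
  counted; classes lethal (0), deleterious (<1), neutral (=1), beneficial
  (>1); windowed subsampling (5,000 pairs per 1,000-generation window at
  full scale) applies when data suffice.
- Robustness: λ(g) = 1 − Σ|W_g′−W_g|·M_{g→g′} / ΣM_{g→g′} over recorded
  mutants; undefined (error) with no mutants.
- Epistasis: for every ordered site pair i≠j, the normal model
  F = b + aᵢgᵢ + aⱼgⱼ + a_ij gᵢgⱼ + ε is fitted by maximum likelihood
  (identical to least squares; verified against a lstsq oracle to 1e-8),
  compared to the additive model by likelihood-ratio test with the
  asymptotic χ²(1) null, and corrected by Benjamini–Hochberg over all
  performed tests. Ordered pairs are enumerated because the full-scale
  count of tests (9,900 for 100 sites) corresponds to ordered enumeration;
  the model itself is symmetric in (i,j). A pair is skipped, with reason,
  when a site is monomorphic or an allele combination is absent (the design
  matrix is then singular). The scan is fully vectorised (closed-form 4×4
  normal equations per pair), so the 9,900-test scan takes well under a
  second.
- Trajectories: derived-allele frequency per site per generation relative
  to the ancestor; fixation time is the first generation at frequency ≥ 1.0
  (default threshold), with the 90% crossing exported alongside; richness
  is the count of distinct genotypes and distinct spec texts.
- Repeated evaluation: independent initialise-train-evaluate cycles with
  distinct substreams give mean/SD of F and V per genotype; correlations
  with fitness use a two-sided permutation test.
- Mutagen comparison: per-individual mutation rates under two image
  conditions with the same trained state, compared by paired t-test.

## Synthetic data

The image fixture generates L classes of m×n grayscale glyphs: distinct
deterministic stroke templates (bars, diagonals, crosses, boxes) with ±1
pixel translation jitter and additive Gaussian noise (σ = 0.15), clipped to
[0,1]. It emulates the statistical shape of a small digit-classification
task — distinct class geometry, within-class variability, balanced labels —
but not the difficulty of real handwriting: a linear classifier exceeds
chance by a wide margin within a few hundred examples. Passing tests on
glyphs therefore demonstrate the machinery (training improves the loss,
fertility responds to architecture, replication errors arise
endogenously), not real-data accuracy levels. An IDX reader is provided for
the standard handwritten-digit files.

## Desk-scale configuration and problem sizes

The shipped `tiny` preset runs the full pipeline on one CPU: N=16
individuals, G=10 generations, k=24-bit genotypes, 12×12 five-class glyphs
(240 training / 60 evaluation images), 64-token specs, a 200-spec codec
corpus, and 20 training epochs per individual at learning rate 0.01 (the
higher rate and epoch count compensate for the small training set; the
full-scale setup uses five epochs over 57,000 examples). Test suites use
these sizes, with Monte-Carlo checks at 2,000–10,000 replicates.

## Known limitations

- The printed-form relaxation is kept for reference but does not train at
  desk scale (see codec section); the default is the standard Concrete.
- Without temperature annealing (the relaxation is fixed at temperature 1),
  the noisy reconstruction objective tolerates rare token errors, so
  whole-sequence recall of the training corpus saturates well below 100% at
  desk scale: on a 200-spec low-entropy corpus with k = 24 the codec
  reaches ~98% distinct codes and ~91% token-level accuracy but only
  ~20-45% exact-sequence recall depending on training length. Decoded
  validity (what survival selection actually uses) is much higher than
  exact recall, and near-faithful replication in the evolution runs comes
  from individuals copying genotypes, not from codec round trips.
- Whole-sequence reconstruction fidelity depends on the ratio of corpus
  entropy to genotype length; at k=24 the tiny corpus needs the coarsened
  priors to be representable.
- Stride-1 'same' convolutions only in built phenotypes; pooling uses floor
  division, so repeated pooling on small images invalidates a spec rather
  than emitting zero-size tensors.
- The engine keeps trained network states ephemeral (weights are not
  inherited and not serialized); checkpoints store genotypes and seeds,
  from which all streams re-derive.
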