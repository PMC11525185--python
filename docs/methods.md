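# Methods

This note documents the models and procedures implemented in `credesign`,
the defaults they use, and the choices made where the design was open.

## Activity model

**Architecture.** Three functional segments: (1) three blocks of 1-D
convolution → batch normalization → ReLU → non-overlapping max pooling;
(2) flatten → fully connected layer; (3) one independent branch per cell
type, each a stack of four linear transforms, emitting one log2FC estimate.
The full-scale default is Basset-family sized (channels 300/200/200,
kernels 19/11/7, pools 3/4/4, 600-nt input), under which the conv stack
leaves 10 spatial positions before flattening. Any configuration whose
pool/kernel arithmetic leaves at least one position is accepted;
`PredictorConfig.desk_scale()` is the small single-CPU variant used by the
test suite (channels 32/32/64, kernels 11/7/5, pools 3/4/2, 230-nt input,
15-nt flanks). Branch activations are leaky ReLU (slope 0.1): at desk
widths, plain ReLU can leave an entire per-cell branch dead from
initialization, which silently zeroes one output; the conv trunk keeps
plain ReLU. Segment-3 activation placement is a documented default, not a
fidelity claim.

**Input contract.** 200-nt inserts are padded on both sides with constant
reporter-backbone flanks to the model input length. The true vector flanks
are not published, so the package ships a fixed, documented 200-nt flank
pair (trimmable; the sequence adjacent to the insert is stable as the
flank length varies) and accepts user-supplied flanks in the model config.

**Strand handling.** Training augmentation adds the reverse complement of
every training record (insert-level), plus one forward-orientation
duplicate of records exceeding 0.5 log2FC in any cell type. Prediction
averages the model output for the insert and its reverse complement under
the same flanks. These two conventions are deliberately consistent: both
orientations seen at training time are exactly the ones averaged at
prediction time, and the API becomes exactly strand-symmetric
(predict(x) = predict(rc(x))). The alternative — reverse-complementing the
entire padded sequence — would expose reverse-oriented flanks the model
never trains on in the insert-level augmentation regime.

**Training.** Adam on mean-squared error, batch 256, cosine-annealed
learning rate (held flat for the first 40% of steps), early model
selection by validation loss. `loss="weighted_mse"` weights each cell
type's squared error by the inverse of its training-label variance
(normalized); this stops a low-dynamic-range cell type from being drowned
out of the shared trunk's gradient and is the desk-scale default, while
plain MSE remains the config default. NaN loss aborts with diagnostics.
Bit-exact retraining requires identical BLAS kernels; tests assert
statistical outcomes, not bit equality.

**Splits.** Pure function of chromosome: 19/21/X validation, 7/13 test,
everything else trains. Filtering order for real tables: count filter
(plasmid < 20 or any zero RNA count removed) → duplicate resolution by
library precedence (top-tier duplicates averaged, lower tiers dropped) →
low-tail filter (log2FC more than 6 s.d. below the per-cell mean). The
replicate-SE filter (drop if SE > 1 in any cell type) is separate and
applied for evaluation and specificity counting, not model training.

## Specificity objectives

MinGap = y₊ − max(y₋); bent-MinGap = g(y₊) − g(max y₋) with
g(x) = x − e^(−x) + 1 after clamping predictions into [−2, 6]. The clamp
guards against pathological out-of-distribution predictions during
optimization; its gradient is zero outside the interval and the off-target
max routes gradient only to the arg-max cell. g is strictly increasing
(g′ = 1 + e^(−x)) and pole-free for |x| ≤ 50 in double precision.

**Motif penalty.** For a pool of m motifs in inclusion order (1-based
index i), penalty = (1/(mn)) Σᵢ (m−i+1)^{1/3} Σ_{j: sⱼ⁽ⁱ⁾ ≥ t⁽ⁱ⁾} sⱼ⁽ⁱ⁾,
where j runs over all windows of all n batch sequences and their reverse
complements. Match scores are PWM log2-odds against a uniform 0.25
background (with a 10⁻³ pseudocount); thresholds are expressed as a
fraction of the motif's consensus score — 0 for maximally stringent
penalization, 0.25 otherwise. The penalty is linear in the one-hot batch,
so its gradient is exact and flows through the straight-through estimator.
The motif-presence score of one sequence is the sum of match scores above
the Patser threshold (Biopython's score distribution) divided by the
consensus score.

**Propeller geometry.** For a 3-cell activity vector: radius = max − min
(MaxGap); deviation angle from the argmax axis = 60° · (median − min) /
(max − min), toward the median cell's axis. Zero radius maps to angle 0 by
convention; argmax ties break to the lowest cell index and are flagged.
A sequence is called cell-type specific when MaxGap > 1 (stringent: > 4)
and MinGap/MaxGap > 0.5, both strict; the effective target is the argmax
cell, and calls that pass only because the argmax differs from the
designed target are counted as reassigned. Strictness matters: the
textbook triple (5, 3, 1) has ratio exactly 0.5 and is *not* specific.

## Designers

**Fast SeqProp.** Learnable 200×4 logits initialized from a standard
normal; per step the logits are instance-normalized per base-channel over
the length axis (ε = 10⁻⁵, no learnable affine), softmaxed, and 20 one-hot
sequences are sampled per run. The loss is the negative mean bent-MinGap
of the samples plus the motif penalty; the straight-through estimator
passes the sample gradient to the probabilities unchanged. Adam
(β = 0.9/0.999) at learning rate 0.5, cosine-annealed to 10⁻⁶ over 300
steps. Finalization samples 20 sequences and keeps the best by
bent-MinGap unless below the collection threshold 3.6 (the threshold is
applied to bent-MinGap, the quantity being ranked).

**AdaLead.** 20 random sequences, 30 generations, mu = 1 expected
mutations per child, recomb_rate = 0.1 per-site crossover,
threshold = 0.25 relative parent-selection window, rho = 2 interpreted as
greedy rollout depth (children keep mutating while the mutation improves
fitness, up to rho − 1 extra steps). Fitness is bent-MinGap; one sequence
per run is collected unless its unbent MinGap is below 2. A collapsed
population stops the run early with a log entry.

**Simulated annealing.** Metropolis–Hastings with symmetric proposals
(three uniformly chosen positions mutated to uniformly chosen different
bases), energy −MinGap without bending on clamped predictions, and
τ(s) = 1/(1 + s^0.501), a strictly decreasing schedule with a divergent
temperature sum. The chain length is not dictated by the method; the
default is 3,000 steps, and the best-so-far state is returned (both
config-exposed). Initialization is a uniform-random sequence. An optional
acceptance log records (τ, ΔE, accepted) for every worsening proposal so
the Boltzmann rule can be verified externally.

**Penalization track.** Round 0 designs an unpenalized batch (default
500); its top enriched motif (lengths 8–15, top 10 reported) seeds the
penalty pool; each of rounds 1–5 designs 250 sequences against the growing
pool and appends that round's top motif. Motif discovery uses a built-in
seed-and-extend enrichment routine (most over-represented strand-canonical
w-mer vs per-sequence shuffled background, occurrences aligned into a PPM,
two EM-style rescan polish passes, found instances masked between rounds),
so tracks run fully offline; motifs from an external discovery tool in
MEME minimal format are accepted interchangeably. Track batches keep every
run's best sequence (no collection threshold) so round sizes stay fixed.

## Interpretation

**Sampled integrated gradients.** The path runs in logit space from the
zero matrix (uniform background) to scale · one-hot with scale = 8
(softmax puts ≈0.999 on the observed base at the endpoint). 16 midpoint
path points, 8 categorical samples per point by default; gradients are
taken through the sampling with the straight-through estimator, pushed
through the softmax Jacobian, averaged, and multiplied by the path scale.
Hypothetical scores keep all four bases per position (no masking); masked
scores multiply by the one-hot. On a linear model the masked map equals
the deterministic path integral and satisfies the completeness identity
Σ masked ≈ f(x) − E_background[f]; both are asserted in tests within
Monte-Carlo error.

**Contribution blocks.** The per-position track (masked scores summed over
bases) is smoothed with a Gaussian filter (σ = 1.15, reflect boundary);
positive blocks are runs of ≥ 4 positions above 0.015, negative blocks
runs below −0.015. The negative threshold is symmetric by design: a
threshold of +0.015 for negative blocks would re-capture weak positive
signal. Ablation replaces block positions with uniform-random bases
(averaged over n_random draws; 5 recommended to marginalize the random
replacement) and reports the prediction change; "outside" ablations match
the upper half of the block-coverage distribution with a 5-position
minimum, and are recorded as skipped when infeasible.

**Pattern → PWM.** Contribution-space patterns are divided by the maximum
position score sum and multiplied by 10; the PPM is the row softmax.
Negative patterns first flip the sign of rows whose position sum is
negative and scale their magnitude by 1.2 (negative contributions are
systematically smaller in magnitude). The original pattern is retained as
the motif's CWM.

**Contribution-score motif scan.** Hypothetical maps are zero-padded by 5
on both sides; every window is Pearson-correlated with each motif CWM in
both orientations. Zero-variance windows are excluded (their correlation
is undefined) rather than scored 0. Per (cell, motif), up to 500,000
coefficients are sampled to set the threshold min(0.75, μ + 4σ).

**Motif summaries.** Per-motif contribution is the hit-correlation-
weighted mean of the masked-score sums inside hit spans, per cell;
directionality is the sign of the cross-cell mean (masked scores are used;
the hypothetical alternative is switchable upstream by passing different
maps). Co-occurrence is the percentage of a group's sequences containing
at least one instance of each motif of a pair. Motif ablation merges
overlapping hit spans before replacement.

**NMF programs.** Motif-count matrices (unique hit loci per sequence and
motif) are decomposed with Frobenius-loss NMF, deterministic NNDSVDa
initialization and multiplicative updates (scikit-learn; 2,000 iterations,
tol 10⁻⁶), k = 12 by default; k selection by bi-cross-validation is out
of scope. Coefficient rows are normalized to
sum 1 for reporting; program activity signatures are H-weighted averages
of per-motif contributions clipped at an upper bound of 3.

**Saturation mutagenesis.** Effects are variant activity minus reference
activity over the complete 3 · L variant table; the per-position logo
height is the negative mean effect, so destructive positions plot upward.

**k-mer diversity.** 4-mer count vectors, mean Manhattan distance to the
4 nearest neighbours (self excluded), via scikit-learn's NearestNeighbors.

## Synthetic-MPRA generator

The generator is the package's study condition, not a tuning knob. Default
grammar: 3 simulated cell types, each with 2 activators (effects drawn
once, uniformly from [1.5, 3.5] log2FC) and 1 repressor (effects in
[−2.5, −1]), motif widths 8–10 with 0.95 dominant-base probability,
baseline 0, Gaussian noise σ = 0.25, additive effects saturating (hard
clip) at ±6. Each simulated oligo is a uniform-random 200-mer with 0–4
planted consensus instances at non-overlapping positions and random
strands. Activities are computed from the *final* sequence: every grammar
motif's strong matches (PWM score ≥ 0.9 × consensus, both strands) are
counted and multiplied by the motif's effect. Counting occurrences rather
than planting events makes the label an exact function of the sequence —
with bookkeeping labels, incidental background occurrences of narrow
motifs decouple label from sequence and cap attainable held-out accuracy —
and matches the biological reading that a binding site acts wherever it
occurs. Planted consensus instances (sites at the motif's optimum) are the
deliberate simplification; the instance-level degeneracy of real binding
sites is represented in the PPMs used for scanning, penalties and
enrichment, not in the planted sites themselves.

What the generator does *not* emulate: barcode-level counting noise,
position or orientation effects, motif–motif synergy beyond additive
saturation, chromatin context, and sequence composition biases of real
genomes. Passing the recovery tests therefore demonstrates that the
machinery (model, designers, attribution, scan, NMF) is correct and
internally consistent — not that the desk-scale model matches the
performance of a production model trained on hundreds of thousands of
measured oligos.

## Problem sizes

The test suite and reference recomputations run at sizes chosen for a
single CPU: parameter recovery trains on 20,000 simulated oligos for 6
epochs (held-out r ≈ 0.97 per cell type, comfortably above the 0.85 bar);
the shared surrogate model for design/interpretation tests trains on
6,000; design comparisons use 10,000 random sequences as the baseline;
penalization-track checks use 12-sequence batches and 80-step
optimizations; SIG-based recall uses 30 sequences with two planted
activators each. Production-scale settings (full Basset-sized model,
500/250-sequence track batches, 300-step designs with 20 samples) remain
the config defaults.

## Known limitations

- The numpy engine is CPU-only and single-threaded beyond BLAS; it is not
  intended for training on full-scale MPRA compendia.
- The enrichment routine is a surrogate for a dedicated discovery tool:
  it finds strong ungapped motifs reliably but has no significance model
  beyond a count-ratio floor, and does not model gapped or multi-part
  patterns.
- The contribution scanner assumes ungapped CWMs; gapped patterns are
  better matched with sequence-space tools before summarization.
- Library-scale specificity percentages depend on the published per-oligo
  results table, which must be supplied by the user (`data/`); the SE ≤ 1
  filter is applied before counting, with an option to skip it.
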