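# Methods

## Task and data model

A sample is a pair of chromatin bins on one chromosome: two nucleotide
sequences over {A, C, G, T, N}, a numeric genomic-feature vector, and a
binary label (interacting / not). Coordinates are 0-based half-open
throughout. Datasets keep a 1:10 positive:negative ratio, mirroring the
class balance the training strategy is designed for. Bins of a pair are
required to share a chromosome; the chromosome-grouped splitter is undefined
otherwise and raises.

## Tokenization

The BPE trainer initializes the vocabulary with the base symbols (plus a
reserved padding token, id 0) and repeatedly merges the most frequent
adjacent token pair, rewriting the corpus, until the target size (default
4096) is reached or no pair occurs twice. Ties on the pair count are broken
in favour of the pair whose first occurrence appears earliest in the
rewritten corpus; this rule is what makes the two-iteration worked example
("AACGCACTATATA" → merge TA, then AC rather than TA+TA) deterministic, and
it is covered by an exact golden test. Inference applies the recorded merges
in training order (equivalently: always merge the present pair with the
lowest merge rank, left to right), so segmentations concatenate exactly to
the input; an independent replay oracle checks this equivalence.

Each sample becomes eight channels: {bin 1, bin 2} × {forward,
reverse orientation} × {top-k by corpus frequency, top-k by token length},
each mapped to ids and right-padded/truncated to a fixed slot count.
"Reverse orientation" is the reverse complement by default (the other
strand read 5′→3′); plain string reversal is available as
`reverse_mode="mirror"` for ablations. Top-k applies to token *occurrences
within one sequence* with ties broken by earlier position, so outputs are
order-preserving subsequences. N is an ordinary symbol for the tokenizer;
PWM scanning, by contrast, skips windows containing N because their score is
undefined.

Vocabularies are trained per fold on training-split sequences only — a
leakage guard asserted in tests — and serialized as a token-table TSV, a
merges TSV, and JSON metadata.

## Network

The sequence module embeds all eight channels with one shared matrix
(row 0 = padding, excluded from pooling by a mask). Each channel type gets an
ECA gate: with embedding dimensions as channels and token slots as positions,
attention is σ(Conv1Dₖ(GAP(F))) ⊙ F with the kernel size
k = ⌊log₂C/γ + b/γ⌋_odd (γ = 2, b = 1; floored to the nearest odd integer
per the governing formula — nearest-odd rounding is available via
`kernel_rounding="nearest"`). Because the attention coefficient is constant
across positions, gating commutes with the masked mean pooling that follows;
the implementation pools first and differentiates that form. Same-type
channel vectors from the two bins are concatenated and passed through a
dense/ReLU layer; the four fused vectors are concatenated and passed through
a second dense/ReLU layer. The genomic module is batch normalization
followed by dense/ReLU layers with dropout before its last layer. The two
module outputs are concatenated (either branch can be ablated via
`mode="seq"` / `"genomic"`), dropped out, and mapped by a final dense layer
to a sigmoid probability; labels are called at 0.5.

No deep-learning framework is used: forward and backward passes are written
in NumPy (embedding scatter-gradients via a sparse matrix product), with an
Adam optimizer. Correctness is enforced by finite-difference gradient checks
on every parameter group and an overfit-one-batch sanity property (200 steps
drive the loss below 0.05). Hidden sizes (64/128 dense units, 128-d
embeddings, dropout 0.5, Adam lr 1e-3, batch 32) are package defaults chosen
as conventional values for networks of this size; all are exposed in
`ModelConfig`.

## Training and evaluation

Chromosomes are shuffled by seed and split into 10 groups; each fold trains
on 9 groups and tests on 1, so train and test never share a chromosome —
positional autocorrelation otherwise inflates every metric (demonstrated
below). Within a fold, negatives are shuffled and dealt round-robin into
round(neg/pos) disjoint subsets (minimum 1; remainders make subset sizes
differ by at most one). Each subset plus all positives trains one sub-model
with a stratified 9:1 train/validation split, binary cross-entropy, and
early stopping on validation loss (patience 5, max 50 epochs; the
best-validation weights are restored). The ensemble prediction is the
arithmetic mean of sub-model probabilities. Test sets are balanced by
undersampling negatives (all positives kept) before computing AUPRC
(step-wise precision–recall integration, as in scikit-learn's average
precision), accuracy, Matthews correlation, and F1; folds whose test set
lacks positives are flagged invalid. Cross-cell protocols reuse the fold
plan: `cross_cell_matched` evaluates each fold's held-out chromosomes on a
second cell line's samples, and `cross_cell_plain` is ordinary (non-grouped)
K-fold, included to demonstrate leakage inflation.

The perturbation harness mutates each base independently with the configured
rate; event types are drawn from substitution:insertion:deletion weights
(default 10:1:1). Substitutions replace the base with a different uniform
base, insertions append one uniform base after it, deletions remove it — so
insertion/deletion events change sequence length, which the tokenizer
absorbs naturally.

## Motif analysis

A motif match is a length-L window whose summed PWM score reaches the
motif's threshold; all L_s − L_m + 1 windows are examined. Thresholds are
calibrated to a tail p-value (default 1e-4, uniform background) by exact
dynamic programming: PWM entries are quantized to a fixed grid (default
1e-4), per-position score distributions are convolved, and the smallest
achievable score whose tail mass is ≤ p is returned. On the quantized grid
the DP distribution equals brute-force enumeration over all 4^L windows
exactly, which the tests assert for L ≤ 8. HOCOMOCO-style plain-text count
matrices are converted to natural-log odds against a uniform background with
a configurable pseudocount (default 0.01).

Erasure replaces the union of a motif's matched intervals with uniform
random bases (length-preserving, overlaps erased once), using an RNG stream
keyed by (sample id, motif name) so per-motif experiments are reproducible
and independent of iteration order. For each motif the trained ensemble
re-predicts the modified held-out samples under three conditions (erase in
bin 1 only, bin 2 only, or both) and the AUPRC drop Δ_m is converted to

  Score_m = (Δ_m / C_m) · [α·f_m·log₂(α·f_m) + 1],

with C_m the mean matches per sample (both bins counted together), f_m the
length-weighted proportion C_m·l_m / Σ_j C_j·l_j, and α the correction
factor. The bracket is the p·log p entropy component shifted by one; with
α = N_M/e it attains its minimum exactly at f_m = 1/N_M and grows on both
sides, which is the stated purpose of the correction. The package therefore
defaults to `alpha_rule="corrected"` (α = N_M/e); the variant α = e/N_M is
kept as `alpha_rule="as_printed"` for comparability, since for that value
the minimum would sit at f_m = e²/N_M instead. Motifs that never match get a
null score and are excluded from ranking; the top 20 % by score are flagged.
A collateral-effect counter reports how many other motifs' total match
counts change after one motif is erased, quantifying motif overlap.

When several chromosome folds are available, the erasure experiment is
pooled: each fold's own ensemble scores its held-out balanced samples, the
per-fold AUPRC drops are averaged (raw probabilities are *not* pooled across
ensembles, whose calibrations differ), and erasure noise is additionally
averaged over independent replicate draws. This keeps every prediction
strictly chromosome-held-out while shrinking the variance of Δ estimates,
which on desk-scale data (tens of positives per fold) would otherwise drown
small effects.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes:
uniform-background sequences (optional GC skew), 200 positives and 2000
negatives of 2 kb bins on 20 chromosomes (round-robin within each class, so
every chromosome carries both classes at the global ratio), one causal
consensus motif planted in bin 1 and another in bin 2 (probability 0.9 in
positives, 0.1 in negatives), 18 decoy consensi planted label-independently
(probability 0.3 per bin), 8 informative features (signal label + Gaussian
noise, σ = 0.5) and 24 pure-noise features. Label noise flips the *causal
signal* of 2 % of samples while keeping their recorded label, so the class
ratio stays exactly 1:10. A manifest records every planted offset; a test
verifies that exact-match scanning recovers each planted causal occurrence.
Consensus PWMs score +2 on the consensus base and −1 elsewhere; the
threshold 2L − 3m admits up to m mismatches. For erasure experiments the
synthetic motif set uses exact-match thresholds (m = 0): a 7-mer at one
allowed mismatch has ≈5 chance matches per 4 kb sample, which would swamp
the planted occurrences in both C_m and Δ.

What the generator does *not* emulate: real contact-frequency statistics,
GC/repeat structure, chromatin-state filtering, overlapping regulatory
grammar, or distance effects. Passing the recovery tests therefore shows the
machinery is wired correctly and can detect planted signal at realistic
sizes — not that the model attains any particular accuracy on real data.

The leakage fixture removes the chromosome-agnostic feature signal and adds
(i) a per-chromosome random code vector and (ii) a signal feature whose sign
s_c ∈ {−1, +1} is fixed per chromosome: s_c·(2y − 1) + noise. A model can
exploit it only by learning a per-chromosome rule, which works under plain
K-fold (chromosomes shared between train and test) and fails under grouped
CV — reproducing the qualitative inflation of non-grouped evaluation.

## Problem sizes and numerical choices

The end-to-end experiments run at the generator defaults above with a model
configuration sized for a single CPU: 4096-token vocabulary, 32-dimensional
embeddings, top-120 token slots per channel (2 kb bins segment into ≈400
tokens of mean length ≈5; keeping the 120 highest-ranked occurrences
concentrates the long, specific tokens that carry planted-motif information
and reduces pooling dilution), dropout 0.2, Adam lr 2e-3, ≤50 epochs,
patience 8. Vocabularies are learned from a 300-sample (600-sequence)
subsample of each training split — BPE statistics are scale-invariant well
above this corpus size. The recovery experiment trains the full
(sequence+genomic) ensemble on one fold and sequence-only ensembles on three
folds for the pooled erasure ranking with three erasure replicates.
Motif-erasure and mutation experiments use sequence-only ensembles: the
synthetic genomic features are strongly label-correlated by design, and a
joint model's predictions would be dominated by them, masking the sequence
contribution being measured.

Other numerical details: BCE probabilities are clipped at 1e-12; batch-norm
uses ε = 1e-5 and momentum 0.1 (batches of fewer than 2 samples are skipped
during training); the score-distribution DP warns on degenerate PWMs whose
windows all score equally; `round(neg/pos)` uses banker's rounding (Python's
built-in), so 1050 negatives against 100 positives give 10 subsets.

## Known limitations

- Greedy BPE fragments planted motifs context-dependently: a planted 7-mer
  surfaces as its own (or a containing) token in only a minority of
  occurrences, and the mean-pooled bag-of-embeddings sequence module can
  only exploit token-level evidence. Sequence-only AUPRC on the synthetic
  default (≈0.6–0.75 per fold) sits well below the string-level ceiling
  (≈0.85), and erasure Δs are correspondingly small — the pooled,
  replicate-averaged design exists to make the causal-vs-decoy contrast
  reliable despite this.
- Balanced held-out folds contain only ≈20 positives at desk scale, so all
  per-fold AUPRC values carry noise of a few hundredths.
- Batch normalization of the genomic branch uses running statistics at
  evaluation; very small training subsets make those statistics themselves
  noisy.
- The NumPy network is single-threaded-CPU oriented; it is not intended for
  genome-scale training runs.
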