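# Methods

## Data model and encodings

A genotype matrix holds `n_samples × n_markers` integer classes with 0
reserved for missing. Two encodings are supported. Haploid two-parent cross
data uses classes {1, 2} for the two parental origins; raw −1/1 calls are
recoded so all values are non-negative (−1 → 2). Biallelic diploid data
uses {1, 2, 3} for `0|0`, heterozygous, and `1|1`; phased and unphased GT
separators are treated identically because the encoding is unordered, and
multiallelic or non-diploid VCF records are skipped with a warning rather
than erroring. For the network, classes are one-hot expanded over
`n_classes` channels; a missing entry is the all-zero channel vector, which
lets the same tensor represent "no information here" without a dedicated
missing channel.

## Corruption protocol and splits

Benchmarks corrupt a fully observed matrix by masking a fraction of the
*observed* entries to 0, uniformly without replacement, recording
coordinates and original values so the truth can be restored and scored.
Restricting the sampling pool to observed entries is invisible on fully
observed simulated data but generalises safely to real matrices with
pre-existing missingness (pre-existing holes are never "masked over" and
never scored). Splitting is sample-wise (whole individuals) into
train/validation/test. Validation and test sizes are `floor(frac·n)` with
the remainder assigned to the training split — e.g. 10 samples at
(0.65, 0.15, 0.20) give (7, 1, 2) — a deterministic rule that keeps the
training split the largest on small inputs.

## The autoencoder

The network is a 1-D convolutional hourglass over marker position. The
seven-layer variant (input layer plus six convolutions, hidden kernel
counts 32-64-128-128-64 and a final softmax layer with `n_classes`
kernels) interleaves the first two encoder convolutions with width-2
max-pooling and places width-2 nearest-neighbour upsampling before the
last two decoder convolutions; the five-layer variant (32-64-32 plus
output) has one pool/upsample pair. All convolutions share one odd filter
size (default 5), are same-padded, use ReLU hidden activations, and carry
an L1 penalty `λ Σ‖F‖₁` on filter weights only (λ = 10⁻⁴ default).
Dropout (p = 0.25) follows each pooling stage. Input lengths that are not
a multiple of the total pooling factor (4, or 2 for the five-layer
variant) are zero-padded internally and cropped on output; the pad region
carries target class 0 and is therefore automatically excluded from the
loss.

The output layer deserves a note: with three diploid genotype classes a
single sigmoid kernel cannot represent the reconstruction, so the model
ends in `n_classes` kernels with a channel-wise softmax trained by
categorical cross-entropy over non-missing target entries. For two-class
cross data this reduces to the binary case. Loss support is all observed
target entries, not just the masked ones — the denoising convention, which
also regularises the reconstruction of entries the corruption left intact.
A scalar-regression output is deliberately not implemented.

Training uses Adam (lr 10⁻³), minibatches of 32, at most a configurable
number of epochs with early stopping on validation loss (default patience
20) and restoration of the best-validation weights. The L1 term enters the
gradient as `λ·sign(W)` (subgradient); with Adam this parks irrelevant
weights in a small oscillation around zero rather than exactly at zero, so
"sparsity" is measured as the fraction of weights below a small magnitude
threshold. All layers and the optimiser are implemented directly in NumPy
(im2col convolutions through BLAS, float32 throughout); correctness is
guarded by a brute-force convolution oracle and end-to-end
finite-difference gradient checks in the test suite.

Imputation preserves every observed entry and assigns each missing entry
the argmax class of the softmax output; argmax ties break to the lowest
class index, deterministically, as do all other tie rules in the package.

## Classical baselines

*Column central value*: missing entries take the column's observed mode
(ties to the lower class) or the observed mean rounded to the nearest
class (half-way ties to the lower class); fully missing columns fall back
to the global mode. *KNN*: candidates for a missing entry (i, j) are rows
observed at j; distances are computed over markers observed in both rows
and normalised by the shared count (so rows with different missingness are
comparable — root-mean-square difference for the euclidean metric;
Pearson- and cosine-based distances are also available). The k nearest
candidates vote for their class at j, uniformly or inverse-distance
weighted (zero distances capped at 10⁸), with distance ties resolved by
stable sort toward the lower sample index. Voting is by (weighted) mode
rather than average-then-round because diploid classes are nominal; for
two-class data the two coincide. *SVD-EM*: missing entries start at
observed column means, then alternate between a rank-r truncated SVD of
the filled matrix and replacement of the missing entries by the low-rank
reconstruction, until the largest absolute change at a missing entry falls
below `tol` (default 10⁻⁴) or `max_iter` is reached (non-convergence
returns a flagged result rather than an error); final continuous values
are rounded to the nearest class. No log-transformation is applied
anywhere: genotype classes are bounded small integers, not outlier-prone
magnitudes.

All methods run behind one plug-in interface (corrupted matrix in,
completed matrix out), so the evaluation harness treats the autoencoder
and the baselines identically.

## Synthetic data

The simulators are structural emulators, not population-genetics
simulators — no coalescent, recombination map, or mutation model. The
*cross* simulator draws each sample as a Markov mosaic over the two
parental classes: first marker uniform, every subsequent marker switching
parent with probability `switch_rate` (default 0.01, giving mean parental
runs of 100 markers and near-balanced marginal class frequencies; run
lengths are geometric by construction). The *population* simulator draws,
per block of `block_length` markers (default 16), a pool of
`haplotypes_per_block` binary haplotypes (default 6) with per-marker
alternate-allele probability `1 − ref_allele_bias` (default bias 0.97);
each individual draws two pool haplotypes per block with replacement and
the genotype class is the allele sum plus one. Sharing the pool across
individuals produces genuine within-block LD rather than mere marginal
skew, while blocks remain independent. The defaults were chosen once to
place the two regimes where reference-free methods qualitatively separate:
balanced classes with very strong local correlation (column-wise
imputation near chance, ≈0.5) versus skewed classes with weaker blockwise
correlation (column-wise imputation already ≈0.95). Neither simulator
ever emits the missing code.

What the simulators do **not** capture: allele-frequency spectra of real
panels, long-range LD decay, population stratification, genotyping-error
processes, or non-random missingness. Passing benchmarks here demonstrates
that each method exploits the kind of structure it claims to exploit — not
that any particular accuracy will transfer to a real dataset.

## Evaluation design

Accuracy is the fraction of *masked test-split entries* imputed to the
held-out truth. The denominator is masked entries only; scoring observed
entries would saturate every method near 1 and is the only convention
under which a near-chance column-average result on balanced two-class data
is arithmetically sensible. The repeated-split experiment masks and splits
afresh per repeat (seed = base seed + repeat index, logged), applies every
method to the identical bundle, and summarises each (method, level) cell
by mean and standard deviation over repeats, plus a "total" row per method
whose mean and sd are the unweighted averages of the per-level means and
sds. Because the total row is a cross-level average, its sd is *not* the
standard deviation of the pooled run list — the pooled list is still
carried for plotting. Baselines are training-free and applied directly to
the corrupted test split; the autoencoder trains on the corrupted training
split against the clean training matrix with the corrupted/clean
validation pair driving early stopping.

The architecture sweep trains each (depth, filter size, kernel-count)
grid point at a reduced epoch budget and scores masked accuracy on the
validation split, reporting the full grid and the argmax. Kernel grids are
given as seven-layer hidden counts (a, b, c, c, b); the five-layer variant
uses (a, b, a).

## Problem sizes and numerical choices

The benchmark scale is 1000 samples × 1024 markers — large enough that
block and run structure dominate, small enough to train in minutes on one
CPU core; the headline comparisons in the tests and the acceptance script
train for ~10 epochs with early stopping, which on the strongly linked
cross data is already deep into the >0.98 accuracy plateau (the loss keeps
improving slowly through the L1 term long after accuracy saturates).
Unit-scale training tests use smaller matrices with proportionally higher
learning rates. Probabilities are clipped at 10⁻¹² before logs; non-finite
training loss aborts with a diagnostic rather than continuing silently.
Reproducibility is by explicit seeds everywhere (simulation, masking,
splitting, weight initialisation, minibatch order, dropout); training is
bit-reproducible on a fixed BLAS but not across BLAS implementations.

## Known limitations

- The L1 subgradient under Adam yields near-zeros, not exact zeros; at the
  default λ = 10⁻⁴ and short epoch budgets the weight distribution only
  begins to concentrate near zero, and strong sparsity appears at larger λ
  or much longer training.
- KNN is quadratic in samples (full pairwise distance matrix) and the
  per-entry vote is a Python loop; it is comfortable at benchmark scale
  but not tuned for biobank-scale inputs.
- The VCF writer emits a minimal synthetic header (positions are marker
  indices); it is a carrier for the encoded matrix, not an annotation-
  preserving round trip.
- Heterozygous class 2 collapses `0|1` and `1|0`; phase is not modelled.
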