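# Methods

## Problem and model

`ptmvar` predicts whether a specific residue of a protein carries a
post-translational modification (PTM), treating the question as binary
classification of a fixed-length peptide window centered on the candidate
site. Six PTM types are supported, each restricted to its modifiable
residues: phosphorylation (S/T/Y), acetylation (K), methylation (K/R),
sumoylation (K), ubiquitination (K) and N-glycosylation (N). The models are
enzyme-agnostic: they score whether *any* enzyme of the class could modify
the residue, not a particular kinase or ligase.

A window of odd length *n* (31 ≤ *n* ≤ 61 in production; smaller odd values
are allowed for fast fixtures) is one-hot encoded as an *n* × 22 matrix:
one channel per standard residue plus selenocysteine (U) and pyrrolysine
(O), with the pad character `X` — used where the window extends past a
protein terminus — mapping to the all-zero row. The channel order is the
20 standard residues alphabetically, then U, then O; only the content of
the alphabet matters to the model, the order is a fixed convention.

Each classifier is a stack of 1–4 `same`-padded 1-D convolutional blocks
(feature maps, kernel size, activation, optional batch normalization,
optional stride-2 max pooling, dropout), a fixed bidirectional GRU with 50
units per direction whose two final hidden states are concatenated, 1–3
dense blocks, and a single sigmoid output. Convolutions capture local
sequence motifs; the recurrent layer integrates longer-range dependencies
along the window. Training minimizes binary cross-entropy by mini-batch
gradient descent (batch 64) with early stopping; the weights of the epoch
with the best validation accuracy are kept.

The numerical core is an in-package reverse-mode automatic-differentiation
engine over float32 numpy arrays (`ptmvar._autodiff`). It implements
exactly the primitives these networks need (broadcast arithmetic, matmul,
activations, reductions, a patch extractor for convolution, max pooling)
and is verified against central finite differences in the test suite.
Runs are bit-reproducible given the integer seed: all randomness (weight
initialization, batch order, dropout masks) flows from seeded
`numpy.random.Generator` instances and execution is single-threaded
deterministic numpy.

## Corpus construction

Positives are sites with (in production) MS/MS evidence; in the synthetic
setting they are windows carrying a planted motif. Negatives are drawn
from the same residue types on proteins that carry at least ten positive
sites — the coverage requirement makes "no evidence" informative — after
removing anything present in the positive set or in a user-supplied
known-site list. The negative:positive ratio defaults to 1:1 by seeded
downsampling of the eligible pool; the ratio is configurable because no
canonical value exists. Samples are split 81% / 9% / 10% into
train / validation / test with exact-count (largest-remainder)
partitioning so split sizes are deterministic, either per site or per
protein; the per-protein mode guarantees no protein contributes windows to
two splits.

Sequence-similarity leakage control uses positional identity between
equal-length, center-anchored windows: matches divided by the number of
positions where both windows are non-pad (0 when there is no overlap).
Because windows are fixed-length and aligned on their centers, no general
alignment or clustering is needed; a test window is removed when its
maximum identity against any train/validation window exceeds the chosen
threshold (0.9 / 0.8 / 0.7).

## Architecture search

Network hyperparameters — the conv stack, dense stack, optimizer and the
window length itself — are evolved by a genetic algorithm. Production
defaults are 20 generations of 50 individuals, each evaluated by training
from scratch for at most 20 epochs with early stopping and scoring
validation accuracy at threshold 0.5. Selection is a size-3 tournament
with 2 elites carried over unchanged; crossover inherits each top-level
field intact from one parent; mutation independently resamples genes at
rate 0.2 and can grow or shrink a layer stack by one within bounds.
Fitness values are cached by genome so duplicates are never retrained.
The discrete option sets (feature maps {16, 32, 64, 128}, kernels
{3, 5, 7, 9}, dense units {32, 64, 128, 256}, dropout {0, 0.1, 0.25, 0.5},
four activations, three optimizers) live in one `SearchSpace` object and
can be swapped wholesale; `reduced_space()` provides a small space for
fast runs. The GRU width is fixed at 50 and is not searched; the layer
sits between the conv stack and the dense stack.

Optimizer step sizes (Adam 5e-3, RMSprop 2e-3, SGD with 0.9 momentum at
0.1) were chosen once so that all three optimizer choices reach high
validation accuracy on separable planted-motif data within the search
epoch budget of this engine; they are constants of the implementation,
not searched.

## Ensembling, thresholds, evaluation

After the search, the top genomes by validation accuracy (ten in
production) are retrained from scratch for up to 100 epochs. At prediction
time each member cuts its *own* window length around the queried position
— members with different *n* see different amounts of context — and the
member probabilities are combined by an outlier-excluded average: with
linearly interpolated quartiles Q1 and Q3 and IQR = Q3 − Q1, values
outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR] are dropped and the rest averaged.
When all members agree the bounds collapse to that value.

A site is called positive at ensemble probability ≥ 0.5. A stricter
high-confidence class uses the threshold at which at most 1% of held-out
negative test scores are exceeded (calibrated on ensemble scores, and
strict: high-confidence requires probability *above* the threshold).
Discrimination is summarized by AUROC in its Mann–Whitney form (ties count
one half), computed via scikit-learn and cross-checked against pair
enumeration in the tests.

## Variant delta scores

For a missense variant, candidate PTM sites are all positions within seven
residues of the variant where the reference and/or variant residue is
modifiable. The ensemble scores the site on both allele sequences using 15
true flanking residues per side (a 31-residue context, X-padded past the
protein ends, then re-padded or center-cropped to each member's window
length). The allele whose site residue is not modifiable is assigned
probability exactly 0; consequently a direct loss has delta equal to
−P(reference) and a direct gain equal to +P(variant), bit-exactly. The
signed delta P(variant) − P(reference) is primary; its magnitude at or
above 0.5 calls the variant PTM-altering (the inclusive boundary is a
convention of this package), the sign gives the direction, and the site's
coincidence with the variant position separates direct from proximal
effects. Concordance with modified-peptide MS evidence counts
variant-peptide-only detection as support for an increase call and
wild-type-only detection as support for a decrease; opposite detections
conflict; sites detected on both peptides, or not at all, are unevaluable.

## Positional attribution

Per-position contributions are Shapley values with the all-pad (all-zero)
window as the baseline, estimated by Monte-Carlo permutation sampling:
positions are revealed in random order and each position is credited with
the model-output change it causes, averaged over permutations. The
efficiency residual |Σ contributions − (f(x) − f(baseline))| is reported
and is zero up to Monte-Carlo noise; an exact subset-enumeration
implementation (feasible to 12 positions) serves as the oracle in tests,
where the Monte-Carlo estimate agrees within 0.02 at 2,000 permutations.

## Target-decoy site aggregation

Per-dataset site tables merge on (protein, position, residue, decoy
flag), keeping the maximum score, maximum localization probability, PSM
sum and dataset count. The global site FDR at score threshold t is
(#decoys ≥ t)/(#targets ≥ t) — plain counting without pi0 correction,
with score ties accepted or rejected together — and q-values are the
running minimum of FDR from the weakest score upward, so retention at any
q cutoff is threshold-consistent. Filtering retains targets with q ≤ 0.01
and maximum localization probability strictly greater than 0.5;
N-glycosylation sites must additionally sit in an N-!P-[ST] sequon (the
residue after the N is not proline and the second residue after is serine
or threonine; an N within two residues of the C terminus fails).
Rarefaction curves average the cumulative unique-site count over random
dataset orderings. Decoys are pooled per run, i.e. per PTM type.

## Synthetic data: what it emulates and what it does not

The generators produce the statistical skeleton of a PTM corpus without
any MS data. Positive windows carry a position-constrained motif
(N-!P-[ST] sequon; R-R-x-[ST]; [ST]-P) with configurable penetrance over a
uniform 20-residue background (U/O excluded); negatives share the center
residue and are rejection-resampled (capped at 1,000 attempts) so they
never match the motif. At penetrance 1 the classes are perfectly separable
— a Bayes classifier reaches accuracy 1 — which gives training a known
ceiling; at penetrance 0 the classes are identical and AUROC is 0.5 by
construction. Variant benchmarks plant or break the motif at known offsets
to produce direct/proximal gain/loss cases in equal rotation with recorded
ground truth. Site-table generators emit recurrent high-scoring true sites
and one decoy per noise site from a lower-shifted score distribution, so
FDR behavior has a designed expectation.

Real corpora differ in ways these fixtures deliberately omit: residue
composition is not uniform, real motifs are degenerate and overlapping,
negatives are contaminated by undetected true sites, and detectability is
biased by tryptic digestion. Passing the synthetic tests therefore
demonstrates that the machinery — encoding, search, training, ensembling,
delta scoring, FDR control — is correct, not that any particular accuracy
will transfer to biological data.

## Problem sizes and numerical conventions

The end-to-end tests and the acceptance script use a reduced configuration
chosen as a realistic desk-scale exercise of every component: a 500/500
strict-sequon corpus at window 31, a 3-generation × 8-individual search
over the reduced space at ≤ 5 epochs, a top-3 ensemble trained up to 60
epochs, a 200-case variant benchmark, and 30 attribution windows at 150
permutations each. Quartiles use linear interpolation; the positive call
is inclusive at 0.5 while high-confidence and localization filters are
strict; degenerate inputs (single score, all-pad window, zero decoys)
take the limits stated above. Window lengths are restricted to odd values
so "centered" is exact.

## Known limitations

The classifiers see only local sequence; structural context (burial,
disorder) is invisible, so solvent-inaccessible look-alike motifs will
score as modifiable. The autodiff engine is CPU-bound and sized for
desk-scale corpora, not for hundreds of thousands of sites. The
similarity filter is positional identity between aligned windows, which is
stricter in spirit but narrower in scope than general sequence clustering.
HGVS parsing covers simple substitutions only (no indels or stop-gains),
and variants are protein-coordinate; genomic mapping is out of scope.
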