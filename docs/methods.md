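# Methods

## Terminator definition and coordinates

A terminator is the 170-nt window around a cleavage and polyadenylation
site: the 150 nt ending immediately before the cleavage base plus the 20 nt
beginning at it, extracted half-open as `[site − 150, site + 20)` on the
annotated strand (minus-strand sites are reverse-complemented so output
always reads 5'→3'). Designed library members carry a CA dinucleotide
written at 1-based positions 150–151; a molecule cleaved at the designed
site therefore retains exactly 150 bases, and throughout the package
"cleavage position" equals the 1-based length of the retained prefix. All
sequences are stored in the DNA alphabet; RNA motifs (AAUAAA, UGUA) are
matched through the U↔T equivalence, since synthesis and sequencing operate
on DNA.

Site selection keeps every experimentally determined primary site, secondary
sites supported by at least 30% of a gene's reads, and annotation-derived
3'-UTR ends only for genes with no experimental site. The library-size
constants (18,450 + 2,325 + 3,754 Arabidopsis records; 25,685 + 4,407 maize
records; control-class sizes) are recorded in `seqlib.LIBRARY_COMPOSITION`.

## Strength estimation

Per sample, barcodes with fewer than 5 reads are discarded; the filter is
applied independently to the DNA input and RNA output, and a barcode
contributes only if it survives in both. Counts are aggregated per
terminator, converted to within-sample shares, and the output/input share
ratio is scaled to the 35S reference. Terminators absent from either sample
are dropped rather than zero-filled — no pseudocounts are used, matching the
exclusion of data not present in both replicates. Replicates are averaged on
the linear scale and the log₂ taken afterwards. Ψ is computed over the set
of terminators quantified in both systems: per system, log₂ strengths are
min-max normalized to [0, 1] and Ψ is the tobacco-minus-maize difference, so
+1 is maximally tobacco-specific.

## Synthetic data generator

The generator provides a parameter-recovery surface for every downstream
stage. Its deterministic strength model is

    S(seq, system) = baseline × Π_m (1 + b_m · 1[motif m present])
                     × exp(−(GC − opt)² / 2σ²)

with motif bonuses b = (0.40, 0.50, 0.40) for AAUAAA/UGUA/U-G-rich in
tobacco and (0.20, 0.20, 0.20) in maize — the average strength gains
measured for motif-positive terminators — and GC optima 0.325 (tobacco) and
0.40 (maize), the mean GC content of Arabidopsis and maize terminators. The
penalty width σ = 0.12 was fixed once so that the strength range across a
typical random library spans the observed order-of-magnitude differences
without collapsing GC-atypical sequences to zero. Motif presence is defined
by substring indicators (AATAAA; TGTA; TGTTT or GTGTG) so that an
independent script can recompute any strength exactly.

`make_library` emits random 170-mers scrubbed of chance indicator
occurrences, plants each motif independently (probability 0.5 by default) at
its modal library position (AAUAAA at 125–130, i.e. ending ~20 nt upstream
of the cleavage site; UGUA at 112–115; the U/G-rich element at 131–140), and
writes the designed CA at 150–151. Planting at fixed modal positions mirrors
the strong positional preferences of the real elements; it also means a
model trained on these data need not learn position invariance.

Counts are negative binomial (variance μ + μ²/φ, dispersion φ = 10 by
default) around a configurable DNA depth; RNA counts are negative binomial
with mean proportional to the *realized* DNA count times the true strength,
independently per replicate and system, which mirrors the estimator's
conditional RNA/DNA definition. 3'-end molecules draw a cut position from
the terminator's site mixture or, with the read-through probability, extend
the full insert into a 52-nt plasmid backbone; each receives a geometric
poly-A tail of ≥10 A's and an 8-nt UMI, and PCR duplicates sharing sequence
and UMI are injected at rate 0.3. The simulated backbone is poly-A-free and
C-terminated so that tail trimming of backbone-cleaved molecules stays
unambiguous.

What the generator does **not** emulate: sequencing errors and quality
scores, barcode synthesis errors, adapter chimeras, internal priming, RNA
secondary structure, and any coupling between strength and cleavage-site
choice. Passing recovery tests therefore demonstrates the correctness of the
estimators under the stated noise model, not robustness to artifacts of real
libraries.

## Feature analytics

k-mer counting is overlapping, forward-strand only (terminators act at the
RNA level), with the 4ᵏ columns in fixed lexicographic ACGT order; row sums
equal L − k + 1 by construction. PWM scanning scores log₂ odds against a
uniform background (matrix entries floored at 1e-4), normalizes the best
offset score so the weakest possible sequence scores 0 and the consensus 1,
and calls a match at ≥ 0.85. Normalization makes the score invariant to
per-column constants, so the choice of log base is immaterial. Undefined
correlations (zero-variance windows or constant k-mer columns) are reported
as missing, never coerced to 0. The rank-sum test uses the exact null
distribution for tie-free groups of ≤25 and the tie-corrected normal
approximation otherwise (delegated to scipy's Mann-Whitney implementation;
verified against a full permutation-enumeration oracle in the tests).

## Strength models

The 6-mer lasso fits one L1-penalized linear model per assay system on a
70/30 train/test split, with the penalty chosen by 5-fold cross-validation
on the training split (scikit-learn LassoCV). Targets are log₂ strengths.

The convolutional model is a DenseNet over one-hot DNA: a 128-filter
kernel-5 stem; four dense blocks of 6, 12, 24, and 16 composite layers
(batch-norm → ReLU → 12-filter kernel-3 convolution), each layer's output
concatenated onto its input; transitions with a kernel-1 convolution halving
the channels and average pooling by 2; and a fully connected head with two
outputs (tobacco, maize). Channel bookkeeping follows the concatenation
formula (128 + 6×12 = 200 after block 1, 100 after its transition) and is
validated structurally at construction. The layers run on `termstarr.nn`, a
compact numpy engine (single-precision, im2col convolutions, hand-derived
backward passes, Adam) that is deterministic given a seed under
single-threaded BLAS.

Training choices, fixed as conventions where the problem is genuinely open:
Adam at 1e-3 (halved on validation plateaus, floor 1e-4), batch 128, at most
100 epochs, early stopping with patience 10 on validation loss and
restoration of the best weights; mean squared error summed over the two
outputs on per-output standardized log₂ strengths; 81/9/10
train/validation/test split. The head is configurable: `flatten` (the
default, position-specific read-out) or `gap` (global average pooling before
the linear layer). Averaging over positions matches globally defined
targets such as composition effects and motif presence, and generalizes much
better from a few thousand training sequences; the learnability checks
therefore use a reduced configuration (32-filter stem, two 2-layer blocks,
growth 8, `gap` head) sized for single-CPU runs, while the full-depth
default is exercised structurally.

In-silico evolution enumerates all 3L = 510 single-substitution variants per
round, scores them in one batch, and keeps the argmax of the objective (one
system's predicted strength, or the sum of both), breaking ties
lexicographically by (position, base). By default the best variant is always
taken, matching the literal iterative procedure; with `keep_current=True`
the incumbent is retained when no variant improves, guaranteeing a monotone
objective. Attribution is in-silico mutagenesis: the score delta of every
possible point substitution, zero at the reference base.

## Cleavage-site calling

Reads are poly-A trimmed (maximal 3' suffix that starts with a clean A-run —
10 bases or the full suffix, whichever is shorter — is ≥5 long, and contains
at most one non-A per 10 tail bases), then matched as prefixes of the
designed sequences extended with the 52-nt backbone, allowing ≤2 Hamming
mismatches; reads whose best hit is tied between references are discarded,
an ambiguity rejection that plays the role of a map-quality filter when the
reference set is a known designed library. One molecule is kept per
(terminator, UMI) pair; conflicting lengths under one UMI collapse to the
modal length, ties to the shortest. Terminators with fewer than 20 unique
molecules are discarded.

Sites are local maxima of the read-length histogram smoothed with a centered
3-point moving average; each maximum is snapped to the raw-count argmax
within the smoothing half-window, peaks closer than 5 nt to a stronger peak
are suppressed, and a site's fraction is the raw-count share within ±2 nt of
the peak (minimum 0.05 to be reported). The primary site is the
largest-fraction site; a strong secondary site is any other site with ≥30%
of the reads. Cleavage probability is the fraction of unique molecules with
length ≤ 170. The five-way classification (site at 150 ± 5, primary at
150 ± 5, multiple sites, strong secondary, backbone-only cleavage) uses the
inclusive interval [145, 155]. The smoothing window, separation, and
fraction thresholds are declared defaults of this implementation — the
notion of "local maxima" admits many concrete realizations — and are all
configurable.

## Numerical and degenerate-input conventions

- Seeds: every stochastic routine takes an explicit seed; generators are
  bit-reproducible for a fixed seed and emit only A/C/G/T.
- Quantile binning breaks value ties by identifier so bin sizes differ by at
  most one for distinct values.
- Ψ raises on a degenerate (constant) strength range rather than dividing by
  zero; empty histograms, empty groups, and windows wider than their
  sequence raise informative errors.
- Random 8-nt UMIs collide at the birthday rate, so deduplicated molecule
  counts can fall marginally below the simulated molecule count; this is a
  property of UMI labelling itself, not a defect of the deduplicator.

## Problem sizes

Recovery checks run at 500 terminators × 8 barcodes × 2 replicates at ~100
DNA reads per barcode (strength), 2,000 sequences for network training, 400
sequences for lasso recovery, and 200 terminators × 150 molecules for
cleavage calling — sizes at which the guarantees above hold with margin on a
single CPU in a few minutes.

## Known limitations

- The DenseNet's real-data predictive ceiling cannot be assessed here; the
  learnability checks quantify optimization and generalization on the
  generator's noise-free surface only.
- Subassembly (terminator↔barcode linkage from paired reads) is out of
  scope; the barcode map is an input.
- The cleavage caller assumes a designed reference library; it is not a
  genome-wide poly(A)-site caller and performs no internal-priming
  filtering.
- Motif discovery (STREME-style) and DeepLIFT/TF-MoDISco attribution are out
  of scope; motif matrices are inputs, and attribution is in-silico
  mutagenesis.
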