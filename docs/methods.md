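# Methods

## Coordinates and the locus window

All coordinates — on disk and in memory — are 0-based, half-open. The
CYP2D6 capture window on hg19 is `chr22:[42521567, 42528984)`, length
7,417 bp, spanning the gene body plus 2,103 bp of upstream and 934 bp of
downstream flank. Variants use a left-aligned minimal representation
(single-base ref/alt for SNVs; a shared single anchor base for indels,
e.g. `T>TA`, `TA>T`); loaders reject non-minimal or multi-nucleotide
records rather than normalizing them, and multi-allelic or overlapping
variants on one haplotype are an error.

## The functional variant representation

A haplotype is encoded as an L × C binary matrix. Channels 0–3 one-hot
encode the nucleotide after applying the haplotype's variants; the
remaining channels are binary annotations in a fixed order: coding, rare,
deleterious, indel, methylation, dnase, tfbs, eqtl, active_site. Two
points in this design were genuinely open and are resolved as follows:

* **12 vs 13 channels.** The default (`paper12`) uses eight annotation
  channels, dropping `active_site` — the only protein-level annotation and
  the last listed — for a 7417 × 12 matrix over the locus window. A
  `full13` mode keeps all nine; its first twelve columns coincide with
  `paper12` (a tested invariant). The baseline count vector always uses
  all nine annotations.
* **Channel scope.** Interval-track annotations (coding, methylation,
  DNase, TFBS, eQTL, active site) are set at *every* covered position, so
  the reference context is informative; variant-scoped annotations (rare,
  deleterious, indel) are set only at positions where the haplotype
  carries a non-reference allele, so variants stay salient. A
  variant-only mode for the track channels is available as a config
  switch (`tracks_everywhere=False`).

Indel handling keeps L fixed: an insertion writes its first inserted base
at the anchor position and raises the INDEL flag there; a deletion leaves
the reference bases in place and raises the flag at the anchor. The
rare/deleterious flags are consumed from a precomputed table (upstream
pipelines combine population frequency filters with deleteriousness
predictors, loss-of-function calls taking precedence); the encoder treats
that table as authoritative and errors on variants missing from it.

Diplotypes are channel-wise concatenations (L × 2C) of two haplotype
matrices; a single haplotype is duplicated into both halves, matching how
the final classifier consumes star alleles. Concatenation was chosen over
summing the two matrices because it preserves phase and makes "two
identical copies" the natural single-haplotype input.

## Activity score and simulation

Per-allele activity values are none = 0, decreased = 0.5 (0.25 by
configuration), normal = 1; a diplotype's AS is the sum, giving classes
{0, 0.5, 1, 1.5, 2} at the default. The simulator draws ordered allele
pairs uniformly *within* each AS class until each class holds exactly
`n_per_class` samples — distributionally equivalent to rejection-sampling
uniform pairs into class quotas, but constant-time per draw. Suballeles
participate with their parent core allele's function. Background
variation: at every site of the allele-frequency table, each haplotype
independently carries the alternate with probability equal to its
population frequency; sites must be disjoint from all star-allele core
variant sites (checked, error otherwise). Gene duplications and other
structural variants are out of scope, so increased function is never
predicted.

Continuous activity measurements (the stage-2 signal) are synthetic:
`activity = intercept + slope · AS + N(0, σ)`, in percent of reference,
defaults slope = 50, intercept = 0, σ = 26. With balanced classes,
Var(AS) = 0.5 and the closed-form variance fraction explained by the AS is
s²Var(AS)/(s²Var(AS)+σ²) ≈ 0.65 at the defaults — chosen to emulate how
much of real liver-microsome activity an activity score typically
explains. This is a stand-in for a real in vitro dataset: it has the right
signal-to-noise structure but none of the substrate-, lab- or
expression-system effects of real assays.

## The synthetic locus generator

`generate_synthetic_locus` builds a self-consistent miniature study
system: a random reference window; a coding track over the interior
(~10–80 %) of the window with the remaining tracks as random intervals;
star alleles whose core variants carry class-informative flag patterns —
no-function alleles a rare *and* deleterious coding variant
(loss-of-function-like), decreased-function alleles a rare, benign-
predicted coding variant, normal-function alleles one or two common benign
variants; and a background allele-frequency table. Background sites are
placed outside the coding track with frequencies in [0.05, 0.5), i.e.
common polymorphisms whose `rare` flag is 0 under the frequency rule, so
background variation adds nucleotide-level noise without mimicking a class
signal. Every emitted variant appears in the flag table, and the same seed
regenerates byte-identical tables.

What passing tests on this fixture do and do not show: they demonstrate
that the pipeline can extract a function signal that is genuinely present
in the annotation channels and generalize it to unseen variant positions;
they do not show that real curated labels are predictable at the same
accuracy, since the real mapping from variants to function is far noisier
and not a deterministic function of two flags.

## Architecture and training

The network is three convolution blocks (convolution spanning the full
channel depth → ReLU → non-overlapping max pool), a flatten, fully
connected layers with dropout, and an interchangeable head: 5-way softmax
(AS classification), one linear unit (activity regression), or two sigmoid
units (the ordinal function classifier). Full-scale defaults are filters
(100, 64, 64) of widths (19, 11, 7), pools (3, 4, 4), dense (256, 256),
dropout 0.3; these sizes are not critical and everything is configurable.
Two documented reductions exist: `small()` — filters (32, 32, 32), pools
(4, 4, 4), dense (64, 64), dropout 0.1 — for windows of a few kb, and
`tiny()` for sub-kb test windows. The lighter dropout in the reduced
specs matters: with small dense layers and sparse binary inputs, dropout
0.3 reliably stalls optimization in the uniform-prediction plateau of the
softmax loss.

Losses are cross-entropy (stage 1), mean squared error on standardized
targets (stage 2), and the sum of two binary cross-entropies (stage 3).
Optimization is Adam on shuffled minibatches; training monitors a
stratified holdout (⌈0.10 · n⌉ per class) and restores the weights of the
best validation epoch (early stopping with configurable patience). All
randomness flows through seeded generators; a fixed master seed fixes
splits, initializations, dropout masks and batch order, and therefore the
entire loss trace.

Weight transfer is exact (bit-level copies): stage 1 → stage 2 transfers
the convolutional layers, stage 2 → stage 3 transfers convolutional and
dense layers; heads are always freshly initialized. The final stage trains
`ensemble_size` members (default 10; the ablation harness uses 7) that
differ only in head initialization and minibatch order; scores are
arithmetic means over members. One practical finding encoded in the
defaults: fine-tuning on the small star-allele set must use a learning
rate at or below the pre-training rate (`final_learning_rate`, default
equal to `learning_rate`), otherwise the fine-tuning stage overwrites the
transferred representation and generalization to unseen alleles collapses.

## Cutoff calibration

For each score separately, the cutoff maximizes Youden's J over the
training scores under the rule *positive = score > c*. J is piecewise
constant between consecutive unique score values; the fitted cutoff is the
midpoint of the optimal interval (edge intervals close at 0 and 1, scores
being probabilities), and ties take the lowest optimal interval. Mapping:
`s_notnone ≤ c1` → none; otherwise `s_normal ≥ c2` → normal, else
decreased. Degenerate sub-tasks (a single target class, or all scores
identical) are an error rather than a silent J = 0 fit.

## Baseline

The comparison model is a proportional-odds ordinal logistic regression
from the nine annotation counts to the ordered classes, parameterized as
`logit P(Y ≤ k | x) = ζ_k − x·β` with strictly increasing thresholds (the
convention of the classical polr implementations, so a positive
coefficient shifts mass toward higher classes). The likelihood is
maximized by BFGS (gradient tolerance 1e-8) on centered features with an
unconstrained threshold re-parameterization ζ₂ = ζ₁ + exp(δ). Complete or
quasi-separation drives the ML slopes unbounded; fits whose slope norm
exceeds 10 (or goes non-finite) are refit with an L2 penalty (α = 1) on
the slopes and flagged `regularized=True`. The reported log-likelihood is
always the unpenalized one at the returned parameters.

## Attribution

Attributions follow the DeepLIFT rescale rule, propagated as multipliers
from one output back to the input: linear layers contribute their weights;
elementwise nonlinearities the ratio Δoutput/Δinput relative to the
reference (falling back to the local gradient where Δinput ≈ 0, where the
contribution is zero anyway); max pooling distributes its output delta
across window inputs proportionally to their squared input deltas. Each
per-layer rule satisfies Σᵢ mᵢ·Δxᵢ = Δy exactly, and the chain rule
preserves this, so summation-to-delta holds to numerical precision for
the whole network — inputs identical to the reference get exactly zero
attributions, and for a purely linear model the attribution reduces to
weight × (input − reference). The reference is the variant-free *1
haplotype encoded with the same tracks (duplicated for diplotype inputs).
The post-sigmoid output is attributed by default (configurable to the
logit); per-variant importance is the channel sum of attributions at the
variant's anchor position, covering both diplotype halves, and is defined
only where the input encoding actually differs from the reference. Signs
are retained; magnitude is the natural ranking key.

## Evaluation statistics

Accuracy and the 3 × 3 confusion matrix use the fixed class order none,
decreased, normal (rows = truth). AUROC uses the Mann–Whitney rank
formulation with ties counted one half — identical to pair counting and to
the trapezoidal ROC area. Variance explained by predicted labels is the R²
of a group-means (label-indicator) linear model, SS_between/SS_total. The
one-way ANOVA is the classical F test across predicted groups. Outlier
exclusion (e.g. extreme in vitro measurements) is the caller's
responsibility; the metric functions take filtered input.

## Problem sizes in the checks

The acceptance workflow uses a 2 kb synthetic window with three alleles
per class and 50 background sites; stage-1 training uses 1,000 diplotypes
per AS class (5,000 total) with 200 per class held out for testing, the
`small()` architecture, batch 64, learning rate 1e-3, up to 10 epochs with
patience 3. The simulator quota check runs the full 10,000-per-class
(50,000-sample) generation and verifies every label against the
brute-force AS oracle. Unit and property tests use 500–600 bp windows and
the `tiny()` architecture so the whole suite stays lightweight.

## Known limitations

* Structural variants, hybrid genes, deletions and duplications are out of
  scope; increased function is never predicted.
* Rarity and deleteriousness are consumed as precomputed flags, not
  derived from annotation databases.
* The positional information in the flattened dense layers means
  generalization to variants at unseen positions leans on pre-training
  coverage of those positions; the simulation stage is what provides it.
* The synthetic activity data emulate signal-to-noise only; conclusions
  about real in vitro assays require real measurements.
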