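# Methods

This note documents the models, conventions and numerical choices behind
`regionrsa`, and what the synthetic-data validation does and does not show.

## Design assumptions

The pipeline targets a fixed experimental design: 6 stimuli (2 faces, 2
tools, 2 nonsense images), 2 merged sections of up to 80 presentations per
stimulus, epochs −100…700 ms resampled to 10 ms (81 bins), and a
whole-cortex parcellation of 82 regions (41 areas × 2 hemispheres). The
canonical region order interleaves hemispheres — each area appears as a
(left, right) pair — so averaging homologous regions to 41 areas is a
reshape. Left-hemisphere MNI seeds are x-mirrored from the packaged
right-hemisphere table. The 12 (stimulus, section) conditions are ordered
stimuli 1–6 of section 1, then of section 2.

## Region reduction

Each region's spatial basis is the top-3 left singular vectors of the
vertex × (time·trials) matrix, vertex-mean centered, fitted once per
subject on all trials of both sections jointly. A single fixed basis keeps
the classifier's feature space identical across conditions; the alternative
of fitting per section would break cross-section generalization of boundary
weights, so it is not the default. Component signs are fixed by
making the largest-magnitude vertex loading positive, which makes boundary
weights reproducible across runs. Regions need ≥ 3 vertices; with exactly 3
the reduction is an orthonormal rotation (lossless).

## Decoding

Two-class LDA on the 3-dimensional scores with pooled within-class
covariance Σ and ridge Σ + λ·(tr Σ/3)·I, λ = 10⁻³. Eighteen training
points in 3 dimensions are almost always well conditioned; the trace-scaled
ridge only guards degenerate draws and keeps the rule invariant under
global rotations and rescalings of the component space. Each of the
`n_randomizations` (default 100) repetitions re-draws both the pseudo-trial
composition (random partition of the condition's trials into 10 groups of
⌊n/10⌋ or ⌈n/10⌉, larger groups first) and the held-out pseudo-trial per
class; accuracy pools all 2·n_randomizations test classifications.
Decision-score ties (exactly 0) count as errors; none are expected with
continuous data. The dissimilarity handed to RSA is the mean accuracy, not
d′. Boundary normals are oriented from the second class toward the first
(pairs are stored with the lower canonical entry index first).

## Model RDMs

Values are 0 (similar) / 1 (dissimilar) on valid cells; diagonals and all
cells of an excluded condition are invalid. Type 2 ("category vs nonsense")
restricts the matrix to the 8 entries of one meaningful category plus
nonsense and additionally masks same-stimulus cross-section cells (4 of the
28); type 3 ("one vs rest") keeps all 12 entries and masks all 6
same-stimulus cross-section cells. The "meaningful" type-3 variant treats
faces + tools as one group, so face–tool pairs are *similar* cells. No
exclusions beyond these are applied (in particular, face–tool cells remain
valid in type 3). Correlation is Spearman with average-rank ties (decoding
accuracies tie often, being multiples of 1/(2·n_randomizations)); a cell
needs ≥ 3 jointly valid pairs and a non-constant model, otherwise it
propagates as missing (NaN), never as zero. Fisher z = atanh(ρ) with |ρ|
clipped to 1 − 10⁻⁶.

## Group statistics

One-sample t of subject z-values against 0, two-sided by default (the
directional hypotheses would justify one-sided; sidedness is a flag).
BH-FDR is pooled over the full region × time grid per model — q = 0.01 for
type-1/2 models, 0.05 for type-3 — not per region. A region's onset is the
first significant bin strictly after 0 ms, with no minimum run length.
Bootstrap tests of decodability characteristics resample participants with
replacement (1000 samples, percentile 95% CI; reject when 0 is outside).
The chance level for raw decoding comes from a label-permutation null that
reassigns class labels to the pooled raw trials *before* pseudo-trial
averaging.

Model specificity of the spatial maps uses Bartlett's sequential
dimensionality test in a one-way MANOVA with the g = 3 model maps as
groups: χ² = (n − 1 − (p + g)/2) Σ_{i>d} ln(1 + λ_i) on the eigenvalues of
W⁻¹B, df = (p − d)(g − d − 1); with p = 41 hemisphere-averaged areas and
d = 1 the test of "means are collinear" has df = 40. Treating a subject's
three maps as independent observations ignores their within-subject
dependence; the function's docstring carries this caveat and the test
should be read as descriptive.

## Repetition analysis

Only section 1 is analyzed by default. Sequential segments use the same
⌊n/10⌋/⌈n/10⌉ block rule as pseudo-trials but in presentation order, with
the larger blocks first so segment 1 is the start of the section. The
boundary weights of a category's pattern are the mean of the unit
discriminant normals over that category's exemplar-versus-nonsense pair
classifiers and the window's time bins (both sections' entries by default),
each normal oriented toward the category exemplar, renormalized. Amplitude
extraction averages the projected evoked response over the window, then
over the category's 2 exemplars, and takes the absolute value *last* — so
the result is invariant to a global sign flip of the weights. The pooled
regression fits all subject × segment points at once: the printed df
(1, 10·n_subjects − 2) comes from pooling, not from averaging per-subject
slopes.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:
trials = Σ effects + i.i.d. Gaussian noise (optionally time-smoothed with a
unit-energy Hann kernel). An effect is a region-confined unit spatial
loading × temporal envelope × per-trial amplitude. The envelope is a
raised-cosine (sin π x) bump stretched half a time-step beyond the stated
window so every bin inside the window carries signal while bins outside
carry none; its window mean (≈ 0.65 for a 4-bin window) attenuates
recovered repetition slopes by a known factor. Category-shaped effects
share one loading across exemplars plus a small exemplar jitter (relative
magnitude 0.2), which is exactly the within-category similarity structure
the type-2/3 models assume; stimulus-specific effects draw an independent
loading per stimulus, identical across sections, matching the
stimulus-recognizer model. Repetition trends add `slope × segment` to the
amplitude of each trial by its presentation-order segment, making injected
segment means exactly linear before noise. Spatial leakage (a stand-in for
inverse-solution blur) mixes vertices with a row-normalized triangular
kernel over region distance on the synthetic line layout.

What the simulations do *not* emulate: realistic forward/inverse geometry,
1/f and physiological noise, inter-subject anatomical variability, trial
autocorrelation, or any empirical effect-size information — no real
recordings ship with the package, so injected amplitudes are free
parameters chosen to make recovery well-posed. Passing tests therefore demonstrate
correctness and calibration of the *procedure*, not expected performance on
real recordings.

## Validation problem sizes

The validation experiments (`regionrsa.experiments`, reused by the test
suite and `scripts/acceptance.py`) default to reduced sizes chosen as a
deliberate trade-off between Monte-Carlo resolution and a desk-scale
runtime: null decoding at 8 subjects × 20 regions × 12 conditions × 50
trials × 20 randomizations; FDR calibration as 100 replicate end-to-end
null pipelines at a miniature size (4 regions, 21 bins, 10 randomizations);
effect recovery at 6 subjects × 20 regions over the full 81-bin grid (so
onsets live on the 10 ms grid) × 20 replicates with 10 randomizations;
repetition sign recovery at 4 subjects × 20 replicates. The recovery grid
is deliberately mostly null: a region's onset is its *first* significant
post-stimulus bin, so one BH false positive landing pre-window in a target
region spoils that replicate's onset; the realized BH threshold scales as
q·k/m, and a larger grid m keeps that event near the 1% level per
replicate. In the recovery experiment, cells carrying
*either* injected effect are excluded from the false-positive count in both
model maps, because the other category's effect is neither a true positive
nor a clean null there. All randomness flows from one seed through keyed
child streams (`regionrsa._rng`), so results are independent of execution
order.

## Known limitations

- The LDA randomization couples pseudo-trial re-draws with fold selection;
  variance estimates across randomizations are therefore not independent.
- FDR control is marginal per model map; no across-model correction.
- The MANOVA independence caveat above.
- `read_dataset` materializes all subjects in memory; very large vertex
  counts should be processed per subject via `simulate_subject` or split
  files.
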