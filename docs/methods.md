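# Methods

## Scope and model

`uvfrac` analyses a fractionated (chromatin pellet vs cytoplasm) RNA-seq time
course after UV-C irradiation and ships a mechanistic generator that produces
such data with known ground truth. The biological picture: UV-C deposits
RNAP-II-blocking photolesions (chiefly cyclobutane pyrimidine dimers) on the
DNA template; elongation stalls at the first unrepaired lesion while
transcription-coupled repair clears them over hours; nascent chromatin-bound
signal therefore collapses and recovers gene by gene, and the cytoplasmic
mRNA pool follows with the lag set by export and decay.

### Lesion placement and repair

Lesions are placed on the *genomic* template (introns included), since the
polymerase traverses the full span: the count is Poisson(rate × span) with a
default rate of 5×10⁻⁴ lesions per base (500 per megabase) at the reference
10 J/m² dose, scaling linearly with dose, and positions are uniform over the
span. Each lesion carries an exponential repair time with configurable
half-life (default 4 h, in the range of hours-scale CPD clearance from
transcribed strands); repair is i.i.d. per lesion with no strand bias. A
drawn repair time per lesion — rather than an independent Bernoulli per
timepoint — makes the unrepaired count non-increasing along each gene's
trajectory.

### Lesion-blocked elongation

Transcriptional activity at time t is the transcribable fraction of the
template:

    activity(t) = min(D, span) / span,
    D = max(proximal_window, offset of first unrepaired lesion),

with D = span when no unrepaired lesion remains. The promoter-proximal
window (default 25 kb, the upper end of the 20–25 kb of residual activity
reported for damaged long genes) keeps the 5′ end productive regardless of
downstream damage. A direct consequence is that genes shorter than the
window are never called repressed, and strong (≥4-fold) repression requires
a span of at least four windows — the simulator's length–recovery coupling
is purely mechanistic, not imposed.

### Two compartments

The chromatin (nascent) expected signal is `baseline × activity(t) ×
retention(biotype) × induction(t)`; noncoding biotypes carry chromatin
retention multipliers > 1 (4–6×) so that lncRNAs/TUCPs are
chromatin-enriched, as fractionation experiments consistently find. The
cytoplasmic pool follows first-order accumulation

    M(t+Δ) = M(t)·e^(−δΔ) + (s̄/δ)(1 − e^(−δΔ)),

with s̄ the trapezoidal interval mean of exported synthesis
(`baseline × activity × export_fraction`), decay δ = 0.25 h⁻¹ (cytoplasmic
half-life ≈ 2.8 h), and the analytic δ→0 limit M(t) + s̄Δ. M(0) is the
pre-UV steady state s(0)/δ. The 0 h library is harvested *untreated*;
kinetic quantities indexed at t = 0 describe the instant after exposure.

### UV-induced genes

A configurable fraction of genes (default 10%) is UV-induced with a constant
post-exposure multiplier (default +2.5 log2). Without this class the design
would contain no "induced" ground truth and the four-way recovery
classification could not be validated. Induction and lesion blockage
multiply, so an induced long gene can legitimately present as repressed
early and induced late.

### Counts

Expected compartment means are rescaled per library to a fixed depth
(default here 10⁶–2×10⁶ fragments; analyses in the tests use 10⁶) and counts
are drawn negative-binomially with variance μ + αμ² (α = 0.05; α = 0 gives
Poisson). Replicates (default 3) are i.i.d. The real experiment sequenced
pooled replicates; simulated true replicates are a statistical necessity for
dispersion estimation, and no attempt is made to mimic pooled-library
inference. All randomness derives from one seed through per-gene
`SeedSequence` substreams keyed by (domain, gene index), so growing the gene
set never changes earlier genes' draws and every output is byte-reproducible.

### Ground truth labels

Expected (noise-free) log2 effects versus baseline are thresholded at
|log2FC| ≥ 1 into down/ns/up per timepoint, and the same five-way pattern
rule used by the analysis classifier maps the pattern to a truth class.
Sharing the rule means accuracy measurements isolate the noise/inference
chain rather than a definitional mismatch. A fifth label, `other`, can occur
(e.g. a cytoplasmic dip at 3 h only); accuracy summaries use the four named
classes. `strong_effect_mask` selects genes whose non-null effects are ≥ 2
in magnitude and null effects ≤ 0.25, i.e. genes away from the decision
boundary.

### Direction switch for noncoding recovery

`fraction_effect_direction` defaults to `short_first`: all biotypes share
the lesion-load model, under which short genes carry fewer lesions and are
released sooner, so recovered genes are shorter on average. `long_first`
applies to noncoding biotypes only and scales the per-gene repair half-life
as `repair_length_scale / span` (default scale 100 kb): longer noncoding
genes clear lesions faster and recover first, flipping the sign of the
length–recovery association without touching any analysis stage. This is a
phenomenological hook for the observation that chromatin-associated
noncoding transcripts that recover tend to be the longer ones; it makes no
mechanistic claim.

## Analysis stages

* **FPKM** — counts × 10⁹ / (length × column total), with gene length = sum
  of exon lengths (the standard convention; the upstream pipeline's length
  convention is not recoverable). An FPKM entry is zero iff the count is.
* **Expressed-gene filter** — max FPKM over the samples of at least one
  fraction ≥ 1 (inclusive).
* **Size factors** — median-of-ratios over genes nonzero in all samples,
  rescaled to geometric mean 1. Accurate to <1% when ≥80% of genes are
  non-DE (verified by simulation).
* **Chromatin enrichment** — (mean chromatin FPKM + ε)/(mean cytoplasm FPKM
  + ε), ε = 0.1 FPKM by default; a drop-zero-cytoplasm mode is available
  since no zero-handling rule is standard. Pooled-timepoint and
  untreated-only modes are both exposed; neither is privileged. Per-biotype
  summaries use Welch's t on log2 folds (unequal variances are the norm
  between biotype groups; a pooled-variance flag exists).
* **Differential expression** — a self-contained NB Wald test: per-fraction
  median-of-ratios normalisation; method-of-moments dispersion
  `max(0, (var − mean)/mean²)` pooled across timepoint groups and shrunk
  50/50 toward the 12.5%-trimmed mean across genes; log2FC on normalised
  means with a 0.5-count pseudocount; delta-method SE
  `(1/ln2)²[(1/μ_A + α)/n_A + (1/μ_B + α)/n_B]` with means floored at the
  pseudocount inside 1/μ so on/off genes keep a finite statistic; two-sided
  normal p; BH adjustment within each (fraction, contrast) family; calls at
  |log2FC| ≥ 1 (inclusive) and padj < 0.05 (strict). No LFC shrinkage is
  applied because the decision boundary operates on raw log2FC. Type-I error
  is verified ≈ 5% on null NB simulations.
* **Recovery classification** — the five-way rule over (0.5 h, 3 h, 24 h)
  statuses given in `temporal`. The boundary case [down, ns, down] is
  assigned `not_recovered` (repressed early and still down at the endpoint);
  `other` is reserved for patterns such as down only at 24 h.
* **Clustering / PCA** — k-means (k-means++ init, best of 50 restarts,
  seeded) on row-z-scored per-timepoint log2(FPKM+1) profiles; zero-variance
  rows z-score to zeros. Default k values (7 cytoplasm mRNA, 6 chromatin
  mRNA, 12 chromatin lncRNA) mirror common choices for this design but carry
  no claim about membership. Sample PCA is column-centred SVD with variance
  fractions from squared singular values.
* **Feature analysis** — group means/medians of CDS length, transcript
  length, exon length and intron count; 100 bp histograms for lengths, width
  1 for intron/exon counts, with interior empty bins emitted; Welch t tests
  against a reference group; single-exon fraction = exon-count bin 1 / n.
  `per_isoform` mode counts all isoforms when an isoform table is supplied.
* **lncRNA/TUCP cascade** — fixed stage order: (1) length ≥ 200 nt and
  determinate strand; (2) no ≥1-base same-strand exonic overlap with the
  reference (any-strand mode available; an unknown-strand candidate is
  checked against both strands); (3) max FPKM ≥ 0.5; (4) ORF-based
  coding-potential scoring of survivors. The ORF heuristic (longest
  ATG→stop ORF over the three sense frames, stop excluded; noncoding < 300
  nt; coding ≥ 900 nt with ≥ 0.8 transcript coverage; uncertain otherwise →
  TUCP) is a deliberately simple, fully testable proxy for external
  coding-potential predictors; its thresholds are conventional ORF-length
  cutoffs, and the class boundaries should not be over-interpreted
  biologically. Antisense ORFs are not scanned (sequences are sense-strand
  by contract). Known-lncRNA database matching is out of scope.

## What the generator does and does not emulate

Emulated: the fraction × timepoint × replicate design; realistic biotype
mixtures, span/exon-count/CDS distributions; dose-scaled lesion density;
hours-scale repair; promoter-proximal escape; compartment lag; NB
overdispersion; chromatin retention of noncoding RNAs; UV induction.

Not emulated: read-level artefacts (mappability, GC, positional bias),
isoform switching and splicing dynamics, transcription-coupled vs global
repair strand asymmetry, inter-replicate batch effects, pooled-library
sequencing, genotype differences (a `--no-repair` flag sets the half-life
infinite, nothing more). Passing tests therefore demonstrate correctness of
the inference chain under the stated generative model, not performance on
any real dataset; the real study's headline magnitudes (mean CDS lengths,
single-exon percentages, gene counts) depend on its external data and are
deliberately not targets.

## Numerical choices and degenerate inputs

Gene spans are clipped to [200 nt, 2.5 Mb]; exon counts to what the span can
host (≥ 300 nt per exon+intron pair on average). Exon placement scales drawn
exon lengths down when they exceed span − (k−1) and distributes intron
lengths by a multinomial composition with 1 nt minimum. FPKM refuses
zero-total columns by name; size factors refuse matrices with no
all-nonzero gene and advise a pseudocount. The Wald test defines
(log2FC, p) = (0, 1) when both group means are zero. BH validates inputs to
[0, 1]. Truth/fixture TSVs store floats via `repr` and are read back with
round-trip float parsing, so fixture I/O is exactly lossless. k-means
restarts share a seed-derived prefix, so inertia is non-increasing in the
number of restarts.

## Problem sizes used in tests and the acceptance script

Routine tests run a 320-gene experiment; statistical checks use 1,500–2,000
genes, 3 replicates and 10⁶-fragment libraries, sizes at which every
verified property (FDR ≤ nominal, balanced accuracy ≥ 0.9, Welch p < 0.01
on the length–recovery effect, moment recovery of α within 10–20%) is
stable across seeds. These are the package's reference conditions for
desk-scale validation; all of them are configuration, not constants.
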