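# uvfrac

Analysis toolkit for **fractionated UV-response transcriptomics**: RNA-seq
of chromatin-associated (nascent) and cytoplasmic (mature) RNA sampled at
0, 0.5, 3 and 24 h after UV-C irradiation. UV photolesions stall elongating
RNA polymerase II; transcription-coupled repair clears them over hours, so
nascent output collapses and recovers gene by gene while the cytoplasmic
pool follows with an export/decay lag. `uvfrac` is for computational
biologists studying this transcriptional shutdown-and-recovery programme —
and for anyone who wants a fully controlled synthetic benchmark of it.

The package pairs every analysis stage with a mechanistic simulator, so the
whole pipeline is testable without any external download:

* **`simdata`** — synthetic annotation (four biotypes: mRNA, annotated
  lncRNA, novel lncRNA, TUCP); Poisson lesion placement at 5×10⁻⁴ per
  template base (500 per megabase at 10 J/m²); per-lesion exponential
  repair; lesion-blocked elongation with a 25 kb promoter-proximal active
  window — activity(t) = min(max(window, first unrepaired lesion offset),
  span)/span; first-order cytoplasmic accumulation
  M(t+Δ) = M·e^(−δΔ) + (s̄/δ)(1 − e^(−δΔ)); negative-binomial counts
  (variance μ + αμ²); ground-truth labels per gene and fraction.
* **`quant`** — FPKM = counts·10⁹/(length·total); expressed-gene filter
  (FPKM ≥ 1 in at least one fraction); median-of-ratios size factors;
  chromatin enrichment (chromatin FPKM/cytoplasm FPKM) with per-biotype
  summaries.
* **`diffexpr`** — self-contained NB Wald test per fraction and timepoint
  vs 0 h: method-of-moments dispersion with shrinkage, delta-method SE,
  Benjamini–Hochberg adjustment, calls at |log2FC| ≥ 1 and padj < 0.05.
* **`temporal`** — recovery classification (recovered / not_recovered /
  induced / unchanged / other) from the post-UV status pattern; seeded
  k-means clustering of temporal profiles; sample-level PCA.
* **`features`** — CDS/transcript/exon-length and intron-count
  distributions for gene groups, 100 bp histograms, Welch t tests.
* **`lncfilter`** — the novel-lncRNA/TUCP cascade: ≥ 200 nt with known
  strand → no same-strand exonic overlap with the reference annotation →
  max FPKM ≥ 0.5 → ORF-heuristic coding-potential call (noncoding → novel
  lncRNA, uncertain → TUCP, coding → discard), with per-stage audit counts.

## Worked example

```python
import pandas as pd
from uvfrac import SimConfig, simulate_experiment
from uvfrac.quant import CountMatrix, compute_fpkm, chromatin_enrichment
from uvfrac.diffexpr import run_de
from uvfrac.temporal import classify_recovery_table

cfg = SimConfig(
    n_genes={"mRNA": 300, "annotated_lncRNA": 80, "novel_lncRNA": 80, "TUCP": 40},
    library_size=500_000, seed=42,
)
models, truths, counts, lengths, design = simulate_experiment(cfg)

fpkm = compute_fpkm(CountMatrix(counts, lengths))
biotypes = pd.Series({g.gene_id: g.biotype for g in models})
fold, summary = chromatin_enrichment(fpkm, design, biotypes=biotypes)
print(summary.round(3))

calls = classify_recovery_table(run_de(counts, design))
print(calls[calls.fraction == "chromatin"]["label"].value_counts())
```

prints

```
                    n     q1  median     q3  t_vs_ref  p_vs_ref
biotype
mRNA              300  0.376   0.415  0.462       NaN       NaN
annotated_lncRNA   80  1.486   1.662  1.895    42.089       0.0
novel_lncRNA      80  2.207   2.507  2.751    61.748       0.0
TUCP               40  1.574   1.705  1.834    37.867       0.0
label
unchanged        339
recovered         58
induced           54
not_recovered     34
other             15
```

The enrichment table shows the simulated noncoding biotypes
chromatin-enriched relative to mRNA (median folds 1.7–2.5 vs 0.4), and the
chromatin time courses split into the recovery classes; in this run the 58
recovered genes average a 104 kb genomic span versus 209 kb for the 34
not-recovered genes — short genes, carrying fewer lesions, recover first.

The same steps are available from the shell:

```sh
uvfrac simulate --seed 42 --out fixtures/
uvfrac quantify --counts fixtures/counts.tsv --design fixtures/design.tsv \
    --gtf fixtures/annotation.gtf --out quant/
uvfrac de --counts fixtures/counts.tsv --design fixtures/design.tsv --out de/
uvfrac classify-recovery --de de/de_all.tsv --out recovery.tsv
```

## Limitations

The simulator validates the inference chain, not any real dataset: it omits
read-level biases, splicing dynamics, repair strand asymmetry and
pooled-library effects, and the published magnitudes for this experimental
design depend on external data that is out of scope here. See
`docs/methods.md` for the full model description, parameter rationale and
numerical conventions.
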