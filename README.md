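# screenkit

Analysis toolkit for three related pipelines from a murine AML study design:

1. **Pooled shRNA dropout screen** — NTC-anchored count normalization,
   per-shRNA log2 fold changes against input samples, quantile
   normalization, alpha-RRA gene essentiality with a shRNA-permutation FDR
   (essential = gene FDR < 0.01 with >= 3/5 supporting shRNAs and negative
   mean logFC), and differential fold-change (DFC) classification of genes
   with preferential growth inhibition in one cell line, thresholded at an
   empirical NTC quantile.
2. **Single-cell signature scoring** — percent-expressing per cell, mean
   z-score signature and lineage scores, boxplot-style cluster summaries
   and pseudotime-binned score trajectories.
3. **Region-set GSEA** — partition transcription-factor peaks by
   co-binding with a partner factor, assign peaks to genes through ±50 kb
   TSS windows, group them into signature-specific region sets, and test
   each set for a global differential-binding shift with a preranked
   enrichment score, random-set permutation null, NES and FDR.

A synthetic-data module generates screen libraries (default design: 344
target genes × 5 shRNAs, 30 killing controls in 3 pseudo-genes, 45 NTCs),
barcode count matrices from multinomial sequencing of exponentially grown
clones (10 doublings by default), signature-structured single-cell
expression fixtures with a pseudotime axis, and genomic peak fixtures with
planted co-binding and binding shifts — so every stage is testable with
known ground truth.

## CLI

```sh
# synthetic screen with ground truth
screenkit simulate --config cfg.yaml --outdir sim/ --seed 7

# normalization -> fold changes -> quantile normalization
screenkit screen normalize --counts sim/counts.tsv --meta sim/samples.tsv \
    --library sim/library.tsv --out fc.tsv

# essentiality (alpha-RRA + permutation FDR)
screenkit screen essential --fc fc.tsv --library sim/library.tsv \
    --cell-line mut --alpha 0.25 --nperm 1000 --seed 7 --out essential.tsv

# differential essentiality between two lines
screenkit screen dfc --fc fc.tsv --library sim/library.tsv \
    --line-a mut --line-b ref --essential-a essential.tsv \
    --ntc-quantile 0.05 --out dfc.tsv

# signature scoring (dense TSV or MTX triplet input)
screenkit score --expr expr.tsv --ann ann.tsv --sig sig3.txt --out scores.tsv

# region-set enrichment
screenkit gsea-regions --tf tf.bed --partner partner.bed --tss tss.tsv \
    --stats stats.tsv --nperm 1000 --seed 7 --out gsea.tsv
```

All coordinates are BED-style 0-based half-open; TSS tables are read as
1-based and converted. Fold-change TSV columns follow
`<cellline>__r<replicate>`.

## Layout

```
src/screenkit/
  synthetic.py     fixture generators (screen, expression, genomic) + ground truth
  screen.py        library/counts I/O, NTC size factors, logFC, quantile normalization
  essentiality.py  NTC empirical null, alpha-RRA, permutation FDR, essential calls
  dfc.py           differential fold changes, NTC cutoff, preferential classification
  signatures.py    signature/lineage scores, cluster summaries, pseudotime profiles
  regions.py       interval overlap, TSS windows, region sets, preranked GSEA
  cli.py           click entry points
tests/             unit + property tests per module, test_acceptance.py
scripts/acceptance.py
```
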