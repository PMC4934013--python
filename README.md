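# riboscope

Analysis toolkit for ligation-free ribosome profiling of complex tissue.
It covers the full computational path from raw reads to biology:

- **`riboscope.synthetic`** — synthetic data generator: transcript
  annotations with AUG-controlled 5'UTRs, cell-type expression with a
  bimodal neuronal TE mixture, ligation-free-structured footprint reads
  (G-rich prefix + footprint + poly(A) tail), RNA-seq count tables, and
  RiboTag IP/homogenate pairs. Pure function of (config, seed).
- **`riboscope.preprocess`** — fixed trimming (first 5 / last 20 bases),
  3' poly(A) clipping (runs of ≥ 8 A's), a 15-nt length filter, rRNA
  subtraction (substring match, ≤ 1 mismatch), a toy exact/near-exact
  transcriptome mapper with unique-gene semantics, duplicate marking.
- **`riboscope.qc`** — 3-nt periodicity power spectrum of 5' mapping
  positions, gene-body distribution, saturation curves under nested
  downsampling, between-library count correlation.
- **`riboscope.quantify`** — region counting, median-of-ratios size
  factors, translation efficiency (per-sample / group modes with the 37 /
  75 raw-count thresholds), RiboTag enrichment scores, and the
  qPCR `2^(1−CQ)` abundance conversion.
- **`riboscope.celltype`** — cell-type enrichment scores
  `E = FPKM_ij / Σ_k FPKM_ik − 1/2`, specific gene lists (score > 0.2),
  pairwise comparison scores, deterministic rank lists.
- **`riboscope.gsea`** — classic (unweighted) pre-ranked GSEA with
  gene-set-permutation NES / nominal p / FDR q, TE-binned gene sets
  (0.75 log2-TE-unit bins anchored at the median), NES heatmaps, and
  margin-based GO-to-cell-type assignment (≥ 3 NES units).
- **`riboscope.utr`** — 5'UTR ribosomal-density flags, uAUG scanning,
  abundance-weighted UTR length / GC, binned median TE, Mann–Whitney
  comparisons.
- **`riboscope.diffte`** — treated-vs-untreated TE fold changes, a
  condition-label permutation test with BH FDR (a clearly labelled
  substitute for RiboDiff, which is not re-implemented), and the
  three-way TOP-motif / ribosomal-protein overlap summary.

## Command-line interface

All stages are exposed via `riboscope <subcommand>`:

```bash
riboscope simulate --n-genes 200 --depth 100000 --seed 1 --out-dir sim/
riboscope preprocess --fastq sim/footprints.fastq --annotation sim/annotation.tsv \
    --fasta sim/transcripts.fasta --out aln.tsv
riboscope qc --alignments aln.tsv --annotation sim/annotation.tsv \
    --fasta sim/transcripts.fasta --out-dir qc/
riboscope quant --ribo-counts ribo.tsv --rna-counts rna.tsv --mode group --out te.tsv
riboscope celltype --fpkm fpkm.tsv --out-dir celltype/
riboscope gsea --rnk celltype/neuron.rnk --gmt te_bins.gmt --out gsea.tsv
riboscope go-assign --nes nes_matrix.tsv --out go.tsv
riboscope utr --annotation sim/annotation.tsv --fasta sim/transcripts.fasta \
    --counts counts.tsv --te te.tsv --out utr.tsv
riboscope diffte --te-treated te_trt.tsv --te-untreated te_unt.tsv --out diffte.tsv
riboscope qpcr --cq 1 --cq 2 --cq 3
```

File formats are plain text throughout: FASTA/FASTQ (optionally gzipped),
TSV count tables, GSEA-dialect RNK rank lists and GMT gene sets.

## Conventions

- Transcript coordinates are 0-based half-open; regions tile the
  transcript as `utr5 = [0, cds_start)`, `cds`, `utr3`.
- Reads are assigned to regions by their 5' end position.
- TE uses CDS counts only; thresholds apply to raw counts and guarantee
  positive denominators (no pseudocounts).
- GSEA tie-breaking in rank lists is lexicographic by gene id; TE bin
  intervals are half-open `[edge, edge + width)`.
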