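# epidrift

Analysis pipeline for histone-code drift between tissue and organoid samples,
built around H3K4me3/H3K27me3 ChIP-seq peak lists and RNA-seq count matrices:

1. **peak consensus** — per-condition summarized peak lists from two
   replicates: a peak is kept if it appears in both replicates (pairs merged
   by maximum breadth / maximum tag density) or if a singleton's fold
   enrichment is strictly above a rescue threshold (default 5.0);
2. **gene annotation** — each gene gets a binary two-bit modification code
   per sample (order H3K4me3–H3K27me3: `00`, `10`, `01`, `11`); a mark is
   present when a consensus peak overlaps the promoter (TSS ± 1000 b) or gene
   body by ≥ 5% of the peak's breadth; sex-chromosome genes are excluded;
3. **SOM profiles** — self-organizing-map metagene grids over per-gene
   profiles, with sample portraits, correlation clusters, under-expression
   spots, K-means landscape partitions and a correlation spanning tree of
   samples;
4. **drift calling** — deterministic classification of genes into transition
   clusters `a`–`h` (e.g. `c`: `(10)` in every tissue sample and `(00)` in
   every organoid sample; `g`: loss of H3K27me3 at stable H3K4me3 only in
   long-term culture) with strict all-sample consistency;
5. **transcription** — RPM/RPKM normalization, group log10-ratios
   (Δlog(T)), pooled Welch tests of cluster expression, gene-set Z-scores and
   hypergeometric over-representation with Benjamini–Hochberg correction;
6. **synthetic data** — a planted-truth simulator (genomes, per-condition
   modification states, noisy replicate peak calls with dropout and
   fold-enrichment draws, negative-binomial counts coupled to the planted
   states) that makes every downstream stage testable offline.

All state communicated between stages is plain text (BED6+, TSV, GMT, JSON),
0-based half-open coordinates throughout.

## CLI

```sh
epidrift run --config config.yaml --seed 1      # full synthetic pipeline
epidrift validate --config config.yaml          # config check, no execution
epidrift simulate --outdir sim --seed 1         # scenario inputs only
epidrift consensus --rep1 r1.bed --rep2 r2.bed --mark H3K4me3 -o cons.bed
epidrift encode --genes genes.tsv --peaks s1 H3K4me3 cons_k4.bed \
                --peaks s1 H3K27me3 cons_k27.bed -o codes.tsv
epidrift som --matrix codes.tsv --codes --rows 30 --cols 30 -o som_out
epidrift drift --codes codes.tsv --sample-sheet samples.tsv -o calls.tsv
epidrift normalize --counts counts.tsv --out-rpkm rpkm.tsv
epidrift expr-test --rpkm rpkm.tsv --cluster genes.txt --group-a t1,t2 --group-b s1,s2
epidrift gsz --rpkm rpkm.tsv --gmt sets.gmt -o gsz.tsv
epidrift enrich --cluster genes.txt --gmt sets.gmt --universe universe.txt -o enrich.tsv
```

Config is YAML; every `RunConfig` field (see `epidrift/pipeline.py`) is a
key.  `epidrift run` writes all intermediates plus `manifest.json` with
parameters, seeds, artifact checksums and planted-truth recovery metrics —
reruns with the same config are byte-identical.

## Declared statistical conventions

Where the upstream methods leave details open, this implementation fixes:
log base 10 and a pseudocount of 0.1 RPKM for all log transforms; the
gene-set Z-score of a sample is the mean of the member genes' across-sample
z-scores of log RPKM times √(set size); Welch's unequal-variance t-test on
per-gene group means; Benjamini–Hochberg correction across gene sets;
"reliably measured" means mean RPKM ≥ 1 across samples.  Each is a keyword
argument or config knob.
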