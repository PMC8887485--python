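# epiquant

Quantitative analysis of chromatin-mark dynamics, in two arms:

1. **Histone PTM quantification** from LC-MS/MS of chemically derivatized
   H3 tryptic peptides. Free and monomethylated lysines are labelled with
   heavy-isotope methyls (reductive dimethylation, ¹³CD₂O/NaBD₃CN) and
   peptide N-termini propionylated, so every modification isoform of a
   peptide acquires a predictable mass. Relative abundances follow the
   standard convention: the total XIC area of a peptide across all its PTM
   forms is 100 %, and each form's percentage is its area over that
   total. Positional isomers that are isobaric at MS1 (e.g.
   K27me1·K36me2 vs. K27me2·K36me1) share one precursor peak and are
   split by the ratio of their unique b/y fragment-ion intensities.
   Condition contrasts are reported as log₁.₅(%B / %A).

2. **ChIP-Rx domain analysis** for two-condition spike-in ChIP-seq.
   Per-sample scaling factors Rx = 10⁶ / (spike-in reads) normalize
   20-bp binned coverage so samples are quantitatively comparable across
   sequencing depths; replicates are averaged; peak sets partition into
   cluster I (A-only), II (shared, overlap ≥ read length) and III
   (B-only); genes are associated with peaks through TSS−2.5 kb ..
   TES+2.5 kb windows, and genes whose normalized signal rises ≥ 2-fold
   are classified "strong". Composite profiles around peak centers
   (± 5 kb) and scaled TSS–TES metagenes are computed from the same
   tracks.

Both arms ship a synthetic-data generator with known ground truth
(log-normal area noise for MS1, proportional fragments plus an additive
floor for MS2, Poisson bin counts for ChIP), so the whole pipeline is
testable from first principles at desk scale. It is aimed at chromatin
biologists and proteomics analysts who want the arithmetic behind these
two workflows reusable, seeded, and verified against independent oracles.

## Worked example

PTM arm, pure Python:

```python
from epiquant import simulate, ptm_model, ptm_quant

scheme = ptm_model.DerivatizationScheme()
truth = simulate.demo_ptm_truth(seed=1)              # sigma = 0.05 noise
peaks, spectra = simulate.simulate_ptm_run(truth, scheme)
catalogue = ptm_model.h3_isoform_catalogue()
table = ptm_quant.quantify_run(peaks, spectra, catalogue, scheme)
for lab, pct in sorted(table.marginals["H3:27-40"].items()):
    print(f"{lab:8s} {pct:6.2f} %")
```

prints, for the H3 27–40 peptide (marginal per-site percentages; each
site totals 100 %):

```
K27ac      5.20 %
K27me1    28.70 %
K27me2    23.16 %
K27me3    18.42 %
K27un     24.53 %
K36me1    12.52 %
K36me2    16.67 %
K36un     70.80 %
```

i.e. the simulated ground truth (K27me1 28 %, K27me3 20 %, …) recovered
within the configured log-normal area noise; rerunning with
`area_sigma=0` recovers it exactly.

ChIP-Rx arm, from the shell:

```bash
epiquant simulate-chiprx --seed 1 --out-dir sim       # 20 basal + 8 new domains
epiquant normalize --counts sim/counts.tsv --tracks-dir sim --out-dir norm
epiquant cluster --peaks-a sim/peaks_A.bed --peaks-b sim/peaks_B.bed --out-dir clus
epiquant classify --track-a norm/A.normalized.bedgraph \
                  --track-b norm/B.normalized.bedgraph \
                  --genes sim/genes.tsv --out-dir cls
cat clus/summary.json
```

```json
{
  "cluster_I": 0,
  "cluster_II_A": 20,
  "cluster_II_B": 20,
  "cluster_III": 8
}
```

The 8 domains present only in condition B land in cluster III, and
`cls/gene_signal.tsv` flags exactly those 8 genes as strong
(`fold_change ≥ 2` on Rx-normalized means over TSS−2.5 kb .. TES+2.5 kb)
despite condition B being sequenced 1.5× deeper — the depth imbalance the
spike-in normalization removes. Every command drops a `manifest.json`
with its parameters and output checksums; rerunning with the same seed
reproduces identical checksums.

Other subcommands: `simulate-ptm`, `quant-ptm`, `report` (log₁.₅
fold-change matrix), `assign-genes`, `profile` (peak-center or scaled
TSS–TES composite profiles).

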