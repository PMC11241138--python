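# tfmirnet

Reconstruction of a transcription-factor-driven miRNA regulatory network
from ChIP-seq promoter binding and knockdown differential expression.

## The problem

A master transcription factor (the bundled defaults are written for TFEB,
the lysosomal/autophagy regulator studied in endothelial cells) does not
only act on protein-coding genes: by binding the promoters of primary
miRNA transcripts it can switch whole post-transcriptional programs on or
off. Identifying that indirect layer requires integrating three assays:

* **ChIP-seq** peak calls for the TF, assigned to promoter windows
  (±2500 bp around each transcript and pri-miRNA TSS);
* **mRNA-seq** of knockdown vs control, giving differentially expressed
  genes (DEGs: |log2FC| > 1, FDR < 0.05, among genes with TPM > 1 in at
  least one replicate);
* **small-RNA-seq** of the same contrast, giving differentially expressed
  mature miRNAs (DEMs: |log2FC| > 0.5, FDR < 0.1, among matures with a
  normalized count > 1 in at least one sample; each mature's expression is
  the mean over its precursors).

A peak counts for a promoter only when its −log10(p) exceeds 3 **and** it
overlaps the window by more than 100 bp (both strict); a gene is bound when
any of its transcript promoters is. DEMs whose promoters carry a binding
event are linked to predicted targets (TargetScan-style pairs) through the
**sign-opposition rule**: an edge miRNA→gene is kept iff

    (log2FC_miRNA > 0 and log2FC_gene < 0)  or
    (log2FC_miRNA < 0 and log2FC_gene > 0).

Two networks are exported: one with all sign-opposed DEG targets, and one
restricted to target genes whose own promoters are TF-bound (with TF→gene
edges added). Promoters are additionally annotated with H3K27ac/H3K4me3
presence and scanned for the TF's JASPAR-style motif (log2-odds PWM,
relative score ≥ 0.8 on either strand).

Because the real knockdown sequencing data are not public, the package
ships a first-class synthetic-data module: it generates a toy genome,
plants a known TF→miRNA→target network (bound promoters with passing
peaks, negative-binomial counts with planted effects, miRNA-mediated
repression that produces sign-opposed fold changes), and scores how
exactly the pipeline recovers what was planted.

## Worked example

```python
from tfmirnet import SimulationConfig, simulate
from tfmirnet.pipeline import run_integration
from tfmirnet.synthetic_data import score_recovery

bundle = simulate(SimulationConfig.strong_signal(seed=1))
result = run_integration(
    tss=bundle.tss, chrom_sizes=bundle.chrom_sizes, matures=bundle.matures,
    gene_lengths=bundle.gene_lengths, tf_peaks=bundle.tf_peaks,
    gene_counts=bundle.gene_counts, gene_condition=bundle.gene_condition,
    arm_counts=bundle.arm_counts, mirna_condition=bundle.mirna_condition,
    target_map=bundle.target_map, h3k27ac_peaks=bundle.h3k27ac_peaks,
    h3k4me3_peaks=bundle.h3k4me3_peaks,
    promoter_seqs=bundle.mirna_promoter_seqs, pfm=bundle.pfm)

print(result.report.counts["n_degs"], result.report.counts["n_dems_bound"])
print(score_recovery(result.network_bound, bundle.truth))
```

Output:

```
209 20
{'tf_binds_mirna': {'precision': 1.0, 'recall': 1.0},
 'mirna_represses_gene': {'precision': 1.0, 'recall': 1.0},
 'tf_binds_gene': {'precision': 1.0, 'recall': 1.0}}
```

Of 1,999 expressed genes, 209 come out as DEGs (102 up, 107 down); 20
promoter-bound DEMs point at 100 sign-opposed DEG targets, and in this
noise-free regime (effects |log2FC| ≥ 2, NB dispersion 0.05, no decoy
peaks or decoy target pairs) the recovered bound network equals the
planted one exactly — precision and recall 1.0 for every edge type.

## Command line

```sh
tfmirnet simulate --preset strong_signal --seed 1 --out fixtures/
tfmirnet run --config cfg.yaml          # full pipeline from a YAML config
tfmirnet bind --peaks tf.narrowPeak --promoters promoters.bed \
              --min-logp 3 --min-overlap 100
tfmirnet network --outdir tfmirnet_out  # summarize exported networks
```

`tfmirnet run` writes, under the configured output directory: the promoter
BED, gene/miRNA DE tables, the binding annotation table, the
anti-correlated target list, both networks in SIF/GraphML/TSV form, and
`report.json` with the counts of every stratum (expressed, DEG/DEM up and
down, bound and unbound, target strata) — all byte-deterministic given
identical inputs. Externally produced DE tables (e.g. real DESeq2 output)
can be plugged in with `de_mode: external`.

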