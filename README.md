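# icefp

Community fingerprinting and clone-library analysis for sea-ice microbial
time series.

`icefp` implements the analysis chain used to test whether bacterial and
archaeal communities trapped in first-year Arctic winter sea ice changed
over a multi-month sampling series. It takes capillary-electrophoresis
fingerprints — ARISA (automated ribosomal intergenic spacer analysis) for
*Bacteria*, T-RFLP (terminal restriction fragment length polymorphism) for
*Archaea* — from raw electropherograms to community-level statistics, and
16S rRNA clone libraries from aligned sequences to phylotypes, diversity
estimates and fingerprint cross-matches. It is written for microbial
ecologists who have fragment-analysis traces and clone sequences and want a
reproducible, scriptable version of this classic workflow, including a
synthetic-data generator for validating every stage without instrument data.

## The analysis

1. **Electropherogram → peaks** (`icefp.trace`): low-pass Fourier filtering;
   baseline RMS estimation by iterative peak masking; peak calling at height
   > 5 × RMS; Gaussian-fit recovery of detector-saturated peak heights;
   fragment sizing against the internal ladder with a constant dye-offset
   correction (−7 bp for ARISA).
2. **Peaks → OTU table** (`icefp.binning`): profile QC (cumulative peak
   height ≥ 10⁴ RFU for ARISA, 8 × 10⁴ for T-RFLP); cross-sample greedy
   binning with size-dependent cut-offs (1 bp at 70–700 bp, 2 bp at
   700–1200 bp, 4 bp above); presence/absence filtering at 1.0% (ARISA) or
   0.25% (T-RFLP) of cumulative height.
3. **Community statistics** (`icefp.commstats`): Sørensen similarity
   C_s = 2C/(A+B); similarity-to-first-sample time series; Pearson and
   partial Pearson trend tests (richness controlled for cumulative height);
   group-average (UPGMA) clustering; SIMPROF permutation tests at 95%
   confidence.
4. **Clone libraries** (`icefp.clones`): phylotypes by complete-linkage
   clustering (>98% identity for bacteria, >99% for archaea); subtypes by
   predicted fragment length; Chao1, Shannon H and Good's coverage;
   two-library LIBSHUFF comparison; in-silico ARISA/T-RF length prediction;
   maximum-covariance dye-offset estimation and subtype↔OTU matching
   (±1 bp tight, ±2.5 bp putative).
5. **Synthetic data** (`icefp.synth`): planted core/transient communities,
   forward-modelled traces (Gaussian peaks, baseline noise, saturation,
   dye offset) and clone libraries with known truth, used throughout the
   tests and the acceptance script.

## Worked example

Run the default synthetic bacterial study — 11 weekly ARISA profiles from a
community with 14 ubiquitous "core" OTUs carrying 77.5% of total signal plus
transient OTUs — through the full pipeline and compare against the planted
truth:

```python
from icefp.config import RunConfig
from icefp.study import run_synthetic_study

result = run_synthetic_study(RunConfig(assay="ARISA", seed=1))
print(result.evaluation.to_string(index=False))
```

```
                      metric    planted  recovered
                 n_core_otus         14         14
        core_signal_fraction   0.747511   0.747473
mean_similarity_to_reference   0.846175   0.846175
               mean_richness  21.272727  21.272727
similarity_trend_significant      False      False
  richness_trend_significant      False      False
```

Reading the report: the pipeline re-identified all 14 planted core OTUs from
the rendered traces; their share of the binned signal (74.7% for this seed;
77.5% on average over seeds) matches the planted value to four decimals;
the mean Sørensen similarity of each sample to the first (84.6%) and the
per-sample richness are recovered exactly; and, as planted, neither the
similarity trend (r = 0.065, P = 0.86) nor the richness trend (partial
r = 0.392, P = 0.26) is significant — the community is correctly judged
stable over the winter. SIMPROF on the dendrogram's root likewise finds no
internal structure (P = 0.93).

The same pipeline runs on real data from the shell:

```bash
icefp simulate --assay ARISA --seed 1 --out demo/         # or your own traces
icefp peaks --traces demo/ --ladder demo/ladder_lengths.tsv --out demo/peaks.tsv
icefp bin   --peaks demo/peaks.tsv --assay ARISA --out demo/binned/
icefp stats --presence demo/binned/presence_matrix.tsv \
            --metadata meta.tsv --out demo/stats/
icefp clones --fasta demo/clones.fasta --domain bacteria --out demo/clones_out/
```

Every run writes its resolved configuration and a manifest next to its
outputs; fixed seeds give byte-identical results.

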