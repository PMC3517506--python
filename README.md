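# tetermi

Discovery and characterization of transposable-element-derived transcription
termination sites (TE-TTS) from paired-end ditag (PET) transcript-boundary
data across multiple cell types.

## The problem

PET sequencing marks the 5′ and 3′ ends of individual full-length
polyadenylated mRNAs, linking each transcript's start site to the exact base
where it was terminated. Pooling the 3′ ends across a deep library reveals
every termination site (TTS) a gene uses — canonical terminators, but also
alternative sites inside introns, UTRs and downstream regions. Many of these
alternative terminators are donated by transposable element (TE) insertions,
whose own polyadenylation signals can truncate host-gene transcripts; this is
one proposed driver of the well-known antisense orientation bias of intronic
TEs. `tetermi` implements the full analysis chain for this question, for
genomicists working with PET-style 3′-end data, RepeatMasker annotations and
gene models:

1. **TTS calling** — strand-specific single-linkage clustering of PET 3′
   ends (gap ≤ 20 bp), a depth filter of ≥ 20 tags per 10 million mapped in
   at least one cell type, a peak base at the densest position, and merging
   of clusters that overlap reciprocally by ≥ 80% across cell types.
2. **Gene association** — a cluster belongs to the gene whose promoter
   captured the plurality of its linked 5′ ends, provided the cluster lies
   within the locus or ≤ 5 kb downstream; each TTS is classified as
   5′-UTR / internal / 3′-UTR / annotated / downstream.
3. **TE assignment** — a TTS is TE-derived when its peak is ≥ 50 bp past the
   element start and < 15 bp past its end (measured in the host gene's
   transcription direction), with sense/antisense orientation and a mapping
   of the peak onto the element consensus sequence.
4. **Statistics** — per-cell-type utilization,

       utilization = reads_terminated / (reads_terminated + reads_passing),

   cell-type specificity of a terminator,

       specificity = Σ_{i≠argmax}(MAXutilization − utilization_i) / (C − 1) / MAXutilization,

   Pearson χ² tests (df = 1) for orientation bias and observed-versus-expected
   family contributions, Wilcoxon rank-sum contrasts of sense versus antisense
   utilization, and rarefaction over all cell-type combinations with a
   logarithmic trend fit `y = a·ln x + b` for extrapolating the total number
   of TE-TTS.
5. **Chromatin metaprofiles** — average normalized ChIP tag density in fixed
   bins ± 5 kb around TE-TTS, non-TE TTS and non-terminating intragenic TEs.

A first-class synthetic-data generator (`tetermi.synthetic_data`) emits
miniature genomes — gene models, RepeatMasker-style TE annotations,
per-cell-type PET libraries, ChIP tags — with planted termination
probabilities, so every stage has a recoverable ground truth
(`tetermi.evaluation` scores recovery, utilization calibration and TE
assignment fidelity against it).

## Worked example

```python
from tetermi.synthetic_data import SimConfig, generate_gene_set, generate_pet_library
from tetermi.pipeline import run_analysis, PipelineConfig

cfg = SimConfig(n_genes=20, n_celltypes=3, genome_length=600_000,
                library_size=50_000, seed=7)
genes, tes, truth = generate_gene_set(cfg)
libs = {ct: generate_pet_library(genes, truth, ct, cfg)
        for ct in cfg.celltype_names}
res = run_analysis(genes, tes, libs, PipelineConfig())

n_te = sum(1 for r in res.records if r.te is not None)
print(f"{len(res.records)} TTS called, {n_te} TE-derived")
print(res.location_counts.loc[["internal", "annotated"], ["non_te", "all_te", "Alu", "L1"]])
print(res.rarefaction_tts.round(2))
```

prints

```
2107 TTS called, 250 TE-derived
           non_te  all_te  Alu  L1
internal     1730     250   77  69
annotated      29       0    0   0
   k    mean     sd
0  1   89.00  12.03
1  2  170.67  12.39
2  3  250.00   0.00
```

At this shallow depth (50 k tags, so the 20-per-10M filter keeps even
single-tag clusters) most called TTS are background noise; the 250 TE-derived
records are the clusters falling under the 50 bp/15 bp rule, broken down by
family in the location table. The rarefaction rows give the mean (± SD)
number of distinct TE-TTS found over all combinations of k cell types: one
cell type finds 89 on average, all three find 250.

The same stages are available from the shell:

```sh
tetermi simulate --config sim.yaml --outdir data --seed 7
tetermi run --genes data/genes.bed12 --repeats data/repeats.out \
    --ditags ct01=data/ct01.bedpe --ditags ct02=data/ct02.bedpe \
    --chip data/chip.bed --outdir run1
```

`run` writes the annotated TTS table, utilization, specificity, bias tests,
rarefaction curves, metaprofiles and a manifest (config hash, input
checksums, seed) that makes the run byte-reproducible.

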