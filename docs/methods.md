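# Methods

This note documents the analysis model, its parameters, the synthetic data
it is validated on, and the design decisions taken where the procedure was
genuinely open.

## TTS calling

PET 3′-end bases from one cell type are clustered per chromosome and strand
by single linkage: two point ends p ≤ q join the same cluster iff
q − p − 1 ≤ `max_gap` (default 20), read as "at most 20 intervening bases".
This is a point-feature interpretation; "separation" is not otherwise
defined for single-base features. Clusters partition the input, the cluster
interval spans the minimum to the maximum member base (half-open), and the
peak is the argmax of the per-base 3′-end histogram with ties broken to the
smallest coordinate so the result is deterministic.

Depth is normalized to tags per 10 million mapped
(`raw × 1e7 / library_size`, with the library size taken as the cell type's
total mapped ditag count). A cluster is kept when its normalized count
reaches `min_norm` (default 20) in at least one cell type; since the filter
runs before cross-cell-type merging, each cluster is judged on its own cell
type's depth. Note the threshold scales with library size: at 10⁶ tags per
library any 2-tag cluster survives, which is the intended behaviour of the
normalized filter, not an artifact.

Clusters called in different cell types are merged when they overlap by at
least `min_reciprocal_overlap` (default 0.8) of **both** cluster lengths;
connected components under this relation (transitive closure, needed when
many cell types chain) become one TTS whose interval is the union span,
whose histogram is the sum of member histograms, and whose peak is
recomputed from the pooled histogram. Whether the 80% requirement is
reciprocal or single-sided is an open choice; reciprocal is the default
because it prevents a long cluster from absorbing unrelated short ones, and
`reciprocal=False` switches to the single-sided (shorter-length) reading.

## Gene association and location classes

A merged cluster's member ditags vote through their linked 5′ ends: a ditag
supports the gene whose annotated TSS lies within `promoter_halfwidth`
(default 500 bp — "annotated promoter" has no standard width, so this is
config-exposed) of its 5′ point. The gene with the plurality of votes wins,
ties broken toward the nearest TSS; the cluster must also lie within the
gene locus or at most `downstream_limit` (default 5,000 bp) past the
annotated terminator in the transcription direction. Clusters supported by
promoters of two genes are flagged `ambiguous_promoter` rather than
resolved by any further rule.

Location classes partition the locus plus the downstream window, with
precedence annotated → downstream → UTR → internal: *annotated* when the
cluster overlaps an annotated terminator position (a set, to accommodate
multi-isoform gene models); *downstream* when the peak is strictly past the
annotated terminator by ≤ 5 kb; *5′/3′-UTR* when the peak is exonic and
outside the CDS bounds on the appropriate side (genes without a CDS have no
UTR classes); *internal* otherwise, covering introns and CDS exons.
Family-share percentages in the location-by-family summary are integer
**truncated**, and shares are taken over the eight named TE families in each
row; this matches the printed convention of the published grid the
arithmetic is checked against. The "alternative fraction" of a column is
(total − annotated) / total.

## TE assignment

A TTS is TE-derived when its peak is at least `min_into_te` = 50 bp past the
start of a TE insertion (transcription termination occurs downstream of the
polyadenylation signal, so a peak this far in can be driven by element
sequence) and less than `max_past_end` = 15 bp past its end. Start and end
are taken in the **host gene's transcription direction** by default: for an
antisense element the "start" is its genomic right edge under a plus-strand
gene. This is the reading under which antisense TE-TTS are scorable at all;
`coordinate_mode="genomic"` provides the purely left-to-right alternative.
When several elements qualify, the one whose end is nearest the peak wins,
with deterministic order-independent tie-breaks. Orientation is *sense* iff
the element strand equals the gene strand.

Peaks map onto the element consensus linearly
(`consensus_begin + offset` for plus-strand elements, `consensus_end −
offset` for minus), treating the RepeatMasker alignment as gapless — the
`.out` format carries no indel structure. Positions past either aligned
edge (e.g. peaks up to 15 bp past the element) clamp to that edge; at the
5-bp binning used for consensus densities this is immaterial.

## Utilization, activity and specificity

For a TTS in one cell type, over the gene's ditags whose 5′ point lies
upstream of the cluster: *terminated* ditags end inside the cluster
interval, *passing* ditags end strictly downstream; ditags ending upstream
count in neither, and utilization = terminated / (terminated + passing),
undefined (not zero) when no reads reach the cluster.

A gene region is *transcribed* in a cell type when its normalized PET count
is ≥ 20 per 10 M, and *active* when additionally in the top 75%
(`active_quantile`) most transcribed of the transcribed regions in that cell
type, ties kept (all regions tying the cutoff value are active). The region
used is the associated gene locus; the alternative (cluster ± 1 kb) is a
config choice away but not the default.

Specificity of a terminator is the mean shortfall from its maximal
utilization, normalized by the maximum:
`Σ_{i≠argmax}(max − u_i) / (C − 1) / max`, 0 for uniform use and 1 for use
in a single cell type. Eligibility requires utilization ≥ 20% in at least
one cell type and activity in at least 3 cell types. The activity condition
is an *eligibility filter only*: the specificity sum runs over every cell
type with defined utilization (when several cell types tie at the maximum,
one is excluded and the rest contribute shortfall 0; undefined utilizations
are excluded, not treated as 0). Summing over active cell types only was
considered and rejected: it makes the score of a genuinely single-cell-type
terminator depend on whether its one firing cell type clears the activity
quantile, which inverts the metric's meaning.

## Hypothesis tests and rarefaction

Orientation bias uses the Pearson χ² statistic on the 2×2 table
(orientation × TTS status) with df = 1 and no continuity correction — only
the distribution and df are prescribed, and the uncorrected statistic is the
plain reading. Observed/expected family contributions use expected =
total × family_genic_fraction with the two-cell Pearson sum; genic fractions
count intragenic insertions (not base pairs; a bp-weighted mode would be a
straightforward variant but insertion counts match the "fraction of
intragenic sequences" convention used for the expected counts). P-values
are reported raw; no multiple-testing layer is applied. Sense-versus-
antisense utilization contrasts use the two-sided Wilcoxon rank-sum test,
exact for tie-free samples of ≤ 20 per group and the tie-corrected normal
approximation otherwise.

Rarefaction enumerates, for every k, all C-choose-k cell-type combinations
(exact for C ≤ 12; seeded subsampling of at most 1,000 combinations above
that) and reports the mean and population SD of the union sizes. The curve
is fitted by least squares to `y = a·ln x + b`; `r` is the Pearson
correlation between fitted and observed means, and extrapolation scales the
observed distinct-TTS count by `y(target)/y(observed)`. Under the published
coefficients (a = 31.34, b = 33.61) the value at x = 8 is 98.78 and the
8 → 16 ratio is 1.2199 — i.e. doubling the number of cell types is predicted
to add ≈ 22% more TE-TTS; the often-quoted "20% increase" understates the
trend's own arithmetic, and this package reports the computed ratio.

## Chromatin metaprofiles

For each anchor, ChIP tags within `halfwidth` (5,000 bp) are binned by
signed offset — flipped for minus-strand anchors so downstream is positive —
scaled to tags per million mapped, and averaged **across anchors** (not
pooled), matching an "average normalized counts" convention. The bin width
default is 10 bp with 5 bp available; the two appear interchangeably in
descriptions of such profiles and neither is privileged. Anchors are TTS
peaks; for intragenic elements without a TTS the anchor is the element
midpoint (no anchor is prescribed for that set; the midpoint is symmetric
and parameter-free), oriented by the host gene's strand.

## The synthetic generator

`SimConfig` defaults define the reference fixture: 200 genes on one
synthetic chromosome (4 Mb), 8 cell types, 10⁶ ditags per cell type — a PET
depth in the range of real single-library experiments, chosen as a free
parameter since no per-cell-type depth is prescribed. Each gene (4–8 kb,
3–6 exons, CDS bounds inside the outer exons) carries a canonical
terminator at its annotated 3′ end plus 0–3 planted alternatives separated
by ≥ 300 bp, a 60% share of them inside TE spans at offsets satisfying the
50/15 rule exactly. TEs (200–350 bp fragments of eight families with
realistic consensus lengths) are placed ≥ 100 bp apart and ≥ 500 bp from
locus ends; elements hosting a terminator are sense-oriented with
probability 0.75 and background elements with probability 0.35, emulating
the antisense bias of neutral insertions and the sense bias of terminating
ones.

Genes fall into three termination patterns so the specificity statistics
have known answers: *specific* genes (25%) whose alternatives fire in
exactly one cell type, *uniform* genes (25%) with one alternative used with
the same probability (0.35–0.65) everywhere — a per-gene single alternative,
so the read-through denominator is also constant across cell types — and
*variable* genes with independently drawn per-cell-type probabilities.
Generated alternative probabilities are capped so the canonical terminator
keeps ≥ 10% of transcripts in every cell type; an explicit
`termination_prob_matrix` bypasses generation and is used as given.

Each cell type's ditags are apportioned over genes multinomially with
log-normal expression weights (σ = 1, drawn per gene × cell type — the
top-75% activity filter needs expression variation to be testable). A tag's
5′ point sits at the promoter with Gaussian jitter (σ = 20 bp, clipped at
3σ); its 3′ point is drawn from the gene's terminator probabilities with
Gaussian jitter (σ = 2 bp by default, rounded, truncated at the locus
downstream boundary) — observed PET clusters span tens of bases and no tag
dispersion model is prescribed, so a small discretized Gaussian is the
minimal choice. A `noise_rate` = 2% fraction of tags get uniform 3′ ends
over the gene locus (locus-wide, not genome-wide, so the gene-association
stage still links them and the noise specifically stresses the depth
filter). ChIP tags are uniform background (`chip_background`, expected tags
per base) plus per-anchor Gaussian enrichment (`chip_enrichment_height`
expected tags per anchor, σ = 200 bp). All streams derive from
`numpy.random.default_rng` seeded from `SimConfig.seed` per stage and cell
type, so identical configs give byte-identical files.

What the generator does **not** emulate: sequence (no FASTA, no poly-A
motifs, so internal-priming artifacts cannot arise by construction),
multi-mapping ambiguity, indels in TE alignments, overlapping or nested
genes, isoform structure beyond a single annotated terminator per gene, and
inter-chromosomal ditags. Passing recovery tests therefore demonstrates the
correctness of the coordinate logic and the statistics under the stated
noise model, not robustness to alignment artifacts in real tracks.

## Expected-utilization oracle

Validation compares estimated utilization to the planted expectation under
the generative model, not to the raw planted probability: for terminator j
of a gene, the expected utilization in cell type c is

    [(1−ν)·p_jc + ν·w/L] / [(1−ν)·(p_jc + P_down) + ν·(w + L_down)/L]

where ν is the noise rate, p_jc the planted probability, P_down the summed
planted probability of terminators strictly downstream of the discovered
cluster, w the cluster width inside the locus and L_down the locus length
downstream of the cluster. Estimates are required to fall within 3 binomial
standard deviations of this value, for pairs with ≥ 50 informative reads
(below which the normal envelope is unreliable).

## Problem sizes and tolerances

The test suite exercises unit semantics on worked examples, property tests
(seeded/derandomized hypothesis) and brute-force oracles (O(n²) single
linkage on ≤ 200 ends, exhaustive rarefaction on 4 cell types, exact
rational utilization, closed-form specificity, textbook χ²), and end-to-end
recovery on the reference fixture — 8 cell types × 10⁶ tags — plus a
zero-jitter replicate for TE-assignment fidelity; the full suite runs in
about a minute on one CPU. Formula oracles are held to 1e−12 (1e−9 for χ²
p-values), exact-model log-trend fits to 1e−9, and stochastic recovery
checks to the 3σ envelopes described above.

## Known limitations

* Cluster membership for utilization counting uses the merged interval;
  3′-end jitter tails falling just outside a narrow cluster are counted as
  read-through, a sub-percent bias at the default jitter.
* Bidirectional promoters: a cluster whose 5′ ends match two promoters is
  assigned by plurality/nearest-TSS and flagged, which may misattribute
  genuinely bidirectional loci.
* Consensus mapping is gapless; for heavily deleted elements the mapped
  position can drift by the cumulative indel length (recorded per element
  as `indel_tolerance`).
* At high sequencing depth the normalized ≥ 20/10M filter admits very
  shallow clusters (2 raw tags at 10⁶), so discovery output contains
  noise-level TTS by design; downstream analyses that need confident sites
  should filter on utilization or recurrence across cell types.
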