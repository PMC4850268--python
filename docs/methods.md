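# Methods

## Scope and model

`regulomap` maps the regulon of a bacterial transcription factor from
binned ChIP-seq coverage and classifies its targets from expression time
courses.  The statistical core is deliberately simple and transparent:
independent per-bin Poisson tests against an input-derived expectation,
family-wise (Hochberg) correction, and rule-based downstream logic.
Every stage consumes and emits flat TSV tables so intermediate results
are auditable.

### Binning and local normalization

Coverage lives on a fixed grid of 25-bp bins over a **linear**
chromosome (no wraparound; streptomycete chromosomes are linear).  The
final partial bin is retained.  BedGraph records are interpreted as
counts attributed to intervals and apportioned to bins by overlap
fraction, so total counts are conserved exactly.

Local normalization divides each bin by the running **median** of its
centered 401-bin (~10 kb) window, truncated at the chromosome ends, with
the median floored at ε = 1 so zero-coverage deserts cannot blow up the
ratio.  The median (not the mean) keeps genuine peaks from inflating
their own background.  The window length is a tunable
(`lnorm_window_bins`): it must be long enough that a binding footprint
(~a dozen bins) cannot dominate the median, and short enough to track
kilobase-scale shearing bias.  The per-bin enrichment statistic reported
with every peak is `diff = ln(IP) − ln(input)`.

### Per-bin significance and error control

Each bin is tested one-sided: `p_b = P(Poisson(e_b) ≥ ip_b)` with
`e_b = max(s · r_b, λ_min)`, where `s` is the IP/input total-count ratio
and `λ_min = 0.25` prevents spurious significance over zero-input bins.
`bin_pvalues` accepts any expectation track; the pipeline passes the
**locally averaged input rate** `r_b` (centered 41-bin ≈ 1-kb rolling
mean) rather than the raw per-bin input count.  This choice is
load-bearing: the raw input bin is a single Poisson draw, and using it
as if it were the true rate makes the extreme tail of the null badly
anti-conservative — numerically, ≈ 5 expected false peaks per 1-Mb null
genome at the genome-wide threshold.  Averaging over ~1 kb suppresses
the counting noise (relative error ~3 % at depth 30) while still
tracking the shearing field, whose correlation length is ~2 kb; with it,
200 simulated null genomes yield zero false-positive runs.  The 41-bin
window (`rate_window_bins`) is exposed in the configuration.

Raw p-values are adjusted genome-wide (m = number of bins) by the
Hochberg step-up procedure, implemented here directly from the step-up
definition and cross-checked in the tests against both a brute-force
evaluation and an independent library implementation.  Bins with
adjusted p-value below α = 10⁻⁴ are significant.  Hochberg controls the
family-wise error rate under independence/positive dependence, which
matches the per-bin Poisson model.

### Peaks, controls, annotation

Significant bins from any test dataset are merged into runs, tolerating
gaps of one non-significant bin (`max_gap_bins = 1`; the 25-bp grid is
finer than a binding footprint).  The summit is the member bin with the
largest diff across test datasets, leftmost on ties.  A peak whose
summit lies within 2 bins of a bin significant in the negative-control
IP is an antibody-background artifact and is removed.

Targets are assigned strand-aware: candidate genes are those whose start
codon (start coordinate for +, end coordinate for −) lies downstream of
the peak in the gene's own orientation and whose body does not contain
the peak; the smallest start-codon distance wins, with ties broken
toward the + strand and then the smaller gene id.  Divergent promoters
therefore resolve to the closer start codon; a peak inside a gene body
is never assigned to that gene (it may still have a candidate beyond the
gene end).  Peaks with distance > 300 bases are flagged and dropped from
the regulon; distance exactly 300 is retained.

### Regulon comparison and codependence

Peak sets are matched by greedy globally-closest pairing of summit
positions within 50 bases (2 bins) — summits are points on a coarse
grid, so interval overlap adds nothing.  Shared-regulon strength is the
shared fraction plus the Spearman correlation of `−log₁₀(apv)` over
shared peaks (adjusted p-values floored at 10⁻³⁰⁰ before the log).
Codependence is presence/absence: each wild-type peak is `dependent` if
the mutant's own called peak set (same α, same pipeline) has no summit
within the tolerance.  No quantitative differential-binding statistic is
attempted — the biological claim being tested is all-or-none occupancy.

### Expression classification

Input matrices are log2 abundances (genes × timepoints).  Per-gene
normalization subtracts each gene's mean pooled **across strains and
timepoints jointly**, so wild-type and mutant levels remain directly
comparable (within-strain normalization would erase exactly the
mutant-vs-WT differences of interest).  Classification uses the
mutant−WT log2 fold change at the assessed timepoints 16, 18, 20 h —
sporulation onset and later; earlier timepoints reflect vegetative
growth where targets are not yet factor-dependent.  A gene is
`activated` if any assessed logfc ≤ −1 (expression falls ≥ 2-fold in
the mutant), `repressed` if any ≥ +1; if both thresholds are crossed
the larger magnitude wins, and an exact tie stays `unclassified` so the
classification is antisymmetric under sign flip.

### Motif scan

GACAC occurrences are counted exactly (overlaps allowed) on the forward
strand plus reverse-complement occurrences; ambiguity codes never match.
Peak-level enrichment resamples the same number of positions uniformly
over the genome and reports `p = (1 + #{null ≥ observed}) / (1 + n_perm)`.

## Synthetic data generator

The generator emulates the features of the real experiment that the
analysis depends on, at desk scale:

- **Genome**: random sequence, default 1 Mb at GC 0.72 (a slice-sized
  stand-in for a ~8-Mb, ~72 %-GC streptomycete chromosome); 400
  non-overlapping genes of 800–1200 bp on both strands with seeded
  random intergenic gaps (minimum 150 bp).
- **Sites**: default 50 (stand-in for the ~240 real target transcription
  units), each placed 60–300 bases upstream of a distinct target gene's
  start codon inside the intergenic region, with GACAC (random
  orientation) written into the sequence at the site.  The lower bound
  of 60 bases keeps planted sites identifiable: summit resolution on the
  25-bp grid is ±2 bins, and a site closer than ~50 bases to the gene
  body could yield a summit inside the gene, which the annotation rules
  deliberately refuse to assign.  Enrichment is uniform on [8, 15];
  modes alternate activated/repressed (so 50 sites give exactly 25/25).
  Five artifact sites are placed uniformly, ≥ 500 bp from true sites.
- **Occupancy**: a site is occupied only in genotypes with both factors
  functional and the iron-sulfur cluster intact.  Artifact sites enrich
  every IP-type sample (including the negative-control IP) in every
  genotype; the input never carries site signal.
- **Coverage**: per-bin expectation = mean depth (default 30 reads/bin)
  × a shearing-bias field, with occupied sites multiplying the
  expectation under a triangular taper of half-width 150 bases (a
  fragment-pileup shape without a read-level model); counts are Poisson.
  The field is log-normal (σ = 0.5) with ~2-kb Gaussian autocorrelation,
  clipped to [0.2, 5], and is a property of the simulated chromosome:
  seeded by the genome seed alone, hence shared by all samples drawn
  from it.  This reflects that shearing bias tracks local sequence and
  chromatin composition, and it is what makes significance values
  comparable across independently sequenced samples — with fully
  independent per-sample fields, the local-depth term would dominate the
  log-significance and the observed cross-factor correlation of
  significance ranks could not arise, contrary to the real data.
  Reads are never materialized; the analysis consumes per-bin counts,
  and BedGraph export covers interoperability.
- **Expression**: each gene has a genotype-independent constant baseline
  (N(7, 1) log2 units); in occupancy-permitting genotypes, activated
  targets rise and repressed targets fall by 2 log2 units from 16 h
  onward; Gaussian noise (σ = 0.3) is independent across strains.
  Timepoints are 8–20 h at 2-h intervals.

Determinism: every random stream is derived from the configuration seed
plus a fixed purpose tag (genome, sites, field, counts-per-role/genotype/
replicate, expression baseline, expression noise), so identical
configurations give bit-identical outputs, and separate samples are
independent but reproducible.

What the generator does **not** emulate: read-level artifacts
(sequencing error, mappability, PCR duplicates), replicate structure and
biological variance beyond Poisson, GC-dependent amplification bias
within a sample, operon structure (each target gene is independent), and
any dependence of expression dynamics beyond a single step effect.
Passing tests therefore demonstrate the correctness and calibration of
the analysis under its own model assumptions — not robustness to the
full messiness of real sequencing data.

## Numerical and edge-case choices

- Fractional bin counts (possible after BedGraph apportionment) are
  rounded **up** before the Poisson tail, the conservative direction.
- `p = 1` exactly when the IP count is 0.
- Summit ties break leftmost; target-assignment ties break + strand
  first, then smaller gene id; an exact activated/repressed tie is
  `unclassified`.
- Empty inputs: an all-zero track normalizes to all zeros; an empty
  peak set annotates to an empty table; a zero-total input track is a
  hard error (no library scale exists).
- Problem sizes: the default study conditions (1-Mb genome, 200-genome
  null ensemble, 500-replicate Monte-Carlo checks) were chosen so the
  full statistical verification runs in tens of seconds while keeping
  every binomial confidence interval comfortably inside the asserted
  bounds.

## Known limitations

- The Poisson null ignores overdispersion between biological replicates;
  it is isolated behind `bin_pvalues` so a negative-binomial variant
  could be swapped in.
- The local-normalization window and statistic are a reconstruction of
  a standard practice, not a published constant; both are configurable.
- Near-threshold rescue (a peak "just outside" the significance
  threshold in one dataset but clearly present in the other) is
  deliberately not implemented; such peaks appear as non-shared.
- The 300-bp distance filter anchors on start codons, so targets with
  long 5′ UTRs can be dropped even when binding is promoter-proximal.
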