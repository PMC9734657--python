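# Methods

This note documents the models and algorithmic choices behind `scimet`:
what the simulator generates and deliberately omits, how each pipeline
stage is defined, the parameters that matter, and the numerical
conventions (tie-breaks, degenerate inputs, determinism).

## 1. The generative model

### Genomes

`sim.make_genomes` draws two i.i.d. base sequences with a configurable GC
fraction (default 0.42, a mammalian-like value). Two independent draws
share ~26% per-base identity, so species assignment of a read by its
chromosome label is unambiguous — which is all the barnyard logic needs.
Chromosome names carry the species label (`hsap_chr1`, `mmus_chr1`), so a
merged reference still identifies the species of every alignment. The
simulator makes no attempt at realistic genome structure (no repeats,
isochores, CpG islands); analyses that depend on such structure
(e.g. real motif biology) are exercised with *constructed* call tables
instead.

Cytosine context is precomputed per chromosome on both strands: a
forward-strand C is CG iff the next base is G, else CH; a reverse-strand
cytosine sits at a forward G and is CG iff the preceding forward base is C.
A terminal cytosine (no following base) is CH. CHG and CHH are never
distinguished: the pipeline merges them as CH throughout.

### Cells and barcoding

`ExperimentDesign` fixes the study conditions. Defaults describe a skewed
two-species mixing experiment: 90/10 species mix, 22 sort events per PCR
well, 96 tagmentation barcodes, 96 wells. Each nucleus draws a species
from the mix, a cell type uniformly from the supplied profiles, a uniform
tag barcode, and lands in a well filled with `events_per_well` nuclei.
Nuclei sharing (well, tag) are *collision doublets*: they are physically
indistinguishable downstream, so their reads are emitted as the union
under one merged observed barcode. The implied per-nucleus collision
probability is the birthday bound `1 − (1 − 1/B)^(n−1)` (n events/well,
B tag barcodes), which `barnyard.expected_collision` exposes as the
package's collision model.

Whitelists are rejection-sampled random codes with a minimum pairwise
Hamming distance. Distance ≥ 5 makes distance-2 correction *exact* (a
2-error read can never be within 2 of a wrong entry), but a distance-5
code of length 8 saturates near ~45 codewords — 96 such tag barcodes do
not exist within reach of random search, consistent with coding-theory
bounds. The package therefore uses distance 5 where exact correction is
being demonstrated (with ≤ 40 tags), and distance 4 for the 96-barcode
default, at which correction may occasionally reject but can never
mis-assign (ambiguous corrections are rejected, see §3).

### Cell-type methylomes

A `CellTypeProfile` is (global mCG, global mCH, marker-region overrides).
Defaults: neuron-like mCG 0.82 / mCH 0.06; glia-like mCG 0.78 / mCH 0.01 —
non-CG methylation is the neuron/glia discriminator, and the invariant
`neuron mCH > glia mCH` is asserted by construction in the presets.
Marker regions override the site probability within an interval for one
context (hypomethylated promoters, type-specific window signatures).
Every cytosine of every cell then draws an independent Bernoulli state
from its type's site probability; forward- and reverse-strand states are
drawn independently (real CpG methylation is largely symmetric; nothing
downstream depends on symmetry, and independent draws keep the truth
table per-strand exact).

`make_separated_profiles` builds well-separated types for clustering
recovery experiments: each type flips ~30% of genomic windows to a high
(0.35) or low (0.02) CH level over a 0.08 baseline. With ~50+ covered
sites per window the between-type separation is ≥ 5× the binomial noise
of a window estimate, the regime the clustering contract is stated for.

### Reads, duplicates, noise

Each unique molecule is a genomic fragment from one cell. Read 1 carries a
10-nt random-primer segment of H bases (A/C/T at ⅓ each — bisulfite-
converted DNA is C-poor, and the simulator's primer composition mirrors
that) followed by genomic sequence; read 2 carries the 8-nt tag index, a
21-nt mosaic-end segment (the canonical 19-nt Tn5 ME plus a 2-nt pad — the
pad composition is a free choice fixed as a package constant), genomic
sequence, and a 10-nt tail that the trimmer removes. i5/i7 are emitted as
separate index reads.

Bisulfite chemistry happens once per molecule: a conversion strand is
drawn OT/OB at 50/50 and conversion noise is applied *before* PCR
(`conversion_failure_rate`: unmethylated C kept as C, default 0.5%;
`overconversion_rate`: methylated C read as T, default 0.5% — both typical
of real conversion efficiencies ≥ 99%). PCR then emits
`1 + Poisson(duplicate_rate)` copies (default rate 0.3, i.e. ~77% of reads
unique, a realistic sequencing-saturation point); each copy receives fresh
sequencing errors (default 0.5%/base on genomic bases) and index errors
(default 0.2%/base on index segments). An optional `crosstalk_rate`
reassigns a fraction of molecules to a random other barcode to exercise
the crosstalk estimator (default 0).

Orientation convention: no real aligner runs in this package, so the
truth SAM *is* the alignment stage's output. All records are written in
reference-forward projection; original-bottom molecules carry FLAG 16 and
`XG:Z:GA`, original-top molecules FLAG 0 and `XG:Z:CT` (the bismark tag
convention). The extractor keys all logic off `XG`, exactly as it would on
a real bismark BAM. Each fragment yields two single-end records (the R1
and R2 segments), matching the single-end processing model of the
pipeline; the molecule table has one row per single-end molecule, with
copy counts, so read conservation and dedup recovery are exactly
checkable. Indels, chimeras and quality-score structure are out of scope;
qualities are constant.

Determinism: every stochastic step flows from one `numpy` Generator
seeded by the design/caller, and equal seeds give byte-identical FASTQ,
SAM and truth tables (asserted in tests).

### Fast generation paths

Two shortcut generators sample from the same model at a cheaper level:
`simulate_site_calls` emits per-cell methylation *calls* directly (each
cell covers a without-replacement sample of sites; the call state is the
site's Bernoulli draw), and `simulate_species_counts` emits per-barcode
species read *counts* (with read-level crosstalk). Clustering, saturation,
similarity and doublet-statistics experiments use these; everything that
exercises read handling (demux, dedup, calling) uses the full read-level
path.

## 2. What passing tests do and do not show

The simulator reproduces the statistical structure the pipeline assumes —
barcode collisions, duplicate lineages, conversion noise, type-specific
methylation landscapes — with known truth, so tests can demand exactness
(100% demux recovery under ≤ 2 injected errors, call-for-call agreement
with the truth table). It does not emulate alignment ambiguity, mapping
bias, chimeric reads, copy-number variation, or realistic genome
composition; performance on those axes is a property of the upstream
aligner and the data, not of this package, and passing tests here say
nothing about them.

## 3. Pipeline definitions and numerical choices

**Demultiplexing.** Each of the three indexes is corrected independently
(joint correction across indexes is not attempted). A read is assigned iff
all three correct uniquely within `max_hamming` (default 2); an index with
≥ 2 whitelist entries tied at the minimal distance is *ambiguous* and the
pair is rejected — mis-assignment corrupts single-cell identity
irreversibly, rejection only costs coverage. N bases count as mismatches.
The corrected composite barcode `i5 + i7 + tag` is appended to the read
name after a `:`; demultiplexing its own output is a no-op (pass-through),
making the operation idempotent. Two input dialects are supported:
separate I1/I2 FASTQs (I1 = i7, I2 = i5) or indexes embedded in the
read-1 header (`…:<i7>+<i5>`), auto-selected by whether index files are
given. Trims: read 1 loses its first 10 bases; read 2 loses bases 1–29,
then any perfect 3'-suffix overlap (≥ 5 nt) of the configured adapter, then
its last 10 bases. The adapter step is a deliberately minimal stand-in for
a full adapter trimmer: single fixed adapter, perfect suffix matching only.
Reads emptied by trimming are counted as rejected, preserving
`assigned + rejected = total`.

**Duplicate removal.** Key = (barcode, chrom, start, strand); start-only
(no fragment end) because randomly primed bisulfite libraries have
unreliable mate structure. Tie-break: lexicographically smallest read
name, which makes the retained set invariant to input order and dedup
idempotent. Unmapped records are skipped and counted.

**Methylation calling.** Calls are made only at reference cytosines of
the read's conversion strand; a read base matching neither the converted
nor the unconverted reference base (sequencing error or variant) yields
no call. Context always comes from the reference, never the read.
Records without a conversion-strand tag are skipped and counted, not
guessed. Call files are laid out `{CG|CH}/{chrom}.tsv`, sorted by
(barcode, position); both context directories exist even for empty input.

**Per-cell QC.** `pass_qc ⇔ unique_reads ≥ min_unique_reads AND
global_mCH < 0.10`. The mCH bound is strict and a cell with zero CH calls
fails (an undefined conversion estimate is not evidence of quality). The
read threshold has no principled default and must be supplied by the
caller.

**TSS enrichment.** Signal = mean coverage in TSS ± 100 bp; background =
mean of two 200-bp windows *centered* at ±1000 bp (the centering is a
package convention — "1000 bp away" admits edge- or center-anchoring; the
offset is configurable). Coverage is aggregated across all TSSs
(strand-flipped) before the ratio. Zero background → NaN. By design this
score sits near 1 for shotgun-like coverage; successful nucleosome
disruption drives it to ~1 where intact-nuclei tagmentation would give
≫ 1.

**Barnyard.** A barcode is assigned to a species iff purity
(majority reads / total) ≥ 0.9 — a conventional threshold, configurable,
with ties broken toward the first species column (purity exactly 0.5 is
below any sensible threshold anyway). The corrected doublet rate
divides the observed mixed fraction by `2·p_A·p_B` with singlet-derived
proportions (robust to depth differences between species); its Wilson CI
is the observed binomial CI scaled by the same factor. This correction
and the collision bound are the package's own documented models; no claim
is made that they reproduce any particular published estimate, whose
derivation is not stated in a reproducible form. Crosstalk is measured on
singlets as the fraction of reads aligning to the other species — note
this sees only *cross-species* deliveries, so with species proportions
(p, 1−p) a true crosstalk rate c appears as c·(1−p) for the majority
species.

**Window matrices.** Windows half-open, tiling each chromosome exactly
(last window short). The matrix stores methylated/total call fractions
(NaN where a cell has no calls) alongside distinct-site counts. The
two-pass filter is order-sensitive by contract: cells are judged against
ALL windows, then windows against the RETAINED cells only; both
threshold sets (CH: 20 sites / 75% / 75%; CG: 5 / 25% / 50%) are
context defaults. An all-filtered result is an explicit empty matrix, not
an error. Merging concatenates rows over an identical window definition,
prefixes barcodes with experiment ids, and applies no normalization of
any kind.

**Reduction and clustering.** Missing fractions are imputed with the
window's mean across covered cells (a per-cell global-level fill is
available; the choice is recorded here because nothing upstream dictates
it). Windows are then mean-centered by default: without centering the
first component is dominated by each cell's global methylation level
rather than regional differences; centering can be switched off to
process raw fractions. Truncated SVD (seeded randomized solver) to
min(50, rank) components; exact kNN graph (Euclidean on component scores,
k = 30 — a common community-detection default, reduced with a warning when
cells < k); seeded Louvain community detection (networkx); labels
relabeled by decreasing cluster size. Degenerate geometry (all pairwise
distances zero, e.g. identical rows) short-circuits to a single cluster
rather than letting graph structure invent communities. The 2-D embedding
is decorative and pluggable: the default projects the first two
components; a UMAP embedder is selectable when umap-learn is installed.
Fixed seeds reproduce labels bit-identically.

## 4. Downstream analyses

**Coverage saturation.** Per iteration (default 100), sample n cells
(default 250) without replacement in random order and accumulate the
union of covered sites; report the mean cells needed to reach 80% of the
site universe (∞ if never reached). Two closed-form regimes anchor the
tests: cells covering disjoint 10% slices need exactly 8 cells; cells
covering independent 20% subsets need the smallest n with
1 − 0.8ⁿ ≥ 0.8, i.e. 8.

**Region methylation.** Cluster × region values pool calls across member
cells (methylated/total) rather than averaging per-cell fractions —
per-cell promoter coverage is far too sparse for stable means, and
pooling makes the weighted-mean identity exactly checkable. Z-scores
standardize each region across clusters with the sample (ddof = 1) SD;
zero SD gives z = 0, clusters without calls in a region are excluded from
that region's z-scoring. Region presets: promoters −1500/+1000 of the
TSS for region calls (the source conventions for promoter orientation are
contradictory between −1500/+1000 and +1500/−1000; upstream-1500 was
chosen and the preset is configurable), wide promoters −5000/+2500, gene
bodies ± 2000; all strand-aware and clipped to chromosome bounds.

**Cell–cell concordance.** Sites are binarized (methylated iff the
methylated-call fraction ≥ 0.5, ties to methylated — deterministic and
consistent with single-read dominance), restricted to promoter regions;
concordance for a cell pair is shared-state sites / shared sites,
computed by sparse matrix products, NaN under a minimum-shared-sites
floor. The matrix is symmetric with unit diagonal; cluster × cluster mean
matrices are hierarchically ordered (average linkage on 1 − similarity)
for display. Two independent cells with site probability p have expected
concordance p² + (1−p)² = 0.5 at p = 0.5, the calibration point used in
tests.

**Motif profiles.** 100 half-open 10-bp bins tiling [−500, +500) around
each motif center (the center falls on a bin boundary; a center bin is
not singled out), strand-flipped as offset ↦ −offset−1 so bins mirror
exactly. Values are cluster-pooled fractions; out-of-bounds bins at
chromosome edges simply collect no calls. Motif *scanning* is out of
scope — centers arrive as intervals from upstream tools.

## 5. Problem sizes

Tests and the acceptance script run on desk-scale versions of the study
conditions, chosen once: 20–200 kb toy chromosomes, tens to hundreds of
cells per experiment, 600 cells / 3 types / 10-kb windows for clustering
recovery (the window size scales with the toy genome so windows hold the
same tens-of-sites coverage that 250-kb windows hold on a real genome),
2000 read pairs for demultiplexing exactness, ~10,000 alignments for
dedup recovery, and 20 replicates × 6 designs × 2000 cells for doublet
CI coverage. Sequencing depth defaults (2000 molecules/cell) are likewise
desk-scale; real experiments differ in scale, not structure.

## 6. Known limitations

- No alignment: the truth SAM stands in for the aligner, so mapping
  ambiguity/bias is untested (and out of scope).
- The adapter trimmer is minimal (perfect suffix of one adapter); real
  libraries need a full trimmer upstream.
- Within-species doublets are invisible to the barnyard estimator by
  construction, as in any two-species design.
- The doublet correction assumes doublets pair cells independently of
  species; strong sorting correlations would bias it.
- Paired-end overlap double-counting is not clipped; with the default
  adjacent R1/R2 segments this cannot occur in simulation, but real
  overlapping mates would double-count cytosines.
- Batch-effect correction is deliberately absent (merging applies no
  normalization); the package measures batch mixing, it does not fix it.
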