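# Methods

## Coordinate and peak conventions

All coordinates are 0-based, half-open (BED convention).  Chromosome names
are compared as exact strings; no `chr` aliasing is attempted (the CLI
provides a converter).  A peak carries a single-bp summit; narrowPeak
input resolves the summit from the 10th-column offset (midpoint when the
offset is −1), plain BED uses the floor midpoint.  In the narrowPeak
writer/reader the 5th (BED score) column carries the integer tag count and
the 7th (signalValue) the caller score, so round trips preserve both.

Merging coalesces any intervals sharing at least one base *and*
book-ended intervals (as `bedtools merge` does), so the merged interval
count equals the number of connected runs of covered bases; a merged site
takes the summit of its highest-scoring constituent — preserving the
strongest local maximum for profile centring — the summed tag counts and
the maximum score.  Overlap queries use a ≥ 1 bp criterion throughout;
subtraction is peak-level (whole peaks are removed, never trimmed),
matching Venn-style site counting, and together with the ≥ 1 bp overlap
partition this makes `|A| = |A overlapping B| + |A \ B|` an identity.

## Consensus and cistrome classes

A consensus site is one connected component of the ≥ 1 bp overlap graph of
the two replicates' peaks that contains at least one peak from each
replicate; its interval is the union of the component, its summit comes
from the highest-scoring member and its tag count is the member maximum.
Peaks overlapping a blacklist interval or exceeding 1000 tags (strictly
greater; exactly 1000 is retained) are removed before consensus building.

Pooled cistromes merge a factor's consensus sets over the three
conditions; a pooled site's membership flag for a condition is a ≥ 1 bp
overlap against that condition's consensus set.  Factor-unique sites are
computed at two stringencies: subtracting the other factor's pooled
consensus cistrome (`non_overlapping`), then additionally subtracting the
merged *raw single-replicate* peak calls of the other factor
(`strict_unique`) — the robust definition of a factor-only site.
Damage-induced classes are subtractive on consensus sets: agent-only sites
overlap neither the untreated nor the other agent's consensus;
shared-damage sites overlap both agents' consensus but not untreated.
Chains of partially overlapping sites are treated as whole connected
components, so counts can differ from conventions that split chains.

## Signal

Tracks are per-chromosome step vectors (default step 10 bp in the
generator); normalization multiplies by 10⁷ / library size so all samples
are on a reads-per-10-million scale.  Site matrices average the per-base
track value in 50-bp bins across summit ± 5 kb (bin width is a package
choice; the flank matches the heatmap convention).  Peaks are unstranded,
so rows are never flipped.  K-means clustering runs Lloyd's algorithm with
k-means++ seeding on the raw, unscaled rows (no standardization),
deterministic per seed, with clusters relabelled by descending mean row
signal; k is a required parameter because no canonical value exists for
arbitrary signal panels.

## Differential occupancy

The published analysis used a negative-binomial framework with libraries
normalized to total library size.  With two replicates per condition,
dispersion estimation is fragile, so this package defines its differential
statistic as an exact conditional binomial test on pooled counts: with
group totals x_a, x_b and library totals L_a, L_b, conditional on
x_a + x_b the group-A count is Binomial(x_a + x_b, L_a/(L_a + L_b)) under
the null, and the two-sided p-value is the exact minimum-likelihood
binomial test.  Fold changes use a 0.5 pseudocount on the per-10⁷ scale;
q-values are Benjamini–Hochberg; a site is significant at q < 0.1.
Consequences: p-values are exact under Poisson sampling (the type-I
calibration in the tests uses Poisson nulls), and the pooled test ignores
replicate-level overdispersion, so on the generator's deliberately
overdispersed negative-binomial counts it is anticonservative —
significant-site counts are not comparable with replicate-aware
negative-binomial analyses, which is the main caveat of this stage.

## Annotation

A peak is associated with every gene whose span extended by the window
(default 25 kb, a study parameter) it overlaps by ≥ 1 bp — extended-span
association, not separate TSS/TTS point windows, which can differ in
counts.  Signed distances run from the summit (the same anchor used for
profile centring) to the TSS/TTS, negated on the minus strand so positive
is always downstream in the direction of transcription.  TSS
stratification uses |summit − nearest TSS| with proximal < 5 kb,
5 kb ≤ distal ≤ 25 kb (both boundaries assigned to distal; "within 25 kb"
is read inclusively) and remote beyond.

## Expression classification

Fold changes compare every siRNA × treatment sample with the mean of the
two untreated control samples (no-siRNA and scrambled).  Genes failing
detection (DABG p ≥ 0.05) or expression (< 1) in both control samples are
dropped before fold changes.  Treatment responses are read from the
scrambled series so that siRNA carriers are comparable: induced means
FC ≥ 1.7 (inclusive), repressed FC ≤ 1/1.7.  TP53 dependence is a ratio
test between the siTP53 and scrambled samples under the same treatment
(≥ 1.5-fold in the direction opposite to the response); this sample-ratio
form — rather than comparing the two samples' control-relative fold
changes against fixed cutoffs separately — is the largest interpretive
choice in the package, chosen because it expresses "1.5-fold change in
opposite direction" as a single well-defined quantity.  TP63 sensitivity
is the siTP63/controls fold change in untreated cells against the same
1.5-fold threshold.

## Integration

A gene's binding category (both / TP53-only / TP63-only / none) derives
from its annotations against the two pooled cistromes — "bound" means any
associated site in any condition's consensus (pooled semantics).
Constitutive/damage flags come from the untreated membership flag of
associated pooled TP53 sites.  Genelist overlap uses the upper-tail
hypergeometric probability P(X ≥ k) with the universe defaulting to the
genes surviving the expression filter (the testable background; the
appropriate universe is exposed as a parameter since no canonical choice
exists).  The survival function is evaluated in log space and is exact to
relative error well below 1e−12 for universes up to thousands of genes.

## Motif scanning

Scanning is consensus (IUPAC class) matching, not PWM scoring: a half-site
is `RRRCWWGYYY`, a full site two half-sites on the same strand separated
by a 0–13 bp spacer (a configurable range spanning the canonical
literature values), and the core is `CxxG` with any two non-N bases
between; N never matches.  The decamer's class pattern is its own reverse
complement (as is `CxxG`), so forward-strand scanning is complete and all
coverage statistics are strand-symmetric.  Core hits are reported
separately and never count toward full/half fractions.  Because consensus
matching differs from de-novo position-weight matrices, coverage fractions
on real peaksets are not comparable with PWM-derived percentages.
Windows are 500 bp around the summit, clipped at chromosome ends, with a
seeded uniform subsample of 5000 windows when the peakset is larger.

## Synthetic study design

The generator emulates the experimental design end to end: two ChIP
replicates per factor (TP53, TP63) per condition (untreated, adriamycin,
cisplatin); site classes shared / TP53-only / TP63-only crossed with
binding timing (TP53: 30% constitutive, 5% adriamycin-only, 25%
cisplatin-only, 40% shared-damage — damage-dominated with a strong
cisplatin skew, as observed for TP53; TP63: 60% constitutive, 30% lost
under adriamycin, 10% untreated-only — reflecting the adriamycin-dominant
TP63 collapse); single-replicate distractor peaks, blacklist artifacts and
high-read (3000-tag) spurious peaks to exercise consensus building and
filtering; negative-binomial per-site counts (dispersion 0.2, bound mean
150, condition multipliers 1.2/1.5 for TP53 under adriamycin/cisplatin)
despite the binomial differential test — a deliberate robustness stress;
and a 12-condition expression matrix with planted TP53-dependent induced
genes (2.5-fold, near shared sites — canonical co-bound targets),
repressed genes (2.5-fold down, near TP63-only sites) and TP63-maintained
genes (2-fold down under siTP63), log-normal expression noise of 0.1 on
the log2 scale, 20-bp replicate coordinate jitter and 5% per-peak dropout.

The genome is organized as isolated 55-kb regulatory blocks — one gene at
each block centre, sites of a single class family within ± 17.5 kb —
because with a 25-kb annotation window, neighborhoods must be farther
apart than the window for per-gene binding categories to be well defined;
a uniformly dense toy genome makes every gene "both"-bound and the
integration stage degenerate.  This fixes the default scale at three
2.75-Mb chromosomes for 150 genes and ~500 genuine sites; the full
pipeline still completes in a few seconds.  A concrete full response
element (spacer 0) is written into the sequence at every genuine site
summit.  All randomness flows through seeded PCG64 generators, making
every emitted file byte-deterministic per seed.

What the generator does **not** emulate — and what passing tests therefore
do not demonstrate about real data: read-level sampling (no FASTQ/BAM),
mappability structure and GC bias, peak-width and summit-offset
heterogeneity, fragmented or chained peak calls, isoform-level gene
models, partially penetrant or treatment-asymmetric expression responses,
and realistic genome density (real cistromes are far sparser per Mb, and
real genes see overlapping regulatory neighborhoods).

## Validation scale and calibration checks

The test suite validates interval algebra, annotation and the motif
scanner against brute-force per-base / regex / enumeration oracles on
randomized instances; the differential test's type-I error on 2,000
Poisson null sites (bound by nominal + 3 Monte-Carlo s.e.) and BH's
empirical false-discovery proportion on a 2,000-site mixed simulation
(bound by the 0.1 level); noiseless synthetic runs for exact recovery of
all planted classes; and ten seeded noisy runs (defaults above) for
≥ 0.9 recall and precision of site classes and gene classifications.
Fast tests use a scaled-down generator configuration (three 770-kb
chromosomes, 40 genes, ~130 genuine sites); the acceptance script runs the
full default design over ten seeds.

## Known limitations

* The differential stage is a pooled exact test, not a replicate-aware
  dispersion model; its significant-site counts are expected to exceed
  those of negative-binomial analyses on overdispersed data.
* Consensus matching cannot reproduce PWM-based motif-coverage
  percentages.
* Hypergeometric enrichment inherits the arbitrariness of the background
  universe; results should be reported together with the universe used.
* Gene models are single-span BED6 records; isoform collapsing is the
  caller's responsibility.
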