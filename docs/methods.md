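# Methods

## Problem and model

`svtable` operates downstream of per-sample long-read SV calling. Its unit
of analysis is the *merged site*: one reference position at which calls
from different samples are judged to be the same structural variant. The
judgement uses a positional-offset threshold that scales with variant
length,

    threshold(a, b) = M · sqrt(min(len_a, len_b)),    M = 250 (default),

reflecting that breakpoint estimates of long SVs scatter more between
samples than those of short SVs. `M` is dimensionless; raising it merges
more aggressively, and the number of clusters is non-increasing in `M`.

Clustering is deliberately simple: calls of one (chromosome, SV type) are
sorted by position and adjacent calls are chained whenever their gap is
within the pairwise threshold; clusters are the maximal chained runs
(single-linkage over the sorted order). This is deterministic, O(n log n),
and pinned by a brute-force union-find oracle in the tests. SV types never
mix within a site. Breakend (BND) calls carry no length, so BND pairs are
compared against a fixed window of `M` bp — a choice this package makes
explicitly, since no length-scaled rule is definable for them.

Each cluster is summarized by:

- representative position and length: the *lower median* of member values
  (robust to one outlier sample; the lower middle keeps the statistic an
  observed integer for even counts);
- `STDEV_POS`, `STDEV_LEN`: *population* standard deviations over member
  calls. Population rather than sample SD is load-bearing: a singleton
  cluster must score 0, not NaN, so that sites seen in a single sample
  survive the default filter. These dispersions are defined across member
  calls (i.e. across samples), not across supporting reads within a
  sample — callers may define similarly named quantities differently;
- `PRECISE` iff every member is precise;
- one genotype per cohort sample, `0/0` for samples with no member call.
  If a sample contributes more than one call to a cluster, its genotype
  comes from the call nearest the representative position, ties broken
  toward the higher alt dosage. All constituent calls are retained in
  `members`, so no input call is lost in accounting.

## Confidence filter

A site is removed when `STDEV_POS >= 1`, `STDEV_LEN >= 1`, it is flagged
imprecise, or its representative length is below 50 bp (re-checked at the
site level because the merged median can differ from the per-call lengths;
BND sites are exempt from the length rule). The `>=` is intentional: a
dispersion of exactly one is already out. Removals are attributed to the
first failing rule in the order listed, which makes filter reports
reproducible; the criteria themselves are an unordered "any".

## Coordinates and sequences

SV calls and merged sites use 1-based VCF coordinates; gene features use
0-based half-open BED coordinates, converted exactly once at the reader
boundary. For a merged site with anchor `pos`:

- upstream flank = reference bases `[pos − flank + 1, pos]` (default
  flank = 300), ending at the anchor base, so that for deletions
  `upstream + sv + downstream` reads off the reference contiguously
  (the deleted segment is `pos+1 .. end`);
- deletion/inversion/duplication sequence = bases `[pos + 1, end]`,
  downstream flank = `[end + 1, end + flank]`;
- insertion sequence = the inserted allele of the member call nearest the
  representative position (one row stores one sequence; the nearest
  member's is the least jittered choice); downstream flank starts at
  `pos + 1`;
- breakends have an empty variant sequence.

Flanks truncate at contig boundaries rather than erroring, because sites
near chromosome ends must still be reportable.

## Gene context

The gene-track format has no strand column, so "upstream" is strandless
and means lower coordinates; directional promoter logic is out of reach of
this input format and deliberately not attempted. A gene's upstream region
is `[max(start − U, end of nearest preceding gene, 0), start)` with
U = 2,000 bp by default. A site is *genic* for every gene body its
footprint intersects (footprint = spanned segment for length-resolved
types, the 1-bp anchor for insertions and breakends) and *upstream* for
every gene whose upstream window it intersects without touching the body;
genic excludes upstream for the same gene, and a site overlapping several
genes yields one output row per gene context. Sites spanning a gene
boundary count as genic for that gene — the intersect rule is this
package's definition, as interval semantics for that edge case are not
standardized.

## Outputs

The site table holds one row per merged site: hyphen-joined position, SV
type, reliability, length (empty string — never 0 — when undefined, so
re-read histograms are not corrupted), the two dispersions, per-sample
genotypes in manifest order, and the three sequences. The gene table
appends gene, neighboring-gene, region, and pass-through annotation
columns and is restricted to sites with at least one gene context. Both
are plain TSV (tab separator, no quoting, `\n` endings, one header line)
and byte-deterministic; a cell-for-cell spreadsheet export exists for
bench use. A merged multi-sample VCF export provides interoperability
with standard VCF tooling.

## PCA

Genotypes encode as alt-allele dosage (0/0→0, 0/1→1, 1/1→2). Columns with
zero variance cannot be unit-scaled and are dropped (counted and
reported); the remaining matrix is centered and scaled column-wise with
the sample (n−1) standard deviation, matching R's `prcomp(center=TRUE,
scale.=TRUE)`, and decomposed by full SVD. Component signs are arbitrary;
every consumer and test treats scores sign-invariantly. No imputation is
needed because the readers normalize missing genotypes (`./.`) to `0/0`
on ingestion — a deliberate collapse to the three-state genotype
vocabulary, logged with a warning when it happens.

## Genotype map

For one chromosome, sites are rows (ordered by position, but drawn at
uniform spacing) and samples are columns, colored dark blue (0/0), green
(0/1), yellow (1/1). Neutral scaffold rows are inserted every 50,000 bp
and at both chromosome ends so chromosomes render on a uniform physical
scale even where no SV was detected. Scaffold rows default to a fourth
light-gray category — "no site here" is information distinct from "site
here, genotype 0/0" — with an option to blend them into 0/0 for the
classic look. A scaffold point coinciding with a site position yields only
the site row.

## Synthetic cohorts

The simulator emulates the statistical shape of a multi-sample long-read
call set, not reads: a uniform-random reference (default 2 × 1.5 Mb), a
non-overlapping gene track whose inter-gene gaps straddle the 2,000 bp
upstream window (so truncation paths are exercised), and 50 planted sites
across 5 samples by default, spaced ≥ 50 kb, lengths 50–1,000 bp, type mix
DEL 0.48 / INS 0.42 / INV 0.05 / DUP 0.05 (deletions and insertions
dominate real long-read call sets), and per-sample genotype frequencies
0/0 0.45, 0/1 0.35, 1/1 0.20 (heterozygous calls outnumber homozygous
ones, as in outcrossing cohorts). Each site is forced to have at least one
carrier. Positional/length jitter is rounded Gaussian noise — no caller
noise model is standardized, and Gaussian scatter with sub-bp to few-bp SD
matches the dispersions the filter is designed around.

The planting guard `min_spacing > M · sqrt(max_length)` ties the simulator
to the merge threshold: distinct planted sites can never co-cluster under
the default `M`, so zero-jitter recovery (recall, precision, genotype
accuracy all 1.0) is a strict property of a correct implementation.
Everything is deterministic under fixed seeds, down to file bytes.

What the simulator does *not* emulate — and what passing tests therefore
do not show about real data: read-depth-dependent genotype errors,
caller-specific breakpoint biases, segmental duplications and other
repeat-driven false calls, clustered/nested SVs closer than the spacing
guard, and reference bias near divergent haplotypes. Results on real
cohorts depend on the upstream caller's behaviour in exactly those
regimes.

## Problem sizes

The default simulated cohort (50 sites × 5 samples on 3 Mb) keeps every
end-to-end check sub-second while still covering all four SV types, both
chromosomes, and every filter path; frequency-recovery checks scale up to
100 sites × 50 samples where binomial bounds need the extra draws. The
embedded validation grids (9 markers × 14 cultivars, genotype calls from
the pipeline and from PCR/electrophoresis on a citrus cohort) make the
concordance computation an exact, deterministic reproduction: per-marker
agreement {13,13,12,14,13,14,14,13,13}/14, unweighted mean 94.4%.

## Known limitations

- Merging is single-linkage over sorted-adjacent pairs; long chains of
  borderline-spaced calls can bridge into one cluster (the usual
  single-linkage caveat). The brute-force oracle pins this semantics.
- Genotypes are taken from the callers as-is; there is no coverage-based
  re-genotyping or quality recalibration.
- The BND fixed-window rule and the strandless upstream definition are
  package conventions where no standard exists; both are documented above
  and configurable where meaningful (`-M`, `--region`).
- Bit-exact agreement with any particular caller's own multi-sample mode
  is not claimed; the merge semantics here are defined by the threshold
  formula and the oracle tests.
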