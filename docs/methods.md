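# Methods

## Problem setting

Founder animals produced by zygotic Cas9 editing carry (i) the designed
deletion between flanking guide cut sites, (ii) whatever natural
variation their colony already segregates, plus new spontaneous
mutations, and possibly (iii) rare mutations at loci resembling the
guide protospacer.  The audit must separate (iii) from (ii) using only
per-animal variant calls, a reference genome, a known-variant database
and the guide sequences.  `otaudit` does this with an in-silico site
search, a strict filter cascade that isolates per-animal unique
variants, interval intersection of the two, and a resampling null that
quantifies how often unedited controls would show the same overlaps by
chance.

## Off-target site model

A candidate site for a 20-nt protospacer *P* is a genomic window *W* of
19, 20 or 21 nt with a PAM immediately 3′:

* |W| = 20 — gapless alignment, cost = Hamming(*W*, *P*);
* |W| = 21 — one unpaired genomic base (DNA bulge) at any of 21
  placements;
* |W| = 19 — one unpaired guide base (RNA bulge) at any of 20
  placements.

The PAM is N[G/A]G; its first base is never scored.  Only substitutions
count toward the mismatch ceiling (0–6); at most one bulge of either
kind is allowed per site, reflecting the single-bulge setting of
standard enumeration tools.  A locus is keyed by (strand, PAM
position).  A site is emitted when **any** alignment satisfies the
configuration, and the reported alignment is the minimum of
(bulge size, mismatches, bulge preference none→DNA→RNA, leftmost gap)
**over the valid alignments only** — ranking invalid alignments too
would paradoxically suppress bulged sites whenever the gapless distance
exceeds the ceiling.  Windows containing N are skipped (N never
matches).  Mitochondrial and non-canonical contigs are excluded by
default.

Two independent implementations exist: `enumerate_sites` anchors on PAM
positions and computes all alignment costs with vectorized
prefix/suffix mismatch sums (≈ 0.3 s per guide on a 900-kb genome at
ceiling 6), and `oracle_enumerate`, a deliberately naive
every-window/every-gap scan restricted to ≤ 100 kb genomes.  Their exact
equality on randomized inputs across every (ceiling, bulge) setting is
a standing test invariant.

Cut-site geometry is the standard blunt cut 3 bp 5′ of the PAM
(between protospacer positions 17 and 18), strand-aware.  The
mismatch-position profile indexes protospacer positions 1 (PAM-distal)
to 20 (PAM-proximal), with bulges in a separate gap bucket.

## Variant filter cascade

Stage order: **quality → repeats → known → het-ratio → callable →
secondary**.  All thresholds are strict inequalities: QUAL > 30,
DP > 9, GQ > 30, AF > 0.1; heterozygous calls with
ad_alt/(ad_ref+ad_alt) < 0.2 are excluded (AD absent → the AF field;
both absent → the record is kept with a logged warning, since the rule
cannot be applied).  Repeat intervals are padded by 2 bp on both sides
and matched by any overlap, so indels straddling a repeat boundary are
caught.  Known-variant matching uses left-normalized identity tuples
(contig, pos, ref, alt); position-only matching is available as a
sensitivity flag.  Callable filtering keeps a variant only when its
full reference span lies inside the intersection of every sample's
callable intervals.  The secondary filter removes any tuple observed in
≥ 2 distinct samples, leaving each animal's unique variants.  Known and
repeat stages commute (both are pure removals); a test asserts this.

SV consensus: after dropping missing and hom-ref genotypes, a record
needs ≥ 2 callers, ≥ 3 supporting reads and 200 bp < length < 5 kb;
shared SVs are then removed by breakpoint-pair matching across samples
(same type, both breakpoints within 100 bp — the tolerance is not
dictated by any source and is configurable; 100 bp is typical caller
jitter).  Strand is ignored.

Variant identity everywhere is the 4-tuple after left-normalization
against the genome (suffix/prefix trimming with left extension), so the
same indel written with different paddings compares equal.  Internal
coordinates are 0-based half-open; VCF positions convert at the I/O
boundary, with an indel occupying [pos−1, pos−1+len(ref)).
Multi-allelic rows are split per ALT before any filtering.

## Intersection, classification, on-target confirmation

A hit is any (site, variant) pair with ≥ 1 bp interval overlap, scoped
to the guides actually used for that founder; on-target loci are
excluded.  A small deletion and an SV deletion describing the same
event at one site (interval containment) are deduplicated in favour of
the SV record.  Hits are classified by variant class, PAM class,
mismatch bin (≤4 / 5 / 6) and genic context (exonic if overlapping any
exon, else intronic if inside a gene body, else intergenic —
upstream/downstream fold into intergenic).  On-target calls are
confirmed by a consensus SV deletion overlapping the expected interval
between the outermost cut sites, or by a small-variant deletion
covering ≥ 50% of it.  Three-way site-list comparisons (in-silico vs
in-vitro vs WGS evidence) count connected components of the
tolerance-overlap match graph (default 10 bp), labelled by the sources
present.

## Null model and statistics

Each control draws `n` sites uniformly without replacement from the
pooled prediction set, where `n` is the median per-founder predicted
site count (median rounds half up between counts); control *i* uses
seed *i* so every draw is reproducible, and the draws are logged to a
manifest.  Under uniform placement the expected pooled hit count is
`n_controls · n_sites · n_variants · (w + ℓ − 1)/L` for site footprint
*w*, mean variant span ℓ and genome length *L*; the calibration test
requires agreement within 3 Poisson standard errors over seeds 1..28.

Group comparisons are two-sided Wilcoxon rank-sum (Mann–Whitney) tests
per feature (total, SNV, indel, zygosity and genic classes), Bonferroni
corrected within the compared family, evaluated at α = 0.05.
Heterogeneity entries are percent Jaccard — the sources that inspired
this convention do not fix a denominator, and Jaccard keeps the matrix
symmetric, bounded and 100 on the diagonal; `denominator="min"` is
available.  Clustering uses Euclidean distance with complete linkage on
matrix rows (the defaults of the common heatmap packages), with a
2-cluster cut reported.

## Synthetic cohort generator

The generator emulates the study design the pipeline targets, at desk
scale.  Defaults (all in `CohortConfig`):

| parameter | default | meaning |
| --- | --- | --- |
| genome | 3 contigs × 300 kb | large enough for 50 founder designs; oracle-friendly subregions |
| cohort | 28 controls + 50 founders | two substrains interleaved across both groups |
| guides/founder | 2–4 | flanking a 200-bp "critical exon"; deletion span ≈ 0.5–1.5 kb |
| private variants | Poisson(756) SNVs + Poisson(276) indels per mouse | ~80% heterozygous |
| de novo | Poisson(25) SNVs + Poisson(1.5) indels | spontaneous per-generation load |
| substrain pools | 120 homozygous variants each | shared by every member of a substrain |
| ancestral pool | 400 variants, 70% in the known DB | carried by every animal |
| repeats | 5% of each contig | embedded dinucleotide expansions |
| callable | whole genome per sample | see below |
| edit decay | p(0)=1, p(1)=0.25, p(2)=0.05, p(3)=0.01, p(≥4)=0.001 | synthetic stand-in |
| SV callers | 4 names, detect p=0.9 | one founder forced to single-caller |

Choices that matter for interpreting test results:

* **Global tuple uniqueness.** Background identity tuples are drawn
  without replacement across the whole cohort (collisions resampled),
  so "private" variants are private by construction and the filter
  cascade's expected output is exact set arithmetic over the truth
  ledger.  Real colonies contain recurrent mutation and shared rare
  alleles that this deliberately omits; the exactness tests validate
  the cascade's logic, not its behaviour under allele sharing beyond
  the modelled pools.
* **Decoy loci.** Each guide gets planted near-match loci at mismatch
  distances 1–6, on both strands, inside its founder's design block
  (clear of repeats and deletion spans).  Distances 1–2 receive NAG
  PAMs so guides honour the design rule (no < 3-mismatch NGG site);
  a config flag plants rule-violating decoys to exercise the checker,
  which itself scores gapless, non-on-target-overlapping sites only —
  the way guide-design tools count mismatches.
* **Edit injection.** Off-target indels (1–8 bp deletions or 1–4 bp
  insertions at the cut position, heterozygous, passing quality) are
  injected per predicted site with probability p(mismatches).  Sites
  overlapping the guide's own on-target locus are skipped: bulged
  re-alignments of the on-target protospacer at adjacent PAMs are the
  same physical cut, already modelled by the on-target deletion.  The
  truth ledger records, per edit, whether it lies in a padded repeat
  and whether its annotations pass the thresholds, so recovery tests
  condition on what the cascade could possibly retain.  The decay
  values are **not** estimates from any dataset; they are defaults
  chosen so both positive and negative recovery cases occur at the
  default cohort size.
* **Callable intervals** default to full-genome coverage per sample,
  keeping truth reconciliation exact; fractional coverage (random
  gaps) is available and callable-intersection logic is tested
  separately on adversarial interval sets.
* **Quality annotations** are drawn from passing distributions
  (DP ≈ N(36, 6) clipped ≥ 12, GQ ≈ N(75, 12) clipped to (35, 99],
  QUAL ≈ N(250, 80) ≥ 40, het AD ratios clipped to [0.28, 0.72]);
  a configurable failure fraction (default 0) redraws a record to fail
  exactly one named stage, exercising every filter branch.
* **Scale caveat.** ~190 predicted sites per guide at ceiling 6 on
  900 kb is ~3000× denser than a mammalian genome; absolute hit rates
  from synthetic runs are therefore not comparable to real cohorts,
  and the meaningful outputs are truth-ledger reconciliations,
  recall/precision accounting and the calibrated null.

Determinism: one `numpy` generator seeded from `CohortConfig.seed`
drives everything; regeneration and re-emission are byte-identical,
and the emitted `manifest.json` records the config.

## Reporting conventions

Percentages are rounded half up; the default policy is one decimal at
≥ 1% and three decimals below 1%, and each headline ratio carries the
precision conventional for it (e.g. 8/163 → 4.9%, 26/555,032 → 0.005%,
10/26 → 38%).  A zero denominator reports "undefined", never 0.  Every
ratio in a summary is re-derived from its stored counts at render time;
any mismatch raises.

## Problem sizes used by the default test/acceptance runs

Site enumeration for ~150 guides on the 900-kb default genome takes
about a minute; the full suite runs in ~2 minutes and the acceptance
script in ~1 minute on one CPU.  The search-oracle sweep uses ≥ 50
random guide/genome pairs at ≤ 2 kb; the null calibration uses 28
controls × 500 drawn sites from a 3,000-site pool on an abstract 1-Mb
contig; the type-I check uses 100 replicates of 28 + 50 samples with
Poisson(60) variant loads.

## Known limitations

* No read-level simulation (no FASTQ/BAM); quality annotations are
  parametric, not re-called.
* Phased genotypes are treated as unphased; symbolic ALTs other than
  SV types are skipped.
* The search makes no performance claims at mammalian genome scale;
  it is vectorized but unindexed.
* CIRCLE-seq-style external site lists enter only as tables for the
  set-overlap comparison; no in-vitro read processing.
* Sanger/ICE validation status is an external annotation the user
  supplies; the pipeline never fabricates it.
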