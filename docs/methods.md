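# Methods

`circaparam` re-implements, as a tested library, a characterization
workflow for circadian genes in a peripheral tissue: detect rhythmic rows in
a dense temporal expression matrix, reduce probe-level calls to gene loci,
partition the gene universe into circadian and non-circadian sets, compare
the sets' genomic and expression parameters, cluster the circadian genes
into temporal co-expression groups, and test those groups for phase-specific
annotation terms and miRNA targets.  Everything runs end-to-end on synthetic
data with known ground truth; this note records the models, the defaults,
and the judgment calls.

## Rhythm detection

**Rank scan (JTK-style).**  For each row the Kendall S statistic
(concordant minus discordant pairs) is computed against reference cosines on
a (period x phase) grid — periods 20–28 h in 1-h steps (a ±4 h band around
24 h), phase step equal to the sampling interval.  Reference cosines sampled
on an even grid are heavily tied (a 48-point, 24-h reference repeats each
value across the two cycles and mirrors it around the peak), so p-values
come from the *exact* null of S for the reference's tie pattern: with tied
group sizes n_1..n_g, the count generating function of the concordant-pair
statistic is the q-multinomial coefficient — the product of Gaussian
binomials [N_k choose n_k]_q over cumulative sizes N_k — evaluated by
integer polynomial convolution.  The untied case reduces to the classical
inversion-count product.  Exact nulls are built up to n = 60 points; the
test suite checks them against full permutation enumeration for small n.
Per row, the minimum two-sided tail probability over the grid is
Bonferroni-multiplied by the number of *distinct* alternatives (a reference
and its antiphase mate are the same two-sided test) and capped at 1.
Ties in the data enter through the tie-adjusted S (tied pairs contribute 0);
the null is not re-derived for data ties, which are rare for continuous
intensities.  Constant rows score S = 0, p = 1.

**Model-library matcher.**  Rows missed by the rank scan are matched by
Pearson correlation against discretized templates — cosine, spike (Gaussian
bump, sigma 1.5 h per 24 h), box (high for 6 h per 24 h), and sawtooth
(peak then linear decline) — over the same period grid and all phase
shifts.  p is the two-sided t transform of the best r with T-2 degrees of
freedom, Bonferroni-corrected over the template grid.  The template library
deliberately matches the simulator's waveform library so detector coverage
of non-cosine shapes is testable.

**Combination.**  q-values are Benjamini–Hochberg within each detector
across rows.  Rows passing the rank scan at q < threshold (default 0.001)
keep that call; among the rest, rows passing the matcher are added.  One
call per row, detector recorded.

## From probes to gene sets

Probes map to loci through a probe map; transcript features can also be
clustered into loci directly (shared splice site joins multi-exon features,
overlap joins single-exon ones, transitive closure; representative =
most exons, then longest transcript).  Loci with multiple rhythmic probes
keep the lowest-q probe as representative; every other rhythmic probe must
agree within 4 h of period and 6 h of circular phase distance (phases
compared on the 24-h scale after period normalization — circular distance is
the only convention bounded by 12 h).  If the failing probes outnumber half
the locus's rhythmic probes (strictly: 2 x failures > probes), the locus is
excluded from the circadian list; such loci are also withheld from the
non-circadian control set, under the residual "AL-only" label, because
their rhythmicity is ambiguous in both directions.

The expressed/non-expressed cutoff is the midpoint between the two highest
peaks of a Gaussian-kernel density estimate of the log10 expression values
(peaks below 5% prominence of the maximum are ignored; a unimodal density is
an error and the caller may fall back to the fixed default 1.45).  A locus
is expressed when its maximum over timepoints exceeds the cutoff.  The
partition is then: LCG = circadian and expressed; LNLCG = on the general
circadian list (rhythmic in some tissue), not rhythmic here, expressed;
LNCG = off-list, not rhythmic, expressed; plus the unexpressed remainders.
False-positive rates are percentages of negative-control (resp. literature
circadian) gene lists landing in the LCG (resp. LNCG) set.

## Genomic parameters

Neighbor counts extend a locus by half a window on each side (the first or
last locus of a chromosome extends a full window on its inner side only, per
the stated edge rule) and count any-strand loci overlapping the extension by
at least one base, excluding the locus itself; profiles run over 0–1.5 Mb in
15-kb steps and are monotone in the window by construction.  Density/GC and
group-percentage/GC relations use Pearson correlation with the two-sided
t-test.  Length statistics are medians (mean-of-middle-two for even n) of
the representative transcript's genomic span, 5'-UTR, 3'-UTR and CDS
lengths; loci lacking a structure are excluded from that structure's median.
Divergent pairs are head-to-head opposite-strand loci with TSS gap at most
1 kb (configurable; the distance rule follows the bidirectional-promoter
literature) whose circular phase distance is at most 6 h.  Binding sites
annotate to the nearest TSS within 50 kb, one highest-mean-signal site per
locus, ranked by mean signal for top-N group percentages; methylation probes
annotate within 2 kb of the nearest TSS with no per-locus reduction (every
probe contributes its M-value).

## Expression features

Amplitude is the peak-to-trough ratio, 95th over 5th percentile of the
*linear* intensities (antilog of the stored log10 values; fold-change
amplitudes near 2–3 are impossible on the log scale), with the interpolated
order statistic at position 1 + (n-1)p — both conventions fixed for
reproducibility and oracle-tested.  Expression bins rank genes by mean
expression and fill 300-gene bins bottom-up, the remainder merging into the
top bin (8,429 genes give 27 x 300 + 329).  Temporal and cross-tissue
statistics are per-gene mean and sample SD (n-1).  Expression breadth is the
number of tissues above the cutoff, histogrammed in the fixed 11-bin scheme
({0,1}, nine 5-wide bins, {42–45}, {46} for 46 tissues; other tissue counts
use the analogous scheme).  Half-life records whose ES-versus-differentiated
difference has p <= 0.1 are excluded before group comparison.  Group
comparisons use the one-sided Wilcoxon rank-sum test — exact by enumeration
when min(n, m) <= 8 without ties, tie-corrected normal approximation
otherwise — and p-values below 2.2e-16 are reported as "<2.2e-16".

## Temporal co-expression clustering

LCG profiles are median-normalized per row and shifted to be nonnegative
(preserves temporal shape), then factorized by KL-divergence
multiplicative-update NMF from 20 random starts (seeds derived from one
master seed), rank k = 3 by default.  Genes are assigned to their argmax
factor per run; the mean co-assignment matrix is the consensus.  Clusters
come from average-linkage grouping of 1 - consensus, cut at the smallest
number of flat clusters where every cluster's mean within-cluster consensus
exceeds 0.8 (if no cut achieves that, the cut retaining the most passing
clusters is used and only those are kept).  When expression profiles are
supplied, each consensus cluster must additionally be internally correlated:
average linkage on 1 - Pearson correlation at cut 0.2 separates phase
groups whose mean cross-correlation falls below 0.8.  This refinement is
what lets a rank-3 consensus resolve four phase groups — a stable
factorization always merges the two closest archetypes into one binary
block that consensus values alone cannot split.  A split is accepted only
when it reveals at least two subclusters of the minimum size (default 100);
a coherent phase continuum that would merely shatter stays whole.  Clusters
below the minimum size are discarded.  Each cluster is labelled by the
window containing the circular mean of its members' phases: dawn [CT22, 2),
day [2, 10), dusk [10, 14), night [14, 22), half-open boundaries.  Phases
of arbitrary periods are first normalized to circadian time,
CT = (phase mod period) x 24 / period.

## Enrichment

2x2 tables use Fisher's exact test when any expected cell is below 5 and
Pearson's chi-squared without continuity correction otherwise; the
enrichment fold is the proportion ratio (k_in/n_in)/(k_out/n_out), infinite
when only the focal set carries the property.  A term is phase-specific for
a cluster when at least 3 of the 4 comparisons — against each other cluster
and against the non-circadian background — have p < 0.05 and fold > 1.5
(raw p-values, faithful to the procedure; an optional BH flag exists).  The
miRNA variant uses only the three inter-cluster comparisons and requires all
three.  With fewer than three recovered clusters no term can be flagged.
miRNA targets are exact occurrences of the reverse complement of the seed
(miRNA bases 2–8, U normalized to T) on the 3'-UTR sense strand; overlapping
occurrences count separately.

## The synthetic-data generator

The generator emulates the statistical shape of a high-density liver time
course and a multi-tissue compendium: by default 10,000 loci with 1–3
probes each, 48 hourly timepoints, bimodal log10 intensities (modes 0.8 and
2.1, so the expressed/non-expressed midpoint sits near 1.45), a 46-column
tissue matrix, and 19 chromosomes with a GC gradient.  The rhythmic signal
is y(t) = m + (log10 A / 2) x w((t - phi)/tau) + eps with waveform w in
[-1, 1] peaking at phi, so the planted peak/trough ratio A (drawn uniform
2–5) is exact on the linear scale; eps is additive Gaussian on the log10
scale (sd 0.05 by default).  Exactly floor(fraction x n) loci are rhythmic —
a deterministic count, so downstream sensitivity/FDR are exact set
comparisons — preferring AT-rich chromosomes (the planted anti-correlation
between rhythmic-gene share and GC).  Phases are drawn from a normal
(sd 1.3 h) around the window centers CT0 / CT6.5 / CT12 / CT15.5 and clipped
to the window: observed circadian phase distributions are concentrated, and
a uniform-over-window continuum would make the fixed 0.8/min-100 cluster
selection vacuously empty at realistic set sizes.  Head-to-head pairs are
planted at an exact count (floor of the divergent fraction x n / 2, TSS gaps
100–900 bp; all other intergenic gaps exceed 2 kb so no accidental pairs
arise), and half of the singly-rhythmic pairs are completed to co-rhythmic
pairs with partner phases within ~1.5 h.  Auxiliary tables plant the
directions the analysis measures: rhythmic loci get more and stronger
TSS-proximal binding sites, slightly lower promoter M-values, shorter
half-lives (log-median 7.0 vs 8.4 h), and denser 3'-UTR seed sites; planted
seed-site counts are exact (accidental occurrences are mutated away), and
tissue-matrix values are drawn clear of the cutoff so planted breadths are
exactly recoverable.  Gene-to-term tables carry one term per temporal window
at 35% within-window versus 2% background frequency.  A fixed seed gives
byte-identical outputs (generator algorithm version 1); sub-generators
derive from independent children of the master seed.

**What the generator does not emulate** — probe-level chemistry and
normalization artifacts, heteroscedastic noise, correlated noise across
probes of a locus, non-sinusoidal asymmetric real waveforms beyond the
four-template library, linkage between gene structure and rhythmicity
(length contrasts are not planted), and annotation errors.  Passing tests
therefore demonstrate correctness of the *procedures* under the stated
model, not detector performance on real microarray data.

## Problem sizes and numerics

The default test suite and the acceptance script use scaled problem sizes
chosen as adequate for their statistical checks: 1,000 genes (200 planted
rhythmic) for detector power/FDR, 600 genes for clustering recovery, and
1,200–1,500 loci for end-to-end runs.  Tolerances: reference values are
rounded to 9 decimals for tie detection; KDE peaks below 5% relative
prominence are ignored; NMF runs cap at 500 multiplicative updates with
relative tolerance 1e-5.  Ties in ranked quantities break by identifier for
run-to-run stability.  Degenerate inputs (constant rows, empty groups,
unimodal densities, zero-variance correlations) raise errors or report null
statistics as documented on each function.

## Known limitations

The rank-scan null conditions on the reference's tie pattern but not the
data's; the Bonferroni factor over grid alternatives is conservative for
correlated references; consensus clustering inherits NMF's local-optimum
behavior (mitigated but not removed by 20 restarts); the phase-specific
criterion applies no multiple-testing correction across terms by design;
and the divergent-pair TSS-gap rule (1 kb) is a configurable convention,
not a derived quantity.
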