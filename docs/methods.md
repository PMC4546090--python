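# Methods

`methstage` re-implements, as a tested library, the methylome computations
used to characterise DNA-methylation dynamics across mouse spermatogonial
stem-cell formation (neonatal prospermatogonia through early postnatal
Kit− and Kit+ spermatogonia): coverage filtering and strand merging of
whole-genome bisulfite (WGBS) calls, conversion-failure correction,
window-level methylation tracks, segmentation of partially methylated
domains (PMDs), sliding-window calling of stage-specific differentially
methylated regions (DMRs), trajectory clustering of DMRs, 5hmC estimation
from paired BS/oxBS libraries, and regulatory-domain association of DMRs
with gene-expression changes. A synthetic-data generator with exact planted
truth stands in for the original sequencing data, so every procedure can be
scored for recovery.

## Data model and preprocessing

The atom is a cytosine call table: one row per (chrom, pos, strand) with
methylated/total read counts and a trinucleotide context class (CG, CHG,
CHH; "CH" always means CHG ∪ CHH). All internal coordinates are 0-based
half-open; Bismark-style cytosine reports (1-based) are shifted at the I/O
boundary and nowhere else.

Preprocessing follows the study's filters exactly:

* symmetric CG dyads (plus-strand C at p, minus-strand C at p+1) are merged
  into one strand-free record at p with summed counts; a one-strand dyad is
  kept as-is;
* after merging, CG records need ≥ 6 reads, CH records ≥ 4 reads, and any
  record above 100 reads is discarded as a likely collapsed repeat.

Every methylation level in the package is a pooled-read fraction
(Σ methylated / Σ total reads), not a mean of per-site fractions; per-site
fractions appear only as the observation vectors of the DMR test. The
pooled definition is the WGBS convention for global and window levels and
remains well defined at low coverage.

Because contexts are taken from the report's context column, the CH
breakdown is reported at the CHG/CHH class level; a per-dinucleotide
(CA/CC/CT) split would need the reference sequence, which the pipeline
deliberately does not require.

### Conversion-failure correction

The unmethylated lambda spike-in estimates the per-sample nonconversion
rate r as its pooled apparent methylation (one global estimate per sample,
not per context). Correction inverts the mixing model
observed = true + (1 − true)·r, i.e. corrected = (observed − r)/(1 − r),
clamped at zero. At r ≈ 0.003 this differs negligibly from naive
subtraction but is exact for any r and never produces levels above 1.

## PMD segmentation

PMDs — megabase blocks of intermediate methylation, gene-poor and
silenced — are segmented on a 10-kb nonoverlapping window track (≥ 5
informative CG dyads per window) by a two-state hidden Markov model with
Gaussian emissions on the window level, authored in-repo:

* emission means/variances are initialised from a two-component Gaussian
  mixture and refined by Baum–Welch; the transition matrix carries a sticky
  Dirichlet prior (pseudocount 10 on self-transitions) so decoded states
  persist at the domain scale;
* the lower-mean state is the PMD state; Viterbi decoding labels observed
  windows, and consecutive PMD windows (bridging interior windows with
  missing levels) become segments;
* segments shorter than `min_length` (100 kb) are dropped; a separate
  `report_min_length` (500 kb) reproduces the reporting convention of
  showing only large domains, so detection and display rules stay distinct;
* if the two fitted emission means are closer than `min_state_separation`
  (0.1), the track is declared homogeneous and no PMDs are called — this
  guards the null case where a two-component fit on a unimodal histogram
  would otherwise split noise.

The segmenter is validated against planted truth (base-pair Jaccard ≥ 0.9
on ≥ 800-kb planted domains at 15×), not against any published PMD
coordinates, since the original study used an external tool whose exact
settings are unstated.

Windows overlapping a PMD by ≥ 1 bp are PMD windows; a gene is a PMD gene
when its promoter — 2 kb upstream to 500 bp downstream of the TSS,
strand-aware — overlaps a PMD. PMD-gene silencing is summarised as
log2(FPKM + 1) distributions.

## DMR calling

Two stages are compared in 500-bp windows sliding by 100 bp, anchored at
multiples of the step. Replicates are pooled at the count level; a window
is a candidate when it contains ≥ 5 CG dyads covered ≥ 10× in both stages
(the same dyad set on both sides). With two replicates per stage a
replicate-level t-test is not meaningful (zero residual degrees of
freedom), so the observation unit is the per-dyad methylation fraction
within the window — the ≥ 5-dyad floor then guarantees ≥ 5 observations
per group.

Each candidate gets:

* a Welch (unequal-variance) two-sample t-test on the two fraction
  vectors, computed in closed form from windowed moments (algebraically
  identical to the per-window test, vectorised over all windows);
* a delta: the pooled-level difference (stage B − stage A) in percentage
  points — ">30 %" is read as an absolute 30-point difference, the
  standard reading in WGBS DMR work (a relative criterion would make every
  hypomethylated region trivially significant);
* a Benjamini–Hochberg q-value, adjusted once across all candidates of the
  comparison (not per chromosome).

Windows with |delta| > 30, p < 0.02 and q < 0.05 are significant; both
p and q thresholds are enforced jointly, as stated. Overlapping significant
windows of the same direction merge into maximal runs (gain and loss runs
never merge — a mixed-sign "DMR" would be self-contradictory); abutting
but non-overlapping windows stay separate. Every DMR therefore has length
500 + 100k bp. DMR stage levels are recomputed as pooled levels over the
merged interval. When both groups have zero variance the statistic is
undefined; the decision is deterministic and logged: p = 1 for equal
means, p = 0 otherwise (constant unequal vectors disagree at every site).

Calibration and power are demonstrated on synthetic two-stage screens
(5-Mb genome, 100 planted 40-point DMRs of 8 dyads, 15× with two
replicates, binomial reads): the realised false-discovery proportion
averages ≈ 0 over 20 screens and sensitivity exceeds 0.98. An optional
beta-binomial depth model exposes the caller to overdispersed noise.

## Trajectory clustering

Each DMR is summarised by (L0, Δ1, Δ2): its pooled level in the first
stage and the changes over the two transitions, in percentage points.
Agglomerative clustering with Euclidean distance and complete linkage
(the R `hclust` defaults) cuts the dendrogram into k = 6 groups, the
number of trajectory archetypes distinguished in the study. Cluster
numbers are canonicalised by sorting cluster mean trajectories
lexicographically in descending order, so "cluster 1" is always the
high-start/stable/late-loss archetype regardless of input order. A
silhouette-based k selection is provided for validation on planted data
(it recovers k = 6); it is not used to second-guess the fixed k.

## 5hmC estimation

Bisulfite reads 5mC and 5hmC as methylated; oxidative bisulfite reads only
5mC. At every CG site covered ≥ 6× in both assays, 5hmC = BS − oxBS and
5mC = oxBS. Per-site negative differences are clamped at zero with the raw
value retained; the pooled compartment estimate uses the difference of
pooled levels (unclamped) by default because per-site clamping biases a
small true signal upward — a strict-clamping flag reproduces the other
convention. Modified-base densities (per 100 bp) are Σ per-site level /
region length × 100, computed separately for 5mC and 5hmC; a CG-dense
compartment can rank higher by density than by level, the phenomenon seen
at satellite repeats.

## Gene association

Each gene's regulatory domain follows the basal-plus-extension rule: a
basal window from 5 kb upstream to 1 kb downstream of the TSS, extended up
to 1 Mb on each side but truncated at the nearest non-overlapping
neighbouring basal domain (basal windows are never truncated; overlapping
basals simply leave no room to extend). A DMR links to every gene whose
extended domain it overlaps by ≥ 1 bp.

An expression change between two stages requires jointly fold change > 2.0
(larger/smaller FPKM) and |ΔFPKM| > 5.0. When the smaller FPKM is 0 the
fold is undefined; the fold criterion is treated as satisfied, so a gene
switching on from zero is changed iff it clears the delta threshold
(0 → 0 is unchanged). Enrichment of change among DMR-linked genes is a
Pearson chi-squared test (df = 1, no continuity correction) on the 2×2
linked × changed table.

## Synthetic data

The generator plants, per chromosome: CG dyads at exponential spacing
(mean 100 bp); PMDs (two per chromosome, 0.8–1.5 Mb, level 0.45);
DMRs from the six archetypes with exact per-stage levels, each carrying 8
dyads spaced at the screen's 100-bp step (replacing background dyads, so
every planted DMR is enumerable); optional CH sites per strand; and a
latent per-site CG heterogeneity (Beta with concentration 50, shared
across stages so null windows differ only by sampling noise). Reads are
Binomial(depth, observed_p) per strand per replicate — Poisson depth with
mean 15 by default, negative-binomial under the overdispersion knob — with
observed_p = true_p + (1 − true_p) × 0.003 mixing in conversion failures.
The spike-in emits 10,000 truly unmethylated cytosines at 20×.

Default stage structure mirrors the study: CG backgrounds 76.1/76.6/76.4 %
across P0.5, Kit− and Kit+; CH methylation 7.8 % in P0.5 and 0 afterwards
(the transient non-CpG wave that disappears once mitosis resumes); 5hmC
1.4 % at CG sites, visible to BS but not oxBS. With a realistic CG:CH
cytosine ratio (~4 % of cytosines in CG context) the generated neonatal
methylome reproduces the headline partition: ≈ 3.3 % of all cytosines
methylated at CG, ≈ 7.5 % at CH, ≈ 10.8 % total.

Archetype trajectories for the two small clusters (3 and 4) are
approximations — the study describes them only qualitatively (cluster 3
gains methylation on the Kit−→Kit+ transition) — and are flagged
`approximate` in the truth table.

Expression simulation draws PMD genes from a low-FPKM log-normal
(median ≈ 0.4) and others from a higher one (median ≈ 10); DMR-linked
genes change between consecutive stages with probability 0.5 (others
0.02), with multiplicative factors of 3–6 and guards ensuring each planted
change clears both call thresholds (downward changes are only planted from
baselines high enough to clear the 5-FPKM delta). Everything derives from
a single integer seed; identical (config, seed) gives bit-identical
tables.

### What the generator does not emulate

Sequence composition (GC isochores, CpG islands), repeat structure and
mappability, per-read error profiles, spatial autocorrelation of coverage,
and biological replicate-to-replicate shifts beyond binomial/beta-binomial
noise. Passing recovery tests therefore demonstrates correctness of the
algorithms under the stated noise model, not robustness to every artefact
of real libraries.

## Problem sizes and numerical choices

Simulation-backed tests run on 0.2–5 Mb genomes (1/500–1/5000 of a
mammalian genome) at the study's depth and replicate structure; these sizes
give the calibration and recovery suites comfortable margins while keeping
the whole test run in well under a minute per scenario. Tolerances:
nonconversion inversion is exact to 1e-12; BH q-values match a brute-force
step-up oracle to 1e-12; stochastic recovery checks use explicit
Monte-Carlo slack (2 standard errors) or the sampling-error bounds stated
alongside each test. Degenerate inputs (empty tables, zero-variance
windows, empty spike-ins, k exceeding the row count) raise or return the
documented conservative decision rather than propagating NaNs.

## Known limitations

* The DMR unit-of-observation choice (per-dyad fractions, replicates
  pooled) is one reading of "two-sample t-tests with unequal variance";
  replicate-aware dispersion modelling (beta-binomial DMR callers) is
  explicitly out of scope.
* The PMD segmenter is a defined, testable stand-in validated on planted
  truth; its boundaries need not coincide with those of alpha-distribution
  based segmentation tools on real data.
* Whether published global CG levels were conversion-corrected is unclear;
  both raw and corrected modes are exposed and the context-partition
  figures always correct.
* Gene structure is reduced to (TSS, TES, strand); exon-level DMR
  annotation activates only when an exon table is supplied, otherwise
  non-promoter genic DMRs are labelled intronic.
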