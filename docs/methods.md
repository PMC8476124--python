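# Methods

## The de-repression statistic

For a miRNA seed family *f* with predicted target set T_f, restricted to
expressed genes (m = |T_f ∩ expressed|), the statistic is

    Z_f = (Sm − µ) · m^(1/2) / ∂

with Sm the mean log2 fold change (treatment vs control) over the m
targets, and µ, ∂ the mean and sample standard deviation (n − 1
denominator) of the background log2 fold changes.  The background for each
family is the expressed transcriptome minus that family's own predicted
targets; targets of *other* families remain in the background.  Removing
every family's targets would empty the background — in a TargetScan-style
map most expressed genes are a predicted target of something — and the
per-family exclusion keeps the null interpretation clean: under no
de-repression, Sm is the mean of m draws from (approximately) the
background distribution, so Z ~ N(0, 1).  A configuration switch
(`per_family_background=False`) uses the full expressed set instead.

Assumptions worth keeping in mind:

* the normal approximation needs a reasonable set size — families with
  m < `m_min` (default 10) are reported with a status code, not scored;
* a degenerate background (∂ = 0) or one with fewer than two genes is a
  hard error, never silently patched;
* Z values of different families are not independent (they share the
  background and may share targets); the statistic describes each family,
  not a joint test.

The same split feeds a two-sided two-sample Kolmogorov–Smirnov comparison
of the empirical log2FC distributions: D = sup |F_targets − F_background|,
exact p-value when the smaller set has ≤ 25 genes, asymptotic otherwise.
The KS panel is descriptive; across families a Benjamini–Hochberg
adjustment of the KS p-values is reported in a separate column
(`ks_p_bh`) as a convenience for reuse — the core statistic involves no
multiple-testing machinery.  The CDF comparison also records a shift sign:
+1 when the targets' CDF is right-shifted (the signed sup-difference
toward de-repression exceeds the opposite one), −1 when left-shifted.

The bubble table keeps scored families with a defined abundance, sorted by
abundance descending; z is the y-coordinate, a_f the x-coordinate, and
bubble area is proportional to m.

## Mature miRNA quantification

Reads are expected as precursor-space alignments (SAM/BAM against pre-miRNA
hairpins).  A read is assigned to an annotated mature miRNA when **both**
|Δ5′| ≤ w and |Δ3′| ≤ w with window w = 4 nt, bounds inclusive.  The
conjunction is deliberate: templated isomiRs wobble at both ends within a
few nucleotides, whereas degradation fragments typically match at most one
end.  Only primary, plus-strand alignments count (the reference is a
sense-strand hairpin index; secondary hits would double-count), and
alignment ends are aligned-segment ends in precursor coordinates, so soft
clips are excluded.  A read compatible with several matures — possible
only for overlapping annotations — goes to the mature minimising
|Δ5′| + |Δ3′|, ties broken by lexicographically smallest mature ID
(deterministic closest-annotation assignment).  Reads are never silently
dropped: per-library QC reports assigned, out-of-window and
unknown-reference tallies, and their sum equals the number of primary
plus-strand alignments.

Family abundance is a_f = log10 of the summed counts over the family's
member miRNAs (log10 chosen as the conventional abundance axis;
zero-count families have undefined abundance, are flagged, and are excluded
from abundance-dependent outputs).  Between-library miRNA comparisons use
counts-per-million with a 0.5-CPM pseudocount on the log-ratio and report
a Spearman correlation.

## Fold changes

The statistic consumes only per-gene log2 fold changes, so the
differential-expression stage is deliberately minimal, and an externally
computed table (e.g. a DESeq2 run) can be ingested verbatim — that is the
preferred input for real data.  The built-in stand-in:

1. **Median-of-ratios normalisation.**  Reported size factors follow the
   DESeq convention: per sample, the median (taken on the log scale, which
   interpolates geometrically at even reference counts — matching DESeq2,
   and cross-checked against pydeseq2 in the test suite) of
   count_gs/geomean_g over genes with nonzero counts in all samples.
   The *normalised matrix*, however, applies the same composition
   correction to CPM-scaled samples rather than raw counts.  Plain
   counts/size-factor normalisation is not invariant to rescaling one
   sample — the geometric-mean reference absorbs a factor c^(1/n) — while
   the CPM-based matrix is exactly invariant: multiplying any sample's
   counts by a positive constant changes nothing downstream.  Normalised
   values are therefore in scale-free CPM-like units.
2. **Pseudocount log-ratio.**  log2FC = log2((mean_trt + pc)/(mean_ctl + pc))
   with pc = 0.5 (in normalised units), keeping zero-mean genes finite.
3. **Expression filter.**  `expressed` ⇔ mean normalised expression ≥
   `min_mean` (default 10, i.e. 10 CPM-like units given the normalisation
   above); downstream stages see only expressed genes.

No dispersion shrinkage, Wald tests or independent filtering: none of it
is consumed by the statistic.  Whether fold changes came from the stand-in
or an external table is recorded in the run manifest.

## The simulator

The generator emulates a miRISC-inhibition experiment end to end; its
defaults are the package's reference study conditions.

* **Annotation.**  Hairpin precursors of 75–100 nt carry one or two mature
  arms of 20–23 nt, placed 8–12 nt from the hairpin ends (enough margin
  that end-jittered reads never leave the reference).  Matures are
  partitioned into `n_families` = 40 seed families (each family's seed
  string is nt 2–8 of its first member), averaging two members per family
  — a few dozen conserved families is what passes an abundance floor in a
  typical tissue.
* **Small-RNA reads.**  Per-mature expected read counts are lognormal:
  median `reads_per_mirna_scale` = 100 reads, σ = 1.0 in log10 units —
  miRNA abundance spans several orders of magnitude in real libraries.
  Each read's 5′ and 3′ offsets are drawn independently from
  `end_jitter_probs` (default: 55% exact ends, decaying to ±6 nt; the
  support deliberately exceeds the ±4 counting window so window exclusion
  is exercised).  Two libraries ("control", "treatment") share the same
  expected abundances — miRISC inhibition leaves miRNA levels unchanged —
  and differ only in Poisson/jitter noise, which the abundance-scatter
  comparison should show as a near-perfect correlation.  Reads are emitted
  only on the precursor sense strand, matching both miRNA biogenesis and
  the quantifier's strand rule.
* **Targets.**  Each family predicts `targets_per_family` = 400 genes out
  of `n_genes` = 12 000 — TargetScan-scale conserved target sets over an
  expressed-transcriptome-scale universe.  By default sets are drawn
  independently, so genes can be targeted by several families (TargetScan
  semantics); a "disjoint" mode tiles families over distinct genes for
  calibration designs.
* **Effects.**  True per-family de-repression is linear in log abundance:
  δ_f = δ_max · a_f / max_g(a_g), with a_f the log10 family-summed
  within-window read count of the control library and δ_max
  (`max_effect_log2`) = 0.5.  This is the minimal generative model
  reproducing the observed monotone abundance–effect trend; the
  proportionality is a modelling choice, not an estimated law.  A gene
  targeted by several families takes the **maximum** δ over them (not the
  sum) — compound additive effects would be unbounded and are not what a
  single-release mechanism predicts.
* **Counts.**  Gene counts are negative-binomial with
  mean = baseline · 2^(δ_gene · 1[treatment]) and a single shared
  dispersion 0.1 (variance = µ + 0.1 µ²), a standard bulk-RNA-seq noise
  level; baselines are log-uniform over 10^0.5–10^3.5.  Three samples per
  condition.  Means are capped at 10^9 to stay overflow-safe.

Everything is driven by one `numpy.random.Generator` seeded from
`rng_seed`; identical config + seed gives byte-identical output files, and
the pipeline manifest records seed, config and input digests.

What the simulator does **not** model: sequencing error, adapters and
ligation biases, multi-mapping between paralogous precursors, GC/length
biases, batch or sample-level covariance, gene–gene correlation, partial
repression heterogeneity across targets (site type, context).  Passing
tests therefore demonstrate that the statistics behave correctly under the
assumed generative model — clean NB counts with set-level mean shifts —
not that they are robust to every artefact of real libraries; for real
data the DESeq2-ingestion path is preferred precisely because that stage
handles what the stand-in does not.

## Reference experiments

* **Null calibration** (`experiments.null_calibration`): 200 families ×
  100 targets tiled disjointly plus 2 000 never-targeted genes
  (n = 22 000), δ_max = 0.  Baselines are drawn from 10^2.5–10^3.5 so the
  expression filter keeps every family at its nominal m = 100 — the design
  calibrates the statistic at a fixed set size, not the filter.  Checks:
  per-seed family-z mean within ±0.1, SD within [0.9, 1.1], Kolmogorov
  distance to N(0,1) below 0.1, over seeds 0–4.
* **Signal recovery** (`experiments.signal_recovery`): the default study
  configuration with δ_max = 0.5.  Family abundance is re-derived through
  the end-window quantifier from the simulated alignments (not read off
  the ground truth).  Checks: Spearman ρ(true δ_f, z) ≥ 0.8, every family
  in the top abundance quartile has z > 0, and sign(z) agrees with the CDF
  shift direction for ≥ 99% of families with |z| > 2.

Problem sizes keep both experiments in the low seconds per seed.

## Numerical choices and degenerate inputs

* z is computed exactly as (Sm − µ)·√m/∂ — the test suite asserts the
  identity at machine precision for every reported family.
* KS: exact method when min(n) ≤ 25, asymptotic otherwise (scipy's
  finite-sample-corrected asymptotic; the classical Kolmogorov series
  agrees to ~15% at n = 500, which is the tolerance the oracle test uses).
* Empirical CDFs are right-continuous step functions evaluated as
  rank/n at the sorted sample points.
* Errors, not guesses: missing `Derives_from`, unresolvable precursors,
  duplicate mature IDs, counted matures without a family, zero-total
  libraries, no all-nonzero reference gene, empty or degenerate
  backgrounds all raise immediately with the offending identifiers; CLI
  maps them to exit code 1 (internal errors: 2).
* Families falling below m_min or lacking a defined abundance are carried
  through the output table with a status code rather than dropped, so row
  counts always reconcile across stages.

## Known limitations

* The ±4 rule is read as a conjunction over both ends and multi-mapped
  reads are counted once (primary alignment only); both are configurable
  readings of an underdetermined convention, surfaced as options
  (`window`, and the per-record predicate `match_read`).
* The median-of-ratios stand-in assumes most genes are not differentially
  expressed; under strong asymmetric global shifts (exactly the miRISC
  regime at large δ) it absorbs part of the shift into size factors and
  compresses fold changes — another reason external DESeq2 input is the
  preferred path for real data.
* The z statistic treats target genes as exchangeable draws; correlated
  targets (co-regulated complexes) would inflate |z| beyond the nominal
  null.
* Scored families share the background, so family z-scores are mildly
  positively correlated; cross-family inference should use the provided
  BH-adjusted KS p-values, not the z values, and even those share data.
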