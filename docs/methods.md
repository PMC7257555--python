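# Methods

## Locus discovery

A microsatellite locus is a maximal tract of tandem copies of a primitive
1–5 bp unit whose whole-copy length is 10–100 bp.  The scanner works per
unit size *k*: positions where the sequence agrees with itself at lag *k*
are collected into maximal runs; a run of *r* agreements starting at *i*
is a periodic stretch of length *r + k*, reported as ⌊(*r + k*)/*k*⌋
whole unit copies anchored at *i*.  Canonicalization rules:

* the unit must be primitive ("AA" runs are reported once, as "A");
* among rotations ("AC" vs "CA") the tract is anchored at the leftmost
  position where the periodicity starts, with the unit as it appears
  there — two tracts of length ≥ 10 cannot otherwise collide, since unit
  sizes ≤ 5 and the periodicity lemma for strings would force a shorter
  common period;
* `N` never matches anything, so tracts break at undefined bases;
* soft-masked (lowercase) sequence is scanned as ordinary sequence;
* a tract longer than the maximum is excluded entirely, not clipped —
  the bounds are properties of reported loci, not a window.

Panel restriction requires *containment* in a target interval, not mere
overlap, because profiling needs reads that span the whole tract.
Downstream analysis uses mononucleotide loci only; the catalog itself
retains all unit sizes.

## Profiling

A read contributes to a locus iff it spans the tract plus ≥ `anchor`
(default 3) flank bases on each side, and both flank anchors align
gap-free and match the reference.  The observed repeat count is the
number of complete unit copies between the anchors, counted by exact
head-anchored matching; a mismatch inside the tract truncates the count
(a flag excludes such reads entirely instead).  Overlapping paired-end
mates are counted independently — fragment-level deduplication is left to
upstream tools.

Read filter: drop iff length < 35 bp or mean Phred over the whole read
< 25.  Locus filter: fail iff either sample has coverage < 30× or mean
Phred over contributing tract bases < 30.  All failure conditions are
strict less-than, so the printed thresholds themselves pass.  The
averaging windows (whole read / tract bases) follow peer MSI callers.

The minimum-support rule ("repeat type … < 3") admits two readings and we
implement both, switchable: the default prunes repeat-count alleles with
fewer than 3 supporting reads before scoring; the alternative fails loci
showing fewer than 3 distinct repeat lengths.  The alternative is not the
default because it discards perfectly stable loci and would make MSS
undetectable.

## Scoring and classification

Per-locus instability is the L1 distance between proportion-normalized
tumor and normal repeat-count histograms, in [0, 2].  Normalization makes
the score invariant to coverage, which raw-count L1 is not.  The sample
score is the unweighted mean over QC-passing loci only (failed loci leave
both numerator and denominator).  A sample with fewer than
`min_passing_loci` (default 5, a majority of a 9-locus panel) passing
loci is *uncallable* — a distinct verdict, not MSS.  Classification is
MSI-H iff score ≥ cutoff; the cutoff defaults to 0.4 and the boundary
counts as MSI-H (configurable; scores exactly at the boundary are not
observed in practice).

## Marker training

Per locus, mean scores are computed separately over MSI-H and MSS
samples, ignoring missing (QC-failed) entries.  A locus must be evaluable
in ≥ 90% of each class to be rankable, so sparsely covered loci cannot
enter the panel on a few lucky observations.  Markers are the
intersection of the top-k loci by descending MSI-H mean with the bottom-k
by ascending MSS mean (k = 50).  Ties break by genomic coordinate
(contig, start) under a stable sort, making selection deterministic and
input-order invariant.  The model file records k, cutoff, QC thresholds,
evaluability threshold, class sizes, seed and a fingerprint of the
training matrix, so classification runs are auditable.

## Cohort statistics

The Fisher exact test is the two-sided Freeman–Halton rule for r×c
tables: all margin-preserving tables are enumerated (log-gamma
arithmetic) and the p-value sums the probabilities of tables no more
probable than the observed one, with a 1e-7 relative tolerance so
floating-point noise cannot split symmetric ties.  This is the convention
of mainstream statistical software and reproduces published
clinical-table p-values; enumeration is restricted to totals ≤ 500
(clinical tables here are ≤ 64).  Rows with missing category information
are removed before testing, never imputed.  The Mann–Whitney U test uses
the exact null when the smaller sample has ≤ 8 tie-free observations,
otherwise the tie- and continuity-corrected normal approximation.  The
MSI-PCR rule calls MSI-H at ≥ 2 unstable loci of 6.

## Simulator

The generator emulates targeted sequencing of paired tumor/normal
specimens at microsatellite loci:

* **Reference.**  One contig embeds homopolymer tracts at exact, recorded
  coordinates, separated by flanks (default 250 bp, longer than a read)
  generated under constraints that forbid repeat-forming periodicity; the
  assembled contig is re-scanned and must reproduce the truth catalog
  exactly, otherwise it is rebuilt.  Seeds change flank sequence, never
  locus geometry.
* **Stutter.**  Per read: with probability *s* the observed count
  deviates from the template; |deviation| is truncated-geometric
  (decay 0.3, max 5) and deviations contract with probability 0.8,
  matching the deletion-dominant slippage of mononucleotide tracts.
  *s* grows linearly with tract length (0.02 per base around 0.10 at
  13 bp, clamped to [0.01, 0.60], with an explicit 0 kept at 0) —
  slippage increases with homopolymer length, and this heterogeneity is
  what makes a bottom-k "quiet in MSS" ranking meaningful at all.
* **Somatic signal.**  At unstable loci, a read's template is the shifted
  allele (default −3 units, clonal) with probability purity ×
  somatic_fraction, otherwise germline.  The tumor profile is therefore
  the mixture (1−π)·normal + π·somatic, which bounds the per-locus L1
  score by 2π at effective purity π — a structural property of any
  mixture model that the dilution tests make visible.
* **Reads.**  Emitted pre-aligned (CIGAR with the tract indel), base
  qualities ~ Normal(35, 3) clipped to [2, 40] so default QC passes;
  degraded-quality runs are a matter of passing a different quality mean.
  Reads are single-end records; the read filters apply per record.
* **Dilution.**  Per locus, each of the output reads is drawn from the
  tumor pool with the given fraction, else from the matched normal pool;
  effective purity = fraction × original purity is recorded.
* **Cohorts.**  Default 7 MSI-H / 21 MSS paired samples over 363 loci
  with 9 informative (somatically shifting) loci.  MSI-H purities are
  drawn uniformly from 0.25–0.65, the clinically typical range for
  resected colorectal specimens; MSS tumors carry no shifts.  Informative
  loci are modelled as the shortest (10 bp) tracts, i.e. the
  lowest-stutter stratum, with background tracts cycling 11–24 bp: marker
  loci are, by construction of the selection procedure, loci that are
  both responsive in MSI-H and unusually stable in MSS, and a generator
  with i.i.d. locus noise would have no such stratum to find.  Cohorts
  are sampled at distribution level by default — per-locus histograms
  drawn from the same generative law as the reads, which profiling
  error-free reads would recover exactly — keeping cohort-scale runs in
  seconds; `read_level=True` routes every sample through read simulation
  and the profiler.  One seed fixes reference geometry; an optional
  second seed varies sample draws over the same catalog, which is how an
  independent validation cohort for a trained model is produced.

### What the simulator does not model

Sequencing substitution errors, platform-specific error profiles, FFPE
artifacts, alignment ambiguity (reads are placed by construction),
fragment duplicates, subclonal somatic fractions per locus, and germline
polymorphism at microsatellites (germline equals the reference allele).
Passing tests therefore demonstrate correctness of the method's
bookkeeping and the identifiability of its selection procedure under
clean, well-covered data — not robustness to real-world artifacts.

Because the simulated tumor is an exact mixture, the sample score of an
MSI-H specimen scales like ~2 × effective purity (slightly less, as
stutter overlaps the shifted allele): the simulated dilution series
crosses the 0.4 cutoff near 20% effective purity.  Published dilution
assays on real specimens report scores above this mixture bound, i.e.
pathology-estimated tumor content understates the somatic DNA fraction in
those specimens; the simulator asserts only the monotone decline of the
score under dilution, not the published crossing point.

## Numerical and degenerate-input choices

* Zero-coverage distributions are an error at scoring time; they must be
  QC-failed upstream.
* Pruning all alleles from a distribution fails the locus rather than
  producing an empty "pass".
* NaN tract quality (no contributing reads) fails the locus-quality
  comparison and the locus.
* Fisher enumeration compares log-probabilities with a log1p(1e-7)
  threshold; the 2×2 case agrees with the hypergeometric closed form to
  1e-9.
* Catalog scanning is order-invariant across contigs; output is sorted by
  (contig, start).

## Problem sizes used in the test and acceptance runs

Training cohorts are 28 samples × 363 loci at 100× coverage; validation
cohorts 36 samples; marker-recovery checks run 20 seeded replicates;
scanner oracle-equivalence runs on ~12 kb of salted random sequence plus
property-based short sequences; dilution series use 9 marker-like loci at
200× with 3 replicate mixtures per fraction.  These sizes were chosen to
exercise every code path at the study's own cohort geometry while keeping
a full run of the suite on one CPU in the low minutes.
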