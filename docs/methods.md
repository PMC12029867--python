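# Methods

## The analysis model

`microsnv` treats a probiotic intervention study as a
2-group (treatment / control) × 2-segment (small / large intestine) ×
3-day (1, 3, 7) × n-replicate design.  For each sample, alignment evidence
against one reference genome per species is reduced to a *pileup*: per-site
A/C/G/T read counts.  The analysis makes three inferential moves.

**Consensus-threshold calling.**  A site is an SNV when
`depth ≥ min_coverage` and the most frequent non-reference base accounts for
at least `min_freq` of the depth.  Defaults are `min_coverage = 100` and
`min_freq = 0.49`; with a threshold just below one half this is
consensus-style calling — the resident strain's consensus allele differs from
the reference — rather than low-frequency-variant detection.  Both
inequalities are inclusive (a site at exactly 100 reads or exactly 0.49
alternate fraction is called); the boundary is pinned by the near-threshold
synthetic preset, which plants variants at frequency 0.49 (called) and 0.45
(not called).  The reference base always comes from the reference sequence,
never the pileup majority, since a divergent majority is precisely the signal.
The alternate allele is the top non-reference base, ties broken A < C < G < T;
only that single top allele is reported per site.

**Codon annotation.**  Variants are classified *coding* when inside a CDS,
*noncoding-genic* when only inside a structural-RNA gene, else *intergenic*.
A variant under overlapping CDSs is reported once per gene context rather
than silently resolved.  For coding variants, the codon index is
`offset-within-CDS // 3` on the coding strand (reverse complement for minus
strand genes, with the alternate base complemented onto the coding strand;
reported ref/alt bases stay in reference orientation).  Both codons are
translated with the bacterial genetic code (NCBI table 11, identical to the
standard code for every sense codon); synonymous iff the amino acids match,
and a created stop is nonsynonymous with amino acid `*`.  The classifier is
checked exhaustively against an independent whole-protein translation diff
over all 900 single-base substitutions of random 300-bp CDSs on both strands.

**Two-stage negative-control filtering.**  Variant identity is
(species, contig, position, alternate base) — two alternate alleles at one
position are distinct variants, and allele frequency plays no role in
identity.  Per-sample call sets are first aggregated per
(group, segment, day, species) cell; the default aggregation is *union*
(present in any replicate), the only mode that cannot miss a
control-observed artifact.  *Majority* and *intersection* are available
because replicate handling in pooled designs is genuinely ambiguous.
Stage 1 removes every variant seen in the control group of the same segment,
pooled over all days — such variants reflect the chosen reference strain
differing from the resident strain, not mutation.  Stage 2 removes surviving
variants also present in the day-matched control cell — variation that arose
over time in both arms.  Both stages are set subtractions against fixed
sets, so their order cannot change the retained set; it only changes stage
attribution, which is fixed artifact-first.  Note a consequence of the
all-days stage-1 scope: temporal variants present in controls on other days
are already caught at stage 1, so stage 2 counts are often zero under the
default scope (a `day_matched` stage-1 scope is available).  The report
enforces the conservation identity
`n_input = n_removed_artifact + n_removed_natural + n_retained` per cell and
treats a violation as an internal bug.

**Correlation screen.**  Species tracking the focal probiotic are found by
Spearman correlation against the focal taxon's relative abundance.  The
samples entering the correlation default to all treatment-group samples of
one segment, days pooled (n = 18 under the emulated design) — the pooling is
a documented choice, configurable, since the design does not force it.  A
species passes with p < 0.05 **and** |ρ| > 0.5, both strict, no
multiple-testing correction by default (Benjamini–Hochberg by flag).  ρ is
the Pearson correlation of midranks (tie-aware); the two-sided p-value is
exact by full permutation enumeration for n ≤ 8 and a t approximation with
n − 2 df otherwise.  A constant candidate has undefined ρ and is excluded,
logged, rather than failing.

## Community statistics

Shannon diversity is −Σ p ln p in nats; Simpson is the Gini–Simpson form
1 − Σ p² by default (the convention of the vegan family), with the dominance
form Σ p² by flag.  Group comparisons gate on Shapiro–Wilk normality and
Levene homogeneity at α = 0.05: ANOVA + Tukey HSD when both pass, otherwise
Kruskal–Wallis (tie-corrected H, χ² approximation; all-identical data
degenerates to H = 0, p = 1) with Dunn pairwise z tests.  Bray–Curtis
dissimilarity feeds classical-scaling PCoA; because Bray–Curtis is
non-Euclidean, negative eigenvalues can appear and are excluded from the
axis-proportion denominator (logged; no Cailliez correction by default).
Group separation in distance space is tested by PERMANOVA with the pseudo-F
from the among/within partition of squared distances and
p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm), 999 permutations by default,
fully seed-controlled.

## The synthetic study generator

The generator is first-class, tested code: it defines the conditions under
which every guarantee above is verified.  It emulates:

* i.i.d.-uniform 50 kb genomes (5 species by default) with 40 non-overlapping
  CDS genes of 180–450 bp on mixed strands plus one tRNA gene;
* per-site depth ~ Poisson(150), matching a deeply covered metagenome
  relative to the c = 100 gate;
* planted variants of three provenance classes with a 2:1
  transition:transversion bias — *induced* (treatment-only, one segment, from
  a start day onward), *artifact* (all samples of a segment, both groups, all
  days), *natural* (both groups of a segment on one designated day) — 12/6/6
  per species by default;
* planted alternate-allele frequency 0.6, comfortably above the 0.49 gate;
* an abundance table over the full 72-sample design in which the focal
  probiotic appears only in treatment samples at 1 % on day 1, halving per
  elapsed day (transient carriage after a single dose), with a deterministic
  ±10 % replicate spread so its ranks are well defined even at zero noise;
  positive-design species exactly proportional to the focal taxon (so their
  rank correlation survives compositional closure exactly), a
  negative-design species decreasing affinely in it, and background species
  as independent lognormal noise (σ = 0.35) around large baselines, which
  keeps closure-induced spurious correlation well inside the screen's null
  budget.

**Allele counts at planted sites are deterministic by default**:
`alt = ceil(depth × freq)`, so the planted frequency is guaranteed at every
site.  This is a deliberate design choice: it makes threshold semantics
exactly testable (the near-threshold preset is meaningless under sampling
noise) and makes the headline exactness guarantees — perfect caller
recall/precision and filter exactness on clean data — properties of the
generator-caller pair rather than high-probability events.  A `binomial`
mode (alt ~ Binomial(depth, freq)) is available and tested for realistic
sampling noise.  Even in deterministic mode one stochastic escape remains:
Poisson depth can dip below the coverage gate (P ≈ 6 × 10⁻⁶ per site at mean
150), so per-sample recall is a measured quantity reported by the acceptance
script, while group-level recovery (union over 6 replicates) is robust.

The generator does **not** emulate read-level error profiles, indels, strand
bias, mapping or alignment artifacts, chimeras, or uneven coverage along the
genome.  Passing tests therefore demonstrate the correctness of the calling,
classification, filtering and screening *logic* under its stated thresholds —
not robustness to upstream alignment pathology, which is out of scope by
design (pileups, not reads, are the canonical input).

Determinism: every random draw flows from `numpy` `SeedSequence` substreams
keyed by (seed, purpose, species, sample), so pileups can be materialized
lazily, in any order, with byte-identical results; the end-to-end pipeline
writes byte-identical TSVs under a fixed seed.

## Numerical and interface choices

* Coordinates are 1-based inclusive at every interface, matching GFF3;
  upstream pileup tools differ, so this is stated prominently.
* All TSVs are UTF-8, tab-delimited, `.` for missing; allele frequencies
  print at 6 decimals and every writer round-trips bit-identically through
  its paired reader at that precision.  Readers reject rather than repair
  (ambiguity codes in FASTA are rejected by default, maskable to `N`;
  masked sites are never callable).
* Abundance tables are renormalized to column sum 1 on load (tolerating
  percent-scaled input, logged); all-zero samples are errors.
* A CDS whose length is not divisible by 3 is excluded from annotation with
  a logged warning rather than mis-framed.
* The SNV-count-vs-abundance relationship is fitted by ordinary least
  squares with a two-sided t test on the slope — the simplest model
  consistent with asking whether mutation counts track abundance — with a
  pointwise 95 % confidence band; pairing is per sample (each treatment
  sample contributes its species abundance and its retained-call count).
* PCoA axis proportions match eigenvalue ratios to 1e−10; eigenvalues below
  a relative 1e−10 tolerance are treated as zero.
* `group_compare(pairwise=False)` skips post hoc tests for calibration
  loops; the omnibus p is unchanged.

## Scaling of the verification suite

The exactness checks run on the full study scale (5 species × 50 kb × 36
samples, ~9 M simulated sites, seconds with vectorized calling).  The
calibration suites use 2,000 replicate simulations for the screen's null
pass rate and the type-I error of the group test and PERMANOVA (99
permutations per run, so the p-value lattice makes the nominal 5 % level
exactly attainable), and 1,000 for the regression slope test; these sizes
put the binomial standard error of an estimated 5 % rate near 0.5 %, well
inside the ±2 % acceptance band.  The codon oracle is exhaustive per CDS
(900 substitutions) over 20 random CDSs.

## Known limitations

* The filter is purely set-theoretic, as the procedure it implements
  specifies; it performs no frequency-based differential testing, so a
  variant present in both arms at very different frequencies is removed.
* Only the single top alternate allele per site is reported; true
  multi-allelic sites lose their minor alternates.
* With the default all-days stage-1 scope, the "natural variation" stage is
  largely subsumed by the negative control (see above); per-stage counts are
  scope-dependent even though the retained set is not.
* The t-approximate Spearman p is anti-conservative for very small n; exact
  enumeration covers n ≤ 8, and the screen's operating characteristics are
  verified by simulation at the design's n = 18.
* Whether real pileups were produced per animal or per pooled group changes
  what replicate aggregation means; the mode is exposed rather than assumed.
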