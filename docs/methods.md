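# Methods

This note records the models, parameter choices and numerical conventions
behind `tagarray`, and what the synthetic-data tests do and do not
establish.

## Genotype model and LD

Genotypes are unphased diploid ALT-allele dosages in {0, 1, 2} with an
explicit missing state. LD is the squared Pearson correlation of dosage
columns (composite LD), computed over pairwise-complete samples with a
minimum overlap of 4 lines. This matches what standard tooling reports for
unphased data and requires no phasing step. Pairs that are monomorphic
over their shared samples are omitted from the LD table rather than
assigned r² = 0: an undefined correlation is not evidence of linkage
equilibrium, and writing 0 would spuriously break tag sets.

The LD window is 2 Mb of total tag-set span, i.e. a maximum pair distance
of 1 Mb from the focal SNP. Coordinates are 1-based with inclusive bounds
throughout. Singletons — SNPs with no partner at r² ≥ 0.9 within 1 Mb up-
or downstream — can only be tagged directly and are removed from tagging
candidacy before selection; the 1 Mb radius is deliberately fixed
independently of the configured LD window (a config override exists).

## Filters

Panel QC keeps SNPs with MAF *strictly* above 1% (5% for barley-style
panels with smaller reference populations) and call rate strictly above
60%; the probe design score uses an inclusive ≥ 0.6. The asymmetry is
intentional and matches how the thresholds are conventionally stated. The
"maximum 40% missing" and "minimum 60% call rate" formulations are treated
as the same filter.

Probe filtering excludes A/T and C/G variants (two-probe Infinium Type I
chemistry), probes with known polymorphism under the 50-mer, probes
aligning to the other species' genome (the array supports dual
wheat+barley hybridization, so cross-species specificity is required), and
probes without a unique target-genome alignment. The relaxed tier used by
the rescue pass allows up to three target-genome alignments; everything
else is unchanged, so a strict pass always implies a relaxed pass.

## Greedy selection

Tag sets are ordered by decreasing member count, with ties broken by the
focal SNP's (chromosome, position, snp_id) — selection is therefore
byte-deterministic. Because removal always discards whole sets (any set
intersecting the committed set), set sizes never change during the sweep,
so a single pass with a monotone pointer over the pre-sorted sequence is
exactly equivalent to re-sorting after every iteration; the test suite
checks this equivalence against a naive re-sorting trace on random
instances.

Choices the underlying procedure leaves open, fixed here:

- Set sizes count the focal SNP. This affects the m = 10 loop guard and
  the redundancy tiers (≥ 50 → 3 tags, ≥ 20 → 2, ≥ 10 → 1).
- Redundant tags are the member SNPs passing strict filters with the
  highest r² to the focal SNP, ties by position. Redundancy applies only
  to the strict pass; the relaxed rescue selects focal SNPs only, since
  sets reachable only through relaxed filters rarely have multiple
  designable members and redundancy there would spend assays on the
  weakest content.
- Gap-fill considers remaining sets with 2–(m−1) members spanning at least
  500 kb (1 Mb for barley) and commits them in decreasing span × size
  order; the ranking is this package's construction, as only the
  sparsity/span criterion itself is conventionally stated.
- Coverage-fill scans 10 Mb non-overlapping windows and adds the
  highest-MAF designable SNP to windows with content but no selection.
  The 10 Mb default is this package's choice; no standard value exists.
- The F_st "top 2%" is computed over SNPs with a defined Weir–Cockerham θ,
  with ties at the cutoff included.

## F_st

Between-group differentiation uses the two-population Weir–Cockerham
(1984) θ from genotype counts: variance components a (between
populations), b (between individuals within populations) and c (within
individuals), with observed heterozygosity entering b and c. θ is NaN when
either group has fewer than two called samples at the SNP. θ = 1 for fixed
differences and can be slightly negative for undifferentiated SNPs; the
estimator is checked against an independent scalar transcription of the
published formulas to 1e-10.

## Imputation model

Production imputation (phased-reference HMMs) is out of scope. The
evaluation imputer is a per-SNP conditional model: each target SNP is
predicted from the single selected SNP with the highest r² to it, via the
map tag-dosage → modal target dosage estimated from the reference lines.
A tag dosage never observed in the reference is filled from the rounded
linear regression of target on tag over the reference; only when that fit
is undefined (constant tag) does the target's marginal mode apply. The
linear extrapolation matters: under perfect LD the tag–target relation is
exactly linear (identity or allele flip), and a masked line that is the
sole carrier of a rare homozygote would otherwise be mis-imputed by a
marginal mode even though the LD structure determines its genotype — which
would break the perfect-recovery property the evaluation relies on.

Cross-validation masks `n_mask` lines per repetition (drawn without
replacement within a repetition, with replacement across repetitions),
fits on the remainder, and scores four metrics per masked line:
concordance and squared Pearson correlation, each including and excluding
heterozygous calls (a position is dropped when either call is
heterozygous). Per-line values are averaged over the repetitions in which
the line was drawn, and the report gives the across-line mean and SD per
target threshold. Per-line correlation is computed genome-wide, not per
chromosome.

This imputer understates what an HMM achieves on real panels with decayed
LD (it uses one tag, not a haplotype context), and overstates nothing: on
block-structured panels its accuracy is driven by the same r² that drives
HMM accuracy, which is what makes the threshold-ordering comparison
(accuracy at q′ = 0.9 ≥ 0.7 ≥ 0.5) meaningful.

## Synthetic panels

The simulator generates independent haplotype blocks, each a set of
founder haplotypes in perfect internal LD; samples draw two founders per
block with frequencies from a symmetric Dirichlet whose concentration is
the `maf_spectrum` parameter (0.5 by default; values < 1 give the U-shaped
folded MAF spectrum typical of diverse resequencing panels). Defaults —
200 samples, 5 chromosomes × 10 blocks, 5–40 SNPs per block, 2 founders
per block, blocks spanning 50–400 kb, 5% missing data — describe a small
diversity panel with strong block structure. Heterozygote errors flip a
random homozygote to dosage 1, emulating the error mode suspected in
exome-capture heterozygous calls. Probe annotations are drawn
independently of genotypes with per-filter failure rates (8% Type I, 15%
low score, 10% multi-hit, 5% other-genome hit, 5% underlying
polymorphism) — plausible magnitudes chosen once; correlated failure
modes are not modelled.

What a green test on these panels establishes: the selection algorithm's
combinatorial contracts (cover, disjointness, determinism), the metric
definitions, and exact recovery when LD is truly perfect. What it does not
establish: imputation accuracy under LD decay within blocks,
ascertainment effects of real probe-failure correlations, or performance
at the scale of millions of SNPs — the pipeline is O(SNPs × window
density) and has only been exercised at desk scale.

## Numerical conventions

- MAF is min(p, 1−p) over called alleles; heterozygotes contribute one of
  each allele.
- Multi-allelic and non-diploid VCF records are skipped (and counted),
  not split.
- r² values are clipped to [0, 1] against floating-point overshoot.
- All stochastic steps take explicit integer seeds; identical inputs and
  seeds give byte-identical outputs, which the tests assert.
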