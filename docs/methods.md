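# Methods

## Scope and model overview

`gsikit` implements the analysis layer of a GT-seq genetic stock
identification workflow: marker selection from an FST landscape,
microhaplotype genotype calling, Pella–Masuda conditional mixture inference,
leave-one-out accuracy assessment, and seasonal movement tests. Sequencing,
alignment and variant calling are explicitly out of scope; the package
consumes tables (read counts, genotypes, FST values) and a synthetic-data
module that generates all of them with known ground truth.

## Synthetic data

**Divergence model.** Population allele frequencies follow the
Balding–Nichols model: at a locus with ancestral frequency vector q, a
population at divergence F carries a Dirichlet(q · (1−F)/F) draw. This gives
closed-form moments (Var(p) = F·q(1−q) per allele) used as independent
oracles in the tests. F = 0 returns q verbatim; F = 1 is rejected. Very
small concentrations ((1−F)/F · q < ~1e−3) underflow ordinary gamma
sampling to exactly zero, so Dirichlet draws go through log-space gamma
sampling (the G(a) = G(a+1)·U^{1/a} identity); this matters for the
near-fixation regime (F → 1) only.

**Default panel geometry.** `default_population_model` emulates a
microhaplotype amplicon panel: 2–8 alleles per locus (mean ≈ 3.5, matching
the multi-allelism of real GT-seq microhaplotype panels), geometric-decay
ancestral frequencies with multiplicative jitter, allele names as distinct
nucleotide 3-mers (so tables export as valid multi-allelic VCF), and loci
spread round-robin over 23 chromosomes — the Pacific cod karyotype, and the
chromosome count the selection arithmetic (6 windows × 2 loci × 23 = 276)
refers to.

**Read counts.** Per individual-locus cell, total depth is negative-binomial
with mean m and dispersion k (variance m + m²/k; k → ∞ recovers Poisson;
default k = 5, reflecting the overdispersion typical of multiplexed
amplicon sequencing). Reads split Binomial(depth, 1/2) between the two true
haplotypes; each read is mis-assigned with probability `error_rate` to a
uniformly chosen other haplotype of the locus. Haplotype counts always sum
to the drawn depth.

**FST landscapes.** `simulate_fst_landscape` draws background per-pair FST
from a Beta(0.5, 8) scaled below the selection floor, then plants
high-FST loci per configuration: `saturated` guarantees every window on
every chromosome at least two loci above the floor with distinct argmax
pairs (so windowed selection attains its maximum), `all_below_floor` yields
an empty selection, `random` plants hot loci independently. Positions are
stratified across windows so no window is empty by accident.

**What the generator does not emulate.** Linkage between loci (loci are
independent given the population), genotyping error correlated across
individuals (e.g. allele-specific amplification bias), null alleles, locus
dropout correlated with depth, and within-unit substructure. Passing tests
therefore demonstrate correctness of the algorithms under the stated model,
not robustness of GSI to those real-data pathologies.

## Population-genetic statistics

**FST.** Weir & Cockerham's (1984) θ from called genotypes; multi-allelic
loci sum the per-allele variance components a, b, c before taking the
ratio. Negative estimates are retained for ranking (clamping would distort
order near zero) and only clamped in reports. The multi-locus estimator is
the ratio of averages Σa / Σ(a+b+c), which recovers the parametric
Balding–Nichols divergence to within 0.002 at n = 100 per population and
500 loci (the per-locus ratio average is biased low by ~10–15 % and is not
used for calibration claims). Loci monomorphic across both collections, or
with fewer than two genotyped individuals in either, are flagged NaN, never
zero-filled.

**Hardy–Weinberg tests.** Biallelic loci use the exact conditional
(Levene/Haldane) test by full enumeration of heterozygote counts given the
allele counts; multi-allelic loci use a Monte-Carlo exact test that
randomly re-pairs the observed allele pool (default 10,000 permutations,
add-one p). A subtlety worth stating: the exact conditional p-value is
discrete and *super-uniform* (P(p ≤ α) ≤ α), so its null distribution is
deliberately conservative; the test suite checks validity (no excess of
small p-values; type-I rate ≈ 4.5 % at α = 0.05, n = 100) rather than
literal uniformity, which no valid exact test can satisfy.

**Linkage screen.** Same-chromosome locus pairs are screened with the
squared Pearson correlation of allele dosages (dosage of each locus's most
frequent allele; multi-allelic loci thereby reduce to a one-dimensional
dosage) against a permutation null (999 shuffles, add-one p). This is a
deliberate substitution for the index of association used in the original
workflow: the decision function — flag linked pairs at a chosen α — is
preserved, and the permutation null makes the type-I rate exact by
construction (measured 5 % ± 2 % on independent loci).

## Panel selection

Steps: (1) top-N (default 10) loci by FST per chromosome per pair; (2)
unique loci; (3) drop loci whose **maximum** FST over pairs is below the
floor (default 0.2) — the max is what counts, because a locus selected by
one informative comparison should not be disqualified by the many
uninformative ones; (4) split each chromosome into equal *physical* windows
(default 6; lengths supplied or carried by the landscape), score each locus
by its max pairwise FST, attribute it to the argmax pair (ties to the
lexicographically first pair id), and accept loci in descending score order
(ties by position, then id), skipping full windows and — with the
one-pair-per-chromosome constraint on — loci whose attributed pair is
already consumed on that chromosome.

Open choices resolved here: windows are physical intervals, not equal-SNP
bins ("equal windows" read physically; configurable); the greedy order runs
over the whole chromosome jointly rather than window by window, since no
resolution order is canonical — the greedy result is deterministic and, on
single-window instances, provably the max-score feasible pick (verified by
enumeration in the tests; with multiple windows a cleverer pair assignment
can occasionally beat greedy, which is accepted as the documented rule).
Supplemental loci (e.g. known outlier regions) are injected by explicit
list; duplicates are skipped with a warning. The attrition report is pure
bookkeeping over externally supplied stage counts (primer design and
multiplex optimisation happen in the lab, not here).

## Microhaplotype calling

Per cell: total depth < 20 ⇒ missing; haplotypes below 0.2 of the deepest
haplotype's depth are dropped; two or more survivors ⇒ heterozygous for the
two deepest (second-place depth ties broken lexicographically and flagged);
exactly one ⇒ homozygous. The 20-read minimum is interpreted as total cell
depth (the microhaplot convention) — a per-haplotype minimum would make the
0.2 ratio rule nearly vacuous. Cells with more than two surviving
haplotypes keep the top two and carry a quality flag (possible
contamination or paralogy).

Missingness filtering is two-pass in fixed order: individuals against the
full panel (strict > 0.75), then loci against the remaining individuals
(strict > 0.75). The order matters and is preserved exactly; note the
procedure is not strictly idempotent in adversarial corner cases (dropping
loci shrinks individual call-rate denominators, so an individual can sit at
exactly the boundary on a second pass) — under realistic missingness it is
idempotent and tested as such.

The HWE filter drops a locus when it is out of equilibrium (p < 0.05) in at
least ⌊n_collections/2⌋+1 collections (with 15 reference collections that
threshold is 8); collections with fewer than 5 genotyped individuals at the
locus are excluded from the count rather than counted as non-significant,
since an exact test on 3 fish is uninformative either way.

## Mixture model and diagnostics

The conditional Pella–Masuda model: baseline allele frequencies are fixed
at their Dirichlet-posterior means (pseudo-count 1/A_l per allele, i.e. one
prior observation per locus; configurable), and the Gibbs sampler
alternates latent origins and mixing proportions (π prior Dirichlet(1/C)).
Defaults: 2000 sweeps, 100 burn-in. The fully Bayesian baseline-resampling
variant is out of scope. Sweep-averaged per-individual origin posteriors
use the Rao-Blackwellised conditional P(z_i | π_t) rather than the sampled
indicators. Mixture alleles unseen in the baseline extend the locus's
allele universe (they receive prior mass only); mixture loci absent from
the baseline are uninformative and contribute a factor 1, as do missing
genotypes.

The z-score references posterior-mean frequencies *including* the focal
individual (it is a diagnostic for baseline membership, not an assignment
statistic): per locus the exact mean and variance of log P(G) under HWE
draws are accumulated over the individual's called loci. With a finite
baseline the empirical z of true members is shifted negative by roughly the
summed KL divergence between true and estimated frequencies over σ — at 200
multi-allelic loci this is visible below ~300 reference fish per
collection, which is worth knowing before reading small negative z means as
model misfit. Individuals with zero informative-locus variance get NaN and
are excluded by the confidence filter with an explicit reason.

Confidence filtering retains individuals with max reporting-unit posterior
strictly above 0.9 and z strictly inside (−5, 5).

**Leave-one-out assessment** draws unit proportions from Dirichlet(1.5)
(the conventional simulated-mixture prior; an equal-proportions mode is
also reported since published per-unit accuracies do not state which was
used), resamples baseline individuals with replacement, and evaluates each
sampled individual against its own collection with its two alleles removed
from the counts (posterior-mean frequencies recomputed at 2(n−1) gene
copies). Disabling LOO measurably inflates accuracy on weakly separated
baselines, which the tests assert. Accuracy is reported per unit and
overall, filtered and unfiltered.

## Seasonal movement tests

2×2 season × (local / non-local assignment) tables, Pearson X² without
continuity correction. When any expected cell is below 5 the p-value is
Monte-Carlo: replicate tables drawn multinomially over the four cells with
margin-derived expected probabilities and the total fixed (a
fixed-both-margins Patefield sampler is available as an option; both give
the same add-one floor), p = (1 + #{X²_rep ≥ X²_obs}) / (B + 1), so p is
never 0 and bottoms out at 1/5001 ≈ 0.0002 at the default 5000 replicates.
Zero-margin tables are degenerate: X² = 0, p = 1. Significance bands:
*** p < 0.001, ** p < 0.01, * p < 0.05, NS otherwise.

## Numerical choices and problem sizes

All stochastic operations take explicit integer seeds and are bit-for-bit
reproducible; the pipeline manifest records every derived stage seed and
output hash. Gibbs likelihood rows are max-shifted before exponentiation;
tie-breaks are lexicographic everywhere a rule needs one (documented at
each site). The test suite and acceptance script size their simulations to
what the statistics need rather than more: e.g. 500 loci × n = 100 for
estimator bias, 2000 replicates for calibration rates, 50 simulated
mixtures of 200 individuals (≈ 178-locus baseline) for LOO accuracy — the
full suite runs in well under a minute on one core.

## Known limitations

- Genotype-likelihood (ANGSD-style) FST and SFS machinery are not
  implemented; the WC84 substitution preserves locus *ranking* semantics
  for panel selection but not numerical equivalence with SFS estimators.
- The linkage statistic is not the index of association; only the flagging
  decision is comparable.
- The mixture model assumes HWE within collections and independent loci;
  linked panel loci violate the latter mildly (the original workflow found
  assignment accuracy insensitive to this, and no correction is applied).
- `mixture_composition_report` rejects or flags undersized sites; merging
  by geographic proximity is the caller's decision before inference, not
  automated.
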