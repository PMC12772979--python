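# gsikit

Genetic stock identification (GSI) for highly mobile marine fishes managed as
discrete spawning stocks — the motivating system is Pacific cod (*Gadus
macrocephalus*) in Alaska waters, where four genetically distinct stocks mix
outside the spawning season. `gsikit` re-implements the full analysis chain
around a GT-seq (genotyping-in-thousands by sequencing) microhaplotype panel:

1. **Panel selection** — from a per-locus, per-population-pair FST landscape,
   a four-step downsampling picks markers that maximise discriminatory power
   while spreading them across the genome: top-10 loci per chromosome per
   pairwise comparison → unique loci → drop loci with max FST < 0.2 → six
   equal windows per chromosome, two loci each, at most one locus per
   pairwise comparison per chromosome (276 candidates over 23 chromosomes,
   plus explicitly injected outlier-region loci).
2. **Microhaplotype calling** — haplotype read counts become multi-allelic
   genotypes under the standard amplicon rules: ≥ 20 reads per locus per
   individual, drop haplotypes below 0.2 of the deepest haplotype's depth,
   heterozygous for the two deepest survivors or homozygous for one; then
   individuals (> 75 % of loci) and loci (> 75 % of remaining individuals)
   are filtered, and loci out of Hardy–Weinberg equilibrium in a majority of
   reference collections are removed.
3. **Mixture inference** — the Pella–Masuda conditional Bayesian mixture
   model. With baseline collections c = 1..C carrying Dirichlet-posterior
   mean allele frequencies p̂_c, a Gibbs sampler alternates

       z_i | π  ∼  Categorical( π_c · P(y_i | p̂_c) )
       π | z    ∼  Dirichlet( α + n(z) ),       α_c = 1/C

   where P(y_i | p̂_c) is the Hardy–Weinberg product over loci (p² / 2pq) and
   missing loci contribute a factor 1. Reporting-unit quantities are sums
   over member collections. Per-individual assignments are screened by a
   > 0.9 posterior confidence filter and a z-score diagnostic
   z = (log L_obs − μ) / σ, with μ, σ² the exact per-locus moments of
   log P(G) under the MAP collection's frequencies, excluding fish from
   populations absent from the baseline (|z| ≥ 5).
4. **Accuracy assessment** — leave-one-out simulated mixtures: reporting-unit
   proportions drawn from Dirichlet(1.5), baseline individuals resampled
   accordingly, each individual's own alleles removed from its source
   collection's frequency estimate before scoring MAP assignments.
5. **Seasonal movement tests** — 2×2 Pearson chi-square (season ×
   local/non-local assignment) with Monte-Carlo p-values (5000 replicates,
   add-one rule, smallest attainable p = 1/5001 ≈ 0.0002) when expected
   cells fall below 5.

Everything upstream of these stages (sequencing, alignment, variant calling)
is out of scope; a synthetic-data module generates all inputs — Balding–
Nichols baselines at specified FST, mixtures with known proportions,
negative-binomial read counts with configurable error, and FST landscapes
with controllable window saturation — so every stage is testable end to end
with known ground truth.

## Worked example

Four synthetic stocks (178 microhaplotype loci, between-stock FST 0.05,
50 reference fish each), a 200-fish mixture drawn at proportions
(0.60, 0.25, 0.10, 0.05):

```python
import numpy as np
import gsikit as gk
from gsikit.gsi import Baseline, McmcConfig, infer_mixture, confidence_filter

model = gk.default_population_model(n_pops=4, n_loci=178, fst=0.05, seed=1)
pfreqs = gk.draw_population_freqs(model, seed=2)
baseline = gk.simulate_baseline(pfreqs, n_per_pop=50, seed=3)

truth = np.array([0.6, 0.25, 0.1, 0.05])
mixture = gk.simulate_mixture(pfreqs, gk.MixtureSpec(truth, 200, seed=4))

result = infer_mixture(Baseline(baseline), mixture,
                       McmcConfig(n_sweeps=2000, burn_in=100, seed=5))
print(result.unit_mixing_proportions.round(3).to_string())
retained, excluded = confidence_filter(result)
print(f"retained {len(retained)} of 200; excluded {len(excluded)}")
```

prints

```
P01    0.536
P02    0.276
P03    0.121
P04    0.067
retained 200 of 200; excluded 0
```

The chain-averaged mixing proportions track the *realized* composition of
this particular 200-fish sample — (0.540, 0.275, 0.120, 0.065) — to within
±0.004, every individual clears the 0.9 confidence filter, and all retained
MAP assignments are correct. The gap to the nominal (0.60, 0.25, ...) is
binomial sampling noise in the mixture draw itself, not estimation error.

A full demo pipeline (simulate → FST → panel → calling → GSI → movement
test) runs from the command line and writes a manifest of seeds and output
hashes:

```bash
gsikit run --out-dir demo_run
```

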