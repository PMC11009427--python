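# rhinoload

Population-genetic analysis of deleterious load and forward simulation of a
population restored from cryobanked genomes, motivated by the northern white
rhinoceros (NWR): a functionally extinct subspecies whose recovery would
start from a handful of banked cell lines, with the recovered southern white
rhinoceros (SWR) as a benchmark for a viable level of genetic load.

The package is aimed at conservation-genomics researchers who want to ask,
for a small founder panel: how much deleterious variation do these genomes
carry, how is it partitioned between homozygous (realized) and heterozygous
(masked) states, how much of it sits in runs of homozygosity from past
inbreeding — and what happens to fitness over the first generations of a
restored population under different growth and supplementation strategies?

## What it computes

**Severity-binned load.** Variants are polarized to ancestral/derived
states using two outgroup genomes, binned by GERP rejected-substitutions
(RS) score — neutral (RS < 2), mild [2, 4), moderate [4, 5.8),
severe (≥ 5.8) — and given per-bin selection and dominance coefficients
(defaults s = 0, −0.0001, −0.001, −0.002; h = 0.5, 0.293, 0.062, 0.033).
Per genome:

    fitness cost   W   = ∏ hom (1 + s_i) · ∏ het (1 + h_j s_j)
    realized load  L_R = Σ hom |s_i| + Σ het |h_j s_j|

plus hom/het counts per bin and per deleterious flag (conserved RS > 4,
missense-at-conserved, loss of function), fixation contrasts between
populations (Pearson χ²), call-rate-adjusted heterozygosity, private
alleles, and the hypergeometrically projected joint site-frequency
spectrum.

**Runs of homozygosity.** A two-state HMM (autozygous / non-autozygous with
distance-dependent transitions, Viterbi decoding, forward–backward
qualities) calls ROH; F_ROH sums tracts > 1 Mb with quality > 30 over the
genome length; a tract of L Mb is dated to ~50/L generations since its
common ancestor; and deleterious enrichment inside ROH is tested by length
bin (regressions and paired t-tests).

**Restoration simulation.** A non-Wright–Fisher forward simulator starts
from founder haplotypes reconstructed out of the banked genotypes, draws
two distinct fitness-weighted parents per offspring, recombines at
10⁻⁸ /bp with independently assorting scaffolds, imposes census
trajectories for growth rates 0–50% per generation, and optionally
reintroduces one random founder genome per generation. Outputs are
per-generation, per-replicate traces and cross-replicate medians of load,
fitness, heterozygosity and fixation, with the benchmark cohort's medians
as reference lines.

A synthetic-cohort generator (Balding–Nichols substructure, severity-graded
allele-frequency spectra, plantable ROH) makes the whole pipeline runnable
and testable without any restricted data.

## Worked example

```python
import numpy as np
import rhinoload as rl

spec = rl.CohortSpec(seed=0)                       # 9 founders, 13 benchmark, 10x10 Mb
founders, table, scaffolds = rl.generate_founder_cohort(spec)
benchmark = rl.generate_benchmark_cohort(spec, table)

ind = rl.load_summary(founders, table)["individual"]
print(ind["fitness_cost"].median(), ind["realized_load"].median())

banked = rl.GenotypeMatrix(founders.samples[:8], founders.populations[:8],
                           founders.dosages[:8])
panel = rl.build_founder_haplotypes(banked, table, scaffolds,
                                    rng=np.random.default_rng(0))
cfg = rl.SimConfig(growth_rates=(0.0, 0.3), replicates=10, base_seed=0)
out = rl.run_replicates(panel, cfg, benchmark=(benchmark, table))
```

On the default synthetic cohort this prints a founder median fitness cost
W = 0.8404 against a benchmark median of 0.6533 (the inbred benchmark
carries more realized load: L_R medians 0.1738 vs 0.4255), and the
generation-10 medians show the growth effect — at 0% growth W falls to
0.8193 (L_R 0.1992, census 8) while at 30% growth W stays at 0.8305
(L_R 0.1857, census 108). Realized load accumulates as heterozygous
deleterious alleles drift to homozygosity, and faster growth damps that
loss; the 8 → 108 census at 30% growth is the compounding trajectory
`rl.population_trajectory(8, 0.3, 10)`.

Demography helpers convert the fitted piecewise model's change points into
calendar time: `rl.years_from_generations(37, 8)` → 296 years, and
`rl.harmonic_mean_linear(13456, 1042)` gives the harmonic-mean Ne of the
long linear decline epoch (≈ 4852).

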