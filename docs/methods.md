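# Methods

## Variant polarization and severity binning

Ancestral states are assigned from two outgroup genomes: a site's ancestral
allele is the one homozygous in *both* outgroups, and it must be one of the
focal ref/alt alleles. Any heterozygous outgroup call, disagreement between
outgroups, third allele, or missing genotype marks the site `unknown`, and
unknown sites are excluded from all load analyses. Polarization is
idempotent and never adds sites.

Severity bins partition the GERP RS axis with left-closed boundaries at
2, 4 and 5.8: neutral, mild, moderate, severe. Two deliberate extensions of
the binning rule: RS below −2 is still neutral (everything under the first
boundary behaves neutrally), and a missing RS score maps to neutral and is
excluded from the deleterious flags — a site we cannot score cannot be
declared deleterious. Indels are binned by RS exactly like SNVs.
Multi-allelic records are rejected at load time; dosage coding and
polarization assume biallelic sites.

Two coefficient sets ship with the package (per-bin s, h):

| set      | s (neutral, mild, moderate, severe)    | h                          |
|----------|----------------------------------------|----------------------------|
| henn     | 0, −0.0001, −0.001, −0.002             | 0.5, 0.293, 0.062, 0.033   |
| peischl  | 0, −0.024, −0.032, −0.072              | reuses the henn h values   |

The alternate set has no published dominance values, so it reuses the
default h vector; this is a package choice, exposed so sensitivity runs
change only s.

## Load metrics

Fitness cost is the product over homozygous-derived sites of (1 + s) and
heterozygous sites of (1 + h·s), evaluated in log space so ten thousand
multiplications lose no precision; realized load is the additive burden
Σ|s| + Σ|h·s|, reported positive. For the default coefficients
(|s| ≤ 0.002) the two are linked by exp(−L_R) ≈ W to better than 10⁻⁴
relative, which the tests assert on random genomes against a direct
brute-force product oracle.

Population summaries use a complete-case rule: only sites with a called
genotype in every cohort member contribute, mirroring how joint
fixed/segregating contrasts must be computed on a shared denominator.
"Fixed" means derived dosage 2 in every *sampled* member — sample fixation,
the only kind observable. The fixed-deleterious contrast between two
populations is a Pearson χ² on the 2×2 (fixed deleterious, fixed
non-deleterious) table without continuity correction, so small worked
examples are exact against the Σ(O−E)²/E formula.

Heterozygosity per sample is het-site count divided by gapless genome
length times the sample's call rate, after masking genotypes with GQ < 20
and dropping sites with > 30% cohort-wide missingness — the cohort filter
runs first, then the per-sample adjustment.

The joint SFS is projected to smaller allele counts (m₁, m₂) with
hypergeometric weights C(d,j)C(n−d,m−j)/C(n,m) per site, computed via log
gamma for stability; sites with fewer called alleles than the projection
size in either population are dropped, so total matrix mass equals the
number of projectable sites. At m = n the projection is the identity.

## ROH model

Autozygosity is decoded with a two-state HMM over biallelic genotypes.
Emissions: the non-autozygous state emits heterozygotes at the
Hardy–Weinberg rate 2p(1−p) from cohort allele frequencies; the autozygous
state emits them at a fixed error rate ε = 10⁻³ (a genotype-error proxy).
Transitions between adjacent markers at distance d bp are
1 − exp(−αd) into autozygosity (α = 6.7×10⁻⁸) and 1 − exp(−βd) out of it
(β = 5×10⁻⁹), mirroring the published defaults of the standard
genotype-based ROH caller this model follows; all three are exposed on the
CLI. The initial state distribution is uniform. Genotype likelihoods
(GL/PL) are not modelled — hard genotypes only — which is the main
divergence from that caller.

Viterbi decoding defines segments as maximal runs of autozygous markers;
coordinates span first to last marker (0-based half-open) rather than
midpoints between flanking markers, for determinism. Segment quality is
the median phred-scaled autozygosity posterior from forward–backward,
capped at 99; the median is robust to low-confidence edge markers. Viterbi
ties break toward the non-autozygous state. The decoder is validated
against exhaustive path enumeration on instances up to 12 sites, and
posteriors are checked to sum to 1 at 10⁻¹⁰.

A planted autozygous tract can only be localized up to the nearest
heterozygous marker outside it — homozygous background markers adjoining
the tract are indistinguishable from it — so recovery tests place
informative flanking markers and then require boundary agreement within
one inter-marker gap at 10 kb density.

F_ROH sums tracts longer than 1 Mb with quality above 30 and divides by
genome length. Tract length dates the inbreeding event as 50/L generations
(L in Mb), from the rule of thumb that ~50 Mb of identity-by-descent tract
material is transmitted per generation. Enrichment statistics use length
bins [0.1, 0.5), [0.5, 1), [1, 3), [3, ∞) Mb; regressions are on bin
midpoints, with the open top bin assigned 3 Mb plus half the preceding
bin's width (4 Mb). Bins with no homozygous sites are flagged NaN and
excluded from regression; paired t-tests with zero difference variance
raise rather than return an unstable statistic.

## Restoration simulator

Non-Wright–Fisher, individual-based, discrete generations. Founder
haplotypes are reconstructed from observed genotypes at every variant with
RS ≥ 2 plus 10,000 randomly chosen neutral variants; heterozygous sites
place the derived allele on a random haplotype. Only scaffolds > 1 Mb are
simulated. Each generation: census size comes from the imposed trajectory
N_{t+1} = round-half-up(N_t(1+g)) — half-up rounding reproduces the
printed 8 → 108 trajectory at g = 0.3 — and each offspring draws two
*distinct* parents with probability w_i/Σw (fitness-weighted, redrawn per
offspring), then one gamete from each. Gametes recombine per scaffold with
Poisson(L·10⁻⁸) crossovers at uniform positions; scaffolds assort
independently. The mutation rate is pinned to 0: the model studies
standing variation only, so every allele in every generation traces to a
founder haplotype (asserted in tests), and fitness is a relative cost of
realized load, not absolute fitness.

There are no sexes and no selfing; with banked-cell-line-derived gametes
either-sex contribution is plausible, and requiring distinct parents is
the minimal mating structure. A consequence worth knowing: heterozygosity
decays slightly slower than the idealized (1 − 1/(2N))ᵗ — the no-selfing
scheme introduces a one-generation lag, ~10% over 10 generations at N = 8
(exact recursion: f_{t+1} = g_t, g_{t+1} = (1+f_t)/(2N) + (1−1/N)g_t).
The decay test therefore compares at 15% relative slack, covering that
known bias plus Monte-Carlo noise at 50 replicates.

In supplemented mode one founder, drawn uniformly with replacement (8
lines over 10 generations force reuse), is instantiated from its panel
haplotypes each generation and *replaces* one bred offspring, so census
matches the trajectory exactly and census curves are comparable across
strategies; a flag switches to adding it on top instead. The reintroduced
founder's fitness is computed like anyone else's and it joins the parent
pool.

Reproducibility: every random draw comes from a stream seeded by
(base seed, growth rate, replicate, generation, purpose), where purpose
separates parent choice, meiosis and supplementation — so turning
supplementation on does not perturb the meiosis draws, and re-running any
scenario with the same seed is bit-identical.

Per-generation summaries report census, medians across individuals of
fitness cost, realized load, hom/het site counts overall and per bin,
fixed-derived and fixed-deleterious counts, and the fraction of
founder-polymorphic sites fixed derived. Medians across replicates are the
headline trajectories; a benchmark cohort's median W and L_R are attached
as reference values, and the report utility finds the first generation a
scenario's median fitness falls *strictly* below the benchmark median
(a tie is not a crossing).

## Demography constants

The fitted two-population piecewise model ships as constants (JSON): an
ancestral population of 14,024 splitting 5,864 generations ago, long
linear declines, and two short recent epochs beginning 37 and 28
generations ago, with weak asymmetric migration (Nm = 0.031). The package
does not refit it — SFS model fitting is out of scope. Conversions:
generations × generation time (8 or 25.5 years), rounded half-up to whole
years; and the harmonic-mean Ne of a linear epoch,
(N₁−N₂)/ln(N₁/N₂) — the logarithmic mean of the endpoints, which lies
between their geometric and arithmetic means and is cross-checked against
trapezoid integration of 1/N(t). For the 13,456 → 1,042 decline this gives
≈ 4852.5.

## Synthetic cohorts: what they emulate and what they don't

The generator reproduces the *statistical shape* the analysis assumes, at
desk scale: 9 founders (8 banked + 1 extra sequenced) and 13 benchmark
genomes over 10 × 10 Mb scaffolds with ~5×10⁴ sites (40k neutral, 6k mild,
3k moderate, 1k severe — a tractable miniature of a whole-genome variant
set). Mean derived-allele frequencies decline with severity
(0.2/0.1/0.05/0.02), encoding purifying selection's footprint on the
spectrum without fitting a DFE; ancestral frequencies are Beta with
concentration 1, giving a skewed, rare-allele-heavy spectrum. Founder
substructure is Balding–Nichols with two subgroups at F_ST = 0.1 —
enough Wahlund deficit that random mating produces the expected
generation-1 heterozygosity uptick. The benchmark cohort gets excess
homozygosity via an inbreeding coefficient F = 0.2, 5% of
conserved-deleterious sites fixed derived, and one planted ~2.5 Mb ROH per
individual, so it shows the higher F_ROH and homozygous load the analysis
is designed to detect. GQ values are mostly 20–99 with 2% low-quality
calls to exercise the filters.

Not emulated: linkage disequilibrium within founder haplotypes (sites are
drawn independently, so generation-0 LD is absent and early-generation ROH
in simulated offspring are shorter than reality), realistic SFS or π
values of the actual populations, sequence context, genotyping error
structure beyond GQ, and indel/SNV differences. Passing tests on this
cohort demonstrate the estimators and the simulator are correct and
internally consistent — not that the synthetic numbers match any real
population's values.

## Problem sizes

Default analyses and the simulator property checks run at the desk scale
above; the full growth sweep is 6 scenarios × 50 replicates × 10
generations (~2×10⁴ panel sites), the drift check uses a neutral-only
8,000-site panel over 5 generations × 50 replicates, and HMM enumeration
checks cap instances at 12 sites where exhaustive search is exact. Full-
scale inputs (real VCFs over thousands of scaffolds) are accepted by the
same interfaces but are not required by anything in the repository.

## Known limitations

- The ROH caller consumes hard genotypes; no GL/PL support.
- The simulator's founder haplotype phasing is random at heterozygous
  sites, which destroys real phase information a user might have.
- The 50 Mb/L dating rule is a coarse expectation; recombination-rate
  variation across the genome is ignored by design.
- `harmonic_mean_linear` is exact for a single linear epoch between its
  endpoints; averaging windows that mix epochs need explicit composition
  by the caller.
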