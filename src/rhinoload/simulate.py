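"""Non-Wright–Fisher forward simulation of a restored population.

A population is founded from a small panel of banked genomes (haplotypes
reconstructed from observed genotypes), then evolved for a fixed number of
non-overlapping generations along a predefined census trajectory.  Each
offspring draws two distinct parents with probability proportional to
fitness, and one recombinant gamete from each; scaffolds assort
independently and crossovers are Poisson along each scaffold.  There are no
new mutations, no sexes and no selfing.  Optionally one founder genome is
reintroduced per generation ("supplementation"), standing in for thawing a
banked cell line.

Because only neutral and deleterious variants are modelled, fitness is the
cost of realized load relative to the cohort, not absolute fitness; census
sizes are imposed, not emergent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import load as load_metrics
from .annotation import BINS, CoefficientSet, HENN_COEFFICIENTS
from .demography import round_half_up

MB = 1_000_000


@dataclass
class FounderPanel:
    """Phased founder haplotypes over the simulated scaffolds.

    ``haplotypes[k]`` has shape (n_founders, 2, n_sites_k) for scaffold k;
    ``table`` is the concatenated per-site annotation in scaffold order,
    with ``s``/``h`` populated, and row order matching the concatenation of
    the per-scaffold position arrays.
    """

    founders: list[str]
    scaffold_names: list[str]
    scaffold_lengths: np.ndarray
    positions: list[np.ndarray]
    haplotypes: list[np.ndarray]
    table: pd.DataFrame

    @property
    def n_founders(self) -> int:
        return len(self.founders)

    @property
    def n_sites(self) -> int:
        return sum(len(p) for p in self.positions)

    def founder_population(self) -> list[np.ndarray]:
        return [h.copy() for h in self.haplotypes]


@dataclass(frozen=True)
class SimConfig:
    growth_rates: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)
    generations: int = 10
    replicates: int = 50
    supplemented: bool = False
    recomb_rate: float = 1e-8
    mutation_rate: float = 0.0
    coefficients: CoefficientSet = HENN_COEFFICIENTS
    base_seed: int = 0
    #: if True, the reintroduced founder is added on top of the trajectory
    #: census instead of replacing one bred offspring.
    supplement_extra: bool = False

    def __post_init__(self) -> None:
        if any(g < 0 for g in self.growth_rates):
            raise ValueError("growth rates must be >= 0")
        if self.mutation_rate != 0.0:
            raise ValueError("the model is closed: mutation_rate is fixed at 0")


def population_trajectory(n0: int, growth: float, generations: int) -> list[int]:
    """Census sizes [N_0 .. N_T] under compound growth, rounding half-up."""
    if n0 < 1:
        raise ValueError("n0 must be >= 1")
    sizes = [n0]
    for _ in range(generations):
        sizes.append(round_half_up(sizes[-1] * (1.0 + growth)))
    return sizes


def build_founder_haplotypes(
    gm: load_metrics.GenotypeMatrix,
    table: pd.DataFrame,
    scaffold_lengths: pd.DataFrame,
    n_neutral: int = 10_000,
    rng: np.random.Generator | None = None,
    min_scaffold_length: int = 1 * MB,
) -> FounderPanel:
    """Reconstruct phased founder haplotypes from observed genotypes.

    Included sites are every non-neutral variant (RS >= 2) plus
    ``n_neutral`` neutral variants sampled without replacement; only
    scaffolds longer than ``min_scaffold_length`` are simulated.
    Heterozygous genotypes place their derived allele on a uniformly random
    haplotype.
    """
    rng = np.random.default_rng() if rng is None else rng
    lengths = dict(zip(scaffold_lengths["scaffold"], scaffold_lengths["length"]))
    keep_scaffolds = [s for s in scaffold_lengths["scaffold"] if lengths[s] > min_scaffold_length]

    on_kept = table["scaffold"].isin(keep_scaffolds).to_numpy()
    neutral = (table["bin"].to_numpy() == "neutral") & on_kept
    non_neutral = ~(table["bin"].to_numpy() == "neutral") & on_kept
    neutral_idx = np.flatnonzero(neutral)
    if len(neutral_idx) > n_neutral:
        neutral_idx = np.sort(rng.choice(neutral_idx, size=n_neutral, replace=False))
    include = np.zeros(len(table), dtype=bool)
    include[neutral_idx] = True
    include[non_neutral] = True

    if (gm.dosages[:, include] == load_metrics.MISSING).any():
        raise ValueError("founder genotypes must be complete at panel sites")

    positions, haplotypes, chunks = [], [], []
    for scaf in keep_scaffolds:
        m = include & (table["scaffold"].to_numpy() == scaf)
        idx = np.flatnonzero(m)
        pos = table["pos"].to_numpy()[idx]
        d = gm.dosages[:, idx]
        hap = np.zeros((gm.n_individuals, 2, len(idx)), dtype=np.uint8)
        hap[:, 0][d == 2] = 1
        hap[:, 1][d == 2] = 1
        het = d == 1
        which = rng.integers(0, 2, size=int(het.sum()))
        ind_i, site_i = np.nonzero(het)
        hap[ind_i, which, site_i] = 1
        positions.append(pos.astype(np.int64))
        haplotypes.append(hap)
        chunks.append(table.iloc[idx])
    if not positions:
        raise ValueError("no scaffolds exceed the minimum simulated length")
    return FounderPanel(
        founders=list(gm.samples),
        scaffold_names=keep_scaffolds,
        scaffold_lengths=np.array([lengths[s] for s in keep_scaffolds], dtype=np.int64),
        positions=positions,
        haplotypes=haplotypes,
        table=pd.concat(chunks, ignore_index=True),
    )


def meiosis(
    hap_pair: np.ndarray,
    positions: np.ndarray,
    scaffold_length: int,
    recomb_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One recombinant gamete from a (2, n_sites) haplotype pair.

    Crossover count is Poisson(L*r); breakpoint positions are uniform on
    the scaffold; the starting haplotype is chosen uniformly and the gamete
    alternates source haplotype at each breakpoint.
    """
    start = int(rng.integers(0, 2))
    n_co = int(rng.poisson(scaffold_length * recomb_rate))
    if n_co == 0:
        return hap_pair[start].copy()
    breaks = np.sort(rng.uniform(0, scaffold_length, size=n_co))
    flips = np.searchsorted(breaks, positions, side="right")
    return hap_pair[(start + flips) % 2, np.arange(len(positions))].copy()


def _draw_parent_pairs(
    weights: np.ndarray, n_offspring: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_offspring, 2) indices of distinct, fitness-weighted parents."""
    n = len(weights)
    if n < 2:
        raise ValueError("need at least two potential parents (no selfing)")
    probs = weights / weights.sum()
    p1 = rng.choice(n, size=n_offspring, p=probs)
    p2 = rng.choice(n, size=n_offspring, p=probs)
    clash = p1 == p2
    while clash.any():
        p2[clash] = rng.choice(n, size=int(clash.sum()), p=probs)
        clash = p1 == p2
    return np.column_stack([p1, p2])


def dosage_matrix(pop: list[np.ndarray]) -> np.ndarray:
    """(N, total_sites) derived-allele dosages from per-scaffold haplotypes."""
    return np.concatenate([h.sum(axis=1) for h in pop], axis=1)


def next_generation(
    pop: list[np.ndarray],
    fitness: np.ndarray,
    n_next: int,
    panel: FounderPanel,
    cfg: SimConfig,
    rng_parents: np.random.Generator,
    rng_meiosis: np.random.Generator,
    rng_supplement: np.random.Generator | None,
) -> list[np.ndarray]:
    """Produce the next generation's haplotypes.

    If ``rng_supplement`` is given (supplemented mode), one founder genome
    drawn uniformly with replacement from the panel joins the generation —
    by default replacing one bred offspring so the census still matches the
    trajectory.
    """
    if n_next < 1:
        raise ValueError("census must be >= 1")
    supplemented = rng_supplement is not None
    n_bred = n_next - 1 if (supplemented and not cfg.supplement_extra) else n_next
    pairs = _draw_parent_pairs(fitness, n_bred, rng_parents)

    new_pop = []
    for k, hap in enumerate(pop):
        n_sites = hap.shape[2]
        out_n = n_bred + (1 if supplemented else 0)
        out = np.empty((out_n, 2, n_sites), dtype=np.uint8)
        for o in range(n_bred):
            for which, parent in enumerate(pairs[o]):
                out[o, which] = meiosis(
                    hap[parent],
                    panel.positions[k],
                    int(panel.scaffold_lengths[k]),
                    cfg.recomb_rate,
                    rng_meiosis,
                )
        new_pop.append(out)
    if supplemented:
        f = int(rng_supplement.integers(0, panel.n_founders))
        for k in range(len(new_pop)):
            new_pop[k][-1] = panel.haplotypes[k][f]
    return new_pop


def _rng(cfg: SimConfig, growth: float, replicate: int, generation: int, stream: int):
    seq = np.random.SeedSequence(
        entropy=(cfg.base_seed, int(round(growth * 1000)), replicate, generation, stream)
    )
    return np.random.default_rng(seq)


def summarize_generation(
    generation: int,
    pop: list[np.ndarray],
    panel: FounderPanel,
    founder_polymorphic: np.ndarray,
) -> dict[str, float]:
    """Per-generation summary of the load and diversity state of a population."""
    d = dosage_matrix(pop)
    table = panel.table
    w = load_metrics.fitness_matrix(d, table)
    lr = load_metrics.realized_load_matrix(d, table)
    hom = d == 2
    het = d == 1
    fixed = hom.all(axis=0)
    deleterious = table["conserved_deleterious"].to_numpy(dtype=bool)
    row: dict[str, float] = {
        "generation": generation,
        "census": d.shape[0],
        "median_fitness": float(np.median(w)),
        "median_realized_load": float(np.median(lr)),
        "median_hom_sites": float(np.median(hom.sum(axis=1))),
        "median_het_sites": float(np.median(het.sum(axis=1))),
        "mean_het_sites": float(het.sum(axis=1).mean()),
        "fixed_derived": int(fixed.sum()),
        "fixed_deleterious": int((fixed & deleterious).sum()),
        "frac_polymorphic_fixed": float(
            (fixed & founder_polymorphic).sum() / founder_polymorphic.sum()
        )
        if founder_polymorphic.any()
        else np.nan,
    }
    bins = table["bin"].to_numpy()
    for b in BINS:
        m = bins == b
        row[f"median_hom_{b}"] = float(np.median(hom[:, m].sum(axis=1)))
        row[f"median_het_{b}"] = float(np.median(het[:, m].sum(axis=1)))
    return row


def run_scenario(
    panel: FounderPanel,
    cfg: SimConfig,
    growth: float,
    replicate: int,
) -> pd.DataFrame:
    """One replicate of one growth scenario; one summary row per generation."""
    trajectory = population_trajectory(panel.n_founders, growth, cfg.generations)
    pop = panel.founder_population()
    founder_d = dosage_matrix(pop)
    freqs = founder_d.sum(axis=0) / (2 * panel.n_founders)
    founder_polymorphic = (freqs > 0) & (freqs < 1)

    rows = [summarize_generation(0, pop, panel, founder_polymorphic)]
    for gen in range(1, cfg.generations + 1):
        fitness = load_metrics.fitness_matrix(dosage_matrix(pop), panel.table)
        pop = next_generation(
            pop,
            fitness,
            trajectory[gen],
            panel,
            cfg,
            rng_parents=_rng(cfg, growth, replicate, gen, 0),
            rng_meiosis=_rng(cfg, growth, replicate, gen, 1),
            rng_supplement=_rng(cfg, growth, replicate, gen, 2) if cfg.supplemented else None,
        )
        rows.append(summarize_generation(gen, pop, panel, founder_polymorphic))
    out = pd.DataFrame(rows)
    out.insert(0, "replicate", replicate)
    out.insert(0, "growth", growth)
    return out


def run_replicates(
    panel: FounderPanel,
    cfg: SimConfig,
    benchmark: tuple[load_metrics.GenotypeMatrix, pd.DataFrame] | None = None,
) -> dict[str, pd.DataFrame]:
    """All growth scenarios x replicates; medians across replicates.

    Returns ``{"replicates": per-replicate traces, "medians": per-scenario
    per-generation medians}``; when a benchmark cohort is supplied its
    median fitness cost and realized load are attached as reference columns
    on the medians table.
    """
    if cfg.replicates < 1:
        raise ValueError("need at least one replicate")
    traces = pd.concat(
        [
            run_scenario(panel, cfg, growth, rep)
            for growth in cfg.growth_rates
            for rep in range(cfg.replicates)
        ],
        ignore_index=True,
    )
    medians = (
        traces.drop(columns="replicate")
        .groupby(["growth", "generation"], as_index=False)
        .median()
    )
    if benchmark is not None:
        bgm, btable = benchmark
        keep = bgm.complete_case_mask()
        bw = load_metrics.fitness_matrix(bgm.dosages[:, keep], btable.loc[keep])
        blr = load_metrics.realized_load_matrix(bgm.dosages[:, keep], btable.loc[keep])
        medians["benchmark_median_fitness"] = float(np.median(bw))
        medians["benchmark_median_realized_load"] = float(np.median(blr))
    return {"replicates": traces, "medians": medians}
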