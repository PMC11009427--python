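"""Synthetic founder and benchmark cohorts for desk-scale analysis.

The generator emulates the statistical structure the pipeline assumes,
without any sequence data: a small founder cohort (eight banked genomes
plus one extra sequenced individual) with mild two-subgroup substructure,
severity-binned variants whose derived-allele frequencies decrease with
severity, and a larger benchmark cohort (the recovered-population role)
with elevated homozygosity, a fraction of deleterious sites fixed derived,
and planted long runs of homozygosity.

Subgroup allele frequencies follow the Balding–Nichols model: given an
ancestral frequency p and differentiation F_ST = F, each subgroup draws its
frequency from Beta(p(1-F)/F, (1-p)(1-F)/F).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import annotate
from .load import GenotypeMatrix

MB = 1_000_000

#: RS intervals sites are drawn from, per bin (severe is open above; 10 is
#: a practical ceiling for sampling).
RS_RANGES = {
    "neutral": (-2.0, 2.0),
    "mild": (2.0, 4.0),
    "moderate": (4.0, 5.8),
    "severe": (5.8, 10.0),
}


@dataclass
class CohortSpec:
    """Desk-scale cohort description; defaults mirror the study's shape."""

    n_individuals: int = 9  # 8 banked founders + 1 extra sequenced genome
    n_banked: int = 8
    n_scaffolds: int = 10
    scaffold_length: int = 10 * MB
    sites_per_bin: dict[str, int] = field(
        default_factory=lambda: {
            "neutral": 40_000,
            "mild": 6_000,
            "moderate": 3_000,
            "severe": 1_000,
        }
    )
    #: mean derived-allele frequency per bin; lower for more severe bins.
    mean_daf: dict[str, float] = field(
        default_factory=lambda: {
            "neutral": 0.2,
            "mild": 0.1,
            "moderate": 0.05,
            "severe": 0.02,
        }
    )
    #: Beta concentration for ancestral frequencies (a+b); small values give
    #: the skewed, rare-allele-heavy spectra typical of real cohorts.
    daf_concentration: float = 1.0
    substructure: tuple[int, float] = (2, 0.1)  # (n_groups, F_ST)
    planted_roh: list[tuple[int, int, tuple[int, int]]] = field(default_factory=list)
    #: impact-class mixture at conserved (RS > 4) sites.
    impact_mixture: dict[str, float] = field(
        default_factory=lambda: {"LOW": 0.55, "MODERATE": 0.40, "LOF": 0.05}
    )
    # benchmark cohort knobs
    benchmark_n: int = 13
    benchmark_inbreeding_f: float = 0.2
    benchmark_fixed_fraction: float = 0.05
    benchmark_planted_roh: list[tuple[int, int, tuple[int, int]]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        n_groups, fst = self.substructure
        if not (0.0 <= fst < 1.0):
            raise ValueError("F_ST must lie in [0, 1)")
        if n_groups < 1:
            raise ValueError("need at least one subgroup")
        for _, scaf, (start, end) in self.planted_roh + self.benchmark_planted_roh:
            if not (0 <= start < end <= self.scaffold_length) or scaf >= self.n_scaffolds:
                raise ValueError("planted ROH interval outside the genome")
        for v in self.mean_daf.values():
            if not (0.0 < v < 1.0):
                raise ValueError("mean derived-allele frequencies must be in (0,1)")


def default_benchmark_roh(spec: CohortSpec, tract_length: int = 2_500_000):
    """One long planted ROH per benchmark individual, staggered over scaffolds."""
    out = []
    for i in range(spec.benchmark_n):
        scaf = i % spec.n_scaffolds
        start = 3 * MB + (i // spec.n_scaffolds) * 3 * MB
        out.append((i, scaf, (start, min(start + tract_length, spec.scaffold_length))))
    return out


_NUCS = np.array(list("ACGT"))


def _site_table(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    n_total = sum(spec.sites_per_bin.values())
    bins = np.concatenate([np.repeat(b, n) for b, n in spec.sites_per_bin.items()])
    rng.shuffle(bins)

    scaf_idx = rng.integers(0, spec.n_scaffolds, size=n_total)
    pos = rng.integers(0, spec.scaffold_length, size=n_total)
    order = np.lexsort((pos, scaf_idx))
    scaf_idx, pos, bins = scaf_idx[order], pos[order], bins[order]
    # enforce strictly increasing positions within scaffolds
    for k in range(spec.n_scaffolds):
        m = scaf_idx == k
        p = np.sort(np.unique(pos[m]))
        while len(p) < m.sum():  # collisions: top up and dedupe
            extra = rng.integers(0, spec.scaffold_length, size=m.sum() - len(p))
            p = np.sort(np.unique(np.concatenate([p, extra])))
        pos[m] = p[: m.sum()]

    lo = np.array([RS_RANGES[b][0] for b in bins])
    hi = np.array([RS_RANGES[b][1] for b in bins])
    rs = rng.uniform(lo, hi)

    ref = _NUCS[rng.integers(0, 4, size=n_total)]
    shift = rng.integers(1, 4, size=n_total)
    alt = _NUCS[(np.searchsorted(_NUCS, ref) + shift) % 4]

    conserved = rs > 4.0
    impact = np.full(n_total, "NONE", dtype=object)
    impact[rng.random(n_total) < 0.3] = "LOW"
    classes = list(spec.impact_mixture)
    probs = np.array([spec.impact_mixture[c] for c in classes])
    impact[conserved] = rng.choice(classes, size=int(conserved.sum()), p=probs / probs.sum())

    mean = np.array([spec.mean_daf[b] for b in bins])
    k = spec.daf_concentration
    p_anc = rng.beta(mean * k, (1 - mean) * k)
    p_anc = np.clip(p_anc, 1e-3, 1 - 1e-3)

    table = pd.DataFrame(
        {
            "scaffold": np.array([f"scaffold_{i}" for i in range(spec.n_scaffolds)])[scaf_idx],
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "ancestral_state": "ref",
            "rs": rs,
            "impact": impact,
            "true_daf": p_anc,
        }
    )
    return annotate(table)


def _group_freqs(p_anc: np.ndarray, spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """(n_groups, n_sites) subgroup frequencies under Balding–Nichols."""
    n_groups, fst = spec.substructure
    if fst == 0.0 or n_groups == 1:
        return np.tile(p_anc, (n_groups, 1))
    a = p_anc * (1 - fst) / fst
    b = (1 - p_anc) * (1 - fst) / fst
    return np.clip(rng.beta(a, b, size=(n_groups, len(p_anc))), 1e-6, 1 - 1e-6)


def _plant_roh(dosages, table, planted, rng):
    scafs = table["scaffold"].to_numpy(dtype=object)
    pos = table["pos"].to_numpy()
    p = table["true_daf"].to_numpy()
    for ind, scaf_k, (start, end) in planted:
        m = (scafs == f"scaffold_{scaf_k}") & (pos >= start) & (pos < end)
        dosages[ind, m] = 2 * (rng.random(int(m.sum())) < p[m]).astype(np.int8)


def _draw_gq(shape, rng):
    gq = rng.integers(20, 100, size=shape).astype(np.int16)
    low = rng.random(shape) < 0.02
    gq[low] = rng.integers(0, 20, size=int(low.sum()))
    return gq


def generate_founder_cohort(
    spec: CohortSpec,
) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame]:
    """Founder cohort: (genotypes, annotated variant table, scaffold lengths).

    Individuals are split evenly across the spec's subgroups; dosages are
    binomial(2, subgroup frequency).  All outputs are deterministic in
    ``spec.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 1)))
    table = _site_table(spec, rng)
    p_groups = _group_freqs(table["true_daf"].to_numpy(), spec, rng)
    n_groups = spec.substructure[0]
    group_of = np.arange(spec.n_individuals) % n_groups
    dosages = np.empty((spec.n_individuals, len(table)), dtype=np.int8)
    for i in range(spec.n_individuals):
        dosages[i] = rng.binomial(2, p_groups[group_of[i]])
    _plant_roh(dosages, table, spec.planted_roh, rng)
    gm = GenotypeMatrix(
        samples=[f"NWR_F{i:02d}" for i in range(spec.n_individuals)],
        populations=["NWR"] * spec.n_individuals,
        dosages=dosages,
        gq=_draw_gq(dosages.shape, rng),
    )
    scaffolds = pd.DataFrame(
        {
            "scaffold": [f"scaffold_{i}" for i in range(spec.n_scaffolds)],
            "length": spec.scaffold_length,
        }
    )
    return gm, table, scaffolds


def generate_benchmark_cohort(spec: CohortSpec, founder_table: pd.DataFrame) -> GenotypeMatrix:
    """Benchmark cohort on the founder site list, with excess homozygosity.

    Heterozygosity is reduced by the inbreeding coefficient
    (P(het) = 2p(1-p)(1-F)); a configurable fraction of
    conserved-deleterious sites is fixed derived in every individual; and
    planted intervals have heterozygotes suppressed so long ROH are
    detectable.
    """
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 2)))
    p = founder_table["true_daf"].to_numpy()
    f = spec.benchmark_inbreeding_f
    p_hom = p * p + f * p * (1 - p)
    p_het = 2 * p * (1 - p) * (1 - f)
    n = spec.benchmark_n
    u = rng.random((n, len(p)))
    dosages = np.where(u < p_hom, 2, np.where(u < p_hom + p_het, 1, 0)).astype(np.int8)

    planted = spec.benchmark_planted_roh or default_benchmark_roh(spec)
    _plant_roh(dosages, founder_table, planted, rng)

    deleterious = founder_table["conserved_deleterious"].to_numpy(dtype=bool)
    del_idx = np.flatnonzero(deleterious)
    n_fix = int(round(spec.benchmark_fixed_fraction * len(del_idx)))
    if n_fix:
        fixed_sites = rng.choice(del_idx, size=n_fix, replace=False)
        dosages[:, fixed_sites] = 2
    return GenotypeMatrix(
        samples=[f"SWR_B{i:02d}" for i in range(n)],
        populations=["SWR"] * n,
        dosages=dosages,
        gq=_draw_gq(dosages.shape, rng),
    )
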