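"""Per-genome fitness cost, realized load, and population load summaries.

The central container is :class:`GenotypeMatrix`: individuals x sites
derived-allele dosages in {0, 1, 2} with -1 for missing, carrying sample
labels and population tags.  Dosages count the *derived* allele, so the
table rows they are paired with must already be polarized.

Fitness cost of a genome is the multiplicative model

    W = prod_hom (1 + s_i) * prod_het (1 + h_j * s_j)

and realized load is the additive burden reported as a positive number

    L_R = sum_hom |s_i| + sum_het |h_j * s_j|

so that for weak selection exp(-L_R) ~= W.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Derived-allele dosages for a cohort at a shared site list."""

    samples: list[str]
    populations: list[str]
    dosages: np.ndarray  # (n_individuals, n_sites) int8; -1 = missing
    gq: np.ndarray | None = None  # optional parallel matrix of genotype qualities

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2 or self.dosages.shape[0] != len(self.samples):
            raise ValueError("dosages must be (n_individuals, n_sites)")
        if len(self.populations) != len(self.samples):
            raise ValueError("one population tag per sample required")
        bad = ~np.isin(self.dosages, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("dosages must be in {-1, 0, 1, 2}")
        if self.gq is not None:
            self.gq = np.asarray(self.gq)
            if self.gq.shape != self.dosages.shape:
                raise ValueError("gq must parallel dosages")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]

    def complete_case_mask(self) -> np.ndarray:
        """Sites with a called genotype in every individual."""
        return ~(self.dosages == MISSING).any(axis=0)

    def subpop(self, population: str) -> "GenotypeMatrix":
        idx = [i for i, p in enumerate(self.populations) if p == population]
        if not idx:
            raise ValueError(f"no individuals tagged {population!r}")
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            populations=[population] * len(idx),
            dosages=self.dosages[idx],
            gq=None if self.gq is None else self.gq[idx],
        )


def _check_complete(dosages: np.ndarray) -> np.ndarray:
    d = np.asarray(dosages)
    if (d == MISSING).any():
        raise ValueError("dosages must be complete (no missing) for load metrics")
    return d


def genome_fitness(dosages: np.ndarray, table: pd.DataFrame) -> float:
    """Multiplicative fitness cost W of one genome, computed in log space."""
    d = _check_complete(dosages)
    s = table["s"].to_numpy(dtype=float)
    h = table["h"].to_numpy(dtype=float)
    hom = d == 2
    het = d == 1
    terms_hom = 1.0 + s[hom]
    terms_het = 1.0 + h[het] * s[het]
    if (terms_hom <= 0).any() or (terms_het <= 0).any():
        raise ValueError("fitness factor (1 + h*s) <= 0; invalid coefficients")
    return float(np.exp(np.log(terms_hom).sum() + np.log(terms_het).sum()))


def realized_load(dosages: np.ndarray, table: pd.DataFrame) -> float:
    """Additive realized load L_R of one genome (positive burden)."""
    d = _check_complete(dosages)
    s = table["s"].to_numpy(dtype=float)
    h = table["h"].to_numpy(dtype=float)
    return float(np.abs(s[d == 2]).sum() + np.abs(h[d == 1] * s[d == 1]).sum())


def fitness_matrix(dosages: np.ndarray, table: pd.DataFrame) -> np.ndarray:
    """W for every row of an (n_individuals, n_sites) dosage matrix."""
    d = np.asarray(dosages)
    s = table["s"].to_numpy(dtype=float)
    h = table["h"].to_numpy(dtype=float)
    log_hom = np.log1p(s)
    log_het = np.log1p(h * s)
    return np.exp((d == 2) @ log_hom + (d == 1) @ log_het)


def realized_load_matrix(dosages: np.ndarray, table: pd.DataFrame) -> np.ndarray:
    """L_R for every row of a dosage matrix."""
    d = np.asarray(dosages)
    s = table["s"].to_numpy(dtype=float)
    h = table["h"].to_numpy(dtype=float)
    return (d == 2) @ np.abs(s) + (d == 1) @ np.abs(h * s)


FLAG_COLUMNS = ("conserved_deleterious", "missense_conserved", "lof")


def load_summary(gm: GenotypeMatrix, table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Hom/het load counts per individual and fixation summaries per population.

    Only complete-case sites (called in every individual) contribute.
    Returns ``{"individual": ..., "population": ...}`` DataFrames.  The
    individual table has one row per sample with hom/het counts per
    deleterious flag and per severity bin, plus fitness cost W and realized
    load L_R.  The population table counts segregating-deleterious sites
    (>= 1 derived allele at a conserved-deleterious site), fixed-derived
    sites (dosage 2 in every sampled member), fixed-deleterious sites and
    their proportion of fixed-derived.
    """
    if gm.n_individuals == 0:
        raise ValueError("empty cohort")
    keep = gm.complete_case_mask()
    d = gm.dosages[:, keep]
    t = table.loc[keep].reset_index(drop=True)

    rows = []
    for i, sample in enumerate(gm.samples):
        hom = d[i] == 2
        het = d[i] == 1
        row: dict[str, object] = {
            "sample": sample,
            "population": gm.populations[i],
            "hom_derived": int(hom.sum()),
            "het_derived": int(het.sum()),
        }
        for flag in FLAG_COLUMNS:
            f = t[flag].to_numpy(dtype=bool)
            row[f"hom_{flag}"] = int((hom & f).sum())
            row[f"het_{flag}"] = int((het & f).sum())
        for b in ("neutral", "mild", "moderate", "severe"):
            m = t["bin"].to_numpy() == b
            row[f"hom_{b}"] = int((hom & m).sum())
            row[f"het_{b}"] = int((het & m).sum())
        row["fitness_cost"] = genome_fitness(d[i], t)
        row["realized_load"] = realized_load(d[i], t)
        rows.append(row)
    individual = pd.DataFrame(rows)

    pops = []
    deleterious = t["conserved_deleterious"].to_numpy(dtype=bool)
    for pop in dict.fromkeys(gm.populations):
        idx = [i for i, p in enumerate(gm.populations) if p == pop]
        dp = d[idx]
        carries = (dp > 0).any(axis=0)
        fixed = (dp == 2).all(axis=0)
        segregating = carries & ~fixed
        n_fixed = int(fixed.sum())
        n_fixed_del = int((fixed & deleterious).sum())
        pops.append(
            {
                "population": pop,
                "n_individuals": len(idx),
                "segregating_deleterious": int((segregating & deleterious).sum()),
                "sites_with_derived": int(carries.sum()),
                "fixed_derived": n_fixed,
                "fixed_deleterious": n_fixed_del,
                "prop_fixed_deleterious": (n_fixed_del / n_fixed) if n_fixed else np.nan,
            }
        )
    return {"individual": individual, "population": pd.DataFrame(pops)}


def fixed_deleterious_test(
    popA_counts: tuple[int, int], popB_counts: tuple[int, int]
) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on a 2x2 table of
    (fixed deleterious, fixed non-deleterious) counts for two populations."""
    table = np.array([popA_counts, popB_counts], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero margin in 2x2 table")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def heterozygosity(
    sample_dosages: np.ndarray,
    gq: np.ndarray | None,
    gapless_length: float,
    *,
    min_gq: int = 20,
    max_missing: float = 0.30,
) -> np.ndarray:
    """Per-bp heterozygosity per sample, call-rate adjusted.

    Genotypes with GQ below ``min_gq`` are set missing; sites missing in
    more than ``max_missing`` of the cohort are dropped; each sample's het
    count is divided by ``gapless_length`` times its call rate over the
    retained sites.
    """
    if gapless_length <= 0:
        raise ValueError("gapless_length must be positive")
    d = np.array(sample_dosages, dtype=np.int8, copy=True)
    if d.ndim == 1:
        d = d[None, :]
    if gq is not None:
        gq = np.asarray(gq)
        d[gq < min_gq] = MISSING
    miss_frac = (d == MISSING).mean(axis=0)
    keep = miss_frac <= max_missing
    d = d[:, keep]
    called = (d != MISSING).sum(axis=1)
    if (called == 0).any() or d.shape[1] == 0:
        raise ValueError("a sample has call rate 0 after filtering")
    call_rate = called / d.shape[1]
    het = (d == 1).sum(axis=1)
    return het / (gapless_length * call_rate)


def private_alleles(gmA: GenotypeMatrix, gmB: GenotypeMatrix) -> pd.DataFrame:
    """Derived alleles present in one population and absent from the other.

    Both matrices must share the site list.  An allele is private to A when
    at least one copy is observed in A and none in B; the proportion is
    relative to sites polymorphic (segregating) within that population.
    Sites with any missing genotype in either cohort are excluded.
    """
    if gmA.n_sites != gmB.n_sites:
        raise ValueError("populations must share the site list")
    keep = gmA.complete_case_mask() & gmB.complete_case_mask()
    dA, dB = gmA.dosages[:, keep], gmB.dosages[:, keep]
    presentA, presentB = (dA > 0).any(axis=0), (dB > 0).any(axis=0)
    polyA = presentA & ~(dA == 2).all(axis=0)
    polyB = presentB & ~(dB == 2).all(axis=0)
    privA = presentA & ~presentB
    privB = presentB & ~presentA
    return pd.DataFrame(
        {
            "population": ["A", "B"],
            "private": [int(privA.sum()), int(privB.sum())],
            "polymorphic": [int(polyA.sum()), int(polyB.sum())],
            "prop_private": [
                int(privA.sum()) / int(polyA.sum()) if polyA.any() else np.nan,
                int(privB.sum()) / int(polyB.sum()) if polyB.any() else np.nan,
            ],
        }
    )


def projection_weights(d: int, n: int, m: int) -> np.ndarray:
    """Hypergeometric weights over derived counts j = 0..m when down-sampling
    a site with d derived of n called alleles to m alleles."""
    if m <= 0:
        raise ValueError("projection size must be positive")
    if n < m:
        raise ValueError("cannot project up")
    j = np.arange(m + 1)
    with np.errstate(divide="ignore"):
        logw = (
            _log_comb(d, j) + _log_comb(n - d, m - j) - _log_comb(n, m)
        )
    w = np.exp(logw)
    w[(j > d) | (m - j > n - d)] = 0.0
    return w


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    out = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return np.where((k < 0) | (k > n), -np.inf, out)


def project_sfs2d(gmA: GenotypeMatrix, gmB: GenotypeMatrix, m1: int, m2: int) -> np.ndarray:
    """Joint derived-allele site-frequency spectrum projected to (m1, m2) alleles.

    Each site contributes the outer product of its two populations'
    hypergeometric projection weights; sites with fewer called alleles than
    the projection size in either population are dropped.  The returned
    (m1+1) x (m2+1) matrix therefore has total mass equal to the number of
    projectable sites.
    """
    if m1 <= 0 or m2 <= 0:
        raise ValueError("projection sizes must be positive")
    if gmA.n_sites != gmB.n_sites:
        raise ValueError("populations must share the site list")
    if m1 > 2 * gmA.n_individuals or m2 > 2 * gmB.n_individuals:
        raise ValueError("projection size exceeds sampled alleles")
    sfs = np.zeros((m1 + 1, m2 + 1))
    dA, dB = gmA.dosages, gmB.dosages
    calledA = (dA != MISSING).sum(axis=0) * 2
    calledB = (dB != MISSING).sum(axis=0) * 2
    derivedA = np.where(dA == MISSING, 0, dA).sum(axis=0)
    derivedB = np.where(dB == MISSING, 0, dB).sum(axis=0)
    ok = (calledA >= m1) & (calledB >= m2)
    for site in np.nonzero(ok)[0]:
        wA = projection_weights(int(derivedA[site]), int(calledA[site]), m1)
        wB = projection_weights(int(derivedB[site]), int(calledB[site]), m2)
        sfs += np.outer(wA, wB)
    return sfs
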