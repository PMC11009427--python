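"""Runs of homozygosity: HMM detection, F_ROH, timing, and load enrichment.

Autozygous tracts are called per individual per scaffold with a two-state
hidden Markov model over biallelic genotypes: state HW (non-autozygous)
emits heterozygotes at the Hardy–Weinberg rate 2p(1-p), state AZ
(autozygous) emits them only at a small error rate eps.  Transition
probabilities between adjacent markers at distance d bp are
P(HW->AZ) = 1 - exp(-alpha*d) and P(AZ->HW) = 1 - exp(-beta*d).  Segments
are the maximal runs of Viterbi-AZ markers; their quality is the median
phred-scaled AZ posterior from the forward–backward pass, capped at 99.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

MB = 1_000_000

#: Mean IBD tract material transmitted per generation; a tract of length L
#: Mb therefore dates its common ancestor ~50/L generations back.
IBD_MB_PER_GENERATION = 50.0


@dataclass(frozen=True)
class RohParams:
    """HMM parameters. Defaults mirror the published bcftools roh settings."""

    eps: float = 1e-3  # het emission probability in the AZ state
    hw_to_az: float = 6.7e-8  # alpha, per bp
    az_to_hw: float = 5e-9  # beta, per bp
    init_az: float = 0.5  # P(AZ) at the first marker


@dataclass(frozen=True)
class ROHSegment:
    scaffold: str
    start: int  # 0-based, inclusive
    end: int  # exclusive
    quality: float
    n_sites: int

    @property
    def length(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")


def _hmm_matrices(dosages, positions, allele_freqs, params):
    """Log-emissions and per-gap log-transition matrices for one scaffold.

    Returns (kept site index, log_emission (n,2), log_trans (n-1,2,2)) with
    state order (HW, AZ).  Sites with p outside (0,1) or missing genotype
    are skipped.
    """
    d = np.asarray(dosages)
    pos = np.asarray(positions, dtype=np.int64)
    p = np.asarray(allele_freqs, dtype=float)
    if np.any(np.diff(pos) <= 0):
        raise ValueError("site positions must be strictly increasing")
    keep = (p > 0) & (p < 1) & (d != -1)
    d, pos, p = d[keep], pos[keep], p[keep]
    het = d == 1
    p_het_hw = 2 * p * (1 - p)
    e_hw = np.where(het, p_het_hw, 1 - p_het_hw)
    e_az = np.where(het, params.eps, 1 - params.eps)
    log_e = np.log(np.column_stack([e_hw, e_az]))
    gaps = np.diff(pos).astype(float)
    t_ha = -np.expm1(-params.hw_to_az * gaps)  # 1 - exp(-alpha d)
    t_ah = -np.expm1(-params.az_to_hw * gaps)
    log_t = np.log(
        np.stack(
            [
                np.column_stack([1 - t_ha, t_ha]),
                np.column_stack([t_ah, 1 - t_ah]),
            ],
            axis=1,
        )
    )  # (n-1, from_state, to_state)
    return np.nonzero(keep)[0], log_e, log_t


def viterbi_path(log_e: np.ndarray, log_t: np.ndarray, log_init: np.ndarray) -> np.ndarray:
    """Most probable state sequence; ties break toward HW (state 0)."""
    n = log_e.shape[0]
    delta = log_init + log_e[0]
    back = np.zeros((n, 2), dtype=np.int8)
    for i in range(1, n):
        cand = delta[:, None] + log_t[i - 1]  # (from, to)
        back[i] = np.argmax(cand, axis=0)
        delta = cand[back[i], [0, 1]] + log_e[i]
    path = np.zeros(n, dtype=np.int8)
    path[-1] = int(np.argmax(delta))
    for i in range(n - 1, 0, -1):
        path[i - 1] = back[i, path[i]]
    return path


def forward_backward(log_e: np.ndarray, log_t: np.ndarray, log_init: np.ndarray) -> np.ndarray:
    """Posterior state probabilities, (n, 2), rows summing to 1."""
    n = log_e.shape[0]
    log_a = np.zeros((n, 2))
    log_a[0] = log_init + log_e[0]
    for i in range(1, n):
        log_a[i] = log_e[i] + logsumexp(log_a[i - 1][:, None] + log_t[i - 1], axis=0)
    log_b = np.zeros((n, 2))
    for i in range(n - 2, -1, -1):
        log_b[i] = logsumexp(log_t[i] + (log_e[i + 1] + log_b[i + 1])[None, :], axis=1)
    log_post = log_a + log_b
    log_post -= logsumexp(log_post, axis=1)[:, None]
    return np.exp(log_post)


def detect_roh(
    sample_dosages: np.ndarray,
    site_positions: np.ndarray,
    allele_freqs: np.ndarray,
    params: RohParams = RohParams(),
    scaffold: str = "scaffold",
) -> list[ROHSegment]:
    """Call autozygous segments for one sample on one scaffold.

    Segments span from the first to the last AZ-decoded marker (0-based
    half-open).  Quality is the median phred posterior of AZ over the
    segment's markers, capped at 99.
    """
    kept_idx, log_e, log_t = _hmm_matrices(sample_dosages, site_positions, allele_freqs, params)
    if len(kept_idx) == 0:
        return []
    pos = np.asarray(site_positions, dtype=np.int64)[kept_idx]
    log_init = np.log([1 - params.init_az, params.init_az])
    path = viterbi_path(log_e, log_t, log_init)
    post_az = forward_backward(log_e, log_t, log_init)[:, 1]
    phred = -10 * np.log10(np.clip(1 - post_az, 1e-10, None))
    phred = np.minimum(phred, 99.0)

    segments: list[ROHSegment] = []
    in_az = np.flatnonzero(path == 1)
    if len(in_az) == 0:
        return segments
    breaks = np.flatnonzero(np.diff(in_az) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(in_az) - 1]])
    for s, e in zip(starts, ends):
        i0, i1 = in_az[s], in_az[e]
        segments.append(
            ROHSegment(
                scaffold=scaffold,
                start=int(pos[i0]),
                end=int(pos[i1]) + 1,
                quality=float(np.median(phred[i0 : i1 + 1])),
                n_sites=int(i1 - i0 + 1),
            )
        )
    return segments


def froh(
    segments: list[ROHSegment],
    genome_length: float,
    min_length: float = 1 * MB,
    min_quality: float = 30.0,
) -> float:
    """Genomic inbreeding coefficient: fraction of the genome in qualifying ROH."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    total = sum(s.length for s in segments if s.length > min_length and s.quality > min_quality)
    return total / genome_length


def generations_since_inbreeding(tract_length_mb: float) -> float:
    """Generations back to the common ancestor of a tract of the given length (Mb)."""
    if tract_length_mb <= 0:
        raise ValueError("tract length must be positive")
    return IBD_MB_PER_GENERATION / tract_length_mb


def roh_profile(
    segments_by_individual: dict[str, list[ROHSegment]],
    group_labels: dict[str, str],
    genome_length: float,
    *,
    grid_step: int = 10_000,
    window: int = 1 * MB,
) -> dict[str, pd.DataFrame]:
    """Cumulative ROH-length curves, group means, and sliding-window slopes.

    For each individual the curve at tract length L is the summed length of
    ROH with length <= L, as a fraction of the genome.  Group mean curves
    are compared through their local slopes in 1 Mb windows advanced by the
    grid step; a steeper slope marks greater representation of that tract
    length in that group.
    """
    max_len = max(
        (s.length for segs in segments_by_individual.values() for s in segs), default=window
    )
    grid = np.arange(0, max_len + window + grid_step, grid_step)

    curves = {}
    for ind, segs in segments_by_individual.items():
        lengths = np.sort([s.length for s in segs])
        csum = np.concatenate([[0.0], np.cumsum(lengths)]) / genome_length
        idx = np.searchsorted(lengths, grid, side="right")
        curves[ind] = csum[idx]
    curve_df = pd.DataFrame(curves, index=grid)
    curve_df.index.name = "tract_length"

    groups = sorted(set(group_labels.values()))
    mean_df = pd.DataFrame(
        {
            g: curve_df[[i for i in curves if group_labels[i] == g]].mean(axis=1)
            for g in groups
        },
        index=grid,
    )

    half = window // 2
    centers = grid[(grid >= half) & (grid <= grid[-1] - half)]
    slopes = {}
    for g in groups:
        c = mean_df[g].to_numpy()
        lo = np.searchsorted(grid, centers - half)
        hi = np.searchsorted(grid, centers + half)
        slopes[g] = (c[hi] - c[lo]) / window
    slope_df = pd.DataFrame(slopes, index=centers)
    slope_df.index.name = "window_center"
    if len(groups) == 2:
        slope_df["difference"] = slope_df[groups[0]] - slope_df[groups[1]]
    return {"individual": curve_df, "group_mean": mean_df, "slopes": slope_df}


DEFAULT_LENGTH_BINS = ((0.1 * MB, 0.5 * MB), (0.5 * MB, 1 * MB), (1 * MB, 3 * MB), (3 * MB, np.inf))


def _bin_of_length(length: float, bins) -> int:
    for k, (lo, hi) in enumerate(bins):
        if lo <= length < hi:
            return k
    return -1


def _bin_midpoints(bins) -> np.ndarray:
    mids = []
    widths = [hi - lo for lo, hi in bins if np.isfinite(hi)]
    for lo, hi in bins:
        mids.append((lo + hi) / 2 if np.isfinite(hi) else lo + widths[-1] / 2)
    return np.asarray(mids)


def roh_enrichment(
    segments_by_individual: dict[str, list[ROHSegment]],
    gm,
    table: pd.DataFrame,
    bins=DEFAULT_LENGTH_BINS,
    min_paired_length: float = 1 * MB,
) -> dict[str, object]:
    """Deleterious enrichment of homozygous sites inside ROH, by length bin.

    Per individual and bin: the proportion of homozygous-derived sites that
    are conserved-deleterious, and the ratio of missense-conserved to
    low-impact homozygous sites.  Across bins, each statistic is regressed
    on the bin midpoint.  Paired t-tests compare, per individual, the
    hom-deleterious proportion inside ROH > ``min_paired_length`` against
    (a) the hom-deleterious proportion and (b) the het-deleterious
    proportion outside all ROH.
    """
    scaffold = table["scaffold"].to_numpy(dtype=object)
    pos = table["pos"].to_numpy(dtype=np.int64)
    conserved = table["conserved_deleterious"].to_numpy(dtype=bool)
    missense = table["missense_conserved"].to_numpy(dtype=bool)
    low = (table["impact"].to_numpy(dtype=object) == "LOW")

    rows = []
    paired = []
    for i, ind in enumerate(gm.samples):
        segs = segments_by_individual.get(ind, [])
        site_bin = np.full(len(table), -2, dtype=np.int8)  # -2 = outside ROH
        in_long = np.zeros(len(table), dtype=bool)
        for seg in segs:
            m = (scaffold == seg.scaffold) & (pos >= seg.start) & (pos < seg.end)
            site_bin[m] = _bin_of_length(seg.length, bins)
            if seg.length > min_paired_length:
                in_long[m] = True
        hom = gm.dosages[i] == 2
        het = gm.dosages[i] == 1
        for k in range(len(bins)):
            in_bin = site_bin == k
            n_hom = int((hom & in_bin).sum())
            n_low = int((hom & in_bin & low).sum())
            rows.append(
                {
                    "sample": ind,
                    "bin": k,
                    "bin_midpoint": _bin_midpoints(bins)[k],
                    "n_hom": n_hom,
                    "prop_conserved": (hom & in_bin & conserved).sum() / n_hom
                    if n_hom
                    else np.nan,
                    "ratio_missense_low": (hom & in_bin & missense).sum() / n_low
                    if n_low
                    else np.nan,
                }
            )
        outside = site_bin == -2
        n_hom_long = int((hom & in_long).sum())
        n_hom_out = int((hom & outside).sum())
        n_het_out = int((het & outside).sum())
        paired.append(
            {
                "sample": ind,
                "roh_hom_prop": (hom & in_long & conserved).sum() / n_hom_long
                if n_hom_long
                else np.nan,
                "outside_hom_prop": (hom & outside & conserved).sum() / n_hom_out
                if n_hom_out
                else np.nan,
                "outside_het_prop": (het & outside & conserved).sum() / n_het_out
                if n_het_out
                else np.nan,
            }
        )
    per_bin = pd.DataFrame(rows)
    paired_df = pd.DataFrame(paired)

    regressions = {}
    for stat in ("prop_conserved", "ratio_missense_low"):
        ok = per_bin[stat].notna()
        if ok.sum() >= 3 and per_bin.loc[ok, "bin_midpoint"].nunique() >= 2:
            res = stats.linregress(per_bin.loc[ok, "bin_midpoint"], per_bin.loc[ok, stat])
            regressions[stat] = {"slope": res.slope, "p": res.pvalue}
        else:
            regressions[stat] = {"slope": np.nan, "p": np.nan}

    tests = {}
    for name, col in (("vs_outside_hom", "outside_hom_prop"), ("vs_outside_het", "outside_het_prop")):
        ok = paired_df[["roh_hom_prop", col]].notna().all(axis=1)
        a = paired_df.loc[ok, "roh_hom_prop"]
        b = paired_df.loc[ok, col]
        diffs = a.to_numpy() - b.to_numpy()
        if len(diffs) >= 2 and np.std(diffs, ddof=1) == 0:
            raise ValueError("paired t-test undefined: zero variance of differences")
        t, p = stats.ttest_rel(a, b) if len(diffs) >= 2 else (np.nan, np.nan)
        tests[name] = {"t": float(t), "p": float(p), "n": int(len(diffs))}

    return {"per_bin": per_bin, "paired": paired_df, "regressions": regressions, "t_tests": tests}
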