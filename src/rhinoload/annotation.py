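"""Variant polarization, GERP severity binning, and deleterious flags.

A variant table is a :class:`pandas.DataFrame` with one row per biallelic
site, columns ``scaffold, pos, ref, alt`` plus, as they are attached by the
functions here, ``ancestral_state`` (``ref``/``alt``/``unknown``), ``rs``
(GERP rejected-substitutions score, NaN when the site has no score),
``impact`` (``LOW``/``MODERATE``/``LOF``/``NONE``), ``bin``
(``neutral``/``mild``/``moderate``/``severe``), selection coefficient ``s``,
dominance coefficient ``h``, and the boolean flags
``conserved_deleterious``, ``missense_conserved``, ``lof``.

Positions are 0-based and strictly increasing within each scaffold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

BINS = ("neutral", "mild", "moderate", "severe")

#: Left-closed RS boundaries between mild/moderate/severe; anything below
#: the first boundary (including missing RS) is neutral.
DEFAULT_BOUNDARIES = (2.0, 4.0, 5.8)

#: RS threshold above which a site counts as evolutionarily conserved.
CONSERVED_RS = 4.0

IMPACTS = ("LOW", "MODERATE", "LOF", "NONE")


@dataclass(frozen=True)
class CoefficientSet:
    """Per-bin selection (s <= 0) and dominance (0 <= h <= 0.5) coefficients."""

    name: str
    s_by_bin: dict[str, float]
    h_by_bin: dict[str, float]

    def __post_init__(self) -> None:
        for b in BINS:
            if b not in self.s_by_bin or b not in self.h_by_bin:
                raise ValueError(f"coefficient set {self.name!r} missing bin {b!r}")
        if self.s_by_bin["neutral"] != 0.0:
            raise ValueError("neutral selection coefficient must be 0")
        if any(s > 0 for s in self.s_by_bin.values()):
            raise ValueError("selection coefficients must be <= 0")
        if any(not (0.0 <= h <= 0.5) for h in self.h_by_bin.values()):
            raise ValueError("dominance coefficients must lie in [0, 0.5]")


#: Human-genome-derived coefficients (the default simulation set).
HENN_COEFFICIENTS = CoefficientSet(
    name="henn",
    s_by_bin={"neutral": 0.0, "mild": -0.0001, "moderate": -0.001, "severe": -0.002},
    h_by_bin={"neutral": 0.5, "mild": 0.293, "moderate": 0.062, "severe": 0.033},
)

#: Stronger alternate selection coefficients used as a sensitivity check.
#: No dominance values accompany this set; the default h values are reused.
PEISCHL_COEFFICIENTS = CoefficientSet(
    name="peischl",
    s_by_bin={"neutral": 0.0, "mild": -0.024, "moderate": -0.032, "severe": -0.072},
    h_by_bin={"neutral": 0.5, "mild": 0.293, "moderate": 0.062, "severe": 0.033},
)

COEFFICIENT_SETS = {c.name: c for c in (HENN_COEFFICIENTS, PEISCHL_COEFFICIENTS)}


def classify_severity(
    rs_score: float,
    coefficients: CoefficientSet = HENN_COEFFICIENTS,
    boundaries: tuple[float, float, float] = DEFAULT_BOUNDARIES,
) -> tuple[str, float, float]:
    """Map an RS score to its severity bin and (s, h) coefficients.

    Bins are left-closed: RS in [2, 4) is mild, [4, 5.8) moderate,
    >= 5.8 severe.  Everything below 2 — including strongly negative
    scores and missing (NaN) scores — is treated as neutral.
    """
    b0, b1, b2 = boundaries
    if rs_score is None or (isinstance(rs_score, float) and np.isnan(rs_score)):
        bin_ = "neutral"
    elif rs_score >= b2:
        bin_ = "severe"
    elif rs_score >= b1:
        bin_ = "moderate"
    elif rs_score >= b0:
        bin_ = "mild"
    else:
        bin_ = "neutral"
    return bin_, coefficients.s_by_bin[bin_], coefficients.h_by_bin[bin_]


def assign_bins(
    table: pd.DataFrame,
    coefficients: CoefficientSet = HENN_COEFFICIENTS,
    boundaries: tuple[float, float, float] = DEFAULT_BOUNDARIES,
) -> pd.DataFrame:
    """Vectorised :func:`classify_severity` over a variant table.

    Returns a copy with ``bin``, ``s`` and ``h`` columns attached.
    """
    rs = pd.to_numeric(table["rs"], errors="coerce").to_numpy(dtype=float)
    b0, b1, b2 = boundaries
    bins = np.full(len(rs), "neutral", dtype=object)
    with np.errstate(invalid="ignore"):
        bins[rs >= b0] = "mild"
        bins[rs >= b1] = "moderate"
        bins[rs >= b2] = "severe"
    out = table.copy()
    out["bin"] = bins
    out["s"] = [coefficients.s_by_bin[b] for b in bins]
    out["h"] = [coefficients.h_by_bin[b] for b in bins]
    return out


def polarize_alleles(
    focal_sites: pd.DataFrame,
    outgroup1_gt: np.ndarray,
    outgroup2_gt: np.ndarray,
) -> pd.DataFrame:
    """Assign ancestral/derived states from two outgroup genomes.

    ``outgroup*_gt`` are (n_sites, 2) arrays of allele strings aligned to
    ``focal_sites`` row order; missing genotypes are encoded as ``"."`` or
    ``None``.  The ancestral allele is the one homozygous in *both*
    outgroups; sites where the outgroups are heterozygous, disagree, carry
    an allele that is neither ref nor alt, or are missing, are marked
    ``unknown`` (and downstream analyses drop them).
    """
    out1 = np.asarray(outgroup1_gt, dtype=object)
    out2 = np.asarray(outgroup2_gt, dtype=object)
    n = len(focal_sites)
    if out1.shape != (n, 2) or out2.shape != (n, 2):
        raise ValueError(
            f"outgroup genotypes must align with the {n} focal sites; "
            f"got shapes {out1.shape} and {out2.shape}"
        )

    ref = focal_sites["ref"].to_numpy(dtype=object)
    alt = focal_sites["alt"].to_numpy(dtype=object)

    def _missing(a) -> bool:
        return a is None or a == "." or a == ""

    state = np.full(n, "unknown", dtype=object)
    for i in range(n):
        a1, b1 = out1[i]
        a2, b2 = out2[i]
        if _missing(a1) or _missing(b1) or _missing(a2) or _missing(b2):
            continue
        # single allele across both outgroups, and it must be ref or alt
        if a1 == b1 == a2 == b2:
            if a1 == ref[i]:
                state[i] = "ref"
            elif a1 == alt[i]:
                state[i] = "alt"

    out = focal_sites.copy()
    out["ancestral_state"] = state
    return out


def flag_deleterious(table: pd.DataFrame) -> pd.DataFrame:
    """Attach the three deleterious-variant flags.

    ``conserved_deleterious``: RS > 4 (evolutionary constraint alone);
    ``missense_conserved``: moderate protein impact at a conserved site;
    ``lof``: predicted loss of function.  Sites with missing RS never get
    the conservation-based flags.
    """
    rs = pd.to_numeric(table["rs"], errors="coerce").to_numpy(dtype=float)
    impact = table["impact"].to_numpy(dtype=object)
    with np.errstate(invalid="ignore"):
        conserved = (rs > CONSERVED_RS) & ~np.isnan(rs)
    out = table.copy()
    out["conserved_deleterious"] = conserved
    out["missense_conserved"] = conserved & (impact == "MODERATE")
    out["lof"] = impact == "LOF"
    return out


def annotate(
    table: pd.DataFrame,
    coefficients: CoefficientSet = HENN_COEFFICIENTS,
    boundaries: tuple[float, float, float] = DEFAULT_BOUNDARIES,
) -> pd.DataFrame:
    """Bins + coefficients + deleterious flags in one pass."""
    return flag_deleterious(assign_bins(table, coefficients, boundaries))


def validate_table(table: pd.DataFrame) -> None:
    """Check the structural invariants downstream code relies on."""
    grouped = table.groupby("scaffold", sort=False)["pos"]
    if not grouped.apply(lambda p: bool(np.all(np.diff(p.to_numpy()) > 0))).all():
        raise ValueError("positions must be strictly increasing within scaffolds")
    if "bin" in table.columns and "s" in table.columns:
        neutral = table["bin"].to_numpy() == "neutral"
        s_zero = table["s"].to_numpy() == 0.0
        if not np.array_equal(neutral, s_zero):
            raise ValueError("s == 0 must hold exactly for neutral sites")
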