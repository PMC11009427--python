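import numpy as np
import pandas as pd
import pytest

from rhinoload import CohortSpec, GenotypeMatrix, generate_benchmark_cohort, generate_founder_cohort
from rhinoload.annotation import annotate


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale-but-fast cohort: 1/10th the default site counts."""
    return CohortSpec(
        sites_per_bin={"neutral": 4000, "mild": 600, "moderate": 300, "severe": 100},
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_founder_cohort(small_spec)


@pytest.fixture(scope="session")
def small_benchmark(small_spec, small_cohort):
    _, table, _ = small_cohort
    return generate_benchmark_cohort(small_spec, table)


def toy_table(s_h_pairs, **extra):
    """Variant table from explicit (s, h) pairs, one row per site."""
    n = len(s_h_pairs)
    base = {
        "scaffold": ["s0"] * n,
        "pos": np.arange(n) * 1000,
        "ref": ["A"] * n,
        "alt": ["G"] * n,
        "ancestral_state": ["ref"] * n,
        "s": [s for s, _ in s_h_pairs],
        "h": [h for _, h in s_h_pairs],
    }
    base.update(extra)
    return pd.DataFrame(base)


def annotated_toy_table(rs_scores, impacts):
    table = pd.DataFrame(
        {
            "scaffold": ["s0"] * len(rs_scores),
            "pos": np.arange(len(rs_scores)) * 1000,
            "ref": ["A"] * len(rs_scores),
            "alt": ["G"] * len(rs_scores),
            "ancestral_state": ["ref"] * len(rs_scores),
            "rs": rs_scores,
            "impact": impacts,
        }
    )
    return annotate(table)


def make_gm(dosages, populations=None, gq=None):
    dosages = np.asarray(dosages, dtype=np.int8)
    n = dosages.shape[0]
    return GenotypeMatrix(
        samples=[f"ind{i}" for i in range(n)],
        populations=populations or ["pop"] * n,
        dosages=dosages,
        gq=gq,
    )
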