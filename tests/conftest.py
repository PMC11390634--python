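import numpy as np
import pandas as pd
import pytest

from dtmr.mr import pairs_frame
from dtmr.simulate import SimulationConfig, simulate_pair


def make_sumstats(rows):
    """Canonical summary-statistic frame from (vid, chrom, pos, ea, oa, eaf,
    beta, se, pval, n) tuples."""
    return pd.DataFrame(
        rows,
        columns=[
            "variant_id", "chrom", "pos", "effect_allele", "other_allele",
            "eaf", "beta", "se", "pval", "n",
        ],
    )


@pytest.fixture
def two_snp_pairs():
    """The closed-form IVW fixture: beta 0.24, fixed se 1/sqrt(125), Q = 0.8."""
    return pairs_frame(
        beta_exp=[1.0, 1.0],
        se_exp=[0.01, 0.01],
        beta_out=[0.2, 0.4],
        se_out=[0.1, 0.2],
        variant_id=["rsA", "rsB"],
    )


@pytest.fixture
def random_pairs_factory():
    """Random harmonized-pair frames for property and oracle tests."""

    def _make(seed, k=10, slope=0.1):
        rng = np.random.default_rng(seed)
        bx = rng.uniform(0.02, 0.06, k) * rng.choice([-1, 1], k)
        sx = rng.uniform(0.003, 0.008, k)
        sy = rng.uniform(0.003, 0.01, k)
        by = slope * bx + rng.standard_normal(k) * sy
        return pairs_frame(bx, sx, by, sy)

    return _make


def independent_instruments_config(seed, n_instruments=20, true_effect=0.1,
                                   **overrides):
    """Config giving exactly n independent, non-palindromic instruments."""
    kwargs = dict(
        n_genes=n_instruments,
        snps_per_gene=1,
        n_null_snps=0,
        palindrome_frac=0.0,
        ld_block_r2=0.0,
        true_effect=true_effect,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def simulated_pairs(seed, n_instruments=20, true_effect=0.1, **overrides):
    """Simulate and merge exposure/outcome into a harmonized-pairs frame.

    Alleles match by construction (shared variant rows), so the merge is the
    harmonization identity; used where tests need many fast replicates.
    """
    study = simulate_pair(
        independent_instruments_config(seed, n_instruments, true_effect, **overrides)
    )
    return pairs_frame(
        beta_exp=study.exposure["beta"].to_numpy(),
        se_exp=study.exposure["se"].to_numpy(),
        beta_out=study.outcome["beta"].to_numpy(),
        se_out=study.outcome["se"].to_numpy(),
        variant_id=study.exposure["variant_id"].tolist(),
    ), study
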