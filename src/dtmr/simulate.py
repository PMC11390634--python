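"""Synthetic exposure/outcome GWAS summary statistics with known truth.

The generator emulates the summary-statistic setting two-sample MR assumes:
an exposure (systolic blood pressure, mmHg) with true per-SNP effects
concentrated inside drug-target gene windows and ~zero elsewhere, and a
binary outcome generated directly on the log-odds scale, causally downstream
of the exposure with a configurable effect.  Observed effects are the true
effects plus normal noise at the usual GWAS standard error
``1/sqrt(2·n·eaf·(1−eaf))``; within an LD block, observed effects are
correlated with correlation ``sqrt(r²)``.  A configurable fraction of
instruments receives a direct (pleiotropic) outcome effect, violating the
exclusion restriction; the truth table records which instruments remain
valid.

True instrument effect sizes are drawn as |z|-scores uniform on
``instrument_z_range`` times each SNP's standard error, which puts per-SNP
F-statistics in the ~40–75 range typical of well-powered drug-target
instruments.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .sumstats_io import LDTable, SUMSTAT_FIELDS

_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_NONPAL_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]

TRUTH_COLUMNS = (
    "variant_id",
    "gene_symbol",
    "ld_block_id",
    "true_exposure_beta",
    "true_direct_outcome_beta",
    "is_instrument_valid",
)


@dataclass
class SimulationConfig:
    """Generative settings for one exposure/outcome study pair.

    Defaults describe a small but realistic drug-target study: 4 target
    genes of 5 SNPs each plus 50 null SNPs, GWAS sample sizes of 100 000,
    a causal effect of 0.1 log-odds per unit exposure, no pleiotropy,
    moderate within-gene LD, and a realistic share of palindromic variants.
    """

    n_genes: int = 4
    window_bp: int = 100_000
    snps_per_gene: int = 5
    n_null_snps: int = 50
    n_exp: int = 100_000
    n_out: int = 100_000
    true_effect: float = 0.1
    pleiotropy_frac: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.05
    ld_block_r2: float = 0.3
    palindrome_frac: float = 0.15
    eaf_range: tuple[float, float] = (0.05, 0.5)
    instrument_z_range: tuple[float, float] = (6.5, 8.5)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "window_bp", "snps_per_gene", "n_null_snps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("n_exp", "n_out"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("pleiotropy_frac", "ld_block_r2", "palindrome_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        lo, hi = self.eaf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("eaf_range must satisfy 0 < lo <= hi < 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("eaf_range", "instrument_z_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


class SimulatedStudy(NamedTuple):
    exposure: pd.DataFrame
    outcome: pd.DataFrame
    regions: pd.DataFrame
    ld: LDTable
    truth: pd.DataFrame


def _empty_sumstats() -> pd.DataFrame:
    df = pd.DataFrame(columns=list(SUMSTAT_FIELDS))
    df["pos"] = df["pos"].astype(np.int64)
    return df


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.maximum(p, 1e-320)  # validation requires p > 0


def _block_noise(rng: np.random.Generator, block_id: np.ndarray, r2: float) -> np.ndarray:
    """Standard-normal noise with within-block correlation sqrt(r2)."""
    eps = rng.standard_normal(len(block_id))
    if r2 <= 0:
        return eps
    a = r2 ** 0.25  # corr(e_i, e_j) = a**2 = sqrt(r2)
    blocks = np.unique(block_id[block_id >= 0])
    shared = {b: rng.standard_normal() for b in blocks}
    mix = np.sqrt(1 - a**2)
    out = eps.copy()
    for i, b in enumerate(block_id):
        if b >= 0:
            out[i] = a * shared[b] + mix * eps[i]
    return out


def simulate_pair(config: SimulationConfig) -> SimulatedStudy:
    """Generate one exposure/outcome study pair with its truth table.

    Deterministic for a fixed config (including the seed).  Returns
    exposure and outcome summary-statistic frames, gene regions (1-based
    inclusive), a within-block LD table, and the truth table.
    """
    rng = np.random.default_rng(config.seed)
    m_gene = config.n_genes * config.snps_per_gene
    m = m_gene + config.n_null_snps

    gene_symbols = [f"GENE{i + 1}" for i in range(config.n_genes)]
    starts = 1_000_000 + 5_000_000 * np.arange(config.n_genes, dtype=np.int64)
    regions = pd.DataFrame(
        {
            "gene_symbol": gene_symbols,
            "chrom": "1",
            "start": starts,
            "end": starts + 49_999,
        }
    )
    if m == 0:
        empty_truth = pd.DataFrame(columns=list(TRUTH_COLUMNS))
        return SimulatedStudy(
            _empty_sumstats(), _empty_sumstats(), regions, LDTable(), empty_truth
        )

    # layout: gene SNPs on chrom 1 inside their gene, null SNPs on chrom 2
    chrom = np.array(["1"] * m_gene + ["2"] * config.n_null_snps)
    pos = np.empty(m, dtype=np.int64)
    gene_of = np.array([""] * m, dtype=object)
    block_id = np.full(m, -1, dtype=np.int64)
    for g in range(config.n_genes):
        sl = slice(g * config.snps_per_gene, (g + 1) * config.snps_per_gene)
        pos[sl] = np.sort(
            rng.integers(starts[g], starts[g] + 50_000, size=config.snps_per_gene)
        )
        gene_of[sl] = gene_symbols[g]
        block_id[sl] = g
    if config.n_null_snps:
        pos[m_gene:] = 1_000_000 + 10_000 * np.arange(config.n_null_snps)
    variant_id = np.array([f"rs{i + 1:06d}" for i in range(m)])

    eaf = rng.uniform(*config.eaf_range, size=m)
    pal = rng.random(m) < config.palindrome_frac
    pair_choice = np.where(
        pal,
        rng.integers(0, len(_PALINDROMIC_PAIRS), size=m),
        rng.integers(0, len(_NONPAL_PAIRS), size=m),
    )
    effect_allele = np.array(
        [
            (_PALINDROMIC_PAIRS if pal[i] else _NONPAL_PAIRS)[pair_choice[i]][0]
            for i in range(m)
        ]
    )
    other_allele = np.array(
        [
            (_PALINDROMIC_PAIRS if pal[i] else _NONPAL_PAIRS)[pair_choice[i]][1]
            for i in range(m)
        ]
    )

    se_exp = 1.0 / np.sqrt(2.0 * config.n_exp * eaf * (1.0 - eaf))
    se_out = 1.0 / np.sqrt(2.0 * config.n_out * eaf * (1.0 - eaf))

    true_beta = np.zeros(m)
    if m_gene:
        z = rng.uniform(*config.instrument_z_range, size=m_gene)
        sign = rng.choice([-1.0, 1.0], size=m_gene)
        true_beta[:m_gene] = sign * z * se_exp[:m_gene]

    # direct (pleiotropic) outcome effects are parameterised per
    # exposure-raising allele — the convention under which a non-zero
    # pleiotropy_mean is "directional" and shifts the Egger intercept —
    # then re-signed to this SNP's effect-allele orientation
    direct = np.zeros(m)
    n_pleio = int(round(config.pleiotropy_frac * m_gene))
    if n_pleio:
        pleio_idx = rng.choice(m_gene, size=n_pleio, replace=False)
        draws = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=n_pleio)
        direct[pleio_idx] = draws * np.where(true_beta[pleio_idx] < 0, -1.0, 1.0)

    beta_exp = true_beta + _block_noise(rng, block_id, config.ld_block_r2) * se_exp
    true_out = config.true_effect * true_beta + direct
    beta_out = true_out + _block_noise(rng, block_id, config.ld_block_r2) * se_out

    exposure = pd.DataFrame(
        {
            "variant_id": variant_id,
            "chrom": chrom,
            "pos": pos,
            "effect_allele": effect_allele,
            "other_allele": other_allele,
            "eaf": eaf,
            "beta": beta_exp,
            "se": se_exp,
            "pval": _pvals(beta_exp, se_exp),
            "n": float(config.n_exp),
        }
    )
    outcome = exposure.copy()
    outcome["beta"] = beta_out
    outcome["se"] = se_out
    outcome["pval"] = _pvals(beta_out, se_out)
    outcome["n"] = float(config.n_out)

    ld = LDTable()
    if config.snps_per_gene > 1 and config.ld_block_r2 > 0:
        for g in range(config.n_genes):
            ids = variant_id[g * config.snps_per_gene : (g + 1) * config.snps_per_gene]
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    ld.add(ids[i], ids[j], config.ld_block_r2)

    truth = pd.DataFrame(
        {
            "variant_id": variant_id,
            "gene_symbol": gene_of,
            "ld_block_id": block_id,
            "true_exposure_beta": true_beta,
            "true_direct_outcome_beta": direct,
            "is_instrument_valid": direct == 0.0,
        }
    )
    return SimulatedStudy(exposure, outcome, regions, ld, truth)


def inject_outliers(
    outcome: pd.DataFrame,
    truth: pd.DataFrame,
    k: int,
    magnitude: float,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shift k valid instruments' outcome betas by ``magnitude × se``.

    Targets are chosen at random among currently-valid instruments (truth
    rows with a non-zero exposure effect); their truth flags flip to
    invalid.  Returns modified copies of the outcome table and truth.
    """
    eligible = truth.loc[
        truth["is_instrument_valid"] & (truth["true_exposure_beta"] != 0.0),
        "variant_id",
    ].to_numpy()
    if k > len(eligible):
        raise ValueError(
            f"k={k} exceeds the {len(eligible)} available valid instruments"
        )
    outcome = outcome.copy()
    truth = truth.copy()
    if k == 0:
        return outcome, truth
    rng = np.random.default_rng(seed)
    chosen = rng.choice(eligible, size=k, replace=False)
    mask = outcome["variant_id"].isin(chosen)
    shift = magnitude * outcome.loc[mask, "se"]
    outcome.loc[mask, "beta"] = outcome.loc[mask, "beta"] + shift
    outcome.loc[mask, "pval"] = _pvals(
        outcome.loc[mask, "beta"].to_numpy(), outcome.loc[mask, "se"].to_numpy()
    )
    tmask = truth["variant_id"].isin(chosen)
    se_by_id = outcome.set_index("variant_id")["se"]
    truth.loc[tmask, "true_direct_outcome_beta"] = (
        truth.loc[tmask, "true_direct_outcome_beta"]
        + magnitude * se_by_id.loc[truth.loc[tmask, "variant_id"]].to_numpy()
    )
    truth.loc[tmask, "is_instrument_valid"] = False
    return outcome, truth


def make_class_map(gene_symbols: list[str], n_classes: int) -> dict[str, list[str]]:
    """Assign simulated genes round-robin to synthetic drug classes."""
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    classes: dict[str, list[str]] = {
        f"synthetic_class_{i + 1}": [] for i in range(n_classes)
    }
    for i, gene in enumerate(gene_symbols):
        classes[f"synthetic_class_{i % n_classes + 1}"].append(gene)
    return {k: v for k, v in classes.items() if v}
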