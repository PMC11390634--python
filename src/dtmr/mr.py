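"""Functional surface over the MR estimators, plus result containers.

Thin wrappers around the estimator classes in :mod:`dtmr.estimators` that
return frozen dataclasses convenient for reporting.  All causal effects are
log odds per 1 unit of exposure; odds ratios in this study are expressed per
1 mmHg *decline* in systolic blood pressure after
:func:`orient_per_mmhg_decline`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .estimators import (
    Z_CRIT,
    EggerRegression,
    InsufficientInstruments,
    IVWEstimator,
    MRPresso,
    SteigerTest,
    WaldRatio,
    cochran_q,
)

__all__ = [
    "MREstimate",
    "SensitivityReport",
    "EggerResult",
    "PressoResult",
    "SteigerResult",
    "LeaveOneOutResult",
    "pairs_frame",
    "wald_ratio",
    "ivw",
    "cochran_q",
    "egger",
    "mr_presso",
    "steiger",
    "leave_one_out",
    "orient_per_mmhg_decline",
    "sensitivity_battery",
]


@dataclass(frozen=True)
class MREstimate:
    """A causal estimate on the log-odds scale with its OR formatting.

    Invariants: ``or_ == exp(beta)`` and ``ci_low < or_ < ci_high`` whenever
    ``se > 0``.
    """

    method: str
    beta: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int

    @classmethod
    def from_beta_se(cls, method: str, beta: float, se: float, n_snp: int) -> "MREstimate":
        from scipy.stats import norm

        if se <= 0:
            raise ValueError("se must be positive")
        return cls(
            method=method,
            beta=float(beta),
            se=float(se),
            or_=math.exp(beta),
            ci_low=math.exp(beta - Z_CRIT * se),
            ci_high=math.exp(beta + Z_CRIT * se),
            pval=float(2.0 * norm.sf(abs(beta) / se)),
            n_snp=int(n_snp),
        )

    @classmethod
    def from_or_ci(
        cls,
        ci_low: float,
        ci_high: float,
        method: str = "ivw_mre",
        n_snp: int = 0,
    ) -> "MREstimate":
        """Reconstruct an estimate from 95% CI bounds on the OR scale.

        ``beta`` is the midpoint of the log bounds and ``se`` the half-width
        divided by the normal critical value — the inverse of how the CI was
        formatted, so re-formatting reproduces the published OR/CI line.
        """
        if not 0 < ci_low < ci_high:
            raise ValueError("require 0 < ci_low < ci_high")
        lo, hi = math.log(ci_low), math.log(ci_high)
        return cls.from_beta_se(method, (lo + hi) / 2.0, (hi - lo) / (2.0 * Z_CRIT), n_snp)

    @classmethod
    def _from_fitted(cls, est) -> "MREstimate":
        return cls(
            method=est.method_,
            beta=est.beta_,
            se=est.se_,
            or_=est.or_,
            ci_low=est.ci_low_,
            ci_high=est.ci_high_,
            pval=est.pval_,
            n_snp=est.n_snp_,
        )


@dataclass(frozen=True)
class EggerResult:
    estimate: MREstimate
    intercept: float
    intercept_se: float
    intercept_pval: float


@dataclass(frozen=True)
class PressoResult:
    global_pval: float
    outliers: tuple[str, ...]
    distortion_pval: float | None
    corrected: MREstimate | None


@dataclass(frozen=True)
class SteigerResult:
    #: True = exposure→outcome, False = reverse, None = not established
    direction: bool | None
    pval: float
    r2_exp: float
    r2_out: float

    @property
    def label(self) -> str:
        if self.direction is None:
            return "not_established"
        return "exposure_to_outcome" if self.direction else "outcome_to_exposure"


@dataclass(frozen=True)
class LeaveOneOutResult:
    variant_ids: tuple[str, ...]
    estimates: tuple[MREstimate, ...]
    max_abs_deviation: float


@dataclass(frozen=True)
class SensitivityReport:
    """The full sensitivity battery for one analysis cell.

    Components that cannot be computed for small k are None, with a note.
    """

    q: float | None = None
    q_df: int | None = None
    q_pval: float | None = None
    egger: EggerResult | None = None
    presso: PressoResult | None = None
    steiger: SteigerResult | None = None
    loo: LeaveOneOutResult | None = None
    notes: tuple[str, ...] = field(default_factory=tuple)


def pairs_frame(
    beta_exp: Sequence[float],
    se_exp: Sequence[float],
    beta_out: Sequence[float],
    se_out: Sequence[float],
    variant_id: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Assemble a harmonized-pairs frame from parallel sequences."""
    k = len(beta_exp)
    if variant_id is None:
        variant_id = [f"snp{i + 1}" for i in range(k)]
    return pd.DataFrame(
        {
            "variant_id": list(variant_id),
            "beta_exp": np.asarray(beta_exp, dtype=float),
            "se_exp": np.asarray(se_exp, dtype=float),
            "beta_out": np.asarray(beta_out, dtype=float),
            "se_out": np.asarray(se_out, dtype=float),
        }
    )


def wald_ratio(pair) -> MREstimate:
    """Single-SNP Wald ratio estimate; errors if ``beta_exp == 0``."""
    return MREstimate._from_fitted(WaldRatio().fit(pair))


def ivw(pairs, model: str = "mre") -> MREstimate:
    """IVW estimate (``model`` fixed or mre); one pair delegates to Wald."""
    return MREstimate._from_fitted(IVWEstimator(model=model).fit(pairs))


def egger(pairs) -> EggerResult:
    """MR-Egger slope and intercept pleiotropy test (requires k >= 3)."""
    est = EggerRegression().fit(pairs)
    return EggerResult(
        estimate=MREstimate._from_fitted(est),
        intercept=est.intercept_,
        intercept_se=est.intercept_se_,
        intercept_pval=est.intercept_pval_,
    )


def mr_presso(
    pairs,
    nsim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int = 0,
    n_boot: int = 1000,
) -> PressoResult:
    """MR-PRESSO global, outlier and distortion tests (deterministic by seed)."""
    est = MRPresso(
        nsim=nsim, outlier_alpha=outlier_alpha, n_boot=n_boot, random_state=seed
    ).fit(pairs)
    corrected = (
        MREstimate._from_fitted(est.corrected_) if est.corrected_ is not None else None
    )
    return PressoResult(
        global_pval=est.global_pval_,
        outliers=tuple(est.outliers_),
        distortion_pval=est.distortion_pval_,
        corrected=corrected,
    )


def steiger(pairs, n_exp: float, n_out: float) -> SteigerResult:
    """Directionality test from aggregate variance explained in each trait."""
    est = SteigerTest(n_exp=n_exp, n_out=n_out).fit(pairs)
    return SteigerResult(
        direction=est.direction_,
        pval=est.pval_,
        r2_exp=est.r2_exp_,
        r2_out=est.r2_out_,
    )


def leave_one_out(pairs, model: str = "mre") -> LeaveOneOutResult:
    """Re-estimate omitting each SNP in turn (requires k >= 3)."""
    if isinstance(pairs, pd.DataFrame):
        df = pairs.reset_index(drop=True)
    else:
        arr = np.asarray(pairs, dtype=float)
        df = pairs_frame(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3])
    k = len(df)
    if k < 3:
        raise InsufficientInstruments("leave-one-out requires k >= 3")
    full = ivw(df, model=model)
    ids = []
    estimates = []
    for i in range(k):
        sub = df.drop(index=i)
        ids.append(str(df["variant_id"].iloc[i]) if "variant_id" in df.columns else str(i))
        estimates.append(ivw(sub, model=model))
    max_dev = max(abs(e.beta - full.beta) for e in estimates)
    return LeaveOneOutResult(
        variant_ids=tuple(ids),
        estimates=tuple(estimates),
        max_abs_deviation=float(max_dev),
    )


def orient_per_mmhg_decline(pairs: pd.DataFrame) -> pd.DataFrame:
    """Negate exposure betas so ORs read per 1 mmHg SBP *decline*.

    The outcome column is untouched; applying twice is the identity.
    """
    out = pairs.copy()
    out["beta_exp"] = -out["beta_exp"].astype(float)
    return out


def sensitivity_battery(
    pairs,
    n_exp: float,
    n_out: float,
    *,
    nsim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int = 0,
    n_boot: int = 1000,
) -> SensitivityReport:
    """Run every applicable sensitivity test for one harmonized pair set.

    Tests whose minimum-k requirement is not met are reported as None with a
    note, never as a failure; the battery always returns a complete report.
    """
    if isinstance(pairs, pd.DataFrame):
        k = len(pairs)
    else:
        k = np.atleast_2d(np.asarray(pairs, dtype=float)).shape[0]
    notes: list[str] = []
    q = q_df = q_pval = None
    egger_res = presso_res = steiger_res = loo_res = None

    if k >= 2:
        est = ivw(pairs, model="mre")
        q, q_df, q_pval = cochran_q(pairs, est.beta)
    else:
        notes.append("heterogeneity skipped (k < 2)")

    if k >= 3:
        try:
            egger_res = egger(pairs)
        except ValueError as exc:
            notes.append(f"egger not computed ({exc})")
    else:
        notes.append("egger skipped (k < 3)")

    if k >= 2:
        presso_res = mr_presso(
            pairs, nsim=nsim, outlier_alpha=outlier_alpha, seed=seed, n_boot=n_boot
        )
        if k < 4:
            notes.append("presso outlier test skipped (k < 4, global test only)")
    else:
        notes.append("presso skipped (k < 2)")

    if n_exp > 3 and n_out > 3 and k >= 1:
        steiger_res = steiger(pairs, n_exp=n_exp, n_out=n_out)
    else:
        notes.append("steiger skipped (missing sample sizes)")

    if k >= 3:
        loo_res = leave_one_out(pairs, model="mre")
    else:
        notes.append("leave-one-out skipped (k < 3)")

    return SensitivityReport(
        q=q,
        q_df=q_df,
        q_pval=q_pval,
        egger=egger_res,
        presso=presso_res,
        steiger=steiger_res,
        loo=loo_res,
        notes=tuple(notes),
    )
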