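"""Study orchestration: positive-control gating, the drug-class × outcome
scan, Bonferroni tiering, and result rows.

The positive control (coronary artery disease, CAD) validates each drug
class's instruments before any pain outcome is tested: per 1 mmHg decline in
systolic blood pressure the class must show a nominally significant
*protective* CAD association.  Surviving classes are scanned against the
outcome panel with IVW (multiplicative random effects; Wald ratio for a
single SNP) and the full sensitivity battery, and each cell is tiered
against the Bonferroni threshold computed from the number of classes
originally tested — not the number surviving the gate — matching the
conventional 0.05/12 design.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from .estimators import InsufficientInstruments
from .instruments import InstrumentSet, harmonize
from .mr import (
    MREstimate,
    SensitivityReport,
    ivw,
    orient_per_mmhg_decline,
    sensitivity_battery,
)
from .sumstats_io import LDTable

logger = logging.getLogger(__name__)

TIER_STRONG = "strong"
TIER_SUGGESTIVE = "suggestive"
TIER_NONE = "none"


class BonferroniThreshold(NamedTuple):
    alpha: float
    #: display form rounded to 4 decimals, as conventionally printed
    display: float


def bonferroni_alpha(n_classes: int, family_alpha: float = 0.05) -> BonferroniThreshold:
    """Family-wise threshold ``family_alpha / n_classes`` with its display form."""
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    alpha = family_alpha / n_classes
    return BonferroniThreshold(alpha=alpha, display=round(alpha, 4))


def tier(pval: float, alpha_bonferroni: float) -> str:
    """Evidence tier: strong below the Bonferroni threshold, suggestive in
    [threshold, 0.05), none otherwise.  Partitions (0, 1]."""
    if not 0.0 < pval <= 1.0:
        raise ValueError(f"pval {pval} outside (0, 1]")
    if pval < alpha_bonferroni:
        return TIER_STRONG
    if pval < 0.05:
        return TIER_SUGGESTIVE
    return TIER_NONE


@dataclass(frozen=True)
class ControlGateResult:
    class_name: str
    estimate: MREstimate | None
    passed: bool
    reason: str


def _cell_seed(seed: int, *parts: str) -> int:
    """Stable per-cell RNG seed below 2**31, independent of iteration order."""
    return zlib.crc32(":".join((str(seed),) + parts).encode()) % (2**31)


def _estimate_pairs(pairs: pd.DataFrame) -> MREstimate:
    return ivw(pairs, model="mre")  # delegates to Wald for a single pair


def control_gate(
    instrument_sets: Mapping[str, InstrumentSet],
    control_outcome: pd.DataFrame,
    *,
    ld: LDTable | None = None,
    gate_alpha: float = 0.05,
    proxy_policy: str = "drop",
) -> list[ControlGateResult]:
    """Validate each class's instruments against the positive-control outcome.

    A class passes iff its IVW (or single-SNP Wald) estimate per 1 mmHg SBP
    decline is significant at ``gate_alpha`` *and* protective (OR < 1).
    Classes with no harmonizable instruments fail with reason
    ``"no instruments"``.
    """
    results: list[ControlGateResult] = []
    for name, inst in instrument_sets.items():
        if inst.records.empty:
            results.append(ControlGateResult(name, None, False, "no instruments"))
            continue
        harm = harmonize(
            inst.records, control_outcome, ld=ld, proxy_policy=proxy_policy
        )
        if harm.pairs.empty:
            results.append(ControlGateResult(name, None, False, "no instruments"))
            continue
        pairs = orient_per_mmhg_decline(harm.pairs)
        try:
            est = _estimate_pairs(pairs)
        except (ValueError, InsufficientInstruments) as exc:
            results.append(ControlGateResult(name, None, False, str(exc)))
            continue
        if est.pval >= gate_alpha:
            results.append(ControlGateResult(name, est, False, "not significant"))
        elif est.or_ >= 1.0:
            results.append(ControlGateResult(name, est, False, "direction"))
        else:
            results.append(ControlGateResult(name, est, True, ""))
    for r in results:
        if not r.passed:
            logger.info("control gate: %s excluded (%s)", r.class_name, r.reason)
    return results


@dataclass(frozen=True)
class ScanResult:
    """One drug-class × outcome cell."""

    class_name: str
    outcome_name: str
    estimate: MREstimate | None
    sensitivity: SensitivityReport | None
    tier: str
    n_snp_used: int
    notes: tuple[str, ...]

    def to_row(self) -> dict:
        e = self.estimate
        s = self.sensitivity
        row = {
            "class": self.class_name,
            "outcome": self.outcome_name,
            "method": e.method if e else "",
            "n_snp": self.n_snp_used,
            "beta": e.beta if e else np.nan,
            "se": e.se if e else np.nan,
            "or": e.or_ if e else np.nan,
            "ci_low": e.ci_low if e else np.nan,
            "ci_high": e.ci_high if e else np.nan,
            "pval": e.pval if e else np.nan,
            "q_pval": np.nan,
            "egger_intercept_pval": np.nan,
            "presso_global_pval": np.nan,
            "steiger_direction": "",
            "steiger_pval": np.nan,
            "tier": self.tier,
        }
        if s is not None:
            if s.q_pval is not None:
                row["q_pval"] = s.q_pval
            if s.egger is not None:
                row["egger_intercept_pval"] = s.egger.intercept_pval
            if s.presso is not None:
                row["presso_global_pval"] = s.presso.global_pval
            if s.steiger is not None:
                row["steiger_direction"] = s.steiger.label
                row["steiger_pval"] = s.steiger.pval
        return row


def run_scan(
    instrument_sets: Mapping[str, InstrumentSet],
    outcome_tables: Mapping[str, pd.DataFrame],
    *,
    ld: LDTable | None = None,
    blocklist: pd.DataFrame | None = None,
    n_classes_tested: int | None = None,
    family_alpha: float = 0.05,
    presso_nsim: int = 1000,
    seed: int = 0,
    proxy_policy: str = "drop",
) -> list[ScanResult]:
    """Estimate every surviving class × outcome cell with full sensitivity.

    ``n_classes_tested`` sets the Bonferroni denominator (defaults to the
    number of instrument sets supplied — pass the number of classes
    *originally* tested when some failed the control gate).  A missing or
    empty cell is reported as a row with notes, never an exception; the scan
    always yields ``len(instrument_sets) × len(outcome_tables)`` rows.
    """
    n_tested = n_classes_tested if n_classes_tested is not None else len(instrument_sets)
    alpha = bonferroni_alpha(n_tested, family_alpha).alpha
    results: list[ScanResult] = []
    for class_name, inst in instrument_sets.items():
        for outcome_name, table in outcome_tables.items():
            notes: list[str] = []
            if table is None:
                results.append(
                    ScanResult(class_name, outcome_name, None, None, TIER_NONE, 0,
                               ("outcome table missing",))
                )
                continue
            harm = harmonize(inst.records, table, ld=ld, proxy_policy=proxy_policy)
            pairs = harm.pairs
            n_proxied = int((pairs["provenance"] != "direct").sum()) if len(pairs) else 0
            if n_proxied:
                notes.append(f"{n_proxied} proxy substitution(s)")
            if blocklist is not None and len(pairs):
                before = len(pairs)
                listed = pairs["variant_id"].astype(str).isin(
                    set(blocklist["variant_id"].astype(str))
                )
                pairs = pairs.loc[~listed].reset_index(drop=True)
                if before != len(pairs):
                    notes.append(f"{before - len(pairs)} blocklisted SNP(s) removed")
            if pairs.empty:
                results.append(
                    ScanResult(class_name, outcome_name, None, None, TIER_NONE, 0,
                               tuple(notes) + ("no harmonized instruments",))
                )
                continue
            pairs = orient_per_mmhg_decline(pairs)
            est = _estimate_pairs(pairs)
            report = sensitivity_battery(
                pairs,
                n_exp=float(pairs["n_exp"].median()),
                n_out=float(pairs["n_out"].median()),
                nsim=presso_nsim,
                seed=_cell_seed(seed, class_name, outcome_name),
            )
            notes.extend(report.notes)
            if report.presso is not None and report.presso.outliers:
                notes.append(
                    "presso outliers: " + ",".join(report.presso.outliers)
                )
            results.append(
                ScanResult(
                    class_name=class_name,
                    outcome_name=outcome_name,
                    estimate=est,
                    sensitivity=report,
                    tier=tier(est.pval, alpha),
                    n_snp_used=est.n_snp,
                    notes=tuple(notes),
                )
            )
    return results


def results_frame(results: list[ScanResult]) -> pd.DataFrame:
    """Scan results as a frame in the stable results-column order."""
    from .sumstats_io import RESULT_COLUMNS

    return pd.DataFrame([r.to_row() for r in results], columns=list(RESULT_COLUMNS))


def gate_frame(results: list[ControlGateResult]) -> pd.DataFrame:
    """Control-gate report as a frame."""
    rows = []
    for r in results:
        e = r.estimate
        rows.append(
            {
                "class": r.class_name,
                "n_snp": e.n_snp if e else 0,
                "or": e.or_ if e else np.nan,
                "ci_low": e.ci_low if e else np.nan,
                "ci_high": e.ci_high if e else np.nan,
                "pval": e.pval if e else np.nan,
                "passed": r.passed,
                "reason": r.reason,
            }
        )
    return pd.DataFrame(rows)
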