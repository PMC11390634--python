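"""Two-sample Mendelian randomization estimators, scikit-learn style.

Every estimator fits on a table of harmonized SNP pairs — a frame with
columns ``beta_exp``, ``se_exp``, ``beta_out``, ``se_out`` (and optionally
``variant_id``) or an equivalent ``(k, 4)`` array — and exposes fitted
attributes with a trailing underscore (``beta_``, ``se_``, ``or_``,
``ci_low_``, ``ci_high_``, ``pval_``, ``n_snp_``).  All estimators inherit
:class:`sklearn.base.BaseEstimator`, so ``get_params``/``set_params``,
cloning and pipeline composition behave as for any scikit-learn estimator.

The model: each SNP i gives an exposure association ``beta_exp_i`` (per
1 mmHg systolic blood pressure) and an outcome association ``beta_out_i``
(log odds).  Under the instrumental-variable assumptions the per-SNP Wald
ratios ``beta_out_i / beta_exp_i`` share a common causal slope; IVW pools
them as the zero-intercept weighted regression of outcome on exposure
effects with weights ``1 / se_out_i**2``.  The multiplicative random-effects
(MRE) variant inflates the slope standard error by residual overdispersion,
``sqrt(max(Q / (k - 1), 1))`` with Cochran's Q, and never deflates it.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

#: two-sided 95% normal critical value used for all confidence intervals
Z_CRIT = 1.959964

PAIR_COLUMNS = ("beta_exp", "se_exp", "beta_out", "se_out")


class InsufficientInstruments(ValueError):
    """Too few SNPs for the requested estimator (reportable as not-computed)."""


def _extract_pairs(X) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Return (ids, beta_exp, se_exp, beta_out, se_out) as 1-D arrays."""
    if isinstance(X, pd.DataFrame):
        missing = [c for c in PAIR_COLUMNS if c not in X.columns]
        if missing:
            raise ValueError(f"pairs frame missing column(s): {missing}")
        if "variant_id" in X.columns:
            ids = X["variant_id"].astype(str).to_numpy()
        else:
            ids = X.index.astype(str).to_numpy()
        arr = X.loc[:, list(PAIR_COLUMNS)].to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 1:
            arr = arr.reshape(1, -1)
        if arr.ndim != 2 or arr.shape[1] != 4:
            raise ValueError(
                "pairs array must have 4 columns (beta_exp, se_exp, beta_out, se_out)"
            )
        ids = np.arange(arr.shape[0]).astype(str)
    if not np.all(np.isfinite(arr)):
        raise ValueError("pairs contain non-finite values")
    bx, sx, by, sy = arr.T
    if np.any(sy <= 0) or np.any(sx <= 0):
        raise ValueError("standard errors must be positive")
    return ids, bx, sx, by, sy


def _normal_p(beta: float, se: float) -> float:
    return float(2.0 * stats.norm.sf(abs(beta) / se))


class _MRBase(BaseEstimator):
    """Shared finalisation of a causal estimate on the log-odds scale."""

    method_: str

    def _finalize(self, beta: float, se: float, k: int, method: str) -> "_MRBase":
        self.beta_ = float(beta)
        self.se_ = float(se)
        self.or_ = float(np.exp(beta))
        self.ci_low_ = float(np.exp(beta - Z_CRIT * se))
        self.ci_high_ = float(np.exp(beta + Z_CRIT * se))
        self.pval_ = _normal_p(beta, se)
        self.n_snp_ = int(k)
        self.method_ = method
        return self


class WaldRatio(_MRBase):
    """Single-SNP causal estimate: ``beta_out / beta_exp``.

    The standard error is the first-order delta-method form
    ``se_out / |beta_exp|`` (exposure uncertainty ignored, as conventional
    for strong instruments).
    """

    def fit(self, X, y=None):
        ids, bx, sx, by, sy = _extract_pairs(X)
        if len(bx) != 1:
            raise ValueError(f"WaldRatio requires exactly 1 pair, got {len(bx)}")
        if bx[0] == 0:
            raise ValueError("Wald ratio undefined: beta_exp = 0")
        return self._finalize(by[0] / bx[0], sy[0] / abs(bx[0]), 1, "wald")


class IVWEstimator(_MRBase):
    """Inverse-variance-weighted estimator (fixed or multiplicative random effects).

    Parameters
    ----------
    model
        ``"fixed"`` or ``"mre"``.  Point estimates are identical; MRE scales
        the standard error by ``sqrt(max(Q/(k-1), 1))``.

    A single pair delegates to the Wald ratio (``method_ == "wald"``).

    Attributes (after fit): ``beta_``, ``se_``, ``se_fixed_``, ``or_``,
    ``ci_low_``, ``ci_high_``, ``pval_``, ``n_snp_``, ``q_``, ``q_df_``,
    ``q_pval_``, ``method_``.
    """

    def __init__(self, model: str = "mre"):
        self.model = model

    def fit(self, X, y=None):
        if self.model not in ("fixed", "mre"):
            raise ValueError(f"model must be 'fixed' or 'mre', got {self.model!r}")
        ids, bx, sx, by, sy = _extract_pairs(X)
        k = len(bx)
        if k == 0:
            raise InsufficientInstruments("no pairs")
        if k == 1:
            self.q_ = self.q_df_ = self.q_pval_ = None
            self.se_fixed_ = float(sy[0] / abs(bx[0])) if bx[0] != 0 else np.nan
            if bx[0] == 0:
                raise ValueError("Wald ratio undefined: beta_exp = 0")
            return self._finalize(by[0] / bx[0], sy[0] / abs(bx[0]), 1, "wald")
        w = 1.0 / sy**2
        sxx = float(np.sum(w * bx**2))
        if sxx == 0:
            raise ValueError("all exposure betas are zero")
        beta = float(np.sum(w * bx * by) / sxx)
        se_fixed = float(np.sqrt(1.0 / sxx))
        q = float(np.sum(w * (by - beta * bx) ** 2))
        df = k - 1
        self.q_ = q
        self.q_df_ = df
        self.q_pval_ = float(stats.chi2.sf(q, df))
        self.se_fixed_ = se_fixed
        scale = float(np.sqrt(max(q / df, 1.0))) if self.model == "mre" else 1.0
        return self._finalize(beta, se_fixed * scale, k, f"ivw_{self.model}")


def cochran_q(X, beta_ivw: float) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity statistic around a given pooled slope.

    Returns ``(Q, df, pval)`` with ``Q = sum w_i (beta_out_i - beta *
    beta_exp_i)**2``, ``w_i = 1/se_out_i**2``, ``df = k - 1`` and the
    chi-square upper-tail p-value.
    """
    ids, bx, sx, by, sy = _extract_pairs(X)
    k = len(bx)
    if k < 2:
        raise InsufficientInstruments("Cochran's Q requires k >= 2")
    w = 1.0 / sy**2
    q = float(np.sum(w * (by - beta_ivw * bx) ** 2))
    df = k - 1
    return q, df, float(stats.chi2.sf(q, df))


class EggerRegression(_MRBase):
    """MR-Egger: weighted regression of outcome on exposure effects with intercept.

    Exposure effects are oriented non-negative first (each pair's signs
    flipped together), as the intercept is only interpretable under that
    orientation.  Slope and intercept standard errors are scaled by
    ``sqrt(max(Q_egger/(k-2), 1))``; a non-zero intercept indicates
    directional pleiotropy.

    Attributes: slope estimate via the shared fields, plus ``intercept_``,
    ``intercept_se_``, ``intercept_pval_``, ``q_``, ``q_df_``.
    """

    def fit(self, X, y=None):
        ids, bx, sx, by, sy = _extract_pairs(X)
        k = len(bx)
        if k < 3:
            raise InsufficientInstruments("MR-Egger requires k >= 3")
        sign = np.where(bx < 0, -1.0, 1.0)
        bx = bx * sign
        by = by * sign
        w = 1.0 / sy**2
        sw = float(np.sum(w))
        xbar = float(np.sum(w * bx) / sw)
        sxx = float(np.sum(w * (bx - xbar) ** 2))
        if sxx <= 1e-12 * max(1.0, float(np.sum(w * bx**2))):
            raise ValueError("exposure betas are collinear (zero weighted variance)")
        slope = float(np.sum(w * (bx - xbar) * by) / sxx)
        intercept = float(np.sum(w * by) / sw - slope * xbar)
        resid = by - intercept - slope * bx
        q = float(np.sum(w * resid**2))
        df = k - 2
        sigma = float(np.sqrt(max(q / df, 1.0)))
        se_slope = sigma * float(np.sqrt(1.0 / sxx))
        se_int = sigma * float(np.sqrt(1.0 / sw + xbar**2 / sxx))
        self.intercept_ = intercept
        self.intercept_se_ = se_int
        self.intercept_pval_ = _normal_p(intercept, se_int)
        self.q_ = q
        self.q_df_ = df
        return self._finalize(slope, se_slope, k, "egger")


class SteigerTest(BaseEstimator):
    """Directionality check: do the instruments explain more variance in the
    exposure than in the outcome?

    Aggregate variance explained is summed per SNP as ``z**2 / (z**2 + n)``
    (independent instruments assumed).  The p-value compares the two
    Fisher-transformed aggregate correlations with sampling variances
    ``1/(n_exp - 3)`` and ``1/(n_out - 3)``.

    Attributes: ``r2_exp_``, ``r2_out_``, ``direction_`` (True for
    exposure→outcome, False for the reverse, None for an exact tie),
    ``pval_``.
    """

    def __init__(self, n_exp: float = 0.0, n_out: float = 0.0):
        self.n_exp = n_exp
        self.n_out = n_out

    def fit(self, X, y=None):
        if self.n_exp <= 3 or self.n_out <= 3:
            raise ValueError("Steiger test requires sample sizes > 3")
        ids, bx, sx, by, sy = _extract_pairs(X)
        zx2 = (bx / sx) ** 2
        zy2 = (by / sy) ** 2
        r2x = float(np.sum(zx2 / (zx2 + self.n_exp)))
        r2y = float(np.sum(zy2 / (zy2 + self.n_out)))
        r2x = min(r2x, 1.0 - 1e-12)
        r2y = min(r2y, 1.0 - 1e-12)
        self.r2_exp_ = r2x
        self.r2_out_ = r2y
        if r2x == r2y:
            self.direction_ = None
            self.pval_ = 1.0
            return self
        zfx = float(np.arctanh(np.sqrt(r2x)))
        zfy = float(np.arctanh(np.sqrt(r2y)))
        sd = float(np.sqrt(1.0 / (self.n_exp - 3) + 1.0 / (self.n_out - 3)))
        stat = (zfx - zfy) / sd
        self.direction_ = bool(r2x > r2y)
        self.pval_ = float(2.0 * stats.norm.sf(abs(stat)))
        return self


class MRPresso(_MRBase):
    """MR-PRESSO: simulation-based residual-sum-of-squares pleiotropy test.

    The observed RSS uses leave-one-out IVW slopes: ``RSS = sum_i w_i
    (beta_out_i - beta_loo(-i) * beta_exp_i)**2``.  The null distribution
    comes from ``nsim`` parametric draws ``beta_out_i* ~ Normal(beta_loo(-i)
    * beta_exp_i, se_out_i**2)`` with leave-one-out slopes recomputed per
    draw.  P-values use the add-one rule ``(1 + #exceed) / (nsim + 1)``.
    Per-SNP outlier p-values (computed when k >= 4) are Bonferroni-adjusted
    by k; flagged SNPs are removed for the corrected IVW-MRE estimate, and
    the distortion test compares the observed shift of the slope against a
    bootstrap of random equally-sized removals among non-outliers.

    Parameters: ``nsim`` (>= 100 recommended), ``outlier_alpha``,
    ``n_boot`` (distortion bootstrap size), ``random_state`` (mandatory
    determinism; same seed, same result).

    Attributes: ``global_pval_``, ``outliers_`` (variant ids),
    ``outlier_pvals_``, ``distortion_pval_``, ``corrected_`` (fitted
    :class:`IVWEstimator` on non-outliers, or None), ``rss_obs_``, plus the
    all-SNP IVW-MRE estimate in the shared fields.
    """

    def __init__(
        self,
        nsim: int = 1000,
        outlier_alpha: float = 0.05,
        n_boot: int = 1000,
        random_state: int = 0,
    ):
        self.nsim = nsim
        self.outlier_alpha = outlier_alpha
        self.n_boot = n_boot
        self.random_state = random_state

    def fit(self, X, y=None):
        ids, bx, sx, by, sy = _extract_pairs(X)
        k = len(bx)
        if k < 2:
            raise InsufficientInstruments("MR-PRESSO requires k >= 2")
        if self.nsim < 100:
            warnings.warn(
                f"nsim={self.nsim} < 100 gives a coarse null distribution",
                UserWarning,
                stacklevel=2,
            )
        rng = np.random.default_rng(self.random_state)
        w = 1.0 / sy**2
        sxx = float(np.sum(w * bx**2))
        sxy = float(np.sum(w * bx * by))
        denom = sxx - w * bx**2
        if np.any(denom <= 0):
            raise ValueError("degenerate leave-one-out denominator")
        loo_slope = (sxy - w * bx * by) / denom
        pred = loo_slope * bx
        res_obs = w * (by - pred) ** 2
        rss_obs = float(np.sum(res_obs))
        self.rss_obs_ = rss_obs

        ystar = pred[None, :] + rng.standard_normal((self.nsim, k)) * sy[None, :]
        sxy_star = ystar @ (w * bx)
        loo_star = (sxy_star[:, None] - (w * bx)[None, :] * ystar) / denom[None, :]
        res_star = w[None, :] * (ystar - loo_star * bx[None, :]) ** 2
        rss_star = res_star.sum(axis=1)
        self.global_pval_ = float(
            (1 + int(np.sum(rss_star >= rss_obs))) / (self.nsim + 1)
        )

        outlier_idx: np.ndarray = np.array([], dtype=int)
        if k >= 4:
            p_raw = (1 + (res_star >= res_obs[None, :]).sum(axis=0)) / (self.nsim + 1)
            p_adj = np.minimum(1.0, p_raw * k)
            self.outlier_pvals_ = pd.Series(p_adj, index=ids)
            outlier_idx = np.flatnonzero(p_adj < self.outlier_alpha)
        else:
            self.outlier_pvals_ = None
        self.outliers_ = [str(ids[i]) for i in outlier_idx]

        self.corrected_ = None
        self.distortion_pval_ = None
        keep = np.setdiff1d(np.arange(k), outlier_idx)
        if len(outlier_idx) and len(keep) >= 2:
            sub = np.column_stack([bx[keep], sx[keep], by[keep], sy[keep]])
            self.corrected_ = IVWEstimator(model="mre").fit(sub)
            beta_all = sxy / sxx
            if beta_all != 0 and len(keep) > len(outlier_idx):
                d_obs = abs(100.0 * (self.corrected_.beta_ - beta_all) / abs(beta_all))
                n_rm = len(outlier_idx)
                exceed = 0
                for _ in range(self.n_boot):
                    drop = rng.choice(keep, size=n_rm, replace=False)
                    mask = np.ones(k, dtype=bool)
                    mask[drop] = False
                    beta_b = float(
                        np.sum(w[mask] * bx[mask] * by[mask])
                        / np.sum(w[mask] * bx[mask] ** 2)
                    )
                    if abs(100.0 * (beta_b - beta_all) / abs(beta_all)) >= d_obs:
                        exceed += 1
                self.distortion_pval_ = float((1 + exceed) / (self.n_boot + 1))

        # all-SNP IVW-MRE estimate for reference
        beta = sxy / sxx
        q = float(np.sum(w * (by - beta * bx) ** 2))
        scale = float(np.sqrt(max(q / (k - 1), 1.0)))
        return self._finalize(beta, np.sqrt(1.0 / sxx) * scale, k, "ivw_mre")
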