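"""Causal-effect estimators for Mendelian randomization.

Two-sample estimators operate on harmonized per-SNP (beta_x, se_x, beta_y,
se_y) instrument sets:

* ``ivw`` — fixed-effects inverse-variance weighted estimate: the
  zero-intercept weighted regression of outcome betas on exposure betas with
  weights 1/se_y^2.  Assumes no unbalanced horizontal pleiotropy.
* ``mr_egger`` — the same regression with a free intercept; a non-zero
  intercept is evidence of unbalanced pleiotropy, and the slope is a
  consistent causal estimate under the InSIDE assumption.  Inference on
  t(J-2).
* ``weighted_median`` / ``penalized_weighted_median`` — the weighted median
  of per-SNP ratio estimates, consistent when at least half the instrument
  weight is valid; penalization down-weights SNPs contributing outlying
  heterogeneity.  SEs by seeded parametric bootstrap.
* ``leave_one_out`` / ``exclude_and_reestimate`` — sensitivity companions.

One-sample estimation is provided by ``tsls`` (two-stage least squares with
a genetic-score instrument), and two small helpers convert effects between
units (``sd_unit_conversion``) and propagate a product-of-paths mediation
expectation with a delta-method SE (``mediation_expectation``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import EstimationError, ParameterError, WeakInstrumentError
from .summary_stats import HarmonizedPairs

Z95 = 1.96  # CI multiplier for normal-reference methods


@dataclass
class MrEstimate:
    """One estimator's causal-effect estimate, outcome units per 1-SD exposure."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    reference: str = "normal"
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None
    intercept_ci: tuple[float, float] | None = None
    n_boot: int | None = None
    seed: int | None = None
    omitted: str | None = None

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pval": self.pval,
            "n_snps": self.n_snps,
            "reference": self.reference,
        }
        if self.intercept is not None:
            d.update(
                intercept=self.intercept,
                intercept_se=self.intercept_se,
                intercept_pval=self.intercept_pval,
                intercept_ci=list(self.intercept_ci),
            )
        if self.omitted is not None:
            d["omitted"] = self.omitted
        return d


@dataclass
class TslsEstimate:
    """Two-stage least-squares estimate with first-stage strength."""

    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    first_stage_f: float
    n: int


@dataclass
class MediationExpectation:
    """Product-of-paths expected effect under full mediation."""

    effect: float
    se: float
    ci_low: float
    ci_high: float
    a: float
    b: float
    unit: str = ""


def _extract(pairs) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list]:
    df = pairs.pairs if isinstance(pairs, HarmonizedPairs) else pairs
    return (
        df["beta_x"].to_numpy(dtype=float),
        df["se_x"].to_numpy(dtype=float),
        df["beta_y"].to_numpy(dtype=float),
        df["se_y"].to_numpy(dtype=float),
        list(df["rsid"]),
    )


def _pairs_frame(pairs) -> pd.DataFrame:
    return pairs.pairs if isinstance(pairs, HarmonizedPairs) else pairs


# ---------------------------------------------------------------------------
# IVW and MR-Egger
# ---------------------------------------------------------------------------


def ivw(pairs) -> MrEstimate:
    """Fixed-effects inverse-variance weighted estimate.

    Zero-intercept weighted least squares of beta_y on beta_x with weights
    w_j = 1/se_y_j^2 (first-order):

        beta = sum w b_x b_y / sum w b_x^2,   se = (sum w b_x^2)^(-1/2)

    Two-sided p from the normal reference.  With a single SNP this reduces
    to the ratio estimate beta_y / beta_x.
    """
    bx, _, by, sy, _ = _extract(pairs)
    if len(bx) == 0:
        raise EstimationError("IVW requires at least 1 instrument")
    w = sy**-2.0
    denom = float(np.sum(w * bx**2))
    if denom == 0:
        raise EstimationError("undefined IVW estimate: all exposure betas are zero")
    beta = float(np.sum(w * bx * by) / denom)
    se = denom**-0.5
    p = float(2 * stats.norm.sf(abs(beta / se)))
    return MrEstimate(
        "IVW (fixed effects)", beta, se, beta - Z95 * se, beta + Z95 * se, p, len(bx)
    )


def mr_egger(pairs) -> MrEstimate:
    """MR-Egger regression: weighted fit of beta_y on beta_x with intercept.

    Instruments are first oriented so every exposure beta is non-negative
    (flipping the outcome beta in tandem; the fit is invariant to per-SNP
    sign flips only after this orientation).  Weights are 1/se_y^2, the
    residual scale is estimated, and slope/intercept inference uses the
    t distribution with J-2 degrees of freedom.
    """
    bx, _, by, sy, rsids = _extract(pairs)
    if len(bx) < 3:
        raise EstimationError("MR-Egger requires at least 3 instruments")
    zero = bx == 0
    if zero.any():
        warnings.warn(
            f"MR-Egger: excluding SNP(s) with beta_x = 0: "
            f"{[r for r, z in zip(rsids, zero) if z]}",
            stacklevel=2,
        )
        bx, by, sy = bx[~zero], by[~zero], sy[~zero]
        if len(bx) < 3:
            raise EstimationError("MR-Egger requires at least 3 instruments")
    sign = np.sign(bx)
    bx, by = bx * sign, by * sign

    w = sy**-2.0
    X = np.column_stack([np.ones_like(bx), bx])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = by - X @ coef
    dof = len(bx) - 2
    scale = float(np.sum(w * resid**2) / dof)
    cov = scale * np.linalg.inv(xtwx)
    se = np.sqrt(np.diag(cov))
    tq = stats.t.ppf(0.975, dof)
    pvals = 2 * stats.t.sf(np.abs(coef / se), dof)
    return MrEstimate(
        "MR-Egger",
        float(coef[1]),
        float(se[1]),
        float(coef[1] - tq * se[1]),
        float(coef[1] + tq * se[1]),
        float(pvals[1]),
        len(bx),
        reference=f"t({dof})",
        intercept=float(coef[0]),
        intercept_se=float(se[0]),
        intercept_pval=float(pvals[0]),
        intercept_ci=(float(coef[0] - tq * se[0]), float(coef[0] + tq * se[0])),
    )


# ---------------------------------------------------------------------------
# weighted median family
# ---------------------------------------------------------------------------


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Linear interpolation of the weighted empirical CDF at probability 0.5."""
    order = np.argsort(ratios)
    r, w = ratios[order], weights[order]
    cum = np.cumsum(w) - 0.5 * w
    cum = cum / np.sum(w)
    return float(np.interp(0.5, cum, r))


def _ratios_and_weights(pairs, warn: bool = True):
    bx, sx, by, sy, rsids = _extract(pairs)
    zero = bx == 0
    if zero.any():
        if warn:
            warnings.warn(
                f"weighted median: excluding SNP(s) with beta_x = 0: "
                f"{[r for r, z in zip(rsids, zero) if z]}",
                stacklevel=3,
            )
        bx, sx, by, sy = bx[~zero], sx[~zero], by[~zero], sy[~zero]
    ratios = by / bx
    weights = bx**2 / sy**2  # first-order inverse ratio variance
    return bx, sx, by, sy, ratios, weights


def _bootstrap_se(
    bx, sx, by, sy, point_fn, n_boot: int, seed: int
) -> float:
    rng = np.random.default_rng(seed)
    est = np.empty(n_boot)
    for i in range(n_boot):
        bxs = bx + sx * rng.standard_normal(len(bx))
        bys = by + sy * rng.standard_normal(len(by))
        est[i] = point_fn(bxs, bys, sy)
    return float(est.std(ddof=1))


def _wm_point(bxs, bys, sy) -> float:
    ok = bxs != 0
    bxs, bys, sy = bxs[ok], bys[ok], sy[ok]
    return _weighted_median(bys / bxs, bxs**2 / sy**2)


def weighted_median(pairs, n_boot: int = 1000, seed: int = 0) -> MrEstimate:
    """Weighted median of the per-SNP ratio estimates.

    Ratios r_j = beta_y_j / beta_x_j are weighted by the first-order inverse
    ratio variance beta_x_j^2 / se_y_j^2; the estimate interpolates the
    weighted empirical distribution at cumulative probability 0.5.  The SE
    is the SD of ``n_boot`` parametric-bootstrap replicates (betas resampled
    from normal(beta, se), deterministic under ``seed``).
    """
    if len(_pairs_frame(pairs)) < 3:
        raise EstimationError("weighted median requires at least 3 instruments")
    bx, sx, by, sy, ratios, weights = _ratios_and_weights(pairs)
    if len(ratios) == 0:
        raise EstimationError("no usable ratios (all exposure betas zero)")
    beta = _weighted_median(ratios, weights)
    se = _bootstrap_se(bx, sx, by, sy, _wm_point, n_boot, seed)
    p = float(2 * stats.norm.sf(abs(beta / se))) if se > 0 else 0.0
    return MrEstimate(
        "weighted median",
        beta,
        se,
        beta - Z95 * se,
        beta + Z95 * se,
        p,
        len(ratios),
        n_boot=n_boot,
        seed=seed,
    )


def _penalized_weights(
    ratios: np.ndarray, weights: np.ndarray, penalty_scale: float
) -> np.ndarray:
    beta_wm = _weighted_median(ratios, weights)
    q_j = weights * (ratios - beta_wm) ** 2
    p_j = stats.chi2.sf(q_j, df=1)
    penalized = weights * np.minimum(1.0, penalty_scale * p_j)
    if penalized.sum() == 0:
        # penalty_scale -> 0 limit: weights proportional to w_j * p_j, so the
        # best-fitting (largest p_j) SNPs determine the estimate
        penalized = weights * p_j
    return penalized


def penalized_weighted_median(
    pairs, n_boot: int = 1000, seed: int = 0, penalty_scale: float = 20.0
) -> MrEstimate:
    """Weighted median with heterogeneity-penalized weights.

    Each SNP's contribution to heterogeneity about the plain weighted median
    Q_j = w_j (r_j - beta_WM)^2 is referred to chi-square(1); weights become
    w_j * min(1, penalty_scale * p_j), shrinking gross outliers (default
    penalty_scale 20, the published convention), and the weighted-median
    procedure is re-run.  When no SNP is outlying (all p_j >= 1/penalty_scale)
    the estimate equals the plain weighted median exactly.
    """
    if penalty_scale < 0:
        raise ParameterError("penalty_scale must be non-negative")
    if len(_pairs_frame(pairs)) < 3:
        raise EstimationError("penalized weighted median requires at least 3 instruments")
    bx, sx, by, sy, ratios, weights = _ratios_and_weights(pairs)
    if len(ratios) == 0:
        raise EstimationError("no usable ratios (all exposure betas zero)")
    beta = _weighted_median(ratios, _penalized_weights(ratios, weights, penalty_scale))

    def _point(bxs, bys, syv):
        ok = bxs != 0
        bxs, bys, syv = bxs[ok], bys[ok], syv[ok]
        r = bys / bxs
        w = bxs**2 / syv**2
        return _weighted_median(r, _penalized_weights(r, w, penalty_scale))

    se = _bootstrap_se(bx, sx, by, sy, _point, n_boot, seed)
    p = float(2 * stats.norm.sf(abs(beta / se))) if se > 0 else 0.0
    return MrEstimate(
        "penalized weighted median",
        beta,
        se,
        beta - Z95 * se,
        beta + Z95 * se,
        p,
        len(ratios),
        n_boot=n_boot,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# sensitivity wrappers
# ---------------------------------------------------------------------------


def leave_one_out(pairs, estimator=ivw, **kwargs) -> list[MrEstimate]:
    """Re-run ``estimator`` J times, omitting one instrument each time."""
    df = _pairs_frame(pairs)
    if len(df) < 2:
        raise EstimationError("leave-one-out requires at least 2 instruments")
    out = []
    for rsid in df["rsid"]:
        sub = df[df["rsid"] != rsid].reset_index(drop=True)
        est = estimator(sub, **kwargs)
        est.omitted = rsid
        out.append(est)
    return out


def exclude_and_reestimate(pairs, exclude, estimator=ivw, **kwargs) -> MrEstimate:
    """Apply ``estimator`` to the complement of an exclusion set.

    rsids in ``exclude`` that are not instruments are reported (warning) and
    ignored; an empty complement is an error.
    """
    df = _pairs_frame(pairs)
    exclude = set(exclude)
    unknown = exclude - set(df["rsid"])
    if unknown:
        warnings.warn(
            f"exclusion set contains non-instrument rsid(s), ignored: {sorted(unknown)}",
            stacklevel=2,
        )
    sub = df[~df["rsid"].isin(exclude)].reset_index(drop=True)
    if sub.empty:
        raise EstimationError("exclusion removes every instrument")
    return estimator(sub, **kwargs)


# ---------------------------------------------------------------------------
# one-sample two-stage least squares
# ---------------------------------------------------------------------------


def tsls(exposure, outcome, instrument) -> TslsEstimate:
    """Two-stage least squares with a single (genetic-score) instrument.

    Stage 1 regresses the exposure on the instrument; stage 2 regresses the
    outcome on the stage-1 fitted values.  The SE uses the standard IV
    variance formula with stage-2 residuals computed against the *observed*
    exposure.  The first-stage F statistic is reported; an instrument with
    (numerically) zero first-stage association raises
    ``WeakInstrumentError``.
    """
    x = np.asarray(exposure, dtype=float)
    y = np.asarray(outcome, dtype=float)
    z = np.asarray(instrument, dtype=float)
    n = len(x)
    if n < 3 or len(y) != n or len(z) != n:
        raise ParameterError("exposure, outcome and instrument must share length >= 3")
    xc, yc, zc = x - x.mean(), y - y.mean(), z - z.mean()
    szz = float(zc @ zc)
    szx = float(zc @ xc)
    if szz == 0:
        raise WeakInstrumentError("instrument is constant")
    if abs(szx) < 1e-12 * np.sqrt(szz * float(xc @ xc)):
        raise WeakInstrumentError("instrument has no first-stage association")

    beta = float(zc @ yc) / szx
    alpha = y.mean() - beta * x.mean()
    resid = y - alpha - beta * x  # against observed exposure
    sigma2 = float(resid @ resid) / (n - 2)
    se = float(np.sqrt(sigma2 * szz / szx**2))

    r2_first = szx**2 / (szz * float(xc @ xc))
    f_first = (n - 2) * r2_first / (1 - r2_first) if r2_first < 1 else np.inf
    p = float(2 * stats.norm.sf(abs(beta / se))) if se > 0 else 0.0
    return TslsEstimate(
        beta, se, beta - Z95 * se, beta + Z95 * se, p, float(f_first), n
    )


# ---------------------------------------------------------------------------
# unit conversion and mediation
# ---------------------------------------------------------------------------


def sd_unit_conversion(beta: float, sd_outcome: float) -> float:
    """Convert an effect from raw outcome units to SD-of-outcome units."""
    if sd_outcome <= 0:
        raise ParameterError("sd_outcome must be positive")
    return beta / sd_outcome


def mediation_expectation(
    a: float, se_a: float, b: float, se_b: float, unit: str = ""
) -> MediationExpectation:
    """Expected total effect if the exposure acts only through the mediator.

    Product of paths a (mediator per 1-SD exposure) and b (outcome per
    mediator unit): point estimate a*b with first-order delta-method SE
    sqrt(a^2 se_b^2 + b^2 se_a^2).  The caller is responsible for the units
    of ``b``'s denominator matching ``a``'s numerator.
    """
    effect = a * b
    se = float(np.sqrt(a**2 * se_b**2 + b**2 * se_a**2))
    return MediationExpectation(
        effect, se, effect - Z95 * se, effect + Z95 * se, a, b, unit
    )
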