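"""Genetic-score construction and instrument-strength diagnostics.

A set of independent exposure-associated SNPs is summarized two ways:

* per individual, as a weighted allele score ``GS = sum_i w_i g_i`` (weights
  = per-allele GWAS effects, ``g_i`` = dosage 0-2), standardized within the
  analysis sample;
* per instrument, as the share of exposure variance explained
  ``beta^2 * 2p(1-p) / var(Y)`` (summed across independent SNPs for the
  total), the F statistic ``(beta/se)^2`` (averaged for the mean F), and
  Cochran's Q heterogeneity about the inverse-variance-weighted fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateSnpError, EstimationError, ParameterError
from .summary_stats import HarmonizedPairs


@dataclass
class GeneticScore:
    """A weighted allele score and its standardized form."""

    rsids: list[str]
    weights: np.ndarray
    raw: np.ndarray
    standardized: np.ndarray


@dataclass
class InstrumentDiagnostics:
    """Instrument-strength and heterogeneity summary for one SNP panel.

    ``weighting`` records the weighting scheme Cochran's Q was computed
    under (first-order weights use the outcome SE only).
    """

    per_snp: pd.DataFrame  # rsid, r2, f
    total_r2: float
    mean_f: float
    q: float | None = None
    q_df: int | None = None
    q_pval: float | None = None
    weighting: str = "first-order (outcome SE only)"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean_F": [self.mean_f],
                "Q": [self.q],
                "df": [self.q_df],
                "p": [self.q_pval],
                "total_r2": [self.total_r2],
                "weighting": [self.weighting],
            }
        )


def variance_explained(beta, p, var_y: float):
    """Share of phenotypic variance explained by a SNP: beta^2*2p(1-p)/var(Y).

    ``beta`` is the per-allele effect on the raw phenotype scale, ``p`` the
    allele frequency and ``var_y`` the phenotypic variance on that same
    scale.  Summing over independent SNPs gives the panel's total r2.
    Symmetric in allele labelling: (beta, p) and (-beta, 1-p) give the same
    value.  Accepts scalars or arrays.
    """
    beta = np.asarray(beta, dtype=float)
    p = np.asarray(p, dtype=float)
    if var_y <= 0:
        raise ParameterError("var_y must be positive")
    if np.any((p <= 0) | (p >= 1)):
        raise DegenerateSnpError("allele frequency must be strictly inside (0, 1)")
    out = beta**2 * 2 * p * (1 - p) / var_y
    return float(out) if out.ndim == 0 else out


def total_variance_explained(beta, p, var_y: float) -> float:
    return float(np.sum(variance_explained(beta, p, var_y)))


def build_score(
    genotypes: np.ndarray,
    weights: np.ndarray,
    rsids: list[str] | None = None,
) -> GeneticScore:
    """Weighted standardized genetic score from a dosage matrix.

    ``genotypes`` is (n_individuals, n_snps) with dosages in [0, 2]; missing
    dosages (NaN) are mean-imputed per SNP, and SNPs missing in everyone are
    excluded with a warning.  The raw score is the weighted dosage sum; the
    standardized score is z-scored against the sample (mean 0, SD 1,
    denominator ddof=1).
    """
    G = np.asarray(genotypes, dtype=float)
    w = np.asarray(weights, dtype=float)
    if G.ndim != 2 or G.shape[1] != w.shape[0]:
        raise ParameterError(
            f"genotype matrix {G.shape} does not match {w.shape[0]} weights"
        )
    if np.nanmin(G) < 0 or np.nanmax(G) > 2:
        raise ParameterError("dosages must lie in [0, 2]")
    if rsids is None:
        rsids = [f"snp{i}" for i in range(G.shape[1])]

    all_missing = np.all(np.isnan(G), axis=0)
    if all_missing.any():
        warnings.warn(
            f"excluding SNP(s) with no observed dosages: "
            f"{[rsids[i] for i in np.flatnonzero(all_missing)]}",
            stacklevel=2,
        )
        G = G[:, ~all_missing]
        w = w[~all_missing]
        rsids = [r for r, m in zip(rsids, all_missing) if not m]

    if np.isnan(G).any():
        col_means = np.nanmean(G, axis=0)
        nan_idx = np.where(np.isnan(G))
        G = G.copy()
        G[nan_idx] = np.take(col_means, nan_idx[1])

    raw = G @ w
    if len(raw) < 2:
        # a one-person sample carries no scale; the raw score is still valid
        standardized = np.zeros_like(raw)
    else:
        sd = raw.std(ddof=1)
        if sd == 0:
            raise EstimationError("genetic score has zero variance in this sample")
        standardized = (raw - raw.mean()) / sd
    return GeneticScore(list(rsids), w, raw, standardized)


def f_statistics(pairs: HarmonizedPairs | pd.DataFrame) -> tuple[np.ndarray, float]:
    """Per-SNP F = (beta_x / se_x)^2 and the arithmetic mean F."""
    df = pairs.pairs if isinstance(pairs, HarmonizedPairs) else pairs
    if len(df) == 0:
        raise EstimationError("cannot compute F statistics on an empty instrument set")
    bx = df["beta_x"].to_numpy(dtype=float)
    sx = df["se_x"].to_numpy(dtype=float)
    if np.any(sx <= 0):
        raise ParameterError("se_x must be > 0 for all instruments")
    f = (bx / sx) ** 2
    return f, float(f.mean())


def cochran_q(
    pairs: HarmonizedPairs | pd.DataFrame, beta_ivw: float
) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity of the instruments about the IVW fit.

    Q = sum_j (beta_y_j - beta_ivw * beta_x_j)^2 / se_y_j^2 with J-1 degrees
    of freedom and an upper-tail chi-square p-value.  Weights are first-order
    (outcome SE only), matching the fixed-effects IVW weighting.
    """
    df = pairs.pairs if isinstance(pairs, HarmonizedPairs) else pairs
    if len(df) < 2:
        raise EstimationError("Cochran's Q requires at least 2 instruments")
    resid = df["beta_y"].to_numpy(dtype=float) - beta_ivw * df["beta_x"].to_numpy(
        dtype=float
    )
    q = float(np.sum((resid / df["se_y"].to_numpy(dtype=float)) ** 2))
    dof = len(df) - 1
    return q, dof, float(stats.chi2.sf(q, dof))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Bonferroni-corrected per-test significance threshold alpha/m."""
    if not 0 < alpha < 1:
        raise ParameterError("alpha must be in (0, 1)")
    if m < 1:
        raise ParameterError("m must be >= 1")
    return alpha / m


def compute_diagnostics(
    pairs: HarmonizedPairs | pd.DataFrame,
    var_y: float,
    exposure_beta=None,
    exposure_eaf=None,
) -> InstrumentDiagnostics:
    """All instrument diagnostics for a harmonized panel in one object.

    Variance explained is evaluated from the pairs' exposure betas and
    frequencies unless raw-scale ``exposure_beta``/``exposure_eaf`` arrays
    are supplied (use these when the pairs have been rescaled to SD units,
    since r2 must be computed on the scale ``var_y`` refers to).  Q is taken
    about the fixed-effects IVW estimate.
    """
    from .estimators import ivw  # local import: estimators builds on this module

    df = pairs.pairs if isinstance(pairs, HarmonizedPairs) else pairs
    if exposure_beta is None:
        exposure_beta = df["beta_x"].to_numpy(dtype=float)
        exposure_eaf = df["eaf"].to_numpy(dtype=float)
    r2 = variance_explained(exposure_beta, exposure_eaf, var_y)
    f, mean_f = f_statistics(df)
    per_snp = pd.DataFrame({"rsid": df["rsid"], "r2": r2, "f": f})
    est = ivw(df)
    q, q_df, q_p = cochran_q(df, est.beta)
    return InstrumentDiagnostics(
        per_snp=per_snp,
        total_r2=float(np.sum(r2)),
        mean_f=mean_f,
        q=q,
        q_df=q_df,
        q_pval=q_p,
    )
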