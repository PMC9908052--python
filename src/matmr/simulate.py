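"""Synthetic mother-offspring duo cohorts with a urate -> SBP -> birthweight
causal chain.

The generator emulates the statistical structure of the data behind a
maternal Mendelian-randomization study of serum urate on offspring
birthweight:

* a panel of independent biallelic SNPs whose per-allele effects on the
  exposure are rescaled so that jointly they explain a fixed share of the
  exposure variance (default 6.4% across 114 SNPs, the published urate
  instrument strength);
* Mendelian transmission — each offspring inherits one maternal allele at
  random plus one paternal allele drawn from the population frequency, giving
  a per-locus mother-offspring dosage correlation of 0.5;
* a causal chain urate -> systolic blood pressure -> birthweight with
  optional direct (non-mediated) exposure effect, per-SNP fetal effects on
  birthweight, per-SNP horizontal-pleiotropy effects of the maternal
  genotype, and a shared latent confounder loading on both exposure and
  outcome (what makes the observational regression biased while MR is not).

Exposure effects are generated on the standardized (SD) scale internally;
GWAS-style summary statistics are emitted on the raw phenotypic scale whose
variance is ``var_y_exposure`` (default 1.767, the published urate phenotypic
variance in mg/dL units), so that the textbook variance-explained formula
beta^2 * 2p(1-p) / var(Y) applied to the emitted table recovers the target
r-squared.

Everything is driven by a single integer seed; a fixed config + seed yields
byte-identical cohorts and summary tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError
from .summary_stats import HarmonizedPairs, SummaryStatTable

# Non-palindromic effect/other allele pairs (strand-unambiguous by
# construction; palindromic handling is exercised separately in harmonization
# tests so that the default instrument count is stable).
_ALLELE_PAIRS = [
    ("A", "C"),
    ("A", "G"),
    ("C", "A"),
    ("C", "T"),
    ("G", "A"),
    ("G", "T"),
    ("T", "C"),
    ("T", "G"),
]


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for a mother-offspring duo cohort.

    ``b_sbp_to_bw`` (the SBP -> birthweight path, in grams per 1 SD of SBP)
    has no published point value in the source material available here and
    must be set explicitly by the caller.

    Notes
    -----
    * ``target_r2_exposure`` — share of exposure variance jointly explained
      by the SNP panel (default 0.064).
    * ``var_y_exposure`` — raw-scale phenotypic variance of the exposure
      (default 1.767 mg/dL^2); summary statistics are emitted on this scale.
    * ``a_urate_to_sbp`` — mediator path, SD SBP per SD urate (default 0.07).
    * ``confounder_effects`` — loadings of a standard-Gaussian latent
      confounder on (exposure in SD units, birthweight in grams).
    * ``pleiotropy_*`` — per-SNP direct maternal-genotype -> birthweight
      effects (grams per allele) for the fraction of invalid instruments;
      mean 0 is balanced (InSIDE-satisfying), nonzero mean directional.
    """

    n_duos: int
    b_sbp_to_bw: float
    n_snps: int = 114
    maf_range: tuple[float, float] = (0.05, 0.5)
    target_r2_exposure: float = 0.064
    var_y_exposure: float = 1.767
    a_urate_to_sbp: float = 0.07
    sd_sbp_mmHg: float = 24.23
    direct_urate_to_bw: float = 0.0
    fetal_effect_scale: float = 2.0
    confounder_effects: tuple[float, float] = (0.32, -50.0)
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    pleiotropy_frac: float = 0.0
    mean_bw: float = 3503.0
    sd_bw_resid: float = 430.0
    mean_sbp_mmHg: float = 122.0
    mean_urate_umol: float = 214.3
    sd_urate_umol: float = 41.2
    smoking_prevalence: float = 0.139
    seed: int = 0

    def __post_init__(self):
        if self.n_duos <= 0:
            raise ConfigurationError("n_duos must be positive")
        if self.n_snps <= 0:
            raise ConfigurationError("n_snps must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        if not 0 < self.target_r2_exposure < 1:
            raise ConfigurationError("target_r2_exposure must be in (0, 1)")
        if self.var_y_exposure <= 0:
            raise ConfigurationError("var_y_exposure must be positive")
        c_x, _ = self.confounder_effects
        if self.target_r2_exposure + c_x**2 >= 1:
            raise ConfigurationError(
                "infeasible exposure variance budget: "
                f"r2 ({self.target_r2_exposure}) + confounder loading^2 "
                f"({c_x**2:.3f}) must be < 1"
            )
        if abs(self.a_urate_to_sbp) >= 1:
            raise ConfigurationError(
                "infeasible SBP variance budget: |a_urate_to_sbp| must be < 1 "
                "on the SD scale"
            )
        if not 0 <= self.pleiotropy_frac <= 1:
            raise ConfigurationError("pleiotropy_frac must be in [0, 1]")


@dataclass
class SnpTruth:
    """Ground-truth per-SNP parameters shared across simulated samples."""

    rsids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    effect_allele: list[str]
    other_allele: list[str]
    maf: np.ndarray
    #: per-allele effect on the exposure, SD-of-exposure units
    w_sd: np.ndarray
    #: per-allele fetal effect on birthweight, grams
    fetal: np.ndarray
    #: per-allele direct (pleiotropic) maternal effect on birthweight, grams
    pleio: np.ndarray

    @property
    def n_snps(self) -> int:
        return len(self.rsids)

    def maternal_bw_effect(self, config: SimulationConfig) -> np.ndarray:
        """True maternal-specific per-allele effect on birthweight (grams)."""
        causal = (
            config.a_urate_to_sbp * config.b_sbp_to_bw + config.direct_urate_to_bw
        )
        return self.w_sd * causal + self.pleio

    def fetal_bw_effect(self) -> np.ndarray:
        return self.fetal.copy()


@dataclass
class DuoCohort:
    """Simulated individual-level mother-offspring records."""

    config: SimulationConfig
    truth: SnpTruth | None
    g_mother: np.ndarray  # (n_duos, n_snps) dosages 0/1/2
    g_offspring: np.ndarray
    phenotypes: pd.DataFrame
    rsids: list[str]

    @property
    def n_duos(self) -> int:
        return self.g_mother.shape[0]

    def to_frame(self) -> pd.DataFrame:
        gm = pd.DataFrame(
            self.g_mother, columns=[f"gM_{r}" for r in self.rsids]
        )
        go = pd.DataFrame(
            self.g_offspring, columns=[f"gO_{r}" for r in self.rsids]
        )
        return pd.concat(
            [self.phenotypes.reset_index(drop=True), gm, go], axis=1
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DuoCohort":
        gm_cols = [c for c in df.columns if c.startswith("gM_")]
        go_cols = [c for c in df.columns if c.startswith("gO_")]
        rsids = [c[3:] for c in gm_cols]
        pheno = df[[c for c in df.columns if not c.startswith(("gM_", "gO_"))]]
        return cls(
            config=None,
            truth=None,
            g_mother=df[gm_cols].to_numpy(dtype=np.int8),
            g_offspring=df[go_cols].to_numpy(dtype=np.int8),
            phenotypes=pheno.copy(),
            rsids=rsids,
        )

    @classmethod
    def read_tsv(cls, path: str | Path) -> "DuoCohort":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def draw_truth(config: SimulationConfig, rng: np.random.Generator) -> SnpTruth:
    """Sample the per-SNP ground truth implied by a configuration.

    Raw exposure weights are drawn standard-normal and rescaled so that the
    genetic component's variance share equals ``target_r2_exposure`` exactly
    under the sampled allele frequencies (sum over SNPs of w^2 * 2p(1-p),
    with the exposure on a unit-variance scale).
    """
    J = config.n_snps
    maf = rng.uniform(*config.maf_range, size=J)
    raw = rng.standard_normal(J)
    het = 2 * maf * (1 - maf)
    scale = np.sqrt(config.target_r2_exposure / np.sum(raw**2 * het))
    w_sd = raw * scale

    fetal = rng.normal(0.0, config.fetal_effect_scale, size=J)
    invalid = rng.random(J) < config.pleiotropy_frac
    pleio = np.where(
        invalid, rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=J), 0.0
    )

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=J)
    ea = [_ALLELE_PAIRS[i][0] for i in pair_idx]
    oa = [_ALLELE_PAIRS[i][1] for i in pair_idx]
    width = len(str(J))
    rsids = [f"rs{i + 1:0{width}d}" for i in range(J)]
    chrom = (np.arange(J) % 22) + 1
    pos = 1_000_000 + np.arange(J) * 750_000
    return SnpTruth(rsids, chrom, pos, ea, oa, maf, w_sd, fetal, pleio)


def simulate_duos(
    config: SimulationConfig,
    truth: SnpTruth | None = None,
    rng: np.random.Generator | None = None,
) -> DuoCohort:
    """Generate a mother-offspring duo cohort under the configured model.

    Pass a shared ``truth`` (and distinct ``rng`` streams) to draw several
    independent samples — e.g. an exposure-GWAS sample and an outcome-GWAS
    sample — from one underlying set of SNP effects, as a two-sample design
    requires.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if truth is None:
        truth = draw_truth(config, rng)

    n, J = config.n_duos, truth.n_snps
    maf = truth.maf
    g_m = rng.binomial(2, maf, size=(n, J)).astype(np.int8)
    transmitted = rng.binomial(1, g_m / 2.0).astype(np.int8)
    paternal = rng.binomial(1, maf, size=(n, J)).astype(np.int8)
    g_o = (transmitted + paternal).astype(np.int8)

    c_x, c_y = config.confounder_effects
    r2 = config.target_r2_exposure
    centered_m = g_m - 2 * maf
    gs_sd = centered_m @ truth.w_sd

    confounder = rng.standard_normal(n)
    e_x = rng.normal(0.0, np.sqrt(1 - r2 - c_x**2), size=n)
    urate_sd = gs_sd + c_x * confounder + e_x

    a = config.a_urate_to_sbp
    sbp_sd = a * urate_sd + rng.normal(0.0, np.sqrt(1 - a**2), size=n)

    centered_o = g_o - 2 * maf
    bw = (
        config.mean_bw
        + config.b_sbp_to_bw * sbp_sd
        + config.direct_urate_to_bw * urate_sd
        + centered_o @ truth.fetal
        + centered_m @ truth.pleio
        + c_y * confounder
        + rng.normal(0.0, config.sd_bw_resid, size=n)
    )

    pheno = pd.DataFrame(
        {
            "urate_sd": urate_sd,
            "urate_umol": config.mean_urate_umol + config.sd_urate_umol * urate_sd,
            "urate_gwas": np.sqrt(config.var_y_exposure) * urate_sd,
            "sbp_sd": sbp_sd,
            "sbp_mmHg": config.mean_sbp_mmHg + config.sd_sbp_mmHg * sbp_sd,
            "birthweight": bw,
            "confounder": confounder,
            "age": rng.normal(30.5, 5.1, size=n),
            "bmi": rng.normal(27.9, 4.6, size=n),
            "smoking": rng.binomial(1, config.smoking_prevalence, size=n),
            "offspring_sex": rng.binomial(1, 0.5, size=n),
            "gestational_age": rng.normal(40.1, 1.2, size=n),
        }
    )
    return DuoCohort(config, truth, g_m, g_o, pheno, list(truth.rsids))


# ---------------------------------------------------------------------------
# per-SNP association scans
# ---------------------------------------------------------------------------


def _simple_regression_scan(
    y: np.ndarray, G: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-column OLS of y on each genotype column.

    Returns (beta, se, pval, keep_mask); monomorphic columns get
    ``keep_mask = False``.
    """
    n = len(y)
    G = G.astype(np.float64)
    gbar = G.mean(axis=0)
    yc = y - y.mean()
    Gc = G - gbar
    sgg = np.einsum("ij,ij->j", Gc, Gc)
    sgy = Gc.T @ yc
    keep = sgg > 0
    beta = np.full(G.shape[1], np.nan)
    se = np.full(G.shape[1], np.nan)
    beta[keep] = sgy[keep] / sgg[keep]
    syy = float(yc @ yc)
    rss = syy - beta[keep] * sgy[keep]
    sigma2 = np.maximum(rss, 0.0) / (n - 2)
    se[keep] = np.sqrt(sigma2 / sgg[keep])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    pval = 2 * stats.t.sf(np.abs(tstat), df=n - 2)
    # guard against exact zeros that would violate the (0, 1] invariant
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)
    return beta, se, pval, keep


def _scan_to_table(
    cohort: DuoCohort,
    y: np.ndarray,
    G: np.ndarray,
    trait: str,
    unit: str,
) -> SummaryStatTable:
    truth = cohort.truth
    beta, se, pval, keep = _simple_regression_scan(y, G)
    if not keep.all():
        bad = [cohort.rsids[i] for i in np.flatnonzero(~keep)]
        warnings.warn(
            f"{trait}: excluded monomorphic SNP(s) with undefined beta: {bad}",
            stacklevel=2,
        )
    eaf = G.mean(axis=0) / 2.0
    df = pd.DataFrame(
        {
            "rsid": cohort.rsids,
            "chrom": truth.chrom if truth else 0,
            "pos": truth.pos if truth else 0,
            "effect_allele": truth.effect_allele if truth else "A",
            "other_allele": truth.other_allele if truth else "G",
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pval": pval,
            "n": cohort.n_duos,
        }
    )
    return SummaryStatTable(trait, unit, df[keep].reset_index(drop=True))


def cohort_to_summary_stats(
    cohort: DuoCohort,
) -> tuple[SummaryStatTable, SummaryStatTable, SummaryStatTable]:
    """Emulate the three GWAS the two-sample design consumes.

    Per SNP, simple linear regression of (i) maternal exposure (raw GWAS
    scale) on maternal dosage, (ii) birthweight on offspring dosage ("own
    birthweight" GWAS), (iii) birthweight on maternal dosage ("offspring
    birthweight" GWAS).  Monomorphic SNPs are excluded with a warning.
    """
    if cohort.n_duos < 3:
        raise ConfigurationError("cohort too small for per-SNP regression")
    y_x = cohort.phenotypes["urate_gwas"].to_numpy()
    y_bw = cohort.phenotypes["birthweight"].to_numpy()
    exposure = _scan_to_table(cohort, y_x, cohort.g_mother, "urate", "mg/dL urate")
    own = _scan_to_table(
        cohort, y_bw, cohort.g_offspring, "own_birthweight", "g birthweight"
    )
    offspring = _scan_to_table(
        cohort, y_bw, cohort.g_mother, "offspring_birthweight", "g birthweight"
    )
    return exposure, own, offspring


def own_offspring_sampling_cov(cohort: DuoCohort) -> pd.Series:
    """Per-SNP sampling covariance between the own-BW and offspring-BW betas
    when both scans are run on the *same* duos.

    For simple regressions of one outcome y on two correlated regressors
    (offspring and maternal dosage), the estimation errors covary by
    approximately rho_j * se_own_j * se_off_j with rho_j the sample
    mother-offspring dosage correlation (~0.5).  Needed by the weighted
    linear model when the two birthweight GWAS share their sample; for
    disjoint samples the covariance is zero.
    """
    g_m = cohort.g_mother.astype(np.float64)
    g_o = cohort.g_offspring.astype(np.float64)
    g_m -= g_m.mean(axis=0)
    g_o -= g_o.mean(axis=0)
    n = cohort.n_duos
    var_m = np.einsum("ij,ij->j", g_m, g_m)
    var_o = np.einsum("ij,ij->j", g_o, g_o)
    cov_mo = np.einsum("ij,ij->j", g_m, g_o)

    y = cohort.phenotypes["birthweight"].to_numpy()
    _, se_own, _, keep = _simple_regression_scan(y, cohort.g_offspring)
    _, se_off, _, _ = _simple_regression_scan(y, cohort.g_mother)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = cov_mo / np.sqrt(var_m * var_o)
    cov = rho * se_own * se_off
    return pd.Series(cov, index=cohort.rsids)[pd.Series(keep, index=cohort.rsids)]


# ---------------------------------------------------------------------------
# summary-level replication (fast Monte Carlo over the GWAS sampling step)
# ---------------------------------------------------------------------------


def gwas_se(n: int, maf: np.ndarray, resid_sd: float | np.ndarray) -> np.ndarray:
    """Asymptotic per-allele SE of a simple-regression GWAS beta."""
    return np.asarray(resid_sd) / np.sqrt(n * 2 * maf * (1 - maf))


def simulate_summary_instruments(
    truth: SnpTruth,
    config: SimulationConfig,
    n_exposure: int,
    n_outcome: int,
    rng: np.random.Generator,
    exposure_scale: str = "sd",
) -> HarmonizedPairs:
    """Draw one harmonized instrument set directly at the summary level.

    Samples the exposure and (maternal-specific) outcome betas from their
    asymptotic GWAS sampling distributions around the generative truth —
    orders of magnitude faster than simulating individuals, hence suited to
    replicate-heavy Monte Carlo checks of the estimators.  The outcome SE
    uses the cohort's total birthweight SD as residual scale.

    ``exposure_scale`` is ``"sd"`` (betas per allele in SD-of-exposure units)
    or ``"raw"`` (multiplied by sqrt(var_y_exposure), the emitted GWAS scale).
    """
    sd_x = np.sqrt(1 - config.target_r2_exposure)
    se_x = gwas_se(n_exposure, truth.maf, sd_x)
    bx = truth.w_sd + rng.normal(0.0, se_x)
    if exposure_scale == "raw":
        f = np.sqrt(config.var_y_exposure)
        bx, se_x = bx * f, se_x * f
    elif exposure_scale != "sd":
        raise ValueError("exposure_scale must be 'sd' or 'raw'")

    sd_bw = total_birthweight_sd(config, truth)
    se_y = gwas_se(n_outcome, truth.maf, sd_bw)
    by = truth.maternal_bw_effect(config) + rng.normal(0.0, se_y)

    pairs = pd.DataFrame(
        {
            "rsid": truth.rsids,
            "beta_x": bx,
            "se_x": se_x,
            "beta_y": by,
            "se_y": se_y,
            "eaf": truth.maf,
            "flags": "",
        }
    )
    return HarmonizedPairs(pairs, pd.DataFrame(columns=["rsid", "reason"]))


def total_birthweight_sd(config: SimulationConfig, truth: SnpTruth) -> float:
    """Model-implied total SD of birthweight (grams)."""
    het = 2 * truth.maf * (1 - truth.maf)
    causal = config.a_urate_to_sbp * config.b_sbp_to_bw + config.direct_urate_to_bw
    # small genotype-mediated cross-covariances (order Sum pq*w*f) are ignored
    var = (
        config.b_sbp_to_bw**2 * (1 - config.a_urate_to_sbp**2)
        + causal**2  # via urate (unit variance)
        + float(het @ truth.fetal**2)
        + float(het @ truth.pleio**2)
        + config.confounder_effects[1] ** 2
        + 2
        * causal
        * config.confounder_effects[0]
        * config.confounder_effects[1]
        + config.sd_bw_resid**2
    )
    return float(np.sqrt(var))


def make_pleiotropy_lookup(
    truth: SnpTruth,
    rng: np.random.Generator,
    n_genome_wide: int = 2,
    n_bonferroni_extra: int = 6,
) -> pd.DataFrame:
    """Emulate an external-trait (smoking) GWAS lookup table for the panel.

    Mirrors the published worked case: a couple of instruments reach
    genome-wide significance for the external trait and a handful more pass
    only a Bonferroni threshold; the remainder are null.  The flagged SNPs
    are chosen at random and carry no actual pleiotropic effect in the
    default generative model.
    """
    J = truth.n_snps
    flagged = rng.choice(J, size=min(J, n_genome_wide + n_bonferroni_extra), replace=False)
    pvals = rng.uniform(0.05, 1.0, size=J)
    pvals[flagged[:n_genome_wide]] = 10.0 ** rng.uniform(-12, -9, size=n_genome_wide)
    pvals[flagged[n_genome_wide:]] = 10.0 ** rng.uniform(
        -6, -4, size=len(flagged) - n_genome_wide
    )
    return pd.DataFrame({"rsid": truth.rsids, "pval": pvals})


def make_proxy_scenario(
    cohort: DuoCohort,
    rng: np.random.Generator,
    n_missing: int = 10,
    n_proxied: int = 6,
    r2_good: tuple[float, float] = (0.82, 0.99),
    r2_bad: tuple[float, float] = (0.3, 0.79),
) -> tuple[list[str], pd.DataFrame, pd.DataFrame]:
    """Construct an LD-proxy worked case on a genotyped cohort.

    Marks ``n_missing`` instruments as ungenotyped; for ``n_proxied`` of them
    creates a correlated proxy variant (dosages copied allele-wise from the
    target with error, so that the realized r2 matches the advertised one)
    while the rest get only sub-threshold proxies.  Returns
    ``(missing_rsids, proxy_genotypes, proxy_table)`` where
    ``proxy_genotypes`` is a DataFrame of maternal proxy dosages keyed by
    proxy rsid.
    """
    J = cohort.g_mother.shape[1]
    missing_idx = rng.choice(J, size=n_missing, replace=False)
    missing = [cohort.rsids[i] for i in missing_idx]
    rows, geno = [], {}
    for k, idx in enumerate(missing_idx):
        rsid = cohort.rsids[idx]
        proxy_id = f"{rsid}_proxy"
        if k < n_proxied:
            r2 = rng.uniform(*r2_good)
            theta = np.sqrt(r2)  # per-allele copy fidelity -> dosage corr
            g_t = cohort.g_mother[:, idx].astype(np.int64)
            maf = g_t.mean() / 2.0
            keep_allele = rng.random((cohort.n_duos, 2)) < theta
            alleles_t = np.column_stack(
                [(g_t >= 1).astype(np.int8), (g_t == 2).astype(np.int8)]
            )
            random_alleles = rng.binomial(1, maf, size=(cohort.n_duos, 2))
            g_p = np.where(keep_allele, alleles_t, random_alleles).sum(axis=1)
            geno[f"gM_{proxy_id}"] = g_p.astype(np.int8)
            rows.append((rsid, proxy_id, float(r2)))
        else:
            rows.append((rsid, proxy_id, float(rng.uniform(*r2_bad))))
    proxy_table = pd.DataFrame(rows, columns=["target", "proxy", "r2"])
    return missing, pd.DataFrame(geno), proxy_table
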