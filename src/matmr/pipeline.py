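"""Config-driven end-to-end orchestration of the maternal-MR analysis graph.

Stages, in dependency order:

1. load and validate the exposure / own-birthweight / offspring-birthweight
   summary tables;
2. partition the two birthweight GWAS into maternal- and fetal-specific
   effects (weighted linear model) and take the maternal effects as the MR
   outcome;
3. harmonize exposure and outcome to a common effect allele and rescale
   exposure betas to per-1-SD units;
4. instrument diagnostics (total r2, mean F, Cochran's Q, Bonferroni
   threshold);
5. two-sample MR (IVW, MR-Egger, weighted median, penalized weighted
   median) plus the pleiotropy sensitivity set (external-trait lookup,
   SNP-exclusion re-estimation, optional leave-one-out);
6. one-sample stages on an individual-level cohort, when provided: genetic
   score (with LD-proxy substitution for ungenotyped instruments), GS
   validation against the measured exposure, two-stage least squares of the
   mediator on the exposure, GS-covariate association, and the
   confounder-adjusted observational regression;
7. mediation expectation (product of the estimated exposure->mediator path
   and a supplied mediator->outcome path);
8. report with full provenance (config hash, seed, input checksums).

Given a fixed config and seed the report is bitwise reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml

from . import __version__
from .estimators import (
    MrEstimate,
    exclude_and_reestimate,
    ivw,
    leave_one_out,
    mediation_expectation,
    mr_egger,
    penalized_weighted_median,
    sd_unit_conversion,
    tsls,
    weighted_median,
)
from .exceptions import EstimationError, ParameterError, StageError
from .instruments import (
    bonferroni_threshold,
    build_score,
    cochran_q,
    f_statistics,
    total_variance_explained,
)
from .simulate import DuoCohort
from .summary_stats import (
    SummaryStatTable,
    harmonize,
    read_summary_stats,
    substitute_proxies,
)
from .wlm import wlm_partition

logger = logging.getLogger("matmr.pipeline")

_METHODS = {
    "ivw": ivw,
    "egger": mr_egger,
    "wm": weighted_median,
    "pwm": penalized_weighted_median,
}


@dataclass
class AnalysisConfig:
    """Inputs, thresholds and switches for one pipeline run.

    Paths are resolved relative to the config file when loaded with
    ``AnalysisConfig.from_yaml``.  ``seed`` drives every stochastic step
    (the median bootstraps) and is mandatory.
    """

    exposure: str
    own_bw: str
    offspring_bw: str
    seed: int
    cohort: str | None = None
    lookup: str | None = None
    proxies: str | None = None
    out_dir: str | None = None
    dialects: dict = field(default_factory=dict)
    covariates: list[str] = field(default_factory=list)
    methods: list[str] = field(default_factory=lambda: ["ivw", "egger", "wm", "pwm"])
    gw_threshold: float = 5e-8
    bonferroni_alpha: float = 0.05
    bonferroni_m: int | None = None
    palindrome_eaf_limit: float = 0.42
    r2_min: float = 0.8
    var_y_exposure: float = 1.767
    n_boot: int = 1000
    exclude: list[str] = field(default_factory=list)
    mediator_to_outcome: float | None = None
    mediator_to_outcome_se: float = 0.0
    run_sensitivity: bool = True
    run_leave_one_out: bool = False
    exposure_col: str = "urate_umol"
    mediator_col: str = "sbp_mmHg"
    outcome_col: str = "birthweight"
    binary_covariate_col: str = "smoking"

    def __post_init__(self):
        unknown = [m for m in self.methods if m not in _METHODS]
        if unknown:
            raise ParameterError(f"unknown MR method(s): {unknown}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("exposure", "own_bw", "offspring_bw", "cohort", "lookup", "proxies", "out_dir"):
            if raw.get(key):
                raw[key] = str((path.parent / raw[key]).resolve())
        return cls(**raw)


@dataclass
class ObservationalEstimate:
    beta: float  # outcome units per 1-SD exposure
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_used: int
    n_dropped: int
    covariates: list[str]


@dataclass
class GroupDifference:
    diff: float  # difference in mean standardized GS between groups
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n0: int
    n1: int


@dataclass
class LookupResult:
    gw_significant: set[str]
    bonferroni_significant: set[str]  # nested: includes the genome-wide set
    unevaluable: set[str]
    gw_threshold: float
    bonferroni_threshold: float


@dataclass
class RunReport:
    """Per-stage estimates with provenance."""

    stages: dict
    provenance: dict

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(
            {"stages": self.stages, "provenance": self.provenance},
            indent=indent,
            sort_keys=True,
            default=_jsonable,
        )

    def summary_text(self) -> str:
        lines = [f"matmr run report (seed {self.provenance['seed']})", "=" * 40]
        for stage, payload in self.stages.items():
            lines.append(f"\n[{stage}]")
            lines.append(json.dumps(payload, indent=2, sort_keys=True, default=_jsonable))
        return "\n".join(lines)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    if hasattr(obj, "to_dict"):
        return obj.to_dict()
    if hasattr(obj, "__dataclass_fields__"):
        return asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# individual stages (usable standalone)
# ---------------------------------------------------------------------------


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    """Name columns involved in exact linear dependence, via R^2 on the rest."""
    bad = []
    arr = X.to_numpy(dtype=float)
    for i, col in enumerate(X.columns):
        others = np.delete(arr, i, axis=1)
        beta, *_ = np.linalg.lstsq(others, arr[:, i], rcond=None)
        resid = arr[:, i] - others @ beta
        denom = np.var(arr[:, i])
        if denom == 0 or float(resid @ resid) / (len(resid) * denom) < 1e-10:
            bad.append(col)
    return bad


def observational_stage(
    frame: pd.DataFrame,
    exposure_col: str,
    outcome_col: str,
    covariates: list[str] | None = None,
) -> ObservationalEstimate:
    """Confounder-adjusted OLS of the outcome on the standardized exposure.

    Listwise deletion on the used columns (counts reported); the exposure is
    z-scored within the analysis sample so the coefficient is in outcome
    units per 1-SD exposure.  A rank-deficient design raises an error naming
    the collinear columns.
    """
    covariates = covariates or []
    used = [exposure_col, outcome_col] + covariates
    missing_cols = [c for c in used if c not in frame.columns]
    if missing_cols:
        raise ParameterError(f"columns not in cohort table: {missing_cols}")
    data = frame[used].dropna()
    n_dropped = len(frame) - len(data)
    if len(data) < len(covariates) + 2:
        raise EstimationError("too few complete-case rows for the design")
    if n_dropped:
        logger.info("observational stage: %d rows dropped listwise", n_dropped)

    x = data[exposure_col]
    x_sd = (x - x.mean()) / x.std(ddof=1)
    X = pd.DataFrame({"exposure_sd": x_sd})
    for c in covariates:
        X[c] = data[c].to_numpy(dtype=float)
    X = sm.add_constant(X)
    if np.linalg.matrix_rank(X.to_numpy(dtype=float)) < X.shape[1]:
        bad = [c for c in _collinear_columns(X) if c != "const"]
        raise EstimationError(f"rank-deficient design; collinear columns: {bad}")

    fit = sm.OLS(data[outcome_col].to_numpy(dtype=float), X).fit()
    ci = fit.conf_int().loc["exposure_sd"]
    return ObservationalEstimate(
        beta=float(fit.params["exposure_sd"]),
        se=float(fit.bse["exposure_sd"]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        pval=float(fit.pvalues["exposure_sd"]),
        n_used=len(data),
        n_dropped=n_dropped,
        covariates=list(covariates),
    )


def pleiotropy_lookup(
    rsids,
    lookup: pd.DataFrame,
    gw_threshold: float = 5e-8,
    bonferroni_thresh: float | None = None,
) -> LookupResult:
    """Flag instruments associated with an external trait.

    ``lookup`` needs columns ``rsid`` and ``pval``.  Returns the nested sets
    of instruments at genome-wide significance and at the Bonferroni
    threshold, plus instruments absent from the lookup (unevaluable).
    """
    if bonferroni_thresh is None:
        bonferroni_thresh = bonferroni_threshold(0.05, len(list(rsids)))
    pv = lookup.set_index("rsid")["pval"]
    gw, bonf, unevaluable = set(), set(), set()
    for rsid in rsids:
        if rsid not in pv.index:
            unevaluable.add(rsid)
            continue
        p = float(pv.loc[rsid])
        if p <= gw_threshold:
            gw.add(rsid)
        if p <= bonferroni_thresh:
            bonf.add(rsid)
    return LookupResult(gw, bonf, unevaluable, gw_threshold, bonferroni_thresh)


def score_covariate_association(
    gs_standardized, covariate
) -> GroupDifference:
    """Difference in mean standardized GS between the two covariate classes.

    Equivalent to OLS of the GS on the 0/1 indicator; an instrument score
    that differs between classes flags a potential pleiotropic path through
    that covariate.
    """
    gs = np.asarray(gs_standardized, dtype=float)
    cov = np.asarray(covariate, dtype=float)
    classes = np.unique(cov)
    if not np.all(np.isin(classes, [0.0, 1.0])):
        raise ParameterError("covariate must be coded 0/1")
    if len(classes) < 2:
        raise EstimationError("covariate has a single class")
    X = sm.add_constant(cov)
    fit = sm.OLS(gs, X).fit()
    ci = fit.conf_int()[1]
    return GroupDifference(
        diff=float(fit.params[1]),
        se=float(fit.bse[1]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        pval=float(fit.pvalues[1]),
        n0=int((cov == 0).sum()),
        n1=int((cov == 1).sum()),
    )


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _genotyped_weight_table(
    exposure: SummaryStatTable, cohort_rsids: list[str], proxies: pd.DataFrame | None
) -> SummaryStatTable:
    """Exposure records restricted to genotyped SNPs, with proxy records.

    A proxy variant present in the cohort but absent from the exposure GWAS
    table inherits its target's weight (record cloned under the proxy rsid)
    so that proxy substitution can hand the score builder a usable weight.
    """
    have = set(cohort_rsids)
    rows = exposure.data[exposure.data["rsid"].isin(have)]
    extra = []
    if proxies is not None:
        by_rsid = exposure.data.set_index("rsid")
        for rec in proxies.itertuples(index=False):
            if rec.proxy in have and rec.proxy not in set(rows["rsid"]) and rec.target in by_rsid.index:
                clone = by_rsid.loc[rec.target].copy()
                clone["rsid"] = rec.proxy
                extra.append(clone)
    if extra:
        rows = pd.concat([rows, pd.DataFrame(extra)], ignore_index=True)
    return SummaryStatTable(exposure.trait, exposure.unit, rows.reset_index(drop=True))


def run_pipeline(config: AnalysisConfig) -> RunReport:
    """Execute the full analysis graph; any stage failure halts with a
    stage-named error.  Returns the report (and writes ``report.json``,
    ``report.txt`` and per-stage TSVs when ``config.out_dir`` is set)."""
    stages: dict = {}
    tables: dict[str, pd.DataFrame] = {}
    sd_exposure = float(np.sqrt(config.var_y_exposure))

    def _run(stage, fn):
        logger.info("stage %s ...", stage)
        try:
            return fn()
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(stage, str(exc)) from exc

    # -- load ---------------------------------------------------------------
    def _load():
        dial = config.dialects or {}
        exposure = read_summary_stats(
            config.exposure, dial.get("exposure"), trait="exposure"
        )
        own = read_summary_stats(config.own_bw, dial.get("own_bw"), trait="own_bw")
        off = read_summary_stats(
            config.offspring_bw, dial.get("offspring_bw"), trait="offspring_bw"
        )
        stages["load"] = {
            "n_exposure": len(exposure),
            "n_own_bw": len(own),
            "n_offspring_bw": len(off),
            "rejected_rows": int(
                len(exposure.rejected) + len(own.rejected) + len(off.rejected)
            ),
        }
        return exposure, own, off

    exposure, own, off = _run("load", _load)

    # -- WLM partition ------------------------------------------------------
    def _wlm():
        effects = wlm_partition(own, off)
        tables["wlm_effects"] = effects.data
        stages["wlm"] = {
            "n_snps": len(effects),
            "n_excluded": len(effects.excluded),
        }
        return effects

    effects = _run("wlm", _wlm)
    maternal = effects.maternal_table()

    # -- harmonize ----------------------------------------------------------
    def _harmonize():
        pairs = harmonize(exposure, maternal, config.palindrome_eaf_limit)
        tables["harmonized_pairs"] = pairs.pairs
        tables["harmonization_dropped"] = pairs.dropped
        stages["harmonize"] = {
            "n_pairs": len(pairs),
            "n_dropped": len(pairs.dropped),
            "dropped": pairs.dropped.to_dict("records"),
        }
        return pairs.with_exposure_per_sd(sd_exposure)

    pairs_sd = _run("harmonize", _harmonize)

    # -- diagnostics --------------------------------------------------------
    def _diagnostics():
        eaf = exposure.data["eaf"].to_numpy(dtype=float)
        total_r2 = total_variance_explained(
            exposure.data["beta"].to_numpy(dtype=float), eaf, config.var_y_exposure
        )
        _, mean_f = f_statistics(pairs_sd)
        est = ivw(pairs_sd)
        q, q_df, q_p = cochran_q(pairs_sd, est.beta)
        m = config.bonferroni_m or len(exposure)
        bonf = bonferroni_threshold(config.bonferroni_alpha, m)
        stages["diagnostics"] = {
            "total_r2": total_r2,
            "mean_F": mean_f,
            "cochran_q": q,
            "cochran_q_df": q_df,
            "cochran_q_pval": q_p,
            "q_weighting": "first-order (outcome SE only)",
            "bonferroni_threshold": bonf,
            "bonferroni_m": m,
        }
        return bonf

    bonf_thresh = _run("diagnostics", _diagnostics)

    # -- two-sample MR ------------------------------------------------------
    def _mr():
        out = {}
        for i, name in enumerate(config.methods):
            fn = _METHODS[name]
            if name in ("wm", "pwm"):
                est = fn(pairs_sd, n_boot=config.n_boot, seed=config.seed + i)
            else:
                est = fn(pairs_sd)
            out[name] = est.to_dict()
        stages["mr"] = out
        tables["mr_estimates"] = pd.DataFrame(out.values())
        return out

    _run("mr", _mr)

    # -- sensitivity --------------------------------------------------------
    if config.run_sensitivity:

        def _sensitivity():
            block: dict = {}
            flagged: set[str] = set(config.exclude)
            if config.lookup:
                lookup = pd.read_csv(config.lookup, sep="\t")
                res = pleiotropy_lookup(
                    exposure.rsids, lookup, config.gw_threshold, bonf_thresh
                )
                block["lookup"] = {
                    "n_genome_wide": len(res.gw_significant),
                    "n_bonferroni": len(res.bonferroni_significant),
                    "n_unevaluable": len(res.unevaluable),
                    "genome_wide": sorted(res.gw_significant),
                    "bonferroni": sorted(res.bonferroni_significant),
                }
                flagged |= res.bonferroni_significant
            if flagged:
                est = exclude_and_reestimate(pairs_sd, flagged, ivw)
                block["excluded_rsids"] = sorted(flagged)
                block["ivw_after_exclusion"] = est.to_dict()
            if config.run_leave_one_out:
                loo = leave_one_out(pairs_sd, ivw)
                tables["leave_one_out"] = pd.DataFrame(
                    [{"omitted": e.omitted, **e.to_dict()} for e in loo]
                )
                betas = [e.beta for e in loo]
                block["leave_one_out_range"] = [min(betas), max(betas)]
            stages["sensitivity"] = block

        _run("sensitivity", _sensitivity)

    # -- one-sample stages --------------------------------------------------
    cohort = None
    tsls_sd = None
    if config.cohort:

        def _one_sample():
            nonlocal cohort, tsls_sd
            cohort = DuoCohort.read_tsv(config.cohort)
            proxies = (
                pd.read_csv(config.proxies, sep="\t") if config.proxies else None
            )
            geno_table = _genotyped_weight_table(exposure, cohort.rsids, proxies)
            if proxies is not None:
                usable, report = substitute_proxies(
                    geno_table, exposure.rsids, proxies, config.r2_min
                )
                tables["proxy_report"] = report
            else:
                usable = geno_table.subset(exposure.rsids)
                report = None
            idx = [cohort.rsids.index(r) for r in usable.rsids]
            gs = build_score(
                cohort.g_mother[:, idx].astype(float),
                usable.data["beta"].to_numpy(dtype=float),
                usable.rsids,
            )
            pheno = cohort.phenotypes
            x = pheno[config.exposure_col].to_numpy(dtype=float)
            x_sd = (x - x.mean()) / x.std(ddof=1)

            gs_fit = sm.OLS(x, sm.add_constant(gs.standardized)).fit()
            block = {
                "n_instruments_usable": len(usable),
                "gs_validation": {
                    "beta_per_sd_gs": float(gs_fit.params[1]),
                    "se": float(gs_fit.bse[1]),
                    "ci_low": float(gs_fit.conf_int()[1][0]),
                    "ci_high": float(gs_fit.conf_int()[1][1]),
                    "unit": "exposure raw units per 1-SD GS",
                    "n": cohort.n_duos,
                },
            }
            if report is not None:
                block["proxy_substitution"] = {
                    "n_wanted": len(exposure),
                    "n_present": int((report["status"] == "present").sum()),
                    "n_proxied": int((report["status"] == "proxied").sum()),
                    "n_excluded": int((report["status"] == "excluded").sum()),
                }

            med = pheno[config.mediator_col].to_numpy(dtype=float)
            est = tsls(x_sd, med, gs.standardized)
            sd_med = float(med.std(ddof=1))
            tsls_sd = (
                sd_unit_conversion(est.beta, sd_med),
                sd_unit_conversion(est.se, sd_med),
            )
            block["tsls_exposure_to_mediator"] = {
                "beta": est.beta,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "pval": est.pval,
                "first_stage_F": est.first_stage_f,
                "n": est.n,
                "unit": "mediator raw units per 1-SD exposure",
                "beta_sd_units": tsls_sd[0],
                "sd_mediator": sd_med,
            }

            if config.binary_covariate_col in pheno.columns:
                assoc = score_covariate_association(
                    gs.standardized, pheno[config.binary_covariate_col].to_numpy()
                )
                block["gs_covariate_association"] = asdict(assoc)

            obs = observational_stage(
                pheno, config.exposure_col, config.outcome_col, config.covariates
            )
            stages["observational"] = asdict(obs)
            stages["one_sample"] = block

        _run("one_sample", _one_sample)

    # -- mediation ----------------------------------------------------------
    if config.mediator_to_outcome is not None and tsls_sd is not None:

        def _mediation():
            a, se_a = tsls_sd
            med = mediation_expectation(
                a,
                se_a,
                config.mediator_to_outcome,
                config.mediator_to_outcome_se,
                unit="outcome units per 1-SD exposure (full mediation)",
            )
            stages["mediation"] = asdict(med)

        _run("mediation", _mediation)

    # -- report -------------------------------------------------------------
    provenance = {
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True).encode()
        ).hexdigest(),
        "input_sha256": {
            name: _sha256(path)
            for name, path in {
                "exposure": config.exposure,
                "own_bw": config.own_bw,
                "offspring_bw": config.offspring_bw,
                "cohort": config.cohort,
                "lookup": config.lookup,
                "proxies": config.proxies,
            }.items()
            if path
        },
    }
    report = RunReport(stages, provenance)

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json())
        (out / "report.txt").write_text(report.summary_text())
        for name, df in tables.items():
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    return report
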