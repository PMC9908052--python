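"""Partition of birthweight GWAS effects into maternal- and fetal-specific
components.

A GWAS of *own* birthweight mixes the direct effect of an individual's
genotype with the indirect effect of the correlated maternal genotype on the
intrauterine environment, and vice versa for a GWAS of *offspring*
birthweight in mothers.  With a mother-offspring dosage correlation of 0.5
(Mendelian transmission) the expectations are

    E[beta_own]       = beta_F + 0.5 * beta_M
    E[beta_offspring] = beta_M + 0.5 * beta_F

Inverting this two-equation structural system gives the adjusted effects

    beta_M = (4 * beta_offspring - 2 * beta_own) / 3
    beta_F = (4 * beta_own - 2 * beta_offspring) / 3

with variances by the linear combination, e.g.
``var(beta_M) = (16 var(beta_offspring) + 4 var(beta_own) - 16 cov) / 9``
(cov is the per-SNP sampling covariance between the two input betas; zero
when the two GWAS samples are disjoint, the default).  Using the
maternal-specific effects as the MR outcome keeps the fetal genome from
violating the exclusion restriction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import EstimationError
from .summary_stats import SummaryStatTable


@dataclass
class WlmEffects:
    """Per-SNP maternal- and fetal-specific birthweight effects.

    ``data`` columns: rsid, effect_allele, other_allele, eaf, beta_maternal,
    se_maternal, beta_fetal, se_fetal, n_own, n_offspring.  ``excluded``
    lists SNPs dropped with a reason (present in only one table, or
    irreconcilable alleles).
    """

    data: pd.DataFrame
    excluded: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["rsid", "reason"])
    )

    def __len__(self) -> int:
        return len(self.data)

    def maternal_table(self, trait: str = "offspring_birthweight_maternal") -> SummaryStatTable:
        """Maternal-specific effects as a summary table (the MR outcome)."""
        return self._as_table("maternal", trait)

    def fetal_table(self, trait: str = "own_birthweight_fetal") -> SummaryStatTable:
        return self._as_table("fetal", trait)

    def _as_table(self, which: str, trait: str) -> SummaryStatTable:
        d = self.data
        df = pd.DataFrame(
            {
                "rsid": d["rsid"],
                "chrom": d.get("chrom", np.nan),
                "pos": d.get("pos", np.nan),
                "effect_allele": d["effect_allele"],
                "other_allele": d["other_allele"],
                "eaf": d["eaf"],
                "beta": d[f"beta_{which}"],
                "se": d[f"se_{which}"],
                "pval": d[f"pval_{which}"],
                "n": d["n_offspring"] if which == "maternal" else d["n_own"],
            }
        )
        return SummaryStatTable(trait, "g birthweight", df)


def wlm_partition(
    own: SummaryStatTable,
    offspring: SummaryStatTable,
    cov_own_off: pd.Series | float | None = None,
) -> WlmEffects:
    """Solve the maternal/fetal structural system per SNP.

    The two tables are first aligned to the own-table's effect allele (a
    swapped allele pair in the offspring table flips its beta); SNPs present
    in only one table or with irreconcilable alleles are excluded with a
    report.  ``cov_own_off`` is the per-SNP sampling covariance between the
    input betas — a scalar, a Series indexed by rsid, or None for 0
    (independent samples).
    """
    own_df = own.data.set_index("rsid")
    off_df = offspring.data.set_index("rsid")
    shared = [r for r in own.rsids if r in off_df.index]
    excluded = [
        (r, "absent from offspring table") for r in own.rsids if r not in off_df.index
    ] + [(r, "absent from own table") for r in offspring.rsids if r not in own_df.index]

    rows = []
    for rsid in shared:
        o, f = own_df.loc[rsid], off_df.loc[rsid]
        b_off = f["beta"]
        if (f["effect_allele"], f["other_allele"]) == (
            o["effect_allele"],
            o["other_allele"],
        ):
            pass
        elif (f["effect_allele"], f["other_allele"]) == (
            o["other_allele"],
            o["effect_allele"],
        ):
            b_off = -b_off
        else:
            excluded.append((rsid, "allele mismatch"))
            continue

        if cov_own_off is None:
            cov = 0.0
        elif np.isscalar(cov_own_off):
            cov = float(cov_own_off)
        else:
            cov = float(cov_own_off.get(rsid, 0.0))

        b_own = o["beta"]
        v_own, v_off = o["se"] ** 2, f["se"] ** 2
        beta_m = (4 * b_off - 2 * b_own) / 3
        beta_f = (4 * b_own - 2 * b_off) / 3
        var_m = (16 * v_off + 4 * v_own - 16 * cov) / 9
        var_f = (16 * v_own + 4 * v_off - 16 * cov) / 9
        if var_m <= 0 or var_f <= 0:
            excluded.append((rsid, "non-positive adjusted variance"))
            continue
        rows.append(
            {
                "rsid": rsid,
                "chrom": o["chrom"],
                "pos": o["pos"],
                "effect_allele": o["effect_allele"],
                "other_allele": o["other_allele"],
                "eaf": o["eaf"] if np.isfinite(o["eaf"]) else f["eaf"],
                "beta_maternal": beta_m,
                "se_maternal": np.sqrt(var_m),
                "beta_fetal": beta_f,
                "se_fetal": np.sqrt(var_f),
                "n_own": o["n"],
                "n_offspring": f["n"],
            }
        )

    if not rows:
        raise EstimationError("no SNP shared between own and offspring tables")
    data = pd.DataFrame(rows)
    from scipy import stats

    for which in ("maternal", "fetal"):
        z = data[f"beta_{which}"] / data[f"se_{which}"]
        data[f"pval_{which}"] = np.clip(
            2 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0
        )
    return WlmEffects(data, pd.DataFrame(excluded, columns=["rsid", "reason"]))


def recompose(effects: WlmEffects) -> pd.DataFrame:
    """Invert the partition: reconstruct the own/offspring GWAS betas.

    The partition is a linear bijection, so this reproduces the harmonized
    input betas exactly: beta_own = beta_F + 0.5 beta_M and
    beta_offspring = beta_M + 0.5 beta_F.
    """
    d = effects.data
    return pd.DataFrame(
        {
            "rsid": d["rsid"],
            "beta_own": d["beta_fetal"] + 0.5 * d["beta_maternal"],
            "beta_offspring": d["beta_maternal"] + 0.5 * d["beta_fetal"],
        }
    )
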