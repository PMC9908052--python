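"""Reading, validation and harmonization of GWAS summary-statistic tables.

Two-sample Mendelian randomization combines per-SNP effect estimates from an
exposure GWAS with estimates from an outcome GWAS.  Before any estimator can
be applied the two tables must refer to the *same* effect allele at every
shared SNP; this module aligns them, flips signs where the alleles are
swapped, screens strand-ambiguous (palindromic) variants, and substitutes
linkage-disequilibrium proxies for variants missing from a table.

Tables are tab-separated text with the canonical header

    rsid  chrom  pos  effect_allele  other_allele  eaf  beta  se  pval  n

Positions are 1-based GRCh37 coordinates; tables are keyed on rsid.
Alternative headers (e.g. consortium-style ``A1``/``A2``) are mapped onto the
canonical names through a *dialect*: a ``{file column -> canonical column}``
mapping, optionally loaded from a YAML or JSON file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import FormatError, ParameterError

CANONICAL_COLUMNS = [
    "rsid",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]

#: Columns that must be resolvable in every input file.
MANDATORY_COLUMNS = ["rsid", "effect_allele", "other_allele", "beta", "se"]

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Default frequency cut-off above which a palindromic SNP's strand cannot be
#: inferred from allele frequency and the SNP is dropped.
DEFAULT_PALINDROME_EAF_LIMIT = 0.42


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class SummaryStatTable:
    """A validated per-SNP GWAS association table for one trait.

    Parameters
    ----------
    trait :
        Trait label, e.g. ``"urate"``.
    unit :
        Unit of the per-allele effect, e.g. ``"mg/dL urate"`` or
        ``"g birthweight"``.
    data :
        Records with the canonical columns, one row per SNP, unique rsids.
    rejected :
        Per-row validation report for rows that failed an invariant
        (columns ``rsid``/``row``/``reason``); empty for clean input.
    """

    trait: str
    unit: str
    data: pd.DataFrame
    rejected: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["row", "rsid", "reason"])
    )

    def __post_init__(self):
        missing = [c for c in MANDATORY_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"missing mandatory column(s): {', '.join(missing)}")
        for col in CANONICAL_COLUMNS:
            if col not in self.data.columns:
                self.data[col] = np.nan
        self.data = self.data[CANONICAL_COLUMNS].reset_index(drop=True)
        if self.data["rsid"].duplicated().any():
            dupes = self.data.loc[self.data["rsid"].duplicated(), "rsid"].tolist()
            raise FormatError(f"duplicate rsid(s): {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def rsids(self) -> list[str]:
        return self.data["rsid"].tolist()

    def get(self, rsid: str) -> pd.Series:
        row = self.data[self.data["rsid"] == rsid]
        if row.empty:
            raise KeyError(rsid)
        return row.iloc[0]

    def subset(self, rsids: Iterable[str]) -> "SummaryStatTable":
        keep = set(rsids)
        sub = self.data[self.data["rsid"].isin(keep)].reset_index(drop=True)
        return SummaryStatTable(self.trait, self.unit, sub)

    def write(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


@dataclass
class HarmonizedPairs:
    """Exposure/outcome effect pairs aligned to a common effect allele.

    ``pairs`` has columns ``rsid, beta_x, se_x, beta_y, se_y, eaf, flags``
    where ``flags`` is a semicolon-joined subset of
    ``{"flipped", "palindromic_dropped", "proxy_substituted"}`` (dropped SNPs
    appear in ``dropped``, not in ``pairs``).  ``dropped`` has columns
    ``rsid, reason``.
    """

    pairs: pd.DataFrame
    dropped: pd.DataFrame

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return self.pairs.itertuples(index=False)

    @property
    def rsids(self) -> list[str]:
        return self.pairs["rsid"].tolist()

    def subset(self, rsids: Iterable[str]) -> "HarmonizedPairs":
        keep = set(rsids)
        return HarmonizedPairs(
            self.pairs[self.pairs["rsid"].isin(keep)].reset_index(drop=True),
            self.dropped.copy(),
        )

    def with_exposure_per_sd(self, sd_exposure: float) -> "HarmonizedPairs":
        """Rescale exposure betas/SEs to per-1-SD-of-exposure units."""
        if sd_exposure <= 0:
            raise ParameterError("sd_exposure must be positive")
        p = self.pairs.copy()
        p["beta_x"] = p["beta_x"] / sd_exposure
        p["se_x"] = p["se_x"] / sd_exposure
        return HarmonizedPairs(p, self.dropped.copy())


# ---------------------------------------------------------------------------
# reading / validation
# ---------------------------------------------------------------------------


def load_dialect(path: str | Path) -> dict[str, str]:
    """Load a ``{file column -> canonical column}`` mapping from YAML/JSON."""
    with open(path) as fh:
        mapping = yaml.safe_load(fh)
    if not isinstance(mapping, Mapping):
        raise FormatError(f"dialect file {path} does not contain a mapping")
    return dict(mapping)


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split rows into (valid, rejected-with-reason), preserving row order."""
    reasons = pd.Series("", index=df.index, dtype=object)

    def _flag(mask, reason):
        nonlocal reasons
        mask = mask & (reasons == "")
        reasons[mask] = reason

    ea = df["effect_allele"].astype(str).str.upper()
    oa = df["other_allele"].astype(str).str.upper()
    _flag(~ea.isin(_VALID_ALLELES) | ~oa.isin(_VALID_ALLELES), "non-ACGT allele")
    _flag(ea == oa, "effect and other allele identical")
    se = pd.to_numeric(df["se"], errors="coerce")
    _flag(se.isna() | (se <= 0), "se must be > 0")
    beta = pd.to_numeric(df["beta"], errors="coerce")
    _flag(beta.isna(), "beta not numeric")
    if "eaf" in df:
        eaf = pd.to_numeric(df["eaf"], errors="coerce")
        _flag(eaf.notna() & ((eaf < 0) | (eaf > 1)), "eaf outside [0, 1]")
    if "pval" in df:
        pv = pd.to_numeric(df["pval"], errors="coerce")
        _flag(pv.notna() & ((pv <= 0) | (pv > 1)), "pval outside (0, 1]")
    _flag(df["rsid"].duplicated(), "duplicate rsid")

    bad = reasons != ""
    rejected = pd.DataFrame(
        {"row": df.index[bad], "rsid": df.loc[bad, "rsid"], "reason": reasons[bad]}
    ).reset_index(drop=True)
    valid = df[~bad].copy()
    valid["effect_allele"] = ea[~bad]
    valid["other_allele"] = oa[~bad]
    return valid, rejected


def read_summary_stats(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    trait: str = "",
    unit: str = "",
) -> SummaryStatTable:
    """Read and validate a GWAS summary-statistic TSV.

    Rows that violate a record invariant (non-ACGT allele, non-positive SE,
    frequency outside [0, 1], duplicate rsid, ...) are rejected individually
    and reported in the returned table's ``rejected`` attribute; row order of
    the surviving records is preserved.

    Raises
    ------
    FormatError
        If a mandatory column cannot be resolved (the message names it).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str})
    if dialect:
        df = df.rename(columns=dict(dialect))
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path.name}: missing mandatory column(s): {', '.join(missing)}"
        )
    valid, rejected = _validate_rows(df)
    table = SummaryStatTable(trait or path.stem, unit, valid)
    table.rejected = rejected
    return table


def write_summary_stats(table: SummaryStatTable, path: str | Path) -> None:
    table.write(path)


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT[ea] == oa


def harmonize(
    exposure: SummaryStatTable,
    outcome: SummaryStatTable,
    palindrome_eaf_limit: float = DEFAULT_PALINDROME_EAF_LIMIT,
) -> HarmonizedPairs:
    """Align outcome effects to the exposure's effect allele at shared SNPs.

    The rsid intersection is taken (in exposure row order).  Where the
    outcome's effect allele equals the exposure's other allele — directly or
    after strand complement — the outcome beta is sign-flipped and its
    frequency complemented, and the pair is flagged ``flipped``.  Palindromic
    (A/T or G/C) SNPs whose minor-allele frequency exceeds
    ``palindrome_eaf_limit`` are dropped (strand unresolvable from frequency);
    the screen uses the exposure frequency, falling back to the outcome's.
    Allele pairs irreconcilable after flip and strand complement are dropped
    with reason ``allele mismatch``.  Every exclusion is recorded in
    ``dropped``.
    """
    if not 0 < palindrome_eaf_limit <= 0.5:
        raise ParameterError("palindrome_eaf_limit must be in (0, 0.5]")

    out_by_rsid = outcome.data.set_index("rsid")
    rows, dropped = [], []
    for ex in exposure.data.itertuples(index=False):
        if ex.rsid not in out_by_rsid.index:
            continue
        oc = out_by_rsid.loc[ex.rsid]
        flags: list[str] = []
        ex_ea, ex_oa = ex.effect_allele, ex.other_allele
        oc_ea, oc_oa = oc["effect_allele"], oc["other_allele"]

        if _is_palindromic(ex_ea, ex_oa):
            eaf_ref = ex.eaf if np.isfinite(ex.eaf) else oc["eaf"]
            maf = min(eaf_ref, 1.0 - eaf_ref) if np.isfinite(eaf_ref) else np.nan
            if not np.isfinite(maf) or maf > palindrome_eaf_limit:
                dropped.append((ex.rsid, "palindromic_dropped"))
                continue
            # Retained palindrome: alleles compared letter-for-letter on the
            # assumption both tables report the same strand.

        beta_y, eaf_y = oc["beta"], oc["eaf"]
        if (oc_ea, oc_oa) == (ex_ea, ex_oa):
            pass
        elif (oc_ea, oc_oa) == (ex_oa, ex_ea):
            beta_y = -beta_y
            eaf_y = 1.0 - eaf_y if np.isfinite(eaf_y) else np.nan
            flags.append("flipped")
        else:
            c_ea, c_oa = _COMPLEMENT[oc_ea], _COMPLEMENT[oc_oa]
            if (c_ea, c_oa) == (ex_ea, ex_oa):
                pass
            elif (c_ea, c_oa) == (ex_oa, ex_ea):
                beta_y = -beta_y
                eaf_y = 1.0 - eaf_y if np.isfinite(eaf_y) else np.nan
                flags.append("flipped")
            else:
                dropped.append((ex.rsid, "allele mismatch"))
                continue

        eaf = ex.eaf if np.isfinite(ex.eaf) else eaf_y
        rows.append(
            {
                "rsid": ex.rsid,
                "beta_x": ex.beta,
                "se_x": ex.se,
                "beta_y": beta_y,
                "se_y": oc["se"],
                "eaf": eaf,
                "flags": ";".join(flags),
            }
        )

    pairs = pd.DataFrame(
        rows, columns=["rsid", "beta_x", "se_x", "beta_y", "se_y", "eaf", "flags"]
    )
    dropped_df = pd.DataFrame(dropped, columns=["rsid", "reason"])
    return HarmonizedPairs(pairs, dropped_df)


# ---------------------------------------------------------------------------
# proxy substitution
# ---------------------------------------------------------------------------


def substitute_proxies(
    table: SummaryStatTable,
    wanted: Sequence[str],
    proxies: pd.DataFrame,
    r2_min: float = 0.8,
) -> tuple[SummaryStatTable, pd.DataFrame]:
    """Replace wanted SNPs absent from ``table`` with their best LD proxy.

    ``proxies`` must have columns ``target``, ``proxy`` and ``r2`` (squared
    correlation between the two variants, as a web LD service would report
    within a window of the target).  For each wanted rsid missing from
    ``table`` the available proxy with the highest ``r2 >= r2_min`` whose own
    record *is* in ``table`` is substituted; ties at equal r2 are broken by
    lexicographic proxy rsid.  Targets with no qualifying proxy are excluded.

    Returns the reduced/substituted table (rows in ``wanted`` order) and a
    substitution report with columns ``target, proxy, r2, status, reason``.
    """
    if not 0 < r2_min <= 1:
        raise ParameterError(f"r2_min must be in (0, 1], got {r2_min}")
    for col in ("target", "proxy", "r2"):
        if col not in proxies.columns:
            raise FormatError(f"proxy table missing column: {col}")

    have = set(table.rsids)
    chosen_rows, report = [], []
    for rsid in wanted:
        if rsid in have:
            chosen_rows.append(rsid)
            report.append((rsid, rsid, 1.0, "present", ""))
            continue
        cand = proxies[
            (proxies["target"] == rsid)
            & (proxies["r2"] >= r2_min)
            & (proxies["proxy"].isin(have))
        ]
        if cand.empty:
            best = proxies[proxies["target"] == rsid]["r2"].max()
            reason = (
                f"best available proxy r2 {best:.3g} < {r2_min}"
                if np.isfinite(best)
                else "no proxy available"
            )
            report.append((rsid, "", np.nan, "excluded", reason))
            continue
        # argmax r2, deterministic lexicographic tie-break on proxy rsid
        cand = cand.sort_values(["r2", "proxy"], ascending=[False, True])
        pick = cand.iloc[0]
        chosen_rows.append(pick["proxy"])
        report.append((rsid, pick["proxy"], float(pick["r2"]), "proxied", ""))

    sub = (
        table.data.set_index("rsid")
        .loc[chosen_rows]
        .reset_index()[CANONICAL_COLUMNS]
    )
    report_df = pd.DataFrame(
        report, columns=["target", "proxy", "r2", "status", "reason"]
    )
    return SummaryStatTable(table.trait, table.unit, sub), report_df
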