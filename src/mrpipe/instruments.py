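"""Instrument selection, allele harmonization, and instrument strength.

Selection follows the usual two-sample MR recipe for microbiome exposures:

1. screen candidate SNPs at a locus-wide threshold (default p < 1e-5 —
   genome-wide 5e-8 would leave most genera with no instruments);
2. LD-clump greedily at r2 < 0.001 within a 10,000 kb window, keeping the
   lowest-p SNP of each clump;
3. drop rare variants (MAF <= 0.01);
4. pair each instrument with the outcome GWAS, resolving strand and
   effect-allele orientation; palindromic (A/T, C/G) SNPs are resolved by
   comparing effect-allele frequencies to 0.5, or dropped when either
   frequency is too close to 0.5 to call.

Instrument strength is summarized by R2 (variance in the exposure explained,
``sum 2 p (1-p) beta^2`` for a standardized trait) and by the F-statistic
``F = R2 (N - 1 - K) / ((1 - R2) K)``; F > 10 is the conventional bar for
"no weak-instrument bias".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .sumstats import LdTable, SumstatsTable

__all__ = [
    "InstrumentPair",
    "HarmonizedSet",
    "StrengthResult",
    "select_candidates",
    "clump",
    "harmonize",
    "instrument_strength",
    "mr_power",
]

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Columns of the harmonized pair table, mirroring a supplementary
#: "instrumental variables used in MR analysis" sheet.
PAIR_COLUMNS = (
    "snp", "chr", "pos", "ea", "oa",
    "eaf_exp", "beta_exp", "se_exp", "pval_exp", "n_exp",
    "eaf_out", "beta_out", "se_out", "pval_out", "n_out",
    "action",
)

KEPT_ACTIONS = ("kept", "flipped")


@dataclass(frozen=True)
class InstrumentPair:
    """One harmonized exposure/outcome instrument pair."""

    snp_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float = math.nan
    eaf_out: float = math.nan
    action: str = "kept"


@dataclass(frozen=True)
class HarmonizedSet:
    """Exposure/outcome instrument pairs on a common effect allele.

    ``pairs`` holds the analyzable rows (action kept/flipped); ``audit``
    additionally records every dropped SNP with the reason encoded in its
    ``action`` (dropped_palindromic / dropped_incompatible / dropped_missing).
    """

    exposure_name: str
    outcome_name: str
    pairs: pd.DataFrame
    audit: pd.DataFrame

    def __post_init__(self) -> None:
        if self.pairs["snp"].duplicated().any():
            raise ValidationError("duplicate snp_id in harmonized pairs")
        bad = ~self.pairs["action"].isin(KEPT_ACTIONS)
        if bad.any():
            raise ValidationError("pairs may only contain kept/flipped actions")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def is_empty(self) -> bool:
        return len(self.pairs) == 0

    def iter_pairs(self) -> Iterator[InstrumentPair]:
        for row in self.pairs.itertuples(index=False):
            yield InstrumentPair(
                snp_id=row.snp, beta_exp=row.beta_exp, se_exp=row.se_exp,
                beta_out=row.beta_out, se_out=row.se_out,
                eaf_exp=row.eaf_exp, eaf_out=row.eaf_out, action=row.action)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_exp, se_exp, beta_out, se_out) as float arrays."""
        p = self.pairs
        return (p["beta_exp"].to_numpy(float), p["se_exp"].to_numpy(float),
                p["beta_out"].to_numpy(float), p["se_out"].to_numpy(float))

    @classmethod
    def from_pairs(cls, pairs: list[InstrumentPair] | pd.DataFrame,
                   exposure_name: str = "exposure",
                   outcome_name: str = "outcome") -> "HarmonizedSet":
        """Build a set directly from pair records (e.g. a supplementary
        instrument table); chromosome/position default to placeholders."""
        if isinstance(pairs, pd.DataFrame):
            df = pairs.copy()
            for col in PAIR_COLUMNS:
                if col not in df.columns:
                    df[col] = "kept" if col == "action" else np.nan
            df = df.loc[:, list(PAIR_COLUMNS)]
        else:
            df = pd.DataFrame([{
                "snp": p.snp_id, "chr": "NA", "pos": 0, "ea": "A", "oa": "G",
                "eaf_exp": p.eaf_exp, "beta_exp": p.beta_exp,
                "se_exp": p.se_exp, "pval_exp": np.nan, "n_exp": np.nan,
                "eaf_out": p.eaf_out, "beta_out": p.beta_out,
                "se_out": p.se_out, "pval_out": np.nan, "n_out": np.nan,
                "action": p.action,
            } for p in pairs], columns=list(PAIR_COLUMNS))
        return cls(exposure_name=exposure_name, outcome_name=outcome_name,
                   pairs=df.reset_index(drop=True), audit=df.reset_index(drop=True))


@dataclass(frozen=True)
class StrengthResult:
    """Instrument-strength summary: variance explained and F-statistic."""

    r2_total: float
    f_stat: float
    n: int
    k: int


def select_candidates(table: SumstatsTable, p_thresh: float = 1e-5,
                      maf_min: float = 0.01) -> SumstatsTable:
    """Apply the significance and MAF screens.

    Keeps rows with ``pval < p_thresh`` and minor-allele frequency strictly
    above ``maf_min`` (MAF <= maf_min removed).  Rows with missing eaf pass
    the MAF screen (frequency unknown) and are logged.
    """
    if not (0.0 < p_thresh < 1.0 and 0.0 < maf_min < 0.5):
        raise ValidationError("thresholds out of range")
    df = table.records
    sig = df["pval"] < p_thresh
    maf = np.minimum(df["eaf"], 1.0 - df["eaf"])
    # tolerance so that eaf = 0.99 sits exactly on the MAF = 0.01 boundary
    # (1 - 0.99 overshoots by one ulp) and is removed, as the rule is "<="
    common = (maf - maf_min > 1e-12) | df["eaf"].isna()
    kept = df[sig & common]
    missing = kept["snp"][kept["eaf"].isna()]
    if len(missing):
        logger.warning("%s: %d candidate SNP(s) kept with unknown allele "
                       "frequency: %s", table.trait_name, len(missing),
                       ", ".join(missing.head(5)))
    return table.with_records(kept)


def clump(candidates: SumstatsTable, ld: LdTable, r2_thresh: float = 0.001,
          window_kb: int = 10_000) -> SumstatsTable:
    """Greedy LD clumping.

    SNPs are visited in order of ascending p-value (ties broken by
    lexicographic snp id).  Each visit takes the best remaining SNP as an
    index SNP and discards every remaining SNP on the same chromosome
    within ``window_kb`` kilobases whose r2 with the index is >=
    ``r2_thresh``.  Index SNPs are returned in genomic order.
    """
    df = candidates.records
    if df.empty:
        return candidates.with_records(df)
    order = df.sort_values(["pval", "snp"], kind="mergesort")
    window_bp = window_kb * 1000
    remaining = list(order.itertuples(index=False))
    kept_ids: list[str] = []
    while remaining:
        index_snp = remaining.pop(0)
        kept_ids.append(index_snp.snp)
        survivors = []
        for row in remaining:
            if (row.chr == index_snp.chr
                    and abs(row.pos - index_snp.pos) <= window_bp
                    and ld.r2(index_snp.snp, row.snp) >= r2_thresh):
                continue
            survivors.append(row)
        remaining = survivors
    out = df[df["snp"].isin(kept_ids)].sort_values(["chr", "pos"],
                                                   kind="mergesort")
    return candidates.with_records(out)


def _is_palindromic(ea: str, oa: str) -> bool:
    return {ea, oa} in ({"A", "T"}, {"C", "G"})


def harmonize(exposure_ivs: SumstatsTable, outcome: SumstatsTable,
              ambiguity_window: tuple[float, float] = (0.42, 0.58),
              ) -> HarmonizedSet:
    """Pair exposure instruments with the outcome GWAS on a common allele.

    For each instrument found in the outcome: identical allele pairs are
    kept; swapped pairs have the outcome beta negated and eaf reflected;
    opposite-strand pairs are complemented first.  Palindromic SNPs are
    resolved by allele frequency: dropped when either frequency falls in
    ``ambiguity_window`` (or is missing), kept when both frequencies sit on
    the same side of 0.5, flipped otherwise.  Instruments absent from the
    outcome are dropped (no proxy search).  Every decision is recorded in
    the audit table.
    """
    lo, hi = ambiguity_window
    out_idx = outcome.records.set_index("snp")
    rows = []
    for e in exposure_ivs.records.itertuples(index=False):
        rec = {
            "snp": e.snp, "chr": e.chr, "pos": e.pos, "ea": e.ea, "oa": e.oa,
            "eaf_exp": e.eaf, "beta_exp": e.beta, "se_exp": e.se,
            "pval_exp": e.pval, "n_exp": e.n,
            "eaf_out": np.nan, "beta_out": np.nan, "se_out": np.nan,
            "pval_out": np.nan, "n_out": np.nan,
        }
        if e.snp not in out_idx.index:
            rec["action"] = "dropped_missing"
            rows.append(rec)
            continue
        o = out_idx.loc[e.snp]
        o_ea, o_oa = o["ea"], o["oa"]
        rec.update(eaf_out=o["eaf"], beta_out=o["beta"], se_out=o["se"],
                   pval_out=o["pval"], n_out=o["n"])

        if _is_palindromic(e.ea, e.oa):
            if {o_ea, o_oa} != {e.ea, e.oa}:
                rec["action"] = "dropped_incompatible"
            elif (math.isnan(rec["eaf_exp"]) or math.isnan(rec["eaf_out"])
                    or lo <= rec["eaf_exp"] <= hi or lo <= rec["eaf_out"] <= hi):
                rec["action"] = "dropped_palindromic"
            elif (rec["eaf_exp"] - 0.5) * (rec["eaf_out"] - 0.5) >= 0:
                rec["action"] = "kept"
            else:
                rec["action"] = "flipped"
                rec["beta_out"] = -rec["beta_out"]
                rec["eaf_out"] = 1.0 - rec["eaf_out"]
        else:
            if {o_ea, o_oa} != {e.ea, e.oa}:
                o_ea = _COMPLEMENT.get(o_ea, "?")
                o_oa = _COMPLEMENT.get(o_oa, "?")
            if (o_ea, o_oa) == (e.ea, e.oa):
                rec["action"] = "kept"
            elif (o_ea, o_oa) == (e.oa, e.ea):
                rec["action"] = "flipped"
                rec["beta_out"] = -rec["beta_out"]
                if not math.isnan(rec["eaf_out"]):
                    rec["eaf_out"] = 1.0 - rec["eaf_out"]
            else:
                rec["action"] = "dropped_incompatible"
        rows.append(rec)

    audit = pd.DataFrame(rows, columns=list(PAIR_COLUMNS))
    pairs = audit[audit["action"].isin(KEPT_ACTIONS)].reset_index(drop=True)
    if pairs.empty:
        logger.warning("harmonization of %s vs %s left no analyzable pairs",
                       exposure_ivs.trait_name, outcome.trait_name)
    return HarmonizedSet(exposure_name=exposure_ivs.trait_name,
                         outcome_name=outcome.trait_name,
                         pairs=pairs, audit=audit)


def instrument_strength(hset: HarmonizedSet, n: int) -> StrengthResult:
    """Variance explained and F-statistic of the instrument set.

    Per-SNP variance explained is ``2 p (1-p) beta^2`` (standardized
    exposure); when the allele frequency is unknown the t-statistic
    approximation ``t^2 / (t^2 + N - 2)`` is used instead.
    """
    k = len(hset)
    if k < 1:
        raise ValidationError("instrument_strength requires >= 1 pair")
    if n <= k + 1:
        raise ValidationError("insufficient sample size: N must exceed K + 1")
    p = hset.pairs
    eaf = p["eaf_exp"].to_numpy(float)
    beta = p["beta_exp"].to_numpy(float)
    se = p["se_exp"].to_numpy(float)
    r2_snp = 2.0 * eaf * (1.0 - eaf) * beta ** 2
    t2 = (beta / se) ** 2
    fallback = t2 / (t2 + n - 2)
    r2_snp = np.where(np.isnan(eaf), fallback, r2_snp)
    r2 = float(np.sum(r2_snp))
    if r2 >= 1.0:
        raise ValidationError(f"total R2 >= 1 ({r2:.3f}); inputs implausible")
    f = r2 * (n - 1 - k) / ((1.0 - r2) * k)
    return StrengthResult(r2_total=r2, f_stat=f, n=int(n), k=k)


def mr_power(n_outcome: int, case_fraction: float, r2: float, theta: float,
             alpha: float = 0.05) -> float:
    """Approximate power of an MR test against a binary outcome.

    Uses the standard non-centrality approximation behind the common online
    two-sample MR power calculators: the IVW z-statistic is approximately
    ``theta * sqrt(n * r2 * v * (1 - v))`` where v is the case fraction and
    r2 the exposure variance explained by the instruments.
    """
    if r2 <= 0:
        raise ValidationError("r2 must be > 0")
    if not 0.0 < case_fraction < 1.0:
        raise ValidationError("case_fraction must be in (0, 1)")
    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    ncp = abs(theta) * math.sqrt(n_outcome * r2 * case_fraction
                                 * (1.0 - case_fraction))
    return float(stats.norm.cdf(ncp - z_crit))
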