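"""Panel orchestration: forward and reverse MR across many exposures.

``run_mr_panel`` takes a list of exposure summary-statistics tables (one
per bacterial genus, say), one outcome table, and an LD table, and runs
the full chain per exposure — candidate screening, LD clumping, allele
harmonization, the configured estimator ensemble, and heterogeneity /
pleiotropy / outlier diagnostics.  P-values are then FDR-corrected with
Storey q-values *within each method across exposures* (the report layout
has one q column per method), and every row is classified:

* ``significant`` — p < 0.05 and q < 0.1,
* ``suggestive``  — p < 0.05 but q >= 0.1,
* ``null``        — otherwise.

``run_bidirectional`` additionally re-runs the analysis in reverse
(outcome instruments against each forward hit) with identical settings,
to probe reverse causation.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .estimators import (MrResult, cochran_q, egger, ivw, leave_one_out,
                         max_likelihood, weighted_median, weighted_mode)
from .exceptions import MrPipeError, ValidationError
from .instruments import (HarmonizedSet, clump, harmonize,
                          instrument_strength, select_candidates)
from .qvalue import qvalues
from .robust import cml_ma_result, mr_presso
from .sumstats import LdTable, SumstatsTable

__all__ = [
    "PipelineConfig",
    "PanelReport",
    "classify_association",
    "run_mr_panel",
    "run_bidirectional",
    "render_report",
    "read_report",
]

logger = logging.getLogger(__name__)

ALL_METHODS = ("ivw", "ml", "egger", "wmedian", "wmode", "presso", "cml")

_MIN_SNPS_PER_METHOD = {"ivw": 1, "ml": 2, "egger": 3, "wmedian": 3,
                        "wmode": 3, "presso": 4, "cml": 3}

REPORT_COLUMNS = (
    "exposure", "outcome", "direction", "method", "n_snp", "f_stat",
    "beta", "se", "or", "ci_low", "ci_high", "pval", "qval",
    "classification", "het_q", "het_p", "egger_intercept_p",
    "presso_global_p", "seed",
)


@dataclass(frozen=True)
class PipelineConfig:
    """All thresholds and seeds of a panel run.

    Defaults are the conventional two-sample MR settings for microbiome
    exposure panels: locus-wide instrument screen p < 1e-5, clumping at
    r2 < 0.001 within 10,000 kb, MAF > 0.01, FDR call at q < 0.1.
    """

    p_thresh: float = 1e-5
    maf_min: float = 0.01
    clump_r2: float = 0.001
    clump_kb: int = 10_000
    ambiguity_window: tuple[float, float] = (0.42, 0.58)
    min_snps: int = 3
    methods: tuple[str, ...] = ALL_METHODS
    ivw_mode: str = "mre-floor"
    n_boot: int = 1000
    n_sim: int = 1000
    q_method: str = "smoother"
    q_thresh: float = 0.1
    p_suggestive: float = 0.05
    primary_method: str = "ivw"
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ValidationError(f"unknown method(s): {sorted(unknown)}")
        if self.primary_method not in self.methods:
            raise ValidationError(
                f"primary_method {self.primary_method!r} not in methods")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "ambiguity_window" in raw:
            raw["ambiguity_window"] = tuple(raw["ambiguity_window"])
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ambiguity_window"] = list(self.ambiguity_window)
        d["methods"] = list(self.methods)
        return d


@dataclass
class PanelReport:
    """The Table-1-shaped long report plus its supplementary-style sidecars."""

    table: pd.DataFrame
    heterogeneity: pd.DataFrame
    pleiotropy: pd.DataFrame
    presso: pd.DataFrame
    leave_one_out: pd.DataFrame
    scatter: pd.DataFrame
    skipped: pd.DataFrame
    metadata: dict = field(default_factory=dict)


def classify_association(pvalue: float, qvalue: float, q_thresh: float = 0.1,
                         p_thresh: float = 0.05) -> str:
    """Classify one association by its p- and q-value."""
    for v in (pvalue, qvalue):
        if not 0.0 <= v <= 1.0:
            raise ValidationError("p/q values must lie in [0, 1]")
    if pvalue < p_thresh and qvalue < q_thresh:
        return "significant"
    if pvalue < p_thresh:
        return "suggestive"
    return "null"


def _method_seeds(config_seed: int, analysis_index: int) -> dict[str, int]:
    """Deterministic per-analysis, per-method integer seeds (< 2**31)."""
    state = np.random.SeedSequence([config_seed, analysis_index]).generate_state(4)
    names = ("wmedian", "wmode", "presso", "cml")
    return {name: int(s & 0x7FFFFFFF) for name, s in zip(names, state)}


def _run_method(method: str, hset: HarmonizedSet, config: PipelineConfig,
                seeds: dict[str, int]):
    """Dispatch one estimator; returns (MrResult, presso_detail_or_None)."""
    if method == "ivw":
        return ivw(hset, mode=config.ivw_mode), None
    if method == "ml":
        return max_likelihood(hset), None
    if method == "egger":
        return egger(hset), None
    if method == "wmedian":
        return weighted_median(hset, n_boot=config.n_boot,
                               seed=seeds["wmedian"]), None
    if method == "wmode":
        return weighted_mode(hset, n_boot=config.n_boot,
                             seed=seeds["wmode"]), None
    if method == "cml":
        return cml_ma_result(hset, seed=seeds["cml"]), None
    if method == "presso":
        res = mr_presso(hset, n_sim=config.n_sim, seed=seeds["presso"])
        est = res.corrected_estimate or res.raw_estimate
        row = MrResult(method="presso", n_snp=est.n_snp, beta=est.beta,
                       se=est.se, pvalue=est.pvalue,
                       extras={"global_p": res.global_p,
                               "n_outliers": len(res.outlier_set)})
        return row, res
    raise ValidationError(f"unknown method {method!r}")


def _analyze_one(exposure: SumstatsTable, outcome: SumstatsTable,
                 ld: LdTable, config: PipelineConfig, direction: str,
                 analysis_index: int, acc: dict) -> None:
    """Run the full chain for one exposure/outcome pair, appending rows to
    the accumulator dict of lists."""
    name = exposure.trait_name
    seeds = _method_seeds(config.seed, analysis_index)
    cand = select_candidates(exposure, config.p_thresh, config.maf_min)
    clumped = clump(cand, ld, config.clump_r2, config.clump_kb)
    hset = harmonize(clumped, outcome, config.ambiguity_window)
    j = len(hset)
    if j == 0:
        acc["skipped"].append({"exposure": name, "direction": direction,
                               "reason": "no harmonized instruments"})
        return
    methods = config.methods
    if j < config.min_snps:
        acc["skipped"].append({
            "exposure": name, "direction": direction,
            "reason": f"only {j} instrument(s) (< {config.min_snps}); "
                      "IVW-only analysis"})
        methods = tuple(m for m in ("ivw",) if m in config.methods) or ("ivw",)

    n_exposure = int(hset.pairs["n_exp"].median())
    try:
        strength = instrument_strength(hset, n_exposure)
        f_stat = strength.f_stat
    except MrPipeError as exc:
        logger.warning("%s: F-statistic unavailable (%s)", name, exc)
        f_stat = np.nan

    het_q = het_p = np.nan
    if j >= 2:
        het = cochran_q(hset)
        het_q, het_p = het.q_stat, het.pvalue
        acc["heterogeneity"].append({
            "exposure": name, "outcome": outcome.trait_name,
            "direction": direction, "q_stat": het.q_stat, "df": het.df,
            "pval": het.pvalue})
    if j >= 3:
        for snp, res in leave_one_out(hset, mode=config.ivw_mode):
            acc["loo"].append({
                "exposure": name, "direction": direction, "omitted_snp": snp,
                "beta": res.beta, "se": res.se, "pval": res.pvalue})
    for row in hset.pairs.itertuples(index=False):
        acc["scatter"].append({
            "exposure": name, "direction": direction, "snp": row.snp,
            "beta_exp": row.beta_exp, "se_exp": row.se_exp,
            "beta_out": row.beta_out, "se_out": row.se_out})

    intercept_p = np.nan
    presso_global_p = np.nan
    results: list[MrResult] = []
    for method in methods:
        if j < _MIN_SNPS_PER_METHOD[method]:
            acc["skipped"].append({
                "exposure": name, "direction": direction,
                "reason": f"method {method} needs >= "
                          f"{_MIN_SNPS_PER_METHOD[method]} instruments, "
                          f"have {j}"})
            continue
        res, presso_detail = _run_method(method, hset, config, seeds)
        results.append(res)
        if method == "egger":
            intercept_p = res.extras["intercept_p"]
            acc["pleiotropy"].append({
                "exposure": name, "direction": direction,
                "egger_intercept": res.extras["egger_intercept"],
                "intercept_se": res.extras["intercept_se"],
                "intercept_p": res.extras["intercept_p"]})
        if presso_detail is not None:
            presso_global_p = presso_detail.global_p
            outlier_snps = hset.pairs["snp"].iloc[
                presso_detail.outlier_set].tolist()
            acc["presso"].append({
                "exposure": name, "direction": direction,
                "global_rss": presso_detail.global_rss,
                "global_p": presso_detail.global_p,
                "n_outliers": len(presso_detail.outlier_set),
                "outlier_snps": ",".join(outlier_snps) or "none",
                "distortion_p": presso_detail.distortion_p
                if presso_detail.distortion_p is not None else np.nan})

    for res in results:
        acc["rows"].append({
            "exposure": name, "outcome": outcome.trait_name,
            "direction": direction, "method": res.method, "n_snp": res.n_snp,
            "f_stat": f_stat, "beta": res.beta, "se": res.se, "or": res.or_,
            "ci_low": res.ci_low, "ci_high": res.ci_high,
            "pval": max(res.pvalue, 1e-300), "qval": np.nan,
            "classification": "", "het_q": het_q, "het_p": het_p,
            "egger_intercept_p": intercept_p,
            "presso_global_p": presso_global_p,
            "seed": seeds.get(res.method, config.seed)})


def _finalize(acc: dict, config: PipelineConfig) -> PanelReport:
    table = pd.DataFrame(acc["rows"], columns=list(REPORT_COLUMNS))
    if len(table):
        for (_, _), idx in table.groupby(["direction", "method"]).groups.items():
            sub = table.loc[idx]
            qres = qvalues(sub["pval"].to_numpy(), method=config.q_method)
            table.loc[idx, "qval"] = qres.qvalues
        table["classification"] = [
            classify_association(p, q, config.q_thresh, config.p_suggestive)
            for p, q in zip(table["pval"], table["qval"])]
    meta = {
        "mrpipe_version": __version__,
        "config": config.to_dict(),
        "fdr_family": "per method across exposures, within direction",
    }
    meta["config_hash"] = hashlib.sha256(
        yaml.safe_dump(meta["config"], sort_keys=True).encode()).hexdigest()
    return PanelReport(
        table=table,
        heterogeneity=pd.DataFrame(
            acc["heterogeneity"],
            columns=["exposure", "outcome", "direction", "q_stat", "df", "pval"]),
        pleiotropy=pd.DataFrame(
            acc["pleiotropy"],
            columns=["exposure", "direction", "egger_intercept",
                     "intercept_se", "intercept_p"]),
        presso=pd.DataFrame(
            acc["presso"],
            columns=["exposure", "direction", "global_rss", "global_p",
                     "n_outliers", "outlier_snps", "distortion_p"]),
        leave_one_out=pd.DataFrame(
            acc["loo"],
            columns=["exposure", "direction", "omitted_snp", "beta", "se",
                     "pval"]),
        scatter=pd.DataFrame(
            acc["scatter"],
            columns=["exposure", "direction", "snp", "beta_exp", "se_exp",
                     "beta_out", "se_out"]),
        skipped=pd.DataFrame(acc["skipped"],
                             columns=["exposure", "direction", "reason"]),
        metadata=meta)


def _new_acc() -> dict:
    return {k: [] for k in ("rows", "heterogeneity", "pleiotropy", "presso",
                            "loo", "scatter", "skipped")}


def run_mr_panel(exposures: Sequence[SumstatsTable], outcome: SumstatsTable,
                 ld: LdTable, config: PipelineConfig | None = None,
                 direction: str = "forward") -> PanelReport:
    """Run the estimator ensemble for every exposure against one outcome."""
    if len(exposures) == 0:
        raise ValidationError("empty exposure panel")
    config = config or PipelineConfig()
    acc = _new_acc()
    for i, exposure in enumerate(exposures):
        logger.info("analyzing %s (%d/%d)", exposure.trait_name, i + 1,
                    len(exposures))
        _analyze_one(exposure, outcome, ld, config, direction, i, acc)
    return _finalize(acc, config)


def run_bidirectional(exposures: Sequence[SumstatsTable],
                      outcome: SumstatsTable, ld_exposures: LdTable,
                      ld_outcome: LdTable,
                      config: PipelineConfig | None = None,
                      ) -> tuple[PanelReport, PanelReport]:
    """Forward panel, then reverse MR on the forward hits.

    A hit is an exposure whose primary-method row (default IVW) is
    classified better than ``null``.  The reverse analyses instrument the
    outcome GWAS with the same selection criteria and treat each hit taxon
    as the outcome; estimator settings are identical.
    """
    config = config or PipelineConfig()
    forward = run_mr_panel(exposures, outcome, ld_exposures, config,
                           direction="forward")
    t = forward.table
    hits = t[(t["method"] == config.primary_method)
             & (t["classification"] != "null")]["exposure"].tolist()
    by_name = {e.trait_name: e for e in exposures}
    acc = _new_acc()
    for i, hit in enumerate(hits):
        _analyze_one(outcome, by_name[hit], ld_outcome, config,
                     direction="reverse", analysis_index=100_000 + i, acc=acc)
    reverse = _finalize(acc, config)
    return forward, reverse


_FLOAT_FMT = "%.17g"


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT,
              na_rep="NA")


def render_report(report: PanelReport, out_dir: str | Path) -> dict[str, Path]:
    """Write a report as supplementary-table-style TSVs plus run metadata.

    Emits: main results, heterogeneity, Egger-intercept pleiotropy,
    MR-PRESSO, leave-one-out, per-SNP scatter data (for plotting), the
    skipped-exposure log and a ``run_metadata.yaml``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for stem, df in (("results", report.table),
                     ("heterogeneity", report.heterogeneity),
                     ("pleiotropy", report.pleiotropy),
                     ("presso", report.presso),
                     ("leave_one_out", report.leave_one_out),
                     ("scatter_data", report.scatter),
                     ("skipped", report.skipped)):
        path = out_dir / f"{stem}.tsv"
        _write_tsv(df, path)
        paths[stem] = path
    meta_path = out_dir / "run_metadata.yaml"
    with open(meta_path, "w") as fh:
        yaml.safe_dump(report.metadata, fh, sort_keys=True)
    paths["metadata"] = meta_path
    return paths


def read_report(out_dir: str | Path) -> PanelReport:
    """Re-read a rendered report directory into a :class:`PanelReport`."""
    out_dir = Path(out_dir)

    def _read(stem: str, str_cols: tuple[str, ...]) -> pd.DataFrame:
        df = pd.read_csv(out_dir / f"{stem}.tsv", sep="\t",
                         na_values=["NA"], keep_default_na=False,
                         float_precision="round_trip")
        for c in str_cols:
            if c in df.columns:
                df[c] = df[c].astype(str)
        return df

    with open(out_dir / "run_metadata.yaml") as fh:
        meta = yaml.safe_load(fh)
    return PanelReport(
        table=_read("results", ("exposure", "outcome", "direction", "method",
                                "classification")),
        heterogeneity=_read("heterogeneity", ("exposure", "outcome",
                                              "direction")),
        pleiotropy=_read("pleiotropy", ("exposure", "direction")),
        presso=_read("presso", ("exposure", "direction", "outlier_snps")),
        leave_one_out=_read("leave_one_out", ("exposure", "direction",
                                              "omitted_snp")),
        scatter=_read("scatter_data", ("exposure", "direction", "snp")),
        skipped=_read("skipped", ("exposure", "direction", "reason")),
        metadata=meta)
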