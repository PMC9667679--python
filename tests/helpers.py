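"""Shared builders and independent oracles for the test suite."""

import numpy as np
import pandas as pd

from mrpipe.instruments import PAIR_COLUMNS, HarmonizedSet


def make_hset(bx, sx, by, sy, eaf_exp=None, eaf_out=None,
              n_exp=13_266, n_out=166_401, snps=None,
              exposure_name="exposure", outcome_name="outcome"):
    """Build a HarmonizedSet directly from effect arrays."""
    bx = np.asarray(bx, dtype=float)
    j = len(bx)
    df = pd.DataFrame({
        "snp": snps if snps is not None else [f"rs{i:04d}" for i in range(j)],
        "chr": "1",
        "pos": np.arange(j) * 1_000_000 + 1,
        "ea": "A",
        "oa": "G",
        "eaf_exp": eaf_exp if eaf_exp is not None else np.full(j, np.nan),
        "beta_exp": bx,
        "se_exp": np.asarray(sx, dtype=float),
        "pval_exp": 1e-6,
        "n_exp": n_exp,
        "eaf_out": eaf_out if eaf_out is not None else np.full(j, np.nan),
        "beta_out": np.asarray(by, dtype=float),
        "se_out": np.asarray(sy, dtype=float),
        "pval_out": 0.5,
        "n_out": n_out,
        "action": "kept",
    }, columns=list(PAIR_COLUMNS))
    return HarmonizedSet(exposure_name=exposure_name,
                         outcome_name=outcome_name, pairs=df, audit=df)


def panel_hset(exposure, outcome):
    """Pair a simulated exposure/outcome table by SNP id, bypassing the
    selection stages (both tables share alleles by construction)."""
    rec = exposure.records
    out = outcome.records.set_index("snp").loc[rec["snp"]]
    return make_hset(rec["beta"], rec["se"], out["beta"], out["se"],
                     eaf_exp=rec["eaf"].to_numpy(),
                     eaf_out=out["eaf"].to_numpy(),
                     snps=list(rec["snp"]),
                     exposure_name=exposure.trait_name,
                     outcome_name=outcome.trait_name)


def ivw_oracle(bx, by, sy):
    """Independent fixed-effect IVW: precision-weighted mean of per-SNP
    ratio estimates, straight from the defining formulas."""
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    sy = np.asarray(sy, dtype=float)
    w = bx**2 / sy**2
    return float(np.sum(w * (by / bx)) / np.sum(w)), float(np.sum(w) ** -0.5)


def greedy_clump_oracle(df, ld, r2_thresh, window_bp):
    """Independent clumping semantics: scan SNPs in (p, id) order and keep
    each one unless a previously kept SNP on the same chromosome within the
    window is in LD with it at or above the threshold."""
    kept = []
    for row in df.sort_values(["pval", "snp"]).itertuples(index=False):
        conflict = any(
            k.chr == row.chr and abs(k.pos - row.pos) <= window_bp
            and ld.r2(k.snp, row.snp) >= r2_thresh
            for k in kept)
        if not conflict:
            kept.append(row)
    return sorted(r.snp for r in kept)
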