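"""Outlier- and pleiotropy-robust MR: MR-PRESSO and cML-MA.

MR-PRESSO compares the observed leave-one-out weighted residual sum of
squares to a parametric null simulated from the summary statistics: a
large global RSS signals horizontal pleiotropy, per-SNP residual tails
identify outlier instruments (Bonferroni across instruments), and the
distortion test asks whether removing those outliers moves the estimate
more than removing random subsets of the same size would.

cML-MA (constrained maximum likelihood with model averaging) fits, for
every possible count K of invalid instruments, the joint normal likelihood
with exactly K unconstrained direct effects, selected by coordinate
descent on the standardized outcome residuals.  Candidate models are then
BIC-weighted and averaged.  Unlike MR-Egger, it does not require the
InSIDE assumption, so it remains consistent under correlated pleiotropy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .estimators import MrResult, _ivw_core, _normal_p, ivw
from .exceptions import ConvergenceError, InsufficientInstrumentsError, ValidationError
from .instruments import HarmonizedSet

__all__ = [
    "PressoResult",
    "CmlResult",
    "mr_presso",
    "cml_fixed_k",
    "cml_ma_bic",
]


@dataclass(frozen=True)
class PressoResult:
    """MR-PRESSO global, outlier and distortion test results."""

    global_rss: float
    global_p: float
    per_snp_p: np.ndarray
    outlier_set: np.ndarray
    raw_estimate: MrResult
    corrected_estimate: MrResult | None
    distortion_p: float | None
    n_sim: int
    seed: int


@dataclass(frozen=True)
class CmlResult:
    """cML fits for each invalid-instrument count K plus the BIC-weighted
    model average."""

    per_k: list
    ma_theta: float
    ma_se: float
    ma_p: float
    weights: np.ndarray
    n_effective: int

    @property
    def best_k(self) -> int:
        bics = np.array([row["bic"] for row in self.per_k])
        return int(np.argmin(bics))


def _loo_ivw_theta(w: np.ndarray, ratios: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effect IVW estimates, vectorized over the
    trailing (instrument) axis; supports a leading simulation axis."""
    s0 = w.sum(axis=-1, keepdims=True)
    s1 = (w * ratios).sum(axis=-1, keepdims=True)
    return (s1 - w * ratios) / (s0 - w)


def mr_presso(hset: HarmonizedSet, n_sim: int = 1000, sig: float = 0.05,
              seed: int = 0) -> PressoResult:
    """MR-PRESSO global, outlier and distortion tests.

    The observed statistic is ``RSS = sum_j (Gamma_j - theta_(-j) gamma_j)^2
    / se_out_j^2`` with ``theta_(-j)`` the leave-one-out IVW estimate; its
    null distribution comes from ``n_sim`` parametric draws of both effect
    vectors.  p-values use the add-one rule (1 + exceedances)/(n_sim + 1),
    so they are never exactly zero.  Outliers are instruments whose per-SNP
    residual p falls below ``sig / J``.
    """
    if len(hset) < 4:
        raise InsufficientInstrumentsError(
            "insufficient instruments for MR-PRESSO (needs >= 4)")
    bx, sx, by, sy = hset.arrays()
    j = len(bx)
    w_ivw = bx ** 2 / sy ** 2
    ratios = by / bx
    theta_loo = _loo_ivw_theta(w_ivw, ratios)
    w_reg = 1.0 / sy ** 2
    rss_j_obs = w_reg * (by - theta_loo * bx) ** 2
    rss_obs = float(rss_j_obs.sum())

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    bx_sim = rng.normal(bx, sx, size=(n_sim, j))
    by_sim = rng.normal(theta_loo * bx, sy, size=(n_sim, j))
    w_sim = bx_sim ** 2 / sy ** 2
    ratios_sim = by_sim / bx_sim
    theta_loo_sim = _loo_ivw_theta(w_sim, ratios_sim)
    rss_j_sim = w_reg * (by_sim - theta_loo_sim * bx_sim) ** 2
    rss_sim = rss_j_sim.sum(axis=1)

    global_p = float((1 + (rss_sim >= rss_obs).sum()) / (n_sim + 1))
    per_snp_p = (1 + (rss_j_sim >= rss_j_obs).sum(axis=0)) / (n_sim + 1)
    outliers = np.nonzero(per_snp_p < sig / j)[0]

    raw = ivw(hset)
    corrected = None
    distortion_p = None
    if len(outliers) and len(outliers) < j - 1:
        keep = np.setdiff1d(np.arange(j), outliers)
        sub = hset.pairs.iloc[keep].reset_index(drop=True)
        corrected = ivw(HarmonizedSet(hset.exposure_name, hset.outcome_name,
                                      sub, sub))
        d_obs = raw.beta - corrected.beta
        # null distortion: remove random subsets of the outlier size
        d_null = np.empty(n_sim)
        for s in range(n_sim):
            drop = rng.choice(j, size=len(outliers), replace=False)
            mask = np.ones(j, dtype=bool)
            mask[drop] = False
            t, _, _ = _ivw_core(bx[mask], by[mask], sy[mask])
            d_null[s] = raw.beta - t
        distortion_p = float(
            (1 + (np.abs(d_null) >= abs(d_obs)).sum()) / (n_sim + 1))
    return PressoResult(global_rss=rss_obs, global_p=global_p,
                        per_snp_p=per_snp_p, outlier_set=outliers,
                        raw_estimate=raw, corrected_estimate=corrected,
                        distortion_p=distortion_p, n_sim=n_sim, seed=seed)


def _cml_descent(theta0: np.ndarray, k: int, bx, sx, by, sy,
                 tol: float, max_iter: int):
    """Coordinate descent for the K-invalid constrained likelihood,
    vectorized over starting values (leading axis)."""
    n_starts = len(theta0)
    j = len(bx)
    theta = theta0.copy()
    b = np.broadcast_to(bx, (n_starts, j)).copy()
    converged = np.zeros(n_starts, dtype=bool)
    invalid = np.zeros((n_starts, j), dtype=bool)
    sx2 = sx ** 2
    sy2 = sy ** 2
    for _ in range(max_iter):
        resid = (by - theta[:, None] * b) ** 2 / sy2
        invalid[:] = False
        if k > 0:
            top = np.argpartition(resid, j - k, axis=1)[:, j - k:]
            np.put_along_axis(invalid, top, True, axis=1)
        t = theta[:, None]
        b_valid = (bx / sx2 + t * by / sy2) / (1.0 / sx2 + t ** 2 / sy2)
        b = np.where(invalid, bx, b_valid)
        valid = ~invalid
        num = (np.where(valid, b * by / sy2, 0.0)).sum(axis=1)
        den = (np.where(valid, b ** 2 / sy2, 0.0)).sum(axis=1)
        theta_new = np.where(den > 0, num / np.where(den > 0, den, 1.0), theta)
        moved = np.abs(theta_new - theta)
        theta = theta_new
        newly = moved < tol
        converged |= newly
        if converged.all():
            break
    valid = ~invalid
    neg2ll = (np.where(valid,
                       ((bx - b) ** 2 / sx2 + (by - theta[:, None] * b) ** 2 / sy2),
                       0.0)).sum(axis=1)
    return theta, b, invalid, neg2ll, converged


def _cml_se(theta: float, b: np.ndarray, valid: np.ndarray,
            bx, sx, by, sy) -> float:
    """Profile-information SE of theta over the valid instruments."""
    sx2, sy2 = sx ** 2, sy ** 2
    bv, byv = b[valid], by[valid]
    i_tt = (bv ** 2 / sy2[valid]).sum()
    i_tb = (2.0 * theta * bv - byv) / sy2[valid]
    i_bb = 1.0 / sx2[valid] + theta ** 2 / sy2[valid]
    info = i_tt - (i_tb ** 2 / i_bb).sum()
    if info <= 0:
        raise ConvergenceError("non-positive cML information")
    return float(info ** -0.5)


def cml_fixed_k(hset: HarmonizedSet, k: int, n_starts: int = 10,
                tol: float = 1e-8, max_iter: int = 500,
                seed: int = 0) -> dict:
    """Constrained ML with exactly ``k`` invalid instruments.

    Minimizes the joint normal objective subject to exactly k nonzero
    direct effects, selected each iteration as the k largest standardized
    outcome residuals.  Multi-start around the IVW estimate guards against
    the non-convex subset selection; the best converged objective wins.

    Returns a dict with ``theta``, ``se``, ``neg2ll``, ``invalid_set``.
    """
    j = len(hset)
    if not 0 <= k <= j - 2:
        raise ValidationError(f"k must be in [0, J-2] = [0, {j - 2}], got {k}")
    bx, sx, by, sy = hset.arrays()
    theta0, se0, _ = _ivw_core(bx, by, sy)
    rng = np.random.default_rng(np.random.SeedSequence([seed, k]))
    starts = np.concatenate([
        [theta0], theta0 + rng.normal(0.0, 0.5 * abs(se0) + 1e-12,
                                      size=max(0, n_starts - 1))])
    theta, b, invalid, neg2ll, converged = _cml_descent(
        starts, k, bx, sx, by, sy, tol, max_iter)
    if not converged.any():
        raise ConvergenceError(
            f"cML(k={k}) failed to converge in {max_iter} iterations "
            f"from {n_starts} starts (last thetas: {theta[:3]})")
    neg2ll = np.where(converged, neg2ll, np.inf)
    best = int(np.argmin(neg2ll))
    th = float(theta[best])
    valid = ~invalid[best]
    se = _cml_se(th, b[best], valid, bx, sx, by, sy)
    return {"theta": th, "se": se, "neg2ll": float(neg2ll[best]),
            "invalid_set": np.nonzero(invalid[best])[0]}


def cml_ma_bic(hset: HarmonizedSet, n_effective: int | None = None,
               n_starts: int = 10, tol: float = 1e-8, max_iter: int = 500,
               seed: int = 0) -> CmlResult:
    """cML with BIC model averaging over the invalid-instrument count.

    For K = 0..J-2: ``BIC_K = neg2ll_K + K ln(n_effective)``; model weights
    are ``exp(-(BIC_K - min BIC)/2)`` normalized.  The averaged estimate is
    the weighted mean of the per-K estimates and the averaged variance adds
    the between-model spread to the within-model variances.

    ``n_effective`` defaults to the smaller of the exposure and outcome
    sample sizes carried by the harmonized pairs.
    """
    j = len(hset)
    if j < 3:
        raise InsufficientInstrumentsError("cML-MA requires >= 3 pairs")
    if n_effective is None:
        n_exp = hset.pairs["n_exp"].min()
        n_out = hset.pairs["n_out"].min()
        if np.isnan(n_exp) or np.isnan(n_out):
            raise ValidationError(
                "n_effective not given and pair table lacks sample sizes")
        n_effective = int(min(n_exp, n_out))
    if n_effective <= 0:
        raise ValidationError("n_effective must be positive")
    per_k = []
    for k in range(0, j - 1):
        fit = cml_fixed_k(hset, k, n_starts=n_starts, tol=tol,
                          max_iter=max_iter, seed=seed)
        fit["k"] = k
        fit["bic"] = fit["neg2ll"] + k * math.log(n_effective)
        per_k.append(fit)
    bics = np.array([f["bic"] for f in per_k])
    w = np.exp(-(bics - bics.min()) / 2.0)
    w /= w.sum()
    thetas = np.array([f["theta"] for f in per_k])
    ses = np.array([f["se"] for f in per_k])
    ma_theta = float((w * thetas).sum())
    ma_se = float(math.sqrt((w * (ses ** 2 + (thetas - ma_theta) ** 2)).sum()))
    return CmlResult(per_k=per_k, ma_theta=ma_theta, ma_se=ma_se,
                     ma_p=_normal_p(ma_theta, ma_se), weights=w,
                     n_effective=int(n_effective))


def cml_ma_result(hset: HarmonizedSet, **kwargs) -> MrResult:
    """cML-MA-BIC as an :class:`MrResult` row."""
    res = cml_ma_bic(hset, **kwargs)
    return MrResult(method="cml", n_snp=len(hset), beta=res.ma_theta,
                    se=res.ma_se, pvalue=res.ma_p,
                    extras={"best_k": res.best_k,
                            "n_effective": res.n_effective})
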