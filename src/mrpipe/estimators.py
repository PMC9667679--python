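"""Core two-sample MR estimators and diagnostics.

All estimators consume a :class:`~mrpipe.instruments.HarmonizedSet` of J
instrument pairs (gamma_hat_j, Gamma_hat_j) with standard errors, and
return an :class:`MrResult` on the log-odds scale together with the odds
ratio and its 95% CI.

Estimators
----------
* ``wald_ratio`` — single-SNP ratio estimate Gamma/gamma with first-order
  delta-method SE.
* ``ivw`` — inverse-variance-weighted meta-analysis of Wald ratios
  (equivalently a weighted zero-intercept regression of Gamma on gamma).
  Default inference is multiplicative random effects with a fixed-effect
  floor: the SE is inflated by sqrt(Q / (J - 1)) when Q exceeds its df.
* ``max_likelihood`` — joint normal likelihood in (theta, true instrument
  effects); unbiased when neither heterogeneity nor pleiotropy is present,
  with slightly smaller SEs than IVW.
* ``egger`` — weighted regression with a free intercept; the intercept
  estimates average directional pleiotropy (InSIDE assumption).  Inference
  uses t with J - 2 df, SEs floored at the fixed-effect level.
* ``weighted_median`` — consistent when at least half the weight comes
  from valid instruments; bootstrap SE.
* ``weighted_mode`` — mode of the kernel-smoothed ratio distribution;
  consistent when the largest homogeneous cluster of instruments is valid;
  bootstrap SE.

Diagnostics: Cochran's Q against the fixed-effect IVW estimate, and
leave-one-out IVW.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .exceptions import InsufficientInstrumentsError, ValidationError
from .instruments import HarmonizedSet, InstrumentPair

__all__ = [
    "MrResult",
    "HeterogeneityResult",
    "wald_ratio",
    "ivw",
    "max_likelihood",
    "egger",
    "weighted_median",
    "weighted_mode",
    "cochran_q",
    "leave_one_out",
]

_Z975 = 1.96


@dataclass(frozen=True)
class MrResult:
    """One estimator's causal estimate for one exposure-outcome pair."""

    method: str
    n_snp: int
    beta: float
    se: float
    pvalue: float
    extras: dict = field(default_factory=dict)

    @property
    def or_(self) -> float:
        return math.exp(self.beta)

    @property
    def ci_low(self) -> float:
        return math.exp(self.beta - _Z975 * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.beta + _Z975 * self.se)

    def to_dict(self) -> dict:
        d = {"method": self.method, "n_snp": self.n_snp, "beta": self.beta,
             "se": self.se, "or": self.or_, "ci_low": self.ci_low,
             "ci_high": self.ci_high, "pval": self.pvalue}
        d.update(self.extras)
        return d


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q heterogeneity statistic for an instrument set."""

    q_stat: float
    df: int
    pvalue: float


def _normal_p(beta: float, se: float) -> float:
    return float(2.0 * stats.norm.sf(abs(beta) / se)) if se > 0 else 0.0


def _arrays(hset: HarmonizedSet):
    bx, sx, by, sy = hset.arrays()
    if np.any(sx <= 0) or np.any(sy <= 0):
        raise ValidationError("standard errors must be positive")
    return bx, sx, by, sy


def wald_ratio(pair: InstrumentPair) -> MrResult:
    """Single-instrument ratio estimate with first-order delta-method SE."""
    if pair.beta_exp == 0:
        raise ValidationError("null instrument: beta_exp is zero")
    beta = pair.beta_out / pair.beta_exp
    se = pair.se_out / abs(pair.beta_exp)
    return MrResult(method="wald_ratio", n_snp=1, beta=beta, se=se,
                    pvalue=_normal_p(beta, se))


def _ivw_core(bx: np.ndarray, by: np.ndarray, sy: np.ndarray):
    """Fixed-effect IVW point estimate, SE, and Cochran's Q."""
    w = bx ** 2 / sy ** 2
    if not np.any(w > 0):
        raise ValidationError("all IVW weights are zero")
    ratios = np.divide(by, bx, out=np.zeros_like(by), where=bx != 0)
    sw = w.sum()
    theta = float((w * ratios).sum() / sw)
    se_fixed = float(sw ** -0.5)
    q = float((w * (ratios - theta) ** 2).sum())
    return theta, se_fixed, q


def ivw(hset: HarmonizedSet, mode: str = "mre-floor") -> MrResult:
    """Inverse-variance-weighted estimate.

    ``mode="fixed"`` reports the fixed-effect SE; ``"mre-floor"`` (default)
    multiplies it by ``max(1, sqrt(Q / (J - 1)))`` — multiplicative random
    effects that never fall below the fixed-effect SE.
    """
    if mode not in ("mre-floor", "fixed"):
        raise ValidationError(f"unknown IVW mode {mode!r}")
    if len(hset) == 1:
        r = wald_ratio(next(hset.iter_pairs()))
        return MrResult(method="ivw", n_snp=1, beta=r.beta, se=r.se,
                        pvalue=r.pvalue)
    if len(hset) < 1:
        raise InsufficientInstrumentsError("ivw requires >= 1 instrument")
    bx, sx, by, sy = _arrays(hset)
    theta, se_fixed, q = _ivw_core(bx, by, sy)
    j = len(bx)
    se = se_fixed
    if mode == "mre-floor":
        se = se_fixed * max(1.0, math.sqrt(q / (j - 1)))
    return MrResult(method="ivw", n_snp=j, beta=theta, se=se,
                    pvalue=_normal_p(theta, se),
                    extras={"q_stat": q, "ivw_mode": mode})


def _profile_g(theta, bx, sx, by, sy):
    """Inner maximizer of the joint likelihood: true instrument effects."""
    return (bx / sx ** 2 + theta * by / sy ** 2) / (1.0 / sx ** 2
                                                    + theta ** 2 / sy ** 2)


def _ml_neg2ll(theta, bx, sx, by, sy):
    g = _profile_g(theta, bx, sx, by, sy)
    return float((((bx - g) / sx) ** 2 + ((by - theta * g) / sy) ** 2).sum())


def _theta_information_se(theta, g, bx, sx, by, sy):
    """SE of theta from the observed information of the joint likelihood,
    profiling out the per-SNP true effects by block inversion."""
    i_tt = (g ** 2 / sy ** 2).sum()
    i_tg = (2.0 * theta * g - by) / sy ** 2
    i_gg = 1.0 / sx ** 2 + theta ** 2 / sy ** 2
    info = i_tt - (i_tg ** 2 / i_gg).sum()
    if info <= 0:
        raise ValidationError("non-positive information; cannot compute SE")
    return float(info ** -0.5)


def max_likelihood(hset: HarmonizedSet) -> MrResult:
    """Maximum-likelihood estimate under the no-pleiotropy model.

    Jointly models the observed exposure and outcome effects as normal
    around (g_j, theta * g_j); the per-SNP effects are profiled in closed
    form and theta optimized numerically from the IVW starting point.
    """
    if len(hset) == 1:
        r = wald_ratio(next(hset.iter_pairs()))
        return MrResult(method="ml", n_snp=1, beta=r.beta, se=r.se,
                        pvalue=r.pvalue)
    if len(hset) < 2:
        raise InsufficientInstrumentsError("max_likelihood requires >= 2 pairs")
    bx, sx, by, sy = _arrays(hset)
    theta0, se0, _ = _ivw_core(bx, by, sy)
    span = 10.0 * se0 + 1.0
    res = optimize.minimize_scalar(
        _ml_neg2ll, args=(bx, sx, by, sy),
        bounds=(theta0 - span, theta0 + span), method="bounded",
        options={"xatol": 1e-10})
    if not res.success:
        raise ValidationError(f"ML optimization failed: {res.message}")
    theta = float(res.x)
    g = _profile_g(theta, bx, sx, by, sy)
    se = _theta_information_se(theta, g, bx, sx, by, sy)
    return MrResult(method="ml", n_snp=len(bx), beta=theta, se=se,
                    pvalue=_normal_p(theta, se))


def egger(hset: HarmonizedSet) -> MrResult:
    """MR-Egger weighted regression with a free pleiotropy intercept.

    Pairs are oriented so every exposure effect is non-negative (the
    intercept is not orientation-invariant), then Gamma is regressed on
    gamma with weights 1/se_out^2.  SEs carry a multiplicative residual
    floor max(1, sigma); p-values use t with J - 2 df.
    """
    if len(hset) < 3:
        raise InsufficientInstrumentsError(
            "insufficient instruments: MR-Egger requires >= 3 pairs")
    bx, sx, by, sy = _arrays(hset)
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    x = bx * flip
    y = by * flip
    w = 1.0 / sy ** 2
    # weighted least squares with intercept, closed form
    xm = np.vstack([np.ones_like(x), x]).T
    xtwx = xm.T @ (w[:, None] * xm)
    xtwy = xm.T @ (w * y)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = y - xm @ coef
    j = len(x)
    sigma2 = float((w * resid ** 2).sum() / (j - 2))
    cov_unit = np.linalg.inv(xtwx)
    scale = max(1.0, math.sqrt(sigma2))
    se_alpha, se_theta = np.sqrt(np.diag(cov_unit)) * scale
    alpha, theta = coef
    p_theta = float(2.0 * stats.t.sf(abs(theta) / se_theta, df=j - 2))
    p_alpha = float(2.0 * stats.t.sf(abs(alpha) / se_alpha, df=j - 2))
    return MrResult(
        method="egger", n_snp=j, beta=float(theta), se=float(se_theta),
        pvalue=p_theta,
        extras={"egger_intercept": float(alpha),
                "intercept_se": float(se_alpha),
                "intercept_p": p_alpha,
                "residual_sigma": math.sqrt(sigma2)})


def _weighted_median_est(ratios: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Vectorized weighted median; trailing axis indexes instruments."""
    ratios = np.atleast_2d(ratios)
    weights = np.atleast_2d(weights)
    order = np.argsort(ratios, axis=1)
    r = np.take_along_axis(ratios, order, axis=1)
    w = np.take_along_axis(weights, order, axis=1)
    w = w / w.sum(axis=1, keepdims=True)
    s = np.cumsum(w, axis=1) - 0.5 * w
    # linear interpolation of r at s = 0.5 per row
    idx = (s < 0.5).sum(axis=1)
    j = ratios.shape[1]
    est = np.empty(ratios.shape[0])
    lowmask = idx == 0
    highmask = idx == j
    est[lowmask] = r[lowmask, 0]
    est[highmask] = r[highmask, -1]
    mid = ~(lowmask | highmask)
    i = idx[mid]
    rows = np.nonzero(mid)[0]
    s0 = s[rows, i - 1]
    s1 = s[rows, i]
    r0 = r[rows, i - 1]
    r1 = r[rows, i]
    frac = np.where(s1 > s0, (0.5 - s0) / np.where(s1 > s0, s1 - s0, 1.0), 0.0)
    est[mid] = r0 + frac * (r1 - r0)
    return est


def _bootstrap_draws(bx, sx, by, sy, n_boot, rng):
    bxs = rng.normal(bx, sx, size=(n_boot, len(bx)))
    bys = rng.normal(by, sy, size=(n_boot, len(by)))
    return bxs, bys


def weighted_median(hset: HarmonizedSet, n_boot: int = 1000,
                    seed: int = 0) -> MrResult:
    """Weighted median of Wald ratios with parametric-bootstrap SE.

    Consistent when instruments contributing at least 50% of the weight
    are valid.  The SE is the SD of the estimate over ``n_boot`` draws of
    (gamma_hat, Gamma_hat) from their sampling distributions.
    """
    if len(hset) < 3:
        raise InsufficientInstrumentsError("weighted_median requires >= 3 pairs")
    bx, sx, by, sy = _arrays(hset)
    ratios = by / bx
    weights = (bx / sy) ** 2
    est = float(_weighted_median_est(ratios, weights)[0])
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    bxs, bys = _bootstrap_draws(bx, sx, by, sy, n_boot, rng)
    boot = _weighted_median_est(bys / bxs, (bxs / sy) ** 2)
    se = float(boot.std(ddof=1))
    return MrResult(method="wmedian", n_snp=len(bx), beta=est, se=se,
                    pvalue=_normal_p(est, se),
                    extras={"n_boot": n_boot, "seed": seed})


def _mode_bandwidth(ratios: np.ndarray, phi: float) -> float:
    sd = ratios.std(ddof=1) if len(ratios) > 1 else 0.0
    mad = stats.median_abs_deviation(ratios, scale="normal")
    spread = min(sd, mad) if mad > 0 else sd
    return phi * 0.9 * spread * len(ratios) ** (-1 / 5)


def _weighted_mode_est(ratios: np.ndarray, weights: np.ndarray,
                       h: float, n_grid: int = 512) -> np.ndarray:
    """Vectorized argmax of the weighted normal-kernel ratio density."""
    ratios = np.atleast_2d(ratios)
    weights = np.atleast_2d(weights)
    lo = ratios.min(axis=1, keepdims=True) - 3.0 * h
    hi = ratios.max(axis=1, keepdims=True) + 3.0 * h
    grid = lo + (hi - lo) * np.linspace(0.0, 1.0, n_grid)[None, :]
    # density over (rows, grid): sum over instruments of w * K((x - r)/h)
    z = (grid[:, :, None] - ratios[:, None, :]) / h
    dens = (weights[:, None, :] * np.exp(-0.5 * z ** 2)).sum(axis=2)
    return np.take_along_axis(grid, dens.argmax(axis=1)[:, None], axis=1)[:, 0]


def weighted_mode(hset: HarmonizedSet, phi: float = 1.0, n_boot: int = 1000,
                  seed: int = 0) -> MrResult:
    """Mode-based estimate: the peak of the inverse-variance-weighted
    kernel density of Wald ratios, with parametric-bootstrap SE.

    Bandwidth is ``phi * 0.9 * min(sd, mad) * J**(-1/5)`` (mad on the
    normal-consistent scale); ``phi`` trades robustness against precision.
    """
    if len(hset) < 3:
        raise InsufficientInstrumentsError("weighted_mode requires >= 3 pairs")
    bx, sx, by, sy = _arrays(hset)
    ratios = by / bx
    weights = (bx / sy) ** 2
    h = _mode_bandwidth(ratios, phi)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if h == 0.0:  # all ratios identical: the mode is the common ratio
        est = float(ratios[0])
        bxs, bys = _bootstrap_draws(bx, sx, by, sy, n_boot, rng)
        rb = bys / bxs
        hb = np.array([_mode_bandwidth(r, phi) for r in rb])
        boot = np.array([
            _weighted_mode_est(r, w, max(hj, 1e-12))[0]
            for r, w, hj in zip(rb, (bxs / sy) ** 2, hb)])
        se = float(boot.std(ddof=1))
        return MrResult(method="wmode", n_snp=len(bx), beta=est, se=se,
                        pvalue=_normal_p(est, se),
                        extras={"n_boot": n_boot, "seed": seed, "phi": phi})
    est = float(_weighted_mode_est(ratios, weights, h)[0])
    bxs, bys = _bootstrap_draws(bx, sx, by, sy, n_boot, rng)
    rb = bys / bxs
    wb = (bxs / sy) ** 2
    # per-draw bandwidth, as the plug-in rule is data-dependent
    sd = rb.std(axis=1, ddof=1)
    mad = stats.median_abs_deviation(rb, axis=1, scale="normal")
    spread = np.where(mad > 0, np.minimum(sd, mad), sd)
    hb = phi * 0.9 * spread * rb.shape[1] ** (-1 / 5)
    hb = np.maximum(hb, 1e-12)
    boot = np.empty(n_boot)
    # group draws into chunks of equal bandwidth handling via loop on chunks
    chunk = 200
    for start in range(0, n_boot, chunk):
        sl = slice(start, min(start + chunk, n_boot))
        sub_r, sub_w, sub_h = rb[sl], wb[sl], hb[sl]
        lo = sub_r.min(axis=1, keepdims=True) - 3.0 * sub_h[:, None]
        hi = sub_r.max(axis=1, keepdims=True) + 3.0 * sub_h[:, None]
        grid = lo + (hi - lo) * np.linspace(0.0, 1.0, 512)[None, :]
        z = (grid[:, :, None] - sub_r[:, None, :]) / sub_h[:, None, None]
        dens = (sub_w[:, None, :] * np.exp(-0.5 * z ** 2)).sum(axis=2)
        boot[sl] = np.take_along_axis(
            grid, dens.argmax(axis=1)[:, None], axis=1)[:, 0]
    se = float(boot.std(ddof=1))
    return MrResult(method="wmode", n_snp=len(bx), beta=est, se=se,
                    pvalue=_normal_p(est, se),
                    extras={"n_boot": n_boot, "seed": seed, "phi": phi})


def cochran_q(hset: HarmonizedSet) -> HeterogeneityResult:
    """Cochran's Q of the Wald ratios around the fixed-effect IVW estimate."""
    if len(hset) < 2:
        raise InsufficientInstrumentsError("cochran_q requires >= 2 pairs")
    bx, sx, by, sy = _arrays(hset)
    _, _, q = _ivw_core(bx, by, sy)
    df = len(bx) - 1
    return HeterogeneityResult(q_stat=q, df=df,
                               pvalue=float(stats.chi2.sf(q, df)))


def leave_one_out(hset: HarmonizedSet,
                  mode: str = "mre-floor") -> list[tuple[str, MrResult]]:
    """IVW re-estimated with each instrument omitted in turn."""
    if len(hset) < 3:
        raise InsufficientInstrumentsError("leave_one_out requires >= 3 pairs")
    results = []
    for snp in hset.pairs["snp"]:
        sub = hset.pairs[hset.pairs["snp"] != snp].reset_index(drop=True)
        sub_set = HarmonizedSet(exposure_name=hset.exposure_name,
                                outcome_name=hset.outcome_name,
                                pairs=sub, audit=sub)
        results.append((snp, ivw(sub_set, mode=mode)))
    return results
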