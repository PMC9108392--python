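"""Causal-effect estimators for two-sample Mendelian randomization.

Four ratio-based estimators operate on a :class:`~causalmr.instruments.HarmonizedSet`:

- **IVW**: inverse-variance-weighted combination of per-SNP Wald ratios,
  algebraically a weighted regression of the outcome effects on the
  exposure effects through the origin.  The default error model inflates
  the fixed-effect SE by ``max(1, sqrt(Q/(k-1)))`` (multiplicative random
  effects, floored at the fixed-effect value).
- **MR-Egger**: weighted regression *with* an intercept on data oriented so
  every exposure effect is non-negative; the intercept estimates average
  directional pleiotropy and its deviation from zero is a pleiotropy test.
- **Weighted median**: the 50th weighted percentile of the ordered Wald
  ratios; consistent when valid instruments carry a majority of weight.
- **Weighted mode**: the maximum of a weighted Gaussian kernel density of
  the Wald ratios (NOME weights), consistent when the largest group of
  instruments sharing one ratio is valid.

Median and mode standard errors come from a seeded parametric bootstrap.
Binary outcomes are reported on the odds-ratio scale as well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .exceptions import (
    ConfigurationError,
    DegenerateInstrumentError,
    EmptyInstrumentError,
    InsufficientInstrumentsError,
)
from .instruments import HarmonizedSet

log = logging.getLogger("causalmr")

Z95 = 1.959963984540054  # normal 97.5% quantile

MODE_GRID_POINTS = 10_001
MODE_BOOT_GRID_POINTS = 1_001  # coarser grid is ample for a bootstrap SD
MAD_NORMAL_CONSISTENCY = 1.4826022185056018  # 1/Phi^-1(3/4)


@dataclass
class MREstimate:
    """One method's causal estimate with confidence interval and p-value."""

    method: str  # wald | ivw | egger | wme | mbe
    nsnp: int
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    or_scale: Optional[tuple[float, float, float]] = None
    intercept: Optional[float] = None
    intercept_se: Optional[float] = None
    intercept_pval: Optional[float] = None
    note: Optional[str] = None
    error: Optional[str] = None  # set on per-method failure records
    metadata: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.error is None

    def with_or_scale(self) -> "MREstimate":
        self.or_scale = (
            float(np.exp(self.beta)),
            float(np.exp(self.ci_low)),
            float(np.exp(self.ci_high)),
        )
        return self


def _two_sided_normal_p(z: float) -> float:
    return float(max(2.0 * stats.norm.sf(abs(z)), np.finfo(float).tiny))


def wald_ratios(h: HarmonizedSet):
    """Per-SNP causal estimates ``by/bx`` with first-order SEs ``sey/|bx|``."""
    if np.any(h.bx == 0):
        bad = [s for s, b in zip(h.snp_ids, h.bx) if b == 0]
        raise DegenerateInstrumentError(f"zero exposure effect for {bad}")
    theta = h.by / h.bx
    theta_se = h.sey / np.abs(h.bx)
    return theta, theta_se


def _ivw_core(bx, by, sey):
    w = sey ** -2.0
    denom = float(np.sum(bx ** 2 * w))
    beta = float(np.sum(bx * by * w)) / denom
    se_fixed = denom ** -0.5
    return beta, se_fixed


def cochran_q_statistic(bx, by, sey, beta):
    """Cochran's Q of the Wald ratios about ``beta`` with weights (bx/sey)^2."""
    theta = by / bx
    w = (bx / sey) ** 2
    return float(np.sum(w * (theta - beta) ** 2))


def ivw(h: HarmonizedSet, re_model: str = "multiplicative_floored") -> MREstimate:
    """Inverse-variance-weighted estimate (weighted regression through the
    origin).  With one SNP this degrades to the Wald ratio with a note."""
    if re_model not in ("fixed", "multiplicative_floored"):
        raise ConfigurationError(f"unknown error model {re_model!r}")
    k = h.nsnp
    if k == 0:
        raise EmptyInstrumentError("cannot run IVW on an empty set")
    if np.any(h.bx == 0):
        raise DegenerateInstrumentError("IVW requires nonzero exposure effects")

    beta, se_fixed = _ivw_core(h.bx, h.by, h.sey)
    note = None
    if k == 1:
        se = se_fixed
        note = "single instrument: IVW degrades to the Wald ratio"
        log.info("%s on %s: %s", h.exposure_name, h.outcome_name, note)
        method = "wald"
        q = 0.0
    else:
        q = cochran_q_statistic(h.bx, h.by, h.sey, beta)
        scale = max(1.0, np.sqrt(q / (k - 1))) if re_model == "multiplicative_floored" else 1.0
        se = se_fixed * scale
        method = "ivw"

    z = beta / se
    est = MREstimate(
        method=method, nsnp=k, beta=beta, se=se,
        ci_low=beta - Z95 * se, ci_high=beta + Z95 * se,
        pval=_two_sided_normal_p(z), note=note,
        metadata={"q": q, "re_model": re_model, "se_fixed": se_fixed},
    )
    if h.outcome_type == "binary":
        est.with_or_scale()
    return est


def _orient_positive(bx, by, sex=None):
    """Jointly negate (bx, by) where bx < 0 so all exposure effects are
    non-negative; the Egger fit is invariant to this per-SNP sign choice."""
    sign = np.where(bx < 0, -1.0, 1.0)
    out = (bx * sign, by * sign)
    if sex is not None:
        out = out + (sex,)
    return out


def egger(h: HarmonizedSet) -> MREstimate:
    """MR-Egger weighted regression with intercept on bx>=0-oriented data.

    The slope is the causal estimate; the intercept estimates average
    directional pleiotropy, tested against zero with t(k-2).  Slope and
    intercept SEs carry the floored residual-scale inflation.
    """
    k = h.nsnp
    if k < 3:
        raise InsufficientInstrumentsError(f"MR-Egger needs >= 3 SNPs, got {k}")
    bxo, byo = _orient_positive(h.bx, h.by)
    X = sm.add_constant(bxo)
    fit = sm.WLS(byo, X, weights=h.sey ** -2.0).fit()
    intercept, slope = fit.params
    # floor the residual scale at 1 so SEs never undercut the fixed model
    sigma = float(np.sqrt(fit.mse_resid))
    se_unit = np.sqrt(np.diag(fit.normalized_cov_params))
    se_int, se_slope = max(1.0, sigma) * se_unit
    tq = stats.t.ppf(0.975, k - 2)
    p_slope = float(2.0 * stats.t.sf(abs(slope / se_slope), k - 2))
    p_int = float(2.0 * stats.t.sf(abs(intercept / se_int), k - 2))
    est = MREstimate(
        method="egger", nsnp=k,
        beta=float(slope), se=float(se_slope),
        ci_low=float(slope - tq * se_slope), ci_high=float(slope + tq * se_slope),
        pval=max(p_slope, np.finfo(float).tiny),
        intercept=float(intercept), intercept_se=float(se_int),
        intercept_pval=max(p_int, np.finfo(float).tiny),
        metadata={"sigma": float(sigma)},
    )
    if h.outcome_type == "binary":
        est.with_or_scale()
    return est


def _weighted_median_point(theta, weights):
    order = np.argsort(theta, kind="stable")
    t = theta[order]
    w = weights[order] / np.sum(weights)
    cum = np.cumsum(w)
    s = cum - w / 2.0  # midpoint percentile of each ordered ratio
    if 0.5 <= s[0]:
        return float(t[0])
    if 0.5 >= s[-1]:
        return float(t[-1])
    return float(np.interp(0.5, s, t))


def _parametric_bootstrap(h: HarmonizedSet, n_boot: int, seed: int):
    rng = np.random.default_rng(seed)
    bx = rng.normal(h.bx, h.sex, size=(n_boot, h.nsnp))
    by = rng.normal(h.by, h.sey, size=(n_boot, h.nsnp))
    return bx, by


def weighted_median(h: HarmonizedSet, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted-median estimator with parametric-bootstrap standard error.

    Weights are ``bx^2/sey^2`` (inverse first-order Wald-ratio variance),
    normalized; the estimate interpolates the ordered ratios at the 50%
    cumulative-weight midpoint.
    """
    k = h.nsnp
    if k < 3:
        raise InsufficientInstrumentsError(f"weighted median needs >= 3 SNPs, got {k}")
    if n_boot < 100:
        log.warning("weighted_median: n_boot=%d < 100 gives an unstable SE", n_boot)
    theta, _ = wald_ratios(h)
    weights = (h.bx / h.sey) ** 2
    beta = _weighted_median_point(theta, weights)

    bxb, byb = _parametric_bootstrap(h, n_boot, seed)
    bxb = np.where(bxb == 0, np.finfo(float).tiny, bxb)
    boot = np.empty(n_boot)
    for i in range(n_boot):
        boot[i] = _weighted_median_point(byb[i] / bxb[i], (bxb[i] / h.sey) ** 2)
    se = float(np.std(boot, ddof=1))
    se_eff = se if se > 0 else np.finfo(float).tiny
    est = MREstimate(
        method="wme", nsnp=k, beta=beta, se=se,
        ci_low=beta - Z95 * se, ci_high=beta + Z95 * se,
        pval=_two_sided_normal_p(beta / se_eff),
        metadata={"n_boot": n_boot, "seed": seed},
    )
    if h.outcome_type == "binary":
        est.with_or_scale()
    return est


def _mode_bandwidth(theta, phi):
    sd = np.std(theta, ddof=1)
    mad = MAD_NORMAL_CONSISTENCY * np.median(np.abs(theta - np.median(theta)))
    spread = min(sd, mad) if mad > 0 else sd
    return phi * 0.9 * spread * len(theta) ** (-0.2)


def _mode_point(theta, weights, h_band, n_grid=MODE_GRID_POINTS):
    if h_band <= 0 or np.allclose(theta, theta[0]):
        return float(theta[0])
    grid = np.linspace(theta.min() - 3 * h_band, theta.max() + 3 * h_band, n_grid)
    z = (grid[:, None] - theta[None, :]) / h_band
    density = np.exp(-0.5 * z ** 2) @ weights
    return float(grid[np.argmax(density)])


def weighted_mode(h: HarmonizedSet, phi: float = 1.0, n_boot: int = 1000,
                  seed: int = 0) -> MREstimate:
    """Weighted-mode (NOME-assumption) estimator.

    The Wald-ratio density is smoothed with a Gaussian kernel of bandwidth
    ``phi * 0.9 * min(sd, mad) * k^(-1/5)`` (MAD scaled for normal
    consistency) and maximized over a dense grid; weights are normalized
    ``bx^2/sey^2``.  SE via the same parametric bootstrap as the weighted
    median.  If all ratios coincide the common ratio is returned.
    """
    k = h.nsnp
    if k < 3:
        raise InsufficientInstrumentsError(f"weighted mode needs >= 3 SNPs, got {k}")
    if phi <= 0:
        raise ConfigurationError("phi must be positive")
    theta, _ = wald_ratios(h)
    weights = (h.bx / h.sey) ** 2
    weights = weights / weights.sum()
    beta = _mode_point(theta, weights, _mode_bandwidth(theta, phi))

    bxb, byb = _parametric_bootstrap(h, n_boot, seed)
    bxb = np.where(bxb == 0, np.finfo(float).tiny, bxb)
    boot = np.empty(n_boot)
    for i in range(n_boot):
        tb = byb[i] / bxb[i]
        wb = (bxb[i] / h.sey) ** 2
        boot[i] = _mode_point(tb, wb / wb.sum(), _mode_bandwidth(tb, phi),
                              n_grid=MODE_BOOT_GRID_POINTS)
    se = float(np.std(boot, ddof=1))
    se_eff = se if se > 0 else np.finfo(float).tiny
    est = MREstimate(
        method="mbe", nsnp=k, beta=beta, se=se,
        ci_low=beta - Z95 * se, ci_high=beta + Z95 * se,
        pval=_two_sided_normal_p(beta / se_eff),
        metadata={"phi": phi, "n_boot": n_boot, "seed": seed},
    )
    if h.outcome_type == "binary":
        est.with_or_scale()
    return est


def estimate_all(
    h: HarmonizedSet,
    re_model: str = "multiplicative_floored",
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> list[MREstimate]:
    """Run every estimator whose precondition the set satisfies.

    Member failures become per-method records with ``error`` set rather
    than aborting the run.  Deterministic given ``seed``.
    """
    if h.nsnp < 1:
        raise EmptyInstrumentError("empty harmonized set")
    out: list[MREstimate] = []
    methods = (
        ("ivw", lambda: ivw(h, re_model=re_model)),
        ("egger", lambda: egger(h)),
        ("wme", lambda: weighted_median(h, n_boot=n_boot, seed=seed)),
        ("mbe", lambda: weighted_mode(h, phi=phi, n_boot=n_boot, seed=seed + 1)),
    )
    for name, fn in methods:
        try:
            out.append(fn())
        except (InsufficientInstrumentsError, DegenerateInstrumentError,
                EmptyInstrumentError) as exc:
            out.append(MREstimate(
                method=name, nsnp=h.nsnp,
                beta=float("nan"), se=float("nan"),
                ci_low=float("nan"), ci_high=float("nan"), pval=float("nan"),
                error=str(exc),
            ))
    return out
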