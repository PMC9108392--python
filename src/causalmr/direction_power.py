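"""Directionality testing, statistical power, and multiple-testing bookkeeping.

The Steiger test asks whether the instruments explain more variance in the
exposure than in the outcome — the pattern expected when causation runs
exposure -> outcome — by comparing Fisher-z-transformed pooled correlations
across the two (independent) GWAS samples.

Binary-outcome power uses the standard normal approximation with
noncentrality ``NCP = n * R2 * K * (1-K) * (ln OR)^2`` where ``n`` is the
outcome sample size, ``K`` the case fraction and ``R2`` the pooled variance
in the exposure explained by the instruments.  ``detectable_effect``
inverts this for the smallest odds ratio detectable at a target power.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .exceptions import ConfigurationError, InsufficientInstrumentsError
from .instruments import HarmonizedSet


@dataclass
class SteigerResult:
    r2_exposure: float
    r2_outcome: float
    n_exposure: float
    n_outcome: float
    direction_ok: bool  # True when the instruments explain more of the exposure
    zval: float
    pval: float
    outcome_r2_method: str = "eaf"  # "eaf" | "f_approx"


@dataclass
class PowerSpec:
    """Inputs of the binary-outcome power approximation."""

    n: float  # outcome sample size
    case_fraction: float
    r2: float  # pooled instrument variance explained in the exposure
    alpha: float = 1.42857142857e-3
    power_target: float = 0.80

    def __post_init__(self) -> None:
        if not (self.n > 0):
            raise ConfigurationError("n must be positive")
        for name in ("case_fraction", "alpha", "power_target"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ConfigurationError(f"{name} must be in (0,1), got {v}")
        if not (0 < self.r2 < 1):
            raise ConfigurationError(f"r2 must be in (0,1), got {self.r2}")


def steiger_test(
    h: HarmonizedSet,
    n_x: float,
    n_y: float,
    eaf_y: np.ndarray | None = None,
) -> SteigerResult:
    """Directionality test comparing instrument variance explained.

    Pooled R2 in the exposure uses ``2*bx^2*eaf*(1-eaf)`` (exposure EAF
    mandatory).  Pooled R2 in the outcome uses the same formula on the
    outcome associations when outcome EAFs are available, otherwise the
    per-SNP F approximation ``r2 = F / (F + n_y - 2)``.  The z statistic
    compares Fisher-transformed correlations with variances 1/(n-3).
    """
    if n_x <= 3 or n_y <= 3:
        raise ConfigurationError("sample sizes must exceed 3")
    eaf_x = h.eaf_x
    if np.any(np.isnan(eaf_x)):
        raise ConfigurationError("Steiger test requires exposure EAF for every SNP")
    r2_x = float(np.sum(2.0 * h.bx ** 2 * eaf_x * (1.0 - eaf_x)))

    if eaf_y is None and h.eaf_y is not None and not np.any(np.isnan(h.eaf_y)):
        eaf_y = h.eaf_y
    if eaf_y is not None:
        eaf_y = np.asarray(eaf_y, dtype=float)
        if np.any(np.isnan(eaf_y)) or np.any((eaf_y <= 0) | (eaf_y >= 1)):
            raise ConfigurationError("outcome EAF must lie in (0,1)")
        r2_y = float(np.sum(2.0 * h.by ** 2 * eaf_y * (1.0 - eaf_y)))
        method = "eaf"
    else:
        f_y = (h.by / h.sey) ** 2
        r2_y = float(np.sum(f_y / (f_y + n_y - 2.0)))
        method = "f_approx"

    r2_x = min(r2_x, 1.0 - 1e-12)
    r2_y = min(r2_y, 1.0 - 1e-12)
    z = (math.atanh(math.sqrt(r2_x)) - math.atanh(math.sqrt(r2_y))) / math.sqrt(
        1.0 / (n_x - 3.0) + 1.0 / (n_y - 3.0)
    )
    pval = float(max(2.0 * stats.norm.sf(abs(z)), np.finfo(float).tiny))
    return SteigerResult(
        r2_exposure=r2_x, r2_outcome=r2_y,
        n_exposure=n_x, n_outcome=n_y,
        direction_ok=r2_x > r2_y,
        zval=float(z), pval=pval,
        outcome_r2_method=method,
    )


def power_binary(spec: PowerSpec, odds_ratio: float) -> float:
    """Power to detect ``odds_ratio`` in a binary-outcome MR at ``spec.alpha``."""
    if odds_ratio <= 0:
        raise ConfigurationError("odds_ratio must be positive")
    beta = math.log(odds_ratio)
    ncp_root = math.sqrt(spec.n * spec.r2 * spec.case_fraction * (1.0 - spec.case_fraction)) * abs(beta)
    z_crit = stats.norm.isf(spec.alpha / 2.0)
    return float(stats.norm.cdf(ncp_root - z_crit))


def detectable_effect(spec: PowerSpec, side: str = "risky") -> float:
    """Smallest odds ratio detectable at ``spec.power_target``.

    ``side="risky"`` returns OR > 1, ``side="protective"`` its reciprocal
    (the power depends on |ln OR| only).  Solved by root bracketing to 1e-6.
    """
    if side not in ("risky", "protective"):
        raise ConfigurationError(f"side must be 'risky' or 'protective', got {side!r}")
    if not (spec.alpha < spec.power_target < 1):
        raise ConfigurationError("power_target must lie in (alpha, 1)")

    def gap(log_or: float) -> float:
        return power_binary(spec, math.exp(log_or)) - spec.power_target

    hi = 1e-6
    while gap(hi) < 0:
        hi *= 2.0
        if hi > 1e3:
            raise ConfigurationError("detectable effect search failed to bracket")
    log_or = optimize.brentq(gap, 0.0, hi, xtol=1e-10, rtol=8.9e-16)
    if side == "protective":
        log_or = -log_or
    return float(math.exp(log_or))


def power_grid(specs_by_outcome: dict[str, PowerSpec], r2_values) -> "pd.DataFrame":
    """Detectable risky/protective ORs per outcome across a grid of pooled R2."""
    import pandas as pd

    from dataclasses import replace
    rows = []
    for outcome, spec in specs_by_outcome.items():
        for r2 in r2_values:
            s = replace(spec, r2=float(r2))
            rows.append({
                "outcome": outcome,
                "r2": float(r2),
                "detectable_or_risky": detectable_effect(s, "risky"),
                "detectable_or_protective": detectable_effect(s, "protective"),
            })
    return pd.DataFrame(rows)


def bonferroni_threshold(n_tests: int, alpha_family: float = 0.05) -> float:
    """Family-wise significance threshold ``alpha / n_tests``."""
    if n_tests < 1:
        raise ConfigurationError("n_tests must be >= 1")
    return alpha_family / n_tests


def format_threshold(value: float, digits: int = 2) -> str:
    """Render a threshold in truncated scientific notation, e.g.
    0.05/35 -> "1.42 x 10^-3" (mantissa truncated, not rounded, matching
    the convention used in epidemiological reporting of 0.05/35)."""
    if value <= 0:
        raise ConfigurationError("value must be positive")
    exponent = math.floor(math.log10(value))
    mantissa = value / 10 ** exponent
    factor = 10 ** digits
    mantissa = math.floor(mantissa * factor) / factor
    return f"{mantissa:.{digits}f} x 10^{exponent}"
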