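"""Heterogeneity diagnostics and robustness analyses.

Cochran's Q (about the IVW estimate) and Rucker's Q' (about the Egger fit)
quantify heterogeneity among per-SNP Wald ratios; their ratio diagnoses
whether directional pleiotropy (the Egger intercept) explains it.
MR-PRESSO detects outlying instruments by comparing an observed
leave-one-out residual sum of squares against a parametric null.
Leave-one-out / leave-one-group-out re-estimation and scatter/funnel plot
tables support visual outlier screening.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, InsufficientInstrumentsError
from .instruments import HarmonizedSet
from .estimators import (
    MREstimate,
    _ivw_core,
    _orient_positive,
    cochran_q_statistic,
    egger as egger_fit_fn,
    ivw as ivw_fn,
    wald_ratios,
    weighted_median,
    weighted_mode,
)


@dataclass
class HeterogeneityReport:
    """Q/I2/Rucker/intercept/PRESSO diagnostics for one analysis pair."""

    q: float
    q_df: int
    q_pval: float
    i2: float  # percentage in [0, 100]
    rucker_q: Optional[float] = None
    rucker_df: Optional[int] = None
    rucker_pval: Optional[float] = None
    rucker_ratio: Optional[float] = None
    intercept_pval: Optional[float] = None
    presso_global_pval: Optional[float] = None
    presso_global_str: Optional[str] = None


@dataclass
class LeaveOutRow:
    left_out: str
    nsnp_used: int
    beta: float
    se: float
    pval: float


def cochran_q(h: HarmonizedSet, ivw_beta: float):
    """Cochran's Q of the Wald ratios about the IVW estimate.

    Weights are ``(bx/sey)^2``; df = k-1; I2 = max(0, (Q-df)/Q) * 100.
    """
    k = h.nsnp
    if k < 2:
        raise InsufficientInstrumentsError("Cochran's Q needs >= 2 SNPs")
    q = cochran_q_statistic(h.bx, h.by, h.sey, ivw_beta)
    q_df = k - 1
    q_pval = float(stats.chi2.sf(q, q_df))
    i2 = max(0.0, (q - q_df) / q) * 100.0 if q > 0 else 0.0
    return q, q_df, q_pval, i2


def rucker_q(h: HarmonizedSet, egger_fit: MREstimate):
    """Rucker's Q': weighted residual sum of squares about the Egger fit
    on bx>=0-oriented data; df = k-2.  ``rucker_ratio`` is Q'/Q."""
    k = h.nsnp
    if k < 3:
        raise InsufficientInstrumentsError("Rucker's Q needs >= 3 SNPs")
    bxo, byo = _orient_positive(h.bx, h.by)
    resid = byo - egger_fit.intercept - egger_fit.beta * bxo
    rq = float(np.sum(resid ** 2 / h.sey ** 2))
    rdf = k - 2
    rp = float(stats.chi2.sf(rq, rdf))
    beta_ivw, _ = _ivw_core(h.bx, h.by, h.sey)
    q = cochran_q_statistic(h.bx, h.by, h.sey, beta_ivw)
    ratio = rq / q if q > 0 else float("nan")
    return rq, rdf, rp, ratio


def _loo_ivw_estimates(bx, by, sey):
    """Leave-one-out IVW estimate for each SNP, via sum subtraction.

    Supports batched input of shape (..., k); returns the same shape.
    """
    w = sey ** -2.0
    num = bx * by * w
    den = bx ** 2 * w
    num_tot = num.sum(axis=-1, keepdims=True)
    den_tot = den.sum(axis=-1, keepdims=True)
    return (num_tot - num) / (den_tot - den)


def mr_presso(
    h: HarmonizedSet,
    n_sim: int = 1000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
):
    """MR-PRESSO global and per-SNP outlier tests.

    The observed statistic is the weighted residual sum of squares
    ``sum_j w_j (by_j - theta_(-j) bx_j)^2`` with leave-one-out IVW
    predictions and weights ``1/sey^2``.  The null distribution comes from
    ``n_sim`` parametric replicates drawn under the leave-one-out model,
    each evaluated with its own leave-one-out predictions.  The global
    p-value is the exceedance proportion (reported as "<1/n_sim" when no
    replicate exceeds the observed value); per-SNP p-values are
    Bonferroni-adjusted by k and thresholded at ``outlier_alpha``.

    Returns ``(global_pval, global_str, per_snp_pvals, outlier_ids)``.
    """
    k = h.nsnp
    if k < 4:
        raise InsufficientInstrumentsError("MR-PRESSO needs >= 4 SNPs")
    if n_sim < 1:
        raise ConfigurationError("n_sim must be >= 1")

    w = h.sey ** -2.0
    theta_loo = _loo_ivw_estimates(h.bx, h.by, h.sey)
    obs_terms = w * (h.by - theta_loo * h.bx) ** 2
    obs_rss = float(obs_terms.sum())

    rng = np.random.default_rng(seed)
    bx_sim = rng.normal(h.bx, h.sex, size=(n_sim, k))
    by_sim = rng.normal(theta_loo * h.bx, h.sey, size=(n_sim, k))
    theta_loo_sim = _loo_ivw_estimates(bx_sim, by_sim, h.sey)
    sim_terms = w * (by_sim - theta_loo_sim * bx_sim) ** 2
    sim_rss = sim_terms.sum(axis=1)

    exceed = int(np.sum(sim_rss >= obs_rss))
    global_pval = exceed / n_sim
    global_str = f"<{1.0 / n_sim:g}" if exceed == 0 else f"{global_pval:.4g}"

    per_raw = np.mean(sim_terms >= obs_terms[None, :], axis=0)
    per_snp = np.minimum(per_raw * k, 1.0)  # Bonferroni
    outliers = [s for s, p in zip(h.snp_ids, per_snp) if p < outlier_alpha]
    return global_pval, global_str, per_snp, outliers


_ESTIMATOR_FNS: dict[str, Callable[[HarmonizedSet], MREstimate]] = {
    "ivw": lambda h: ivw_fn(h),
    "egger": lambda h: egger_fit_fn(h),
    "wme": lambda h: weighted_median(h, n_boot=200, seed=0),
    "mbe": lambda h: weighted_mode(h, n_boot=200, seed=0),
}


def leave_out(
    h: HarmonizedSet,
    grouping: Optional[Mapping[str, str]] = None,
    estimator: str = "ivw",
) -> list[LeaveOutRow]:
    """Leave-one-out (grouping=None) or leave-one-group-out re-estimation."""
    if estimator not in _ESTIMATOR_FNS:
        raise ConfigurationError(f"unknown estimator {estimator!r}")
    fn = _ESTIMATOR_FNS[estimator]

    if grouping is None:
        units = [(s, [s]) for s in h.snp_ids]
    else:
        labels: dict[str, list[str]] = {}
        for s in h.snp_ids:
            lab = grouping.get(s)
            if lab is not None:
                labels.setdefault(lab, []).append(s)
        units = sorted(labels.items())

    rows: list[LeaveOutRow] = []
    ids = np.array(h.snp_ids)
    for label, members in units:
        mask = ~np.isin(ids, members)
        n_left = int(mask.sum())
        if n_left < 2:
            raise ConfigurationError(
                f"leaving out {label!r} leaves {n_left} SNP(s); >= 2 required"
            )
        est = fn(h.subset(mask))
        rows.append(LeaveOutRow(
            left_out=label, nsnp_used=n_left,
            beta=est.beta, se=est.se, pval=est.pval,
        ))
    return rows


def scatter_funnel_data(h: HarmonizedSet, estimates: Sequence[MREstimate]):
    """Plot-ready tables for the scatter and funnel diagnostics.

    The scatter table holds one point per SNP (bx, by, sex, sey) and one
    (method, slope, intercept) row per estimate; the funnel table holds
    each Wald ratio against its precision with one vertical reference per
    method's estimate.
    """
    if not estimates:
        raise ConfigurationError("at least one estimate is required")
    theta, theta_se = wald_ratios(h)
    scatter_points = pd.DataFrame({
        "snp_id": h.snp_ids, "bx": h.bx, "by": h.by, "sex": h.sex, "sey": h.sey,
    })
    lines = pd.DataFrame({
        "method": [e.method for e in estimates],
        "slope": [e.beta for e in estimates],
        "intercept": [e.intercept if e.intercept is not None else 0.0 for e in estimates],
    })
    scatter = {"points": scatter_points, "lines": lines}
    funnel_points = pd.DataFrame({
        "snp_id": h.snp_ids, "theta": theta, "precision": 1.0 / theta_se,
    })
    refs = pd.DataFrame({
        "method": [e.method for e in estimates],
        "beta": [e.beta for e in estimates],
    })
    funnel = {"points": funnel_points, "references": refs}
    return scatter, funnel


def heterogeneity_report(
    h: HarmonizedSet,
    ivw_est: MREstimate,
    egger_est: Optional[MREstimate] = None,
    presso_sims: int = 1000,
    seed: int = 0,
) -> HeterogeneityReport:
    """Assemble the full diagnostic block for one analysis pair."""
    q, q_df, q_pval, i2 = cochran_q(h, ivw_est.beta)
    report = HeterogeneityReport(q=q, q_df=q_df, q_pval=q_pval, i2=i2)
    if egger_est is not None and egger_est.ok and h.nsnp >= 3:
        rq, rdf, rp, ratio = rucker_q(h, egger_est)
        report.rucker_q, report.rucker_df = rq, rdf
        report.rucker_pval, report.rucker_ratio = rp, ratio
        report.intercept_pval = egger_est.intercept_pval
    if h.nsnp >= 4:
        gp, gs, _, _ = mr_presso(h, n_sim=presso_sims, seed=seed)
        report.presso_global_pval = gp
        report.presso_global_str = gs
    return report
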