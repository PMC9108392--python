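"""Multivariable Mendelian randomization by inverse-variance weighting.

When exposures are genetically correlated (e.g. chronic pain with sleep
traits), a univariable estimate for one exposure absorbs the direct effects
of the others.  Multivariable IVW regresses the outcome associations on
the instrument associations with *all* exposures jointly (weighted least
squares, no intercept, weights ``1/sey^2``), so each coefficient is the
direct effect of its exposure conditional on the co-exposures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .exceptions import (
    CollinearExposuresError,
    ConfigurationError,
    InsufficientInstrumentsError,
)
from .estimators import MREstimate, Z95
from .instruments import InstrumentSet, align_alleles
from .io_summary import AssociationTable

log = logging.getLogger("causalmr")

CONDITION_NUMBER_LIMIT = 1e8


@dataclass
class MultiHarmonizedSet:
    """Row-aligned instrument effects on m exposures and one outcome."""

    snp_ids: list[str]
    bx_matrix: np.ndarray  # (k, m)
    sex_matrix: np.ndarray  # (k, m)
    by: np.ndarray
    sey: np.ndarray
    exposure_names: list[str]
    outcome_name: str = ""
    outcome_type: str = "binary"
    imputed: list[tuple[str, str]] = field(default_factory=list)  # (snp, exposure)
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.bx_matrix = np.atleast_2d(np.asarray(self.bx_matrix, dtype=float))
        self.sex_matrix = np.atleast_2d(np.asarray(self.sex_matrix, dtype=float))
        self.by = np.asarray(self.by, dtype=float)
        self.sey = np.asarray(self.sey, dtype=float)
        k, m = self.bx_matrix.shape
        if len(self.exposure_names) != m:
            raise ConfigurationError("exposure_names length must match bx_matrix columns")
        if self.sex_matrix.shape != (k, m) or self.by.shape != (k,) or self.sey.shape != (k,):
            raise ConfigurationError("row-misaligned multivariable set")

    @property
    def nsnp(self) -> int:
        return self.bx_matrix.shape[0]

    @property
    def n_exposures(self) -> int:
        return self.bx_matrix.shape[1]


def build_multi_set(
    instrument_sets: Sequence[InstrumentSet],
    exposure_tables: Sequence[AssociationTable],
    outcome: AssociationTable,
) -> MultiHarmonizedSet:
    """Pool clumped instruments across exposures into one design matrix.

    The union of instruments (first-appearance order) is looked up in every
    exposure table and the outcome.  A SNP missing from an exposure table
    enters with effect 0 and that table's median SE, flagged in
    ``imputed``; a SNP missing from the outcome, or with irreconcilable
    alleles anywhere, is dropped.  Allele orientation follows the
    instrument record that contributed the SNP.
    """
    if len(instrument_sets) < 2:
        raise ConfigurationError("multivariable MR needs >= 2 exposures")
    if len(instrument_sets) != len(exposure_tables):
        raise ConfigurationError("one exposure table per instrument set required")

    union: dict[str, object] = {}
    for iset in instrument_sets:
        for rec in iset.records:
            union.setdefault(rec.snp_id, rec)

    lookups = [t.by_id() for t in exposure_tables]
    median_ses = [float(np.median([r.se for r in t.records])) for t in exposure_tables]
    out_by_id = outcome.by_id()

    snp_ids, rows_bx, rows_sex, by, sey = [], [], [], [], []
    imputed: list[tuple[str, str]] = []
    dropped: list[tuple[str, str]] = []

    for snp_id, ref in union.items():
        out = out_by_id.get(snp_id)
        if out is None:
            dropped.append((snp_id, "missing_in_outcome"))
            continue
        orient_out = align_alleles(ref.effect_allele, ref.other_allele,
                                   out.effect_allele, out.other_allele)
        if orient_out is None:
            dropped.append((snp_id, "allele_mismatch"))
            continue

        bx_row, sex_row = [], []
        ok = True
        for table, lookup, med_se in zip(exposure_tables, lookups, median_ses):
            rec = lookup.get(snp_id)
            if rec is None:
                bx_row.append(0.0)
                sex_row.append(med_se)
                imputed.append((snp_id, table.trait_name))
                continue
            orient = align_alleles(ref.effect_allele, ref.other_allele,
                                   rec.effect_allele, rec.other_allele)
            if orient is None:
                dropped.append((snp_id, "allele_mismatch"))
                ok = False
                break
            bx_row.append(rec.beta if orient == "same" else -rec.beta)
            sex_row.append(rec.se)
        if not ok:
            continue

        snp_ids.append(snp_id)
        rows_bx.append(bx_row)
        rows_sex.append(sex_row)
        by.append(out.beta if orient_out == "same" else -out.beta)
        sey.append(out.se)

    if not snp_ids:
        raise InsufficientInstrumentsError("no SNP survived multivariable pooling")
    if imputed:
        log.info("multivariable set: %d zero-imputed exposure associations", len(imputed))

    return MultiHarmonizedSet(
        snp_ids=snp_ids,
        bx_matrix=np.array(rows_bx),
        sex_matrix=np.array(rows_sex),
        by=np.array(by), sey=np.array(sey),
        exposure_names=[t.trait_name for t in exposure_tables],
        outcome_name=outcome.trait_name,
        outcome_type=outcome.trait_type,
        imputed=imputed, dropped=dropped,
    )


def mvmr_ivw(mh: MultiHarmonizedSet) -> list[MREstimate]:
    """Multivariable IVW: WLS of by on the exposure-effect columns, no
    intercept, weights ``1/sey^2``; per-exposure SEs carry the
    multiplicative-floored residual inflation.  Returns one estimate per
    exposure, tagged with the co-exposures adjusted for."""
    k, m = mh.nsnp, mh.n_exposures
    if k <= m:
        raise InsufficientInstrumentsError(
            f"multivariable IVW needs more SNPs ({k}) than exposures ({m})"
        )

    sw = 1.0 / mh.sey
    Xw = mh.bx_matrix * sw[:, None]
    yw = mh.by * sw

    cond = np.linalg.cond(Xw)
    if cond > CONDITION_NUMBER_LIMIT:
        corr = np.corrcoef(Xw, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        raise CollinearExposuresError(
            f"collinear exposures (condition number {cond:.3g}): "
            f"{mh.exposure_names[i]!r} vs {mh.exposure_names[j]!r}"
        )

    xtx = Xw.T @ Xw
    coef = np.linalg.solve(xtx, Xw.T @ yw)
    resid = yw - Xw @ coef
    dof = k - m
    sigma2 = float(resid @ resid) / dof
    cov_unit = np.linalg.inv(xtx)
    scale = max(1.0, np.sqrt(sigma2))
    se = scale * np.sqrt(np.diag(cov_unit))

    estimates = []
    for idx, name in enumerate(mh.exposure_names):
        b, s = float(coef[idx]), float(se[idx])
        z = b / s if s > 0 else np.inf * np.sign(b)
        pval = float(max(2.0 * stats.norm.sf(abs(z)), np.finfo(float).tiny))
        est = MREstimate(
            method="mvmr_ivw", nsnp=k, beta=b, se=s,
            ci_low=b - Z95 * s, ci_high=b + Z95 * s, pval=pval,
            metadata={
                "exposure": name,
                "adjusted_for": [n for n in mh.exposure_names if n != name],
                "n_imputed": len(mh.imputed),
            },
        )
        if mh.outcome_type == "binary":
            est.with_or_scale()
        estimates.append(est)
    return estimates
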