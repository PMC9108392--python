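"""Synthetic GWAS summary-statistic generator with known ground truth.

Emulates the data structure a two-sample summary-level MR analysis
consumes: per-variant effect/SE/EAF rows for an exposure and an outcome,
a true causal effect, optional balanced or directional horizontal
pleiotropy, case/control log-odds scaling on the outcome, and block LD
panels for clumping.  Individual genotypes are never simulated; standard
errors follow the usual summary-level approximations
``se_x = 1/sqrt(2 maf (1-maf) n)`` and, for case-control outcomes,
``se_y = 1/sqrt(2 maf (1-maf) n K (1-K))``.

Per-SNP variance-explained contributions are drawn lognormally
(``effect_dispersion``) so that a realistic instrument set combines a
large pooled R2 with a median F-statistic far below the mean — the
strongly right-skewed instrument-strength profile seen in real GWAS
instrument lists (median F in the thirties, maxima in the hundreds).
True exposure effects are oriented positive, matching the convention of
reporting instruments by their trait-increasing allele; directional
pleiotropy is therefore well-defined on the Egger orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .exceptions import ConfigurationError
from .instruments import HarmonizedSet, LDPanel
from .io_summary import (
    AssociationTable,
    StudyConfig,
    VariantAssociation,
    write_gwas_summary,
    write_study_config,
)
from .mvmr import MultiHarmonizedSet

_P_FLOOR = np.finfo(float).tiny

#: Non-palindromic allele pairs; the generator avoids strand-ambiguous SNPs
#: unless asked for them explicitly.
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass
class SimTruth:
    """Generating parameters of one synthetic exposure/outcome pair.

    Defaults mirror the headline morning-chronotype -> macular-degeneration
    analysis scale: 121 instruments explaining 5.75% of the exposure in
    ~403k individuals, a case-control outcome of ~455k with 15.8% cases,
    and a true causal effect of 0.175 log-odds per exposure unit (OR 1.19).
    """

    beta_causal: float = 0.175
    n_instruments: int = 121
    pleiotropy_mode: str = "none"  # none | balanced | directional
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_frac: float = 1.0  # fraction of instruments carrying pleiotropy
    n_exp: float = 403_195
    n_out: float = 455_258
    case_fraction: float = 0.158
    maf_range: tuple[float, float] = (0.05, 0.45)
    instrument_h2: float = 0.0575
    effect_dispersion: float = 1.8  # lognormal sigma of per-SNP R2 shares
    outcome_type: str = "binary"  # binary | continuous
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.instrument_h2 < 0.5):
            raise ConfigurationError("instrument_h2 must be in (0, 0.5)")
        lo, hi = self.maf_range
        if not (0.01 <= lo < hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0.01, 0.5)")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ConfigurationError(f"unknown pleiotropy mode {self.pleiotropy_mode!r}")
        if not (0 <= self.pleiotropy_frac <= 1):
            raise ConfigurationError("pleiotropy_frac must be in [0,1]")
        if self.outcome_type not in ("binary", "continuous"):
            raise ConfigurationError(f"unknown outcome type {self.outcome_type!r}")
        if self.n_instruments < 1:
            raise ConfigurationError("n_instruments must be >= 1")


def _wald_p(beta, se):
    z = np.abs(beta) / se
    return np.maximum(2.0 * stats.norm.sf(z), _P_FLOOR)


def _draw_effects(truth: SimTruth, rng: np.random.Generator):
    """MAFs, true exposure effects (positive, pooled R2 = instrument_h2),
    per-SNP SEs for both samples, and pleiotropic direct effects."""
    k = truth.n_instruments
    maf = rng.uniform(*truth.maf_range, size=k)
    het = 2.0 * maf * (1.0 - maf)

    if truth.effect_dispersion > 0:
        shares = rng.lognormal(0.0, truth.effect_dispersion, size=k)
    else:
        shares = np.ones(k)
    r2 = truth.instrument_h2 * shares / shares.sum()
    beta_true = np.sqrt(r2 / het)

    se_x = 1.0 / np.sqrt(het * truth.n_exp)
    if truth.outcome_type == "binary":
        kk = truth.case_fraction
        se_y = 1.0 / np.sqrt(het * truth.n_out * kk * (1.0 - kk))
    else:
        se_y = 1.0 / np.sqrt(het * truth.n_out)

    alpha = np.zeros(k)
    if truth.pleiotropy_mode != "none" and truth.pleiotropy_frac > 0:
        n_invalid = int(np.ceil(truth.pleiotropy_frac * k))
        which = rng.choice(k, size=n_invalid, replace=False)
        mean = truth.pleiotropy_mean if truth.pleiotropy_mode == "directional" else 0.0
        alpha[which] = rng.normal(mean, truth.pleiotropy_sd, size=n_invalid)

    mean_f = float(np.mean((beta_true / se_x) ** 2))
    weak = mean_f < 10.0
    return maf, beta_true, se_x, se_y, alpha, weak


def _observe(truth: SimTruth, rng: np.random.Generator):
    maf, beta_true, se_x, se_y, alpha, weak = _draw_effects(truth, rng)
    bx = beta_true + rng.normal(0.0, se_x)
    by_true = truth.beta_causal * beta_true + alpha
    by = by_true + rng.normal(0.0, se_y)
    return maf, beta_true, bx, se_x, by, se_y, weak


def simulate_harmonized(truth: SimTruth) -> tuple[HarmonizedSet, SimTruth]:
    """Generate an already-harmonized exposure/outcome pair directly.

    Equivalent to :func:`simulate_gwas_pair` followed by lossless
    harmonization; preferred inside simulation loops.
    """
    rng = np.random.default_rng(truth.seed)
    maf, _, bx, se_x, by, se_y, weak = _observe(truth, rng)
    if weak:
        import logging

        logging.getLogger("causalmr").warning(
            "simulated mean F < 10: weak-instrument regime"
        )
    k = truth.n_instruments
    case_frac = truth.case_fraction if truth.outcome_type == "binary" else None
    h = HarmonizedSet(
        exposure_name=truth.exposure_name,
        outcome_name=truth.outcome_name,
        snp_ids=[f"rs{1000 + j}" for j in range(k)],
        bx=bx, sex=np.broadcast_to(se_x, (k,)).copy(),
        by=by, sey=np.broadcast_to(se_y, (k,)).copy(),
        eaf_x=maf, eaf_y=maf.copy(),
        exposure_type="continuous",
        outcome_type=truth.outcome_type,
        n_exposure=truth.n_exp,
        n_outcome=truth.n_out,
        outcome_case_fraction=case_frac,
    )
    return h, truth


def _records_from_arrays(snp_ids, alleles, maf, beta, se, n, chrom=None, pos=None,
                         n_case=None, n_control=None):
    pvals = _wald_p(beta, se)
    records = []
    for j, sid in enumerate(snp_ids):
        ea, oa = alleles[j]
        records.append(VariantAssociation(
            snp_id=sid, effect_allele=ea, other_allele=oa,
            beta=float(beta[j]), se=float(se[j]), pval=float(pvals[j]),
            n=float(n), eaf=float(maf[j]),
            chrom=None if chrom is None else chrom[j],
            pos=None if pos is None else int(pos[j]),
            n_case=n_case, n_control=n_control,
        ))
    return records


def simulate_gwas_pair(truth: SimTruth):
    """Generate exposure and outcome summary tables with known truth.

    Returns ``(exposure_table, outcome_table, truth)``.  Deterministic and
    byte-identical under a fixed seed.  Alleles are non-palindromic; each
    SNP sits on its own LD-independent position (>=20 Mb apart within a
    chromosome), so the tables pass straight through selection and
    harmonization in tests.
    """
    rng = np.random.default_rng(truth.seed)
    maf, _, bx, se_x, by, se_y, weak = _observe(truth, rng)
    if weak:
        import logging

        logging.getLogger("causalmr").warning(
            "simulated mean F < 10: weak-instrument regime"
        )
    k = truth.n_instruments
    snp_ids = [f"rs{1000 + j}" for j in range(k)]
    alleles = [_ALLELE_PAIRS[int(i)] for i in rng.integers(0, len(_ALLELE_PAIRS), size=k)]
    chrom = [str(j % 22 + 1) for j in range(k)]
    pos = [20_000_000 * (j // 22 + 1) + (j % 22) for j in range(k)]

    exposure = AssociationTable(
        trait_name=truth.exposure_name, trait_type="continuous",
        records=_records_from_arrays(
            snp_ids, alleles, maf, bx, np.broadcast_to(se_x, (k,)), truth.n_exp,
            chrom, pos,
        ),
    )
    if truth.outcome_type == "binary":
        n_case = int(round(truth.n_out * truth.case_fraction))
        n_control = int(round(truth.n_out)) - n_case
    else:
        n_case = n_control = None
    outcome = AssociationTable(
        trait_name=truth.outcome_name, trait_type=truth.outcome_type,
        records=_records_from_arrays(
            snp_ids, alleles, maf, by, np.broadcast_to(se_y, (k,)), truth.n_out,
            chrom, pos, n_case=n_case, n_control=n_control,
        ),
    )
    return exposure, outcome, truth


def simulate_ld_panel(
    n_blocks: int,
    block_size: int,
    within_r2: float,
    seed: int = 0,
) -> tuple[LDPanel, AssociationTable]:
    """Block-diagonal LD panel plus one association per SNP.

    Within-block r2 is constant, between-block r2 is zero, and the first
    SNP of each block carries the smallest p-value, so greedy clumping at
    any threshold below ``within_r2`` keeps exactly the block leads.
    """
    if not (0 <= within_r2 < 1):
        raise ConfigurationError("within_r2 must be in [0,1)")
    rng = np.random.default_rng(seed)
    k = n_blocks * block_size
    r2 = np.zeros((k, k))
    snp_ids, records = [], []
    for b in range(n_blocks):
        sl = slice(b * block_size, (b + 1) * block_size)
        r2[sl, sl] = within_r2
    np.fill_diagonal(r2, 1.0)

    maf = rng.uniform(0.1, 0.4, size=k)
    het = 2.0 * maf * (1.0 - maf)
    se = 1.0 / np.sqrt(het * 100_000)
    for b in range(n_blocks):
        for i in range(block_size):
            j = b * block_size + i
            sid = f"blk{b}_snp{i}"
            snp_ids.append(sid)
            # leads get z ~ 8, followers z ~ 6..7: leads always most significant
            z = 8.0 + rng.uniform(0, 0.5) if i == 0 else 6.0 + rng.uniform(0, 0.9)
            beta = z * se[j]
            records.append(VariantAssociation(
                snp_id=sid, effect_allele="A", other_allele="G",
                beta=float(beta), se=float(se[j]),
                pval=float(max(2.0 * stats.norm.sf(z), _P_FLOOR)),
                n=100_000, eaf=float(maf[j]),
                chrom=str(b % 22 + 1), pos=30_000_000 * (b // 22 + 1) + i * 1_000,
            ))
    table = AssociationTable(trait_name="sim_trait", trait_type="continuous",
                             records=records)
    return LDPanel(snp_ids=snp_ids, r2=r2), table


def _multi_true_effects(m, rho, truth: SimTruth, rng):
    k = truth.n_instruments
    if not (abs(rho) < 1):
        raise ConfigurationError("|exposure_correlation| must be < 1")
    maf = rng.uniform(*truth.maf_range, size=k)
    het = 2.0 * maf * (1.0 - maf)
    if rho < 0 and m > 2:
        raise ConfigurationError(
            "a common negative pairwise correlation is infeasible for m > 2"
        )
    signs = np.ones(m)
    if rho < 0:
        signs[1] = -1.0
    shared = rng.standard_normal(k)
    specific = rng.standard_normal((k, m))
    e = np.sqrt(abs(rho)) * shared[:, None] * signs \
        + np.sqrt(1.0 - abs(rho)) * specific
    beta_true = np.empty((k, m))
    for i in range(m):
        raw_r2 = het * e[:, i] ** 2
        lam = np.sqrt(truth.instrument_h2 / raw_r2.sum())
        beta_true[:, i] = lam * e[:, i]
    return maf, het, beta_true


def simulate_multi_harmonized(
    m: int,
    direct_effects: Sequence[float],
    exposure_correlation: float,
    truth: SimTruth,
) -> tuple[MultiHarmonizedSet, list[HarmonizedSet], SimTruth]:
    """Correlated-exposure system, returned in analysis-ready containers.

    The outcome is generated from ``direct_effects`` only, so multivariable
    IVW should recover them while univariable estimates absorb the
    correlated co-exposures.  Also returns per-exposure univariable views
    (every pooled SNP used as an instrument for each exposure).
    """
    if m < 2:
        raise ConfigurationError("m must be >= 2")
    direct = np.asarray(direct_effects, dtype=float)
    if direct.shape != (m,):
        raise ConfigurationError("direct_effects length must equal m")
    rng = np.random.default_rng(truth.seed)
    k = truth.n_instruments
    maf, het, beta_true = _multi_true_effects(m, exposure_correlation, truth, rng)

    se_x = 1.0 / np.sqrt(het * truth.n_exp)
    bx = beta_true + rng.normal(0.0, 1.0, size=(k, m)) * se_x[:, None]
    if truth.outcome_type == "binary":
        kk = truth.case_fraction
        se_y = 1.0 / np.sqrt(het * truth.n_out * kk * (1.0 - kk))
    else:
        se_y = 1.0 / np.sqrt(het * truth.n_out)
    by = beta_true @ direct + rng.normal(0.0, se_y)

    snp_ids = [f"rs{1000 + j}" for j in range(k)]
    names = [f"exposure_{i + 1}" for i in range(m)]
    mh = MultiHarmonizedSet(
        snp_ids=snp_ids,
        bx_matrix=bx,
        sex_matrix=np.tile(se_x[:, None], (1, m)),
        by=by, sey=se_y,
        exposure_names=names,
        outcome_name=truth.outcome_name,
        outcome_type=truth.outcome_type,
    )
    uni = [
        HarmonizedSet(
            exposure_name=names[i], outcome_name=truth.outcome_name,
            snp_ids=snp_ids,
            bx=bx[:, i], sex=se_x.copy(), by=by.copy(), sey=se_y.copy(),
            eaf_x=maf.copy(), eaf_y=maf.copy(),
            outcome_type=truth.outcome_type,
            n_exposure=truth.n_exp, n_outcome=truth.n_out,
            outcome_case_fraction=truth.case_fraction if truth.outcome_type == "binary" else None,
        )
        for i in range(m)
    ]
    return mh, uni, truth


def simulate_multi_exposure(
    m: int,
    direct_effects: Sequence[float],
    exposure_correlation: float,
    truth: SimTruth,
):
    """Correlated-exposure system as summary tables.

    Returns ``(exposure_tables, outcome_table, truth)``; the outcome is
    generated from ``direct_effects`` only.
    """
    mh, _, truth = simulate_multi_harmonized(m, direct_effects, exposure_correlation, truth)
    k = truth.n_instruments
    rng = np.random.default_rng(truth.seed + 1)
    alleles = [_ALLELE_PAIRS[int(i)] for i in rng.integers(0, len(_ALLELE_PAIRS), size=k)]
    chrom = [str(j % 22 + 1) for j in range(k)]
    pos = [20_000_000 * (j // 22 + 1) + (j % 22) for j in range(k)]
    maf = rng.uniform(*truth.maf_range, size=k)  # bookkeeping EAFs for the tables

    tables = []
    for i, name in enumerate(mh.exposure_names):
        tables.append(AssociationTable(
            trait_name=name, trait_type="continuous",
            records=_records_from_arrays(
                mh.snp_ids, alleles, maf, mh.bx_matrix[:, i], mh.sex_matrix[:, i],
                truth.n_exp, chrom, pos,
            ),
        ))
    if truth.outcome_type == "binary":
        n_case = int(round(truth.n_out * truth.case_fraction))
        n_control = int(round(truth.n_out)) - n_case
    else:
        n_case = n_control = None
    outcome = AssociationTable(
        trait_name=truth.outcome_name, trait_type=truth.outcome_type,
        records=_records_from_arrays(
            mh.snp_ids, alleles, maf, mh.by, mh.sey, truth.n_out, chrom, pos,
            n_case=n_case, n_control=n_control,
        ),
    )
    return tables, outcome, truth


# ---------------------------------------------------------------------------
# Ready-to-run fixture study (seven exposures x five outcomes)

#: Desk-scale analogue of a sleep/pain -> neurodegeneration study: per-trait
#: instrument counts are scaled down from the real post-clumping counts so a
#: full 7x5 run stays interactive, while sample sizes stay at GWAS scale.
FIXTURE_EXPOSURES = {
    "SD": {"k": 40, "n": 446_118},
    "SS": {"k": 26, "n": 411_934},
    "LS": {"k": 9, "n": 339_926},
    "CHR": {"k": 50, "n": 449_734},
    "MP": {"k": 45, "n": 403_195},
    "INS": {"k": 13, "n": 386_533},
    "MCP": {"k": 30, "n": 387_649},
}

FIXTURE_OUTCOMES = {
    "AD": {"n": 33_976, "case_fraction": 0.475},
    "AMD": {"n": 455_258, "case_fraction": 0.158},
    "ALS": {"n": 36_052, "case_fraction": 0.349},
    "MS": {"n": 115_635, "case_fraction": 0.409},
    "PD": {"n": 482_730, "case_fraction": 0.070},
}

#: True causal effects of the fixture (log-odds per exposure unit); the
#: morning-person-like and chronotype-like exposures causally raise the
#: macular-degeneration-like outcome, everything else is null.
FIXTURE_EFFECTS = {("MP", "AMD"): 0.175, ("CHR", "AMD"): 0.12}

_FIXTURE_F_TARGET = 45.0  # mean per-SNP F; keeps every instrument significant


def simulate_study_directory(out_dir, seed: int = 0) -> StudyConfig:
    """Write a complete ready-to-run study directory.

    Seven exposure files, five outcome files, per-exposure identity LD
    panels and a ``config.yaml``, shaped like a bidirectional sleep/pain
    versus neurodegeneration study at desk scale.  Returns the config.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    # draw per-exposure instruments once; outcome effects reuse the truth
    exposure_truth = {}
    for name, meta in FIXTURE_EXPOSURES.items():
        k, n = meta["k"], meta["n"]
        h2 = _FIXTURE_F_TARGET * k / n
        truth = SimTruth(
            beta_causal=0.0, n_instruments=k, n_exp=n, n_out=1,
            instrument_h2=h2, effect_dispersion=0.3,
            exposure_name=name, seed=int(rng.integers(0, 2**31 - 1)),
        )
        trng = np.random.default_rng(truth.seed)
        maf, beta_true, se_x, _, _, _ = _draw_effects(truth, trng)
        bx = beta_true + trng.normal(0.0, se_x)
        exposure_truth[name] = (truth, maf, beta_true, bx, se_x)

    # globally unique SNP ids, alleles and positions per exposure
    offset = 0
    panels = {}
    for name, (truth, maf, beta_true, bx, se_x) in exposure_truth.items():
        k = truth.n_instruments
        snp_ids = [f"rs{10_000 + offset + j}" for j in range(k)]
        arng = np.random.default_rng(truth.seed + 7)
        alleles = [_ALLELE_PAIRS[int(i)] for i in arng.integers(0, len(_ALLELE_PAIRS), size=k)]
        chrom = [str(j % 22 + 1) for j in range(k)]
        pos = [20_000_000 * (j // 22 + 1) + offset * 100 + (j % 22) for j in range(k)]
        exposure_truth[name] = (truth, maf, beta_true, bx, se_x, snp_ids, alleles, chrom, pos)
        panels[name] = LDPanel(snp_ids=snp_ids, r2=np.eye(k))
        offset += k

    for name, payload in exposure_truth.items():
        truth, maf, beta_true, bx, se_x, snp_ids, alleles, chrom, pos = payload
        table = AssociationTable(
            trait_name=name, trait_type="continuous",
            records=_records_from_arrays(
                snp_ids, alleles, maf, bx, np.broadcast_to(se_x, bx.shape),
                truth.n_exp, chrom, pos,
            ),
        )
        write_gwas_summary(table, out_dir / f"{name}.tsv")
        panel = panels[name]
        import pandas as pd

        pd.DataFrame(panel.r2, index=panel.snp_ids, columns=panel.snp_ids).to_csv(
            out_dir / f"ld_{name}.tsv", sep="\t", float_format="%.3g"
        )

    orng = np.random.default_rng(seed + 101)
    for oname, meta in FIXTURE_OUTCOMES.items():
        n_out, kk = meta["n"], meta["case_fraction"]
        records = []
        for ename, payload in exposure_truth.items():
            truth, maf, beta_true, bx, se_x, snp_ids, alleles, chrom, pos = payload
            het = 2.0 * maf * (1.0 - maf)
            se_y = 1.0 / np.sqrt(het * n_out * kk * (1.0 - kk))
            effect = FIXTURE_EFFECTS.get((ename, oname), 0.0)
            by = effect * beta_true + orng.normal(0.0, se_y)
            n_case = int(round(n_out * kk))
            records.extend(_records_from_arrays(
                snp_ids, alleles, maf, by, se_y, n_out, chrom, pos,
                n_case=n_case, n_control=int(n_out) - n_case,
            ))
        table = AssociationTable(trait_name=oname, trait_type="binary", records=records)
        write_gwas_summary(table, out_dir / f"{oname}.tsv")

    config = StudyConfig(
        exposures=[(n, f"{n}.tsv", "continuous") for n in FIXTURE_EXPOSURES],
        outcomes=[(n, f"{n}.tsv", "binary") for n in FIXTURE_OUTCOMES],
        directions="forward",
        seed=seed,
    )
    write_study_config(config, out_dir / "config.yaml")
    return config
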