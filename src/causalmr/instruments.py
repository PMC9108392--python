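"""Instrument selection, LD pruning, strength scoring and harmonization.

Instruments are genome-wide-significant variants for the exposure (strict
``pval < threshold``), pruned to approximate linkage independence by greedy
clumping against a user-supplied LD panel, scored by the single-SNP
F-statistic ``(beta/se)^2`` and variance explained ``2*beta^2*EAF*(1-EAF)``,
and aligned to an outcome table so that both effects refer to the same
effect allele.  Weak instruments (F < 10) are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    EmptyInstrumentError,
    HarmonizationEmptyError,
    MissingFromPanelError,
)
from .io_summary import AssociationTable, VariantAssociation

log = logging.getLogger("causalmr")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Effect-allele-frequency band inside which a palindromic SNP's strand
#: cannot be inferred from frequency; community default.
PALINDROME_EAF_BAND = (0.42, 0.58)


@dataclass
class InstrumentSet:
    """Selected instruments for one exposure, with per-SNP strength scores."""

    exposure_name: str
    records: list[VariantAssociation]
    per_snp_f: np.ndarray
    per_snp_r2: np.ndarray  # NaN where eaf is missing
    trait_type: str = "continuous"

    @property
    def pooled_r2(self) -> float:
        """Sum of per-SNP variance explained (additive under independence)."""
        return float(np.nansum(self.per_snp_r2))

    def __len__(self) -> int:
        return len(self.records)

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]


@dataclass
class LDPanel:
    """Pairwise r-squared matrix plus an optional proxy lookup table."""

    snp_ids: list[str]
    r2: np.ndarray
    proxy_table: Optional[list[tuple[str, str, float]]] = None

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.snp_ids)
        if self.r2.shape != (k, k):
            raise ConfigurationError("LD matrix shape does not match snp_ids")
        if not np.allclose(self.r2, self.r2.T):
            raise ConfigurationError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ConfigurationError("LD matrix diagonal must be 1")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def r2_between(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def proxy_for(self, snp_id: str) -> Optional[tuple[str, float]]:
        if not self.proxy_table:
            return None
        best = None
        for missing, proxy, r2 in self.proxy_table:
            if missing == snp_id and r2 > 0.8:
                if best is None or r2 > best[1]:
                    best = (proxy, r2)
        return best


def read_ld_panel(matrix_path, proxy_path=None) -> LDPanel:
    """Read a square LD matrix (header row and index column of snp_ids)
    and an optional 3-column proxy table (snp, proxy, r2)."""
    df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    proxies = None
    if proxy_path is not None:
        pt = pd.read_csv(proxy_path, sep="\t", header=None, names=["snp", "proxy", "r2"])
        proxies = list(pt.itertuples(index=False, name=None))
    return LDPanel(snp_ids=list(df.columns), r2=df.to_numpy(), proxy_table=proxies)


@dataclass
class HarmonizedSet:
    """Aligned exposure/outcome effect arrays for one analysis pair.

    All effects refer to the exposure's effect allele.  ``dropped`` records
    every instrument lost in harmonization with its reason.
    """

    exposure_name: str
    outcome_name: str
    snp_ids: list[str]
    bx: np.ndarray
    sex: np.ndarray
    by: np.ndarray
    sey: np.ndarray
    eaf_x: np.ndarray  # NaN where missing
    eaf_y: Optional[np.ndarray] = None
    dropped: list[tuple[str, str]] = field(default_factory=list)
    exposure_type: str = "continuous"
    outcome_type: str = "binary"
    n_exposure: Optional[float] = None
    n_outcome: Optional[float] = None
    outcome_case_fraction: Optional[float] = None
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("bx", "sex", "by", "sey", "eaf_x"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.eaf_y is not None:
            self.eaf_y = np.asarray(self.eaf_y, dtype=float)
        k = len(self.snp_ids)
        for name in ("bx", "sex", "by", "sey", "eaf_x"):
            if getattr(self, name).shape != (k,):
                raise ConfigurationError(f"{name} length does not match snp_ids")
        if k and (np.any(self.sex <= 0) or np.any(self.sey <= 0)):
            raise ConfigurationError("standard errors must be positive")

    @property
    def nsnp(self) -> int:
        return len(self.snp_ids)

    def subset(self, mask: np.ndarray) -> "HarmonizedSet":
        mask = np.asarray(mask, dtype=bool)
        return replace(
            self,
            snp_ids=[s for s, m in zip(self.snp_ids, mask) if m],
            bx=self.bx[mask], sex=self.sex[mask],
            by=self.by[mask], sey=self.sey[mask],
            eaf_x=self.eaf_x[mask],
            eaf_y=None if self.eaf_y is None else self.eaf_y[mask],
            dropped=list(self.dropped),
            notes=list(self.notes),
        )


def instrument_strength(beta: float, se: float, eaf: Optional[float]):
    """F-statistic and variance explained for a single instrument.

    F = (beta/se)^2; r2 = 2*beta^2*EAF*(1-EAF).  r2 is NaN when eaf is
    missing (never imputed).
    """
    if se <= 0:
        raise ConfigurationError("se must be positive")
    f = (beta / se) ** 2
    if eaf is None:
        return f, float("nan")
    if not (0 < eaf < 1):
        raise ConfigurationError(f"eaf must be in (0,1), got {eaf}")
    r2 = 2.0 * beta ** 2 * eaf * (1.0 - eaf)
    return f, r2


def select_instruments(
    table: AssociationTable,
    p_threshold: float = 5e-8,
    min_f: Optional[float] = 10.0,
) -> InstrumentSet:
    """Keep variants with ``pval`` strictly below the threshold, in input
    order, scored by F and r2.  Instruments with F below ``min_f`` are
    excluded; pass ``min_f=None`` to defer the weak-instrument filter (e.g.
    until after clumping)."""
    if len(table) == 0:
        raise EmptyInstrumentError(f"association table {table.trait_name!r} is empty")
    kept = [r for r in table.records if r.pval < p_threshold]
    if not kept:
        raise EmptyInstrumentError(
            f"no instrument passes p < {p_threshold:g} for trait {table.trait_name!r}"
        )
    scores = [instrument_strength(r.beta, r.se, r.eaf) for r in kept]
    f = np.array([s[0] for s in scores])
    r2 = np.array([s[1] for s in scores])
    if min_f is not None:
        strong = f >= min_f
        if not strong.any():
            raise EmptyInstrumentError(
                f"all instruments for {table.trait_name!r} have F < {min_f:g}"
            )
        kept = [r for r, m in zip(kept, strong) if m]
        f, r2 = f[strong], r2[strong]
    return InstrumentSet(
        exposure_name=table.trait_name,
        records=kept,
        per_snp_f=f,
        per_snp_r2=r2,
        trait_type=table.trait_type,
    )


def apply_f_filter(instruments: InstrumentSet, min_f: float = 10.0) -> InstrumentSet:
    """Drop instruments with F below ``min_f`` (weak-instrument rule)."""
    strong = instruments.per_snp_f >= min_f
    if not strong.any():
        raise EmptyInstrumentError(
            f"all instruments for {instruments.exposure_name!r} have F < {min_f:g}"
        )
    return InstrumentSet(
        exposure_name=instruments.exposure_name,
        records=[r for r, m in zip(instruments.records, strong) if m],
        per_snp_f=instruments.per_snp_f[strong],
        per_snp_r2=instruments.per_snp_r2[strong],
        trait_type=instruments.trait_type,
    )


def _genomic_sort_key(rec: VariantAssociation, original_index: int):
    if rec.chrom is not None and rec.pos is not None:
        chrom = rec.chrom
        try:
            chrom_key = (0, int(chrom))
        except ValueError:
            chrom_key = (1, chrom)
        return (0, chrom_key, rec.pos, original_index)
    return (1, (2, ""), 0, original_index)


def ld_clump(
    instruments: InstrumentSet,
    panel: LDPanel,
    r2_threshold: float = 0.001,
    window_kb: int = 10_000,
) -> InstrumentSet:
    """Greedy LD clumping: repeatedly keep the most significant remaining
    SNP and discard remaining SNPs correlated with it at ``r2 >=
    r2_threshold`` within ``window_kb``.

    SNPs on different chromosomes, or lacking positions, are compared on r2
    alone.  Output is in genomic order.  Deterministic: ties in p-value are
    broken by input order.
    """
    missing = [r.snp_id for r in instruments.records if r.snp_id not in panel]
    if missing:
        raise MissingFromPanelError(missing)

    order = sorted(range(len(instruments)), key=lambda i: (instruments.records[i].pval, i))
    alive = set(order)
    kept_idx: list[int] = []
    window_bp = window_kb * 1000
    for i in order:
        if i not in alive:
            continue
        kept_idx.append(i)
        alive.discard(i)
        ri = instruments.records[i]
        for j in list(alive):
            rj = instruments.records[j]
            r2 = panel.r2_between(ri.snp_id, rj.snp_id)
            if r2 < r2_threshold:
                continue
            have_pos = (
                ri.chrom is not None and ri.pos is not None
                and rj.chrom is not None and rj.pos is not None
            )
            if have_pos and ri.chrom == rj.chrom:
                within = abs(ri.pos - rj.pos) <= window_bp
            elif have_pos:  # different chromosomes: r2 alone decides
                within = True
            else:  # no positional information: r2 alone decides
                within = True
            if within:
                alive.discard(j)

    kept_idx.sort(key=lambda i: _genomic_sort_key(instruments.records[i], i))
    return InstrumentSet(
        exposure_name=instruments.exposure_name,
        records=[instruments.records[i] for i in kept_idx],
        per_snp_f=instruments.per_snp_f[kept_idx],
        per_snp_r2=instruments.per_snp_r2[kept_idx],
        trait_type=instruments.trait_type,
    )


def align_alleles(ea_ref: str, oa_ref: str, ea: str, oa: str):
    """Classify the orientation of an allele pair against a reference pair.

    Returns one of ``"same"`` (aligned), ``"swap"`` (negate effect, flip
    eaf), or ``None`` (irreconcilable).  Strand flips (complement) map onto
    the same two outcomes.  For palindromic pairs "same" and "swap" are
    indistinguishable from alleles alone; callers must use frequency.
    """
    if (ea, oa) == (ea_ref, oa_ref):
        return "same"
    if (ea, oa) == (oa_ref, ea_ref):
        return "swap"
    cea, coa = _COMPLEMENT[ea], _COMPLEMENT[oa]
    if (cea, coa) == (ea_ref, oa_ref):
        return "same"
    if (cea, coa) == (oa_ref, ea_ref):
        return "swap"
    return None


def harmonize(
    instruments: InstrumentSet,
    outcome: AssociationTable,
    palindrome_policy: str = "drop_ambiguous",
    panel: Optional[LDPanel] = None,
) -> HarmonizedSet:
    """Align outcome associations to the exposure's effect alleles.

    For each instrument the same snp_id is located in the outcome table
    (else its proxy with r2 > 0.8 from ``panel.proxy_table``, else dropped
    as ``missing_in_outcome``).  Swapped alleles negate the outcome effect
    and flip its EAF; strand flips are complemented then aligned.
    Palindromic (A/T, C/G) variants are resolved by ``palindrome_policy``:

    - ``drop_ambiguous`` (default): dropped when either trait's EAF lies in
      the ambiguity band [0.42, 0.58] or is missing; otherwise orientation
      is inferred from frequency agreement.
    - ``drop_all``: every palindromic variant is dropped.
    """
    if palindrome_policy not in ("drop_ambiguous", "drop_all"):
        raise ConfigurationError(f"unknown palindrome policy {palindrome_policy!r}")
    if len(instruments) == 0:
        raise HarmonizationEmptyError("no instruments to harmonize")

    out_by_id = outcome.by_id()
    lo, hi = PALINDROME_EAF_BAND

    snp_ids, bx, sex, by, sey, eaf_x, eaf_y = [], [], [], [], [], [], []
    dropped: list[tuple[str, str]] = []
    notes: list[str] = []

    for exp in instruments.records:
        out = out_by_id.get(exp.snp_id)
        if out is None and panel is not None:
            prox = panel.proxy_for(exp.snp_id)
            if prox is not None and prox[0] in out_by_id:
                out = out_by_id[prox[0]]
                notes.append(f"{exp.snp_id}: proxied by {prox[0]} (r2={prox[1]:.2f})")
        if out is None:
            dropped.append((exp.snp_id, "missing_in_outcome"))
            continue

        orient = align_alleles(exp.effect_allele, exp.other_allele,
                               out.effect_allele, out.other_allele)
        if orient is None:
            dropped.append((exp.snp_id, "allele_mismatch"))
            continue

        if exp.is_palindromic():
            if palindrome_policy == "drop_all":
                dropped.append((exp.snp_id, "palindromic_ambiguous"))
                continue
            ex_eaf, out_eaf = exp.eaf, out.eaf
            ambiguous = (
                ex_eaf is None or out_eaf is None
                or lo <= ex_eaf <= hi or lo <= out_eaf <= hi
            )
            if ambiguous:
                dropped.append((exp.snp_id, "palindromic_ambiguous"))
                continue
            # infer orientation by frequency agreement
            orient = "same" if (ex_eaf < 0.5) == (out_eaf < 0.5) else "swap"

        b_out = out.beta
        f_out = out.eaf
        if orient == "swap":
            b_out = -b_out
            if f_out is not None:
                f_out = 1.0 - f_out

        snp_ids.append(exp.snp_id)
        bx.append(exp.beta)
        sex.append(exp.se)
        by.append(b_out)
        sey.append(out.se)
        eaf_x.append(exp.eaf if exp.eaf is not None else np.nan)
        eaf_y.append(f_out if f_out is not None else np.nan)

    if not snp_ids:
        raise HarmonizationEmptyError(
            f"no SNP survived harmonization of {instruments.exposure_name!r} "
            f"against {outcome.trait_name!r}"
        )

    case_frac = None
    cases = [r for r in outcome.records if r.n_case is not None and r.n_control is not None]
    if cases:
        case_frac = float(np.median([r.n_case / r.n for r in cases]))

    return HarmonizedSet(
        exposure_name=instruments.exposure_name,
        outcome_name=outcome.trait_name,
        snp_ids=snp_ids,
        bx=np.array(bx), sex=np.array(sex),
        by=np.array(by), sey=np.array(sey),
        eaf_x=np.array(eaf_x), eaf_y=np.array(eaf_y),
        dropped=dropped,
        exposure_type=instruments.trait_type,
        outcome_type=outcome.trait_type,
        n_exposure=float(np.median([r.n for r in instruments.records])),
        n_outcome=float(outcome.median_n()) if len(outcome) else None,
        outcome_case_fraction=case_frac,
        notes=notes,
    )


def filter_snps(h: HarmonizedSet, exclude: Sequence[str], reason: str) -> HarmonizedSet:
    """Remove the listed SNPs, appending them to ``dropped`` with ``reason``."""
    exclude_set = set(exclude)
    mask = np.array([s not in exclude_set for s in h.snp_ids])
    if not mask.any():
        raise HarmonizationEmptyError(
            f"excluding {len(exclude_set)} SNPs ({reason}) empties the set"
        )
    out = h.subset(mask)
    out.dropped.extend((s, reason) for s in h.snp_ids if s in exclude_set)
    return out
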