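"""Orchestration of a full bidirectional two-sample MR study.

For every exposure-outcome pair and requested direction the pipeline runs
instrument selection, LD clumping, the weak-instrument filter,
harmonization, the four-estimator suite, heterogeneity diagnostics
(Cochran/Rucker/Egger intercept/MR-PRESSO), the Steiger directionality
test and the family-wise multiple-testing flag, emitting one
:class:`AnalysisResult` per pair.  Partial failures (too few instruments
after harmonization, say) populate the result's notes instead of aborting
the run; re-running with the same config and seed reproduces every number.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from . import io_summary
from .direction_power import SteigerResult, bonferroni_threshold, steiger_test
from .estimators import MREstimate, estimate_all
from .exceptions import (
    CausalMRError,
    ConfigurationError,
    EmptyInstrumentError,
    HarmonizationEmptyError,
    InsufficientInstrumentsError,
)
from .instruments import (
    HarmonizedSet,
    LDPanel,
    apply_f_filter,
    filter_snps,
    harmonize,
    ld_clump,
    select_instruments,
)
from .io_summary import AssociationTable, StudyConfig
from .sensitivity import HeterogeneityReport, heterogeneity_report

log = logging.getLogger("causalmr")


@dataclass
class AnalysisResult:
    """Everything the study reports for one exposure-outcome-direction."""

    exposure: str
    outcome: str
    direction: str  # forward | reverse
    estimates: list[MREstimate] = field(default_factory=list)
    heterogeneity: Optional[HeterogeneityReport] = None
    steiger: Optional[SteigerResult] = None
    nsnp: int = 0
    n_clumped: int = 0
    passes_bonferroni: bool = False
    notes: list[str] = field(default_factory=list)
    harmonized: Optional[HarmonizedSet] = None
    variant_label: str = "baseline"

    @property
    def ivw(self) -> Optional[MREstimate]:
        for e in self.estimates:
            if e.method in ("ivw", "wald") and e.ok:
                return e
        return None


def _load_tables(config: StudyConfig, base_dir: Path):
    tables: dict[str, AssociationTable] = {}
    for name, path, trait_type in list(config.exposures) + list(config.outcomes):
        if name in tables:
            continue
        p = Path(path)
        if not p.is_absolute():
            p = base_dir / p
        if not p.exists():
            raise ConfigurationError(f"input file for {name!r} not found: {p}")
        tables[name] = io_summary.read_gwas_summary(
            p, trait_type=trait_type, trait_name=name
        )
    return tables


def resolve_n_tests(config: StudyConfig) -> int:
    """Number of tests the family-wise threshold divides by.

    ``auto`` counts exposure-outcome pairs times requested directions.
    A bidirectional convention that nonetheless divides by the one-way
    count is a legitimate (if conservative-sounding) choice some studies
    make; we surface the doubling rather than resolving it silently.
    """
    if config.n_tests == "auto":
        n_dir = 2 if config.directions == "both" else 1
        n = len(config.exposures) * len(config.outcomes) * n_dir
        if n_dir == 2:
            log.warning(
                "n_tests=auto with both directions counts %d tests; studies "
                "sometimes divide by the one-way count instead — set n_tests "
                "explicitly to override", n,
            )
        return n
    return int(config.n_tests)


def analyze_pair(
    exposure_table: AssociationTable,
    outcome_table: AssociationTable,
    config: StudyConfig,
    direction: str,
    panel: Optional[LDPanel] = None,
    exclude: Optional[Sequence[str]] = None,
    alpha_corrected: Optional[float] = None,
    seed: int = 0,
) -> AnalysisResult:
    """Run the full per-pair analysis chain; failures populate notes."""
    result = AnalysisResult(
        exposure=exposure_table.trait_name,
        outcome=outcome_table.trait_name,
        direction=direction,
    )
    alpha = alpha_corrected if alpha_corrected is not None else config.alpha_family
    try:
        inst = select_instruments(exposure_table, config.p_instrument, min_f=None)
        if panel is not None:
            inst = ld_clump(inst, panel, config.clump_r2, config.clump_window_kb)
        else:
            result.notes.append("no LD panel supplied: clumping skipped")
        inst = apply_f_filter(inst, 10.0)
        result.n_clumped = len(inst)

        h = harmonize(inst, outcome_table,
                      palindrome_policy=config.palindrome_policy)
        if exclude:
            h = filter_snps(h, exclude, "user_exclusion")
        result.harmonized = h
        result.nsnp = h.nsnp
        for snp, reason in h.dropped:
            result.notes.append(f"dropped {snp}: {reason}")

        result.estimates = estimate_all(
            h, re_model=config.re_model, n_boot=config.n_boot, seed=seed,
        )
        ivw_est = result.ivw
        if ivw_est is not None and h.nsnp >= 2:
            egger_est = next((e for e in result.estimates if e.method == "egger" and e.ok), None)
            result.heterogeneity = heterogeneity_report(
                h, ivw_est, egger_est,
                presso_sims=config.presso_sims, seed=seed + 1,
            )
        try:
            if h.n_exposure and h.n_outcome:
                result.steiger = steiger_test(h, n_x=h.n_exposure, n_y=h.n_outcome)
        except ConfigurationError as exc:
            result.notes.append(f"steiger skipped: {exc}")

        if ivw_est is not None:
            result.passes_bonferroni = bool(ivw_est.pval < alpha)
    except (EmptyInstrumentError, HarmonizationEmptyError,
            InsufficientInstrumentsError, CausalMRError) as exc:
        result.notes.append(f"analysis incomplete: {exc}")
    return result


def run_study(
    config: StudyConfig,
    panels: Optional[Mapping[str, LDPanel]] = None,
    exclusions: Optional[Mapping[str, Sequence[str]]] = None,
    groupings: Optional[Mapping[str, Mapping[str, str]]] = None,
    base_dir=".",
) -> list[AnalysisResult]:
    """Execute every exposure x outcome x direction analysis of a study.

    ``panels`` maps exposure trait name to its LD panel; ``exclusions``
    maps "exposure|outcome" (or a trait name, applying to all its pairs)
    to SNP lists.  Deterministic given ``config.seed``.
    """
    base_dir = Path(base_dir)
    tables = _load_tables(config, base_dir)
    panels = panels or {}
    exclusions = exclusions or {}
    n_tests = resolve_n_tests(config)
    alpha_corr = bonferroni_threshold(n_tests, config.alpha_family)

    directions = {"forward": ["forward"], "reverse": ["reverse"],
                  "both": ["forward", "reverse"]}[config.directions]

    results: list[AnalysisResult] = []
    pair_index = 0
    for exp_name, _, _ in config.exposures:
        for out_name, _, _ in config.outcomes:
            for direction in directions:
                if direction == "forward":
                    e_tab, o_tab = tables[exp_name], tables[out_name]
                else:
                    e_tab, o_tab = tables[out_name], tables[exp_name]
                excl = list(exclusions.get(f"{e_tab.trait_name}|{o_tab.trait_name}", [])) \
                    + list(exclusions.get(e_tab.trait_name, []))
                res = analyze_pair(
                    e_tab, o_tab, config, direction,
                    panel=panels.get(e_tab.trait_name),
                    exclude=excl or None,
                    alpha_corrected=alpha_corr,
                    seed=config.seed + pair_index,
                )
                results.append(res)
                pair_index += 1
    return results


def sensitivity_rerun(
    baseline: Sequence[AnalysisResult],
    variant: str,
    payload: Mapping,
    config: StudyConfig,
    tables: Optional[Mapping[str, AssociationTable]] = None,
    panels: Optional[Mapping[str, LDPanel]] = None,
    base_dir=".",
) -> list[AnalysisResult]:
    """Re-execute only affected pairs under one sensitivity variant.

    - ``exclude_list``: payload maps exposure (or "exposure|outcome") to
      SNPs to drop before re-estimation.
    - ``leave_group``: payload maps "exposure|outcome" to a snp->label
      grouping; each label's members are removed in turn (re-estimation
      handled by :func:`causalmr.sensitivity.leave_out` downstream).
    - ``alternate_outcome``: payload maps outcome name to an alternate
      summary file; the lineage note records both dataset names.
    """
    if variant not in ("exclude_list", "leave_group", "alternate_outcome"):
        raise ConfigurationError(f"unknown sensitivity variant {variant!r}")
    base_dir = Path(base_dir)
    tables = dict(tables) if tables else _load_tables(config, base_dir)
    panels = panels or {}
    n_tests = resolve_n_tests(config)
    alpha_corr = bonferroni_threshold(n_tests, config.alpha_family)

    known = {f"{r.exposure}|{r.outcome}" for r in baseline}
    for key in payload:
        if variant != "alternate_outcome" and "|" in key and key not in known:
            raise ConfigurationError(f"payload references unknown pair {key!r}")

    out: list[AnalysisResult] = []
    for idx, res in enumerate(baseline):
        key = f"{res.exposure}|{res.outcome}"
        affected = key in payload or res.exposure in payload or res.outcome in payload
        if not affected:
            continue
        e_tab = tables[res.exposure]
        o_tab = tables[res.outcome]
        note = None
        exclude = None
        if variant == "exclude_list":
            exclude = list(payload.get(key, payload.get(res.exposure, [])))
        elif variant == "alternate_outcome":
            alt_path = payload[res.outcome]
            alt = io_summary.read_gwas_summary(
                Path(base_dir) / alt_path, trait_type=o_tab.trait_type,
                trait_name=o_tab.trait_name,
            )
            note = f"alternate outcome dataset: {o_tab.trait_name} -> {alt_path}"
            o_tab = alt
        elif variant == "leave_group":
            grouping = payload[key]
            exclude = [s for s in grouping]  # remove all grouped SNPs at once
            note = f"leave-group-out: {sorted(set(grouping.values()))}"
        rerun = analyze_pair(
            e_tab, o_tab, config, res.direction,
            panel=panels.get(res.exposure),
            exclude=exclude, alpha_corrected=alpha_corr,
            seed=config.seed + idx,
        )
        rerun.variant_label = variant
        if note:
            rerun.notes.append(note)
        out.append(rerun)
    return out


def results_to_rows(results: Sequence[AnalysisResult]) -> list[dict]:
    """Flatten results into the TSV schema (one row per method)."""
    rows = []
    for res in results:
        het = res.heterogeneity
        st = res.steiger
        for est in res.estimates:
            if not est.ok:
                continue
            row = {
                "exposure": res.exposure, "outcome": res.outcome,
                "direction": res.direction, "method": est.method,
                "nsnp": est.nsnp, "beta": est.beta, "se": est.se,
                "ci_low": est.ci_low, "ci_high": est.ci_high, "pval": est.pval,
            }
            if est.or_scale is not None:
                row["or"], row["or_ci_low"], row["or_ci_high"] = est.or_scale
            if het is not None:
                row.update(q=het.q, q_df=het.q_df, q_pval=het.q_pval, i2=het.i2,
                           rucker_q=het.rucker_q, rucker_pval=het.rucker_pval,
                           presso_global_pval=het.presso_global_str)
                row["intercept_pval"] = het.intercept_pval
            if est.method == "egger":
                row["egger_intercept"] = est.intercept
                row["intercept_pval"] = est.intercept_pval
            if st is not None:
                row["steiger_dir"] = st.direction_ok
                row["steiger_pval"] = st.pval
            row["passes_bonferroni"] = res.passes_bonferroni
            rows.append(row)
        if not res.estimates:
            rows.append({
                "exposure": res.exposure, "outcome": res.outcome,
                "direction": res.direction, "method": "none", "nsnp": res.nsnp,
            })
    return rows
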