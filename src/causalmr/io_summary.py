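"""Reading and writing GWAS summary-statistic tables and study configuration.

Every downstream stage consumes the :class:`VariantAssociation` /
:class:`AssociationTable` data model defined here.  Input files are headered
delimited text (TSV by default; delimiter auto-detected among tab, comma and
runs of spaces).  Alleles are uppercased on read; no strand logic is applied
at read time — allele reconciliation belongs to harmonization.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml

from .exceptions import ConfigurationError, EmptyTableError

log = logging.getLogger("causalmr")

VALID_ALLELES = frozenset("ACGT")

#: Smallest positive normal double; p-values of exactly 0 are clamped here.
SMALLEST_P = sys.float_info.min

#: Default header names for summary-statistic files written by this package.
DEFAULT_COLUMN_MAP = {
    "snp_id": "SNP",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pval": "P",
    "n": "N",
    "chrom": "CHR",
    "pos": "POS",
    "n_case": "N_CASE",
    "n_control": "N_CONTROL",
}

MANDATORY_FIELDS = ("snp_id", "effect_allele", "other_allele", "beta", "se", "pval", "n")

#: Column order of the results table (one row per exposure/outcome/method).
RESULT_COLUMNS = [
    "exposure", "outcome", "direction", "method", "nsnp",
    "beta", "se", "ci_low", "ci_high", "pval",
    "or", "or_ci_low", "or_ci_high",
    "q", "q_df", "q_pval", "i2",
    "egger_intercept", "intercept_pval",
    "rucker_q", "rucker_pval", "presso_global_pval",
    "steiger_dir", "steiger_pval", "passes_bonferroni",
]


@dataclass
class VariantAssociation:
    """One variant's summary association with one trait.

    ``beta`` is in SD units for continuous traits and log-odds for binary
    traits.  ``eaf`` may be absent; operations that need it (palindrome
    resolution, variance explained) must fail loudly rather than impute.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    n: float
    eaf: Optional[float] = None
    chrom: Optional[str] = None
    pos: Optional[int] = None
    n_case: Optional[int] = None
    n_control: Optional[int] = None

    def invalid_reason(self) -> Optional[str]:
        """Return a short reason string if any invariant fails, else None."""
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            return "invalid_allele"
        if self.effect_allele == self.other_allele:
            return "identical_alleles"
        if not (self.se > 0):
            return "nonpositive_se"
        if not (0 < self.pval <= 1):
            return "pval_out_of_range"
        if self.eaf is not None and not (0 < self.eaf < 1):
            return "eaf_out_of_range"
        if not (self.n > 0):
            return "nonpositive_n"
        if self.n_case is not None and self.n_control is not None:
            if self.n_case < 0 or self.n_control < 0:
                return "negative_counts"
            if self.n_case + self.n_control != int(round(self.n)):
                return "case_control_sum_mismatch"
        return None

    def is_palindromic(self) -> bool:
        pair = {self.effect_allele, self.other_allele}
        return pair == {"A", "T"} or pair == {"C", "G"}


@dataclass
class AssociationTable:
    """An ordered collection of variant associations for one trait."""

    trait_name: str
    trait_type: str  # "continuous" | "binary"
    records: list[VariantAssociation] = field(default_factory=list)
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ConfigurationError(
                f"trait_type must be 'continuous' or 'binary', got {self.trait_type!r}"
            )
        ids = [r.snp_id for r in self.records]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ConfigurationError(f"duplicate snp_id in table {self.trait_name!r}: {dup}")

    def __len__(self) -> int:
        return len(self.records)

    def by_id(self) -> dict[str, VariantAssociation]:
        return {r.snp_id: r for r in self.records}

    def median_n(self) -> float:
        import statistics

        return statistics.median(r.n for r in self.records)

    def to_frame(self, column_map: Mapping[str, str] = DEFAULT_COLUMN_MAP) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {}
            for fld, col in column_map.items():
                val = getattr(r, fld, None)
                if val is not None:
                    row[col] = val
            rows.append(row)
        return pd.DataFrame(rows)


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    return r"\s+"


def read_gwas_summary(
    path,
    column_map: Optional[Mapping[str, str]] = None,
    trait_type: str = "continuous",
    trait_name: Optional[str] = None,
    delimiter: Optional[str] = None,
) -> AssociationTable:
    """Parse a headered delimited summary-statistic file.

    Rows violating the type invariants (bad alleles, se<=0, p outside (0,1],
    indels, inconsistent case/control counts) are dropped with a logged
    count; row order is preserved.  A p-value of exactly 0 (an underflowed
    export) is clamped to the smallest positive normal float with a warning.
    """
    path = Path(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    sep = delimiter if delimiter is not None else _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, engine="python" if sep == r"\s+" else "c",
                     dtype={cmap["snp_id"]: str})
    if df.empty:
        raise EmptyTableError(f"{path} contains a header but no data rows")

    for fld in MANDATORY_FIELDS:
        if cmap[fld] not in df.columns:
            raise ConfigurationError(
                f"mandatory column {cmap[fld]!r} (field {fld!r}) missing from {path}"
            )

    def _opt(row, fld, cast):
        col = cmap.get(fld)
        if col is None or col not in df.columns:
            return None
        val = row[col]
        if pd.isna(val):
            return None
        return cast(val)

    records: list[VariantAssociation] = []
    n_dropped = 0
    n_clamped = 0
    for _, row in df.iterrows():
        pval = float(row[cmap["pval"]])
        if pval == 0.0:
            pval = SMALLEST_P
            n_clamped += 1
        rec = VariantAssociation(
            snp_id=str(row[cmap["snp_id"]]),
            effect_allele=str(row[cmap["effect_allele"]]).upper(),
            other_allele=str(row[cmap["other_allele"]]).upper(),
            beta=float(row[cmap["beta"]]),
            se=float(row[cmap["se"]]),
            pval=pval,
            n=float(row[cmap["n"]]),
            eaf=_opt(row, "eaf", float),
            chrom=_opt(row, "chrom", lambda v: str(v)),
            pos=_opt(row, "pos", lambda v: int(v)),
            n_case=_opt(row, "n_case", lambda v: int(v)),
            n_control=_opt(row, "n_control", lambda v: int(v)),
        )
        reason = rec.invalid_reason()
        if reason is not None:
            n_dropped += 1
            log.debug("dropping %s from %s: %s", rec.snp_id, path.name, reason)
            continue
        records.append(rec)

    if n_clamped:
        log.warning("%s: clamped %d zero p-values to %.3e", path.name, n_clamped, SMALLEST_P)
    if n_dropped:
        log.info("%s: dropped %d invalid rows (%d survive)", path.name, n_dropped, len(records))

    return AssociationTable(
        trait_name=trait_name or path.stem,
        trait_type=trait_type,
        records=records,
        n_dropped=n_dropped,
    )


def write_gwas_summary(table: AssociationTable, path,
                       column_map: Mapping[str, str] = DEFAULT_COLUMN_MAP) -> None:
    """Write a table in the TSV dialect ``read_gwas_summary`` reads back."""
    df = table.to_frame(column_map)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_results_table(rows: Sequence[Mapping], path) -> None:
    """Write analysis result records as TSV with a deterministic column order.

    Zero rows yield a header-only file.  Unknown keys are ignored; missing
    keys become empty fields.
    """
    df = pd.DataFrame(list(rows), columns=RESULT_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


@dataclass
class StudyConfig:
    """Declarative description of a multi-pair two-sample MR study."""

    exposures: list[tuple[str, str, str]]  # (trait_name, file, trait_type)
    outcomes: list[tuple[str, str, str]]
    directions: str = "forward"  # forward | reverse | both
    p_instrument: float = 5e-8
    clump_window_kb: int = 10_000
    clump_r2: float = 0.001
    alpha_family: float = 0.05
    n_tests: object = "auto"  # int or "auto"
    palindrome_policy: str = "drop_ambiguous"
    re_model: str = "multiplicative_floored"
    n_boot: int = 1000
    presso_sims: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.p_instrument < 1):
            raise ConfigurationError("p_instrument must be in (0,1)")
        if not (0 < self.clump_r2 < 1):
            raise ConfigurationError("clump_r2 must be in (0,1)")
        if not (0 < self.alpha_family < 1):
            raise ConfigurationError("alpha_family must be in (0,1)")
        if self.directions not in ("forward", "reverse", "both"):
            raise ConfigurationError(f"unknown directions {self.directions!r}")
        self.exposures = [tuple(e) for e in self.exposures]
        self.outcomes = [tuple(o) for o in self.outcomes]


def read_study_config(path) -> StudyConfig:
    """Load a YAML study configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: expected a mapping at top level")
    try:
        return StudyConfig(**raw)
    except TypeError as exc:
        raise ConfigurationError(f"{path}: {exc}") from exc


def write_study_config(config: StudyConfig, path) -> None:
    data = {
        "exposures": [list(e) for e in config.exposures],
        "outcomes": [list(o) for o in config.outcomes],
        "directions": config.directions,
        "p_instrument": config.p_instrument,
        "clump_window_kb": config.clump_window_kb,
        "clump_r2": config.clump_r2,
        "alpha_family": config.alpha_family,
        "n_tests": config.n_tests,
        "palindrome_policy": config.palindrome_policy,
        "re_model": config.re_model,
        "n_boot": config.n_boot,
        "presso_sims": config.presso_sims,
        "seed": config.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
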