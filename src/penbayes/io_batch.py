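"""Variant tables: strict readers, batch estimation, cross-study aggregation, writers.

The batch format is delimited text (comma or tab, autodetected from the file
extension) with required columns ``variant_id, study, carriers_cases,
total_cases, carriers_controls, total_controls`` and an optional per-row
``baseline_risk`` that overrides any global baseline. Parsing is strict:
every malformed row raises an error naming its line number; counts must be
integers and carriers may not exceed totals.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, TextIO, Union

import pandas as pd

from .core import (
    BaselineRisk,
    CaseControlCounts,
    IntervalConfig,
    PenetranceEstimate,
    estimate_penetrance,
)
from .errors import InputDomainError, TableParseError, UndefinedEstimateError

__all__ = [
    "VariantRecord",
    "VariantResult",
    "AggregateSummary",
    "read_variant_table",
    "run_batch",
    "aggregate_by_variant",
    "write_results",
]

REQUIRED_COLUMNS = (
    "variant_id",
    "study",
    "carriers_cases",
    "total_cases",
    "carriers_controls",
    "total_controls",
)

Source = Union[str, Path, TextIO]


@dataclass(frozen=True)
class VariantRecord:
    """One input row: a variant's counts in one study, with its baseline risk."""

    variant_id: str
    study_label: str
    counts: CaseControlCounts
    baseline: BaselineRisk

    def __post_init__(self) -> None:
        if not self.variant_id:
            raise InputDomainError("variant_id must be non-empty")


@dataclass(frozen=True)
class VariantResult:
    """One output row; ``error`` is set (and ``estimate`` None) for flagged rows."""

    variant_id: str
    study_label: str
    estimate: PenetranceEstimate | None
    error: str | None = None

    @property
    def flagged(self) -> bool:
        return self.error is not None


@dataclass(frozen=True)
class AggregateSummary:
    """Per-variant spread of median penetrance across studies."""

    variant_id: str
    n_studies: int
    mean_median: float
    min_median: float
    max_median: float

    def __post_init__(self) -> None:
        if self.n_studies < 1:
            raise InputDomainError("n_studies must be at least 1")
        if not (self.min_median <= self.mean_median <= self.max_median):
            raise InputDomainError("aggregate mean must lie within [min, max]")


def _separator_for(source: Source) -> str:
    name = source if isinstance(source, (str, Path)) else getattr(source, "name", "")
    return "\t" if str(name).lower().endswith((".tsv", ".tab")) else ","


def _parse_count(row: pd.Series, column: str, line: int) -> int:
    value = row[column]
    if pd.isna(value):
        raise TableParseError(f"missing value in column {column!r}", line=line)
    fval = float(value)
    if not fval.is_integer():
        raise TableParseError(f"column {column!r} must be an integer, got {value!r}", line=line)
    return int(fval)


def read_variant_table(
    source: Source,
    global_baseline: BaselineRisk | None = None,
) -> list[VariantRecord]:
    """Parse a delimited variant table into records, preserving row order.

    A per-row ``baseline_risk`` value overrides ``global_baseline``; a row with
    neither is a parse error. All validation failures name the 1-based line
    number of the offending row (the header is line 1).
    """
    sep = _separator_for(source)
    try:
        df = pd.read_csv(source, sep=sep, dtype={"variant_id": str, "study": str})
    except pd.errors.EmptyDataError as exc:
        raise TableParseError("input table is empty (no header row)") from exc

    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise TableParseError(f"missing required columns: {sorted(missing)}")
    has_baseline_col = "baseline_risk" in df.columns

    records: list[VariantRecord] = []
    for idx, row in df.iterrows():
        line = int(idx) + 2
        variant_id = row["variant_id"]
        if pd.isna(variant_id) or not str(variant_id):
            raise TableParseError("variant_id must be non-empty", line=line)
        study = "" if pd.isna(row["study"]) else str(row["study"])

        try:
            counts = CaseControlCounts(
                carriers_cases=_parse_count(row, "carriers_cases", line),
                total_cases=_parse_count(row, "total_cases", line),
                carriers_controls=_parse_count(row, "carriers_controls", line),
                total_controls=_parse_count(row, "total_controls", line),
            )
        except TableParseError:
            raise
        except InputDomainError as exc:
            raise TableParseError(str(exc), line=line) from exc

        baseline = global_baseline
        if has_baseline_col and not pd.isna(row["baseline_risk"]):
            try:
                baseline = BaselineRisk(float(row["baseline_risk"]))
            except InputDomainError as exc:
                raise TableParseError(str(exc), line=line) from exc
        if baseline is None:
            raise TableParseError(
                "no baseline risk: provide a baseline_risk column or a global value",
                line=line,
            )
        records.append(
            VariantRecord(
                variant_id=str(variant_id), study_label=study, counts=counts, baseline=baseline
            )
        )
    return records


def run_batch(
    records: Sequence[VariantRecord],
    cfg: IntervalConfig = IntervalConfig(),
) -> list[VariantResult]:
    """Estimate penetrance for every record, in order.

    A record whose estimate is undefined (no carriers in either arm) yields a
    flagged result instead of aborting the batch.
    """
    results: list[VariantResult] = []
    for rec in records:
        try:
            est = estimate_penetrance(rec.counts, rec.baseline, cfg)
            results.append(VariantResult(rec.variant_id, rec.study_label, est))
        except (UndefinedEstimateError, InputDomainError) as exc:
            results.append(VariantResult(rec.variant_id, rec.study_label, None, error=str(exc)))
    return results


def aggregate_by_variant(
    results: Sequence[VariantResult],
    weights: Sequence[float] | None = None,
) -> list[AggregateSummary]:
    """Summarise median penetrance per variant across studies.

    Returns the unweighted mean (default; pass per-result ``weights`` such as
    sample sizes for a weighted mean), minimum and maximum of the study
    medians for each variant, sorted by variant id. Flagged results are
    skipped; a variant with only flagged results is omitted.
    """
    if weights is not None and len(weights) != len(results):
        raise InputDomainError("weights must match results in length")
    by_variant: dict[str, list[tuple[float, float]]] = {}
    for i, res in enumerate(results):
        if res.flagged or res.estimate is None:
            continue
        w = 1.0 if weights is None else float(weights[i])
        by_variant.setdefault(res.variant_id, []).append((res.estimate.median, w))

    summaries = []
    for variant_id in sorted(by_variant):
        medians = [m for m, _ in by_variant[variant_id]]
        wsum = sum(w for _, w in by_variant[variant_id])
        mean = sum(m * w for m, w in by_variant[variant_id]) / wsum
        summaries.append(
            AggregateSummary(
                variant_id=variant_id,
                n_studies=len(medians),
                mean_median=mean,
                min_median=min(medians),
                max_median=max(medians),
            )
        )
    return summaries


def _round_display(value: float | None, decimals: int) -> float | None:
    return None if value is None else round(value, decimals)


def write_results(
    items: Sequence[VariantResult] | Sequence[AggregateSummary],
    sink: Source,
    display_rounding: bool = False,
) -> None:
    """Write results or aggregate summaries as delimited text.

    With ``display_rounding`` medians are rounded to 3 decimals and interval
    bounds to 2 (the convention of the published comparison tables); without
    it full precision is kept so the file round-trips losslessly.
    """
    sep = _separator_for(sink)
    if items and isinstance(items[0], AggregateSummary):
        rows = [
            {
                "variant_id": s.variant_id,
                "n_studies": s.n_studies,
                "mean_median": _round_display(s.mean_median, 3) if display_rounding else s.mean_median,
                "min_median": _round_display(s.min_median, 3) if display_rounding else s.min_median,
                "max_median": _round_display(s.max_median, 3) if display_rounding else s.max_median,
            }
            for s in items
        ]
        columns = ["variant_id", "n_studies", "mean_median", "min_median", "max_median"]
    else:
        rows = []
        for r in items:
            est = r.estimate
            rows.append(
                {
                    "variant_id": r.variant_id,
                    "study": r.study_label,
                    "median": _round_display(est.median, 3) if display_rounding and est else (est.median if est else None),
                    "ci_lower": _round_display(est.ci_lower, 2) if display_rounding and est else (est.ci_lower if est else None),
                    "ci_upper": _round_display(est.ci_upper, 2) if display_rounding and est else (est.ci_upper if est else None),
                    "error": r.error,
                }
            )
        columns = ["variant_id", "study", "median", "ci_lower", "ci_upper", "error"]
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(sink, sep=sep, index=False)
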