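"""Tool-availability and reporting-completeness metrics.

At the facility level, a *tool-month* is one (facility, tool, service area,
month) cell: the register, tally sheet, or monthly report form that should
exist for that service area and month.  The availability rate is the
percentage of expected tool-months the review team could actually locate.
At the district level the same construction over the district's copies of
facility reports measures *reporting completeness*.

Rates are computed per facility first and then summarised across facilities
within a stratum as median / p25 / p75 / range (p75 − p25), and banded into
four availability categories.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from hmisdq.months import expected_months, year_of  # noqa: F401  (re-exported)

logger = logging.getLogger(__name__)

#: facility-held tools and the count source that evidences each of them
TOOL_SOURCE = {
    "register": "register",
    "tally_sheet": "tally",
    "report_form": "facility_report",
}
TOOLS = tuple(TOOL_SOURCE)

_CELL_KEYS = ["facility_id", "district", "level", "ownership", "setting", "service_area", "month"]


class AvailabilityCategory(str, Enum):
    """Four bands partitioning [0, 100]: low [0,25), average [25,50),
    high [50,75], very_high (75,100]."""

    very_high = "very_high"
    high = "high"
    average = "average"
    low = "low"


@dataclass(frozen=True)
class AvailabilityRecord:
    """Observed vs expected tool-months for one unit within one stratum."""

    unit: str
    tool: str
    stratum: dict
    observed_months: int
    expected_months: int

    @property
    def rate(self) -> float:
        return availability_rate(self.observed_months, self.expected_months)


@dataclass(frozen=True)
class DistributionSummary:
    """Median / quartile summary of a set of percentage rates."""

    median: float
    p25: float
    p75: float
    range: float
    n: int


def availability_rate(observed: int, expected: int) -> float:
    """Percentage of expected tool-months actually located."""
    if expected <= 0:
        raise ValueError("expected must be > 0")
    if not 0 <= observed <= expected:
        raise ValueError(f"observed must lie in [0, {expected}], got {observed}")
    return 100.0 * observed / expected


def district_report_completeness(received: int, expected: int) -> float:
    """Percentage of expected facility reports found at the district office."""
    return availability_rate(received, expected)


def categorize_availability(rate: float) -> AvailabilityCategory:
    """Band a rate into the four availability categories.

    Boundary convention: 25 and 50 open the band above them, 75 stays in
    ``high`` because ``very_high`` starts strictly above 75.
    """
    if not 0.0 <= rate <= 100.0:
        raise ValueError(f"rate must lie in [0, 100], got {rate}")
    if rate < 25.0:
        return AvailabilityCategory.low
    if rate < 50.0:
        return AvailabilityCategory.average
    if rate <= 75.0:
        return AvailabilityCategory.high
    return AvailabilityCategory.very_high


def summarize_distribution(values: Iterable[float], method: str = "linear") -> DistributionSummary:
    """Median, quartiles and range (p75 − p25) of a collection of rates.

    ``method`` is the quantile interpolation convention, passed through to
    :func:`numpy.percentile` (default: linear interpolation between closest
    order statistics).
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarise an empty collection")
    p25, med, p75 = np.percentile(arr, [25.0, 50.0, 75.0], method=method)
    return DistributionSummary(
        median=float(med), p25=float(p25), p75=float(p75), range=float(p75 - p25), n=int(arr.size)
    )


# ---------------------------------------------------------------------------
# table builders


def _with_year(df: pd.DataFrame) -> pd.DataFrame:
    if "year" not in df.columns:
        df = df.copy()
        df["year"] = df["month"].str.slice(0, 4)
    return df


def tool_cells(counts: pd.DataFrame) -> pd.DataFrame:
    """Collapse wide counts to one row per (facility, service area, month)
    with a boolean observed flag per tool.  A tool-month counts as observed
    when at least one indicator row for it is present."""
    agg = {f"{src}_present": "any" for src in TOOL_SOURCE.values()}
    agg["district_report_present"] = "any"
    cells = counts.groupby(_CELL_KEYS, sort=True, as_index=False).agg(agg)
    return cells


def _facility_rates(
    cells: pd.DataFrame, tool_col: str, by: Sequence[str]
) -> pd.DataFrame:
    keys = ["facility_id"] + [c for c in by if c != "facility_id"]
    grouped = cells.groupby(keys, sort=True, as_index=False).agg(
        observed=(tool_col, "sum"), expected=(tool_col, "size")
    )
    zero = grouped["expected"] == 0
    if zero.any():
        logger.warning("%d unit(s) with zero expected tool-months excluded", int(zero.sum()))
        grouped = grouped[~zero]
    grouped["rate"] = 100.0 * grouped["observed"] / grouped["expected"]
    grouped["category"] = [categorize_availability(r).value for r in grouped["rate"]]
    return grouped


def availability_table(
    counts: pd.DataFrame,
    by: Sequence[str] = (),
    method: str = "linear",
    include_overall_tool: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Facility-level availability rates and their stratum summaries.

    Returns ``(records, summary)``: per-facility rates (with category), and
    one median/p25/p75/range row per (tool × stratum).  ``by`` may contain
    ``year, service_area, level, ownership, district, setting``.  The
    pseudo-tool ``overall`` pools the three tools' cells.
    """
    cells = _with_year(tool_cells(counts))
    unknown = set(by) - set(cells.columns)
    if unknown:
        raise ValueError(f"unknown grouping attributes {sorted(unknown)}")
    rec_frames: list[pd.DataFrame] = []
    for tool, src in TOOL_SOURCE.items():
        rec = _facility_rates(cells, f"{src}_present", by)
        rec.insert(1, "tool", tool)
        rec_frames.append(rec)
    if include_overall_tool:
        stacked = pd.concat(
            [
                cells[_CELL_KEYS + ["year"]].assign(observed_flag=cells[f"{src}_present"])
                for src in TOOL_SOURCE.values()
            ],
            ignore_index=True,
        )
        rec = _facility_rates(stacked, "observed_flag", by)
        rec.insert(1, "tool", "overall")
        rec_frames.append(rec)
    records = pd.concat(rec_frames, ignore_index=True)

    summary = summarize_rates(records, by, method=method)
    return records, summary


def summarize_rates(records: pd.DataFrame, by: Sequence[str], method: str = "linear") -> pd.DataFrame:
    """Median/p25/p75/range summary rows per (tool × stratum) from
    per-facility rate records."""
    keys = ["tool"] + list(by)
    rows = []
    for key_vals, grp in records.groupby(keys, sort=True):
        if not isinstance(key_vals, tuple):
            key_vals = (key_vals,)
        s = summarize_distribution(grp["rate"], method=method)
        rows.append(
            dict(zip(keys, key_vals))
            | {"n": s.n, "median": s.median, "p25": s.p25, "p75": s.p75, "range": s.range}
        )
    return pd.DataFrame(rows, columns=keys + ["n", "median", "p25", "p75", "range"])


def district_reporting_table(
    counts: pd.DataFrame,
    by: Sequence[str] = ("district",),
    method: str = "linear",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reporting completeness at the district office: per-facility rates of
    locatable district report copies, summarised per stratum."""
    cells = _with_year(tool_cells(counts))
    unknown = set(by) - set(cells.columns)
    if unknown:
        raise ValueError(f"unknown grouping attributes {sorted(unknown)}")
    records = _facility_rates(cells, "district_report_present", by)
    records.insert(1, "tool", "district_report")
    summary = summarize_rates(records, by, method=method)
    return records, summary
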