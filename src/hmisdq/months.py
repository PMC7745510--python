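"""Calendar-month helpers.

Months are plain ``YYYY-MM`` strings everywhere in the package; ranges are
inclusive on both endpoints.
"""

from __future__ import annotations

import re

import pandas as pd

_MONTH_RE = re.compile(r"^\d{4}-(0[1-9]|1[0-2])$")


def parse_month(month: str) -> pd.Period:
    """Validate and convert a ``YYYY-MM`` string to a monthly Period."""
    if not isinstance(month, str) or not _MONTH_RE.match(month):
        raise ValueError(f"not a valid YYYY-MM month: {month!r}")
    return pd.Period(month, freq="M")


def expected_months(start: str, end: str) -> int:
    """Number of calendar months in the inclusive range ``start..end``.

    ``expected_months("2014-01", "2017-09")`` is 45: a January-2014 to
    September-2017 review window spans 45 report-months.
    """
    a, b = parse_month(start), parse_month(end)
    if b < a:
        raise ValueError(f"end month {end} precedes start month {start}")
    return int(b.ordinal - a.ordinal) + 1


def month_range(start: str, end: str) -> list[str]:
    """All months of the inclusive range as sorted ``YYYY-MM`` strings."""
    a, b = parse_month(start), parse_month(end)
    if b < a:
        raise ValueError(f"end month {end} precedes start month {start}")
    return [str(p) for p in pd.period_range(a, b, freq="M")]


def next_month(month: str) -> str:
    return str(parse_month(month) + 1)


def year_of(month: str) -> str:
    """The YYYY prefix; how the 'year' stratification attribute is derived."""
    return str(parse_month(month).year)
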