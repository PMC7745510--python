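"""Difference-ratio accuracy indices across the data journey.

The accuracy of a reporting cascade is measured by six *difference ratio*
(DR) indices, each the ratio of an indicator's pooled count in a subsequent
source to its pooled count in an earlier source:

====== ===========================  ================
index  ratio                        phase
====== ===========================  ================
Diff1  tally / register             health_facility
Diff2  facility report / register   health_facility
Diff3  district copy / facility     transmission
Diff4  DHIS2 / district copy        transmission
Diff5  DHIS2 / facility report      transmission
Diff6  DHIS2 / register             robust
====== ===========================  ================

DR < 1 means fewer data in the subsequent source (under-representation),
DR > 1 over-representation, DR ≈ 1 consistency.  The *robust* phase
compares the two extreme ends of the journey — a register recount against
the DHIS2 entry — masking where along the way the distortion happened.

Pooling semantics: for each index, numerator and denominator sums run over
exactly the facility-months where **both** sources are present
(pairwise-complete pooling); absence is never imputed as zero, and the DR
is the ratio of pooled sums, not a mean of per-row ratios.  Each DR is
banded into a five-level match category from "matched" (within ±5%) to
"extremely over-represented" (DR > 2).
"""

from __future__ import annotations

import math
from collections.abc import Sequence
from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

from hmisdq.journey import KEY_COLS

#: index -> (numerator source, denominator source, phase), in journey order
INDEX_DEFS: dict[str, tuple[str, str, str]] = {
    "Diff1": ("tally", "register", "health_facility"),
    "Diff2": ("facility_report", "register", "health_facility"),
    "Diff3": ("district_report", "facility_report", "transmission"),
    "Diff4": ("dhis2", "district_report", "transmission"),
    "Diff5": ("dhis2", "facility_report", "transmission"),
    "Diff6": ("dhis2", "register", "robust"),
}
INDEX_IDS = tuple(INDEX_DEFS)

UNDEFINED_0_OVER_0 = "undefined_0_over_0"
INFINITE_OVER = "infinite_over"
NO_PAIRS = "no_pairwise_rows"


class MatchCategory(str, Enum):
    matched = "matched"
    moderately_matched = "moderately_matched"
    moderately_under = "moderately_under"
    moderately_over = "moderately_over"
    highly_under = "highly_under"
    highly_over = "highly_over"
    extremely_over = "extremely_over"


def phase_of(index_id: str) -> str:
    """The data-journey phase an index belongs to."""
    try:
        return INDEX_DEFS[index_id][2]
    except KeyError:
        raise ValueError(f"unknown difference-ratio index {index_id!r}") from None


def difference_ratio(numerator_sum: int, denominator_sum: int) -> float | str:
    """Pooled-sum difference ratio, or a flag for the degenerate cases.

    0/0 is ``undefined_0_over_0`` (there were paired rows but no events on
    either side); positive/0 is ``infinite_over`` (events reported that the
    denominator source has no trace of).
    """
    if numerator_sum < 0 or denominator_sum < 0:
        raise ValueError("pooled sums must be nonnegative")
    if denominator_sum == 0:
        return UNDEFINED_0_OVER_0 if numerator_sum == 0 else INFINITE_OVER
    return numerator_sum / denominator_sum


def categorize_dr(dr: float | str) -> MatchCategory:
    """Band a difference ratio into the five-level match category scheme.

    matched           0.95 ≤ DR ≤ 1.05 (acceptable difference ±5%)
    moderately_matched 0.75 ≤ DR < 0.95 or 1.05 < DR ≤ 1.25
    moderately_under  0.5 ≤ DR < 0.75
    moderately_over   1.25 < DR ≤ 1.5
    highly_under      DR < 0.5
    highly_over       1.5 < DR ≤ 2
    extremely_over    DR > 2 (including the infinite_over flag)

    Boundary convention: 0.5 belongs to moderately_under and 0.75 to
    moderately_matched, which closes the published half-open scheme into an
    exact partition of [0, ∞).
    """
    if dr == INFINITE_OVER:
        return MatchCategory.extremely_over
    if isinstance(dr, str):
        raise ValueError(f"cannot categorise flag {dr!r}")
    if not math.isfinite(dr) or dr < 0:
        raise ValueError(f"difference ratio must be finite and >= 0, got {dr}")
    if dr < 0.5:
        return MatchCategory.highly_under
    if dr < 0.75:
        return MatchCategory.moderately_under
    if dr < 0.95:
        return MatchCategory.moderately_matched
    if dr <= 1.05:
        return MatchCategory.matched
    if dr <= 1.25:
        return MatchCategory.moderately_matched
    if dr <= 1.5:
        return MatchCategory.moderately_over
    if dr <= 2.0:
        return MatchCategory.highly_over
    return MatchCategory.extremely_over


@dataclass(frozen=True)
class DiffRatioResult:
    """One difference-ratio index for one stratum."""

    index_id: str
    phase: str
    numerator_sum: int
    denominator_sum: int
    n_pairs: int
    dr: float | None
    flag: str | None
    category: MatchCategory | None
    stratum: dict = field(default_factory=dict)


def _index_result(sub: pd.DataFrame, index_id: str, stratum: dict) -> DiffRatioResult:
    num_src, den_src, phase = INDEX_DEFS[index_id]
    both = sub[f"{num_src}_present"] & sub[f"{den_src}_present"]
    n_pairs = int(both.sum())
    if n_pairs == 0:
        return DiffRatioResult(index_id, phase, 0, 0, 0, None, NO_PAIRS, None, stratum)
    num_sum = int(sub.loc[both, num_src].sum())
    den_sum = int(sub.loc[both, den_src].sum())
    dr = difference_ratio(num_sum, den_sum)
    if isinstance(dr, str):
        category = MatchCategory.extremely_over if dr == INFINITE_OVER else None
        return DiffRatioResult(index_id, phase, num_sum, den_sum, n_pairs, None, dr, category, stratum)
    return DiffRatioResult(
        index_id, phase, num_sum, den_sum, n_pairs, dr, None, categorize_dr(dr), stratum
    )


def compute_diff_indices(counts: pd.DataFrame, stratum: dict | None = None) -> list[DiffRatioResult]:
    """All six difference-ratio indices over a (possibly pre-filtered) wide
    count frame, with pairwise-complete pooling per index."""
    if counts.empty:
        raise ValueError("cannot compute difference ratios on an empty count set")
    return [_index_result(counts, idx, dict(stratum or {})) for idx in INDEX_IDS]


def _with_year(counts: pd.DataFrame) -> pd.DataFrame:
    if "year" not in counts.columns:
        counts = counts.copy()
        counts["year"] = counts["month"].str.slice(0, 4)
    return counts


def results_frame(results: Sequence[DiffRatioResult], by: Sequence[str] = ()) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {k: r.stratum.get(k) for k in by}
            | {
                "index_id": r.index_id,
                "phase": r.phase,
                "numerator_sum": r.numerator_sum,
                "denominator_sum": r.denominator_sum,
                "n_pairs": r.n_pairs,
                "dr": r.dr if r.dr is not None else float("nan"),
                "flag": r.flag or "",
                "category": r.category.value if r.category is not None else "",
            }
        )
    cols = list(by) + [
        "index_id", "phase", "numerator_sum", "denominator_sum", "n_pairs", "dr", "flag", "category",
    ]
    return pd.DataFrame(rows, columns=cols)


def stratified_accuracy(
    counts: pd.DataFrame,
    by: Sequence[str] = (),
    months: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Six DR rows per stratum, stratified by any of ``year, service_area,
    indicator_id, level, ownership, district, setting``.

    ``months`` optionally restricts the pooled window (e.g. to a detailed
    review subset).  Rows are ordered stratum-lexicographically, indices in
    journey order.
    """
    counts = _with_year(counts)
    allowed = set(KEY_COLS) | {"year"}
    unknown = set(by) - allowed
    if unknown:
        raise ValueError(f"unknown stratification attributes {sorted(unknown)}")
    if months is not None:
        counts = counts[counts["month"].isin(list(months))]
    if counts.empty:
        raise ValueError("no rows left after filtering")
    results: list[DiffRatioResult] = []
    if by:
        for key, sub in counts.groupby(list(by), sort=True):
            if not isinstance(key, tuple):
                key = (key,)
            results.extend(compute_diff_indices(sub, dict(zip(by, key))))
    else:
        results.extend(compute_diff_indices(counts))
    return results_frame(results, by)
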