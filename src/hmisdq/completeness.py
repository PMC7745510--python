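"""Rule-based completeness audit of row-level register records.

Registers are audited against the filling instructions printed in them:
required demographic fields (sex, age, weight, height), a diagnosis with a
severity category, the Kiswahili yes/no code ("N-Ndiyo" / "H-Hapana" — a
lone "Y" or an English-style "N-No" is a coding violation), and tick-mark
service fields.  A blank required field counts as *blank*; a non-blank
value outside the allowed codes or numeric range counts as *invalid*; a row
is *adherent* iff it has no violations at all.

Blank means the empty string after whitespace trimming.  Code comparison is
case-sensitive, deliberately: the single letter "N" means "yes" under the
Kiswahili convention and "no" under the English one, so preserving case
keeps that ambiguity visible instead of papering over it.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

KEY_COLS = ("facility_id", "service_area", "month", "row_id")


@dataclass(frozen=True)
class FieldRule:
    """Audit rule for one register field.

    ``required_if`` names a sibling field: the requiredness (blank check)
    only applies to rows where that sibling is non-blank — e.g. severity is
    only required once a diagnosis is recorded.  Invalid-code/range checks
    always apply to non-blank values.
    """

    field_name: str
    kind: str  # {"coded", "numeric", "free_text"}
    allowed_codes: frozenset[str] = frozenset()
    numeric_range: tuple[float, float] | None = None
    required: bool = True
    required_if: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"coded", "numeric", "free_text"}:
            raise ValueError(f"unknown rule kind {self.kind!r}")
        if self.kind == "coded" and not self.allowed_codes:
            raise ValueError(f"coded rule {self.field_name!r} needs allowed_codes")
        if self.kind == "numeric" and self.numeric_range is None:
            raise ValueError(f"numeric rule {self.field_name!r} needs numeric_range")


def default_rule_set() -> tuple[FieldRule, ...]:
    """The shipped register-audit rules (pure; stable across calls)."""
    return (
        FieldRule("sex", "coded", allowed_codes=frozenset({"M", "F"})),
        FieldRule("age", "numeric", numeric_range=(0.0, 120.0)),
        FieldRule("weight", "numeric", numeric_range=(1.0, 300.0)),
        FieldRule("height", "numeric", numeric_range=(30.0, 250.0)),
        FieldRule("diagnosis", "free_text"),
        FieldRule(
            "severity",
            "coded",
            allowed_codes=frozenset({"mild", "moderate", "severe"}),
            required_if="diagnosis",
        ),
        FieldRule("yes_no_code", "coded", allowed_codes=frozenset({"N", "H"})),
        FieldRule("service_tick", "coded", allowed_codes=frozenset({"tick"})),
    )


@dataclass
class CompletenessReport:
    """Per-field blank/invalid rates and per-row adherence, per stratum.

    ``fields``: one row per (stratum × field) with n_rows, n_blank,
    n_invalid_code, blank_rate, invalid_rate (percentages).
    ``adherence``: one row per stratum with n_rows, n_adherent,
    adherence_rate.
    """

    fields: pd.DataFrame
    adherence: pd.DataFrame
    group_by: tuple[str, ...] = field(default_factory=tuple)


def _norm(values: pd.Series) -> pd.Series:
    return values.fillna("").astype(str).str.strip()


def _invalid_mask(values: pd.Series, rule: FieldRule) -> np.ndarray:
    nonblank = values != ""
    if rule.kind == "coded":
        return (nonblank & ~values.isin(sorted(rule.allowed_codes))).to_numpy()
    if rule.kind == "numeric":
        lo, hi = rule.numeric_range
        num = pd.to_numeric(values.where(nonblank), errors="coerce")
        return (nonblank & (num.isna() | (num < lo) | (num > hi))).to_numpy()
    return np.zeros(len(values), dtype=bool)


def audit_register_rows(
    rows: pd.DataFrame,
    rules: Sequence[FieldRule] | None = None,
    group_by: Sequence[str] = (),
) -> CompletenessReport:
    """Audit register rows against field rules, per stratum.

    ``rows`` is wide: the key columns plus one column per field.  Every
    non-key column must have a rule; a missing rule is an error listing the
    offending field names.
    """
    rules = tuple(rules) if rules is not None else default_rule_set()
    rule_map = {r.field_name: r for r in rules}
    field_cols = [c for c in rows.columns if c not in KEY_COLS and c not in group_by]
    unruled = [c for c in field_cols if c not in rule_map]
    if unruled:
        raise ValueError(f"fields present in rows but absent from rules: {sorted(unruled)}")
    unknown = set(group_by) - set(rows.columns)
    if unknown:
        raise ValueError(f"unknown grouping attributes {sorted(unknown)}")

    norm = {c: _norm(rows[c]) for c in field_cols}
    n = len(rows)
    violation_any = np.zeros(n, dtype=bool)
    per_field: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c in field_cols:
        rule = rule_map[c]
        values = norm[c]
        applicable = np.ones(n, dtype=bool) if rule.required else np.zeros(n, dtype=bool)
        if rule.required and rule.required_if is not None:
            if rule.required_if not in norm:
                raise ValueError(
                    f"rule for {c!r} conditions on missing field {rule.required_if!r}"
                )
            applicable &= (norm[rule.required_if] != "").to_numpy()
        blank = applicable & (values == "").to_numpy()
        invalid = _invalid_mask(values, rule)
        per_field[c] = (blank, invalid)
        violation_any |= blank | invalid

    groups: list[tuple[dict, np.ndarray]]
    if group_by:
        idx = rows.groupby(list(group_by), sort=True).indices
        groups = []
        for key, positions in sorted(idx.items(), key=lambda kv: kv[0] if isinstance(kv[0], tuple) else (kv[0],)):
            if not isinstance(key, tuple):
                key = (key,)
            groups.append((dict(zip(group_by, key)), np.asarray(positions)))
    else:
        groups = [({}, np.arange(n))]

    field_records, adherence_records = [], []
    for stratum, pos in groups:
        m = len(pos)
        for c in field_cols:
            blank, invalid = per_field[c]
            nb, ni = int(blank[pos].sum()), int(invalid[pos].sum())
            field_records.append(
                stratum
                | {
                    "field": c,
                    "n_rows": m,
                    "n_blank": nb,
                    "n_invalid_code": ni,
                    "blank_rate": 100.0 * nb / m if m else float("nan"),
                    "invalid_rate": 100.0 * ni / m if m else float("nan"),
                }
            )
        ok = int((~violation_any[pos]).sum())
        adherence_records.append(
            stratum
            | {
                "n_rows": m,
                "n_adherent": ok,
                "adherence_rate": 100.0 * ok / m if m else float("nan"),
            }
        )
    fields_df = pd.DataFrame(
        field_records,
        columns=list(group_by)
        + ["field", "n_rows", "n_blank", "n_invalid_code", "blank_rate", "invalid_rate"],
    )
    adherence_df = pd.DataFrame(
        adherence_records, columns=list(group_by) + ["n_rows", "n_adherent", "adherence_rate"]
    )
    return CompletenessReport(fields=fields_df, adherence=adherence_df, group_by=tuple(group_by))


# ---------------------------------------------------------------------------
# YAML rules


def rules_from_yaml(path) -> tuple[FieldRule, ...]:
    """Load field rules from a YAML list of mappings with the FieldRule
    field names (``allowed_codes`` as a list, ``numeric_range`` as a
    two-element list)."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, list):
        raise ValueError("rules YAML must be a list of field-rule mappings")
    rules = []
    for item in raw:
        rules.append(
            FieldRule(
                field_name=item["field_name"],
                kind=item["kind"],
                allowed_codes=frozenset(item.get("allowed_codes", ())),
                numeric_range=tuple(item["numeric_range"]) if item.get("numeric_range") else None,
                required=bool(item.get("required", True)),
                required_if=item.get("required_if"),
            )
        )
    return tuple(rules)
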