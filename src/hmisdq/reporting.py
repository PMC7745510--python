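"""Run configuration, colour-coded table export and the end-to-end pipeline.

``run_pipeline`` wires the whole assessment together: simulate a dataset
(roster, indicator catalogue, true events, five-source journey, register
rows), write it out, then compute availability tables, the register
completeness audit and stratified difference-ratio accuracy tables, and
export the accuracy results as a colour-coded HTML table with a CSV twin.
A manifest records the seed, a hash of the configuration and the package
version, so outputs are fully determined by (config, seed, code version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import html
import json
import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

import hmisdq
from hmisdq import accuracy as acc
from hmisdq import availability as avail
from hmisdq import completeness as comp
from hmisdq import journey
from hmisdq.months import month_range, parse_month

logger = logging.getLogger(__name__)

#: fixed 12-month detailed-review subset: four quarters at equal 6-month
#: spacing across the window
DETAILED_REVIEW_MONTHS = (
    "2014-10", "2014-11", "2014-12",
    "2015-07", "2015-08", "2015-09",
    "2016-04", "2016-05", "2016-06",
    "2017-01", "2017-02", "2017-03",
)

#: Okabe–Ito derived palette (colour-blind safe), keyed by match category
CATEGORY_COLOURS = {
    "matched": "#009E73",
    "moderately_matched": "#56B4E9",
    "moderately_under": "#F0E442",
    "moderately_over": "#E69F00",
    "highly_under": "#0072B2",
    "highly_over": "#D55E00",
    "extremely_over": "#CC79A7",
}
_MISSING_COLOUR = "#BBBBBB"


@dataclass
class RunConfig:
    """End-to-end pipeline configuration."""

    out_dir: str
    seed: int = 0
    window: tuple[str, str] = ("2014-01", "2017-09")
    detailed_months: tuple[str, ...] = DETAILED_REVIEW_MONTHS
    group_by: tuple[str, ...] = ("year", "service_area")
    quantile_method: str = "linear"
    params: journey.JourneyParams | str = "typical"
    roster: journey.RosterConfig = field(default_factory=lambda: journey.DEFAULT_ROSTER)
    include_register_rows: bool = True
    register_error_rates: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "height": {"blank": 0.4},
            "weight": {"blank": 0.35},
            "sex": {"blank": 0.05},
            "age": {"blank": 0.08},
            "severity": {"blank": 0.3, "invalid": 0.1},
            "yes_no_code": {"invalid": 0.25},
            "service_tick": {"invalid": 0.15, "blank": 0.1},
            "diagnosis": {"blank": 0.1},
        }
    )
    register_rows_per_month: int = 8

    def __post_init__(self) -> None:
        a, b = (parse_month(m) for m in self.window)
        if b < a:
            raise ValueError("review window end precedes start")
        for m in self.detailed_months:
            parse_month(m)

    def resolved_params(self) -> journey.JourneyParams:
        p = self.params
        if isinstance(p, str):
            if p == "typical":
                p = journey.preset_typical()
            elif p == "lossless":
                p = journey.preset_lossless()
            else:
                raise ValueError(f"unknown parameter preset {p!r}")
        return dataclasses.replace(p, seed=self.seed)


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d.pop("out_dir", None)  # the hash covers the science, not the destination
    params = config.resolved_params()
    d["params"] = dataclasses.asdict(params)
    if isinstance(params.mean_monthly_volume, Mapping):
        d["params"]["mean_monthly_volume"] = {
            k: (dict(v) if isinstance(v, Mapping) else v)
            for k, v in params.mean_monthly_volume.items()
        }
    return d


def config_from_file(path, out_dir: str | None = None, seed: int | None = None) -> RunConfig:
    """Load a RunConfig from YAML or JSON; ``params`` may be a preset name
    or a mapping of JourneyParams fields, ``roster`` a mapping with
    districts/level_counts/ownership_counts/offer_rates."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "params" in raw and isinstance(raw["params"], Mapping):
        raw["params"] = journey.JourneyParams(**raw["params"])
    if "roster" in raw and isinstance(raw["roster"], Mapping):
        r = raw["roster"]
        raw["roster"] = journey.RosterConfig(
            districts=tuple(journey.DistrictSpec(**d) for d in r["districts"]),
            level_counts=r["level_counts"],
            ownership_counts=r["ownership_counts"],
            offer_rates=r["offer_rates"],
        )
    for key in ("window", "detailed_months", "group_by"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    if out_dir is not None:
        raw["out_dir"] = out_dir
    if seed is not None:
        raw["seed"] = seed
    return RunConfig(**raw)


# ---------------------------------------------------------------------------
# colour-coded table export


def export_colour_coded_table(results: pd.DataFrame, out_base) -> tuple[Path, Path]:
    """Export a DR results table as colour-coded HTML plus a CSV twin.

    The HTML pivots strata into rows and indices into columns; each cell
    prints the DR to two decimals on a background keyed to its match
    category, with the seven-colour legend below.  The CSV twin carries the
    same rows with the category as text.  Returns (html_path, csv_path).
    """
    if results is None or results.empty:
        raise ValueError("cannot export an empty results table")
    out_base = Path(out_base)
    out_base.parent.mkdir(parents=True, exist_ok=True)
    html_path = out_base.with_suffix(".html")
    csv_path = out_base.with_suffix(".csv")

    stratum_cols = [c for c in results.columns if c not in (
        "index_id", "phase", "numerator_sum", "denominator_sum", "n_pairs", "dr", "flag", "category"
    )]
    csv_out = results.copy()
    csv_out["dr"] = csv_out["dr"].round(2)
    csv_out.to_csv(csv_path, index=False)

    index_ids = [i for i in acc.INDEX_IDS if i in set(results["index_id"])]
    cell = {}
    for row in results.itertuples(index=False):
        key = tuple(getattr(row, c) for c in stratum_cols)
        cell[(key, row.index_id)] = (row.dr, row.category, row.flag)

    strata = sorted({tuple(getattr(r, c) for c in stratum_cols) for r in results.itertuples(index=False)})
    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        "<style>table{border-collapse:collapse}td,th{border:1px solid #444;padding:4px 8px;"
        "font-family:sans-serif;font-size:13px;text-align:center}</style>",
        "</head><body>",
        "<h2>Difference-ratio accuracy</h2><table><tr>",
    ]
    for c in stratum_cols:
        parts.append(f"<th>{html.escape(str(c))}</th>")
    for i in index_ids:
        parts.append(f"<th>{html.escape(i)}</th>")
    parts.append("</tr>")
    for key in strata:
        parts.append("<tr>")
        for v in key:
            parts.append(f"<td>{html.escape(str(v))}</td>")
        for i in index_ids:
            dr, category, flag = cell.get((key, i), (float("nan"), "", ""))
            if category:
                colour = CATEGORY_COLOURS[str(category)]
                text = f"{dr:.2f}" if pd.notna(dr) else html.escape(str(flag))
            else:
                colour = _MISSING_COLOUR
                text = html.escape(str(flag)) if flag else "&ndash;"
            parts.append(f"<td style='background:{colour}'>{text}</td>")
        parts.append("</tr>")
    parts.append("</table><h3>Legend</h3><table>")
    for cat, colour in CATEGORY_COLOURS.items():
        parts.append(
            f"<tr><td style='background:{colour};width:3em'>&nbsp;</td>"
            f"<td>{html.escape(cat)}</td></tr>"
        )
    parts.append("</table></body></html>")
    html_path.write_text("".join(parts))
    return html_path, csv_path


# ---------------------------------------------------------------------------
# pipeline


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name: str):
    import contextlib

    @contextlib.contextmanager
    def ctx():
        logger.info("stage %s", name)
        try:
            yield
        except Exception as e:  # annotate with the failing stage
            raise PipelineError(f"stage {name!r} failed: {e}") from e

    return ctx()


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run simulate → availability → completeness → accuracy → report.

    Returns a mapping of artifact names to written paths.  Outputs are
    byte-identical across runs with the same config and seed.  Register
    rows (and hence the completeness stage) cover the detailed-review
    months only; the count journey covers the full window.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.resolved_params()
    artifacts: dict[str, Path] = {}

    with _stage("simulate"):
        roster = journey.simulate_roster(config.roster, seed=config.seed)
        indicators = journey.default_indicators()
        truth = journey.simulate_true_events(roster, indicators, config.window, params)
        counts = journey.propagate_journey(truth, params)
        register_rows = None
        if config.include_register_rows and config.detailed_months:
            start, end = min(config.detailed_months), max(config.detailed_months)
            rows = journey.simulate_register_rows(
                roster,
                (start, end),
                error_rates=config.register_error_rates,
                seed=config.seed,
                rows_per_month=config.register_rows_per_month,
            )
            register_rows = rows[rows["month"].isin(config.detailed_months)].reset_index(drop=True)
        dataset = journey.Dataset(
            counts=counts,
            roster=journey.roster_frame(roster),
            indicators=journey.indicators_frame(indicators),
            register_rows=register_rows,
        )
        data_dir = out / "data"
        journey.write_dataset(dataset, data_dir)
        artifacts["data"] = data_dir

    with _stage("availability"):
        _, summary = avail.availability_table(
            counts, by=config.group_by, method=config.quantile_method
        )
        p = out / "availability.csv"
        summary.to_csv(p, index=False)
        artifacts["availability"] = p
        _, dsummary = avail.district_reporting_table(
            counts, by=("district",), method=config.quantile_method
        )
        p = out / "district_availability.csv"
        dsummary.to_csv(p, index=False)
        artifacts["district_availability"] = p

    if register_rows is not None:
        with _stage("completeness"):
            report = comp.audit_register_rows(register_rows, group_by=("service_area",))
            p = out / "completeness.csv"
            report.fields.to_csv(p, index=False)
            pa = out / "adherence.csv"
            report.adherence.to_csv(pa, index=False)
            artifacts["completeness"] = p
            artifacts["adherence"] = pa
    else:
        logger.info("no register rows configured; completeness stage skipped")

    with _stage("accuracy"):
        results = acc.stratified_accuracy(counts, by=config.group_by)
        p = out / "accuracy.csv"
        results.to_csv(p, index=False)
        artifacts["accuracy"] = p

    with _stage("report"):
        html_path, csv_path = export_colour_coded_table(results, out / "accuracy_table")
        artifacts["accuracy_table_html"] = html_path
        artifacts["accuracy_table_csv"] = csv_path

    with _stage("manifest"):
        cfg = _config_dict(config)
        digest = hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()
        manifest = {
            "package": "hmisdq",
            "version": hmisdq.__version__,
            "seed": config.seed,
            "config_sha256": digest,
            "window": list(config.window),
            "n_facilities": len(roster),
            "artifacts": {k: str(v.relative_to(out)) for k, v in artifacts.items()},
        }
        p = out / "manifest.json"
        p.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        artifacts["manifest"] = p

    return artifacts
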