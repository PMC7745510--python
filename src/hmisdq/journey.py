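"""Generative simulator of the routine-HMIS "data journey".

A client event first exists as a row in a paper **register**, is marked on a
daily **tally sheet**, is compiled into the **facility monthly report**
(carbon copy kept at the facility), whose original travels to the district
office (**district report copy**) and is finally keyed into **DHIS2**.  Each
hop has its own error process: events missed in the register or on the
tally sheet, over-marking of tallies, reports compiled from tally totals /
register recounts / inflated guesses, tools that auditors cannot locate,
reports lost in transmission, undocumented revisions before DHIS2 entry,
and keystroke errors.

The simulator draws true monthly event counts per (facility, indicator,
month) and propagates them through those five sources, producing exactly
the long-format count dataset a field data-quality review would abstract,
so the downstream availability/completeness/accuracy metrics can be
validated by parameter recovery.

Randomness is organised as one global seed expanded into independent
per-facility substreams (keyed by a CRC32 of the facility id), so enlarging
the roster never reshuffles the draws of existing facilities.
"""

from __future__ import annotations

import zlib
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from hmisdq.months import month_range

SERVICE_AREAS = ("OPD", "IPD", "ANC", "PNC", "LnD", "FP", "PITC")
LEVELS = ("dispensary", "health_centre", "hospital")
OWNERSHIPS = ("government", "faith_based", "private")
SETTINGS = ("urban", "rural")
#: the five sources of the data journey, in journey order
SOURCES = ("register", "tally", "facility_report", "district_report", "dhis2")
COMPILE_MODES = ("tally", "register", "inflated")

COMPLEXITY_FLAGS = (
    "multi_variable",
    "severity_categorised",
    "medicine_linked",
    "subset_population",
    "time_window",
)

#: attribute columns carried on every count row (denormalised from the roster)
KEY_COLS = (
    "facility_id",
    "district",
    "level",
    "ownership",
    "setting",
    "service_area",
    "indicator_id",
    "month",
)

# substream tags: keep draw streams for different simulation stages disjoint
_STREAM_TRUTH = 1
_STREAM_JOURNEY = 2
_STREAM_REGISTER = 3


def _facility_rng(seed: int, facility_id: str, stream: int) -> np.random.Generator:
    key = zlib.crc32(facility_id.encode("utf-8")) & 0xFFFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed), key, stream]))


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class FacilityProfile:
    """One primary-care facility and its reporting-relevant attributes."""

    facility_id: str
    level: str
    ownership: str
    district: str
    setting: str
    offered_service_areas: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown facility level {self.level!r}")
        if self.ownership not in OWNERSHIPS:
            raise ValueError(f"unknown ownership {self.ownership!r}")
        if self.setting not in SETTINGS:
            raise ValueError(f"unknown setting {self.setting!r}")
        bad = set(self.offered_service_areas) - set(SERVICE_AREAS)
        if bad:
            raise ValueError(f"unknown service areas {sorted(bad)}")
        if not self.offered_service_areas:
            raise ValueError("offered_service_areas must be non-empty")


@dataclass(frozen=True)
class IndicatorDef:
    """One monthly-reported indicator within a service area."""

    indicator_id: str
    service_area: str
    label: str
    age_split: bool = False
    complexity_flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.service_area not in SERVICE_AREAS:
            raise ValueError(f"unknown service area {self.service_area!r}")
        bad = set(self.complexity_flags) - set(COMPLEXITY_FLAGS)
        if bad:
            raise ValueError(f"unknown complexity flags {sorted(bad)}")


@dataclass(frozen=True)
class DistrictSpec:
    name: str
    setting: str
    n_facilities: int

    def __post_init__(self) -> None:
        if self.setting not in SETTINGS:
            raise ValueError(f"unknown setting {self.setting!r}")
        if self.n_facilities < 0:
            raise ValueError("n_facilities must be >= 0")


@dataclass(frozen=True)
class RosterConfig:
    """Requested composition of a synthetic facility roster.

    ``level_counts`` and ``ownership_counts`` are exact totals over the whole
    roster; ``offer_rates`` gives, per service area, the probability that a
    facility offers it (IPD, for example, is mostly a hospital/health-centre
    service and has a low rate).
    """

    districts: tuple[DistrictSpec, ...]
    level_counts: Mapping[str, int]
    ownership_counts: Mapping[str, int]
    offer_rates: Mapping[str, float]

    def __post_init__(self) -> None:
        n = sum(d.n_facilities for d in self.districts)
        if set(self.level_counts) - set(LEVELS):
            raise ValueError("unknown facility level in level_counts")
        if set(self.ownership_counts) - set(OWNERSHIPS):
            raise ValueError("unknown ownership in ownership_counts")
        if set(self.offer_rates) - set(SERVICE_AREAS):
            raise ValueError("unknown service area in offer_rates")
        if any(v < 0 for v in self.level_counts.values()):
            raise ValueError("negative level count")
        if any(v < 0 for v in self.ownership_counts.values()):
            raise ValueError("negative ownership count")
        if sum(self.level_counts.values()) != n:
            raise ValueError("level_counts must sum to the district totals")
        if sum(self.ownership_counts.values()) != n:
            raise ValueError("ownership_counts must sum to the district totals")
        if any(not 0 <= p <= 1 for p in self.offer_rates.values()):
            raise ValueError("offer rates must lie in [0, 1]")

    @property
    def n_facilities(self) -> int:
        return sum(d.n_facilities for d in self.districts)


#: 11-district / 115-facility roster emulating a national primary-care sample:
#: 67 dispensaries, 36 health centres, 12 hospitals; offer rates follow the
#: observed share of facilities running each service area (e.g. nearly all
#: offer OPD, under half offer inpatient care).
DEFAULT_ROSTER = RosterConfig(
    districts=(
        DistrictSpec("Dodoma", "urban", 11),
        DistrictSpec("Igunga", "urban", 10),
        DistrictSpec("Kahama", "urban", 10),
        DistrictSpec("Kinondoni", "urban", 18),
        DistrictSpec("Njombe", "urban", 10),
        DistrictSpec("Hai", "rural", 10),
        DistrictSpec("Kibaha", "rural", 8),
        DistrictSpec("Mbinga", "rural", 10),
        DistrictSpec("Mbulu", "rural", 8),
        DistrictSpec("Nkasi", "rural", 10),
        DistrictSpec("Tandahimba", "rural", 10),
    ),
    level_counts={"dispensary": 67, "health_centre": 36, "hospital": 12},
    ownership_counts={"government": 81, "faith_based": 23, "private": 11},
    offer_rates={
        "OPD": 114 / 115,
        "IPD": 43 / 115,
        "ANC": 108 / 115,
        "PNC": 105 / 115,
        "PITC": 94 / 115,
        "LnD": 93 / 115,
        "FP": 88 / 115,
    },
)


@dataclass(frozen=True)
class JourneyParams:
    """Stage-wise error-process parameters of the reporting cascade.

    mean_monthly_volume
        Expected true client events per indicator-month.  Either a scalar,
        a mapping ``service_area -> mean``, or a nested mapping
        ``service_area -> {facility level -> mean}``.
    p_register_miss / p_tally_miss
        Probability that a true event is never written in the register /
        never marked on the tally sheet (binomial thinning).
    tally_overmark_rate
        Expected *extra* tally marks per true event (Poisson over-marking;
        double ticks, marks without registration).
    compile_mode_probs
        How the monthly report is compiled: from the tally totals, from a
        register recount, or as an inflated guess (register recount times
        ``report_inflation_factor``, rounded half away from zero).
    p_register_absent / p_tally_absent / p_facility_report_absent
        Per (facility, service area, month) probability that the tool cannot
        be located by the review team.  An absent facility report also wipes
        out the district copy and the DHIS2 value; an absent register or
        tally sheet hides only its own value (reports can exist without
        locatable register support).
    p_transmission_loss
        Probability the submitted report is unlocatable at the district
        office (and hence never entered in DHIS2).
    p_district_correction / correction_factor
        Probability the district copy is revised before DHIS2 entry, and the
        multiplicative revision applied (undocumented correction).
    p_entry_error
        Per-cell probability of a keystroke error at DHIS2 entry (one digit
        replaced at random).
    """

    mean_monthly_volume: float | Mapping = 50.0
    p_register_miss: float = 0.0
    p_tally_miss: float = 0.0
    tally_overmark_rate: float = 0.0
    compile_mode_probs: Mapping[str, float] = field(
        default_factory=lambda: {"tally": 1.0, "register": 0.0, "inflated": 0.0}
    )
    report_inflation_factor: float = 1.0
    p_register_absent: float = 0.0
    p_tally_absent: float = 0.0
    p_facility_report_absent: float = 0.0
    p_transmission_loss: float = 0.0
    p_district_correction: float = 0.0
    correction_factor: float = 1.0
    p_entry_error: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "p_register_miss": self.p_register_miss,
            "p_tally_miss": self.p_tally_miss,
            "p_register_absent": self.p_register_absent,
            "p_tally_absent": self.p_tally_absent,
            "p_facility_report_absent": self.p_facility_report_absent,
            "p_transmission_loss": self.p_transmission_loss,
            "p_district_correction": self.p_district_correction,
            "p_entry_error": self.p_entry_error,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.tally_overmark_rate < 0:
            raise ValueError("tally_overmark_rate must be >= 0")
        if self.report_inflation_factor <= 0:
            raise ValueError("report_inflation_factor must be > 0")
        if self.correction_factor <= 0:
            raise ValueError("correction_factor must be > 0")
        if set(self.compile_mode_probs) != set(COMPILE_MODES):
            raise ValueError(f"compile_mode_probs needs exactly the keys {COMPILE_MODES}")
        total = sum(self.compile_mode_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"compile_mode_probs must sum to 1, got {total}")
        if any(p < 0 for p in self.compile_mode_probs.values()):
            raise ValueError("compile_mode_probs must be nonnegative")

    def mean_volume(self, service_area: str, level: str) -> float:
        """Resolve the configured mean for one (service area, level) cell."""
        v = self.mean_monthly_volume
        if isinstance(v, Mapping):
            v = v.get(service_area, 0.0)
            if isinstance(v, Mapping):
                v = v.get(level, 0.0)
        out = float(v)
        if out < 0:
            raise ValueError("mean_monthly_volume must be >= 0")
        return out


def preset_lossless(seed: int = 0, mean_monthly_volume: float | Mapping = 50.0) -> JourneyParams:
    """An error-free journey: every source reproduces the truth exactly."""
    return JourneyParams(mean_monthly_volume=mean_monthly_volume, seed=seed)


#: per-service-area base monthly volumes (dispensary scale); client loads
#: rise steeply with facility level
_BASE_VOLUMES = {"OPD": 200.0, "IPD": 30.0, "ANC": 45.0, "PNC": 25.0, "LnD": 15.0, "FP": 35.0, "PITC": 20.0}
_LEVEL_MULT = {"dispensary": 1.0, "health_centre": 2.5, "hospital": 6.0}


def preset_typical(seed: int = 0) -> JourneyParams:
    """An illustrative error regime reproducing the dysfunctions a routine
    paper-based HMIS exhibits: registers that under-capture events, patchy
    tally-sheet use, occasional grossly inflated report compilation, roughly
    a third of reports unlocatable at the district, and undocumented
    corrections before DHIS2 entry.  Rates are illustrative defaults, not a
    calibration to any one country's system.
    """
    volumes = {
        sa: {lv: base * mult for lv, mult in _LEVEL_MULT.items()}
        for sa, base in _BASE_VOLUMES.items()
    }
    return JourneyParams(
        mean_monthly_volume=volumes,
        p_register_miss=0.35,
        p_tally_miss=0.15,
        tally_overmark_rate=0.05,
        compile_mode_probs={"tally": 0.6, "register": 0.2, "inflated": 0.2},
        report_inflation_factor=3.0,
        p_register_absent=0.09,
        p_tally_absent=0.25,
        p_facility_report_absent=0.13,
        p_transmission_loss=0.35,
        p_district_correction=0.15,
        correction_factor=1.2,
        p_entry_error=0.02,
        seed=seed,
    )


@dataclass(frozen=True)
class SourceCount:
    """Counts of one indicator for one facility-month across all five
    sources; a value is present iff its flag is set."""

    facility_id: str
    indicator_id: str
    month: str
    register_recount: int | None = None
    tally_count: int | None = None
    facility_report_value: int | None = None
    district_report_value: int | None = None
    dhis2_value: int | None = None

    def __post_init__(self) -> None:
        for name in ("register_recount", "tally_count", "facility_report_value",
                     "district_report_value", "dhis2_value"):
            v = getattr(self, name)
            if v is not None and (int(v) != v or v < 0):
                raise ValueError(f"{name} must be a nonnegative integer, got {v}")

    @property
    def presence(self) -> dict[str, bool]:
        return {
            "register": self.register_recount is not None,
            "tally": self.tally_count is not None,
            "facility_report": self.facility_report_value is not None,
            "district_report": self.district_report_value is not None,
            "dhis2": self.dhis2_value is not None,
        }


@dataclass(frozen=True)
class RegisterRow:
    """A row-level register record (one client contact)."""

    facility_id: str
    service_area: str
    month: str
    field_values: Mapping[str, str]
    field_schema: Mapping[str, object]

    def __post_init__(self) -> None:
        missing = set(self.field_values) - set(self.field_schema)
        if missing:
            raise ValueError(f"fields without schema: {sorted(missing)}")


# ---------------------------------------------------------------------------
# indicator catalogue


def default_indicators() -> tuple[IndicatorDef, ...]:
    """The default 34-indicator catalogue (OPD 5, IPD 4, ANC 8, PNC 6,
    LnD 2, FP 6, PITC 3), mirroring the content mix of a routine primary
    care review: anaemia and malaria morbidity with age splits and severity
    categories, antenatal vaccine/prophylaxis doses, postnatal follow-up
    windows, delivery counts, family-planning methods and HIV testing."""
    f = frozenset
    return (
        IndicatorDef("ANC-1", "ANC", "First visit before 12 weeks gestation", False, f({"subset_population", "time_window"})),
        IndicatorDef("ANC-2", "ANC", "First visit at 12 weeks gestation or later", False, f({"subset_population"})),
        IndicatorDef("ANC-3", "ANC", "Tetanus toxoid second dose given", False, f({"medicine_linked"})),
        IndicatorDef("ANC-4", "ANC", "Malaria intermittent preventive treatment dose given", False, f({"medicine_linked"})),
        IndicatorDef("ANC-5", "ANC", "First HIV test during pregnancy", False, f()),
        IndicatorDef("ANC-6", "ANC", "HIV positive at first test", False, f({"subset_population"})),
        IndicatorDef("ANC-7", "ANC", "HIV test, pregnant women under 25 years", False, f({"subset_population"})),
        IndicatorDef("ANC-8", "ANC", "Four or more visits completed", False, f({"time_window"})),
        IndicatorDef("FP-1", "FP", "Clients receiving injectable methods", False, f({"medicine_linked"})),
        IndicatorDef("FP-2", "FP", "Clients receiving pills at the facility", False, f({"medicine_linked"})),
        IndicatorDef("FP-3", "FP", "Intra-uterine device insertions", False, f({"medicine_linked"})),
        IndicatorDef("FP-4", "FP", "New family-planning acceptors", False, f()),
        IndicatorDef("FP-5", "FP", "Clients screened for breast cancer", False, f({"subset_population"})),
        IndicatorDef("FP-6", "FP", "Clients screened for cervical cancer", False, f({"subset_population"})),
        IndicatorDef("IPD-1", "IPD", "Anaemia admissions, mild or moderate", True, f({"multi_variable", "severity_categorised"})),
        IndicatorDef("IPD-2", "IPD", "Anaemia admissions, severe", True, f({"severity_categorised"})),
        IndicatorDef("IPD-3", "IPD", "Confirmed malaria admissions", True, f({"multi_variable"})),
        IndicatorDef("IPD-4", "IPD", "Clinical malaria admissions", True, f()),
        IndicatorDef("LnD-1", "LnD", "Deliveries at the health facility", False, f()),
        IndicatorDef("LnD-2", "LnD", "Deliveries assisted by skilled personnel", False, f({"subset_population"})),
        IndicatorDef("OPD-1", "OPD", "Anaemia, mild or moderate", True, f({"multi_variable", "severity_categorised"})),
        IndicatorDef("OPD-2", "OPD", "Anaemia, severe", True, f({"severity_categorised"})),
        IndicatorDef("OPD-3", "OPD", "Confirmed malaria, blood slide positive", True, f({"multi_variable"})),
        IndicatorDef("OPD-4", "OPD", "Blood slides examined for malaria", True, f({"multi_variable"})),
        IndicatorDef("OPD-5", "OPD", "Clinical malaria", True, f()),
        IndicatorDef("PITC-1", "PITC", "New counselling-and-testing clients", False, f()),
        IndicatorDef("PITC-2", "PITC", "New clients tested HIV positive", False, f({"subset_population"})),
        IndicatorDef("PITC-3", "PITC", "Clients returned for post-test counselling", False, f({"time_window"})),
        IndicatorDef("PNC-1", "PNC", "Mothers attended within 48 hours of delivery", False, f({"time_window"})),
        IndicatorDef("PNC-2", "PNC", "Mothers who completed all postnatal visits", False, f({"time_window"})),
        IndicatorDef("PNC-3", "PNC", "Severe anaemia diagnosed postnatally", False, f({"severity_categorised"})),
        IndicatorDef("PNC-4", "PNC", "Postnatal mental illness", False, f()),
        IndicatorDef("PNC-5", "PNC", "Exclusive breastfeeding chosen", False, f()),
        IndicatorDef("PNC-6", "PNC", "Mothers attended at day 3 to 7", False, f({"time_window"})),
    )


# ---------------------------------------------------------------------------
# roster


def _exact_allocation(counts: Mapping[str, int], order: Sequence[str]) -> list[str]:
    out: list[str] = []
    for key in order:
        out.extend([key] * int(counts.get(key, 0)))
    return out


def simulate_roster(config: RosterConfig, seed: int) -> list[FacilityProfile]:
    """Draw a facility roster matching the configured composition exactly.

    Level and ownership totals are honoured exactly (labels are shuffled
    across facilities); service-area offers are independent Bernoulli draws
    at the configured rates, with OPD forced on when a draw would otherwise
    leave a facility offering nothing.
    """
    n = config.n_facilities
    if n == 0:
        return []
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA11]))
    levels = np.array(_exact_allocation(config.level_counts, LEVELS))
    owners = np.array(_exact_allocation(config.ownership_counts, OWNERSHIPS))
    rng.shuffle(levels)
    rng.shuffle(owners)
    profiles: list[FacilityProfile] = []
    i = 0
    for dist in config.districts:
        for j in range(dist.n_facilities):
            fid = f"{dist.name}-{j + 1:03d}"
            offered = tuple(
                sa for sa in SERVICE_AREAS
                if rng.random() < config.offer_rates.get(sa, 0.0)
            )
            if not offered:
                offered = ("OPD",)
            profiles.append(
                FacilityProfile(
                    facility_id=fid,
                    level=str(levels[i]),
                    ownership=str(owners[i]),
                    district=dist.name,
                    setting=dist.setting,
                    offered_service_areas=offered,
                )
            )
            i += 1
    return profiles


def roster_frame(roster: Iterable[FacilityProfile]) -> pd.DataFrame:
    rows = [
        {
            "facility_id": p.facility_id,
            "level": p.level,
            "ownership": p.ownership,
            "district": p.district,
            "setting": p.setting,
            "offered_service_areas": "|".join(p.offered_service_areas),
        }
        for p in roster
    ]
    cols = ["facility_id", "level", "ownership", "district", "setting", "offered_service_areas"]
    return pd.DataFrame(rows, columns=cols)


def indicators_frame(indicators: Iterable[IndicatorDef]) -> pd.DataFrame:
    rows = [
        {
            "indicator_id": d.indicator_id,
            "service_area": d.service_area,
            "label": d.label,
            "age_split": int(d.age_split),
            "complexity_flags": "|".join(sorted(d.complexity_flags)),
        }
        for d in indicators
    ]
    cols = ["indicator_id", "service_area", "label", "age_split", "complexity_flags"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# true events


def simulate_true_events(
    roster: Sequence[FacilityProfile],
    indicators: Sequence[IndicatorDef],
    period: tuple[str, str],
    params: JourneyParams,
) -> pd.DataFrame:
    """Draw true monthly client-event counts per (facility, indicator, month).

    Counts are Poisson with the configured (service area, facility level)
    mean.  Only indicators whose service area the facility offers produce
    rows.  Draws come from per-facility substreams, in a fixed
    (indicator_id, month) order, so the output for a facility is invariant
    to the rest of the roster.
    """
    months = month_range(*period)
    by_sa: dict[str, list[IndicatorDef]] = {}
    for ind in sorted(indicators, key=lambda d: d.indicator_id):
        by_sa.setdefault(ind.service_area, []).append(ind)
    frames: list[pd.DataFrame] = []
    for prof in roster:
        inds = [d for sa in SERVICE_AREAS if sa in prof.offered_service_areas for d in by_sa.get(sa, [])]
        if not inds:
            continue
        rng = _facility_rng(params.seed, prof.facility_id, _STREAM_TRUTH)
        means = np.repeat(
            [params.mean_volume(d.service_area, prof.level) for d in inds], len(months)
        )
        counts = rng.poisson(means)
        frames.append(
            pd.DataFrame(
                {
                    "facility_id": prof.facility_id,
                    "district": prof.district,
                    "level": prof.level,
                    "ownership": prof.ownership,
                    "setting": prof.setting,
                    "service_area": np.repeat([d.service_area for d in inds], len(months)),
                    "indicator_id": np.repeat([d.indicator_id for d in inds], len(months)),
                    "month": np.tile(months, len(inds)),
                    "true_count": counts.astype(np.int64),
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=list(KEY_COLS) + ["true_count"])
    out = pd.concat(frames, ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# journey propagation


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # nonnegative inputs only: round half away from zero == floor(x + 0.5)
    return np.floor(x + 0.5).astype(np.int64)


def _perturb_digit(value: int, rng: np.random.Generator) -> int:
    """Keystroke error: one digit of the decimal representation replaced by
    a different uniformly-drawn digit."""
    s = str(int(value))
    i = int(rng.integers(len(s)))
    options = [d for d in "0123456789" if d != s[i]]
    return int(s[:i] + options[int(rng.integers(9))] + s[i + 1 :])


def propagate_journey(true_events: pd.DataFrame, params: JourneyParams) -> pd.DataFrame:
    """Propagate true counts through the five-source reporting cascade.

    Returns a wide frame with one row per (facility, indicator, month) and,
    for each source, a value column (nullable integer; NA when the source is
    absent) plus a boolean ``<source>_present`` flag.

    Monthly decisions — tool absence, compile mode, transmission loss,
    district correction — are drawn once per (facility, service area, month)
    because registers, tally sheets and reports are physical per-service-area
    monthly artefacts; event-level noise (register/tally misses, over-marks,
    keystroke errors) is drawn per indicator row.  Tool absence masks what
    the review team can see; it does not alter the values propagating
    downstream (a report compiled from tallies still reaches the district
    even if the tally sheet is later unlocatable), except that an absent
    facility report suppresses the district copy and the DHIS2 entry, and a
    transmission loss suppresses both district and DHIS2.
    """
    required = set(KEY_COLS) | {"true_count"}
    missing = required - set(true_events.columns)
    if missing:
        raise ValueError(f"true_events is missing columns {sorted(missing)}")
    if len(true_events) and (true_events["true_count"] < 0).any():
        raise ValueError("true counts must be nonnegative")

    mode_p = [params.compile_mode_probs[m] for m in COMPILE_MODES]
    out_frames: list[pd.DataFrame] = []
    for fid, sub in true_events.groupby("facility_id", sort=True):
        sub = sub.sort_values(["service_area", "indicator_id", "month"], kind="mergesort").reset_index(drop=True)
        rng = _facility_rng(params.seed, str(fid), _STREAM_JOURNEY)
        t = sub["true_count"].to_numpy(np.int64)
        n = len(sub)

        # one draw block per (service area, month) = one physical tool/report
        grp_keys = sub[["service_area", "month"]].drop_duplicates().sort_values(
            ["service_area", "month"], kind="mergesort"
        )
        k = len(grp_keys)
        gid_of = {tuple(row): i for i, row in enumerate(grp_keys.itertuples(index=False))}
        gid = np.array([gid_of[(sa, m)] for sa, m in zip(sub["service_area"], sub["month"])])

        reg_absent = rng.random(k) < params.p_register_absent
        tally_absent = rng.random(k) < params.p_tally_absent
        rep_absent = rng.random(k) < params.p_facility_report_absent
        mode = rng.choice(len(COMPILE_MODES), size=k, p=mode_p)
        lost = rng.random(k) < params.p_transmission_loss
        corrected = rng.random(k) < params.p_district_correction

        register = rng.binomial(t, 1.0 - params.p_register_miss)
        tally = rng.binomial(t, 1.0 - params.p_tally_miss)
        if params.tally_overmark_rate > 0:
            tally = tally + rng.poisson(params.tally_overmark_rate * t)

        mode_row = mode[gid]
        report = np.where(
            mode_row == 0,
            tally,
            np.where(mode_row == 1, register, _round_half_away(register * params.report_inflation_factor)),
        ).astype(np.int64)
        district = report.copy()
        dhis2 = district.copy()
        corr_row = corrected[gid]
        if corr_row.any():
            dhis2 = np.where(corr_row, _round_half_away(dhis2 * params.correction_factor), dhis2)
        if params.p_entry_error > 0:
            hit = rng.random(n) < params.p_entry_error
            for i in np.flatnonzero(hit):
                dhis2[i] = _perturb_digit(int(dhis2[i]), rng)

        reg_present = ~reg_absent[gid]
        tally_present = ~tally_absent[gid]
        rep_present = ~rep_absent[gid]
        district_present = rep_present & ~lost[gid]
        dhis2_present = district_present

        frame = sub[list(KEY_COLS)].copy()
        for src, vals, pres in (
            ("register", register, reg_present),
            ("tally", tally, tally_present),
            ("facility_report", report, rep_present),
            ("district_report", district, district_present),
            ("dhis2", dhis2, dhis2_present),
        ):
            col = pd.array(vals, dtype="Int64")
            col[~pres] = pd.NA
            frame[src] = col
            frame[f"{src}_present"] = pres
        out_frames.append(frame)

    if not out_frames:
        cols = list(KEY_COLS) + [c for s in SOURCES for c in (s, f"{s}_present")]
        return pd.DataFrame(columns=cols)
    return pd.concat(out_frames, ignore_index=True)


# ---------------------------------------------------------------------------
# register rows (row-level records for the completeness audit)


def simulate_register_rows(
    roster: Sequence[FacilityProfile],
    period: tuple[str, str],
    error_rates: Mapping[str, Mapping[str, float]] | None = None,
    seed: int = 0,
    rows_per_month: int = 8,
) -> pd.DataFrame:
    """Generate row-level register records with injected blanks and invalid
    codes.

    ``error_rates`` maps field name to ``{"blank": p, "invalid": p}``; a
    blank draw wins over an invalid one.  The field schema is the audit
    module's default rule set (sex/age/weight/height, diagnosis with a
    severity category, a Kiswahili yes/no code with allowed {N, H}, and a
    tick-mark service field).  Severity follows the diagnosis: it is left
    blank whenever the diagnosis itself is blank.
    """
    from hmisdq.completeness import default_rule_set

    rules = {r.field_name: r for r in default_rule_set()}
    error_rates = dict(error_rates or {})
    unknown = set(error_rates) - set(rules)
    if unknown:
        raise ValueError(f"error rates for unknown fields: {sorted(unknown)}")
    for fname, spec in error_rates.items():
        for kind, p in spec.items():
            if kind not in {"blank", "invalid"}:
                raise ValueError(f"unknown error kind {kind!r} for field {fname!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{kind} rate for {fname!r} must lie in [0, 1]")

    months = month_range(*period)
    diagnoses = np.array(["malaria", "anaemia", "pneumonia", "diarrhoea"])
    invalid_tokens = {
        "sex": np.array(["U", "?"]),
        "yes_no_code": np.array(["Y", "X"]),
        "service_tick": np.array(["N", "X"]),
        "severity": np.array(["serious", "bad"]),
        "diagnosis": np.array(["?", "illegible"]),
    }

    frames: list[pd.DataFrame] = []
    for prof in roster:
        rng = _facility_rng(seed, prof.facility_id, _STREAM_REGISTER)
        for sa in prof.offered_service_areas:
            n = rows_per_month * len(months)
            frame = pd.DataFrame(
                {
                    "facility_id": prof.facility_id,
                    "service_area": sa,
                    "month": np.repeat(months, rows_per_month),
                }
            )
            frame["row_id"] = [
                f"{prof.facility_id}:{sa}:{m}:{i % rows_per_month}" for i, m in enumerate(frame["month"])
            ]
            values: dict[str, np.ndarray] = {}
            for fname, rule in rules.items():
                rates = error_rates.get(fname, {})
                blank = rng.random(n) < rates.get("blank", 0.0)
                invalid = rng.random(n) < rates.get("invalid", 0.0)
                if rule.kind == "numeric":
                    lo, hi = rule.numeric_range
                    valid = np.char.mod("%g", np.round(rng.uniform(lo, hi, n), 1))
                    bad = np.char.mod("%g", np.full(n, hi * 10 + 9))
                elif fname == "diagnosis":
                    valid = rng.choice(diagnoses, n)
                    bad = rng.choice(invalid_tokens["diagnosis"], n)
                else:
                    valid = rng.choice(np.array(sorted(rule.allowed_codes)), n)
                    bad = rng.choice(invalid_tokens.get(fname, np.array(["?"])), n)
                col = np.where(blank, "", np.where(invalid, bad, valid))
                values[fname] = col
            # severity exists only for diagnosed rows
            values["severity"] = np.where(values["diagnosis"] == "", "", values["severity"])
            for fname in rules:
                frame[fname] = values[fname]
            frames.append(frame)
    cols = ["facility_id", "service_area", "month", "row_id"] + list(rules)
    if not frames:
        return pd.DataFrame(columns=cols)
    return pd.concat(frames, ignore_index=True)[cols]


# ---------------------------------------------------------------------------
# dataset I/O


@dataclass
class Dataset:
    """An in-memory HMIS review dataset: wide source counts, the facility
    roster, the indicator catalogue and (optionally) row-level register
    records."""

    counts: pd.DataFrame
    roster: pd.DataFrame
    indicators: pd.DataFrame
    register_rows: pd.DataFrame | None = None


class DatasetError(ValueError):
    """Malformed on-disk dataset; message carries row-level diagnostics."""


def counts_to_long(wide: pd.DataFrame) -> pd.DataFrame:
    """Wide journey output -> the canonical long count table
    (one row per facility/indicator/month/source)."""
    frames = []
    for src in SOURCES:
        f = wide[list(KEY_COLS)].copy()
        f["source"] = src
        f["present"] = wide[f"{src}_present"].astype(int)
        f["value"] = wide[src]
        frames.append(f)
    long = pd.concat(frames, ignore_index=True)
    long["source"] = pd.Categorical(long["source"], categories=SOURCES, ordered=True)
    long = long.sort_values(
        ["facility_id", "service_area", "indicator_id", "month", "source"], kind="mergesort"
    ).reset_index(drop=True)
    long["source"] = long["source"].astype(str)
    return long


def counts_to_wide(long: pd.DataFrame) -> pd.DataFrame:
    """Long count table -> wide frame with per-source value/presence columns."""
    wide = None
    for src in SOURCES:
        sub = long[long["source"] == src]
        f = sub[list(KEY_COLS)].copy()
        f[src] = pd.array(sub["value"], dtype="Int64")
        f[f"{src}_present"] = sub["present"].astype(bool).to_numpy()
        wide = f if wide is None else wide.merge(f, on=list(KEY_COLS), how="outer")
    wide = wide.sort_values(
        ["facility_id", "service_area", "indicator_id", "month"], kind="mergesort"
    ).reset_index(drop=True)
    return wide


def write_dataset(dataset: Dataset, path) -> None:
    """Write ``counts.csv`` (long), ``roster.csv``, ``indicators.csv`` and,
    when present, ``register_rows.csv`` (long, with a ``row_id`` that groups
    the fields of one record) under ``path``."""
    from pathlib import Path

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    long = counts_to_long(dataset.counts)
    long.to_csv(path / "counts.csv", index=False)
    dataset.roster.to_csv(path / "roster.csv", index=False)
    dataset.indicators.to_csv(path / "indicators.csv", index=False)
    if dataset.register_rows is not None:
        reg_long = dataset.register_rows.melt(
            id_vars=["facility_id", "service_area", "month", "row_id"],
            var_name="field",
            value_name="value",
        ).sort_values(
            ["facility_id", "service_area", "month", "row_id", "field"], kind="mergesort"
        ).reset_index(drop=True)
        reg_long.to_csv(path / "register_rows.csv", index=False)


def _validate_counts_long(long: pd.DataFrame) -> pd.DataFrame:
    required = set(KEY_COLS) | {"source", "present", "value"}
    missing = required - set(long.columns)
    if missing:
        raise DatasetError(f"counts.csv is missing columns {sorted(missing)}")
    problems: list[str] = []
    bad_src = ~long["source"].isin(SOURCES)
    for i in long.index[bad_src][:5]:
        problems.append(f"row {i}: unknown source {long.at[i, 'source']!r}")
    bad_pres = ~long["present"].isin([0, 1])
    for i in long.index[bad_pres][:5]:
        problems.append(f"row {i}: present must be 0 or 1, got {long.at[i, 'present']!r}")
    vals = pd.to_numeric(long["value"], errors="coerce")
    present = long["present"] == 1
    bad_val = present & (vals.isna() | (vals < 0) | (vals % 1 != 0))
    for i in long.index[bad_val][:5]:
        problems.append(f"row {i}: present value must be a nonnegative integer, got {long.at[i, 'value']!r}")
    orphan = (~present) & vals.notna()
    for i in long.index[orphan][:5]:
        problems.append(f"row {i}: value given but present=0")
    if problems:
        raise DatasetError("malformed counts.csv: " + "; ".join(problems))
    out = long.copy()
    out["present"] = out["present"].astype(int)
    out["value"] = pd.array(vals, dtype="Int64")
    return out


def read_dataset(path) -> Dataset:
    """Read a dataset written by :func:`write_dataset`, validating counts
    row-by-row (source labels, presence flags, nonnegative integer values)."""
    from pathlib import Path

    path = Path(path)
    long = pd.read_csv(path / "counts.csv", dtype={"month": str})
    long = _validate_counts_long(long)
    counts = counts_to_wide(long)
    # keep_default_na=False: empty flag/offer strings are empty, not NaN
    roster = pd.read_csv(path / "roster.csv", keep_default_na=False)
    indicators = pd.read_csv(path / "indicators.csv", keep_default_na=False)
    register_rows = None
    reg_path = path / "register_rows.csv"
    if reg_path.exists():
        reg_long = pd.read_csv(reg_path, dtype=str, keep_default_na=False)
        register_rows = (
            reg_long.pivot(
                index=["facility_id", "service_area", "month", "row_id"],
                columns="field",
                values="value",
            )
            .reset_index()
            .rename_axis(columns=None)
        )
        from hmisdq.completeness import default_rule_set

        field_order = [r.field_name for r in default_rule_set() if r.field_name in register_rows.columns]
        other = [c for c in register_rows.columns if c not in field_order]
        register_rows = register_rows[other + field_order]
        register_rows = register_rows.sort_values(
            ["facility_id", "service_area", "month", "row_id"], kind="mergesort"
        ).reset_index(drop=True)
    return Dataset(counts=counts, roster=roster, indicators=indicators, register_rows=register_rows)
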