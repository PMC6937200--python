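"""Survey data structures, tabular I/O, and grouping/filter rules.

The unit of observation is a single fish stomach sampled at a pelagic trawl
station.  Prey items inside a stomach are classified into ten coarse taxon
groups (plus two bookkeeping categories, ``unidentified`` and ``parasite``,
that are recorded but excluded from every diet statistic).  Stations carry
the environmental covariates used by the stomach-weight model: position,
date-time, 0-50 m mean temperature and salinity, bottom depth, zooplankton
dry-weight biomass and total catch.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from datetime import datetime as _datetime

import numpy as np
import pandas as pd
from shapely.geometry import Point, box
from shapely.geometry.base import BaseGeometry

from .errors import ConfigurationError, LinkageError, NoDataError, ValidationError

#: The ten prey groups retained in every diet analysis, in reporting order.
PREY_GROUPS: tuple[str, ...] = (
    "molluscs",
    "copepods",
    "amphipods",
    "euphausiids",
    "large_crustaceans",
    "small_crustaceans",
    "fish",
    "appendicularians",
    "chaetognaths",
    "ova",
)

#: Categories that are recorded when reading stomachs but excluded from analysis.
EXCLUDED_GROUPS: tuple[str, ...] = ("unidentified", "parasite")

VALID_GROUPS = frozenset(PREY_GROUPS) | frozenset(EXCLUDED_GROUPS)

#: Sub-area labels, in the precedence order used for boundary ties.
AREAS: tuple[str, ...] = ("N", "E", "SE", "SW", "W")

#: Depth-profile ("distance to shore") classes by bottom depth in metres:
#: D1 = 0-200, D2 = 201-500, D3 = 501-1000, D4 = > 1000.
SHORE_CLASSES: tuple[str, ...] = ("D1", "D2", "D3", "D4")

TIME_PERIODS: tuple[str, ...] = ("P1", "P2", "P3", "P4")

# Plausibility bounds for mackerel total length (cm).
LENGTH_BOUNDS = (10.0, 60.0)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PreyItem:
    """One identified prey entry inside a stomach.

    Counts may be non-integer after volumetric subsample expansion; they are
    kept real-valued so numerical composition stays additive.
    """

    taxon_name: str
    prey_group: str
    count: float
    weight: float  # wet weight, g
    prey_length: float | None = None  # mm, larger prey only
    scale_factor: float = 1.0  # provenance of subsample expansion

    def __post_init__(self) -> None:
        if self.prey_group not in VALID_GROUPS:
            raise ValidationError(
                f"unknown prey group {self.prey_group!r}; expected one of "
                f"{sorted(VALID_GROUPS)}"
            )
        if self.count < 0 or self.weight < 0:
            raise ValidationError(
                f"negative count/weight for {self.taxon_name!r}: "
                f"count={self.count}, weight={self.weight}"
            )
        if self.count == 0 and self.weight == 0:
            raise ValidationError(
                f"prey item {self.taxon_name!r} has zero count and zero weight"
            )

    @property
    def excluded(self) -> bool:
        """True for unidentified matter and parasites (kept out of all indices)."""
        return self.prey_group in EXCLUDED_GROUPS


@dataclass(frozen=True)
class StomachRecord:
    """One fish: biometrics, its prey items, and stomach weight (organ + content)."""

    fish_id: str
    station_id: str
    length: float  # total length, cm
    body_weight: float  # whole body wet weight, g
    stomach_weight: float  # g, includes the content
    items: tuple[PreyItem, ...] = ()
    gonad_weight: float | None = None
    sex: str | None = None
    maturity: str | None = None
    age: float | None = None

    def __post_init__(self) -> None:
        lo, hi = LENGTH_BOUNDS
        if not (lo < self.length < hi):
            raise ValidationError(
                f"fish {self.fish_id}: length {self.length} cm outside plausibility "
                f"bounds ({lo}, {hi})"
            )
        if self.stomach_weight < 0:
            raise ValidationError(
                f"fish {self.fish_id}: negative stomach weight {self.stomach_weight}"
            )
        if self.body_weight <= 0:
            raise ValidationError(
                f"fish {self.fish_id}: non-positive body weight {self.body_weight}"
            )

    @property
    def analysis_items(self) -> tuple[PreyItem, ...]:
        return tuple(it for it in self.items if not it.excluded)

    @property
    def is_empty(self) -> bool:
        """Empty means: no analysable prey (parasites/unidentified do not count)."""
        return len(self.analysis_items) == 0


@dataclass(frozen=True)
class StationRecord:
    """One trawl station: position, time, environment and catch."""

    station_id: str
    longitude: float
    latitude: float
    datetime: _datetime
    year: int
    week_number: int
    bottom_depth: float  # m
    sst_0_50: float  # mean temperature 0-50 m, deg C
    sss_0_50: float  # mean salinity 0-50 m, PSU
    zooplankton_biomass: float  # mg dry weight / m3
    total_catch: float  # kg of mackerel in the haul
    area: str | None = None
    distance_to_shore_class: str | None = None
    time_period: str | None = None

    def with_derived_labels(
        self, boundaries: dict[str, BaseGeometry] | None = None
    ) -> "StationRecord":
        """Return a copy with area, time period and shore class filled in."""
        return replace(
            self,
            area=assign_area(self.longitude, self.latitude, boundaries),
            time_period=assign_time_period(self.datetime),
            distance_to_shore_class=assign_shore_class(self.bottom_depth),
        )


@dataclass
class DietMatrix:
    """Stomachs x prey-group matrices of wet weight (g) and count.

    Rows are individual stomachs (including empty ones -- needed for the
    vacuity index); columns are the ten analysis prey groups.  ``labels``
    carries per-stomach grouping factors (station, year, area, length group)
    aligned row-for-row with the matrices.
    """

    weight: pd.DataFrame
    count: pd.DataFrame
    labels: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.weight.index.equals(self.count.index):
            raise ValidationError("weight and count matrices have different row order")
        if list(self.weight.columns) != list(self.count.columns):
            raise ValidationError("weight and count matrices have different columns")
        bad = set(self.weight.columns) & set(EXCLUDED_GROUPS)
        if bad:
            raise ValidationError(f"excluded groups present as columns: {sorted(bad)}")

    @property
    def n_stomachs(self) -> int:
        return len(self.weight)

    def subset(self, mask) -> "DietMatrix":
        return DietMatrix(
            self.weight.loc[mask], self.count.loc[mask], self.labels.loc[mask]
        )


# ---------------------------------------------------------------------------
# grouping rules
# ---------------------------------------------------------------------------


def assign_length_group(length: float) -> str:
    """Classify a fish by total length: S <= 33 cm, M 34-38 cm, L >= 39 cm.

    Boundaries are integer-centimetre: the survey records length to 1 cm.
    """
    if length <= 0:
        raise ValidationError(f"non-positive length {length}")
    if length <= 33:
        return "S"
    if length < 39:
        return "M"
    return "L"


def assign_time_period(dt: _datetime) -> str:
    """Map local hour to one of four half-open six-hour periods.

    P1 = [00:00, 06:00), P2 = [06:00, 12:00), P3 = [12:00, 18:00),
    P4 = [18:00, 24:00).
    """
    return TIME_PERIODS[dt.hour // 6]


def assign_shore_class(bottom_depth: float) -> str:
    """Depth-profile class from bottom depth: 0-200, 201-500, 501-1000, >1000 m."""
    if bottom_depth < 0:
        raise ValidationError(f"negative bottom depth {bottom_depth}")
    if bottom_depth <= 200:
        return "D1"
    if bottom_depth <= 500:
        return "D2"
    if bottom_depth <= 1000:
        return "D3"
    return "D4"


def default_area_boundaries() -> dict[str, BaseGeometry]:
    """Rectangular sub-area polygons approximating the survey map around Iceland.

    The survey defines five sub-areas (N, E, SE, SW, W) by oceanographic and
    geographic boundaries but publishes no coordinates, so the polygons are a
    configuration input.  These defaults split a box around Iceland
    (62-70 N, 30-5 W) at 66 N (N vs the rest), 15 W (E), 19 W (SE vs SW) and
    64 N (SW/SE vs W).  Boxes are (lon_min, lat_min, lon_max, lat_max).
    """
    return {
        "N": box(-30.0, 66.0, -5.0, 70.0),
        "E": box(-15.0, 62.0, -5.0, 66.0),
        "SE": box(-19.0, 62.0, -15.0, 64.0),
        "SW": box(-25.0, 62.0, -19.0, 64.0),
        "W": box(-30.0, 64.0, -15.0, 66.0),
    }


def assign_area(
    longitude: float,
    latitude: float,
    boundaries: dict[str, BaseGeometry] | None = None,
) -> str:
    """Assign the sub-area containing a point; ties resolved by N > E > SE > SW > W.

    Points on a shared edge belong to the first area in the precedence order
    whose (closed) polygon covers them.  A point outside every polygon is
    labelled ``"unassigned"``.
    """
    if boundaries is None:
        boundaries = default_area_boundaries()
    p = Point(longitude, latitude)
    for area in AREAS:
        geom = boundaries.get(area)
        if geom is not None and (geom.covers(p)):
            return area
    return "unassigned"


def fulton_k(body_weight: float, length: float) -> float:
    """Fulton's condition factor K = 100 * W / L^3 (W in g, L in cm)."""
    if body_weight <= 0 or length <= 0:
        raise ValidationError(
            f"fulton_k requires positive weight and length, got W={body_weight}, "
            f"L={length}"
        )
    return 100.0 * body_weight / length**3


def expand_subsample(
    item: PreyItem, total_volume: float, subsample_volume: float
) -> PreyItem:
    """Scale a counted subsample up to the whole stomach by volumetric proportion.

    Dense zooplankton stomachs are counted from a 1-2 mL aliquot of the mixed
    content; counts and weights scale linearly with total/subsample volume.
    The scale factor is recorded on the item for provenance.
    """
    if subsample_volume <= 0 or total_volume <= 0:
        raise ValidationError(
            f"volumes must be positive, got total={total_volume}, "
            f"subsample={subsample_volume}"
        )
    if subsample_volume > total_volume:
        raise ValidationError(
            f"subsample volume {subsample_volume} mL exceeds total {total_volume} mL"
        )
    f = total_volume / subsample_volume
    return replace(
        item,
        count=item.count * f,
        weight=item.weight * f,
        scale_factor=item.scale_factor * f,
    )


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


@dataclass
class FilterReport:
    """Counts removed at each filtering step, in application order."""

    n_fish_in: int = 0
    n_fish_removed_small: int = 0
    n_stations_in: int = 0
    n_stations_removed_sparse: int = 0
    n_fish_removed_with_station: int = 0
    n_fish_out: int = 0
    n_stations_out: int = 0

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def apply_model_filters(
    stomachs: list[StomachRecord],
    stations: list[StationRecord],
    *,
    min_length: float = 25.0,
    min_stomachs: int = 10,
) -> tuple[list[StomachRecord], list[StationRecord], FilterReport]:
    """Apply the modelling filters: drop small fish, then sparse stations.

    Fish shorter than ``min_length`` cm are removed first; stations are then
    kept only if more than ``min_stomachs - 1`` stomachs remain (the survey
    design aims for ten stomachs per station).  The report records counts
    removed at each step, in that order.  Filtering is idempotent.
    """
    report = FilterReport(n_fish_in=len(stomachs), n_stations_in=len(stations))
    station_ids = {s.station_id for s in stations}
    for st in stomachs:
        if st.station_id not in station_ids:
            raise LinkageError(
                f"stomach {st.fish_id} references unknown station {st.station_id}"
            )

    kept = [s for s in stomachs if s.length >= min_length]
    report.n_fish_removed_small = len(stomachs) - len(kept)

    counts: dict[str, int] = {}
    for s in kept:
        counts[s.station_id] = counts.get(s.station_id, 0) + 1
    keep_stations = {sid for sid, n in counts.items() if n >= min_stomachs}
    report.n_stations_removed_sparse = len(stations) - len(
        [s for s in stations if s.station_id in keep_stations]
    )

    final = [s for s in kept if s.station_id in keep_stations]
    report.n_fish_removed_with_station = len(kept) - len(final)
    out_stations = [s for s in stations if s.station_id in keep_stations]
    report.n_fish_out = len(final)
    report.n_stations_out = len(out_stations)

    if not final:
        raise NoDataError(
            "no stomachs remain after length and station-size filters "
            f"(removed {report.n_fish_removed_small} small fish, "
            f"{report.n_stations_removed_sparse} sparse stations)"
        )
    return final, out_stations, report


# ---------------------------------------------------------------------------
# diet matrix construction
# ---------------------------------------------------------------------------


def build_diet_matrix(
    stomachs: list[StomachRecord],
    stations: list[StationRecord] | None = None,
    boundaries: dict[str, BaseGeometry] | None = None,
) -> DietMatrix:
    """Aggregate prey items into stomach x prey-group weight and count matrices.

    Empty stomachs become all-zero rows (they are needed for the vacuity
    index and for frequency-of-occurrence denominators).  Excluded groups
    never appear as columns.  If ``stations`` is given, each row is labelled
    with its station's year and area; otherwise those labels are NA.
    """
    if not stomachs:
        raise NoDataError("cannot build a diet matrix from zero stomachs")
    st_by_id: dict[str, StationRecord] = {}
    if stations is not None:
        st_by_id = {s.station_id: s for s in stations}
        for s in stomachs:
            if s.station_id not in st_by_id:
                raise LinkageError(
                    f"stomach {s.fish_id} references unknown station {s.station_id}"
                )

    index = [s.fish_id for s in stomachs]
    col_of = {g: j for j, g in enumerate(PREY_GROUPS)}
    w_arr = np.zeros((len(stomachs), len(PREY_GROUPS)))
    c_arr = np.zeros_like(w_arr)
    rows = []
    for i, s in enumerate(stomachs):
        for it in s.analysis_items:
            j = col_of[it.prey_group]
            w_arr[i, j] += it.weight
            c_arr[i, j] += it.count
        station = st_by_id.get(s.station_id)
        rows.append(
            {
                "fish_id": s.fish_id,
                "station_id": s.station_id,
                "year": station.year if station else pd.NA,
                "area": (
                    (station.area or assign_area(station.longitude, station.latitude, boundaries))
                    if station
                    else pd.NA
                ),
                "length_group": assign_length_group(s.length),
            }
        )
    labels = pd.DataFrame(rows).set_index("fish_id")
    labels.index = pd.Index(index, name="fish_id")
    w = pd.DataFrame(w_arr, index=index, columns=list(PREY_GROUPS))
    c = pd.DataFrame(c_arr, index=index, columns=list(PREY_GROUPS))
    return DietMatrix(weight=w, count=c, labels=labels)


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

#: Canonical stomach-table columns.  A "dialect" maps these canonical names to
#: the column names actually present in a file.
STOMACH_COLUMNS = (
    "fish_id",
    "station_id",
    "length_cm",
    "body_weight_g",
    "stomach_weight_g",
    "taxon",
    "prey_group",
    "prey_count",
    "prey_weight_g",
    "prey_length_mm",
)

STATION_COLUMNS = (
    "station_id",
    "longitude",
    "latitude",
    "datetime",
    "year",
    "week",
    "bottom_depth_m",
    "sst_0_50_c",
    "sss_0_50",
    "zooplankton_mg_m3",
    "total_catch_kg",
)

_REQUIRED_STOMACH = STOMACH_COLUMNS[:5]


def _resolve(dialect: dict[str, str] | None, canonical: str) -> str:
    if dialect is None:
        return canonical
    return dialect.get(canonical, canonical)


def read_stomach_table(
    path, dialect: dict[str, str] | None = None
) -> list[StomachRecord]:
    """Read a long-format stomach CSV: one prey item per row, empty stomachs as
    a single row with blank prey fields.  Prey rows are aggregated per fish.

    Raises :class:`ConfigurationError` if a required column is missing and
    :class:`ValidationError` (naming the line) for negative counts/weights.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ConfigurationError(f"{path}: empty file")
        for canonical in _REQUIRED_STOMACH:
            if _resolve(dialect, canonical) not in reader.fieldnames:
                raise ConfigurationError(
                    f"{path}: missing required column "
                    f"{_resolve(dialect, canonical)!r} (for {canonical})"
                )
        fish: dict[str, dict] = {}
        order: list[str] = []
        for lineno, row in enumerate(reader, start=2):
            fid = row[_resolve(dialect, "fish_id")]
            if fid not in fish:
                try:
                    fish[fid] = {
                        "station_id": row[_resolve(dialect, "station_id")],
                        "length": float(row[_resolve(dialect, "length_cm")]),
                        "body_weight": float(row[_resolve(dialect, "body_weight_g")]),
                        "stomach_weight": float(
                            row[_resolve(dialect, "stomach_weight_g")]
                        ),
                        "items": [],
                    }
                except ValueError as exc:
                    raise ValidationError(f"{path} line {lineno}: {exc}") from exc
                order.append(fid)
            taxon = (row.get(_resolve(dialect, "taxon")) or "").strip()
            group = (row.get(_resolve(dialect, "prey_group")) or "").strip()
            if not taxon and not group:
                continue  # empty-stomach marker row
            try:
                cnt = float(row.get(_resolve(dialect, "prey_count")) or 0.0)
                wgt = float(row.get(_resolve(dialect, "prey_weight_g")) or 0.0)
                plen_raw = (row.get(_resolve(dialect, "prey_length_mm")) or "").strip()
                plen = float(plen_raw) if plen_raw else None
                item = PreyItem(
                    taxon_name=taxon,
                    prey_group=group,
                    count=cnt,
                    weight=wgt,
                    prey_length=plen,
                )
            except (ValueError, ValidationError) as exc:
                raise ValidationError(f"{path} line {lineno}: {exc}") from exc
            fish[fid]["items"].append(item)

    return [
        StomachRecord(
            fish_id=fid,
            station_id=rec["station_id"],
            length=rec["length"],
            body_weight=rec["body_weight"],
            stomach_weight=rec["stomach_weight"],
            items=tuple(rec["items"]),
        )
        for fid, rec in ((f, fish[f]) for f in order)
    ]


def write_stomach_table(stomachs: list[StomachRecord], path) -> None:
    """Write stomachs in the long CSV format that :func:`read_stomach_table` reads."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(STOMACH_COLUMNS)
        for s in stomachs:
            base = [
                s.fish_id,
                s.station_id,
                repr(s.length),
                repr(s.body_weight),
                repr(s.stomach_weight),
            ]
            if not s.items:
                writer.writerow(base + ["", "", "", "", ""])
                continue
            for it in s.items:
                writer.writerow(
                    base
                    + [
                        it.taxon_name,
                        it.prey_group,
                        repr(it.count),
                        repr(it.weight),
                        "" if it.prey_length is None else repr(it.prey_length),
                    ]
                )


def read_station_table(
    path, dialect: dict[str, str] | None = None
) -> list[StationRecord]:
    """Read the station CSV and derive area/time-period/shore-class labels."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ConfigurationError(f"{path}: empty file")
        for canonical in STATION_COLUMNS:
            if _resolve(dialect, canonical) not in reader.fieldnames:
                raise ConfigurationError(
                    f"{path}: missing required column "
                    f"{_resolve(dialect, canonical)!r} (for {canonical})"
                )
        out = []
        for lineno, row in enumerate(reader, start=2):
            try:
                rec = StationRecord(
                    station_id=row[_resolve(dialect, "station_id")],
                    longitude=float(row[_resolve(dialect, "longitude")]),
                    latitude=float(row[_resolve(dialect, "latitude")]),
                    datetime=_datetime.fromisoformat(
                        row[_resolve(dialect, "datetime")]
                    ),
                    year=int(row[_resolve(dialect, "year")]),
                    week_number=int(row[_resolve(dialect, "week")]),
                    bottom_depth=float(row[_resolve(dialect, "bottom_depth_m")]),
                    sst_0_50=float(row[_resolve(dialect, "sst_0_50_c")]),
                    sss_0_50=float(row[_resolve(dialect, "sss_0_50")]),
                    zooplankton_biomass=float(
                        row[_resolve(dialect, "zooplankton_mg_m3")]
                    ),
                    total_catch=float(row[_resolve(dialect, "total_catch_kg")]),
                )
            except ValueError as exc:
                raise ValidationError(f"{path} line {lineno}: {exc}") from exc
            out.append(rec.with_derived_labels())
    return out


def write_station_table(stations: list[StationRecord], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(STATION_COLUMNS)
        for s in stations:
            writer.writerow(
                [
                    s.station_id,
                    repr(s.longitude),
                    repr(s.latitude),
                    s.datetime.isoformat(),
                    s.year,
                    s.week_number,
                    repr(s.bottom_depth),
                    repr(s.sst_0_50),
                    repr(s.sss_0_50),
                    repr(s.zooplankton_biomass),
                    repr(s.total_catch),
                ]
            )


def modelling_table(
    stomachs: list[StomachRecord],
    stations: list[StationRecord],
    *,
    content_only: bool = False,
) -> pd.DataFrame:
    """Join stomachs with station covariates into the one-row-per-stomach table
    used by the stomach-weight model.

    The response column ``log_stomach_weight`` is log stomach weight (organ
    including content, as recorded at sea).  ``content_only`` is provided for
    generators that track tissue and content separately; it has no effect on
    field data where only the combined weight exists.
    """
    st_by_id = {s.station_id: s for s in stations}
    rows = []
    for s in stomachs:
        station = st_by_id.get(s.station_id)
        if station is None:
            raise LinkageError(
                f"stomach {s.fish_id} references unknown station {s.station_id}"
            )
        if s.stomach_weight <= 0:
            continue  # log-response requires positive weight
        station = (
            station
            if station.area and station.time_period
            else station.with_derived_labels()
        )
        rows.append(
            {
                "fish_id": s.fish_id,
                "station_id": s.station_id,
                "log_stomach_weight": math.log(s.stomach_weight),
                "length": s.length,
                "fulton_k": fulton_k(s.body_weight, s.length),
                "longitude": station.longitude,
                "latitude": station.latitude,
                "year": station.year,
                "week": station.week_number,
                "bottom_depth": station.bottom_depth,
                "sst_0_50": station.sst_0_50,
                "sss_0_50": station.sss_0_50,
                "zooplankton_biomass": station.zooplankton_biomass,
                "log_total_catch": math.log(max(station.total_catch, 1e-12)),
                "time_period": station.time_period,
                "distance_to_shore_class": station.distance_to_shore_class,
                "area": station.area,
            }
        )
    if not rows:
        raise NoDataError("no stomachs with positive stomach weight to model")
    return pd.DataFrame(rows).set_index("fish_id")
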