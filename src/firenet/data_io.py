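"""Readers and spatial/temporal classification for group-sighting data.

The observational unit is a *group sighting*: a set of individually marked
birds seen (or mist-netted) together at one place on one day, under the
gambit-of-the-group assumption that every member associates with every other
member.  This module reads sighting CSVs (long or wide layout), fire-scar
polygons (GeoJSON), and vegetation-plot CSVs, classifies individuals as
affected / unaffected / excluded by their distances to the fire scar, and
slices observations into pre- and post-fire study windows.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from shapely.geometry import Point, mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

log = logging.getLogger(__name__)

EARTH_RADIUS_M = 6_371_000.0

GRASS_GRAIN = 5  # percent-cover measurement grain

#: Default logical-field -> CSV-header mapping for sighting tables.  The
#: canonical long layout has one row per (group, member).
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "group_id": "group_id",
    "date": "date",
    "x": "x",
    "y": "y",
    "individual": "individual",
    "source": "source",
    "members": "members",  # wide layout only: delimited member list
}


class SightingSource(str, Enum):
    RESIGHT = "resight"
    MISTNET = "mistnet"


class Treatment(str, Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    EXCLUDED = "excluded"


class ConfigurationError(ValueError):
    """A column map or config option does not match the data."""


class RowError(ValueError):
    """A data row failed validation; carries the 0-based row index."""

    def __init__(self, row: int, message: str):
        super().__init__(f"row {row}: {message}")
        self.row = row


@dataclass(frozen=True)
class GroupObservation:
    """One sighted or netted group: who, when, where."""

    group_id: str
    obs_date: dt.date
    location: tuple[float, float]  # planar meters (x, y)
    members: frozenset[str]
    source: SightingSource = SightingSource.RESIGHT

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"group {self.group_id}: empty member set")
        x, y = self.location
        if not (math.isfinite(x) and math.isfinite(y)):
            raise ValueError(f"group {self.group_id}: non-finite location")


@dataclass(frozen=True)
class FireScar:
    """Burned-area footprint: one or more planar polygons plus the burn date."""

    polygons: tuple[BaseGeometry, ...]
    burn_date: dt.date

    def __post_init__(self) -> None:
        for poly in self.polygons:
            if poly.is_empty or poly.area <= 0:
                raise ValueError("degenerate fire-scar polygon (zero area)")

    @property
    def geometry(self) -> BaseGeometry:
        return unary_union(list(self.polygons))

    def distance_to(self, location: tuple[float, float]) -> float:
        """Distance in meters from a point to the scar; 0 inside."""
        return float(self.geometry.distance(Point(location)))


@dataclass(frozen=True)
class TreatmentAssignment:
    individual_id: str
    treatment: Treatment
    min_distance_m: float
    max_distance_m: float

    def __post_init__(self) -> None:
        if self.min_distance_m > self.max_distance_m:
            raise ValueError("min_distance_m exceeds max_distance_m")
        if min(self.min_distance_m, self.max_distance_m) < 0:
            raise ValueError("negative distance")


@dataclass(frozen=True)
class StudyWindow:
    label: str  # "pre" or "post"
    start_date: dt.date
    end_date: dt.date

    def __post_init__(self) -> None:
        if self.label not in ("pre", "post"):
            raise ValueError(f"window label must be 'pre' or 'post', got {self.label!r}")
        if self.start_date > self.end_date:
            raise ValueError("window start after end")

    def contains(self, d: dt.date) -> bool:
        return self.start_date <= d <= self.end_date


@dataclass(frozen=True)
class VegPlot:
    """A 10 x 10 m vegetation plot with grass cover to the nearest 5%."""

    plot_type: str  # "used" or "random"
    period: str  # "pre" or "post"
    grass_cover: float  # percent, multiple of 5 in [0, 100]

    def __post_init__(self) -> None:
        if self.plot_type not in ("used", "random"):
            raise ValueError(f"plot_type must be used/random, got {self.plot_type!r}")
        if self.period not in ("pre", "post"):
            raise ValueError(f"period must be pre/post, got {self.period!r}")
        if not 0 <= self.grass_cover <= 100:
            raise ValueError(f"grass_cover {self.grass_cover} outside [0, 100]")
        if self.grass_cover % GRASS_GRAIN != 0:
            raise ValueError(
                f"grass_cover {self.grass_cover} is not a multiple of {GRASS_GRAIN}"
            )


# ---------------------------------------------------------------------------
# coordinate handling


def lonlat_to_local_meters(
    lon: float, lat: float, origin: tuple[float, float]
) -> tuple[float, float]:
    """Project a lon/lat pair to planar meters about a local origin.

    A local transverse-Mercator-style tangent-plane projection: accurate to
    well under a meter over a study site a few kilometers across, which is
    all the 100 m / 500 m buffer rules require.
    """
    lon0, lat0 = origin
    x = math.radians(lon - lon0) * EARTH_RADIUS_M * math.cos(math.radians(lat0))
    y = math.radians(lat - lat0) * EARTH_RADIUS_M
    return (x, y)


# ---------------------------------------------------------------------------
# date parsing

_DATE_FORMATS_WITH_YEAR = ("%Y-%m-%d", "%d/%m/%Y", "%d-%b-%Y", "%d-%b-%y")
_DATE_FORMATS_NO_YEAR = ("%d-%b", "%d %b", "%b %d")


def parse_date(value: object, year: int | None = None) -> dt.date:
    """Parse a calendar date; day-month strings take the configured year."""
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    text = str(value).strip()
    for fmt in _DATE_FORMATS_WITH_YEAR:
        try:
            return dt.datetime.strptime(text, fmt).date()
        except ValueError:
            continue
    for fmt in _DATE_FORMATS_NO_YEAR:
        try:
            parsed = dt.datetime.strptime(text, fmt).date()
        except ValueError:
            continue
        if year is None:
            raise ValueError(f"date {text!r} has no year and no study year configured")
        return parsed.replace(year=year)
    raise ValueError(f"unparseable date: {text!r}")


# ---------------------------------------------------------------------------
# sightings


def read_sightings(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    year: int | None = None,
    coords: str = "meters",
    origin: tuple[float, float] | None = None,
    member_delimiter: str = ";",
) -> list[GroupObservation]:
    """Read group sightings from CSV into :class:`GroupObservation` records.

    Long layout (canonical): one row per group member, rows sharing the
    mapped ``group_id`` merged into one observation.  Wide layout: one row
    per group with a ``members`` column holding a delimited ID list.

    Parameters
    ----------
    column_map
        Logical field -> CSV header.  Defaults to :data:`DEFAULT_COLUMN_MAP`;
        only overrides need supplying.  Deposited field tables rarely ship a
        documented schema, so the mapping is always explicit and overridable.
    year
        Study year applied to day-month dates lacking a year.
    coords
        ``"meters"`` (planar, used as-is) or ``"lonlat"`` (projected to local
        meters about *origin*, default the centroid of the data).
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, dtype=str)
    if df.empty:
        log.warning("sightings file %s is empty", path)
        return []
    wide = cmap["members"] in df.columns and cmap["individual"] not in df.columns
    member_col = cmap["members"] if wide else cmap["individual"]
    required = [cmap["group_id"], cmap["date"], member_col]
    for col in required:
        if col not in df.columns:
            raise ConfigurationError(
                f"mapped column {col!r} not found in {path} "
                f"(available: {list(df.columns)})"
            )
    have_xy = cmap["x"] in df.columns and cmap["y"] in df.columns
    have_source = cmap["source"] in df.columns

    if coords == "lonlat" and have_xy and origin is None:
        lons = pd.to_numeric(df[cmap["x"]])
        lats = pd.to_numeric(df[cmap["y"]])
        origin = (float(lons.mean()), float(lats.mean()))

    groups: dict[str, dict] = {}
    n_rows = 0
    for idx, row in df.iterrows():
        n_rows += 1
        gid = str(row[cmap["group_id"]])
        try:
            date = parse_date(row[cmap["date"]], year=year)
        except ValueError as exc:
            raise RowError(int(idx), str(exc)) from exc
        if have_xy:
            x, y = float(row[cmap["x"]]), float(row[cmap["y"]])
            if coords == "lonlat":
                x, y = lonlat_to_local_meters(x, y, origin)  # type: ignore[arg-type]
        else:
            x, y = 0.0, 0.0
        source = SightingSource.RESIGHT
        if have_source and not pd.isna(row[cmap["source"]]):
            source = SightingSource(str(row[cmap["source"]]))
        if wide:
            members = [
                m.strip() for m in str(row[member_col]).split(member_delimiter) if m.strip()
            ]
        else:
            members = [str(row[member_col]).strip()]
        if not members:
            raise RowError(int(idx), "no member IDs")
        rec = groups.setdefault(
            gid, {"date": date, "loc": (x, y), "members": set(), "source": source}
        )
        rec["members"].update(members)

    observations = [
        GroupObservation(
            group_id=gid,
            obs_date=rec["date"],
            location=rec["loc"],
            members=frozenset(rec["members"]),
            source=rec["source"],
        )
        for gid, rec in groups.items()
    ]
    log.info(
        "read %d rows -> %d group observations from %s", n_rows, len(observations), path
    )
    return observations


def write_sightings(
    observations: Iterable[GroupObservation], path: str | Path
) -> None:
    """Write observations as the canonical long-format CSV (one row/member)."""
    rows = [
        {
            "group_id": obs.group_id,
            "date": obs.obs_date.isoformat(),
            "x": repr(obs.location[0]),
            "y": repr(obs.location[1]),
            "source": obs.source.value,
            "individual": member,
        }
        for obs in observations
        for member in sorted(obs.members)
    ]
    pd.DataFrame(
        rows, columns=["group_id", "date", "x", "y", "source", "individual"]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# fire scars


def read_fire_scar(path: str | Path, burn_date: dt.date | None = None) -> FireScar:
    """Read a GeoJSON FeatureCollection (or bare geometry) of scar polygons.

    The burn date is taken from a ``burn_date`` feature property when present,
    otherwise from the *burn_date* argument.
    """
    with open(path) as fh:
        obj = json.load(fh)
    polys: list[BaseGeometry] = []
    found_date = burn_date
    if obj.get("type") == "FeatureCollection":
        for feat in obj["features"]:
            polys.append(shape(feat["geometry"]))
            props = feat.get("properties") or {}
            if "burn_date" in props:
                found_date = parse_date(props["burn_date"])
    elif obj.get("type") == "Feature":
        polys.append(shape(obj["geometry"]))
        props = obj.get("properties") or {}
        if "burn_date" in props:
            found_date = parse_date(props["burn_date"])
    else:
        polys.append(shape(obj))
    if found_date is None:
        raise ConfigurationError(f"{path}: no burn_date property and none supplied")
    return FireScar(polygons=tuple(polys), burn_date=found_date)


def write_fire_scar(scar: FireScar, path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": mapping(poly),
            "properties": {"burn_date": scar.burn_date.isoformat()},
        }
        for poly in scar.polygons
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


# ---------------------------------------------------------------------------
# treatment classification


def classify_treatment(
    sightings_of_individual: Sequence[GroupObservation],
    scar: FireScar,
    affected_radius_m: float = 100.0,
    unaffected_radius_m: float = 500.0,
) -> TreatmentAssignment:
    """Classify one individual by where all of its sightings fall.

    An individual consistently sighted on or within ``affected_radius_m`` of
    the scar is *affected*; one whose sightings all lie at least
    ``unaffected_radius_m`` away is *unaffected*.  Anything else — any
    sighting in the buffer band between the radii, or sightings straddling
    the two zones — is *excluded* from analysis.
    """
    if not sightings_of_individual:
        raise ValueError("individual has no sightings")
    if not 0 < affected_radius_m < unaffected_radius_m:
        raise ValueError("radii must satisfy 0 < affected < unaffected")
    ids = {m for obs in sightings_of_individual for m in obs.members}
    individual_id = sorted(ids)[0] if len(ids) > 1 else next(iter(ids))
    distances = [scar.distance_to(obs.location) for obs in sightings_of_individual]
    dmin, dmax = min(distances), max(distances)
    if dmax <= affected_radius_m:
        treatment = Treatment.AFFECTED
    elif dmin >= unaffected_radius_m:
        treatment = Treatment.UNAFFECTED
    else:
        treatment = Treatment.EXCLUDED
    return TreatmentAssignment(
        individual_id=individual_id,
        treatment=treatment,
        min_distance_m=dmin,
        max_distance_m=dmax,
    )


def classify_population(
    observations: Sequence[GroupObservation],
    scar: FireScar,
    affected_radius_m: float = 100.0,
    unaffected_radius_m: float = 500.0,
) -> dict[str, TreatmentAssignment]:
    """Classify every individual appearing in *observations*."""
    per_individual: dict[str, list[GroupObservation]] = {}
    for obs in observations:
        for member in obs.members:
            per_individual.setdefault(member, []).append(obs)
    out = {}
    for ind, sightings in per_individual.items():
        assignment = classify_treatment(
            sightings, scar, affected_radius_m, unaffected_radius_m
        )
        out[ind] = TreatmentAssignment(
            individual_id=ind,
            treatment=assignment.treatment,
            min_distance_m=assignment.min_distance_m,
            max_distance_m=assignment.max_distance_m,
        )
    n = {t: sum(1 for a in out.values() if a.treatment is t) for t in Treatment}
    log.info(
        "classified %d individuals: %d affected, %d unaffected, %d excluded",
        len(out), n[Treatment.AFFECTED], n[Treatment.UNAFFECTED], n[Treatment.EXCLUDED],
    )
    return out


# ---------------------------------------------------------------------------
# temporal windows


def slice_window(
    observations: Sequence[GroupObservation], window: StudyWindow
) -> list[GroupObservation]:
    """Observations whose date falls inside the window, both ends inclusive."""
    return [obs for obs in observations if window.contains(obs.obs_date)]


# ---------------------------------------------------------------------------
# vegetation plots


def _snap_to_grain(value: float, grain: int = GRASS_GRAIN) -> float:
    """Round to the measurement grain; exact halves round down (35 not 40 for 37.5)."""
    return float(math.ceil(value / grain - 0.5) * grain)


def read_veg_plots(path: str | Path, strict: bool = True) -> list[VegPlot]:
    """Read vegetation plots; cover values off the 5% grain error out in
    strict mode and are snapped (with a logged warning) in lenient mode."""
    df = pd.read_csv(path)
    for col in ("plot_type", "period", "grass_cover"):
        if col not in df.columns:
            raise ConfigurationError(f"column {col!r} not found in {path}")
    plots: list[VegPlot] = []
    for idx, row in df.iterrows():
        cover = float(row["grass_cover"])
        if not 0 <= cover <= 100:
            raise RowError(int(idx), f"grass_cover {cover} outside [0, 100]")
        if cover % GRASS_GRAIN != 0:
            if strict:
                raise RowError(
                    int(idx), f"grass_cover {cover} not a multiple of {GRASS_GRAIN}"
                )
            snapped = _snap_to_grain(cover)
            log.warning(
                "row %d: grass_cover %s snapped to %s", idx, cover, snapped
            )
            cover = snapped
        plots.append(
            VegPlot(
                plot_type=str(row["plot_type"]),
                period=str(row["period"]),
                grass_cover=cover,
            )
        )
    log.info("read %d vegetation plots from %s", len(plots), path)
    return plots


def write_veg_plots(plots: Iterable[VegPlot], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"plot_type": p.plot_type, "period": p.period, "grass_cover": p.grass_cover}
            for p in plots
        ]
    ).to_csv(path, index=False)
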