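"""Areas, geological events, time slices, and dispersal multiplier matrices.

Paleogeography enters a time-stratified DEC analysis through two channels:

* *availability* -- an island that has not yet emerged cannot be colonised,
  so every dispersal multiplier into it is zero for time slices older than
  its appearance; and
* *distance / corridor structure* -- within a slice, dispersal between a
  pair of emergent areas is scaled by a nonnegative multiplier that encodes
  overwater distance and, optionally, transient land corridors such as the
  hypothesised GAARlandia bridge (Greater Antilles + Aves Ridge, ca.
  35-33 mya) between South America and the Greater Antilles.

The time axis is measured in millions of years before present (mya) and
increases into the past; extant tips sit at age 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ALWAYS",
    "Area",
    "PaleoEvent",
    "TimeSlice",
    "DispersalModelSpec",
    "Corridor",
    "Geography",
    "GeographyError",
    "MODEL_SPECS",
    "build_time_slices",
    "area_available",
    "build_multiplier_matrix",
    "caribbean_five_area",
    "caribbean_six_area",
]

#: Sentinel availability age for land that has always existed.
ALWAYS = math.inf

#: Default multiplier per ordinal distance class (0 = same/adjacent
#: landmass, 1 = near overwater, 2 = far overwater).
DEFAULT_TIERS = {0: 1.0, 1: 0.5, 2: 0.1}

#: Default uniform multiplier for the "little dispersal" models.  A small
#: positive value rather than literal zero, so that a dispersal rate remains
#: identifiable under these models.
DEFAULT_EPSILON = 0.01


class GeographyError(ValueError):
    """Raised for inconsistent geography / model configuration."""


@dataclass(frozen=True)
class Area:
    """A discrete biogeographic region.

    Parameters
    ----------
    label : str
        Short unique name, e.g. ``"GA"`` for the Greater Antilles.
    index : int
        0-based position in every matrix and bitmask.
    availability_age : float
        Age (mya) after which land exists.  ``ALWAYS`` (``math.inf``) marks
        land that predates the analysis window.  An area appearing at age
        *a* is available in time slices strictly younger than *a*.
    """

    label: str
    index: int
    availability_age: float = ALWAYS

    def __post_init__(self) -> None:
        if self.availability_age <= 0:
            raise GeographyError(
                f"area {self.label!r}: availability age must be positive"
            )


@dataclass(frozen=True)
class PaleoEvent:
    """A dated geological event that bounds time slices."""

    name: str
    age: float

    def __post_init__(self) -> None:
        if not (self.age > 0):
            raise GeographyError(f"event {self.name!r}: age must be > 0 mya")


@dataclass(frozen=True)
class TimeSlice:
    """Half-open age interval ``[young_bound, old_bound)`` of constant geography.

    The oldest slice of a tiling is closed at its old bound so that the root
    age itself is covered.
    """

    young_bound: float
    old_bound: float

    def __post_init__(self) -> None:
        if not (self.old_bound > self.young_bound >= 0):
            raise GeographyError(
                f"invalid time slice [{self.young_bound}, {self.old_bound})"
            )

    @property
    def width(self) -> float:
        return self.old_bound - self.young_bound

    def contains(self, age: float) -> bool:
        return self.young_bound <= age < self.old_bound

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"TimeSlice[{self.young_bound:g}, {self.old_bound:g})"


@dataclass(frozen=True)
class DispersalModelSpec:
    """One of the six dispersal/vicariance hypotheses (A-F).

    ``gaarlandia`` toggles the land-bridge corridor; ``mode`` selects how
    between-area multipliers are formed: ``"distance"`` (tiered by distance
    class), ``"uniform"`` (all equal to 1), or ``"minimal"`` (all equal to a
    small epsilon, the "little dispersal" scenario).
    """

    id: str
    gaarlandia: bool
    mode: str

    _MODES = ("distance", "uniform", "minimal")

    def __post_init__(self) -> None:
        if self.mode not in self._MODES:
            raise GeographyError(f"unknown dispersal mode {self.mode!r}")


#: The canonical hypothesis set: land-bridge flag x dispersal mode.
MODEL_SPECS: dict[str, DispersalModelSpec] = {
    "A": DispersalModelSpec("A", gaarlandia=False, mode="distance"),
    "B": DispersalModelSpec("B", gaarlandia=True, mode="distance"),
    "C": DispersalModelSpec("C", gaarlandia=False, mode="uniform"),
    "D": DispersalModelSpec("D", gaarlandia=True, mode="uniform"),
    "E": DispersalModelSpec("E", gaarlandia=False, mode="minimal"),
    "F": DispersalModelSpec("F", gaarlandia=True, mode="minimal"),
}


@dataclass(frozen=True)
class Corridor:
    """A transient land corridor between two areas.

    Active only for model specs with ``gaarlandia=True`` and only in time
    slices fully contained in ``[young_age, old_age)``; while active, the
    multipliers between the two areas (both directions) are raised to
    ``multiplier``.
    """

    area_a: str
    area_b: str
    young_age: float
    old_age: float
    multiplier: float = 1.0

    def active_in(self, sl: TimeSlice) -> bool:
        return sl.young_bound >= self.young_age and sl.old_bound <= self.old_age


def build_time_slices(
    events: list[PaleoEvent], root_age: float, strict: bool = False
) -> list[TimeSlice]:
    """Tile ``[0, root_age]`` into half-open slices bounded by event ages.

    Returns slices sorted young to old: ``[0, a1), [a1, a2), ..., [ak, root_age]``
    where the ``a_i`` are the distinct event ages strictly below ``root_age``.
    An event exactly at ``root_age`` bounds the oldest slice but opens no
    new one.  Duplicate ages are a configuration error.  Events older than
    the root predate the analysis window entirely and are dropped, so a
    global paleogeographic scenario can be applied to a shallower clade;
    ``strict=True`` makes them an error naming the offending event instead.
    """
    ages = sorted(e.age for e in events)
    if len(set(ages)) != len(ages):
        dup = [a for a in set(ages) if ages.count(a) > 1]
        raise GeographyError(f"duplicate event ages: {sorted(dup)}")
    if strict:
        for e in events:
            if e.age > root_age:
                raise GeographyError(
                    f"event {e.name!r} at {e.age} mya is older than the root "
                    f"age {root_age} mya"
                )
    bounds = [0.0] + [a for a in ages if a < root_age] + [root_age]
    return [TimeSlice(y, o) for y, o in zip(bounds[:-1], bounds[1:])]


def area_available(area: Area, sl: TimeSlice) -> bool:
    """True iff ``area`` is emergent land during (at least the young end of) ``sl``.

    An area appearing at age *a* counts as available in slices strictly
    younger than *a*; within the slice where it emerges it is treated as
    available throughout.
    """
    return sl.young_bound < area.availability_age


def build_multiplier_matrix(
    sl: TimeSlice,
    spec: DispersalModelSpec,
    dist: np.ndarray,
    areas: list[Area],
    tiers: dict[int, float] | None = None,
    epsilon: float = DEFAULT_EPSILON,
    corridors: list[Corridor] | None = None,
) -> np.ndarray:
    """Dispersal multiplier matrix m[i, k] for one time slice under one model.

    ``m[i, k]`` scales the rate of dispersal from source area *i* into
    target area *k*.  Entries into areas unavailable in the slice are zero;
    otherwise the entry is set by the model's mode (distance tier, 1.0, or
    epsilon).  If the spec carries the land bridge and the slice falls in a
    corridor's window, the corridor pair is raised to the corridor
    multiplier in both directions.  The diagonal is zero by convention
    (self-dispersal is meaningless).
    """
    n = len(areas)
    dist = np.asarray(dist)
    if dist.shape != (n, n):
        raise GeographyError(
            f"distance-class matrix shape {dist.shape} does not match {n} areas"
        )
    tiers = DEFAULT_TIERS if tiers is None else tiers

    avail = np.array([area_available(a, sl) for a in areas], dtype=bool)
    m = np.zeros((n, n))
    for i in range(n):
        for k in range(n):
            if i == k or not avail[k]:
                continue
            if spec.mode == "uniform":
                m[i, k] = 1.0
            elif spec.mode == "minimal":
                m[i, k] = epsilon
            else:  # distance
                cls = int(dist[i, k])
                try:
                    m[i, k] = tiers[cls]
                except KeyError:
                    raise GeographyError(
                        f"no multiplier tier configured for distance class {cls}"
                    ) from None
    if spec.gaarlandia and corridors:
        idx = {a.label: a.index for a in areas}
        for c in corridors:
            if not c.active_in(sl):
                continue
            ia, ib = idx[c.area_a], idx[c.area_b]
            if avail[ib]:
                m[ia, ib] = max(m[ia, ib], c.multiplier)
            if avail[ia]:
                m[ib, ia] = max(m[ib, ia], c.multiplier)
    return m


@dataclass
class Geography:
    """A complete geographic scenario: areas, events, distances, corridors.

    ``distance_classes`` is the global ordinal distance-class matrix;
    ``slice_distance_overrides`` optionally replaces it within particular
    age windows (matched to slices fully contained in the window), so that
    e.g. the closure of the Isthmus of Panama can change a distance class.
    """

    areas: list[Area]
    events: list[PaleoEvent] = field(default_factory=list)
    distance_classes: np.ndarray | None = None
    slice_distance_overrides: list[tuple[float, float, np.ndarray]] = field(
        default_factory=list
    )
    tiers: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_TIERS))
    epsilon: float = DEFAULT_EPSILON
    corridors: list[Corridor] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [a.label for a in self.areas]
        if len(set(labels)) != len(labels):
            raise GeographyError("area labels must be unique")
        if sorted(a.index for a in self.areas) != list(range(len(self.areas))):
            raise GeographyError("area indices must be a permutation of 0..N-1")
        self.areas = sorted(self.areas, key=lambda a: a.index)
        if self.distance_classes is None:
            n = len(self.areas)
            self.distance_classes = np.zeros((n, n), dtype=int)
        self.distance_classes = np.asarray(self.distance_classes)
        d = self.distance_classes
        if not np.array_equal(d, d.T) or np.any(np.diag(d) != 0):
            raise GeographyError(
                "distance-class matrix must be symmetric with zero diagonal"
            )
        known = {a.label for a in self.areas}
        for c in self.corridors:
            if c.area_a not in known or c.area_b not in known:
                raise GeographyError(
                    f"corridor references unknown area: {c.area_a!r}/{c.area_b!r}"
                )

    # -- convenience ----------------------------------------------------

    @property
    def n_areas(self) -> int:
        return len(self.areas)

    @property
    def labels(self) -> list[str]:
        return [a.label for a in self.areas]

    def area(self, label: str) -> Area:
        for a in self.areas:
            if a.label == label:
                return a
        raise KeyError(label)

    def time_slices(self, root_age: float) -> list[TimeSlice]:
        return build_time_slices(self.events, root_age)

    def distances_for(self, sl: TimeSlice) -> np.ndarray:
        for young, old, mat in self.slice_distance_overrides:
            if sl.young_bound >= young and sl.old_bound <= old:
                return np.asarray(mat)
        return self.distance_classes

    def multiplier_matrix(self, sl: TimeSlice, spec: DispersalModelSpec) -> np.ndarray:
        return build_multiplier_matrix(
            sl,
            spec,
            self.distances_for(sl),
            self.areas,
            tiers=self.tiers,
            epsilon=self.epsilon,
            corridors=self.corridors,
        )

    def multiplier_matrices(
        self, root_age: float, spec: DispersalModelSpec
    ) -> tuple[list[TimeSlice], list[np.ndarray]]:
        slices = self.time_slices(root_age)
        return slices, [self.multiplier_matrix(sl, spec) for sl in slices]

    def with_epsilon(self, epsilon: float) -> "Geography":
        return replace(self, epsilon=epsilon)


# ----------------------------------------------------------------------
# Named presets
# ----------------------------------------------------------------------

def caribbean_five_area() -> Geography:
    """The five-region Caribbean scheme used for likelihood model testing.

    Areas: SA (South America south of the Isthmus of Panama, plus Aruba,
    Curacao and Bonaire), NCA (North + Central America), GA (Greater
    Antilles incl. the Bahamian Bank), nLA (northern Lesser Antilles,
    volcanic arc north of Martinique), sLA (southern Lesser Antilles, south
    of Dominica).  Six geological events bound the time slices: closure of
    the Isthmus of Panama (3 mya), most recent appearance of the northern
    (5 mya) and southern (12 mya) Lesser Antilles, disappearance (33 mya)
    and appearance (35 mya) of GAARlandia, and exposure of land in the
    Greater Antilles (55 mya).

    The ordinal distance classes shipped here are a documented default
    (0 adjacent, 1 near overwater, 2 far overwater); the Isthmus closure is
    modelled as an override making SA-NCA adjacent in the youngest slice.
    """
    areas = [
        Area("SA", 0, ALWAYS),
        Area("NCA", 1, ALWAYS),
        Area("GA", 2, 55.0),
        Area("nLA", 3, 5.0),
        Area("sLA", 4, 12.0),
    ]
    events = [
        PaleoEvent("Closure of Isthmus of Panama", 3.0),
        PaleoEvent("Most recent appearance of northern Lesser Antilles", 5.0),
        PaleoEvent("Most recent appearance of southern Lesser Antilles", 12.0),
        PaleoEvent("Disappearance of GAARlandia", 33.0),
        PaleoEvent("Appearance of GAARlandia", 35.0),
        PaleoEvent("Time after which land exposed in Greater Antilles", 55.0),
    ]
    dist = np.array(
        [
            [0, 1, 2, 2, 1],
            [1, 0, 1, 2, 2],
            [2, 1, 0, 1, 2],
            [2, 2, 1, 0, 0],
            [1, 2, 2, 0, 0],
        ]
    )
    post_isthmus = dist.copy()
    post_isthmus[0, 1] = post_isthmus[1, 0] = 0
    return Geography(
        areas=areas,
        events=events,
        distance_classes=dist,
        slice_distance_overrides=[(0.0, 3.0, post_isthmus)],
        corridors=[Corridor("SA", "GA", 33.0, 35.0, multiplier=1.0)],
    )


def caribbean_six_area() -> Geography:
    """The six-region scheme used for ancestral-range reconstruction.

    Splits Central from North America at the Isthmus of Tehuantepec, merges
    the Lesser Antilles into one area, and adds Australasia (the outgroup
    region).  Shipped for parity of area schemes; distances default to
    "near" between American mainland neighbours and "far" otherwise.
    """
    areas = [
        Area("AUS", 0, ALWAYS),
        Area("SA", 1, ALWAYS),
        Area("CA", 2, ALWAYS),
        Area("NA", 3, ALWAYS),
        Area("GA", 4, 55.0),
        Area("LA", 5, 12.0),
    ]
    events = [
        PaleoEvent("Closure of Isthmus of Panama", 3.0),
        PaleoEvent("Most recent appearance of Lesser Antilles", 12.0),
        PaleoEvent("Disappearance of GAARlandia", 33.0),
        PaleoEvent("Appearance of GAARlandia", 35.0),
        PaleoEvent("Time after which land exposed in Greater Antilles", 55.0),
    ]
    dist = np.array(
        [
            [0, 2, 2, 2, 2, 2],
            [2, 0, 1, 2, 2, 1],
            [2, 1, 0, 0, 1, 2],
            [2, 2, 0, 0, 1, 2],
            [2, 2, 1, 1, 0, 1],
            [2, 1, 2, 2, 1, 0],
        ]
    )
    return Geography(
        areas=areas,
        events=events,
        distance_classes=dist,
        corridors=[Corridor("SA", "GA", 33.0, 35.0, multiplier=1.0)],
    )
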