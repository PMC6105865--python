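"""Core domain types shared across pipeline stages.

Geometry is planar Cartesian in statute miles throughout: the sampling
protocol is defined in miles (2-mile grid, 1-mile counting radius) and no
geodesic handling is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterator, Optional

from shapely.geometry import Polygon

#: Sampling-slot labels, chronological. Data collection runs Monday through
#: Wednesday evenings, split at 8 pm; ``Mon<8pm`` is the regression reference.
SLOT_LABELS: tuple[str, ...] = (
    "Mon<8pm",
    "Mon>=8pm",
    "Tue<8pm",
    "Tue>=8pm",
    "Wed<8pm",
    "Wed>=8pm",
)


@dataclass(frozen=True)
class StudyRegion:
    """Rectangular study extent in planar miles."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError("region bounds must satisfy x_max > x_min and y_max > y_min")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        """Region area in square miles."""
        return self.width * self.height

    def contains(self, x: float, y: float) -> bool:
        """Closed-region membership test."""
        return self.x_min <= x <= self.x_max and self.y_min <= y <= self.y_max


@dataclass
class DisseminationArea:
    """Ecological covariate unit: a polygon with population and census-style
    covariates.

    ``covariates`` holds raw-unit values (persons/km^2, Can$, percentages,
    years, persons per household); regression scalings are applied when the
    design matrix is built.
    """

    id: str
    polygon: Polygon
    population: float = 0.0
    covariates: dict[str, float] = field(default_factory=dict)

    @property
    def area(self) -> float:
        """Polygon area in square miles."""
        return self.polygon.area

    @property
    def centroid(self) -> tuple[float, float]:
        c = self.polygon.centroid
        return (c.x, c.y)


@dataclass(frozen=True)
class UserPoint:
    """A simulated app user: a static point with a location-privacy flag."""

    id: str
    x: float
    y: float
    shows_location: bool = True


@dataclass(frozen=True)
class ListingEntry:
    """One row of an app screen: a user id and its displayed distance.

    ``distance`` is ``None`` when the user withholds location; the entry still
    occupies its true rank in the distance-ordered list.
    """

    user_id: str
    distance: Optional[float]

    @property
    def hidden(self) -> bool:
        return self.distance is None


@dataclass
class ProfileListing:
    """Distance-ordered app listing observed at one sampling location."""

    entries: list[ListingEntry]
    origin: Optional[tuple[float, float]] = None

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[ListingEntry]:
        return iter(self.entries)

    def displayed_distances(self) -> list[float]:
        return [e.distance for e in self.entries if e.distance is not None]

    def validate_order(self) -> None:
        """Displayed distances must be non-decreasing along the list."""
        d = self.displayed_distances()
        for a, b in zip(d, d[1:]):
            if b < a:
                raise ValueError("displayed distances are not non-decreasing")


@dataclass
class SamplingPoint:
    """A virtual sampling location on the systematic grid."""

    id: int
    x: float
    y: float
    slot: Optional[str] = None
    sample_order: Optional[int] = None


@dataclass
class ListingClassification:
    """Per-entry inclusion labels for a listing against a counting radius.

    Labels are ``included``, ``excluded`` or ``ambiguous``; only hidden
    entries can be ambiguous.
    """

    labels: list[str]

    @property
    def included(self) -> int:
        return self.labels.count("included")

    @property
    def excluded(self) -> int:
        return self.labels.count("excluded")

    @property
    def ambiguous(self) -> int:
        return self.labels.count("ambiguous")


@dataclass
class BufferObservation:
    """One retained sampling buffer: counts, land area and the density outcome."""

    point: SamplingPoint
    radius: float
    user_count: int
    ambiguous_count: int
    land_area: float
    density: int

    def __post_init__(self) -> None:
        if self.land_area <= 0:
            raise ValueError("BufferObservation requires positive land area")
        if self.land_area > math.pi * self.radius**2 * (1 + 1e-9):
            raise ValueError("land area exceeds disc area")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic world generator.

    ``beta`` is the true log-linear intensity coefficient vector on the
    regression (model) scale: intercept plus one coefficient per covariate
    name, giving log users per square mile. ``slot_effects`` are log relative
    activity levels per sampling slot (reference slot first, value 0); they
    enter the simulation as per-user visibility thinning.
    """

    region: StudyRegion = field(default_factory=lambda: StudyRegion(0.0, 32.0, 0.0, 32.0))
    n_das: int = 1200
    rng_seed: int = 20250929
    beta: dict[str, float] = field(default_factory=dict)
    p_hidden: float = 0.254
    covariate_smoothing_bandwidth: float = 4.0
    slot_effects: tuple[float, ...] = (
        0.0,
        math.log(2.16),
        math.log(2.00),
        math.log(2.28),
        math.log(1.15),
        math.log(1.13),
    )
    #: app-screen truncation length; None means the observer scrolls the
    #: entire distance-ordered list, as the counting protocol requires
    max_list: Optional[int] = None
    #: optional hook for spatially varying privacy: callable (x, y) -> prob
    p_hidden_field: Optional[Callable[[float, float], float]] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_hidden <= 1.0):
            raise ValueError("p_hidden must lie in [0, 1]")
        if self.covariate_smoothing_bandwidth <= 0:
            raise ValueError("covariate_smoothing_bandwidth must be positive")
        if len(self.slot_effects) != len(SLOT_LABELS):
            raise ValueError(f"slot_effects must have length {len(SLOT_LABELS)}")
        if not all(math.isfinite(v) for v in self.beta.values()):
            raise ValueError("beta must be finite")
        if self.n_das < 3:
            raise ValueError("n_das must be at least 3")
        if self.max_list is not None and self.max_list < 1:
            raise ValueError("max_list must be at least 1")
        if not self.beta:
            from .covariates import default_beta

            self.beta = default_beta()
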