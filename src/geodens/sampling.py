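"""Virtual spatial-sampling protocol.

Implements the grid-based counting design: a systematic lattice of sampling
points, random ordering with evening sampling-slot assignment, the
distance-ordered hidden-profile inclusion rule within a counting radius,
campaign-level deduplication of users, land-area computation within each
buffer, and the rounded density outcome.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Optional, Sequence

import numpy as np
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from ._geometry import buffer_disc
from .types import (
    DisseminationArea,
    ListingClassification,
    ProfileListing,
    SamplingPoint,
    StudyRegion,
    SLOT_LABELS,
)

logger = logging.getLogger(__name__)


def build_grid(
    region: StudyRegion, spacing: float, origin: tuple[float, float]
) -> list[SamplingPoint]:
    """All lattice points ``origin + (i*spacing, j*spacing)`` inside the region.

    Points are returned in row-major order (increasing y, then increasing x)
    before any randomization. ``origin`` must itself lie inside the region.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    ox, oy = origin
    if not region.contains(ox, oy):
        raise ValueError("origin must lie inside the region")
    i_lo = math.ceil((region.x_min - ox) / spacing - 1e-12)
    i_hi = math.floor((region.x_max - ox) / spacing + 1e-12)
    j_lo = math.ceil((region.y_min - oy) / spacing - 1e-12)
    j_hi = math.floor((region.y_max - oy) / spacing + 1e-12)
    points = []
    pid = 0
    for j in range(j_lo, j_hi + 1):
        for i in range(i_lo, i_hi + 1):
            x = ox + i * spacing
            y = oy + j * spacing
            if region.contains(x, y):
                points.append(SamplingPoint(id=pid, x=x, y=y))
                pid += 1
    return points


def assign_slots(points: Sequence[SamplingPoint], rng_seed: int) -> list[SamplingPoint]:
    """Randomize sampling order and assign evening slots.

    ``sample_order`` (1-based) is a uniform random permutation of the
    points; the permuted sequence is then partitioned into six nearly equal
    contiguous blocks assigned to the slot labels in chronological order, so
    block sizes differ by at most one. Returns the points in sampling order.
    """
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(len(points))
    ordered = [points[i] for i in perm]
    n = len(ordered)
    n_slots = len(SLOT_LABELS)
    base, extra = divmod(n, n_slots)
    sizes = [base + (1 if s < extra else 0) for s in range(n_slots)]
    k = 0
    for slot, size in zip(SLOT_LABELS, sizes):
        for _ in range(size):
            ordered[k].slot = slot
            ordered[k].sample_order = k + 1
            k += 1
    return ordered


def classify_listing(listing: ProfileListing, radius: float) -> ListingClassification:
    """Apply the distance-ordered inclusion rule to a listing.

    Displayed entries are included iff their distance is within ``radius``.
    A hidden entry is included when it appears earlier in the list than the
    farthest displayed entry within the radius (its true distance is then
    bounded above by an in-radius distance), excluded when it appears later
    than the nearest displayed entry beyond the radius, and ambiguous
    otherwise — including when the listing provides no resolving anchor.
    """
    listing.validate_order()
    last_in = None  # last displayed index with distance <= radius
    first_out = None  # first displayed index with distance > radius
    for i, e in enumerate(listing.entries):
        if e.distance is None:
            continue
        if e.distance <= radius:
            last_in = i
        elif first_out is None:
            first_out = i
    labels = []
    for i, e in enumerate(listing.entries):
        if e.distance is not None:
            labels.append("included" if e.distance <= radius else "excluded")
        elif last_in is not None and i < last_in:
            labels.append("included")
        elif first_out is not None and i > first_out:
            labels.append("excluded")
        else:
            labels.append("ambiguous")
    return ListingClassification(labels=labels)


def count_buffer(
    listing: ProfileListing,
    radius: float,
    already_counted: Optional[set[str]] = None,
) -> tuple[int, int]:
    """Count users within ``radius`` of a sampling point, per the protocol.

    Ambiguous profiles are never counted. When ``already_counted`` is
    supplied, users counted at an earlier sampling order are skipped
    (first-seen wins) and newly counted ids are added to the set, so each
    user contributes at most once per campaign.

    Returns ``(user_count, ambiguous_count)``.
    """
    cls = classify_listing(listing, radius)
    user_count = 0
    for e, label in zip(listing.entries, cls.labels):
        if label != "included":
            continue
        if already_counted is not None:
            if e.user_id in already_counted:
                continue
            already_counted.add(e.user_id)
        user_count += 1
    return user_count, cls.ambiguous


def land_union(das: Iterable[DisseminationArea]) -> BaseGeometry:
    """Union of DA polygons; territory outside it is treated as non-land."""
    return unary_union([da.polygon for da in das])


def land_area(
    sampling_point: tuple[float, float],
    radius: float,
    das_or_land: Iterable[DisseminationArea] | BaseGeometry,
) -> float:
    """Land area (sq mi) inside the sampling disc.

    Accepts either the DA list or a precomputed :func:`land_union` geometry.
    Returns 0.0 when the disc misses the land entirely — the sentinel for a
    droppable buffer.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    land = (
        das_or_land
        if isinstance(das_or_land, BaseGeometry)
        else land_union(das_or_land)
    )
    disc = buffer_disc(sampling_point[0], sampling_point[1], radius)
    return float(disc.intersection(land).area)


def compute_density(user_count: int, land_area: float) -> int:
    """Density outcome: users per square mile, rounded half away from zero."""
    if land_area <= 0:
        raise ValueError("land_area must be positive")
    if user_count < 0:
        raise ValueError("user_count must be non-negative")
    return int(math.floor(user_count / land_area + 0.5))
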