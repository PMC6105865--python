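"""Synthetic study-region generator.

Emulates the data environment of a grid-sampled geosocial-app density study:
an irregular tessellation of census-style dissemination areas (DAs) with
spatially autocorrelated socioeconomic covariates, an inhomogeneous Poisson
point process of app users whose log-intensity is linear in those
covariates, independent per-user location-privacy flags, and the
distance-ordered app screen (profile listing) observed from any point.

The generator is fully deterministic given a :class:`~geodens.types.SimulationConfig`.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import MultiPoint, Point, box
from shapely.ops import voronoi_diagram
from shapely.strtree import STRtree

from ._geometry import sample_points_in_polygon
from .covariates import COVARIATE_NAMES, KM2_PER_MI2, REGISTRY, scale_to_model
from .types import (
    DisseminationArea,
    ListingEntry,
    ProfileListing,
    SimulationConfig,
    StudyRegion,
    UserPoint,
)

_MAX_TESSELLATION_RETRIES = 5


def generate_tessellation(
    region: StudyRegion, n_das: int, rng_seed: int
) -> list[DisseminationArea]:
    """Partition ``region`` into ``n_das`` Voronoi cells of uniform seeds.

    Cells are clipped to the region rectangle, so they partition it exactly
    (areas sum to the region area). Degenerate seed draws (coincident or
    collinear points that break the diagram) are re-drawn a bounded number
    of times.

    Returns geometry-only :class:`DisseminationArea` objects, ordered to
    match the seed points, with ids ``da0000``, ``da0001``, ...
    """
    if n_das < 3:
        raise ValueError("n_das must be at least 3")
    rng = np.random.default_rng(rng_seed)
    envelope = box(region.x_min, region.y_min, region.x_max, region.y_max)
    for _ in range(_MAX_TESSELLATION_RETRIES):
        xs = rng.uniform(region.x_min, region.x_max, n_das)
        ys = rng.uniform(region.y_min, region.y_max, n_das)
        seeds = MultiPoint(list(zip(xs, ys)))
        try:
            cells = voronoi_diagram(seeds, envelope=envelope)
        except Exception:  # shapely raises GEOSException on degenerate input
            continue
        polys = [g.intersection(envelope) for g in cells.geoms]
        polys = [p for p in polys if not p.is_empty and p.area > 0]
        if len(polys) != n_das:
            continue
        # voronoi_diagram does not preserve seed order; match by containment
        tree = STRtree(polys)
        order = np.full(n_das, -1)
        ok = True
        for i in range(n_das):
            hits = tree.query(Point(xs[i], ys[i]), predicate="intersects")
            if len(hits) == 0:
                ok = False
                break
            order[i] = hits[0]
        if not ok or len(set(order.tolist())) != n_das:
            continue
        return [
            DisseminationArea(id=f"da{i:04d}", polygon=polys[order[i]])
            for i in range(n_das)
        ]
    raise RuntimeError(
        f"could not build a valid tessellation after {_MAX_TESSELLATION_RETRIES} draws"
    )


def _smoothing_kernel(centroids: np.ndarray, bandwidth: float) -> np.ndarray:
    """Row-normalized Gaussian kernel between DA centroids."""
    d2 = ((centroids[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    w = np.exp(-d2 / (2.0 * bandwidth**2))
    return w / w.sum(axis=1, keepdims=True)


def _smoothed_field(kernel: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Gaussian-kernel-smoothed white noise evaluated at DA centroids."""
    return kernel @ rng.standard_normal(kernel.shape[0])


def assign_covariates(
    das: list[DisseminationArea], config: SimulationConfig
) -> list[DisseminationArea]:
    """Attach spatially autocorrelated covariates and population to a tessellation.

    Each covariate is an independent kernel-smoothed Gaussian random field
    evaluated at DA centroids, then affinely mapped so that the empirical
    median and interquartile range match the registry anchors (on the log
    scale for right-skewed covariates), then clipped to the covariate's
    admissible range. In the infinite-bandwidth limit the field is constant,
    so every DA receives the anchor median.

    Population is made internally consistent with the density covariate:
    ``population = population_density [persons/km^2] * area [mi^2] * km^2/mi^2``.

    Modifies and returns the input list.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.rng_seed, 1]).generate_state(1)[0]
    )
    centroids = np.array([da.centroid for da in das])
    kernel = _smoothing_kernel(centroids, config.covariate_smoothing_bandwidth)
    for name in COVARIATE_NAMES:
        spec = REGISTRY[name]
        f = _smoothed_field(kernel, rng)
        q1, med, q3 = np.quantile(f, [0.25, 0.5, 0.75])
        iqr = q3 - q1
        g = np.zeros_like(f) if iqr < 1e-12 else (f - med) / iqr
        if spec.log_scale:
            values = np.exp(
                np.log(spec.median) + g * (np.log(spec.q3) - np.log(spec.q1))
            )
        else:
            values = spec.median + g * (spec.q3 - spec.q1)
        lo = -np.inf if spec.lower is None else spec.lower
        hi = np.inf if spec.upper is None else spec.upper
        values = np.clip(values, lo, hi)
        for da, v in zip(das, values):
            da.covariates[name] = float(v)
    for da in das:
        da.population = da.covariates["population_density"] * da.area * KM2_PER_MI2
    return das


def intensity(da: DisseminationArea, beta: dict[str, float]) -> float:
    """True user intensity (users per square mile) of one DA.

    ``log lambda = beta_0 + sum_k beta_k x_k`` with covariates on the
    regression scale (density per 100, income per Can $1000).
    """
    eta = beta.get("intercept", 0.0)
    for name, b in beta.items():
        if name == "intercept":
            continue
        if name not in da.covariates:
            raise KeyError(f"beta names a covariate the DA lacks: {name}")
        eta += b * scale_to_model(name, da.covariates[name])
    with np.errstate(over="ignore"):
        lam = np.exp(eta)
    if not np.isfinite(lam):
        raise ValueError("non-finite intensity; check beta/covariate scaling")
    return float(lam)


def simulate_users(
    das: list[DisseminationArea], config: SimulationConfig
) -> list[UserPoint]:
    """Draw app users from an inhomogeneous Poisson process over the tessellation.

    Per DA *j* the user count is Poisson(lambda_j * area_j) with the
    log-linear intensity of :func:`intensity`; locations are uniform within
    the DA polygon; ``shows_location`` is an independent Bernoulli(1 -
    p_hidden) flag (optionally spatially varying via
    ``config.p_hidden_field``).
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.rng_seed, 2]).generate_state(1)[0]
    )
    users: list[UserPoint] = []
    uid = 0
    for da in das:
        lam = intensity(da, config.beta)
        n = int(rng.poisson(lam * da.area))
        if n == 0:
            continue
        pts = sample_points_in_polygon(da.polygon, n, rng)
        for x, y in pts:
            p_hide = (
                config.p_hidden
                if config.p_hidden_field is None
                else float(config.p_hidden_field(x, y))
            )
            users.append(
                UserPoint(
                    id=f"u{uid:06d}",
                    x=float(x),
                    y=float(y),
                    shows_location=bool(rng.random() >= p_hide),
                )
            )
            uid += 1
    return users


def build_listing(
    sampling_point: tuple[float, float],
    users: list[UserPoint],
    max_list: int | None = None,
) -> ProfileListing:
    """Emulate the app screen at a location: users by ascending Euclidean
    distance, truncated to ``max_list`` entries (``None`` keeps the full
    list, i.e. the observer scrolls to the end).

    A user's distance is displayed only if ``shows_location`` is true; hidden
    users keep their true rank. Ties break by user id. An empty user set
    yields an empty listing.
    """
    if max_list is not None and max_list < 1:
        raise ValueError("max_list must be at least 1")
    x0, y0 = sampling_point
    if not users:
        return ProfileListing(entries=[], origin=(x0, y0))
    xy = np.array([(u.x, u.y) for u in users])
    d = np.hypot(xy[:, 0] - x0, xy[:, 1] - y0)
    order = sorted(range(len(users)), key=lambda i: (d[i], users[i].id))[:max_list]
    entries = [
        ListingEntry(
            user_id=users[i].id,
            distance=float(d[i]) if users[i].shows_location else None,
        )
        for i in order
    ]
    return ProfileListing(entries=entries, origin=(x0, y0))


def generate_world(
    config: SimulationConfig,
) -> tuple[list[DisseminationArea], list[UserPoint]]:
    """Convenience: tessellate, attach covariates, and simulate users."""
    das = generate_tessellation(config.region, config.n_das, config.rng_seed)
    assign_covariates(das, config)
    users = simulate_users(das, config)
    return das, users
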