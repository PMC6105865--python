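"""End-to-end campaign orchestration.

``run_pipeline`` composes the stages — simulate a synthetic world, run the
virtual sampling campaign, build the areal-weighted design matrix, fit and
compare the Poisson models, and export reports — into one seeded,
reproducible run. The standalone privacy audit quantifies how often
location-withholding profiles are actually ambiguous under the
distance-ordered inclusion rule.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import mapping

from . import io
from ._geometry import buffer_disc
from .areal import build_design_matrix, summarize_covariates
from .covariates import COVARIATE_NAMES, REGISTRY
from .model import (
    TIME_TERM,
    ModelFit,
    OutlierReport,
    backward_eliminate_aic,
    bonferroni_outlier_test,
    fit_null,
    fit_poisson,
    irr_table,
    likelihood_ratio_test,
    mcfadden_r2,
)
from .sampling import (
    assign_slots,
    build_grid,
    classify_listing,
    compute_density,
    count_buffer,
    land_area,
    land_union,
)
from .synthetic_data import build_listing, generate_world
from .types import (
    BufferObservation,
    DisseminationArea,
    ProfileListing,
    SimulationConfig,
    SLOT_LABELS,
    UserPoint,
)

logger = logging.getLogger(__name__)


@dataclass
class CampaignConfig:
    """Full configuration of a sampling campaign.

    Defaults mirror the reference protocol: a 2-mile systematic grid with a
    1-mile counting radius sampled over six weekday-evening slots, plus a
    500-profile privacy audit spread over 5 locations.
    """

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    spacing: float = 2.0
    radius: float = 1.0
    grid_origin: Optional[tuple[float, float]] = None
    seed_sampling: int = 20161129
    n_audit_locations: int = 5
    n_profiles_per_location: int = 100
    offset_mode: bool = False

    def __post_init__(self) -> None:
        if self.spacing < 2.0 * self.radius:
            warnings.warn(
                "grid spacing below twice the radius: sampling buffers overlap",
                stacklevel=2,
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = io.simulation_config_to_dict(self.sim)
        d["grid_origin"] = list(self.grid_origin) if self.grid_origin else None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CampaignConfig":
        d = dict(d)
        sim = d.pop("sim", None)
        kwargs = {}
        if sim is not None:
            kwargs["sim"] = io.simulation_config_from_dict(sim)
        origin = d.pop("grid_origin", None)
        if origin is not None:
            kwargs["grid_origin"] = tuple(origin)
        kwargs.update(d)
        return cls(**kwargs)


def slot_visibility(slot_effects: Sequence[float]) -> np.ndarray:
    """Per-slot user visibility probabilities.

    Slot effects are log relative activity; probabilities are
    ``exp(effect - max effect)`` so the busiest slot has visibility 1 and the
    fitted slot coefficients recover effect differences against the
    reference slot.
    """
    e = np.asarray(slot_effects, dtype=float)
    return np.exp(e - e.max())


def _listing_from_arrays(
    origin: tuple[float, float],
    xy: np.ndarray,
    uids: np.ndarray,
    shows: np.ndarray,
    max_list: int | None,
    radius: float | None = None,
) -> ProfileListing:
    """Vectorized equivalent of :func:`geodens.synthetic_data.build_listing`
    for the campaign's hot loop: same ordering (distance, then user id) and
    the same hidden-distance convention.

    When ``radius`` is given the listing is additionally cut just after the
    first *displayed* entry beyond the radius. Every later entry is
    necessarily classified ``excluded`` (displayed distances are
    non-decreasing, and hidden entries after that anchor resolve to
    excluded), so the cut cannot change counts or ambiguity.
    """
    from .types import ListingEntry

    if len(xy) == 0:
        return ProfileListing(entries=[], origin=origin)
    d = np.hypot(xy[:, 0] - origin[0], xy[:, 1] - origin[1])
    order = None
    if radius is not None and max_list is None:
        # sort only a neighbourhood if it certainly contains the cut point
        # (a displayed entry beyond the radius)
        near = np.flatnonzero(d <= 1.5 * radius)
        if np.any(shows[near] & (d[near] > radius)):
            order = near[np.lexsort((uids[near], d[near]))]
    if order is None:
        order = np.lexsort((uids, d))[:max_list]
    if radius is not None:
        disp = np.flatnonzero(shows[order] & (d[order] > radius))
        if disp.size:
            order = order[: disp[0] + 1]
    entries = [
        ListingEntry(user_id=uids[i], distance=float(d[i]) if shows[i] else None)
        for i in order
    ]
    return ProfileListing(entries=entries, origin=origin)


def run_sampling_campaign(
    das: Sequence[DisseminationArea],
    users: Sequence[UserPoint],
    config: CampaignConfig,
) -> list[BufferObservation]:
    """Execute the counting protocol over the full grid.

    Points are visited in randomized sample order; at each, users active in
    the point's slot (Bernoulli per the slot visibility) are listed by
    distance, the hidden-profile rule classifies the listing, unambiguous
    in-radius users not already counted earlier in the campaign are counted,
    and the rounded density is attached. Buffers with zero land area are
    dropped with a warning.
    """
    region = config.sim.region
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed_sampling, 3]).generate_state(1)[0]
    )
    origin = config.grid_origin
    if origin is None:
        origin = (
            float(rng.uniform(region.x_min, region.x_min + config.spacing)),
            float(rng.uniform(region.y_min, region.y_min + config.spacing)),
        )
        # keep the random origin inside the region
        origin = (min(origin[0], region.x_max), min(origin[1], region.y_max))
    grid = build_grid(region, config.spacing, origin)
    ordered = assign_slots(grid, config.seed_sampling)
    vis = slot_visibility(config.sim.slot_effects)
    land = land_union(das)

    observations: list[BufferObservation] = []
    counted: set[str] = set()
    n_dropped = 0
    user_list = list(users)
    # array views for the vectorized listing path (equivalent to calling
    # build_listing on the active sublist; see _listing_from_arrays)
    xy = np.array([(u.x, u.y) for u in user_list]).reshape(len(user_list), 2)
    uids = np.array([u.id for u in user_list], dtype=object)
    shows = np.array([u.shows_location for u in user_list], dtype=bool)
    for pt in ordered:
        area = land_area((pt.x, pt.y), config.radius, land)
        if area <= 0:
            n_dropped += 1
            logger.warning("[sample] dropping buffer %d: zero land area", pt.id)
            continue
        p_vis = vis[SLOT_LABELS.index(pt.slot)]
        if p_vis >= 1.0 or len(user_list) == 0:
            active = slice(None)
        else:
            active = rng.random(len(user_list)) < p_vis
        listing = _listing_from_arrays(
            (pt.x, pt.y), xy[active], uids[active], shows[active],
            config.sim.max_list, radius=config.radius,
        )
        user_count, ambiguous = count_buffer(listing, config.radius, counted)
        observations.append(
            BufferObservation(
                point=pt,
                radius=config.radius,
                user_count=user_count,
                ambiguous_count=ambiguous,
                land_area=area,
                density=compute_density(user_count, area),
            )
        )
    if n_dropped:
        logger.warning("[sample] dropped %d zero-land buffers", n_dropped)
    return observations


# ---------------------------------------------------------------------------
# privacy audit


@dataclass
class PrivacyAudit:
    """Counts and percentages of location-withholding profiles."""

    total_profiles: int
    hidden_count: int
    ambiguous_count: int
    per_location_hidden: tuple[int, ...] = ()
    per_location_ambiguous: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.ambiguous_count > self.hidden_count:
            raise ValueError("ambiguous profiles are a subset of hidden profiles")

    @property
    def unambiguous_hidden_count(self) -> int:
        return self.hidden_count - self.ambiguous_count

    @property
    def hidden_percent(self) -> float:
        """Percent of profiles withholding location, to one decimal."""
        return round(100.0 * self.hidden_count / self.total_profiles, 1)

    @property
    def ambiguous_percent_of_hidden(self) -> Optional[float]:
        """Percent of hidden profiles whose inclusion is ambiguous; not
        applicable (None) when nothing is hidden."""
        if self.hidden_count == 0:
            return None
        return round(100.0 * self.ambiguous_count / self.hidden_count, 1)

    @property
    def hidden_range(self) -> Optional[tuple[int, int]]:
        if not self.per_location_hidden:
            return None
        return (min(self.per_location_hidden), max(self.per_location_hidden))

    @property
    def ambiguous_range(self) -> Optional[tuple[int, int]]:
        if not self.per_location_ambiguous:
            return None
        return (min(self.per_location_ambiguous), max(self.per_location_ambiguous))

    def to_dict(self) -> dict:
        return {
            "total_profiles": self.total_profiles,
            "hidden_count": self.hidden_count,
            "ambiguous_count": self.ambiguous_count,
            "unambiguous_hidden_count": self.unambiguous_hidden_count,
            "hidden_percent": self.hidden_percent,
            "ambiguous_percent_of_hidden": self.ambiguous_percent_of_hidden,
            "per_location_hidden": list(self.per_location_hidden),
            "per_location_ambiguous": list(self.per_location_ambiguous),
        }


def privacy_audit(
    listings: Optional[Sequence[ProfileListing]] = None,
    counts: Optional[tuple[int, int, int]] = None,
    radius: float = 1.0,
) -> PrivacyAudit:
    """Audit the impact of location privacy on the counting rule.

    Either pass recorded ``counts = (total, hidden, ambiguous)`` or raw
    ``listings``, in which case hidden entries are enumerated directly and
    ambiguity is determined by the same classification rule the campaign
    uses, with per-location ranges reported.
    """
    if (listings is None) == (counts is None):
        raise ValueError("pass exactly one of listings or counts")
    if counts is not None:
        total, hidden, ambiguous = counts
        return PrivacyAudit(total, hidden, ambiguous)
    if not listings or all(len(l) == 0 for l in listings):
        raise ValueError("audit listings are empty")
    per_hidden, per_amb = [], []
    total = 0
    for listing in listings:
        cls = classify_listing(listing, radius)
        total += len(listing)
        per_hidden.append(sum(1 for e in listing if e.hidden))
        per_amb.append(cls.ambiguous)
    return PrivacyAudit(
        total_profiles=total,
        hidden_count=sum(per_hidden),
        ambiguous_count=sum(per_amb),
        per_location_hidden=tuple(per_hidden),
        per_location_ambiguous=tuple(per_amb),
    )


def audit_locations(config: CampaignConfig) -> list[tuple[float, float]]:
    """Spatially diverse audit sites: region corners inset by a quarter of
    each extent, plus the centre, cycled up to ``n_audit_locations``."""
    r = config.sim.region
    dx, dy = r.width / 4.0, r.height / 4.0
    candidates = [
        (r.x_min + dx, r.y_min + dy),
        (r.x_max - dx, r.y_max - dy),
        (r.x_min + dx, r.y_max - dy),
        (r.x_max - dx, r.y_min + dy),
        ((r.x_min + r.x_max) / 2.0, (r.y_min + r.y_max) / 2.0),
    ]
    out = []
    i = 0
    while len(out) < config.n_audit_locations:
        out.append(candidates[i % len(candidates)])
        i += 1
    return out


# ---------------------------------------------------------------------------
# exports


def export_geojson(
    observations: Sequence[BufferObservation],
    path: str | Path,
    fit: Optional[ModelFit] = None,
    outliers: Optional[OutlierReport] = None,
) -> None:
    """Write sampling buffers as a GeoJSON FeatureCollection of discs.

    Properties carry the observation (count, density, land area, slot) and,
    when a fit / outlier report is supplied, the fitted mean, studentized
    residual and outlier flag keyed by sampling-point id.
    """
    mu_by_id, res_by_id, flag_by_id = {}, {}, {}
    if fit is not None and fit.design_index is not None:
        mu_by_id = dict(zip(fit.design_index, fit.mu))
    if outliers is not None:
        res_by_id = outliers.table["residual"].to_dict()
        flag_by_id = outliers.table["outlier"].to_dict()
    features = []
    for obs in observations:
        pid = obs.point.id
        props = {
            "point_id": pid,
            "x": obs.point.x,
            "y": obs.point.y,
            "slot": obs.point.slot,
            "sample_order": obs.point.sample_order,
            "user_count": obs.user_count,
            "ambiguous_count": obs.ambiguous_count,
            "land_area": obs.land_area,
            "density": obs.density,
        }
        if pid in mu_by_id:
            props["fitted_mean"] = float(mu_by_id[pid])
        if pid in res_by_id:
            props["residual"] = float(res_by_id[pid])
            props["outlier"] = bool(flag_by_id[pid])
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(buffer_disc(obs.point.x, obs.point.y, obs.radius)),
                "properties": props,
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


# ---------------------------------------------------------------------------
# full pipeline


@dataclass
class PipelineResult:
    config: CampaignConfig
    das: list[DisseminationArea]
    users: list[UserPoint]
    observations: list[BufferObservation]
    design: pd.DataFrame
    fits: dict[str, ModelFit]
    selected_terms: tuple[str, ...]
    lrt: dict
    pseudo_r2: dict[str, float]
    outlier_reports: dict[str, OutlierReport]
    irr: pd.DataFrame
    audit: PrivacyAudit
    out_dir: Optional[Path] = None


def run_pipeline(
    config: CampaignConfig, out_dir: Optional[str | Path] = None
) -> PipelineResult:
    """Run simulate -> sample -> weight -> model -> audit -> export.

    When ``out_dir`` is given, every artifact (synthetic world, buffer
    observations, design matrix, descriptive and IRR tables, model
    comparison, outlier report, buffer GeoJSON, manifest) is written there;
    the manifest records all seeds so a run is fully reproducible.
    """
    try:
        logger.info("[simulate] generating synthetic world")
        das, users = generate_world(config.sim)
    except Exception as exc:
        raise RuntimeError(f"[simulate] stage failed: {exc}") from exc

    try:
        logger.info("[sample] running counting campaign")
        observations = run_sampling_campaign(das, users, config)
        if not observations:
            raise ValueError("no retained buffers")
    except Exception as exc:
        raise RuntimeError(f"[sample] stage failed: {exc}") from exc

    try:
        logger.info("[weight] building areal-weighted design matrix")
        design = build_design_matrix(observations, das)
    except Exception as exc:
        raise RuntimeError(f"[weight] stage failed: {exc}") from exc

    try:
        logger.info("[model] fitting Poisson models")
        outcome = "user_count" if config.offset_mode else "density"
        offset_col = "land_area" if config.offset_mode else None
        density_only = fit_poisson(
            design, ("population_density", TIME_TERM), outcome=outcome,
            offset_col=offset_col,
        )
        full = fit_poisson(
            design, (*COVARIATE_NAMES, TIME_TERM), outcome=outcome,
            offset_col=offset_col,
        )
        selected = backward_eliminate_aic(
            design, COVARIATE_NAMES, outcome=outcome, offset_col=offset_col
        )
        null = fit_null(design, outcome=outcome, offset_col=offset_col)
        pseudo_r2 = {
            "density_only": mcfadden_r2(density_only, null),
            "full": mcfadden_r2(full, null),
            "selected": mcfadden_r2(selected, null),
        }
        if set(density_only.terms) <= set(selected.terms):
            stat, df, p = likelihood_ratio_test(selected, density_only)
            lrt = {"comparison": "selected_vs_density_only", "statistic": stat,
                   "df": df, "p": p}
        else:
            stat, df, p = likelihood_ratio_test(full, density_only)
            lrt = {"comparison": "full_vs_density_only", "statistic": stat,
                   "df": df, "p": p}
        outlier_reports = {
            "density_only": bonferroni_outlier_test(density_only),
            "selected": bonferroni_outlier_test(selected),
        }
        irr = irr_table(selected)
        fits = {"density_only": density_only, "full": full,
                "selected": selected, "null": null}
        logger.info(
            "[model] quasi-Poisson scale (diagnostic only): %.3f",
            selected.quasi_poisson_scale(),
        )
    except Exception as exc:
        raise RuntimeError(f"[model] stage failed: {exc}") from exc

    try:
        logger.info("[audit] running privacy audit")
        listings = [
            build_listing(loc, users, config.n_profiles_per_location)
            for loc in audit_locations(config)
        ]
        audit = privacy_audit(listings=listings, radius=config.radius)
    except Exception as exc:
        raise RuntimeError(f"[audit] stage failed: {exc}") from exc

    result = PipelineResult(
        config=config, das=das, users=users, observations=observations,
        design=design, fits=fits, selected_terms=selected.terms, lrt=lrt,
        pseudo_r2=pseudo_r2, outlier_reports=outlier_reports, irr=irr,
        audit=audit,
    )
    if out_dir is not None:
        result.out_dir = Path(out_dir)
        _write_outputs(result)
    return result


def _table1_frame(design: pd.DataFrame) -> pd.DataFrame:
    """Descriptive medians/quartiles of the buffer covariates in raw units."""
    raw = design[list(COVARIATE_NAMES)].copy()
    for name in COVARIATE_NAMES:
        raw[name] = raw[name] * REGISTRY[name].model_scale
    return summarize_covariates(raw)


def _write_outputs(result: PipelineResult) -> None:
    out = result.out_dir
    out.mkdir(parents=True, exist_ok=True)
    io.write_das_geojson(result.das, out / "das.geojson")
    io.write_users_csv(result.users, out / "users.csv")
    io.write_yaml(result.config.to_dict(), out / "config.yaml")
    io.write_buffers_csv(result.observations, out / "buffers.csv")
    result.design.to_csv(out / "design.csv")
    _table1_frame(result.design).to_csv(out / "table1_summary.csv")
    result.irr.to_csv(out / "table2_irr.csv")
    comparison = {
        "aic": {k: result.fits[k].aic for k in ("density_only", "full", "selected")},
        "pseudo_r2": result.pseudo_r2,
        "lrt": result.lrt,
        "selected_terms": list(result.selected_terms),
        "n_outliers": {k: v.n_flagged for k, v in result.outlier_reports.items()},
        "quasi_poisson_scale": result.fits["selected"].quasi_poisson_scale(),
    }
    (out / "model_comparison.json").write_text(
        json.dumps(comparison, indent=2, sort_keys=True)
    )
    result.outlier_reports["selected"].table.to_csv(out / "outliers.csv")
    export_geojson(
        result.observations,
        out / "buffers.geojson",
        fit=result.fits["selected"],
        outliers=result.outlier_reports["selected"],
    )
    (out / "audit.json").write_text(
        json.dumps(result.audit.to_dict(), indent=2, sort_keys=True)
    )
    manifest = {
        "package": "geodens",
        "seeds": {
            "simulation": result.config.sim.rng_seed,
            "sampling": result.config.seed_sampling,
        },
        "config": result.config.to_dict(),
        "n_users": len(result.users),
        "n_buffers": len(result.observations),
        "files": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
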