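"""Areal interpolation of DA-level covariates to sampling buffers.

Explanatory variables live on dissemination areas while the outcome lives on
sampling buffers, so each buffer covariate is a combined area- and
population-weighted average over intersecting DAs:

    x_bar_i = sum_j w_ij x_j / sum_j w_ij,   w_ij = P_j * (a_ij / A_j)

where ``a_ij`` is the area of DA *j* inside buffer *i*, ``A_j`` the DA's
total area and ``P_j`` its population. The weight is the DA population times
the proportion of the DA falling inside the sampling radius; since no closed
form is standard, this defining formula is stated here prominently.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from shapely.strtree import STRtree

from ._geometry import buffer_disc
from .covariates import COVARIATE_NAMES, scale_to_model
from .types import BufferObservation, DisseminationArea, SLOT_LABELS


def intersection_fraction(
    da: DisseminationArea, sampling_point: tuple[float, float], radius: float
) -> float:
    """Proportion of the DA polygon lying inside the sampling disc, in [0, 1]."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    if da.polygon.area <= 0:
        raise ValueError(f"zero-area polygon for DA {da.id}")
    disc = buffer_disc(sampling_point[0], sampling_point[1], radius)
    frac = da.polygon.intersection(disc).area / da.polygon.area
    return float(min(max(frac, 0.0), 1.0))


def areal_weights(
    das: Sequence[DisseminationArea],
    sampling_point: tuple[float, float],
    radius: float,
    tree: STRtree | None = None,
) -> pd.DataFrame:
    """Per-DA weights for one buffer: intersection fraction and population weight.

    Only DAs with positive intersection are returned. Pass a prebuilt
    ``STRtree`` over ``[da.polygon for da in das]`` to amortize lookups
    across buffers.
    """
    disc = buffer_disc(sampling_point[0], sampling_point[1], radius)
    if tree is None:
        tree = STRtree([da.polygon for da in das])
    idx = tree.query(disc, predicate="intersects")
    rows = []
    for i in sorted(int(k) for k in idx):
        da = das[i]
        inter = da.polygon.intersection(disc).area
        if inter <= 0:
            continue
        frac = min(inter / da.polygon.area, 1.0)
        rows.append(
            {
                "da_id": da.id,
                "da_index": i,
                "intersection_fraction": frac,
                "weight": da.population * frac,
            }
        )
    return pd.DataFrame(rows, columns=["da_id", "da_index", "intersection_fraction", "weight"])


def weighted_covariate(
    das: Sequence[DisseminationArea],
    sampling_point: tuple[float, float],
    radius: float,
    covariate_name: str,
    tree: STRtree | None = None,
) -> float:
    """Combined area- and population-weighted covariate average for one buffer.

    Raises ``ValueError`` when every weight is zero (the buffer should then
    be excluded from the analysis).
    """
    if covariate_name not in COVARIATE_NAMES:
        raise KeyError(f"unknown covariate: {covariate_name}")
    w = areal_weights(das, sampling_point, radius, tree=tree)
    total = w["weight"].sum() if len(w) else 0.0
    if total <= 0:
        raise ValueError("all-zero areal weights; buffer must be excluded")
    values = np.array([das[i].covariates[covariate_name] for i in w["da_index"]])
    return float((w["weight"].to_numpy() * values).sum() / total)


def build_design_matrix(
    buffers: Sequence[BufferObservation],
    das: Sequence[DisseminationArea],
    covariate_names: Sequence[str] = COVARIATE_NAMES,
) -> pd.DataFrame:
    """Model-ready design matrix: one row per retained buffer.

    Columns are the areal-weighted covariates on the regression scale
    (population density per 100 persons/km^2, income per Can $1000), the
    sampling-slot indicator block with the first slot as reference, the
    integer ``density`` outcome, and bookkeeping columns (``x``, ``y``,
    ``slot``, ``sample_order``, ``user_count``, ``ambiguous_count``,
    ``land_area``) used by the offset-mode model and the exports. The index
    is the sampling-point id.
    """
    for name in covariate_names:
        if name not in COVARIATE_NAMES:
            raise KeyError(f"unknown covariate: {name}")
    tree = STRtree([da.polygon for da in das])
    rows = []
    for obs in buffers:
        pt = (obs.point.x, obs.point.y)
        row: dict[str, float] = {
            "point_id": obs.point.id,
            "x": obs.point.x,
            "y": obs.point.y,
            "slot": obs.point.slot,
            "sample_order": obs.point.sample_order,
            "user_count": obs.user_count,
            "ambiguous_count": obs.ambiguous_count,
            "land_area": obs.land_area,
            "density": obs.density,
        }
        w = areal_weights(das, pt, obs.radius, tree=tree)
        total = w["weight"].sum() if len(w) else 0.0
        if total <= 0:
            raise ValueError(
                f"buffer {obs.point.id}: all-zero areal weights; "
                "it should have been excluded by the land-area rule"
            )
        wts = w["weight"].to_numpy()
        for name in covariate_names:
            values = np.array([das[i].covariates[name] for i in w["da_index"]])
            row[name] = scale_to_model(name, float((wts * values).sum() / total))
        for slot in SLOT_LABELS[1:]:
            row[f"slot_{slot}"] = 1.0 if obs.point.slot == slot else 0.0
        rows.append(row)
    design = pd.DataFrame(rows).set_index("point_id")
    if design[list(covariate_names)].isna().any().any():
        raise ValueError("design matrix contains missing covariate cells")
    return design


def summarize_covariates(
    data: pd.DataFrame | Sequence[DisseminationArea],
    covariate_names: Sequence[str] = COVARIATE_NAMES,
) -> pd.DataFrame:
    """Descriptive table: median and Q1–Q3 per covariate.

    Accepts either a design matrix (columns already on the regression scale)
    or a DA list (raw units). Quantiles use the linear-interpolation rule.
    Requires at least 4 rows.
    """
    if isinstance(data, pd.DataFrame):
        df = data
    else:
        df = pd.DataFrame([da.covariates for da in data])
    cols = [c for c in covariate_names if c in df.columns]
    if len(df) < 4:
        raise ValueError("need at least 4 rows to summarize")
    out = []
    for c in cols:
        q1, med, q3 = np.quantile(df[c].to_numpy(float), [0.25, 0.5, 0.75])
        out.append({"covariate": c, "median": med, "q1": q1, "q3": q3})
    return pd.DataFrame(out).set_index("covariate")
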