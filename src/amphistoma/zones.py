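"""Voronoi stomatal zones and the length-zone-area association.

The stomatal zone of a stomate is the part of the imaged window closer to
it than to any other stomate — its Voronoi cell clipped to the window
rectangle — and serves as a proxy for the mesophyll volume it supplies.
Cells are bounded by reflecting the point set across all four window edges
before tessellating, which makes every clipped cell exact; boundary stomata
keep their clipped zones (no buffer exclusion).

The association between guard-cell length and zone area is estimated per
(treatment, surface) group by ordinary least squares with a hierarchical
bootstrap (resample plants, then leaves within plants, then refit) for the
95 % percentile interval.  This replaces a full mixed-effects treatment:
the estimand is the marginal within-group slope, which the cluster
bootstrap delivers directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi
from shapely.geometry import Polygon, box

from .leaf_data import SurfaceRecord
from .synthetic import _rng


@dataclass(frozen=True)
class ZoneSet:
    """Clipped Voronoi cells (one per stomate, input order) tiling the window."""

    surface_id: str
    polygons: list
    areas: np.ndarray
    window: tuple[float, float]


@dataclass(frozen=True)
class SlopeEstimate:
    """Per-group OLS slope with a hierarchical-bootstrap percentile interval."""

    group: tuple[str, str]
    slope: float
    ci_low: float
    ci_high: float
    n_boot: int
    n_stomata: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.slope <= self.ci_high):
            raise ValueError(f"{self.group}: slope outside its own interval")


def voronoi_zones(record: SurfaceRecord) -> ZoneSet:
    """Voronoi cells of the stomata clipped to the window rectangle.

    Duplicated centroids are rejected (their cells would be undefined).
    A single stomate owns the whole window.
    """
    if record.n < 1:
        raise ValueError("need at least one stomate")
    w, h = record.window
    win = box(0.0, 0.0, w, h)
    if record.n == 1:
        return ZoneSet(record.surface_id, [win], np.array([w * h]), (w, h))

    pts = record.xy
    rounded = np.round(pts, 12)
    _, idx, counts = np.unique(rounded, axis=0, return_index=True, return_counts=True)
    if np.any(counts > 1):
        dup_rows = sorted(int(i) for i in idx[counts > 1])
        raise ValueError(f"duplicate stomatal centroids at rows {dup_rows}")

    # reflect across the four edges so every original cell is bounded and
    # terminates exactly on the window boundary
    mirrors = [
        np.column_stack([-pts[:, 0], pts[:, 1]]),
        np.column_stack([2 * w - pts[:, 0], pts[:, 1]]),
        np.column_stack([pts[:, 0], -pts[:, 1]]),
        np.column_stack([pts[:, 0], 2 * h - pts[:, 1]]),
    ]
    vor = Voronoi(np.vstack([pts] + mirrors))
    polys = []
    areas = np.empty(record.n)
    for i in range(record.n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) == 0:
            raise RuntimeError(f"unbounded Voronoi cell for stomate {i}")
        poly = Polygon(vor.vertices[region]).intersection(win)
        polys.append(poly)
        areas[i] = poly.area
    return ZoneSet(record.surface_id, polys, areas, (w, h))


def _fit_slope(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: zero variance")
    return float(np.polyfit(x, y, 1)[0])


def zone_length_slope(
    records: Sequence[SurfaceRecord],
    n_boot: int = 1000,
    seed=None,
    direction: str = "area_on_length",
) -> dict[tuple[str, str], SlopeEstimate]:
    """Length-zone-area slope per (treatment, surface) group.

    ``direction="area_on_length"`` regresses zone area (mm²) on guard-cell
    length (μm), the convention used for reporting; ``"length_on_area"``
    swaps the roles, which is the direction in which a planted generative
    coefficient is recovered without attenuation.  The 95 % interval comes
    from ``n_boot`` hierarchical resamples: plants with replacement, then
    leaves within each drawn plant, then an OLS refit on the pooled stomata.
    """
    if direction not in ("area_on_length", "length_on_area"):
        raise ValueError("direction must be 'area_on_length' or 'length_on_area'")
    rng = _rng(seed)

    rows = []
    for rec in records:
        if rec.lengths is None:
            continue
        keep = ~np.isnan(rec.lengths)
        if keep.sum() == 0:
            continue
        areas = voronoi_zones(rec).areas
        for length, area in zip(rec.lengths[keep], areas[keep]):
            rows.append((rec.treatment, rec.surface, rec.plant_id, rec.leaf_id,
                         float(length), float(area)))
    if not rows:
        raise ValueError("no stomata with measured lengths")
    df = pd.DataFrame(rows, columns=["treatment", "surface", "plant", "leaf",
                                     "length", "area"])

    out: dict[tuple[str, str], SlopeEstimate] = {}
    for (treatment, surface), grp in df.groupby(["treatment", "surface"], sort=True):
        if len(grp) < 3:
            raise ValueError(f"group {(treatment, surface)}: need >= 3 stomata with lengths")
        plants = grp["plant"].unique()
        n_leaves = grp.groupby("plant")["leaf"].nunique().sum()
        if n_leaves < 2:
            raise ValueError(f"group {(treatment, surface)}: need >= 2 leaves for resampling")
        if direction == "area_on_length":
            x, y = grp["length"].to_numpy(), grp["area"].to_numpy()
        else:
            x, y = grp["area"].to_numpy(), grp["length"].to_numpy()
        slope = _fit_slope(x, y)

        leaves_of = {p: grp.loc[grp["plant"] == p, "leaf"].unique() for p in plants}
        cells = {(p, l): grp.index[(grp["plant"] == p) & (grp["leaf"] == l)].to_numpy()
                 for p in plants for l in leaves_of[p]}
        boot = np.empty(n_boot)
        for b in range(n_boot):
            chosen_plants = rng.choice(plants, size=len(plants), replace=True)
            idx_parts = []
            for p in chosen_plants:
                ls = leaves_of[p]
                chosen_leaves = rng.choice(ls, size=len(ls), replace=True)
                idx_parts.extend(cells[(p, l)] for l in chosen_leaves)
            idx = np.concatenate(idx_parts)
            xb = df.loc[idx, "length" if direction == "area_on_length" else "area"].to_numpy()
            yb = df.loc[idx, "area" if direction == "area_on_length" else "length"].to_numpy()
            if np.ptp(xb) == 0:
                boot[b] = np.nan
                continue
            boot[b] = _fit_slope(xb, yb)
        boot = boot[~np.isnan(boot)]
        lo, hi = np.percentile(boot, [2.5, 97.5])
        out[(str(treatment), str(surface))] = SlopeEstimate(
            group=(str(treatment), str(surface)),
            slope=slope, ci_low=float(min(lo, slope)), ci_high=float(max(hi, slope)),
            n_boot=n_boot, n_stomata=len(grp),
        )
    return out
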