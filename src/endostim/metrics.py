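"""Decision metrics on the solved field: wall average, homogeneity, LV.

The analysis window is a 50 mm axial section centered on the electrode
group. The wall region of interest (ROI) is the upper arterial wall strip
(1.5 mm thick) in that window; the tissue ROI is the muscle block extending
100 mm outward from the outer wall surface over the same window. The
localization value LV = mean|E|_wall / mean|E|_tissue quantifies how
concentrated the stimulus is on the treatment target; homogeneity is the
normalized standard deviation 100 * std/mean over the wall ROI.

All statistics are area-weighted over cell centers falling inside the ROI
rectangle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import materials as mat
from .errors import RegionError
from .electrostatics import FieldSolution
from .geometry import DomainModel

log = logging.getLogger(__name__)

#: Axial length of the analysis window, m.
ROI_WINDOW = 0.050
#: Outward extent of the tissue ROI from the outer wall, m.
TISSUE_DEPTH = 0.100


@dataclass(frozen=True)
class Rect:
    """Axis-aligned ROI rectangle (meters)."""

    x0: float
    x1: float
    y0: float
    y1: float


@dataclass(frozen=True)
class RegionOfInterest:
    wall: Rect
    tissue: Rect


@dataclass(frozen=True)
class WallMetrics:
    """The three wall-field decision metrics."""

    mean_field: float          # V/m
    normalized_std: float      # percent
    localization_value: float  # dimensionless


def default_rois(domain: DomainModel, center_x: float = 0.0,
                 window: float = ROI_WINDOW) -> RegionOfInterest:
    """ROIs for the standard analysis: upper wall strip + outward muscle.

    The tissue ROI spans the upper muscle from the outer wall surface to
    the edge of the geometry — nominally 100 mm in the reference box
    (92.5 mm of muscle above the wall); a remote-ground domain extends
    further and so does its tissue ROI. A deviation from the nominal
    depth is logged.
    """
    p = domain.params
    x0, x1 = center_x - window / 2, center_x + window / 2
    wall = Rect(x0, x1, p.lumen_radius, p.outer_wall)
    top = float(domain.y.faces[-1])
    depth = top - p.outer_wall
    if abs(depth - TISSUE_DEPTH) > 0.1 * TISSUE_DEPTH:
        log.info("tissue ROI depth %.1f mm (nominal %.0f mm): averaging "
                 "to the edge of the geometry", 1e3 * depth,
                 1e3 * TISSUE_DEPTH)
    tissue = Rect(x0, x1, p.outer_wall, top)
    return RegionOfInterest(wall, tissue)


def roi_mask(domain: DomainModel, rect: Rect) -> np.ndarray:
    """Boolean (ny, nx) mask of cells whose centers fall inside the rect."""
    xc, yc = np.meshgrid(domain.x.centers, domain.y.centers)
    return (xc > rect.x0) & (xc < rect.x1) & (yc > rect.y0) & (yc < rect.y1)


def _weighted_stats(values: np.ndarray, weights: np.ndarray
                    ) -> tuple[float, float]:
    mean = float(np.average(values, weights=weights))
    var = float(np.average((values - mean) ** 2, weights=weights))
    return mean, np.sqrt(var)


def _roi_values(solution: FieldSolution, rect: Rect,
                require_material: int | None = None,
                restrict_material: int | None = None):
    domain = solution.domain
    mask = roi_mask(domain, rect)
    if not mask.any():
        raise RegionError("region of interest contains no cells")
    if require_material is not None:
        wrong = mask & (domain.material != require_material)
        if wrong.any():
            raise RegionError(
                f"ROI contains {int(wrong.sum())} cells that are not "
                f"{mat.LABEL_NAMES[require_material]}")
    if restrict_material is not None:
        # e.g. the tissue ROI may contain extravascular electrode disks;
        # the average is taken over the tissue cells only
        mask = mask & (domain.material == restrict_material)
        if not mask.any():
            raise RegionError("region of interest contains no tissue cells")
    return solution.field_magnitude[mask], domain.cell_areas[mask]


def wall_average(solution: FieldSolution, rect: Rect) -> float:
    """Area-weighted mean |E| over the wall ROI, V/m."""
    values, weights = _roi_values(solution, rect, require_material=mat.WALL)
    return _weighted_stats(values, weights)[0]


def homogeneity(solution: FieldSolution, rect: Rect) -> float:
    """Normalized standard deviation of |E| over the wall ROI, percent."""
    values, weights = _roi_values(solution, rect, require_material=mat.WALL)
    mean, std = _weighted_stats(values, weights)
    if mean <= 0:
        raise RegionError("homogeneity undefined: zero mean field in ROI")
    return 100.0 * std / mean


def localization_value(solution: FieldSolution, wall: Rect,
                       tissue: Rect) -> float:
    """LV = mean|E| over the wall ROI / mean|E| over the tissue ROI."""
    wall_mean = wall_average(solution, wall)
    t_values, t_weights = _roi_values(solution, tissue,
                                      restrict_material=mat.MUSCLE)
    tissue_mean = _weighted_stats(t_values, t_weights)[0]
    if tissue_mean <= 0:
        raise RegionError("localization undefined: zero tissue mean field")
    return wall_mean / tissue_mean


def wall_profile(solution: FieldSolution):
    """|E| averaged through the upper wall thickness, per axial position.

    Returns a pandas DataFrame with columns ``x_mm`` and
    ``mean_field_V_per_m`` — the field profile "along the arterial length"
    used to visualize stimulus uniformity.
    """
    import pandas as pd
    domain = solution.domain
    p = domain.params
    rows = (domain.y.centers > p.lumen_radius) & \
        (domain.y.centers < p.outer_wall)
    in_vessel = np.abs(domain.x.centers) < p.vessel_length / 2
    weights = domain.y.widths[rows]
    prof = np.average(solution.field_magnitude[rows, :], axis=0,
                      weights=weights)
    return pd.DataFrame({"x_mm": 1e3 * domain.x.centers[in_vessel],
                         "mean_field_V_per_m": prof[in_vessel]})


def wall_metrics(solution: FieldSolution,
                 rois: RegionOfInterest | None = None) -> WallMetrics:
    """All three metrics from one solution (default ROIs if not given)."""
    if rois is None:
        cx = 0.0
        if solution.domain.configuration is not None:
            cx = solution.domain.configuration.group_center()
        rois = default_rois(solution.domain, center_x=cx)
    return WallMetrics(
        mean_field=wall_average(solution, rois.wall),
        normalized_std=homogeneity(solution, rois.wall),
        localization_value=localization_value(solution, rois.wall,
                                              rois.tissue),
    )
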