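"""Planar computational domain: artery in muscle, rasterized to a grid.

The model is a 2-D Cartesian cross-section through the vessel axis (unit
depth for all volumetric quantities). The x axis runs along the vessel, the
y axis across it; the origin sits at the vessel's axial and radial center.
The lumen is a horizontal strip of height equal to the vessel diameter,
bounded above and below by wall strips of the stated thickness, embedded in
a rectangular muscle block.

The grid is a tensor-product rectilinear grid: uniform fine spacing in a
window that contains the vessel cross-section, the electrodes and the
analysis regions, with geometric coarsening toward the far muscle
boundaries. Material interfaces in the fine window coincide with cell
faces, so rasterization by cell center is exact there.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import cached_property

import numpy as np

from . import materials as mat
from .errors import (ConfigurationError, GeometryError, PlacementError,
                     ResolutionError)

# ---------------------------------------------------------------------------
# 1-D rectilinear axes


@dataclass(frozen=True)
class Axis:
    """A 1-D rectilinear axis defined by its cell face coordinates."""

    faces: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.faces, dtype=float)
        if f.ndim != 1 or f.size < 2 or np.any(np.diff(f) <= 0):
            raise GeometryError("axis faces must be strictly increasing")
        object.__setattr__(self, "faces", f)

    @cached_property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.faces[:-1] + self.faces[1:])

    @cached_property
    def widths(self) -> np.ndarray:
        return np.diff(self.faces)

    @property
    def n(self) -> int:
        return self.faces.size - 1


def _graded_widths(span: float, h0: float, ratio: float, h_max: float
                   ) -> np.ndarray:
    """Cell widths covering ``span``, growing geometrically from ``h0``."""
    if span <= 0:
        return np.zeros(0)
    widths, w, total = [], h0, 0.0
    while total < span:
        w = min(w * ratio, h_max)
        widths.append(w)
        total += w
    out = np.asarray(widths)
    return out * (span / total)  # rescale so the region closes exactly


def graded_axis(lo: float, hi: float, fine_lo: float, fine_hi: float,
                h: float, ratio: float = 1.35, h_max: float = 0.02) -> Axis:
    """Axis uniform at spacing ``h`` on [fine_lo, fine_hi], graded outside."""
    if not (lo <= fine_lo < fine_hi <= hi):
        raise GeometryError("fine window must lie inside the axis extent")
    n_fine = round((fine_hi - fine_lo) / h)
    if n_fine < 1 or abs(n_fine * h - (fine_hi - fine_lo)) > 1e-9:
        raise GeometryError("fine spacing must divide the fine window")
    fine = fine_lo + h * np.arange(n_fine + 1)
    left_w = _graded_widths(fine_lo - lo, h, ratio, h_max)
    right_w = _graded_widths(hi - fine_hi, h, ratio, h_max)
    left = fine_lo - np.cumsum(left_w)[::-1]
    right = fine_hi + np.cumsum(right_w)
    return Axis(np.concatenate([left, fine, right]))


def uniform_axis(lo: float, hi: float, n: int) -> Axis:
    return Axis(np.linspace(lo, hi, n + 1))


# ---------------------------------------------------------------------------
# Geometry parameters and electrode configurations


@dataclass(frozen=True)
class GeometryParams:
    """Dimensions of the artery-in-muscle world (all in meters)."""

    lumen_diameter: float = 0.012
    wall_thickness: float = 0.0015
    vessel_length: float = 0.250
    muscle_width: float = 0.700     # axial extent of the muscle box
    muscle_height: float = 0.200    # transverse extent, vessel centered
    top_extension: float = 0.0      # extra height above, for remote returns

    @property
    def lumen_radius(self) -> float:
        return self.lumen_diameter / 2

    @property
    def outer_wall(self) -> float:
        """Transverse coordinate of the outer wall surface (upper side)."""
        return self.lumen_radius + self.wall_thickness


SCHEME_NAMES = {1: "endo_bipolar",
                2: "endo_active_extravascular_return",
                3: "remote_ground"}


@dataclass(frozen=True)
class ElectrodeConfiguration:
    """One of the three stimulation schemes.

    Scheme 1 (endo_bipolar): ``n_electrodes`` is the total endovascular
    electrode count; polarity alternates, with the center electrode active
    when the count is odd (so n=3 is one active flanked by two returns).

    Scheme 2 (endo_active_extravascular_return): ``n_electrodes`` active
    endovascular electrodes; two 3 mm circular return electrodes sit 1.5 mm
    outside the wall, one above and one below the vessel, at the active
    group's axial midpoint.

    Scheme 3 (remote_ground): ``n_electrodes`` active endovascular
    electrodes; a 150 x 15 mm grounded plate sits 40 cm above the outer
    wall, on the upper domain boundary.

    Endovascular electrodes are catheter-mounted bands: in the 2-D
    cross-section through the vessel axis a band appears as a symmetric
    pair of 1 x 1 mm squares whose centers sit at +/- the catheter radius
    from the centerline (both carrying the band's potential). Set
    ``catheter_diameter = 0`` for a single square on the centerline.
    """

    scheme: int
    n_electrodes: int
    inter_electrode_distance: float = 0.0   # center-to-center, m
    pulse_potential: float = 40.0           # Vp, volts
    electrode_size: tuple[float, float] = (0.001, 0.001)  # (axial, transverse)
    catheter_diameter: float = 0.003        # band pair separation, m
    return_diameter: float = 0.003          # scheme 2 disks
    return_gap: float = 0.0015              # scheme 2: disk edge to outer wall
    remote_size: tuple[float, float] = (0.150, 0.015)  # scheme 3 plate (x, y)
    remote_distance: float = 0.400          # scheme 3: outer wall to plate

    def __post_init__(self):
        if self.scheme not in SCHEME_NAMES:
            raise ConfigurationError(f"unknown scheme {self.scheme}")
        if self.n_electrodes < 1:
            raise ConfigurationError("need at least one endovascular electrode")
        if self.scheme == 1 and self.n_electrodes < 2:
            raise ConfigurationError(
                "scheme 1 needs >= 2 electrodes (active and return in-lumen)")
        if self.n_electrodes > 1:
            if self.inter_electrode_distance < self.electrode_size[0]:
                raise ConfigurationError(
                    "electrodes overlap: inter-electrode distance "
                    f"{self.inter_electrode_distance} m < electrode width "
                    f"{self.electrode_size[0]} m")

    @property
    def scheme_name(self) -> str:
        return SCHEME_NAMES[self.scheme]

    def endovascular_electrodes(self) -> list[tuple[float, float]]:
        """(axial center, potential) of each in-lumen electrode.

        Centers are symmetric about x = 0 with equal spacing.
        """
        n, d, vp = self.n_electrodes, self.inter_electrode_distance, \
            self.pulse_potential
        span = (n - 1) * d
        centers = -span / 2 + d * np.arange(n)
        if self.scheme == 1:
            if n % 2:  # center electrode active, alternating outward
                pots = [vp if (i - n // 2) % 2 == 0 else 0.0 for i in range(n)]
            else:
                pots = [vp if i % 2 == 0 else 0.0 for i in range(n)]
        else:      # schemes 2, 3: every endovascular electrode is active
            pots = [vp] * n
        return list(zip(centers.tolist(), pots))

    def group_center(self) -> float:
        return 0.0


# ---------------------------------------------------------------------------
# The rasterized domain


@dataclass(frozen=True)
class DomainModel:
    """Geometry + per-cell material map on a rectilinear grid.

    ``material`` has shape (ny, nx) with integer labels from
    :mod:`endostim.materials`. After electrode placement,
    ``electrode_potential`` holds the Dirichlet potential on electrode cells
    and NaN elsewhere.
    """

    params: GeometryParams
    x: Axis
    y: Axis
    material: np.ndarray
    electrode_potential: np.ndarray
    configuration: ElectrodeConfiguration | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.material.shape

    @property
    def n_cells(self) -> int:
        return self.material.size

    @cached_property
    def cell_areas(self) -> np.ndarray:
        return np.outer(self.y.widths, self.x.widths)

    @cached_property
    def electrode_mask(self) -> np.ndarray:
        return np.isfinite(self.electrode_potential)

    def property_map(self, attr: str, perfusion_factor: float = 1.0,
                     overrides=None) -> np.ndarray:
        """Per-cell map of one material property (shape (ny, nx))."""
        values = np.empty(4)
        for label, name in mat.LABEL_NAMES.items():
            props = mat.material_lookup(name, perfusion_factor, overrides)
            values[label] = getattr(props, attr)
        return values[self.material]

    def label_area(self, label: int) -> float:
        """Total cell area carrying a given material label."""
        return float(self.cell_areas[self.material == label].sum())


def build_domain(params: GeometryParams | None = None,
                 spacing: float = 0.25e-3,
                 axial_spacing: float | None = None,
                 fine_half_width: float = 0.080,
                 fine_half_height: float = 0.013,
                 grading_ratio: float = 1.35) -> DomainModel:
    """Rasterize the artery-in-muscle geometry to a rectilinear grid.

    Parameters
    ----------
    spacing : float
        Transverse (y) cell size in the fine window, m. Must be <= 0.5 mm so
        the 1.5 mm wall spans at least 3 cells, and must divide the wall
        thickness and lumen radius so interfaces land on cell faces.
    axial_spacing : float, optional
        Axial (x) cell size in the fine window; defaults to ``2 * spacing``.
    fine_half_width, fine_half_height : float
        Half-extent of the uniformly fine window around the vessel center.
    """
    p = params or GeometryParams()
    if spacing > 0.5e-3 + 1e-12:
        raise ResolutionError(
            f"spacing {spacing} m too coarse: the {p.wall_thickness} m wall "
            "must span >= 3 cells (need <= 0.5 mm)")
    for feature in (p.wall_thickness, p.lumen_radius):
        if abs(round(feature / spacing) * spacing - feature) > 0.1 * spacing:
            raise ResolutionError(
                f"spacing {spacing} m does not divide feature {feature} m")
    if (p.lumen_diameter + 2 * p.wall_thickness >= p.muscle_height
            or p.vessel_length >= p.muscle_width):
        raise GeometryError("vessel does not fit inside the muscle box")

    hx = axial_spacing if axial_spacing is not None else 2 * spacing
    half_w, half_h = p.muscle_width / 2, p.muscle_height / 2
    fhh = min(fine_half_height, half_h)
    fhh = round(fhh / spacing) * spacing
    fhw = min(fine_half_width, half_w)
    fhw = round(fhw / hx) * hx
    x = graded_axis(-half_w, half_w, -fhw, fhw, hx, grading_ratio)
    y = graded_axis(-half_h, half_h + p.top_extension, -fhh, fhh,
                    spacing, grading_ratio)

    xc, yc = np.meshgrid(x.centers, y.centers)
    material = np.full((y.n, x.n), mat.MUSCLE, dtype=np.int8)
    in_vessel_x = np.abs(xc) < p.vessel_length / 2
    material[in_vessel_x & (np.abs(yc) < p.outer_wall)] = mat.WALL
    material[in_vessel_x & (np.abs(yc) < p.lumen_radius)] = mat.BLOOD

    potential = np.full((y.n, x.n), np.nan)
    return DomainModel(p, x, y, material, potential)


def _overlap_fraction(faces: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Per-cell fraction of each 1-D cell covered by the interval [lo, hi]."""
    left = np.maximum(faces[:-1], lo)
    right = np.minimum(faces[1:], hi)
    return np.clip(right - left, 0.0, None) / np.diff(faces)


def _paint_rect(domain: DomainModel, x0, x1, y0, y1, potential: float,
                material: np.ndarray, pot_map: np.ndarray) -> int:
    # a cell belongs to the electrode when the rectangle covers at least
    # half of it (exact for face-aligned electrodes in the fine window,
    # robust for the remote plate sitting in the coarsened region)
    fx = _overlap_fraction(domain.x.faces, x0, x1)
    fy = _overlap_fraction(domain.y.faces, y0, y1)
    sel = np.outer(fy, fx) >= 0.5 - 1e-9
    if np.any(sel & np.isfinite(pot_map)):
        raise ConfigurationError("electrodes overlap")
    material[sel] = mat.ELECTRODE
    pot_map[sel] = potential
    return int(sel.sum())


def add_electrode_rect(domain: DomainModel, x0: float, x1: float,
                       y0: float, y1: float, potential: float) -> DomainModel:
    """Paint a rectangular Dirichlet electrode onto a copy of the domain.

    Low-level hook used by the verification fixtures; study configurations
    go through :func:`place_electrodes`.
    """
    material = domain.material.copy()
    pot = domain.electrode_potential.copy()
    n = _paint_rect(domain, x0, x1, y0, y1, potential, material, pot)
    if n == 0:
        raise PlacementError("electrode rectangle contains no cell centers")
    return replace(domain, material=material, electrode_potential=pot)


def place_electrodes(domain: DomainModel, config: ElectrodeConfiguration
                     ) -> DomainModel:
    """Place a configuration's electrodes; returns a new DomainModel.

    Endovascular electrodes are centered on the lumen centerline and the
    group on the vessel's axial midpoint. Raises
    :class:`~endostim.errors.PlacementError` if any electrode leaves its
    required region and :class:`~endostim.errors.ConfigurationError` on
    overlap.
    """
    p = domain.params
    ex, ey = config.electrode_size
    span = (config.n_electrodes - 1) * config.inter_electrode_distance
    if span + ex > p.vessel_length:
        raise PlacementError("endovascular electrode group exceeds the vessel")
    if ey > p.lumen_diameter:
        raise PlacementError("electrode taller than the lumen")

    material = domain.material.copy()
    pot = domain.electrode_potential.copy()

    offsets = (0.0,) if config.catheter_diameter == 0 else \
        (-config.catheter_diameter / 2, config.catheter_diameter / 2)
    if max(abs(o) for o in offsets) + ey / 2 > p.lumen_radius:
        raise PlacementError("electrode band leaves the lumen")
    for cx, v in config.endovascular_electrodes():
        if abs(cx) + ex / 2 > p.vessel_length / 2:
            raise PlacementError(f"electrode at x={cx} outside the vessel")
        for oy in offsets:
            n = _paint_rect(domain, cx - ex / 2, cx + ex / 2,
                            oy - ey / 2, oy + ey / 2, v, material, pot)
            if n == 0:
                raise PlacementError("electrode not resolved by the grid")

    if config.scheme == 2:
        r = config.return_diameter / 2
        cy = p.outer_wall + config.return_gap + r
        xc, yc = np.meshgrid(domain.x.centers, domain.y.centers)
        for side in (+1, -1):
            sel = (xc - config.group_center()) ** 2 + \
                (yc - side * cy) ** 2 < r ** 2
            if not sel.any():
                raise PlacementError("return disk not resolved by the grid")
            if np.any(sel & np.isfinite(pot)):
                raise ConfigurationError("return disk overlaps an electrode")
            material[sel] = mat.ELECTRODE
            pot[sel] = 0.0

    elif config.scheme == 3:
        wx, wy = config.remote_size
        y0 = p.outer_wall + config.remote_distance
        if y0 + wy > p.muscle_height / 2 + p.top_extension + 1e-9:
            raise PlacementError(
                "remote return outside the domain; extend top_extension")
        n = _paint_rect(domain, -wx / 2, wx / 2, y0, y0 + wy, 0.0,
                        material, pot)
        if n == 0:
            raise PlacementError("remote return not resolved by the grid")

    out = replace(domain, material=material, electrode_potential=pot,
                  configuration=config)
    finite = np.isfinite(pot)
    if not finite.any():
        raise ConfigurationError("no electrodes placed")
    vals = pot[finite]
    if not (np.any(vals == 0.0) and np.any(vals != 0.0)):
        raise ConfigurationError(
            "need at least one active and one return electrode")
    return out


def crop_domain(domain: DomainModel, x0: float, x1: float,
                y0: float, y1: float
                ) -> tuple[DomainModel, tuple[slice, slice]]:
    """Sub-domain covering [x0,x1] x [y0,y1], snapped outward to faces.

    Returns the cropped model and the (row, column) slices into the parent
    grid. Used by the transient thermal solver, where the temperature
    perturbation stays within a few mm of the Joule sources.
    """
    xf, yf = domain.x.faces, domain.y.faces
    i0 = max(int(np.searchsorted(xf, x0, "right")) - 1, 0)
    i1 = min(int(np.searchsorted(xf, x1, "left")), xf.size - 1)
    j0 = max(int(np.searchsorted(yf, y0, "right")) - 1, 0)
    j1 = min(int(np.searchsorted(yf, y1, "left")), yf.size - 1)
    if i1 - i0 < 1 or j1 - j0 < 1:
        raise GeometryError("crop window contains no cells")
    rows, cols = slice(j0, j1), slice(i0, i1)
    cropped = replace(domain,
                      x=Axis(xf[i0:i1 + 1]), y=Axis(yf[j0:j1 + 1]),
                      material=domain.material[rows, cols].copy(),
                      electrode_potential=domain.electrode_potential[
                          rows, cols].copy())
    return cropped, (rows, cols)


def domain_for(config: ElectrodeConfiguration,
               params: GeometryParams | None = None,
               **grid_kwargs) -> DomainModel:
    """Build a domain sized for a configuration and place its electrodes.

    For scheme 3 the box is extended upward so the remote return plate ends
    on the outer boundary.
    """
    p = params or GeometryParams()
    if config.scheme == 3 and p.top_extension == 0.0:
        ext = (p.outer_wall + config.remote_distance + config.remote_size[1]
               - p.muscle_height / 2)
        p = replace(p, top_extension=max(ext, 0.0))
    base = build_domain(p, **grid_kwargs)
    return place_electrodes(base, config)
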