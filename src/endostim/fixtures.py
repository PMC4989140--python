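"""Analytic verification fixtures and canned study configurations.

Every fixture carries a closed-form expected value that is computable
without running the main solvers, plus a runner that feeds the same
scenario through them. Fixtures are generated programmatically; the
package ships no data files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import materials as mat
from .bioheat import BioheatSystem
from .electrostatics import solve
from .geometry import (DomainModel, ElectrodeConfiguration,
                       GeometryParams, add_electrode_rect, uniform_axis)


@dataclass(frozen=True)
class FixtureCase:
    """A named scenario with a closed-form expected value."""

    name: str
    description: str
    expected: float
    tolerance: float            # relative
    runner: Callable[[], float]
    config: dict = field(default_factory=dict)

    def run(self) -> float:
        return self.runner()

    def check(self) -> bool:
        value = self.run()
        return abs(value - self.expected) <= self.tolerance * abs(
            self.expected or 1.0)


def make_box_domain(width: float, height: float, nx: int, ny: int,
                    label: int = mat.MUSCLE) -> DomainModel:
    """Uniform single-material box, origin at the lower-left corner."""
    params = GeometryParams(muscle_width=width, muscle_height=height)
    x = uniform_axis(0.0, width, nx)
    y = uniform_axis(0.0, height, ny)
    material = np.full((ny, nx), label, dtype=np.int8)
    potential = np.full((ny, nx), np.nan)
    return DomainModel(params, x, y, material, potential)


def _slab_domain(gap: float, vp: float, n_gap: int, label_lower: int,
                 label_upper: int | None = None, width: float | None = None,
                 nx: int = 8) -> DomainModel:
    """Plate-capacitor slab: full-width Dirichlet rows top and bottom.

    The plates occupy one cell row each; because steel is ~10^7 x more
    conductive than tissue, the fixed potential effectively sits on the
    plate's inner face, so the tissue gap between the inner faces is
    exactly ``gap`` (n_gap interior rows) and the interior field is
    vp/gap to rounding.
    """
    dy = gap / n_gap
    height = (n_gap + 2) * dy
    width = width or gap
    domain = make_box_domain(width, height, nx, n_gap + 2, label_lower)
    if label_upper is not None:
        yc = domain.y.centers
        upper = yc > height / 2
        material = domain.material.copy()
        material[upper, :] = label_upper
        domain = DomainModel(domain.params, domain.x, domain.y, material,
                             domain.electrode_potential.copy())
    eps = 0.25 * dy
    domain = add_electrode_rect(domain, -eps, width + eps, -eps, dy - eps, vp)
    domain = add_electrode_rect(domain, -eps, width + eps,
                                height - dy + eps, height + eps, 0.0)
    return domain


def make_parallel_plate(gap: float, vp: float, n_gap: int = 40
                        ) -> FixtureCase:
    """Uniform slab between plates: |E| = vp / gap everywhere.

    Conductivity cancels in the Laplace problem, so any single material
    gives the same field.
    """
    if gap <= 0:
        raise ValueError("gap must be positive")

    def runner() -> float:
        domain = _slab_domain(gap, vp, n_gap, mat.MUSCLE)
        solution = solve(domain)
        interior = ~domain.electrode_mask
        return float(solution.field_magnitude[interior].mean())

    return FixtureCase(
        name=f"parallel_plate_{1e3 * gap:g}mm",
        description=f"plates {1e3 * gap:g} mm apart at {vp:g} V; "
                    f"uniform field {vp / gap:g} V/m",
        expected=vp / gap, tolerance=1e-6, runner=runner,
        config={"kind": "parallel_plate", "gap_m": gap, "vp": vp})


def make_two_layer_slab(gap: float, vp: float, n_gap: int = 40
                        ) -> FixtureCase:
    """Two-layer slab (blood below, wall above): E1/E2 = sigma2/sigma1.

    Current continuity across the interface fixes the field ratio to the
    inverse conductivity ratio.
    """
    s1 = mat.MATERIALS["blood"].electrical_conductivity
    s2 = mat.MATERIALS["wall"].electrical_conductivity

    def runner() -> float:
        domain = _slab_domain(gap, vp, n_gap, mat.BLOOD, mat.WALL)
        solution = solve(domain)
        interior = ~domain.electrode_mask
        lower = interior & (domain.material == mat.BLOOD)
        upper = interior & (domain.material == mat.WALL)
        e1 = float(solution.field_magnitude[lower].mean())
        e2 = float(solution.field_magnitude[upper].mean())
        return e1 / e2

    return FixtureCase(
        name=f"two_layer_slab_{1e3 * gap:g}mm",
        description="blood-over-wall slab; field ratio = sigma_wall/sigma_blood",
        expected=s2 / s1, tolerance=1e-6, runner=runner,
        config={"kind": "two_layer_slab", "gap_m": gap, "vp": vp})


def lumped_pennes_temperature(t: float, p: float, perfusion_factor: float,
                              material: str = "blood") -> float:
    """Closed-form point-tissue Pennes temperature at time t.

    With perfusion: T(t) = T_a + dT_inf (1 - exp(-t/tau)),
    dT_inf = p / (w c_b rho_b), tau = rho c_p / (w c_b rho_b).
    Without perfusion: linear ramp T_a + p t / (rho c_p).
    """
    props = mat.material_lookup(material, perfusion_factor)
    blood = mat.MATERIALS["blood"]
    rho_c = props.density * props.heat_capacity
    sink = props.perfusion_rate * blood.heat_capacity * blood.density
    if sink <= 0:
        return mat.BODY_TEMPERATURE_K + p * t / rho_c
    tau = rho_c / sink
    return mat.BODY_TEMPERATURE_K + (p / sink) * (1 - np.exp(-t / tau))


def make_lumped_thermal(p: float, perfusion_factor: float,
                        material: str = "blood", t_end: float = 0.05,
                        dt: float = 1e-4) -> FixtureCase:
    """Single-cell Pennes ODE stepped against its closed form."""
    if p < 0:
        raise ValueError("Joule power must be >= 0")
    # compare temperature RISE so the tolerance is not diluted by the
    # 310.15 K baseline
    expected = lumped_pennes_temperature(t_end, p, perfusion_factor,
                                         material) - mat.BODY_TEMPERATURE_K

    def runner() -> float:
        domain = make_box_domain(1e-3, 1e-3, 1, 1, mat.NAME_LABELS[material])
        system = BioheatSystem(domain, perfusion_factor)
        temp = np.full((1, 1), mat.BODY_TEMPERATURE_K)
        n = int(round(t_end / dt))
        power = np.full((1, 1), p)
        for _ in range(n):
            temp = system.step(temp, dt, power)
        return float(temp[0, 0]) - mat.BODY_TEMPERATURE_K

    return FixtureCase(
        name=f"lumped_pennes_p{p:g}_w{perfusion_factor:g}",
        description="point-tissue Pennes step response vs closed form",
        expected=expected, tolerance=2e-2, runner=runner,
        config={"kind": "lumped_thermal", "p": p,
                "perfusion_factor": perfusion_factor, "material": material})


#: (scheme, n_electrodes, optimal inter-electrode distance in mm) of the
#: nine studied combinations; None = single electrode, no spacing.
STUDY_COMBINATIONS: tuple[tuple[int, int, float | None], ...] = (
    (1, 2, 25.0), (1, 3, 17.0), (1, 4, 13.0),
    (2, 1, None), (2, 2, 35.0), (2, 3, 14.5),
    (3, 1, None), (3, 2, 20.0), (3, 3, 10.0),
)

#: The thermal scenarios: repetition rates x perfusion factors, all on the
#: optimal 4-electrode endovascular configuration.
THERMAL_SCENARIOS: tuple[tuple[float, float], ...] = tuple(
    (rate, perf) for rate in (1.0, 10.0, 50.0) for perf in (1.0, 0.1, 0.01))


def reference_configs() -> list[dict]:
    """Ready-to-run configuration dicts for the studied scenarios.

    Nine electrostatic (scheme, electrode count) combinations at their
    tabulated optimal spacings plus nine thermal sessions (three repetition
    rates x three perfusion factors).
    """
    configs: list[dict] = []
    for scheme, n, d_mm in STUDY_COMBINATIONS:
        configs.append({
            "kind": "electrostatic",
            "scheme": scheme,
            "n_electrodes": n,
            "distance_mm": d_mm,
            "pulse_potential": 40.0,
        })
    for rate, perf in THERMAL_SCENARIOS:
        configs.append({
            "kind": "thermal",
            "scheme": 1,
            "n_electrodes": 4,
            "distance_mm": 13.0,
            "pulse_potential": 40.0,
            "pulse_duration_ms": 10.0,
            "repetition_rate_hz": rate,
            "session_duration_s": 40.0,
            "perfusion_factor": perf,
        })
    return configs


def config_object(entry: dict) -> ElectrodeConfiguration:
    """Turn a reference-config dict into an ElectrodeConfiguration."""
    d = entry.get("distance_mm")
    return ElectrodeConfiguration(
        scheme=entry["scheme"], n_electrodes=entry["n_electrodes"],
        inter_electrode_distance=0.0 if d is None else d * 1e-3,
        pulse_potential=entry.get("pulse_potential", 40.0))


def standard_fixtures() -> list[FixtureCase]:
    """The default verification battery."""
    return [
        make_parallel_plate(gap=0.010, vp=40.0),
        make_parallel_plate(gap=0.040, vp=40.0),
        make_two_layer_slab(gap=0.020, vp=40.0),
        make_lumped_thermal(p=0.0, perfusion_factor=1.0),
        make_lumped_thermal(p=5e5, perfusion_factor=1.0),
        make_lumped_thermal(p=5e5, perfusion_factor=0.0, material="wall",
                            t_end=0.02),
    ]
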