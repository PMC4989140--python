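"""Dielectric and thermal material properties of the tissues and electrodes.

All values are in SI units. The database covers the four materials of the
artery-in-muscle model: blood filling the lumen, the arterial wall, the
surrounding skeletal muscle, and 304 stainless-steel electrodes. Baseline
lumen perfusion (58.34 1/s) corresponds to a flow of 1.575 L/min through a
6 mm inner-diameter vessel with a 50 mm heated length; a run's perfusion
factor (1.0 / 0.1 / 0.01) scales it to emulate progressive constriction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .errors import ConfigurationError

#: Arterial (core body) temperature, K. Also the uniform initial temperature.
BODY_TEMPERATURE_K = 310.15

#: Baseline blood perfusion rate in the lumen, 1/s.
BASELINE_PERFUSION_RATE = 58.34

#: Metabolic heat generation in perfused tissue (wall + muscle), W/m^3.
METABOLIC_HEAT = 33_800.0


@dataclass(frozen=True)
class MaterialProperties:
    """Electrical and thermal constants of one material.

    Attributes
    ----------
    electrical_conductivity : float
        sigma, S/m.
    relative_permittivity : float
        eps_r, dimensionless. Carried for completeness; the conduction model
        is purely resistive (charge-relaxation times eps/sigma are ~us, far
        below the 10 ms pulse plateau), so it is never used in a solve.
    density : float
        rho, kg/m^3.
    thermal_conductivity : float
        k, W/(m K).
    heat_capacity : float
        c_p, J/(kg K).
    perfusion_rate : float
        w_b, 1/s. Non-zero only for blood.
    metabolic_heat : float
        q''', W/m^3. Non-zero only for living tissue (wall, muscle).
    """

    electrical_conductivity: float
    relative_permittivity: float
    density: float
    thermal_conductivity: float
    heat_capacity: float
    perfusion_rate: float = 0.0
    metabolic_heat: float = 0.0

    def __post_init__(self) -> None:
        for name in ("electrical_conductivity", "density",
                     "thermal_conductivity", "heat_capacity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.perfusion_rate < 0:
            raise ValueError("perfusion_rate must be >= 0")
        if self.metabolic_heat < 0:
            raise ValueError("metabolic_heat must be >= 0")


#: Integer cell labels used in the rasterized material map.
BLOOD, WALL, MUSCLE, ELECTRODE = 0, 1, 2, 3

LABEL_NAMES = {BLOOD: "blood", WALL: "wall", MUSCLE: "muscle",
               ELECTRODE: "electrode"}
NAME_LABELS = {v: k for k, v in LABEL_NAMES.items()}

MATERIALS: dict[str, MaterialProperties] = {
    "blood": MaterialProperties(
        electrical_conductivity=0.7,
        relative_permittivity=1.4e3,
        density=1000.0,
        thermal_conductivity=0.52,
        heat_capacity=3640.0,
        perfusion_rate=BASELINE_PERFUSION_RATE,
        metabolic_heat=0.0,
    ),
    "wall": MaterialProperties(
        electrical_conductivity=0.25,
        relative_permittivity=1.0e7,
        density=1102.0,
        thermal_conductivity=0.46,
        heat_capacity=3306.0,
        perfusion_rate=0.0,
        metabolic_heat=METABOLIC_HEAT,
    ),
    "muscle": MaterialProperties(
        electrical_conductivity=0.25,
        relative_permittivity=1.4e7,
        density=1090.0,
        thermal_conductivity=0.49,
        heat_capacity=3421.0,
        perfusion_rate=0.0,
        metabolic_heat=METABOLIC_HEAT,
    ),
    # 304 stainless steel
    "electrode": MaterialProperties(
        electrical_conductivity=2.22e6,
        relative_permittivity=1.0,
        density=7900.0,
        thermal_conductivity=14.0,
        heat_capacity=477.0,
        perfusion_rate=0.0,
        metabolic_heat=0.0,
    ),
}


def material_lookup(label: str, perfusion_factor: float = 1.0,
                    overrides: dict[str, MaterialProperties] | None = None,
                    ) -> MaterialProperties:
    """Return the properties of a material label.

    Parameters
    ----------
    label : str
        One of ``blood``, ``wall``, ``muscle``, ``electrode``.
    perfusion_factor : float
        Multiplier on the baseline blood perfusion rate (1.0, 0.1, 0.01 in
        the study scenarios). Applied only to blood.
    overrides : dict, optional
        Replacement property records keyed by label, e.g. from a config file.
    """
    table = dict(MATERIALS)
    if overrides:
        table.update(overrides)
    try:
        props = table[label]
    except KeyError:
        raise ConfigurationError(f"unknown material label {label!r}") from None
    if label == "blood" and perfusion_factor != 1.0:
        if perfusion_factor < 0:
            raise ConfigurationError("perfusion_factor must be >= 0")
        props = replace(props,
                        perfusion_rate=props.perfusion_rate * perfusion_factor)
    return props
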