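"""Ferumoxytol dose tailoring and acquisition-geometry helpers.

The contrast protocol targets a fixed starting blood concentration of iron
(default 200 µg Fe/ml) from a ferumoxytol stock (default 6 mg Fe/ml),
assuming blood is 7% of body weight at unit density — so the injected stock
volume scales linearly with body mass. Ferumoxytol's long intravascular
half-life (~15 h) justifies treating the concentration as constant over an
imaging session; pharmacokinetic decay is not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Molar mass of iron, g/mol.
IRON_MOLAR_MASS = 55.845


@dataclass
class DoseSpec:
    """Dose calculation inputs for one animal."""

    body_mass: float  # grams
    blood_fraction: float = 0.07  # blood as fraction of body weight
    target_conc: float = 200.0  # µg Fe per ml blood
    stock_conc: float = 6.0  # mg Fe per ml stock

    def __post_init__(self) -> None:
        if min(self.body_mass, self.blood_fraction, self.stock_conc) <= 0:
            raise ValueError("body_mass, blood_fraction and stock_conc must be positive")
        if self.target_conc < 0:
            raise ValueError("target_conc must be >= 0")
        if self.blood_fraction >= 0.2:
            raise ValueError(f"blood_fraction {self.blood_fraction} implausibly large (>= 0.2)")


def injected_volume(spec: DoseSpec) -> float:
    """Millilitres of stock to inject to hit the target blood concentration.

    Blood volume is body_mass * blood_fraction (1 g of blood ~ 1 ml); the
    required iron mass is blood_volume * target_conc (µg), delivered from a
    stock of stock_conc mg/ml.
    """
    blood_ml = spec.body_mass * spec.blood_fraction
    fe_ug = blood_ml * spec.target_conc
    return fe_ug / (1000.0 * spec.stock_conc)


def fe_mass_conc_to_molar(conc: float, molar_mass: float = IRON_MOLAR_MASS) -> float:
    """Convert an iron mass concentration in µg/ml to mM.

    µg/ml divided by g/mol is mmol/l: 200 µg/ml of Fe is 3.58 mM.
    """
    if conc < 0:
        raise ValueError("concentration must be >= 0")
    return conc / molar_mass


def molar_to_fe_mass_conc(conc_mm: float, molar_mass: float = IRON_MOLAR_MASS) -> float:
    """Inverse of :func:`fe_mass_conc_to_molar` (mM to µg/ml)."""
    if conc_mm < 0:
        raise ValueError("concentration must be >= 0")
    return conc_mm * molar_mass


def isotropic_voxel_size(fov_mm: float, matrix: int) -> int:
    """Isotropic voxel edge in µm for a cubic FOV (mm) and matrix size.

    30 mm over a 180-point matrix gives 167 µm. Rounded to the nearest µm
    for display.
    """
    if matrix < 1:
        raise ValueError("matrix size must be >= 1")
    if fov_mm <= 0:
        raise ValueError("field of view must be positive")
    return int(round(fov_mm * 1000.0 / matrix))
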