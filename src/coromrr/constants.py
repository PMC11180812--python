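"""Physical constants used throughout the hemodynamic calculations.

All pressures are in mmHg, flows in ml/s, and geometry in mm at the API
surface; SI conversions happen inside the loss-coefficient formulas.
"""

from __future__ import annotations

from dataclasses import dataclass

PA_PER_MMHG = 133.322
"""Pascal per millimetre of mercury."""


@dataclass(frozen=True)
class PhysicalConstants:
    """Blood and gravity constants plus the calibration factors of the model.

    Parameters
    ----------
    rho : float
        Blood density in kg/m^3. The conventional assumed value for whole
        blood is 1050 kg/m^3.
    g : float
        Gravitational acceleration in m/s^2.
    mmhg_per_cm : float
        Hydrostatic pressure per centimetre of blood column, in mmHg/cm.
        The default 0.77 is the rounded value of ``rho * g * 0.01 / 133.322``
        and is kept at the published rounding so that corrected pressures
        reproduce the clinical arithmetic digit for digit.
    mu : float
        Dynamic blood viscosity in Pa*s.
    pa_per_mmhg : float
        Unit conversion, Pa per mmHg.
    k_e : float
        Dimensionless expansion-loss coefficient of the separation
        (Bernoulli-type) stenosis pressure-loss term.
    """

    rho: float = 1050.0
    g: float = 9.81
    mmhg_per_cm: float = 0.77
    mu: float = 0.0035
    pa_per_mmhg: float = PA_PER_MMHG
    k_e: float = 1.21

    def __post_init__(self) -> None:
        for name in ("rho", "g", "mmhg_per_cm", "mu", "pa_per_mmhg", "k_e"):
            if getattr(self, name) <= 0:
                raise ValueError(f"PhysicalConstants.{name} must be > 0")

    def hydrostatic_factor_exact(self) -> float:
        """Unrounded hydrostatic factor rho*g*h per cm, in mmHg/cm."""
        return self.rho * self.g * 0.01 / self.pa_per_mmhg


DEFAULT_CONSTANTS = PhysicalConstants()
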