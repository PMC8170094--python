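"""Thermodynamic constants and unit conversions.

Free energies are carried in kcal/mol throughout the package; the empirical
electron-transfer rate expressions work in eV internally, so the conversion
factor between the two scales lives here as well.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Boltzmann constant, kcal/mol/K.
KB_KCAL_MOL_K = 0.0019872
#: Boltzmann constant, eV/K.
KB_EV_K = 8.6173e-5
#: kcal/mol per eV.
KCAL_MOL_PER_EV = 23.0609
#: Reduced Planck constant, eV*s.
HBAR_EV_S = 6.5821e-16


@dataclass(frozen=True)
class Thermo:
    """Temperature and derived thermal energies.

    Parameters
    ----------
    temperature : float
        Absolute temperature in K. Default 300 K.
    """

    temperature: float = 300.0

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")

    @property
    def kbt(self) -> float:
        """Thermal energy k_B*T in kcal/mol."""
        return KB_KCAL_MOL_K * self.temperature

    @property
    def kbt_ev(self) -> float:
        """Thermal energy k_B*T in eV."""
        return KB_EV_K * self.temperature


def kcal_to_ev(x: float) -> float:
    """Convert an energy from kcal/mol to eV."""
    return x / KCAL_MOL_PER_EV


def ev_to_kcal(x: float) -> float:
    """Convert an energy from eV to kcal/mol."""
    return x * KCAL_MOL_PER_EV
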