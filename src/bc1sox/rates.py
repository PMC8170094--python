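"""Electron-transfer and superoxide-production rates.

Two rate expressions convert free-energy parameters into electron-transfer
rates.  The nonadiabatic Marcus rate,

    k_et = (2 pi / hbar) |T_AB|^2 (4 pi Lambda kBT)^(-1/2)
           exp(-(Lambda + dG0)^2 / (4 Lambda kBT)),

requires an electronic coupling |T_AB| that is rarely available for a
protein site, so the default chain instead uses the Moser-Dutton ruler,
the empirical tunneling relation for biological electron transfer,

    log10 k_et = 15 - 0.6 R - 3.1 (dG + Lambda)^2 / Lambda,

with R the donor-acceptor edge-to-edge distance in Angstrom and energies
in eV.  Because R fluctuates in simulation, the ruler can be averaged
arithmetically over a per-snapshot distance series.  Finally the
production rate of superoxide while the site holds a semiquinone couples
the electron-transfer rate with O2 binding and unbinding:

    k = k_bind * k_et / (k_et + k_unbind),

optionally scaled by the fraction of time the complex is in the
semiquinone state at all.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import CapabilityError
from .thermo import HBAR_EV_S, Thermo, kcal_to_ev


@dataclass
class EtRateParams:
    """Free-energy inputs for the electron-transfer rate expressions.

    Energies are given in kcal/mol and converted to eV internally.
    ``r_A`` may be a scalar distance or a per-snapshot series; the
    electronic coupling is optional and only needed for the Marcus form.
    """

    delta_g0_kcal_mol: float
    lambda_kcal_mol: float
    r_A: float | np.ndarray | None = None
    coupling_ev: float | None = None
    thermo: Thermo = field(default_factory=Thermo)

    def __post_init__(self) -> None:
        if not self.lambda_kcal_mol > 0:
            raise ValueError("reorganization energy must be positive")
        if self.r_A is not None and np.any(np.asarray(self.r_A) < 0):
            raise ValueError("distances must be non-negative")


@dataclass
class ProductionRateParams:
    k_bind: float  # s^-1
    k_unbind: float  # s^-1
    k_et: float  # s^-1
    x_sq: float | None = None  # semiquinone-state occupancy fraction

    def __post_init__(self) -> None:
        for name in ("k_bind", "k_unbind", "k_et"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class RateResult:
    k_et_per_snapshot: np.ndarray | None  # s^-1
    k_et_mean: float  # s^-1
    production_rate: float | None = None  # s^-1
    per_complex_rate: float | None = None  # s^-1


def marcus_rate(params: EtRateParams) -> float:
    """Nonadiabatic Marcus rate in s^-1 (requires the coupling |T_AB|)."""
    if params.coupling_ev is None:
        raise CapabilityError("Marcus rate needs the electronic coupling |T_AB|")
    lam = kcal_to_ev(params.lambda_kcal_mol)
    dg = kcal_to_ev(params.delta_g0_kcal_mol)
    kbt = params.thermo.kbt_ev
    prefactor = (2.0 * math.pi / HBAR_EV_S) * params.coupling_ev**2
    return float(
        prefactor
        / math.sqrt(4.0 * math.pi * lam * kbt)
        * math.exp(-((lam + dg) ** 2) / (4.0 * lam * kbt))
    )


def moser_dutton_log10_rate(dg_ev: float, lambda_ev: float, r_A) -> np.ndarray:
    """log10 of the Moser-Dutton ruler rate; vectorized over R."""
    if lambda_ev <= 0:
        raise ValueError("reorganization energy must be positive")
    r = np.asarray(r_A, dtype=float)
    return 15.0 - 0.6 * r - 3.1 * (dg_ev + lambda_ev) ** 2 / lambda_ev


def moser_dutton_rate(params: EtRateParams) -> float | np.ndarray:
    """Moser-Dutton ruler rate in s^-1 at the distance(s) in ``params.r_A``."""
    if params.r_A is None:
        raise CapabilityError("Moser-Dutton rate needs the distance R")
    log10k = moser_dutton_log10_rate(
        kcal_to_ev(params.delta_g0_kcal_mol),
        kcal_to_ev(params.lambda_kcal_mol),
        params.r_A,
    )
    k = np.power(10.0, log10k)
    return float(k) if np.ndim(params.r_A) == 0 else k


def implied_distance(params: EtRateParams, k_target: float) -> float:
    """Distance R at which the Moser-Dutton ruler yields ``k_target``.

    Inverts the ruler; a negative R is returned as-is with a warning (it
    signals that no physical distance reproduces the target rate).
    """
    if not k_target > 0:
        raise ValueError("target rate must be positive")
    dg = kcal_to_ev(params.delta_g0_kcal_mol)
    lam = kcal_to_ev(params.lambda_kcal_mol)
    r = (15.0 - 3.1 * (dg + lam) ** 2 / lam - math.log10(k_target)) / 0.6
    if r < 0:
        warnings.warn(f"implied distance is negative ({r:.2f} A)")
    return float(r)


def average_rate_over_snapshots(params: EtRateParams) -> tuple[np.ndarray, float]:
    """Per-snapshot Moser-Dutton rates over an R series and their mean.

    The arithmetic mean of rates (not of log-rates) is dominated by the
    close-approach snapshots, as the ruler is exponential in R.
    """
    r = np.atleast_1d(np.asarray(params.r_A, dtype=float))
    if r.size == 0:
        raise ValueError("empty distance series")
    series = np.power(
        10.0,
        moser_dutton_log10_rate(
            kcal_to_ev(params.delta_g0_kcal_mol),
            kcal_to_ev(params.lambda_kcal_mol),
            r,
        ),
    )
    return series, float(series.mean())


def production_rate(params: ProductionRateParams) -> RateResult:
    """Binding-weighted superoxide production rate.

    k = k_bind * k_et / (k_et + k_unbind); saturates at k_bind for fast
    electron transfer.  When the semiquinone occupancy fraction is given,
    the per-complex rate x_sq * k is reported alongside.
    """
    denom = params.k_et + params.k_unbind
    if denom <= 0:
        raise ValueError("k_et + k_unbind must be positive")
    k = params.k_bind * params.k_et / denom
    per_complex = params.x_sq * k if params.x_sq is not None else None
    return RateResult(
        k_et_per_snapshot=None,
        k_et_mean=params.k_et,
        production_rate=float(k),
        per_complex_rate=per_complex,
    )
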