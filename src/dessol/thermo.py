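"""Ideal solubility of a pure solid solute from fusion thermodynamics.

The solid-liquid equilibrium activity of the solute at saturation is obtained
from the melting temperature Tm, the heat of fusion dHfus, and the heat
capacity change on melting dCp.  dCp is rarely measured; the working
approximation here is dCp ~ dSfus = dHfus / Tm, under which the full
expression collapses to (dHfus / (R*Tm)) * ln(T/Tm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["R_GAS", "FusionData", "heat_capacity_approx", "ideal_log_activity", "gibbs_fusion"]

R_GAS = 8.31446  # J/(mol K)


@dataclass(frozen=True)
class FusionData:
    """Melting temperature (K) and heat of fusion (J/mol) of a solute."""

    compound_id: str
    Tm: float
    dHfus: float

    def __post_init__(self) -> None:
        if not self.Tm > 0:
            raise ValueError(f"Tm must be positive, got {self.Tm}")
        if not self.dHfus > 0:
            raise ValueError(f"dHfus must be positive, got {self.dHfus}")

    @property
    def dSfus(self) -> float:
        """Entropy of fusion at Tm, J/(mol K)."""
        return self.dHfus / self.Tm


def heat_capacity_approx(fusion: FusionData) -> float:
    """Heat-capacity change on melting, approximated as dHfus / Tm, J/(mol K)."""
    return fusion.dHfus / fusion.Tm


def _check_temperature(fusion: FusionData, T: float) -> None:
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    if T > fusion.Tm:
        raise ValueError(
            f"T={T} K exceeds Tm={fusion.Tm} K for {fusion.compound_id!r}: no solid phase"
        )


def ideal_log_activity(fusion: FusionData, T: float, dCp: float | None = None) -> float:
    """ln a_s of the solid solute at saturation, for 0 < T <= Tm.

    Evaluates

        ln a_s = (dHfus/R)(1/Tm - 1/T) - (dCp/R)(T - Tm)/T + (dCp/R) ln(T/Tm)

    with dCp defaulting to :func:`heat_capacity_approx` (pass ``dCp`` to
    override, e.g. ``dCp=0`` for the van 't Hoff form).
    """
    _check_temperature(fusion, T)
    if dCp is None:
        dCp = heat_capacity_approx(fusion)
    Tm, dH = fusion.Tm, fusion.dHfus
    vant_hoff = (dH / R_GAS) * (1.0 / Tm - 1.0 / T)
    cp_term = (dCp / R_GAS) * (np.log(T / Tm) - (T - Tm) / T)
    return float(vant_hoff + cp_term)


def gibbs_fusion(fusion: FusionData, T: float, dCp: float | None = None) -> float:
    """Gibbs energy of fusion dGfus(T) = -R*T*ln a_s, J/mol; zero at Tm."""
    return -R_GAS * T * ideal_log_activity(fusion, T, dCp=dCp)
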