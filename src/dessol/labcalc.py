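"""Shake-flask assay arithmetic.

Spectrophotometric calibration lines (absorbance vs concentration in mg/mL),
ICH detection/quantification limits, absorbance-to-concentration inversion,
molar masses from Hill-notation formulas, and the conversion of a measured
concentration to a mole-fraction solubility in an HBA:HBD eutectic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ATOMIC_WEIGHTS",
    "CalibrationCurve",
    "AssaySample",
    "fit_calibration",
    "lod_loq",
    "concentration_from_absorbance",
    "molar_mass",
    "mole_fraction_from_assay",
]

# IUPAC conventional atomic weights, 5 significant figures; extendable.
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "Cl": 35.45,
    "P": 30.974,
    "F": 18.998,
    "Br": 79.904,
    "I": 126.90,
    "Na": 22.990,
    "K": 39.098,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def molar_mass(formula: str) -> float:
    """Molar mass (g/mol, 2 decimals) of a Hill-notation molecular formula."""
    if not formula or not re.fullmatch(r"(?:[A-Z][a-z]?\d*)+", formula):
        raise ValueError(f"malformed molecular formula: {formula!r}")
    total = 0.0
    for symbol, count in _FORMULA_TOKEN.findall(formula):
        if not symbol:
            continue
        if symbol not in ATOMIC_WEIGHTS:
            raise ValueError(f"unknown element symbol {symbol!r} in {formula!r}")
        total += ATOMIC_WEIGHTS[symbol] * (int(count) if count else 1)
    return round(total, 2)


@dataclass(frozen=True)
class CalibrationCurve:
    """A linear absorbance-vs-concentration calibration with its validation limits."""

    compound_id: str
    lambda_max: float  # nm
    slope: float  # absorbance per (mg/mL)
    intercept: float  # absorbance
    r_squared: float
    lod: float  # mg/mL
    loq: float  # mg/mL

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError(f"slope must be positive, got {self.slope}")
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError(f"r_squared must be in [0, 1], got {self.r_squared}")
        if not self.loq > self.lod > 0:
            raise ValueError(f"need loq > lod > 0, got lod={self.lod}, loq={self.loq}")


def fit_calibration(concentrations, absorbances) -> tuple[float, float, float]:
    """Ordinary-least-squares calibration line; returns (slope, intercept, R^2)."""
    c = np.asarray(concentrations, dtype=float)
    a = np.asarray(absorbances, dtype=float)
    if c.shape != a.shape or c.ndim != 1:
        raise ValueError("concentrations and absorbances must be equal-length vectors")
    if c.size < 3:
        raise ValueError(f"need at least 3 calibration points, got {c.size}")
    if np.unique(c).size != c.size:
        raise ValueError("calibration concentrations must be distinct")
    res = stats.linregress(c, a)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def lod_loq(blank_sd: float, slope: float) -> tuple[float, float]:
    """ICH limits of detection and quantification: 3.3*sd/slope and 10*sd/slope."""
    if slope <= 0:
        raise ValueError(f"slope must be positive, got {slope}")
    if blank_sd < 0:
        raise ValueError("blank SD must be non-negative")
    return 3.3 * blank_sd / slope, 10.0 * blank_sd / slope


def concentration_from_absorbance(
    curve: CalibrationCurve, absorbance: float, dilution_factor: float = 1.0
) -> tuple[float, bool]:
    """Invert the calibration line; returns (mg/mL, below_loq flag)."""
    if absorbance <= curve.intercept:
        raise ValueError(
            f"absorbance {absorbance} at or below the blank intercept {curve.intercept}"
        )
    if dilution_factor < 1:
        raise ValueError("dilution factor must be >= 1")
    undiluted = (absorbance - curve.intercept) / curve.slope
    conc = dilution_factor * undiluted
    return conc, undiluted < curve.loq


@dataclass(frozen=True)
class AssaySample:
    """One assayed saturated sample and the data needed for mole-fraction conversion."""

    absorbance: float
    dilution_factor: float
    density: float  # g/mL of the saturated solution
    mw_solute: float  # g/mol
    hba_id: str
    hbd_id: str
    mw_hba: float
    mw_hbd: float
    hbd_per_hba: float = 2.0  # HBA:HBD molar ratio 1:r

    def __post_init__(self) -> None:
        positive = {
            "absorbance": self.absorbance,
            "density": self.density,
            "mw_solute": self.mw_solute,
            "mw_hba": self.mw_hba,
            "mw_hbd": self.mw_hbd,
            "hbd_per_hba": self.hbd_per_hba,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.dilution_factor < 1:
            raise ValueError("dilution factor must be >= 1")


def mole_fraction_from_assay(sample: AssaySample, concentration: float) -> float:
    """Mole-fraction solubility from a concentration in mg/mL.

    Bookkeeping per 1 mL of saturated solution: solute moles from the
    concentration; the remaining mass is solvent, split into HBA and HBD
    moles according to the eutectic molar ratio (one formula unit =
    MW_HBA + r*MW_HBD).
    """
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    c_g = concentration / 1000.0  # g of solute per mL
    if c_g >= sample.density:
        raise ValueError(
            f"solute mass {c_g} g/mL not below sample mass {sample.density} g/mL"
        )
    n_solute = c_g / sample.mw_solute
    solvent_mass = sample.density - c_g
    unit_mass = sample.mw_hba + sample.hbd_per_hba * sample.mw_hbd
    units = solvent_mass / unit_mass
    n_hba = units
    n_hbd = sample.hbd_per_hba * units
    return n_solute / (n_solute + n_hba + n_hbd)
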