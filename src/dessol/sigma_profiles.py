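"""Sigma-potential profiles on the canonical 61-point charge-density grid.

A sigma-potential mu(sigma) expresses the affinity of a phase for molecular
surface of screening-charge density sigma (e/A^2).  Profiles for solutes and
solvent components live on a fixed grid of 61 points from -0.03 to +0.03
e/A^2.  This module provides the profile container, mixture weighting by
solute-free mole fractions, the relative (solute minus solvent) potential,
coarse-grained step-function representations, and a plain-text file format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GRID_SIZE",
    "SIGMA_MIN",
    "SIGMA_MAX",
    "SIGMA_STEP",
    "SigmaProfile",
    "SolventComposition",
    "make_grid",
    "mixture_potential",
    "relative_sigma_potential",
    "step_average",
    "region_decomposition",
    "read_profile",
    "write_profile",
]

GRID_SIZE = 61
SIGMA_MIN = -0.03
SIGMA_MAX = 0.03
SIGMA_STEP = 0.001

_T_CELSIUS_OFFSET = 273.15


def make_grid() -> np.ndarray:
    """Return the canonical 61-point sigma grid, -0.03 to +0.03 e/A^2, step 0.001."""
    return np.linspace(SIGMA_MIN, SIGMA_MAX, GRID_SIZE)


@dataclass(frozen=True)
class SigmaProfile:
    """A sigma-potential curve for one compound at one temperature.

    Parameters
    ----------
    compound_id
        Identifier of the compound the profile belongs to.
    temperature
        Temperature in kelvin.
    potential
        Energy-per-area values, one per grid point (arbitrary but
        consistent units).
    """

    compound_id: str
    temperature: float
    potential: np.ndarray

    def __post_init__(self) -> None:
        pot = np.asarray(self.potential, dtype=float)
        if pot.shape != (GRID_SIZE,):
            raise ValueError(
                f"profile for {self.compound_id!r} must have {GRID_SIZE} values, "
                f"got {pot.shape}"
            )
        if not np.all(np.isfinite(pot)):
            raise ValueError(f"profile for {self.compound_id!r} contains non-finite values")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        object.__setattr__(self, "potential", pot)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SigmaProfile):
            return NotImplemented
        return (
            self.compound_id == other.compound_id
            and self.temperature == other.temperature
            and np.array_equal(self.potential, other.potential)
        )

    def allclose(self, other: "SigmaProfile", atol: float = 1e-12) -> bool:
        return (
            self.compound_id == other.compound_id
            and abs(self.temperature - other.temperature) <= atol
            and np.allclose(self.potential, other.potential, atol=atol, rtol=0.0)
        )


@dataclass(frozen=True)
class SolventComposition:
    """Solute-free composition of a solvent mixture.

    ``components`` maps component ids to solute-free mole fractions x*;
    fractions must be non-negative and sum to one.
    """

    components: tuple[tuple[str, float], ...]

    def __init__(self, components: Iterable[tuple[str, float]]) -> None:
        comps = tuple((str(cid), float(x)) for cid, x in components)
        if not 1 <= len(comps) <= 4:
            raise ValueError(f"composition must have 1-4 components, got {len(comps)}")
        if any(x < 0 for _, x in comps):
            raise ValueError("solute-free mole fractions must be non-negative")
        total = sum(x for _, x in comps)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"solute-free mole fractions must sum to 1, got {total!r}")
        ids = [cid for cid, _ in comps]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate component ids in composition: {ids}")
        object.__setattr__(self, "components", comps)

    @property
    def component_ids(self) -> tuple[str, ...]:
        return tuple(cid for cid, _ in self.components)

    @property
    def fractions(self) -> tuple[float, ...]:
        return tuple(x for _, x in self.components)

    def __len__(self) -> int:
        return len(self.components)


def _check_same_temperature(profiles: Sequence[SigmaProfile], atol: float = 1e-9) -> float:
    temps = {p.temperature for p in profiles}
    t0 = profiles[0].temperature
    if any(abs(t - t0) > atol for t in temps):
        raise ValueError(f"temperature mismatch among profiles: {sorted(temps)}")
    return t0


def mixture_potential(
    profiles: Sequence[SigmaProfile],
    comp: SolventComposition,
    mixture_id: str = "mixture",
) -> SigmaProfile:
    """Solute-free-mole-fraction-weighted sigma-potential of a solvent mixture.

    Every component of ``comp`` must have a matching profile (by compound id)
    and all profiles must share one temperature.
    """
    by_id = {p.compound_id: p for p in profiles}
    missing = [cid for cid in comp.component_ids if cid not in by_id]
    if missing:
        raise KeyError(f"no sigma profile supplied for component(s): {missing}")
    used = [by_id[cid] for cid in comp.component_ids]
    temperature = _check_same_temperature(used)
    mixed = np.zeros(GRID_SIZE)
    for (cid, x), prof in zip(comp.components, used):
        mixed += x * prof.potential
    return SigmaProfile(mixture_id, temperature, mixed)


def relative_sigma_potential(api: SigmaProfile, solvent: SigmaProfile) -> SigmaProfile:
    """Pointwise solute-minus-solvent potential difference at one temperature.

    ``solvent`` is expected to already be mixture-weighted (see
    :func:`mixture_potential`).
    """
    _check_same_temperature([api, solvent])
    return SigmaProfile(
        f"{api.compound_id}-rel-{solvent.compound_id}",
        api.temperature,
        api.potential - solvent.potential,
    )


# Coarse graining: 61 points do not split into 6 or 12 equal bins, so the
# final grid point (sigma = +0.03) is dropped and the remaining 60 are binned.
_BINNABLE = GRID_SIZE - 1


def step_average(profile: SigmaProfile | np.ndarray, n_bins: int) -> np.ndarray:
    """Step-function representation: contiguous equal-width bin means over sigma.

    The last grid point is excluded so that the remaining 60 points divide
    evenly; ``n_bins`` must be a positive divisor of 60 (the canonical
    choices are 6 and 12).
    """
    if n_bins <= 0 or _BINNABLE % n_bins != 0:
        raise ValueError(
            f"n_bins must be a positive divisor of {_BINNABLE}, got {n_bins}"
        )
    values = profile.potential if isinstance(profile, SigmaProfile) else np.asarray(profile, float)
    if values.shape != (GRID_SIZE,):
        raise ValueError(f"expected {GRID_SIZE} potential values, got {values.shape}")
    return values[:_BINNABLE].reshape(n_bins, _BINNABLE // n_bins).mean(axis=1)


# Region boundaries are symmetric: sigma = -0.01 closes the HBA region and
# +0.01 opens the HBD region, so the two bonding regions mirror each other
# and each grid point belongs to exactly one region.
_HBA_SLICE = slice(0, 21)   # sigma in [-0.03, -0.01]
_HYD_SLICE = slice(21, 40)  # sigma in (-0.01, +0.01)
_HBD_SLICE = slice(40, 61)  # sigma in [+0.01, +0.03]


def region_decomposition(profile: SigmaProfile) -> tuple[float, float, float]:
    """Mean potential over the acceptor, hydrophobic and donor sigma regions.

    Returns ``(hba_mean, hyd_mean, hbd_mean)`` for sigma in [-0.03, -0.01],
    (-0.01, +0.01) and [+0.01, +0.03] respectively.
    """
    pot = profile.potential
    return (
        float(pot[_HBA_SLICE].mean()),
        float(pot[_HYD_SLICE].mean()),
        float(pot[_HBD_SLICE].mean()),
    )


def write_profile(profile: SigmaProfile, path: str | Path) -> None:
    """Write a profile as two-column text with a ``# compound=... temperature_C=...`` header."""
    grid = make_grid()
    temp_c = profile.temperature - _T_CELSIUS_OFFSET
    lines = [f"# compound={profile.compound_id} temperature_C={temp_c!r}"]
    for sigma, mu in zip(grid, profile.potential):
        lines.append(f"{sigma:.3f} {float(mu)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_profile(path: str | Path) -> SigmaProfile:
    """Read a profile written by :func:`write_profile`.

    Raises on a missing header, wrong row count, or a non-monotone sigma column.
    """
    path = Path(path)
    compound_id: str | None = None
    temperature: float | None = None
    sigmas: list[float] = []
    potentials: list[float] = []
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            for token in line.lstrip("#").split():
                if token.startswith("compound="):
                    compound_id = token.split("=", 1)[1]
                elif token.startswith("temperature_C="):
                    temperature = float(token.split("=", 1)[1]) + _T_CELSIUS_OFFSET
            continue
        cols = line.split()
        if len(cols) != 2:
            raise ValueError(f"{path}: expected two columns, got {len(cols)}: {line!r}")
        sigmas.append(float(cols[0]))
        potentials.append(float(cols[1]))
    if compound_id is None or temperature is None:
        raise ValueError(f"{path}: missing '# compound=<id> temperature_C=<float>' header")
    if len(sigmas) != GRID_SIZE:
        raise ValueError(f"{path}: expected {GRID_SIZE} data rows, got {len(sigmas)}")
    sig = np.array(sigmas)
    if not np.all(np.diff(sig) > 0):
        raise ValueError(f"{path}: sigma column is not strictly increasing")
    if not np.allclose(sig, make_grid(), atol=5e-4):
        raise ValueError(f"{path}: sigma column does not match the canonical grid")
    return SigmaProfile(compound_id, temperature, np.array(potentials))
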