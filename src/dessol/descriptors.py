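"""Assembly of the six descriptor sets from relative sigma-potentials.

Set layout (fixed ordering):

=====  =================================================================  ====
id     contents                                                           len
=====  =================================================================  ====
A1     6-bin step of the relative potential, 5 energies, 1 solubility      12
A2     A1 without the solubility feature                                   11
B1     12-bin step, 5 energies, 1 solubility                               18
B2     B1 without the solubility feature                                   17
C1     full 61-point relative potential, 1 solubility                      62
C2     C1 without the solubility feature                                   61
=====  =================================================================  ====

The five relative interaction-energy terms are the solute-minus-weighted-
solvent values of the mixture chemical potential and the total, hydrogen-bond,
misfit and van der Waals energy contributions; they are inputs here, not
computed ab initio.  The solubility feature is on the target scale
(log10 mole fraction).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

from .dataset import SolubilityRecord
from .sigma_profiles import (
    GRID_SIZE,
    SigmaProfile,
    SolventComposition,
    mixture_potential,
    relative_sigma_potential,
    step_average,
)

__all__ = [
    "InteractionEnergies",
    "DescriptorSet",
    "relative_energy",
    "build_features",
    "featurize_dataset",
]


@dataclass(frozen=True)
class InteractionEnergies:
    """Relative (solute minus weighted solvent) interaction-energy terms."""

    d_mu_mix: float
    dE_tot: float
    dE_HB: float
    dE_misfit: float
    dE_vdW: float

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.as_array())):
            raise ValueError("interaction energies must be finite")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.d_mu_mix, self.dE_tot, self.dE_HB, self.dE_misfit, self.dE_vdW]
        )


class DescriptorSet(str, Enum):
    A1 = "A1"
    A2 = "A2"
    B1 = "B1"
    B2 = "B2"
    C1 = "C1"
    C2 = "C2"

    @property
    def n_bins(self) -> int | None:
        """Step-function resolution; ``None`` for the full-profile C sets."""
        return {"A": 6, "B": 12, "C": None}[self.value[0]]

    @property
    def uses_energies(self) -> bool:
        return self.value[0] in ("A", "B")

    @property
    def uses_solubility(self) -> bool:
        return self.value[1] == "1"

    @property
    def n_descriptors(self) -> int:
        profile_len = self.n_bins if self.n_bins is not None else GRID_SIZE
        return profile_len + (5 if self.uses_energies else 0) + (1 if self.uses_solubility else 0)


def relative_energy(
    api_value: float, component_values: Sequence[float], comp: SolventComposition
) -> float:
    """Solute value minus the solute-free-mole-fraction-weighted solvent value."""
    if len(component_values) != len(comp):
        raise ValueError(
            f"got {len(component_values)} component values for "
            f"{len(comp)}-component composition"
        )
    weighted = sum(x * v for x, v in zip(comp.fractions, component_values))
    return float(api_value) - weighted


def build_features(
    set_id: DescriptorSet | str,
    delta_profile: SigmaProfile,
    energies: InteractionEnergies | None = None,
    cosmors_log_solubility: float | None = None,
) -> np.ndarray:
    """Assemble one feature vector for a record under a descriptor-set definition."""
    set_id = DescriptorSet(set_id)
    if set_id.uses_energies and energies is None:
        raise ValueError(f"descriptor set {set_id.value} requires interaction energies")
    if set_id.uses_solubility and cosmors_log_solubility is None:
        raise ValueError(
            f"descriptor set {set_id.value} requires a computed log-solubility feature"
        )
    if set_id.n_bins is None:
        parts = [delta_profile.potential]
    else:
        parts = [step_average(delta_profile, set_id.n_bins)]
    if set_id.uses_energies:
        parts.append(energies.as_array())
    if set_id.uses_solubility:
        parts.append(np.array([float(cosmors_log_solubility)]))
    vec = np.concatenate(parts)
    assert vec.shape == (set_id.n_descriptors,)
    return vec


class ProfileStore(dict):
    """Mapping ``(compound_id, temperature_K) -> SigmaProfile`` with linear
    interpolation in temperature when an exact temperature is missing."""

    def add(self, profile: SigmaProfile) -> None:
        self[(profile.compound_id, round(profile.temperature, 6))] = profile

    def lookup(self, compound_id: str, temperature: float) -> SigmaProfile:
        key = (compound_id, round(temperature, 6))
        if key in self:
            return self[key]
        temps = sorted(t for cid, t in self if cid == compound_id)
        if not temps:
            raise KeyError(f"no sigma profiles stored for compound {compound_id!r}")
        lower = [t for t in temps if t < temperature]
        upper = [t for t in temps if t > temperature]
        if not lower or not upper:
            raise KeyError(
                f"no profile for {compound_id!r} at {temperature} K and "
                f"temperature outside stored range {temps[0]}-{temps[-1]} K"
            )
        t0, t1 = lower[-1], upper[0]
        p0, p1 = self[(compound_id, t0)], self[(compound_id, t1)]
        w = (temperature - t0) / (t1 - t0)
        return SigmaProfile(
            compound_id, temperature, (1 - w) * p0.potential + w * p1.potential
        )


def record_delta_profile(record: SolubilityRecord, profiles: ProfileStore) -> SigmaProfile:
    """Relative sigma-potential of one record's solute against its solvent mixture."""
    api = profiles.lookup(record.solute_id, record.temperature)
    comps = [profiles.lookup(cid, record.temperature) for cid in record.solvent.component_ids]
    solvent = mixture_potential(comps, record.solvent)
    return relative_sigma_potential(api, solvent)


def featurize_dataset(
    records: Sequence[SolubilityRecord],
    profiles: ProfileStore,
    set_id: DescriptorSet | str,
    energies: Mapping[int, InteractionEnergies] | Sequence[InteractionEnergies] | None = None,
    cosmors: Mapping[int, float] | Sequence[float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix and target vector for a record list, rows in input order.

    ``energies`` and ``cosmors`` are indexed by record position.  Missing
    profiles for any (compound, temperature) raise with the gap listed.
    """
    set_id = DescriptorSet(set_id)
    n = len(records)
    X = np.empty((n, set_id.n_descriptors))
    y = np.empty(n)
    for i, rec in enumerate(records):
        try:
            delta = record_delta_profile(rec, profiles)
        except KeyError as exc:
            raise KeyError(f"record {i} ({rec.solute_id!r}): {exc}") from exc
        e = energies[i] if set_id.uses_energies else None
        s = cosmors[i] if set_id.uses_solubility else None
        X[i] = build_features(set_id, delta, energies=e, cosmors_log_solubility=s)
        y[i] = rec.log10_x
    return X, y
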