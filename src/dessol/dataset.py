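"""Solubility dataset model: records, CSV I/O, classification, splitting, coverage.

A record is one saturated-system observation — solute, solute-free solvent
composition with component roles, temperature, and the decadal logarithm of
the mole-fraction solubility.  Systems are classified into the four subset
labels ``neat``, ``binary``, ``dry_des`` and ``wet_des`` from the component
roles (hydrogen-bond acceptor, donor, water, or generic solvent).
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .sigma_profiles import SolventComposition

__all__ = [
    "Role",
    "SolubilityRecord",
    "CoverageMap",
    "classify_system",
    "read_dataset",
    "write_dataset",
    "train_test_split",
    "subset_counts",
    "coverage_fraction",
]

_T_CELSIUS_OFFSET = 273.15

SUBSET_LABELS = ("neat", "binary", "dry_des", "wet_des")


class Role(str, Enum):
    """Role of a solvent component in a mixture."""

    HBA = "hba"
    HBD = "hbd"
    WATER = "water"
    SOLVENT = "solvent"


def classify_system(comp: SolventComposition, roles: Mapping[str, Role]) -> str:
    """Assign the subset label of a solvent system from component roles.

    One component is ``neat``; an HBA+HBD pair is ``dry_des``; the same plus
    water (3 or 4 components) is ``wet_des``; any other two-component mixture
    is ``binary``.
    """
    missing = [cid for cid in comp.component_ids if cid not in roles]
    if missing:
        raise ValueError(f"no role annotation for component(s): {missing}")
    rset = Counter(roles[cid] for cid in comp.component_ids)
    n = len(comp)
    if n == 1:
        return "neat"
    if n == 2:
        if rset[Role.HBA] == 1 and rset[Role.HBD] == 1:
            return "dry_des"
        return "binary"
    # 3 or 4 components must be a wet DES: HBA + HBD(s) + water
    if rset[Role.WATER] == 1 and rset[Role.HBA] >= 1 and rset[Role.HBD] >= 1 and rset[Role.SOLVENT] == 0:
        return "wet_des"
    raise ValueError(
        f"cannot classify {n}-component system with roles "
        f"{[roles[c].value for c in comp.component_ids]}"
    )


@dataclass(frozen=True)
class SolubilityRecord:
    """One saturated-system observation.

    ``log10_x`` is the decadal log of the mole-fraction solubility and must be
    negative; ``roles`` annotates every component of ``solvent``.
    """

    solute_id: str
    solvent: SolventComposition
    roles: Mapping[str, Role]
    temperature: float
    log10_x: float
    source_tag: str = ""
    subset_label: str = field(init=False)

    def __post_init__(self) -> None:
        if not self.log10_x < 0:
            raise ValueError(
                f"log10_x must be negative (mole fraction < 1), got {self.log10_x}"
            )
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        roles = {str(k): Role(v) for k, v in dict(self.roles).items()}
        object.__setattr__(self, "roles", roles)
        object.__setattr__(self, "subset_label", classify_system(self.solvent, roles))


_CSV_COLUMNS = (
    "solute_id",
    "component_ids",
    "roles",
    "x_star",
    "temperature_C",
    "log10_x",
    "source_tag",
)


def write_dataset(records: Sequence[SolubilityRecord], path: str | Path) -> None:
    """Write records as CSV (compositions ;-joined, temperature in Celsius)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.solute_id,
                    ";".join(rec.solvent.component_ids),
                    ";".join(rec.roles[c].value for c in rec.solvent.component_ids),
                    ";".join(repr(float(x)) for x in rec.solvent.fractions),
                    repr(float(rec.temperature) - _T_CELSIUS_OFFSET),
                    repr(float(rec.log10_x)),
                    rec.source_tag,
                ]
            )


def read_dataset(path: str | Path) -> list[SolubilityRecord]:
    """Read a dataset CSV; invalid rows raise with their row number."""
    records: list[SolubilityRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(_CSV_COLUMNS) - set(reader.fieldnames):
            raise ValueError(f"{path}: expected columns {_CSV_COLUMNS}")
        for i, row in enumerate(reader, start=2):
            try:
                ids = row["component_ids"].split(";")
                roles = {c: Role(r) for c, r in zip(ids, row["roles"].split(";"))}
                if len(roles) != len(ids):
                    raise ValueError("roles do not match component_ids")
                comp = SolventComposition(
                    zip(ids, (float(x) for x in row["x_star"].split(";")))
                )
                records.append(
                    SolubilityRecord(
                        solute_id=row["solute_id"],
                        solvent=comp,
                        roles=roles,
                        temperature=float(row["temperature_C"]) + _T_CELSIUS_OFFSET,
                        log10_x=float(row["log10_x"]),
                        source_tag=row["source_tag"],
                    )
                )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}: row {i}: {exc}") from exc
    return records


def train_test_split(
    records: Sequence, test_fraction: float = 0.20, seed: int = 0
) -> tuple[list, list]:
    """Random, reproducible, disjoint and exhaustive train/test partition."""
    if not records:
        raise ValueError("cannot split an empty record list")
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    n_test = int(round(len(records) * test_fraction))
    test_idx = set(order[:n_test].tolist())
    train = [records[i] for i in range(len(records)) if i not in test_idx]
    test = [records[i] for i in range(len(records)) if i in test_idx]
    return train, test


def subset_counts(records: Iterable[SolubilityRecord]) -> dict[str, dict[str, int]]:
    """Count records per subset label and, for DES records, per HBA component.

    Returns ``{"by_subset": {...}, "by_hba": {...}, "total": {"all": n}}``;
    the subset counts always partition the total.
    """
    by_subset: Counter[str] = Counter({label: 0 for label in SUBSET_LABELS})
    by_hba: Counter[str] = Counter()
    total = 0
    for rec in records:
        total += 1
        by_subset[rec.subset_label] += 1
        if rec.subset_label in ("dry_des", "wet_des"):
            for cid in rec.solvent.component_ids:
                if rec.roles[cid] is Role.HBA:
                    by_hba[cid] += 1
    return {"by_subset": dict(by_subset), "by_hba": dict(by_hba), "total": {"all": total}}


@dataclass(frozen=True)
class CoverageMap:
    """Membership matrix of studied (solute, solvent system) combinations."""

    solute_ids: tuple[str, ...]
    system_ids: tuple[str, ...]
    studied: np.ndarray

    def __post_init__(self) -> None:
        studied = np.asarray(self.studied, dtype=bool)
        expected = (len(self.solute_ids), len(self.system_ids))
        if studied.shape != expected:
            raise ValueError(f"studied matrix must have shape {expected}, got {studied.shape}")
        object.__setattr__(self, "studied", studied)

    @classmethod
    def from_records(
        cls, records: Sequence[SolubilityRecord]
    ) -> "CoverageMap":
        solutes = tuple(sorted({r.solute_id for r in records}))
        systems = tuple(sorted({"+".join(r.solvent.component_ids) for r in records}))
        mat = np.zeros((len(solutes), len(systems)), dtype=bool)
        si = {s: i for i, s in enumerate(solutes)}
        yi = {s: i for i, s in enumerate(systems)}
        for r in records:
            mat[si[r.solute_id], yi["+".join(r.solvent.component_ids)]] = True
        return cls(solutes, systems, mat)


def coverage_fraction(cmap: CoverageMap) -> float:
    """Percentage of studied cells in the coverage map."""
    if cmap.studied.size == 0:
        raise ValueError("coverage map has empty axes")
    return 100.0 * float(cmap.studied.sum()) / cmap.studied.size
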