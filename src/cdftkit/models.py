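"""Core data model: frontier-orbital records, atomic population tables,
volumetric scalar fields, and descriptor containers.

Validation happens at construction time so that every instance in
circulation satisfies its invariants.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .constants import PKA_INTERCEPT, PKA_SLOPE
from .errors import DataError, DegenerateGapError, StructureError, ValidationError

CHARGE_SUM_TOL = 1e-3
SPIN_SUM_TOL = 1e-2


@dataclass(frozen=True)
class FrontierOrbitalRecord:
    """HOMO/LUMO energies (eV) for one species.

    ``source`` tags provenance: ``parsed`` (from a QC log), ``fixture``
    (printed table values) or ``synthetic`` (mock generator).
    """

    label: str
    epsilon_homo: float
    epsilon_lumo: float
    source: str = "parsed"

    def __post_init__(self) -> None:
        for name in ("epsilon_homo", "epsilon_lumo"):
            if not math.isfinite(getattr(self, name)):
                raise ValidationError(f"{self.label!r}: {name} is not finite")
        if not self.epsilon_homo < self.epsilon_lumo:
            raise DegenerateGapError(
                f"{self.label!r}: epsilon_homo ({self.epsilon_homo}) must lie "
                f"below epsilon_lumo ({self.epsilon_lumo})"
            )

    @property
    def gap(self) -> float:
        """HOMO–LUMO gap in eV (always positive)."""
        return self.epsilon_lumo - self.epsilon_homo


@dataclass
class AtomicPopulationTable:
    """Per-atom Mulliken charges (and optional spin densities) for one
    charge state of a molecule.

    ``charge_state`` is the net charge relative to the neutral species
    (−1, 0, +1 in normal use); ``multiplicity_hint`` is the spin
    multiplicity, so ``multiplicity_hint − 1`` unpaired electrons are
    expected when spin densities are present.
    """

    charge_state: int
    multiplicity_hint: int
    indices: np.ndarray
    elements: tuple[str, ...]
    charges: np.ndarray
    spins: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.charges = np.asarray(self.charges, dtype=float)
        if self.spins is not None:
            self.spins = np.asarray(self.spins, dtype=float)
        n = len(self.indices)
        if n == 0:
            raise StructureError("population table has no atoms")
        if len(self.elements) != n or len(self.charges) != n:
            raise StructureError("index/element/charge columns differ in length")
        if self.multiplicity_hint < 1:
            raise ValidationError(f"multiplicity_hint must be >= 1, got {self.multiplicity_hint}")
        expected = np.arange(1, n + 1)
        if not np.array_equal(self.indices, expected):
            bad = int(np.flatnonzero(self.indices != expected)[0])
            raise StructureError(
                f"atom indices must run 1..{n} without gaps or duplicates; "
                f"row {bad + 1} carries index {self.indices[bad]}"
            )
        total = float(self.charges.sum())
        if abs(total - self.charge_state) > CHARGE_SUM_TOL:
            raise ValidationError(
                f"sum of Mulliken charges is {total:.6f} but the declared net "
                f"charge is {self.charge_state:+d} (deviation "
                f"{abs(total - self.charge_state):.2e} > {CHARGE_SUM_TOL})"
            )
        if self.spins is not None:
            if len(self.spins) != n:
                raise StructureError("spin column length differs from atom count")
            spin_total = float(self.spins.sum())
            if abs(spin_total - self.unpaired_electrons) > SPIN_SUM_TOL:
                warnings.warn(
                    f"spin densities sum to {spin_total:.4f}, expected "
                    f"{self.unpaired_electrons} unpaired electrons",
                    stacklevel=2,
                )

    @property
    def n_atoms(self) -> int:
        return len(self.indices)

    @property
    def unpaired_electrons(self) -> int:
        return self.multiplicity_hint - 1

    @property
    def has_spins(self) -> bool:
        return self.spins is not None

    def require_spins(self) -> np.ndarray:
        if self.spins is None:
            raise DataError(
                f"population table (charge state {self.charge_state:+d}) "
                "carries no spin-density column"
            )
        return self.spins


@dataclass
class ScalarField:
    """A volumetric scalar on a regular grid, mirroring the cube format.

    ``origin`` (Bohr), ``axes`` (3×3 step vectors, Bohr, rows are axes),
    ``counts`` (points along each axis) and a flat ``values`` array in
    cube ordering (last axis fastest). ``atoms`` holds the cube header's
    atom records as an (natoms, 5) array (Z, charge, x, y, z)."""

    origin: np.ndarray
    axes: np.ndarray
    counts: tuple[int, int, int]
    values: np.ndarray
    natoms: int = 0
    atoms: Optional[np.ndarray] = None
    comments: tuple[str, str] = ("cdftkit scalar field", "")

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        self.counts = tuple(int(c) for c in self.counts)
        self.values = np.asarray(self.values, dtype=float).ravel()
        if any(c < 1 for c in self.counts):
            raise ValidationError(f"grid counts must be positive, got {self.counts}")
        npts = int(np.prod(self.counts))
        if self.values.size != npts:
            raise ValidationError(
                f"expected {npts} grid values for counts {self.counts}, "
                f"got {self.values.size}"
            )
        if abs(np.linalg.det(self.axes)) < 1e-30:
            raise ValidationError("grid axes are singular")
        if self.atoms is None:
            self.atoms = np.zeros((self.natoms, 5))
        self.atoms = np.asarray(self.atoms, dtype=float).reshape(self.natoms, 5)

    @property
    def voxel_volume(self) -> float:
        """Volume of one grid cell in Bohr³."""
        return abs(float(np.linalg.det(self.axes)))

    def integral(self) -> float:
        """Grid-quadrature integral: voxel volume times the value sum."""
        return self.voxel_volume * float(self.values.sum())

    def grid(self) -> np.ndarray:
        """Values reshaped to ``counts``."""
        return self.values.reshape(self.counts)


@dataclass(frozen=True)
class KidEnergies:
    """Vertical ionization potential and electron affinity (eV) obtained by
    identifying I with −εHOMO and A with −εLUMO."""

    ionization_potential: float
    electron_affinity: float

    def __post_init__(self) -> None:
        if not self.ionization_potential > self.electron_affinity:
            raise DegenerateGapError(
                f"I ({self.ionization_potential}) must exceed A "
                f"({self.electron_affinity}); the gap is non-positive"
            )

    @property
    def gap(self) -> float:
        return self.ionization_potential - self.electron_affinity


@dataclass(frozen=True)
class PkaModel:
    """Linear hardness→pKa relation: pKa = intercept + slope·η."""

    intercept: float = PKA_INTERCEPT
    slope: float = PKA_SLOPE

    def __call__(self, eta: float) -> float:
        return self.intercept + self.slope * eta


@dataclass
class GlobalDescriptorSet:
    """Global reactivity descriptors for one species (all in eV, except
    ``lambda_max_nm`` in nm and the dimensionless ``pka``). Values are kept
    at full precision; rounding happens only in the reporting layer."""

    label: str
    electronegativity: float
    global_hardness: float
    electrophilicity: float
    electrodonating_power: float
    electroaccepting_power: float
    net_electrophilicity: float
    lambda_max_nm: Optional[float] = None
    pka: Optional[float] = None


SITE_COLUMNS = [
    "atom_index",
    "element",
    "f_plus",
    "f_minus",
    "dual",
    "dual_scaled",
    "parr_plus",
    "parr_minus",
]


@dataclass
class CondensedSiteTable:
    """Per-atom condensed local descriptors.

    Backed by a DataFrame with columns ``atom_index``, ``element``,
    ``f_plus``, ``f_minus``, ``dual``, ``dual_scaled`` (dual × 100, the
    reporting convention), ``parr_plus`` and ``parr_minus``; columns not
    yet computed hold NaN.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        for col in SITE_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        self.data = df[SITE_COLUMNS].reset_index(drop=True)
        if self.data["atom_index"].duplicated().any():
            raise StructureError("duplicate atom indices in site table")

    @classmethod
    def from_atoms(cls, indices: Sequence[int], elements: Sequence[str], **columns) -> "CondensedSiteTable":
        frame = pd.DataFrame({"atom_index": list(indices), "element": list(elements)})
        for name, values in columns.items():
            frame[name] = values
        return cls(frame)

    @property
    def n_atoms(self) -> int:
        return len(self.data)

    def has_column(self, name: str) -> bool:
        return name in self.data.columns and self.data[name].notna().all()

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)


@dataclass
class DescriptorReport:
    """Rounded per-molecule descriptor rows plus run metadata.

    ``rows`` preserve input order; ``errors`` records per-molecule
    failures ({'label', 'error'}); ``metadata`` pins every constant that
    was applied."""

    rows: list[dict]
    errors: list[dict]
    metadata: dict
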