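"""Offline test-input generation.

Two kinds of inputs are produced: (a) the five virotoxin fixture records
and their published descriptor values, loaded from packaged JSON; (b)
seed-deterministic mock QC artifacts (logs with orbital listings and
Mulliken blocks, cube-grid density triples) with planted ground truth, so
every parser and descriptor path can be exercised without a quantum
chemistry code.

Mock Mulliken charges are drawn symmetrically and then fixed up in integer
micro-electron units so that every printed column sums *exactly* to its
target; exactness of sums is prioritized over realism.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np

from .constants import HARTREE_TO_EV
from .errors import MockSpecError
from .models import CondensedSiteTable, FrontierOrbitalRecord, ScalarField

_MICRO = 1_000_000  # charges handled in 1e-6 e units so printed sums are exact


def _fixture_doc() -> dict:
    with resources.files("cdftkit.data").joinpath("virotoxins.json").open() as fh:
        return json.load(fh)


@dataclass
class FixtureBundle:
    """The five virotoxin records plus their published reference values.

    ``records`` maps molecule name → FrontierOrbitalRecord;
    ``site_blocks`` maps name → the two published extreme-site rows as a
    CondensedSiteTable; ``expected`` maps name → published values
    (descriptors, gap, λmax, pKa, and the original pKa row label).
    """

    records: dict[str, FrontierOrbitalRecord]
    site_blocks: dict[str, CondensedSiteTable]
    expected: dict[str, dict]

    @property
    def molecules(self) -> list[str]:
        return list(self.records)


def load_virotoxin_fixtures() -> FixtureBundle:
    """Load the packaged virotoxin fixture bundle."""
    doc = _fixture_doc()
    records: dict[str, FrontierOrbitalRecord] = {}
    site_blocks: dict[str, CondensedSiteTable] = {}
    expected: dict[str, dict] = {}
    for name in doc["molecules"]:
        fr = doc["frontier"][name]
        records[name] = FrontierOrbitalRecord(
            label=name,
            epsilon_homo=fr["epsilon_homo"],
            epsilon_lumo=fr["epsilon_lumo"],
            source="fixture",
        )
        rows = doc["extreme_sites"][name]
        site_blocks[name] = CondensedSiteTable.from_atoms(
            [r["atom_index"] for r in rows],
            [r["element"] for r in rows],
            dual=[r["dual_scaled"] / 100.0 for r in rows],
            dual_scaled=[r["dual_scaled"] for r in rows],
            parr_plus=[r["parr_plus"] for r in rows],
            parr_minus=[r["parr_minus"] for r in rows],
        )
        exp = dict(doc["expected_global"][name])
        exp.update(doc["expected_pka"][name])
        expected[name] = exp
    return FixtureBundle(records=records, site_blocks=site_blocks, expected=expected)


@dataclass(frozen=True)
class MockSpec:
    """Parameters of one deterministic mock system.

    ``net_charge`` is the neutral reference's charge; the ion states carry
    ``net_charge ± 1``. ``unpaired`` is the unpaired-electron count of each
    radical-ion state. ``planted_offsets`` are the (J_I, J_A) deviations
    baked into the mock total energies.
    """

    seed: int = 0
    n_atoms: int = 12
    net_charge: int = 0
    unpaired: int = 1
    homo_ev: float = -6.072
    lumo_ev: float = -1.700
    planted_offsets: tuple[float, float] = (0.0, 0.0)
    grid_points: int = 24
    grid_extent: float = 12.0

    def __post_init__(self) -> None:
        if self.n_atoms < 1:
            raise MockSpecError(f"n_atoms must be >= 1, got {self.n_atoms}")
        if self.unpaired < 0:
            raise MockSpecError(f"unpaired must be >= 0, got {self.unpaired}")
        if not self.homo_ev < self.lumo_ev:
            raise MockSpecError("homo_ev must lie below lumo_ev")
        if self.grid_points < 2:
            raise MockSpecError(f"grid_points must be >= 2, got {self.grid_points}")
        if self.grid_extent <= 0:
            raise MockSpecError(
                f"grid_extent must be positive, got {self.grid_extent} (zero-width grid)"
            )


@dataclass
class MockLogBundle:
    """Three mock log texts (one per charge state) plus planted truth.

    ``total_energies`` holds eV total energies keyed 'neutral'/'cation'/
    'anion', constructed so the ΔSCF deviations equal
    ``spec.planted_offsets``. ``truth`` holds the exact printed per-atom
    columns (charges per state, f±, Parr functions).
    """

    spec: MockSpec
    neutral: str
    cation: str
    anion: str
    total_energies: dict[str, float]
    truth: dict[str, np.ndarray]

    def logs(self) -> dict[str, str]:
        return {"neutral": self.neutral, "cation": self.cation, "anion": self.anion}


_ELEMENTS = ("C", "N", "O", "S", "H")


def _signed_micro(rng: np.random.Generator, n: int, total: int) -> np.ndarray:
    parts = rng.integers(-400_000, 400_001, size=n)
    parts[-1] = total - int(parts[:-1].sum())
    return parts


def _positive_micro(rng: np.random.Generator, n: int, total: int) -> np.ndarray:
    w = rng.random(n) + 0.05
    parts = np.floor(w / w.sum() * total).astype(np.int64)
    parts[: total - int(parts.sum())] += 1
    return parts


def _eigenvalue_lines(kind: str, values_ha: np.ndarray) -> list[str]:
    lines = []
    for i in range(0, values_ha.size, 5):
        chunk = "".join(f"{v:11.5f}" for v in values_ha[i : i + 5])
        lines.append(f" Alpha {'occ. ' if kind == 'occ' else 'virt.'} eigenvalues --{chunk}")
    return lines


def _mulliken_block(
    elements: tuple[str, ...], charges_micro: np.ndarray, spins_micro: Optional[np.ndarray]
) -> list[str]:
    if spins_micro is None:
        lines = [" Mulliken charges:", "               1"]
        for i, (el, q) in enumerate(zip(elements, charges_micro), start=1):
            lines.append(f"{i:6d}  {el:<2s}  {q / _MICRO:10.6f}")
    else:
        lines = [" Mulliken charges and spin densities:", "               1          2"]
        for i, (el, q, s) in enumerate(zip(elements, charges_micro, spins_micro), start=1):
            lines.append(f"{i:6d}  {el:<2s}  {q / _MICRO:10.6f}  {s / _MICRO:10.6f}")
    total = charges_micro.sum() / _MICRO
    lines.append(f" Sum of Mulliken charges = {total:10.5f}")
    return lines


def make_mock_log(spec: MockSpec) -> MockLogBundle:
    """Emit three parseable mock logs with planted ground truth.

    The neutral log parses back to the spec's frontier targets (within the
    5-decimal Hartree print precision); the three Mulliken blocks sum
    exactly to charges q, q+1, q−1, with ion spin densities summing
    exactly to ``spec.unpaired``. By construction the condensed Fukui
    columns over the triple each sum to exactly 1.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_atoms
    elements = tuple(rng.choice(_ELEMENTS, size=n))

    q_neutral = _signed_micro(rng, n, spec.net_charge * _MICRO)
    f_minus = _positive_micro(rng, n, _MICRO)
    f_plus = _positive_micro(rng, n, _MICRO)
    q_cation = q_neutral + f_minus
    q_anion = q_neutral - f_plus
    spin_total = spec.unpaired * _MICRO
    spin_cation = _positive_micro(rng, n, spin_total) if spin_total else np.zeros(n, dtype=np.int64)
    spin_anion = _positive_micro(rng, n, spin_total) if spin_total else np.zeros(n, dtype=np.int64)

    homo_ha = round(spec.homo_ev / HARTREE_TO_EV, 5)
    lumo_ha = round(spec.lumo_ev / HARTREE_TO_EV, 5)
    n_occ, n_virt = 8, 8
    occ = homo_ha - np.sort(rng.uniform(0.02, 1.5, size=n_occ - 1))[::-1]
    occ = np.round(np.append(occ, homo_ha), 5)
    virt = lumo_ha + np.sort(rng.uniform(0.02, 1.5, size=n_virt - 1))
    virt = np.round(np.insert(virt, 0, lumo_ha), 5)

    e_neutral = -3000.0 + float(rng.uniform(-10.0, 10.0))
    j_i, j_a = spec.planted_offsets
    energies = {
        "neutral": e_neutral,
        "cation": e_neutral - spec.homo_ev + j_i,
        "anion": e_neutral + spec.lumo_ev - j_a,
    }

    def log_text(state: str, charges: np.ndarray, spins: Optional[np.ndarray]) -> str:
        lines = [
            " Entering mock quantum-chemistry output",
            f" Charge state: {state}",
            f" SCF Done:  E(mock) = {energies[state] / HARTREE_TO_EV:16.8f}     A.U. after   13 cycles",
            " Population analysis using the SCF density.",
        ]
        lines += _eigenvalue_lines("occ", occ)
        lines += _eigenvalue_lines("virt", virt)
        lines += _mulliken_block(elements, charges, spins)
        lines.append(" Normal termination of mock job.")
        return "\n".join(lines) + "\n"

    truth = {
        "elements": np.array(elements),
        "q_neutral": q_neutral / _MICRO,
        "q_cation": q_cation / _MICRO,
        "q_anion": q_anion / _MICRO,
        "f_plus": f_plus / _MICRO,
        "f_minus": f_minus / _MICRO,
        "parr_minus": spin_cation / _MICRO,
        "parr_plus": spin_anion / _MICRO,
    }
    return MockLogBundle(
        spec=spec,
        neutral=log_text("neutral", q_neutral, None),
        cation=log_text("cation", q_cation, spin_cation),
        anion=log_text("anion", q_anion, spin_anion),
        total_energies=energies,
        truth=truth,
    )


def _gaussian_on_grid(
    points: np.ndarray, center: np.ndarray, sigma: float, electrons: float
) -> np.ndarray:
    norm = electrons / (2.0 * np.pi * sigma**2) ** 1.5
    d2 = ((points - center) ** 2).sum(axis=1)
    return norm * np.exp(-d2 / (2.0 * sigma**2))


def make_mock_cubes(spec: MockSpec) -> tuple[ScalarField, ScalarField, ScalarField]:
    """Congruent (ρN, ρN−1, ρN+1) grids built from isotropic Gaussians.

    ρN−1 = ρN − g1 and ρN+1 = ρN + g2 with g1, g2 unit-normalized
    Gaussians well inside the box, so ∫(ρN − ρN−1) = ∫(ρN+1 − ρN) = 1
    analytically and the grid quadrature reproduces it to ≲1e-3.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.grid_points
    step = spec.grid_extent / p
    origin = np.full(3, -spec.grid_extent / 2.0 + step / 2.0)
    axes = np.eye(3) * step
    idx = np.indices((p, p, p)).reshape(3, -1).T
    points = origin + idx @ axes

    rho_n = np.zeros(len(points))
    for _ in range(3):
        center = rng.uniform(-1.0, 1.0, size=3)
        rho_n += _gaussian_on_grid(points, center, float(rng.uniform(1.2, 1.8)), 4.0)
    g_minus = _gaussian_on_grid(
        points, rng.uniform(-1.0, 1.0, size=3), float(rng.uniform(0.6, 0.9)), 1.0
    )
    g_plus = _gaussian_on_grid(
        points, rng.uniform(-1.0, 1.0, size=3), float(rng.uniform(0.6, 0.9)), 1.0
    )

    def pack(values: np.ndarray, tag: str) -> ScalarField:
        return ScalarField(
            origin=origin,
            axes=axes,
            counts=(p, p, p),
            values=values,
            natoms=1,
            atoms=np.array([[6.0, 0.0, 0.0, 0.0, 0.0]]),
            comments=(f"mock density {tag}", f"seed={spec.seed}"),
        )

    return pack(rho_n, "N"), pack(rho_n - g_minus, "N-1"), pack(rho_n + g_plus, "N+1")
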