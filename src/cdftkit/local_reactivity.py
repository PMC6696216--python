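"""Condensed local reactivity descriptors and volumetric Fukui fields.

Condensed Fukui functions from Mulliken charges q of the N, N−1 and N+1
electron systems (f in electrons, each summing to 1 for one-electron
differences):

    f−_k = q_k(N−1) − q_k(N)
    f+_k = q_k(N) − q_k(N+1)

Dual descriptor Δf_k = f+_k − f−_k (reported ×100); Parr functions are the
raw atomic spin densities of the radical cation (P−) and anion (P+).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, GridMismatchError, ValidationError
from .models import AtomicPopulationTable, CondensedSiteTable, ScalarField

FUKUI_SUM_TOL = 1e-3
PARR_SUM_TOL = 1e-2
GRID_TOL = 1e-6


def _check_aligned(*tables: AtomicPopulationTable) -> None:
    ref = tables[0]
    for other in tables[1:]:
        if other.n_atoms != ref.n_atoms:
            raise AlignmentError(
                f"atom counts differ between charge states: "
                f"{ref.n_atoms} vs {other.n_atoms}"
            )
        for i, (a, b) in enumerate(zip(ref.elements, other.elements)):
            if a != b:
                raise AlignmentError(
                    f"element sequences diverge at atom {i + 1}: {a!r} vs {b!r}"
                )


def condensed_fukui(
    neutral: AtomicPopulationTable,
    cation: AtomicPopulationTable,
    anion: AtomicPopulationTable,
) -> CondensedSiteTable:
    """Condensed Fukui functions from a 0/+1/−1 charge-state triple.

    The three tables must describe the same atoms in the same order. Each
    f column must sum to 1 (one electron) within ``FUKUI_SUM_TOL``; a
    violation raises, since it means the tables do not differ by single
    electrons.
    """
    _check_aligned(neutral, cation, anion)
    expected = {"neutral": 0, "cation": 1, "anion": -1}
    for name, table in (("neutral", neutral), ("cation", cation), ("anion", anion)):
        if table.charge_state != expected[name]:
            raise ValidationError(
                f"{name} table declares charge state {table.charge_state:+d}, "
                f"expected {expected[name]:+d}"
            )
    f_minus = cation.charges - neutral.charges
    f_plus = neutral.charges - anion.charges
    for name, col in (("f_plus", f_plus), ("f_minus", f_minus)):
        total = float(col.sum())
        if abs(total - 1.0) > FUKUI_SUM_TOL:
            raise ValidationError(
                f"{name} sums to {total:.6f}, not 1 (deviation "
                f"{abs(total - 1.0):.2e} > {FUKUI_SUM_TOL}); charge states do "
                "not differ by single electrons"
            )
    return CondensedSiteTable.from_atoms(
        neutral.indices, neutral.elements, f_plus=f_plus, f_minus=f_minus
    )


def dual_descriptor(table: CondensedSiteTable) -> CondensedSiteTable:
    """Fill dual = f+ − f− and dual_scaled = 100·dual on a site table."""
    if not (table.has_column("f_plus") and table.has_column("f_minus")):
        raise ValidationError("dual descriptor requires f_plus and f_minus columns")
    out = table.data.copy()
    out["dual"] = out["f_plus"] - out["f_minus"]
    out["dual_scaled"] = 100.0 * out["dual"]
    return CondensedSiteTable(out)


def parr_functions(
    cation: AtomicPopulationTable,
    anion: AtomicPopulationTable,
    into: CondensedSiteTable | None = None,
) -> CondensedSiteTable:
    """Parr functions from radical-ion spin densities.

    P−_k is the spin density of atom k in the radical cation, P+_k that in
    the radical anion; values are taken as-is (no renormalization). Sums
    deviating from the unpaired-electron counts by more than
    ``PARR_SUM_TOL`` trigger a warning, not an error, since printed tables
    truncate. When ``into`` is given, the columns are merged into it.
    """
    _check_aligned(cation, anion)
    parr_minus = cation.require_spins()
    parr_plus = anion.require_spins()
    for name, col, table in (
        ("parr_minus", parr_minus, cation),
        ("parr_plus", parr_plus, anion),
    ):
        total = float(col.sum())
        if abs(total - table.unpaired_electrons) > PARR_SUM_TOL:
            warnings.warn(
                f"{name} sums to {total:.4f}, expected "
                f"{table.unpaired_electrons} unpaired electrons",
                stacklevel=2,
            )
    if into is not None:
        if into.n_atoms != cation.n_atoms:
            raise AlignmentError(
                f"site table holds {into.n_atoms} atoms, spin tables {cation.n_atoms}"
            )
        out = into.data.copy()
        out["parr_plus"] = parr_plus
        out["parr_minus"] = parr_minus
        return CondensedSiteTable(out)
    return CondensedSiteTable.from_atoms(
        cation.indices, cation.elements, parr_plus=parr_plus, parr_minus=parr_minus
    )


@dataclass(frozen=True)
class Site:
    atom_index: int
    element: str
    value: float


@dataclass(frozen=True)
class SiteRanking:
    """Extreme reactive sites of one molecule.

    ``nucleophilic_attack`` is where a nucleophile prefers to attack (top
    positive dual, or max P+); ``electrophilic_attack`` is where an
    electrophile attacks (top negative dual, or max P−). ``degenerate``
    flags an all-tied column where the pick fell to atom 1 by the
    lowest-index tie-break.
    """

    mode: str
    nucleophilic_attack: Site
    electrophilic_attack: Site
    degenerate: bool


def _extreme(df, column: str, maximize: bool) -> Site:
    vals = df[column].to_numpy(dtype=float)
    pos = int(np.argmax(vals) if maximize else np.argmin(vals))  # first wins ties
    row = df.iloc[pos]
    return Site(int(row["atom_index"]), str(row["element"]), float(row[column]))


def rank_sites(table: CondensedSiteTable, mode: str = "dual") -> SiteRanking:
    """Pick the preferred nucleophilic- and electrophilic-attack sites.

    ``mode="dual"`` uses the dual-descriptor extremes; ``mode="parr"``
    uses the arg-max of each Parr column. Ties break to the lowest atom
    index, deterministically.
    """
    df = table.data.sort_values("atom_index", kind="stable").reset_index(drop=True)
    sorted_table = CondensedSiteTable(df)
    if mode == "dual":
        if not sorted_table.has_column("dual"):
            raise ValidationError("dual column not filled; run dual_descriptor first")
        nuc = _extreme(df, "dual", maximize=True)
        elec = _extreme(df, "dual", maximize=False)
        degenerate = nuc.value == elec.value
    elif mode == "parr":
        for col in ("parr_plus", "parr_minus"):
            if not sorted_table.has_column(col):
                raise ValidationError(f"{col} column not filled; run parr_functions first")
        nuc = _extreme(df, "parr_plus", maximize=True)
        elec = _extreme(df, "parr_minus", maximize=True)
        degenerate = (
            df["parr_plus"].nunique() == 1 and df["parr_minus"].nunique() == 1
        )
    else:
        raise ValueError(f"mode must be 'dual' or 'parr', got {mode!r}")
    return SiteRanking(
        mode=mode,
        nucleophilic_attack=nuc,
        electrophilic_attack=elec,
        degenerate=degenerate,
    )


def _check_congruent(a: ScalarField, b: ScalarField) -> None:
    if a.counts != b.counts:
        raise GridMismatchError(f"counts differ: {a.counts} vs {b.counts}")
    if not np.allclose(a.origin, b.origin, atol=GRID_TOL, rtol=0):
        raise GridMismatchError(f"origins differ: {a.origin} vs {b.origin}")
    if not np.allclose(a.axes, b.axes, atol=GRID_TOL, rtol=0):
        raise GridMismatchError("axis step vectors differ")


def fukui_field(
    rho_ref: ScalarField, rho_other: ScalarField, kind: str
) -> ScalarField:
    """Volumetric Fukui function as a density difference on a shared grid.

    ``rho_ref`` is the N-electron density. For ``kind="minus"``
    ``rho_other`` is the (N−1)-electron density and f− = ρN − ρN−1; for
    ``kind="plus"`` it is the (N+1)-electron density and f+ = ρN+1 − ρN.
    The grid-quadrature integral of the result is ≈ 1 for true
    one-electron differences (use ``ScalarField.integral``).
    """
    if kind not in ("plus", "minus"):
        raise ValueError(f"kind must be 'plus' or 'minus', got {kind!r}")
    _check_congruent(rho_ref, rho_other)
    if kind == "minus":
        diff = rho_ref.values - rho_other.values
    else:
        diff = rho_other.values - rho_ref.values
    return ScalarField(
        origin=rho_ref.origin.copy(),
        axes=rho_ref.axes.copy(),
        counts=rho_ref.counts,
        values=diff,
        natoms=rho_ref.natoms,
        atoms=rho_ref.atoms.copy(),
        comments=(f"fukui f{'+' if kind == 'plus' else '-'}", "density difference"),
    )
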