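"""Global reactivity descriptors in the frontier-orbital (Koopmans-type)
approximation, the gap→wavelength proxy, the hardness-based pKa relation,
and a ΔSCF consistency check on the frontier identification.

Working formulas (I, A in eV):

    χ    = (I + A) / 2
    η    = I − A
    ω    = χ² / (2η)
    ω−   = (3I + A)² / (16η)
    ω+   = (I + 3A)² / (16η)
    Δω±  = ω− + ω+
    λmax = hc / η              (hc = 1239.84193 eV·nm)
    pKa  = 16.3088 − 0.8268 η  (default model, overridable)

Two algebraic identities follow and are enforced by the test suite:
ω− − ω+ = χ and Δω± = ω− + ω+.
"""
from __future__ import annotations

from typing import Optional

from .constants import HC_EV_NM
from .errors import DegenerateGapError
from .models import FrontierOrbitalRecord, GlobalDescriptorSet, KidEnergies, PkaModel


def kid_energies(record: FrontierOrbitalRecord) -> KidEnergies:
    """Map frontier energies to vertical I and A: I = −εHOMO, A = −εLUMO."""
    return KidEnergies(
        ionization_potential=-record.epsilon_homo,
        electron_affinity=-record.epsilon_lumo,
    )


def global_descriptors(k: KidEnergies, label: str = "") -> GlobalDescriptorSet:
    """Compute χ, η, ω, ω−, ω+ and Δω± from vertical I and A.

    Values are returned at full precision; the reporting layer rounds.
    """
    I, A = k.ionization_potential, k.electron_affinity
    eta = I - A
    if eta <= 0:
        raise DegenerateGapError(f"hardness must be positive, got {eta}")
    chi = (I + A) / 2.0
    omega = chi * chi / (2.0 * eta)
    omega_minus = (3.0 * I + A) ** 2 / (16.0 * eta)
    omega_plus = (I + 3.0 * A) ** 2 / (16.0 * eta)
    return GlobalDescriptorSet(
        label=label,
        electronegativity=chi,
        global_hardness=eta,
        electrophilicity=omega,
        electrodonating_power=omega_minus,
        electroaccepting_power=omega_plus,
        net_electrophilicity=omega_minus + omega_plus,
    )


def lambda_max(gap: float, hc: float = HC_EV_NM) -> float:
    """Maximum-absorption wavelength (nm) from a frontier gap (eV).

    Unrounded; reports round to the nearest integer nm.
    """
    if gap <= 0:
        raise DegenerateGapError(f"gap must be positive, got {gap}")
    return hc / gap


def predict_pka(eta: float, model: Optional[PkaModel] = None) -> float:
    """Evaluate the linear hardness→pKa relation at η (eV)."""
    if eta <= 0:
        raise DegenerateGapError(f"hardness must be positive, got {eta}")
    return (model or PkaModel())(eta)


def describe(
    record: FrontierOrbitalRecord,
    pka_model: Optional[PkaModel] = None,
    hc: float = HC_EV_NM,
) -> GlobalDescriptorSet:
    """Full pipeline for one species: descriptors plus λmax and pKa."""
    ds = global_descriptors(kid_energies(record), label=record.label)
    ds.lambda_max_nm = lambda_max(ds.global_hardness, hc=hc)
    ds.pka = predict_pka(ds.global_hardness, pka_model)
    return ds


def kid_deviation(
    record: FrontierOrbitalRecord,
    e_neutral: float,
    e_cation: float,
    e_anion: float,
) -> tuple[float, float]:
    """ΔSCF consistency of the frontier identification.

    Given total energies (eV) of the N, N−1 and N+1 electron systems at a
    common geometry, returns (J_I, J_A) with

        J_I = |εHOMO + (E_cation − E_neutral)|
        J_A = |εLUMO + (E_neutral − E_anion)|

    Both vanish when the frontier eigenvalues reproduce the ΔSCF I and A
    exactly.
    """
    i_dscf = e_cation - e_neutral
    a_dscf = e_neutral - e_anion
    return abs(record.epsilon_homo + i_dscf), abs(record.epsilon_lumo + a_dscf)
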