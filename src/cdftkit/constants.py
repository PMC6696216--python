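"""Physical constants and default model coefficients.

All energies in this package are carried in electron-volts unless a function
explicitly says otherwise; grids are in Bohr.
"""

#: CODATA 2018 Hartree energy expressed in eV.
HARTREE_TO_EV: float = 27.211386245988

#: hc in eV·nm, used to convert a frontier-orbital gap into a wavelength.
HC_EV_NM: float = 1239.84193

#: Default coefficients of the hardness-based pKa regression,
#: pKa = intercept + slope * eta  (eta in eV).
PKA_INTERCEPT: float = 16.3088
PKA_SLOPE: float = -0.8268

#: Printed-precision defaults used by the reporting layer.
DESCRIPTOR_DECIMALS: int = 3
PKA_DECIMALS: int = 2


def hartree_to_ev(value: float) -> float:
    """Convert an energy from Hartree to eV."""
    return value * HARTREE_TO_EV


def ev_to_hartree(value: float) -> float:
    """Convert an energy from eV to Hartree."""
    return value / HARTREE_TO_EV
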