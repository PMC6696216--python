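"""Exception hierarchy for cdftkit."""


class CdftError(Exception):
    """Base class for all cdftkit errors."""


class ParseError(CdftError):
    """A text stream could not be parsed into the requested structure."""


class StructureError(CdftError):
    """A parsed block is present but structurally invalid (missing class of
    orbitals, duplicate/gapped atom indices, unsupported dialect)."""


class ValidationError(CdftError):
    """Parsed data violates a physical consistency check (e.g. charge sum)."""


class AlignmentError(CdftError):
    """Charge-state tables do not describe the same atom sequence."""


class GridMismatchError(CdftError):
    """Two volumetric grids are not congruent; the message names the first
    differing header field."""


class DegenerateGapError(CdftError):
    """The frontier gap is zero or negative; descriptors are undefined."""


class DataError(CdftError):
    """Required data column (e.g. spin densities) is absent."""


class MockSpecError(CdftError):
    """A synthetic-input specification is unusable."""
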