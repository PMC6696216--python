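"""Readers and writers for quantum-chemistry text artifacts.

One Gaussian-style text dialect is supported for orbital-eigenvalue
listings and Mulliken population blocks, plus the standard cube format
for volumetric grids and a plain-JSON route for frontier-orbital records.
Optimization logs print many listings; only the final block of a stream
is ever used.
"""
from __future__ import annotations

import json
import re
from pathlib import Path
from typing import IO, Iterable, Union

import numpy as np

from .constants import hartree_to_ev
from .errors import ParseError, StructureError, ValidationError
from .models import AtomicPopulationTable, FrontierOrbitalRecord, ScalarField

TextSource = Union[str, Path, IO[str]]

_EIGENVALUE_RE = re.compile(
    r"^\s*(?P<spin>Alpha|Beta)?\s*(?P<kind>occ|virt)\.?\s+eigenvalues\s*--\s*(?P<values>.*)$",
    re.IGNORECASE,
)
_MULLIKEN_HEADER_RE = re.compile(
    r"^\s*Mulliken charges(?P<spin> and spin densities)?\s*:\s*$", re.IGNORECASE
)
_ATOM_LINE_RE = re.compile(
    r"^\s*(?P<index>\d+)\s+(?P<element>[A-Z][a-z]?)\s+"
    r"(?P<charge>-?\d+\.\d+)(?:\s+(?P<spin>-?\d+\.\d+))?\s*$"
)
_FLOAT_RE = re.compile(r"-?\d+\.\d+(?:[EeDd][+-]?\d+)?|-?\d+")


def _as_lines(source: TextSource) -> list[str]:
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, Path):
        text = source.read_text()
    else:
        text = str(source)
        if "\n" not in text and len(text) < 4096:
            try:
                if Path(text).is_file():
                    text = Path(text).read_text()
            except OSError:
                pass
    return text.splitlines()


def _parse_floats(chunk: str) -> list[float]:
    return [float(tok.replace("D", "E").replace("d", "e")) for tok in _FLOAT_RE.findall(chunk)]


def parse_orbital_energies(
    source: TextSource, unit: str = "hartree", label: str = "unknown"
) -> FrontierOrbitalRecord:
    """Extract εHOMO/εLUMO (in eV) from the final orbital listing of a log.

    A listing is a maximal run of consecutive ``... occ./virt. eigenvalues --``
    lines. For unrestricted listings the HOMO is the highest occupied
    eigenvalue over both spin channels and the LUMO the lowest virtual one.
    ``unit`` declares the eigenvalue unit in the text ("hartree" or "ev").
    """
    if unit not in ("hartree", "ev"):
        raise ValueError(f"unit must be 'hartree' or 'ev', got {unit!r}")
    blocks: list[list[tuple[str, list[float]]]] = []
    current: list[tuple[str, list[float]]] = []
    for line in _as_lines(source):
        m = _EIGENVALUE_RE.match(line)
        if m:
            current.append((m.group("kind").lower(), _parse_floats(m.group("values"))))
        elif current:
            blocks.append(current)
            current = []
    if current:
        blocks.append(current)
    if not blocks:
        raise ParseError("no orbital-eigenvalue listing found in stream")
    final = blocks[-1]
    occupied = [v for kind, vals in final for v in vals if kind == "occ"]
    virtual = [v for kind, vals in final for v in vals if kind == "virt"]
    if not occupied:
        raise StructureError("final orbital listing has no occupied eigenvalues")
    if not virtual:
        raise StructureError("final orbital listing has no virtual eigenvalues")
    homo, lumo = max(occupied), min(virtual)
    if unit == "hartree":
        homo, lumo = hartree_to_ev(homo), hartree_to_ev(lumo)
    return FrontierOrbitalRecord(
        label=label, epsilon_homo=homo, epsilon_lumo=lumo, source="parsed"
    )


def parse_mulliken_table(source: TextSource, charge_state: int) -> AtomicPopulationTable:
    """Parse the final Mulliken block of a log into a population table.

    Both the plain-charges block and the combined charges-and-spin-densities
    block are accepted. Atom order in the text is preserved; the charge sum
    is validated against ``charge_state``.
    """
    lines = _as_lines(source)
    starts = [i for i, line in enumerate(lines) if _MULLIKEN_HEADER_RE.match(line)]
    if not starts:
        raise ParseError("no Mulliken charges block found in stream")
    start = starts[-1]
    with_spin = bool(_MULLIKEN_HEADER_RE.match(lines[start]).group("spin"))

    indices: list[int] = []
    elements: list[str] = []
    charges: list[float] = []
    spins: list[float] = []
    for line in lines[start + 1 :]:
        m = _ATOM_LINE_RE.match(line)
        if m:
            indices.append(int(m.group("index")))
            elements.append(m.group("element"))
            charges.append(float(m.group("charge")))
            if m.group("spin") is not None:
                spins.append(float(m.group("spin")))
            continue
        if indices:
            break  # footer ("Sum of Mulliken charges = ...") or next section
        # column-number header lines between the title and the atoms
        if line.strip() and not re.fullmatch(r"[\d\s]+", line):
            break
    if not indices:
        raise ParseError("Mulliken block contains no atom rows")
    if with_spin and len(spins) != len(indices):
        raise StructureError(
            "charges-and-spin-densities block is missing spin values on some rows"
        )
    spin_arr = np.asarray(spins) if (with_spin and spins) else None
    if spin_arr is not None:
        multiplicity = int(round(abs(float(spin_arr.sum())))) + 1
    else:
        multiplicity = 1
    return AtomicPopulationTable(
        charge_state=charge_state,
        multiplicity_hint=multiplicity,
        indices=np.asarray(indices),
        elements=tuple(elements),
        charges=np.asarray(charges),
        spins=spin_arr,
    )


def load_record_json(source: Union[str, Path, dict]) -> FrontierOrbitalRecord:
    """Build a record from ``{label, epsilon_homo, epsilon_lumo, unit}``.

    ``unit`` defaults to eV; Hartree inputs are converted.
    """
    if isinstance(source, dict):
        doc = source
    else:
        doc = json.loads(Path(source).read_text())
    unit = doc.get("unit", "ev").lower()
    homo, lumo = float(doc["epsilon_homo"]), float(doc["epsilon_lumo"])
    if unit == "hartree":
        homo, lumo = hartree_to_ev(homo), hartree_to_ev(lumo)
    elif unit != "ev":
        raise ValueError(f"unsupported unit {unit!r} in record document")
    return FrontierOrbitalRecord(
        label=str(doc.get("label", "unknown")),
        epsilon_homo=homo,
        epsilon_lumo=lumo,
        source=str(doc.get("source", "parsed")),
    )


def read_cube(path: Union[str, Path]) -> ScalarField:
    """Read a Gaussian cube file.

    The molecular-orbital dialect (negative atom count) is rejected. A
    truncated value section raises with expected vs found counts.
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 6:
        raise ParseError(f"cube file {path} is too short to hold a header")
    comments = (lines[0].rstrip(), lines[1].rstrip())
    header = _parse_floats(lines[2])
    if len(header) < 4:
        raise ParseError("malformed atom-count/origin line in cube header")
    natoms = int(header[0])
    if natoms < 0:
        raise StructureError(
            "negative atom count marks a molecular-orbital cube; "
            "only scalar-density cubes are supported"
        )
    origin = np.array(header[1:4])
    counts = []
    axes = np.zeros((3, 3))
    for i in range(3):
        vals = _parse_floats(lines[3 + i])
        if len(vals) < 4:
            raise ParseError(f"malformed axis line {i + 1} in cube header")
        n = int(vals[0])
        if n < 1:
            raise ParseError(f"axis {i + 1} declares a non-positive point count {n}")
        counts.append(n)
        axes[i] = vals[1:4]
    atom_lines = lines[6 : 6 + natoms]
    if len(atom_lines) < natoms:
        raise ParseError(f"cube declares {natoms} atoms but the header ends early")
    atoms = np.array([_parse_floats(line)[:5] for line in atom_lines]).reshape(natoms, 5)
    values: list[float] = []
    for line in lines[6 + natoms :]:
        values.extend(_parse_floats(line))
    expected = counts[0] * counts[1] * counts[2]
    if len(values) != expected:
        raise ParseError(
            f"cube value section holds {len(values)} numbers, expected {expected}"
        )
    return ScalarField(
        origin=origin,
        axes=axes,
        counts=tuple(counts),
        values=np.asarray(values),
        natoms=natoms,
        atoms=atoms,
        comments=comments,
    )


def write_cube(field: ScalarField, path: Union[str, Path]) -> Path:
    """Write a ScalarField as a Gaussian cube file (values at 6 s.f.)."""
    path = Path(path)
    out: list[str] = [field.comments[0], field.comments[1]]
    out.append(_cube_header_line(field.natoms, field.origin))
    for i in range(3):
        out.append(_cube_header_line(field.counts[i], field.axes[i]))
    for row in field.atoms:
        z = int(row[0])
        out.append(f"{z:5d}" + "".join(f"{v:12.6f}" for v in row[1:5]))
    vals = field.values
    for i in range(0, vals.size, 6):
        out.append("".join(f"{v:13.5E}" for v in vals[i : i + 6]))
    path.write_text("\n".join(out) + "\n")
    return path


def _cube_header_line(count: int, vec: Iterable[float]) -> str:
    return f"{count:5d}" + "".join(f"{v:12.6f}" for v in vec)
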