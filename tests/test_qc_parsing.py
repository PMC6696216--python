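import numpy as np
import pytest
from hypothesis import given, strategies as st

from cdftkit.constants import ev_to_hartree, hartree_to_ev
from cdftkit.errors import ParseError, StructureError, ValidationError
from cdftkit.models import ScalarField
from cdftkit.qc_parsing import (
    load_record_json,
    parse_mulliken_table,
    parse_orbital_energies,
    read_cube,
    write_cube,
)

OCC_VIRT_HA = """\
 Some preamble line
 Alpha  occ. eigenvalues --   -0.91234   -0.55555   -0.22316
 Alpha virt. eigenvalues --   -0.06247    0.01234    0.94000
 Trailer
"""


class TestParseOrbitalEnergies:
    def test_hartree_fragment_matches_ev_targets(self):
        # -0.22316 Ha / -0.06247 Ha chosen to invert to the -6.072/-1.700 eV
        # record at 5-decimal Hartree print precision
        rec = parse_orbital_energies(OCC_VIRT_HA, unit="hartree")
        assert rec.epsilon_homo == pytest.approx(-6.072, abs=1e-3)
        assert rec.epsilon_lumo == pytest.approx(-1.700, abs=1e-3)

    def test_ev_listing_taken_verbatim(self):
        text = (
            " Alpha  occ. eigenvalues --   -8.100   -6.072\n"
            " Alpha virt. eigenvalues --   -1.700    0.500\n"
        )
        rec = parse_orbital_energies(text, unit="ev")
        assert (rec.epsilon_homo, rec.epsilon_lumo) == (-6.072, -1.700)

    def test_last_block_wins(self):
        text = (
            " Alpha  occ. eigenvalues --   -0.90000\n"
            " Alpha virt. eigenvalues --    0.90000\n"
            " SCF iteration separator\n"
            " Alpha  occ. eigenvalues --   -0.50000\n"
            " Alpha virt. eigenvalues --    0.10000\n"
        )
        rec = parse_orbital_energies(text, unit="hartree")
        assert rec.epsilon_homo == pytest.approx(hartree_to_ev(-0.5))
        assert rec.epsilon_lumo == pytest.approx(hartree_to_ev(0.1))

    def test_unrestricted_uses_both_channels(self):
        text = (
            " Alpha  occ. eigenvalues --   -0.40000\n"
            " Alpha virt. eigenvalues --    0.30000\n"
            "  Beta  occ. eigenvalues --   -0.35000\n"
            "  Beta virt. eigenvalues --    0.20000\n"
        )
        rec = parse_orbital_energies(text, unit="hartree")
        assert rec.epsilon_homo == pytest.approx(hartree_to_ev(-0.35))
        assert rec.epsilon_lumo == pytest.approx(hartree_to_ev(0.20))

    def test_no_block_is_parse_error(self):
        with pytest.raises(ParseError):
            parse_orbital_energies("nothing of interest here\n")

    @pytest.mark.parametrize(
        "text,missing",
        [
            (" Alpha  occ. eigenvalues --   -0.4  -0.3\n", "virtual"),
            (" Alpha virt. eigenvalues --    0.3   0.4\n", "occupied"),
        ],
    )
    def test_one_sided_listing_names_missing_class(self, text, missing):
        with pytest.raises(StructureError, match=missing):
            parse_orbital_energies(text)

    def test_bad_unit_rejected(self):
        with pytest.raises(ValueError):
            parse_orbital_energies(OCC_VIRT_HA, unit="kcal")


def mulliken_text(rows, spin=False, footer=True):
    head = " Mulliken charges and spin densities:" if spin else " Mulliken charges:"
    lines = [head, "               1          2" if spin else "               1"]
    for i, row in enumerate(rows, start=1):
        if spin:
            el, q, s = row
            lines.append(f"{i:6d}  {el:<2s}  {q:10.6f}  {s:10.6f}")
        else:
            el, q = row
            lines.append(f"{i:6d}  {el:<2s}  {q:10.6f}")
    if footer:
        total = sum(r[1] for r in rows)
        lines.append(f" Sum of Mulliken charges = {total:10.5f}")
    return "\n".join(lines) + "\n"


class TestParseMulliken:
    def test_exact_sum_accepted(self):
        text = mulliken_text([("C", 0.5), ("N", 0.4), ("O", 0.1)])
        table = parse_mulliken_table(text, charge_state=1)
        assert table.n_atoms == 3
        assert table.charges.sum() == pytest.approx(1.0)
        assert table.elements == ("C", "N", "O")
        assert not table.has_spins

    def test_wrong_declared_charge_is_validation_error(self):
        text = mulliken_text([("C", 0.5), ("N", 0.4), ("O", 0.1)])
        with pytest.raises(ValidationError, match="1.0"):
            parse_mulliken_table(text, charge_state=0)

    def test_doublet_spin_block(self):
        text = mulliken_text(
            [("C", 0.5, 0.7), ("N", 0.4, 0.2), ("O", 0.1, 0.1)], spin=True
        )
        table = parse_mulliken_table(text, charge_state=1)
        assert table.has_spins
        assert table.spins.sum() == pytest.approx(1.0)
        assert table.multiplicity_hint == 2

    def test_order_preserved(self):
        rows = [("H", 0.11), ("He", -0.23), ("C", 0.12)]
        table = parse_mulliken_table(mulliken_text(rows), charge_state=0)
        assert table.elements == ("H", "He", "C")
        np.testing.assert_allclose(table.charges, [0.11, -0.23, 0.12])

    def test_last_block_wins(self):
        first = mulliken_text([("C", 0.9), ("N", 0.1)])
        second = mulliken_text([("C", 0.5), ("N", 0.5)])
        table = parse_mulliken_table(first + " separator\n" + second, charge_state=1)
        np.testing.assert_allclose(table.charges, [0.5, 0.5])

    def test_gapped_indices_rejected(self):
        text = (
            " Mulliken charges:\n               1\n"
            "     1  C    0.500000\n"
            "     3  N    0.500000\n"
        )
        with pytest.raises(StructureError, match="index"):
            parse_mulliken_table(text, charge_state=1)

    def test_missing_block_is_parse_error(self):
        with pytest.raises(ParseError):
            parse_mulliken_table("no populations here\n", charge_state=0)


@given(st.floats(min_value=-1000.0, max_value=1000.0, allow_nan=False))
def test_hartree_ev_round_trip(x):
    assert ev_to_hartree(hartree_to_ev(x)) == pytest.approx(x, rel=1e-9, abs=1e-12)


def random_field(rng, n=3):
    return ScalarField(
        origin=rng.normal(size=3),
        axes=np.diag(rng.uniform(0.2, 0.6, size=3)),
        counts=(n, n, n),
        values=rng.normal(size=n**3),
        natoms=2,
        atoms=np.array([[6, 0, 0.1, 0.2, 0.3], [8, 0, -0.1, 0.4, 0.9]], dtype=float),
    )


class TestCubeIO:
    def test_constant_unit_cube(self, tmp_path):
        field = ScalarField(
            origin=[0, 0, 0], axes=np.eye(3), counts=(2, 2, 2), values=np.ones(8)
        )
        path = write_cube(field, tmp_path / "ones.cube")
        back = read_cube(path)
        assert back.counts == (2, 2, 2)
        np.testing.assert_array_equal(back.values, np.ones(8))

    def test_round_trip_six_significant_figures(self, tmp_path):
        field = random_field(np.random.default_rng(11))
        back = read_cube(write_cube(field, tmp_path / "f.cube"))
        np.testing.assert_allclose(back.values, field.values, rtol=5e-6)
        np.testing.assert_allclose(back.origin, field.origin, atol=5e-7)
        np.testing.assert_allclose(back.axes, field.axes, atol=5e-7)
        assert back.natoms == field.natoms
        np.testing.assert_allclose(back.atoms, field.atoms, atol=5e-7)

    def test_read_write_read_is_fixed_point(self, tmp_path):
        field = random_field(np.random.default_rng(7))
        once = read_cube(write_cube(field, tmp_path / "a.cube"))
        twice = read_cube(write_cube(once, tmp_path / "b.cube"))
        np.testing.assert_array_equal(once.values, twice.values)
        np.testing.assert_array_equal(once.origin, twice.origin)
        np.testing.assert_array_equal(once.axes, twice.axes)
        np.testing.assert_array_equal(once.atoms, twice.atoms)
        assert once.comments == twice.comments

    def test_truncated_values_reported(self, tmp_path):
        field = ScalarField(
            origin=[0, 0, 0], axes=np.eye(3), counts=(2, 2, 2), values=np.ones(8)
        )
        path = write_cube(field, tmp_path / "t.cube")
        lines = path.read_text().splitlines()
        path.write_text("\n".join(lines[:-1]) + "\n")  # drop the last value row
        with pytest.raises(ParseError, match="expected 8"):
            read_cube(path)

    def test_mo_cube_dialect_rejected(self, tmp_path):
        path = tmp_path / "mo.cube"
        path.write_text(
            "c1\nc2\n   -1    0.0 0.0 0.0\n"
            "    2    1.0 0.0 0.0\n    2    0.0 1.0 0.0\n    2    0.0 0.0 1.0\n"
            "    6    0.0 0.0 0.0 0.0\n"
            "    1\n" + " 1.0" * 8 + "\n"
        )
        with pytest.raises(StructureError, match="orbital"):
            read_cube(path)


class TestRecordJson:
    def test_ev_document(self):
        rec = load_record_json(
            {"label": "x", "epsilon_homo": -6.072, "epsilon_lumo": -1.700, "unit": "ev"}
        )
        assert (rec.epsilon_homo, rec.epsilon_lumo) == (-6.072, -1.700)

    def test_hartree_document_converted(self):
        rec = load_record_json(
            {"label": "x", "epsilon_homo": -0.5, "epsilon_lumo": 0.1, "unit": "hartree"}
        )
        assert rec.epsilon_homo == pytest.approx(hartree_to_ev(-0.5))

    def test_file_round_trip(self, tmp_path):
        path = tmp_path / "rec.json"
        path.write_text('{"label": "m", "epsilon_homo": -5.0, "epsilon_lumo": -1.0}')
        assert load_record_json(path).label == "m"
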