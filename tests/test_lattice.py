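"""Lattice construction, charge assignment and tyrosination editing."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyn2lattice import (
    LatticeSpec,
    ModelValidationError,
    PlacementSpec,
    assign_charges,
    build_lattice,
    make_site_grid,
    place_dimer,
    set_tyrosination,
)
from dyn2lattice.bead_model import AA1TO3, BeadModel
from dyn2lattice.synthetic import gen_toy_motor


def _chain(seq, chain="T", start=1):
    n = len(seq)
    return BeadModel(
        chain_id=[chain] * n,
        residue_index=np.arange(start, start + n, dtype=np.int64),
        residue_name=[AA1TO3[a] for a in seq],
        positions=np.column_stack([np.arange(n) * 0.38, np.zeros(n), np.zeros(n)]),
        charges=np.zeros(n),
        group=["tail"] * n,
        bonds=np.column_stack([np.arange(n - 1), np.arange(1, n)]).astype(np.int64),
    )


# ----------------------------------------------------------------------
class TestBuildLattice:
    @pytest.mark.parametrize(
        "n_pf,n_dimers",
        [(4, 3), (1, 1), (2, 5)],
    )
    def test_bead_count_formula(self, n_pf, n_dimers):
        spec = LatticeSpec(n_pf=n_pf, n_dimers_per_pf=n_dimers)
        model = build_lattice(spec)
        per_dimer = 2 * spec.beads_per_monomer + len(spec.tail_sequence)
        assert model.n_beads == n_pf * n_dimers * per_dimer

    def test_tail_chain_count(self):
        model = build_lattice(LatticeSpec())
        tail_chains = {model.chain_id[i] for i in model.group_beads("tail")}
        assert len(tail_chains) == 12

    def test_minimal_lattice(self):
        model = build_lattice(LatticeSpec(n_pf=1, n_dimers_per_pf=1))
        monomers = {c for c in model.chains()}
        assert len(monomers) == 2  # one alpha chain (with tail) + one beta
        assert len({model.chain_id[i] for i in model.group_beads("tail")}) == 1

    def test_lateral_geometry_matches_spec(self):
        """Equivalent beads on adjacent PFs differ by the lateral spacing
        (and by the B-lattice stagger axially), by direct coordinate
        arithmetic."""
        spec = LatticeSpec()
        model = build_lattice(spec)
        a0 = model.chain_beads("A0.0")
        a1 = model.chain_beads("A1.0")
        delta = model.positions[a1[0]] - model.positions[a0[0]]
        assert delta[1] == pytest.approx(spec.lateral_spacing)
        assert delta[0] == pytest.approx(spec.stagger)
        assert delta[2] == pytest.approx(0.0)

    def test_axial_rise(self):
        spec = LatticeSpec()
        model = build_lattice(spec)
        d00 = model.chain_beads("A0.0")
        d01 = model.chain_beads("A0.1")
        delta = model.positions[d01[0]] - model.positions[d00[0]]
        assert delta[0] == pytest.approx(spec.axial_rise_per_dimer)

    def test_deterministic(self):
        m1 = build_lattice(LatticeSpec())
        m2 = build_lattice(LatticeSpec())
        np.testing.assert_array_equal(m1.positions, m2.positions)
        np.testing.assert_array_equal(m1.charges, m2.charges)

    @pytest.mark.parametrize(
        "bad",
        [
            {"n_pf": 0},
            {"n_dimers_per_pf": -1},
            {"axial_rise_per_dimer": 0.0},
            {"lateral_spacing": -5.2},
            {"tail_sequence": ""},
            {"tail_state": "maybe"},
        ],
    )
    def test_validation_errors(self, bad):
        with pytest.raises(ModelValidationError):
            build_lattice(LatticeSpec(**bad))


# ----------------------------------------------------------------------
class TestAssignCharges:
    def test_polyglycine_terminal_charge_only(self):
        model = assign_charges(_chain("GGGGG"))
        np.testing.assert_array_equal(model.charges, [0, 0, 0, 0, -1])

    def test_tyrosinated_tail_eey(self):
        model = assign_charges(_chain("EEY"))
        np.testing.assert_array_equal(model.charges, [-1, -1, -1])

    def test_detyrosinated_tail_ee(self):
        """The exposed terminal glutamate carries side chain plus
        carboxylate: −2."""
        model = assign_charges(_chain("EE"))
        np.testing.assert_array_equal(model.charges, [-1, -2])

    def test_idempotent(self):
        model = assign_charges(assign_charges(_chain("KDEY")))
        np.testing.assert_array_equal(model.charges, [1, -1, -1, -1])

    def test_unknown_residue_listed(self):
        model = _chain("GG")
        model.residue_name[1] = "XXX"
        with pytest.raises(ModelValidationError, match="XXX"):
            assign_charges(model)

    @given(seq=st.text(alphabet=sorted(AA1TO3), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_tail_total_charge_rule(self, seq):
        """Total charge = (#K/R) − (#D/E) − 1 for any chain."""
        model = assign_charges(_chain(seq))
        expected = sum(+1 for a in seq if a in "KR") \
            - sum(1 for a in seq if a in "DE") - 1
        assert model.charges.sum() == pytest.approx(expected)


# ----------------------------------------------------------------------
class TestSetTyrosination:
    def test_dy_removes_terminal_tyr(self):
        model = assign_charges(_chain("GEGEGEEY"))
        out = set_tyrosination(model, "dY", chains=["T"])
        assert out.n_beads == model.n_beads - 1
        assert out.residue_name[-1] == "GLU"
        assert out.charges[-1] == -2

    def test_dy_on_lattice_removes_one_bead_per_tail(self, y_lattice):
        out = set_tyrosination(y_lattice, "dY")
        assert out.n_beads == y_lattice.n_beads - 12

    def test_double_dy_raises(self):
        model = assign_charges(_chain("EEY"))
        once = set_tyrosination(model, "dY", chains=["T"])
        with pytest.raises(ModelValidationError, match="TYR"):
            set_tyrosination(once, "dY", chains=["T"])

    def test_y_is_identity_with_warning(self, caplog):
        model = assign_charges(_chain("EE"))
        with caplog.at_level(logging.WARNING):
            out = set_tyrosination(model, "Y", chains=["T"])
        assert out.n_beads == model.n_beads
        assert any("detyrosinated" in r.message for r in caplog.records)

    def test_y_idempotent_on_tyrosinated(self):
        model = assign_charges(_chain("EEY"))
        out = set_tyrosination(model, "Y", chains=["T"])
        np.testing.assert_array_equal(out.charges, model.charges)

    def test_preserves_net_tail_charge(self):
        model = assign_charges(_chain("AEGAGEGEGEEY"))
        out = set_tyrosination(model, "dY", chains=["T"])
        assert out.charges.sum() == model.charges.sum()  # Tyr was neutral


# ----------------------------------------------------------------------
@pytest.fixture(scope="module")
def parts():
    spec = LatticeSpec()
    return (build_lattice(spec), make_site_grid(spec), spec)


@pytest.fixture(scope="module")
def straight_parts():
    """Stagger-free lattice: adjacent-PF sites are axially aligned, so
    the placement symmetries hold exactly."""
    spec = LatticeSpec(stagger=0.0)
    return (build_lattice(spec), make_site_grid(spec), spec)


class TestPlaceDimer:
    @staticmethod
    def _system(parts, position):
        lattice, grid, spec = parts
        low, high = gen_toy_motor()
        return place_dimer(lattice, low, high,
                           PlacementSpec(position_id=position), grid)

    def test_low_head_at_center_site(self, parts):
        lattice, grid, _ = parts
        system = self._system(parts, 2)
        com = system.group_com("mtbd_low")
        np.testing.assert_allclose(com, grid.site_centers[1, 1], atol=1e-9)

    def test_lateral_position_zero_axial_offset(self, straight_parts):
        system = self._system(straight_parts, 2)
        delta = system.group_com("mtbd_high") - system.group_com("mtbd_low")
        assert delta[0] == pytest.approx(0.0, abs=1e-9)

    def test_lateral_offset_is_stagger_on_b_lattice(self, parts):
        *_, spec = parts
        system = self._system(parts, 2)
        delta = system.group_com("mtbd_high") - system.group_com("mtbd_low")
        assert delta[0] == pytest.approx(spec.stagger, abs=1e-9)

    def test_forward_position_toward_minus_end(self, straight_parts):
        _, grid, spec = straight_parts
        system = self._system(straight_parts, 3)
        delta = system.group_com("mtbd_high") - system.group_com("mtbd_low")
        assert delta @ grid.axial_direction == pytest.approx(
            spec.axial_rise_per_dimer, abs=1e-9)

    def test_backward_forward_mirror(self, straight_parts):
        """Positions 1 and 3 are mirror images under axial reflection."""
        s1 = self._system(straight_parts, 1)
        s3 = self._system(straight_parts, 3)
        d1 = s1.group_com("mtbd_high") - s1.group_com("mtbd_low")
        d3 = s3.group_com("mtbd_high") - s3.group_com("mtbd_low")
        np.testing.assert_allclose(d1 * np.array([-1, 1, 1]), d3, atol=1e-9)

    def test_lattice_coordinates_unchanged(self, parts):
        lattice, _, _ = parts
        system = self._system(parts, 2)
        np.testing.assert_array_equal(system.positions[: lattice.n_beads],
                                      lattice.positions)

    def test_too_small_lattice_rejected(self):
        spec = LatticeSpec(n_pf=1, n_dimers_per_pf=1)
        small = build_lattice(spec)
        grid = make_site_grid(LatticeSpec())
        low, high = gen_toy_motor()
        with pytest.raises(ModelValidationError):
            place_dimer(small, low, high, PlacementSpec(2), grid)

    def test_tether_added(self, parts):
        system = self._system(parts, 2)
        assert len(system.tethers) == 1

    def test_native_interface_includes_terminal_tyrosine(self, parts):
        system = self._system(parts, 2)
        y451 = {
            i for i in range(system.n_beads)
            if system.residue_name[i] == "TYR" and system.residue_index[i] == 451
        }
        in_contacts = {
            int(x) for pair in system.native_contacts for x in pair
        }
        assert y451 & in_contacts


class TestSiteGrid:
    def test_spacings_and_orthogonality(self, lattice_spec, site_grid):
        c = site_grid.site_centers
        ax, lat = site_grid.axial_direction, site_grid.lateral_direction
        assert (c[0, 1] - c[0, 0]) @ ax == pytest.approx(
            lattice_spec.axial_rise_per_dimer)
        assert (c[1, 0] - c[0, 0]) @ lat == pytest.approx(
            lattice_spec.lateral_spacing)
        assert abs(ax @ lat) < 1e-12
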