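"""Charge scaling, LJ interpolation, Born and Eyring utilities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eccperm.io import read_topology
from eccperm.topology import (
    AtomRecord,
    BornModelParams,
    IonLJAnchorTable,
    ScalingScheme,
    SolvationTarget,
    Topology,
    born_electronic_term,
    born_scaled_solvation_target,
    eyring_barrier_difference,
    interpolate_ion_sigma,
    scale_group_charges,
    scale_weighted_charges,
    scaling_factor_from_dielectric,
)

from conftest import ASP_GROUP


def make_topology(residues):
    """residues: list of (res_name, [(atom, charge), ...])."""
    atoms = []
    for rid, (name, atom_charges) in enumerate(residues, start=1):
        for aname, q in atom_charges:
            atoms.append(
                AtomRecord(
                    atom_name=aname, residue_name=name, residue_id=rid,
                    charge_group_id=rid, partial_charge=q,
                )
            )
    return Topology(atoms=atoms)


class TestGroupScaling:
    def test_asp_group_scales_to_q_times_formal(self, asp_itp):
        top = read_topology(asp_itp)
        scaled = scale_group_charges(top, ASP_GROUP, 0.78)
        group = [
            a.partial_charge
            for a in scaled.atoms
            if a.residue_name == "ASP" and a.atom_name in ASP_GROUP["ASP"]
        ]
        assert sum(group) == pytest.approx(-0.78, abs=1e-9)
        # single-atom K+ group
        pot = [a for a in scaled.atoms if a.residue_name == "POT"]
        assert pot[0].partial_charge == pytest.approx(0.78, abs=1e-12)

    def test_identity_at_q_one(self, asp_itp):
        top = read_topology(asp_itp)
        scaled = scale_group_charges(top, ASP_GROUP, 1.0)
        assert [a.partial_charge for a in scaled.atoms] == [
            a.partial_charge for a in top.atoms
        ]

    def test_untouched_atoms_unchanged(self, asp_itp):
        top = read_topology(asp_itp)
        scaled = scale_group_charges(top, ASP_GROUP, 0.7)
        for a, b in zip(top.atoms, scaled.atoms):
            if a.atom_name not in ASP_GROUP.get(a.residue_name, ()):
                assert b.partial_charge == a.partial_charge

    def test_non_integral_group_rejected_with_residue_name(self):
        top = make_topology([("GLU", [("CD", 0.5), ("OE1", -0.8)])])
        with pytest.raises(ValueError, match="GLU"):
            scale_group_charges(top, {"GLU": ["CD", "OE1"]}, 0.8)

    def test_unknown_residue_rejected(self, asp_itp):
        top = read_topology(asp_itp)
        with pytest.raises(ValueError, match="LYS"):
            scale_group_charges(top, {"LYS": ["NZ"]}, 0.8)

    def test_missing_group_atom_rejected(self, asp_itp):
        top = read_topology(asp_itp)
        with pytest.raises(ValueError, match="OD9"):
            scale_group_charges(top, {"ASP": ["CG", "OD1", "OD9"]}, 0.8)

    def test_inversion_recovers_original(self, asp_itp):
        top = read_topology(asp_itp)
        scaled = scale_group_charges(top, ASP_GROUP, 0.78)
        back = scale_group_charges(scaled, ASP_GROUP, 1.0 / 0.78)
        for a, b in zip(top.atoms, back.atoms):
            assert abs(a.partial_charge - b.partial_charge) < 1e-9

    @given(q=st.floats(0.65, 1.0))
    @settings(deadline=None, max_examples=30)
    def test_charge_conservation_scales_net_charge(self, q):
        """Net charge of the system goes from Q to q*Q; neutral stays neutral."""
        top = make_topology(
            [
                ("ASP", [("N", -0.3), ("CB", -0.4), ("CG", 0.2), ("OD1", -0.8), ("H", 0.3)]),
                ("LYS", [("CE", 0.2), ("NZ", -0.1), ("HZ1", 0.9), ("C", 0.1), ("O", -0.1)]),
                ("POT", [("POT", 1.0)]),
            ]
        )
        groups = {"ASP": ["CB", "CG", "OD1"], "LYS": ["CE", "NZ", "HZ1"], "POT": ["POT"]}
        q0 = top.system_net_charge
        scaled = scale_group_charges(top, groups, q)
        n = len(top.atoms)
        assert abs(scaled.system_net_charge - q * q0) < n * 1e-6

    def test_neutral_system_stays_neutral(self, asp_itp):
        top = read_topology(asp_itp)
        assert top.system_net_charge == pytest.approx(0.0, abs=1e-9)
        for q in (0.65, 0.78, 0.9):
            assert scale_group_charges(top, ASP_GROUP, q).system_net_charge == pytest.approx(
                0.0, abs=13 * 1e-6
            )


class TestWeightedScaling:
    CHARGED = {"N": -0.3, "H": 0.25, "CA": 0.05, "CB": -0.80, "CG": 1.80}
    NEUTRAL = {"N": -0.4, "H": 0.30, "CA": 0.10, "CB": -0.60, "CG": 0.60}

    def test_hand_arithmetic_example(self):
        out = scale_weighted_charges(self.CHARGED, self.NEUTRAL, 0.75)
        assert out["CB"] == pytest.approx(0.75 * -0.80 + 0.25 * -0.60, abs=1e-12)
        assert out["CB"] == pytest.approx(-0.75, abs=1e-12)

    def test_q_one_returns_charged_state(self):
        out = scale_weighted_charges(self.CHARGED, self.NEUTRAL, 1.0)
        assert out == pytest.approx(self.CHARGED)

    @given(q=st.floats(0.1, 1.0))
    @settings(deadline=None, max_examples=25)
    def test_residue_net_is_q_times_formal(self, q):
        out = scale_weighted_charges(self.CHARGED, self.NEUTRAL, q)
        assert sum(out.values()) == pytest.approx(q * 1.0, abs=1e-9)

    def test_atom_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            scale_weighted_charges({"A": 1.0}, {"B": 0.0}, 0.8)

    def test_non_neutral_neutral_state_rejected(self):
        with pytest.raises(ValueError, match="net-zero"):
            scale_weighted_charges({"A": 1.0}, {"A": 0.2}, 0.8)

    def test_agrees_with_group_mode_when_change_is_localized(self):
        """If charged and neutral states differ only inside the charge group,
        the weighted average equals multiplying that group by q."""
        charged = {"N": -0.3, "H": 0.3, "CB": -0.4, "CG": 0.2, "OD1": -0.8}
        neutral = {"N": -0.3, "H": 0.3, "CB": 0.0, "CG": 0.0, "OD1": 0.0}
        q = 0.7
        weighted = scale_weighted_charges(charged, neutral, q)
        for atom in ("CB", "CG", "OD1"):  # the group: scaled by q
            assert weighted[atom] == pytest.approx(q * charged[atom], abs=1e-12)
        for atom in ("N", "H"):  # outside the group: unchanged
            assert weighted[atom] == pytest.approx(charged[atom], abs=1e-12)


class TestSigmaInterpolation:
    def test_exact_at_anchors_and_midpoint(self):
        table = IonLJAnchorTable(
            ion="K", anchors={1.00: 0.3000, 0.80: 0.2850, 0.75: 0.2800}, epsilon=0.37
        )
        assert interpolate_ion_sigma(table, 0.80) == pytest.approx(0.2850, abs=1e-15)
        assert interpolate_ion_sigma(table, 0.775) == pytest.approx(
            (0.2850 + 0.2800) / 2, abs=1e-12
        )

    @given(q=st.floats(0.65, 1.0))
    @settings(deadline=None, max_examples=50)
    def test_linear_table_reproduced_in_closed_form(self, q):
        anchors = {qa: 0.3 - 0.1 * (1 - qa) for qa in np.arange(0.65, 1.0001, 0.05)}
        table = IonLJAnchorTable(ion="NA", anchors=anchors, epsilon=0.2)
        assert interpolate_ion_sigma(table, q) == pytest.approx(
            0.3 - 0.1 * (1 - q), abs=1e-12
        )

    def test_no_extrapolation(self):
        table = IonLJAnchorTable(ion="K", anchors={1.0: 0.3, 0.8: 0.28}, epsilon=0.4)
        with pytest.raises(ValueError, match="extrapolat"):
            interpolate_ion_sigma(table, 0.5)


class TestBornModel:
    def test_target_limits_and_hand_value(self):
        assert born_scaled_solvation_target(-80.0, 1.0) == -80.0
        assert born_scaled_solvation_target(-123.4, 0.0) == 0.0
        assert born_scaled_solvation_target(-80.0, 0.78) == pytest.approx(-48.672, abs=1e-9)
        assert SolvationTarget(dG_exp=-80.0, q=0.78).dG_target == pytest.approx(-48.672)

    def test_monotone_in_q_for_negative_dg(self):
        qs = np.linspace(0, 1, 20)
        vals = [born_scaled_solvation_target(-80.0, q) for q in qs]
        assert all(b < a for a, b in zip(vals, vals[1:]))
        assert vals[-1] == -80.0

    def test_electronic_term_limits(self):
        p = BornModelParams(z=1, r0=0.2)
        assert born_electronic_term(p, 1.0) == 0.0
        assert born_electronic_term(BornModelParams(z=0, r0=0.2), 0.5) == 0.0

    def test_electronic_term_against_scipy_constants(self):
        """Full-screening value for z=1, r0=0.2 nm computed independently."""
        from scipy import constants

        expected = -(
            constants.N_A * constants.e**2
            / (8 * math.pi * constants.epsilon_0 * 0.2e-9)
        ) / (constants.calorie * 1000)
        got = born_electronic_term(BornModelParams(z=1, r0=0.2), 0.0)
        assert got == pytest.approx(expected, rel=1e-9)

    def test_bad_radius_rejected(self):
        with pytest.raises(ValueError):
            BornModelParams(z=1, r0=-0.1)


class TestEyring:
    @pytest.mark.parametrize(
        "ratio,temp,expected",
        [(10.0, 310.0, 1.4), (2.5, 310.0, 0.6), (1.0, 310.0, 0.0)],
    )
    def test_printed_values(self, ratio, temp, expected):
        assert round(eyring_barrier_difference(ratio, temp), 1) == expected

    @given(r1=st.floats(0.1, 50), r2=st.floats(0.1, 50))
    @settings(deadline=None, max_examples=50)
    def test_log_additivity(self, r1, r2):
        T = 310.0
        assert eyring_barrier_difference(r1 * r2, T) == pytest.approx(
            eyring_barrier_difference(r1, T) + eyring_barrier_difference(r2, T),
            abs=1e-9,
        )

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            eyring_barrier_difference(0.0, 310.0)


class TestScalingFactor:
    def test_values(self):
        assert round(scaling_factor_from_dielectric(2.0), 1) == 0.7
        assert scaling_factor_from_dielectric(1.0) == 1.0
        assert scaling_factor_from_dielectric(4.0) == 0.5

    def test_below_one_rejected(self):
        with pytest.raises(ValueError):
            scaling_factor_from_dielectric(0.5)


def test_scaling_scheme_validation():
    with pytest.raises(ValueError):
        ScalingScheme(mode="group", q=0.0)
    with pytest.raises(ValueError):
        ScalingScheme(mode="magic", q=0.8)
    assert ScalingScheme(mode="weighted", q=0.78).q == 0.78
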