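"""Binding assembly arithmetic: restraint correction, pose combination,
averaging, consensus, relative free energies and accuracy metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neqbind.binding import (
    BindingRecord,
    PoseEstimate,
    RestraintDefinition,
    assemble_binding,
    average_repeats,
    combine_poses,
    consensus,
    ddg_matrix,
    kcal_to_kj,
    kj_to_kcal,
    metrics,
    restraint_correction,
)
from neqbind.constants import kt_kj

from oracles import boresch_numeric

PAPER_RESTRAINT = dict(
    r0=0.5,
    theta_a0=math.pi / 2,
    theta_b0=math.pi / 2,
    k_r=4184.0,
    k_theta_a=41.84,
    k_theta_b=41.84,
    k_phi_a=41.84,
    k_phi_b=41.84,
    k_phi_c=41.84,
)


class TestRestraintCorrection:
    def test_force_constant_scaling_law(self):
        """Multiplying all six force constants by 4 adds -kT ln 64
        (sqrt of 4^6) to the correction."""
        t = 300.15
        base = RestraintDefinition(**PAPER_RESTRAINT)
        scaled = RestraintDefinition(
            **{
                k: (v * 4 if k.startswith("k_") else v)
                for k, v in PAPER_RESTRAINT.items()
            }
        )
        diff = restraint_correction(scaled, t) - restraint_correction(base, t)
        assert diff == pytest.approx(-kt_kj(t) * math.log(64.0), rel=1e-12)

    def test_standard_volume_scaling_law(self):
        t = 298.0
        base = RestraintDefinition(**PAPER_RESTRAINT)
        doubled = RestraintDefinition(**PAPER_RESTRAINT, standard_volume=2 * 1.6605)
        diff = restraint_correction(doubled, t) - restraint_correction(base, t)
        assert diff == pytest.approx(-kt_kj(t) * math.log(2.0), rel=1e-12)

    def test_exact_jacobian_matches_6d_integral_at_soft_angles(self):
        """With the soft angular springs (41.84 kJ/mol/rad^2) the exact
        Gaussian-moment evaluation reproduces the full 6-D restrained
        configurational integral; the reference-Jacobian form sits
        ~0.14 kJ/mol away (the sin(theta) width effect)."""
        t = 300.15
        restr = RestraintDefinition(**PAPER_RESTRAINT)
        oracle = boresch_numeric(restr, t)
        exact = restraint_correction(restr, t, jacobian="exact")
        ref = restraint_correction(restr, t, jacobian="reference")
        assert exact == pytest.approx(oracle, abs=0.02)
        assert 0.05 < abs(ref - oracle) < 0.3

    def test_reference_jacobian_valid_in_stiff_regime(self):
        """Randomized sweep with stiffness ratios k*scale^2/kT >= 200:
        the standard formula matches quadrature within 0.05 kJ/mol."""
        rng = np.random.default_rng(5)
        t = 300.15
        kt = kt_kj(t)
        for _ in range(10):
            r0 = rng.uniform(0.3, 0.8)
            th_a, th_b = rng.uniform(0.6, math.pi - 0.6, 2)
            restr = RestraintDefinition(
                r0=r0,
                theta_a0=th_a,
                theta_b0=th_b,
                k_r=rng.uniform(200, 400) * kt / r0**2,
                k_theta_a=rng.uniform(200, 400) * kt,
                k_theta_b=rng.uniform(200, 400) * kt,
                k_phi_a=rng.uniform(200, 400) * kt,
                k_phi_b=rng.uniform(200, 400) * kt,
                k_phi_c=rng.uniform(200, 400) * kt,
            )
            assert restraint_correction(restr, t) == pytest.approx(
                boresch_numeric(restr, t), abs=0.05
            )

    def test_collinear_reference_geometry_rejected(self):
        bad = dict(PAPER_RESTRAINT, theta_a0=1e-12)
        with pytest.raises(ValueError):
            restraint_correction(RestraintDefinition(**bad), 300.0)


class TestCombinePoses:
    def test_single_pose_identity(self):
        est = combine_poses([PoseEstimate(pose="primary", dg=-20.0)], 300.15)
        assert est.dg == pytest.approx(-20.0)

    def test_two_equal_poses_gain_kt_ln2(self):
        t = 300.15
        poses = [
            PoseEstimate(pose="primary", dg=-20.0),
            PoseEstimate(pose="secondary", dg=-20.0),
        ]
        assert combine_poses(poses, t).dg == pytest.approx(
            -20.0 - kt_kj(t) * math.log(2.0)
        )

    def test_unequal_poses_closed_form(self):
        """-5 and -3 kcal/mol at 300.15 K: dominated by the stronger
        pose, within kT ln 2 of it (closed form evaluated directly)."""
        t = 300.15
        kt = kt_kj(t)
        dgs_kj = [kcal_to_kj(-5.0), kcal_to_kj(-3.0)]
        expected = -kt * np.logaddexp(-dgs_kj[0] / kt, -dgs_kj[1] / kt)
        poses = [
            PoseEstimate(pose="primary", dg=dgs_kj[0]),
            PoseEstimate(pose="secondary", dg=dgs_kj[1]),
        ]
        got = combine_poses(poses, t).dg
        assert got == pytest.approx(expected, rel=1e-12)
        assert dgs_kj[0] - kt * math.log(2) <= got <= dgs_kj[0]

    @given(
        dgs=st.lists(st.floats(-80, 20), min_size=1, max_size=4),
    )
    @settings(max_examples=50, deadline=None)
    def test_bounds_property(self, dgs):
        """Combined dG lies in [min - kT ln n, min]."""
        t = 300.15
        poses = [PoseEstimate(pose=f"p{i}", dg=g) for i, g in enumerate(dgs)]
        out = combine_poses(poses, t).dg
        lo = min(dgs) - kt_kj(t) * math.log(len(dgs))
        assert lo - 1e-9 <= out <= min(dgs) + 1e-9

    def test_discarded_poses_excluded_and_all_discarded_raises(self):
        poses = [
            PoseEstimate(pose="primary", dg=None, discarded=True, discard_reason="flip"),
            PoseEstimate(pose="secondary", dg=-10.0),
        ]
        assert combine_poses(poses, 300.15).dg == pytest.approx(-10.0)
        with pytest.raises(ValueError, match="discarded"):
            combine_poses([poses[0]], 300.15)

    def test_weighted_mean_variant(self):
        t = 300.15
        poses = [
            PoseEstimate(pose="primary", dg=-20.0),
            PoseEstimate(pose="secondary", dg=-20.0),
        ]
        assert combine_poses(poses, t, method="weighted-mean").dg == pytest.approx(-20.0)


class TestAverageRepeats:
    def test_identical_repeats(self):
        mean, sem, ok = average_repeats([3.0, 3.0, 3.0])
        assert (mean, sem, ok) == (3.0, 0.0, True)

    def test_hand_arithmetic(self):
        mean, sem, ok = average_repeats([1.0, 2.0, 3.0])
        assert mean == pytest.approx(2.0)
        assert sem == pytest.approx(1.0 / math.sqrt(3.0))
        assert ok

    def test_single_value_flags_undefined_sem(self):
        mean, sem, ok = average_repeats([4.2])
        assert mean == 4.2 and math.isnan(sem) and not ok

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_repeats([])


class TestConsensus:
    def test_two_force_field_average_and_error(self):
        """Consensus of -6.76 +- 0.38 and -5.25 +- 0.11 kcal/mol."""
        records = [
            BindingRecord("MGLab 24", "g2", "GAFF 1.81", -6.76, 0.38),
            BindingRecord("MGLab 24", "g2", "CGenFF 4.1", -5.25, 0.11),
        ]
        c = consensus(records)
        assert c.dg_bind == pytest.approx(-6.005)
        assert c.stderr == pytest.approx(0.5 * math.hypot(0.38, 0.11), rel=1e-12)
        assert c.stderr == pytest.approx(0.198, abs=5e-4)

    def test_identical_records_shrink_error_by_sqrt2(self):
        records = [
            BindingRecord("h", "g1", "ff1", -5.0, 0.2),
            BindingRecord("h", "g1", "ff2", -5.0, 0.2),
        ]
        c = consensus(records)
        assert c.dg_bind == -5.0
        assert c.stderr == pytest.approx(0.2 / math.sqrt(2.0))

    def test_single_record_identity_with_label(self):
        c = consensus([BindingRecord("h", "g1", "ff1", -5.0, 0.2)])
        assert c.dg_bind == -5.0 and c.forcefield.startswith("single:")

    def test_mixed_systems_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            consensus(
                [
                    BindingRecord("h1", "g1", "ff1", -5.0, 0.1),
                    BindingRecord("h2", "g1", "ff2", -4.0, 0.1),
                ]
            )


class TestAssembleBinding:
    def test_zero_inputs(self):
        assert assemble_binding(0.0, 0.0) == 0.0

    def test_unbinding_convention_sign(self):
        assert assemble_binding(20.0, -4.0, convention="dssb-unbinding") == -24.0

    def test_opposite_convention_negates_transition_term_only(self):
        a = assemble_binding(20.0, -4.0, convention="dssb-unbinding")
        b = assemble_binding(20.0, -4.0, convention="dssb-binding")
        assert b - a == pytest.approx(2 * 20.0)

    def test_unknown_convention_rejected(self):
        with pytest.raises(ValueError, match="convention"):
            assemble_binding(1.0, 0.0, convention="mystery")


class TestDdgMatrix:
    def _records(self, n, guest="g1"):
        return [
            BindingRecord(f"host{i:02d}", guest, "ff", -float(i), 0.1 * i)
            for i in range(1, n + 1)
        ]

    def test_nine_hosts_give_36_pairs(self):
        assert len(ddg_matrix(self._records(9))) == 36

    def test_equal_dg_zero_ddg(self):
        recs = [
            BindingRecord("a", "g1", "ff", -5.0, 0.1),
            BindingRecord("b", "g1", "ff", -5.0, 0.2),
        ]
        assert ddg_matrix(recs)[0][2] == 0.0

    def test_cycle_consistency(self):
        pairs = {(i, j): d for i, j, d, _ in ddg_matrix(self._records(5))}
        hosts = sorted({h for pair in pairs for h in pair})
        for a, b, c in [(0, 1, 2), (0, 2, 4), (1, 3, 4)]:
            hi, hj, hk = hosts[a], hosts[b], hosts[c]
            assert pairs[(hi, hj)] + pairs[(hj, hk)] == pytest.approx(pairs[(hi, hk)])

    def test_duplicate_hosts_rejected(self):
        recs = self._records(3) + [BindingRecord("host01", "g1", "ff", 0.0, 0.0)]
        with pytest.raises(ValueError, match="duplicate"):
            ddg_matrix(recs)


class TestMetrics:
    def test_perfect_agreement(self):
        rep = metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], n_boot=10, seed=0)
        assert rep.aue == 0.0 and rep.pearson == pytest.approx(1.0)

    def test_uniform_offset_insensitivity_of_pearson(self):
        exp = [-3.0, -4.0, -5.0, -6.0]
        calc = [e + 1.0 for e in exp]
        rep = metrics(calc, exp, n_boot=10, seed=0)
        assert rep.aue == pytest.approx(1.0)
        assert rep.pearson == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        calc, exp = [-1.0, -2.0, -3.0], [-1.5, -2.0, -2.5]
        rep = metrics(calc, exp, n_boot=10, seed=0)
        assert rep.aue == pytest.approx(1.0 / 3.0)
        # hand Pearson: both vectors linear in index -> r = -(-1) ... = 1 magnitude
        r_hand = np.corrcoef(calc, exp)[0, 1]
        assert rep.pearson == pytest.approx(r_hand)

    def test_bootstrap_determinism_and_shrinkage(self):
        rng = np.random.default_rng(3)
        exp = rng.normal(-5, 1.5, 40)
        calc = exp + rng.normal(0, 0.8, 40)
        a = metrics(calc, exp, n_boot=200, seed=9)
        b = metrics(calc, exp, n_boot=200, seed=9)
        assert (a.aue_err, a.pearson_err) == (b.aue_err, b.pearson_err)
        small = metrics(calc[:10], exp[:10], n_boot=200, seed=9)
        assert a.aue_err < small.aue_err

    def test_zero_variance_flags_pearson(self):
        rep = metrics([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], n_boot=10, seed=0)
        assert not rep.pearson_defined and math.isnan(rep.pearson)

    def test_unit_round_trip(self):
        assert kj_to_kcal(kcal_to_kj(-6.005)) == pytest.approx(-6.005, rel=1e-15)
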