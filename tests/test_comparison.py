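"""Clothing-vs-body agreement statistics."""

import numpy as np
import pytest

from clothgait.comparison import (
    angle_difference_at,
    assemble_phase_portrait,
    find_shank_vertical,
    per_cycle_correlation,
)
from clothgait.errors import EmptyResultError, InvalidParameterError
from clothgait.orientation import SvaSeries
from clothgait.segmentation import Cycle, GaitCycleSet
from clothgait.simulate import FabricCoupling, GaitParams, clothing_transform, generate_kinematics


def _sva(theta, omega=None, placement="lower_shank", attachment="body"):
    theta = np.asarray(theta, dtype=float)
    n = len(theta)
    return SvaSeries(
        time=np.arange(n) / 50.0,
        theta=theta,
        theta_z=np.abs(theta),
        omega=np.zeros(n) if omega is None else np.asarray(omega, dtype=float),
        placement=placement,
        attachment=attachment,
    )


class TestPerCycleCorrelation:
    def test_identical_matrices_give_unit_correlation(self, rng):
        m = rng.standard_normal((8, 40))
        r, r_mean, _, nexc = per_cycle_correlation(m, m)
        assert np.allclose(r, 1.0)
        assert nexc == 0

    @pytest.mark.parametrize("a, expected", [(2.5, 1.0), (-0.7, -1.0)])
    def test_affine_relation_gives_signed_unity(self, rng, a, expected):
        m = rng.standard_normal((6, 30))
        r, _, _, _ = per_cycle_correlation(m, a * m + 3.0)
        assert np.allclose(r, expected)

    def test_matches_numpy_corrcoef_oracle(self, rng):
        b = rng.standard_normal((10, 50))
        c = 0.8 * b + 0.6 * rng.standard_normal((10, 50))
        r, r_mean, _, _ = per_cycle_correlation(b, c)
        oracle = np.array([np.corrcoef(b[i], c[i])[0, 1] for i in range(10)])
        assert np.allclose(r, oracle, atol=1e-12)
        assert r_mean == pytest.approx(oracle.mean(), abs=1e-12)

    def test_zero_variance_cycle_excluded_with_warning(self, rng):
        b = rng.standard_normal((4, 20))
        b[2] = 5.0  # flat cycle
        with pytest.warns(UserWarning):
            r, _, _, nexc = per_cycle_correlation(b, rng.standard_normal((4, 20)))
        assert nexc == 1 and len(r) == 3

    def test_mismatched_shapes_rejected(self, rng):
        with pytest.raises(InvalidParameterError):
            per_cycle_correlation(rng.standard_normal((3, 10)), rng.standard_normal((4, 10)))

    def test_common_affine_rescaling_leaves_r_mean_invariant(self, rng):
        b = rng.standard_normal((7, 25))
        c = b + 0.3 * rng.standard_normal((7, 25))
        _, r1, _, _ = per_cycle_correlation(b, c)
        _, r2, _, _ = per_cycle_correlation(4.0 * b - 2.0, 4.0 * c - 2.0)
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestAngleDifferences:
    def _cycles(self):
        return GaitCycleSet(
            ms_indices=np.array([0, 50, 100]),
            cycle_length=50,
            cycles=[
                Cycle(start=0, ic=12, to=40),
                Cycle(start=50, ic=62, to=90),
                Cycle(start=100, ic=112, to=140),
            ],
        )

    def test_identical_series_zero_difference(self, rng):
        theta = rng.standard_normal(200)
        d = angle_difference_at(_sva(theta), _sva(theta), "ic", cycles=self._cycles())
        assert d == (0.0, 0.0)

    def test_constant_offset_recovered(self, rng):
        theta = rng.standard_normal(200)
        d = angle_difference_at(
            _sva(theta), _sva(theta + 5.0), "standing", standing_range=(20, 120)
        )
        assert d[0] == pytest.approx(5.0, abs=1e-12)
        assert d[1] == pytest.approx(0.0, abs=1e-12)

    def test_ic_difference_matches_manual_indexing(self, rng):
        tb, tc = rng.standard_normal(200), rng.standard_normal(200)
        cycles = self._cycles()
        mean, sd = angle_difference_at(_sva(tb), _sva(tc), "ic", cycles=cycles)
        manual = np.array([tc[i] - tb[i] for i in (12, 62, 112)])
        assert mean == pytest.approx(manual.mean(), abs=1e-12)
        assert sd == pytest.approx(manual.std(), abs=1e-12)

    def test_empty_event_set_raises(self, rng):
        empty = GaitCycleSet(
            ms_indices=np.array([0, 50]), cycle_length=50, cycles=[Cycle(start=0, flagged=True)]
        )
        with pytest.raises(EmptyResultError):
            angle_difference_at(
                _sva(rng.standard_normal(100)),
                _sva(rng.standard_normal(100)),
                "ic",
                cycles=empty,
            )


class TestShankVertical:
    def test_linear_crossing_found_at_midpoint(self):
        theta = np.zeros(50)
        theta[12:41] = np.linspace(-10.0, 10.0, 29)  # crosses zero at index 26
        cycles = GaitCycleSet(
            ms_indices=np.array([0, 50]),
            cycle_length=50,
            cycles=[Cycle(start=0, ic=12, to=40)],
        )
        idx = find_shank_vertical(theta, cycles)
        assert idx == [26]

    def test_all_positive_stance_yields_none(self):
        theta = np.ones(50) * 5.0
        cycles = GaitCycleSet(
            ms_indices=np.array([0, 50]),
            cycle_length=50,
            cycles=[Cycle(start=0, ic=10, to=40)],
        )
        assert find_shank_vertical(theta, cycles) == [None]

    def test_noise_free_crossing_matches_generator_truth(self):
        """The detected vertical instant sits within one sample of the true
        zero crossing of the generated shank angle."""
        kin = generate_kinematics(GaitParams(n_cycles=6, variability=0.0), seed=0)
        dt = kin.time[1] - kin.time[0]
        cycles = []
        for k, ms, ic, to in kin.event_times:
            cycles.append(
                Cycle(start=int(round(ms / dt)), ic=int(round(ic / dt)), to=int(round(to / dt)))
            )
        cs = GaitCycleSet(
            ms_indices=np.array([c.start for c in cycles]),
            cycle_length=60,
            cycles=cycles,
        )
        found = find_shank_vertical(kin.angle_shank, cs)
        for c, idx in zip(cycles, found):
            assert idx is not None
            # true crossing: first sign change of the continuous angle in stance
            seg = kin.angle_shank[c.ic : c.to + 1]
            true_rel = np.nonzero(np.diff(np.signbit(seg)))[0][0]
            assert abs((idx - c.ic) - true_rel) <= 1


class TestPhasePortrait:
    def test_constant_angle_degenerate_portrait(self):
        sva = _sva(np.full(50, 3.0))
        pp = assemble_phase_portrait(sva, Cycle(start=0, ic=10, to=40), 50)
        assert pp.theta_range == 0.0 and pp.omega_range == 0.0
        assert pp.markers == {"ms": 0, "ic": 10, "to": 40}

    def test_rigid_coupling_preserves_theta_range(self):
        kin = generate_kinematics(GaitParams(n_cycles=6), seed=1)
        rigid = clothing_transform(
            kin, FabricCoupling(stiffness=4e6, damping=2800.0, gain=1.0), seed=0
        )
        assert np.ptp(rigid.angle_shank) == pytest.approx(
            np.ptp(kin.angle_shank), rel=0.02
        )

    def test_fabric_gain_widens_clothing_range(self):
        kin = generate_kinematics(GaitParams(n_cycles=6), seed=1)
        wide = clothing_transform(
            kin, FabricCoupling(stiffness=2500.0, damping=45.0, gain=1.2), seed=0
        )
        assert np.ptp(wide.angle_shank) > np.ptp(kin.angle_shank)


class TestMonotoneDegradation:
    def test_increasing_fabric_noise_decreases_mean_r(self):
        """Mean per-cycle r falls strictly as fabric angle noise grows."""
        kin = generate_kinematics(GaitParams(n_cycles=30), seed=4)
        dt = kin.time[1] - kin.time[0]
        starts = [int(round(ms / dt)) for _, ms, _, _ in kin.event_times]
        L = 60
        body = np.vstack([kin.angle_shank[s : s + L] for s in starts[:-1]])
        means = []
        for noise in (0.0, 1.0, 3.0, 8.0):
            c = FabricCoupling(stiffness=2500.0, damping=45.0, gain=1.05, noise_sd=noise)
            cloth = clothing_transform(kin, c, seed=9)
            mat = np.vstack([cloth.angle_shank[s : s + L] for s in starts[:-1]])
            _, r_mean, _, _ = per_cycle_correlation(body, mat)
            means.append(r_mean)
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_increasing_stiffness_increases_mean_r(self):
        """Rigid-limit approach is monotone over a stiffness grid."""
        kin = generate_kinematics(GaitParams(n_cycles=20), seed=5)
        dt = kin.time[1] - kin.time[0]
        starts = [int(round(ms / dt)) for _, ms, _, _ in kin.event_times]
        L = 60
        body = np.vstack([kin.angle_shank[s : s + L] for s in starts[:-1]])
        means = []
        for k in (100.0, 1e3, 1e4, 1e5):
            c = FabricCoupling(stiffness=k, damping=2 * 0.7 * np.sqrt(k), gain=1.0)
            cloth = clothing_transform(kin, c, seed=0)
            mat = np.vstack([cloth.angle_shank[s : s + L] for s in starts[:-1]])
            _, r_mean, _, _ = per_cycle_correlation(body, mat)
            means.append(r_mean)
        assert all(a < b for a, b in zip(means, means[1:]))
        assert means[-1] > 0.999
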