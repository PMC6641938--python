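"""Tests for generator assembly, event execution, and acquisition."""

import math

import numpy as np
import pytest
import scipy.linalg as sla

from spindrift.kinetics import ReactionNetwork
from spindrift.liouville import SpinSystem, hamiltonian_isotropic
from spindrift.presets import gaussian_envelope, two_spin_systems_abc
from spindrift.sequence import (Acquire, Delay, GradientPulse, HardPulse,
                                Problem, Simulation, SoftPulse,
                                assemble_generator, run_events, spectrum)
from spindrift.spatial import Grid, TransportSpec


def single_species_problem(shift=1.0, grid=None, **kw):
    s = SpinSystem(["1H"], [shift])
    return Problem(network=ReactionNetwork(["a"], [s]), grid=grid, **kw)


class TestDimensionBookkeeping:
    def test_two_spin_on_500_point_grid(self):
        s = SpinSystem(["1H", "1H"], [1.0, -1.0])
        p = Problem(network=ReactionNetwork(["a"], [s]),
                    grid=Grid((500,), (0.015,)))
        assert p.total_dim == 500 * 16 == 8000
        gen = assemble_generator(p, gradients=(0.1,))
        assert gen.shape == (8000, 8000)
        assert gen.max_factor_dimension() <= 500

    def test_gaba_water_concatenated_dimension(self):
        # six-spin + two-spin pair: 4^6 + 4^2 = 4112; x 500 voxels = 2,056,000
        gaba = SpinSystem(["1H"] * 6, [1.9, 1.9, 2.3, 2.3, 3.0, 3.0])
        water = SpinSystem(["1H", "1H"], [4.7, 4.7])
        net = ReactionNetwork(["gaba", "water"], [gaba, water])
        assert net.total_dim == 4096 + 16 == 4112
        p = Problem(network=net, grid=Grid((500,), (0.015,)))
        assert p.total_dim == 2_056_000

    def test_three_two_spin_systems_block_dimension(self):
        net = ReactionNetwork(["A", "B", "C"], two_spin_systems_abc())
        assert net.total_dim == 3 * 16 == 48

    def test_empty_physics_zero_generator(self):
        p = single_species_problem(shift=0.0)
        gen = assemble_generator(p)
        v = np.random.default_rng(0).random(4)
        assert np.max(np.abs(gen.apply(v))) == 0.0
        assert gen.shape == (4, 4)

    def test_generator_never_opens_space_spin_product(self):
        p = single_species_problem(grid=Grid((64,), (0.01,)),
                                   transport=TransportSpec(d=1e-9))
        gen = assemble_generator(p, gradients=(0.1,))
        assert gen.max_factor_dimension() <= max(64, p.sdim)


class TestEvolve:
    def test_zero_delay_is_identity(self):
        sim = Simulation(single_species_problem())
        before = sim.state.copy()
        sim.delay(0.0)
        assert np.array_equal(sim.state, before)

    def test_fid_phase_of_offset_spin(self):
        p = single_species_problem(shift=1.0)
        om = p.network.systems[0].offset_rad(0)
        sim = Simulation(p)
        sim.hard_pulse("x", math.pi / 2)
        sigma = p.detection_state()
        a0 = sim.expectation(sigma)
        t = 3.3e-4
        sim.delay(t)
        a1 = sim.expectation(sigma)
        assert a1 / a0 == pytest.approx(np.exp(-1j * om * t), rel=1e-9)

    def test_unitary_norm_conservation_along_events(self):
        s = SpinSystem(["1H", "1H"], [1.0, -0.6],
                       j_hz=np.array([[0.0, 8.0], [8.0, 0.0]]))
        p = Problem(network=ReactionNetwork(["a"], [s]),
                    grid=Grid((20,), (0.01,)))
        sim = Simulation(p, initial="Sz")
        n0 = np.linalg.norm(sim.state)
        sim.hard_pulse("y", math.pi / 2)
        sim.gradient_pulse((0.05,), 5e-4)
        sim.delay(1e-3)
        sim.hard_pulse("x", math.pi)
        sim.gradient_pulse((0.05,), 5e-4)
        assert np.linalg.norm(sim.state) == pytest.approx(n0, rel=1e-8)

    def test_gradient_echo_identity(self):
        """A zero-integral gradient waveform refocuses a diffusion-free sample."""
        p = single_species_problem(shift=0.0, grid=Grid((32,), (0.01,)))
        sim = Simulation(p)
        sim.hard_pulse("x", math.pi / 2)
        before = sim.state.copy()
        sim.gradient_pulse((0.2,), 1e-3)
        sim.gradient_pulse((-0.1,), 2e-3)
        assert np.max(np.abs(sim.state - before)) < 1e-8


class TestHardPulse:
    def test_zero_flip_identity(self):
        sim = Simulation(single_species_problem())
        before = sim.state.copy()
        sim.hard_pulse("x", 0.0)
        assert np.array_equal(sim.state, before)

    def test_90y_creates_pure_sx(self):
        from spindrift.liouville import state as spin_state
        p = single_species_problem(shift=0.0)
        sim = Simulation(p)
        sim.hard_pulse("y", math.pi / 2)
        sx = spin_state(p.network.systems[0], "Sx")
        overlap = np.vdot(sx, sim.state) / np.vdot(sx, sx)
        assert overlap.real == pytest.approx(1.0, rel=1e-9)

    def test_four_90x_pulses_are_identity(self):
        sim = Simulation(single_species_problem(shift=0.3))
        before = sim.state.copy()
        for _ in range(4):
            sim.hard_pulse("x", math.pi / 2)
        assert np.max(np.abs(sim.state - before)) < 1e-10


class TestSoftPulse:
    def test_zero_amplitude_envelope_is_identity(self):
        sim = Simulation(single_species_problem(shift=0.0))
        before = sim.state.copy()
        sim.soft_pulse(np.zeros(4), 0.0, 1e-3)
        assert np.max(np.abs(sim.state - before)) < 1e-12

    def test_calibrated_gaussian_inverts_on_resonance(self):
        from spindrift.liouville import state as spin_state
        p = single_species_problem(shift=0.0)
        env = gaussian_envelope(10)
        dur = 10e-3
        env = env * (math.pi / (env.sum() * dur / 10))
        sim = Simulation(p)
        sim.soft_pulse(env, 0.0, dur)
        sz = spin_state(p.network.systems[0], "Sz")
        mz = np.vdot(sz, sim.state).real / 0.5
        assert mz <= -0.99

    def test_methods_agree_on_coupled_system(self):
        s = SpinSystem(["1H", "1H"], [1.0, -0.5],
                       j_hz=np.array([[0.0, 7.0], [7.0, 0.0]]))
        p = Problem(network=ReactionNetwork(["a"], [s]))
        env = gaussian_envelope(10)
        dur = 10e-3
        env = env * (math.pi / (env.sum() * dur / 10))
        states = {}
        for method in ("timeslice", "phase-coordinate"):
            sim = Simulation(p)
            sim.hard_pulse("x", math.pi / 2)
            sim.soft_pulse(env, 300.0, dur, method=method)
            states[method] = sim.state
        diff = np.linalg.norm(states["timeslice"] - states["phase-coordinate"])
        assert diff / np.linalg.norm(states["timeslice"]) < 0.01

    def test_zero_duration_rejected(self):
        sim = Simulation(single_species_problem())
        with pytest.raises(ValueError):
            sim.soft_pulse(np.ones(4), 0.0, 0.0)


class TestAcquire:
    def test_zero_state_zero_fid(self):
        p = single_species_problem()
        sim = Simulation(p, initial=np.zeros(4, dtype=complex))
        fid = sim.acquire(16, 1e-4)
        assert np.max(np.abs(fid)) == 0.0

    def test_spectrum_peak_at_offset(self):
        p = single_species_problem(shift=1.0)
        om_hz = p.network.systems[0].offset_rad(0) / (2 * math.pi)
        sim = Simulation(p)
        sim.hard_pulse("x", math.pi / 2)
        fid = sim.acquire(512, 2e-4)
        f, s = spectrum(fid, 2e-4, magnitude=True)
        assert f[np.argmax(s)] == pytest.approx(om_hz, abs=f[1] - f[0])

    def test_two_spin_doublet_splitting(self):
        """System A shows doublets split by J = 30 Hz at +-1 ppm."""
        sysA = two_spin_systems_abc()[0]
        p = Problem(network=ReactionNetwork(["A"], [sysA]))
        sim = Simulation(p)
        sim.hard_pulse("x", math.pi / 2)
        npts, dwell = 4096, 2e-4
        fid = sim.acquire(npts, dwell)
        f, s = spectrum(fid, dwell, magnitude=True)
        s = s / s.max()
        # four resolved lines: two doublets centred at +-499.9 Hz, 30 Hz apart
        peaks = [f[i] for i in range(1, npts - 1)
                 if s[i] > 0.3 and s[i] >= s[i - 1] and s[i] >= s[i + 1]]
        assert len(peaks) == 4
        nu0 = sysA.offset_rad(0) / (2 * math.pi)
        expected = sorted([-nu0 - 15, -nu0 + 15, nu0 - 15, nu0 + 15])
        assert np.allclose(sorted(peaks), expected, atol=2 * (f[1] - f[0]))

    def test_nonpositive_dwell_rejected(self):
        sim = Simulation(single_species_problem())
        with pytest.raises(ValueError):
            sim.acquire(8, 0.0)


class TestPixelwiseEquivalence:
    def test_distributed_equals_per_voxel_without_transport(self):
        """With transport off, each voxel evolves independently: the composite
        simulation must agree with a voxel-by-voxel dense oracle."""
        s = SpinSystem(["1H", "1H"], [1.0, -1.0],
                       j_hz=np.array([[0.0, 30.0], [30.0, 0.0]]))
        net = ReactionNetwork(["a"], [s])
        grid = Grid((6,), (0.01,))
        p = Problem(network=net, grid=grid)
        g_amp, t = 0.02, 5e-4

        sim = Simulation(p)
        sim.hard_pulse("x", math.pi / 2)
        sim.gradient_pulse((g_amp,), t)
        composite = sim.state.reshape(6, 16)

        # dense per-voxel oracle
        from spindrift.liouville import state as spin_state
        from spindrift.liouville import commutation_superoperator, \
            single_spin_operator
        H0 = hamiltonian_isotropic(s).toarray()
        hz = sum((1 + s.shifts_ppm[n] * 1e-6) * s.gamma(n)
                 * single_spin_operator(s, n, "z").toarray() for n in range(2))
        Cz = commutation_superoperator(hz).toarray()
        rho0 = spin_state(s, "equilibrium")
        cx, cy = p.rf_blocks()
        u90 = sla.expm(-1j * (math.pi / 2) * cx.toarray())
        for i, x in enumerate(grid.coords(0)):
            rho = u90 @ rho0
            G = -1j * (H0 + g_amp * x * Cz)
            rho = sla.expm(G * t) @ rho
            assert np.max(np.abs(composite[i] - rho)) < 1e-10

    def test_no_exchange_two_species_equals_independent(self):
        sa = SpinSystem(["1H"], [1.0])
        sb = SpinSystem(["1H"], [-2.0])
        joint = Problem(network=ReactionNetwork(["A", "B"], [sa, sb]))
        sim = Simulation(joint)
        sim.hard_pulse("x", math.pi / 2)
        fid_joint = sim.acquire(64, 1e-4)
        fids = []
        for s in (sa, sb):
            solo = Simulation(Problem(network=ReactionNetwork(["x"], [s])))
            solo.hard_pulse("x", math.pi / 2)
            fids.append(solo.acquire(64, 1e-4))
        assert np.allclose(fid_joint, fids[0] + fids[1], atol=1e-10)


class TestEventList:
    def test_declarative_run_matches_imperative(self):
        p = single_species_problem(shift=0.5, grid=Grid((12,), (0.01,)))
        events = [HardPulse("x", math.pi / 2), GradientPulse((0.03,), 4e-4),
                  Delay(1e-3), HardPulse("x", math.pi),
                  GradientPulse((0.03,), 4e-4), Acquire(8, 1e-4)]
        sim, fids = run_events(p, events)
        assert len(fids) == 1 and fids[0].shape == (8,)

        sim2 = Simulation(p)
        sim2.hard_pulse("x", math.pi / 2)
        sim2.gradient_pulse((0.03,), 4e-4)
        sim2.delay(1e-3)
        sim2.hard_pulse("x", math.pi)
        sim2.gradient_pulse((0.03,), 4e-4)
        fid2 = sim2.acquire(8, 1e-4)
        assert np.allclose(fids[0], fid2)

    def test_unknown_event_rejected(self):
        with pytest.raises(TypeError):
            run_events(single_species_problem(), [object()])
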