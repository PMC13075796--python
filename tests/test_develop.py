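"""Development engine: Hill responses, dimer equilibrium, integration."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import samdrift as sd
from samdrift.config import DevConfig
from samdrift.develop import (DevState, develop, dimer_partition,
                              initial_state, neighbour_weighted_concentration,
                              step, tfbs_contribution, transcription_rate)
from samdrift.genome import Gene, Genome, Tfbs
from samdrift.tissue import Cell, Tissue


def _toy_tissue(n=1, edges=(), areas=None, l1=()):
    """Hand-built tissue: unit squares, explicit adjacency."""
    cells = []
    for i in range(n):
        poly = np.array([[i, 0], [i + 1, 0], [i + 1, 1], [i, 1]], float)
        c = Cell(centroid=(i + 0.5, 0.5), polygon=poly,
                 area=1.0 if areas is None else areas[i])
        c.is_l1 = i in l1
        cells.append(c)
    return Tissue(cells=cells, edges=list(edges))


class TestTfbsContribution:
    def test_half_saturation(self):
        assert tfbs_contribution(Tfbs(0, 1, 50.0), 50.0) == pytest.approx(0.5)

    def test_zero_input(self):
        assert tfbs_contribution(Tfbs(0, 1, 50.0), 0.0) == 0.0

    def test_inhibitor_at_twice_hill(self):
        assert tfbs_contribution(Tfbs(0, -1, 10.0), 20.0) == pytest.approx(-0.8)


class TestNeighbourWeighted:
    def test_single_neighbour_passthrough(self):
        t = _toy_tissue(2, edges=[(0, 1, 2.5)])
        p = np.array([0.0, 7.0])
        assert neighbour_weighted_concentration(t, 0, p) == pytest.approx(7.0)

    def test_equal_edges_average(self):
        t = _toy_tissue(3, edges=[(0, 1, 1.0), (0, 2, 1.0)])
        p = np.array([0.0, 2.0, 4.0])
        assert neighbour_weighted_concentration(t, 0, p) == pytest.approx(3.0)

    def test_isolated_cell_returns_zero(self):
        t = _toy_tissue(1)
        assert neighbour_weighted_concentration(t, 0, np.array([5.0])) == 0.0


class TestTranscriptionRate:
    def test_half_saturation_of_activity(self):
        g = Gene(12, 8.0, 0.1)
        assert transcription_rate(g, [1.0]) == pytest.approx(4.0)

    def test_net_inhibition_floors_to_zero(self):
        g = Gene(12, 8.0, 0.1)
        assert transcription_rate(g, [0.3, -0.9]) == 0.0

    def test_no_sites_no_transcription(self):
        assert transcription_rate(Gene(12, 8.0, 0.1), []) == 0.0


class TestDimerPartition:
    def test_no_partner_no_dimer(self):
        f8, f9, d = dimer_partition(0.0, 3.0, 1.0)
        assert d == 0.0 and f9 == 3.0

    def test_weak_binding_limit(self):
        _, _, d = dimer_partition(2.0, 2.0, 1e12)
        assert d == pytest.approx(0.0, abs=1e-9)

    def test_hand_solved_quadratic(self):
        # (2 - d)(2 - d) = 1 * d  =>  d = 1
        f8, f9, d = dimer_partition(2.0, 2.0, 1.0)
        assert d == pytest.approx(1.0, abs=1e-12)
        assert f8 == pytest.approx(1.0) and f9 == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_mass_balance(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.uniform(0, 500, 2)
        kd = rng.uniform(1e-3, 1e3)
        f8, f9, d = dimer_partition(a, b, kd)
        assert f8 + d == pytest.approx(a, abs=1e-9)
        assert f9 + d == pytest.approx(b, abs=1e-9)
        assert 0 <= d <= min(a, b)
        # equilibrium law
        assert f8 * f9 == pytest.approx(kd * d, rel=1e-6, abs=1e-6)


def _single_cell_cfg(**kw):
    base = dict(dt=0.01, t_end=50.0, noise=False, beta=0.1,
                init_tf_type=4, init_concentration=100.0,
                l1_tf_type=0, l1_production=0.0,
                fitness_windows=((41, 50),))
    base.update(kw)
    return DevConfig(**base)


class TestIntegration:
    def test_closed_form_relaxation(self):
        # constant activator (beta = 0 keeps it constant), one gene:
        # G(t) -> tau/alpha; the integrator and the closed form share the
        # same fixed point to high precision
        genome = Genome(elements=[Tfbs(4, 1, 100.0), Gene(12, 5.0, 0.1)])
        cfg = _single_cell_cfg(beta=0.0, t_end=400.0,
                               fitness_windows=((391, 400),))
        tissue = _toy_tissue(1)
        traj = develop(genome, tissue, cfg)
        theta = 0.5  # P = H = 100
        tau = 5.0 * theta**2 / (theta**2 + 1)
        assert traj.final.G[0, 0] == pytest.approx(tau / 0.1, abs=1e-6)

    def test_matches_independent_ode_oracle(self):
        # two-gene cascade in one cell, no noise: 4 -> 12 -> (via protein
        # 12) 13; independent RK45 integration of the same rate laws
        genome = Genome(elements=[
            Tfbs(4, 1, 100.0), Gene(12, 5.0, 0.1),
            Tfbs(12, 1, 50.0), Gene(13, 3.0, 0.2),
        ])
        cfg = _single_cell_cfg(dt=0.002, t_end=50.0, beta=0.02,
                               fitness_windows=((41, 50),))
        tissue = _toy_tissue(1)
        traj = develop(genome, tissue, cfg)

        beta = cfg.beta

        def rhs(t, y):
            g12, g13, p12, p13, p4 = y
            th = p4**2 / (p4**2 + 100.0**2)
            tau12 = 5.0 * th**2 / (th**2 + 1.0)
            th2 = p12**2 / (p12**2 + 50.0**2)
            tau13 = 3.0 * th2**2 / (th2**2 + 1.0)
            return [tau12 - 0.1 * g12, tau13 - 0.2 * g13,
                    g12 - beta * p12, g13 - beta * p13, -beta * p4]

        sol = solve_ivp(rhs, (0, 50.0), [0, 0, 0, 0, 100.0],
                        t_eval=traj.times, rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(traj.P[:, 12, 0], sol.y[2], rtol=1e-4)
        np.testing.assert_allclose(traj.P[:, 13, 0], sol.y[3], rtol=1e-4,
                                   atol=1e-8)
        np.testing.assert_allclose(traj.G[:, 0, 0], sol.y[0], rtol=1e-4)

    def test_step_size_robustness(self):
        genome = Genome(elements=[Tfbs(4, 1, 100.0), Gene(12, 5.0, 0.1)])
        tissue = _toy_tissue(1)
        a = develop(genome, tissue, _single_cell_cfg(dt=0.02))
        b = develop(genome, tissue, _single_cell_cfg(dt=0.01))
        ref = np.abs(b.P[:, 12, 0]).max()
        assert np.abs(a.P[:, 12, 0] - b.P[:, 12, 0]).max() < 1e-3 * ref

    def test_diffusion_conserves_mass(self):
        # a diffusing species with no production and no decay on a closed
        # three-cell chain: total amount (area-weighted) is invariant
        tissue = _toy_tissue(3, edges=[(0, 1, 1.0), (1, 2, 0.5)],
                             areas=[1.0, 2.0, 1.5])
        genome = Genome(elements=[], diffusion={0: 1.0, 1: 0.0})
        cfg = _single_cell_cfg(beta=0.0, init_tf_type=0,
                               init_concentration=10.0, t_end=20.0,
                               fitness_windows=((11, 20),))
        state = initial_state(genome, tissue, cfg)
        state.P[0, :] = [10.0, 0.0, 0.0]  # all mass in cell 0
        areas = tissue.areas
        total0 = (state.P[0] * areas).sum()
        for _ in range(200):
            state = step(state, genome, tissue, cfg)
        assert (state.P[0] * areas).sum() == pytest.approx(total0, rel=1e-9)
        # and it actually spread
        assert state.P[0, 2] > 0.1

    def test_cell_cell_signalling_acts_on_neighbours_only(self):
        # TF 2 produced only in cell 0 (via its L1-constitutive input);
        # target gene responds in the neighbour, not in cell 0 itself
        tissue = _toy_tissue(2, edges=[(0, 1, 1.0)], l1=(0,))
        genome = Genome(elements=[Tfbs(2, 1, 10.0), Gene(12, 5.0, 0.1)])
        cfg = _single_cell_cfg(l1_tf_type=2, l1_production=10.0,
                               init_concentration=0.0, t_end=50.0)
        traj = develop(genome, tissue, cfg)
        p2 = traj.final.P[2]
        g12 = traj.final.G[0]
        assert p2[0] > 1.0 and p2[1] == pytest.approx(0.0, abs=1e-9)
        assert g12[1] > 10 * max(g12[0], 1e-12)

    def test_noise_reproducible_and_nonnegative(self, small_tissue):
        rng = np.random.default_rng(0)
        genome = sd.init_genome(rng, sd.GenomeConfig())
        cfg = sd.desk_config(0).dev
        a = develop(genome, small_tissue, cfg, seed=123)
        b = develop(genome, small_tissue, cfg, seed=123)
        np.testing.assert_array_equal(a.P, b.P)
        assert (a.P >= 0).all() and (a.G >= 0).all()
        c = develop(genome, small_tissue, cfg, seed=124)
        assert np.abs(a.P - c.P).max() > 0

    def test_unresponsive_genome_keeps_fitness_proteins_silent(
            self, small_tissue):
        # no gene responds to the initial TFs: both fitness proteins stay 0
        genome = Genome(elements=[Tfbs(5, 1, 10.0), Gene(12, 5.0, 0.1)])
        cfg = sd.desk_config(0).dev
        traj = develop(genome, small_tissue, cfg, seed=5)
        assert np.abs(traj.P[:, 12, :]).max() == 0.0
        assert np.abs(traj.P[:, 13, :]).max() == 0.0

    def test_noise_off_noise_on_agree_at_sample_times(self, small_tissue):
        # the Langevin ensemble mean tracks the deterministic path for a
        # steadily driven target (L1-produced diffusing activator); the
        # residual offset is the Jensen bias of the Hill nonlinearity and
        # stays within the statistical tolerance
        genome = Genome(elements=[Tfbs(0, 1, 100.0), Gene(13, 5.0, 0.1)])
        cfg_det = sd.desk_config(0).dev
        cfg_det.noise = False
        det = develop(genome, small_tissue, cfg_det, seed=0)
        cfg_sto = sd.desk_config(0).dev
        reps = [develop(genome, small_tissue, cfg_sto, seed=i).P[:, 13, :]
                for i in range(30)]
        mean = np.mean(reps, axis=0)
        ref = det.P[:, 13, :]
        mask = ref > 10.0
        assert mask.sum() > 50
        rel = (mean[mask] - ref[mask]) / ref[mask]
        assert abs(rel.mean()) < 0.1
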