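import numpy as np
import pytest
from scipy import stats

from tmaze.errors import DomainError, StabilityError
from tmaze.geometry import Segment
from tmaze.heterogeneity import empirical_sorting_index, fit_sigma, log_slope
from tmaze.synthetic import (AgentPopulation, generate_mixed_population,
                             junction_decision_counts, phenotypes_to_agents,
                             render_observation, simulate_agents,
                             single_junction_control_geometry,
                             synthetic_sorting_indices)


@pytest.fixture(scope="module")
def free_box():
    # first segment seeds the agents; the large box keeps walls far away
    return [Segment("seed", 0, -100.0, -100.0, 100.0, 100.0),
            Segment("box", 0, -4000.0, -4000.0, 4000.0, 4000.0)]


@pytest.fixture(scope="module")
def mixed_run(geom, log_field, params):
    """Two-strain maze run shared by the sorting and dilution checks."""
    return generate_mixed_population(4000, 4000, geom, log_field, params,
                                     seed=101, t_end=6000.0, dt=0.5)


class TestAgentDynamics:
    def test_free_diffusion_msd(self, geom, free_box):
        pop = AgentPopulation.homogeneous(6000, D=330.0, vc=0.0)
        traj = simulate_agents(geom, None, pop, t_end=200.0, dt=0.5,
                               seed=4, record_interval=200.0,
                               segments=free_box)
        # displacement from the seeded region center, before wall contact
        disp = traj.positions[-1] - traj.positions[0]
        t = traj.times[-1] - traj.times[0]
        msd = np.mean(np.sum(disp ** 2, axis=1))
        assert msd == pytest.approx(4 * 330.0 * t, rel=0.05)
        assert np.abs(disp.mean(axis=0)).max() < 10.0

    def test_seed_reproducibility(self, geom, linear_field):
        pop = AgentPopulation.homogeneous(200, D=330.0, vc=0.9)
        a = simulate_agents(geom, linear_field, pop, t_end=300.0, dt=0.5,
                            seed=7)
        b = simulate_agents(geom, linear_field, pop, t_end=300.0, dt=0.5,
                            seed=7)
        assert np.array_equal(a.positions, b.positions)
        c = simulate_agents(geom, linear_field, pop, t_end=300.0, dt=0.5,
                            seed=8)
        assert not np.array_equal(a.positions, c.positions)

    def test_oversized_step_rejected(self, geom, linear_field):
        pop = AgentPopulation.homogeneous(10, D=50000.0, vc=0.0)
        with pytest.raises(StabilityError):
            simulate_agents(geom, linear_field, pop, t_end=10.0, dt=1.0)

    def test_ensemble_matches_transport_solution(self, geom, linear_field,
                                                 params):
        """Junction-1 stem occupancy of the agent ensemble agrees with the
        PDE profile (the two are independent implementations of the same
        drift-diffusion process)."""
        from tmaze.transport import (TransportSolver, extract_junction_profile,
                                     initial_state)

        pop = AgentPopulation.homogeneous(10000, D=330.0, vc=0.9)
        traj = simulate_agents(geom, linear_field, pop, t_end=2400.0, dt=0.5,
                               seed=21)
        solver = TransportSolver(geom, field=linear_field, params=params,
                                 dx=10.0, dt=1.0)
        st = solver.run(initial_state(geom, dx=10.0), t_end=2400.0)[-1]
        prof = extract_junction_profile(st, geom, 1)
        pos = traj.positions[-1]
        lo, hi = geom.stem_interval(1)
        sel = ((np.abs(pos[:, 0] - geom.stem_x(1)) <= geom.channel_width / 2)
               & (pos[:, 1] >= lo) & (pos[:, 1] <= hi))
        assert sel.sum() > 1000
        cdf = np.cumsum(prof.density)
        cdf /= cdf[-1]
        ks = stats.ks_1samp(pos[sel, 1] - lo,
                            lambda x: np.interp(x, prof.y, cdf))
        assert ks.statistic < 0.05


class TestRendering:
    def test_noise_free_counts_equal_occupancy(self, mixed_run, geom):
        profiles = render_observation(mixed_run, [6000.0], noise=None)
        total = sum(p.counts.sum() for p in profiles)
        assert total <= mixed_run.population.n
        pos = mixed_run.positions[-1]
        n = 2
        lo, hi = geom.stem_interval(n)
        occ = ((np.abs(pos[:, 0] - geom.stem_x(n)) <= geom.channel_width / 2)
               & (pos[:, 1] >= lo) & (pos[:, 1] <= hi)).sum()
        prof = [p for p in profiles if p.junction == n][0]
        assert prof.counts.sum() == occ

    def test_poisson_noise_variance_matches_mean(self, mixed_run):
        ref = render_observation(mixed_run, [6000.0], noise=None)[0]
        draws = np.stack([
            render_observation(mixed_run, [6000.0], noise="poisson",
                               noise_seed=k)[0].counts
            for k in range(300)])
        busy = ref.counts >= 20
        ratio = draws[:, busy].var(axis=0) / draws[:, busy].mean(axis=0)
        assert ratio.mean() == pytest.approx(1.0, abs=0.15)


class TestMixedStrains:
    def test_null_strain_decisions_unbiased(self, mixed_run):
        null = mixed_run.population.labels == "null"
        table = junction_decision_counts(mixed_run, null)
        # junctions with enough resolved decisions halve the population
        busy = table[(table.n_up + table.n_down) >= 500]
        assert len(busy) >= 2
        assert np.allclose(busy.dilution_factor, 2.0, rtol=0.1)

    def test_chemotactic_strain_prefers_up_gradient(self, mixed_run):
        wt = mixed_run.population.labels == "WT"
        table = junction_decision_counts(mixed_run, wt)
        cf = (table.n_up - table.n_down) / (table.n_up + table.n_down)
        assert (cf.iloc[:3] > 0.3).all()

    def test_mixture_sorting_index_increases(self, mixed_run):
        wt = mixed_run.population.labels == "WT"
        up_wt = junction_decision_counts(mixed_run, wt).n_up.to_numpy()
        up_null = junction_decision_counts(mixed_run, ~wt).n_up.to_numpy()
        s = empirical_sorting_index(up_wt[:3], up_null[:3])
        assert s[0] == 1.0
        assert np.all(np.diff(s) > 0)

    def test_strain_counts_must_be_positive(self, geom, log_field):
        with pytest.raises(DomainError):
            generate_mixed_population(0, 10, geom, log_field)


class TestHeterogeneousExperiment:
    def test_phenotype_mapping_conventions(self, hyper, geom, linear_field,
                                           params, model_linear):
        from tmaze.population import sample_phenotypes

        phen = sample_phenotypes(hyper, 2000, seed=3)
        pop = phenotypes_to_agents(phen, hyper, linear_field, geom, params)
        # mean-phenotype diffusivity is the population value
        tbar = hyper.mean_tumble_bias
        assert pop.D[0] == pytest.approx(330.0 * tbar / phen.T_B[0])
        # drift scales as (g / gbar) (tbar / T_B) times the fitted velocity
        expected = (phen.g[0] / model_linear.gbar) * (tbar / phen.T_B[0]) \
            * 640.0 * linear_field.gradient
        assert pop.vc[0] == pytest.approx(expected, rel=1e-6)

    def test_control_geometry_matches_last_junction(self, geom, log_field):
        g1, f1 = single_junction_control_geometry(geom, log_field)
        assert g1.n_junctions == 1
        lo, hi = geom.stem_interval(4)
        assert f1.concentration(0.0) == pytest.approx(
            float(log_field.concentration(lo)))
        assert f1.concentration(g1.span) == pytest.approx(
            float(log_field.concentration(hi)))
        assert f1.gradient == pytest.approx(log_field.gradient)

    def test_sigma_recovered_from_noisy_observations(self, hyper, geom,
                                                     linear_field):
        table = synthetic_sorting_indices(hyper, geom, linear_field,
                                          noise=0.1, n_replicates=3, seed=17)
        H = table.groupby("junction")["H_n"].mean().to_numpy()
        res = fit_sigma(H, hyper.with_sigma(4.0), geom, linear_field)
        assert res.value == pytest.approx(hyper.sigma, rel=0.15)

    def test_homogeneous_population_shows_no_sorting_effect(self, geom,
                                                            log_field,
                                                            params):
        """With a degenerate (single-phenotype) population the full-maze
        last junction and the single-junction control develop the same
        profile slope, within Monte-Carlo error."""
        g1, f1 = single_junction_control_geometry(geom, log_field)
        seeds = {"maze": 31, "control": 32}
        slopes = {}
        lo, hi = geom.stem_interval(4)
        Cmid = float(log_field.concentration((lo + hi) / 2))
        for tag, (gg, ff, junction) in {"maze": (geom, log_field, 4),
                                        "control": (g1, f1, 1)}.items():
            pop = AgentPopulation(D=np.full(6000, 330.0), drift_mode="log",
                                  coeff=np.full(6000,
                                                params.chi_log * ff.gradient))
            traj = simulate_agents(gg, ff, pop, t_end=7200.0, dt=0.5,
                                   seed=seeds[tag])
            prof = render_observation(traj, [7200.0], noise=None)
            prof = [p for p in prof if p.junction == junction][0]
            slopes[tag], se = log_slope(prof, geom=gg)
        # same local steady slope chi_L*gradC/(C*D) at the shared window
        expected = params.chi_log * log_field.gradient / Cmid / 330.0
        assert slopes["maze"] == pytest.approx(slopes["control"], abs=6e-4)
        assert slopes["control"] == pytest.approx(expected, rel=0.5)
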