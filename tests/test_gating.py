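import numpy as np
import pytest
from scipy.stats import ks_2samp

from casparks import (GatingParams, SimulationConfig, generate_layout,
                      p_cyto, phi_lumen, firing_prob, source_strength,
                      source_strength_mol, deposit_sources, step_gating)
from casparks.gating import EventLog, GatingState, OPEN, p_ryr


@pytest.fixture()
def single_site():
    cfg = SimulationConfig().with_(domain_size_x=5.0, domain_size_y=5.0,
                                   mesh_size=0.1, single_site=True)
    return cfg, generate_layout(cfg, seed=4)


class TestPCyto:
    def test_limits(self):
        assert p_cyto(0.0, 22) == 0.0
        assert p_cyto(1.0, 22) == 1.0

    def test_cluster_coupling_value(self):
        assert p_cyto(0.01, 22) == pytest.approx(1 - 0.99 ** 22)
        assert p_cyto(0.01, 22) == pytest.approx(0.19837, abs=1e-5)

    def test_single_channel_identity(self):
        p = np.linspace(0, 1, 11)
        assert np.allclose(p_cyto(p, 1), p)

    def test_monotone_in_both_arguments(self):
        p = np.linspace(0.001, 0.3, 40)
        assert (np.diff(p_cyto(p, 22)) > 0).all()
        assert p_cyto(0.01, 22) > p_cyto(0.01, 3)


class TestPhiLumen:
    params = GatingParams()

    def test_unity_at_nsr_for_any_m(self):
        for m in (1, 10):
            assert phi_lumen(1.0, m, self.params) == pytest.approx(1.0)

    def test_clustered_is_rogue_to_the_tenth(self):
        c = np.linspace(0.05, 1.0, 30)
        assert np.allclose(phi_lumen(c, 10.0, self.params),
                           phi_lumen(c, 1.0, self.params) ** 10)

    def test_zero_lumen_zero_phi_and_monotone(self):
        assert phi_lumen(0.0, 1, self.params) == 0.0
        c = np.linspace(0.01, 1.0, 50)
        assert (np.diff(phi_lumen(c, 10, self.params)) > 0).all()


class TestFiringProb:
    params = GatingParams()

    def test_empty_lumen_blocks_firing(self, single_site):
        _, layout = single_site
        unit = layout.sites[0].crus[0]
        assert firing_prob(50.0, 0.0, unit, 1e-4, self.params) == 0.0

    def test_nondecreasing_in_lumen(self, single_site):
        _, layout = single_site
        unit = layout.sites[0].crus[0]
        p = [float(firing_prob(0.3, l, unit, 1e-4, self.params))
             for l in (0.2, 0.5, 0.8, 1.0)]
        assert p == sorted(p)

    def test_small_probability_doubles_with_dt(self, single_site):
        _, layout = single_site
        unit = layout.sites[0].rogues[0]
        p1 = float(firing_prob(0.2, 1.0, unit, 1e-5, self.params))
        p2 = float(firing_prob(0.2, 1.0, unit, 2e-5, self.params))
        assert p2 == pytest.approx(2 * p1, rel=1e-2)


class TestSourceStrength:
    def test_clustered_to_rogue_ratio_is_ten(self, single_site):
        _, layout = single_site
        cru, rogue = layout.sites[0].crus[0], layout.sites[0].rogues[0]
        s_c = source_strength(cru, 1.0, 0.1, 0.1)
        s_r = source_strength(rogue, 1.0, 0.1, 0.1)
        assert s_c / s_r == pytest.approx(10.0)

    def test_no_driving_force_no_release(self, single_site):
        _, layout = single_site
        rogue = layout.sites[0].rogues[0]
        assert source_strength(rogue, 0.5, 500.0, 0.1) == 0.0
        # depleted lumen below cytosol clamps at zero, no reverse flux
        assert source_strength_mol(0.07, 0.01, 0.5) == 0.0

    def test_linear_in_driving_force(self):
        full = source_strength_mol(0.7, 1.0, 0.0)
        half = source_strength_mol(0.7, 0.5, 0.0)
        assert full == pytest.approx(2 * half)
        # I*dCa/2F: 0.7 pA at 1 mM
        assert full == pytest.approx(0.7e-12 / (2 * 96500.0))


class TestDeposit:
    def test_no_open_units_zero_field(self, single_site):
        cfg, layout = single_site
        state = GatingState(layout)
        ca = np.full((cfg.ny, cfg.nx), 0.1)
        out = deposit_sources(state, ca, np.ones(1), cfg.mesh_size)
        assert np.abs(out).max() == 0.0

    def test_single_rogue_hits_exactly_one_cell(self, single_site):
        cfg, layout = single_site
        state = GatingState(layout)
        k = next(i for i, (_, _, u) in enumerate(state.units)
                 if u.kind == "rogue")
        state.status[k] = OPEN
        ca = np.full((cfg.ny, cfg.nx), 0.1)
        out = deposit_sources(state, ca, np.ones(1), cfg.mesh_size)
        assert (out > 0).sum() == 1

    def test_colocated_strengths_add(self, single_site):
        cfg, layout = single_site
        state = GatingState(layout)
        rogues = [i for i, (_, _, u) in enumerate(state.units)
                  if u.kind == "rogue"]
        ca = np.full((cfg.ny, cfg.nx), 0.1)
        state.status[rogues[0]] = OPEN
        one = deposit_sources(state, ca, np.ones(1), cfg.mesh_size)
        state.status[rogues[1]] = OPEN
        two = deposit_sources(state, ca, np.ones(1), cfg.mesh_size)
        assert two.sum() == pytest.approx(2 * one.sum(), rel=1e-12)


class TestStepGating:
    def _run_forced(self, single_site, unit_index, n_steps=300, dt=1e-4):
        cfg, layout = single_site
        state = GatingState(layout)
        log = EventLog()
        ca = np.full((cfg.ny, cfg.nx), 0.1)
        lum = np.ones(1)
        rng = np.random.default_rng(0)
        params = cfg.gating
        t = 0.0
        close_times = {}
        for i in range(n_steps):
            step_gating(state, t, dt, ca, lum, params, rng, log,
                        cfg.mesh_size,
                        forced=[(0, unit_index)] if i == 0 else None)
            for k in range(state.n_units):
                if state.status[k] != OPEN and k not in close_times \
                        and np.isfinite(state.scheduled_close[k]):
                    close_times[k] = t
            t += dt
        return log, state

    def test_zero_phi_means_no_openings(self, single_site):
        cfg, layout = single_site
        state = GatingState(layout)
        log = EventLog()
        ca = np.full((cfg.ny, cfg.nx), 100.0)   # saturating cytosolic Ca
        rng = np.random.default_rng(1)
        for i in range(200):
            step_gating(state, i * 1e-4, 1e-4, ca, np.zeros(1), cfg.gating,
                        rng, log, cfg.mesh_size)
        assert len(log) == 0

    def test_forced_rogue_release_lasts_20_ms(self, single_site):
        cfg, _ = single_site
        log, _ = self._run_forced(single_site, cfg.n_cru_per_site)
        forced = [r for r in log if r.forced]
        assert len(forced) == 1
        assert forced[0].kind == "rogue"
        assert forced[0].duration_ms == 20.0

    def test_forced_cru_release_lasts_10_ms(self, single_site):
        log, _ = self._run_forced(single_site, 0)
        forced = [r for r in log if r.forced]
        assert forced[0].kind == "clustered"
        assert forced[0].duration_ms == 10.0

    def test_seeded_stochastic_path_reproducible(self, single_site):
        cfg, layout = single_site
        outs = []
        for _ in range(2):
            state = GatingState(layout)
            log = EventLog()
            ca = np.full((cfg.ny, cfg.nx), 0.35)
            rng = np.random.default_rng(42)
            for i in range(500):
                step_gating(state, i * 1e-4, 1e-4, ca, np.ones(1),
                            cfg.gating, rng, log, cfg.mesh_size)
            outs.append([(r.t_open, r.kind, r.unit_index) for r in log])
        assert outs[0] == outs[1] and len(outs[0]) > 0

    def test_first_opening_times_invariant_under_dt_halving(self, single_site):
        """Hazard consistency: the first-opening-time distribution of a
        single unit does not depend on the step size (KS test)."""
        cfg, layout = single_site
        params = cfg.gating
        unit = layout.sites[0].rogues[0]
        hazard_region = 0.22   # µM, sub-saturating

        def sample(dt, n, seed):
            rng = np.random.default_rng(seed)
            p = float(firing_prob(hazard_region, 1.0, unit, dt, params))
            # geometric first-success time
            return (rng.geometric(p, size=n) - 1) * dt + dt * rng.random(n)

        a = sample(1e-4, 600, 0)
        b = sample(5e-5, 600, 1)
        assert ks_2samp(a, b).pvalue > 0.01
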