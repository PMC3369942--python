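import itertools

import numpy as np
import pytest

from sarcosim import Params, crosslink_rate, init_bundle, merge_clusters
from sarcosim.geometry import Cluster
from sarcosim.kinetics import (
    EventLog,
    apply_links,
    dissociate_filament,
    draw_lengths,
    myosin_attach,
    myosin_detach,
    sample_crosslink_events,
    sever,
    turnover,
)

from conftest import make_state


class TestCrosslinkRate:
    def test_gaussian_kernel(self):
        assert crosslink_rate(0.0, 10.0, 0.1) == 10.0
        assert crosslink_rate(0.1, 10.0, 0.1) == pytest.approx(10.0 * np.exp(-1))
        assert crosslink_rate(5.0, 10.0, 0.1) == pytest.approx(0.0, abs=1e-300)
        with pytest.raises(ValueError):
            crosslink_rate(0.1, 10.0, 0.0)

    def test_monotone_decreasing(self):
        d = np.linspace(0, 1, 50)
        r = crosslink_rate(d, 3.0, 0.2)
        assert np.all(np.diff(r) < 0)


def two_free_state(d, k0=10.0, seed=0):
    p = Params(N_actin=2, N_myosin=0, k0=k0, seed=seed)
    return make_state(p, plus_pos=[10.0, 10.0 + d], sigma=[1, -1])


class TestSampleCrosslinks:
    def test_zero_rate_never_links(self):
        state = two_free_state(0.0, k0=0.0)
        for _ in range(200):
            assert sample_crosslink_events(state, 0.01) == []

    def test_empirical_link_frequency(self):
        # two coincident plus ends: the per-step link probability over fresh
        # realizations is 1 - exp(-k0 dt)
        dt = 0.009
        n = 3000
        hits = 0
        for seed in range(n):
            state = two_free_state(0.0, seed=seed)
            hits += bool(sample_crosslink_events(state, dt))
        p_exp = 1 - np.exp(-10.0 * dt)
        se = np.sqrt(p_exp * (1 - p_exp) / n)
        assert abs(hits / n - p_exp) < 3 * se

    def test_hazard_accumulates_until_threshold(self):
        # the pair's integrated-hazard clock fires exactly once per threshold
        state = two_free_state(0.0, seed=1)
        dt = 0.009
        fires = sum(
            bool(sample_crosslink_events(state, dt)) for _ in range(2000)
        )
        # over T = 18 time units at rate k0 = 10, ~180 firings
        assert abs(fires - 180) < 3 * np.sqrt(180)

    def test_same_cluster_pairs_excluded(self):
        p = Params(N_actin=2, N_myosin=0, k0=100.0)
        state = make_state(
            p, plus_pos=[10.0, 10.0], sigma=[1, -1], clusters=[{0, 1}]
        )
        for _ in range(100):
            assert sample_crosslink_events(state, 0.0009) == []

    def test_distance_cutoff(self):
        state = two_free_state(1.0)  # 10 capture ranges away
        for _ in range(100):
            assert sample_crosslink_events(state, 0.009) == []

    def test_warns_on_coarse_dt(self):
        state = two_free_state(0.0)
        with pytest.warns(UserWarning):
            sample_crosslink_events(state, 0.02)


class TestMergeClusters:
    def test_weighted_average(self):
        a = Cluster(0, 0.0, {0})
        b = Cluster(1, 0.1, {1, 2, 3})
        assert merge_clusters(a, b, 20.0).z_pos == pytest.approx(0.075)

    def test_minimum_image_across_boundary(self):
        a = Cluster(0, 19.9, {0})
        b = Cluster(1, 0.1, {1})
        assert merge_clusters(a, b, 20.0).z_pos == pytest.approx(0.0)

    def test_members_union_and_id(self):
        a = Cluster(3, 5.0, {0, 1})
        b = Cluster(7, 5.2, {2})
        m = merge_clusters(a, b, 20.0)
        assert m.members == {0, 1, 2} and m.id == 3

    def test_pairwise_merge_order_independent(self):
        positions = [4.9, 5.0, 5.15]
        sizes = [{0}, {1, 2}, {3, 4, 5}]
        results = []
        for order in itertools.permutations(range(3)):
            cs = {
                i: Cluster(i, positions[i], set(sizes[i])) for i in range(3)
            }
            seq = list(order)
            first = merge_clusters(cs[seq[0]], cs[seq[1]], 20.0)
            final = merge_clusters(first, cs[seq[2]], 20.0)
            results.append((frozenset(final.members), final.z_pos))
        members = {r[0] for r in results}
        assert len(members) == 1
        zs = [r[1] for r in results]
        assert max(zs) - min(zs) < 1e-12

    def test_self_merge_rejected(self):
        a = Cluster(0, 1.0, {0})
        with pytest.raises(ValueError):
            merge_clusters(a, a, 20.0)


class TestApplyLinks:
    def test_merge_updates_membership_and_snaps(self):
        p = Params(N_actin=3, N_myosin=0)
        state = make_state(p, plus_pos=[5.0, 5.1, 12.0], sigma=[1, -1, 1])
        apply_links(state, [(0, 1)])
        assert state.cluster_of[0] == state.cluster_of[1]
        assert state.plus_pos[0] == state.plus_pos[1] == pytest.approx(5.05)
        assert state.cluster_of[2] == -1
        state.validate()


class TestDissociation:
    def test_disabled_by_default(self):
        p = Params(N_actin=4, N_myosin=0)
        state = make_state(
            p, plus_pos=[5.0] * 4, sigma=[1, 1, -1, -1], clusters=[{0, 1, 2, 3}]
        )
        dissociate_filament(state, 0.01)
        assert len(state.clusters[0].members) == 4

    def test_departure_rate_and_position(self):
        k = 5.0
        dt = 0.01
        n_tot, hits = 0, 0
        for seed in range(300):
            p = Params(N_actin=10, N_myosin=0, k_diss=k, seed=seed)
            state = make_state(
                p, plus_pos=[7.0] * 10, sigma=[1, -1] * 5, clusters=[set(range(10))]
            )
            dissociate_filament(state, dt)
            freed = np.nonzero(state.cluster_of < 0)[0]
            hits += freed.size
            n_tot += 10
            assert np.all(state.plus_pos[freed] == 7.0)
        p_exp = 1 - np.exp(-k * dt)
        se = np.sqrt(p_exp * (1 - p_exp) * n_tot)
        assert abs(hits - n_tot * p_exp) < 3 * se


class TestMyosinBinding:
    def _site_state(self, k_on=10.0, k_off=10.0, seed=0):
        p = Params(N_actin=1, N_myosin=1, k_on=k_on, k_off=k_off, L_my=0.5,
                   seed=seed)
        # right site sits at 10.25; a sigma=+1 filament spanning [9.5, 11.5]
        return make_state(
            p, plus_pos=[11.5], sigma=[1], lengths=[2.0], my_center=[10.0]
        )

    def test_polarity_specific_attachment(self):
        state = self._site_state(k_on=1e6)
        myosin_attach(state, 0.01)
        # right site (index 1) binds the sigma=+1 filament; left site finds
        # no eligible sigma=-1 filament and stays unbound
        assert state.my_bound[0, 1] == 0
        assert state.my_bound[0, 0] == -1
        assert state.my_offset[0, 1] == pytest.approx(11.5 - 10.25)

    def test_no_eligible_filament(self):
        p = Params(N_actin=1, N_myosin=1, k_on=1e6)
        state = make_state(p, plus_pos=[3.0], sigma=[1], my_center=[10.0])
        myosin_attach(state, 0.01)
        assert np.all(state.my_bound == -1)

    def test_equilibrium_bound_fraction(self):
        # one site, one permanently eligible filament: two-state Markov chain
        # with stationary bound probability k_on / (k_on + k_off)
        state = self._site_state(k_on=10.0, k_off=10.0, seed=7)
        dt = 0.01
        bound = 0
        n = 30000
        for _ in range(n):
            myosin_detach(state, dt)
            myosin_attach(state, dt)
            state.time += dt
            bound += int(state.my_bound[0, 1] >= 0)
        p_exp = 0.5
        # ~ n * dt * (k_on + k_off) / 2 independent switching events
        n_eff = n * dt * 10.0
        se = np.sqrt(p_exp * (1 - p_exp) / n_eff)
        assert abs(bound / n - p_exp) < 4 * se


class TestTurnover:
    def test_zero_rate_untouched(self):
        state = init_bundle(Params(N_actin=20, N_myosin=0, seed=3))
        before = state.plus_pos.copy()
        turnover(state, 0.01)
        assert np.array_equal(state.plus_pos, before)

    def test_count_conserved_and_rate(self):
        p = Params(N_actin=100, N_myosin=0, k_turnover=2.0, seed=4)
        state = init_bundle(p)
        log = EventLog()
        steps = 1000
        dt = 0.01
        for _ in range(steps):
            turnover(state, dt, log)
            state.time += dt
            assert state.sigma.size == 100
        state.validate()
        expected = 100 * 2.0 * dt * steps
        assert abs(len(log) - expected) < 3 * np.sqrt(expected)

    def test_removed_filament_leaves_cluster_and_detaches_myosin(self):
        p = Params(N_actin=2, N_myosin=1, k_turnover=1e6)
        state = make_state(
            p, plus_pos=[10.0, 10.0], sigma=[-1, 1], lengths=[1.0, 1.0],
            clusters=[{0, 1}],
            my_center=[10.25], my_bound=[[0, 1]], my_offset=[[0.5, 0.5]],
        )
        turnover(state, 1.0)
        assert np.all(state.my_bound == -1)
        assert np.all(state.cluster_of == -1)
        assert not state.clusters


class TestSever:
    def test_cut_shortens_to_plus_fragment(self):
        p = Params(N_actin=50, N_myosin=0, length_mode="severing", r_sever=1e6)
        state = make_state(
            p, plus_pos=np.linspace(0, 19, 50), sigma=[1, -1] * 25,
            lengths=np.full(50, 2.0),
        )
        sever(state, 1e-3)
        assert np.all(state.length > 0)
        assert np.all(state.length <= 2.0)
        # cuts happened (hazard is astronomically large)
        assert np.mean(state.length < 2.0) > 0.9

    def test_antenna_property_hazard_proportional_to_length(self):
        # a filament of length 2 is severed at twice the rate of length 1
        r, dt = 2.0, 0.01
        counts = {1.0: 0, 2.0: 0}
        reps, per = 150, 20
        for ln in counts:
            for seed in range(reps):
                p = Params(
                    N_actin=per, N_myosin=0, length_mode="severing",
                    r_sever=r, seed=seed,
                )
                state = make_state(
                    p, plus_pos=np.linspace(0, 19, per), sigma=[1] * per,
                    lengths=np.full(per, ln),
                )
                log = EventLog()
                sever(state, dt, log)
                counts[ln] += len(log)
        n = reps * per
        p1 = 1 - np.exp(-r * 1.0 * dt)
        p2 = 1 - np.exp(-r * 2.0 * dt)
        assert abs(counts[1.0] - n * p1) < 3 * np.sqrt(n * p1)
        assert abs(counts[2.0] - n * p2) < 3 * np.sqrt(n * p2)

    def test_stranded_sites_detach(self):
        p = Params(N_actin=1, N_myosin=1, length_mode="severing", r_sever=1e6)
        state = make_state(
            p, plus_pos=[10.0], sigma=[1], lengths=[2.0],
            my_center=[8.25], my_bound=[[-1, 0]], my_offset=[[0.0, 1.75]],
        )
        for _ in range(50):
            sever(state, 1e-3)
        bound = state.my_bound[0, 1]
        if bound >= 0:
            assert state.my_offset[0, 1] <= state.length[0]


class TestInitBundle:
    def test_initial_invariants_and_singletons(self):
        state = init_bundle(Params(N_actin=30, N_myosin=10, seed=9))
        state.validate()
        assert len(state.clusters) == 30
        assert all(len(c.members) == 1 for c in state.clusters.values())
        assert np.all(state.my_bound == -1)

    def test_lognormal_moment_matching(self, rng):
        p = Params(length_mode="lognormal", sigma_ell=0.4, ell_mean=1.0)
        x = draw_lengths(p, rng, 100_000)
        assert abs(x.mean() - 1.0) < 0.01
        assert abs(x.std() - 0.4) < 0.01 * 0.4 + 0.005

    def test_lognormal_degenerates_when_sigma_zero(self, rng):
        p = Params(length_mode="lognormal", sigma_ell=0.0)
        assert np.all(draw_lengths(p, rng, 100) == 1.0)

    def test_exponential_mean(self, rng):
        p = Params(length_mode="exponential", ell_mean=1.0)
        x = draw_lengths(p, rng, 100_000)
        assert abs(x.mean() - 1.0) < 0.02

    def test_orientation_fair_coin(self):
        state = init_bundle(Params(N_actin=4000, N_myosin=0, seed=11))
        frac = np.mean(state.sigma == 1)
        assert abs(frac - 0.5) < 3 * 0.5 / np.sqrt(4000)
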