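"""Energy terms, analytic forces and their contracts."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

import cocomo2 as c
from cocomo2.params import KE, scale_interactions
from cocomo2.structure_io import DomainDefinition
from tests.conftest import make_state


def neutral_params(params):
    """Short-range only: no charges' partner terms, no solvation repulsion."""
    return params.replace(A0_polar=0.0, A0_hydrophobic=0.0)


def random_safe_state(params, n_chains=3, n_res=10, seed=3, box=30.0,
                      min_sep=0.55):
    """Random multi-chain state with no deep core overlaps (for FD checks)."""
    rng = np.random.default_rng(seed)
    seqs, coords = [], []
    for k in range(n_chains):
        seq = "".join(rng.choice(list("ARNDCQEGHIKLMFPSTWYV"), n_res))
        seqs.append(seq)
        coil = c.make_random_coil(seq, seed=int(rng.integers(1000)),
                                  min_separation=min_sep)
        coords.append(coil.coords + rng.random(3) * 4 + box / 2 - 2)
    def min_interchain(cs):
        from scipy.spatial.distance import cdist
        best = np.inf
        for a in range(len(cs)):
            for b in range(a + 1, len(cs)):
                best = min(best, cdist(cs[a], cs[b]).min())
        return best

    # shift whole chains until no inter-chain core overlap remains
    for _ in range(200):
        if min_interchain(coords) >= min_sep * 0.8:
            break
        coords = [x + rng.random(3) * 2 for x in coords]
    return make_state(seqs, coords, [box] * 3, params)


class TestBondEnergy:
    def test_rest_length_is_zero(self, params2):
        st = make_state(["AA"], [np.array([[1.0, 1, 1], [1.38, 1, 1]])],
                        [50] * 3, params2)
        assert c.bond_energy(st, params2) == pytest.approx(0.0, abs=1e-12)

    def test_stretched_bond_half_k_convention(self, params2):
        st = make_state(["AA"], [np.array([[1.0, 1, 1], [1.48, 1, 1]])],
                        [50] * 3, params2)
        assert c.bond_energy(st, params2) == pytest.approx(
            0.5 * 4184 * 0.1 ** 2, rel=1e-9)  # 20.92 kJ/mol

    def test_translation_invariance(self, params2):
        st = make_state(["AAA"], [c.make_random_coil("AAA", seed=1).coords + 5],
                        [50] * 3, params2)
        moved = c.SystemState(st.coords + [3.3, -1.2, 7.7], st.box,
                              st.chain_index, st.topologies)
        assert c.bond_energy(moved, params2) == pytest.approx(
            c.bond_energy(st, params2), abs=1e-9)


class TestEnmAndAngleEnergy:
    def test_reference_conformation_is_network_ground_state(self, params2):
        helix = c.make_ideal_helix("A" * 12)
        st = make_state(["A" * 12], [helix.coords + 10], [50] * 3, params2,
                        domains=[DomainDefinition(((1, 12),))],
                        references=[helix])
        assert c.enm_energy(st, params2) == pytest.approx(0.0, abs=1e-18)

    def test_straight_trimer_has_no_angle_energy(self, params2):
        st = make_state(["AAA"], [np.array([[1.0, 1, 1], [1.38, 1, 1],
                                            [1.76, 1, 1]])], [50] * 3, params2)
        assert c.angle_energy(st, params2) == pytest.approx(0.0, abs=1e-12)

    def test_right_angle_trimer(self, params2):
        st = make_state(["AAA"], [np.array([[1.38, 1, 1], [1.0, 1, 1],
                                            [1.0, 1.38, 1]])], [50] * 3, params2)
        expected = 0.5 * 4.184 * (math.pi / 2) ** 2
        assert c.angle_energy(st, params2) == pytest.approx(expected, rel=1e-9)


class TestShortRange:
    def test_zero_crossing_at_sigma(self, table, params2, dimer_factory):
        sij = 0.5 * (table["F"].sigma + table["L"].sigma)
        st = dimer_factory("F", "L", sij)
        assert c.short_range_energy(st, params2) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("pair", [("F", "L"), ("R", "F"), ("S", "Q"),
                                      ("W", "W"), ("K", "E")])
    def test_numeric_minimum_equals_pair_depth(self, table, params2,
                                               dimer_factory, pair):
        a, b = pair
        p = neutral_params(params2)
        sij = 0.5 * (table[a].sigma + table[b].sigma)
        eps = c.pair_epsilon(table[a], table[b], 1, 1, p)

        def u(r):
            return c.short_range_energy(dimer_factory(a, b, r, params=p), p)

        res = minimize_scalar(u, bounds=(0.8 * sij, 2.9), method="bounded")
        assert res.fun == pytest.approx(-eps, rel=1e-6)
        assert res.x > sij

    def test_beyond_cutoff_contributes_nothing(self, params2, dimer_factory):
        st = dimer_factory("F", "F", 3.05, box=50.0)
        assert c.short_range_energy(st, params2) == 0.0

    def test_lambda_weakens_folded_attraction(self, params2):
        # u_short_range of a folded dimer moves toward zero as lambda grows.
        # xi is frozen from a compact reference ball (varied burial), while the
        # evaluated state is two extended strands with no core overlaps, so
        # every nonbonded pair sits in the attractive region.
        n = 25
        ball = c.make_random_coil("L" * n, seed=7, min_separation=0.3)
        line = np.column_stack([np.arange(n) * 0.38, np.zeros(n), np.zeros(n)])
        dom = DomainDefinition(((1, n),))
        prev = -np.inf
        for lam in np.linspace(0.1, 0.9, 5):
            p = neutral_params(params2).replace(lambda_threshold=lam)
            st = make_state(["L" * n, "L" * n],
                            [line + 10, line + [10, 11.0, 10]],
                            [40] * 3, p, domains=[dom, dom],
                            references=[ball, ball])
            u = c.short_range_energy(st, p)
            assert u >= prev - 1e-9
            prev = u


class TestElectrostatics:
    def test_no_sources_no_energy(self, params1, dimer_factory):
        # generation-1 hydrophobic beads: q = 0 and A0_hydrophobic = 0
        p = params1
        st = dimer_factory("G", "L", 1.0, params=p)
        assert c.electrostatic_energy(st, p) == 0.0

    def test_sign_symmetry_of_charge_products(self, params2, dimer_factory):
        p = neutral_params(params2)
        u_pp = c.electrostatic_energy(dimer_factory("R", "K", 1.0, params=p), p)
        u_pm = c.electrostatic_energy(dimer_factory("R", "E", 1.0, params=p), p)
        assert u_pp > 0
        assert u_pm == pytest.approx(-u_pp, rel=1e-12)

    def test_screened_decay_matches_closed_form(self, params2, dimer_factory):
        p = neutral_params(params2)
        u1 = c.electrostatic_energy(dimer_factory("R", "K", 1.0, params=p), p)
        u2 = c.electrostatic_energy(dimer_factory("R", "K", 2.0, params=p), p)
        kappa = p.debye_length
        expected_ratio = (math.exp(-2 / kappa) / 2) / (math.exp(-1 / kappa) / 1)
        assert u2 / u1 == pytest.approx(expected_ratio, rel=1e-12)
        # absolute scale: Debye-Hueckel prefactor ke/eps_r
        assert u1 == pytest.approx(KE / p.dielectric * math.exp(-1.0), rel=1e-12)

    def test_solvation_repulsion_is_positive(self, params2, dimer_factory):
        st = dimer_factory("G", "L", 1.5)
        assert c.electrostatic_energy(st, params2) > 0


class TestTotalEnergyAndForces:
    def test_components_sum_to_total(self, params2):
        st = random_safe_state(params2)
        rep = c.total_energy(st, params2)
        assert rep.u_total == pytest.approx(
            rep.u_bond + rep.u_enm + rep.u_angle + rep.u_short_range
            + rep.u_electrostatic, rel=1e-12)
        assert rep.per_bead(st.n_beads) == pytest.approx(rep.u_total / st.n_beads)

    def test_distant_dimer_keeps_only_bonded_terms(self, params2):
        st = make_state(
            ["AA", "AA"],
            [np.array([[5.0, 5, 5], [5.38, 5, 5]]),
             np.array([[25.0, 25, 25], [25.38, 25, 25]])],
            [60] * 3, params2)
        rep = c.total_energy(st, params2)
        assert rep.u_short_range == 0.0
        assert rep.u_electrostatic == 0.0

    def test_cell_list_equals_all_pairs_loop(self, params2):
        st = random_safe_state(params2, n_chains=5, n_res=12, seed=9)
        a = c.total_energy(st, params2, method="kdtree")
        b = c.total_energy(st, params2, method="all")
        assert a.u_short_range == pytest.approx(b.u_short_range, abs=1e-10)
        assert a.u_electrostatic == pytest.approx(b.u_electrostatic, abs=1e-10)

    def test_rigid_translation_and_rotation_invariance(self, params2):
        st = random_safe_state(params2, seed=12)
        u0 = c.total_energy(st, params2).u_total
        moved = c.SystemState(st.coords + [2.1, -3.3, 0.7], st.box,
                              st.chain_index, st.topologies)
        assert abs(c.total_energy(moved, params2).u_total - u0) < 1e-6
        from scipy.spatial.transform import Rotation
        rot = Rotation.from_euler("xyz", [20, -35, 64], degrees=True).as_matrix()
        center = st.box / 2
        rotated = c.SystemState((st.coords - center) @ rot.T + center, st.box,
                                st.chain_index, st.topologies)
        assert abs(c.total_energy(rotated, params2).u_total - u0) < 1e-6

    def test_box_doubling_preserves_pair_energies(self, params2):
        st = random_safe_state(params2, seed=4, box=30.0)
        big = c.SystemState(st.coords.copy(), np.array([60.0] * 3),
                            st.chain_index, st.topologies)
        a = c.total_energy(st, params2)
        b = c.total_energy(big, params2)
        assert a.u_total == pytest.approx(b.u_total, abs=1e-9)

    def test_exposure_scaling_weakens_attraction(self, params2):
        # xi <= 1 scales attractive wells down: the folded system's energy is
        # above the same state with full interaction strength (no core overlap)
        n = 20
        ball = c.make_random_coil("M" * n, seed=3, min_separation=0.3)
        line = np.column_stack([np.arange(n) * 0.38, np.zeros(n), np.zeros(n)])
        dom = DomainDefinition(((1, n),))
        p = neutral_params(params2)
        st = make_state(["M" * n, "M" * n],
                        [line + 10, line + [10, 11.0, 10]],
                        [40] * 3, p, domains=[dom, dom], references=[ball, ball])
        u_scaled = c.short_range_energy(st, p)
        full_top = c.build_chain_topology("M" * n, params=p)
        st_full = c.SystemState(st.coords, st.box, st.chain_index,
                                [full_top, full_top])
        u_full = c.short_range_energy(st_full, p)
        assert np.any(st.topologies[0].bead_xi < 1)
        assert u_full < 0
        assert u_scaled >= u_full

    def test_forces_match_finite_differences(self, params2):
        st = random_safe_state(params2, n_chains=3, n_res=10, seed=21)
        f = c.forces(st, params2)
        h = 1e-4  # central difference on a smooth region of the landscape
        scale = max(1.0, np.abs(f).max())
        for i in range(0, st.n_beads, 4):
            for d in range(3):
                cp = st.coords.copy()
                cp[i, d] += h
                cm = st.coords.copy()
                cm[i, d] -= h
                up = c.total_energy(c.SystemState(cp, st.box, st.chain_index,
                                                  st.topologies), params2).u_total
                um = c.total_energy(c.SystemState(cm, st.box, st.chain_index,
                                                  st.topologies), params2).u_total
                fd = -(up - um) / (2 * h)
                assert fd == pytest.approx(f[i, d], abs=2e-4 * scale)

    def test_newtons_third_law_on_isolated_pair(self, params2, dimer_factory):
        st = dimer_factory("F", "W", 0.8)
        f = c.forces(st, params2)
        assert np.allclose(f[0], -f[1], atol=1e-12)

    def test_forces_vanish_at_network_reference(self, params2):
        # with only the elastic network active, the reference conformation is
        # a stationary point of the energy
        helix = c.make_ideal_helix("A" * 10)
        p = neutral_params(params2).replace(
            epsilon_polar=0.0, epsilon_hydrophobic=0.0,
            k_bond=0.0, k_angle_protein=0.0)
        st = make_state(["A" * 10], [helix.coords + 10], [50] * 3, p,
                        domains=[DomainDefinition(((1, 10),))],
                        references=[helix])
        f = c.forces(st, p)
        assert np.abs(f).max() < 1e-8

    def test_small_box_rejected(self, params2, dimer_factory):
        with pytest.raises(ValueError, match="twice the nonbonded cutoff"):
            c.total_energy(dimer_factory("A", "A", 1.0, box=5.0), params2)
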