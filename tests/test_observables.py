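import numpy as np
import pytest

from cmapoly import observables as obs
from cmapoly.fixtures import make_disk, make_rod, make_uniform_points
from cmapoly.lattice import LatticeSpec, to_cartesian
from cmapoly.state import Chain, RunConfig, SystemState, build_initial

from conftest import random_saw_chain


def chain_of(points, spec=None):
    beads = np.array([(a, b, 0) for a, b in points], dtype=np.int32)
    return Chain(0, beads)


class TestUnwrap:
    def test_interior_chain_matches_direct_embedding(self, spec8):
        ch = chain_of([(2, 2), (3, 2), (4, 2)])
        pos = obs.unwrap_chain(ch, spec8)
        direct = to_cartesian(ch.beads[:, :2])
        assert pos == pytest.approx(direct)

    def test_boundary_straddling_chain_is_collinear(self, spec8):
        ch = chain_of([(7, 0), (0, 0), (1, 0)])
        pos = obs.unwrap_chain(ch, spec8)
        assert np.linalg.norm(pos[2] - pos[0]) == pytest.approx(2.0)

    def test_bond_steps_telescope_to_end_to_end_vector(self, spec8):
        ch = random_saw_chain(7, spec8, seed=3)
        pos = obs.unwrap_chain(ch, spec8)
        bonds = np.diff(pos, axis=0)
        assert bonds.sum(axis=0) == pytest.approx(pos[-1] - pos[0])
        assert np.linalg.norm(bonds, axis=1) == pytest.approx(np.ones(6))

    def test_broken_bond_raises(self, spec8):
        ch = chain_of([(0, 0), (2, 0)])
        with pytest.raises(ValueError):
            obs.unwrap_chain(ch, spec8)


class TestSingleChainScalars:
    def test_dimer_rg2(self, spec8):
        assert obs.radius_of_gyration_sq(chain_of([(0, 0), (1, 0)]), spec8) == (
            pytest.approx(0.25)
        )

    def test_three_bead_rod(self, spec8):
        rod = chain_of([(0, 0), (1, 0), (2, 0)])
        assert obs.radius_of_gyration_sq(rod, spec8) == pytest.approx(2 / 3)
        assert obs.end_to_end_sq(rod, spec8) == pytest.approx(4.0)
        _, lam = obs.gyration_tensor(rod, spec8)
        assert lam == pytest.approx([0.0, 2 / 3], abs=1e-12)

    def test_hexagon_disk_is_isotropic(self):
        fx = make_disk()
        ch = next(fx.to_state().chains())
        T, lam = obs.gyration_tensor(ch, fx.spec)
        assert lam == pytest.approx([3 / 7, 3 / 7], abs=1e-12)
        assert np.trace(T) == pytest.approx(6 / 7, abs=1e-12)

    def test_hairpin_end_to_end(self, spec8):
        ch = chain_of([(0, 0), (1, 0), (1, 1), (0, 1)])
        assert obs.end_to_end_sq(ch, spec8) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_trace_identity_on_random_chains(self, spec8, seed):
        ch = random_saw_chain(8, spec8, seed=seed)
        T, lam = obs.gyration_tensor(ch, spec8)
        rg2 = obs.radius_of_gyration_sq(ch, spec8)
        assert abs(np.trace(T) - rg2) < 1e-12
        assert abs(lam.sum() - rg2) < 1e-12

    def test_observables_invariant_under_periodic_translation(self, spec8):
        ch = random_saw_chain(8, spec8, seed=9)
        vals = (
            obs.radius_of_gyration_sq(ch, spec8),
            obs.end_to_end_sq(ch, spec8),
        )
        shifted = Chain(0, np.column_stack(
            [(ch.beads[:, :2] + [5, 3]) % 8, ch.beads[:, 2]]
        ).astype(np.int32))
        assert obs.radius_of_gyration_sq(shifted, spec8) == pytest.approx(vals[0])
        assert obs.end_to_end_sq(shifted, spec8) == pytest.approx(vals[1])


class TestAsphericity:
    def test_rods_give_one(self):
        lams = np.array([[0.0, s] for s in (1.0, 2.0, 5.0)])
        assert obs.asphericity(lams) == pytest.approx(1.0)

    def test_disks_give_zero(self):
        lams = np.array([[0.7, 0.7], [0.3, 0.3]])
        assert obs.asphericity(lams) == pytest.approx(0.0)

    def test_equal_sum_rod_disk_mixture_is_half(self):
        # rod (0, s) and disk (s/2, s/2): <(diff)^2>/<(sum)^2> = (s^2/2)/s^2
        s = 3.0
        lams = np.array([[0.0, s], [s / 2, s / 2]])
        assert obs.asphericity(lams) == pytest.approx(0.5)

    def test_ratio_of_means_not_mean_of_ratios(self):
        lams = np.array([[0.0, 1.0], [1.0, 1.0]])
        # mean of ratios would give (1 + 0)/2 = 0.5; ratio of means differs
        assert obs.asphericity(lams) == pytest.approx(1.0 / (1 + 4))

    def test_empty_or_degenerate_rejected(self):
        with pytest.raises(ValueError):
            obs.asphericity(np.array([[0.0, 0.0]]))


class TestIntramolecularCorrelation:
    def test_dimer_weights(self, spec8):
        prof = obs.intramolecular_correlation(chain_of([(0, 0), (1, 0)]), spec8)
        # gamma carries weight 1 at r=0 (2 self pairs / N) and 1 at r=1
        assert prof.exact_r[0] == 0.0
        np.testing.assert_allclose(prof.exact_weight, [2.0, 2.0])
        assert prof.values.sum() == pytest.approx(2.0)  # = N

    def test_total_weight_is_N(self, spec8):
        ch = random_saw_chain(9, spec8, seed=1)
        prof = obs.intramolecular_correlation(ch, spec8)
        assert prof.values.sum() == pytest.approx(9.0)

    def test_three_bead_rod_pair_counts(self, spec8):
        prof = obs.intramolecular_correlation(
            chain_of([(0, 0), (1, 0), (2, 0)]), spec8
        )
        w = dict(zip(prof.exact_r.tolist(), (prof.exact_weight / 3).tolist()))
        assert w[1.0] == pytest.approx(4 / 3)
        assert w[2.0] == pytest.approx(2 / 3)


class TestStructureFactor:
    def test_low_q_limit_is_chain_length(self, spec8):
        ch = random_saw_chain(8, spec8, seed=2)
        prof = obs.intramolecular_correlation(ch, spec8)
        s = obs.structure_factor(prof, np.array([1e-4])).s[0]
        assert s == pytest.approx(8.0, rel=1e-3)

    def test_dimer_closed_form(self, spec8):
        prof = obs.intramolecular_correlation(chain_of([(0, 0), (1, 0)]), spec8)
        q = np.linspace(0.2, 3.0, 20)
        expected = 1.0 + np.sin(q) / q
        np.testing.assert_allclose(obs.structure_factor(prof, q).s, expected)

    def test_hexagon_matches_direct_double_sum(self):
        fx = make_disk()
        ch = next(fx.to_state().chains())
        prof = obs.intramolecular_correlation(ch, fx.spec)
        q = np.geomspace(0.1, 3.0, 12)
        pos = obs.unwrap_chain(ch, fx.spec)
        expected = []
        for qi in q:
            total = 0.0
            for i in range(7):
                for j in range(7):
                    r = np.linalg.norm(pos[i] - pos[j])
                    total += 1.0 if r == 0 else np.sin(qi * r) / (qi * r)
            expected.append(total / 7)
        np.testing.assert_allclose(obs.structure_factor(prof, q).s, expected, rtol=1e-10)

    def test_nonpositive_q_rejected(self, spec8):
        prof = obs.intramolecular_correlation(chain_of([(0, 0), (1, 0)]), spec8)
        with pytest.raises(ValueError):
            obs.structure_factor(prof, np.array([0.0, 1.0]))

    def test_bessel_kernel_variant_close_to_sinc_at_low_q(self, spec8):
        ch = random_saw_chain(8, spec8, seed=5)
        prof = obs.intramolecular_correlation(ch, spec8)
        q = np.array([0.02])
        s_sinc = obs.structure_factor(prof, q).s[0]
        s_j0 = obs.structure_factor(prof, q, kernel="j0").s[0]
        assert s_sinc == pytest.approx(s_j0, rel=1e-3)
        # both kernels agree with the exact N limit
        assert s_sinc == pytest.approx(8.0, rel=1e-3)


class TestPairCorrelation:
    def test_uniform_points_plateau_at_one(self):
        spec = LatticeSpec(64)
        sets = [make_uniform_points(200, 64, seed=s) for s in range(20)]
        bins = np.arange(2.0, 30.0, 2.0)
        prof = obs.points_pair_correlation(sets, spec, bins)
        assert prof.values == pytest.approx(np.ones_like(prof.values), abs=0.12)

    def test_two_chain_distance_lands_in_one_bin(self):
        spec = LatticeSpec(16)
        chains = [
            np.array([(0, 0, 0), (1, 0, 0)]),
            np.array([(8, 0, 0), (9, 0, 0)]),
        ]
        state = SystemState.from_chains(spec, chains)
        bins = np.arange(0.0, 12.0, 1.0)
        prof = obs.cm_pair_correlation(state, bins)
        assert prof.counts.sum() == 1
        # centres at x=0.5 and x=8.5 -> min-image distance 7.5... wait 8
        occupied = np.flatnonzero(prof.counts)
        assert len(occupied) == 1

    def test_single_chain_rejected(self):
        spec = LatticeSpec(16)
        state = SystemState.from_chains(spec, [np.array([(0, 0, 0), (1, 0, 0)])])
        with pytest.raises(ValueError):
            obs.cm_pair_correlation(state, np.arange(0, 5.0))

    def test_melt_shows_correlation_hole(self, melt_small):
        from cmapoly.engine import run
        from cmapoly.rng import Pcg32

        rng = Pcg32(8)
        states = []
        for _ in range(40):
            run(melt_small, 50, rng, mode="guided")
            states.append(melt_small.copy())
        rg = np.sqrt(obs.measure_state(states[0]).rg2.mean())
        bins = np.array([0.0, rg, 2 * rg, 4 * rg, 6 * rg])
        prof = obs.cm_pair_correlation(states, bins)
        assert prof.values[0] < 1.0  # centres of other chains are excluded


class TestSolventClusters:
    def test_single_solvent_site(self):
        spec = LatticeSpec(4)
        # fill all but one site with a single Hamiltonian-path chain
        from cmapoly.state import _boustrophedon_path

        path = _boustrophedon_path(spec)[:-1]
        state = SystemState.from_chains(spec, [path])
        assert obs.solvent_cluster_sizes(state) == [1]

    def test_melt_has_no_clusters(self, melt_small):
        assert obs.solvent_cluster_sizes(melt_small) == []

    def test_sizes_match_networkx_flood_fill(self, dilute_small):
        import networkx as nx

        from cmapoly.lattice import neighbors

        state = dilute_small
        sizes = obs.solvent_cluster_sizes(state)
        g = nx.Graph()
        solvent = set(state.solvent_sites().tolist())
        g.add_nodes_from(solvent)
        for s in solvent:
            for nb in neighbors(state.spec.site_coord(s), state.spec):
                t = state.spec.site_index(*nb)
                if t in solvent:
                    g.add_edge(s, t)
        expected = sorted(len(c) for c in nx.connected_components(g))
        assert sizes == expected
        assert sum(sizes) == len(solvent)
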