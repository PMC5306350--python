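import numpy as np
import pytest

from cmapoly import observables as obs
from cmapoly.fixtures import (
    TRIANGULAR_SAW_COUNTS,
    enumerate_saws,
    make_disk,
    make_rod,
    make_uniform_points,
    sample_ideal_walks,
    sample_saw_chains,
    walk_key,
)
from cmapoly.state import validate


class TestRodFixture:
    @pytest.mark.parametrize("N", [2, 3, 8, 33])
    def test_closed_forms_match_direct_evaluation(self, N):
        fx = make_rod(N)
        state = fx.to_state()
        assert validate(state) == []
        ch = next(state.chains())
        assert obs.radius_of_gyration_sq(ch, fx.spec) == pytest.approx(
            (N**2 - 1) / 12.0
        )
        assert obs.end_to_end_sq(ch, fx.spec) == pytest.approx((N - 1) ** 2)

    def test_rod_asphericity_references(self):
        fx = make_rod(5)
        _, lam = obs.gyration_tensor(next(fx.to_state().chains()), fx.spec)
        assert lam[0] == pytest.approx(0.0, abs=1e-12)
        assert obs.asphericity(lam[None, :]) == pytest.approx(1.0)

    def test_oversized_rod_rejected(self):
        with pytest.raises(ValueError):
            make_rod(10, L=8)


class TestDiskFixture:
    def test_reference_values(self):
        fx = make_disk()
        state = fx.to_state()
        assert validate(state) == []
        ch = next(state.chains())
        _, lam = obs.gyration_tensor(ch, fx.spec)
        assert lam == pytest.approx([3 / 7, 3 / 7], abs=1e-12)
        assert obs.asphericity(lam[None, :]) == pytest.approx(0.0, abs=1e-12)
        assert obs.radius_of_gyration_sq(ch, fx.spec) == pytest.approx(6 / 7)


class TestSawEnumeration:
    def test_counts_match_published_census(self):
        for steps, count in TRIANGULAR_SAW_COUNTS.items():
            if steps == 0:
                continue
            assert enumerate_saws(steps + 1).count == count

    def test_dimers(self):
        e = enumerate_saws(2)
        assert e.count == 6
        assert np.all(e.ree2 == pytest.approx(1.0))

    def test_trimer_mean_end_to_end(self):
        e = enumerate_saws(3)
        assert e.count == 30
        # from each 2-step walk: distances 1 (60 deg, x2), sqrt(3) (120, x2), 2 (straight)
        expected = (2 * 1.0 + 2 * 3.0 + 4.0) / 5
        assert e.mean_ree2 == pytest.approx(expected)

    def test_cap_guards_combinatorial_explosion(self):
        with pytest.raises(ValueError):
            enumerate_saws(11)

    def test_walk_key_round_trip(self, spec8):
        e = enumerate_saws(4)
        ki = e.key_index()
        # translate a walk into the box; its key must map back to itself
        ab = e.steps[17].cumsum(axis=0)
        beads = np.vstack([[0, 0], ab]) + 3
        beads = np.column_stack([beads % 8, np.zeros(4, dtype=int)])
        assert ki[walk_key(beads, spec8)] == 17


class TestIdealWalks:
    def test_mean_square_end_to_end_is_step_count(self):
        ens = sample_ideal_walks(50, 10000, seed=3)
        mean = ens.ree2.mean()
        sem = ens.ree2.std(ddof=1) / np.sqrt(len(ens.ree2))
        assert abs(mean - 49.0) < 3 * sem

    def test_seed_reproducibility(self):
        a = sample_ideal_walks(10, 5, seed=11).positions
        b = sample_ideal_walks(10, 5, seed=11).positions
        assert np.array_equal(a, b)


class TestPivotSampler:
    @pytest.mark.parametrize("N", [6, 8])
    def test_matches_exact_enumeration(self, N):
        exact = enumerate_saws(N)
        conf = sample_saw_chains(N, 3000, seed=2, thin=10)
        pos = np.stack(
            [conf[..., 0] + 0.5 * conf[..., 1], conf[..., 1] * np.sqrt(3) / 2],
            axis=-1,
        )
        c = pos - pos.mean(axis=1, keepdims=True)
        rg2 = np.einsum("mni,mni->m", c, c) / N
        sem = rg2.std(ddof=1) / np.sqrt(len(rg2))
        # thinned pivot samples are mildly correlated; allow 4 nominal sigma
        assert abs(rg2.mean() - exact.mean_rg2) < 4 * sem

    def test_walks_are_self_avoiding(self):
        conf = sample_saw_chains(20, 10, seed=1)
        for walk in conf:
            assert len({tuple(p) for p in walk}) == 20
            steps = np.diff(walk, axis=0)
            assert set(map(tuple, steps)) <= {
                (1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1)
            }


def test_uniform_points_shape_and_determinism():
    pts = make_uniform_points(100, 32, seed=4)
    assert pts.shape == (100, 2)
    assert np.array_equal(pts, make_uniform_points(100, 32, seed=4))
    with pytest.raises(ValueError):
        make_uniform_points(1, 32, seed=4)
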