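from fractions import Fraction

import numpy as np
import pytest

from cmapoly.lattice import LatticeSpec
from cmapoly.state import (
    RunConfig,
    build_disordered,
    build_initial,
    concentration,
    read_snapshot,
    validate,
    write_snapshot,
)


class TestConcentration:
    def test_single_long_chain_on_production_box(self):
        spec = LatticeSpec(256)
        assert concentration(1, 1024, spec) == Fraction(1, 64)
        assert float(concentration(1, 1024, spec)) == 0.015625

    def test_two_chains(self):
        spec = LatticeSpec(256)
        assert float(concentration(2, 1024, spec)) == 0.03125

    def test_melt_is_one(self):
        assert concentration(4, 16, LatticeSpec(8)) == 1

    def test_overfull_rejected(self):
        with pytest.raises(ValueError):
            concentration(5, 16, LatticeSpec(8))


class TestBuildInitial:
    def test_short_chain_lies_along_first_row(self):
        state = build_initial(RunConfig(N=4, n_chains=1, L=8))
        beads = state.bead_coords()[0]
        assert beads[:, :2].tolist() == [[0, 0], [1, 0], [2, 0], [3, 0]]
        assert len(state.solvent_sites()) == 60

    def test_fold_rule_hairpins_into_next_row(self):
        state = build_initial(RunConfig(N=10, n_chains=1, L=8))
        beads = state.bead_coords()[0]
        assert (beads[:8, 1] == 0).all() and (beads[8:, 1] == 1).all()
        assert validate(state) == []

    def test_melt_fill_leaves_no_solvent(self):
        state = build_initial(RunConfig(N=16, n_chains=4, L=8))
        assert len(state.solvent_sites()) == 0
        assert validate(state) == []

    def test_aligned_melt_gets_hairpins(self):
        # N a multiple of L would otherwise give straight torus-wrapping
        # chains, which are frozen under cooperative loops
        state = build_initial(RunConfig(N=8, n_chains=8, L=8))
        assert validate(state) == []
        b = state.bead_coords()[0][:, 1]
        assert len(set(b.tolist())) > 1  # chain spans more than one row

    def test_folded_fill(self):
        state = build_initial(RunConfig(N=16, n_chains=16, L=16, fold_width=4))
        assert validate(state) == []
        assert len(state.solvent_sites()) == 0

    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError):
            RunConfig(N=100, n_chains=1, L=8)


class TestValidate:
    def test_clean_state_is_empty(self, dilute_small):
        assert validate(dilute_small) == []

    def test_teleported_bead_reports_bond_and_occupancy(self, dilute_small):
        state = dilute_small
        spec = state.spec
        # move chain 0 bead 0 onto chain 1 bead 0's site without bookkeeping
        state.bead_site[0, 0] = state.bead_site[1, 0]
        issues = "\n".join(validate(state))
        assert "occupied by more than one bead" in issues or "disagree" in issues
        assert "broken bond" in issues


class TestDisorderedFill:
    def test_valid_at_full_occupancy(self):
        state = build_disordered(RunConfig(N=16, n_chains=16, L=16, seed=3))
        assert validate(state) == []
        assert float(state.phi) == 1.0

    def test_seed_determinism(self):
        cfg = RunConfig(N=8, n_chains=10, L=16, seed=9)
        assert build_disordered(cfg) == build_disordered(cfg)

    def test_differs_from_extended_fill(self):
        cfg = RunConfig(N=16, n_chains=8, L=16, seed=5)
        assert not (build_disordered(cfg) == build_initial(cfg))


class TestSnapshotFormat:
    def test_round_trip_is_exact(self, tmp_path, melt_small):
        path = tmp_path / "snap.txt"
        melt_small.timestep = 123
        write_snapshot(melt_small, path)
        back = read_snapshot(path)
        assert back == melt_small
        assert back.timestep == 123
        assert np.array_equal(back.occ_chain, melt_small.occ_chain)

    def test_phi_header_checked(self, tmp_path, dilute_small):
        path = tmp_path / "snap.txt"
        write_snapshot(dilute_small, path)
        text = path.read_text().replace("phi 3/16", "phi 1/2")
        path.write_text(text)
        with pytest.raises(ValueError):
            read_snapshot(path)

    def test_missing_bead_rejected(self, tmp_path, dilute_small):
        path = tmp_path / "snap.txt"
        write_snapshot(dilute_small, path)
        lines = path.read_text().splitlines()
        path.write_text("\n".join(lines[:-1]) + "\n")
        with pytest.raises(ValueError):
            read_snapshot(path)
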