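import numpy as np
import pytest

import gblupacc as ga
from gblupacc.exceptions import (
    InconsistentInputsError,
    StateFormatError,
    StateIntegrityError,
    ValidationError,
    WrongOperationError,
)
from gblupacc.update import schur_update_parts

from conftest import classic_cqq_for, random_instance


class TestBuildReference:
    def test_single_core_animal_scalar_inverse(self, single_core_state):
        np.testing.assert_allclose(single_core_state.minv, [[0.5]], atol=1e-15)
        assert single_core_state.core_ids == ("a",)
        assert single_core_state.alpha == 1.0

    def test_identity_core_grm(self, params):
        state = ga.build_reference(
            np.eye(6), ga.RecordCounts(np.ones(6, dtype=int)), params
        )
        np.testing.assert_allclose(state.minv, 0.5 * np.eye(6), atol=1e-14)

    def test_minv_times_m_is_identity(self, params):
        g = ga.blend_grm(ga.build_grm(ga.simulate_genotypes(10, 60, seed=1)), 0.95)
        z = ga.RecordCounts(np.full(10, 2, dtype=np.int64))
        state = ga.build_reference(g, z, params)
        m = g.values + np.diag(params.alpha / z.counts)
        np.testing.assert_allclose(state.minv @ m, np.eye(10), atol=1e-12)

    def test_unphenotyped_core_animal_rejected(self, params):
        with pytest.raises(ValidationError, match="phenotyped"):
            ga.build_reference(
                np.eye(3), ga.RecordCounts(np.array([1, 0, 1])), params
            )


class TestQueries:
    def test_phenotyped_query_2x2_closed_form(self, single_core_state):
        ind = ga.NewIndividual("q", g_pq=[0.5], g_qq=1.0, z_qq=1)
        assert ga.cqq_with_phenotype(single_core_state, ind) == pytest.approx(
            7 / 15, abs=1e-15
        )

    def test_unphenotyped_query_2x2_closed_form(self, single_core_state):
        ind = ga.NewIndividual("q", g_pq=[0.5], g_qq=1.0, z_qq=0)
        assert ga.cqq_without_phenotype(single_core_state, ind) == pytest.approx(
            7 / 8, abs=1e-15
        )

    def test_unrelated_animal_reduces_to_single_animal_formula(
        self, single_core_state
    ):
        ind = ga.NewIndividual("q", g_pq=[0.0], g_qq=1.0, z_qq=1)
        assert ga.cqq_with_phenotype(single_core_state, ind) == pytest.approx(0.5)
        ind0 = ga.NewIndividual("q", g_pq=[0.0], g_qq=1.0, z_qq=0)
        state2 = ga.ReferenceState(core_ids=("a",), alpha=2.0,
                                   minv=single_core_state.minv)
        assert ga.cqq_without_phenotype(state2, ind0) == pytest.approx(0.5)
        r = ga.score_new_individual(state2, ind0)
        assert r.reliability == 0.0 and r.accuracy == 0.0

    def test_queries_match_full_inverse_oracle_on_random_core(self):
        gq, state_q, _ = random_instance(seed=12, n_core=50, n_new=1)
        for z_qq in (0, 1, 3):
            ind = ga.NewIndividual(
                "q", g_pq=gq.values[:50, 50], g_qq=gq.values[50, 50], z_qq=z_qq
            )
            got = (
                ga.cqq_with_phenotype(state_q, ind)
                if z_qq
                else ga.cqq_without_phenotype(state_q, ind)
            )
            want = classic_cqq_for(gq, 50, 50, z_qq)
            assert got == pytest.approx(want, abs=1e-12)

    def test_wrong_operation_dispatch_raises(self, single_core_state):
        with pytest.raises(WrongOperationError, match="without"):
            ga.cqq_with_phenotype(
                single_core_state, ga.NewIndividual("q", [0.5], 1.0, 0)
            )
        with pytest.raises(WrongOperationError, match="with"):
            ga.cqq_without_phenotype(
                single_core_state, ga.NewIndividual("q", [0.5], 1.0, 2)
            )

    def test_inconsistent_relationships_raise(self, single_core_state):
        # g_pq far too large for g_qq: augmented G not PD, k <= 0
        with pytest.raises(InconsistentInputsError, match="k ="):
            ga.cqq_without_phenotype(
                single_core_state, ga.NewIndividual("q", [3.0], 1.0, 0)
            )

    def test_score_dispatches_and_applies_henderson(self, single_core_state):
        r0 = ga.score_new_individual(
            single_core_state, ga.NewIndividual("q", [0.5], 1.0, 0)
        )
        assert not r0.phenotyped
        assert r0.reliability == pytest.approx(0.125, abs=1e-14)
        assert r0.accuracy == pytest.approx(0.3535533905932738, abs=1e-12)
        r1 = ga.score_new_individual(
            single_core_state, ga.NewIndividual("q", [0.5], 1.0, 1)
        )
        assert r1.phenotyped
        assert r1.reliability == pytest.approx(1 - 7 / 15, abs=1e-14)


class TestLimitConsistency:
    def test_phenotyped_formula_converges_to_limit_form(self, single_core_state):
        """Evaluating the with-phenotype expression at z = 1e-2, 1e-4, 1e-6
        converges monotonically to the without-phenotype value k/alpha."""
        ind = ga.NewIndividual("q", [0.5], 1.0, 0)
        limit = ga.cqq_without_phenotype(single_core_state, ind)
        parts = schur_update_parts(single_core_state, ind)
        k, alpha = parts.k, single_core_state.alpha
        gaps = [abs(k / (k * z + alpha) - limit) for z in (1e-2, 1e-4, 1e-6)]
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] < 1e-6


class TestUpdateReference:
    def test_2x2_block_update_closed_form(self, single_core_state):
        state = ga.update_reference(
            single_core_state, ga.NewIndividual("b", [0.5], 1.0, 1)
        )
        np.testing.assert_allclose(
            state.minv,
            [[8 / 15, -2 / 15], [-2 / 15, 8 / 15]],
            atol=1e-14,
        )
        assert state.core_ids == ("a", "b")

    def test_unrelated_animal_gives_block_diagonal_update(self, single_core_state):
        state = ga.update_reference(
            single_core_state, ga.NewIndividual("b", [0.0], 1.5, 3)
        )
        np.testing.assert_allclose(
            state.minv,
            [[0.5, 0.0], [0.0, 1.0 / (1.5 + 1.0 / 3.0)]],
            atol=1e-14,
        )

    def test_update_then_query_matches_rebuilt_reference(self, params):
        g, state, _ = random_instance(seed=21, n_core=30, n_new=2)
        a = ga.NewIndividual("A", g.values[:30, 30], g.values[30, 30], 1)
        b_gpq = np.append(g.values[:30, 31], g.values[30, 31])
        grown = ga.update_reference(state, a)
        rebuilt = ga.build_reference(
            g.values[:31, :31],
            ga.RecordCounts(np.ones(31, dtype=int)),
            params,
            ids=g.ids[:31],
        )
        np.testing.assert_allclose(grown.minv, rebuilt.minv, atol=1e-10)
        b = ga.NewIndividual("B", b_gpq, g.values[31, 31], 0)
        assert ga.cqq_without_phenotype(grown, b) == pytest.approx(
            ga.cqq_without_phenotype(rebuilt, b), abs=1e-12
        )

    def test_unphenotyped_or_duplicate_additions_rejected(self, single_core_state):
        with pytest.raises(ValidationError, match="phenotype"):
            ga.update_reference(
                single_core_state, ga.NewIndividual("b", [0.5], 1.0, 0)
            )
        with pytest.raises(ValidationError, match="already"):
            ga.update_reference(
                single_core_state, ga.NewIndividual("a", [0.5], 1.0, 1)
            )

    def test_minv_stays_symmetric_and_pd_through_updates(self):
        g, state, _ = random_instance(seed=33, n_core=10, n_new=15)
        for j in range(15):
            q = 10 + j
            ind = ga.NewIndividual(
                g.ids[q], g.values[:10 + j, q], g.values[q, q], 1
            )
            state = ga.update_reference(state, ind)
            assert np.array_equal(state.minv, state.minv.T)
            assert np.linalg.eigvalsh(state.minv).min() > 0


class TestPersistence:
    def make_state(self, single_core_state):
        return ga.update_reference(
            single_core_state, ga.NewIndividual("b", [0.5], 1.0, 1)
        )

    @pytest.mark.parametrize("compress", [False, True])
    def test_round_trip_is_bit_exact(self, single_core_state, tmp_path, compress):
        state = self.make_state(single_core_state)
        path = tmp_path / "ref.minv"
        ga.save_state(state, path, compress=compress)
        loaded = ga.load_state(path)
        assert loaded.core_ids == state.core_ids
        assert loaded.alpha == state.alpha
        assert np.array_equal(loaded.minv, state.minv)
        np.testing.assert_array_equal(loaded.core_grm_diag, state.core_grm_diag)

    def test_wrong_magic_bytes_rejected(self, tmp_path):
        path = tmp_path / "bad.minv"
        path.write_bytes(b"NOPE" + b"\x00" * 64)
        with pytest.raises(StateFormatError, match="magic"):
            ga.load_state(path)

    def test_truncated_file_rejected(self, single_core_state, tmp_path):
        state = self.make_state(single_core_state)
        path = tmp_path / "ref.minv"
        ga.save_state(state, path)
        data = path.read_bytes()
        path.write_bytes(data[: len(data) - 10])
        with pytest.raises(StateIntegrityError):
            ga.load_state(path)

    def test_corrupted_payload_fails_checksum(self, single_core_state, tmp_path):
        state = self.make_state(single_core_state)
        path = tmp_path / "ref.minv"
        ga.save_state(state, path)
        data = bytearray(path.read_bytes())
        data[-20] ^= 0xFF  # flip a bit inside the matrix payload
        path.write_bytes(bytes(data))
        with pytest.raises(StateIntegrityError, match="checksum"):
            ga.load_state(path)

    def test_save_grow_save_yields_larger_readable_file(
        self, single_core_state, tmp_path
    ):
        p1, p2 = tmp_path / "a.minv", tmp_path / "b.minv"
        ga.save_state(single_core_state, p1)
        grown = self.make_state(single_core_state)
        ga.save_state(grown, p2)
        assert ga.load_state(p1).n_core + 1 == ga.load_state(p2).n_core
        assert p2.stat().st_size > p1.stat().st_size
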