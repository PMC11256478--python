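"""Dummy-progeny designs and the relationship block R = 2 P1' diag(F_d) P2."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pedkin import (
    DummyDesign,
    RawPedigree,
    assemble_R_from_Fd,
    calc_relationships,
    compute_inbreeding,
    make_dummies,
    order_and_recode,
    tabular_A,
)
from pedkin.errors import AlignmentError, DisjointnessError, RoleError, UnknownCodeError

from conftest import random_pedigree, role_valid_sets


class TestMakeDummies:
    def test_six_animal_dummy_parentage(self, six_ped):
        ext, design = make_dummies(six_ped, [1, 4], [3, 6])
        # dummies 7-10: sired by 1,1,4,4 with dams 3,6,3,6
        assert ext.n == 10
        assert ext.sire[6:].tolist() == [1, 1, 4, 4]
        assert ext.dam[6:].tolist() == [3, 6, 3, 6]
        assert np.array_equal(ext.sire[:6], six_ped.sire)
        assert np.array_equal(ext.dam[:6], six_ped.dam)

    def test_six_animal_incidence_matrices(self, six_ped):
        _, design = make_dummies(six_ped, [1, 4], [3, 6])
        P1t = design.P1().toarray().T
        P2 = design.P2().toarray()
        assert P1t.tolist() == [[1, 1, 0, 0], [0, 0, 1, 1]]
        assert P2.tolist() == [[1, 0], [0, 1], [1, 0], [0, 1]]

    def test_incidence_rows_sum_to_one(self, six_ped):
        _, design = make_dummies(six_ped, [1, 4], [3, 6])
        assert np.all(design.P1().sum(axis=1) == 1)
        assert np.all(design.P2().sum(axis=1) == 1)

    def test_overlapping_sets_rejected(self, six_ped):
        with pytest.raises(DisjointnessError):
            make_dummies(six_ped, [1], [1])

    def test_duplicate_ids_within_set_rejected(self, six_ped):
        with pytest.raises(DisjointnessError):
            make_dummies(six_ped, [1, 1], [3])

    def test_empty_set_rejected(self, six_ped):
        with pytest.raises(DisjointnessError):
            make_dummies(six_ped, [], [3])

    def test_unknown_code_rejected(self, six_ped):
        with pytest.raises(UnknownCodeError):
            make_dummies(six_ped, [1], [99])

    def test_notdam_notsire_role_violations_named(self, six_ped):
        with pytest.raises(RoleError, match="3"):
            make_dummies(six_ped, [3], [6])  # 3 is a dam, not allowed in set1
        with pytest.raises(RoleError, match="5"):
            make_dummies(six_ped, [1], [5])  # 5 is a sire, not allowed in set2

    def test_sire_sire_and_dam_dam_types(self, six_ped):
        _, d1 = make_dummies(six_ped, [1], [4, 5], rel_type="sire-sire")
        assert d1.n_pairs == 2
        _, d2 = make_dummies(six_ped, [2], [3], rel_type="dam-dam")
        assert d2.n_pairs == 1
        with pytest.raises(RoleError):
            make_dummies(six_ped, [1], [6], rel_type="sire-sire")  # 6 never a sire


class TestAssembleR:
    def test_worked_example_direct_fill(self, six_ped):
        _, design = make_dummies(six_ped, [1, 4], [3, 6])
        F_d = np.array([1 / 4, 1 / 8, 1 / 8, 5 / 32])
        block = assemble_R_from_Fd(design, F_d)
        assert block.R.tolist() == [[0.5, 0.25], [0.25, 0.3125]]

    def test_all_zero_and_scalar_cases(self, six_ped):
        _, design = make_dummies(six_ped, [1, 4], [3, 6])
        assert np.all(assemble_R_from_Fd(design, np.zeros(4)).R == 0)
        scalar = DummyDesign(set1=np.array([1]), set2=np.array([2]))
        assert assemble_R_from_Fd(scalar, np.array([0.3])).R.tolist() == [[0.6]]

    def test_length_mismatch_rejected(self, six_ped):
        _, design = make_dummies(six_ped, [1, 4], [3, 6])
        with pytest.raises(AlignmentError):
            assemble_R_from_Fd(design, np.zeros(3))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 100_000), m=st.integers(1, 8), n=st.integers(1, 8))
    def test_direct_fill_equals_matrix_product(self, seed, m, n):
        """Direct placement reproduces 2 P1' diag(F_d) P2 exactly."""
        rng = np.random.default_rng(seed)
        codes = rng.choice(np.arange(1, 100), size=m + n, replace=False)
        design = DummyDesign(set1=codes[:m], set2=codes[m:])
        F_d = rng.uniform(0, 0.5, size=m * n)
        block = assemble_R_from_Fd(design, F_d)
        product = 2.0 * (design.P1().T @ np.diag(F_d) @ design.P2())
        assert np.array_equal(block.R, np.asarray(product))


class TestCalcRelationships:
    def test_worked_example_dummy_inbreeding(self, six_ped):
        block = calc_relationships(six_ped, [1, 4], [3, 6])
        assert block.F_d.tolist() == [1 / 4, 1 / 8, 1 / 8, 5 / 32]

    def test_worked_example_relationships(self, six_ped):
        block = calc_relationships(six_ped, [1, 4], [3, 6])
        assert block.R.tolist() == [[0.5, 0.25], [0.25, 0.3125]]

    def test_unrelated_founders_zero(self):
        ped = order_and_recode(RawPedigree([("A", "0", "0"), ("B", "0", "0")]))
        block = calc_relationships(ped, [1], [2])
        assert block.R.tolist() == [[0.0]]

    def test_results_unchanged_by_prefixes(self, six_ped):
        base = compute_inbreeding(six_ped)
        plain = calc_relationships(six_ped, [1, 4], [3, 6])
        with_f = calc_relationships(six_ped, [1, 4], [3, 6], f_prefix=base.f)
        with_fd = calc_relationships(
            six_ped, [1, 4], [3, 6], f_prefix=base.f, d_prefix=base.d
        )
        assert np.array_equal(plain.F_d, with_f.F_d)
        assert np.array_equal(plain.F_d, with_fd.F_d)

    def test_real_progeny_consistency(self, six_ped):
        """For a pair with a real progeny, R equals twice that progeny's F."""
        # 5 is the real progeny of sire 4 and dam 3
        f5 = compute_inbreeding(six_ped).f[4]
        block = calc_relationships(six_ped, [4], [3])
        assert block.R[0, 0] == 2 * f5

    def test_symmetry_under_set_swap(self):
        """Swapping set1 and set2 (same-sex query) transposes R exactly."""
        from pedkin import classify_sex_roles

        checked = 0
        for seed in range(12):
            ped = random_pedigree(seed, max_n=100)
            rng = np.random.default_rng(seed + 500)
            sires, _, _ = classify_sex_roles(ped)
            pool = np.array(sorted(sires), dtype=np.int64)
            if pool.size < 6:
                continue
            picked = rng.choice(pool, size=6, replace=False)
            s1, s2 = picked[:3].tolist(), picked[3:].tolist()
            fwd = calc_relationships(ped, s1, s2, rel_type="sire-sire")
            rev = calc_relationships(ped, s2, s1, rel_type="sire-sire")
            assert np.array_equal(fwd.R, rev.R.T)
            checked += 1
        assert checked >= 3

    def test_dummies_do_not_alter_real_inbreeding(self, six_ped):
        ext, _ = make_dummies(six_ped, [1, 4], [3, 6])
        real = compute_inbreeding(six_ped)
        extended = compute_inbreeding(ext)
        assert np.array_equal(extended.f[:6], real.f)
        assert np.array_equal(extended.d[:6], real.d)

    def test_batched_equals_monolithic_bitwise(self):
        """Pair-kernel batches reproduce the full extended-pedigree run bitwise."""
        ped = random_pedigree(11, max_n=150)
        rng = np.random.default_rng(11)
        sets = role_valid_sets(ped, rng, 4, 5)
        assert sets is not None
        s1, s2 = sets
        ext, design = make_dummies(ped, s1, s2)
        monolithic = compute_inbreeding(ext).f[ped.n :]
        for batch_size in (1, 3, design.n_pairs):
            block = calc_relationships(ped, s1, s2, batch_size=batch_size)
            assert np.array_equal(block.F_d, monolithic)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_block_matches_tabular_oracle(self, seed):
        """R equals the corresponding off-diagonal block of A."""
        ped = random_pedigree(seed, max_n=120)
        rng = np.random.default_rng(seed)
        sets = role_valid_sets(ped, rng, 3, 4)
        if sets is None:
            return
        s1, s2 = sets
        block = calc_relationships(ped, s1, s2)
        A = tabular_A(ped).A
        expected = A[np.ix_(s1 - 1, s2 - 1)]
        assert np.max(np.abs(block.R - expected)) < 1e-12
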