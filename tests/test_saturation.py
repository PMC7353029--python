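from itertools import combinations
from math import comb

import numpy as np
import pytest

from conftest import make_matrix, random_matrix
from truncalis.saturation import (
    avg_ppv,
    avg_ptv,
    avg_unique,
    friedman_load_test,
    increment_stats,
    min_samples_required,
    saturation_profile,
)


# --- independent oracles -----------------------------------------------------
# avg_unique / avg_ptv via per-variant combinatorial counting: a variant
# present in m of b biopsies contributes C(m,k)/C(b,k) to avg_ptv and
# 1 - C(b-m,k)/C(b,k) to avg_unique. PPV via an independent frozenset
# enumeration (no shared code with the implementation).


def oracle_avg_unique(matrix, k):
    b = matrix.n_biopsies
    return sum(
        1 - comb(b - int(m), k) / comb(b, k) for m in matrix.presence.sum(axis=1)
    )


def oracle_avg_ptv(matrix, k):
    b = matrix.n_biopsies
    return sum(comb(int(m), k) / comb(b, k) for m in matrix.presence.sum(axis=1))


def oracle_avg_ppv(matrix, k):
    memberships = [
        frozenset(j for j in range(matrix.n_biopsies) if matrix.presence[i, j])
        for i in range(matrix.n_variants)
    ]
    c = sum(1 for s in memberships if len(s) == matrix.n_biopsies)
    terms = []
    for subset in combinations(range(matrix.n_biopsies), k):
        chosen = set(subset)
        ptv = sum(1 for s in memberships if chosen <= s)
        if ptv > 0:
            terms.append(c / ptv)
    return float(np.mean(terms)) if terms else float("nan")


class TestF1HandValues:
    def test_avg_unique(self, f1_matrix):
        expected = {1: 2.0, 2: 2.5, 3: 2.75, 4: 3.0}
        for k, value in expected.items():
            assert avg_unique(f1_matrix, k)[0] == pytest.approx(value)

    def test_avg_ptv(self, f1_matrix):
        expected = {1: 2.0, 2: 1.5, 3: 1.25, 4: 1.0}
        for k, value in expected.items():
            assert avg_ptv(f1_matrix, k)[0] == pytest.approx(value)

    def test_avg_ppv(self, f1_matrix):
        expected = {1: (1 / 3 + 1 / 2 + 1 / 2 + 1) / 4, 2: 0.75, 3: 0.875, 4: 1.0}
        for k, value in expected.items():
            mean, _, excluded = avg_ppv(f1_matrix, k)
            assert mean == pytest.approx(value)
            assert excluded == 0

    def test_k_out_of_range(self, f1_matrix):
        with pytest.raises(ValueError):
            avg_unique(f1_matrix, 0)
        with pytest.raises(ValueError):
            avg_unique(f1_matrix, 5)

    def test_per_subset_values_returned(self, f1_matrix):
        _, uniques = avg_unique(f1_matrix, 2)
        assert sorted(uniques.tolist()) == [2, 2, 2, 3, 3, 3]
        _, ptvs = avg_ptv(f1_matrix, 2)
        assert sorted(ptvs.tolist()) == [1, 1, 1, 2, 2, 2]


class TestOracleEquivalence:
    def test_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            m = random_matrix(rng)
            for k in range(1, m.n_biopsies + 1):
                assert avg_unique(m, k)[0] == pytest.approx(
                    oracle_avg_unique(m, k), abs=1e-12
                )
                assert avg_ptv(m, k)[0] == pytest.approx(
                    oracle_avg_ptv(m, k), abs=1e-12
                )
                got = avg_ppv(m, k)[0]
                want = oracle_avg_ppv(m, k)
                if np.isnan(want):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(want, abs=1e-12)

    def test_monotonicity_and_bounds(self):
        rng = np.random.default_rng(43)
        for _ in range(40):
            m = random_matrix(rng)
            profile = saturation_profile(m)
            ks = sorted(profile.avg_unique)
            uq = [profile.avg_unique[k] for k in ks]
            pt = [profile.avg_ptv[k] for k in ks]
            assert all(a <= b + 1e-12 for a, b in zip(uq, uq[1:]))
            assert all(a >= b - 1e-12 for a, b in zip(pt, pt[1:]))
            c = int(m.presence.all(axis=1).sum())
            for k in ks:
                ppv = profile.avg_ppv[k]
                if not np.isnan(ppv):
                    assert ppv <= 1 + 1e-12
            if c > 0:
                assert profile.avg_ppv[m.n_biopsies] == pytest.approx(1.0)
            # k=1: unique == ptv == mean per-biopsy count
            assert profile.avg_unique[1] == pytest.approx(profile.avg_ptv[1])
            assert profile.avg_unique[1] == pytest.approx(
                m.column_counts().mean()
            )

    def test_truncal_subset_of_any_intersection(self):
        rng = np.random.default_rng(44)
        for _ in range(20):
            m = random_matrix(rng)
            c = int(m.presence.all(axis=1).sum())
            for k in range(1, m.n_biopsies + 1):
                _, ptvs = avg_ptv(m, k)
                assert (ptvs >= c).all()


class TestNoTruncalExclusion:
    def test_all_terms_excluded_when_no_variants_in_subset(self):
        # v1 only in B1, v2 only in B2: the {B3} subset has PTV 0
        m = make_matrix([[1, 0, 0], [0, 1, 0], [0, 0, 1]])
        mean, terms, excluded = avg_ppv(m, 1)
        assert excluded == 0  # each singleton subset holds one variant
        m2 = make_matrix([[1, 0, 0], [0, 1, 0]])
        mean2, _, excluded2 = avg_ppv(m2, 1)
        assert excluded2 == 1  # B3 carries nothing
        assert mean2 == pytest.approx(0.0)  # C=0 over non-empty subsets

    def test_zero_truncal_gives_zero_ppv_not_nan(self):
        m = make_matrix([[1, 1, 0], [0, 1, 1]])
        mean, _, excluded = avg_ppv(m, 2)
        assert mean == pytest.approx(0.0)


class TestIncrementStats:
    def test_f1_unique_deltas(self, f1_matrix):
        stats = increment_stats([saturation_profile(f1_matrix)])
        per = stats["per_patient"]
        deltas = per.sort_values("k")["delta_unique"].tolist()
        assert deltas == pytest.approx([0.5, 0.25, 0.25])
        assert stats["pooled"]["unique_mean"] == pytest.approx(1 / 3)

    def test_all_truncal_zero_deltas(self):
        m = make_matrix(np.ones((5, 4)))
        stats = increment_stats([saturation_profile(m)])
        assert stats["pooled"]["unique_mean"] == 0.0
        assert stats["pooled"]["ptv_drop_mean"] == 0.0

    def test_identical_patients_zero_sd(self, f1_matrix):
        p1 = saturation_profile(f1_matrix)
        m2 = make_matrix(f1_matrix.presence, patient_id="P2")
        p2 = saturation_profile(m2)
        stats = increment_stats([p1, p2])
        per_step = stats["per_step"]
        assert (per_step[("delta_unique", "sd")] == 0).all()

    def test_first_step_ptv_drop_reported(self, f1_matrix):
        stats = increment_stats([saturation_profile(f1_matrix)])
        assert stats["first_step_ptv_drop"]["mean"] == pytest.approx(0.5)


class TestMinSamplesRequired:
    @staticmethod
    def _constant_after_2_profiles(n=8):
        # truncal + private variants only: PTV(k) = n_truncal for every
        # k >= 2, but PTV(1) = n_truncal + n_private/4 > PTV(2)
        rng = np.random.default_rng(0)
        profiles = []
        for i in range(n):
            n_truncal = int(rng.integers(5, 10))
            n_private = int(rng.integers(4, 9))
            presence = np.zeros((n_truncal + n_private, 4), bool)
            presence[:n_truncal] = True
            for r in range(n_truncal, n_truncal + n_private):
                presence[r, rng.integers(0, 4)] = True
            profiles.append(
                saturation_profile(make_matrix(presence, patient_id=f"P{i}"))
            )
        return profiles

    def test_constant_from_two_returns_two(self):
        profiles = self._constant_after_2_profiles()
        k, within = min_samples_required(profiles, alpha=0.05, statistic="ptv")
        assert within
        assert k == 2

    def test_large_drops_every_step_returns_b_flagged(self):
        rng = np.random.default_rng(123)
        profiles = []
        for i in range(20):
            m = random_matrix(rng, max_biopsies=4, max_variants=50, patient_id=f"P{i}")
            while m.n_biopsies != 4 or m.n_variants < 20:
                m = random_matrix(rng, max_biopsies=4, max_variants=50, patient_id=f"P{i}")
            profiles.append(saturation_profile(m))
        k, within = min_samples_required(profiles, alpha=0.05, statistic="unique")
        assert not within
        assert k == 4

    def test_alpha_one_returns_one(self):
        profiles = self._constant_after_2_profiles()
        k, within = min_samples_required(profiles, alpha=1.0)
        assert (k, within) == (1, True)

    def test_fewer_than_two_patients_error(self, f1_matrix):
        with pytest.raises(ValueError):
            min_samples_required([saturation_profile(f1_matrix)])


class TestFriedman:
    def test_identical_columns_p_one(self):
        loads = np.tile([[10], [12], [9], [15]], (1, 4))
        assert friedman_load_test(loads) == 1.0

    def test_inflated_biopsy_significant(self):
        rng = np.random.default_rng(77)
        base = rng.normal(100, 5, size=(20, 4))
        base[:, 2] += 25  # one biopsy systematically inflated by 5 sd
        assert friedman_load_test(base) < 0.05

    def test_null_data_not_significant(self):
        rng = np.random.default_rng(78)
        base = rng.normal(100, 5, size=(20, 4))
        assert friedman_load_test(base) > 0.05

    def test_two_patients_error(self):
        with pytest.raises(ValueError):
            friedman_load_test(np.ones((2, 4)))
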