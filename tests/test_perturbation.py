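"""Tests of stratification, DE gates, the rewiring score and permutation p."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from lncperturb.candidates import TripletCandidate
from lncperturb.exceptions import DataError, DomainError
from lncperturb.perturbation import (
    DetectionParams,
    detect_triplets,
    fisher_z,
    group_de_gate,
    permutation_pvalue,
    results_to_frame,
    rewiring_score,
    split_groups,
    triplet_seed,
)

from conftest import make_layer


def series(values, prefix="S"):
    return pd.Series(
        np.asarray(values, dtype=float),
        index=[f"{prefix}{i + 1:03d}" for i in range(len(values))],
    )


class TestSplitGroups:
    def test_quartile_sizes(self):
        split = split_groups(series(range(40)))
        assert split.n_high == split.n_low == 10

    def test_floor_rule(self):
        split = split_groups(series(range(401)))
        assert split.n_high == split.n_low == 100

    def test_ordering_and_disjointness(self):
        vals = series(range(20))
        split = split_groups(vals)
        assert set(split.h_samples).isdisjoint(split.l_samples)
        assert min(vals[split.h_samples]) > max(vals[split.l_samples])

    def test_all_equal_warns_and_uses_id_tiebreak(self):
        vals = series([5.0] * 20)
        with pytest.warns(UserWarning, match="tie-break"):
            split = split_groups(vals, lnc_id="lncX")
        assert split.h_samples == sorted(vals.index)[:5]
        assert split.l_samples == sorted(vals.index)[-5:]

    def test_too_few_samples(self):
        with pytest.raises(DataError):
            split_groups(series(range(15)))


class TestGroupDEGate:
    def _split(self, n=16):
        lnc = series(range(n, 0, -1))
        return split_groups(lnc)

    def test_clear_up_in_h_passes_with_fc3(self):
        split = self._split()
        # H linear means 30, L linear means 10 -> fc = 3 (tiny jitter for the t-test)
        vals = np.full(16, np.log2(20 + 1))
        vals[:4] = np.log2(np.array([29, 31, 30.5, 29.5]) + 1)
        vals[-4:] = np.log2(np.array([9, 11, 10.5, 9.5]) + 1)
        res = group_de_gate(series(vals), split, "up_in_H")
        assert res.passed
        assert res.fc == pytest.approx(3.0, rel=0.01)

    def test_identical_distributions_fail(self):
        split = self._split()
        vals = series(list(range(16)))
        shuffled = pd.Series(
            np.resize([2.0, 3.0, 2.5, 3.5], 16), index=vals.index
        )
        assert not group_de_gate(shuffled, split, "up_in_H").passed

    def test_exact_fold_change_boundary_fails(self):
        split = self._split()
        # H linear {2,2,4,4} mean 3; L linear {1,1,3,3} mean 2 -> fc exactly 1.5
        vals = np.full(16, 1.0)
        vals[:4] = np.log2(np.array([2, 2, 4, 4]) + 1)
        vals[-4:] = np.log2(np.array([1, 1, 3, 3]) + 1)
        res = group_de_gate(series(vals), split, "up_in_H")
        assert res.fc == pytest.approx(1.5, abs=1e-12)
        assert not res.passed

    def test_direction_orientation(self):
        split = self._split()
        vals = np.full(16, np.log2(21.0))
        vals[:4] = np.log2(np.array([5, 5.2, 4.8, 5.1]))  # low in H
        vals[-4:] = np.log2(np.array([30, 31, 29, 30.5]))  # high in L
        down = group_de_gate(series(vals), split, "down_in_H")
        up = group_de_gate(series(vals), split, "up_in_H")
        assert down.passed and down.fc > 1.5
        assert not up.passed and up.fc < 1

    def test_zero_variance_both_groups_warns(self):
        split = self._split()
        with pytest.warns(UserWarning, match="zero variance"):
            res = group_de_gate(series([2.0] * 16), split, "up_in_H")
        assert not res.passed and math.isnan(res.p)


class TestFisherZ:
    def test_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_half_ln_three(self):
        assert fisher_z(0.5) == pytest.approx(0.5 * math.log(3), abs=1e-12)

    @given(st.floats(-0.999, 0.999))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_odd_symmetry(self, r):
        assert fisher_z(-r) == pytest.approx(-fisher_z(r), abs=1e-12)

    def test_domain_error_and_clip(self):
        with pytest.raises(DomainError):
            fisher_z(1.0)
        assert fisher_z(1.0, clip=True) == pytest.approx(math.atanh(1 - 1e-12))


class TestRewiringScore:
    def test_symmetric_point_is_half(self):
        assert rewiring_score(-0.5, -0.5, 30, 30) == pytest.approx(0.5)
        assert rewiring_score(-0.5, -0.5, 30, 30, "literal") == pytest.approx(0.5)

    def test_worked_example_against_normal_cdf(self):
        # Z = (F(0) - F(-0.8)) / sqrt(2/25) = 1.098612 / 0.282843 = 3.8842
        score = rewiring_score(-0.8, 0.0, 28, 28)
        z = (math.atanh(0.0) - math.atanh(-0.8)) / math.sqrt(2 / 25)
        assert z == pytest.approx(3.8842, abs=1e-4)
        assert score == pytest.approx(stats.norm.cdf(z), abs=1e-12)
        assert score == pytest.approx(0.99995, abs=5e-6)

    def test_literal_is_complement(self):
        a = rewiring_score(-0.8, 0.0, 28, 28, "corrected")
        b = rewiring_score(-0.8, 0.0, 28, 28, "literal")
        assert a + b == pytest.approx(1.0, abs=1e-12)
        assert b == pytest.approx(5.1e-5, rel=0.05)

    def test_monotone_in_delta(self):
        scores = [rewiring_score(-0.8, r, 30, 30) for r in (-0.6, -0.2, 0.2, 0.6)]
        assert all(a < b for a, b in zip(scores, scores[1:]))

    def test_monotone_in_group_size(self):
        scores = [rewiring_score(-0.8, 0.0, n, n) for n in (8, 16, 32, 64)]
        assert all(a < b for a, b in zip(scores, scores[1:]))

    def test_small_groups_rejected(self):
        with pytest.raises(DomainError):
            rewiring_score(-0.5, 0.0, 3, 30)


class TestPermutationPvalue:
    def test_observed_one_gives_zero(self):
        rng = np.random.default_rng(0)
        p, n_exceed = permutation_pvalue(
            rng.uniform(0, 5, 100), rng.uniform(0, 5, 100), 1.0, seed=1
        )
        assert p == 0.0 and n_exceed == 0

    def test_observed_zero_gives_one_with_continuous_data(self):
        rng = np.random.default_rng(0)
        p, _ = permutation_pvalue(
            rng.uniform(0, 5, 100), rng.uniform(0, 5, 100), 0.0, seed=1
        )
        assert p == 1.0

    def test_deterministic_per_seed(self):
        rng = np.random.default_rng(3)
        mir, mrna = rng.uniform(0, 5, 80), rng.uniform(0, 5, 80)
        a = permutation_pvalue(mir, mrna, 0.7, seed=42)
        b = permutation_pvalue(mir, mrna, 0.7, seed=42)
        assert a == b

    def test_add_one_estimator(self):
        rng = np.random.default_rng(0)
        mir, mrna = rng.uniform(0, 5, 80), rng.uniform(0, 5, 80)
        p, n_exceed = permutation_pvalue(mir, mrna, 1.0, m=100, seed=5, add_one=True)
        assert p == pytest.approx((n_exceed + 1) / 101)


def planted_series(n=200, seed=0):
    """lnc/mir/mrna with strong low-group coupling released at high lnc."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    lnc = 5 + z
    mir = np.clip(5 - 0.4 * z + 0.9 * rng.standard_normal(n), 0, None)
    q = np.argsort(np.argsort(lnc)) / (n - 1)
    c = -0.9 + q * 0.9
    mrna = np.clip(9.5 + c * mir + 0.3 * rng.standard_normal(n), 0, None)
    return lnc, mir, mrna


class TestDetectTriplets:
    def _setup(self, seed=0):
        lnc, mir, mrna = planted_series(seed=seed)
        layers = (
            make_layer([np.clip(lnc, 0, None)], "lncRNA", genes=["l1"]),
            make_layer([mir], "miRNA", genes=["m1"]),
            make_layer([mrna], "mRNA", genes=["r1"]),
        )
        cand = TripletCandidate("l1", "m1", "r1", 1, 1, 1, 10, 1e-4, 1e-3)
        return cand, layers

    def test_planted_triplet_passes(self):
        cand, layers = self._setup()
        [res] = detect_triplets([cand], *layers)
        assert res.passed
        assert res.r_low < -0.4
        assert res.r_high - res.r_low > 0.3
        assert res.p_perm < 0.01

    def test_flat_rewiring_fails_delta_gate(self):
        """A pair equally coupled in both strata fails |dR| > 0.3 even with
        a strongly negative Rlow."""
        rng = np.random.default_rng(1)
        n = 160
        lnc = np.clip(5 + rng.standard_normal(n), 0, None)
        mir = np.clip(5 - 0.4 * (lnc - 5) + 0.9 * rng.standard_normal(n), 0, None)
        mrna = np.clip(9.5 - 0.9 * mir + 0.5 * rng.standard_normal(n), 0, None)
        layers = (
            make_layer([lnc], "lncRNA", genes=["l1"]),
            make_layer([mir], "miRNA", genes=["m1"]),
            make_layer([mrna], "mRNA", genes=["r1"]),
        )
        cand = TripletCandidate("l1", "m1", "r1", 1, 1, 1, 10, 1e-4, 1e-3)
        [res] = detect_triplets([cand], *layers)
        assert res.r_low < -0.4
        assert abs(res.r_low - res.r_high) < 0.3 or not res.passed
        assert not res.passed

    def test_failed_de_gate_excludes_triplet(self):
        cand, layers = self._setup()
        # make the miRNA independent of the lncRNA: DE gate must fail
        rng = np.random.default_rng(2)
        flat_mir = make_layer(
            [rng.uniform(4, 6, layers[1].n_samples)], "miRNA", genes=["m1"]
        )
        [res] = detect_triplets([cand], layers[0], flat_mir, layers[2])
        assert not res.de_pass_mir
        assert not res.passed

    def test_deterministic_and_order_independent(self):
        cand_a = TripletCandidate("l1", "m1", "r1", 1, 1, 1, 10, 1e-4, 1e-3)
        first = planted_series(seed=3)
        second = planted_series(seed=4)
        layers = (
            make_layer([np.clip(first[0], 0, None), np.clip(second[0], 0, None)],
                       "lncRNA", genes=["l1", "l2"]),
            make_layer([first[1], second[1]], "miRNA", genes=["m1", "m2"]),
            make_layer([first[2], second[2]], "mRNA", genes=["r1", "r2"]),
        )
        cand_b = TripletCandidate("l2", "m2", "r2", 1, 1, 1, 10, 1e-4, 1e-3)
        params = DetectionParams(seed=99)
        fwd = detect_triplets([cand_a, cand_b], *layers, params)
        rev = detect_triplets([cand_b, cand_a], *layers, params)
        frame_fwd = results_to_frame(fwd).sort_values("lnc_id", ignore_index=True)
        frame_rev = results_to_frame(rev).sort_values("lnc_id", ignore_index=True)
        pd.testing.assert_frame_equal(frame_fwd, frame_rev)

    def test_triplet_seed_stable(self):
        assert triplet_seed(1, "a", "b", "c") == triplet_seed(1, "a", "b", "c")
        assert triplet_seed(1, "a", "b", "c") != triplet_seed(2, "a", "b", "c")
        assert 0 <= triplet_seed(123, "x", "y", "z") < 2**31
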