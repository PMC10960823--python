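import numpy as np
import pytest

import wetmap as wm
from wetmap.assessment import (ErrorMatrix, SamplingDesign, accuracy_metrics,
                               allocate_sample_size, build_error_matrix,
                               load_error_matrix_2020,
                               load_validation_design_2020)

from oracles import brute_confusion_metrics


class TestSampleSize:
    def test_single_stratum_closed_form(self):
        al = allocate_sample_size(SamplingDesign(W=(1.0,), p=(0.5,),
                                                 d=0.05, t=1.96))
        assert al.n_real == pytest.approx(0.25 / (0.05 / 1.96) ** 2, rel=1e-12)
        assert al.n_real == pytest.approx(384.16, abs=0.01)

    def test_two_strata_example(self):
        al = allocate_sample_size(SamplingDesign(W=(0.8, 0.2), p=(0.9, 0.7),
                                                 d=0.01, t=1.96))
        assert al.n == pytest.approx(4225, abs=1)
        assert sum(al.n_i) == al.n

    def test_equal_strata_equal_allocation(self):
        al = allocate_sample_size(SamplingDesign(W=(0.5, 0.5), p=(0.8, 0.8),
                                                 d=0.02))
        # symmetric strata split the integer total as evenly as possible
        assert abs(al.n_i[0] - al.n_i[1]) <= 1
        assert sum(al.n_i) == al.n

    def test_monotone_in_half_width_and_confidence(self):
        base = dict(W=(0.6, 0.4), p=(0.9, 0.7))
        n_wide = allocate_sample_size(SamplingDesign(d=0.05, **base)).n_real
        n_narrow = allocate_sample_size(SamplingDesign(d=0.02, **base)).n_real
        assert n_narrow > n_wide
        n_95 = allocate_sample_size(SamplingDesign(d=0.02, t=1.96, **base)).n_real
        n_975 = allocate_sample_size(SamplingDesign(d=0.02, t=2.33, **base)).n_real
        assert n_975 > n_95

    def test_degenerate_accuracies_rejected(self):
        with pytest.raises(ValueError):
            SamplingDesign(W=(1.0,), p=(1.0,))


class TestErrorMatrix:
    def test_perfect_agreement_is_diagonal(self):
        m = build_error_matrix([1, 1, 2, 2], [1, 1, 2, 2])
        assert np.allclose(m.proportions, np.diag([50.0, 50.0]))

    def test_two_class_toy_counts(self):
        ref = ["A"] * 5 + ["B"] * 5
        mp = ["A"] * 4 + ["B"] + ["B"] * 5
        m = build_error_matrix(ref, mp, labels=("A", "B"))
        assert np.allclose(m.proportions, [[40.0, 10.0], [0.0, 50.0]])

    def test_stratified_weighting(self):
        # stratum 0 (weight .9) perfect; stratum 1 (weight .1) all confused
        ref = np.array([1, 1, 2, 2])
        mp = np.array([1, 1, 1, 1])
        strata = np.array([0, 0, 1, 1])
        m = build_error_matrix(ref, mp, labels=(1, 2), strata=strata,
                               stratum_weights={0: 0.9, 1: 0.1})
        assert np.allclose(m.proportions, [[90.0, 0.0], [10.0, 0.0]])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            build_error_matrix([1, 3], [1, 1], labels=(1, 2))

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            ErrorMatrix(labels=(1, 2), proportions=np.array([[60, 0], [0, 50]]))
        with pytest.raises(ValueError):
            ErrorMatrix(labels=(1, 2), proportions=np.array([[-1, 51], [0, 50]]))


class TestMetrics:
    def test_identity_matrix_perfect_scores(self):
        m = ErrorMatrix(labels=tuple("abcd"), proportions=np.diag([25.0] * 4))
        met = accuracy_metrics(m)
        assert met["oa"] == pytest.approx(100.0)
        assert met["kappa"] == pytest.approx(1.0)

    def test_hand_evaluated_kappa(self):
        # proportions {{0.4, 0.1}, {0.2, 0.3}}: OA .7, p_e .5, kappa .4
        m = ErrorMatrix(labels=("w", "d"),
                        proportions=np.array([[40.0, 10.0], [20.0, 30.0]]))
        met = accuracy_metrics(m)
        assert met["oa"] == pytest.approx(70.0)
        assert met["kappa"] == pytest.approx(0.4)

    def test_matches_direct_counting_on_random_labels(self):
        rng = np.random.default_rng(0)
        ref = rng.choice([1, 2, 3], 200)
        mp = rng.choice([1, 2, 3], 200)
        met = accuracy_metrics(build_error_matrix(ref, mp, labels=(1, 2, 3)))
        oa, kappa, pa, ua = brute_confusion_metrics(ref, mp)
        assert met["oa"] == pytest.approx(oa)
        assert met["kappa"] == pytest.approx(kappa)
        for lab in (1, 2, 3):
            assert met["pa"][lab] == pytest.approx(pa[lab])
            assert met["ua"][lab] == pytest.approx(ua[lab])

    def test_empty_row_signalled_not_zeroed(self):
        P = np.array([[50.0, 0.0, 0.0], [50.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        m = ErrorMatrix(labels=(1, 2, 3), proportions=P)
        met = accuracy_metrics(m)
        assert 3 in met["undefined"]
        assert np.isnan(met["pa"][3])

    def test_bounds_and_kappa_below_oa(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            ref = rng.choice([1, 2, 3, 4], 100)
            mp = np.where(rng.random(100) < 0.7, ref, rng.choice([1, 2, 3, 4], 100))
            met = accuracy_metrics(build_error_matrix(ref, mp, labels=(1, 2, 3, 4)))
            assert 0 <= met["oa"] <= 100
            assert met["kappa"] <= met["oa"] / 100 + 1e-12


class TestPackagedFixtures:
    def test_error_matrix_marginals_match_stored_totals(self):
        m = load_error_matrix_2020()
        assert m.proportions.shape == (9, 9)
        np.testing.assert_allclose(m.proportions.sum(axis=1), m.row_totals,
                                   atol=0.002)
        np.testing.assert_allclose(m.proportions.sum(axis=0), m.col_totals,
                                   atol=0.002)
        assert m.proportions.sum() == pytest.approx(100.0, abs=0.05)

    def test_standard_errors_plausible_order(self):
        """SEs computed with the validation stratum sizes land in the same
        order of magnitude as published (tenths of a percent for OA)."""
        m = load_error_matrix_2020()
        design = load_validation_design_2020()
        n = design["total_points"]
        counts = {lab: max(int(round(t / 100 * n)), 2)
                  for lab, t in zip(m.labels, m.col_totals)}
        met = accuracy_metrics(m, stratum_counts=counts)
        assert 0.05 < met["se_oa"] < 1.5
        for lab in m.labels:
            assert 0.01 < met["se_pa"][lab] < 6.0
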