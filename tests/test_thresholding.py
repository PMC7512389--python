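import numpy as np
import pytest

from nlmtdh import (
    DegenerateInputError,
    Histogram2D,
    InfeasibleThresholdError,
    InputError,
    NLMParams,
    ThresholdVector,
    binarize,
    build_joint_histogram,
    class_statistics,
    kl_divergence,
    misclassification_error,
    objective_constant,
    polarity_align,
    relative_entropy_objective,
    segment,
    select_threshold,
)
from oracles import (
    naive_binarize,
    naive_class_stats,
    naive_direct_objective,
    naive_level_entropy_constant,
    naive_offdiag_entropy,
    naive_reduced_objective,
    naive_select_scan,
)


def point_mass_histogram(masses, levels=256):
    p = np.zeros((levels, levels))
    for (i, j), m in masses.items():
        p[i, j] = m
    return Histogram2D(p=p, n_pixels=1000)


class TestClassStatistics:
    def test_single_point_mass_is_infeasible(self):
        h = point_mass_histogram({(10, 10): 1.0})
        st = class_statistics(h, ThresholdVector(20, 20))
        assert st.P0 == pytest.approx(1.0)
        assert st.mu0 == (pytest.approx(10.0), pytest.approx(10.0))
        assert st.P1 == 0.0
        assert not st.feasible

    def test_two_point_masses(self, two_spike_histogram):
        st = class_statistics(two_spike_histogram, ThresholdVector(100, 100))
        assert st.P0 == pytest.approx(0.4)
        assert st.P1 == pytest.approx(0.6)
        assert st.mu0 == (pytest.approx(50.0), pytest.approx(50.0))
        assert st.mu1 == (pytest.approx(200.0), pytest.approx(200.0))
        assert st.feasible

    def test_matches_direct_region_sums(self, random_histogram):
        h = random_histogram(17)
        st = class_statistics(h, ThresholdVector(97, 131))
        P0, P1, mu0, mu1 = naive_class_stats(h.p, 97, 131)
        assert st.P0 == pytest.approx(P0, rel=1e-12)
        assert st.P1 == pytest.approx(P1, rel=1e-12)
        np.testing.assert_allclose(st.mu0, mu0, rtol=1e-10)
        np.testing.assert_allclose(st.mu1, mu1, rtol=1e-10)


class TestObjective:
    def test_infeasible_vector_raises(self):
        h = point_mass_histogram({(10, 10): 1.0})
        with pytest.raises(InfeasibleThresholdError):
            relative_entropy_objective(h, ThresholdVector(20, 20))

    def test_matches_term_by_term_evaluation(self, random_histogram):
        h = random_histogram(17)
        tv = ThresholdVector(97, 131)
        got = relative_entropy_objective(h, tv, form="direct")
        assert got == pytest.approx(naive_direct_objective(h.p, 97, 131), abs=1e-8)
        got_red = relative_entropy_objective(h, tv, form="reduced")
        assert got_red == pytest.approx(naive_reduced_objective(h.p, 97, 131), abs=1e-8)

    def test_reduced_is_direct_plus_offdiagonal_entropy(self, random_histogram):
        """The two objective forms differ by exactly the gray-level entropy
        carried by the off-diagonal quadrants at that threshold vector."""
        h = random_histogram(23)
        g = np.random.default_rng(2)
        for s, t in g.integers(5, 250, (10, 2)):
            tv = ThresholdVector(int(s), int(t))
            direct = relative_entropy_objective(h, tv, form="direct")
            reduced = relative_entropy_objective(h, tv, form="reduced")
            assert reduced - direct == pytest.approx(
                naive_offdiag_entropy(h.p, int(s), int(t)), abs=1e-8
            )

    def test_constant_term_matches_direct_summation(self, random_histogram):
        h = random_histogram(29)
        assert objective_constant(h) == pytest.approx(
            naive_level_entropy_constant(h.p), rel=1e-12
        )

    def test_two_point_classes_reach_zero_within_class_divergence(
        self, two_spike_histogram
    ):
        # each class is a point mass at its own mean: the diagonal-box
        # divergence vanishes and the reduced form hits its floor
        tv = ThresholdVector(100, 100)
        assert relative_entropy_objective(
            two_spike_histogram, tv, form="direct"
        ) == pytest.approx(0.0, abs=1e-10)

    def test_unknown_form_rejected(self, two_spike_histogram):
        with pytest.raises(InputError):
            relative_entropy_objective(
                two_spike_histogram, ThresholdVector(100, 100), form="exotic"
            )


class TestSelectThreshold:
    def test_two_spikes_separated_with_lexicographic_tie_break(
        self, two_spike_histogram
    ):
        tv, obj = select_threshold(two_spike_histogram)
        assert (tv.s, tv.t) == (50, 50)
        assert obj.P0 == pytest.approx(0.4)
        assert obj.mu1 == (pytest.approx(200.0), pytest.approx(200.0))

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_naive_full_scan(self, seed):
        g = np.random.default_rng(seed)
        p = g.random((64, 64))
        p /= p.sum()
        h = Histogram2D(p=p, n_pixels=64 * 64)
        tv, obj = select_threshold(h)
        (s, t), d = naive_select_scan(p)
        assert (tv.s, tv.t) == (s, t)
        assert obj.D == pytest.approx(d, abs=1e-8)

    def test_constant_image_is_degenerate(self):
        img = np.full((8, 8), 77)
        h = build_joint_histogram(img, img)
        with pytest.raises(DegenerateInputError):
            select_threshold(h)

    def test_gray_shift_moves_threshold_with_it(self):
        for c in (0, 17, 40):
            h = point_mass_histogram({(50 + c, 50 + c): 0.4, (200 + c, 200 + c): 0.6})
            tv, _ = select_threshold(h)
            assert (tv.s, tv.t) == (50 + c, 50 + c)

    def test_surface_export(self, tmp_path, two_spike_histogram):
        path = tmp_path / "surface.csv"
        select_threshold(two_spike_histogram, surface_csv=path)
        surface = np.loadtxt(path, delimiter=",")
        assert surface.shape == (256, 256)
        assert np.isinf(surface[0, 0])  # infeasible corner


class TestBinarize:
    def test_all_low_low_pixels_are_background(self):
        img = np.full((4, 4), 30)
        img[0, 0] = 10
        assert not binarize(img, img, ThresholdVector(100, 100)).any()

    def test_two_level_image_recovers_ground_truth(self):
        truth = np.zeros((10, 10), dtype=bool)
        truth[3:7, 2:9] = True
        img = np.where(truth, 200, 50)
        mask = binarize(img, img, ThresholdVector(100, 100))
        np.testing.assert_array_equal(mask, truth)

    def test_mixed_quadrant_pixels_follow_nearest_mean_rule(self, rng):
        a = rng.integers(0, 256, (16, 16))
        b = rng.integers(0, 256, (16, 16))
        tv = ThresholdVector(120, 130)
        got = binarize(a, b, tv)
        want = naive_binarize(a, b, 120, 130, 256)
        np.testing.assert_array_equal(got, want)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InputError):
            binarize(np.zeros((3, 3), int), np.zeros((4, 3), int),
                     ThresholdVector(1, 1))


class TestKLDivergence:
    def test_identical_distributions_have_zero_divergence(self):
        assert kl_divergence([0.5, 0.5], [0.5, 0.5]) == 0.0

    def test_point_mass_against_uniform_is_log_two(self):
        assert kl_divergence([1.0, 0.0], [0.5, 0.5]) == pytest.approx(np.log(2))

    def test_matches_direct_summation(self, rng):
        for _ in range(5):
            p = rng.random(32)
            p /= p.sum()
            q = rng.random(32)
            q /= q.sum()
            want = float(sum(pi * np.log(pi / qi) for pi, qi in zip(p, q) if pi > 0))
            assert kl_divergence(p, q) == pytest.approx(want, abs=1e-12)

    @pytest.mark.parametrize(
        "p,q",
        [
            ([0.5, 0.5], [1.0, 0.0]),        # support violation
            ([0.7, 0.7], [0.5, 0.5]),        # p not normalized
            ([0.5, 0.5], [0.5, 0.5, 0.0]),   # length mismatch
        ],
    )
    def test_invalid_inputs_rejected(self, p, q):
        with pytest.raises(InputError):
            kl_divergence(p, q)


class TestParameterRecovery:
    def test_noisy_two_class_image_recovered(self, noisy_two_class_image):
        """Well-separated two-class scene (contrast 120, noise sigma 10 <=
        contrast/6): the full pipeline should make at most 2% label errors."""
        image, truth = noisy_two_class_image
        result = segment(image, NLMParams(search_radius=5))
        aligned = polarity_align(truth, result.mask)
        assert misclassification_error(truth, aligned) <= 0.02
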