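import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import emgsym as es
from emgsym import Side
from emgsym.model import boxplot_stats
from emgsym.montage import MUSCLE_ORDER
from emgsym.synthetic import TrialSpec, generate_trial


def power_vectors(draw_positive=True):
    return st.lists(
        st.floats(min_value=0.0, max_value=100.0, allow_nan=False),
        min_size=9,
        max_size=9,
    )


class TestRmsPerSecond:
    def test_constant_signal(self):
        out = es.rms_per_second(np.full(5000, 2.5), 1000.0)
        np.testing.assert_allclose(out, 2.5)
        assert out.shape == (5,)

    def test_twenty_second_trial_gives_twenty_windows(self):
        out = es.rms_per_second(np.zeros(20_000), 1000.0)
        assert out.shape == (20,)

    def test_trailing_partial_second_dropped(self):
        out = es.rms_per_second(np.ones(2999), 1000.0)
        assert out.shape == (2,)

    def test_sine_rms_closed_form(self):
        t = np.arange(4000) / 1000.0
        x = np.sin(2 * np.pi * 5.0 * t)  # 5 whole cycles per second
        np.testing.assert_allclose(es.rms_per_second(x, 1000.0), 2 ** -0.5, rtol=1e-3)

    def test_sub_second_segment_rejected(self):
        with pytest.raises(es.LengthError):
            es.rms_per_second(np.ones(500), 1000.0)


class TestTrialPowers:
    def test_side_totals_are_sums(self, make_segment):
        seg = make_segment({"BR_RIGHT": 3.0, "PT_RIGHT": 1.0})
        powers = es.trial_powers(seg)
        assert powers.total_right == pytest.approx(4.0)
        assert powers.total_left == 0.0

    def test_missing_channel_named(self, make_segment):
        seg = make_segment({})
        short = es.TrialSegment(
            motion=seg.motion,
            samples=seg.samples[:-1],
            channels=seg.channels[:-1],
            sample_rate=seg.sample_rate,
            meta=seg.meta,
        )
        with pytest.raises(es.MontageError, match="ES_LEFT"):
            es.trial_powers(short)

    def test_powers_track_programmed_amplitudes(self):
        # generator ground truth: P_i proportional to gain * w_i
        spec = TrialSpec(seed=21, duration_s=10.0)
        env = es.preprocess_trial(generate_trial(spec))
        powers = es.trial_powers(env)
        p = powers.side_vector(Side.RIGHT)
        w = spec.coordination_right
        ratio = p / p.sum()
        np.testing.assert_allclose(ratio, w, atol=0.05 * w.max())

    def test_too_short_after_trim_rejected(self, make_segment):
        seg = make_segment({"B_RIGHT": 1.0}, duration_s=2.5)
        with pytest.raises(es.LengthError):
            es.trial_powers(seg, edge_trim_s=1.0)


class TestCoordinationCoefficients:
    def _powers(self, right, left):
        values = {}
        for m, r, l in zip(MUSCLE_ORDER, right, left):
            values[es.ChannelLabel(m, Side.RIGHT)] = float(r)
            values[es.ChannelLabel(m, Side.LEFT)] = float(l)
        return es.MusclePowers(values)

    def test_equal_powers_give_uniform_shares(self):
        powers = self._powers([2.0] * 9, [5.0] * 9)
        coeffs = es.coordination_coefficients(powers)
        np.testing.assert_allclose(coeffs.a, 1 / 9)
        np.testing.assert_allclose(coeffs.b, 1 / 9)

    def test_single_active_muscle(self):
        powers = self._powers([0, 0, 7, 0, 0, 0, 0, 0, 0], [1] * 9)
        coeffs = es.coordination_coefficients(powers)
        assert coeffs.a[2] == 1.0
        assert coeffs.a.sum() == pytest.approx(1.0, abs=1e-15)

    def test_direct_division(self):
        powers = self._powers([2, 1, 1, 0, 0, 0, 0, 0, 0], [1] * 9)
        coeffs = es.coordination_coefficients(powers)
        np.testing.assert_allclose(coeffs.a[:3], [0.5, 0.25, 0.25])

    def test_zero_side_rejected(self):
        with pytest.raises(es.DegenerateSignalError):
            es.coordination_coefficients(self._powers([1] * 9, [0] * 9))

    @settings(max_examples=100, derandomize=True)
    @given(right=power_vectors(), left=power_vectors())
    def test_normalization_invariant(self, right, left):
        right, left = np.asarray(right) + 1e-6, np.asarray(left) + 1e-6
        coeffs = es.coordination_coefficients(self._powers(right, left))
        assert abs(coeffs.a.sum() - 1.0) < 1e-12
        assert abs(coeffs.b.sum() - 1.0) < 1e-12


class TestEffectiveStrengthBalance:
    @pytest.mark.parametrize(
        "pr, pl, expected",
        [(5.0, 5.0, 0.0), (3.0, 0.0, 1.0), (0.0, 3.0, -1.0), (3.0, 1.0, 0.5)],
    )
    def test_anchor_values(self, pr, pl, expected):
        assert es.effective_strength_balance(pr, pl) == expected

    def test_undefined_when_both_zero(self):
        with pytest.raises(es.UndefinedIndexError):
            es.effective_strength_balance(0.0, 0.0)

    @settings(max_examples=200, derandomize=True)
    @given(
        pr=st.floats(min_value=0.0, max_value=1e6),
        pl=st.floats(min_value=0.0, max_value=1e6),
    )
    def test_bounded_and_antisymmetric(self, pr, pl):
        if pr + pl == 0:
            return
        esb = es.effective_strength_balance(pr, pl)
        assert -1.0 <= esb <= 1.0
        assert es.effective_strength_balance(pl, pr) == -esb


class TestMuscleCoordinationSimilarity:
    def test_identical_vectors_give_one(self):
        a = [0.5, 0.3, 0.2]
        assert es.muscle_coordination_similarity(a, a) == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_example(self):
        # Pearson of the three pairs (0.5,0.2),(0.3,0.3),(0.2,0.5) = -13/14
        value = es.muscle_coordination_similarity([0.5, 0.3, 0.2], [0.2, 0.3, 0.5])
        assert value == pytest.approx(-13 / 14, abs=1e-12)

    def test_affine_invariance(self):
        a = np.array([0.5, 0.3, 0.2, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        b = 0.4 * a + 0.0667
        assert es.muscle_coordination_similarity(a, b) == pytest.approx(1.0, abs=1e-9)

    def test_zero_variance_flagged(self):
        with pytest.raises(es.UndefinedIndexError):
            es.muscle_coordination_similarity([1 / 3] * 3, [0.5, 0.3, 0.2])

    def test_length_mismatch_rejected(self):
        with pytest.raises(es.ParameterError):
            es.muscle_coordination_similarity([0.5, 0.5], [0.2, 0.3, 0.5])

    def test_agrees_with_independent_pearson(self):
        # summation-form implementation vs scipy's product-moment correlation
        rng = np.random.default_rng(42)
        for _ in range(300):
            a = rng.dirichlet(np.ones(9))
            b = rng.dirichlet(np.ones(9))
            ours = es.muscle_coordination_similarity(a, b)
            oracle = sps.pearsonr(a, b).statistic
            assert ours == pytest.approx(oracle, abs=1e-12)

    @settings(max_examples=200, derandomize=True)
    @given(
        data=st.lists(
            st.floats(min_value=0.0, max_value=1.0), min_size=18, max_size=18
        )
    )
    def test_bounded_on_random_vectors(self, data):
        a, b = np.asarray(data[:9]), np.asarray(data[9:])
        if a.sum() == 0 or b.sum() == 0:
            return
        a, b = a / a.sum(), b / b.sum()
        try:
            value = es.muscle_coordination_similarity(a, b)
        except es.UndefinedIndexError:
            return
        assert -1.0 <= value <= 1.0


class TestDissociation:
    """The model's central design: strength and coordination decouple."""

    def _powers(self):
        # dyadic values: scaling by 0.5, 2 or 10 is exact in binary floating
        # point, so the coefficient quotients (and hence MCS) are bitwise equal
        rng = np.random.default_rng(3)
        right = rng.integers(1, 64, 9) / 8.0
        left = rng.integers(1, 64, 9) / 8.0
        return right, left

    def test_side_scaling_moves_esb_not_mcs(self):
        right, left = self._powers()
        base_mcs = es.muscle_coordination_similarity(right / right.sum(), left / left.sum())
        esbs = []
        for k in (0.5, 1.0, 2.0, 10.0):
            scaled = k * left
            esbs.append(es.effective_strength_balance(right.sum(), scaled.sum()))
            mcs = es.muscle_coordination_similarity(
                right / right.sum(), scaled / scaled.sum()
            )
            assert mcs == base_mcs  # bit-identical: coefficients are scale-free
        assert esbs == sorted(esbs, reverse=True)  # growing left power lowers ESB

    def test_permuting_one_side_moves_mcs_not_esb(self):
        right, left = self._powers()
        base_esb = es.effective_strength_balance(right.sum(), left.sum())
        base_mcs = es.muscle_coordination_similarity(right / right.sum(), left / left.sum())
        permuted = np.roll(left, 4)
        assert (
            es.effective_strength_balance(right.sum(), permuted.sum()) == base_esb
        )
        assert (
            es.muscle_coordination_similarity(right / right.sum(), permuted / permuted.sum())
            != base_mcs
        )


class TestTrialIndexes:
    def test_symmetric_trial_near_perfect_mirroring(self):
        esbs, mcss = [], []
        for seed in range(5):
            seg = generate_trial(TrialSpec(seed=seed, mirror_noise=True, duration_s=10.0))
            rec = es.trial_indexes(es.preprocess_trial(seg))
            esbs.append(rec.esb)
            mcss.append(rec.mcs)
        assert abs(np.mean(esbs)) < 0.05
        assert np.mean(mcss) > 0.95

    def test_one_sided_activity_degenerates_cleanly(self, make_segment):
        seg = make_segment({"B_RIGHT": 2.0, "BR_RIGHT": 1.0})
        rec = es.trial_indexes(seg)
        assert rec.esb == 1.0
        assert rec.mcs is None

    def test_silent_trial_rejected(self, make_segment):
        with pytest.raises(es.UndefinedIndexError):
            es.trial_indexes(make_segment({}))

    def test_gain_ratio_maps_to_esb(self):
        g = 2.0
        esbs = [
            es.trial_indexes(
                es.preprocess_trial(generate_trial(TrialSpec(seed=s, gain_right=g, duration_s=10.0)))
            ).esb
            for s in range(5)
        ]
        assert np.mean(esbs) == pytest.approx((g - 1) / (g + 1), abs=0.05)


class TestActivityPrint:
    def test_constant_values_collapse_box(self):
        stats = boxplot_stats([0.1, 0.1, 0.1, 0.1])
        assert stats.median == stats.q1 == stats.q3 == 0.1
        assert stats.outliers == ()

    def test_far_point_is_outlier(self):
        stats = boxplot_stats([1.0, 2.0, 3.0, 100.0])
        # q3 = 27.25, IQR = 25.5 under linear interpolation; 100 > q3 + 1.5 IQR
        assert stats.outliers == (100.0,)
        assert stats.whisker_high == 3.0

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(0, 1, 25)
        assert boxplot_stats(values) == boxplot_stats(values[::-1])

    def _coeff_sets(self, n):
        rng = np.random.default_rng(9)
        return [
            es.CoordinationCoefficients(rng.dirichlet(np.ones(9)), rng.dirichlet(np.ones(9)))
            for _ in range(n)
        ]

    def test_roles_partition_sides(self):
        sets = self._coeff_sets(6)
        affected = [Side.LEFT] * 6
        stats = es.activity_print(sets, affected)
        assert len(stats) == 18  # 9 muscles x 2 roles
        key = (MUSCLE_ORDER[0], "affected")
        expected = boxplot_stats([c.b[0] for c in sets])  # left = affected here
        assert stats[key] == expected

    def test_too_few_trials_rejected(self):
        with pytest.raises(es.ParameterError):
            es.activity_print(self._coeff_sets(3), [Side.LEFT] * 3)
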