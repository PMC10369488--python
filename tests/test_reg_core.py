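import numpy as np
import pytest

from _oracles import random_decomposition, scipy_pearson, scipy_slope
from regpes import (
    Dataset,
    DegenerateSegmentError,
    Segment,
    Trend,
    analyze,
    analyze_segment,
    canonical_label,
    center,
    pearson,
    reg_value,
    split_segments,
    weighted_decomposition,
)

SEG3 = Segment(0, 2, Trend.RISING)


class TestCenter:
    def test_translates_over_mean(self):
        np.testing.assert_array_equal(center([1.0, 2.0, 3.0], SEG3), [-1.0, 0.0, 1.0])

    def test_constant_series_goes_to_zero(self):
        np.testing.assert_array_equal(center([5.0, 5.0, 5.0], SEG3), [0.0, 0.0, 0.0])

    def test_restricts_to_segment_window(self, lj_dataset):
        segment = split_segments(lj_dataset)[0]
        window = lj_dataset.e_total[segment.slice]
        np.testing.assert_allclose(
            center(lj_dataset.e_total, segment), window - window.mean(), rtol=1e-15
        )

    def test_short_segment_rejected(self):
        with pytest.raises(DegenerateSegmentError):
            center([1.0, 2.0], (0, 1))


class TestRegValue:
    def test_self_regression_is_one(self):
        total = [1.0, 3.0, 2.0, 5.0]
        assert reg_value(total, total, (0, 3)) == pytest.approx(1.0)

    def test_linear_term_recovers_weight(self):
        total = np.array([1.0, 3.0, 2.0, 5.0])
        term = 0.7 * total + 42.0  # the constant vanishes under translation
        assert reg_value(term, total, (0, 3)) == pytest.approx(0.7)

    def test_matches_scipy_on_lj_segment(self, lj_dataset):
        segment = split_segments(lj_dataset)[0]  # repulsive-wall, falling
        attractive = lj_dataset.terms[canonical_label("xc", "b1", "b2")]
        expected = scipy_slope(
            lj_dataset.e_total[segment.slice], attractive[segment.slice]
        )
        assert reg_value(attractive, lj_dataset.e_total, segment) == pytest.approx(
            expected, rel=1e-12
        )

    def test_zero_total_variance_rejected(self):
        with pytest.raises(DegenerateSegmentError):
            reg_value([1.0, 2.0, 3.0], [4.0, 4.0, 4.0], (0, 2))


class TestPearson:
    @pytest.mark.parametrize(
        "term, expected",
        [([2.0, 4.0, 6.0], 1.0), ([-1.0, -2.0, -3.0], -1.0)],
    )
    def test_perfect_correlation(self, term, expected):
        assert pearson(term, [1.0, 2.0, 3.0], SEG3) == pytest.approx(expected)

    def test_symmetric_term_has_zero_correlation(self):
        assert pearson([1.0, -2.0, 1.0], [-1.0, 0.0, 1.0], SEG3) == pytest.approx(0.0)

    def test_zero_variance_is_an_error_not_nan(self):
        with pytest.raises(DegenerateSegmentError):
            pearson([3.0, 3.0, 3.0], [1.0, 2.0, 3.0], SEG3)


class TestAnalyzeSegment:
    def test_exact_two_term_decomposition(self, weighted_exact):
        (segment,) = split_segments(weighted_exact)
        result = analyze_segment(weighted_exact, segment)
        assert [e.reg for e in result.entries] == pytest.approx([0.7, 0.3])
        assert [e.pearson for e in result.entries] == [1.0, 1.0]
        assert [e.rank for e in result.entries] == [1, 2]
        assert result.sum_of_reg == pytest.approx(1.0)

    def test_lj_falling_segment_sign_structure(self, lj_dataset):
        segment = split_segments(lj_dataset)[0]
        result = analyze_segment(lj_dataset, segment)
        by_label = {str(e.label): e for e in result.entries}
        rep, att = by_label["xc(a1,a2)"], by_label["xc(b1,b2)"]
        assert rep.reg > 1.0 and att.reg < 0.0
        assert rep.reg + att.reg == pytest.approx(1.0, abs=1e-9)
        for entry in (rep, att):
            expected = scipy_slope(
                lj_dataset.e_total[segment.slice],
                lj_dataset.terms[entry.label][segment.slice],
            )
            assert entry.reg == pytest.approx(expected, rel=1e-12)

    def test_noise_term_flagged_but_ranking_unchanged(self, weighted_exact):
        rng = np.random.default_rng(5)
        noise = rng.normal(scale=1e-3, size=weighted_exact.n_points)
        terms = dict(weighted_exact.terms)
        noise_label = canonical_label("intra", "z9")
        terms[noise_label] = noise
        dataset = Dataset(s=weighted_exact.s, e_total=weighted_exact.e_total, terms=terms)
        (segment,) = split_segments(dataset)
        result = analyze_segment(dataset, segment, r_threshold=0.7)
        noisy = next(e for e in result.entries if e.label == noise_label)
        assert abs(scipy_pearson(dataset.e_total, noise)) < 0.7  # premise
        assert noisy.discarded and noisy.rank is None
        survivors = [e for e in result.entries if not e.discarded]
        assert [e.reg for e in survivors] == pytest.approx([0.7, 0.3])
        assert result.sum_of_reg_retained == pytest.approx(1.0, abs=1e-6)

    def test_constant_term_reported_discarded_with_zero_slope(self, weighted_exact):
        terms = dict(weighted_exact.terms)
        terms[canonical_label("intra", "k1")] = np.full(weighted_exact.n_points, 3.0)
        dataset = Dataset(s=weighted_exact.s, e_total=weighted_exact.e_total, terms=terms)
        (segment,) = split_segments(dataset)
        entry = next(
            e
            for e in analyze_segment(dataset, segment).entries
            if str(e.label) == "intra(k1)"
        )
        assert entry.reg == 0.0 and entry.pearson == 0.0 and entry.discarded

    def test_invalid_threshold_rejected(self, weighted_exact):
        (segment,) = split_segments(weighted_exact)
        with pytest.raises(ValueError):
            analyze_segment(weighted_exact, segment, r_threshold=1.0)


class TestAnalyze:
    def test_v_shape_gives_opposite_signs_per_segment(self):
        total = np.array([2.0, 1.0, 0.0, 1.0, 2.0])
        term = 0.4 * total + 1.0
        dataset = Dataset(
            s=np.arange(5.0),
            e_total=total,
            terms={canonical_label("intra", "a1"): term},
        )
        falling, rising = analyze(dataset)
        assert falling.entries[0].reg == pytest.approx(0.4)
        assert rising.entries[0].reg == pytest.approx(0.4)
        assert falling.segment.classification is Trend.FALLING
        assert rising.segment.classification is Trend.RISING

    def test_sum_rule_on_every_segment(self, lj_dataset, double_well_dataset):
        for dataset in (lj_dataset, double_well_dataset):
            for result in analyze(dataset):
                assert result.error is None
                assert result.sum_of_reg == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_segment_reported_others_proceed(self):
        # zigzag: interior segments have only 2 points each
        total = np.array([0.0, 1.0, 0.5, 2.0])
        dataset = Dataset(
            s=np.arange(4.0),
            e_total=total,
            terms={canonical_label("intra", "a1"): total.copy()},
        )
        results = analyze(dataset)
        assert len(results) == 3
        assert all(r.error is not None for r in results)


class TestInvariants:
    def test_reparameterization_shift_and_scale(self, lj_dataset):
        segment = split_segments(lj_dataset)[0]
        label = canonical_label("xc", "b1", "b2")
        base_reg = reg_value(lj_dataset.terms[label], lj_dataset.e_total, segment)
        base_r = pearson(lj_dataset.terms[label], lj_dataset.e_total, segment)

        # reg/pearson never look at s, so any strictly monotone transform of
        # the control coordinate leaves both untouched by construction
        reparam = Dataset(
            s=lj_dataset.s**3, e_total=lj_dataset.e_total, terms=lj_dataset.terms
        )
        assert reg_value(reparam.terms[label], reparam.e_total, segment) == base_reg

        shifted = lj_dataset.terms[label] + 77.0
        assert reg_value(shifted, lj_dataset.e_total, segment) == pytest.approx(
            base_reg, rel=1e-12
        )
        scaled = 3.5 * lj_dataset.terms[label]
        assert reg_value(scaled, lj_dataset.e_total, segment) == pytest.approx(
            3.5 * base_reg, rel=1e-12
        )
        assert abs(pearson(scaled, lj_dataset.e_total, segment)) == pytest.approx(
            abs(base_r), rel=1e-12
        )

    def test_oracle_equivalence_on_seeded_random_datasets(self):
        rng = np.random.default_rng(2024)
        for _ in range(25):
            dataset = random_decomposition(rng)
            segment = (0, dataset.n_points - 1)
            for label, series in dataset.terms.items():
                got = reg_value(series, dataset.e_total, segment)
                assert got == pytest.approx(
                    scipy_slope(dataset.e_total, series), rel=1e-10
                )
                assert pearson(series, dataset.e_total, segment) == pytest.approx(
                    scipy_pearson(dataset.e_total, series), rel=1e-10
                )

    def test_parameter_recovery_with_noise(self):
        # small-scale replicate battery; the acceptance suite runs 200 seeds
        weights = np.array([0.7, 0.3])
        recovered = []
        for seed in range(50):
            dataset = weighted_decomposition(
                weights, sigma=0.66, seed=seed, exact_total=False
            )
            (segment,) = split_segments(dataset)
            result = analyze_segment(dataset, segment, r_threshold=0.0)
            by_label = {str(e.label): e.reg for e in result.entries}
            recovered.append([by_label["intra(t1)"], by_label["intra(t2)"]])
        recovered = np.asarray(recovered)
        mean = recovered.mean(axis=0)
        se = recovered.std(axis=0, ddof=1) / np.sqrt(len(recovered))
        assert np.all(np.abs(mean - weights) <= 3 * np.maximum(se, 1e-12))
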