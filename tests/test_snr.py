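"""Line-profile extraction, allocation, the SNR statistic and Wilcoxon test."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from cle_afq import (
    AllocationError,
    FieldImage,
    LineProfile,
    SceneSpec,
    allocate_profile,
    compare_filters,
    compute_snr,
    extract_profile,
    render_scene,
    wilcoxon_signed_rank,
)
from cle_afq.benchmarks import signed_rank_enumeration_p, snr_consistency
from cle_afq.frames import IMAGE_SHAPE, PIXEL_SIZE_UM
from cle_afq.simulate import NoiseParams


def _const_image(value=100):
    return FieldImage(pixels=np.full(IMAGE_SHAPE, value, dtype=np.uint16))


class TestExtractProfile:
    def test_constant_image_gives_constant_profile(self):
        prof = extract_profile(_const_image(100), (10, 10), (10, 80))
        assert np.all(prof.values == 100)

    def test_unit_spacing_inclusive_endpoints(self):
        prof = extract_profile(_const_image(), (5, 5), (5, 55))
        assert len(prof.values) == 51

    def test_oblique_segment_sample_count(self):
        prof = extract_profile(_const_image(), (0, 0), (30, 40))  # length 50
        assert len(prof.values) == 51

    def test_profile_through_gaussian_spot_hits_peak(self):
        spec = SceneSpec(n_spots=1, spot_diameter_um=(2.0, 2.0),
                         noise=NoiseParams(0.0, 0.0), seed=21)
        img, gt = render_scene(spec, "BP", seed=21)
        o = gt.of_class("spot")[0]
        row, col = o.y_um / PIXEL_SIZE_UM, o.x_um / PIXEL_SIZE_UM
        prof = extract_profile(img, (row, col - 20), (row, col + 20))
        expected_peak = 500.0 + o.peak
        assert prof.values.max() == pytest.approx(expected_peak, rel=0.02)

    def test_zero_length_segment_rejected(self):
        with pytest.raises(ValueError):
            extract_profile(_const_image(), (5, 5), (5, 5))

    def test_endpoint_outside_image_rejected(self):
        with pytest.raises(ValueError):
            extract_profile(_const_image(), (0, 0), (0, 5000))


def _best_between_class_threshold(values):
    """Exhaustive threshold search maximizing between-class variance."""
    values = np.asarray(values, dtype=float)
    best_t, best_score = None, -1.0
    for t in np.unique(values)[:-1]:
        lo, hi = values[values <= t], values[values > t]
        score = len(lo) * len(hi) * (lo.mean() - hi.mean()) ** 2
        if score > best_score:
            best_t, best_score = t, score
    return best_t


class TestAllocateProfile:
    def test_otsu_matches_exhaustive_search(self):
        values = [10, 11, 9, 10, 30, 31, 30, 10, 9]
        prof = LineProfile(np.arange(9, dtype=float), values)
        labeled = allocate_profile(prof, "otsu")
        t = _best_between_class_threshold(values)
        expected = ["signal" if v > t else "background" for v in values]
        assert labeled.labels == expected
        assert all(
            lab == "signal" for v, lab in zip(values, labeled.labels) if v >= 30
        )

    def test_manual_labels_applied_verbatim(self):
        prof = LineProfile(np.arange(4, dtype=float), [1, 2, 3, 4])
        labels = ["background", "background", "signal", "signal"]
        labeled = allocate_profile(prof, "manual", manual_labels=labels)
        assert labeled.labels == labels

    def test_constant_profile_has_no_contrast(self):
        prof = LineProfile(np.arange(6, dtype=float), [5.0] * 6)
        with pytest.raises(AllocationError):
            allocate_profile(prof, "otsu")


class TestComputeSNR:
    def test_worked_example(self):
        bg = [10, 12, 8, 10, 11, 9]
        sig = [24, 26, 25]
        prof = LineProfile(
            np.arange(9, dtype=float), bg + sig,
            ["background"] * 6 + ["signal"] * 3,
        )
        res = compute_snr(prof)
        assert res.delta_mu == pytest.approx(15.0)
        assert res.sigma_bg == pytest.approx(1.41421, abs=1e-5)
        assert res.snr == pytest.approx(10.6066, abs=1e-4)

    def test_equal_means_give_zero(self):
        prof = LineProfile(
            np.arange(6, dtype=float), [10, 12, 8, 10, 9, 11],
            ["background"] * 5 + ["signal"],
        )
        prof.values[5] = np.mean(prof.values[:5])  # equal to background mean
        assert compute_snr(prof).snr == pytest.approx(0.0)

    def test_constant_background_degenerate(self):
        prof = LineProfile(
            np.arange(5, dtype=float), [10, 10, 10, 20, 21],
            ["background"] * 3 + ["signal"] * 2,
        )
        with pytest.raises(ValueError):
            compute_snr(prof)

    @given(
        shift=st.floats(-1000, 1000, allow_nan=False),
        scale=st.floats(0.01, 100, allow_nan=False),
    )
    def test_affine_invariance(self, shift, scale):
        rng = np.random.default_rng(0)
        values = np.concatenate([rng.normal(50, 5, 20), rng.normal(90, 5, 5)])
        labels = ["background"] * 20 + ["signal"] * 5
        base = compute_snr(LineProfile(np.arange(25, dtype=float), values, labels)).snr
        moved = compute_snr(
            LineProfile(np.arange(25, dtype=float), values * scale + shift, labels)
        ).snr
        assert moved == pytest.approx(base, rel=1e-9)

    def test_population_sd_option(self):
        bg = [10, 12, 8, 10, 11, 9]
        prof = LineProfile(
            np.arange(7, dtype=float), bg + [25],
            ["background"] * 6 + ["signal"],
        )
        res = compute_snr(prof, ddof=0)
        assert res.sigma_bg == pytest.approx(np.std(bg))


class TestWilcoxon:
    def test_all_positive_n5(self):
        w, p, degenerate, method = wilcoxon_signed_rank(np.array([1, 2, 3, 4, 5.0]))
        assert (w, method, degenerate) == (15.0, "exact", False)
        assert p == pytest.approx(0.0625)

    def test_constant_positive_differences_n3(self):
        res = compare_filters([(3, 1), (4, 2), (5, 3)])
        assert (res.median_bp, res.median_lp) == (4.0, 2.0)
        assert res.p_value == pytest.approx(0.25)

    def test_identical_pairs_degenerate(self):
        res = compare_filters([(2.0, 2.0), (3.0, 3.0)])
        assert res.degenerate
        assert res.p_value == 1.0
        assert res.statistic == 0.0

    @given(st.data())
    def test_exact_matches_enumeration_small_n(self, data):
        n = data.draw(st.integers(2, 10))
        # half-integer magnitudes produce ties in |d| with probability ~1
        diffs = np.array(
            data.draw(
                st.lists(
                    st.sampled_from([-3.0, -2.0, -1.5, -1.0, 1.0, 1.5, 2.0, 3.0]),
                    min_size=n, max_size=n,
                )
            )
        )
        w_impl, p_impl, _, method = wilcoxon_signed_rank(diffs)
        w_ref, p_ref = signed_rank_enumeration_p(diffs)
        assert method == "exact"
        assert w_impl == w_ref
        assert p_impl == pytest.approx(p_ref, abs=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            d = rng.normal(0.3, 1.0, 12)
            _, p_impl, _, _ = wilcoxon_signed_rank(d)
            p_scipy = stats.wilcoxon(d, mode="exact").pvalue
            assert p_impl == pytest.approx(p_scipy, abs=1e-10)

    def test_normal_approximation_large_n(self):
        rng = np.random.default_rng(6)
        d = rng.normal(0.5, 1.0, 60)
        w, p, _, method = wilcoxon_signed_rank(d)
        assert method == "normal"
        p_scipy = stats.wilcoxon(d, mode="approx", correction=False).pvalue
        assert p == pytest.approx(p_scipy, rel=1e-6)


def test_estimator_consistency():
    res = snr_consistency(n_profiles=200, n_background=200, seed=42)
    assert res["relative_error"] < 0.10
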