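import csv
import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from synthzoo.evaluation import (
    FidReport,
    GaussianSummary,
    compute_fid,
    fid_lower_bound,
    fit_gaussian,
    frechet_distance,
    normalize_images,
    report_table,
    rfid,
)
from synthzoo.fixtures import synth_image_set

from conftest import BLOB_ID, SHIFT_ID


def _diag_gaussian(means, variances):
    return GaussianSummary(mean=np.asarray(means, float),
                           cov=np.diag(np.asarray(variances, float)))


def diagonal_closed_form(mu1, var1, mu2, var2):
    """Independent oracle: for diagonal covariances the distance decomposes
    into per-dimension 1-D terms (mu1-mu2)^2 + (sigma1-sigma2)^2."""
    mu1, var1, mu2, var2 = (np.asarray(a, float) for a in (mu1, var1, mu2, var2))
    return float(np.sum((mu1 - mu2) ** 2 + (np.sqrt(var1) - np.sqrt(var2)) ** 2))


class TestFitGaussian:
    def test_hand_computed_unbiased_covariance(self):
        g = fit_gaussian(np.array([[0.0], [2.0]]))
        np.testing.assert_allclose(g.mean, [1.0])
        np.testing.assert_allclose(g.cov, [[2.0]])  # ((0-1)^2+(2-1)^2)/(2-1)

    def test_identical_rows_zero_covariance(self):
        g = fit_gaussian(np.ones((5, 3)))
        np.testing.assert_allclose(g.cov, 0.0)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((20, 4))
        g1 = fit_gaussian(x)
        g2 = fit_gaussian(x[rng.permutation(20)])
        np.testing.assert_allclose(g1.mean, g2.mean)
        np.testing.assert_allclose(g1.cov, g2.cov)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            fit_gaussian(np.ones((1, 3)))


class TestFrechetDistance:
    def test_identity_of_indiscernibles(self):
        g = _diag_gaussian([1.0, -2.0], [0.5, 3.0])
        assert frechet_distance(g, g) == pytest.approx(0.0, abs=1e-12)

    def test_one_dimensional_mean_shift(self):
        # (mu1-mu2)^2 + (s1-s2)^2 = 9 + 0
        a = _diag_gaussian([0.0], [1.0])
        b = _diag_gaussian([3.0], [1.0])
        assert frechet_distance(a, b) == pytest.approx(9.0, abs=1e-10)

    def test_one_dimensional_variance_gap(self):
        # tr(1 + 4 - 2*sqrt(4)) = 1
        a = _diag_gaussian([0.0], [1.0])
        b = _diag_gaussian([0.0], [4.0])
        assert frechet_distance(a, b) == pytest.approx(1.0, abs=1e-10)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        d=st.integers(1, 10),
        seed=st.integers(0, 10_000),
    )
    def test_diagonal_case_matches_closed_form(self, d, seed):
        rng = np.random.default_rng(seed)
        mu1, mu2 = rng.normal(size=(2, d)) * 3
        var1, var2 = rng.uniform(0.1, 5.0, size=(2, d))
        got = frechet_distance(_diag_gaussian(mu1, var1), _diag_gaussian(mu2, var2))
        assert got == pytest.approx(diagonal_closed_form(mu1, var1, mu2, var2),
                                    abs=1e-8, rel=1e-8)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((50, 5))
        y = rng.standard_normal((40, 5)) + 0.5
        a, b = fit_gaussian(x), fit_gaussian(y)
        assert frechet_distance(a, b) == pytest.approx(frechet_distance(b, a), abs=1e-8)

    def test_monotone_in_mean_separation(self):
        base = _diag_gaussian([0.0], [1.0])
        distances = [frechet_distance(base, _diag_gaussian([mu], [1.0]))
                     for mu in (0.5, 1.0, 2.0, 4.0)]
        assert distances == sorted(distances)
        assert all(d2 > d1 for d1, d2 in zip(distances, distances[1:]))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            frechet_distance(_diag_gaussian([0.0], [1.0]),
                             _diag_gaussian([0.0, 0.0], [1.0, 1.0]))

    def test_near_singular_covariances_stabilized(self):
        # rank-deficient covariance: sqrtm needs the complex-part discard path
        x = np.zeros((10, 3))
        x[:, 0] = np.arange(10)
        a = fit_gaussian(x)
        assert frechet_distance(a, a) == pytest.approx(0.0, abs=1e-6)


class TestNormalization:
    def test_bitdepth_full_range(self):
        imgs = np.arange(256, dtype=np.uint8).reshape(1, 16, 16)
        out = normalize_images(imgs, "bitdepth")
        assert out.min() == 0.0 and out.max() == 1.0

    def test_minmax_constant_dataset_is_zero(self):
        out = normalize_images(np.full((3, 4, 4), 7, dtype=np.uint8), "minmax")
        np.testing.assert_array_equal(out, 0.0)

    def test_bitdepth_on_prenormalized_floats_warns(self):
        imgs = np.random.default_rng(0).uniform(size=(2, 8, 8))
        with pytest.warns(UserWarning, match="already within"):
            out = normalize_images(imgs, "bitdepth")
        assert out.max() < 0.01  # shrunk by 255

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            normalize_images(np.zeros((2, 4, 4)), "zscore")


class TestComputeFid:
    def test_identical_sets_give_zero(self, toy_extractor):
        imgs = synth_image_set(30, seed=0)
        assert compute_fid(imgs, imgs, toy_extractor) == pytest.approx(0.0, abs=1e-6)

    def test_within_set_permutation_invariance(self, toy_extractor):
        a = synth_image_set(30, seed=0)
        b = synth_image_set(30, seed=1)
        base = compute_fid(a, b, toy_extractor)
        shuffled = compute_fid(a[::-1], b, toy_extractor)
        # summation order in the mean/covariance differs; agreement is to
        # floating rounding, not bit-exact
        assert shuffled == pytest.approx(base, rel=1e-6)

    def test_distribution_shift_increases_fid(self, toy_extractor, real_images):
        """Two draws of one distribution are closer than a shifted draw."""
        same = synth_image_set(200, seed=11)
        shifted = synth_image_set(200, seed=12, shift=64)
        fid_same = compute_fid(real_images, same, toy_extractor)
        fid_shifted = compute_fid(real_images, shifted, toy_extractor)
        assert 0 <= fid_same < fid_shifted

    def test_too_few_images_rejected(self, toy_extractor):
        with pytest.raises(ValueError):
            compute_fid(synth_image_set(1, seed=0), synth_image_set(4, seed=0),
                        toy_extractor)

    def test_normalized_and_raw_both_finite(self, toy_extractor):
        a = synth_image_set(40, seed=0)
        b = synth_image_set(40, seed=1)
        raw = compute_fid(a, b, toy_extractor)
        norm = compute_fid(a, b, toy_extractor, normalize="bitdepth")
        assert np.isfinite(raw) and np.isfinite(norm)


class TestFidLowerBound:
    def test_duplicated_dataset_forced_copy_split_is_zero(self, toy_extractor):
        half = synth_image_set(20, seed=4)
        doubled = np.concatenate([half, half])
        split = fid_lower_bound(
            doubled, toy_extractor,
            split_indices=(range(20), range(20, 40)),
        )
        assert split.value == pytest.approx(0.0, abs=1e-6)
        assert (split.n_first, split.n_second) == (20, 20)

    def test_fixed_seed_reproducible(self, toy_extractor, real_images):
        a = fid_lower_bound(real_images[:60], toy_extractor, seed=9)
        b = fid_lower_bound(real_images[:60], toy_extractor, seed=9)
        assert a.value == b.value

    def test_odd_count_split_sizes(self, toy_extractor):
        split = fid_lower_bound(synth_image_set(21, seed=0), toy_extractor, seed=0)
        assert (split.n_first, split.n_second) == (10, 11)

    def test_different_seeds_differ_but_nonnegative(self, toy_extractor, real_images):
        a = fid_lower_bound(real_images[:60], toy_extractor, seed=1)
        b = fid_lower_bound(real_images[:60], toy_extractor, seed=2)
        assert a.value >= 0 and b.value >= 0
        assert a.value != b.value

    def test_too_few_images_rejected(self, toy_extractor):
        with pytest.raises(ValueError):
            fid_lower_bound(synth_image_set(3, seed=0), toy_extractor)


class TestRfid:
    def test_equal_distances_give_one(self):
        assert rfid(5.0, 5.0) == pytest.approx(1.0)

    def test_zero_lower_bound_gives_zero(self):
        assert rfid(5.0, 0.0) == pytest.approx(0.0)

    def test_lower_bound_above_rs_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            assert rfid(2.0, 3.0) == 1.0

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            rfid(0.0, 1.0)
        with pytest.raises(ValueError):
            rfid(1.0, -0.1)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(rs=st.floats(0.01, 1e4), frac=st.floats(0.0, 1.0))
    def test_bounded_in_unit_interval(self, rs, frac):
        assert 0.0 <= rfid(rs, rs * frac) <= 1.0


class TestEvaluateModel:
    def test_matched_model_scores_higher_rfid_than_shifted(
        self, generators, real_images
    ):
        matched = generators.evaluate(BLOB_ID, real_images, n_syn=200, seed=5)
        shifted = generators.evaluate(SHIFT_ID, real_images, n_syn=200, seed=5)
        assert matched.rfid > shifted.rfid
        assert shifted.rfid < 0.5

    def test_report_invariant_links_the_three_numbers(self, generators, real_images):
        report = generators.evaluate(SHIFT_ID, real_images, n_syn=200, seed=5)
        expected = 1.0 - (report.fid_rs - report.fid_rr) / report.fid_rs
        assert report.rfid == pytest.approx(expected, abs=1e-9)

    def test_provenance_fields_recorded(self, generators, real_images, toy_extractor):
        report = generators.evaluate(BLOB_ID, real_images[:40], n_syn=40, seed=7,
                                     extractor=toy_extractor, normalize="bitdepth")
        assert report.model_id == BLOB_ID
        assert report.extractor_id == toy_extractor.id
        assert report.normalized is True and report.normalize_mode == "bitdepth"
        assert (report.n_real, report.n_syn) == (40, 40)
        assert report.seed == 7


class TestReportTable:
    def _report(self, rr, rs, mid="00001_A"):
        return FidReport(model_id=mid, fid_rr=rr, fid_rs=rs, rfid=rfid(rs, min(rr, rs)),
                         n_real=10, n_syn=10, normalized=False,
                         extractor_id="toy-rp-0-64", seed=0)

    def test_two_reports_two_rows_plus_header(self):
        table = report_table([self._report(1.0, 2.0), self._report(2.0, 4.0, "00002_B")])
        lines = table.csv_text.strip().split("\n")
        assert len(lines) == 3
        assert lines[0].startswith("model_id,fid_rr,fid_rs,rfid")

    def test_exact_trend_line(self):
        table = report_table([self._report(1.0, 2.0), self._report(2.0, 4.0, "00002_B")])
        assert table.slope == pytest.approx(2.0)
        assert table.intercept == pytest.approx(0.0, abs=1e-12)
        assert table.pairs == [(1.0, 2.0), (2.0, 4.0)]

    def test_csv_round_trips(self):
        reports = [self._report(1.5, 3.25), self._report(2.0, 8.0, "00002_B")]
        table = report_table(reports)
        rows = list(csv.DictReader(io.StringIO(table.csv_text)))
        for row, rep in zip(rows, reports):
            assert float(row["fid_rr"]) == rep.fid_rr
            assert float(row["fid_rs"]) == rep.fid_rs
            assert float(row["rfid"]) == rep.rfid

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            report_table([])
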