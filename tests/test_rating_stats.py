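import numpy as np
import pandas as pd
import pytest

from audioscene.rating_stats import (DegenerateRatingsError, RatingMatrix,
                                     SceneTruth, bin_temperature, chance_level,
                                     icc_2k, percent_correct,
                                     property_correlations,
                                     ratings_from_long_csv)


def anova_icc_oracle(ratings):
    """Explicit two-way ANOVA mean-squares oracle (scenes = rows)."""
    x = np.asarray(ratings, float).T
    n, k = x.shape
    grand = x.mean()
    ss_rows = k * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_cols = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_err = ((x - grand) ** 2).sum() - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    return (ms_r - ms_e) / ms_r


def random_matrix(rng, n_raters=None, n_scenes=None):
    n_raters = n_raters or int(rng.integers(3, 8))
    n_scenes = n_scenes or int(rng.integers(4, 15))
    return RatingMatrix(rng.integers(1, 8, size=(n_raters, n_scenes)),
                        "synthetic")


class TestIcc2k:
    def test_identical_raters_give_unity(self):
        m = RatingMatrix(np.array([[1, 2, 3, 4]] * 3), "p")
        r = icc_2k(m)
        assert r.icc == 1.0
        assert r.ci_high == 1.0

    def test_fixed_matrix_matches_anova_oracle(self):
        ratings = np.array([[1, 2, 3, 4], [2, 3, 4, 5], [1, 3, 3, 5]])
        r = icc_2k(RatingMatrix(ratings, "p"))
        assert r.icc == pytest.approx(anova_icc_oracle(ratings), abs=1e-12)
        assert (r.df1, r.df2) == (3, 6)

    def test_random_matrices_match_oracle(self, rng):
        for _ in range(300):
            m = random_matrix(rng)
            try:
                r = icc_2k(m)
            except DegenerateRatingsError:
                continue
            assert r.icc == pytest.approx(anova_icc_oracle(m.ratings),
                                          abs=1e-10)

    def test_matches_pingouin_consistency_average(self, rng):
        pingouin = pytest.importorskip("pingouin")
        m = random_matrix(rng, n_raters=5, n_scenes=12)
        long = pd.DataFrame([
            {"targets": j, "raters": i, "scores": m.ratings[i, j]}
            for i in range(m.n_raters) for j in range(m.n_scenes)])
        ref = pingouin.intraclass_corr(long, targets="targets", raters="raters",
                                       ratings="scores")
        ref_row = ref[ref["Type"] == "ICC(C,k)"].iloc[0]
        r = icc_2k(m)
        assert r.icc == pytest.approx(ref_row["ICC"], abs=1e-9)
        assert r.f_value == pytest.approx(ref_row["F"], rel=1e-9)
        ci = list(ref_row["CI95"])  # pingouin rounds its interval to 2 dp
        assert r.ci_low == pytest.approx(ci[0], abs=0.011)
        assert r.ci_high == pytest.approx(ci[1], abs=0.011)

    def test_invariant_to_rater_constant_offsets(self, rng):
        base = rng.integers(2, 5, size=(4, 20))
        shifted = base + np.array([[0], [1], [2], [0]])
        r1 = icc_2k(RatingMatrix(base, "p"))
        r2 = icc_2k(RatingMatrix(shifted, "p"))
        assert r1.icc == pytest.approx(r2.icc, abs=1e-12)

    def test_independent_noise_gives_near_zero(self, rng):
        estimates = [icc_2k(random_matrix(rng, 10, 200)).icc for _ in range(30)]
        assert abs(np.mean(estimates)) < 0.1

    def test_degenerate_matrix_rejected(self):
        with pytest.raises(DegenerateRatingsError):
            icc_2k(RatingMatrix(np.full((3, 4), 4), "p"))

    def test_ci_brackets_estimate(self, rng):
        for _ in range(20):
            m = random_matrix(rng)
            try:
                r = icc_2k(m)
            except DegenerateRatingsError:
                continue
            assert r.ci_low <= r.icc <= r.ci_high


class TestPropertyCorrelations:
    def test_perfect_and_inverse(self, rng):
        x = rng.normal(size=50)
        df = pd.DataFrame({"a": x, "b": -x, "c": rng.normal(size=50)})
        corr, pvals, flags = property_correlations(df)
        assert corr.loc["a", "a"] == 1.0
        assert corr.loc["a", "b"] == pytest.approx(-1.0)
        assert pvals.loc["a", "b"] < 1e-10
        assert flags == []

    def test_sampling_bound_at_rho_06(self, rng):
        errors = []
        for _ in range(50):
            z = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], size=200)
            corr, _, _ = property_correlations(
                pd.DataFrame(z, columns=["x", "y"]))
            errors.append(abs(corr.loc["x", "y"] - 0.6))
        assert np.mean(np.asarray(errors) <= 0.12) > 0.9

    def test_zero_variance_column_flagged(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=20), "b": np.ones(20)})
        corr, _, flags = property_correlations(df)
        assert "b" in flags
        assert np.isnan(corr.loc["a", "b"])


class TestBinTemperature:
    @pytest.mark.parametrize("t,expected", [
        (15, 1), (30, 1), (31, 2), (46, 2), (47, 3), (62, 3), (63, 4),
        (78, 4), (79, 5), (94, 5), (95, 6), (110, 6), (111, 7), (126, 7),
    ])
    def test_printed_bin_edges(self, t, expected):
        assert bin_temperature(t) == expected

    @pytest.mark.parametrize("t", [14.9, 127, -10])
    def test_out_of_range_rejected(self, t):
        with pytest.raises(ValueError, match=str(t)):
            bin_temperature(t)


class TestChanceLevels:
    def test_closed_forms(self):
        assert chance_level("temperature") == pytest.approx(100 / 7)
        assert chance_level("season") == pytest.approx(100 / 7)
        assert chance_level("indoor_outdoor") == 50.0


def metadata_for(matrix, rng):
    from audioscene.synthetic_data import synth_metadata
    return synth_metadata(matrix.n_scenes, seed=int(rng.integers(1 << 30)),
                          scene_ids=matrix.scene_ids)


class TestPercentCorrect:
    def test_perfect_rater_scores_100(self, rng):
        truth = [SceneTruth(f"scene{j:04d}", "indoor", "Winter",
                            float(rng.uniform(15, 126))) for j in range(10)]
        correct = np.array([[bin_temperature(t.temperature_f) for t in truth]] * 2)
        m = RatingMatrix(correct, "Temperature",
                         tuple(t.scene_id for t in truth))
        out = percent_correct(m, truth, "temperature")
        assert out["mean"] == 100.0

    def test_monotone_in_corrections(self, rng):
        truth = [SceneTruth(f"scene{j:04d}", "indoor", "Winter", 20.0)
                 for j in range(20)]
        wrong = RatingMatrix(np.full((2, 20), 5), "Temperature",
                             tuple(t.scene_id for t in truth))
        part = np.full((2, 20), 5)
        part[:, :8] = 1  # true bin for 20 °F
        partially = RatingMatrix(part, "Temperature", wrong.scene_ids)
        s0 = percent_correct(wrong, truth, "temperature")["mean"]
        s1 = percent_correct(partially, truth, "temperature")["mean"]
        assert 0 <= s0 < s1 <= 100

    def test_midpoint_policies(self):
        truth = [SceneTruth("scene0000", "indoor", "Winter", 20.0),
                 SceneTruth("scene0001", "outdoor", "Winter", 20.0)]
        m = RatingMatrix(np.array([[4, 4], [7, 1]]), "Outdoor vs. Indoor",
                         ("scene0000", "scene0001"))
        excl = percent_correct(m, truth, "indoor_outdoor", "exclude")
        assert np.isnan(excl["per_rater"][0])  # all midpoints excluded
        assert excl["per_rater"][1] == 100.0
        high = percent_correct(m, truth, "indoor_outdoor", "nearest-high")
        assert high["per_rater"][0] == 50.0  # 4 judged indoor

    def test_missing_truth_rejected(self):
        m = RatingMatrix(np.array([[1, 2], [3, 4]]), "Temperature")
        with pytest.raises(ValueError, match="missing metadata"):
            percent_correct(m, [], "temperature")


class TestLongCsvIngestion:
    def test_round_trip(self, tmp_path, rng):
        rows = []
        ratings = rng.integers(1, 8, size=(3, 4))
        for i in range(3):
            for j in range(4):
                rows.append({"rater_id": f"r{i}", "scene_id": f"s{j}",
                             "property": "Sparseness",
                             "rating": int(ratings[i, j])})
        path = tmp_path / "ratings.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        panels = ratings_from_long_csv(path)
        assert set(panels) == {"Sparseness"}
        assert panels["Sparseness"].ratings.shape == (3, 4)
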