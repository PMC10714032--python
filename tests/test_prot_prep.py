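import numpy as np
import pandas as pd
import pytest

from evintegra.containers import CASE, CONTROL, IntensityMatrix
from evintegra.prot_prep import (
    ImputationParams,
    filter_missing,
    impute_minprob,
    log2_transform,
    vst_normalize,
)


def _matrix(values, n_ctrl, n_case, stages=("log2",)):
    samples = [f"c{i}" for i in range(n_ctrl)] + [f"t{i}" for i in range(n_case)]
    groups = pd.Series([CONTROL] * n_ctrl + [CASE] * n_case, index=samples)
    vals = pd.DataFrame(values, columns=samples)
    vals.index = [f"P{i:03d}" for i in range(len(vals))]
    return IntensityMatrix(values=vals, groups=groups, stages=stages)


class TestFilterMissing:
    def test_three_of_five_missing_in_one_group_removed(self):
        row_bad = [np.nan, np.nan, np.nan, 1, 1] + [1] * 5
        row_good = [np.nan, np.nan, 1, 1, 1] + [1] * 5
        m = _matrix([row_bad, row_good], 5, 5)
        out = filter_missing(m, max_missing_per_group=2)
        assert list(out.feature_ids) == ["P001"]

    def test_fully_observed_matrix_is_identity(self, small_matrix):
        out = filter_missing(small_matrix)
        assert out.values.equals(small_matrix.values)

    def test_matches_brute_force_count_oracle(self, cohort):
        m, _ = cohort
        out = filter_missing(m, max_missing_per_group=2)
        expected = []
        for f in m.feature_ids:
            ok = True
            for g in (CONTROL, CASE):
                cols = m.group_samples(g)
                if int(m.values.loc[f, cols].isna().sum()) > 2:
                    ok = False
            if ok:
                expected.append(f)
        assert list(out.feature_ids) == expected

    def test_idempotent(self, cohort):
        m, _ = cohort
        once = filter_missing(m)
        twice = filter_missing(once)
        assert once.values.equals(twice.values)


class TestImputation:
    def test_params_literal_reading_of_mu_and_sigma(self):
        vals = np.array([[1.0, 2.0, 3.0, 4.0],
                         [10.0, 12.0, np.nan, np.nan],  # observed in half: excluded
                         [5.0, 6.0, 7.0, np.nan]])
        m = _matrix(vals, 2, 2, stages=("log2", "filtered"))
        p = ImputationParams.estimate(m)
        assert p.mu == 1.0
        eligible_sds = [np.std([1, 2, 3, 4], ddof=1), np.std([5, 6, 7], ddof=1)]
        assert p.sigma == pytest.approx(np.median(eligible_sds))

    def test_sigma_undefined_raises(self):
        vals = np.array([[1.0, np.nan, np.nan, np.nan],
                         [np.nan, 2.0, np.nan, np.nan]])
        m = _matrix(vals, 2, 2, stages=("log2", "filtered"))
        with pytest.raises(ValueError, match="sigma undefined"):
            ImputationParams.estimate(m)

    def test_no_missing_is_identity(self, small_matrix):
        m = IntensityMatrix(values=small_matrix.values, groups=small_matrix.groups,
                            stages=("log2", "filtered"))
        out = impute_minprob(m, ImputationParams(mu=0.0, sigma=1.0, seed=1))
        assert out.values.equals(m.values)

    def test_observed_values_bit_identical_and_mask_kept(self, cohort):
        m, _ = cohort
        f = filter_missing(m)
        out = impute_minprob(f, ImputationParams.estimate(f, seed=2))
        obs = ~f.mask.to_numpy()
        assert np.array_equal(out.values.to_numpy()[obs], f.values.to_numpy()[obs])
        assert out.original_mask.equals(f.mask)
        assert not out.values.isna().any().any()

    def test_draws_match_gaussian_moments(self):
        # law-of-large-numbers check on ~10,000 imputed entries
        from evintegra.benchmarks import imputation_moments
        res = imputation_moments(seed=3)
        assert res["n"] >= 10000
        assert res["mean_dev_se"] < 3.0
        assert res["sd_rel_dev"] < 0.05
        assert res["observed_unchanged"]

    def test_downstream_identical_for_fully_observed_features(self, cohort):
        m, _ = cohort
        f = filter_missing(m)
        complete = f.values.dropna().index
        a = impute_minprob(f, ImputationParams.estimate(f, seed=1))
        b = impute_minprob(f, ImputationParams.estimate(f, seed=99))
        assert a.values.loc[complete].equals(b.values.loc[complete])

    def test_requires_filter_stage(self, cohort):
        m, _ = cohort
        with pytest.raises(ValueError, match="stage 'filtered'"):
            impute_minprob(m, ImputationParams(mu=0.0, sigma=1.0))


class TestVst:
    def _complete(self, values, n_ctrl, n_case):
        return _matrix(values, n_ctrl, n_case, stages=("log2", "filtered", "imputed"))

    def test_additive_offset_between_samples_removed(self):
        rng = np.random.default_rng(0)
        base = rng.normal(10, 2, size=(200, 1))
        vals = np.hstack([base + rng.normal(0, 1, (200, 1)) for _ in range(4)])
        vals[:, 2:] += 5.0  # case samples offset
        m = self._complete(vals, 2, 2)
        out = vst_normalize(m)
        medians = np.median(out.values.to_numpy(), axis=0)
        assert np.allclose(medians, medians[0], atol=1e-9)

    def test_stabilized_gaussian_matrix_is_rank_preserved(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 1, size=(300, 6)) + rng.normal(10, 3, size=(300, 1))
        m = self._complete(vals, 3, 3)
        out = vst_normalize(m)
        for c in m.samples:
            assert (out.values[c].rank() == m.values[c].rank()).all()

    def test_residual_sd_trend_is_flat(self):
        rng = np.random.default_rng(2)
        means = rng.uniform(5, 15, size=(400, 1))
        vals = means + rng.normal(0, 1, size=(400, 6))
        out = vst_normalize(self._complete(vals, 3, 3))
        from evintegra.prot_prep import _trend_slope
        v = out.values.to_numpy()
        assert abs(_trend_slope(v.mean(axis=1), v.std(axis=1, ddof=1))) < 0.05

    def test_constant_sample_raises(self):
        vals = np.ones((50, 4))
        vals[:, 0] = np.arange(50)
        with pytest.raises(ValueError, match="constant sample"):
            vst_normalize(self._complete(vals, 2, 2))

    def test_incomplete_matrix_rejected(self, cohort):
        m, _ = cohort
        with pytest.raises(ValueError, match="complete"):
            vst_normalize(m)


def test_log2_transform_handles_nonpositive_as_missing():
    raw = pd.DataFrame([[4.0, 0.0], [2.0, 8.0]], columns=["a", "b"],
                       index=["P0", "P1"])
    groups = pd.Series({"a": CONTROL, "b": CASE})
    # two samples per group not required for transform itself
    groups = pd.Series({"a": CONTROL, "b": CASE})
    m = log2_transform(raw, groups)
    assert m.values.loc["P0", "a"] == 2.0
    assert np.isnan(m.values.loc["P0", "b"])
    assert m.values.loc["P1", "b"] == 3.0
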