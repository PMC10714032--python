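import itertools

import numpy as np
import pandas as pd
import pytest

from evintegra import syndata
from evintegra.containers import CASE, CONTROL, CtMatrix, CtThresholds
from evintegra.ctarray import (
    OriginEvidence,
    classify_origin,
    classify_origin_table,
    ct_differential_expression,
    ddct_percent,
    filter_unreliable,
    normalize_ct,
    unreliable_mask,
)


def _groups(n_per_group):
    samples = [f"ctrl_{i}" for i in range(n_per_group)] + \
              [f"case_{i}" for i in range(n_per_group)]
    return pd.Series([CONTROL] * n_per_group + [CASE] * n_per_group, index=samples)


class TestFilter:
    def test_four_unreliable_of_twelve_removed(self):
        groups = _groups(6)
        ct = pd.DataFrame(25.0, index=["mirA", "mirB"], columns=groups.index)
        amp = pd.DataFrame(1.6, index=["mirA", "mirB"], columns=groups.index)
        amp.loc["mirA", groups.index[:4]] = 1.0  # four failing AmpScores
        m = CtMatrix(ct=ct, amp_score=amp, groups=groups)
        out = filter_unreliable(m)
        assert list(out.ct.index) == ["mirB"]

    def test_remaining_unreliable_entries_become_missing(self):
        groups = _groups(6)
        ct = pd.DataFrame(25.0, index=["mirA"], columns=groups.index)
        ct.loc["mirA", groups.index[0]] = 39.0  # above the Ct ceiling
        amp = pd.DataFrame(1.6, index=["mirA"], columns=groups.index)
        out = filter_unreliable(CtMatrix(ct=ct, amp_score=amp, groups=groups))
        assert np.isnan(out.ct.loc["mirA", groups.index[0]])
        assert out.ct.loc["mirA"].notna().sum() == 11

    def test_matches_brute_force_oracle_on_generated_matrix(self):
        from evintegra.benchmarks import ct_filter_matches_oracle
        assert ct_filter_matches_oracle(seed=13)["agreement"] == 1.0

    def test_column_permutation_insensitive(self):
        ct, _ = syndata.gen_ct_array(60, 6, 5, -1.0, 0.08, seed=5)
        perm = list(reversed(ct.ct.columns))
        permuted = CtMatrix(ct=ct.ct[perm], amp_score=ct.amp_score[perm],
                            groups=ct.groups, thresholds=ct.thresholds)
        a = filter_unreliable(ct)
        b = filter_unreliable(permuted)
        assert set(a.ct.index) == set(b.ct.index)
        assert np.allclose(a.ct.to_numpy(),
                           b.ct[a.ct.columns].to_numpy(), equal_nan=True)


class TestNormalize:
    def test_geomean_removes_constant_offsets_exactly(self):
        groups = _groups(3)
        rng = np.random.default_rng(0)
        base = rng.uniform(22, 30, size=(40, 1))
        offsets = np.array([0.0, 1.5, -2.0, 0.5, 3.0, -1.0])
        ct = pd.DataFrame(base + offsets, index=[f"m{i}" for i in range(40)],
                          columns=groups.index)
        amp = pd.DataFrame(1.6, index=ct.index, columns=ct.columns)
        out, diag = normalize_ct(CtMatrix(ct=ct, amp_score=amp, groups=groups),
                                 "geomean")
        spread = out.ct.to_numpy() - out.ct.to_numpy()[:, [0]]
        assert np.allclose(spread, 0.0, atol=1e-12)
        assert np.allclose(diag["rle_after"], 0.0, atol=1e-12)

    def test_rle_small_after_normalization_of_generated_data(self):
        ct, _ = syndata.gen_ct_array(120, 6, 0, -1.0, 0.0, seed=7)
        out, diag = normalize_ct(filter_unreliable(ct), "geomean")
        assert diag["rle_after"].abs().max() < 0.05

    def test_three_methods_agree_on_offset_only_data(self):
        ct, _ = syndata.gen_ct_array(80, 6, 0, -1.0, 0.0, seed=13, ct_sd=0.05)
        f = filter_unreliable(ct)
        mats = [normalize_ct(f, m)[0].ct for m in
                ("geomean", "rank_invariant", "scale_invariant")]
        assert (mats[0] - mats[1]).abs().max().max() < 0.1
        assert (mats[0] - mats[2]).abs().max().max() < 0.1

    def test_fallback_to_geomean_when_no_invariant_features(self):
        ct, _ = syndata.gen_ct_array(50, 6, 0, -1.0, 0.0, seed=3)
        f = filter_unreliable(ct)
        with pytest.warns(UserWarning, match="falling back"):
            out, _ = normalize_ct(f, "scale_invariant", cv_max=1e-12)
        ref, _ = normalize_ct(f, "geomean")
        assert out.ct.equals(ref.ct)

    def test_unknown_method_rejected(self):
        ct, _ = syndata.gen_ct_array(10, 3, 0, -1.0, 0.0, seed=1)
        with pytest.raises(ValueError, match="method"):
            normalize_ct(ct, "median_polish")


class TestDdct:
    def test_identical_groups_give_100_percent(self):
        groups = _groups(3)
        target = pd.Series(27.0, index=groups.index)
        ref = pd.Series(20.0, index=groups.index)
        assert ddct_percent(target, ref, groups) == pytest.approx(100.0)

    def test_delta_delta_ct_of_minus_one_gives_200_percent(self):
        from evintegra.benchmarks import ddct_exact
        assert ddct_exact() == pytest.approx(200.0)

    def test_matches_hand_computed_formula(self):
        rng = np.random.default_rng(21)
        groups = _groups(4)
        target = pd.Series(rng.uniform(24, 30, 8), index=groups.index)
        ref = pd.Series(rng.uniform(18, 22, 8), index=groups.index)
        dct = target - ref
        ddct = dct[groups == CASE].mean() - dct[groups == CONTROL].mean()
        expected = 2.0 ** (-ddct) * 100.0
        assert ddct_percent(target, ref, groups) == pytest.approx(expected, abs=1e-12)

    def test_missing_group_rejected(self):
        groups = pd.Series({"a": CONTROL, "b": CONTROL})
        t = pd.Series({"a": 25.0, "b": 26.0})
        with pytest.raises(ValueError, match="absent"):
            ddct_percent(t, t, groups)


class TestCtDifferentialExpression:
    def test_recovers_planted_de_mirnas(self):
        ct, de_map = syndata.gen_ct_array(120, 6, 12, -1.0, 0.05, seed=17)
        norm, _ = normalize_ct(filter_unreliable(ct), "geomean")
        de = ct_differential_expression(norm)
        hits = set(de.index[de["p_adj"] < 0.05])
        sensitivity = len(hits & set(de_map)) / len(de_map)
        assert sensitivity > 0.8

    def test_sign_convention_matches_abundance(self):
        # planted delta Ct of -1 (lower Ct = more abundant) -> positive logFC
        ct, de_map = syndata.gen_ct_array(60, 6, 6, -1.0, 0.0, seed=19)
        norm, _ = normalize_ct(filter_unreliable(ct), "geomean")
        de = ct_differential_expression(norm)
        assert (de.loc[list(de_map), "logFC"] > 0).all()


class TestOriginClassifier:
    def test_ko_down_significant_is_endogenous(self):
        call = classify_origin(OriginEvidence(-1.2, 0.01))
        assert call.call == "endogenous"

    def test_ko_up_without_pri_or_pre_is_exogenous(self):
        assert classify_origin(OriginEvidence(0.8, 0.3)).call == "exogenous"
        assert classify_origin(OriginEvidence(0.8, 0.01)).call == "exogenous"

    def test_non_significant_with_pre_change_is_indeterminate(self):
        call = classify_origin(OriginEvidence(0.1, 0.5, pre_changed=True))
        assert call.call == "indeterminate"

    def test_pri_detection_forces_endogenous(self):
        call = classify_origin(OriginEvidence(0.8, 0.01, pri_detected=True))
        assert call.call == "endogenous"

    def test_classifier_is_total(self):
        calls = set()
        for lfc, p, pri, pre in itertools.product(
                (-1.0, 0.0, 1.0), (0.01, 0.5), (False, True), (False, True)):
            c = classify_origin(OriginEvidence(lfc, p, pri, pre)).call
            assert c in {"endogenous", "exogenous", "indeterminate"}
            calls.add(c)
        assert calls == {"endogenous", "exogenous", "indeterminate"}

    def test_table_interface_matches_scalar_calls(self):
        table = pd.DataFrame({
            "dicer_ko_logfc": [-1.2, 0.8, 0.1],
            "dicer_ko_p": [0.01, 0.3, 0.5],
            "pre_changed": [False, False, True],
        }, index=["mir-a", "mir-b", "mir-c"])
        out = classify_origin_table(table)
        assert out["call"].tolist() == ["endogenous", "exogenous", "indeterminate"]
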