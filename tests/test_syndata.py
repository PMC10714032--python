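import numpy as np
import pandas as pd
import pytest

from evintegra import syndata
from evintegra.ctarray import filter_unreliable


class TestCellSignatures:
    def test_marker_sets_are_disjoint_and_sized(self, planted):
        sig, markers = planted
        assert all(len(m) == 60 for m in markers.values())
        all_markers = [g for m in markers.values() for g in m]
        assert len(all_markers) == len(set(all_markers))
        assert sig.shape == (500, 5)

    def test_markers_are_elevated_by_stated_fold_change(self, planted):
        sig, markers = planted
        for ct, genes in markers.items():
            others = [c for c in sig.columns if c != ct]
            diff = sig.loc[genes, ct] - sig.loc[genes, others].mean(axis=1)
            assert np.allclose(diff, 3.0)

    def test_zero_fold_change_gives_identical_columns(self):
        sig, _ = syndata.gen_cell_signatures(100, 3, 10, 0.0, seed=1)
        assert np.allclose(sig.to_numpy(), sig.iloc[:, [0]].to_numpy())

    def test_infeasible_marker_allocation_raises(self):
        with pytest.raises(ValueError, match="allocate"):
            syndata.gen_cell_signatures(50, 5, 20, 2.0, seed=1)

    def test_fixed_seed_is_bit_identical(self):
        a, ma = syndata.gen_cell_signatures(100, 4, 10, 2.0, seed=7)
        b, mb = syndata.gen_cell_signatures(100, 4, 10, 2.0, seed=7)
        assert a.equals(b) and ma == mb


class TestEvProteome:
    def test_pure_mixture_equals_signature_column(self, planted):
        sig, _ = planted
        truth = syndata.make_truth(sig.columns, (1, 0, 0, 0, 0), (1, 0, 0, 0, 0),
                                   n_samples_per_group=2, seed=3)
        m = syndata.gen_ev_proteome(sig, truth)
        assert np.allclose(m.values["ctrl_1"], sig.iloc[:, 0], atol=1e-9)

    def test_invalid_proportions_rejected(self, planted):
        sig, _ = planted
        with pytest.raises(ValueError, match="sum to 1"):
            syndata.make_truth(sig.columns, (0.5, 0.2, 0.1, 0.1, 0.05),
                               (1, 0, 0, 0, 0), 2, seed=1)

    def test_empirical_missing_fraction_matches_dropout_rate(self):
        # Monte-Carlo check at ~10,000-entry scale
        sig, _ = syndata.gen_cell_signatures(1000, 5, 60, 3.0, seed=5)
        truth = syndata.make_truth(sig.columns, (0.4, 0.3, 0.15, 0.1, 0.05),
                                   (0.4, 0.3, 0.15, 0.1, 0.05), 5,
                                   dropout_rate=0.2, seed=6)
        m = syndata.gen_ev_proteome(sig, truth)
        assert abs(m.mask.to_numpy().mean() - 0.2) < 0.02

    def test_missingness_is_left_skewed(self, planted, cohort):
        sig, _ = planted
        m, truth = cohort
        # reconstruct the noiseless matrix to compare against truth values
        linear = np.power(2.0, sig[truth.proportions.columns].to_numpy())
        noiseless = np.log2(linear @ truth.proportions.to_numpy().T)
        mask = m.mask.to_numpy()
        assert noiseless[~mask].mean() > noiseless[mask].mean()

    def test_group_effect_applied_to_case_samples_only(self, planted):
        sig, _ = planted
        feat = sig.index[0]
        truth = syndata.make_truth(sig.columns, (1, 0, 0, 0, 0), (1, 0, 0, 0, 0),
                                   2, de_features={feat: 2.0}, seed=3)
        m = syndata.gen_ev_proteome(sig, truth)
        assert np.isclose(m.values.loc[feat, "case_1"] - m.values.loc[feat, "ctrl_1"], 2.0)

    def test_fixed_seed_is_bit_identical(self, planted):
        sig, _ = planted
        truth = syndata.make_truth(sig.columns, (0.4, 0.3, 0.15, 0.1, 0.05),
                                   (0.4, 0.3, 0.15, 0.1, 0.05), 3,
                                   dropout_rate=0.1, noise_sd=0.2, seed=9)
        assert syndata.gen_ev_proteome(sig, truth).values.equals(
            syndata.gen_ev_proteome(sig, truth).values)


class TestSingleCellCounts:
    def test_poisson_limit_mean_within_three_se(self, planted):
        sig, _ = planted
        cells = syndata.gen_single_cell_counts(sig, 100, 20000.0, 0.0, seed=41)
        ct = cells.cell_types[0]
        lin = np.power(2.0, sig[ct].to_numpy())
        mu = 20000.0 * lin / lin.sum()
        sample_mean = cells.counts[cells.cells_of(ct)].mean(axis=1).to_numpy()
        se = np.sqrt(mu / 100)
        big = mu > 5  # normal approximation needs some counts
        frac_within = np.mean(np.abs(sample_mean - mu)[big] <= 3 * se[big])
        assert frac_within > 0.98

    def test_library_size_doubling_doubles_column_sums(self, planted):
        sig, _ = planted
        a = syndata.gen_single_cell_counts(sig, 10, 10000.0, 0.1, seed=42)
        b = syndata.gen_single_cell_counts(sig, 10, 20000.0, 0.1, seed=42)
        ratio = b.counts.sum(axis=0) / a.counts.sum(axis=0)
        assert abs(np.median(ratio) - 2.0) < 0.1
        assert ratio.between(1.6, 2.4).all()

    def test_every_cell_labelled_and_reproducible(self, cells, planted):
        sig, _ = planted
        assert set(cells.counts.columns) == set(cells.labels.index)
        again = syndata.gen_single_cell_counts(sig, 40, 20000.0, 0.3, seed=31)
        assert cells.counts.equals(again.counts)

    def test_too_few_cells_per_type_rejected(self, planted):
        sig, _ = planted
        with pytest.raises(ValueError, match="cells_per_type"):
            syndata.gen_single_cell_counts(sig, 1, 1000.0, 0.1, seed=1)


class TestCtArrayGenerator:
    def test_zero_unreliable_fraction_survives_filter_unchanged(self):
        ct, _ = syndata.gen_ct_array(50, 6, 5, -1.0, 0.0, seed=4)
        filtered = filter_unreliable(ct)
        assert filtered.ct.shape == ct.ct.shape
        assert filtered.ct.equals(ct.ct)

    def test_planted_shift_appears_in_case_group(self):
        ct, de_map = syndata.gen_ct_array(100, 6, 10, -1.0, 0.0, seed=4,
                                          sample_offset_sd=0.0)
        target = next(iter(de_map))
        case = ct.ct.loc[target, ct.groups.index[ct.groups == "case"]].mean()
        ctrl = ct.ct.loc[target, ct.groups.index[ct.groups == "control"]].mean()
        assert case - ctrl == pytest.approx(-1.0, abs=0.5)

    def test_fixed_seed_is_bit_identical(self):
        a, da = syndata.gen_ct_array(50, 6, 5, -1.0, 0.1, seed=4)
        b, db = syndata.gen_ct_array(50, 6, 5, -1.0, 0.1, seed=4)
        assert a.ct.equals(b.ct) and a.amp_score.equals(b.amp_score) and da == db


class TestLrDatabase:
    def test_no_sharing_yields_sum_of_slots(self):
        lr = syndata.gen_lr_database(5, 4, 0.0, seed=2)
        assert len(lr) == 20
        assert lr["receptor"].nunique() == 20

    def test_paper_topology_shape(self):
        # six ligands joining to 40 pairs over 32 distinct receptors
        lr = syndata.gen_lr_database(6, [7, 7, 7, 7, 6, 6], 0.2, seed=3)
        assert len(lr) == 40
        assert lr["receptor"].nunique() == 32
        assert lr["ligand"].nunique() == 6

    def test_no_duplicate_pairs_and_reproducible(self):
        lr = syndata.gen_lr_database(8, 5, 0.5, seed=9)
        assert not lr.duplicated(["ligand", "receptor"]).any()
        assert lr.equals(syndata.gen_lr_database(8, 5, 0.5, seed=9))
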