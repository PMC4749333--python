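import numpy as np
import pandas as pd
import pytest

from refstab import (
    CqDataset,
    aggregate_replicates,
    descriptive_stats,
    read_cq_table,
    write_cq_table,
)
from refstab.qpcr_data import CqValidationError, SampleRecord


def make_dataset(cq, genes=None, n_obs=None, sets=("all",)):
    cq = np.asarray(cq, dtype=float)
    genes = genes or [f"g{i}" for i in range(cq.shape[0])]
    obs = [f"o{i}" for i in range(cq.shape[1])]
    sheet = {
        o: SampleRecord(o, "b1", frozenset(sets), "grp", False) for o in obs
    }
    return CqDataset(genes, obs, cq, sheet)


class TestValidation:
    def test_duplicate_gene_ids_rejected(self):
        with pytest.raises(CqValidationError, match="duplicate gene"):
            make_dataset(np.full((2, 2, 2), 20.0), genes=["g", "g"])

    def test_out_of_range_cq_names_the_cell(self):
        cq = np.full((2, 2, 2), 20.0)
        cq[1, 0, 1] = 55.0
        with pytest.raises(CqValidationError, match="g1.*o0"):
            make_dataset(cq)

    def test_sampleless_set_membership_rejected(self):
        with pytest.raises(CqValidationError, match="no sample set"):
            make_dataset(np.full((2, 2, 2), 20.0), sets=())


class TestIO:
    def test_round_trip_is_bit_exact(self, tmp_path):
        rng = np.random.default_rng(0)
        cq = rng.uniform(15, 35, size=(4, 6, 3))
        cq[1, 2, 0] = np.nan
        d = make_dataset(cq)
        write_cq_table(d, tmp_path / "cq.csv", tmp_path / "sheet.csv")
        d2 = read_cq_table(tmp_path / "cq.csv", tmp_path / "sheet.csv")
        assert d2.genes == d.genes
        assert d2.observations == d.observations
        np.testing.assert_array_equal(d2.cq, d.cq)

    def test_empty_file_is_an_error(self, tmp_path):
        (tmp_path / "cq.csv").write_text("gene,o0_t1\n")
        (tmp_path / "sheet.csv").write_text(
            "observation_id,sample_id,bio_rep,set_memberships,group,is_control\no0,s0,b1,all,g,0\n"
        )
        with pytest.raises(CqValidationError, match="no genes parsed"):
            read_cq_table(tmp_path / "cq.csv", tmp_path / "sheet.csv")

    def test_unmapped_column_is_an_error(self, tmp_path):
        (tmp_path / "cq.csv").write_text("gene,oX_t1\ng0,20.0\n")
        (tmp_path / "sheet.csv").write_text(
            "observation_id,sample_id,bio_rep,set_memberships,group,is_control\no0,s0,b1,all,g,0\n"
        )
        with pytest.raises(CqValidationError, match="oX"):
            read_cq_table(tmp_path / "cq.csv", tmp_path / "sheet.csv")

    def test_missing_cells_become_nan_not_zero(self, tmp_path):
        (tmp_path / "cq.csv").write_text("gene,o0_t1,o0_t2\ng0,20.0,\n")
        (tmp_path / "sheet.csv").write_text(
            "observation_id,sample_id,bio_rep,set_memberships,group,is_control\no0,s0,b1,all,g,0\n"
        )
        d = read_cq_table(tmp_path / "cq.csv", tmp_path / "sheet.csv")
        assert np.isnan(d.cq[0, 0, 1])


class TestAggregation:
    @pytest.mark.parametrize(
        "reps, expected",
        [((20.0, 20.2, 20.1), 20.1), ((20.0, np.nan, 20.4), 20.2)],
    )
    def test_technical_replicate_mean(self, reps, expected):
        d = make_dataset(np.array(reps).reshape(1, 1, 3))
        m, flags = aggregate_replicates(d)
        assert m.cq_mean[0, 0] == pytest.approx(expected)
        assert not flags

    def test_high_sd_cell_is_flagged_not_removed(self):
        d = make_dataset(np.array([20.0, 23.0, 20.1]).reshape(1, 1, 3))
        m, flags = aggregate_replicates(d, sd_flag_threshold=0.5)
        assert m.cq_mean[0, 0] == pytest.approx(21.0333333333)
        assert len(flags) == 1 and flags[0].gene == "g0"

    def test_biological_replicates_averaged_after_technical(self):
        cq = np.empty((1, 2, 2))
        cq[0, 0] = [20.0, 20.0]
        cq[0, 1] = [22.0, 24.0]
        d = make_dataset(cq)
        d.sample_sheet["o0"].sample_id = "S"
        d.sample_sheet["o1"].sample_id = "S"
        m, _ = aggregate_replicates(d)
        assert m.samples == ["S"]
        # mean of per-observation means (20, 23), not of the 4 raw values
        assert m.cq_mean[0, 0] == pytest.approx(21.5)

    def test_all_missing_cell_warns_and_stays_missing(self):
        cq = np.array([[[20.0, 20.0], [np.nan, np.nan]]])
        d = make_dataset(cq)
        with pytest.warns(UserWarning, match="no non-missing replicate"):
            m, _ = aggregate_replicates(d)
        assert np.isnan(m.cq_mean[0, 1])

    def test_replicate_order_irrelevant(self):
        rng = np.random.default_rng(3)
        cq = rng.uniform(18, 30, size=(3, 4, 3))
        m1, _ = aggregate_replicates(make_dataset(cq))
        m2, _ = aggregate_replicates(make_dataset(cq[:, :, ::-1]))
        np.testing.assert_allclose(m1.cq_mean, m2.cq_mean)


class TestDescriptiveStats:
    def test_constant_gene_has_zero_cv(self):
        d = make_dataset(np.full((1, 3, 1), 20.0))
        m, _ = aggregate_replicates(d)
        (s,) = descriptive_stats(m)
        assert (s.mean_cq, s.cv_percent) == (20.0, 0.0)

    def test_two_sample_cv(self):
        d = make_dataset(np.array([19.0, 21.0]).reshape(1, 2, 1))
        m, _ = aggregate_replicates(d)
        (s,) = descriptive_stats(m)
        assert s.mean_cq == pytest.approx(20.0)
        assert s.cv_percent == pytest.approx(100.0 * np.sqrt(2.0) / 20.0)  # 7.071%
        assert s.min_cq <= s.mean_cq <= s.max_cq

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(5)
        cq = rng.uniform(18, 30, size=(4, 6, 1))
        m1, _ = aggregate_replicates(make_dataset(cq))
        perm = rng.permutation(6)
        m2, _ = aggregate_replicates(make_dataset(cq[:, perm, :]))
        for s1, s2 in zip(descriptive_stats(m1), descriptive_stats(m2)):
            assert s1.cv_percent == pytest.approx(s2.cv_percent)
            assert (s1.min_cq, s1.max_cq) == (s2.min_cq, s2.max_cq)

    def test_constant_shift_moves_mean_keeps_sd(self):
        rng = np.random.default_rng(6)
        cq = rng.uniform(18, 30, size=(1, 6, 1))
        m1, _ = aggregate_replicates(make_dataset(cq))
        m2, _ = aggregate_replicates(make_dataset(cq + 3.0))
        (s1,), (s2,) = descriptive_stats(m1), descriptive_stats(m2)
        assert s2.mean_cq == pytest.approx(s1.mean_cq + 3.0)
        # SD unchanged => CV rescales by the mean ratio
        assert s2.cv_percent * s2.mean_cq == pytest.approx(s1.cv_percent * s1.mean_cq)
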