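"""I/O, the low-count detection filter, VST, and Spearman consistency QC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chronode import (TimeSeriesCounts, read_counts, write_counts,
                      filter_low_counts, vst_normalize, spearman_consistency)
from chronode.counts_io import vst_closed_form


def _container(counts, conditions, times, series=None):
    samples = [f"s{i}" for i in range(len(conditions))]
    meta = pd.DataFrame({
        "condition": conditions,
        "series": series or ["X"] * len(conditions),
        "time_hpt": times,
        "batch": series or ["X"] * len(conditions),
    }, index=pd.Index(samples, name="sample_id"))
    cdf = pd.DataFrame(counts, index=[f"g{i}" for i in range(len(counts))],
                       columns=samples)
    return TimeSeriesCounts(counts=cdf, meta=meta)


class TestReadWrite:
    def test_round_trip(self, toy_counts, tmp_path):
        write_counts(toy_counts, tmp_path / "c.tsv", tmp_path / "m.tsv")
        back = read_counts(tmp_path / "c.tsv", tmp_path / "m.tsv")
        assert back.counts.equals(toy_counts.counts)
        pd.testing.assert_frame_equal(back.meta[toy_counts.meta.columns],
                                      toy_counts.meta, check_dtype=False)

    def test_missing_sample_metadata_names_the_sample(self, toy_counts, tmp_path):
        write_counts(toy_counts, tmp_path / "c.tsv", tmp_path / "m.tsv")
        sheet = pd.read_csv(tmp_path / "m.tsv", sep="\t")
        sheet[sheet["sample_id"] != "s3"].to_csv(tmp_path / "m.tsv", sep="\t", index=False)
        with pytest.raises(ValueError, match="s3"):
            read_counts(tmp_path / "c.tsv", tmp_path / "m.tsv")

    def test_negative_counts_rejected(self, toy_counts, tmp_path):
        write_counts(toy_counts, tmp_path / "c.tsv", tmp_path / "m.tsv")
        df = pd.read_csv(tmp_path / "c.tsv", sep="\t", index_col=0)
        df.iloc[0, 0] = -3
        df.to_csv(tmp_path / "c.tsv", sep="\t")
        with pytest.raises(ValueError, match="non-negative"):
            read_counts(tmp_path / "c.tsv", tmp_path / "m.tsv")

    def test_mtx_input_matches_tsv(self, toy_counts, tmp_path):
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix
        from chronode.counts_io import read_counts_mtx
        write_counts(toy_counts, tmp_path / "c.tsv", tmp_path / "m.tsv")
        mmwrite(tmp_path / "c.mtx", csr_matrix(toy_counts.counts.to_numpy()))
        (tmp_path / "genes.txt").write_text("\n".join(toy_counts.genes) + "\n")
        (tmp_path / "samples.txt").write_text("\n".join(toy_counts.samples) + "\n")
        back = read_counts_mtx(tmp_path / "c.mtx", tmp_path / "genes.txt",
                               tmp_path / "samples.txt", tmp_path / "m.tsv")
        assert np.array_equal(back.counts.to_numpy(), toy_counts.counts.to_numpy())
        assert back.genes == toy_counts.genes

    def test_duplicate_gene_ids_rejected(self):
        meta = pd.DataFrame({"condition": ["a", "a"], "series": ["s", "s"],
                             "time_hpt": [0, 1], "batch": ["s", "s"]},
                            index=pd.Index(["x", "y"], name="sample_id"))
        counts = pd.DataFrame([[1, 2], [3, 4]], index=["g", "g"], columns=["x", "y"])
        with pytest.raises(ValueError, match="duplicated gene"):
            TimeSeriesCounts(counts=counts, meta=meta)


class TestFilterLowCounts:
    def test_gene_detected_at_exactly_four_timepoints_retained(self):
        # >=5 counts at exactly 4 distinct time points of one condition
        counts = [[5, 5, 5, 5, 0, 0, 0, 0]]
        data = _container(counts, ["transected"] * 4 + ["sham"] * 4,
                          [0, 1, 2, 3, 0, 1, 2, 3])
        assert len(filter_low_counts(data).counts) == 1

    def test_gene_detected_at_three_timepoints_everywhere_removed(self):
        counts = [[9, 9, 9, 0, 9, 9, 9, 0]]
        data = _container(counts, ["transected"] * 4 + ["sham"] * 4,
                          [0, 1, 2, 3, 0, 1, 2, 3])
        assert len(filter_low_counts(data).counts) == 0

    def test_all_zero_matrix_keeps_no_genes(self):
        data = _container(np.zeros((5, 8), dtype=int),
                          ["transected"] * 8, [0, 1, 2, 3, 4, 5, 6, 7])
        assert len(filter_low_counts(data).counts) == 0

    def test_replicates_count_once_per_timepoint(self):
        # 4 samples at only 2 distinct times: detection at 2 time points only
        counts = [[8, 8, 8, 8]]
        data = _container(counts, ["transected"] * 4, [0, 0, 1, 1])
        assert len(filter_low_counts(data, min_timepoints=3).counts) == 0
        assert len(filter_low_counts(data, min_timepoints=2).counts) == 1

    def test_filter_idempotent(self, small_experiment):
        once = filter_low_counts(small_experiment.counts)
        twice = filter_low_counts(once)
        assert once.counts.equals(twice.counts)


class TestVst:
    def test_identical_samples_identical_columns(self):
        col = [10, 200, 3000, 7, 55]
        data = _container(np.column_stack([col, col]), ["a", "a"], [0, 1])
        norm = vst_normalize(data)
        assert np.allclose(norm.values.iloc[:, 0], norm.values.iloc[:, 1])

    def test_monotone_in_counts(self):
        assert np.all(np.diff(vst_closed_form(np.arange(0, 5000, 7), 0.05, 1.2)) > 0)

    def test_all_zero_sample_rejected(self):
        data = _container([[5, 0], [7, 0]], ["a", "a"], [0, 1])
        with pytest.raises(ValueError, match="all-zero"):
            vst_normalize(data)

    def test_variance_flattening_on_nb_data(self):
        """On NB data with common dispersion across a wide mean grid, the
        SD-vs-mean slope after transform drops below 0.1x the raw slope."""
        rng = np.random.default_rng(0)
        means = np.geomspace(5, 5000, 100)
        phi = 0.05
        counts = rng.negative_binomial(1 / phi, (1 / phi) / (1 / phi + means[:, None]),
                                       size=(100, 50))
        data = _container(counts, ["a"] * 50, list(range(50)))
        norm = vst_normalize(data)
        pre = np.polyfit(counts.mean(1), counts.std(1), 1)[0]
        post = np.polyfit(norm.values.mean(1), norm.values.std(1), 1)[0]
        assert abs(post / pre) <= 0.1

    def test_invariant_to_gene_and_sample_permutation(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(50, size=(20, 10))
        data = _container(counts, ["a"] * 10, list(range(10)))
        norm = vst_normalize(data)
        gp = rng.permutation(20)
        sp = rng.permutation(10)
        permuted = TimeSeriesCounts(counts=data.counts.iloc[gp, sp].copy(),
                                    meta=data.meta.iloc[sp].copy())
        norm_p = vst_normalize(permuted)
        assert np.allclose(norm_p.values.to_numpy(),
                           norm.values.iloc[gp, sp].to_numpy())


class TestSpearmanConsistency:
    def _norm(self, values, meta):
        from chronode import NormalizedMatrix
        return NormalizedMatrix(values=values, method="vst")

    def test_duplicated_column_gives_rho_one(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        vals = pd.DataFrame({"s0": x, "s1": x, "s2": rng.normal(size=30)})
        meta = pd.DataFrame({"condition": "t", "series": "S1",
                             "time_hpt": [0.0, 1.0, 2.0], "batch": "S1"},
                            index=pd.Index(["s0", "s1", "s2"], name="sample_id"))
        rep = spearman_consistency(self._norm(vals, meta), meta)
        assert rep.neighbor_rho[0] == pytest.approx(1.0)

    def test_reversed_ranking_gives_rho_minus_one(self):
        x = np.arange(20.0)
        vals = pd.DataFrame({"s0": x, "s1": x[::-1]})
        meta = pd.DataFrame({"condition": "t", "series": "S1",
                             "time_hpt": [0.0, 1.0], "batch": "S1"},
                            index=pd.Index(["s0", "s1"], name="sample_id"))
        rep = spearman_consistency(self._norm(vals, meta), meta)
        assert rep.neighbor_rho[0] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        """Spearman rho equals ranking both vectors (average ranks for
        ties) and taking the Pearson correlation of the ranks."""
        rng = np.random.default_rng(3)
        for _ in range(30):
            x = rng.integers(0, 10, size=25).astype(float)  # ties likely
            y = rng.integers(0, 10, size=25).astype(float)
            oracle = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
            assert stats.spearmanr(x, y).statistic == pytest.approx(oracle, abs=1e-12)

    def test_replicates_and_overlaps_are_separated(self, small_experiment):
        from chronode import vst_normalize
        norm = vst_normalize(small_experiment.counts)
        rep = spearman_consistency(norm, small_experiment.counts.meta)
        assert all(-1 <= r <= 1 for r in
                   rep.neighbor_rho + rep.overlap_rho + rep.replicate_rho)
        summ = rep.summary()
        assert summ["neighbor_rho"]["n_pairs"] > 0
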