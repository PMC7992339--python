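"""Reading, filtering, imputing, scaling and aligning omics matrices."""

import numpy as np
import pandas as pd
import pytest

from lateomics import omics_io
from lateomics.omics_io import (
    DrugResponseTable,
    OmicsMatrix,
    align_samples,
    filter_cell_lines,
    filter_missing,
    knn_impute,
    read_omics_matrix,
    scale_matrix,
    write_omics_matrix,
)


def _write(tmp_path, text, name="m.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadWrite:
    def test_na_cells_become_missing(self, tmp_path):
        p = _write(tmp_path, "id\tg1\tg2\nA\t1.0\tNA\nB\t2.0\t3.0\nC\t4.0\t5.0\n")
        m = read_omics_matrix(p, "mrna")
        assert m.values.isna().sum().sum() == 1
        assert np.isnan(m.values.loc["A", "g2"])

    def test_non_numeric_cell_reports_address(self, tmp_path):
        p = _write(tmp_path, "id\tg1\nA\t1.0\nB\toops\n")
        with pytest.raises(ValueError, match="'oops'.*row 'B'.*column 'g1'"):
            read_omics_matrix(p, "mrna")

    def test_duplicate_sample_id_rejected(self, tmp_path):
        p = _write(tmp_path, "id\tg1\nA\t1.0\nA\t2.0\n")
        with pytest.raises(ValueError, match="duplicate sample identifier: 'A'"):
            read_omics_matrix(p, "mrna")

    def test_mutation_value_outside_binary_rejected(self, tmp_path):
        p = _write(tmp_path, "id\tg1\nA\t1\nB\t2\n")
        with pytest.raises(ValueError, match="non-binary"):
            read_omics_matrix(p, "mutation")

    def test_round_trip_preserves_values(self, tmp_path, small_matrix):
        p = tmp_path / "round.tsv"
        write_omics_matrix(small_matrix, p)
        back = read_omics_matrix(p, "mrna")
        pd.testing.assert_frame_equal(back.values, small_matrix.values)


class TestFilterMissing:
    def test_complete_matrix_is_identity(self, rng):
        m = OmicsMatrix(pd.DataFrame(rng.standard_normal((5, 4))), "mrna")
        pd.testing.assert_frame_equal(filter_missing(m).values, m.values)

    def test_single_bad_sample_removed(self, rng):
        df = pd.DataFrame(rng.standard_normal((5, 5)))
        df.iloc[2, :3] = np.nan  # 60% missing sample
        out = filter_missing(OmicsMatrix(df, "mrna"), 0.2)
        assert list(out.values.index) == [0, 1, 3, 4]
        assert out.values.shape[1] == 5

    def test_matches_two_pass_recount(self, rng):
        df = pd.DataFrame(rng.standard_normal((50, 40)))
        mask = rng.random((50, 40)) < 0.25
        df = df.mask(mask)
        out = filter_missing(OmicsMatrix(df, "mrna"), 0.2)
        # independent recount: samples first, then features on survivors
        keep_s = [i for i in range(50) if np.isnan(df.iloc[i]).mean() <= 0.2]
        sub = df.iloc[keep_s]
        keep_f = [j for j in range(40) if np.isnan(sub.iloc[:, j]).mean() <= 0.2]
        assert list(out.values.index) == [df.index[i] for i in keep_s]
        assert list(out.values.columns) == [df.columns[j] for j in keep_f]

    def test_all_samples_dropped_is_error(self):
        df = pd.DataFrame(np.full((3, 3), np.nan))
        with pytest.raises(ValueError, match="all samples"):
            filter_missing(OmicsMatrix(df, "mrna"), 0.2)


def _bruteforce_knn_impute(df: pd.DataFrame, k: int) -> pd.DataFrame:
    """Feature-neighbour kNN mean with sklearn's nan-Euclidean scaling."""
    out = df.copy()
    X = df.to_numpy().T  # features x samples
    p, n = X.shape
    for f in range(p):
        for s in range(n):
            if not np.isnan(X[f, s]):
                continue
            dists = []
            for g in range(p):
                if g == f or np.isnan(X[g, s]):
                    continue  # donor must observe sample s
                co = ~np.isnan(X[f]) & ~np.isnan(X[g])
                if not co.any():
                    continue
                d2 = ((X[f, co] - X[g, co]) ** 2).sum() * n / co.sum()
                dists.append((np.sqrt(d2), g))
            dists.sort()
            donors = [g for _, g in dists[:k]]
            out.iat[s, f] = np.mean([X[g, s] for g in donors])
    return out


class TestKnnImpute:
    def test_complete_matrix_is_identity(self, rng):
        m = OmicsMatrix(pd.DataFrame(rng.standard_normal((6, 5))), "mrna")
        pd.testing.assert_frame_equal(knn_impute(m, 2).values, m.values)

    def test_duplicate_column_is_the_nearest_neighbour(self, rng):
        base = rng.standard_normal(6)
        df = pd.DataFrame({"a": base, "b": base, "c": rng.standard_normal(6)})
        df.iat[2, 0] = np.nan
        out = knn_impute(OmicsMatrix(df, "mrna"), 1)
        assert out.values.iat[2, 0] == pytest.approx(base[2])

    def test_matches_bruteforce_oracle(self, small_matrix):
        out = knn_impute(small_matrix, 3)
        oracle = _bruteforce_knn_impute(small_matrix.values, 3)
        pd.testing.assert_frame_equal(out.values, oracle)

    def test_idempotent_on_own_output(self, small_matrix):
        once = knn_impute(small_matrix, 3)
        twice = knn_impute(once, 3)
        pd.testing.assert_frame_equal(twice.values, once.values)

    def test_observed_values_untouched_and_mutation_rebinarized(self, rng):
        df = pd.DataFrame((rng.random((8, 5)) < 0.4).astype(float))
        df.iat[1, 1] = np.nan
        m = OmicsMatrix(df, "mutation")
        out = knn_impute(m, 2)
        obs = (~df.isna()).to_numpy()
        assert np.array_equal(out.values.to_numpy()[obs], df.to_numpy()[obs])
        assert set(np.unique(out.values)) <= {0.0, 1.0}

    def test_k_too_large_is_error(self, small_matrix):
        with pytest.raises(ValueError, match="k="):
            knn_impute(small_matrix, 8)


class TestAlignSamples:
    def _layer(self, ids, rng):
        return OmicsMatrix(
            pd.DataFrame(rng.standard_normal((len(ids), 3)), index=ids), "mrna"
        )

    def test_intersection_of_two_layers(self, rng):
        ds = align_samples(
            {"mrna": self._layer(["A", "B", "C"], rng), "cnv": self._layer(["B", "C", "D"], rng)}
        )
        assert ds.sample_ids == ["B", "C"]
        ds.check_aligned()

    def test_identical_sets_keep_everything(self, rng):
        ds = align_samples({"mrna": self._layer(list("ABC"), rng)})
        assert ds.sample_ids == ["A", "B", "C"]

    def test_six_random_layers_match_bruteforce(self, rng):
        types = ["mrna", "mirna", "protein", "methylation", "mutation", "cnv"]
        pools = [sorted(rng.choice(30, size=20, replace=False)) for _ in types]
        layers = {}
        for t, pool in zip(types, pools):
            ids = [f"S{j}" for j in pool]
            vals = rng.random((len(ids), 3))  # valid for every layer convention
            if t == "mutation":
                vals = (vals < 0.5).astype(float)
            layers[t] = OmicsMatrix(pd.DataFrame(vals, index=ids), t)
        expected = set.intersection(*[{f"S{j}" for j in pool} for pool in pools])
        ds = align_samples(layers)
        assert ds.sample_ids == sorted(expected)

    def test_layer_permutation_gives_same_result(self, rng):
        a = self._layer(list("ABCD"), rng)
        b = self._layer(list("BCDE"), rng)
        d1 = align_samples({"mrna": a, "cnv": b})
        d2 = align_samples({"cnv": b, "mrna": a})
        assert d1.sample_ids == d2.sample_ids

    def test_empty_intersection_reports_counts(self, rng):
        with pytest.raises(ValueError, match="per-input counts"):
            align_samples({"mrna": self._layer(["A"], rng), "cnv": self._layer(["B"], rng)})


class TestFilterCellLines:
    def _dataset(self, ids, rng):
        return align_samples(
            {"mrna": OmicsMatrix(pd.DataFrame(rng.standard_normal((len(ids), 4)), index=ids), "mrna")}
        )

    def test_coverage_boundary(self, rng):
        ids = [f"C{i}" for i in range(3)]
        ic50 = pd.DataFrame(rng.standard_normal((3, 100)), index=ids)
        ic50.iloc[0, :21] = np.nan  # 79% coverage -> dropped
        ic50.iloc[1, :20] = np.nan  # exactly 80% -> kept
        ds, drugs = filter_cell_lines(self._dataset(ids, rng), DrugResponseTable(ic50))
        assert drugs.cell_line_ids == ["C1", "C2"]

    def test_complete_table_is_identity(self, rng):
        ids = [f"C{i}" for i in range(4)]
        ic50 = pd.DataFrame(rng.standard_normal((4, 5)), index=ids)
        _, drugs = filter_cell_lines(self._dataset(ids, rng), DrugResponseTable(ic50))
        pd.testing.assert_frame_equal(drugs.ic50, ic50)

    def test_survivors_match_independent_coverage_count(self, rng):
        ids = [f"C{i}" for i in range(12)]
        ic50 = pd.DataFrame(rng.standard_normal((12, 10)), index=ids)
        mask = rng.random((12, 10)) < 0.3
        ic50 = ic50.mask(mask)
        expected = [i for i in ids if (~ic50.loc[i].isna()).mean() >= 0.8]
        try:
            _, drugs = filter_cell_lines(self._dataset(ids, rng), DrugResponseTable(ic50))
        except ValueError:
            assert not expected
            return
        assert drugs.cell_line_ids == expected


class TestScaleMatrix:
    def test_zscore_moments(self, rng):
        m = OmicsMatrix(pd.DataFrame(rng.standard_normal((30, 4)) * 5 + 2), "mrna")
        out = scale_matrix(m)
        assert np.allclose(out.values.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(out.values.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_constant_feature_becomes_zero(self, rng):
        df = pd.DataFrame({"a": rng.standard_normal(10), "b": np.ones(10)})
        out = scale_matrix(OmicsMatrix(df, "mrna"))
        assert (out.values["b"] == 0).all()

    def test_mirna_log2_zscore_matches_hand_computation(self, rng):
        raw = rng.integers(0, 500, size=(12, 3)).astype(float)
        out = scale_matrix(OmicsMatrix(pd.DataFrame(raw), "mirna"))
        logd = np.log2(raw + 1)
        expected = (logd - logd.mean(axis=0)) / logd.std(axis=0, ddof=1)
        assert np.allclose(out.values.to_numpy(), expected)

    @pytest.mark.parametrize("omics_type", ["protein", "methylation", "cnv", "mutation"])
    def test_source_scaled_layers_pass_through(self, rng, omics_type):
        vals = rng.random((6, 3))
        if omics_type == "mutation":
            vals = (vals < 0.5).astype(float)
        if omics_type == "cnv":
            vals = vals * 2 - 1
        m = OmicsMatrix(pd.DataFrame(vals), omics_type)
        out = scale_matrix(m)
        pd.testing.assert_frame_equal(out.values, m.values)
        assert out.scaling == "source"
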