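import numpy as np
import pandas as pd
import pytest

from scipac.data import (ExpressionMatrix, Phenotype, harmonize_genes,
                         load_expression_matrix, normalize)


def _em(values, obs=None, genes=None, tag="raw_counts"):
    values = np.asarray(values, dtype=float)
    obs = obs or [f"o{i}" for i in range(values.shape[0])]
    genes = genes or [f"g{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(values, obs, genes, tag)


class TestExpressionMatrix:
    def test_rejects_negative_and_nonfinite(self):
        with pytest.raises(ValueError, match="non-negative"):
            _em([[1, -1], [0, 2]])
        with pytest.raises(ValueError, match="finite"):
            _em([[1, np.nan], [0, 2]])

    def test_rejects_duplicate_ids(self):
        with pytest.raises(ValueError, match="duplicate gene ids.*dup"):
            _em([[1, 2], [3, 4]], genes=["dup", "dup"])

    def test_rejects_tiny_matrices(self):
        with pytest.raises(ValueError, match="at least 2"):
            _em([[1, 2]])


class TestLoaders:
    def test_csv_read_back(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("id,g1,g2\nc1,1,2\nc2,3,4\nc3,5,6\n")
        m = load_expression_matrix(path, format="csv")
        assert m.gene_ids == ["g1", "g2"]
        assert m.obs_ids == ["c1", "c2", "c3"]
        assert np.array_equal(m.values, [[1, 2], [3, 4], [5, 6]])

    def test_gene_by_obs_is_transpose_of_obs_by_gene(self, tmp_path):
        (tmp_path / "a.csv").write_text("id,g1,g2\nc1,1,2\nc2,3,4\nc3,5,6\n")
        (tmp_path / "b.csv").write_text("id,c1,c2,c3\ng1,1,3,5\ng2,2,4,6\n")
        a = load_expression_matrix(tmp_path / "a.csv", format="csv")
        b = load_expression_matrix(tmp_path / "b.csv", format="csv",
                                   orientation="gene_by_obs")
        assert a.obs_ids == b.obs_ids and a.gene_ids == b.gene_ids
        assert np.array_equal(a.values, b.values)

    def test_empty_mtx_gives_zero_matrix(self, tmp_path):
        (tmp_path / "x.mtx").write_text(
            "%%MatrixMarket matrix coordinate real general\n3 2 0\n")
        (tmp_path / "x.barcodes.tsv").write_text("c1\nc2\n")
        (tmp_path / "x.features.tsv").write_text("g1\ng2\ng3\n")
        m = load_expression_matrix(tmp_path / "x.mtx", format="mtx")
        assert m.values.shape == (2, 3) and not m.values.any()

    def test_malformed_file_raises(self, tmp_path):
        (tmp_path / "bad.mtx").write_text("%%MatrixMarket matrix\nnot numbers\n")
        (tmp_path / "bad.barcodes.tsv").write_text("c1\n")
        (tmp_path / "bad.features.tsv").write_text("g1\n")
        with pytest.raises((ValueError, Exception)):
            load_expression_matrix(tmp_path / "bad.mtx", format="mtx")

    @pytest.mark.parametrize("writer,fmt", [("write_csv", "csv"), ("write_mtx", "mtx")])
    def test_round_trip(self, tmp_path, rng, writer, fmt):
        m = _em(rng.gamma(1.0, 2.0, size=(5, 4)))
        target = tmp_path / ("m.csv" if fmt == "csv" else "m")
        getattr(m, writer)(target)
        back = load_expression_matrix(
            str(target) if fmt == "csv" else str(target) + ".mtx", format=fmt)
        assert back.obs_ids == m.obs_ids and back.gene_ids == m.gene_ids
        np.testing.assert_allclose(back.values, m.values, rtol=1e-9)


class TestHarmonize:
    def test_intersection_and_order(self):
        sc = _em([[1, 2, 3], [4, 5, 6]], genes=["a", "b", "c"])
        bulk = _em([[1, 2, 3], [4, 6, 5]], genes=["b", "c", "d"])
        sc2, bulk2 = harmonize_genes(sc, bulk)
        assert sc2.gene_ids == bulk2.gene_ids == ["b", "c"]

    def test_zero_variance_bulk_gene_dropped_from_both(self):
        sc = _em([[1, 2, 3], [4, 5, 6]], genes=["a", "b", "c"])
        bulk = _em([[7, 2, 3], [7, 6, 5]], genes=["a", "b", "c"])  # a constant
        sc2, bulk2 = harmonize_genes(sc, bulk)
        assert sc2.gene_ids == bulk2.gene_ids == ["b", "c"]

    def test_disjoint_gene_sets_error(self):
        sc = _em([[1, 2], [3, 4]], genes=["a", "b"])
        bulk = _em([[1, 2], [3, 4]], genes=["c", "d"])
        with pytest.raises(ValueError, match="insufficient shared genes"):
            harmonize_genes(sc, bulk)

    def test_idempotent(self, rng):
        sc = _em(rng.poisson(3, (4, 6)) + 0.0, genes=list("abcdef"))
        bulk = _em(rng.poisson(3, (5, 6)) + 1.0, genes=list("bcdefg")[::-1])
        sc1, bulk1 = harmonize_genes(sc, bulk)
        sc2, bulk2 = harmonize_genes(sc1, bulk1)
        assert sc2.gene_ids == sc1.gene_ids
        np.testing.assert_array_equal(sc2.values, sc1.values)
        np.testing.assert_array_equal(bulk2.values, bulk1.values)


class TestNormalize:
    @pytest.mark.parametrize(
        "row,scale,log,expected",
        [
            ([2, 8], 10, False, [2, 8]),
            ([1, 1], 10, False, [5, 5]),
            ([0, 4], 4, True, [0.0, np.log(5)]),
        ],
    )
    def test_closed_forms(self, row, scale, log, expected):
        m = _em([row, [1, 1]])
        out = normalize(m, scale_total=scale, log_transform=log)
        np.testing.assert_allclose(out.values[0], expected, rtol=1e-12)
        assert out.layer_tag == "normalized"

    def test_preserves_within_observation_ranks(self, rng):
        m = _em(rng.gamma(1.0, 3.0, size=(6, 12)))
        out = normalize(m)
        for before, after in zip(m.values, out.values):
            np.testing.assert_array_equal(np.argsort(before), np.argsort(after))

    def test_zero_total_observation_errors(self):
        m = _em([[0, 0], [1, 2]], obs=["dead", "ok"])
        with pytest.raises(ValueError, match="dead"):
            normalize(m)

    def test_refuses_double_normalization(self):
        m = _em([[1, 2], [3, 4]])
        out = normalize(m)
        with pytest.raises(ValueError, match="raw_counts"):
            normalize(out)


class TestPhenotype:
    def test_binary_needs_both_classes(self):
        with pytest.raises(ValueError, match="both classes"):
            Phenotype("binary", [1, 1, 1])

    def test_survival_needs_an_event(self):
        with pytest.raises(ValueError, match="at least one event"):
            Phenotype("survival", None, time=[1.0, 2.0], event=[0, 0])

    def test_ordinal_levels_inferred(self):
        ph = Phenotype("ordinal", [1, 2, 3, 2])
        assert ph.n_levels == 3
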