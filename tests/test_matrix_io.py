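"""Data model, readers/writers, gene summarization and sample alignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drugresponse import (
    ExpressionMatrix,
    PhenotypePanel,
    align_samples,
    read_expression,
    read_phenotype,
    summarize_duplicate_genes,
    write_expression,
)


class TestExpressionMatrixInvariants:
    def test_duplicate_sample_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate sample"):
            ExpressionMatrix(["g1"], ["a", "a"], np.zeros((1, 2)))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            ExpressionMatrix(["g1"], ["a"], np.array([[np.nan]]))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            ExpressionMatrix(["g1", "g2"], ["a"], np.zeros((1, 1)))


class TestReadWriteExpression:
    def test_tsv_round_trip_exact(self, tiny_expr, tmp_path):
        path = tmp_path / "m.tsv"
        write_expression(tiny_expr, path)
        back = read_expression(path)
        assert back.gene_ids == tiny_expr.gene_ids
        assert back.sample_ids == tiny_expr.sample_ids
        np.testing.assert_array_equal(back.values, tiny_expr.values)

    def test_gct_matches_tsv_payload(self, tiny_expr, tmp_path):
        write_expression(tiny_expr, tmp_path / "m.tsv")
        write_expression(tiny_expr, tmp_path / "m.gct")
        a = read_expression(tmp_path / "m.tsv")
        b = read_expression(tmp_path / "m.gct")
        assert a.gene_ids == b.gene_ids and a.sample_ids == b.sample_ids
        np.testing.assert_array_equal(a.values, b.values)

    def test_duplicate_sample_header_rejected(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text("gene_id\ts1\ts1\ng1\t1.0\t2.0\n")
        with pytest.raises(ValueError, match="duplicate sample"):
            read_expression(p)

    def test_non_numeric_cell_names_location(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("gene_id\ts1\ns1g\toops\n")
        with pytest.raises(ValueError, match="s1g.*s1|oops"):
            read_expression(p)

    def test_empty_matrix_rejected(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("gene_id\ts1\n")
        with pytest.raises(ValueError, match="empty"):
            read_expression(p)

    def test_write_zero_samples_rejected(self, tmp_path):
        m = ExpressionMatrix(["g1"], ["s1"], np.array([[1.0]]))
        m.sample_ids = []  # bypass constructor to simulate a degenerate object
        m.values = np.zeros((1, 0))
        with pytest.raises(ValueError):
            write_expression(m, tmp_path / "x.tsv")

    def test_one_by_one_matrix(self, tmp_path):
        m = ExpressionMatrix(["solo"], ["s1"], np.array([[2.5]]))
        write_expression(m, tmp_path / "solo.tsv")
        lines = (tmp_path / "solo.tsv").read_text().splitlines()
        assert len(lines) == 2 and lines[1].startswith("solo\t")

    @settings(max_examples=25, deadline=None)
    @given(
        n_genes=st.integers(1, 6),
        n_samples=st.integers(1, 5),
        fmt=st.sampled_from(["tsv", "gct"]),
        data=st.data(),
    )
    def test_round_trip_random(self, n_genes, n_samples, fmt, data, tmp_path_factory):
        vals = data.draw(
            st.lists(
                st.lists(
                    st.floats(-50, 50, allow_nan=False, width=32),
                    min_size=n_samples, max_size=n_samples,
                ),
                min_size=n_genes, max_size=n_genes,
            )
        )
        m = ExpressionMatrix(
            [f"g{i}" for i in range(n_genes)],
            [f"s{j}" for j in range(n_samples)],
            np.array(vals, dtype=float),
        )
        path = tmp_path_factory.mktemp("rt") / f"m.{fmt}"
        write_expression(m, path, format=fmt)
        back = read_expression(path, format=fmt)
        assert back.gene_ids == m.gene_ids and back.sample_ids == m.sample_ids
        # identity at the written 6-significant-digit precision
        np.testing.assert_allclose(back.values, m.values, rtol=1e-5, atol=1e-7)


class TestSummarizeDuplicateGenes:
    def test_mean_collapse(self):
        m = ExpressionMatrix(
            ["TP53", "TP53"], ["a", "b"], np.array([[1.0, 3.0], [3.0, 5.0]])
        )
        out = summarize_duplicate_genes(m)
        assert out.gene_ids == ["TP53"]
        np.testing.assert_array_equal(out.values, [[2.0, 4.0]])

    def test_identity_when_unique(self, tiny_expr):
        out = summarize_duplicate_genes(tiny_expr)
        assert out.gene_ids == tiny_expr.gene_ids
        np.testing.assert_array_equal(out.values, tiny_expr.values)

    def test_three_way_mean(self):
        m = ExpressionMatrix(
            ["A", "A", "A"], ["s"], np.array([[0.0], [0.0], [3.0]])
        )
        np.testing.assert_array_equal(
            summarize_duplicate_genes(m).values, [[1.0]]
        )

    def test_first_occurrence_order_and_idempotence(self):
        m = ExpressionMatrix(
            ["B", "A", "B", "C"], ["s"],
            np.array([[1.0], [2.0], [3.0], [4.0]]),
        )
        once = summarize_duplicate_genes(m)
        assert once.gene_ids == ["B", "A", "C"]
        twice = summarize_duplicate_genes(once)
        assert twice.gene_ids == once.gene_ids
        np.testing.assert_array_equal(twice.values, once.values)


class TestReadPhenotype:
    def test_read_with_missing(self, tmp_path):
        p = tmp_path / "ic50.tsv"
        p.write_text(
            "cell_line\tdocetaxel\nc1\t-2.5\nc2\t\nc3\t0.75\nc4\tNA\nc5\t1\n"
        )
        panel = read_phenotype(p)
        assert panel.drug_name == "docetaxel"
        assert panel.n_samples == 5
        assert np.isnan(panel.ic50[1]) and np.isnan(panel.ic50[3])
        assert panel.ic50[0] == -2.5

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text("id\tdrug\nc1\t1\nc1\t2\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_phenotype(p)

    def test_no_rows_rejected(self, tmp_path):
        p = tmp_path / "none.tsv"
        p.write_text("id\tdrug\n")
        with pytest.raises(ValueError, match="no phenotype rows"):
            read_phenotype(p)


class TestAlignSamples:
    def test_intersection_and_order(self):
        expr = ExpressionMatrix(["g"], ["A", "B", "C"], np.array([[1.0, 2.0, 3.0]]))
        pheno = PhenotypePanel("d", ["B", "C", "D"], np.array([1.0, 2.0, 3.0]))
        e2, p2 = align_samples(expr, pheno)
        assert e2.sample_ids == ["B", "C"] == p2.sample_ids
        np.testing.assert_array_equal(e2.values, [[2.0, 3.0]])
        np.testing.assert_array_equal(p2.ic50, [1.0, 2.0])

    def test_missing_ic50_excluded(self, tiny_pheno):
        expr = ExpressionMatrix(
            ["g"], ["s1", "s2", "s3", "s4", "s5"], np.arange(5.0)[None, :]
        )
        e2, p2 = align_samples(expr, tiny_pheno)
        assert "s3" not in e2.sample_ids
        assert np.all(np.isfinite(p2.ic50))

    def test_identical_sets_identity(self):
        expr = ExpressionMatrix(["g"], ["x", "y"], np.array([[1.0, 2.0]]))
        pheno = PhenotypePanel("d", ["x", "y"], np.array([0.0, 1.0]))
        e2, p2 = align_samples(expr, pheno)
        assert e2.sample_ids == ["x", "y"] == p2.sample_ids

    def test_disjoint_sets_error(self):
        expr = ExpressionMatrix(["g"], ["a"], np.array([[1.0]]))
        pheno = PhenotypePanel("d", ["b"], np.array([1.0]))
        with pytest.raises(ValueError, match="no samples"):
            align_samples(expr, pheno)
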