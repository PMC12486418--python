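"""Count-table I/O, rarefaction and taxonomic aggregation."""

import json

import numpy as np
import pytest

from halocline.tables import (
    CountTable,
    TableError,
    TaxonomyTable,
    aggregate_taxonomy,
    rarefy,
    read_biom_table,
    read_count_table,
    to_relative,
    top_n_taxa,
    write_count_table,
)
from .conftest import make_table, random_table


class TestReadWrite:
    def test_round_trip_identity(self, tmp_path):
        t = make_table([[1, 2], [3, 4], [0, 5]])
        path = tmp_path / "counts.tsv"
        write_count_table(t, path)
        back = read_count_table(path)
        assert back.taxon_ids == t.taxon_ids
        assert back.sample_ids == t.sample_ids
        np.testing.assert_array_equal(back.counts, t.counts)

    def test_negative_cell_names_offender(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("id\tS1\tS2\nOTU1\t3\t2\nOTU2\t-4\t1\n")
        with pytest.raises(TableError, match="OTU2.*S1"):
            read_count_table(path)

    def test_non_numeric_cell_names_offender(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("id\tS1\nOTU1\tthree\n")
        with pytest.raises(TableError, match="OTU1.*S1"):
            read_count_table(path)

    def test_duplicate_taxon_id_is_structural_error(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("id\tS1\nOTU1\t3\nOTU1\t2\n")
        with pytest.raises(TableError, match="duplicate taxon id"):
            read_count_table(path)

    def test_transposed_layout(self, tmp_path):
        t = make_table([[1, 2], [3, 4]])
        path = tmp_path / "t.tsv"
        t.to_frame().T.to_csv(path, sep="\t", index_label="sample_id")
        back = read_count_table(path, transposed=True)
        np.testing.assert_array_equal(back.counts, t.counts)

    def test_biom_json_reader(self, tmp_path):
        doc = {
            "rows": [{"id": "OTU1"}, {"id": "OTU2"}],
            "columns": [{"id": "S1"}, {"id": "S2"}, {"id": "S3"}],
            "shape": [2, 3],
            "matrix_type": "sparse",
            "data": [[0, 0, 5], [1, 2, 7]],
        }
        path = tmp_path / "t.biom"
        path.write_text(json.dumps(doc))
        t = read_biom_table(path)
        np.testing.assert_array_equal(t.counts, [[5, 0, 0], [0, 0, 7]])


class TestCountTableInvariants:
    def test_negative_counts_rejected(self):
        with pytest.raises(TableError, match="negative"):
            make_table([[1, -1]])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(TableError):
            CountTable(["a", "b"], ["s"], np.array([[1]]))


class TestRarefy:
    def test_sample_at_exact_depth_unchanged(self):
        t = make_table([[5, 10], [5, 40]])
        r = rarefy(t, 10, seed=0)
        np.testing.assert_array_equal(r.counts[:, 0], [5, 5])
        assert r.sample_totals().tolist() == [10, 10]

    def test_under_depth_samples_dropped(self):
        t = make_table([[5, 3], [5, 2]])
        r = rarefy(t, 10, seed=0)
        assert r.sample_ids == ["S1"]

    def test_all_below_depth_errors(self):
        with pytest.raises(ValueError, match="below"):
            rarefy(make_table([[1], [1]]), 100, seed=0)

    def test_nonpositive_depth_errors(self):
        with pytest.raises(ValueError):
            rarefy(make_table([[5]]), 0, seed=0)

    def test_determinism_and_seed_sensitivity(self, rng):
        t = random_table(rng, n_taxa=30, n_samples=5, lam=40)
        a = rarefy(t, 100, seed=7)
        b = rarefy(t, 100, seed=7)
        c = rarefy(t, 100, seed=8)
        np.testing.assert_array_equal(a.counts, b.counts)
        assert c.sample_totals().tolist() == a.sample_totals().tolist()

    def test_expected_proportions_preserved(self, rng):
        # hypergeometric subsampling is unbiased: mean proportion over
        # replicates matches the original within 3 Monte-Carlo SE
        counts = rng.integers(10, 200, size=(10, 1))
        t = make_table(counts)
        total = int(counts.sum())
        depth = total // 2
        reps = 200
        acc = np.zeros(10)
        for k in range(reps):
            acc += rarefy(t, depth, seed=1000 + k).counts[:, 0] / depth
        mean_prop = acc / reps
        p = counts[:, 0] / total
        se = np.sqrt(p * (1 - p) / depth / reps)
        assert np.all(np.abs(mean_prop - p) <= 3 * se + 1e-12)


class TestToRelative:
    @pytest.mark.parametrize(
        "column, expected",
        [([2, 2], [0.5, 0.5]), ([7, 0, 0], [1, 0, 0]), ([5, 3, 2], [0.5, 0.3, 0.2])],
    )
    def test_columns(self, column, expected):
        t = make_table(np.array(column)[:, None])
        np.testing.assert_allclose(to_relative(t).proportions[:, 0], expected)

    def test_zero_total_sample_named(self):
        with pytest.raises(ValueError, match="S2"):
            to_relative(make_table([[1, 0], [1, 0]]))

    def test_round_trip_with_totals(self, rng):
        t = random_table(rng)
        ra = to_relative(t)
        np.testing.assert_array_equal(
            np.round(ra.proportions * t.sample_totals()), t.counts
        )


class TestAggregateTaxonomy:
    tax = TaxonomyTable(
        {
            "OTU1": ("Bacteria", "Proteobacteria", "Gamma", "Vibrionales", "Vibrionaceae", "Vibrio"),
            "OTU2": ("Bacteria", "Proteobacteria", "Gamma", "Vibrionales", "Vibrionaceae", "Vibrio"),
            "OTU3": ("Bacteria", "Cyanobacteria", "", "", "", ""),
        }
    )

    def test_same_genus_rows_sum(self):
        t = make_table([[3], [4], [1]], taxa=["OTU1", "OTU2", "OTU3"])
        agg = aggregate_taxonomy(t, self.tax, "genus")
        assert agg.counts[agg.taxon_ids.index("Vibrio"), 0] == 7

    def test_missing_rank_pools_under_sentinel(self):
        t = make_table([[3], [4], [1]], taxa=["OTU1", "OTU2", "OTU3"])
        agg = aggregate_taxonomy(t, self.tax, "genus")
        assert "norank_Cyanobacteria" in agg.taxon_ids

    def test_grand_total_conserved(self, rng):
        t = random_table(rng, n_taxa=3, n_samples=4)
        t = make_table(t.counts, taxa=["OTU1", "OTU2", "OTU3"])
        agg = aggregate_taxonomy(t, self.tax, "phylum")
        assert agg.counts.sum() == t.counts.sum()

    def test_finest_rank_all_unique_identity(self):
        tax = TaxonomyTable(
            {"OTU1": ("B", "P1", "c", "o", "f", "g1"), "OTU2": ("B", "P1", "c", "o", "f", "g2")}
        )
        t = make_table([[1], [2]], taxa=["OTU1", "OTU2"])
        assert len(aggregate_taxonomy(t, tax, "genus").taxon_ids) == 2

    def test_unknown_rank_errors(self):
        t = make_table([[1]], taxa=["OTU1"])
        with pytest.raises(ValueError, match="rank"):
            aggregate_taxonomy(t, self.tax, "species")

    def test_missing_taxon_errors(self):
        t = make_table([[1]], taxa=["OTUX"])
        with pytest.raises(TableError, match="OTUX"):
            aggregate_taxonomy(t, self.tax, "genus")


class TestTopN:
    def test_n_larger_than_table_identity(self, small_table):
        assert top_n_taxa(small_table, 10) is small_table

    def test_argmax(self):
        t = make_table([[5], [3], [2]], taxa=["A", "B", "C"])
        assert top_n_taxa(t, 1).taxon_ids == ["A"]

    def test_lexicographic_tie_break(self):
        t = make_table([[5], [5], [2]], taxa=["B", "A", "C"])
        assert top_n_taxa(t, 1).taxon_ids == ["A"]

    def test_original_order_preserved(self):
        t = make_table([[1], [9], [5]], taxa=["x", "y", "z"])
        assert top_n_taxa(t, 2).taxon_ids == ["y", "z"]

    def test_nonpositive_n_errors(self, small_table):
        with pytest.raises(ValueError):
            top_n_taxa(small_table, 0)
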