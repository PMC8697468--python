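import numpy as np
import pandas as pd
import pytest

from kpccf import taxa_io
from kpccf.taxa_io import (
    LineageParseError,
    OtuTable,
    OtuTableError,
    SampleFeatureMatrix,
    TaxonomyLineage,
    aggregate_to_rank,
    attach_labels,
    fuse_metadata,
    parse_lineage,
    read_otu_table,
    write_otu_table,
)
from kpccf.synthetic_data import SyntheticSpec, generate_otu_fixture


class TestParseLineage:
    @pytest.mark.parametrize(
        "raw,rank,expected",
        [
            (
                "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;"
                "f__Lachnospiraceae;g__Blautia",
                "family",
                "Lachnospiraceae",
            ),
            (
                "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;"
                "f__Lachnospiraceae;g__Blautia",
                "genus",
                "Blautia",
            ),
            # empty-name field parses to absent
            (
                "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;"
                "f__Lachnospiraceae;g__",
                "genus",
                None,
            ),
            # truncated lineage: deeper ranks absent
            ("k__Bacteria;p__Bacteroidetes", "family", None),
            ("k__Bacteria;p__Bacteroidetes", "phylum", "Bacteroidetes"),
        ],
    )
    def test_rank_assignment(self, raw, rank, expected):
        assert parse_lineage(raw).get(rank) == expected

    def test_prefixless_fields_assigned_positionally(self):
        lin = parse_lineage("Bacteria;Firmicutes;Clostridia")
        assert lin.get("kingdom") == "Bacteria"
        assert lin.get("class") == "Clostridia"

    def test_unknown_prefix_is_a_parse_error_naming_the_field(self):
        with pytest.raises(LineageParseError, match="x__Oops"):
            parse_lineage("k__Bacteria;x__Oops")

    def test_duplicate_rank_rejected(self):
        with pytest.raises(LineageParseError, match="twice"):
            parse_lineage("k__Bacteria;k__Archaea")

    def test_empty_string_rejected(self):
        with pytest.raises(LineageParseError):
            parse_lineage("   ")


class TestOtuTableIO:
    def test_read_shape_and_counts(self, tmp_path):
        path = tmp_path / "otu.tsv"
        path.write_text(
            "taxonomy\tS1\tS2\tS3\n"
            "k__Bacteria;f__FamA\t3\t0\t1\n"
            "k__Bacteria;f__FamB\t4\t2\t0\n"
        )
        table = read_otu_table(path)
        assert table.counts.shape == (2, 3)
        assert table.sample_ids == ["S1", "S2", "S3"]
        assert table.counts[1, 0] == 4

    def test_duplicate_sample_id_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("taxonomy\tS1\tS1\nk__B;f__F\t1\t2\n")
        with pytest.raises(OtuTableError, match="S1"):
            read_otu_table(path)

    def test_negative_count_rejected(self, tmp_path):
        path = tmp_path / "neg.tsv"
        path.write_text("taxonomy\tS1\tS2\nk__B;f__F\t1\t-2\n")
        with pytest.raises(OtuTableError, match="negative"):
            read_otu_table(path)

    def test_round_trip_preserves_counts_and_lineages(self, otu_table, tmp_path):
        path = tmp_path / "rt.tsv"
        write_otu_table(otu_table, path)
        back = read_otu_table(path)
        np.testing.assert_array_equal(back.counts, otu_table.counts)
        assert [l.to_string() for l in back.lineages] == [
            l.to_string() for l in otu_table.lineages
        ]
        assert back.sample_ids == otu_table.sample_ids


class TestAggregateToRank:
    def test_counts_pool_within_a_family(self):
        lins = [
            parse_lineage("k__B;f__Lachnospiraceae;g__Blautia"),
            parse_lineage("k__B;f__Lachnospiraceae;g__Roseburia"),
        ]
        table = OtuTable(lins, ["S1"], np.array([[3], [4]]))
        mat = aggregate_to_rank(table, "family")
        assert mat.feature_names == ["Lachnospiraceae"]
        assert mat.values[0, 0] == 7

    def test_distinct_families_never_pool(self):
        lins = [parse_lineage("k__B;f__FamA"), parse_lineage("k__B;f__FamB")]
        table = OtuTable(lins, ["S1"], np.array([[3], [4]]))
        mat = aggregate_to_rank(table, "family")
        assert mat.feature_names == ["FamA", "FamB"]
        np.testing.assert_array_equal(mat.values, [[3.0, 4.0]])

    @pytest.mark.parametrize("policy", ["drop", "bucket"])
    def test_feature_count_equals_family_count(self, otu_table, policy):
        mat = aggregate_to_rank(otu_table, "family", unclassified_policy=policy)
        assert len(mat.feature_names) == 5

    def test_conservation_of_total_counts(self, otu_table):
        mat = aggregate_to_rank(otu_table, "family")
        assert mat.values.sum() == otu_table.counts.sum()

    def test_orientation_is_samples_by_features(self, otu_table):
        mat = aggregate_to_rank(otu_table, "family")
        assert mat.values.shape == (otu_table.n_samples, 5)

    def test_row_permutation_invariance(self, otu_table, rng):
        perm = rng.permutation(otu_table.n_otus)
        shuffled = OtuTable(
            [otu_table.lineages[i] for i in perm],
            otu_table.sample_ids,
            otu_table.counts[perm],
        )
        a = aggregate_to_rank(otu_table, "genus")
        b = aggregate_to_rank(shuffled, "genus")
        assert a.feature_names == b.feature_names
        np.testing.assert_array_equal(a.values, b.values)

    def test_drop_policy_excludes_truncated_lineages(self):
        spec = SyntheticSpec(n_samples=10, sparsity=0.0, seed=2)
        table = generate_otu_fixture(spec, n_families=3, otus_per_family=2,
                                     n_truncated=2)
        mat = aggregate_to_rank(table, "family", unclassified_policy="drop")
        truncated_total = table.counts[-2:].sum()
        assert truncated_total > 0
        assert mat.values.sum() == table.counts.sum() - truncated_total

    def test_bucket_policy_keeps_truncated_counts(self):
        spec = SyntheticSpec(n_samples=10, sparsity=0.0, seed=2)
        table = generate_otu_fixture(spec, n_families=3, otus_per_family=2,
                                     n_truncated=2)
        mat = aggregate_to_rank(table, "family", unclassified_policy="bucket")
        assert mat.values.sum() == table.counts.sum()
        assert any(n.startswith("unclassified_") for n in mat.feature_names)

    def test_absent_rank_raises(self):
        table = OtuTable([parse_lineage("k__B;p__P")], ["S1"], np.array([[1]]))
        with pytest.raises(OtuTableError, match="absent"):
            aggregate_to_rank(table, "genus")

    def test_total_sum_scaling_flag(self, otu_table):
        mat = aggregate_to_rank(otu_table, "family", normalize=True)
        sums = mat.values.sum(axis=1)
        np.testing.assert_allclose(sums[sums > 0], 1.0)


def _tiny_matrix():
    return SampleFeatureMatrix(
        ["a", "b", "c"], ["f1", "f2"], np.arange(6, dtype=float).reshape(3, 2)
    )


class TestAttachLabels:
    def test_class_names_sorted(self):
        meta = pd.DataFrame({"DiseaseState": ["H", "CDI", "nonCDI"]},
                            index=["a", "b", "c"])
        ds = attach_labels(_tiny_matrix(), meta)
        assert ds.class_names == ["CDI", "H", "nonCDI"]

    def test_join_is_by_id_not_position(self):
        meta = pd.DataFrame({"DiseaseState": ["H", "CDI", "nonCDI"]},
                            index=["a", "b", "c"])
        shuffled = meta.loc[["c", "a", "b"]]
        ds1 = attach_labels(_tiny_matrix(), meta)
        ds2 = attach_labels(_tiny_matrix(), shuffled)
        assert ds1.labels == ds2.labels
        np.testing.assert_array_equal(ds1.y, ds2.y)

    def test_extra_metadata_rows_ignored(self):
        meta = pd.DataFrame({"DiseaseState": ["H", "CDI", "nonCDI", "H"]},
                            index=["a", "b", "c", "unused"])
        ds = attach_labels(_tiny_matrix(), meta)
        assert len(ds.labels) == 3

    def test_missing_sample_raises_with_ids(self):
        meta = pd.DataFrame({"DiseaseState": ["H", "CDI"]}, index=["a", "b"])
        with pytest.raises(OtuTableError, match="'c'"):
            attach_labels(_tiny_matrix(), meta)

    def test_single_class_rejected(self):
        meta = pd.DataFrame({"DiseaseState": ["H", "H", "H"]},
                            index=["a", "b", "c"])
        with pytest.raises(OtuTableError, match="2 classes"):
            attach_labels(_tiny_matrix(), meta)

    def test_reattachment_is_idempotent(self, labeled_small, metadata_for):
        ds2 = attach_labels(labeled_small.matrix, metadata_for)
        assert ds2.labels == labeled_small.labels
        assert ds2.class_names == labeled_small.class_names


class TestFuseMetadata:
    def test_numeric_plus_onehot_widths(self, labeled_small, metadata_for):
        p = len(labeled_small.matrix.feature_names)
        fused = fuse_metadata(labeled_small, metadata_for, ["age", "gender"])
        # age appends 1 column, gender (M/F) one-hot appends 2
        assert len(fused.matrix.feature_names) == p + 1 + 2

    def test_missing_numeric_imputed_with_median(self, labeled_small, metadata_for):
        meta = metadata_for.copy()
        meta.iloc[0, meta.columns.get_loc("age")] = np.nan
        fused = fuse_metadata(labeled_small, meta, ["age"])
        observed_median = meta["age"].median()
        assert fused.matrix.values[0, -1] == observed_median

    def test_zero_fields_is_identity(self, labeled_small, metadata_for):
        fused = fuse_metadata(labeled_small, metadata_for, [])
        np.testing.assert_array_equal(fused.X, labeled_small.X)
        assert fused.matrix.feature_names == labeled_small.matrix.feature_names

    def test_absent_field_raises(self, labeled_small, metadata_for):
        with pytest.raises(OtuTableError, match="bmi"):
            fuse_metadata(labeled_small, metadata_for, ["bmi"])

    def test_constant_field_dropped_with_warning(self, labeled_small, metadata_for, caplog):
        meta = metadata_for.copy()
        meta["site"] = "clinic_a"
        with caplog.at_level("WARNING", logger="kpccf.taxa_io"):
            fused = fuse_metadata(labeled_small, meta, ["site"])
        assert "constant" in caplog.text
        assert len(fused.matrix.feature_names) == len(labeled_small.matrix.feature_names)


def test_prepare_dataset_end_to_end(tmp_path):
    from kpccf.synthetic_data import generate_metadata
    from kpccf.taxa_io import prepare_dataset, write_otu_table

    spec = SyntheticSpec(n_samples=24, sparsity=0.3, seed=11)
    table = generate_otu_fixture(spec, n_families=4, otus_per_family=3)
    from kpccf.synthetic_data import generate_labeled

    labels = generate_labeled(spec).labels
    meta = generate_metadata(table.sample_ids, labels, seed=1)
    otu_path, meta_path = tmp_path / "otu.tsv", tmp_path / "meta.tsv"
    write_otu_table(table, otu_path)
    meta.to_csv(meta_path, sep="\t")
    ds = prepare_dataset(otu_path, meta_path, rank="family", fuse_fields=["age"])
    assert len(ds.matrix.feature_names) == 4 + 1
    assert len(ds.labels) == 24
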