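"""The view-transform algebra: normalize, log, sort, filter, group, collapse, transpose."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cellpop as cp
from cellpop import transforms as tf
from cellpop.errors import ValidationError

from conftest import small_atlas


class TestNormalize:
    def test_within_sample(self, f1):
        out = cp.normalize(f1, "within_sample")
        assert out.matrix.values.tolist() == [[0.75, 0.25], [0.0, 1.0]]
        assert out.matrix.value_kind == cp.ValueKind.FRACTION_WITHIN_SAMPLE

    def test_within_celltype(self, f1):
        out = cp.normalize(f1, "within_celltype")
        assert np.allclose(out.matrix.values, [[1.0, 1 / 3], [0.0, 2 / 3]])

    def test_none_is_identity(self, f1):
        out = cp.normalize(f1, "none")
        assert out.matrix.values.tolist() == f1.matrix.values.tolist()

    def test_zero_sample_stays_zero(self):
        m = cp.PopulationMatrix(("A", "Z"), ("T", "B"), [[1, 1], [0, 0]])
        ds = cp.Dataset.from_matrix(m)
        out = cp.normalize(ds, "within_sample")
        assert out.matrix.values[1].tolist() == [0.0, 0.0]

    def test_renormalize_rejected(self, f1):
        once = cp.normalize(f1, "within_sample")
        with pytest.raises(ValidationError):
            cp.normalize(once, "within_sample")

    @pytest.mark.parametrize("seed", range(5))
    def test_row_sums_one(self, seed):
        ds, _ = small_atlas(seed)
        out = cp.normalize(ds, "within_sample")
        sums = out.matrix.values.sum(axis=1)
        totals = ds.matrix.values.sum(axis=1)
        assert np.allclose(sums[totals > 0], 1.0, atol=1e-9)

    def test_within_sample_respects_orientation(self, f1):
        flipped = cp.transpose_view(f1)
        out = cp.normalize(flipped, "within_sample")
        # samples are now columns; each sample (column) sums to 1
        assert np.allclose(out.matrix.values.sum(axis=0), 1.0)


class TestLogTransform:
    def test_zero_maps_to_zero(self, f1):
        out = cp.log_transform(f1)
        assert out.matrix.values[1, 0] == 0.0
        assert out.matrix.value_kind == cp.ValueKind.LOG_COUNT

    def test_value_99_base10(self):
        m = cp.PopulationMatrix(("A",), ("T",), [[99]])
        out = cp.log_transform(cp.Dataset.from_matrix(m))
        assert out.matrix.values[0, 0] == pytest.approx(2.0)

    def test_elementwise_oracle(self):
        rng = np.random.default_rng(11)
        vals = rng.integers(0, 500, size=(7, 5)).astype(float)
        ds = cp.Dataset.from_matrix(
            cp.PopulationMatrix(
                tuple(f"s{i}" for i in range(7)), tuple(f"t{j}" for j in range(5)), vals
            )
        )
        out = cp.log_transform(ds, base=2, pseudocount=0.5)
        expected = np.array(
            [[math.log(v + 0.5, 2) for v in row] for row in vals]
        )
        assert np.allclose(out.matrix.values, expected, atol=1e-12)

    def test_monotone(self):
        ds = cp.fixture_f1()
        out = cp.log_transform(ds)
        flat_in = ds.matrix.values.ravel()
        flat_out = out.matrix.values.ravel()
        for i in range(len(flat_in)):
            for j in range(len(flat_in)):
                if flat_in[i] < flat_in[j]:
                    assert flat_out[i] < flat_out[j]

    def test_bad_pseudocount_with_zeros(self, f1):
        with pytest.raises(ValidationError, match="pseudocount"):
            cp.log_transform(f1, pseudocount=0.0)

    def test_fraction_becomes_log_fraction(self, f1):
        out = cp.log_transform(cp.normalize(f1, "within_sample"))
        assert out.matrix.value_kind == cp.ValueKind.LOG_FRACTION


def dsu_oracle(labels, key_funcs):
    """Decorate-sort-undecorate comparison oracle for multi-key sorting."""
    decorated = [(tuple(k(lab) for k in key_funcs), i, lab) for i, lab in enumerate(labels)]
    decorated.sort(key=lambda t: (t[0], t[1]))
    return [lab for _, _, lab in decorated]


class TestSort:
    def test_total_count_descending(self, f1):
        out = cp.sort(f1, [cp.SortKey(axis="rows", kind=cp.SortKind.TOTAL_COUNT, direction="descending")])
        assert out.matrix.row_labels == ("A", "B")
        flipped = cp.sort(f1, [cp.SortKey(axis="rows", kind=cp.SortKind.TOTAL_COUNT, direction="ascending")])
        assert flipped.matrix.row_labels == ("B", "A")

    def test_alphabetical(self):
        m = cp.PopulationMatrix(("b", "a", "c"), ("T",), [[1], [2], [3]])
        ds = cp.Dataset.from_matrix(m)
        out = cp.sort(ds, [cp.SortKey(axis="rows", kind=cp.SortKind.ALPHABETICAL)])
        assert out.matrix.row_labels == ("a", "b", "c")
        assert out.matrix.values.ravel().tolist() == [2, 1, 3]

    def test_multi_key_matches_dsu_oracle(self):
        rng = np.random.default_rng(5)
        n = 50
        labels = tuple(f"s{i:02d}" for i in range(n))
        vals = rng.integers(0, 30, size=(n, 3)).astype(float)
        ages = rng.integers(20, 40, size=n).astype(float)
        meta = cp.MetadataTable(pd.DataFrame({"age": ages}, index=pd.Index(labels)))
        ds = cp.Dataset(
            cp.PopulationMatrix(labels, ("x", "y", "z"), vals), meta,
            cp.MetadataTable.empty(["x", "y", "z"]),
        )
        out = cp.sort(
            ds,
            [
                cp.SortKey(axis="rows", kind=cp.SortKind.METADATA_FIELD, field="age"),
                cp.SortKey(axis="rows", kind=cp.SortKind.TOTAL_COUNT, direction="descending"),
            ],
        )
        age_of = dict(zip(labels, ages))
        tot_of = dict(zip(labels, vals.sum(axis=1)))
        expected = dsu_oracle(labels, [lambda l: age_of[l], lambda l: -tot_of[l]])
        assert list(out.matrix.row_labels) == expected

    def test_permutation_property(self, atlas):
        ds, _ = atlas
        out = cp.sort(ds, [cp.SortKey(axis="rows", kind=cp.SortKind.ALPHABETICAL, direction="descending"),
                           cp.SortKey(axis="cols", kind=cp.SortKind.TOTAL_COUNT)])
        before = {(r, c): ds.matrix.values[i, j]
                  for i, r in enumerate(ds.matrix.row_labels)
                  for j, c in enumerate(ds.matrix.col_labels)}
        after = {(r, c): out.matrix.values[i, j]
                 for i, r in enumerate(out.matrix.row_labels)
                 for j, c in enumerate(out.matrix.col_labels)}
        assert before == after

    def test_missing_metadata_sorts_last_both_directions(self):
        labels = ("a", "b", "c")
        meta = cp.MetadataTable(
            pd.DataFrame({"age": [30.0, None, 10.0]}, index=pd.Index(labels))
        )
        ds = cp.Dataset(
            cp.PopulationMatrix(labels, ("T",), [[1], [1], [1]]), meta,
            cp.MetadataTable.empty(["T"]),
        )
        asc = cp.sort(ds, [cp.SortKey(axis="rows", kind=cp.SortKind.METADATA_FIELD, field="age")])
        desc = cp.sort(ds, [cp.SortKey(axis="rows", kind=cp.SortKind.METADATA_FIELD, field="age", direction="descending")])
        assert asc.matrix.row_labels == ("c", "a", "b")
        assert desc.matrix.row_labels == ("a", "c", "b")

    def test_hierarchy_order_depth_first_siblings_alpha(self, atlas):
        ds, _ = atlas
        out = cp.sort(ds, [cp.SortKey(axis="cols", kind=cp.SortKind.HIERARCHY)])
        assert list(out.matrix.col_labels) == ds.hierarchy.order_labels(ds.matrix.col_labels)

    def test_missing_field_rejected(self, f1):
        with pytest.raises(ValidationError, match="nope"):
            cp.sort(f1, [cp.SortKey(axis="rows", kind=cp.SortKind.METADATA_FIELD, field="nope")])

    def test_hierarchy_key_without_hierarchy_rejected(self, f1):
        ds = f1.replace(hierarchy=None)
        with pytest.raises(ValidationError, match="hierarchy"):
            cp.sort(ds, [cp.SortKey(axis="cols", kind=cp.SortKind.HIERARCHY)])


class TestFilter:
    def test_keep_values(self, f1):
        spec = cp.FilterSpec(axis="rows", field="disease", mode=cp.FilterMode.KEEP_VALUES, values={"covid"})
        out = cp.filter_dataset(f1, spec)
        assert out.matrix.row_labels == ("A",)
        assert out.sample_meta.entity_ids == ("A",)

    def test_numeric_range_identity(self):
        labels = ("a", "b")
        meta = cp.MetadataTable(pd.DataFrame({"age": [30.0, 50.0]}, index=pd.Index(labels)))
        ds = cp.Dataset(
            cp.PopulationMatrix(labels, ("T",), [[1], [2]]), meta,
            cp.MetadataTable.empty(["T"]),
        )
        out = cp.filter_dataset(ds, cp.FilterSpec(axis="rows", field="age", mode=cp.FilterMode.NUMERIC_RANGE, values=(0, 200)))
        assert out.matrix.row_labels == labels

    def test_missing_dropped_under_keep_kept_under_drop(self):
        labels = ("a", "b")
        meta = cp.MetadataTable(pd.DataFrame({"disease": ["covid", None]}, index=pd.Index(labels)))
        ds = cp.Dataset(
            cp.PopulationMatrix(labels, ("T",), [[1], [2]]), meta,
            cp.MetadataTable.empty(["T"]),
        )
        kept = cp.filter_dataset(ds, cp.FilterSpec(axis="rows", field="disease", mode=cp.FilterMode.KEEP_VALUES, values={"covid"}))
        assert kept.matrix.row_labels == ("a",)
        dropped = cp.filter_dataset(ds, cp.FilterSpec(axis="rows", field="disease", mode=cp.FilterMode.DROP_VALUES, values={"covid"}))
        assert dropped.matrix.row_labels == ("b",)

    def test_random_filter_matches_set_oracle(self):
        rng = np.random.default_rng(99)
        for trial in range(10):
            ds, _ = small_atlas(seed=trial)
            cats = ds.sample_meta.df["disease"]
            keep = {"covid", "fibrosis"}
            out = cp.filter_dataset(
                ds, cp.FilterSpec(axis="rows", field="disease", mode=cp.FilterMode.KEEP_VALUES, values=keep)
            )
            oracle = {s for s in ds.matrix.row_labels if cats[s] in keep}
            assert set(out.matrix.row_labels) == oracle
            # survivor order preserved
            assert list(out.matrix.row_labels) == [s for s in ds.matrix.row_labels if s in oracle]

    def test_sequential_keep_equals_intersection(self, atlas):
        ds, _ = atlas
        mk = lambda vals: cp.FilterSpec(axis="rows", field="disease", mode=cp.FilterMode.KEEP_VALUES, values=vals)
        seq = cp.filter_dataset(cp.filter_dataset(ds, mk({"covid", "normal"})), mk({"covid", "fibrosis"}))
        once = cp.filter_dataset(ds, mk({"covid"}))
        assert seq.matrix.row_labels == once.matrix.row_labels
        assert np.array_equal(seq.matrix.values, once.matrix.values)

    def test_absent_field_rejected(self, f1):
        with pytest.raises(ValidationError, match="organ"):
            cp.filter_dataset(f1, cp.FilterSpec(axis="rows", field="organ", mode=cp.FilterMode.KEEP_VALUES, values={"lung"}))


class TestGroupBy:
    def test_sum_by_category(self):
        labels = ("A", "B", "C")
        meta = cp.MetadataTable(pd.DataFrame({"donor": ["d1", "d1", "d2"]}, index=pd.Index(labels)))
        ds = cp.Dataset(
            cp.PopulationMatrix(labels, ("T", "X"), [[1, 0], [2, 2], [5, 1]]), meta,
            cp.MetadataTable.empty(["T", "X"]),
        )
        out = cp.group_by(ds, "rows", "donor")
        assert out.matrix.row_labels == ("d1", "d2")
        assert out.matrix.values.tolist() == [[3, 2], [5, 1]]
        assert out.sample_meta.fields == ("donor",)

    def test_single_category_gives_column_totals(self, f1):
        meta = cp.MetadataTable(pd.DataFrame({"k": ["all", "all"]}, index=pd.Index(["A", "B"])))
        ds = f1.replace(sample_meta=meta)
        out = cp.group_by(ds, "rows", "k")
        assert out.matrix.values.tolist() == [[3, 3]]

    def test_random_accumulation_oracle_and_conservation(self):
        for seed in range(8):
            ds, _ = small_atlas(seed=seed)
            out = cp.group_by(ds, "rows", "disease")
            acc = {}
            for i, s in enumerate(ds.matrix.row_labels):
                cat = ds.sample_meta.df.loc[s, "disease"]
                acc.setdefault(cat, np.zeros(len(ds.matrix.col_labels)))
                acc[cat] += ds.matrix.values[i]
            for i, cat in enumerate(out.matrix.row_labels):
                assert np.array_equal(out.matrix.values[i], acc[cat])
            assert out.matrix.grand_total() == ds.matrix.grand_total()

    def test_numeric_field_rejected(self, atlas):
        ds, _ = atlas
        with pytest.raises(ValidationError, match="numeric"):
            cp.group_by(ds, "rows", "age")

    def test_normalized_matrix_rejected(self, f1):
        with pytest.raises(ValidationError):
            cp.group_by(cp.normalize(f1, "within_sample"), "rows", "disease")


class TestCollapseToDepth:
    def test_collapse_to_root(self, f1):
        out = cp.collapse_to_depth(f1, 0)
        assert out.matrix.col_labels == ("lymphocyte",)
        assert out.matrix.values.ravel().tolist() == [4, 2]

    def test_depth_beyond_max_is_identity_up_to_order(self, atlas):
        ds, _ = atlas
        out = cp.collapse_to_depth(ds, 10)
        assert set(out.matrix.col_labels) == set(ds.matrix.col_labels)
        a = out.matrix.to_dataframe().sort_index(axis=1)
        b = ds.matrix.to_dataframe().sort_index(axis=1)
        pd.testing.assert_frame_equal(a, b)

    def test_ancestor_walk_oracle(self):
        for seed in range(8):
            ds, _ = small_atlas(seed=seed, hierarchy_depth=3, branching=3, n_celltypes=9)
            out = cp.collapse_to_depth(ds, 1)
            oracle = {}
            for j, ct in enumerate(ds.matrix.col_labels):
                # walk the ancestor chain by hand
                chain = [ct]
                cur = ct
                while cur in ds.hierarchy.parent:
                    cur = ds.hierarchy.parent[cur]
                    chain.append(cur)
                chain.reverse()
                anc = ct if len(chain) - 1 <= 1 else chain[1]
                oracle.setdefault(anc, np.zeros(len(ds.matrix.row_labels)))
                oracle[anc] += ds.matrix.values[:, j]
            assert set(out.matrix.col_labels) == set(oracle)
            for j, anc in enumerate(out.matrix.col_labels):
                assert np.array_equal(out.matrix.values[:, j], oracle[anc])
            assert out.matrix.grand_total() == ds.matrix.grand_total()

    def test_no_hierarchy_rejected(self, f1):
        with pytest.raises(ValidationError, match="hierarchy"):
            cp.collapse_to_depth(f1.replace(hierarchy=None), 0)


class TestTranspose:
    def test_values_and_orientation(self, f1):
        out = cp.transpose_view(f1)
        assert out.matrix.values.tolist() == [[3, 0], [1, 2]]
        assert out.matrix.orientation == cp.Orientation.CELLTYPES_AS_ROWS
        assert out.matrix.sample_labels == f1.matrix.sample_labels

    def test_involution(self, atlas):
        ds, _ = atlas
        back = cp.transpose_view(cp.transpose_view(ds))
        assert back.matrix.row_labels == ds.matrix.row_labels
        assert back.matrix.col_labels == ds.matrix.col_labels
        assert np.array_equal(back.matrix.values, ds.matrix.values)
        assert back.matrix.orientation == ds.matrix.orientation

    def test_exhaustive_index_check(self, atlas):
        ds, _ = atlas
        out = cp.transpose_view(ds)
        for i in range(len(ds.matrix.row_labels)):
            for j in range(len(ds.matrix.col_labels)):
                assert out.matrix.values[j, i] == ds.matrix.values[i, j]


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_pipeline_conserves_counts_property(seed):
    """Group + collapse keep the grand total exactly for any atlas seed."""
    ds, gt = small_atlas(seed=seed % 1000)
    total = gt.counts.sum()
    grouped = cp.group_by(ds, "rows", "disease")
    collapsed = cp.collapse_to_depth(grouped, 0)
    assert collapsed.matrix.grand_total() == total
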