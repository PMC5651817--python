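"""Abundance-table IO, taxonomic aggregation, and equilibrium estimation."""

import numpy as np
import pandas as pd
import pytest

from glvnet import (
    AbundanceTable,
    SampleMetadata,
    aggregate_taxa,
    estimate_equilibrium,
    read_metadata,
    read_table,
    relative_abundance,
    subject_trajectories,
    write_table,
)

SEVEN_PHYLA = (
    "Actinobacteria", "Bacteroidetes", "Cyanobacteria", "Firmicutes",
    "Proteobacteria", "Tenericutes", "Verrucomicrobia",
)


def table_from(lineages, samples, values, is_relative=False):
    return AbundanceTable(
        taxa=tuple(lineages), lineages=tuple(lineages),
        samples=tuple(samples), values=np.asarray(values, dtype=float),
        is_relative=is_relative,
    )


def random_table(rng, n_taxa=5, n_samples=8):
    lineages = [f"k__Bacteria;p__P{i};g__G{i}" for i in range(n_taxa)]
    values = rng.integers(0, 500, size=(n_taxa, n_samples)).astype(float)
    return table_from(lineages, [f"s{j}" for j in range(n_samples)], values)


class TestReadWrite:
    def test_tsv_round_trip(self, tmp_path):
        t = table_from(
            ["k__Bacteria;p__Firmicutes", "k__Bacteria;p__Bacteroidetes"],
            ["m1_w3", "m1_w4"],
            [[10, 20], [30, 40]],
        )
        p = tmp_path / "table.tsv"
        write_table(t, p)
        back = read_table(p)
        assert back.lineages == t.lineages
        assert back.samples == t.samples
        np.testing.assert_array_equal(back.values, t.values)
        assert back.is_relative is False

    def test_all_zero_sample_accepted(self, tmp_path):
        p = tmp_path / "z.tsv"
        p.write_text("taxonomy\ts1\ts2\np__A\t3\t0\np__B\t1\t0\n")
        t = read_table(p)
        np.testing.assert_array_equal(t.values[:, 1], [0, 0])

    def test_malformed_cell_cites_row_and_column(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("taxonomy\ts1\ns_x\toops\n")
        with pytest.raises(ValueError, match=r"row 2.*'s1'"):
            read_table(p)

    def test_ragged_row_rejected(self, tmp_path):
        p = tmp_path / "ragged.tsv"
        p.write_text("taxonomy\ts1\ts2\np__A\t1\t2\t3\n")
        with pytest.raises(ValueError, match="ragged row 2"):
            read_table(p)

    def test_negative_value_rejected(self, tmp_path):
        p = tmp_path / "neg.tsv"
        p.write_text("taxonomy\ts1\np__A\t-1\n")
        with pytest.raises(ValueError, match="negative"):
            read_table(p)

    def test_proportions_detected(self, tmp_path):
        p = tmp_path / "rel.tsv"
        p.write_text("taxonomy\ts1\np__A\t0.25\np__B\t0.75\n")
        assert read_table(p).is_relative is True

    def test_biom_json_sparse(self, tmp_path):
        import json

        doc = {
            "rows": [
                {"id": "otu1", "metadata": {"taxonomy": ["k__Bacteria",
                                                         "p__Firmicutes"]}},
                {"id": "otu2", "metadata": None},
            ],
            "columns": [{"id": "s1"}, {"id": "s2"}],
            "shape": [2, 2],
            "matrix_type": "sparse",
            "data": [[0, 0, 5.0], [1, 1, 3.0]],
        }
        p = tmp_path / "t.biom"
        p.write_text(json.dumps(doc))
        t = read_table(p, format="biom-json")
        assert t.lineages[0] == "k__Bacteria;p__Firmicutes"
        np.testing.assert_array_equal(t.values, [[5, 0], [0, 3]])


class TestAggregate:
    def test_two_genera_sum_within_phylum(self):
        t = table_from(
            ["k__Bacteria;p__Firmicutes;g__Lactobacillus",
             "k__Bacteria;p__Firmicutes;g__Clostridium"],
            ["s1"], [[5], [7]],
        )
        agg = aggregate_taxa(t, "phylum")
        assert agg.taxa == ("Firmicutes",)
        np.testing.assert_array_equal(agg.values, [[12]])

    def test_seven_phyla_labels(self):
        lineages = [f"k__Bacteria;p__{p};g__g{i}"
                    for i, p in enumerate(SEVEN_PHYLA)]
        t = table_from(lineages, ["s1"], [[1]] * 7)
        agg = aggregate_taxa(t, "phylum")
        assert agg.taxa == SEVEN_PHYLA

    def test_unlabeled_pooled_as_unclassified(self):
        t = table_from(
            ["k__Bacteria;p__Firmicutes", "k__Bacteria", "k__Bacteria;p__"],
            ["s1"], [[1], [2], [3]],
        )
        agg = aggregate_taxa(t, "phylum")
        assert set(agg.taxa) == {"Firmicutes", "unclassified"}
        assert dict(zip(agg.taxa, agg.values[:, 0]))["unclassified"] == 5

    def test_bare_labels_fall_back_to_requested_rank(self):
        t = table_from(["Firmicutes", "Bacteroidetes"], ["s1"], [[1], [2]])
        agg = aggregate_taxa(t, "phylum")
        assert agg.taxa == ("Firmicutes", "Bacteroidetes")

    def test_missing_rank_everywhere_raises(self):
        t = table_from(["k__Bacteria;p__Firmicutes"], ["s1"], [[1]])
        with pytest.raises(ValueError, match="species"):
            aggregate_taxa(t, "species")

    def test_conserves_column_sums(self, rng):
        t = random_table(rng)
        agg = aggregate_taxa(t, "phylum")
        np.testing.assert_array_equal(
            agg.values.sum(axis=0), t.values.sum(axis=0)
        )

    def test_commutes_with_relative_abundance(self, rng):
        t = random_table(rng)
        a = relative_abundance(aggregate_taxa(t, "phylum"), floor=0.0)
        b = aggregate_taxa(relative_abundance(t, floor=0.0), "phylum")
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)


class TestRelativeAbundance:
    def test_simple_proportions(self):
        t = table_from(["p__A", "p__B"], ["s1"], [[3], [1]])
        rel = relative_abundance(t, floor=0.0)
        np.testing.assert_allclose(rel.values[:, 0], [0.75, 0.25])

    def test_floor_keeps_zeros_positive(self):
        t = table_from(["p__A", "p__B"], ["s1"], [[1], [0]])
        rel = relative_abundance(t, floor=1e-4)
        assert np.all(rel.values > 0)
        assert rel.values[:, 0].sum() == pytest.approx(1.0)

    def test_all_zero_column_with_zero_floor_raises(self):
        t = table_from(["p__A"], ["s1"], [[0]])
        with pytest.raises(ValueError, match="all-zero"):
            relative_abundance(t, floor=0.0)

    def test_columns_sum_to_one(self, rng):
        rel = relative_abundance(random_table(rng))
        np.testing.assert_allclose(
            rel.values.sum(axis=0), 1.0, atol=1e-12
        )
        assert rel.is_relative


def meta_frame(rows):
    return SampleMetadata(
        frame=pd.DataFrame(
            rows, columns=["subject", "week", "group"],
            index=pd.Index([f"s{i}" for i in range(len(rows))], name="sample"),
        )
    )


class TestEstimateEquilibrium:
    def make_rel(self, cols):
        t = table_from(["p__A", "p__B"], [f"s{i}" for i in range(len(cols))],
                       np.array(cols).T, is_relative=True)
        return t

    def test_identical_samples_give_that_column(self):
        rel = self.make_rel([[0.3, 0.7], [0.3, 0.7]])
        meta = meta_frame([("m1", 3, "ctl"), ("m2", 4, "ctl")])
        eq = estimate_equilibrium(rel, meta, "ctl", (3, 15))
        np.testing.assert_allclose(eq.y_bar, [0.3, 0.7])

    def test_hand_mean(self):
        rel = self.make_rel([[0.2, 0.8], [0.4, 0.6]])
        meta = meta_frame([("m1", 3, "ctl"), ("m1", 4, "ctl")])
        eq = estimate_equilibrium(rel, meta, "ctl", (3, 15))
        np.testing.assert_allclose(eq.y_bar, [0.3, 0.7])

    def test_out_of_window_sample_is_noop(self):
        rel3 = self.make_rel([[0.2, 0.8], [0.4, 0.6], [0.9, 0.1]])
        meta3 = meta_frame(
            [("m1", 10, "ctl"), ("m1", 11, "ctl"), ("m1", 3, "ctl")]
        )
        eq = estimate_equilibrium(rel3, meta3, "ctl", (9, 15))
        np.testing.assert_allclose(eq.y_bar, [0.3, 0.7])

    def test_empty_window_raises(self):
        rel = self.make_rel([[0.2, 0.8], [0.4, 0.6]])
        meta = meta_frame([("m1", 3, "ctl"), ("m1", 4, "ctl")])
        with pytest.raises(ValueError, match="found 0"):
            estimate_equilibrium(rel, meta, "ctl", (9, 15))

    def test_requires_relative_table(self):
        t = table_from(["p__A"], ["s0"], [[5.0]])
        meta = meta_frame([("m1", 3, "ctl")])
        with pytest.raises(ValueError, match="relative"):
            estimate_equilibrium(t, meta, "ctl", (3, 15))

    def test_sample_order_equivariance(self, rng):
        values = rng.dirichlet(np.ones(3), size=6).T
        samples = [f"s{i}" for i in range(6)]
        rows = [("m1", 3 + i, "ctl") for i in range(6)]
        t1 = table_from(["p__A", "p__B", "p__C"], samples, values,
                        is_relative=True)
        meta = meta_frame(rows)
        perm = rng.permutation(6)
        t2 = AbundanceTable(
            taxa=t1.taxa, lineages=t1.lineages,
            samples=tuple(np.array(samples)[perm]), values=values[:, perm],
            is_relative=True,
        )
        eq1 = estimate_equilibrium(t1, meta, "ctl", (3, 15))
        eq2 = estimate_equilibrium(t2, meta, "ctl", (3, 15))
        np.testing.assert_allclose(eq1.y_bar, eq2.y_bar, atol=1e-15)


class TestSubjectTrajectories:
    def test_grouping_and_week_ordering(self, tmp_path):
        values = np.array([
            [0.2, 0.4, 0.1, 0.5],
            [0.8, 0.6, 0.9, 0.5],
        ])
        t = table_from(["p__A", "p__B"], ["a_w4", "a_w3", "b_w3", "b_w4"],
                       values, is_relative=True)
        meta = SampleMetadata(
            frame=pd.DataFrame(
                [("a", 4, "g"), ("a", 3, "g"), ("b", 3, "g"), ("b", 4, "g")],
                columns=["subject", "week", "group"],
                index=pd.Index(["a_w4", "a_w3", "b_w3", "b_w4"],
                               name="sample"),
            )
        )
        trajs = subject_trajectories(t, meta, "g")
        assert len(trajs) == 2
        np.testing.assert_array_equal(trajs[0].times, [3, 4])
        np.testing.assert_allclose(trajs[0].states[:, 0], [0.4, 0.2])


class TestMetadata:
    def test_read_metadata_tsv(self, tmp_path):
        p = tmp_path / "meta.tsv"
        p.write_text("sample\tsubject\tweek\tgroup\ns1\tm1\t3\tctl\n")
        meta = read_metadata(p)
        assert meta.frame.loc["s1", "group"] == "ctl"

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="week"):
            SampleMetadata(frame=pd.DataFrame({"subject": [], "group": []}))
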