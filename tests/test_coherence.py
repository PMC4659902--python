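import numpy as np
import pandas as pd
import pytest

from rivercoherence.coherence import (
    CoherencePartition,
    class_abundance,
    flag_dominant_otus,
    partition_class,
    positive_fraction,
    subgroup_summary,
    subgroup_taxonomy,
)
from rivercoherence.datatypes import Lineage, OtuTable, TaxonomyMap
from tests.conftest import tree_from


def make_tax(assignments: dict[str, tuple[str, str | None]]) -> TaxonomyMap:
    return TaxonomyMap(
        {
            o: Lineage("Bacteria", "P", cls, order)
            for o, (cls, order) in assignments.items()
        }
    )


class TestClassAbundance:
    def test_single_otu_class(self):
        t = OtuTable(["a", "b"], ["s1", "s2"], np.array([[1, 2], [5, 5]]))
        tax = make_tax({"a": ("X", None), "b": ("Y", None)})
        assert class_abundance(t, tax, "X").tolist() == [1, 2]

    def test_additivity(self):
        t = OtuTable(["a", "b"], ["s1", "s2", "s3"], np.array([[1, 2, 3], [0, 1, 0]]))
        tax = make_tax({"a": ("X", None), "b": ("X", None)})
        assert class_abundance(t, tax, "X").tolist() == [1, 3, 3]

    def test_conservation_over_classes(self, small_bundle):
        b = small_bundle
        total = np.zeros(len(b.table.sample_ids))
        for cls in b.taxonomy.classes():
            total += class_abundance(b.table, b.taxonomy, cls)
        unassigned = [o for o in b.table.otu_ids if b.taxonomy.class_of(o) is None]
        total += b.table.subset_otus(unassigned).counts.sum(axis=0)
        assert np.array_equal(total.astype(int), b.table.sample_sums())

    def test_unknown_label_rejected(self, small_bundle):
        with pytest.raises(KeyError, match="Nonexistent"):
            class_abundance(small_bundle.table, small_bundle.taxonomy, "Nonexistent")


class TestDominantOtus:
    def test_strictly_above_threshold(self):
        counts = np.concatenate([[11], np.full(100, 1)])
        pad = 10000 - counts.sum()
        counts = np.concatenate([counts, [pad]])
        t = OtuTable([f"o{i}" for i in range(len(counts))], ["s"], counts[:, None])
        dom = flag_dominant_otus(t)
        assert "o0" in dom  # 11 / 10000 = 0.11 % > 0.1 %

    def test_exact_threshold_not_dominant(self):
        counts = np.array([10, 9990])
        t = OtuTable(["edge", "bulk"], ["s"], counts[:, None])
        assert "edge" not in flag_dominant_otus(t)  # exactly 0.1 %, strict >

    def test_scale_free(self, small_bundle):
        t = small_bundle.table
        doubled = OtuTable(list(t.otu_ids), list(t.sample_ids), t.counts * 2)
        assert flag_dominant_otus(t) == flag_dominant_otus(doubled)


class TestPartitionClass:
    def test_single_otu_class_positive_r_one(self):
        t = OtuTable(
            ["a", "b"],
            [f"s{i}" for i in range(6)],
            np.array([[1, 5, 2, 8, 3, 9], [1, 1, 1, 1, 1, 2]]),
        )
        tax = make_tax({"a": ("X", None), "b": ("Y", None)})
        part = partition_class(t, tax, "X")
        rec = part.records.iloc[0]
        assert rec["pearson_r"] == pytest.approx(1.0)
        assert rec["verdict"] == "positive"

    def test_constant_otu_untestable(self):
        t = OtuTable(
            ["a", "b"],
            [f"s{i}" for i in range(6)],
            np.array([[2, 2, 2, 2, 2, 2], [1, 5, 2, 8, 3, 9]]),
        )
        tax = make_tax({"a": ("X", None), "b": ("X", None)})
        part = partition_class(t, tax, "X")
        verdicts = dict(zip(part.records["otu_id"], part.records["verdict"]))
        assert verdicts["a"] == "untestable"

    def test_mirror_otu_negative(self):
        """A class whose total is held constant by an exactly mirrored OTU
        yields a negative verdict for the mirror."""
        rng = np.random.default_rng(0)
        n = 32
        x = rng.integers(10, 200, n)
        y = rng.integers(10, 200, n)
        mirror = 500 - x - y  # class total constant at 500
        t = OtuTable(
            ["x", "y", "mirror"],
            [f"s{i}" for i in range(n)],
            np.vstack([x, y, mirror]),
        )
        tax = make_tax({o: ("X", None) for o in ["x", "y", "mirror"]})
        part = partition_class(t, tax, "X", self_inclusion=False)
        verdicts = dict(zip(part.records["otu_id"], part.records["verdict"]))
        assert verdicts["mirror"] == "negative"

    def test_exhaustive_and_exclusive(self, small_bundle):
        b = small_bundle
        part = partition_class(b.table, b.taxonomy, "ClassA")
        n_class = sum(1 for o in b.table.otu_ids if b.taxonomy.class_of(o) == "ClassA")
        assert len(part.records) == n_class
        assert part.records["verdict"].isin(
            ["positive", "negative", "nonsignificant", "untestable"]
        ).all()

    def test_bonferroni_family_monotonicity(self, small_bundle):
        """Enlarging the correction family can only demote significance."""
        b = small_bundle
        within = partition_class(b.table, b.taxonomy, "ClassA", family="within_class")
        global_ = partition_class(
            b.table, b.taxonomy, "ClassA", family="global", family_size=10_000
        )
        w = within.records.set_index("otu_id")["verdict"]
        g = global_.records.set_index("otu_id")["verdict"]
        for otu in w.index:
            if g[otu] in ("positive", "negative"):
                assert w[otu] == g[otu]

    def test_too_few_samples_rejected(self):
        t = OtuTable(["a"], ["s1", "s2", "s3"], np.array([[1, 2, 3]]))
        tax = make_tax({"a": ("X", None)})
        with pytest.raises(ValueError, match=">= 4 samples"):
            partition_class(t, tax, "X")


def build_partition(class_label, verdict_counts, pooled_counts):
    """Construct a partition and matching one-sample table from printed
    group-level counts (n OTUs per verdict, pooled sequences per verdict)."""
    otu_ids, verdicts, counts = [], [], []
    k = 0
    for verdict, (n_otus, n_seqs) in verdict_counts.items():
        per = np.full(n_otus, n_seqs // n_otus)
        per[: n_seqs % n_otus] += 1
        for c in per:
            otu_ids.append(f"{class_label}_{k}")
            verdicts.append(verdict)
            counts.append(c)
            k += 1
    records = pd.DataFrame(
        {
            "otu_id": otu_ids,
            "pearson_r": np.nan,
            "p_raw": np.nan,
            "p_adjusted": np.nan,
            "verdict": verdicts,
        }
    )
    table = OtuTable(otu_ids, ["pooled"], np.array(counts)[:, None])
    part = CoherencePartition(class_label, records, len(otu_ids), 0.05, 1)
    return part, table


class TestPositiveFraction:
    def test_all_positive(self):
        part, table = build_partition("X", {"positive": (3, 30)}, None)
        otu_pct, seq_pct = positive_fraction(part, table)
        assert otu_pct == pytest.approx(100.0)
        assert seq_pct == pytest.approx(100.0)

    def test_untestable_excluded_from_otu_percent(self):
        part, table = build_partition(
            "X", {"positive": (1, 10), "nonsignificant": (1, 10), "untestable": (2, 20)}, None
        )
        otu_pct, seq_pct = positive_fraction(part, table)
        assert otu_pct == pytest.approx(50.0)
        assert seq_pct == pytest.approx(25.0)  # untestable count in sequences


class TestSubgroupSummary:
    def test_single_otu_group_shannon_zero_mpd_missing(self):
        part, table = build_partition(
            "X", {"positive": (1, 50), "nonsignificant": (3, 30)}, None
        )
        tree = tree_from("((X_0:1,X_1:1):1,(X_2:1,X_3:1):1);")
        pos, nc = subgroup_summary(part, table, tree, dominant_set=set())
        assert pos.shannon == pytest.approx(0.0)
        assert pos.mpd is None
        assert nc.mpd is not None

    def test_percent_dominant_sums_to_100(self):
        part, table = build_partition(
            "X", {"positive": (2, 200), "nonsignificant": (3, 300)}, None
        )
        dominant = {"X_0", "X_2", "X_3"}
        pos, nc = subgroup_summary(part, table, None, dominant)
        assert pos.percent_dominant + nc.percent_dominant == pytest.approx(100.0)

    def test_no_dominant_otus_gives_none(self):
        part, table = build_partition(
            "X", {"positive": (2, 20), "nonsignificant": (2, 20)}, None
        )
        pos, nc = subgroup_summary(part, table, None, set())
        assert pos.percent_dominant is None and nc.percent_dominant is None


class TestSubgroupTaxonomy:
    def test_single_order_group_is_100(self):
        part, table = build_partition("X", {"positive": (2, 20)}, None)
        tax = make_tax({"X_0": ("X", "Ord1"), "X_1": ("X", "Ord1")})
        out = subgroup_taxonomy(part, table, tax)
        assert len(out) == 1
        assert out.iloc[0]["percent"] == pytest.approx(100.0)

    def test_empty_group_empty_rows_not_error(self):
        part, table = build_partition("X", {"nonsignificant": (2, 20)}, None)
        tax = make_tax({"X_0": ("X", None), "X_1": ("X", "Ord2")})
        out = subgroup_taxonomy(part, table, tax)
        assert set(out["group"]) == {"noncorrelated"}

    def test_rows_sum_to_100(self, small_bundle):
        b = small_bundle
        part = partition_class(b.table, b.taxonomy, "ClassA")
        out = subgroup_taxonomy(part, b.table, b.taxonomy)
        sums = out.groupby("group")["percent"].sum()
        assert np.allclose(sums, 100.0)
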