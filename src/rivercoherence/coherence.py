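"""Ecological coherence of a bacterial class with its constituent OTUs.

The central statistic of the pipeline: within each class, every OTU's
per-sample abundance is correlated (Pearson, two-sided) against the summed
abundance of its parent class.  After Bonferroni correction over the
family of testable OTUs, the class's OTUs are partitioned into
``positive`` (covary with the class), ``negative`` (anti-covary),
``nonsignificant`` and ``untestable`` (constant vector, no defined r).
The positive subgroup is the set of taxa whose dynamics the class-level
abundance pattern actually represents; its size, sequence share,
taxonomic diversity (Shannon) and phylogenetic dispersion (MPD) are
compared against the non-correlated remainder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skbio import TreeNode

from .datatypes import JoinError, OtuTable, TaxonomyMap
from .diversity import mpd, shannon

__all__ = [
    "class_abundance",
    "flag_dominant_otus",
    "CoherencePartition",
    "partition_class",
    "partition_all_classes",
    "positive_fraction",
    "SubgroupSummary",
    "subgroup_summary",
    "subgroup_taxonomy",
]

VERDICTS = ("positive", "negative", "nonsignificant", "untestable")


def class_abundance(
    table: OtuTable, taxonomy: TaxonomyMap, focal: str, rank: str = "class"
) -> np.ndarray:
    """Per-sample summed abundance of all OTUs assigned to ``focal`` at the
    given rank (class by default), in the table's sample order."""
    if rank == "class":
        members = [o for o in table.otu_ids if taxonomy.class_of(o) == focal]
    elif rank == "order":
        members = [o for o in table.otu_ids if taxonomy.order_of(o) == focal]
    else:
        raise ValueError(f"unsupported rank {rank!r}")
    if not members:
        raise KeyError(f"no OTUs assigned to {focal!r} at rank {rank!r}")
    return table.subset_otus(members).counts.sum(axis=0)


def flag_dominant_otus(table: OtuTable, threshold_fraction: float = 0.001) -> set[str]:
    """OTUs whose pooled count strictly exceeds ``threshold_fraction`` of
    the grand total (the 0.1 % 'dominant' cut by default).  Run on the
    non-rarefied table."""
    grand = table.grand_total()
    pooled = table.otu_sums()
    return {o for o, c in zip(table.otu_ids, pooled) if c > threshold_fraction * grand}


@dataclass
class CoherencePartition:
    """Per-OTU verdicts for one class.

    ``records`` columns: otu_id, pearson_r, p_raw, p_adjusted, verdict.
    ``family_size`` is the Bonferroni family actually used; ``n_samples``
    the number of samples the correlations were computed over.
    """

    class_label: str
    records: pd.DataFrame
    family_size: int
    alpha: float
    n_samples: int

    def otus_with_verdict(self, verdict: str) -> list[str]:
        return self.records.loc[self.records["verdict"] == verdict, "otu_id"].tolist()

    @property
    def testable(self) -> pd.DataFrame:
        return self.records[self.records["verdict"] != "untestable"]


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Pearson r and p via the t transform, n-2 df."""
    n = len(x)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    r = float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, float(p)


def partition_class(
    table: OtuTable,
    taxonomy: TaxonomyMap,
    class_label: str,
    alpha: float = 0.05,
    family: str = "within_class",
    self_inclusion: bool = True,
    family_size: int | None = None,
) -> CoherencePartition:
    """Partition one class's OTUs by sign/significance of their Pearson
    correlation with the class abundance vector.

    The class vector includes the focal OTU itself by default
    (``self_inclusion``); a leave-one-out mode subtracts it, which avoids
    the self-correlation inflating positives in tiny classes.
    ``family='within_class'`` Bonferroni-corrects over the class's testable
    OTUs; ``family='global'`` over ``family_size`` (e.g. all testable OTUs
    in the dataset).
    """
    n = len(table.sample_ids)
    if n < 4:
        raise ValueError(f"need >= 4 samples for correlation testing, got {n}")
    members = [o for o in table.otu_ids if taxonomy.class_of(o) == class_label]
    if not members:
        raise KeyError(f"class {class_label!r} has no OTUs in the table")
    sub = table.subset_otus(members).counts.astype(float)
    class_vec = sub.sum(axis=0)
    if self_inclusion and class_vec.std() == 0:
        raise ValueError(f"class {class_label!r} abundance vector has zero variance")

    testable_mask = sub.std(axis=1) > 0
    n_testable = int(testable_mask.sum())
    if family == "within_class":
        fam = n_testable
    elif family == "global":
        if family_size is None:
            raise ValueError("family='global' requires family_size")
        fam = family_size
    else:
        raise ValueError(f"unknown family mode {family!r}")

    rows = []
    for otu, vec, ok in zip(members, sub, testable_mask):
        if not ok:
            rows.append((otu, np.nan, np.nan, np.nan, "untestable"))
            continue
        target = class_vec if self_inclusion else class_vec - vec
        if target.std() == 0:
            rows.append((otu, np.nan, np.nan, np.nan, "untestable"))
            continue
        r, p = _pearson_with_p(vec, target)
        p_adj = min(1.0, p * fam)
        if p_adj < alpha and r > 0:
            verdict = "positive"
        elif p_adj < alpha and r < 0:
            verdict = "negative"
        else:
            verdict = "nonsignificant"
        rows.append((otu, r, p, p_adj, verdict))
    records = pd.DataFrame(
        rows, columns=["otu_id", "pearson_r", "p_raw", "p_adjusted", "verdict"]
    )
    return CoherencePartition(class_label, records, fam, alpha, n)


def partition_all_classes(
    table: OtuTable,
    taxonomy: TaxonomyMap,
    classes: list[str] | None = None,
    **kwargs,
) -> dict[str, CoherencePartition]:
    """Run :func:`partition_class` for each class present in the table."""
    present = {taxonomy.class_of(o) for o in table.otu_ids}
    if classes is None:
        classes = sorted(c for c in present if c)
    out = {}
    for cls in classes:
        out[cls] = partition_class(table, taxonomy, cls, **kwargs)
    return out


def positive_fraction(
    partition: CoherencePartition, table: OtuTable
) -> tuple[float, float]:
    """(percent of testable OTUs positive, percent of class sequences in
    positive OTUs).

    The sequence denominator pools every partitioned OTU (untestable
    included); the OTU denominator counts only testable ones.
    """
    rec = partition.records
    if rec.empty:
        raise ValueError(f"class {partition.class_label!r} has no partitioned OTUs")
    testable = rec[rec["verdict"] != "untestable"]
    if testable.empty:
        raise ValueError(f"class {partition.class_label!r} has no testable OTUs")
    n_pos = int((testable["verdict"] == "positive").sum())
    otu_pct = 100.0 * n_pos / len(testable)
    pooled = {o: int(table.otu_vector(o).sum()) for o in rec["otu_id"]}
    total = sum(pooled.values())
    pos_total = sum(pooled[o] for o in rec.loc[rec["verdict"] == "positive", "otu_id"])
    seq_pct = 100.0 * pos_total / total if total else float("nan")
    return otu_pct, seq_pct


@dataclass
class SubgroupSummary:
    """Pooled summary of one coherence subgroup within a class."""

    class_label: str
    group: str  # "positive" | "noncorrelated"
    n_sequences: int
    n_otus: int
    percent_dominant: float | None
    shannon: float | None
    mpd: float | None
    shannon_per_sample_mean: float | None = None


def _group_otus(partition: CoherencePartition, group: str) -> list[str]:
    if group == "positive":
        return partition.otus_with_verdict("positive")
    if group == "noncorrelated":
        return partition.otus_with_verdict("nonsignificant")
    raise ValueError(f"unknown subgroup {group!r}")


def subgroup_summary(
    partition: CoherencePartition,
    table: OtuTable,
    tree: TreeNode | None,
    dominant_set: set[str],
) -> tuple[SubgroupSummary, SubgroupSummary]:
    """Summarize the positive and non-correlated subgroups of a class:
    pooled sequence and OTU counts, share of the class's dominant OTUs,
    pooled Shannon index and MPD of the subgroup's OTU set.

    Percent-dominant is relative to the class's dominant OTUs falling in
    either subgroup, so the two percentages sum to 100 whenever any
    dominant OTU exists; it is None when none does.
    """
    groups = {g: _group_otus(partition, g) for g in ("positive", "noncorrelated")}
    dom_in_groups = sum(
        1 for g in groups.values() for o in g if o in dominant_set
    )
    out = []
    for g, otus in groups.items():
        if otus:
            sub = table.subset_otus(otus)
            pooled = sub.otu_sums()
            n_seq = int(pooled.sum())
            h = shannon(pooled) if n_seq > 0 else None
            per_sample = []
            for col in sub.counts.T:
                if col.sum() > 0:
                    per_sample.append(shannon(col))
            h_mean = float(np.mean(per_sample)) if per_sample else None
            m = mpd(otus, tree) if tree is not None and len(otus) >= 2 else None
            n_dom = sum(1 for o in otus if o in dominant_set)
            pct_dom = 100.0 * n_dom / dom_in_groups if dom_in_groups else None
        else:
            n_seq, h, h_mean, m = 0, None, None, None
            pct_dom = 0.0 if dom_in_groups else None
        out.append(
            SubgroupSummary(
                partition.class_label, g, n_seq, len(otus), pct_dom, h, m, h_mean
            )
        )
    return out[0], out[1]


def subgroup_taxonomy(
    partition: CoherencePartition,
    table: OtuTable,
    taxonomy: TaxonomyMap,
) -> pd.DataFrame:
    """Percent of each subgroup's sequences per taxonomic order.

    OTUs without an order-level assignment are grouped as ``unclassified``.
    Rows: class, group, order, percent; percents sum to 100 within a
    non-empty group.
    """
    rows = []
    for g in ("positive", "noncorrelated"):
        otus = _group_otus(partition, g)
        if not otus:
            continue
        pooled = {o: int(table.otu_vector(o).sum()) for o in otus}
        total = sum(pooled.values())
        if total == 0:
            continue
        per_order: dict[str, int] = {}
        for o, c in pooled.items():
            order = taxonomy.order_of(o) or "unclassified"
            per_order[order] = per_order.get(order, 0) + c
        for order, c in sorted(per_order.items(), key=lambda kv: -kv[1]):
            rows.append(
                {
                    "class": partition.class_label,
                    "group": g,
                    "order": order,
                    "percent": 100.0 * c / total,
                }
            )
    return pd.DataFrame(rows, columns=["class", "group", "order", "percent"])
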