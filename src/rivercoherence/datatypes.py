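"""Core domain types for the river-metacommunity pipeline.

The single substrate of every analysis stage is an :class:`OtuTable`
(non-negative integer OTU x sample count matrix).  Sample-level design
information (river reach, along-flow order, sampling campaign) lives in a
:class:`SampleFrame`; taxonomic lineages in a :class:`TaxonomyMap`;
environmental measurements in an :class:`EnvMatrix`.  Phylogenies are
plain :class:`skbio.TreeNode` objects and distance matrices plain
:class:`skbio.DistanceMatrix` objects — the established containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "REACHES",
    "UPSTREAM",
    "RESERVOIR",
    "DOWNSTREAM",
    "ValidationError",
    "JoinError",
    "OtuTable",
    "SampleFrame",
    "Lineage",
    "TaxonomyMap",
    "EnvMatrix",
    "check_tree",
    "check_tips",
]

UPSTREAM = "upstream"
RESERVOIR = "reservoir"
DOWNSTREAM = "downstream"
#: Canonical ordering of river reaches in the downstream direction.
REACHES = (UPSTREAM, RESERVOIR, DOWNSTREAM)

RANKS = ("domain", "phylum", "class", "order", "family", "genus")


class ValidationError(ValueError):
    """An input violated a structural invariant at load/construction time."""


class JoinError(KeyError):
    """Identifiers failed to match between two joined data structures."""

    def __init__(self, message: str, missing: Sequence[str] = ()):
        super().__init__(message)
        self.missing = list(missing)

    def __str__(self) -> str:  # KeyError quotes its arg; we want plain text
        return self.args[0]


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    dupes = [i for i in ids if i in seen or seen.add(i)]
    if dupes:
        raise ValidationError(f"duplicate {what}: {sorted(set(dupes))}")


@dataclass
class OtuTable:
    """OTU-by-sample count matrix with aligned identifier lists.

    Rows are OTUs, columns are samples.  Counts must be non-negative
    integers; identifiers unique along both axes.
    """

    otu_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.otu_ids = [str(i) for i in self.otu_ids]
        self.sample_ids = [str(i) for i in self.sample_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.otu_ids)} OTUs x {len(self.sample_ids)} samples"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.isfinite(counts)) or np.any(counts != np.floor(counts)):
                raise ValidationError("counts must be integral")
            counts = counts.astype(np.int64)
        if counts.size and counts.min(initial=0) < 0:
            r, c = np.argwhere(counts < 0)[0]
            raise ValidationError(
                f"negative count at OTU {self.otu_ids[r]!r}, sample {self.sample_ids[c]!r}"
            )
        _check_unique(self.otu_ids, "OTU ids")
        _check_unique(self.sample_ids, "sample ids")
        self.counts = np.ascontiguousarray(counts, dtype=np.int64)

    # -- basic accessors -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def otu_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def grand_total(self) -> int:
        return int(self.counts.sum())

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise JoinError(f"sample {sample_id!r} not in table", [sample_id])

    def otu_vector(self, otu_id: str) -> np.ndarray:
        try:
            return self.counts[self.otu_ids.index(otu_id)]
        except ValueError:
            raise JoinError(f"OTU {otu_id!r} not in table", [otu_id])

    # -- subsetting ------------------------------------------------------
    def subset_otus(self, keep: Iterable[str]) -> "OtuTable":
        keep = list(keep)
        missing = sorted(set(keep) - set(self.otu_ids))
        if missing:
            raise JoinError(f"OTUs not in table: {missing}", missing)
        pos = {o: i for i, o in enumerate(self.otu_ids)}
        idx = [pos[o] for o in keep]
        return OtuTable(keep, list(self.sample_ids), self.counts[idx])

    def subset_samples(self, keep: Iterable[str]) -> "OtuTable":
        keep = list(keep)
        missing = sorted(set(keep) - set(self.sample_ids))
        if missing:
            raise JoinError(f"samples not in table: {missing}", missing)
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in keep]
        return OtuTable(list(self.otu_ids), keep, self.counts[:, idx])

    def drop_empty_otus(self) -> "OtuTable":
        nz = self.otu_sums() > 0
        return OtuTable(
            [o for o, k in zip(self.otu_ids, nz) if k],
            list(self.sample_ids),
            self.counts[nz],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.otu_ids, columns=self.sample_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return (
            self.otu_ids == other.otu_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass
class SampleFrame:
    """Per-sample design metadata: site, reach, along-flow order, campaign.

    ``flow_order`` is a strictly-increasing rank along the downstream
    direction; every upstream site must precede the reservoir, which must
    precede every downstream site.
    """

    frame: pd.DataFrame

    REQUIRED = ("sample_id", "site_id", "reach", "flow_order", "campaign")

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"metadata missing required columns: {missing}")
        for col in self.REQUIRED:
            if df[col].isna().any():
                bad = df.index[df[col].isna()].tolist()
                raise ValidationError(f"metadata column {col!r} empty at rows {bad}")
        df = df.copy()
        df["sample_id"] = df["sample_id"].astype(str)
        df["site_id"] = df["site_id"].astype(str)
        df["reach"] = df["reach"].astype(str).str.lower()
        df["flow_order"] = df["flow_order"].astype(int)
        df["campaign"] = df["campaign"].astype(str)
        bad_reach = sorted(set(df["reach"]) - set(REACHES))
        if bad_reach:
            raise ValidationError(f"unknown reach labels: {bad_reach}")
        _check_unique(df["sample_id"].tolist(), "sample ids")
        pairs = list(zip(df["site_id"], df["campaign"]))
        _check_unique([f"{s}/{c}" for s, c in pairs], "(site_id, campaign) pairs")
        # along-flow ordering must be consistent with reach labels
        orders = {r: df.loc[df["reach"] == r, "flow_order"] for r in REACHES}
        for hi, lo in ((RESERVOIR, UPSTREAM), (DOWNSTREAM, RESERVOIR), (DOWNSTREAM, UPSTREAM)):
            if len(orders[hi]) and len(orders[lo]) and orders[lo].max() >= orders[hi].min():
                raise ValidationError(
                    f"flow_order ordering violated: some {lo} site has flow_order "
                    f">= some {hi} site"
                )
        self.frame = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    def reach_of(self) -> pd.Series:
        return self.frame.set_index("sample_id")["reach"]

    def campaigns(self) -> list[str]:
        return list(dict.fromkeys(self.frame["campaign"]))

    def samples_in_reach(self, reach: str) -> list[str]:
        return self.frame.loc[self.frame["reach"] == reach, "sample_id"].tolist()

    def subset(self, sample_ids: Iterable[str]) -> "SampleFrame":
        ids = set(sample_ids)
        return SampleFrame(self.frame[self.frame["sample_id"].isin(ids)].copy())

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class Lineage:
    """Ordered taxonomic lineage; unassigned ranks are None."""

    domain: str | None = None
    phylum: str | None = None
    klass: str | None = None
    order: str | None = None
    family: str | None = None
    genus: str | None = None

    @classmethod
    def from_string(cls, lineage: str) -> "Lineage":
        parts = [p.strip() for p in lineage.split(";")]
        clean: list[str | None] = []
        for p in parts[: len(RANKS)]:
            # tolerate Greengenes-style rank prefixes ("c__Betaproteobacteria")
            if len(p) >= 3 and p[1:3] == "__":
                p = p[3:]
            clean.append(p if p else None)
        clean += [None] * (len(RANKS) - len(clean))
        return cls(*clean)

    def to_string(self) -> str:
        vals = [self.domain, self.phylum, self.klass, self.order, self.family, self.genus]
        while vals and vals[-1] is None:
            vals.pop()
        return ";".join(v if v is not None else "" for v in vals)


@dataclass
class TaxonomyMap:
    """otu_id -> lineage assignment; at most one lineage per OTU."""

    lineages: dict[str, Lineage] = field(default_factory=dict)

    def class_of(self, otu_id: str) -> str | None:
        lin = self.lineages.get(otu_id)
        return lin.klass if lin is not None else None

    def order_of(self, otu_id: str) -> str | None:
        lin = self.lineages.get(otu_id)
        return lin.order if lin is not None else None

    def classes(self) -> list[str]:
        seen = dict.fromkeys(
            lin.klass for lin in self.lineages.values() if lin.klass is not None
        )
        return list(seen)

    def otus_in_class(self, class_label: str) -> list[str]:
        return [o for o, lin in self.lineages.items() if lin.klass == class_label]

    def require(self, otu_ids: Iterable[str]) -> None:
        missing = sorted(set(otu_ids) - set(self.lineages))
        if missing:
            raise JoinError(f"OTUs missing from taxonomy: {missing}", missing)

    def __len__(self) -> int:
        return len(self.lineages)


@dataclass
class EnvMatrix:
    """Sample x environmental-variable matrix with optional unit annotations."""

    frame: pd.DataFrame
    units: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.frame
        if df.isna().any().any():
            bad = df.columns[df.isna().any()].tolist()
            raise ValidationError(f"environment table has missing values in {bad}")
        _check_unique([str(i) for i in df.index], "environment sample ids")

    @property
    def sample_ids(self) -> list[str]:
        return [str(i) for i in self.frame.index]

    @property
    def variables(self) -> list[str]:
        return list(self.frame.columns)


def check_tree(tree: TreeNode) -> TreeNode:
    """Validate branch lengths (finite, >= 0) and tip-label uniqueness."""
    tips = [t.name for t in tree.tips()]
    _check_unique(tips, "tree tip labels")
    for node in tree.traverse(include_self=False):
        bl = node.length
        if bl is None:
            node.length = 0.0
        elif not np.isfinite(bl) or bl < 0:
            raise ValidationError(f"invalid branch length {bl!r} at node {node.name!r}")
    return tree


def check_tips(tree: TreeNode, otu_ids: Iterable[str]) -> None:
    """Fail loudly if any OTU id is absent from the tree's tips."""
    tips = {t.name for t in tree.tips()}
    missing = sorted(set(otu_ids) - tips)
    if missing:
        raise JoinError(f"OTUs missing from tree tips: {missing}", missing)
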