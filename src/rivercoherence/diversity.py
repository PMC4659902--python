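"""Rarefaction, alpha diversity (richness, Shannon, MPD), collector curves
and upstream/downstream contrasts.

Rarefaction is without replacement (multivariate hypergeometric draw per
sample); samples below the target depth are dropped and reported, mirroring
field practice when a few samples return too few sequences.  MPD is the
mean pairwise patristic distance among the taxa present in a community;
the default is presence-based, with an abundance-weighted variant behind a
flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import TreeNode

from .datatypes import (
    DOWNSTREAM,
    UPSTREAM,
    JoinError,
    OtuTable,
    SampleFrame,
)

__all__ = [
    "RarefactionResult",
    "rarefy",
    "shannon",
    "mpd",
    "collector_curve",
    "alpha_records",
    "ReachContrast",
    "reach_contrast",
]


@dataclass
class RarefactionResult:
    table: OtuTable
    depth: int
    dropped_samples: list[str]


def rarefy(
    table: OtuTable, depth: int, seed: int | np.random.Generator
) -> RarefactionResult:
    """Subsample every sample to exactly ``depth`` sequences without
    replacement; samples whose total is below ``depth`` are dropped.

    Identical seeds give identical output.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be positive, got {depth}")
    rng = np.random.default_rng(seed)
    sums = table.sample_sums()
    keep = sums >= depth
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if not keep.any():
        raise ValueError(
            f"all {len(table.sample_ids)} samples have fewer than {depth} sequences"
        )
    kept_ids = [s for s, k in zip(table.sample_ids, keep) if k]
    out = np.empty((len(table.otu_ids), len(kept_ids)), dtype=np.int64)
    j = 0
    for col, k, total in zip(table.counts.T, keep, sums):
        if not k:
            continue
        if total == depth:
            out[:, j] = col
        else:
            out[:, j] = rng.multivariate_hypergeometric(col, depth)
        j += 1
    return RarefactionResult(OtuTable(list(table.otu_ids), kept_ids, out), depth, dropped)


def shannon(counts: np.ndarray, base: str = "e") -> float:
    """Shannon index H = -sum p_i log p_i over positive entries.

    ``base`` is ``"e"`` (nats, default) or ``"2"`` (bits).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0 or counts.sum() <= 0:
        raise ValueError("Shannon index undefined for an all-zero vector")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    p = counts[counts > 0]
    p = p / p.sum()
    h = float(-(p * np.log(p)).sum())
    if base == "2":
        h /= math.log(2)
    elif base != "e":
        raise ValueError(f"unknown log base {base!r}")
    return h


def mpd(
    present_taxa: set[str] | list[str],
    tree: TreeNode,
    weighted: bool = False,
    abundances: np.ndarray | None = None,
) -> float | None:
    """Mean pairwise phylogenetic (patristic) distance among present taxa.

    Unweighted (default): the plain mean over all unordered pairs of
    distinct taxa.  Weighted: each pair weighted by the product of relative
    abundances.  Returns None for fewer than two taxa.
    """
    taxa = list(dict.fromkeys(present_taxa))
    if len(taxa) < 2:
        return None
    tips = {t.name for t in tree.tips()}
    missing = sorted(set(taxa) - tips)
    if missing:
        raise JoinError(f"taxa missing from tree: {missing}", missing)
    dm = tree.tip_tip_distances(taxa)
    d = dm.filter(taxa).data  # order as given
    iu = np.triu_indices(len(taxa), k=1)
    if not weighted:
        return float(d[iu].mean())
    if abundances is None:
        raise ValueError("weighted MPD requires abundances")
    a = np.asarray(abundances, dtype=float)
    if a.shape != (len(taxa),):
        raise ValueError("abundances must align with present_taxa")
    p = a / a.sum()
    w = np.outer(p, p)[iu]
    return float((d[iu] * w).sum() / w.sum())


def collector_curve(
    table: OtuTable, grain: int, reps: int, seed: int | np.random.Generator
) -> list[tuple[int, float]]:
    """OTU accumulation (collector) curve over the pooled sequence pool.

    Sequences from all samples are pooled, shuffled, and accumulated in
    steps of ``grain``; the mean cumulative OTU count over ``reps``
    shuffles is returned.  The final point equals the observed richness.
    """
    if grain <= 0:
        raise ValueError("grain must be positive")
    pooled = table.otu_sums()
    total = int(pooled.sum())
    if grain > total:
        raise ValueError(f"grain {grain} exceeds pooled total {total}")
    rng = np.random.default_rng(seed)
    checkpoints = list(range(grain, total + 1, grain))
    if checkpoints[-1] != total:
        checkpoints.append(total)
    labels = np.repeat(np.arange(len(table.otu_ids)), pooled)
    acc = np.zeros(len(checkpoints))
    for _ in range(reps):
        perm = rng.permutation(labels)
        seen = np.zeros(len(table.otu_ids), dtype=bool)
        prev = 0
        for k, n in enumerate(checkpoints):
            seen[perm[prev:n]] = True
            acc[k] += seen.sum()
            prev = n
    return [(n, a / reps) for n, a in zip(checkpoints, acc)]


def alpha_records(
    table: OtuTable,
    tree: TreeNode | None = None,
    scope: str = "all",
    weighted_mpd: bool = False,
) -> pd.DataFrame:
    """Per-sample alpha diversity: n_sequences, richness, Shannon, MPD.

    MPD is None when the tree is absent or a sample holds fewer than two
    taxa; all-zero samples get richness 0 and missing Shannon/MPD.
    """
    rows = []
    for j, sid in enumerate(table.sample_ids):
        col = table.counts[:, j]
        present = col > 0
        n_seq = int(col.sum())
        rich = int(present.sum())
        h = shannon(col) if n_seq > 0 else None
        m = None
        if tree is not None and rich >= 2:
            taxa = [o for o, p in zip(table.otu_ids, present) if p]
            m = mpd(taxa, tree, weighted=weighted_mpd, abundances=col[present] if weighted_mpd else None)
        rows.append(
            {
                "sample_id": sid,
                "scope": scope,
                "n_sequences": n_seq,
                "richness": rich,
                "shannon": h,
                "mpd": m,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ReachContrast:
    """Upstream-vs-downstream contrast of one alpha metric.

    ``signed_ratio`` is the fold change: up/down when the upstream mean is
    at least the downstream mean, otherwise -(down/up), so positive values
    mean higher upstream.  ``log2_ratio`` = log2(up/down).
    """

    metric: str
    mean_upstream: float
    mean_downstream: float
    signed_ratio: float
    log2_ratio: float
    anova_p: float


def reach_contrast(
    records: pd.DataFrame, frames: SampleFrame, metric: str
) -> ReachContrast:
    """One-way ANOVA contrast of an alpha metric between upstream and
    downstream samples (reservoir excluded)."""
    reach = frames.reach_of()
    merged = records.merge(
        reach.rename("reach"), left_on="sample_id", right_index=True, how="inner"
    )
    up = merged.loc[merged["reach"] == UPSTREAM, metric].dropna().to_numpy(float)
    down = merged.loc[merged["reach"] == DOWNSTREAM, metric].dropna().to_numpy(float)
    if len(up) < 2 or len(down) < 2:
        raise ValueError(
            f"need >= 2 samples per group for {metric!r}: "
            f"upstream={len(up)}, downstream={len(down)}"
        )
    mu, md = float(up.mean()), float(down.mean())
    if mu == md:
        ratio, p = 1.0, 1.0
    else:
        ratio = mu / md if mu >= md else -(md / mu)
        f, p = stats.f_oneway(up, down)
        if not np.isfinite(p):  # zero within-group variance, unequal means
            p = 0.0
        p = float(p)
    log2_ratio = float(np.log2(mu / md)) if mu > 0 and md > 0 else float("nan")
    return ReachContrast(metric, mu, md, ratio, log2_ratio, p)
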