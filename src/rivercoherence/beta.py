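"""Between-sample community structure: Bray-Curtis and weighted-normalized
UniFrac distances, and ANOSIM contrasts between groups of samples.

ANOSIM is Clarke's rank-based statistic
R = (r̄_between - r̄_within) / (M/2), with M = n(n-1)/2 pairwise distance
ranks; its permutation p-value uses the +1 correction so it can never be
exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity

from .datatypes import JoinError, OtuTable, check_tips

__all__ = [
    "bray_curtis",
    "weighted_normalized_unifrac",
    "AnosimResult",
    "anosim",
]


def bray_curtis(table: OtuTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(x,y) = sum|x-y| / sum(x+y) between all
    sample pairs.  Computed on the counts as given; the pipeline applies it
    to the rarefied table so sample depths are comparable."""
    if len(table.sample_ids) < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    sums = table.sample_sums()
    if (sums == 0).any():
        empty = [s for s, t in zip(table.sample_ids, sums) if t == 0]
        raise ValueError(f"Bray-Curtis undefined for all-zero samples: {empty}")
    d = squareform(pdist(table.counts.T.astype(float), metric="braycurtis"))
    return DistanceMatrix(d, ids=table.sample_ids)


def weighted_normalized_unifrac(table: OtuTable, tree: TreeNode) -> DistanceMatrix:
    """Weighted-normalized UniFrac between all sample pairs.

    For samples x, y: sum_b l_b |p_b(x) - p_b(y)| / sum_b l_b (p_b(x) + p_b(y)),
    where b runs over branches, l_b is branch length and p_b the fraction
    of a sample's sequences descending from b.  Entries lie in [0, 1].
    """
    if len(table.sample_ids) < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    nonzero = table.otu_sums() > 0
    present = [o for o, nz in zip(table.otu_ids, nonzero) if nz]
    check_tips(tree, present)
    sub = table.counts[nonzero]
    return beta_diversity(
        "weighted_unifrac",
        sub.T,
        ids=table.sample_ids,
        taxa=present,
        tree=tree,
        normalized=True,
        validate=True,
    )


@dataclass
class AnosimResult:
    grouping: str
    r: float
    p_value: float
    n_permutations: int
    n_samples: int
    seed: int | None


def _anosim_r(ranks_condensed: np.ndarray, within_mask: np.ndarray) -> float:
    n_pairs = ranks_condensed.size
    r_within = ranks_condensed[within_mask].mean()
    r_between = ranks_condensed[~within_mask].mean()
    return float((r_between - r_within) / (n_pairs / 2.0))


def anosim(
    dist: DistanceMatrix,
    grouping: dict[str, str],
    n_permutations: int = 9999,
    seed: int | None = None,
    grouping_name: str = "grouping",
) -> AnosimResult:
    """Analysis of similarities between >= 2 groups of samples.

    ``grouping`` maps every sample id in ``dist`` to a group label; every
    group must contain at least two samples.  p = (#{R_perm >= R_obs} + 1)
    / (n_permutations + 1).
    """
    ids = list(dist.ids)
    missing = sorted(set(ids) - set(grouping))
    if missing:
        raise JoinError(f"samples missing from grouping: {missing}", missing)
    labels = np.array([grouping[s] for s in ids])
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("ANOSIM needs at least 2 groups")
    singletons = uniq[counts < 2].tolist()
    if singletons:
        raise ValueError(f"groups with fewer than 2 samples: {singletons}")
    n = len(ids)
    ranks = rankdata(dist.condensed_form())
    iu = np.triu_indices(n, k=1)

    def within(perm_labels: np.ndarray) -> np.ndarray:
        return perm_labels[iu[0]] == perm_labels[iu[1]]

    r_obs = _anosim_r(ranks, within(labels))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        r_perm = _anosim_r(ranks, within(rng.permutation(labels)))
        if r_perm >= r_obs:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return AnosimResult(grouping_name, r_obs, float(p), n_permutations, n, seed)
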