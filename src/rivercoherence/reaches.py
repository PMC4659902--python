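"""OTU origin and reach-dominance categorization under unidirectional flow.

Origin: each OTU is assigned to the farthest-upstream river reach (or
site) where it is detected, assuming water — and the cells it carries —
moves only downstream.  Dominance: the reach where the OTU's summed
sequence abundance is strictly greatest; any tie for the maximum is
labeled ``no_change``.  Both schemes run on the non-rarefied table with
all sampling campaigns pooled (a per-campaign mode is available).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import (
    REACHES,
    JoinError,
    OtuTable,
    SampleFrame,
    TaxonomyMap,
)

__all__ = [
    "DOMINANCE_LABELS",
    "assign_origin",
    "assign_dominance",
    "summarize_reach_fractions",
]

DOMINANCE_LABELS = (
    "upstream_dominant",
    "reservoir_dominant",
    "downstream_dominant",
    "no_change",
)


def _check_samples(table: OtuTable, frames: SampleFrame) -> None:
    missing = sorted(set(table.sample_ids) - set(frames.sample_ids))
    if missing:
        raise JoinError(f"samples missing from metadata: {missing}", missing)


def assign_origin(
    table: OtuTable,
    frames: SampleFrame,
    resolution: str = "reach",
) -> tuple[dict[str, str], list[str]]:
    """Assign each OTU to the farthest-upstream reach (or site) where it is
    first detected, pooling all campaigns.

    Returns ``(origin_map, excluded)`` where ``excluded`` lists zero-total
    OTUs that received no label.
    """
    if resolution not in ("reach", "site"):
        raise ValueError(f"unknown resolution {resolution!r}")
    _check_samples(table, frames)
    meta = frames.frame.set_index("sample_id").loc[table.sample_ids]
    reach = meta["reach"].to_numpy()
    flow = meta["flow_order"].to_numpy()
    present = table.counts > 0
    origin: dict[str, str] = {}
    excluded: list[str] = []
    for otu, row in zip(table.otu_ids, present):
        if not row.any():
            excluded.append(otu)
            continue
        if resolution == "reach":
            # farthest-upstream = lowest-indexed reach with a detection
            detected = set(reach[row])
            origin[otu] = next(r for r in REACHES if r in detected)
        else:
            origin[otu] = reach[row][np.argmin(flow[row])]
    return origin, excluded


def assign_dominance(
    table: OtuTable, frames: SampleFrame
) -> tuple[dict[str, str], list[str]]:
    """Label each OTU by the reach where its summed abundance is strictly
    greatest; ties for the maximum become ``no_change``."""
    _check_samples(table, frames)
    meta = frames.frame.set_index("sample_id").loc[table.sample_ids]
    reach = meta["reach"].to_numpy()
    sums = {r: table.counts[:, reach == r].sum(axis=1) for r in REACHES}
    stacked = np.stack([sums[r] for r in REACHES])  # 3 x n_otus
    dominance: dict[str, str] = {}
    excluded: list[str] = []
    for i, otu in enumerate(table.otu_ids):
        col = stacked[:, i]
        if col.sum() == 0:
            excluded.append(otu)
            continue
        top = col.max()
        winners = [r for r, v in zip(REACHES, col) if v == top]
        if len(winners) > 1:
            dominance[otu] = "no_change"
        else:
            dominance[otu] = f"{winners[0]}_dominant"
    return dominance, excluded


def assign_dominance_site_mean(
    table: OtuTable, frames: SampleFrame
) -> tuple[dict[str, str], list[str]]:
    """Dominance variant comparing per-site mean abundance per reach instead
    of raw reach sums, compensating unequal site counts per reach."""
    _check_samples(table, frames)
    meta = frames.frame.set_index("sample_id").loc[table.sample_ids]
    reach = meta["reach"].to_numpy()
    means = {}
    for r in REACHES:
        cols = reach == r
        means[r] = table.counts[:, cols].sum(axis=1) / max(int(cols.sum()), 1)
    stacked = np.stack([means[r] for r in REACHES])
    dominance: dict[str, str] = {}
    excluded: list[str] = []
    for i, otu in enumerate(table.otu_ids):
        col = stacked[:, i]
        if col.sum() == 0:
            excluded.append(otu)
            continue
        top = col.max()
        winners = [r for r, v in zip(REACHES, col) if v == top]
        dominance[otu] = "no_change" if len(winners) > 1 else f"{winners[0]}_dominant"
    return dominance, excluded


def summarize_reach_fractions(
    table: OtuTable,
    frames: SampleFrame,
    taxonomy: TaxonomyMap,
    categories: dict[str, str],
    by: str = "origin",
) -> pd.DataFrame:
    """Per-class, per-focal-reach fraction of sequences carried by OTUs of
    each category.

    Sites within a reach are pooled by summation within each campaign;
    per-campaign fractions are then averaged over campaigns.  A class with
    zero sequences in a reach (every campaign) yields missing fractions,
    not zeros.  Columns: class, focal_reach, category, fraction.
    """
    if by == "origin":
        cat_labels = list(REACHES)
    elif by == "dominance":
        cat_labels = list(DOMINANCE_LABELS)
    else:
        raise ValueError(f"unknown scheme {by!r}")
    _check_samples(table, frames)
    meta = frames.frame.set_index("sample_id").loc[table.sample_ids]
    reach = meta["reach"].to_numpy()
    campaign = meta["campaign"].to_numpy()
    campaigns = list(dict.fromkeys(campaign))

    klass = np.array([taxonomy.class_of(o) or "" for o in table.otu_ids])
    cat = np.array([categories.get(o, "") for o in table.otu_ids])
    classes = [c for c in dict.fromkeys(klass) if c]

    rows = []
    for cls in classes:
        in_cls = klass == cls
        for focal in REACHES:
            per_campaign: dict[str, list[float]] = {g: [] for g in cat_labels}
            for camp in campaigns:
                cols = (reach == focal) & (campaign == camp)
                sub = table.counts[np.ix_(in_cls, cols)]
                total = sub.sum()
                if total == 0:
                    continue
                for g in cat_labels:
                    sel = cat[in_cls] == g
                    per_campaign[g].append(sub[sel].sum() / total)
            for g in cat_labels:
                vals = per_campaign[g]
                rows.append(
                    {
                        "class": cls,
                        "focal_reach": focal,
                        "category": g,
                        "fraction": float(np.mean(vals)) if vals else None,
                    }
                )
    return pd.DataFrame(rows)
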