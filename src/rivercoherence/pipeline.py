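"""End-to-end orchestration of the analysis with a single YAML config.

Stage order is fixed: load/validate -> rarefy -> alpha diversity + reach
contrasts -> beta distances + ANOSIM -> origin/dominance categorization ->
coherence partitions + subgroup summaries -> environmental PCA + axis
correlations.  Every stage writes its table; a manifest records each
output file with the config hash.  One global seed is deterministically
split per stochastic stage so stages are individually reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .beta import anosim, bray_curtis, weighted_normalized_unifrac
from .coherence import (
    flag_dominant_otus,
    partition_all_classes,
    positive_fraction,
    subgroup_summary,
    subgroup_taxonomy,
)
from .datatypes import DOWNSTREAM, JoinError, UPSTREAM
from .diversity import alpha_records, rarefy, reach_contrast
from .envpca import correlate_with_axes, env_pca
from .reaches import assign_dominance, assign_origin, summarize_reach_fractions

log = logging.getLogger("rivercoherence")

__all__ = ["PipelineConfig", "run_pipeline", "derive_seed"]


def derive_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 from one global seed."""
    ss = np.random.SeedSequence([seed, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class PipelineConfig:
    table: str
    metadata: str
    taxonomy: str
    out_dir: str
    tree: str | None = None
    env: str | None = None
    depth: int = 1000
    seed: int = 0
    alpha: float = 0.05
    family: str = "within_class"
    dominance_threshold: float = 0.001
    n_permutations: int = 9999
    rotation: str = "oblimin"
    classes: list[str] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        return cls(**doc)

    def validate(self) -> None:
        for name in ("table", "metadata", "taxonomy", "tree", "env"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config path {name!r} does not exist: {p}")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

    def digest(self) -> str:
        doc = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(doc.encode()).hexdigest()[:12]


def _contrast_row(contrast) -> dict:
    return {
        "metric": contrast.metric,
        "mean_upstream": contrast.mean_upstream,
        "mean_downstream": contrast.mean_downstream,
        "signed_ratio": contrast.signed_ratio,
        "log2_ratio": contrast.log2_ratio,
        "anova_p": contrast.anova_p,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (also written to disk).

    On a stage failure the manifest is still written, marked incomplete,
    before the error propagates with a stage-named message.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.digest(),
        "config": dict(config.__dict__),
        "outputs": [],
        "complete": False,
    }

    def emit(name: str, df: pd.DataFrame, index: bool = False) -> None:
        path = out / name
        rio.write_table(df, path, index=index)
        manifest["outputs"].append(name)

    stage = "load"
    try:
        # ---- load / validate ----------------------------------------
        table = rio.read_otu_table(config.table)
        frames = rio.read_metadata(config.metadata)
        taxonomy = rio.read_taxonomy(config.taxonomy)
        tree = rio.read_tree(config.tree) if config.tree else None
        env = rio.read_env(config.env) if config.env else None
        missing = sorted(set(table.sample_ids) - set(frames.sample_ids))
        if missing:
            raise JoinError(f"samples missing from metadata: {missing}", missing)
        log.info(
            "loaded %d OTUs x %d samples", len(table.otu_ids), len(table.sample_ids)
        )
        reach_map = frames.reach_of().to_dict()
        campaign_map = frames.frame.set_index("sample_id")["campaign"].to_dict()
        classes = config.classes or sorted(
            {c for c in (taxonomy.class_of(o) for o in table.otu_ids) if c}
        )

        # ---- rarefy --------------------------------------------------
        stage = "rarefy"
        rr = rarefy(table, config.depth, derive_seed(config.seed, "rarefy"))
        rare = rr.table
        log.info(
            "rarefied to depth %d; dropped %d samples %s",
            config.depth,
            len(rr.dropped_samples),
            rr.dropped_samples,
        )
        rio.write_otu_table(rare, out / "rarefied_table.tsv")
        manifest["outputs"].append("rarefied_table.tsv")
        manifest["dropped_samples"] = rr.dropped_samples

        # ---- alpha diversity + contrasts ----------------------------
        stage = "diversity"
        alpha_parts = [alpha_records(rare, tree, scope="all")]
        for cls in classes:
            members = [o for o in rare.otu_ids if taxonomy.class_of(o) == cls]
            if members:
                alpha_parts.append(
                    alpha_records(rare.subset_otus(members), tree, scope=cls)
                )
        alpha = pd.concat(alpha_parts, ignore_index=True)
        emit("alpha_diversity.tsv", alpha)
        raw_alpha = alpha_records(table, None, scope="all")
        contrasts = []
        frames_rare = frames.subset(rare.sample_ids)
        for scope, records in (
            ("all", alpha[alpha["scope"] == "all"]),
            *[(c, alpha[alpha["scope"] == c]) for c in classes],
        ):
            for metric in ("n_sequences", "richness", "shannon", "mpd"):
                sub = records.dropna(subset=[metric]) if metric == "mpd" else records
                try:
                    c = reach_contrast(sub, frames_rare, metric)
                except ValueError:
                    continue
                row = {"scope": scope, **_contrast_row(c)}
                contrasts.append(row)
        contrasts.append(
            {"scope": "all_nonrarefied", **_contrast_row(reach_contrast(raw_alpha, frames, "n_sequences"))}
        )
        emit("reach_contrasts.tsv", pd.DataFrame(contrasts))

        # ---- beta structure -----------------------------------------
        stage = "beta"
        bc = bray_curtis(rare)
        rio.write_table(
            pd.DataFrame(bc.data, index=bc.ids, columns=bc.ids),
            out / "bray_curtis.tsv",
            index=True,
        )
        manifest["outputs"].append("bray_curtis.tsv")
        dms = {"bray_curtis": bc}
        if tree is not None:
            wu = weighted_normalized_unifrac(rare, tree)
            rio.write_table(
                pd.DataFrame(wu.data, index=wu.ids, columns=wu.ids),
                out / "weighted_normalized_unifrac.tsv",
                index=True,
            )
            manifest["outputs"].append("weighted_normalized_unifrac.tsv")
            dms["weighted_normalized_unifrac"] = wu

        anosim_rows = []
        ud_samples = [
            s for s in rare.sample_ids if reach_map[s] in (UPSTREAM, DOWNSTREAM)
        ]
        scopes = [("all", rare)]
        for cls in classes:
            members = [o for o in rare.otu_ids if taxonomy.class_of(o) == cls]
            if members:
                # class subset of the rarefied table, not renormalized
                scopes.append((cls, rare.subset_otus(members)))
        for scope, scoped in scopes:
            for metric_name, builder in (
                ("bray_curtis", bray_curtis),
                ("weighted_normalized_unifrac", lambda t: weighted_normalized_unifrac(t, tree)),
            ):
                if metric_name != "bray_curtis" and tree is None:
                    continue
                try:
                    dm = builder(scoped)
                except ValueError as exc:
                    log.warning("skipping %s/%s: %s", scope, metric_name, exc)
                    continue
                for grouping_name, samples, mapping in (
                    ("reach_up_vs_down", ud_samples, reach_map),
                    ("campaign", list(scoped.sample_ids), campaign_map),
                ):
                    sub_dm = dm.filter([s for s in samples if s in dm.ids])
                    try:
                        res = anosim(
                            sub_dm,
                            {s: mapping[s] for s in sub_dm.ids},
                            config.n_permutations,
                            derive_seed(config.seed, f"anosim/{scope}/{metric_name}/{grouping_name}"),
                            grouping_name,
                        )
                    except ValueError as exc:
                        log.warning("ANOSIM skipped (%s/%s/%s): %s", scope, metric_name, grouping_name, exc)
                        continue
                    anosim_rows.append(
                        {
                            "scope": scope,
                            "metric": metric_name,
                            "grouping": grouping_name,
                            "R": res.r,
                            "p_value": res.p_value,
                            "n_permutations": res.n_permutations,
                            "n_samples": res.n_samples,
                        }
                    )
        emit("anosim.tsv", pd.DataFrame(anosim_rows))

        # ---- reach categorization (non-rarefied, pooled) -------------
        stage = "categorize"
        origin, origin_excluded = assign_origin(table, frames)
        dominance, dom_excluded = assign_dominance(table, frames)
        cat = pd.DataFrame(
            {
                "otu_id": list(origin),
                "origin": [origin[o] for o in origin],
                "dominance": [dominance[o] for o in origin],
            }
        )
        emit("otu_categories.tsv", cat)
        manifest["excluded_zero_total_otus"] = origin_excluded
        for scheme, cats in (("origin", origin), ("dominance", dominance)):
            summ = summarize_reach_fractions(table, frames, taxonomy, cats, by=scheme)
            emit(f"reach_fractions_{scheme}.tsv", summ)

        # ---- class coherence (non-rarefied, pooled) -------------------
        stage = "coherence"
        dominant = flag_dominant_otus(table, config.dominance_threshold)
        partitions = partition_all_classes(
            table, taxonomy, classes, alpha=config.alpha, family=config.family
        )
        part_rows, summary_rows, taxo_frames, frac_rows = [], [], [], []
        for cls, part in partitions.items():
            rec = part.records.copy()
            rec.insert(0, "class", cls)
            part_rows.append(rec)
            otu_pct, seq_pct = positive_fraction(part, table)
            frac_rows.append(
                {
                    "class": cls,
                    "otu_percent_positive": otu_pct,
                    "sequence_percent_positive": seq_pct,
                    "n_samples": part.n_samples,
                    "family_size": part.family_size,
                }
            )
            pos, nc = subgroup_summary(part, table, tree, dominant)
            for s in (pos, nc):
                summary_rows.append(
                    {
                        "class": s.class_label,
                        "group": s.group,
                        "n_sequences": s.n_sequences,
                        "n_otus": s.n_otus,
                        "percent_dominant": s.percent_dominant,
                        "shannon": s.shannon,
                        "mpd": s.mpd,
                    }
                )
            taxo_frames.append(subgroup_taxonomy(part, table, taxonomy))
        emit("coherence_partition.tsv", pd.concat(part_rows, ignore_index=True))
        emit("coherence_fractions.tsv", pd.DataFrame(frac_rows))
        emit("subgroup_summary.tsv", pd.DataFrame(summary_rows))
        emit("subgroup_taxonomy.tsv", pd.concat(taxo_frames, ignore_index=True))

        # ---- environmental response ----------------------------------
        if env is not None:
            stage = "envpca"
            pca = env_pca(env, rotation=config.rotation)
            rio.write_table(pca.loadings, out / "env_pca_loadings.tsv", index=True)
            rio.write_table(pca.scores, out / "env_pca_scores.tsv", index=True)
            manifest["outputs"] += ["env_pca_loadings.tsv", "env_pca_scores.tsv"]
            emit(
                "env_pca_variance.tsv",
                pd.DataFrame(
                    {
                        "component": ["PC1", "PC2", "total"],
                        "proportion_variance": [
                            *pca.proportion_variance,
                            pca.total_variance,
                        ],
                        "rotation": pca.rotation,
                        "component_correlation": pca.component_correlation,
                    }
                ),
            )
            # unadjusted by default (documented divergence from the
            # Bonferroni used elsewhere in the pipeline)
            otu_corr = correlate_with_axes(table, pca.scores, alpha=config.alpha)
            otu_corr.insert(0, "level", "otu")
            class_vectors = pd.DataFrame(
                {
                    cls: table.subset_otus(
                        [o for o in table.otu_ids if taxonomy.class_of(o) == cls]
                    ).counts.sum(axis=0)
                    for cls in classes
                },
                index=table.sample_ids,
            ).T
            cls_corr = correlate_with_axes(class_vectors, pca.scores, alpha=config.alpha)
            cls_corr.insert(0, "level", "class")
            emit("axis_correlations.tsv", pd.concat([otu_corr, cls_corr], ignore_index=True))

        manifest["complete"] = True
        return manifest
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, default=str)
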