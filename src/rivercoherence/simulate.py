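"""Synthetic river-metacommunity generator with exported ground truth.

Emulates a dam-regulated river survey: 6 upstream sites, 1 reservoir site
and 5 downstream sites sampled over 3 campaigns; a community dominated by
a few bacterial classes with a lognormal rank-abundance structure; and,
within each class, planted subgroups of OTUs that respond to the spatial
(reservoir) step gradient with the class's sign (coherent), the opposite
sign (anti-responders) or not at all (null responders).

Per OTU i and sample s the log intensity is

    log w_i + sigma_i * beta * space(s) + gamma_i * season(s) + jitter

where ``space`` is a step function at the reservoir (0 upstream, 1 at and
below it), ``season`` a campaign score (+1 summer, 0 autumn, -1 winter),
and the jitter a lognormal overdispersion term.  Counts are drawn
multinomially per sample at a depth drawn uniformly from the configured
range, so every sample column sums exactly to its depth.  Environmental
variables are linear combinations of the same space/season factors plus
noise, giving separable seasonal and spatial axes for the rotated PCA.

The same seed always yields a bit-identical bundle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .coherence import CoherencePartition
from .datatypes import (
    DOWNSTREAM,
    REACHES,
    RESERVOIR,
    UPSTREAM,
    EnvMatrix,
    JoinError,
    Lineage,
    OtuTable,
    SampleFrame,
    TaxonomyMap,
)

__all__ = [
    "ClassSpec",
    "SimConfig",
    "GroundTruth",
    "SimulatedBundle",
    "recovery_config",
    "simulate_dataset",
    "score_recovery",
    "write_bundle",
]

RESPONSES = ("coherent_with_class", "anti_responder", "null_responder")


@dataclass(frozen=True)
class ClassSpec:
    """One simulated bacterial class: OTU richness, target share of total
    sequences (at the upstream baseline) and the sign of its spatial trend
    (+1 = more abundant at/below the reservoir)."""

    name: str
    phylum: str
    n_otus: int
    share: float
    spatial_sign: int
    seasonal_sign: int = 1


def _default_classes() -> list[ClassSpec]:
    # richness and shares mirror the six dominant classes of a
    # dam-regulated river survey; Actinobacteria and Alphaproteobacteria
    # increase below the reservoir, the rest decrease.
    return [
        ClassSpec("Actinobacteria", "Actinobacteria", 387, 0.68, +1, +1),
        ClassSpec("Betaproteobacteria", "Proteobacteria", 149, 0.15, -1, -1),
        ClassSpec("Alphaproteobacteria", "Proteobacteria", 79, 0.06, +1, +1),
        ClassSpec("Gammaproteobacteria", "Proteobacteria", 45, 0.006, -1, +1),
        ClassSpec("Flavobacteria", "Bacteroidetes", 65, 0.04, -1, -1),
        ClassSpec("Sphingobacteria", "Bacteroidetes", 36, 0.03, -1, +1),
    ]


@dataclass
class SimConfig:
    """Study-design and effect-size parameters of the generator."""

    sites_per_reach: tuple[int, int, int] = (6, 1, 5)
    campaigns: tuple[str, ...] = ("Jul", "Sep", "Dec")
    classes: list[ClassSpec] = field(default_factory=_default_classes)
    coherent_fraction: float = 0.25
    anti_fraction: float | None = None  # None -> 10 % of the class (capped)
    spatial_effect: float = 1.0  # beta, log scale
    seasonal_effect: float = 0.5  # gamma, log scale
    base_sigma: float = 1.2  # lognormal rank-abundance spread
    coherent_core_decay: float = 0.3  # geometric decay planting a low-diversity core
    n_filler: int = 196  # rare tail OTUs outside the focal classes
    filler_share: float = 0.034
    depth_range: tuple[int, int] = (1000, 6222)
    jitter_cv: float = 0.3  # per-OTU-per-sample lognormal overdispersion
    origin_probs: tuple[float, float, float] = (0.8, 0.1, 0.1)
    class_monophyletic: bool = True
    seed: int = 0

    def validate(self) -> None:
        share_sum = sum(c.share for c in self.classes) + self.filler_share
        if share_sum > 1.0 + 1e-9:
            raise ValueError(f"class + filler shares sum to {share_sum:.3f} > 1")
        if not 0.0 <= self.coherent_fraction <= 1.0:
            raise ValueError("coherent_fraction must lie in [0, 1]")
        if self.anti_fraction is not None and not (
            0.0 <= self.anti_fraction <= 1.0 - self.coherent_fraction
        ):
            raise ValueError("anti_fraction must lie in [0, 1 - coherent_fraction]")
        lo, hi = self.depth_range
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid depth range {self.depth_range}")
        if abs(sum(self.origin_probs) - 1.0) > 1e-9:
            raise ValueError("origin_probs must sum to 1")


def recovery_config(coherent_fraction: float, **overrides) -> SimConfig:
    """Fixed two-class design for parameter-recovery experiments.

    Two focal classes with opposite spatial trends (48 and 32 OTUs,
    baseline shares 0.5 and 0.4), a 10 % rare-filler tail, even sampling
    at depth 2000, a strong reservoir effect (beta = 2 on the log scale)
    and a moderate rank-abundance spread so the planted responders are
    detectable at that depth.
    """
    params: dict = dict(
        classes=[
            ClassSpec("ClassA", "PhylumA", 48, 0.5, +1, +1),
            ClassSpec("ClassB", "PhylumB", 32, 0.4, -1, -1),
        ],
        coherent_fraction=coherent_fraction,
        spatial_effect=2.0,
        base_sigma=0.8,
        coherent_core_decay=0.0,
        n_filler=20,
        filler_share=0.1,
        depth_range=(2000, 2000),
    )
    params.update(overrides)
    return SimConfig(**params)


@dataclass
class GroundTruth:
    """Planted per-OTU labels and effect sizes.

    ``frame`` columns: otu_id, class, response (coherent_with_class /
    anti_responder / null_responder), spatial_sign, spatial_effect,
    seasonal_effect, origin.  ``class_trends`` maps class -> spatial sign.
    """

    frame: pd.DataFrame
    class_trends: dict[str, int]

    def response_of(self) -> pd.Series:
        return self.frame.set_index("otu_id")["response"]

    def coherent_fraction(self, class_label: str | None = None) -> float:
        df = self.frame
        if class_label is not None:
            df = df[df["class"] == class_label]
        return float((df["response"] == "coherent_with_class").mean())


@dataclass
class SimulatedBundle:
    table: OtuTable
    taxonomy: TaxonomyMap
    tree: TreeNode
    frames: SampleFrame
    env: EnvMatrix
    truth: GroundTruth
    config: SimConfig


def _season_score(campaign: str, campaigns: tuple[str, ...]) -> float:
    """Map campaigns to a symmetric seasonal score (+1 ... -1)."""
    k = len(campaigns)
    if k == 1:
        return 0.0
    return 1.0 - 2.0 * campaigns.index(campaign) / (k - 1)


def _random_clade(labels: list[str], rng: np.random.Generator, mean_bl: float) -> str:
    """Random bifurcating newick subtree over labels with exponential
    branch lengths (order-of-labels randomized by the caller)."""

    def build(lbls: list[str]) -> str:
        if len(lbls) == 1:
            return f"{lbls[0]}:{rng.exponential(mean_bl):.6f}"
        cut = int(rng.integers(1, len(lbls)))
        left = build(lbls[:cut])
        right = build(lbls[cut:])
        return f"({left},{right}):{rng.exponential(mean_bl):.6f}"

    return build(labels)


def simulate_dataset(config: SimConfig, seed: int | None = None) -> SimulatedBundle:
    """Generate a complete input bundle (table, taxonomy, tree, metadata,
    environment) plus the planted ground truth."""
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    # ---- design -----------------------------------------------------
    n_up, n_rs, n_dw = config.sites_per_reach
    sites: list[tuple[str, str, int]] = []
    order = 0
    for prefix, reach, n in (("U", UPSTREAM, n_up), ("R", RESERVOIR, n_rs), ("D", DOWNSTREAM, n_dw)):
        for i in range(n):
            order += 1
            sites.append((f"{prefix}{i + 1}", reach, order))
    rows = []
    for site_id, reach, flow in sites:
        for camp in config.campaigns:
            rows.append(
                {
                    "sample_id": f"{site_id}_{camp}",
                    "site_id": site_id,
                    "reach": reach,
                    "flow_order": flow,
                    "campaign": camp,
                }
            )
    frames = SampleFrame(pd.DataFrame(rows))
    sample_ids = frames.sample_ids
    n_samples = len(sample_ids)
    space = np.array(
        [0.0 if r == UPSTREAM else 1.0 for r in frames.frame["reach"]]
    )
    season = np.array(
        [_season_score(c, tuple(config.campaigns)) for c in frames.frame["campaign"]]
    )

    # ---- per-OTU structure ------------------------------------------
    otu_ids: list[str] = []
    base_w: list[float] = []
    sigma: list[float] = []  # spatial sign
    gamma_sign: list[float] = []
    responses: list[str] = []
    klasses: list[str] = []
    lineages: dict[str, Lineage] = {}
    coherent_by_class: dict[str, list[str]] = {}
    other_by_class: dict[str, list[str]] = {}

    f = config.coherent_fraction
    # anti-responders are a minority by default: enough to produce
    # opposite-sign dynamics within every class without cancelling the
    # class's own trend
    anti_f = (
        config.anti_fraction
        if config.anti_fraction is not None
        else min(0.1, 1.0 - f)
    )

    counter = 0
    for spec in config.classes:
        n = spec.n_otus
        n_coh = int(round(f * n))
        n_anti = min(int(round(anti_f * n)), n - n_coh)
        labels = [f"OTU_{counter + i + 1:04d}" for i in range(n)]
        counter += n
        perm = rng.permutation(n)
        coh_idx = set(perm[:n_coh].tolist())
        anti_idx = set(perm[n_coh : n_coh + n_anti].tolist())

        w = np.exp(rng.normal(0.0, config.base_sigma, n))
        # plant a low-diversity coherent core: geometric decay over the
        # coherent OTUs makes the positive subgroup more uneven
        rank = 0
        for i in sorted(coh_idx):
            w[i] *= math.exp(-config.coherent_core_decay * rank)
            rank += 1
        w *= spec.share / w.sum()

        coherent_by_class[spec.name] = []
        other_by_class[spec.name] = []
        for i, otu in enumerate(labels):
            otu_ids.append(otu)
            base_w.append(w[i])
            klasses.append(spec.name)
            if i in coh_idx:
                responses.append("coherent_with_class")
                sigma.append(float(spec.spatial_sign))
                gamma_sign.append(float(spec.seasonal_sign))
                order_label = f"{spec.name}_order_1"
                coherent_by_class[spec.name].append(otu)
            elif i in anti_idx:
                responses.append("anti_responder")
                sigma.append(-float(spec.spatial_sign))
                gamma_sign.append(-float(spec.seasonal_sign))
                order_label = f"{spec.name}_order_{int(rng.integers(2, 6))}"
                other_by_class[spec.name].append(otu)
            else:
                # null responders have no systematic response on either
                # axis; their variation is pure sampling + overdispersion
                responses.append("null_responder")
                sigma.append(0.0)
                gamma_sign.append(0.0)
                order_label = f"{spec.name}_order_{int(rng.integers(2, 6))}"
                other_by_class[spec.name].append(otu)
            lineages[otu] = Lineage(
                domain="Bacteria",
                phylum=spec.phylum,
                klass=spec.name,
                order=order_label,
            )

    filler_ids = [f"OTU_{counter + i + 1:04d}" for i in range(config.n_filler)]
    if filler_ids:
        wf = np.exp(rng.normal(0.0, 2.0, config.n_filler))
        wf *= config.filler_share / wf.sum()
        for otu, w in zip(filler_ids, wf):
            otu_ids.append(otu)
            base_w.append(float(w))
            klasses.append("")
            responses.append("null_responder")
            sigma.append(0.0)
            gamma_sign.append(0.0)
            lineages[otu] = Lineage(domain="Bacteria", phylum="Other")

    n_otus = len(otu_ids)
    base = np.array(base_w)
    sigma_arr = np.array(sigma)
    gamma_arr = np.array(gamma_sign) * config.seasonal_effect

    # planted origin: an OTU originating at the reservoir (downstream) is
    # structurally absent from every sample above its origin reach
    origins = rng.choice(len(REACHES), size=n_otus, p=list(config.origin_probs))
    reach_rank = {UPSTREAM: 0, RESERVOIR: 1, DOWNSTREAM: 2}
    sample_rank = np.array([reach_rank[r] for r in frames.frame["reach"]])
    allowed = sample_rank[None, :] >= origins[:, None]  # n_otus x n_samples

    # ---- counts ------------------------------------------------------
    jitter_sd = math.sqrt(math.log(1.0 + config.jitter_cv**2))
    # effects enter as deviations from the design mean so a responder's
    # base weight stays its design-average abundance; this keeps the
    # class trend the f-weighted resultant of its members' responses
    space_c = space - space.mean()
    season_c = season - season.mean()
    log_lambda = (
        np.log(base)[:, None]
        + sigma_arr[:, None] * config.spatial_effect * space_c[None, :]
        + gamma_arr[:, None] * season_c[None, :]
        + rng.normal(0.0, jitter_sd, (n_otus, n_samples))
    )
    intensity = np.exp(log_lambda) * allowed
    depths = rng.integers(config.depth_range[0], config.depth_range[1] + 1, n_samples)
    counts = np.zeros((n_otus, n_samples), dtype=np.int64)
    for j in range(n_samples):
        probs = intensity[:, j] / intensity[:, j].sum()
        counts[:, j] = rng.multinomial(depths[j], probs)
    table = OtuTable(otu_ids, sample_ids, counts)

    # ---- tree --------------------------------------------------------
    clades = []
    for spec in config.classes:
        coh = list(coherent_by_class[spec.name])
        rest = list(other_by_class[spec.name])
        rng.shuffle(coh)
        rng.shuffle(rest)
        parts = []
        if coh:
            parts.append(_random_clade(coh, rng, 0.03))
        if rest:
            parts.append(_random_clade(rest, rng, 0.12))
        if len(parts) == 2:
            clades.append(f"({parts[0]},{parts[1]}):{rng.exponential(0.2):.6f}")
        else:
            clades.append(parts[0])
    if filler_ids:
        fl = list(filler_ids)
        rng.shuffle(fl)
        clades.append(_random_clade(fl, rng, 0.15))
    if not config.class_monophyletic:
        # shuffle tips across the whole tree instead of per-class clades
        all_tips = list(otu_ids)
        rng.shuffle(all_tips)
        newick = f"({_random_clade(all_tips, rng, 0.1)});"
    else:
        # fold class clades pairwise so the root stays strictly bifurcating
        while len(clades) > 1:
            a, b = clades.pop(0), clades.pop(0)
            clades.append(f"({a},{b}):{rng.exponential(0.2):.6f}")
        newick = f"({clades[0]});"
    import io as _io

    tree = TreeNode.read(_io.StringIO(newick), convert_underscores=False)

    # ---- environment -------------------------------------------------
    # (name, unit, mean, seasonal amplitude, spatial amplitude, noise sd)
    env_spec = [
        ("temperature", "degC", 14.0, 8.0, 0.0, 1.0),
        ("dissolved_oxygen", "mg L-1", 9.0, -2.5, 0.0, 0.4),
        ("daylength", "h", 12.0, 3.5, 0.0, 0.5),
        ("conductivity", "uS cm-1", 900.0, 0.0, -450.0, 60.0),
        ("DIN", "umol L-1", 60.0, 0.0, -35.0, 6.0),
        ("chlorophyll_a", "ug L-1", 6.0, 0.0, -3.5, 0.6),
        ("suspended_solids", "mg L-1", 20.0, 0.0, -12.0, 2.0),
        ("DOC", "mg L-1", 4.0, 0.8, -1.5, 0.4),
    ]
    env_data = {}
    units = {}
    for name, unit, mean, amp_season, amp_space, sd in env_spec:
        env_data[name] = (
            mean
            + amp_season * season
            + amp_space * (space - 0.5)
            + rng.normal(0.0, sd, n_samples)
        )
        units[name] = unit
    env = EnvMatrix(pd.DataFrame(env_data, index=sample_ids), units)

    truth = GroundTruth(
        frame=pd.DataFrame(
            {
                "otu_id": otu_ids,
                "class": klasses,
                "response": responses,
                "spatial_sign": sigma_arr,
                "spatial_effect": sigma_arr * config.spatial_effect,
                "seasonal_effect": gamma_arr,
                "origin": [REACHES[o] for o in origins],
            }
        ),
        class_trends={c.name: c.spatial_sign for c in config.classes},
    )
    return SimulatedBundle(table, TaxonomyMap(lineages), tree, frames, env, truth, config)


def score_recovery(
    partition: CoherencePartition | pd.DataFrame,
    truth: GroundTruth,
    planted_fraction: float | None = None,
) -> tuple[float, float, float]:
    """(sensitivity, specificity, fraction error) of a coherence partition
    against the planted ground truth.

    sensitivity: share of planted coherent OTUs with verdict positive;
    specificity: share of anti/null responders not given positive;
    fraction error: |positive share of testable OTUs - planted coherent
    fraction| (the planted fraction is taken from the truth over the
    partitioned OTUs unless given explicitly).
    """
    records = partition.records if isinstance(partition, CoherencePartition) else partition
    resp = truth.response_of()
    missing = sorted(set(records["otu_id"]) - set(resp.index))
    if missing:
        raise JoinError(f"partition OTUs missing from ground truth: {missing}", missing)
    merged = records.merge(
        resp.rename("response"), left_on="otu_id", right_index=True
    )
    coherent = merged["response"] == "coherent_with_class"
    positive = merged["verdict"] == "positive"
    sensitivity = float(positive[coherent].mean()) if coherent.any() else float("nan")
    specificity = float((~positive[~coherent]).mean()) if (~coherent).any() else float("nan")
    testable = merged["verdict"] != "untestable"
    recovered = float(positive[testable].mean()) if testable.any() else float("nan")
    if planted_fraction is None:
        planted_fraction = float(coherent.mean())
    return sensitivity, specificity, abs(recovered - planted_fraction)


def write_bundle(bundle: SimulatedBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the five input files plus ground truth and the serialized
    config into ``out_dir``; returns the path map."""
    import yaml

    from . import io as rio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "table": out / "otu_table.tsv",
        "taxonomy": out / "taxonomy.tsv",
        "tree": out / "tree.nwk",
        "metadata": out / "metadata.tsv",
        "env": out / "environment.tsv",
        "ground_truth": out / "ground_truth.tsv",
        "config": out / "sim_config.yaml",
    }
    rio.write_otu_table(bundle.table, paths["table"])
    rio.write_taxonomy(bundle.taxonomy, paths["taxonomy"])
    rio.write_tree(bundle.tree, paths["tree"])
    rio.write_metadata(bundle.frames, paths["metadata"])
    rio.write_env(bundle.env, paths["env"])
    bundle.truth.frame.to_csv(paths["ground_truth"], sep="\t", index=False)
    cfg = asdict(bundle.config)
    cfg["classes"] = [asdict(c) for c in bundle.config.classes]
    with open(paths["config"], "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return paths
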