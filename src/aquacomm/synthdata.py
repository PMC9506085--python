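"""Synthetic bacterioplankton datasets with known assembly regimes.

The generator mirrors a two-group pond experiment: ponds with (PC) and
without (MC) an apex predator, sampled at successive culture stages.  It
produces a pure-birth phylogeny, phylogenetically conserved niche optima
(Brownian trait evolution), environmental trajectories whose nitrate
excursion is amplified in the predator group, and OTU count tables drawn
under one of three regimes:

``selection``
    sampling weights follow Gaussian niche responses to a driver factor
    (nitrate by default), so communities are environmentally filtered;
``neutral``
    every sample is a multinomial draw from one shared log-normal
    metacommunity, so differences between samples are pure sampling drift;
``homogenizing_dispersal``
    a single realized pool composition is drawn once and every sample is a
    multinomial draw from it — high migration homogenizes composition.

Because the regime is known, downstream null-model inference (betaNTI,
Raup-Crick, process partitioning) can be validated by parameter recovery.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from skbio import TreeNode

from aquacomm.core_io import ENV_FACTORS

STAGE_LABELS = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII")

# Stage-mean anchor profiles (early -> late culture), in field-realistic
# units for crustacean ponds: temperature cools toward harvest, ammonia and
# nitrite peak mid-culture as feeding intensifies, nitrate and total
# nitrogen show the opposite trajectory (dip then accumulate).
_ANCHORS = {
    "temperature": (30.0, 27.0, 24.0, 21.0),  # degC, strictly decreasing
    "pH": (8.2, 8.0, 7.9, 7.8),
    "DO": (7.5, 6.8, 6.5, 7.0),  # mg/L
    "ammonia": (0.20, 0.80, 0.60, 0.30),  # mg/L, rise then fall
    "nitrite": (0.05, 0.25, 0.20, 0.10),  # rise then fall
    "nitrate": (0.60, 0.25, 0.35, 0.80),  # fall then rise
    "TN": (2.50, 1.80, 2.00, 3.00),  # fall then rise
    "TP": (0.30, 0.25, 0.28, 0.35),
}

REGIMES = ("selection", "neutral", "homogenizing_dispersal")


@dataclass
class Scenario:
    """Design and generative parameters for one synthetic dataset.

    Defaults mirror the emulated study: 2 groups x 4 stages x 4 ponds
    (32 samples), thousands of taxa, a per-sample depth of 16,984 reads,
    and a predator-group nitrate excursion twice the control group's.
    """

    n_taxa: int = 2000
    n_ponds_per_group: int = 4
    n_stages: int = 4
    depth: int = 16984
    regime: str = "neutral"
    selection_width: float = 0.1
    trait_rate: float = 0.05
    nitrate_amplitude_ratio: float = 2.0
    noise_sd: float = 0.02
    driver: str = "nitrate"
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 1 or self.n_ponds_per_group < 1 or self.n_stages < 1:
            raise ValueError("all design counts must be >= 1")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.selection_width <= 0:
            raise ValueError("selection_width must be > 0")
        if self.nitrate_amplitude_ratio < 1:
            raise ValueError("nitrate_amplitude_ratio must be >= 1")
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}")
        if self.driver not in ENV_FACTORS:
            raise ValueError(f"driver must be one of {ENV_FACTORS}")

    @property
    def n_samples(self) -> int:
        return 2 * self.n_ponds_per_group * self.n_stages


@dataclass
class SyntheticDataset:
    otu_table: pd.DataFrame
    tree: TreeNode
    env: pd.DataFrame
    metadata: pd.DataFrame
    truth: dict = field(default_factory=dict)


def simulate_tree(n_taxa: int, seed: int | None = None) -> TreeNode:
    """Pure-birth (Yule) tree with ``n_taxa`` tips labeled OTU_1..OTU_n.

    Lineages split at unit rate; all branch lengths are strictly positive
    exponential increments, so every pair of tips has positive patristic
    distance.  Deterministic for a fixed seed.
    """
    if n_taxa < 1:
        raise ValueError(f"n_taxa must be >= 1, got {n_taxa}")
    rng = np.random.default_rng(seed)
    root = TreeNode()
    if n_taxa == 1:
        tip = TreeNode(length=float(rng.exponential(1.0)))
        root.append(tip)
        tip.name = "OTU_1"
        return root

    birth: dict[int, float] = {}
    active: list[TreeNode] = []
    t = 0.0
    for _ in range(2):
        child = TreeNode()
        root.append(child)
        birth[id(child)] = 0.0
        active.append(child)
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / len(active))
        idx = int(rng.integers(len(active)))
        node = active.pop(idx)
        node.length = t - birth.pop(id(node))
        for _ in range(2):
            child = TreeNode()
            node.append(child)
            birth[id(child)] = t
            active.append(child)
    t_end = t + rng.exponential(1.0 / len(active))
    for node in active:
        node.length = t_end - birth.pop(id(node))
    for i, tip in enumerate(root.tips(), start=1):
        tip.name = f"OTU_{i}"
    return root


def evolve_trait_optima(
    tree: TreeNode,
    trait_rate: float,
    env_range: tuple[float, float],
    seed: int | None = None,
) -> dict[str, float]:
    """Niche optima by a Brownian walk along branches.

    Per-branch increments are Gaussian with variance ``trait_rate x branch
    length``; the root state is the midpoint of ``env_range`` and tip values
    are clipped into the range.  Close relatives therefore receive similar
    optima — the phylogenetic niche conservatism that makes selection
    detectable by betaNTI.
    """
    if trait_rate < 0:
        raise ValueError(f"trait_rate must be >= 0, got {trait_rate}")
    lo, hi = float(env_range[0]), float(env_range[1])
    if not (np.isfinite(lo) and np.isfinite(hi)):
        raise ValueError("env_range must be finite")
    rng = np.random.default_rng(seed)
    states = {id(tree): 0.5 * (lo + hi)}
    optima: dict[str, float] = {}
    for node in tree.preorder(include_self=False):
        bl = node.length or 0.0
        step = rng.normal(0.0, np.sqrt(trait_rate * bl)) if trait_rate * bl > 0 else 0.0
        state = states[id(node.parent)] + step
        states[id(node)] = state
        if node.is_tip():
            optima[node.name] = float(np.clip(state, lo, hi))
    return optima


def _stage_means(factor: str, n_stages: int) -> np.ndarray:
    anchors = np.asarray(_ANCHORS[factor], dtype=float)
    if n_stages == len(anchors):
        return anchors
    u = np.linspace(0.0, 1.0, n_stages)
    return np.interp(u, np.linspace(0.0, 1.0, len(anchors)), anchors)


def sample_ids_and_metadata(scenario: Scenario) -> pd.DataFrame:
    """Sample sheet for the 2-group x stages x ponds design."""
    rows = []
    for group in ("MC", "PC"):
        for pond in range(1, scenario.n_ponds_per_group + 1):
            for s in range(scenario.n_stages):
                stage = (
                    STAGE_LABELS[s] if s < len(STAGE_LABELS) else f"S{s + 1}"
                )
                sid = f"{group}{pond}_{stage}"
                rows.append((sid, group, stage, f"{group}{pond}"))
    md = pd.DataFrame(rows, columns=["sample_id", "group", "stage", "pond"])
    return md.set_index("sample_id")


def simulate_env(scenario: Scenario, seed: int | None = None) -> pd.DataFrame:
    """Environmental trajectories for all samples.

    Stage means follow the anchor profiles; the PC group's nitrate stage
    means are rescaled about their mean so the excursion (max - min) equals
    ``nitrate_amplitude_ratio`` times the MC excursion before noise.
    Per-observation Gaussian noise with sd ``noise_sd`` is then added.
    """
    if seed is None:
        seed = scenario.seed
    rng = np.random.default_rng(seed)
    md = sample_ids_and_metadata(scenario)
    stage_order = {lab: i for i, lab in enumerate(pd.unique(md["stage"]))}
    env = pd.DataFrame(index=md.index, columns=list(ENV_FACTORS), dtype=float)
    for factor in ENV_FACTORS:
        means = _stage_means(factor, scenario.n_stages)
        for group in ("MC", "PC"):
            g_means = means.copy()
            if factor == "nitrate" and group == "PC":
                center = g_means.mean()
                g_means = center + scenario.nitrate_amplitude_ratio * (g_means - center)
            mask = md["group"] == group
            stages = md.loc[mask, "stage"].map(stage_order).to_numpy()
            env.loc[mask, factor] = g_means[stages]
    noise = rng.normal(0.0, scenario.noise_sd, size=env.shape)
    env = env + noise
    return env


def driver_range(scenario: Scenario) -> tuple[float, float]:
    """Noiseless span of the driver factor across both groups, 10% padded."""
    means = _stage_means(scenario.driver, scenario.n_stages)
    values = [means]
    if scenario.driver == "nitrate":
        center = means.mean()
        values.append(center + scenario.nitrate_amplitude_ratio * (means - center))
    allv = np.concatenate(values)
    lo, hi = allv.min(), allv.max()
    pad = 0.1 * (hi - lo) if hi > lo else 1.0
    return float(lo - pad), float(hi + pad)


def assemble_communities(
    scenario: Scenario,
    tree: TreeNode,
    optima: Mapping[str, float],
    env: pd.DataFrame,
    seed: int | None = None,
) -> pd.DataFrame:
    """OTU counts per sample under the scenario's assembly regime.

    Every sample is ``depth`` categorical draws (a multinomial), so each
    column sums exactly to ``depth``.
    """
    if seed is None:
        seed = scenario.seed
    rng = np.random.default_rng(seed)
    taxa = [tip.name for tip in tree.tips()]
    missing = [t for t in taxa if t not in optima]
    if missing:
        raise ValueError(f"optima missing for taxa: {missing[:5]}")
    n_taxa = len(taxa)
    samples = list(env.index)
    counts = np.zeros((n_taxa, len(samples)), dtype=np.int64)

    meta_abund = rng.lognormal(mean=0.0, sigma=1.5, size=n_taxa)
    meta_p = meta_abund / meta_abund.sum()

    if scenario.regime == "selection":
        if scenario.selection_width <= 0:
            raise ValueError("selection_width must be > 0 under selection")
        o = np.array([optima[t] for t in taxa])
        x = env[scenario.driver].to_numpy(dtype=float)
        for j, xs in enumerate(x):
            logw = -((xs - o) ** 2) / (2.0 * scenario.selection_width**2)
            w = np.exp(logw - logw.max())
            counts[:, j] = rng.multinomial(scenario.depth, w / w.sum())
    elif scenario.regime == "neutral":
        for j in range(len(samples)):
            counts[:, j] = rng.multinomial(scenario.depth, meta_p)
    else:  # homogenizing_dispersal
        pool = rng.multinomial(scenario.depth, meta_p) / scenario.depth
        for j in range(len(samples)):
            counts[:, j] = rng.multinomial(scenario.depth, pool)
    return pd.DataFrame(counts, index=taxa, columns=samples)


def simulate_taxonomy(taxa, seed: int | None = None, n_genera: int = 40) -> pd.Series:
    """Genus-like taxonomy strings for function-assignment fixtures."""
    rng = np.random.default_rng(seed)
    phyla = [f"p__Phylum{k}" for k in range(1, 7)]
    genera = [f"g__Genus{k}" for k in range(1, n_genera + 1)]
    strings = [
        "d__Bacteria; "
        + phyla[int(rng.integers(len(phyla)))]
        + "; "
        + genera[int(rng.integers(len(genera)))]
        for _ in taxa
    ]
    return pd.Series(strings, index=list(taxa), name="taxonomy")


def generate_dataset(scenario: Scenario) -> SyntheticDataset:
    """Compose tree, optima, environment and communities with truth labels."""
    ss = np.random.SeedSequence(scenario.seed)
    s_tree, s_trait, s_env, s_comm = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)
    )
    tree = simulate_tree(scenario.n_taxa, seed=s_tree)
    env_range = driver_range(scenario)
    optima = evolve_trait_optima(tree, scenario.trait_rate, env_range, seed=s_trait)
    metadata = sample_ids_and_metadata(scenario)
    env = simulate_env(scenario, seed=s_env)
    table = assemble_communities(scenario, tree, optima, env, seed=s_comm)
    truth = {
        "regime": scenario.regime,
        "driver": scenario.driver,
        "optima": dict(optima),
        "selection_width": scenario.selection_width,
    }
    return SyntheticDataset(table, tree, env, metadata, truth)


def write_dataset(dataset: SyntheticDataset, outdir) -> dict[str, Path]:
    """Write table/tree/metadata/env plus a truth sidecar as plain text."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "otu_table": outdir / "otu_table.tsv",
        "tree": outdir / "tree.nwk",
        "metadata": outdir / "metadata.tsv",
        "env": outdir / "env.tsv",
        "truth": outdir / "truth.tsv",
    }
    dataset.otu_table.to_csv(paths["otu_table"], sep="\t", index_label="taxon_id")
    buf = io.StringIO()
    dataset.tree.write(buf, format="newick")
    paths["tree"].write_text(buf.getvalue())
    dataset.metadata.to_csv(paths["metadata"], sep="\t", index_label="sample_id")
    dataset.env.to_csv(paths["env"], sep="\t", index_label="sample_id")
    truth = pd.DataFrame(
        {
            "taxon_id": list(dataset.truth.get("optima", {})),
            "optimum": list(dataset.truth.get("optima", {}).values()),
        }
    )
    with open(paths["truth"], "w") as fh:
        fh.write(f"# regime={dataset.truth.get('regime')}\n")
        fh.write(f"# driver={dataset.truth.get('driver')}\n")
        truth.to_csv(fh, sep="\t", index=False)
    return paths
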