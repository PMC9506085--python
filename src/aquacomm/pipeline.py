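"""End-to-end orchestration: preprocess -> diversity -> assembly ->
environment -> functions -> networks, from a declarative YAML config.

A run either loads the four study inputs (OTU table, tree, metadata,
environment) or generates a synthetic dataset from a scenario block.  One
global seed is split into per-stage sub-seeds by hashing the stage name, so
toggling one stage never shifts another stage's random stream.  Every
output file carries the configuration hash, and a manifest records
versions, seeds and parameters so a report can be regenerated from stage
outputs alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from aquacomm import assembly, core_io, diversity, envadapt, functions, netstab, synthdata
from aquacomm._exceptions import NoTransitionError

log = logging.getLogger("aquacomm.pipeline")

STAGES = ("preprocess", "diversity", "assembly", "envadapt", "functions", "netstab")

# upstream requirements: a stage may only run when these ran before it
_DEPENDENCIES = {
    "diversity": ("preprocess",),
    "assembly": ("preprocess",),
    "envadapt": ("preprocess",),
    "functions": ("preprocess", "assembly"),
    "netstab": ("preprocess",),
}


class ConfigError(ValueError):
    pass


@dataclasses.dataclass
class PipelineConfig:
    outdir: str = "aquacomm_out"
    seed: int = 0
    stages: tuple = STAGES
    scenario: dict | None = None  # synthetic input
    inputs: dict | None = None  # paths: otu_table, tree, metadata, env
    params: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ConfigError(f"unknown stages: {unknown}")
        if self.scenario is None and self.inputs is None:
            raise ConfigError("config needs either a 'scenario' or an 'inputs' block")
        enabled = set(self.stages)
        for stage in self.stages:
            missing = [d for d in _DEPENDENCIES.get(stage, ()) if d not in enabled]
            if missing:
                raise ConfigError(
                    f"stage {stage!r} requires upstream stage(s) {missing}"
                )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def canonical(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("outdir", None)  # where results land does not change what they are
        return json.dumps(d, sort_keys=True, default=str)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage sub-seed derived from the stage name."""
    return (zlib.crc32(stage.encode()) ^ (global_seed * 2654435761)) % (2**31)


def _write(df: pd.DataFrame, path: Path, cfg_hash: str, index_label="sample_id"):
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, index_label=index_label)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; return the summary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash
    p = config.params
    summary: dict = {"config_hash": cfg_hash}
    from aquacomm import __version__ as _version

    manifest = {
        "version": _version,
        "config_hash": cfg_hash,
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in config.stages},
        "params": p,
        "stages": list(config.stages),
    }

    # ---- inputs -------------------------------------------------------
    if config.scenario is not None:
        scen = synthdata.Scenario(**{**config.scenario, "seed": config.seed})
        dataset = synthdata.generate_dataset(scen)
        table, tree = dataset.otu_table, dataset.tree
        metadata, env = dataset.metadata, dataset.env
        synthdata.write_dataset(dataset, outdir / "synthetic")
    else:
        table, tree, metadata, env = core_io.load_inputs(
            config.inputs["otu_table"],
            config.inputs["tree"],
            config.inputs["metadata"],
            config.inputs["env"],
        )

    # ---- preprocess ---------------------------------------------------
    if "preprocess" in config.stages:
        log.info("preprocess: singleton filter + rarefaction")
        table = core_io.preprocess(
            table,
            threshold_fraction=p.get("singleton_threshold", 1e-5),
            depth=p.get("rarefaction_depth"),
            seed=stage_seed(config.seed, "preprocess"),
        )
        table = table.loc[table.sum(axis=1) > 0]
        tree = tree.shear(list(table.index))
        core_io.write_otu_table(
            table, outdir / "otu_table.preprocessed.tsv", f"config_hash={cfg_hash}"
        )
        summary["preprocess"] = {
            "n_taxa": int(table.shape[0]),
            "n_samples": int(table.shape[1]),
            "depth": int(table.sum(axis=0).min()),
        }

    groups = list(pd.unique(metadata["group"]))

    # ---- diversity ----------------------------------------------------
    if "diversity" in config.stages:
        log.info("diversity: alpha, Bray-Curtis, PCoA, PERMANOVA")
        alpha = diversity.alpha_diversity_table(table, tree=tree)
        _write(alpha, outdir / "alpha_diversity.csv", cfg_hash)
        bc = diversity.bray_curtis_matrix(table)
        ord_res = diversity.pcoa(bc, n_axes=2)
        _write(ord_res.coordinates, outdir / "pcoa_coordinates.csv", cfg_hash)
        perm = diversity.permanova(
            bc,
            metadata,
            formula="group + stage + group:stage",
            n_permutations=p.get("permanova_permutations", 999),
            seed=stage_seed(config.seed, "diversity"),
        )
        _write(perm.terms, outdir / "permanova.csv", cfg_hash, index_label="term")
        summary["diversity"] = {
            "permanova": {
                t: {"R2": float(perm.terms.loc[t, "R2"]), "p": float(perm.terms.loc[t, "p"])}
                for t in perm.terms.index
                if t not in ("Residual", "Total")
            },
            "pcoa_axis1_proportion": float(ord_res.proportion_explained[0]),
        }

    # ---- assembly -----------------------------------------------------
    driver = p.get("driver_factor", "nitrate")
    if "assembly" in config.stages:
        log.info("assembly: betaNTI + Raup-Crick partition per group")
        nm = assembly.NullModelConfig(
            n_null=p.get("n_null", 199),
            seed=stage_seed(config.seed, "assembly"),
        )
        summary["assembly"] = {}
        for group in groups:
            samples = metadata.index[metadata["group"] == group]
            sub = table[samples]
            sub = sub.loc[sub.sum(axis=1) > 0]
            sub_tree = tree.shear(list(sub.index))
            bnti = assembly.beta_nti(sub, sub_tree, nm)
            rc = assembly.raup_crick_bray(sub, nm)
            part = assembly.partition_processes(bnti.values, rc, nm)
            assembly.export_pair_matrix(
                bnti.values, outdir / f"bnti.{group}.tsv", flags=bnti.degenerate
            )
            assembly.export_pair_matrix(rc, outdir / f"raup_crick.{group}.tsv")
            part.as_series().to_csv(outdir / f"partition.{group}.csv")
            reg = assembly.pairwise_regression(
                env.loc[samples, driver], bnti.observed_betamntd
            )
            summary["assembly"][group] = {
                "partition": {k: float(v) for k, v in part.as_series().items()},
                "deterministic": float(part.deterministic),
                "stochastic": float(part.stochastic),
                f"betamntd_vs_{driver}": {
                    "slope": reg.slope,
                    "r_squared": reg.r_squared,
                    "p": reg.p_value,
                },
            }
            summary["assembly"][group]["_bnti"] = bnti  # in-memory handoff
        manifest["n_null"] = nm.n_null

    # ---- envadapt -----------------------------------------------------
    if "envadapt" in config.stages:
        log.info("envadapt: RDA + TITAN breadth")
        rda = envadapt.rda_variance(
            table,
            env,
            n_permutations=p.get("rda_permutations", 199),
            seed=stage_seed(config.seed, "envadapt"),
        )
        summary["envadapt"] = {
            "rda_constrained_proportion": float(rda.constrained_proportion),
            "breadth": {},
        }
        factors = p.get("titan_factors", [driver])
        breadth_rows = []
        for group in groups:
            samples = metadata.index[metadata["group"] == group]
            sub = table[samples]
            sub = sub.loc[sub.sum(axis=1) > 0]
            for factor in factors:
                titan = envadapt.titan_change_points(
                    sub,
                    env.loc[samples, factor],
                    n_permutations=p.get("titan_permutations", 100),
                    n_bootstrap=p.get("titan_bootstrap", 50),
                    seed=stage_seed(config.seed, f"envadapt.{group}.{factor}"),
                )
                breadth = envadapt.environmental_breadth(titan)
                titan.taxa.to_csv(outdir / f"titan.{group}.{factor}.tsv", sep="\t")
                breadth_rows.append(
                    {
                        "group": group,
                        "factor": factor,
                        "score_sum": breadth.score_sum,
                        "span_low": breadth.span[0],
                        "span_high": breadth.span[1],
                        "span_width": breadth.span_width,
                        "n_indicators": breadth.n_indicators,
                    }
                )
                summary["envadapt"]["breadth"][f"{group}.{factor}"] = {
                    "span_width": breadth.span_width,
                    "score_sum": breadth.score_sum,
                }
        pd.DataFrame(breadth_rows).to_csv(outdir / "breadth.csv", index=False)

    # ---- functions ----------------------------------------------------
    if "functions" in config.stages:
        log.info("functions: FRI + group ratios + FRI~betaNTI coupling")
        seed_f = stage_seed(config.seed, "functions")
        rng = np.random.default_rng(seed_f)
        if "incidence" in p:
            incidence = pd.read_csv(p["incidence"], sep="\t", index_col=0)
        else:
            # synthetic incidence: each taxon can perform a random subset
            n_funcs = p.get("n_functions", 20)
            incidence = pd.DataFrame(
                rng.random((table.shape[0], n_funcs)) < 0.3,
                index=table.index,
                columns=[f"F{k + 1}" for k in range(n_funcs)],
            ).astype(int)
        fri_by_group = {}
        summary["functions"] = {}
        for group in groups:
            samples = metadata.index[metadata["group"] == group]
            sub = table[samples]
            fri_by_group[group] = functions.functional_redundancy_index(
                sub, tree, incidence
            )
            _write(
                fri_by_group[group].T,
                outdir / f"fri.{group}.csv",
                cfg_hash,
            )
            bnti = summary.get("assembly", {}).get(group, {}).get("_bnti")
            if bnti is not None:
                dfri = functions.delta_fri_matrix(
                    fri_by_group[group][list(bnti.values.index)]
                )
                reg = functions.fri_bnti_regression(dfri, bnti.values)
                summary["functions"][f"fri_bnti.{group}"] = {
                    "slope": reg.slope,
                    "r_squared": reg.r_squared,
                    "p": reg.p_value,
                }
        if len(groups) == 2:
            ratio, more_a, more_b, _ = functions.fri_group_log_ratio(
                fri_by_group[groups[0]], fri_by_group[groups[1]],
                pseudocount=p.get("fri_pseudocount", 1e-6),
            )
            ratio.to_csv(outdir / "fri_log_ratio.csv")
            summary["functions"]["log_ratio_counts"] = {
                f"more_redundant_in_{groups[0]}": more_a,
                f"more_redundant_in_{groups[1]}": more_b,
            }

    # ---- netstab ------------------------------------------------------
    if "netstab" in config.stages:
        log.info("netstab: network construction + stability")
        seed_n = stage_seed(config.seed, "netstab")
        summary["netstab"] = {}
        for group in groups:
            samples = metadata.index[metadata["group"] == group]
            sub = table[samples]
            sub = sub.loc[sub.sum(axis=1) > 0]
            try:
                net = netstab.correlation_network(
                    sub,
                    prevalence_min=p.get("prevalence_min", 0.5),
                    threshold=p.get("network_threshold"),
                    rmt=p.get("rmt", True),
                    seed=seed_n,
                )
            except NoTransitionError:
                log.warning("RMT scan found no transition; fixed threshold 0.8")
                net = netstab.correlation_network(
                    sub,
                    prevalence_min=p.get("prevalence_min", 0.5),
                    threshold=0.8,
                    rmt=False,
                    seed=seed_n,
                )
            topo = netstab.network_topology(net)
            robust_mean, robust_sd = netstab.network_robustness(
                net,
                removal_fraction=p.get("removal_fraction", 0.5),
                n_reps=p.get("robustness_reps", 100),
                seed=seed_n,
            )
            try:
                vuln = netstab.network_vulnerability(net)
            except ValueError:
                vuln = float("nan")
            coh = netstab.cohesion(
                sub, n_null=p.get("cohesion_null", 200), seed=seed_n
            )
            netstab.export_network(net, outdir / f"network.{group}")
            summary["netstab"][group] = {
                "topology": {k: float(v) for k, v in topo.as_series().items()},
                "robustness": {"mean": robust_mean, "sd": robust_sd},
                "vulnerability": vuln,
                "cohesion": {
                    "positive_mean": float(coh.positive.mean()),
                    "negative_mean": float(coh.negative.mean()),
                    "np_ratio_mean": float(coh.np_ratio.mean()),
                },
            }

    # strip in-memory handoffs before serialization
    for group_block in summary.get("assembly", {}).values():
        if isinstance(group_block, dict):
            group_block.pop("_bnti", None)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    return summary
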