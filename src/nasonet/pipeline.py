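"""End-to-end orchestration: simulate/load -> filter/merge -> cluster ->
per-group network inference -> robustness comparison -> keystones.

A single global seed fans out to per-stage seeds through
``numpy.random.SeedSequence(global_seed).spawn``-style state derivation, so
each stage is reproducible in isolation and the whole run is deterministic.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ensemble import EnsembleConfig, SignedNetwork, infer_network, split_subnetworks
from .fusion import (
    FusionConfig,
    eigengap_n_clusters,
    richness_weights,
    similarity_from_profile,
    snf_fuse,
    spectral_cluster,
)
from .profiles import (
    BACTERIA_FILTER,
    FUNGI_FILTER,
    AbundanceTable,
    FilterSpec,
    merge_domains_renormalize,
    prevalence_abundance_filter,
    read_abundance_table,
    read_metadata,
    to_relative,
)
from .robustness import (
    compare_group_robustness,
    keystone_detection,
    negative_subnetwork,
    random_attack,
)
from .synthetic import SimulationConfig, SyntheticCohort, export_ground_truth, simulate_cohort

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "summarize_networks"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one run needs. Exactly one of ``input_tables`` (mapping
    domain -> TSV path, plus ``metadata``) or ``simulation`` must be set."""

    output_dir: str
    simulation: SimulationConfig | None = None
    input_tables: dict[str, str] | None = None
    metadata: str | None = None
    filters: dict[str, FilterSpec] = field(
        default_factory=lambda: {"bacteria": BACTERIA_FILTER, "fungi": FUNGI_FILTER}
    )
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    fusion_iterations: int = 20
    n_attacks: int = 1000
    keystone_permutations: int = 1000
    keystone_alpha: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.input_tables is None):
            raise ValueError("set exactly one of simulation / input_tables")
        if self.input_tables is not None and self.metadata is None:
            raise ValueError("input_tables requires a metadata path")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        kwargs = dict(raw)
        if "simulation" in kwargs and kwargs["simulation"] is not None:
            kwargs["simulation"] = SimulationConfig.from_dict(kwargs["simulation"])
        if "filters" in kwargs:
            kwargs["filters"] = {
                d: FilterSpec(**spec) for d, spec in kwargs["filters"].items()
            }
        if "ensemble" in kwargs and kwargs["ensemble"] is not None:
            kwargs["ensemble"] = EnsembleConfig(**kwargs["ensemble"])
        return cls(**kwargs)


@dataclass
class RunManifest:
    config_echo: dict
    version: str
    seeds: dict[str, int]
    outputs: dict[str, str]
    timings: dict[str, float]
    failure: str | None = None

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)


def _stage_seeds(seed: int) -> dict[str, int]:
    names = ["simulate", "cluster", "infer", "attack", "keystone"]
    state = np.random.SeedSequence(seed).generate_state(len(names)) % (2**31)
    return {name: int(s) for name, s in zip(names, state)}


def _load_tables(config: PipelineConfig) -> tuple[dict[str, AbundanceTable], pd.Series]:
    tables = {}
    for domain, path in config.input_tables.items():
        if not Path(path).exists():
            raise FileNotFoundError(f"input table not found: {path}")
        t = read_abundance_table(path, domain)
        tables[domain] = t if t.mode == "relative" else to_relative(t)
    meta = read_metadata(config.metadata)
    return tables, meta["group"]


def _split_groups(table: AbundanceTable, groups: pd.Series) -> dict[str, AbundanceTable]:
    out = {}
    for group in sorted(groups.unique()):
        samples = [s for s in table.sample_ids if groups.get(s) == group]
        out[group] = to_relative(
            AbundanceTable(table.data[samples], table.domain, "counts")
        )
    return out


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage; outputs land under ``config.output_dir``.

    Stage order: cohort (simulated or loaded), per-domain filtering, merge +
    renormalization, WSNF clustering, per-group ensemble network inference,
    sub-network split, attack-robustness comparison (full and negative-only),
    and keystone detection per group.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    outputs: dict[str, str] = {}
    timings: dict[str, float] = {}
    manifest = RunManifest(
        config_echo=_echo_config(config), version=__version__, seeds=seeds,
        outputs=outputs, timings=timings,
    )
    try:
        _run_stages(config, out, seeds, outputs, timings)
    except Exception as exc:  # partial outputs are retained for debugging
        manifest.failure = f"{type(exc).__name__}: {exc}"
        manifest.write(out / "manifest.json")
        raise
    manifest.write(out / "manifest.json")
    return manifest


def _echo_config(config: PipelineConfig) -> dict:
    echo = {
        "output_dir": config.output_dir,
        "seed": config.seed,
        "n_attacks": config.n_attacks,
        "keystone_permutations": config.keystone_permutations,
        "keystone_alpha": config.keystone_alpha,
        "fusion_iterations": config.fusion_iterations,
        "filters": {
            d: {"min_relative_abundance": f.min_relative_abundance,
                "min_prevalence": f.min_prevalence}
            for d, f in config.filters.items()
        },
        "ensemble": {k: v for k, v in config.ensemble.__dict__.items()},
        "simulation": config.simulation.to_dict() if config.simulation else None,
        "input_tables": config.input_tables,
        "metadata": config.metadata,
    }
    return echo


def _run_stages(config, out, seeds, outputs, timings):
    # ---- stage: cohort ----------------------------------------------------
    t0 = time.perf_counter()
    if config.simulation is not None:
        sim_cfg = SimulationConfig(**{**config.simulation.to_dict(), "seed": seeds["simulate"]
                                      if config.simulation.seed == 0 else config.simulation.seed})
        cohort: SyntheticCohort | None = simulate_cohort(sim_cfg)
        truth_files = export_ground_truth(cohort, out / "ground_truth")
        outputs.update({f"ground_truth_{k}": str(v) for k, v in truth_files.items()})
        full = cohort.merged_relative()
        groups = cohort.group_labels
    else:
        cohort = None
        domain_tables, groups = _load_tables(config)
        full = merge_domains_renormalize(list(domain_tables.values()))
    by_domain = {
        d: AbundanceTable(full.data.loc[full.domain == d], full.domain[full.domain == d],
                          "counts")
        for d in sorted(set(full.domain))
    }
    by_domain = {d: to_relative(t) for d, t in by_domain.items()}
    timings["cohort"] = time.perf_counter() - t0

    # ---- stage: filter + merge -------------------------------------------
    t0 = time.perf_counter()
    filtered = {}
    for domain, t in by_domain.items():
        spec = config.filters.get(domain)
        filtered[domain] = prevalence_abundance_filter(t, spec) if spec else t
    merged = merge_domains_renormalize(list(filtered.values()))
    merged.to_tsv(out / "merged_filtered.tsv")
    outputs["merged_filtered"] = str(out / "merged_filtered.tsv")
    timings["filter_merge"] = time.perf_counter() - t0

    # ---- stage: WSNF clustering ------------------------------------------
    t0 = time.perf_counter()
    sims = [similarity_from_profile(t) for t in filtered.values() if t.n_taxa > 0]
    weights = richness_weights([t for t in filtered.values() if t.n_taxa > 0])
    n = merged.n_samples
    k_nn = max(2, min(20, n // 5))
    fused = snf_fuse(
        sims,
        FusionConfig(k_neighbors=k_nn, iterations=config.fusion_iterations,
                     domain_weights=weights),
    )
    n_clusters = eigengap_n_clusters(fused, k_max=min(10, n - 1))
    assign = spectral_cluster(fused, n_clusters, seed=seeds["cluster"])
    labels = pd.DataFrame({"sample_id": assign.sample_ids, "cluster": assign.labels})
    labels.to_csv(out / "clusters.tsv", sep="\t", index=False)
    outputs["clusters"] = str(out / "clusters.tsv")
    np.savetxt(out / "fused_similarity.tsv", fused.matrix, delimiter="\t")
    outputs["fused_similarity"] = str(out / "fused_similarity.tsv")
    timings["cluster"] = time.perf_counter() - t0

    # ---- stage: per-group network inference ------------------------------
    t0 = time.perf_counter()
    group_tables = _split_groups(merged, groups)
    networks: dict[str, SignedNetwork] = {}
    for g_idx, (group, table) in enumerate(sorted(group_tables.items())):
        cfg = EnsembleConfig(**{**config.ensemble.__dict__,
                                "seed": (seeds["infer"] + g_idx) % (2**31)})
        result = infer_network(table, cfg)
        networks[group] = result.network
        result.network.to_tsv(out / f"network_{group}.tsv")
        result.network.to_graphml(out / f"network_{group}.graphml")
        outputs[f"network_{group}"] = str(out / f"network_{group}.tsv")
        subs = split_subnetworks(result.network)
        for part, sub in subs.items():
            sub.to_tsv(out / f"network_{group}_{part}.tsv")
            outputs[f"network_{group}_{part}"] = str(out / f"network_{group}_{part}.tsv")
    summary = summarize_networks(networks)
    summary.to_csv(out / "network_summary.tsv", sep="\t")
    outputs["network_summary"] = str(out / "network_summary.tsv")
    timings["infer"] = time.perf_counter() - t0

    # ---- stage: robustness + keystones -----------------------------------
    t0 = time.perf_counter()
    group_names = sorted(networks)
    robustness_report: dict = {}
    if len(group_names) == 2:
        g_a, g_b = group_names
        trajs = {}
        for g_idx, g_name in enumerate(group_names):
            net = networks[g_name]
            if net.graph.number_of_nodes() >= 2 and net.n_edges > 0:
                trajs[g_name] = random_attack(
                    net, config.n_attacks, seed=(seeds["attack"] + g_idx) % (2**31)
                )
        if len(trajs) == 2:
            cmp = compare_group_robustness(trajs[g_a], trajs[g_b])
            robustness_report["full"] = {
                "groups": group_names,
                "merged_p": cmp["merged_p"],
                "overall_direction": group_names[0] if cmp["overall_direction"] == "a"
                else (group_names[1] if cmp["overall_direction"] == "b" else "tie"),
            }
    with open(out / "robustness.json", "w") as fh:
        json.dump(robustness_report, fh, indent=2)
    outputs["robustness"] = str(out / "robustness.json")

    for g_idx, g_name in enumerate(group_names):
        net = networks[g_name]
        if net.graph.number_of_nodes() < 3 or net.n_edges == 0:
            continue
        report = keystone_detection(
            net,
            n_permutations=config.keystone_permutations,
            alpha=config.keystone_alpha,
            seed=(seeds["keystone"] + g_idx) % (2**31),
        )
        df = pd.DataFrame(
            {
                "node": report.ranking[: len(report.prefix_p)],
                "prefix_p": report.prefix_p,
                "keystone": [v in report.keystone_nodes
                             for v in report.ranking[: len(report.prefix_p)]],
            }
        )
        df.to_csv(out / f"keystones_{g_name}.tsv", sep="\t", index=False)
        outputs[f"keystones_{g_name}"] = str(out / f"keystones_{g_name}.tsv")
    timings["robustness_keystones"] = time.perf_counter() - t0


def summarize_networks(nets: dict[str, SignedNetwork]) -> pd.DataFrame:
    """Per-group node/edge/sign/sub-network counts (the network summary table)."""
    if not nets:
        raise ValueError("need at least one network")
    rows = {}
    for name, net in sorted(nets.items()):
        by_sign = net.edge_count_by_sign()
        subs = split_subnetworks(net)
        rows[name] = {
            "nodes": net.graph.number_of_nodes(),
            "edges": net.n_edges,
            "positive": by_sign[1],
            "negative": by_sign[-1],
            "bacteria_bacteria": subs["bacteria"].n_edges,
            "fungi_fungi": subs["fungi"].n_edges,
            "cross_domain": subs["cross"].n_edges,
        }
    return pd.DataFrame(rows).T
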