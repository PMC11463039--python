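"""Synthetic two-group multi-kingdom cohorts with planted interaction networks.

The generative model is a latent log-normal composition: per group, sample
log-abundances are multivariate normal with covariance equal to the inverse
of a sparse planted precision matrix, so the planted edge set is exactly the
conditional-dependence structure the network-inference stage targets. The
"interaction sign" of a planted edge is the sign of the partial correlation,
i.e. minus the sign of the precision entry. Latent abundances are
exponentiated, closed to a composition, sampled multinomially at a fixed
sequencing depth, and optionally zero-inflated per cell.

Defaults mirror the study cohort this package was designed around: 122
bacterial and 131 fungal taxa, two groups of 439 and 807 samples, and a
dominance-skewed baseline (log-normal sd 1.5) under which the top-10 taxa
carry most of the community.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .profiles import AbundanceTable, to_relative

__all__ = [
    "PlantedNetwork",
    "SimulationConfig",
    "SyntheticCohort",
    "sample_planted_network",
    "simulate_cohort",
    "export_ground_truth",
]


@dataclass(frozen=True)
class PlantedNetwork:
    """Ground-truth conditional-dependence network for one group.

    ``edge_set`` maps unordered taxon pairs to the interaction sign
    (+1 cooperative, -1 antagonistic) = -sign(precision entry).
    """

    taxa: list[str]
    domain: dict[str, str]
    precision_matrix: np.ndarray
    edge_set: dict[tuple[str, str], int]

    def __post_init__(self) -> None:
        omega = self.precision_matrix
        if not np.allclose(omega, omega.T, atol=1e-10):
            raise ValueError("precision matrix must be symmetric")
        min_eig = float(np.linalg.eigvalsh(omega)[0])
        if min_eig <= 0:
            raise ValueError(f"precision matrix not positive definite (min eig {min_eig:g})")

    @property
    def covariance(self) -> np.ndarray:
        """Latent covariance: inverse precision rescaled to unit variances.

        The correlation rescale fixes the per-taxon latent log-abundance
        standard deviation at 1, so differential effects are expressed in
        sd units; it preserves the support and signs of the conditional-
        dependence structure.
        """
        sigma = np.linalg.inv(self.precision_matrix)
        d = np.sqrt(np.diag(sigma))
        return sigma / np.outer(d, d)

    def edge_sign(self, a: str, b: str) -> int:
        key = (a, b) if a < b else (b, a)
        return self.edge_set[key]


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation parameters.

    differential_taxa maps taxon id -> log-fold effect added to group 2's
    latent mean (so a +2 effect multiplies that taxon's basis abundance by
    e^2 in group 2 before closure).
    """

    n_samples: tuple[int, int] = (439, 807)
    n_bacteria: int = 122
    n_fungi: int = 131
    edge_density: float = 0.05
    fraction_negative_edges: float = 0.3
    group_specific_edge_fraction: float = 0.3
    dominance: float = 1.5
    latent_sd: float = 0.5
    sequencing_depth: int = 100_000
    zero_inflation_prob: float = 0.02
    differential_taxa: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("edge_density", "fraction_negative_edges", "group_specific_edge_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.sequencing_depth <= 0:
            raise ValueError("sequencing_depth must be positive")
        if self.latent_sd <= 0:
            raise ValueError("latent_sd must be positive")
        if self.zero_inflation_prob < 0 or self.zero_inflation_prob >= 1:
            raise ValueError("zero_inflation_prob must lie in [0, 1)")
        if min(self.n_samples) < 1 or self.n_bacteria + self.n_fungi < 2:
            raise ValueError("need at least one sample per group and two taxa")

    @property
    def n_taxa(self) -> int:
        return self.n_bacteria + self.n_fungi

    @property
    def taxon_ids(self) -> list[str]:
        return [f"B{i:03d}" for i in range(self.n_bacteria)] + [
            f"F{i:03d}" for i in range(self.n_fungi)
        ]

    @property
    def domains(self) -> dict[str, str]:
        return {
            t: ("bacteria" if t.startswith("B") else "fungi") for t in self.taxon_ids
        }

    def to_dict(self) -> dict:
        return {
            "n_samples": list(self.n_samples),
            "n_bacteria": self.n_bacteria,
            "n_fungi": self.n_fungi,
            "edge_density": self.edge_density,
            "fraction_negative_edges": self.fraction_negative_edges,
            "group_specific_edge_fraction": self.group_specific_edge_fraction,
            "dominance": self.dominance,
            "latent_sd": self.latent_sd,
            "sequencing_depth": self.sequencing_depth,
            "zero_inflation_prob": self.zero_inflation_prob,
            "differential_taxa": dict(self.differential_taxa),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "n_samples" in d:
            d["n_samples"] = tuple(d["n_samples"])
        return cls(**d)


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated two-group cohort plus its ground truth."""

    config: SimulationConfig
    counts: dict[str, AbundanceTable]
    relative: dict[str, AbundanceTable]
    group_labels: pd.Series
    planted: dict[str, PlantedNetwork]
    differential_taxa: dict[str, float]

    @property
    def groups(self) -> list[str]:
        return sorted(self.counts)

    def merged_relative(self) -> AbundanceTable:
        """All samples of both groups in one relative-mode table."""
        dfs = [self.relative[g].data for g in self.groups]
        data = pd.concat(dfs, axis=1)
        dom = self.relative[self.groups[0]].domain
        return AbundanceTable(data, dom, "relative")


def _edge_signs(n_edges: int, fraction_negative: float, rng: np.random.Generator) -> np.ndarray:
    signs = np.ones(n_edges, dtype=int)
    n_neg = int(round(fraction_negative * n_edges))
    neg_idx = rng.choice(n_edges, size=n_neg, replace=False) if n_neg else []
    signs[neg_idx] = -1
    return signs


def _precision_from_edges(
    p: int, edges: np.ndarray, signs: np.ndarray, magnitudes: np.ndarray
) -> np.ndarray:
    """Sparse symmetric precision matrix, positive-definite by diagonal dominance.

    An interaction sign s (the sign of the partial correlation) corresponds to
    a precision entry of sign -s.
    """
    omega = np.zeros((p, p))
    for (i, j), s, m in zip(edges, signs, magnitudes):
        omega[i, j] = omega[j, i] = -s * m
    row_abs = np.abs(omega).sum(axis=1)
    np.fill_diagonal(omega, row_abs + 0.5)
    return omega


def sample_planted_network(
    config: SimulationConfig, rng_seed: int
) -> dict[str, PlantedNetwork]:
    """Draw one planted network per group sharing a common backbone.

    A fraction ``group_specific_edge_fraction`` of each group's edges is
    private to that group; the remainder (backbone) is shared, with shared
    signs and magnitudes. Positive definiteness is enforced by setting each
    diagonal entry to the row's absolute off-diagonal sum plus 0.5.
    """
    rng = np.random.default_rng(rng_seed)
    p = config.n_taxa
    all_pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
    n_edges = int(round(config.edge_density * len(all_pairs)))
    if n_edges > len(all_pairs):
        raise ValueError("requested edge count exceeds p(p-1)/2")

    n_private = int(round(config.group_specific_edge_fraction * n_edges))
    n_shared = n_edges - n_private
    if n_shared + 2 * n_private > len(all_pairs):
        raise ValueError(
            "requested edges (shared backbone + two private sets) exceed p(p-1)/2"
        )
    order = rng.permutation(len(all_pairs))
    shared_idx = order[:n_shared]
    private_a = order[n_shared : n_shared + n_private]
    private_b = order[n_shared + n_private : n_shared + 2 * n_private]

    taxa = config.taxon_ids
    domains = config.domains
    networks: dict[str, PlantedNetwork] = {}
    shared_signs = _edge_signs(n_shared, config.fraction_negative_edges, rng)
    shared_mags = rng.uniform(0.2, 0.4, size=n_shared)
    for group, private in (("group1", private_a), ("group2", private_b)):
        priv_signs = _edge_signs(len(private), config.fraction_negative_edges, rng)
        priv_mags = rng.uniform(0.2, 0.4, size=len(private))
        idx = np.concatenate([shared_idx, private]).astype(int)
        edges = np.array([all_pairs[k] for k in idx], dtype=int).reshape(-1, 2)
        signs = np.concatenate([shared_signs, priv_signs]).astype(int)
        mags = np.concatenate([shared_mags, priv_mags])
        omega = _precision_from_edges(p, edges, signs, mags)
        edge_set = {
            (taxa[i], taxa[j]): int(s) for (i, j), s in zip(edges, signs)
        }
        networks[group] = PlantedNetwork(list(taxa), domains, omega, edge_set)
    return networks


def baseline_log_means(config: SimulationConfig) -> pd.Series:
    """The baseline latent log-mean per taxon that ``simulate_cohort`` will use.

    Deterministic in ``config.seed``; lets callers plant differential effects
    on taxa of known community rank (e.g. the dominant ones) before
    generating the cohort.
    """
    seeds = np.random.SeedSequence(config.seed).generate_state(2) % (2**31)
    rng = np.random.default_rng(int(seeds[1]))
    return pd.Series(
        rng.normal(0.0, config.dominance, size=config.n_taxa), index=config.taxon_ids
    )


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate the two-group cohort (counts + relative tables + ground truth).

    Reproducible: the same config (including seed) yields bit-identical
    output. Seeds for the network draw and the sampling stage are derived
    from ``config.seed`` via ``numpy.random.SeedSequence``.
    """
    seeds = np.random.SeedSequence(config.seed).generate_state(2) % (2**31)
    planted = sample_planted_network(config, int(seeds[0]))
    rng = np.random.default_rng(int(seeds[1]))

    p = config.n_taxa
    taxa = config.taxon_ids
    base_log_mean = rng.normal(0.0, config.dominance, size=p)

    counts_tables: dict[str, AbundanceTable] = {}
    rel_tables: dict[str, AbundanceTable] = {}
    labels = {}
    domain = pd.Series({t: config.domains[t] for t in taxa}, name="domain")
    for g_idx, group in enumerate(("group1", "group2")):
        n = config.n_samples[g_idx]
        mean = base_log_mean.copy()
        if g_idx == 1:
            for taxon, effect in config.differential_taxa.items():
                mean[taxa.index(taxon)] += effect
        # unit-variance latent correlation structure scaled to the
        # within-group log-abundance sd
        cov = planted[group].covariance * config.latent_sd**2
        z = rng.multivariate_normal(mean, cov, size=n, method="cholesky")
        basis = np.exp(z)  # samples x taxa
        comp = basis / basis.sum(axis=1, keepdims=True)
        counts = np.empty((n, p), dtype=np.int64)
        for s in range(n):
            counts[s] = rng.multinomial(config.sequencing_depth, comp[s])
        if config.zero_inflation_prob > 0:
            keep = rng.random(counts.shape) >= config.zero_inflation_prob
            counts = counts * keep
        sample_ids = [f"{group}_S{s:04d}" for s in range(n)]
        df = pd.DataFrame(counts.T, index=taxa, columns=sample_ids)
        # guard: a fully zeroed sample column would break closure downstream
        empty = df.sum(axis=0) == 0
        if empty.any():
            for col in df.columns[empty]:
                top = int(np.argmax(comp[sample_ids.index(col)]))
                df.loc[taxa[top], col] = 1
        counts_tables[group] = AbundanceTable(df, domain, "counts")
        rel_tables[group] = to_relative(counts_tables[group])
        for sid in sample_ids:
            labels[sid] = group

    return SyntheticCohort(
        config=config,
        counts=counts_tables,
        relative=rel_tables,
        group_labels=pd.Series(labels, name="group"),
        planted=planted,
        differential_taxa=dict(config.differential_taxa),
    )


def export_ground_truth(cohort: SyntheticCohort, path: str | Path) -> dict[str, Path]:
    """Write planted edge sets, differential taxa, and a config echo.

    Returns the mapping of artifact name to written path. Edge TSV columns:
    taxon_a, taxon_b, sign, group.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    for group in cohort.groups:
        for (a, b), s in sorted(cohort.planted[group].edge_set.items()):
            rows.append({"taxon_a": a, "taxon_b": b, "sign": s, "group": group})
    edges = pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "sign", "group"])
    edge_path = path / "planted_edges.tsv"
    edges.to_csv(edge_path, sep="\t", index=False)

    diff_path = path / "differential_taxa.tsv"
    diff = pd.DataFrame(
        sorted(cohort.differential_taxa.items()), columns=["taxon_id", "log_fold_effect"]
    )
    diff.to_csv(diff_path, sep="\t", index=False)

    cfg_path = path / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(cohort.config.to_dict(), fh, sort_keys=True)
    return {"edges": edge_path, "differential_taxa": diff_path, "config": cfg_path}


def read_ground_truth_edges(path: str | Path) -> dict[str, dict[tuple[str, str], int]]:
    """Round-trip reader for the planted-edge TSV."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, dict[tuple[str, str], int]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["group"], {})[(row["taxon_a"], row["taxon_b"])] = int(row["sign"])
    return out
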