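"""Ensemble co-occurrence network inference for compositional profiles.

Four association methods are combined: COAT (composition-adjusted
thresholding of the CLR covariance, carrying signs), a sparse Gaussian
graphical model (graphical lasso with StARS penalty selection, carrying
signs via partial correlations), mutual information, and Bray-Curtis
similarity (both magnitude-only). Per-edge significance follows the ReBoot
scheme: the observed statistic is a bootstrap mean over resampled,
re-closed samples, and the null re-computes the statistic after shuffling
one endpoint taxon across samples and re-closing every sample, so the null
retains the compositional artifact. Per-method p-values are merged with the
weighted Simes test; the edge sign comes from COAT and the sparse graphical
model, with conflicting signs excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.covariance import graphical_lasso

from .profiles import AbundanceTable

__all__ = [
    "MethodScoreMatrix",
    "SignedNetwork",
    "EnsembleConfig",
    "EnsembleResult",
    "clr_transform",
    "coat_correlation",
    "sparse_graph_partial_correlation",
    "mutual_information_matrix",
    "bray_curtis_association",
    "reboot_edge_pvalues",
    "weighted_simes",
    "aggregate_ensemble",
    "build_network",
    "split_subnetworks",
    "infer_network",
]

METHODS = ("coat", "sparse_graph", "mutual_information", "bray_curtis")


# --------------------------------------------------------------------------
# containers


@dataclass
class MethodScoreMatrix:
    """Taxon-pair association scores for one ensemble member.

    raw_scores is symmetric with NaN diagonal; signs uses {-1, +1} where the
    method defines a direction and 0 where it does not; p_values (when
    filled by ReBoot) lie in (0, 1].
    """

    method: str
    taxon_ids: list[str]
    raw_scores: np.ndarray
    signs: np.ndarray | None = None
    p_values: np.ndarray | None = None

    @property
    def normalized_abs_scores(self) -> np.ndarray:
        """Min-max normalization of |raw_scores| over all off-diagonal pairs."""
        return _minmax_offdiag(np.abs(self.raw_scores))


@dataclass
class SignedNetwork:
    """Undirected signed interaction network over taxa.

    Wraps a networkx Graph whose nodes carry a ``domain`` attribute and whose
    edges carry ``sign`` (+1/-1), ``score`` and ``p``.
    """

    graph: nx.Graph

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_count_by_sign(self) -> dict[int, int]:
        counts = {1: 0, -1: 0}
        for _, _, d in self.graph.edges(data=True):
            counts[d["sign"]] += 1
        return counts

    def to_edgelist(self) -> pd.DataFrame:
        rows = [
            {
                "taxon_a": a,
                "taxon_b": b,
                "sign": d["sign"],
                "score": d["score"],
                "p": d["p"],
            }
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "sign", "score", "p"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_edgelist().to_csv(path, sep="\t", index=False)

    def to_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, path)

    @classmethod
    def from_edges(
        cls,
        edges: dict[tuple[str, str], int] | Sequence[tuple[str, str, int]],
        domains: dict[str, str],
        nodes: Sequence[str] | None = None,
    ) -> "SignedNetwork":
        """Build a network from (a, b) -> sign pairs (score 1, p 0 placeholders)."""
        g = nx.Graph()
        for node in nodes if nodes is not None else domains:
            g.add_node(node, domain=domains[node])
        items = edges.items() if isinstance(edges, dict) else [((a, b), s) for a, b, s in edges]
        for (a, b), s in items:
            g.add_edge(a, b, sign=int(s), score=1.0, p=0.0)
            for node in (a, b):
                g.nodes[node]["domain"] = domains[node]
        return cls(g)


@dataclass(frozen=True)
class EnsembleConfig:
    coat_soft: float = 0.2
    sparse_nlambda: int = 100
    mi_bins: int | None = None  # default floor(sqrt(n)) capped at 10
    n_permutations: int = 100
    n_bootstraps: int = 100
    edge_p_threshold: float = 1e-3
    pseudocount: float | None = None  # default: half the smallest nonzero abundance
    method_weights: dict[str, float] | None = None  # default equal
    sign_conflict: str = "exclude"  # or "magnitude"
    stars_subsamples: int = 20
    stars_beta: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.edge_p_threshold < 1:
            raise ValueError("edge_p_threshold must be in (0, 1)")
        if self.n_permutations < 1 or self.n_bootstraps < 1:
            raise ValueError("resampling counts must be >= 1")
        if self.sign_conflict not in ("exclude", "magnitude"):
            raise ValueError("sign_conflict must be 'exclude' or 'magnitude'")

    def weights_vector(self) -> np.ndarray:
        if self.method_weights is None:
            return np.full(len(METHODS), 1.0 / len(METHODS))
        w = np.array([self.method_weights[m] for m in METHODS], dtype=float)
        if (w <= 0).any():
            raise ValueError("method weights must be positive")
        return w / w.sum()


@dataclass
class EnsembleResult:
    taxon_ids: list[str]
    per_method: dict[str, MethodScoreMatrix]
    aggregate_score: np.ndarray
    signs: np.ndarray
    merged_p: np.ndarray
    conflicts: np.ndarray
    network: SignedNetwork


# --------------------------------------------------------------------------
# helpers


def _minmax_offdiag(values: np.ndarray) -> np.ndarray:
    """Min-max scale over off-diagonal entries; NaN entries map to 0."""
    p = values.shape[0]
    off = ~np.eye(p, dtype=bool)
    vals = values[off]
    finite = vals[np.isfinite(vals)]
    out = np.zeros_like(values, dtype=float)
    if finite.size == 0:
        return out
    lo, hi = finite.min(), finite.max()
    if hi > lo:
        scaled = (values - lo) / (hi - lo)
    else:
        scaled = np.ones_like(values, dtype=float)
    scaled = np.where(np.isfinite(values), scaled, 0.0)
    out[off] = np.clip(scaled[off], 0.0, 1.0)
    return out


def _default_pseudocount(rel: np.ndarray) -> float:
    nz = rel[rel > 0]
    if nz.size == 0:
        raise ValueError("table is all zeros")
    return float(nz.min() / 2.0)


def _clr_matrix(rel: np.ndarray, pseudocount: float) -> np.ndarray:
    """CLR of a taxa-x-samples relative matrix after pseudocount addition.

    The CLR is invariant to per-sample re-closure, so the renormalization
    after pseudocount addition is implicit.
    """
    if pseudocount <= 0 and (rel <= 0).any():
        raise ValueError("zeros present: a positive pseudocount is required")
    logx = np.log(rel + pseudocount)
    return logx - logx.mean(axis=0, keepdims=True)


def clr_transform(table: AbundanceTable, pseudocount: float | None = None) -> np.ndarray:
    """Centered log-ratio transform of a relative-mode table (taxa x samples).

    Columns of the result have zero mean over taxa. When ``pseudocount`` is
    None, half the smallest nonzero relative abundance is used (0 if the
    table has no zeros).
    """
    if table.mode != "relative":
        raise ValueError("clr_transform requires a relative-mode table")
    rel = table.values
    if pseudocount is None:
        pseudocount = 0.0 if (rel > 0).all() else _default_pseudocount(rel)
    return _clr_matrix(rel, pseudocount)


# --------------------------------------------------------------------------
# ensemble members


def coat_correlation(clr_matrix: np.ndarray, soft: float = 0.2) -> MethodScoreMatrix:
    """Composition-adjusted thresholding on the CLR covariance.

    The CLR sample covariance estimates the basis covariance up to a rank-2
    nuisance; COAT shrinks each off-diagonal entry by the adaptive threshold
    lambda_ij = soft * sqrt(theta_ij * ln(p) / n), with theta_ij the
    empirical variance of the centered cross-products, then reports the
    result on the correlation scale. Signs are the signs of the thresholded
    correlations (0 where shrunk to zero).
    """
    x = np.asarray(clr_matrix, dtype=float)
    p, n = x.shape
    if p < 2 or n < 4:
        raise ValueError("need at least 2 taxa and 4 samples")
    xc = x - x.mean(axis=1, keepdims=True)
    sigma = (xc @ xc.T) / n
    theta = (xc**2) @ (xc**2).T / n - sigma**2
    theta = np.maximum(theta, 0.0)
    lam = soft * np.sqrt(theta * np.log(p) / n)
    shrunk = np.sign(sigma) * np.maximum(np.abs(sigma) - lam, 0.0)
    var = np.diag(sigma).copy()
    const = var <= 1e-15
    if const.any():
        warnings.warn("constant taxon row(s); their correlations are undefined", stacklevel=2)
        var[const] = np.nan
    denom = np.sqrt(np.outer(var, var))
    corr = shrunk / denom
    np.fill_diagonal(corr, np.nan)
    corr = np.clip(corr, -1.0, 1.0)
    signs = np.sign(np.nan_to_num(corr)).astype(int)
    return MethodScoreMatrix("coat", [], corr, signs)


def _lambda_path(corr: np.ndarray, nlambda: int) -> np.ndarray:
    lam_max = float(np.max(np.abs(corr - np.diag(np.diag(corr))))) or 1.0
    return np.logspace(np.log10(lam_max), np.log10(lam_max * 0.01), nlambda)


def _glasso_precision(emp_corr: np.ndarray, alpha: float) -> np.ndarray | None:
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, prec = graphical_lasso(emp_corr, alpha=alpha, max_iter=100, tol=1e-3)
        return prec
    except (FloatingPointError, np.linalg.LinAlgError, ValueError):
        return None


def stars_select_penalty(
    clr_matrix: np.ndarray,
    nlambda: int = 100,
    n_subsamples: int = 20,
    beta: float = 0.05,
    seed: int = 0,
) -> float:
    """StARS: pick the least penalty whose edge-set instability stays <= beta.

    Subsamples of size floor(0.8 n) are refit along the penalty path; edge
    instability 2*xi*(1-xi) (xi = selection frequency) is averaged over
    pairs, monotonized from the sparse end, and the smallest penalty with
    monotonized instability <= beta is returned.
    """
    x = np.asarray(clr_matrix, dtype=float)
    p, n = x.shape
    if n < 10:
        raise ValueError("StARS needs at least 10 samples")
    rng = np.random.default_rng(seed)
    lambdas = _lambda_path(np.corrcoef(x), nlambda)  # descending
    m = int(np.floor(0.8 * n))
    sub_corrs = [
        np.corrcoef(x[:, rng.choice(n, size=m, replace=False)])
        for _ in range(n_subsamples)
    ]
    off = ~np.eye(p, dtype=bool)
    selected = None
    running_max = 0.0
    any_ok = False
    # walk the path from sparse to dense; the monotonized instability is a
    # running maximum, so once it exceeds beta no denser penalty can win and
    # the remainder of the path can be skipped
    for lam in lambdas:
        freq = np.zeros((p, p))
        n_ok = 0
        for sub_corr in sub_corrs:
            prec = _glasso_precision(sub_corr, lam)
            if prec is None:
                continue
            freq += (np.abs(prec) > 1e-8) & ~np.eye(p, dtype=bool)
            n_ok += 1
        if n_ok == 0:
            warnings.warn(f"graphical lasso failed at penalty {lam:g}; skipped",
                          stacklevel=2)
            continue
        any_ok = True
        xi = freq[off] / n_ok
        running_max = max(running_max, float(np.mean(2 * xi * (1 - xi))))
        if running_max <= beta:
            selected = lam
        else:
            break
    if not any_ok:
        raise RuntimeError("graphical lasso failed at every penalty")
    return float(selected if selected is not None else lambdas[0])


def _partial_correlations(prec: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(prec))
    pc = -prec / np.outer(d, d)
    np.fill_diagonal(pc, np.nan)
    return pc


def sparse_graph_partial_correlation(
    clr_matrix: np.ndarray,
    nlambda: int = 100,
    seed: int = 0,
    n_subsamples: int = 20,
    beta: float = 0.05,
    alpha: float | None = None,
) -> MethodScoreMatrix:
    """Sparse Gaussian graphical model scores: partial correlations at the
    StARS-selected graphical-lasso penalty (or at a caller-fixed ``alpha``).

    Pairs absent from the selected graph score exactly 0; signs follow the
    partial correlations.
    """
    x = np.asarray(clr_matrix, dtype=float)
    if alpha is None:
        alpha = stars_select_penalty(x, nlambda, n_subsamples, beta, seed)
    emp_corr = np.corrcoef(x)
    prec = _glasso_precision(emp_corr, alpha)
    if prec is None:
        warnings.warn("graphical lasso failed at the selected penalty", stacklevel=2)
        p = x.shape[0]
        scores = np.zeros((p, p)) * np.nan
        return MethodScoreMatrix("sparse_graph", [], scores, np.zeros((p, p), dtype=int))
    pc = _partial_correlations(prec)
    pc = np.where(np.abs(np.nan_to_num(pc)) > 1e-8, pc, 0.0)
    np.fill_diagonal(pc, np.nan)
    signs = np.sign(np.nan_to_num(pc)).astype(int)
    m = MethodScoreMatrix("sparse_graph", [], pc, signs)
    m.selected_alpha = alpha  # type: ignore[attr-defined]
    return m


def _equal_frequency_labels(row: np.ndarray, bins: int) -> np.ndarray:
    n = row.size
    order = np.argsort(row, kind="mergesort")
    labels = np.empty(n, dtype=np.int64)
    labels[order] = (np.arange(n) * bins) // n
    return labels


def _mi_from_labels(li: np.ndarray, lj: np.ndarray, bins: int) -> float:
    joint = np.bincount(li * bins + lj, minlength=bins * bins).astype(float)
    joint = joint.reshape(bins, bins) / li.size
    pi = joint.sum(axis=1, keepdims=True)
    pj = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log(joint / (pi * pj))
    return float(np.nansum(terms))


def mutual_information_matrix(
    table: AbundanceTable | np.ndarray, bins: int | None = None
) -> MethodScoreMatrix:
    """Plug-in mutual information (nats) between equal-frequency-discretized
    taxon abundance profiles. Magnitude-only: signs are all 0.
    """
    rel = table.values if isinstance(table, AbundanceTable) else np.asarray(table, float)
    p, n = rel.shape
    if bins is None:
        bins = min(int(np.sqrt(n)), 10)
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if n < bins:
        raise ValueError("need at least as many samples as bins")
    labels = np.stack([_equal_frequency_labels(rel[i], bins) for i in range(p)])
    mi = np.full((p, p), np.nan)
    for i in range(p):
        for j in range(i + 1, p):
            mi[i, j] = mi[j, i] = _mi_from_labels(labels[i], labels[j], bins)
    return MethodScoreMatrix("mutual_information", [], mi, np.zeros((p, p), dtype=int))


def bray_curtis_association(table: AbundanceTable | np.ndarray) -> MethodScoreMatrix:
    """1 - Bray-Curtis dissimilarity between taxon abundance vectors.

    Similarity orientation, so larger = stronger for every ensemble member.
    Magnitude-only: signs are all 0; a pair of all-zero taxa is undefined (NaN).
    """
    rel = table.values if isinstance(table, AbundanceTable) else np.asarray(table, float)
    p = rel.shape[0]
    totals = rel.sum(axis=1)
    denom = totals[:, None] + totals[None, :]
    num = np.zeros((p, p))
    for i in range(p):
        num[i] = np.abs(rel - rel[i]).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = 1.0 - num / denom
    scores[denom == 0] = np.nan
    np.fill_diagonal(scores, np.nan)
    return MethodScoreMatrix("bray_curtis", [], scores, np.zeros((p, p), dtype=int))


# --------------------------------------------------------------------------
# method adapters for resampling


class _MethodAdapter:
    """Uniform interface: score a taxa-x-samples relative matrix.

    ``score_matrix`` is the method's estimate (may involve hard
    thresholding); ``test_statistic`` is the smooth association functional
    the permutation null compares, identical by default. Thresholded
    estimators override ``test_statistic``: exact zeros would otherwise tie
    with every null draw and pile p-values at 1.
    """

    name: str
    prepared: bool = False

    def prepare(self, rel: np.ndarray) -> None:  # called once on observed data
        self.prepared = True

    def score_matrix(self, rel: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def test_statistic(self, rel: np.ndarray) -> np.ndarray:
        return self.score_matrix(rel)

    def taxon_test_statistic(self, rel: np.ndarray, i: int) -> np.ndarray:
        return self.test_statistic(rel)[i]


class CoatAdapter(_MethodAdapter):
    name = "coat"

    def __init__(self, soft: float, pseudocount: float):
        self.soft = soft
        self.pseudocount = pseudocount

    def score_matrix(self, rel: np.ndarray) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clr = _clr_matrix(rel, self.pseudocount)
            return coat_correlation(clr, self.soft).raw_scores

    def test_statistic(self, rel: np.ndarray) -> np.ndarray:
        # unthresholded CLR correlation: the smooth statistic behind COAT
        clr = _clr_matrix(rel, self.pseudocount)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(clr)
        np.fill_diagonal(corr, np.nan)
        return corr

    def taxon_test_statistic(self, rel: np.ndarray, i: int) -> np.ndarray:
        clr = _clr_matrix(rel, self.pseudocount)
        xc = clr - clr.mean(axis=1, keepdims=True)
        norms = np.sqrt((xc**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            row = (xc @ xc[i]) / (norms * norms[i])
        row[i] = np.nan
        return row


class SparseGraphAdapter(_MethodAdapter):
    name = "sparse_graph"

    def __init__(self, nlambda: int, seed: int, n_subsamples: int = 20, beta: float = 0.05,
                 pseudocount: float = 0.0):
        self.nlambda = nlambda
        self.seed = seed
        self.n_subsamples = n_subsamples
        self.beta = beta
        self.pseudocount = pseudocount
        self.alpha: float | None = None

    def prepare(self, rel: np.ndarray) -> None:
        # penalty selected once on the observed data and held fixed across
        # resamples: StARS is itself subsampling-based, so re-running it
        # inside every bootstrap/permutation replicate would be circular
        clr = _clr_matrix(rel, self.pseudocount)
        self.alpha = stars_select_penalty(
            clr, self.nlambda, self.n_subsamples, self.beta, self.seed
        )
        self.prepared = True

    def score_matrix(self, rel: np.ndarray) -> np.ndarray:
        if self.alpha is None:
            self.prepare(rel)
        clr = _clr_matrix(rel, self.pseudocount)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = sparse_graph_partial_correlation(clr, alpha=self.alpha, seed=self.seed)
        return m.raw_scores

    def test_statistic(self, rel: np.ndarray) -> np.ndarray:
        # smooth counterpart of the sparse estimate: empirical partial
        # correlations from the (ridge-stabilized) inverse CLR correlation
        clr = _clr_matrix(rel, self.pseudocount)
        corr = np.corrcoef(clr)
        p = corr.shape[0]
        prec = np.linalg.pinv(corr + 1e-6 * np.eye(p))
        return _partial_correlations(prec)


class MutualInformationAdapter(_MethodAdapter):
    name = "mutual_information"

    def __init__(self, bins: int):
        self.bins = bins

    def score_matrix(self, rel: np.ndarray) -> np.ndarray:
        return mutual_information_matrix(rel, self.bins).raw_scores

    def taxon_test_statistic(self, rel: np.ndarray, i: int) -> np.ndarray:
        p = rel.shape[0]
        labels = np.stack(
            [_equal_frequency_labels(rel[j], self.bins) for j in range(p)]
        )
        out = np.full(p, np.nan)
        for j in range(p):
            if j != i:
                out[j] = _mi_from_labels(labels[i], labels[j], self.bins)
        return out


class BrayCurtisAdapter(_MethodAdapter):
    name = "bray_curtis"

    def score_matrix(self, rel: np.ndarray) -> np.ndarray:
        return bray_curtis_association(rel).raw_scores

    def taxon_test_statistic(self, rel: np.ndarray, i: int) -> np.ndarray:
        totals = rel.sum(axis=1)
        denom = totals + totals[i]
        num = np.abs(rel - rel[i]).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = 1.0 - num / denom
        out[denom == 0] = np.nan
        out[i] = np.nan
        return out


def _make_adapters(rel: np.ndarray, config: EnsembleConfig) -> dict[str, _MethodAdapter]:
    pc = config.pseudocount
    if pc is None:
        pc = 0.0 if (rel > 0).all() else _default_pseudocount(rel)
    n = rel.shape[1]
    bins = config.mi_bins if config.mi_bins is not None else min(int(np.sqrt(n)), 10)
    return {
        "coat": CoatAdapter(config.coat_soft, pc),
        "sparse_graph": SparseGraphAdapter(
            config.sparse_nlambda, config.seed, config.stars_subsamples,
            config.stars_beta, pc,
        ),
        "mutual_information": MutualInformationAdapter(bins),
        "bray_curtis": BrayCurtisAdapter(),
    }


# --------------------------------------------------------------------------
# ReBoot significance


def _renormalize_columns(rel: np.ndarray) -> np.ndarray:
    sums = rel.sum(axis=0, keepdims=True)
    sums = np.where(sums > 0, sums, 1.0)
    return rel / sums


def reboot_edge_pvalues(
    table: AbundanceTable | np.ndarray,
    adapter: _MethodAdapter,
    config: EnsembleConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Bootstrap + renormalized-permutation significance for one method.

    Two resampling layers. (1) Stability: the bootstrap mean of the statistic
    over ``n_bootstraps`` resamples of the sample columns (with replacement,
    re-closed) is returned as the observed edge score. (2) Significance: the
    null for pair (i, j), i < j, shuffles taxon i's abundances across
    samples, re-closes every sample column and recomputes the statistic,
    ``n_permutations`` times; p = (1 + #{|null| >= |t_obs|}) /
    (n_permutations + 1), where t_obs is the statistic on the original
    (unresampled) table — the same functional each null replicate evaluates,
    which keeps the permutation p-values exactly valid (a bootstrap-mean
    observed would be biased for plug-in statistics such as MI, where
    duplicated samples inflate the estimate).

    Returns (observed bootstrap-mean matrix, p-value matrix).
    """
    rel = table.values if isinstance(table, AbundanceTable) else np.asarray(table, float)
    p, n = rel.shape
    if config.n_permutations < 19:
        warnings.warn(
            "fewer than 19 permutations: the p-value floor exceeds 0.05", stacklevel=2
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if isinstance(adapter, str):
        adapter = _make_adapters(rel, config)[adapter]
    if not adapter.prepared:
        adapter.prepare(rel)

    boot_sum = np.zeros((p, p))
    boot_n = np.zeros((p, p))
    for _ in range(config.n_bootstraps):
        cols = rng.integers(0, n, size=n)
        scores = adapter.score_matrix(_renormalize_columns(rel[:, cols]))
        finite = np.isfinite(scores)
        boot_sum[finite] += scores[finite]
        boot_n += finite
    with np.errstate(invalid="ignore", divide="ignore"):
        observed = boot_sum / boot_n
    observed[boot_n == 0] = np.nan
    np.fill_diagonal(observed, np.nan)

    t_obs = adapter.test_statistic(rel)
    exceed = np.zeros((p, p))
    valid = np.zeros((p, p))
    for i in range(p - 1):
        for _ in range(config.n_permutations):
            shuffled = rel.copy()
            shuffled[i] = rel[i, rng.permutation(n)]
            null_row = adapter.taxon_test_statistic(_renormalize_columns(shuffled), i)
            for j in range(i + 1, p):
                if np.isfinite(null_row[j]) and np.isfinite(t_obs[i, j]):
                    valid[i, j] += 1
                    if abs(null_row[j]) >= abs(t_obs[i, j]):
                        exceed[i, j] += 1
    pvals = np.ones((p, p))
    iu = np.triu_indices(p, k=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        upper = (1.0 + exceed[iu]) / (1.0 + np.maximum(valid[iu], 1))
    # pairs with no valid permutation (undefined statistic) keep p = 1
    upper = np.where(valid[iu] > 0, upper, 1.0)
    pvals[iu] = upper
    pvals[(iu[1], iu[0])] = upper
    np.fill_diagonal(pvals, np.nan)
    return observed, pvals


# --------------------------------------------------------------------------
# merging


def weighted_simes(p_values: Sequence[float], weights: Sequence[float] | None = None) -> float:
    """Weighted Simes combination: min over i of (sum w) * p_(i) / cumw_(i).

    With equal weights this reduces to the classic Simes test. The result is
    capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if weights is None:
        w = np.ones_like(p)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != p.shape or np.any(w <= 0):
            raise ValueError("weights must be positive and match p-values in length")
    order = np.argsort(p, kind="mergesort")
    cumw = np.cumsum(w[order])
    candidates = w.sum() * p[order] / cumw
    return float(min(candidates.min(), 1.0))


def aggregate_ensemble(
    method_matrices: dict[str, MethodScoreMatrix],
    weights: np.ndarray | None = None,
    sign_conflict: str = "exclude",
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Combine the four method matrices into aggregate scores, signs and
    merged p-values.

    aggregate = weighted mean of per-method min-max-normalized |scores|.
    Sign: COAT and the sparse graphical model vote; agreement or a single
    nonzero vote decides, a conflict excludes the edge (merged_p forced to 1)
    under the default policy, or the larger normalized magnitude wins under
    ``sign_conflict="magnitude"``. merged_p = weighted Simes of the
    per-method ReBoot p-values.

    Returns (aggregate_score, signs, merged_p, conflict_mask).
    """
    missing = [m for m in METHODS if m not in method_matrices]
    if missing:
        raise ValueError(f"missing ensemble methods: {missing}")
    mats = [method_matrices[m] for m in METHODS]
    p = mats[0].raw_scores.shape[0]
    if weights is None:
        weights = np.full(len(METHODS), 1.0 / len(METHODS))
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()

    normalized = np.stack([m.normalized_abs_scores for m in mats])
    aggregate = np.tensordot(weights, normalized, axes=1)
    np.fill_diagonal(aggregate, 0.0)

    coat_sign = method_matrices["coat"].signs
    huge_sign = method_matrices["sparse_graph"].signs
    signs = np.zeros((p, p), dtype=int)
    agree_or_single = (coat_sign * huge_sign >= 0) & ((coat_sign != 0) | (huge_sign != 0))
    signs[agree_or_single] = np.sign(coat_sign + huge_sign)[agree_or_single]
    conflict = coat_sign * huge_sign < 0
    if sign_conflict == "magnitude":
        coat_mag = method_matrices["coat"].normalized_abs_scores
        huge_mag = method_matrices["sparse_graph"].normalized_abs_scores
        winner = np.where(coat_mag >= huge_mag, coat_sign, huge_sign)
        signs[conflict] = winner[conflict]
        conflict = np.zeros_like(conflict)

    merged = np.ones((p, p))
    pstack = np.stack(
        [np.nan_to_num(m.p_values, nan=1.0) if m.p_values is not None else np.ones((p, p))
         for m in mats]
    )
    for i in range(p):
        for j in range(i + 1, p):
            merged[i, j] = merged[j, i] = weighted_simes(
                np.clip(pstack[:, i, j], 1e-300, 1.0), weights
            )
    merged[conflict] = 1.0
    np.fill_diagonal(merged, 1.0)
    return aggregate, signs, merged, conflict


def build_network(
    aggregate: np.ndarray,
    signs: np.ndarray,
    merged_p: np.ndarray,
    threshold: float,
    node_domains: dict[str, str],
    taxon_ids: Sequence[str],
) -> SignedNetwork:
    """Retain sign-defined pairs with merged_p < threshold; isolated nodes
    stay in the node set."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    g = nx.Graph()
    for t in taxon_ids:
        g.add_node(t, domain=node_domains[t])
    p = len(taxon_ids)
    for i in range(p):
        for j in range(i + 1, p):
            if signs[i, j] != 0 and merged_p[i, j] < threshold:
                g.add_edge(
                    taxon_ids[i],
                    taxon_ids[j],
                    sign=int(signs[i, j]),
                    score=float(aggregate[i, j]),
                    p=float(merged_p[i, j]),
                )
    return SignedNetwork(g)


def split_subnetworks(net: SignedNetwork) -> dict[str, SignedNetwork]:
    """Partition edges into bacteria-bacteria, fungi-fungi and cross-kingdom."""
    parts = {"bacteria": nx.Graph(), "fungi": nx.Graph(), "cross": nx.Graph()}
    for node, data in net.graph.nodes(data=True):
        if "domain" not in data:
            raise ValueError(f"node {node!r} lacks a domain label")
        if data["domain"] in parts:
            parts[data["domain"]].add_node(node, **data)
        parts["cross"].add_node(node, **data)
    for a, b, data in net.graph.edges(data=True):
        da, db = net.graph.nodes[a]["domain"], net.graph.nodes[b]["domain"]
        key = da if da == db else "cross"
        parts[key].add_edge(a, b, **data)
    return {k: SignedNetwork(g) for k, g in parts.items()}


# --------------------------------------------------------------------------
# orchestration


def infer_network(table: AbundanceTable, config: EnsembleConfig | None = None) -> EnsembleResult:
    """Run the full ensemble on one group's relative-mode table.

    Computes the four method score matrices on the observed data, ReBoot
    p-values per method, the aggregate/sign/merged-p combination, and the
    thresholded signed network.
    """
    config = config or EnsembleConfig()
    if table.mode != "relative":
        raise ValueError("infer_network requires a relative-mode table")
    rel = table.values
    taxa = table.taxon_ids
    adapters = _make_adapters(rel, config)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).generate_state(1)[0] % (2**31))

    per_method: dict[str, MethodScoreMatrix] = {}
    for name in METHODS:
        adapter = adapters[name]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            adapter.prepare(rel)
            raw = adapter.score_matrix(rel)
        observed, pvals = reboot_edge_pvalues(rel, adapter, config, rng)
        if name == "coat":
            signs = np.sign(np.nan_to_num(raw)).astype(int)
        elif name == "sparse_graph":
            signs = np.sign(np.nan_to_num(raw)).astype(int)
        else:
            signs = np.zeros_like(raw, dtype=int)
        m = MethodScoreMatrix(name, taxa, raw, signs, pvals)
        m.bootstrap_mean = observed  # type: ignore[attr-defined]
        per_method[name] = m

    aggregate, signs, merged, conflicts = aggregate_ensemble(
        per_method, config.weights_vector(), config.sign_conflict
    )
    network = build_network(
        aggregate, signs, merged, config.edge_p_threshold,
        dict(table.domain), taxa,
    )
    return EnsembleResult(taxa, per_method, aggregate, signs, merged, conflicts, network)
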