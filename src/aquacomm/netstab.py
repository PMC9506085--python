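"""Co-occurrence network construction and stability indices.

Molecular ecological networks (MENs) are built from pairwise correlations
between taxa across samples, keeping edges whose |r| exceeds a threshold.
The threshold can be chosen by the random-matrix-theory criterion: scan
candidate cutoffs and keep the smallest one at which the nearest-neighbor
spacing distribution (NNSD) of the thresholded matrix's unfolded eigenvalue
spectrum follows the Poisson law (uncorrelated, modular structure) rather
than the Gaussian-orthogonal-ensemble law of dense random noise.

Stability is summarized three ways:

* **robustness** — mean fraction of taxa still connected after randomly
  removing a fraction of nodes, with abundance-weighted interaction
  strengths; a node goes extinct when all of its weighted links are lost;
* **vulnerability** — the largest relative drop in global efficiency (mean
  inverse shortest-path length) caused by deleting a single node;
* **cohesion** — per-sample sums of abundance-weighted, null-corrected
  taxon connectedness, split into positive and negative components; the
  negative:positive magnitude ratio tracks the stabilizing contribution of
  antagonistic covariation.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from aquacomm._exceptions import NoTransitionError
from aquacomm.core_io import relative_abundance


def correlation_matrix(table: pd.DataFrame, method: str = "spearman") -> pd.DataFrame:
    """Taxon x taxon correlation across samples."""
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    data = table.T.astype(float)  # samples x taxa
    corr = data.corr(method=method)
    return corr.fillna(0.0)


def correlation_network(
    table: pd.DataFrame,
    method: str = "spearman",
    prevalence_min: float = 0.5,
    threshold: float | None = None,
    rmt: bool = True,
    seed: int | None = None,
) -> nx.Graph:
    """Thresholded co-occurrence graph over prevalent taxa.

    Taxa present in fewer than ``prevalence_min`` of the samples are
    dropped first.  When ``rmt`` is true and no fixed threshold is given,
    the cutoff comes from :func:`rmt_threshold`.  Isolated nodes are
    removed.  Node attribute ``abundance`` holds the taxon's mean relative
    abundance; edges carry ``weight`` (the correlation) and ``sign``.
    """
    if table.shape[1] < 8:
        raise ValueError("need at least 8 samples for a correlation network")
    prevalence = (table > 0).mean(axis=1)
    sub = table.loc[prevalence >= prevalence_min]
    if sub.shape[0] < 2:
        raise ValueError("fewer than 2 taxa pass the prevalence filter")
    corr = correlation_matrix(sub, method=method)
    if threshold is None:
        threshold = rmt_threshold(corr) if rmt else 0.8
    rel = relative_abundance(table).loc[sub.index].mean(axis=1)

    g = nx.Graph(threshold=float(threshold), method=method)
    arr = corr.to_numpy()
    taxa = list(corr.index)
    n = len(taxa)
    for i in range(n):
        for j in range(i + 1, n):
            r = arr[i, j]
            if abs(r) >= threshold:
                g.add_edge(
                    taxa[i], taxa[j], weight=float(r), sign=1 if r > 0 else -1
                )
    for node in g.nodes:
        g.nodes[node]["abundance"] = float(rel[node])
    if g.number_of_nodes() < 2:
        raise ValueError("no edges at the chosen threshold")
    return g


def _nnsd_poisson_pvalue(eigenvalues: np.ndarray, n_bins: int = 30) -> float:
    """Chi-square goodness of fit of the unfolded NNSD to the Poisson law.

    The cumulative eigenvalue count is smoothed with a cubic polynomial
    (spectral unfolding); spacings of the unfolded levels are binned and
    compared with the exponential (Poisson) expectation.
    """
    lam = np.unique(np.round(np.sort(eigenvalues), 8))
    m = lam.size
    if m < 2 * n_bins:
        return -1.0  # spectrum too degenerate to test
    counts = np.arange(1, m + 1, dtype=float)
    coef = np.polyfit(lam, counts, 3)
    unfolded = np.polyval(coef, lam)
    spacings = np.diff(unfolded)
    spacings = spacings[spacings > 0]
    if spacings.size < n_bins:
        return -1.0
    spacings = spacings / spacings.mean()
    upper = np.quantile(spacings, 0.99)
    edges = np.linspace(0.0, max(upper, 1e-6), n_bins + 1)
    obs, _ = np.histogram(spacings, bins=edges)
    total = obs.sum()
    expected = total * (np.exp(-edges[:-1]) - np.exp(-edges[1:]))
    expected = expected * total / expected.sum()
    keep = expected > 1e-9
    chi2 = float(((obs[keep] - expected[keep]) ** 2 / expected[keep]).sum())
    dof = int(keep.sum()) - 1 - 1  # normalization + fitted mean spacing
    return float(stats.chi2.sf(chi2, max(dof, 1)))


def rmt_threshold(
    corr: pd.DataFrame | np.ndarray,
    scan: np.ndarray | None = None,
    alpha: float = 0.05,
    consecutive: int = 2,
) -> float:
    """Smallest scan threshold with a Poisson-consistent NNSD.

    Scans 0.30..0.95 (step 0.01) by default and returns the first
    candidate whose NNSD chi-square p-value exceeds ``alpha`` and stays
    above it for ``consecutive`` steps.  Raises
    :class:`~aquacomm._exceptions.NoTransitionError` when no candidate
    qualifies (degenerate spectra included), so the caller can fall back to
    a fixed cutoff.
    """
    arr = corr.to_numpy() if isinstance(corr, pd.DataFrame) else np.asarray(corr, float)
    if arr.shape[0] != arr.shape[1] or not np.allclose(arr, arr.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    if scan is None:
        scan = np.round(np.arange(0.30, 0.96, 0.01), 2)
    pvals = []
    for t in scan:
        w = arr.copy()
        w[np.abs(w) < t] = 0.0
        pvals.append(_nnsd_poisson_pvalue(np.linalg.eigvalsh(w)))
    pvals = np.asarray(pvals)
    ok = pvals > alpha
    for i in range(len(scan) - consecutive + 1):
        if ok[i : i + consecutive].all():
            return float(scan[i])
    raise NoTransitionError("no scan threshold gives a Poisson-consistent NNSD")


@dataclass
class NetworkTopology:
    n_nodes: int
    n_edges: int
    average_degree: float
    density: float
    diameter: int
    modularity: float
    modules: dict

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "n_nodes": self.n_nodes,
                "n_edges": self.n_edges,
                "average_degree": self.average_degree,
                "density": self.density,
                "diameter": self.diameter,
                "modularity": self.modularity,
            }
        )


def network_topology(net: nx.Graph) -> NetworkTopology:
    """Node/edge counts, average degree, density, diameter and modularity.

    The diameter uses unweighted shortest paths on the largest connected
    component, since thresholded graphs are typically disconnected.
    """
    if net.number_of_edges() < 1:
        raise ValueError("network has no edges")
    n, e = net.number_of_nodes(), net.number_of_edges()
    largest = max(nx.connected_components(net), key=len)
    diameter = nx.diameter(net.subgraph(largest))
    communities = nx.community.greedy_modularity_communities(net, weight=None)
    modularity = nx.community.modularity(net, communities, weight=None)
    modules = {node: k for k, comm in enumerate(communities) for node in comm}
    return NetworkTopology(
        n_nodes=n,
        n_edges=e,
        average_degree=2.0 * e / n,
        density=2.0 * e / (n * (n - 1)),
        diameter=int(diameter),
        modularity=float(modularity),
        modules=modules,
    )


def _interaction_strengths(net: nx.Graph) -> dict[tuple, float]:
    b = {}
    for u, v, data in net.edges(data=True):
        au = net.nodes[u].get("abundance", 1.0)
        av = net.nodes[v].get("abundance", 1.0)
        b[(u, v)] = abs(data.get("weight", 1.0)) * float(np.sqrt(au * av))
    return b


def network_robustness(
    net: nx.Graph,
    removal_fraction: float = 0.5,
    n_reps: int = 100,
    seed: int | None = None,
) -> tuple[float, float]:
    """Mean +/- sd fraction of taxa surviving random removal with cascades.

    Interaction strength ``b_ij = |w_ij| * sqrt(a_i a_j)`` with ``a`` the
    mean relative abundances.  Each replicate removes ``floor(f N)`` random
    nodes; remaining nodes then go extinct iteratively once the summed
    |b_ij| over surviving neighbors reaches zero (all links lost).
    Robustness is the mean surviving fraction of the original N.
    """
    if not 0 < removal_fraction < 1:
        raise ValueError("removal_fraction must be in (0, 1)")
    nodes = list(net.nodes)
    n = len(nodes)
    n_remove = int(np.floor(removal_fraction * n))
    rng = np.random.default_rng(seed)
    b = _interaction_strengths(net)
    fractions = np.empty(n_reps)
    for rep in range(n_reps):
        removed = set(rng.choice(n, size=n_remove, replace=False))
        alive = {nodes[i] for i in range(n) if i not in removed}
        changed = True
        while changed:
            changed = False
            for node in list(alive):
                strength = sum(
                    b.get((node, nb), b.get((nb, node), 0.0))
                    for nb in net.neighbors(node)
                    if nb in alive
                )
                if strength <= 0:
                    alive.discard(node)
                    changed = True
        fractions[rep] = len(alive) / n
    return float(fractions.mean()), float(fractions.std(ddof=0))


def global_efficiency(net: nx.Graph) -> float:
    """Mean inverse unweighted shortest-path length over node pairs."""
    return float(nx.global_efficiency(net))


def network_vulnerability(net: nx.Graph) -> float:
    """Largest single-node relative loss in global efficiency.

    ``V_i = (E - E_{-i}) / E`` with E the global efficiency; the maximum
    over nodes is returned.
    """
    components = [c for c in nx.connected_components(net) if len(c) >= 3]
    if not components:
        raise ValueError("vulnerability needs a connected component with >= 3 nodes")
    e_full = global_efficiency(net)
    if e_full <= 0:
        raise ValueError("zero global efficiency")
    worst = -np.inf
    for node in net.nodes:
        sub = net.subgraph([n for n in net.nodes if n != node])
        worst = max(worst, (e_full - global_efficiency(sub)) / e_full)
    return float(worst)


@dataclass
class CohesionResult:
    positive: pd.Series  # per-sample positive cohesion (>= 0)
    negative: pd.Series  # per-sample negative cohesion (<= 0)
    np_ratio: pd.Series  # |negative| / positive, NaN when positive == 0
    connectedness: pd.DataFrame  # per-taxon positive/negative connectedness


def cohesion(
    table: pd.DataFrame,
    n_null: int = 200,
    seed: int | None = None,
    method: str = "pearson",
) -> CohesionResult:
    """Null-corrected cohesion per sample.

    Pairwise correlations are corrected twice against a taxon-shuffle null
    (permuting each taxon's abundances across samples): first each ordered
    pair (i, j) has the mean null correlation subtracted, then each taxon's
    positive (negative) connectedness — the mean positive (negative) part
    of its corrected correlations — has the null expectation of that same
    statistic subtracted.  The second step matters because the positive
    part of pure sampling noise has a positive mean; after it, connectedness
    of an i.i.d. table is centered at zero.  Per-sample cohesion weights
    connectedness by relative abundance; positive cohesion is >= 0 and
    negative cohesion <= 0 by construction.
    """
    if table.shape[1] < 8:
        raise ValueError("need at least 8 samples")
    rel = relative_abundance(table)
    x = rel.T.to_numpy(dtype=float)  # samples x taxa
    n, m = x.shape
    if method == "spearman":
        x = np.apply_along_axis(stats.rankdata, 0, x)
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=0)) / sd
    r = z.T @ z / n
    np.fill_diagonal(r, 0.0)

    def null_correlations(generator):
        for _ in range(n_null):
            zp = np.empty_like(z)
            for j in range(m):
                zp[:, j] = z[generator.permutation(n), j]
            rn = z.T @ zp / n  # [i, j] = corr(original i, permuted j)
            np.fill_diagonal(rn, 0.0)
            yield rn

    # pass 1: per-pair null mean (bias from shared structure / composition)
    seed_seq = np.random.SeedSequence(seed)
    null_mean = np.zeros((m, m))
    for rn in null_correlations(np.random.default_rng(seed_seq)):
        null_mean += rn
    null_mean /= n_null
    r_corrected = r - null_mean
    np.fill_diagonal(r_corrected, 0.0)

    def split_conn(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        pos = np.clip(mat, 0.0, None).sum(axis=1) / (m - 1)
        neg = np.clip(mat, None, 0.0).sum(axis=1) / (m - 1)
        return pos, neg

    # pass 2 (identical null stream): expectation of the positive/negative
    # connectedness statistic itself, so pure sampling noise centers at zero
    null_pos = np.zeros(m)
    null_neg = np.zeros(m)
    for rn in null_correlations(np.random.default_rng(seed_seq)):
        p_k, n_k = split_conn(rn - null_mean)
        null_pos += p_k
        null_neg += n_k
    null_pos /= n_null
    null_neg /= n_null

    obs_pos, obs_neg = split_conn(r_corrected)
    pos_c = np.clip(obs_pos - null_pos, 0.0, None)
    neg_c = np.clip(obs_neg - null_neg, None, 0.0)

    rel_arr = rel.to_numpy(dtype=float)  # taxa x samples
    coh_pos = rel_arr.T @ pos_c
    coh_neg = rel_arr.T @ neg_c
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(coh_pos > 0, np.abs(coh_neg) / coh_pos, np.nan)
    samples = list(table.columns)
    return CohesionResult(
        positive=pd.Series(coh_pos, index=samples, name="positive_cohesion"),
        negative=pd.Series(coh_neg, index=samples, name="negative_cohesion"),
        np_ratio=pd.Series(ratio, index=samples, name="np_ratio"),
        connectedness=pd.DataFrame(
            {"positive": pos_c, "negative": neg_c}, index=list(table.index)
        ),
    )


def export_network(net: nx.Graph, basename) -> None:
    """Write GEXF and GraphML renderings of the network."""
    nx.write_gexf(net, f"{basename}.gexf")
    nx.write_graphml(net, f"{basename}.graphml")
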