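"""Null-model partitioning of community assembly processes.

The framework compares observed phylogenetic and taxonomic turnover between
sample pairs against null expectations:

* **betaMNTD** — for each taxon in one community, the patristic distance to
  its nearest relative in the other community, abundance-weighted and
  averaged over both directions.
* **betaNTI** — the standardized effect size of betaMNTD against a null in
  which tip labels are shuffled uniformly across the whole tree, abundances
  untouched.  ``betaNTI < -2`` indicates homogeneous selection (communities
  more phylogenetically similar than chance), ``> +2`` variable selection.
* **Raup-Crick (Bray-Curtis)** — for pairs not explained by selection
  (``|betaNTI| <= 2``), the observed Bray-Curtis dissimilarity is ranked
  against null community pairs that preserve each sample's richness and
  read total, drawing taxa by metacommunity occurrence frequency and reads
  by metacommunity relative abundance.  ``RC < -0.95`` indicates
  homogenizing dispersal, ``RC > 0.95`` dispersal limitation, and the
  remainder drift.

Homogeneous + variable selection form the deterministic fraction; the three
others are stochastic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix, TreeNode

from aquacomm._exceptions import AlignmentError

PROCESSES = (
    "variable_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
)


@dataclass
class NullModelConfig:
    """Replicates, seed and classification thresholds for the null models."""

    n_null: int = 999
    seed: int | None = None
    abundance_weighted: bool = True
    bnti_thresholds: tuple[float, float] = (-2.0, 2.0)
    rc_thresholds: tuple[float, float] = (-0.95, 0.95)

    def __post_init__(self):
        if self.n_null < 1:
            raise ValueError("n_null must be >= 1")


@dataclass
class ProcessPartition:
    variable_selection: float
    homogeneous_selection: float
    dispersal_limitation: float
    homogenizing_dispersal: float
    drift: float
    n_pairs: int

    @property
    def deterministic(self) -> float:
        return self.variable_selection + self.homogeneous_selection

    @property
    def stochastic(self) -> float:
        return (
            self.dispersal_limitation + self.homogenizing_dispersal + self.drift
        )

    def as_series(self) -> pd.Series:
        return pd.Series({p: getattr(self, p) for p in PROCESSES}, name="fraction")


@dataclass
class BetaNTIResult:
    values: pd.DataFrame  # samples x samples, symmetric, zero diagonal
    degenerate: pd.DataFrame  # True where sd(null) == 0 and betaNTI set to 0
    observed_betamntd: pd.DataFrame


def patristic_matrix(tree: TreeNode, taxa) -> np.ndarray:
    """Tip-to-tip patristic distances aligned to ``taxa`` order."""
    dm = tree.tip_tip_distances()
    try:
        idx = [dm.index(t) for t in taxa]
    except KeyError as exc:
        raise AlignmentError(f"taxon missing from tree: {exc}") from exc
    d = np.asarray(dm.data, dtype=float)
    return d[np.ix_(idx, idx)]


def _betamntd_from_arrays(
    freq: np.ndarray, presence: np.ndarray, d: np.ndarray
) -> np.ndarray:
    """betaMNTD for all sample pairs.

    ``freq``: taxa x samples weights (rows of absent taxa are zero);
    ``presence``: boolean taxa x samples; ``d``: taxa x taxa patristic
    distances.  The nearest taxon in the other community may be the focal
    taxon itself (shared taxa contribute distance zero).
    """
    n_samples = presence.shape[1]
    mins = np.empty((d.shape[0], n_samples))
    for s in range(n_samples):
        cols = presence[:, s]
        mins[:, s] = d[:, cols].min(axis=1)
    t = freq.T @ mins  # t[a, b] = sum_i f_ia * min_{j in b} d_ij
    return 0.5 * (t + t.T)


def _weights(counts: np.ndarray, abundance_weighted: bool) -> tuple[np.ndarray, np.ndarray]:
    presence = counts > 0
    if presence.sum(axis=0).min() == 0:
        raise ValueError("empty sample in table")
    if abundance_weighted:
        freq = counts / counts.sum(axis=0)
    else:
        freq = presence / presence.sum(axis=0)
    return freq.astype(float), presence


def beta_mntd(
    table: pd.DataFrame, tree: TreeNode, abundance_weighted: bool = True
) -> DistanceMatrix:
    """Observed betaMNTD between all sample pairs."""
    d = patristic_matrix(tree, table.index)
    freq, presence = _weights(table.to_numpy(dtype=float), abundance_weighted)
    bm = _betamntd_from_arrays(freq, presence, d)
    np.fill_diagonal(bm, 0.0)
    return DistanceMatrix(bm, ids=list(table.columns))


def beta_nti(
    table: pd.DataFrame, tree: TreeNode, config: NullModelConfig | None = None
) -> BetaNTIResult:
    """Standardized effect size of betaMNTD under tip-label shuffling.

    Pairs whose null distribution has zero spread (e.g. identical
    communities, or a star phylogeny where every shuffle is equivalent)
    cannot be standardized; they are reported as 0 with a degeneracy flag.
    """
    config = config or NullModelConfig()
    d = patristic_matrix(tree, table.index)
    counts = table.to_numpy(dtype=float)
    freq, presence = _weights(counts, config.abundance_weighted)
    obs = _betamntd_from_arrays(freq, presence, d)

    rng = np.random.default_rng(config.seed)
    n_taxa = d.shape[0]
    null_sum = np.zeros_like(obs)
    null_sq = np.zeros_like(obs)
    for _ in range(config.n_null):
        perm = rng.permutation(n_taxa)
        bm = _betamntd_from_arrays(freq, presence, d[np.ix_(perm, perm)])
        null_sum += bm
        null_sq += bm**2
    mean = null_sum / config.n_null
    var = np.maximum(null_sq / config.n_null - mean**2, 0.0)
    sd = np.sqrt(var)
    degenerate = sd < 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        bnti = np.where(degenerate, 0.0, (obs - mean) / np.where(degenerate, 1.0, sd))
    np.fill_diagonal(bnti, 0.0)
    np.fill_diagonal(degenerate, True)
    ids = list(table.columns)
    return BetaNTIResult(
        values=pd.DataFrame(bnti, index=ids, columns=ids),
        degenerate=pd.DataFrame(degenerate, index=ids, columns=ids),
        observed_betamntd=pd.DataFrame(obs, index=ids, columns=ids),
    )


def _null_community_draws(
    rng: np.random.Generator,
    n_null: int,
    richness: int,
    depth: int,
    occ_p: np.ndarray,
    abund_p: np.ndarray,
) -> np.ndarray:
    """``n_null`` random communities with fixed richness and read total.

    Taxa are selected without replacement with probability proportional to
    metacommunity occurrence frequency; each selected taxon gets one read
    and the remaining reads are multinomial with probability proportional
    to metacommunity relative abundance restricted to the selected taxa.
    """
    n_taxa = occ_p.size
    out = np.zeros((n_null, n_taxa), dtype=np.int64)
    for k in range(n_null):
        chosen = rng.choice(n_taxa, size=richness, replace=False, p=occ_p)
        out[k, chosen] = 1
        rest = depth - richness
        if rest > 0:
            p = abund_p[chosen]
            ps = p.sum()
            p = np.full(richness, 1.0 / richness) if ps <= 0 else p / ps
            out[k, chosen] += rng.multinomial(rest, p)
    return out


def raup_crick_bray(
    table: pd.DataFrame,
    config: NullModelConfig | None = None,
    metacommunity: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Raup-Crick metric on Bray-Curtis, scaled to [-1, 1].

    ``RC = 2 [ P(null BC < obs BC) + 0.5 P(null BC = obs BC) ] - 1``.
    The metacommunity defaults to the analyzed table itself (pooled
    samples); pass a wider table to rank against a larger species pool.
    """
    config = config or NullModelConfig()
    counts = table.to_numpy()
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("Raup-Crick requires integer counts")
        counts = np.round(counts).astype(np.int64)
    meta = table if metacommunity is None else metacommunity
    meta_counts = meta.to_numpy(dtype=float)
    occ = (meta_counts > 0).mean(axis=1)
    occ_p = occ / occ.sum()
    abund = meta_counts.sum(axis=1)
    abund_p = abund / abund.sum()

    n_samples = counts.shape[1]
    rng = np.random.default_rng(config.seed)
    richness = (counts > 0).sum(axis=0)
    depths = counts.sum(axis=0)
    nulls = [
        _null_community_draws(
            rng, config.n_null, int(richness[s]), int(depths[s]), occ_p, abund_p
        )
        for s in range(n_samples)
    ]

    rc = np.zeros((n_samples, n_samples))
    for a in range(n_samples):
        for b in range(a + 1, n_samples):
            x, y = counts[:, a].astype(float), counts[:, b].astype(float)
            obs = np.abs(x - y).sum() / (x + y).sum()
            na, nb = nulls[a].astype(float), nulls[b].astype(float)
            null_bc = np.abs(na - nb).sum(axis=1) / (na + nb).sum(axis=1)
            less = (null_bc < obs - 1e-12).mean()
            equal = (np.abs(null_bc - obs) <= 1e-12).mean()
            rc[a, b] = rc[b, a] = 2.0 * (less + 0.5 * equal) - 1.0
    ids = list(table.columns)
    return pd.DataFrame(rc, index=ids, columns=ids)


def _condensed_pairs(values: pd.DataFrame) -> np.ndarray:
    arr = values.to_numpy(dtype=float)
    iu = np.triu_indices(arr.shape[0], k=1)
    return arr[iu]


def partition_processes(
    bnti: pd.DataFrame, rc: pd.DataFrame, config: NullModelConfig | None = None
) -> ProcessPartition:
    """Assign every sample pair to exactly one of five assembly processes.

    betaNTI > +2: variable selection; < -2: homogeneous selection.  Among
    the remaining pairs, RC < -0.95: homogenizing dispersal; RC > +0.95:
    dispersal limitation; otherwise drift.
    """
    config = config or NullModelConfig()
    if list(bnti.index) != list(rc.index) or list(bnti.columns) != list(rc.columns):
        raise AlignmentError("betaNTI and RC matrices cover different sample pairs")
    b = _condensed_pairs(bnti)
    r = _condensed_pairs(rc)
    lo_b, hi_b = config.bnti_thresholds
    lo_r, hi_r = config.rc_thresholds
    n = b.size
    var_sel = (b > hi_b).sum()
    hom_sel = (b < lo_b).sum()
    within = (b >= lo_b) & (b <= hi_b)
    hom_disp = (within & (r < lo_r)).sum()
    disp_lim = (within & (r > hi_r)).sum()
    drift = (within & (r >= lo_r) & (r <= hi_r)).sum()
    return ProcessPartition(
        variable_selection=var_sel / n,
        homogeneous_selection=hom_sel / n,
        dispersal_limitation=disp_lim / n,
        homogenizing_dispersal=hom_disp / n,
        drift=drift / n,
        n_pairs=int(n),
    )


def partition_by_group(
    table: pd.DataFrame,
    tree: TreeNode,
    metadata: pd.DataFrame,
    config: NullModelConfig | None = None,
) -> dict[str, ProcessPartition]:
    """Per-group partitions: pairs spanning groups are excluded.

    Each group's null models (including the Raup-Crick metacommunity) use
    only that group's samples.
    """
    config = config or NullModelConfig()
    out: dict[str, ProcessPartition] = {}
    for group in pd.unique(metadata["group"]):
        samples = metadata.index[metadata["group"] == group]
        sub = table[samples]
        sub = sub.loc[sub.sum(axis=1) > 0]
        sub_tree = tree.shear(list(sub.index))
        bnti = beta_nti(sub, sub_tree, config)
        rc = raup_crick_bray(sub, config)
        out[str(group)] = partition_processes(bnti.values, rc, config)
    return out


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_pairs: int
    permutation_p: float | None = None


def _as_pairs(x, ids=None) -> tuple[np.ndarray, list]:
    """Condensed upper-triangle pairs from a per-sample vector or a matrix."""
    if isinstance(x, pd.Series):
        v = x.to_numpy(dtype=float)
        pairs = np.abs(v[:, None] - v[None, :])
        ids = list(x.index)
        iu = np.triu_indices(v.size, k=1)
        return pairs[iu], ids
    if isinstance(x, DistanceMatrix):
        ids = list(x.ids)
        arr = np.asarray(x.data, dtype=float)
    elif isinstance(x, pd.DataFrame):
        ids = list(x.index)
        arr = x.to_numpy(dtype=float)
    else:
        arr = np.asarray(x, dtype=float)
        if arr.ndim == 1:
            return arr, ids
    iu = np.triu_indices(arr.shape[0], k=1)
    return arr[iu], ids


def pairwise_regression(
    x, y, n_permutations: int = 0, seed: int | None = None
) -> RegressionResult:
    """OLS of pairwise dissimilarities on pairwise environmental change.

    ``x`` may be a per-sample scalar (pairwise absolute differences are
    formed) or an already-pairwise matrix; ``y`` is a distance matrix or
    pairwise matrix.  The p-value is the standard slope t-test; when
    ``n_permutations > 0`` a Mantel-style permutation p-value (shuffling
    sample order in x) is also reported, as pairwise observations are not
    independent.
    """
    x_pairs, x_ids = _as_pairs(x)
    y_pairs, y_ids = _as_pairs(y)
    if x_ids is not None and y_ids is not None and list(x_ids) != list(y_ids):
        raise AlignmentError("pair sets of x and y differ")
    if x_pairs.size != y_pairs.size:
        raise AlignmentError("x and y have different numbers of pairs")
    if np.std(x_pairs) == 0:
        raise ValueError("zero variance in x pairs")
    res = stats.linregress(x_pairs, y_pairs)
    perm_p = None
    if n_permutations > 0:
        if not isinstance(x, pd.Series):
            raise ValueError("permutation p requires per-sample x values")
        rng = np.random.default_rng(seed)
        v = x.to_numpy(dtype=float)
        n = v.size
        iu = np.triu_indices(n, k=1)
        obs = abs(res.rvalue)
        exceed = 0
        for _ in range(n_permutations):
            vp = v[rng.permutation(n)]
            xp = np.abs(vp[:, None] - vp[None, :])[iu]
            r = np.corrcoef(xp, y_pairs)[0, 1]
            exceed += abs(r) >= obs - 1e-12
        perm_p = (1.0 + exceed) / (1.0 + n_permutations)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n_pairs=int(x_pairs.size),
        permutation_p=perm_p,
    )


def export_pair_matrix(values: pd.DataFrame, path, flags: pd.DataFrame | None = None) -> None:
    """Long-format TSV (sample_a, sample_b, value[, flag]) of a pair matrix."""
    rows = []
    ids = list(values.index)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            row = {"sample_a": a, "sample_b": b, "value": values.loc[a, b]}
            if flags is not None:
                row["flag"] = bool(flags.loc[a, b])
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
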