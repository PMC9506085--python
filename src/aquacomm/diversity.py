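"""Alpha diversity, Bray-Curtis dissimilarity, PCoA and PERMANOVA.

Alpha indices follow the standard definitions: Chao1 richness
``S_obs + F1(F1-1) / (2(F2+1))``, Shannon entropy with natural logarithm,
Pielou evenness ``H / ln(S_obs)``, and Faith's phylogenetic diversity (total
branch length of the subtree spanning the observed taxa and the root).

PERMANOVA is implemented on the Gower-centered squared-distance matrix with
sequential (Type-I) sums of squares, so two-way designs with an interaction
term are supported; p-values come from free permutation of whole samples
with the add-one rule, hence are never exactly zero.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from skbio.diversity.alpha import faith_pd

from aquacomm._exceptions import ConfoundingError

ALPHA_INDICES = ("chao1", "shannon", "pielou", "faith_pd")


def _chao1(counts: np.ndarray) -> float:
    counts = counts[counts > 0]
    s_obs = counts.size
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def _shannon(counts: np.ndarray) -> float:
    p = counts[counts > 0].astype(float)
    p /= p.sum()
    return float(-(p * np.log(p)).sum())


def alpha_diversity(
    table: pd.DataFrame, index: str, tree: TreeNode | None = None
) -> pd.Series:
    """Per-sample alpha diversity for one index.

    Pielou evenness is undefined for samples with fewer than two observed
    taxa and is returned as NaN with a warning.
    """
    if index not in ALPHA_INDICES:
        raise ValueError(f"index must be one of {ALPHA_INDICES}")
    values = {}
    if index == "faith_pd":
        if tree is None:
            raise ValueError("faith_pd requires a phylogenetic tree")
        taxa = list(table.index)
        for sample in table.columns:
            values[sample] = float(
                faith_pd(table[sample].to_numpy(), taxa=taxa, tree=tree)
            )
        return pd.Series(values, name=index)
    for sample in table.columns:
        counts = table[sample].to_numpy()
        if index == "chao1":
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("chao1 requires integer counts")
            values[sample] = _chao1(counts)
        elif index == "shannon":
            values[sample] = _shannon(counts)
        else:  # pielou
            s_obs = int((counts > 0).sum())
            if s_obs < 2:
                warnings.warn(
                    f"Pielou evenness undefined for sample {sample!r} (<2 taxa)"
                )
                values[sample] = np.nan
            else:
                values[sample] = _shannon(counts) / np.log(s_obs)
    return pd.Series(values, name=index)


def alpha_diversity_table(table: pd.DataFrame, tree: TreeNode | None = None) -> pd.DataFrame:
    """All four indices as a tidy per-sample table."""
    idx = [i for i in ALPHA_INDICES if i != "faith_pd" or tree is not None]
    return pd.DataFrame({i: alpha_diversity(table, i, tree=tree) for i in idx})


def bray_curtis_matrix(table: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities between samples."""
    if table.shape[1] < 2:
        raise ValueError("need at least two samples")
    sums = table.sum(axis=0)
    if (sums == 0).any():
        zero = sums.index[sums == 0].tolist()
        raise ValueError(f"all-zero samples: {zero}")
    d = pdist(table.T.to_numpy(dtype=float), metric="braycurtis")
    return DistanceMatrix(squareform(d), ids=list(table.columns))


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives kept)
    proportion_explained: np.ndarray  # over positive eigenvalue mass


def pcoa(d: DistanceMatrix, n_axes: int = 2) -> PCoAResult:
    """Classical metric multidimensional scaling (principal coordinates).

    The Gower-centered matrix is eigendecomposed; negative eigenvalues are
    reported unchanged and the proportion explained is computed over the
    positive eigenvalue mass only.
    """
    dm = np.asarray(d.data, dtype=float)
    n = dm.shape[0]
    a = -0.5 * dm**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    eigval, eigvec = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > 1e-12
    rank = int(pos.sum())
    if n_axes > rank:
        warnings.warn(f"requested {n_axes} axes but rank is {rank}; truncating")
        n_axes = rank
    coords = eigvec[:, :n_axes] * np.sqrt(eigval[:n_axes])
    proportion = np.where(pos, eigval, 0.0) / eigval[pos].sum()
    return PCoAResult(
        coordinates=pd.DataFrame(
            coords, index=list(d.ids), columns=[f"PCo{i + 1}" for i in range(n_axes)]
        ),
        eigenvalues=eigval,
        proportion_explained=proportion,
    )


@dataclass
class PermanovaResult:
    terms: pd.DataFrame  # rows: terms + Residual + Total; cols: df, SS, R2, F, p
    n_permutations: int
    formula: str


def _parse_formula(formula: str) -> list[str]:
    terms = [t.strip() for t in formula.split("+") if t.strip()]
    if not terms:
        raise ValueError("empty formula")
    return terms


def _design_columns(term: str, metadata: pd.DataFrame) -> np.ndarray:
    """Full-rank-free dummy block for one term (factor or a:b interaction)."""
    factors = [f.strip() for f in term.split(":")]
    labels = metadata[factors[0]].astype(str)
    for f in factors[1:]:
        labels = labels + "\x1f" + metadata[f].astype(str)
    return pd.get_dummies(labels).to_numpy(dtype=float)


def _check_confounding(terms: list[str], metadata: pd.DataFrame) -> None:
    simple = [t for t in terms if ":" not in t]
    for a, b in itertools.combinations(simple, 2):
        la, lb = metadata[a].astype(str), metadata[b].astype(str)
        if la.nunique() > 1 and la.nunique() == lb.nunique():
            mapping = pd.crosstab(la, lb)
            if ((mapping > 0).sum(axis=1) == 1).all() and (
                (mapping > 0).sum(axis=0) == 1
            ).all():
                raise ConfoundingError(f"factors {a!r} and {b!r} are 1:1 confounded")


def _orthobasis(x: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(x)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    return q[:, keep]


def _cumulative_bases(n: int, designs: list[np.ndarray]) -> list[np.ndarray]:
    """Orthonormal bases of intercept, intercept+T1, intercept+T1+T2, ..."""
    x = np.ones((n, 1))
    bases = [_orthobasis(x)]
    for block in designs:
        x = np.hstack([x, block])
        bases.append(_orthobasis(x))
    return bases


def _sequential_ss(g: np.ndarray, bases: list[np.ndarray]) -> np.ndarray:
    """Sequential sums of squares: tr(H_k G) - tr(H_{k-1} G) per term."""
    traces = np.array([np.einsum("ij,ji->", q.T @ g, q) for q in bases])
    return np.diff(traces)


def permanova(
    d: DistanceMatrix,
    metadata: pd.DataFrame,
    formula: str,
    n_permutations: int = 999,
    seed: int | None = None,
    exhaustive: bool = False,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    ``formula`` is a ``+``-separated list of metadata factors; an
    interaction is written ``a:b``.  Sums of squares are sequential in
    formula order; the permutation unit is the whole sample (free
    exchange).  With ``exhaustive=True`` every permutation of the samples
    is enumerated (small n only) and the p-value is the exact fraction of
    permutations, identity included, reaching the observed pseudo-F.
    """
    ids = list(d.ids)
    md = metadata.loc[ids]
    terms = _parse_formula(formula)
    for t in terms:
        for f in t.split(":"):
            if md[f.strip()].nunique() < 2:
                raise ValueError(f"factor {f!r} has fewer than 2 levels")
    _check_confounding(terms, md)

    dm = np.asarray(d.data, dtype=float)
    n = dm.shape[0]
    a = -0.5 * dm**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    designs = [_design_columns(t, md) for t in terms]
    bases = _cumulative_bases(n, designs)
    df_terms = np.diff([q.shape[1] for q in bases])

    ss_total = np.trace(g)
    ss_terms = _sequential_ss(g, bases)
    df_model = int(df_terms.sum())
    df_resid = n - 1 - df_model
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    ss_resid = ss_total - ss_terms.sum()
    ms_resid = ss_resid / df_resid
    f_obs = (ss_terms / np.maximum(df_terms, 1)) / ms_resid

    if exhaustive:
        if n > 8:
            raise ValueError("exhaustive enumeration is limited to n <= 8")
        perms = list(itertools.permutations(range(n)))
        reach = np.zeros(len(terms))
        for perm in perms:
            gp = g[np.ix_(perm, perm)]
            ss_p = _sequential_ss(gp, bases)
            ss_res_p = ss_total - ss_p.sum()
            f_p = (ss_p / np.maximum(df_terms, 1)) / (ss_res_p / df_resid)
            reach += f_p >= f_obs - 1e-12
        pvals = reach / len(perms)
        n_permutations = len(perms)
    else:
        rng = np.random.default_rng(seed)
        exceed = np.zeros(len(terms))
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            gp = g[np.ix_(perm, perm)]
            ss_p = _sequential_ss(gp, bases)
            ss_res_p = ss_total - ss_p.sum()
            f_p = (ss_p / np.maximum(df_terms, 1)) / (ss_res_p / df_resid)
            exceed += f_p >= f_obs - 1e-12
        pvals = (1.0 + exceed) / (1.0 + n_permutations)

    rows = []
    for k, t in enumerate(terms):
        rows.append((t, df_terms[k], ss_terms[k], ss_terms[k] / ss_total, f_obs[k], pvals[k]))
    rows.append(("Residual", df_resid, ss_resid, ss_resid / ss_total, np.nan, np.nan))
    rows.append(("Total", n - 1, ss_total, 1.0, np.nan, np.nan))
    table = pd.DataFrame(rows, columns=["term", "df", "SS", "R2", "F", "p"]).set_index("term")
    return PermanovaResult(terms=table, n_permutations=n_permutations, formula=formula)
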