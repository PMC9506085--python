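"""Rule-based functional profiling and the functional redundancy index.

Functional profiles are obtained by matching taxonomy strings against a
user-supplied rule table (pattern at a taxonomic rank -> function label),
the mechanism behind rule-based annotators for prokaryotic 16S surveys.

The functional redundancy index (FRI) quantifies, per sample and function,
how much of the community can perform the function *and* how
phylogenetically spread those performers are:

    FRI(s, f) = sum over possessing taxa i present in s of
                p_is * mean_{j != i, possessing, present} (1 - d_ij / d_max)

where ``p_is`` is relative abundance, ``d`` patristic distance and
``d_max`` the tree diameter.  A function carried by one present taxon has
no redundancy (FRI = 0); redundancy rises with the abundance of the
performers and with their phylogenetic closeness, and is bounded by 1.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from skbio import TreeNode

from aquacomm._exceptions import AlignmentError
from aquacomm.assembly import (
    RegressionResult,
    pairwise_regression,
    patristic_matrix,
)
from aquacomm.core_io import relative_abundance


def load_rules(path) -> pd.DataFrame:
    """Two-column TSV (pattern, function)."""
    rules = pd.read_csv(path, sep="\t", comment="#")
    rules.columns = [c.strip() for c in rules.columns]
    if list(rules.columns[:2]) != ["pattern", "function"]:
        raise ValueError("rule table must have columns: pattern, function")
    return rules


def _ranks(taxonomy: str) -> list[str]:
    return [tok.strip() for tok in taxonomy.split(";") if tok.strip()]


def assign_functions(
    table: pd.DataFrame,
    taxonomy: Mapping[str, str] | pd.Series,
    rules: pd.DataFrame,
) -> tuple[pd.DataFrame, list[str]]:
    """Function x sample relative-abundance table from a rule table.

    A taxon contributes its full relative abundance to every function whose
    pattern equals one of its taxonomy ranks (no splitting across
    functions).  Returns the profile and the list of unmatched taxa.
    """
    taxonomy = pd.Series(dict(taxonomy)) if not isinstance(taxonomy, pd.Series) else taxonomy
    missing = [t for t in table.index if t not in taxonomy.index]
    if missing:
        raise AlignmentError(f"taxa without taxonomy strings: {missing[:5]}")
    functions = list(pd.unique(rules["function"]))
    rel = relative_abundance(table)
    profile = pd.DataFrame(0.0, index=functions, columns=table.columns)
    unmatched = []
    by_pattern: dict[str, list[str]] = {}
    for _, row in rules.iterrows():
        by_pattern.setdefault(str(row["pattern"]).strip(), []).append(row["function"])
    for taxon in table.index:
        hit = False
        for rank in _ranks(str(taxonomy[taxon])):
            for func in by_pattern.get(rank, ()):
                profile.loc[func] += rel.loc[taxon]
                hit = True
        if not hit:
            unmatched.append(taxon)
    return profile, unmatched


def functional_redundancy_index(
    table: pd.DataFrame,
    tree: TreeNode,
    incidence: pd.DataFrame,
) -> pd.DataFrame:
    """FRI per (sample, function); returns a function x sample frame.

    ``incidence`` is a binary taxa x functions matrix (1 = the taxon can
    perform the function).  Taxa absent from the incidence frame are
    treated as performing nothing; taxa listed there but absent from the
    table are ignored, so padding the incidence with extra taxa never
    changes the result.
    """
    taxa = list(table.index)
    d = patristic_matrix(tree, taxa)
    d_max = float(d.max())
    if d_max <= 0:
        raise ValueError("tree diameter is zero; phylogenetic similarity undefined")
    sim = 1.0 - d / d_max
    g = incidence.reindex(index=taxa, fill_value=0).to_numpy(dtype=float)
    g = (g > 0).astype(float)
    rel = relative_abundance(table).to_numpy(dtype=float)
    presence = rel > 0

    n_funcs = g.shape[1]
    out = np.zeros((n_funcs, table.shape[1]))
    for s in range(table.shape[1]):
        pres = presence[:, s]
        for f in range(n_funcs):
            idx = np.flatnonzero(pres & (g[:, f] > 0))
            if idx.size <= 1:
                continue
            sub = sim[np.ix_(idx, idx)]
            np.fill_diagonal(sub, 0.0)
            mean_sim = sub.sum(axis=1) / (idx.size - 1)
            out[f, s] = float((rel[idx, s] * mean_sim).sum())
    return pd.DataFrame(out, index=list(incidence.columns), columns=table.columns)


def fri_group_log_ratio(
    fri_a: pd.DataFrame,
    fri_b: pd.DataFrame,
    pseudocount: float = 0.0,
) -> tuple[pd.Series, int, int, list[str]]:
    """Per-function log10 ratio of group-mean FRI, A over B.

    Returns (log ratios, count of functions more redundant in A, count more
    redundant in B, excluded functions with zero mean in both groups).
    """
    if list(fri_a.index) != list(fri_b.index):
        raise AlignmentError("FRI tables cover different function sets")
    mean_a = fri_a.mean(axis=1)
    mean_b = fri_b.mean(axis=1)
    both_zero = (mean_a == 0) & (mean_b == 0)
    excluded = list(mean_a.index[both_zero])
    ma = mean_a[~both_zero] + pseudocount
    mb = mean_b[~both_zero] + pseudocount
    with np.errstate(divide="ignore"):
        ratio = np.log10(ma / mb)
    ratio = pd.Series(ratio, index=ma.index, name="log10_ratio")
    more_a = int((ratio > 0).sum())
    more_b = int((ratio < 0).sum())
    return ratio, more_a, more_b, excluded


def delta_fri_matrix(fri: pd.DataFrame, function: str | None = None) -> pd.DataFrame:
    """Pairwise |ΔFRI| between samples (one function, or the mean over all)."""
    values = fri.loc[function] if function is not None else fri.mean(axis=0)
    v = values.to_numpy(dtype=float)
    pairs = np.abs(v[:, None] - v[None, :])
    return pd.DataFrame(pairs, index=fri.columns, columns=fri.columns)


def fri_bnti_regression(delta_fri, bnti, **kwargs) -> RegressionResult:
    """OLS of pairwise FRI change on betaNTI (shared regression engine)."""
    return pairwise_regression(delta_fri, bnti, **kwargs)
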