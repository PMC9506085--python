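"""Environment-community analysis: RDA, correlation screens and TITAN.

Threshold indicator taxa analysis (TITAN) locates, for every taxon, the
point along an environmental gradient where its indicator value (IndVal —
relative-abundance concentration x relative frequency, scaled to 100) is
maximized; the split side with the larger IndVal gives the response
direction (+ for taxa increasing above the change point).  Permuting the
gradient yields a z-score for the observed IndVal, and bootstrapping the
samples yields *purity* (fraction of bootstraps agreeing in direction) and
*reliability* (fraction with permutation p < 0.05).  Taxa passing both at
0.95 are "pure and reliable" indicators.

The community's environmental breadth for a factor is summarized from its
indicator taxa in two ways: the sum of |z| scores, and the 5th-95th
percentile span of the indicator change points.  A wider span means the
community keeps responding across a wider stretch of the gradient, i.e.
broader environmental adaptation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=0)
    if (sd == 0).any():
        raise ValueError("constant environmental factor cannot be standardized")
    return (x - x.mean(axis=0)) / sd


@dataclass
class RdaResult:
    constrained_proportion: float
    factor_f: pd.Series
    factor_p: pd.Series
    n_permutations: int


def rda_variance(
    table: pd.DataFrame,
    env: pd.DataFrame,
    transform: str = "hellinger",
    n_permutations: int = 199,
    seed: int | None = None,
) -> RdaResult:
    """Redundancy analysis: fraction of community variance explained.

    The community matrix (samples x taxa, optionally Hellinger-transformed)
    is regressed on the standardized factors; the constrained proportion is
    the fitted sum of squares over the total.  Each factor's marginal
    pseudo-F (drop-one) gets a permutation p-value by shuffling that
    factor's values.
    """
    if transform not in ("hellinger", "none"):
        raise ValueError("transform must be 'hellinger' or 'none'")
    env = env.loc[table.columns]
    y = table.T.to_numpy(dtype=float)
    if transform == "hellinger":
        rowsums = y.sum(axis=1, keepdims=True)
        rowsums[rowsums == 0] = 1.0
        y = np.sqrt(y / rowsums)
    y = y - y.mean(axis=0)
    x = _standardize(env.to_numpy(dtype=float))
    n, m = x.shape
    if m > n - 1:
        raise ValueError(f"{m} factors exceed n-1 = {n - 1}")

    def fitted_ss(xmat: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(xmat, y, rcond=None)
        return float(((xmat @ beta) ** 2).sum())

    ss_total = float((y**2).sum())
    ss_full = fitted_ss(x)
    constrained = ss_full / ss_total if ss_total > 0 else 0.0
    df_resid = n - m - 1
    ss_resid = ss_total - ss_full

    rng = np.random.default_rng(seed)
    f_vals, p_vals = {}, {}
    for k, factor in enumerate(env.columns):
        reduced = np.delete(x, k, axis=1)
        ss_k = ss_full - (fitted_ss(reduced) if reduced.size else 0.0)
        f_obs = (ss_k / 1.0) / (ss_resid / max(df_resid, 1))
        exceed = 0
        for _ in range(n_permutations):
            xp = x.copy()
            xp[:, k] = x[rng.permutation(n), k]
            ss_full_p = fitted_ss(xp)
            ss_k_p = ss_full_p - fitted_ss(np.delete(xp, k, axis=1))
            f_p = ss_k_p / ((ss_total - ss_full_p) / max(df_resid, 1))
            exceed += f_p >= f_obs - 1e-12
        f_vals[factor] = f_obs
        p_vals[factor] = (1.0 + exceed) / (1.0 + n_permutations)
    return RdaResult(
        constrained_proportion=constrained,
        factor_f=pd.Series(f_vals, name="F"),
        factor_p=pd.Series(p_vals, name="p"),
        n_permutations=n_permutations,
    )


def env_correlation_screen(
    abundances: pd.DataFrame,
    env: pd.DataFrame,
    adjust: str = "bonferroni",
    tiers: tuple[float, float] = (0.05, 0.01),
) -> pd.DataFrame:
    """Spearman correlations of taxa against factors with Bonferroni tiers.

    Returns a long-format frame with rho, raw and adjusted p, and a
    significance marker: '++' below the stricter tier, '+' below the looser
    one, '' otherwise.  Constant vectors yield missing correlations.
    """
    if abundances.shape[1] < 4:
        raise ValueError("need at least 4 samples for a rank correlation")
    if adjust != "bonferroni":
        raise ValueError("only bonferroni adjustment is implemented")
    env = env.loc[abundances.columns]
    n_tests = abundances.shape[0] * env.shape[1]
    rows = []
    for taxon in abundances.index:
        a = abundances.loc[taxon].to_numpy(dtype=float)
        for factor in env.columns:
            e = env[factor].to_numpy(dtype=float)
            if np.ptp(a) == 0 or np.ptp(e) == 0:
                rho, p_raw = np.nan, np.nan
            else:
                rho, p_raw = stats.spearmanr(a, e)
            p_adj = min(1.0, p_raw * n_tests) if np.isfinite(p_raw) else np.nan
            marker = ""
            if np.isfinite(p_adj):
                if p_adj < tiers[1]:
                    marker = "++"
                elif p_adj < tiers[0]:
                    marker = "+"
            rows.append((taxon, factor, rho, p_raw, p_adj, marker))
    return pd.DataFrame(
        rows, columns=["taxon", "factor", "rho", "p", "p_adjusted", "significance"]
    )


@dataclass
class TitanResult:
    taxa: pd.DataFrame  # per-taxon change_point, direction, indval, z, purity, reliability
    factor: str
    n_permutations: int
    n_bootstrap: int

    @property
    def indicators(self) -> pd.DataFrame:
        """Pure-and-reliable indicator taxa (both >= 0.95)."""
        t = self.taxa
        return t[(t["purity"] >= 0.95) & (t["reliability"] >= 0.95)]


def _scan_indvals(abund: np.ndarray, order: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Best split per taxon along a sample ordering.

    ``abund``: taxa x samples; ``order``: sample indices sorted by factor;
    returns (best IndVal, best split index, direction sign) per taxon.
    Split index k puts samples order[:k+1] on the low side.
    """
    a = abund[:, order].astype(float)
    n_taxa, n = a.shape
    tot = a.sum(axis=1, keepdims=True)
    tot[tot == 0] = 1.0
    cum = np.cumsum(a, axis=1)
    pres = (a > 0).astype(float)
    cum_pres = np.cumsum(pres, axis=1)
    ks = np.arange(1, n)  # low side sizes
    a_low = cum[:, :-1] / tot  # abundance concentration, low side
    a_high = 1.0 - a_low
    b_low = cum_pres[:, :-1] / ks
    b_high = (cum_pres[:, -1:] - cum_pres[:, :-1]) / (n - ks)
    iv_low = a_low * b_low * 100.0
    iv_high = a_high * b_high * 100.0
    iv = np.maximum(iv_low, iv_high)
    best_k = iv.argmax(axis=1)
    rows = np.arange(n_taxa)
    best_iv = iv[rows, best_k]
    direction = np.where(iv_high[rows, best_k] >= iv_low[rows, best_k], 1, -1)
    return best_iv, best_k, direction


def _split_midpoints(factor_sorted: np.ndarray) -> np.ndarray:
    return 0.5 * (factor_sorted[:-1] + factor_sorted[1:])


def titan_change_points(
    table: pd.DataFrame,
    factor: pd.Series,
    n_permutations: int = 250,
    n_bootstrap: int = 100,
    seed: int | None = None,
    min_occurrence: int = 3,
) -> TitanResult:
    """Threshold indicator taxa analysis along one environmental factor."""
    factor = factor.loc[table.columns].astype(float)
    values = factor.to_numpy()
    if np.unique(values).size < 5:
        raise ValueError("factor needs at least 5 distinct values")
    keep = (table.to_numpy() > 0).sum(axis=1) >= min_occurrence
    sub = table.loc[keep]
    if sub.shape[0] == 0:
        raise ValueError("no taxon passes the occurrence filter")
    abund = sub.to_numpy(dtype=float)
    n = values.size
    order = np.argsort(values, kind="stable")
    mids = _split_midpoints(values[order])

    obs_iv, obs_k, obs_dir = _scan_indvals(abund, order)
    change_points = mids[obs_k]

    rng = np.random.default_rng(seed)
    perm_ivs = np.empty((n_permutations, abund.shape[0]))
    for p in range(n_permutations):
        perm_order = rng.permutation(n)
        perm_ivs[p], _, _ = _scan_indvals(abund, perm_order)
    mu = perm_ivs.mean(axis=0)
    sd = perm_ivs.std(axis=0, ddof=0)
    sd_safe = np.where(sd < 1e-12, 1.0, sd)
    z = np.where(sd < 1e-12, 0.0, (obs_iv - mu) / sd_safe)
    perm_p = (1.0 + (perm_ivs >= obs_iv[None, :] - 1e-12).sum(axis=0)) / (
        1.0 + n_permutations
    )

    agree = np.zeros(abund.shape[0])
    reliable = np.zeros(abund.shape[0])
    n_boot_perm = max(50, n_permutations // 5)
    for _ in range(n_bootstrap):
        bidx = rng.integers(0, n, size=n)
        bvals = values[bidx]
        border = np.argsort(bvals, kind="stable")
        babund = abund[:, bidx]
        biv, _, bdir = _scan_indvals(babund, border)
        agree += bdir == obs_dir
        bperm = np.empty((n_boot_perm, abund.shape[0]))
        for p in range(n_boot_perm):
            bperm[p], _, _ = _scan_indvals(babund, rng.permutation(n))
        bp = (1.0 + (bperm >= biv[None, :] - 1e-12).sum(axis=0)) / (1.0 + n_boot_perm)
        reliable += bp < 0.05
    purity = agree / n_bootstrap
    reliability = reliable / n_bootstrap

    taxa = pd.DataFrame(
        {
            "change_point": change_points,
            "direction": obs_dir,
            "indval": obs_iv,
            "z": z,
            "p_permutation": perm_p,
            "purity": purity,
            "reliability": reliability,
        },
        index=sub.index,
    )
    return TitanResult(
        taxa=taxa,
        factor=str(factor.name),
        n_permutations=n_permutations,
        n_bootstrap=n_bootstrap,
    )


@dataclass
class BreadthResult:
    score_sum: float
    span: tuple[float, float]
    span_width: float
    n_indicators: int


def environmental_breadth(titan: TitanResult) -> BreadthResult:
    """Breadth of community response from pure-and-reliable indicators.

    ``score_sum`` adds the |z| scores of the indicator taxa; ``span`` is
    the [5th, 95th] percentile interval of their change points.  Group
    comparisons default to the span width; both readings are reported.
    """
    ind = titan.indicators
    if len(ind) < 2:
        warnings.warn(
            f"fewer than 2 indicator taxa for {titan.factor}; breadth undefined"
        )
        return BreadthResult(np.nan, (np.nan, np.nan), np.nan, len(ind))
    score_sum = float(ind["z"].abs().sum())
    lo, hi = np.percentile(ind["change_point"].to_numpy(), [5, 95])
    return BreadthResult(score_sum, (float(lo), float(hi)), float(hi - lo), len(ind))
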