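"""Attractor (GSEA-ANOVA) differential-pathway statistics.

The procedure scores each pathway by how strongly its member genes'
one-way ANOVA F-statistics exceed the genome-wide average:

* per gene i, ``F_i = MSS_i / RSS_i`` with
  ``MSS_i = Σ_k r_k (ȳ·k − ȳ··)² / (K−1)`` (between-group mean square)
  and ``RSS_i = Σ_k Σ_j (y_jk − ȳ·k)² / (N−K)`` (residual mean square);
* per pathway p with g_p scored member genes,

  ``T_p = (mean_p F − mean_G F) / sqrt(S_p²/g_p + S_G²/G)``

  where S_p² and S_G² are the unbiased sample variances of the F values
  within the pathway and over the whole gene universe G. T_p is exactly
  a Welch two-sample t statistic between the pathway's F values and all
  genes' F values; its two-sided P value is taken from a t distribution
  with Welch–Satterthwaite degrees of freedom. A permutation reference
  (random gene sets of the same size) is available as an alternative.
* P values are adjusted across pathways by Benjamini–Hochberg step-up.

The gene universe G defaults to every gene in the expression matrix
(``universe="matrix"``); ``universe="sets"`` restricts it to the union
of pathway members.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError
from .io import ExpressionStudy, GeneSetCollection

logger = logging.getLogger(__name__)


def gene_f_statistics(study: ExpressionStudy) -> pd.DataFrame:
    """One-way ANOVA decomposition per gene.

    Returns a DataFrame indexed by gene id with columns ``mss``, ``rss``
    and ``f``. Genes with zero residual variance get F = +inf when the
    group means differ and F = 0 otherwise; downstream pathway means
    exclude non-finite F values.
    """
    K = study.n_groups
    N = study.n_samples
    if K < 2:
        raise ContractError(f"need ≥ 2 groups, found {K}")
    if N <= K:
        raise ContractError(f"need N > K samples (N={N}, K={K})")

    y = study.values.to_numpy(dtype=float)
    grand = y.mean(axis=1)
    between = np.zeros(y.shape[0])
    within = np.zeros(y.shape[0])
    for g in study.group_order:
        yg = study.group_matrix(g)
        rk = yg.shape[1]
        mg = yg.mean(axis=1)
        between += rk * (mg - grand) ** 2
        within += ((yg - mg[:, None]) ** 2).sum(axis=1)
    mss = between / (K - 1)
    rss = within / (N - K)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(rss > 0, mss / np.where(rss > 0, rss, 1.0),
                     np.where(mss > 0, np.inf, 0.0))
    return pd.DataFrame(
        {"mss": mss, "rss": rss, "f": f},
        index=pd.Index(study.gene_ids, name="gene_id"),
    )


@dataclass
class PathwayTestResult:
    """Per-pathway attractor statistics plus a skip report."""

    table: pd.DataFrame          # pathway_id × (g_p, t_stat, p_value, fdr)
    skipped: dict[str, str] = field(default_factory=dict)  # pathway_id -> reason


def pathway_t_statistics(
    f_table: pd.DataFrame,
    sets: GeneSetCollection,
    method: str = "t",
    n_permutations: int = 10_000,
    seed: int | None = None,
    universe: str = "matrix",
) -> PathwayTestResult:
    """Welch-type pathway T statistics over gene F values, BH-adjusted.

    Pathways with fewer than two scored member genes are excluded and
    recorded in the skip report. ``method="permutation"`` replaces the
    t reference by random same-size gene sets (seeded).
    """
    f_all = f_table["f"]
    n_inf = int(np.isinf(f_all).sum())
    if n_inf:
        logger.warning("excluding %d gene(s) with infinite F from pathway means", n_inf)
    finite = f_all[np.isfinite(f_all)]

    if universe == "sets":
        members = {g for gs in sets for g in gs.genes}
        finite = finite[finite.index.isin(members)]
    elif universe != "matrix":
        raise ContractError(f"unknown universe {universe!r}")

    fvals = finite.to_numpy()
    G = fvals.size
    if G < 2:
        raise ContractError("need ≥ 2 genes with finite F statistics")
    m_G = fvals.mean()
    s2_G = fvals.var(ddof=1)

    rng = np.random.default_rng(seed)
    rows = []
    skipped: dict[str, str] = {}
    for gs in sets:
        idx = finite.index.intersection(gs.genes)
        g_p = len(idx)
        if g_p < 2:
            skipped[gs.id] = f"{g_p} scored gene(s); ≥2 required"
            continue
        fp = finite.loc[idx].to_numpy()
        t_stat, p = _welch_vs_universe(fp, fvals, m_G, s2_G)
        if method == "permutation":
            p = _permutation_p(t_stat, g_p, fvals, m_G, s2_G, n_permutations, rng)
        elif method != "t":
            raise ContractError(f"unknown pathway test method {method!r}")
        rows.append((gs.id, g_p, t_stat, p))
    if skipped:
        logger.warning("skipped %d pathway(s) with <2 scored genes", len(skipped))

    table = pd.DataFrame(
        rows, columns=["pathway_id", "g_p", "t_stat", "p_value"]
    ).set_index("pathway_id")
    table["fdr"] = bh_adjust(table["p_value"].to_numpy()) if len(table) else []
    return PathwayTestResult(table, skipped)


def _welch_vs_universe(fp: np.ndarray, fvals: np.ndarray,
                       m_G: float, s2_G: float) -> tuple[float, float]:
    g_p, G = fp.size, fvals.size
    s2_p = fp.var(ddof=1)
    denom2 = s2_p / g_p + s2_G / G
    if denom2 == 0:
        return 0.0, 1.0
    t_stat = (fp.mean() - m_G) / np.sqrt(denom2)
    df = denom2**2 / ((s2_p / g_p) ** 2 / (g_p - 1) + (s2_G / G) ** 2 / (G - 1))
    p = 2.0 * stats.t.sf(abs(t_stat), df)
    return float(t_stat), float(p)


def _permutation_p(t_obs: float, g_p: int, fvals: np.ndarray, m_G: float,
                   s2_G: float, n_perm: int, rng: np.random.Generator) -> float:
    G = fvals.size
    # random same-size gene subsets via random-key selection
    keys = rng.random((n_perm, G))
    idx = np.argpartition(keys, g_p, axis=1)[:, :g_p]
    sub = fvals[idx]
    m = sub.mean(axis=1)
    s2 = sub.var(axis=1, ddof=1)
    denom2 = s2 / g_p + s2_G / G
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = np.where(denom2 > 0, (m - m_G) / np.sqrt(np.where(denom2 > 0, denom2, 1.0)), 0.0)
    exceed = int((np.abs(t_perm) >= abs(t_obs)).sum())
    return (1 + exceed) / (n_perm + 1)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted P values, in input order.

    ``q_(i) = min_{j ≥ i} p_(j)·m/j`` over the ascending order
    statistics, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ContractError("bh_adjust expects a 1-d vector")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ContractError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def write_pathway_table(result: PathwayTestResult, path) -> None:
    result.table.to_csv(path, sep="\t", float_format="%.10g")
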