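"""Rank-product / Impact-Factor integration and core-pathway selection.

Each pathway carries two criteria: its attractor P value ("inter") and
its disease-network degree ("outer"). The rank product normalises the
two ranks,

    RP = (rank_inter / Total) × (rank_outer / Total),

with rank 1 for the smallest P value and for the largest degree
(average ranks on ties), and the Impact Factor combines magnitude and
significance,

    IF = degree × (1 − P).

Core pathways satisfy all three of P < 0.05, RP < 0.05 and IF > 100
(strict inequalities).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError

SCORECARD_COLUMNS = [
    "p_value", "fdr", "bg_degree", "test_degree", "score",
    "rank_inter", "rank_outer", "rp", "impact",
    "pass_p", "pass_rp", "pass_if", "is_core",
]


def rank_product(p_values, degrees, ties: str = "average") -> pd.DataFrame:
    """RP values over aligned pathway vectors.

    ``ties`` is the rank method for tied values (``average`` or
    ``min``, as in :func:`scipy.stats.rankdata`).
    """
    p = np.asarray(p_values, dtype=float)
    d = np.asarray(degrees, dtype=float)
    if p.shape != d.shape or p.ndim != 1:
        raise ContractError("p_values and degrees must be 1-d vectors of equal length")
    if p.size == 0:
        raise ContractError("need at least one pathway")
    total = p.size
    rank_inter = stats.rankdata(p, method=ties)
    rank_outer = stats.rankdata(-d, method=ties)
    rp = (rank_inter / total) * (rank_outer / total)
    return pd.DataFrame({"rank_inter": rank_inter, "rank_outer": rank_outer, "rp": rp})


def impact_factor(degree, p_value):
    """IF = degree × (1 − P); vectorised."""
    d = np.asarray(degree, dtype=float)
    p = np.asarray(p_value, dtype=float)
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ContractError("p values must lie in [0, 1]")
    if np.any(d < 0):
        raise ContractError("degrees must be ≥ 0")
    out = d * (1.0 - p)
    return float(out) if out.ndim == 0 else out


def build_scorecard(
    pathway_table: pd.DataFrame,
    score_table: pd.DataFrame,
    p_cut: float = 0.05,
    rp_cut: float = 0.05,
    if_cut: float = 100.0,
    use_fdr: bool = False,
    ties: str = "average",
) -> pd.DataFrame:
    """Join attractor statistics with network degrees and flag core pathways.

    ``pathway_table`` must carry ``p_value`` and ``fdr`` (attractor
    stage); ``score_table`` must carry ``bg_degree``, ``test_degree``
    and ``score``. Pathways missing from the score table get degree 0.
    ``use_fdr=True`` selects on the BH-adjusted P value instead of the
    raw one (the raw value is the default reading of the printed
    selection rule).
    """
    ids = pathway_table.index
    card = pd.DataFrame(index=ids.copy())
    card["p_value"] = pathway_table["p_value"]
    card["fdr"] = pathway_table["fdr"]
    for col in ("bg_degree", "test_degree"):
        card[col] = score_table[col].reindex(ids).fillna(0).astype(int)
    card["score"] = score_table["score"].reindex(ids).fillna(0.0)

    sel_p = card["fdr"] if use_fdr else card["p_value"]
    rp = rank_product(sel_p.to_numpy(), card["test_degree"].to_numpy(), ties=ties)
    card[["rank_inter", "rank_outer", "rp"]] = rp.to_numpy()
    card["impact"] = impact_factor(card["test_degree"].to_numpy(), sel_p.to_numpy())

    card["pass_p"] = sel_p < p_cut
    card["pass_rp"] = card["rp"] < rp_cut
    card["pass_if"] = card["impact"] > if_cut
    card["is_core"] = card["pass_p"] & card["pass_rp"] & card["pass_if"]
    return card[SCORECARD_COLUMNS]


def select_core(scorecard: pd.DataFrame) -> list[str]:
    """Core pathway ids, sorted by RP ascending."""
    core = scorecard.loc[scorecard["is_core"]]
    return list(core.sort_values("rp").index)


def write_scorecard(scorecard: pd.DataFrame, path) -> None:
    scorecard.to_csv(path, sep="\t", float_format="%.10g")
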