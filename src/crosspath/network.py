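"""Pathway cross-talk network (PCN) construction.

A PCN is a graph whose nodes are pathways and whose edges ("cross
talks") are pathway pairs supported by more than ``weight_threshold``
distinct PPI gene pairs whose endpoints fall one in each pathway.

Two networks are built per study: the *background* PCN from the full
PPI edge list, and the *disease* PCN from the dynamically filtered edge
set — PPIs whose within-group Spearman correlation changes by at least
``delta_threshold`` between the two groups (|Δr| = |r₁ − r₂| ≥ 0.5), or
whose two endpoint genes are both DEGs. The pathway score (degree
ratio) compares a pathway's degree in the two networks:

    score = degree in disease network / degree in background network.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError
from .io import ExpressionStudy, GeneSetCollection, PPIEdgeTable

logger = logging.getLogger(__name__)

EDGE_COLUMNS = ["gene_i", "gene_j", "r_group1", "r_group2", "mean_r", "delta_r"]


# ---------------------------------------------------------------------------
# per-edge Spearman correlation, per group
# ---------------------------------------------------------------------------

def edge_spearman(study: ExpressionStudy, ppi: PPIEdgeTable | Iterable[tuple[str, str]]
                  ) -> pd.DataFrame:
    """Within-group Spearman correlation for every PPI edge.

    For each edge, ranks are assigned within each group's samples
    (average ranks on ties) and the rank-Pearson coefficient is
    computed per group; ``mean_r = (r1 + r2)/2`` and
    ``delta_r = r1 − r2``. Edges with an endpoint missing from the
    matrix, or with a gene constant within a group (undefined
    coefficient), are excluded with logged counts.
    """
    g1, g2 = study.require_two_groups()
    for g in (g1, g2):
        if len(study.samples_in(g)) < 3:
            raise ContractError(f"group {g!r} needs ≥ 3 samples for Spearman correlation")

    edges = list(ppi)
    present = set(study.gene_ids)
    kept = [(u, v) for u, v in edges if u in present and v in present]
    n_missing = len(edges) - len(kept)
    if n_missing:
        logger.info("skipped %d edge(s) with endpoint gene(s) absent from the matrix", n_missing)
    if not kept:
        return pd.DataFrame(columns=EDGE_COLUMNS)

    genes = sorted({g for e in kept for g in e})
    pos = {g: i for i, g in enumerate(genes)}
    iu = np.array([pos[u] for u, _ in kept])
    iv = np.array([pos[v] for _, v in kept])

    rs = []
    defined = np.ones(len(kept), dtype=bool)
    for group in (g1, g2):
        sub = study.values.loc[genes, study.samples_in(group)].to_numpy(dtype=float)
        ranks = stats.rankdata(sub, axis=1)
        centered = ranks - ranks.mean(axis=1, keepdims=True)
        norm = np.sqrt((centered**2).sum(axis=1))
        num = (centered[iu] * centered[iv]).sum(axis=1)
        den = norm[iu] * norm[iv]
        ok = den > 0
        defined &= ok
        r = np.full(len(kept), np.nan)
        r[ok] = num[ok] / den[ok]
        rs.append(np.clip(r, -1.0, 1.0))

    n_const = int((~defined).sum())
    if n_const:
        logger.warning("excluded %d edge(s) with a constant gene within a group", n_const)

    r1, r2 = rs[0][defined], rs[1][defined]
    pairs = [e for e, ok in zip(kept, defined) if ok]
    return pd.DataFrame(
        {
            "gene_i": [u for u, _ in pairs],
            "gene_j": [v for _, v in pairs],
            "r_group1": r1,
            "r_group2": r2,
            "mean_r": (r1 + r2) / 2.0,
            "delta_r": r1 - r2,
        }
    )


def filter_dynamic_edges(corr: pd.DataFrame, deg_ids: set[str],
                         delta_threshold: float = 0.5) -> pd.DataFrame:
    """Keep edges with |Δr| ≥ threshold (inclusive) or both endpoints DEGs.

    Adds a ``retained_reason`` column (``delta`` or ``deg_pair``; the
    correlation criterion takes precedence when both hold).
    """
    by_delta = np.abs(corr["delta_r"].to_numpy()) >= delta_threshold
    both_deg = corr["gene_i"].isin(deg_ids).to_numpy() & corr["gene_j"].isin(deg_ids).to_numpy()
    keep = by_delta | both_deg
    out = corr.loc[keep].copy()
    out["retained_reason"] = np.where(by_delta[keep], "delta", "deg_pair")
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# pathway-level network
# ---------------------------------------------------------------------------

@dataclass
class CrosstalkNetwork:
    """Pathway graph with per-edge PPI-support weights."""

    graph: nx.Graph
    weight_threshold: int = 5

    @property
    def degree_of(self) -> dict[str, int]:
        return dict(self.graph.degree())

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes())

    def edge_table(self) -> pd.DataFrame:
        rows = [(a, b, d["weight"]) for a, b, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["pathway_a", "pathway_b", "weight"])


def build_crosstalk(
    edges: PPIEdgeTable | pd.DataFrame | Iterable[tuple[str, str]],
    sets: GeneSetCollection,
    weight_threshold: int = 5,
    count: str = "distinct_pairs",
) -> CrosstalkNetwork:
    """Lift gene-pair edges to a pathway cross-talk network.

    For each unordered pathway pair (A, B), A ≠ B, the weight is the
    number of distinct input gene pairs (u, v) with one endpoint in
    each pathway; a gene pair spanning overlapping pathways counts once
    for every such pathway pair, and (A, A) is never formed. Pairs with
    weight strictly greater than ``weight_threshold`` become edges;
    every pathway is a node (degree 0 when isolated).

    ``count="multiset"`` counts every input record instead of distinct
    unordered gene pairs (an alternative reading of per-interaction
    weights for edge lists carrying repeated records).
    """
    if len(sets) == 0:
        raise ContractError("gene-set collection is empty")
    if count not in ("distinct_pairs", "multiset"):
        raise ContractError(f"unknown count mode {count!r}")

    if isinstance(edges, pd.DataFrame):
        pairs = list(zip(edges["gene_i"], edges["gene_j"]))
    else:
        pairs = list(edges)
    if count == "distinct_pairs":
        pairs = list({(u, v) if u < v else (v, u) for u, v in pairs})

    membership = sets.membership()
    weights: dict[tuple[str, str], int] = {}
    for u, v in pairs:
        pu = membership.get(u)
        pv = membership.get(v)
        if not pu or not pv:
            continue
        seen = {(a, b) if a < b else (b, a) for a in pu for b in pv if a != b}
        for key in seen:
            weights[key] = weights.get(key, 0) + 1

    graph = nx.Graph()
    graph.add_nodes_from(sets.ids)
    for (a, b), w in weights.items():
        if w > weight_threshold:
            graph.add_edge(a, b, weight=w)
    logger.info("cross-talk network: %d/%d pathway pairs kept (weight > %d)",
                graph.number_of_edges(), len(weights), weight_threshold)
    return CrosstalkNetwork(graph, weight_threshold)


def crosstalk_oracle(pairs: Iterable[tuple[str, str]], sets: GeneSetCollection,
                     weight_threshold: int = 5) -> dict[tuple[str, str], int]:
    """Exhaustive double-loop pathway-pair counting (reference, O(P²·E)).

    Returns kept pathway-pair → weight; intended for cross-checking
    :func:`build_crosstalk` on small instances.
    """
    uniq = {(u, v) if u < v else (v, u) for u, v in pairs}
    out: dict[tuple[str, str], int] = {}
    for a, b in itertools.combinations(sorted(sets.ids), 2):
        ga, gb = set(sets[a].genes), set(sets[b].genes)
        w = sum(1 for u, v in uniq
                if (u in ga and v in gb) or (u in gb and v in ga))
        if w > weight_threshold:
            out[(a, b)] = w
    return out


# ---------------------------------------------------------------------------
# degrees and pathway scores
# ---------------------------------------------------------------------------

def pathway_scores(background: CrosstalkNetwork, disease: CrosstalkNetwork) -> pd.DataFrame:
    """Degree-ratio table over the union of both networks' nodes."""
    bg, test = background.degree_of, disease.degree_of
    ids = sorted(set(bg) | set(test))
    return pathway_scores_from_degrees(
        {p: bg.get(p, 0) for p in ids}, {p: test.get(p, 0) for p in ids}
    )


def pathway_scores_from_degrees(bg_degree: dict[str, int],
                                test_degree: dict[str, int]) -> pd.DataFrame:
    """Pathway score = disease-network degree / background-network degree.

    Pathways with background degree 0 get score 0 and a ``bg_zero``
    flag. Accepts plain degree maps so printed degree tables can be
    re-scored directly.
    """
    ids = sorted(set(bg_degree) | set(test_degree))
    bg = np.array([bg_degree.get(p, 0) for p in ids], dtype=float)
    test = np.array([test_degree.get(p, 0) for p in ids], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(bg > 0, test / np.where(bg > 0, bg, 1.0), 0.0)
    return pd.DataFrame(
        {"bg_degree": bg.astype(int), "test_degree": test.astype(int),
         "score": score, "bg_zero": bg == 0},
        index=pd.Index(ids, name="pathway_id"),
    )
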