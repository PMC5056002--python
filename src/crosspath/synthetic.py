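"""Synthetic two-group expression studies with known planted structure.

A generated bundle emulates the inputs of a disease-vs-normal pathway
study: a log2-scale expression matrix for two sample groups, a
collection of pathway gene sets, and a PPI edge list. Known structure
is planted so every downstream stage can be verified against truth:

* a subset of pathways is *differential*: a fraction
  (``deg_enrichment``) of their member genes receive an additive group
  shift of magnitude ``deg_log_fc`` (random sign per gene) — the
  planted DEGs. A ``deg_hub_frac`` fraction of the planted DEGs act
  as disease-module *hub* genes; hubs are exclusive members of the
  planted pathways (they are swapped out of any non-planted pathway
  that sampled them), the way driver genes anchor a disease module;
* a fraction of PPI edges is *rewired*: the pair shares a latent
  factor whose loading sign flips in the test group, so the pair is
  positively rank-correlated in one group and negatively in the other
  (expected |Δr| well above 0.5 at the default loading);
* a fraction of PPI edges is placed between planted DEG pairs
  (``frac_deg_ppi``), emulating the dense interconnection of a disease
  module — these drive the disease-network degrees of the planted
  pathways. As in scale-free interactomes the module is organised
  around its hubs: every disease-module edge joins a hub to another
  planted DEG;
* remaining edges are uniform gene pairs; shared latent factors (same
  sign in both groups) are assigned greedily to edges whose endpoints
  carry no other factor, so those pairs are co-expressed with a stable
  correlation in both groups.

Everything is driven by one integer seed through named substreams, so
identical configurations produce byte-identical bundles on disk.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .errors import ConfigurationError
from .io import ExpressionStudy, GeneSet, GeneSetCollection, PPIEdgeTable

#: substream order for per-component seed derivation — never reorder
_STREAMS = ("pathways", "degs", "baseline", "noise", "ppi", "latent")


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Parameters of a synthetic study bundle.

    Defaults describe the shipped demo study: a moderately sized
    two-group cohort (40 vs 40 samples over 2000 genes) with 150
    overlapping pathways of 40–70 genes, of which 4% are planted as
    differential with a 3-log2-unit shift on 80% of their members, and
    a 12000-edge PPI list in which 2% of edges are rewired between
    groups and 40% form a hub-centred disease module over the planted
    DEGs.
    """

    seed: int = 0
    n_genes: int = 2000
    n_samples_per_group: tuple[int, int] = (40, 40)
    n_pathways: int = 150
    pathway_size_range: tuple[int, int] = (40, 70)
    frac_differential_pathways: float = 0.04
    deg_log_fc: float = 3.0
    noise_sd: float = 0.5
    ppi_edges: int = 12000
    frac_rewired_edges: float = 0.02
    # placement knobs (not part of the minimal surface, documented defaults)
    deg_enrichment: float = 0.8
    frac_deg_ppi: float = 0.4
    deg_hub_frac: float = 0.2
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    latent_loading: float | None = None   # default: 2 × noise_sd
    group_labels: tuple[str, str] = ("normal", "disease")

    def validate(self) -> None:
        def positive(name: str, value) -> None:
            if not value > 0:
                raise ConfigurationError(name, f"must be positive, got {value}")

        def fraction(name: str, value) -> None:
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(name, f"must lie in [0, 1], got {value}")

        positive("n_genes", self.n_genes)
        positive("n_pathways", self.n_pathways)
        positive("ppi_edges", self.ppi_edges)
        for n in self.n_samples_per_group:
            positive("n_samples_per_group", n)
        fraction("frac_differential_pathways", self.frac_differential_pathways)
        fraction("frac_rewired_edges", self.frac_rewired_edges)
        fraction("deg_enrichment", self.deg_enrichment)
        fraction("frac_deg_ppi", self.frac_deg_ppi)
        fraction("deg_hub_frac", self.deg_hub_frac)
        positive("deg_log_fc", self.deg_log_fc)
        positive("noise_sd", self.noise_sd)
        lo, hi = self.pathway_size_range
        if lo < 2:
            raise ConfigurationError("pathway_size_range", f"min must be ≥ 2, got {lo}")
        if hi > self.n_genes:
            raise ConfigurationError(
                "pathway_size_range", f"max {hi} exceeds n_genes {self.n_genes}")
        if lo > hi:
            raise ConfigurationError("pathway_size_range", f"min {lo} > max {hi}")
        n_rewired = round(self.frac_rewired_edges * self.ppi_edges)
        if 2 * n_rewired > self.n_genes:
            raise ConfigurationError(
                "frac_rewired_edges",
                f"{n_rewired} rewired edges need {2 * n_rewired} distinct genes, "
                f"but n_genes is {self.n_genes}")
        if len(self.group_labels) != 2 or self.group_labels[0] == self.group_labels[1]:
            raise ConfigurationError("group_labels", "need two distinct labels")

    @property
    def loading(self) -> float:
        # 2σ loading on a unit-variance factor gives within-group
        # Spearman ≈ 4σ²/(4σ²+σ²) = 0.8 for a dedicated edge
        return 2.0 * self.noise_sd if self.latent_loading is None else self.latent_loading

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class StudyTruth:
    """Planted structure of a synthetic bundle."""

    planted_degs: list[str] = field(default_factory=list)
    planted_pathways: list[str] = field(default_factory=list)
    rewired_edges: list[tuple[str, str]] = field(default_factory=list)
    deg_signs: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "planted_degs": self.planted_degs,
            "planted_pathways": self.planted_pathways,
            "rewired_edges": [list(e) for e in self.rewired_edges],
            "deg_signs": self.deg_signs,
        }


@dataclass
class SyntheticStudy:
    config: SyntheticStudyConfig
    expression: ExpressionStudy
    gene_sets: GeneSetCollection
    ppi: PPIEdgeTable
    truth: StudyTruth


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(s) for name, s in zip(_STREAMS, children)}


def generate_study(config: SyntheticStudyConfig) -> SyntheticStudy:
    """Generate a study bundle with planted truth; deterministic per seed."""
    config.validate()
    rngs = _substreams(config.seed)

    gene_ids = np.array([f"G{i:05d}" for i in range(config.n_genes)])
    n1, n2 = config.n_samples_per_group
    sample_ids = [f"S{i:03d}" for i in range(n1 + n2)]
    groups = pd.Series(
        [config.group_labels[0]] * n1 + [config.group_labels[1]] * n2,
        index=sample_ids,
    )
    test_cols = np.arange(n1, n1 + n2)

    # --- pathways ---------------------------------------------------------
    rng = rngs["pathways"]
    lo, hi = config.pathway_size_range
    members: list[np.ndarray] = []
    for p in range(config.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        members.append(rng.choice(config.n_genes, size=size, replace=False))
    n_diff = round(config.frac_differential_pathways * config.n_pathways)
    planted_pw = np.sort(rng.choice(config.n_pathways, size=n_diff, replace=False))

    # --- planted DEGs and disease-module hubs -----------------------------
    rng = rngs["degs"]
    truth = StudyTruth(planted_pathways=[f"PW{p:03d}" for p in planted_pw])
    deg_idx = np.array([], dtype=int)
    hub_idx = np.array([], dtype=int)
    if n_diff:
        union = np.unique(np.concatenate([members[p] for p in planted_pw]))
        n_deg = round(config.deg_enrichment * union.size)
        deg_idx = np.sort(rng.choice(union, size=n_deg, replace=False))
        signs = rng.choice([-1, 1], size=n_deg)
        truth.planted_degs = [str(g) for g in gene_ids[deg_idx]]
        truth.deg_signs = {str(g): int(s) for g, s in zip(gene_ids[deg_idx], signs)}
        n_hubs = max(1, round(config.deg_hub_frac * n_deg))
        hub_idx = np.sort(rng.choice(deg_idx, size=n_hubs, replace=False))
        # hubs anchor the disease module: evict them from null pathways,
        # substituting a fresh gene so sizes are preserved
        hubs = set(hub_idx.tolist())
        planted_set = set(planted_pw.tolist())
        for p in range(config.n_pathways):
            if p in planted_set or not hubs.intersection(members[p].tolist()):
                continue
            current = set(members[p].tolist())
            keep = [g for g in members[p].tolist() if g not in hubs]
            n_replace = len(members[p]) - len(keep)
            pool = np.setdiff1d(np.arange(config.n_genes),
                                np.fromiter(current | hubs, dtype=int))
            keep.extend(rng.choice(pool, size=n_replace, replace=False).tolist())
            members[p] = np.array(keep, dtype=int)

    sets = GeneSetCollection()
    for p in range(config.n_pathways):
        sets.add(GeneSet(f"PW{p:03d}", f"synthetic pathway {p}",
                         tuple(gene_ids[np.sort(members[p])])))

    # --- expression matrix ------------------------------------------------
    baseline = rngs["baseline"].normal(config.baseline_mean, config.baseline_sd,
                                       size=config.n_genes)
    values = baseline[:, None] + rngs["noise"].normal(
        0.0, config.noise_sd, size=(config.n_genes, n1 + n2))
    if deg_idx.size:
        shift = np.array([truth.deg_signs[str(g)] for g in gene_ids[deg_idx]])
        values[np.ix_(deg_idx, test_cols)] += shift[:, None] * config.deg_log_fc

    # --- PPI edge list ----------------------------------------------------
    rng = rngs["ppi"]
    n_rewired = round(config.frac_rewired_edges * config.ppi_edges)
    planted_genes = (np.unique(np.concatenate([members[p] for p in planted_pw]))
                     if n_diff else np.array([], dtype=int))

    rewired = _sample_rewired(rng, config, planted_genes)
    n_deg_ppi = round(config.frac_deg_ppi * config.ppi_edges) if deg_idx.size >= 2 else 0
    existing = {tuple(sorted(e)) for e in rewired}
    deg_pairs = _sample_hub_pairs(rng, deg_idx, hub_idx, n_deg_ppi, existing)
    n_uniform = config.ppi_edges - len(rewired) - len(deg_pairs)
    uniform = _sample_pairs(rng, np.arange(config.n_genes), max(n_uniform, 0), existing)
    all_edges = rewired + deg_pairs + uniform

    # --- latent co-expression factors -------------------------------------
    rng = rngs["latent"]
    lam = config.loading
    loaded: set[int] = set()
    for u, v in rewired:
        z = rng.normal(0.0, 1.0, size=n1 + n2)
        values[u] += lam * z
        values[v, :n1] += lam * z[:n1]
        values[v, n1:] -= lam * z[n1:]
        loaded.update((u, v))
    for u, v in deg_pairs + uniform:
        if u in loaded or v in loaded:
            continue
        z = rng.normal(0.0, 1.0, size=n1 + n2)
        values[u] += lam * z
        values[v] += lam * z
        loaded.update((u, v))

    truth.rewired_edges = [(str(gene_ids[u]), str(gene_ids[v])) for u, v in rewired]
    ppi = PPIEdgeTable.from_pairs(
        (str(gene_ids[u]), str(gene_ids[v])) for u, v in all_edges)

    expression = ExpressionStudy(
        pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                     columns=sample_ids),
        groups, config.group_labels,
    )
    return SyntheticStudy(config, expression, sets, ppi, truth)


def _sample_rewired(rng: np.random.Generator, config: SyntheticStudyConfig,
                    planted_genes: np.ndarray) -> list[tuple[int, int]]:
    """Disjoint gene pairs for rewired edges, anchored in planted pathways.

    Endpoints are drawn without replacement so each rewired pair owns
    its latent factor outright (|Δr| is then ≈ 2·loading²/(loading²+σ²)
    in expectation, not diluted by other factors). The first endpoint
    comes from planted-pathway genes while they last.
    """
    n_rewired = round(config.frac_rewired_edges * config.ppi_edges)
    if n_rewired == 0:
        return []
    anchors = rng.permutation(planted_genes) if planted_genes.size else np.array([], dtype=int)
    others = rng.permutation(np.setdiff1d(np.arange(config.n_genes), planted_genes))
    pool = np.concatenate([anchors, others])
    first = pool[:n_rewired]
    rest = pool[n_rewired:]
    partners = rng.permutation(rest)[:n_rewired]
    return list(zip(first.tolist(), partners.tolist()))


def _sample_hub_pairs(rng: np.random.Generator, deg_idx: np.ndarray,
                      hubs: np.ndarray, n: int,
                      existing: set[tuple[int, int]]) -> list[tuple[int, int]]:
    """Disease-module edges: each joins a hub DEG to another planted DEG."""
    if n <= 0 or deg_idx.size < 2 or hubs.size == 0:
        return []
    n_hubs = hubs.size
    out: list[tuple[int, int]] = []
    max_pairs = n_hubs * deg_idx.size - n_hubs - n_hubs * (n_hubs - 1) // 2
    n = min(n, max_pairs)
    attempts = 0
    while len(out) < n and attempts < 50 * n + 1000:
        m = max(2 * (n - len(out)), 16)
        us = hubs[rng.integers(0, n_hubs, size=m)]
        vs = deg_idx[rng.integers(0, deg_idx.size, size=m)]
        for u, v in zip(us.tolist(), vs.tolist()):
            if u == v or len(out) >= n:
                continue
            key = (u, v) if u < v else (v, u)
            if key in existing:
                continue
            existing.add(key)
            out.append(key)
        attempts += m
    return out


def _sample_pairs(rng: np.random.Generator, pool: np.ndarray, n: int,
                  existing: set[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sample n distinct unordered pairs from pool, avoiding *existing*."""
    out: list[tuple[int, int]] = []
    if n <= 0 or pool.size < 2:
        return out
    max_pairs = pool.size * (pool.size - 1) // 2
    n = min(n, max_pairs - len({e for e in existing
                                if e[0] in pool and e[1] in pool}))
    attempts = 0
    while len(out) < n and attempts < 50 * n + 1000:
        m = max(2 * (n - len(out)), 16)
        us = pool[rng.integers(0, pool.size, size=m)]
        vs = pool[rng.integers(0, pool.size, size=m)]
        for u, v in zip(us.tolist(), vs.tolist()):
            if u == v or len(out) >= n:
                continue
            key = (u, v) if u < v else (v, u)
            if key in existing:
                continue
            existing.add(key)
            out.append(key)
        attempts += m
    return out


def write_bundle(study: SyntheticStudy, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle's five files; returns name → path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "labels": outdir / "labels.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "edges": outdir / "ppi_edges.tsv",
        "truth": outdir / "truth.json",
    }
    io.write_expression(study.expression, paths["expression"], paths["labels"])
    io.write_gmt(study.gene_sets, paths["gene_sets"])
    io.write_edges(study.ppi, paths["edges"])
    io.write_truth(study.truth.to_dict(), paths["truth"])
    return paths
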