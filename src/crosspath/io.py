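"""Containers and readers/writers for the pipeline's file formats.

Three on-disk formats are supported, all plain text:

* expression matrix — TSV, genes in rows, one header row of sample ids,
  log-scale intensities; group labels in a separate two-column TSV
  (sample_id, group);
* gene sets — standard GMT (set id, description, tab-separated member
  gene ids);
* protein–protein interactions — two-column edge list of gene ids.

Identifiers are opaque, case-sensitive strings throughout; no id mapping
is performed. Genes that appear in gene sets or edges but not in the
expression matrix are kept in their containers and ignored (with logged
counts) by downstream statistics, mirroring the coverage gap between
pathway/interaction databases and any one array platform.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import ContractError, FormatError

logger = logging.getLogger(__name__)

#: significant digits preserved by the TSV writers (round-trip contract)
FLOAT_FORMAT = "%.10g"


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionStudy:
    """A log-expression matrix plus a sample→group mapping.

    Parameters
    ----------
    values
        genes × samples DataFrame of log-scale intensities.
    groups
        Series mapping sample id → group label. Exactly two groups are
        used downstream; ``group_order[0]`` is the reference (normal)
        group and ``group_order[1]`` the test (disease) group.
    group_order
        Group labels in reference-first order. Defaults to order of
        first appearance in ``groups``.
    """

    values: pd.DataFrame
    groups: pd.Series
    group_order: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.groups = pd.Series(self.groups)
        if not self.group_order:
            self.group_order = tuple(pd.unique(self.groups))
        self.validate()

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        genes = self.values.index
        samples = self.values.columns
        dup = genes[genes.duplicated()]
        if len(dup):
            raise FormatError(f"duplicate gene id {dup[0]!r}")
        dup = samples[samples.duplicated()]
        if len(dup):
            raise FormatError(f"duplicate sample id {dup[0]!r}")
        missing = [s for s in samples if s not in self.groups.index]
        if missing:
            raise FormatError(f"sample {missing[0]!r} has no group label")
        counts = self.groups.loc[list(samples)].value_counts()
        if set(self.group_order) != set(counts.index):
            raise FormatError(
                f"group_order {self.group_order} does not match labels "
                f"{tuple(counts.index)}"
            )
        small = counts[counts < 2]
        if len(small):
            raise FormatError(
                f"group {small.index[0]!r} has {int(small.iloc[0])} sample(s); ≥2 required"
            )

    # -- accessors ---------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_groups(self) -> int:
        return len(self.group_order)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]

    def replicates(self) -> dict[str, int]:
        """Number of samples per group (the r_k of the ANOVA layout)."""
        return {g: len(self.samples_in(g)) for g in self.group_order}

    def group_matrix(self, group: str) -> np.ndarray:
        """genes × replicates array for one group."""
        return self.values[self.samples_in(group)].to_numpy(dtype=float)

    def require_two_groups(self) -> tuple[str, str]:
        if self.n_groups != 2:
            raise ContractError(
                f"exactly two groups required, found {self.n_groups}: {self.group_order}"
            )
        return self.group_order[0], self.group_order[1]


@dataclass(frozen=True)
class GeneSet:
    id: str
    name: str
    genes: tuple[str, ...]


@dataclass
class GeneSetCollection:
    """Pathway id → member genes (GMT semantics)."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets.values())

    def __getitem__(self, set_id: str) -> GeneSet:
        return self.sets[set_id]

    def __contains__(self, set_id: str) -> bool:
        return set_id in self.sets

    @property
    def ids(self) -> list[str]:
        return list(self.sets)

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.id in self.sets:
            raise FormatError(f"duplicate pathway id {gene_set.id!r}")
        self.sets[gene_set.id] = gene_set

    def membership(self) -> dict[str, set[str]]:
        """gene → set of pathway ids containing it."""
        out: dict[str, set[str]] = {}
        for gs in self:
            for g in gs.genes:
                out.setdefault(g, set()).add(gs.id)
        return out

    def drop_empty(self, universe: Iterable[str]) -> tuple["GeneSetCollection", int]:
        """Drop sets sharing no genes with *universe*; return (kept, n_removed)."""
        uni = set(universe)
        kept = {sid: gs for sid, gs in self.sets.items() if uni.intersection(gs.genes)}
        removed = len(self.sets) - len(kept)
        if removed:
            logger.info("dropped %d gene set(s) with no gene in the matrix", removed)
        return GeneSetCollection(kept), removed


@dataclass
class PPIEdgeTable:
    """Deduplicated, unordered gene-pair edges (no self-edges)."""

    edges: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for u, v in self.edges:
            if u == v:
                raise FormatError(f"self-edge {u!r}")
        canon = [tuple(sorted(e)) for e in self.edges]
        if len(set(canon)) != len(canon):
            raise FormatError("duplicate unordered gene pair in edge table")

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.edges)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "PPIEdgeTable":
        """Build a table, silently removing self-edges and duplicates (counts logged)."""
        seen: set[tuple[str, str]] = set()
        edges: list[tuple[str, str]] = []
        n_self = n_dup = 0
        for u, v in pairs:
            if u == v:
                n_self += 1
                continue
            key = (u, v) if u < v else (v, u)
            if key in seen:
                n_dup += 1
                continue
            seen.add(key)
            edges.append(key)
        if n_self or n_dup:
            logger.info("edge table: removed %d self-edge(s), %d duplicate(s)", n_self, n_dup)
        return cls(edges)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_expression(matrix_path: str | Path, labels_path: str | Path) -> ExpressionStudy:
    """Read a genes × samples TSV and a two-column sample→group TSV.

    Genes with any missing value are dropped (count logged). Duplicate
    ids, dimension mismatches and groups with <2 samples raise
    :class:`FormatError`.
    """
    matrix_path, labels_path = Path(matrix_path), Path(labels_path)
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    dup = values.index[values.index.duplicated()]
    if len(dup):
        raise FormatError(f"duplicate gene id {dup[0]!r}", path=str(matrix_path))

    labels: dict[str, str] = {}
    order: list[str] = []
    with open(labels_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise FormatError(
                    f"expected 2 tab-separated fields, found {len(parts)}",
                    path=str(labels_path), line=lineno,
                )
            sample, group = parts
            if sample in labels:
                raise FormatError(
                    f"duplicate sample id {sample!r}", path=str(labels_path), line=lineno
                )
            labels[sample] = group
            if group not in order:
                order.append(group)

    n_na = int(values.isna().any(axis=1).sum())
    if n_na:
        logger.info("dropping %d gene(s) with missing values", n_na)
        values = values.dropna(axis=0)
    try:
        return ExpressionStudy(values, pd.Series(labels), tuple(order))
    except FormatError as exc:
        raise FormatError(str(exc), path=str(matrix_path)) from None


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a standard GMT file (id, description, ≥1 gene per line)."""
    collection = GeneSetCollection()
    path = Path(path)
    n = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"GMT line needs ≥3 tab-separated fields, found {len(parts)}",
                    path=str(path), line=lineno,
                )
            sid, name, genes = parts[0], parts[1], tuple(g for g in parts[2:] if g)
            if not genes:
                raise FormatError("gene set has no genes", path=str(path), line=lineno)
            try:
                collection.add(GeneSet(sid, name, genes))
            except FormatError as exc:
                raise FormatError(str(exc), path=str(path), line=lineno) from None
            n += 1
    if n == 0:
        logger.warning("GMT file %s is empty", path)
    return collection


def read_edges(path: str | Path) -> PPIEdgeTable:
    """Read a two-column gene-pair edge list (whitespace/tab separated).

    Self-edges and duplicate unordered pairs are removed with logged
    counts; malformed lines raise :class:`FormatError`.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(
                    f"expected 2 fields, found {len(parts)}", path=str(path), line=lineno
                )
            pairs.append((parts[0], parts[1]))
    return PPIEdgeTable.from_pairs(pairs)


def read_truth(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_expression(study: ExpressionStudy, matrix_path: str | Path,
                     labels_path: str | Path) -> None:
    study.values.to_csv(matrix_path, sep="\t", float_format=FLOAT_FORMAT,
                        index_label="gene_id")
    with open(labels_path, "w") as fh:
        for s in study.sample_ids:
            fh.write(f"{s}\t{study.groups[s]}\n")


def write_gmt(sets: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join((gs.id, gs.name, *gs.genes)) + "\n")


def write_edges(edges: PPIEdgeTable | Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v in edges:
            fh.write(f"{u}\t{v}\n")


def write_truth(truth: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(dict(truth), fh, indent=1, sort_keys=True)
        fh.write("\n")
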