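"""Domain types and file I/O for the miRNA localisation pipeline.

The canonical miRNA index space is the FASTA file order; every network,
feature or label matrix that references miRNAs is aligned to that order
(missing miRNAs receive all-zero rows, extra rows are an error).

External formats are deliberately plain text: FASTA for sequences,
two-column TSV edge lists for bipartite associations, child<TAB>parent TSV
for the disease DAG, and header-ed TSV matrices (row id in the first
column, ``%.10g`` numeric formatting so write→read round-trips bit-exactly).
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The seven subcellular compartments, in canonical column order.
COMPARTMENTS: tuple[str, ...] = (
    "cytoplasm",
    "exosome",
    "nucleolus",
    "nucleus",
    "extracellular vesicle",
    "microvesicle",
    "mitochondrion",
)

ENTITY_KINDS = ("disease", "drug", "mrna")

_RNA_ALPHABET = frozenset("ACGU")


class DataModelError(ValueError):
    """Raised for any violated format or invariant contract."""


@dataclass(frozen=True)
class MirnaSet:
    """An ordered universe of miRNAs with their RNA sequences."""

    ids: tuple[str, ...]
    sequences: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.ids:
            raise DataModelError("MirnaSet must contain at least one miRNA")
        if len(set(self.ids)) != len(self.ids):
            raise DataModelError("duplicate miRNA ids")
        for mid in self.ids:
            seq = self.sequences.get(mid, "")
            if not seq:
                raise DataModelError(f"empty sequence for miRNA {mid!r}")
            bad = set(seq) - _RNA_ALPHABET
            if bad:
                raise DataModelError(
                    f"sequence for {mid!r} contains non-RNA symbols {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class AssociationNetwork:
    """Binary bipartite adjacency between miRNAs and one entity class."""

    mirna_ids: tuple[str, ...]
    entity_ids: tuple[str, ...]
    entity_kind: str
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        if self.entity_kind not in ENTITY_KINDS:
            raise DataModelError(f"unknown entity kind {self.entity_kind!r}")
        adj = np.asarray(self.adjacency)
        if adj.shape != (len(self.mirna_ids), len(self.entity_ids)):
            raise DataModelError(
                f"adjacency shape {adj.shape} does not match id lists "
                f"({len(self.mirna_ids)}x{len(self.entity_ids)})"
            )
        if adj.size and not np.isin(adj, (0, 1)).all():
            raise DataModelError("adjacency entries must be 0 or 1")
        if len(set(self.mirna_ids)) != len(self.mirna_ids):
            raise DataModelError("duplicate miRNA ids in network")
        if len(set(self.entity_ids)) != len(self.entity_ids):
            raise DataModelError("duplicate entity ids in network")
        object.__setattr__(self, "adjacency", adj.astype(np.int8))

    def align_to(self, mirna_ids: Sequence[str]) -> "AssociationNetwork":
        """Reorder rows to ``mirna_ids``; miRNAs absent here get zero rows."""
        pos = {m: i for i, m in enumerate(self.mirna_ids)}
        extra = set(self.mirna_ids) - set(mirna_ids)
        if extra:
            raise DataModelError(
                f"network references miRNAs outside the universe: {sorted(extra)[:5]}"
            )
        out = np.zeros((len(mirna_ids), len(self.entity_ids)), dtype=np.int8)
        for i, m in enumerate(mirna_ids):
            if m in pos:
                out[i] = self.adjacency[pos[m]]
        return AssociationNetwork(tuple(mirna_ids), self.entity_ids, self.entity_kind, out)


@dataclass(frozen=True)
class DiseaseDAG:
    """A rooted-up disease hierarchy given as (child, parent) edges."""

    nodes: frozenset[str]
    parent_edges: frozenset[tuple[str, str]]
    _parents: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        parents: dict[str, set[str]] = {n: set() for n in self.nodes}
        for child, parent in self.parent_edges:
            if child == parent:
                raise DataModelError(f"self-loop on {child!r}")
            if child not in self.nodes or parent not in self.nodes:
                raise DataModelError(f"edge ({child!r},{parent!r}) has endpoint outside node set")
            parents[child].add(parent)
        cycle = _find_cycle(parents)
        if cycle:
            raise DataModelError(f"cycle in disease DAG: {' -> '.join(cycle)}")
        object.__setattr__(self, "_parents", {k: frozenset(v) for k, v in parents.items()})

    def parents_of(self, node: str) -> frozenset[str]:
        return self._parents[node]

    def ancestor_layers(self, node: str) -> dict[str, int]:
        """Map each ancestor (and the node itself) to its shortest child→parent distance."""
        if node not in self.nodes:
            raise DataModelError(f"unknown disease {node!r}")
        dist = {node: 0}
        queue = deque([node])
        while queue:
            cur = queue.popleft()
            for par in self._parents[cur]:
                if par not in dist:
                    dist[par] = dist[cur] + 1
                    queue.append(par)
        return dist

    @property
    def roots(self) -> frozenset[str]:
        return frozenset(n for n in self.nodes if not self._parents[n])


def _find_cycle(parents: Mapping[str, set[str]]) -> list[str] | None:
    WHITE, GREY, BLACK = 0, 1, 2
    colour = {n: WHITE for n in parents}
    stack_trace: list[str] = []

    def visit(n: str) -> list[str] | None:
        colour[n] = GREY
        stack_trace.append(n)
        for p in parents[n]:
            if colour[p] == GREY:
                i = stack_trace.index(p)
                return stack_trace[i:] + [p]
            if colour[p] == WHITE:
                found = visit(p)
                if found:
                    return found
        stack_trace.pop()
        colour[n] = BLACK
        return None

    for n in parents:
        if colour[n] == WHITE:
            found = visit(n)
            if found:
                return found
    return None


@dataclass(frozen=True)
class LocalizationMatrix:
    """Entity × 7 binary localisation labels in canonical compartment order."""

    entity_ids: tuple[str, ...]
    labels: np.ndarray
    compartments: tuple[str, ...] = COMPARTMENTS

    def __post_init__(self) -> None:
        if self.compartments != COMPARTMENTS:
            raise DataModelError("compartment order must be the canonical 7-tuple")
        lab = np.asarray(self.labels)
        if lab.shape != (len(self.entity_ids), 7):
            raise DataModelError(f"label shape {lab.shape} != ({len(self.entity_ids)}, 7)")
        if lab.size and not np.isin(lab, (0, 1)).all():
            raise DataModelError("labels must be 0/1")
        object.__setattr__(self, "labels", lab.astype(np.int8))

    def row_map(self) -> dict[str, np.ndarray]:
        return {e: self.labels[i] for i, e in enumerate(self.entity_ids)}

    def align_to(self, entity_ids: Sequence[str]) -> "LocalizationMatrix":
        pos = {e: i for i, e in enumerate(self.entity_ids)}
        missing = [e for e in entity_ids if e not in pos]
        if missing:
            raise DataModelError(f"entities missing from localisation matrix: {missing[:5]}")
        idx = [pos[e] for e in entity_ids]
        return LocalizationMatrix(tuple(entity_ids), self.labels[idx])


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square symmetric similarity with unit diagonal and entries in [0, 1]."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if vals.shape != (n, n):
            raise DataModelError(f"similarity shape {vals.shape} != ({n}, {n})")
        if n:
            if not np.allclose(vals, vals.T, atol=1e-9):
                raise DataModelError("similarity matrix not symmetric")
            if not np.allclose(np.diag(vals), 1.0, atol=1e-9):
                raise DataModelError("similarity diagonal must be 1")
            if vals.min() < -1e-12 or vals.max() > 1 + 1e-9:
                raise DataModelError("similarity entries must lie in [0, 1]")
        object.__setattr__(self, "values", vals)


@dataclass(frozen=True)
class FeatureMatrix:
    """A miRNA-indexed feature block for one of the five fusion branches."""

    mirna_ids: tuple[str, ...]
    values: np.ndarray
    branch: str

    BRANCHES = ("seq", "disease", "drug", "mrna_net", "mrna_loc")

    def __post_init__(self) -> None:
        if self.branch not in self.BRANCHES:
            raise DataModelError(f"unknown branch {self.branch!r}")
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.shape[0] != len(self.mirna_ids):
            raise DataModelError("feature matrix must be |miRNA| x d")
        if not np.isfinite(vals).all():
            raise DataModelError("feature matrix contains non-finite entries")
        object.__setattr__(self, "values", vals)


# ---------------------------------------------------------------------------
# readers / writers


def read_fasta(path: str | Path) -> MirnaSet:
    """Read miRNA sequences. DNA-style T is normalised to U, case to upper."""
    ids: list[str] = []
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise DataModelError(f"duplicate id {record.id}")
        seq = str(record.seq).upper().replace("T", "U")
        if not seq:
            raise DataModelError(f"empty record {record.id}")
        ids.append(record.id)
        seqs[record.id] = seq
    if not ids:
        raise DataModelError(f"no FASTA records in {path}")
    return MirnaSet(tuple(ids), seqs)


def _data_lines(path: str | Path) -> Iterable[tuple[int, str]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_edge_list(
    path: str | Path, entity_kind: str, mirna_universe: Sequence[str]
) -> AssociationNetwork:
    """Read a two-column miRNA<TAB>entity edge list.

    Edges whose miRNA is outside ``mirna_universe`` are dropped (counted in
    the log); entity ids are the sorted distinct entities that survive.
    An optional header line ``mirna_id<TAB>entity_id`` is skipped.
    """
    universe = set(mirna_universe)
    edges: list[tuple[str, str]] = []
    dropped = 0
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 2:
            raise DataModelError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
        m, e = fields
        if lineno == 1 and (m, e) == ("mirna_id", "entity_id"):
            continue
        if m not in universe:
            dropped += 1
            continue
        edges.append((m, e))
    if dropped:
        logger.info("read_edge_list(%s): dropped %d edges outside the miRNA universe", path, dropped)
    entity_ids = tuple(sorted({e for _, e in edges}))
    epos = {e: j for j, e in enumerate(entity_ids)}
    mpos = {m: i for i, m in enumerate(mirna_universe)}
    adj = np.zeros((len(mirna_universe), len(entity_ids)), dtype=np.int8)
    for m, e in edges:
        adj[mpos[m], epos[e]] = 1
    return AssociationNetwork(tuple(mirna_universe), entity_ids, entity_kind, adj)


def read_dag(path: str | Path) -> DiseaseDAG:
    """Read child<TAB>parent rows; acyclicity is verified on construction."""
    edges: set[tuple[str, str]] = set()
    nodes: set[str] = set()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 2:
            raise DataModelError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
        child, parent = fields
        if (child, parent) == ("child", "parent") and lineno == 1:
            continue
        edges.add((child, parent))
        nodes.update((child, parent))
    return DiseaseDAG(frozenset(nodes), frozenset(edges))


def read_localization(path: str | Path) -> LocalizationMatrix:
    """Read an entity × 7 binary TSV whose header names the compartments."""
    rows = list(_data_lines(path))
    if not rows:
        raise DataModelError(f"empty localisation file {path}")
    header = rows[0][1].split("\t")
    if tuple(header[1:]) != COMPARTMENTS:
        raise DataModelError(
            f"{path}: header compartments {header[1:]} do not match canonical order"
        )
    ids: list[str] = []
    labels: list[list[int]] = []
    for lineno, line in rows[1:]:
        fields = line.split("\t")
        if len(fields) != 8:
            raise DataModelError(f"{path}:{lineno}: expected 8 fields, got {len(fields)}")
        ids.append(fields[0])
        row = []
        for v in fields[1:]:
            if v not in ("0", "1"):
                raise DataModelError(f"{path}:{lineno}: label entry {v!r} not in {{0,1}}")
            row.append(int(v))
        labels.append(row)
    return LocalizationMatrix(tuple(ids), np.array(labels, dtype=np.int8).reshape(len(ids), 7))


def write_localization(path: str | Path, loc: LocalizationMatrix) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\t" + "\t".join(COMPARTMENTS) + "\n")
        for i, e in enumerate(loc.entity_ids):
            fh.write(e + "\t" + "\t".join(str(int(v)) for v in loc.labels[i]) + "\n")


def write_matrix(path: str | Path, ids: Sequence[str], values: np.ndarray,
                 columns: Sequence[str] | None = None) -> None:
    """Write a row-id-first TSV matrix with %.10g formatting (round-trip safe)."""
    values = np.asarray(values)
    if columns is None:
        columns = [f"c{j}" for j in range(values.shape[1])]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\t" + "\t".join(columns) + "\n")
        for i, rid in enumerate(ids):
            fh.write(rid + "\t" + "\t".join("%.10g" % v for v in values[i]) + "\n")


def read_matrix(path: str | Path) -> tuple[tuple[str, ...], np.ndarray, tuple[str, ...]]:
    """Read a matrix written by :func:`write_matrix`. Returns (ids, values, columns)."""
    rows = list(_data_lines(path))
    if not rows:
        raise DataModelError(f"empty matrix file {path}")
    columns = tuple(rows[0][1].split("\t")[1:])
    ids: list[str] = []
    data: list[list[float]] = []
    for lineno, line in rows[1:]:
        fields = line.split("\t")
        if len(fields) != len(columns) + 1:
            raise DataModelError(f"{path}:{lineno}: ragged row")
        ids.append(fields[0])
        data.append([float(v) for v in fields[1:]])
    return tuple(ids), np.array(data, dtype=float).reshape(len(ids), len(columns)), columns


def write_edge_list(path: str | Path, net: AssociationNetwork) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("mirna_id\tentity_id\n")
        rows, cols = np.nonzero(net.adjacency)
        for i, j in zip(rows, cols):
            fh.write(f"{net.mirna_ids[i]}\t{net.entity_ids[j]}\n")


def write_fasta(path: str | Path, mirnas: MirnaSet) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for mid in mirnas.ids:
            fh.write(f">{mid}\n{mirnas.sequences[mid]}\n")


def write_dag(path: str | Path, dag: DiseaseDAG) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for child, parent in sorted(dag.parent_edges):
            fh.write(f"{child}\t{parent}\n")
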