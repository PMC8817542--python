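"""Core data containers and file formats.

The canonical in-memory objects are:

* :class:`OTUTable` — integer count matrix, OTUs as rows, samples as columns.
* :class:`AbundanceTable` — the same matrix converted to per-sample relative
  abundances (columns sum to one).
* :class:`PhyloTree` — a rooted phylogeny with branch lengths whose leaves are
  keyed by OTU identifier (a thin wrapper around :class:`skbio.TreeNode`).
* :class:`DistanceMatrix` — a symmetric matrix of pairwise sample
  dissimilarities with the metric name and parameters attached.
* :class:`Partition` — an integer cluster label per sample.

On disk, OTU tables and distance matrices are tab-separated text, trees are
Newick, and partitions are two-column CSV (``sample_id,label``).
"""

from __future__ import annotations

import math
import os
import tempfile
from dataclasses import dataclass, field
from io import StringIO
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import skbio


class FormatError(ValueError):
    """Raised when an input file or object violates the format contract."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class OTUTable:
    """Integer count matrix with ``p`` OTU rows and ``n`` sample columns."""

    counts: np.ndarray
    otu_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise FormatError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.otu_ids)} OTU ids x {len(self.sample_ids)} sample ids"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                bad = np.argwhere(self.counts != np.floor(self.counts))
                r, c = bad[0]
                raise FormatError(
                    f"non-integer count at OTU {self.otu_ids[r]!r}, "
                    f"sample {self.sample_ids[c]!r}"
                )
            self.counts = as_int
        else:
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            r, c = np.argwhere(self.counts < 0)[0]
            raise FormatError(
                f"negative count at OTU {self.otu_ids[r]!r}, "
                f"sample {self.sample_ids[c]!r}"
            )
        self.otu_ids = [str(i) for i in self.otu_ids]
        self.sample_ids = [str(i) for i in self.sample_ids]
        _check_unique(self.otu_ids, "OTU")
        _check_unique(self.sample_ids, "sample")

    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def copy(self) -> "OTUTable":
        return OTUTable(self.counts.copy(), list(self.otu_ids), list(self.sample_ids))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.otu_ids, columns=self.sample_ids)

    def select_otus(self, ids: Sequence[str]) -> "OTUTable":
        index = {o: i for i, o in enumerate(self.otu_ids)}
        rows = [index[i] for i in ids]
        return OTUTable(self.counts[rows], list(ids), list(self.sample_ids))


@dataclass
class AbundanceTable:
    """Relative-abundance matrix; columns sum to 1, zeros match source counts."""

    abundances: np.ndarray
    otu_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        col = self.abundances.sum(axis=0)
        if not np.allclose(col, 1.0, atol=1e-9):
            raise FormatError("abundance columns must each sum to 1")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise sample dissimilarities."""

    values: np.ndarray
    sample_ids: list[str]
    metric_name: str = ""
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise FormatError(f"distance matrix shape {v.shape} != ({n}, {n})")
        if not np.isfinite(v).all():
            raise FormatError("distance matrix contains non-finite values")
        if not np.allclose(v, v.T, atol=1e-12):
            raise FormatError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise FormatError("distance matrix diagonal is not zero")
        if (v < -1e-12).any():
            raise FormatError("distance matrix has negative entries")
        v = np.clip((v + v.T) / 2.0, 0.0, None)
        np.fill_diagonal(v, 0.0)
        self.values = v
        _check_unique(self.sample_ids, "sample")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy's condensed order."""
        iu = np.triu_indices(self.n_samples, k=1)
        return self.values[iu]

    def to_skbio(self) -> skbio.DistanceMatrix:
        return skbio.DistanceMatrix(self.values, ids=self.sample_ids)


@dataclass
class Partition:
    """Cluster label (small positive integer) per sample."""

    labels: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.shape != (len(self.sample_ids),):
            raise FormatError("one label per sample id required")
        _check_unique(self.sample_ids, "sample")

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))

    def relabeled(self, mapping: dict[int, int]) -> "Partition":
        return Partition(np.array([mapping[x] for x in self.labels]), list(self.sample_ids))


class PhyloTree:
    """Rooted phylogeny with non-negative branch lengths.

    Wraps :class:`skbio.TreeNode`. Internal nodes without a name are assigned
    deterministic preorder names ``N1, N2, ...`` so trimmed/merged taxa can be
    referred to stably. A Newick string without an explicit root is treated as
    rooted at its outermost node; no re-rooting is ever performed.
    """

    def __init__(self, root: skbio.TreeNode):
        self.root = root
        self._assign_internal_names()
        self._validate()

    def _assign_internal_names(self) -> None:
        used = {n.name for n in self.root.traverse() if n.name is not None}
        counter = 1
        for node in self.root.preorder():
            if node.name is None:
                while f"N{counter}" in used:
                    counter += 1
                node.name = f"N{counter}"
                used.add(node.name)

    def _validate(self) -> None:
        leaf_names = [t.name for t in self.root.tips()]
        if self.root.is_tip():
            leaf_names = [self.root.name]
        _check_unique(leaf_names, "leaf")
        for node in self.root.traverse():
            if node is self.root:
                continue
            if node.length is None:
                node.length = 0.0
            if node.length < 0:
                raise FormatError(f"negative branch length at node {node.name!r}")

    @property
    def leaf_names(self) -> list[str]:
        if self.root.is_tip():
            return [self.root.name]
        return [t.name for t in self.root.tips()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.root.copy())

    def leaf_depths(self) -> dict[str, int]:
        """Edge-count depth from the root for every leaf."""
        depths: dict[str, int] = {}
        stack = [(self.root, 0)]
        while stack:
            node, d = stack.pop()
            if node.is_tip():
                depths[node.name] = d
            else:
                stack.extend((c, d + 1) for c in node.children)
        return depths

    def total_branch_length(self) -> float:
        return sum(n.length or 0.0 for n in self.root.traverse() if n is not self.root)

    def shear(self, names: Iterable[str]) -> "PhyloTree":
        """Restrict to the given leaves, collapsing unary nodes by summing lengths."""
        names = list(names)
        sub = self.root.shear(names)
        # skbio can leave the root with a single internal child; promote that
        # child to be the new root. Its branch would be shared by every
        # retained sample, so dropping it cannot change any UniFrac value.
        while len(sub.children) == 1 and not sub.children[0].is_tip():
            sub = sub.children[0]
            sub.parent = None
            sub.length = None
        return PhyloTree(sub)


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    Raises :class:`FormatError` with a character offset for unbalanced
    parentheses or a missing terminating semicolon.
    """
    depth = 0
    for offset, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise FormatError(f"unbalanced ')' at character {offset}")
    if depth != 0:
        raise FormatError(
            f"unbalanced parentheses: {depth} unclosed '(' by character {len(text)}"
        )
    if ";" not in text:
        raise FormatError(f"missing ';' terminator at character {len(text)}")
    try:
        # convert_underscores=False: leaf ids must round-trip verbatim
        root = skbio.TreeNode.read(
            StringIO(text), format="newick", convert_underscores=False
        )
    except Exception as exc:  # skbio raises its own parse errors
        raise FormatError(f"newick parse error: {exc}") from exc
    return PhyloTree(root)


def _format_length(x: float) -> str:
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return f"{x:.10g}"


def write_newick(tree: PhyloTree) -> str:
    """Serialize deterministically: children in stored order, lengths to 10
    significant digits."""

    def fmt(node: skbio.TreeNode) -> str:
        if node.is_tip():
            core = node.name or ""
        else:
            core = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.name:
                core += node.name
        if node is not tree.root and node.length is not None:
            core += f":{_format_length(node.length)}"
        return core

    return fmt(tree.root) + ";"


def read_newick(path: str) -> PhyloTree:
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick_file(tree: PhyloTree, path: str) -> None:
    atomic_write_text(path, write_newick(tree) + "\n")


# ---------------------------------------------------------------------------
# Tables, labels, distance matrices
# ---------------------------------------------------------------------------

def read_otu_table(path: str, orientation: str = "otus_as_rows") -> OTUTable:
    """Read a tab-separated count table (header row + id column).

    ``orientation`` says what the file's rows are; the returned table is always
    in canonical orientation (OTUs as rows).
    """
    if orientation not in ("otus_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    _check_unique(row_ids, "row")
    _check_unique(col_ids, "column")
    values = np.empty(df.shape, dtype=np.int64)
    raw = df.to_numpy()
    for r in range(df.shape[0]):
        for c in range(df.shape[1]):
            cell = raw[r, c]
            try:
                v = int(cell)
                if v < 0 or str(v) != str(cell).strip():
                    raise ValueError
            except (TypeError, ValueError):
                raise FormatError(
                    f"cell at row {row_ids[r]!r}, column {col_ids[c]!r} is not a "
                    f"non-negative integer: {cell!r}"
                ) from None
            values[r, c] = v
    if orientation == "samples_as_rows":
        values = values.T
        row_ids, col_ids = col_ids, row_ids
    table = OTUTable(values, row_ids, col_ids)
    zero = np.flatnonzero(table.counts.sum(axis=0) < 1)
    if zero.size:
        raise FormatError(f"sample {table.sample_ids[zero[0]]!r} has zero total count")
    return table


def write_otu_table(table: OTUTable, path: str) -> None:
    atomic_write_text(path, table.to_dataframe().to_csv(sep="\t"))


def read_labels(path: str) -> Partition:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise FormatError("label file needs two columns: sample_id,label")
    ids = [str(x) for x in df.iloc[:, 0]]
    labels = df.iloc[:, 1].astype(int).to_numpy()
    return Partition(labels, ids)


def write_labels(part: Partition, path: str) -> None:
    df = pd.DataFrame({"sample_id": part.sample_ids, "label": part.labels})
    atomic_write_text(path, df.to_csv(index=False))


def read_distance_matrix(path: str) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(i) for i in df.index]
    if ids != [str(c) for c in df.columns]:
        raise FormatError("distance matrix row and column ids differ")
    return DistanceMatrix(df.to_numpy(dtype=float), ids)


def write_distance_matrix(dm: DistanceMatrix, path: str) -> None:
    df = pd.DataFrame(dm.values, index=dm.sample_ids, columns=dm.sample_ids)
    atomic_write_text(path, df.to_csv(sep="\t"))


def atomic_write_text(path: str, text: str) -> None:
    """Write via a temporary file in the same directory, then rename."""
    directory = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=directory, prefix=".tmp_", suffix=".part")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# Harmonization and normalization
# ---------------------------------------------------------------------------

def harmonize(
    table: OTUTable, tree: PhyloTree, policy: str = "strict"
) -> tuple[OTUTable, PhyloTree]:
    """Reconcile the OTU set of a table with the leaf set of a tree.

    ``strict`` errors on any mismatch; ``prune`` keeps the intersection,
    dropping table rows without leaves and shearing tree leaves without rows
    (unary nodes left by shearing are collapsed with summed branch lengths).
    """
    table_set = set(table.otu_ids)
    leaf_set = set(tree.leaf_names)
    if policy == "strict":
        extra_t = sorted(table_set - leaf_set)
        extra_l = sorted(leaf_set - table_set)
        if extra_t or extra_l:
            raise FormatError(
                "table/tree mismatch: "
                f"table-only={extra_t}, tree-only={extra_l}"
            )
        return table, tree
    if policy != "prune":
        raise ValueError(f"unknown policy {policy!r}")
    shared = [o for o in table.otu_ids if o in leaf_set]
    if not shared:
        raise FormatError("pruning leaves no shared OTUs between table and tree")
    new_table = table.select_otus(shared)
    if table_set == leaf_set:
        return new_table, tree
    new_tree = tree.shear(shared)
    return new_table, new_tree


def relative_abundance(table: OTUTable) -> AbundanceTable:
    """Divide each sample column by its total count (zero pattern preserved)."""
    sums = table.counts.sum(axis=0)
    zero = np.flatnonzero(sums < 1)
    if zero.size:
        raise FormatError(
            f"sample {table.sample_ids[zero[0]]!r} has zero total count"
        )
    ab = table.counts / sums[np.newaxis, :]
    return AbundanceTable(ab, list(table.otu_ids), list(table.sample_ids))
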