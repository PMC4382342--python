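"""Trees, tabular inputs, and clade identity.

The in-memory tree is an array-backed :class:`TimeTree`: node ``i`` owns the
branch above it, tips occupy indices ``0..n_tips-1``, and node ages (million
years before present) are rebuilt from branch lengths by max-path so that all
tips sit exactly at age 0. Newick/NEXUS parsing and writing are delegated to
dendropy; everything downstream works on the arrays.

Clades are identified across trees by :class:`CladeKey`, the sorted tuple of
tip labels, so "the same shift node" is well defined between topologically
different trees via MRCA lookup.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import dendropy

log = logging.getLogger(__name__)

#: Relative (to root age) tolerance below which a tree counts as ultrametric.
ULTRAMETRIC_RTOL = 1e-3

CladeKey = tuple  # sorted tuple of tip labels; see clade_key()


def clade_key(labels: Iterable[str]) -> CladeKey:
    """Canonical, hashable identity of a clade: the sorted tuple of tip labels."""
    key = tuple(sorted(set(labels)))
    if not key:
        raise ValueError("a clade key needs at least one tip label")
    return key


class TreeError(ValueError):
    """Raised for structurally invalid trees or inconsistent tree inputs."""


class TimeTree:
    """Rooted time-calibrated tree with ages in My before present.

    Parameters
    ----------
    parent : (n_nodes,) int array, ``-1`` for the root.
    lengths : (n_nodes,) float array, branch length above each node
        (ignored for the root).
    labels : sequence of ``n_tips`` unique tip labels; tips are nodes
        ``0..n_tips-1``.
    """

    def __init__(self, parent, lengths, labels):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.lengths = np.asarray(lengths, dtype=np.float64).copy()
        self.labels = list(labels)
        self.n_nodes = len(self.parent)
        self.n_tips = len(self.labels)
        if len(set(self.labels)) != self.n_tips:
            dupes = sorted({x for x in self.labels if self.labels.count(x) > 1})
            raise TreeError(f"duplicate tip labels: {dupes}")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise TreeError(f"expected exactly one root, found {len(roots)}")
        self.root = int(roots[0])
        self.lengths[self.root] = 0.0
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i in range(self.n_nodes):
            p = self.parent[i]
            if p >= 0:
                self.children[p].append(i)
        for i in range(self.n_tips):
            if self.children[i]:
                raise TreeError(f"node {i} is labelled as a tip but has children")
        for i in range(self.n_tips, self.n_nodes):
            if len(self.children[i]) == 1 and i != self.root:
                raise TreeError(f"internal node {i} has a single child")
        self._label_to_tip = {lab: i for i, lab in enumerate(self.labels)}
        self.postorder = self._compute_postorder()
        self.ages = self._rebuild_ages()
        self.is_ultrametric = self._check_ultrametric()

    # -- construction -----------------------------------------------------

    def _compute_postorder(self) -> np.ndarray:
        order = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        return np.asarray(order[::-1], dtype=np.int64)

    def _rebuild_ages(self) -> np.ndarray:
        """Node ages from branch lengths by max-path; tips pinned at 0."""
        ages = np.zeros(self.n_nodes)
        for v in self.postorder:
            if self.children[v]:
                ages[v] = max(ages[c] + self.lengths[c] for c in self.children[v])
        return ages

    def _check_ultrametric(self) -> bool:
        depth = np.zeros(self.n_nodes)
        for v in self.postorder[::-1]:
            p = self.parent[v]
            if p >= 0:
                depth[v] = depth[p] + self.lengths[v]
        tip_depths = depth[: self.n_tips]
        root_age = max(tip_depths.max(), 1e-300)
        ok = bool(tip_depths.max() - tip_depths.min() <= ULTRAMETRIC_RTOL * root_age)
        if not ok:
            log.warning(
                "tree is not ultrametric within tolerance (tip depth spread %.3g "
                "on root age %.3g); ages rebuilt by max-path",
                tip_depths.max() - tip_depths.min(), root_age,
            )
        return ok

    # -- basic queries -----------------------------------------------------

    @property
    def root_age(self) -> float:
        return float(self.ages[self.root])

    def is_binary(self) -> bool:
        return all(len(self.children[v]) == 2
                   for v in range(self.n_nodes) if self.children[v])

    def is_tip(self, node: int) -> bool:
        return node < self.n_tips

    def tip_set(self) -> frozenset:
        return frozenset(self.labels)

    def clade_tips(self, node: int) -> CladeKey:
        """Sorted tuple of tip labels descending from ``node`` (inclusive)."""
        out = []
        stack = [int(node)]
        while stack:
            v = stack.pop()
            if v < self.n_tips:
                out.append(self.labels[v])
            stack.extend(self.children[v])
        return clade_key(out)

    def mrca(self, key: Iterable[str]) -> int:
        """Most recent common ancestor of the given tip labels."""
        labels = list(key)
        try:
            tips = [self._label_to_tip[lab] for lab in labels]
        except KeyError as e:
            raise TreeError(f"label {e.args[0]!r} not in tree") from None
        if len(tips) == 1:
            return tips[0]
        count = np.zeros(self.n_nodes, dtype=np.int64)
        want = len(set(tips))
        for t in set(tips):
            count[t] = 1
        for v in self.postorder:
            for c in self.children[v]:
                count[v] += count[c]
            if count[v] == want:
                return int(v)
        raise TreeError("unreachable: marked tips not covered by root")

    def total_branch_length(self) -> float:
        mask = np.ones(self.n_nodes, dtype=bool)
        mask[self.root] = False
        return float(self.lengths[mask].sum())

    def subtree_nodes(self, node: int) -> list[int]:
        out = []
        stack = [int(node)]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(self.children[v])
        return out

    # -- conversion --------------------------------------------------------

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "TimeTree":
        nodes = list(dtree.preorder_node_iter())
        tips = [nd for nd in nodes if nd.is_leaf()]
        internals = [nd for nd in nodes if not nd.is_leaf()]
        index = {}
        labels = []
        for i, nd in enumerate(tips):
            if nd.taxon is not None and nd.taxon.label is not None:
                labels.append(str(nd.taxon.label))
            elif nd.label:
                labels.append(str(nd.label))
            else:
                raise TreeError("unlabelled tip in input tree")
            index[id(nd)] = i
        for j, nd in enumerate(internals):
            index[id(nd)] = len(tips) + j
        n = len(nodes)
        parent = np.full(n, -1, dtype=np.int64)
        lengths = np.zeros(n)
        for nd in nodes:
            i = index[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                lengths[i] = float(nd.edge.length or 0.0)
        return cls(parent, lengths, labels)

    def to_dendropy(self, taxon_namespace=None) -> dendropy.Tree:
        tns = taxon_namespace or dendropy.TaxonNamespace()
        dtree = dendropy.Tree(taxon_namespace=tns)
        dnodes = [dendropy.Node() for _ in range(self.n_nodes)]
        for i in range(self.n_tips):
            dnodes[i].taxon = tns.require_taxon(label=self.labels[i])
        for v in self.postorder[::-1]:          # preorder
            for c in self.children[v]:
                dnodes[v].add_child(dnodes[c])
                dnodes[c].edge.length = float(self.lengths[c])
        dtree.seed_node = dnodes[self.root]
        return dtree

    @classmethod
    def from_newick(cls, s: str) -> "TimeTree":
        try:
            dtree = dendropy.Tree.get(data=s, schema="newick",
                                      preserve_underscores=True)
        except Exception as e:       # normalize parser errors
            raise TreeError(f"newick parse failed: {e}") from e
        return cls.from_dendropy(dtree)

    def to_newick(self) -> str:
        s = self.to_dendropy().as_string(
            schema="newick", suppress_rooting=True, real_value_format_specifier=".17g")
        return s.strip()

    def __repr__(self) -> str:
        return (f"TimeTree(n_tips={self.n_tips}, root_age={self.root_age:.4g}, "
                f"ultrametric={self.is_ultrametric})")


@dataclass
class TreeSample:
    """An ordered sample of trees over (nominally) a shared tip set."""

    trees: list
    source: str = ""
    problems: list = field(default_factory=list)

    def __post_init__(self):
        if not self.trees:
            raise TreeError("empty tree sample")

    def __len__(self):
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i):
        return self.trees[i]

    def shared_tip_violations(self) -> list[str]:
        """Report (do not fix) trees whose tip set differs from tree 0's."""
        ref = self.trees[0].tip_set()
        out = []
        for i, t in enumerate(self.trees[1:], start=1):
            if t.tip_set() != ref:
                missing = sorted(ref - t.tip_set())[:5]
                extra = sorted(t.tip_set() - ref)[:5]
                out.append(f"tree {i}: tip set differs "
                           f"(missing e.g. {missing}, extra e.g. {extra})")
        return out


# ---------------------------------------------------------------------------
# readers / writers


def read_trees(path, schema: str = "newick") -> TreeSample:
    """Read a newick or nexus file (translate tables honored) into a TreeSample.

    Every tree is validated against the TimeTree invariants; a parse or
    validation failure reports the index of the offending tree.  Duplicate
    tip labels are fatal; a non-ultrametric tree is flagged with a warning
    and its ages rebuilt from branch lengths.
    """
    if schema not in ("newick", "nexus"):
        raise ValueError(f"unsupported tree schema {schema!r}")
    try:
        dtrees = dendropy.TreeList.get(path=str(path), schema=schema,
                                       preserve_underscores=True)
    except Exception as e:
        raise TreeError(f"could not parse {path}: {e}") from e
    if len(dtrees) == 0:
        raise TreeError(f"no trees found in {path}")
    trees = []
    for i, dt in enumerate(dtrees):
        try:
            trees.append(TimeTree.from_dendropy(dt))
        except TreeError as e:
            raise TreeError(f"tree {i} in {path}: {e}") from e
    sample = TreeSample(trees, source=str(path))
    sample.problems = sample.shared_tip_violations()
    for msg in sample.problems:
        log.warning("%s: %s", path, msg)
    return sample


def write_trees(sample, path, schema: str = "newick") -> None:
    """Write a TreeSample (or iterable of TimeTree) to newick or nexus."""
    tns = dendropy.TaxonNamespace()
    tl = dendropy.TreeList(taxon_namespace=tns)
    for t in sample:
        tl.append(t.to_dendropy(taxon_namespace=tns))
    tl.write(path=str(path), schema=schema,
             real_value_format_specifier=".17g",
             suppress_rooting=True)


def read_richness(path) -> dict:
    """Read a ``taxon,richness`` CSV into a mapping; counts must be >= 1."""
    table = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            taxon = row["taxon"].strip()
            n = int(row["richness"])
            if n < 1:
                raise ValueError(f"richness for {taxon!r} must be >= 1, got {n}")
            if taxon in table:
                raise ValueError(f"duplicate richness entry for {taxon!r}")
            table[taxon] = n
    if not table:
        raise ValueError(f"no richness rows in {path}")
    return table


def write_richness(table: Mapping[str, int], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["taxon", "richness"])
        for taxon in sorted(table):
            w.writerow([taxon, table[taxon]])


def validate_richness(tree: TimeTree, table: Mapping[str, int]) -> None:
    """Every tree tip must have a richness entry (missing entries are errors)."""
    missing = [lab for lab in tree.labels if lab not in table]
    if missing:
        raise ValueError(f"richness missing for {len(missing)} tips, "
                         f"e.g. {missing[:5]}")
    bad = [lab for lab in tree.labels if table[lab] < 1]
    if bad:
        raise ValueError(f"richness < 1 for {bad[:5]}")


def read_traits(path) -> dict:
    """Read a ``taxon,state`` CSV; states are 0, 1 or blank/NA (missing=None)."""
    table = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            taxon = row["taxon"].strip()
            raw = (row["state"] or "").strip()
            if raw in ("", "NA", "?", "-"):
                table[taxon] = None
            elif raw in ("0", "1"):
                table[taxon] = int(raw)
            else:
                raise ValueError(f"invalid trait state {raw!r} for {taxon!r}")
    if not table:
        raise ValueError(f"no trait rows in {path}")
    return table


def write_traits(table: Mapping[str, object], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["taxon", "state"])
        for taxon in sorted(table):
            s = table[taxon]
            w.writerow([taxon, "" if s is None else int(s)])


def trait_coverage(tree: TimeTree, table: Mapping[str, object]) -> dict:
    """Coverage report of a trait table against a tree's tips."""
    states = {lab: table.get(lab, None) for lab in tree.labels}
    n0 = sum(1 for s in states.values() if s == 0)
    n1 = sum(1 for s in states.values() if s == 1)
    missing = sorted(lab for lab, s in states.items() if s is None)
    return {"n0": n0, "n1": n1, "n_missing": len(missing), "missing": missing}


def read_hostplants(path):
    """Read a hostplant records CSV into a pandas DataFrame.

    Expected columns: ``butterfly_genus, plant_family, plant_genus, reference``
    (extra columns are kept).
    """
    import pandas as pd

    df = pd.read_csv(path)
    required = {"butterfly_genus", "plant_family"}
    if not required.issubset(df.columns):
        raise ValueError(f"hostplant table must have columns {sorted(required)}")
    if len(df) == 0:
        raise ValueError("empty hostplant record table")
    return df


# ---------------------------------------------------------------------------
# tree surgery


def prune_outgroup(tree: TimeTree, labels: Iterable[str]) -> TimeTree:
    """Remove the given tips; suppress degree-2 nodes, summing branch lengths.

    The ingroup root is the deepest remaining node with >= 2 surviving
    children; its (former) stem branch is dropped so the returned tree's root
    age is the ingroup crown age.
    """
    drop = set(labels)
    unknown = drop - tree.tip_set()
    if unknown:
        raise TreeError(f"labels not in tree: {sorted(unknown)[:5]}")
    keep = [lab for lab in tree.labels if lab not in drop]
    if len(keep) < 2:
        raise TreeError("pruning would leave fewer than 2 tips")
    return retain_tips(tree, keep)


def retain_tips(tree: TimeTree, labels: Iterable[str]) -> TimeTree:
    """Restriction of the tree to the given tips (order-insensitive)."""
    keep_labels = set(labels)
    if not keep_labels.issubset(tree.tip_set()):
        raise TreeError("retain set contains labels not in tree")
    keep_tip = np.zeros(tree.n_nodes, dtype=bool)
    for lab in keep_labels:
        keep_tip[tree._label_to_tip[lab]] = True

    # per node: surviving (child_repr, extra_length) pairs, bottom-up
    surv: list = [None] * tree.n_nodes
    new_parent: list = []
    new_length: list = []
    new_labels: list = []
    # first pass: assign indices for surviving tips
    tip_index = {}
    for i in range(tree.n_tips):
        if keep_tip[i]:
            tip_index[i] = len(new_labels)
            new_labels.append(tree.labels[i])
            new_parent.append(-2)       # filled later
            new_length.append(0.0)
    n_new_tips = len(new_labels)
    internal_records = []               # (old_node, [children records])

    for v in tree.postorder:
        if tree.is_tip(v):
            surv[v] = (tip_index[v], tree.lengths[v]) if keep_tip[v] else None
            continue
        kids = [surv[c] for c in tree.children[v] if surv[c] is not None]
        if not kids:
            surv[v] = None
        elif len(kids) == 1:
            node, ln = kids[0]
            surv[v] = (node, ln + tree.lengths[v])   # suppress degree-2
        else:
            internal_records.append((v, kids))
            surv[v] = (("int", len(internal_records) - 1), tree.lengths[v])

    if surv[tree.root] is None:
        raise TreeError("no tips retained")
    root_repr = surv[tree.root][0]
    if not (isinstance(root_repr, tuple) and root_repr[0] == "int"):
        raise TreeError("pruning would leave fewer than 2 tips")

    n_internal = len(internal_records)
    n_nodes = n_new_tips + n_internal
    parent = np.full(n_nodes, -1, dtype=np.int64)
    length = np.zeros(n_nodes)

    def node_id(repr_):
        if isinstance(repr_, tuple) and repr_[0] == "int":
            return n_new_tips + repr_[1]
        return repr_

    for rec_i, (_, kids) in enumerate(internal_records):
        me = n_new_tips + rec_i
        for child_repr, ln in kids:
            c = node_id(child_repr)
            parent[c] = me
            length[c] = ln
    root_id = node_id(root_repr)
    parent[root_id] = -1
    length[root_id] = 0.0
    return TimeTree(parent, length, new_labels)


def mrca(tree: TimeTree, key: Iterable[str]) -> int:
    """Module-level MRCA helper (see :meth:`TimeTree.mrca`)."""
    return tree.mrca(key)
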