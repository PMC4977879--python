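"""Annotated rooted species trees and their tabular companions.

The tree data model used throughout the package: a rooted (possibly
multifurcating) species tree whose tips carry three annotations —
phylum, lifestyle (sympatric/allopatric) and cell plan
(compartmentalized / non_compartmentalized / unknown).  Newick
parsing and serialization stand on dendropy; the class additionally
exposes flat index arrays (parent pointers, branch lengths, postorder)
that the reconstruction and simulation algorithms consume directly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

LIFESTYLES = ("sympatric", "allopatric")
CELL_PLANS = ("compartmentalized", "non_compartmentalized", "unknown")

ANNOTATION_COLUMNS = ("phylum", "lifestyle", "cell_plan")


class TreeIOError(ValueError):
    """Raised for malformed trees or annotation tables."""


@dataclass(frozen=True)
class Branch:
    """Directed edge child -> parent with a non-negative length.

    A branch is *terminal* iff its child is a tip; gains placed on a
    terminal branch are "specific" (occurred in a modern species), gains
    on internal branches are "non-specific" (occurred in an ancestor).
    """

    child: str
    parent: str
    length: float
    terminal: bool

    def __post_init__(self):
        if self.length < 0:
            raise TreeIOError(f"negative branch length on {self.child}")


class AnnotatedTree:
    """Rooted species tree with per-tip phylum/lifestyle/cell-plan labels.

    Parameters
    ----------
    dtree :
        A rooted dendropy tree.  Internal nodes without labels are
        assigned stable names ``N1, N2, ...`` in postorder.
    annotations :
        DataFrame indexed by species (tip label) with columns
        ``phylum``, ``lifestyle``, ``cell_plan``.

    Attributes (flat arrays, node-indexed)
    --------------------------------------
    labels : list[str]           node id per index (tips keep species name)
    parent : ndarray[int]        parent index per node, -1 at the root
    brlen : ndarray[float]       branch length above each node (0 at root)
    postorder : ndarray[int]     node indices, children before parents
    is_tip : ndarray[bool]
    """

    def __init__(self, dtree: dendropy.Tree, annotations: pd.DataFrame):
        self.dtree = dtree
        self.annotations = _validate_annotations(annotations)
        self._index()
        self._validate()

    # -- construction ------------------------------------------------

    def _index(self) -> None:
        nodes = list(self.dtree.postorder_node_iter())
        counter = 0
        seen: set[str] = set()
        for nd in nodes:
            if nd.is_leaf():
                if nd.taxon is None or not nd.taxon.label:
                    raise TreeIOError("tip without a name")
                nd._psid = nd.taxon.label
            else:
                if nd.label:
                    nd._psid = str(nd.label)
                else:
                    counter += 1
                    while f"N{counter}" in seen:
                        counter += 1
                    nd._psid = f"N{counter}"
                    nd.label = nd._psid
            if nd._psid in seen:
                raise TreeIOError(f"duplicate node id {nd._psid!r}")
            seen.add(nd._psid)

        self._nodes = nodes
        self.labels: list[str] = [nd._psid for nd in nodes]
        self.index: dict[str, int] = {l: i for i, l in enumerate(self.labels)}
        n = len(nodes)
        self.parent = np.full(n, -1, dtype=np.int64)
        self.brlen = np.zeros(n, dtype=float)
        self.is_tip = np.zeros(n, dtype=bool)
        for i, nd in enumerate(nodes):
            nd._psidx = i
        for i, nd in enumerate(nodes):
            self.is_tip[i] = nd.is_leaf()
            if nd.parent_node is not None:
                self.parent[i] = nd.parent_node._psidx
                el = nd.edge.length
                if el is None:
                    log.warning("branch above %s has no length; defaulting to 1.0",
                                nd._psid)
                    el = 1.0
                if el < 0:
                    raise TreeIOError(
                        f"negative branch length above {nd._psid}")
                self.brlen[i] = float(el)
        # dendropy postorder_node_iter already yields children before parents
        self.postorder = np.arange(n, dtype=np.int64)
        self.root = int(np.flatnonzero(self.parent == -1)[0])
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            if self.parent[i] >= 0:
                self.children[self.parent[i]].append(i)

    def _validate(self) -> None:
        if np.count_nonzero(self.parent == -1) != 1:
            raise TreeIOError("exactly one root required")
        tips = set(self.tip_labels)
        annotated = set(self.annotations.index)
        missing = tips - annotated
        if missing:
            raise TreeIOError(
                "missing annotation for tip(s): " + ", ".join(sorted(missing)))
        extra = annotated - tips
        if extra:
            raise TreeIOError(
                "annotation rows for unknown tip(s): " + ", ".join(sorted(extra)))

    # -- views -------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in np.flatnonzero(self.is_tip)]

    @property
    def tip_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_tip)

    def branches(self) -> list[Branch]:
        out = []
        for i in range(self.n_nodes):
            p = self.parent[i]
            if p >= 0:
                out.append(Branch(self.labels[i], self.labels[p],
                                  float(self.brlen[i]), bool(self.is_tip[i])))
        return out

    def annotation(self, species: str, column: str) -> str:
        return str(self.annotations.loc[species, column])

    def tip_column(self, column: str) -> dict[str, str]:
        """Mapping tip label -> annotation value for one column (cached)."""
        cache = getattr(self, "_tipcol_cache", None)
        if cache is None:
            cache = self._tipcol_cache = {}
        if column not in cache:
            col = self.annotations[column]
            cache[column] = {t: str(col[t]) for t in self.tip_labels}
        return cache[column]

    def preorder(self) -> np.ndarray:
        return self.postorder[::-1]

    def subtree_tips(self, node: int | str) -> list[str]:
        """Tip labels below (and including) a node."""
        if isinstance(node, str):
            node = self.index[node]
        below = np.zeros(self.n_nodes, dtype=bool)
        below[node] = True
        for i in self.preorder():
            p = self.parent[i]
            if p >= 0 and below[p]:
                below[i] = True
        return [self.labels[i] for i in np.flatnonzero(below & self.is_tip)]

    def mrca(self, tips: Iterable[str]) -> int:
        """Index of the most recent common ancestor of a set of tips."""
        want = set(tips)
        if not want:
            raise TreeIOError("mrca of empty tip set")
        count = np.zeros(self.n_nodes, dtype=np.int64)
        for i in self.postorder:
            if self.is_tip[i]:
                count[i] = 1 if self.labels[i] in want else 0
            if self.parent[i] >= 0:
                count[self.parent[i]] += count[i]
        full = len(want & set(self.tip_labels))
        for i in self.postorder:
            if count[i] == full:
                return int(i)
        return self.root

    def copy(self) -> "AnnotatedTree":
        return AnnotatedTree(self.dtree.clone(depth=1), self.annotations.copy())

    def __repr__(self) -> str:  # pragma: no cover
        return (f"AnnotatedTree({len(self.tip_labels)} tips, "
                f"{self.n_nodes} nodes)")


def _validate_annotations(annotations: pd.DataFrame) -> pd.DataFrame:
    df = annotations.copy()
    if df.index.name is None and "species" in df.columns:
        df = df.set_index("species")
    for col in ANNOTATION_COLUMNS:
        if col not in df.columns:
            raise TreeIOError(f"annotation table lacks column {col!r}")
    df = df[list(ANNOTATION_COLUMNS)]
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise TreeIOError(f"duplicate annotation rows for {dups}")
    df["lifestyle"] = df["lifestyle"].astype(str).str.strip().str.lower()
    bad = ~df["lifestyle"].isin(LIFESTYLES)
    if bad.any():
        raise TreeIOError(
            f"invalid lifestyle value(s): {sorted(df.loc[bad, 'lifestyle'].unique())}")
    cp = df["cell_plan"].astype(str).str.strip().str.lower()
    cp = cp.replace({"na": "unknown", "nan": "unknown", "": "unknown"})
    bad = ~cp.isin(CELL_PLANS)
    if bad.any():
        raise TreeIOError(
            f"invalid cell_plan value(s): {sorted(cp[bad].unique())}")
    df["cell_plan"] = cp
    df["phylum"] = df["phylum"].astype(str).str.strip()
    return df


def read_tree(tree_path: str | Path,
              annotation_path: str | Path) -> AnnotatedTree:
    """Read a rooted newick tree plus its tab-separated annotation table.

    The annotation table must have a header
    ``species<TAB>phylum<TAB>lifestyle<TAB>cell_plan`` (enum values are
    case-insensitive; ``unknown``/``NA`` accepted for cell_plan) and cover
    every tip exactly once.  An explicitly unrooted newick (``[&U]``) is
    rejected: gain/loss polarity and "ancestor" semantics depend on the root.
    """
    text = Path(tree_path).read_text()
    if "[&U]" in text.upper().replace(" ", ""):
        raise TreeIOError("rooted tree required (input flagged unrooted)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True, rooting="default-rooted")
    annotations = pd.read_csv(annotation_path, sep="\t", dtype=str)
    return AnnotatedTree(dtree, annotations)


def write_tree(tree: AnnotatedTree, tree_path: str | Path,
               annotation_path: str | Path | None = None) -> None:
    """Serialize tree (newick, lengths at full precision) and annotations."""
    s = tree.dtree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True,
        real_value_format_specifier=".10g")
    Path(tree_path).write_text(s.strip() + "\n")
    if annotation_path is not None:
        tree.annotations.to_csv(annotation_path, sep="\t",
                                index_label="species")


def from_newick(newick: str,
                annotations: pd.DataFrame | None = None) -> AnnotatedTree:
    """Build an AnnotatedTree from a newick string.

    If no annotation table is given, tips get placeholder annotations
    (phylum "unassigned", sympatric, unknown cell plan) — convenient for
    algorithm-level work where only the topology matters.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dtree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True, rooting="default-rooted")
    if annotations is None:
        tips = [lf.taxon.label for lf in dtree.leaf_node_iter()]
        annotations = pd.DataFrame(
            {"phylum": "unassigned", "lifestyle": "sympatric",
             "cell_plan": "unknown"}, index=pd.Index(tips, name="species"))
    return AnnotatedTree(dtree, annotations)
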