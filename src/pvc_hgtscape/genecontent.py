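"""Gene-family clustering and gain/loss event mapping on the species tree.

The stage that turns a protein-similarity graph into gene families
(Markov clustering), maps each family's phyletic pattern (presence/
absence across species) onto the rooted species tree as gain and loss
events by weighted parsimony, and aggregates per-species horizontal
gene transfer (HGT) quantities once the gains have been classified.

Event semantics: a gain on a terminal branch is *specific* (acquired by
a modern species); a gain on an internal branch — including a family
already present at the root, modelled as a gain on the root stem — is
*non-specific* (acquired by an ancestor).  Replaying a family's events
from the root must reproduce its tip pattern exactly; this conservation
law is enforced by ``replay_events`` and tested on every simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csgraph, csr_matrix

from .treeio import AnnotatedTree

ROOT_STEM = "@root_stem"

GAIN_COST_DEFAULT = 2.0
LOSS_COST_DEFAULT = 1.0

#: classification labels a gain may carry (filled in by the hit filter)
GAIN_CLASSES = ("HGT", "not_HGT", "ORFan", "unclassified")


class GeneContentError(ValueError):
    pass


# ---------------------------------------------------------------------------
# phyletic matrix
# ---------------------------------------------------------------------------

@dataclass
class PhyleticMatrix:
    """Binary families x species presence matrix with member-gene counts.

    ``presence`` is 0/1 (families as rows); ``gene_counts`` has the same
    shape and gives member genes per (family, species) — it defaults to
    ``presence`` (one gene per present family).  ``proteome_sizes`` is
    the per-species total gene count used as the denominator of HGT
    proportions; it defaults to the column sums of ``gene_counts``.
    """

    presence: pd.DataFrame
    gene_counts: pd.DataFrame | None = None
    proteome_sizes: pd.Series | None = None

    def __post_init__(self):
        pres = self.presence
        vals = pres.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise GeneContentError("presence matrix must be binary")
        self.presence = pres.astype(np.int8)
        if self.gene_counts is None:
            self.gene_counts = self.presence.astype(np.int64)
        else:
            self.gene_counts = self.gene_counts.reindex(
                index=pres.index, columns=pres.columns).fillna(0).astype(np.int64)
            if ((self.gene_counts.to_numpy() > 0) != (vals > 0)).any():
                raise GeneContentError(
                    "gene_counts support must match presence")
        if self.proteome_sizes is None:
            self.proteome_sizes = self.gene_counts.sum(axis=0)
        self.proteome_sizes = self.proteome_sizes.reindex(pres.columns)
        short = self.proteome_sizes < self.presence.sum(axis=0)
        if short.any():
            raise GeneContentError(
                f"proteome size below family count for "
                f"{list(self.proteome_sizes.index[short])}")

    @property
    def families(self) -> list[str]:
        return list(self.presence.index)

    @property
    def species(self) -> list[str]:
        return list(self.presence.columns)

    def to_tsv(self, path) -> None:
        self.presence.to_csv(path, sep="\t", index_label="family")

    @classmethod
    def from_tsv(cls, path, proteome_sizes: pd.Series | None = None
                 ) -> "PhyleticMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, proteome_sizes=proteome_sizes)


# ---------------------------------------------------------------------------
# Markov clustering of the similarity graph
# ---------------------------------------------------------------------------

def markov_cluster(adj: np.ndarray, inflation: float = 1.5,
                   expansion: int = 2, prune: float = 1e-6,
                   tol: float = 1e-9, max_iter: int = 1000) -> list[list[int]]:
    """Markov clustering (MCL) of a non-negative adjacency matrix.

    Column-normalizes the adjacency with self-loops, then alternates
    expansion (matrix power) and inflation (entrywise power, renormalize),
    pruning entries below ``prune``, until the flow matrix is stable to
    ``tol``.  Clusters are the connected components of the converged
    flow's support.
    """
    n = adj.shape[0]
    if n == 0:
        return []
    M = adj.astype(float).copy()
    if (M < 0).any():
        raise GeneContentError("similarity weights must be non-negative")
    np.fill_diagonal(M, np.maximum(M.diagonal(), 1.0))
    M /= M.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        new = np.linalg.matrix_power(M, expansion)
        new = new ** inflation
        new[new < prune] = 0.0
        colsum = new.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        new /= colsum
        delta = np.abs(new - M).max()
        M = new
        if delta < tol:
            break
    else:
        raise GeneContentError(
            f"MCL failed to converge in {max_iter} iterations "
            f"(residual {delta:.3g})")
    support = csr_matrix((M > prune) | (M.T > prune))
    ncomp, lab = csgraph.connected_components(support, directed=False)
    return [list(np.flatnonzero(lab == k)) for k in range(ncomp)]


def cluster_families(similarity: pd.DataFrame,
                     species: Sequence[str],
                     species_of: Mapping[str, str] | None = None,
                     inflation: float = 1.5,
                     proteome_sizes: pd.Series | None = None
                     ) -> PhyleticMatrix:
    """Group genes into families by MCL on a weighted similarity graph.

    ``similarity`` has columns ``gene_a, gene_b, weight``.  The species
    of origin is read from ``species_of`` or, failing that, parsed from
    the gene id as the text before the first ``|``.  Genes present in
    the graph but connected to nothing become singleton families.
    """
    genes = sorted(set(similarity["gene_a"]) | set(similarity["gene_b"]))
    idx = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    adj = np.zeros((n, n))
    for a, b, w in similarity[["gene_a", "gene_b", "weight"]].itertuples(
            index=False):
        if w < 0:
            raise GeneContentError(f"negative weight on edge {a}--{b}")
        i, j = idx[a], idx[b]
        adj[i, j] = max(adj[i, j], w)
        adj[j, i] = max(adj[j, i], w)

    def sp(gene: str) -> str:
        if species_of is not None:
            return species_of[gene]
        return gene.split("|", 1)[0]

    clusters = markov_cluster(adj, inflation=inflation)
    clusters.sort(key=lambda c: genes[min(c)])
    fam_ids = [f"F{k+1:05d}" for k in range(len(clusters))]
    counts = pd.DataFrame(0, index=fam_ids, columns=list(species),
                          dtype=np.int64)
    for fid, members in zip(fam_ids, clusters):
        for m in members:
            counts.loc[fid, sp(genes[m])] += 1
    presence = (counts > 0).astype(np.int8)
    return PhyleticMatrix(presence, gene_counts=counts,
                          proteome_sizes=proteome_sizes)


# ---------------------------------------------------------------------------
# event map + parsimony inference
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GainEvent:
    family: str
    branch_child: str          # node id below the gained branch; ROOT_STEM at root
    specific: bool             # terminal branch (modern species)?
    classification: str = "unclassified"


@dataclass
class EventMap:
    """Gains and losses per family, placed on branches of one tree."""
    gains: list[GainEvent]
    losses: list[tuple[str, str]]          # (family, branch_child)
    tree: AnnotatedTree = field(repr=False)

    def gains_of(self, family: str) -> list[GainEvent]:
        return [g for g in self.gains if g.family == family]

    def with_classifications(self, labels: Mapping[tuple[str, str], str]
                             ) -> "EventMap":
        """New EventMap with classifications set per (family, branch_child)."""
        new = [replace(g, classification=labels.get(
                   (g.family, g.branch_child), g.classification))
               for g in self.gains]
        return EventMap(new, list(self.losses), self.tree)

    def to_frame(self) -> pd.DataFrame:
        rows = [(g.family, g.branch_child, "gain",
                 "specific" if g.specific else "non_specific",
                 g.classification) for g in self.gains]
        rows += [(f, b, "loss", "", "") for f, b in self.losses]
        return pd.DataFrame(
            rows, columns=["family", "branch_child", "event_type",
                           "specificity", "classification"])


def infer_events(tree: AnnotatedTree, matrix: PhyleticMatrix,
                 gain_cost: float = GAIN_COST_DEFAULT,
                 loss_cost: float = LOSS_COST_DEFAULT,
                 dollo: bool = False) -> EventMap:
    """Map per-family gains/losses onto the tree from phyletic patterns.

    Default mode is Sankoff parsimony on the presence character with
    asymmetric costs (gain:loss = 2:1 — a gain is the rarer event); the
    family's root state participates in the same minimization via a
    virtual absent ancestor above the root, so a root-present family
    carries one (non-specific) gain on the root stem.  Cost ties are
    broken deterministically toward keeping the parent's state, which
    pushes gains tipward.  ``dollo=True`` instead allows exactly one
    gain per family (at the MRCA of its present tips) and places the
    minimal set of losses as early as possible.
    """
    if gain_cost <= 0 or loss_cost <= 0:
        raise GeneContentError("gain and loss costs must be positive")
    species = set(matrix.species)
    if species != set(tree.tip_labels):
        raise GeneContentError("matrix species set must equal tree tip set")
    empty = matrix.presence.sum(axis=1) == 0
    if empty.any():
        raise GeneContentError(
            f"families absent from every species: "
            f"{list(matrix.presence.index[empty])}")

    pres = matrix.presence.to_numpy()           # F x S
    fams = matrix.families
    tipcol = {s: j for j, s in enumerate(matrix.species)}
    F, n = len(fams), tree.n_nodes

    if dollo:
        state = _dollo_states(tree, matrix)
    else:
        state = _sankoff_states(tree, pres, tipcol, gain_cost, loss_cost)

    gains: list[GainEvent] = []
    losses: list[tuple[str, str]] = []
    root = tree.root
    for f in range(F):
        if state[f, root] == 1:
            gains.append(GainEvent(fams[f], ROOT_STEM, specific=False))
    for i in range(n):
        p = tree.parent[i]
        if p < 0:
            continue
        diff = state[:, i] != state[:, p]
        for f in np.flatnonzero(diff):
            if state[f, i] == 1:
                gains.append(GainEvent(fams[f], tree.labels[i],
                                       specific=bool(tree.is_tip[i])))
            else:
                losses.append((fams[f], tree.labels[i]))
    return EventMap(gains, losses, tree)


def _sankoff_states(tree: AnnotatedTree, pres: np.ndarray,
                    tipcol: Mapping[str, int],
                    gain_cost: float, loss_cost: float) -> np.ndarray:
    F = pres.shape[0]
    n = tree.n_nodes
    INF = 1e18
    S = np.zeros((F, n, 2))
    # cost of moving parent state sp -> child state sc
    step = np.array([[0.0, gain_cost], [loss_cost, 0.0]])
    for i in tree.postorder:
        if tree.is_tip[i]:
            obs = pres[:, tipcol[tree.labels[i]]]
            S[:, i, 0] = np.where(obs == 0, 0.0, INF)
            S[:, i, 1] = np.where(obs == 1, 0.0, INF)
        else:
            for s in (0, 1):
                tot = np.zeros(F)
                for c in tree.children[i]:
                    tot += np.minimum(S[:, c, 0] + step[s, 0],
                                      S[:, c, 1] + step[s, 1])
                S[:, i, s] = tot
    state = np.zeros((F, n), dtype=np.int8)
    root = tree.root
    # virtual absent ancestor above the root; tie prefers staying absent
    state[:, root] = np.where(
        S[:, root, 1] + gain_cost < S[:, root, 0], 1, 0)
    for i in tree.preorder():
        for c in tree.children[i]:
            sp = state[:, i]
            c0 = step[sp, 0] + S[:, c, 0]
            c1 = step[sp, 1] + S[:, c, 1]
            # tie-break: keep the parent's state (defers gains tipward)
            keep = np.where(sp == 0, c0 <= c1, c1 <= c0)
            state[:, c] = np.where(keep, sp, 1 - sp)
    return state


def _dollo_states(tree: AnnotatedTree, matrix: PhyleticMatrix) -> np.ndarray:
    pres = matrix.presence
    F, n = pres.shape[0], tree.n_nodes
    state = np.zeros((F, n), dtype=np.int8)
    # subtree present-tip counts per family x node
    count = np.zeros((F, n), dtype=np.int64)
    tipcol = {s: j for j, s in enumerate(matrix.species)}
    arr = pres.to_numpy()
    for i in tree.postorder:
        if tree.is_tip[i]:
            count[:, i] = arr[:, tipcol[tree.labels[i]]]
        if tree.parent[i] >= 0:
            count[:, tree.parent[i]] += count[:, i]
    for f in range(F):
        tot = count[f, tree.root]
        mrca = tree.mrca([s for s in matrix.species
                          if arr[f, tipcol[s]] == 1])
        inside = np.zeros(n, dtype=bool)
        inside[mrca] = True
        for i in tree.preorder():
            p = tree.parent[i]
            if p >= 0 and inside[p]:
                inside[i] = True
        state[f] = (inside & (count[f] > 0)).astype(np.int8)
    return state


def replay_events(events: EventMap, families: Sequence[str] | None = None
                  ) -> pd.DataFrame:
    """Tip presence implied by an event map (the conservation check).

    Walks each family's gains/losses from the root down; a gain sets the
    lineage present, a loss absent, otherwise the parent's state is
    inherited.  The result must equal the phyletic matrix the events
    were inferred from.
    """
    tree = events.tree
    fams = sorted({g.family for g in events.gains} |
                  {f for f, _ in events.losses})
    if families is not None:
        fams = list(families)
    gain_at: dict[str, set[str]] = {f: set() for f in fams}
    loss_at: dict[str, set[str]] = {f: set() for f in fams}
    for g in events.gains:
        gain_at.setdefault(g.family, set()).add(g.branch_child)
    for f, b in events.losses:
        loss_at.setdefault(f, set()).add(b)
    out = pd.DataFrame(0, index=pd.Index(fams, name="family"),
                       columns=tree.tip_labels, dtype=np.int8)
    state = np.zeros(tree.n_nodes, dtype=np.int8)
    for f in fams:
        state[:] = 0
        for i in tree.preorder():
            lbl = tree.labels[i]
            if i == tree.root:
                state[i] = 1 if ROOT_STEM in gain_at[f] else 0
            else:
                state[i] = state[tree.parent[i]]
            if lbl in gain_at[f]:
                state[i] = 1
            elif lbl in loss_at[f]:
                state[i] = 0
        for i in tree.tip_indices:
            out.loc[f, tree.labels[i]] = state[i]
    return out


# ---------------------------------------------------------------------------
# HGT summary
# ---------------------------------------------------------------------------

@dataclass
class HgtSummary:
    """Per-species HGT gene counts/proportions and per-branch gain counts."""
    per_species: pd.DataFrame
    per_branch: pd.Series

    def group_means(self, tree: AnnotatedTree, column: str) -> pd.Series:
        key = self.per_species.index.map(
            lambda s: tree.annotation(s, column))
        return self.per_species.groupby(key)["total_proportion"].mean()


def hgt_gene_flags(events: EventMap, matrix: PhyleticMatrix) -> pd.DataFrame:
    """Per-(family, species) HGT status of each present tip copy.

    Walking from the tip toward the root, the first event met on the
    path is the gain responsible for the tip's copy (a family gained
    then lost on the same lineage contributes nothing below the loss).
    Returns a families x species frame of strings: empty for a non-HGT
    or absent copy, ``"specific"`` / ``"nonspecific"`` for copies
    tracing back to an HGT-classified gain.
    """
    tree = events.tree
    for g in events.gains:
        if g.classification not in GAIN_CLASSES:
            raise GeneContentError(
                f"unclassified gain {g.family}@{g.branch_child}: "
                f"{g.classification!r}")
    species = matrix.species
    paths: dict[str, list[str]] = {}
    for i in tree.tip_indices:
        path, j = [], i
        while j >= 0:
            path.append(tree.labels[j])
            j = tree.parent[j]
        paths[tree.labels[i]] = path
    gains_by_family: dict[str, dict[str, GainEvent]] = {}
    for g in events.gains:
        gains_by_family.setdefault(g.family, {})[g.branch_child] = g
    losses_by_family: dict[str, set[str]] = {}
    for f, b in events.losses:
        losses_by_family.setdefault(f, set()).add(b)

    arr = matrix.presence.to_numpy()
    flags = pd.DataFrame("", index=matrix.presence.index, columns=species)
    for fi, fam in enumerate(matrix.families):
        fam_gains = gains_by_family.get(fam)
        if not fam_gains:
            continue
        fam_losses = losses_by_family.get(fam, set())
        for sj in np.flatnonzero(arr[fi]):
            sp = species[sj]
            responsible = None
            for b in paths[sp]:
                if b in fam_gains:
                    responsible = fam_gains[b]
                    break
                if b in fam_losses:
                    break
            else:
                responsible = fam_gains.get(ROOT_STEM)
            if responsible is not None and responsible.classification == "HGT":
                flags.iloc[fi, sj] = ("specific" if responsible.specific
                                      else "nonspecific")
    return flags


def summarize_hgt(events: EventMap, matrix: PhyleticMatrix) -> HgtSummary:
    """Aggregate classified gains into per-species HGT quantities.

    Counts sum member genes of HGT-flagged tip copies (see
    ``hgt_gene_flags``); proportions divide by proteome size; per-branch
    counts tally HGT-classified gains on each branch.
    """
    tree = events.tree
    species = matrix.species
    flags = hgt_gene_flags(events, matrix).to_numpy()
    counts = matrix.gene_counts.to_numpy()
    total = ((flags != "") * counts).sum(axis=0)
    specific = ((flags == "specific") * counts).sum(axis=0)

    branch_counts = pd.Series(0, index=pd.Index(
        [ROOT_STEM] + [tree.labels[i] for i in range(tree.n_nodes)
                       if tree.parent[i] >= 0], name="branch_child"),
        dtype=np.int64)
    for g in events.gains:
        if g.classification == "HGT":
            branch_counts.loc[g.branch_child] += 1

    out = pd.DataFrame(
        {"total_hgt": total, "specific_hgt": specific,
         "nonspecific_hgt": total - specific,
         "proteome_size": matrix.proteome_sizes.to_numpy()},
        index=pd.Index(species, name="species"))
    size = out["proteome_size"].astype(float)
    out["total_proportion"] = out["total_hgt"] / size
    out["specific_proportion"] = out["specific_hgt"] / size
    out["nonspecific_proportion"] = out["nonspecific_hgt"] / size
    return HgtSummary(out, branch_counts)
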