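"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — exhaustive enumeration over all
internal labelings, literal rule transcriptions — and shares no code
with the package's implementations.
"""

from __future__ import annotations

from itertools import product

import numpy as np

from pvc_hgtscape.treeio import AnnotatedTree, from_newick


# ---------------------------------------------------------------------------
# random rooted trees
# ---------------------------------------------------------------------------

def random_tree(rng: np.random.Generator, n_tips: int,
                max_len: float = 2.0) -> AnnotatedTree:
    """Random rooted binary tree by sequential joining, random lengths."""
    parts = [f"T{i}" for i in range(n_tips)]
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        b = parts.pop(j)
        a = parts.pop(i)
        la, lb = rng.uniform(0.05, max_len, 2)
        parts.append(f"({a}:{la:.4f},{b}:{lb:.4f})")
    return from_newick(parts[0] + ";")


def random_tip_states(rng: np.random.Generator, tree: AnnotatedTree,
                      p_unknown: float = 0.0) -> dict[str, object]:
    out = {}
    for t in tree.tip_labels:
        if rng.uniform() < p_unknown:
            out[t] = "unknown"
        else:
            out[t] = int(rng.integers(0, 2))
    # guarantee at least one known tip
    first = tree.tip_labels[0]
    if all(v == "unknown" for v in out.values()):
        out[first] = int(rng.integers(0, 2))
    return out


# ---------------------------------------------------------------------------
# exhaustive parsimony
# ---------------------------------------------------------------------------

def _labelings(tree: AnnotatedTree, tip_states: dict[str, object]):
    """Yield full 0/1 labelings consistent with the (possibly unknown)
    tip states, as arrays over node indices."""
    free = []     # internal nodes and unknown tips
    fixed = {}
    for i in range(tree.n_nodes):
        if tree.is_tip[i]:
            s = tip_states[tree.labels[i]]
            if s == "unknown":
                free.append(i)
            else:
                fixed[i] = int(s)
        else:
            free.append(i)
    for combo in product((0, 1), repeat=len(free)):
        lab = np.zeros(tree.n_nodes, dtype=int)
        for i, s in fixed.items():
            lab[i] = s
        for i, s in zip(free, combo):
            lab[i] = s
        yield lab


def exhaustive_parsimony(tree: AnnotatedTree, tip_states: dict[str, object]):
    """(min change count, per-node optimal state sets, optimal change
    branches) by enumerating every full labeling."""
    best = None
    sets = {lbl: set() for lbl in tree.labels}
    branches = set()
    optimal = []
    for lab in _labelings(tree, tip_states):
        changes = sum(int(lab[i] != lab[tree.parent[i]])
                      for i in range(tree.n_nodes) if tree.parent[i] >= 0)
        if best is None or changes < best:
            best = changes
            optimal = [lab.copy()]
        elif changes == best:
            optimal.append(lab.copy())
    for lab in optimal:
        for i in range(tree.n_nodes):
            sets[tree.labels[i]].add(int(lab[i]))
            p = tree.parent[i]
            if p >= 0 and lab[i] != lab[p]:
                branches.add((tree.labels[i], int(lab[p]), int(lab[i])))
    return best, {k: frozenset(v) for k, v in sets.items()}, branches


def exhaustive_gain_loss(tree: AnnotatedTree, pattern: dict[str, int],
                         gain_cost: float, loss_cost: float) -> float:
    """Minimal weighted gain/loss cost over all ancestral labelings,
    including the virtual absent ancestor above the root."""
    best = np.inf
    for lab in _labelings(tree, pattern):
        # virtual root stem: a present root is one gain
        cost = gain_cost if lab[tree.root] == 1 else 0.0
        for i in range(tree.n_nodes):
            p = tree.parent[i]
            if p < 0:
                continue
            if lab[p] == 0 and lab[i] == 1:
                cost += gain_cost
            elif lab[p] == 1 and lab[i] == 0:
                cost += loss_cost
        best = min(best, cost)
    return best


# ---------------------------------------------------------------------------
# exhaustive Mk likelihood / marginals
# ---------------------------------------------------------------------------

def _transition(q01: float, q10: float, t: float) -> np.ndarray:
    Q = np.array([[-q01, q01], [q10, -q10]])
    # series exponential, independent of the package's closed form
    P = np.eye(2)
    term = np.eye(2)
    for k in range(1, 60):
        term = term @ (Q * t) / k
        P = P + term
    return P


def exhaustive_mk(tree: AnnotatedTree, tip_states: dict[str, object],
                  q01: float, q10: float, prior=(0.5, 0.5)):
    """(likelihood, per-node marginal P(state=1)) by direct summation."""
    total = 0.0
    node_mass = np.zeros((tree.n_nodes, 2))
    for lab in _labelings(tree, tip_states):
        w = prior[lab[tree.root]]
        for i in range(tree.n_nodes):
            p = tree.parent[i]
            if p < 0:
                continue
            P = _transition(q01, q10, float(tree.brlen[i]))
            w *= P[lab[p], lab[i]]
        total += w
        for i in range(tree.n_nodes):
            node_mass[i, lab[i]] += w
    marg = node_mass / total
    return total, marg


# ---------------------------------------------------------------------------
# literal transcription of the hit-filtering rules
# ---------------------------------------------------------------------------

def brute_force_classify(rows: list[dict], self_phyla: set[str],
                         sister_phyla: set[str], top_n: int = 10) -> str:
    """Re-evaluate the HGT rule from its printed wording, step by step."""
    # order the blast report: best e-value first; tie -> higher identity,
    # then species name
    report = sorted(rows, key=lambda r: (r["evalue"], -r["identity"],
                                         r["subject_species"]))
    # step 1: remove sequences derived from the phylum of the gain
    report = [r for r in report if r["subject_phylum"] not in self_phyla]
    # step 2: remove on e-value > 1e-5, coverage < 60 or identity < 30
    report = [r for r in report
              if not (r["evalue"] > 1e-5 or r["query_coverage"] < 60
                      or r["identity"] < 30)]
    if not report:
        return "unclassified"
    # step 3: species of the first ten remaining sequences
    species = []
    phyla_of = {}
    for r in report[:top_n]:
        if r["subject_species"] not in species:
            species.append(r["subject_species"])
        phyla_of[r["subject_species"]] = r["subject_phylum"]
    # step 4: HGT iff none belongs to a sister phylum
    for s in species:
        if phyla_of[s] in sister_phyla:
            return "not_HGT"
    return "HGT"


def brute_force_orfan(rows: list[dict]) -> bool:
    for r in rows:
        if r["evalue"] < 1e-4 and r["query_coverage"] > 50:
            return False
    return True


# ---------------------------------------------------------------------------
# MCL fixed point
# ---------------------------------------------------------------------------

def mcl_fixed_point(adj: np.ndarray, inflation: float) -> list[set[int]]:
    """Straight fixed-point iteration of expansion/inflation."""
    M = adj.astype(float).copy()
    np.fill_diagonal(M, np.maximum(M.diagonal(), 1.0))
    M = M / M.sum(axis=0)
    for _ in range(10000):
        N = M @ M
        N = N ** inflation
        N[N < 1e-6] = 0
        s = N.sum(axis=0)
        s[s == 0] = 1
        N = N / s
        if np.abs(N - M).max() < 1e-12:
            M = N
            break
        M = N
    link = (M > 1e-6) | (M.T > 1e-6)
    n = adj.shape[0]
    seen, comps = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            j = stack.pop()
            if j in comp:
                continue
            comp.add(j)
            stack.extend(k for k in range(n) if link[j, k] and k not in comp)
        seen |= comp
        comps.append(comp)
    return comps
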