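"""Rule-based classification of gene gains as HGT, ORFan or unclassified.

A gain mapped onto the species tree is interrogated against the ranked
homology hits of a member gene.  Two printed rule sets drive the calls,
encoded with their exact inequality senses:

* **ORFan rule** — a gene is an ORFan iff it has *no* hit with
  e-value < 1e-4 AND query coverage > 50% (strict inequalities).

* **HGT rule** — (1) hits from the phylum where the gain occurred are
  removed; (2) hits with e-value > 1e-5 OR coverage < 60% OR identity
  < 30% are removed (boundary values are kept); (3) the species of the
  first ten remaining hits are inspected; (4) the gain is an HGT iff
  none of them belongs to a sister phylum of the gaining lineage.
  Fewer than ten survivors: all are inspected; zero survivors: the gain
  stays unclassified (no evidence either way).

Sister phyla are derived from the annotated species tree: the phyla of
the tips in the sibling subtree(s) of the focal phylum's MRCA (walking
rootward until at least one foreign phylum is found).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .treeio import AnnotatedTree
from .genecontent import ROOT_STEM

HIT_COLUMNS = ("query", "subject_species", "subject_phylum",
               "evalue", "query_coverage", "identity")


class HitTableError(ValueError):
    pass


@dataclass(frozen=True)
class FilterPolicy:
    """Thresholds of the homology-filtering rules, defaulting to the
    published values (ORFan: e-value 1e-4 / coverage 50; HGT filter:
    e-value 1e-5 / coverage 60 / identity 30; ten inspected hits)."""
    orfan_evalue_max: float = 1e-4
    orfan_coverage_min: float = 50.0
    hgt_evalue_max: float = 1e-5
    hgt_coverage_min: float = 60.0
    hgt_identity_min: float = 30.0
    top_n: int = 10
    self_phyla: frozenset[str] = frozenset()
    sister_phyla: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        for v in (self.orfan_evalue_max, self.hgt_evalue_max,
                  self.orfan_coverage_min, self.hgt_coverage_min,
                  self.hgt_identity_min):
            if v < 0:
                raise ValueError("thresholds must be non-negative")

    def for_lineage(self, self_phyla, sister_phyla) -> "FilterPolicy":
        return replace(self, self_phyla=frozenset(self_phyla),
                       sister_phyla=frozenset(sister_phyla))


def _rank_order(evalue: np.ndarray, identity: np.ndarray,
                species: np.ndarray) -> np.ndarray:
    # last lexsort key is primary: e-value asc, identity desc, species asc
    return np.lexsort((species, -identity, evalue))


def _validate_table(hits: pd.DataFrame) -> None:
    for col in HIT_COLUMNS:
        if col not in hits.columns:
            raise HitTableError(f"hit table lacks column {col!r}")
    phyl = hits["subject_phylum"].to_numpy(dtype=object)
    bad = np.array([p is None or (isinstance(p, float) and np.isnan(p))
                    or str(p).strip() == "" for p in phyl])
    if bad.any():
        raise HitTableError(
            "hit(s) with unknown subject phylum (taxonomy map incomplete): "
            + ", ".join(hits.loc[bad, "subject_species"].astype(str).head(5)))


def rank_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """Deterministic hit ranking: ascending e-value, ties by descending
    identity, then by subject species name for full determinism."""
    _validate_table(hits)
    order = _rank_order(hits["evalue"].to_numpy(float),
                        hits["identity"].to_numpy(float),
                        hits["subject_species"].to_numpy(str))
    out = hits.iloc[order].reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def orfan_test(hits: pd.DataFrame, policy: FilterPolicy = FilterPolicy()
               ) -> bool:
    """True iff the gene has no identifiable homolog.

    No hit may satisfy e-value < ``orfan_evalue_max`` AND coverage >
    ``orfan_coverage_min`` (both strict, as the rule is printed; a hit
    at exactly coverage 50 does not rescue the gene from ORFan status).
    """
    if len(hits) == 0:
        return True
    ok = ((hits["evalue"] < policy.orfan_evalue_max) &
          (hits["query_coverage"] > policy.orfan_coverage_min))
    return not bool(ok.any())


def filtered_hits(hits: pd.DataFrame, policy: FilterPolicy) -> pd.DataFrame:
    """Apply self-phylum removal and the quality filter, then re-rank."""
    if len(hits) == 0:
        return hits.assign(rank=pd.Series(dtype=int))
    ranked = rank_hits(hits)
    keep = ~ranked["subject_phylum"].isin(policy.self_phyla)
    # removal on e-value > max OR coverage < min OR identity < min
    keep &= ~((ranked["evalue"] > policy.hgt_evalue_max) |
              (ranked["query_coverage"] < policy.hgt_coverage_min) |
              (ranked["identity"] < policy.hgt_identity_min))
    out = ranked[keep].reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def _classify_arrays(ev: np.ndarray, cov: np.ndarray, ident: np.ndarray,
                     phyl: np.ndarray, spec: np.ndarray,
                     policy: FilterPolicy) -> tuple[str, np.ndarray]:
    """Core of the HGT rule on plain arrays; returns (label, window idx)."""
    order = _rank_order(ev, ident, spec)
    keep = (~np.isin(phyl[order], list(policy.self_phyla)) &
            (ev[order] <= policy.hgt_evalue_max) &
            (cov[order] >= policy.hgt_coverage_min) &
            (ident[order] >= policy.hgt_identity_min))
    surv = order[keep]
    if surv.size == 0:
        return "unclassified", surv
    window = surv[:policy.top_n]
    if np.isin(phyl[window], list(policy.sister_phyla)).any():
        return "not_HGT", window
    if not policy.sister_phyla:
        # no sister phyla defined (a gain spanning the whole study
        # clade): the veto cannot run, so an HGT call has no support
        return "unclassified", window
    return "HGT", window


def classify_gain(hits: pd.DataFrame, policy: FilterPolicy) -> str:
    """Classify one gain as ``HGT``, ``not_HGT`` or ``unclassified``.

    The species of the first ``top_n`` surviving hits are inspected
    (duplicate species count once, which cannot change the verdict);
    the gain is HGT iff none of them belongs to a sister phylum.  Zero
    surviving hits yield ``unclassified`` — an HGT call needs positive
    evidence.
    """
    if len(hits) == 0:
        return "unclassified"
    _validate_table(hits)
    label, _ = _classify_arrays(
        hits["evalue"].to_numpy(float),
        hits["query_coverage"].to_numpy(float),
        hits["identity"].to_numpy(float),
        hits["subject_phylum"].to_numpy(object),
        hits["subject_species"].to_numpy(str), policy)
    return label


def assign_partner(hits: pd.DataFrame, policy: FilterPolicy) -> str:
    """Most frequent phylum among the retained top-N hits of an HGT gain;
    ties go to the best-ranked hit's phylum."""
    surv = filtered_hits(hits, policy).head(policy.top_n)
    if len(surv) == 0:
        raise HitTableError("cannot assign a partner with no surviving hits")
    counts = surv["subject_phylum"].value_counts()
    top = counts[counts == counts.max()].index
    if len(top) == 1:
        return str(top[0])
    for phylum in surv["subject_phylum"]:
        if phylum in set(top):
            return str(phylum)
    return str(top[0])  # pragma: no cover


# ---------------------------------------------------------------------------
# lineage context from the species tree
# ---------------------------------------------------------------------------

def lineage_context(tree: AnnotatedTree, branch_child: str
                    ) -> tuple[frozenset[str], frozenset[str]]:
    """(self phyla, sister phyla) for a gain on a given branch.

    Self phyla are the phyla of the tips below the gained branch.  The
    sister set contains the phyla (outside the self set) of the sibling
    subtree(s), walking rootward until a foreign phylum appears.  A gain
    on the root stem has every study phylum as self and no sisters.
    """
    phyla = tree.tip_column("phylum")
    if branch_child == ROOT_STEM:
        return frozenset(phyla.values()), frozenset()
    node = tree.index[branch_child]
    self_phyla = frozenset(phyla[t] for t in tree.subtree_tips(node))
    sisters: set[str] = set()
    cur = node
    while tree.parent[cur] >= 0 and not sisters:
        parent = tree.parent[cur]
        for sib in tree.children[parent]:
            if sib == cur:
                continue
            sisters.update(phyla[t] for t in tree.subtree_tips(sib)
                           if phyla[t] not in self_phyla)
        cur = parent
    return self_phyla, frozenset(sisters)


def classify_event_map(events, hit_tables: dict[str, pd.DataFrame],
                       representative: dict[tuple[str, str], str],
                       policy: FilterPolicy = FilterPolicy()):
    """Classify every gain of an EventMap from per-gene hit tables.

    ``representative`` maps (family, branch_child) to the gene id whose
    hit table stands for that gain; a gain without a representative or
    whose gene is an ORFan is labelled accordingly.  Returns a new
    EventMap plus a per-gain partner table for the HGT calls.
    """
    labels: dict[tuple[str, str], str] = {}
    partners: list[tuple[str, str, str]] = []
    ctx_cache: dict[str, tuple[frozenset[str], frozenset[str]]] = {}
    for g in events.gains:
        key = (g.family, g.branch_child)
        gene = representative.get(key)
        hits = hit_tables.get(gene) if gene is not None else None
        if g.branch_child not in ctx_cache:
            ctx_cache[g.branch_child] = lineage_context(
                events.tree, g.branch_child)
        self_p, sister_p = ctx_cache[g.branch_child]
        pol = policy.for_lineage(self_p, sister_p)
        if hits is None or len(hits) == 0:
            labels[key] = "ORFan"
            continue
        ev = hits["evalue"].to_numpy(float)
        cov = hits["query_coverage"].to_numpy(float)
        ident = hits["identity"].to_numpy(float)
        phyl = hits["subject_phylum"].to_numpy(object)
        spec = hits["subject_species"].to_numpy(str)
        if not ((ev < pol.orfan_evalue_max) &
                (cov > pol.orfan_coverage_min)).any():
            labels[key] = "ORFan"
            continue
        label, window = _classify_arrays(ev, cov, ident, phyl, spec, pol)
        labels[key] = label
        if label == "HGT":
            vals, counts = np.unique(np.asarray(phyl[window], dtype=str),
                                     return_counts=True)
            top = set(vals[counts == counts.max()])
            partner = next(str(p) for p in phyl[window] if str(p) in top)
            partners.append((g.family, g.branch_child, partner))
    classified = events.with_classifications(labels)
    partner_df = pd.DataFrame(
        partners, columns=["family", "branch_child", "partner_phylum"])
    return classified, partner_df
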