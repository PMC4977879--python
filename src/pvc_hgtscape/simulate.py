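"""Synthetic gene-content evolution with ground truth.

Generates every input the analysis consumes — phyletic matrices, ranked
homology-hit tables, a binary cell-plan character and mobilome count
tables — from an explicit generative model on the species tree, keeping
a complete event log so recovery can be scored against truth.

The gene-content model: a pool of root families is carried down the
tree; on each branch, events are placed at exponential/Poisson times
(Gillespie-style, so a loss can follow a gain on the same branch):

* losses — each extant family draws an exponential waiting time at rate
  ``rate_loss``;
* originations — new families appear as a Poisson process at rate
  ``rate_origination`` (de novo genes: downstream they look like ORFans);
* transfers-in — a Poisson process at rate ``rate_transfer`` scaled by
  the branch's lifestyle multiplier (allopatric lineages, isolated from
  other microorganisms, exchange less).  With probability
  ``external_donor_fraction`` the donor lies outside the study clade
  (a genuinely new family whose homologs are foreign — a true HGT);
  otherwise an existing clade family is copied in.

Every present gene copy at a tip carries its true origin tag (vertical /
de-novo / internal transfer / external transfer with donor taxon), which
is what the hit-table generator conditions on and what recovery tests
score against.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .treeio import AnnotatedTree
from .genecontent import PhyleticMatrix, ROOT_STEM
from . import hgtfilter

EXTERNAL_TAXA_DEFAULT = ("Firmicutes", "Proteobacteria", "Actinobacteria",
                         "Bacteroidetes", "Cyanobacteria")

MOBILOME_CLASSES = ("phages_complete", "phages_incomplete",
                    "conjugation_genes", "plasmids", "transposases",
                    "integrases", "crispr_candidate", "crispr_confirmed",
                    "trna")

#: baseline per-genome expected counts for the nine element classes
MOBILOME_BASELINE = {
    "phages_complete": 1.5, "phages_incomplete": 3.0,
    "conjugation_genes": 20.0, "plasmids": 1.0, "transposases": 30.0,
    "integrases": 12.0, "crispr_candidate": 2.0, "crispr_confirmed": 1.0,
    "trna": 45.0,
}


@dataclass
class SimConfig:
    """Knobs of the generative model.  All rates are events per unit
    branch length; the same seed always yields identical output."""
    seed: int = 0
    n_root_families: int = 600
    rate_origination: float = 25.0
    rate_loss: float = 0.4
    rate_transfer: float = 30.0
    external_donor_fraction: float = 0.75
    lifestyle_rate_multipliers: dict = field(
        default_factory=lambda: {"sympatric": 1.0, "allopatric": 0.2})
    external_taxa: tuple = EXTERNAL_TAXA_DEFAULT
    # binary cell-plan character (1 = compartmentalized)
    character_q01: float = 0.05
    character_q10: float = 0.3
    character_root_state: int = 1
    unknown_fraction: float = 0.0
    # hit tables
    mean_hits: int = 12
    hit_phylum_noise: float = 0.05
    # mobilome
    mobilome_means: dict = field(
        default_factory=lambda: dict(MOBILOME_BASELINE))
    mobilome_lifestyle_multipliers: dict = field(default_factory=dict)
    proteome_mean: float = 2500.0
    proteome_sd: float = 250.0

    def __post_init__(self):
        for r in (self.rate_origination, self.rate_loss, self.rate_transfer,
                  self.character_q01, self.character_q10):
            if r < 0:
                raise ValueError("rates must be non-negative")
        for p in (self.external_donor_fraction, self.unknown_fraction,
                  self.hit_phylum_noise):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class FamilyRecord:
    family: str
    origin_branch: str      # ROOT_STEM or branch child label
    origin_kind: str        # root | de_novo | hgt_external | hgt_internal
    donor: str | None
    events: list = field(default_factory=list)  # (branch, type, donor, time)


@dataclass
class TrueEventLog:
    """Complete simulation truth: one origination per family, all
    subsequent losses/transfers, and the origin tag of every tip copy."""
    records: dict[str, FamilyRecord]
    copy_origin: dict[tuple[str, str], tuple[str, str | None]]
    tree: AnnotatedTree = field(repr=False)

    def external_transfers(self) -> list[tuple[str, str]]:
        """(family, branch_child) of every external-donor arrival."""
        out = []
        for rec in self.records.values():
            if rec.origin_kind == "hgt_external":
                out.append((rec.family, rec.origin_branch))
            for b, typ, donor, _t in rec.events:
                if typ == "transfer_in" and donor is not None \
                        and donor.startswith("external:"):
                    out.append((rec.family, b))
        return out

    def hgt_truth(self, matrix: PhyleticMatrix) -> pd.DataFrame:
        """Boolean families x species frame: tip copy descends from an
        external transfer (the positive class of recovery scoring)."""
        truth = pd.DataFrame(False, index=matrix.presence.index,
                             columns=matrix.presence.columns)
        for (sp, fam), (tag, _donor) in self.copy_origin.items():
            if tag == "external" and fam in truth.index:
                truth.loc[fam, sp] = True
        return truth

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records.values():
            rows.append((rec.family, rec.origin_branch, "origination",
                         rec.origin_kind, rec.donor or "", 0.0))
            for b, typ, donor, t in rec.events:
                rows.append((rec.family, b, typ, "", donor or "", t))
        return pd.DataFrame(rows, columns=[
            "family", "branch_child", "event", "origin_kind", "donor",
            "time"])


def _branch_lifestyle(tree: AnnotatedTree) -> dict[int, str]:
    """Lifestyle attached to each branch: the lifestyle shared by every
    descendant tip, else 'sympatric' (the baseline) for mixed clades."""
    styles = tree.tip_column("lifestyle")
    out: dict[int, str] = {}
    below: dict[int, set[str]] = {}
    for i in tree.postorder:
        if tree.is_tip[i]:
            below[i] = {styles[tree.labels[i]]}
        else:
            below[i] = set().union(*(below[c] for c in tree.children[i]))
        out[i] = next(iter(below[i])) if len(below[i]) == 1 else "sympatric"
    return out


def simulate_gene_content(tree: AnnotatedTree, cfg: SimConfig,
                          rng: np.random.Generator | None = None
                          ) -> tuple[PhyleticMatrix, TrueEventLog]:
    """Evolve gene families along the tree; return matrix plus truth."""
    if tree.n_nodes == 0:
        raise ValueError("empty tree")
    rng = cfg.rng() if rng is None else rng
    styles = _branch_lifestyle(tree)
    records: dict[str, FamilyRecord] = {}
    counter = 0

    def new_family(branch: str, kind: str, donor: str | None) -> str:
        nonlocal counter
        counter += 1
        fid = f"F{counter:05d}"
        records[fid] = FamilyRecord(fid, branch, kind, donor)
        return fid

    root_families = [new_family(ROOT_STEM, "root", None)
                     for _ in range(cfg.n_root_families)]
    # per node: {family: origin tag of the current copy}
    present: dict[int, dict[str, tuple[str, str | None]]] = {
        tree.root: {f: ("vertical", None) for f in root_families}}

    for i in tree.preorder():
        if i == tree.root:
            continue
        p = tree.parent[i]
        L = float(tree.brlen[i])
        mult = cfg.lifestyle_rate_multipliers.get(styles[i], 1.0)
        label = tree.labels[i]
        state = dict(present[p])

        # event queue processed in true chronological order so that a
        # loss can precede or follow an arrival on the same branch
        queue: list[tuple[float, int, str, object]] = []
        tick = 0

        def push(t, kind, payload):
            nonlocal tick
            heapq.heappush(queue, (t, tick, kind, payload))
            tick += 1

        def loss_time(after: float) -> float:
            if cfg.rate_loss <= 0:
                return np.inf
            return after + rng.exponential(1.0 / cfg.rate_loss)

        for fam in sorted(state):
            t = loss_time(0.0)
            if t < L:
                push(t, "loss", fam)
        n_orig = rng.poisson(cfg.rate_origination * L)
        for t in np.sort(rng.uniform(0, L, n_orig)):
            push(float(t), "origination", None)
        n_tr = rng.poisson(cfg.rate_transfer * mult * L)
        for t in np.sort(rng.uniform(0, L, n_tr)):
            push(float(t), "transfer", None)

        while queue:
            t0, _, kind, payload = heapq.heappop(queue)
            if kind == "loss":
                fam = payload
                if fam in state:
                    del state[fam]
                    records[fam].events.append((label, "loss", None,
                                                float(t0)))
                continue
            if kind == "origination":
                fid = new_family(label, "de_novo", None)
                state[fid] = ("de_novo", None)
            else:  # transfer
                if rng.uniform() < cfg.external_donor_fraction:
                    donor = "external:" + str(rng.choice(cfg.external_taxa))
                    fid = new_family(label, "hgt_external", donor)
                    state[fid] = ("external", donor)
                else:
                    # donors restricted to clade-born families so that a
                    # copy's horizontal/vertical status stays well defined
                    pool = sorted(f for f, r in records.items()
                                  if r.origin_kind != "hgt_external")
                    if not pool:
                        continue  # nothing in the clade to transfer yet
                    fid = str(rng.choice(pool))
                    if fid in state:
                        # redundant arrival: invisible to the matrix, logged
                        records[fid].events.append(
                            (label, "transfer_in_noop", "internal", t0))
                        continue
                    records[fid].events.append(
                        (label, "transfer_in", "internal", t0))
                    state[fid] = ("internal", "internal")
            t = loss_time(t0)
            if t < L:
                push(t, "loss", fid)
        present[i] = state

    fams = sorted(records)
    fidx = {f: k for k, f in enumerate(fams)}
    species = tree.tip_labels
    arr = np.zeros((len(fams), len(species)), dtype=np.int8)
    copy_origin: dict[tuple[str, str], tuple[str, str | None]] = {}
    for j, i in enumerate(tree.tip_indices):
        sp = tree.labels[i]
        for fam, tag in present[i].items():
            arr[fidx[fam], j] = 1
            copy_origin[(sp, fam)] = tag
    pres = pd.DataFrame(arr, index=pd.Index(fams, name="family"),
                        columns=species)
    pres = pres.loc[pres.sum(axis=1) > 0]  # drop families that died out
    matrix = PhyleticMatrix(pres)
    log = TrueEventLog(records, copy_origin, tree)
    return matrix, log


# ---------------------------------------------------------------------------
# binary character
# ---------------------------------------------------------------------------

def simulate_character(tree: AnnotatedTree, cfg: SimConfig,
                       rng: np.random.Generator | None = None
                       ) -> dict[str, str]:
    """Two-state Markov chain down the tree; returns tip cell plans
    ('compartmentalized'/'non_compartmentalized'/'unknown')."""
    from .ancestral import MkModel
    rng = cfg.rng() if rng is None else rng
    model = MkModel(cfg.character_q01, cfg.character_q10)
    state = np.zeros(tree.n_nodes, dtype=np.int64)
    state[tree.root] = cfg.character_root_state
    for i in tree.preorder():
        if i == tree.root:
            continue
        P = model.transition(tree.brlen[i])
        state[i] = rng.choice(2, p=P[state[tree.parent[i]]])
    names = {1: "compartmentalized", 0: "non_compartmentalized"}
    out = {tree.labels[i]: names[state[i]] for i in tree.tip_indices}
    if cfg.unknown_fraction > 0:
        tips = sorted(out)
        n_mask = int(round(cfg.unknown_fraction * len(tips)))
        for t in rng.choice(tips, size=n_mask, replace=False):
            out[str(t)] = "unknown"
    return out


# ---------------------------------------------------------------------------
# hit tables
# ---------------------------------------------------------------------------

def gene_id(species: str, family: str) -> str:
    return f"{species}|{family}"


def simulate_hit_table(matrix: PhyleticMatrix, log: TrueEventLog,
                       cfg: SimConfig,
                       genes: list[tuple[str, str]] | None = None,
                       rng: np.random.Generator | None = None
                       ) -> dict[str, pd.DataFrame]:
    """Ranked homology-hit tables conditioned on each copy's true origin.

    External-transfer copies draw their hits from external donor taxa;
    vertical and internal-transfer copies from their own and sister
    phyla; de novo copies get no qualifying hits (ORFans).  True
    homologs fall inside the quality thresholds, decoys outside.  With
    ``hit_phylum_noise`` > 0, each hit's phylum is swapped for a random
    one with that probability (mislabelled taxonomy).

    ``genes`` restricts generation to selected (species, family) copies;
    the default generates one table for every present copy.
    """
    tree = log.tree
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    phyla = tree.tip_column("phylum")
    study_phyla = sorted(set(phyla.values()))
    all_phyla = study_phyla + sorted(cfg.external_taxa)
    sisters_of: dict[str, list[str]] = {}
    for t in tree.tip_labels:
        _self, sis = hgtfilter.lineage_context(tree, t)
        fallback = [p for p in study_phyla if p != phyla[t]]
        sisters_of[t] = sorted(sis) or fallback

    if genes is None:
        arr = matrix.presence.to_numpy()
        genes = [(sp, fam)
                 for fi, fam in enumerate(matrix.families)
                 for sj, sp in enumerate(matrix.species) if arr[fi, sj]]

    out: dict[str, pd.DataFrame] = {}
    for sp, fam in genes:
        tag, donor = log.copy_origin.get((sp, fam), ("vertical", None))
        rows = []
        if tag == "de_novo":
            for _ in range(int(rng.integers(0, 3))):
                rows.append(_junk_hit(rng, all_phyla))
        else:
            n = max(5, int(rng.poisson(cfg.mean_hits)))
            if tag == "external":
                donor_taxon = donor.split(":", 1)[1]
                others = [p for p in cfg.external_taxa if p != donor_taxon]
                for _ in range(n):
                    ph = donor_taxon if (rng.uniform() < 0.7 or not others) \
                        else str(rng.choice(others))
                    rows.append(_good_hit(rng, ph))
            else:
                own, sis = phyla[sp], sisters_of[sp]
                for k in range(n):
                    ph = own if rng.uniform() < 0.4 else str(rng.choice(sis))
                    rows.append(_good_hit(rng, ph))
        if cfg.hit_phylum_noise > 0:
            for r in rows:
                if rng.uniform() < cfg.hit_phylum_noise:
                    r["subject_phylum"] = str(rng.choice(all_phyla))
                    r["subject_species"] = (r["subject_phylum"] + "_sp" +
                                            str(int(rng.integers(1, 500))))
        gid = gene_id(sp, fam)
        df = pd.DataFrame(rows, columns=list(hgtfilter.HIT_COLUMNS))
        df["query"] = gid
        out[gid] = hgtfilter.rank_hits(df) if len(df) else df
    return out


def _good_hit(rng, phylum: str) -> dict:
    return {"query": "", "subject_phylum": phylum,
            "subject_species": f"{phylum}_sp{int(rng.integers(1, 500))}",
            "evalue": float(10.0 ** rng.uniform(-80, -20)),
            "query_coverage": float(rng.uniform(65, 100)),
            "identity": float(rng.uniform(35, 95))}


def _junk_hit(rng, all_phyla) -> dict:
    phylum = str(rng.choice(all_phyla))
    return {"query": "", "subject_phylum": phylum,
            "subject_species": f"{phylum}_sp{int(rng.integers(1, 500))}",
            "evalue": float(10.0 ** rng.uniform(-3, 1)),
            "query_coverage": float(rng.uniform(5, 45)),
            "identity": float(rng.uniform(15, 28))}


# ---------------------------------------------------------------------------
# mobilome
# ---------------------------------------------------------------------------

def simulate_mobilome(tree: AnnotatedTree, cfg: SimConfig,
                      rng: np.random.Generator | None = None
                      ) -> pd.DataFrame:
    """Poisson mobile-element counts per species with lifestyle-scaled
    means, plus a per-species proteome size column."""
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    styles = tree.tip_column("lifestyle")
    rows = {}
    for sp in tree.tip_labels:
        mult = cfg.mobilome_lifestyle_multipliers.get(styles[sp], {})
        counts = {cl: int(rng.poisson(cfg.mobilome_means[cl] *
                                      mult.get(cl, 1.0)))
                  for cl in MOBILOME_CLASSES}
        counts["proteome_size"] = max(
            500, int(round(rng.normal(cfg.proteome_mean, cfg.proteome_sd))))
        rows[sp] = counts
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("species")
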