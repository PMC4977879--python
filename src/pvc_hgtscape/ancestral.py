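"""Ancestral reconstruction of the binary cell-plan character.

Two routes, mirroring standard practice for a two-state discrete
character on a rooted species tree:

* **Parsimony** — unit-cost Sankoff (equivalent to Fitch on binary
  trees, and valid on multifurcations), returning the minimal change
  count, the full most-parsimonious-reconstruction (MPR) state set per
  node, and the set of equally parsimonious branch placements for each
  change.  Ambiguity is reported, never silently resolved.

* **Maximum likelihood under the Mk model** — a continuous-time
  two-state Markov chain with gain rate ``q01`` (0→1) and loss rate
  ``q10`` (1→0).  The transition matrix has the closed form
  ``P(t) = pi + (I - pi) * exp(-(q01+q10) t)`` (rows of the stationary
  distribution pi).  Likelihoods use Felsenstein pruning with per-node
  rescaling; marginal ancestral-state probabilities combine the inside
  (subtree) conditional likelihoods with the outside likelihood of the
  rest of the tree, renormalized per node.

State coding throughout: 1 = compartmentalized, 0 = non-compartmentalized;
an unknown cell plan is missing data (all-ones tip conditional), never a
third state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .treeio import AnnotatedTree

STATE_NAMES = {0: "non_compartmentalized", 1: "compartmentalized"}
_BIG = np.inf


# ---------------------------------------------------------------------------
# tip-state handling
# ---------------------------------------------------------------------------

def _coerce_state(v) -> int | None:
    if v is None:
        return None
    if isinstance(v, str):
        s = v.strip().lower()
        if s in ("unknown", "na", "nan", "?", ""):
            return None
        if s in ("1", "compartmentalized"):
            return 1
        if s in ("0", "non_compartmentalized", "noncompartmentalized"):
            return 0
        raise ValueError(f"unrecognized character state {v!r}")
    if isinstance(v, float) and np.isnan(v):
        return None
    iv = int(v)
    if iv not in (0, 1):
        raise ValueError(f"binary character state must be 0/1, got {v!r}")
    return iv


def tip_state_array(tree: AnnotatedTree,
                    tip_states: Mapping[str, object] | pd.Series | None = None
                    ) -> np.ndarray:
    """Per-node state column: 0, 1, or -1 for unknown/internal.

    ``tip_states`` defaults to the tree's own ``cell_plan`` annotations.
    """
    if tip_states is None:
        tip_states = tree.tip_column("cell_plan")
    out = np.full(tree.n_nodes, -1, dtype=np.int64)
    for t in tree.tip_labels:
        if t not in tip_states:
            raise ValueError(f"no character state for tip {t!r}")
        s = _coerce_state(tip_states[t])
        out[tree.index[t]] = -1 if s is None else s
    return out


# ---------------------------------------------------------------------------
# parsimony
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChangePlacement:
    """One equally-parsimonious placement of a state change on a branch."""
    child: str
    parent: str
    from_state: int
    to_state: int

    @property
    def kind(self) -> str:
        return "loss" if self.from_state == 1 else "gain"


@dataclass
class ParsimonyResult:
    """Minimal change count plus per-node MPR state sets.

    ``state_sets[n]`` contains every state assigned to node *n* by at
    least one most-parsimonious labeling; ``placements`` lists every
    branch on which a change sits in at least one such labeling (for an
    unambiguous reconstruction this is exactly ``score`` entries).
    """
    score: int
    state_sets: dict[str, frozenset[int]]
    placements: list[ChangePlacement]

    def changes_on(self, child_label: str) -> list[ChangePlacement]:
        return [p for p in self.placements if p.child == child_label]


def fitch_parsimony(tree: AnnotatedTree,
                    tip_states: Mapping[str, object] | None = None
                    ) -> ParsimonyResult:
    """Unit-cost parsimony reconstruction of a binary character.

    Unknown tips carry the full state set (cost 0 for either state).
    Multifurcations are handled natively by the Sankoff recursion.
    """
    states = tip_state_array(tree, tip_states)
    tips = tree.tip_indices
    if all(states[i] == -1 for i in tips):
        raise ValueError("all tips have unknown state; nothing to reconstruct")

    n = tree.n_nodes
    # inside (down-pass) Sankoff costs
    S = np.zeros((n, 2))
    for i in tree.postorder:
        if tree.is_tip[i]:
            if states[i] == 0:
                S[i] = [0.0, _BIG]
            elif states[i] == 1:
                S[i] = [_BIG, 0.0]
            else:
                S[i] = [0.0, 0.0]
        else:
            for s in (0, 1):
                tot = 0.0
                for c in tree.children[i]:
                    tot += min(S[c][0] + (s != 0), S[c][1] + (s != 1))
                S[i][s] = tot

    # outside costs U[v][s]: best cost of the rest of the tree given v=s
    U = np.zeros((n, 2))
    for i in tree.preorder():
        if i == tree.root:
            U[i] = [0.0, 0.0]
            continue
        p = tree.parent[i]
        sib = [b for b in tree.children[p] if b != i]
        for sc in (0, 1):
            best = _BIG
            for sp in (0, 1):
                v = U[p][sp] + (sp != sc)
                for b in sib:
                    v += min(S[b][0] + (sp != 0), S[b][1] + (sp != 1))
                best = min(best, v)
            U[i][sc] = best

    total = min(S[tree.root][0], S[tree.root][1])
    state_sets = {
        tree.labels[i]: frozenset(
            s for s in (0, 1) if S[i][s] + U[i][s] == total)
        for i in range(n)
    }

    placements: list[ChangePlacement] = []
    for i in range(n):
        p = tree.parent[i]
        if p < 0:
            continue
        sib = [b for b in tree.children[p] if b != i]
        for sp in (0, 1):
            sc = 1 - sp
            v = U[p][sp] + 1 + S[i][sc]
            for b in sib:
                v += min(S[b][0] + (sp != 0), S[b][1] + (sp != 1))
            if v == total:
                placements.append(ChangePlacement(
                    tree.labels[i], tree.labels[p], sp, sc))

    return ParsimonyResult(int(total), state_sets, placements)


# ---------------------------------------------------------------------------
# Mk model machinery
# ---------------------------------------------------------------------------

@dataclass
class MkModel:
    """Two-state Mk rate model: q01 = gain rate, q10 = loss rate."""
    q01: float
    q10: float
    root_prior: str = "flat"  # flat | stationary | fixed0 | fixed1

    def __post_init__(self):
        if self.q01 < 0 or self.q10 < 0:
            raise ValueError("Mk rates must be non-negative")

    def prior(self) -> np.ndarray:
        if self.root_prior == "flat":
            return np.array([0.5, 0.5])
        if self.root_prior == "stationary":
            q = self.q01 + self.q10
            if q == 0:
                return np.array([0.5, 0.5])
            return np.array([self.q10 / q, self.q01 / q])
        if self.root_prior == "fixed0":
            return np.array([1.0, 0.0])
        if self.root_prior == "fixed1":
            return np.array([0.0, 1.0])
        raise ValueError(f"unknown root prior {self.root_prior!r}")

    def transition(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt) for Q = [[-q01, q01], [q10, -q10]], closed form."""
        if t < 0:
            raise ValueError("negative branch length")
        q = self.q01 + self.q10
        if q == 0:
            return np.eye(2)
        e = np.exp(-q * t)
        pi0, pi1 = self.q10 / q, self.q01 / q
        return np.array([[pi0 + pi1 * e, pi1 * (1 - e)],
                         [pi0 * (1 - e), pi1 + pi0 * e]])


def _tip_conditionals(tree: AnnotatedTree, states: np.ndarray) -> np.ndarray:
    L = np.ones((tree.n_nodes, 2))
    for i in tree.tip_indices:
        if states[i] == 0:
            L[i] = [1.0, 0.0]
        elif states[i] == 1:
            L[i] = [0.0, 1.0]
    return L


def _prune(tree: AnnotatedTree, states: np.ndarray, model: MkModel
           ) -> tuple[np.ndarray, float]:
    """Inside conditionals per node (rescaled) and the total log scale."""
    down = _tip_conditionals(tree, states)
    logscale = 0.0
    P = {i: model.transition(tree.brlen[i])
         for i in range(tree.n_nodes) if tree.parent[i] >= 0}
    for i in tree.postorder:
        if tree.is_tip[i]:
            continue
        for c in tree.children[i]:
            down[i] *= P[c] @ down[c]
        m = down[i].max()
        if m <= 0:
            return down, -np.inf
        down[i] /= m
        logscale += np.log(m)
    return down, logscale


def mk_loglik(tree: AnnotatedTree,
              tip_states: Mapping[str, object] | None,
              model: MkModel) -> float:
    """Log-likelihood of the tip data by Felsenstein pruning."""
    states = tip_state_array(tree, tip_states)
    down, logscale = _prune(tree, states, model)
    if not np.isfinite(logscale):
        return -np.inf
    lik = float(model.prior() @ down[tree.root])
    return (np.log(lik) + logscale) if lik > 0 else -np.inf


def mk_marginal(tree: AnnotatedTree,
                tip_states: Mapping[str, object] | None,
                model: MkModel) -> pd.DataFrame:
    """Marginal ancestral-state probabilities at every node.

    Returns a DataFrame indexed by node id with columns
    ``P_compartmentalized`` and ``P_noncompartmentalized``; every row
    sums to 1, and tips with an observed state get probability 1 there.
    """
    states = tip_state_array(tree, tip_states)
    down, logscale = _prune(tree, states, model)
    if not np.isfinite(logscale):
        raise ValueError("data have zero likelihood under this model")
    n = tree.n_nodes
    P = {i: model.transition(tree.brlen[i])
         for i in range(n) if tree.parent[i] >= 0}
    up = np.ones((n, 2))
    up[tree.root] = model.prior()
    for i in tree.preorder():
        for c in tree.children[i]:
            out = up[i].copy()
            for b in tree.children[i]:
                if b != c:
                    out *= P[b] @ down[b]
            up[c] = out @ P[c]
            m = up[c].max()
            if m > 0:
                up[c] /= m
    marg = up * down
    marg /= marg.sum(axis=1, keepdims=True)
    return pd.DataFrame(
        {"P_compartmentalized": marg[:, 1],
         "P_noncompartmentalized": marg[:, 0]},
        index=pd.Index(tree.labels, name="node"))


# ---------------------------------------------------------------------------
# fitting: statsmodels-style model / results pair
# ---------------------------------------------------------------------------

class MkCharacterModel:
    """Mk model of a binary character on a fixed rooted tree.

    The estimable parameters are the transition rates (one rate for the
    equal-rates "ER" variant, two for all-rates-different "ARD"),
    maximized by bounded quasi-Newton search on log-rates with a
    deterministic multi-start at 0.01, 0.1 and 1 changes per unit branch
    length.

    Examples
    --------
    >>> model = MkCharacterModel.from_annotations(tree)   # doctest: +SKIP
    >>> res = model.fit()                                 # doctest: +SKIP
    >>> res.summary()                                     # doctest: +SKIP
    """

    #: deterministic multi-start points (rates per unit branch length)
    STARTS = (0.01, 0.1, 1.0)
    _BOUNDS = (np.log(1e-8), np.log(1e4))

    def __init__(self, tree: AnnotatedTree,
                 tip_states: Mapping[str, object] | None = None,
                 variant: str = "ER", root_prior: str = "flat"):
        if variant not in ("ER", "ARD"):
            raise ValueError("variant must be 'ER' or 'ARD'")
        self.tree = tree
        self.variant = variant
        self.root_prior = root_prior
        self._states = tip_state_array(tree, tip_states)
        self._tip_states = (dict(tip_states) if tip_states is not None
                            else tree.tip_column("cell_plan"))
        known = self._states[tree.tip_indices]
        known = known[known >= 0]
        if known.size < 2 or known.min() == known.max():
            raise ValueError(
                "rate estimation needs >= 2 known tips with both states "
                "observed; use the parsimony reconstruction for a constant "
                "character")

    @classmethod
    def from_annotations(cls, tree: AnnotatedTree, **kw) -> "MkCharacterModel":
        """Build from the tree's own cell_plan annotation column."""
        return cls(tree, tip_states=None, **kw)

    # -- likelihood --------------------------------------------------

    def _model(self, params: Sequence[float]) -> MkModel:
        if self.variant == "ER":
            return MkModel(params[0], params[0], self.root_prior)
        return MkModel(params[0], params[1], self.root_prior)

    def loglike(self, params: Sequence[float]) -> float:
        return mk_loglik(self.tree, self._tip_states, self._model(params))

    def fit(self) -> "MkFitResult":
        k = 1 if self.variant == "ER" else 2

        def nll(logp):
            v = self.loglike(np.exp(logp))
            return -v if np.isfinite(v) else 1e12

        best = None
        for s0 in self.STARTS:
            x0 = np.log(np.full(k, s0))
            r = optimize.minimize(
                nll, x0, method="L-BFGS-B",
                bounds=[self._BOUNDS] * k,
                options={"ftol": 1e-12, "gtol": 1e-10})
            if best is None or r.fun < best.fun:
                best = r
        rates = np.exp(best.x)
        llf = -float(best.fun)
        model = self._model(rates)
        se = self._rate_se(best.x)
        return MkFitResult(self, model, llf, rates, se)

    def _rate_se(self, log_opt: np.ndarray) -> np.ndarray:
        """Delta-method SEs from a finite-difference Hessian on log-rates."""
        k = log_opt.size
        h = 1e-4
        H = np.zeros((k, k))

        def f(x):
            v = self.loglike(np.exp(x))
            return v if np.isfinite(v) else -1e12

        f0 = f(log_opt)
        for a in range(k):
            for b in range(k):
                xpp = log_opt.copy(); xpp[a] += h; xpp[b] += h
                xpm = log_opt.copy(); xpm[a] += h; xpm[b] -= h
                xmp = log_opt.copy(); xmp[a] -= h; xmp[b] += h
                xmm = log_opt.copy(); xmm[a] -= h; xmm[b] -= h
                H[a, b] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * h * h)
        try:
            cov_log = np.linalg.inv(-H)
            var_log = np.clip(np.diag(cov_log), 0, None)
            return np.exp(log_opt) * np.sqrt(var_log)  # delta method
        except np.linalg.LinAlgError:
            return np.full(k, np.nan)


@dataclass
class MkFitResult:
    """Fitted Mk model: rates, their (delta-method) SEs, log-likelihood.

    ``marginals()`` gives the per-node ancestral state probabilities at
    the fitted rates; ``summary()`` a human-readable report.
    """
    model_obj: MkCharacterModel
    model: MkModel
    llf: float
    rates: np.ndarray
    rate_se: np.ndarray
    _marginals: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def params(self) -> pd.Series:
        names = (["q"] if self.model_obj.variant == "ER" else ["q01", "q10"])
        return pd.Series(self.rates, index=names)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(self.rate_se, index=self.params.index)

    @property
    def aic(self) -> float:
        return 2 * len(self.rates) - 2 * self.llf

    def marginals(self) -> pd.DataFrame:
        if self._marginals is None:
            self._marginals = mk_marginal(
                self.model_obj.tree, self.model_obj._tip_states, self.model)
        return self._marginals

    def root_probability(self, state: int = 1) -> float:
        root_label = self.model_obj.tree.labels[self.model_obj.tree.root]
        col = ("P_compartmentalized" if state == 1
               else "P_noncompartmentalized")
        return float(self.marginals().loc[root_label, col])

    def summary(self) -> str:
        lines = [
            "Mk character model ({} variant, {} root prior)".format(
                self.model_obj.variant, self.model_obj.root_prior),
            "tips: {}  (known states: {})".format(
                len(self.model_obj.tree.tip_labels),
                int((self.model_obj._states[
                    self.model_obj.tree.tip_indices] >= 0).sum())),
            "log-likelihood: {:.6f}   AIC: {:.6f}".format(self.llf, self.aic),
            "",
            "{:<6s}{:>12s}{:>12s}".format("rate", "estimate", "std err"),
        ]
        for name, est, se in zip(self.params.index, self.rates, self.rate_se):
            lines.append("{:<6s}{:>12.6g}{:>12.3g}".format(name, est, se))
        root_label = self.model_obj.tree.labels[self.model_obj.tree.root]
        lines += ["",
                  "root P(compartmentalized) = {:.4f}".format(
                      self.root_probability(1)),
                  "root node: {}".format(root_label)]
        return "\n".join(lines)


def mk_fit(tree: AnnotatedTree,
           tip_states: Mapping[str, object] | None = None,
           variant: str = "ER", root_prior: str = "flat") -> MkFitResult:
    """Maximum-likelihood Mk rates (functional wrapper over the model class)."""
    return MkCharacterModel(tree, tip_states, variant, root_prior).fit()


def ancestral_table(tree: AnnotatedTree,
                    tip_states: Mapping[str, object] | None = None,
                    variant: str = "ER", root_prior: str = "flat"
                    ) -> pd.DataFrame:
    """ML marginals and parsimony state sets, one row per node."""
    res = mk_fit(tree, tip_states, variant, root_prior)
    pars = fitch_parsimony(tree, tip_states)
    tbl = res.marginals().copy()
    tbl["parsimony_states"] = [
        "/".join(STATE_NAMES[s] for s in sorted(pars.state_sets[n]))
        for n in tbl.index]
    return tbl
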