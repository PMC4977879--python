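"""Group-comparison workflow for HGT and mobilome proportions.

One fixed decision cascade, applied identically to every measure:
Shapiro-Wilk normality per group and Levene variance homogeneity across
groups decide between the parametric branch (one-way ANOVA with Tukey
HSD post-hoc) and the nonparametric branch (Kruskal-Wallis with Nemenyi
post-hoc).  The parametric branch requires *every* group to pass
Shapiro-Wilk and Levene to pass, all at the working level alpha = 0.05;
any failure — or a group too small to test — falls to the
nonparametric branch.

Groupings supported: cell plan, lifestyle, phylum (the confounding
control: if phylum-based classes separate the same way, a cell-plan
effect cannot be distinguished from phylogenetic structure), and the
combined lifestyle x cell-plan classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .treeio import AnnotatedTree
from .genecontent import HgtSummary

ALPHA_DEFAULT = 0.05

#: element classes whose abundance scales with genome size: reported as
#: proportions of the proteome rather than raw counts
SIZE_LINKED_ELEMENTS = ("conjugation_genes", "transposases", "integrases",
                        "crispr_candidate", "crispr_confirmed")

GROUPING_SCHEMES = ("cell_plan", "lifestyle", "phylum", "combined")


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# mobilome proportions
# ---------------------------------------------------------------------------

def mobilome_proportions(table: pd.DataFrame) -> pd.DataFrame:
    """Per-species measures for the nine element classes.

    Size-linked classes (CRISPRs, transposases, integrases, conjugation
    genes) are divided by proteome size; the rest pass through as raw
    counts.  The proteome_size column is preserved.
    """
    if "proteome_size" not in table.columns:
        raise StatsError("mobilome table lacks a proteome_size column")
    if (table["proteome_size"] <= 0).any():
        bad = table.index[table["proteome_size"] <= 0].tolist()
        raise StatsError(f"zero/negative proteome size for {bad}")
    counts = table.drop(columns="proteome_size")
    if (counts < 0).any().any():
        raise StatsError("mobilome counts must be non-negative")
    out = counts.astype(float).copy()
    for cl in SIZE_LINKED_ELEMENTS:
        if cl in out.columns:
            out[cl] = counts[cl] / table["proteome_size"]
    out["proteome_size"] = table["proteome_size"]
    return out


# ---------------------------------------------------------------------------
# the decision cascade
# ---------------------------------------------------------------------------

@dataclass
class ComparisonReport:
    """Full audit trail of one group comparison."""
    measure: str
    scheme: str
    groups: dict[str, np.ndarray]
    normality_p: dict[str, float]
    levene_p: float
    test_name: str                 # "anova" | "kruskal" | "none"
    statistic: float
    p_value: float
    posthoc_name: str              # "tukey" | "nemenyi" | "none"
    posthoc: pd.DataFrame | None
    alpha: float
    warnings: list[str] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return np.isfinite(self.p_value) and self.p_value < self.alpha

    @property
    def parametric(self) -> bool:
        return self.test_name == "anova"

    def summary(self) -> str:
        lines = [f"comparison of {self.measure} across {self.scheme} groups",
                 "groups: " + ", ".join(
                     f"{g} (n={len(v)})" for g, v in self.groups.items())]
        for g, p in self.normality_p.items():
            lines.append(f"  Shapiro-Wilk {g}: p={p:.4g}")
        lines.append(f"  Levene: p={self.levene_p:.4g}")
        lines.append(f"  omnibus: {self.test_name} stat={self.statistic:.4g} "
                     f"p={self.p_value:.4g} "
                     f"({'significant' if self.significant else 'ns'} "
                     f"at alpha={self.alpha})")
        for w in self.warnings:
            lines.append(f"  ! {w}")
        return "\n".join(lines)


def nemenyi_posthoc(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """All-pairs Nemenyi test on pooled ranks (Kruskal-Wallis follow-up).

    The statistic for a pair is the absolute mean-rank difference scaled
    by sqrt(N(N+1)/12 * (1/n_i + 1/n_j)); p-values come from the
    studentized-range distribution with k groups and infinite df.
    """
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    ranks = sps.rankdata(pooled)
    n_tot = len(pooled)
    mean_rank, sizes, off = {}, {}, 0
    for g in names:
        n = len(groups[g])
        mean_rank[g] = ranks[off:off + n].mean()
        sizes[g] = n
        off += n
    k = len(names)
    p = pd.DataFrame(np.ones((k, k)), index=names, columns=names)
    for a, b in combinations(names, 2):
        se = np.sqrt(n_tot * (n_tot + 1) / 12.0 *
                     (1.0 / sizes[a] + 1.0 / sizes[b]))
        q = abs(mean_rank[a] - mean_rank[b]) / se * np.sqrt(2.0)
        pv = float(np.clip(sps.studentized_range.sf(q, k, np.inf), 0, 1))
        p.loc[a, b] = p.loc[b, a] = pv
    return p


def tukey_posthoc(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    names = list(groups)
    res = sps.tukey_hsd(*[groups[g] for g in names])
    return pd.DataFrame(res.pvalue, index=names, columns=names)


def compare_groups(data: pd.DataFrame, measure: str = "value",
                   group_col: str = "group", value_col: str = "value",
                   scheme: str = "", alpha: float = ALPHA_DEFAULT
                   ) -> ComparisonReport:
    """Run the full cascade on a long-format (species, group, value) table."""
    warns: list[str] = []
    groups = {str(g): np.asarray(sub[value_col], dtype=float)
              for g, sub in data.groupby(group_col, sort=True)}
    groups = {g: v for g, v in groups.items() if len(v) > 0}
    if len(groups) < 2:
        raise StatsError("need at least two non-empty groups")
    if any(len(v) < 2 for v in groups.values()):
        warns.append("group(s) with a single observation: omnibus test "
                     "abstains")
        return ComparisonReport(measure, scheme, groups, {}, np.nan, "none",
                                np.nan, np.nan, "none", None, alpha, warns)
    pooled = np.concatenate(list(groups.values()))
    if np.ptp(pooled) == 0:
        warns.append("no variance in the data: all tests abstain")
        return ComparisonReport(measure, scheme, groups, {}, np.nan, "none",
                                np.nan, np.nan, "none", None, alpha, warns)

    normality_p: dict[str, float] = {}
    all_normal = True
    for g, v in groups.items():
        if len(v) < 3 or np.ptp(v) == 0:
            normality_p[g] = np.nan
            all_normal = False
            warns.append(f"normality untestable for group {g!r} "
                         "(n < 3 or constant); using nonparametric branch")
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = float(sps.shapiro(v).pvalue)
        normality_p[g] = p
        if p < alpha:
            all_normal = False
    try:
        levene_p = float(sps.levene(*groups.values(), center="median").pvalue)
    except Exception:
        levene_p = np.nan

    parametric = all_normal and np.isfinite(levene_p) and levene_p >= alpha
    vals = list(groups.values())
    if parametric:
        stat, p = sps.f_oneway(*vals)
        test, post_name = "anova", "tukey"
        posthoc = tukey_posthoc(groups)
    else:
        try:
            stat, p = sps.kruskal(*vals)
        except ValueError:
            warns.append("Kruskal-Wallis undefined (all values identical)")
            return ComparisonReport(measure, scheme, groups, normality_p,
                                    levene_p, "none", np.nan, np.nan, "none",
                                    None, alpha, warns)
        test, post_name = "kruskal", "nemenyi"
        posthoc = nemenyi_posthoc(groups)
    return ComparisonReport(measure, scheme, groups, normality_p, levene_p,
                            test, float(stat), float(p), post_name, posthoc,
                            alpha, warns)


def holm_adjust(pvals: pd.Series) -> pd.Series:
    """Holm step-down adjustment of a family of p-values."""
    p = pvals.dropna()
    m = len(p)
    order = p.sort_values().index
    adj, running = {}, 0.0
    for i, idx in enumerate(order):
        running = max(running, (m - i) * p[idx])
        adj[idx] = min(1.0, running)
    return pd.Series(adj).reindex(pvals.index)


# ---------------------------------------------------------------------------
# the HGT contrasts
# ---------------------------------------------------------------------------

MEASURES = ("total_proportion", "specific_proportion",
            "nonspecific_proportion")


def grouped_measurements(summary: HgtSummary, tree: AnnotatedTree,
                         measure: str, scheme: str) -> pd.DataFrame:
    """Long-format (species, group, value) table for one measure/scheme."""
    if scheme not in GROUPING_SCHEMES:
        raise StatsError(f"unknown grouping scheme {scheme!r}")
    tbl = summary.per_species
    if measure not in tbl.columns:
        raise StatsError(f"unknown measure {measure!r}")

    def label(sp: str) -> str:
        if scheme == "combined":
            return (tree.annotation(sp, "lifestyle") + "/" +
                    tree.annotation(sp, "cell_plan"))
        return tree.annotation(sp, scheme)

    return pd.DataFrame({
        "species": tbl.index,
        "group": [label(s) for s in tbl.index],
        "value": tbl[measure].to_numpy(),
    })


def lifestyle_contrast(summary: HgtSummary, tree: AnnotatedTree,
                       schemes: tuple = GROUPING_SCHEMES,
                       measures: tuple = MEASURES,
                       alpha: float = ALPHA_DEFAULT
                       ) -> pd.DataFrame:
    """Every (measure, scheme) comparison, the phylum control included.

    Returns a tidy table of omnibus results with a clearly-labelled
    Holm-adjusted column (an extension across the report family; raw
    p-values are the primary readout).  The full reports are attached
    as the ``report`` column.
    """
    if "phylum" not in schemes:
        schemes = tuple(schemes) + ("phylum",)
    rows = []
    for measure in measures:
        for scheme in schemes:
            data = grouped_measurements(summary, tree, measure, scheme)
            rep = compare_groups(data, measure=measure, scheme=scheme,
                                 alpha=alpha)
            rows.append({"measure": measure, "scheme": scheme,
                         "test": rep.test_name, "statistic": rep.statistic,
                         "p_value": rep.p_value,
                         "significant": rep.significant, "report": rep})
    out = pd.DataFrame(rows)
    out["p_holm_adjusted"] = holm_adjust(out["p_value"])
    return out


def mobilome_contrast(table: pd.DataFrame, tree: AnnotatedTree,
                      schemes: tuple = ("cell_plan", "lifestyle", "phylum"),
                      alpha: float = ALPHA_DEFAULT) -> pd.DataFrame:
    """The same cascade applied to each mobilome element class."""
    props = mobilome_proportions(table)
    rows = []
    for cl in [c for c in props.columns if c != "proteome_size"]:
        for scheme in schemes:
            data = pd.DataFrame({
                "species": props.index,
                "group": [tree.annotation(s, scheme) for s in props.index],
                "value": props[cl].to_numpy(),
            })
            rep = compare_groups(data, measure=cl, scheme=scheme, alpha=alpha)
            rows.append({"measure": cl, "scheme": scheme,
                         "test": rep.test_name, "statistic": rep.statistic,
                         "p_value": rep.p_value,
                         "significant": rep.significant, "report": rep})
    out = pd.DataFrame(rows)
    out["p_holm_adjusted"] = holm_adjust(out["p_value"])
    return out
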