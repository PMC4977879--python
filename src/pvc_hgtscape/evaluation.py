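"""Recovery scoring against simulation truth.

Utilities that run the detection pipeline on synthetic data and score
it against the generator's event log: gene-level sensitivity /
specificity of the HGT calls, and the lifestyle contrast on replicated
simulations.  Used by the test-suite and the acceptance script alike.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genecontent import hgt_gene_flags, infer_events
from .hgtfilter import classify_event_map
from .pipeline import representatives
from .simulate import SimConfig, simulate_gene_content, simulate_hit_table
from .stats import compare_groups, grouped_measurements
from .genecontent import summarize_hgt
from .treeio import AnnotatedTree


def detect_hgt(tree: AnnotatedTree, cfg: SimConfig):
    """One synthetic replicate through simulate -> infer -> classify.

    Returns (matrix, truth log, classified events).
    """
    matrix, log = simulate_gene_content(tree, cfg)
    events = infer_events(tree, matrix)
    reps = representatives(events, matrix)
    genes = [(g.split("|", 1)[0], g.split("|", 1)[1])
             for g in sorted(set(reps.values()))]
    tables = simulate_hit_table(matrix, log, cfg, genes=genes)
    events, _ = classify_event_map(events, tables, reps)
    return matrix, log, events


def score_recovery(tree: AnnotatedTree, cfg: SimConfig) -> dict[str, float]:
    """Gene-level confusion of HGT calls vs the true copy origins.

    A present tip copy is a positive iff it descends from an
    external-donor transfer; a predicted positive iff the pipeline
    flags it as an HGT gene.
    """
    matrix, log, events = detect_hgt(tree, cfg)
    flags = hgt_gene_flags(events, matrix).to_numpy() != ""
    truth = log.hgt_truth(matrix).to_numpy()
    present = matrix.presence.to_numpy().astype(bool)
    tp = int((flags & truth & present).sum())
    fn = int((~flags & truth & present).sum())
    fp = int((flags & ~truth & present).sum())
    tn = int((~flags & ~truth & present).sum())
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
        "specificity": tn / (tn + fp) if tn + fp else np.nan,
        "false_positive_rate": fp / (fp + tn) if fp + tn else np.nan,
        "true_hgt_genes": tp + fn,
        "predicted_hgt_genes": tp + fp,
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
    }


def specific_hgt_lifestyle_test(tree: AnnotatedTree, cfg: SimConfig,
                                alpha: float = 0.05) -> dict[str, float]:
    """One replicate of the lifestyle contrast on specific-HGT
    proportions; reports the omnibus p-value and the group means."""
    matrix, _log, events = detect_hgt(tree, cfg)
    summary = summarize_hgt(events, matrix)
    data = grouped_measurements(summary, tree, "specific_proportion",
                                "lifestyle")
    rep = compare_groups(data, measure="specific_proportion",
                         scheme="lifestyle", alpha=alpha)
    means = data.groupby("group")["value"].mean()
    return {
        "p_value": rep.p_value,
        "significant": float(rep.significant),
        "allopatric_mean": float(means.get("allopatric", np.nan)),
        "sympatric_mean": float(means.get("sympatric", np.nan)),
    }
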