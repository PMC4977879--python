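"""End-to-end orchestration: simulate/load -> cluster -> map events ->
classify gains -> summarize HGT -> group statistics.

A single :class:`PipelineConfig` (YAML-loadable) drives every stage;
the seed is threaded through all randomness, and a manifest with
per-stage counts and output checksums is written so a rerun with the
same config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ancestral, genecontent, hgtfilter, simulate, stats
from .datasets import load_pvc_demo
from .genecontent import (EventMap, PhyleticMatrix, infer_events,
                          replay_events, summarize_hgt, ROOT_STEM)
from .hgtfilter import FilterPolicy, classify_event_map
from .simulate import SimConfig, TrueEventLog
from .treeio import AnnotatedTree, read_tree


class PipelineError(RuntimeError):
    def __init__(self, stage: str, msg: str):
        super().__init__(f"[stage {stage}] {msg}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything one run needs; all thresholds default to the published
    policy values and every one can be overridden."""
    out_dir: str = "pipeline_out"
    seed: int = 0
    alpha: float = 0.05
    # inputs (all optional; missing pieces are simulated)
    tree: str | None = None
    annotations: str | None = None
    matrix: str | None = None
    similarity_graph: str | None = None
    hit_tables: str | None = None
    mobilome: str | None = None
    # method options
    gain_cost: float = genecontent.GAIN_COST_DEFAULT
    loss_cost: float = genecontent.LOSS_COST_DEFAULT
    dollo: bool = False
    mcl_inflation: float = 1.5
    mk_variant: str = "ER"
    mk_root_prior: str = "flat"
    filter_policy: dict = field(default_factory=dict)
    sim: dict | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def policy(self) -> FilterPolicy:
        return FilterPolicy(**self.filter_policy)

    def sim_config(self) -> SimConfig:
        kw = dict(self.sim or {})
        kw.setdefault("seed", self.seed)
        return SimConfig(**kw)


def representatives(events: EventMap, matrix: PhyleticMatrix
                    ) -> dict[tuple[str, str], str]:
    """One member gene per gain: the alphabetically first species below
    the gained branch that carries the family."""
    tree = events.tree
    below: dict[str, list[str]] = {ROOT_STEM: sorted(tree.tip_labels)}
    for lbl in tree.labels:
        below[lbl] = sorted(tree.subtree_tips(lbl))
    out = {}
    pres = matrix.presence
    for g in events.gains:
        for sp in below[g.branch_child]:
            if g.family in pres.index and pres.loc[g.family, sp] == 1:
                out[(g.family, g.branch_child)] = simulate.gene_id(
                    sp, g.family)
                break
    return out


def load_hit_tables(path: str | Path) -> dict[str, pd.DataFrame]:
    """One TSV with a ``query`` column; split per query gene."""
    df = pd.read_csv(path, sep="\t")
    return {str(q): sub.reset_index(drop=True)
            for q, sub in df.groupby("query", sort=True)}


def run_pipeline(config: PipelineConfig) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}
    counts: dict = {}

    # ---- stage: tree ------------------------------------------------
    try:
        if config.tree is not None:
            if config.annotations is None:
                raise ValueError("tree given without an annotation table")
            tree = read_tree(config.tree, config.annotations)
        else:
            tree = load_pvc_demo()
    except Exception as e:
        raise PipelineError("tree", str(e)) from e
    artifacts["tree"] = tree
    counts["tips"] = len(tree.tip_labels)

    # ---- stage: ancestral cell plan --------------------------------
    try:
        pars = ancestral.fitch_parsimony(tree)
        known = [v for v in tree.tip_column("cell_plan").values()
                 if v != "unknown"]
        if len(set(known)) > 1:
            anc_tbl = ancestral.ancestral_table(
                tree, variant=config.mk_variant,
                root_prior=config.mk_root_prior)
        else:
            anc_tbl = pd.DataFrame(index=pd.Index(tree.labels, name="node"))
            anc_tbl["parsimony_states"] = [
                "/".join(ancestral.STATE_NAMES[s]
                         for s in sorted(pars.state_sets[n]))
                for n in anc_tbl.index]
        anc_tbl.to_csv(out / "ancestral_states.tsv", sep="\t")
        artifacts["ancestral"] = anc_tbl
        artifacts["parsimony"] = pars
        counts["parsimony_changes"] = pars.score
    except Exception as e:
        raise PipelineError("ancestral", str(e)) from e

    # ---- stage: matrix ---------------------------------------------
    log: TrueEventLog | None = None
    try:
        if config.matrix is not None:
            matrix = PhyleticMatrix.from_tsv(config.matrix)
        elif config.similarity_graph is not None:
            graph = pd.read_csv(config.similarity_graph, sep="\t")
            matrix = genecontent.cluster_families(
                graph, species=tree.tip_labels,
                inflation=config.mcl_inflation)
        else:
            matrix, log = simulate.simulate_gene_content(
                tree, config.sim_config())
        matrix.to_tsv(out / "phyletic_matrix.tsv")
        artifacts["matrix"] = matrix
        counts["families"] = len(matrix.families)
    except Exception as e:
        raise PipelineError("matrix", str(e)) from e

    # ---- stage: event inference ------------------------------------
    try:
        events = infer_events(tree, matrix, gain_cost=config.gain_cost,
                              loss_cost=config.loss_cost,
                              dollo=config.dollo)
        replay = replay_events(events, families=matrix.families)
        mism = int((replay[matrix.species].to_numpy() !=
                    matrix.presence.to_numpy()).sum())
        if mism:
            raise ValueError(f"event replay mismatches matrix in {mism} cells")
        counts["gains"] = len(events.gains)
        counts["losses"] = len(events.losses)
    except Exception as e:
        raise PipelineError("events", str(e)) from e

    # ---- stage: classification -------------------------------------
    try:
        reps = representatives(events, matrix)
        if config.hit_tables is not None:
            tables = load_hit_tables(config.hit_tables)
        elif log is not None:
            need = [(g.split("|", 1)[0], g.split("|", 1)[1])
                    for g in sorted(set(reps.values()))]
            tables = simulate.simulate_hit_table(
                matrix, log, config.sim_config(), genes=need)
        else:
            tables = {}
        events, partners = classify_event_map(
            events, tables, reps, policy=config.policy())
        events.to_frame().to_csv(out / "event_map.tsv", sep="\t",
                                 index=False)
        partners.to_csv(out / "hgt_partners.tsv", sep="\t", index=False)
        artifacts["events"] = events
        artifacts["partners"] = partners
        cls = pd.Series([g.classification for g in events.gains])
        counts["hgt_gains"] = int((cls == "HGT").sum())
        counts["orfan_gains"] = int((cls == "ORFan").sum())
    except Exception as e:
        raise PipelineError("classify", str(e)) from e

    # ---- stage: summary --------------------------------------------
    try:
        summary = summarize_hgt(events, matrix)
        summary.per_species.to_csv(out / "hgt_summary.tsv", sep="\t")
        summary.per_branch.to_csv(out / "hgt_per_branch.tsv", sep="\t")
        artifacts["summary"] = summary
        counts["total_hgt_genes"] = int(
            summary.per_species["total_hgt"].sum())
        counts["specific_hgt_genes"] = int(
            summary.per_species["specific_hgt"].sum())
    except Exception as e:
        raise PipelineError("summary", str(e)) from e

    # ---- stage: statistics -----------------------------------------
    try:
        contrast = stats.lifestyle_contrast(summary, tree,
                                            alpha=config.alpha)
        contrast.drop(columns="report").to_csv(
            out / "hgt_comparisons.tsv", sep="\t", index=False)
        artifacts["contrast"] = contrast
        if config.mobilome is not None:
            mob = pd.read_csv(config.mobilome, sep="\t", index_col=0)
        elif config.sim is not None or config.matrix is None:
            mob = simulate.simulate_mobilome(tree, config.sim_config())
        else:
            mob = None
        if mob is not None:
            mob.to_csv(out / "mobilome_counts.tsv", sep="\t")
            mobc = stats.mobilome_contrast(mob, tree, alpha=config.alpha)
            mobc.drop(columns="report").to_csv(
                out / "mobilome_comparisons.tsv", sep="\t", index=False)
            artifacts["mobilome_contrast"] = mobc
    except Exception as e:
        raise PipelineError("stats", str(e)) from e

    # ---- manifest ---------------------------------------------------
    manifest = {
        "seed": config.seed,
        "parameters": {k: v for k, v in asdict(config).items()
                       if k != "out_dir"},
        "counts": counts,
        "checksums": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(out.glob("*.tsv"))},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    artifacts["manifest"] = manifest
    return artifacts
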