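"""Bundled demonstration data.

``load_pvc_demo`` returns a 33-tip rooted species tree of the PVC
super-phylum with the standard three tip annotations.  The topology is
faithful to the published picture of the group — the Chlamydiae are
monophyletic and sister to the Planctomycetes + Verrucomicrobiae +
Lentisphaerae clade; the eight non-compartmentalized, allopatric
Chlamydiaceae form one clade whose stem carries the inferred loss of
compartmentalization — but branch lengths are illustrative, synthetic
stand-ins (the underlying study never published its consensus tree's
lengths).
"""

from __future__ import annotations

from importlib import resources

from .treeio import AnnotatedTree, read_tree

#: node id of the clade of the eight non-compartmentalized Chlamydiaceae
CHLAMYDIACEAE_NODE = "Chlamydiaceae"


def demo_paths() -> tuple[str, str]:
    base = resources.files("pvc_hgtscape") / "data"
    return (str(base / "pvc_demo.nwk"),
            str(base / "pvc_demo_annotations.tsv"))


def load_pvc_demo() -> AnnotatedTree:
    tree_path, annot_path = demo_paths()
    return read_tree(tree_path, annot_path)
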