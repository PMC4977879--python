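import numpy as np
import pandas as pd
import pytest

from pvc_hgtscape import load_pvc_demo, from_newick


@pytest.fixture(scope="session")
def demo_tree():
    return load_pvc_demo()


@pytest.fixture()
def quartet():
    """((A,B),(C,D)) with unit branch lengths."""
    return from_newick("((A:1,B:1):1,(C:1,D:1):1);")


def annotations_for(tips, phylum="P", lifestyle="sympatric",
                    cell_plan="unknown"):
    return pd.DataFrame(
        {"phylum": phylum, "lifestyle": lifestyle, "cell_plan": cell_plan},
        index=pd.Index(tips, name="species"))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
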