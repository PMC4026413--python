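import numpy as np
import pandas as pd
import pytest

from lelpipe.simulate import ExpressionDataset


@pytest.fixture
def paired_dataset():
    """Tiny 4-subject paired dataset with known within-subject differences."""
    rng = np.random.default_rng(0)
    base = rng.normal(8.0, 1.0, size=(60, 1))
    diffs = rng.normal(0.0, 0.3, size=(60, 4))
    cols, values = [], []
    for s in range(4):
        ref = base[:, 0] + rng.normal(0, 0.1, 60)
        cols += [f"R{s+1}_0h", f"R{s+1}_5h"]
        values += [ref, ref + diffs[:, s]]
    mat = pd.DataFrame(
        np.column_stack(values),
        index=pd.Index([f"P{i:03d}" for i in range(60)], name="probe_id"),
        columns=cols,
    )
    sheet = pd.DataFrame(
        {
            "sample_id": cols,
            "subject_id": [c.split("_")[0] for c in cols],
            "condition": ["reference", "treated"] * 4,
        }
    )
    genes = pd.Series([f"G{i:03d}" for i in range(60)], index=mat.index)
    return ExpressionDataset(mat, sheet, genes), diffs


@pytest.fixture
def chain_dag():
    """Three-term chain C -> B -> A (A is the root) with nested gene sets."""
    import networkx as nx

    dag = nx.DiGraph()
    for t in ("A", "B", "C"):
        dag.add_node(t, name=f"term {t}")
    dag.add_edge("B", "A")
    dag.add_edge("C", "B")
    annotations = {
        "g1": {"C"}, "g2": {"C"}, "g3": {"B"}, "g4": {"B"},
        "g5": {"A"}, "g6": {"A"}, "g7": {"A"}, "g8": {"A"},
    }
    return dag, annotations
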