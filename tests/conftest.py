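import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from riboclean import CountMatrix, generate_experiment, paper_like_config

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_scenario():
    """One desk-scale paper-like experiment shared across tests."""
    config, panel = paper_like_config(seed=101, n_genes=400)
    cm, truth = generate_experiment(config)
    return {"config": config, "panel": panel, "cm": cm, "truth": truth}


@pytest.fixture()
def tiny_cm():
    """3 genes x 4 samples (2 IP/input pairs, 2 conditions)."""
    counts = pd.DataFrame(
        {
            "a_IP": [10, 0, 5],
            "a_in": [8, 2, 5],
            "b_IP": [20, 1, 5],
            "b_in": [9, 3, 5],
        },
        index=["g1", "g2", "g3"],
    )
    meta = pd.DataFrame(
        {
            "sample": ["a_IP", "a_in", "b_IP", "b_in"],
            "fraction": ["IP", "input", "IP", "input"],
            "condition": ["naive", "naive", "dpi2", "dpi2"],
            "pair_id": ["a", "a", "b", "b"],
        }
    ).set_index("sample")
    return CountMatrix(counts, meta)


def make_cm(counts: np.ndarray, conditions, fractions, genes=None) -> CountMatrix:
    """Assemble a CountMatrix from an array plus per-sample labels."""
    n_genes, n_samples = counts.shape
    genes = genes if genes is not None else [f"g{i}" for i in range(n_genes)]
    names, pair_ids, seen = [], [], {}
    for c, f in zip(conditions, fractions):
        k = seen.setdefault((c, f), 0)
        seen[(c, f)] += 1
        names.append(f"{c}_r{k}_{f}")
        pair_ids.append(f"{c}_r{k}")
    meta = pd.DataFrame(
        {"fraction": fractions, "condition": conditions, "pair_id": pair_ids},
        index=pd.Index(names, name="sample"),
    )
    return CountMatrix(pd.DataFrame(counts, index=genes, columns=names), meta)
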