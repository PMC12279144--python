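import numpy as np
import pandas as pd
import pytest

from omicsbn.model_core import CONTINUOUS, DISCRETE, DataMatrix, VariableMeta


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def mixed_meta():
    return [
        VariableMeta("age", CONTINUOUS, "clinical"),
        VariableMeta("sex", DISCRETE, "clinical", ("F", "M")),
        VariableMeta("glucose", CONTINUOUS, "clinical"),
        VariableMeta("metab1", CONTINUOUS, "metabolite"),
        VariableMeta("AS_metab1", CONTINUOUS, "allele_score"),
    ]


@pytest.fixture
def mixed_data(mixed_meta, rng):
    n = 60
    sex = rng.choice(["F", "M"], size=n)
    age = rng.normal(60, 7, n)
    score = rng.normal(0, 1, n)
    metab1 = 0.8 * score + rng.normal(0, 1, n)
    glucose = 0.6 * metab1 + rng.normal(0, 1, n)
    frame = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "glucose": glucose,
            "metab1": metab1,
            "AS_metab1": score,
        },
        index=[f"S{i:03d}" for i in range(n)],
    )
    return DataMatrix(frame, mixed_meta)


def random_dag_edges(rng, nodes, p=0.3):
    """Random DAG over ``nodes`` via a random topological order."""
    order = list(rng.permutation(nodes))
    edges = []
    for i, child in enumerate(order):
        for parent in order[:i]:
            if rng.random() < p:
                edges.append((parent, child))
    return edges
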