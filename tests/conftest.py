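import numpy as np
import pandas as pd
import pytest

from cleavemap.activity import ActivityMatrix, CallMatrix


def make_raw_rows(experiment, target, entries, background=2.0, replicates=1):
    """Long-format raw rows: entries maps variant -> raw percentage."""
    rows = []
    for r in range(1, replicates + 1):
        rows.append(
            {
                "experiment_id": experiment,
                "variant_id": "dead",
                "target_id": target,
                "value": background,
                "replicate": r,
                "modality": "disruption",
                "day": 4,
                "is_background": True,
            }
        )
        for vid, val in entries.items():
            rows.append(
                {
                    "experiment_id": experiment,
                    "variant_id": vid,
                    "target_id": target,
                    "value": val,
                    "replicate": r,
                    "modality": "disruption",
                    "day": 4,
                    "is_background": False,
                }
            )
    return rows


def bool_matrix(rows, variant_ids, target_ids):
    df = pd.DataFrame(rows, index=variant_ids, columns=target_ids).astype("boolean")
    return CallMatrix(calls=df, theta=0.20)


def act_matrix(values, variant_ids, target_ids):
    df = pd.DataFrame(np.round(np.asarray(values, float), 2), index=variant_ids, columns=target_ids)
    return ActivityMatrix(values=df)


@pytest.fixture
def staircase_calls():
    # perfect Guttman staircase, 4 variants x 5 targets
    rows = [
        [1, 1, 1, 1, 1],
        [1, 1, 1, 1, 0],
        [1, 1, 0, 0, 0],
        [1, 0, 0, 0, 0],
    ]
    return bool_matrix(rows, ["A", "B", "C", "D"], [f"t{i}" for i in range(1, 6)])
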