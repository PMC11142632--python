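from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from nnbkit import ItemVector, RatingScale, StudyConfig, TrialTable


def make_trials(rows, scale=None):
    """Build a TrialTable from (participant, list, item, response[, rt, type])
    tuples; response None -> missing."""
    records = []
    for row in rows:
        participant, list_id, item, response = row[:4]
        rt = row[4] if len(row) > 4 else np.nan
        trial_type = row[5] if len(row) > 5 else "rating"
        records.append(
            {
                "participant_id": participant,
                "list_id": list_id,
                "item_id": item,
                "response": np.nan if response is None else response,
                "rt_ms": rt,
                "trial_type": trial_type,
            }
        )
    return TrialTable(pd.DataFrame(records), scale or RatingScale(1, 7))


@pytest.fixture
def scale17():
    return RatingScale(1, 7)


@pytest.fixture
def config17(scale17):
    return StudyConfig(scale=scale17, correlation_method="pearson", rng_seed=11)


@pytest.fixture
def two_list_study():
    """Two lists x three raters x four items, hand-checkable, one missing
    response, plus gold and reference vectors covering every item."""
    rows = []
    rng = np.random.default_rng(7)
    gold = {}
    ref = {}
    for lst in ("A", "B"):
        for i in range(4):
            item = f"{lst}{i}"
            gold[item] = float(1 + (i * 7 + (lst == "B") * 3) % 6)
            ref[item] = gold[item] + float(rng.normal(0, 0.8))
        for p in range(3):
            pid = f"{lst}_p{p}"
            for i in range(4):
                item = f"{lst}{i}"
                if lst == "A" and p == 0 and i == 3:
                    rows.append((pid, lst, item, None))
                else:
                    noisy = gold[item] + float(rng.normal(0, 1.0))
                    rows.append((pid, lst, item, min(7, max(1, round(noisy)))))
    trials = make_trials(rows)
    return (
        trials,
        ItemVector(pd.Series(gold), role="gold"),
        ItemVector(pd.Series(ref), role="reference"),
    )
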