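"""Cost model and cost/quality trade-off curves.

Prices a human judgment from an hourly wage and a per-judgment duration, and
a reference-rater (LLM) judgment from per-token API prices, then expresses
each sample type's cost and quality relative to the reference rater: a value
of 1 means parity with the reference rater's cost (or quality).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

HUMAN_ONLY = "human_only"
CENTAUR1 = "centaur1"
CENTAUR2 = "centaur2"
AGGREGATORS = (HUMAN_ONLY, CENTAUR1, CENTAUR2)


@dataclass(frozen=True)
class CostModel:
    """Pricing assumptions for a rating study.

    Defaults: crowd workers at $12/hour producing one judgment every 5 s
    (about $0.017 per judgment), and an API-priced reference rater at
    $0.0003 per 1000 input tokens and $0.0006 per 1000 output tokens with
    roughly 20 input and 10 output tokens per judgment.  All figures are
    deliberately config-exposed: the wage and duration defaults are, if
    anything, underestimates of real crowd costs.
    """

    human_hourly_rate: float = 12.0
    seconds_per_judgment: float = 5.0
    ref_price_per_1k_input_tokens: float = 0.0003
    ref_price_per_1k_output_tokens: float = 0.0006
    ref_input_tokens: float = 20
    ref_output_tokens: float = 10

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")


def human_cost_per_judgment(model: CostModel) -> float:
    """Dollars per human judgment: hourly rate x seconds per judgment / 3600."""
    return model.human_hourly_rate * model.seconds_per_judgment / 3600.0


def reference_cost_per_judgment(model: CostModel) -> float:
    """Dollars per reference-rater judgment from per-1k-token prices."""
    return (
        model.ref_input_tokens * model.ref_price_per_1k_input_tokens / 1000.0
        + model.ref_output_tokens * model.ref_price_per_1k_output_tokens / 1000.0
    )


def implied_hourly_rate(payment: float, completion_minutes: float) -> float:
    """Effective $/hour from a flat study payment and a completion time."""
    if completion_minutes <= 0:
        raise ValueError("completion time must be positive")
    return payment * 60.0 / completion_minutes


def seconds_per_judgment(completion_minutes: float, n_judgments: int) -> float:
    """Average seconds per judgment from a completion time and trial count."""
    if n_judgments <= 0:
        raise ValueError("n_judgments must be positive")
    return completion_minutes * 60.0 / n_judgments


def minutes(mm: int, ss: int) -> float:
    """Convert a mm:ss completion time to fractional minutes."""
    return mm + ss / 60.0


def tradeoff_curve(table: pd.DataFrame, model: CostModel) -> pd.DataFrame:
    """Cost ratio and quality ratio per (k, aggregator) from a sampling table.

    ``table`` is a sampling-analysis frame with columns ``k``, ``aggregator``,
    ``correlation`` and ``reference_correlation`` (one row per participant
    combination).  Per (k, aggregator):

    * quality_ratio = mean combination correlation / mean reference correlation
      (NaN when the mean reference correlation is zero);
    * cost_ratio = k x human cost per judgment / reference cost per judgment,
      with the reference cost added to the numerator for centaur aggregators
      (the reference rater is paid for in a centaur sample).

    Cost is per item-judgment, so list length cancels in the ratio.
    """
    if table.empty:
        raise ValueError("sampling table is empty")
    hc = human_cost_per_judgment(model)
    rc = reference_cost_per_judgment(model)
    if rc == 0:
        raise ValueError("reference cost per judgment is zero; cost ratio undefined")
    rows = []
    grouped = table.groupby(["k", "aggregator"], sort=True)
    for (k, agg), sub in grouped:
        mean_corr = sub["correlation"].mean(skipna=True)
        mean_ref = sub["reference_correlation"].mean(skipna=True)
        quality = mean_corr / mean_ref if mean_ref != 0 else np.nan
        numerator = k * hc + (rc if agg != HUMAN_ONLY else 0.0)
        rows.append(
            {
                "k": int(k),
                "aggregator": agg,
                "cost_ratio": numerator / rc,
                "quality_ratio": quality,
            }
        )
    return pd.DataFrame(rows, columns=["k", "aggregator", "cost_ratio", "quality_ratio"])
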