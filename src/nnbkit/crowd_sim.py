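"""Synthetic rating-study generator and closed-form oracles.

Emulates the list-wise norming design: items are partitioned into lists,
each list is rated by its own raters, and a single reference rater covers
every item.  The generative model is a *parallel-rater* model: each item
has a latent value t ~ Normal(scale midpoint, latent_sd), each human
response is t plus i.i.d. Normal noise (optionally rounded and clipped to
the integer scale), and the reference rater is t plus its own noise.  The
gold standard is the latent value itself by default (so the closed forms
below are exact), with an optional finite "prior crowd" gold for realism.

Under this model the Pearson correlation between one rater and the latent
value is r1 = latent_sd / sqrt(latent_sd^2 + noise_sd^2), and the mean of
k raters correlates at sqrt(k r1^2 / (k r1^2 + 1 - r1^2)) — the
Spearman-Brown prophecy on the correlation scale.  These closed forms give
analytic predictions of the Number Needed to Beat, used as independent
oracles in parameter-recovery tests.

Contamination hooks (catch-trial failers, straight-liners, too-fast
trials) exist to exercise the exclusion pipeline.

Default dimensions follow the concreteness replication this package
models: 17 lists of 50 items, 10 raters per list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ratings_data import (
    TRIAL_CATCH,
    TRIAL_RATING,
    ItemVector,
    RatingScale,
    TrialTable,
    ValidationError,
)

NOT_REACHED = None


@dataclass
class SimConfig:
    """Parameters of a synthetic rating study.

    ``rater_noise_sd`` and ``reference_noise_sd`` are on the latent scale;
    use :func:`noise_sd_for_correlation` to pick them from a target
    rater-gold correlation.  ``rounding`` is "continuous" (default; keeps
    the closed-form oracles exact) or "round-to-scale" (integer responses
    clipped to the scale, as in a real study).  Contamination rates are
    per-participant (catch failure, straight-lining) or per-trial (fast
    responses) probabilities used to test the exclusion filters.
    """

    n_lists: int = 17
    items_per_list: int = 50
    raters_per_list: int = 10
    scale: RatingScale = field(default_factory=lambda: RatingScale(1, 7))
    latent_sd: float = 1.0
    rater_noise_sd: float = 4.0 / 3.0  # single-rater correlation 0.6
    reference_noise_sd: float = 0.75  # reference correlation 0.8
    rounding: str = "continuous"
    catch_expected: int | None = None  # include catch trials when set
    catch_failure_rate: float = 0.0
    straightliner_rate: float = 0.0
    fast_trial_rate: float = 0.0
    rt_mean_ms: float = 2500.0
    gold_crowd_size: int | None = None  # finite prior crowd instead of latent gold
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_lists, self.items_per_list, self.raters_per_list) < 1:
            raise ValidationError("all counts must be >= 1")
        if min(self.latent_sd, self.rater_noise_sd, self.reference_noise_sd) < 0:
            raise ValidationError("noise SDs must be non-negative")
        for rate in (self.catch_failure_rate, self.straightliner_rate, self.fast_trial_rate):
            if not 0 <= rate <= 1:
                raise ValidationError("contamination rates must lie in [0, 1]")
        if self.rounding not in ("continuous", "round-to-scale"):
            raise ValidationError(f"unknown rounding mode {self.rounding!r}")


def noise_sd_for_correlation(r: float, latent_sd: float = 1.0) -> float:
    """Noise SD giving a rater-latent Pearson correlation of ``r``."""
    if not 0 < r <= 1:
        raise ValidationError("correlation must lie in (0, 1]")
    return latent_sd * math.sqrt(1.0 / r**2 - 1.0)


def _round_to_scale(values: np.ndarray, scale: RatingScale) -> np.ndarray:
    return np.clip(np.rint(values), scale.minimum, scale.maximum)


def simulate_study(config: SimConfig) -> tuple[TrialTable, ItemVector, ItemVector]:
    """Generate (trials, gold, reference) for one synthetic study.

    Fully reproducible under ``config.seed``; independent random substreams
    per component, so e.g. turning contamination on does not shift the
    latent values or rater noise.
    """
    root = np.random.SeedSequence(config.seed)
    streams = {
        name: np.random.default_rng(s)
        for name, s in zip(
            ("latent", "raters", "reference", "contamination", "rt", "gold"),
            root.spawn(6),
        )
    }
    scale = config.scale
    mid = scale.midpoint
    n_items = config.n_lists * config.items_per_list

    item_ids = [
        f"L{lst:02d}_I{i:03d}"
        for lst in range(config.n_lists)
        for i in range(config.items_per_list)
    ]
    list_of_item = np.repeat(np.arange(config.n_lists), config.items_per_list)
    latent = mid + streams["latent"].normal(0.0, config.latent_sd, size=n_items)

    # gold standard: latent truth, or the mean of a finite simulated prior crowd
    if config.gold_crowd_size is None:
        gold_values = latent.copy()
    else:
        crowd = latent[None, :] + streams["gold"].normal(
            0.0, config.rater_noise_sd, size=(config.gold_crowd_size, n_items)
        )
        if config.rounding == "round-to-scale":
            crowd = _round_to_scale(crowd, scale)
        gold_values = crowd.mean(axis=0)
    gold = ItemVector(pd.Series(gold_values, index=item_ids), role="gold")

    ref_values = latent + streams["reference"].normal(
        0.0, config.reference_noise_sd, size=n_items
    )
    if config.rounding == "round-to-scale":
        ref_values = _round_to_scale(ref_values, scale)
    reference = ItemVector(pd.Series(ref_values, index=item_ids), role="reference")

    contam = streams["contamination"]
    rows: list[dict] = []
    for lst in range(config.n_lists):
        list_id = f"L{lst:02d}"
        item_idx = np.flatnonzero(list_of_item == lst)
        for r in range(config.raters_per_list):
            pid = f"{list_id}_P{r:02d}"
            is_straightliner = contam.random() < config.straightliner_rate
            responses = latent[item_idx] + streams["raters"].normal(
                0.0, config.rater_noise_sd, size=item_idx.size
            )
            if config.rounding == "round-to-scale" or is_straightliner:
                responses = _round_to_scale(responses, scale)
            if is_straightliner:
                responses[:] = contam.integers(scale.minimum, scale.maximum + 1)
            rts = streams["rt"].gamma(4.0, config.rt_mean_ms / 4.0, size=item_idx.size)
            fast = contam.random(item_idx.size) < config.fast_trial_rate
            rts[fast] = contam.uniform(100.0, 499.0, size=int(fast.sum()))
            for j, idx in enumerate(item_idx):
                rows.append(
                    {
                        "participant_id": pid,
                        "list_id": list_id,
                        "item_id": item_ids[idx],
                        "response": responses[j],
                        "rt_ms": rts[j],
                        "trial_type": TRIAL_RATING,
                    }
                )
            if config.catch_expected is not None:
                fails = contam.random() < config.catch_failure_rate
                wrong = config.catch_expected % (scale.maximum - scale.minimum + 1) + scale.minimum
                rows.append(
                    {
                        "participant_id": pid,
                        "list_id": list_id,
                        "item_id": f"{list_id}_CATCH",
                        "response": float(wrong if fails else config.catch_expected),
                        "rt_ms": float(streams["rt"].gamma(4.0, config.rt_mean_ms / 4.0)),
                        "trial_type": TRIAL_CATCH,
                    }
                )

    frame = pd.DataFrame(rows)
    if config.rounding == "continuous":
        # continuous responses live outside the integer-scale contract; widen
        # the declared scale to the support actually generated
        lo = math.floor(min(frame["response"].min(), scale.minimum))
        hi = math.ceil(max(frame["response"].max(), scale.maximum))
        table_scale = RatingScale(lo, hi)
        frame["response"] = frame["response"].round(9)
    else:
        table_scale = scale
    trials = TrialTable(frame, table_scale)
    return trials, gold, reference


# ---------------------------------------------------------------------------
# closed-form oracles


def expected_pooled_correlation(r1: float, k: int) -> float:
    """Correlation between a k-rater mean and the latent value when a single
    rater correlates at r1 (i.i.d. additive noise):
    sqrt(k r1^2 / (k r1^2 + 1 - r1^2))."""
    if not 0 < r1 < 1:
        raise ValidationError("r1 must lie in (0, 1)")
    if k < 1:
        raise ValidationError("k must be >= 1")
    num = k * r1**2
    return math.sqrt(num / (num + 1.0 - r1**2))


def predicted_nnb(r1: float, r_ref: float) -> int | None:
    """Smallest k with expected_pooled_correlation(r1, k) > r_ref.

    Closed form: k = floor( r_ref^2 (1 - r1^2) / (r1^2 (1 - r_ref^2)) ) + 1.
    Returns the not-reached sentinel (None) when r_ref = 1 — an errorless
    reference can never be strictly beaten.
    """
    if not 0 < r1 < 1:
        raise ValidationError("r1 must lie in (0, 1)")
    if not 0 <= r_ref <= 1:
        raise ValidationError("r_ref must lie in [0, 1]")
    if r_ref >= 1.0:
        return NOT_REACHED
    if r_ref <= r1:
        return 1
    crossing = (r_ref**2 * (1.0 - r1**2)) / (r1**2 * (1.0 - r_ref**2))
    return int(math.floor(crossing)) + 1


# ---------------------------------------------------------------------------
# fixture structure helpers


def relatedness_pair_items(n_words: int = 112, contexts_per_word: int = 4) -> list[str]:
    """Item ids for a contextual-relatedness design: every word appears in
    ``contexts_per_word`` sentences and every unordered sentence pair is one
    item, giving n_words x C(contexts, 2) items (112 x 6 = 672 in the design
    this mirrors)."""
    items = []
    for w in range(n_words):
        for a in range(contexts_per_word):
            for b in range(a + 1, contexts_per_word):
                items.append(f"W{w:03d}_S{a + 1}S{b + 1}")
    return items
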