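"""Participant- and trial-level exclusion filters.

Four data-quality screens are applied before any sampling analysis, in the
order catch -> response-time -> straight-liner -> gold-correlation (so the
correlation screen only sees plausible trials):

* **catch trials**: participants who answer an embedded instructed-response
  item incorrectly are dropped;
* **response-time floor**: individual rating trials answered faster than a
  minimum (default 500 ms) are dropped;
* **straight-liners**: participants whose modal response covers strictly
  more than a set share (default 80%) of their trials are dropped;
* **gold-standard screen**: participants whose ratings correlate with the
  published gold standard below a threshold (default 0.1) are dropped.

All boundary comparisons are strict ("less than 0.1", "under 500 ms",
"over 80%").  The catch and RT/straight-liner screens are per-dataset
options; the gold screen always applies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .agreement import correlate
from .ratings_data import (
    TRIAL_CATCH,
    ItemVector,
    SchemaError,
    StudyConfig,
    TrialTable,
    ValidationError,
)

logger = logging.getLogger(__name__)

REASON_CATCH = "catch_fail"
REASON_GOLD = "low_gold_correlation"
REASON_STRAIGHTLINER = "straightliner"


@dataclass
class ExclusionReport:
    """Outcome of the exclusion pipeline.

    ``excluded`` maps each removed participant to one or more reasons;
    ``gold_correlations`` records the screening correlation for every
    participant that reached that filter (including retained ones).
    """

    retained_participants: set[str] = field(default_factory=set)
    excluded: dict[str, list[str]] = field(default_factory=dict)
    dropped_trials: int = 0
    gold_correlations: dict[str, float] = field(default_factory=dict)

    def add(self, participant: str, reason: str) -> None:
        self.excluded.setdefault(participant, [])
        if reason not in self.excluded[participant]:
            self.excluded[participant].append(reason)

    def to_dict(self) -> dict:
        return {
            "retained_participants": sorted(self.retained_participants),
            "excluded_participants": {p: r for p, r in sorted(self.excluded.items())},
            "dropped_trials": self.dropped_trials,
            "gold_correlations": {p: v for p, v in sorted(self.gold_correlations.items())},
        }


def catch_trial_filter(trials: TrialTable, expected) -> tuple[TrialTable, set[str]]:
    """Drop participants who answered any catch trial incorrectly.

    ``expected`` is the required catch response (an int applying to all
    lists, or a mapping list_id -> int).  Participants without a catch trial
    are retained — with a warning, since a catch-enabled design should show
    one per participant.  Catch trials themselves are removed from the
    surviving table.
    """
    df = trials.frame
    catch = df[df["trial_type"] == TRIAL_CATCH]
    excluded: set[str] = set()
    for _, row in catch.iterrows():
        exp = expected.get(row["list_id"]) if hasattr(expected, "get") else expected
        if exp is None:
            continue
        if not trials.scale.contains(exp):
            raise ValidationError(f"expected catch response {exp} outside scale")
        resp = row["response"]
        if resp is None or resp != exp:
            excluded.add(row["participant_id"])
    no_catch = set(trials.participants) - set(catch["participant_id"])
    if no_catch and len(catch):
        logger.warning(
            "%d participant(s) have no catch trial in a catch-enabled dataset; retained",
            len(no_catch),
        )
    keep = df[df["trial_type"] != TRIAL_CATCH]
    keep = keep[~keep["participant_id"].isin(excluded)]
    return TrialTable(keep, trials.scale), excluded


def rt_filter(trials: TrialTable, min_ms: float) -> tuple[TrialTable, int]:
    """Drop rating trials answered strictly faster than ``min_ms``.

    Participants are retained even if some of their trials are dropped.
    """
    df = trials.frame
    if df["rt_ms"].isna().all():
        raise SchemaError("response-time filter enabled but rt_ms column is empty")
    fast = df["rt_ms"].notna() & (df["rt_ms"] < min_ms)
    dropped = int(fast.sum())
    return TrialTable(df[~fast], trials.scale), dropped


def straightliner_filter(trials: TrialTable, proportion: float) -> tuple[TrialTable, set[str]]:
    """Drop participants whose modal response exceeds ``proportion`` of their
    non-missing rating trials (strictly greater)."""
    if not 0 < proportion < 1:
        raise ValidationError("proportion must lie in (0, 1)")
    ratings = trials.ratings().dropna(subset=["response"])
    excluded: set[str] = set()
    for participant, sub in ratings.groupby("participant_id"):
        modal_share = sub["response"].value_counts(normalize=True).iloc[0]
        if modal_share > proportion:
            excluded.add(str(participant))
    keep = trials.frame[~trials.frame["participant_id"].isin(excluded)]
    return TrialTable(keep, trials.scale), excluded


def gold_correlation_filter(
    trials: TrialTable,
    gold: ItemVector,
    method: str = "spearman",
    threshold: float = 0.1,
) -> tuple[TrialTable, set[str], dict[str, float]]:
    """Drop participants whose ratings correlate with the gold standard
    strictly below ``threshold``.

    Every participant needs at least three items overlapping the gold vector
    (an error otherwise — the screen is meaningless below that).  A
    participant whose correlation is undefined (constant responses) is
    retained with a warning; constant responders are the straight-liner
    filter's business.
    """
    correlations: dict[str, float] = {}
    excluded: set[str] = set()
    ratings = trials.ratings()
    for participant, sub in ratings.groupby("participant_id"):
        merged = sub.dropna(subset=["response"]).set_index("item_id")["response"]
        common = merged.index.intersection(gold.items)
        if len(common) < 3:
            raise ValidationError(
                f"participant {participant!r} has only {len(common)} items "
                "overlapping the gold standard; screening correlation undefined"
            )
        r = correlate(
            merged[common].to_numpy(dtype=float),
            gold.values[common].to_numpy(),
            method,
        )
        correlations[str(participant)] = r
        if r != r:  # NaN
            logger.warning(
                "participant %s has an undefined gold correlation; retained", participant
            )
        elif r < threshold:
            excluded.add(str(participant))
    keep = trials.frame[~trials.frame["participant_id"].isin(excluded)]
    return TrialTable(keep, trials.scale), excluded, correlations


def run_exclusions(
    trials: TrialTable, gold: ItemVector, config: StudyConfig
) -> tuple[TrialTable, ExclusionReport]:
    """Apply the configured filters in order catch -> RT -> straight-liner ->
    gold-correlation and report every exclusion with its reason."""
    report = ExclusionReport()
    table = trials

    if config.catch_expected is not None:
        table, catch_excluded = catch_trial_filter(table, config.catch_expected)
        for p in catch_excluded:
            report.add(p, REASON_CATCH)
    else:
        # strip any stray catch trials so downstream stages see ratings only
        df = table.frame[table.frame["trial_type"] != TRIAL_CATCH]
        table = TrialTable(df, table.scale)

    if config.apply_rt_filter:
        table, dropped = rt_filter(table, config.rt_min_ms)
        report.dropped_trials = dropped

    if config.apply_straightliner:
        table, straight = straightliner_filter(table, config.straightliner_prop)
        for p in straight:
            report.add(p, REASON_STRAIGHTLINER)

    table, low_gold, correlations = gold_correlation_filter(
        table, gold, config.correlation_method, config.gold_corr_threshold
    )
    for p in low_gold:
        report.add(p, REASON_GOLD)
    report.gold_correlations = correlations
    report.retained_participants = set(table.participants)
    logger.info(
        "exclusions: %d retained, %d excluded, %d trials dropped by RT filter",
        len(report.retained_participants),
        len(report.excluded),
        report.dropped_trials,
    )
    return table, report
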