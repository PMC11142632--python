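"""Number-Needed-to-Beat: sampling analysis, centaur aggregators and tests.

The question: how many human raters must be averaged before the sample
mean's correlation with a gold standard matches a single reference rater's
(e.g. an LLM's)?  For every stimulus list and every sample size k, all
combinations of k retained raters (capped at 500, random without
replacement beyond that) are enumerated; each combination's per-item mean
is correlated with the gold standard and compared with the reference
rater's correlation for the same list.  Pooling combinations across lists,
a one-tailed one-sample t-test asks at which k the difference
(reference - human, tested against 0) or the ratio (reference / human,
tested against 1) becomes significantly negative (below 1): the smallest
such k is the NNB.

Two human+reference hybrid ("centaur") aggregators are evaluated alongside
the human-only sample mean:

* **centaur1** averages the reference rating with the human sample mean
  (reference weight 1/2 regardless of k);
* **centaur2** adds the reference rater to the sample as one more
  participant (reference weight 1/(k+1)).

Combinations sharing raters are treated as independent observations in the
t-tests — a deliberate pseudo-replication that matches how NNB is defined;
no cluster correction is applied.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .agreement import correlate, rowwise_correlations
from .cost_quality import AGGREGATORS, CENTAUR1, CENTAUR2, HUMAN_ONLY
from .ratings_data import ItemVector, StudyConfig, TrialTable, ValidationError

logger = logging.getLogger(__name__)

MODE_DIFFERENCE = "difference"
MODE_RATIO = "ratio"
MODES = (MODE_DIFFERENCE, MODE_RATIO)

#: sentinel for "no tested sample size beat the reference"
NOT_REACHED = None


# ---------------------------------------------------------------------------
# combination enumeration


def enumerate_samples(
    participants, k: int, cap: int = 500, seed: int = 0
) -> list[tuple[str, ...]]:
    """All size-k participant combinations, capped.

    If C(n, k) <= cap, every combination is returned in deterministic
    (lexicographic over the sorted ids) order.  Otherwise ``cap`` distinct
    combinations are drawn uniformly without replacement, reproducibly under
    ``seed`` (rejection sampling on the sorted-tuple encoding).
    """
    pool = sorted(str(p) for p in set(participants))
    n = len(pool)
    if not 1 <= k <= n:
        raise ValidationError(f"sample size k={k} outside [1, {n}]")
    if cap < 1:
        raise ValidationError("cap must be >= 1")
    total = math.comb(n, k)
    if total <= cap:
        return [tuple(c) for c in itertools.combinations(pool, k)]
    rng = np.random.default_rng(seed)
    chosen: set[tuple[int, ...]] = set()
    while len(chosen) < cap:
        combo = tuple(sorted(rng.choice(n, size=k, replace=False).tolist()))
        chosen.add(combo)
    return [tuple(pool[i] for i in combo) for combo in sorted(chosen)]


# ---------------------------------------------------------------------------
# centaur aggregators


def centaur1(sample_mean: ItemVector, reference: ItemVector) -> ItemVector:
    """Average of the human sample mean and the reference rating, per item,
    over the item intersection."""
    common = sample_mean.items.intersection(reference.items)
    if len(common) == 0:
        raise ValidationError("sample mean and reference share no items")
    common = sample_mean.items[sample_mean.items.isin(common)]
    merged = (sample_mean.values[common] + reference.values[common]) / 2.0
    return ItemVector(merged, role="centaur")


def centaur2(trials: TrialTable, combination, reference: ItemVector) -> ItemVector:
    """Sample mean with the reference rater included as one extra participant.

    Per item: (sum of the k human responses + reference rating) / (m + 1)
    where m is the number of non-missing human responses for that item.
    Only items carried by the reference vector appear in the output.
    """
    chosen = sorted(set(combination))
    sub = trials.ratings()
    sub = sub[sub["participant_id"].isin(chosen)]
    if set(sub["participant_id"]) != set(chosen):
        raise ValidationError("combination contains unknown participants")
    if sub["list_id"].nunique() > 1:
        raise ValidationError("combination spans multiple lists")
    rated = sub.dropna(subset=["response"])
    sums = rated.groupby("item_id")["response"].sum().astype(float)
    counts = rated.groupby("item_id")["response"].count()
    common = sums.index.intersection(reference.items)
    if len(common) == 0:
        raise ValidationError("combination and reference share no items")
    values = (sums[common] + reference.values[common]) / (counts[common] + 1.0)
    return ItemVector(values, role="centaur")


# ---------------------------------------------------------------------------
# sampling analysis


def _aggregate(agg: str, sums: np.ndarray, counts: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Per-combination item estimates from response sums/counts.

    ``sums``/``counts`` are (n_combos, n_items); items nobody in a
    combination rated come out NaN (human_only, centaur1) and are handled by
    pairwise deletion downstream.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / counts, np.nan)
        if agg == HUMAN_ONLY:
            return means
        if agg == CENTAUR1:
            return (means + ref) / 2.0
        if agg == CENTAUR2:
            return (sums + ref) / (counts + 1.0)
    raise ValidationError(f"unknown aggregator {agg!r}")


def sampling_analysis(
    trials: TrialTable,
    gold: ItemVector,
    reference: ItemVector,
    ks=None,
    aggregators=AGGREGATORS,
    config: StudyConfig | None = None,
) -> pd.DataFrame:
    """Correlation with gold for every (list, k, combination, aggregator).

    ``trials`` should already be exclusion-cleaned.  For every list the
    analysis items are the list's items intersected with the gold and
    reference vectors; the reference rater's own correlation with gold on
    those items is recorded alongside every row.  ``ks`` defaults to
    1 .. min over lists of the retained per-list n.  Returns a long frame
    with columns list_id, k, combination (sorted tuple of participant ids),
    aggregator, correlation, reference_correlation.
    """
    if config is None:
        raise ValidationError("a StudyConfig is required (cap, method, seed)")
    aggregators = tuple(aggregators)
    unknown = set(aggregators) - set(AGGREGATORS)
    if unknown:
        raise ValidationError(f"unknown aggregators: {sorted(unknown)}")
    lists = trials.lists
    if not lists:
        raise ValidationError("no lists in trial table")
    if ks is None:
        n_min = min(len(trials.participants_in(lst)) for lst in lists)
        ks = range(1, n_min + 1)
    ks = sorted(set(int(k) for k in ks))
    if not ks:
        raise ValidationError("ks must be non-empty")

    method = config.correlation_method
    rows: list[dict] = []
    for list_index, list_id in enumerate(lists):
        matrix = trials.response_matrix(list_id)
        items = matrix.columns.intersection(gold.items).intersection(reference.items)
        if len(items) < 3:
            logger.warning("list %s has <3 analysable items; skipped", list_id)
            continue
        R = matrix[items].to_numpy(dtype=float)
        g = gold.values[items].to_numpy()
        ref = reference.values[items].to_numpy()
        ref_corr = correlate(ref, g, method)
        pool = list(matrix.index)
        index_of = {p: i for i, p in enumerate(pool)}
        n = len(pool)
        valid = ~np.isnan(R)
        R0 = np.where(valid, R, 0.0)

        for k in ks:
            if k > n:
                continue
            seed = int(
                np.random.SeedSequence([config.rng_seed, list_index, k]).generate_state(1)[0]
                % (2**31)
            )
            combos = enumerate_samples(pool, k, config.combination_cap, seed)
            idx = np.array([[index_of[p] for p in c] for c in combos])
            sums = R0[idx].sum(axis=1)
            counts = valid[idx].sum(axis=1).astype(float)
            for agg in aggregators:
                estimates = _aggregate(agg, sums, counts, ref)
                corrs = rowwise_correlations(estimates, g, method)
                for combo, r in zip(combos, corrs):
                    rows.append(
                        {
                            "list_id": list_id,
                            "k": k,
                            "combination": combo,
                            "aggregator": agg,
                            "correlation": r,
                            "reference_correlation": ref_corr,
                        }
                    )
    table = pd.DataFrame(
        rows,
        columns=[
            "list_id",
            "k",
            "combination",
            "aggregator",
            "correlation",
            "reference_correlation",
        ],
    )
    if table.empty:
        raise ValidationError("sampling analysis produced no rows")
    return table


# ---------------------------------------------------------------------------
# hypothesis tests and NNB


@dataclass(frozen=True)
class TestResult:
    t: float  # NaN when the pooled statistic has zero variance
    df: int
    p: float
    n_dropped: int = 0  # undefined per-combination statistics removed


def nnb_test(table: pd.DataFrame, k: int, aggregator: str, mode: str) -> TestResult:
    """One-tailed one-sample t-test of reference-vs-sample quality at size k.

    Pools every combination at (k, aggregator) across lists.  Per
    combination the statistic is ``reference_correlation - correlation``
    (mode "difference", tested against 0) or
    ``reference_correlation / correlation`` (mode "ratio", tested against
    1); the alternative is "less than", i.e. the human (or centaur) sample
    beats the reference.  Undefined per-combination statistics (NaN
    correlations, zero denominators) are dropped with a logged count.  With
    zero variance across combinations the t statistic is undefined and p is
    0 when every value lies on the alternative side, 1 otherwise.
    """
    if mode not in MODES:
        raise ValidationError(f"unknown mode {mode!r}")
    sub = table[(table["k"] == k) & (table["aggregator"] == aggregator)]
    ref = sub["reference_correlation"].to_numpy(dtype=float)
    corr = sub["correlation"].to_numpy(dtype=float)
    if mode == MODE_DIFFERENCE:
        values = ref - corr
        null = 0.0
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            values = np.where(corr != 0, ref / corr, np.nan)
        null = 1.0
    defined = np.isfinite(values)
    n_dropped = int((~defined).sum())
    if n_dropped:
        logger.info(
            "k=%d %s/%s: dropped %d undefined combination statistics",
            k, aggregator, mode, n_dropped,
        )
    values = values[defined]
    if values.size < 2:
        raise ValidationError(
            f"need >= 2 defined combinations at k={k}, aggregator={aggregator}"
        )
    if values.std(ddof=1) == 0.0:
        logger.warning("zero variance at k=%d (%s/%s); t undefined", k, aggregator, mode)
        p = 0.0 if values[0] < null else 1.0
        return TestResult(t=float("nan"), df=values.size - 1, p=p, n_dropped=n_dropped)
    res = stats.ttest_1samp(values, popmean=null, alternative="less")
    return TestResult(
        t=float(res.statistic), df=values.size - 1, p=float(res.pvalue), n_dropped=n_dropped
    )


@dataclass
class NNBReport:
    """Per-k test curve and the Number Needed to Beat for one aggregator.

    ``nnb`` maps mode -> smallest k whose one-tailed p falls below alpha, or
    ``None`` when no tested k is significant (the reference rater is never
    beaten in the tested range).  The full curve is kept so non-monotonic
    significance patterns stay visible; NNB is the *smallest* significant k
    with no requirement that larger k remain significant.
    """

    aggregator: str
    alpha: float
    curve: pd.DataFrame  # columns: k, mode, t, df, p, n_dropped
    nnb: dict[str, int | None] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "aggregator": self.aggregator,
            "alpha": self.alpha,
            "nnb": {m: ("not_reached" if v is NOT_REACHED else v) for m, v in self.nnb.items()},
            "curve": self.curve.to_dict(orient="records"),
        }


def compute_nnb(table: pd.DataFrame, aggregator: str = HUMAN_ONLY, alpha: float = 0.05) -> NNBReport:
    """Smallest sample size whose quality significantly exceeds the reference.

    Runs :func:`nnb_test` in both difference and ratio modes at every k
    present for ``aggregator`` and returns the per-k curve plus the NNB per
    mode (``None`` when not reached).
    """
    ks = sorted(table.loc[table["aggregator"] == aggregator, "k"].unique())
    if not ks:
        raise ValidationError(f"no rows for aggregator {aggregator!r}")
    records = []
    nnb: dict[str, int | None] = {}
    for mode in MODES:
        found: int | None = NOT_REACHED
        for k in ks:
            res = nnb_test(table, int(k), aggregator, mode)
            records.append(
                {
                    "k": int(k),
                    "mode": mode,
                    "t": res.t,
                    "df": res.df,
                    "p": res.p,
                    "n_dropped": res.n_dropped,
                }
            )
            if found is NOT_REACHED and res.p < alpha:
                found = int(k)
        nnb[mode] = found
    curve = pd.DataFrame(records, columns=["k", "mode", "t", "df", "p", "n_dropped"])
    return NNBReport(aggregator=aggregator, alpha=alpha, curve=curve, nnb=nnb)
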