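"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive — plain-Python loops, closed-form
textbook formulas, no pandas/vectorisation — so that agreement with the
package is evidence, not tautology.
"""

from __future__ import annotations

import itertools
import math


def midranks(values):
    """Average ranks (1-based) with ties sharing their mean rank."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mean_rank = (i + j) / 2.0 + 1.0
        for idx in order[i : j + 1]:
            ranks[idx] = mean_rank
        i = j + 1
    return ranks


def pearson_closed_form(x, y):
    """Textbook product-moment correlation; None when undefined."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxx = sum((v - mx) ** 2 for v in x)
    syy = sum((v - my) ** 2 for v in y)
    if sxx == 0.0 or syy == 0.0:
        return None
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    return sxy / math.sqrt(sxx * syy)


def corr_oracle(x, y, method):
    """Pairwise-deleted correlation; mid-rank-then-Pearson for spearman."""
    pairs = [(a, b) for a, b in zip(x, y) if a == a and b == b]
    if len(pairs) < 3:
        return None
    xs = [p[0] for p in pairs]
    ys = [p[1] for p in pairs]
    if method == "spearman":
        xs = midranks(xs)
        ys = midranks(ys)
    return pearson_closed_form(xs, ys)


def one_sample_t(values, null):
    """Textbook one-sample t with one-tailed ("less") p via the t CDF."""
    from scipy.stats import t as t_dist  # distribution only, not the test

    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    t = (mean - null) / math.sqrt(var / n)
    return t, n - 1, float(t_dist.cdf(t, n - 1))


def brute_force_sampling(trial_rows, gold, reference, method, aggregators):
    """All-subsets reimplementation of the sampling analysis.

    ``trial_rows`` is a list of (participant, list_id, item, response) with
    response None for missing; ``gold``/``reference`` map item -> value.
    Returns {(list_id, k, combo, aggregator): (correlation, ref_correlation)}.
    """
    lists = sorted({r[1] for r in trial_rows})
    out = {}
    for list_id in lists:
        rows = [r for r in trial_rows if r[1] == list_id]
        participants = sorted({r[0] for r in rows})
        items = sorted(
            {r[2] for r in rows if r[2] in gold and r[2] in reference}
        )
        ref_corr = corr_oracle(
            [reference[i] for i in items], [gold[i] for i in items], method
        )
        resp = {}
        for p, _, item, value in rows:
            if item in gold and item in reference:
                resp[(p, item)] = value
        for k in range(1, len(participants) + 1):
            for combo in itertools.combinations(participants, k):
                per_agg_values = {agg: [] for agg in aggregators}
                gold_values = {agg: [] for agg in aggregators}
                for item in items:
                    obs = [
                        resp[(p, item)]
                        for p in combo
                        if resp.get((p, item)) is not None
                    ]
                    mean = sum(obs) / len(obs) if obs else None
                    for agg in aggregators:
                        if agg == "human_only":
                            value = mean
                        elif agg == "centaur1":
                            value = None if mean is None else (mean + reference[item]) / 2.0
                        elif agg == "centaur2":
                            value = (sum(obs) + reference[item]) / (len(obs) + 1.0)
                        else:
                            raise ValueError(agg)
                        if value is not None:
                            per_agg_values[agg].append(value)
                            gold_values[agg].append(gold[item])
                for agg in aggregators:
                    corr = corr_oracle(per_agg_values[agg], gold_values[agg], method)
                    out[(list_id, k, combo, agg)] = (corr, ref_corr)
    return out
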