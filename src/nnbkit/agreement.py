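"""Correlation engine and list-wise agreement summaries.

Both Pearson's r and Spearman's rho (tie-aware, mid-rank convention) are
supported.  Correlations on fewer than three paired observations, or with a
constant input, are *undefined* and reported as NaN rather than raised —
undefined entries are excluded from summaries with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .ratings_data import ItemVector

logger = logging.getLogger(__name__)

MIN_PAIRS = 3  # below this a correlation is an artifact, not an estimate


def correlate(x, y, method: str = "pearson") -> float:
    """Correlation between two real vectors; NaN when undefined.

    Missing (NaN) entries are removed pairwise.  ``spearman`` is computed as
    Pearson on mid-ranks (ties receive their average rank).  Returns NaN —
    with a log message — when fewer than ``MIN_PAIRS`` pairs remain or either
    vector is constant.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < MIN_PAIRS:
        logger.debug("correlation undefined: only %d complete pairs", x.size)
        return float("nan")
    if method == "spearman":
        x = stats.rankdata(x)  # mid-ranks for ties
        y = stats.rankdata(y)
    sx = x.std()
    sy = y.std()
    if sx == 0.0 or sy == 0.0:
        logger.debug("correlation undefined: constant input vector")
        return float("nan")
    r = float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))
    return max(-1.0, min(1.0, r))


def rowwise_correlations(matrix: np.ndarray, target: np.ndarray, method: str) -> np.ndarray:
    """Correlation of each row of ``matrix`` with ``target``.

    Fully vectorised when the matrix is complete; rows containing NaN fall
    back to :func:`correlate` with pairwise deletion.  Rows with constant
    values (or too few pairs) yield NaN.
    """
    matrix = np.asarray(matrix, dtype=float)
    target = np.asarray(target, dtype=float)
    nan_rows = np.isnan(matrix).any(axis=1)
    out = np.full(matrix.shape[0], np.nan)
    clean = ~nan_rows
    if clean.any():
        M = matrix[clean]
        if method == "spearman":
            M = stats.rankdata(M, axis=1)
            t = stats.rankdata(target)
        else:
            t = target
        Mc = M - M.mean(axis=1, keepdims=True)
        tc = t - t.mean()
        denom = np.sqrt((Mc**2).sum(axis=1) * (tc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, Mc @ tc / denom, np.nan)
        out[clean] = np.clip(r, -1.0, 1.0)
    for i in np.flatnonzero(nan_rows):
        out[i] = correlate(matrix[i], target, method)
    return out


@dataclass
class ListwiseCorrelations:
    """Per-(list, rater-or-sample) correlations with the gold standard.

    ``frame`` has columns list_id, rater_id, correlation (NaN = undefined);
    ``method`` records which correlation was used.  The reference rater, when
    present, appears under ``rater_id == "reference"``.
    """

    frame: pd.DataFrame
    method: str

    REFERENCE_ID = "reference"

    def entry(self, list_id: str, rater_id: str) -> float:
        sub = self.frame[
            (self.frame["list_id"] == list_id) & (self.frame["rater_id"] == rater_id)
        ]
        if sub.empty:
            raise KeyError((list_id, rater_id))
        return float(sub["correlation"].iloc[0])


def listwise_correlations(
    ratings: Mapping[tuple[str, str], ItemVector],
    gold: ItemVector,
    method: str = "spearman",
) -> ListwiseCorrelations:
    """Correlate each (list, rater/sample) item vector with the gold standard.

    ``ratings`` maps (list_id, rater_id) to an ItemVector; each entry is
    correlated with gold over the intersection of items.  Entries with fewer
    than three overlapping items are undefined (NaN).
    """
    rows = []
    for (list_id, rater_id), vec in ratings.items():
        v, g = vec.aligned_with(gold)
        rows.append(
            {
                "list_id": list_id,
                "rater_id": rater_id,
                "correlation": correlate(v, g, method),
            }
        )
    frame = pd.DataFrame(rows, columns=["list_id", "rater_id", "correlation"])
    return ListwiseCorrelations(frame, method)


@dataclass(frozen=True)
class AgreementSummary:
    mean: float
    sd: float  # NaN with a single entry
    count: int
    #: fraction of (non-reference) raters whose correlation falls below the
    #: reference rater's correlation on the same list; NaN if no reference
    reference_exceedance: float


def summarize(corrs: ListwiseCorrelations) -> AgreementSummary:
    """Mean/SD/count of defined rater correlations, plus the fraction of
    raters the reference rater beats on their own list."""
    ref_id = ListwiseCorrelations.REFERENCE_ID
    frame = corrs.frame
    raters = frame[frame["rater_id"] != ref_id]
    defined = raters.dropna(subset=["correlation"])
    n_undefined = len(raters) - len(defined)
    if n_undefined:
        logger.info("excluding %d undefined correlations from summary", n_undefined)
    if defined.empty:
        raise ValueError("no defined correlations to summarize")
    values = defined["correlation"].to_numpy()
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if len(values) > 1 else float("nan")

    refs = frame[frame["rater_id"] == ref_id].set_index("list_id")["correlation"]
    if refs.empty:
        frac = float("nan")
    else:
        ref_for_rater = defined["list_id"].map(refs)
        comparable = ref_for_rater.notna()
        if comparable.any():
            frac = float(
                (defined.loc[comparable, "correlation"] < ref_for_rater[comparable]).mean()
            )
        else:
            frac = float("nan")
    return AgreementSummary(mean=mean, sd=sd, count=len(values), reference_exceedance=frac)
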