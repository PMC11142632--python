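"""Domain types and I/O for rating-study data.

A rating study in this package is a *list-wise* norming design: stimuli
(items) are partitioned into lists, each participant rates every item of
exactly one list on a bounded integer scale, and per-item means from a
previously published large sample serve as the gold standard.  Three tables
describe a study:

* a long-format **trial table** (one row per participant x item judgment,
  with optional response time and a trial-type flag for catch trials);
* **item vectors** mapping item -> value (gold-standard means, a reference
  rater's single ratings, sample means, hybrid "centaur" estimates);
* a **study configuration** holding scale bounds, exclusion thresholds,
  resampling settings and cost parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .cost_quality import CostModel

logger = logging.getLogger(__name__)

TRIAL_RATING = "rating"
TRIAL_CATCH = "catch"

#: canonical trial-table columns, in canonical order
TRIAL_COLUMNS = ("participant_id", "list_id", "item_id", "response", "rt_ms", "trial_type")
_REQUIRED_TRIAL_COLUMNS = ("participant_id", "list_id", "item_id", "response")

#: recognised item-vector roles
ITEM_ROLES = ("gold", "reference", "sample_mean", "centaur")


class SchemaError(ValueError):
    """A required column is missing or a file is structurally malformed."""


class ValidationError(ValueError):
    """Row-level content violates a study invariant."""


@dataclass(frozen=True)
class RatingScale:
    """Bounded integer response scale (e.g. 1-5 relatedness, 1-7 concreteness).

    ``missing_codes`` are response tokens treated as missing data (such as a
    "don't know" option) rather than as ratings.
    """

    minimum: int
    maximum: int
    missing_codes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if int(self.minimum) != self.minimum or int(self.maximum) != self.maximum:
            raise ValidationError("scale bounds must be integers")
        if not self.minimum < self.maximum:
            raise ValidationError(
                f"scale minimum ({self.minimum}) must be below maximum ({self.maximum})"
            )
        object.__setattr__(self, "missing_codes", frozenset(str(c) for c in self.missing_codes))

    def contains(self, value: float) -> bool:
        return self.minimum <= value <= self.maximum

    @property
    def midpoint(self) -> float:
        return (self.minimum + self.maximum) / 2.0


@dataclass
class ItemVector:
    """Ordered mapping item_id -> real value with a role tag.

    Values are stored as a float pandas Series indexed by item id.  Item ids
    must be unique and values finite.
    """

    values: pd.Series
    role: str = "gold"

    def __post_init__(self) -> None:
        s = pd.Series(self.values, dtype=float)
        s.index = s.index.astype(str)
        s.index.name = "item_id"
        s.name = None
        if s.index.has_duplicates:
            dupes = s.index[s.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate item ids: {dupes}")
        if len(s) and not np.isfinite(s.to_numpy()).all():
            raise ValidationError("item values must be finite")
        if self.role not in ITEM_ROLES:
            raise ValidationError(f"unknown role {self.role!r}; expected one of {ITEM_ROLES}")
        self.values = s

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, item_id: str) -> float:
        return float(self.values[item_id])

    @property
    def items(self) -> pd.Index:
        return self.values.index

    def aligned_with(self, other: "ItemVector") -> tuple[np.ndarray, np.ndarray]:
        """Return (self, other) value arrays over the item intersection, in
        self's item order."""
        common = self.items.intersection(other.items)
        common = self.items[self.items.isin(common)]
        return self.values[common].to_numpy(), other.values[common].to_numpy()


@dataclass
class TrialTable:
    """Long-format human trial data.

    One row per presented stimulus: ``participant_id``, ``list_id``,
    ``item_id``, ``response`` (nullable numeric on the study scale),
    ``rt_ms`` (response time, NaN if unrecorded) and ``trial_type``
    ("rating" or "catch").  Invariants enforced on construction: each
    participant belongs to exactly one list, no participant rates the same
    item twice, and every non-missing response lies within scale bounds.
    """

    frame: pd.DataFrame
    scale: RatingScale

    def __post_init__(self) -> None:
        df = self.frame.copy()
        for col in _REQUIRED_TRIAL_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"trial table is missing required column {col!r}")
        if "rt_ms" not in df.columns:
            df["rt_ms"] = np.nan
        if "trial_type" not in df.columns:
            df["trial_type"] = TRIAL_RATING
        for col in ("participant_id", "list_id", "item_id"):
            df[col] = df[col].astype(str)
        df["trial_type"] = df["trial_type"].fillna(TRIAL_RATING).astype(str)
        bad_types = set(df["trial_type"]) - {TRIAL_RATING, TRIAL_CATCH}
        if bad_types:
            raise ValidationError(f"unknown trial_type values: {sorted(bad_types)}")
        df["response"] = df["response"].astype("Float64")
        df["rt_ms"] = pd.to_numeric(df["rt_ms"], errors="raise").astype(float)
        df = df[list(TRIAL_COLUMNS)].reset_index(drop=True)

        resp = df["response"]
        present = resp.notna()
        out_of_scale = present & ~resp[present].map(self.scale.contains).reindex(df.index, fill_value=False)
        if out_of_scale.any():
            row = int(np.flatnonzero(out_of_scale.to_numpy())[0])
            raise ValidationError(
                f"response {resp.iloc[row]} at row {row} outside scale "
                f"[{self.scale.minimum}, {self.scale.maximum}]"
            )
        if (df["rt_ms"].dropna() < 0).any():
            raise ValidationError("negative response times")

        rating = df[df["trial_type"] == TRIAL_RATING]
        dup = rating.duplicated(subset=["participant_id", "item_id"])
        if dup.any():
            p, i = rating.loc[dup.idxmax(), ["participant_id", "item_id"]]
            raise ValidationError(f"duplicate rating of item {i!r} by participant {p!r}")
        lists_per = df.groupby("participant_id")["list_id"].nunique()
        multi = lists_per[lists_per > 1]
        if len(multi):
            raise ValidationError(
                f"participant(s) assigned to multiple lists: {multi.index.tolist()}"
            )
        self.frame = df

    # -- views -------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def participants(self) -> list[str]:
        return sorted(self.frame["participant_id"].unique())

    @property
    def lists(self) -> list[str]:
        return sorted(self.frame["list_id"].unique())

    def list_of(self, participant_id: str) -> str:
        rows = self.frame.loc[self.frame["participant_id"] == participant_id, "list_id"]
        if rows.empty:
            raise KeyError(participant_id)
        return rows.iloc[0]

    def participants_in(self, list_id: str) -> list[str]:
        mask = self.frame["list_id"] == list_id
        return sorted(self.frame.loc[mask, "participant_id"].unique())

    def ratings(self) -> pd.DataFrame:
        """Rating trials only (catch trials removed)."""
        return self.frame[self.frame["trial_type"] == TRIAL_RATING]

    def without_participants(self, participant_ids: Iterable[str]) -> "TrialTable":
        drop = set(participant_ids)
        keep = ~self.frame["participant_id"].isin(drop)
        return TrialTable(self.frame[keep], self.scale)

    def response_matrix(self, list_id: str) -> pd.DataFrame:
        """Participants x items float matrix of rating responses for one list
        (NaN where a response is missing)."""
        sub = self.ratings()
        sub = sub[sub["list_id"] == list_id]
        mat = sub.pivot(index="participant_id", columns="item_id", values="response")
        return mat.astype(float).sort_index()


@dataclass
class StudyConfig:
    """All tunable study constants in one place.

    Defaults follow the replication design this package models: gold-standard
    screening threshold 0.1, response-time floor 500 ms, straight-liner cut at
    80% modal responses, at most 500 participant combinations per (list, k),
    one-tailed alpha 0.05, Spearman correlations.  The RT and straight-liner
    filters are per-dataset options (they were applied only to the iconicity
    norms), so they carry explicit enable flags.
    """

    scale: RatingScale
    catch_expected: Mapping[str, int] | int | None = None
    gold_corr_threshold: float = 0.1
    rt_min_ms: float = 500.0
    apply_rt_filter: bool = False
    straightliner_prop: float = 0.8
    apply_straightliner: bool = False
    combination_cap: int = 500
    alpha: float = 0.05
    correlation_method: str = "spearman"
    cost: CostModel = field(default_factory=CostModel)
    rng_seed: int = 0
    column_map: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.combination_cap < 1:
            raise ValidationError("combination_cap must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if not 0 < self.straightliner_prop < 1:
            raise ValidationError("straightliner_prop must lie in (0, 1)")
        if self.rt_min_ms < 0 or self.gold_corr_threshold < -1:
            raise ValidationError("thresholds out of range")
        if self.correlation_method not in ("pearson", "spearman"):
            raise ValidationError(f"unknown correlation method {self.correlation_method!r}")

    def expected_catch(self, list_id: str) -> int | None:
        if self.catch_expected is None:
            return None
        if isinstance(self.catch_expected, Mapping):
            return self.catch_expected.get(list_id)
        return int(self.catch_expected)

    #: run-level keys that may share a config file with StudyConfig fields
    _PIPELINE_KEYS = ("trials", "gold", "reference", "ks", "aggregators")

    @classmethod
    def from_dict(cls, raw: Mapping) -> "StudyConfig":
        raw = dict(raw)
        for key in cls._PIPELINE_KEYS:
            raw.pop(key, None)
        scale_raw = raw.pop("scale")
        scale = RatingScale(
            minimum=int(scale_raw["minimum"]),
            maximum=int(scale_raw["maximum"]),
            missing_codes=frozenset(scale_raw.get("missing_codes", ()) or ()),
        )
        cost = CostModel(**raw.pop("cost", {}) or {})
        known = {f for f in cls.__dataclass_fields__ if f not in ("scale", "cost")}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(scale=scale, cost=cost, **raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def with_seed(self, seed: int) -> "StudyConfig":
        return replace(self, rng_seed=int(seed))


# ---------------------------------------------------------------------------
# readers / writers


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_trials(path: str | Path, config: StudyConfig) -> TrialTable:
    """Read a long-format trial CSV/TSV and validate it against the study scale.

    ``config.column_map`` maps canonical column names to the file's header
    names; ``config.scale.missing_codes`` are turned into missing responses.
    Row order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trial file not found: {path}")
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    rename = {v: k for k, v in config.column_map.items()}
    df = df.rename(columns=rename)
    for col in _REQUIRED_TRIAL_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"trial file {path} is missing required column {col!r}")

    resp = df["response"].astype(str).str.strip()
    missing = resp.isin(config.scale.missing_codes) | (resp == "")
    numeric = pd.to_numeric(resp.where(~missing), errors="coerce")
    bad = ~missing & numeric.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"non-numeric response {resp.iloc[row]!r} at row {row} "
            f"(not in missing_codes)"
        )
    df["response"] = numeric.astype("Float64")
    if "rt_ms" in df.columns:
        rt = df["rt_ms"].astype(str).str.strip()
        df["rt_ms"] = pd.to_numeric(rt.where(rt != ""), errors="raise")
    return TrialTable(df, config.scale)


def write_trials(table: TrialTable, path: str | Path) -> None:
    """Write a TrialTable back to CSV/TSV in the canonical column order."""
    df = table.frame.copy()
    resp = df["response"]
    if resp.notna().any() and (resp.dropna() == resp.dropna().round()).all():
        df["response"] = resp.astype("Int64")  # keep ordinal scales integral on disk
    df.to_csv(path, sep=_sep_for(path), index=False)


def read_item_vector(path: str | Path, role: str = "gold") -> ItemVector:
    """Read a two-column (item_id, value) CSV/TSV into an ItemVector."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"item file not found: {path}")
    df = pd.read_csv(path, sep=_sep_for(path))
    if df.shape[1] < 2:
        raise SchemaError(f"item file {path} needs columns (item_id, value)")
    if "item_id" in df.columns and "value" in df.columns:
        items, values = df["item_id"], df["value"]
    else:
        items, values = df.iloc[:, 0], df.iloc[:, 1]
    if len(df) == 0:
        raise ValidationError(f"no items in {path}")
    values = pd.to_numeric(values, errors="coerce")
    if values.isna().any():
        raise ValidationError(f"non-numeric value in {path}")
    series = pd.Series(values.to_numpy(), index=items.astype(str))
    return ItemVector(series, role=role)


def write_item_vector(vector: ItemVector, path: str | Path) -> None:
    df = pd.DataFrame({"item_id": vector.items, "value": vector.values.to_numpy()})
    df.to_csv(path, sep=_sep_for(path), index=False)


def item_means(trials: TrialTable, participants: Iterable[str]) -> ItemVector:
    """Per-item arithmetic mean of the selected participants' rating responses.

    All participants must share one list (combinations are within-list by
    design).  Items with no non-missing response among the selection are
    absent from the output.
    """
    chosen = sorted(set(participants))
    if not chosen:
        raise ValidationError("participants must be non-empty")
    sub = trials.ratings()
    sub = sub[sub["participant_id"].isin(chosen)]
    found = set(sub["participant_id"].unique())
    missing = set(chosen) - found
    if missing:
        raise ValidationError(f"unknown participant(s): {sorted(missing)}")
    lists = sub["list_id"].unique()
    if len(lists) > 1:
        raise ValidationError(
            f"participants span multiple lists {sorted(lists)}; sample means are within-list"
        )
    means = sub.dropna(subset=["response"]).groupby("item_id")["response"].mean()
    return ItemVector(means.astype(float), role="sample_mean")
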