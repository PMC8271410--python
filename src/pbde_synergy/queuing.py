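"""Rank-based queuing scores and weighted composite synergy scores.

A cohort of molecules is ranked per endpoint (larger docking score = rank 1),
each rank is mapped linearly onto a 0-100 single score, and the per-endpoint
single scores are combined into one composite score (CS) by a weighted
arithmetic average.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScoreTable",
    "RankResult",
    "CompositeResult",
    "single_score",
    "rank_descending",
    "composite_scores",
]

TIE_POLICIES = ("average", "min", "ordinal")
WEIGHT_MODES = ("own_docking_scores", "fixed_weights")


@dataclass(frozen=True)
class ScoreTable:
    """Per-molecule docking scores for one or more endpoints.

    Parameters
    ----------
    frame:
        DataFrame indexed by unique molecule id with one numeric column per
        endpoint. NaN marks a molecule that failed for that endpoint.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.frame.index
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate molecule_ids: {dupes}")
        if self.frame.shape[1] == 0:
            raise ValueError("ScoreTable needs at least one endpoint column")
        for col in self.frame.columns:
            vals = self.frame[col]
            if not np.issubdtype(vals.dtype, np.number):
                raise TypeError(f"endpoint {col!r} is not numeric")
            if np.isinf(vals.to_numpy()).any():
                raise ValueError(f"endpoint {col!r} contains infinite scores")
            if vals.notna().sum() < 2:
                raise ValueError(f"endpoint {col!r} has fewer than 2 scores")

    @property
    def endpoints(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def molecule_ids(self) -> list:
        return list(self.frame.index)

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class RankResult:
    """Ranks and single scores for one endpoint over a cohort of size n."""

    endpoint: str
    n: int
    ranks: pd.Series
    single_scores: pd.Series


@dataclass(frozen=True)
class CompositeResult:
    """Per-molecule endpoint single scores, weights and composite score."""

    frame: pd.DataFrame  # SS_<ep>, W_<ep> columns plus CS
    endpoints: list[str] = field(default_factory=list)
    weight_mode: str = "own_docking_scores"

    @property
    def cs(self) -> pd.Series:
        return self.frame["CS"]


def single_score(k: float, n: int) -> float:
    """Map rank ``k`` in a cohort of ``n`` onto the 0-100 queuing scale.

    Rank 1 scores 100, rank ``n`` scores 0, linear in between; fractional
    ranks (ties) are allowed.
    """
    if n < 2:
        raise ValueError(f"cohort size n={n} must be at least 2")
    if not 1 <= k <= n:
        raise ValueError(f"rank k={k} outside [1, {n}]")
    return (n - k) / (n - 1) * 100.0


def rank_descending(
    values,
    tie_policy: str = "average",
    ids=None,
) -> np.ndarray:
    """Rank values so the largest gets rank 1.

    ``tie_policy`` is one of 'average' (fractional ranks), 'min', or
    'ordinal' (ties broken by input order).
    """
    if tie_policy not in TIE_POLICIES:
        raise ValueError(f"tie_policy must be one of {TIE_POLICIES}")
    arr = np.asarray(values, dtype=float)
    bad = ~np.isfinite(arr)
    if bad.any():
        labels = (
            [ids[i] for i in np.flatnonzero(bad)]
            if ids is not None
            else np.flatnonzero(bad).tolist()
        )
        raise ValueError(f"non-finite scores for: {labels}")
    method = {"average": "average", "min": "min", "ordinal": "first"}[tie_policy]
    return pd.Series(-arr).rank(method=method).to_numpy()


def rank_endpoint(table: ScoreTable, endpoint: str, tie_policy: str = "average") -> RankResult:
    """Rank one endpoint of a ScoreTable and attach single scores."""
    col = table.frame[endpoint].dropna()
    n = len(col)
    ranks = rank_descending(col.to_numpy(), tie_policy, ids=list(col.index))
    ss = np.array([single_score(k, n) for k in ranks])
    return RankResult(
        endpoint=endpoint,
        n=n,
        ranks=pd.Series(ranks, index=col.index, name=f"rank_{endpoint}"),
        single_scores=pd.Series(ss, index=col.index, name=f"SS_{endpoint}"),
    )


def composite_scores(
    table: ScoreTable,
    weight_mode: str = "own_docking_scores",
    fixed_weights: dict | None = None,
    tie_policy: str = "average",
) -> CompositeResult:
    """Combine per-endpoint single scores into one composite score (CS).

    CS = sum_j SS_j * W_j / sum_j W_j over the endpoints j. Under the default
    ``own_docking_scores`` mode W_j is the molecule's own docking score for
    endpoint j; under ``fixed_weights`` a common positive weight per endpoint
    is used. Molecules missing any endpoint are dropped (with a warning) and
    the cohort size n shrinks accordingly.
    """
    if weight_mode not in WEIGHT_MODES:
        raise ValueError(f"weight_mode must be one of {WEIGHT_MODES}")
    frame = table.frame
    complete = frame.dropna()
    if len(complete) < len(frame):
        dropped = sorted(set(frame.index) - set(complete.index))
        warnings.warn(
            f"excluding {len(dropped)} molecule(s) with missing endpoint "
            f"scores: {dropped}",
            stacklevel=2,
        )
    sub = ScoreTable(complete)
    endpoints = sub.endpoints

    out = pd.DataFrame(index=complete.index)
    for ep in endpoints:
        rr = rank_endpoint(sub, ep, tie_policy)
        out[f"SS_{ep}"] = rr.single_scores
        if weight_mode == "own_docking_scores":
            out[f"W_{ep}"] = complete[ep]
        else:
            if fixed_weights is None or ep not in fixed_weights:
                raise ValueError(f"fixed_weights missing endpoint {ep!r}")
            out[f"W_{ep}"] = float(fixed_weights[ep])

    w_cols = [f"W_{ep}" for ep in endpoints]
    if (out[w_cols].to_numpy() <= 0).any():
        bad = out.index[(out[w_cols] <= 0).any(axis=1)].tolist()
        raise ValueError(f"nonpositive weights for molecules: {bad}")

    ss = out[[f"SS_{ep}" for ep in endpoints]].to_numpy()
    w = out[w_cols].to_numpy()
    out["CS"] = (ss * w).sum(axis=1) / w.sum(axis=1)
    return CompositeResult(frame=out, endpoints=endpoints, weight_mode=weight_mode)
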