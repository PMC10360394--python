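"""Consensus CNV calls: merging, size filtering, cohort frequency and rarity strata.

CNV call tables are plain :class:`pandas.DataFrame` objects. Per-caller input
tables carry columns ``participant_id, chrom, start, end, type, caller``;
consensus tables replace ``caller`` with ``callers`` (a comma-joined, sorted
caller list) and add ``length``. Downstream annotation adds ``frequency`` and
``stratum``. All coordinates are 0-based half-open throughout.

Two calls are considered the same event when their reciprocal overlap — the
minimum of the overlap fraction measured against each interval — reaches a
threshold (default 50%), the field-standard CNV equivalence rule. Consensus
requires support from at least two of the callers; cohort frequency is the
fraction of participants carrying a member of the same single-linkage
reciprocal-overlap cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CNV_TYPES = ("DEL", "DUP")

#: frequency strata bounds: rare < RARE_MAX; LESS_RARE covers [0.01, 0.05];
#: anything above COMMON_MIN is excluded from burden analysis.
RARE_MAX = 0.005
LESS_RARE_MIN = 0.01
LESS_RARE_MAX = 0.05

CALL_COLUMNS = ["participant_id", "chrom", "start", "end", "type", "caller"]
CONSENSUS_COLUMNS = ["participant_id", "chrom", "start", "end", "type", "callers", "length"]


class InputFormatError(ValueError):
    """Raised when a call table violates the documented column/value contract."""


@dataclass(frozen=True)
class ConsensusPolicy:
    """How per-caller calls are merged into consensus events.

    min_callers
        Minimum number of distinct supporting callers for an event to be kept
        (default 2, i.e. "two of three").
    merge_reciprocal_overlap
        Reciprocal-overlap threshold at which two same-type calls of one
        participant are treated as the same event.
    coordinates
        ``"union"`` (maximal extent, default) or ``"intersection"``.
    """

    min_callers: int = 2
    merge_reciprocal_overlap: float = 0.5
    coordinates: str = "union"

    def __post_init__(self) -> None:
        if self.min_callers < 1:
            raise ValueError("min_callers must be >= 1")
        if not 0.0 < self.merge_reciprocal_overlap <= 1.0:
            raise ValueError("merge_reciprocal_overlap must be in (0, 1]")
        if self.coordinates not in ("union", "intersection"):
            raise ValueError("coordinates must be 'union' or 'intersection'")


def reciprocal_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> float:
    """Reciprocal overlap of two half-open intervals on the same chromosome.

    Returns ``min(|a∩b|/|a|, |a∩b|/|b|)``; 0.0 when the intervals are disjoint.
    Callers comparing intervals on different chromosomes should treat the
    result as 0 (this function is coordinate-only).
    """
    if a_end <= a_start or b_end <= b_start:
        raise ValueError("intervals must satisfy end > start")
    inter = min(a_end, b_end) - max(a_start, b_start)
    if inter <= 0:
        return 0.0
    return min(inter / (a_end - a_start), inter / (b_end - b_start))


def _validate_calls(calls: pd.DataFrame, required: list[str]) -> None:
    missing = [c for c in required if c not in calls.columns]
    if missing:
        raise InputFormatError(f"call table missing columns: {missing}")
    if len(calls):
        bad = set(calls["type"].unique()) - set(CNV_TYPES)
        if bad:
            raise InputFormatError(f"unknown CNV type value(s): {sorted(bad)}")
        if (calls["end"] <= calls["start"]).any():
            raise InputFormatError("intervals must satisfy end > start")


def _overlap_clusters(starts: np.ndarray, ends: np.ndarray, ro: float) -> np.ndarray:
    """Single-linkage connected components under RO >= ``ro``.

    Intervals must all lie on one chromosome and share one CNV type. A sweep
    over start-sorted intervals only compares pairs that physically overlap
    (RO > 0 requires a shared base), which keeps the all-pairs cost bounded
    by the local pile-up depth.
    """
    n = len(starts)
    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    order = np.argsort(starts, kind="stable")
    active: list[int] = []  # indices whose interval may still overlap upcoming starts
    for idx in order:
        s, e = starts[idx], ends[idx]
        active = [j for j in active if ends[j] > s]
        for j in active:
            inter = min(e, ends[j]) - max(s, starts[j])
            # reciprocal: the shared stretch must clear the threshold on BOTH lengths
            if inter > 0 and inter >= ro * (e - s) and inter >= ro * (ends[j] - starts[j]):
                ri, rj = find(idx), find(j)
                if ri != rj:
                    parent[ri] = rj
        active.append(idx)
    labels = np.fromiter((find(i) for i in range(n)), dtype=int, count=n)
    # relabel to consecutive ids
    _, labels = np.unique(labels, return_inverse=True)
    return labels


def consensus_merge(calls: pd.DataFrame, policy: ConsensusPolicy | None = None) -> pd.DataFrame:
    """Merge per-caller calls into consensus events.

    Calls of the same participant, chromosome and type whose pairwise
    reciprocal overlap reaches the policy threshold are merged by
    single-linkage into one event (union coordinates, union caller set);
    only events supported by at least ``policy.min_callers`` distinct
    callers are retained.

    Row order of the input does not affect the result.
    """
    policy = policy or ConsensusPolicy()
    _validate_calls(calls, CALL_COLUMNS)
    if calls.empty:
        return pd.DataFrame(columns=CONSENSUS_COLUMNS)

    out_rows = []
    sortcols = ["participant_id", "chrom", "type"]
    for (pid, chrom, ctype), grp in calls.sort_values(
        sortcols + ["start", "end", "caller"], kind="stable"
    ).groupby(sortcols, sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        labels = _overlap_clusters(starts, ends, policy.merge_reciprocal_overlap)
        callers = grp["caller"].to_numpy()
        for lab in np.unique(labels):
            m = labels == lab
            support = sorted(set(callers[m]))
            if len(support) < policy.min_callers:
                continue
            if policy.coordinates == "union":
                s, e = int(starts[m].min()), int(ends[m].max())
            else:
                s, e = int(starts[m].max()), int(ends[m].min())
                if e <= s:  # intersection of single-linkage chain may vanish
                    continue
            out_rows.append((pid, chrom, s, e, ctype, ",".join(support), e - s))
    out = pd.DataFrame(out_rows, columns=CONSENSUS_COLUMNS)
    return out.sort_values(["participant_id", "chrom", "start", "end", "type"], kind="stable").reset_index(
        drop=True
    )


def size_filter(calls: pd.DataFrame, min_length: int = 10_000) -> pd.DataFrame:
    """Drop consensus calls shorter than ``min_length`` bp (boundary inclusive)."""
    if calls.empty:
        return calls.copy()
    length = calls["end"] - calls["start"]
    keep = length >= min_length
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("size_filter removed %d call(s) shorter than %d bp", n_removed, min_length)
    return calls.loc[keep].reset_index(drop=True)


def annotate_frequency(
    calls: pd.DataFrame, n_participants: int, cluster_reciprocal_overlap: float = 0.5
) -> pd.DataFrame:
    """Attach cohort frequency to every consensus call.

    Calls are clustered across participants by single linkage on
    (same chromosome, same type, reciprocal overlap >= threshold); the
    frequency of every member is the number of distinct carriers in its
    cluster divided by the cohort size.
    """
    if n_participants <= 0:
        raise ValueError("cohort size must be positive")
    out = calls.copy()
    out["frequency"] = np.nan
    out["cluster_id"] = -1
    if out.empty:
        return out
    next_cluster = 0
    for (chrom, ctype), grp in out.groupby(["chrom", "type"], sort=True):
        idx = grp.index.to_numpy()
        labels = _overlap_clusters(
            grp["start"].to_numpy(), grp["end"].to_numpy(), cluster_reciprocal_overlap
        )
        for lab in np.unique(labels):
            m = idx[labels == lab]
            carriers = out.loc[m, "participant_id"].nunique()
            out.loc[m, "frequency"] = carriers / n_participants
            out.loc[m, "cluster_id"] = next_cluster
            next_cluster += 1
    return out


def stratify_frequency(calls: pd.DataFrame) -> pd.DataFrame:
    """Assign each call to a rarity stratum from its annotated frequency.

    rare: f < 0.5%; less_rare: 1% <= f <= 5%; common: f > 5% (excluded from
    burden). Frequencies in the unnamed 0.5–1% gap are folded into "rare"
    and reported via a warning so the affected calls are auditable.
    """
    if "frequency" not in calls.columns or calls["frequency"].isna().any():
        raise ValueError("frequencies must be annotated before stratification")
    out = calls.copy()
    f = out["frequency"].to_numpy()
    stratum = np.where(f > LESS_RARE_MAX, "common", np.where(f >= LESS_RARE_MIN, "less_rare", "rare"))
    gap = (f >= RARE_MAX) & (f < LESS_RARE_MIN)
    if gap.any():
        logger.warning(
            "%d call(s) with frequency in [0.5%%, 1%%) assigned to 'rare': rows %s",
            int(gap.sum()),
            list(out.index[gap][:20]),
        )
    out["stratum"] = stratum
    return out
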