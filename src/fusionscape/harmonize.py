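"""Cross-caller consensus: merge per-sample caller records into one
harmonized record per (sample, ordered gene pair).

Matching is at gene-pair level with 5'->3' orientation preserved; read
support is aggregated with max semantics (both callers see the same
library, so summing would double-count the same reads).
"""

from __future__ import annotations

from collections import OrderedDict
from typing import Iterable

from .model import (
    ARRIBA,
    IN_FRAME,
    OUT_OF_FRAME,
    UNKNOWN,
    FusionCall,
    FusionscapeError,
    HarmonizedFusion,
    total_supporting_reads,
)

#: frame reconciliation precedence: a caller that phases the junction wins
FRAME_PRECEDENCE = (IN_FRAME, OUT_OF_FRAME, UNKNOWN)


def match_key(call: FusionCall) -> tuple[str, str]:
    """The (gene5, gene3) merge key; orientation is preserved, so A->B != B->A."""
    return (call.gene5, call.gene3)


def _as_harmonized(call: FusionCall) -> HarmonizedFusion:
    return HarmonizedFusion(
        sample_id=call.sample_id, gene5=call.gene5, gene3=call.gene3,
        bp5=call.bp5, bp3=call.bp3, callers=frozenset({call.caller}),
        total_supporting_reads=total_supporting_reads(call),
        junction_reads=call.junction_reads, spanning_reads=call.spanning_reads,
        frame=call.frame)


def _representative(group: list) -> HarmonizedFusion:
    # highest total support; tie -> arriba; tie -> lexicographic smallest breakpoints
    return min(group, key=lambda f: (-f.total_supporting_reads,
                                     0 if ARRIBA in f.callers else 1,
                                     f.bp5, f.bp3))


def _reconcile_frame(group: list) -> str:
    frames = {f.frame for f in group}
    for label in FRAME_PRECEDENCE:
        if label in frames:
            return label
    return UNKNOWN


def _combine(group: list) -> HarmonizedFusion:
    rep = _representative(group)
    callers = frozenset().union(*(f.callers for f in group))
    return HarmonizedFusion(
        sample_id=rep.sample_id, gene5=rep.gene5, gene3=rep.gene3,
        bp5=rep.bp5, bp3=rep.bp3, callers=callers,
        total_supporting_reads=max(f.total_supporting_reads for f in group),
        junction_reads=max(f.junction_reads for f in group),
        spanning_reads=max(f.spanning_reads for f in group),
        frame=_reconcile_frame(group))


def merge_records(records: Iterable[HarmonizedFusion]) -> list:
    """Merge harmonized records sharing (sample, pair); idempotent."""
    groups: "OrderedDict[tuple, list]" = OrderedDict()
    for rec in records:
        groups.setdefault((rec.sample_id, rec.gene5, rec.gene3), []).append(rec)
    return sorted((_combine(g) for g in groups.values()), key=lambda f: f.sort_key())


def merge_sample(calls: Iterable[FusionCall]) -> list:
    """Merge one sample's caller records into consensus records.

    Returns one :class:`HarmonizedFusion` per distinct ordered gene pair,
    with the supporting-caller set, max-aggregated read support, a
    representative breakpoint pair (from the record with highest total
    support; ties prefer Arriba, then the lexicographically smallest
    breakpoints), and the reconciled frame (in-frame beats out-of-frame
    beats unknown).
    """
    calls = list(calls)
    sample_ids = {c.sample_id for c in calls}
    if len(sample_ids) > 1:
        raise FusionscapeError(f"merge_sample got mixed sample_ids: {sorted(sample_ids)}")
    return merge_records(_as_harmonized(c) for c in calls)


def merge_cohort(per_sample_calls: Iterable[Iterable[FusionCall]]) -> list:
    """Merge each sample's calls and concatenate, in deterministic order.

    ``per_sample_calls`` is one call list per sample; a sample_id appearing
    in two lists is an error (calls for one sample must arrive together).
    """
    seen = set()
    out = []
    for calls in per_sample_calls:
        merged = merge_sample(calls)
        if merged:
            sid = merged[0].sample_id
            if sid in seen:
                raise FusionscapeError(f"duplicate sample_id across call lists: {sid}")
            seen.add(sid)
        out.extend(merged)
    return sorted(out, key=lambda f: f.sort_key())
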