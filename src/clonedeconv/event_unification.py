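"""Collapse per-biopsy detections into unique genetic events.

Copy-number calls for the same underlying lesion rarely share exact
breakpoints across biopsies.  Two detections are therefore treated as
the same event when they lie on the same chromosome, are the same
alteration type, neither is a stem event, and both the start and the
end positions agree within a breakpoint-uncertainty cutoff ``co_ev``
(default 1 Mbp).  Merging is the transitive closure (single linkage) of
that relation within each (chromosome, type) group; stem events — those
present in >= 90% of cells in every biopsy — are never merged.

The module also classifies each unique event's genomic scope
(whole chromosome / chromosome arm / segmental / point), which later
exempts whole-chromosome and arm-level events from parallel-evolution
and back-mutation warnings, and applies the missing-MCF policy:
a missing value on an event the user flags as belonging to the stem is
set to 100%, while subclonal events with missing values are dropped
with a warning so intratumor variation is not overestimated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .genome import GenomeModel
from .segment_io import AlterationRecord, McfMatrix

__all__ = [
    "DEFAULT_CO_EV",
    "DEFAULT_STEM_THRESHOLD",
    "EventCatalog",
    "same_event",
    "unify_events",
    "detect_stem",
    "impute_missing",
    "classify_scope",
]

DEFAULT_CO_EV = 1_000_000  # bp; breakpoint measurement uncertainty
DEFAULT_STEM_THRESHOLD = 90.0  # percent MCF in every biopsy
DEFAULT_ARM_TOLERANCE = 0.05  # fraction of chromosome/arm length

SCOPES = ("whole_chromosome", "chromosome_arm", "segmental", "point")


def _record_is_stem(record: AlterationRecord, threshold: float) -> bool:
    """A raw detection qualifies as stem if its own MCF is >= threshold
    in every biopsy (a missing value disqualifies it)."""
    if not record.mcf:
        return False
    return all(v is not None and v >= threshold for v in record.mcf.values())


@dataclass
class EventCatalog:
    """Partition of raw records into unique events."""

    unique_events: list[AlterationRecord]
    membership: dict[str, str]  # raw event_id -> unique event_id
    is_stem: dict[str, bool] = field(default_factory=dict)
    scope: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def members_of(self, unique_id: str) -> list[str]:
        return [raw for raw, uid in self.membership.items() if uid == unique_id]

    @property
    def event_ids(self) -> list[str]:
        return [e.event_id for e in self.unique_events]

    def stem_ids(self) -> list[str]:
        return [e for e in self.event_ids if self.is_stem.get(e, False)]

    def subclonal_ids(self) -> list[str]:
        return [e for e in self.event_ids if not self.is_stem.get(e, False)]


def same_event(
    a: AlterationRecord,
    b: AlterationRecord,
    co_ev: float = DEFAULT_CO_EV,
    stem_threshold: float = DEFAULT_STEM_THRESHOLD,
) -> bool:
    """True iff two detections from the same patient are one event.

    Requires same chromosome, same alteration type, neither stem, and
    |start_a - start_b| <= co_ev and |end_a - end_b| <= co_ev
    (both inclusive).
    """
    if a.chrom != b.chrom or a.alt_type != b.alt_type:
        return False
    if _record_is_stem(a, stem_threshold) or _record_is_stem(b, stem_threshold):
        return False
    return (
        abs(a.start_bp - b.start_bp) <= co_ev and abs(a.end_bp - b.end_bp) <= co_ev
    )


def unify_events(
    records: Sequence[AlterationRecord],
    co_ev: float = DEFAULT_CO_EV,
    stem_threshold: float = DEFAULT_STEM_THRESHOLD,
    linkage: str = "single",
) -> EventCatalog:
    """Partition detections into unique events.

    ``linkage="single"`` (default) takes the transitive closure of
    :func:`same_event` within each (chromosome, type) group, so chains
    of near-identical breakpoints across many biopsies become one
    event.  ``linkage="greedy"`` assigns each record to the first
    already-formed event it matches (first-match semantics).  The
    representative record of each unique event is its first-seen
    member; per-biopsy MCF of the unique event is the member value,
    with the maximum taken (and a warning emitted) if several members
    carry a value for the same biopsy.
    """
    if linkage not in {"single", "greedy"}:
        raise ValueError(f"unknown linkage {linkage!r}")
    warnings: list[str] = []
    groups: list[list[int]] = []  # lists of record indices, one per unique event

    stem_flags = [_record_is_stem(r, stem_threshold) for r in records]
    # stem detections are always their own events
    by_key: dict[tuple, list[int]] = {}
    for i, r in enumerate(records):
        if stem_flags[i]:
            groups.append([i])
        else:
            by_key.setdefault((r.chrom, r.alt_type), []).append(i)

    for key_indices in by_key.values():
        if linkage == "single":
            # union-find over pairwise same_event within the group
            parent = {i: i for i in key_indices}

            def find(x: int) -> int:
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for ai in range(len(key_indices)):
                for bi in range(ai + 1, len(key_indices)):
                    i, j = key_indices[ai], key_indices[bi]
                    if same_event(records[i], records[j], co_ev, stem_threshold):
                        parent[find(j)] = find(i)
            comp: dict[int, list[int]] = {}
            for i in key_indices:
                comp.setdefault(find(i), []).append(i)
            groups.extend(sorted(members) for members in comp.values())
        else:
            formed: list[list[int]] = []
            for i in key_indices:
                for members in formed:
                    rep = records[members[0]]
                    if same_event(records[i], rep, co_ev, stem_threshold):
                        members.append(i)
                        break
                else:
                    formed.append([i])
            groups.extend(formed)

    # deterministic event order: by first-seen member index
    groups.sort(key=lambda members: members[0])

    unique: list[AlterationRecord] = []
    membership: dict[str, str] = {}
    for members in groups:
        rep = records[members[0]]
        mcf: dict[str, float | None] = dict(rep.mcf)
        for i in members[1:]:
            for biopsy, value in records[i].mcf.items():
                if value is None:
                    continue
                existing = mcf.get(biopsy)
                if existing is None:
                    mcf[biopsy] = value
                elif value != existing:
                    warnings.append(
                        f"event {rep.event_id}: members disagree in biopsy {biopsy} "
                        f"({existing} vs {value}); taking the maximum"
                    )
                    mcf[biopsy] = max(existing, value)
        merged = AlterationRecord(
            event_id=rep.event_id,
            chrom=rep.chrom,
            start_bp=rep.start_bp,
            end_bp=rep.end_bp,
            alt_type=rep.alt_type,
            label=rep.label,
            source=rep.source,
            mcf=mcf,
        )
        unique.append(merged)
        for i in members:
            membership[records[i].event_id] = rep.event_id

    catalog = EventCatalog(unique_events=unique, membership=membership, warnings=warnings)
    return catalog


def build_mcf_matrix(
    catalog: EventCatalog, biopsies: Sequence[str]
) -> McfMatrix:
    """Assemble the unique-event MCF matrix.

    A biopsy with no member detection contributes 0; an explicitly
    missing cell (None) stays missing (NaN) so it is never silently
    coerced to a number.
    """
    values = np.zeros((len(catalog.unique_events), len(biopsies)))
    for i, ev in enumerate(catalog.unique_events):
        for j, b in enumerate(biopsies):
            v = ev.mcf.get(b, 0.0)
            values[i, j] = np.nan if v is None else v
    return McfMatrix(catalog.event_ids, list(biopsies), values)


def detect_stem(T: McfMatrix, threshold: float = DEFAULT_STEM_THRESHOLD) -> dict[str, bool]:
    """Stem flag per event: MCF >= threshold in every biopsy (inclusive)."""
    flags: dict[str, bool] = {}
    for i, event in enumerate(T.events):
        row = T.values[i]
        flags[event] = bool(np.all(np.isfinite(row)) and np.all(row >= threshold))
    return flags


def impute_missing(
    catalog: EventCatalog,
    biopsies: Sequence[str],
    user_stem: Iterable[str] = (),
    threshold: float = DEFAULT_STEM_THRESHOLD,
) -> tuple[EventCatalog, list[str]]:
    """Apply the missing-MCF policy on the unified catalog.

    Events in ``user_stem`` (stem by prior biological knowledge, e.g.
    amplicons whose cellular fraction cannot be measured) get missing
    values replaced by 100%.  Any other event with a missing MCF is
    removed, with a warning naming it.  Finally ``is_stem`` is filled
    from the (now complete) MCF rows.
    """
    user_stem = set(user_stem)
    warnings: list[str] = []
    kept: list[AlterationRecord] = []
    for ev in catalog.unique_events:
        # a biopsy with no detection is 0, not missing
        mcf = {b: ev.mcf.get(b, 0.0) for b in biopsies}
        if any(v is None for v in mcf.values()):
            if ev.event_id in user_stem:
                mcf = {b: 100.0 if v is None else v for b, v in mcf.items()}
            else:
                warnings.append(
                    f"event {ev.event_id}: missing MCF on a subclonal event; removed"
                )
                continue
        kept.append(
            AlterationRecord(
                event_id=ev.event_id, chrom=ev.chrom, start_bp=ev.start_bp,
                end_bp=ev.end_bp, alt_type=ev.alt_type, label=ev.label,
                source=ev.source, mcf=mcf,
            )
        )
    kept_ids = {e.event_id for e in kept}
    membership = {raw: uid for raw, uid in catalog.membership.items() if uid in kept_ids}
    new = EventCatalog(
        unique_events=kept,
        membership=membership,
        warnings=list(catalog.warnings) + warnings,
    )
    matrix = build_mcf_matrix(new, biopsies)
    new.is_stem = detect_stem(matrix, threshold)
    for ev_id in user_stem & kept_ids:
        new.is_stem[ev_id] = True
    return new, warnings


def classify_scope(
    event: AlterationRecord,
    genome: GenomeModel,
    tol: float = DEFAULT_ARM_TOLERANCE,
) -> str:
    """Genomic scope of an event.

    ``whole_chromosome`` if it spans >= (1 - tol) of the chromosome,
    ``chromosome_arm`` if >= (1 - tol) of either arm, ``point`` for
    SNVs, else ``segmental``.
    """
    if event.alt_type == "snv":
        return "point"
    chrom = genome[event.chrom]
    span = event.end_bp - event.start_bp + 1
    if span >= (1 - tol) * chrom.length:
        return "whole_chromosome"
    for lo, hi in (chrom.p_arm, chrom.q_arm):
        arm_len = hi - lo + 1
        overlap = max(0, min(event.end_bp, hi) - max(event.start_bp, lo) + 1)
        if overlap >= (1 - tol) * arm_len:
            return "chromosome_arm"
    return "segmental"


def annotate_scopes(
    catalog: EventCatalog, genome: GenomeModel, tol: float = DEFAULT_ARM_TOLERANCE
) -> None:
    """Fill ``catalog.scope`` for every unique event in place."""
    for ev in catalog.unique_events:
        try:
            catalog.scope[ev.event_id] = classify_scope(ev, genome, tol)
        except KeyError:
            catalog.scope[ev.event_id] = "segmental"
            catalog.warnings.append(
                f"event {ev.event_id}: chromosome {ev.chrom!r} not in genome model; "
                "scope defaulted to segmental"
            )
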