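"""Excision-event taxonomy, de novo accounting and shift spectra.

A deletion interval ``[a, b)`` on the germline is compared with its best
matching annotated IES ``[s, e)``.  Each boundary is *canonical* when it
coincides with the annotated one, *internal* when it falls inside the IES
and *external* when it falls in the flank; the combination defines the
event class.  Each distinct junction is counted once regardless of read
support, and de novo errors are the autogamous junctions not already seen
in the parental sample, normalized per million mapped reads.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from iespipe.annotation import IesRecord, by_scaffold

CORRECT = "CORRECT"
PARTIAL_INTERNAL = "PARTIAL_INTERNAL"
PARTIAL_EXTERNAL = "PARTIAL_EXTERNAL"
INTERNAL = "INTERNAL"
EXTERNAL = "EXTERNAL"
OVERLAPPING = "OVERLAPPING"
UNMATCHED = "UNMATCHED"

#: classes that count as excision errors (everything except CORRECT / UNMATCHED
#: is an error at an annotated IES; UNMATCHED deletions are errors in
#: MAC-destined sequence and are reported separately).
ERROR_CLASSES = (PARTIAL_INTERNAL, PARTIAL_EXTERNAL, INTERNAL, EXTERNAL, OVERLAPPING)

#: optional merge onto the displayed 4-class scheme (partial external events
#: folded into the external class).
DISPLAY_CLASS_MAP = {PARTIAL_EXTERNAL: EXTERNAL}

EventKey = Tuple[str, int, int]


@dataclass
class ExcisionEvent:
    """A distinct TA-bounded deletion junction with aggregated read support."""

    scaffold: str
    start: int
    end: int
    read_count: int
    ies_id: Optional[str]
    klass: str
    left_offset: Optional[int]
    right_offset: Optional[int]
    multi_ies: bool = False

    @property
    def key(self) -> EventKey:
        return (self.scaffold, self.start, self.end)

    @property
    def is_error(self) -> bool:
        return self.klass in ERROR_CLASSES or self.klass == UNMATCHED


@dataclass
class ErrorSummary:
    total_error_junctions: int
    de_novo_junctions: int
    de_novo_per_million: Optional[float]
    class_distribution: Dict[str, float] = field(default_factory=dict)
    error_read_fraction: float = 0.0


def classify_boundaries(a: int, b: int, s: int, e: int) -> Tuple[str, int, int]:
    """Class and signed offsets of event ``[a,b)`` against canonical ``[s,e)``.

    Offsets are TA-start to TA-start: ``left = a - s`` (positive = internal),
    ``right = b - e`` (negative = internal).
    """
    left = "canonical" if a == s else ("internal" if a > s else "external")
    right = "canonical" if b == e else ("internal" if b < e else "external")
    pair = frozenset((left, right))
    if pair == {"canonical"}:
        klass = CORRECT
    elif pair == {"canonical", "internal"}:
        klass = PARTIAL_INTERNAL
    elif pair == {"canonical", "external"}:
        klass = PARTIAL_EXTERNAL
    elif pair == {"internal"}:
        klass = INTERNAL
    elif pair == {"external"}:
        klass = EXTERNAL
    else:
        klass = OVERLAPPING
    return klass, a - s, b - e


def classify_event(
    interval: EventKey, annotation: Sequence[IesRecord]
) -> Tuple[Optional[str], str, Tuple[Optional[int], Optional[int]], bool]:
    """Assign an event to the annotated IES with maximal bp overlap.

    Returns ``(ies_id, klass, (left_offset, right_offset), multi_ies)``;
    ``(None, UNMATCHED, (None, None), False)`` when no IES overlaps. Ties in
    overlap go to the leftmost IES and the event is flagged ``multi_ies``.
    """
    scaffold, a, b = interval
    if b <= a:
        raise ValueError(f"empty interval {interval!r}")
    best: Optional[IesRecord] = None
    best_ov = 0
    n_positive = 0
    for rec in by_scaffold(annotation).get(scaffold, []):
        ov = min(b, rec.end) - max(a, rec.start)
        if ov > 0:
            n_positive += 1
            if ov > best_ov:
                best, best_ov = rec, ov
    if best is None:
        return None, UNMATCHED, (None, None), False
    klass, lo, ro = classify_boundaries(a, b, best.start, best.end)
    return best.ies_id, klass, (lo, ro), n_positive > 1


def collapse_events(evidences: Iterable, annotation: Sequence[IesRecord]) -> List[ExcisionEvent]:
    """Collapse deletion evidences to one event per distinct junction.

    Accepts :class:`~iespipe.mapper.JunctionEvidence` objects of kind
    ``IES_MINUS`` or ``ALT_DELETION``; read support is aggregated, and the
    event is classified against the annotation.
    """
    counts: Counter = Counter()
    for ev in evidences:
        if getattr(ev, "kind", None) not in ("IES_MINUS", "ALT_DELETION"):
            continue
        if ev.scaffold is None or ev.start is None or ev.end is None:
            raise ValueError(f"deletion evidence without interval: {ev!r}")
        counts[(ev.scaffold, int(ev.start), int(ev.end))] += 1
    events = []
    for key in sorted(counts):
        ies_id, klass, (lo, ro), multi = classify_event(key, annotation)
        events.append(
            ExcisionEvent(
                scaffold=key[0],
                start=key[1],
                end=key[2],
                read_count=counts[key],
                ies_id=ies_id,
                klass=klass,
                left_offset=lo,
                right_offset=ro,
                multi_ies=multi,
            )
        )
    return events


def _error_keys(events: Iterable[ExcisionEvent]) -> Set[EventKey]:
    return {ev.key for ev in events if ev.is_error}


def de_novo_errors(
    auto_events: Iterable[ExcisionEvent],
    parental_events: Iterable[ExcisionEvent],
    total_mapped_reads: int,
) -> Tuple[Set[EventKey], float]:
    """Autogamous error junctions absent from the parental sample.

    Each junction counts once; the rate is per million mapped reads of the
    autogamous sample.
    """
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be positive")
    de_novo = _error_keys(auto_events) - _error_keys(parental_events)
    rate = len(de_novo) / total_mapped_reads * 1e6
    return de_novo, rate


def error_read_fraction(events: Iterable[ExcisionEvent]) -> float:
    """Fraction of excision reads supporting an erroneous junction."""
    err = tot = 0
    for ev in events:
        tot += ev.read_count
        if ev.is_error:
            err += ev.read_count
    return err / tot if tot else 0.0


def class_distribution(
    events: Iterable[ExcisionEvent], display: bool = False
) -> Dict[str, float]:
    """Proportion of error junctions per class (junction-level, not reads)."""
    counter: Counter = Counter()
    for ev in events:
        if ev.klass in ERROR_CLASSES:
            klass = DISPLAY_CLASS_MAP.get(ev.klass, ev.klass) if display else ev.klass
            counter[klass] += 1
    total = sum(counter.values())
    return {k: v / total for k, v in sorted(counter.items())} if total else {}


def shift_spectrum(
    events: Iterable[ExcisionEvent], min_shift: int = 3
) -> Tuple[Dict[int, int], Optional[int]]:
    """Histogram of internal-boundary shift distances for partial internal events.

    Shifts smaller than ``min_shift`` (i.e. at <= ``min_shift - 1`` bp from the
    canonical TA) are excluded.  Returns ``(counts, modal_shift)``.
    """
    counts: Counter = Counter()
    for ev in events:
        if ev.klass != PARTIAL_INTERNAL:
            continue
        shift = abs(ev.left_offset) if ev.left_offset else abs(ev.right_offset or 0)
        if shift >= min_shift:
            counts[shift] += 1
    if not counts:
        return {}, None
    mode = max(sorted(counts), key=lambda s: counts[s])
    return dict(sorted(counts.items())), mode


DEFAULT_STRATA: Tuple[Tuple[str, float, float], ...] = (
    ("fully_excised", 0.0, 0.025),
    ("partially_retained", 0.025, 0.5),
    ("strongly_retained", 0.5, 1.0 + 1e-12),
)


def error_prone_fraction(
    results: Iterable,
    events: Iterable[ExcisionEvent],
    strata: Sequence[Tuple[str, float, float]] = DEFAULT_STRATA,
) -> Dict[str, Dict[str, float]]:
    """Per-IRS-stratum fraction of IESs with at least one excision error."""
    with_error = {
        ev.ies_id for ev in events if ev.klass in ERROR_CLASSES and ev.ies_id
    }
    out: Dict[str, Dict[str, float]] = {
        label: {"n_ies": 0, "n_with_error": 0, "fraction": 0.0}
        for label, _, _ in strata
    }
    for res in results:
        irs = getattr(res, "irs", None)
        if irs is None:
            continue
        for label, lo, hi in strata:
            if lo <= irs < hi:
                out[label]["n_ies"] += 1
                if getattr(res, "ies_id") in with_error:
                    out[label]["n_with_error"] += 1
                break
    for label in out:
        n = out[label]["n_ies"]
        out[label]["fraction"] = out[label]["n_with_error"] / n if n else 0.0
    return out


def summarize(
    auto_events: Sequence[ExcisionEvent],
    parental_events: Sequence[ExcisionEvent] = (),
    total_mapped_reads: Optional[int] = None,
) -> ErrorSummary:
    """Bundle junction counts, de novo rate, class mix and read fraction."""
    auto_err = _error_keys(auto_events)
    de_novo = auto_err - _error_keys(parental_events)
    rate = (
        len(de_novo) / total_mapped_reads * 1e6
        if total_mapped_reads
        else None
    )
    return ErrorSummary(
        total_error_junctions=len(auto_err),
        de_novo_junctions=len(de_novo),
        de_novo_per_million=rate,
        class_distribution=class_distribution(auto_events),
        error_read_fraction=error_read_fraction(auto_events),
    )
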