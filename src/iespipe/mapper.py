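"""Deterministic seed-and-extend classification of reads against the
germline reference.

Each read either contains an IES boundary probe (retention evidence), the
somatic junction probe (excision evidence), a split TA-bounded deletion
(alternative excision evidence), or is uninformative.  Because an excised
segment is flanked by a TA direct repeat, a deletion interval is ambiguous
within its micro-homology range; intervals are normalized so that both
``[a, a+2)`` and ``[b, b+2)`` read "TA", preferring the representation that
matches an annotated IES, then the leftmost.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Set, Tuple

from iespipe.annotation import IesRecord, by_scaffold, validate_annotation

IES_PLUS_LEFT = "IES_PLUS_LEFT"
IES_PLUS_RIGHT = "IES_PLUS_RIGHT"
IES_MINUS = "IES_MINUS"
ALT_DELETION = "ALT_DELETION"
NONE = "NONE"

KINDS = (IES_PLUS_LEFT, IES_PLUS_RIGHT, IES_MINUS, ALT_DELETION, NONE)


@dataclass(frozen=True)
class JunctionEvidence:
    """What one read supports; deletion kinds carry a germline interval."""

    read_id: str
    kind: str
    ies_id: Optional[str] = None
    scaffold: Optional[str] = None
    start: Optional[int] = None
    end: Optional[int] = None


class ReferenceIndex:
    """K-mer index of the germline plus per-IES boundary/junction probes.

    Probes are ``2 * min_anchor`` long: the two boundary probes straddle each
    germline IES boundary and the junction probe is the somatic sequence
    around the excision site (left flank + retained TA side).
    """

    def __init__(
        self,
        germline: Mapping[str, str],
        somatic: Optional[Mapping[str, str]],
        annotation: Sequence[IesRecord],
        k: int = 12,
        min_anchor: int = 12,
    ):
        if min_anchor < 8:
            raise ValueError("min_anchor must be >= 8")
        if k > min_anchor:
            raise ValueError("k must not exceed min_anchor")
        names = list(germline)
        if len(set(names)) != len(names):
            raise ValueError("duplicate scaffold names")
        validate_annotation(annotation, germline)
        self.germline = dict(germline)
        self.somatic = dict(somatic) if somatic is not None else None
        self.annotation = sorted(annotation)
        self.k = k
        self.min_anchor = min_anchor
        self.by_scaffold = by_scaffold(self.annotation)
        self.interval_to_ies: Dict[Tuple[str, int, int], str] = {
            rec.interval: rec.ies_id for rec in self.annotation
        }
        self.ies_by_id: Dict[str, IesRecord] = {r.ies_id: r for r in self.annotation}
        self.annotated_by_scaffold: Dict[str, Set[Tuple[int, int]]] = {
            sc: {(r.start, r.end) for r in recs} for sc, recs in self.by_scaffold.items()
        }

        a = min_anchor
        self.probes: Dict[str, List[Tuple[str, str]]] = {}
        for rec in self.annotation:
            g = self.germline[rec.scaffold]
            s, e = rec.start, rec.end
            if s >= a and s + a <= len(g):
                self._add_probe(g[s - a : s + a], rec.ies_id, IES_PLUS_LEFT)
            if e >= a and e + a <= len(g):
                self._add_probe(g[e - a : e + a], rec.ies_id, IES_PLUS_RIGHT)
            if s >= a and e + a <= len(g):
                self._add_probe(g[s - a : s] + g[e : e + a], rec.ies_id, IES_MINUS)

        self.kmers: Dict[str, List[Tuple[str, int]]] = {}
        for name, seq in self.germline.items():
            for pos in range(len(seq) - k + 1):
                self.kmers.setdefault(seq[pos : pos + k], []).append((name, pos))

    def _add_probe(self, probe: str, ies_id: str, kind: str) -> None:
        self.probes.setdefault(probe, []).append((ies_id, kind))

    def lookup_kmer(self, kmer: str) -> List[Tuple[str, int]]:
        return self.kmers.get(kmer, [])


def build_index(
    germline: Mapping[str, str],
    somatic: Optional[Mapping[str, str]],
    annotation: Sequence[IesRecord],
    k: int = 12,
    min_anchor: int = 12,
) -> ReferenceIndex:
    return ReferenceIndex(germline, somatic, annotation, k=k, min_anchor=min_anchor)


def normalize_deletion(
    germ: str,
    a: int,
    b: int,
    annotated: Optional[Set[Tuple[int, int]]] = None,
) -> Optional[Tuple[int, int]]:
    """Canonical TA-led representative of a deletion's micro-homology class.

    Candidates are the equivalent intervals ``[a+d, b+d)`` (identical spliced
    product) where both boundary dinucleotides read "TA"; an annotated
    interval wins, otherwise the leftmost candidate.  Returns None when no
    equivalent interval is TA-bounded.  Idempotent.
    """
    if not 0 <= a < b <= len(germ):
        raise ValueError(f"bad interval [{a}, {b})")
    left = 0
    while a - left - 1 >= 0 and germ[a - left - 1] == germ[b - left - 1]:
        left += 1
    right = 0
    while b + right + 1 <= len(germ) and a + right + 1 < b and germ[a + right] == germ[b + right]:
        right += 1
    candidates = [
        (a + d, b + d)
        for d in range(-left, right + 1)
        if germ[a + d : a + d + 2] == "TA" and germ[b + d : b + d + 2] == "TA"
    ]
    if not candidates:
        return None
    if annotated:
        for cand in candidates:
            if cand in annotated:
                return cand
    return candidates[0]


def _extend_forward(g: str, pos: int, read: str) -> int:
    n = 0
    limit = min(len(read), len(g) - pos)
    while n < limit and g[pos + n] == read[n]:
        n += 1
    return n


def _extend_backward(g: str, end: int, read: str) -> int:
    """Longest t with ``read[-t:] == g[end-t:end]``."""
    n = 0
    limit = min(len(read), end)
    while n < limit and g[end - n - 1] == read[len(read) - n - 1]:
        n += 1
    return n


def detect_deletion(
    read: str, index: ReferenceIndex, min_anchor: Optional[int] = None
) -> Optional[Tuple[str, int, int]]:
    """Unique TA-bounded deletion explaining the read as two germline blocks.

    The read must equal ``germ[p:a) + germ[b:q)`` with both anchors at least
    ``min_anchor``; returns the normalized ``(scaffold, a, b)`` or None when
    the read matches the germline contiguously, no TA-bounded deletion
    explains it, or several distinct deletions do (ambiguous placement).
    """
    a_min = index.min_anchor if min_anchor is None else min_anchor
    k = index.k
    L = len(read)
    if L < 2 * a_min:
        return None
    left_seeds = index.lookup_kmer(read[:k])
    right_seeds = index.lookup_kmer(read[L - k :])
    if not left_seeds or not right_seeds:
        return None

    prefix: List[Tuple[str, int, int]] = []
    for sc, p1 in left_seeds:
        m1 = _extend_forward(index.germline[sc], p1, read)
        if m1 == L:
            return None  # contiguous germline match
        prefix.append((sc, p1, m1))

    suffix: List[Tuple[str, int, int]] = []
    for sc, p2 in right_seeds:
        g = index.germline[sc]
        m2 = _extend_backward(g, p2 + k, read)
        suffix.append((sc, p2 + k - L, m2))  # germline coord aligned to read[0]

    found: Set[Tuple[str, int, int]] = set()
    for sc1, p1, m1 in prefix:
        g = index.germline[sc1]
        for sc2, g2s, m2 in suffix:
            if sc1 != sc2 or g2s <= p1:
                continue
            lo = max(a_min, L - m2)
            hi = min(L - a_min, m1)
            for i in range(lo, hi + 1):
                a, b = p1 + i, g2s + i
                if b <= a or b + 2 > len(g):
                    continue
                if g[a : a + 2] == "TA" and g[b : b + 2] == "TA":
                    norm = normalize_deletion(g, a, b, index.annotated_by_scaffold.get(sc1))
                    if norm is not None:
                        found.add((sc1, norm[0], norm[1]))
    if len(found) == 1:
        return next(iter(found))
    return None


def classify_read(
    read_id: str, seq: str, index: ReferenceIndex
) -> List[JunctionEvidence]:
    """All junction evidence carried by one read.

    A read touching several IES boundaries yields one evidence per boundary;
    a read with no informative content yields a single NONE evidence.
    """
    w = 2 * index.min_anchor
    hits: Set[Tuple[str, str]] = set()
    for i in range(len(seq) - w + 1):
        for ies_id, kind in index.probes.get(seq[i : i + w], ()):
            hits.add((ies_id, kind))

    evidences: List[JunctionEvidence] = []
    minus_seen: Set[str] = set()
    for ies_id, kind in sorted(hits):
        rec = index.ies_by_id[ies_id]
        if kind == IES_MINUS:
            minus_seen.add(ies_id)
            evidences.append(
                JunctionEvidence(read_id, IES_MINUS, ies_id, rec.scaffold, rec.start, rec.end)
            )
        else:
            evidences.append(JunctionEvidence(read_id, kind, ies_id, rec.scaffold))

    det = detect_deletion(seq, index)
    if det is not None:
        sc, a, b = det
        ies_id = index.interval_to_ies.get((sc, a, b))
        if ies_id is not None:
            if ies_id not in minus_seen:
                evidences.append(JunctionEvidence(read_id, IES_MINUS, ies_id, sc, a, b))
        else:
            evidences.append(JunctionEvidence(read_id, ALT_DELETION, None, sc, a, b))

    if not evidences:
        return [JunctionEvidence(read_id, NONE)]
    return evidences


def classify_reads(
    reads: Iterable[Tuple[str, str]], index: ReferenceIndex, keep_none: bool = False
) -> Iterator[JunctionEvidence]:
    """Classify a read stream; NONE evidences are dropped unless requested."""
    for read_id, seq in reads:
        for ev in classify_read(read_id, seq, index):
            if ev.kind != NONE or keep_none:
                yield ev


def evidences_from_sam(path: str, index: ReferenceIndex) -> List[JunctionEvidence]:
    """Ingest pre-aligned reads (SAM against the germline) as evidence.

    Minimal interface: deletion CIGAR operations flanked by >= min_anchor
    aligned bases become IES_MINUS / ALT_DELETION evidence after TA
    normalization; reads without usable deletions are skipped.
    """
    import pysam

    out: List[JunctionEvidence] = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.cigartuples is None:
                continue
            g = index.germline.get(aln.reference_name)
            if g is None:
                continue
            ref_pos = aln.reference_start
            cig = aln.cigartuples
            for ci, (op, length) in enumerate(cig):
                if op == 2:  # D
                    flank_left = sum(l for o, l in cig[:ci] if o == 0)
                    flank_right = sum(l for o, l in cig[ci + 1 :] if o == 0)
                    if min(flank_left, flank_right) >= index.min_anchor:
                        a, b = ref_pos, ref_pos + length
                        if g[a : a + 2] == "TA" and g[b : b + 2] == "TA":
                            annotated = {
                                (r.start, r.end)
                                for r in index.by_scaffold.get(aln.reference_name, [])
                            }
                            norm = normalize_deletion(g, a, b, annotated)
                            if norm is not None:
                                sc = aln.reference_name
                                ies_id = index.interval_to_ies.get((sc, *norm))
                                kind = IES_MINUS if ies_id else ALT_DELETION
                                out.append(
                                    JunctionEvidence(
                                        aln.query_name, kind, ies_id, sc, norm[0], norm[1]
                                    )
                                )
                if op in (0, 2, 3, 7, 8):  # consumes reference
                    ref_pos += length
    return out
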