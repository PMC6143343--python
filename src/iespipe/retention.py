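"""Per-boundary retention scores, IRS and significance calls.

The boundary score is the retained read fraction ``plus / (plus + minus)``;
the IES retention score (IRS) is the mean of the defined boundary scores.
A junction (IES-) read attests excision at both ends and therefore
increments the minus count of both boundaries.  Retention is called against
a control sample with a one-sided Fisher exact test per boundary and
Benjamini-Hochberg correction across all boundaries.

Note: absolute IRS values are relative measurements whenever contaminating
old-MAC reads are present; comparisons against a matched control remain
valid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from iespipe.annotation import IesRecord
from iespipe.mapper import IES_MINUS, IES_PLUS_LEFT, IES_PLUS_RIGHT

LEFT = "left"
RIGHT = "right"

#: IRS below this is reported as fully excised.
FULLY_EXCISED_THRESHOLD = 0.025


@dataclass
class BoundaryCounts:
    ies_id: str
    side: str
    plus_count: int = 0
    minus_count: int = 0


@dataclass
class RetentionResult:
    ies_id: str
    left_score: Optional[float]
    right_score: Optional[float]
    irs: Optional[float]
    p_left: Optional[float] = None
    p_right: Optional[float] = None
    q_left: Optional[float] = None
    q_right: Optional[float] = None
    significantly_retained: bool = False
    fully_excised: bool = False


CountKey = Tuple[str, str]


def tally_boundaries(
    evidences: Iterable, annotation: Sequence[IesRecord]
) -> Dict[CountKey, BoundaryCounts]:
    """Aggregate junction evidence into per-boundary plus/minus counts."""
    known = {rec.ies_id for rec in annotation}
    counts: Dict[CountKey, BoundaryCounts] = {}
    for rec in annotation:
        counts[(rec.ies_id, LEFT)] = BoundaryCounts(rec.ies_id, LEFT)
        counts[(rec.ies_id, RIGHT)] = BoundaryCounts(rec.ies_id, RIGHT)
    for ev in evidences:
        if ev.kind not in (IES_PLUS_LEFT, IES_PLUS_RIGHT, IES_MINUS):
            continue
        if ev.ies_id not in known:
            raise ValueError(f"evidence references unknown IES {ev.ies_id!r}")
        if ev.kind == IES_PLUS_LEFT:
            counts[(ev.ies_id, LEFT)].plus_count += 1
        elif ev.kind == IES_PLUS_RIGHT:
            counts[(ev.ies_id, RIGHT)].plus_count += 1
        else:  # a junction read is excision evidence at both boundaries
            counts[(ev.ies_id, LEFT)].minus_count += 1
            counts[(ev.ies_id, RIGHT)].minus_count += 1
    return counts


def boundary_score(plus: int, minus: int) -> Optional[float]:
    """Retained fraction at one boundary; None when uncovered."""
    if plus < 0 or minus < 0:
        raise ValueError("negative counts")
    total = plus + minus
    if total == 0:
        return None
    return plus / total


def retention_score(
    left_score: Optional[float], right_score: Optional[float]
) -> Optional[float]:
    """IRS: mean of the defined boundary scores."""
    defined = [s for s in (left_score, right_score) if s is not None]
    if not defined:
        return None
    return float(np.mean(defined))


def compute_results(
    counts: Mapping[CountKey, BoundaryCounts],
    threshold: float = FULLY_EXCISED_THRESHOLD,
) -> List[RetentionResult]:
    """Scores and IRS only (no significance) for every tallied IES."""
    ids = sorted({ies_id for ies_id, _ in counts})
    results = []
    for ies_id in ids:
        lc = counts.get((ies_id, LEFT), BoundaryCounts(ies_id, LEFT))
        rc = counts.get((ies_id, RIGHT), BoundaryCounts(ies_id, RIGHT))
        ls = boundary_score(lc.plus_count, lc.minus_count)
        rs = boundary_score(rc.plus_count, rc.minus_count)
        irs = retention_score(ls, rs)
        results.append(
            RetentionResult(
                ies_id=ies_id,
                left_score=ls,
                right_score=rs,
                irs=irs,
                fully_excised=irs is not None and irs < threshold,
            )
        )
    return results


def _fisher_one_sided(sample: BoundaryCounts, control: BoundaryCounts) -> float:
    """One-sided exact p for elevated retention in the sample boundary."""
    table = [
        [sample.plus_count, sample.minus_count],
        [control.plus_count, control.minus_count],
    ]
    return float(stats.fisher_exact(table, alternative="greater")[1])


def call_significance(
    sample: Mapping[CountKey, BoundaryCounts],
    control: Mapping[CountKey, BoundaryCounts],
    alpha: float = 0.05,
    policy: str = "any",
    threshold: float = FULLY_EXCISED_THRESHOLD,
) -> List[RetentionResult]:
    """Retention calls for every IES in the sample against a control.

    ``policy="any"`` (default) calls an IES significantly retained when at
    least one boundary passes BH-corrected significance; ``"both"`` requires
    both boundaries.  IESs not significantly retained form the excised set.
    """
    if policy not in ("any", "both"):
        raise ValueError(f"unknown policy {policy!r}")
    results = compute_results(sample, threshold=threshold)
    keys: List[Tuple[str, str]] = []
    pvals: List[float] = []
    for res in results:
        for side in (LEFT, RIGHT):
            sc = sample.get((res.ies_id, side), BoundaryCounts(res.ies_id, side))
            cc = control.get((res.ies_id, side), BoundaryCounts(res.ies_id, side))
            keys.append((res.ies_id, side))
            pvals.append(_fisher_one_sided(sc, cc))
    if pvals:
        qvals = stats.false_discovery_control(np.asarray(pvals), method="bh")
    else:
        qvals = np.array([])
    by_key = {key: (p, float(q)) for key, p, q in zip(keys, pvals, qvals)}
    for res in results:
        res.p_left, res.q_left = by_key[(res.ies_id, LEFT)]
        res.p_right, res.q_right = by_key[(res.ies_id, RIGHT)]
        hits = [q <= alpha for q in (res.q_left, res.q_right)]
        res.significantly_retained = any(hits) if policy == "any" else all(hits)
    return results


def excised_set(results: Iterable[RetentionResult]) -> set:
    """IESs that did not pass the retention test (the 'non-retained' set)."""
    return {r.ies_id for r in results if not r.significantly_retained}


def retained_set(results: Iterable[RetentionResult]) -> set:
    return {r.ies_id for r in results if r.significantly_retained}
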