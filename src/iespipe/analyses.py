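"""Summary analyses: IRS histograms, set overlaps, size-bias statistics,
end-motif PWMs and internal-TA availability."""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from iespipe.annotation import IesRecord
from iespipe.seqio import revcomp

ALPHABET = "ACGT"

#: limit on the number of rank assignments enumerated by the exact
#: Mann-Whitney path; larger problems use the tie-corrected normal
#: approximation.
_EXACT_ENUM_LIMIT = 200_000

DEFAULT_PEAK_WINDOWS: Tuple[Tuple[str, int, int], ...] = (
    ("26-28", 26, 28),
    ("36-37", 36, 37),
    ("46-47", 46, 47),
    ("55-57", 55, 57),
    ("66-68", 66, 68),
    ("75-77", 75, 77),
)


@dataclass
class SizePeakSpec:
    """Disjoint, ordered (label, min_bp, max_bp) windows; bounds inclusive."""

    windows: Sequence[Tuple[str, int, int]] = DEFAULT_PEAK_WINDOWS

    def validate(self) -> None:
        prev_hi = -1
        for label, lo, hi in self.windows:
            if lo > hi:
                raise ValueError(f"window {label}: min > max")
            if lo <= prev_hi:
                raise ValueError(f"window {label}: overlaps or out of order")
            prev_hi = hi


@dataclass
class EndMotifPWM:
    """Per-position base counts over the 8 bp boundary octamers.

    Both ends read TA-inward: right-end octamers are reverse-complemented
    before stacking, so a perfect-consensus genome shows T and A at the
    first two positions on either side.
    """

    counts: Dict[str, np.ndarray] = field(default_factory=dict)  # side -> (8, 4)
    n_boundaries: Dict[str, int] = field(default_factory=dict)

    def frequencies(self, side: str) -> np.ndarray:
        c = self.counts[side].astype(float)
        totals = c.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1.0
        return c / totals


def irs_histogram(
    results: Iterable, bin_width: float = 0.025
) -> Tuple[np.ndarray, np.ndarray, int]:
    """Counts of defined IRS values in [0, 1] bins; undefined counted apart.

    Returns ``(counts, bin_edges, n_undefined)``; the last bin includes 1.0.
    """
    n_bins = int(round(1.0 / bin_width))
    if not np.isclose(n_bins * bin_width, 1.0):
        raise ValueError("bin_width must divide 1.0")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    values = []
    undefined = 0
    for res in results:
        irs = getattr(res, "irs", res if isinstance(res, float) else None)
        if irs is None:
            undefined += 1
        else:
            values.append(irs)
    counts, _ = np.histogram(values, bins=edges)
    return counts, edges, undefined


def excised_set_overlap(
    set_a: Set[str], set_b: Set[str]
) -> Tuple[int, int, int, float]:
    """Venn counts plus the fraction of B also found in A."""
    inter = set_a & set_b
    frac = len(inter) / len(set_b) if set_b else 0.0
    return len(set_a - set_b), len(inter), len(set_b - set_a), frac


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U of x over y with the 0.5 tie convention."""
    u = 0.0
    for xi in x:
        u += np.sum(xi > y) + 0.5 * np.sum(xi == y)
    return float(u)


def mannwhitney_exact(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating all rank assignments.

    Handles ties exactly (the null permutes the observed pooled values).
    Only feasible for small samples; see ``_EXACT_ENUM_LIMIT``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    u_obs = _u_statistic(x, y)
    mu = n1 * n2 / 2.0
    dev_obs = abs(u_obs - mu)
    total = comb(n1 + n2, n1)
    if total > _EXACT_ENUM_LIMIT:
        raise ValueError("sample too large for exact enumeration")
    hits = 0
    idx = np.arange(n1 + n2)
    for chosen in combinations(idx, n1):
        mask = np.zeros(n1 + n2, dtype=bool)
        mask[list(chosen)] = True
        u = _u_statistic(pooled[mask], pooled[~mask])
        if abs(u - mu) >= dev_obs - 1e-12:
            hits += 1
    return u_obs, hits / total


def compare_lengths(
    lens_a: Sequence[float], lens_b: Sequence[float]
) -> Tuple[float, float, float, float]:
    """Two-sided Mann-Whitney comparison of two length samples.

    Returns ``(median_a, median_b, U, p)``.  Small problems are solved by
    exact enumeration of the permutation null; larger ones use the
    tie-corrected normal approximation.
    """
    if len(lens_a) == 0 or len(lens_b) == 0:
        raise ValueError("empty length sample")
    med_a = float(np.median(lens_a))
    med_b = float(np.median(lens_b))
    if comb(len(lens_a) + len(lens_b), len(lens_a)) <= _EXACT_ENUM_LIMIT:
        u, p = mannwhitney_exact(lens_a, lens_b)
    else:
        res = stats.mannwhitneyu(lens_a, lens_b, alternative="two-sided", method="asymptotic")
        u, p = float(res.statistic), float(res.pvalue)
    return med_a, med_b, u, min(1.0, p)


def size_peak_fractions(
    lengths: Sequence[int],
    spec: Optional[SizePeakSpec] = None,
    reference_lengths: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Fraction of a length set falling in each size-peak window.

    When a reference set is given (e.g. all annotated IESs), its fractions
    are reported side by side for the excess/depletion comparison.
    """
    spec = spec or SizePeakSpec()
    spec.validate()
    lengths = np.asarray(lengths)
    rows = []
    ref = np.asarray(reference_lengths) if reference_lengths is not None else None
    for label, lo, hi in spec.windows:
        frac = float(np.mean((lengths >= lo) & (lengths <= hi))) if len(lengths) else 0.0
        row = {"peak": label, "fraction": frac}
        if ref is not None:
            row["reference_fraction"] = (
                float(np.mean((ref >= lo) & (ref <= hi))) if len(ref) else 0.0
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _octamers(
    intervals: Iterable[Tuple[str, int, int]], germline: Mapping[str, str]
) -> Tuple[List[str], List[str]]:
    left, right = [], []
    for scaffold, s, e in intervals:
        g = germline[scaffold]
        if s + 8 <= len(g):
            left.append(g[s : s + 8])
        if e - 6 >= 0 and e + 2 <= len(g):
            right.append(revcomp(g[e - 6 : e + 2]))
    return left, right


def pwm_from_intervals(
    intervals: Iterable[Tuple[str, int, int]], germline: Mapping[str, str]
) -> EndMotifPWM:
    """Boundary-octamer PWM for arbitrary TA-bounded intervals."""
    left, right = _octamers(intervals, germline)
    pwm = EndMotifPWM()
    for side, seqs in (("left", left), ("right", right)):
        counts = np.zeros((8, 4), dtype=int)
        for seq in seqs:
            for pos, base in enumerate(seq):
                if base in ALPHABET:
                    counts[pos, ALPHABET.index(base)] += 1
        pwm.counts[side] = counts
        pwm.n_boundaries[side] = len(seqs)
    pwm.counts["both"] = pwm.counts["left"] + pwm.counts["right"]
    pwm.n_boundaries["both"] = pwm.n_boundaries["left"] + pwm.n_boundaries["right"]
    return pwm


def end_motif_pwm(
    annotation: Sequence[IesRecord], germline: Mapping[str, str]
) -> EndMotifPWM:
    """PWM of the annotated IES end octamers (left ends; right ends revcomp)."""
    return pwm_from_intervals((rec.interval for rec in annotation), germline)


def ta_positions(
    annotation: Sequence[IesRecord],
    germline: Mapping[str, str],
    window: int = 20,
) -> Dict[str, np.ndarray]:
    """Counts of internal TA starts at offsets 1..window from each boundary.

    Offset ``o`` on the left counts a TA starting at ``s + o``; on the right
    a TA starting at ``e - o``.  Offset 0 (the canonical TA) is excluded.
    """
    if any(rec.length < window for rec in annotation):
        raise ValueError("window exceeds the shortest IES length")
    out = {side: np.zeros(window, dtype=int) for side in ("left", "right")}
    for rec in annotation:
        g = germline[rec.scaffold]
        for o in range(1, window + 1):
            if g[rec.start + o : rec.start + o + 2] == "TA":
                out["left"][o - 1] += 1
            if g[rec.end - o : rec.end - o + 2] == "TA":
                out["right"][o - 1] += 1
    return out


def top_retained_lengths(
    results: Iterable, annotation: Sequence[IesRecord], n: int
) -> List[int]:
    """Lengths of the n IESs with the highest defined IRS.

    Mirrors the comparison set used against the excised set: the same number
    of IESs with the highest retention scores.
    """
    lengths = {rec.ies_id: rec.length for rec in annotation}
    scored = [(r.irs, r.ies_id) for r in results if getattr(r, "irs", None) is not None]
    scored.sort(key=lambda t: (-t[0], t[1]))
    return [lengths[ies_id] for _, ies_id in scored[:n] if ies_id in lengths]
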