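"""Independent brute-force oracles used to cross-check the package.

These deliberately re-derive results from first principles (enumeration,
closed forms) rather than calling the code paths they check.
"""

from itertools import combinations
from math import comb
from typing import Dict, List, Optional, Sequence, Set, Tuple


def ta_starts(seq: str) -> List[int]:
    return [i for i in range(len(seq) - 1) if seq[i : i + 2] == "TA"]


def canonical_representative(
    g: str, a: int, b: int, annotated: Set[Tuple[int, int]]
) -> Optional[Tuple[int, int]]:
    """Leftmost (or annotated) TA-led member of the micro-homology class of
    deletion [a, b): all shifts d with identical spliced product."""
    d = 0
    while a + d - 1 >= 0 and g[a + d - 1] == g[b + d - 1]:
        d -= 1
    lo = d
    d = 0
    while b + d < len(g) and a + d + 1 < b and g[a + d] == g[b + d]:
        d += 1
    hi = d
    cands = [
        (a + d, b + d)
        for d in range(lo, hi + 1)
        if g[a + d : a + d + 2] == "TA" and g[b + d : b + d + 2] == "TA"
    ]
    if not cands:
        return None
    for cand in cands:
        if cand in annotated:
            return cand
    return cands[0]


def brute_force_deletion(
    read: str,
    germline: Dict[str, str],
    annotated_by_scaffold: Dict[str, Set[Tuple[int, int]]],
    min_anchor: int,
) -> Optional[Tuple[str, int, int]]:
    """Enumerate every TA-bounded deletion and test whether the read equals
    the spliced sequence with >= min_anchor on both sides; unique canonical
    hit or None."""
    for g in germline.values():
        if read in g:
            return None  # contiguous germline match
    L = len(read)
    found = set()
    for sc, g in germline.items():
        tas = ta_starts(g)
        # necessity filter: the left/right anchor context must occur in the read
        left_ok = [a for a in tas if a >= min_anchor and g[a - min_anchor : a] in read]
        right_ok = [b for b in tas if g[b : b + min_anchor] in read]
        for a in left_ok:
            for b in right_ok:
                if b <= a:
                    continue
                for j in range(min_anchor, L - min_anchor + 1):
                    if g[a - j : a] == read[:j] and g[b : b + L - j] == read[j:]:
                        cand = canonical_representative(
                            g, a, b, annotated_by_scaffold.get(sc, set())
                        )
                        if cand is not None:
                            found.add((sc, cand[0], cand[1]))
                        break
    if len(found) == 1:
        return next(iter(found))
    return None


_CLASS_TABLE = {
    ("canonical", "canonical"): "CORRECT",
    ("canonical", "internal"): "PARTIAL_INTERNAL",
    ("internal", "canonical"): "PARTIAL_INTERNAL",
    ("canonical", "external"): "PARTIAL_EXTERNAL",
    ("external", "canonical"): "PARTIAL_EXTERNAL",
    ("internal", "internal"): "INTERNAL",
    ("external", "external"): "EXTERNAL",
    ("internal", "external"): "OVERLAPPING",
    ("external", "internal"): "OVERLAPPING",
}


def brute_force_classify(scaffold, a, b, annotation):
    """Direct per-position classification against the max-overlap IES."""
    best = None
    best_ov = 0
    for rec in sorted(annotation):
        if rec.scaffold != scaffold:
            continue
        ov = len(set(range(a, b)) & set(range(rec.start, rec.end)))
        if ov > best_ov:
            best, best_ov = rec, ov
    if best is None:
        return None, "UNMATCHED", (None, None)
    s, e = best.start, best.end
    left = "canonical" if a == s else ("external" if a < s else "internal")
    right = "canonical" if b == e else ("external" if b > e else "internal")
    return best.ies_id, _CLASS_TABLE[(left, right)], (a - s, b - e)


def fisher_greater_p(sp: int, sm: int, cp: int, cm: int) -> float:
    """One-sided hypergeometric tail: P(X >= sp) for the 2x2 table."""
    row1 = sp + sm
    col1 = sp + cp
    n = sp + sm + cp + cm
    denom = comb(n, col1)
    p = 0.0
    for x in range(sp, min(row1, col1) + 1):
        if col1 - x <= cp + cm:
            p += comb(row1, x) * comb(n - row1, col1 - x) / denom
    return min(1.0, p)


def mannwhitney_enumerated(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided exact p by full enumeration of group assignments."""
    n1, n2 = len(x), len(y)
    pooled = list(x) + list(y)

    def u_of(idx_set):
        xs = [pooled[i] for i in idx_set]
        ys = [pooled[i] for i in range(n1 + n2) if i not in idx_set]
        return sum((xi > yi) + 0.5 * (xi == yi) for xi in xs for yi in ys)

    u_obs = u_of(set(range(n1)))
    mu = n1 * n2 / 2.0
    dev = abs(u_obs - mu)
    hits = 0
    total = 0
    for chosen in combinations(range(n1 + n2), n1):
        total += 1
        if abs(u_of(set(chosen)) - mu) >= dev - 1e-12:
            hits += 1
    return hits / total


def binomial_ci(k: int, n: int, level: float = 0.95) -> Tuple[float, float]:
    """Clopper-Pearson interval via the beta quantile."""
    from scipy import stats

    alpha = 1 - level
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi
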