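"""Seeded simulator of paired germline/somatic genomes, IESs and reads.

The somatic ("MAC") genome is the germline ("MAC+IES") genome with every
annotated IES interval excised.  IES intervals are 0-based half-open
``[s, e)`` with the interval starting on a TA and a second TA copy at
``[e, e+2)``, so excising the interval leaves a single TA at the junction
by construction.  IES lengths follow a truncated periodic peak mixture
(~10 bp period, 26 bp minimum, depleted second peak) and IES ends carry a
degenerate TAYAGYNR octamer consensus with configurable fidelity.

Read simulation realizes, per molecule and per IES, a retained / correctly
excised / erroneously excised outcome; erroneous molecules use a planted
alternative TA-bounded junction whose class and boundary shift are drawn
from configurable mixtures.  Contaminating "old MAC" reads come from the
fully excised genome, and a parental vegetative sample carries only a
configurable set of pre-existing error junctions.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from iespipe.annotation import IesRecord, by_scaffold
from iespipe.errors import (
    ERROR_CLASSES,
    EXTERNAL,
    INTERNAL,
    OVERLAPPING,
    PARTIAL_EXTERNAL,
    PARTIAL_INTERNAL,
    classify_boundaries,
)
from iespipe.mapper import normalize_deletion
from iespipe.seqio import revcomp

BASES = "ACGT"

#: IUPAC sets for the degenerate end consensus TAYAGYNR (read TA-inward).
END_CONSENSUS = ("T", "A", "CT", "A", "G", "CT", "ACGT", "AG")

# rng sub-stream labels, combined with the config seed
_STREAM_GENOME = 0
_STREAM_PLAN = 1
_STREAM_SAMPLE = {"autogamous": 2, "parental": 3, "control": 4}


class SimulationError(ValueError):
    """Invalid simulator configuration or failed construction."""


class PlacementError(SimulationError):
    """Not enough scaffold space for the requested IES insertions."""


class InvalidModelError(SimulationError):
    """Degenerate length model (e.g. all peak weights zero)."""


@dataclass
class LengthModel:
    """Periodic peak-mixture model of IES lengths.

    Peak ``k`` is centred near ``min_len + k * period``; the default weights
    deplete the second (36-37 bp) peak.  Sampled lengths are integers
    truncated to ``[min_len, max_len]``.
    """

    min_len: int = 26
    period: float = 10.2
    peak_weights: Sequence[float] = (0.30, 0.01, 0.25, 0.20, 0.14, 0.10)
    peak_sd: float = 1.0
    max_len: int = 150

    def validate(self) -> None:
        if any(w < 0 for w in self.peak_weights):
            raise InvalidModelError("negative peak weight")
        if sum(self.peak_weights) <= 0:
            raise InvalidModelError("all peak weights are zero")
        if self.min_len < 2:
            raise InvalidModelError("min_len must be >= 2 (the boundary TA)")
        if self.max_len < self.min_len:
            raise InvalidModelError("max_len < min_len")

    @property
    def centers(self) -> List[float]:
        return [self.min_len + k * self.period for k in range(len(self.peak_weights))]

    def sample(self, rng: np.random.Generator) -> int:
        return int(sample_ies_length(self, rng))


def sample_ies_length(model: LengthModel, rng: np.random.Generator) -> int:
    """Draw one IES length from the truncated peak mixture."""
    model.validate()
    weights = np.asarray(model.peak_weights, dtype=float)
    probs = weights / weights.sum()
    centers = model.centers
    for _ in range(100):
        k = int(rng.choice(len(probs), p=probs))
        length = int(round(rng.normal(centers[k], model.peak_sd)))
        if length <= model.max_len:
            return max(model.min_len, length)
    return min(model.max_len, max(model.min_len, int(round(centers[0]))))


@dataclass
class SimConfig:
    """All knobs of one simulation, fully determined by ``seed``."""

    n_scaffolds: int = 2
    scaffold_len: int = 10_000
    n_ies: int = 20
    read_len: int = 100
    coverage: float = 100.0
    retention_prob: Union[float, Sequence[float]] = 0.5
    error_rate: float = 0.0
    error_class_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            PARTIAL_INTERNAL: 0.5,
            PARTIAL_EXTERNAL: 0.1,
            INTERNAL: 0.15,
            EXTERNAL: 0.15,
            OVERLAPPING: 0.1,
        }
    )
    shift_model: Mapping[int, float] = field(
        default_factory=lambda: {
            **{10: 0.35, 11: 0.35},
            **{d: 0.3 / 16 for d in (*range(3, 10), *range(12, 21))},
        }
    )
    old_mac_fraction: float = 0.0
    parental_error_junctions: int = 0
    parental_error_read_prob: float = 0.5
    consensus_fidelity: float = 1.0
    substitution_rate: float = 0.0
    min_ies_spacing: int = 250
    edge_margin: int = 150
    seed: int = 0

    def validate(self) -> None:
        for name in ("error_rate", "old_mac_fraction", "parental_error_read_prob",
                     "consensus_fidelity", "substitution_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name}={v} outside [0, 1]")
        probs = np.atleast_1d(np.asarray(self.retention_prob, dtype=float))
        if ((probs < 0) | (probs > 1)).any():
            raise SimulationError("retention_prob outside [0, 1]")
        if self.error_class_mix:
            total = sum(self.error_class_mix.values())
            if not math.isclose(total, 1.0, abs_tol=1e-6):
                raise SimulationError(f"error_class_mix sums to {total}, not 1")
            unknown = set(self.error_class_mix) - set(ERROR_CLASSES)
            if unknown:
                raise SimulationError(f"unknown error classes {unknown}")
        if any(d < 2 for d in self.shift_model):
            raise SimulationError("boundary shifts < 2 bp would clobber the canonical TA")
        if self.parental_error_junctions > self.n_ies:
            raise SimulationError("more parental error junctions than IESs")
        if self.n_ies > 0 and self.read_len > self.scaffold_len:
            raise SimulationError("read_len exceeds scaffold_len")

    def retention_map(self, annotation: Sequence[IesRecord]) -> Dict[str, float]:
        """Per-IES retention probability; sequences are cycled in annotation order."""
        probs = np.atleast_1d(np.asarray(self.retention_prob, dtype=float))
        return {
            rec.ies_id: float(probs[i % len(probs)])
            for i, rec in enumerate(sorted(annotation))
        }


@dataclass(frozen=True)
class PlannedEvent:
    """The alternative TA-bounded junction assigned to one IES."""

    ies_id: str
    scaffold: str
    start: int
    end: int
    klass: str
    left_offset: int
    right_offset: int
    parental: bool = False


@dataclass
class ReadOrigin:
    read_id: str
    sample: str
    source: str  # nascent | old_mac
    scaffold: str
    position: int  # germline coord (nascent) or somatic coord (old_mac)


@dataclass
class GroundTruth:
    """Everything planted: per-IES retention, error junctions, read origins."""

    sample: str
    retention: Dict[str, float]
    planted_events: List[PlannedEvent]
    read_origins: List[ReadOrigin]
    ies_stats: Dict[str, Dict[str, int]]
    n_reads: int

    def realized_retention(self, ies_id: str) -> Optional[float]:
        st = self.ies_stats.get(ies_id)
        if not st or st["draws"] == 0:
            return None
        return st["retained"] / st["draws"]


def _random_bases(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n)


def _sample_octamer(rng: np.random.Generator, fidelity: float) -> str:
    """One 8-mer from the degenerate end consensus, read TA-inward."""
    out = ["T", "A"]
    for allowed in END_CONSENSUS[2:]:
        pool = allowed if rng.random() < fidelity else BASES
        out.append(pool[int(rng.integers(0, len(pool)))])
    return "".join(out)


def _ies_sequence(rng: np.random.Generator, length: int, fidelity: float) -> str:
    """IES sequence of ``length`` bp starting with TA; ends carry the consensus.

    The right-end octamer is completed by the retained TA that follows the
    interval, so only its inner six bases live inside the IES.
    """
    if length < 14:
        core = "".join(BASES[i] for i in _random_bases(rng, length - 2))
        return "TA" + core
    left = _sample_octamer(rng, fidelity)
    right = _sample_octamer(rng, fidelity)
    core = "".join(BASES[i] for i in _random_bases(rng, length - 14))
    return left + core + revcomp(right)[:6]


def _place_insertions(
    rng: np.random.Generator, n: int, scaffold_len: int, margin: int, spacing: int
) -> List[int]:
    """Sorted insertion points with pairwise gaps >= spacing, margin respected."""
    if n == 0:
        return []
    usable = scaffold_len - 2 * margin - (n - 1) * spacing
    if usable < 0:
        raise PlacementError(
            f"cannot place {n} IESs with spacing {spacing} in {scaffold_len} bp"
        )
    offsets = np.sort(rng.integers(0, usable + 1, size=n))
    return [int(margin + offsets[i] + i * spacing) for i in range(n)]


def excise(germline: Mapping[str, str], annotation: Sequence[IesRecord]) -> Dict[str, str]:
    """Remove every annotated interval; the canonical round-trip operation."""
    grouped = by_scaffold(annotation)
    out: Dict[str, str] = {}
    for name, seq in germline.items():
        parts: List[str] = []
        cursor = 0
        for rec in grouped.get(name, []):
            parts.append(seq[cursor : rec.start])
            cursor = rec.end
        parts.append(seq[cursor:])
        out[name] = "".join(parts)
    return out


def generate_genomes(
    cfg: SimConfig, model: Optional[LengthModel] = None
) -> Tuple[Dict[str, str], Dict[str, str], List[IesRecord]]:
    """Build the germline genome, its somatic counterpart and the annotation.

    When the config plants excision errors, the alternative TA boundaries are
    created here (by local substitution where no TA exists) so that both
    genomes and all planted junctions are mutually consistent.
    """
    model = model or LengthModel()
    cfg.validate()
    model.validate()
    rng = np.random.default_rng([cfg.seed, _STREAM_GENOME])

    per_scaffold = [cfg.n_ies // cfg.n_scaffolds] * cfg.n_scaffolds
    for i in range(cfg.n_ies % cfg.n_scaffolds):
        per_scaffold[i] += 1

    germline: Dict[str, str] = {}
    annotation: List[IesRecord] = []
    counter = 0
    for sidx in range(cfg.n_scaffolds):
        name = f"scaffold_{sidx + 1}"
        backbone = _random_bases(rng, cfg.scaffold_len)
        points = _place_insertions(
            rng, per_scaffold[sidx], cfg.scaffold_len, cfg.edge_margin, cfg.min_ies_spacing
        )
        for p in points:
            backbone[p] = 3  # T
            backbone[p + 1] = 0  # A
        somatic_seq = "".join(BASES[i] for i in backbone)
        parts: List[str] = []
        cursor = 0
        offset = 0
        for p in points:
            length = model.sample(rng)
            ies_seq = _ies_sequence(rng, length, cfg.consensus_fidelity)
            parts.append(somatic_seq[cursor:p])
            parts.append(ies_seq)
            start = p + offset
            annotation.append(IesRecord(name, start, start + length, f"IES.{counter:05d}"))
            counter += 1
            offset += length
            cursor = p
        parts.append(somatic_seq[cursor:])
        germline[name] = "".join(parts)

    plan, edits = plan_error_junctions(cfg, annotation, germline)
    _apply_edits(germline, edits)
    somatic = excise(germline, annotation)
    return germline, somatic, annotation


def _draw_shift(
    rng: np.random.Generator, offsets: Sequence[int], probs: np.ndarray, cap: int
) -> int:
    for _ in range(100):
        d = int(offsets[int(rng.choice(len(offsets), p=probs))])
        if d <= cap:
            return d
    return min(cap, min(offsets))


def _apply_edits(genome: Dict[str, str], edits: Sequence[Tuple[str, int, str]]) -> None:
    for scaffold, pos, repl in edits:
        seq = genome[scaffold]
        genome[scaffold] = seq[:pos] + repl + seq[pos + len(repl) :]


def plan_error_junctions(
    cfg: SimConfig, annotation: Sequence[IesRecord], germline: Mapping[str, str]
) -> Tuple[Dict[str, PlannedEvent], List[Tuple[str, int, str]]]:
    """Assign every IES an alternative junction (class + boundary shifts).

    Returns the plan plus the germline edits it requires: a TA is written at
    any shifted boundary lacking one, and single-base edits break
    micro-homology whenever the planted interval would otherwise normalize
    to a different TA-led representation ("class mixes stay exact").
    Deterministic given the config seed and idempotent: on the final
    (already edited) germline the same plan is returned with no edits left.
    """
    if cfg.error_rate <= 0 and cfg.parental_error_junctions == 0:
        return {}, []
    rng = np.random.default_rng([cfg.seed, _STREAM_PLAN])
    classes = [k for k in ERROR_CLASSES if cfg.error_class_mix.get(k, 0) > 0]
    if not classes:
        raise SimulationError("error planting requested but error_class_mix is empty")
    class_probs = np.array([cfg.error_class_mix[k] for k in classes], dtype=float)
    class_probs /= class_probs.sum()
    offsets = sorted(cfg.shift_model)
    shift_probs = np.array([cfg.shift_model[d] for d in offsets], dtype=float)
    shift_probs /= shift_probs.sum()

    recs = sorted(annotation)
    parental_idx = set(
        int(i)
        for i in rng.choice(len(recs), size=cfg.parental_error_junctions, replace=False)
    ) if cfg.parental_error_junctions else set()

    plan: Dict[str, PlannedEvent] = {}
    edits: List[Tuple[str, int, str]] = []
    final = dict(germline)
    annotated_by_sc: Dict[str, set] = {}
    for rec in recs:
        annotated_by_sc.setdefault(rec.scaffold, set()).add((rec.start, rec.end))
    for idx, rec in enumerate(recs):
        s, e, L = rec.start, rec.end, rec.length
        klass = classes[int(rng.choice(len(classes), p=class_probs))]
        draw = lambda cap: _draw_shift(rng, offsets, shift_probs, cap)  # noqa: E731
        if klass == PARTIAL_INTERNAL:
            if rng.integers(0, 2) == 0:
                a, b = s + draw(L - 4), e
            else:
                a, b = s, e - draw(L - 4)
        elif klass == PARTIAL_EXTERNAL:
            if rng.integers(0, 2) == 0:
                a, b = s - draw(cfg.edge_margin // 2), e
            else:
                a, b = s, e + draw(cfg.edge_margin // 2)
        elif klass == INTERNAL:
            d1 = draw(L - 8)
            a, b = s + d1, e - draw(L - 4 - d1)
        elif klass == EXTERNAL:
            a, b = s - draw(cfg.edge_margin // 2), e + draw(cfg.edge_margin // 2)
        else:  # OVERLAPPING
            if rng.integers(0, 2) == 0:
                a, b = s + draw(L - 4), e + draw(cfg.edge_margin // 2)
            else:
                a, b = s - draw(cfg.edge_margin // 2), e - draw(L - 4)
        sc = rec.scaffold
        for pos in (a, b):
            if pos not in (s, e) and final[sc][pos : pos + 2] != "TA":
                edits.append((sc, pos, "TA"))
                _apply_edits(final, edits[-1:])

        # the planted interval must be its own canonical representation or
        # the mapper would report a slid interval (possibly another class);
        # break residual micro-homology with a single C/G edit placed away
        # from the canonical and planted TAs ("class mixes stay exact")
        protected = {s, s + 1, e, e + 1, a, a + 1, b, b + 1}
        for _attempt in range(12):
            g = final[sc]
            norm = normalize_deletion(g, a, b, annotated_by_sc[sc])
            if norm == (a, b):
                break
            shift = (norm[0] - a) if norm is not None else -1
            if shift < 0:
                pos, avoid = b - 1, g[a - 1]
                if pos in protected:
                    pos, avoid = a - 1, g[b - 1]
            else:
                pos, avoid = a + 2, g[b + 2] if b + 2 < len(g) else "T"
                if pos in protected:
                    pos, avoid = b + 2, g[a + 2]
            if pos in protected or not 0 <= pos < len(g):
                break  # cannot break safely; fall through to re-derivation
            new = "C" if avoid != "C" else "G"
            edits.append((sc, pos, new))
            _apply_edits(final, edits[-1:])
        norm = normalize_deletion(final[sc], a, b, annotated_by_sc[sc])
        if norm is not None and norm != (a, b):
            # unbreakable ambiguity: record what the mapper will report
            a, b = norm
            klass = classify_boundaries(a, b, s, e)[0]
        plan[rec.ies_id] = PlannedEvent(
            ies_id=rec.ies_id,
            scaffold=sc,
            start=a,
            end=b,
            klass=klass,
            left_offset=a - s,
            right_offset=b - e,
            parental=idx in parental_idx,
        )
    return plan, edits


def _splice_window(
    germ: str, start: int, deletions: Sequence[Tuple[int, int]], read_len: int
) -> Optional[str]:
    """Read of ``read_len`` bp from the molecule defined by ``deletions``.

    Returns None when the scaffold ends before the window is filled or when
    ``start`` falls inside a deleted interval.
    """
    out: List[str] = []
    got = 0
    p = start
    i = 0
    dels = sorted(deletions)
    while got < read_len:
        while i < len(dels) and dels[i][1] <= p:
            i += 1
        if i < len(dels) and dels[i][0] <= p:
            if p == start:
                return None
            p = dels[i][1]
            i += 1
            continue
        limit = dels[i][0] if i < len(dels) else len(germ)
        take = min(limit - p, read_len - got)
        if take > 0:
            out.append(germ[p : p + take])
            got += take
            p += take
        if got < read_len and p >= len(germ):
            return None
        if got < read_len and i < len(dels) and p == dels[i][0]:
            p = dels[i][1]
            i += 1
    return "".join(out)


def _apply_substitutions(
    rng: np.random.Generator, seq: str, rate: float
) -> str:
    if rate <= 0:
        return seq
    n_sub = rng.binomial(len(seq), rate)
    if n_sub == 0:
        return seq
    positions = rng.choice(len(seq), size=n_sub, replace=False)
    chars = list(seq)
    for pos in positions:
        current = chars[pos]
        alternatives = [b for b in BASES if b != current]
        chars[pos] = alternatives[int(rng.integers(0, 3))]
    return "".join(chars)


def simulate_reads(
    cfg: SimConfig,
    genomes: Tuple[Mapping[str, str], Mapping[str, str]],
    annotation: Sequence[IesRecord],
    *,
    sample: str = "autogamous",
    retention_override: Union[None, float, Sequence[float], Mapping[str, float]] = None,
) -> Tuple[List[Tuple[str, str]], GroundTruth]:
    """Draw fixed-length reads from molecule populations.

    ``sample`` selects the generative rules: ``autogamous`` mixes nascent
    molecules (retained / excised / erroneous per IES) with old-MAC
    contamination; ``control`` is the same with ``retention_override``
    applied (default 0, i.e. complete excision, no errors); ``parental``
    contains only correct excision plus the planted pre-existing error
    junctions.
    """
    cfg.validate()
    germline, somatic = genomes
    if sample not in _STREAM_SAMPLE:
        raise SimulationError(f"unknown sample kind {sample!r}")
    rng = np.random.default_rng([cfg.seed, _STREAM_SAMPLE[sample]])

    plan, edits = plan_error_junctions(cfg, annotation, germline)
    if edits:
        # caller passed genomes without the planted junction edits; apply locally
        germline = dict(germline)
        _apply_edits(germline, edits)
        somatic = excise(germline, annotation)

    retention = cfg.retention_map(annotation)
    if retention_override is not None:
        if isinstance(retention_override, Mapping):
            retention.update(retention_override)
        else:
            probs = np.atleast_1d(np.asarray(retention_override, dtype=float))
            retention = {
                rec.ies_id: float(probs[i % len(probs)])
                for i, rec in enumerate(sorted(annotation))
            }
    if sample == "control" and retention_override is None:
        retention = {k: 0.0 for k in retention}

    grouped = by_scaffold(annotation)
    scaffolds = list(germline)
    germ_lens = np.array([len(germline[s]) for s in scaffolds], dtype=float)
    som_lens = np.array([max(1, len(somatic[s])) for s in scaffolds], dtype=float)
    germ_w = germ_lens / germ_lens.sum()
    som_w = som_lens / som_lens.sum()
    rec_starts = {s: [r.start for r in grouped.get(s, [])] for s in scaffolds}
    pad = max((r.length for r in annotation), default=0) + 2 * max(
        cfg.shift_model, default=0
    ) + 4

    total_somatic = int(sum(len(v) for v in somatic.values()))
    n_reads = max(1, int(round(cfg.coverage * total_somatic / cfg.read_len)))

    erroneous_in_sample = {
        ies_id: ev
        for ies_id, ev in plan.items()
        if (sample != "parental" and cfg.error_rate > 0) or (sample == "parental" and ev.parental)
    }
    use_old_mac = cfg.old_mac_fraction if sample != "parental" else 0.0

    reads: List[Tuple[str, str]] = []
    origins: List[ReadOrigin] = []
    ies_stats = {
        rec.ies_id: {"draws": 0, "retained": 0, "correct": 0, "erroneous": 0}
        for rec in annotation
    }

    for ridx in range(n_reads):
        read_id = f"{sample}_{ridx:07d}"
        if use_old_mac > 0 and rng.random() < use_old_mac:
            sc = scaffolds[int(rng.choice(len(scaffolds), p=som_w))]
            seq = somatic[sc]
            if len(seq) < cfg.read_len:
                raise SimulationError("read_len exceeds somatic scaffold length")
            start = int(rng.integers(0, len(seq) - cfg.read_len + 1))
            read_seq = seq[start : start + cfg.read_len]
            source = "old_mac"
        else:
            sc = scaffolds[int(rng.choice(len(scaffolds), p=germ_w))]
            seq = germline[sc]
            recs = grouped.get(sc, [])
            starts = rec_starts[sc]
            read_seq = None
            for _attempt in range(200):
                start = int(rng.integers(0, len(seq) - cfg.read_len + 1))
                lo = bisect_left(starts, start - pad)
                deletions: List[Tuple[int, int]] = []
                for rec in recs[lo:]:
                    if rec.start > start + cfg.read_len + pad:
                        break
                    # every decision is one molecule-level Bernoulli draw and
                    # is recorded even if the window is later rejected
                    st = ies_stats[rec.ies_id]
                    st["draws"] += 1
                    if sample == "parental":
                        ev = erroneous_in_sample.get(rec.ies_id)
                        if ev is not None and rng.random() < cfg.parental_error_read_prob:
                            st["erroneous"] += 1
                            deletions.append((ev.start, ev.end))
                        else:
                            st["correct"] += 1
                            deletions.append((rec.start, rec.end))
                    elif rng.random() < retention[rec.ies_id]:
                        st["retained"] += 1
                    else:
                        ev = erroneous_in_sample.get(rec.ies_id)
                        if ev is not None and rng.random() < cfg.error_rate:
                            st["erroneous"] += 1
                            deletions.append((ev.start, ev.end))
                        else:
                            st["correct"] += 1
                            deletions.append((rec.start, rec.end))
                read_seq = _splice_window(seq, start, deletions, cfg.read_len)
                if read_seq is not None:
                    break
            if read_seq is None:
                raise SimulationError("failed to draw a read after 200 attempts")
            source = "nascent"
        read_seq = _apply_substitutions(rng, read_seq, cfg.substitution_rate)
        reads.append((read_id, read_seq))
        origins.append(ReadOrigin(read_id, sample, source, sc, start))

    truth = GroundTruth(
        sample=sample,
        retention=retention,
        planted_events=sorted(plan.values(), key=lambda ev: ev.ies_id),
        read_origins=origins,
        ies_stats=ies_stats,
        n_reads=len(reads),
    )
    return reads, truth
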