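"""Dataframe bridges between domain objects and the plain-TSV interchange
tables used by the CLI stages."""

from __future__ import annotations

from typing import Dict, Iterable, List, Sequence

import numpy as np
import pandas as pd

from iespipe.annotation import IesRecord
from iespipe.errors import ExcisionEvent
from iespipe.mapper import JunctionEvidence
from iespipe.retention import RetentionResult
from iespipe.simulate import GroundTruth


def evidence_to_frame(evidences: Iterable[JunctionEvidence]) -> pd.DataFrame:
    rows = [
        {
            "read_id": ev.read_id,
            "kind": ev.kind,
            "ies_id": ev.ies_id if ev.ies_id is not None else "",
            "scaffold": ev.scaffold if ev.scaffold is not None else "",
            "start": ev.start if ev.start is not None else -1,
            "end": ev.end if ev.end is not None else -1,
        }
        for ev in evidences
    ]
    return pd.DataFrame(
        rows, columns=["read_id", "kind", "ies_id", "scaffold", "start", "end"]
    )


def frame_to_evidence(df: pd.DataFrame) -> List[JunctionEvidence]:
    out = []
    for row in df.itertuples(index=False):
        out.append(
            JunctionEvidence(
                read_id=str(row.read_id),
                kind=str(row.kind),
                ies_id=str(row.ies_id) if str(row.ies_id) not in ("", "nan") else None,
                scaffold=str(row.scaffold) if str(row.scaffold) not in ("", "nan") else None,
                start=int(row.start) if int(row.start) >= 0 else None,
                end=int(row.end) if int(row.end) >= 0 else None,
            )
        )
    return out


def events_to_frame(events: Iterable[ExcisionEvent]) -> pd.DataFrame:
    rows = [
        {
            "scaffold": ev.scaffold,
            "start": ev.start,
            "end": ev.end,
            "read_count": ev.read_count,
            "ies_id": ev.ies_id if ev.ies_id is not None else "",
            "klass": ev.klass,
            "left_offset": ev.left_offset if ev.left_offset is not None else "",
            "right_offset": ev.right_offset if ev.right_offset is not None else "",
            "multi_ies": ev.multi_ies,
        }
        for ev in events
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "scaffold", "start", "end", "read_count", "ies_id",
            "klass", "left_offset", "right_offset", "multi_ies",
        ],
    )


def frame_to_events(df: pd.DataFrame) -> List[ExcisionEvent]:
    def _opt_int(value):
        text = str(value)
        return None if text in ("", "nan") else int(float(text))

    out = []
    for row in df.itertuples(index=False):
        out.append(
            ExcisionEvent(
                scaffold=str(row.scaffold),
                start=int(row.start),
                end=int(row.end),
                read_count=int(row.read_count),
                ies_id=str(row.ies_id) if str(row.ies_id) not in ("", "nan") else None,
                klass=str(row.klass),
                left_offset=_opt_int(row.left_offset),
                right_offset=_opt_int(row.right_offset),
                multi_ies=bool(row.multi_ies),
            )
        )
    return out


def results_to_frame(results: Iterable[RetentionResult]) -> pd.DataFrame:
    def _fmt(value):
        return "" if value is None else value

    rows = [
        {
            "ies_id": r.ies_id,
            "left_score": _fmt(r.left_score),
            "right_score": _fmt(r.right_score),
            "irs": _fmt(r.irs),
            "p_left": _fmt(r.p_left),
            "p_right": _fmt(r.p_right),
            "q_left": _fmt(r.q_left),
            "q_right": _fmt(r.q_right),
            "significantly_retained": r.significantly_retained,
            "fully_excised": r.fully_excised,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "ies_id", "left_score", "right_score", "irs",
            "p_left", "p_right", "q_left", "q_right",
            "significantly_retained", "fully_excised",
        ],
    )


def frame_to_results(df: pd.DataFrame) -> List[RetentionResult]:
    def _opt_float(value):
        text = str(value)
        return None if text in ("", "nan") else float(text)

    return [
        RetentionResult(
            ies_id=str(row.ies_id),
            left_score=_opt_float(row.left_score),
            right_score=_opt_float(row.right_score),
            irs=_opt_float(row.irs),
            p_left=_opt_float(row.p_left),
            p_right=_opt_float(row.p_right),
            q_left=_opt_float(row.q_left),
            q_right=_opt_float(row.q_right),
            significantly_retained=bool(row.significantly_retained),
            fully_excised=bool(row.fully_excised),
        )
        for row in df.itertuples(index=False)
    ]


def truth_ies_frame(
    truth: GroundTruth, annotation: Sequence[IesRecord]
) -> pd.DataFrame:
    rows = []
    for rec in sorted(annotation):
        st = truth.ies_stats.get(rec.ies_id, {})
        rows.append(
            {
                "ies_id": rec.ies_id,
                "scaffold": rec.scaffold,
                "start": rec.start,
                "end": rec.end,
                "length": rec.length,
                "retention_prob": truth.retention.get(rec.ies_id, np.nan),
                "draws": st.get("draws", 0),
                "retained": st.get("retained", 0),
                "correct": st.get("correct", 0),
                "erroneous": st.get("erroneous", 0),
            }
        )
    return pd.DataFrame(rows)


def truth_events_frame(truth: GroundTruth) -> pd.DataFrame:
    rows = [
        {
            "ies_id": ev.ies_id,
            "scaffold": ev.scaffold,
            "start": ev.start,
            "end": ev.end,
            "klass": ev.klass,
            "left_offset": ev.left_offset,
            "right_offset": ev.right_offset,
            "parental": ev.parental,
        }
        for ev in truth.planted_events
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "ies_id", "scaffold", "start", "end", "klass",
            "left_offset", "right_offset", "parental",
        ],
    )


def truth_reads_frame(truth: GroundTruth) -> pd.DataFrame:
    rows = [
        {
            "read_id": o.read_id,
            "sample": o.sample,
            "source": o.source,
            "scaffold": o.scaffold,
            "position": o.position,
        }
        for o in truth.read_origins
    ]
    return pd.DataFrame(
        rows, columns=["read_id", "sample", "source", "scaffold", "position"]
    )
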