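"""IES annotation records and GFF3 round-trip.

Internal coordinates are 0-based half-open ``[start, end)`` on the germline
reference; the interval begins with the boundary "TA" and the second TA copy
sits at ``[end, end+2)``.  GFF3 output follows the GFF3 convention (1-based,
inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping

GFF3_SOURCE = "iespipe"
GFF3_TYPE = "internal_eliminated_sequence"


@dataclass(frozen=True, order=True)
class IesRecord:
    """One annotated IES interval on the germline reference.

    ``germline[start:start+2] == "TA"`` and ``germline[end:end+2] == "TA"``;
    excising ``[start, end)`` leaves a single TA at the junction.
    """

    scaffold: str
    start: int
    end: int
    ies_id: str

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> tuple:
        return (self.scaffold, self.start, self.end)


def validate_annotation(
    annotation: Iterable[IesRecord], germline: Mapping[str, str]
) -> None:
    """Raise ``ValueError`` unless every record is TA-anchored at both ends."""
    for rec in annotation:
        if rec.scaffold not in germline:
            raise ValueError(f"{rec.ies_id}: unknown scaffold {rec.scaffold!r}")
        seq = germline[rec.scaffold]
        if not (0 <= rec.start < rec.end and rec.end + 2 <= len(seq)):
            raise ValueError(f"{rec.ies_id}: interval out of bounds")
        if seq[rec.start : rec.start + 2] != "TA":
            raise ValueError(f"{rec.ies_id}: no TA at 5' boundary")
        if seq[rec.end : rec.end + 2] != "TA":
            raise ValueError(f"{rec.ies_id}: no TA after 3' boundary")


def by_scaffold(annotation: Iterable[IesRecord]) -> Dict[str, List[IesRecord]]:
    """Group records per scaffold, sorted by start coordinate."""
    out: Dict[str, List[IesRecord]] = {}
    for rec in annotation:
        out.setdefault(rec.scaffold, []).append(rec)
    for recs in out.values():
        recs.sort(key=lambda r: r.start)
    return out


def write_gff3(annotation: Iterable[IesRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in sorted(annotation):
            fh.write(
                "\t".join(
                    (
                        rec.scaffold,
                        GFF3_SOURCE,
                        GFF3_TYPE,
                        str(rec.start + 1),
                        str(rec.end),
                        ".",
                        "+",
                        ".",
                        f"ID={rec.ies_id}",
                    )
                )
                + "\n"
            )


def read_gff3(path: str) -> List[IesRecord]:
    records: List[IesRecord] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            records.append(
                IesRecord(
                    scaffold=fields[0],
                    start=int(fields[3]) - 1,
                    end=int(fields[4]),
                    ies_id=attrs.get("ID", f"ies_{len(records)}"),
                )
            )
    records.sort()
    return records
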