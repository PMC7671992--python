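"""Reading annotation exports and deriving navigation workflows.

Annotation records are timed intervals listing the visible landmarks, as an
observer would export them from a workflow-annotation tool.  Two plain-text
schemas are supported:

* CSV with header ``start_s,end_s,landmarks`` where ``landmarks`` is a
  ``;``-separated list of landmark names;
* JSON ``{"workflow_id": ..., "records": [{"start_s", "end_s",
  "landmarks": [...]}, ...]}``.

Records are merged into navigation states (consecutive records with an
identical landmark combination form one state, i.e. one continuous
visibility interval), step counts are assigned 1..n, and movement directions
are filled in from the spatial ontology.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .ontology import (
    NavigationState,
    SpatialOntology,
    infer_direction,
    validate_workflow,
)
from .sentences import Sentence, state_to_sentence

__all__ = [
    "AnnotationRecord",
    "NavigationWorkflow",
    "read_annotations",
    "derive_workflow",
    "write_corpus",
    "read_corpus",
]


@dataclass
class AnnotationRecord:
    """One timed landmark observation interval."""

    start_s: float
    end_s: float
    landmarks: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.end_s < self.start_s:
            raise ValueError(f"end_s {self.end_s} < start_s {self.start_s}")
        if not self.landmarks:
            raise ValueError("record without landmarks")


@dataclass
class NavigationWorkflow:
    """An ordered sequence of navigation states from one procedure."""

    workflow_id: str
    states: list[NavigationState] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.states)

    @property
    def duration_s(self) -> float:
        if not self.states:
            return 0.0
        return self.states[-1].end_s - self.states[0].start_s

    def sentences(self, ontology: SpatialOntology) -> list[Sentence]:
        return [state_to_sentence(st, ontology) for st in self.states]


def read_annotations(
    path: str | Path,
    fmt: str | None = None,
    ontology: SpatialOntology | None = None,
    strict: bool = True,
) -> list[AnnotationRecord]:
    """Read annotation records from a CSV or JSON export.

    Records are returned sorted by start time.  Landmark names are validated
    against the ontology when one is given.  Overlapping records raise in
    strict mode; in lenient mode the earlier record is truncated at the
    later record's start.
    """
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    if fmt == "csv":
        records = _read_csv(path)
    elif fmt == "json":
        records = _read_json(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if not records:
        raise ValueError(f"no records in {path}")
    records.sort(key=lambda r: r.start_s)
    if ontology is not None:
        for i, rec in enumerate(records):
            for name in rec.landmarks:
                if name not in ontology:
                    raise ValueError(f"record {i}: unknown landmark {name!r}")
    for i in range(len(records) - 1):
        if records[i].end_s > records[i + 1].start_s:
            if strict:
                raise ValueError(
                    f"records {i} and {i + 1} overlap "
                    f"({records[i].end_s} > {records[i + 1].start_s})"
                )
            records[i].end_s = records[i + 1].start_s
    return records


def _read_csv(path: Path) -> list[AnnotationRecord]:
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return []
        required = {"start_s", "end_s", "landmarks"}
        if not required.issubset(reader.fieldnames):
            raise ValueError(
                f"CSV header must contain {sorted(required)}, got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(
                    AnnotationRecord(
                        start_s=float(row["start_s"]),
                        end_s=float(row["end_s"]),
                        landmarks=tuple(
                            t for t in row["landmarks"].split(";") if t
                        ),
                    )
                )
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from exc
    return records


def _read_json(path: Path) -> list[AnnotationRecord]:
    doc = json.loads(path.read_text())
    records = []
    for i, rec in enumerate(doc.get("records", [])):
        try:
            records.append(
                AnnotationRecord(
                    start_s=float(rec["start_s"]),
                    end_s=float(rec["end_s"]),
                    landmarks=tuple(rec["landmarks"]),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"{path}: record {i}: malformed: {exc}") from exc
    return records


def derive_workflow(
    records: Sequence[AnnotationRecord],
    ontology: SpatialOntology,
    workflow_id: str = "wf",
) -> NavigationWorkflow:
    """Merge annotation records into a navigation workflow.

    Consecutive records with identical landmark combinations are merged into
    a single state (one landmark-combination visit = one step).  Step counts
    are assigned consecutively from 1 and directions are inferred from the
    depth-rank ontology; the first state dwells.
    """
    if not records:
        raise ValueError("empty record list")
    merged: list[tuple[frozenset[str], float, float]] = []
    for rec in records:
        combo = frozenset(rec.landmarks)
        if merged and merged[-1][0] == combo:
            prev_combo, s, _ = merged[-1]
            merged[-1] = (prev_combo, s, rec.end_s)
        else:
            merged.append((combo, rec.start_s, rec.end_s))
    states: list[NavigationState] = []
    prev: frozenset[str] | None = None
    for step, (combo, start_s, end_s) in enumerate(merged, start=1):
        rep = ontology.representative(combo)
        states.append(
            NavigationState(
                step_count=step,
                cavity=rep.cavity,
                landmark_group=rep.group,
                landmark_combination=combo,
                direction=infer_direction(prev, combo, ontology),
                start_s=start_s,
                end_s=end_s,
            )
        )
        prev = combo
    wf = NavigationWorkflow(workflow_id, states)
    problems = validate_workflow(wf.states, ontology)
    if problems:
        raise ValueError(f"derived workflow invalid: {problems}")
    return wf


def write_corpus(
    workflows: Iterable[NavigationWorkflow],
    out_dir: str | Path,
    ontology: SpatialOntology,
) -> list[Path]:
    """Write per-workflow sentence and pair files.

    For each workflow: ``<id>.sents.txt`` with one space-joined sentence per
    line (n lines) and ``<id>.pairs.tsv`` with source TAB target per line
    (n-1 lines).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for wf in workflows:
        sents = [" ".join(s) for s in wf.sentences(ontology)]
        sent_path = out_dir / f"{wf.workflow_id}.sents.txt"
        sent_path.write_text("".join(line + "\n" for line in sents))
        pair_path = out_dir / f"{wf.workflow_id}.pairs.tsv"
        pair_path.write_text(
            "".join(f"{a}\t{b}\n" for a, b in zip(sents, sents[1:]))
        )
        written.extend([sent_path, pair_path])
    return written


def read_corpus(sent_path: str | Path) -> list[Sentence]:
    """Read a sentence file back into token tuples."""
    return [
        tuple(line.split())
        for line in Path(sent_path).read_text().splitlines()
        if line.strip()
    ]
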