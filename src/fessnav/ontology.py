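"""Spatial ontology of FESS landmarks and the navigation-state model.

Functional endoscopic sinus surgery (FESS) navigation is described as a
sequence of timed endoscope states.  Each state names the anatomical
landmarks currently visible (a *landmark combination* of one to three
landmarks), the cavity and landmark group they belong to, and the movement
direction relative to the previous state.  Direction is inferred from a
depth-ranked spatial ontology: a landmark *spatially follows* another when
it lies deeper along the surgical approach.  Moving to a deeper landmark is
``inwards``, to a shallower one ``outwards``, and between spatially
equivalent landmarks ``dwell``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Direction",
    "Landmark",
    "SpatialOntology",
    "NavigationState",
    "infer_direction",
    "validate_workflow",
    "default_ontology",
]


class Direction(str, Enum):
    """Movement direction of the endoscope between two consecutive states."""

    INWARDS = "inwards"
    OUTWARDS = "outwards"
    DWELL = "dwell"


@dataclass(frozen=True)
class Landmark:
    """One anatomical landmark with its position in the spatial ontology.

    Parameters
    ----------
    name : str
        FMA-style identifier, underscore-joined (e.g. ``middle_nasal_concha``).
    depth_rank : int
        Non-negative depth along the anterior-to-posterior surgical approach;
        larger means deeper.  ``out_of_patient`` has the minimum rank.
    group : str
        Landmark group the landmark belongs to.
    cavity : str
        Main cavity the landmark belongs to.
    """

    name: str
    depth_rank: int
    group: str
    cavity: str

    def __post_init__(self) -> None:
        if self.depth_rank < 0:
            raise ValueError(f"depth_rank must be >= 0, got {self.depth_rank}")


# Default depth ranks follow the anterior-to-posterior FESS approach:
# the endoscope passes the middle nasal concha, enters the middle meatus,
# reaches the uncinate process / ethmoidal bulla, then the maxillary sinus
# ostium and finally the spheno-ethmoidal recess.  Ranks are configuration,
# not anatomy ground truth, and can be overridden from a JSON file.
_DEFAULT_TABLE = [
    ("out_of_patient", 0, "external_group", "external"),
    ("middle_nasal_concha", 1, "concha_group", "nasal_cavity"),
    ("middle_nasal_meatus", 2, "meatus_group", "nasal_cavity"),
    ("uncinate_process_of_ethmoid", 3, "ethmoid_group", "ethmoidal_sinus"),
    ("ethmoidal_bulla", 3, "ethmoid_group", "ethmoidal_sinus"),
    ("maxillary_sinus_orifice", 4, "maxillary_group", "maxillary_sinus"),
    ("spheno_ethmoidal_recess", 5, "sphenoid_group", "sphenoidal_sinus"),
]


class SpatialOntology:
    """Depth-ranked landmark table driving direction inference.

    The ontology is a set of :class:`Landmark` entries with unique names.
    Depth ranks induce a total preorder; ties (e.g. uncinate process and
    ethmoidal bulla) are spatially equivalent.
    """

    def __init__(self, landmarks: Iterable[Landmark]):
        self._by_name: dict[str, Landmark] = {}
        for lm in landmarks:
            if lm.name in self._by_name:
                raise ValueError(f"duplicate landmark name: {lm.name}")
            self._by_name[lm.name] = lm
        if not self._by_name:
            raise ValueError("ontology needs at least one landmark")

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __iter__(self):
        return iter(self._by_name.values())

    def __len__(self) -> int:
        return len(self._by_name)

    @property
    def names(self) -> list[str]:
        return list(self._by_name)

    def get(self, name: str) -> Landmark:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown landmark: {name!r}") from None

    def rank(self, name: str) -> int:
        return self.get(name).depth_rank

    def combination_rank(self, combination: Iterable[str]) -> int:
        """Representative rank of a combination = max member rank.

        The deepest visible landmark determines navigational progress.
        """
        names = list(combination)
        if not names:
            raise ValueError("empty landmark combination")
        return max(self.rank(n) for n in names)

    def representative(self, combination: Iterable[str]) -> Landmark:
        """Deepest member of the combination (alphabetical tie-break)."""
        names = sorted(combination)
        if not names:
            raise ValueError("empty landmark combination")
        top = self.combination_rank(names)
        return self.get(min(n for n in names if self.rank(n) == top))

    def sort_combination(self, combination: Iterable[str]) -> list[str]:
        """Canonical order: by depth rank, alphabetical tie-break."""
        return sorted(combination, key=lambda n: (self.rank(n), n))

    @classmethod
    def from_json(cls, path: str | Path) -> "SpatialOntology":
        entries = json.loads(Path(path).read_text())
        return cls(
            Landmark(e["name"], int(e["depth_rank"]), e["group"], e["cavity"])
            for e in entries
        )

    def to_json(self, path: str | Path) -> None:
        entries = [
            {
                "name": lm.name,
                "depth_rank": lm.depth_rank,
                "group": lm.group,
                "cavity": lm.cavity,
            }
            for lm in self
        ]
        Path(path).write_text(json.dumps(entries, indent=1))


def default_ontology() -> SpatialOntology:
    """The shipped seven-landmark FESS ontology."""
    return SpatialOntology(Landmark(*row) for row in _DEFAULT_TABLE)


@dataclass
class NavigationState:
    """One timed endoscope state within a navigation workflow."""

    step_count: int
    cavity: str
    landmark_group: str
    landmark_combination: frozenset[str]
    direction: Direction
    start_s: float = 0.0
    end_s: float = 0.0

    def __post_init__(self) -> None:
        self.landmark_combination = frozenset(self.landmark_combination)
        if isinstance(self.direction, str):
            self.direction = Direction(self.direction)

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def infer_direction(
    prev: Iterable[str] | None,
    curr: Iterable[str],
    ontology: SpatialOntology,
) -> Direction:
    """Direction of movement between two landmark combinations.

    ``inwards`` if the current combination's representative rank exceeds the
    previous one's, ``outwards`` if it is smaller, ``dwell`` if equal or if
    there is no previous state.
    """
    curr_rank = ontology.combination_rank(curr)
    if prev is None:
        return Direction.DWELL
    prev_rank = ontology.combination_rank(prev)
    if curr_rank > prev_rank:
        return Direction.INWARDS
    if curr_rank < prev_rank:
        return Direction.OUTWARDS
    return Direction.DWELL


def validate_workflow(
    states: Sequence[NavigationState], ontology: SpatialOntology
) -> list[str]:
    """Check structural invariants of a workflow; return violation messages.

    Violations are returned rather than raised so a whole workflow can be
    audited in one pass.  An empty list means the workflow is well formed:
    step counts run 1..n, combinations have 1-3 known landmarks, times are
    consistent, and cavity/group match the ontology entry of the
    combination's representative landmark.
    """
    violations: list[str] = []
    for i, st in enumerate(states):
        where = f"state {i}"
        if st.step_count != i + 1:
            violations.append(
                f"{where}: gap - step_count {st.step_count}, expected {i + 1}"
            )
        k = len(st.landmark_combination)
        if not 1 <= k <= 3:
            violations.append(f"{where}: size - combination of size {k}")
        unknown = [n for n in st.landmark_combination if n not in ontology]
        if unknown:
            violations.append(f"{where}: unknown landmarks {sorted(unknown)}")
            continue
        if st.end_s < st.start_s:
            violations.append(f"{where}: time - end_s < start_s")
        rep = ontology.representative(st.landmark_combination)
        if st.cavity != rep.cavity:
            violations.append(
                f"{where}: cavity {st.cavity!r} != ontology {rep.cavity!r}"
            )
        if st.landmark_group != rep.group:
            violations.append(
                f"{where}: group {st.landmark_group!r} != ontology {rep.group!r}"
            )
    for a, b in zip(states, states[1:]):
        if b.start_s < a.start_s:
            violations.append("times not non-decreasing")
            break
    return violations
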