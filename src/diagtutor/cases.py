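"""Authored clinical-case content: factors, reference actions, the I/D/N grid.

A case is written by a human tutor as a JSON document and holds everything the
engine grades against: the opening scenario, the reference anamnestic
questions with answers, the reference physical exams and medical tests with
findings, the reference diagnostic hypotheses (ontology concept ids), the
binary-analysis reference grid (does each factor Increase, Decrease, or Not
affect each hypothesis), the final diagnosis, and optional per-hypothesis
review links shown in the end-of-simulation summary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

__all__ = [
    "MODALITIES",
    "GRID_LABELS",
    "CASE_SCHEMA",
    "DiagnosticFactor",
    "ReferenceQuestion",
    "ReferenceProcedure",
    "BinaryGrid",
    "PatternLink",
    "ClinicalCase",
    "CaseValidationError",
    "load_case",
]

MODALITIES = frozenset({"scenario", "anamnesis", "physical_exam", "medical_test"})
GRID_LABELS = frozenset({"I", "D", "N"})

#: Informal schema of the case JSON (shipped for authors; validation is
#: performed field by field in :func:`load_case` with errors naming the field).
CASE_SCHEMA: dict = {
    "scenario": "str",
    "factors": [{"id": "str", "name": "str", "value": "str", "modality": sorted(MODALITIES)}],
    "questions": [{"id": "str", "text": "str", "answer": "str", "factors": ["factor id"]}],
    "exams": [{"id": "str", "names": ["str"], "finding": "str", "factors": ["factor id"]}],
    "tests": [{"id": "str", "names": ["str"], "finding": "str", "factors": ["factor id"]}],
    "hypotheses": ["concept id"],
    "grid": [{"factor": "factor id", "hypothesis": "concept id", "label": sorted(GRID_LABELS)}],
    "final_diagnosis": "concept id",
    "review_links": {"concept id": "url"},
}


class CaseValidationError(ValueError):
    """Raised when a case file violates the schema; names the offending field."""


@dataclass(frozen=True)
class DiagnosticFactor:
    id: str
    name: str
    value: str
    modality: str

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise CaseValidationError(
                f"factor {self.id!r}: modality {self.modality!r} not in {sorted(MODALITIES)}"
            )


@dataclass(frozen=True)
class ReferenceQuestion:
    id: str
    text: str
    answer: str
    factors: tuple[str, ...]


@dataclass(frozen=True)
class ReferenceProcedure:
    """A reference physical exam or medical test with its finding."""

    id: str
    names: tuple[str, ...]  # display name first, synonyms after
    finding: str
    factors: tuple[str, ...]


@dataclass
class BinaryGrid:
    """(factor id, hypothesis id) -> label in {I, D, N}; None means unset."""

    entries: dict[tuple[str, str], str | None] = field(default_factory=dict)

    def set(self, factor: str, hypothesis: str, label: str) -> None:
        key = (factor, hypothesis)
        if key not in self.entries:
            raise KeyError(f"cell {key} not in grid")
        if label not in GRID_LABELS:
            raise ValueError(f"label {label!r} not in {sorted(GRID_LABELS)}")
        self.entries[key] = label

    def unset_cells(self) -> list[tuple[str, str]]:
        return sorted(k for k, v in self.entries.items() if v is None)

    def cells_for_hypothesis(self, hypothesis: str) -> int:
        return sum(1 for (_, h) in self.entries if h == hypothesis)


@dataclass(frozen=True)
class PatternLink:
    """A signed, weighted factor -> hypothesis link of the pattern analysis."""

    factor_id: str
    hypothesis_id: str
    sign: str  # positive | negative | none
    weight: str = "low"  # low | high; ignored when sign == "none"

    def __post_init__(self) -> None:
        if self.sign not in ("positive", "negative", "none"):
            raise ValueError(f"sign {self.sign!r} invalid")
        if self.weight not in ("low", "high"):
            raise ValueError(f"weight {self.weight!r} invalid")


@dataclass(frozen=True)
class ClinicalCase:
    scenario: str
    factors: dict[str, DiagnosticFactor]
    questions: tuple[ReferenceQuestion, ...]
    exams: tuple[ReferenceProcedure, ...]
    tests: tuple[ReferenceProcedure, ...]
    hypotheses: tuple[str, ...]
    grid: Mapping[tuple[str, str], str]
    final_diagnosis: str
    review_links: Mapping[str, str]

    def scenario_factors(self) -> list[str]:
        """Factors visible up front from the patient's record (the scenario)."""
        return [f.id for f in self.factors.values() if f.modality == "scenario"]


def _require(data: Mapping, key: str, kind: type, where: str = "case"):
    if key not in data:
        raise CaseValidationError(f"{where}: missing required field {key!r}")
    value = data[key]
    if not isinstance(value, kind):
        raise CaseValidationError(
            f"{where}: field {key!r} must be {kind.__name__}, got {type(value).__name__}"
        )
    return value


def load_case(source: str | Path | Mapping) -> ClinicalCase:
    """Load and validate a clinical case from a JSON file, string, or mapping.

    Raises :class:`CaseValidationError` naming the offending field when the
    schema or a cross-reference invariant is violated: every revealed factor
    must exist, the grid must cover exactly the factor x hypothesis cross
    product, and the final diagnosis must be one of the reference hypotheses.
    """
    if isinstance(source, Mapping):
        data = source
    else:
        text = Path(source).read_text(encoding="utf-8") if Path(str(source)).exists() else str(source)
        data = json.loads(text)
    if not isinstance(data, Mapping):
        raise CaseValidationError("case: top level must be a JSON object")

    scenario = _require(data, "scenario", str)

    factors: dict[str, DiagnosticFactor] = {}
    for i, raw in enumerate(_require(data, "factors", list)):
        where = f"factors[{i}]"
        f = DiagnosticFactor(
            _require(raw, "id", str, where),
            _require(raw, "name", str, where),
            _require(raw, "value", str, where),
            _require(raw, "modality", str, where),
        )
        if f.id in factors:
            raise CaseValidationError(f"{where}: duplicate factor id {f.id!r}")
        factors[f.id] = f

    def _check_factors(ids, where):
        for fid in ids:
            if fid not in factors:
                raise CaseValidationError(f"{where}: unknown factor id {fid!r}")

    questions = []
    for i, raw in enumerate(data.get("questions", [])):
        where = f"questions[{i}]"
        q = ReferenceQuestion(
            _require(raw, "id", str, where),
            _require(raw, "text", str, where),
            _require(raw, "answer", str, where),
            tuple(_require(raw, "factors", list, where)),
        )
        _check_factors(q.factors, where)
        questions.append(q)

    def _procedures(key):
        out = []
        for i, raw in enumerate(data.get(key, [])):
            where = f"{key}[{i}]"
            names = tuple(_require(raw, "names", list, where))
            if not names:
                raise CaseValidationError(f"{where}: names list is empty")
            p = ReferenceProcedure(
                _require(raw, "id", str, where),
                names,
                _require(raw, "finding", str, where),
                tuple(_require(raw, "factors", list, where)),
            )
            _check_factors(p.factors, where)
            out.append(p)
        return tuple(out)

    exams = _procedures("exams")
    tests = _procedures("tests")

    hypotheses = tuple(_require(data, "hypotheses", list))
    if not hypotheses:
        raise CaseValidationError("hypotheses: must list at least one reference hypothesis")

    grid: dict[tuple[str, str], str] = {}
    for i, raw in enumerate(_require(data, "grid", list)):
        where = f"grid[{i}]"
        fid = _require(raw, "factor", str, where)
        hid = _require(raw, "hypothesis", str, where)
        label = _require(raw, "label", str, where)
        if fid not in factors:
            raise CaseValidationError(f"{where}: unknown factor id {fid!r}")
        if hid not in hypotheses:
            raise CaseValidationError(f"{where}: unknown hypothesis id {hid!r}")
        if label not in GRID_LABELS:
            raise CaseValidationError(f"{where}: label {label!r} not in {sorted(GRID_LABELS)}")
        if (fid, hid) in grid:
            raise CaseValidationError(f"{where}: duplicate grid cell ({fid!r}, {hid!r})")
        grid[(fid, hid)] = label
    expected = {(f, h) for f in factors for h in hypotheses}
    missing = sorted(expected - set(grid))
    if missing:
        raise CaseValidationError(f"grid: missing cells {missing}")

    final = _require(data, "final_diagnosis", str)
    if final not in hypotheses:
        raise CaseValidationError(
            f"final_diagnosis: {final!r} is not among the reference hypotheses"
        )

    review_links = dict(data.get("review_links", {}))
    for hid in review_links:
        if hid not in hypotheses:
            raise CaseValidationError(f"review_links: unknown hypothesis id {hid!r}")

    return ClinicalCase(
        scenario=scenario,
        factors=factors,
        questions=tuple(questions),
        exams=exams,
        tests=tests,
        hypotheses=hypotheses,
        grid=grid,
        final_diagnosis=final,
        review_links=review_links,
    )
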