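"""The clinical-case simulation engine.

A :class:`Session` walks a student through one simulated encounter: data
gathering (reading the scenario, history taking in free text, physical exams
and medical-test requests) and data analysis (building a differential
diagnosis, filling the binary I/D/N grid, weighting pattern-analysis links,
and selecting the final diagnosis).  Navigation is free: every data-gathering
action stays available after analysis actions until the session is closed by
a final-diagnosis choice.

Free-text inputs are resolved by two different matchers.  Anamnestic
questions go through the Siamese recurrent matcher (sentence semantics
matter); exam and test requests are short noun phrases and are resolved by
Jaccard token overlap against the reference names and synonyms, exactly like
ontology concept matching.

Every operation appends exactly one timestamped entry to the action log
(timestamps come from an injectable clock so runs are reproducible), and
:func:`replay_log` re-executes a recorded log against a fresh session,
reproducing the identical end state and feedback stream.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import asdict
from pathlib import Path
from typing import Callable

from . import ontology as onto
from .cases import BinaryGrid, ClinicalCase, PatternLink
from .siamese import rank_questions
from .tutoring import Feedback, inner_feedback

__all__ = ["Session", "replay_log", "write_log", "read_log"]

_WEIGHT_VALUE = {"low": 1, "high": 2}


def _utc_now() -> str:
    return _dt.datetime.now(_dt.timezone.utc).isoformat()


class SessionFinishedError(RuntimeError):
    """Raised when an action is attempted on a closed session."""


class Session:
    """Mutable state of one student's run through a clinical case."""

    def __init__(
        self,
        case: ClinicalCase,
        ontology: onto.Ontology,
        matcher=None,
        question_threshold: float = 0.5,
        procedure_min_sim: float = 0.2,
        hypothesis_min_sim: float = 0.2,
        clock: Callable[[], str] = _utc_now,
        stopwords: frozenset[str] | None = None,
    ):
        self.case = case
        self.ontology = ontology
        self.matcher = matcher
        self.question_threshold = question_threshold
        self.procedure_min_sim = procedure_min_sim
        self.hypothesis_min_sim = hypothesis_min_sim
        self.clock = clock
        self.stopwords = stopwords if stopwords is not None else onto.default_stopwords()

        self.gathered_factors: list[str] = list(case.scenario_factors())
        self.differential: list[str] = []
        self.binary_grid: BinaryGrid | None = None
        self.pattern_links: list[PatternLink] = []
        self.action_log: list[dict] = []
        self.finished: bool = False
        self.final_choice: str | None = None
        self.last_mistake_counts: dict[str, int] | None = None
        self.feedback_stream: list[Feedback] = []

    # ------------------------------------------------------------- helpers

    def _guard(self) -> None:
        if self.finished:
            raise SessionFinishedError("the simulation has ended")

    def _gather(self, factor_ids) -> list[str]:
        new = []
        for fid in factor_ids:
            if fid not in self.gathered_factors:
                self.gathered_factors.append(fid)
                new.append(fid)
        return new

    def _log(self, action: str, input_text, outcome, feedback: Feedback | None) -> None:
        self.action_log.append(
            {
                "timestamp": self.clock(),
                "action": action,
                "input": input_text,
                "outcome": outcome,
                "feedback": None if feedback is None else feedback.code,
            }
        )
        if feedback is not None:
            self.feedback_stream.append(feedback)

    # ------------------------------------------------------ data gathering

    def ask_history(self, question: str):
        """Match a free-text anamnestic question to reference questions.

        Returns ``(matches, revealed_factor_ids, feedback)`` where matches is
        a list of ``(reference id, reference text, answer)`` (at most three).
        Unmatched questions get "not understood" feedback; either way the
        action is logged.  Re-asking a matched question returns its answer
        again but reveals nothing new (gathered factors are a set).
        """
        self._guard()
        if self.matcher is None:
            raise RuntimeError("no question matcher configured for this session")
        refs = [(q.id, q.text) for q in self.case.questions]
        ranked = rank_questions(
            self.matcher, question, refs, threshold=self.question_threshold
        )
        by_id = {q.id: q for q in self.case.questions}
        matches = [
            (m.reference_question_id, by_id[m.reference_question_id].text,
             by_id[m.reference_question_id].answer)
            for m in ranked
        ]
        revealed: list[str] = []
        for m in ranked:
            revealed += self._gather(by_id[m.reference_question_id].factors)
        if matches:
            fb = inner_feedback("matched_question")
            outcome = {"matched": [m.reference_question_id for m in ranked]}
        else:
            fb = inner_feedback("unmatched_question")
            outcome = {"matched": []}
        self._log("ask_history", question, outcome, fb)
        return matches, revealed, fb

    def request_exam_or_test(self, request: str):
        """Resolve a physical-exam or medical-test request by token overlap.

        Returns ``(finding or None, feedback)``.  A request matching no
        reference procedure earns inner-loop "inappropriate exam" feedback.
        """
        self._guard()
        if not request or not request.strip():
            raise ValueError("empty request; prompt the student for input")
        query = onto.normalize_tokens(request, self.stopwords)
        best: tuple[float, str] | None = None  # (sim, procedure id)
        procedures = {p.id: p for p in (*self.case.exams, *self.case.tests)}
        for pid in sorted(procedures):
            proc = procedures[pid]
            sim = max(
                onto.jaccard(query, onto.normalize_tokens(name, self.stopwords))
                for name in proc.names
            )
            if best is None or sim > best[0]:
                best = (sim, pid)
        if best is None or best[0] < self.procedure_min_sim:
            fb = inner_feedback("unmatched_exam", request=request)
            self._log("request_exam_or_test", request, {"matched": None}, fb)
            return None, fb
        proc = procedures[best[1]]
        self._gather(proc.factors)
        fb = inner_feedback("matched_exam")
        self._log("request_exam_or_test", request, {"matched": proc.id}, fb)
        return proc.finding, fb

    # -------------------------------------------------------- data analysis

    def propose_hypothesis(self, text: str):
        """Grade a free-text diagnostic hypothesis and update the differential.

        Correct hypotheses (ontology distance 0 to a reference) enter the
        differential.  Close hypotheses that are ancestors of the nearest
        reference get "be more specific" feedback; other close ones get a hint
        toward the closest reference.  Distant or unrecognized texts are
        rejected.  Returns ``(MatchResult, feedback)``.
        """
        self._guard()
        result = onto.classify_hypothesis(
            text,
            list(self.case.hypotheses),
            self.ontology,
            min_sim=self.hypothesis_min_sim,
            stopwords=self.stopwords,
        )
        if result.verdict == "correct":
            if result.matched_concept_id not in self.differential:
                self.differential.append(result.matched_concept_id)
            fb = inner_feedback("hypothesis_correct", matched=result.matched_concept_id)
        elif result.verdict == "close":
            if onto.is_ancestor(
                self.ontology, result.matched_concept_id, result.nearest_reference_id
            ):
                fb = inner_feedback(
                    "hypothesis_too_general",
                    matched=result.matched_concept_id,
                    nearest=result.nearest_reference_id,
                )
            else:
                fb = inner_feedback(
                    "hypothesis_close",
                    matched=result.matched_concept_id,
                    nearest=result.nearest_reference_id,
                )
        elif result.verdict == "incorrect":
            fb = inner_feedback("hypothesis_rejected", matched=result.matched_concept_id)
        else:
            fb = inner_feedback("unrecognized_hypothesis")
        self._log(
            "propose_hypothesis",
            text,
            {"verdict": result.verdict, "matched": result.matched_concept_id},
            fb,
        )
        return result, fb

    def build_binary_grid(self) -> BinaryGrid:
        """Empty I/D/N grid over gathered factors x differential hypotheses."""
        if not self.differential:
            raise ValueError(
                "differential diagnosis is empty; propose hypotheses before "
                "the binary analysis"
            )
        if not self.gathered_factors:
            raise ValueError("no diagnostic factors gathered yet")
        grid = BinaryGrid(
            {
                (f, h): None
                for f in self.gathered_factors
                for h in self.differential
            }
        )
        self.binary_grid = grid
        return grid

    def submit_binary_grid(self, grid: BinaryGrid):
        """Grade a fully filled grid cell by cell against the reference grid.

        Returns ``(cell_results, mistake_counts)``: per-cell dicts with the
        given and correct labels (wrong cells carry wrong_binary_cell
        feedback with the correct relationship in the payload), and the
        per-hypothesis mistake tally kept for the learner model.
        """
        self._guard()
        unset = grid.unset_cells()
        if unset:
            raise ValueError(f"grid has unfilled cells: {unset}")
        cell_results = []
        mistakes: dict[str, int] = {h: 0 for _, h in grid.entries}
        for (fid, hid), label in sorted(grid.entries.items()):
            correct = self.case.grid[(fid, hid)]
            ok = label == correct
            if not ok:
                mistakes[hid] += 1
                fb = inner_feedback(
                    "wrong_binary_cell",
                    factor=fid,
                    hypothesis=hid,
                    correct_label=correct,
                    given_label=label,
                )
                self.feedback_stream.append(fb)
            cell_results.append(
                {
                    "factor": fid,
                    "hypothesis": hid,
                    "given": label,
                    "correct": correct,
                    "ok": ok,
                }
            )
        self.binary_grid = grid
        self.last_mistake_counts = mistakes
        total = sum(mistakes.values())
        fb = inner_feedback("grid_submitted", total_mistakes=total)
        self._log(
            "submit_binary_grid",
            {f"{f}|{h}": v for (f, h), v in sorted(grid.entries.items())},
            {"mistakes": dict(sorted(mistakes.items()))},
            fb,
        )
        return cell_results, mistakes

    def submit_pattern_links(self, links: list[PatternLink]):
        """Check pattern links against the student's own binary grid and score.

        A link's sign must agree with the student's I/D/N choice for that cell
        (I - positive, D - negative, N - none); disagreements are reported as
        inconsistencies.  Each hypothesis also gets a display score in [0, 1]
        for rendering its node: the signed weight sum (high=2, low=1)
        rescaled so all-positive evidence maps to 1, all-negative to 0, and
        no weighted links to 0.5.
        """
        self._guard()
        if self.binary_grid is None or self.binary_grid.unset_cells():
            raise ValueError("submit a completed binary grid before pattern analysis")
        sign_for = {"I": "positive", "D": "negative", "N": "none"}
        inconsistencies = []
        signed: dict[str, float] = {h: 0.0 for h in self.differential}
        weight_total: dict[str, float] = {h: 0.0 for h in self.differential}
        for link in links:
            if link.factor_id not in self.gathered_factors:
                raise ValueError(
                    f"link references ungathered factor {link.factor_id!r}"
                )
            if link.hypothesis_id not in self.differential:
                raise ValueError(
                    f"link references hypothesis {link.hypothesis_id!r} not in "
                    f"the differential"
                )
            cell = self.binary_grid.entries.get((link.factor_id, link.hypothesis_id))
            expected = sign_for[cell]
            if link.sign != expected:
                inconsistencies.append(
                    {
                        "factor": link.factor_id,
                        "hypothesis": link.hypothesis_id,
                        "link_sign": link.sign,
                        "grid_label": cell,
                    }
                )
            if link.sign != "none":
                w = _WEIGHT_VALUE[link.weight]
                weight_total[link.hypothesis_id] += w
                signed[link.hypothesis_id] += w if link.sign == "positive" else -w
        scores = {
            h: 0.5 if weight_total[h] == 0 else (signed[h] + weight_total[h]) / (2 * weight_total[h])
            for h in self.differential
        }
        self.pattern_links = list(links)
        fb = inner_feedback("links_submitted", inconsistencies=len(inconsistencies))
        self._log(
            "submit_pattern_links",
            [asdict(l) for l in links],
            {"inconsistencies": inconsistencies, "scores": dict(sorted(scores.items()))},
            fb,
        )
        return inconsistencies, scores

    def select_final_diagnosis(self, hypothesis_id: str):
        """Close the simulation with a final-diagnosis choice from the
        differential; returns ``("correct"|"incorrect", feedback)``."""
        self._guard()
        if hypothesis_id not in self.differential:
            raise ValueError(
                f"{hypothesis_id!r} is not in the differential diagnosis"
            )
        outcome = (
            "correct" if hypothesis_id == self.case.final_diagnosis else "incorrect"
        )
        self.finished = True
        self.final_choice = hypothesis_id
        fb = inner_feedback("final_correct" if outcome == "correct" else "final_incorrect")
        self._log("select_final_diagnosis", hypothesis_id, {"result": outcome}, fb)
        return outcome, fb

    # ------------------------------------------------------------ snapshot

    def snapshot(self) -> dict:
        """JSON-serializable summary of the session end state (used by the
        replay-determinism check and by learner analytics)."""
        return {
            "gathered_factors": list(self.gathered_factors),
            "differential": list(self.differential),
            "binary_grid": None
            if self.binary_grid is None
            else {f"{f}|{h}": v for (f, h), v in sorted(self.binary_grid.entries.items())},
            "pattern_links": [asdict(l) for l in self.pattern_links],
            "finished": self.finished,
            "final_choice": self.final_choice,
            "mistake_counts": self.last_mistake_counts,
            "feedback_codes": [f.code for f in self.feedback_stream],
        }


# ------------------------------------------------------------------ replay

def write_log(session: Session, path: str | Path) -> None:
    """Write the action log as JSON-lines, one action per line."""
    lines = [json.dumps(entry, sort_keys=True) for entry in session.action_log]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_log(path: str | Path) -> list[dict]:
    return [
        json.loads(line)
        for line in Path(path).read_text(encoding="utf-8").splitlines()
        if line.strip()
    ]


def replay_log(
    log: list[dict],
    case: ClinicalCase,
    ontology: onto.Ontology,
    matcher=None,
    **session_kwargs,
) -> Session:
    """Re-execute a recorded action log against a fresh session.

    With the same case, ontology and matcher the engine is deterministic, so
    the replayed session reproduces the original end state and feedback
    stream.  Recorded timestamps are replayed through the clock, making the
    logs byte-identical too.
    """
    stamps = iter(entry["timestamp"] for entry in log)
    session = Session(
        case, ontology, matcher=matcher, clock=lambda: next(stamps), **session_kwargs
    )
    for entry in log:
        action, payload = entry["action"], entry["input"]
        if action == "ask_history":
            session.ask_history(payload)
        elif action == "request_exam_or_test":
            session.request_exam_or_test(payload)
        elif action == "propose_hypothesis":
            session.propose_hypothesis(payload)
        elif action == "submit_binary_grid":
            grid = BinaryGrid(
                {tuple(k.split("|")): v for k, v in payload.items()}
            )
            session.submit_binary_grid(grid)
        elif action == "submit_pattern_links":
            links = [PatternLink(**d) for d in payload]
            session.submit_pattern_links(links)
        elif action == "select_final_diagnosis":
            session.select_final_diagnosis(payload)
        else:
            raise ValueError(f"unknown logged action {action!r}")
    return session
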