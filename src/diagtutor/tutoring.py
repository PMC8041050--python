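"""Intelligent-tutoring layer: step feedback, end-of-case summary, and the
Bayesian Knowledge Tracing (BKT) learner model.

The tutor runs two loops.  The *inner loop* reacts to every single student
action with a feedback message drawn from a closed catalog (inappropriate
exam requested, hypothesis too general, wrong binary-analysis cell with the
correct relationship attached, ...).  The *outer loop* fires when a
simulation ends: it summarizes the diagnostic hypotheses on which the student
made the most binary-analysis mistakes and attaches a review link per topic.

The learner model is classic BKT: for each skill (here, the clinical
understanding of one diagnostic hypothesis) a two-state hidden Markov model
with states {unknown, known}, prior mastery p_L0, learning probability p_T
(unknown -> known after an opportunity; no forgetting), slip probability p_S
(wrong answer while known) and guess probability p_G (right answer while
unknown).  Observations are the binary per-hypothesis outcomes of the binary
analysis across simulations.  Parameters are fit by expectation-maximization
with seeded random restarts, keeping the best fit satisfying the
identifiability guard p_S + p_G < 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "FEEDBACK_CATALOG",
    "Feedback",
    "inner_feedback",
    "outer_summary",
    "binary_observation",
    "BKTParams",
    "bkt_update",
    "bkt_sequence_likelihood",
    "bkt_fit",
    "LearnerState",
    "mastery_report",
]

# ---------------------------------------------------------------- feedback

#: category -> (code, message template).  Every engine outcome category maps
#: to exactly one catalog code; unknown categories are a programming error.
FEEDBACK_CATALOG: dict[str, tuple[str, str]] = {
    "unmatched_exam": (
        "inappropriate_exam",
        "An inappropriate exam or test was asked for: {request!r} is not part "
        "of this clinical case.",
    ),
    "hypothesis_too_general": (
        "be_more_specific",
        "Your hypothesis {matched!r} is too general; be more specific.",
    ),
    "hypothesis_close": (
        "close_hypothesis_hint",
        "Your hypothesis {matched!r} is close to, but not exactly, one of the "
        "expected diagnoses; reconsider in that direction.",
    ),
    "hypothesis_rejected": (
        "hypothesis_rejected",
        "The hypothesis {matched!r} is not compatible with this clinical "
        "picture and was not added to the differential.",
    ),
    "unmatched_question": (
        "not_understood",
        "The question was not understood; please rephrase it.",
    ),
    "unrecognized_hypothesis": (
        "not_understood",
        "The hypothesis text was not recognized; please rephrase it.",
    ),
    "wrong_binary_cell": (
        "wrong_binary_cell",
        "Incorrect: the factor {factor!r} relationship with {hypothesis!r} "
        "is {correct_label!r}, not {given_label!r}.",
    ),
    "matched_question": ("correct_action", "Question understood and answered."),
    "matched_exam": ("correct_action", "Exam/test performed: finding revealed."),
    "hypothesis_correct": (
        "correct_action",
        "Hypothesis {matched!r} added to the differential diagnosis.",
    ),
    "grid_submitted": (
        "correct_action",
        "Binary analysis graded: {total_mistakes} mistaken cell(s).",
    ),
    "links_submitted": (
        "correct_action",
        "Pattern analysis recorded ({inconsistencies} inconsistency/ies).",
    ),
    "final_correct": ("correct_action", "Correct final diagnosis. Simulation complete."),
    "final_incorrect": (
        "review_topics",
        "That was not the correct final diagnosis; review the suggested topics.",
    ),
    "session_summary": (
        "review_topics",
        "Review the topics where you made the most binary-analysis mistakes.",
    ),
}


@dataclass(frozen=True)
class Feedback:
    """One tutoring message: catalog code, rendered text, structured payload."""

    code: str
    message: str
    payload: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.message:
            raise ValueError("feedback message must be non-empty")


def inner_feedback(category: str, **payload) -> Feedback:
    """Deterministic mapping from an engine outcome category to feedback."""
    try:
        code, template = FEEDBACK_CATALOG[category]
    except KeyError:
        raise ValueError(
            f"unknown outcome category {category!r}; the feedback catalog must "
            f"cover every engine outcome"
        ) from None
    return Feedback(code, template.format(**payload), dict(payload))


def outer_summary(session) -> list[tuple[str, int, str | None]]:
    """End-of-simulation mistake summary, worst hypothesis first.

    Returns (hypothesis id, binary-analysis mistake count, review link)
    sorted by descending mistakes, ties by smallest id.  If no binary grid
    was ever submitted the summary is empty (the caller shows a notice).
    """
    if not session.finished:
        raise ValueError("outer-loop summary requires a finished session")
    counts = session.last_mistake_counts
    if counts is None:
        return []
    links = session.case.review_links
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(hid, n, links.get(hid)) for hid, n in ordered]


# ------------------------------------------------------- BKT observation

def binary_observation(
    mistakes: int, cells: int, success_fraction: float = 0.8
) -> int:
    """Discretize one hypothesis's binary-analysis performance to 0/1.

    The outcome counts as correct (1) when the fraction of correctly filled
    cells, 1 - mistakes/cells, reaches ``success_fraction``.
    """
    if cells < 1:
        raise ValueError("cells per hypothesis must be >= 1")
    if not 0 <= mistakes <= cells:
        raise ValueError("mistakes must lie in [0, cells]")
    return int((1.0 - mistakes / cells) >= success_fraction)


# ----------------------------------------------------------------- model

@dataclass(frozen=True)
class BKTParams:
    """BKT parameters: prior mastery, learning, slip, guess — all in [0, 1]."""

    p_L0: float
    p_T: float
    p_S: float
    p_G: float

    def __post_init__(self) -> None:
        for name in ("p_L0", "p_T", "p_S", "p_G"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


def bkt_update(params: BKTParams, p: float, observation: int) -> float:
    """One BKT step: condition mastery on an observation, then apply learning.

    For a correct observation the evidence step is
    ``p* = p(1-p_S) / (p(1-p_S) + (1-p) p_G)`` (complementary form for an
    incorrect one), followed by ``p' = p* + (1-p*) p_T``.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"prior mastery {p} outside [0, 1]")
    if observation not in (0, 1):
        raise ValueError("observation must be 0 or 1")
    if observation:
        num = p * (1.0 - params.p_S)
        den = num + (1.0 - p) * params.p_G
    else:
        num = p * params.p_S
        den = num + (1.0 - p) * (1.0 - params.p_G)
    if den == 0.0:
        raise ValueError(
            "observation has probability zero under the model "
            "(impossible evidence); check slip/guess parameters"
        )
    cond = num / den
    return cond + (1.0 - cond) * params.p_T


def bkt_sequence_likelihood(params: BKTParams, observations) -> float:
    """Forward-algorithm likelihood of a binary observation sequence.

    The hidden chain starts known with probability p_L0, moves unknown ->
    known with probability p_T, and never forgets.  Equals the sum over all
    2^T hidden-state paths.
    """
    obs = list(observations)
    if not obs:
        raise ValueError("observation sequence must have length >= 1")
    if any(o not in (0, 1) for o in obs):
        raise ValueError("observations must be binary (0/1)")
    # states: 0 = unknown, 1 = known
    alpha = np.array([1.0 - params.p_L0, params.p_L0])
    trans = np.array([[1.0 - params.p_T, params.p_T], [0.0, 1.0]])
    for t, o in enumerate(obs):
        emit = (
            np.array([params.p_G, 1.0 - params.p_S])
            if o
            else np.array([1.0 - params.p_G, params.p_S])
        )
        alpha = alpha * emit
        if t < len(obs) - 1:
            alpha = alpha @ trans
    return float(alpha.sum())


def _estep(seqs: np.ndarray, params: BKTParams):
    """Scaled forward-backward over equal-length sequences.

    Returns the total log-likelihood and the expected sufficient statistics
    (gamma0_known, n_sequences, xi_unknown_to_known, xi_unknown_to_unknown,
    known_and_wrong, known_total, unknown_and_right, unknown_total).
    """
    n, T = seqs.shape
    L0, pT, pS, pG = params.p_L0, params.p_T, params.p_S, params.p_G
    e_unknown = np.where(seqs == 1, pG, 1.0 - pG)  # (n, T)
    e_known = np.where(seqs == 1, 1.0 - pS, pS)
    alpha = np.zeros((n, T, 2))
    scale = np.zeros((n, T))
    a = np.stack([(1.0 - L0) * e_unknown[:, 0], L0 * e_known[:, 0]], axis=1)
    scale[:, 0] = a.sum(axis=1)
    alpha[:, 0] = a / scale[:, 0, None]
    for t in range(1, T):
        prev = alpha[:, t - 1]
        pred_unknown = prev[:, 0] * (1.0 - pT)
        pred_known = prev[:, 0] * pT + prev[:, 1]
        a = np.stack(
            [pred_unknown * e_unknown[:, t], pred_known * e_known[:, t]], axis=1
        )
        scale[:, t] = a.sum(axis=1)
        alpha[:, t] = a / scale[:, t, None]
    ll = float(np.log(scale).sum())
    beta = np.zeros((n, T, 2))
    beta[:, T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        bu = beta[:, t + 1, 0] * e_unknown[:, t + 1]
        bk = beta[:, t + 1, 1] * e_known[:, t + 1]
        beta[:, t, 0] = ((1.0 - pT) * bu + pT * bk) / scale[:, t + 1]
        beta[:, t, 1] = bk / scale[:, t + 1]
    gamma = alpha * beta
    gamma = gamma / gamma.sum(axis=2, keepdims=True)
    xi_uk = 0.0
    xi_uu = 0.0
    for t in range(T - 1):
        denom = scale[:, t + 1]
        xi_uk += float(
            (alpha[:, t, 0] * pT * e_known[:, t + 1] * beta[:, t + 1, 1] / denom).sum()
        )
        xi_uu += float(
            (
                alpha[:, t, 0]
                * (1.0 - pT)
                * e_unknown[:, t + 1]
                * beta[:, t + 1, 0]
                / denom
            ).sum()
        )
    g_known = gamma[:, :, 1]
    g_unknown = gamma[:, :, 0]
    stats = np.array(
        [
            float(gamma[:, 0, 1].sum()),
            float(n),
            xi_uk,
            xi_uu,
            float((g_known * (seqs == 0)).sum()),
            float(g_known.sum()),
            float((g_unknown * (seqs == 1)).sum()),
            float(g_unknown.sum()),
        ]
    )
    return ll, stats


def _mstep(stats: np.ndarray, fallback: BKTParams) -> BKTParams:
    eps = 1e-6
    g0, n, uk, uu, kw, kt, ur, ut = stats
    L0 = g0 / n
    pT = uk / (uk + uu) if (uk + uu) > 0 else fallback.p_T
    pS = kw / kt if kt > 0 else fallback.p_S
    pG = ur / ut if ut > 0 else fallback.p_G
    clip = lambda x: float(np.clip(x, eps, 1 - eps))
    return BKTParams(clip(L0), clip(pT), clip(pS), clip(pG))


def _em_fit(groups: list[np.ndarray], init: BKTParams, max_iter: int, tol: float):
    """EM over one or more equal-length sequence groups sharing parameters."""
    params = init
    trace: list[float] = []
    for _ in range(max_iter):
        ll = 0.0
        stats = np.zeros(8)
        for arr in groups:
            g_ll, g_stats = _estep(arr, params)
            ll += g_ll
            stats += g_stats
        trace.append(ll)
        params = _mstep(stats, params)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            break
    return params, trace


def bkt_fit(
    sequences,
    seed: int = 0,
    n_restarts: int = 5,
    max_iter: int = 200,
    tol: float = 1e-6,
    return_trace: bool = False,
):
    """Fit BKT parameters to binary observation sequences by EM.

    Runs ``n_restarts`` seeded random initializations and keeps the best
    log-likelihood among fits satisfying the identifiability guard
    p_S + p_G < 1 (fits violating it are the label-switched degenerate mode
    and are discarded).  Requires at least two sequences with both outcomes
    present somewhere in the data.
    """
    seqs = [np.asarray(s, dtype=int) for s in sequences]
    if len(seqs) < 2:
        raise ValueError("need at least 2 observation sequences")
    flat = np.concatenate(seqs)
    if flat.min() == flat.max():
        raise ValueError(
            "all observations identical; BKT parameters are not identifiable"
        )
    lengths = {len(s) for s in seqs}
    rng = np.random.default_rng(seed)
    best: tuple[float, BKTParams, list[float]] | None = None
    for _ in range(n_restarts):
        init = BKTParams(
            p_L0=float(rng.uniform(0.05, 0.95)),
            p_T=float(rng.uniform(0.05, 0.6)),
            p_S=float(rng.uniform(0.05, 0.4)),
            p_G=float(rng.uniform(0.05, 0.4)),
        )
        by_len: dict[int, list[np.ndarray]] = {}
        for s in seqs:
            by_len.setdefault(len(s), []).append(s)
        groups = [np.vstack(v) for _, v in sorted(by_len.items())]
        params, trace = _em_fit(groups, init, max_iter, tol)
        if params.p_S + params.p_G >= 1.0:
            continue
        ll = trace[-1]
        if best is None or ll > best[0]:
            best = (ll, params, trace)
    if best is None:
        raise ValueError("no EM restart satisfied the guard p_S + p_G < 1")
    _, params, trace = best
    return (params, trace) if return_trace else params


# --------------------------------------------------------- learner state

@dataclass
class LearnerState:
    """Per-skill mastery posteriors with append-only observation histories.

    Skills are diagnostic-hypothesis concept ids; each observation is the
    discretized binary-analysis outcome of one simulation, stamped so that
    histories from several simulations merge by timestamp.
    """

    params: BKTParams
    skills: dict[str, dict] = field(default_factory=dict)

    def _recompute(self, skill: str) -> None:
        p = self.params.p_L0
        for entry in self.skills[skill]["history"]:
            p = bkt_update(self.params, p, entry["correct"])
        self.skills[skill]["posterior"] = p

    def observe(self, skill: str, correct: int, timestamp: str = "") -> float:
        entry = {"timestamp": timestamp, "correct": int(correct)}
        self.skills.setdefault(skill, {"history": [], "posterior": self.params.p_L0})
        self.skills[skill]["history"].append(entry)
        self._recompute(skill)
        return self.skills[skill]["posterior"]

    def posterior(self, skill: str) -> float:
        if skill not in self.skills:
            return self.params.p_L0
        return self.skills[skill]["posterior"]

    # -- persistence -----------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "params": vars(self.params) | {},
                "skills": self.skills,
            },
            default=lambda o: o.__dict__,
            indent=2,
            sort_keys=True,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "LearnerState":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        state = cls(BKTParams(**data["params"]), data["skills"])
        return state

    def merge(self, other: "LearnerState") -> None:
        """Append the other state's histories, re-sorted by timestamp."""
        for skill, rec in other.skills.items():
            self.skills.setdefault(skill, {"history": [], "posterior": self.params.p_L0})
            merged = self.skills[skill]["history"] + rec["history"]
            merged.sort(key=lambda e: e["timestamp"])
            self.skills[skill]["history"] = merged
            self._recompute(skill)


def mastery_report(
    state: LearnerState, mastery_threshold: float = 0.95
) -> list[tuple[str, float, str]]:
    """(skill, posterior, status) sorted weakest first.

    A skill counts as mastered when its posterior reaches the threshold.
    """
    if not state.skills:
        raise ValueError("learner state has no skills to report on")
    rows = [
        (skill, rec["posterior"], "mastered" if rec["posterior"] >= mastery_threshold else "developing")
        for skill, rec in state.skills.items()
    ]
    rows.sort(key=lambda r: (r[1], r[0]))
    return rows
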