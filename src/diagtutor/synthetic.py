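"""Seeded generators that make every module testable without licensed data.

Real deployments pair the engine with the licensed SNOMED CT release, tutor-
authored clinical cases, and thousands of labeled student question pairs.
None of those can ship here, so this module provides deterministic stand-ins:

* :func:`make_toy_ontology` — a rooted is-a tree of synthetic disease
  concepts for distance/classification tests;
* :func:`table1_case` / :func:`table1_ontology` — the worked
  pharyngitis-versus-pneumonia teaching case (three diagnostic factors, the
  full I/D/N reference grid, pneumonia as the final diagnosis) together with
  a small respiratory ontology to grade hypotheses against;
* :func:`make_paraphrase_benchmark` — a multi-simulation question-matching
  benchmark built from slot-substitution paraphrase templates, emulating the
  structure (several simulations, reference questions, held-out paraphrases)
  of a real anamnestic-question test set at desk scale;
* :func:`simulate_learners` — binary observation sequences drawn from the
  BKT generating process for parameter-recovery tests.

Everything is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cases import ClinicalCase, load_case
from .ontology import Concept, Ontology
from .siamese import LabeledPair
from .tutoring import BKTParams

__all__ = [
    "ParaphraseTemplate",
    "ParaphraseBenchmark",
    "SimulatedLearnerSpec",
    "make_toy_ontology",
    "table1_ontology",
    "table1_case",
    "default_templates",
    "make_paraphrase_benchmark",
    "simulate_learners",
]


# ------------------------------------------------------------ toy ontology

def make_toy_ontology(depth: int, branching: int, seed: int = 0) -> Ontology:
    """A rooted is-a tree of synthetic disease concepts.

    Levels 0..depth, each internal node with ``branching`` children, so the
    node count is the geometric series (branching^(depth+1) - 1) /
    (branching - 1).  Every concept gets a unique identifying token in its
    label and one to three generated synonyms.
    """
    if depth < 2 or branching < 2:
        raise ValueError("need depth >= 2 and branching >= 2")
    rng = np.random.default_rng(seed)
    concepts: list[Concept] = []
    counter = 0

    def make(parent: str | None, level: int) -> None:
        nonlocal counter
        tag = f"d{counter:03d}"
        cid = f"C{counter:03d}"
        counter += 1
        syn_pool = (f"{tag} disease", f"{tag} syndrome", f"condition {tag}")
        n_syn = int(rng.integers(1, 4))
        concepts.append(
            Concept(
                cid,
                f"disorder {tag}",
                syn_pool[:n_syn],
                () if parent is None else (parent,),
            )
        )
        if level < depth:
            for _ in range(branching):
                make(cid, level + 1)

    make(None, 0)
    return Ontology(concepts)


# --------------------------------------------------- worked teaching case

def table1_ontology() -> Ontology:
    """Small respiratory/cardiac/GI is-a hierarchy for the worked case."""
    spec = [
        ("disease", "disease", (), None),
        ("respiratory_disease", "respiratory tract disease", (), "disease"),
        ("upper_respiratory_infection", "upper respiratory tract infection", (), "respiratory_disease"),
        ("pharyngitis", "pharyngitis", ("pharynx inflammation", "inflamed pharynx"), "upper_respiratory_infection"),
        ("laryngitis", "laryngitis", ("larynx inflammation",), "upper_respiratory_infection"),
        ("lower_respiratory_infection", "lower respiratory tract infection", (), "respiratory_disease"),
        ("pneumonia", "pneumonia", ("lung infection", "lung inflammation"), "lower_respiratory_infection"),
        ("interstitial_pneumonia", "interstitial pneumonia", (), "pneumonia"),
        ("lobar_pneumonia", "lobar pneumonia", (), "pneumonia"),
        ("bronchitis", "bronchitis", ("bronchial inflammation",), "lower_respiratory_infection"),
        ("cardiovascular_disease", "cardiovascular disease", (), "disease"),
        ("myocardial_infarction", "myocardial infarction", ("heart attack",), "cardiovascular_disease"),
        ("heart_failure", "heart failure", ("cardiac failure",), "cardiovascular_disease"),
        ("gastrointestinal_disease", "gastrointestinal disease", (), "disease"),
        ("gastritis", "gastritis", ("stomach inflammation",), "gastrointestinal_disease"),
    ]
    return Ontology(
        Concept(cid, label, syns, () if parent is None else (parent,))
        for cid, label, syns, parent in spec
    )


def table1_case() -> ClinicalCase:
    """The worked pharyngitis/pneumonia case with its full I/D/N grid.

    Three diagnostic factors (body temperature 38.5 °C, pharynx inspection
    showing no pharyngeal erythema, chest x-ray showing lobar consolidation),
    two reference hypotheses, six reference grid cells, final diagnosis
    pneumonia.
    """
    return load_case(
        {
            "scenario": (
                "A 54-year-old presents with two days of fever and a "
                "productive cough. No sore throat is reported."
            ),
            "factors": [
                {"id": "f_temp", "name": "Body temperature", "value": "38.5 °C", "modality": "physical_exam"},
                {"id": "f_pharynx", "name": "Pharynx inspection", "value": "No pharyngeal erythema", "modality": "physical_exam"},
                {"id": "f_xray", "name": "Chest x-ray", "value": "Lobar consolidation", "modality": "medical_test"},
            ],
            "questions": [
                {
                    "id": "q_fever",
                    "text": "do you have a fever",
                    "answer": "I have felt feverish; this morning it was 38.5 °C.",
                    "factors": ["f_temp"],
                },
                {
                    "id": "q_throat",
                    "text": "do you have a sore throat",
                    "answer": "No, my throat feels fine.",
                    "factors": [],
                },
            ],
            "exams": [
                {
                    "id": "e_temp",
                    "names": ["body temperature", "measure the temperature", "temperature measurement"],
                    "finding": "38.5 °C",
                    "factors": ["f_temp"],
                },
                {
                    "id": "e_pharynx",
                    "names": ["pharynx inspection", "throat examination", "inspect the pharynx"],
                    "finding": "No pharyngeal erythema",
                    "factors": ["f_pharynx"],
                },
            ],
            "tests": [
                {
                    "id": "t_xray",
                    "names": ["chest x-ray", "chest radiograph", "thorax x ray"],
                    "finding": "Lobar consolidation",
                    "factors": ["f_xray"],
                }
            ],
            "hypotheses": ["pharyngitis", "pneumonia"],
            "grid": [
                {"factor": "f_temp", "hypothesis": "pharyngitis", "label": "I"},
                {"factor": "f_temp", "hypothesis": "pneumonia", "label": "I"},
                {"factor": "f_pharynx", "hypothesis": "pharyngitis", "label": "D"},
                {"factor": "f_pharynx", "hypothesis": "pneumonia", "label": "N"},
                {"factor": "f_xray", "hypothesis": "pharyngitis", "label": "N"},
                {"factor": "f_xray", "hypothesis": "pneumonia", "label": "I"},
            ],
            "final_diagnosis": "pneumonia",
            "review_links": {
                "pharyngitis": "https://example.org/topics/pharyngitis",
                "pneumonia": "https://example.org/topics/pneumonia",
            },
        }
    )


# ------------------------------------------------- paraphrase benchmark

@dataclass(frozen=True)
class ParaphraseTemplate:
    """One anamnestic question topic: frames with a synonym slot.

    ``frames`` are phrasings containing the placeholder ``{s}``; ``slot``
    lists interchangeable fillers (symptom synonyms).  The canonical question
    is the first frame with the first filler.
    """

    name: str
    frames: tuple[str, ...]
    slot: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.slot) < 2:
            raise ValueError(f"template {self.name!r}: slot needs >= 2 alternatives")

    @property
    def canonical(self) -> str:
        return self.frames[0].format(s=self.slot[0])

    def realize(self, frame_idx: int, slot_idx: int) -> str:
        return self.frames[frame_idx].format(s=self.slot[slot_idx])

    def variants(self) -> list[str]:
        return [
            self.realize(i, j)
            for i in range(len(self.frames))
            for j in range(len(self.slot))
        ]


_GENERIC_FRAMES = (
    "do you have {s}",
    "have you been experiencing {s}",
    "are you suffering from {s}",
    "have you noticed {s}",
    "do you complain of {s}",
    "have you had {s} lately",
    "is there any {s}",
)

_TOPIC_SLOTS: dict[str, tuple[str, ...]] = {
    "fever": ("a fever", "pyrexia", "a high temperature"),
    "cough": ("a cough", "coughing fits", "a persistent cough"),
    "chest_pain": ("chest pain", "pain in the chest", "chest discomfort"),
    "headache": ("a headache", "head pain", "cephalalgia"),
    "nausea": ("nausea", "queasiness", "an urge to vomit"),
    "vomiting": ("vomiting", "emesis", "episodes of throwing up"),
    "dyspnea": ("shortness of breath", "breathlessness", "dyspnea"),
    "palpitations": ("palpitations", "a racing heart", "heart pounding"),
    "dizziness": ("dizziness", "vertigo", "lightheadedness"),
    "fatigue": ("fatigue", "tiredness", "exhaustion"),
    "weight_loss": ("weight loss", "unintended slimming", "falling weight"),
    "night_sweats": ("night sweats", "sweating at night", "nocturnal sweating"),
    "rash": ("a rash", "a skin eruption", "skin spots"),
    "joint_pain": ("joint pain", "arthralgia", "aching joints"),
    "sore_throat": ("a sore throat", "throat pain", "pharyngeal soreness"),
    "abdominal_pain": ("abdominal pain", "a stomach ache", "belly cramps"),
    "diarrhea": ("diarrhea", "loose stools", "watery bowel movements"),
    "constipation": ("constipation", "hard stools", "infrequent defecation"),
    "dysuria": ("burning urination", "painful urination", "dysuria"),
    "hematuria": ("blood in the urine", "hematuria", "reddish urine"),
    "leg_swelling": ("swollen legs", "leg swelling", "ankle edema"),
    "numbness": ("numbness", "tingling", "pins and needles"),
    "tremor": ("a tremor", "shaking hands", "trembling"),
    "memory": ("memory loss", "forgetfulness", "trouble remembering"),
    "insomnia": ("trouble sleeping", "insomnia", "poor sleep"),
    "appetite": ("loss of appetite", "poor appetite", "reduced hunger"),
    "smoking": ("smoking habits", "tobacco use", "a cigarette habit"),
    "alcohol": ("alcohol consumption", "drinking habits", "liquor intake"),
    "medications": ("current medications", "ongoing medicines", "prescribed drugs"),
    "allergies": ("allergies", "allergic reactions", "hypersensitivity episodes"),
    "travel": ("recent travel", "trips abroad", "journeys overseas"),
    "family_history": ("cardiac disease in your family", "a family history of heart disease", "relatives with heart problems"),
    "back_pain": ("back pain", "a backache", "lumbar pain"),
    "vision": ("blurred vision", "vision problems", "trouble seeing"),
    "hearing": ("hearing loss", "trouble hearing", "reduced hearing"),
    "bruising": ("easy bruising", "frequent bruises", "unexplained bruising"),
}

#: Unrelated non-question utterances used as negative-pair distractors; they
#: deliberately share no slot vocabulary with any template.
_DISTRACTORS = (
    "the weather is lovely today",
    "please close the window",
    "the cafeteria opens at noon",
    "my car would not start this morning",
    "the lecture hall is on the third floor",
    "this form needs a signature at the bottom",
)


def default_templates() -> list[ParaphraseTemplate]:
    """The built-in bank of anamnestic question templates (one per topic)."""
    return [
        ParaphraseTemplate(name, _GENERIC_FRAMES, slot)
        for name, slot in _TOPIC_SLOTS.items()
    ]


@dataclass(frozen=True)
class ParaphraseBenchmark:
    """Training pairs, per-simulation reference lists, and held-out tests."""

    train_pairs: tuple[LabeledPair, ...]
    simulations: tuple[tuple[tuple[str, str], ...], ...]  # per sim: (id, text)
    test: tuple[tuple[int, str, str], ...]  # (sim index, question, true id)
    corpus: tuple[str, ...]
    synonym_pairs: tuple[tuple[str, str], ...]


def _slot_synonym_word_pairs(templates) -> list[tuple[str, str]]:
    """Word-level synonym pairs from slot fillers of the same template."""
    pairs = []
    for tpl in templates:
        fillers = [set(f.split()) for f in tpl.slot]
        for i in range(len(fillers)):
            for j in range(i + 1, len(fillers)):
                only_i = fillers[i] - fillers[j]
                only_j = fillers[j] - fillers[i]
                for a in sorted(only_i):
                    for b in sorted(only_j):
                        if len(a) > 2 and len(b) > 2:
                            pairs.append((a, b))
    return pairs


def make_paraphrase_benchmark(
    templates: list[ParaphraseTemplate] | None = None,
    n_simulations: int = 6,
    refs_per_sim: int = 16,
    pairs: int = 400,
    seed: int = 42,
    tests_per_reference: int = 1,
) -> ParaphraseBenchmark:
    """Build the multi-simulation question-matching benchmark.

    Each simulation receives ``refs_per_sim`` reference questions (canonical
    template realizations).  Training pairs are balanced: positives are two
    distinct paraphrases of one template, negatives mix paraphrases of
    different templates with unrelated distractor sentences.  Test questions
    are paraphrases that never occur among the training texts, each tagged
    with its simulation and true reference id.
    """
    templates = list(templates) if templates is not None else default_templates()
    if refs_per_sim > len(templates):
        raise ValueError(
            f"need at least {refs_per_sim} templates, have {len(templates)}"
        )
    rng = np.random.default_rng(seed)

    def draw(tpl: ParaphraseTemplate) -> str:
        return tpl.realize(
            int(rng.integers(len(tpl.frames))), int(rng.integers(len(tpl.slot)))
        )

    n_pos = pairs // 2
    train_pairs: list[LabeledPair] = []
    train_texts: set[str] = set()
    for _ in range(n_pos):
        tpl = templates[int(rng.integers(len(templates)))]
        a = draw(tpl)
        for _attempt in range(50):
            b = draw(tpl)
            if b != a:
                break
        train_pairs.append(LabeledPair(a, b, 1))
        train_texts.update((a, b))
    for _ in range(pairs - n_pos):
        if rng.random() < 0.2:
            tpl = templates[int(rng.integers(len(templates)))]
            a = draw(tpl)
            b = _DISTRACTORS[int(rng.integers(len(_DISTRACTORS)))]
        else:
            i, j = rng.choice(len(templates), size=2, replace=False)
            a = draw(templates[int(i)])
            b = draw(templates[int(j)])
        train_pairs.append(LabeledPair(a, b, 0))
        train_texts.update((a, b))
    order = rng.permutation(len(train_pairs))
    train_pairs = [train_pairs[i] for i in order]

    simulations: list[tuple[tuple[str, str], ...]] = []
    test: list[tuple[int, str, str]] = []
    for sim in range(n_simulations):
        chosen = rng.choice(len(templates), size=refs_per_sim, replace=False)
        refs = []
        for slot_idx, t_idx in enumerate(sorted(int(i) for i in chosen)):
            tpl = templates[t_idx]
            rid = f"s{sim}_q{slot_idx:02d}"
            refs.append((rid, tpl.canonical))
            held_out = [
                v
                for v in tpl.variants()
                if v not in train_texts and v != tpl.canonical
            ]
            if not held_out:
                raise ValueError(
                    f"template {tpl.name!r} has no paraphrase left unseen by "
                    f"training; enlarge its frames or slot"
                )
            picks = rng.choice(
                len(held_out), size=min(tests_per_reference, len(held_out)), replace=False
            )
            for p in picks:
                test.append((sim, held_out[int(p)], rid))
        simulations.append(tuple(refs))

    corpus = sorted(train_texts | {text for refs in simulations for _, text in refs})
    return ParaphraseBenchmark(
        tuple(train_pairs),
        tuple(simulations),
        tuple(test),
        tuple(corpus),
        tuple(_slot_synonym_word_pairs(templates)),
    )


# ------------------------------------------------------ simulated learners

@dataclass(frozen=True)
class SimulatedLearnerSpec:
    params: BKTParams
    n_learners: int
    n_opportunities: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_learners < 1 or self.n_opportunities < 1:
            raise ValueError("learner and opportunity counts must be positive")


def simulate_learners(spec: SimulatedLearnerSpec) -> np.ndarray:
    """Binary observations drawn from the BKT generating process.

    Each learner starts mastered with probability p_L0; after every
    opportunity an unmastered learner transitions to mastery with probability
    p_T (and never forgets).  A mastered learner answers correctly with
    probability 1 - p_S, an unmastered one with probability p_G.  Returns an
    ``(n_learners, n_opportunities)`` int array.
    """
    p = spec.params
    rng = np.random.default_rng(spec.seed)
    mastered = rng.random(spec.n_learners) < p.p_L0
    obs = np.zeros((spec.n_learners, spec.n_opportunities), dtype=int)
    for t in range(spec.n_opportunities):
        p_correct = np.where(mastered, 1.0 - p.p_S, p.p_G)
        obs[:, t] = rng.random(spec.n_learners) < p_correct
        mastered = mastered | (rng.random(spec.n_learners) < p.p_T)
    return obs
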