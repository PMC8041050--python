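# diagtutor

A virtual-patient simulation engine with natural-language interaction and an
intelligent-tutoring layer, for medical-education software developers and
researchers in clinical-reasoning training.

Students work through an authored clinical case the way they would face a
real patient: they take the history by typing free-text questions, request
physical exams and medical tests, build a differential diagnosis in free
text, fill in a binary analysis grid, weight a pattern-analysis concept map,
and commit to a final diagnosis — receiving automated step-by-step feedback
throughout and a mistake summary with review links at the end.

## The models at the core

**Diagnostic-hypothesis grading.** A free-text hypothesis is linked to a
concept *c* of an is-a ontology by maximizing the Jaccard similarity
|A∩B| / |A∪B| between stop-word-filtered token sets of the input and of each
concept's label and synonyms. The hypothesis is then graded against the
case's reference hypotheses R by the shortest-path edge count
d(c, r) on the undirected is-a graph: verdict *correct* if
min<sub>r∈R</sub> d(c, r) = 0, *close* if 1 ≤ d ≤ 4 (with a hint toward the
nearest reference, or "be more specific" when c is an ancestor of it), and
*incorrect* for d ≥ 5 or disconnected concepts.

**Question matching.** Anamnestic questions are matched by a Siamese
recurrent network: one LSTM encoder (a single shared parameter set) maps
both questions to hidden states h₁, h₂, scored by the Manhattan-distance
similarity

&nbsp;&nbsp;&nbsp;&nbsp;p(q₁ ≡ q₂) = exp(−‖h₁ − h₂‖₁) ∈ (0, 1],

trained by squared error against binary equivalence labels. Word vectors are
trained by skip-gram with negative sampling plus weak synonym supervision so
that clinical synonym pairs (fever/pyrexia) land close together. The ranker
returns the reference questions scoring strictly above a probability
threshold, at most three of them.

**Learner model.** Per diagnostic hypothesis, mastery is tracked by Bayesian
Knowledge Tracing: a two-state HMM (skill unknown/known) with prior p(L₀),
learning p(T), slip p(S) and guess p(G), updated after each simulation's
binary-analysis outcome and fit across students by expectation-maximization
with seeded restarts under the no-forgetting constraint and the
identifiability guard p(S) + p(G) < 1.

## Worked example

The shipped worked case has three diagnostic factors (body temperature
38.5 °C, pharynx inspection showing no pharyngeal erythema, chest x-ray
showing lobar consolidation) and two reference hypotheses, pneumonia being
the final diagnosis.

```python
from diagtutor import Session
from diagtutor.synthetic import table1_case, table1_ontology
from diagtutor.tutoring import outer_summary

session = Session(table1_case(), table1_ontology())
print(session.request_exam_or_test("chest x ray")[0])
print(session.propose_hypothesis("lung infection")[0].verdict)
print(session.propose_hypothesis("pharyngitis")[0].verdict)
for request in ("body temperature", "pharynx inspection"):
    session.request_exam_or_test(request)

grid = session.build_binary_grid()          # 3 factors x 2 hypotheses
for f, h in grid.entries:
    grid.set(f, h, session.case.grid[(f, h)])
grid.set("f_xray", "pneumonia", "D")        # one deliberate mistake
print(session.submit_binary_grid(grid)[1])
print(session.select_final_diagnosis("pneumonia")[0])
print(outer_summary(session)[0])
```

prints

```
Lobar consolidation
correct
correct
{'pneumonia': 1, 'pharyngitis': 0}
correct
('pneumonia', 1, 'https://example.org/topics/pneumonia')
```

"lung infection" resolves to the concept *pneumonia* through its synonym
list and joins the differential; the flipped x-ray cell is the single graded
mistake, so the outer-loop summary puts pneumonia first with its review
link.

A command-line interface covers the same workflow from the shell
(`diagtutor validate-case`, `train-embeddings`, `train-matcher`, `evaluate`,
`run-case`, `replay-log`, `fit-bkt`, `learner-report`).

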