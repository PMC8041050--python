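import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diagtutor.tutoring import (
    FEEDBACK_CATALOG,
    BKTParams,
    LearnerState,
    binary_observation,
    bkt_fit,
    bkt_sequence_likelihood,
    bkt_update,
    inner_feedback,
    mastery_report,
)
from diagtutor.synthetic import SimulatedLearnerSpec, simulate_learners


def brute_force_likelihood(params: BKTParams, obs) -> float:
    """Independent oracle: explicit sum over all 2^T hidden-state paths."""
    T = len(obs)
    total = 0.0
    for path in itertools.product((0, 1), repeat=T):
        prob = params.p_L0 if path[0] else 1.0 - params.p_L0
        for t in range(1, T):
            if path[t - 1] == 0:
                prob *= params.p_T if path[t] else 1.0 - params.p_T
            elif path[t] == 0:
                prob = 0.0  # forgetting is impossible
                break
        for t, o in enumerate(obs):
            if path[t]:
                prob *= 1.0 - params.p_S if o else params.p_S
            else:
                prob *= params.p_G if o else 1.0 - params.p_G
        total += prob
    return total


class TestInnerFeedback:
    def test_catalog_covers_every_engine_category(self):
        for category in FEEDBACK_CATALOG:
            fb = inner_feedback(
                category,
                request="x",
                matched="m",
                nearest="n",
                factor="f",
                hypothesis="h",
                correct_label="I",
                given_label="D",
                total_mistakes=0,
                inconsistencies=0,
            )
            assert fb.code and fb.message

    def test_examples_map_to_expected_codes(self):
        assert inner_feedback("unmatched_exam", request="mri").code == "inappropriate_exam"
        assert (
            inner_feedback("hypothesis_too_general", matched="a", nearest="b").code
            == "be_more_specific"
        )
        fb = inner_feedback(
            "wrong_binary_cell",
            factor="fever",
            hypothesis="pneumonia",
            correct_label="I",
            given_label="D",
        )
        assert fb.code == "wrong_binary_cell"
        assert fb.payload["correct_label"] == "I"

    def test_unknown_category_is_an_error(self):
        with pytest.raises(ValueError, match="catalog"):
            inner_feedback("interpretive_dance")


class TestOuterSummary:
    def test_worst_hypothesis_listed_first_with_link(
        self, worked_case, resp_ontology
    ):
        from diagtutor.session import Session
        from diagtutor.tutoring import outer_summary

        session = Session(worked_case, resp_ontology)
        session.propose_hypothesis("pharyngitis")
        session.propose_hypothesis("pneumonia")
        session.request_exam_or_test("chest x ray")
        session.request_exam_or_test("pharynx inspection")
        session.request_exam_or_test("body temperature")
        grid = session.build_binary_grid()
        for f, h in grid.entries:
            grid.set(f, h, session.case.grid[(f, h)])
        grid.set("f_xray", "pneumonia", "N")
        grid.set("f_temp", "pneumonia", "D")
        session.submit_binary_grid(grid)
        session.select_final_diagnosis("pneumonia")
        summary = outer_summary(session)
        assert summary[0] == ("pneumonia", 2, "https://example.org/topics/pneumonia")
        assert summary[1][0] == "pharyngitis" and summary[1][1] == 0
        # ordering equals an independent sort of the brute-force counts
        counts = {
            h: sum(
                grid.entries[(f, hh)] != session.case.grid[(f, hh)]
                for (f, hh) in grid.entries
                if hh == h
            )
            for h in session.differential
        }
        assert [s[0] for s in summary] == sorted(counts, key=lambda h: (-counts[h], h))

    def test_tie_ordered_by_id(self, worked_case, resp_ontology):
        from diagtutor.session import Session
        from diagtutor.tutoring import outer_summary

        session = Session(worked_case, resp_ontology)
        session.propose_hypothesis("pharyngitis")
        session.propose_hypothesis("pneumonia")
        session.request_exam_or_test("body temperature")
        grid = session.build_binary_grid()
        grid.set("f_temp", "pharyngitis", "N")  # reference I -> mistake
        grid.set("f_temp", "pneumonia", "N")  # reference I -> mistake
        session.submit_binary_grid(grid)
        session.select_final_diagnosis("pneumonia")
        assert [s[0] for s in outer_summary(session)] == ["pharyngitis", "pneumonia"]

    def test_no_grid_submitted_gives_empty_summary(self, worked_case, resp_ontology):
        from diagtutor.session import Session
        from diagtutor.tutoring import outer_summary

        session = Session(worked_case, resp_ontology)
        session.propose_hypothesis("pneumonia")
        session.select_final_diagnosis("pneumonia")
        assert outer_summary(session) == []


class TestBinaryObservation:
    @pytest.mark.parametrize(
        "mistakes, cells, expected",
        [(0, 3, 1), (1, 3, 0), (3, 3, 0), (0, 1, 1), (1, 5, 1)],
    )
    def test_success_fraction_discretization(self, mistakes, cells, expected):
        assert binary_observation(mistakes, cells, success_fraction=0.8) == expected

    def test_zero_cells_rejected(self):
        with pytest.raises(ValueError):
            binary_observation(0, 0)


class TestBKTUpdate:
    def test_noise_free_limits(self):
        params = BKTParams(0.5, 0.0, 0.0, 0.0)
        assert bkt_update(params, 0.5, 1) == 1.0
        assert bkt_update(params, 0.5, 0) == 0.0

    def test_matches_two_state_forward_step(self):
        params = BKTParams(0.5, 0.1, 0.1, 0.2)
        assert bkt_update(params, 0.5, 1) == pytest.approx(0.8364, abs=1e-4)

    def test_impossible_observation_is_an_error(self):
        params = BKTParams(0.5, 0.0, 0.0, 0.0)
        with pytest.raises(ValueError, match="probability zero"):
            bkt_update(params, 0.0, 1)  # unknown learner can never guess

    @settings(derandomize=True, max_examples=300)
    @given(
        p=st.floats(0.01, 0.99),
        pS=st.floats(0.0, 0.45),
        pG=st.floats(0.05, 0.45),
        pT=st.floats(0.0, 0.9),
    )
    def test_bounded_for_all_valid_inputs(self, p, pS, pG, pT):
        params = BKTParams(0.5, pT, pS, pG)
        assert 0.0 <= bkt_update(params, p, 1) <= 1.0
        assert 0.0 <= bkt_update(params, p, 0) <= 1.0

    @settings(derandomize=True, max_examples=300)
    @given(p=st.floats(0.01, 0.99), pS=st.floats(0.0, 0.45), pG=st.floats(0.05, 0.45))
    def test_monotone_before_learning_step(self, p, pS, pG):
        """With p_S + p_G < 1 and p_T = 0, a correct observation never lowers
        mastery and an incorrect one never raises it."""
        params = BKTParams(0.5, 0.0, pS, pG)
        assert bkt_update(params, p, 1) >= p - 1e-12
        assert bkt_update(params, p, 0) <= p + 1e-12


class TestSequenceLikelihood:
    def test_certain_mastery_no_slip(self):
        assert bkt_sequence_likelihood(BKTParams(1.0, 0.0, 0.0, 0.0), [1]) == 1.0

    def test_normalizes_over_outcome_space(self):
        params = BKTParams(0.3, 0.2, 0.1, 0.25)
        total = sum(
            bkt_sequence_likelihood(params, seq)
            for seq in itertools.product((0, 1), repeat=4)
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_enumeration(self):
        params = BKTParams(0.3, 0.25, 0.12, 0.18)
        rng = np.random.default_rng(3)
        for T in (1, 3, 6, 8):
            for _ in range(5):
                obs = list(rng.integers(0, 2, T))
                assert bkt_sequence_likelihood(params, obs) == pytest.approx(
                    brute_force_likelihood(params, obs), abs=1e-10
                )

    def test_matches_hmmlearn_forward(self):
        """Cross-check against an independent HMM library on the equivalent
        unconstrained two-state chain."""
        from hmmlearn import hmm

        params = BKTParams(0.35, 0.22, 0.08, 0.3)
        model = hmm.CategoricalHMM(n_components=2)
        model.startprob_ = np.array([1 - params.p_L0, params.p_L0])
        model.transmat_ = np.array([[1 - params.p_T, params.p_T], [0.0, 1.0]])
        model.emissionprob_ = np.array(
            [[1 - params.p_G, params.p_G], [params.p_S, 1 - params.p_S]]
        )
        obs = [1, 0, 1, 1, 0, 1]
        ours = bkt_sequence_likelihood(params, obs)
        theirs = np.exp(model.score(np.array(obs).reshape(-1, 1)))
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_non_binary_observation_rejected(self):
        with pytest.raises(ValueError):
            bkt_sequence_likelihood(BKTParams(0.5, 0.1, 0.1, 0.1), [0, 2])


class TestBKTFit:
    def test_recovers_generating_parameters(self):
        true = BKTParams(0.2, 0.3, 0.1, 0.2)
        data = simulate_learners(SimulatedLearnerSpec(true, 500, 20, seed=11))
        fit = bkt_fit(list(data), seed=5, n_restarts=5)
        assert fit.p_L0 == pytest.approx(true.p_L0, abs=0.05)
        assert fit.p_T == pytest.approx(true.p_T, abs=0.05)
        assert fit.p_S == pytest.approx(true.p_S, abs=0.05)
        assert fit.p_G == pytest.approx(true.p_G, abs=0.05)
        assert fit.p_S + fit.p_G < 1.0

    def test_loglikelihood_trace_non_decreasing(self):
        data = simulate_learners(
            SimulatedLearnerSpec(BKTParams(0.3, 0.2, 0.15, 0.25), 50, 10, seed=2)
        )
        _, trace = bkt_fit(list(data), seed=0, n_restarts=2, return_trace=True)
        assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))

    def test_seeded_determinism(self):
        data = simulate_learners(
            SimulatedLearnerSpec(BKTParams(0.3, 0.2, 0.15, 0.25), 60, 8, seed=4)
        )
        assert bkt_fit(list(data), seed=9) == bkt_fit(list(data), seed=9)

    def test_mixed_length_sequences_supported(self):
        data = simulate_learners(
            SimulatedLearnerSpec(BKTParams(0.3, 0.2, 0.15, 0.25), 80, 10, seed=6)
        )
        seqs = [list(row)[: 5 + i % 6] for i, row in enumerate(data)]
        params = bkt_fit(seqs, seed=1, n_restarts=2)
        assert 0 < params.p_T < 1

    def test_identical_observations_rejected(self):
        with pytest.raises(ValueError, match="identifiable"):
            bkt_fit([[1, 1, 1], [1, 1, 1]], seed=0)

    def test_fewer_than_two_sequences_rejected(self):
        with pytest.raises(ValueError):
            bkt_fit([[1, 0, 1]], seed=0)


class TestLearnerState:
    def test_empty_history_posterior_is_prior(self):
        state = LearnerState(BKTParams(0.4, 0.1, 0.1, 0.2))
        assert state.posterior("pneumonia") == 0.4

    def test_observations_update_posterior(self):
        state = LearnerState(BKTParams(0.4, 0.1, 0.1, 0.2))
        p1 = state.observe("pneumonia", 1, "t1")
        assert p1 > 0.4
        p2 = state.observe("pneumonia", 0, "t2")
        assert p2 < p1

    def test_persistence_round_trip(self, tmp_path):
        state = LearnerState(BKTParams(0.4, 0.1, 0.1, 0.2))
        state.observe("pneumonia", 1, "t1")
        state.observe("pharyngitis", 0, "t1")
        path = tmp_path / "learner.json"
        state.save(path)
        loaded = LearnerState.load(path)
        assert loaded.params == state.params
        assert loaded.skills == state.skills

    def test_merge_appends_by_timestamp(self):
        params = BKTParams(0.4, 0.1, 0.1, 0.2)
        a = LearnerState(params)
        a.observe("pneumonia", 1, "2024-01-02")
        b = LearnerState(params)
        b.observe("pneumonia", 0, "2024-01-01")
        a.merge(b)
        history = [e["timestamp"] for e in a.skills["pneumonia"]["history"]]
        assert history == ["2024-01-01", "2024-01-02"]

    def test_mastery_report_sorted_weakest_first(self):
        state = LearnerState(BKTParams(0.4, 0.2, 0.05, 0.1))
        for _ in range(6):
            state.observe("pneumonia", 1)
        state.observe("pharyngitis", 0)
        report = mastery_report(state, mastery_threshold=0.95)
        assert report[0][0] == "pharyngitis" and report[0][2] == "developing"
        assert report[-1][0] == "pneumonia" and report[-1][2] == "mastered"

    def test_report_on_empty_state_rejected(self):
        with pytest.raises(ValueError):
            mastery_report(LearnerState(BKTParams(0.4, 0.1, 0.1, 0.2)))
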