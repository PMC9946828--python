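"""Move proposals, bookkeeping across indels, acceptance and the run loop."""

import numpy as np
import pytest

from famhal.mcmc import (AnnealSchedule, HallucinationState, MoveError,
                         MoveProposal, apply_move, metropolis_accept,
                         propose_move, run_hallucination, write_trajectory)


@pytest.fixture()
def state(planted_problem):
    p = planted_problem
    return HallucinationState.initial(
        p.start_sequence, p.annotation, list(p.reference_loop_lengths)
    )


class TestSchedule:
    def test_endpoints(self):
        sched = AnnealSchedule(0.1, 0.001, 500, "geometric")
        assert sched.temperature(0) == pytest.approx(0.1, abs=1e-9)
        assert sched.temperature(499) == pytest.approx(0.001, abs=1e-9)
        lin = AnnealSchedule(0.1, 0.001, 500, "linear")
        assert lin.temperature(0) == pytest.approx(0.1)
        assert lin.temperature(499) == pytest.approx(0.001)

    def test_monotone_decreasing(self):
        sched = AnnealSchedule(0.05, 0.0005, 100)
        temps = [sched.temperature(i) for i in range(100)]
        assert all(a >= b for a, b in zip(temps, temps[1:]))

    def test_validation(self):
        with pytest.raises(ValueError):
            AnnealSchedule(T_initial=0.0)
        with pytest.raises(ValueError):
            AnnealSchedule(T_initial=0.01, T_final=0.1)
        with pytest.raises(ValueError):
            AnnealSchedule(mode="exponentialish")


class TestPropose:
    def test_substitution_only(self, state, rng):
        for _ in range(100):
            move = propose_move(state, (1.0, 0.0, 0.0), rng)
            assert move.kind == "substitute"
            assert move.new_residue != state.sequence[move.position]

    def test_no_insert_when_all_loops_maxed(self, planted_problem, rng):
        p = planted_problem
        hi = p.annotation.loop_length_bounds[0][1]
        nc = p.annotation.n_conserved
        maxed = HallucinationState.initial(
            "A" * (nc + hi), p.annotation, [hi]
        )
        for _ in range(10_000):
            move = propose_move(maxed, (0.0, 0.5, 0.5), rng)
            assert move.kind == "delete"

    def test_kind_frequencies_within_3_sigma(self, state, rng):
        probs = (0.85, 0.075, 0.075)
        n = 100_000
        counts = {"substitute": 0, "insert": 0, "delete": 0}
        for _ in range(n):
            counts[propose_move(state, probs, rng).kind] += 1
        for p_k, kind in zip(probs, ("substitute", "insert", "delete")):
            sigma = np.sqrt(n * p_k * (1 - p_k))
            assert abs(counts[kind] - n * p_k) < 3 * sigma

    def test_no_legal_move(self, planted_problem, rng):
        p = planted_problem
        # freeze every conserved position and pin the loop to one length
        import famhal.family as fam

        ann = fam.RegionAnnotation(
            p.annotation.alignment_length, p.annotation.column_class,
            p.annotation.conserved_segments, p.annotation.variable_segments,
            p.annotation.member_maps, [(2, 2)],
        )
        mapping = fam.build_mapping(ann, [2])
        frozen = tuple(mapping.conserved.values())
        seq = "A" * mapping.length
        st = HallucinationState.initial(seq, ann, [2], frozen)
        # loop positions remain substitutable, so a legal move still exists
        move = propose_move(st, (1.0, 0.0, 0.0), rng)
        assert move.position in mapping.variable_positions
        # with substitution mass zero and the loop pinned: no legal move
        with pytest.raises(MoveError):
            propose_move(st, (0.0, 0.5, 0.5), rng)


class TestApply:
    def test_substitute_involution(self, state):
        move = MoveProposal("substitute", 3, "W")
        back = MoveProposal("substitute", 3, state.sequence[3])
        roundtrip = apply_move(apply_move(state, move), back)
        assert roundtrip.sequence == state.sequence

    def test_insert_then_delete_roundtrip(self, state):
        start, end = state.loop_span(0)
        ins = MoveProposal("insert", start + 1, "G", loop_id=0)
        grown = apply_move(state, ins)
        assert grown.loop_lengths[0] == state.loop_lengths[0] + 1
        dele = MoveProposal("delete", start + 1, loop_id=0)
        back = apply_move(grown, dele)
        assert back.sequence == state.sequence
        assert back.mapping.conserved == state.mapping.conserved

    def test_insertion_preserves_conserved_columns(self, state):
        start, _ = state.loop_span(0)
        grown = apply_move(state, MoveProposal("insert", start, "G", loop_id=0))
        for col, pos in state.mapping.conserved.items():
            new_pos = grown.mapping.conserved[col]
            assert state.sequence[pos] == grown.sequence[new_pos]

    def test_frozen_position_rejected(self, planted_problem):
        p = planted_problem
        st = HallucinationState.initial(
            p.start_sequence, p.annotation, list(p.reference_loop_lengths),
            frozen_positions=(0,),
        )
        with pytest.raises(MoveError):
            apply_move(st, MoveProposal("substitute", 0, "W"))

    def test_original_state_untouched(self, state):
        seq = state.sequence
        apply_move(state, MoveProposal("substitute", 2, "W"))
        assert state.sequence == seq


class TestMetropolis:
    def test_downhill_always_accepted(self, rng):
        assert all(
            metropolis_accept(-abs(x), 0.5, rng)
            for x in rng.normal(size=100)
        )

    def test_zero_temperature_limit_rejects_uphill(self, rng):
        assert not any(
            metropolis_accept(1.0, 1e-12, rng) for _ in range(100)
        )

    def test_acceptance_rate_matches_boltzmann_factor(self, rng):
        n = 100_000
        accepted = sum(metropolis_accept(1.0, 1.0, rng) for _ in range(n))
        p = np.exp(-1.0)
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(accepted - n * p) < 3 * sigma

    def test_validation(self, rng):
        with pytest.raises(ValueError):
            metropolis_accept(float("nan"), 1.0, rng)
        with pytest.raises(ValueError):
            metropolis_accept(0.1, 0.0, rng)


class TestRun:
    def test_zero_steps_returns_initial(self, planted_problem):
        p = planted_problem
        res = run_hallucination(
            p.start_sequence, p.profile, p.background, p.predictor,
            schedule=AnnealSchedule(n_steps=0), seed=0,
        )
        assert res.best.sequence == p.start_sequence
        assert res.trajectory == []

    def test_best_envelope_non_increasing(self, planted_problem):
        p = planted_problem
        res = run_hallucination(
            p.start_sequence, p.profile, p.background, p.predictor,
            schedule=AnnealSchedule(n_steps=300), seed=11,
        )
        env = [row["best_total"] for row in res.trajectory]
        assert all(a >= b - 1e-12 for a, b in zip(env, env[1:]))

    def test_length_bookkeeping_and_bounds(self, planted_problem):
        p = planted_problem
        lo, hi = p.annotation.loop_length_bounds[0]
        nc = p.annotation.n_conserved
        res = run_hallucination(
            p.start_sequence, p.profile, p.background, p.predictor,
            schedule=AnnealSchedule(n_steps=300), seed=5,
        )
        for row in res.trajectory:
            assert nc + lo <= len(row["sequence"]) <= nc + hi

    def test_frozen_identities_never_change(self, planted_problem):
        p = planted_problem
        st = HallucinationState.initial(
            p.start_sequence, p.annotation, list(p.reference_loop_lengths)
        )
        pos = sorted(st.mapping.conserved.values())[:3]
        res = run_hallucination(
            p.start_sequence, p.profile, p.background, p.predictor,
            schedule=AnnealSchedule(n_steps=400), seed=3,
            loop_lengths=list(p.reference_loop_lengths),
            frozen_positions=tuple(pos),
        )
        frozen_letters = [p.start_sequence[i] for i in pos]
        final = res.final
        for col, letter in zip(
            sorted(
                c for c, q in st.mapping.conserved.items() if q in pos
            ),
            frozen_letters,
        ):
            assert final.sequence[final.mapping.conserved[col]] == letter

    def test_reproducible_trajectories(self, planted_problem, tmp_path):
        p = planted_problem
        paths = []
        for run_idx in range(2):
            res = run_hallucination(
                p.start_sequence, p.profile, p.background, p.predictor,
                schedule=AnnealSchedule(n_steps=200), seed=42,
            )
            path = tmp_path / f"traj{run_idx}.tsv"
            write_trajectory(res.trajectory, path)
            paths.append(path)
        assert paths[0].read_bytes() == paths[1].read_bytes()
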