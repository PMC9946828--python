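"""Simulated-annealing Metropolis search over sequences.

The sampler explores sequence space with three move kinds: residue
substitutions anywhere outside frozen positions, and insertions or
deletions confined to variable loops within their per-loop length
bounds.  Conserved positions keep their alignment columns across all
length changes, so restraints stay valid; frozen positions (standing in
for designed hydrogen-bond networks that must be preserved) are never
mutated.  A move is accepted with the Metropolis probability
min(1, exp(−ΔL/T)) under a geometric or linear temperature schedule.

All randomness flows through a single seeded generator in a fixed draw
order (move kind, then the move's position/residue draws, then — only
for uphill moves — the acceptance uniform), so a run is bit-reproducible
given its seed, config and predictor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .family import (FamilyProfile, RegionAnnotation, SequenceMapping,
                     build_mapping)
from .losses import LossConfig, LossReport, total_loss
from .predictor import (BackgroundGeometry, DEFAULT_ALPHABET, Predictor)

__all__ = [
    "AnnealSchedule",
    "MoveProposal",
    "HallucinationState",
    "HallucinationResult",
    "MoveError",
    "propose_move",
    "apply_move",
    "metropolis_accept",
    "run_hallucination",
    "write_trajectory",
]

MOVE_KINDS = ("substitute", "insert", "delete")


class MoveError(ValueError):
    """Raised for illegal or impossible move proposals."""


@dataclass(frozen=True)
class AnnealSchedule:
    """Temperature protocol: T_initial at step 0, T_final at the last step."""

    T_initial: float = 0.02
    T_final: float = 0.0002
    n_steps: int = 2000
    mode: str = "geometric"

    def __post_init__(self):
        if not (self.T_initial > 0 and self.T_final > 0):
            raise ValueError("temperatures must be positive")
        if self.T_final > self.T_initial:
            raise ValueError("T_final must not exceed T_initial")
        if self.mode not in ("geometric", "linear"):
            raise ValueError(f"unknown schedule mode {self.mode!r}")

    def temperature(self, step: int) -> float:
        if self.n_steps <= 1:
            return self.T_initial
        frac = step / (self.n_steps - 1)
        if self.mode == "geometric":
            return float(
                self.T_initial * (self.T_final / self.T_initial) ** frac
            )
        return float(self.T_initial + frac * (self.T_final - self.T_initial))


@dataclass(frozen=True)
class MoveProposal:
    kind: str
    position: int
    new_residue: str | None = None
    loop_id: int | None = None


@dataclass
class HallucinationState:
    """One point of the search: sequence plus region bookkeeping."""

    sequence: str
    annotation: RegionAnnotation
    loop_lengths: tuple[int, ...]
    frozen_columns: frozenset[int] = frozenset()
    loss: LossReport | None = None
    iteration: int = 0

    def __post_init__(self):
        self.mapping: SequenceMapping = build_mapping(
            self.annotation, list(self.loop_lengths)
        )
        if self.mapping.length != len(self.sequence):
            raise MoveError(
                f"sequence length {len(self.sequence)} != layout "
                f"{self.mapping.length} for loops {self.loop_lengths}"
            )
        for k, ell in enumerate(self.loop_lengths):
            lo, hi = self.annotation.loop_length_bounds[k]
            if not lo <= ell <= hi:
                raise MoveError(
                    f"loop {k} length {ell} outside bounds ({lo}, {hi})"
                )
        bad = self.frozen_columns - set(self.mapping.conserved)
        if bad:
            raise MoveError(f"frozen columns {sorted(bad)} are not conserved")

    @classmethod
    def initial(cls, sequence: str, annotation: RegionAnnotation,
                loop_lengths: list[int] | None = None,
                frozen_positions: tuple[int, ...] = ()) -> "HallucinationState":
        """Build the starting state; loop lengths are inferred when the
        annotation has at most one variable segment."""
        if loop_lengths is None:
            n_loops = len(annotation.variable_segments)
            nc = annotation.n_conserved
            if n_loops == 0:
                loop_lengths = []
            elif n_loops == 1:
                loop_lengths = [len(sequence) - nc]
            else:
                raise MoveError(
                    "loop_lengths required with multiple variable segments"
                )
        mapping = build_mapping(annotation, list(loop_lengths))
        pos_to_col = {p: c for c, p in mapping.conserved.items()}
        frozen_cols = set()
        for p in frozen_positions:
            if p not in pos_to_col:
                raise MoveError(f"frozen position {p} is not conserved")
            frozen_cols.add(pos_to_col[p])
        return cls(sequence, annotation, tuple(loop_lengths),
                   frozenset(frozen_cols))

    @property
    def frozen_positions(self) -> frozenset[int]:
        return frozenset(self.mapping.conserved[c] for c in self.frozen_columns)

    def loop_span(self, k: int) -> tuple[int, int]:
        """Half-open sequence-position interval of variable loop k."""
        positions = [p for p, (kk, _) in self.mapping.loop_of.items() if kk == k]
        if not positions:
            # empty loop: its insertion slot sits where it would start
            before = [
                self.mapping.conserved[c]
                for (s, e) in self.annotation.conserved_segments
                if e <= self.annotation.variable_segments[k][0]
                for c in range(s, e)
            ]
            start = (max(before) + 1) if before else 0
            return (start, start)
        return (min(positions), max(positions) + 1)


def propose_move(state: HallucinationState,
                 move_probs: tuple[float, float, float],
                 rng: np.random.Generator,
                 alphabet: str = DEFAULT_ALPHABET) -> MoveProposal:
    """Draw one legal move.

    Kind probabilities are renormalized over the currently legal kinds
    (e.g. insertion mass vanishes when every loop is at its maximum);
    positions and residues are uniform over their legal sets.
    """
    probs = np.asarray(move_probs, dtype=float)
    if not np.isclose(probs.sum(), 1.0):
        raise MoveError("move_probs must sum to 1")
    frozen = state.frozen_positions
    subst_ok = len(frozen) < len(state.sequence)
    bounds = state.annotation.loop_length_bounds
    grow = [k for k, ell in enumerate(state.loop_lengths) if ell < bounds[k][1]]
    shrink = [
        k for k, ell in enumerate(state.loop_lengths)
        if ell > max(bounds[k][0], 0) and ell > 0
    ]
    legal = np.array([subst_ok, len(grow) > 0, len(shrink) > 0])
    masked = np.where(legal, probs, 0.0)
    if masked.sum() == 0:
        raise MoveError("no legal move: all loops at bounds, all positions frozen")
    masked /= masked.sum()
    kind = MOVE_KINDS[int(rng.choice(3, p=masked))]

    if kind == "substitute":
        candidates = [p for p in range(len(state.sequence)) if p not in frozen]
        pos = int(candidates[rng.integers(len(candidates))])
        current = state.sequence[pos]
        others = [a for a in alphabet if a != current]
        return MoveProposal("substitute", pos, others[rng.integers(len(others))])
    if kind == "insert":
        k = int(grow[rng.integers(len(grow))])
        start, end = state.loop_span(k)
        pos = int(start + rng.integers(end - start + 1))  # ell + 1 slots
        residue = alphabet[rng.integers(len(alphabet))]
        return MoveProposal("insert", pos, residue, loop_id=k)
    k = int(shrink[rng.integers(len(shrink))])
    start, end = state.loop_span(k)
    pos = int(start + rng.integers(end - start))
    return MoveProposal("delete", pos, loop_id=k)


def apply_move(state: HallucinationState, move: MoveProposal) -> HallucinationState:
    """Return the successor state; the input state is left untouched."""
    seq = state.sequence
    loops = list(state.loop_lengths)
    if move.kind == "substitute":
        if move.position in state.frozen_positions:
            raise MoveError(f"position {move.position} is frozen")
        if not 0 <= move.position < len(seq):
            raise MoveError(f"position {move.position} out of range")
        seq = seq[: move.position] + move.new_residue + seq[move.position + 1:]
    elif move.kind == "insert":
        k = move.loop_id
        start, end = state.loop_span(k)
        if not start <= move.position <= end:
            raise MoveError(f"insert position {move.position} outside loop {k}")
        if loops[k] + 1 > state.annotation.loop_length_bounds[k][1]:
            raise MoveError(f"loop {k} already at maximum length")
        seq = seq[: move.position] + move.new_residue + seq[move.position:]
        loops[k] += 1
    elif move.kind == "delete":
        k = move.loop_id
        start, end = state.loop_span(k)
        if not start <= move.position < end:
            raise MoveError(f"delete position {move.position} outside loop {k}")
        if loops[k] - 1 < max(state.annotation.loop_length_bounds[k][0], 0):
            raise MoveError(f"loop {k} already at minimum length")
        seq = seq[: move.position] + seq[move.position + 1:]
        loops[k] -= 1
    else:
        raise MoveError(f"unknown move kind {move.kind!r}")
    return HallucinationState(
        seq, state.annotation, tuple(loops), state.frozen_columns,
        loss=None, iteration=state.iteration + 1,
    )


def metropolis_accept(delta_loss: float, temperature: float,
                      rng: np.random.Generator) -> bool:
    """Accept with probability min(1, exp(−ΔL/T)).

    Downhill moves are accepted without consuming a random draw.
    """
    if not np.isfinite(delta_loss):
        raise ValueError("delta_loss must be finite")
    if not temperature > 0:
        raise ValueError("temperature must be positive")
    if delta_loss <= 0:
        return True
    return bool(rng.random() < np.exp(-delta_loss / temperature))


@dataclass
class HallucinationResult:
    best: HallucinationState
    final: HallucinationState
    trajectory: list[dict] = field(default_factory=list)
    n_accepted: int = 0


def _evaluate(state: HallucinationState, predictor: Predictor,
              profile: FamilyProfile, background: BackgroundGeometry,
              cfg: LossConfig, cache: dict) -> LossReport:
    key = (state.sequence, state.loop_lengths)
    if key in cache:
        return cache[key]
    pred = predictor.predict(state.sequence)
    report = total_loss(pred, profile, background, state.mapping, cfg)
    if len(cache) > 20000:
        cache.clear()
    cache[key] = report
    return report


def run_hallucination(start_sequence: str, profile: FamilyProfile,
                      background: BackgroundGeometry, predictor: Predictor,
                      schedule: AnnealSchedule | None = None,
                      move_probs: tuple[float, float, float] = (0.85, 0.075, 0.075),
                      loss_cfg: LossConfig | None = None,
                      seed: int = 0,
                      loop_lengths: list[int] | None = None,
                      frozen_positions: tuple[int, ...] = (),
                      alphabet: str | None = None) -> HallucinationResult:
    """Anneal a sequence against the profile/confidence loss.

    Executes ``schedule.n_steps`` propose → apply → predict → score →
    accept cycles and returns the best state by total loss (first
    iteration achieving the minimum wins ties) along with the full
    per-step trajectory.
    """
    schedule = schedule or AnnealSchedule()
    loss_cfg = loss_cfg or LossConfig()
    alphabet = alphabet or predictor.alphabet
    rng = np.random.default_rng(seed)
    cache: dict = {}

    state = HallucinationState.initial(
        start_sequence, profile.annotation, loop_lengths, frozen_positions
    )
    state.loss = _evaluate(state, predictor, profile, background, loss_cfg, cache)
    best = state
    result = HallucinationResult(best=best, final=state)

    for step in range(schedule.n_steps):
        T = schedule.temperature(step)
        move = propose_move(state, move_probs, rng, alphabet)
        cand = apply_move(state, move)
        cand.loss = _evaluate(cand, predictor, profile, background, loss_cfg,
                              cache)
        delta = cand.loss.total - state.loss.total
        accepted = metropolis_accept(delta, T, rng)
        if accepted:
            state = cand
            result.n_accepted += 1
            if state.loss.total < best.loss.total:
                best = state
        result.trajectory.append(
            {
                "iteration": step + 1,
                "kind": move.kind,
                "position": move.position,
                "residue": move.new_residue or "-",
                "loop_id": -1 if move.loop_id is None else move.loop_id,
                "delta": delta,
                "temperature": T,
                "accepted": int(accepted),
                "restraint": state.loss.restraint,
                "confidence": state.loss.confidence,
                "total": state.loss.total,
                "best_total": best.loss.total,
                "sequence": state.sequence,
            }
        )
    result.best = best
    result.final = state
    return result


TRAJECTORY_COLUMNS = (
    "iteration", "kind", "position", "residue", "loop_id", "delta",
    "temperature", "accepted", "restraint", "confidence", "total",
    "best_total", "sequence",
)


def write_trajectory(trajectory: list[dict], path) -> None:
    """Write the per-step record as a TSV with deterministic formatting."""
    def fmt(v):
        return f"{v:.10g}" if isinstance(v, float) else str(v)

    with open(path, "w") as fh:
        fh.write("\t".join(TRAJECTORY_COLUMNS) + "\n")
        for row in trajectory:
            fh.write("\t".join(fmt(row[c]) for c in TRAJECTORY_COLUMNS) + "\n")
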