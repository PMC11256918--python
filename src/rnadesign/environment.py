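"""Episodic decision process for filling unconstrained task positions.

One episode designs one candidate for one fixed-length task.  The agent
visits the unconstrained sequence positions left to right; at each step
it observes a local window of the numerically encoded task and places a
nucleotide.  With *action semantics* enabled, placing a nucleotide at a
matched opening bracket whose partner is also unconstrained places the
Watson-Crick complement at the partner site in the same step, and the
partner is removed from the visit order.  When every position is filled
the sequence is folded and the configured objective's reward is returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .design_space import Candidate, Task
from .folding import COMPLEMENT, FoldingEngine, pair_table
from .rewards import Objective, RewardConfig

#: encoding order of sequence constraint symbols
SEQ_ORDER = "ACGU?"
#: encoding order of structure constraint symbols
STRUCT_ORDER = ".()?"
#: index of the (#, #) padding symbol
PAD_INDEX = 20
N_SYMBOLS = 21
N_ACTIONS = 4
#: action index -> nucleotide
ACTION_TO_NT = "AGCU"


class EpisodeError(RuntimeError):
    pass


def symbol_index(seq_symbol: str, struct_symbol: str) -> int:
    """Index of a (sequence, structure) symbol pair.

    Pairs are enumerated as ``4 * seq_rank + struct_rank`` with sequence
    order A, C, G, U, ? and structure order ., (, ), ?; the padding pair
    (#, #) gets the last index, 20.
    """
    if seq_symbol == "#" and struct_symbol == "#":
        return PAD_INDEX
    return 4 * SEQ_ORDER.index(seq_symbol) + STRUCT_ORDER.index(struct_symbol)


def encode_task(
    task: Task, kappa: int, fills: dict[int, str] | None = None
) -> list[int]:
    """Numeric encoding of a task with ``kappa`` pads on both ends.

    ``fills`` optionally substitutes already-placed nucleotides for their
    sequence wildcards, so the encoding of a partially filled task is a
    pure function of (task, fills).
    """
    symbols = [PAD_INDEX] * kappa
    for i, (s, t) in enumerate(
        zip(task.sequence_constraints, task.structure_constraints)
    ):
        if fills and i in fills:
            s = fills[i]
        symbols.append(symbol_index(s, t))
    symbols.extend([PAD_INDEX] * kappa)
    return symbols


@dataclass
class EnvConfig:
    """Decision-process configuration.

    ``state_radius`` (kappa) is the half width of the observation window,
    ``include_actions_in_state`` (sigma) substitutes placed nucleotides
    into subsequent observations, and ``action_semantics`` enables
    Watson-Crick pair placement at matched brackets.
    """

    state_radius: int = 16
    include_actions_in_state: bool = True
    action_semantics: bool = True
    reward_cfg: RewardConfig = field(default_factory=RewardConfig)

    def __post_init__(self) -> None:
        if self.state_radius < 0:
            raise ValueError("state_radius must be >= 0")


def observe(
    encoded: list[int], task: Task, t: int, cfg: EnvConfig
) -> list[int]:
    """The (2 kappa + 1)-gram centred on the t-th unconstrained position."""
    free = task.free_positions
    if t >= len(free):
        raise EpisodeError(f"step {t} out of range ({len(free)} free positions)")
    centre = free[t] + cfg.state_radius  # position in the padded vector
    k = cfg.state_radius
    return encoded[centre - k : centre + k + 1]


def _visit_order(task: Task, action_semantics: bool) -> tuple[list[int], dict]:
    """Left-to-right visit order and the pair map used for auto-filling.

    A free position that is the matched *closing* partner of an earlier
    free opening bracket is auto-filled and therefore skipped.  When a
    matched partner position is sequence-constrained, no auto-fill
    happens for that pair.
    """
    partner = pair_table(task.structure_constraints)
    free = set(task.free_positions)
    order: list[int] = []
    auto: dict[int, int] = {}  # opening position -> partner to auto-fill
    skipped: set[int] = set()
    for i in task.free_positions:
        if i in skipped:
            continue
        order.append(i)
        j = partner[i]
        if (
            action_semantics
            and j is not None
            and j > i
            and j in free
        ):
            auto[i] = j
            skipped.add(j)
    return order, auto


def episode_length(task: Task, action_semantics: bool) -> int:
    """Number of agent decisions for a task: free positions minus the
    auto-filled pairing partners reachable under action semantics."""
    order, _ = _visit_order(task, action_semantics)
    return len(order)


@dataclass
class EnvState:
    step: int
    terminal_step: int
    window: list[int]
    filled: dict[int, str]


class DesignEnvironment:
    """Single-task episodic environment.

    ``reset(task)`` starts an episode, ``step(action)`` places a
    nucleotide (and possibly its Watson-Crick partner) and returns
    ``(state, reward, done)``; the reward is 0.0 until the terminal step,
    where the full sequence is folded with the engine and scored by the
    objective.  Episodes are deterministic functions of (task, actions,
    config).
    """

    def __init__(
        self, cfg: EnvConfig, engine: FoldingEngine, objective: Objective
    ) -> None:
        self.cfg = cfg
        self.engine = engine
        self.objective = objective
        self.task: Task | None = None

    def reset(self, task: Task) -> EnvState | None:
        self.task = task
        self.order, self.auto = _visit_order(
            task, self.cfg.action_semantics
        )
        self.fills: dict[int, str] = {}
        self.t = 0
        self.terminal = len(self.order)
        self.encoded = encode_task(task, self.cfg.state_radius)
        self.last_candidate: Candidate | None = None
        if self.terminal == 0:
            return None  # degenerate episode: nothing to decide
        return self._state()

    def _state(self) -> EnvState:
        assert self.task is not None
        window = observe_at(
            self.encoded, self.task, self.order[self.t], self.cfg
        )
        return EnvState(
            step=self.t,
            terminal_step=self.terminal,
            window=window,
            filled=dict(self.fills),
        )

    def step(self, action: int) -> tuple[EnvState | None, float, bool]:
        if self.task is None:
            raise EpisodeError("reset() must be called before step()")
        if self.t >= self.terminal:
            raise EpisodeError("episode already terminated")
        if not 0 <= action < N_ACTIONS:
            raise ValueError(f"action {action} outside 0..3")
        pos = self.order[self.t]
        nt = ACTION_TO_NT[action]
        self._fill(pos, nt)
        if pos in self.auto:
            self._fill(self.auto[pos], COMPLEMENT[nt])
        self.t += 1
        if self.t >= self.terminal:
            return None, self._terminal_reward(), True
        return self._state(), 0.0, False

    def _fill(self, pos: int, nt: str) -> None:
        self.fills[pos] = nt
        if self.cfg.include_actions_in_state:
            struct = self.task.structure_constraints[pos]
            self.encoded[pos + self.cfg.state_radius] = symbol_index(nt, struct)

    def finish(self) -> tuple[Candidate, float]:
        """Terminal evaluation for degenerate (zero-decision) episodes."""
        if self.task is None:
            raise EpisodeError("reset() must be called first")
        reward = self._terminal_reward()
        assert self.last_candidate is not None
        return self.last_candidate, reward

    def _terminal_reward(self) -> float:
        assert self.task is not None
        seq = "".join(
            self.fills.get(i, c) if c == "?" else c
            for i, c in enumerate(self.task.sequence_constraints)
        )
        if "?" in seq:  # pragma: no cover - defensive
            raise EpisodeError("unfilled position at terminal step")
        folded = self.engine.fold(seq)
        candidate = Candidate(sequence=seq, folded_structure=folded)
        reward = self.objective.reward(candidate, self.task)
        candidate.scores[self.objective.name] = reward
        self.last_candidate = candidate
        return reward


def observe_at(
    encoded: list[int], task: Task, position: int, cfg: EnvConfig
) -> list[int]:
    """Window centred on an absolute task position (0-based)."""
    centre = position + cfg.state_radius
    k = cfg.state_radius
    return encoded[centre - k : centre + k + 1]


def run_episode(
    env: DesignEnvironment, task: Task, actions
) -> tuple[Candidate, float, list]:
    """Drive one full episode with an action callable or iterable.

    ``actions`` is either an iterable of action indices or a callable
    ``window -> action``.  Returns the candidate, the terminal reward and
    the (window, action) trajectory.
    """
    state = env.reset(task)
    trajectory = []
    if state is None:
        candidate, reward = env.finish()
        return candidate, reward, trajectory
    if callable(actions):
        chooser = actions
        while True:
            a = chooser(state.window)
            trajectory.append((state.window, a))
            state, reward, done = env.step(a)
            if done:
                break
    else:
        it = iter(actions)
        while True:
            a = next(it)
            trajectory.append((state.window, a))
            state, reward, done = env.step(a)
            if done:
                break
    assert env.last_candidate is not None
    return env.last_candidate, reward, trajectory
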