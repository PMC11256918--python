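"""Policy network, policy-gradient training, and the design loop.

The policy maps the (2 kappa + 1)-gram observation to a distribution over
the four nucleotide actions.  The network is a small NumPy implementation
(embedding, optional 1-D convolutions, optional LSTM layers, dense head)
with manual backpropagation, trained by synchronous minibatch REINFORCE
with an entropy bonus and Adam.  Gradients are verified against finite
differences in the test suite.

The design loop repeatedly samples a fixed-length task from the design
space, solves it in a single episode, optionally applies the local
improvement and GC improvement steps, emits the candidate with its
scores, and (when adapting) updates the policy between episodes.  A
restart interval resets the parameters to their initial values, which
escapes adaptation dead ends on long runs.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import asdict, dataclass
from typing import Iterator

import numpy as np

from .design_space import (
    Candidate,
    DesignSpace,
    Task,
    sample_task,
    satisfies_hard_constraints,
)
from .environment import DesignEnvironment, EnvConfig, N_ACTIONS, N_SYMBOLS
from .folding import FoldingEngine
from .rewards import Objective, gc_improvement, local_improvement


@dataclass
class PolicyConfig:
    """Architecture and optimisation hyperparameters of the policy."""

    embedding_size: int = 8
    conv_layers: tuple[tuple[int, int], ...] = ((3, 8),)  # (kernel, channels)
    lstm_layers: int = 1
    dense_units: tuple[int, ...] = (32,)
    learning_rate: float = 1e-3
    batch_size: int = 32
    entropy_weight: float = 5e-3

    def __post_init__(self) -> None:
        if not (self.conv_layers or self.lstm_layers or self.dense_units):
            raise ValueError(
                "at least one of conv/lstm/dense layers must be present"
            )
        if not 0 <= self.lstm_layers <= 2:
            raise ValueError("lstm_layers must be 0, 1 or 2")


@dataclass
class TrainingConfig:
    episodes: int = 2000
    dataset_choice: str = "mixed"
    schedule: str = "uniform"
    seed: int = 0
    restart_interval: float = 1800.0

    def __post_init__(self) -> None:
        if self.episodes < 0:
            raise ValueError("episodes must be >= 0")
        if self.restart_interval <= 0:
            raise ValueError("restart_interval must be positive")


# ---------------------------------------------------------------------------
# the network


class Policy:
    """Window -> action-distribution network with manual gradients."""

    def __init__(self, cfg: PolicyConfig, kappa: int, seed: int = 0) -> None:
        self.cfg = cfg
        self.kappa = kappa
        self.window = 2 * kappa + 1
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        dim = cfg.embedding_size
        self._init("emb", (N_SYMBOLS, dim), rng)
        for li, (kw, ch) in enumerate(cfg.conv_layers):
            self._init(f"conv{li}_W", (kw, dim, ch), rng)
            self.params[f"conv{li}_b"] = np.zeros(ch)
            dim = ch
        for li in range(cfg.lstm_layers):
            h = dim
            self._init(f"lstm{li}_Wx", (dim, 4 * h), rng)
            self._init(f"lstm{li}_Wh", (h, 4 * h), rng)
            b = np.zeros(4 * h)
            b[h : 2 * h] = 1.0  # forget-gate bias
            self.params[f"lstm{li}_b"] = b
            dim = h
        flat = dim if cfg.lstm_layers else dim * self.window
        prev = flat
        for di, units in enumerate(cfg.dense_units):
            self._init(f"dense{di}_W", (prev, units), rng)
            self.params[f"dense{di}_b"] = np.zeros(units)
            prev = units
        self._init("out_W", (prev, N_ACTIONS), rng)
        self.params["out_b"] = np.zeros(N_ACTIONS)

    def _init(self, name: str, shape: tuple[int, ...], rng) -> None:
        fan_in = shape[0] if len(shape) == 2 else shape[0] * shape[1]
        scale = np.sqrt(1.0 / max(fan_in, 1))
        self.params[name] = rng.normal(0.0, scale, size=shape)

    # -- forward -----------------------------------------------------------

    def forward(self, windows: np.ndarray):
        """Probabilities (B, 4) and a cache for backward()."""
        cfg = self.cfg
        p = self.params
        ids = np.asarray(windows, dtype=np.int64)
        if ids.ndim == 1:
            ids = ids[None, :]
        cache: dict = {"ids": ids}
        x = p["emb"][ids]  # (B, W, E)
        cache["conv"] = []
        for li, (kw, ch) in enumerate(cfg.conv_layers):
            W, b = p[f"conv{li}_W"], p[f"conv{li}_b"]
            left = (kw - 1) // 2
            right = kw - 1 - left
            xp = np.pad(x, ((0, 0), (left, right), (0, 0)))
            T = x.shape[1]
            y = np.tile(b, (x.shape[0], T, 1)).astype(float)
            for k in range(kw):
                y += xp[:, k : k + T, :] @ W[k]
            mask = y > 0
            cache["conv"].append((x, xp, mask))
            x = y * mask
        cache["lstm"] = []
        if cfg.lstm_layers:
            for li in range(cfg.lstm_layers):
                x, lcache = self._lstm_forward(x, li)
                cache["lstm"].append(lcache)
            feat = x[:, -1, :]  # last timestep
            cache["lstm_out"] = x
        else:
            feat = x.reshape(x.shape[0], -1)
        cache["pre_dense_shape"] = x.shape
        cache["dense"] = []
        h = feat
        for di in range(len(cfg.dense_units)):
            W, b = p[f"dense{di}_W"], p[f"dense{di}_b"]
            z = h @ W + b
            mask = z > 0
            cache["dense"].append((h, mask))
            h = z * mask
        cache["head_in"] = h
        logits = h @ p["out_W"] + p["out_b"]
        logits -= logits.max(axis=1, keepdims=True)
        exp = np.exp(logits)
        probs = exp / exp.sum(axis=1, keepdims=True)
        cache["probs"] = probs
        return probs, cache

    def _lstm_forward(self, x: np.ndarray, li: int):
        p = self.params
        Wx, Wh, b = p[f"lstm{li}_Wx"], p[f"lstm{li}_Wh"], p[f"lstm{li}_b"]
        B, T, _ = x.shape
        H = Wh.shape[0]
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        hs = np.zeros((B, T, H))
        steps = []
        for t in range(T):
            z = x[:, t, :] @ Wx + h @ Wh + b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            steps.append((x[:, t, :], h, c, i, f, g, o, c_new, tanh_c))
            h, c = h_new, c_new
            hs[:, t, :] = h
        return hs, (steps, x.shape)

    # -- backward ----------------------------------------------------------

    def backward(self, cache: dict, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        cfg = self.cfg
        p = self.params
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        h = cache["head_in"]
        grads["out_W"] += h.T @ dlogits
        grads["out_b"] += dlogits.sum(axis=0)
        dh = dlogits @ p["out_W"].T
        for di in reversed(range(len(cfg.dense_units))):
            hin, mask = cache["dense"][di]
            dz = dh * mask
            grads[f"dense{di}_W"] += hin.T @ dz
            grads[f"dense{di}_b"] += dz.sum(axis=0)
            dh = dz @ p[f"dense{di}_W"].T
        B, T, _ = cache["pre_dense_shape"]
        if cfg.lstm_layers:
            dseq = np.zeros(cache["pre_dense_shape"])
            dseq[:, -1, :] = dh
            for li in reversed(range(cfg.lstm_layers)):
                dseq = self._lstm_backward(dseq, li, cache["lstm"][li], grads)
            dx = dseq
        else:
            dx = dh.reshape(cache["pre_dense_shape"])
        for li in reversed(range(len(cfg.conv_layers))):
            kw, ch = cfg.conv_layers[li]
            x, xp, mask = cache["conv"][li]
            dy = dx * mask
            W = p[f"conv{li}_W"]
            grads[f"conv{li}_b"] += dy.sum(axis=(0, 1))
            dxp = np.zeros_like(xp)
            for k in range(kw):
                grads[f"conv{li}_W"][k] += np.einsum(
                    "bti,bto->io", xp[:, k : k + T, :], dy
                )
                dxp[:, k : k + T, :] += dy @ W[k].T
            left = (kw - 1) // 2
            dx = dxp[:, left : left + T, :]
        ids = cache["ids"]
        np.add.at(grads["emb"], ids.reshape(-1), dx.reshape(-1, dx.shape[-1]))
        return grads

    def _lstm_backward(self, dhs, li, lcache, grads):
        p = self.params
        Wx, Wh = p[f"lstm{li}_Wx"], p[f"lstm{li}_Wh"]
        steps, xshape = lcache
        B, T, _ = xshape
        H = Wh.shape[0]
        dx = np.zeros(xshape)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in reversed(range(T)):
            xt, h_prev, c_prev, i, f, g, o, c_new, tanh_c = steps[t]
            dh = dhs[:, t, :] + dh_next
            do = dh * tanh_c
            dc = dh * o * (1 - tanh_c**2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g**2),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            grads[f"lstm{li}_Wx"] += xt.T @ dz
            grads[f"lstm{li}_Wh"] += h_prev.T @ dz
            grads[f"lstm{li}_b"] += dz.sum(axis=0)
            dx[:, t, :] = dz @ Wx.T
            dh_next = dz @ Wh.T
            dc_next = dc * f
        return dx

    # -- acting ------------------------------------------------------------

    def probabilities(self, window) -> np.ndarray:
        probs, _ = self.forward(np.asarray(window))
        return probs[0]

    def act(self, window, rng: np.random.Generator) -> int:
        return int(rng.choice(N_ACTIONS, p=self.probabilities(window)))

    # -- persistence -------------------------------------------------------

    def state_copy(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = state[k].copy()

    def save(self, path, extra: dict | None = None) -> None:
        """Versioned, self-describing checkpoint (numpy archive)."""
        meta = {
            "format": "rnadesign-policy",
            "version": 1,
            "config": asdict(self.cfg),
            "kappa": self.kappa,
        }
        if extra:
            meta.update(extra)
        np.savez(
            path,
            __meta__=np.frombuffer(
                json.dumps(meta).encode("utf-8"), dtype=np.uint8
            ),
            **self.params,
        )

    @classmethod
    def load(cls, path) -> "Policy":
        with np.load(path) as archive:
            meta = json.loads(bytes(archive["__meta__"]).decode("utf-8"))
            if meta.get("format") != "rnadesign-policy":
                raise ValueError(f"{path} is not a policy checkpoint")
            cfgd = meta["config"]
            cfgd["conv_layers"] = tuple(
                tuple(x) for x in cfgd["conv_layers"]
            )
            cfgd["dense_units"] = tuple(cfgd["dense_units"])
            policy = cls(PolicyConfig(**cfgd), kappa=meta["kappa"])
            for k in policy.params:
                policy.params[k] = archive[k].copy()
        return policy


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def build_policy(cfg: PolicyConfig, kappa: int, seed: int = 0) -> Policy:
    """Seeded policy construction; identical seeds give identical weights."""
    return Policy(cfg, kappa, seed=seed)


# ---------------------------------------------------------------------------
# optimisation


class Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float) -> None:
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / (1 - self.beta1**self.t)
            vhat = self.v[k] / (1 - self.beta2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def policy_gradient_dlogits(
    probs: np.ndarray,
    actions: np.ndarray,
    advantages: np.ndarray,
    entropy_weight: float,
) -> np.ndarray:
    """Gradient of the REINFORCE + entropy-bonus loss w.r.t. the logits.

    The loss is ``-mean(adv * log pi(a)) - entropy_weight * mean(H(pi))``.
    """
    B = probs.shape[0]
    onehot = np.zeros_like(probs)
    onehot[np.arange(B), actions] = 1.0
    d = advantages[:, None] * (probs - onehot)
    logp = np.log(np.clip(probs, 1e-12, None))
    entropy = -(probs * logp).sum(axis=1, keepdims=True)
    d += entropy_weight * probs * (logp + entropy)
    return d / B


MAX_GRAD_NORM = 5.0


class PolicyUpdater:
    """Synchronous minibatch REINFORCE with a moving-average baseline."""

    def __init__(self, policy: Policy) -> None:
        self.policy = policy
        self.opt = Adam(policy.params, policy.cfg.learning_rate)
        self.baseline = 0.0
        self.baseline_initialised = False

    def reset_optimizer(self) -> None:
        self.opt = Adam(self.policy.params, self.policy.cfg.learning_rate)

    def update(self, episodes: list[tuple[list, float]]) -> float:
        """One gradient step from a batch of (trajectory, reward) episodes.

        Returns the mean policy loss over the batch (for logging).
        """
        windows, actions, advantages = [], [], []
        for trajectory, reward in episodes:
            if not self.baseline_initialised:
                self.baseline = reward
                self.baseline_initialised = True
            adv = reward - self.baseline
            self.baseline = 0.99 * self.baseline + 0.01 * reward
            for window, action in trajectory:
                windows.append(window)
                actions.append(action)
                advantages.append(adv)
        if not windows:
            return 0.0
        W = np.asarray(windows)
        A = np.asarray(actions)
        adv = np.asarray(advantages, dtype=float)
        probs, cache = self.policy.forward(W)
        dlogits = policy_gradient_dlogits(
            probs, A, adv, self.policy.cfg.entropy_weight
        )
        grads = self.policy.backward(cache, dlogits)
        norm = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
        if norm > MAX_GRAD_NORM:
            scale = MAX_GRAD_NORM / norm
            grads = {k: g * scale for k, g in grads.items()}
        self.opt.step(self.policy.params, grads)
        logp = np.log(np.clip(probs[np.arange(len(A)), A], 1e-12, None))
        return float(-(adv * logp).mean())


# ---------------------------------------------------------------------------
# training


def train(
    policy: Policy,
    task_source,
    env_cfg: EnvConfig,
    engine: FoldingEngine,
    objective: Objective,
    train_cfg: TrainingConfig,
) -> tuple[Policy, list[dict]]:
    """Policy-gradient training over tasks drawn from ``task_source``.

    ``task_source`` is a callable ``rng -> Task`` or an iterable of tasks.
    Episodes with an empty structure part are skipped with a warning.
    Fully reproducible from ``train_cfg.seed``.
    """
    rng = np.random.default_rng(train_cfg.seed)
    env = DesignEnvironment(env_cfg, engine, objective)
    updater = PolicyUpdater(policy)
    log: list[dict] = []
    batch: list[tuple[list, float]] = []
    source = _task_iterator(task_source, rng)
    for episode in range(train_cfg.episodes):
        task = next(source)
        if len(task) == 0:
            warnings.warn("skipping task with empty structure part")
            continue
        candidate, reward, trajectory = _policy_episode(env, task, policy, rng)
        batch.append((trajectory, reward))
        loss = None
        if len(batch) >= policy.cfg.batch_size:
            loss = updater.update(batch)
            batch = []
        log.append(
            {
                "episode": episode,
                "task_id": hash(task.sequence_constraints + task.structure_constraints) & 0x7FFFFFFF,
                "reward": reward,
                "loss": loss,
            }
        )
    if batch:
        updater.update(batch)
    return policy, log


def _task_iterator(task_source, rng) -> Iterator[Task]:
    if callable(task_source):

        def from_callable():
            while True:
                yield task_source(rng)

        return from_callable()
    tasks = list(task_source)

    def from_list():
        while True:
            yield tasks[int(rng.integers(len(tasks)))]

    return from_list()


def _policy_episode(env: DesignEnvironment, task: Task, policy: Policy, rng):
    state = env.reset(task)
    trajectory = []
    if state is None:
        candidate, reward = env.finish()
        return candidate, reward, trajectory
    while True:
        a = policy.act(state.window, rng)
        trajectory.append((state.window, a))
        state, reward, done = env.step(a)
        if done:
            break
    return env.last_candidate, reward, trajectory


# ---------------------------------------------------------------------------
# the design loop


@dataclass
class DesignResult:
    candidate: Candidate
    task: Task
    reward: float
    solved: bool
    episode: int


def design(
    policy: Policy,
    space: DesignSpace,
    objective: Objective,
    engine: FoldingEngine,
    env_cfg: EnvConfig,
    rng: np.random.Generator,
    num_candidates: int | None = None,
    timeout: float | None = None,
    adapt: bool = True,
    restart_interval: float = 1800.0,
    use_lis: bool = True,
    use_gis: bool | None = None,
    lis_max_mismatches: int = 5,
) -> Iterator[DesignResult]:
    """Stream of candidates for a design space under one objective.

    Each iteration samples a fixed-length task from the space, solves it
    in a single episode, optionally refines the candidate (local
    improvement, then GC improvement when a GC target is set), scores it
    and yields it with a solved flag (hard constraints plus the
    objective's own criterion).  With ``adapt`` the policy is updated
    after every ``batch_size`` episodes; every ``restart_interval``
    seconds of wall clock the parameters are reset to their initial
    values.
    """
    if num_candidates is None and timeout is None:
        raise ValueError("need a candidate budget or a timeout")
    env = DesignEnvironment(env_cfg, engine, objective)
    updater = PolicyUpdater(policy) if adapt else None
    initial_state = policy.state_copy()
    if use_gis is None:
        use_gis = objective.cfg.gc_desired is not None
    start = time.monotonic()
    last_restart = start
    batch: list[tuple[list, float]] = []
    episode = 0
    while True:
        if num_candidates is not None and episode >= num_candidates:
            break
        if timeout is not None and time.monotonic() - start >= timeout:
            break
        if time.monotonic() - last_restart >= restart_interval:
            policy.load_state(initial_state)
            if updater is not None:
                updater.reset_optimizer()
            last_restart = time.monotonic()
        task = sample_task(space, rng=rng)
        candidate, reward, trajectory = _policy_episode(env, task, policy, rng)
        if use_lis:
            candidate = local_improvement(
                candidate, task, engine, max_mismatches=lis_max_mismatches
            )
            if use_gis:
                candidate = gc_improvement(candidate, task, objective.cfg, engine)
            reward = objective.reward(candidate, task)
        candidate.scores[objective.name] = reward
        candidate.scores["gc"] = candidate.gc_content
        solved = (
            satisfies_hard_constraints(task, candidate)
            and objective.solved(candidate, task)
        )
        if adapt and updater is not None:
            batch.append((trajectory, reward))
            if len(batch) >= policy.cfg.batch_size:
                updater.update(batch)
                batch = []
        yield DesignResult(candidate, task, reward, solved, episode)
        episode += 1


def random_agent(
    space: DesignSpace,
    objective: Objective,
    engine: FoldingEngine,
    env_cfg: EnvConfig,
    rng: np.random.Generator,
    num_candidates: int | None = None,
    timeout: float | None = None,
) -> Iterator[DesignResult]:
    """Uniform-random baseline: actions sampled uniformly, no updates."""
    if num_candidates is None and timeout is None:
        raise ValueError("need a candidate budget or a timeout")
    env = DesignEnvironment(env_cfg, engine, objective)
    start = time.monotonic()
    episode = 0
    while True:
        if num_candidates is not None and episode >= num_candidates:
            break
        if timeout is not None and time.monotonic() - start >= timeout:
            break
        task = sample_task(space, rng=rng)
        state = env.reset(task)
        if state is None:
            candidate, reward = env.finish()
        else:
            while True:
                a = int(rng.integers(N_ACTIONS))
                state, reward, done = env.step(a)
                if done:
                    break
            candidate = env.last_candidate
        candidate.scores[objective.name] = reward
        candidate.scores["gc"] = candidate.gc_content
        solved = (
            satisfies_hard_constraints(task, candidate)
            and objective.solved(candidate, task)
        )
        yield DesignResult(candidate, task, reward, solved, episode)
        episode += 1
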