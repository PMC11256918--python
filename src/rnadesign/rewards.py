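"""Objective functions for RNA design.

Design objectives are expressed as losses over a candidate and a task and
mapped to rewards in [0, 1]:

* structure loss: number of violated structure constraints (Hamming
  distance restricted to constrained sites), normalised by length and
  shaped with an exponent alpha,
* GC loss: absolute deviation of the GC content from a desired value,
  with a tolerance band epsilon inside which the loss is zero,
* a combined weighted objective,
* a Weisfeiler-Lehman graph distance between secondary structures as an
  alternative to the positional Hamming distance,
* transforms for plug-in scorers (covariance-model bitscores,
  RNA-RNA-interaction energies).

Two local refinement procedures operate on finished candidates: a local
improvement step (exhaustive repair around constraint violations) and a
greedy GC improvement step.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np

from .design_space import Candidate, Task
from .folding import pair_table


@dataclass
class RewardConfig:
    """Weights and tolerances of the built-in objectives.

    alpha shapes the normalised reward (higher alpha sharpens the signal
    near perfect solutions), beta/gamma weight the structure and GC terms
    of the combined objective, gc_tolerance is the band inside which a GC
    deviation counts as zero, and wl_iterations is the number of
    label-refinement rounds of the Weisfeiler-Lehman distance.
    """

    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0
    gc_desired: float | None = None
    gc_tolerance: float = 0.01
    wl_iterations: int = 2

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.beta < 0 or self.gamma < 0:
            raise ValueError("beta and gamma must be non-negative")
        if not 0 <= self.gc_tolerance < 1:
            raise ValueError("gc_tolerance must lie in [0, 1)")
        if self.gc_desired is not None and not 0 <= self.gc_desired <= 1:
            raise ValueError("gc_desired must lie in [0, 1]")


def structure_loss(omega_bar: str, folded: str) -> int:
    """Number of violated structure constraints.

    Hamming distance between the constraint string and the folded
    structure restricted to constrained sites; ``?`` positions contribute
    nothing.  Reduces to the plain Hamming distance when the constraint
    string contains no wildcard.
    """
    if len(omega_bar) != len(folded):
        raise ValueError(
            f"length mismatch: constraints {len(omega_bar)} vs folded "
            f"{len(folded)}"
        )
    return sum(om != "?" and om != y for om, y in zip(omega_bar, folded))


def structure_reward(loss: int, length: int, alpha: float = 1.0) -> float:
    """Normalised structure reward ``(1 - loss/length) ** alpha``."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0 <= loss <= length:
        raise ValueError(f"loss {loss} outside [0, {length}]")
    return (1.0 - loss / length) ** alpha


def gc_content(sequence: str) -> float:
    if not sequence:
        raise ValueError("empty sequence")
    return sum(c in "GC" for c in sequence) / len(sequence)


def gc_loss(sequence: str, gc_desired: float, epsilon: float = 0.01) -> float:
    """Absolute GC deviation, zero inside the tolerance band."""
    dev = abs(gc_desired - gc_content(sequence))
    return 0.0 if dev <= epsilon else dev


def combined_reward(
    loss: int, length: int, gc_l: float, cfg: RewardConfig
) -> float:
    """Weighted structure + GC reward, clipped to zero when the weighted
    loss sum exceeds one."""
    total = cfg.beta * loss / length + cfg.gamma * gc_l
    if total > 1.0:
        return 0.0
    return (1.0 - total) ** cfg.alpha


# ---------------------------------------------------------------------------
# Weisfeiler-Lehman structure distance


def _structure_graph(structure: str) -> tuple[list[str], list[list[int]]]:
    """Labelled graph of a dot-bracket string.

    Nodes are positions labelled with their structure symbol; edges are
    backbone adjacencies plus matched base pairs.
    """
    n = len(structure)
    labels = list(structure)
    adj: list[list[int]] = [[] for _ in range(n)]
    for i in range(n - 1):
        adj[i].append(i + 1)
        adj[i + 1].append(i)
    for i, j in enumerate(pair_table(structure)):
        if j is not None and j > i:
            adj[i].append(j)
            adj[j].append(i)
    return labels, adj


def _wl_features(structure: str, iterations: int) -> dict[str, int]:
    """Multiset of node labels accumulated over WL refinement rounds."""
    labels, adj = _structure_graph(structure)
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    for _ in range(iterations):
        new_labels = []
        for i, lab in enumerate(labels):
            neigh = sorted(labels[j] for j in adj[i])
            new_labels.append(lab + "|" + ",".join(neigh))
        labels = new_labels
        for lab in labels:
            counts[lab] = counts.get(lab, 0) + 1
    return counts


def wl_distance(structure_a: str, structure_b: str, iterations: int = 2) -> float:
    """Weisfeiler-Lehman distance between two secondary structures.

    Both structures are turned into labelled graphs (backbone + matched
    pairs), label multisets are refined for the given number of rounds,
    and the distance is ``1 - cos(psi(G1), psi(G2))`` over the
    concatenated label-count feature vectors.  The cosine normalisation
    keeps the distance inside [0, 1]; identical structures have distance
    zero and structures with disjoint label multisets distance one.
    """
    if not structure_a or not structure_b:
        raise ValueError("structures must be non-empty")
    fa = _wl_features(structure_a, iterations)
    fb = _wl_features(structure_b, iterations)
    dot = sum(v * fb.get(k, 0) for k, v in fa.items())
    na = np.sqrt(sum(v * v for v in fa.values()))
    nb = np.sqrt(sum(v * v for v in fb.values()))
    return float(1.0 - dot / (na * nb))


# ---------------------------------------------------------------------------
# plug-in reward transforms


def plugin_reward_transform(raw: float | None, kind: str) -> float:
    """Transforms applied to external scorer outputs.

    ``bitscore``: the raw covariance-model bitscore is used directly; a
    scorer that reports no match at all (``raw is None``) yields the floor
    value -200.  ``rri_energy``: an interaction energy (negative is
    better) is mapped to ``(-energy) ** 3`` so that lower energies give
    steeply larger rewards.
    """
    if kind == "bitscore":
        return -200.0 if raw is None else float(raw)
    if kind == "rri_energy":
        if raw is None:
            raise ValueError("rri_energy transform needs a numeric energy")
        return float((-raw) ** 3)
    raise ValueError(f"unknown plug-in transform kind {kind!r}")


# ---------------------------------------------------------------------------
# local refinement


def _mismatch_sites(task: Task, folded: str) -> list[int]:
    return [
        i
        for i, (om, y) in enumerate(zip(task.structure_constraints, folded))
        if om != "?" and om != y
    ]


def local_improvement(
    candidate: Candidate,
    task: Task,
    engine,
    max_mismatches: int = 5,
    neighbourhood: int = 1,
    max_positions: int = 6,
) -> Candidate:
    """Exhaustive local repair of near-solutions.

    When the number of violated structure constraints is positive but at
    most ``max_mismatches``, every assignment of nucleotides to the
    unconstrained sequence positions within ``neighbourhood`` of a
    violation is tried and the candidate with minimal structure loss is
    returned (ties: first in enumeration order, which preserves the
    input assignment).  Constrained sequence positions are never touched.
    To bound the enumeration, at most ``max_positions`` free positions
    (closest to violations, then leftmost) are varied.
    """
    folded = candidate.folded_structure or engine.fold(candidate.sequence)
    mismatches = _mismatch_sites(task, folded)
    if not mismatches or len(mismatches) > max_mismatches:
        return candidate
    free = [
        i
        for i in task.free_positions
        if min(abs(i - m) for m in mismatches) <= neighbourhood
    ]
    if not free:
        return candidate
    if len(free) > max_positions:
        free = sorted(
            free, key=lambda i: (min(abs(i - m) for m in mismatches), i)
        )[:max_positions]
        free.sort()
    base = list(candidate.sequence)
    best_seq = candidate.sequence
    best_fold = folded
    best_loss = len(mismatches)
    original = tuple(base[i] for i in free)
    trials = [original] + [
        assign
        for assign in itertools.product("ACGU", repeat=len(free))
        if assign != original
    ]
    for assign in trials:
        for pos, nt in zip(free, assign):
            base[pos] = nt
        seq = "".join(base)
        fold = engine.fold(seq)
        loss = structure_loss(task.structure_constraints, fold)
        if loss < best_loss:
            best_loss, best_seq, best_fold = loss, seq, fold
            if loss == 0:
                break
    return replace(
        candidate, sequence=best_seq, folded_structure=best_fold, scores={}
    )


def gc_improvement(
    candidate: Candidate,
    task: Task,
    cfg: RewardConfig,
    engine,
) -> Candidate:
    """Greedy GC repair at unconstrained positions.

    While the GC content deviates from the desired value by more than the
    tolerance, the single mutation (A/U -> G or C to raise GC, G/C -> A
    or U to lower it) with the smallest structure-loss increase is
    applied; the procedure stops when the tolerance is met or no mutation
    moves the GC content in the right direction.
    """
    if cfg.gc_desired is None:
        raise ValueError("gc_improvement needs cfg.gc_desired")
    seq = list(candidate.sequence)
    n = len(seq)
    folded = candidate.folded_structure or engine.fold(candidate.sequence)
    loss = structure_loss(task.structure_constraints, folded)
    free = list(task.free_positions)
    while True:
        gc = sum(c in "GC" for c in seq) / n
        dev = cfg.gc_desired - gc
        if abs(dev) <= cfg.gc_tolerance:
            break
        if dev > 0:
            sources, targets = "AU", "GC"
        else:
            sources, targets = "GC", "AU"
        mutable = [i for i in free if seq[i] in sources]
        if not mutable:
            break
        best = None  # (loss_increase, position, nucleotide, fold, loss)
        for i in mutable:
            for nt in targets:
                trial = seq.copy()
                trial[i] = nt
                tseq = "".join(trial)
                tfold = engine.fold(tseq)
                tloss = structure_loss(task.structure_constraints, tfold)
                key = (tloss - loss, i, nt)
                if best is None or key < best[:3]:
                    best = (tloss - loss, i, nt, tfold, tloss)
        assert best is not None
        _, i, nt, folded, loss = best
        seq[i] = nt
    return replace(
        candidate,
        sequence="".join(seq),
        folded_structure=folded,
        scores={},
    )


# ---------------------------------------------------------------------------
# named objectives


@dataclass
class Objective:
    """A named reward function over (candidate, task)."""

    name: str
    cfg: RewardConfig
    engine: object  # FoldingEngine

    def reward(self, candidate: Candidate, task: Task) -> float:
        folded = candidate.folded_structure
        if folded is None:
            folded = self.engine.fold(candidate.sequence)
        loss = structure_loss(task.structure_constraints, folded)
        if self.name == "structure":
            return structure_reward(loss, len(task), self.cfg.alpha)
        if self.name == "structure+gc":
            if self.cfg.gc_desired is None:
                raise ValueError("structure+gc objective needs gc_desired")
            gcl = gc_loss(
                candidate.sequence, self.cfg.gc_desired, self.cfg.gc_tolerance
            )
            return combined_reward(loss, len(task), gcl, self.cfg)
        raise ValueError(f"unknown objective {self.name!r}")

    def solved(self, candidate: Candidate, task: Task) -> bool:
        folded = candidate.folded_structure
        if folded is None:
            folded = self.engine.fold(candidate.sequence)
        if structure_loss(task.structure_constraints, folded) != 0:
            return False
        if self.name == "structure+gc" or self.cfg.gc_desired is not None:
            if (
                gc_loss(
                    candidate.sequence,
                    self.cfg.gc_desired,
                    self.cfg.gc_tolerance,
                )
                > 0
            ):
                return False
        return True


def make_objective(name: str, cfg: RewardConfig, engine) -> Objective:
    if name not in ("structure", "structure+gc"):
        raise ValueError(
            f"unknown objective {name!r}; built-ins: structure, structure+gc"
        )
    if name == "structure+gc" and cfg.gc_desired is None:
        raise ValueError("structure+gc objective needs cfg.gc_desired")
    return Objective(name=name, cfg=cfg, engine=engine)
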