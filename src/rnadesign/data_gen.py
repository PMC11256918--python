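"""Synthetic training corpora and the masking pipeline.

Training tasks are derived from a corpus of (sequence, structure) pairs
by masking.  The bundled generator emulates a database-derived corpus
with uniform-random sequences in one of three length regimes (short,
long, mixed) folded by a configurable engine; a loader accepts a
user-provided two-column file of (sequence, dot-bracket) pairs for
fidelity runs with real data.

Masking proceeds in three steps per sample: (1) up to ``max_parts``
non-overlapping structure intervals, each covering up to
``max_part_fraction`` of the length, are replaced by wildcards, with the
number of parts, the positions and the lengths all uniform at random;
(2) the sequence is masked exactly where the structure remained
unmasked, producing alternating sequence/structure constraints (with
zero structure parts masked this degenerates to inverse folding: a fully
masked sequence against a complete structure); (3) a configurable
fraction of samples instead receives independent random sequence
masking, emulating design from arbitrary sequence and structure motifs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design_space import Task
from .folding import FoldingEngine

#: per-position masking probability inside a randomly masked sample
RANDOM_MASK_DENSITY = 0.5

#: length regimes of the corpus generator (nt)
LENGTH_REGIMES = {
    "short": (50, 200),
    "long": (200, 450),
    "mixed": (50, 450),
}


@dataclass
class CorpusSpec:
    n_samples: int = 100
    length_distribution: str = "mixed"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if self.length_distribution not in LENGTH_REGIMES:
            raise ValueError(
                f"unknown length_distribution "
                f"{self.length_distribution!r}; one of {sorted(LENGTH_REGIMES)}"
            )


@dataclass
class MaskingSpec:
    max_parts: int = 5
    max_part_fraction: float = 0.2
    random_mask_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not 0 < self.max_part_fraction <= 1:
            raise ValueError("max_part_fraction must lie in (0, 1]")
        if not 0 <= self.random_mask_fraction <= 1:
            raise ValueError("random_mask_fraction must lie in [0, 1]")
        if self.max_parts < 0:
            raise ValueError("max_parts must be >= 0")


def generate_corpus(
    spec: CorpusSpec, engine: FoldingEngine
) -> list[tuple[str, str]]:
    """Uniform-random sequences folded by ``engine``; seeded, deterministic."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = LENGTH_REGIMES[spec.length_distribution]
    corpus = []
    for _ in range(spec.n_samples):
        n = int(rng.integers(lo, hi + 1))
        seq = "".join(np.array(list("ACGU"))[rng.integers(0, 4, size=n)])
        corpus.append((seq, engine.fold(seq)))
    return corpus


def mask_sample(
    seq: str,
    struct: str,
    spec: MaskingSpec,
    rng: np.random.Generator,
    n_parts: int | None = None,
    force_random: bool | None = None,
) -> tuple[Task, str]:
    """Mask one (sequence, structure) pair into a training task.

    Returns the task and its category: ``inverse`` (no structure part
    masked, sequence fully masked), ``alternating`` (complementary
    sequence/structure masks) or ``random`` (independent random sequence
    masking).  ``n_parts``/``force_random`` pin the random draws for
    testing.
    """
    if len(seq) != len(struct):
        raise ValueError("sequence and structure must have equal length")
    L = len(seq)
    max_part_len = max(1, int(spec.max_part_fraction * L))
    if n_parts is None:
        n_parts = int(rng.integers(0, spec.max_parts + 1))
    struct_masked = np.zeros(L, dtype=bool)
    for _ in range(n_parts):
        length = int(rng.integers(1, max_part_len + 1))
        # uniform position among starts keeping the interval in range;
        # overlapping draws are retried a bounded number of times
        for _attempt in range(20):
            start = int(rng.integers(0, L - length + 1))
            if not struct_masked[start : start + length].any():
                struct_masked[start : start + length] = True
                break
    if force_random is None:
        force_random = bool(rng.random() < spec.random_mask_fraction)
    if force_random:
        seq_masked = rng.random(L) < RANDOM_MASK_DENSITY
        category = "random"
    else:
        seq_masked = ~struct_masked
        category = "inverse" if not struct_masked.any() else "alternating"
    phi = "".join("?" if m else c for c, m in zip(seq, seq_masked))
    omega = "".join("?" if m else c for c, m in zip(struct, struct_masked))
    return Task(phi, omega), category


@dataclass
class TrainingExample:
    task: Task
    category: str


def build_training_set(
    corpus: list[tuple[str, str]],
    spec: MaskingSpec,
    rng: np.random.Generator,
) -> list[TrainingExample]:
    """Apply the masking pipeline to every corpus entry."""
    if not corpus:
        raise ValueError("empty corpus")
    out = []
    for seq, struct in corpus:
        task, category = mask_sample(seq, struct, spec, rng)
        out.append(TrainingExample(task, category))
    return out


# ---------------------------------------------------------------------------
# file formats


def write_corpus(path, corpus: list[tuple[str, str]]) -> None:
    """Two-column tab-separated (sequence, dot-bracket) file."""
    with open(path, "w", encoding="utf-8") as fh:
        for seq, struct in corpus:
            fh.write(f"{seq}\t{struct}\n")


def read_corpus(path) -> list[tuple[str, str]]:
    corpus = []
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or len(parts[0]) != len(parts[1]):
                raise ValueError(
                    f"{path}:{ln}: expected two tab-separated columns of "
                    "equal length"
                )
            corpus.append((parts[0], parts[1]))
    return corpus


def write_tasks(path, examples: list[TrainingExample]) -> None:
    """Task file in the design-space text format, one record per task."""
    with open(path, "w", encoding="utf-8") as fh:
        for ex in examples:
            fh.write(f"# category: {ex.category}\n")
            fh.write(f"sequence: {ex.task.sequence_constraints}\n")
            fh.write(f"structure: {ex.task.structure_constraints}\n")
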