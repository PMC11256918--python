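"""Motif-based RNA design spaces.

A design space is an ordered list of *motifs*, each a pair of a sequence
constraint string over ``{A, C, G, U, ?}`` and a structure constraint
string over ``{., (, ), ?}``.  Two wildcards extend the alphabets: ``?``
marks a single unconstrained position and ``?*`` an unconstrained region
of variable (possibly zero) length.  A design space therefore describes a
family of fixed-length *tasks*; every task is obtained by replacing each
``?*`` region with a run of ``?`` symbols so that the total length falls
inside the configured bounds.

Structure constraint strings may contain any composition of brackets,
balanced or unbalanced: a lone ``(`` simply demands a paired position
without naming its partner.  No balancing validation is performed.

All user-facing positions in error messages are 1-based; internal storage
is 0-based.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

SEQ_ALPHABET = "ACGU"
SEQ_CONSTRAINT_ALPHABET = "ACGU?"
STRUCT_ALPHABET = ".()"
STRUCT_CONSTRAINT_ALPHABET = ".()?"

#: IUPAC degenerate nucleotide codes accepted in motif sequence parts.
#: A degenerate code survives parsing and rendering verbatim but is
#: relaxed to the wildcard ``?`` when a fixed-length task is instantiated
#: (tasks carry only concrete nucleotides and ``?``).
IUPAC_DEGENERATE = {
    "R": "AG", "Y": "CU", "S": "GC", "W": "AU", "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG", "N": "ACGU",
}

#: token used for a variable-length unconstrained region
VAR = "?*"


class DesignSpaceError(ValueError):
    """Base class for design-space errors."""


class ParseError(DesignSpaceError):
    """An illegal character or malformed token in a constraint string."""


class StructuralError(DesignSpaceError):
    """Sequence and structure constraint lines do not align."""


class ConfigurationError(DesignSpaceError):
    """Inconsistent or missing configuration (e.g. length bounds)."""


class RangeError(DesignSpaceError):
    """A requested length falls outside the feasible bounds."""


class StateError(DesignSpaceError):
    """An operation was called on an object in an unsuitable state."""


def tokenize(line: str, alphabet: str, channel: str) -> list[str]:
    """Split a constraint line into single-character tokens and ``?*`` tokens.

    ``*`` is only legal immediately after ``?`` (together forming the
    two-character ``?*`` token).
    """
    tokens: list[str] = []
    i = 0
    while i < len(line):
        c = line[i]
        if c == "*":
            raise ParseError(
                f"{channel} constraints: '*' at position {i + 1} (1-based) is only "
                "legal immediately after '?'"
            )
        if c == "?" and i + 1 < len(line) and line[i + 1] == "*":
            tokens.append(VAR)
            i += 2
            continue
        if c not in alphabet and c != "?":
            if channel == "sequence" and c in IUPAC_DEGENERATE:
                tokens.append(c)
                i += 1
                continue
            raise ParseError(
                f"{channel} constraints: illegal character {c!r} at position "
                f"{i + 1} (1-based); allowed: {alphabet + '?'} and '?*'"
            )
        tokens.append(c)
        i += 1
    return tokens


@dataclass(frozen=True)
class Motif:
    """A pair of aligned sequence/structure constraint fragments.

    Either both parts are the variable-length wildcard ``?*`` or both are
    fixed-length token strings of equal length.
    """

    sequence_part: str
    structure_part: str

    def __post_init__(self) -> None:
        if self.is_variable:
            if not (self.sequence_part == VAR and self.structure_part == VAR):
                raise StructuralError(
                    "a variable-length region must be unconstrained in both "
                    "channels: got "
                    f"({self.sequence_part!r}, {self.structure_part!r})"
                )
            return
        for c in self.sequence_part:
            if c not in SEQ_CONSTRAINT_ALPHABET and c not in IUPAC_DEGENERATE:
                raise ParseError(f"illegal sequence token {c!r} in motif")
        for c in self.structure_part:
            if c not in STRUCT_CONSTRAINT_ALPHABET:
                raise ParseError(f"illegal structure token {c!r} in motif")
        if len(self.sequence_part) != len(self.structure_part):
            raise StructuralError(
                "fixed-length motif parts must have equal length: "
                f"|{self.sequence_part!r}| = {len(self.sequence_part)} vs "
                f"|{self.structure_part!r}| = {len(self.structure_part)}"
            )

    @property
    def is_variable(self) -> bool:
        return self.sequence_part == VAR or self.structure_part == VAR

    @property
    def length(self) -> int:
        """Token length of a fixed motif (0 for a variable region)."""
        return 0 if self.is_variable else len(self.sequence_part)


@dataclass(frozen=True)
class Task:
    """A fixed-length instantiation of a design space.

    ``sequence_constraints`` is a string over ``{A,C,G,U,?}`` and
    ``structure_constraints`` a string of equal length over ``{.,(,),?}``;
    no variable-length wildcard remains.  The number of ``?`` in the
    sequence constraints is the number of decisions an agent has to make
    before pair-filling.
    """

    sequence_constraints: str
    structure_constraints: str

    def __post_init__(self) -> None:
        if len(self.sequence_constraints) != len(self.structure_constraints):
            raise StructuralError(
                "task channels must have equal length: "
                f"{len(self.sequence_constraints)} vs "
                f"{len(self.structure_constraints)}"
            )
        for c in self.sequence_constraints:
            if c not in SEQ_CONSTRAINT_ALPHABET:
                raise ParseError(f"illegal task sequence symbol {c!r}")
        for c in self.structure_constraints:
            if c not in STRUCT_CONSTRAINT_ALPHABET:
                raise ParseError(f"illegal task structure symbol {c!r}")

    def __len__(self) -> int:
        return len(self.sequence_constraints)

    @property
    def free_positions(self) -> tuple[int, ...]:
        """0-based indices of unconstrained sequence positions."""
        return tuple(
            i for i, c in enumerate(self.sequence_constraints) if c == "?"
        )


@dataclass
class Candidate:
    """A fully specified nucleotide sequence with optional fold and scores."""

    sequence: str
    folded_structure: str | None = None
    scores: dict[str, float] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for c in self.sequence:
            if c not in SEQ_ALPHABET:
                raise ParseError(f"illegal nucleotide {c!r} in candidate")
        if (
            self.folded_structure is not None
            and len(self.folded_structure) != len(self.sequence)
        ):
            raise StructuralError(
                "folded structure length differs from sequence length"
            )

    @property
    def gc_content(self) -> float:
        return sum(c in "GC" for c in self.sequence) / len(self.sequence)


@dataclass(frozen=True)
class DesignSpace:
    """An ordered motif sequence with total-length bounds.

    The space holds the variables and domains of the underlying constraint
    satisfaction problem: each motif carries a sequence variable and a
    structure variable; objectives (hard constraints, the folding relation,
    GC content, plug-in scores) are attached externally as relations over
    the concatenated assignment.
    """

    motifs: tuple[Motif, ...]
    min_total_length: int
    max_total_length: int

    def __post_init__(self) -> None:
        if len(self.motifs) < 1:
            raise ConfigurationError("a design space needs at least one motif")
        if self.min_total_length > self.max_total_length:
            raise ConfigurationError(
                f"min_total_length {self.min_total_length} > "
                f"max_total_length {self.max_total_length}"
            )
        if self.min_total_length < self.fixed_length:
            # lower bound silently clamped by length_bounds; only a
            # genuinely infeasible configuration is an error
            pass
        if self.fixed_length > self.max_total_length:
            raise ConfigurationError(
                f"fixed tokens occupy {self.fixed_length} nt which exceeds "
                f"max_total_length {self.max_total_length}"
            )

    @property
    def fixed_length(self) -> int:
        return sum(m.length for m in self.motifs)

    @property
    def variable_regions(self) -> tuple[int, ...]:
        """Indices of the variable-length motifs."""
        return tuple(i for i, m in enumerate(self.motifs) if m.is_variable)

    def render(self) -> tuple[str, str]:
        """Reproduce the two constraint lines (round-trip of parsing)."""
        seq = "".join(m.sequence_part for m in self.motifs)
        struct = "".join(m.structure_part for m in self.motifs)
        return seq, struct


def parse_design_space(
    sequence_line: str,
    structure_line: str,
    min_len: int | None = None,
    max_len: int | None = None,
) -> DesignSpace:
    """Parse a pair of constraint lines into a :class:`DesignSpace`.

    Motifs are the maximal runs split at ``?*`` boundaries; the two lines
    must align token-by-token, with ``?*`` regions occurring at the same
    run boundaries in both channels.  ``min_len``/``max_len`` are required
    exactly when a ``?*`` occurs.
    """
    if not sequence_line or not structure_line:
        raise ParseError("constraint lines must be non-empty")
    seq_tokens = tokenize(sequence_line, SEQ_ALPHABET, "sequence")
    struct_tokens = tokenize(structure_line, STRUCT_ALPHABET, "structure")

    seq_runs = _split_runs(seq_tokens)
    struct_runs = _split_runs(struct_tokens)
    if len(seq_runs) != len(struct_runs) or any(
        (a == VAR) != (b == VAR) for a, b in zip(seq_runs, struct_runs)
    ):
        raise StructuralError(
            "sequence and structure lines disagree on the placement of "
            "variable-length '?*' regions"
        )
    motifs = []
    for k, (a, b) in enumerate(zip(seq_runs, struct_runs)):
        if a == VAR:
            motifs.append(Motif(VAR, VAR))
            continue
        if len(a) != len(b):
            raise StructuralError(
                f"fixed-length region {k + 1} (1-based) has mismatched "
                f"lengths: sequence {len(a)} vs structure {len(b)}"
            )
        motifs.append(Motif(a, b))

    has_var = any(m.is_variable for m in motifs)
    fixed = sum(m.length for m in motifs)
    if has_var:
        if min_len is None or max_len is None:
            raise ConfigurationError(
                "a '?*' region makes the design space unbounded: "
                "min/max total length are required"
            )
        return DesignSpace(tuple(motifs), int(min_len), int(max_len))
    if min_len is not None or max_len is not None:
        if (min_len is not None and min_len > fixed) or (
            max_len is not None and max_len < fixed
        ):
            raise ConfigurationError(
                f"length bounds exclude the fixed length {fixed}"
            )
    return DesignSpace(tuple(motifs), fixed, fixed)


def _split_runs(tokens: list[str]) -> list[str]:
    """Group tokens into alternating fixed-run strings and ``?*`` markers."""
    runs: list[str] = []
    for is_var, grp in itertools.groupby(tokens, key=lambda t: t == VAR):
        if is_var:
            runs.extend(VAR for _ in grp)  # adjacent ?* stay distinct regions
        else:
            runs.append("".join(grp))
    return runs


def length_bounds(space: DesignSpace) -> tuple[int, int]:
    """Feasible total-length interval of a design space.

    The lower bound is clamped to the number of fixed tokens; without any
    variable region both bounds equal the fixed length.
    """
    lo = max(space.min_total_length, space.fixed_length)
    hi = space.max_total_length
    return lo, hi


def sample_task(
    space: DesignSpace,
    total_length: int | None = None,
    rng: np.random.Generator | None = None,
) -> Task:
    """Sample a fixed-length :class:`Task` from a design space.

    When ``total_length`` is ``None`` it is drawn uniformly from
    :func:`length_bounds`.  The surplus length beyond the fixed tokens is
    then distributed over the ``?*`` regions uniformly at random over weak
    compositions (stars and bars), i.e. every split of the surplus into
    per-region run lengths (zeros allowed) is equally likely.
    """
    if rng is None:
        rng = np.random.default_rng()
    lo, hi = length_bounds(space)
    if total_length is None:
        total_length = int(rng.integers(lo, hi + 1))
    if not lo <= total_length <= hi:
        raise RangeError(
            f"requested length {total_length} outside feasible bounds "
            f"[{lo}, {hi}]"
        )
    var_idx = space.variable_regions
    surplus = total_length - space.fixed_length
    if not var_idx:
        if surplus != 0:
            raise RangeError(
                f"space has no variable region but requested length "
                f"{total_length} != fixed length {space.fixed_length}"
            )
        lengths: dict[int, int] = {}
    else:
        lengths = dict(
            zip(var_idx, _uniform_weak_composition(surplus, len(var_idx), rng))
        )
    seq_parts = []
    struct_parts = []
    for i, m in enumerate(space.motifs):
        if m.is_variable:
            run = "?" * lengths[i]
            seq_parts.append(run)
            struct_parts.append(run)
        else:
            seq_parts.append(_relax_degenerate(m.sequence_part))
            struct_parts.append(m.structure_part)
    return Task("".join(seq_parts), "".join(struct_parts))


def _relax_degenerate(seq_part: str) -> str:
    """Degenerate IUPAC codes become ``?`` in fixed-length tasks."""
    return "".join("?" if c in IUPAC_DEGENERATE else c for c in seq_part)


def _uniform_weak_composition(
    total: int, parts: int, rng: np.random.Generator
) -> list[int]:
    """Uniform sample over weak compositions of ``total`` into ``parts``."""
    if parts == 1:
        return [total]
    if total == 0:
        return [0] * parts
    # stars and bars: choose bar positions among total + parts - 1 slots
    slots = total + parts - 1
    bars = np.sort(rng.choice(slots, size=parts - 1, replace=False))
    prev = -1
    out = []
    for b in bars:
        out.append(int(b - prev - 1))
        prev = b
    out.append(int(slots - 1 - prev))
    return out


def enumerate_tasks(space: DesignSpace) -> list[Task]:
    """Exhaustively enumerate every task instantiation of a small space.

    Intended as an oracle for testing; the number of instantiations grows
    combinatorially with the length bounds and region count.
    """
    lo, hi = length_bounds(space)
    var_idx = space.variable_regions
    tasks = []
    for total in range(lo, hi + 1):
        surplus = total - space.fixed_length
        if surplus < 0:
            continue
        if not var_idx:
            if surplus == 0:
                tasks.append(sample_task(space, total))
            continue
        for comp in _weak_compositions(surplus, len(var_idx)):
            lengths = dict(zip(var_idx, comp))
            seq = "".join(
                "?" * lengths[i]
                if m.is_variable
                else _relax_degenerate(m.sequence_part)
                for i, m in enumerate(space.motifs)
            )
            struct = "".join(
                "?" * lengths[i] if m.is_variable else m.structure_part
                for i, m in enumerate(space.motifs)
            )
            tasks.append(Task(seq, struct))
    return tasks


def _weak_compositions(total: int, parts: int):
    if parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in _weak_compositions(total - first, parts - 1):
            yield (first,) + rest


def satisfies_hard_constraints(task: Task, candidate: Candidate) -> bool:
    """Check the hard-constraint relation of a task against a candidate.

    True iff every concrete nucleotide of the task's sequence constraints
    is matched by the candidate sequence and every concrete structure
    symbol is matched by the candidate's folded structure.
    """
    if len(candidate.sequence) != len(task):
        raise StructuralError(
            f"candidate length {len(candidate.sequence)} != task length "
            f"{len(task)}"
        )
    for phi_i, x_i in zip(task.sequence_constraints, candidate.sequence):
        if phi_i != "?" and phi_i != x_i:
            return False
    needs_structure = any(c != "?" for c in task.structure_constraints)
    if needs_structure:
        if candidate.folded_structure is None:
            raise StateError(
                "task has concrete structure constraints but the candidate "
                "carries no folded structure"
            )
        for om_j, y_j in zip(
            task.structure_constraints, candidate.folded_structure
        ):
            if om_j != "?" and om_j != y_j:
                return False
    return True


def satisfies_folding_relation(candidate: Candidate, task: Task, engine) -> bool:
    """Check the folding relation: the candidate's predicted structure must
    satisfy every concrete structure symbol of the task.

    The candidate is folded with ``engine`` (its cached fold, if present
    and produced by the same engine, is not reused — the relation is
    defined through the supplied engine).
    """
    folded = engine.fold(candidate.sequence)
    return all(
        om == "?" or om == y
        for om, y in zip(task.structure_constraints, folded)
    )


# ---------------------------------------------------------------------------
# file formats


def read_design_space_text(text: str) -> tuple[str, str]:
    """Extract the two constraint lines from design-space file text.

    The format is two logical records introduced by ``sequence:`` and
    ``structure:`` headers (in that order), the constraint string on the
    following line (or inline after the header); ``#`` comment lines are
    ignored.
    """
    lines = [
        ln.strip()
        for ln in text.splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    records: dict[str, str] = {}
    order: list[str] = []
    i = 0
    while i < len(lines):
        ln = lines[i]
        for key in ("sequence", "structure"):
            if ln.lower().startswith(key + ":"):
                rest = ln[len(key) + 1 :].strip()
                if rest:
                    records[key] = rest
                else:
                    i += 1
                    if i >= len(lines):
                        raise ParseError(f"'{key}:' header without a record")
                    records[key] = lines[i]
                order.append(key)
                break
        else:
            raise ParseError(f"unexpected line in design-space file: {ln!r}")
        i += 1
    if order != ["sequence", "structure"]:
        raise ParseError(
            "design-space file must contain a 'sequence:' record followed "
            f"by a 'structure:' record; found {order}"
        )
    return records["sequence"], records["structure"]


def load_design_space(
    path, min_len: int | None = None, max_len: int | None = None
) -> DesignSpace:
    with open(path, encoding="utf-8") as fh:
        seq_line, struct_line = read_design_space_text(fh.read())
    return parse_design_space(seq_line, struct_line, min_len, max_len)


def design_space_text(space: DesignSpace) -> str:
    seq, struct = space.render()
    return f"sequence: {seq}\nstructure: {struct}\n"
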