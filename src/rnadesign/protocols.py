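"""Theophylline riboswitch library design protocol.

A transcription-regulating theophylline riboswitch construct consists of
(i) the TCT8-4 theophylline aptamer, (ii) a spacer of 6-20 nt, (iii) a
region of 10-21 nt complementary to the 3'-end of the aptamer that forms
the terminator hairpin with it, and (iv) an 8-U stretch at the 3'-end.
This module renders that construction as a motif design space, provides
the classical random library baseline (random spacer plus sampled
complement length), evaluates candidate validity on the predicted MFE
structure, and summarises libraries (valid fraction, structure
diversity, length and GC histograms).

The design-space record itself is a synthetic reconstruction: see
:func:`synthetic_riboswitch_definition`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design_space import Candidate, DesignSpace, Task, parse_design_space
from .folding import COMPLEMENT, FoldingEngine
from .rewards import structure_loss

#: TCT8-4 theophylline aptamer (42 nt) used in the published riboswitch
#: construction protocol for transcriptional activation.
THEOPHYLLINE_APTAMER = "AAGUGAUACCAGCAUCGUCUUGAUGCCCUUGGCAGCACUUCA"

#: structure constraint over the aptamer region: the inner (core) hairpin
#: of the aptamer MFE fold at positions 12-26 (1-based) is required, the
#: last 10 nt must open the terminator helix, everything else is free.
APTAMER_STRUCTURE_CONSTRAINT = "?" * 11 + "(((((.....)))))" + "?" * 6 + "(" * 10

SPACER_BOUNDS = (6, 20)
COMPLEMENT_BOUNDS = (10, 21)
U_STRETCH = 8


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[c] for c in reversed(seq))


def synthetic_riboswitch_definition() -> str:
    """Synthetic reconstruction of the riboswitch design-space record.

    The published experiment defines its design space from the shared
    motifs of six riboswitch constructs; that record is not bundled here,
    so this function rebuilds an equivalent space from the construction
    protocol itself: aptamer + variable spacer + the minimal 10-nt
    reverse complement of the aptamer 3'-end (longer complements extend
    into the following variable region) + 8-U stretch, with total length
    bounds 66-91 nt.  The structure channel demands the aptamer core
    hairpin, the 10-bp terminator helix and an unpaired U-stretch.
    """
    comp10 = reverse_complement(THEOPHYLLINE_APTAMER[-10:])
    seq = THEOPHYLLINE_APTAMER + "?*" + comp10 + "?*" + "U" * U_STRETCH
    struct = (
        APTAMER_STRUCTURE_CONSTRAINT + "?*" + ")" * 10 + "?*" + "." * U_STRETCH
    )
    return f"sequence: {seq}\nstructure: {struct}\n"


@dataclass
class RiboswitchSpace:
    """The riboswitch design space plus the protocol's per-region bounds.

    The motif language only carries global length bounds, so the rendered
    :class:`DesignSpace` is a relaxation in which the surplus length may
    be split arbitrarily between the spacer and the complement extension;
    the baseline sampler enforces the true per-region bounds.
    """

    space: DesignSpace
    aptamer_sequence: str = THEOPHYLLINE_APTAMER
    spacer_bounds: tuple[int, int] = SPACER_BOUNDS
    complement_bounds: tuple[int, int] = COMPLEMENT_BOUNDS
    u_stretch: int = U_STRETCH

    @property
    def aptamer_length(self) -> int:
        return len(self.aptamer_sequence)

    def instantiate(self, spacer_len: int, extension_len: int) -> Task:
        """Fixed-length task for given spacer/extension region lengths."""
        lengths = iter((spacer_len, extension_len))
        seq_parts, struct_parts = [], []
        for m in self.space.motifs:
            if m.is_variable:
                run = "?" * next(lengths)
                seq_parts.append(run)
                struct_parts.append(run)
            else:
                seq_parts.append(m.sequence_part)
                struct_parts.append(m.structure_part)
        return Task("".join(seq_parts), "".join(struct_parts))


def riboswitch_space(definition: str | None = None) -> RiboswitchSpace:
    """Parse a riboswitch design-space record (default: the synthetic
    reconstruction) into a :class:`RiboswitchSpace`."""
    from .design_space import read_design_space_text

    text = definition if definition is not None else synthetic_riboswitch_definition()
    seq_line, struct_line = read_design_space_text(text)
    apt = len(THEOPHYLLINE_APTAMER)
    space = parse_design_space(
        seq_line,
        struct_line,
        min_len=apt + SPACER_BOUNDS[0] + COMPLEMENT_BOUNDS[0] + U_STRETCH,
        max_len=apt + SPACER_BOUNDS[1] + COMPLEMENT_BOUNDS[1] + U_STRETCH,
    )
    return RiboswitchSpace(space=space)


def wachsmuth_sample(
    rspace: RiboswitchSpace, rng: np.random.Generator
) -> Candidate:
    """One candidate from the classical random library procedure.

    Draws a uniform random spacer of 6-20 nt and a complement length of
    10-21 nt, emits the reverse complement of the aptamer 3'-end prefix
    of that length, and concatenates aptamer + spacer + complement +
    U-stretch.
    """
    apt = rspace.aptamer_sequence
    s_lo, s_hi = rspace.spacer_bounds
    c_lo, c_hi = rspace.complement_bounds
    spacer_len = int(rng.integers(s_lo, s_hi + 1))
    spacer = "".join(
        np.array(list("ACGU"))[rng.integers(0, 4, size=spacer_len)]
    )
    comp_len = int(rng.integers(c_lo, c_hi + 1))
    complement = reverse_complement(apt[-comp_len:])
    seq = apt + spacer + complement + "U" * rspace.u_stretch
    return Candidate(
        sequence=seq,
        meta={"spacer_len": spacer_len, "complement_len": comp_len},
    )


@dataclass
class ValidityResult:
    passed: bool
    outcomes: dict[str, bool] = field(default_factory=dict)

    def __bool__(self) -> bool:
        return self.passed


def evaluate_validity(
    candidate: Candidate,
    rspace: RiboswitchSpace,
    engine: FoldingEngine,
    criteria=None,
    task: Task | None = None,
) -> ValidityResult:
    """Fold a candidate and apply the validity criteria.

    The default criteria are the structural constraints of the design
    space instantiated at the candidate's region lengths, applied to the
    MFE fold: intact aptamer core hairpin, formed terminator helix and
    unpaired U-stretch, plus the hard sequence constraints.  Custom
    ``criteria`` are (name, predicate(candidate, task)) pairs; candidates
    carry their folded structure when the predicate runs.
    """
    if task is None:
        task = _task_for_candidate(candidate, rspace)
    if candidate.folded_structure is None:
        candidate.folded_structure = engine.fold(candidate.sequence)
    if criteria is None:
        criteria = [
            ("sequence_constraints", _sequence_criterion),
            ("structure_constraints", _structure_criterion),
        ]
    outcomes = {}
    for name, predicate in criteria:
        outcomes[name] = bool(predicate(candidate, task))
    return ValidityResult(all(outcomes.values()), outcomes)


def _task_for_candidate(candidate: Candidate, rspace: RiboswitchSpace) -> Task:
    meta = candidate.meta
    if "spacer_len" in meta and "complement_len" in meta:
        spacer = meta["spacer_len"]
        extension = meta["complement_len"] - rspace.complement_bounds[0]
        return rspace.instantiate(spacer, extension)
    raise ValueError(
        "candidate carries no region lengths; pass the instantiated task "
        "explicitly"
    )


def _sequence_criterion(candidate: Candidate, task: Task) -> bool:
    return all(
        phi == "?" or phi == x
        for phi, x in zip(task.sequence_constraints, candidate.sequence)
    )


def _structure_criterion(candidate: Candidate, task: Task) -> bool:
    assert candidate.folded_structure is not None
    return (
        structure_loss(task.structure_constraints, candidate.folded_structure)
        == 0
    )


def gc_bounds(space: DesignSpace) -> tuple[float, float]:
    """Analytic extreme GC contents over all admissible lengths and
    assignments of a design space.

    Concrete nucleotides contribute their fixed GC count; every
    unconstrained position (single ``?`` or variable-region position) can
    be A/U for the minimum or G/C for the maximum.  Both extremes are
    attained at the maximal total length.
    """
    from .design_space import length_bounds

    lo, hi = length_bounds(space)
    concrete = 0
    gc_fixed = 0
    for m in space.motifs:
        if m.is_variable:
            continue
        for c in m.sequence_part:
            if c in "ACGU":
                concrete += 1
                if c in "GC":
                    gc_fixed += 1
    # min(L) = gc_fixed / L is smallest at L = hi;
    # max(L) = (gc_fixed + L - concrete) / L grows with L, largest at hi
    gc_min = min(gc_fixed / L for L in (lo, hi))
    gc_max = max((gc_fixed + L - concrete) / L for L in (lo, hi))
    return gc_min, gc_max


@dataclass
class LibraryReport:
    """Library summary.

    ``unique_structures`` counts distinct MFE dot-bracket strings among
    the *valid* candidates (the designed constructs of the library);
    ``unique_structures_all`` counts over every candidate.
    """

    n_candidates: int
    valid_fraction: float  # percentage in [0, 100]
    unique_structures: int
    unique_structures_all: int
    length_histogram: dict[int, int]
    gc_histogram: dict[float, int]
    criterion_counts: dict[str, int]

    def summary(self) -> str:
        lines = [
            f"candidates          {self.n_candidates}",
            f"valid candidates    {self.valid_fraction:.1f} %",
            f"unique structures   {self.unique_structures} "
            f"({self.unique_structures_all} incl. invalid)",
        ]
        for name, count in self.criterion_counts.items():
            lines.append(
                f"  criterion {name}: {100 * count / self.n_candidates:.1f} %"
            )
        return "\n".join(lines)


GC_BIN_WIDTH = 0.05


def library_report(
    items,
    rspace: RiboswitchSpace,
    engine: FoldingEngine,
    criteria=None,
) -> LibraryReport:
    """Summarise a candidate library.

    ``items`` are either bare candidates (carrying region lengths in
    their ``meta``) or (candidate, task) pairs.  Validity of each entry
    is recomputed with :func:`evaluate_validity`; unique structures are
    counted by exact dot-bracket string equality (no coarser structure
    abstraction), over the valid candidates and over all candidates.
    """
    n = 0
    n_valid = 0
    valid_structures = set()
    structures = set()
    length_hist: dict[int, int] = {}
    gc_hist: dict[float, int] = {}
    crit_counts: dict[str, int] = {}
    for item in items:
        if isinstance(item, tuple):
            candidate, task = item
        else:
            candidate, task = item, None
        result = evaluate_validity(
            candidate, rspace, engine, criteria=criteria, task=task
        )
        n += 1
        n_valid += result.passed
        for name, ok in result.outcomes.items():
            crit_counts[name] = crit_counts.get(name, 0) + ok
        structures.add(candidate.folded_structure)
        if result.passed:
            valid_structures.add(candidate.folded_structure)
        L = len(candidate.sequence)
        length_hist[L] = length_hist.get(L, 0) + 1
        gc_bin = round(
            int(candidate.gc_content / GC_BIN_WIDTH) * GC_BIN_WIDTH, 10
        )
        gc_hist[gc_bin] = gc_hist.get(gc_bin, 0) + 1
    if n == 0:
        raise ValueError("empty candidate list")
    return LibraryReport(
        n_candidates=n,
        valid_fraction=100.0 * n_valid / n,
        unique_structures=len(valid_structures),
        unique_structures_all=len(structures),
        length_histogram=dict(sorted(length_hist.items())),
        gc_histogram=dict(sorted(gc_hist.items())),
        criterion_counts=crit_counts,
    )


def baseline_library(
    rspace: RiboswitchSpace,
    engine: FoldingEngine,
    n_candidates: int,
    seed: int,
) -> list[tuple[Candidate, Task]]:
    """A full random-procedure library with instantiated tasks."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_candidates):
        cand = wachsmuth_sample(rspace, rng)
        out.append((cand, _task_for_candidate(cand, rspace)))
    return out
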