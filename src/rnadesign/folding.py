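"""Secondary-structure prediction engines and pairing utilities.

The package treats folding engines as interchangeable objects with a
``fold(sequence) -> dot_bracket`` operation.  Two families are provided:

* :func:`external_engine` wraps the ViennaRNA Python bindings (MFE or MEA
  prediction) when they are installed;
* :class:`NussinovEngine` is a bundled, dependency-free maximum
  base-pairing folder used as a deterministic test engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
#: pairs scored by the bundled folder: Watson-Crick plus the GU wobble pair
CANONICAL_PAIRS = {
    ("A", "U"), ("U", "A"),
    ("G", "C"), ("C", "G"),
    ("G", "U"), ("U", "G"),
}


class FoldingError(RuntimeError):
    pass


class CapabilityError(FoldingError):
    """A requested external capability is not available."""


@dataclass
class FoldingEngine:
    """A named secondary-structure predictor.

    ``fold`` maps a nucleotide string to a dot-bracket string of the same
    length with balanced brackets.
    """

    name: str
    mode: str  # one of {"MFE", "MEA", "custom"}
    fold_fn: Callable[[str], str]
    params: dict = field(default_factory=dict)

    def fold(self, sequence: str) -> str:
        structure = self.fold_fn(sequence)
        if len(structure) != len(sequence):
            raise FoldingError(
                f"engine {self.name!r} returned a structure of length "
                f"{len(structure)} for a sequence of length {len(sequence)}"
            )
        return structure


def pair_table(structure: str) -> list[int | None]:
    """Partner map of a dot-bracket string (wildcards allowed).

    Brackets are stack-matched; unmatched brackets and all ``.``/``?``
    positions map to ``None``.  Unbalanced input is legal: a design-space
    constraint may demand a paired position without naming its partner.
    Indices are 0-based.
    """
    partner: list[int | None] = [None] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if stack:
                j = stack.pop()
                partner[i] = j
                partner[j] = i
        elif c not in ".?":
            raise FoldingError(f"illegal structure character {c!r}")
    return partner


def nussinov_fold(sequence: str, min_hairpin: int = 3) -> str:
    """Maximum base-pairing structure by Nussinov dynamic programming.

    Pairs scored: Watson-Crick and GU wobble.  ``min_hairpin`` is the
    minimal number of unpaired positions enclosed by a pair (default 3,
    the standard steric minimum).  Ties are broken deterministically:
    leaving position ``j`` unpaired is preferred over pairing, and among
    pairings the earliest pairing partner wins.
    """
    seq = sequence.upper().replace("T", "U")
    n = len(seq)
    if n == 0:
        raise FoldingError("empty sequence")
    for c in seq:
        if c not in "ACGU":
            raise FoldingError(f"illegal nucleotide {c!r}")
    import numpy as np

    codes = np.array([("ACGU").index(c) for c in seq], dtype=np.int8)
    pairable = np.zeros((n, n), dtype=bool)  # pairable[k, j]: seq k with j
    for a, b in CANONICAL_PAIRS:
        pairable |= (codes[:, None] == "ACGU".index(a)) & (
            codes[None, :] == "ACGU".index(b)
        )

    dp = np.zeros((n + 1, n + 1), dtype=np.int32)  # dp[i][j], j exclusive
    for span in range(min_hairpin + 2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span  # subsequence seq[i:j], last index j-1
            best = dp[i][j - 1]  # j-1 unpaired (preferred on ties)
            ks = np.nonzero(pairable[i : j - 1 - min_hairpin, j - 1])[0]
            if ks.size:
                cands = dp[i, ks + i] + dp[ks + i + 1, j - 1] + 1
                best = max(best, int(cands.max()))
            dp[i][j] = best
    structure = ["."] * n

    def traceback(i: int, j: int) -> None:
        while j - i >= min_hairpin + 2:
            if dp[i][j] == dp[i][j - 1]:
                j -= 1
                continue
            for k in range(i, j - 1 - min_hairpin):
                if (seq[k], seq[j - 1]) in CANONICAL_PAIRS:
                    if dp[i][k] + dp[k + 1][j - 1] + 1 == dp[i][j]:
                        structure[k] = "("
                        structure[j - 1] = ")"
                        traceback(k + 1, j - 1)
                        j = k
                        break
            else:  # pragma: no cover - defensive
                raise FoldingError("traceback inconsistency")

    traceback(0, n)
    return "".join(structure)


def nussinov_engine(min_hairpin: int = 3) -> FoldingEngine:
    """The bundled deterministic test folder as an engine object."""
    return FoldingEngine(
        name="nussinov",
        mode="custom",
        fold_fn=lambda s: nussinov_fold(s, min_hairpin=min_hairpin),
        params={"min_hairpin": min_hairpin},
    )


def external_engine(kind: str = "MFE") -> FoldingEngine:
    """A ViennaRNA-backed engine for MFE or MEA structure prediction.

    Raises :class:`CapabilityError` with a pointer to the bundled engine
    when the ViennaRNA Python bindings are not installed.
    """
    kind = kind.upper()
    if kind not in ("MFE", "MEA"):
        raise FoldingError(f"unknown engine kind {kind!r}; use 'MFE' or 'MEA'")
    try:
        import RNA  # ViennaRNA python bindings
    except ImportError as exc:  # pragma: no cover - depends on environment
        raise CapabilityError(
            "ViennaRNA python bindings are not installed; use the bundled "
            "nussinov_engine() instead"
        ) from exc

    if kind == "MFE":

        def fold_fn(sequence: str) -> str:
            structure, _energy = RNA.fold(sequence)
            return structure

    else:

        def fold_fn(sequence: str) -> str:
            fc = RNA.fold_compound(sequence)
            fc.pf()
            structure, _mea = fc.MEA()
            return structure

    return FoldingEngine(
        name=f"viennarna-{kind.lower()}",
        mode=kind,
        fold_fn=fold_fn,
        params={"package": "ViennaRNA", "version": getattr(RNA, "__version__", "?")},
    )


def has_external_engine() -> bool:
    try:
        import RNA  # noqa: F401
    except ImportError:
        return False
    return True
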