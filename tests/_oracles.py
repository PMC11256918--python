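"""Shared independent oracles for the test suite."""

from rnadesign.folding import CANONICAL_PAIRS


def max_pairs_exhaustive(seq: str, min_hairpin: int = 3) -> int:
    """Brute-force maximum non-crossing canonical pairing."""

    def best(positions: tuple[int, ...]) -> int:
        if len(positions) < 2:
            return 0
        i, rest = positions[0], positions[1:]
        score = best(rest)  # i unpaired
        for idx, j in enumerate(rest):
            if j - i <= min_hairpin:
                continue
            if (seq[i], seq[j]) not in CANONICAL_PAIRS:
                continue
            score = max(
                score, 1 + best(tuple(rest[:idx])) + best(tuple(rest[idx + 1 :]))
            )
        return score

    return best(tuple(range(len(seq))))
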