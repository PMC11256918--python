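"""Reading and writing candidate libraries (FASTA + TSV sidecar)."""

from __future__ import annotations

import csv

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design_space import Candidate


def write_candidates_fasta(path, candidates: list[Candidate], prefix="cand"):
    """Write candidate sequences as FASTA records named ``prefix_<i>``."""
    records = [
        SeqRecord(Seq(c.sequence), id=f"{prefix}_{i}", description="")
        for i, c in enumerate(candidates)
    ]
    SeqIO.write(records, str(path), "fasta")


def write_candidates_tsv(path, candidates: list[Candidate], prefix="cand"):
    """Sidecar table: id, sequence, dot-bracket, length, GC, scores."""
    score_names = sorted({k for c in candidates for k in c.scores} - {"gc"})
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["id", "sequence", "structure", "length", "gc"]
            + [f"score_{k}" for k in score_names]
        )
        for i, c in enumerate(candidates):
            writer.writerow(
                [
                    f"{prefix}_{i}",
                    c.sequence,
                    c.folded_structure or "",
                    len(c.sequence),
                    f"{c.gc_content:.4f}",
                ]
                + [
                    f"{c.scores[k]:.6g}" if k in c.scores else ""
                    for k in score_names
                ]
            )


def read_fasta_sequences(path) -> list[tuple[str, str]]:
    """(id, sequence) pairs from a FASTA file, T mapped to U."""
    return [
        (rec.id, str(rec.seq).upper().replace("T", "U"))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
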