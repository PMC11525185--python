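"""File formats: FASTA, MEME minimal motifs, BED6.

Thin wrappers over Biopython; the package's in-memory types live in
:mod:`credesign.seqcore`.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seqcore import BASES, MotifModel, OneHotSequence, ScoredMatch, encode_onehot


def read_fasta(path: str | Path) -> list[OneHotSequence]:
    return [encode_onehot(str(rec.seq), name=rec.id) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path: str | Path, seqs: Iterable[OneHotSequence | tuple[str, str]]) -> None:
    records = []
    for i, s in enumerate(seqs):
        if isinstance(s, OneHotSequence):
            name, seq = s.name or f"seq_{i}", s.decode()
        else:
            name, seq = s
        records.append(SeqRecord(Seq(seq), id=name, description=""))
    SeqIO.write(records, str(path), "fasta")


def read_meme(path: str | Path) -> list[MotifModel]:
    """Read a MEME minimal-format motif file into MotifModel objects."""
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "minimal")
    out = []
    for m in parsed:
        ppm = np.array([m.pwm[b] for b in BASES]).T  # (w, 4)
        out.append(MotifModel(ppm, id=m.name or m.base_id, source="supplied"))
    return out


def write_meme(path: str | Path, motifs_: Iterable[MotifModel]) -> None:
    buf = _io.StringIO()
    buf.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
    buf.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
    for m in motifs_:
        buf.write(f"MOTIF {m.id}\n")
        # large nsites so parsers that rebuild counts keep full precision
        buf.write(f"letter-probability matrix: alength= 4 w= {m.width} "
                  "nsites= 1000000 E= 0\n")
        for row in m.ppm:
            buf.write(" ".join(f"{v:.6f}" for v in row) + "\n")
        buf.write("\n")
    Path(path).write_text(buf.getvalue())


def write_bed6(path: str | Path, matches: Iterable[ScoredMatch],
               score_scale: float = 100.0) -> None:
    """Export matches as BED6 (0-based half-open; score column scaled and
    clipped into BED's 0-1000 range)."""
    with open(path, "w") as fh:
        for m in matches:
            bed_score = int(np.clip(m.score * score_scale, 0, 1000))
            name = m.motif_id or "match"
            fh.write(f"{m.seq_id}\t{m.start}\t{m.end}\t{name}\t{bed_score}\t{m.strand}\n")
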