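"""Small sequence helpers shared across modules."""

from __future__ import annotations

from pathlib import Path
from typing import Iterator

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# A<C<G<T so that the numeric order of 2-bit big-endian k-mer codes equals
# lexicographic order of the k-mer strings.
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """2-bit codes (A=0,C=1,G=2,T=3); anything else (incl. N) is -1."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Return (id, uppercase sequence) pairs from a FASTA file."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path: str | Path, records: Iterator[tuple[str, str]] | list[tuple[str, str]],
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
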