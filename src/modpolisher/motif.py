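"""Recover the modified sequence motif from corrected loci.

Bacterial modification systems target short sequence motifs (often
pentanucleotides such as GCAGC); the loci a conservation-gated polisher
corrects should therefore pile up on the responsible motif. This module takes
the corrected positions, cuts a fixed-width window around each, orients the
windows canonically, and summarises them as a position frequency matrix with
an IUPAC consensus plus a ranked list of the k-mers overlapping the window
centers. The design is deliberately simple and auditable — a PFM and exact
k-mer counting — rather than a wrapper around a motif-discovery suite.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from modpolisher._seq import BASES, BASE_INDEX, revcomp

DEFAULT_WIDTH = 11
DEFAULT_KMER = 5

# two-base IUPAC codes, keyed by the sorted base pair
_IUPAC2 = {"AC": "M", "AG": "R", "AT": "W", "CG": "S", "CT": "Y", "GT": "K"}


@dataclass
class MotifReport:
    window_width: int
    position_frequency_matrix: np.ndarray  # 4 x width counts (rows A,C,G,T)
    consensus: str
    top_kmers: list[tuple[str, int, float]]  # (kmer, count, fraction of loci covered)
    n_windows: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "window_width": self.window_width,
            "n_windows": self.n_windows,
            "consensus": self.consensus,
            "position_frequency_matrix": {
                base: self.position_frequency_matrix[i].tolist()
                for i, base in enumerate(BASES)},
            "top_kmers": [{"kmer": k, "count": c, "fraction": f}
                          for k, c, f in self.top_kmers],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")

    def pfm_table(self) -> str:
        lines = ["pos\t" + "\t".join(BASES)]
        for j in range(self.window_width):
            lines.append(f"{j}\t" + "\t".join(
                str(int(self.position_frequency_matrix[i, j])) for i in range(4)))
        return "\n".join(lines) + "\n"


def extract_windows(genome: str, corrected_positions: Sequence[int],
                    width: int = DEFAULT_WIDTH, canonical: bool = True) -> list[str]:
    """Width-length windows centered on each corrected position.

    Windows that would overhang a contig end are dropped. With ``canonical``
    each window is replaced by the lexicographically smaller of itself and its
    reverse complement, making the downstream report invariant to the strand
    the genome happened to be written on.
    """
    if width % 2 == 0:
        raise ValueError("window width must be odd")
    half = width // 2
    genome = genome.upper()
    windows = []
    for pos in corrected_positions:
        if pos - half < 0 or pos + half >= len(genome):
            continue
        w = genome[pos - half:pos + half + 1]
        if canonical:
            w = min(w, revcomp(w))
        windows.append(w)
    return windows


def build_motif(windows: Sequence[str], k: int = DEFAULT_KMER) -> MotifReport:
    """Position frequency matrix, IUPAC consensus and center k-mer ranking.

    Consensus per column: the single base if its frequency is >= 0.75; the
    two-base IUPAC code if the top two sum to >= 0.9; else N. The k-mer table
    counts, per window, the distinct strand-canonical k-mers overlapping the
    center position; the fraction is the share of windows containing the
    k-mer there.
    """
    if not windows:
        raise ValueError("no windows to build a motif from")
    width = len(windows[0])
    if any(len(w) != width for w in windows):
        raise ValueError("windows must share one width")
    pfm = np.zeros((4, width), dtype=np.int64)
    for w in windows:
        for j, base in enumerate(w):
            if base in BASE_INDEX:
                pfm[BASE_INDEX[base], j] += 1
    n = len(windows)
    consensus = []
    for j in range(width):
        freqs = pfm[:, j] / n
        order = np.argsort(-freqs, kind="stable")
        if freqs[order[0]] >= 0.75:
            consensus.append(BASES[order[0]])
        elif freqs[order[0]] + freqs[order[1]] >= 0.9:
            pair = "".join(sorted(BASES[order[0]] + BASES[order[1]]))
            consensus.append(_IUPAC2[pair])
        else:
            consensus.append("N")
    center = width // 2
    counts: Counter[str] = Counter()
    for w in windows:
        seen = set()
        for start in range(max(0, center - k + 1), min(center, width - k) + 1):
            kmer = w[start:start + k]
            seen.add(min(kmer, revcomp(kmer)))
        counts.update(seen)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    top = [(kmer, cnt, cnt / n) for kmer, cnt in ranked]
    return MotifReport(window_width=width, position_frequency_matrix=pfm,
                       consensus="".join(consensus), top_kmers=top, n_windows=n)
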