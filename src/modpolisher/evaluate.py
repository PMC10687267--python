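"""Assembly-quality evaluation: Phred-scaled accuracy against a reference.

The quality of an assembly is summarised as ``Q = -10 * log10(errors /
aligned bases)``, the convention behind reported values such as Q40 (one
error per 10 kb). Errors are mismatches plus inserted and deleted bases
counted over the aligned blocks of a whole-genome alignment; a perfect
assembly is reported at a configurable cap (default Q60) since zero observed
errors only bounds the true error rate.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import edlib

from modpolisher._seq import read_fasta

DEFAULT_Q_CAP = 60.0

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class QualityReport:
    aligned_length: int
    mismatches: int
    insertions: int
    deletions: int
    q_score: Optional[float]   # None when nothing aligned
    identity: Optional[float]

    @property
    def total_errors(self) -> int:
        return self.mismatches + self.insertions + self.deletions


def _align_counts(assembly: str, reference: str,
                  per_event_indels: bool) -> tuple[int, int, int, int]:
    res = edlib.align(assembly, reference, mode="NW", task="path")
    matches = mismatches = ins = dels = 0
    for num, op in _CIGAR_RE.findall(res["cigar"]):
        n = int(num)
        if op == "=":
            matches += n
        elif op == "X":
            mismatches += n
        elif op == "I":  # in the assembly, absent from the reference
            ins += 1 if per_event_indels else n
        elif op == "D":
            dels += 1 if per_event_indels else n
    return matches, mismatches, ins, dels


def assembly_quality(assembly: str | Path, reference: str | Path,
                     q_cap: float = DEFAULT_Q_CAP,
                     per_event_indels: bool = False) -> QualityReport:
    """Mismatch/indel counts and Q score of ``assembly`` vs ``reference``.

    Accepts FASTA paths or raw sequences. Contigs are paired by rank (largest
    against largest); each pair is globally aligned and the error counts
    pooled. ``aligned_length`` counts base-aligned columns (match + mismatch).
    Indels are counted per base by default, per event with
    ``per_event_indels``.
    """
    asm_seqs = _load(assembly)
    ref_seqs = _load(reference)
    if not asm_seqs or not ref_seqs:
        return QualityReport(0, 0, 0, 0, None, None)
    asm_seqs.sort(key=len, reverse=True)
    ref_seqs.sort(key=len, reverse=True)
    matches = mismatches = ins = dels = 0
    for a, r in zip(asm_seqs, ref_seqs):
        m, x, i, d = _align_counts(a, r, per_event_indels)
        matches += m
        mismatches += x
        ins += i
        dels += d
    aligned = matches + mismatches
    if aligned == 0:
        return QualityReport(0, mismatches, ins, dels, None, None)
    errors = mismatches + ins + dels
    if errors == 0:
        q = q_cap
    else:
        q = min(q_cap, -10.0 * math.log10(errors / aligned))
    identity = matches / aligned
    return QualityReport(aligned_length=aligned, mismatches=mismatches,
                         insertions=ins, deletions=dels, q_score=q,
                         identity=identity)


def _load(source: str | Path) -> list[str]:
    if isinstance(source, Path):
        return [seq for _, seq in read_fasta(source)]
    s = str(source)
    try:
        is_file = "\n" not in s and Path(s).exists()
    except OSError:
        is_file = False
    if is_file:
        return [seq for _, seq in read_fasta(s)]
    return [s.upper()]
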