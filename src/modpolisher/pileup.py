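"""Per-locus pileup summary statistics from read and homolog alignments.

For every draft position we keep the allele counts of A, C, G and T seen in
the aligned nanopore reads, the mean Phred quality of those read bases, and a
second set of allele counts contributed by homolog genomes aligned to the
draft. Insertion and deletion gaps contribute nothing: the target error class
is the substitution, and indel columns are another polisher's job. The two
count tables plus the quality track are the entire evidence the correction
stage consumes.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pysam

from modpolisher._seq import encode

logger = logging.getLogger(__name__)


@dataclass
class LocusSummary:
    """Read-only view of the pileup at one draft position."""

    position: int
    draft_allele: str
    read_counts: tuple[int, int, int, int]      # A, C, G, T
    homolog_counts: tuple[int, int, int, int]   # A, C, G, T
    read_depth: int
    homolog_depth: int
    mean_quality: Optional[float]               # None when read_depth == 0


class PileupMatrix:
    """Dense per-position pileup over one draft contig.

    Columns of the two count arrays are A, C, G, T in that order.
    """

    def __init__(self, contig_id: str, draft_sequence: str):
        self.contig_id = contig_id
        self.draft_sequence = draft_sequence.upper()
        n = len(draft_sequence)
        self.read_counts = np.zeros((n, 4), dtype=np.int64)
        self.homolog_counts = np.zeros((n, 4), dtype=np.int64)
        self.qual_sum = np.zeros(n, dtype=np.float64)
        self.n_warnings = 0

    def __len__(self) -> int:
        return len(self.draft_sequence)

    @property
    def read_depth(self) -> np.ndarray:
        return self.read_counts.sum(axis=1)

    @property
    def homolog_depth(self) -> np.ndarray:
        return self.homolog_counts.sum(axis=1)

    @property
    def mean_quality(self) -> np.ndarray:
        """Arithmetic mean Phred score per position; NaN where depth is 0."""
        depth = self.read_depth
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(depth > 0, self.qual_sum / depth, np.nan)

    def locus(self, position: int) -> LocusSummary:
        depth = int(self.read_counts[position].sum())
        hdepth = int(self.homolog_counts[position].sum())
        mq = float(self.qual_sum[position] / depth) if depth > 0 else None
        return LocusSummary(
            position=position,
            draft_allele=self.draft_sequence[position],
            read_counts=tuple(int(c) for c in self.read_counts[position]),
            homolog_counts=tuple(int(c) for c in self.homolog_counts[position]),
            read_depth=depth,
            homolog_depth=hdepth,
            mean_quality=mq,
        )

    def to_tsv(self, path: str | Path) -> None:
        """Debug dump of the per-locus table."""
        mq = self.mean_quality
        with open(path, "w") as fh:
            fh.write("position\tdraft_allele\tread_A\tread_C\tread_G\tread_T\t"
                     "hom_A\thom_C\thom_G\thom_T\tmean_quality\n")
            for i in range(len(self)):
                rc = "\t".join(str(c) for c in self.read_counts[i])
                hc = "\t".join(str(c) for c in self.homolog_counts[i])
                q = f"{mq[i]:.3f}" if np.isfinite(mq[i]) else "NA"
                fh.write(f"{i}\t{self.draft_sequence[i]}\t{rc}\t{hc}\t{q}\n")


def _check_references(sam: pysam.AlignmentFile, known: set[str]) -> None:
    for name in sam.references:
        if name not in known:
            raise ValueError(f"SAM reference {name!r} is not a draft contig")


def _usable(read: pysam.AlignedSegment) -> bool:
    return not (read.is_unmapped or read.is_secondary or read.is_supplementary)


def pileup_from_read_alignments(contig_id: str, draft_sequence: str,
                                sam_path: str | Path, min_mapq: int = 0,
                                known_contigs: Optional[set[str]] = None) -> PileupMatrix:
    """Populate the read side of the pileup from a read-to-draft SAM/BAM.

    Secondary, supplementary and unmapped records are excluded; every aligned
    (M/=/X) base increments its allele counter and adds its Phred score to the
    quality mean. Indel gaps and soft clips contribute nothing; N calls are
    ignored. Records without base qualities are skipped with a warning.
    """
    matrix = PileupMatrix(contig_id, draft_sequence)
    known = known_contigs if known_contigs is not None else {contig_id}
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as sam:
        _check_references(sam, known)
        for read in sam:
            if not _usable(read) or read.reference_name != contig_id:
                continue
            if read.mapping_quality < min_mapq:
                continue
            if read.query_qualities is None:
                logger.warning("read %s has no base qualities; skipped", read.query_name)
                matrix.n_warnings += 1
                continue
            try:
                pairs = read.get_aligned_pairs(matches_only=True)
            except (ValueError, SystemError):
                logger.warning("read %s has a malformed CIGAR; skipped", read.query_name)
                matrix.n_warnings += 1
                continue
            if not pairs:
                continue
            arr = np.asarray(pairs, dtype=np.int64)
            qpos, rpos = arr[:, 0], arr[:, 1]
            codes = encode(read.query_sequence)[qpos]
            quals = np.asarray(read.query_qualities, dtype=np.float64)[qpos]
            ok = (codes >= 0) & (rpos >= 0) & (rpos < len(matrix))
            np.add.at(matrix.read_counts, (rpos[ok], codes[ok].astype(np.int64)), 1)
            np.add.at(matrix.qual_sum, rpos[ok], quals[ok])
    return matrix


def pileup_add_homologs(matrix: PileupMatrix, sam_paths: Sequence[str | Path],
                        known_contigs: Optional[set[str]] = None) -> PileupMatrix:
    """Populate the homolog side of the pileup from homolog-to-draft SAMs.

    Homolog evidence is count-only (a genome has no base qualities). A homolog
    genome — identified by its query name — contributes at most one count per
    draft position, however many alignment records it produced; indel gaps are
    ignored as for reads.
    """
    known = known_contigs if known_contigs is not None else {matrix.contig_id}
    for sam_path in sam_paths:
        covered: dict[str, np.ndarray] = {}
        with pysam.AlignmentFile(str(sam_path), check_sq=False) as sam:
            _check_references(sam, known)
            for rec in sam:
                if not _usable(rec) or rec.reference_name != matrix.contig_id:
                    continue
                try:
                    pairs = rec.get_aligned_pairs(matches_only=True)
                except (ValueError, SystemError):
                    logger.warning("homolog record %s has a malformed CIGAR; skipped",
                                   rec.query_name)
                    matrix.n_warnings += 1
                    continue
                if not pairs:
                    continue
                mask = covered.setdefault(rec.query_name,
                                          np.zeros(len(matrix), dtype=bool))
                arr = np.asarray(pairs, dtype=np.int64)
                qpos, rpos = arr[:, 0], arr[:, 1]
                codes = encode(rec.query_sequence)[qpos]
                ok = (codes >= 0) & (rpos >= 0) & (rpos < len(matrix)) & ~mask[rpos]
                np.add.at(matrix.homolog_counts,
                          (rpos[ok], codes[ok].astype(np.int64)), 1)
                mask[rpos[ok]] = True
    return matrix


def allele_discordancy(counts: Sequence[int]) -> float:
    """Fraction of non-major alleles: ``1 - max(counts) / sum(counts)``."""
    counts = np.asarray(counts)
    total = counts.sum()
    if total <= 0:
        raise ValueError("discordancy undefined at zero depth")
    return float(1.0 - counts.max() / total)


def align_reads(reads_fastq: str | Path, draft_fasta: str | Path,
                out_sam: str | Path, preset: str = "map-ont") -> Path:
    """Optional convenience: map reads to the draft with minimap2, sort, write SAM.

    All core computation accepts a SAM directly; use this only when no
    pre-computed alignment exists.
    """
    if shutil.which("minimap2") is None:
        raise RuntimeError(
            "minimap2 not found on PATH; align your reads externally and pass the SAM")
    out_sam = Path(out_sam)
    raw = subprocess.run(
        ["minimap2", "-a", "-x", preset, str(draft_fasta), str(reads_fastq)],
        check=True, capture_output=True)
    unsorted = out_sam.with_suffix(".unsorted.sam")
    unsorted.write_bytes(raw.stdout)
    pysam.sort("-O", "sam", "-o", str(out_sam), str(unsorted))
    unsorted.unlink()
    return out_sam
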