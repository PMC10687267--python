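"""Conservation-gated correction of modification-mediated mismatch errors.

A locus is a correction *candidate* when its read pileup is both discordant
(more than 5% of read bases disagree with the major allele) and of low mean
basecall quality (below Phred 15) — the two empirical signatures of an
untrained DNA modification confusing the basecaller. A candidate is actually
*corrected* only when the homolog pileup is 100% conserved on an allele that
differs from the draft and that is itself observed among the read bases: the
draft base is then replaced by that allele. Genuine strain variants are left
alone because their reads are confident (high quality, concordant) even when
every homolog disagrees with the draft; the gates are deliberately tuned for
specificity over sensitivity.

A motif-aware mode relaxes the conservation gate from 100% to 80% at loci
lying inside an occurrence of a user-supplied modified motif (e.g. CCGAC),
for the case where the modification system is known in advance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from modpolisher._seq import BASES, BASE_INDEX, read_fasta, write_fasta
from modpolisher.pileup import PileupMatrix, pileup_from_read_alignments, pileup_add_homologs

logger = logging.getLogger(__name__)

DEFAULT_DISCORDANCY_MIN = 0.05
DEFAULT_QUALITY_MAX = 15.0
DEFAULT_MIN_READ_DEPTH = 5
DEFAULT_MIN_HOMOLOG_DEPTH = 3
DEFAULT_CONSERVATION = 1.0
MOTIF_CONSERVATION = 0.8

# IUPAC codes accepted in motifs; W/S appear in real modified motifs
# (GCWGC = GCAGC/GCTGC, GCSGC), other ambiguity codes are rejected.
_IUPAC = {"A": "A", "C": "C", "G": "G", "T": "T", "W": "AT", "S": "CG"}
_IUPAC_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "W": "W", "S": "S"}


@dataclass
class CandidateLocus:
    """A potentially modified locus: discordant pileup with low quality."""

    position: int
    discordancy: float
    mean_quality: float
    homolog_consensus_allele: Optional[str]
    homolog_conservation: float
    matched_motif: bool = False


@dataclass
class Correction:
    """One applied substitution with the evidence that licensed it."""

    position: int
    old_allele: str
    new_allele: str
    homolog_conservation: float
    read_support_of_new_allele: float
    mode: str  # "default" | "motif"
    discordancy: float = 0.0
    mean_quality: float = 0.0


@dataclass
class ContigReport:
    candidates: int = 0
    corrections: int = 0
    skipped: dict = field(default_factory=lambda: {
        "conservation": 0, "consensus_tie": 0,
        "consensus_equals_draft": 0, "unseen_allele": 0})


@dataclass
class PolishReport:
    parameters: dict
    per_contig: dict[str, ContigReport] = field(default_factory=dict)
    corrections: list[tuple[str, Correction]] = field(default_factory=list)

    @property
    def n_candidates(self) -> int:
        return sum(c.candidates for c in self.per_contig.values())

    @property
    def n_corrections(self) -> int:
        return sum(c.corrections for c in self.per_contig.values())

    def to_json(self, path: str | Path) -> None:
        payload = {
            "parameters": self.parameters,
            "per_contig": {k: asdict(v) for k, v in self.per_contig.items()},
            "corrections": [dict(contig=c, **asdict(corr))
                            for c, corr in self.corrections],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")


def parse_motif(motif: str) -> list[str]:
    """Expand a motif string into per-position allowed-base strings."""
    out = []
    for ch in motif.upper():
        if ch not in _IUPAC:
            raise ValueError(
                f"unsupported motif character {ch!r} (ACGT plus IUPAC W/S only)")
        out.append(_IUPAC[ch])
    if not out:
        raise ValueError("empty motif")
    return out


def _revcomp_motif(motif: str) -> str:
    return "".join(_IUPAC_COMP[c] for c in reversed(motif.upper()))


def locus_in_motif(draft: str, position: int, motif: str) -> bool:
    """Does any motif placement (either strand) cover ``position``?

    The queried position itself is treated as a wildcard: a modification
    error at that base would otherwise break the very occurrence that marks
    it as a motif locus. All other positions of the placement must match the
    draft.
    """
    for pat in (parse_motif(motif), parse_motif(_revcomp_motif(motif))):
        m = len(pat)
        for start in range(max(0, position - m + 1), min(position, len(draft) - m) + 1):
            if all(draft[start + j] in pat[j]
                   for j in range(m) if start + j != position):
                return True
    return False


def homolog_conservation(counts: Sequence[int]) -> tuple[Optional[str], float]:
    """Consensus allele and its conservation fraction from homolog counts.

    A tie for the maximum yields an undefined consensus (None) with the
    conservation of the tied maximum.
    """
    counts = np.asarray(counts)
    total = counts.sum()
    if total <= 0:
        raise ValueError("conservation undefined at zero homolog depth")
    top = counts.max()
    winners = np.flatnonzero(counts == top)
    allele = BASES[winners[0]] if winners.size == 1 else None
    return allele, float(top / total)


def find_candidates(matrix: PileupMatrix,
                    discordancy_min: float = DEFAULT_DISCORDANCY_MIN,
                    quality_max: float = DEFAULT_QUALITY_MAX,
                    min_read_depth: int = DEFAULT_MIN_READ_DEPTH,
                    min_homolog_depth: int = DEFAULT_MIN_HOMOLOG_DEPTH,
                    ) -> list[CandidateLocus]:
    """Loci whose pileup is discordant AND low-quality, at sufficient depth.

    Both thresholds are strict: discordancy exactly at ``discordancy_min`` or
    mean quality exactly at ``quality_max`` does not qualify.
    """
    if len(matrix) == 0:
        return []
    rdepth = matrix.read_depth
    hdepth = matrix.homolog_depth
    alt = rdepth - matrix.read_counts.max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        discordancy = np.where(rdepth > 0, alt / np.maximum(rdepth, 1), 0.0)
    mq = matrix.mean_quality
    # the discordancy comparison is done on integer counts so that a pileup
    # sitting exactly on the threshold (e.g. 1 alternative base in 20) is
    # excluded regardless of floating-point representation
    mask = ((rdepth >= min_read_depth) & (hdepth >= min_homolog_depth)
            & (alt > discordancy_min * rdepth) & (mq < quality_max))
    out = []
    for pos in np.flatnonzero(mask):
        allele, conservation = homolog_conservation(matrix.homolog_counts[pos])
        out.append(CandidateLocus(
            position=int(pos),
            discordancy=float(discordancy[pos]),
            mean_quality=float(mq[pos]),
            homolog_consensus_allele=allele,
            homolog_conservation=conservation,
        ))
    return out


def apply_corrections(matrix: PileupMatrix, candidates: list[CandidateLocus],
                      motif: Optional[str] = None,
                      conservation_default: float = DEFAULT_CONSERVATION,
                      conservation_motif: float = MOTIF_CONSERVATION,
                      allow_unseen_allele: bool = False,
                      ) -> tuple[str, ContigReport, list[Correction]]:
    """Apply conservation-gated substitutions to the draft contig.

    A candidate is corrected to the homolog consensus allele iff the consensus
    is defined, differs from the draft base, meets the conservation bound of
    its mode (>= 100% by default; >= 80% inside a motif occurrence), and is
    observed among the read alleles at the locus (unless
    ``allow_unseen_allele``). Only substitutions are made, so coordinates
    never shift.
    """
    if motif is not None:
        parse_motif(motif)  # validate early
    seq = list(matrix.draft_sequence)
    report = ContigReport(candidates=len(candidates))
    corrections: list[Correction] = []
    for cand in candidates:
        pos = cand.position
        allele = cand.homolog_consensus_allele
        if allele is None:
            report.skipped["consensus_tie"] += 1
            continue
        draft_base = matrix.draft_sequence[pos]
        if allele == draft_base:
            report.skipped["consensus_equals_draft"] += 1
            continue
        in_motif = motif is not None and locus_in_motif(matrix.draft_sequence, pos, motif)
        cand.matched_motif = in_motif
        required = conservation_motif if in_motif else conservation_default
        if cand.homolog_conservation < required:
            report.skipped["conservation"] += 1
            continue
        support = matrix.read_counts[pos, BASE_INDEX[allele]]
        rdepth = matrix.read_counts[pos].sum()
        if support == 0 and not allow_unseen_allele:
            report.skipped["unseen_allele"] += 1
            continue
        seq[pos] = allele
        corrections.append(Correction(
            position=pos, old_allele=draft_base, new_allele=allele,
            homolog_conservation=cand.homolog_conservation,
            read_support_of_new_allele=float(support / rdepth) if rdepth else 0.0,
            mode="motif" if in_motif else "default",
            discordancy=cand.discordancy, mean_quality=cand.mean_quality))
    report.corrections = len(corrections)
    return "".join(seq), report, corrections


def polish(draft_fasta: str | Path, read_sam: str | Path,
           homolog_sams: Sequence[str | Path],
           motif: Optional[str] = None,
           discordancy_min: float = DEFAULT_DISCORDANCY_MIN,
           quality_max: float = DEFAULT_QUALITY_MAX,
           min_read_depth: int = DEFAULT_MIN_READ_DEPTH,
           min_homolog_depth: int = DEFAULT_MIN_HOMOLOG_DEPTH,
           conservation_default: float = DEFAULT_CONSERVATION,
           conservation_motif: float = MOTIF_CONSERVATION,
           allow_unseen_allele: bool = False,
           min_mapq: int = 0,
           ) -> tuple[list[tuple[str, str]], PolishReport]:
    """End-to-end polishing: pileup -> candidates -> gated corrections.

    Returns the polished contig records and a report. Refuses to run without
    homolog alignments — conservation is undefined without homologs.
    """
    homolog_sams = list(homolog_sams)
    if not homolog_sams:
        raise ValueError(
            "no homolog alignments supplied; conservation-gated polishing "
            "requires at least one homolog-to-draft SAM (run the selection "
            "stage, or align homolog genomes to the draft)")
    contigs = read_fasta(draft_fasta)
    if not contigs:
        raise ValueError(f"{draft_fasta}: no contigs")
    known = {name for name, _ in contigs}
    params = dict(motif=motif, discordancy_min=discordancy_min,
                  quality_max=quality_max, min_read_depth=min_read_depth,
                  min_homolog_depth=min_homolog_depth,
                  conservation_default=conservation_default,
                  conservation_motif=conservation_motif,
                  allow_unseen_allele=allow_unseen_allele, min_mapq=min_mapq)
    report = PolishReport(parameters=params)
    polished: list[tuple[str, str]] = []
    for name, seq in contigs:
        matrix = pileup_from_read_alignments(name, seq, read_sam,
                                             min_mapq=min_mapq, known_contigs=known)
        pileup_add_homologs(matrix, homolog_sams, known_contigs=known)
        candidates = find_candidates(matrix, discordancy_min, quality_max,
                                     min_read_depth, min_homolog_depth)
        new_seq, contig_report, corrections = apply_corrections(
            matrix, candidates, motif, conservation_default,
            conservation_motif, allow_unseen_allele)
        report.per_contig[name] = contig_report
        report.corrections.extend((name, c) for c in corrections)
        polished.append((name, new_seq))
        logger.info("%s: %d candidates, %d corrections", name,
                    contig_report.candidates, contig_report.corrections)
    return polished, report


def write_outputs(polished: list[tuple[str, str]], report: PolishReport,
                  out_dir: str | Path) -> dict[str, Path]:
    """Write polished FASTA, corrections TSV + BED, and the JSON report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "polished.fasta",
        "tsv": out / "corrections.tsv",
        "bed": out / "corrections.bed",
        "report": out / "polish_report.json",
    }
    write_fasta(paths["fasta"], polished)
    with open(paths["tsv"], "w") as fh:
        fh.write("contig\tposition\told_allele\tnew_allele\tdiscordancy\t"
                 "mean_quality\thomolog_conservation\tread_support\tmode\n")
        for contig, c in report.corrections:
            fh.write(f"{contig}\t{c.position}\t{c.old_allele}\t{c.new_allele}\t"
                     f"{c.discordancy:.4f}\t{c.mean_quality:.2f}\t"
                     f"{c.homolog_conservation:.4f}\t"
                     f"{c.read_support_of_new_allele:.4f}\t{c.mode}\n")
    with open(paths["bed"], "w") as fh:
        for contig, c in report.corrections:
            fh.write(f"{contig}\t{c.position}\t{c.position + 1}\t"
                     f"{c.old_allele}>{c.new_allele}\n")
    report.to_json(paths["report"])
    return paths
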