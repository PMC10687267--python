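"""Synthetic truth sets for exercising every polishing stage at desk scale.

The generator emulates the error structure of a modification-riddled nanopore
draft: a truth genome with planted occurrences of a modification motif; a
draft that carries a substitution error at the (central) modified base of a
subset of those occurrences; reads whose pileups at modified loci are
discordant (a minority of reads still call the truth base) with depressed
Phred qualities, while background positions are near-unanimous and
high-quality; homolog genomes at a controlled SNP distance that carry the
truth allele at every modified locus; and strain-variant decoy loci where
every homolog disagrees with the draft but the reads confidently support it —
the case a specific polisher must leave alone.

Reads are emitted both as FASTQ and pre-aligned SAM with exact CIGARs, so the
test suite never needs an external aligner. All randomness flows from one
seed; a fixed seed reproduces every file byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pysam

from modpolisher._seq import BASES, write_fasta

CONTIG = "contig_1"

# fixed truth->error substitution table, transversions favored
ERROR_ALLELE = {"A": "C", "C": "A", "G": "T", "T": "G"}
# decoy (strain-variant) allele carried by homologs, distinct from the draft base
DECOY_ALLELE = {"A": "G", "C": "T", "G": "A", "T": "C"}

_IUPAC_CHOICES = {"A": "A", "C": "C", "G": "G", "T": "T", "W": "AT", "S": "CG"}


@dataclass
class SynthParams:
    """Study conditions for one synthetic truth set.

    Defaults model a 50 kb draft at 30x read depth with 40 modified loci
    planted inside GCAGC occurrences, 20 strain-variant decoys, and 10
    homologs at ~99.5% ANI. Modified-locus pileups carry ~30% alternative
    alleles at Phred 6-12; background bases err at 1% with Phred 20-30.
    """

    length: int = 50_000
    gc: float = 0.5
    motif: str = "GCAGC"
    n_motif_sites: int = 60
    n_modified: int = 40
    n_decoys: int = 20
    n_homologs: int = 10
    homolog_snp_rate: float = 0.005
    modified_locus_conservation: float = 1.0  # homolog fraction carrying the truth allele
    depth: int = 30
    read_length: int = 2000
    read_error_rate: float = 0.01
    modified_minor_fraction: float = 0.3      # reads calling the truth base at a modified locus
    modified_qual: tuple[int, int] = (6, 12)
    background_qual: tuple[int, int] = (20, 30)
    margin: int = 2000                        # keep planted loci away from contig ends
    site_spacing: int = 50


@dataclass
class SyntheticTruthSet:
    truth_genome: str
    draft_genome: str
    modified_loci: list[tuple[int, str, str]]      # position, truth allele, draft-error allele
    decoy_variant_loci: list[tuple[int, str, str]]  # position, draft allele, homolog allele
    homolog_genomes: list[str]
    params: SynthParams
    seed: int
    paths: dict[str, Path] = field(default_factory=dict)

    @property
    def modified_positions(self) -> list[int]:
        return [p for p, _, _ in self.modified_loci]

    @property
    def decoy_positions(self) -> list[int]:
        return [p for p, _, _ in self.decoy_variant_loci]


def _random_genome(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p)


def _codes_to_str(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


def _instantiate_motif(motif: str, rng: np.random.Generator) -> str:
    out = []
    for ch in motif.upper():
        if ch not in _IUPAC_CHOICES:
            raise ValueError(f"motif character {ch!r} unsupported")
        choices = _IUPAC_CHOICES[ch]
        out.append(choices if len(choices) == 1 else choices[rng.integers(len(choices))])
    return "".join(out)


def read_pileup_model(locus_class: str, depth: int, rng: np.random.Generator,
                      truth_base: str = "A", error_base: Optional[str] = None,
                      params: Optional[SynthParams] = None) -> list[tuple[str, int]]:
    """Sample the (base, Phred) pileup column of one locus.

    ``background``: the truth base with probability 1 - e, otherwise a random
    other base; quality uniform over the background range. ``modified``: the
    draft-error base with probability 1 - m and the truth base with
    probability m, quality uniform over the depressed range — guaranteeing,
    in expectation, discordancy above 5% and mean quality below 15.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    p = params or SynthParams()
    if error_base is None:
        error_base = ERROR_ALLELE[truth_base]
    column = []
    if locus_class == "background":
        lo, hi = p.background_qual
        for _ in range(depth):
            if rng.random() < p.read_error_rate:
                base = BASES[(BASES.index(truth_base) + rng.integers(1, 4)) % 4]
            else:
                base = truth_base
            column.append((base, int(rng.integers(lo, hi + 1))))
    elif locus_class == "modified":
        lo, hi = p.modified_qual
        for _ in range(depth):
            base = truth_base if rng.random() < p.modified_minor_fraction else error_base
            column.append((base, int(rng.integers(lo, hi + 1))))
    else:
        raise ValueError(f"unknown locus class {locus_class!r}")
    return column


def homolog_model(truth: str, snp_rate: float, rng: np.random.Generator,
                  sv_blocks: Optional[list[tuple[int, int]]] = None,
                  protected: Optional[set[int]] = None) -> str:
    """One homolog genome: SNPs at ``snp_rate`` plus optional SV blocks.

    Each ``(position, length)`` SV block is replaced by random sequence of the
    same length, lowering structural identity without changing coordinates.
    SNPs are never placed at ``protected`` positions (the planted loci).
    """
    sv_blocks = sv_blocks or []
    ends = sorted((s, s + ln) for s, ln in sv_blocks)
    for (s1, e1), (s2, e2) in zip(ends, ends[1:]):
        if s2 < e1:
            raise ValueError("sv_blocks overlap")
    codes = np.array([BASES.index(b) for b in truth], dtype=np.int64)
    n_snps = rng.binomial(len(truth), snp_rate)
    protected = protected or set()
    placed = 0
    while placed < n_snps:
        pos = int(rng.integers(len(truth)))
        if pos in protected:
            continue
        codes[pos] = (codes[pos] + int(rng.integers(1, 4))) % 4
        placed += 1
    for start, length in sv_blocks:
        codes[start:start + length] = rng.integers(0, 4, size=length)
    return _codes_to_str(codes)


def _sam_header(length: int) -> dict:
    return {"HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": CONTIG, "LN": length}]}


def _write_homolog_sam(path: Path, name: str, seq: str, length: int) -> None:
    with pysam.AlignmentFile(str(path), "w", header=_sam_header(length)) as out:
        a = pysam.AlignedSegment(out.header)
        a.query_name = name
        a.query_sequence = seq
        a.flag = 0
        a.reference_id = 0
        a.reference_start = 0
        a.mapping_quality = 60
        a.cigarstring = f"{len(seq)}M"
        out.write(a)


def generate(params: Optional[SynthParams] = None, seed: int = 0,
             out_dir: Optional[str | Path] = None) -> SyntheticTruthSet:
    """Build one synthetic truth set; optionally write all files to ``out_dir``.

    Emits truth.fa, draft.fa, reads.fastq, reads.sam (pre-aligned to the
    draft), homolog_<i>.fa / homolog_<i>.sam, and truth_table.tsv.
    """
    p = params or SynthParams()
    rng = np.random.Generator(np.random.PCG64(seed))
    mlen = len(p.motif)
    if p.n_modified > p.n_motif_sites:
        raise ValueError("more modified loci requested than planted motif sites")
    grid = np.arange(p.margin, p.length - p.margin - mlen, p.site_spacing)
    if grid.size < p.n_motif_sites + p.n_decoys:
        raise ValueError("genome too short for the requested loci")
    slots = rng.choice(grid, size=p.n_motif_sites + p.n_decoys, replace=False)
    motif_starts = np.sort(slots[:p.n_motif_sites])
    decoy_positions = np.sort(slots[p.n_motif_sites:]) + mlen // 2

    truth_codes = _random_genome(rng, p.length, p.gc)
    for start in motif_starts:
        site = _instantiate_motif(p.motif, rng)
        for j, b in enumerate(site):
            truth_codes[start + j] = BASES.index(b)
    truth = _codes_to_str(truth_codes)

    chosen = np.sort(rng.choice(motif_starts, size=p.n_modified, replace=False))
    modified_loci = []
    draft_codes = truth_codes.copy()
    for start in chosen:
        pos = int(start) + mlen // 2
        t_allele = truth[pos]
        e_allele = ERROR_ALLELE[t_allele]
        draft_codes[pos] = BASES.index(e_allele)
        modified_loci.append((pos, t_allele, e_allele))
    draft = _codes_to_str(draft_codes)

    decoy_loci = []
    for pos in decoy_positions:
        d_allele = draft[int(pos)]
        decoy_loci.append((int(pos), d_allele, DECOY_ALLELE[d_allele]))

    protected = {pos for pos, _, _ in modified_loci} | {pos for pos, _, _ in decoy_loci}
    n_error_homologs = int(round((1.0 - p.modified_locus_conservation) * p.n_homologs))
    homologs = []
    for i in range(p.n_homologs):
        hom = list(homolog_model(truth, p.homolog_snp_rate, rng, protected=protected))
        for pos, d_allele, h_allele in decoy_loci:
            hom[pos] = h_allele
        if i < n_error_homologs:  # minority homologs carrying the draft error
            for pos, _, e_allele in modified_loci:
                hom[pos] = e_allele
        homologs.append("".join(hom))

    # tiled reads over the draft at ~depth coverage, substitution-only
    step = max(1, p.read_length // p.depth)
    starts = np.arange(0, p.length - p.read_length + 1, step)
    modified_map = {pos: (t, e) for pos, t, e in modified_loci}
    reads: list[tuple[str, int, str, np.ndarray]] = []
    bg_lo, bg_hi = p.background_qual
    mod_lo, mod_hi = p.modified_qual
    for ridx, s in enumerate(starts):
        s = int(s)
        codes = draft_codes[s:s + p.read_length].copy()
        quals = rng.integers(bg_lo, bg_hi + 1, size=p.read_length)
        errs = np.flatnonzero(rng.random(p.read_length) < p.read_error_rate)
        codes[errs] = (codes[errs] + rng.integers(1, 4, size=errs.size)) % 4
        for pos, (t_allele, e_allele) in modified_map.items():
            if s <= pos < s + p.read_length:
                off = pos - s
                base = t_allele if rng.random() < p.modified_minor_fraction else e_allele
                codes[off] = BASES.index(base)
                quals[off] = rng.integers(mod_lo, mod_hi + 1)
        reads.append((f"read_{ridx:05d}", s, _codes_to_str(codes), quals))

    result = SyntheticTruthSet(truth_genome=truth, draft_genome=draft,
                               modified_loci=modified_loci,
                               decoy_variant_loci=decoy_loci,
                               homolog_genomes=homologs, params=p, seed=seed)
    if out_dir is not None:
        result.paths = _write_files(result, reads, Path(out_dir))
    return result


def _write_files(ts: SyntheticTruthSet, reads, out_dir: Path) -> dict[str, Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    p = ts.params
    paths: dict[str, Path] = {
        "truth": out_dir / "truth.fa",
        "draft": out_dir / "draft.fa",
        "reads_fastq": out_dir / "reads.fastq",
        "reads_sam": out_dir / "reads.sam",
        "truth_table": out_dir / "truth_table.tsv",
    }
    write_fasta(paths["truth"], [(CONTIG, ts.truth_genome)])
    write_fasta(paths["draft"], [(CONTIG, ts.draft_genome)])

    with open(paths["reads_fastq"], "w") as fq:
        for name, _, seq, quals in reads:
            qstr = "".join(chr(q + 33) for q in quals)
            fq.write(f"@{name}\n{seq}\n+\n{qstr}\n")
    with pysam.AlignmentFile(str(paths["reads_sam"]), "w",
                             header=_sam_header(p.length)) as sam:
        for name, start, seq, quals in reads:
            a = pysam.AlignedSegment(sam.header)
            a.query_name = name
            a.query_sequence = seq
            a.flag = 0
            a.reference_id = 0
            a.reference_start = start
            a.mapping_quality = 60
            a.cigarstring = f"{len(seq)}M"
            a.query_qualities = [int(q) for q in quals]
            sam.write(a)

    homolog_sams = []
    homolog_fastas = []
    for i, hom in enumerate(ts.homolog_genomes):
        name = f"homolog_{i}"
        fa = out_dir / f"{name}.fa"
        samp = out_dir / f"{name}.sam"
        write_fasta(fa, [(name, hom)])
        _write_homolog_sam(samp, name, hom, p.length)
        homolog_fastas.append(fa)
        homolog_sams.append(samp)
    paths["homolog_fastas"] = homolog_fastas
    paths["homolog_sams"] = homolog_sams

    with open(paths["truth_table"], "w") as fh:
        fh.write("position\tclass\ttruth_allele\tdraft_allele\thomolog_allele\n")
        rows = ([(pos, "modified", t, e, t) for pos, t, e in ts.modified_loci]
                + [(pos, "decoy", d, d, h) for pos, d, h in ts.decoy_variant_loci])
        for pos, cls, t, d, h in sorted(rows):
            fh.write(f"{pos}\t{cls}\t{t}\t{d}\t{h}\n")
    return paths
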