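"""Pipeline orchestration: select -> align -> polish -> motif -> evaluate."""

from __future__ import annotations

import json
import logging
import shutil
import subprocess
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import edlib
import pysam

import modpolisher
from modpolisher._seq import read_fasta
from modpolisher.sketch import (build_sketch, rank_candidates, fragment_ani,
                                filter_homologs, load_sketch_db, SimilarityRecord,
                                DEFAULT_K, DEFAULT_SKETCH_SIZE, DEFAULT_HASH_SEED)
from modpolisher.correct import polish, write_outputs, PolishReport
from modpolisher.motif import extract_windows, build_motif
from modpolisher.evaluate import assembly_quality
from modpolisher.pileup import align_reads

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    draft: Path
    out_dir: Path
    reads_sam: Optional[Path] = None
    reads_fastq: Optional[Path] = None
    genomes_dir: Optional[Path] = None
    sketch_db: Optional[Path] = None
    homolog_sams: Optional[list[Path]] = None
    truth: Optional[Path] = None
    motif: Optional[str] = None
    t: int = 20
    mash_min: float = 0.95
    ani_min: float = 99.0
    asi_min: float = 90.0
    min_retained: int = 3
    k: int = DEFAULT_K
    sketch_size: int = DEFAULT_SKETCH_SIZE
    hash_seed: int = DEFAULT_HASH_SEED
    discordancy_min: float = 0.05
    quality_max: float = 15.0
    min_read_depth: int = 5
    min_homolog_depth: int = 3
    motif_width: int = 11
    motif_k: int = 5


def select_homologs(draft_fasta: Path, genomes_dir: Optional[Path] = None,
                    sketch_db: Optional[Path] = None, t: int = 20,
                    mash_min: float = 0.95, ani_min: float = 99.0,
                    asi_min: float = 90.0, min_retained: int = 3,
                    k: int = DEFAULT_K, sketch_size: int = DEFAULT_SKETCH_SIZE,
                    hash_seed: int = DEFAULT_HASH_SEED,
                    ) -> tuple[list[SimilarityRecord], dict[str, Path]]:
    """Mash screen then ANI/ASI filter over a local genome collection.

    Returns the retained records plus a genome_id -> FASTA path map for the
    genomes that came from ``genomes_dir`` (sketch-db entries carry no
    sequence, so ANI/ASI need the FASTA directory).
    """
    draft_records = read_fasta(draft_fasta)
    draft_seq = "".join(seq for _, seq in draft_records)
    draft_sketch = build_sketch(draft_seq, k, sketch_size,
                                genome_id="draft", hash_seed=hash_seed)
    paths: dict[str, Path] = {}
    database = []
    if genomes_dir is not None:
        fastas = sorted(Path(genomes_dir).glob("*.fa")) + \
            sorted(Path(genomes_dir).glob("*.fasta"))
        for fa in fastas:
            records = read_fasta(fa)
            if not records:
                continue
            seq = "".join(s for _, s in records)
            gid = fa.stem
            paths[gid] = fa
            database.append(build_sketch(seq, k, sketch_size,
                                         genome_id=gid, hash_seed=hash_seed))
    elif sketch_db is not None:
        database = load_sketch_db(sketch_db)
    else:
        raise ValueError("provide a genome directory or a sketch database")
    records = rank_candidates(draft_sketch, database, t=t, min_identity=mash_min)
    for rec in records:
        fa = paths.get(rec.genome_id)
        if fa is None:
            continue
        seq = "".join(s for _, s in read_fasta(fa))
        rec.ani, rec.asi = fragment_ani(seq, draft_seq)
    retained = filter_homologs(records, ani_min=ani_min, asi_min=asi_min,
                               min_retained=min_retained)
    return retained, paths


def write_selection_tsv(records: Sequence[SimilarityRecord], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\tmash_identity\tani\tasi\tretained\tfallback_used\n")
        for r in records:
            ani = f"{r.ani:.3f}" if r.ani is not None else "NA"
            asi = f"{r.asi:.3f}" if r.asi is not None else "NA"
            fh.write(f"{r.genome_id}\t{r.mash_identity:.5f}\t{ani}\t{asi}\t"
                     f"{int(r.retained)}\t{int(r.fallback_used)}\n")


def align_homolog_to_draft(homolog_fasta: Path, draft_fasta: Path,
                           out_sam: Path) -> Path:
    """Whole-genome homolog-to-draft alignment, written as SAM.

    Uses minimap2 (asm5 preset) when available; otherwise falls back to a
    global edit-distance alignment per contig pair, which is adequate for the
    collinear, equal-scale genomes this package targets.
    """
    if shutil.which("minimap2") is not None:
        raw = subprocess.run(["minimap2", "-a", "-x", "asm5", "--eqx",
                              str(draft_fasta), str(homolog_fasta)],
                             check=True, capture_output=True)
        out_sam.write_bytes(raw.stdout)
        return out_sam
    logger.info("minimap2 not found; using the built-in global aligner")
    draft = read_fasta(draft_fasta)
    hom = read_fasta(homolog_fasta)
    header = {"HD": {"VN": "1.6"},
              "SQ": [{"SN": name, "LN": len(seq)} for name, seq in draft]}
    draft_sorted = sorted(range(len(draft)), key=lambda i: -len(draft[i][1]))
    hom_sorted = sorted(hom, key=lambda r: -len(r[1]))
    with pysam.AlignmentFile(str(out_sam), "w", header=header) as out:
        for (hname, hseq), di in zip(hom_sorted, draft_sorted):
            res = edlib.align(hseq, draft[di][1], mode="NW", task="path")
            a = pysam.AlignedSegment(out.header)
            a.query_name = hname
            a.query_sequence = hseq
            a.flag = 0
            a.reference_id = di
            a.reference_start = 0
            a.mapping_quality = 60
            a.cigarstring = res["cigar"]
            out.write(a)
    return out_sam


def run_pipeline(config: PipelineConfig) -> dict:
    """Run select -> align/ingest -> polish -> motif -> evaluate; write a manifest."""
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": modpolisher.__version__,
                      "parameters": {k: str(v) for k, v in asdict(cfg).items()},
                      "stages": {}}

    homolog_sams: list[Path]
    if cfg.homolog_sams:
        homolog_sams = [Path(p) for p in cfg.homolog_sams]
        manifest["stages"]["select"] = {"skipped": "homolog SAMs supplied directly"}
    else:
        if cfg.genomes_dir is None and cfg.sketch_db is None:
            raise ValueError("select stage: no homolog genomes supplied "
                             "(need --genomes, --db, or --homolog-sams)")
        retained, paths = select_homologs(
            cfg.draft, cfg.genomes_dir, cfg.sketch_db, t=cfg.t,
            mash_min=cfg.mash_min, ani_min=cfg.ani_min, asi_min=cfg.asi_min,
            min_retained=cfg.min_retained, k=cfg.k, sketch_size=cfg.sketch_size,
            hash_seed=cfg.hash_seed)
        write_selection_tsv(retained, out / "selection.tsv")
        manifest["stages"]["select"] = {
            "n_retained": len(retained),
            "fallback_used": bool(retained and retained[0].fallback_used)}
        if not retained:
            raise ValueError("select stage: no homolog passed the Mash screen; "
                             "polishing without homologs is refused")
        aln_dir = out / "homolog_alignments"
        aln_dir.mkdir(exist_ok=True)
        homolog_sams = []
        for rec in retained:
            fa = paths.get(rec.genome_id)
            if fa is None:
                raise ValueError(f"select stage: no FASTA for {rec.genome_id} "
                                 "(sketch-db mode needs --genomes for alignment)")
            homolog_sams.append(align_homolog_to_draft(
                fa, cfg.draft, aln_dir / f"{rec.genome_id}.sam"))

    reads_sam = cfg.reads_sam
    if reads_sam is None:
        if cfg.reads_fastq is None:
            raise ValueError("polish stage: supply reads as SAM or FASTQ")
        reads_sam = align_reads(cfg.reads_fastq, cfg.draft, out / "reads.sam")
    polished, report = polish(cfg.draft, reads_sam, homolog_sams,
                              motif=cfg.motif,
                              discordancy_min=cfg.discordancy_min,
                              quality_max=cfg.quality_max,
                              min_read_depth=cfg.min_read_depth,
                              min_homolog_depth=cfg.min_homolog_depth)
    paths_out = write_outputs(polished, report, out)
    manifest["stages"]["polish"] = {"candidates": report.n_candidates,
                                    "corrections": report.n_corrections}

    if report.corrections:
        polished_by_name = dict(polished)
        windows = []
        for contig, corr in report.corrections:
            windows.extend(extract_windows(polished_by_name[contig],
                                           [corr.position], width=cfg.motif_width))
        if windows:
            motif_report = build_motif(windows, k=cfg.motif_k)
            motif_report.to_json(out / "motif.json")
            (out / "motif_pfm.tsv").write_text(motif_report.pfm_table())
            manifest["stages"]["motif"] = {
                "consensus": motif_report.consensus,
                "top_kmer": motif_report.top_kmers[0][0],
                "top_kmer_fraction": motif_report.top_kmers[0][2]}
    else:
        manifest["stages"]["motif"] = {"skipped": "no corrections"}

    if cfg.truth is not None:
        pre = assembly_quality(cfg.draft, cfg.truth)
        post = assembly_quality(paths_out["fasta"], cfg.truth)
        manifest["stages"]["evaluate"] = {
            "pre_polish": {"q_score": pre.q_score, "mismatches": pre.mismatches},
            "post_polish": {"q_score": post.q_score, "mismatches": post.mismatches}}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    return manifest
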