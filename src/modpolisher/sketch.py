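"""Homolog selection: MinHash sketching, Mash identity, fragment ANI/ASI.

A draft genome is screened against a local collection of candidate homologs in
two stages. A fast MinHash (Mash-style) screen ranks candidates by k-mer
Jaccard similarity and keeps the top ``t`` genomes above a Mash-identity
cutoff. Because a sampled k-mer sketch has low resolution between close
strains, survivors are re-examined at base resolution: the candidate is
chopped into fragments, each fragment is aligned to the draft, and two
statistics are computed — ANI (mean alignment identity of the fragments that
align) and ASI (the percentage of fragments that align at all, a proxy for
structural agreement). Candidates need high ANI and ASI to be retained; when
too few survive, the strict filters are waived and the Mash screen alone
decides (fallback).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import edlib
import numpy as np

from modpolisher._seq import encode, revcomp

logger = logging.getLogger(__name__)

DEFAULT_K = 21
DEFAULT_SKETCH_SIZE = 1000
DEFAULT_HASH_SEED = 42
MAX_K = 31  # 2-bit packed k-mers must fit in a 64-bit word

_M1 = np.uint64(0xFF51AFD7ED558CCD)
_M2 = np.uint64(0xC4CEB9FE1A85EC53)
_SHIFT = np.uint64(33)


@dataclass(frozen=True)
class GenomeSketch:
    """Bottom-s MinHash sketch of one genome's canonical k-mers."""

    genome_id: str
    k: int
    sketch_size: int
    hashes: np.ndarray  # sorted, strictly increasing uint64
    genome_length: int
    hash_seed: int = DEFAULT_HASH_SEED

    def __post_init__(self) -> None:
        h = np.asarray(self.hashes, dtype=np.uint64)
        if h.size > 1 and not np.all(h[1:] > h[:-1]):
            raise ValueError("sketch hashes must be strictly increasing")
        if h.size > self.sketch_size:
            raise ValueError("sketch holds more hashes than sketch_size")
        object.__setattr__(self, "hashes", h)


@dataclass
class SimilarityRecord:
    """Similarity of one candidate homolog to the draft, with its verdict."""

    genome_id: str
    mash_jaccard: float
    mash_identity: float
    ani: Optional[float] = None   # percent; None when no fragment aligned
    asi: Optional[float] = None   # percent
    retained: bool = False
    fallback_used: bool = False


def _mix64(x: np.ndarray, seed: int) -> np.ndarray:
    """Seeded 64-bit finalizer (murmur3 fmix64 on kmer XOR seed)."""
    x = x ^ np.uint64(seed & 0xFFFFFFFFFFFFFFFF)
    x = x ^ (x >> _SHIFT)
    x = x * _M1
    x = x ^ (x >> _SHIFT)
    x = x * _M2
    x = x ^ (x >> _SHIFT)
    return x


def canonical_kmer_hashes(sequence: str, k: int, hash_seed: int = DEFAULT_HASH_SEED) -> np.ndarray:
    """Sorted distinct 64-bit hashes of all canonical k-mers of ``sequence``.

    A canonical k-mer is the lexicographically smaller of the k-mer and its
    reverse complement; windows containing a non-ACGT character are skipped.
    """
    if k <= 1:
        raise ValueError("k must be >= 2")
    if k > MAX_K:
        raise ValueError(f"k must be <= {MAX_K}")
    if len(sequence) < k:
        raise ValueError("sequence shorter than k: empty sketch")
    codes = encode(sequence).astype(np.int64)
    n = len(codes) - k + 1
    # window is valid iff it contains no negative code
    bad = (codes < 0).astype(np.int64)
    cbad = np.concatenate([[0], np.cumsum(bad)])
    valid = (cbad[k:] - cbad[:-k]) == 0
    c = np.where(codes < 0, 0, codes).astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rc = np.zeros(n, dtype=np.uint64)
    four = np.uint64(4)
    three = np.uint64(3)
    for j in range(k):
        fwd = fwd * four + c[j:j + n]
    for j in range(k - 1, -1, -1):
        rc = rc * four + (three - c[j:j + n])
    canon = np.minimum(fwd, rc)[valid]
    if canon.size == 0:
        raise ValueError("no valid k-mers (sequence is all ambiguous bases)")
    return np.sort(_mix64(np.unique(canon), hash_seed))


def build_sketch(sequence: str, k: int = DEFAULT_K, sketch_size: int = DEFAULT_SKETCH_SIZE,
                 genome_id: str = "", hash_seed: int = DEFAULT_HASH_SEED) -> GenomeSketch:
    """Bottom-``sketch_size`` MinHash sketch of the canonical k-mers of ``sequence``."""
    if sketch_size < 1:
        raise ValueError("sketch_size must be >= 1")
    hashes = canonical_kmer_hashes(sequence, k, hash_seed)[:sketch_size]
    return GenomeSketch(genome_id=genome_id, k=k, sketch_size=sketch_size,
                        hashes=hashes, genome_length=len(sequence), hash_seed=hash_seed)


def mash_similarity(a: GenomeSketch, b: GenomeSketch) -> tuple[float, float]:
    """(jaccard, identity) between two sketches, Mash's merged-bottom estimator.

    The bottom ``s`` hashes of the union of the two sketches form the sample;
    the Jaccard estimate is the fraction of sampled hashes present in both
    sketches. Identity is ``1 - d`` with the Mash distance
    ``d = -(1/k) * ln(2j / (1 + j))``, clamped to [0, 1]; a disjoint pair
    (j = 0) has identity 0 by convention.
    """
    if a.k != b.k:
        raise ValueError(f"k mismatch: {a.k} != {b.k}")
    if a.hash_seed != b.hash_seed:
        raise ValueError("sketches built with different hash seeds")
    s = min(a.sketch_size, b.sketch_size)
    union = np.union1d(a.hashes, b.hashes)
    merged = union[:min(s, union.size)]
    shared = np.intersect1d(merged, np.intersect1d(a.hashes, b.hashes),
                            assume_unique=True).size
    if merged.size == 0:
        return 0.0, 0.0
    j = shared / merged.size
    if j <= 0.0:
        return 0.0, 0.0
    d = -(1.0 / a.k) * np.log(2.0 * j / (1.0 + j))
    identity = float(min(1.0, max(0.0, 1.0 - d)))
    return float(j), identity


def rank_candidates(draft: GenomeSketch, database: Sequence[GenomeSketch],
                    t: int = 20, min_identity: float = 0.95) -> list[SimilarityRecord]:
    """Top ``t`` database genomes with Mash identity strictly above ``min_identity``.

    Sorted by identity descending, ties broken by genome_id.
    """
    if not database:
        logger.warning("empty sketch database: no candidate homologs")
        return []
    records = []
    for sk in database:
        jac, ident = mash_similarity(draft, sk)
        if ident > min_identity:
            records.append(SimilarityRecord(genome_id=sk.genome_id,
                                            mash_jaccard=jac, mash_identity=ident))
    records.sort(key=lambda r: (-r.mash_identity, r.genome_id))
    return records[:t]


def fragment_ani(query: str, reference: str, fragment_length: int = 3000,
                 aligned_threshold: float = 0.80) -> tuple[Optional[float], float]:
    """FastANI-style fragment ANI and ASI of ``query`` against ``reference``.

    The query is cut into consecutive non-overlapping fragments (a terminal
    remainder shorter than half a fragment is dropped). Each fragment is
    aligned end-to-free against the reference; it counts as aligned when its
    identity ``1 - edits/len`` reaches ``aligned_threshold``. Returns
    ``(ani, asi)`` in percent; ANI is the mean identity over aligned fragments
    (None when nothing aligns), ASI the percentage of fragments that aligned.
    """
    if fragment_length < 100:
        raise ValueError("fragment_length must be >= 100")
    fragments = []
    pos = 0
    while pos + fragment_length <= len(query):
        fragments.append(query[pos:pos + fragment_length])
        pos += fragment_length
    remainder = len(query) - pos
    if remainder >= fragment_length / 2:
        fragments.append(query[pos:])
    if not fragments:
        raise ValueError("query too short: no fragments to align")
    identities = []
    aligned = 0
    for frag in fragments:
        res = edlib.align(frag, reference, mode="HW", task="distance")
        ident = 1.0 - res["editDistance"] / len(frag)
        if ident >= aligned_threshold:
            aligned += 1
            identities.append(ident)
    asi = 100.0 * aligned / len(fragments)
    if aligned == 0:
        return None, asi
    return 100.0 * float(np.mean(identities)), asi


def filter_homologs(records: list[SimilarityRecord], ani_min: float = 99.0,
                    asi_min: float = 90.0, min_retained: int = 3) -> list[SimilarityRecord]:
    """Keep records with ANI > ``ani_min`` and ASI > ``asi_min`` (strict).

    When fewer than ``min_retained`` survive, the strict filters are waived:
    every input record (the Mash-identity screen survivors) is returned with
    ``fallback_used`` set.
    """
    if not records:
        return []
    strict = [r for r in records
              if r.ani is not None and r.ani > ani_min
              and r.asi is not None and r.asi > asi_min]
    if len(strict) >= min_retained:
        strict_ids = {id(r) for r in strict}
        for r in records:
            r.retained = id(r) in strict_ids
            r.fallback_used = False
        return strict
    logger.info("only %d/%d homologs pass ANI/ASI; falling back to the Mash screen",
                len(strict), len(records))
    for r in records:
        r.retained = True
        r.fallback_used = True
    return list(records)


# ---------------------------------------------------------------------------
# sketch database persistence (versioned flat file)

_DB_MAGIC = "#modpolisher-sketches"
_DB_VERSION = "v1"


def save_sketch_db(path: str | Path, sketches: Sequence[GenomeSketch]) -> None:
    if not sketches:
        raise ValueError("refusing to write an empty sketch database")
    k = sketches[0].k
    s = sketches[0].sketch_size
    seed = sketches[0].hash_seed
    for sk in sketches:
        if (sk.k, sk.sketch_size, sk.hash_seed) != (k, s, seed):
            raise ValueError("all sketches in a database must share k/sketch_size/seed")
    with open(path, "w") as fh:
        fh.write(f"{_DB_MAGIC}\t{_DB_VERSION}\tk={k}\tsketch_size={s}\tseed={seed}\n")
        for sk in sketches:
            hashes = ",".join(format(h, "x") for h in sk.hashes)
            fh.write(f"{sk.genome_id}\t{sk.genome_length}\t{hashes}\n")


def load_sketch_db(path: str | Path) -> list[GenomeSketch]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 5 or header[0] != _DB_MAGIC or header[1] != _DB_VERSION:
            raise ValueError(f"{path}: not a modpolisher sketch database")
        meta = dict(part.split("=", 1) for part in header[2:])
        k, s, seed = int(meta["k"]), int(meta["sketch_size"]), int(meta["seed"])
        sketches = []
        for line in fh:
            gid, length, hashes = line.rstrip("\n").split("\t")
            h = np.array([int(x, 16) for x in hashes.split(",")], dtype=np.uint64)
            sketches.append(GenomeSketch(genome_id=gid, k=k, sketch_size=s,
                                         hashes=h, genome_length=int(length),
                                         hash_seed=seed))
    return sketches
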